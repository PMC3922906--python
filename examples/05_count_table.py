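"""Aggregate statistics from the packaged transporter count table.

The packaged table lists the AMT1, AMT2, NRT1/PTR and NRT2 nitrogen
transporter family members per species (20 land plants + 2 green algae).
"""

from famclade.report import LAND_PLANT_RANKS, aggregate, load_reference_counts

table, taxonomy = load_reference_counts()
print(table.df.to_string())

print("\nNRT1/PTR totals:")
print("  all species:      ", aggregate(table, "NRT1/PTR"))
print("  land-plant mean:  ", aggregate(table, "NRT1/PTR", LAND_PLANT_RANKS,
                                         "mean_rounded"))
print("  land-plant range: ",
      aggregate(table, "NRT1/PTR", LAND_PLANT_RANKS, "min"), "-",
      aggregate(table, "NRT1/PTR", LAND_PLANT_RANKS, "max"))
print("grand total over the four families:", table.total())
# The NRT1/PTR family dominates: ~54 members per land-plant genome on
# average, from 18 in the moss to 96 in soybean.
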