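"""Monophyly via the clan test, then outgroup rooting.

A clan is the unrooted analogue of a clade: leaves separable from the rest
by cutting one edge. If all outgroup homologs (here, non-plant sequences)
form one clan, the ingroup is consistent with vertical inheritance from a
single ancestral gene, and the tree can be rooted on that edge.
"""

from famclade import (
    TaxonomyTable,
    is_clan,
    monophyly_report,
    newick_string,
    parse_newick,
    root_by_outgroup,
)

taxonomy = TaxonomyTable(
    {
        "At": ("Arabidopsis thaliana", "eudicot"),
        "Os": ("Oryza sativa", "monocot"),
        "Pp": ("Physcomitrella patens", "bryophyte"),
        "Cr": ("Chlamydomonas reinhardtii", "green_algae"),
        "Hs": ("Homo sapiens", "nonplant"),
        "Sc": ("Saccharomyces cerevisiae", "nonplant"),
    }
)

tree = parse_newick(
    "((HsT1:0.9,ScT1:1.1):0.5,(CrT1:0.7,(PpT1:0.4,(OsT1:0.3,AtT1:0.3):0.2):0.2):0.3);",
    rooted=False,
)

report = monophyly_report(tree, taxonomy)
for rank, (n, clan) in report.by_rank.items():
    print(f"{rank:12s} n={n}  single clan: {clan}")
print(f"{'plant':12s} n={report.plant[0]}  single clan: {report.plant[1]}")
# Non-plant sequences forming one clan (and all plants the complementary
# clan) is the vertical-inheritance test passing for this family.

print("\nis_clan({HsT1, ScT1}):", is_clan(tree, {"HsT1", "ScT1"}))
rooted = root_by_outgroup(tree, {"HsT1", "ScT1"})
print("rooted on the non-plant clan:")
print(newick_string(rooted))
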