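"""Family-count tables and aggregate statistics.

Counts of family members per species, arranged with species rows ordered
eudicot -> monocot -> lycophyte -> bryophyte -> green algae (the
conventional presentation for land-plant comparative tables), and simple
aggregates over rank-filtered selections (sum, half-up rounded mean, min,
max).

A transcribed reference count table for the AMT1, AMT2, NRT1/PTR and NRT2
nitrogen-transporter families across 20 land plants and two green algae is
packaged with the module (:func:`load_reference_counts`).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable

import pandas as pd

from .io_formats import TaxonomyTable, read_taxonomy

__all__ = [
    "RANK_ORDER",
    "LAND_PLANT_RANKS",
    "FamilyCountTable",
    "count_table",
    "aggregate",
    "load_reference_counts",
    "write_count_table",
    "read_count_table",
]

#: Row ordering of count tables, top to bottom.
RANK_ORDER = ("eudicot", "monocot", "lycophyte", "bryophyte", "green_algae")

#: The land-plant ranks (excludes green algae and any non-plant class).
LAND_PLANT_RANKS = frozenset({"eudicot", "monocot", "lycophyte", "bryophyte"})


@dataclass
class FamilyCountTable:
    """Species x family table of non-negative member counts.

    ``df`` is indexed by species abbreviation (in rank order) with one
    column per family; ``ranks`` maps each abbreviation to its rank.
    """

    df: pd.DataFrame
    ranks: dict[str, str]

    def __post_init__(self) -> None:
        if (self.df.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.df.index.duplicated().any():
            raise ValueError("duplicate species rows")
        missing = set(self.df.index) - set(self.ranks)
        if missing:
            raise ValueError(f"species without rank: {sorted(missing)}")

    @property
    def families(self) -> list[str]:
        return list(self.df.columns)

    @property
    def species(self) -> list[str]:
        return list(self.df.index)

    def total(self) -> int:
        return int(self.df.values.sum())


def _rank_sorted(abbrevs: Iterable[str], ranks: dict[str, str]) -> list[str]:
    order = {r: i for i, r in enumerate(RANK_ORDER)}
    return sorted(abbrevs, key=lambda a: (order.get(ranks[a], len(order)), 0))


def count_table(
    assignments: list[tuple[str, str, str]], taxonomy: TaxonomyTable
) -> FamilyCountTable:
    """Tabulate ``(seq_id, species_abbrev, family)`` assignments.

    Every species in the taxonomy appears as a row (rank order preserved,
    original order within a rank); absent combinations count 0.
    """
    for _seq, abbrev, _fam in assignments:
        if abbrev not in taxonomy:
            raise KeyError(f"unknown species abbreviation {abbrev!r}")
    ranks = {ab: rank for ab, (_name, rank) in taxonomy.items()}
    families = sorted({fam for _, _, fam in assignments})
    species = _rank_sorted(ranks, ranks)
    df = pd.DataFrame(0, index=species, columns=families, dtype=int)
    for _seq, abbrev, fam in assignments:
        df.loc[abbrev, fam] += 1
    return FamilyCountTable(df=df, ranks=ranks)


def aggregate(
    table: FamilyCountTable,
    family: str,
    rank_filter: str | Iterable[str] | None = None,
    stat: str = "sum",
) -> int | float:
    """A statistic of one family's counts over a rank-filtered species set.

    ``rank_filter`` is None (all species), a single rank, or an iterable of
    ranks (e.g. :data:`LAND_PLANT_RANKS`). ``stat`` is one of ``sum``,
    ``mean_rounded`` (arithmetic mean rounded half-up to the nearest
    integer), ``min``, ``max``.
    """
    if family not in table.df.columns:
        raise KeyError(f"unknown family {family!r}")
    if rank_filter is None:
        selected = list(table.df.index)
    else:
        wanted = {rank_filter} if isinstance(rank_filter, str) else set(rank_filter)
        selected = [s for s in table.df.index if table.ranks[s] in wanted]
    if not selected:
        raise ValueError(f"no species match rank filter {rank_filter!r}")
    values = table.df.loc[selected, family]
    if stat == "sum":
        return int(values.sum())
    if stat == "mean_rounded":
        mean = Decimal(int(values.sum())) / Decimal(len(values))
        return int(mean.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    if stat == "min":
        return int(values.min())
    if stat == "max":
        return int(values.max())
    raise ValueError(f"unknown stat {stat!r}")


def write_count_table(table: FamilyCountTable, path) -> None:
    out = table.df.copy()
    out.insert(0, "rank", [table.ranks[s] for s in out.index])
    out.to_csv(path, sep="\t", index_label="abbrev")


def read_count_table(path) -> FamilyCountTable:
    df = pd.read_csv(path, sep="\t", index_col="abbrev")
    if "rank" in df.columns:
        ranks = dict(df["rank"])
        df = df.drop(columns=["rank"])
    else:
        raise ValueError(f"{path}: missing 'rank' column")
    return FamilyCountTable(df=df.astype(int), ranks=ranks)


def load_reference_counts() -> tuple[FamilyCountTable, TaxonomyTable]:
    """The packaged nitrogen-transporter count table (20 land plants + 2
    green algae x 4 families) and its taxonomy."""
    data = resources.files("famclade.data")
    with resources.as_file(data / "nitrogen_transporter_taxonomy.tsv") as p:
        taxonomy = read_taxonomy(p)
    with resources.as_file(data / "nitrogen_transporter_counts.tsv") as p:
        df = pd.read_csv(p, sep="\t", index_col="abbrev")
    ranks = {ab: rank for ab, (_n, rank) in taxonomy.items()}
    return FamilyCountTable(df=df.astype(int), ranks=ranks), taxonomy
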