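"""rpkm abundance profiles and relative abundances.

The abundance unit is rpkm = reads per kilobase *covered* per million mapped
reads: the kilobase denominator uses the union of reference bases touched by
at least one alignment, not the full gene length (a ``gene`` length
normalisation is available for sensitivity analysis). Relative abundances
are expressed over a declared denominator set of taxa (total phytoplankton,
eukaryotic phytoplankton, or picophytoplankton).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .markers import ReferenceDatabase
from .recruit import RecruitmentResult
from .taxonomy import CYANOBACTERIA

#: Plankton size-fraction labels (filter pore-size partitions, µm).
SIZE_FRACTIONS: tuple[str, ...] = ("0.2-3", "0.8-5", "5-20", "20-180", "180-2000")

#: Named denominator sets for relative abundance.
DENOMINATOR_SETS: tuple[str, ...] = (
    "total_phytoplankton",
    "eukaryotic_phytoplankton",
    "picophytoplankton",
)

#: Groups counted as picophytoplankton when using the named denominator
#: (the two picocyanobacteria plus the typically pico-sized eukaryote groups).
PICO_GROUPS: frozenset[str] = frozenset(
    {"Prochlorococcus", "Synechococcus", "chlorophytes", "haptophytes", "pelagophytes"}
)


@dataclass
class CoverageStats:
    """Read count and covered-base union for one reference."""

    reference_id: str
    n_reads: int
    covered_bases: int
    gene_length_bp: int

    def __post_init__(self) -> None:
        if not 0 <= self.covered_bases <= self.gene_length_bp:
            raise ValidationError(
                f"{self.reference_id}: covered_bases {self.covered_bases} outside "
                f"[0, {self.gene_length_bp}]"
            )
        if (self.covered_bases > 0) != (self.n_reads > 0):
            raise ValidationError(
                f"{self.reference_id}: covered_bases and n_reads must be zero together"
            )


@dataclass
class AbundanceTable:
    """Per-reference (or per-taxon) rpkm values for one sample/size fraction."""

    sample_id: str
    size_fraction: str
    values: dict[str, float]
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.size_fraction not in SIZE_FRACTIONS:
            raise ValidationError(
                f"unknown size fraction {self.size_fraction!r}; "
                f"expected one of {SIZE_FRACTIONS}"
            )
        for key, v in self.values.items():
            if v < 0:
                raise ValidationError(f"negative rpkm for {key!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "size_fraction": self.size_fraction,
                "taxon": list(self.values),
                "rpkm": list(self.values.values()),
            }
        )


@dataclass
class RelativeAbundanceTable:
    """Percentages over a denominator set; undefined when the denominator is zero."""

    denominator_set: str
    percents: dict[str, float]
    undefined: bool = False

    def total(self) -> float:
        return float(sum(self.percents.values()))


def coverage_stats(result: RecruitmentResult, db: ReferenceDatabase) -> list[CoverageStats]:
    """Per-reference read counts and covered-base unions (all refs, zeros kept)."""
    intervals: dict[str, list[tuple[int, int]]] = {rid: [] for rid in db.ids}
    counts: dict[str, int] = {rid: 0 for rid in db.ids}
    for hit in result.hits:
        if hit.reference_id not in intervals:
            raise ValidationError(f"hit to unknown reference {hit.reference_id!r}")
        intervals[hit.reference_id].append((hit.ref_start, hit.ref_end))
        counts[hit.reference_id] += 1
    out = []
    for rec in db.records:
        covered = _interval_union_size(intervals[rec.record_id])
        out.append(
            CoverageStats(
                reference_id=rec.record_id,
                n_reads=counts[rec.record_id],
                covered_bases=covered,
                gene_length_bp=rec.length_bp,
            )
        )
    return out


def _interval_union_size(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    total += cur_end - cur_start
    return total


def rpkm(
    stats: CoverageStats,
    total_mapped_reads: int,
    length_normalization: Literal["covered", "gene"] = "covered",
) -> float:
    """rpkm = n_reads / ((covered kb) x (mapped reads / 1e6)); 0 when no reads."""
    if total_mapped_reads <= 0:
        raise ValidationError("total_mapped_reads must be > 0")
    if stats.n_reads == 0:
        return 0.0
    denom_bases = stats.covered_bases if length_normalization == "covered" else stats.gene_length_bp
    return stats.n_reads / ((denom_bases / 1000.0) * (total_mapped_reads / 1e6))


def abundance_table(
    result: RecruitmentResult,
    db: ReferenceDatabase,
    sample_id: str = "sample",
    size_fraction: str = "0.2-3",
    length_normalization: Literal["covered", "gene"] = "covered",
) -> AbundanceTable:
    """Full rpkm table for one recruitment result (zero-coverage refs kept)."""
    stats = coverage_stats(result, db)
    total = result.total_mapped_reads
    values = {
        s.reference_id: (rpkm(s, total, length_normalization) if total > 0 else 0.0)
        for s in stats
    }
    return AbundanceTable(
        sample_id=sample_id,
        size_fraction=size_fraction,
        values=values,
        total_mapped_reads=total,
    )


def aggregate_by_taxon(
    table: AbundanceTable,
    db: ReferenceDatabase,
    rank_or_group: int | str = "group",
) -> AbundanceTable:
    """Sum reference rpkm into taxon rpkm.

    ``rank_or_group`` is either the string ``"group"`` (coarse group labels)
    or an integer rank index into the taxonomy path. References absent from
    the database land in ``"unclassified"``.
    """
    agg: dict[str, float] = {}
    for ref_id, value in table.values.items():
        if ref_id in db:
            tax = db[ref_id].taxonomy
            if rank_or_group == "group":
                key = tax.group
            else:
                idx = int(rank_or_group)
                key = tax.ranks[idx] if idx < len(tax.ranks) else "unclassified"
        else:
            key = "unclassified"
        agg[key] = agg.get(key, 0.0) + value
    return AbundanceTable(
        sample_id=table.sample_id,
        size_fraction=table.size_fraction,
        values=agg,
        total_mapped_reads=table.total_mapped_reads,
    )


def relative_abundance(
    aggregate: AbundanceTable,
    denominator_set: str,
    denominator_taxa: Iterable[str] | None = None,
) -> RelativeAbundanceTable:
    """Percentages of each denominator taxon over the denominator total.

    ``denominator_set`` is one of the named sets, or ``"custom"`` with
    explicit ``denominator_taxa``. An all-zero denominator yields an
    undefined-flagged table (no NaN propagation).
    """
    if denominator_set == "custom":
        if denominator_taxa is None:
            raise ValidationError("custom denominator requires denominator_taxa")
        taxa = list(denominator_taxa)
    elif denominator_set == "total_phytoplankton":
        taxa = list(aggregate.values)
    elif denominator_set == "eukaryotic_phytoplankton":
        taxa = [t for t in aggregate.values if t not in CYANOBACTERIA]
    elif denominator_set == "picophytoplankton":
        taxa = [t for t in aggregate.values if t in PICO_GROUPS]
    else:
        raise ValidationError(
            f"unknown denominator set {denominator_set!r}; expected one of "
            f"{DENOMINATOR_SETS + ('custom',)}"
        )
    total = sum(aggregate.values.get(t, 0.0) for t in taxa)
    if total <= 0:
        return RelativeAbundanceTable(
            denominator_set=denominator_set,
            percents={t: 0.0 for t in taxa},
            undefined=True,
        )
    percents = {t: 100.0 * aggregate.values.get(t, 0.0) / total for t in taxa}
    return RelativeAbundanceTable(denominator_set=denominator_set, percents=percents)
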