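"""Phototroph-fraction ratio statistics.

The photosynthetic fraction of a community (or of one taxon) is estimated by
dividing the rpkm of a photosynthesis-specific single-copy gene by the rpkm
of universal single-copy housekeeping genes measured on the same reads:
psbO / recA for bacteria, psbO over the mean of 25 ribosomal-protein genes
for eukaryotes, and chloroplast/mitochondrial Rieske (petC and its
mitochondrial homologue) as an alternative eukaryote statistic. Under
single-copy genes the raw ratio estimates the phototroph cell fraction;
copy-number variation (psbO 1-2, petC 2-3) scales it proportionally, so raw
values above 1 are possible and both raw and clamped values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Mapping, Sequence

from .abundance import AbundanceTable
from .errors import ValidationError
from .markers import ReferenceDatabase, RIBOSOMAL_PROTEIN_GENES


@dataclass(frozen=True)
class RatioStatistic:
    """A phototroph-fraction estimate (raw and clamped to [0, 1])."""

    numerator_gene: str
    denominator_genes: tuple[str, ...]
    scope: str  # "whole_bacteria" | "whole_eukaryotes" | "taxon:<label>"
    raw_ratio: float
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined and self.raw_ratio < 0:
            raise ValidationError("raw_ratio must be >= 0")

    @property
    def clamped_fraction(self) -> float:
        return min(self.raw_ratio, 1.0) if not self.undefined else float("nan")


def _ratio(num: float, den: float, numerator: str, denominators: tuple[str, ...], scope: str) -> RatioStatistic:
    if den <= 0:
        return RatioStatistic(numerator, denominators, scope, 0.0, undefined=True)
    return RatioStatistic(numerator, denominators, scope, num / den)


def phototroph_fraction_bacteria(psbo_rpkm: float, reca_rpkm: float) -> RatioStatistic:
    """Cyanobacterial share of the bacterioplankton: psbO rpkm / recA rpkm."""
    return _ratio(psbo_rpkm, reca_rpkm, "psbO", ("recA",), "whole_bacteria")


def phototroph_fraction_eukaryotes(
    psbo_rpkm: float,
    ribo_rpkms: Sequence[float],
    absent_flags: Sequence[bool] | None = None,
) -> RatioStatistic:
    """Phytoplankton share of eukaryotes: psbO over the mean ribosomal-protein rpkm.

    Genes explicitly flagged absent are excluded from the mean; otherwise a
    zero observation counts as a zero (not missing).
    """
    if absent_flags is not None:
        values = [v for v, absent in zip(ribo_rpkms, absent_flags) if not absent]
    else:
        values = list(ribo_rpkms)
    if not values or all(v == 0 for v in values):
        return RatioStatistic("psbO", RIBOSOMAL_PROTEIN_GENES, "whole_eukaryotes", 0.0, undefined=True)
    return _ratio(psbo_rpkm, fmean(values), "psbO", RIBOSOMAL_PROTEIN_GENES, "whole_eukaryotes")


def rieske_ratio(chloro_petc_rpkm: float, mito_rieske_rpkm: float) -> RatioStatistic:
    """Chloroplast vs mitochondrial Rieske subunit ratio.

    Every eukaryotic cell carries the mitochondrial homologue; phototrophs
    additionally carry the chloroplast form, so the ratio estimates the
    phototroph fraction (times the petC copy number, typically 2-3).
    """
    return _ratio(
        chloro_petc_rpkm, mito_rieske_rpkm,
        "petC_chloroplast", ("rieske_mitochondrial",), "whole_eukaryotes",
    )


def fraction_by_taxon(
    gene_tables: Mapping[str, AbundanceTable],
    dbs: Mapping[str, ReferenceDatabase],
    taxon: str,
    numerator_gene: str = "psbO",
    denominator_genes: Sequence[str] | None = None,
) -> RatioStatistic:
    """Phototroph fraction within one taxon (group label or rank label).

    Both numerator and denominator rpkm are restricted to references whose
    taxonomy carries ``taxon`` before the ratio is formed. The denominator
    is the mean across ``denominator_genes`` of their per-gene taxon totals.
    Undefined when the taxon contributes nothing to the denominator.
    """
    if denominator_genes is None:
        denominator_genes = [g for g in gene_tables if g != numerator_gene]
    denominator_genes = tuple(denominator_genes)
    if numerator_gene not in gene_tables:
        raise ValidationError(f"no abundance table for {numerator_gene!r}")

    def taxon_total(gene: str) -> float:
        table = gene_tables[gene]
        db = dbs[gene]
        total = 0.0
        for ref_id, value in table.values.items():
            if ref_id in db:
                tax = db[ref_id].taxonomy
                if tax.group == taxon or taxon in tax.ranks:
                    total += value
        return total

    num = taxon_total(numerator_gene)
    den_values = [taxon_total(g) for g in denominator_genes]
    if not den_values or all(v == 0 for v in den_values):
        return RatioStatistic(
            numerator_gene, denominator_genes, f"taxon:{taxon}", 0.0, undefined=True
        )
    return _ratio(num, fmean(den_values), numerator_gene, denominator_genes, f"taxon:{taxon}")


def ratios_frame(stats: Sequence[RatioStatistic]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "scope": s.scope,
                "numerator_gene": s.numerator_gene,
                "denominator_genes": ",".join(s.denominator_genes),
                "raw_ratio": s.raw_ratio if not s.undefined else float("nan"),
                "clamped_fraction": s.clamped_fraction,
                "flags": "undefined" if s.undefined else "",
            }
            for s in stats
        ]
    )
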