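"""End-to-end convenience pipelines: simulate -> recruit -> profile -> ratios.

These wire the modules together the way the command-line ``demo`` runs them
and the way the validation experiments use them: generate a community with
known truth, recruit its reads to the marker databases, convert to rpkm,
aggregate by group, and express relative abundances and phototroph-fraction
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

from .abundance import AbundanceTable, abundance_table, aggregate_by_taxon, relative_abundance
from .markers import ReferenceDatabase
from .ratios import RatioStatistic, phototroph_fraction_bacteria
from .recruit import RecruitmentParams, RecruitmentResult, recruit_multi
from .simulate import (
    CommunityTruth,
    SimulatedReferences,
    TaxonSpec,
    simulate_reads,
    simulate_reference_set,
)


@dataclass
class ProfileRun:
    """Everything produced by one simulate-recruit-profile run."""

    taxa: list[TaxonSpec]
    refs: SimulatedReferences
    truth: CommunityTruth
    results: dict[str, RecruitmentResult]
    ref_tables: dict[str, AbundanceTable]
    group_tables: dict[str, AbundanceTable]

    def group_percents(self, gene: str, denominator_set: str = "total_phytoplankton") -> dict[str, float]:
        rel = relative_abundance(self.group_tables[gene], denominator_set)
        return rel.percents

    def true_group_percents(self) -> dict[str, float]:
        return {g: 100.0 * f for g, f in self.truth.group_fractions(self.taxa).items()}


def profile_community(
    taxa: list[TaxonSpec],
    n_reads: int = 100_000,
    read_length: int = 100,
    error_rate: float = 0.01,
    divergence: float = 0.15,
    seed: int = 1,
    genes: tuple[str, ...] = ("psbO",),
    params: RecruitmentParams | None = None,
    sample_id: str = "sim",
    size_fraction: str = "0.2-3",
) -> ProfileRun:
    """Simulate a community and profile it with the given marker genes.

    The reference set uses ``seed`` and the read draw ``seed + 1`` so that
    the same community can be resampled while keeping its references.
    """
    refs = simulate_reference_set(taxa, divergence=divergence, seed=seed, genes=list(genes))
    reads, truth = simulate_reads(
        taxa, refs, n_reads=n_reads, read_length=read_length,
        error_rate=error_rate, seed=seed + 1, genes=list(genes),
    )
    dbs = {g: refs.databases[g] for g in genes if g in refs.databases}
    results = recruit_multi(reads, dbs, params)
    ref_tables = {
        g: abundance_table(results[g], dbs[g], sample_id=sample_id, size_fraction=size_fraction)
        for g in dbs
    }
    group_tables = {g: aggregate_by_taxon(ref_tables[g], dbs[g], "group") for g in dbs}
    return ProfileRun(
        taxa=taxa, refs=refs, truth=truth, results=results,
        ref_tables=ref_tables, group_tables=group_tables,
    )


def bacterial_phototroph_ratio(run: ProfileRun) -> RatioStatistic:
    """psbO/recA ratio from a run profiled with both genes."""
    psbo = sum(run.ref_tables["psbO"].values.values()) if "psbO" in run.ref_tables else 0.0
    reca = sum(run.ref_tables["recA"].values.values())
    return phototroph_fraction_bacteria(psbo, reca)
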