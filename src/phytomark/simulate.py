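"""Mock plankton communities with known truth.

The generator encodes the abundance model the marker-gene method relies on:
the expected read share of a taxon in a shotgun metagenome is proportional
to its cell abundance x the marker's per-genome copy number x the marker's
length. Single-copy markers (psbO, recA, ribosomal proteins) therefore read
out cell fractions directly, while rRNA genes - whose effective copy number
spans one to tens of thousands across protists - do not. Reference sets are
evolved down a random coalescent tree under Jukes-Cantor substitutions so
that the mean pairwise identity of the references is controlled exactly.

Everything is driven by one integer seed; reruns are byte-identical.

Desk-scale defaults (documented in the methods note): 450 nt markers,
100 bp reads, a 6-taxon surface-ocean community dominated by
picocyanobacteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ValidationError
from .markers import GENES, MarkerRecord, ReferenceDatabase, RIBOSOMAL_PROTEIN_GENES
from .placement import ReferenceAlignment, ReferenceTree
from .recruit import Read
from .taxonomy import GROUPS, TaxonomyPath

#: Default simulated marker length (nt); inside the observed psbO catalogue
#: range (94-733 bp, mean 473) and shared by all genes for desk-scale runs.
DEFAULT_GENE_LENGTH = 450

#: Representative cell diameters (µm) per group for optical simulations.
GROUP_DIAMETER_UM: dict[str, float] = {
    "Prochlorococcus": 0.6,
    "Synechococcus": 1.0,
    "other_cyanobacteria": 1.5,
    "chlorophytes": 1.5,
    "pelagophytes": 2.0,
    "haptophytes": 4.0,
    "chrysophytes": 5.0,
    "cryptophytes": 6.0,
    "dictyochophytes": 8.0,
    "diatoms": 15.0,
    "dinoflagellates": 25.0,
    "heterotrophic_bacteria": 0.5,
    "other": 5.0,
}

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]


@dataclass
class TaxonSpec:
    """One community member: identity, cell fraction and per-gene copy numbers."""

    name: str
    group: str
    domain: str  # "bacteria" | "eukaryote"
    photosynthetic: bool
    cell_fraction: float
    copies: dict[str, int] = field(default_factory=dict)
    gene_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.domain not in ("bacteria", "eukaryote"):
            raise ValidationError(f"domain must be bacteria|eukaryote, got {self.domain!r}")
        if not 0 <= self.cell_fraction <= 1:
            raise ValidationError("cell_fraction must be in [0, 1]")
        for gene, c in self.copies.items():
            if gene not in GENES:
                raise ValidationError(f"unknown gene {gene!r}")
            if c < 0:
                raise ValidationError(f"negative copy number for {gene!r}")
        if not self.photosynthetic and self.copies.get("psbO", 0) > 0:
            raise ValidationError(
                f"{self.name!r} is not photosynthetic but carries psbO"
            )
        if self.copies.get("psbO", 0) > 2:
            raise ValidationError("psbO copy number is bounded by 2")

    def length(self, gene: str) -> int:
        return self.gene_lengths.get(gene, DEFAULT_GENE_LENGTH)

    @property
    def taxonomy(self) -> TaxonomyPath:
        domain_rank = "Bacteria" if self.domain == "bacteria" else "Eukaryota"
        return TaxonomyPath((domain_rank, self.group, self.name), self.group)


def _check_fractions(taxa: list[TaxonSpec]) -> None:
    total = sum(t.cell_fraction for t in taxa)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"cell fractions sum to {total}, expected 1")
    if len({t.name for t in taxa}) != len(taxa):
        raise ValidationError("taxon names must be unique")


def default_phytoplankton_community() -> list[TaxonSpec]:
    """Six-taxon surface-ocean mock community (picocyanobacteria-dominated).

    Copy numbers: psbO and recA single copy; 16S at 2 per cyanobacterium;
    effective 18S copies spanning the chlorophyte-to-dinoflagellate range.
    """
    return [
        TaxonSpec("Prochlorococcus_A", "Prochlorococcus", "bacteria", True, 0.35,
                  {"psbO": 1, "recA": 1, "rRNA_16S": 2}),
        TaxonSpec("Synechococcus_A", "Synechococcus", "bacteria", True, 0.20,
                  {"psbO": 1, "recA": 1, "rRNA_16S": 2}),
        TaxonSpec("Chlorophyte_A", "chlorophytes", "eukaryote", True, 0.18,
                  {"psbO": 1, "rRNA_18S": 2}),
        TaxonSpec("Haptophyte_A", "haptophytes", "eukaryote", True, 0.12,
                  {"psbO": 1, "rRNA_18S": 20}),
        TaxonSpec("Diatom_A", "diatoms", "eukaryote", True, 0.10,
                  {"psbO": 1, "rRNA_18S": 100}),
        TaxonSpec("Dinoflagellate_A", "dinoflagellates", "eukaryote", True, 0.05,
                  {"psbO": 1, "rRNA_18S": 1000}),
    ]


def uniform_copy_community(
    biased_taxon: str | None = None, bias_copies: int = 100
) -> list[TaxonSpec]:
    """The default community with all rRNA copy numbers set to 1, except an
    optional single taxon raised to ``bias_copies`` (the copy-number bias
    experiment in miniature)."""
    taxa = default_phytoplankton_community()
    for t in taxa:
        for gene in ("rRNA_16S", "rRNA_18S"):
            if gene in t.copies:
                t.copies[gene] = 1
    if biased_taxon is not None:
        found = False
        for t in taxa:
            if t.name == biased_taxon or t.group == biased_taxon:
                gene = "rRNA_16S" if t.domain == "bacteria" else "rRNA_18S"
                t.copies[gene] = bias_copies
                found = True
        if not found:
            raise ValidationError(f"taxon {biased_taxon!r} not in community")
    return taxa


def bacterioplankton_community(
    phototroph_fraction: float, n_heterotrophs: int = 4
) -> list[TaxonSpec]:
    """Bacterial community: cyanobacteria (psbO + recA) at the given cell
    fraction (60/40 Prochlorococcus/Synechococcus) plus heterotrophs (recA
    only) sharing the remainder equally."""
    if not 0 <= phototroph_fraction <= 1:
        raise ValidationError("phototroph_fraction must be in [0, 1]")
    f = phototroph_fraction
    taxa = [
        TaxonSpec("Prochlorococcus_A", "Prochlorococcus", "bacteria", True,
                  round(0.6 * f, 12), {"psbO": 1, "recA": 1}),
        TaxonSpec("Synechococcus_A", "Synechococcus", "bacteria", True,
                  round(0.4 * f, 12), {"psbO": 1, "recA": 1}),
    ]
    rest = (1.0 - taxa[0].cell_fraction - taxa[1].cell_fraction) / n_heterotrophs
    for i in range(n_heterotrophs):
        frac = rest if i < n_heterotrophs - 1 else 1.0 - sum(t.cell_fraction for t in taxa)
        taxa.append(
            TaxonSpec(f"Heterotroph_{i + 1}", "heterotrophic_bacteria", "bacteria",
                      False, frac, {"recA": 1})
        )
    _check_fractions(taxa)
    return taxa


def eukaryote_community(photo_fraction: float, n_taxa: int = 6) -> list[TaxonSpec]:
    """Eukaryote community with ribosomal proteins in every taxon and psbO in
    phototrophs; the photosynthetic taxa jointly hold ``photo_fraction`` of
    the cells."""
    groups_photo = ["chlorophytes", "haptophytes", "diatoms"]
    groups_hetero = ["other", "other", "other"]
    n_photo = max(1, n_taxa // 2) if photo_fraction > 0 else 0
    n_hetero = n_taxa - n_photo
    taxa = []
    rp = {g: 1 for g in RIBOSOMAL_PROTEIN_GENES}
    for i in range(n_photo):
        frac = photo_fraction / n_photo
        taxa.append(
            TaxonSpec(f"Photo_{i + 1}", groups_photo[i % len(groups_photo)],
                      "eukaryote", True, frac, {"psbO": 1, **rp})
        )
    for i in range(n_hetero):
        frac = (1 - photo_fraction) / n_hetero
        taxa.append(
            TaxonSpec(f"Hetero_{i + 1}", groups_hetero[i % len(groups_hetero)],
                      "eukaryote", False, frac, dict(rp))
        )
    # absorb rounding into the last taxon
    total = sum(t.cell_fraction for t in taxa)
    taxa[-1].cell_fraction += 1.0 - total
    _check_fractions(taxa)
    return taxa


# ---------------------------------------------------------------------------
# reference evolution


@dataclass
class SimulatedReferences:
    """Per-gene reference databases plus the true tree and psbO protein alignment."""

    databases: dict[str, ReferenceDatabase]
    tree: ReferenceTree | None
    newick: str | None
    alignment: ReferenceAlignment | None
    branch_scale: float


def _coalescent_tree(names: list[str], rng: np.random.Generator):
    """Random-join coalescent topology with evenly spread, jittered heights.

    Raw Kingman waiting times regularly place two tips on a near-zero-length
    cherry, i.e. two essentially identical references - something a curated,
    redundancy-reduced marker database never contains. Heights are therefore
    spread evenly over the tree depth with +/-25% jitter per join, keeping
    every reference pair distinguishable at the requested divergence while
    the topology stays a random coalescent. Returns (children, heights,
    root); nodes 0..n-1 are the tips.
    """
    n = len(names)
    children: dict[int, tuple[int, int]] = {}
    heights = {i: 0.0 for i in range(n)}
    active = list(range(n))
    next_id = n
    for join in range(1, n):
        k = len(active)
        h = (join + rng.uniform(-0.25, 0.25)) / (n - 1)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        children[next_id] = (a, b)
        heights[next_id] = h
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return children, heights, active[0]


def _group_structured_tree(taxa: list[TaxonSpec], rng: np.random.Generator):
    """Two-level topology: groups are monophyletic clades.

    Members of each group coalesce at low heights (0-0.3), group ancestors
    at high heights (0.6-1.0), so within-group divergence is well below
    between-group divergence - the structure a curated marker phylogeny
    shows and the placement classifier relies on. Join order and jitter are
    random; returns (children, heights, root) with tips 0..n-1.
    """
    n = len(taxa)
    children: dict[int, tuple[int, int]] = {}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    next_id = n
    group_roots: list[int] = []
    by_group: dict[str, list[int]] = {}
    for idx, t in enumerate(taxa):
        by_group.setdefault(t.group, []).append(idx)
    for group in sorted(by_group):
        members = list(by_group[group])
        k = len(members)
        for join in range(1, k):
            h = 0.3 * (join + rng.uniform(-0.25, 0.25)) / k
            i, j = sorted(rng.choice(len(members), size=2, replace=False))
            a, b = members[i], members[j]
            children[next_id] = (a, b)
            heights[next_id] = h
            members = [x for x in members if x not in (a, b)] + [next_id]
            next_id += 1
        group_roots.append(members[0])
    active = group_roots
    n_groups = len(group_roots)
    for join in range(1, n_groups):
        h = 0.6 + 0.4 * (join + rng.uniform(-0.25, 0.25)) / max(n_groups - 1, 1)
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        children[next_id] = (a, b)
        heights[next_id] = h
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return children, heights, active[0]


def _pairwise_path_lengths(children, heights, root, n_tips) -> list[float]:
    # tip sets per internal node -> path length between tips a,b = 2 * h(mrca)
    below: dict[int, set[int]] = {}

    def collect(node: int) -> set[int]:
        if node < n_tips:
            below[node] = {node}
        else:
            a, b = children[node]
            below[node] = collect(a) | collect(b)
        return below[node]

    collect(root)
    dists = []
    for node, (a, b) in children.items():
        for x in below[a]:
            for y in below[b]:
                dists.append(2.0 * heights[node])
    return dists


def _jc_p(t: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


def _mutate(seq: np.ndarray, branch: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor transition along one branch (exact per-branch kernel)."""
    q = _jc_p(branch)
    out = seq.copy()
    hit = rng.random(seq.size) < q
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


_NT_CHARS = np.array(list("ACGT"))


def simulate_reference_set(
    taxa: list[TaxonSpec],
    divergence: float = 0.15,
    seed: int = 0,
    genes: list[str] | None = None,
    support: float = 1.0,
    group_structured: bool = False,
) -> SimulatedReferences:
    """Evolve per-gene references down one random coalescent species tree.

    Branch lengths are rescaled so that the expected mean pairwise
    nucleotide difference between references equals ``divergence`` exactly
    (Jukes-Cantor per-branch kernels compose exactly along paths).
    ``divergence = 0`` yields identical references. The true tree is emitted
    for psbO with all internal supports set to ``support``, together with
    the true (ungapped) protein alignment. With ``group_structured`` the
    topology makes every group a monophyletic clade (see
    :func:`_group_structured_tree`); otherwise it is a random coalescent.
    """
    _check_fractions(taxa)
    if not 0.0 <= divergence < 0.5:
        raise ValidationError("divergence must be in [0, 0.5)")
    if not 2 <= len(taxa) <= 200:
        raise ValidationError("need between 2 and 200 taxa")
    if genes is None:
        genes = sorted({g for t in taxa for g, c in t.copies.items() if c > 0})
    for t in taxa:
        for g in genes:
            if divergence > 0 and t.copies.get(g, 0) > 0 and divergence * t.length(g) < 1:
                raise ValidationError(
                    f"divergence {divergence} on a {t.length(g)} nt gene expects "
                    "fewer than one difference"
                )
    rng = np.random.default_rng(seed)
    names = [t.name for t in taxa]
    by_name = {t.name: t for t in taxa}
    if group_structured:
        children, heights, root = _group_structured_tree(taxa, rng)
    else:
        children, heights, root = _coalescent_tree(names, rng)
    paths = _pairwise_path_lengths(children, heights, root, len(names))

    if divergence > 0:
        def objective(s: float) -> float:
            return float(np.mean([_jc_p(s * t) for t in paths])) - divergence

        hi = 1.0
        while objective(hi) < 0 and hi < 1e6:
            hi *= 2.0
        scale = float(brentq(objective, 0.0, hi))
    else:
        scale = 0.0

    databases: dict[str, ReferenceDatabase] = {}
    alignment = None
    for gene in sorted(genes):
        carriers = [t for t in taxa if t.copies.get(gene, 0) > 0]
        if not carriers:
            continue
        length = carriers[0].length(gene)
        if any(t.length(gene) != length for t in carriers):
            raise ValidationError(f"all carriers of {gene!r} must share a length")
        if gene == "psbO":
            ncod = length // 3
            codons = rng.choice(len(_SENSE_CODONS), size=ncod)
            ancestral = np.array(
                [
                    "ACGT".index(c)
                    for cod in codons
                    for c in _SENSE_CODONS[int(cod)]
                ],
                dtype=np.int8,
            )
        else:
            ancestral = rng.integers(0, 4, size=length).astype(np.int8)
        # evolve: depth-first from root, per-branch JC kernel
        seqs: dict[int, np.ndarray] = {root: ancestral}
        stack = [root]
        while stack:
            node = stack.pop()
            if node in children:
                for child in children[node]:
                    branch = (heights[node] - heights[child]) * scale
                    seqs[child] = _mutate(seqs[node], branch, rng)
                    stack.append(child)
        records = []
        for idx, name in enumerate(names):
            t = by_name[name]
            if t.copies.get(gene, 0) > 0:
                seq = "".join(_NT_CHARS[seqs[idx]])
                records.append(MarkerRecord(f"{name}_{gene}", gene, t.taxonomy, seq))
        databases[gene] = ReferenceDatabase(gene=gene, records=records)
        if gene == "psbO":
            from Bio.Seq import Seq

            alignment = ReferenceAlignment(
                {r.record_id: str(Seq(r.sequence).translate()) for r in records}
            )

    tree = newick = None
    if "psbO" in databases:
        carriers = {t.name for t in taxa if t.copies.get("psbO", 0) > 0}
        newick = (
            _to_newick(children, heights, root, names, scale, support, carriers) + ";"
        )
        taxonomy = {
            f"{name}_psbO": by_name[name].taxonomy for name in names if name in carriers
        }
        tree = ReferenceTree.from_newick(newick, taxonomy)
    return SimulatedReferences(
        databases=databases, tree=tree, newick=newick,
        alignment=alignment, branch_scale=scale,
    )


def _to_newick(children, heights, root, names, scale, support, keep: set[str]) -> str:
    def render(node: int, parent_h: float) -> str | None:
        blen = (parent_h - heights[node]) * scale
        if node < len(names):
            if names[node] not in keep:
                return None
            return f"{names[node]}_psbO:{blen:.6f}"
        a, b = children[node]
        parts = [p for p in (render(a, heights[node]), render(b, heights[node])) if p]
        if not parts:
            return None
        if len(parts) == 1:
            # pruned to a unary node: collapse it (topology-preserving)
            return parts[0]
        return f"({','.join(parts)}){support:g}:{blen:.6f}"

    return render(root, heights[root])


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class CommunityTruth:
    """Ground truth for a simulated read set."""

    cell_fractions: dict[str, float]
    expected_read_share: dict[str, dict[str, float]]  # gene -> taxon -> share
    provenance: pd.DataFrame  # read_id, taxon, gene, start, strand, n_errors

    def group_fractions(self, taxa: list[TaxonSpec]) -> dict[str, float]:
        out: dict[str, float] = {}
        for t in taxa:
            out[t.group] = out.get(t.group, 0.0) + self.cell_fractions[t.name]
        return out


def simulate_reads(
    taxa: list[TaxonSpec],
    refs: SimulatedReferences,
    n_reads: int,
    read_length: int = 100,
    error_rate: float = 0.01,
    seed: int = 0,
    genes: list[str] | None = None,
    pcr_bias: dict[str, float] | None = None,
) -> tuple[list[Read], CommunityTruth]:
    """Draw shotgun reads from the simulated references.

    Reads are multinomial over (taxon, gene) with weight cell_fraction x
    copy number x gene length (optionally x a PCR bias factor on rRNA
    genes), start positions uniform, substitution errors per base at
    ``error_rate``, and half the reads reverse-complemented. Provenance of
    every read is recorded.
    """
    _check_fractions(taxa)
    if n_reads <= 0:
        raise ValidationError("n_reads must be positive")
    if not 0 <= error_rate < 0.1:
        raise ValidationError("error_rate must be in [0, 0.1)")
    if genes is None:
        genes = sorted(refs.databases)
    pairs: list[tuple[TaxonSpec, str]] = []
    weights: list[float] = []
    for t in taxa:
        for gene in genes:
            copies = t.copies.get(gene, 0)
            if copies <= 0 or gene not in refs.databases:
                continue
            if f"{t.name}_{gene}" not in refs.databases[gene]:
                continue
            if read_length > t.length(gene):
                raise ValidationError(
                    f"read length {read_length} exceeds {gene} length {t.length(gene)}"
                )
            w = t.cell_fraction * copies * t.length(gene)
            if pcr_bias and gene.startswith("rRNA"):
                w *= pcr_bias.get(t.name, 1.0)
            pairs.append((t, gene))
            weights.append(w)
    if not pairs:
        raise ValidationError("no (taxon, gene) pair has positive weight")
    w = np.asarray(weights)
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, p)
    reads: list[Read] = []
    prov_rows = []
    read_no = 0
    for (t, gene), k in zip(pairs, counts):
        if k == 0:
            continue
        ref_seq = refs.databases[gene][f"{t.name}_{gene}"].sequence
        codes = np.array(["ACGT".index(c) for c in ref_seq], dtype=np.int8)
        starts = rng.integers(0, len(ref_seq) - read_length + 1, size=k)
        flips = rng.random(k) < 0.5
        for start, flip in zip(starts, flips):
            frag = codes[start : start + read_length].copy()
            n_err = 0
            if error_rate > 0:
                hit = rng.random(read_length) < error_rate
                n_err = int(hit.sum())
                if n_err:
                    shift = rng.integers(1, 4, size=n_err)
                    frag[hit] = (frag[hit] + shift) % 4
            seq = "".join(_NT_CHARS[frag])
            if flip:
                seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            rid = f"r{read_no:07d}"
            read_no += 1
            reads.append(Read(rid, seq))
            prov_rows.append(
                {"read_id": rid, "taxon": t.name, "gene": gene,
                 "start": int(start), "strand": "-" if flip else "+",
                 "n_errors": n_err}
            )
    # expected read share per gene, normalised within gene
    share: dict[str, dict[str, float]] = {}
    for gene in genes:
        gene_w = {
            t.name: wv for (t, g), wv in zip(pairs, weights) if g == gene
        }
        total = sum(gene_w.values())
        if total > 0:
            share[gene] = {name: v / total for name, v in gene_w.items()}
    truth = CommunityTruth(
        cell_fractions={t.name: t.cell_fraction for t in taxa},
        expected_read_share=share,
        provenance=pd.DataFrame(
            prov_rows,
            columns=["read_id", "taxon", "gene", "start", "strand", "n_errors"],
        ),
    )
    return reads, truth


def simulate_optical_counts(
    taxa: list[TaxonSpec],
    n_cells: int = 10_000,
    noise_cv: float = 0.1,
    seed: int = 0,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Optical count table: one row per counted cell, spherical geometry.

    Cells are multinomial over the true fractions; per-cell diameters are
    lognormal around the group mean with coefficient of variation
    ``noise_cv`` (exactly the group mean when zero).
    """
    _check_fractions(taxa)
    if n_cells < 100:
        raise ValidationError("n_cells must be >= 100")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    fracs = np.array([t.cell_fraction for t in taxa])
    counts = rng.multinomial(n_cells, fracs)
    rows = []
    for t, k in zip(taxa, counts):
        if k == 0:
            continue
        mean_d = GROUP_DIAMETER_UM[t.group]
        if noise_cv > 0:
            sigma2 = math.log(1.0 + noise_cv**2)
            mu = math.log(mean_d) - sigma2 / 2.0
            diam = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=k)
        else:
            diam = np.full(k, mean_d)
        for d in diam:
            rows.append(
                {"sample_id": sample_id, "taxon": t.group, "cell_count": 1,
                 "major_axis": float(d), "minor_axis": float(d)}
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "taxon", "cell_count", "major_axis", "minor_axis"]
    )
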