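"""Curated marker-gene reference databases: parsing, validation, clustering.

A reference database is a set of nucleotide marker sequences for one gene,
each carrying a taxonomy path and a coarse group label. The FASTA header
dialect is ``>id|gene|group|rank1;rank2;...``.

Redundancy reduction follows the cd-hit convention: greedy incremental
clustering at a global (end-gap-free) identity cutoff, longest sequence
first, each sequence joining the first cluster whose representative it
matches at or above the cutoff.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._sw import encode_nt, glocal_matrix, OP_MATCH, OP_DEL
from .errors import ParseError, ValidationError
from .taxonomy import TaxonomyPath

#: Recognised gene labels.
GENES: frozenset[str] = frozenset(
    {"psbO", "recA", "petC_chloroplast", "rieske_mitochondrial", "rRNA_16S", "rRNA_18S"}
    | {f"rp{i:02d}" for i in range(1, 26)}
)

#: The 25 ribosomal-protein genes used as the eukaryotic single-copy baseline.
RIBOSOMAL_PROTEIN_GENES: tuple[str, ...] = tuple(f"rp{i:02d}" for i in range(1, 26))

_VALID_NT = set("ACGTN")


@dataclass
class MarkerRecord:
    """One reference sequence with taxonomy and gene metadata."""

    record_id: str
    gene: str
    taxonomy: TaxonomyPath
    sequence: str

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValidationError(f"unknown gene label {self.gene!r}")
        if not self.sequence:
            raise ValidationError(f"record {self.record_id!r} has an empty sequence")
        bad = set(self.sequence) - _VALID_NT
        if bad:
            raise ValidationError(
                f"record {self.record_id!r} has invalid characters {sorted(bad)}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceDatabase:
    """All reference records for one marker gene."""

    gene: str
    records: list[MarkerRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene != self.gene:
                raise ValidationError(
                    f"record {rec.record_id!r} has gene {rec.gene!r}, "
                    f"database is {self.gene!r}"
                )
            if rec.record_id in seen:
                raise ValidationError(f"duplicate record id {rec.record_id!r}")
            seen.add(rec.record_id)
        self._index = {rec.record_id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._index

    def __getitem__(self, record_id: str) -> MarkerRecord:
        return self._index[record_id]

    @property
    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]


@dataclass
class CopyNumberTable:
    """Copies per genome by (group, gene), plus plastid multiplicities.

    Values may be a single integer or an inclusive ``(lo, hi)`` range; psbO
    defaults to the 1-2 range. Plastid-encoded markers multiply by plastids
    per cell and plastid genomes per plastid.
    """

    copies: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    plastids_per_cell: dict[str, int] = field(default_factory=dict)
    plastid_genomes_per_plastid: tuple[int, int] = (50, 100)

    def __post_init__(self) -> None:
        for (group, gene), (lo, hi) in self.copies.items():
            if lo < 1 or hi < lo:
                raise ValidationError(
                    f"copy number for ({group}, {gene}) must be >= 1, got ({lo}, {hi})"
                )

    def set(self, group: str, gene: str, lo: int, hi: int | None = None) -> None:
        rng = (lo, hi if hi is not None else lo)
        if rng[0] < 1 or rng[1] < rng[0]:
            raise ValidationError(f"invalid copy range {rng}")
        self.copies[(group, gene)] = rng

    @classmethod
    def defaults(cls) -> "CopyNumberTable":
        """Copy-number envelope for the supported genes (psbO 1-2, petC 2-3)."""
        table = cls()
        for group in ("diatoms", "dinoflagellates", "haptophytes", "chlorophytes"):
            table.set(group, "psbO", 1, 2)
            table.set(group, "petC_chloroplast", 2, 3)
            table.set(group, "rieske_mitochondrial", 1)
        for group in ("Prochlorococcus", "Synechococcus"):
            table.set(group, "psbO", 1)
            table.set(group, "recA", 1)
            table.set(group, "rRNA_16S", 1, 2)
        table.set("heterotrophic_bacteria", "recA", 1)
        table.set("chlorophytes", "rRNA_18S", 1, 4)
        table.set("haptophytes", "rRNA_18S", 1, 100)
        table.set("diatoms", "rRNA_18S", 1, 1000)
        table.set("dinoflagellates", "rRNA_18S", 100, 35000)
        return table


def parse_reference_fasta(stream: TextIO | str, gene: str) -> ReferenceDatabase:
    """Parse a reference FASTA with ``>id|gene|group|rank1;rank2;...`` headers.

    Sequences are uppercased and U is mapped to T; line wrapping is
    irrelevant. Duplicate ids, malformed headers (with line number) and
    empty sequences are hard errors.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    header_lines: dict[str, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            header_lines.setdefault(line[1:].strip(), lineno)
    records: list[MarkerRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(io.StringIO(text), "fasta"):
        lineno = header_lines.get(entry.description)
        parts = entry.description.split("|")
        if len(parts) != 4:
            raise ParseError(
                f"malformed header {entry.description!r}: expected "
                "'id|gene|group|rank1;rank2;...'",
                line=lineno,
            )
        rec_id, rec_gene, group, ranks = (p.strip() for p in parts)
        if rec_id in seen:
            raise ValidationError(f"duplicate record id {rec_id!r}")
        seen.add(rec_id)
        if rec_gene != gene:
            raise ParseError(
                f"record {rec_id!r} is labelled gene {rec_gene!r}, expected {gene!r}",
                line=lineno,
            )
        seq = str(entry.seq).upper().replace("U", "T")
        if not seq:
            raise ParseError(f"record {rec_id!r} has an empty sequence", line=lineno)
        try:
            taxonomy = TaxonomyPath(tuple(r for r in ranks.split(";")), group)
        except ValidationError as exc:
            raise ParseError(f"record {rec_id!r}: {exc}", line=lineno) from exc
        records.append(MarkerRecord(rec_id, gene, taxonomy, seq))
    return ReferenceDatabase(gene=gene, records=records)


def write_reference_fasta(db: ReferenceDatabase, handle: TextIO, width: int = 70) -> None:
    """Write a database back to the header dialect (round-trips with the parser)."""
    for rec in db.records:
        handle.write(f">{rec.record_id}|{rec.gene}|{rec.taxonomy.group}|{rec.taxonomy}\n")
        for i in range(0, len(rec.sequence), width):
            handle.write(rec.sequence[i : i + width] + "\n")


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global end-gap-free identity between two nucleotide sequences.

    The shorter sequence is aligned globally within the longer one (terminal
    gaps on the longer sequence are free); identity = matches / alignment
    columns on the aligned core. N never counts as a match.
    """
    if len(seq_a) > len(seq_b):
        seq_a, seq_b = seq_b, seq_a
    a = encode_nt(seq_a)
    b = encode_nt(seq_b)
    S = np.where(
        (a[:, None] == b[None, :]) & (a[:, None] < 4), 1.0, -1.0
    )
    _, ops, j_start = glocal_matrix(S, -2.0, -1.0)
    matches = 0
    i = 0
    j = j_start
    for op in ops:
        if op == OP_MATCH:
            if a[i] == b[j] and a[i] < 4:
                matches += 1
            i += 1
            j += 1
        elif op == OP_DEL:
            j += 1
        else:
            i += 1
    cols = len(ops)
    return matches / cols if cols else 0.0


def cluster_redundant(
    db: ReferenceDatabase, identity_cutoff: float = 0.80
) -> tuple[ReferenceDatabase, dict[str, str]]:
    """Greedy longest-first redundancy clustering at ``identity_cutoff``.

    Records are processed by descending length (ties: lexicographic id); each
    joins the first existing cluster whose representative it matches at
    >= cutoff end-gap-free global identity, otherwise it founds a new
    cluster. Returns the representatives-only database and a member ->
    representative map (representatives map to themselves).
    """
    if not 0.0 < identity_cutoff <= 1.0:
        raise ValidationError(f"identity cutoff must be in (0, 1], got {identity_cutoff}")
    order = sorted(db.records, key=lambda r: (-r.length_bp, r.record_id))
    representatives: list[MarkerRecord] = []
    cluster_map: dict[str, str] = {}
    for rec in order:
        assigned = False
        for rep in representatives:
            if pairwise_identity(rec.sequence, rep.sequence) >= identity_cutoff:
                cluster_map[rec.record_id] = rep.record_id
                assigned = True
                break
        if not assigned:
            representatives.append(rec)
            cluster_map[rec.record_id] = rec.record_id
    kept = {r.record_id for r in representatives}
    out_records = [r for r in db.records if r.record_id in kept]
    out = ReferenceDatabase(gene=db.gene, records=out_records, provenance=db.provenance)
    return out, cluster_map


def validate_database(db: ReferenceDatabase) -> pd.DataFrame:
    """Report-only validation: per-record stats plus flags.

    Flags records with more than 10% N characters or shorter than 60 nt.
    Returns a DataFrame (record_id, group, length_bp, n_fraction, flags).
    """
    rows = []
    for rec in db.records:
        n_frac = rec.sequence.count("N") / rec.length_bp
        flags = []
        if rec.length_bp < 60:
            flags.append("short")
        if n_frac > 0.10:
            flags.append("high_N")
        rows.append(
            {
                "record_id": rec.record_id,
                "group": rec.taxonomy.group,
                "length_bp": rec.length_bp,
                "n_fraction": n_frac,
                "flags": ",".join(flags),
            }
        )
    return pd.DataFrame(
        rows, columns=["record_id", "group", "length_bp", "n_fraction", "flags"]
    )


def database_summary(report: pd.DataFrame) -> dict:
    """Aggregate a validation report: counts per group and length stats."""
    if report.empty:
        return {"n_records": 0, "per_group": {}, "length_min": None,
                "length_mean": None, "length_max": None, "n_flagged": 0}
    return {
        "n_records": int(len(report)),
        "per_group": report.groupby("group").size().to_dict(),
        "length_min": int(report["length_bp"].min()),
        "length_mean": float(report["length_bp"].mean()),
        "length_max": int(report["length_bp"].max()),
        "n_flagged": int((report["flags"] != "").sum()),
    }
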