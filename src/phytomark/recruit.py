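"""Metagenomic read recruitment against marker reference databases.

A read is recruited when it passes the length and complexity screens and its
best local-alignment hit reaches both the identity and the aligned-fraction
thresholds (defaults 70 bp / 80% / 80% / 75% / 30, the standard short-read
mapping parameters for this kind of survey). Also provides the simplified
rRNA "miTag" best-hit / last-common-ancestor classifier.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._sw import encode_nt, glocal_matrix, revcomp, sw_score, sw_traceback, OP_MATCH, OP_DEL
from .errors import ValidationError
from .markers import MarkerRecord, ReferenceDatabase
from .taxonomy import TaxonomyPath, last_common_ancestor

_VALID_NT = set("ACGTN")


@dataclass(frozen=True)
class Read:
    """A single sequencing read (pairs are treated as independent reads)."""

    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_NT
        if bad:
            raise ValidationError(f"read {self.read_id!r}: invalid characters {sorted(bad)}")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RecruitmentParams:
    """Recruitment thresholds; defaults are the standard mapping parameters."""

    min_read_size: int = 70
    min_identity: float = 80.0
    min_aligned_fraction: float = 80.0
    complexity_percent: float = 75.0
    complexity_number: int = 30
    kmer_size_complexity: int = 3
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_aligned_fraction", "complexity_percent"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValidationError(f"{name} must be in (0, 100], got {v}")
        if self.min_read_size < 1:
            raise ValidationError("min_read_size must be >= 1")


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of a read against one reference."""

    read_id: str
    reference_id: str
    identity: float  # percent over alignment columns
    aligned_read_fraction: float  # percent of read length inside the alignment
    ref_start: int  # 0-based half-open, forward reference coordinates
    ref_end: int
    strand: str  # '+' or '-'
    score: int


@dataclass
class RecruitmentResult:
    """Best hit per recruited read plus per-read rejection reasons."""

    hits: list[AlignmentHit]
    rejected: dict[str, str]
    total_input_reads: int
    total_mapped_reads: int  # reads recruited to ANY database supplied in the run

    def hits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [h.__dict__ for h in self.hits],
            columns=[
                "read_id", "reference_id", "identity", "aligned_read_fraction",
                "ref_start", "ref_end", "strand", "score",
            ],
        )

    def rejected_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.rejected.items()), columns=["read_id", "reason"]
        )


@dataclass(frozen=True)
class LCAAssignment:
    """Taxonomy inherited from the best rRNA hit(s); truncated to the LCA on ties."""

    read_id: str
    taxonomy: tuple[str, ...]
    n_tied_hits: int


def complexity_pass(read: Read, params: RecruitmentParams) -> tuple[bool, str]:
    """Dinucleotide-entropy-free k-mer complexity screen.

    FAIL when the read has fewer than ``complexity_number`` distinct k-mers,
    or when the most frequent k-mer occupies at least ``complexity_percent``
    percent of all k-mer windows. Catches homopolymers and short repeats.
    """
    k = params.kmer_size_complexity
    if read.length_bp < k:
        return False, "too_short_for_complexity"
    counts: dict[str, int] = {}
    seq = read.sequence
    n_windows = read.length_bp - k + 1
    for i in range(n_windows):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    if len(counts) < params.complexity_number:
        return False, "low_complexity"
    if max(counts.values()) * 100.0 >= params.complexity_percent * n_windows:
        return False, "low_complexity"
    return True, "pass"


def align_read(
    read: Read, reference: MarkerRecord, params: RecruitmentParams | None = None
) -> AlignmentHit | None:
    """Maximum-score local alignment of the read (either strand) to a reference.

    Equals a full Smith-Waterman on the same scoring by construction: the
    kernel is an exact DP, not a heuristic. Identity is computed over
    alignment columns; reverse-strand hits are reported in forward reference
    coordinates. Returns None when no alignment scores above 0. Forward
    strand wins score ties.
    """
    params = params or RecruitmentParams()
    ref_codes = encode_nt(reference.sequence)
    best = None
    for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        res = sw_traceback(
            encode_nt(seq), ref_codes,
            params.match, params.mismatch, params.gap_open, params.gap_extend,
        )
        score, _, _, j0, j1, matches, cols = res
        if score <= 0:
            continue
        if best is None or score > best[0]:
            best = (score, strand, j0, j1, matches, cols, res)
    if best is None:
        return None
    score, strand, j0, j1, matches, cols, res = best
    _, i0, i1, _, _, _, _ = res
    return AlignmentHit(
        read_id=read.read_id,
        reference_id=reference.record_id,
        identity=100.0 * matches / cols,
        aligned_read_fraction=100.0 * (i1 - i0) / read.length_bp,
        ref_start=j0,
        ref_end=j1,
        strand=strand,
        score=score,
    )


_QGRAM_K = 8
_QGRAM_POW = 5 ** np.arange(_QGRAM_K - 1, -1, -1)


def _kmer_codes(codes: np.ndarray) -> np.ndarray:
    """Base-5 integer codes of all overlapping 8-mers (empty if too short)."""
    if codes.size < _QGRAM_K:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), _QGRAM_K)
    return windows @ _QGRAM_POW


def _best_hit(
    read: Read,
    entries: list[tuple[MarkerRecord, np.ndarray, frozenset]],
    params: RecruitmentParams,
) -> AlignmentHit | None:
    """Best hit over all references: highest score, ties by higher identity,
    then more alignment columns, then lexicographically smallest reference id.

    A q-gram prescreen makes this exact search fast: an alignment scoring at
    least B over a read of length L has at least B matches and at most
    E = floor((L - B) / 2) error columns (mismatches are the cheapest way to
    lose score), and any such alignment forces the read to share at least
    B + 1 - k(E + 1) k-mer positions with the reference (q-gram lemma). A
    (reference, strand) whose shared-k-mer count falls below that bound
    (with an extra k of slack) provably cannot reach the current best score
    and is skipped without altering the result.
    """
    fwd = encode_nt(read.sequence)
    rev = encode_nt(revcomp(read.sequence))
    L = read.length_bp
    kmers = {"+": _kmer_codes(fwd), "-": _kmer_codes(rev)}
    # order candidates by shared k-mers so the true source sets the bar early
    candidates_in = []
    for rec, ref_codes, ref_kmers in entries:
        for strand in ("+", "-"):
            km = kmers[strand]
            if len(km) and len(ref_kmers):
                idx = np.searchsorted(ref_kmers, km)
                idx[idx == len(ref_kmers)] = 0
                shared = int((ref_kmers[idx] == km).sum())
            else:
                shared = 0
            candidates_in.append((shared, strand, rec, ref_codes))
    candidates_in.sort(key=lambda t: -t[0])
    scored: list[tuple[int, str, MarkerRecord, np.ndarray]] = []
    best_score = 0
    for shared, strand, rec, ref_codes in candidates_in:
        if best_score > 0:
            if best_score > L:
                break
            E = (L - best_score) // 2
            bound = best_score + 1 - _QGRAM_K * (E + 2)  # extra k of slack
            if shared < bound:
                continue
        codes = fwd if strand == "+" else rev
        s = sw_score(codes, ref_codes, params.match, params.mismatch,
                     params.gap_open, params.gap_extend)
        if s > 0 and s >= best_score:
            scored.append((s, strand, rec, ref_codes))
            if s > best_score:
                best_score = s
    if best_score <= 0:
        return None
    # full traceback only for candidates at the maximal score
    candidates: list[AlignmentHit] = []
    for s, strand, rec, ref_codes in scored:
        if s != best_score:
            continue
        codes = fwd if strand == "+" else rev
        score, i0, i1, j0, j1, matches, cols = sw_traceback(
            codes, ref_codes,
            params.match, params.mismatch, params.gap_open, params.gap_extend,
        )
        candidates.append(
            AlignmentHit(
                read_id=read.read_id,
                reference_id=rec.record_id,
                identity=100.0 * matches / cols,
                aligned_read_fraction=100.0 * (i1 - i0) / read.length_bp,
                ref_start=j0,
                ref_end=j1,
                strand=strand,
                score=score,
            )
        )
    candidates.sort(
        key=lambda h: (-h.score, -h.identity, -(h.ref_end - h.ref_start),
                       h.reference_id, h.strand)
    )
    return candidates[0]


def recruit(
    reads: Sequence[Read], db: ReferenceDatabase, params: RecruitmentParams | None = None
) -> RecruitmentResult:
    """Recruit reads to a marker database under the standard filters.

    A read is recruited iff length >= min_read_size AND it passes the
    complexity screen AND its best hit has identity >= min_identity AND
    aligned_read_fraction >= min_aligned_fraction. Rejection reasons:
    too_short, low_complexity, low_identity, low_coverage, no_hit.
    """
    params = params or RecruitmentParams()
    if len(db) == 0:
        raise ValidationError("reference database is empty")
    entries = []
    for rec in db.records:
        codes = encode_nt(rec.sequence)
        entries.append((rec, codes, np.unique(_kmer_codes(codes))))
    hits: list[AlignmentHit] = []
    rejected: dict[str, str] = {}
    for read in reads:
        if read.length_bp < params.min_read_size:
            rejected[read.read_id] = "too_short"
            continue
        ok, reason = complexity_pass(read, params)
        if not ok:
            rejected[read.read_id] = reason if reason != "pass" else "low_complexity"
            continue
        hit = _best_hit(read, entries, params)
        if hit is None:
            rejected[read.read_id] = "no_hit"
        elif hit.identity < params.min_identity:
            rejected[read.read_id] = "low_identity"
        elif hit.aligned_read_fraction < params.min_aligned_fraction:
            rejected[read.read_id] = "low_coverage"
        else:
            hits.append(hit)
    return RecruitmentResult(
        hits=hits,
        rejected=rejected,
        total_input_reads=len(reads),
        total_mapped_reads=len(hits),
    )


def recruit_multi(
    reads: Sequence[Read],
    dbs: dict[str, ReferenceDatabase],
    params: RecruitmentParams | None = None,
) -> dict[str, RecruitmentResult]:
    """Recruit one read set against several marker databases.

    ``total_mapped_reads`` on every result is the number of reads recruited
    to ANY of the supplied databases (the rpkm denominator universe).
    """
    results = {gene: recruit(reads, db, params) for gene, db in dbs.items()}
    mapped: set[str] = set()
    for res in results.values():
        mapped.update(h.read_id for h in res.hits)
    for res in results.values():
        res.total_mapped_reads = len(mapped)
    return results


def classify_ribotag(
    read: Read,
    ribo_db: ReferenceDatabase,
    min_len: int = 100,
    min_identity: float = 80.0,
) -> LCAAssignment | str:
    """Best-hit / LCA classification of an rRNA fragment (the miTag rule).

    Reads shorter than ``min_len`` or containing any N are rejected. The
    best hit is the reference with the fewest differences (edit operations)
    over a region covering 100% of the read; references tying on differences
    vote by last common ancestor (longest shared rank prefix). Returns a
    rejection reason string ("too_short", "has_N", "no_hit") when not
    classifiable.
    """
    if read.length_bp < min_len:
        return "too_short"
    if "N" in read.sequence:
        return "has_N"
    best_diffs = None
    tied: list[MarkerRecord] = []
    for strand_seq in (read.sequence, revcomp(read.sequence)):
        q = encode_nt(strand_seq)
        for rec in ribo_db.records:
            r = encode_nt(rec.sequence)
            # unit-cost infix alignment: match 0, mismatch/gap -1
            S = np.where((q[:, None] == r[None, :]) & (q[:, None] < 4), 0.0, -1.0)
            score, _, _ = glocal_matrix(S, 0.0, -1.0)
            diffs = int(round(-score))
            if best_diffs is None or diffs < best_diffs:
                best_diffs = diffs
                tied = [rec]
            elif diffs == best_diffs and rec not in tied:
                tied.append(rec)
    assert best_diffs is not None
    identity = 100.0 * (read.length_bp - best_diffs) / read.length_bp
    if identity < min_identity:
        return "no_hit"
    if len(tied) == 1:
        taxonomy = tied[0].taxonomy.ranks
    else:
        taxonomy = last_common_ancestor([rec.taxonomy for rec in tied])
    return LCAAssignment(read_id=read.read_id, taxonomy=taxonomy, n_tied_hits=len(tied))


def read_reads(handle: TextIO | str, fmt: str = "fasta") -> list[Read]:
    """Load reads from FASTA or FASTQ (qualities parsed but unused)."""
    if isinstance(handle, str):
        handle = io.StringIO(handle)
    return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, fmt)]
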