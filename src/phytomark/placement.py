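"""Taxonomy assignment of environmental marker fragments by tree placement.

Nucleotide fragments are translated in their best reading frame, aligned to
a fixed reference protein alignment (columns are never altered), placed on
the pendant edge of their nearest reference in a support-annotated reference
tree, and classified by walking rootward to the first well-supported
(support strictly above the threshold, default 0.7) monophyletic clade whose
reference tips all share one group label. Full tree re-inference per query
batch is deliberately replaced by this deterministic distance-based
placement; the classification rule itself is unchanged.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from skbio import TreeNode

from ._sw import OP_DEL, OP_INS, OP_MATCH, glocal_matrix, local_matrix_score, revcomp
from .errors import ValidationError
from .taxonomy import TaxonomyPath

#: Frame labels in tie-break priority order.
FRAMES: tuple[int, ...] = (1, 2, 3, -1, -2, -3)

#: Default affine gap penalties for amino-acid alignment (BLOSUM62 standard).
AA_GAP_OPEN = -11.0
AA_GAP_EXTEND = -1.0

_BLOSUM = substitution_matrices.load("BLOSUM62")
_AA_ALPHABET = str(_BLOSUM.alphabet)
_AA_INDEX = {aa: i for i, aa in enumerate(_AA_ALPHABET)}
_X_INDEX = _AA_INDEX["X"]
_BLOSUM_ARR = np.asarray(_BLOSUM, dtype=np.float64)


def encode_aa(seq: str) -> np.ndarray:
    """Encode amino acids as BLOSUM62 row indices (unknowns map to X)."""
    return np.array([_AA_INDEX.get(c, _X_INDEX) for c in seq.upper()], dtype=np.int64)


@dataclass
class ReferenceAlignment:
    """Fixed reference protein alignment: equal-length gapped rows by id."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows.values()}
        if len(widths) > 1:
            raise ValidationError("alignment rows differ in length")
        self.width = widths.pop() if widths else 0

    def consensus(self) -> str:
        """Majority non-gap residue per column (ties: alphabetical); gap-only
        columns yield X."""
        cons = []
        for j in range(self.width):
            counts: dict[str, int] = {}
            for row in self.rows.values():
                c = row[j]
                if c != "-":
                    counts[c] = counts.get(c, 0) + 1
            if not counts:
                cons.append("X")
            else:
                cons.append(max(sorted(counts), key=lambda c: counts[c]))
        return "".join(cons)

    @classmethod
    def from_fasta(cls, text: str) -> "ReferenceAlignment":
        rows: dict[str, str] = {}
        current = None
        for line in text.splitlines():
            line = line.strip()
            if line.startswith(">"):
                current = line[1:].split()[0].split("|")[0]
                rows[current] = ""
            elif current is not None:
                rows[current] += line.upper()
        return cls(rows)

    def to_fasta(self) -> str:
        return "".join(f">{rid}\n{row}\n" for rid, row in self.rows.items())


@dataclass
class ReferenceTree:
    """Rooted support-annotated tree with group labels on the tips.

    Internal node names are read as support values in [0, 1]; unannotated
    internal nodes (including the root) never classify. An unrooted input
    (trifurcating root) is midpoint-rooted.
    """

    tree: TreeNode
    taxonomy: dict[str, TaxonomyPath]
    midpoint_rooted: bool = False

    def __post_init__(self) -> None:
        tips = [t.name for t in self.tree.tips()]
        if len(set(tips)) != len(tips):
            raise ValidationError("tip ids are not unique")
        missing = [t for t in tips if t not in self.taxonomy]
        if missing:
            raise ValidationError(f"tips without taxonomy: {missing}")
        for node in self.tree.non_tips(include_self=True):
            s = _parse_support(node)
            if s is not None and not 0.0 <= s <= 1.0:
                raise ValidationError(f"support {s} outside [0, 1]")

    @classmethod
    def from_newick(cls, newick: str, taxonomy: Mapping[str, TaxonomyPath]) -> "ReferenceTree":
        tree = TreeNode.read(io.StringIO(newick), convert_underscores=False)
        midpoint = False
        if len(tree.children) > 2:  # unrooted convention
            tree = tree.root_at_midpoint()
            midpoint = True
        return cls(tree=tree, taxonomy=dict(taxonomy), midpoint_rooted=midpoint)

    def tip(self, name: str) -> TreeNode:
        return self.tree.find(name)

    def group_of(self, tip_name: str) -> str:
        return self.taxonomy[tip_name].group


def _parse_support(node: TreeNode) -> float | None:
    if node.name is None:
        return None
    try:
        return float(node.name)
    except ValueError:
        return None


@dataclass(frozen=True)
class TranslationResult:
    frame: int
    protein: str
    score: float


@dataclass
class AlignedQuery:
    query_id: str
    row: str  # gapped row of the profile width
    score: float
    n_insertions: int
    low_confidence: bool = False


@dataclass(frozen=True)
class QueryPlacement:
    query_id: str
    attachment_edge: str  # child-node id of the edge (= nearest tip name)
    nearest_reference_id: str
    distance: float  # Poisson-corrected substitutions per site
    assigned_group: str = "unclassified"


def best_frame_translate(
    nt: str, profile: ReferenceAlignment
) -> TranslationResult | None:
    """Translate all six frames and keep the best-scoring one.

    Each frame's translation (standard code, internal stops kept as ``*``
    and scored by the substitution matrix) is locally aligned against the
    profile consensus; the highest score wins, ties go to the lowest frame
    in the order +1, +2, +3, -1, -2, -3. Returns None ("untranslatable")
    when no frame scores above 0.
    """
    if len(nt) < 60:
        raise ValidationError("fragment shorter than 60 nt")
    cons = encode_aa(profile.consensus())
    best: tuple[float, int, str] | None = None
    for frame in FRAMES:
        seq = nt if frame > 0 else revcomp(nt)
        off = abs(frame) - 1
        sub = seq[off : off + 3 * ((len(seq) - off) // 3)]
        protein = str(Seq(sub).translate())
        if not protein:
            continue
        S = _BLOSUM_ARR[np.ix_(encode_aa(protein), cons)]
        score = float(local_matrix_score(S, AA_GAP_OPEN, AA_GAP_EXTEND))
        if best is None or score > best[0]:
            best = (score, frame, protein)
    if best is None or best[0] <= 0:
        return None
    return TranslationResult(frame=best[1], protein=best[2], score=best[0])


def align_to_profile(
    aa: str, ref_aln: ReferenceAlignment, query_id: str = "query"
) -> AlignedQuery:
    """Add a fragment to the fixed reference alignment.

    Position-specific scores are the mean substitution score of the query
    residue against the non-gap residues of each column; gaps are affine;
    leading/trailing profile columns are free. Reference columns are never
    altered: query insertions are penalised, counted, and dropped from the
    emitted row.
    """
    if len(aa) < 20:
        raise ValidationError("fragment shorter than 20 aa")
    if len(aa) > 2 * ref_aln.width:
        raise ValidationError("fragment more than twice the profile length")
    q = encode_aa(aa)
    # column profiles: mean BLOSUM score per residue class
    S = np.zeros((len(aa), ref_aln.width))
    col_codes: list[np.ndarray] = []
    for j in range(ref_aln.width):
        residues = [row[j] for row in ref_aln.rows.values() if row[j] != "-"]
        col_codes.append(encode_aa("".join(residues)))
    for j, codes in enumerate(col_codes):
        if codes.size:
            S[:, j] = _BLOSUM_ARR[np.ix_(q, codes)].mean(axis=1)
    score, ops, j_start = glocal_matrix(S, AA_GAP_OPEN, AA_GAP_EXTEND)
    row = ["-"] * ref_aln.width
    i = 0
    j = j_start
    n_ins = 0
    for op in ops:
        if op == OP_MATCH:
            row[j] = aa[i].upper()
            i += 1
            j += 1
        elif op == OP_DEL:
            j += 1
        else:
            n_ins += 1
            i += 1
    informative = sum(1 for c in aa.upper() if c not in ("X", "*"))
    return AlignedQuery(
        query_id=query_id,
        row="".join(row),
        score=float(score),
        n_insertions=n_ins,
        low_confidence=bool(score <= 0 or informative == 0),
    )


def place_query(
    aligned: AlignedQuery, ref_aln: ReferenceAlignment, tree: ReferenceTree,
    min_shared_columns: int = 20,
) -> QueryPlacement | str:
    """Attach a profile-aligned query to its nearest reference's pendant edge.

    The distance to each reference is the mismatch proportion over shared
    ungapped columns with a Poisson correction d = -ln(1 - p); the minimum
    wins (ties: smallest reference id). Returns "unplaceable" when fewer
    than ``min_shared_columns`` columns are shared with every reference.
    """
    best: tuple[float, str] | None = None
    any_shared = False
    for rid in sorted(ref_aln.rows):
        if rid not in tree.taxonomy:
            continue
        ref_row = ref_aln.rows[rid]
        shared = mism = 0
        for qc, rc in zip(aligned.row, ref_row):
            if qc != "-" and rc != "-":
                shared += 1
                if qc != rc:
                    mism += 1
        if shared < min_shared_columns:
            continue
        any_shared = True
        p = mism / shared
        if p == 0.0:
            d = 0.0
        elif p < 1.0:
            d = -math.log(1.0 - p)
        else:
            d = math.inf
        if best is None or d < best[0]:
            best = (d, rid)
    if not any_shared or best is None:
        return "unplaceable"
    return QueryPlacement(
        query_id=aligned.query_id,
        attachment_edge=best[1],
        nearest_reference_id=best[1],
        distance=best[0],
    )


def classify_placement(
    tree: ReferenceTree, placement: QueryPlacement, support_threshold: float = 0.7
) -> str:
    """Group label by the monophyly-plus-support rule.

    Walk rootward from the attachment edge; at the first internal node whose
    support is strictly above the threshold and whose tip set carries exactly
    one group label, return that label. Otherwise "unclassified". Support
    exactly equal to the threshold never classifies.
    """
    node = tree.tip(placement.attachment_edge)
    node = node.parent
    while node is not None:
        support = _parse_support(node)
        if support is not None and support > support_threshold:
            groups = {tree.group_of(t.name) for t in node.tips()}
            if len(groups) == 1:
                return groups.pop()
        node = node.parent
    return "unclassified"


def classify_queries(
    nt_fragments: Mapping[str, str],
    ref_aln: ReferenceAlignment,
    tree: ReferenceTree,
    support_threshold: float = 0.7,
) -> "pd.DataFrame":
    """End-to-end: translate, align, place and classify nucleotide fragments."""
    import pandas as pd

    rows = []
    for qid, nt in nt_fragments.items():
        entry = {"query_id": qid, "frame": None, "nearest_reference": None,
                 "distance": None, "assigned_group": "unclassified", "status": "ok"}
        tr = best_frame_translate(nt, ref_aln)
        if tr is None:
            entry["status"] = "untranslatable"
            rows.append(entry)
            continue
        entry["frame"] = tr.frame
        aligned = align_to_profile(tr.protein, ref_aln, query_id=qid)
        placed = place_query(aligned, ref_aln, tree)
        if isinstance(placed, str):
            entry["status"] = placed
            rows.append(entry)
            continue
        entry["nearest_reference"] = placed.nearest_reference_id
        entry["distance"] = placed.distance
        entry["assigned_group"] = classify_placement(tree, placed, support_threshold)
        rows.append(entry)
    return pd.DataFrame(rows)
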