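"""Diversity, correlation, barcoding-gap and biovolume statistics.

These are the validation statistics used alongside the marker-based
profiles: Shannon diversity of estimated communities, Spearman rank
correlation between molecular and optical relative abundances, intra- vs
inter-specific genetic distance summaries (barcoding gap), and per-cell
biovolumes from flow-cytometry side scatter (spheres) or microscopy axes
(prolate spheroids).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

# ---------------------------------------------------------------------------
# diversity and correlation


def shannon(abundances: Sequence[float]) -> float:
    """Shannon index H = -sum p_i ln p_i over positive entries (natural log)."""
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValidationError("abundances must be nonnegative")
    total = a.sum()
    if total <= 0:
        raise ValidationError("at least one abundance must be positive")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    undefined: bool = False


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    The p-value is an exact two-sided permutation value (enumeration of all
    n! orderings) for n <= 9, and the two-sided t approximation
    t = rho * sqrt((n-2)/(1-rho^2)) for larger n. Constant input vectors
    give an undefined-flagged result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    n = x.size
    if n < 4:
        raise ValidationError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(float("nan"), float("nan"), n, undefined=True)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_rho(rx, ry)
    if n <= 9:
        target = abs(rho) - 1e-12
        hits = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_rho(rx, np.asarray(perm))) >= target:
                hits += 1
        p = hits / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = 2 * sps.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, float(p), n)


# ---------------------------------------------------------------------------
# genetic distances and the barcoding gap

_NT = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINES = {"A", "G"}


def _pair_counts(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """(shared sites, transitions, transversions), skipping gap/N columns."""
    shared = transitions = transversions = 0
    for ca, cb in zip(seq_a, seq_b):
        if ca not in _NT or cb not in _NT:
            continue
        shared += 1
        if ca == cb:
            continue
        if (ca in _PURINES) == (cb in _PURINES):
            transitions += 1
        else:
            transversions += 1
    return shared, transitions, transversions


def pairwise_distance(
    seq_a: str, seq_b: str, model: Literal["p_distance", "K2P", "TN93"] = "p_distance"
) -> float:
    """Pairwise distance under the chosen substitution model.

    Columns where either sequence has a gap or N are ignored pairwise; at
    least 50 shared columns are required. K2P and TN93 apply the standard
    closed-form corrections and return ``inf`` when the logarithm arguments
    are non-positive (saturation).
    """
    if len(seq_a) != len(seq_b):
        raise ValidationError("sequences must be aligned (equal length)")
    shared, P_count, Q_count = _pair_counts(seq_a, seq_b)
    if shared < 50:
        raise ValidationError(f"only {shared} shared columns; need >= 50")
    P = P_count / shared
    Q = Q_count / shared
    if model == "p_distance":
        return P + Q
    if model == "K2P":
        w1 = 1 - 2 * P - Q
        w2 = 1 - 2 * Q
        if w1 <= 0 or w2 <= 0:
            return float("inf")
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    if model == "TN93":
        return _tn93(seq_a, seq_b)
    raise ValidationError(f"unknown model {model!r}")


def _tn93(seq_a: str, seq_b: str) -> float:
    """Tamura-Nei 1993 distance with empirical base frequencies."""
    pairs = [
        (ca, cb)
        for ca, cb in zip(seq_a, seq_b)
        if ca in _NT and cb in _NT
    ]
    n = len(pairs)
    freq = np.zeros(4)
    for ca, cb in pairs:
        freq[_NT[ca]] += 1
        freq[_NT[cb]] += 1
    freq /= freq.sum()
    gA, gC, gG, gT = freq
    gR = gA + gG
    gY = gC + gT
    P1 = sum(1 for ca, cb in pairs if {ca, cb} == {"A", "G"}) / n  # purine transitions
    P2 = sum(1 for ca, cb in pairs if {ca, cb} == {"C", "T"}) / n  # pyrimidine transitions
    Q = sum(1 for ca, cb in pairs if ca != cb and ((ca in _PURINES) != (cb in _PURINES))) / n
    k1 = 2 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2 * gC * gT / gY if gY > 0 else 0.0
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY) if gR > 0 and gY > 0 else 0.0
    w1 = 1 - P1 / k1 - Q / (2 * gR) if k1 > 0 else 1.0
    w2 = 1 - P2 / k2 - Q / (2 * gY) if k2 > 0 else 1.0
    w3 = 1 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return float("inf")
    d = 0.0
    if k1 > 0:
        d += -k1 * math.log(w1)
    if k2 > 0:
        d += -k2 * math.log(w2)
    d += -k3 * math.log(w3)
    return d


@dataclass
class DistanceSummary:
    """Pairwise distances partitioned into intra- and interspecific sets."""

    pairs: pd.DataFrame  # species_a, species_b, seq_a, seq_b, distance, kind
    warnings: list[str]

    @property
    def intraspecific(self) -> np.ndarray:
        return self.pairs.loc[self.pairs["kind"] == "intra", "distance"].to_numpy()

    @property
    def interspecific(self) -> np.ndarray:
        return self.pairs.loc[self.pairs["kind"] == "inter", "distance"].to_numpy()


def genetic_distances(
    seqs_by_species: Mapping[str, Mapping[str, str]],
    model: Literal["p_distance", "K2P", "TN93"] = "TN93",
) -> tuple[DistanceSummary, dict]:
    """All pairwise distances plus a barcoding-gap report.

    ``seqs_by_species`` maps species -> {sequence id -> aligned sequence}.
    Species with a single sequence are excluded from the intraspecific set
    (with a warning). The report gives, per species, the maximum
    intraspecific and minimum interspecific distance (the local gap), and a
    global-gap verdict: minimum interspecific over all pairs strictly above
    maximum intraspecific over all pairs.
    """
    species = sorted(seqs_by_species)
    if len(species) < 2:
        raise ValidationError("need at least 2 species")
    warnings = [
        f"species {sp!r} has a single sequence; excluded from intraspecific set"
        for sp in species
        if len(seqs_by_species[sp]) < 2
    ]
    rows = []
    flat = [
        (sp, sid, seq)
        for sp in species
        for sid, seq in sorted(seqs_by_species[sp].items())
    ]
    for (sp_a, id_a, s_a), (sp_b, id_b, s_b) in itertools.combinations(flat, 2):
        d = pairwise_distance(s_a, s_b, model)
        rows.append(
            {
                "species_a": sp_a, "species_b": sp_b,
                "seq_a": id_a, "seq_b": id_b,
                "distance": d,
                "kind": "intra" if sp_a == sp_b else "inter",
            }
        )
    pairs = pd.DataFrame(rows)
    summary = DistanceSummary(pairs=pairs, warnings=warnings)
    per_species = {}
    for sp in species:
        intra = pairs.loc[
            (pairs["kind"] == "intra") & (pairs["species_a"] == sp), "distance"
        ]
        inter = pairs.loc[
            (pairs["kind"] == "inter")
            & ((pairs["species_a"] == sp) | (pairs["species_b"] == sp)),
            "distance",
        ]
        max_intra = float(intra.max()) if len(intra) else None
        min_inter = float(inter.min()) if len(inter) else None
        per_species[sp] = {
            "max_intraspecific": max_intra,
            "min_interspecific": min_inter,
            "local_gap": (
                min_inter > max_intra
                if max_intra is not None and min_inter is not None
                else None
            ),
        }
    intra_all = summary.intraspecific
    inter_all = summary.interspecific
    report = {
        "per_species": per_species,
        "global_gap": (
            bool(inter_all.min() > intra_all.max())
            if len(intra_all) and len(inter_all)
            else None
        ),
    }
    return summary, report


# ---------------------------------------------------------------------------
# biovolume


def sphere_biovolume_from_ssc(ssc: float, coeffs: Mapping[str, float]) -> float:
    """Spherical cell volume from bead-standardised side scatter.

    Uses the power-law calibration d = a * ssc**b (coefficients must be
    supplied; the calibration constants are instrument-specific and are not
    bundled), then V = (pi/6) d^3 in µm^3.
    """
    if ssc <= 0:
        raise ValidationError("side scatter must be positive")
    try:
        a, b = float(coeffs["a"]), float(coeffs["b"])
    except (KeyError, TypeError) as exc:
        raise ValidationError("coeffs must supply 'a' and 'b'") from exc
    d = a * ssc**b
    return math.pi / 6.0 * d**3


def ellipsoid_biovolume(major: float, minor: float) -> float:
    """Prolate-spheroid volume V = (pi/6) * major * minor^2 (axes in µm)."""
    if minor <= 0 or major < minor:
        raise ValidationError(f"need major >= minor > 0, got ({major}, {minor})")
    return math.pi / 6.0 * major * minor**2


def relative_biovolume(
    records: pd.DataFrame, ssc_coeffs: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Percent of total biovolume per taxon from an optical count table.

    ``records`` columns: taxon, cell_count, and either (major_axis,
    minor_axis) or ssc. Mixing geometry types requires ``ssc_coeffs`` so
    that ssc rows are resolvable; otherwise it is an error.
    """
    required = {"taxon", "cell_count"}
    if not required <= set(records.columns):
        raise ValidationError(f"records must have columns {sorted(required)}")
    volumes: dict[str, float] = {}
    for _, row in records.iterrows():
        if row["cell_count"] < 0:
            raise ValidationError("cell counts must be >= 0")
        has_axes = (
            "major_axis" in records.columns
            and pd.notna(row.get("major_axis"))
            and pd.notna(row.get("minor_axis"))
        )
        if has_axes:
            vol = ellipsoid_biovolume(float(row["major_axis"]), float(row["minor_axis"]))
        elif "ssc" in records.columns and pd.notna(row.get("ssc")):
            if ssc_coeffs is None:
                raise ValidationError(
                    "records mix geometry types; supply ssc_coeffs to resolve ssc rows"
                )
            vol = sphere_biovolume_from_ssc(float(row["ssc"]), ssc_coeffs)
        else:
            raise ValidationError("record with neither axes nor ssc")
        taxon = str(row["taxon"])
        volumes[taxon] = volumes.get(taxon, 0.0) + float(row["cell_count"]) * vol
    total = sum(volumes.values())
    if total <= 0:
        raise ValidationError("total biovolume is zero")
    return {t: 100.0 * v / total for t, v in volumes.items()}
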