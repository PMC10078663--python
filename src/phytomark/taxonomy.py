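"""Taxonomy paths and the controlled vocabulary of coarse plankton groups.

A :class:`TaxonomyPath` is an ordered list of rank labels from domain down to
(at most) species, plus a coarse group label used for plotting and for
placement classification. Group labels are restricted to a controlled
vocabulary covering the main marine phytoplankton groups, plus
``heterotrophic_bacteria`` (needed for recA reference sets) and ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: Controlled vocabulary of coarse group labels.
GROUPS: frozenset[str] = frozenset(
    {
        "Prochlorococcus",
        "Synechococcus",
        "other_cyanobacteria",
        "diatoms",
        "dinoflagellates",
        "haptophytes",
        "chlorophytes",
        "pelagophytes",
        "cryptophytes",
        "dictyochophytes",
        "chrysophytes",
        "heterotrophic_bacteria",
        "other",
    }
)

#: Groups that are cyanobacterial (prokaryotic phototrophs).
CYANOBACTERIA: frozenset[str] = frozenset(
    {"Prochlorococcus", "Synechococcus", "other_cyanobacteria"}
)


@dataclass(frozen=True)
class TaxonomyPath:
    """Ordered rank labels (domain -> species, variable depth) plus group label."""

    ranks: tuple[str, ...]
    group: str

    def __post_init__(self) -> None:
        if not self.ranks:
            raise ValidationError("taxonomy must have at least one rank")
        if any(not r for r in self.ranks):
            raise ValidationError("taxonomy ranks must be non-empty strings")
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group label {self.group!r}; expected one of {sorted(GROUPS)}"
            )
        object.__setattr__(self, "ranks", tuple(self.ranks))

    def is_prefix_of(self, other: "TaxonomyPath") -> bool:
        return self.ranks == other.ranks[: len(self.ranks)]

    def __str__(self) -> str:
        return ";".join(self.ranks)


def last_common_ancestor(paths: list[TaxonomyPath]) -> tuple[str, ...]:
    """Longest shared rank prefix of ``paths`` (may be empty)."""
    if not paths:
        return ()
    shared = list(paths[0].ranks)
    for p in paths[1:]:
        n = 0
        for a, b in zip(shared, p.ranks):
            if a != b:
                break
            n += 1
        shared = shared[:n]
    return tuple(shared)
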