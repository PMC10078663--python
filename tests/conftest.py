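"""Shared fixtures.

The heavyweight simulated-community runs used by the validation criteria are
session-scoped so that identical computations are not repeated across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from phytomark import default_phytoplankton_community
from phytomark.pipeline import profile_community


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_db_fasta():
    """Three clean psbO references in the header dialect."""
    rng = np.random.default_rng(99)
    seqs = ["".join(rng.choice(list("ACGT"), size=n)) for n in (94, 473, 733)]
    entries = [
        (f"ref{i + 1}", group, ranks, seq)
        for i, (group, ranks, seq) in enumerate(
            zip(
                ["diatoms", "haptophytes", "Prochlorococcus"],
                [
                    "Eukaryota;Bacillariophyta",
                    "Eukaryota;Haptophyta",
                    "Bacteria;Cyanobacteria;Prochlorococcus",
                ],
                seqs,
            )
        )
    ]
    return "".join(
        f">{rid}|psbO|{group}|{ranks}\n{seq}\n" for rid, group, ranks, seq in entries
    )


@pytest.fixture(scope="session")
def standard_runs():
    """psbO profiling of the default 6-taxon community.

    Seeds 1-3, 1e5 reads, 1% error, 15% divergence: the standard
    single-copy-recovery configuration. Computed once per session.
    """
    taxa = default_phytoplankton_community()
    return {
        seed: profile_community(
            taxa, n_reads=100_000, error_rate=0.01, divergence=0.15,
            seed=seed, genes=("psbO",),
        )
        for seed in (1, 2, 3)
    }
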