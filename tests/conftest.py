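"""Shared fixtures: small germline reference sets and repertoires."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ighrep.simulate import (
    GermlineRefs,
    SimConfig,
    make_germline_refs,
    sample_true_repertoire,
    synthesize_reads,
)


@pytest.fixture(scope="session")
def refs() -> GermlineRefs:
    return make_germline_refs(4, 120, seed=1)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A small noiseless sample: quick and exactly recoverable."""
    return dataclasses.replace(SimConfig(), n_clones=300, per_base_error=0.0, seed=5)


@pytest.fixture(scope="session")
def small_rep(refs, small_cfg):
    return sample_true_repertoire(small_cfg, refs)


@pytest.fixture(scope="session")
def small_batch(refs, small_cfg, small_rep):
    return synthesize_reads(small_rep, small_cfg)


@pytest.fixture(scope="session")
def primer_sets(refs):
    return ([p for _, p in refs.v_primers], [p for _, p in refs.c_primers])


def sw_oracle(a: str, b: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1) -> int:
    """Exhaustive affine-gap Smith-Waterman, straightforward three-matrix DP.

    Independent of the package's aligner: plain Python, textbook recurrences.
    A gap of length L costs gap_open + (L-1)*gap_extend.
    """
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
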