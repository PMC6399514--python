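"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from bspmeth.reference import gc_fraction, obs_exp_cpg
from bspmeth.simulate import SyntheticConfig, generate_reference


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def synthetic_reference(default_config):
    """Reference + truth generated once for the whole session (seed 1)."""
    return generate_reference(default_config, 1)


# --------------------------------------------------------------------------
# Independent oracles (deliberately simple; no shared code with the package
# internals beyond the public criterion helpers)
# --------------------------------------------------------------------------

def brute_force_islands(seq: str, min_length=200, min_gc=0.5, min_obs_exp=0.6,
                        window=100, step=1, max_n_frac=0.10):
    """Enumerate every scan window directly, union qualifying spans, trim.

    Mirrors the stated detection semantics by brute force: per-window
    criteria are recomputed by direct string counting with no prefix-sum
    shortcuts; merged unions are trimmed base by base until they re-satisfy
    the criteria, preferring to drop non-G/C terminal bases (left first).
    """
    covered = [False] * len(seq)
    for start in range(0, len(seq) - window + 1, step):
        sub = seq[start:start + window]
        if sub.count("N") > max_n_frac * window:
            continue
        denom = window - sub.count("N")
        gc = (sub.count("C") + sub.count("G")) / denom if denom else 0.0
        nc, ng = sub.count("C"), sub.count("G")
        oe = sub.count("CG") * window / (nc * ng) if nc and ng else 0.0
        if gc >= min_gc and oe >= min_obs_exp:
            for k in range(start, start + window):
                covered[k] = True

    def ok(a, b):
        sub = seq[a:b]
        denom = len(sub) - sub.count("N")
        gc = (sub.count("C") + sub.count("G")) / denom if denom else 0.0
        nc, ng = sub.count("C"), sub.count("G")
        oe = sub.count("CG") * len(sub) / (nc * ng) if nc and ng else 0.0
        return b - a >= min_length and gc >= min_gc and oe >= min_obs_exp

    islands = []
    i = 0
    while i < len(seq):
        if not covered[i]:
            i += 1
            continue
        j = i
        while j < len(seq) and covered[j]:
            j += 1
        a, b = i, j
        while b - a >= min_length and not ok(a, b):
            if b - a == min_length:
                a = b  # drop
                break
            if seq[a] not in "CG":
                a += 1
            elif seq[b - 1] not in "CG":
                b -= 1
            else:
                a += 1
        if b - a >= min_length and ok(a, b):
            islands.append((a, b))
        i = j
    return islands


def dp_alignment_score(target: str, query: str) -> float:
    """Exhaustive Gotoh alignment score with the package's conventions.

    Bisulfite-aware scoring (target C vs query T is a match), affine gaps
    (a length-k internal gap costs 4 + k), free end gaps on one sequence
    at each end.  O(nm) over three state matrices; independent of the
    package's aligner.
    """

    def s(t, q):
        if t == q:
            return 1.0
        if t == "C" and q == "T":
            return 1.0
        if t == "N" or q == "N":
            return 0.0
        return -1.0

    n, m = len(target), len(query)
    NEG = -1e9
    A = np.full((n + 1, m + 1), NEG)  # ends in an aligned pair
    B = np.full((n + 1, m + 1), NEG)  # ends in a gap in the query
    C = np.full((n + 1, m + 1), NEG)  # ends in a gap in the target
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            start = 0.0 if (i == 1 or j == 1) else NEG
            diag = max(A[i - 1, j - 1], B[i - 1, j - 1], C[i - 1, j - 1], start)
            A[i, j] = s(target[i - 1], query[j - 1]) + diag
            B[i, j] = max(A[i - 1, j] - 5, B[i - 1, j] - 1)
            C[i, j] = max(A[i, j - 1] - 5, C[i, j - 1] - 1)
    return float(max(0.0, A[1:, m].max(), A[n, 1:].max()))


def random_dna(rng, length: int, p=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list("ACGT"), size=length, p=list(p)))
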