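"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — pairwise enumeration, direct
summation of the published constants, exhaustive enumeration of control
combinations, normal-equation least squares — and shares no code with
the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

BASES = "ACGT"


def expand_column(counts) -> list[str]:
    """Turn an A,C,G,T count row into an explicit list of base calls."""
    out = []
    for base, c in zip(BASES, counts):
        out.extend(base * int(c))
    return out


def brute_pi_per_site(counts: np.ndarray) -> float:
    """Per-site pi by enumerating every haplotype pair at every column."""
    total = 0.0
    for row in counts:
        calls = expand_column(row)
        n = len(calls)
        if n < 2:
            continue
        mism = sum(a != b for a, b in itertools.combinations(calls, 2))
        total += mism / (n * (n - 1) / 2)
    return total / len(counts)


def brute_segregating(counts: np.ndarray) -> int:
    return int(sum(len(set(expand_column(row))) > 1 for row in counts))


def _a1(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def brute_theta_per_site(counts: np.ndarray) -> float:
    total = 0.0
    for row in counts:
        calls = expand_column(row)
        if len(set(calls)) > 1:
            total += 1.0 / _a1(len(calls))
    return total / len(counts)


def brute_tajimas_d(counts: np.ndarray) -> float | None:
    """Tajima's D by direct evaluation of the 1989 constants.

    Assumes complete data (constant column sample size), which is how
    the oracle suite draws its matrices.
    """
    n = int(counts[0].sum())
    s = brute_segregating(counts)
    if s == 0 or n < 4:
        return None
    pi_total = brute_pi_per_site(counts) * len(counts)
    theta_total = s / _a1(n)
    a1 = _a1(n)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_total - theta_total) / np.sqrt(e1 * s + e2 * s * (s - 1))


def random_complete_matrix(rng: np.random.Generator, n_max=10, l_max=30) -> np.ndarray:
    """Random silent-site count matrix with no missing data."""
    n = int(rng.integers(4, n_max + 1))
    length = int(rng.integers(1, l_max + 1))
    counts = np.zeros((length, 4), dtype=int)
    for j in range(length):
        if rng.random() < 0.5:  # monomorphic
            counts[j, rng.integers(0, 4)] = n
        else:
            bases = rng.choice(4, size=2, replace=False)
            k = int(rng.integers(1, n))
            counts[j, bases[0]] = k
            counts[j, bases[1]] = n - k
    return counts


def enumerate_resampling_mean(focal_values, candidate_sets) -> float:
    """Exact expectation of the mean focal-minus-control difference over
    every equiprobable combination of control draws."""
    deltas = []
    for combo in itertools.product(*candidate_sets):
        diffs = [f - c for f, c in zip(focal_values, combo)]
        deltas.append(float(np.mean(diffs)))
    return float(np.mean(deltas))


def ols_f_test(y, x_reduced, x_full):
    """F statistic for the extra columns of x_full over x_reduced, by
    normal-equation least squares."""
    y = np.asarray(y, float)

    def rss(x):
        x = np.column_stack([np.ones(len(y)), x]) if x is not None else np.ones((len(y), 1))
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r), int(np.linalg.matrix_rank(x))

    rss_r, rank_r = rss(x_reduced)
    rss_f, rank_f = rss(x_full)
    df_num = rank_f - rank_r
    df_den = len(y) - rank_f
    f = (rss_r - rss_f) / df_num / (rss_f / df_den)
    return f, df_num, df_den
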