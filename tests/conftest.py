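import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_integer_table(rng, max_cell=60):
    """A random 3x3 integer confusion table with positive total."""
    while True:
        t = rng.integers(0, max_cell, size=(3, 3)).astype(float)
        if t.sum() > 0:
            return t


def brute_force_kappa(table):
    """Textbook unweighted Cohen's kappa from a square count table.

    Deliberately written with plain Python loops, independent of the
    package's vectorised code path.  Returns None when the chance-agreement
    denominator vanishes.
    """
    k = len(table)
    total = sum(sum(row) for row in table)
    po = sum(table[i][i] for i in range(k)) / total
    pe = 0.0
    for i in range(k):
        row_i = sum(table[i][j] for j in range(k))
        col_i = sum(table[j][i] for j in range(k))
        pe += (row_i / total) * (col_i / total)
    if abs(1.0 - pe) < 1e-12:
        return None
    return (po - pe) / (1.0 - pe)


def cochran_armitage_chi2(table_2x3, weights=(0, 1, 2)):
    """Classical Cochran-Armitage trend chi-square from a 2x3 count table.

    Rows are (controls, cases), columns genotype counts.  Plain-arithmetic
    contingency-table formula, independent of the dosage-based score test.
    """
    r, s = table_2x3  # controls, cases
    n_i = [r[i] + s[i] for i in range(3)]
    big_n = sum(n_i)
    big_s = sum(s)
    sw = sum(weights[i] * s[i] for i in range(3))
    nw = sum(weights[i] * n_i[i] for i in range(3))
    nw2 = sum(weights[i] ** 2 * n_i[i] for i in range(3))
    num = big_n * (big_n * sw - big_s * nw) ** 2
    den = big_s * (big_n - big_s) * (big_n * nw2 - nw**2)
    if den == 0:
        return 0.0
    return num / den


def hwe_onehot(calls):
    """One-hot (N, 3) posterior rows for certain calls."""
    probs = np.zeros((len(calls), 3))
    probs[np.arange(len(calls)), calls] = 1.0
    return probs
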