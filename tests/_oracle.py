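"""Independent high-precision (50-digit) recomputation of the pipeline.

Implements the entropy, standardization, weighting and compromise-score
formulas directly in mpmath, completely separately from the package's numpy
implementation, for use as a cross-check oracle in tests.
"""

from fractions import Fraction

import mpmath

mpmath.mp.dps = 50


def to_mpf(x):
    # exact decimal -> mpf conversion for fixture values printed with <=10 dp
    return mpmath.mpf(Fraction(str(round(float(x), 10))).numerator) / mpmath.mpf(
        Fraction(str(round(float(x), 10))).denominator
    )


def k_to_mp(k):
    """Balance parameter: Fractions exactly, floats at full binary value."""
    if isinstance(k, Fraction):
        return mpmath.mpf(k.numerator) / mpmath.mpf(k.denominator)
    return mpmath.mpf(k)


def hp_entropy(cell, k, q):
    """Entropy of one (mu_lo, mu_hi, nu_lo, nu_hi) cell."""
    k = k_to_mp(k)
    mu_lo, mu_hi, nu_lo, nu_hi = (to_mpf(b) for b in cell)
    dm = [abs(mu_lo**q - k), abs(mu_hi**q - k)]
    dn = [abs(nu_lo**q - k), abs(nu_hi**q - k)]
    return ((1 - min(dm) - min(dn)) + (1 - max(dm) - max(dn))) / 2


def hp_standardize(cells, directions_by_col, k, q):
    """cells: nested list [alt][crit] of 4-tuples -> normalized matrix of mpf."""
    n_alt = len(cells)
    n_crit = len(cells[0])
    r = [[None] * n_crit for _ in range(n_alt)]
    for i in range(n_alt):
        for j in range(n_crit):
            e = hp_entropy(cells[i][j], k, q)
            r[i][j] = e if directions_by_col[j] == "benefit" else 1 - e
    out = [[None] * n_crit for _ in range(n_alt)]
    for j in range(n_crit):
        total = mpmath.fsum(r[i][j] for i in range(n_alt))
        for i in range(n_alt):
            out[i][j] = r[i][j] / total
    return out


def hp_attribute_weights(cells, k, q):
    """Mean entropy per criterion -> normalized -> entropy-method weights."""
    n_alt = len(cells)
    n_crit = len(cells[0])
    raw = []
    for j in range(n_crit):
        raw.append(mpmath.fsum(hp_entropy(cells[i][j], k, q) for i in range(n_alt)) / n_alt)
    total = mpmath.fsum(raw)
    nrm = [e / total for e in raw]
    w = [(1 - e) / (n_crit - mpmath.fsum(nrm)) for e in nrm]
    wsum = mpmath.fsum(w)
    return [x / wsum for x in w]


def hp_scores(matrix, weights, epsilon):
    """Weighted sum, power sum, and the three compromise scores."""
    eps = k_to_mp(epsilon)
    n_alt = len(matrix)
    S = [mpmath.fsum(w * r for w, r in zip(weights, row)) for row in matrix]
    M = [mpmath.fsum(r**w for w, r in zip(weights, row)) for row in matrix]
    total = mpmath.fsum(S[i] + M[i] for i in range(n_alt))
    s1 = [(S[i] + M[i]) / total for i in range(n_alt)]
    s2 = [S[i] / min(S) + M[i] / min(M) for i in range(n_alt)]
    denom = eps * max(S) + (1 - eps) * max(M)
    s3 = [(eps * S[i] + (1 - eps) * M[i]) / denom for i in range(n_alt)]
    return S, M, s1, s2, s3


def hp_final(s1, s2, s3):
    return [
        (a + b + c) / 3 + (a * b * c) ** (mpmath.mpf(1) / 3)
        for a, b, c in zip(s1, s2, s3)
    ]
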