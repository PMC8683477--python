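"""Independent brute-force oracles used to cross-check the implementations.

Everything here is written for clarity, not speed: plain loops and direct
formula evaluation, sharing no code with the package internals.
"""

import numpy as np


def roh_oracle(genos, pos, *, window_snps, window_het, window_missing,
               hit_frac, min_snps, min_length_bp):
    """Enumerate every window and candidate run explicitly.

    Returns a list of (start0, end0, n_snps) with BED-style coordinates.
    """
    L = len(genos)
    W = window_snps
    windows = []
    for s in range(L - W + 1):
        chunk = genos[s : s + W]
        n_het = sum(1 for g in chunk if g == 1)
        n_mis = sum(1 for g in chunk if g == -1)
        windows.append(n_het <= window_het and n_mis <= window_missing)
    qualifies = []
    for j in range(L):
        covering = [w for s, w in enumerate(windows) if s <= j <= s + W - 1]
        if not covering:
            qualifies.append(False)
            continue
        qualifies.append(sum(covering) / len(covering) >= hit_frac)
    segments = []
    j = 0
    while j < L:
        if qualifies[j]:
            j0 = j
            while j + 1 < L and qualifies[j + 1]:
                j += 1
            n = j - j0 + 1
            start0, end0 = int(pos[j0]) - 1, int(pos[j])
            if n >= min_snps and end0 - start0 >= min_length_bp:
                segments.append((start0, end0, n))
        j += 1
    return segments


def mendel_allowed(sire, dam):
    """Set of child dosages consistent with biallelic transmission."""
    transmit = {0: [0], 1: [0, 1], 2: [1]}
    return {a + b for a in transmit[sire] for b in transmit[dam]}


def sandwich_oracle(X, resid, flavor):
    """Direct matrix-product evaluation of the HC sandwich covariance."""
    X = np.asarray(X, float)
    n, k = X.shape
    bread = np.linalg.inv(X.T @ X)
    if flavor == "HC0":
        w = resid**2
    elif flavor == "HC1":
        w = resid**2 * n / (n - k)
    elif flavor == "HC3":
        H = X @ bread @ X.T
        w = resid**2 / (1 - np.diag(H)) ** 2
    else:
        raise ValueError(flavor)
    return bread @ (X.T @ np.diag(w) @ X) @ bread


def ols_oracle(X, y):
    """Textbook normal-equations solve (X'X)^-1 X'y."""
    X = np.asarray(X, float)
    return np.linalg.inv(X.T @ X) @ X.T @ np.asarray(y, float)
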