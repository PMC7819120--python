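"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity from its definition by direct enumeration,
sharing no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def enc_oracle(counts: dict[str, int], table) -> float:
    """Wright's ENC by literal per-family summation.

    F per amino acid with n >= 2 codons: (n * sum p^2 - 1)/(n - 1); class
    means over usable (F > 0) amino acids; threefold class imputed as the
    mean of the two- and fourfold means when unusable; 2 + sum k/Fk, capped
    to [20, 61].
    """
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, family in table.families.items():
        k = len(family)
        if k < 2:
            continue
        n = sum(counts.get(c, 0) for c in family)
        if n < 2:
            continue
        s = 0.0
        for c in family:
            p = counts.get(c, 0) / n
            s += p * p
        f = (n * s - 1) / (n - 1)
        if f > 0:
            per_class[k].append(f)
    means = {k: sum(v) / len(v) for k, v in per_class.items() if v}
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2
    sizes = {2: 9, 3: 1, 4: 5, 6: 3}
    if any(k not in means for k in sizes):
        return float("nan")
    enc = 2.0
    for k, size in sizes.items():
        enc += size / means[k]
    return min(61.0, max(20.0, enc))


def x3s_oracle(counts: dict[str, int], table) -> dict[str, float]:
    """Synonymous third-position base fractions by enumeration.

    Numerator: synonymous codons ending in the base.  Denominator: synonymous
    codons whose family has a member ending in the base (codonW silent-base
    convention).  Also returns gc3s over all synonymous codons.
    """
    out: dict[str, float] = {}
    syn = [f for f in table.families.values() if len(f) >= 2]
    total = sum(counts.get(c, 0) for fam in syn for c in fam)
    gc_end = sum(
        counts.get(c, 0) for fam in syn for c in fam if c[2] in "GC"
    )
    out["gc3s"] = gc_end / total if total else float("nan")
    for base in "ATGC":
        num = 0
        den = 0
        for fam in syn:
            fam_total = sum(counts.get(c, 0) for c in fam)
            if any(c[2] == base for c in fam):
                den += fam_total
            num += sum(counts.get(c, 0) for c in fam if c[2] == base)
        out[base.lower() + "3s"] = num / den if den else float("nan")
    return out


def ca_inertia_oracle(x: np.ndarray) -> np.ndarray:
    """Principal inertias of a CA by eigendecomposition of S^T S."""
    total = x.sum()
    p = x / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = np.zeros_like(p, dtype=float)
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if r[i] > 0 and c[j] > 0:
                s[i, j] = (p[i, j] - r[i] * c[j]) / np.sqrt(r[i] * c[j])
    eig = np.linalg.eigvalsh(s.T @ s)
    eig = np.clip(eig, 0, None)
    return np.sort(eig)[::-1]


def spearman_rho_oracle(x, y) -> float:
    """Spearman rho via explicit average ranks and the Pearson formula."""

    def average_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx = average_ranks(list(x))
    ry = average_ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def ols_oracle(x, y) -> tuple[float, float]:
    """Closed-form simple OLS slope and intercept."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    slope = sxy / sxx
    return slope, my - slope * mx
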