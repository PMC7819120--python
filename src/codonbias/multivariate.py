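"""Ordination of the gene x codon RSCU matrix and index correlations.

Correspondence analysis (CA) is the field's standard ordination for codon
usage: the RSCU matrix is treated as a frequency table, doubly centred by
row/column masses, and the standardized residuals are decomposed by SVD.
Axis i explains a fraction sigma_i^2 / sum(sigma^2) of the total inertia.
PCA on column-centred RSCU values is provided alongside, as the two are
often conflated in the literature and give different axis fractions.

Correlations between composition indices and axis coordinates use Spearman
(default, with average ranks for ties and an exact permutation p-value for
n < 10) or Pearson.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_model import CodonTable, informative_codons
from .metrics import GeneIndices, RscuTable


@dataclass(frozen=True)
class RscuMatrix:
    """Genes x informative-codons matrix of per-gene RSCU values.

    Codons of families unobserved in a gene are imputed as 0 (they
    contribute nothing); the number imputed is reported per gene.
    """

    genes: tuple[str, ...]
    codons: tuple[str, ...]
    values: np.ndarray
    imputed: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.genes), len(self.codons)):
            raise ValueError("matrix shape does not match labels")
        if np.any(self.values < 0) or np.any(~np.isfinite(self.values)):
            raise ValueError("matrix must be finite and non-negative")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes), columns=list(self.codons))


@dataclass(frozen=True)
class CoaResult:
    """Axes of a correspondence analysis (or PCA, same shape).

    ``inertia_fractions`` sum to 1 over the returned axes; coordinates are
    principal coordinates (rows = genes, columns = codons).
    """

    method: str
    inertia_fractions: np.ndarray
    singular_values: np.ndarray
    gene_coords: pd.DataFrame
    codon_coords: pd.DataFrame | None

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)


def build_rscu_matrix(
    per_gene_rscu: Sequence[RscuTable], table: CodonTable
) -> RscuMatrix:
    """Stack per-gene RSCU vectors over the informative codons (59 columns)."""
    if len(per_gene_rscu) < 2:
        raise ValueError("need at least 2 genes")
    codons = tuple(informative_codons(table))
    rows = []
    imputed: dict[str, int] = {}
    for r in per_gene_rscu:
        if all(t == 0 for t in r.family_totals.values()):
            raise ValueError(f"gene {r.scope} has zero codons")
        vec = np.array([r.get(c) for c in codons], dtype=float)
        n_undef = int(np.isnan(vec).sum())
        imputed[r.scope] = n_undef
        rows.append(np.nan_to_num(vec, nan=0.0))
    genes = tuple(r.scope for r in per_gene_rscu)
    return RscuMatrix(genes=genes, codons=codons, values=np.vstack(rows), imputed=imputed)


def _orient_axes(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix axis signs: the largest-|loading| column coordinate is positive."""
    for j in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, j])))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
            u[:, j] = -u[:, j]
    return u, v


def correspondence_analysis(m: RscuMatrix, tol: float = 1e-12) -> CoaResult:
    """Standard CA of a non-negative matrix.

    P = X / total; S = Dr^-1/2 (P - r c^T) Dc^-1/2; SVD of S.  Axes with
    numerically zero singular value are dropped (degenerate matrices return
    fewer axes, never raise).
    """
    x = m.values
    total = x.sum()
    if total <= 0:
        raise ValueError("matrix grand total must be positive")
    p = x / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    # rows/columns with zero mass carry no information; guard the rescaling
    dr = np.where(r > 0, 1.0 / np.sqrt(np.where(r > 0, r, 1)), 0.0)
    dc = np.where(c > 0, 1.0 / np.sqrt(np.where(c > 0, c, 1)), 0.0)
    s = dr[:, None] * (p - np.outer(r, c)) * dc[None, :]
    u, sig, vt = np.linalg.svd(s, full_matrices=False)
    keep = sig > tol * max(1.0, sig[0] if len(sig) else 0.0)
    max_axes = min(len(m.genes), len(m.codons)) - 1
    u, sig, v = u[:, keep][:, :max_axes], sig[keep][:max_axes], vt[keep].T[:, :max_axes]
    inertia = sig**2
    fractions = inertia / inertia.sum() if inertia.sum() > 0 else inertia
    row_coords = dr[:, None] * u * sig[None, :]
    col_coords = dc[:, None] * v * sig[None, :]
    row_coords, col_coords = _orient_axes(row_coords, col_coords)
    axes = [f"Axis{i + 1}" for i in range(len(sig))]
    return CoaResult(
        method="ca",
        inertia_fractions=fractions,
        singular_values=sig,
        gene_coords=pd.DataFrame(row_coords, index=list(m.genes), columns=axes),
        codon_coords=pd.DataFrame(col_coords, index=list(m.codons), columns=axes),
    )


def pca(m: RscuMatrix, tol: float = 1e-12) -> CoaResult:
    """PCA of the column-centred RSCU matrix (variance fractions per axis)."""
    x = m.values - m.values.mean(axis=0, keepdims=True)
    u, sig, vt = np.linalg.svd(x, full_matrices=False)
    keep = sig > tol * max(1.0, sig[0] if len(sig) else 0.0)
    max_axes = min(len(m.genes) - 1, len(m.codons))
    u, sig, v = u[:, keep][:, :max_axes], sig[keep][:max_axes], vt[keep].T[:, :max_axes]
    var = sig**2
    fractions = var / var.sum() if var.sum() > 0 else var
    axes = [f"Axis{i + 1}" for i in range(len(sig))]
    scores = u * sig[None, :]
    scores, v = _orient_axes(scores, v)
    return CoaResult(
        method="pca",
        inertia_fractions=fractions,
        singular_values=sig,
        gene_coords=pd.DataFrame(scores, index=list(m.genes), columns=axes),
        codon_coords=pd.DataFrame(v, index=list(m.codons), columns=axes),
    )


@dataclass(frozen=True)
class CorrelationResult:
    index_a: str
    index_b: str
    method: str
    rho: float
    p_value: float


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with average ranks; exact permutation p below n = 10."""
    n = len(x)
    rho = float(stats.spearmanr(x, y).statistic)
    if math.isnan(rho):
        return rho, math.nan
    if n < 10:
        # exact two-sided permutation test on the rank covariance (the
        # rank variances are permutation-invariant, so covariance suffices)
        rx = stats.rankdata(x) - (n + 1) / 2
        ry = stats.rankdata(y) - (n + 1) / 2
        obs = abs(float(rx @ ry))
        perms = np.array(list(itertools.permutations(ry)))
        stat = np.abs(perms @ rx)
        return rho, float(np.mean(stat >= obs - 1e-9))
    return rho, float(stats.spearmanr(x, y).pvalue)


def correlate_indices(
    indices: Sequence[GeneIndices],
    axes: CoaResult | None = None,
    method: str = "spearman",
    n_axes: int = 4,
) -> list[CorrelationResult]:
    """All pairwise correlations among {GC, ENC, GC3s, GC3, Axis1..AxisK}."""
    if len(indices) < 3:
        raise ValueError("need at least 3 genes for correlations")
    cols: dict[str, np.ndarray] = {
        "GC": np.array([ix.gc for ix in indices]),
        "ENC": np.array([ix.enc for ix in indices]),
        "GC3s": np.array([ix.gc3s for ix in indices]),
        "GC3": np.array([ix.gc3 for ix in indices]),
    }
    if axes is not None:
        gene_order = [ix.gene_id for ix in indices]
        coords = axes.gene_coords.loc[gene_order]
        for j in range(min(n_axes, coords.shape[1])):
            cols[f"Axis{j + 1}"] = coords.iloc[:, j].to_numpy()
    out: list[CorrelationResult] = []
    names = list(cols)
    for i, a in enumerate(names):
        for b in names[i:]:
            x, y = cols[a], cols[b]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho, p = (1.0, 0.0) if a == b else (math.nan, math.nan)
            elif a == b:
                rho, p = 1.0, 0.0
            elif method == "spearman":
                rho, p = _spearman(x, y)
            elif method == "pearson":
                res = stats.pearsonr(x, y)
                rho, p = float(res.statistic), float(res.pvalue)
            else:
                raise ValueError(f"unknown method: {method!r}")
            out.append(CorrelationResult(a, b, method, rho, p))
    return out


def correlation_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Lower-triangular matrix of rho with significance stars."""
    names: list[str] = []
    for res in results:
        for n in (res.index_a, res.index_b):
            if n not in names:
                names.append(n)
    mat = pd.DataFrame("", index=names, columns=names, dtype=object)
    for res in results:
        star = ""
        if not math.isnan(res.p_value):
            if res.p_value < 0.01:
                star = "**"
            elif res.p_value < 0.05:
                star = "*"
        cell = f"{res.rho:.3f}{star}" if not math.isnan(res.rho) else "NA"
        mat.loc[res.index_b, res.index_a] = cell
    return mat
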