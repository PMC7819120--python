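"""Diagnostics separating mutation pressure from selection.

Three classical plots, emitted as plot-ready tables:

* **PR2-bias plot** — per gene (and per fourfold family), the third-position
  ratios y = A3/(A3+T3) against x = G3/(G3+C3).  Under parity rule 2 (no
  strand-asymmetric mutation or selection) both ratios are 0.5; displacement
  signals directional forces.  Measured over the eight four-codon blocks
  whose third position is fully degenerate (an all-sense-codon universe is
  available behind a switch).
* **ENC plot** — observed ENC against GC3s, with Wright's expected curve
  ENC_exp(s) = 2 + s + 29 / (s^2 + (1-s)^2) for genes shaped by third-
  position composition alone.  Genes under translational selection fall
  below the curve (positive deviation = expected - observed).
* **Neutrality plot** — GC12 against GC3 with an OLS fit; slope near 1 means
  third-position composition drives all positions (mutation dominance),
  slope near 0 means positions 1-2 are conserved against third-position
  drift (selection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_model import CodonSet, fourfold_pr2_families
from .metrics import CodonCountTable, GeneIndices


@dataclass(frozen=True)
class Pr2Point:
    scope: str
    x: float  # G3/(G3+C3)
    y: float  # A3/(A3+T3)
    n_codons: int

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.x) or math.isnan(self.y))


@dataclass(frozen=True)
class EncPlotPoint:
    gene_id: str
    gc3s: float
    enc_observed: float
    enc_expected: float

    @property
    def deviation(self) -> float:
        """Expected minus observed; positive = below Wright's curve."""
        return self.enc_expected - self.enc_observed


@dataclass(frozen=True)
class NeutralityFit:
    points: tuple[tuple[str, float, float], ...]  # (gene, gc3, gc12)
    slope: float
    intercept: float
    r: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["gene_id", "gc3", "gc12"])


def _pr2_point(
    counts: CodonCountTable, codon_universe: Sequence[str], scope: str
) -> Pr2Point:
    tallies = {b: 0 for b in "ATGC"}
    n = 0
    for codon in codon_universe:
        k = counts.get(codon)
        tallies[codon[2]] += k
        n += k
    at = tallies["A"] + tallies["T"]
    gc = tallies["G"] + tallies["C"]
    return Pr2Point(
        scope=scope,
        x=tallies["G"] / gc if gc else math.nan,
        y=tallies["A"] / at if at else math.nan,
        n_codons=n,
    )


def pr2_gene(
    counts: CodonCountTable,
    families: Sequence[CodonSet] | None = None,
    universe: str = "fourfold",
) -> Pr2Point:
    """Gene-level PR2 point over the eight fourfold blocks (default) or all
    sense codons (``universe="all"``)."""
    table = counts.table
    if universe == "fourfold":
        fams = families if families is not None else fourfold_pr2_families(table)
        codons = [c for fam in fams for c in fam]
    elif universe == "all":
        codons = list(table.sense_codons)
    else:
        raise ValueError(f"unknown PR2 universe: {universe!r}")
    return _pr2_point(counts, codons, scope=counts.scope)


def pr2_family(
    per_gene_counts: Sequence[CodonCountTable], family: CodonSet
) -> list[Pr2Point]:
    """One PR2 point per gene restricted to one four-codon family."""
    return [
        _pr2_point(c, list(family), scope=f"{c.scope}:{family.name}")
        for c in per_gene_counts
    ]


def pr2_weighted_mean(
    per_gene_counts: Sequence[CodonCountTable],
    families: Sequence[CodonSet] | None = None,
) -> tuple[float, float]:
    """Codon-number-weighted mean (y, x) over all genes and families.

    Each defined per-gene-per-family point is weighted by its codon support;
    this is the summary statistic quoted for fourfold PR2 analyses.
    """
    table = per_gene_counts[0].table if per_gene_counts else None
    fams = families if families is not None else fourfold_pr2_families(table)
    pts = [p for fam in fams for p in pr2_family(per_gene_counts, fam)]
    num_y = num_x = wy = wx = 0.0
    for p in pts:
        if not math.isnan(p.y):
            num_y += p.y * p.n_codons
            wy += p.n_codons
        if not math.isnan(p.x):
            num_x += p.x * p.n_codons
            wx += p.n_codons
    return (num_y / wy if wy else math.nan, num_x / wx if wx else math.nan)


def expected_enc(gc3s: float) -> float:
    """Wright's expected ENC under third-position composition alone."""
    if not 0 <= gc3s <= 1:
        raise ValueError("gc3s must lie in [0, 1]")
    s = gc3s
    value = 2 + s + 29.0 / (s**2 + (1 - s) ** 2)
    return min(61.0, value)


def enc_plot(indices: Sequence[GeneIndices]) -> list[EncPlotPoint]:
    """One ENC-plot point per gene with a defined ENC and GC3s."""
    pts = []
    for ix in indices:
        if math.isnan(ix.enc) or math.isnan(ix.gc3s):
            continue
        pts.append(
            EncPlotPoint(
                gene_id=ix.gene_id,
                gc3s=ix.gc3s,
                enc_observed=ix.enc,
                enc_expected=expected_enc(ix.gc3s),
            )
        )
    return pts


def enc_plot_summary(
    points: Sequence[EncPlotPoint], tolerance: float = 2.0
) -> dict[str, int]:
    """Counts of genes on/below/above the expected curve at a closeness
    tolerance (in ENC units)."""
    on = sum(1 for p in points if abs(p.deviation) <= tolerance)
    below = sum(1 for p in points if p.deviation > tolerance)
    above = sum(1 for p in points if p.deviation < -tolerance)
    return {"on_curve": on, "below_curve": below, "above_curve": above}


def neutrality_fit(indices: Sequence[GeneIndices]) -> NeutralityFit:
    """OLS of GC12 on GC3 with the Pearson correlation of the scatter."""
    pts = [
        (ix.gene_id, ix.gc3, ix.gc12)
        for ix in indices
        if not (math.isnan(ix.gc3) or math.isnan(ix.gc12))
    ]
    if len(pts) < 3:
        raise ValueError("need at least 3 genes for the neutrality fit")
    gc3 = np.array([p[1] for p in pts])
    gc12 = np.array([p[2] for p in pts])
    if np.ptp(gc3) == 0:
        return NeutralityFit(tuple(pts), math.nan, math.nan, math.nan)
    res = stats.linregress(gc3, gc12)
    return NeutralityFit(
        points=tuple(pts),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
    )
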