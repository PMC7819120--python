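"""Optimal-codon identification from ENC-ranked expression proxy sets.

With no expression measurements, codon-bias strength (low ENC) is the
standard proxy for high expression in organellar codon-usage studies.  The
procedure:

1. rank genes by ENC; the lowest-ENC fraction (default 5%) is the
   high-expression set, the highest-ENC fraction the low-expression set;
2. pool codon counts within each set and compute RSCU in each;
3. dRSCU = RSCU(high) - RSCU(low); codons with dRSCU above a threshold
   (default 0.08) are "high-expression" codons;
4. the optimal codons are those that are also the genome-wide top-RSCU
   codon of their synonymous family ("high-frequency" codons).

An alternative selection mode uses absolute ENC cut-offs instead of ranked
fractions (``mode="enc_threshold"``); on data whose ENC range does not reach
such cut-offs it produces empty sets, so the ranked-fraction mode is the
default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .codon_model import CodonSet, CodonTable
from .metrics import CodonCountTable, GeneIndices, RscuTable, pool_counts, rscu


@dataclass(frozen=True)
class ExpressionSets:
    """Disjoint high- and low-bias gene sets with their pooled counts."""

    high_genes: tuple[str, ...]
    low_genes: tuple[str, ...]
    fraction: float
    high_counts: CodonCountTable | None = None
    low_counts: CodonCountTable | None = None


@dataclass(frozen=True)
class DeltaRscuTable:
    """Per-codon RSCU in the two sets and their difference."""

    rscu_high: Mapping[str, float]
    rscu_low: Mapping[str, float]
    delta: Mapping[str, float]  # NaN where a family is absent from a set
    threshold: float
    high_expression_codons: CodonSet

    def frame(self, table: CodonTable) -> pd.DataFrame:
        rows = []
        for aa, family in sorted(table.families.items()):
            for codon in family:
                rows.append(
                    {
                        "amino_acid": aa,
                        "codon": codon,
                        "rscu_high": self.rscu_high.get(codon, math.nan),
                        "rscu_low": self.rscu_low.get(codon, math.nan),
                        "delta_rscu": self.delta.get(codon, math.nan),
                        "high_expression": codon in self.high_expression_codons,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class OptimalCodonCall:
    high_frequency_codons: CodonSet
    high_expression_codons: CodonSet
    optimal_codons: CodonSet
    ties: tuple[str, ...] = ()  # families whose top-RSCU codon was a tie


def high_frequency_codons(
    pooled_rscu: RscuTable, table: CodonTable | None = None
) -> tuple[CodonSet, tuple[str, ...]]:
    """The top-RSCU codon of every degenerate family, with tie accounting.

    Ties are broken by larger raw count implied by RSCU (equivalent here to
    RSCU since counts are proportional within a family), then alphabetically;
    tied families are reported so callers can flag them.  Met/Trp and
    unobserved families are skipped.
    """
    table = table or pooled_rscu.table
    chosen: list[str] = []
    tied: list[str] = []
    for aa, family in table.families.items():
        if len(family) < 2:
            continue
        values = [(pooled_rscu.get(c), c) for c in family]
        if all(math.isnan(v) for v, _ in values):
            warnings.warn(f"family {aa} unobserved; skipped", stacklevel=2)
            continue
        best = max(v for v, _ in values)
        best_codons = sorted(c for v, c in values if v == best)
        if len(best_codons) > 1:
            tied.append(aa)
        chosen.append(best_codons[0])
    return CodonSet("high_frequency", tuple(sorted(chosen))), tuple(tied)


def select_expression_sets(
    indices: Sequence[GeneIndices],
    fraction: float = 0.05,
    counts_by_gene: Mapping[str, CodonCountTable] | None = None,
    mode: str = "fraction",
    enc_low_cut: float = 30.0,
    enc_high_cut: float = 55.0,
    set_size: int | None = None,
) -> ExpressionSets:
    """Pick high-bias (low ENC) and low-bias (high ENC) gene sets.

    ``mode="fraction"`` takes max(1, round(fraction * n)) genes from each end
    of the ENC ranking (``set_size`` overrides the computed size);
    ``mode="enc_threshold"`` takes genes with ENC below/above the absolute
    cut-offs.  Ranking ties are broken stably by gene id.
    """
    if len(indices) < 2:
        raise ValueError("need at least 2 genes to form expression sets")
    if any(math.isnan(ix.enc) for ix in indices):
        raise ValueError("all genes must have a defined ENC")
    ranked = sorted(indices, key=lambda ix: (ix.enc, ix.gene_id))
    if mode == "fraction":
        if not 0 < fraction < 0.5:
            raise ValueError("fraction must be in (0, 0.5)")
        k = set_size if set_size is not None else max(1, round(fraction * len(ranked)))
        k = min(k, len(ranked) // 2)
        high = ranked[:k]
        low = ranked[-k:]
    elif mode == "enc_threshold":
        high = [ix for ix in ranked if ix.enc < enc_low_cut]
        low = [ix for ix in ranked if ix.enc > enc_high_cut]
    else:
        raise ValueError(f"unknown selection mode: {mode!r}")
    high_ids = tuple(ix.gene_id for ix in high)
    low_ids = tuple(ix.gene_id for ix in low)
    high_counts = low_counts = None
    if counts_by_gene is not None:
        if high_ids:
            high_counts = pool_counts([counts_by_gene[g] for g in high_ids])
        if low_ids:
            low_counts = pool_counts([counts_by_gene[g] for g in low_ids])
    return ExpressionSets(
        high_genes=high_ids,
        low_genes=low_ids,
        fraction=fraction,
        high_counts=high_counts,
        low_counts=low_counts,
    )


def delta_rscu(
    high_counts: CodonCountTable,
    low_counts: CodonCountTable,
    table: CodonTable | None = None,
    threshold: float = 0.08,
) -> DeltaRscuTable:
    """RSCU within each pooled set and their per-codon difference.

    A codon whose family is unobserved in either set has an undefined delta
    and is never flagged.  Met/Trp (no synonymous choice) are never flagged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    table = table or high_counts.table
    r_high = rscu(high_counts, table)
    r_low = rscu(low_counts, table)
    delta: dict[str, float] = {}
    flagged: list[str] = []
    for aa, family in table.families.items():
        for c in family:
            d = r_high.get(c) - r_low.get(c)
            delta[c] = d
            if len(family) >= 2 and not math.isnan(d) and d > threshold:
                flagged.append(c)
    return DeltaRscuTable(
        rscu_high=dict(r_high.rscu),
        rscu_low=dict(r_low.rscu),
        delta=delta,
        threshold=threshold,
        high_expression_codons=CodonSet("high_expression", tuple(sorted(flagged))),
    )


def call_optimal_codons(
    hf: CodonSet, dr: DeltaRscuTable, ties: tuple[str, ...] = ()
) -> OptimalCodonCall:
    """Optimal codons = high-frequency AND high-expression."""
    optimal = tuple(sorted(set(hf.codons) & set(dr.high_expression_codons.codons)))
    return OptimalCodonCall(
        high_frequency_codons=hf,
        high_expression_codons=dr.high_expression_codons,
        optimal_codons=CodonSet("optimal", optimal),
        ties=ties,
    )
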