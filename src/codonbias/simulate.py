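"""Synthetic CDS sets with controlled mutation pressure and selection.

The generator emulates the statistical structure the downstream analysis
assumes: a set of genes whose third-position composition is set per gene by
a mutational GC3 target, optionally mixed with translational selection that
moves probability mass to one preferred codon per synonymous family.

Per gene, codons are drawn independently per amino-acid site from

    p(codon) = (1 - w) * p_mut(codon) + w * [codon == preferred(family)]

where p_mut factorizes over positions: positions 1-2 use a fixed genome-like
base composition (A .30, T .31, C .18, G .21, matching an AT-rich plastid),
and position 3 uses A = T = (1 - g)/2, G = C = g/2 for the gene's GC3 target
g, all renormalized within the synonymous family.  With w = 0 genes are
shaped by third-position composition alone and fall on Wright's expected
ENC-GC3s curve; with increasing w they drop below it.  This is the
parameter-recovery ground truth the test-suite leans on.

Not emulated: amino-acid composition tied to real protein families, codon
autocorrelation along a gene, RNA editing, or among-family differences in
selection strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_model import CodonTable, standard_table
from .cds_io import CodingSequence
from .metrics import GeneIndices
from .selection import EncPlotPoint, NeutralityFit

#: published high-frequency codon set of the D. grandiflorum chloroplast
#: (top-RSCU codon of each degenerate family); the default selection target
DEFAULT_PREFERRED_CODONS: tuple[str, ...] = (
    "GCT", "TGT", "GAT", "GAA", "TTT", "GGA", "CAT", "ATT", "AAA",
    "TTA", "AAT", "CCT", "CAA", "AGA", "TCT", "ACT", "GTA", "TAT",
)

#: genome-like base composition used at codon positions 1-2
DEFAULT_POS12_COMPOSITION: Mapping[str, float] = {
    "A": 0.30, "T": 0.31, "C": 0.18, "G": 0.21,
}


@dataclass(frozen=True)
class SimSpec:
    """Study-condition parameters of the generator.

    Defaults mirror the scale of a chloroplast CDS set: ~50 genes of
    300-6,500 nt with per-gene third-position GC targets spanning 0.20-0.50
    and no translational selection.
    """

    n_genes: int = 50
    length_codons: tuple[int, int] = (100, 2166)
    gc3_range: tuple[float, float] = (0.20, 0.50)
    selection_weight: float = 0.0
    preferred_codons: tuple[str, ...] = DEFAULT_PREFERRED_CODONS
    pos12_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POS12_COMPOSITION)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.selection_weight <= 1:
            raise ValueError("selection_weight must lie in [0, 1]")
        lo, hi = self.gc3_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("gc3_range bounds must satisfy 0 <= lo <= hi <= 1")
        if self.length_codons[0] > self.length_codons[1] or self.length_codons[0] < 1:
            raise ValueError("length_codons range is empty or non-positive")


@dataclass(frozen=True)
class SimTruth:
    """Per-gene ground truth emitted alongside the sequences."""

    records: tuple[dict, ...]  # gene_id, target_gc3, selection_weight, length_codons
    spec: SimSpec

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.records))

    @staticmethod
    def concat(parts: Sequence["SimTruth"]) -> "SimTruth":
        records = tuple(r for p in parts for r in p.records)
        return SimTruth(records=records, spec=parts[0].spec)


def _family_distributions(
    table: CodonTable,
    gc3: float,
    w: float,
    preferred: set[str],
    pos12: Mapping[str, float],
) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    p3 = {"A": (1 - gc3) / 2, "T": (1 - gc3) / 2, "G": gc3 / 2, "C": gc3 / 2}
    out: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for aa, family in table.families.items():
        weights = np.array(
            [pos12[c[0]] * pos12[c[1]] * p3[c[2]] for c in family], dtype=float
        )
        p_mut = weights / weights.sum()
        pref = [i for i, c in enumerate(family) if c in preferred]
        if pref and len(family) >= 2:
            p_sel = np.zeros(len(family))
            p_sel[pref[0]] = 1.0
            p = (1 - w) * p_mut + w * p_sel
        else:
            p = p_mut
        out[aa] = (family, p / p.sum())
    return out


def simulate_cds_set(
    spec: SimSpec, table: CodonTable | None = None
) -> tuple[list[CodingSequence], SimTruth]:
    """Draw a reproducible synthetic CDS set under ``spec``.

    Every gene starts with ATG, ends with TAA, and is otherwise i.i.d. codons
    from the per-gene mixture distribution.  Amino acids are uniform over the
    20; the same seed yields byte-identical sequences.
    """
    table = table or standard_table()
    rng = np.random.default_rng(spec.seed)
    preferred = {c for c in spec.preferred_codons}
    amino_acids = sorted(table.families)
    genes: list[CodingSequence] = []
    records: list[dict] = []
    lo, hi = spec.length_codons
    for g in range(spec.n_genes):
        length = int(rng.integers(lo, hi + 1))
        gc3 = float(rng.uniform(*spec.gc3_range))
        dists = _family_distributions(
            table, gc3, spec.selection_weight, preferred, spec.pos12_composition
        )
        aa_idx = rng.integers(0, len(amino_acids), size=length)
        codons = np.empty(length, dtype=object)
        for ai, aa in enumerate(amino_acids):
            sites = np.nonzero(aa_idx == ai)[0]
            if sites.size:
                family, p = dists[aa]
                draws = rng.choice(len(family), size=sites.size, p=p)
                for s, d in zip(sites, draws):
                    codons[s] = family[d]
        gene_id = f"sim{g + 1:03d}"
        genes.append(CodingSequence(gene_id, "ATG" + "".join(codons) + "TAA"))
        records.append(
            {
                "gene_id": gene_id,
                "target_gc3": gc3,
                "selection_weight": spec.selection_weight,
                "length_codons": length,
            }
        )
    return genes, SimTruth(records=tuple(records), spec=spec)


def simulate_cohorts(
    spec: SimSpec, selection_weights: Sequence[float], table: CodonTable | None = None
) -> tuple[list[CodingSequence], SimTruth]:
    """One cohort per selection weight, with distinct gene ids and seeds
    derived from ``spec.seed``."""
    genes: list[CodingSequence] = []
    truths: list[SimTruth] = []
    for j, w in enumerate(selection_weights):
        sub = replace(spec, selection_weight=w, seed=spec.seed + j)
        g, t = simulate_cds_set(sub, table)
        tag = f"w{str(w).replace('.', 'p')}"
        g = [replace(cds, gene_id=f"{tag}_{cds.gene_id}") for cds in g]
        t = SimTruth(
            records=tuple(
                {**r, "gene_id": f"{tag}_{r['gene_id']}"} for r in t.records
            ),
            spec=sub,
        )
        genes.extend(g)
        truths.append(t)
    return genes, SimTruth.concat(truths)


@dataclass(frozen=True)
class RecoveryReport:
    """Did the analysis recover what the generator put in?"""

    gc3_target_realized_corr: float
    gc3_corr_by_w: Mapping[float, float]
    mean_deviation_by_w: Mapping[float, float]
    mean_abs_deviation_by_w: Mapping[float, float]
    neutrality_slope: float
    deviation_ordering_ok: bool


def recovery_report(
    truth: SimTruth,
    indices: Sequence[GeneIndices],
    fit: NeutralityFit,
    enc_points: Sequence[EncPlotPoint],
) -> RecoveryReport:
    """Compare generator ground truth with the recomputed indices.

    Reports the correlation between target and realized GC3s, ENC-plot
    deviation stratified by selection weight, the neutrality slope, and
    whether mean deviation increases with selection weight.
    """
    truth_by_gene = {r["gene_id"]: r for r in truth.records}
    if set(truth_by_gene) != {ix.gene_id for ix in indices}:
        raise ValueError("truth and indices cover different gene sets")
    targets = np.array([truth_by_gene[ix.gene_id]["target_gc3"] for ix in indices])
    realized = np.array([ix.gc3s for ix in indices])
    ws_per_gene = np.array(
        [truth_by_gene[ix.gene_id]["selection_weight"] for ix in indices]
    )
    corr = float(np.corrcoef(targets, realized)[0, 1]) if len(indices) > 2 else math.nan
    corr_by_w: dict[float, float] = {}
    for w in sorted(set(ws_per_gene)):
        mask = ws_per_gene == w
        if mask.sum() > 2 and np.ptp(targets[mask]) > 0 and np.ptp(realized[mask]) > 0:
            corr_by_w[float(w)] = float(
                np.corrcoef(targets[mask], realized[mask])[0, 1]
            )
        else:
            corr_by_w[float(w)] = math.nan
    dev_by_w: dict[float, list[float]] = {}
    for p in enc_points:
        w = truth_by_gene[p.gene_id]["selection_weight"]
        dev_by_w.setdefault(w, []).append(p.deviation)
    mean_dev = {w: float(np.mean(v)) for w, v in sorted(dev_by_w.items())}
    mean_abs = {w: float(np.mean(np.abs(v))) for w, v in sorted(dev_by_w.items())}
    ws = sorted(mean_dev)
    ordering = all(mean_dev[a] < mean_dev[b] for a, b in zip(ws, ws[1:]))
    return RecoveryReport(
        gc3_target_realized_corr=corr,
        gc3_corr_by_w=corr_by_w,
        mean_deviation_by_w=mean_dev,
        mean_abs_deviation_by_w=mean_abs,
        neutrality_slope=fit.slope,
        deviation_ordering_ok=ordering,
    )
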