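"""Per-gene and pooled codon-usage statistics.

Implements the classical index set of codon-usage analysis:

* codon counting and pooling;
* RSCU, the relative synonymous codon usage — a codon's count divided by the
  mean count of its synonymous family, so RSCU = 1 means no bias and a
  family's RSCU values sum to its degeneracy;
* positional GC content (GC, GC1, GC2, GC3, GC12) over sense codons;
* synonymous third-position composition (GC3s, A3s/T3s/G3s/C3s) with the
  codonW "silent base" denominator convention;
* Wright's effective number of codons (ENC), the equivalent number of
  equally-used codons, ranging from 20 (one codon per amino acid) to 61
  (uniform usage).

Stop codons never enter any statistic; undefined quantities are NaN, never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .codon_model import ALL_CODONS, STOP, CodonTable, fourfold_pr2_families
from .cds_io import CodingSequence


@dataclass(frozen=True)
class CodonCountTable:
    """Raw codon counts for one gene or a pooled gene set.

    ``n_codons`` counts sense codons only; stop-codon tallies are retained
    in ``counts`` but excluded from every downstream statistic.
    """

    scope: str
    counts: Mapping[str, int]
    table: CodonTable

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(ALL_CODONS)
        if bad:
            raise ValueError(f"unknown codons in counts: {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("codon counts must be non-negative")

    @property
    def n_codons(self) -> int:
        return sum(self.counts.get(c, 0) for c in self.table.sense_codons)

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def family_total(self, aa: str) -> int:
        return sum(self.counts.get(c, 0) for c in self.table.families[aa])


@dataclass(frozen=True)
class RscuTable:
    scope: str
    rscu: Mapping[str, float]  # NaN marks codons of unobserved families
    family_totals: Mapping[str, int]
    table: CodonTable

    def get(self, codon: str) -> float:
        return self.rscu.get(codon, math.nan)


class PositionalGc(NamedTuple):
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float


class SynonymousThird(NamedTuple):
    gc3s: float
    a3s: float
    t3s: float
    g3s: float
    c3s: float


@dataclass(frozen=True)
class GeneIndices:
    """The full per-gene index set used by the downstream diagnostics."""

    gene_id: str
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float
    a3s: float
    t3s: float
    g3s: float
    c3s: float
    a3: int
    t3: int
    g3: int
    c3: int
    enc: float
    n_codons: int

    @property
    def n_aa(self) -> int:
        return self.n_codons


def iter_codons(seq: str) -> Iterable[str]:
    for i in range(0, len(seq) - len(seq) % 3, 3):
        yield seq[i : i + 3]


def count_codons(cds: CodingSequence, table: CodonTable) -> CodonCountTable:
    """Tally frame-0 codons of a QC-accepted CDS."""
    if cds.length_nt % 3:
        raise ValueError(
            f"{cds.gene_id}: length {cds.length_nt} is not a multiple of 3"
        )
    counts: dict[str, int] = {}
    for codon in iter_codons(cds.seq):
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(scope=cds.gene_id, counts=counts, table=table)


def pool_counts(tables: Sequence[CodonCountTable]) -> CodonCountTable:
    """Element-wise sum of count tables (a genome-wide pooled table)."""
    if not tables:
        raise ValueError("cannot pool an empty list of count tables")
    counts: dict[str, int] = {}
    for t in tables:
        for codon, n in t.counts.items():
            counts[codon] = counts.get(codon, 0) + n
    return CodonCountTable(scope="pooled", counts=counts, table=tables[0].table)


def counts_from_mapping(
    counts: Mapping[str, int], table: CodonTable, scope: str = "pooled"
) -> CodonCountTable:
    """Build a count table from a plain codon -> count mapping."""
    return CodonCountTable(scope=scope, counts=dict(counts), table=table)


def rscu(counts: CodonCountTable, table: CodonTable | None = None) -> RscuTable:
    """Relative synonymous codon usage of every sense codon.

    RSCU(c) = count(c) * k / family_total, k the family's degeneracy.  Codons
    of families with zero observations get NaN (no usage to be relative to).
    Met and Trp, when observed, have RSCU identically 1.
    """
    table = table or counts.table
    values: dict[str, float] = {}
    totals: dict[str, int] = {}
    for aa, family in table.families.items():
        total = sum(counts.get(c) for c in family)
        totals[aa] = total
        k = len(family)
        for c in family:
            values[c] = counts.get(c) * k / total if total else math.nan
    return RscuTable(
        scope=counts.scope, rscu=values, family_totals=totals, table=table
    )


def positional_gc(cds: CodingSequence, table: CodonTable) -> PositionalGc:
    """GC fraction overall and by codon position, over sense codons only."""
    n = 0
    gc_pos = [0, 0, 0]
    for codon in iter_codons(cds.seq):
        if table.codon_to_aa.get(codon, STOP) == STOP:
            continue
        n += 1
        for i, base in enumerate(codon):
            if base in "GC":
                gc_pos[i] += 1
    if n == 0:
        return PositionalGc(*(math.nan,) * 5)
    gc1, gc2, gc3 = (g / n for g in gc_pos)
    return PositionalGc(
        gc=sum(gc_pos) / (3 * n), gc1=gc1, gc2=gc2, gc3=gc3, gc12=(gc1 + gc2) / 2
    )


def synonymous_third_position(
    counts: CodonCountTable,
    table: CodonTable | None = None,
    denominator: str = "codonw",
) -> SynonymousThird:
    """Third-position composition over synonymous codons.

    Synonymous codons are those of families with degeneracy >= 2 (Met, Trp
    and stops excluded).  GC3s is the fraction of synonymous codons ending in
    G or C.  For the per-base fractions x3s the numerator is the number of
    synonymous codons ending in base x; the denominator follows the codonW
    "silent base" convention — synonymous codons whose family contains an
    x-ending member — or, with ``denominator="all"``, simply all synonymous
    codons.
    """
    table = table or counts.table
    syn_families = [f for f in table.families.values() if len(f) >= 2]
    n_syn = 0
    end_count = {b: 0 for b in "ACGT"}
    denom = {b: 0 for b in "ACGT"}
    for family in syn_families:
        fam_n = sum(counts.get(c) for c in family)
        n_syn += fam_n
        fam_ends = {c[2] for c in family}
        for b in fam_ends:
            denom[b] += fam_n
        for c in family:
            end_count[c[2]] += counts.get(c)
    if n_syn == 0:
        return SynonymousThird(*(math.nan,) * 5)
    if denominator == "all":
        denom = {b: n_syn for b in "ACGT"}
    elif denominator != "codonw":
        raise ValueError(f"unknown denominator convention: {denominator!r}")

    def frac(b: str) -> float:
        return end_count[b] / denom[b] if denom[b] else math.nan

    gc3s = (end_count["G"] + end_count["C"]) / n_syn
    return SynonymousThird(
        gc3s=gc3s, a3s=frac("A"), t3s=frac("T"), g3s=frac("G"), c3s=frac("C")
    )


def effective_number_of_codons(
    counts: CodonCountTable, table: CodonTable | None = None
) -> float:
    """Wright's ENC from a codon count table.

    Per amino acid with n >= 2 observed codons the codon homozygosity is
    estimated as F = (n * sum p_i^2 - 1) / (n - 1); amino acids with n < 2
    or F <= 0 are dropped from their degeneracy-class mean.  ENC = 2 +
    9/F2 + 1/F3 + 5/F4 + 3/F6 over the class means.  If the threefold class
    (Ile) is unusable its mean is imputed as (F2 + F4) / 2; if any other
    class mean is unusable the ENC is undefined (NaN).  The result is capped
    to [20, 61].
    """
    table = table or counts.table
    f_hat: dict[str, float] = {}
    for aa, family in table.families.items():
        if len(family) < 2:
            continue
        n = sum(counts.get(c) for c in family)
        if n < 2:
            continue
        sum_p2 = sum((counts.get(c) / n) ** 2 for c in family)
        f = (n * sum_p2 - 1) / (n - 1)
        if f > 0:
            f_hat[aa] = f
    class_mean: dict[int, float] = {}
    for k, aas in table.degeneracy_classes.items():
        usable = [f_hat[aa] for aa in aas if aa in f_hat]
        if usable:
            class_mean[k] = sum(usable) / len(usable)
    if 3 not in class_mean and 2 in class_mean and 4 in class_mean:
        class_mean[3] = (class_mean[2] + class_mean[4]) / 2
    class_sizes = {k: len(aas) for k, aas in table.degeneracy_classes.items()}
    if any(k not in class_mean for k in class_sizes):
        return math.nan
    enc = 2.0 + sum(class_sizes[k] / class_mean[k] for k in class_sizes)
    return min(61.0, max(20.0, enc))


def pr2_third_position_counts(
    counts: CodonCountTable, table: CodonTable | None = None
) -> tuple[int, int, int, int]:
    """(A3, T3, G3, C3) over the eight fourfold PR2 codon blocks."""
    table = table or counts.table
    tallies = {b: 0 for b in "ATGC"}
    for family in fourfold_pr2_families(table):
        for codon in family:
            tallies[codon[2]] += counts.get(codon)
    return tallies["A"], tallies["T"], tallies["G"], tallies["C"]


def gene_indices(cds: CodingSequence, table: CodonTable) -> GeneIndices:
    """Compute the complete index set for one QC-accepted CDS."""
    counts = count_codons(cds, table)
    pos = positional_gc(cds, table)
    syn = synonymous_third_position(counts, table)
    a3, t3, g3, c3 = pr2_third_position_counts(counts, table)
    return GeneIndices(
        gene_id=cds.gene_id,
        gc=pos.gc,
        gc1=pos.gc1,
        gc2=pos.gc2,
        gc3=pos.gc3,
        gc12=pos.gc12,
        gc3s=syn.gc3s,
        a3s=syn.a3s,
        t3s=syn.t3s,
        g3s=syn.g3s,
        c3s=syn.c3s,
        a3=a3,
        t3=t3,
        g3=g3,
        c3=c3,
        enc=effective_number_of_codons(counts, table),
        n_codons=counts.n_codons,
    )


def indices_frame(indices: Sequence[GeneIndices]) -> pd.DataFrame:
    """Per-gene indices as a DataFrame (one row per gene)."""
    return pd.DataFrame([vars(ix) for ix in indices]).set_index("gene_id")


def usage_frame(counts: CodonCountTable, table: CodonTable | None = None) -> pd.DataFrame:
    """Pooled codon-usage table: amino acid, codon, count, RSCU."""
    table = table or counts.table
    r = rscu(counts, table)
    rows = []
    for aa, family in sorted(table.families.items()):
        for codon in family:
            rows.append(
                {
                    "amino_acid": aa,
                    "codon": codon,
                    "count": counts.get(codon),
                    "rscu": r.get(codon),
                }
            )
    return pd.DataFrame(rows)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero, as printed tables use."""
    if math.isnan(x):
        return x
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
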