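# codonbias

Synonymous codon usage (SCU) bias analysis for chloroplast coding
sequences, built around the analysis of the *Delphinium grandiflorum*
chloroplast genome: from a set of CDSs it computes the classical codon-usage
index set, identifies optimal codons, ordinates genes by correspondence
analysis of RSCU, and emits the three diagnostics — PR2-bias, ENC-plot and
neutrality-plot — that separate mutation pressure from natural selection as
drivers of codon choice. It is aimed at molecular-evolution researchers
analysing organellar (or other small) gene sets, and at anyone who needs a
tested, scriptable replacement for the codonW/cusp/spreadsheet tool chain.

## The statistics

For a codon *c* in a synonymous family of degeneracy *k* with counts
*x₁…x_k*, the relative synonymous codon usage is

    RSCU(c) = x_c · k / Σⱼ xⱼ

so RSCU = 1 means no bias and each family's values sum to *k*. Wright's
effective number of codons summarises a gene's overall bias: per amino acid
with *n* observed codons the codon homozygosity is estimated as
F̂ = (n·Σp̂ᵢ² − 1)/(n − 1), class averages F̄₂, F̄₃, F̄₄, F̄₆ are taken over
amino acids of each degeneracy class, and

    ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ ,  capped to [20, 61].

Under third-position composition alone (GC3s = *s*), the expected value is
Wright's curve ENC_exp(s) = 2 + s + 29/(s² + (1−s)²); genes under
translational selection fall below it. The PR2-bias plot places each gene
at (G₃/(G₃+C₃), A₃/(A₃+T₃)) over the eight fourfold-degenerate codon
blocks — (0.5, 0.5) under parity rule 2. The neutrality plot regresses
GC12 on GC3: slope ≈ 1 indicates mutation dominance, slope ≈ 0 conservation
of positions 1–2 against third-position drift. Optimal codons are those
that are both the genome-wide top-RSCU codon of their family
(high-frequency) and enriched in low-ENC genes, ΔRSCU = RSCU(high bias) −
RSCU(low bias) > 0.08 (high-expression). Gene × codon RSCU matrices
(59 informative codons; ATG and TGG excluded) are ordinated by
correspondence analysis — SVD of the standardized residuals of the
frequency table — with PCA available alongside.

## Worked example: the published chloroplast tables

The pooled codon counts, per-gene indices and expression-set counts of the
51 qualified *D. grandiflorum* chloroplast CDSs ship with the package:

```python
from codonbias import (datasets, standard_table, rscu,
                       high_frequency_codons, delta_rscu, call_optimal_codons)
from codonbias.metrics import round_half_up

table = standard_table()                      # NCBI code 11 (plastid)
pooled = datasets.pooled_counts(table)
r = rscu(pooled)
print("RSCU(TTA) =", round_half_up(r.get("TTA"), 2))
print("codons with RSCU >= 1:",
      sum(1 for c in table.sense_codons if r.get(c) >= 1))

hf, ties = high_frequency_codons(r, table)
high, low = datasets.expression_counts(table)
dr = delta_rscu(high, low, table, threshold=0.08)
call = call_optimal_codons(hf, dr, ties)
print("optimal codons:", ", ".join(call.optimal_codons.codons))
```

prints

```
RSCU(TTA) = 1.88
codons with RSCU >= 1: 31
optimal codons: AAA, ACT, ATT, CAA, GAT, GCT, TAT, TCT, TTT
```

TTA (Leu) is the most over-used codon in the genome (RSCU 1.88), 31 of the
61 sense codons are used above parity — almost all A/T-ending — and nine
codons are simultaneously high-frequency and high-expression. Eight of
them (all but CAA) are the published optimal set; CAA satisfies both
published criteria too and is reported rather than suppressed.

## Command line

```sh
codonbias simulate --out-fasta demo.fasta --n-genes 20 \
    --length-codons 100 500 --seed 7
codonbias run demo.fasta --out-dir demo_out
```

logs each stage and writes `gene_indices.tsv`, `codon_usage.tsv`,
`delta_rscu.tsv`, `optimal_codons.tsv`, `coa_*.tsv`, `pr2_*.tsv`,
`enc_plot.tsv`, `neutrality.tsv` and a `manifest.json` under `demo_out/`:

```
codonbias INFO filter: 20 input, 20 accepted
codonbias INFO indices: 20 genes, 5754 pooled codons
codonbias INFO optimal: 18 high-frequency, 25 high-expression, 11 optimal
codonbias INFO ordination: 19 axes, axis1 16.86%
codonbias INFO selection: PR2 weighted mean (y=0.503, x=0.534); ENC plot
  {'on_curve': 14, 'below_curve': 2, 'above_curve': 4}; neutrality slope 0.011 r 0.035
```

This simulated set has no translational selection, so most genes sit on
Wright's curve and the PR2 means stay near 0.5. Subcommands (`filter`,
`indices`, `rscu`, `optimal`, `coa`, `pr2`, `encplot`, `neutrality`) expose
the individual stages; every output is a plot-ready TSV.

## Layout

- `codonbias.codon_model` — genetic code, synonymous families, codon sets
- `codonbias.cds_io` — FASTA/GenBank reading and the QC filter chain
- `codonbias.metrics` — counts, RSCU, positional GC, GC3s/x3s, ENC
- `codonbias.expression` — expression sets, ΔRSCU, optimal codons
- `codonbias.multivariate` — CA/PCA of the RSCU matrix, correlations
- `codonbias.selection` — PR2, ENC-plot, neutrality-plot diagnostics
- `codonbias.simulate` — synthetic CDS generator with known ground truth
- `codonbias.pipeline` / `codonbias.cli` — orchestration and CLI
- `codonbias.datasets` — the packaged published study tables

See `docs/methods.md` for the modelling choices and their rationale.
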