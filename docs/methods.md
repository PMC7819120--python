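# Methods

This note records how the package defines each quantity, the conventions
chosen where tools in this field disagree, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Genetic code and codon universes

All statistics are defined relative to a genetic code; the default is NCBI
translation table 11 (bacterial/plastid), whose codon → amino-acid map is
identical to the standard code, so the degeneracy structure is the familiar
9 twofold, 1 threefold (Ile), 5 fourfold and 3 sixfold families, with Met
(ATG) and Trp (TGG) as the single-codon amino acids. Any NCBI code id can
be passed; the family and degeneracy-class structure is derived from the
code, not hard-wired. DNA (T) is the canonical alphabet; U is
transliterated on input, and all emitted tables use T.

Two derived codon sets recur: the 59 *informative* codons (sense codons
minus ATG and TGG), which form the ordination space, and the eight
*fourfold PR2 blocks* — the five strict fourfold families plus the CGN,
CTN and TCN sub-blocks of Arg, Leu and Ser — the universe over which
parity-rule-2 ratios are measured.

## CDS quality control

The filter chain drops, in order: sequences shorter than `min_len`
(default 300 nt), exact full-length duplicates keeping the first
occurrence (inverted-repeat gene copies are exact duplicates, which is why
string identity suffices), and records that are not clean reading frames.
A clean frame requires length ≡ 0 (mod 3), a pure ACGT alphabet and no
internal in-frame stop. A start codon is *not* required by default —
plastid genes may use alternative starts (GTG/TTG under code 11), and a
`strict_start` switch enforces the code's start set when wanted. A
terminal stop codon is tolerated and trimmed from accepted sequences
(`keep_terminal_stop` retains it); either way stop codons never enter any
downstream statistic. Every rejection is reported with its flag rather
than raised, the chain is idempotent, and the report's counts reconcile
with the input by construction.

## Index conventions

**RSCU.** count × degeneracy / family total. Codons of a family with zero
observations carry NaN, never 0 — there is no usage for them to be
relative to. Observed Met/Trp have RSCU ≡ 1.

**Positional GC.** GC, GC1, GC2, GC3 are computed over sense codons only;
GC12 = (GC1 + GC2)/2 exactly. Whether to include stop codons is a genuine
ambiguity in the field's tooling; excluding them is the package's single
convention, applied uniformly.

**GC3s and x3s.** Synonymous codons are those of families with degeneracy
≥ 2. GC3s = (synonymous codons ending G or C) / (all synonymous codons).
For the per-base fractions (A3s etc.) the numerator is synonymous codons
ending in that base; the denominator follows codonW's "silent base"
convention — synonymous codons whose family *has* a member ending in that
base — because published values in this field come from codonW. The naive
all-synonymous-codons denominator is available via `denominator="all"`.

**ENC.** Wright's estimator with explicit edge handling: per amino acid
with n ≥ 2 observed codons, F̂ = (n·Σp̂² − 1)/(n − 1); amino acids with
n < 2 or F̂ ≤ 0 are dropped from their class mean; if the threefold class
(Ile alone) is unusable it is imputed as (F̄₂ + F̄₄)/2; if any other class
mean is unusable the gene's ENC is undefined (NaN). The result is capped
to [20, 61], matching the convention under which unbiased genes print as
exactly 61.00. These rules make every edge case testable; an enumeration
oracle in the test suite checks the implementation to 1e-9 on random
tables.

**Rounding.** Comparisons with published 2 d.p. tables use half-up
decimal rounding (`round_half_up`), the behaviour of the spreadsheets that
produced such tables, not banker's rounding.

## Optimal codons

Genes are ranked by ENC (ascending; ties broken by gene id for
determinism). The high-expression proxy set is the lowest-ENC
max(1, round(fraction·n)) genes (default fraction 0.05) and the
low-expression set the same number from the top; an absolute-cut-off mode
(ENC < 30 / > 55) exists but selects nothing on gene sets whose ENC range
does not reach the cut-offs, which is why the ranked-fraction mode is the
default. Codon counts are pooled within each set, RSCU computed per set,
and ΔRSCU = RSCU(high) − RSCU(low); codons with ΔRSCU > threshold (default
0.08) are high-expression codons. A codon whose family is absent from
either set has an undefined ΔRSCU and is never flagged. Optimal codons
are the intersection of the high-expression set with the high-frequency
set (the per-family top-RSCU codon, ties broken alphabetically and
reported). The intersection is reported as computed: on the packaged
study tables it contains nine codons, the eight published ones plus CAA,
which qualifies under both published rules; the package does not
special-case it.

## Ordination

The gene × 59-codon RSCU matrix (unobserved families imputed as 0, with
per-gene imputation counts reported) is analysed by correspondence
analysis in the codonW tradition: the matrix itself is treated as the
frequency table (a switch allows raw counts), P = X/total, row/column
masses r and c, standardized residuals S = D_r^(−1/2)(P − rcᵀ)D_c^(−1/2),
SVD of S; axis i carries inertia fraction σᵢ²/Σσ², and principal
coordinates are reported for genes and codons. Numerically zero singular
values are dropped, so degenerate (e.g. rank-1) matrices return fewer
axes instead of raising. Axis signs are arbitrary in the SVD; the package
orients each axis so the largest-magnitude codon coordinate is positive,
making outputs reproducible across BLAS implementations. PCA of the
column-centred matrix is provided in the same result shape, since the
literature often reports the two interchangeably and the axis fractions
differ.

Correlations among {GC, ENC, GC3s, GC3, Axis1..4} use Spearman by default
(average ranks for ties; exact permutation p-values below n = 10, where
the t-approximation is poorest; t-approximation otherwise) or Pearson,
both two-tailed. The neutrality analysis reports Pearson's r, as is
conventional for that plot.

## Selection diagnostics

PR2 ratios are measured over the eight fourfold blocks by default —
parity-rule-2 logic applies where the third position is free of amino-acid
constraint — with an all-sense-codon mode behind a switch for comparison
with axis-label conventions that do not restrict the universe. Points
with a zero denominator are undefined and reported as such. The
codon-number-weighted mean over genes × families summarises the eight
per-family panels.

The ENC plot pairs each gene's observed ENC with ENC_exp(GC3s) =
2 + s + 29/(s² + (1−s)²) (capped at 61); deviation = expected − observed,
so positive deviations lie below the curve. The on-curve tolerance for
the summary counts is |deviation| ≤ 2 ENC units (configurable; the
literature states no tolerance). The neutrality fit is ordinary least
squares of GC12 on GC3 — GC12 is the response, per the plot's axis
convention — with the Pearson r of the scatter.

## Synthetic data

The generator draws, per gene, a length (default range 100–2,166 codons,
i.e. 300–6,500 nt), a third-position GC target g uniform in a range
(default 0.20–0.50), and then i.i.d. codons: amino acids uniform over the
20; within a family, codon probabilities proportional to per-position base
probabilities — positions 1–2 fixed at A .30 / T .31 / C .18 / G .21
(an AT-rich plastid-like composition that puts simulated GC12 near 0.45),
position 3 at A = T = (1−g)/2, G = C = g/2 — mixed with weight w toward
one preferred codon per family (default: the published high-frequency set
of the study chloroplast). ATG is prepended and TAA appended, so
simulated genes pass the QC chain by construction. Everything is driven
by one `numpy` generator seeded from the spec: identical seeds give
byte-identical FASTA.

With w = 0 every family's third position follows the same composition, so
genes land on Wright's curve up to sampling noise and the small
departures caused by the non-uniform position-1/2 composition inside the
sixfold families; at 300 codons per gene the mean |deviation| stays under
2 ENC units. Increasing w concentrates usage on preferred codons, drives
ENC down monotonically (exactly 20 at w = 1) and pushes genes below the
curve — this monotone ordering is the parameter-recovery check. The
generator does **not** emulate realistic amino-acid profiles tied to gene
function, codon autocorrelation, among-gene selection heterogeneity, GC12
variation coupled to GC3 (its neutrality slope is ≈ 0 by construction), or
RNA editing; passing recovery tests therefore demonstrates that the
estimators detect the forces they model, not that real chloroplast data
satisfy those models.

## Problem sizes and numerics

The test suite's simulations use 50 genes × 300 codons per selection
cohort and random count tables with Poisson(2–5) per-codon means — large
enough for the asymptotic behaviour the assertions rely on, small enough
that the whole suite runs in seconds. Oracle comparisons (ENC, x3s, CA
spectra, Spearman, OLS) are at 1e-9; RSCU family-sum conservation at
1e-9; CA inertia-fraction normalization at 1e-9. Singular values below
1e-12 relative to the largest are treated as zero rank.

## Known limitations

- The QC duplicate rule is exact string identity; near-duplicates (e.g.
  IR copies with edits) are retained.
- No codon adaptation index, tAI or Fop; ENC is the only expression proxy.
- GenBank reading extracts CDS features by their `gene` qualifier only; it
  does not splice multi-interval features beyond what the feature location
  encodes.
- Plot rendering is out of scope; the pipeline emits plot-ready TSVs.
- The packaged study tables are printed at 2 d.p.; statistics that depend
  on full-precision per-gene values (rank correlations especially) cannot
  be recovered from them exactly.
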