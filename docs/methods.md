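# Methods

## Scope and model

riboseed implements two statistically coupled but independent tracks: a
targeted RNA bisulfite-sequencing caller for one rRNA m⁵C site, and a
translational-efficiency (TE) differential pipeline for paired
transcriptome/translatome log₂ expression data. Both are driven by
synthetic-data generators whose ground truth makes every stage testable by
parameter recovery.

## Read track

### Conversion model

At a reference cytosine with true methylation level m, a read shows C with
probability

    P(C) = m·(1 − c_meth) + (1 − m)·c_fail

where `c_fail` is the conversion-failure probability (an unmethylated C
surviving as C; the assay background) and `c_meth` the probability that a
true m⁵C is erroneously converted (default 0). The estimator used for
reporting is f(target) − b with b the mean background fraction over the
other cytosines. Note this subtraction estimator carries a small intrinsic
bias of −m·c_fail (at m = 0.8, c_fail = 0.01 it reports 0.792 rather than
0.800): with the raw fraction f = m + (1−m)c and background b ≈ c, f − b =
m(1 − c). We keep the plain subtraction because it is the field's standard
report for this assay; the bias is far below the assay's replicate
variation. Negative corrected values are reported as-is.

The background is an **unweighted per-position mean** of fractions, not a
pooled count ratio, so deep and shallow sites contribute equally; sites
below a minimum coverage (default 10 reads, configurable — the assay's
deep amplicon coverage makes the choice inert in practice) are excluded,
as is the target site itself.

### Alignment

Global alignment is Needleman–Wunsch under a linear gap model, one score
per alignment column (match +1, mismatch −1, gap −2 by default; all
configurable, including an optional bisulfite-aware mode scoring read-T vs
reference-C as a match — off by default because the counting stage, not
the aligner, interprets conversion). Traceback ties resolve deterministically
as diagonal > deletion > insertion. Before the global pass, the longer
sequence's overhangs are removed by an end-gap-free overlap alignment;
reads whose best overlap scores ≤ 0 are counted as unalignable and
excluded. Reads are assumed sense-strand (amplicon RT-PCR with
strand-specific primers); no reverse-complement search is attempted.

The indel filter removes a read when its insertion fraction ≥ 15%,
deletion fraction ≥ 15%, or combined fraction ≥ 20% of alignment columns.
Strict inequalities and a conjunctive pass rule are used: the literal
"or" reading of the rule (pass if any bound holds) would remove almost
nothing, since nearly every read trivially satisfies at least one bound;
that reading remains available via configuration (`rule="any"`), as does a
read-length denominator.

### Outlier test

Grubbs' test runs one-sided (upper tail) on the raw per-site C fractions
of all covered cytosines, target included: only elevated methylation is
biologically meaningful, and the test statistic is compared against the
α/N-quantile critical value (α = 0.01 default; a two-sided α/(2N) variant
is available). The target is called an outlier only when it is itself the
maximum. The test needs ≥ 3 covered sites and non-zero spread; fractions
are binomial, not normal, but with amplicon-scale coverage the normal
approximation is comfortable and the null flag rate stays below α
(verified by simulation in the test suite).

### Coordinates

All user-facing positions are absolute rRNA coordinates, computed as
1-based amplicon-local index + `coordinate_offset`, so the yeast target
prints as 2278. The bundled 122-nt reference is synthetic (a generated
amplicon-like sequence with 32 cytosines and the target at local position
62), not a GenBank extract; real references load from FASTA with a
user-supplied target position and offset.

## Expression track

### Pairing and TE

Each translatome sample is paired with the transcriptome sample from the
same lysate; Ti = log₂ translatome − log₂ transcriptome per pair cancels
the shared lysate effect exactly. This explicit within-pair differencing
replaces array-era normalization chains (within-array loess, between-array
Aquantile, duplicate-correlation modelling): for single-channel log₂ data
the pairing is the statistical content, and the remaining between-sample
step is a plain quantile normalization (all columns mapped to the mean
order-statistic profile). Quantile normalization can tie a gene's values
across samples and zero its variance; the prior fit floors variances at
1e-5 × median for exactly this reason.

### Moderated t

The variance model is the standard hierarchical one: gene variances
s² ~ s₀²·F(d, d₀) around a prior with d₀ df and scale s₀². The package
fits (d₀, s₀²) by **maximum marginal likelihood** on the scaled-F density
(Nelder–Mead from a moment-matching start). Closed-form moment matching on
log-variances is implemented and available (`method="moments"`), but at
d = 1 — the relevant case for duplicate experiments — the log-χ²₁ moments
are so heavy-tailed that the moment estimate of d₀ occasionally explodes
upward (observed estimates above 70 when the truth is 4, reproducing
exactly what the canonical Bioconductor implementation returns on the same
data, in both its default and robust modes). An inflated d₀ means
over-confident tail p-values and loss of null FDR control at the BH
p < 0.05 threshold. The likelihood fit has no such instability (estimates
stay within ±1.5 of the truth across seeds) and restores FDR control, so
it is the default.

Posterior variance and test: s̃² = (d₀s₀² + d·s²)/(d₀ + d),
t = mean(Ti)/√(s̃²/n), two-sided p on d₀ + d df (normal when d₀ = ∞;
d₀ = 0 recovers the ordinary t exactly). BH adjustment uses the step-up
procedure (delegated to statsmodels). Calls: up iff mean Ti > log₂(2) and
adjusted p < 0.05, down symmetric; the |log₂ TE| > 1.5 variant used in
some displays is available by setting the fold-change threshold to 2^1.5.

### Enrichment

Preranked GSEA: genes sorted by decreasing log₂ TE (ties broken by gene
identifier), running sum advancing by |metric|^1 (normalized within the
set) on hits and retreating by 1/(N − set size) on misses; ES is the
maximum signed deviation. With two replicates sample permutation is
impossible, so the null comes from gene-set permutation: random same-size
sets drawn from the ranked universe (1,000 permutations by default). NES
divides by the mean same-sign null |ES|; nominal p is the same-sign
exceedance fraction (add-one corrected); FDR q follows the pooled-null
recipe (fraction of pooled null NES at least as extreme, divided by the
fraction of observed NES at least as extreme, clipped at 1). Sets whose
intersection with the ranking falls outside [5, 1000] are dropped.

## Synthetic-data generators

**Reads.** Per read: conversion outcomes drawn at every reference C from
the profile, then substitution errors (uniform to the three other bases),
then per-base insertions/deletions (uniform; an optional homopolymer
multiplier inflates rates inside runs, a coarse nod to flow-based
chemistry — real IonTorrent flow-space error structure is not modelled),
then the sample barcode, possibly truncated from its 5′ end. The truth
table records each read's pre-error base at every C position and its true
indel counts. Defaults emulate the study conditions the caller targets:
one high-methylation site (0.8), ~1% conversion failure, error rates of a
few per mille, read length = amplicon length, depth configurable.

**Expression.** Gene baselines ~ N(8, 1.5²) (log₂ intensity scale);
per-gene residual sd drawn as s₀·√(d₀/χ²_{d₀}) — the scaled
inverse-chi-square prior, so the moderated-t hierarchical model is true by
construction — shared by both channels of a pair; a shared per-pair lysate
effect (sd 0.5) added to both channels; the true log₂ TE added to the
translatome channel only. Defaults: 2 replicates, d₀ = 4, s₀ = 0.25.
Because Ti differences two noisy channels, Ti variances scale as 2·s₀²;
recovery tests that target (d₀, s₀²) directly therefore simulate variances
from the prior rather than routing through the matrix.

What passing tests do **not** show about real data: microarray scanner
backgrounds, probe effects and dye bias are not simulated (the
normalization stage is correspondingly simplified), and sequencing errors
are uniform rather than flow-space structured, so real-data filter rates
and backgrounds will differ quantitatively.

## Numerical and design choices

- Alignment kernels are numba-jitted when numba is importable; semantics
  are identical without it.
- Problem sizes in the test-suite recovery checks (20 seeds × 5,000 reads;
  50 null simulations × 2,000 genes; 5 spiked simulations) were chosen to
  hold Monte-Carlo error comfortably below the asserted tolerances.
- Degenerate cases: empty sequences and empty barcodes tables reject;
  zero passing reads yield an all-zero count table with a warning;
  all-equal variances give d₀ = ∞ with s₀² equal to that value; a gene
  with zero mean and zero moderated variance gets t = 0 (no evidence).
- Determinism: every stochastic step takes an explicit seed
  (`numpy.random.default_rng`); pipelines are byte-identical across reruns
  with the same inputs and seed.

## Known limitations

- The aligner is quadratic per read and linear-gap only; fine for ~120-nt
  amplicons, not intended for genome-scale bisulfite data.
- Grubbs' test addresses a single outlier; two genuinely methylated sites
  in one amplicon would mask each other.
- Gene-set permutation (the only feasible scheme at n = 2) tests a
  different null than sample permutation and is known to be liberal for
  correlated gene sets.
- Exact reproduction of published array-based gene counts is out of scope:
  those depend on the original scanner-level normalization chain and array
  annotation.
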