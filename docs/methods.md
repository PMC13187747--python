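# Methods

## Scope and units of analysis

`mitocodon` analyses protein-coding sequences grouped by species and genomic
compartment (mitochondrial vs nuclear). Mitochondrial input is the 13
canonical PCGs (ATP6, ATP8, COX1–3, COB, NAD1–6, NAD4L) extracted from
GenBank feature tables; nuclear input is a CDS FASTA. Gene-level statistics
are computed per CDS; species-level statistics on the within-compartment
concatenation (canonical 13-gene order for mito, lexicographic for nuclear;
terminal stop codons removed before joining). All family-dependent
statistics (RSCU, ENC classes, CAI weights, GC3s degeneracy) are derived
from the genetic code attached to each sequence, so table 5 data (62 sense
codons, 8-fold Ser, no single-codon families) is handled self-consistently
rather than through standard-code assumptions.

## Quality control

Rules, in order: (1) a trailing 1–2 nt overhang of T or TA on a
mitochondrial CDS is treated as an incomplete stop codon completed by
polyadenylation — trimmed and logged, not rejected, since rejection would
discard many real ATP6/NAD annotations; (2) length not divisible by 3 after
trimming is treated as a frameshift (the only sequence-intrinsic test
available) and rejected; (3) ambiguous fraction > 1% rejects; (4) nuclear
CDSs < 150 nt reject; (5) any stop codon before the final position rejects.
Filtering is total (never raises) and idempotent, and every decision is
written to a TSV rejection log. Genes enter ENC–GC3 analyses only at ≥ 100
codons.

## Estimators and numerical choices

**ENC.** Wright's estimator with degeneracy classes derived from the active
code. Per family with n ≥ 2 observed codons, F̂ = (n·Σp̂² − 1)/(n − 1); an
F̂ ≤ 0 is floored at 1/k and flagged. Class averages use equal family
weights; ENC = (number of single-codon families in the code) + Σ_k N_k/F̄_k
with N_k the number of k-fold families *in the code* (CodonW-style). A class
with no observed family is imputed as the mean of the two adjacent class
averages when both exist; otherwise it is skipped and the estimate flagged
low-confidence. The result is capped at the code's sense-codon count.

**GC3 vs GC3s.** Both are computed: raw third-position GC over all codons,
and GC3s over synonymously variable codons only (stop codons and
single-codon families excluded, with an optional amino-acid exclusion list
for the variant that also drops Met/Trp). The neutrality regression uses raw
GC3; ENC–curve comparisons use GC3s.

**CAI.** Relative adaptiveness w = X/X_max within each family of the
reference set, zero reference counts replaced by a 0.5 pseudo-count (the
Sharp & Li convention); CAI is the count-weighted geometric mean of w over a
gene's degenerate-family codons. Without an expression-calibrated reference,
the reference set is the species' own pooled mitochondrial PCGs, so CAI
measures within-genome codon concordance, not absolute expression
optimization. Genes with no eligible codon give missing CAI (a
paper-compatibility flag writes 0 instead).

**Neutrality regression.** OLS of GC12 on GC3, gene-level points pooled over
species by default (a species-level concatenated mode is also available).
CIs are percentile bootstrap over B resamples of genes with replacement
within species (default B = 10 000; replicates with zero GC3 variance are
skipped and tallied). Note an intrinsic property of this regression: because
the regressor GC3 is measured per gene with binomial sampling noise, the OLS
slope is attenuated below the generative slope by roughly
var_between/(var_between + var_within); at 300-codon genes spanning GC3
0.2–0.8 this factor is ≈ 0.98, and stop-codon exclusion contributes a
further ≈ 0.99 multiplicative flattening. A fitted neutral slope of ~0.95
therefore does *not* indicate selection; interpretation should compare
slopes between compartments or against matched neutral simulations rather
than against exactly 1.

**PERMANOVA.** One-way, Euclidean distances on the z-scored RSCU matrix.
pseudo-F = (SS_between/(g−1))/(SS_within/(N−g)) from the squared-distance
partition, p = (#{F_perm ≥ F_obs} + 1)/(B + 1) over uniform random label
permutations. Rows are sorted canonically (lexicographically) before
permuting so results are invariant to input order. The companion dispersion
test permutes the one-way ANOVA F of per-sample distances to own-group
centroids (coordinates are already a Euclidean embedding, so no PCoA step is
needed). PCA uses SVD of the column-centered matrix with a deterministic
sign convention (largest-|loading| coefficient of each component is
non-negative); contrib = 100·loading², cos² from codon–component
correlations.

**RSCU matrices.** Two codon sets: `paper_compat_60` (standard-code sense
codons minus ATG — the conventional 60-column matrix) and `code_aware` (the
active code's degenerate sense codons, e.g. including TGA as part of the
table-5 Trp family). Codons of families a species never uses are imputed as
0 — zero usage genuinely is extreme under-use — with the imputation count
logged; zero-variance columns are dropped at scaling and listed.

**Mutual information |M|.** Both RSCU vectors are discretized into 4
equal-frequency bins by rank over the shared codons (ties broken by codon
label, so the statistic is deterministic); plug-in MI from the joint
histogram is normalized by the smaller marginal entropy, giving |M| ∈ [0, 1]
with 1 attained at identity and invariance to monotone transforms. A
constant vector returns 0. This estimator is one defensible operationalization
of a mitonuclear dependence score, chosen for determinism and the [0, 1]
bound; the coadaptation *classification* deliberately uses only Pearson r
(≥ 0.7 coadapted; < 0.2 decoupled, our reading of "near zero"; both
thresholds configurable), with r, ρ and |M| all reported.

## The synthetic cohort generator

Each compartment has an explicit mutation–selection model. Mutation:
per-nucleotide propensities from a GC propensity `gc_bias` and skew
parameters (`π_A = (1−gc)(1+at_skew)/2`, etc.); a codon's mutational weight
is the product over its three positions. Selection: per-codon preference
weights w (log-normal within families, unit mean) enter as w^S. Sampling
distribution: p(c) ∝ m(c)·w(c)^S over sense codons; S = 0 is the neutral
limit, S → ∞ concentrates each family on its preferred codon.

Amino-acid usage has two modes. *Mutation-induced* (default for neutral
cohorts): codons are drawn from the joint sense-codon distribution, so
positions 1–2 track the same GC driver as position 3 — the regime where the
neutrality slope is ~1 (up to the attenuation above). *Fixed*: a constant
amino-acid composition pins GC12, the regime of selective constraint at
positions 1–2 (slope → 0). Cohorts use a fixed composition that is
compartment-specific — the neutral mutational amino-acid marginal of each
compartment's preset — because an AT-rich mutational regime also yields an
AT-rich proteome (Phe/Ile/Lys-heavy), which is what lets overall base
composition track the presets at all three positions. It is constant across
species, so within-compartment comparative statistics are not confounded by
protein composition; RSCU-based cross-compartment comparisons are unaffected
by the compositional difference because RSCU normalizes within families.

Defaults (one choice, stated here): mito gc_bias 0.28, AT skew −0.345, GC
skew +0.365, table 5 — landing near the empirical invertebrate-mitogenome
regime of ~72% AT with T > A and G > C; nuclear gc_bias 0.44, skews
+0.05/+0.036, table 1 (~56% AT). Cohorts: species GC jitter SD 0.05;
order-level preference offsets SD 0.8 plus species-level SD 0.6 (so PCA and
PERMANOVA have a recoverable group signal); selection strength S = 1.5 —
strong enough that shared-preference compartments sit clearly above the
r = 0.7 coadaptation threshold while within-family codon distributions stay
far from winner-take-all; gene lengths uniform in 150–450 codons, 13
mitochondrial PCGs per species. `coupling` controls whether the nuclear
compartment reuses the mito preference vector ("shared" → coadapted truth)
or draws its own ("independent" → decoupled truth). Every cohort carries a
truth manifest (per-species gc_bias, skews, S, coupling, preference
vectors), and generation is fully deterministic given the seed
(per-species child streams from a single SeedSequence).

What the generator does *not* emulate: phylogenetic autocorrelation (species
are exchangeable within orders), real gene order or tRNA/rRNA content,
expression-linked selection heterogeneity among genes, within-genome strand
switching, and indel/annotation noise. Passing recovery tests therefore
shows the estimators are correct and well-calibrated under the stated model,
not that real helminth data will show any particular effect size.

## Determinism and defaults

All stochastic procedures (bootstrap, permutation tests, simulation) take
explicit seeds; the package-wide default is 12345. Pipeline outputs are
written with a fixed float format; rerunning an identical configuration
produces byte-identical CSV/JSON. Default problem sizes in the examples and
tests (tens of species, hundreds of genes, B in the hundreds-to-thousands)
are chosen so a full run completes in seconds on one core; production
analyses should raise permutations and bootstrap B to 10 000 as in the
config defaults.

## Known limitations

- Nuclear transcript isoforms are not deduplicated; all CDSs passing QC are
  analysed (duplicate FASTA ids are suffixed and warned about).
- CAI with a self-referenced (pooled-PCG) reference compresses the scale and
  is comparable within, not across, reference choices.
- The ENC low-confidence flag (unimputable missing degeneracy class) signals
  an estimate computed from a subset of classes; treat such values with
  caution in genes of unusual amino-acid composition.
- The |M| estimator's plug-in MI is biased upward at 59 codons × 4 bins;
  comparisons should be against matched nulls (e.g. permuted vectors), which
  is how the test-suite benchmarks it.
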