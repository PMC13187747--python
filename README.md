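# mitocodon

Compartment-matched analysis of synonymous codon-usage bias: mitochondrial
genomes against nuclear CDS sets, with a mutation–selection cohort simulator
for validation.

## The problem

Synonymous codon usage is shaped by two forces: mutational pressure (in
animal mitogenomes, a strong AT bias with strand-asymmetric skews from
replication-linked deamination) and translational selection (preference for
codons matching the tRNA pool, strongest in highly expressed genes). Because
the OXPHOS machinery is co-encoded by the mitochondrial and nuclear genomes,
their codon landscapes may be coordinated (*coadapted*) or evolve
independently (*decoupled*). `mitocodon` is for comparative molecular
evolution work that needs to (i) quantify codon bias per gene and species,
(ii) partition mutation from selection, (iii) test taxonomic structure, and
(iv) classify mitonuclear concordance — with every statistic testable
against a generative model with known ground truth.

## The statistics

For codon *j* of amino acid *i* with *nᵢ* synonyms and count *X_ij*:

- **RSCU**: `RSCU_ij = X_ij · nᵢ / Σⱼ X_ij` — 1 means no bias; ≥ 1.5 is
  flagged as strong preference.
- **ENC** (Wright 1990): per-family codon homozygosity
  `F̂ = (n·Σp̂² − 1)/(n − 1)` averaged within degeneracy classes of the
  active genetic code; `ENC = N₁ + Σ_k N_k / F̄_k`, capped at the code's
  sense-codon count (61 standard, 62 invertebrate-mito). 20 = one codon per
  amino acid.
- **Expected ENC**: `ENC_exp = 2 + GC3 + 29/(GC3² + (1 − GC3)²)`; genes
  below the curve are more biased than composition predicts.
- **Neutrality regression**: OLS of `GC12 = (GC1 + GC2)/2` on GC3 — slope
  ≈ 1 means mutation-driven, ≪ 1 means selective constraint; CIs by a
  gene-within-species bootstrap.
- **CAI**: geometric mean of relative adaptiveness `w = X / X_max` within
  families of a reference set (here, each species' own pooled 13 mito PCGs).
- **Skews**: `(A − T)/(A + T)` and `(G − C)/(G + C)` on the coding strand.
- **Multivariate**: z-scored species × codon RSCU matrices → PCA
  (contrib/cos² loadings), one-way PERMANOVA on Euclidean distances with a
  homogeneity-of-dispersion check, complete-linkage clustering.
- **Coadaptation**: per-species Pearson r / Spearman ρ and a normalized
  mutual information |M| ∈ [0, 1] between compartment RSCU vectors over the
  59 shared degenerate codons; classification coadapted (r ≥ 0.7) /
  intermediate / decoupled (r < 0.2).

## Worked example

```bash
python examples/05_coadaptation.py
```

prints, for ten simulated species whose compartments share one codon
preference vector (`coupling="shared"`) and ten that draw independent
vectors:

```
== coupling: shared
median r = 0.854, median |M| = 0.377
== coupling: independent
median r = 0.016, median |M| = 0.055
```

Shared-preference species sit above the r = 0.7 coadaptation threshold and
are classified `coadapted`; independent species scatter around r = 0 and are
classified `decoupled` — the generator's coupling switch is recovered by the
statistics. `examples/03_neutrality.py` shows the complementary neutral
check: a pure-mutation cohort sits on Wright's curve
(`mean |ENC − ENC_exp(GC3s)|: 2.06 ENC units`) with neutrality slope
`0.947 [0.927, 0.966]` (the small shortfall below 1 is OLS attenuation from
per-gene GC3 sampling noise; see `docs/methods.md`).

The other examples cover per-gene metrics (01), cohort simulation and
composition (02), PCA/PERMANOVA structure (04) and the one-call pipeline
(06). A thin CLI wraps the same library:

```bash
mitocodon simulate --outdir cohort --seed 12345
mitocodon analyze --input-dir cohort --outdir run1 --seed 12345
```

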