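"""Mitonuclear coadaptation vs decoupling on matched synthetic cohorts.

Two cohorts differing only in compartment coupling: 'shared' species sample
both compartments from one preference vector (coadaptation); 'independent'
species draw separate vectors (decoupling). Per species we report Pearson r,
Spearman rho and normalized mutual information |M| over the 59 shared
degenerate codons, plus the threshold classification (r >= 0.7 coadapted,
r < 0.2 decoupled).
"""

from mitocodon import (
    CohortSpec,
    coadaptation_table,
    compute_rscu,
    count_codons,
    generate_cohort,
    merge_counts,
)

for coupling in ("shared", "independent"):
    spec = CohortSpec(n_species=10, coupling=coupling, seed=12345)
    records, _ = generate_cohort(spec)
    profiles = {}
    for rec in records:
        mito = compute_rscu(merge_counts(
            [count_codons(g) for g in rec.mito_genes], "m"))
        nuc = compute_rscu(merge_counts(
            [count_codons(g) for g in rec.nuclear_genes], "n"))
        profiles[rec.species_id] = (mito, nuc)
    tab = coadaptation_table(profiles)
    print(f"== coupling: {coupling}")
    print(tab.round(3).to_string(index=False))
    print(f"median r = {tab['r_pearson'].median():.3f}, "
          f"median |M| = {tab['m_norm'].median():.3f}\n")

print("Shared-preference species sit above the r = 0.7 coadaptation "
      "threshold; independent ones scatter around r = 0 (decoupled).")
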