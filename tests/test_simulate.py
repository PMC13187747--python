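"""The mutation-selection generator: distributions, determinism, and
parameter recovery of the statistics the pipeline measures."""

import numpy as np
import pytest

from mitocodon.codon_metrics import (
    compute_rscu,
    count_codons,
    merge_counts,
    positional_gc,
)
from mitocodon.mitonuclear import coadaptation_table
from mitocodon.multivariate import assemble_matrix, permanova, zscore_columns
from mitocodon.sequence_io import qc_filter
from mitocodon.simulate import (
    CohortSpec,
    CompartmentModel,
    codon_distribution,
    generate_cohort,
    generate_gene,
    sample_preference_weights,
    sense_codon_distribution,
    write_cohort,
)


class TestCodonDistribution:
    def test_neutral_balanced_two_fold_is_half_half(self, code1):
        m = CompartmentModel(gc_bias=0.5, code=code1)
        codons, p = codon_distribution(m, "E")  # GAA/GAG
        assert p == pytest.approx([0.5, 0.5])

    def test_gc_limit_concentrates_on_gc_ending(self, code1):
        m = CompartmentModel(gc_bias=0.999, code=code1)
        codons, p = codon_distribution(m, "E")
        assert p[codons.index("GAG")] > 0.99

    def test_strong_selection_concentrates_on_preferred(self, code1):
        w = {c: 1.0 for c in code1.sense_codons}
        w["GAA"], w["GAG"] = 2.0, 0.01
        m = CompartmentModel(gc_bias=0.5, selection_strength=10.0,
                             preference_weights=w, code=code1)
        codons, p = codon_distribution(m, "E")
        assert p[codons.index("GAA")] > 0.99

    def test_sums_to_one_everywhere(self, code5):
        m = CompartmentModel(gc_bias=0.3, at_skew_param=-0.3,
                             gc_skew_param=0.4, code=code5)
        for aa in code5.families:
            _, p = codon_distribution(m, aa)
            assert p.sum() == pytest.approx(1.0) and (p >= 0).all()

    def test_preference_weights_unit_mean_per_family(self, code1, rng):
        w = sample_preference_weights(code1, rng, sigma=1.0)
        for aa, fam in code1.families.items():
            assert np.mean([w[c] for c in fam]) == pytest.approx(1.0)


class TestGenerateGene:
    def test_same_seed_identical(self, code1):
        m = CompartmentModel(gc_bias=0.4, code=code1)
        g1 = generate_gene(m, 200, 77)
        g2 = generate_gene(m, 200, 77)
        assert g1.sequence == g2.sequence

    def test_gc3_tracks_analytic_expectation(self, code1):
        m = CompartmentModel(gc_bias=0.2, code=code1)
        codons, p = sense_codon_distribution(m)
        expected_gc3 = sum(pi for c, pi in zip(codons, p) if c[2] in "GC")
        g = generate_gene(m, 8000, 3)
        assert positional_gc(g).gc3 == pytest.approx(expected_gc3, abs=0.02)

    def test_always_passes_default_qc(self, code5, rng):
        m = CompartmentModel(gc_bias=0.28, at_skew_param=-0.345,
                             gc_skew_param=0.365, code=code5)
        genes = [generate_gene(m, int(rng.integers(60, 300)), rng)
                 for _ in range(20)]
        kept, log = qc_filter(genes)
        assert len(kept) == len(genes)

    def test_fixed_composition_contains_all_amino_acids(self, code1):
        from mitocodon.simulate import default_aa_composition
        m = CompartmentModel(gc_bias=0.4, code=code1,
                             aa_composition=default_aa_composition(code1))
        g = generate_gene(m, 120, 5)
        aas = {code1.translate_codon(c) for c in g.codons if not code1.is_stop(c)}
        assert len(aas) == 20


class TestCohort:
    def test_deterministic_under_seed(self):
        spec = CohortSpec(n_species=4, genes_per_species=3,
                          nuclear_genes_per_species=2,
                          gene_length_codons=(60, 120), seed=99)
        a, _ = generate_cohort(spec)
        b, _ = generate_cohort(spec)
        for ra, rb in zip(a, b):
            assert [g.sequence for g in ra.mito_genes] == [g.sequence for g in rb.mito_genes]
            assert [g.sequence for g in ra.nuclear_genes] == [g.sequence for g in rb.nuclear_genes]

    def test_compositional_presets(self):
        """Default mito compartment is AT-rich with negative AT skew and
        positive GC skew; nuclear compartment is more balanced."""
        spec = CohortSpec(n_species=6, genes_per_species=13,
                          nuclear_genes_per_species=6, seed=12345)
        records, _ = generate_cohort(spec)
        mito_at, nuc_at, at_sk, gc_sk = [], [], [], []
        for rec in records:
            seq = "".join(g.sequence for g in rec.mito_genes)
            at = (seq.count("A") + seq.count("T")) / len(seq)
            mito_at.append(at)
            a, t = seq.count("A"), seq.count("T")
            g, c = seq.count("G"), seq.count("C")
            at_sk.append((a - t) / (a + t))
            gc_sk.append((g - c) / (g + c))
            nseq = "".join(x.sequence for x in rec.nuclear_genes)
            nuc_at.append((nseq.count("A") + nseq.count("T")) / len(nseq))
        assert 0.65 < np.mean(mito_at) < 0.80
        assert 0.50 < np.mean(nuc_at) < 0.62
        assert np.mean(at_sk) < -0.15
        assert np.mean(gc_sk) > 0.15

    def test_truth_manifest_covers_all_species(self):
        spec = CohortSpec(n_species=5, genes_per_species=2,
                          nuclear_genes_per_species=2,
                          gene_length_codons=(60, 100), seed=3)
        records, manifest = generate_cohort(spec)
        assert set(manifest.species) == {r.species_id for r in records}
        sp = manifest.species[records[0].species_id]
        assert {"order_label", "mito_gc_bias", "mito_log_pref"} <= set(sp)

    def test_order_structure_recovered_by_permanova(self):
        spec = CohortSpec(n_species=30, orders=("O1", "O2", "O3"),
                          genes_per_species=13, nuclear_genes_per_species=2,
                          gene_length_codons=(150, 300), seed=12345)
        records, _ = generate_cohort(spec)
        profs, labels = [], []
        for rec in records:
            counts = merge_counts([count_codons(g) for g in rec.mito_genes],
                                  rec.species_id)
            profs.append(compute_rscu(counts))
            labels.append(rec.order_label)
        m = zscore_columns(assemble_matrix(profs))
        res = permanova(m, labels, permutations=999, seed=12345)
        assert res.p_value < 0.01

    def test_coupling_controls_compartment_correlation(self):
        medians = {}
        for coupling in ("shared", "independent"):
            spec = CohortSpec(n_species=8, coupling=coupling, seed=12345,
                              gene_length_codons=(150, 300))
            records, _ = generate_cohort(spec)
            profs = {}
            for rec in records:
                mito = compute_rscu(merge_counts(
                    [count_codons(g) for g in rec.mito_genes], "m"))
                nuc = compute_rscu(merge_counts(
                    [count_codons(g) for g in rec.nuclear_genes], "n"))
                profs[rec.species_id] = (mito, nuc)
            medians[coupling] = coadaptation_table(profs)["r_pearson"].median()
        assert medians["shared"] > 0.7
        assert abs(medians["independent"]) < 0.2

    def test_written_cohort_roundtrips_through_readers(self, tmp_path):
        from mitocodon.sequence_io import read_fasta_cds, read_genbank_cds
        spec = CohortSpec(n_species=2, genes_per_species=3,
                          nuclear_genes_per_species=2,
                          gene_length_codons=(60, 100), seed=8)
        records, manifest = generate_cohort(spec)
        write_cohort(records, manifest, tmp_path)
        back = read_genbank_cds(tmp_path / "mito" / "sp001.gb")
        assert [c.sequence for c in back] == [c.sequence for c in records[0].mito_genes]
        assert back[0].code.table_id == 5
        nuc = read_fasta_cds(tmp_path / "nuclear" / "sp001.fasta")
        assert [c.sequence for c in nuc] == [c.sequence for c in records[0].nuclear_genes]
        assert (tmp_path / "truth_manifest.json").exists()
        assert (tmp_path / "metadata.tsv").read_text().startswith("species_id")


class TestNeutralLimits:
    def test_neutral_enc_tracks_wright_curve(self, code1, rng):
        """S = 0 genes of >= 300 codons sit on Wright's expected-ENC curve
        within 3 ENC units on average."""
        from mitocodon.codon_metrics import compute_enc
        from mitocodon.selection import enc_expected
        devs = []
        for gc in np.linspace(0.25, 0.75, 12):
            m = CompartmentModel(gc_bias=float(gc), code=code1)
            g = generate_gene(m, 300, rng)
            pos = positional_gc(g)
            devs.append(abs(compute_enc(count_codons(g)) - enc_expected(pos.gc3s)))
        assert np.mean(devs) <= 3.0

    def test_selection_pulls_enc_below_curve(self, code1):
        """Sparse preferences with S > 0 push mean ENC below the neutral
        expectation (directional check)."""
        from mitocodon.codon_metrics import compute_enc
        from mitocodon.selection import enc_expected
        rng = np.random.default_rng(21)
        w = sample_preference_weights(code1, rng, sigma=2.0)
        below = []
        for rep in range(8):
            m = CompartmentModel(gc_bias=0.5, selection_strength=2.0,
                                 preference_weights=w, code=code1)
            g = generate_gene(m, 400, rng)
            pos = positional_gc(g)
            below.append(enc_expected(pos.gc3s) - compute_enc(count_codons(g)))
        assert np.mean(below) > 0

    def test_pinned_aa_composition_flattens_neutrality_slope(self, code1):
        """With amino-acid composition fixed (GC12 pinned) and only the GC
        driver varying, the GC12~GC3 slope collapses toward 0, while the
        mutation-induced mode tracks the driver at all positions."""
        from mitocodon.selection import neutrality_fit
        from mitocodon.simulate import default_aa_composition
        rng = np.random.default_rng(31)
        slopes = {}
        for mode in ("induced", "pinned"):
            pts = []
            for gc in np.linspace(0.2, 0.8, 15):
                comp = default_aa_composition(code1) if mode == "pinned" else None
                m = CompartmentModel(gc_bias=float(gc), code=code1,
                                     aa_composition=comp)
                g = generate_gene(m, 400, rng)
                pos = positional_gc(g)
                pts.append((pos.gc12, pos.gc3))
            slopes[mode] = neutrality_fit(
                [p[0] for p in pts], [p[1] for p in pts]).slope
        assert slopes["pinned"] < 0.2
        assert slopes["induced"] > 0.8
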