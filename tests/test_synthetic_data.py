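import numpy as np
import pandas as pd
import pytest

from chfmap.io_formats import HET, HOM_ALT, MISSING
from chfmap.synthetic_data import (
    SimConfig,
    SimulationError,
    WgsClassCounts,
    _genotypes_of,
    simulate_ase_counts,
    simulate_null_cohort,
    simulate_pedigree_genotypes,
    simulate_study,
    simulate_wgs_variants,
)

SMALL = dict(
    n_markers=600,
    n_chromosomes=4,
    chromosome_length_bp=40_000_000,
    causal_chromosome="chr2",
    causal_position_bp=20_000_000,
)


class TestConfigValidation:
    def test_rates_must_be_probabilities(self):
        with pytest.raises(ValueError):
            SimConfig(penetrance=1.5)
        with pytest.raises(ValueError):
            SimConfig(phenocopy_rate=-0.1)

    def test_causal_position_inside_map(self):
        with pytest.raises(ValueError):
            SimConfig(causal_position_bp=10**9)
        with pytest.raises(ValueError):
            SimConfig(n_chromosomes=10)  # default causal chr20 not simulated

    def test_wgs_counts_need_causal(self):
        with pytest.raises(ValueError):
            WgsClassCounts(breed_private_nested=0)


class TestPedigreeGenotypes:
    def test_full_penetrance_genotype_phenotype_link(self):
        study = simulate_pedigree_genotypes(SimConfig(seed=3, **SMALL))
        st, gt = study.samples, study.ground_truth
        for sid in st.ids_with_role("case"):
            assert gt.causal_genotypes[sid] == 2
            assert st.phenotype_of(sid) == "affected"
        for sid in st.ids_with_role("control"):
            assert gt.causal_genotypes[sid] < 2
            assert st.phenotype_of(sid) == "unaffected"

    def test_same_seed_identical_study(self):
        a = simulate_study(SimConfig(seed=9, **SMALL))
        b = simulate_study(SimConfig(seed=9, **SMALL))
        np.testing.assert_array_equal(a.genotypes.calls, b.genotypes.calls)
        pd.testing.assert_frame_equal(a.marker_map.df, b.marker_map.df)
        pd.testing.assert_frame_equal(a.pedigree, b.pedigree)
        assert [v.variant_id for v in a.wgs_variants] == [
            v.variant_id for v in b.wgs_variants
        ]
        assert a.ground_truth == b.ground_truth

    def test_reduced_penetrance_binomial(self):
        """With f=0.5 the fraction of homozygotes labelled affected follows
        a fair binomial across replicates."""
        n_hom = 0
        n_affected = 0
        for seed in range(200):
            cfg = SimConfig(
                seed=seed, penetrance=0.5, n_markers=40, n_chromosomes=2,
                chromosome_length_bp=30_000_000, causal_chromosome="chr1",
                causal_position_bp=15_000_000,
            )
            study = simulate_pedigree_genotypes(cfg)
            for sid, g in study.ground_truth.causal_genotypes.items():
                if g == 2:
                    n_hom += 1
                    n_affected += study.samples.phenotype_of(sid) == "affected"
        frac = n_affected / n_hom
        sd = np.sqrt(0.25 / n_hom)
        assert abs(frac - 0.5) <= 3 * sd

    def test_mendelian_consistency_per_trio(self):
        """Every case genotype is compatible with its parents' genotypes."""
        study = simulate_pedigree_genotypes(SimConfig(seed=5, **SMALL))
        ped = study.pedigree.set_index("individual")
        mm, fa = study.marker_map, study.founder_alleles
        for cid in study.samples.ids_with_role("case"):
            sire, dam = ped.loc[cid, "sire"], ped.loc[cid, "dam"]
            g_child = _genotypes_of(study.haplotypes[cid], mm, fa)
            g_sire = _genotypes_of(study.haplotypes[sire], mm, fa)
            g_dam = _genotypes_of(study.haplotypes[dam], mm, fa)
            # a child allele dose must be achievable from one allele of each parent
            lo = (g_sire // 2).astype(int) + (g_dam // 2).astype(int)
            hi = (g_sire > 0).astype(int) + (g_dam > 0).astype(int)
            assert np.all(g_child >= lo)
            assert np.all(g_child <= hi)

    def test_founder_maf_matches_configuration(self):
        study = simulate_pedigree_genotypes(SimConfig(seed=2, **SMALL))
        freqs = study.founder_alleles.mean(axis=0)
        target = (0.05 + 0.5) / 2  # mean of the uniform MAF distribution
        sd = np.sqrt(freqs.var() / len(freqs))
        assert abs(freqs.mean() - target) <= 3 * sd + 0.01

    def test_ground_truth_run_is_maximal(self):
        study = simulate_pedigree_genotypes(SimConfig(seed=4, **SMALL))
        gt = study.ground_truth
        first, last = gt.shared_run_first_marker, gt.shared_run_last_marker
        assert first is not None
        k = len(study.samples.ids_with_role("case"))
        clean = study.clean_calls[:k]
        idx = study.marker_map.chrom_indices(gt.causal_chromosome)

        def identical(j):
            col = clean[:, j]
            return ((col == 0).all()) or ((col == 2).all())

        for j in range(first, last + 1):
            assert identical(j)
        if first > idx[0]:
            assert not identical(first - 1)
        if last < idx[-1]:
            assert not identical(last + 1)

    def test_ibd_segment_covers_causal(self):
        study = simulate_pedigree_genotypes(SimConfig(seed=6, **SMALL))
        gt = study.ground_truth
        for sid, (s, e) in gt.case_ibd_segments.items():
            assert s <= gt.causal_position_bp <= e


class TestWgsVariants:
    def test_class_construction(self):
        cfg = SimConfig(seed=8, **SMALL)
        study = simulate_pedigree_genotypes(cfg)
        recs = simulate_wgs_variants(cfg, study)
        counts = cfg.wgs_variant_counts
        case, carrier = study.wgs_case_id, study.wgs_carrier_id
        n_case_hom = sum(r.genotype(case) == HOM_ALT for r in recs)
        assert len(recs) == (
            counts.shared_hom_in_controls
            + counts.het_only_in_controls
            + counts.breed_private_nested
            + counts.outside_region
        )
        seg = study.ground_truth.case_ibd_segments[case]
        inside = [r for r in recs if seg[0] <= r.position_bp <= seg[1]]
        assert len(inside) == (
            counts.shared_hom_in_controls
            + counts.het_only_in_controls
            + counts.breed_private_nested
        )
        assert all(r.genotype(case) == HOM_ALT for r in inside)
        n_carrier_het = sum(r.genotype(carrier) == HET for r in inside)
        assert n_carrier_het == counts.het_only_in_controls + counts.breed_private_nested
        causal = [r for r in recs if r.variant_id == study.ground_truth.causal_variant_id]
        assert len(causal) == 1
        assert causal[0].position_bp == cfg.causal_position_bp
        # causal alt allele never homozygous in, and absent outside, the target breed
        breeds = dict(zip(study.samples.df["sample_id"], study.samples.df["breed"]))
        for s in study.wgs_control_ids:
            g = causal[0].genotype(s)
            assert g != HOM_ALT
            if breeds[s] != cfg.target_breed:
                assert g == 0
        assert n_case_hom >= len(inside)

    def test_sample_table_resolves_wgs_panel(self):
        study = simulate_study(SimConfig(seed=8, **SMALL))
        known = set(study.samples.df["sample_id"])
        for r in study.wgs_variants:
            assert set(r.genotypes) <= known

    def test_infeasible_class_counts(self):
        cfg = SimConfig(
            seed=8,
            **{**SMALL, "n_markers": 100},
        )
        study = simulate_pedigree_genotypes(cfg)
        case = study.wgs_case_id
        seg = study.ground_truth.case_ibd_segments[case]
        big = (seg[1] - seg[0]) + 10
        cfg2 = SimConfig(
            seed=8,
            wgs_variant_counts=WgsClassCounts(shared_hom_in_controls=big),
            **{**SMALL, "n_markers": 100},
        )
        with pytest.raises(SimulationError):
            simulate_wgs_variants(cfg2, study)


class TestAseCounts:
    def test_depth_validation(self):
        with pytest.raises(ValueError):
            simulate_ase_counts(5, 0, 0.5, 0)
        with pytest.raises(ValueError):
            simulate_ase_counts(5, 10, 1.0, 0)

    def test_counts_sum_to_depth(self):
        obs = simulate_ase_counts(20, 50, 0.3, 1)
        assert all(o.gdna_ref + o.gdna_alt == 50 for o in obs)
        assert all(o.cdna_ref + o.cdna_alt == 50 for o in obs)

    def test_skewed_cdna_mean(self):
        obs = simulate_ase_counts(400, 100, 0.9, 2)
        mean_frac = np.mean([o.cdna_alt / 100 for o in obs])
        assert abs(mean_frac - 0.9) < 3 * np.sqrt(0.09 / (400 * 100)) + 0.01


class TestNullCohort:
    def test_shape_and_labels(self):
        gm, mm, st = simulate_null_cohort(SimConfig(seed=1, **SMALL))
        assert gm.calls.shape == (17, 600)
        assert sum(st.case_mask(gm.sample_ids)) == 5

    def test_no_structure(self):
        gm, _, _ = simulate_null_cohort(SimConfig(seed=1, missing_rate=0.0, **SMALL))
        assert not np.any(gm.calls == MISSING)
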