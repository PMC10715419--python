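import numpy as np
import pandas as pd
import pytest

from uremia_omics import (
    SynthConfig,
    generate_association_edges,
    generate_cohort,
    generate_dose_response,
    generate_pathway_sets,
    generate_reference_library,
    generate_tmt_proteome,
    perturb_spectrum,
)
from uremia_omics.synthetic_data import synthetic_spectrum


class TestCohort:
    def test_same_seed_gives_identical_tables(self):
        a, ta = generate_cohort(SynthConfig(n_features=100, seed=1))
        b, tb = generate_cohort(SynthConfig(n_features=100, seed=1))
        pd.testing.assert_frame_equal(a.intensities, b.intensities)
        pd.testing.assert_frame_equal(a.features, b.features)
        pd.testing.assert_frame_equal(ta, tb)

    def test_different_seeds_differ(self):
        a, _ = generate_cohort(SynthConfig(n_features=100, seed=1))
        b, _ = generate_cohort(SynthConfig(n_features=100, seed=2))
        assert not a.intensities.equals(b.intensities)

    def test_noiseless_all_category_I_post_below_pre(self):
        cfg = SynthConfig(n_features=50, frac_catI=1.0, frac_catII=0.0,
                          frac_catIII=0.0, noise_sigma=0.0, seed=5)
        table, _ = generate_cohort(cfg)
        pre = table.intensities[table.samples_with_role("PRE")].mean(axis=1)
        post = table.intensities[table.samples_with_role("POST")].mean(axis=1)
        assert (post < pre).all()

    def test_planted_category_counts_exact(self):
        cfg = SynthConfig(n_features=1000, frac_catI=0.3, frac_catII=0.2,
                          frac_catIII=0.1, seed=0)
        _, truth = generate_cohort(cfg)
        counts = truth["planted_category"].value_counts()
        assert counts["I"] == 300 and counts["II"] == 200
        assert counts["III"] == 100 and counts["unchanged"] == 400

    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            generate_cohort(SynthConfig(frac_catI=0.6, frac_catII=0.6))

    def test_qc_columns_resample_pooled_mean(self):
        table, _ = generate_cohort(SynthConfig(n_features=40, noise_sigma=0.0, seed=2))
        pooled = table.intensities[table.biological_samples()].mean(axis=1)
        for qc in table.samples_with_role("QC"):
            np.testing.assert_allclose(table.intensities[qc], pooled)

    def test_blanks_sit_far_below_samples(self):
        table, _ = generate_cohort(SynthConfig(n_features=40, noise_sigma=0.0, seed=2))
        bio = table.intensities[table.biological_samples()].mean(axis=1)
        blank = table.intensities[table.samples_with_role("BLANK")].mean(axis=1)
        np.testing.assert_allclose(bio / blank, 50.0)

    def test_planted_identities_carry_standard_metadata(self, library):
        cfg = SynthConfig(n_features=500, seed=4)
        table, truth = generate_cohort(cfg, standards=library)
        named = truth[truth["planted_identity"] != ""]
        assert len(named) == len(library)
        by_name = {s.name: s for s in library}
        for fid, name in named["planted_identity"].items():
            std = by_name[name]
            assert table.features.loc[fid, "mz"] == pytest.approx(std.theoretical_mz)
            assert table.features.loc[fid, "rt_min"] == std.rt
            assert table.features.loc[fid, "mode"] == std.mode

    def test_tsv_round_trip(self, tmp_path):
        table, _ = generate_cohort(SynthConfig(n_features=30, seed=9))
        table.to_tsv(tmp_path / "f.tsv", tmp_path / "s.tsv")
        back = type(table).from_tsv(tmp_path / "f.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back.intensities, table.intensities)
        assert dict(back.roles) == dict(table.roles)
        assert dict(back.subjects) == dict(table.subjects)


class TestReferenceLibrary:
    def test_creatinine_record_matches_printed_table(self, library):
        cre = next(s for s in library if s.name == "Creatinine")
        assert cre.formula == "C4H7N3O"
        assert cre.adduct == "[M+H]+"
        assert cre.observed_mz == pytest.approx(114.06605)

    def test_taurine_is_negative_mode(self, library):
        tau = next(s for s in library if s.name == "Taurine")
        assert tau.adduct == "[M-H]-"
        assert tau.observed_mz == pytest.approx(124.00748)

    def test_empty_selection_and_unknown_name(self):
        assert generate_reference_library([]) == []
        with pytest.raises(KeyError):
            generate_reference_library(["Unobtainium"])

    def test_library_has_21_compounds_with_spectra(self, library):
        assert len(library) == 21
        assert all(s.spectrum is not None and s.spectrum.n_peaks > 0 for s in library)


class TestPerturbSpectrum:
    def test_no_perturbation_is_identity(self):
        spec = synthetic_spectrum("x", 300.0, "positive")
        out = perturb_spectrum(spec, jitter_da=0.0, drop_frac=0.0, seed=1)
        np.testing.assert_array_equal(out.mz, spec.mz)
        np.testing.assert_array_equal(out.intensities, spec.intensities)

    def test_drop_fraction_floor_arithmetic(self):
        spec = synthetic_spectrum("x", 300.0, "positive", n_fragments=10)
        assert perturb_spectrum(spec, drop_frac=0.5, seed=1).n_peaks == 5
        assert perturb_spectrum(spec, drop_frac=0.19, seed=1).n_peaks == 9

    def test_seeded_reproducibility_and_jitter_bound(self):
        spec = synthetic_spectrum("x", 300.0, "positive")
        a = perturb_spectrum(spec, jitter_da=0.01, drop_frac=0.2, seed=7)
        b = perturb_spectrum(spec, jitter_da=0.01, drop_frac=0.2, seed=7)
        np.testing.assert_array_equal(a.mz, b.mz)
        # every surviving peak within jitter of an original one
        assert all(np.min(np.abs(spec.mz - m)) <= 0.01 for m in a.mz)

    def test_drop_frac_one_rejected(self):
        spec = synthetic_spectrum("x", 300.0, "positive")
        with pytest.raises(ValueError):
            perturb_spectrum(spec, drop_frac=1.0)


class TestProteome:
    def test_channel_layout_and_determinism(self):
        a, ta = generate_tmt_proteome(n_proteins=50, n_diff=10, seed=3)
        b, _ = generate_tmt_proteome(n_proteins=50, n_diff=10, seed=3)
        assert a.intensities.shape == (50, 15)
        assert a.channel_groups.value_counts().to_dict() == {
            "CTRL": 5, "PRE": 5, "POST": 5}
        pd.testing.assert_frame_equal(a.intensities, b.intensities)
        assert ta["planted_diff"].sum() == 10

    def test_noiseless_geometric_ratio_equals_fc(self):
        table, truth = generate_tmt_proteome(
            n_proteins=20, n_diff=5, fc=3.0, noise_sigma=0.0, seed=0)
        L = np.log2(table.intensities)
        ratio = 2 ** (
            L[table.channels_with_group("PRE")].mean(axis=1)
            - L[table.channels_with_group("CTRL")].mean(axis=1)
        )
        np.testing.assert_allclose(ratio[truth["planted_diff"].values], 3.0)
        np.testing.assert_allclose(ratio[~truth["planted_diff"].values], 1.0)

    def test_too_many_diff_rejected(self):
        with pytest.raises(ValueError):
            generate_tmt_proteome(n_proteins=5, n_diff=6)


class TestEdgesAndPathways:
    def test_planted_pairs_always_present(self):
        edges = generate_association_edges(
            ["m1", "m2"], ["p1", "p2"], density=0.0,
            planted_pairs=[("m1", "p1")], seed=0)
        assert [(e.metabolite, e.protein) for e in edges] == [("m1", "p1")]

    def test_expected_random_edge_count(self):
        mets = [f"m{i}" for i in range(50)]
        prots = [f"p{i}" for i in range(40)]
        edges = generate_association_edges(mets, prots, density=0.1, seed=1)
        expected = 0.1 * 50 * 40  # binomial mean 200, sd ~13.4
        assert abs(len(edges) - expected) < 5 * np.sqrt(expected * 0.9)

    def test_scores_in_unit_interval(self):
        edges = generate_association_edges(
            ["m1"], ["p1", "p2", "p3"], density=1.0, seed=2)
        assert all(0 < e.score <= 1 for e in edges)

    def test_pathway_sets_contain_planted(self):
        universe = [f"m{i}" for i in range(30)]
        sets = generate_pathway_sets(universe, planted_members=universe[:5],
                                     n_random_sets=3, seed=0)
        assert sets["planted_pathway"] == universe[:5]
        assert len(sets) == 4


class TestDoseResponse:
    def test_noiseless_midpoint_at_ic50(self):
        dr = generate_dose_response(ic50=10.0, hill=1.0, top=1.0, bottom=0.2,
                                    doses=[10.0], noise_sd=0.0, n_replicates=1)
        assert dr.responses[0] == pytest.approx(0.6)

    def test_monotone_decreasing_for_positive_hill(self):
        dr = generate_dose_response(ic50=5.0, hill=2.0, noise_sd=0.0,
                                    n_replicates=1)
        order = np.argsort(dr.doses)
        assert (np.diff(dr.responses[order]) < 0).all()

    def test_seed_reproducibility(self):
        a = generate_dose_response(ic50=5.0, noise_sd=0.1, seed=4)
        b = generate_dose_response(ic50=5.0, noise_sd=0.1, seed=4)
        np.testing.assert_array_equal(a.responses, b.responses)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            generate_dose_response(ic50=5.0, doses=[1.0, 0.0])
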