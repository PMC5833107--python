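import numpy as np
import pandas as pd
import pytest

from taxafun.containers import ValidationError
from taxafun.model import (
    RobustnessModel,
    run_pipeline,
    summarize_environments,
)
from taxafun.simulate import ScenarioConfig, generate_community, generate_scenario


@pytest.fixture(scope="module")
def scenario():
    return generate_scenario(
        ScenarioConfig(n_taxa=20, n_functions=80, redundancy=0.5, seed=21))


class TestRobustnessModel:
    def test_fit_produces_finite_coefficients(self, scenario):
        profile, tree, content, hierarchy = scenario
        res = RobustnessModel(profile, content, tree,
                              hierarchy=hierarchy).fit(seed=0)
        assert not res.unfittable
        assert np.isfinite(res.attenuation) and np.isfinite(res.buffering)
        assert res.buffering > 0  # larger perturbations shift function more
        assert len(res.records) == 4500

    def test_fit_deterministic_under_seed(self, scenario):
        profile, tree, content, hierarchy = scenario
        m = RobustnessModel(profile, content, tree, hierarchy=hierarchy)
        r1 = m.fit(seed=5, n_magnitudes=10, n_per_magnitude=20)
        r2 = m.fit(seed=5, n_magnitudes=10, n_per_magnitude=20)
        assert r1.attenuation == r2.attenuation
        assert r1.buffering == r2.buffering
        pd.testing.assert_frame_equal(r1.records, r2.records)

    def test_from_dataframe_constructor(self, scenario):
        profile, tree, content, hierarchy = scenario
        s = profile.to_series() * 5000  # unnormalised counts
        m = RobustnessModel.from_dataframe(s, content, tree)
        assert m.profile.abundances.sum() == pytest.approx(1.0)

    def test_identical_genomes_unfittable(self):
        profile, tree, content, hierarchy = generate_scenario(
            ScenarioConfig(n_taxa=10, n_functions=40, redundancy=1.0, seed=3))
        res = RobustnessModel(profile, content, tree).fit(
            seed=0, n_magnitudes=10, n_per_magnitude=10)
        assert res.unfittable
        assert (res.records["f"] < 1e-12).all()
        assert np.isnan(res.attenuation)
        with pytest.raises(ValidationError):
            res.predict(0.1)

    def test_summary_reports_key_quantities(self, scenario):
        profile, tree, content, hierarchy = scenario
        res = RobustnessModel(profile, content, tree, hierarchy=hierarchy,
                              community_id="gutlike",
                              environment="gut").fit(seed=0, n_magnitudes=10,
                                                     n_per_magnitude=20)
        text = res.summary()
        assert "gutlike" in text
        assert "attenuation" in text
        assert f"{res.buffering:.4f}" in text

    def test_predict_uses_power_law(self, scenario):
        profile, tree, content, hierarchy = scenario
        res = RobustnessModel(profile, content, tree).fit(
            seed=1, n_magnitudes=10, n_per_magnitude=20)
        t = 0.07
        expected = t ** res.buffering * np.exp(-res.attenuation)
        assert res.predict(t) == pytest.approx(expected)


class TestFunctionSpecific:
    def test_single_carrier_function_matches_direct_computation(self):
        """A function carried by one taxon shifts exactly like that taxon's
        renormalised relative abundance."""
        import pandas as pd

        from taxafun.containers import GenomeContentMatrix, TaxonomicProfile
        from taxafun.perturb import perturbation_matrix
        from taxafun.simulate import generate_tree

        taxa = ["T0000", "T0001", "T0002"]
        content = GenomeContentMatrix(pd.DataFrame(
            [[1.0, 2.0], [1.0, 0.0], [1.0, 0.0]], index=taxa,
            columns=["Fshared", "Fprivate"]))
        profile = TaxonomicProfile(np.array(taxa, dtype=object),
                                   np.array([0.5, 0.3, 0.2]))
        tree = generate_tree(3, seed=0)
        model = RobustnessModel(profile, content, tree,
                                copy_number_correction=False)
        model.simulate_records(n_magnitudes=5, n_per_magnitude=10, seed=2)
        P, _, base = perturbation_matrix(profile, 5, n_per_magnitude=10,
                                         seed=2)
        j = model._function_labels.index("Fprivate")
        shifts = np.abs(model._last_F[:, j] - model._last_f0[j]) / model._last_f0[j]
        direct = np.abs(P[:, 0] * 2.0 - 0.5 * 2.0) / (0.5 * 2.0)
        np.testing.assert_allclose(shifts, direct, atol=1e-12)

    def test_constant_function_excluded(self, scenario):
        profile, tree, content, hierarchy = scenario
        # marker function is single-copy in every genome: abundance constant
        model = RobustnessModel(profile, content, tree,
                                copy_number_correction=False)
        with pytest.warns(UserWarning, match="skipped"):
            curves = model.fit_function_specific(n_magnitudes=8,
                                                 n_per_magnitude=10, seed=0)
        assert "F_marker" not in curves
        assert len(curves) > 0

    def test_reproducible_under_seed(self, scenario):
        profile, tree, content, hierarchy = scenario
        model = RobustnessModel(profile, content, tree)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c1 = model.fit_function_specific(n_magnitudes=6,
                                             n_per_magnitude=10, seed=4)
            c2 = model.fit_function_specific(n_magnitudes=6,
                                             n_per_magnitude=10, seed=4)
        assert c1.keys() == c2.keys()
        for k in c1:
            assert c1[k].attenuation == c2[k].attenuation


@pytest.fixture(scope="module")
def bundle():
    profile, tree, content, hierarchy = generate_scenario(
        ScenarioConfig(n_taxa=15, n_functions=60, redundancy=0.5, seed=8))
    profiles = {f"S{i}": generate_community(15, seed=100 + i)
                for i in range(4)}
    environments = {"S0": "envA", "S1": "envA", "S2": "envB", "S3": "envB"}
    return profiles, content, tree, hierarchy, environments


class TestPipeline:
    def test_outputs_one_result_per_community(self, bundle, tmp_path):
        profiles, content, tree, hierarchy, envs = bundle
        results = run_pipeline(profiles, content, tree, hierarchy=hierarchy,
                               environments=envs, seed=0,
                               out_dir=tmp_path / "out",
                               n_magnitudes=8, n_per_magnitude=15)
        assert len(results) == 4
        curves = pd.read_csv(tmp_path / "out" / "curves.tsv", sep="\t")
        assert len(curves) == 4
        assert (tmp_path / "out" / "summaries.tsv").exists()

    def test_byte_identical_outputs_under_same_seed(self, bundle, tmp_path):
        profiles, content, tree, hierarchy, envs = bundle
        for d in ("a", "b"):
            run_pipeline(profiles, content, tree, hierarchy=hierarchy,
                         environments=envs, seed=42, out_dir=tmp_path / d,
                         n_magnitudes=6, n_per_magnitude=10)
        for name in ("curves.tsv", "gdfs.tsv", "summaries.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_tiny_community_skipped_with_warning(self, bundle):
        profiles, content, tree, hierarchy, envs = bundle
        from taxafun.containers import TaxonomicProfile

        profiles = dict(profiles)
        profiles["tiny"] = TaxonomicProfile(np.array(["T0000"], dtype=object),
                                            np.array([1.0]))
        with pytest.warns(UserWarning, match="tiny"):
            results = run_pipeline(profiles, content, tree, seed=0,
                                   n_magnitudes=6, n_per_magnitude=10)
        assert len(results) == 4

    def test_environment_summaries_within_member_range(self, bundle):
        profiles, content, tree, hierarchy, envs = bundle
        results = run_pipeline(profiles, content, tree, environments=envs,
                               seed=1, n_magnitudes=8, n_per_magnitude=15)
        summaries, contrasts = summarize_environments(results)
        for env in ("envA", "envB"):
            members = [r.attenuation for r in results
                       if r.model.environment == env]
            row = summaries[(summaries.environment == env)
                            & (summaries.metric == "attenuation")].iloc[0]
            assert min(members) <= row.pseudomedian <= max(members)
        assert {"p_value", "q_value"} <= set(contrasts.columns)
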