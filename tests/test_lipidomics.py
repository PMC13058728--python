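"""Internal-standard normalization, duplicate averaging, moderated ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from turnomix.io import ExperimentDesign, ValidationError
from turnomix.lipidomics import (average_technical_replicates, class_summary,
                                 differential_lipids,
                                 normalize_internal_standard)
from turnomix.simulate import SimulationSpec, simulate_lipidome

from conftest import quiet_spec


def lipid_rows(rows):
    """rows: (species, cls, run, sample, intensity, is_std)."""
    out = []
    for species, cls, run, sample, intensity, is_std in rows:
        g, c, r = sample.rsplit("_", 2)
        out.append(dict(species=species, lipid_class=cls,
                        internal_standard_id=f"IS_{cls}", run_id=run,
                        sample_id=sample, genotype=g, condition=c,
                        replicate=int(r.lstrip("r")), intensity=intensity,
                        is_internal_standard=is_std))
    return pd.DataFrame(out)


class TestNormalization:
    def test_species_divided_by_matched_standard(self):
        table = lipid_rows([
            ("TAG_1", "TAG", "r1", "isogenic_CM_r1", 100.0, False),
            ("TAG_2", "TAG", "r1", "isogenic_CM_r1", 0.0, False),
            ("IS_TAG", "TAG", "r1", "isogenic_CM_r1", 50.0, True),
        ])
        out = normalize_internal_standard(table)
        assert out.set_index("species")["normalized"].to_dict() == {
            "TAG_1": 2.0, "TAG_2": 0.0}

    def test_zero_standard_is_an_error(self):
        table = lipid_rows([
            ("TAG_1", "TAG", "r1", "isogenic_CM_r1", 100.0, False),
            ("IS_TAG", "TAG", "r1", "isogenic_CM_r1", 0.0, True),
        ])
        with pytest.raises(ValidationError, match="IS_TAG"):
            normalize_internal_standard(table)

    def test_run_scaling_invariance(self):
        base = lipid_rows([
            ("TAG_1", "TAG", "r1", "isogenic_CM_r1", 100.0, False),
            ("IS_TAG", "TAG", "r1", "isogenic_CM_r1", 50.0, True),
            ("TAG_1", "TAG", "r2", "isogenic_CM_r2", 80.0, False),
            ("IS_TAG", "TAG", "r2", "isogenic_CM_r2", 40.0, True),
        ])
        scaled = base.copy()
        scaled.loc[scaled["run_id"] == "r1", "intensity"] *= 37.5
        a = normalize_internal_standard(base)["normalized"]
        b = normalize_internal_standard(scaled)["normalized"]
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestAveraging:
    @pytest.mark.parametrize("values,expected", [
        ([2.0, 4.0], 3.0),
        ([5.0], 5.0),
        ([1.0, 1.0, 4.0], 2.0),
    ])
    def test_mean_across_runs(self, values, expected):
        rows = [("TAG_1", "TAG", f"r{i}", "isogenic_CM_r1", v, False)
                for i, v in enumerate(values)]
        rows += [("IS_TAG", "TAG", f"r{i}", "isogenic_CM_r1", 1.0, True)
                 for i in range(len(values))]
        matrix = average_technical_replicates(
            normalize_internal_standard(lipid_rows(rows)))
        assert matrix.loc[("TAG_1", "TAG"), "isogenic_CM_r1"] == \
            pytest.approx(expected)


def _toy_matrix(design, values_by_species):
    cols = design.sample_ids("CM")
    idx = pd.MultiIndex.from_tuples(
        [(s, s.split("_")[0]) for s in values_by_species],
        names=["species", "lipid_class"])
    return pd.DataFrame(list(values_by_species.values()), index=idx,
                        columns=cols)


class TestDifferential:
    def test_identical_groups_not_significant(self, design_cm):
        matrix = _toy_matrix(design_cm, {"TAG_1": [1, 2, 3, 4] * 3})
        out = differential_lipids(matrix, design_cm, condition="CM",
                                  moderate=False)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)
        assert not out.loc[0, "significant"]

    def test_moderation_off_matches_plain_anova(self, design_cm):
        rng = np.random.default_rng(1)
        vals = {f"TAG_{i}": list(rng.lognormal(0, 0.4, 12)) for i in range(15)}
        matrix = _toy_matrix(design_cm, vals)
        out = differential_lipids(matrix, design_cm, condition="CM",
                                  moderate=False).set_index("feature_id")
        eps = {s: min(v) / 2 for s, v in vals.items()}
        for s, v in vals.items():
            logged = np.log2(np.asarray(v) + eps[s])
            expected = sps.f_oneway(logged[0:4], logged[4:8], logged[8:12]).pvalue
            assert out.at[s, "p_value"] == pytest.approx(expected, abs=1e-10)

    def test_moderated_p_converges_to_plain_as_prior_df_vanishes(self, design_cm):
        rng = np.random.default_rng(2)
        vals = {f"TAG_{i}": list(rng.lognormal(0, 0.4, 12)) for i in range(15)}
        matrix = _toy_matrix(design_cm, vals)
        plain = differential_lipids(matrix, design_cm, condition="CM",
                                    moderate=False)["p_value"]
        for prior_df, tol in [(1.0, 0.2), (1e-3, 1e-3), (0.0, 1e-12)]:
            mod = differential_lipids(matrix, design_cm, condition="CM",
                                      moderate=True,
                                      prior_df=prior_df)["p_value"]
            assert np.max(np.abs(mod - plain)) < tol

    def test_all_zero_species_excluded_and_flagged(self, design_cm):
        matrix = _toy_matrix(design_cm, {
            "TAG_1": [0.0] * 12,
            "TAG_2": list(np.linspace(1, 2, 12)),
        })
        out = differential_lipids(matrix, design_cm, condition="CM",
                                  moderate=False).set_index("feature_id")
        assert bool(out.at["TAG_1", "excluded_all_zero"])
        assert not out.at["TAG_1", "tested"]
        assert np.isnan(out.at["TAG_1", "p_value"])
        assert out.at["TAG_2", "tested"]

    def test_fold_change_gate_requires_twofold(self, design_cm):
        # clear significance but only 1.5-fold change: not 'significant'
        base = [1.0, 1.01, 0.99, 1.0]
        vals = {"TAG_1": base + [1.5 * b for b in base] + base}
        matrix = _toy_matrix(design_cm, vals)
        out = differential_lipids(matrix, design_cm, condition="CM",
                                  moderate=False)
        assert out.loc[0, "p_adj"] < 0.05
        assert not out.loc[0, "significant"]

    def test_null_simulation_rarely_rejects_after_bh(self, design_cm_unused=None):
        runs_with_zero = 0
        n_runs = 8
        for seed in range(n_runs):
            spec = quiet_spec(seed=seed, n_lipids=1000, lipid_fold_changes=())
            table, _ = simulate_lipidome(spec)
            matrix = average_technical_replicates(
                normalize_internal_standard(table))
            out = differential_lipids(matrix, spec.design, condition="CM")
            runs_with_zero += int((out["p_adj"] < 0.05).sum() == 0)
        assert runs_with_zero >= n_runs - 1

    def test_null_p_values_uniform(self):
        from scipy.stats import kstest
        spec = quiet_spec(seed=1, n_lipids=1000, lipid_fold_changes=())
        table, _ = simulate_lipidome(spec)
        matrix = average_technical_replicates(normalize_internal_standard(table))
        out = differential_lipids(matrix, spec.design, condition="CM",
                                  moderate=False)
        assert kstest(out["p_value"].dropna(), "uniform").pvalue > 0.01

    def test_power_on_depleted_class(self):
        hits = []
        for seed in range(5):
            spec = quiet_spec(seed=seed, n_lipids=120,
                              lipid_fold_changes=(("TAG", 0.25),))
            table, truth = simulate_lipidome(spec)
            matrix = average_technical_replicates(
                normalize_internal_standard(table))
            out = differential_lipids(matrix, spec.design,
                                      condition="CM").set_index("feature_id")
            tags = truth.loc[truth["lipid_class"] == "TAG", "species"]
            d = out.loc[tags]
            down = (d["significant"] & (d["direction_P497H"] == "down")
                    & (d["direction_P506T"] == "down"))
            hits.append(down.mean())
        assert np.mean(hits) >= 0.9

    def test_significant_set_enriched_for_affected_classes(self):
        from scipy.stats import hypergeom
        spec = SimulationSpec(seed=0)
        table, _ = simulate_lipidome(spec)
        matrix = average_technical_replicates(normalize_internal_standard(table))
        out = differential_lipids(matrix, spec.design, condition="CM")
        sig = out["significant"]
        affected = out["lipid_class"].isin(["TAG", "CE"])
        p = hypergeom.sf(int((sig & affected).sum()) - 1, len(out),
                         int(affected.sum()), int(sig.sum()))
        assert p < 0.01


class TestClassSummary:
    def test_mean_of_member_species(self, design_cm):
        matrix = _toy_matrix(design_cm, {"TAG_1": [1.0] * 12,
                                         "TAG_2": [3.0] * 12,
                                         "CE_1": [5.0] * 12})
        out = class_summary(matrix)
        assert out.loc["TAG"].tolist() == [2.0] * 12
        assert out.loc["CE"].tolist() == [5.0] * 12
        assert set(out.index) == {"TAG", "CE"}

    def test_hand_computed_two_class_matrix(self, design_cm):
        matrix = _toy_matrix(design_cm, {
            "TAG_1": list(range(12)),
            "TAG_2": list(range(12, 24)),
            "CE_1": [7.0] * 12,
        })
        out = class_summary(matrix)
        np.testing.assert_allclose(out.loc["TAG"],
                                   (np.arange(12) + np.arange(12, 24)) / 2.0)
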