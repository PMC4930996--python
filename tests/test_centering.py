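import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoniche.centering import (
    between_effect_pvalue,
    build_environment_model_set,
    build_trait_model_set,
    center_within_individual,
    env_window_correlations,
    env_window_mean,
    standardize_within_year,
    test_within_effect_then_slopes as gate_within_then_slopes,
    tissue_correlation,
    trait_observation_table,
    isotope_observation_table,
)
from isoniche.lmm import ModelSpec, RandomTerm, fit_mixed_model
from isoniche.simulate import SyntheticConfig, generate_dataset

from conftest import make_dataset


class TestCentering:
    def test_single_observation_individual(self):
        df = pd.DataFrame({"individual_id": ["A"], "x": [5.0]})
        cd = center_within_individual(df, "x")
        assert cd.within.iloc[0] == 0.0 and cd.between.iloc[0] == 5.0

    def test_hand_example(self):
        df = pd.DataFrame({"individual_id": ["A"] * 3, "x": [2.0, 4.0, 6.0]})
        cd = center_within_individual(df, "x")
        assert cd.within.tolist() == [-2.0, 0.0, 2.0]
        assert cd.between.tolist() == [4.0, 4.0, 4.0]

    def test_identical_series_gives_zero_between_variance(self):
        df = pd.DataFrame(
            {"individual_id": ["A", "A", "B", "B"], "x": [1.0, 3.0, 1.0, 3.0]}
        )
        cd = center_within_individual(df, "x")
        assert cd.between.nunique() == 1

    @settings(max_examples=40, deadline=None)
    @given(
        vals=st.lists(st.floats(-1e3, 1e3), min_size=6, max_size=18),
        n_ind=st.integers(2, 5),
    )
    def test_reconstruction_and_zero_sums(self, vals, n_ind):
        """within + between reconstructs x exactly; within sums to zero per
        individual; within is orthogonal to any per-individual constant."""
        inds = [f"I{k % n_ind}" for k in range(len(vals))]
        df = pd.DataFrame({"individual_id": inds, "x": vals})
        cd = center_within_individual(df, "x")
        np.testing.assert_allclose(cd.reconstruct(), df["x"], atol=1e-9)
        sums = cd.within.groupby(df["individual_id"]).sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)
        # orthogonality of within and between columns
        cov = np.cov(cd.within, cd.between, ddof=0)[0, 1]
        scale = max(1.0, float(np.abs(vals).max()) ** 2)
        assert abs(cov) < 1e-8 * scale


class TestStandardize:
    def test_hand_example_sample_sd(self):
        df = pd.DataFrame({"year": [2006] * 3, "v": [1.0, 2.0, 3.0]})
        z = standardize_within_year(df, "v")
        assert z.tolist() == [-1.0, 0.0, 1.0]

    def test_idempotent(self, rng):
        df = pd.DataFrame({"year": np.repeat([2006, 2007], 10), "v": rng.normal(size=20)})
        z1 = standardize_within_year(df, "v")
        df2 = df.assign(v=z1)
        z2 = standardize_within_year(df2, "v")
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_constant_stratum_errors_naming_year(self):
        df = pd.DataFrame({"year": [2007, 2007], "v": [5.0, 5.0]})
        with pytest.raises(ValueError, match="2007"):
            standardize_within_year(df, "v")


class TestEnvWindow:
    def _env(self):
        rows = [
            ("SAM", 2006, 8, 1.0),
            ("SAM", 2006, 9, 2.0),
            ("SAM", 2006, 2, 5.0),
            ("SAM", 2006, 3, 5.0),
            ("SAM", 2007, 2, -3.0),
            ("SAM", 2007, 3, -3.0),
        ]
        return pd.DataFrame(rows, columns=["index_name", "year", "month", "value"])

    def test_mean_of_two_months(self):
        assert env_window_mean(self._env(), "SAM", 2006, (8, 9)) == 1.5
        assert env_window_mean(self._env(), "SAM", 2006, (2, 3)) == 5.0

    def test_no_cross_year_wrap(self):
        # Feb-Mar window for 2007 uses 2007's own months, not 2006's
        assert env_window_mean(self._env(), "SAM", 2007, (2, 3)) == -3.0

    def test_missing_month_error_names_key(self):
        with pytest.raises(KeyError, match="SAM.*2007.*month 8"):
            env_window_mean(self._env(), "SAM", 2007, (8, 9))

    def test_env_correlation_guard_reports_pairs(self):
        ds, _ = generate_dataset(SyntheticConfig(seed=3))
        tab = env_window_correlations(ds.env, [2006, 2007, 2008, 2010], (8, 9))
        assert set(zip(tab["index_a"], tab["index_b"])) == {
            ("SAM", "SOI"), ("SAM", "SSTA"), ("SOI", "SSTA")
        }
        assert tab["r"].abs().max() <= 1.0


class TestTissueCorrelation:
    def test_identical_and_anti_ordered_pairs(self):
        rows = []
        vals = [10.0, 11.0, 12.0, 13.0, 15.0]
        for k, v in enumerate(vals):
            rows.append(("A", 2006 + k, "red_blood_cell", v, v))
            rows.append(("A", 2006 + k, "feather", v, -v))
        ds = make_dataset(rows)
        assert tissue_correlation(ds, "d15N")["r"] == pytest.approx(1.0, abs=1e-12)
        assert tissue_correlation(ds, "d13C")["r"] == pytest.approx(-1.0, abs=1e-12)

    def test_five_pair_hand_oracle(self):
        x = [10.0, 11.0, 12.0, 13.0, 15.0]
        y = [20.0, 19.5, 21.0, 22.0, 24.0]
        rows = []
        for k, (a, b) in enumerate(zip(x, y)):
            rows.append(("A", 2006 + k, "red_blood_cell", a, a))
            rows.append(("A", 2006 + k, "feather", b, b))
        ds = make_dataset(rows)
        assert tissue_correlation(ds, "d15N")["r"] == pytest.approx(
            0.959043019636509, abs=1e-10
        )

    def test_too_few_pairs_error(self):
        rows = [
            ("A", 2006, "red_blood_cell", 10.0, -21.0),
            ("A", 2006, "feather", 11.0, -20.0),
            ("A", 2007, "red_blood_cell", 10.5, -21.0),
            ("A", 2007, "feather", 11.5, -20.0),
        ]
        with pytest.raises(ValueError):
            tissue_correlation(make_dataset(rows), "d15N")


def test_environment_model_set_shape():
    ds, _ = generate_dataset(SyntheticConfig(seed=7))
    mct = build_environment_model_set(ds, "red_blood_cell", "d15N", "SAM", quadratic=True)
    assert len(mct.table) == 3
    assert mct.table["delta_aic"].iloc[0] == 0.0
    assert mct.table["delta_aic"].is_monotonic_increasing
    assert ((0 <= mct.table["r2_marginal"]) & (mct.table["r2_marginal"] <= 1)).all()
    assert (mct.table["r2_marginal"] <= mct.table["r2_conditional"] + 1e-12).all()
    single = build_environment_model_set(
        ds, "red_blood_cell", "d15N", "SAM", quadratic=False, include_null=True
    )
    assert len(single.table) == 2


def test_env_effect_detected_when_strong(rng):
    """A strong within-individual environmental effect makes the linear model
    beat the null by more than 2 AIC units in most replicates."""
    wins = 0
    n_rep = 100
    for k in range(n_rep):
        cfg = SyntheticConfig(
            seed=1000 + k, beta_within=1.0, sigma2_residual=0.25,
            sigma2_year=0.0,
        )
        ds, _ = generate_dataset(cfg)
        mct = build_environment_model_set(
            ds, "red_blood_cell", "d15N", "SAM", quadratic=False
        )
        tab = mct.table.set_index("model")
        if (
            tab.loc["null", "akaike_ic"]
            - tab.loc["SAM_within+SAM_between", "akaike_ic"]
        ) > 2:
            wins += 1
    assert wins >= 0.90 * n_rep


def test_env_null_keeps_null_model_competitive():
    """With no environmental effect the null model stays within 2 AIC of the
    best model most of the time."""
    ok = 0
    n_rep = 100
    for k in range(n_rep):
        ds, _ = generate_dataset(SyntheticConfig(seed=5000 + k))
        mct = build_environment_model_set(
            ds, "red_blood_cell", "d15N", "SAM", quadratic=False
        )
        tab = mct.table
        null_delta = float(tab.loc[tab["model"] == "null", "delta_aic"].iloc[0])
        if null_delta <= 2.0:
            ok += 1
    assert ok >= 0.70 * n_rep


class TestGate:
    def test_gate_skips_slope_stage_when_within_null(self):
        """No within effect -> slope stage marked not evaluated."""
        skipped = 0
        n_rep = 50
        for k in range(n_rep):
            ds, _ = generate_dataset(SyntheticConfig(seed=300 + k))
            obs = isotope_observation_table(ds, "red_blood_cell", "d15N", "SAM")
            res = gate_within_then_slopes(obs)
            if not res.slopes_evaluated:
                skipped += 1
                assert res.slope_p is None
        assert skipped >= 0.80 * n_rep

    def test_gate_fires_and_supports_heterogeneous_slopes(self):
        fired = 0
        n_rep = 60
        for k in range(n_rep):
            cfg = SyntheticConfig(
                seed=700 + k, beta_within=1.0, slope_sd=1.0, sigma2_residual=0.25,
                sigma2_year=0.0,
            )
            ds, _ = generate_dataset(cfg)
            obs = isotope_observation_table(ds, "red_blood_cell", "d15N", "SAM")
            res = gate_within_then_slopes(obs)
            if res.slopes_evaluated and res.slope_p is not None and res.slope_p < 0.05:
                fired += 1
        assert fired >= 0.80 * n_rep

    def test_common_slope_not_supported(self):
        unsupported = 0
        n_rep = 60
        for k in range(n_rep):
            cfg = SyntheticConfig(
                seed=900 + k, beta_within=1.0, slope_sd=0.0, sigma2_residual=0.25,
                sigma2_year=0.0,
            )
            ds, _ = generate_dataset(cfg)
            obs = isotope_observation_table(ds, "red_blood_cell", "d15N", "SAM")
            res = gate_within_then_slopes(obs)
            if res.slopes_evaluated and res.slope_p is not None and res.slope_p >= 0.05:
                unsupported += 1
        assert unsupported >= 0.80 * n_rep


class TestTraitModels:
    def test_null_row_always_present_and_table_shape(self):
        ds, _ = generate_dataset(SyntheticConfig(seed=13))
        mct, gate, lost = build_trait_model_set(ds, "body_mass", "d15N")
        assert "null" in set(mct.table["model"])
        assert len(mct.table) == 2
        assert 0 <= gate.within_p <= 1

    def test_between_only_link_detected_as_between(self):
        """An among-individual-only link (beta_b = 0.8, beta_w = 0) shows up
        in the between effect, not the within effect."""
        hits = 0
        n_rep = 60
        for k in range(n_rep):
            cfg = SyntheticConfig(
                seed=1500 + k,
                trait_link=dataclasses.replace(
                    SyntheticConfig().trait_link, beta_between=0.8, beta_within=0.0,
                    noise_sd=0.3,
                ),
                trait_sigma2_individual=0.0,
                trait_sigma2_year=0.0,
            )
            ds, _ = generate_dataset(cfg)
            obs, _ = trait_observation_table(ds, "body_mass", "d15N")
            p_b = between_effect_pvalue(obs)
            res = gate_within_then_slopes(
                obs, within="iso_within", between="iso_between"
            )
            if p_b < 0.05 and res.within_p >= 0.05:
                hits += 1
        assert hits >= 0.80 * n_rep

    def test_trait_inference_invariant_to_per_year_rescaling(self):
        ds, _ = generate_dataset(SyntheticConfig(seed=21))
        obs1, _ = trait_observation_table(ds, "body_mass", "d15N")
        ds2 = ds.copy()
        scale = {y: 1.0 + 0.1 * i for i, y in enumerate(sorted(ds2.traits["year"].unique()))}
        ds2.traits["body_mass"] = ds2.traits["body_mass"] * ds2.traits["year"].map(scale)
        obs2, _ = trait_observation_table(ds2, "body_mass", "d15N")
        r1 = gate_within_then_slopes(obs2, within="iso_within", between="iso_between")
        r0 = gate_within_then_slopes(obs1, within="iso_within", between="iso_between")
        assert r1.within_p == pytest.approx(r0.within_p, abs=1e-8)


def test_within_between_separation_recovery():
    """Distinct within (beta_w = 1) and between (beta_b = -1) effects are both
    recovered with small bias at the study design scale — the key property of
    the within-individual centering decomposition."""
    bw, bb = [], []
    for k in range(40):
        cfg = SyntheticConfig(seed=2500 + k, beta_within=1.0, beta_between=-1.0)
        ds, _ = generate_dataset(cfg)
        obs = isotope_observation_table(ds, "red_blood_cell", "d15N", "SAM")
        fit = fit_mixed_model(
            obs,
            ModelSpec(
                "response", ("env_within", "env_between"),
                (RandomTerm("individual_id"), RandomTerm("year")), "REML",
            ),
        )
        bw.append(float(fit.beta["env_within"]))
        bb.append(float(fit.beta["env_between"]))
    assert abs(np.mean(bw) - 1.0) < 0.12
    assert abs(np.mean(bb) + 1.0) < 0.25
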