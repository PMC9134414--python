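import json
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solvpka import regression_stats as rs
from solvpka.synthetic_fixtures import generate_scaling_dataset


def l1(x, y, slope, intercept):
    return float(np.abs(np.asarray(y) - slope * np.asarray(x) - intercept).sum())


class TestLadFit:
    def test_collinear_points_interpolated_exactly(self):
        x = np.array([0.0, 1.0, 2.0])
        y = 2.0 * x + 1.0
        relation, report = rs.lad_fit(x, y)
        assert relation.slope == 2.0
        assert relation.intercept == 1.0
        assert report.mae == 0.0

    def test_gross_outlier_ignored(self):
        x = np.arange(9, dtype=float)
        y = 0.75 * x + 2.0
        x = np.append(x, 4.5)
        y = np.append(y, 0.75 * 4.5 + 2.0 + 20.0)
        relation, report = rs.lad_fit(x, y)
        assert relation.slope == pytest.approx(0.75, abs=1e-12)
        assert relation.intercept == pytest.approx(2.0, abs=1e-12)
        # the outlier carries the whole objective
        assert l1(x, y, relation.slope, relation.intercept) == pytest.approx(20.0)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            rs.lad_fit([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="2 points"):
            rs.lad_fit([1.0], [2.0])

    def test_objective_not_worse_than_quantile_regression(self, rng):
        # independent oracle: statsmodels median regression on noisy data
        import statsmodels.api as sm

        x = rng.uniform(-5, 25, 60)
        y = 0.6 * x - 1.0 + rng.normal(0, 1.5, 60)
        relation, _ = rs.lad_fit(x, y)
        qr = sm.QuantReg(y, sm.add_constant(x)).fit(q=0.5)
        ours = l1(x, y, relation.slope, relation.intercept)
        theirs = l1(x, y, qr.params[1], qr.params[0])
        assert ours <= theirs + 1e-6

    def test_objective_not_worse_than_ols(self, rng):
        for _ in range(5):
            x = rng.uniform(-10, 10, 30)
            y = rng.normal(0, 3, 30) + 0.3 * x
            relation, _ = rs.lad_fit(x, y)
            slope_ols, intercept_ols = np.polyfit(x, y, 1)
            assert l1(x, y, relation.slope, relation.intercept) <= l1(
                x, y, slope_ols, intercept_ols
            ) + 1e-9

    @given(
        c=st.floats(min_value=-50, max_value=50, allow_nan=False),
        s=st.floats(min_value=0.1, max_value=10, allow_nan=False),
    )
    @settings(max_examples=20)
    def test_equivariance(self, c, s):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 10, 25)
        y = 1.3 * x - 0.7 + rng.normal(0, 0.5, 25)
        base, _ = rs.lad_fit(x, y)
        shifted, _ = rs.lad_fit(x, y + c)
        assert shifted.slope == pytest.approx(base.slope, abs=1e-7)
        assert shifted.intercept == pytest.approx(base.intercept + c, abs=1e-7)
        scaled, _ = rs.lad_fit(x * s, y)
        assert scaled.slope == pytest.approx(base.slope / s, rel=1e-6, abs=1e-7)


class TestApplyScaling:
    def test_identity_relation(self):
        relation = rs.ScalingRelation(1.0, 0.0)
        assert rs.apply_scaling(8.8, relation) == 8.8

    def test_aprotic_regime_example(self):
        relation = rs.ScalingRelation(0.75, 2.0, scope="aprotic")
        assert rs.apply_scaling(8.0, relation) == pytest.approx(8.0)

    def test_inverse_round_trip(self):
        relation = rs.ScalingRelation(0.46, -1.0)
        assert rs.invert_scaling(rs.apply_scaling(7.3, relation), relation) == (
            pytest.approx(7.3, abs=1e-12)
        )

    def test_placeholder_relation_refused(self):
        unset = rs.ScalingRelation(None, None, scope="universal", provenance="unfit")
        with pytest.raises(ValueError, match="not usable"):
            rs.apply_scaling(5.0, unset)


class TestErrorStats:
    def test_mean_absolute_error(self):
        report = rs.error_stats([1.0, -1.0, 2.0], [0.0, 0.0, 0.0])
        assert report.mae == pytest.approx(4.0 / 3.0)

    def test_perfect_prediction(self):
        report = rs.error_stats([1.0, 2.0], [1.0, 2.0])
        assert report.mae == 0.0 and report.sigma == 0.0

    def test_permutation_invariance(self, rng):
        pred = rng.normal(0, 1, 20)
        exp = rng.normal(0, 1, 20)
        perm = rng.permutation(20)
        a = rs.error_stats(pred, exp)
        b = rs.error_stats(pred[perm], exp[perm])
        assert a.mae == pytest.approx(b.mae) and a.sigma == pytest.approx(b.sigma)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rs.error_stats([1.0], [1.0, 2.0])


class TestRepeatedKfoldCv:
    def test_noiseless_recovery_zero_dispersion(self):
        x, y = generate_scaling_dataset(0.75, 2.0, 50, 0.0, 0.0, seed=4)
        report = rs.repeated_kfold_cv(x, y, k=5, runs=3, seed=4)
        for run in report.run_results:
            assert run.slopes == pytest.approx([0.75] * 5, abs=1e-9)
            assert run.intercepts == pytest.approx([2.0] * 5, abs=1e-9)
            assert run.sd_slope == pytest.approx(0.0, abs=1e-9)
            assert run.var_slope == pytest.approx(0.0, abs=1e-18)

    def test_seed_reproducibility_and_distinct_partitions(self):
        x, y = generate_scaling_dataset(0.75, 2.0, 50, 1.0, 0.0, seed=4)
        a = rs.repeated_kfold_cv(x, y, seed=10)
        b = rs.repeated_kfold_cv(x, y, seed=10)
        c = rs.repeated_kfold_cv(x, y, seed=11)
        assert a.to_dict() == b.to_dict()
        assert a.run_results[0].slopes != c.run_results[0].slopes

    def test_variance_is_squared_sd(self):
        x, y = generate_scaling_dataset(0.6, -1.0, 40, 1.0, 0.0, seed=9)
        report = rs.repeated_kfold_cv(x, y, seed=9)
        for run in report.run_results:
            assert run.var_slope == pytest.approx(run.sd_slope**2, rel=1e-12)
            assert run.var_intercept == pytest.approx(run.sd_intercept**2, rel=1e-12)

    def test_selected_run_maximizes_dispersion(self):
        x, y = generate_scaling_dataset(0.6, -1.0, 40, 1.0, 0.0, seed=9)
        report = rs.repeated_kfold_cv(x, y, seed=9)
        ranks = [r.sd_slope + r.sd_intercept for r in report.run_results]
        assert report.selected_run == int(np.argmax(ranks))

    def test_small_sample_warns_but_proceeds(self):
        x, y = generate_scaling_dataset(1.0, 0.0, 10, 0.5, 0.0, seed=2)
        with pytest.warns(UserWarning, match="n >= 14"):
            report = rs.repeated_kfold_cv(x, y, k=5, runs=1, seed=2)
        assert report.n == 10

    def test_fewer_points_than_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            rs.repeated_kfold_cv([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], k=5)


class TestRelationRegistry:
    @staticmethod
    def two_class_table(seed=5):
        x1, y1 = generate_scaling_dataset(0.5, 1.0, 60, 0.3, 0.0, seed=seed)
        x2, y2 = generate_scaling_dataset(0.75, -2.0, 60, 0.3, 0.0, seed=seed + 1)
        return pd.DataFrame(
            {
                "pka_raw": np.concatenate([x1, x2]),
                "pka_exp": np.concatenate([y1, y2]),
                "solvent_class": ["protic"] * 60 + ["aprotic"] * 60,
            }
        )

    def test_universal_grouping_reduces_to_lad_fit(self, rng):
        x = rng.uniform(0, 20, 30)
        y = 0.9 * x + 0.5 + rng.normal(0, 0.2, 30)
        table = pd.DataFrame({"pka_raw": x, "pka_exp": y})
        registry = rs.fit_relation_registry(table, "universal")
        relation, _ = rs.lad_fit(x, y)
        assert registry["universal"].slope == pytest.approx(relation.slope)
        assert registry["universal"].intercept == pytest.approx(relation.intercept)

    def test_per_class_recovers_both_regimes(self):
        registry = rs.fit_relation_registry(self.two_class_table(), "per-class")
        assert registry["protic"].slope == pytest.approx(0.5, abs=0.05)
        assert registry["aprotic"].slope == pytest.approx(0.75, abs=0.05)

    def test_universal_relation_worse_than_per_class(self):
        # a single water-anchored relation leaves systematic residuals on
        # data whose two classes follow different scaling regimes
        table = self.two_class_table()
        universal = rs.fit_relation_registry(table, "universal")["universal"]
        per_class = rs.fit_relation_registry(table, "per-class")
        mae_universal = rs.error_stats(
            rs.apply_scaling(table["pka_raw"].to_numpy(), universal),
            table["pka_exp"].to_numpy(),
        ).mae
        maes = []
        for cls in ("protic", "aprotic"):
            sub = table[table["solvent_class"] == cls]
            maes.append(
                rs.error_stats(
                    rs.apply_scaling(sub["pka_raw"].to_numpy(), per_class[cls]),
                    sub["pka_exp"].to_numpy(),
                ).mae
            )
        assert mae_universal > max(maes)

    def test_undersized_group_reported_unfit(self):
        table = pd.DataFrame(
            {
                "pka_raw": [1.0, 2.0, 3.0, 4.0],
                "pka_exp": [1.1, 2.1, 3.2, 4.1],
                "solvent": ["water", "water", "water", "DMSO"],
            }
        )
        registry = rs.fit_relation_registry(table, "per-solvent", min_n=2)
        assert registry["solvent:water"].usable
        assert not registry["solvent:DMSO"].usable
        assert registry["solvent:DMSO"].provenance == "unfit"

    def test_empty_join_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rs.fit_relation_registry(pd.DataFrame(), "universal")

    def test_precedence_solvent_over_class_over_universal(self):
        registry = {
            "universal": rs.ScalingRelation(1.0, 0.0, "universal"),
            "aprotic": rs.ScalingRelation(0.75, 2.0, "aprotic"),
            "solvent:DMSO": rs.ScalingRelation(0.8, -6.0, "solvent:DMSO"),
        }
        assert (
            rs.relation_for(registry, solvent="DMSO", solvent_class="aprotic").scope
            == "solvent:DMSO"
        )
        assert (
            rs.relation_for(registry, solvent="THF", solvent_class="aprotic").scope
            == "aprotic"
        )
        assert rs.relation_for(registry, solvent="methanol").scope == "universal"

    def test_registry_json_round_trip(self):
        registry = {
            "universal": rs.ScalingRelation(0.9, 1.2, "universal", "fitted", 30),
            "solvent:THF": rs.ScalingRelation(None, None, "solvent:THF", "unfit", 1),
        }
        again = rs.registry_from_json(rs.registry_to_json(registry))
        assert again["universal"].slope == 0.9
        assert again["universal"].n == 30
        assert not again["solvent:THF"].usable


class TestKamletTaft:
    TRUE = (-10.0, -0.5, -0.4, -0.45)

    @staticmethod
    def design(n, seed):
        rng = np.random.default_rng(seed)
        return (
            rng.uniform(0.0, 1.2, n),
            rng.uniform(0.0, 1.2, n),
            rng.uniform(0.0, 1.0, n),
        )

    def table(self, n, seed, noise=0.0):
        pi, alpha, beta = self.design(n, seed)
        c0, c_pi, c_a, c_b = self.TRUE
        dg = c0 + c_pi * pi + c_a * alpha + c_b * beta
        if noise:
            dg = dg + np.random.default_rng(seed + 100).normal(0, noise, n)
        return pd.DataFrame(
            {"pi_star": pi, "alpha": alpha, "beta": beta, "dg_solv": dg}
        )

    def test_exact_interpolation_four_solvents(self):
        model, report = rs.kamlet_taft_fit(self.table(4, seed=1))
        assert model.c0 == pytest.approx(self.TRUE[0], abs=1e-9)
        assert model.c_pi == pytest.approx(self.TRUE[1], abs=1e-9)
        assert model.c_alpha == pytest.approx(self.TRUE[2], abs=1e-9)
        assert model.c_beta == pytest.approx(self.TRUE[3], abs=1e-9)
        assert report.mae == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_twenty_solvents(self):
        model, _ = rs.kamlet_taft_fit(self.table(20, seed=3, noise=0.05))
        assert model.c0 == pytest.approx(self.TRUE[0], abs=0.1)
        assert model.c_pi == pytest.approx(self.TRUE[1], abs=0.1)
        assert model.c_alpha == pytest.approx(self.TRUE[2], abs=0.1)
        assert model.c_beta == pytest.approx(self.TRUE[3], abs=0.1)

    def test_predict_linearity(self):
        model, _ = rs.kamlet_taft_fit(self.table(8, seed=2))
        assert model.predict(1.09, 1.17, 0.47) == pytest.approx(
            self.TRUE[0]
            + self.TRUE[1] * 1.09
            + self.TRUE[2] * 1.17
            + self.TRUE[3] * 0.47,
            abs=1e-8,
        )

    def test_constant_parameter_rejected_by_name(self):
        table = self.table(6, seed=4)
        table["beta"] = 0.0
        with pytest.raises(ValueError, match="beta"):
            rs.kamlet_taft_fit(table)

    def test_linearly_dependent_design_rejected(self):
        table = self.table(6, seed=5)
        table["alpha"] = 2.0 * table["pi_star"] + 0.1
        table["beta"] = table["pi_star"] - table["alpha"]
        with pytest.raises(ValueError, match="rank"):
            rs.kamlet_taft_fit(table)

    def test_too_few_solvents_rejected(self):
        with pytest.raises(ValueError, match="4 solvents"):
            rs.kamlet_taft_fit(self.table(3, seed=6))
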