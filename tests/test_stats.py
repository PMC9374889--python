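import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conndyn import (
    Cohort,
    adjusted_group_test,
    bonferroni,
    metric_intercorrelation,
    omnibus_anova,
    partial_spearman,
)
from conndyn.stats import adjusted_t, batch_adjusted_t


def make_cohort(groups, values, ages=None, sexes=None, global_values=None, rng=None):
    """Assemble a Cohort directly from per-subject metric values (1 region)."""
    rng = rng or np.random.default_rng(0)
    n = len(groups)
    values = np.asarray(values, dtype=float).reshape(n, -1)
    ages = np.asarray(ages) if ages is not None else rng.integers(21, 51, n).astype(float)
    sexes = list(sexes) if sexes is not None else list(rng.choice(["M", "F"], n))
    subjects = pd.DataFrame(
        {"subject_id": [f"s{i}" for i in range(n)], "group": groups, "age": ages, "sex": sexes}
    )
    metrics = {m: values for m in ("average", "modal", "synchronizability")}
    gm = global_values if global_values is not None else {m: values.mean(axis=1) for m in metrics}
    return Cohort(
        subjects=subjects,
        region_ids=[str(j) for j in range(values.shape[1])],
        metrics=metrics,
        global_metrics=pd.DataFrame(gm),
    )


class TestBonferroni:
    def test_arithmetic(self):
        assert bonferroni(np.array([0.0001]), 246)[0] == pytest.approx(0.0246)

    def test_capped_at_one(self):
        assert bonferroni(np.array([0.01]), 246)[0] == 1.0

    def test_identity_for_single_test(self):
        np.testing.assert_array_equal(bonferroni(np.array([0.3, 0.7]), 1), [0.3, 0.7])

    def test_monotone(self):
        p = np.array([0.001, 0.002, 0.5])
        out = bonferroni(p, 10)
        assert np.all(np.diff(out) >= 0) and np.all(out >= p)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(np.array([1.2]), 2)


class TestOmnibusAnova:
    def test_separated_groups_detected(self):
        rng = np.random.default_rng(1)
        groups = ["HC"] * 30 + ["SZ"] * 30 + ["BD"] * 30
        y = np.concatenate([rng.normal(0, 0.1, 30), rng.normal(0, 0.1, 30), rng.normal(1, 0.1, 30)])
        gc = omnibus_anova(make_cohort(groups, y), "average", "global")
        assert gc.table["p"].iloc[0] < 1e-6

    def test_identical_groups_f_near_zero(self):
        base = np.arange(20, dtype=float)
        groups = ["HC"] * 20 + ["SZ"] * 20
        gc = omnibus_anova(make_cohort(groups, np.concatenate([base, base])), "average", "global")
        assert gc.table["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        groups = ["HC"] * 5 + ["SZ"] * 5
        with pytest.raises(ValueError, match="variance"):
            omnibus_anova(make_cohort(groups, np.ones(10)), "average", "global")

    def test_type_one_error_calibrated(self):
        # 300 null replicates: rejection rate compatible with the nominal level
        rng = np.random.default_rng(2)
        groups = ["HC"] * 30 + ["SZ"] * 20 + ["BD"] * 20
        hits = 0
        reps = 300
        for _ in range(reps):
            gc = omnibus_anova(make_cohort(groups, rng.normal(size=70), rng=rng), "average", "global")
            hits += gc.table["p"].iloc[0] < 0.05
        assert 0.02 <= hits / reps <= 0.09


class TestAdjustedGroupTest:
    def test_reduces_to_plain_t_with_constant_covariates(self):
        rng = np.random.default_rng(3)
        groups = ["HC"] * 25 + ["SZ"] * 25
        y = rng.normal(size=50)
        y[25:] += 0.4
        cohort = make_cohort(groups, y, ages=np.full(50, 30.0), sexes=["M"] * 50)
        gc = adjusted_group_test(cohort, "average", "SZ-HC", "global")
        t_plain, _ = sps.ttest_ind(y[25:], y[:25], equal_var=True)
        assert gc.table["statistic"].iloc[0] == pytest.approx(t_plain, abs=1e-6)

    def test_identical_groups_t_near_zero(self):
        rng = np.random.default_rng(99)
        base = rng.normal(size=15)
        ages = np.tile(rng.uniform(21, 50, 15), 2)
        sexes = list(rng.choice(["M", "F"], 15)) * 2  # identical covariates per group
        cohort = make_cohort(["HC"] * 15 + ["SZ"] * 15, np.concatenate([base, base]), ages=ages,
                             sexes=sexes)
        gc = adjusted_group_test(cohort, "average", "SZ-HC", "global")
        assert abs(gc.table["statistic"].iloc[0]) < 1e-10

    def test_injected_effect_detected_with_power(self):
        rng = np.random.default_rng(4)
        groups = ["HC"] * 105 + ["SZ"] * 45
        hits = 0
        for _ in range(50):
            y = rng.normal(0, 0.5, 150)
            y[105:] += 1.0
            gc = adjusted_group_test(make_cohort(groups, y, rng=rng), "average", "SZ-HC", "global")
            hits += gc.table["p"].iloc[0] < 0.001
        assert hits >= 48  # >= 95% expected

    def test_age_confounder_removed(self):
        # metric depends only on age; groups differ in age; adjusted test must
        # not call this a group effect more often than the nominal rate
        rng = np.random.default_rng(5)
        hits = 0
        reps = 200
        for _ in range(reps):
            age_hc = rng.uniform(21, 40, 60)
            age_sz = rng.uniform(31, 50, 40)
            ages = np.concatenate([age_hc, age_sz])
            y = 0.1 * ages + rng.normal(0, 0.5, 100)
            cohort = make_cohort(["HC"] * 60 + ["SZ"] * 40, y, ages=ages, rng=rng)
            gc = adjusted_group_test(cohort, "average", "SZ-HC", "global")
            hits += gc.table["p"].iloc[0] < 0.05
        assert hits / reps <= 0.10

    def test_single_sex_contrast_drops_covariate(self, caplog):
        rng = np.random.default_rng(6)
        cohort = make_cohort(["HC"] * 15 + ["SZ"] * 15, rng.normal(size=30), sexes=["M"] * 30, rng=rng)
        gc = adjusted_group_test(cohort, "average", "SZ-HC", "global")
        assert np.isfinite(gc.table["statistic"].iloc[0])

    def test_batch_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        n = 40
        Y = rng.normal(size=(n, 6))
        g = (np.arange(n) < 20).astype(float)
        age = rng.uniform(21, 50, n)
        sex = rng.integers(0, 2, n).astype(float)
        t_batch, p_batch = batch_adjusted_t(Y, g, age, sex)
        for j in range(6):
            t_ref, p_ref = adjusted_t(Y[:, j], g, age, sex)
            assert t_batch[j] == pytest.approx(t_ref, abs=1e-8)
            assert p_batch[j] == pytest.approx(p_ref, abs=1e-10)

    def test_regional_bonferroni_applied(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(60, 5))
        cohort = make_cohort(["HC"] * 30 + ["SZ"] * 30, vals, rng=rng)
        gc = adjusted_group_test(cohort, "average", "SZ-HC", "regional", bonferroni_m=60)
        np.testing.assert_allclose(
            gc.table["p_corrected"], np.minimum(1.0, gc.table["p"] * 60), atol=1e-12
        )


class TestPartialSpearman:
    def test_monotone_transform_recovered(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=45)
        y = np.exp(x)  # monotone map of the metric
        C = np.column_stack([rng.uniform(21, 50, 45), rng.integers(0, 2, 45)])
        rho, p = partial_spearman(x, y, C)
        assert rho > 0.98 and p < 1e-10

    def test_null_type_one_calibrated(self):
        rng = np.random.default_rng(10)
        hits, reps = 0, 400
        for _ in range(reps):
            x = rng.normal(size=45)
            y = rng.normal(size=45)
            C = np.column_stack([rng.uniform(21, 50, 45), rng.integers(0, 2, 45)])
            _, p = partial_spearman(x, y, C)
            hits += p < 0.05
        assert 0.02 <= hits / reps <= 0.085

    def test_age_mediated_association_removed(self):
        rng = np.random.default_rng(11)
        rhos = []
        for _ in range(100):
            age = rng.uniform(21, 50, 45)
            x = age + rng.normal(0, 5, 45)
            y = age + rng.normal(0, 5, 45)
            C = np.column_stack([age, rng.integers(0, 2, 45)])
            rho, _ = partial_spearman(x, y, C)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.05

    def test_constant_scale_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.arange(12.0), np.ones(12), np.zeros((12, 1)))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            partial_spearman(np.arange(5.0), np.arange(5.0), np.zeros((5, 1)))

    def test_missing_values_dropped_pairwise(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        y = x + rng.normal(0, 0.1, 30)
        y[:5] = np.nan
        rho, _ = partial_spearman(x, y, np.column_stack([rng.uniform(21, 50, 30)]))
        assert rho > 0.9


class TestMetricIntercorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(13)
        cohort = make_cohort(["HC"] * 30, rng.normal(size=30), rng=rng)
        t = metric_intercorrelation(cohort, "HC")
        diag = t[t["metric_a"] == t["metric_b"]]
        assert (diag["rho"] == 1.0).all()

    def test_known_correlation_recovered(self):
        rng = np.random.default_rng(14)
        n = 105
        shared = rng.normal(size=n)
        gm = {
            "average": shared + rng.normal(0, 1, n),
            "modal": shared + rng.normal(0, 1, n),
            "synchronizability": rng.normal(size=n),
        }
        cohort = make_cohort(["HC"] * n, np.zeros(n), global_values=gm, rng=rng)
        t = metric_intercorrelation(cohort, "HC").set_index(["metric_a", "metric_b"])
        assert t.loc[("average", "modal"), "rho"] == pytest.approx(0.5, abs=0.15)

    def test_independent_metrics_rarely_significant(self):
        rng = np.random.default_rng(15)
        n_sig = 0
        for _ in range(30):
            gm = {m: rng.normal(size=40) for m in ("average", "modal", "synchronizability")}
            cohort = make_cohort(["HC"] * 40, np.zeros(40), global_values=gm, rng=rng)
            t = metric_intercorrelation(cohort, "HC")
            off = t[t["metric_a"] != t["metric_b"]]
            n_sig += (off["p"] < 0.05).any()
        assert n_sig <= 10  # ~86% of replicates fully null at alpha=.05 over 3 tests
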