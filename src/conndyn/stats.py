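"""Cohort container and covariate-adjusted group statistics.

Implements the comparison battery applied to the three dynamics metrics
(average controllability, modal controllability, synchronizability) at the
global and regional level:

* omnibus one-way ANOVA across the three groups;
* pairwise two-tailed group contrasts adjusted for age and sex, read off as
  the group-coefficient t in an OLS fit (equivalently ANCOVA);
* Bonferroni correction over regions at the nodal level;
* Spearman correlations with clinical scales controlling age and sex
  (rank-transform, residualize both variables on the covariates, Pearson
  correlation of the residuals with a t-distribution p-value).

All p-values are two-tailed. Non-finite metric values (the degenerate
synchronizability sentinel) are excluded from every statistic with a logged
count rather than propagated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .connectome import Connectome, stabilize
from .dynamics import average_controllability, modal_controllability
from .synchrony import global_synchronizability

logger = logging.getLogger("conndyn")

METRICS = ("average", "modal", "synchronizability")
GROUPS = ("HC", "SZ", "BD")
CONTRASTS = ("SZ-HC", "BD-HC", "SZ-BD")


# ---------------------------------------------------------------------------
# cohort container

@dataclass
class Cohort:
    """Subjects × {group, age, sex, scales} with per-region dynamics metrics.

    ``metrics[name]`` is an (n_subjects, n_regions) array aligned with
    ``subjects`` rows and ``region_ids`` columns; ``global_metrics`` holds
    one column per metric (regional mean for the controllability metrics,
    the whole-network value for synchronizability).
    """

    subjects: pd.DataFrame
    region_ids: list[str]
    metrics: dict[str, np.ndarray]
    global_metrics: pd.DataFrame
    connectomes: list[Connectome] | None = None

    def __post_init__(self) -> None:
        if self.subjects["subject_id"].duplicated().any():
            raise ValueError("duplicated subject_ids")
        if (self.subjects["age"] <= 0).any():
            raise ValueError("ages must be positive")
        n = len(self.subjects)
        for name, m in self.metrics.items():
            if m.shape != (n, len(self.region_ids)):
                raise ValueError(f"metric {name!r} has shape {m.shape}, expected {(n, len(self.region_ids))}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def group_mask(self, group: str) -> np.ndarray:
        return (self.subjects["group"] == group).to_numpy()

    def scale_names(self) -> list[str]:
        fixed = {"subject_id", "group", "age", "sex", "connectome_path"}
        return [c for c in self.subjects.columns if c not in fixed]


def nodal_metrics(c: Connectome) -> dict[str, np.ndarray | float]:
    """All three per-region metrics plus global values for one subject.

    Controllability is computed on the stabilized matrix; synchronizability
    on the raw weights (its d̄ normalization already removes overall scale).
    """
    S = stabilize(c)
    avg = average_controllability(S)
    modal = modal_controllability(S)
    sync = global_synchronizability(c)
    return {
        "average": avg,
        "modal": modal,
        "synchronizability": sync.regional_values,
        "global_average": float(avg.mean()),
        "global_modal": float(modal.mean()),
        "global_synchronizability": float(sync.global_value),
    }


def build_cohort(subjects: pd.DataFrame, connectomes: list[Connectome], keep_connectomes: bool = False) -> Cohort:
    """Compute the full metric battery for a list of subjects' connectomes."""
    if len(subjects) != len(connectomes):
        raise ValueError("subjects and connectomes must align")
    region_ids = connectomes[0].region_ids
    mats = {m: np.empty((len(connectomes), len(region_ids))) for m in METRICS}
    glob = {m: np.empty(len(connectomes)) for m in METRICS}
    for i, c in enumerate(connectomes):
        nm = nodal_metrics(c)
        for m in METRICS:
            mats[m][i] = nm[m]
            glob[m][i] = nm[f"global_{m}"]
    return Cohort(
        subjects=subjects.reset_index(drop=True),
        region_ids=list(region_ids),
        metrics=mats,
        global_metrics=pd.DataFrame(glob),
        connectomes=list(connectomes) if keep_connectomes else None,
    )


# ---------------------------------------------------------------------------
# result container

@dataclass
class GroupComparison:
    """Tidy per-target test results for one metric × level × contrast."""

    metric: str
    level: str  # {global, regional}
    contrast: str  # {omnibus, SZ-HC, BD-HC, SZ-BD}
    table: pd.DataFrame = field(repr=False)  # target, statistic, p, p_corrected, direction


# ---------------------------------------------------------------------------
# primitives

def bonferroni(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """min(1, p·m) elementwise; m defaults to the number of tests supplied."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, p * m)


def _finite(y: np.ndarray) -> np.ndarray:
    mask = np.isfinite(y)
    n_bad = int((~mask).sum())
    if n_bad:
        logger.info("excluding %d non-finite metric values from test", n_bad)
    return mask


def adjusted_t(y: np.ndarray, group01: np.ndarray, age: np.ndarray, sex01: np.ndarray) -> tuple[float, float]:
    """Group-coefficient t and two-tailed p from y ~ 1 + group + age + sex.

    Degenerate covariate columns (constant age or single-sex contrast) are
    dropped with a warning rather than producing a singular fit.
    """
    cols = [np.asarray(group01, dtype=float)]
    names = ["group"]
    for name, v in (("age", age), ("sex", sex01)):
        v = np.asarray(v, dtype=float)
        if np.ptp(v) == 0:
            logger.warning("covariate %s is constant in this contrast; dropped", name)
            continue
        cols.append(v)
        names.append(name)
    X = sm.add_constant(np.column_stack(cols), has_constant="add")
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return float(fit.tvalues[1]), float(fit.pvalues[1])


def batch_adjusted_t(Y: np.ndarray, group01: np.ndarray, age: np.ndarray, sex01: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS group-term t and two-tailed p for many outcomes at once.

    ``Y`` is (n_subjects, n_targets). Same model as :func:`adjusted_t`,
    solved for all columns in one least-squares call; used where thousands
    of per-feature fits are needed (regional tests, in-fold feature
    selection). Agreement with the statsmodels route is asserted in tests.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    cols = [np.ones(n), np.asarray(group01, dtype=float)]
    for v in (age, sex01):
        v = np.asarray(v, dtype=float)
        if np.ptp(v) != 0:
            cols.append(v)
    X = np.column_stack(cols)
    k = X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)  # (k, n_targets)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    return t, p


# ---------------------------------------------------------------------------
# cohort-level tests

def _metric_values(cohort: Cohort, metric: str, level: str) -> tuple[np.ndarray, list[str]]:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if level == "global":
        return cohort.global_metrics[metric].to_numpy()[:, None], ["global"]
    if level == "regional":
        return cohort.metrics[metric], list(cohort.region_ids)
    raise ValueError(f"unknown level {level!r}")


def omnibus_anova(cohort: Cohort, metric: str, level: str = "global", bonferroni_m: int | None = None) -> GroupComparison:
    """One-way ANOVA of the metric across all groups present in the cohort."""
    groups = [g for g in GROUPS if cohort.group_mask(g).any()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if cohort.group_mask(g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
    Y, targets = _metric_values(cohort, metric, level)
    rows = []
    for j, target in enumerate(targets):
        samples = []
        for g in groups:
            y = Y[cohort.group_mask(g), j]
            samples.append(y[_finite(y)])
        if all(np.ptp(s) == 0 for s in samples if len(s)):
            raise ValueError("zero within-group variance everywhere")
        F, p = sps.f_oneway(*samples)
        rows.append((target, float(F), float(p)))
    table = pd.DataFrame(rows, columns=["target", "statistic", "p"])
    m = bonferroni_m if bonferroni_m is not None else len(targets)
    table["p_corrected"] = bonferroni(table["p"].to_numpy(), m) if level == "regional" else table["p"]
    table["direction"] = ""
    return GroupComparison(metric=metric, level=level, contrast="omnibus", table=table)


def adjusted_group_test(
    cohort: Cohort,
    metric: str,
    contrast: str,
    level: str = "global",
    bonferroni_m: int | None = None,
) -> GroupComparison:
    """Two-tailed group contrast adjusted for age and sex.

    The contrast ``"A-B"`` codes group A as 1 and B as 0, so a positive t
    means A > B after adjustment. Regional p-values are Bonferroni-corrected
    over ``bonferroni_m`` tests (defaults to the number of regions).
    """
    a, b = contrast.split("-")
    mask = cohort.group_mask(a) | cohort.group_mask(b)
    if not cohort.group_mask(a).any() or not cohort.group_mask(b).any():
        raise ValueError(f"contrast {contrast}: both groups must be present")
    sub = cohort.subjects.loc[mask]
    g01 = (sub["group"] == a).to_numpy(dtype=float)
    age = sub["age"].to_numpy(dtype=float)
    sex01 = (sub["sex"] == "M").to_numpy(dtype=float)
    Y, targets = _metric_values(cohort, metric, level)
    Y = Y[mask]

    rows = []
    if level == "global":
        y = Y[:, 0]
        keep = _finite(y)
        t, p = adjusted_t(y[keep], g01[keep], age[keep], sex01[keep])
        rows.append(("global", t, p))
    else:
        col_ok = np.isfinite(Y).all(axis=0)
        n_bad = int((~col_ok).sum())
        if n_bad:
            logger.info("%d regions with non-finite values excluded from %s contrast", n_bad, contrast)
        t_ok, p_ok = batch_adjusted_t(Y[:, col_ok], g01, age, sex01)
        it = iter(zip(t_ok, p_ok))
        for target, ok in zip(targets, col_ok):
            if ok:
                t, p = next(it)
                rows.append((target, float(t), float(p)))
            else:
                rows.append((target, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["target", "statistic", "p"])
    if level == "regional":
        m = bonferroni_m if bonferroni_m is not None else len(targets)
        pc = np.full(len(table), np.nan)
        fin = table["p"].notna().to_numpy()
        pc[fin] = bonferroni(table.loc[fin, "p"].to_numpy(), m)
        table["p_corrected"] = pc
    else:
        table["p_corrected"] = table["p"]
    table["direction"] = np.where(table["statistic"] > 0, f"{a}>{b}", f"{a}<{b}")
    return GroupComparison(metric=metric, level=level, contrast=contrast, table=table)


# ---------------------------------------------------------------------------
# covariate-controlled Spearman correlations

def partial_spearman(x: np.ndarray, y: np.ndarray, covariates: np.ndarray) -> tuple[float, float]:
    """Spearman correlation of x and y controlling for covariates.

    All variables — metric, scale and each covariate column — are
    rank-transformed (average ranks for ties), the metric and scale ranks
    are residualized on an intercept plus the covariate ranks, and the
    Pearson correlation of the residuals is tested two-tailed against a
    t-distribution with n − 2 − k degrees of freedom. Ranking the
    covariates makes the adjustment the rank-based partial correlation,
    robust to monotone covariate-metric relationships.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != len(x):
        C = C.T
    keep = np.isfinite(x) & np.isfinite(y)
    x, y, C = x[keep], y[keep], C[keep]
    n = len(x)
    if n < 10:
        raise ValueError(f"need at least 10 paired observations, have {n}")
    if np.ptp(y) == 0:
        raise ValueError("constant scale: correlation undefined")
    if np.ptp(x) == 0:
        raise ValueError("constant metric: correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    D = np.column_stack([np.ones(n), sps.rankdata(C, axis=0)])
    rx_res = rx - D @ np.linalg.lstsq(D, rx, rcond=None)[0]
    ry_res = ry - D @ np.linalg.lstsq(D, ry, rcond=None)[0]
    denom = np.sqrt(np.sum(rx_res**2) * np.sum(ry_res**2))
    if denom == 0:
        raise ValueError("residual variance is zero after covariate removal")
    rho = float(np.dot(rx_res, ry_res) / denom)
    dof = n - 2 - C.shape[1]
    t = rho * np.sqrt(dof / max(1e-300, 1.0 - rho**2))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return rho, p


def cohort_partial_spearman(cohort: Cohort, group: str, metric: str, region: str, scale: str) -> tuple[float, float]:
    """Metric–scale correlation within one group, controlling age and sex."""
    mask = cohort.group_mask(group)
    sub = cohort.subjects.loc[mask]
    j = cohort.region_ids.index(region)
    x = cohort.metrics[metric][mask, j]
    y = sub[scale].to_numpy(dtype=float)
    n_missing = int(np.sum(~np.isfinite(y)))
    if n_missing:
        logger.info("%s/%s: dropping %d subjects with missing %s", group, metric, n_missing, scale)
    C = np.column_stack([sub["age"].to_numpy(dtype=float), (sub["sex"] == "M").to_numpy(dtype=float)])
    return partial_spearman(x, y, C)


def metric_intercorrelation(cohort: Cohort, group: str) -> pd.DataFrame:
    """Pairwise partial Spearman correlations among the three global metrics.

    Within one group, controlling age and sex; p-values Bonferroni-corrected
    across the three distinct pairs. Diagonal is exactly 1.
    """
    mask = cohort.group_mask(group)
    sub = cohort.subjects.loc[mask]
    C = np.column_stack([sub["age"].to_numpy(dtype=float), (sub["sex"] == "M").to_numpy(dtype=float)])
    rows = []
    raw_p = {}
    for i, m1 in enumerate(METRICS):
        for j, m2 in enumerate(METRICS):
            if i < j:
                rho, p = partial_spearman(
                    cohort.global_metrics[m1].to_numpy()[mask],
                    cohort.global_metrics[m2].to_numpy()[mask],
                    C,
                )
                raw_p[(m1, m2)] = (rho, p)
    for (m1, m2), (rho, p) in raw_p.items():
        rows.append((m1, m2, rho, p, min(1.0, p * len(raw_p))))
    for m in METRICS:
        rows.append((m, m, 1.0, 0.0, 0.0))
    return pd.DataFrame(rows, columns=["metric_a", "metric_b", "rho", "p", "p_corrected"])
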