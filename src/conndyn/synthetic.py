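"""Synthetic cohorts with the statistical structure the analysis assumes.

Emulates the products of a three-group structural-connectome study —
healthy controls (HC, n=105), schizophrenia (SZ, n=45) and bipolar disorder
(BD, n=47) — without any imaging data:

* connectomes share a cohort-level template: a modular weighted graph with
  edges drawn block-wise (higher density within than between modules) and
  log-normal weights mimicking heavy-tailed streamline counts. Each subject
  applies independent multiplicative log-normal jitter to the template
  edges, the way real cohorts share a common wiring backbone with
  individual variation; weights are rounded to integers ≥ 1 and matrices
  are symmetric, zero-diagonal and connected (templates are redrawn until
  connected);
* group effects are injected on the structure, not the metrics: the
  incident weights of designated regions are rescaled, which raises (or
  lowers) that region's dynamics metrics so the entire metric pipeline sits
  inside every test loop. Effect sizes stated in within-group SD units of a
  target metric are translated to a weight multiplier by a paired pilot
  simulation;
* covariates follow the study demographics (ages 21–50, group-specific sex
  ratios); clinical scales are linear combinations of designated node
  metrics plus noise, or pure noise around plausible scale baselines when
  no drivers are specified (SZ: BDRS, SANS, SAPS; BD: YMRS, HAMD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csgraph, csr_matrix

from .connectome import Connectome, write_connectome
from .stats import Cohort, build_cohort, nodal_metrics

logger = logging.getLogger("conndyn")

#: male fraction per group, from the study demographics (58/47, 34/11, 28/19)
DEFAULT_MALE_FRACTION = {"HC": 58 / 105, "SZ": 34 / 45, "BD": 28 / 47}

#: plausible clinical-scale baselines (mean, SD) when a scale has no drivers
SCALE_BASELINES = {
    "BDRS": (10.0, 5.0),
    "SANS": (25.0, 15.0),
    "SAPS": (20.0, 12.0),
    "YMRS": (8.0, 6.0),
    "HAMD": (10.0, 6.0),
}

DEFAULT_SCALE_GROUPS = {"BDRS": "SZ", "SANS": "SZ", "SAPS": "SZ", "YMRS": "BD", "HAMD": "BD"}


@dataclass(frozen=True)
class Effect:
    """A structural group effect on designated regions.

    Either ``weight_scale`` (direct incident-weight multiplier) or
    ``size_sd`` (target shift of ``metric`` in within-group SD units,
    calibrated by pilot simulation) must be given.
    """

    group: str
    metric: str
    regions: tuple[int, ...]
    size_sd: float | None = None
    weight_scale: float | None = None


@dataclass(frozen=True)
class ScaleModel:
    """How one clinical scale is generated.

    ``drivers`` are (metric, region_index, coefficient) triples; the scale
    is baseline + Σ coef·metric + Gaussian noise with SD either absolute
    (``noise_sd``) or a fraction of the across-subject signal SD
    (``noise_ratio``). With ``standardized`` the coefficients apply to the
    within-group z-scored metric values, i.e. effects are stated in
    standardized units (the convention used for group effects as well).
    With no drivers the scale is baseline noise only.
    """

    name: str
    group: str
    drivers: tuple[tuple[str, int, float], ...] = ()
    noise_sd: float | None = None
    noise_ratio: float | None = None
    standardized: bool = False


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_regions: int = 60
    group_sizes: tuple[tuple[str, int], ...] = (("HC", 105), ("SZ", 45), ("BD", 47))
    n_modules: int = 4
    density_within: float = 0.6
    density_between: float = 0.15
    weight_mu: float = 2.0  # log-scale mean of template streamline-like counts
    weight_sigma: float = 0.8  # log-scale SD across template edges
    subject_sigma: float = 0.3  # log-scale SD of per-subject edge jitter
    effects: tuple[Effect, ...] = ()
    age_range: tuple[int, int] = (21, 50)
    male_fraction: tuple[tuple[str, float], ...] = tuple(DEFAULT_MALE_FRACTION.items())
    age_shift: tuple[tuple[str, float], ...] = ()  # additive group age shifts
    age_weight_slope: float = 0.0  # per-year multiplicative trend on all weights
    scale_models: tuple[ScaleModel, ...] = tuple(
        ScaleModel(name=s, group=g) for s, g in DEFAULT_SCALE_GROUPS.items()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.density_within <= 1 and 0 < self.density_between <= 1):
            raise ValueError("densities must lie in (0, 1]")
        for g, n in self.group_sizes:
            if n < 2:
                raise ValueError(f"group {g} size must be >= 2")


def _module_assignment(n_regions: int, n_modules: int) -> np.ndarray:
    return np.concatenate([np.full(len(chunk), i) for i, chunk in enumerate(np.array_split(np.arange(n_regions), n_modules))])


def generate_template(spec: CohortSpec, rng: np.random.Generator, max_attempts: int = 100) -> np.ndarray:
    """Draw the cohort-level template weight matrix (float, symmetric).

    Block-modular edge presence with log-normal weights; redrawn until
    connected (attempts logged).
    """
    n = spec.n_regions
    modules = _module_assignment(n, spec.n_modules)
    same = modules[:, None] == modules[None, :]
    p_edge = np.where(same, spec.density_within, spec.density_between)
    iu = np.triu_indices(n, k=1)
    for attempt in range(max_attempts):
        present = rng.random(len(iu[0])) < p_edge[iu]
        w = rng.lognormal(mean=spec.weight_mu, sigma=spec.weight_sigma, size=len(iu[0]))
        w = np.where(present, w, 0.0)
        W = np.zeros((n, n))
        W[iu] = w
        W = W + W.T
        n_comp, _ = csgraph.connected_components(csr_matrix(W), directed=False)
        if n_comp == 1:
            if attempt:
                logger.info("template: connected after %d redraws", attempt)
            return W
    raise RuntimeError(f"no connected template after {max_attempts} attempts; increase density")


def generate_connectome(
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "sim",
    age: float | None = None,
    weight_scales: dict[int, float] | None = None,
    template: np.ndarray | None = None,
) -> Connectome:
    """Draw one subject's integer-weighted connectome around a template.

    Each template edge is multiplied by independent log-normal jitter
    (subject-level individual variation); when no template is supplied a
    fresh one is drawn from ``rng``. ``weight_scales`` multiplies the
    incident edge weights of the given 0-based region indices (the
    group-effect mechanism). Rounding keeps present edges at weight ≥ 1, so
    subject matrices inherit the template's connectedness.
    """
    n = spec.n_regions
    if template is None:
        template = generate_template(spec, rng)
    iu = np.triu_indices(n, k=1)
    jitter = rng.lognormal(mean=0.0, sigma=spec.subject_sigma, size=len(iu[0]))
    w = template[iu] * jitter
    if age is not None and spec.age_weight_slope != 0.0:
        mid = (spec.age_range[0] + spec.age_range[1]) / 2.0
        w = w * max(0.05, 1.0 + spec.age_weight_slope * (age - mid))
    W = np.zeros((n, n))
    W[iu] = w
    W = W + W.T
    if weight_scales:
        for r, s in weight_scales.items():
            W[r, :] *= s
            W[:, r] *= s
    A = np.where(W > 0, np.maximum(1.0, np.rint(W)), 0.0)
    return Connectome(subject_id=subject_id, A=A)


# ---------------------------------------------------------------------------
# effect calibration

def calibrate_effect(
    spec: CohortSpec,
    effect: Effect,
    rng: np.random.Generator,
    template: np.ndarray,
    n_pilot: int = 20,
) -> float:
    """Weight multiplier achieving the requested metric shift in SD units.

    Generates ``n_pilot`` paired baseline/scaled pilot subjects around the
    cohort template on a grid of candidate multipliers, measures the mean
    metric shift at the affected regions against the across-pilot baseline
    SD, and interpolates the multiplier whose shift matches ``size_sd`` ×
    SD. The shift is monotone in the multiplier for all three metrics;
    targets outside the grid are clipped with a warning.
    """
    if effect.size_sd is None:
        raise ValueError("calibrate_effect needs an effect with size_sd")
    seeds = rng.integers(0, 2**31 - 1, size=n_pilot)
    grid = np.geomspace(0.5, 2.5, 7)
    regions = list(effect.regions)
    base_vals = np.empty((n_pilot, len(regions)))
    shift = np.zeros((len(grid), n_pilot))
    for i, s in enumerate(seeds):
        c0 = generate_connectome(spec, effect.group, np.random.default_rng(int(s)), template=template)
        v0 = np.asarray(nodal_metrics(c0)[effect.metric])[regions]
        base_vals[i] = v0
        for gidx, scale in enumerate(grid):
            c1 = generate_connectome(
                spec, effect.group, np.random.default_rng(int(s)), template=template,
                weight_scales={r: scale for r in regions},
            )
            v1 = np.asarray(nodal_metrics(c1)[effect.metric])[regions]
            shift[gidx, i] = float(np.mean(v1 - v0))
    sd = float(np.mean(base_vals.std(axis=0, ddof=1)))
    target = effect.size_sd * sd
    mean_shift = shift.mean(axis=1)
    order = np.argsort(mean_shift)
    chosen = float(np.interp(target, mean_shift[order], grid[order]))
    if target < mean_shift.min() or target > mean_shift.max():
        logger.warning(
            "effect %s/%s: target shift %.3g outside calibration grid [%.3g, %.3g]; clipping",
            effect.group, effect.metric, target, mean_shift.min(), mean_shift.max(),
        )
    logger.info("effect %s/%s: size %.2f SD -> weight scale %.3f", effect.group, effect.metric, effect.size_sd, chosen)
    return chosen


# ---------------------------------------------------------------------------
# cohort generation

def generate_cohort(spec: CohortSpec, seed: int | None = None, keep_connectomes: bool = False) -> Cohort:
    """Generate a full synthetic cohort: connectomes, covariates, scales, metrics."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    template = generate_template(spec, rng)

    # resolve effects to weight multipliers (calibrated where given in SD units)
    scales_by_group: dict[str, dict[int, float]] = {}
    for eff in spec.effects:
        if eff.weight_scale is not None:
            ws = eff.weight_scale
        else:
            ws = calibrate_effect(spec, eff, np.random.default_rng(seed + 7), template)
        d = scales_by_group.setdefault(eff.group, {})
        for r in eff.regions:
            d[r] = d.get(r, 1.0) * ws

    male_frac = dict(spec.male_fraction)
    age_shift = dict(spec.age_shift)
    rows, connectomes = [], []
    i_subj = 0
    for group, size in spec.group_sizes:
        for _ in range(size):
            sid = f"sub-{i_subj:04d}"
            age = float(rng.integers(spec.age_range[0], spec.age_range[1] + 1)) + age_shift.get(group, 0.0)
            sex = "M" if rng.random() < male_frac.get(group, 0.5) else "F"
            c = generate_connectome(
                spec, group, rng, subject_id=sid, age=age,
                weight_scales=scales_by_group.get(group), template=template,
            )
            rows.append({"subject_id": sid, "group": group, "age": age, "sex": sex})
            connectomes.append(c)
            i_subj += 1
    subjects = pd.DataFrame(rows)
    cohort = build_cohort(subjects, connectomes, keep_connectomes=keep_connectomes)

    # clinical scales: linear combinations of node metrics plus noise
    for sm in spec.scale_models:
        col = np.full(len(subjects), np.nan)
        mask = cohort.group_mask(sm.group)
        n_g = int(mask.sum())
        base_mu, base_sd = SCALE_BASELINES.get(sm.name, (10.0, 5.0))
        if sm.drivers:
            signal = np.zeros(n_g)
            for metric, region, coef in sm.drivers:
                x = cohort.metrics[metric][mask, region]
                if sm.standardized:
                    sd = x.std(ddof=1)
                    x = (x - x.mean()) / (sd if sd > 0 else 1.0)
                signal = signal + coef * x
            sig_sd = float(signal.std(ddof=1))
            noise_sd = sm.noise_sd if sm.noise_sd is not None else (sm.noise_ratio or 0.0) * sig_sd
            col[mask] = base_mu + signal + rng.normal(0.0, noise_sd, size=n_g)
        else:
            col[mask] = np.maximum(0.0, base_mu + rng.normal(0.0, base_sd, size=n_g))
        cohort.subjects[sm.name] = col
    return cohort


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write manifest + dense matrix files; returns the manifest path.

    Requires the cohort to have been generated with ``keep_connectomes=True``
    (or loaded from files).
    """
    if cohort.connectomes is None:
        raise ValueError("cohort carries no connectomes to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "connectomes").mkdir(exist_ok=True)
    manifest = cohort.subjects.copy()
    paths = []
    for c in cohort.connectomes:
        p = outdir / "connectomes" / f"{c.subject_id}.txt"
        write_connectome(c, p)
        paths.append(str(p.relative_to(outdir)))
    manifest.insert(4, "connectome_path", paths)
    mpath = outdir / "manifest.csv"
    manifest.to_csv(mpath, index=False)
    return mpath


def module_scale_model(
    name: str,
    group: str,
    spec: CohortSpec,
    module: int = 0,
    noise_ratio: float = 0.2,
    avg_coef: float = 1.0,
    modal_coef: float = -1.0,
) -> ScaleModel:
    """Scale driven by one module's controllability profile.

    Clinical severity is modeled as tracking the dynamics of a coherent
    subsystem rather than a single isolated node: the scale loads positively
    on the average controllability and negatively on the modal
    controllability of every region in the chosen module (the two metrics
    are anti-correlated at the node level, so both feature directions carry
    signal). Coefficients apply to standardized metric values so each
    region contributes in within-group SD units, matching the convention
    used for structural group effects.
    """
    blocks = np.array_split(np.arange(spec.n_regions), spec.n_modules)
    regions = blocks[module]
    drivers = tuple(("average", int(r), avg_coef) for r in regions) + tuple(
        ("modal", int(r), modal_coef) for r in regions
    )
    return ScaleModel(name=name, group=group, drivers=drivers, noise_ratio=noise_ratio, standardized=True)


def null_spec(n_regions: int = 60, seed: int = 0, **kw) -> CohortSpec:
    """Convenience: a cohort spec with no group effects and noise-only scales."""
    return CohortSpec(n_regions=n_regions, seed=seed, effects=(), **kw)
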