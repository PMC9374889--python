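"""Supercontroller regions and their distribution over cognitive systems.

A supercontroller is a region whose group-mean metric value exceeds the
across-region mean plus one standard deviation. Group-level regional values
are averaged across subjects per region before thresholding (one map per
group), the SD uses the sample (n−1) denominator, and the inequality is
strict — so a flat map yields an empty set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import validate_region_table


@dataclass(frozen=True)
class SupercontrollerSet:
    metric: str
    group: str
    regions: frozenset[str]
    threshold: float


def supercontroller_regions(
    group_mean_values: np.ndarray,
    region_ids: Sequence[str],
    metric: str = "",
    group: str = "",
    top_k: int | None = None,
) -> SupercontrollerSet:
    """Regions whose group-mean value exceeds mean + 1 SD (sample SD).

    Non-finite entries (degenerate-synchronizability sentinels) are excluded
    before thresholding. ``top_k`` switches to rank selection of the k
    highest regions instead of the mean+SD rule; it has no default.
    """
    values = np.asarray(group_mean_values, dtype=float)
    region_ids = list(region_ids)
    if values.shape != (len(region_ids),):
        raise ValueError("values and region_ids must have matching length")
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite values")
    v = values[finite]
    ids = [r for r, f in zip(region_ids, finite) if f]
    if top_k is not None:
        order = np.argsort(v)[::-1][:top_k]
        chosen = frozenset(ids[i] for i in order)
        threshold = float(v[order[-1]]) if top_k else np.inf
        return SupercontrollerSet(metric=metric, group=group, regions=chosen, threshold=threshold)
    threshold = float(v.mean() + v.std(ddof=1))
    chosen = frozenset(r for r, x in zip(ids, v) if x > threshold)
    return SupercontrollerSet(metric=metric, group=group, regions=chosen, threshold=threshold)


def system_distribution(s: SupercontrollerSet, region_table: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of supercontroller regions per cognitive system.

    ``fraction`` is the share of each system's regions that carry the
    supercontroller role, so a system fully covered by the set scores 1.0.
    """
    rt = validate_region_table(region_table)
    known = set(rt["region_id"])
    unknown = s.regions - known
    if unknown:
        raise ValueError(f"regions not in region table: {sorted(unknown)[:5]}")
    totals = rt.groupby("yeo_system", sort=True)["region_id"].count()
    member = rt[rt["region_id"].isin(s.regions)]
    counts = member.groupby("yeo_system", sort=True)["region_id"].count()
    out = pd.DataFrame({"n_regions": totals, "n_supercontrollers": counts}).fillna(0)
    out["n_supercontrollers"] = out["n_supercontrollers"].astype(int)
    out["fraction"] = out["n_supercontrollers"] / out["n_regions"]
    return out.reset_index()
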