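"""Growth summaries, stress-robustness scores and factor-effect tests.

Robustness is the microbiological log-reduction score
``log10(Nt) - log10(N0)`` (0 = full survival, -3 = 1000-fold kill),
averaged over plating replicates.  Factor effects on any per-fermentation
scalar (mu_max, OD_final, robustness) are assessed with a Welch two-sample
t-test between the fermentations at one factor level and those at another,
all remaining factors varying in the background as the combinatorial design
intends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "estimate_mu_max",
    "growth_summaries",
    "compute_robustness",
    "correlate_profiles",
    "test_parameter_effect",
    "ParameterEffect",
]


def estimate_mu_max(times, od, window: int = 4) -> float:
    """Maximum specific growth rate (h^-1) from an OD600 time series.

    The steepest slope of ln(OD) vs time over all sliding windows of
    ``window`` consecutive points, floored at zero.  Windows containing
    non-positive OD are skipped.
    """
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    if window < 3:
        raise ValueError("window must span at least 3 points")
    if times.size < window:
        raise ValueError("curve shorter than the fitting window")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    best = None
    for i in range(times.size - window + 1):
        t = times[i:i + window]
        y = od[i:i + window]
        if np.any(y <= 0):
            continue
        slope = np.polyfit(t, np.log(y), 1)[0]
        best = slope if best is None else max(best, slope)
    if best is None:
        raise ValueError("no window with all-positive OD values")
    return max(best, 0.0)


def growth_summaries(curves: pd.DataFrame, window: int = 4) -> pd.DataFrame:
    """Per-fermentation mu_max and final OD from a long-format curve table."""
    out = []
    for fid, grp in curves.groupby("fermentation_id", sort=True):
        grp = grp.sort_values("time_h")
        out.append({
            "fermentation_id": fid,
            "mu_max": estimate_mu_max(grp["time_h"], grp["od600"], window=window),
            "od_final": float(grp["od600"].iloc[-1]),
        })
    return pd.DataFrame(out)


def compute_robustness(records: pd.DataFrame) -> pd.DataFrame:
    """Robustness profile from CFU records.

    Input columns: ``fermentation_id, stress, time_min, replicate,
    n0_cfu_per_ml, nt_cfu_per_ml``.  Per fermentation x stress x time point,
    replicate log10(nt/n0) ratios are averaged (mean of log ratios, not log of
    mean counts).  Survival percentage is ``100 * 10**robustness``.  Entries at
    time 0 define N0 and have robustness 0.  Replicates with ``nt = 0`` are
    below the plating detection limit: they are flagged (``censored``) and
    excluded from the average with a warning; a group with no uncensored
    replicate gets NaN robustness.
    """
    df = records.copy()
    if (df["n0_cfu_per_ml"] <= 0).any():
        raise ValueError("n0 must be positive")
    if (df["nt_cfu_per_ml"] < 0).any():
        raise ValueError("nt must be non-negative")
    rows = []
    n_censored = 0
    for (fid, stress, t), grp in df.groupby(
            ["fermentation_id", "stress", "time_min"], sort=True):
        if t == 0:
            rows.append((fid, stress, t, 0.0, 100.0, False))
            continue
        ok = grp["nt_cfu_per_ml"] > 0
        n_censored += int((~ok).sum())
        if ok.any():
            ratios = (np.log10(grp.loc[ok, "nt_cfu_per_ml"])
                      - np.log10(grp.loc[ok, "n0_cfu_per_ml"]))
            rob = float(ratios.mean())
            rows.append((fid, stress, t, rob, 100.0 * 10.0 ** rob, (~ok).any()))
        else:
            rows.append((fid, stress, t, np.nan, np.nan, True))
    if n_censored:
        warnings.warn(
            f"{n_censored} replicate(s) below detection limit (nt = 0) excluded",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows,
        columns=["fermentation_id", "stress", "time_min",
                 "robustness_log10", "survival_pct", "censored"],
    )


def correlate_profiles(x, y) -> tuple[float, float]:
    """Pearson correlation and two-sided p-value between two phenotype vectors
    (e.g. 30- vs 60-minute robustness, or heat vs oxidative survival)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("profiles must be finite (drop censored entries first)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a profile; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class ParameterEffect:
    factor: str
    level_a: object
    level_b: object
    t_statistic: float
    p_value: float
    direction: str      # "a_higher", "b_higher" or "none"
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def test_parameter_effect(design: pd.DataFrame, values: pd.Series, factor: str,
                          level_a, level_b) -> ParameterEffect:
    """Welch t-test of a per-fermentation scalar between two factor levels.

    ``values`` is indexed by fermentation_id.  Both groups need at least two
    fermentations.  ``direction`` reports which level has the higher mean
    (``"none"`` when the means tie exactly).
    """
    if factor not in design.columns:
        raise KeyError(f"factor {factor!r} not in design")
    idx = design.set_index("fermentation_id")[factor]
    va = values[idx.index[idx == level_a]].astype(float)
    vb = values[idx.index[idx == level_b]].astype(float)
    if len(va) < 2 or len(vb) < 2:
        raise ValueError(
            f"need >=2 fermentations per level; got {len(va)} at {level_a!r} "
            f"and {len(vb)} at {level_b!r}"
        )
    if va.var() == 0 and vb.var() == 0 and va.mean() == vb.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(va, vb, equal_var=False)
    if va.mean() > vb.mean():
        direction = "a_higher"
    elif vb.mean() > va.mean():
        direction = "b_higher"
    else:
        direction = "none"
    return ParameterEffect(factor, level_a, level_b, float(t), float(p),
                           direction, len(va), len(vb))
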