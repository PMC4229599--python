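"""Two-channel probe intensities -> ORF-level log2 expression matrix.

The chain is the classic two-color workflow: per-probe MA transform
(M = log2 sample/reference, A = mean log2 intensity), per-array lowess
normalization of M against A to remove intensity-dependent dye bias,
per-array scaling (zero median, unit median absolute deviation) to make
arrays comparable, and median summarization of probe M values per ORF.
Arrays are assumed to share a common reference channel, so each array's
corrected M is directly the sample's relative log2 expression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ma_transform",
    "lowess_normalize",
    "scale_arrays",
    "summarize_probes_to_orfs",
    "preprocess_probes",
    "residual_trend_amplitude",
]

_MIN_PROBES_FOR_LOWESS = 20


def ma_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Compute M and A per probe; probes with a zero channel are flagged.

    Expects columns ``array_id, probe_id, orf_id, channel_sample,
    channel_reference``.  Raises if any array is left without a single
    unflagged probe.
    """
    if (table["channel_sample"] < 0).any() or (table["channel_reference"] < 0).any():
        raise ValueError("channel intensities must be non-negative")
    df = table.copy()
    ok = (df["channel_sample"] > 0) & (df["channel_reference"] > 0)
    df["flagged"] = ~ok
    with np.errstate(divide="ignore"):
        s = np.log2(df["channel_sample"].to_numpy(dtype=float))
        r = np.log2(df["channel_reference"].to_numpy(dtype=float))
    df["M"] = np.where(ok, s - r, np.nan)
    df["A"] = np.where(ok, 0.5 * (s + r), np.nan)
    dead = df.groupby("array_id")["flagged"].all()
    if dead.any():
        bad = list(dead.index[dead])
        raise ValueError(f"all probes flagged on array(s) {bad}")
    return df


def _fit_lowess(m: np.ndarray, a: np.ndarray, span: float, iters: int) -> np.ndarray:
    delta = 0.005 * float(np.ptp(a))
    return sm.nonparametric.lowess(
        m, a, frac=span, it=iters, delta=delta, return_sorted=False
    )


def lowess_normalize(matrix: pd.DataFrame, span: float = 0.4,
                     iters: int = 3) -> pd.DataFrame:
    """Remove the M-vs-A trend per array by locally weighted regression.

    Adds/overwrites ``M_norm = M - lowess(M ~ A)``.  ``span`` is the lowess
    fraction (default 0.4); ``iters`` robustifying reweights.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    df = matrix.copy()
    df["M_norm"] = np.nan
    for aid, grp in df.groupby("array_id", sort=False):
        sel = grp.index[~grp["flagged"]]
        if len(sel) < _MIN_PROBES_FOR_LOWESS:
            raise ValueError(
                f"array {aid!r}: need >= {_MIN_PROBES_FOR_LOWESS} unflagged probes"
            )
        a = df.loc[sel, "A"].to_numpy(dtype=float)
        m = df.loc[sel, "M"].to_numpy(dtype=float)
        if np.ptp(a) == 0:
            raise ValueError(f"array {aid!r}: degenerate A values, cannot fit trend")
        df.loc[sel, "M_norm"] = m - _fit_lowess(m, a, span, iters)
    return df


def residual_trend_amplitude(matrix: pd.DataFrame, span: float = 0.4,
                             quantiles: tuple[float, float] = (0.05, 0.95)) -> float:
    """Max |lowess fit| of the corrected M values over all arrays.

    Diagnostic for how much intensity-dependent trend is left after
    normalization, evaluated on the well-sampled part of the A axis (between
    the given quantiles; the sparse extremes of a lowess fit are unstable).
    Well-normalized arrays stay below ~0.05.
    """
    worst = 0.0
    for _, grp in matrix.groupby("array_id", sort=False):
        ok = ~grp["flagged"]
        a = grp.loc[ok, "A"].to_numpy(dtype=float)
        fit = _fit_lowess(grp.loc[ok, "M_norm"].to_numpy(dtype=float),
                          a, span, 3)
        lo, hi = np.quantile(a, quantiles)
        core = (a >= lo) & (a <= hi)
        worst = max(worst, float(np.abs(fit[core]).max()))
    return worst


def scale_arrays(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale each array's normalized M to zero median and unit MAD.

    MAD is the raw median absolute deviation (no consistency constant).
    Raises on an array with zero MAD.
    """
    df = matrix.copy()
    col = "M_norm" if "M_norm" in df.columns else "M"
    out = df[col].to_numpy(dtype=float).copy()
    for aid, grp in df.groupby("array_id", sort=False):
        sel = grp.index[~grp["flagged"]]
        vals = df.loc[sel, col].to_numpy(dtype=float)
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        if mad == 0:
            raise ValueError(f"array {aid!r}: zero MAD, cannot scale")
        out[df.index.get_indexer(sel)] = (vals - med) / mad
    df["M_norm"] = out
    df.loc[df["flagged"], "M_norm"] = np.nan
    return df


def summarize_probes_to_orfs(matrix: pd.DataFrame) -> pd.DataFrame:
    """ORF-level log2 expression: median of each ORF's probe values per array.

    ORFs lacking an unflagged probe on one or more arrays are dropped with a
    warning.  Returns a DataFrame indexed by ``orf_id`` with one column per
    ``array_id`` in order of first appearance.
    """
    if matrix.empty:
        raise ValueError("empty probe matrix")
    col = "M_norm" if "M_norm" in matrix.columns else "M"
    ok = matrix[~matrix["flagged"]]
    wide = ok.pivot_table(index="orf_id", columns="array_id", values=col,
                          aggfunc="median")
    array_order = list(dict.fromkeys(matrix["array_id"]))
    wide = wide.reindex(columns=array_order)
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} ORF(s) without probes on every array",
            stacklevel=2,
        )
        wide = wide.drop(index=incomplete)
    wide.columns.name = "fermentation_id"
    return wide


def preprocess_probes(table: pd.DataFrame, span: float = 0.4,
                      normalize: bool = True, scale: bool = True) -> pd.DataFrame:
    """Full chain: MA transform, optional lowess + scaling, ORF summarization."""
    df = ma_transform(table)
    if normalize:
        df = lowess_normalize(df, span=span)
    if scale:
        df = scale_arrays(df)
    return summarize_probes_to_orfs(df)
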