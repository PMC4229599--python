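"""Transcriptome-phenotype matching: robustness signatures by dual-time-point
p-value product.

For each gene, expression across fermentations is regressed on the robustness
phenotype at 30 and at 60 minutes of a stress (ordinary least squares; the
slope's two-sided p-value equals the Pearson-correlation p-value).  A gene
enters the stress signature when it correlates significantly at BOTH time
points (p < alpha, default 0.05) and the product of the two p-values falls
below a stringent combined cutoff (default 5e-5), with concordant slope signs
at the two time points.  The signature is ordered by ascending p-value
product (most significant first).

The null behaviour of the combined criterion is available both in closed form
and by Monte Carlo: for independent uniform p-value pairs and cutoff
c < alpha^2 the pass probability is ``c * (1 + ln(alpha^2 / c))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionCriterion",
    "SignatureSet",
    "correlate_gene",
    "correlate_matrix",
    "apply_criterion",
    "build_signature",
    "intersect_signatures",
    "summarize_signs",
    "signature_from_table",
    "null_selection_probability",
    "null_selection_probability_exact",
]


@dataclass(frozen=True)
class SelectionCriterion:
    """Per-time-point alpha and combined p-value-product cutoff (both strict)."""

    alpha: float = 0.05
    product_cutoff: float = 5e-5

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.product_cutoff <= 1:
            raise ValueError("product_cutoff must be in (0, 1]")


def correlate_gene(expr_row, robustness) -> tuple[float, float, float]:
    """OLS of one gene's expression on robustness: (slope, pearson_r, p).

    The two-sided p-value of the slope equals the Pearson-correlation
    p-value.  Requires >= 4 paired finite observations; zero variance on
    either side raises (the caller flags and excludes such genes).
    """
    x = np.asarray(robustness, dtype=float)
    y = np.asarray(expr_row, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 paired finite observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue), float(fit.pvalue)


def correlate_matrix(expr: pd.DataFrame, robustness: pd.Series) -> pd.DataFrame:
    """Vectorized :func:`correlate_gene` over every row of an expression matrix.

    ``robustness`` is indexed by fermentation id; only fermentations present
    in both and finite are used.  Returns a DataFrame (index = gene) with
    ``slope, r, p`` and NaN rows for zero-variance genes.
    """
    rob = robustness.dropna()
    cols = [c for c in expr.columns if c in rob.index]
    if len(cols) < 4:
        raise ValueError("need at least 4 fermentations with finite robustness")
    x = rob[cols].to_numpy(dtype=float)
    y = expr[cols].to_numpy(dtype=float)
    n = x.size
    if np.ptp(x) == 0:
        raise ValueError("zero variance in robustness")
    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = float(np.dot(xc, xc))
    sxy = yc @ xc
    syy = (yc ** 2).sum(axis=1)
    slope = sxy / sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, np.finfo(float).tiny))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    flat = syy == 0
    out = pd.DataFrame({"slope": slope, "r": r, "p": p}, index=expr.index)
    out.loc[flat] = np.nan
    return out


def apply_criterion(p30: float, p60: float,
                    crit: SelectionCriterion) -> tuple[bool, float]:
    """Dual-time-point selection: both p < alpha and their product < cutoff."""
    if not (0 <= p30 <= 1 and 0 <= p60 <= 1):
        raise ValueError("p-values must lie in [0, 1]")
    product = p30 * p60
    selected = (p30 < crit.alpha and p60 < crit.alpha
                and product < crit.product_cutoff)
    return selected, product


@dataclass
class SignatureSet:
    """Genes whose expression tracks robustness towards one stress."""

    stress: str
    table: pd.DataFrame  # gene_id, direction, plus per-time-point statistics

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    @property
    def directions(self) -> dict[str, str]:
        return dict(zip(self.table["gene_id"], self.table["direction"]))

    def __len__(self) -> int:
        return len(self.table)


def signature_from_table(stress: str, table: pd.DataFrame) -> SignatureSet:
    """Wrap an external gene/direction listing (e.g. a published signature)."""
    df = table.rename(columns={"locus_tag": "gene_id"})[["gene_id", "direction"]]
    return SignatureSet(stress=stress, table=df.reset_index(drop=True))


def build_signature(expr: pd.DataFrame, profile: pd.DataFrame, stress: str,
                    crit: SelectionCriterion = SelectionCriterion(),
                    times: tuple[int, int] = (30, 60)) -> SignatureSet:
    """Select the robustness signature for one stress.

    ``profile`` is the robustness table from
    :func:`robustmatch.phenotype.compute_robustness`.  Every gene is
    correlated with robustness at both time points; the dual criterion is
    applied; slope-sign-discordant genes are excluded; the result is sorted
    by ascending p-value product.
    """
    sub = profile[profile["stress"] == stress]
    per_time = {}
    for t in times:
        rob = sub[sub["time_min"] == t].set_index("fermentation_id")["robustness_log10"]
        if rob.empty:
            raise ValueError(f"no robustness values for {stress!r} at {t} min")
        per_time[t] = correlate_matrix(expr, rob)
    t30, t60 = times
    a, b = per_time[t30], per_time[t60]
    product = a["p"] * b["p"]
    concordant = np.sign(a["slope"]) == np.sign(b["slope"])
    ok = a["p"].notna() & b["p"].notna()
    selected = (ok & concordant
                & (a["p"] < crit.alpha) & (b["p"] < crit.alpha)
                & (product < crit.product_cutoff))
    tab = pd.DataFrame({
        "gene_id": expr.index,
        f"slope_{t30}": a["slope"], f"r_{t30}": a["r"], f"p_{t30}": a["p"],
        f"slope_{t60}": b["slope"], f"r_{t60}": b["r"], f"p_{t60}": b["p"],
        "product": product,
        "direction": np.where(a["slope"] > 0, "positive", "negative"),
    })
    tab = tab[selected.to_numpy()].sort_values("product").reset_index(drop=True)
    return SignatureSet(stress=stress, table=tab)


def intersect_signatures(a: SignatureSet, b: SignatureSet) -> pd.DataFrame:
    """Genes present in both signatures, with each stress's direction label."""
    da, db = a.directions, b.directions
    common = [g for g in a.gene_ids if g in db]
    return pd.DataFrame({
        "gene_id": common,
        f"direction_{a.stress}": [da[g] for g in common],
        f"direction_{b.stress}": [db[g] for g in common],
    })


def summarize_signs(sig: SignatureSet) -> tuple[int, int]:
    """(number of positively, negatively) correlating signature genes."""
    d = sig.table["direction"] if len(sig.table) else pd.Series(dtype=object)
    return int((d == "positive").sum()), int((d == "negative").sum())


def null_selection_probability_exact(crit: SelectionCriterion) -> float:
    """Closed-form pass probability for independent uniform p-value pairs.

    Area of {(x, y) in (0, alpha)^2 : xy < c}; for c < alpha^2 this is
    c (1 + ln(alpha^2 / c)), otherwise the product constraint is inactive
    and the area is alpha^2.
    """
    a, c = crit.alpha, crit.product_cutoff
    if c >= a * a:
        return a * a
    return c * (1.0 + np.log(a * a / c))


def null_selection_probability(crit: SelectionCriterion, n_pairs: int = 10 ** 6,
                               seed: int = 0) -> float:
    """Monte-Carlo pass fraction of independent uniform p-value pairs."""
    if n_pairs < 10 ** 4:
        raise ValueError("n_pairs must be at least 10^4")
    rng = np.random.default_rng(seed)
    p1 = rng.random(n_pairs)
    p2 = rng.random(n_pairs)
    passed = (p1 < crit.alpha) & (p2 < crit.alpha) & (p1 * p2 < crit.product_cutoff)
    return float(passed.mean())
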