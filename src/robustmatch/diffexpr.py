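"""Per-factor differential expression and DE-set overlap matrices.

Each fermentation factor is tested level-pair by level-pair with a per-gene
Welch t-test across fermentation groups; the DE set is everything with raw
p < 0.05 (no multiple-testing correction by default, matching the headline
convention of the study this package models; Benjamini-Hochberg is available
behind a flag).  Overlaps between DE sets are reported as shared-gene counts
(symmetric) and row-denominated percentages (asymmetric).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["DEResult", "de_by_parameter", "de_all_factors", "overlap_matrix"]


@dataclass
class DEResult:
    factor: str
    level_a: object
    level_b: object
    p_values: pd.Series          # per gene; NaN = excluded (zero variance)
    alpha: float = 0.05
    excluded: list = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.factor}:{self.level_a}|{self.level_b}"

    @property
    def de_set(self) -> set:
        p = self.p_values.dropna()
        return set(p.index[p < self.alpha])


def de_by_parameter(expr: pd.DataFrame, design: pd.DataFrame, factor: str,
                    level_a, level_b, alpha: float = 0.05,
                    fdr: bool = False) -> DEResult:
    """Welch t-test per gene between fermentations at two factor levels.

    ``expr`` is the ORF x fermentation log2 matrix; columns are matched to
    ``design.fermentation_id``.  Genes with zero variance in both groups are
    excluded (NaN p).  With ``fdr=True`` p-values are Benjamini-Hochberg
    adjusted before thresholding.
    """
    lv = design.set_index("fermentation_id")[factor]
    cols_a = [c for c in expr.columns if lv.get(c) == level_a]
    cols_b = [c for c in expr.columns if lv.get(c) == level_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"need >=2 fermentations per level for {factor!r} "
            f"({level_a!r}: {len(cols_a)}, {level_b!r}: {len(cols_b)})"
        )
    a = expr[cols_a].to_numpy(dtype=float)
    b = expr[cols_b].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    # identical constant groups: no evidence either way -> p = 1; differing
    # constant groups have no within-group variance to test against -> excluded
    same_mean = degenerate & (a.mean(axis=1) == b.mean(axis=1))
    p = np.where(same_mean, 1.0, p)
    p = np.where(degenerate & ~same_mean, np.nan, p)
    pv = pd.Series(p, index=expr.index, name="p")
    excluded = list(pv.index[pv.isna()])
    if fdr:
        ok = pv.notna()
        adj = pv.copy()
        adj[ok] = multipletests(pv[ok], method="fdr_bh")[1]
        pv = adj
    return DEResult(factor, level_a, level_b, pv, alpha=alpha, excluded=excluded)


def de_all_factors(expr: pd.DataFrame, design: pd.DataFrame,
                   factors: dict[str, tuple] | None = None,
                   alpha: float = 0.05, fdr: bool = False) -> list[DEResult]:
    """DE for every level pair of every factor (all pairs for 3-level factors)."""
    if factors is None:
        factors = {
            f: tuple(sorted(design[f].unique(), key=str))
            for f in design.columns if f != "fermentation_id"
        }
    results = []
    for factor, levels in factors.items():
        for la, lb in itertools.combinations(levels, 2):
            results.append(de_by_parameter(expr, design, factor, la, lb,
                                           alpha=alpha, fdr=fdr))
    return results


def overlap_matrix(results) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise DE-set overlaps.

    ``results`` is a list of :class:`DEResult` or a mapping label -> gene set.
    Returns ``(counts, pct)``: ``counts[a, b]`` is |A ∩ B| (diagonal = set
    size); ``pct[a, b] = 100 |A ∩ B| / |A|`` (0 for an empty row set).
    """
    if isinstance(results, dict):
        sets = {k: set(v) for k, v in results.items()}
    else:
        sets = {r.label: r.de_set for r in results}
    if len(sets) < 2:
        raise ValueError("need at least two DE sets")
    labels = list(sets)
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    pct = pd.DataFrame(0.0, index=labels, columns=labels)
    for la in labels:
        for lb in labels:
            inter = len(sets[la] & sets[lb])
            counts.loc[la, lb] = inter
            pct.loc[la, lb] = 100.0 * inter / len(sets[la]) if sets[la] else 0.0
    return counts, pct
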