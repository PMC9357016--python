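"""Tissue enrichment of cell clusters: observed/expected ratio + chi-squared.

For each (cluster, tissue) cell of the contingency table the enrichment
statistic is observed / expected with expected = row * column / N.  The
p-value comes from a two-sided chi-squared test on the collapsed 2x2 table
(cluster vs rest) x (tissue vs rest), df = 1, without continuity correction
by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from tmekit.core_io import CellAnnotation


def _chi2_2x2(a: float, b: float, c: float, d: float, correction: bool) -> float:
    """Pearson chi-squared statistic of the table [[a, b], [c, d]]."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - n / 2.0, 0.0)
    return n * diff * diff / denom


def ro_e_table(
    ann: CellAnnotation | pd.DataFrame,
    by: str = "cluster",
    within: str = "tissue",
    correction: bool = False,
    omnibus: bool = False,
) -> pd.DataFrame:
    """Observed/expected ratios with per-cell 2x2 chi-squared p-values.

    Parameters
    ----------
    ann:
        Cell annotation (or a bare data frame with the two columns).
    by, within:
        Column names of the grouping factor (clusters) and the environment
        factor (tissues).
    correction:
        Apply Yates continuity correction to the 2x2 statistic.
    omnibus:
        Report one chi-squared p per cluster (the cluster-vs-rest x all-tissue
        omnibus test) instead of per (cluster, tissue) 2x2 tests.
    """
    df = ann.df if isinstance(ann, CellAnnotation) else ann
    tab = pd.crosstab(df[by], df[within])
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need >= 2 levels in both factors")
    observed = tab.to_numpy(dtype=float)
    row = observed.sum(axis=1)
    col = observed.sum(axis=0)
    n = observed.sum()
    expected = np.outer(row, col) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        ro_e = np.where(expected > 0, observed / expected, np.nan)

    rows = []
    for i, cluster in enumerate(tab.index):
        if omnibus:
            chi2 = float(
                np.sum((observed[i] - expected[i]) ** 2 / expected[i])
                + np.sum(
                    ((col - observed[i]) - (col - expected[i])) ** 2
                    / np.where(col - expected[i] > 0, col - expected[i], np.nan)
                )
            )
            p_cluster = stats.chi2.sf(chi2, df=tab.shape[1] - 1)
        for j, tissue in enumerate(tab.columns):
            a = observed[i, j]
            b = row[i] - a
            c = col[j] - a
            d = n - a - b - c
            if omnibus:
                chi2_val, p = chi2, p_cluster
            else:
                chi2_val = _chi2_2x2(a, b, c, d, correction)
                p = float(stats.chi2.sf(chi2_val, df=1))
            rows.append(
                {
                    "cluster": cluster,
                    "tissue": tissue,
                    "observed": int(a),
                    "expected": expected[i, j],
                    "ro_e": ro_e[i, j],
                    "chi2": chi2_val,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def preference_flags(
    tab: pd.DataFrame,
    enrich_cut: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each (cluster, tissue) as enriched / depleted / neutral."""
    if enrich_cut < 1:
        raise ValueError("enrich_cut must be >= 1")
    ro_e = tab["ro_e"].to_numpy(dtype=float)
    p = tab["p"].to_numpy(dtype=float)
    flag = np.full(len(tab), "neutral", dtype=object)
    flag[(ro_e > enrich_cut) & (p < alpha)] = "enriched"
    flag[(ro_e < 1.0 / enrich_cut) & (p < alpha)] = "depleted"
    out = tab.loc[:, ["cluster", "tissue"]].copy()
    out["flag"] = flag
    return out
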