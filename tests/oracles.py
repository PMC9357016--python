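"""Independent brute-force reimplementations used as test oracles.

Everything here is deliberately written as plain loops over cells and genes,
sharing no code path with the package implementations it checks.
"""

import numpy as np
from scipy import stats


def rank_sum_p(x, y) -> float:
    """Two-sided normal-approximation rank-sum p with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma_sq <= 0:
        return 1.0
    z = (u1 - mu) / np.sqrt(sigma_sq)
    return float(2 * stats.norm.sf(abs(z)))


def marker_admissions(mat, ann, cluster, min_fc=2.0, min_pct_diff=0.20, alpha=0.01):
    """Brute-force three-criterion marker admission; returns the admitted gene set."""
    clusters = ann.df["cluster"].to_numpy()
    in_mask = clusters == cluster
    admitted = set()
    linear = 2.0 ** mat.normalized - 1.0
    for gi, gene in enumerate(mat.gene_ids):
        values = mat.normalized[gi]
        if values.max() == 0:
            continue
        p = rank_sum_p(values[in_mask], values[~in_mask])
        p_adj = min(1.0, p * mat.n_genes)
        mean_in = linear[gi, in_mask].mean()
        mean_out = linear[gi, ~in_mask].mean()
        fc = (mean_in + 1e-9) / (mean_out + 1e-9)
        pct_in = float((values[in_mask] > 0).mean())
        pct_out = float((values[~in_mask] > 0).mean())
        if p_adj < alpha and fc >= min_fc and pct_in - pct_out >= min_pct_diff:
            admitted.add(gene)
    return admitted


def ro_e_brute(by_labels, within_labels):
    """Loop-over-cells observed / expected ratios and 2x2 chi-squared stats.

    Returns dicts keyed by (by, within): observed, expected, ro_e, chi2, p.
    """
    by_labels = list(by_labels)
    within_labels = list(within_labels)
    n = len(by_labels)
    by_levels = sorted(set(by_labels))
    within_levels = sorted(set(within_labels))
    obs = {(b, w): 0 for b in by_levels for w in within_levels}
    for b, w in zip(by_labels, within_labels):
        obs[(b, w)] += 1
    row = {b: sum(obs[(b, w)] for w in within_levels) for b in by_levels}
    col = {w: sum(obs[(b, w)] for b in by_levels) for w in within_levels}
    out = {}
    for b in by_levels:
        for w in within_levels:
            expected = row[b] * col[w] / n
            a = obs[(b, w)]
            table = np.array(
                [[a, row[b] - a], [col[w] - a, n - row[b] - col[w] + a]], dtype=float
            )
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                chi2, p = 0.0, 1.0
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            out[(b, w)] = {
                "observed": a,
                "expected": expected,
                "ro_e": a / expected if expected > 0 else np.nan,
                "chi2": chi2,
                "p": p,
            }
    return out


def weighted_fc_brute(markers_q, markers_r, fc_cap=100.0):
    """Double-loop shared-marker FC product sums."""
    out = {}
    for qc in sorted(markers_q["cluster"].unique()):
        qrows = markers_q[markers_q["cluster"] == qc]
        for rc in sorted(markers_r["cluster"].unique()):
            rrows = markers_r[markers_r["cluster"] == rc]
            s = 0.0
            for _, qrow in qrows.iterrows():
                for _, rrow in rrows.iterrows():
                    if qrow["gene"] == rrow["gene"]:
                        s += min(qrow["fold_change"], fc_cap) * min(
                            rrow["fold_change"], fc_cap
                        )
            out[(qc, rc)] = s
    return out
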