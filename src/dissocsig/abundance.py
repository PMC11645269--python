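"""Compositional (differential-abundance) testing and cell-level two-group DE.

Cluster proportions are compared between groups on the arcsine-square-root
scale with a Welch two-sample t-test per cluster and BH correction across
the clusters of one comparison. The cell-level test is the two-sided
Wilcoxon rank-sum test (exact enumeration for tiny tie-free samples, a
tie- and continuity-corrected normal approximation otherwise) with
Bonferroni correction — the standard choice for before/after comparisons
such as a freezing-delay experiment.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import CellAnnotations, NormalizedMatrix


def proportions(
    ann: CellAnnotations, cluster_labels: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per (sample, cluster) cell counts and within-sample proportions.

    Every cell must carry a cluster label; clusters absent from a sample are
    recorded with proportion 0 (not missing).
    """
    labels = pd.Series(cluster_labels)
    missing = [b for b in ann.df.index if b not in labels.index or pd.isna(labels[b])]
    if missing:
        raise ValidationError(f"cell {missing[0]!r} has no cluster label")
    lab = labels.loc[ann.df.index]
    counts = (
        pd.crosstab(ann.df["sample_id"], lab)
        .stack()
        .rename("count")
        .reset_index()
        .rename(columns={lab.name or 0: "cluster"})
    )
    counts.columns = ["sample_id", "cluster", "count"]
    totals = counts.groupby("sample_id")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    group_of = ann.df.groupby("sample_id")["group"].first()
    counts.insert(1, "group", counts["sample_id"].map(group_of))
    return counts


def differential_abundance(
    pt: pd.DataFrame, group_a: str, group_b: str
) -> pd.DataFrame:
    """Welch t-test on arcsin(sqrt(proportion)) per cluster, BH across clusters.

    Returns per-cluster mean proportions, the transformed-scale difference
    (B minus A), t statistic, p and BH-adjusted fdr. Requires >= 2 samples
    per group.
    """
    for g in (group_a, group_b):
        n = pt.loc[pt["group"] == g, "sample_id"].nunique()
        if n < 2:
            raise ValidationError(f"group {g!r} has {n} samples; need >= 2")
    rows = []
    for cluster, sub in pt.groupby("cluster", sort=True):
        pa = sub.loc[sub["group"] == group_a, "proportion"].to_numpy()
        pb = sub.loc[sub["group"] == group_b, "proportion"].to_numpy()
        ya = np.arcsin(np.sqrt(pa))
        yb = np.arcsin(np.sqrt(pb))
        if np.ptp(ya) == 0 and np.ptp(yb) == 0:
            t, p = (0.0, 1.0) if np.allclose(ya.mean(), yb.mean()) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(yb, ya, equal_var=False)
        rows.append(
            {
                "cluster": cluster,
                "mean_prop_a": pa.mean(),
                "mean_prop_b": pb.mean(),
                "diff_transformed": yb.mean() - ya.mean(),
                "t": float(t),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def _ranksum_normal(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p via normal approximation, tie and continuity corrected."""
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    ra = ranks[:na].sum()
    u = ra - na * (na + 1) / 2.0
    mean_u = na * nb / 2.0
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var_u = na * nb / 12.0 * (n + 1 - tie_term)
    if var_u == 0:
        return 1.0
    z = (abs(u - mean_u) - 0.5) / np.sqrt(var_u)
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def two_group_cell_de(
    norm: NormalizedMatrix,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two disjoint cell sets.

    Exact enumeration is used when ``n_a + n_b <= 10`` and the gene has no
    tied values; otherwise the tie-corrected normal approximation with
    continuity correction. The fold-change is
    ``log2((mean(expm1 a) + 1) / (mean(expm1 b) + 1))`` and the adjusted
    p-value is Bonferroni over all tested genes.
    """
    set_a, set_b = set(cells_a), set(cells_b)
    if not set_a or not set_b:
        raise ValidationError("both cell sets must be non-empty")
    overlap = set_a & set_b
    if overlap:
        raise ValidationError(f"cell sets overlap (e.g. {sorted(overlap)[0]!r})")
    pos = {b: i for i, b in enumerate(norm.barcodes)}
    try:
        ia = np.array([pos[c] for c in cells_a])
        ib = np.array([pos[c] for c in cells_b])
    except KeyError as exc:
        raise ValidationError(f"cell {exc.args[0]!r} not in matrix") from exc

    dense = norm.values.toarray()
    A = dense[:, ia]
    B = dense[:, ib]
    na, nb = ia.size, ib.size

    pvals = np.empty(norm.n_genes)
    exact_ok = na + nb <= 10
    for gi in range(norm.n_genes):
        a, b = A[gi], B[gi]
        if exact_ok and np.unique(np.concatenate([a, b])).size == na + nb:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            pvals[gi] = res.pvalue
        else:
            pvals[gi] = _ranksum_normal(a, b)

    log2fc = np.log2((np.expm1(A).mean(axis=1) + 1.0) / (np.expm1(B).mean(axis=1) + 1.0))
    G = norm.n_genes
    return pd.DataFrame(
        {
            "gene": norm.genes,
            "log2fc": log2fc,
            "p": pvals,
            "p_adj": np.minimum(1.0, pvals * G),
            "n_a": na,
            "n_b": nb,
        }
    )
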