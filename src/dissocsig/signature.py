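"""Pseudobulk aggregation, NB Wald differential expression, and the
consensus-intersection signature rule.

Each biological replicate is collapsed to one pseudobulk profile by summing
UMIs over its cells (optionally restricted to a cell-class subset), so DE is
performed at the sample level with genuine biological replication. The test
is a deliberately simple negative-binomial Wald test: median-of-ratios size
factors, a method-of-moments residual dispersion estimate, a delta-method
standard error on the log2 fold-change, and Benjamini-Hochberg adjustment.
It makes no claim of numerical equivalence to shrinkage-based bulk DE tools;
its type-I calibration and power are established by simulation in the test
suite.

The consensus signature is the set of genes significant in the same
direction in *every* pairwise comparison supplied, mirroring designs where
one treated group is contrasted against several control groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import CellAnnotations, CountMatrix, GeneList

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


@dataclass
class PseudobulkMatrix:
    """Per-sample summed UMI counts (n_samples x n_genes, int64)."""

    samples: list[str]
    groups: list[str]
    genes: list[str]
    sums: np.ndarray

    def __post_init__(self) -> None:
        self.sums = np.asarray(self.sums, dtype=np.int64)
        if self.sums.shape != (len(self.samples), len(self.genes)):
            raise ValidationError(
                f"pseudobulk shape {self.sums.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )
        if len(self.groups) != len(self.samples):
            raise ValidationError("one group label per sample required")
        if np.any(self.sums < 0):
            raise ValidationError("pseudobulk sums must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.sums, index=self.samples, columns=self.genes)
        df.insert(0, "group", self.groups)
        df.index.name = "sample_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PseudobulkMatrix":
        groups = df["group"].tolist()
        genes = [c for c in df.columns if c != "group"]
        return cls(list(df.index), groups, genes, df[genes].to_numpy())

    def subset_samples(self, idx: Sequence[int]) -> "PseudobulkMatrix":
        return PseudobulkMatrix(
            [self.samples[i] for i in idx],
            [self.groups[i] for i in idx],
            list(self.genes),
            self.sums[list(idx), :],
        )


@dataclass
class DEThresholds:
    """Significance gates for calling a gene differentially expressed.

    Defaults: adjusted p <= 0.05 and |log2 fold-change| >= 0.58
    (a 1.5-fold change). Boundary comparisons are inclusive.
    """

    padj_max: float = 0.05
    abs_log2fc_min: float = 0.58

    def __post_init__(self) -> None:
        if not 0.0 < self.padj_max < 1.0:
            raise ValidationError("padj_max must be in (0, 1)")
        if self.abs_log2fc_min < 0:
            raise ValidationError("abs_log2fc_min must be >= 0")


def aggregate_pseudobulk(
    m: CountMatrix,
    ann: CellAnnotations,
    class_filter: Iterable[str] | str | None = None,
) -> PseudobulkMatrix:
    """Sum UMIs per sample, optionally over one or more cell classes.

    Samples are ordered lexicographically. A sample left with zero
    contributing cells is an error naming that sample.
    """
    sub = ann.subset(m.barcodes).df
    if class_filter is not None:
        if isinstance(class_filter, str):
            class_filter = {class_filter}
        class_filter = set(class_filter)
        if "cell_class" not in sub.columns:
            raise ValidationError("class_filter given but annotations lack 'cell_class'")
        mask = sub["cell_class"].isin(class_filter).to_numpy()
    else:
        mask = np.ones(len(sub), dtype=bool)

    samples = sorted(sub["sample_id"].unique())
    group_of = sub.groupby("sample_id")["group"].first()
    sample_pos = {s: i for i, s in enumerate(samples)}
    kept = np.flatnonzero(mask)
    contributing = set(sub["sample_id"].to_numpy()[kept])
    for s in samples:
        if s not in contributing:
            raise ValidationError(f"sample {s!r} has no contributing cells")

    rows = np.array([sample_pos[s] for s in sub["sample_id"].to_numpy()[kept]])
    indicator = sp.csr_matrix(
        (np.ones(kept.size), (rows, kept)), shape=(len(samples), m.n_cells)
    )
    sums = np.asarray((indicator @ m.counts.T.tocsc()).todense(), dtype=np.int64)
    return PseudobulkMatrix(samples, [group_of[s] for s in samples], list(m.genes), sums)


def size_factors(pb: PseudobulkMatrix) -> np.ndarray:
    """Median-of-ratios sample normalisation factors, geometric mean 1.

    For each gene expressed in all samples, the ratio of its count to its
    across-sample geometric mean is formed; a sample's factor is the median
    ratio. Requires at least one gene expressed in every sample.
    """
    s = pb.sums.astype(float)
    expressed = (s > 0).all(axis=0)
    if not expressed.any():
        raise ValidationError("no gene is expressed in all samples")
    sub = s[:, expressed]
    geomean = np.exp(np.mean(np.log(sub), axis=0))
    factors = np.median(sub / geomean, axis=1)
    return factors / np.exp(np.mean(np.log(factors)))


def nb_wald_de(
    pb: PseudobulkMatrix, group_a: str, group_b: str
) -> pd.DataFrame:
    """NB Wald test of group_b vs group_a on pseudobulk counts.

    Genes are tested if nonzero in at least one sample of each group.
    Returns a per-gene table with base_mean, log2fc (B over A), se, wald_z,
    two-sided normal p, and BH-adjusted padj. Requires >= 2 samples per
    group.
    """
    groups = np.array(pb.groups)
    ia = np.flatnonzero(groups == group_a)
    ib = np.flatnonzero(groups == group_b)
    for name, idx in ((group_a, ia), (group_b, ib)):
        if idx.size < 2:
            raise ValidationError(f"group {name!r} has {idx.size} samples; need >= 2")

    sub = pb.subset_samples(list(ia) + list(ib))
    sf = size_factors(sub)
    y = sub.sums / sf[:, None]
    na, nb = ia.size, ib.size
    ya, yb = y[:na], y[na:]

    tested = (sub.sums[:na] > 0).any(axis=0) & (sub.sums[na:] > 0).any(axis=0)
    if not tested.any():
        raise ValidationError("no gene is expressed in both groups")

    mu_a = ya.mean(axis=0)
    mu_b = yb.mean(axis=0)
    base_mean = y.mean(axis=0)

    pos = y[:, tested]
    eps = 0.5 * pos[pos > 0].min()

    # residual method-of-moments dispersion: per-group df correction plus an
    # overall n/(n-2) small-sample factor, which keeps the Wald test's
    # type-I error near nominal at 3-4 samples per group (see test suite)
    ss_a = ((ya - mu_a) ** 2).sum(axis=0) * (na / (na - 1))
    ss_b = ((yb - mu_b) ** 2).sum(axis=0) * (nb / (nb - 1))
    n_tot = na + nb
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (n_tot / (n_tot - 2)) * (ss_a + ss_b - (na * mu_a + nb * mu_b))
        den = na * mu_a**2 + nb * mu_b**2
        alpha = np.clip(num / den, DISPERSION_FLOOR, None)

        log2fc = np.log2((mu_b + eps) / (mu_a + eps))
        se = np.sqrt(
            (1.0 / LN2**2)
            * ((1.0 / na) * (1.0 / mu_a + alpha) + (1.0 / nb) * (1.0 / mu_b + alpha))
        )
        z = np.where(log2fc == 0.0, 0.0, log2fc / se)
    p = 2.0 * stats.norm.sf(np.abs(z))

    table = pd.DataFrame(
        {
            "gene": pb.genes,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_z": z,
            "p": p,
        }
    )[tested].reset_index(drop=True)
    table["padj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table


def significant_genes(
    table: pd.DataFrame, thresholds: DEThresholds, direction: str = "up"
) -> pd.DataFrame:
    """Rows passing the significance gates in the given direction."""
    if direction == "up":
        fc_ok = table["log2fc"] >= thresholds.abs_log2fc_min
    elif direction == "down":
        fc_ok = table["log2fc"] <= -thresholds.abs_log2fc_min
    elif direction == "both":
        fc_ok = table["log2fc"].abs() >= thresholds.abs_log2fc_min
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    return table[(table["padj"] <= thresholds.padj_max) & fc_ok]


def consensus_signature(
    tables: Sequence[pd.DataFrame],
    thresholds: DEThresholds | None = None,
    direction: str = "up",
    name: str = "consensus",
    species: str = "mouse",
) -> GeneList | None:
    """Genes significant in the same direction in every DE table.

    Ordered by mean log2 fold-change (descending for "up"), ties broken by
    symbol. Returns None (with a warning) when the intersection is empty.
    """
    if thresholds is None:
        thresholds = DEThresholds()
    tables = list(tables)
    if not tables:
        raise ValidationError("consensus requires at least one DE table")
    sets = [set(significant_genes(t, thresholds, direction)["gene"]) for t in tables]
    common = set.intersection(*sets)
    if not common:
        warnings.warn("consensus signature is empty", stacklevel=2)
        return None
    mean_fc = (
        pd.concat([t.set_index("gene")["log2fc"] for t in tables], axis=1)
        .loc[sorted(common)]
        .mean(axis=1)
    )
    ascending = direction == "down"
    ordered = mean_fc.sort_values(ascending=ascending, kind="stable")
    return GeneList(name=name, species=species, symbols=list(ordered.index))
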