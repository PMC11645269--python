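"""Permutation-null calibration of the module-score enrichment threshold,
per-sample enrichment fractions, factor-gene selection, and sample-level
metadata correlation.

The procedure: build the gene universe (intersection across datasets),
downsample each dataset so all major cell classes have equal cell numbers,
score many random gene lists of the same length as the signature of
interest, compute each list's outlier threshold — median score across all
cells plus three (unscaled) median absolute deviations — and set the
enrichment cutoff at the top tail (default 2.5%) of those thresholds, taken
as an order statistic. A cell is "enriched" when its signature score is
strictly above the cutoff; enrichment is summarised per sample as the
fraction of cells of a class above the cutoff and can then be correlated
against sample covariates (PMI, age, ...) by Spearman rank correlation.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import CellAnnotations, CountMatrix, GeneList, NormalizedMatrix
from .scoring import ModuleScorer, ScoreVector


@dataclass
class CalibrationResult:
    """Null threshold distribution and the derived enrichment cutoff."""

    n_lists: int
    list_length: int
    thresholds: np.ndarray
    cutoff: float
    tail: float
    seed: int
    universe_fingerprint: str

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.size != self.n_lists:
            raise ValidationError("one threshold per random list required")

    def to_jsonable(self) -> dict:
        return {
            "n_lists": self.n_lists,
            "list_length": self.list_length,
            "thresholds": self.thresholds.tolist(),
            "cutoff": self.cutoff,
            "tail": self.tail,
            "seed": self.seed,
            "universe_fingerprint": self.universe_fingerprint,
        }


@dataclass
class FactorLoadings:
    """Non-negative per-gene loadings of one factorisation component."""

    factor_name: str
    loadings: pd.Series  # index: gene symbol

    def __post_init__(self) -> None:
        if self.loadings.index.duplicated().any():
            raise ValidationError("duplicate gene symbol in factor loadings")
        if (self.loadings < 0).any():
            raise ValidationError("factor loadings must be non-negative")


def universe_fingerprint(genes: Sequence[str]) -> str:
    """Short stable hash of an ordered gene universe."""
    h = hashlib.sha256("\n".join(genes).encode())
    return h.hexdigest()[:16]


def intersect_universe(
    matrices: Sequence[CountMatrix | NormalizedMatrix],
) -> list[str]:
    """Genes present in every matrix, in the first matrix's order."""
    if not matrices:
        raise ValidationError("need at least one matrix")
    common = set(matrices[0].genes)
    for m in matrices[1:]:
        common &= set(m.genes)
    if not common:
        raise ValidationError("gene universes have an empty intersection")
    return [g for g in matrices[0].genes if g in common]


def downsample_equal_classes(
    m: CountMatrix | NormalizedMatrix, ann: CellAnnotations, seed: int
) -> tuple[CountMatrix | NormalizedMatrix, CellAnnotations]:
    """Subsample cells so every cell class has the minimum class size.

    Sampling is seeded and without replacement; kept cells retain their
    original values and relative order.
    """
    sub = ann.subset(m.barcodes).df
    if "cell_class" not in sub.columns:
        raise ValidationError("downsampling requires a 'cell_class' column")
    classes = sub["cell_class"].to_numpy()
    sizes = pd.Series(classes).value_counts()
    target = int(sizes.min())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in sorted(sizes.index):
        idx = np.flatnonzero(classes == c)
        keep.append(rng.choice(idx, target, replace=False) if idx.size > target else idx)
    keep_idx = np.sort(np.concatenate(keep))
    m2 = m.subset_cells(keep_idx)
    return m2, ann.subset(m2.barcodes)


def random_gene_lists(
    universe: Sequence[str], list_length: int, n_lists: int = 1000, seed: int = 0
) -> list[GeneList]:
    """Seeded random gene lists sampled without replacement from the universe."""
    universe = list(universe)
    if list_length > len(universe):
        raise ValidationError(
            f"list_length {list_length} exceeds universe size {len(universe)}"
        )
    rng = np.random.default_rng(seed)
    arr = np.array(universe)
    return [
        GeneList(
            name=f"random_{i:04d}",
            species="none",
            symbols=list(rng.choice(arr, list_length, replace=False)),
        )
        for i in range(n_lists)
    ]


def mad_outlier_threshold(
    scores: np.ndarray | pd.Series, n_mads: float = 3.0, mad_scale: float = 1.0
) -> float:
    """median(scores) + n_mads * MAD, with the raw (unscaled) MAD by default.

    ``mad_scale`` exposes the 1.4826 normal-consistency constant for
    sensitivity analyses; the default keeps the literal median-absolute-
    deviation definition.
    """
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot compute an outlier threshold of no scores")
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * mad_scale
    return float(med + n_mads * mad)


def calibrate_cutoff(thresholds: np.ndarray | Sequence[float], tail: float = 0.025) -> float:
    """Order-statistic cutoff at the top ``tail`` of the null thresholds.

    The cutoff is the (n - floor(tail*n))-th smallest threshold, so exactly
    floor(tail*n) thresholds lie strictly above it when values are distinct.
    """
    x = np.sort(np.asarray(thresholds, dtype=float))
    if not 0.0 < tail < 1.0:
        raise ValidationError("tail must be in (0, 1)")
    if x.size < 1.0 / tail:
        raise ValidationError(
            f"need at least {math.ceil(1 / tail)} thresholds for tail={tail}"
        )
    k = math.floor(tail * x.size)
    return float(x[x.size - k - 1])


def null_thresholds(
    scorer: ModuleScorer,
    universe: Sequence[str],
    list_length: int,
    n_lists: int,
    list_seed: int,
    score_seed: int,
    n_mads: float = 3.0,
    mad_scale: float = 1.0,
) -> np.ndarray:
    """Outlier thresholds of ``n_lists`` random gene-list scores."""
    lists = random_gene_lists(universe, list_length, n_lists, seed=list_seed)
    scores = scorer.score_lists(lists, seed=score_seed)
    med = np.median(scores, axis=1)
    mad = np.median(np.abs(scores - med[:, None]), axis=1) * mad_scale
    return med + n_mads * mad


def run_calibration(
    norm: NormalizedMatrix,
    ann: CellAnnotations,
    list_length: int,
    universe: Sequence[str] | None = None,
    n_lists: int = 1000,
    tail: float = 0.025,
    seed: int = 0,
    n_bins: int = 25,
    ctrl_per_gene: int = 100,
    n_mads: float = 3.0,
    mad_scale: float = 1.0,
    downsample: bool = True,
) -> CalibrationResult:
    """Full calibration on one dataset.

    One seed stream (split deterministically from ``seed``) governs class
    downsampling, random-list sampling, and control-gene draws.
    """
    ds_seed, list_seed, score_seed = derive_seeds(seed, 3)
    if universe is None:
        universe = list(norm.genes)
    if downsample:
        norm, ann = downsample_equal_classes(norm, ann, seed=ds_seed)
    scorer = ModuleScorer(norm, n_bins=n_bins, ctrl_per_gene=ctrl_per_gene)
    thresholds = null_thresholds(
        scorer, universe, list_length, n_lists, list_seed, score_seed,
        n_mads=n_mads, mad_scale=mad_scale,
    )
    return CalibrationResult(
        n_lists=n_lists,
        list_length=list_length,
        thresholds=thresholds,
        cutoff=calibrate_cutoff(thresholds, tail),
        tail=tail,
        seed=seed,
        universe_fingerprint=universe_fingerprint(universe),
    )


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) from one parent seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def enrichment_fractions(
    score: ScoreVector,
    ann: CellAnnotations,
    cutoff: float,
    class_filter: str | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample fraction of cells (of a class) scoring strictly above cutoff.

    Samples with no cells of the class get ``n_cells = 0`` and a missing
    fraction. Group labels and per-sample covariates are carried through.
    """
    df = ann.df
    if class_filter is not None:
        if isinstance(class_filter, str):
            class_filter = {class_filter}
        if "cell_class" not in df.columns:
            raise ValidationError("class_filter given but annotations lack 'cell_class'")
        cells = df.index[df["cell_class"].isin(set(class_filter))]
    else:
        cells = df.index
    missing = cells.difference(score.scores.index)
    if len(missing):
        raise ValidationError(
            f"scores missing for {len(missing)} cells (e.g. {missing[0]!r})"
        )
    above = score.scores.loc[cells] > cutoff
    per_sample = (
        pd.DataFrame({"sample_id": df.loc[cells, "sample_id"], "above": above.to_numpy()})
        .groupby("sample_id")
        .agg(n_cells=("above", "size"), n_above=("above", "sum"))
    )
    table = ann.sample_table().join(per_sample, how="left")
    table[["n_cells", "n_above"]] = (
        table[["n_cells", "n_above"]].fillna(0).astype(int)
    )
    with np.errstate(invalid="ignore"):
        table["fraction"] = np.where(
            table["n_cells"] > 0, table["n_above"] / table["n_cells"], np.nan
        )
    return table.reset_index()


def read_factor_loadings(path, factor_name: str | None = None) -> FactorLoadings:
    """Two-column TSV (gene, loading) -> :class:`FactorLoadings`."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (gene, loading)")
    gene_col, load_col = df.columns[:2]
    s = pd.Series(df[load_col].to_numpy(dtype=float), index=df[gene_col].astype(str))
    return FactorLoadings(factor_name or str(load_col), s)


def select_factor_genes(fl: FactorLoadings, threshold: float) -> GeneList | None:
    """Genes loading strictly above threshold, descending, ties by symbol."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    sel = fl.loadings[fl.loadings > threshold]
    if sel.empty:
        warnings.warn(
            f"no gene exceeds loading threshold {threshold} for factor "
            f"{fl.factor_name!r}",
            stacklevel=2,
        )
        return None
    ordered = sel.sort_index(kind="stable").sort_values(
        ascending=False, kind="stable"
    )
    return GeneList(name=fl.factor_name, species="human", symbols=list(ordered.index))


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    n: int


def correlate_metadata(et: pd.DataFrame, covariate: str) -> SpearmanResult:
    """Spearman correlation of per-sample enrichment fraction vs a covariate.

    Average ranks, t-approximation p-value; rows with missing fraction or
    covariate are excluded and the usable n reported. Fewer than 3 usable
    samples, or a constant input, is an error.
    """
    if covariate not in et.columns:
        raise ValidationError(f"covariate {covariate!r} not in enrichment table")
    sub = et[["fraction", covariate]].dropna()
    n = len(sub)
    if n < 3:
        raise ValidationError(f"need >= 3 usable samples, got {n}")
    x = sub[covariate].to_numpy(dtype=float)
    y = sub["fraction"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Spearman rho undefined: constant input")
    res = stats.spearmanr(x, y)
    return SpearmanResult(float(res.statistic), float(res.pvalue), n)
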