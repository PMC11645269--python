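"""Synthetic UMI count matrices with a spiked activation program.

The generator emulates the structure of a multi-replicate dissociation
experiment: several biological replicates per protocol group, a few cell
classes of unequal abundance, negative-binomially distributed counts with
gene-specific means, lognormal per-cell library factors, a mitochondrial
gene subset for QC, and an "activation program" — a small set of
IEG/stress-like genes multiplicatively upregulated (``2**effect`` on the NB
mean) in a configurable fraction of cells of designated classes in
designated groups. Every run is fully determined by the config seed, and
the returned :class:`SimTruth` carries the ground truth (which cells were
activated, which genes carry which log2 effect) for downstream recovery
tests.

Classes differ in abundance and activation eligibility only, not in
baseline expression profile; see the methods note for what this does and
does not exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError
from .io import CellAnnotations, CountMatrix

# IEG / heat-shock / chemokine-like symbols used for the default program so
# simulated signatures read like real dissociation signatures.
DEFAULT_PROGRAM_SYMBOLS = (
    "Fos", "Jun", "Junb", "Jund", "Fosb", "Egr1", "Atf3", "Ier2", "Ier3",
    "Btg2", "Dusp1", "Klf2", "Klf4", "Socs3", "Ccl3", "Ccl4", "Nfkbia",
    "Zfp36", "Rhob", "Hspa1a", "Hspa1b", "Hsp90aa1", "Dnajb1", "Nr4a1", "Ubc",
)

DEFAULT_CLASS_PROPORTIONS = {"myeloid": 0.25, "astrocyte": 0.35, "neuron": 0.40}
DEFAULT_GROUPS = ("ENZ-NONE", "ENZ-INHIB", "DNC-NONE", "DNC-INHIB")


@dataclass
class SimConfig:
    """Configuration of one simulated dataset.

    ``activated_fraction`` maps ``(group, class)`` to the fraction of those
    cells carrying the activation program; strata not listed get 0.
    Dispersion is the NB alpha in ``Var = mu + alpha * mu**2`` (scalar or
    per gene).
    """

    seed: int
    n_genes: int = 3000
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    groups: Sequence[str] = DEFAULT_GROUPS
    samples_per_group: int = 4
    cells_per_sample: int = 1000
    base_mean_log_mu: float = 0.0
    base_mean_log_sd: float = 1.5
    dispersion: float | Sequence[float] = 0.3
    libsize_factor_sd: float = 0.35
    program_size: int = 25
    program_log2_effect: float | Sequence[float] = 1.5
    program_symbols: Sequence[str] | None = None
    program_base_mean_log_mu: float = 1.0
    program_base_mean_log_sd: float = 0.5
    activated_fraction: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("ENZ-NONE", "myeloid"): 0.85}
    )
    mito_fraction_of_genes: float = 0.02
    mito_mean_scale: float = 3.0
    species: str = "mouse"
    emit_covariates: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed is required and must be an integer")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions sum to {total}, expected 1")
        for (g, c), f in self.activated_fraction.items():
            if g not in self.groups:
                raise ConfigError(f"activated_fraction references unknown group {g!r}")
            if c not in self.class_proportions:
                raise ConfigError(f"activated_fraction references unknown class {c!r}")
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"activated fraction {f} for {(g, c)} outside [0, 1]")
        effects = np.atleast_1d(np.asarray(self.program_log2_effect, dtype=float))
        if not np.all(np.isfinite(effects)):
            raise ConfigError("program effect sizes must be finite")
        if effects.size not in (1, self.program_size):
            raise ConfigError(
                "program_log2_effect must be a scalar or one value per program gene"
            )
        if self.program_symbols is not None and len(self.program_symbols) != self.program_size:
            raise ConfigError("program_symbols length must equal program_size")
        n_mito = self.n_mito_genes
        if n_mito + self.program_size > self.n_genes:
            raise ConfigError("n_genes too small for mito + program genes")
        alpha = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if alpha.size not in (1, self.n_genes) or np.any(alpha < 0):
            raise ConfigError("dispersion must be a non-negative scalar or per-gene vector")
        if not 0.0 <= self.mito_fraction_of_genes < 1.0:
            raise ConfigError("mito_fraction_of_genes must be in [0, 1)")

    @property
    def n_mito_genes(self) -> int:
        return int(round(self.mito_fraction_of_genes * self.n_genes))

    @property
    def mito_prefix(self) -> str:
        return "mt-" if self.species == "mouse" else "MT-"


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    activated_barcodes: frozenset[str]
    program_genes: dict[str, float]  # symbol -> true log2 effect
    base_means: np.ndarray  # per-gene NB mean at library factor 1, unactivated
    per_cell_class: dict[str, str]

    def to_jsonable(self) -> dict:
        return {
            "activated_barcodes": sorted(self.activated_barcodes),
            "program_genes": self.program_genes,
            "base_means": self.base_means.tolist(),
            "per_cell_class": self.per_cell_class,
        }


def _largest_remainder_counts(proportions: Sequence[float], n: int) -> np.ndarray:
    """Integer class counts summing to n, proportional with largest-remainder ties."""
    props = np.asarray(proportions, dtype=float)
    raw = props * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _gene_names(cfg: SimConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Returns (names, mito index array, program index array)."""
    n_mito = cfg.n_mito_genes
    mito_idx = np.arange(n_mito)
    program_idx = np.arange(n_mito, n_mito + cfg.program_size)
    if cfg.program_symbols is not None:
        prog_names = list(cfg.program_symbols)
    else:
        prog_names = [
            DEFAULT_PROGRAM_SYMBOLS[i]
            if i < len(DEFAULT_PROGRAM_SYMBOLS)
            else f"Prog{i:03d}"
            for i in range(cfg.program_size)
        ]
    names = [f"{cfg.mito_prefix}Gene{i:04d}" for i in range(n_mito)]
    names += prog_names
    names += [f"Gene{i:05d}" for i in range(cfg.n_genes - n_mito - cfg.program_size)]
    return names, mito_idx, program_idx


def simulate_dataset(cfg: SimConfig) -> tuple[CountMatrix, CellAnnotations, SimTruth]:
    """Draw one dataset; deterministic given ``cfg.seed``.

    Counts are NB with mean ``mu_g * ell_c * 2**(e_g * activated)`` and
    dispersion alpha (gamma-Poisson mixture; alpha 0 degrades to Poisson).
    Activated cells are the first ``floor(fraction * n)`` cells of each
    (group, class) stratum after a seeded shuffle, so realised fractions are
    exact up to rounding.
    """
    rng = np.random.default_rng(cfg.seed)
    names, mito_idx, program_idx = _gene_names(cfg)

    mu = rng.lognormal(cfg.base_mean_log_mu, cfg.base_mean_log_sd, cfg.n_genes)
    mu[mito_idx] *= cfg.mito_mean_scale
    mu[program_idx] = rng.lognormal(
        cfg.program_base_mean_log_mu, cfg.program_base_mean_log_sd, cfg.program_size
    )
    effects = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.program_log2_effect, dtype=float)),
        (cfg.program_size,),
    ).copy()
    alpha = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.dispersion, dtype=float)), (cfg.n_genes,)
    ).copy()

    class_names = list(cfg.class_proportions)
    class_counts = _largest_remainder_counts(
        [cfg.class_proportions[c] for c in class_names], cfg.cells_per_sample
    )

    sample_ids: list[str] = []
    sample_group: dict[str, str] = {}
    barcodes: list[str] = []
    cell_sample: list[str] = []
    cell_group: list[str] = []
    cell_class: list[str] = []
    for g in cfg.groups:
        for k in range(1, cfg.samples_per_group + 1):
            sid = f"{g}_s{k}"
            sample_ids.append(sid)
            sample_group[sid] = g
            labels = np.repeat(class_names, class_counts)
            for j, lab in enumerate(labels):
                barcodes.append(f"{sid}_c{j:04d}")
                cell_sample.append(sid)
                cell_group.append(g)
                cell_class.append(lab)
    n_cells = len(barcodes)
    cell_group_arr = np.array(cell_group)
    cell_class_arr = np.array(cell_class)

    ell = rng.lognormal(0.0, cfg.libsize_factor_sd, n_cells)

    activated = np.zeros(n_cells, dtype=bool)
    for (g, c) in sorted(cfg.activated_fraction):
        frac = cfg.activated_fraction[(g, c)]
        stratum = np.flatnonzero((cell_group_arr == g) & (cell_class_arr == c))
        if stratum.size == 0:
            continue
        perm = rng.permutation(stratum)
        activated[perm[: math.floor(frac * stratum.size)]] = True

    # per-sample chunks keep peak memory bounded
    poisson_like = alpha < 1e-12
    chunks: list[sp.csr_matrix] = []
    start = 0
    for sid in sample_ids:
        stop = start + cfg.cells_per_sample
        cols = slice(start, stop)
        mean = mu[:, None] * ell[None, cols]
        act_cols = activated[cols]
        if act_cols.any():
            mean[np.ix_(program_idx, np.flatnonzero(act_cols))] *= (
                2.0 ** effects[:, None]
            )
        lam = np.empty_like(mean)
        nbrows = ~poisson_like
        if nbrows.any():
            a = alpha[nbrows][:, None]
            lam[nbrows] = rng.gamma(shape=1.0 / a, scale=mean[nbrows] * a)
        if poisson_like.any():
            lam[poisson_like] = mean[poisson_like]
        chunk = rng.poisson(lam)
        chunks.append(sp.csr_matrix(chunk))
        start = stop
    counts = sp.hstack(chunks, format="csr")

    ann_df = pd.DataFrame(
        {
            "barcode": barcodes,
            "sample_id": cell_sample,
            "group": cell_group,
            "cell_class": cell_class,
        }
    )
    if cfg.emit_covariates:
        pmi = dict(zip(sample_ids, np.round(rng.uniform(4.0, 48.0, len(sample_ids)), 1)))
        age = dict(zip(sample_ids, rng.integers(45, 95, len(sample_ids))))
        ann_df["PMI"] = ann_df["sample_id"].map(pmi)
        ann_df["age"] = ann_df["sample_id"].map(age).astype(float)

    m = CountMatrix(names, barcodes, counts)
    ann = CellAnnotations(ann_df)
    truth = SimTruth(
        activated_barcodes=frozenset(np.array(barcodes)[activated]),
        program_genes={names[i]: float(e) for i, e in zip(program_idx, effects)},
        base_means=mu,
        per_cell_class=dict(zip(barcodes, cell_class)),
    )
    return m, ann, truth


def spike_report(truth: SimTruth, ann: CellAnnotations) -> pd.DataFrame:
    """Realised activated fraction per (group, cell class) stratum."""
    df = ann.df
    act = df.index.isin(truth.activated_barcodes)
    out = (
        pd.DataFrame(
            {
                "group": df["group"].to_numpy(),
                "cell_class": df["cell_class"].to_numpy(),
                "activated": act,
            }
        )
        .groupby(["group", "cell_class"], sort=True)
        .agg(n_cells=("activated", "size"), n_activated=("activated", "sum"))
        .reset_index()
    )
    out["fraction"] = out["n_activated"] / out["n_cells"]
    return out
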