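"""Gene-module scoring with expression-bin-matched control genes, and
cross-species signature transfer.

A cell's module score is the mean log-normalised expression of the signature
genes minus the mean expression of a pool of control genes drawn from the
same average-expression bins as the signature genes (the binned-control
scheme popularised by single-cell toolkits). For a random gene set the score
is therefore ~0 in expectation, which is what makes permutation-null
calibration of enrichment thresholds possible downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GeneList, NormalizedMatrix


@dataclass
class ScoreVector:
    """Per-cell scores for one signature, with the resolved gene list."""

    signature_name: str
    scores: pd.Series  # index: barcode
    resolved_genes: list[str]
    dropped_genes: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValidationError("module scores must be finite")


@dataclass
class OrthologResult:
    genes: GeneList
    dropped: list[str]


def map_orthologs(
    gl: GeneList,
    target_species: str,
    target_universe: Sequence[str],
    mapping_table: dict[str, str] | None = None,
) -> OrthologResult:
    """Transfer a signature between mouse and human symbol conventions.

    Without a mapping table, mouse->human upper-cases symbols and
    human->mouse title-cases them (a documented heuristic; supply
    ``mapping_table`` for curated orthologs). The result is intersected with
    ``target_universe``; symbols lost at either step are recorded. An empty
    result is an error.
    """
    universe = set(target_universe)
    mapped: list[str] = []
    dropped: list[str] = []
    seen: set[str] = set()
    for s in gl.symbols:
        if mapping_table is not None:
            t = mapping_table.get(s)
        elif gl.species == target_species:
            t = s
        elif gl.species == "mouse" and target_species == "human":
            t = s.upper()
        elif gl.species == "human" and target_species == "mouse":
            t = s.capitalize()
        else:
            raise ValidationError(
                f"no default mapping {gl.species!r} -> {target_species!r}; "
                "provide mapping_table"
            )
        if t is None or t not in universe or t in seen:
            dropped.append(s)
            continue
        mapped.append(t)
        seen.add(t)
    if not mapped:
        raise ValidationError(
            f"signature {gl.name!r}: no symbol mapped into the target universe"
        )
    return OrthologResult(
        genes=GeneList(name=gl.name, species=target_species, symbols=mapped),
        dropped=dropped,
    )


class ModuleScorer:
    """Reusable scorer: bins genes once, then scores any number of signatures.

    Genes are ranked by mean expression across the cells of ``norm`` and cut
    into ``n_bins`` equal-size bins (stable ties). For each signature gene,
    ``ctrl_per_gene`` control genes are drawn from its bin — seeded, without
    replacement, signature genes excluded; if the eligible pool is smaller
    than ``ctrl_per_gene`` the draw falls back to with-replacement and
    warns. The pooled control draws (duplicates counted) define the control
    mean.
    """

    def __init__(
        self, norm: NormalizedMatrix, n_bins: int = 25, ctrl_per_gene: int = 100
    ) -> None:
        if n_bins < 1 or ctrl_per_gene < 1:
            raise ValidationError("n_bins and ctrl_per_gene must be positive")
        self.n_bins = n_bins
        self.ctrl_per_gene = ctrl_per_gene
        self.genes = list(norm.genes)
        self.barcodes = list(norm.barcodes)
        self._index = {g: i for i, g in enumerate(self.genes)}
        self._values = norm.values.toarray()
        means = self._values.mean(axis=1)
        order = np.argsort(means, kind="stable")
        self._bins = [np.sort(b) for b in np.array_split(order, n_bins)]
        self._bin_of = np.empty(len(self.genes), dtype=int)
        for b, members in enumerate(self._bins):
            self._bin_of[members] = b

    def resolve(self, gl: GeneList) -> tuple[list[int], list[str], list[str]]:
        idx = [self._index[s] for s in gl.symbols if s in self._index]
        resolved = [s for s in gl.symbols if s in self._index]
        dropped = [s for s in gl.symbols if s not in self._index]
        if not idx:
            raise ValidationError(
                f"signature {gl.name!r}: none of {len(gl)} genes found in matrix"
            )
        return idx, resolved, dropped

    def _control_indices(
        self, sig_idx: Sequence[int], rng: np.random.Generator
    ) -> np.ndarray:
        excluded = np.zeros(len(self.genes), dtype=bool)
        excluded[list(sig_idx)] = True
        draws: list[np.ndarray] = []
        # canonical gene order keeps the score invariant to signature order
        for g in sorted(sig_idx):
            members = self._bins[self._bin_of[g]]
            pool = members[~excluded[members]]
            if pool.size == 0:
                raise ValidationError(
                    "control pool empty: a bin consists entirely of signature genes"
                )
            if pool.size >= self.ctrl_per_gene:
                draws.append(rng.choice(pool, self.ctrl_per_gene, replace=False))
            else:
                warnings.warn(
                    f"control pool ({pool.size}) smaller than ctrl_per_gene "
                    f"({self.ctrl_per_gene}); sampling with replacement",
                    stacklevel=3,
                )
                draws.append(rng.choice(pool, self.ctrl_per_gene, replace=True))
        return np.concatenate(draws)

    def _weight_row(
        self, sig_idx: Sequence[int], rng: np.random.Generator
    ) -> np.ndarray:
        """Per-gene weight vector w such that score = w @ values."""
        ctrl = self._control_indices(sig_idx, rng)
        w = np.bincount(ctrl, minlength=len(self.genes)).astype(float)
        w /= -ctrl.size
        w[list(sig_idx)] += 1.0 / len(sig_idx)
        return w

    def score(self, gl: GeneList, seed: int) -> ScoreVector:
        sig_idx, resolved, dropped = self.resolve(gl)
        rng = np.random.default_rng(seed)
        w = self._weight_row(sig_idx, rng)
        scores = w @ self._values
        return ScoreVector(
            signature_name=gl.name,
            scores=pd.Series(scores, index=self.barcodes, name=gl.name),
            resolved_genes=resolved,
            dropped_genes=dropped,
        )

    def score_lists(self, lists: Sequence[GeneList], seed: int) -> np.ndarray:
        """Score many signatures under one seed stream.

        Returns an (n_lists x n_cells) array; row order follows ``lists``.
        Much faster than repeated :meth:`score` calls for calibration runs.
        """
        rng = np.random.default_rng(seed)
        W = np.empty((len(lists), len(self.genes)))
        for i, gl in enumerate(lists):
            sig_idx, _, _ = self.resolve(gl)
            W[i] = self._weight_row(sig_idx, rng)
        return W @ self._values


def module_score(
    norm: NormalizedMatrix,
    gl: GeneList,
    n_bins: int = 25,
    ctrl_per_gene: int = 100,
    seed: int = 0,
) -> ScoreVector:
    """One-shot module score; see :class:`ModuleScorer` for the scheme."""
    return ModuleScorer(norm, n_bins=n_bins, ctrl_per_gene=ctrl_per_gene).score(
        gl, seed
    )
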