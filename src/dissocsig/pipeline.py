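"""Config-driven pipeline driver.

Stages execute in fixed dependency order, hand data to each other through
plain files under ``out_dir/<stage>/``, and each stage writes a
``metadata.json`` recording its parameters, derived seed, input-file hashes
and package version. Result tables are byte-identical across reruns with
the same config and inputs; only the metadata timestamp differs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Any, Callable

from . import __version__
from .calibration import (
    correlate_metadata,
    derive_seeds,
    enrichment_fractions,
    run_calibration,
)
from .config import STAGE_ORDER, load_config, validate_config
from .errors import DissocsigError, PipelineError
from .io import (
    read_annotations,
    read_counts_dir,
    read_gene_list,
    write_annotations,
    write_counts,
    write_gene_list,
    write_json,
    write_normalized,
    write_table,
)
from .preprocess import QCThresholds, log_normalize, qc_filter
from .scoring import ModuleScorer, map_orthologs
from .signature import (
    DEThresholds,
    aggregate_pseudobulk,
    consensus_signature,
    nb_wald_de,
)
from .simulate import SimConfig, simulate_dataset, spike_report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class PipelineRun:
    def __init__(self, cfg: dict, base_dir: Path, log: Callable[[str], None]):
        self.cfg = cfg
        self.base_dir = base_dir
        self.log = log
        self.out_dir = base_dir / cfg["out_dir"]
        self.stage_seeds = dict(
            zip(STAGE_ORDER, derive_seeds(cfg["seed"], len(STAGE_ORDER)))
        )
        self.state: dict[str, Any] = {}

    def _rel(self, p: Path) -> str:
        try:
            return str(p.relative_to(self.out_dir))
        except ValueError:
            return p.name

    def stage_dir(self, stage: str) -> Path:
        d = self.out_dir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def write_metadata(
        self, stage: str, params: dict, inputs: list[Path], outputs: list[Path]
    ) -> None:
        meta = {
            "stage": stage,
            "parameters": params,
            "seed": self.stage_seeds[stage],
            "global_seed": self.cfg["seed"],
            "config_hash": _config_hash(self.cfg),
            "input_hashes": {p.name: _sha256(p) for p in inputs if p.is_file()},
            "outputs": [self._rel(p) for p in outputs],
            "package_version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "status": "complete",
        }
        write_json(meta, self.stage_dir(stage) / "metadata.json")

    # ------------------------------------------------------------------ stages
    def run_simulate(self, raw_params: dict) -> None:
        params = dict(raw_params)
        if "activated_fraction" in params:
            params["activated_fraction"] = {
                tuple(k.split("/")) if isinstance(k, str) else tuple(k): v
                for k, v in params["activated_fraction"].items()
            }
        if "groups" in params:
            params["groups"] = tuple(params["groups"])
        sim_cfg = SimConfig(seed=self.stage_seeds["simulate"], **params)
        m, ann, truth = simulate_dataset(sim_cfg)
        d = self.stage_dir("simulate")
        paths = write_counts(m, d)
        ann_path = write_annotations(ann, d / "annotations.tsv")
        truth_path = write_json(truth.to_jsonable(), d / "truth.json")
        report_path = write_table(spike_report(truth, ann), d / "spike_report.tsv")
        self.state.update(counts=m, ann=ann, truth=truth)
        self.write_metadata(
            "simulate", raw_params, [],
            list(paths.values()) + [ann_path, truth_path, report_path],
        )

    def load_inputs(self) -> None:
        inputs = self.cfg["inputs"]
        counts_dir = self.base_dir / inputs["counts_dir"]
        ann_path = self.base_dir / inputs["annotations"]
        self.state["counts"] = read_counts_dir(counts_dir)
        self.state["ann"] = read_annotations(ann_path)
        self.state["input_paths"] = [counts_dir / "matrix.mtx", ann_path]

    def run_qc(self, params: dict) -> None:
        t = QCThresholds(
            min_genes_per_cell=params["min_genes_per_cell"],
            min_umis=params["min_umis"],
            max_umis=params["max_umis"],
            max_mito_fraction=params["max_mito_fraction"],
        )
        prefixes = tuple(params.get("mito_prefixes", ("mt-", "MT-")))
        m, ann, report = qc_filter(self.state["counts"], self.state["ann"], t, prefixes)
        d = self.stage_dir("qc")
        paths = write_counts(m, d)
        ann_path = write_annotations(ann, d / "annotations.tsv")
        rep_path = write_table(report, d / "qc_report.tsv")
        self.state.update(counts=m, ann=ann)
        self.write_metadata(
            "qc", params, self.state.get("input_paths", []),
            list(paths.values()) + [ann_path, rep_path],
        )

    def run_normalize(self, params: dict) -> None:
        norm = log_normalize(self.state["counts"], scale=params.get("scale", 1e4))
        d = self.stage_dir("normalize")
        paths = write_normalized(norm, d)
        self.state["norm"] = norm
        self.write_metadata("normalize", params, [], list(paths.values()))

    def run_pseudobulk(self, params: dict) -> None:
        classes = params.get("classes")
        pb = aggregate_pseudobulk(
            self.state["counts"], self.state["ann"],
            class_filter=set(classes) if classes else None,
        )
        d = self.stage_dir("pseudobulk")
        path = write_table(pb.to_frame().reset_index(), d / "pseudobulk.tsv")
        self.state["pb"] = pb
        self.write_metadata("pseudobulk", params, [], [path])

    def run_de(self, params: dict) -> None:
        pb = self.state["pb"]
        d = self.stage_dir("de")
        tables = []
        outputs = []
        for a, b in params["comparisons"]:
            table = nb_wald_de(pb, a, b)
            tables.append(table)
            outputs.append(write_table(table, d / f"de_{a}_vs_{b}.tsv"))
        self.state["de_tables"] = tables
        self.state["de_thresholds"] = DEThresholds(
            padj_max=params.get("padj_max", 0.05),
            abs_log2fc_min=params.get("abs_log2fc_min", 0.58),
        )
        self.write_metadata("de", params, [], outputs)

    def run_consensus(self, params: dict) -> None:
        gl = consensus_signature(
            self.state["de_tables"],
            thresholds=self.state.get("de_thresholds", DEThresholds()),
            direction=params.get("direction", "up"),
        )
        if gl is None:
            raise PipelineError("consensus signature is empty; nothing to score")
        d = self.stage_dir("consensus")
        path = write_gene_list(gl, d / "consensus.txt")
        self.state["signature"] = gl
        self.write_metadata("consensus", params, [], [path])

    def run_score(self, params: dict) -> None:
        norm = self.state["norm"]
        if "signature" in params and params["signature"] is not None:
            gl = read_gene_list(
                self.base_dir / params["signature"],
                species=params.get("species", "mouse"),
            )
        else:
            gl = self.state["signature"]
        target = params.get("target_species")
        if target and target != gl.species:
            res = map_orthologs(gl, target, norm.genes)
            gl = res.genes
        scorer = ModuleScorer(
            norm,
            n_bins=params.get("n_bins", 25),
            ctrl_per_gene=params.get("ctrl_per_gene", 100),
        )
        sv = scorer.score(gl, seed=self.stage_seeds["score"])
        d = self.stage_dir("score")
        df = sv.scores.rename("score").rename_axis("barcode").reset_index()
        path = write_table(df, d / "scores.tsv")
        genes_path = write_json(
            {"resolved": sv.resolved_genes, "dropped": sv.dropped_genes},
            d / "scores.genes.json",
        )
        self.state["score"] = sv
        self.write_metadata("score", params, [], [path, genes_path])

    def run_calibrate(self, params: dict) -> None:
        norm = self.state["norm"]
        list_length = params.get("list_length")
        if list_length is None:
            list_length = len(self.state["score"].resolved_genes)
        result = run_calibration(
            norm,
            self.state["ann"],
            list_length=list_length,
            n_lists=params.get("n_lists", 1000),
            tail=params.get("tail", 0.025),
            seed=self.stage_seeds["calibrate"],
            n_bins=params.get("n_bins", 25),
            ctrl_per_gene=params.get("ctrl_per_gene", 100),
            n_mads=params.get("n_mads", 3.0),
            mad_scale=params.get("mad_scale", 1.0),
            downsample=params.get("downsample", True),
        )
        d = self.stage_dir("calibrate")
        path = write_json(result.to_jsonable(), d / "calibration.json")
        self.state["calibration"] = result
        self.write_metadata("calibrate", params, [], [path])

    def run_enrich(self, params: dict) -> None:
        et = enrichment_fractions(
            self.state["score"],
            self.state["ann"],
            cutoff=self.state["calibration"].cutoff,
            class_filter=params.get("cell_class"),
        )
        d = self.stage_dir("enrich")
        path = write_table(et, d / "enrichment.tsv")
        self.state["enrichment"] = et
        self.write_metadata("enrich", params, [], [path])

    def run_correlate(self, params: dict) -> None:
        et = self.state["enrichment"]
        out: dict[str, dict] = {}
        for cov in params["covariates"]:
            try:
                res = correlate_metadata(et, cov)
                out[cov] = {"rho": res.rho, "p": res.p, "n": res.n}
            except DissocsigError as exc:
                out[cov] = {"error": str(exc)}
        d = self.stage_dir("correlate")
        path = write_json(out, d / "correlations.json")
        self.write_metadata("correlate", params, [], [path])

    # ------------------------------------------------------------------ driver
    def run(self) -> Path:
        stages = self.cfg["stages"]
        if "simulate" not in stages:
            self.load_inputs()
        runners = {
            "simulate": self.run_simulate,
            "qc": self.run_qc,
            "normalize": self.run_normalize,
            "pseudobulk": self.run_pseudobulk,
            "de": self.run_de,
            "consensus": self.run_consensus,
            "score": self.run_score,
            "calibrate": self.run_calibrate,
            "enrich": self.run_enrich,
            "correlate": self.run_correlate,
        }
        for stage in STAGE_ORDER:
            if stage not in stages:
                continue
            params = stages[stage] or {}
            self.log(f"[{stage}] starting")
            try:
                runners[stage](params)
            except DissocsigError as exc:
                meta_path = self.stage_dir(stage) / "metadata.json"
                write_json(
                    {"stage": stage, "status": "failed", "error": str(exc)}, meta_path
                )
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
            self.log(f"[{stage}] done")
        return self.out_dir


def run_pipeline(
    config_path: str | Path, log: Callable[[str], None] | None = None
) -> Path:
    """Validate and execute a run config; returns the output directory."""
    config_path = Path(config_path)
    cfg = load_config(config_path)
    validate_config(cfg, base_dir=config_path.parent)
    if log is None:
        log = lambda msg: print(msg, file=sys.stderr)
    return PipelineRun(cfg, config_path.parent, log).run()
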