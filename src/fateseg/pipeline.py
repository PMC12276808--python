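"""Run configuration and end-to-end pipeline assembly.

A run is described by a YAML config; every threshold that is a judgement
call in practice (signature-score threshold, image threshold) must appear
explicitly in the config — there are no hidden defaults for those.  The
pipeline executes profile → score → correlate → classify, writes every
intermediate table as TSV, and emits a manifest with the config hash,
package version and seeds so a run can be replayed byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml
from anndata import AnnData

from . import __version__
from .classify import classify_cells, expression_by_class, intersect_summary, tissue_distribution
from .correlation import count_significant_markers, pairwise_correlation
from .io import attach_annotation, load_annotation, load_expression, load_gene_sets
from .profile import celltype_distribution, identify_focal_cells, stage_expression_summary
from .scoring import AUCellScorer, suggest_thresholds
from .simulate import AtlasConfig, generate_atlas

__all__ = [
    "ConfigError",
    "PipelineError",
    "RunConfig",
    "validate_config",
    "run_pipeline",
    "EXPECTED_TABLES",
]

EXPECTED_TABLES = (
    "stage_summary.tsv",
    "celltype_distribution.tsv",
    "auc_scores.tsv",
    "thresholds.tsv",
    "correlations.tsv",
    "significant_marker_counts.tsv",
    "classification.tsv",
    "intersect_summary.tsv",
    "tissue_distribution.tsv",
    "class_expression.tsv",
)


class ConfigError(ValueError):
    """Invalid run configuration; carries the full error list."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))


class PipelineError(RuntimeError):
    """A pipeline stage failed; names the stage and the cause."""


_TOP_KEYS = {
    "focal_gene", "positivity_threshold", "min_genes", "top_fraction",
    "score_threshold", "tie_seed", "seed", "out_dir", "gene_sets",
    "correlation", "input", "synthetic", "exclude_dual", "alias_map",
}
_INPUT_KEYS = {"matrix", "genes", "barcodes", "annotation"}
_CORR_KEYS = {"nonzero_only", "fdr"}


@dataclass
class RunConfig:
    """Typed, validated run configuration."""

    focal_gene: str = "Wt1"
    positivity_threshold: float = 0.0
    min_genes: int = 3
    top_fraction: float = 0.05
    score_threshold: float | str = "auto"
    tie_seed: int = 0
    seed: int = 0
    out_dir: str = "fateseg_out"
    gene_sets: str | None = None
    alias_map: dict[str, str] = field(default_factory=dict)
    correlation: dict[str, Any] = field(default_factory=dict)
    input: dict[str, str] | None = None
    synthetic: dict[str, Any] | None = None
    exclude_dual: bool = True

    def canonical_dict(self) -> dict:
        d = {
            "focal_gene": self.focal_gene,
            "positivity_threshold": self.positivity_threshold,
            "min_genes": self.min_genes,
            "top_fraction": self.top_fraction,
            "score_threshold": self.score_threshold,
            "tie_seed": self.tie_seed,
            "seed": self.seed,
            "gene_sets": self.gene_sets,
            "alias_map": self.alias_map,
            "correlation": self.correlation,
            "input": self.input,
            "synthetic": self.synthetic,
            "exclude_dual": self.exclude_dual,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def validate_config(path_or_dict: str | Path | Mapping) -> RunConfig:
    """Parse and validate a YAML run config; raise with an exhaustive error list."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text())
    else:
        raw = dict(path_or_dict)
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])

    errors: list[str] = []
    unknown = sorted(set(raw) - _TOP_KEYS)
    if unknown:
        errors.append(f"unknown keys: {unknown}")

    cfg = RunConfig()
    for key in _TOP_KEYS & set(raw):
        setattr(cfg, key, raw[key])

    if cfg.min_genes is None or not isinstance(cfg.min_genes, int) or cfg.min_genes < 1:
        errors.append(f"min_genes must be an integer >= 1, got {cfg.min_genes!r}")
    if not isinstance(cfg.top_fraction, (int, float)) or not 0 < cfg.top_fraction <= 1:
        errors.append(f"top_fraction must lie in (0, 1], got {cfg.top_fraction!r}")
    if not isinstance(cfg.positivity_threshold, (int, float)):
        errors.append("positivity_threshold must be numeric")
    if cfg.score_threshold != "auto" and not isinstance(cfg.score_threshold, (int, float)):
        errors.append("score_threshold must be 'auto' or a number")
    if cfg.input is not None:
        bad = sorted(set(cfg.input) - _INPUT_KEYS)
        if bad:
            errors.append(f"unknown input keys: {bad}")
        for k in _INPUT_KEYS:
            p = cfg.input.get(k)
            if p is None:
                errors.append(f"input.{k} is required when input is given")
            elif not Path(p).exists():
                errors.append(f"input.{k}: no such file {p!r}")
    if cfg.input is None and cfg.synthetic is None:
        errors.append("either 'input' files or a 'synthetic' block is required")
    if cfg.gene_sets is not None and not Path(cfg.gene_sets).exists():
        errors.append(f"gene_sets: no such file {cfg.gene_sets!r}")
    if cfg.input is not None and cfg.gene_sets is None:
        errors.append("gene_sets GMT path is required with real input files")
    bad_corr = sorted(set(cfg.correlation) - _CORR_KEYS)
    if bad_corr:
        errors.append(f"unknown correlation keys: {bad_corr}")

    if errors:
        raise ConfigError(errors)
    return cfg


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic is not None:
        sim = AtlasConfig(**{**cfg.synthetic, "seed": cfg.synthetic.get("seed", cfg.seed)})
        adata, truth = generate_atlas(sim)
        if cfg.gene_sets is not None:
            sets = load_gene_sets(cfg.gene_sets)
        else:
            sets = list(truth.gene_sets)
        return adata, sets
    inp = cfg.input
    adata = load_expression(inp["matrix"], inp["genes"], inp["barcodes"])
    annotation = load_annotation(inp["annotation"], cfg.alias_map or None)
    attach_annotation(adata, annotation)
    sets = load_gene_sets(cfg.gene_sets)
    return adata, sets


def _write(df: pd.DataFrame, path: Path, *, index: bool = False,
           index_label: str | None = None) -> str:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format="%.6g")
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute profile → score → correlate → classify and write the report.

    Returns the manifest dict (also written to ``manifest.json``).
    Re-running with the same config produces byte-identical tables.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashes: dict[str, str] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    @stage("load")
    def loaded():
        return _load_inputs(cfg)

    adata, sets = loaded
    if len(sets) < 2:
        raise PipelineError("stage 'load' failed: need at least two gene sets")
    set_a, set_b = sets[0], sets[1]

    @stage("profile")
    def profiled():
        subset = identify_focal_cells(adata, cfg.focal_gene, cfg.positivity_threshold)
        hashes["stage_summary.tsv"] = _write(
            stage_expression_summary(subset, adata), out / "stage_summary.tsv")
        hashes["celltype_distribution.tsv"] = _write(
            celltype_distribution(subset, adata), out / "celltype_distribution.tsv")
        return subset

    subset = profiled

    @stage("score")
    def scored():
        scorer = AUCellScorer([set_a, set_b], cfg.top_fraction, cfg.tie_seed)
        scores = scorer.score_table(adata)
        sub_scores = scores.loc[scores.index.isin(subset.cell_ids)]
        thresholds, rows = {}, []
        for name in scores.columns:
            if cfg.score_threshold == "auto":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sug = suggest_thresholds(sub_scores[name].to_numpy(), seed=cfg.seed)
            else:
                vals = sub_scores[name].to_numpy()
                sug = suggest_thresholds(
                    vals, mode="manual", manual_value=float(cfg.score_threshold),
                    seed=cfg.seed)
            thresholds[name] = sug.selected
            for cand, val in sug.candidates.items():
                rows.append((name, cand, val, ""))
            rows.append((name, "selected", sug.selected, sug.mode))
        hashes["auc_scores.tsv"] = _write(
            sub_scores.reset_index().melt(
                id_vars="cell_id", var_name="gene_set", value_name="auc"),
            out / "auc_scores.tsv")
        hashes["thresholds.tsv"] = _write(
            pd.DataFrame(rows, columns=["gene_set", "candidate", "value", "mode"]),
            out / "thresholds.tsv")
        return thresholds

    thresholds = scored

    @stage("correlate")
    def correlated():
        table = pairwise_correlation(
            adata, subset, [set_a, set_b],
            nonzero_only=bool(cfg.correlation.get("nonzero_only", False)),
            fdr=bool(cfg.correlation.get("fdr", True)),
        )
        hashes["correlations.tsv"] = _write(table, out / "correlations.tsv")
        hashes["significant_marker_counts.tsv"] = _write(
            count_significant_markers(table), out / "significant_marker_counts.tsv")
        return table

    correlated

    @stage("classify")
    def classified():
        cls = classify_cells(adata, subset, set_a, set_b, cfg.min_genes)
        hashes["classification.tsv"] = _write(
            cls, out / "classification.tsv", index=True, index_label="cell_id")
        hashes["intersect_summary.tsv"] = _write(
            intersect_summary(cls), out / "intersect_summary.tsv")
        hashes["tissue_distribution.tsv"] = _write(
            tissue_distribution(cls), out / "tissue_distribution.tsv")
        hashes["class_expression.tsv"] = _write(
            expression_by_class(cls, adata, cfg.focal_gene,
                                exclude_dual=cfg.exclude_dual),
            out / "class_expression.tsv")
        return cls

    classified

    manifest = {
        "package_version": __version__,
        "config": cfg.canonical_dict(),
        "config_hash": cfg.config_hash(),
        "seeds": {"seed": cfg.seed, "tie_seed": cfg.tie_seed},
        "score_thresholds": thresholds,
        "tables": hashes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
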