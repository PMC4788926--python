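"""End-to-end pipeline driver: read -> normalise -> fit -> select -> infer.

Each stage writes its artifacts into the run directory; a manifest with
content hashes makes a run reproducible and auditable. Stage failures are
wrapped in :class:`StageError` carrying the stage name; partial artifacts
written before the failure are retained next to a ``FAILED`` marker.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError, StageError
from .qpcr import CONTROL, FormatConfig, compute_ddct, read_ct_table, select_reference_gene
from .error_model import (
    VARIANTS, bin_variances, collect_replicate_stats, fit_all_variants,
    select_error_model, write_report,
)
from .selection import run_selection, summarize_modulator
from .ffl import infer_modules, inference_report, write_dot, write_graphml, write_sif
from .reporting import make_heatmap_table, write_manifest

log = logging.getLogger("fflscreen")


@dataclass
class PipelineConfig:
    """Settings for one analysis run."""

    input_path: str
    outdir: str
    dialect: str = "long"
    metadata_path: str | None = None
    control_label: str = CONTROL
    reference: str | None = None  # None: pick the stablest housekeeping candidate
    housekeeping: tuple = ()
    pairing: str = "paired"
    variants: tuple = VARIANTS
    n_bins: int = 10
    min_bin_size: int = 3
    cv_max: float = 0.5
    percentile: float = 95.0
    alpha_level: float = 0.05
    m_policy: str = "post_filter"
    include_time0: bool = False
    washout_after_h: float = 8.0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not Path(self.input_path).exists():
            raise ConfigError(f"input path not found: {self.input_path}")
        if self.metadata_path and not Path(self.metadata_path).exists():
            raise ConfigError(f"metadata path not found: {self.metadata_path}")
        if not 0 < self.alpha_level < 1:
            raise ConfigError("alpha_level must lie in (0, 1)")
        if not 0 < self.percentile < 100:
            raise ConfigError("percentile must lie in (0, 100)")
        if self.n_bins < 1 or self.min_bin_size < 1:
            raise ConfigError("n_bins and min_bin_size must be positive")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ConfigError(f"unknown error-model variants: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("housekeeping", "variants"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    artifacts: list[str] = []
    stage = "read"
    try:
        fmt = FormatConfig(
            dialect=config.dialect,
            metadata_path=config.metadata_path,
            washout_after_h=config.washout_after_h,
            housekeeping=tuple(config.housekeeping),
        )
        ct = read_ct_table(config.input_path, fmt)
        log.info("read %d genes x %d samples", len(ct.genes), len(ct.samples))

        stage = "reference"
        if config.reference is not None:
            reference, scores = config.reference, None
        else:
            reference, scores = select_reference_gene(ct)
            scores.to_csv(outdir / "reference_scores.csv")
            artifacts.append("reference_scores.csv")
        log.info("reference gene: %s", reference)

        stage = "ddct"
        ddct = compute_ddct(ct, reference, config.control_label, config.pairing)
        ddct.write_summary(outdir / "ddct_summary.csv")
        artifacts.append("ddct_summary.csv")

        stage = "error_model"
        stats, diagnostics = collect_replicate_stats(ddct)
        n_bins = min(config.n_bins, max(1, len(stats) // config.min_bin_size))
        binned = bin_variances(stats, n_bins, config.min_bin_size)
        fits = fit_all_variants(binned, config.variants)
        model = select_error_model(fits, config.cv_max)
        write_report(model, binned, outdir / "error_model.json",
                     outdir / "error_model.txt")
        binned.write_csv(outdir / "variance_bins.csv")
        artifacts += ["error_model.json", "error_model.txt", "variance_bins.csv"]
        log.info("variance model: %s (WRSS %.4g)", model.variant, model.wrss)

        stage = "selection"
        result = run_selection(
            ddct, model,
            alpha_level=config.alpha_level, percentile=config.percentile,
            include_time0=config.include_time0, m_policy=config.m_policy,
        )
        result.write_calls(outdir / "calls.csv")
        result.write_summary(outdir / "selection_summary.json")
        artifacts += ["calls.csv", "selection_summary.json"]
        perturbed = list(result.calls["perturbation"].unique())
        summaries = [summarize_modulator(result.calls, p).to_dict() for p in perturbed]
        with open(outdir / "modulator_summaries.json", "w") as fh:
            json.dump(summaries, fh, indent=2, default=float)
        artifacts.append("modulator_summaries.json")
        for pert in perturbed:
            name = f"heatmap_{pert}.csv"
            make_heatmap_table(result.calls, pert).to_csv(outdir / name)
            artifacts.append(name)

        stage = "inference"
        gene_order = list(ct.genes)
        modules = infer_modules(result.calls, perturbed, gene_order)
        report = inference_report(result.calls, perturbed, gene_order)
        report["error_model"] = model.to_dict()
        report["diagnostics"] = diagnostics
        with open(outdir / "modules.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        artifacts.append("modules.json")
        for i, module in enumerate(modules, start=1):
            for suffix, writer in (("sif", write_sif), ("graphml", write_graphml),
                                   ("dot", write_dot)):
                name = f"module_{i}.{suffix}"
                writer(module, outdir / name)
                artifacts.append(name)
        log.info("inferred %d module(s)", len(modules))

        stage = "manifest"
        settings = dataclasses.asdict(config)
        settings["version"] = __version__
        settings["n_modules"] = len(modules)
        manifest = write_manifest(outdir, settings, artifacts)
        return manifest
    except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, exc) from exc
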