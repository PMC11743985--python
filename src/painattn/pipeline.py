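"""End-to-end orchestration: simulate -> phenotype -> spectra -> compare.

A single YAML config drives all four stages; every run writes a manifest
(config hash, seed, package/library versions, per-stage row counts,
warnings) so outputs are traceable. Each stage is also callable on its own
from on-disk intermediates, and is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

import painattn
from painattn import io as pio
from painattn.behavior import phenotype_table
from painattn.simulate import CohortConfig, simulate_cohort
from painattn.spectral import WelchConfig, compute_band_metrics
from painattn.stats import METRIC_NAMES, run_group_comparison

logger = logging.getLogger(__name__)

_COHORT_KEYS = set(CohortConfig.__dataclass_fields__)
_WELCH_KEYS = set(WelchConfig.__dataclass_fields__)


@dataclass
class RunConfig:
    out_dir: Path
    cohort: CohortConfig = field(default_factory=CohortConfig)
    welch: WelchConfig = field(default_factory=WelchConfig)
    contrasts: tuple[str, ...] = ("iap", "ap")
    metrics: tuple[str, ...] = METRIC_NAMES
    fdr_threshold: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        self.out_dir = Path(self.out_dir)


def _coerce_pairs(section: dict) -> dict:
    # YAML lists -> tuples so dataclass fields hash/compare cleanly
    return {
        k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
    }


def load_run_config(path: str | Path, out_dir: str | Path | None = None) -> RunConfig:
    """Parse a YAML run config; unknown keys anywhere are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known_top = {"out_dir", "cohort", "welch", "contrasts", "metrics",
                 "fdr_threshold", "log_level", "seed"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cohort_raw = _coerce_pairs(raw.get("cohort", {}))
    unknown = set(cohort_raw) - _COHORT_KEYS
    if unknown:
        raise ValueError(f"unknown cohort keys: {sorted(unknown)}")
    if "seed" in raw:
        cohort_raw.setdefault("seed", raw["seed"])
    welch_raw = raw.get("welch", {})
    unknown = set(welch_raw) - _WELCH_KEYS
    if unknown:
        raise ValueError(f"unknown welch keys: {sorted(unknown)}")
    resolved_out = Path(out_dir) if out_dir is not None else Path(raw.get("out_dir", "painattn_run"))
    return RunConfig(
        out_dir=resolved_out,
        cohort=CohortConfig(**cohort_raw),
        welch=WelchConfig(**welch_raw),
        contrasts=tuple(raw.get("contrasts", ("iap", "ap"))),
        metrics=tuple(raw.get("metrics", METRIC_NAMES)),
        fdr_threshold=float(raw.get("fdr_threshold", 0.05)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "cohort": asdict(config.cohort),
            "welch": asdict(config.welch),
            "contrasts": list(config.contrasts),
            "metrics": list(config.metrics),
            "fdr_threshold": config.fdr_threshold,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def spectra_stage(
    series_iter, welch: WelchConfig
) -> pd.DataFrame:
    """Band metrics for every ROI series in an iterable, long format."""
    rows = []
    for series in series_iter:
        m = compute_band_metrics(series, welch)
        rows.append(
            {
                "subject_id": m.subject_id,
                "roi": m.roi,
                "total_alpha_power": m.total_alpha_power,
                "total_theta_power": m.total_theta_power,
                "paf_speed": m.paf_speed,
                "paf_power": m.paf_power,
                "paf_at_band_edge": m.paf_at_band_edge,
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig, write_series: bool = False) -> dict:
    """Run every stage; returns (and writes) the run manifest.

    Stage outputs land under ``config.out_dir``: behavioral tables,
    phenotypes, the spectral metrics table, and one comparison table per
    (contrast, metric). ``write_series`` additionally materializes the raw
    ROI matrices (large at study scale; off by default).
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.cohort.seed,
        "versions": {
            "painattn": painattn.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "warnings": warnings,
    }

    def _fail(stage: str, exc: Exception) -> None:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    try:
        cohort = simulate_cohort(config.cohort)
        pio.write_table(cohort.es_table, out / "experience_sampling.tsv")
        pio.write_table(cohort.ni_table, out / "ni_trials.tsv")
        pio.write_table(cohort.truth_table, out / "ground_truth.tsv")
        if write_series:
            for t in cohort.truths:
                pio.write_subject_series(
                    cohort.iter_subject_series(t.subject_id), out / "series"
                )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _fail("simulate", exc)
    manifest["stages"]["simulate"] = {
        "n_subjects": len(cohort.truths),
        "es_rows": len(cohort.es_table),
        "ni_rows": len(cohort.ni_table),
    }

    try:
        phenotypes = phenotype_table(cohort.es_table, cohort.ni_table)
        pio.write_table(phenotypes, out / "phenotypes.tsv")
    except Exception as exc:
        _fail("phenotype", exc)
    n_boundary = int(
        (phenotypes["iap_group"] == "boundary").sum()
        + (phenotypes["ap_type"] == "boundary").sum()
    )
    if n_boundary:
        warnings.append(f"{n_boundary} boundary phenotype labels")
    manifest["stages"]["phenotype"] = {
        "rows": len(phenotypes),
        "boundary_labels": n_boundary,
    }

    try:
        series_iter = (
            series
            for t in cohort.truths
            for series in cohort.iter_subject_series(t.subject_id)
        )
        metrics = spectra_stage(series_iter, config.welch)
        pio.write_table(metrics, out / "band_metrics.tsv")
    except Exception as exc:
        _fail("spectra", exc)
    n_edge = int(metrics["paf_at_band_edge"].sum())
    if n_edge:
        warnings.append(f"{n_edge} PAF estimates at the alpha band edge")
    manifest["stages"]["spectra"] = {"rows": len(metrics), "edge_pafs": n_edge}

    try:
        comparison_counts = {}
        for contrast in config.contrasts:
            for metric in config.metrics:
                table = run_group_comparison(
                    metrics, phenotypes, contrast, metric, config.fdr_threshold
                )
                name = f"compare_{contrast}_{metric}.tsv"
                pio.write_table(table, out / name)
                comparison_counts[name] = len(table)
    except Exception as exc:
        _fail("compare", exc)
    manifest["stages"]["compare"] = comparison_counts

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
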