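"""End-to-end orchestration: ingest/simulate -> QC -> catalogues -> discovery
-> validation -> population structure -> per-patient filtering.

The pipeline is driven by a :class:`RunConfig` (loadable from YAML) and
produces a :class:`RunReport` whose per-stage counts telescope: every site
removed at a stage is attributed to exactly one rule.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import yaml

from . import __version__
from .cohort_qc import (
    DISCOVERY_QC,
    VALIDATION_QC,
    QcThresholds,
    pairwise_relatedness,
    select_unrelated,
)
from .discovery import PopulationPanel, classify_panel, saturation_curve
from .frequency_catalogue import build_cohort_catalogue
from .genotype_model import (
    read_bed_intervals,
    read_frequency_table,
    read_multisample_vcf,
    select_biallelic_autosomal_snvs,
)
from .patient_filter import retention_benchmark
from .popstruct import mean_pairwise_fst
from .synthetic_data import SimConfig, SimulatedStudy, simulate_study
from .validation import validate_candidates

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one full run.

    Either ``simulate`` carries a synthetic-study configuration, or the
    ``discovery_vcf``/``validation_vcf``/``targets_bed``/``reference_tsvs``
    paths point at real inputs.
    """

    simulate: SimConfig | None = None
    discovery_vcf: str | None = None
    validation_vcf: str | None = None
    targets_bed: str | None = None
    reference_tsvs: list[str] = field(default_factory=list)
    target_name: str = "NAVARRE"
    discovery_qc: QcThresholds = field(default_factory=lambda: DISCOVERY_QC)
    validation_qc: QcThresholds = field(default_factory=lambda: VALIDATION_QC)
    common_threshold: float = 0.01
    saturation_sizes: list[int] = field(default_factory=list)
    saturation_replicates: int = 25
    saturation_rel_tol: float = 0.0
    run_relatedness: bool = False
    pi_hat_max: float = 0.1875
    n_patients: int | None = None
    fst_populations: dict[str, list[str]] | None = None
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            sim = dict(kwargs["simulate"])
            kwargs["simulate"] = SimConfig(**sim)
        for key in ("discovery_qc", "validation_qc"):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = QcThresholds(**kwargs[key])
        return cls(**kwargs)


def _load_inputs(cfg: RunConfig) -> tuple[Any, Any, Any, dict[str, Any], SimulatedStudy | None]:
    if cfg.simulate is not None:
        study = simulate_study(cfg.simulate)
        refs = {name: cat for name, cat in study.references.items()}
        return study.discovery, study.validation, study.targets, refs, study
    if cfg.discovery_vcf is None or cfg.targets_bed is None:
        raise ValueError("need either a simulate section or discovery_vcf + targets_bed")
    discovery = read_multisample_vcf(cfg.discovery_vcf)
    validation = (
        read_multisample_vcf(cfg.validation_vcf) if cfg.validation_vcf else None
    )
    targets = read_bed_intervals(cfg.targets_bed)
    refs = {}
    for p in cfg.reference_tsvs:
        cat = read_frequency_table(p)
        refs[cat.population_name] = cat
    return discovery, validation, targets, refs, None


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute every stage in order and return the run report (JSON-safe dict)."""
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "discovery_qc": asdict(cfg.discovery_qc),
            "validation_qc": asdict(cfg.validation_qc),
            "common_threshold": cfg.common_threshold,
        },
        "stages": {},
    }
    stages = report["stages"]

    def stage(name):
        logger.info("stage: %s", name)
        stages[name] = {}
        return stages[name]

    try:
        s = stage("ingest")
        discovery, validation, targets, refs, study = _load_inputs(cfg)
        s["n_discovery_samples"] = discovery.n_samples
        s["n_discovery_sites"] = discovery.n_variants
        s["n_reference_catalogues"] = len(refs)

        s = stage("site_selection")
        selected = select_biallelic_autosomal_snvs(discovery, targets)
        s["n_input"] = discovery.n_variants
        s["n_output"] = selected.n_variants
        s["n_removed"] = discovery.n_variants - selected.n_variants

        if cfg.run_relatedness:
            s = stage("relatedness")
            ests = pairwise_relatedness(selected)
            kept = select_unrelated(ests, cfg.pi_hat_max, samples=selected.samples)
            removed = [x for x in selected.samples if x not in kept]
            s["n_pairs"] = len(ests)
            s["n_samples_removed"] = len(removed)
            s["samples_removed"] = removed
            idx = [i for i, x in enumerate(selected.samples) if x in kept]
            selected = selected.take_samples(idx)

        s = stage("discovery_qc")
        from .cohort_qc import site_qc

        qcd, qc_report = site_qc(selected, cfg.discovery_qc)
        reasons = qc_report["fail_reason"].value_counts().to_dict()
        reasons.pop("", None)
        s["n_input"] = selected.n_variants
        s["n_output"] = qcd.n_variants
        s["removed_by_rule"] = reasons

        s = stage("catalogue")
        target_cat = build_cohort_catalogue(qcd, cfg.target_name)
        from .frequency_catalogue import is_common_freq

        freqs = target_cat.data["alt_freq"].to_numpy()
        s["n_variants"] = len(target_cat)
        s["n_common"] = int(np.sum(is_common_freq(freqs, cfg.common_threshold)))

        s = stage("discovery")
        panel = PopulationPanel(target=target_cat, references=list(refs.values()))
        result = classify_panel(panel, cfg.common_threshold)
        s["category_counts"] = {k: int(v) for k, v in result.category_counts().items()}
        exclusive = result.exclusive_keys
        s["n_exclusive_common"] = len(exclusive)

        if cfg.saturation_sizes:
            s = stage("saturation")
            curve = saturation_curve(
                qcd,
                sizes=cfg.saturation_sizes,
                replicates=cfg.saturation_replicates,
                seed=np.random.default_rng(cfg.seed),
                threshold=cfg.common_threshold,
                rel_tol=cfg.saturation_rel_tol,
            )
            s["sizes"] = curve.sizes
            s["mean_counts"] = curve.mean_counts
            s["full_count"] = curve.full_count
            s["plateau_n"] = curve.plateau_n

        if validation is not None:
            s = stage("validation")
            outcomes, summary = validate_candidates(
                validation,
                exclusive,
                discovery_catalogue=target_cat,
                thr=cfg.validation_qc,
                threshold=cfg.common_threshold,
            )
            s.update(
                {
                    "n_candidates": summary.n_candidates,
                    "n_absent": summary.n_absent,
                    "n_excluded_qc": summary.n_candidates
                    - summary.n_absent
                    - summary.n_pass_qc,
                    "n_pass_qc": summary.n_pass_qc,
                    "n_confirmed": summary.n_confirmed,
                    "n_not_validated": summary.n_not_validated,
                    "n_fold_concordant": summary.n_fold_concordant,
                    "proportion_confirmed": summary.proportion_confirmed,
                }
            )

        if cfg.fst_populations:
            s = stage("fst")
            merged = discovery  # population assignments refer to this matrix
            ests = mean_pairwise_fst(merged, cfg.fst_populations)
            s["pairs"] = {
                f"{e.population_pair[0]}-{e.population_pair[1]}": e.mean_fst for e in ests
            }

        s = stage("patient_filter")
        patients = (
            qcd.samples[: cfg.n_patients] if cfg.n_patients else list(qcd.samples)
        )
        cat_list = [target_cat] + list(refs.values())
        stats = retention_benchmark(qcd, patients, cat_list, cfg.common_threshold)
        s["n_patients"] = len(patients)
        s["median_fraction_retained"] = {
            k: float(v) for k, v in stats.summary["median"].items()
        }
        s["stringency_order"] = stats.stringency_order
    except Exception as exc:
        failed = list(stages)[-1] if stages else "setup"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=_json_safe)
        with open(os.path.join(cfg.out_dir, "report.txt"), "w") as fh:
            fh.write(format_report(report))
    return report


def _json_safe(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def format_report(report: dict[str, Any]) -> str:
    lines = [
        f"popexclusive run report (schema v{report['schema_version']}, "
        f"package {report['package_version']}, seed {report['seed']})",
        "",
    ]
    for name, data in report["stages"].items():
        lines.append(f"[{name}]")
        for k, v in data.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    return "\n".join(lines)
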