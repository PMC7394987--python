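"""Pipeline orchestration: simulate/convert -> fit -> summarize -> stats.

A :class:`PipelineConfig` (plain dataclass, loadable from YAML) binds the
stages together; :func:`run_pipeline` executes them, writes every
intermediate next to the outputs, and leaves a :class:`RunManifest`
(JSON) with input digests, the resolved configuration, software version
and accumulated warnings, sufficient to re-run the analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conversion import (DEFAULT_HEMATOCRIT, extract_vif,
                         tissue_concentration)
from .io import (assert_affines_match, load_series, load_volume, save_series,
                 save_volume)
from .patlak import LeakageMap, fit_patlak_map
from .protocol import AcquisitionProtocol
from .simulate import (CohortSpec, PhantomSpec, default_calibration_curve,
                       simulate_cohort, simulate_subject)
from .stats import KI_COLUMNS, fit_age_model, fit_interaction_model
from .summarize import ROIMaskSet, ROI_ORDER, summarize_rois

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline",
           "run_subject_pipeline", "run_stats_stage"]


class ValidationError(ValueError):
    """Raised for invalid configuration or missing inputs (CLI exit 1)."""


@dataclass
class PipelineConfig:
    """Resolved configuration of a pipeline run.

    When ``simulate`` is true the subject is generated from ``phantom``;
    otherwise the listed input paths must exist.  ``stats_table`` may
    point at an existing cohort CSV; with ``simulate`` it is generated
    from ``cohort``.
    """

    simulate: bool = True
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    # input paths (used when simulate is false)
    fast_path: str | None = None
    slow_path: str | None = None
    t10_path: str | None = None
    sinus_mask_path: str | None = None
    roi_mask_paths: dict = field(default_factory=dict)
    stats_table: str | None = None
    # analysis parameters
    hematocrit: float = DEFAULT_HEMATOCRIT
    cp_floor_mM: float = 0.0
    bolus_frac: float = 0.05
    ceiling: float = 0.999
    bin_width: float | None = 1e-7
    denominator: str = "roi"
    confounders: bool = False
    integrity_measure: str | None = None
    run_stats: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, sub in (("phantom", PhantomSpec),
                         ("protocol", AcquisitionProtocol),
                         ("cohort", CohortSpec)):
            if key in kwargs and isinstance(kwargs[key], dict):
                if "aif_decay_rates" in kwargs[key]:
                    kwargs[key]["aif_decay_rates"] = tuple(
                        kwargs[key]["aif_decay_rates"])
                if "shape" in kwargs[key]:
                    kwargs[key]["shape"] = tuple(kwargs[key]["shape"])
                kwargs[key] = sub(**kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ValidationError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def validate_inputs(self) -> None:
        """Fail fast, naming any missing input path before any compute."""
        if self.simulate:
            return
        required = {"fast": self.fast_path, "slow": self.slow_path,
                    "t10": self.t10_path, "sinus_mask": self.sinus_mask_path}
        for name, p in required.items():
            if p is None:
                raise ValidationError(f"missing required input path: {name}")
            if not Path(p).exists():
                raise ValidationError(f"{name} input does not exist: {p}")
        for roi in ROI_ORDER:
            p = self.roi_mask_paths.get(roi)
            if p is None or not Path(p).exists():
                raise ValidationError(
                    f"missing ROI mask for {roi!r}: {p}")


@dataclass
class RunManifest:
    """Provenance record written alongside every pipeline output."""

    version: str = __version__
    started: float = 0.0
    finished: float = 0.0
    config_hash: str = ""
    stages: list = field(default_factory=list)
    input_digests: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})

    def digest(self, name: str, arr: np.ndarray) -> None:
        self.input_digests[name] = hashlib.sha256(
            np.ascontiguousarray(arr).tobytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True))


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str)
        .encode()).hexdigest()[:16]


def run_subject_pipeline(config: PipelineConfig, out_dir: str | Path,
                         manifest: RunManifest) -> pd.DataFrame:
    """convert -> fit -> summarize for one subject; returns the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    caught: list[warnings.WarningMessage] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if config.simulate:
            subj = simulate_subject(config.phantom, config.protocol,
                                    seed=config.seed)
            fast, slow = subj.fast, subj.slow
            t10, masks = subj.t10_ms, subj.masks
            sinus_mask, brain_mask = subj.sinus_mask, subj.brain_mask
            calibration = subj.calibration
            save_series(out / "fast.nii.gz", fast)
            save_series(out / "slow.nii.gz", slow)
            save_volume(out / "t10.nii.gz", t10)
            save_volume(out / "ki_truth.nii.gz", subj.truth.ki_map)
        else:
            fast = load_series(config.fast_path)
            slow = load_series(config.slow_path)
            t10, aff_t10, _ = load_volume(config.t10_path)
            sinus_mask, aff_sin, _ = load_volume(config.sinus_mask_path)
            assert_affines_match(aff_t10, aff_sin)
            sinus_mask = sinus_mask > 0.5
            roi = {}
            for name in ROI_ORDER:
                m, aff_m, _ = load_volume(config.roi_mask_paths[name])
                assert_affines_match(aff_t10, aff_m)
                roi[name] = m > 0.5
            masks = ROIMaskSet(**roi)
            brain_mask = masks.white_matter | masks.gray_matter
            calibration = default_calibration_curve(config.phantom,
                                                    config.protocol)
        manifest.digest("fast", fast.data)
        manifest.digest("slow", slow.data)
        manifest.digest("t10", t10)

        vif = extract_vif(fast, sinus_mask, calibration,
                          slow_series=slow, hematocrit=config.hematocrit)
        conc = tissue_concentration(fast, slow, t10, config.protocol.
                                    r1_relaxivity, brain_mask,
                                    config.protocol.td_ms, config.ceiling)
        manifest.add_stage("convert", n_timepoints=int(conc.times_s.size),
                           n_clamped=int(conc.n_clamped),
                           vif_voxels=int(vif.n_voxels))

        lmap = fit_patlak_map(conc, vif, brain_mask,
                              cp_floor_mM=config.cp_floor_mM,
                              bolus_frac=config.bolus_frac)
        save_volume(out / "ki.nii.gz", lmap.ki)
        save_volume(out / "vp.nii.gz", lmap.vp)
        save_volume(out / "resid_sd.nii.gz", lmap.resid_sd)
        (out / "fit_report.json").write_text(json.dumps({
            "n_fitted": lmap.n_fitted, "n_flagged": lmap.n_flagged,
            "dof": lmap.dof}, indent=2))
        manifest.add_stage("fit", n_fitted=lmap.n_fitted,
                           n_flagged=lmap.n_flagged)

        summary = summarize_rois(lmap, masks, config.bin_width,
                                 config.denominator)
        summary.to_csv(out / "leakage_summary.csv", index=False)
        manifest.add_stage("summarize", rois=list(summary["roi"]))
    manifest.warnings.extend(str(w.message) for w in caught)
    return summary


def run_stats_stage(config: PipelineConfig, out_dir: str | Path,
                    manifest: RunManifest) -> pd.DataFrame:
    """Cohort regressions on a provided or simulated cohort table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.stats_table is not None:
        p = Path(config.stats_table)
        if not p.exists():
            raise ValidationError(f"cohort table does not exist: {p}")
        table = pd.read_csv(p)
    else:
        table, _ = simulate_cohort(config.cohort, seed=config.seed)
        table.to_csv(out / "cohort_table.csv", index=False)
    frames = []
    for roi in KI_COLUMNS:
        if config.integrity_measure is not None:
            res = fit_interaction_model(table, roi, config.integrity_measure)
        else:
            res = fit_age_model(table, roi, confounders=config.confounders)
        frames.append(res.to_frame())
    results = pd.concat(frames, ignore_index=True)
    results.to_csv(out / "regression_results.csv", index=False)
    manifest.add_stage("stats", n_subjects=int(len(table)),
                       model=("interaction" if config.integrity_measure
                              else ("confounders" if config.confounders
                                    else "age")))
    return results


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path) -> tuple[pd.DataFrame,
                                               pd.DataFrame | None,
                                               RunManifest]:
    """Execute the full pipeline and write outputs + manifest to ``out_dir``.

    Returns (leakage summary, regression results or None, manifest).
    """
    config.validate_inputs()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(started=time.time(),
                           config_hash=_config_hash(config))
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False))
    summary = run_subject_pipeline(config, out, manifest)
    results = None
    if config.run_stats:
        results = run_stats_stage(config, out, manifest)
    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return summary, results, manifest
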