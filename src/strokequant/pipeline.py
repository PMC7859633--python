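"""End-to-end study orchestration: per-pig MRI and gait quantification,
pre/post normalization, breed comparison, and report emission.

A study is described by a JSON config holding a cohort manifest (pig id,
breed, optional exclusion reason, paths to label/ADC/FA volumes, landmark
files and pre/post gait CSVs) plus analysis options.  ``run_study``
produces a per-pig metrics CSV, a breed-comparison CSV and a JSON
summary; excluded pigs appear in the summary but not in the statistics.
``run_validation`` generates phantoms and gait cohorts from the breed
presets, runs the full pipeline on them, and checks every measured value
against its ground truth within the stated tolerances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .imaging_io import (
    DEFAULT_LABEL_SCHEME,
    LabelScheme,
    read_image_volume,
    read_landmarks,
)
from .volumetry import volumetry_report
from .diffusion_metrics import diffusion_report
from .midline_herniation import herniation_indices
from .gait_analysis import (
    aggregate_parameters,
    gait_changes,
    is_good_run,
    parse_footfalls,
    run_parameters,
    runs_from_frame,
)
from .group_stats import breed_comparison
from .synthetic_data import (
    generate_gait_cohort,
    generate_phantom,
    phantom_spec_for_breed,
)

__all__ = ["StudyConfig", "PigEntry", "run_study", "run_validation", "ValidationReport"]


@dataclass
class PigEntry:
    pig_id: str
    breed: str
    excluded: str | None = None
    mri: dict[str, str] = field(default_factory=dict)
    gait: dict[str, str] = field(default_factory=dict)


@dataclass
class StudyConfig:
    pigs: list[PigEntry]
    output_dir: str
    ipsilateral: str = "right"
    lesion_ratio_threshold: float = 0.80
    label_scheme_path: str | None = None
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        raw = json.loads(Path(path).read_text())
        pigs = [
            PigEntry(
                pig_id=str(p["id"]),
                breed=str(p["breed"]),
                excluded=p.get("excluded"),
                mri=dict(p.get("mri", {})),
                gait=dict(p.get("gait", {})),
            )
            for p in raw["pigs"]
        ]
        cfg = cls(
            pigs=pigs,
            output_dir=str(raw["output_dir"]),
            ipsilateral=str(raw.get("ipsilateral", "right")),
            lesion_ratio_threshold=float(raw.get("lesion_ratio_threshold", 0.80)),
            label_scheme_path=raw.get("label_scheme"),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        ids = [p.pig_id for p in self.pigs]
        if len(set(ids)) != len(ids):
            raise ValueError("pig ids in the manifest must be unique")
        for pig in self.pigs:
            for group in (pig.mri, pig.gait):
                for key, p in group.items():
                    path = Path(p)
                    if base is not None and not path.is_absolute():
                        path = base / path
                        group[key] = str(path)
                    if not path.exists():
                        raise FileNotFoundError(
                            f"pig {pig.pig_id}: referenced {key} file does not exist: {path}"
                        )


def _mri_metrics(pig: PigEntry, scheme: LabelScheme, config: StudyConfig, log: list[str]) -> dict[str, float]:
    labels = read_image_volume(pig.mri["labels"], modality="label", scheme=scheme)
    adc = read_image_volume(pig.mri["adc"], modality="adc") if "adc" in pig.mri else None
    fa = read_image_volume(pig.mri["fa"], modality="fa") if "fa" in pig.mri else None
    vol = volumetry_report(
        labels,
        adc=adc,
        scheme=scheme,
        ipsilateral=config.ipsilateral,
        ratio_threshold=config.lesion_ratio_threshold,
    )
    metrics = {
        "hemisphere_ipsi_cm3": vol.hv_ipsi,
        "hemisphere_contra_cm3": vol.hv_contra,
        "cerebellum_cm3": vol.cerebellum,
        "lesion_volume_cm3": vol.lesion_corrected,
        "lesion_uncorrected_cm3": vol.lesion_uncorrected,
        "lesion_normalized_percent": vol.lesion_normalized_percent,
        "swelling_percent": vol.swelling_percent,
        "ventricle_compression_percent": vol.ventricle_compression_percent,
    }
    if adc is not None:
        diff = diffusion_report(adc, fa, labels, scheme, config.ipsilateral)
        metrics["adc_change_percent"] = diff.adc_change_percent
        for j in diff.excluded_slices:
            log.append(f"{pig.pig_id}: coronal slice {j} excluded from ADC averaging")
        if fa is not None:
            metrics["fa_change_percent"] = diff.fa_change_percent
    if "landmarks_sagittal" in pig.mri:
        axial = (
            read_landmarks(pig.mri["landmarks_axial"])
            if "landmarks_axial" in pig.mri
            else None
        )
        geo = herniation_indices(read_landmarks(pig.mri["landmarks_sagittal"]), axial)
        metrics.update({"cth": geo.cth, "fmh": geo.fmh})
        if not math.isnan(geo.mls_mm):
            metrics["mls_mm"] = geo.mls_mm
    return metrics


def _gait_metrics(pig: PigEntry, log: list[str]) -> dict[str, float]:
    phases = {}
    for phase in ("pre", "post"):
        runs = parse_footfalls(pig.gait[phase])
        accepted = []
        for run in runs:
            ok, reason = is_good_run(run)
            if not ok:
                log.append(f"{pig.pig_id} {phase} run {run.run_id}: rejected ({reason})")
                continue
            day = run.run_id.split("r")[0] if phase == "pre" else phase
            accepted.append((day, run_parameters(run)))
        if phase == "post":
            accepted = accepted[:5]  # only data from five runs enter the post average
        phases[phase] = aggregate_parameters(accepted, phase)
    changes = gait_changes(phases["post"], phases["pre"])
    return {f"gait_{k}_change_percent": v for k, v in changes.items()}


def run_study(config: StudyConfig) -> dict:
    """Run the full study and write reports; returns the summary dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = (
        LabelScheme.from_json(config.label_scheme_path)
        if config.label_scheme_path
        else DEFAULT_LABEL_SCHEME
    )
    log: list[str] = []
    rows: list[dict] = []
    skipped: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for pig in config.pigs:
        if pig.excluded:
            excluded[pig.pig_id] = pig.excluded
            log.append(f"{pig.pig_id}: excluded from statistics ({pig.excluded})")
            continue
        try:
            metrics: dict[str, float] = {}
            if pig.mri:
                metrics.update(_mri_metrics(pig, scheme, config, log))
            if pig.gait:
                metrics.update(_gait_metrics(pig, log))
        except Exception as exc:  # partial failure: skip the pig, keep the study
            skipped[pig.pig_id] = str(exc)
            log.append(f"{pig.pig_id}: skipped ({exc})")
            continue
        for metric, value in metrics.items():
            rows.append(
                {"pig_id": pig.pig_id, "breed": pig.breed, "metric": metric, "value": value}
            )
    metrics_df = pd.DataFrame(rows, columns=["pig_id", "breed", "metric", "value"])
    metrics_df = metrics_df.sort_values(["metric", "breed", "pig_id"]).reset_index(drop=True)
    metrics_df.to_csv(out / "metrics.csv", index=False)

    comparison_path = None
    n_breeds = metrics_df["breed"].nunique() if len(metrics_df) else 0
    if n_breeds == 2:
        try:
            comparison = breed_comparison(metrics_df)
        except ValueError as exc:
            log.append(f"breed comparison not computed: {exc}")
        else:
            comparison.to_csv(out / "comparison.csv", index=False)
            comparison_path = str(out / "comparison.csv")

    summary = {
        "n_pigs": len(config.pigs),
        "n_analyzed": len({r["pig_id"] for r in rows}),
        "excluded": excluded,
        "skipped": skipped,
        "metrics_csv": str(out / "metrics.csv"),
        "comparison_csv": comparison_path,
        "log": log,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


# --------------------------------------------------------------------------
# closure validation against synthetic ground truth
# --------------------------------------------------------------------------

#: closure tolerances: volumes 2% relative, percent changes 1 absolute,
#: midline shift one voxel, herniation indices 0.005, gait (noise-free)
#: 1e-6 relative
PHANTOM_TOLERANCES = {
    "hv_contra": ("rel", 0.02),
    "hv_ipsi": ("rel", 0.02),
    "ventricle_contra": ("rel", 0.02),
    "ventricle_ipsi": ("rel", 0.02),
    "cerebellum": ("rel", 0.02),
    "lesion_uncorrected": ("rel", 0.02),
    "lesion_corrected": ("rel", 0.02),
    "swelling_percent": ("abs", 1.0),
    "ventricle_compression_percent": ("abs", 1.0),
    "adc_change_percent": ("abs", 1.0),
    "fa_change_percent": ("abs", 1.0),
    "mls_mm": ("voxel", 1.0),
    "cth": ("abs", 0.005),
    "fmh": ("abs", 0.005),
}


@dataclass
class ValidationReport:
    rows: list[dict]

    @property
    def ok(self) -> bool:
        return all(r["passed"] for r in self.rows)

    def failures(self) -> list[dict]:
        return [r for r in self.rows if not r["passed"]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _check(rows, label, metric, measured, truth, kind, tol):
    if kind == "rel":
        passed = measured == truth if truth == 0 else abs(measured - truth) <= tol * abs(truth)
    else:
        passed = abs(measured - truth) <= tol
    rows.append(
        {
            "dataset": label,
            "metric": metric,
            "measured": float(measured),
            "truth": float(truth),
            "passed": bool(passed),
        }
    )


def run_validation(
    seed: int = 0,
    spacing: float = 1.0,
    n_pigs: int = 2,
    tolerance_scale: float = 1.0,
) -> ValidationReport:
    """Phantom/gait closure validation of the whole measurement path.

    For each breed, a phantom parameterized at the printed group means
    and a noise-free gait cohort are generated and pushed through the
    full pipeline; every measured metric is compared with its ground
    truth.  ``tolerance_scale`` shrinks all tolerances (0 makes every
    comparison exact — a negative control that must fail).
    """
    rows: list[dict] = []
    for breed in ("yc", "lr"):
        spec = phantom_spec_for_breed(breed, spacing=spacing, seed=seed)
        bundle = generate_phantom(spec)
        vol = volumetry_report(bundle.labels, adc=bundle.adc)
        diff = diffusion_report(bundle.adc, bundle.fa, bundle.labels)
        geo = herniation_indices(bundle.landmarks_sagittal, bundle.landmarks_axial)
        measured = {
            "hv_contra": vol.hv_contra,
            "hv_ipsi": vol.hv_ipsi,
            "ventricle_contra": vol.ventricle_contra,
            "ventricle_ipsi": vol.ventricle_ipsi,
            "cerebellum": vol.cerebellum,
            "lesion_uncorrected": vol.lesion_uncorrected,
            "lesion_corrected": vol.lesion_corrected,
            "swelling_percent": vol.swelling_percent,
            "ventricle_compression_percent": vol.ventricle_compression_percent,
            "adc_change_percent": diff.adc_change_percent,
            "fa_change_percent": diff.fa_change_percent,
            "mls_mm": geo.mls_mm,
            "cth": geo.cth,
            "fmh": geo.fmh,
        }
        for metric, (kind, tol) in PHANTOM_TOLERANCES.items():
            tol = tol * tolerance_scale * (spacing if kind == "voxel" else 1.0)
            _check(rows, f"phantom-{breed}", metric, measured[metric], bundle.truth.metrics[metric], "abs" if kind == "voxel" else kind, tol)

        cohort, truth = generate_gait_cohort(
            breed, n_pigs=n_pigs, noise_sd_scale=0.0, seed=seed + 1
        )
        for pig in cohort.pigs:
            pre = aggregate_parameters(
                [(day, run_parameters(_frame_to_run(f))) for day, f in pig.pre_frames], "pre"
            )
            post = aggregate_parameters(
                [("post", run_parameters(_frame_to_run(f))) for f in pig.post_frames], "post"
            )
            changes = gait_changes(post, pre)
            for key, true_val in truth.metrics["per_pig"][pig.pig_id]["change"].items():
                tol = max(1e-6 * abs(true_val), 1e-9) * (tolerance_scale if tolerance_scale > 0 else 0)
                _check(rows, f"gait-{breed}-{pig.pig_id}", key, changes[key], true_val, "abs", tol)
    return ValidationReport(rows=rows)


def _frame_to_run(frame: pd.DataFrame):
    runs = runs_from_frame(frame)
    assert len(runs) == 1
    return runs[0]
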