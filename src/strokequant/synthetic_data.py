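"""Synthetic brain phantoms and gait cohorts with known ground truth.

The phantom is built from ellipsoid/sphere primitives rather than
anatomically realistic meshes: every metric in the battery depends only
on volumes, uniform intensities and planar landmark geometry, so simple
solids give exact analytic ground truth (verifiability over realism).
Structure surfaces are selected by thresholding the squared-radius field
at the value that makes the voxel count match the requested volume, so
voxel-counted ground truth equals the specification to within a handful
of tie voxels at any spacing.

Gait cohorts draw per-pig parameters from breed presets whose every
number is a printed study value (pre-stroke parameter tables and
post-stroke percent-change tables); footfall times and positions are then
constructed so that the extractor recovers the drawn values exactly at
zero noise.  Within-pig run-to-run noise defaults to 20% of the
between-pig SD and is controlled by ``noise_sd_scale``.  Parameters are
drawn independently (between-parameter correlations are not published).
Cadence is derived from the drawn cycle times (60 / mean cycle) rather
than drawn independently, since the extractor defines it that way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging_io import (
    DEFAULT_LABEL_SCHEME,
    ImageVolume,
    LabelScheme,
    LandmarkSet,
    resolve_sides,
    write_image_volume,
    write_landmarks,
)
from .gait_analysis import HOOVES, GaitParameters
from .volumetry import corrected_lesion_volume

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "BreedPreset",
    "GroundTruth",
    "GaitCohort",
    "generate_phantom",
    "generate_gait_cohort",
    "breed_presets",
    "phantom_spec_for_breed",
    "footfall_frame",
]


# --------------------------------------------------------------------------
# ground truth container
# --------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """True metric values for a generated dataset; serializes losslessly."""

    metrics: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.metrics, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(metrics=json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# phantom specification and generation
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Parameters of one synthetic pre/post-stroke brain.

    Volumes in cm^3, lengths in mm, ADC in 10^-3 mm^2/s, FA
    dimensionless.  Defaults follow the Yucatan post-stroke group means
    (contralateral hemisphere 79.8 cm^3 with 13.4% swelling, ventricles
    1.40 / 0.657 cm^3, 10.0 cm^3 lesion at 65.5% of contralateral
    diffusivity, internal-capsule FA 0.500 vs 0.443, midline shift
    1.6 mm, herniation indices 0.12 / 0.11 on a 100 mm skull).
    """

    spacing: float = 0.5
    hv_contra: float = 79.8
    hv_ipsi: float = 90.49
    vent_contra: float = 1.40
    vent_ipsi: float = 0.657
    cerebellum: float = 10.9
    lesion_volume: float = 10.0  # 0 disables the lesion
    adc_contra: float = 1.0
    lesion_adc_ratio: float = 0.655
    adc_ipsi_ratio: float = 1.0  # uniform ipsilateral-hemisphere ADC ratio
    fa_background: float = 0.25
    fa_ic_contra: float = 0.500
    fa_ic_ipsi: float = 0.443
    mls_mm: float = 1.6
    sll_mm: float = 100.0
    ttx_mm: float = 12.0
    fmx_mm: float = 11.0
    noise_sd_adc: float = 0.0
    noise_sd_fa: float = 0.0
    ipsilateral: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "spacing", "hv_contra", "hv_ipsi", "vent_contra", "vent_ipsi",
            "cerebellum", "lesion_volume", "adc_contra", "sll_mm", "ttx_mm", "fmx_mm",
        ):
            if getattr(self, name) < 0 or (name in ("spacing", "hv_contra", "hv_ipsi") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be non-negative (positive for sizes), got {getattr(self, name)}")
        for name in ("lesion_adc_ratio", "adc_ipsi_ratio"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {getattr(self, name)}")
        if self.lesion_volume > self.hv_ipsi:
            raise ValueError("lesion volume exceeds the ipsilateral hemisphere volume")
        if self.ipsilateral not in ("left", "right"):
            raise ValueError("ipsilateral must be 'left' or 'right'")


@dataclass
class PhantomBundle:
    labels: ImageVolume
    lesion_mask: ImageVolume
    adc: ImageVolume
    fa: ImageVolume
    landmarks_sagittal: LandmarkSet
    landmarks_axial: LandmarkSet
    truth: GroundTruth
    spec: PhantomSpec
    scheme: LabelScheme = field(default_factory=lambda: DEFAULT_LABEL_SCHEME)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "labels": out / "labels.nii",
            "lesion_mask": out / "lesion_mask.nii",
            "adc": out / "adc.nii",
            "fa": out / "fa.nii",
            "landmarks_sagittal": out / "landmarks_sagittal.json",
            "landmarks_axial": out / "landmarks_axial.json",
            "ground_truth": out / "ground_truth.json",
            "label_scheme": out / "label_scheme.json",
        }
        write_image_volume(self.labels, paths["labels"])
        write_image_volume(self.lesion_mask, paths["lesion_mask"])
        write_image_volume(self.adc, paths["adc"])
        write_image_volume(self.fa, paths["fa"])
        write_landmarks(self.landmarks_sagittal, paths["landmarks_sagittal"])
        write_landmarks(self.landmarks_axial, paths["landmarks_axial"])
        self.truth.to_json(paths["ground_truth"])
        self.scheme.to_json(paths["label_scheme"])
        return paths


# geometry constants (mm): hemisphere ellipsoids sit at +-X_HEMI on the
# left-right axis; embedded structures are placed at fixed offsets chosen
# so that they stay inside the hemisphere surface for volumes spanning
# both breeds and do not touch the lesion sphere.
_X_HEMI = 24.0
_HEMI_SEMI = (22.0, 38.0, 23.0)
_VENT_SEMI = (5.0, 9.0, 5.0)
_VENT_OFFSET = (0.0, 22.0, 8.0)
_IC_SEMI = (3.0, 6.0, 4.0)
_IC_VOLUME = 0.30  # cm^3, fixed; no volumetric target in the battery
_IC_OFFSET = (-8.0, 8.0, -6.0)  # x toward midline
_CC_CENTER = (0.0, 5.0, 6.0)
_CC_SEMI = (6.0, 4.0, 3.0)
_CC_VOLUME = 0.25
_CEREB_CENTER = (0.0, -52.0, -6.0)
_CEREB_SEMI = (16.0, 11.0, 10.0)
_LESION_OFFSET = (4.0, -10.0, -2.0)
_BOUNDS = ((-52.0, 52.0), (-70.0, 44.0), (-28.0, 28.0))

_ADC_CSF_RATIO = 3.0
_FA_CC = 0.45
_FA_VENT = 0.05


def _axes(spacing: float):
    axes = []
    for lo, hi in _BOUNDS:
        n = int(round((hi - lo) / spacing))
        axes.append(lo + (np.arange(n) + 0.5) * spacing)
    return axes


def _r2_ellipsoid(axes, center, semi) -> np.ndarray:
    x, y, z = axes
    return (
        ((x - center[0]) / semi[0])[:, None, None] ** 2
        + ((y - center[1]) / semi[1])[None, :, None] ** 2
        + ((z - center[2]) / semi[2])[None, None, :] ** 2
    )


def _exact_region(r2: np.ndarray, allowed: np.ndarray, target_cm3: float, voxvol: float):
    """Threshold ``r2`` so the selected voxel count matches ``target_cm3``.

    Returns (mask, threshold).  The count equals round(target/voxel)
    exactly up to ties on the squared-radius field.
    """
    k = int(round(target_cm3 * 1000.0 / voxvol))
    if k <= 0:
        return np.zeros_like(allowed), 0.0
    flat_idx = np.flatnonzero(allowed.ravel())
    vals = r2.ravel()[flat_idx]
    if k > vals.size:
        raise ValueError(
            f"infeasible phantom: {target_cm3} cm^3 requested but only "
            f"{vals.size * voxvol / 1000.0:.1f} cm^3 available"
        )
    # exactly the k smallest squared radii (ties broken deterministically),
    # so the voxel count matches the requested volume to half a voxel
    order = np.argpartition(vals, k - 1)
    chosen = flat_idx[order[:k]]
    thr = float(vals[order[k - 1]])
    mask = np.zeros(r2.size, dtype=bool)
    mask[chosen] = True
    return mask.reshape(r2.shape), thr


def _toward_contour_normal(a, b, toward):
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    d_hat = d / np.linalg.norm(d)
    n_hat = np.array([-d_hat[1], d_hat[0]])
    mid = (np.asarray(a, dtype=float) + np.asarray(b, dtype=float)) / 2.0
    if float(np.dot(np.asarray(toward, dtype=float) - mid, n_hat)) < 0:
        n_hat = -n_hat
    return n_hat, d_hat, mid


def _sagittal_landmarks(spec: PhantomSpec) -> LandmarkSet:
    """Closed-form midsagittal landmark geometry realizing SLL/TTX/FMX.

    A canonical porcine skull skeleton (cribriform plate at the origin,
    dorsal foramen magnum at 28 degrees below the horizontal) is scaled
    so the skull length line equals ``sll_mm``; the cerebellar arcs are
    offset from the transtentorial and foramen-magnum lines by exactly
    ``ttx_mm`` and ``fmx_mm`` along the caudal normals.
    """
    s = spec.sll_mm / 100.0
    crib = np.array([0.0, 0.0])
    sella = np.array([55.0, -30.0]) * s
    tent = np.array([75.0, 10.0]) * s
    fm_d = np.array([96.0, -28.0]) * s
    fm_v = np.array([100.0, -48.0]) * s

    # transtentorial arc: caudal normal points away from the cerebrum
    n_ttl, d_ttl, mid_ttl = _toward_contour_normal(sella, tent, 2 * ((sella + tent) / 2) - crib)
    arc_ttl = np.array(
        [
            mid_ttl + 0.4 * spec.ttx_mm * n_ttl - 6.0 * s * d_ttl,
            mid_ttl + spec.ttx_mm * n_ttl,
            mid_ttl + 0.4 * spec.ttx_mm * n_ttl + 6.0 * s * d_ttl,
        ]
    )
    # caudal (foramen magnum) arc: the cerebellum lies on the intracranial
    # side of the foramen magnum line, so the caudal normal points inward
    n_fml, d_fml, mid_fml = _toward_contour_normal(fm_d, fm_v, crib)
    arc_fml = np.array(
        [
            mid_fml + spec.fmx_mm * n_fml,
            mid_fml + 0.3 * spec.fmx_mm * n_fml + 4.0 * s * d_fml,
        ]
    )
    return LandmarkSet(
        plane="midsagittal",
        points={
            "cribriform_dorsal": crib,
            "sella_dorsal": sella,
            "tentorium_rostral": tent,
            "foramen_magnum_dorsal": fm_d,
            "foramen_magnum_ventral": fm_v,
        },
        contours={"tentorial": arc_ttl, "caudal": arc_fml},
        normals={"ttl": n_ttl, "fml": n_fml},
    )


def _axial_landmarks(spec: PhantomSpec) -> LandmarkSet:
    # septum displaced toward the contralateral side (away from the lesion)
    shift = -spec.mls_mm if spec.ipsilateral == "right" else spec.mls_mm
    return LandmarkSet(
        plane="axial",
        points={
            "midline_anterior": np.array([0.0, 60.0]),
            "midline_posterior": np.array([0.0, -60.0]),
            "septum_pellucidum": np.array([shift, 0.0]),
        },
    )


def generate_phantom(
    spec: PhantomSpec, scheme: LabelScheme = DEFAULT_LABEL_SCHEME
) -> PhantomBundle:
    """Generate label volume, ADC/FA maps, landmarks and ground truth.

    Deterministic for a given spec (noise uses ``spec.seed``).
    """
    axes = _axes(spec.spacing)
    shape = tuple(len(a) for a in axes)
    voxvol = spec.spacing**3
    sides = resolve_sides(scheme, spec.ipsilateral)
    sign_ipsi = 1.0 if spec.ipsilateral == "right" else -1.0

    labels = np.zeros(shape, dtype=np.int16)
    counts: dict[str, int] = {}
    hemi_r2: dict[str, np.ndarray] = {}

    def place(role: str, center, semi, target_cm3: int | float, code: int):
        r2 = _r2_ellipsoid(axes, center, semi)
        mask, _ = _exact_region(r2, labels == 0, target_cm3, voxvol)
        labels[mask] = code
        counts[role] = int(mask.sum())
        return r2

    for side, sign in (("contra", -sign_ipsi), ("ipsi", sign_ipsi)):
        hc = (sign * _X_HEMI, 0.0, 0.0)
        place(
            f"ventricle_{side}",
            (hc[0] + _VENT_OFFSET[0], hc[1] + _VENT_OFFSET[1], hc[2] + _VENT_OFFSET[2]),
            _VENT_SEMI,
            getattr(spec, f"vent_{side}"),
            sides[f"ventricle_{side}"],
        )
        place(
            f"ic_{side}",
            (hc[0] + sign * _IC_OFFSET[0], hc[1] + _IC_OFFSET[1], hc[2] + _IC_OFFSET[2]),
            _IC_SEMI,
            _IC_VOLUME,
            sides[f"ic_{side}"],
        )
    place("corpus_callosum", _CC_CENTER, _CC_SEMI, _CC_VOLUME, scheme.code("corpus_callosum"))

    for side, sign in (("contra", -sign_ipsi), ("ipsi", sign_ipsi)):
        hc = (sign * _X_HEMI, 0.0, 0.0)
        r2 = _r2_ellipsoid(axes, hc, _HEMI_SEMI)
        mask, thr = _exact_region(r2, labels == 0, getattr(spec, f"hv_{side}"), voxvol)
        # embedded structures must sit inside the hemisphere surface
        embedded = (labels == sides[f"ventricle_{side}"]) | (labels == sides[f"ic_{side}"])
        if float(r2[embedded].max()) > thr:
            raise ValueError("infeasible phantom: embedded structure pierces the hemisphere surface")
        labels[mask] = sides[f"hemisphere_{side}"]
        counts[f"hv_{side}"] = int(mask.sum())
        hemi_r2[side] = r2

    place("cerebellum", _CEREB_CENTER, _CEREB_SEMI, spec.cerebellum, sides["cerebellum"])

    # lesion: a sphere of reduced ADC inside the ipsilateral hemisphere;
    # it keeps the hemisphere label (it is an intensity feature, not a
    # separate anatomical compartment)
    lesion = np.zeros(shape, dtype=bool)
    if spec.lesion_volume > 0:
        lc = (
            sign_ipsi * _X_HEMI + sign_ipsi * _LESION_OFFSET[0],
            _LESION_OFFSET[1],
            _LESION_OFFSET[2],
        )
        r2 = _r2_ellipsoid(axes, lc, (1.0, 1.0, 1.0))  # squared distance, mm^2
        lesion, _ = _exact_region(r2, labels == sides["hemisphere_ipsi"], spec.lesion_volume, voxvol)
    counts["lesion"] = int(lesion.sum())

    brain = labels > 0
    adc = np.zeros(shape, dtype=np.float64)
    adc[brain] = spec.adc_contra
    for role in ("hemisphere_ipsi", "ic_ipsi"):
        adc[labels == sides[role]] = spec.adc_contra * spec.adc_ipsi_ratio
    for role in ("ventricle_contra", "ventricle_ipsi"):
        adc[labels == sides[role]] = spec.adc_contra * _ADC_CSF_RATIO
    adc[lesion] = spec.adc_contra * spec.lesion_adc_ratio

    fa = np.zeros(shape, dtype=np.float64)
    fa[brain] = spec.fa_background
    fa[labels == sides["ic_contra"]] = spec.fa_ic_contra
    fa[labels == sides["ic_ipsi"]] = spec.fa_ic_ipsi
    fa[labels == scheme.code("corpus_callosum")] = _FA_CC
    for role in ("ventricle_contra", "ventricle_ipsi"):
        fa[labels == sides[role]] = _FA_VENT

    if spec.noise_sd_adc > 0 or spec.noise_sd_fa > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_sd_adc > 0:
            adc[brain] = np.maximum(
                adc[brain] + rng.normal(0.0, spec.noise_sd_adc, int(brain.sum())), 1e-4
            )
        if spec.noise_sd_fa > 0:
            fa[brain] = np.clip(
                fa[brain] + rng.normal(0.0, spec.noise_sd_fa, int(brain.sum())), 0.0, 1.0
            )

    lesion_vol = ImageVolume(
        data=np.where(lesion, sides["lesion"], 0).astype(np.int16),
        spacing=(spec.spacing,) * 3,
        modality="label",
    )
    spacing3 = (spec.spacing,) * 3
    truth = GroundTruth(
        metrics=_phantom_truth(spec, counts, labels, lesion, sides, voxvol)
    )
    return PhantomBundle(
        labels=ImageVolume(labels, spacing3, "label"),
        lesion_mask=lesion_vol,
        adc=ImageVolume(adc, spacing3, "adc"),
        fa=ImageVolume(fa, spacing3, "fa"),
        landmarks_sagittal=_sagittal_landmarks(spec),
        landmarks_axial=_axial_landmarks(spec),
        truth=truth,
        spec=spec,
        scheme=scheme,
    )


def _phantom_truth(spec, counts, labels, lesion, sides, voxvol) -> dict:
    """Ground-truth metrics from construction counts (independent of the
    measurement modules; per-slice ADC truth is computed analytically from
    the constructed masks)."""
    cm3 = voxvol / 1000.0
    hv_c, hv_i = counts["hv_contra"] * cm3, counts["hv_ipsi"] * cm3
    v_c, v_i = counts["ventricle_contra"] * cm3, counts["ventricle_ipsi"] * cm3
    lv_u = counts["lesion"] * cm3
    # analytic per-slice ADC change from voxel counts: ipsilateral slices
    # mix normal tissue at adc_ipsi_ratio with lesion at lesion_adc_ratio
    ipsi = labels == sides["hemisphere_ipsi"]
    contra = labels == sides["hemisphere_contra"]
    n_i = ipsi.sum(axis=(0, 2)).astype(float)
    n_les = (lesion & ipsi).sum(axis=(0, 2)).astype(float)
    n_c = contra.sum(axis=(0, 2)).astype(float)
    both = (n_i > 0) & (n_c > 0)
    mean_ipsi = (
        (n_i[both] - n_les[both]) * spec.adc_ipsi_ratio + n_les[both] * spec.lesion_adc_ratio
    ) / n_i[both]
    adc_truth = float(np.mean(100.0 * (mean_ipsi - 1.0)))
    return {
        "hv_contra": hv_c,
        "hv_ipsi": hv_i,
        "swelling_percent": 100.0 * (hv_i - hv_c) / hv_c,
        "ventricle_contra": v_c,
        "ventricle_ipsi": v_i,
        "ventricle_compression_percent": 100.0 * (v_i - v_c) / v_c,
        "cerebellum": counts["cerebellum"] * cm3,
        "lesion_uncorrected": lv_u,
        "lesion_corrected": corrected_lesion_volume(hv_c, hv_i, lv_u),
        "adc_change_percent": adc_truth,
        "fa_ipsi": spec.fa_ic_ipsi,
        "fa_contra": spec.fa_ic_contra,
        "fa_change_percent": 100.0 * (spec.fa_ic_ipsi - spec.fa_ic_contra) / spec.fa_ic_contra,
        "mls_mm": spec.mls_mm,
        "sll_mm": spec.sll_mm,
        "ttx_mm": spec.ttx_mm,
        "fmx_mm": spec.fmx_mm,
        "cth": spec.ttx_mm / spec.sll_mm,
        "fmh": spec.fmx_mm / spec.sll_mm,
    }


# --------------------------------------------------------------------------
# breed presets (printed study values)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BreedPreset:
    """Printed group means/SDs for one breed and phase.

    ``gait`` holds pre-stroke parameter values, ``gait_change`` holds
    post-stroke percent changes, ``mri`` holds imaging metrics; each entry
    maps a metric key to (mean, sd).
    """

    name: str
    gait: dict[str, tuple[float, float]] = field(default_factory=dict)
    gait_change: dict[str, tuple[float, float]] = field(default_factory=dict)
    mri: dict[str, tuple[float, float]] = field(default_factory=dict)


def _limb(name, lf, rf, lh, rh):
    return {
        f"{name}_LF": lf, f"{name}_RF": rf, f"{name}_LH": lh, f"{name}_RH": rh,
    }


def breed_presets() -> dict[str, BreedPreset]:
    """The four study presets: yc-pre, yc-post, lr-pre, lr-post."""
    yc_pre_gait = {
        "velocity": (205.2, 13.1),
        "cadence": (135.8, 8.3),
        **_limb("cycle_time", (0.45, 0.03), (0.45, 0.03), (0.45, 0.03), (0.45, 0.03)),
        **_limb("swing_percent", (52.3, 2.6), (52.1, 1.7), (56.4, 1.4), (56.8, 1.2)),
        **_limb("mean_pressure", (2.8, 0.09), (2.8, 0.09), (2.8, 0.04), (2.8, 0.07)),
        **_limb("stride_length", (89.9, 3.5), (90.1, 3.7), (89.3, 3.1), (89.4, 3.5)),
    }
    lr_pre_gait = {
        "velocity": (167.7, 26.3),
        "cadence": (130.8, 5.7),
        **_limb("cycle_time", (0.47, 0.02), (0.46, 0.02), (0.46, 0.02), (0.46, 0.02)),
        **_limb("swing_percent", (47.8, 4.9), (46.7, 4.9), (53.8, 4.6), (53.7, 4.7)),
        **_limb("mean_pressure", (2.8, 0.09), (2.9, 0.06), (2.8, 0.06), (2.8, 0.05)),
        **_limb("stride_length", (76.3, 9.0), (76.3, 9.0), (76.0, 8.9), (76.1, 8.9)),
    }
    yc_post_change = {
        "velocity": (-66.6, 21.1),
        "cadence": (-50.3, 18.9),
        **_limb("cycle_time", (119.8, 62.3), (121.1, 64.5), (118.7, 63.9), (121.4, 67.2)),
        **_limb("swing_percent", (-41.1, 4.9), (-46.4, 5.6), (-33.5, 5.1), (-33.2, 5.0)),
        **_limb("mean_pressure", (-9.7, 2.8), (-4.7, 3.3), (-8.6, 4.2), (-7.5, 3.8)),
        **_limb("stride_length", (-36.3, 11.7), (-36.6, 11.3), (-35.9, 11.4), (-36.9, 11.8)),
    }
    lr_post_change = {
        "velocity": (-59.8, 10.1),
        "cadence": (-50.3, 7.8),
        **_limb("cycle_time", (101.8, 27.7), (103.6, 29.4), (104.5, 29.5), (104.9, 29.9)),
        **_limb("swing_percent", (-31.4, 2.4), (-34.0, 4.1), (-31.9, 2.7), (-30.3, 2.8)),
        **_limb("mean_pressure", (-6.6, 2.2), (-1.7, 2.3), (-7.2, 4.5), (-4.8, 2.3)),
        **_limb("stride_length", (-19.9, 8.1), (-19.6, 7.9), (-19.8, 8.0), (-19.7, 8.3)),
    }
    yc_pre_mri = {
        "hemisphere_cm3": (79.8, 6.5),
        "cerebellum_cm3": (10.9, 1.1),
        "ventricle_cm3": (1.4, 0.3),
    }
    lr_pre_mri = {
        "hemisphere_cm3": (87.6, 3.3),
        "cerebellum_cm3": (13.2, 0.5),
        "ventricle_cm3": (0.97, 0.2),
    }
    yc_post_mri = {
        "lesion_volume_cm3": (10.0, 3.1),
        "swelling_percent": (13.4, 6.8),
        "ventricle_compression_percent": (-53.1, 30.2),
        "adc_change_percent": (-34.5, 13.0),
        "fa_change_percent": (-11.4, 10.6),
        "mls_mm": (1.6, 0.8),
        "cth": (0.12, 0.02),
        "fmh": (0.11, 0.04),
        "lesion_normalized_percent": (59.0, 19.6),
    }
    lr_post_mri = {
        "lesion_volume_cm3": (8.9, 2.9),
        "swelling_percent": (17.0, 3.2),
        "ventricle_compression_percent": (-52.6, 39.7),
        "adc_change_percent": (-45.2, 8.4),
        "fa_change_percent": (-30.4, 6.6),
        "mls_mm": (2.7, 1.3),
        "cth": (0.11, 0.03),
        "fmh": (0.09, 0.04),
        "lesion_normalized_percent": (56.5, 14.5),
    }
    return {
        "yc-pre": BreedPreset("yc-pre", gait=yc_pre_gait, mri=yc_pre_mri),
        "yc-post": BreedPreset("yc-post", gait_change=yc_post_change, mri=yc_post_mri),
        "lr-pre": BreedPreset("lr-pre", gait=lr_pre_gait, mri=lr_pre_mri),
        "lr-post": BreedPreset("lr-post", gait_change=lr_post_change, mri=lr_post_mri),
    }


def phantom_spec_for_breed(breed: str, spacing: float = 0.5, seed: int = 0) -> PhantomSpec:
    """Phantom spec parameterized at a breed's printed group means.

    Hemisphere and ventricle targets combine the pre-stroke volumes with
    the post-stroke percent changes; the internal-capsule FA baseline
    (0.500 contralateral) is a package choice since only the percent
    change is published.
    """
    presets = breed_presets()
    pre, post = presets[f"{breed}-pre"].mri, presets[f"{breed}-post"].mri
    hv = pre["hemisphere_cm3"][0]
    vent = pre["ventricle_cm3"][0]
    fa_contra = 0.500
    return PhantomSpec(
        spacing=spacing,
        hv_contra=hv,
        hv_ipsi=hv * (1 + post["swelling_percent"][0] / 100.0),
        vent_contra=vent,
        vent_ipsi=vent * (1 + post["ventricle_compression_percent"][0] / 100.0),
        cerebellum=pre["cerebellum_cm3"][0],
        lesion_volume=post["lesion_volume_cm3"][0],
        adc_contra=1.0,
        lesion_adc_ratio=1 + post["adc_change_percent"][0] / 100.0,
        adc_ipsi_ratio=1.0,
        fa_ic_contra=fa_contra,
        fa_ic_ipsi=fa_contra * (1 + post["fa_change_percent"][0] / 100.0),
        mls_mm=post["mls_mm"][0],
        sll_mm=100.0,
        ttx_mm=post["cth"][0] * 100.0,
        fmx_mm=post["fmh"][0] * 100.0,
        seed=seed,
    )


# --------------------------------------------------------------------------
# gait cohort generation
# --------------------------------------------------------------------------

_N_CYCLES = 3  # contacts per limb = 4 -> 16 footfalls, satisfies the good-run rule


def footfall_frame(params: GaitParameters, run_id: str, n_cycles: int = _N_CYCLES) -> pd.DataFrame:
    """Construct footfall events that the extractor inverts exactly.

    Limbs are phased as a two-beat pace (lateral pairs near-synchronous,
    the two pairs half a cycle apart).  The first contact is LF at the
    origin and the trailing hind hoof's start position is chosen so that
    first-to-last contact displacement over elapsed time equals
    ``params.velocity`` exactly, while per-limb cycle time, stride length,
    swing share and pressure equal the given values by construction.
    """
    T = params.cycle_time
    L = params.stride_length
    sw = params.swing_percent
    pr = params.mean_pressure
    tbar = float(np.mean([T[h] for h in HOOVES]))
    t0 = {"LF": 0.0, "LH": 0.10 * tbar, "RF": 0.50 * tbar, "RH": 0.0}
    ends = {h: t0[h] + n_cycles * T[h] for h in ("LF", "LH", "RF")}
    t0["RH"] = max(max(ends.values()) - n_cycles * T["RH"] + 0.15 * tbar, 0.05 * tbar)
    v = params.velocity
    x0 = {"LF": 0.0, "LH": v * t0["LH"], "RF": v * t0["RF"]}
    x0["RH"] = v * (t0["RH"] + n_cycles * T["RH"]) - n_cycles * L["RH"]
    y_lane = {"LF": 8.0, "RF": -8.0, "LH": 8.0, "RH": -8.0}

    rows = []
    for hoof in HOOVES:
        stance = T[hoof] * (1.0 - sw[hoof] / 100.0)
        if stance <= 0:
            raise ValueError(f"infeasible swing percent for {hoof}: {sw[hoof]}")
        for k in range(n_cycles + 1):
            t = t0[hoof] + k * T[hoof]
            rows.append(
                {
                    "run_id": run_id,
                    "hoof": hoof,
                    "contact_time_s": t,
                    "lift_time_s": t + stance,
                    "x_cm": x0[hoof] + k * L[hoof],
                    "y_cm": y_lane[hoof],
                    "pressure_au": pr[hoof],
                }
            )
    return pd.DataFrame(rows).sort_values("contact_time_s", kind="stable").reset_index(drop=True)


def _draw_params(gait: dict[str, tuple[float, float]], rng: np.random.Generator) -> GaitParameters:
    """Draw one pig's pre-stroke parameters; cadence derives from cycle times."""

    def draw(key, lo, max_tries=20):
        mean, sd = gait[key]
        for _ in range(max_tries):
            v = rng.normal(mean, sd)
            if v > lo:
                return float(v)
        return float(max(mean, lo + abs(lo) * 0.1 + 1e-3))  # capped redraw

    cycle = {h: draw(f"cycle_time_{h}", 0.05) for h in HOOVES}
    params = GaitParameters(
        velocity=draw("velocity", 1.0),
        cadence=60.0 / float(np.mean([cycle[h] for h in HOOVES])),
        cycle_time=cycle,
        swing_percent={h: float(np.clip(rng.normal(*gait[f"swing_percent_{h}"]), 5.0, 95.0)) for h in HOOVES},
        stride_length={h: draw(f"stride_length_{h}", 1.0) for h in HOOVES},
        mean_pressure={h: draw(f"mean_pressure_{h}", 0.01) for h in HOOVES},
    )
    return params


def _apply_change(pre: GaitParameters, change: dict[str, tuple[float, float]], rng) -> tuple[GaitParameters, dict[str, float]]:
    """Draw per-parameter percent changes and apply them to a pig's pre values."""
    pct: dict[str, float] = {}
    flat = pre.as_flat()
    post_flat = dict(flat)
    for key, (mean, sd) in change.items():
        if key == "cadence":
            continue  # derived below
        for _ in range(20):
            c = float(rng.normal(mean, sd))
            if flat[key] * (1 + c / 100.0) > 0 or key.startswith("swing"):
                break
        pct[key] = c
        post_flat[key] = flat[key] * (1 + c / 100.0)
    for h in HOOVES:
        post_flat[f"swing_percent_{h}"] = float(np.clip(post_flat[f"swing_percent_{h}"], 5.0, 95.0))
        pct[f"swing_percent_{h}"] = 100.0 * (post_flat[f"swing_percent_{h}"] / flat[f"swing_percent_{h}"] - 1.0)
    post_flat["cadence"] = 60.0 / float(np.mean([post_flat[f"cycle_time_{h}"] for h in HOOVES]))
    pct["cadence"] = 100.0 * (post_flat["cadence"] / flat["cadence"] - 1.0)
    return GaitParameters.from_flat(post_flat), pct


def _jitter(params: GaitParameters, gait_sd: dict[str, tuple[float, float]], scale: float, rng) -> GaitParameters:
    if scale == 0:
        return params
    flat = params.as_flat()
    for key, (_, sd) in gait_sd.items():
        if key == "cadence" or key not in flat:
            continue
        flat[key] = max(flat[key] + float(rng.normal(0.0, scale * sd)), 1e-3)
    for h in HOOVES:
        flat[f"swing_percent_{h}"] = float(np.clip(flat[f"swing_percent_{h}"], 5.0, 95.0))
    flat["cadence"] = 60.0 / float(np.mean([flat[f"cycle_time_{h}"] for h in HOOVES]))
    return GaitParameters.from_flat(flat)


@dataclass
class GaitCohortPig:
    pig_id: str
    params_pre: GaitParameters
    params_post: GaitParameters | None
    change: dict[str, float] | None
    pre_frames: list[tuple[int, pd.DataFrame]]
    post_frames: list[pd.DataFrame]


@dataclass
class GaitCohort:
    breed: str
    pigs: list[GaitCohortPig]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for pig in self.pigs:
            pre = pd.concat([f for _, f in pig.pre_frames], ignore_index=True)
            paths[f"{pig.pig_id}_pre"] = p = out / f"{pig.pig_id}_pre.csv"
            pre.to_csv(p, index=False)
            if pig.post_frames:
                post = pd.concat(pig.post_frames, ignore_index=True)
                paths[f"{pig.pig_id}_post"] = p = out / f"{pig.pig_id}_post.csv"
                post.to_csv(p, index=False)
        self.truth().to_json(out / "ground_truth.json")
        paths["ground_truth"] = out / "ground_truth.json"
        return paths

    def truth(self) -> GroundTruth:
        per_pig = {}
        for pig in self.pigs:
            entry = {"pre": pig.params_pre.as_flat()}
            if pig.params_post is not None:
                entry["post"] = pig.params_post.as_flat()
                entry["change"] = pig.change
            per_pig[pig.pig_id] = entry
        pre_keys = self.pigs[0].params_pre.as_flat().keys()
        cohort = {k: float(np.mean([p.params_pre.as_flat()[k] for p in self.pigs])) for k in pre_keys}
        if all(p.change is not None for p in self.pigs):
            for k in self.pigs[0].change:
                cohort[f"change_{k}"] = float(np.mean([p.change[k] for p in self.pigs]))
        return GroundTruth(metrics={"breed": self.breed, "per_pig": per_pig, "cohort": cohort})


def generate_gait_cohort(
    breed: str,
    n_pigs: int,
    runs_per_day: int = 2,
    noise_sd_scale: float = 0.2,
    seed: int = 0,
    include_post: bool = True,
    out_dir: str | Path | None = None,
) -> tuple[GaitCohort, GroundTruth]:
    """Generate a breed cohort of footfall runs with known ground truth.

    Per pig: three pre-stroke collection days with ``runs_per_day`` runs
    each, and (when ``include_post``) one post-stroke session of exactly
    five runs.  Ground truth records the drawn per-pig parameter values
    and percent changes, which the extraction pipeline recovers exactly
    when ``noise_sd_scale`` is zero.
    """
    if n_pigs < 1:
        raise ValueError("n_pigs must be >= 1")
    presets = breed_presets()
    pre_preset = presets[f"{breed}-pre"]
    post_preset = presets[f"{breed}-post"] if include_post else None
    rng = np.random.default_rng(seed)
    pigs: list[GaitCohortPig] = []
    for i in range(n_pigs):
        pig_id = f"{breed}{i + 1:02d}"
        pre = _draw_params(pre_preset.gait, rng)
        post = change = None
        if post_preset is not None:
            post, change = _apply_change(pre, post_preset.gait_change, rng)
        pre_frames = []
        for day in (1, 2, 3):
            for j in range(runs_per_day):
                run_params = _jitter(pre, pre_preset.gait, noise_sd_scale, rng)
                pre_frames.append((day, footfall_frame(run_params, f"d{day}r{j + 1}")))
        post_frames = []
        if post is not None:
            for j in range(5):
                run_params = _jitter(post, pre_preset.gait, noise_sd_scale, rng)
                post_frames.append(footfall_frame(run_params, f"postr{j + 1}"))
        pigs.append(GaitCohortPig(pig_id, pre, post, change, pre_frames, post_frames))
    cohort = GaitCohort(breed=breed, pigs=pigs)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort, cohort.truth()
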