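"""ADC per-slice percent change between hemispheres and FA ROI statistics.

Lesion diffusivity is summarized as the mean ADC of the ipsilateral
hemisphere expressed as a percent change relative to the contralateral
hemisphere, computed per coronal slice and averaged (unweighted) across
slices that contain both hemispheres.  White-matter integrity after
stroke is summarized as the percent change of the mean FA in the
ipsilateral internal capsule relative to the contralateral one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import ImageVolume, LabelScheme, DEFAULT_LABEL_SCHEME, resolve_sides

__all__ = [
    "DiffusionReport",
    "hemisphere_adc_change_percent",
    "roi_mean_fa",
    "internal_capsule_fa_change_percent",
]

CORONAL_AXIS = 1  # anterior-posterior index in RAS order


@dataclass
class DiffusionReport:
    """Per-slice and summary diffusivity changes, plus FA ROI means."""

    per_slice_adc_change: list[float]
    slice_indices: list[int]
    excluded_slices: list[int]
    adc_change_percent: float
    fa_ipsi: float = float("nan")
    fa_contra: float = float("nan")
    fa_change_percent: float = float("nan")
    weighted: bool = False
    notes: list[str] = field(default_factory=list)


def hemisphere_adc_change_percent(
    adc: ImageVolume,
    labels: ImageVolume,
    scheme: LabelScheme = DEFAULT_LABEL_SCHEME,
    ipsilateral: str = "right",
    weighted: bool = False,
    lesion_mask: ImageVolume | None = None,
    lesion_slices_only: bool = False,
) -> DiffusionReport:
    """Per-coronal-slice ADC percent change, ipsilateral vs contralateral.

    Each coronal slice containing at least one voxel of each hemisphere
    contributes ``100 * (mean_ipsi - mean_contra) / mean_contra``; slices
    missing a hemisphere are excluded and recorded.  The summary value is
    the unweighted mean across included slices (``weighted=True`` weights
    by the slice's hemisphere voxel count instead).
    ``lesion_slices_only`` restricts to slices intersecting the given
    lesion mask; off by default since the original protocol does not state
    the restriction.
    """
    if not adc.same_grid(labels):
        raise ValueError("ADC map and label volume must share grid shape and spacing")
    sides = resolve_sides(scheme, ipsilateral)
    ipsi = labels.data == sides["hemisphere_ipsi"]
    contra = labels.data == sides["hemisphere_contra"]
    if not ipsi.any() or not contra.any():
        raise ValueError("both hemisphere labels must be non-empty")
    if lesion_slices_only and lesion_mask is None:
        raise ValueError("lesion_slices_only requires a lesion_mask")

    data = np.asarray(adc.data, dtype=float)
    n_slices = labels.shape[CORONAL_AXIS]
    changes: list[float] = []
    indices: list[int] = []
    weights: list[int] = []
    excluded: list[int] = []
    notes: list[str] = []
    for j in range(n_slices):
        sl = [slice(None)] * 3
        sl[CORONAL_AXIS] = j
        sl = tuple(sl)
        mi, mc = ipsi[sl], contra[sl]
        in_brain = mi.any() or mc.any()
        if not (mi.any() and mc.any()):
            if in_brain:
                excluded.append(j)
                notes.append(f"slice {j}: one hemisphere absent, excluded")
            continue
        if lesion_slices_only and not np.asarray(lesion_mask.data)[sl].any():  # type: ignore[union-attr]
            excluded.append(j)
            continue
        mean_i = float(data[sl][mi].mean())
        mean_c = float(data[sl][mc].mean())
        changes.append(100.0 * (mean_i - mean_c) / mean_c)
        indices.append(j)
        weights.append(int(mi.sum() + mc.sum()))
    if not changes:
        raise ValueError("no coronal slice contains both hemispheres")
    if weighted:
        overall = float(np.average(changes, weights=weights))
    else:
        overall = float(np.mean(changes))
    return DiffusionReport(
        per_slice_adc_change=changes,
        slice_indices=indices,
        excluded_slices=excluded,
        adc_change_percent=overall,
        weighted=weighted,
        notes=notes,
    )


def roi_mean_fa(
    fa: ImageVolume,
    labels: ImageVolume,
    code: int,
    scheme: LabelScheme | None = None,
) -> float:
    """Arithmetic mean FA over the voxels carrying ``code``."""
    if not fa.same_grid(labels):
        raise ValueError("FA map and label volume must share grid shape and spacing")
    if scheme is not None:
        scheme.name(code)
    roi = labels.data == int(code)
    if not roi.any():
        raise ValueError(f"ROI for label code {int(code)} is empty")
    return float(np.asarray(fa.data, dtype=float)[roi].mean())


def internal_capsule_fa_change_percent(
    fa: ImageVolume,
    labels: ImageVolume,
    scheme: LabelScheme = DEFAULT_LABEL_SCHEME,
    ipsilateral: str = "right",
) -> float:
    """Internal-capsule FA percent change, ipsilateral vs contralateral."""
    sides = resolve_sides(scheme, ipsilateral)
    mean_ipsi = roi_mean_fa(fa, labels, sides["ic_ipsi"], scheme)
    mean_contra = roi_mean_fa(fa, labels, sides["ic_contra"], scheme)
    if mean_contra == 0:
        raise ValueError("contralateral internal-capsule mean FA is zero")
    return 100.0 * (mean_ipsi - mean_contra) / mean_contra


def diffusion_report(
    adc: ImageVolume,
    fa: ImageVolume | None,
    labels: ImageVolume,
    scheme: LabelScheme = DEFAULT_LABEL_SCHEME,
    ipsilateral: str = "right",
    **adc_kwargs,
) -> DiffusionReport:
    """ADC summary plus, when an FA map is given, internal-capsule FA change."""
    report = hemisphere_adc_change_percent(adc, labels, scheme, ipsilateral, **adc_kwargs)
    if fa is not None:
        sides = resolve_sides(scheme, ipsilateral)
        report.fa_ipsi = roi_mean_fa(fa, labels, sides["ic_ipsi"], scheme)
        report.fa_contra = roi_mean_fa(fa, labels, sides["ic_contra"], scheme)
        report.fa_change_percent = internal_capsule_fa_change_percent(
            fa, labels, scheme, ipsilateral
        )
    return report
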