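"""Hemisphere/ventricle/cerebellum volumetrics and edema-corrected lesion volume.

Acute infarcts swell: the uncorrected lesion volume LVu measured on the
ipsilateral hemisphere includes the space-occupying effect of edema.  The
correction rescales the combined hemisphere volume by the ratio it would
have had without swelling::

    LVc = (HVc + HVi) - (HVc + HVi - LVu) * (HVc + HVi) / (2 * HVc)

where HVc and HVi are the contralateral and ipsilateral hemisphere
volumes.  When the hemispheres are equal the correction is the identity
(LVc = LVu); ipsilateral swelling (HVi > HVc) shrinks the corrected
lesion.  Swelling and ventricle compression are plain percent changes of
the ipsilateral measure relative to the contralateral one.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .imaging_io import ImageVolume, LabelScheme, DEFAULT_LABEL_SCHEME, mask_volume_cm3, resolve_sides

__all__ = [
    "VolumetryReport",
    "corrected_lesion_volume",
    "swelling_percent",
    "ventricle_compression_percent",
    "segment_lesion",
    "volumetry_report",
]


@dataclass
class VolumetryReport:
    """Volumetric summary for one subject, volumes in cm^3, changes in %."""

    hv_contra: float
    hv_ipsi: float
    lesion_uncorrected: float
    lesion_corrected: float
    swelling_percent: float
    ventricle_ipsi: float
    ventricle_contra: float
    ventricle_compression_percent: float
    cerebellum: float
    #: 100 * LVc / HVi; reported for completeness, the denominator the
    #: original protocol used for its normalized lesion volume is unknown.
    lesion_normalized_percent: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def corrected_lesion_volume(hv_contra: float, hv_ipsi: float, lv_uncorrected: float) -> float:
    """Edema-corrected lesion volume LVc in cm^3.

    Preconditions: ``hv_contra > 0`` and ``0 <= lv_uncorrected <= hv_ipsi``.
    """
    if hv_contra <= 0:
        raise ValueError(f"contralateral hemisphere volume must be positive, got {hv_contra}")
    if lv_uncorrected < 0:
        raise ValueError(f"lesion volume must be non-negative, got {lv_uncorrected}")
    if lv_uncorrected > hv_ipsi:
        raise ValueError(
            f"uncorrected lesion volume {lv_uncorrected} exceeds ipsilateral "
            f"hemisphere volume {hv_ipsi}"
        )
    total = hv_contra + hv_ipsi
    return total - (total - lv_uncorrected) * total / (2.0 * hv_contra)


def swelling_percent(hv_ipsi: float, hv_contra: float) -> float:
    """Hemispheric swelling: 100 * (HVi - HVc) / HVc."""
    if hv_contra <= 0:
        raise ValueError(f"contralateral hemisphere volume must be positive, got {hv_contra}")
    return 100.0 * (hv_ipsi - hv_contra) / hv_contra


def ventricle_compression_percent(v_ipsi: float, v_contra: float) -> float:
    """Lateral-ventricle percent change; negative values indicate compression."""
    if v_contra <= 0:
        raise ValueError(f"contralateral ventricle volume must be positive, got {v_contra}")
    return 100.0 * (v_ipsi - v_contra) / v_contra


def segment_lesion(
    adc: ImageVolume,
    labels: ImageVolume,
    ratio_threshold: float = 0.80,
    scheme: LabelScheme = DEFAULT_LABEL_SCHEME,
    ipsilateral: str = "right",
) -> ImageVolume:
    """Threshold-based lesion segmentation on an ADC map.

    Voxels of the ipsilateral hemisphere whose ADC falls below
    ``ratio_threshold`` times the contralateral-hemisphere mean ADC are
    candidate lesion; the largest 26-connected component is kept.  The
    default threshold 0.80 sits between the diffusivity drop of acute
    infarct (roughly 35-45% below contralateral in this model) and normal
    tissue.  Returns a label volume carrying the lesion code.
    """
    if not (0.0 < ratio_threshold < 1.0):
        raise ValueError(f"ratio_threshold must be in (0, 1), got {ratio_threshold}")
    if not adc.same_grid(labels):
        raise ValueError("ADC map and label volume must share grid shape and spacing")
    sides = resolve_sides(scheme, ipsilateral)
    contra = labels.data == sides["hemisphere_contra"]
    if not contra.any():
        raise ValueError("contralateral hemisphere is empty in the label volume")
    ipsi = labels.data == sides["hemisphere_ipsi"]
    threshold = ratio_threshold * float(np.asarray(adc.data)[contra].mean())
    candidate = ipsi & (np.asarray(adc.data) < threshold)
    mask = np.zeros(labels.shape, dtype=np.int16)
    if candidate.any():
        comp, n = ndimage.label(candidate, structure=np.ones((3, 3, 3), dtype=int))
        largest = int(np.argmax(np.bincount(comp.ravel())[1:])) + 1
        mask[comp == largest] = sides["lesion"]
    return ImageVolume(data=mask, spacing=labels.spacing, modality="label")


def volumetry_report(
    labels: ImageVolume,
    adc: ImageVolume | None = None,
    lesion_mask: ImageVolume | None = None,
    scheme: LabelScheme = DEFAULT_LABEL_SCHEME,
    ipsilateral: str = "right",
    ratio_threshold: float = 0.80,
) -> VolumetryReport:
    """Full volumetric workup for one subject.

    The lesion is taken from ``lesion_mask`` if given, otherwise segmented
    from ``adc``; with neither, lesion volumes are reported as 0.
    """
    sides = resolve_sides(scheme, ipsilateral)
    hv_i = mask_volume_cm3(labels, sides["hemisphere_ipsi"], scheme)
    hv_c = mask_volume_cm3(labels, sides["hemisphere_contra"], scheme)
    v_i = mask_volume_cm3(labels, sides["ventricle_ipsi"], scheme)
    v_c = mask_volume_cm3(labels, sides["ventricle_contra"], scheme)
    cereb = mask_volume_cm3(labels, sides["cerebellum"], scheme)

    if lesion_mask is None and adc is not None:
        lesion_mask = segment_lesion(adc, labels, ratio_threshold, scheme, ipsilateral)
    lv_u = (
        mask_volume_cm3(lesion_mask, sides["lesion"], scheme) if lesion_mask is not None else 0.0
    )
    lv_c = corrected_lesion_volume(hv_c, hv_i, lv_u)
    return VolumetryReport(
        hv_contra=hv_c,
        hv_ipsi=hv_i,
        lesion_uncorrected=lv_u,
        lesion_corrected=lv_c,
        swelling_percent=swelling_percent(hv_i, hv_c),
        ventricle_ipsi=v_i,
        ventricle_contra=v_c,
        ventricle_compression_percent=ventricle_compression_percent(v_i, v_c),
        cerebellum=cereb,
        lesion_normalized_percent=100.0 * lv_c / hv_i if hv_i > 0 else 0.0,
    )
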