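"""Image, label-scheme and landmark I/O.

All volumes are held as 3-D grids in canonical right-anterior-superior
(RAS) axis order with per-axis voxel spacing in mm.  Axis 0 runs
left→right, axis 1 posterior→anterior, axis 2 inferior→superior; a
"coronal slice" is therefore a fixed index along axis 1.  Landmark sets
are planar (axial or midsagittal) with coordinates in mm, because every
linear measurement in the protocol (midline shift, skull length line,
herniation extents) is defined in a single plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "LabelScheme",
    "LandmarkSet",
    "DEFAULT_LABEL_SCHEME",
    "UnknownLabelError",
    "MissingLandmarkError",
    "read_image_volume",
    "write_image_volume",
    "mask_volume_cm3",
    "read_landmarks",
    "write_landmarks",
    "resolve_sides",
]

MODALITIES = ("adc", "fa", "label")

#: Landmark names used by the midsagittal herniation measurements.
SAGITTAL_LANDMARKS = (
    "cribriform_dorsal",
    "sella_dorsal",
    "tentorium_rostral",
    "foramen_magnum_dorsal",
    "foramen_magnum_ventral",
)

#: Landmark names used by the axial midline-shift measurement.
AXIAL_LANDMARKS = ("midline_anterior", "midline_posterior", "septum_pellucidum")


class UnknownLabelError(ValueError):
    """A label code is not registered in the active label scheme."""


class MissingLandmarkError(ValueError):
    """A measurement requires a landmark that the set does not contain."""


@dataclass(frozen=True)
class LabelScheme:
    """Bidirectional map between integer label codes and region names.

    Code 0 is reserved for background and may not be registered.
    """

    codes: dict[int, str]

    def __post_init__(self) -> None:
        if 0 in self.codes:
            raise ValueError("label code 0 is reserved for background")
        names = list(self.codes.values())
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")

    def name(self, code: int) -> str:
        try:
            return self.codes[int(code)]
        except KeyError:
            raise UnknownLabelError(f"label code {int(code)} is not registered") from None

    def code(self, name: str) -> int:
        for c, n in self.codes.items():
            if n == name:
                return c
        raise UnknownLabelError(f"region name {name!r} is not registered")

    def validate_volume(self, data: np.ndarray) -> None:
        present = set(np.unique(data).astype(int).tolist()) - {0}
        unknown = sorted(present - set(self.codes))
        if unknown:
            raise UnknownLabelError(
                f"label volume contains unregistered code(s) {unknown}"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({str(c): n for c, n in self.codes.items()}, indent=1, sort_keys=True)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelScheme":
        raw = json.loads(Path(path).read_text())
        return cls({int(c): str(n) for c, n in raw.items()})


#: Region inventory of the study: hemispheres, cerebellum, lateral
#: ventricles, lesion, internal capsules and corpus callosum.
DEFAULT_LABEL_SCHEME = LabelScheme(
    {
        1: "left_hemisphere",
        2: "right_hemisphere",
        3: "cerebellum",
        4: "left_lateral_ventricle",
        5: "right_lateral_ventricle",
        6: "lesion",
        7: "left_internal_capsule",
        8: "right_internal_capsule",
        9: "corpus_callosum",
    }
)


@dataclass
class ImageVolume:
    """3-D scalar or label grid with voxel spacing in mm.

    ADC maps are in units of 10^-3 mm^2/s, FA maps are dimensionless in
    [0, 1], label volumes carry integer region codes.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got {self.data.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.modality == "fa":
            lo, hi = float(np.min(self.data)), float(np.max(self.data))
            if lo < 0.0 or hi > 1.0:
                raise ValueError(f"FA values must lie in [0, 1], found range [{lo}, {hi}]")
        if self.modality == "label" and not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.array_equal(rounded, self.data):
                raise ValueError("label volume contains non-integer values")
            self.data = rounded.astype(np.int16)

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class LandmarkSet:
    """Named planar points (mm) plus cerebellar contour arcs and caudal normals.

    ``plane`` is ``"midsagittal"`` or ``"axial"``.  ``contours`` may carry
    the single ventral cerebellar contour under ``"ventral"`` or two
    measurement-specific arcs under ``"tentorial"`` (for the
    transtentorial extent TTX) and ``"caudal"`` (for the foramen-magnum
    extent FMX).  ``normals`` optionally stores the caudal unit normal per
    reference line (keys ``"ttl"`` and ``"fml"``); when absent the normal
    is derived from the contour side.
    """

    plane: str
    points: dict[str, np.ndarray]
    contours: dict[str, np.ndarray] = field(default_factory=dict)
    normals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float).reshape(2) for k, v in self.points.items()}
        self.contours = {
            k: np.asarray(v, dtype=float).reshape(-1, 2) for k, v in self.contours.items()
        }
        self.normals = {k: np.asarray(v, dtype=float).reshape(2) for k, v in self.normals.items()}
        for key, arr in self.contours.items():
            if arr.shape[0] < 1:
                raise ValueError(f"contour {key!r} is empty")

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise MissingLandmarkError(
                f"landmark set is missing required point(s): {', '.join(missing)}"
            )
        # line-defining pairs must not be degenerate
        pairs = [
            ("midline_anterior", "midline_posterior"),
            ("sella_dorsal", "tentorium_rostral"),
            ("foramen_magnum_dorsal", "foramen_magnum_ventral"),
            ("cribriform_dorsal", "foramen_magnum_dorsal"),
        ]
        for a, b in pairs:
            if a in names and b in names:
                if np.allclose(self.points[a], self.points[b]):
                    raise ValueError(f"landmarks {a!r} and {b!r} coincide (degenerate line)")

    def contour_for(self, measurement: str) -> np.ndarray:
        """Contour arc for ``measurement`` ('ttx' or 'fmx'), with fallback."""
        key = {"ttx": "tentorial", "fmx": "caudal"}[measurement]
        if key in self.contours:
            return self.contours[key]
        if "ventral" in self.contours:
            return self.contours["ventral"]
        raise MissingLandmarkError(
            f"landmark set has no cerebellar contour for the {measurement.upper()} measurement"
        )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_image_volume(
    path: str | Path,
    modality: str | None = None,
    scheme: LabelScheme | None = None,
) -> ImageVolume:
    """Read a NIfTI-1 volume, reoriented to canonical RAS axis order.

    ``modality`` may be given explicitly or read from a JSON sidecar
    (``{"modality": "adc"}``) written next to the image.  For label
    volumes an optional ``scheme`` validates that every non-zero code is
    registered.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D image, got {data.ndim}-D: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing {spacing} in {path}")
    if modality is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            modality = json.loads(sidecar.read_text()).get("modality")
        if modality is None:
            raise ValueError(
                f"modality not given and no sidecar tag found for {path}; "
                "pass modality='adc'|'fa'|'label'"
            )
    vol = ImageVolume(data=data, spacing=spacing, modality=modality)
    if vol.modality == "label" and scheme is not None:
        scheme.validate_volume(vol.data)
    return vol


def write_image_volume(vol: ImageVolume, path: str | Path, sidecar: bool = True) -> None:
    """Write a volume as NIfTI-1 with an RAS-diagonal affine.

    Grid values round-trip exactly (labels as int16, scalars as float64);
    a JSON sidecar records the modality so ``read_image_volume`` can infer
    it.
    """
    path = Path(path)
    dtype = np.int16 if vol.modality == "label" else np.float64
    affine = np.diag([vol.spacing[0], vol.spacing[1], vol.spacing[2], 1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), affine)
    img.header.set_zooms(vol.spacing)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write image to {path}: {exc}") from exc
    if sidecar:
        _sidecar_path(path).write_text(json.dumps({"modality": vol.modality}))


def mask_volume_cm3(labels: ImageVolume, code: int, scheme: LabelScheme | None = None) -> float:
    """Voxel-counted volume of one label code, in cm^3.

    The voxel-count surrogate for the manual planimetric ROI volumes:
    (number of voxels carrying ``code``) x voxel volume, converted from
    mm^3 to cm^3.  A code absent from the volume yields 0.0.
    """
    if labels.modality != "label":
        raise ValueError("mask_volume_cm3 requires a label volume")
    if scheme is not None:
        scheme.name(code)  # raises UnknownLabelError for unregistered codes
    count = int(np.count_nonzero(labels.data == int(code)))
    return count * labels.voxel_volume_mm3 / 1000.0


def resolve_sides(scheme: LabelScheme, ipsilateral: str = "right") -> dict[str, int]:
    """Map side-relative region roles to label codes.

    The occlusion in this model is right-sided, so ipsilateral defaults to
    the right hemisphere; pass ``ipsilateral='left'`` to flip.
    """
    if ipsilateral not in ("left", "right"):
        raise ValueError("ipsilateral must be 'left' or 'right'")
    contralateral = "left" if ipsilateral == "right" else "right"
    return {
        "hemisphere_ipsi": scheme.code(f"{ipsilateral}_hemisphere"),
        "hemisphere_contra": scheme.code(f"{contralateral}_hemisphere"),
        "ventricle_ipsi": scheme.code(f"{ipsilateral}_lateral_ventricle"),
        "ventricle_contra": scheme.code(f"{contralateral}_lateral_ventricle"),
        "ic_ipsi": scheme.code(f"{ipsilateral}_internal_capsule"),
        "ic_contra": scheme.code(f"{contralateral}_internal_capsule"),
        "cerebellum": scheme.code("cerebellum"),
        "lesion": scheme.code("lesion"),
    }


def read_landmarks(path: str | Path, require: tuple[str, ...] = ()) -> LandmarkSet:
    """Read a planar landmark JSON file.

    Format::

        {"plane": "midsagittal",
         "points": {"cribriform_dorsal": [x, y], ...},
         "contour": [[x, y], ...]                  # single ventral contour
         "contours": {"tentorial": [...], "caudal": [...]},
         "normals": {"ttl": [nx, ny], "fml": [nx, ny]}}

    ``require`` lists landmark names that must be present for the
    requested measurement family; a missing one raises
    :class:`MissingLandmarkError` naming it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such landmark file: {path}")
    raw = json.loads(path.read_text())
    try:
        points = {str(k): np.asarray(v, dtype=float) for k, v in raw.get("points", {}).items()}
        for name, pt in points.items():
            if pt.shape != (2,) or not np.all(np.isfinite(pt)):
                raise ValueError(f"malformed coordinates for landmark {name!r}")
        contours: dict[str, np.ndarray] = {}
        if "contour" in raw:
            contours["ventral"] = np.asarray(raw["contour"], dtype=float)
        for key, arr in raw.get("contours", {}).items():
            contours[str(key)] = np.asarray(arr, dtype=float)
        normals = {str(k): np.asarray(v, dtype=float) for k, v in raw.get("normals", {}).items()}
    except (TypeError, ValueError) as exc:
        raise ValueError(f"malformed landmark file {path}: {exc}") from exc
    lm = LandmarkSet(
        plane=str(raw.get("plane", "midsagittal")),
        points=points,
        contours=contours,
        normals=normals,
    )
    if require:
        lm.require(*require)
    return lm


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    payload: dict = {
        "plane": lm.plane,
        "points": {k: [float(v[0]), float(v[1])] for k, v in sorted(lm.points.items())},
    }
    if lm.contours:
        payload["contours"] = {
            k: [[float(x), float(y)] for x, y in arr] for k, arr in sorted(lm.contours.items())
        }
    if lm.normals:
        payload["normals"] = {
            k: [float(v[0]), float(v[1])] for k, v in sorted(lm.normals.items())
        }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
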