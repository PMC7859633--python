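"""Midline-shift and cerebellar-herniation geometry.

All measurements are planar and landmark-based:

* **MLS** — perpendicular deviation of the septum pellucidum from the
  ideal midline (the line through the anterior and posterior midline
  anchors on the axial plane).  Perpendicular rather than horizontal
  distance makes the measure invariant to head rotation in the scanner.
* **SLL / TTL / FML** — skull length line (dorsal cribriform plate to the
  dorsal foramen magnum margin), transtentorial line (dorsal sella to the
  rostral tentorium) and foramen magnum line (dorsal to ventral foramen
  magnum margin) on the midsagittal plane.
* **TTX / FMX** — maximal perpendicular extent of the ventral cerebellar
  contour beyond the transtentorial / foramen magnum line along the
  caudal direction, clamped at zero when nothing crosses.
* **CTH = TTX/SLL** and **FMH = FMX/SLL** — dimensionless herniation
  indices, invariant under rigid motion and uniform scaling of the plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import LandmarkSet, SAGITTAL_LANDMARKS

__all__ = [
    "GeometryReport",
    "midline_shift_mm",
    "line_length_mm",
    "protrusion_extent_mm",
    "herniation_indices",
]

_PERP_TOL = 1e-6


@dataclass
class GeometryReport:
    """Planar skull/herniation measurements (mm, indices dimensionless)."""

    mls_mm: float
    sll_mm: float
    ttl_mm: float
    fml_mm: float
    ttx_mm: float
    fmx_mm: float
    cth: float
    fmh: float
    #: +1 if the septum is displaced toward the positive normal of the
    #: ideal midline, -1 otherwise, 0 when on the line; MLS itself is
    #: reported as an unsigned magnitude.
    mls_direction: int = 0


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(2)
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError(f"{what} is a zero vector")
    return v / n


def _signed_distance(p: np.ndarray, a: np.ndarray, n_hat: np.ndarray) -> float:
    return float(np.dot(np.asarray(p, dtype=float) - np.asarray(a, dtype=float), n_hat))


def line_length_mm(p, q) -> float:
    """Euclidean distance between two planar points, mm."""
    return float(np.linalg.norm(np.asarray(p, dtype=float) - np.asarray(q, dtype=float)))


def midline_shift_mm(anterior, posterior, septum) -> float:
    """Perpendicular distance (mm) from the septum to the ideal midline."""
    anterior = np.asarray(anterior, dtype=float)
    posterior = np.asarray(posterior, dtype=float)
    if np.allclose(anterior, posterior):
        raise ValueError("midline endpoints coincide (degenerate line)")
    d_hat = _unit(posterior - anterior, "midline direction")
    n_hat = np.array([-d_hat[1], d_hat[0]])
    return abs(_signed_distance(septum, anterior, n_hat))


def protrusion_extent_mm(line_a, line_b, contour, caudal_normal) -> float:
    """Maximum perpendicular extent of ``contour`` beyond the line a-b.

    ``caudal_normal`` is the unit normal of the line pointing in the
    caudal (protrusion) direction; it must be perpendicular to the line
    within 1e-6.  Points on the non-protruded side contribute negatively
    and the result is clamped at 0.  Ties between contour points resolve
    to the same value by construction (the maximum).
    """
    line_a = np.asarray(line_a, dtype=float)
    line_b = np.asarray(line_b, dtype=float)
    if np.allclose(line_a, line_b):
        raise ValueError("reference line endpoints coincide (degenerate line)")
    contour = np.asarray(contour, dtype=float).reshape(-1, 2)
    if contour.shape[0] == 0:
        raise ValueError("contour is empty")
    d_hat = _unit(line_b - line_a, "line direction")
    n_hat = _unit(caudal_normal, "caudal normal")
    if abs(float(np.dot(n_hat, d_hat))) > _PERP_TOL:
        raise ValueError("caudal normal is not perpendicular to the reference line")
    distances = (contour - line_a) @ n_hat
    return max(0.0, float(distances.max()))


def _caudal_normal(line_a, line_b, toward: np.ndarray) -> np.ndarray:
    """Unit normal of line a-b oriented toward the point ``toward``.

    Used when the landmark file supplies no explicit normal: the caudal
    direction for each protrusion is the side of the line on which the
    measured cerebellar arc lies.
    """
    d_hat = _unit(np.asarray(line_b, dtype=float) - np.asarray(line_a, dtype=float), "line")
    n_hat = np.array([-d_hat[1], d_hat[0]])
    mid = (np.asarray(line_a, dtype=float) + np.asarray(line_b, dtype=float)) / 2.0
    if float(np.dot(np.asarray(toward, dtype=float) - mid, n_hat)) < 0:
        n_hat = -n_hat
    return n_hat


def herniation_indices(landmarks: LandmarkSet, septum_landmarks: LandmarkSet | None = None) -> GeometryReport:
    """Compute SLL, TTL, FML, TTX, FMX and the indices CTH, FMH.

    ``landmarks`` is the midsagittal set; an optional axial
    ``septum_landmarks`` set adds the midline shift to the report
    (otherwise MLS is reported as NaN).
    """
    landmarks.require(*SAGITTAL_LANDMARKS)
    crib = landmarks.points["cribriform_dorsal"]
    sella = landmarks.points["sella_dorsal"]
    tent = landmarks.points["tentorium_rostral"]
    fm_d = landmarks.points["foramen_magnum_dorsal"]
    fm_v = landmarks.points["foramen_magnum_ventral"]

    sll = line_length_mm(crib, fm_d)
    if sll == 0:
        raise ValueError("skull length line has zero length")
    ttl = line_length_mm(sella, tent)
    fml = line_length_mm(fm_d, fm_v)

    contour_ttx = landmarks.contour_for("ttx")
    contour_fmx = landmarks.contour_for("fmx")
    n_ttl = landmarks.normals.get("ttl")
    if n_ttl is None:
        n_ttl = _caudal_normal(sella, tent, contour_ttx.mean(axis=0))
    n_fml = landmarks.normals.get("fml")
    if n_fml is None:
        n_fml = _caudal_normal(fm_d, fm_v, contour_fmx.mean(axis=0))

    ttx = protrusion_extent_mm(sella, tent, contour_ttx, n_ttl)
    fmx = protrusion_extent_mm(fm_d, fm_v, contour_fmx, n_fml)

    mls = float("nan")
    direction = 0
    if septum_landmarks is not None:
        septum_landmarks.require("midline_anterior", "midline_posterior", "septum_pellucidum")
        a = septum_landmarks.points["midline_anterior"]
        p = septum_landmarks.points["midline_posterior"]
        s = septum_landmarks.points["septum_pellucidum"]
        mls = midline_shift_mm(a, p, s)
        d_hat = _unit(p - a, "midline direction")
        n_hat = np.array([-d_hat[1], d_hat[0]])
        signed = _signed_distance(s, a, n_hat)
        direction = 0 if signed == 0 else (1 if signed > 0 else -1)

    return GeometryReport(
        mls_mm=mls,
        sll_mm=sll,
        ttl_mm=ttl,
        fml_mm=fml,
        ttx_mm=ttx,
        fmx_mm=fmx,
        cth=ttx / sll,
        fmh=fmx / sll,
        mls_direction=direction,
    )
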