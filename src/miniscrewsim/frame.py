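"""Occlusal coordinate frame recovery and the posterior reference line.

The standardized frame is right-handed with ``ez`` perpendicular to the
occlusal plane (apical for the maxilla), ``ex`` along the transverse line
through the maxillary first-molar mesiobuccal cusps (right to left) and
``ey = ez x ex``.  All downstream distance measurements are taken in this
frame; recovering it from landmarks and mapping a scene back into it is a
rigid transform, so distances and angles are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import SegmentModel, SubjectLandmarks

__all__ = ["OcclusalFrame", "ReferenceLine", "build_occlusal_frame", "to_frame",
           "posterior_reference_line"]


@dataclass
class OcclusalFrame:
    """An orthonormal, right-handed frame anchored on the occlusal plane."""

    origin: np.ndarray
    ex: np.ndarray
    ey: np.ndarray
    ez: np.ndarray

    def __post_init__(self) -> None:
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("frame must be right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose columns are ``ex, ey, ez``."""
        return np.column_stack((self.ex, self.ey, self.ez))

    @property
    def matrix(self) -> np.ndarray:
        """4x4 rigid transform mapping frame coordinates to scene coordinates."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.origin
        return m

    @property
    def inverse_matrix(self) -> np.ndarray:
        """4x4 rigid transform mapping scene coordinates into the frame."""
        m = np.eye(4)
        m[:3, :3] = self.rotation.T
        m[:3, 3] = -self.rotation.T @ self.origin
        return m

    @classmethod
    def identity(cls) -> "OcclusalFrame":
        return cls(np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
                   np.array([0, 0, 1.0]))


@dataclass
class ReferenceLine:
    """The measurement direction: a line through two molar buccal cusps."""

    point: np.ndarray
    direction: np.ndarray  # unit, oriented mesial -> distal

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("reference line direction must be nonzero")
        self.direction = d / n


def build_occlusal_frame(
    occlusal_points: np.ndarray,
    mb_cusp_right: np.ndarray,
    mb_cusp_left: np.ndarray,
    apical_hint: np.ndarray | None = None,
) -> OcclusalFrame:
    """Recover the occlusal frame from landmarks.

    ``ez`` is the unit normal of the least-squares plane through
    ``occlusal_points`` (oriented toward ``apical_hint`` when given), ``ex``
    the unit vector from the right to the left first-molar mesiobuccal cusp
    projected into that plane, ``ey = ez x ex`` and the origin the cusp
    midpoint.

    Raises ``ValueError`` for degenerate landmark sets (collinear occlusal
    points, coincident cusps, cusp line perpendicular to the plane).
    """
    pts = np.asarray(occlusal_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("need at least three occlusal landmarks")
    right = np.asarray(mb_cusp_right, dtype=float)
    left = np.asarray(mb_cusp_left, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("occlusal landmarks are collinear; plane is undefined")
    ez = vt[2]
    if apical_hint is not None:
        hint = np.asarray(apical_hint, dtype=float) - pts.mean(axis=0)
        if np.dot(ez, hint) < 0:
            ez = -ez
    elif ez[np.argmax(np.abs(ez))] < 0:  # deterministic sign without a hint
        ez = -ez
    chord = left - right
    if np.linalg.norm(chord) < 1e-9:
        raise ValueError("molar cusp landmarks coincide")
    ex = chord - np.dot(chord, ez) * ez
    nx = np.linalg.norm(ex)
    if nx < 1e-9:
        raise ValueError("inter-cusp line is perpendicular to the occlusal plane")
    ex = ex / nx
    ey = np.cross(ez, ex)
    origin = 0.5 * (left + right)
    return OcclusalFrame(origin=origin, ex=ex, ey=ey, ez=ez)


def to_frame(geometry, frame: OcclusalFrame):
    """Express ``geometry`` in ``frame`` coordinates (rigid, no scaling).

    Accepts an ``(N, 3)`` / ``(3,)`` array of points, a
    :class:`~miniscrewsim.anatomy.SegmentModel` (whose pose is composed with
    the inverse frame transform) or a
    :class:`~miniscrewsim.anatomy.SubjectLandmarks`.
    """
    m = frame.inverse_matrix
    if isinstance(geometry, SegmentModel):
        return geometry.with_pose(m)
    if isinstance(geometry, SubjectLandmarks):
        return geometry.transformed(m)
    pts = np.asarray(geometry, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = pts @ m[:3, :3].T + m[:3, 3]
    return out[0] if single else out


def posterior_reference_line(segment: SegmentModel) -> ReferenceLine:
    """Line through the buccal cusps of the first and second molars.

    The direction is normalized and oriented mesial to distal (from the
    first toward the second molar).  The generator emits both molar cusps
    for every segment, including "5-6" sites.
    """
    c6 = segment.landmark("molar_cusp_mesial")
    c7 = segment.landmark("molar_cusp_distal")
    d = c7 - c6
    if np.linalg.norm(d) < 1e-9:
        raise ValueError("molar cusp landmarks coincide; reference line undefined")
    return ReferenceLine(point=c6, direction=d)
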