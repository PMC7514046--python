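"""Tapered miniscrew geometry and interradicular placement.

The screw is a solid of revolution: a linear frustum of default neck
diameter 1.5 mm, length 6 mm and configurable tip diameter (0.6 mm by
default; equal neck/tip diameters give a cylinder).  Threads are not
modelled; the whole shank counts as the threaded portion for the
all-threads-in-bone check.

Placement protocol, all in the standardized frame:

1. insertion point on the buccal cortical sheet, 4 mm apical of the mean
   CEJ level of the two adjacent teeth, at the interradicular mesiodistal
   midpoint;
2. at 0 deg the axis is purely buccolingual (parallel to the occlusal
   plane), neck at the insertion point, apex 6 mm lingually;
3. angulation rotates the axis about the mesiodistal axis through the
   insertion point so the tip points apically, then re-seats the neck on
   the sheet so the head stays in contact with bone.  The mesiodistal
   coordinate of the axis never changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .anatomy import SegmentModel

__all__ = [
    "ScrewGeometry",
    "ScrewPlacement",
    "BoneCheck",
    "PlacementError",
    "build_screw",
    "initial_placement",
    "angulate",
    "check_in_bone",
    "DEFAULT_ANGLES",
    "CEJ_OFFSET_MM",
]

DEFAULT_ANGLES = (0, 30, 45, 60)
CEJ_OFFSET_MM = 4.0


class PlacementError(ValueError):
    """Raised when no placement satisfies the protocol's constraints."""


@dataclass(frozen=True)
class ScrewGeometry:
    """Tapered screw body: linear radius profile from neck to tip."""

    length: float = 6.0
    neck_diameter: float = 1.5
    tip_diameter: float = 0.6

    def __post_init__(self) -> None:
        if self.length <= 0 or self.neck_diameter <= 0 or self.tip_diameter <= 0:
            raise ValueError("screw dimensions must be positive")
        if self.tip_diameter > self.neck_diameter:
            raise ValueError("tip diameter cannot exceed neck diameter")

    def radius(self, s):
        """Radius at axial position ``s`` in ``[0, length]`` (0 = neck)."""
        s = np.asarray(s, dtype=float)
        r0 = self.neck_diameter / 2.0
        r1 = self.tip_diameter / 2.0
        return r0 + (r1 - r0) * s / self.length

    @property
    def taper_rate(self) -> float:
        """d(radius)/ds along the axis (non-positive)."""
        return (self.tip_diameter - self.neck_diameter) / (2.0 * self.length)


def build_screw(config=None, **kwargs) -> ScrewGeometry:
    """Construct a :class:`ScrewGeometry` from a mapping or keyword arguments."""
    cfg = dict(config or {})
    cfg.update(kwargs)
    return ScrewGeometry(
        length=float(cfg.get("length", 6.0)),
        neck_diameter=float(cfg.get("neck_diameter", 1.5)),
        tip_diameter=float(cfg.get("tip_diameter", 0.6)),
    )


@dataclass
class ScrewPlacement:
    """A posed screw: insertion point, axis (head to tip) and angle."""

    insertion_point: np.ndarray
    axis: np.ndarray
    angle: float
    neck_point: np.ndarray
    apex_point: np.ndarray
    screw: ScrewGeometry = field(default_factory=ScrewGeometry)

    def __post_init__(self) -> None:
        self.insertion_point = np.asarray(self.insertion_point, dtype=float)
        self.neck_point = np.asarray(self.neck_point, dtype=float)
        self.apex_point = np.asarray(self.apex_point, dtype=float)
        a = np.asarray(self.axis, dtype=float)
        self.axis = a / np.linalg.norm(a)

    # -- derived frame -----------------------------------------------------
    def perp_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two unit vectors spanning the plane perpendicular to the axis."""
        a = self.axis
        helper = np.array([0.0, 1.0, 0.0])
        if abs(np.dot(a, helper)) > 0.9:
            helper = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(a, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        return e1, e2

    def surface_points(self, n_axial: int = 25, n_theta: int = 24) -> np.ndarray:
        """Sample the lateral surface plus both end-cap rims."""
        e1, e2 = self.perp_basis()
        s = np.linspace(0.0, self.screw.length, n_axial)
        th = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
        S, TH = np.meshgrid(s, th, indexing="ij")
        r = self.screw.radius(S)
        pts = (
            self.neck_point[None, None, :]
            + S[..., None] * self.axis[None, None, :]
            + (r * np.cos(TH))[..., None] * e1[None, None, :]
            + (r * np.sin(TH))[..., None] * e2[None, None, :]
        )
        return pts.reshape(-1, 3)

    def z_extent(self) -> tuple[float, float]:
        """Vertical extent of the solid (axis span widened by the rim radii)."""
        a = self.axis
        sin_t = float(np.sqrt(max(0.0, 1.0 - a[2] ** 2)))
        r0 = self.screw.radius(0.0)
        r1 = self.screw.radius(self.screw.length)
        zs = [
            self.neck_point[2] - r0 * sin_t,
            self.neck_point[2] + r0 * sin_t,
            self.apex_point[2] - r1 * sin_t,
            self.apex_point[2] + r1 * sin_t,
        ]
        return (min(zs), max(zs))

    def inside(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        """Vectorized solid-containment test."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = pts - self.neck_point
        s = rel @ self.axis
        perp = rel - np.outer(s, self.axis)
        dist = np.linalg.norm(perp, axis=1)
        ok = (s >= -tol) & (s <= self.screw.length + tol)
        return ok & (dist <= self.screw.radius(np.clip(s, 0, self.screw.length)) + tol)


@dataclass
class BoneCheck:
    """Outcome of the all-threads-in-bone check."""

    ok: bool
    reason: str = ""
    point: np.ndarray | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def _interradicular_midpoint_y(segment: SegmentModel, z: float) -> float:
    """Mesiodistal midpoint between the facing root surfaces at height ``z``."""
    sa = segment.anterior.root.section(z)
    sp = segment.posterior.root.section(z)
    if sa is None or sp is None:
        raise PlacementError("roots do not span the insertion level")
    ant_distal = sa[1] - sa[3]   # cy - r_md: most distal point of anterior root
    post_mesial = sp[1] + sp[3]  # cy + r_md: most mesial point of posterior root
    return 0.5 * (ant_distal + post_mesial)


def initial_placement(
    segment: SegmentModel,
    screw: ScrewGeometry | None = None,
    cej_offset: float = CEJ_OFFSET_MM,
) -> ScrewPlacement:
    """Horizontal (0 deg) placement per the protocol.

    The neck rests on the cortical sheet at the insertion point; the axis
    points lingually, parallel to the occlusal plane, with zero mesiodistal
    component.
    """
    segment.require_standardized()
    screw = screw or ScrewGeometry()
    z_ins = segment.cej_z + segment.apical_sign * cej_offset
    y_mid = _interradicular_midpoint_y(segment, z_ins)
    x_ins = float(segment.bone.x_buccal(y_mid, z_ins))
    insertion = np.array([x_ins, y_mid, z_ins])
    axis = np.array([-float(segment.buccal_sign), 0.0, 0.0])
    placement = ScrewPlacement(
        insertion_point=insertion,
        axis=axis,
        angle=0.0,
        neck_point=insertion,
        apex_point=insertion + screw.length * axis,
        screw=screw,
    )
    check = check_in_bone(placement, segment)
    if not check.ok:
        raise PlacementError(f"initial placement violates bone constraints: {check.reason}")
    return placement


def angulate(
    placement: ScrewPlacement,
    angle: float,
    segment: SegmentModel,
    enforce_in_bone: bool = True,
) -> ScrewPlacement:
    """Rotate a 0-deg placement to ``angle`` degrees, tip pointing apically.

    The rotation is about the mesiodistal axis through the insertion point,
    so every axis point keeps its mesiodistal coordinate; the neck is then
    re-seated along the new axis so the head remains on the cortical sheet.
    """
    segment.require_standardized()
    if abs(placement.angle) > 1e-9:
        raise ValueError("angulate expects the 0-degree placement as input")
    theta = np.deg2rad(angle)
    b = float(segment.buccal_sign)
    axis = np.array(
        [-b * np.cos(theta), 0.0, segment.apical_sign * np.sin(theta)]
    )
    insertion = placement.insertion_point

    # Seating: the tilted neck cap's rim reaches up to r0 * sqrt(1 - ax^2)
    # buccally of the neck centre, so the neck is advanced along the axis
    # until the most buccal rim point lies on the sheet (head in contact,
    # no thread buccal of bone).  t = 0 for a 0-degree placement.
    r0 = placement.screw.radius(0.0)
    rim_reach = r0 * math.sqrt(max(0.0, 1.0 - axis[0] ** 2))

    def rim_excess(t: float) -> float:
        p = insertion + t * axis
        return b * p[0] + rim_reach - b * segment.bone.x_buccal(p[1], p[2])

    if rim_excess(0.0) <= 1e-12:
        t0 = 0.0
    else:
        hi = 4.0
        if rim_excess(hi) > 0:
            raise PlacementError("cannot re-seat screw head on the cortical sheet")
        t0 = brentq(rim_excess, 0.0, hi, xtol=1e-12)
    neck = insertion + t0 * axis
    new = ScrewPlacement(
        insertion_point=insertion,
        axis=axis,
        angle=float(angle),
        neck_point=neck,
        apex_point=neck + placement.screw.length * axis,
        screw=placement.screw,
    )
    if enforce_in_bone:
        check = check_in_bone(new, segment)
        if not check.ok:
            raise PlacementError(
                f"angulated placement ({angle} deg) violates bone constraints: {check.reason}"
            )
    return new


def check_in_bone(
    placement: ScrewPlacement,
    segment: SegmentModel,
    n_axial: int = 25,
    n_theta: int = 24,
    tol: float = 1e-6,
) -> BoneCheck:
    """Sampled all-threads-in-bone check against the modelled bone slab."""
    pts = placement.surface_points(n_axial=n_axial, n_theta=n_theta)
    ok = segment.bone.in_bone(pts, tol=tol)
    if bool(np.all(ok)):
        return BoneCheck(ok=True)
    bad = pts[~ok][0]
    b = segment.buccal_sign
    xb = float(segment.bone.x_buccal(bad[1], bad[2]))
    if b * bad[0] > b * xb + tol:
        reason = "thread sample buccal of the cortical sheet"
    elif b * bad[0] < b * xb - segment.bone.thickness_at(bad[2]) - tol:
        reason = "thread sample lingual of the modelled ridge (screw exits bone)"
    else:
        reason = "thread sample outside the vertical bone band"
    return BoneCheck(ok=False, reason=reason, point=bad)
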