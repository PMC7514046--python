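"""Seeded generator of parametric 3D posterior dental segments and cohorts.

All geometry lives in a standardized, right-handed "occlusal" frame, local to
each interradicular site:

* ``x``  -- buccolingual (transverse).  Buccal is ``+x`` for left-side
  segments and ``-x`` for right-side segments (``SegmentModel.buccal_sign``).
* ``y``  -- mesiodistal.  Mesial (toward the dental midline along the arch)
  is ``+y``; the anterior tooth of a segment therefore sits at positive
  ``y`` and the posterior tooth at negative ``y``.
* ``z``  -- vertical, with the occlusal plane at ``z = 0``.  Apical is
  ``+z`` for maxillary segments and ``-z`` for mandibular segments
  (``SegmentModel.apical_sign``).

Units are millimetres throughout.

Root surfaces are tapered elliptical tubes stacked along near-vertical axes:
the horizontal cross-section at any height is an ellipse whose centre drifts
with the (possibly tilted) root axis and an optional quadratic mesiodistal
"bow", and whose semi-axes shrink linearly with normalized depth.  This makes
axial cross-sections, widths and ray intersections closed-form while still
producing the site-specific interradicular width-vs-depth profiles the
downstream measurement depends on (monotone widening at "5-6" sites and at
the mandibular "6-7" site; a mid-root constriction at the maxillary "6-7"
site realised through opposing bows).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "HYPERDIVERGENT",
    "NORMODIVERGENT",
    "HYPODIVERGENT",
    "EXCLUDED",
    "GROUPS",
    "classify_facial_type",
    "RootSurface",
    "make_root",
    "ToothModel",
    "CorticalSheet",
    "SegmentModel",
    "SubjectLandmarks",
    "Subject",
    "FacialTypeParams",
    "DEFAULT_FACIAL_PARAMS",
    "RootParams",
    "SiteParams",
    "SITE_DEFAULTS",
    "make_segment",
    "interradicular_width",
    "CohortConfig",
    "simulate_cohort",
    "JAWS",
    "SITES",
    "SIDES",
]

JAWS = ("Mx", "Mn")
SITES = ("5-6", "6-7")
SIDES = ("left", "right")

HYPERDIVERGENT = "hyperdivergent"
NORMODIVERGENT = "normodivergent"
HYPODIVERGENT = "hypodivergent"
EXCLUDED = "EXCLUDED"
GROUPS = (HYPERDIVERGENT, NORMODIVERGENT, HYPODIVERGENT)

_IDENTITY = np.eye(4)


# ---------------------------------------------------------------------------
# Facial type classification
# ---------------------------------------------------------------------------

def classify_facial_type(mp_angle: float, fhi: float) -> str:
    """Classify a vertical facial type from two cephalometric measurements.

    Parameters
    ----------
    mp_angle:
        Mandibular plane angle (S-N/Go-Me) in degrees.  ``< 27`` indicates
        hypodivergence, ``27..37`` normodivergence, ``> 37`` hyperdivergence.
    fhi:
        Facial height index (S-Go/N-Me) in percent.  ``< 61`` indicates
        hyperdivergence, ``61..69`` normodivergence, ``> 69`` hypodivergence.

    Returns
    -------
    str
        One of the three group labels when both rules agree, or
        :data:`EXCLUDED` when they disagree.  Values exactly on a boundary
        are assigned to the normodivergent band.
    """
    if not (math.isfinite(mp_angle) and math.isfinite(fhi)):
        raise ValueError("facial measurements must be finite")
    if mp_angle < 27.0:
        by_angle = HYPODIVERGENT
    elif mp_angle <= 37.0:
        by_angle = NORMODIVERGENT
    else:
        by_angle = HYPERDIVERGENT
    if fhi < 61.0:
        by_ratio = HYPERDIVERGENT
    elif fhi <= 69.0:
        by_ratio = NORMODIVERGENT
    else:
        by_ratio = HYPODIVERGENT
    return by_angle if by_angle == by_ratio else EXCLUDED


# ---------------------------------------------------------------------------
# Root / tooth / bone primitives
# ---------------------------------------------------------------------------

def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3D point, got shape {a.shape}")
    return a


@dataclass
class RootSurface:
    """A tapered elliptical root tube with optional mesiodistal bow.

    The tube is a stack of horizontal ellipses.  At axial depth
    ``d = t * length`` (``t`` in ``[0, 1]``) the cross-section is centred at
    ``cej_center + d * axis + bow * 4 t (1 - t) * y_hat`` with semi-axes
    ``semi_axis_bl * (1 - taper * t)`` along ``x`` and
    ``semi_axis_md * (1 - taper * t)`` along ``y``.  Positive ``bow``
    displaces the mid-root centreline mesially (``+y``).
    """

    cej_center: np.ndarray
    axis: np.ndarray
    length: float
    semi_axis_md: float
    semi_axis_bl: float
    taper: float = 0.0
    bow: float = 0.0

    def __post_init__(self) -> None:
        self.cej_center = _as_point(self.cej_center)
        axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("root axis must be nonzero")
        self.axis = axis / n
        if abs(self.axis[2]) < 1e-6:
            raise ValueError("root axis must have a vertical component")
        if self.length <= 0:
            raise ValueError("root length must be positive")
        if self.semi_axis_md <= 0 or self.semi_axis_bl <= 0:
            raise ValueError("root semi-axes must be positive")
        if not (0.0 <= self.taper < 1.0):
            raise ValueError("taper must lie in [0, 1)")

    # -- geometry ----------------------------------------------------------
    @property
    def apex(self) -> np.ndarray:
        return self.cej_center + self.length * self.axis

    @property
    def z_range(self) -> tuple[float, float]:
        z0, z1 = self.cej_center[2], self.apex[2]
        return (min(z0, z1), max(z0, z1))

    def depth_at_z(self, z: float) -> float | None:
        """Axial depth ``d`` such that the section centre is at height ``z``."""
        d = (z - self.cej_center[2]) / self.axis[2]
        if d < -1e-9 or d > self.length + 1e-9:
            return None
        return float(np.clip(d, 0.0, self.length))

    def section(self, z: float) -> tuple[float, float, float, float] | None:
        """Horizontal cross-section at height ``z``.

        Returns ``(cx, cy, rx, ry)`` -- ellipse centre and semi-axes along
        ``x`` (buccolingual) and ``y`` (mesiodistal) -- or ``None`` when the
        root does not reach ``z``.
        """
        d = self.depth_at_z(z)
        if d is None:
            return None
        t = d / self.length
        shrink = 1.0 - self.taper * t
        cx = self.cej_center[0] + d * self.axis[0]
        cy = self.cej_center[1] + d * self.axis[1] + self.bow * 4.0 * t * (1.0 - t)
        return (cx, cy, self.semi_axis_bl * shrink, self.semi_axis_md * shrink)

    def boundary(self, z: float, n: int = 360) -> np.ndarray | None:
        """Polygonal approximation of the section boundary (counterclockwise)."""
        sec = self.section(z)
        if sec is None:
            return None
        cx, cy, rx, ry = sec
        th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return np.column_stack((cx + rx * np.cos(th), cy + ry * np.sin(th)))

    def inside(self, points: np.ndarray) -> np.ndarray:
        """Vectorized containment test for an ``(N, 3)`` array of points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = (pts[:, 2] - self.cej_center[2]) / self.axis[2]
        valid = (d >= 0.0) & (d <= self.length)
        t = np.clip(d / self.length, 0.0, 1.0)
        shrink = 1.0 - self.taper * t
        cx = self.cej_center[0] + d * self.axis[0]
        cy = self.cej_center[1] + d * self.axis[1] + self.bow * 4.0 * t * (1.0 - t)
        rx = self.semi_axis_bl * shrink
        ry = self.semi_axis_md * shrink
        val = ((pts[:, 0] - cx) / rx) ** 2 + ((pts[:, 1] - cy) / ry) ** 2
        return valid & (val <= 1.0)


def make_root(
    cej_center,
    axis,
    length: float,
    semi_axis_md: float,
    semi_axis_bl: float,
    taper: float = 0.0,
    bow: float = 0.0,
) -> RootSurface:
    """Validated constructor for :class:`RootSurface`."""
    return RootSurface(
        cej_center=_as_point(cej_center),
        axis=np.asarray(axis, dtype=float),
        length=float(length),
        semi_axis_md=float(semi_axis_md),
        semi_axis_bl=float(semi_axis_bl),
        taper=float(taper),
        bow=float(bow),
    )


@dataclass
class ToothModel:
    """A tooth reduced to the root surface(s) that face the screw corridor."""

    label: int  # 5 = second premolar, 6 = first molar, 7 = second molar
    roots: list[RootSurface]
    buccal_cusp: np.ndarray
    cej_level: float

    def __post_init__(self) -> None:
        self.buccal_cusp = _as_point(self.buccal_cusp)
        if not self.roots:
            raise ValueError("tooth needs at least one root")
        for r in self.roots:
            if abs(r.cej_center[2] - self.cej_level) > 1e-6:
                raise ValueError("all roots must originate at the tooth CEJ level")

    @property
    def root(self) -> RootSurface:
        return self.roots[0]


@dataclass
class CorticalSheet:
    """Buccal cortical/ridge sheet: a graph ``|x| = f(z)`` plus a thickness.

    ``buccal_offset`` is the unsigned buccolingual distance from the segment
    origin to the buccal bone surface at the CEJ level; ``slope`` tilts the
    sheet with apical depth.  ``thickness`` is the total (cortical +
    cancellous) ridge thickness available lingually of the sheet, again with
    an optional linear depth profile.  Bone is modelled from ``crest_offset``
    mm apical of the CEJ down to ``apical_extent``.
    """

    buccal_offset: float
    thickness: float
    cej_z: float
    apical_sign: int
    buccal_sign: int
    slope: float = 0.0
    thickness_slope: float = 0.0
    crest_offset: float = 0.8
    apical_extent: float = 30.0

    def __post_init__(self) -> None:
        if self.buccal_offset <= 0:
            raise ValueError("buccal offset must be positive")
        if self.thickness <= 0:
            raise ValueError("ridge thickness must be positive")

    def depth(self, z) -> np.ndarray:
        return self.apical_sign * (np.asarray(z, dtype=float) - self.cej_z)

    def x_buccal(self, y, z):
        """Signed ``x`` of the buccal bone surface at ``(y, z)``."""
        return self.buccal_sign * (self.buccal_offset + self.slope * self.depth(z))

    def thickness_at(self, z):
        return self.thickness + self.thickness_slope * self.depth(z)

    def in_bone(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.depth(pts[:, 2])
        xb = self.buccal_offset + self.slope * d
        xs = self.buccal_sign * pts[:, 0]  # buccal-positive coordinate
        ok = (xs <= xb + tol) & (xs >= xb - self.thickness_at(pts[:, 2]) - tol)
        ok &= (d >= self.crest_offset - tol) & (d <= self.apical_extent + tol)
        return ok


@dataclass
class SegmentModel:
    """One interradicular site: two adjacent teeth, buccal bone and landmarks.

    ``molar_cusp_mesial`` / ``molar_cusp_distal`` are the buccal cusps of the
    first and second molars used for the posterior reference line; they are
    always emitted, including for "5-6" segments.  ``pose`` is a rigid 4x4
    transform mapping the canonical (standardized) coordinates stored in the
    parametric fields to the scene's current coordinates; landmark accessors
    apply it, while the analytic machinery requires ``pose`` to be identity
    (see :func:`miniscrewsim.frame.to_frame`).
    """

    jaw: str
    site: str
    side: str
    anterior: ToothModel
    posterior: ToothModel
    bone: CorticalSheet
    molar_cusp_mesial: np.ndarray
    molar_cusp_distal: np.ndarray
    pose: np.ndarray = field(default_factory=lambda: _IDENTITY.copy())

    def __post_init__(self) -> None:
        if self.jaw not in JAWS:
            raise ValueError(f"jaw must be one of {JAWS}")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        self.molar_cusp_mesial = _as_point(self.molar_cusp_mesial)
        self.molar_cusp_distal = _as_point(self.molar_cusp_distal)
        self.pose = np.asarray(self.pose, dtype=float).reshape(4, 4)
        if self.anterior.root.cej_center[1] <= self.posterior.root.cej_center[1]:
            raise ValueError("anterior tooth must be mesial (+y) of posterior tooth")

    # -- conventions -------------------------------------------------------
    @property
    def apical_sign(self) -> int:
        return 1 if self.jaw == "Mx" else -1

    @property
    def buccal_sign(self) -> int:
        return 1 if self.side == "left" else -1

    @property
    def cej_z(self) -> float:
        return 0.5 * (self.anterior.cej_level + self.posterior.cej_level)

    @property
    def is_standardized(self) -> bool:
        return bool(np.allclose(self.pose, _IDENTITY, atol=1e-6))

    # -- pose handling -----------------------------------------------------
    def with_pose(self, matrix: np.ndarray) -> "SegmentModel":
        """Return a copy whose pose is ``matrix @ pose``."""
        m = np.asarray(matrix, dtype=float).reshape(4, 4)
        seg = copy.deepcopy(self)
        seg.pose = m @ self.pose
        return seg

    def _apply_pose(self, p: np.ndarray) -> np.ndarray:
        return self.pose[:3, :3] @ p + self.pose[:3, 3]

    def landmark(self, name: str) -> np.ndarray:
        """Posed landmark coordinates (``molar_cusp_mesial`` etc.)."""
        return self._apply_pose(getattr(self, name))

    def require_standardized(self) -> None:
        if not self.is_standardized:
            raise ValueError(
                "segment is not in the standardized occlusal frame; "
                "recover the frame and apply miniscrewsim.frame.to_frame first"
            )


@dataclass
class SubjectLandmarks:
    """Subject-level landmarks used to recover the occlusal frame.

    In canonical coordinates the occlusal plane is ``z = 0``, the maxillary
    first-molar mesiobuccal cusps sit at ``(+/- arch half-width, 0, 0)`` and
    the apical hint points toward maxillary apical (``+z``), so the canonical
    frame recovered from these landmarks is the identity.
    """

    occlusal_points: np.ndarray
    mb_cusp_right: np.ndarray
    mb_cusp_left: np.ndarray
    apical_hint: np.ndarray

    @classmethod
    def canonical(cls, arch_half_width: float = 25.0) -> "SubjectLandmarks":
        return cls(
            occlusal_points=np.array(
                [[-arch_half_width, 0.0, 0.0], [arch_half_width, 0.0, 0.0], [0.0, 22.0, 0.0]]
            ),
            mb_cusp_right=np.array([-arch_half_width, 0.0, 0.0]),
            mb_cusp_left=np.array([arch_half_width, 0.0, 0.0]),
            apical_hint=np.array([0.0, 10.0, 30.0]),
        )

    def transformed(self, matrix: np.ndarray) -> "SubjectLandmarks":
        m = np.asarray(matrix, dtype=float).reshape(4, 4)

        def tp(p):
            return m[:3, :3] @ np.asarray(p, float) + m[:3, 3]

        return SubjectLandmarks(
            occlusal_points=np.array([tp(p) for p in self.occlusal_points]),
            mb_cusp_right=tp(self.mb_cusp_right),
            mb_cusp_left=tp(self.mb_cusp_left),
            apical_hint=tp(self.apical_hint),
        )


@dataclass
class Subject:
    """A simulated subject: covariates plus bilateral segments."""

    id: str
    sex: str  # "M" | "F"
    mp_angle: float
    fhi: float
    facial_type: str
    segments: dict[tuple[str, str, str], SegmentModel]
    landmarks: SubjectLandmarks = field(default_factory=SubjectLandmarks.canonical)

    def __post_init__(self) -> None:
        expected = classify_facial_type(self.mp_angle, self.fhi)
        if expected != self.facial_type:
            raise ValueError(
                f"facial_type {self.facial_type!r} inconsistent with covariates "
                f"(classification gives {expected!r})"
            )

    def segment(self, jaw: str, site: str, side: str) -> SegmentModel:
        return self.segments[(jaw, site, side)]


# ---------------------------------------------------------------------------
# Facial-type parameters
# ---------------------------------------------------------------------------

@dataclass
class FacialTypeParams:
    """Geometric and covariate parameters for one vertical facial group."""

    group: str
    mandibular_ridge_scale: float
    maxillary_ridge_scale: float = 1.0
    mp_mean: float = 33.6
    mp_sd: float = 2.3
    fhi_mean: float = 66.8
    fhi_sd: float = 1.8
    male_fraction: float = 0.35

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown facial group {self.group!r}")
        if self.mandibular_ridge_scale <= 0 or self.maxillary_ridge_scale <= 0:
            raise ValueError("ridge scales must be positive")


#: Covariate means/SDs follow the cohort characteristics table of the study
#: design; ridge scales are generator configuration (plausible literature-scale
#: contrasts for mandibular posterior ridge thickness), fully overridable.
DEFAULT_FACIAL_PARAMS: dict[str, FacialTypeParams] = {
    HYPERDIVERGENT: FacialTypeParams(
        group=HYPERDIVERGENT,
        mandibular_ridge_scale=0.78,
        mp_mean=42.5,
        mp_sd=3.7,
        fhi_mean=58.7,
        fhi_sd=1.9,
        male_fraction=4 / 20,
    ),
    NORMODIVERGENT: FacialTypeParams(
        group=NORMODIVERGENT,
        mandibular_ridge_scale=1.0,
        mp_mean=33.6,
        mp_sd=2.3,
        fhi_mean=66.8,
        fhi_sd=1.8,
        male_fraction=7 / 20,
    ),
    HYPODIVERGENT: FacialTypeParams(
        group=HYPODIVERGENT,
        mandibular_ridge_scale=1.28,
        mp_mean=23.9,
        mp_sd=3.7,
        fhi_mean=75.3,
        fhi_sd=3.5,
        male_fraction=12 / 20,
    ),
}


# ---------------------------------------------------------------------------
# Site parameter sets
# ---------------------------------------------------------------------------

@dataclass
class RootParams:
    """Generator parameters for one root surface."""

    length: float
    r_md: float
    r_bl: float
    taper: float
    tilt: float = 0.0     # mesial (+) axis tilt component per unit apical
    tilt_bl: float = 0.0  # lingual axis tilt component per unit apical
    bow: float = 0.0


@dataclass
class SiteParams:
    """Generator parameters for one interradicular site.

    Default numeric values are generator configuration chosen at plausible
    literature scale; they are not measured quantities and every field can be
    overridden.
    """

    anterior: RootParams
    posterior: RootParams
    ant_label: int
    post_label: int
    cej_gap: float
    crown_height: float
    ridge_offset: float
    ridge_thickness: float
    ridge_slope: float = 0.0
    cusp_buccal_offset: float = 3.0
    molar_pitch: float = 10.5

    def copy(self) -> "SiteParams":
        return copy.deepcopy(self)


SITE_DEFAULTS: dict[tuple[str, str], SiteParams] = {
    # Second premolar (conical, strongly tapered) against first molar:
    # monotone apical widening.
    ("Mx", "5-6"): SiteParams(
        anterior=RootParams(length=13.0, r_md=3.2, r_bl=3.5, taper=0.45, tilt=0.10, tilt_bl=0.18),
        posterior=RootParams(length=12.5, r_md=3.4, r_bl=3.7, taper=0.35, tilt=-0.10, tilt_bl=0.18),
        ant_label=5,
        post_label=6,
        cej_gap=2.2,
        crown_height=6.0,
        ridge_offset=4.45,
        ridge_thickness=9.0,
    ),
    # First against second molar in the maxilla: opposing bows produce the
    # mid-root constriction (width minimum apical of the insertion level,
    # so a 30-degree screw dips into it).
    ("Mx", "6-7"): SiteParams(
        anterior=RootParams(length=12.5, r_md=3.4, r_bl=3.7, taper=0.05, tilt_bl=0.05, bow=-0.95),
        posterior=RootParams(length=12.0, r_md=3.3, r_bl=3.7, taper=0.05, tilt_bl=0.05, bow=0.95),
        ant_label=6,
        post_label=7,
        cej_gap=4.0,
        crown_height=6.0,
        ridge_offset=4.45,
        ridge_thickness=9.0,
    ),
    ("Mn", "5-6"): SiteParams(
        anterior=RootParams(length=13.5, r_md=3.1, r_bl=3.4, taper=0.45, tilt=0.10, tilt_bl=0.08),
        posterior=RootParams(length=13.0, r_md=3.4, r_bl=3.6, taper=0.35, tilt=-0.10, tilt_bl=0.08),
        ant_label=5,
        post_label=6,
        cej_gap=2.25,
        crown_height=6.0,
        ridge_offset=4.45,
        ridge_thickness=9.0,
    ),
    ("Mn", "6-7"): SiteParams(
        anterior=RootParams(length=13.0, r_md=3.4, r_bl=3.6, taper=0.35, tilt=0.08, tilt_bl=0.08),
        posterior=RootParams(length=12.5, r_md=3.4, r_bl=3.6, taper=0.30, tilt=-0.08, tilt_bl=0.08),
        ant_label=6,
        post_label=7,
        cej_gap=2.35,
        crown_height=6.0,
        ridge_offset=4.45,
        ridge_thickness=9.0,
    ),
}


def _apply_overrides(params: SiteParams, overrides: Mapping | None) -> SiteParams:
    params = params.copy()
    for key, value in (overrides or {}).items():
        if key in ("anterior", "posterior"):
            rp = getattr(params, key)
            for k, v in value.items():
                if not hasattr(rp, k):
                    raise ValueError(f"unknown root parameter {k!r}")
                setattr(rp, k, float(v))
        else:
            if not hasattr(params, key):
                raise ValueError(f"unknown site parameter {key!r}")
            setattr(params, key, float(value))
    return params


# ---------------------------------------------------------------------------
# Segment construction
# ---------------------------------------------------------------------------

def make_segment(
    jaw: str,
    site: str,
    facial_type_params: FacialTypeParams | str | None = None,
    overrides: Mapping | None = None,
    seed: int | None = None,
    side: str = "left",
    jitter: Mapping[str, float] | None = None,
) -> SegmentModel:
    """Build one interradicular segment from site defaults.

    ``facial_type_params`` scales the ridge of mandibular segments only (the
    maxillary scale defaults to 1 for every group).  ``overrides`` is a
    nested mapping patching :class:`SiteParams`.  ``jitter`` maps a subset of
    ``{"cej_gap", "ridge_offset", "cusp"}`` to Gaussian SDs drawn with
    ``seed``; with no jitter the construction is fully deterministic.
    """
    if (jaw, site) not in SITE_DEFAULTS:
        raise ValueError(f"unknown jaw/site combination {(jaw, site)!r}")
    if isinstance(facial_type_params, str):
        facial_type_params = DEFAULT_FACIAL_PARAMS[facial_type_params]
    params = _apply_overrides(SITE_DEFAULTS[(jaw, site)], overrides)

    if facial_type_params is not None:
        scale = (
            facial_type_params.mandibular_ridge_scale
            if jaw == "Mn"
            else facial_type_params.maxillary_ridge_scale
        )
        params.ridge_offset *= scale
        params.ridge_thickness *= scale

    rng = np.random.default_rng(seed)
    jitter = dict(jitter or {})
    if jitter.get("cej_gap"):
        params.cej_gap += rng.normal(0.0, jitter["cej_gap"])
    if jitter.get("ridge_offset"):
        params.ridge_offset += rng.normal(0.0, jitter["ridge_offset"])
    cusp_jit = jitter.get("cusp", 0.0)

    if params.cej_gap <= 0.05:
        raise ValueError(
            f"interradicular gap at CEJ must be positive (got {params.cej_gap:.3f} mm); "
            "root interpenetration rejected"
        )

    apical = 1 if jaw == "Mx" else -1
    buccal = 1 if side == "left" else -1
    cej_z = apical * params.crown_height

    def build_root(rp: RootParams, y_sign: float) -> RootSurface:
        # y_sign +1 for the anterior (mesial) tooth, -1 for the posterior.
        center = np.array([0.0, y_sign * (params.cej_gap / 2.0 + rp.r_md), cej_z])
        # tilt > 0 moves the anterior root mesially / posterior distally with
        # depth, diverging the roots apically; tilt_bl > 0 inclines the root
        # lingually with depth (away from the buccal sheet).
        axis = np.array([-buccal * rp.tilt_bl, y_sign * rp.tilt, float(apical)])
        # bows are stated for the left/anterior convention: positive bow on
        # the posterior root and negative on the anterior both push mid-root
        # surfaces toward the corridor.
        return make_root(
            cej_center=center,
            axis=axis,
            length=rp.length,
            semi_axis_md=rp.r_md,
            semi_axis_bl=rp.r_bl,
            taper=rp.taper,
            bow=rp.bow,
        )

    ant_root = build_root(params.anterior, +1.0)
    post_root = build_root(params.posterior, -1.0)

    def cusp(y: float) -> np.ndarray:
        c = np.array([buccal * params.cusp_buccal_offset, y, 0.0])
        if cusp_jit:
            c = c + rng.normal(0.0, cusp_jit, size=3)
        return c

    ant_cusp = cusp(float(ant_root.cej_center[1]))
    post_cusp = cusp(float(post_root.cej_center[1]))

    anterior = ToothModel(
        label=params.ant_label, roots=[ant_root], buccal_cusp=ant_cusp, cej_level=cej_z
    )
    posterior = ToothModel(
        label=params.post_label, roots=[post_root], buccal_cusp=post_cusp, cej_level=cej_z
    )

    # Molar cusps for the posterior reference line (first and second molars),
    # emitted for every site.
    if site == "5-6":
        cusp6 = post_cusp
        cusp7 = cusp(float(post_root.cej_center[1]) - params.molar_pitch)
    else:
        cusp6 = ant_cusp
        cusp7 = post_cusp

    bone = CorticalSheet(
        buccal_offset=params.ridge_offset,
        thickness=params.ridge_thickness,
        cej_z=cej_z,
        apical_sign=apical,
        buccal_sign=buccal,
        slope=params.ridge_slope,
    )

    return SegmentModel(
        jaw=jaw,
        site=site,
        side=side,
        anterior=anterior,
        posterior=posterior,
        bone=bone,
        molar_cusp_mesial=cusp6,
        molar_cusp_distal=cusp7,
    )


# ---------------------------------------------------------------------------
# Interradicular width profile
# ---------------------------------------------------------------------------

def interradicular_width(segment: SegmentModel, depth: float, n: int = 512) -> float:
    """Minimum mesiodistal gap between the facing root surfaces at ``depth``.

    ``depth`` is the vertical distance apical of the segment CEJ level.  The
    gap is evaluated in the horizontal plane as the minimum, over
    buccolingual offsets shared by both sections, of the distance between the
    anterior root's distal boundary and the posterior root's mesial boundary.
    """
    segment.require_standardized()
    z = segment.cej_z + segment.apical_sign * depth
    sa = segment.anterior.root.section(z)
    sp = segment.posterior.root.section(z)
    if depth < 0 or sa is None or sp is None:
        raise ValueError(f"depth {depth} mm is outside both roots' extent")
    cxa, cya, rxa, rya = sa
    cxp, cyp, rxp, ryp = sp
    lo = max(cxa - rxa, cxp - rxp)
    hi = min(cxa + rxa, cxp + rxp)
    if lo > hi:
        # No shared buccolingual band: the closest approach degenerates to
        # the centre-to-centre mesiodistal separation.
        return float(cya - cyp)
    xs = np.linspace(lo, hi, n)
    # include the ellipse centres so aligned-axis cases are exact
    extra = [c for c in (cxa, cxp) if lo <= c <= hi]
    if extra:
        xs = np.concatenate([xs, np.asarray(extra)])
    ya = cya - rya * np.sqrt(np.clip(1.0 - ((xs - cxa) / rxa) ** 2, 0.0, None))
    yp = cyp + ryp * np.sqrt(np.clip(1.0 - ((xs - cxp) / rxp) ** 2, 0.0, None))
    return float(np.min(ya - yp))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Configuration for :func:`simulate_cohort`.

    ``subject_jitter`` SDs apply once per subject and jaw/site (shared by the
    two sides); ``side_jitter`` SDs add independent left/right perturbations
    on top, producing near-symmetric bilateral segments.  Setting every
    jitter to zero makes left and right measurements identical downstream.
    """

    n_per_group: int = 20
    facial_params: dict[str, FacialTypeParams] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_FACIAL_PARAMS)
    )
    site_overrides: dict = field(default_factory=dict)
    subject_jitter: dict[str, float] = field(
        default_factory=lambda: {"cej_gap": 0.22, "ridge_offset": 0.34}
    )
    side_jitter: dict[str, float] = field(
        default_factory=lambda: {"cej_gap": 0.05, "ridge_offset": 0.07, "cusp": 0.04}
    )

    def overrides_for(self, jaw: str, site: str) -> Mapping | None:
        return self.site_overrides.get((jaw, site)) or self.site_overrides.get(
            f"{jaw} {site}"
        )


def simulate_cohort(
    n_per_group: int | None = None,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> list[Subject]:
    """Simulate a cohort of subjects balanced across the three facial groups.

    Covariates are drawn from per-group Gaussians and redrawn while the
    classification rule would exclude the subject (discordant angle/ratio
    regions), mirroring the study's exclusion rule.  Geometry receives
    seeded subject-level jitter shared across sides plus small left/right
    jitter.  Identical ``(config, seed)`` yield an identical cohort.
    """
    config = config or CohortConfig()
    n = config.n_per_group if n_per_group is None else int(n_per_group)
    if n < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    subjects: list[Subject] = []
    idx = 0
    for group in GROUPS:
        fp = config.facial_params[group]
        for _ in range(n):
            idx += 1
            for _attempt in range(10_000):
                mp = rng.normal(fp.mp_mean, fp.mp_sd)
                fhi = rng.normal(fp.fhi_mean, fp.fhi_sd)
                if classify_facial_type(mp, fhi) == group:
                    break
            else:  # pragma: no cover - defensive
                raise RuntimeError(f"could not draw concordant covariates for {group}")
            sex = "M" if rng.random() < fp.male_fraction else "F"
            segments: dict[tuple[str, str, str], SegmentModel] = {}
            for jaw in JAWS:
                for site in SITES:
                    sj = config.subject_jitter
                    base_gap = rng.normal(0.0, sj.get("cej_gap", 0.0)) if sj.get("cej_gap") else 0.0
                    base_ridge = (
                        rng.normal(0.0, sj.get("ridge_offset", 0.0))
                        if sj.get("ridge_offset")
                        else 0.0
                    )
                    for side in SIDES:
                        defaults = SITE_DEFAULTS[(jaw, site)]
                        overrides = dict(config.overrides_for(jaw, site) or {})
                        gap = overrides.get("cej_gap", defaults.cej_gap) + base_gap
                        ridge = overrides.get("ridge_offset", defaults.ridge_offset) + base_ridge
                        overrides["cej_gap"] = max(float(gap), 0.3)
                        overrides["ridge_offset"] = max(float(ridge), 1.0)
                        side_seed = int(rng.integers(0, 2**31 - 1))
                        segments[(jaw, site, side)] = make_segment(
                            jaw,
                            site,
                            facial_type_params=fp,
                            overrides=overrides,
                            seed=side_seed,
                            side=side,
                            jitter=config.side_jitter,
                        )
            subjects.append(
                Subject(
                    id=f"S{idx:03d}",
                    sex=sex,
                    mp_angle=float(mp),
                    fhi=float(fhi),
                    facial_type=group,
                    segments=segments,
                )
            )
    return subjects
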