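"""Slice-based, direction-constrained miniscrew-root distance.

The protocol: slice the scene axially at 0.1 mm between the screw apex and
neck (both end slices included).  In each slice, take the direction ``u`` of
the posterior reference line projected into the slice plane and its in-plane
perpendicular ``v``.  For every ``v`` offset covered by both the screw
cross-section and the anterior root cross-section, measure the gap along
``u`` between the screw's mesial boundary and the root's distal boundary;
the slice distance is the minimum gap over shared offsets, and the recorded
distance is the minimum over slices.  A slice whose sections share no ``v``
interval contributes ``NO_OVERLAP``; if every slice does, the screw sits
buccally outside the root's distalization corridor and the outcome is
``NONCONTACT``.  If the screw solid intersects a root surface the outcome is
``CONTACT``.

Cross-section boundaries are polygonal approximations at a configurable
angular resolution (1 degree by default).  ``brute_force_distance`` is an
independent verification oracle built on solid-containment scans and exact
ray-ellipse intersections; it converges to ``measure``'s result from above
as the sample count grows.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull, QhullError

from .anatomy import RootSurface, SegmentModel
from .frame import posterior_reference_line
from .screw import ScrewPlacement

__all__ = [
    "NO_OVERLAP",
    "Outcome",
    "AxialSlice",
    "MeasurementRecord",
    "MeasureConfig",
    "screw_section",
    "directional_gap",
    "slice_grid",
    "slice_distance",
    "detect_contact",
    "measure",
    "brute_force_distance",
    "voxel_measure",
]


class _NoOverlap:
    """Sentinel: the screw section is buccal of the root's corridor."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "NO_OVERLAP"


NO_OVERLAP = _NoOverlap()


class Outcome(str, enum.Enum):
    MEASURABLE = "measurable"
    CONTACT = "contact"
    NONCONTACT = "noncontact"


@dataclass(frozen=True)
class AxialSlice:
    z: float
    thickness: float = 0.1


@dataclass
class MeasurementRecord:
    """Outcome of one placement measurement."""

    subject_id: str
    jaw: str
    site: str
    side: str
    angle: float
    outcome: Outcome
    distance: float | None = None
    argmin_slice_z: float | None = None

    def __post_init__(self) -> None:
        self.outcome = Outcome(self.outcome)
        if self.outcome is Outcome.MEASURABLE:
            if self.distance is None or self.distance <= 0:
                raise ValueError("measurable records need a positive distance")
        elif self.distance is not None:
            raise ValueError(f"{self.outcome.value} records carry no distance")


@dataclass
class MeasureConfig:
    slice_thickness: float = 0.1
    resolution_deg: float = 1.0  # angular step of boundary polygons
    n_v: int = 257               # v-offsets per slice for the gap scan
    contact_tol: float = 1e-6
    check_contact: bool = True


# ---------------------------------------------------------------------------
# Cross-sections
# ---------------------------------------------------------------------------

def screw_section(
    placement: ScrewPlacement, z: float, resolution_deg: float = 1.0
) -> np.ndarray | None:
    """Convex polygon of the screw solid's horizontal cross-section at ``z``.

    Boundary points are gathered from the lateral surface (solving the
    plane-crossing equation per angular sample -- linear in the axial
    coordinate for a linear radius profile) and from the end-cap chords,
    then convex-hulled.  Returns ``None`` when the plane misses the solid.
    """
    a = placement.axis
    n0 = placement.neck_point
    geo = placement.screw
    L = geo.length
    r0 = geo.radius(0.0)
    k = geo.taper_rate
    e1, e2 = placement.perp_basis()

    th = np.arange(0.0, 360.0, resolution_deg) * (np.pi / 180.0)
    w = np.cos(th) * e1[2] + np.sin(th) * e2[2]
    den = a[2] + k * w
    num = z - n0[2] - r0 * w
    with np.errstate(divide="ignore", invalid="ignore"):
        s = num / den
    ok = (np.abs(den) > 1e-12) & (s >= -1e-9) & (s <= L + 1e-9)
    pts = []
    if np.any(ok):
        sv = np.clip(s[ok], 0.0, L)
        rv = geo.radius(sv)
        p = (
            n0[None, :]
            + sv[:, None] * a[None, :]
            + (rv * np.cos(th[ok]))[:, None] * e1[None, :]
            + (rv * np.sin(th[ok]))[:, None] * e2[None, :]
        )
        pts.append(p[:, :2])

    # End-cap chords: the flat cap at s = sc meets the plane in a segment
    # whose endpoints lie on the rim circle.
    ez = np.array([e1[2], e2[2]])
    nz = np.linalg.norm(ez)
    if nz > 1e-12:
        for sc in (0.0, L):
            c = n0 + sc * a
            rc = geo.radius(sc)
            dz = z - c[2]
            p0 = ez * dz / nz**2  # closest point of the chord line to centre
            h2 = rc**2 - p0 @ p0
            if h2 < 0:
                continue
            tdir = np.array([-ez[1], ez[0]]) / nz
            h = math.sqrt(h2)
            for sign in (-1.0, 1.0):
                ab = p0 + sign * h * tdir
                q = c + ab[0] * e1 + ab[1] * e2
                pts.append(q[None, :2])
    if not pts:
        return None
    allpts = np.vstack(pts)
    if len(allpts) < 3:
        return None
    try:
        hull = ConvexHull(allpts)
    except QhullError:
        return None
    return allpts[hull.vertices]


def _bounds_on_grid(
    poly: np.ndarray, u_hat: np.ndarray, v_hat: np.ndarray, v_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise (min_u, max_u) of a convex polygon over ``v_grid``.

    The two boundary chains of a convex polygon are interpolated on the
    grid; their pointwise min/max give the lower and upper boundaries.
    ``v_grid`` must lie within the polygon's ``v`` extent.
    """
    v = poly @ v_hat
    u = poly @ u_hat
    imin, imax = int(np.argmin(v)), int(np.argmax(v))
    n = len(poly)

    def chain(i0: int, i1: int) -> tuple[np.ndarray, np.ndarray]:
        idx = [i0]
        i = i0
        while i != i1:
            i = (i + 1) % n
            idx.append(i)
        cv, cu = v[idx], u[idx]
        order = np.argsort(cv, kind="stable")
        return cv[order], cu[order]

    v1, u1 = chain(imin, imax)
    v2, u2 = chain(imax, imin)
    b1 = np.interp(v_grid, v1, u1)
    b2 = np.interp(v_grid, v2, u2)
    return np.minimum(b1, b2), np.maximum(b1, b2)


def directional_gap(
    screw_poly: np.ndarray,
    root_poly: np.ndarray,
    mesial_dir: np.ndarray,
    n_v: int = 257,
):
    """Minimum gap along ``mesial_dir`` between two convex sections.

    ``mesial_dir`` is the in-plane unit vector pointing from the screw
    toward the anterior root.  Returns the minimum, over perpendicular
    offsets shared by both sections, of the distance from the screw's
    mesial boundary to the root's facing boundary -- or :data:`NO_OVERLAP`
    when the perpendicular intervals are disjoint.
    """
    w_hat = np.asarray(mesial_dir, dtype=float)
    w_hat = w_hat / np.linalg.norm(w_hat)
    v_hat = np.array([-w_hat[1], w_hat[0]])
    vs = screw_poly @ v_hat
    vr = root_poly @ v_hat
    lo = max(vs.min(), vr.min())
    hi = min(vs.max(), vr.max())
    if lo > hi:
        return NO_OVERLAP
    v_grid = np.linspace(lo, hi, n_v) if hi > lo else np.array([lo])
    _, screw_wmax = _bounds_on_grid(screw_poly, w_hat, v_hat, v_grid)
    root_wmin, _ = _bounds_on_grid(root_poly, w_hat, v_hat, v_grid)
    return float(np.min(root_wmin - screw_wmax))


def _projected_reference(segment: SegmentModel) -> np.ndarray:
    """Horizontal projection of the reference-line direction (mesial->distal)."""
    ref = posterior_reference_line(segment)
    u2 = np.asarray(ref.direction[:2], dtype=float)
    n = np.linalg.norm(u2)
    if n < 1e-9:
        raise ValueError("reference line is vertical; in-plane direction undefined")
    return u2 / n


def slice_distance(
    segment: SegmentModel,
    placement: ScrewPlacement,
    slice_: AxialSlice | float,
    resolution_deg: float = 1.0,
    n_v: int = 257,
):
    """Direction-constrained gap in one axial slice (mm) or ``NO_OVERLAP``."""
    segment.require_standardized()
    z = slice_.z if isinstance(slice_, AxialSlice) else float(slice_)
    poly = screw_section(placement, z, resolution_deg=resolution_deg)
    if poly is None:
        raise ValueError(f"screw cross-section is empty at z = {z:.3f} mm")
    n_b = max(8, int(round(360.0 / resolution_deg)))
    root_poly = segment.anterior.root.boundary(z, n=n_b)
    if root_poly is None:
        return NO_OVERLAP
    u2 = _projected_reference(segment)
    return directional_gap(poly, root_poly, -u2, n_v=n_v)


def slice_grid(placement: ScrewPlacement, thickness: float = 0.1,
               apical_sign: int = 1) -> np.ndarray:
    """Slice heights between apex and neck, closed at both ends.

    Ordered from cervical (occlusal) to apical so that ties in the minimum
    resolve to the most cervical slice.
    """
    z0 = float(placement.neck_point[2])
    z1 = float(placement.apex_point[2])
    lo, hi = min(z0, z1), max(z0, z1)
    if hi - lo < 1e-12:
        zs = np.array([lo])
    else:
        n = int(math.floor((hi - lo) / thickness + 1e-9))
        zs = lo + np.arange(n + 1) * thickness
        if hi - zs[-1] > 1e-9:
            zs = np.append(zs, hi)
    return zs[np.argsort(apical_sign * zs, kind="stable")]


# ---------------------------------------------------------------------------
# Contact detection
# ---------------------------------------------------------------------------

def _radial_clearance(root: RootSurface, pts: np.ndarray) -> np.ndarray:
    """Signed in-plane radial clearance of points to the root surface.

    Zero exactly on the surface, negative inside; points at heights the
    root does not reach get ``+inf``.
    """
    pts = np.atleast_2d(pts)
    out = np.full(len(pts), np.inf)
    d = (pts[:, 2] - root.cej_center[2]) / root.axis[2]
    valid = (d >= 0.0) & (d <= root.length)
    if not np.any(valid):
        return out
    dv = d[valid]
    t = dv / root.length
    shrink = 1.0 - root.taper * t
    cx = root.cej_center[0] + dv * root.axis[0]
    cy = root.cej_center[1] + dv * root.axis[1] + root.bow * 4.0 * t * (1.0 - t)
    rx = root.semi_axis_bl * shrink
    ry = root.semi_axis_md * shrink
    qx = pts[valid, 0] - cx
    qy = pts[valid, 1] - cy
    rho = np.hypot(qx, qy)
    with np.errstate(divide="ignore", invalid="ignore"):
        psi_x = np.where(rho > 0, qx / np.maximum(rho, 1e-300), 1.0)
        psi_y = np.where(rho > 0, qy / np.maximum(rho, 1e-300), 0.0)
        rho_b = 1.0 / np.sqrt((psi_x / rx) ** 2 + (psi_y / ry) ** 2)
    out[valid] = rho - rho_b
    return out


def detect_contact(
    segment: SegmentModel,
    placement: ScrewPlacement,
    tol: float = 1e-6,
    n_axial: int = 48,
    n_theta: int = 60,
) -> bool:
    """True iff the screw solid touches a root surface of either tooth.

    Evaluated as the minimum signed radial clearance of sampled screw
    surface points to each root's stacked-ellipse surface, with local
    Nelder-Mead refinement of the best lateral-surface candidate.
    """
    segment.require_standardized()
    geo = placement.screw
    e1, e2 = placement.perp_basis()
    a, n0 = placement.axis, placement.neck_point

    s = np.linspace(0.0, geo.length, n_axial)
    th = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    S, TH = np.meshgrid(s, th, indexing="ij")
    R = geo.radius(S)
    lateral = (
        n0[None, None, :]
        + S[..., None] * a[None, None, :]
        + (R * np.cos(TH))[..., None] * e1[None, None, :]
        + (R * np.sin(TH))[..., None] * e2[None, None, :]
    ).reshape(-1, 3)
    caps = []
    for sc in (0.0, geo.length):
        c = n0 + sc * a
        rc = geo.radius(sc)
        for frac in (0.35, 0.7, 1.0):
            ring = c[None, :] + (rc * frac) * (
                np.cos(th)[:, None] * e1[None, :] + np.sin(th)[:, None] * e2[None, :]
            )
            caps.append(ring)
    caps.append((n0 + geo.length * a)[None, :])  # apex centre
    pts = np.vstack([lateral] + caps)

    roots = segment.anterior.roots + segment.posterior.roots
    for root in roots:
        clr = _radial_clearance(root, pts)
        best = float(np.min(clr))
        if best <= tol:
            return True
        # refine the best lateral candidate in (s, theta)
        lclr = clr[: lateral.shape[0]].reshape(n_axial, n_theta)
        i, j = np.unravel_index(np.argmin(lclr), lclr.shape)

        def objective(x, _root=root):
            ss = float(np.clip(x[0], 0.0, geo.length))
            tt = x[1]
            p = n0 + ss * a + geo.radius(ss) * (
                math.cos(tt) * e1 + math.sin(tt) * e2
            )
            return float(_radial_clearance(_root, p[None, :])[0])

        res = minimize(
            objective,
            x0=np.array([s[i], th[j]]),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 200},
        )
        if res.fun <= tol:
            return True
    return False


# ---------------------------------------------------------------------------
# The measurement
# ---------------------------------------------------------------------------

def measure(
    segment: SegmentModel,
    placement: ScrewPlacement,
    config: MeasureConfig | None = None,
    subject_id: str = "",
) -> MeasurementRecord:
    """Full protocol: contact check, slice scan, minimum over slices.

    Returns ``CONTACT`` when the screw touches a root, ``NONCONTACT`` when
    every slice reports ``NO_OVERLAP`` and otherwise ``MEASURABLE`` with the
    smallest slice distance; ties resolve to the most cervical slice.
    """
    config = config or MeasureConfig()
    segment.require_standardized()
    ids = dict(
        subject_id=subject_id,
        jaw=segment.jaw,
        site=segment.site,
        side=segment.side,
        angle=float(placement.angle),
    )
    if config.check_contact and detect_contact(
        segment, placement, tol=config.contact_tol
    ):
        return MeasurementRecord(outcome=Outcome.CONTACT, **ids)

    zs = slice_grid(placement, config.slice_thickness, segment.apical_sign)
    best: float | None = None
    best_z: float | None = None
    for z in zs:
        d = slice_distance(
            segment, placement, z, resolution_deg=config.resolution_deg, n_v=config.n_v
        )
        if d is NO_OVERLAP:
            continue
        if best is None or d < best - 1e-12:
            best, best_z = float(d), float(z)
    if best is None:
        return MeasurementRecord(outcome=Outcome.NONCONTACT, **ids)
    if best <= 0:
        # Degenerate safety net: overlapping sections imply contact.
        return MeasurementRecord(outcome=Outcome.CONTACT, **ids)
    return MeasurementRecord(
        outcome=Outcome.MEASURABLE, distance=best, argmin_slice_z=best_z, **ids
    )


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _root_wmin_exact(
    root: RootSurface, z: float, origin: np.ndarray, v_hat: np.ndarray,
    w_hat: np.ndarray, v: np.ndarray
) -> np.ndarray:
    """Exact mesial-boundary coordinate of the root section along scan lines.

    For each perpendicular offset ``v`` the scan line is
    ``origin + v * v_hat + w * w_hat``; returns the smallest ``w`` on the
    ellipse (NaN where the line misses it).
    """
    sec = root.section(z)
    out = np.full(len(v), np.nan)
    if sec is None:
        return out
    cx, cy, rx, ry = sec
    # line point p(v, w); ellipse ((px-cx)/rx)^2 + ((py-cy)/ry)^2 = 1
    p0x = origin[0] + v * v_hat[0] - cx
    p0y = origin[1] + v * v_hat[1] - cy
    dx, dy = w_hat[0], w_hat[1]
    A = (dx / rx) ** 2 + (dy / ry) ** 2
    B = 2.0 * (p0x * dx / rx**2 + p0y * dy / ry**2)
    C = (p0x / rx) ** 2 + (p0y / ry) ** 2 - 1.0
    disc = B**2 - 4.0 * A * C
    hit = disc >= 0.0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    w1 = (-B - sq) / (2.0 * A)
    out[hit] = w1[hit]
    return out


def brute_force_distance(
    segment: SegmentModel,
    placement: ScrewPlacement,
    n_samples: int = 2000,
    seed: int = 0,
    slice_thickness: float = 0.1,
):
    """Independent oracle for :func:`measure`.

    Works from solid-containment predicates only: per slice, random plus
    edge-ladder perpendicular offsets are scanned along the measurement
    direction to locate the screw's mesial boundary by bisection, and the
    root boundary is intersected in closed form.  Returns
    ``(Outcome, value)`` where ``value`` is the minimum distance for
    measurable scenes and ``None`` otherwise.  The reported minimum is
    non-increasing in ``n_samples`` for a fixed seed.
    """
    segment.require_standardized()
    u2 = _projected_reference(segment)
    w_hat = -u2  # mesial: from the screw toward the anterior root
    v_hat = np.array([-w_hat[1], w_hat[0]])
    root = segment.anterior.root
    geo = placement.screw

    zs = slice_grid(placement, slice_thickness, segment.apical_sign)
    n_per_slice = max(8, n_samples // max(len(zs), 1))

    # 3D containment samples for contact detection.
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    s3 = rng.uniform(0.0, geo.length, 512)
    phi3 = rng.uniform(0.0, 2 * np.pi, 512)
    rho3 = geo.radius(s3) * np.sqrt(rng.uniform(0.0, 1.0, 512))
    e1, e2 = placement.perp_basis()
    body = (
        placement.neck_point[None, :]
        + s3[:, None] * placement.axis[None, :]
        + (rho3 * np.cos(phi3))[:, None] * e1[None, :]
        + (rho3 * np.sin(phi3))[:, None] * e2[None, :]
    )
    for r in segment.anterior.roots + segment.posterior.roots:
        if np.any(r.inside(body)):
            return (Outcome.CONTACT, None)

    # Perpendicular extent of the screw: the axis has zero mesiodistal
    # component, so the whole solid lies within neck radius of the axis
    # along u; along v it spans the axis' v-range widened by the radii.
    nvk = placement.neck_point
    apx = placement.apex_point
    v_axis = np.array([nvk[:2] @ v_hat, apx[:2] @ v_hat])
    w_axis = np.array([nvk[:2] @ w_hat, apx[:2] @ w_hat])
    rmax = geo.radius(0.0)
    w_lo, w_hi = w_axis.min() - rmax, w_axis.max() + rmax

    best = np.inf
    any_overlap = False
    origin = np.zeros(2)
    ladder = 10.0 ** np.arange(-2.0, -8.1, -1.0)
    v_lo, v_hi = v_axis.min() - rmax, v_axis.max() + rmax
    for si, z in enumerate(zs):
        sec = root.section(z)
        if sec is None:
            continue
        cx, cy, rx, ry = sec
        cv = cx * v_hat[0] + cy * v_hat[1]
        rv = math.hypot(rx * v_hat[0], ry * v_hat[1])
        w0, w1 = max(v_lo, cv - rv), min(v_hi, cv + rv)  # overlap window
        if w0 >= w1:
            continue
        rng_s = np.random.default_rng(np.random.SeedSequence([seed, 1, si]))
        span = w1 - w0
        k = max(2, int(math.log2(max(n_per_slice, 4))))
        dyadic = w0 + span * np.arange(2**k + 1) / 2**k  # nested in n_samples
        vs = np.concatenate(
            [
                rng_s.uniform(w0, w1, n_per_slice),
                dyadic,
                w0 + ladder * span,
                w1 - ladder * span,
            ]
        )
        root_w = _root_wmin_exact(root, z, origin, v_hat, w_hat, vs)
        keep = ~np.isnan(root_w)
        if not np.any(keep):
            continue
        vs, root_w = vs[keep], root_w[keep]
        # coarse containment scan along w at each v
        n_w = 160
        ws = np.linspace(w_lo, w_hi, n_w)
        V, W = np.meshgrid(vs, ws, indexing="ij")
        pts = np.column_stack(
            [
                (V * v_hat[0] + W * w_hat[0]).ravel(),
                (V * v_hat[1] + W * w_hat[1]).ravel(),
                np.full(V.size, z),
            ]
        )
        inside = placement.inside(pts).reshape(len(vs), n_w)
        has = inside.any(axis=1)
        if not np.any(has):
            continue
        any_overlap = True
        # mesial-most inside sample per v, then bisect the boundary
        idx_in = np.where(
            has, n_w - 1 - np.argmax(inside[:, ::-1], axis=1), 0
        )
        vsel = vs[has]
        win = ws[idx_in[has]]
        wout = np.minimum(win + (ws[1] - ws[0]), w_hi + 1e-6)
        for _ in range(40):
            mid = 0.5 * (win + wout)
            p = np.column_stack(
                [
                    vsel * v_hat[0] + mid * w_hat[0],
                    vsel * v_hat[1] + mid * w_hat[1],
                    np.full(len(vsel), z),
                ]
            )
            m_in = placement.inside(p)
            win = np.where(m_in, mid, win)
            wout = np.where(m_in, wout, mid)
        gaps = root_w[has] - win
        best = min(best, float(np.min(gaps)))

        # the per-slice gap is convex in v: golden-section refine around the
        # best sample (root boundary in closed form, screw boundary by
        # containment bisection)
        def gap_at(v: float) -> float:
            rw = _root_wmin_exact(root, z, origin, v_hat, w_hat, np.array([v]))[0]
            if np.isnan(rw):
                return np.inf
            ws_scan = np.linspace(w_lo, w_hi, n_w)
            p = np.column_stack(
                [
                    v * v_hat[0] + ws_scan * w_hat[0],
                    v * v_hat[1] + ws_scan * w_hat[1],
                    np.full(n_w, z),
                ]
            )
            m = placement.inside(p)
            if not m.any():
                return np.inf
            j = n_w - 1 - int(np.argmax(m[::-1]))
            a_in, b_out = ws_scan[j], min(ws_scan[j] + (ws_scan[1] - ws_scan[0]), w_hi + 1e-6)
            for _ in range(40):
                mid = 0.5 * (a_in + b_out)
                q = np.array([v * v_hat[0] + mid * w_hat[0],
                              v * v_hat[1] + mid * w_hat[1], z])
                if placement.inside(q[None, :])[0]:
                    a_in = mid
                else:
                    b_out = mid
            return rw - a_in

        order = np.argsort(vs[has])
        vsort = vs[has][order]
        gsort = gaps[order]
        kmin = int(np.argmin(gsort))
        lo_v = vsort[kmin - 1] if kmin > 0 else w0
        hi_v = vsort[kmin + 1] if kmin < len(vsort) - 1 else w1
        phi = (math.sqrt(5.0) - 1.0) / 2.0
        a_v, b_v = lo_v, hi_v
        c_v = b_v - phi * (b_v - a_v)
        d_v = a_v + phi * (b_v - a_v)
        fc, fd = gap_at(c_v), gap_at(d_v)
        for _ in range(40):
            if fc <= fd:
                b_v, d_v, fd = d_v, c_v, fc
                c_v = b_v - phi * (b_v - a_v)
                fc = gap_at(c_v)
            else:
                a_v, c_v, fc = c_v, d_v, fd
                d_v = a_v + phi * (b_v - a_v)
                fd = gap_at(d_v)
        best = min(best, float(min(fc, fd)))

    if not any_overlap:
        return (Outcome.NONCONTACT, None)
    if best <= 0:
        return (Outcome.CONTACT, None)
    return (Outcome.MEASURABLE, best)


# ---------------------------------------------------------------------------
# Voxel-domain counterpart
# ---------------------------------------------------------------------------

def voxel_measure(volume, placement: ScrewPlacement, config=None, subject_id="",
                  jaw="Mx", site="5-6", side="left") -> MeasurementRecord:
    """Image-domain measurement on a labeled volume with the screw rasterized.

    Rows are scanned along the mesiodistal (``y``) axis of the standardized
    grid; per axial layer and buccolingual column, the distance is the count
    of empty voxels between the screw label and the anterior-root label
    times the voxel size, and the minimum over layers is reported.  The
    volume must be sampled in the standardized frame.
    """
    from .voxel import LABEL_ANT_ROOT, LABEL_SCREW

    data = volume.data
    h = volume.voxel_size
    if not np.any(data == LABEL_ANT_ROOT):
        raise ValueError("volume lacks an anterior-root label")
    if not np.any(data == LABEL_SCREW):
        raise ValueError("volume lacks a rasterized screw label")
    screw_mask = data == LABEL_SCREW
    root_mask = data == LABEL_ANT_ROOT

    # restrict layers to the apex-neck span (half-voxel slack)
    z0 = min(placement.neck_point[2], placement.apex_point[2]) - 0.5 * h
    z1 = max(placement.neck_point[2], placement.apex_point[2]) + 0.5 * h
    zc = volume.origin[2] + (np.arange(data.shape[2]) + 0.5) * h
    zsel = (zc >= z0) & (zc <= z1)
    screw_mask = screw_mask & zsel[None, None, :]

    ny = data.shape[1]
    yr = np.arange(ny)
    has_s = screw_mask.any(axis=1)
    has_r = root_mask.any(axis=1)
    both = has_s & has_r
    if not np.any(both):
        return MeasurementRecord(
            subject_id=subject_id, jaw=jaw, site=site, side=side,
            angle=float(placement.angle), outcome=Outcome.NONCONTACT,
        )
    # anterior root is mesial (+y): max screw index vs min root index per column
    smax = np.where(screw_mask, yr[None, :, None], -1).max(axis=1)
    rmin = np.where(root_mask, yr[None, :, None], ny).min(axis=1)
    gap_vox = (rmin - smax - 1)[both]
    if np.any(gap_vox <= 0):
        return MeasurementRecord(
            subject_id=subject_id, jaw=jaw, site=site, side=side,
            angle=float(placement.angle), outcome=Outcome.CONTACT,
        )
    ix, iz = np.where(both)
    k = int(np.argmin(gap_vox))
    return MeasurementRecord(
        subject_id=subject_id, jaw=jaw, site=site, side=side,
        angle=float(placement.angle), outcome=Outcome.MEASURABLE,
        distance=float(gap_vox[k] * h),
        argmin_slice_z=float(zc[iz[k]]),
    )
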