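"""Labeled voxel volumes: a CBCT stand-in for the analytic scene.

``voxelize`` samples a segment's analytic geometry on a regular grid in the
standardized frame, producing an integer label volume
(background / bone / anterior root / posterior root); ``rasterize_screw``
adds the screw label in place.  Volumes can be written as NIfTI with a JSON
label legend sidecar (:mod:`miniscrewsim.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .anatomy import SegmentModel, interradicular_width
from .screw import ScrewPlacement

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_BONE",
    "LABEL_ANT_ROOT",
    "LABEL_POST_ROOT",
    "LABEL_SCREW",
    "LABEL_LEGEND",
    "ResolutionWarning",
    "LabeledVolume",
    "voxelize",
    "rasterize_screw",
]

LABEL_BACKGROUND = 0
LABEL_BONE = 1
LABEL_ANT_ROOT = 2
LABEL_POST_ROOT = 3
LABEL_SCREW = 4

LABEL_LEGEND = {
    LABEL_BACKGROUND: "background",
    LABEL_BONE: "bone",
    LABEL_ANT_ROOT: "anterior_root",
    LABEL_POST_ROOT: "posterior_root",
    LABEL_SCREW: "screw",
}


class ResolutionWarning(UserWarning):
    """Voxel size too coarse for the interradicular gap."""


@dataclass
class LabeledVolume:
    """A label volume on a regular grid; index order is ``(x, y, z)``."""

    data: np.ndarray
    origin: np.ndarray  # corner of voxel (0, 0, 0)
    voxel_size: float
    legend: dict[int, str] = field(default_factory=lambda: dict(LABEL_LEGEND))

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")

    def centers(self, axis: int) -> np.ndarray:
        n = self.data.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size

    def grid_points(self) -> np.ndarray:
        """All voxel-centre coordinates, shape ``(n_voxels, 3)``."""
        xs, ys, zs = (self.centers(i) for i in range(3))
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def voxelize(
    segment: SegmentModel,
    voxel_size: float,
    margin: float = 1.5,
    include_bone: bool = True,
    include_roots: bool = True,
) -> LabeledVolume:
    """Sample a segment into an integer label volume.

    The grid covers the roots and the bone slab with ``margin`` mm of
    padding.  Root labels take precedence over bone.  A
    :class:`ResolutionWarning` is emitted when ``voxel_size`` exceeds the
    interradicular gap near the CEJ.
    """
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    segment.require_standardized()
    try:
        gap = interradicular_width(segment, 0.25)
        if voxel_size > gap:
            warnings.warn(
                f"voxel size {voxel_size} mm exceeds the interradicular gap "
                f"({gap:.2f} mm); sections may not resolve",
                ResolutionWarning,
                stacklevel=2,
            )
    except ValueError:
        pass

    roots = segment.anterior.roots + segment.posterior.roots
    pts = []
    for r in roots:
        for p in (r.cej_center, r.apex):
            pts.append(p + np.array([r.semi_axis_bl, r.semi_axis_md, 0.0]))
            pts.append(p - np.array([r.semi_axis_bl, r.semi_axis_md, 0.0]))
    b = segment.bone
    for depth in (b.crest_offset, 16.0):
        z = b.cej_z + b.apical_sign * depth
        xb = float(b.x_buccal(0.0, z))
        pts.append(np.array([xb, 0.0, z]))
        pts.append(np.array([xb - b.buccal_sign * b.thickness_at(z), 0.0, z]))
    pts = np.array(pts)
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int), 1)
    vol = LabeledVolume(
        data=np.zeros(tuple(shape), dtype=np.uint8), origin=lo, voxel_size=voxel_size
    )
    xs = vol.centers(0)[:, None, None]
    ys = vol.centers(1)[None, :, None]
    zs = vol.centers(2)[None, None, :]
    if include_bone:
        d = b.apical_sign * (zs - b.cej_z)
        xb = b.buccal_offset + b.slope * d
        xsgn = b.buccal_sign * xs
        bone = (
            (xsgn <= xb)
            & (xsgn >= xb - (b.thickness + b.thickness_slope * d))
            & (d >= b.crest_offset)
            & (d <= b.apical_extent)
        )
        vol.data[np.broadcast_to(bone, vol.data.shape)] = LABEL_BONE
    for label, roots in (
        (LABEL_POST_ROOT, segment.posterior.roots if include_roots else []),
        (LABEL_ANT_ROOT, segment.anterior.roots if include_roots else []),
    ):
        for r in roots:
            d = (zs - r.cej_center[2]) / r.axis[2]
            t = np.clip(d / r.length, 0.0, 1.0)
            shrink = 1.0 - r.taper * t
            cx = r.cej_center[0] + d * r.axis[0]
            cy = r.cej_center[1] + d * r.axis[1] + r.bow * 4.0 * t * (1.0 - t)
            mask = (d >= 0.0) & (d <= r.length) & (
                ((xs - cx) / (r.semi_axis_bl * shrink)) ** 2
                + ((ys - cy) / (r.semi_axis_md * shrink)) ** 2
                <= 1.0
            )
            vol.data[mask] = label
    return vol


def rasterize_screw(
    volume: LabeledVolume, placement: ScrewPlacement
) -> tuple[LabeledVolume, int]:
    """Mark screw voxels in place (label 4), preserving root labels.

    Returns the volume and the number of voxels where the screw solid
    overlaps a root label (nonzero indicates interpenetration).
    """
    # evaluate only within the screw's bounding box
    geo = placement.screw
    rmax = geo.radius(0.0)
    lo3 = np.minimum(placement.neck_point, placement.apex_point) - rmax
    hi3 = np.maximum(placement.neck_point, placement.apex_point) + rmax
    h = volume.voxel_size
    i0 = np.maximum(((lo3 - volume.origin) / h).astype(int) - 1, 0)
    i1 = np.minimum(
        ((hi3 - volume.origin) / h).astype(int) + 2, np.array(volume.data.shape)
    )
    if np.any(i0 >= i1):
        return volume, 0
    sub = tuple(slice(a, b) for a, b in zip(i0, i1))
    xs = volume.centers(0)[sub[0]][:, None, None]
    ys = volume.centers(1)[sub[1]][None, :, None]
    zs = volume.centers(2)[sub[2]][None, None, :]
    a = placement.axis
    rel = (xs - placement.neck_point[0]) * a[0] + (ys - placement.neck_point[1]) * a[1] \
        + (zs - placement.neck_point[2]) * a[2]
    px = xs - placement.neck_point[0] - rel * a[0]
    py = ys - placement.neck_point[1] - rel * a[1]
    pz = zs - placement.neck_point[2] - rel * a[2]
    inside = (rel >= 0) & (rel <= geo.length) & (
        px**2 + py**2 + pz**2 <= geo.radius(np.clip(rel, 0, geo.length)) ** 2
    )
    block = volume.data[sub]
    roots = (block == LABEL_ANT_ROOT) | (block == LABEL_POST_ROOT)
    overlap = int(np.count_nonzero(inside & roots))
    block[inside & ~roots] = LABEL_SCREW
    volume.data[sub] = block
    return volume, overlap
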