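"""Scene serialization (JSON/YAML), mesh export (OBJ), NIfTI volumes, CSV.

The scene schema is a plain nested mapping mirroring the dataclasses in
:mod:`miniscrewsim.anatomy`; serialization is deterministic (sorted keys,
``repr`` floats) so identical cohorts produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .anatomy import (
    CorticalSheet,
    RootSurface,
    SegmentModel,
    Subject,
    SubjectLandmarks,
    ToothModel,
)
from .screw import ScrewPlacement

__all__ = [
    "segment_to_dict",
    "segment_from_dict",
    "subject_to_dict",
    "subject_from_dict",
    "save_scene",
    "load_scene",
    "placement_to_dict",
    "matrix_to_json",
    "root_mesh",
    "screw_mesh",
    "write_obj",
    "save_nifti",
]


def _vec(a) -> list[float]:
    return [float(x) for x in np.asarray(a, dtype=float).ravel()]


def _root_to_dict(r: RootSurface) -> dict:
    return dict(
        cej_center=_vec(r.cej_center),
        axis=_vec(r.axis),
        length=float(r.length),
        semi_axis_md=float(r.semi_axis_md),
        semi_axis_bl=float(r.semi_axis_bl),
        taper=float(r.taper),
        bow=float(r.bow),
    )


def _tooth_to_dict(t: ToothModel) -> dict:
    return dict(
        label=int(t.label),
        roots=[_root_to_dict(r) for r in t.roots],
        buccal_cusp=_vec(t.buccal_cusp),
        cej_level=float(t.cej_level),
    )


def _tooth_from_dict(d: dict) -> ToothModel:
    return ToothModel(
        label=int(d["label"]),
        roots=[RootSurface(**{**r, "cej_center": np.array(r["cej_center"]),
                              "axis": np.array(r["axis"])}) for r in d["roots"]],
        buccal_cusp=np.array(d["buccal_cusp"]),
        cej_level=float(d["cej_level"]),
    )


def segment_to_dict(seg: SegmentModel) -> dict:
    b = seg.bone
    return dict(
        jaw=seg.jaw,
        site=seg.site,
        side=seg.side,
        anterior=_tooth_to_dict(seg.anterior),
        posterior=_tooth_to_dict(seg.posterior),
        bone=dict(
            buccal_offset=float(b.buccal_offset),
            thickness=float(b.thickness),
            cej_z=float(b.cej_z),
            apical_sign=int(b.apical_sign),
            buccal_sign=int(b.buccal_sign),
            slope=float(b.slope),
            thickness_slope=float(b.thickness_slope),
            crest_offset=float(b.crest_offset),
            apical_extent=float(b.apical_extent),
        ),
        molar_cusp_mesial=_vec(seg.molar_cusp_mesial),
        molar_cusp_distal=_vec(seg.molar_cusp_distal),
        pose=[_vec(row) for row in seg.pose],
    )


def segment_from_dict(d: dict) -> SegmentModel:
    return SegmentModel(
        jaw=d["jaw"],
        site=d["site"],
        side=d["side"],
        anterior=_tooth_from_dict(d["anterior"]),
        posterior=_tooth_from_dict(d["posterior"]),
        bone=CorticalSheet(**d["bone"]),
        molar_cusp_mesial=np.array(d["molar_cusp_mesial"]),
        molar_cusp_distal=np.array(d["molar_cusp_distal"]),
        pose=np.array(d["pose"]),
    )


def subject_to_dict(s: Subject) -> dict:
    lm = s.landmarks
    return dict(
        id=s.id,
        sex=s.sex,
        mp_angle=float(s.mp_angle),
        fhi=float(s.fhi),
        facial_type=s.facial_type,
        landmarks=dict(
            occlusal_points=[_vec(p) for p in lm.occlusal_points],
            mb_cusp_right=_vec(lm.mb_cusp_right),
            mb_cusp_left=_vec(lm.mb_cusp_left),
            apical_hint=_vec(lm.apical_hint),
        ),
        segments={
            "|".join(k): segment_to_dict(seg) for k, seg in sorted(s.segments.items())
        },
    )


def subject_from_dict(d: dict) -> Subject:
    lm = d["landmarks"]
    return Subject(
        id=d["id"],
        sex=d["sex"],
        mp_angle=float(d["mp_angle"]),
        fhi=float(d["fhi"]),
        facial_type=d["facial_type"],
        segments={
            tuple(k.split("|")): segment_from_dict(v) for k, v in d["segments"].items()
        },
        landmarks=SubjectLandmarks(
            occlusal_points=np.array(lm["occlusal_points"]),
            mb_cusp_right=np.array(lm["mb_cusp_right"]),
            mb_cusp_left=np.array(lm["mb_cusp_left"]),
            apical_hint=np.array(lm["apical_hint"]),
        ),
    )


def save_scene(obj, path) -> None:
    """Write a Subject/SegmentModel (or list of Subjects) as JSON or YAML."""
    path = Path(path)
    if isinstance(obj, Subject):
        payload = subject_to_dict(obj)
    elif isinstance(obj, SegmentModel):
        payload = segment_to_dict(obj)
    else:
        payload = [subject_to_dict(s) for s in obj]
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, sort_keys=True, indent=1))


def load_scene(path):
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        payload = yaml.safe_load(path.read_text())
    else:
        payload = json.loads(path.read_text())
    if isinstance(payload, list):
        return [subject_from_dict(d) for d in payload]
    if "segments" in payload:
        return subject_from_dict(payload)
    return segment_from_dict(payload)


def placement_to_dict(p: ScrewPlacement) -> dict:
    return dict(
        insertion_point=_vec(p.insertion_point),
        axis=_vec(p.axis),
        angle=float(p.angle),
        neck_point=_vec(p.neck_point),
        apex_point=_vec(p.apex_point),
        screw=dict(
            length=float(p.screw.length),
            neck_diameter=float(p.screw.neck_diameter),
            tip_diameter=float(p.screw.tip_diameter),
        ),
    )


def matrix_to_json(matrix: np.ndarray, path) -> None:
    Path(path).write_text(
        json.dumps([_vec(row) for row in np.asarray(matrix, float).reshape(4, 4)])
    )


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def _tube_mesh(centers, rx, ry, n_theta=48):
    """Triangulated tube through a stack of axis-aligned ellipses."""
    th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    rings = []
    for c, a, b in zip(centers, rx, ry):
        rings.append(
            np.column_stack(
                [c[0] + a * np.cos(th), c[1] + b * np.sin(th), np.full(n_theta, c[2])]
            )
        )
    verts = np.vstack(rings)
    faces = []
    n_rings = len(rings)
    for i in range(n_rings - 1):
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            a0, a1 = i * n_theta + j, i * n_theta + j2
            b0, b1 = (i + 1) * n_theta + j, (i + 1) * n_theta + j2
            faces.append((a0, a1, b1))
            faces.append((a0, b1, b0))
    # cap fans
    for ring, flip in ((0, True), (n_rings - 1, False)):
        center = np.mean(rings[ring], axis=0)
        ci = len(verts)
        verts = np.vstack([verts, center[None, :]])
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            tri = (ring * n_theta + j, ring * n_theta + j2, ci)
            faces.append(tri[::-1] if flip else tri)
    return verts, np.array(faces, dtype=int)


def root_mesh(root: RootSurface, n_axial: int = 24, n_theta: int = 48):
    ds = np.linspace(0.0, root.length, n_axial)
    centers, rxs, rys = [], [], []
    for d in ds:
        t = d / root.length
        shrink = 1 - root.taper * t
        c = root.cej_center + d * root.axis
        c = c + np.array([0.0, root.bow * 4 * t * (1 - t), 0.0])
        centers.append(c)
        rxs.append(root.semi_axis_bl * shrink)
        rys.append(root.semi_axis_md * shrink)
    return _tube_mesh(centers, rxs, rys, n_theta)


def screw_mesh(placement: ScrewPlacement, n_axial: int = 12, n_theta: int = 32):
    geo = placement.screw
    e1, e2 = placement.perp_basis()
    th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    ss = np.linspace(0.0, geo.length, n_axial)
    rings = []
    for s in ss:
        c = placement.neck_point + s * placement.axis
        r = geo.radius(s)
        rings.append(
            c[None, :]
            + r * (np.cos(th)[:, None] * e1[None, :] + np.sin(th)[:, None] * e2[None, :])
        )
    verts = np.vstack(rings)
    faces = []
    for i in range(n_axial - 1):
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            a0, a1 = i * n_theta + j, i * n_theta + j2
            b0, b1 = (i + 1) * n_theta + j, (i + 1) * n_theta + j2
            faces.append((a0, a1, b1))
            faces.append((a0, b1, b0))
    return verts, np.array(faces, dtype=int)


def write_obj(path, meshes) -> None:
    """Write one or more ``(vertices, faces)`` meshes to a Wavefront OBJ."""
    if isinstance(meshes, tuple):
        meshes = {"mesh": meshes}
    lines = []
    offset = 0
    for name, (verts, faces) in meshes.items():
        lines.append(f"o {name}")
        for v in verts:
            lines.append(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
        for f in faces:
            lines.append(f"f {f[0] + 1 + offset} {f[1] + 1 + offset} {f[2] + 1 + offset}")
        offset += len(verts)
    Path(path).write_text("\n".join(lines) + "\n")


def save_nifti(volume, path) -> None:
    """Write a labeled volume as NIfTI plus a JSON label-legend sidecar."""
    import nibabel as nib

    affine = np.diag([volume.voxel_size] * 3 + [1.0])
    affine[:3, 3] = volume.origin + 0.5 * volume.voxel_size
    img = nib.Nifti1Image(volume.data.astype(np.uint8), affine)
    path = Path(path)
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix(".labels.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in volume.legend.items()},
                                  sort_keys=True, indent=1))
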