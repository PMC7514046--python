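import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from miniscrewsim._testing import random_scene
from miniscrewsim.anatomy import SubjectLandmarks, make_segment
from miniscrewsim.frame import build_occlusal_frame, to_frame
from miniscrewsim.measure import (
    NO_OVERLAP,
    MeasureConfig,
    Outcome,
    brute_force_distance,
    detect_contact,
    directional_gap,
    measure,
    slice_distance,
    slice_grid,
)
from miniscrewsim.screw import ScrewGeometry, angulate, initial_placement

ANGLES = (0, 30, 45, 60)
GROUP_NAMES = ("hyperdivergent", "normodivergent", "hypodivergent")


def _circle(center, r, n=720):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def _plain_overrides(**extra):
    zero = dict(taper=0.0, tilt=0.0, tilt_bl=0.0, bow=0.0)
    ov = {"anterior": dict(zero), "posterior": dict(zero)}
    ov.update(extra)
    return ov


def _cylinder_scene(cej_gap=3.0, angle=0, jaw="Mx"):
    """Parallel-cylinder roots and a cylindrical screw: closed-form gaps."""
    seg = make_segment(jaw, "5-6", overrides=_plain_overrides(cej_gap=cej_gap))
    geo = ScrewGeometry(tip_diameter=1.5)
    pl = initial_placement(seg, geo)
    if angle:
        pl = angulate(pl, angle, seg)
    return seg, pl


class TestDirectionalGap:
    def test_collinear_circles_closed_form(self):
        screw = _circle((0.0, 0.0), 0.75)
        root = _circle((0.0, 3.0), 1.0)
        gap = directional_gap(screw, root, mesial_dir=[0.0, 1.0])
        assert gap == pytest.approx(3.0 - 1.0 - 0.75, abs=1e-3)

    def test_disjoint_perpendicular_intervals(self):
        # screw v-interval [4, 5.5] vs root [0, 3] along the x (v) axis
        screw = _circle((4.75, 0.0), 0.75)
        root = _circle((1.5, 5.0), 1.5)
        assert directional_gap(screw, root, mesial_dir=[0.0, 1.0]) is NO_OVERLAP

    def test_offset_circles_match_exact_geometry(self):
        # gap along +y at shared v computed against the analytic boundary
        screw = _circle((0.0, 0.0), 0.75)
        root = _circle((0.5, 4.0), 1.0)
        gap = directional_gap(screw, root, mesial_dir=[0.0, 1.0])
        vs = np.linspace(-0.25, 0.75, 20001)
        exact = np.min(
            (4.0 - np.sqrt(1 - (vs - 0.5) ** 2))
            - np.sqrt(0.75**2 - np.clip(vs, -0.75, 0.75) ** 2)
        )
        assert gap == pytest.approx(exact, abs=1e-3)


class TestSliceDistance:
    def test_cylinder_scene_closed_form(self):
        seg, pl = _cylinder_scene(cej_gap=3.0)
        d = slice_distance(seg, pl, float(pl.neck_point[2]))
        assert d == pytest.approx(3.0 / 2 - 0.75, abs=5e-4)

    def test_cylinder_scene_exact_gap_at_every_slice(self):
        # A tilted cylinder's horizontal section is an exact ellipse, so the
        # per-slice gap has a closed-form boundary description: compare the
        # polygon/chain machinery against it on a dense offset grid.
        seg, pl = _cylinder_scene(cej_gap=3.0, angle=45)
        root = seg.anterior.root
        cxa, cya, rxa, rya = root.section(float(pl.neck_point[2]))
        a = pl.axis
        sx = 0.75 / abs(a[2])  # section semi-axis along x for a 45 deg tilt
        zs = slice_grid(pl, 0.1, seg.apical_sign)
        for z in zs[12:-12:5]:  # interior slices, clear of the end caps
            s_c = (z - pl.neck_point[2]) / a[2]
            x_c = pl.neck_point[0] + s_c * a[0]
            lo = max(x_c - sx, cxa - rxa)
            hi = min(x_c + sx, cxa + rxa)
            assert lo < hi
            xg = np.linspace(lo, hi, 40001)
            screw_y = 0.75 * np.sqrt(np.clip(1 - ((xg - x_c) / sx) ** 2, 0, None))
            root_y = cya - rya * np.sqrt(np.clip(1 - ((xg - cxa) / rxa) ** 2, 0, None))
            expected = float(np.min(root_y - screw_y))
            assert slice_distance(seg, pl, float(z)) == pytest.approx(
                expected, abs=5e-4
            )

    def test_empty_screw_section_raises(self):
        seg, pl = _cylinder_scene()
        with pytest.raises(ValueError, match="empty"):
            slice_distance(seg, pl, float(pl.neck_point[2]) + 5.0)

    def test_root_not_reaching_slice_is_no_overlap(self):
        seg, pl = _cylinder_scene(angle=60)
        seg.anterior.roots[0].length = 1.0  # root ends above every slice
        zs = slice_grid(pl, 0.1, seg.apical_sign)
        assert slice_distance(seg, pl, float(zs[-1])) is NO_OVERLAP


class TestDetectContact:
    def test_narrow_corridor_pigeonhole(self):
        # corridor narrower than the 1.5 mm screw must touch a root
        seg, pl = _cylinder_scene(cej_gap=1.2)
        assert detect_contact(seg, pl)

    def test_wide_corridor_no_contact(self):
        seg, pl = _cylinder_scene(cej_gap=4.0)
        assert not detect_contact(seg, pl)

    def test_constructed_tangency(self):
        # root surface exactly on the screw's mesial plane (y = +0.75)
        seg, pl = _cylinder_scene(cej_gap=1.5)
        assert detect_contact(seg, pl, tol=1e-6)


class TestMeasure:
    def test_cylinder_scene_measures_closed_form(self):
        seg, pl = _cylinder_scene(cej_gap=3.0, angle=45)
        rec = measure(seg, pl)
        assert rec.outcome is Outcome.MEASURABLE
        assert rec.distance == pytest.approx(0.75, abs=5e-4)

    def test_contact_scene(self):
        seg, pl = _cylinder_scene(cej_gap=1.2)
        assert measure(seg, pl).outcome is Outcome.CONTACT

    def test_noncontact_scene(self):
        # strongly lingually inclined roots + buccal sheet + 60 degrees:
        # the screw never enters the anterior root's corridor
        ov = _plain_overrides(ridge_offset=5.8)
        for k in ("anterior", "posterior"):
            ov[k].update(taper=0.35, tilt_bl=0.35)
        seg = make_segment("Mx", "5-6", overrides=ov)
        pl = angulate(initial_placement(seg), 60, seg)
        rec = measure(seg, pl)
        assert rec.outcome is Outcome.NONCONTACT
        assert rec.distance is None

    def test_argmin_is_most_cervical_minimum(self):
        seg = make_segment("Mn", "5-6")
        pl = angulate(initial_placement(seg), 45, seg)
        rec = measure(seg, pl)
        zs = slice_grid(pl, 0.1, seg.apical_sign)
        ds = np.array(
            [
                (lambda d: np.inf if d is NO_OVERLAP else d)(
                    slice_distance(seg, pl, float(z))
                )
                for z in zs
            ]
        )
        best = np.min(ds)
        first = zs[np.argmax(ds <= best + 1e-12)]
        assert rec.argmin_slice_z == pytest.approx(float(first))
        assert rec.distance == pytest.approx(best)

    @pytest.mark.parametrize("jaw,site", [("Mx", "5-6"), ("Mn", "5-6"), ("Mn", "6-7")])
    @pytest.mark.parametrize("group", GROUP_NAMES)
    def test_monotone_in_angle_at_widening_sites(self, jaw, site, group):
        seg = make_segment(jaw, site, facial_type_params=group)
        pl0 = initial_placement(seg)
        dists = []
        for angle in ANGLES:
            pl = pl0 if angle == 0 else angulate(pl0, angle, seg)
            rec = measure(seg, pl)
            if rec.outcome is not Outcome.MEASURABLE:
                break  # noncontact terminates the comparable sequence
            dists.append(rec.distance)
        assert len(dists) >= 2
        assert all(b >= a - 1e-9 for a, b in zip(dists, dists[1:]))

    def test_mx67_constriction_dip(self):
        seg = make_segment("Mx", "6-7", facial_type_params="normodivergent")
        pl0 = initial_placement(seg)
        d = {}
        for angle in ANGLES:
            pl = pl0 if angle == 0 else angulate(pl0, angle, seg)
            d[angle] = measure(seg, pl).distance
        assert d[30] < d[0]
        assert d[45] > d[30]
        assert d[60] > d[30]

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_slice_refinement_never_increases_minimum(self, seed):
        seg, pl = random_scene(seed)
        coarse = measure(seg, pl, MeasureConfig(slice_thickness=0.1))
        fine = measure(seg, pl, MeasureConfig(slice_thickness=0.05))
        if coarse.outcome is Outcome.MEASURABLE:
            assert fine.outcome is Outcome.MEASURABLE
            assert fine.distance <= coarse.distance + 1e-12

    def test_pose_invariance(self, rng):
        seg = make_segment("Mx", "6-7")
        base = measure(seg, initial_placement(seg)).distance
        lm = SubjectLandmarks.canonical()
        for _ in range(5):
            m = np.eye(4)
            m[:3, :3] = Rotation.random(rng=rng).as_matrix()
            m[:3, 3] = rng.uniform(-30, 30, 3)
            lm2 = lm.transformed(m)
            fr = build_occlusal_frame(
                lm2.occlusal_points, lm2.mb_cusp_right, lm2.mb_cusp_left,
                lm2.apical_hint,
            )
            seg2 = to_frame(seg.with_pose(m), fr)
            rec = measure(seg2, initial_placement(seg2))
            assert rec.distance == pytest.approx(base, abs=1e-6)

    def test_unstandardized_segment_rejected(self):
        seg = make_segment("Mx", "5-6")
        pl = initial_placement(seg)
        posed = seg.with_pose(
            np.array([[0, -1, 0, 5], [1, 0, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]])
        )
        with pytest.raises(ValueError, match="standardized"):
            measure(posed, pl)


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(12))
    def test_agreement_on_random_scenes(self, seed):
        seg, pl = random_scene(seed)
        rec = measure(seg, pl)
        outcome, value = brute_force_distance(seg, pl, n_samples=8000, seed=seed)
        assert outcome == rec.outcome
        if rec.outcome is Outcome.MEASURABLE:
            assert value == pytest.approx(rec.distance, abs=1e-3)

    def test_min_monotone_in_samples(self):
        seg, pl = random_scene(2)
        values = []
        for n in (1000, 2000, 4000):
            outcome, value = brute_force_distance(seg, pl, n_samples=n, seed=7)
            assert outcome is Outcome.MEASURABLE
            values.append(value)
        assert values[1] <= values[0] + 1e-12
        assert values[2] <= values[1] + 1e-12

    def test_contact_scene(self):
        seg, pl = _cylinder_scene(cej_gap=1.0)
        outcome, _ = brute_force_distance(seg, pl, n_samples=1000, seed=0)
        assert outcome is Outcome.CONTACT

    def test_noncontact_scene(self):
        ov = _plain_overrides(ridge_offset=5.8)
        for k in ("anterior", "posterior"):
            ov[k].update(taper=0.35, tilt_bl=0.35)
        seg = make_segment("Mx", "5-6", overrides=ov)
        pl = angulate(initial_placement(seg), 60, seg)
        outcome, _ = brute_force_distance(seg, pl, n_samples=2000, seed=0)
        assert outcome is Outcome.NONCONTACT
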