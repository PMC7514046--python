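"""Seeded random scenes for oracle-equivalence and agreement suites."""

from __future__ import annotations

import numpy as np

from .anatomy import JAWS, SITES, make_segment
from .screw import ScrewGeometry, angulate, initial_placement

__all__ = ["random_scene"]


def random_scene(seed: int, angles=(0, 30, 45, 60)):
    """A random desk-scale segment plus a valid screw placement.

    Geometry parameters are drawn around the site defaults (corridor width,
    tapers, tilts, bows, ridge offset) and the insertion angle uniformly
    from ``angles``; draws that violate placement constraints are retried
    with a derived seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([0x5CE9E, seed]))
    for _ in range(64):
        jaw = JAWS[rng.integers(2)]
        site = SITES[rng.integers(2)]
        side = ("left", "right")[rng.integers(2)]
        bow = float(rng.uniform(0.0, 0.9))
        overrides = {
            "cej_gap": float(rng.uniform(2.0, 3.8)),
            "ridge_offset": float(rng.uniform(3.6, 5.6)),
            "anterior": {
                "taper": float(rng.uniform(0.05, 0.5)),
                "tilt": float(rng.uniform(0.0, 0.12)),
                "tilt_bl": float(rng.uniform(0.0, 0.2)),
                "bow": -bow,
            },
            "posterior": {
                "taper": float(rng.uniform(0.05, 0.5)),
                "tilt": float(rng.uniform(0.0, 0.12)),
                "tilt_bl": float(rng.uniform(0.0, 0.2)),
                "bow": bow,
            },
        }
        angle = int(angles[rng.integers(len(angles))])
        try:
            segment = make_segment(
                jaw, site, overrides=overrides, side=side,
                seed=int(rng.integers(2**31)), jitter={"cusp": 0.05},
            )
            placement = initial_placement(segment, ScrewGeometry())
            if angle != 0:
                placement = angulate(placement, angle, segment)
        except ValueError:
            continue
        return segment, placement
    raise RuntimeError(f"could not build a valid random scene for seed {seed}")
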