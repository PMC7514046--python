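"""End-to-end orchestration: generator -> placement -> measurement -> stats.

``run_all`` executes every stage, writing scenes, per-side records, the
bilaterally averaged cohort table, the four output tables, the GEE summary
and a manifest capturing config, seeds, package version and per-file SHA-256
digests.  Analytic mode is fully deterministic under a fixed seed, so
re-running with the same manifest reproduces byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .anatomy import CohortConfig, Subject, simulate_cohort
from .io import save_scene
from .measure import MeasureConfig, MeasurementRecord, measure, voxel_measure
from .screw import DEFAULT_ANGLES, ScrewGeometry, angulate, initial_placement
from .stats import (
    GeeSpec,
    build_cohort_table,
    fit_ordinal_gee,
    nonmeasurable_rates,
    paired_side_test,
    rate_gt2,
    summarize_measurable,
)
from .voxel import rasterize_screw, voxelize

logger = logging.getLogger("miniscrewsim")

__all__ = ["RunConfig", "simulate", "measure_cohort", "analyze", "run_all",
           "records_to_frame"]


@dataclass
class RunConfig:
    """Single configuration object for the whole pipeline."""

    n_per_group: int = 20
    seed: int = 0
    angles: tuple = DEFAULT_ANGLES
    mode: str = "analytic"  # "analytic" | "voxel"
    voxel_size: float = 0.3
    slice_thickness: float = 0.1
    resolution_deg: float = 1.0
    screw: dict = field(default_factory=dict)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    gee: GeeSpec = field(default_factory=GeeSpec)
    write_scenes: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        gee = GeeSpec(**raw.pop("gee", {}))
        cfg = cls(cohort=cohort, gee=gee, **raw)
        cfg.angles = tuple(cfg.angles)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["facial_params"] = {
            k: dataclasses.asdict(v) for k, v in self.cohort.facial_params.items()
        }
        d["cohort"]["site_overrides"] = {
            (k if isinstance(k, str) else " ".join(k)): v
            for k, v in self.cohort.site_overrides.items()
        }
        d["angles"] = list(self.angles)
        return d


def simulate(config: RunConfig) -> list[Subject]:
    """Stage 1: generate the cohort."""
    t0 = time.perf_counter()
    subjects = simulate_cohort(config.n_per_group, config.cohort, seed=config.seed)
    logger.info("simulate: %d subjects in %.1fs", len(subjects), time.perf_counter() - t0)
    return subjects


def _measure_one(segment, screw_geo, angle, mcfg, config, subject_id):
    placement0 = initial_placement(segment, screw_geo)
    placement = (
        placement0 if angle == 0 else angulate(placement0, angle, segment)
    )
    if config.mode == "voxel":
        vol = voxelize(segment, config.voxel_size)
        vol, _overlap = rasterize_screw(vol, placement)
        return voxel_measure(
            vol, placement, subject_id=subject_id,
            jaw=segment.jaw, site=segment.site, side=segment.side,
        )
    return measure(segment, placement, mcfg, subject_id=subject_id)


def measure_cohort(subjects: list[Subject], config: RunConfig) -> list[MeasurementRecord]:
    """Stage 2: place and measure every screw (per side, before averaging)."""
    t0 = time.perf_counter()
    screw_geo = ScrewGeometry(**config.screw) if config.screw else ScrewGeometry()
    mcfg = MeasureConfig(
        slice_thickness=config.slice_thickness, resolution_deg=config.resolution_deg
    )
    records: list[MeasurementRecord] = []
    for subj in subjects:
        for key, segment in sorted(subj.segments.items()):
            for angle in config.angles:
                try:
                    records.append(
                        _measure_one(segment, screw_geo, angle, mcfg, config, subj.id)
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"measurement failed at subject={subj.id} segment={key} "
                        f"angle={angle}: {exc}"
                    ) from exc
    logger.info(
        "measure: %d records in %.1fs", len(records), time.perf_counter() - t0
    )
    return records


def records_to_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                subject_id=r.subject_id,
                jaw=r.jaw,
                site=r.site,
                side=r.side,
                angle=int(r.angle),
                outcome=r.outcome.value,
                distance_mm=r.distance,
                argmin_z=r.argmin_slice_z,
            )
            for r in records
        ]
    )


def analyze(
    subjects: list[Subject],
    records: list[MeasurementRecord],
    config: RunConfig,
    fit_gee: bool = True,
) -> dict:
    """Stage 3: bilateral averaging, summary tables and the GEE stage."""
    t0 = time.perf_counter()
    cohort = build_cohort_table(subjects, records)
    side_frame = records_to_frame(records)
    out = {
        "cohort": cohort,
        "paired": paired_side_test(side_frame),
        "t2": cohort["category"].value_counts().reindex(range(7), fill_value=0)
        .rename_axis("category").reset_index(name="count"),
        "t3": summarize_measurable(cohort),
        "t4": rate_gt2(cohort),
        "t5": nonmeasurable_rates(cohort),
    }
    if fit_gee:
        out["gee"] = fit_ordinal_gee(cohort, config.gee)
    logger.info("analyze: done in %.1fs", time.perf_counter() - t0)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, out_dir, fit_gee: bool = True) -> Path:
    """Run every stage and write the output directory.

    Layout: ``scenes/``, ``records.csv`` (per side), ``cohort.csv``
    (bilaterally averaged), ``tables/t{2..5}.csv``, ``gee.json``,
    ``manifest.json``.
    """
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    subjects = simulate(config)
    if config.write_scenes:
        scenes = out / "scenes"
        scenes.mkdir(exist_ok=True)
        for s in subjects:
            save_scene(s, scenes / f"{s.id}.json")
        covs = pd.DataFrame(
            [
                dict(subject_id=s.id, sex=s.sex, mp_angle=s.mp_angle, fhi=s.fhi,
                     facial_type=s.facial_type)
                for s in subjects
            ]
        )
        covs.to_csv(out / "covariates.csv", index=False)
    records = measure_cohort(subjects, config)
    results = analyze(subjects, records, config, fit_gee=fit_gee)

    records_to_frame(records).to_csv(out / "records.csv", index=False)
    results["cohort"].to_csv(out / "cohort.csv", index=False)
    for name in ("t2", "t3", "t4", "t5"):
        results[name].to_csv(out / "tables" / f"{name}.csv", index=False)
    payload = {
        "paired_side_test": dataclasses.asdict(results["paired"]),
    }
    if fit_gee:
        gee = results["gee"]
        payload["gee"] = {
            "term_pvalues": gee.term_pvalues,
            "orderings": {k: [str(x) for x in v] for k, v in gee.orderings.items()},
            "cov_struct": gee.cov_struct,
            "converged": gee.converged,
            "warnings": gee.warnings,
        }
    (out / "gee.json").write_text(json.dumps(payload, sort_keys=True, indent=1))

    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "digests": {str(p.relative_to(out)): _sha256(p) for p in files},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return out
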