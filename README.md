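# miniscrewsim

Virtual placement of a tapered 1.5 x 6 mm orthodontic miniscrew at posterior
interradicular sites on synthetic 3D dental anatomy, with slice-based,
direction-constrained measurement of the miniscrew-root distance available
for molar distalization, and the downstream cohort statistics (ordinal
categorization, bilateral averaging, summary tables, ordinal GEE).

## What it does

* **`miniscrewsim.anatomy`** — seeded parametric generator of interradicular
  segments (two adjacent posterior teeth as tapered/bowed elliptical root
  tubes, a buccal cortical sheet whose thickness varies with jaw and vertical
  facial type) and whole simulated cohorts with per-group cephalometric
  covariates; vertical facial type classification (27/37 degree and 61/69 %
  cutoffs with exclusion of discordant cases).
* **`miniscrewsim.frame`** — occlusal coordinate-frame recovery from
  landmarks and the posterior reference line through the molar buccal cusps
  (the measurement / distalization direction).
* **`miniscrewsim.screw`** — tapered screw geometry and the placement
  protocol: insertion on the cortical sheet 4 mm apical of the CEJ at the
  interradicular mesiodistal midpoint, vertical angulation at 0/30/45/60
  degrees with the head re-seated on bone and an all-threads-in-bone check.
* **`miniscrewsim.measure`** — the core computation: 0.1-mm axial slicing
  between screw apex and neck; per slice, the shortest gap from the screw's
  mesial boundary to the anterior root's distal boundary along the reference
  direction; minimum over slices; contact / noncontact classification.
  Includes an independent brute-force oracle (`brute_force_distance`) and a
  voxel-domain counterpart (`voxel_measure`).
* **`miniscrewsim.voxel`** — labeled volume rasterization (CBCT stand-in)
  with NIfTI export.
* **`miniscrewsim.stats`** — 0-6 ordinal categorization, bilateral
  averaging, paired left/right t-test, summary tables (means/SDs of
  measurable distances, rates of distance > 2 mm, contact/noncontact rates)
  and a cumulative-logit GEE clustered by subject with factor interactions
  and cephalometric covariates.
* **`miniscrewsim.pipeline`** — end-to-end orchestration with manifesting
  (config, seeds, digests); fully deterministic in analytic mode.

## CLI

```sh
miniscrewsim run-all --seed 11 --out-dir out/           # full pipeline
miniscrewsim simulate --n-per-group 20 --seed 11 --out-dir out/
miniscrewsim measure --scenes out/scenes --out out/records.csv
miniscrewsim analyze --scenes out/scenes --records out/records.csv --out-dir out/
```

`run-all` writes `scenes/` (JSON scene files), `records.csv` (per-side),
`cohort.csv` (bilaterally averaged), `tables/t2..t5.csv`, `gee.json` and
`manifest.json`. Add `--voxel` for voxel-domain measurement.

## Notes on the geometry defaults

Default root dimensions, corridor widths and ridge thicknesses are generator
configuration at plausible literature scale — they are not measured values.
The defaults are tuned so the simulated cohorts reproduce the qualitative
structure the analysis expects: interradicular width increasing with depth
at the premolar-molar sites and the mandibular molar site, a mid-root
constriction between the maxillary molars, mandibular ridge thickness
ordered hypodivergent > normodivergent > hyperdivergent with no maxillary
facial-type difference, and noncontact placements appearing predominantly at
steep insertion angles. Every parameter can be overridden per run (YAML
config or `site_overrides`).
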