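"""Statistical layer: ordinal coding, bilateral averaging, summary tables
and the ordinal GEE stage.

The 7-level ordinal code for a measurement is::

    contact                 -> 0
    0   < distance <= 0.5   -> 1
    0.5 < distance <= 1     -> 2
    1   < distance <= 1.5   -> 3
    1.5 < distance <= 2     -> 4
    2   < distance          -> 5
    noncontact              -> 6

with upper bin edges inclusive.  The GEE stage fits a cumulative-logit
marginal model on the 0-6 code with repeated measures clustered by subject;
an established estimation routine (statsmodels ``OrdinalGEE``) is used
behind this module's contract.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.genmod.cov_struct import GlobalOddsRatio, Independence
from statsmodels.genmod.generalized_estimating_equations import OrdinalGEE

from .anatomy import GROUPS, Subject
from .measure import MeasurementRecord, Outcome

__all__ = [
    "CATEGORY_EDGES",
    "categorize",
    "bilateral_average",
    "PairedTestResult",
    "paired_side_test",
    "build_cohort_table",
    "summarize_measurable",
    "rate_gt2",
    "nonmeasurable_rates",
    "GeeSpec",
    "GeeResult",
    "fit_ordinal_gee",
    "round_half_up",
]

CATEGORY_EDGES = (0.5, 1.0, 1.5, 2.0)

_ANGLES_ORDER = (0, 30, 45, 60)


def categorize(record) -> int:
    """Ordinal 0-6 category of a measurement.

    Accepts a :class:`~miniscrewsim.measure.MeasurementRecord` or an
    ``(outcome, distance)`` pair.  Upper bin edges are inclusive
    (a distance of exactly 0.5 mm codes as 1).
    """
    if isinstance(record, MeasurementRecord):
        outcome, distance = record.outcome, record.distance
    else:
        outcome, distance = record
        outcome = Outcome(outcome)
    if outcome is Outcome.CONTACT:
        return 0
    if outcome is Outcome.NONCONTACT:
        return 6
    if distance is None or distance <= 0:
        raise ValueError("measurable outcome requires a positive distance")
    return 1 + int(np.searchsorted(CATEGORY_EDGES, distance, side="left"))


def bilateral_average(
    left: MeasurementRecord, right: MeasurementRecord
) -> tuple[MeasurementRecord, bool]:
    """Average a left/right pair into one record.

    Both measurable: arithmetic mean of distances.  Both contact (or both
    noncontact): that outcome.  Discordant measurability: the measurable
    side's value wins and the returned flag is True; a contact/noncontact
    discordance resolves to contact (the root-interfering outcome), also
    flagged.
    """
    for f in ("subject_id", "jaw", "site", "angle"):
        if getattr(left, f) != getattr(right, f):
            raise ValueError(f"bilateral pair mismatch on {f}")
    ids = dict(
        subject_id=left.subject_id, jaw=left.jaw, site=left.site,
        side="both", angle=left.angle,
    )
    lo, ro = left.outcome, right.outcome
    if lo is Outcome.MEASURABLE and ro is Outcome.MEASURABLE:
        d = 0.5 * (left.distance + right.distance)
        return MeasurementRecord(outcome=Outcome.MEASURABLE, distance=d, **ids), False
    if lo == ro:
        return MeasurementRecord(outcome=lo, **ids), False
    measurable = [r for r in (left, right) if r.outcome is Outcome.MEASURABLE]
    if measurable:
        m = measurable[0]
        return (
            MeasurementRecord(outcome=Outcome.MEASURABLE, distance=m.distance, **ids),
            True,
        )
    return MeasurementRecord(outcome=Outcome.CONTACT, **ids), True


@dataclass
class PairedTestResult:
    statistic: float
    pvalue: float
    n_pairs: int
    degenerate: bool = False


def paired_side_test(records: pd.DataFrame) -> PairedTestResult:
    """Paired t-test on left-minus-right differences of measurable distances.

    ``records`` is a long-format per-side table (columns ``subject_id, jaw,
    site, angle, side, outcome, distance_mm``).  Only conditions measurable
    on both sides contribute.  All-zero differences return ``t = 0, p = 1``;
    a nonzero constant offset has zero variance and is reported as a
    degenerate result.
    """
    df = records[records["outcome"] == Outcome.MEASURABLE.value]
    wide = df.pivot_table(
        index=["subject_id", "jaw", "site", "angle"],
        columns="side",
        values="distance_mm",
    ).dropna()
    if len(wide) < 2 or not {"left", "right"} <= set(wide.columns):
        raise ValueError("need at least two bilateral measurable pairs")
    diff = (wide["left"] - wide["right"]).to_numpy()
    n = len(diff)
    sd = float(np.std(diff, ddof=1))
    mean = float(np.mean(diff))
    if sd <= 1e-12 * max(1.0, abs(mean)):
        if abs(mean) <= 1e-12:
            return PairedTestResult(0.0, 1.0, n)
        return PairedTestResult(float(np.sign(mean)) * np.inf, 0.0, n, degenerate=True)
    from scipy import stats as sps

    t, p = sps.ttest_rel(wide["left"], wide["right"])
    return PairedTestResult(float(t), float(p), n)


def build_cohort_table(
    subjects: list[Subject], side_records: list[MeasurementRecord]
) -> pd.DataFrame:
    """Bilaterally averaged long-format cohort table (16 rows per subject)."""
    subj = {s.id: s for s in subjects}
    by_key: dict[tuple, dict[str, MeasurementRecord]] = {}
    for r in side_records:
        by_key.setdefault((r.subject_id, r.jaw, r.site, r.angle), {})[r.side] = r
    rows = []
    for (sid, jaw, site, angle), sides in sorted(by_key.items()):
        if set(sides) != {"left", "right"}:
            raise ValueError(f"incomplete bilateral pair for {(sid, jaw, site, angle)}")
        avg, discordant = bilateral_average(sides["left"], sides["right"])
        s = subj[sid]
        rows.append(
            dict(
                subject_id=sid,
                facial_type=s.facial_type,
                sex=s.sex,
                mp_angle=s.mp_angle,
                fhi=s.fhi,
                jaw=jaw,
                site=site,
                angle=int(angle),
                outcome=avg.outcome.value,
                distance_mm=avg.distance,
                category=categorize(avg),
                discordant_sides=discordant,
            )
        )
    return pd.DataFrame(rows)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention of the output tables)."""
    x = float(x)
    if not np.isfinite(x):
        return x
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _group_levels(df: pd.DataFrame) -> list[str]:
    return [g for g in GROUPS if g in set(df["facial_type"])]


def summarize_measurable(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of measurable distances by jaw x site x angle x group.

    Contact/noncontact rows are excluded from the statistics.  Cells with no
    measurable value are kept with ``n = 0`` and NaN mean (flagged, not
    dropped).
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    meas = cohort[cohort["outcome"] == Outcome.MEASURABLE.value]
    rows = []
    groups = ["Total"] + _group_levels(cohort)
    for (jaw, site, angle), cell in cohort.groupby(["jaw", "site", "angle"], sort=True):
        mcell = meas[
            (meas["jaw"] == jaw) & (meas["site"] == site) & (meas["angle"] == angle)
        ]
        for g in groups:
            sub = mcell if g == "Total" else mcell[mcell["facial_type"] == g]
            n = len(sub)
            rows.append(
                dict(
                    jaw=jaw,
                    site=site,
                    angle=angle,
                    group=g,
                    mean_mm=float(sub["distance_mm"].mean()) if n else np.nan,
                    sd_mm=float(sub["distance_mm"].std(ddof=1)) if n > 1 else
                    (0.0 if n == 1 else np.nan),
                    n=n,
                    empty_cell=n == 0,
                )
            )
    out = pd.DataFrame(rows)
    out["angle"] = out["angle"].astype(int)
    return out.sort_values(["jaw", "site", "angle", "group"]).reset_index(drop=True)


def rate_gt2(cohort: pd.DataFrame) -> pd.DataFrame:
    """Percent of rows with distance > 2 mm, by (jaw, site) x angle.

    The denominator is every row in the cell (equivalently, the rate of
    category 5).  Percentages are rounded half-up to one decimal.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    df = cohort.copy()
    df["gt2"] = (df["outcome"] == Outcome.MEASURABLE.value) & (df["distance_mm"] > 2.0)
    angles = sorted(df["angle"].unique())
    rows = []
    for (jaw, site), cell in df.groupby(["jaw", "site"], sort=True):
        row = {"jaw": jaw, "site": site}
        for ang in angles:
            sub = cell[cell["angle"] == ang]
            row[f"{int(ang)}"] = (
                round_half_up(100.0 * sub["gt2"].mean()) if len(sub) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def nonmeasurable_rates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Contact/noncontact percentages by jaw x site x angle x facial type.

    Denominators are the number of subjects of the facial group present in
    the cell.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    rows = []
    for (jaw, site, angle), cell in cohort.groupby(["jaw", "site", "angle"], sort=True):
        for g in _group_levels(cohort):
            sub = cell[cell["facial_type"] == g]
            n = len(sub)
            contact = (sub["outcome"] == Outcome.CONTACT.value).sum()
            noncontact = (sub["outcome"] == Outcome.NONCONTACT.value).sum()
            rows.append(
                dict(
                    jaw=jaw,
                    site=site,
                    angle=int(angle),
                    facial_type=g,
                    n=n,
                    contact_pct=round_half_up(100.0 * contact / n) if n else np.nan,
                    noncontact_pct=round_half_up(100.0 * noncontact / n) if n else np.nan,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ordinal GEE
# ---------------------------------------------------------------------------

@dataclass
class GeeSpec:
    """Model specification for :func:`fit_ordinal_gee`.

    Factors are nominal by default (angle and site can be made ordinal by
    passing them in ``ordinal_factors``, coding them as a single linear
    score).  ``cov_struct`` is one of ``independence`` (default) or
    ``global_odds_ratio`` -- the working structures the ordinal estimation
    routine supports.
    """

    factors: tuple[str, ...] = ("facial_type", "jaw", "site", "angle")
    interactions: tuple[tuple[str, str], ...] = (
        ("facial_type", "jaw"),
        ("facial_type", "site"),
        ("facial_type", "angle"),
        ("jaw", "site"),
        ("jaw", "angle"),
        ("site", "angle"),
    )
    covariates: tuple[str, ...] = ("sex", "mp_angle", "fhi")
    ordinal_factors: tuple[str, ...] = ()
    cov_struct: str = "independence"
    maxiter: int = 120


@dataclass
class GeeResult:
    """Term-level Wald tests, coefficients and direction summaries."""

    term_pvalues: dict[str, float]
    coefficients: pd.Series
    cov_struct: str
    orderings: dict[str, list]
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def pvalue(self, term: str) -> float:
        return self.term_pvalues[term]


_FACTOR_LEVELS = {
    "facial_type": list(GROUPS),
    "jaw": ["Mx", "Mn"],
    "site": ["5-6", "6-7"],
    "angle": list(_ANGLES_ORDER),
}


def _dummy_block(df: pd.DataFrame, factor: str, levels: list) -> pd.DataFrame:
    """Treatment-coded dummies (first level is the reference)."""
    block = pd.DataFrame(index=df.index)
    for lev in levels[1:]:
        block[f"{factor}[{lev}]"] = (df[factor] == lev).astype(float)
    return block


def _design(cohort: pd.DataFrame, spec: GeeSpec):
    """Design matrix (no constant: thresholds act as intercepts) + term map."""
    present = {
        f: [l for l in _FACTOR_LEVELS[f] if l in set(cohort[f])] for f in spec.factors
    }
    X = pd.DataFrame(index=cohort.index)
    terms: dict[str, list[str]] = {}
    blocks: dict[str, pd.DataFrame] = {}
    for f in spec.factors:
        if f in spec.ordinal_factors:
            col = f"{f}_linear"
            score = cohort[f].map({l: i for i, l in enumerate(present[f])}).astype(float)
            blocks[f] = pd.DataFrame({col: score}, index=cohort.index)
        else:
            blocks[f] = _dummy_block(cohort, f, present[f])
        X = pd.concat([X, blocks[f]], axis=1)
        terms[f] = list(blocks[f].columns)
    for fa, fb in spec.interactions:
        cols = []
        for ca in blocks[fa].columns:
            for cb in blocks[fb].columns:
                name = f"{ca}:{cb}"
                X[name] = blocks[fa][ca] * blocks[fb][cb]
                cols.append(name)
        terms[f"{fa}*{fb}"] = cols
    for cov in spec.covariates:
        if cov == "sex":
            X["sex[M]"] = (cohort["sex"] == "M").astype(float)
            terms["sex"] = ["sex[M]"]
        else:
            X[cov] = cohort[cov] - cohort[cov].mean()
            terms[cov] = [cov]
    return X, terms, present


def _wald(params: pd.Series, cov: pd.DataFrame, cols: list[str]) -> float:
    from scipy import stats as sps

    b = params[cols].to_numpy()
    V = cov.loc[cols, cols].to_numpy()
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        stat = float(b @ np.linalg.pinv(V) @ b)
    return float(sps.chi2.sf(stat, len(cols)))


def fit_ordinal_gee(cohort: pd.DataFrame, spec: GeeSpec | None = None) -> GeeResult:
    """Cumulative-logit GEE on the 0-6 category, clustered by subject.

    Returns term-level Wald p-values (each factor, the configured two-way
    interactions and the covariates) plus effect-direction summaries:
    ``orderings["facial_type"]`` lists groups by decreasing estimated
    distance, ``orderings["facial_type|Mn"]`` the within-jaw version, and
    similarly for angle.  Degenerate cells and non-convergence are reported
    in ``warnings`` rather than silently dropped.
    """
    spec = spec or GeeSpec()
    msgs: list[str] = []
    counts = cohort.groupby("facial_type")["subject_id"].nunique()
    if (counts < 2).any():
        raise ValueError("need at least two subjects per facial group")
    X, terms, present = _design(cohort, spec)
    y = cohort["category"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; ordinal model is degenerate")
    groups = cohort["subject_id"].to_numpy()
    cov_struct = {
        "independence": Independence,
        "global_odds_ratio": lambda: GlobalOddsRatio("ordinal"),
    }
    if spec.cov_struct not in cov_struct:
        raise ValueError(f"unsupported working correlation {spec.cov_struct!r}")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = OrdinalGEE(y, X.to_numpy(), groups=groups,
                           cov_struct=cov_struct[spec.cov_struct]())
        res = model.fit(maxiter=spec.maxiter)
    for w in caught:
        msgs.append(str(w.message))
    n_thresh = len(np.unique(y)) - 1
    names = [f"threshold_{i}" for i in range(n_thresh)] + list(X.columns)
    params = pd.Series(np.asarray(res.params), index=names)
    cov = pd.DataFrame(np.asarray(res.cov_params())[: len(names), : len(names)],
                       index=names, columns=names)
    if not np.all(np.isfinite(params.to_numpy())):
        raise RuntimeError("ordinal GEE estimation produced non-finite parameters")

    term_p = {t: _wald(params, cov, cols) for t, cols in terms.items() if cols}

    def effect(factor: str, level, jaw: str | None = None) -> float:
        levels = present[factor]
        if factor in spec.ordinal_factors:
            return levels.index(level) * params[f"{factor}_linear"]
        val = 0.0
        col = f"{factor}[{level}]"
        if col in params.index:
            val += params[col]
        if jaw is not None and jaw != present["jaw"][0]:
            icol = f"{col}:jaw[{jaw}]"
            if icol in params.index:
                val += params[icol]
        return val

    orderings: dict[str, list] = {}
    for f in ("facial_type", "angle", "jaw", "site"):
        if f in present:
            orderings[f] = sorted(
                present[f], key=lambda l: -effect(f, l)
            )
    if "facial_type" in present and "jaw" in present:
        for jaw in present["jaw"]:
            orderings[f"facial_type|{jaw}"] = sorted(
                present["facial_type"], key=lambda l: -effect("facial_type", l, jaw=jaw)
            )
    return GeeResult(
        term_pvalues=term_p,
        coefficients=params,
        cov_struct=spec.cov_struct,
        orderings=orderings,
        converged=bool(getattr(res, "converged", True)),
        warnings=msgs,
    )
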