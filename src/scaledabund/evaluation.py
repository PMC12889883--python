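"""Assessment procedures for the Scaled Abundance metric.

Four tools used to judge how well Scaled Abundances track actual abundances:

* :func:`group_cv` — replicate precision as a coefficient of variation
  (100 x sample sd / mean).
* :func:`fit_proportionality` — least-squares proportionality fit (through
  the origin by default, matching the zero-intercept form of the SA model)
  with a goodness-of-fit CV defined as 100 x residual standard error /
  mean(observed y).  Note: the residual standard error is df-corrected,
  ``sqrt(SS_res / (n - p))`` with p fitted coefficients.
* :func:`rotate_internal_standard` — systematically treat each taxon of a
  mock-community set as the internal standard, regress the remaining taxa's
  SA on their known actual abundances, and average the per-taxon regression
  CVs; the relative-abundance baseline (RA regressed on truth, no internal
  standard) is reported alongside.
* :func:`loq_profile` — for a dilution series, regress each taxon's SA on
  the dilution fraction through the origin and pair the regression CV with
  the taxon's relative abundance in the undiluted sample; plotting CV
  against relative abundance reveals the limit of quantitation, the lowest
  relative abundance at which SA still tracks actual abundance within a
  stated CV bound.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .scaling import RelativeAbundanceTable, ScaledAbundanceTable, _t_interval
from .tables import SampleMetadata, SpikeTruth

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "RotationSummary",
    "LoqProfile",
    "group_cv",
    "fit_proportionality",
    "rotate_internal_standard",
    "loq_profile",
    "spikein_precision",
]

#: Minimum number of samples a taxon must be observed in to be regressed.
MIN_REGRESSION_POINTS = 3


@dataclass(frozen=True)
class RegressionResult:
    """A proportionality fit for one taxon."""

    taxon_id: str
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    cv_percent: float
    n_points: int


@dataclass
class RotationSummary:
    """Average regression CVs for every choice of internal standard.

    ``data`` has one row per candidate IS (metric ``"SA"``) plus a single
    relative-abundance baseline row (metric ``"RA"``, candidate ``None``),
    with the mean regression CV across the remaining taxa and its 95%
    t-interval.  ``skipped`` lists (candidate, taxon) regressions dropped
    for having fewer than three usable points.
    """

    data: pd.DataFrame
    skipped: list = field(default_factory=list)


@dataclass
class LoqProfile:
    """Per-taxon regression CV paired with undiluted relative abundance."""

    data: pd.DataFrame  # index: taxon_id; columns: ra_undiluted, cv_percent, slope
    excluded: list = field(default_factory=list)


def group_cv(values: Sequence[float]) -> float:
    """Coefficient of variation, percent: ``100 * sample sd / mean``.

    Needs at least two values.  Returns NaN (undefined) when the mean is
    zero.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValidationError(f"group_cv needs >= 2 values, got {arr.size}")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / mean)


def spikein_precision(
    ra: RelativeAbundanceTable,
    sa: ScaledAbundanceTable,
    truth: SpikeTruth,
    metadata: SampleMetadata,
) -> pd.DataFrame:
    """Replicate and between-background precision of RA and SA for spike taxa.

    For each spiked taxon: within each replicate group (technical
    replicates of one background) the CV of the raw values; between
    backgrounds, the CV of the per-background replicate-mean values — each
    background contributes one averaged measurement, mirroring a comparison
    of distinct communities that were each measured in replicate.

    If Scaled Abundance removes compositionality, its between-background CV
    should approach the technical-replicate CV even though the backgrounds
    differ wildly in composition, while the relative-abundance
    between-background CV stays large.
    """
    metadata_df = metadata.data
    rows = []
    groups = [g for g in metadata_df["replicate_group"].dropna().unique()]
    for taxon in truth.taxon_ids:
        if taxon not in sa.data.columns:
            raise ValidationError(f"spiked taxon {taxon!r} absent from SA table")
        for grp in groups:
            samples = metadata.samples_in_group(grp)
            if len(samples) < 2:
                continue
            rows.append(
                {
                    "taxon_id": taxon,
                    "group": grp,
                    "scope": "within_replicates",
                    "cv_ra_percent": group_cv(ra.data.loc[samples, taxon]),
                    "cv_sa_percent": group_cv(sa.data.loc[samples, taxon]),
                }
            )
        by_bg_ra = (
            ra.data[taxon].groupby(metadata_df["background_id"], sort=False).mean()
        )
        by_bg_sa = (
            sa.data[taxon].groupby(metadata_df["background_id"], sort=False).mean()
        )
        if len(by_bg_sa) >= 2:
            rows.append(
                {
                    "taxon_id": taxon,
                    "group": "all_backgrounds",
                    "scope": "between_backgrounds",
                    "cv_ra_percent": group_cv(by_bg_ra),
                    "cv_sa_percent": group_cv(by_bg_sa),
                }
            )
    return pd.DataFrame(rows)


def fit_proportionality(
    x: Sequence[float],
    y: Sequence[float],
    *,
    through_origin: bool = True,
    ci_level: float = 0.95,
    taxon_id: str = "",
) -> RegressionResult:
    """Least-squares proportionality fit of y on x.

    Through the origin by default (the SA model ``SA = A * bias_ratio`` has
    no intercept); ``through_origin=False`` fits an ordinary line.  The
    goodness-of-fit CV is 100 x residual standard error / mean(y) with the
    residual standard error df-corrected as ``sqrt(SS_res / (n - p))``.
    The slope confidence interval is the standard t-interval.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    n = x.size
    if n < MIN_REGRESSION_POINTS:
        raise ValidationError(
            f"need >= {MIN_REGRESSION_POINTS} points for a regression, got {n}"
        )
    if np.ptp(x) == 0:
        raise ValidationError("degenerate x: all values equal")

    if through_origin:
        sxx = float(np.dot(x, x))
        slope = float(np.dot(x, y)) / sxx
        intercept = 0.0
        resid = y - slope * x
        dof = n - 1
        se_slope = math.sqrt(max(float(np.dot(resid, resid)), 0.0) / dof / sxx)
    else:
        slope_np, intercept_np = np.polyfit(x, y, 1)
        slope, intercept = float(slope_np), float(intercept_np)
        resid = y - (slope * x + intercept)
        dof = n - 2
        sxx = float(np.sum((x - x.mean()) ** 2))
        se_slope = math.sqrt(max(float(np.dot(resid, resid)), 0.0) / dof / sxx)

    rse = math.sqrt(float(np.dot(resid, resid)) / dof)
    tcrit = stats.t.ppf(0.5 + ci_level / 2, df=dof)
    ci = (slope - tcrit * se_slope, slope + tcrit * se_slope)
    mean_y = float(y.mean())
    cv = float("nan") if mean_y == 0 else 100.0 * rse / abs(mean_y)
    return RegressionResult(
        taxon_id=taxon_id,
        slope=slope,
        slope_ci=ci,
        intercept=intercept,
        cv_percent=cv,
        n_points=n,
    )


def _per_taxon_regressions(
    metric: pd.DataFrame,
    truth: pd.DataFrame,
    taxa: Sequence[str],
    *,
    through_origin: bool,
) -> tuple[dict[str, RegressionResult], list]:
    """Regress metric (SA or RA) on truth per taxon over usable samples."""
    fits: dict[str, RegressionResult] = {}
    skipped = []
    for taxon in taxa:
        xs = truth[taxon].to_numpy(dtype=float)
        ys = metric[taxon].to_numpy(dtype=float)
        mask = (xs > 0) & np.isfinite(ys)
        if mask.sum() < MIN_REGRESSION_POINTS or np.ptp(xs[mask]) == 0:
            skipped.append(taxon)
            continue
        fits[taxon] = fit_proportionality(
            xs[mask], ys[mask], through_origin=through_origin, taxon_id=taxon
        )
    return fits, skipped


def rotate_internal_standard(
    ra: RelativeAbundanceTable,
    truth: pd.DataFrame,
    *,
    ci_level: float = 0.95,
    through_origin: bool = True,
) -> RotationSummary:
    """Evaluate every taxon as a candidate internal standard.

    ``truth`` is a samples x taxa table of known actual abundances (zero
    where a taxon was left out of a community).  For each candidate, samples
    lacking the candidate (truth or observed RA zero) are omitted, SA is
    computed for the remaining taxa using the candidate's known abundance as
    the IS abundance, each taxon's SA is regressed on its truth, and the
    per-taxon regression CVs are averaged with a t-interval.  One
    relative-abundance baseline row (RA regressed on truth directly) is
    reported for comparison.

    On noise-free data every rotation gives mean CV 0 — the choice of
    internal standard does not matter.
    """
    taxa = list(ra.data.columns)
    if len(taxa) < 3:
        raise ValidationError("rotation needs >= 3 taxa")
    missing = set(taxa) - set(truth.columns)
    if missing:
        raise ValidationError(f"truth table lacks taxa: {sorted(missing)}")
    truth = truth.loc[ra.data.index, taxa].astype(float)

    rows = []
    skipped: list = []

    ra_fits, ra_skip = _per_taxon_regressions(
        ra.data, truth, taxa, through_origin=through_origin
    )
    skipped += [("RA", t) for t in ra_skip]
    cvs = [f.cv_percent for f in ra_fits.values() if np.isfinite(f.cv_percent)]
    if cvs:
        mean, lo, hi = _t_interval(np.asarray(cvs), ci_level) if len(cvs) > 1 else (
            cvs[0],
            cvs[0],
            cvs[0],
        )
        rows.append(
            {
                "metric": "RA",
                "candidate_is": None,
                "mean_cv_percent": mean,
                "ci_low": lo,
                "ci_high": hi,
                "n_taxa_averaged": len(cvs),
            }
        )

    for candidate in taxa:
        usable = (truth[candidate] > 0) & (ra.data[candidate] > 0)
        if usable.sum() < MIN_REGRESSION_POINTS:
            skipped.append((candidate, "*insufficient-samples*"))
            continue
        sub_ra = ra.data.loc[usable]
        sub_truth = truth.loc[usable]
        rest = [t for t in taxa if t != candidate]
        # SA under this rotation: candidate's known abundance plays A_IS.
        sa = sub_ra[rest].div(sub_ra[candidate], axis=0).mul(
            sub_truth[candidate], axis=0
        )
        fits, skip = _per_taxon_regressions(
            sa, sub_truth, rest, through_origin=through_origin
        )
        skipped += [(candidate, t) for t in skip]
        cvs = [f.cv_percent for f in fits.values() if np.isfinite(f.cv_percent)]
        if not cvs:
            skipped.append((candidate, "*no-usable-regressions*"))
            continue
        if len(cvs) > 1:
            mean, lo, hi = _t_interval(np.asarray(cvs), ci_level)
        else:
            mean = lo = hi = cvs[0]
        rows.append(
            {
                "metric": "SA",
                "candidate_is": candidate,
                "mean_cv_percent": mean,
                "ci_low": lo,
                "ci_high": hi,
                "n_taxa_averaged": len(cvs),
            }
        )

    return RotationSummary(pd.DataFrame(rows), skipped=skipped)


def loq_profile(
    sa: ScaledAbundanceTable,
    metadata: SampleMetadata,
    ra_reference: RelativeAbundanceTable,
    *,
    through_origin: bool = True,
) -> LoqProfile:
    """Regression-CV versus relative-abundance profile for a dilution series.

    Each native taxon's SA is regressed on the dilution fraction (through
    the origin); the regression CV is paired with the taxon's relative
    abundance in the undiluted (fraction = 1) sample.  Taxa absent from all
    samples are excluded and logged.
    """
    fractions = metadata.dilution_fractions().reindex(sa.sample_ids)
    if fractions.isna().any():
        bad = fractions.index[fractions.isna()][0]
        raise ValidationError(f"sample {bad!r} lacks a dilution_fraction")
    if fractions.nunique() < 3:
        raise ValidationError("need >= 3 distinct dilution levels")
    undiluted = fractions.index[fractions == 1.0]
    if len(undiluted) == 0:
        raise ValidationError("no undiluted (dilution_fraction = 1) sample present")

    native = sa.without_internal_standard()
    rows = []
    excluded = []
    for taxon in native.columns:
        ys = native[taxon].to_numpy(dtype=float)
        if not (ys > 0).any():
            excluded.append(taxon)
            continue
        fit = fit_proportionality(
            fractions.to_numpy(dtype=float),
            ys,
            through_origin=through_origin,
            taxon_id=taxon,
        )
        ra_undil = float(ra_reference.data.loc[undiluted, taxon].mean())
        rows.append(
            {
                "taxon_id": taxon,
                "ra_undiluted": ra_undil,
                "cv_percent": fit.cv_percent,
                "slope": fit.slope,
            }
        )
    if excluded:
        logger.info("excluded %d all-zero taxa from LOQ profile", len(excluded))
    df = pd.DataFrame(rows).set_index("taxon_id") if rows else pd.DataFrame(
        columns=["ra_undiluted", "cv_percent", "slope"]
    )
    return LoqProfile(df, excluded=excluded)
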