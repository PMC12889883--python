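"""Core Scaled Abundance arithmetic.

The measurement model: each taxon's analytical response is its actual
abundance times a protocol- and taxon-specific bias factor, and sequencing
closes the responses to a constant read budget, so the observed relative
abundance is

    RA_z = (A_z * B_z) / sum_t (A_t * B_t).

Referencing the internal standard (IS), spiked into every sample at known
actual abundance ``A_IS``, removes the compositional denominator:

    SA_z = (RA_z / RA_IS) * A_IS = A_z * (B_z / B_IS).

So Scaled Abundance is proportional to actual abundance with a
composition-independent slope, the bias ratio ``B_z / B_IS``.  Under a
locked-down protocol the bias ratio is constant across samples, giving

    dSA_z (between two samples) = dA_z,

and, when the bias ratio has been measured on samples with known truth,
``A_z = SA_z / (B_z / B_IS)`` back-calculates absolute abundance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError
from .tables import (
    CountTable,
    InternalStandardSpec,
    SampleMetadata,
    SpikeTruth,
    _validate_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RelativeAbundanceTable",
    "ScaledAbundanceTable",
    "BiasRatioEstimate",
    "FoldChangeTable",
    "AbundanceEstimateTable",
    "relative_abundance",
    "scaled_abundance",
    "estimate_bias_ratio",
    "quantify_actual",
    "fold_change",
]


@dataclass
class RelativeAbundanceTable:
    """Samples x taxa relative abundances; each row sums to 1."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _validate_matrix(self.data, what="relative abundance table")
        sums = self.data.sum(axis=1)
        bad = sums[(sums - 1.0).abs() > 1e-9]
        if len(bad):
            raise ValidationError(
                f"relative abundance rows must sum to 1: sample {bad.index[0]!r} "
                f"sums to {bad.iloc[0]!r}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)


@dataclass
class ScaledAbundanceTable:
    """Per-sample, per-taxon Scaled Abundances in the IS's units.

    The internal standard column is kept (its SA equals the IS actual
    abundance in every sample by construction) and flagged via
    ``is_taxon_id`` so downstream summaries can exclude it.
    """

    data: pd.DataFrame
    units: str = "copies/mcL"
    is_taxon_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _validate_matrix(self.data, what="scaled abundance table")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def without_internal_standard(self) -> pd.DataFrame:
        if self.is_taxon_id is None or self.is_taxon_id not in self.data.columns:
            return self.data
        return self.data.drop(columns=[self.is_taxon_id])


@dataclass(frozen=True)
class BiasRatioEstimate:
    """Point estimate and confidence interval of Bias_taxon / Bias_IS."""

    taxon_id: str
    point: float
    ci_low: float
    ci_high: float
    n_replicates: int
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError("a bias ratio estimate needs >= 2 replicates")
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValidationError(
                f"bias ratio CI ({self.ci_low}, {self.ci_high}) does not bracket "
                f"the point estimate {self.point}"
            )
        if self.point <= 0:
            raise ValidationError("bias ratio point estimate must be positive")


@dataclass
class FoldChangeTable:
    """Per-taxon SA fold changes for ordered sample pairs.

    Long-form table with one row per (numerator_sample, denominator_sample)
    pair and one column per taxon.  Entries are NaN (undefined) wherever
    either sample's Scaled Abundance is zero — a vanished taxon has no
    meaningful ratio, and infinities would poison downstream summaries.
    """

    data: pd.DataFrame  # index: MultiIndex (numerator_sample, denominator_sample)

    @property
    def pairs(self) -> list:
        return list(self.data.index)


@dataclass
class AbundanceEstimateTable:
    """Estimated actual abundances (SA divided by the bias ratio) with CIs."""

    data: pd.DataFrame
    ci_low: Optional[pd.DataFrame] = None
    ci_high: Optional[pd.DataFrame] = None
    units: str = "copies/mcL"


def relative_abundance(
    counts: CountTable, *, pseudocount: float = 0.0
) -> RelativeAbundanceTable:
    """Close each sample's counts to relative abundances.

    Proportions-mode tables pass through after validation.  ``pseudocount``
    adds a constant to every count before normalisation (off by default; the
    framework's equations have none, but log-scale workflows sometimes want
    one).

    Raises a :class:`ValidationError` naming the sample if any sample's
    total count is zero.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be nonnegative")
    df = counts.data
    if counts.mode == "proportions":
        if pseudocount:
            raise ValidationError("pseudocount applies to counts, not proportions")
        return RelativeAbundanceTable(df.copy())
    if pseudocount:
        df = df + pseudocount
    totals = df.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(
            f"sample {zero.index[0]!r} has zero total count; cannot normalise"
        )
    return RelativeAbundanceTable(df.div(totals, axis=0))


def scaled_abundance(
    ra: RelativeAbundanceTable,
    is_spec: InternalStandardSpec,
    *,
    on_zero_is: str = "error",
) -> ScaledAbundanceTable:
    """Compute Scaled Abundances: ``SA_z = (RA_z / RA_IS) * A_IS``.

    The internal standard's own SA equals its actual abundance exactly in
    every sample.  A sample where the internal standard was not observed
    (RA_IS = 0) cannot be scaled; by default this is a hard error because a
    vanished internal standard invalidates the sample.  With
    ``on_zero_is="drop"`` such samples are removed with a logged warning.
    """
    if is_spec.taxon_id not in ra.data.columns:
        raise ConfigError(
            f"internal standard taxon {is_spec.taxon_id!r} not present in table "
            f"(taxa: {list(ra.data.columns)[:8]}...)"
        )
    if on_zero_is not in ("error", "drop"):
        raise ValidationError(f"unknown on_zero_is policy {on_zero_is!r}")

    ra_is = ra.data[is_spec.taxon_id]
    zero = ra_is[ra_is == 0]
    df = ra.data
    if len(zero):
        if on_zero_is == "error":
            raise ValidationError(
                f"internal standard relative abundance is 0 in sample "
                f"{zero.index[0]!r}; pass on_zero_is='drop' to discard such samples"
            )
        logger.warning(
            "dropping %d sample(s) with zero internal-standard relative "
            "abundance: %s",
            len(zero),
            list(zero.index),
        )
        df = df.drop(index=zero.index)
        ra_is = ra_is.drop(index=zero.index)
        if df.empty:
            raise ValidationError("all samples dropped: IS absent everywhere")

    sa = df.div(ra_is, axis=0) * is_spec.actual_abundance
    # Exact identity for the IS column regardless of floating-point division.
    sa[is_spec.taxon_id] = is_spec.actual_abundance
    return ScaledAbundanceTable(sa, units=is_spec.units, is_taxon_id=is_spec.taxon_id)


def _t_interval(values: np.ndarray, ci_level: float) -> tuple[float, float, float]:
    """Mean and two-sided t-interval of a sample; zero width when sd == 0."""
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        return mean, mean, mean
    half = stats.t.ppf(0.5 + ci_level / 2, df=n - 1) * sd / math.sqrt(n)
    return mean, mean - half, mean + half


def estimate_bias_ratio(
    sa: ScaledAbundanceTable,
    truth: SpikeTruth,
    replicate_samples: Optional[Sequence[str]] = None,
    *,
    metadata: Optional[SampleMetadata] = None,
    replicate_group: Optional[str] = None,
    ci_level: float = 0.95,
    aggregation: str = "arithmetic",
) -> dict[str, BiasRatioEstimate]:
    """Estimate ``Bias_taxon / Bias_IS`` from replicate samples with known truth.

    For each spiked taxon the per-replicate ratio ``r_i = SA_i / A_truth`` is
    formed; the point estimate is the arithmetic mean of the ``r_i`` with a
    two-sided t-interval at ``ci_level``.  ``aggregation="geometric"``
    averages in log space instead (geometric mean, t-interval on log ratios
    back-transformed), for workflows that treat ratios multiplicatively.

    Replicates may be given explicitly (``replicate_samples``) or selected
    from ``metadata`` by ``replicate_group``.  At least two replicates are
    required — otherwise no confidence interval is estimable.
    """
    if aggregation not in ("arithmetic", "geometric"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    if replicate_samples is None:
        if metadata is None or replicate_group is None:
            raise ValidationError(
                "pass replicate_samples, or metadata with replicate_group"
            )
        replicate_samples = metadata.samples_in_group(replicate_group)
    replicate_samples = list(replicate_samples)
    unknown = set(replicate_samples) - set(sa.sample_ids)
    if unknown:
        raise ValidationError(f"unknown sample ids: {sorted(unknown)}")
    if len(replicate_samples) < 2:
        raise ValidationError(
            f"need >= 2 replicate samples to estimate a bias ratio, "
            f"got {len(replicate_samples)}"
        )

    estimates: dict[str, BiasRatioEstimate] = {}
    for taxon in truth.taxon_ids:
        if taxon not in sa.data.columns:
            raise ValidationError(
                f"spiked taxon {taxon!r} absent from the scaled abundance table"
            )
        ratios = np.array(
            [
                sa.data.loc[s, taxon] / truth.abundance_for(taxon, s)
                for s in replicate_samples
            ],
            dtype=float,
        )
        if aggregation == "geometric":
            if (ratios <= 0).any():
                raise ValidationError(
                    f"geometric aggregation needs positive ratios for {taxon!r}"
                )
            mean_log, lo_log, hi_log = _t_interval(np.log(ratios), ci_level)
            point, lo, hi = math.exp(mean_log), math.exp(lo_log), math.exp(hi_log)
        else:
            point, lo, hi = _t_interval(ratios, ci_level)
        estimates[taxon] = BiasRatioEstimate(
            taxon_id=taxon,
            point=point,
            ci_low=lo,
            ci_high=hi,
            n_replicates=len(replicate_samples),
            ci_level=ci_level,
        )
    return estimates


def quantify_actual(
    sa: ScaledAbundanceTable,
    bias: Mapping[str, BiasRatioEstimate],
    taxa: Optional[Sequence[str]] = None,
) -> AbundanceEstimateTable:
    """Back-calculate actual abundances: ``A_z = SA_z / (B_z / B_IS)``.

    CI bounds propagate from the bias-ratio interval: dividing by the upper
    bias bound gives the lower abundance bound and vice versa.
    """
    if taxa is None:
        taxa = list(bias)
    missing = [t for t in taxa if t not in bias]
    if missing:
        raise ValidationError(f"no bias ratio available for taxa: {missing}")
    absent = [t for t in taxa if t not in sa.data.columns]
    if absent:
        raise ValidationError(f"taxa absent from SA table: {absent}")

    sa_sub = sa.data[list(taxa)]
    points = pd.Series({t: bias[t].point for t in taxa})
    his = pd.Series({t: bias[t].ci_high for t in taxa})
    los = pd.Series({t: bias[t].ci_low for t in taxa})
    est = sa_sub.div(points, axis=1)
    lo = sa_sub.div(his, axis=1)
    hi = sa_sub.div(los, axis=1)
    degenerate = los.index[los <= 0]
    if len(degenerate):
        hi[degenerate] = np.inf
    return AbundanceEstimateTable(data=est, ci_low=lo, ci_high=hi, units=sa.units)


def fold_change(
    sa: ScaledAbundanceTable,
    pairs: Iterable[tuple[str, str]],
) -> FoldChangeTable:
    """SA fold changes ``dSA_z = SA_z(numerator) / SA_z(denominator)``.

    Under a locked-down protocol dSA equals the fold change in actual
    abundance, with no bias-ratio calculation needed.  The pair order is
    caller-specified and recorded in the output index.  Entries where either
    sample's SA is zero are NaN (undefined), never infinity.
    """
    pairs = list(pairs)
    known = set(sa.sample_ids)
    for num, den in pairs:
        for s in (num, den):
            if s not in known:
                raise ValidationError(f"unknown sample id {s!r}")
    rows = []
    for num, den in pairs:
        a = sa.data.loc[num].to_numpy(dtype=float)
        b = sa.data.loc[den].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((a > 0) & (b > 0), a / b, np.nan)
        rows.append(ratio)
    index = pd.MultiIndex.from_tuples(
        pairs, names=["numerator_sample", "denominator_sample"]
    )
    return FoldChangeTable(pd.DataFrame(rows, index=index, columns=sa.data.columns))
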