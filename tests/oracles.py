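"""Independent brute-force oracles used to cross-check the library.

These deliberately avoid the library's code paths: CVs are computed with
explicit loops, the through-origin slope by numerical minimisation of the
sum of squared residuals rather than the closed form, and rotation
averages by direct re-enumeration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq


def cv_percent_oracle(values) -> float:
    vals = [float(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    if mean == 0:
        return float("nan")
    ss = sum((v - mean) ** 2 for v in vals)
    sd = math.sqrt(ss / (n - 1))
    return 100.0 * sd / mean


def origin_fit_oracle(x, y) -> tuple[float, float]:
    """(slope, cv_percent) for y ~ slope * x by numerically root-finding the
    least-squares normal equation d(SSE)/dk = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def dsse(k):
        return sum(-2.0 * xi * (yi - k * xi) for xi, yi in zip(x, y))

    bound = 10.0 * (1.0 + float(np.sum(np.abs(x) * np.abs(y)) / np.sum(x * x)))
    slope = float(brentq(dsse, -bound, bound, xtol=1e-300, rtol=1e-15))
    resid = [yi - slope * xi for xi, yi in zip(x, y)]
    rse = math.sqrt(sum(r * r for r in resid) / (len(x) - 1))
    mean_y = sum(y) / len(y)
    cv = float("nan") if mean_y == 0 else 100.0 * rse / abs(mean_y)
    return slope, cv


def rotation_mean_cv_oracle(ra, truth, candidate) -> float:
    """Mean per-taxon regression CV for one internal-standard rotation.

    ``ra`` and ``truth`` are pandas DataFrames (samples x taxa).  Loops over
    the non-candidate taxa, builds SA by hand, fits through the origin with
    the numerical oracle, and averages the CVs of taxa with >= 3 usable
    points.
    """
    usable = (truth[candidate] > 0) & (ra[candidate] > 0)
    cvs = []
    for taxon in ra.columns:
        if taxon == candidate:
            continue
        xs, ys = [], []
        for sample in ra.index[usable]:
            x = truth.loc[sample, taxon]
            if x <= 0:
                continue
            sa = (
                ra.loc[sample, taxon]
                / ra.loc[sample, candidate]
                * truth.loc[sample, candidate]
            )
            xs.append(x)
            ys.append(sa)
        if len(xs) < 3 or len(set(xs)) < 2:
            continue
        _, cv = origin_fit_oracle(xs, ys)
        if math.isfinite(cv):
            cvs.append(cv)
    return sum(cvs) / len(cvs)
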