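"""Nonparametric and circular statistics used throughout the package.

Implements the three statistical procedures the analysis relies on:

* :func:`dunn_test` — Dunn's rank-based test for pairwise multiple
  comparisons between k groups, with midrank tie correction and an
  optional Holm or Bonferroni adjustment.
* :func:`rayleigh_test` — Rayleigh's test for circular uniformity, with
  support for axial data (orientations defined modulo 180 deg, which are
  doubled onto the full circle before testing).
* :func:`box_summary` — Tukey-style five-number summary with inner
  fences at Q1 - 1.5*IQR and Q3 + 1.5*IQR; whiskers extend to the most
  extreme data points inside the fences.

Quartiles and all other quantiles in this package use linear
interpolation between order statistics (numpy's default), fixed once so
that every module reports the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = ["dunn_test", "rayleigh_test", "box_summary", "BoxSummary", "RayleighResult"]


class RayleighResult(NamedTuple):
    """Result of Rayleigh's uniformity test."""

    n: int
    rbar: float
    z: float
    pvalue: float


@dataclass(frozen=True)
class BoxSummary:
    """Median/quartile summary with inner fences.

    ``lower_fence = Q1 - 1.5*IQR`` and ``upper_fence = Q3 + 1.5*IQR``;
    whiskers are the extreme data points within the fences; everything
    outside is listed in ``outliers``.
    """

    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray = field(repr=False)


def _as_groups(data) -> dict[str, np.ndarray]:
    if isinstance(data, Mapping):
        items = data.items()
    else:
        items = ((f"group{i}", g) for i, g in enumerate(data))
    groups = {}
    for name, values in items:
        arr = np.asarray(values, dtype=float).ravel()
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {name!r} contains non-finite values")
        groups[str(name)] = arr
    return groups


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    m = p.size
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for k, idx in enumerate(order):
            running = max(running, (m - k) * p[idx])
            adj[idx] = min(1.0, running)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def dunn_test(data, adjustment: str = "holm") -> pd.DataFrame:
    """Dunn's test for nonparametric multiple comparisons.

    All N observations are ranked jointly (midranks for ties).  For each
    pair of groups (i, j),

        z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T) (1/n_i + 1/n_j)]

    with the tie correction ``T = sum(t^3 - t) / (12 (N - 1))`` over tied
    groups of size t.  Two-sided p-values come from the standard normal.

    Parameters
    ----------
    data : mapping of name -> 1-D values, or sequence of 1-D arrays
        Each group needs at least two observations.
    adjustment : {"holm", "bonferroni", "none"}
        Multiplicity adjustment applied to the raw p-values.

    Returns
    -------
    DataFrame with columns group1, group2, z, p_raw, p_adj.
    """
    groups = _as_groups(data)
    if len(groups) < 2:
        raise ValueError("dunn_test needs at least two groups")
    names = list(groups)
    values = np.concatenate([groups[n] for n in names])
    sizes = np.array([groups[n].size for n in names])
    N = values.size
    ranks = _sps.rankdata(values)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(names))]
    )
    # tie correction over the pooled sample
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (N - 1))
    var_term = N * (N + 1) / 12.0 - tie_term

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            denom2 = var_term * (1.0 / sizes[i] + 1.0 / sizes[j])
            if denom2 <= 0:
                z = 0.0  # fully tied pooled sample carries no information
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(denom2)
            p = 2.0 * _sps.norm.sf(abs(z))
            rows.append((names[i], names[j], z, min(1.0, p)))
    table = pd.DataFrame(rows, columns=["group1", "group2", "z", "p_raw"])
    table["p_adj"] = _adjust(table["p_raw"].to_numpy(), adjustment)
    return table


def rayleigh_test(angles_deg: Sequence[float], axial: bool = True) -> RayleighResult:
    """Rayleigh's test for uniformity of circular data.

    Parameters
    ----------
    angles_deg : array-like
        Angles in degrees.  For axial data (orientations defined modulo
        180 deg, e.g. alignment angles in (-90, 90]) set ``axial=True``
        (the default here, since the package's orientation data are
        axial): angles are doubled before testing so that the axial
        circle maps onto the full circle.
    axial : bool
        Whether the data are axial.

    Returns
    -------
    RayleighResult(n, rbar, z, pvalue) where ``z = n * rbar**2`` and the
    p-value uses the standard series approximation

        p = exp(-z) [1 + (2z - z^2)/(4n) - (24z - 132z^2 + 76z^3 - 9z^4)/(288 n^2)]

    clipped to [0, 1].  Requires n >= 5 for the approximation.
    """
    theta = np.deg2rad(np.asarray(angles_deg, dtype=float).ravel())
    n = theta.size
    if n < 5:
        raise ValueError("rayleigh_test requires at least 5 angles")
    if axial:
        theta = 2.0 * theta
    C = np.cos(theta).sum()
    S = np.sin(theta).sum()
    rbar = np.hypot(C, S) / n
    z = n * rbar**2
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return RayleighResult(n=n, rbar=float(rbar), z=float(z), pvalue=float(np.clip(p, 0.0, 1.0)))


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Five-number summary with inner fences (see module docstring)."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 1:
        raise ValueError("box_summary requires at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo) & (arr <= hi)]
    outliers = np.sort(arr[(arr < lo) | (arr > hi)])
    return BoxSummary(
        n=arr.size,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lower_fence=float(lo),
        upper_fence=float(hi),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )
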