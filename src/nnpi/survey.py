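"""Design-based population inference from the probability sites.

Each probability site carries an areal weight (hectares of the sampled
wetland population it represents).  Estimators:

* ``category_extent`` — Horvitz-Thompson totals of weight by stressor-level
  category (wetland area in each category), per domain.
* ``population_mean`` — weight-ratio means of a site metric per domain.
* Variances by either the with-replacement (Hansen-Hurwitz style) estimator
  (``"srs"``) or a local-neighborhood estimator (``"local"``) that exploits
  the spatial balance of the design by contrasting each site's contribution
  with the mean over its nearest-neighbor set.
* ``signal_to_noise`` — among-site variance over within-season revisit
  variance for a metric; ratios above 2 are conventionally deemed useful.

Two-sided 95% confidence intervals use z = 1.96; extent intervals truncate
at 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .classify import StressorLevel

log = logging.getLogger(__name__)

Z95 = 1.96

CATEGORY_ORDER = [lvl.name for lvl in StressorLevel]


@dataclass
class ExtentEstimate:
    """Weighted wetland-area total for one category within one domain."""

    domain: str
    category: str
    area_ha: float
    se: float
    ci95: tuple[float, float]
    pct_of_domain: float
    n_sites: int


@dataclass
class PopMeanEstimate:
    """Population-weighted mean of a metric within one domain."""

    domain: str
    metric: str
    mean: float
    se: Optional[float]
    ci95: Optional[tuple[float, float]]
    n_sites: int


@dataclass
class SNResult:
    """Signal-to-noise decomposition for one metric."""

    metric: str
    signal_var: float
    noise_var: float
    ratio: float  # inf when noise is 0 and signal > 0
    n_sites: int
    n_pairs: int


# ---------------------------------------------------------------------------
# Variance machinery


def srs_total_variance(contributions: np.ndarray) -> float:
    """With-replacement variance of a Horvitz-Thompson total.

    ``contributions`` are the per-site terms z_i = w_i * y_i, so
    v(T) = n/(n-1) * sum((z_i - mean(z))^2).
    """
    z = np.asarray(contributions, dtype=float)
    n = len(z)
    if n < 2:
        return float("nan")
    return float(n / (n - 1) * np.sum((z - z.mean()) ** 2))


def local_mean_variance(
    contributions: np.ndarray,
    coords: np.ndarray,
    weights: np.ndarray | None = None,
    nbh_size: int = 4,
) -> float:
    """Local-neighborhood variance of a total for spatially balanced samples.

    For each site the neighborhood is its ``nbh_size`` nearest sites
    (Euclidean, self included, equal within-neighborhood weights); the
    estimator accumulates squared deviations of contributions from their
    neighborhood means, scaled by ``nbh/(nbh-1)`` so it is approximately
    unbiased for spatially unstructured data while tracking local structure
    when present.  Falls back to the with-replacement estimator (with a
    logged warning) when fewer than ``nbh_size`` sites are available.
    """
    z = np.asarray(contributions, dtype=float)
    n = len(z)
    if n < 2:
        return float("nan")
    if n < nbh_size or nbh_size < 2:
        log.warning(
            "local variance needs >= %d sites, got %d; falling back to SRS",
            nbh_size, n,
        )
        return srs_total_variance(z)
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=nbh_size)
    nbh = z[idx]  # (n, nbh_size)
    dev = nbh - nbh.mean(axis=1, keepdims=True)
    return float(np.sum(dev**2) / (nbh_size - 1))


def _total_and_se(
    z: np.ndarray, coords: np.ndarray | None, method: str, nbh_size: int = 4
) -> tuple[float, float]:
    total = float(z.sum())
    if method == "srs" or coords is None:
        var = srs_total_variance(z)
    elif method == "local":
        var = local_mean_variance(z, coords, nbh_size=nbh_size)
    else:
        raise ValueError(f"unknown variance method {method!r}")
    return total, math.sqrt(var) if var == var else float("nan")


# ---------------------------------------------------------------------------
# Extent and mean estimation


def _domains(sites: pd.DataFrame, domain_spec: str) -> list[tuple[str, pd.DataFrame]]:
    if domain_spec == "national":
        return [("national", sites)]
    if domain_spec in ("ecoregion", "wetland_type"):
        return [(str(v), g) for v, g in sites.groupby(domain_spec, observed=True)]
    raise ValueError(
        f"unknown domain spec {domain_spec!r}; "
        "expected national | ecoregion | wetland_type"
    )


def category_extent(
    sites: pd.DataFrame,
    nnpi_results: pd.DataFrame,
    domain_spec: str = "national",
    variance_method: str = "local",
    nbh_size: int = 4,
) -> list[ExtentEstimate]:
    """Wetland-area extent per stressor-level category within each domain.

    ``sites`` must be probability visit-1 rows with positive weights;
    ``nnpi_results`` must carry site_id and ``overall``.  Category areas
    within a domain sum exactly to the domain's total weight, and the
    percent column sums to 100.
    """
    merged = sites.merge(
        nnpi_results[["site_id", "overall"]], on="site_id", validate="one_to_one"
    )
    out: list[ExtentEstimate] = []
    for domain, g in _domains(merged, domain_spec):
        total_weight = g["weight"].sum()
        coords = g[["x", "y"]].to_numpy()
        for category in CATEGORY_ORDER:
            y = (g["overall"] == category).to_numpy(dtype=float)
            z = g["weight"].to_numpy() * y
            area, se = _total_and_se(z, coords, variance_method, nbh_size)
            lo = max(0.0, area - Z95 * se) if se == se else float("nan")
            hi = area + Z95 * se if se == se else float("nan")
            out.append(
                ExtentEstimate(
                    domain=domain,
                    category=category,
                    area_ha=area,
                    se=se,
                    ci95=(lo, hi),
                    pct_of_domain=area / total_weight * 100.0 if total_weight else 0.0,
                    n_sites=int(y.sum()),
                )
            )
    return out


def extent_table(estimates: Sequence[ExtentEstimate]) -> pd.DataFrame:
    """Extent estimates as a tidy DataFrame."""
    return pd.DataFrame(
        {
            "domain": [e.domain for e in estimates],
            "category": [e.category for e in estimates],
            "area_ha": [e.area_ha for e in estimates],
            "se": [e.se for e in estimates],
            "ci95_lo": [e.ci95[0] for e in estimates],
            "ci95_hi": [e.ci95[1] for e in estimates],
            "pct_of_domain": [e.pct_of_domain for e in estimates],
            "n_sites": [e.n_sites for e in estimates],
        }
    )


def population_mean(
    values: pd.Series | np.ndarray,
    sites: pd.DataFrame,
    domain_spec: str = "national",
    variance_method: str = "local",
    metric: str = "metric",
    nbh_size: int = 4,
) -> list[PopMeanEstimate]:
    """Population-weighted mean of *values* (aligned with ``sites`` rows).

    The mean is sum(w*y)/sum(w); its variance uses the ratio linearization
    e_i = w_i (y_i - mean) with the chosen total-variance estimator.  A
    single-site domain returns the value with SE flagged undefined (None).
    """
    sites = sites.reset_index(drop=True)
    y = np.asarray(values, dtype=float)
    if len(y) != len(sites):
        raise ValueError("values must align one-to-one with site rows")
    df = sites.copy()
    df["_y"] = y
    out: list[PopMeanEstimate] = []
    for domain, g in _domains(df, domain_spec):
        w = g["weight"].to_numpy(dtype=float)
        yv = g["_y"].to_numpy(dtype=float)
        mean = float(np.sum(w * yv) / np.sum(w))
        if len(g) < 2:
            out.append(PopMeanEstimate(domain, metric, mean, None, None, len(g)))
            continue
        e = w * (yv - mean)
        coords = g[["x", "y"]].to_numpy()
        _, se_total = _total_and_se(e, coords, variance_method, nbh_size)
        se = se_total / np.sum(w)
        out.append(
            PopMeanEstimate(
                domain, metric, mean, float(se),
                (mean - Z95 * se, mean + Z95 * se), len(g),
            )
        )
    return out


def popmean_table(estimates: Sequence[PopMeanEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "domain": [e.domain for e in estimates],
            "metric": [e.metric for e in estimates],
            "mean": [e.mean for e in estimates],
            "se": [e.se for e in estimates],
            "ci95_lo": [e.ci95[0] if e.ci95 else float("nan") for e in estimates],
            "ci95_hi": [e.ci95[1] if e.ci95 else float("nan") for e in estimates],
            "n_sites": [e.n_sites for e in estimates],
        }
    )


def ci_nonoverlap(
    a: tuple[float, float], b: tuple[float, float]
) -> bool:
    """Convenience comparison: True when two 95% CIs do not overlap.

    Mirrors the practice of recognizing differences by nonoverlapping CIs;
    no multiplicity adjustment is applied.
    """
    return a[1] < b[0] or b[1] < a[0]


# ---------------------------------------------------------------------------
# Signal-to-noise


def signal_to_noise(values: pd.DataFrame, metric: str = "metric") -> SNResult:
    """Repeatability of a metric from revisit pairs.

    ``values`` needs columns site_id, visit_no, value.  Signal variance is
    the sample variance of visit-1 values across sites; noise variance is
    the mean over revisit pairs of (visit1 - visit2)^2 / 2 (the one-way
    within-site variance component for paired revisits).  Zero noise with
    positive signal yields an infinite ratio; zero signal and zero noise is
    undefined and raises.
    """
    v1 = values[values["visit_no"] == 1].set_index("site_id")["value"]
    v2 = values[values["visit_no"] == 2].set_index("site_id")["value"]
    if len(v1) < 2:
        raise ValueError("signal variance needs >= 2 sites")
    pairs = v1.index.intersection(v2.index)
    if len(pairs) < 2:
        raise ValueError("noise variance needs >= 2 revisit pairs")
    signal = float(np.var(v1.to_numpy(), ddof=1))
    d = v1.loc[pairs].to_numpy() - v2.loc[pairs].to_numpy()
    noise = float(np.mean(d**2) / 2.0)
    if noise == 0.0:
        if signal == 0.0:
            raise ValueError("S:N undefined: zero signal and zero noise")
        ratio = float("inf")
    else:
        ratio = signal / noise
    return SNResult(
        metric=metric,
        signal_var=signal,
        noise_var=noise,
        ratio=ratio,
        n_sites=len(v1),
        n_pairs=len(pairs),
    )
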