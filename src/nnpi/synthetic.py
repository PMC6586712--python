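"""Synthetic wetland-survey data generator.

Emulates the structure of a national wetland vegetation survey: five 100-m2
vegetation plots per site, a species pool with a nonnative fraction spanning
forb/graminoid/vine/shrub/tree growth habits, percent covers in (0, 100],
OBL-UPL wetland indicator statuses, unequal areal survey weights from a
spatially balanced probability design, within-season revisit pairs, and
eight site-level disturbance sub-indices positively associated with
nonnative abundance when ``disturbance_effect > 0``.

The defaults reflect the published national survey conditions: a 12%
nonnative species pool, ~10% revisit rate, mixing proportions of ecoregions
and aggregated wetland types matching the probability-site roster, and a
right-skewed weight distribution averaging ~26,000 ha per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .core_data import Dataset, ECOREGIONS, WETLAND_TYPES, wis_numeric


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


# Probability-site shares by ecoregion (CPL, EMU, IPL, XER, WMT) and
# aggregated wetland type (EH, EW, PRLH, PRLW) in the 2011 national survey.
_ECO_PROBS = (0.531, 0.157, 0.161, 0.061, 0.090)
_WT_PROBS = (0.267, 0.071, 0.312, 0.350)

# Growth-habit mix of the observed nonnative flora: 54% forb, 20% graminoid,
# 10% vine, 7% shrub, 9% tree.  Natives use a similar mix with more woodiness.
_HABITS = ("FORB", "GRAMINOID", "VINE", "SHRUB", "TREE")
_NONNATIVE_HABIT_PROBS = (0.54, 0.20, 0.10, 0.07, 0.09)
_NATIVE_HABIT_PROBS = (0.40, 0.22, 0.08, 0.13, 0.17)

# Target wetland index by wetland type: estuarine herbaceous wettest (~1.4),
# inland woody driest (~2.3-2.6); drives site-level taxon selection bias.
_TARGET_WI = {"EH": 1.4, "EW": 1.7, "PRLH": 1.8, "PRLW": 2.4}
_WI_ECO_SHIFT = {"CPL": 0.0, "EMU": -0.1, "IPL": 0.0, "XER": 0.5, "WMT": 0.3}


def _default_eco_mult() -> dict[str, float]:
    # western ecoregions carry higher nonnative prevalence
    return {"CPL": 0.7, "EMU": 0.7, "IPL": 1.8, "XER": 3.0, "WMT": 1.3}


def _default_wt_mult() -> dict[str, float]:
    # herbaceous types more invaded than woody, inland more than estuarine
    return {"EH": 1.3, "EW": 0.3, "PRLH": 1.8, "PRLW": 0.7}


@dataclass
class SimConfig:
    """Knobs for :func:`generate_dataset`; seed fixes output bit-for-bit."""

    n_sites: int = 200
    n_plots: int = 5
    seed: int = 0
    species_pool_size: int = 400
    nonnative_fraction: float = 0.12
    eco_multiplier: dict[str, float] = field(default_factory=_default_eco_mult)
    wt_multiplier: dict[str, float] = field(default_factory=_default_wt_mult)
    cover_lognormal_mu: float = 1.3
    cover_lognormal_sigma: float = 1.2
    richness_mean: float = 28.0
    undetermined_fraction: float = 0.03
    revisit_fraction: float = 0.10
    revisit_noise_sd: float = 0.20
    revisit_turnover: float = 0.05
    disturbance_effect: float = 1.5
    weight_gamma_shape: float = 1.2
    weight_gamma_mean: float = 26000.0

    def validate(self) -> None:
        for name in ("nonnative_fraction", "undetermined_fraction", "revisit_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]; got {v}")
        if self.n_sites < 1 or self.n_plots < 1 or self.species_pool_size < 2:
            raise ConfigError("n_sites, n_plots, species_pool_size must be positive")
        if self.revisit_noise_sd < 0:
            raise ConfigError("revisit_noise_sd must be >= 0")
        if self.nonnative_fraction == 0.0 and self.disturbance_effect != 0.0:
            raise ConfigError(
                "disturbance_effect requires a nonzero nonnative_fraction "
                "(no nonnatives to respond to disturbance)"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def _species_pool(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.species_pool_size
    n_nn = int(round(cfg.nonnative_fraction * n))
    n_und = int(round(cfg.undetermined_fraction * n))
    n_nat = n - n_nn - n_und
    status = np.array(
        ["NATIVE"] * n_nat
        + list(rng.choice(["INTRODUCED", "ADVENTIVE", "CRYPTOGENIC"],
                          size=n_nn, p=[0.75, 0.10, 0.15]))
        + ["UNDETERMINED"] * n_und
    )
    habit = np.empty(n, dtype=object)
    nn_mask = np.isin(status, ["INTRODUCED", "ADVENTIVE", "CRYPTOGENIC"])
    habit[nn_mask] = rng.choice(_HABITS, size=nn_mask.sum(), p=_NONNATIVE_HABIT_PROBS)
    habit[~nn_mask] = rng.choice(_HABITS, size=(~nn_mask).sum(), p=_NATIVE_HABIT_PROBS)
    # wetland indicator status: nonnatives skew to the dry end (>75% FAC or
    # drier in the observed flora), natives flatter
    wis_levels = np.array(["OBL", "FACW", "FAC", "FACU", "UPL"])
    wis = np.empty(n, dtype=object)
    wis[nn_mask] = rng.choice(wis_levels, size=nn_mask.sum(),
                              p=[0.10, 0.14, 0.20, 0.27, 0.29])
    wis[~nn_mask] = rng.choice(wis_levels, size=(~nn_mask).sum(),
                               p=[0.28, 0.24, 0.20, 0.16, 0.12])
    # a small share of taxa has no assigned indicator status
    missing = rng.random(n) < 0.05
    wis = pd.Series(wis, dtype=object)
    wis[missing] = np.nan
    # abundance propensity: a few common species, many rare (lognormal)
    propensity = rng.lognormal(0.0, 1.0, size=n)
    return pd.DataFrame(
        {
            "taxon_id": [f"TX{i:04d}" for i in range(n)],
            "native_status": status,
            "growth_habit": habit,
            "wis": wis,
            "_propensity": propensity,
        }
    )


def generate_dataset(cfg: SimConfig) -> Dataset:
    """Draw a complete synthetic survey :class:`~nnpi.core_data.Dataset`.

    Strata with larger prevalence multipliers receive stochastically more
    nonnative cover; the eight disturbance sub-indices share a latent
    site-disturbance score that also scales nonnative selection odds by
    ``exp(disturbance_effect * (d - 0.5))``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    pool = _species_pool(cfg, rng)
    pool_wis_value = wis_numeric(pool["wis"])
    nn_mask = pool["native_status"].isin(["INTRODUCED", "ADVENTIVE", "CRYPTOGENIC"]).to_numpy()

    n = cfg.n_sites
    eco = rng.choice(ECOREGIONS, size=n, p=_ECO_PROBS)
    wt = rng.choice(WETLAND_TYPES, size=n, p=_WT_PROBS)
    xy = rng.random((n, 2))
    weight = rng.gamma(cfg.weight_gamma_shape,
                       cfg.weight_gamma_mean / cfg.weight_gamma_shape, size=n)
    bareground = np.round(rng.beta(1.2, 8.0, size=n) * 100, 1)
    disturb_latent = rng.random(n)

    site_ids = [f"S{i:04d}" for i in range(n)]
    sites = pd.DataFrame(
        {
            "site_id": site_ids,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "weight": weight,
            "ecoregion": eco,
            "wetland_type": wt,
            "is_probability": True,
            "visit_no": 1,
            "bareground": bareground,
        }
    )

    # eight raw sub-indices sharing the latent disturbance, on different
    # raw scales so min-max standardization has real work to do
    idx_scale = rng.uniform(0.5, 50.0, size=8)
    dist_cols = {}
    for k in range(8):
        noise = rng.normal(0.0, 0.25, size=n)
        dist_cols[f"idx{k + 1}"] = np.clip(disturb_latent + noise, 0.0, None) * idx_scale[k]
    disturbance = pd.DataFrame({"site_id": site_ids, **dist_cols})

    cover_rows: list[pd.DataFrame] = []
    prop = pool["_propensity"].to_numpy()
    wis_val = pool_wis_value.to_numpy()

    for i in range(n):
        richness = max(1, rng.poisson(cfg.richness_mean))
        richness = min(richness, cfg.species_pool_size)
        target_wi = _TARGET_WI[wt[i]] + _WI_ECO_SHIFT[eco[i]]
        sel = prop.copy()
        # hydrologic affinity: prefer taxa whose indicator status matches
        # the stratum's target wetness (missing wis -> neutral)
        affinity = np.exp(-0.5 * np.abs(np.nan_to_num(wis_val, nan=target_wi) - target_wi))
        sel = sel * affinity
        mult = (
            cfg.eco_multiplier[eco[i]]
            * cfg.wt_multiplier[wt[i]]
            * np.exp(cfg.disturbance_effect * (disturb_latent[i] - 0.5))
        )
        sel[nn_mask] *= mult
        sel = sel / sel.sum()
        chosen = rng.choice(cfg.species_pool_size, size=richness, replace=False, p=sel)

        mean_cover = np.minimum(
            rng.lognormal(cfg.cover_lognormal_mu, cfg.cover_lognormal_sigma, size=richness),
            100.0,
        )
        occ_prob = rng.uniform(0.3, 1.0, size=richness)
        present = rng.random((richness, cfg.n_plots)) < occ_prob[:, None]
        empty = ~present.any(axis=1)
        if empty.any():  # every selected species occurs in >= 1 plot
            forced = rng.integers(0, cfg.n_plots, size=int(empty.sum()))
            present[np.nonzero(empty)[0], forced] = True
        plot_noise = np.exp(rng.normal(0.0, 0.4, size=(richness, cfg.n_plots)))
        plot_cover = np.clip(mean_cover[:, None] * plot_noise, 0.01, 100.0)

        sp_idx, plot_idx = np.nonzero(present)
        cover_rows.append(
            pd.DataFrame(
                {
                    "site_id": site_ids[i],
                    "plot_id": plot_idx + 1,
                    "taxon_id": pool["taxon_id"].to_numpy()[chosen[sp_idx]],
                    "cover": np.round(plot_cover[sp_idx, plot_idx], 3),
                    "visit_no": 1,
                }
            )
        )

    cover = pd.concat(cover_rows, ignore_index=True)

    # revisit pairs: same sites with (a) per-observation multiplicative
    # lognormal cover noise (exact SD = revisit_noise_sd on the log scale)
    # and (b) small detection turnover — each observation may be missed and
    # each species may be picked up in a plot it was not recorded in — so
    # frequency- and richness-based metrics also carry revisit noise
    n_revisit = int(round(cfg.revisit_fraction * n))
    if n_revisit:
        revisit_ids = list(rng.choice(site_ids, size=n_revisit, replace=False))
        v2_sites = sites[sites["site_id"].isin(revisit_ids)].copy()
        v2_sites["visit_no"] = 2
        sites = pd.concat([sites, v2_sites], ignore_index=True)
        v2 = cover[cover["site_id"].isin(revisit_ids)].copy()
        noise = np.exp(rng.normal(0.0, cfg.revisit_noise_sd, size=len(v2)))
        v2["cover"] = np.minimum(v2["cover"] * noise, 100.0).round(3)
        kept = rng.random(len(v2)) >= cfg.revisit_turnover
        additions = []
        if cfg.revisit_turnover > 0:
            mean_cov = v2.groupby(["site_id", "taxon_id"])["cover"].mean()
            seen = v2.groupby(["site_id", "taxon_id"])["plot_id"].agg(set)
            for (sid, tax), plots in seen.items():
                for p in range(1, cfg.n_plots + 1):
                    if p not in plots and rng.random() < cfg.revisit_turnover:
                        c = mean_cov[(sid, tax)] * float(
                            np.exp(rng.normal(0.0, cfg.revisit_noise_sd))
                        )
                        additions.append(
                            {"site_id": sid, "plot_id": p, "taxon_id": tax,
                             "cover": round(min(c, 100.0), 3), "visit_no": 2}
                        )
        v2 = v2[kept]
        v2["visit_no"] = 2
        parts = [cover, v2]
        if additions:
            parts.append(pd.DataFrame(additions))
        cover = pd.concat(parts, ignore_index=True)

    traits = pool.drop(columns="_propensity").copy()
    traits["wis_value"] = pool_wis_value
    return Dataset(
        cover=cover,
        traits=traits,
        sites=sites,
        disturbance=disturbance,
        n_plots=cfg.n_plots,
    )
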