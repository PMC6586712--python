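"""End-to-end orchestration: simulate -> metrics -> classification ->
extent / population means / signal-to-noise -> disturbance -> forest.

:class:`RunConfig` round-trips through YAML and carries one seed that
propagates to every stochastic stage; :func:`run_all` writes all stage
outputs plus a JSON manifest (package version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_data import Dataset, write_dataset, validate_dataset
from .synthetic import SimConfig, generate_dataset
from .metrics import site_metrics, species_occurrence_table
from .classify import ThresholdMatrix, classify_table
from .survey import (
    category_extent,
    extent_table,
    population_mean,
    popmean_table,
    signal_to_noise,
)
from .disturbance import score_disturbance
from .forest import BalancedRandomForest, ForestConfig

log = logging.getLogger(__name__)

#: Site-metric columns offered to the forest alongside disturbance,
#: bareground, ecoregion, and wetland type.
DEFAULT_RF_METRIC_PREDICTORS = [
    "native_richness",
    "wetland_index",
    "native_cover_forb",
    "native_cover_graminoid",
    "native_cover_vine",
    "native_cover_shrub",
    "native_cover_tree",
]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: str = "nnpi_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=lambda: SimConfig(n_sites=200))
    thresholds: ThresholdMatrix = field(default_factory=ThresholdMatrix)
    variance_method: str = "local"
    nbh_size: int = 4
    n_trees: int = 1000
    sn_metrics: tuple[str, ...] = ("nn_richness", "nn_rel_freq", "nn_rel_cover")

    def __post_init__(self) -> None:
        # one master seed drives both simulation and forest
        self.sim.seed = self.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = {m: list(getattr(self.thresholds, m))
                           for m in ("rel_cover", "richness", "rel_freq")}
        d["sn_metrics"] = list(self.sn_metrics)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig(**d["sim"])
        if "thresholds" in d:
            d["thresholds"] = ThresholdMatrix(
                **{k: tuple(v) for k, v in d["thresholds"].items()}
            )
        if "sn_metrics" in d:
            d["sn_metrics"] = tuple(d["sn_metrics"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def build_rf_inputs(
    metrics_df: pd.DataFrame,
    nnpi_df: pd.DataFrame,
    scored_disturbance: pd.DataFrame,
    sites: pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the predictor table and combined labels for the forest.

    Uses all visit-1 sites (probability and otherwise; survey weights play
    no role here).  Predictors: the native-vegetation metrics and wetland
    index, bareground, the overall disturbance index, ecoregion, and
    wetland type.
    """
    v1 = sites[sites["visit_no"] == 1][
        ["site_id", "ecoregion", "wetland_type", "bareground"]
    ]
    m1 = metrics_df[metrics_df["visit_no"] == 1]
    df = (
        v1.merge(m1, on="site_id", validate="one_to_one")
        .merge(nnpi_df[["site_id", "combined"]].drop_duplicates("site_id"), on="site_id")
        .merge(scored_disturbance[["site_id", "overall"]].rename(
            columns={"overall": "disturbance_index"}), on="site_id", how="left")
    )
    predictors = [c for c in DEFAULT_RF_METRIC_PREDICTORS if c in df.columns]
    predictors += ["bareground", "disturbance_index", "ecoregion", "wetland_type"]
    X = df[predictors].copy()
    # wetland index is undefined for sites with no scored taxa; the forest
    # requires complete predictors, so fill with the overall median
    if "wetland_index" in X.columns and X["wetland_index"].isna().any():
        X["wetland_index"] = X["wetland_index"].fillna(X["wetland_index"].median())
    X = X.dropna(axis=1, how="all")
    y = df["combined"].to_numpy()
    return X, y


def run_all(config: RunConfig, dataset: Optional[Dataset] = None) -> dict:
    """Run every stage, write outputs under ``config.out_dir``, and return
    the manifest.  With no *dataset*, synthetic data are generated from
    ``config.sim``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": [],
    }
    t0 = time.perf_counter()

    # timings go to the log, not the manifest, which must be bit-identical
    # across runs at a fixed seed
    def stage(name):
        log.info("stage %s ... (t=%.1fs)", name, time.perf_counter() - t0)
        manifest["stages"].append(name)

    stage("simulate")
    ds = dataset if dataset is not None else generate_dataset(config.sim)
    write_dataset(ds, out / "data")
    issues = validate_dataset(ds)
    if issues:
        raise RuntimeError(f"dataset failed validation: {issues[:3]}")

    stage("metrics")
    mdf = site_metrics(ds)
    mdf.round(6).to_csv(out / "site_metrics.csv", index=False)

    stage("species_table")
    species_occurrence_table(ds).round(2).to_csv(out / "species_table.csv", index=False)

    stage("nnpi")
    ndf = classify_table(mdf, config.thresholds)
    ndf.round(6).to_csv(out / "nnpi.csv", index=False)

    stage("extent")
    prob = ds.probability_sites()
    n1 = ndf[ndf["visit_no"] == 1]
    ext = []
    for dom in ("national", "ecoregion", "wetland_type"):
        ext.extend(category_extent(prob, n1, dom, config.variance_method, config.nbh_size))
    extent_table(ext).round(4).to_csv(out / "extent.csv", index=False)

    stage("popmean")
    m_prob = prob.merge(
        mdf[mdf["visit_no"] == 1], on="site_id", validate="one_to_one"
    )
    means = []
    for metric in ("nn_richness", "nn_rel_freq", "nn_rel_cover"):
        for dom in ("national", "ecoregion", "wetland_type"):
            means.extend(
                population_mean(
                    m_prob[metric], m_prob, dom, config.variance_method,
                    metric=metric, nbh_size=config.nbh_size,
                )
            )
    popmean_table(means).round(6).to_csv(out / "popmean.csv", index=False)

    stage("sn")
    sn_rows = []
    for metric in config.sn_metrics:
        vals = mdf.rename(columns={metric: "value"})[["site_id", "visit_no", "value"]]
        try:
            r = signal_to_noise(vals, metric)
            sn_rows.append(
                {"metric": metric, "signal_var": r.signal_var,
                 "noise_var": r.noise_var, "ratio": r.ratio,
                 "n_sites": r.n_sites, "n_pairs": r.n_pairs}
            )
        except ValueError as exc:
            log.warning("S:N for %s unavailable: %s", metric, exc)
    pd.DataFrame(sn_rows).round(6).to_csv(out / "sn.csv", index=False)

    stage("disturbance")
    scored = score_disturbance(ds.disturbance)
    scored.round(6).to_csv(out / "disturbance_scored.csv", index=False)

    stage("rf")
    X, y = build_rf_inputs(mdf, ndf, scored, ds.sites)
    forest = BalancedRandomForest(
        ForestConfig(n_trees=config.n_trees, seed=config.seed)
    )
    forest.fit(X, y)
    rep = forest.report()
    rf_report = {
        "pcc_all": rep.pcc_all,
        "pcc_lm": rep.pcc_lm,
        "pcc_hvh": rep.pcc_hvh,
        "mtry": rep.mtry,
        "n_trees": rep.n_trees,
        "per_class_bootstrap": rep.per_class_bootstrap,
        "encoding": rep.encoding,
        "importance": rep.importance,
    }
    with open(out / "rf_report.json", "w") as fh:
        json.dump(rf_report, fh, indent=2, sort_keys=True)
    imp = pd.DataFrame(
        sorted(rep.importance.items(), key=lambda kv: -kv[1]),
        columns=["predictor", "mean_decrease_accuracy"],
    )
    imp.round(6).to_csv(out / "rf_importance.csv", index=False)

    cfg_dict = config.to_dict()
    # hash the analytic configuration only, not where outputs land
    hashed = {k: v for k, v in cfg_dict.items() if k != "out_dir"}
    manifest["config"] = cfg_dict
    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(hashed, sort_keys=True).encode()
    ).hexdigest()
    manifest["rf"] = {k: rf_report[k] for k in ("pcc_all", "pcc_lm", "pcc_hvh")}
    manifest["n_sites"] = int(ds.sites["site_id"].nunique())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete in %.1fs", time.perf_counter() - t0)
    return manifest
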