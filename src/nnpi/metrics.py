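"""Per-site vegetation metrics.

Site-level species summaries aggregate the five-plot cover observations:
a species' site cover is its mean absolute cover over all configured plots
(plots where it is absent contribute 0), and its frequency is the percent
of plots in which it occurred.  From these the three nonnative-plant
indicator (NNPI) component metrics are computed:

* nonnative richness — number of unique nonnative species,
* nonnative relative frequency — sum of nonnative frequencies over the sum
  of all-taxa frequencies, x100,
* nonnative relative cover — same ratio on site covers.

Also here: native richness, the cover-weighted wetland index (WI, 1 =
entirely obligate wetland vegetation, 5 = entirely upland), absolute cover
by growth-habit group, per-species importance values, and the ordered
occurrence table of nonnative taxa.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import Dataset, ECOREGIONS, is_nonnative

HABIT_GROUPS = ("FORB", "GRAMINOID", "VINE", "SHRUB", "TREE")


def summarize_species_by_site(cover: pd.DataFrame, n_plots: int) -> pd.DataFrame:
    """Per-taxon site summary for one site-visit's cover rows.

    Returns columns ``taxon_id, freq_pct, site_cover, importance``; empty
    frame for a site with no cover rows.  The frequency and cover
    denominators are the configured plot count, so absences are true zeros.
    """
    if n_plots <= 0:
        raise ValueError(f"n_plots must be positive; got {n_plots}")
    if len(cover) and (cover["plot_id"] > n_plots).any():
        raise ValueError("cover rows reference plot ids above n_plots")
    if not len(cover):
        return pd.DataFrame(columns=["taxon_id", "freq_pct", "site_cover", "importance"])
    g = cover.groupby("taxon_id")["cover"].agg(["count", "sum"]).reset_index()
    out = pd.DataFrame(
        {
            "taxon_id": g["taxon_id"],
            "freq_pct": g["count"] / n_plots * 100.0,
            "site_cover": g["sum"] / n_plots,
        }
    )
    out["importance"] = (out["freq_pct"] + out["site_cover"]) / 2.0
    return out


def importance_value(freq_pct: float, site_cover: float) -> float:
    """Species importance at a site: (% frequency + % cover) / 2."""
    for name, v in (("freq_pct", freq_pct), ("site_cover", site_cover)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be in [0, 100]; got {v}")
    return (freq_pct + site_cover) / 2.0


def nonnative_metrics(
    summaries: pd.DataFrame, traits: pd.DataFrame
) -> tuple[int, float, float]:
    """The three NNPI component metrics for one site.

    Returns ``(nn_richness, nn_rel_freq, nn_rel_cover)``.  Denominators sum
    over *all* taxa (natives and undetermined included, so undetermined
    taxa dilute but never inflate the nonnative share); a vegetation-free
    site reports (0, 0.0, 0.0).
    """
    if not len(summaries):
        return 0, 0.0, 0.0
    merged = summaries.merge(traits[["taxon_id", "native_status"]], on="taxon_id",
                             how="left", validate="many_to_one")
    if merged["native_status"].isna().any():
        missing = merged.loc[merged["native_status"].isna(), "taxon_id"].tolist()
        raise KeyError(f"taxa without trait rows: {missing[:5]}")
    nn = merged["native_status"].isin(["INTRODUCED", "ADVENTIVE", "CRYPTOGENIC"])
    richness = int(nn.sum())
    tot_freq = merged["freq_pct"].sum()
    tot_cover = merged["site_cover"].sum()
    rel_freq = float(merged.loc[nn, "freq_pct"].sum() / tot_freq * 100.0) if tot_freq else 0.0
    rel_cover = float(merged.loc[nn, "site_cover"].sum() / tot_cover * 100.0) if tot_cover else 0.0
    return richness, rel_freq, rel_cover


def wetland_index(summaries: pd.DataFrame, traits: pd.DataFrame) -> float:
    """Cover-weighted mean wetland indicator value over taxa with a defined
    status; NaN when no such taxon occurs."""
    if not len(summaries):
        return float("nan")
    merged = summaries.merge(traits[["taxon_id", "wis_value"]], on="taxon_id",
                             how="left", validate="many_to_one")
    merged = merged.dropna(subset=["wis_value"])
    total = merged["site_cover"].sum()
    if total == 0:
        return float("nan")
    return float((merged["wis_value"] * merged["site_cover"]).sum() / total)


def growth_habit_cover(
    summaries: pd.DataFrame,
    traits: pd.DataFrame,
    status_filter: str = "NONNATIVE",
    combine_tree_shrub: bool = False,
) -> dict[str, float]:
    """Summed absolute site cover by growth-habit group.

    ``status_filter`` is ``"NONNATIVE"``, ``"NATIVE"``, or ``"ALL"``.  With
    ``combine_tree_shrub`` trees and shrubs merge into ``TREE_SHRUB`` (the
    convention for nonnatives, whose woody taxa often span both habits).
    Groups with no member taxa report 0.
    """
    groups = (
        ["FORB", "GRAMINOID", "VINE", "TREE_SHRUB"]
        if combine_tree_shrub
        else list(HABIT_GROUPS)
    )
    out = {g: 0.0 for g in groups}
    if not len(summaries):
        return out
    merged = summaries.merge(
        traits[["taxon_id", "native_status", "growth_habit"]],
        on="taxon_id", how="left", validate="many_to_one",
    )
    nn = merged["native_status"].isin(["INTRODUCED", "ADVENTIVE", "CRYPTOGENIC"])
    if status_filter == "NONNATIVE":
        merged = merged[nn]
    elif status_filter == "NATIVE":
        merged = merged[merged["native_status"] == "NATIVE"]
    elif status_filter != "ALL":
        raise ValueError(f"unknown status_filter {status_filter!r}")
    habit = merged["growth_habit"].copy()
    if combine_tree_shrub:
        habit = habit.replace({"TREE": "TREE_SHRUB", "SHRUB": "TREE_SHRUB"})
    sums = merged.groupby(habit)["site_cover"].sum()
    for g, v in sums.items():
        out[str(g)] = float(v)
    return out


def site_metrics(ds: Dataset) -> pd.DataFrame:
    """All per-site-visit metrics as one DataFrame.

    Columns: site_id, visit_no, the three NNPI metrics, native_richness,
    total_richness, wetland_index, and absolute nonnative / native cover by
    growth-habit group (nonnatives with trees+shrubs combined).
    """
    rows = []
    grouped = dict(tuple(ds.cover.groupby(["site_id", "visit_no"])))
    for _, sv in ds.site_visits().iterrows():
        key = (sv["site_id"], sv["visit_no"])
        cov = grouped.get(key, ds.cover.iloc[0:0])
        summ = summarize_species_by_site(cov, ds.n_plots)
        richness, rel_freq, rel_cover = nonnative_metrics(summ, ds.traits)
        wi = wetland_index(summ, ds.traits)
        nn_habit = growth_habit_cover(summ, ds.traits, "NONNATIVE", combine_tree_shrub=True)
        nat_habit = growth_habit_cover(summ, ds.traits, "NATIVE", combine_tree_shrub=False)
        native_rich = 0
        if len(summ):
            merged = summ.merge(ds.traits[["taxon_id", "native_status"]], on="taxon_id")
            native_rich = int((merged["native_status"] == "NATIVE").sum())
        rows.append(
            {
                "site_id": sv["site_id"],
                "visit_no": sv["visit_no"],
                "nn_richness": richness,
                "nn_rel_freq": rel_freq,
                "nn_rel_cover": rel_cover,
                "native_richness": native_rich,
                "total_richness": int(len(summ)),
                "wetland_index": wi,
                **{f"nn_cover_{k.lower()}": v for k, v in nn_habit.items()},
                **{f"native_cover_{k.lower()}": v for k, v in nat_habit.items()},
            }
        )
    return pd.DataFrame(rows)


def species_occurrence_table(ds: Dataset) -> pd.DataFrame:
    """Ordered occurrence table of nonnative taxa across visit-1 sites.

    One row per nonnative taxon occurring at >= 1 site, ordered by
    growth-habit group then descending number of site occurrences, with the
    mean importance value at sites of occurrence and per-ecoregion site
    counts (which sum to n_sites).
    """
    cover = ds.cover[ds.cover["visit_no"] == 1]
    nn_taxa = ds.traits.loc[is_nonnative(ds.traits), "taxon_id"]
    cover = cover[cover["taxon_id"].isin(set(nn_taxa))]
    rows = []
    eco_by_site = ds.sites[ds.sites["visit_no"] == 1].set_index("site_id")["ecoregion"]
    habit_by_taxon = ds.traits.set_index("taxon_id")["growth_habit"]
    # a taxon's frequency and site cover depend only on its own plot rows,
    # so summarizing the nonnative rows alone is exact
    for (site_id,), cov in cover.groupby(["site_id"]):
        summ = summarize_species_by_site(cov, ds.n_plots)
        for _, r in summ.iterrows():
            rows.append(
                {
                    "taxon_id": r["taxon_id"],
                    "site_id": site_id,
                    "importance": r["importance"],
                    "ecoregion": eco_by_site.get(site_id),
                }
            )
    if not rows:
        cols = (
            ["taxon_id", "habit_group", "n_sites", "mean_importance"]
            + [f"n_sites_{e}" for e in ECOREGIONS]
        )
        return pd.DataFrame(columns=cols)
    occ = pd.DataFrame(rows)
    table = (
        occ.groupby("taxon_id")
        .agg(n_sites=("site_id", "nunique"), mean_importance=("importance", "mean"))
        .reset_index()
    )
    table["habit_group"] = table["taxon_id"].map(habit_by_taxon)
    eco_counts = (
        occ.pivot_table(index="taxon_id", columns="ecoregion", values="site_id",
                        aggfunc="nunique", fill_value=0)
        .reindex(columns=list(ECOREGIONS), fill_value=0)
    )
    for e in ECOREGIONS:
        table[f"n_sites_{e}"] = table["taxon_id"].map(eco_counts[e]).fillna(0).astype(int)
    table = table.sort_values(
        ["habit_group", "n_sites", "taxon_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    cols = ["taxon_id", "habit_group", "n_sites", "mean_importance"] + [
        f"n_sites_{e}" for e in ECOREGIONS
    ]
    return table[cols]
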