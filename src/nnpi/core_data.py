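"""Domain types, CSV I/O, and validation for wetland vegetation survey data.

The in-memory container is a :class:`Dataset` of four pandas DataFrames:

``cover``
    One row per (site, visit, plot, taxon) observation with percent absolute
    cover in ``(0, 100]``.  ``visit_no`` is optional on disk (default 1).
``traits``
    One row per taxon: native status, growth habit, and wetland indicator
    status (OBL..UPL, numeric 1..5, possibly missing).
``sites``
    One row per site-visit: planar coordinates, areal survey weight
    (hectares), ecoregion, aggregated wetland type, probability-design flag,
    visit number, and percent bareground.
``disturbance``
    Optional; one row per site with eight raw disturbance sub-indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Controlled vocabularies

NATIVE_STATUSES = frozenset(
    {"NATIVE", "INTRODUCED", "ADVENTIVE", "CRYPTOGENIC", "UNDETERMINED"}
)
#: Alien (introduced + adventive) plus cryptogenic taxa count as nonnative.
NONNATIVE_STATUSES = frozenset({"INTRODUCED", "ADVENTIVE", "CRYPTOGENIC"})

GROWTH_HABITS = frozenset({"FORB", "GRAMINOID", "VINE", "SHRUB", "TREE"})

#: Wetland indicator status -> numeric value (1 = obligate wetland,
#: 5 = upland).
WIS_VALUES = {"OBL": 1, "FACW": 2, "FAC": 3, "FACU": 4, "UPL": 5}

ECOREGIONS = ("CPL", "EMU", "IPL", "XER", "WMT")
WETLAND_TYPES = ("EH", "EW", "PRLH", "PRLW")

COVER_COLUMNS = ["site_id", "plot_id", "taxon_id", "cover"]
TRAIT_COLUMNS = ["taxon_id", "native_status", "growth_habit", "wis"]
SITE_COLUMNS = [
    "site_id",
    "x",
    "y",
    "weight",
    "ecoregion",
    "wetland_type",
    "is_probability",
    "visit_no",
    "bareground",
]
DISTURBANCE_COLUMNS = ["site_id"] + [f"idx{i}" for i in range(1, 9)]


class SchemaError(ValueError):
    """A CSV is missing required columns or has the wrong layout."""


class DataValueError(ValueError):
    """A field value violates its domain (e.g. cover outside (0, 100])."""


class ReferentialError(KeyError):
    """A row references a site or taxon id with no matching master row."""


@dataclass
class Issue:
    """One validation finding, carrying the offending identifiers."""

    code: str
    message: str
    site_id: Optional[str] = None
    taxon_id: Optional[str] = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ids = ", ".join(
            f"{k}={v}"
            for k, v in (("site", self.site_id), ("taxon", self.taxon_id))
            if v is not None
        )
        return f"[{self.code}] {self.message}" + (f" ({ids})" if ids else "")


@dataclass
class Dataset:
    """Validated survey dataset; see module docstring for table layouts."""

    cover: pd.DataFrame
    traits: pd.DataFrame
    sites: pd.DataFrame
    disturbance: Optional[pd.DataFrame] = None
    n_plots: int = 5

    def site_visits(self) -> pd.DataFrame:
        """Distinct (site_id, visit_no) pairs present in the site table."""
        return self.sites[["site_id", "visit_no"]].drop_duplicates()

    def probability_sites(self) -> pd.DataFrame:
        """Visit-1 probability-design site rows (drive all population-scale
        estimation)."""
        s = self.sites
        return s[(s["is_probability"]) & (s["visit_no"] == 1)].copy()


# ---------------------------------------------------------------------------
# Readers / writers


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, dtype={"site_id": str, "taxon_id": str})


def load_dataset(
    cover_path: str | Path,
    traits_path: str | Path,
    sites_path: str | Path,
    disturbance_path: str | Path | None = None,
    n_plots: int = 5,
) -> Dataset:
    """Read the survey CSVs and return a checked :class:`Dataset`.

    Raises :class:`SchemaError` for missing columns, :class:`DataValueError`
    for out-of-domain values (cover outside ``(0, 100]``, bad enums), and
    :class:`ReferentialError` for cover rows whose taxon or site id has no
    master row.
    """
    cover = _read_csv(cover_path)
    traits = _read_csv(traits_path)
    sites = _read_csv(sites_path)
    disturbance = _read_csv(disturbance_path) if disturbance_path else None

    _require_columns(cover, COVER_COLUMNS, "cover")
    _require_columns(traits, TRAIT_COLUMNS, "traits")
    _require_columns(sites, SITE_COLUMNS, "sites")
    if disturbance is not None:
        _require_columns(disturbance, DISTURBANCE_COLUMNS, "disturbance")

    if "visit_no" not in cover.columns:
        cover = cover.assign(visit_no=1)
    cover["visit_no"] = cover["visit_no"].astype(int)
    cover["plot_id"] = cover["plot_id"].astype(int)
    cover["cover"] = cover["cover"].astype(float)
    sites["visit_no"] = sites["visit_no"].astype(int)
    flag = sites["is_probability"]
    if flag.dtype == object:  # CSV round-trip writes True/False strings
        flag = flag.astype(str).str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        if flag.isna().any():
            raise DataValueError("is_probability must be boolean")
    sites["is_probability"] = flag.astype(bool)

    bad = cover[(cover["cover"] <= 0) | (cover["cover"] > 100)]
    if len(bad):
        row = bad.iloc[0]
        raise DataValueError(
            f"cover must be in (0, 100]; got {row['cover']!r} for "
            f"site {row['site_id']} taxon {row['taxon_id']}"
        )

    bad_status = set(traits["native_status"]) - NATIVE_STATUSES
    if bad_status:
        raise DataValueError(f"unknown native_status value(s): {sorted(bad_status)}")
    bad_habit = set(traits["growth_habit"]) - GROWTH_HABITS
    if bad_habit:
        raise DataValueError(f"unknown growth_habit value(s): {sorted(bad_habit)}")
    wis = traits["wis"].dropna()
    wis_named = wis[wis.astype(str).isin(WIS_VALUES)]
    wis_rest = wis.drop(wis_named.index)
    if len(wis_rest):
        vals = pd.to_numeric(wis_rest, errors="coerce")
        if vals.isna().any() or not vals.dropna().isin([1, 2, 3, 4, 5]).all():
            raise DataValueError("wis must be OBL/FACW/FAC/FACU/UPL or 1..5")

    orphan_taxa = set(cover["taxon_id"]) - set(traits["taxon_id"])
    if orphan_taxa:
        raise ReferentialError(
            f"cover references taxa with no trait row: {sorted(orphan_taxa)[:5]}"
        )
    orphan_sites = set(cover["site_id"]) - set(sites["site_id"])
    if orphan_sites:
        raise ReferentialError(
            f"cover references sites with no site row: {sorted(orphan_sites)[:5]}"
        )

    traits = traits.copy()
    traits["wis_value"] = wis_numeric(traits["wis"])
    return Dataset(
        cover=cover,
        traits=traits,
        sites=sites,
        disturbance=disturbance,
        n_plots=n_plots,
    )


def wis_numeric(wis: pd.Series) -> pd.Series:
    """Map wetland indicator statuses (names or numbers) to floats 1..5."""
    named = wis.astype(str).map(WIS_VALUES)
    numeric = pd.to_numeric(wis, errors="coerce")
    return named.fillna(numeric).astype(float)


def is_nonnative(traits: pd.DataFrame) -> pd.Series:
    """Boolean per trait row: alien (introduced/adventive) or cryptogenic."""
    return traits["native_status"].isin(NONNATIVE_STATUSES)


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset CSVs to *out_dir*; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    cover = ds.cover
    if (cover["visit_no"] == 1).all():
        cover = cover[COVER_COLUMNS]
    else:
        cover = cover[COVER_COLUMNS + ["visit_no"]]
    for name, df in [
        ("cover", cover),
        ("traits", ds.traits[TRAIT_COLUMNS]),
        ("sites", ds.sites[SITE_COLUMNS]),
    ]:
        paths[name] = out / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    if ds.disturbance is not None:
        paths["disturbance"] = out / "disturbance.csv"
        ds.disturbance[DISTURBANCE_COLUMNS].to_csv(paths["disturbance"], index=False)
    return paths


def load_dataset_dir(in_dir: str | Path, n_plots: int = 5) -> Dataset:
    """Load a dataset from a directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    dist = in_dir / "disturbance.csv"
    return load_dataset(
        in_dir / "cover.csv",
        in_dir / "traits.csv",
        in_dir / "sites.csv",
        dist if dist.exists() else None,
        n_plots=n_plots,
    )


# ---------------------------------------------------------------------------
# Validation (reports, does not throw)


def validate_dataset(ds: Dataset) -> list[Issue]:
    """Check every dataset invariant; empty list iff all hold."""
    issues: list[Issue] = []

    key = ["site_id", "visit_no", "plot_id", "taxon_id"]
    dups = ds.cover[ds.cover.duplicated(key, keep="first")]
    for _, row in dups.iterrows():
        issues.append(
            Issue(
                "duplicate_cover_row",
                f"duplicate (site, visit, plot, taxon) observation "
                f"plot {row['plot_id']}",
                site_id=row["site_id"],
                taxon_id=row["taxon_id"],
            )
        )

    bad_plot = ds.cover[
        (ds.cover["plot_id"] < 1) | (ds.cover["plot_id"] > ds.n_plots)
    ]
    for _, row in bad_plot.iterrows():
        issues.append(
            Issue(
                "plot_id_out_of_range",
                f"plot_id {row['plot_id']} outside 1..{ds.n_plots}",
                site_id=row["site_id"],
                taxon_id=row["taxon_id"],
            )
        )

    bad_cover = ds.cover[(ds.cover["cover"] <= 0) | (ds.cover["cover"] > 100)]
    for _, row in bad_cover.iterrows():
        issues.append(
            Issue(
                "cover_out_of_range",
                f"cover {row['cover']} outside (0, 100]",
                site_id=row["site_id"],
                taxon_id=row["taxon_id"],
            )
        )

    dup_traits = ds.traits[ds.traits.duplicated("taxon_id", keep="first")]
    for _, row in dup_traits.iterrows():
        issues.append(
            Issue("duplicate_taxon", "duplicate trait row", taxon_id=row["taxon_id"])
        )

    dup_sites = ds.sites[ds.sites.duplicated(["site_id", "visit_no"], keep="first")]
    for _, row in dup_sites.iterrows():
        issues.append(
            Issue("duplicate_site_visit", "duplicate site-visit row", site_id=row["site_id"])
        )

    prob = ds.sites[ds.sites["is_probability"]]
    for _, row in prob[prob["weight"] <= 0].iterrows():
        issues.append(
            Issue(
                "nonpositive_weight",
                f"probability site has weight {row['weight']}",
                site_id=row["site_id"],
            )
        )

    bad_eco = ds.sites[~ds.sites["ecoregion"].isin(ECOREGIONS)]
    for _, row in bad_eco.iterrows():
        issues.append(
            Issue("unknown_ecoregion", f"ecoregion {row['ecoregion']!r}", site_id=row["site_id"])
        )
    bad_wt = ds.sites[~ds.sites["wetland_type"].isin(WETLAND_TYPES)]
    for _, row in bad_wt.iterrows():
        issues.append(
            Issue(
                "unknown_wetland_type",
                f"wetland_type {row['wetland_type']!r}",
                site_id=row["site_id"],
            )
        )

    bg = ds.sites[(ds.sites["bareground"] < 0) | (ds.sites["bareground"] > 100)]
    for _, row in bg.iterrows():
        issues.append(
            Issue(
                "bareground_out_of_range",
                f"bareground {row['bareground']} outside 0..100",
                site_id=row["site_id"],
            )
        )

    # revisit rows must reference an existing visit-1 site
    visit1 = set(ds.sites.loc[ds.sites["visit_no"] == 1, "site_id"])
    revisit = ds.sites[ds.sites["visit_no"] >= 2]
    for _, row in revisit[~revisit["site_id"].isin(visit1)].iterrows():
        issues.append(
            Issue(
                "orphan_revisit",
                f"visit {row['visit_no']} has no visit-1 row",
                site_id=row["site_id"],
            )
        )

    if ds.disturbance is not None:
        neg = ds.disturbance[
            (ds.disturbance[[f"idx{i}" for i in range(1, 9)]] < 0).any(axis=1)
        ]
        for _, row in neg.iterrows():
            issues.append(
                Issue(
                    "negative_disturbance_index",
                    "raw disturbance sub-index < 0",
                    site_id=row["site_id"],
                )
            )

    return issues
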