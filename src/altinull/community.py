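"""Site tables, community matrices, and the occupancy filter.

The two core containers are thin wrappers around :class:`pandas.DataFrame`:

* :class:`SiteTable` — one row per lake, with an altitude column (m a.s.l.)
  and any number of environmental variables, each tagged with a *kind*
  (``concentration``, ``percentage``, ``ph`` or ``nominal``) that drives
  downstream transformation rules.
* :class:`CommunityMatrix` — sites x species non-negative integer counts,
  labelled with a taxonomic group name.

Both validate their invariants on construction, so every downstream stage
can assume a clean table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VAR_KINDS = frozenset({"concentration", "percentage", "ph", "nominal"})


class CommunityDataError(ValueError):
    """Raised when a site table or community matrix violates an invariant."""


@dataclass
class SiteTable:
    """Lakes with altitude and environmental variables.

    Parameters
    ----------
    data:
        DataFrame indexed by unique ``site_id`` with an ``altitude`` column
        (meters a.s.l.) plus zero or more environmental variables.
    var_kind:
        Mapping of environmental-variable name to kind.  Every non-altitude
        column must be covered.
    """

    data: pd.DataFrame
    var_kind: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        if "altitude" not in df.columns:
            raise CommunityDataError("site table requires an 'altitude' column")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise CommunityDataError(f"duplicate site_id values: {dupes}")
        alt = pd.to_numeric(df["altitude"], errors="coerce")
        if alt.isna().any() or not np.isfinite(alt.to_numpy(dtype=float)).all():
            raise CommunityDataError("altitudes must be finite numbers")
        self.data = df.assign(altitude=alt.astype(float))
        env_cols = [c for c in df.columns if c != "altitude"]
        missing = set(env_cols) - set(self.var_kind)
        if missing:
            raise CommunityDataError(f"no var_kind declared for: {sorted(missing)}")
        bad_kinds = {v for v in self.var_kind.values()} - VAR_KINDS
        if bad_kinds:
            raise CommunityDataError(f"unknown variable kinds: {sorted(bad_kinds)}")
        if df[env_cols].isna().any().any():
            raise CommunityDataError("missing environmental values are not allowed")
        for name in env_cols:
            kind = self.var_kind[name]
            vals = df[name].to_numpy(dtype=float)
            if kind == "percentage" and ((vals < 0) | (vals > 100)).any():
                raise CommunityDataError(f"percentage variable {name!r} outside [0, 100]")
            if kind == "nominal" and not np.isin(vals, (0.0, 1.0)).all():
                raise CommunityDataError(f"nominal variable {name!r} must be coded 0/1")

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def altitude(self) -> pd.Series:
        return self.data["altitude"]

    @property
    def env(self) -> pd.DataFrame:
        """Environmental variables only (altitude excluded)."""
        return self.data.drop(columns="altitude")

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="site_id")


@dataclass
class CommunityMatrix:
    """Sites x species count matrix for one taxonomic group."""

    group: str
    counts: pd.DataFrame  # index = site_id, columns = species

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            raise CommunityDataError("duplicate site_id in community matrix")
        if df.columns.duplicated().any():
            raise CommunityDataError("duplicate species names in community matrix")
        if df.size:
            arr = df.to_numpy()
            if not np.issubdtype(arr.dtype, np.number):
                raise CommunityDataError("non-numeric counts in community matrix")
            if (arr < 0).any():
                raise CommunityDataError("negative counts in community matrix")
            if not np.allclose(arr, np.round(arr)):
                raise CommunityDataError("counts must be integers")
            self.counts = df.astype(np.int64)

    @property
    def sites(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_sites(self) -> int:
        return len(self.counts.index)

    @property
    def n_species(self) -> int:
        return len(self.counts.columns)

    def occupancy(self) -> pd.Series:
        """Number of occupied sites (count > 0) per species."""
        return (self.counts > 0).sum(axis=0)

    def align_to(self, sites: SiteTable) -> "CommunityMatrix":
        """Reorder rows to match a site table; error on unknown sites."""
        unknown = set(self.sites) - set(sites.site_ids)
        if unknown:
            raise CommunityDataError(f"community sites absent from site table: {sorted(unknown)}")
        return CommunityMatrix(self.group, self.counts.loc[[s for s in sites.site_ids if s in self.counts.index]])

    def to_csv(self, path) -> None:
        self.counts.to_csv(path, index_label="site_id")


@dataclass
class OccupancyFilterReport:
    """Which species survived the minimum-occupancy filter."""

    retained: list[str]
    dropped: list[str]
    min_sites: int


def load_site_table(path, var_kind: dict[str, str]) -> SiteTable:
    """Read a site table CSV (columns ``site_id, altitude, <var>, ...``)."""
    df = pd.read_csv(path, index_col="site_id")
    return SiteTable(df, var_kind=dict(var_kind))


def load_community_matrix(path, group: str) -> CommunityMatrix:
    """Read a community CSV (first column ``site_id``, remaining species counts)."""
    df = pd.read_csv(path, index_col="site_id")
    return CommunityMatrix(group=group, counts=df)


def filter_by_occupancy(
    cm: CommunityMatrix, min_sites: int = 4
) -> tuple[CommunityMatrix, OccupancyFilterReport]:
    """Keep species present (count > 0) in at least ``min_sites`` sites.

    The default of four occupied lakes is the inclusion rule applied before
    every analysis stage; the site set is never altered.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    occ = cm.occupancy()
    retained = [s for s in cm.species if occ[s] >= min_sites]
    dropped = [s for s in cm.species if occ[s] < min_sites]
    out = CommunityMatrix(cm.group, cm.counts[retained])
    return out, OccupancyFilterReport(retained=retained, dropped=dropped, min_sites=min_sites)


def to_presence_absence(cm: CommunityMatrix) -> CommunityMatrix:
    """Map counts to 0/1 occurrence. Idempotent."""
    return CommunityMatrix(cm.group, (cm.counts > 0).astype(np.int64))
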