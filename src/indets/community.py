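"""Community data model and I/O.

The substrate of every analysis in this package is a plot × morpho-species
abundance table of stem counts together with a per-species metadata record
(identification status and genus) and, optionally, plot coordinates.

Three *views* of the same inventory are built from it:

* **AMS** — all morpho-species: the table as read.
* **IMS** — identified morpho-species only (:func:`subset_identified`);
  the complement is the UMS (unidentified) set, so ``S(AMS) = S(IMS) + S(UMS)``.
* **genus** — columns aggregated to genus (:func:`aggregate_to_genus`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

STATUS_IDENTIFIED = "identified"
STATUS_UNIDENTIFIED = "unidentified"
#: Sentinel genus label for morpho-species with no genus-level determination.
UNKNOWN_GENUS = "unknown"

_VALID_STATUS = {STATUS_IDENTIFIED, STATUS_UNIDENTIFIED}


class ValidationError(ValueError):
    """Raised when a community table or its sidecars violate an invariant."""


def _check_unique(labels, what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} label(s): {dupes}")


@dataclass(frozen=True)
class CommunityTable:
    """Plot × morpho-species stem-count matrix with species metadata.

    Parameters
    ----------
    plot_ids, species_ids
        Ordered, unique labels for the matrix axes.
    abundance
        Integer matrix of shape ``(n_plots, n_species)``, counts >= 0.
        Every species column must have a positive total; plot rows may be
        empty only as the result of truncation (such plots are *flagged*
        via :attr:`empty_plots` and excluded from pairwise analyses).
    species_meta
        One row per species (indexed by species id) with columns ``status``
        (``identified``/``unidentified``) and ``genus``.
    """

    plot_ids: tuple
    species_ids: tuple
    abundance: np.ndarray
    species_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "plot_ids", tuple(str(p) for p in self.plot_ids))
        object.__setattr__(self, "species_ids", tuple(str(s) for s in self.species_ids))
        _check_unique(self.plot_ids, "plot")
        _check_unique(self.species_ids, "species")
        ab = np.asarray(self.abundance)
        if ab.shape != (len(self.plot_ids), len(self.species_ids)):
            raise ValidationError(
                f"abundance shape {ab.shape} != "
                f"({len(self.plot_ids)}, {len(self.species_ids)})"
            )
        if not np.issubdtype(ab.dtype, np.integer):
            if not np.all(np.equal(np.mod(ab, 1), 0)):
                bad = np.argwhere(np.mod(ab, 1) != 0)[0]
                raise ValidationError(
                    f"non-integer abundance at plot {self.plot_ids[bad[0]]!r}, "
                    f"species {self.species_ids[bad[1]]!r}"
                )
            ab = ab.astype(np.int64)
        if np.any(ab < 0):
            bad = np.argwhere(ab < 0)[0]
            raise ValidationError(
                f"negative abundance at plot {self.plot_ids[bad[0]]!r}, "
                f"species {self.species_ids[bad[1]]!r}"
            )
        ab = np.ascontiguousarray(ab, dtype=np.int64)
        ab.setflags(write=False)
        object.__setattr__(self, "abundance", ab)

        meta = self.species_meta
        missing = [s for s in self.species_ids if s not in meta.index]
        if missing:
            raise ValidationError(f"species missing from metadata: {missing[:5]}")
        for col in ("status", "genus"):
            if col not in meta.columns:
                raise ValidationError(f"species metadata lacks column {col!r}")
        meta = meta.loc[list(self.species_ids), ["status", "genus"]].copy()
        meta["genus"] = (
            meta["genus"].fillna(UNKNOWN_GENUS).astype(str).replace("", UNKNOWN_GENUS)
        )
        meta["status"] = meta["status"].astype(str)
        bad_status = set(meta["status"]) - _VALID_STATUS
        if bad_status:
            raise ValidationError(f"invalid status value(s): {sorted(bad_status)}")
        object.__setattr__(self, "species_meta", meta)

        if self.n_species and np.any(ab.sum(axis=0) == 0):
            empty = [
                self.species_ids[j] for j in np.flatnonzero(ab.sum(axis=0) == 0)
            ]
            raise ValidationError(f"species with zero total abundance: {empty[:5]}")

    # ------------------------------------------------------------------ views
    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def row_sums(self) -> np.ndarray:
        return self.abundance.sum(axis=1)

    @property
    def species_totals(self) -> np.ndarray:
        return self.abundance.sum(axis=0)

    @property
    def empty_plots(self) -> tuple:
        """Plots with zero stems (possible only after truncation)."""
        return tuple(
            self.plot_ids[i] for i in np.flatnonzero(self.row_sums == 0)
        )

    @property
    def statuses(self) -> np.ndarray:
        return self.species_meta["status"].to_numpy()

    @property
    def genera(self) -> np.ndarray:
        return self.species_meta["genus"].to_numpy()

    def presence(self) -> np.ndarray:
        return self.abundance > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundance, index=list(self.plot_ids), columns=list(self.species_ids)
        )

    def drop_empty_plots(self) -> "CommunityTable":
        keep = self.row_sums > 0
        if keep.all():
            return self
        return CommunityTable(
            tuple(p for p, k in zip(self.plot_ids, keep) if k),
            self.species_ids,
            self.abundance[keep],
            self.species_meta,
        )

    def subset_plots(self, plot_ids, drop_lost_species: bool = True) -> "CommunityTable":
        """Restrict to the given plots; species absent from them are dropped
        (keeping the column-total invariant) unless told otherwise."""
        pos = {p: i for i, p in enumerate(self.plot_ids)}
        missing = [p for p in plot_ids if p not in pos]
        if missing:
            raise ValidationError(f"unknown plot(s): {missing[:5]}")
        idx = [pos[p] for p in plot_ids]
        ab = self.abundance[idx]
        species = self.species_ids
        if drop_lost_species:
            keep = ab.sum(axis=0) > 0
            ab = ab[:, keep]
            species = tuple(s for s, k in zip(species, keep) if k)
        return CommunityTable(tuple(plot_ids), species, ab, self.species_meta)

    def select_species(self, species: list) -> "CommunityTable":
        """Restrict to the given species (order preserved from this table)."""
        wanted = set(species)
        idx = [j for j, s in enumerate(self.species_ids) if s in wanted]
        return CommunityTable(
            self.plot_ids,
            tuple(self.species_ids[j] for j in idx),
            self.abundance[:, idx],
            self.species_meta,
        )


@dataclass(frozen=True)
class PlotGeo:
    """Plot coordinates, either geographic (lon/lat degrees) or planar (km)."""

    plot_ids: tuple
    coord_mode: str  # "geographic" | "planar"
    x: np.ndarray  # longitude degrees, or km easting
    y: np.ndarray  # latitude degrees, or km northing

    def __post_init__(self):
        object.__setattr__(self, "plot_ids", tuple(str(p) for p in self.plot_ids))
        _check_unique(self.plot_ids, "plot")
        if self.coord_mode not in ("geographic", "planar"):
            raise ValidationError(f"unknown coord_mode {self.coord_mode!r}")
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != (len(self.plot_ids),) or y.shape != (len(self.plot_ids),):
            raise ValidationError("coordinate arrays must match plot_ids length")
        if self.coord_mode == "geographic":
            if np.any((y < -90) | (y > 90)):
                raise ValidationError("latitude outside [-90, 90]")
            if np.any((x < -180) | (x > 180)):
                raise ValidationError("longitude outside [-180, 180]")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def subset(self, plot_ids) -> "PlotGeo":
        pos = {p: i for i, p in enumerate(self.plot_ids)}
        missing = [p for p in plot_ids if p not in pos]
        if missing:
            raise ValidationError(f"plots without coordinates: {missing[:5]}")
        idx = [pos[p] for p in plot_ids]
        return PlotGeo(tuple(plot_ids), self.coord_mode, self.x[idx], self.y[idx])


# ---------------------------------------------------------------------- I/O

def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_community_table(table_path, meta_path) -> CommunityTable:
    """Read a wide plot × species table and its species-metadata sidecar.

    The table is delimited text with the plot id in the first column and one
    column per species; the metadata file has columns ``species_id``,
    ``status`` and ``genus``. Any species present in the table but absent
    from the metadata is an error, as is a negative, non-integer or
    duplicate entry.
    """
    table = pd.read_csv(table_path, sep=_sep_for(table_path), index_col=0)
    meta = pd.read_csv(meta_path, sep=_sep_for(meta_path), dtype=str)
    if "species_id" not in meta.columns:
        raise ValidationError("metadata file lacks a species_id column")
    _check_unique(meta["species_id"], "species (metadata)")
    meta = meta.set_index("species_id")
    t = CommunityTable(
        tuple(table.index.astype(str)),
        tuple(table.columns.astype(str)),
        table.to_numpy(),
        meta,
    )
    if t.n_plots and np.any(t.row_sums == 0):
        raise ValidationError(f"plot(s) with zero stems on input: {t.empty_plots[:5]}")
    return t


def write_community_table(t: CommunityTable, table_path, meta_path) -> None:
    t.to_frame().rename_axis("plot_id").to_csv(table_path, sep=_sep_for(table_path))
    t.species_meta.rename_axis("species_id").to_csv(
        meta_path, sep=_sep_for(meta_path)
    )


def read_plot_geo(path, coord_mode: str | None = None) -> PlotGeo:
    """Read plot coordinates: columns ``plot_id, lat, lon`` (geographic) or
    ``plot_id, x_km, y_km`` (planar). Mode is inferred from the columns
    unless given explicitly."""
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = set(df.columns)
    if coord_mode is None:
        coord_mode = "geographic" if {"lat", "lon"} <= cols else "planar"
    if coord_mode == "geographic":
        if not {"lat", "lon"} <= cols:
            raise ValidationError("geographic coordinates need lat and lon columns")
        return PlotGeo(
            tuple(df["plot_id"].astype(str)), "geographic",
            df["lon"].to_numpy(float), df["lat"].to_numpy(float),
        )
    if not {"x_km", "y_km"} <= cols:
        raise ValidationError("planar coordinates need x_km and y_km columns")
    return PlotGeo(
        tuple(df["plot_id"].astype(str)), "planar",
        df["x_km"].to_numpy(float), df["y_km"].to_numpy(float),
    )


def write_plot_geo(g: PlotGeo, path) -> None:
    if g.coord_mode == "geographic":
        df = pd.DataFrame({"plot_id": g.plot_ids, "lat": g.y, "lon": g.x})
    else:
        df = pd.DataFrame({"plot_id": g.plot_ids, "x_km": g.x, "y_km": g.y})
    df.to_csv(path, sep=_sep_for(path), index=False)


# ------------------------------------------------------------------- views

def subset_identified(t: CommunityTable) -> CommunityTable:
    """Return the IMS view: only species with status ``identified``.

    Plots whose stems were all unidentified become empty rows; they are kept
    in the object (so plot sets stay aligned) but flagged through
    :attr:`CommunityTable.empty_plots` and dropped by pairwise analyses.
    """
    keep = t.statuses == STATUS_IDENTIFIED
    return CommunityTable(
        t.plot_ids,
        tuple(s for s, k in zip(t.species_ids, keep) if k),
        t.abundance[:, keep],
        t.species_meta,
    )


def aggregate_to_genus(
    t: CommunityTable, include_unidentified: bool = True
) -> CommunityTable:
    """Aggregate species columns to genus (higher-taxon view).

    Species whose genus is :data:`UNKNOWN_GENUS` are dropped. By default
    unidentified morpho-species that do carry a genus label contribute to
    their genus total (the higher-taxon view discards species-level
    identification, so genus-known indets are usable information); pass
    ``include_unidentified=False`` to aggregate the IMS view instead.
    Output genera are ordered lexicographically.
    """
    genera = t.genera
    keep = genera != UNKNOWN_GENUS
    if not include_unidentified:
        keep &= t.statuses == STATUS_IDENTIFIED
    if not keep.any():
        raise ValidationError("no species with a known genus to aggregate")
    out_genera = sorted(set(genera[keep]))
    col = {g: i for i, g in enumerate(out_genera)}
    ab = np.zeros((t.n_plots, len(out_genera)), dtype=np.int64)
    for j in np.flatnonzero(keep):
        ab[:, col[genera[j]]] += t.abundance[:, j]
    meta = pd.DataFrame(
        {"status": STATUS_IDENTIFIED, "genus": out_genera},
        index=pd.Index(out_genera, name="species_id"),
    )
    nonzero = ab.sum(axis=0) > 0
    return CommunityTable(
        t.plot_ids,
        tuple(g for g, k in zip(out_genera, nonzero) if k),
        ab[:, nonzero],
        meta,
    )
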