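"""Core data containers and CSV readers/writers shared by every analysis stage.

All tabular objects are label-indexed pandas structures wrapped in light
validating classes; matrices are never addressed positionally. Species order
is canonicalized (sorted) on construction so that downstream permutation
streams are reproducible regardless of input column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALUE_KINDS = ("presence", "braun_blanquet", "abundance")
GUILDS = ("plant", "orthopteran")

#: Midpoint percent cover for the 7-degree Braun-Blanquet scale
#: (0 = absent, 1 = r, 2 = +, then interval midpoints up to 75-100%).
BRAUN_BLANQUET_MIDPOINTS = {
    0: 0.0,
    1: 0.1,
    2: 0.5,
    3: 2.5,
    4: 15.0,
    5: 37.5,
    6: 62.5,
    7: 87.5,
}


class DataValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _check_unique(labels: Iterable[str], what: str) -> list[str]:
    labels = list(labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise DataValidationError(f"duplicate {what} labels: {dupes}")
    return labels


@dataclass
class SiteSpeciesMatrix:
    """Sites × species table of occurrence or abundance with guild labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Sites in rows, species in columns, non-negative numeric cells.
    guild : mapping
        ``species -> {"plant", "orthopteran"}`` for every species.
    value_kind : str
        One of ``presence`` (0/1), ``braun_blanquet`` (ordinal class 0-7)
        or ``abundance`` (continuous, e.g. percent cover).
    """

    values: pd.DataFrame
    guild: dict[str, str]
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise DataValidationError(f"unknown value_kind {self.value_kind!r}")
        _check_unique(self.values.index, "site")
        _check_unique(self.values.columns, "species")
        # canonical sorted species order; sites keep input order
        self.values = self.values.reindex(columns=sorted(self.values.columns))
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise DataValidationError(
                f"non-numeric or non-finite cell at site "
                f"{self.values.index[bad[0]]!r}, species {self.values.columns[bad[1]]!r}"
            )
        if (arr < 0).any():
            raise DataValidationError("negative values in site × species matrix")
        if self.value_kind == "presence" and not np.isin(arr, (0.0, 1.0)).all():
            bad = np.argwhere(~np.isin(arr, (0.0, 1.0)))[0]
            raise DataValidationError(
                f"presence matrix has non 0/1 cell at site "
                f"{self.values.index[bad[0]]!r}, species {self.values.columns[bad[1]]!r}"
            )
        if self.value_kind == "braun_blanquet" and not np.isin(arr, range(8)).all():
            raise DataValidationError("braun_blanquet values must be integer classes 0-7")
        missing = [s for s in self.values.columns if s not in self.guild]
        if missing:
            raise DataValidationError(f"species without guild label: {missing}")
        bad_guild = {s: g for s, g in self.guild.items() if g not in GUILDS}
        if bad_guild:
            raise DataValidationError(f"unknown guild labels: {bad_guild}")

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.columns)

    def species_of_guild(self, guild: str) -> list[str]:
        return [s for s in self.species_ids if self.guild[s] == guild]

    def subset_species(self, species: Iterable[str]) -> "SiteSpeciesMatrix":
        species = list(species)
        missing = [s for s in species if s not in self.values.columns]
        if missing:
            raise DataValidationError(f"species not in matrix: {missing}")
        return SiteSpeciesMatrix(
            values=self.values[species].copy(),
            guild={s: self.guild[s] for s in species},
            value_kind=self.value_kind,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SiteSpeciesMatrix):
            return NotImplemented
        return (
            self.value_kind == other.value_kind
            and self.guild == other.guild
            and self.values.equals(other.values)
        )


@dataclass
class TraitTable:
    """Species × trait table with per-trait kind (continuous or binary).

    Missing values are NaN; binary traits take values in {0, 1, NaN}.
    """

    values: pd.DataFrame  # species in rows, traits in columns
    trait_kind: dict[str, str]

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "species")
        _check_unique(self.values.columns, "trait")
        self.values = self.values.sort_index()
        for t in self.values.columns:
            kind = self.trait_kind.get(t)
            if kind not in ("continuous", "binary"):
                raise DataValidationError(f"trait {t!r} has no declared kind")
            if kind == "binary":
                col = self.values[t].dropna().to_numpy(dtype=float)
                if not np.isin(col, (0.0, 1.0)).all():
                    raise DataValidationError(f"binary trait {t!r} has non 0/1 values")

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal, non-negative species distance matrix."""

    values: pd.DataFrame
    kind: str = "functional"  # or "phylogenetic"

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "species")
        if list(self.values.index) != list(self.values.columns):
            raise DataValidationError("distance matrix rows and columns must match")
        order = sorted(self.values.index)
        self.values = self.values.loc[order, order]
        arr = self.values.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise DataValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
            raise DataValidationError("distance matrix diagonal is not zero")
        if (arr < -1e-12).any():
            raise DataValidationError("negative distances")
        # exact symmetry / zero diagonal after validation
        arr = np.clip((arr + arr.T) / 2.0, 0.0, None)
        np.fill_diagonal(arr, 0.0)
        self.values = pd.DataFrame(arr, index=order, columns=order)

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.index)

    def subset(self, species: Iterable[str]) -> "DistanceMatrix":
        species = sorted(species)
        missing = [s for s in species if s not in self.values.index]
        if missing:
            raise DataValidationError(f"species not in distance matrix: {missing}")
        return DistanceMatrix(self.values.loc[species, species].copy(), kind=self.kind)


@dataclass
class EnvTables:
    """Three site-level explanatory sets used in the variance partitioning.

    X1 agricultural practices (cutting, grazing, fertilizers), X2 soil
    conditions (total N, C/N, CEC), X3 spatial location (longitude,
    latitude, elevation).
    """

    x1: pd.DataFrame
    x2: pd.DataFrame
    x3: pd.DataFrame

    def __post_init__(self) -> None:
        sites = list(self.x1.index)
        for name, df in (("X2", self.x2), ("X3", self.x3)):
            if list(df.index) != sites:
                raise DataValidationError(f"{name} site set differs from X1")
        for name, df in (("X1", self.x1), ("X2", self.x2), ("X3", self.x3)):
            if df.shape[1] == 0:
                raise DataValidationError(f"{name} has no variables")

    @property
    def site_ids(self) -> list[str]:
        return list(self.x1.index)

    def sets(self) -> dict[str, pd.DataFrame]:
        return {"X1": self.x1, "X2": self.x2, "X3": self.x3}


# ---------------------------------------------------------------------------
# readers / writers


def read_site_species(
    path: str | Path,
    value_kind: str,
    guild_map: Mapping[str, str] | str | Path,
) -> SiteSpeciesMatrix:
    """Read a sites × species CSV (sites as rows) into a validated matrix.

    ``guild_map`` is either a mapping or a path to a two-column CSV
    (species, guild).
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise DataValidationError(
                f"non-numeric cell in column {col!r}, row {bad.index[0]!r}: {bad.iloc[0]!r}"
            )
    if not isinstance(guild_map, Mapping):
        gdf = pd.read_csv(guild_map)
        guild_map = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)))
    return SiteSpeciesMatrix(values=df.astype(float), guild=dict(guild_map), value_kind=value_kind)


def write_site_species(m: SiteSpeciesMatrix, path: str | Path) -> None:
    m.values.to_csv(path, index_label="site")


def read_traits(path: str | Path, trait_kind: Mapping[str, str]) -> TraitTable:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return TraitTable(values=df.astype(float), trait_kind=dict(trait_kind))


def write_traits(t: TraitTable, path: str | Path) -> None:
    t.values.to_csv(path, index_label="species")


def read_distance_matrix(path: str | Path, kind: str = "functional") -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DistanceMatrix(values=df.astype(float), kind=kind)


def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    d.values.to_csv(path, index_label="species")


def read_env_tables(
    path_x1: str | Path, path_x2: str | Path, path_x3: str | Path
) -> EnvTables:
    frames = [pd.read_csv(p, index_col=0) for p in (path_x1, path_x2, path_x3)]
    for f in frames:
        f.index = f.index.astype(str)
    return EnvTables(*[f.astype(float) for f in frames])


def write_env_tables(env: EnvTables, directory: str | Path, prefix: str = "env") -> None:
    directory = Path(directory)
    for name, df in env.sets().items():
        df.to_csv(directory / f"{prefix}_{name}.csv", index_label="site")


# ---------------------------------------------------------------------------
# transforms


def braun_blanquet_to_cover(
    m: SiteSpeciesMatrix, scale: Mapping[int, float] | None = None
) -> SiteSpeciesMatrix:
    """Map ordinal Braun-Blanquet classes to midpoint percent cover.

    The default table assigns 0 to absence, token covers to the 'r' and '+'
    classes, and interval midpoints to classes 3-7.
    """
    if m.value_kind != "braun_blanquet":
        raise DataValidationError("input is not a Braun-Blanquet matrix")
    table = dict(BRAUN_BLANQUET_MIDPOINTS if scale is None else scale)
    arr = m.values.to_numpy(dtype=float)
    out = np.empty_like(arr)
    for cls, cover in table.items():
        out[arr == cls] = cover
    covered = np.isin(arr, list(table))
    if not covered.all():
        raise DataValidationError("Braun-Blanquet class outside the 0-7 table")
    return SiteSpeciesMatrix(
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        guild=dict(m.guild),
        value_kind="abundance",
    )


def to_presence(m: SiteSpeciesMatrix) -> SiteSpeciesMatrix:
    """Threshold any matrix to presence/absence (value > 0 becomes 1)."""
    arr = (m.values.to_numpy(dtype=float) > 0).astype(float)
    return SiteSpeciesMatrix(
        values=pd.DataFrame(arr, index=m.values.index, columns=m.values.columns),
        guild=dict(m.guild),
        value_kind="presence",
    )
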