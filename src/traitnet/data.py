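"""Trait tables and environment tables: containers, validation and CSV IO.

The canonical layout is wide: one row per sampled individual (or pooled
replicate), metadata columns ``species``, ``plant_type``, ``elevation_m``,
``replicate``, and one numeric column per trait code.  Missing trait values
are explicit NaN, never silent zeros.  A long -> wide converter is provided
for data recorded as (sample, trait, value) triples.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import DEFAULT_CATALOG, TraitDefinition, catalog_codes
from .errors import SchemaError, ParseError, ValidationError

META_COLUMNS = ("species", "plant_type", "elevation_m", "replicate")
PLANT_TYPES = ("ephemeral", "non_ephemeral")


class TraitTable:
    """Validated per-sample trait measurements with species metadata.

    Parameters
    ----------
    frame:
        Wide-format DataFrame with the four metadata columns and one
        column per trait code.
    catalog:
        Trait definitions; trait columns must be a subset of its codes.
        Unknown columns are kept aside (reported, not analyzed).
    """

    def __init__(self, frame: pd.DataFrame, catalog: Sequence[TraitDefinition] = DEFAULT_CATALOG):
        self.catalog = tuple(catalog)
        known = set(catalog_codes(self.catalog))

        missing_meta = [c for c in META_COLUMNS if c not in frame.columns]
        if missing_meta:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing_meta)}")

        self.trait_codes: list[str] = [c for c in frame.columns if c in known]
        self.unknown_columns: list[str] = [
            c for c in frame.columns if c not in known and c not in META_COLUMNS
        ]
        if self.unknown_columns:
            warnings.warn(
                f"ignoring {len(self.unknown_columns)} unknown column(s): "
                f"{', '.join(self.unknown_columns)}",
                stacklevel=2,
            )

        frame = frame.reset_index(drop=True)
        for code in self.trait_codes:
            col = frame[code]
            if not pd.api.types.is_numeric_dtype(col):
                coerced = pd.to_numeric(col, errors="coerce")
                bad = coerced.isna() & col.notna()
                if bad.any():
                    row = int(np.flatnonzero(bad.to_numpy())[0])
                    raise ParseError(
                        f"non-numeric value {col.iloc[row]!r} for trait {code!r} at row {row}"
                    )
                frame[code] = coerced
            frame[code] = frame[code].astype(float)

        elev = pd.to_numeric(frame["elevation_m"], errors="coerce")
        if elev.isna().any() or (elev <= 0).any():
            raise ValidationError("elevation_m must be numeric and > 0 for every row")
        frame["elevation_m"] = elev.astype(float)

        bad_types = set(frame["plant_type"].unique()) - set(PLANT_TYPES)
        if bad_types:
            raise ValidationError(
                f"plant_type must be one of {PLANT_TYPES}; found {sorted(bad_types)}"
            )

        key = frame[["species", "elevation_m", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(
                "duplicated (species, elevation, replicate) key: "
                f"({dup['species']}, {dup['elevation_m']}, {dup['replicate']})"
            )

        self.data = frame[list(META_COLUMNS) + self.trait_codes].copy()

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return (
            f"TraitTable({len(self.data)} samples, {len(self.trait_codes)} traits, "
            f"{self.data['species'].nunique()} species)"
        )

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    @property
    def elevations(self) -> list[float]:
        return sorted(self.data["elevation_m"].unique())

    def trait_matrix(self) -> pd.DataFrame:
        """Samples x traits numeric block."""
        return self.data[self.trait_codes]

    def species_types(self) -> dict[str, str]:
        return dict(self.data.groupby("species")["plant_type"].first())

    def species_means(self, traits: Iterable[str] | None = None) -> pd.DataFrame:
        """Collapse replicates (and elevations) to one mean per species."""
        cols = list(traits) if traits is not None else self.trait_codes
        return self.data.groupby("species")[cols].mean()

    def subset(self, mask) -> "TraitTable":
        return TraitTable(self.data[mask].reset_index(drop=True), self.catalog)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, catalog: Sequence[TraitDefinition] = DEFAULT_CATALOG) -> "TraitTable":
        frame = pd.read_csv(path)
        return cls(frame, catalog)


def read_trait_table(path, catalog: Sequence[TraitDefinition] = DEFAULT_CATALOG) -> TraitTable:
    """Read a wide-format trait CSV and validate it against the catalog."""
    return TraitTable.from_csv(path, catalog)


def long_to_wide(frame: pd.DataFrame, value_col: str = "value", trait_col: str = "trait") -> pd.DataFrame:
    """Pivot (sample metadata, trait, value) triples into the wide layout."""
    required = set(META_COLUMNS) | {trait_col, value_col}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(sorted(missing))}")
    wide = frame.pivot_table(
        index=list(META_COLUMNS), columns=trait_col, values=value_col, aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    return wide


ENV_COLUMNS = (
    "elevation_m",
    "soil_pH",
    "soil_C",
    "soil_P",
    "soil_N",
    "soil_EC",
    "MAP",
    "MASR",
    "MAT",
)


def read_environment_table(path) -> pd.DataFrame:
    """Read a per-site environment CSV (one record per elevation band)."""
    frame = pd.read_csv(path)
    missing = [c for c in ENV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing environment column(s): {', '.join(missing)}")
    frame = frame[list(ENV_COLUMNS)].astype(float)
    if not np.isfinite(frame.to_numpy()).all():
        raise ValidationError("environment table contains non-finite values")
    if frame["elevation_m"].duplicated().any():
        raise ValidationError("one environment record per elevation band is required")
    return frame
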