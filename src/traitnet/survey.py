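"""Importance values (IV) from quadrat survey data.

IV = (relative frequency + relative density + relative coverage) / 3, with
frequency the number of quadrats a species occurs in, density its total
individual count, and coverage its summed cover; each component is
normalized to sum to 1 over species, so IVs form a simplex as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import SchemaError, TraitnetError

SURVEY_COLUMNS = ("plot", "quadrat", "species", "count", "cover")


class QuadratSurvey:
    """Species occurrence, count and cover per (plot, quadrat).

    A ``height`` column is accepted and carried along but unused by IV.
    """

    def __init__(self, frame: pd.DataFrame, allow_layered_cover: bool = True):
        missing = [c for c in SURVEY_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        frame = frame.reset_index(drop=True)
        if (frame["count"] < 0).any():
            raise TraitnetError("counts must be nonnegative")
        if (frame["cover"] < 0).any():
            raise TraitnetError("cover must be nonnegative")
        key = frame[["plot", "quadrat", "species"]]
        if key.duplicated().any():
            raise TraitnetError("duplicated (plot, quadrat, species) record")
        if not allow_layered_cover:
            per_quadrat = frame.groupby(["plot", "quadrat"])["cover"].sum()
            if (per_quadrat > 1 + 1e-9).any():
                raise TraitnetError("cover sums exceed 1 in a quadrat (layered cover disallowed)")
        self.data = frame

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "QuadratSurvey":
        return cls(pd.read_csv(path), **kwargs)


@dataclass
class IVResult:
    """Per-species relative frequency / density / coverage and IV."""

    table: pd.DataFrame  # index species; columns the three components + importance_value
    frequency_unit: str = "quadrat"
    flags: list[str] = field(default_factory=list)

    @property
    def importance_values(self) -> pd.Series:
        return self.table["importance_value"]


def important_value(survey: QuadratSurvey, frequency_unit: str = "quadrat") -> IVResult:
    """Compute per-species importance values from a quadrat survey.

    ``frequency_unit`` selects whether frequency counts occupied quadrats
    (default, the sampling unit) or occupied plots.
    """
    df = survey.data[survey.data["count"] > 0]
    if df.empty:
        raise TraitnetError("empty survey: no nonzero records")
    if frequency_unit == "quadrat":
        freq = df.groupby("species").apply(
            lambda g: g[["plot", "quadrat"]].drop_duplicates().shape[0], include_groups=False
        )
    elif frequency_unit == "plot":
        freq = df.groupby("species")["plot"].nunique()
    else:
        raise TraitnetError(f"frequency_unit must be 'quadrat' or 'plot', got {frequency_unit!r}")
    density = df.groupby("species")["count"].sum()
    coverage = df.groupby("species")["cover"].sum()

    flags = []
    out = pd.DataFrame(index=sorted(df["species"].unique()))
    out["relative_frequency"] = (freq / freq.sum()).reindex(out.index).fillna(0.0)
    out["relative_density"] = (density / density.sum()).reindex(out.index).fillna(0.0)
    if coverage.sum() == 0:
        flags.append("all-zero cover: coverage component set to 0 for all species")
        warnings.warn(flags[-1], stacklevel=2)
        out["relative_coverage"] = 0.0
        out["importance_value"] = (out["relative_frequency"] + out["relative_density"]) / 3.0
    else:
        out["relative_coverage"] = (coverage / coverage.sum()).reindex(out.index).fillna(0.0)
        out["importance_value"] = (
            out["relative_frequency"] + out["relative_density"] + out["relative_coverage"]
        ) / 3.0
    out.index.name = "species"
    return IVResult(out, frequency_unit, flags)


def rank_species(iv: IVResult, top_k: int = 15) -> list[str]:
    """Species sorted by IV descending (ties broken by label ascending)."""
    if top_k < 1:
        raise TraitnetError("top_k must be >= 1")
    tab = iv.table.reset_index().sort_values(
        ["importance_value", "species"], ascending=[False, True]
    )
    ranked = list(tab["species"])
    if top_k > len(ranked):
        warnings.warn(
            f"top_k={top_k} exceeds the {len(ranked)} surveyed species; returning all",
            stacklevel=2,
        )
        return ranked
    return ranked[:top_k]
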