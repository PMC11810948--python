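"""Catalog of the 26 functional traits.

Traits are grouped into three functional categories — economic (leaf
resource-economics traits), nutrient (elemental and carbohydrate pools of
leaf and root), and defensive (structural and secondary-metabolite
defenses) — with 7 / 11 / 8 members respectively.  Codes follow the
conventional abbreviations of the trait-ecology literature (LDMC, SLA, ...).
Units are metadata only; no conversion is ever applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

CATEGORIES = ("economic", "nutrient", "defensive")
ORGANS = ("leaf", "root", "whole")


@dataclass(frozen=True)
class TraitDefinition:
    """A single functional trait: code, name, category, organ and units."""

    code: str
    full_name: str
    category: str
    organ: str
    units: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown trait category {self.category!r}")
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}")


def _t(code: str, full_name: str, category: str, organ: str, units: str) -> TraitDefinition:
    return TraitDefinition(code, full_name, category, organ, units)


#: The default 26-trait catalog (7 economic, 11 nutrient, 8 defensive).
DEFAULT_CATALOG: tuple[TraitDefinition, ...] = (
    # economic traits (leaf)
    _t("LDMC", "leaf dry matter content", "economic", "leaf", "g g^-1"),
    _t("SLA", "specific leaf area", "economic", "leaf", "cm^2 g^-1"),
    _t("LC", "leaf carbon concentration", "economic", "leaf", "mg g^-1"),
    _t("LN", "leaf nitrogen concentration", "economic", "leaf", "mg g^-1"),
    _t("LP", "leaf phosphorus concentration", "economic", "leaf", "mg g^-1"),
    _t("LC/N", "ratio of leaf carbon to nitrogen concentration", "economic", "leaf", "dimensionless"),
    _t("LN/P", "ratio of leaf nitrogen to phosphorus concentration", "economic", "leaf", "dimensionless"),
    # nutrient traits (root element pools and leaf/root carbohydrates)
    _t("RC", "root carbon concentration", "nutrient", "root", "mg g^-1"),
    _t("RN", "root nitrogen concentration", "nutrient", "root", "mg g^-1"),
    _t("RP", "root phosphorus concentration", "nutrient", "root", "mg g^-1"),
    _t("RC/N", "ratio of root carbon to nitrogen concentration", "nutrient", "root", "dimensionless"),
    _t("RN/P", "ratio of root nitrogen to phosphorus concentration", "nutrient", "root", "dimensionless"),
    _t("LSS", "leaf soluble sugar concentration", "nutrient", "leaf", "mg g^-1"),
    _t("LS", "leaf starch concentration", "nutrient", "leaf", "mg g^-1"),
    _t("LNSC", "leaf nonstructural carbohydrates", "nutrient", "leaf", "mg g^-1"),
    _t("RSS", "root soluble sugar concentration", "nutrient", "root", "mg g^-1"),
    _t("RS", "root starch concentration", "nutrient", "root", "mg g^-1"),
    _t("RNSC", "root nonstructural carbohydrates", "nutrient", "root", "mg g^-1"),
    # defensive traits (structure and secondary metabolites)
    _t("LCC", "leaf cellulose content", "defensive", "leaf", "mg g^-1"),
    _t("LLC", "leaf lignin content", "defensive", "leaf", "mg g^-1"),
    _t("LTPC", "leaf total phenols concentration", "defensive", "leaf", "mg g^-1"),
    _t("LTFC", "leaf total flavonoids concentration", "defensive", "leaf", "mg g^-1"),
    _t("RCC", "root cellulose content", "defensive", "root", "mg g^-1"),
    _t("RLC", "root lignin content", "defensive", "root", "mg g^-1"),
    _t("RTPC", "root total phenols concentration", "defensive", "root", "mg g^-1"),
    _t("RTFC", "root total flavonoids concentration", "defensive", "root", "mg g^-1"),
)


def default_catalog() -> tuple[TraitDefinition, ...]:
    """Return the default 26-trait catalog."""
    return DEFAULT_CATALOG


def catalog_codes(catalog: Iterable[TraitDefinition] = DEFAULT_CATALOG) -> list[str]:
    return [t.code for t in catalog]


def category_of(catalog: Iterable[TraitDefinition] = DEFAULT_CATALOG) -> dict[str, str]:
    """Map trait code -> category."""
    return {t.code: t.category for t in catalog}


def codes_in_category(category: str, catalog: Iterable[TraitDefinition] = DEFAULT_CATALOG) -> list[str]:
    return [t.code for t in catalog if t.category == category]
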