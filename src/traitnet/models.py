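"""Linear models of traits on plant type, elevation and their interaction.

For every trait an OLS model ``trait ~ type + elevation + type:elevation``
is fitted with elevation continuous (meters, centered) and effects tested
by sequential (Type-I) sums of squares in the stated order.  When the
interaction is significant, per-type simple regressions quantify the
type-specific elevation trends.  Environmental regressions relate each
trait (normalized by a rank-based inverse-normal transform by default) to
each site-level environmental variable by simple OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .data import TraitTable, ENV_COLUMNS
from .errors import TraitnetError


@dataclass
class ModelFit:
    """Sequential-SS ANOVA and coefficient table for one trait's model."""

    trait: str
    anova: pd.DataFrame  # index: factor, elevation, interaction, Residual
    coefficients: pd.DataFrame  # estimate, SE, t, p per term
    r_squared: float
    df_resid: float
    group_factor: str  # "type" or "species"

    def effect(self, name: str) -> tuple[float, float]:
        """(F, p) for 'factor' | 'elevation' | 'interaction'."""
        row = self.anova.loc[name]
        return float(row["F"]), float(row["PR(>F)"])


def _model_frame(trait: str, table: TraitTable, species_mode: str) -> tuple[pd.DataFrame, str]:
    df = table.data[["species", "plant_type", "elevation_m", trait]].dropna().copy()
    df["elev_c"] = df["elevation_m"] - df["elevation_m"].mean()
    df["y"] = df[trait]
    if species_mode == "type":
        df["grp"] = df["plant_type"]
    elif species_mode == "species":
        df["grp"] = df["species"]
    else:
        raise TraitnetError("species_mode must be 'type' or 'species'")
    return df, "grp"


def fit_trait_model(
    trait: str,
    table: TraitTable,
    species_mode: str = "type",
    ss_type: int = 1,
) -> ModelFit:
    """OLS of one trait on group, centered elevation and their interaction."""
    df, grp = _model_frame(trait, table, species_mode)
    if df["grp"].nunique() < 2:
        raise TraitnetError(f"singular design: factor 'grp' has a single level for {trait!r}")
    if df["elevation_m"].nunique() < 2:
        raise TraitnetError(f"singular design: elevation is constant for {trait!r}")
    if len(df) <= 4:
        raise TraitnetError(f"too few observations (n={len(df)}) to fit the model for {trait!r}")
    fit = smf.ols("y ~ C(grp) + elev_c + C(grp):elev_c", data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=ss_type)
    anova = anova.rename(
        index={
            "C(grp)": "factor",
            "elev_c": "elevation",
            "C(grp):elev_c": "interaction",
        }
    )
    coef = pd.DataFrame(
        {
            "estimate": fit.params,
            "SE": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return ModelFit(trait, anova, coef, float(fit.rsquared), float(fit.df_resid), species_mode)


def fit_all_models(table: TraitTable, species_mode: str = "type", ss_type: int = 1) -> pd.DataFrame:
    """Model table over all traits (one row per trait: F and p per effect)."""
    rows = []
    for trait in table.trait_codes:
        m = fit_trait_model(trait, table, species_mode=species_mode, ss_type=ss_type)
        f1, p1 = m.effect("factor")
        f2, p2 = m.effect("elevation")
        f3, p3 = m.effect("interaction")
        rows.append(
            {
                "trait": trait,
                "F_factor": f1,
                "p_factor": p1,
                "F_elevation": f2,
                "p_elevation": p2,
                "F_interaction": f3,
                "p_interaction": p3,
                "r_squared": m.r_squared,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupSlopes:
    """Per-type elevation regressions, run when the interaction demands it."""

    trait: str
    interaction_p: float
    pooled: bool  # True when the pooled model was retained
    slopes: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: group, slope, SE, ci_low, ci_high, p, n


def fit_by_group(
    trait: str,
    table: TraitTable,
    species_mode: str = "type",
    interaction_alpha: float = 0.05,
) -> GroupSlopes:
    """Per-group elevation slopes, gated on the interaction test.

    If the interaction p >= ``interaction_alpha`` the pooled model is
    retained and no per-group fits are run.
    """
    full = fit_trait_model(trait, table, species_mode=species_mode)
    _, p_int = full.effect("interaction")
    if p_int >= interaction_alpha:
        return GroupSlopes(trait, p_int, pooled=True)
    df, _ = _model_frame(trait, table, species_mode)
    rows = []
    for grp, sub in df.groupby("grp"):
        if len(sub) < 3:
            warnings.warn(f"group {grp!r} has < 3 points; skipped", stacklevel=2)
            continue
        fit = smf.ols("y ~ elev_c", data=sub).fit()
        ci = fit.conf_int().loc["elev_c"]
        rows.append(
            {
                "group": grp,
                "slope": float(fit.params["elev_c"]),
                "SE": float(fit.bse["elev_c"]),
                "ci_low": float(ci[0]),
                "ci_high": float(ci[1]),
                "p": float(fit.pvalues["elev_c"]),
                "n": int(len(sub)),
            }
        )
    return GroupSlopes(trait, p_int, pooled=False, slopes=pd.DataFrame(rows))


def rank_inverse_normal(x: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse-normal transform (ties share average ranks)."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    r = stats.rankdata(x[ok])
    n = ok.sum()
    out[ok] = stats.norm.ppf((r - 0.375) / (n + 0.25))
    return out


_TRANSFORMS = {
    "rankit": rank_inverse_normal,
    "log": lambda x: np.log(x),
    "none": lambda x: np.asarray(x, dtype=float),
}


def env_regressions(
    table: TraitTable,
    env: pd.DataFrame,
    transform: str = "rankit",
    plant_type: str | None = None,
) -> pd.DataFrame:
    """Simple OLS of each (transformed) trait on each environmental variable.

    Environment records are joined to samples by elevation band.  Returns a
    tidy frame with one row per (trait, env variable): slope, intercept,
    r2, p, n.  Constant environmental variables are skipped with a warning.
    """
    if transform not in _TRANSFORMS:
        raise TraitnetError(f"unknown transform {transform!r}")
    tf = _TRANSFORMS[transform]
    df = table.data if plant_type is None else table.data[table.data["plant_type"] == plant_type]
    merged = df.merge(env, on="elevation_m", how="inner")
    if merged.empty:
        raise TraitnetError("no samples matched an environment record by elevation band")
    env_vars = [c for c in ENV_COLUMNS if c != "elevation_m" and c in env.columns]
    rows = []
    for var in env_vars:
        if merged[var].nunique() <= 1:
            warnings.warn(f"environment variable {var!r} is constant; skipped", stacklevel=2)
            continue
        for trait in table.trait_codes:
            sub = merged[[trait, var]].dropna()
            if len(sub) < 3:
                continue
            y = tf(sub[trait].to_numpy())
            res = stats.linregress(sub[var].to_numpy(), y)
            rows.append(
                {
                    "trait": trait,
                    "env_var": var,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r2": res.rvalue**2,
                    "p": res.pvalue,
                    "n": int(len(sub)),
                }
            )
    return pd.DataFrame(rows)
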