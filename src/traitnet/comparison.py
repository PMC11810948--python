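"""Two-group trait comparisons with a normality gate, plus PCA.

Each trait is compared between ephemeral and non-ephemeral plants.  A
Shapiro-Wilk gate (per group, alpha = 0.05) decides the test: when both
groups look normal a paired t-test is used, pairing the per-type mean
values within each (elevation band, replicate index) cell; otherwise a
two-sided Mann-Whitney test on all values.  PCA operates on standardized
traits, i.e. on the correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import TraitTable
from .errors import TraitnetError


@dataclass
class ComparisonResult:
    trait: str
    chosen_test: str  # "paired_t" | "mann_whitney" | "unpaired_t"
    statistic: float
    p_value: float
    group_means: dict[str, float]
    group_medians: dict[str, float]
    direction: str  # which group has the larger mean ("tie" when equal)
    warnings: list[str] = field(default_factory=list)


def normality_gate(x, y, alpha: float = 0.05) -> bool:
    """True iff Shapiro-Wilk p > alpha in both groups (n >= 3 each)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    for g in (x, y):
        if len(g) < 3:
            warnings.warn("normality gate: group with n < 3, Shapiro-Wilk undefined", stacklevel=2)
            return False
        if np.ptp(g) == 0:  # constant sample: shapiro errors; clearly non-normal fit
            return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for n > 5000
        px = stats.shapiro(x).pvalue
        py = stats.shapiro(y).pvalue
    return bool(px > alpha and py > alpha)


def _paired_values(table: TraitTable, trait: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-(elevation, replicate) means of each type, kept where both exist."""
    df = table.data[["plant_type", "elevation_m", "replicate", trait]].dropna()
    cell = df.groupby(["elevation_m", "replicate", "plant_type"])[trait].mean().unstack("plant_type")
    cell = cell.dropna()
    if cell.empty or "ephemeral" not in cell or "non_ephemeral" not in cell:
        return np.array([]), np.array([])
    return cell["ephemeral"].to_numpy(), cell["non_ephemeral"].to_numpy()


def compare_trait(
    trait: str,
    table: TraitTable,
    pairing: str = "elevation_replicate",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Compare one trait between the two plant types (gate -> paired t / MW)."""
    df = table.data[["plant_type", trait]].dropna()
    groups = {t: df.loc[df["plant_type"] == t, trait].to_numpy() for t in df["plant_type"].unique()}
    if set(groups) != {"ephemeral", "non_ephemeral"}:
        raise TraitnetError(f"both plant types required to compare trait {trait!r}")
    x, y = groups["ephemeral"], groups["non_ephemeral"]
    notes: list[str] = []

    means = {"ephemeral": float(np.mean(x)), "non_ephemeral": float(np.mean(y))}
    medians = {"ephemeral": float(np.median(x)), "non_ephemeral": float(np.median(y))}
    if means["ephemeral"] > means["non_ephemeral"]:
        direction = "ephemeral"
    elif means["ephemeral"] < means["non_ephemeral"]:
        direction = "non_ephemeral"
    else:
        direction = "tie"

    if normality_gate(x, y, alpha=alpha):
        if pairing == "unpaired":
            stat, p = stats.ttest_ind(x, y)
            chosen = "unpaired_t"
        else:
            a, b = _paired_values(table, trait)
            if len(a) >= 2:
                if np.ptp(a - b) == 0:
                    # constant paired differences: t undefined (sd = 0)
                    stat, p = (0.0, 1.0) if np.allclose(a, b) else (np.inf, 0.0)
                    notes.append("paired differences constant")
                else:
                    stat, p = stats.ttest_rel(a, b)
                chosen = "paired_t"
            else:
                notes.append("unmatched pairs under paired strategy; fell back to unpaired t")
                warnings.warn(notes[-1], stacklevel=2)
                stat, p = stats.ttest_ind(x, y)
                chosen = "unpaired_t"
    else:
        if np.ptp(np.concatenate([x, y])) == 0:
            stat, p = float(len(x) * len(y)) / 2.0, 1.0  # all values tied
        else:
            method = "exact" if (len(x) + len(y) <= 20 and _no_ties(x, y)) else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            stat, p = res.statistic, res.pvalue
        chosen = "mann_whitney"

    return ComparisonResult(trait, chosen, float(stat), float(p), means, medians, direction, notes)


def _no_ties(x: np.ndarray, y: np.ndarray) -> bool:
    combined = np.concatenate([x, y])
    return len(np.unique(combined)) == len(combined)


def compare_all(table: TraitTable, pairing: str = "elevation_replicate", alpha: float = 0.05) -> pd.DataFrame:
    """Comparison table over every trait, with a Benjamini-Hochberg column.

    The BH-adjusted p is reported for reference only; nothing downstream
    gates on it.
    """
    results = [compare_trait(t, table, pairing=pairing, alpha=alpha) for t in table.trait_codes]
    out = pd.DataFrame(
        {
            "trait": [r.trait for r in results],
            "test": [r.chosen_test for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p_value for r in results],
            "mean_ephemeral": [r.group_means["ephemeral"] for r in results],
            "mean_non_ephemeral": [r.group_means["non_ephemeral"] for r in results],
            "direction": [r.direction for r in results],
        }
    )
    out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each column to mean 0, sample SD 1 (ddof = 1).

    Zero-variance columns are dropped with a warning (they carry no
    information for correlation-based analyses).
    """
    sd = matrix.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping zero-variance trait(s): {', '.join(map(str, constant))}", stacklevel=2)
        matrix = matrix.drop(columns=constant)
        sd = sd.drop(constant)
    return (matrix - matrix.mean()) / sd


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # traits x components
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # fraction per component, sums to 1

    def summary(self, n: int = 5) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(min(n, len(self.variance_explained)))],
                "variance_explained": self.variance_explained[:n],
            }
        )


def pca(standardized: pd.DataFrame) -> PCAResult:
    """PCA by eigendecomposition of the correlation matrix.

    Components are ordered by decreasing variance explained; each column's
    sign is fixed so its largest-magnitude loading is positive.  With
    standardized input the correlation matrix equals the covariance matrix,
    so variance fractions sum to 1 over all components (trace identity).
    """
    if standardized.shape[0] < 2 or standardized.shape[1] < 2:
        raise TraitnetError("PCA needs at least 2 samples and 2 traits")
    Z = standardized.to_numpy(dtype=float)
    if np.isnan(Z).any():
        raise TraitnetError("PCA input contains missing values; impute or drop first")
    R = np.cov(Z, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)  # rank-deficiency -> exact zeros
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):  # sign convention
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comp_names = [f"PC{i + 1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=standardized.columns, columns=comp_names)
    scores = pd.DataFrame(Z @ eigvec, index=standardized.index, columns=comp_names)
    return PCAResult(loadings, scores, eigval / eigval.sum())
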