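"""Blomberg's K phylogenetic signal and its tip-shuffle permutation test.

K compares the observed ratio of phylogenetically uncorrected to corrected
trait variance with its expectation under Brownian motion (BM) on the given
tree.  K = 1 matches BM; K < 1 means less signal than BM, K > 1 more.
Significance comes from shuffling trait values across the tips: the p-value
is the (add-one corrected) fraction of shuffles whose K reaches the
observed K.

With C the phylogenetic covariance matrix and a-hat the GLS estimate of
the root state,

    MSE0 = (x - a)' (x - a) / (n - 1)
    MSE  = (x - a)' C^-1 (x - a) / (n - 1)
    K    = (MSE0 / MSE) / ([tr C - n / (1' C^-1 1)] / (n - 1))

On a star tree C is proportional to the identity and K = 1 identically for
any trait vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import TraitnetError, ValidationError
from .tree import Phylogeny

#: condition number above which C is treated as numerically singular
MAX_CONDITION = 1e12


@dataclass
class KResult:
    """K statistic with its permutation null."""

    trait: str
    K: float
    p_value: float | None
    n_permutations: int
    observed_ratio: float
    expected_ratio: float
    seed: int | None = None


def phylo_vcv(tree: Phylogeny, order: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance matrix of the tips (shared path lengths)."""
    return tree.vcv(order=order)


def _k_pieces(C: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Factorizations reused across permutations: C^-1 rows summed, etc."""
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise TraitnetError(
            f"phylogenetic covariance matrix is numerically singular (condition {cond:.3g})"
        )
    n = C.shape[0]
    Cinv = np.linalg.solve(C, np.eye(n))
    Cinv = (Cinv + Cinv.T) / 2.0
    ones = np.ones(n)
    denom = ones @ Cinv @ ones
    expected = (np.trace(C) - n / denom) / (n - 1)
    return Cinv, ones, expected


def _k_from_vector(x: np.ndarray, C: np.ndarray, Cinv: np.ndarray, ones: np.ndarray,
                   expected: float) -> tuple[float, float]:
    n = len(x)
    a_hat = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
    d = x - a_hat
    mse0 = (d @ d) / (n - 1)
    mse = (d @ Cinv @ d) / (n - 1)
    observed = mse0 / mse
    return observed / expected, observed


def blomberg_k(tree: Phylogeny, x: Mapping[str, float], trait: str = "trait") -> KResult:
    """Blomberg's K for one trait (no permutation test; p_value is None)."""
    labels = list(tree.tip_labels)
    missing = set(labels) - set(x)
    if missing:
        raise ValidationError(f"trait values missing for tips: {sorted(missing)}")
    vec = np.asarray([float(x[lab]) for lab in labels])
    if np.var(vec) == 0:
        raise TraitnetError("zero trait variance: K undefined")
    _, C = tree.vcv(order=labels)
    Cinv, ones, expected = _k_pieces(C)
    k, observed = _k_from_vector(vec, C, Cinv, ones, expected)
    return KResult(trait, k, None, 0, observed, expected)


def permutation_test_k(
    tree: Phylogeny,
    x: Mapping[str, float],
    n_perm: int = 999,
    seed: int | None = None,
    trait: str = "trait",
) -> KResult:
    """K with a tip-shuffle permutation null.

    Trait values are shuffled across tips ``n_perm`` times; the p-value is
    ``(1 + #{K_null >= K_obs}) / (n_perm + 1)`` so its resolution is
    1/(n_perm + 1) and it is never zero.
    """
    if n_perm < 1:
        raise TraitnetError("n_perm must be >= 1")
    labels = list(tree.tip_labels)
    missing = set(labels) - set(x)
    if missing:
        raise ValidationError(f"trait values missing for tips: {sorted(missing)}")
    vec = np.asarray([float(x[lab]) for lab in labels])
    if np.var(vec) == 0:
        raise TraitnetError("zero trait variance: K undefined")
    _, C = tree.vcv(order=labels)
    Cinv, ones, expected = _k_pieces(C)
    k_obs, observed = _k_from_vector(vec, C, Cinv, ones, expected)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(vec)
        k_null, _ = _k_from_vector(perm, C, Cinv, ones, expected)
        if k_null >= k_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return KResult(trait, k_obs, p, n_perm, observed, expected, seed)


def k_table(tree: Phylogeny, species_means, n_perm: int = 999, seed: int | None = None):
    """Permutation K for every trait column of a species-mean table.

    ``species_means`` is a DataFrame indexed by species (one row per tip).
    Returns a DataFrame with columns trait, K, p, n_perm, seed.  Per-trait
    seeds are derived deterministically from ``seed``.
    """
    import pandas as pd

    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(species_means.columns))]
    for trait, s in zip(species_means.columns, child_seeds):
        x = species_means[trait].to_dict()
        res = permutation_test_k(tree, x, n_perm=n_perm, seed=s, trait=trait)
        rows.append(
            {"trait": trait, "K": res.K, "p": res.p_value, "n_perm": res.n_permutations, "seed": s}
        )
    return pd.DataFrame(rows)
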