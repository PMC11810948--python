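"""Synthetic trait datasets with planted, recoverable ground truth.

The generator emulates the structure of an understory trait survey: eight
herbaceous species (half spring ephemerals, half non-ephemerals) sampled in
three elevation bands with a few pooled replicates each, measured for the
26-trait catalog.  Every effect the downstream analyses estimate is planted
explicitly and echoed back as ground truth:

* phylogenetic signal — each trait's species-level mean blends a Brownian
  motion draw on the tree (weight ``sqrt(signal_lambda)``) with iid noise
  (weight ``sqrt(1 - signal_lambda)``);
* group differences — additive mean offsets for ephemeral species, in
  units of the replicate noise SD;
* elevation trends — linear slopes per kilometre of elevation (centered),
  with optional type x elevation interaction slopes;
* trait correlation structure — traits in the same latent module share a
  per-sample factor with loading rho, giving pairwise correlation rho**2
  within the module and zero between modules.

The species-level blend is scaled by ``species_sd`` (standardized units;
default 1).  Setting it to 0 removes between-species heterogeneity
entirely, which is the null condition for type-I-error and
module-recovery experiments: with only 8 species, nonzero species-level
random means induce realized between-trait correlations of order
1/sqrt(8) that are not part of any planted effect, and cluster samples
within species, which invalidates nominal test levels.

Elevation enters the linear predictors in kilometres so planted slope
magnitudes stay O(1).  A fixed seed makes every output byte-identical.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .catalog import DEFAULT_CATALOG, TraitDefinition, catalog_codes
from .data import TraitTable, ENV_COLUMNS
from .errors import ConfigError, TraitnetError
from .tree import Phylogeny

#: Default per-band environments: soil physicochemistry and climate of the
#: three elevation bands of the study design (means per band).
DEFAULT_ENVIRONMENTS: dict[float, dict[str, float]] = {
    600.0: {
        "soil_pH": 6.187, "soil_C": 6.84, "soil_P": 0.100, "soil_N": 1.073,
        "soil_EC": 176.0, "MAP": 69.23, "MASR": 13715.83, "MAT": 3.82,
    },
    800.0: {
        "soil_pH": 5.77, "soil_C": 8.877, "soil_P": 0.080, "soil_N": 0.803,
        "soil_EC": 132.0, "MAP": 71.593, "MASR": 13559.75, "MAT": 2.98,
    },
    1000.0: {
        "soil_pH": 5.617, "soil_C": 11.243, "soil_P": 0.083, "soil_N": 0.953,
        "soil_EC": 129.333, "MAP": 72.6, "MASR": 13559.113, "MAT": 2.507,
    },
}


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic dataset generator."""

    n_species: int = 8
    n_ephemeral: int = 4
    elevations_m: Sequence[float] = (600.0, 800.0, 1000.0)
    n_replicates: int = 3
    tree: Phylogeny | None = None
    birth_rate: float = 1.0
    signal_lambda: float | Mapping[str, float] = 0.0
    module_spec: Mapping[str, Sequence[str]] | None = None
    module_loading: float | Mapping[str, float] = 0.0
    type_offsets: Mapping[str, float] = field(default_factory=dict)
    elevation_slopes: Mapping[str, float] = field(default_factory=dict)
    interaction_slopes: Mapping[str, float] = field(default_factory=dict)
    species_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    traits: Sequence[str] | None = None
    catalog: Sequence[TraitDefinition] = DEFAULT_CATALOG

    def trait_codes(self) -> list[str]:
        codes = list(self.traits) if self.traits is not None else catalog_codes(self.catalog)
        return codes

    def lambda_for(self, code: str) -> float:
        if isinstance(self.signal_lambda, Mapping):
            lam = float(self.signal_lambda.get(code, 0.0))
        else:
            lam = float(self.signal_lambda)
        if not 0.0 <= lam <= 1.0:
            raise ConfigError(f"signal_lambda for {code!r} must lie in [0, 1], got {lam}")
        return lam

    def loading_for(self, module: str) -> float:
        if isinstance(self.module_loading, Mapping):
            rho = float(self.module_loading.get(module, 0.0))
        else:
            rho = float(self.module_loading)
        if not 0.0 <= rho < 1.0:
            raise ConfigError(f"module loading for {module!r} must lie in [0, 1), got {rho}")
        return rho

    def validate(self) -> None:
        codes = set(self.trait_codes())
        if self.n_ephemeral > self.n_species:
            raise ConfigError("n_ephemeral cannot exceed n_species")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.species_sd < 0:
            raise ConfigError("species_sd must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.module_spec is not None:
            seen: set[str] = set()
            for module, members in self.module_spec.items():
                for code in members:
                    if code not in codes:
                        raise ConfigError(f"module {module!r} lists unknown trait {code!r}")
                    if code in seen:
                        raise ConfigError(f"trait {code!r} appears in more than one module")
                    seen.add(code)
                self.loading_for(module)
        for mapping in (self.type_offsets, self.elevation_slopes, self.interaction_slopes):
            for code in mapping:
                if code not in codes:
                    raise ConfigError(f"unknown trait {code!r} in effect specification")


def simulate_bm(
    tree: Phylogeny, sigma2: float, root_value: float = 0.0, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Simulate Brownian-motion trait evolution along the tree.

    Each branch contributes an independent Normal(0, sigma2 * length)
    increment; tip values therefore have covariance sigma2 * C with C the
    shared-path-length matrix.
    """
    if sigma2 < 0:
        raise TraitnetError("sigma2 must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    dtree = tree.dendropy_tree
    values: dict = {dtree.seed_node: float(root_value)}
    out: dict[str, float] = {}
    for node in dtree.preorder_node_iter():
        if node is not dtree.seed_node:
            t = node.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt(sigma2 * t)) if sigma2 > 0 and t > 0 else 0.0
            values[node] = values[node.parent_node] + step
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return out


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int | None = None,
                  prefix: str = "sp") -> Phylogeny:
    """A pure-birth (Yule) tree with depth rescaled to 1."""
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace([f"{prefix}{i + 1:02d}" for i in range(n_species)])
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        taxon_namespace=taxa,
        rng=random.Random(seed),
    )
    # the process stops at the n-th birth, leaving the newest tips with
    # zero-length terminal edges; extend every terminal edge equally (the
    # tree stays ultrametric) so the tip covariance matrix is nonsingular
    mean_edge = np.mean([e.length for e in tree.preorder_edge_iter() if e.length])
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + 0.5 * float(mean_edge)
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return Phylogeny(tree)


def default_environments(elevations_m: Sequence[float]) -> pd.DataFrame:
    """Environment records per band, interpolated from the default table."""
    bands = np.array(sorted(DEFAULT_ENVIRONMENTS))
    rows = []
    for elev in elevations_m:
        rec = {"elevation_m": float(elev)}
        for var in ENV_COLUMNS[1:]:
            known = np.array([DEFAULT_ENVIRONMENTS[b][var] for b in bands])
            rec[var] = float(np.interp(elev, bands, known))
        rows.append(rec)
    return pd.DataFrame(rows)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[TraitTable, Phylogeny, pd.DataFrame, dict]:
    """Generate (trait table, tree, environment table, ground truth).

    Species-level means follow the signal/offset/slope model in the module
    docstring; replicate values add module-structured noise with SD
    ``noise_sd``.  The ground-truth record echoes every planted parameter.
    """
    config.validate()
    codes = config.trait_codes()
    master = np.random.SeedSequence(config.seed)
    s_tree, s_bm, s_white, s_noise = (int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(4))

    tree = config.tree or simulate_tree(config.n_species, config.birth_rate, seed=s_tree)
    if tree.n_tips != config.n_species:
        raise ConfigError(
            f"tree has {tree.n_tips} tips but config declares {config.n_species} species"
        )
    species = list(tree.tip_labels)
    ephemeral = set(species[: config.n_ephemeral])

    elev_km = np.asarray(config.elevations_m, dtype=float) / 1000.0
    center = elev_km.mean()

    # species-level base values: BM / white-noise blend, standardized scale
    rng_bm = np.random.default_rng(s_bm)
    rng_white = np.random.default_rng(s_white)
    base: dict[str, dict[str, float]] = {}
    for code in codes:
        lam = config.lambda_for(code)
        bm = simulate_bm(tree, sigma2=1.0, rng=rng_bm)
        bm_vec = np.array([bm[s] for s in species])
        sd = bm_vec.std(ddof=1)
        bm_z = (bm_vec - bm_vec.mean()) / sd if sd > 0 else np.zeros_like(bm_vec)
        white = rng_white.standard_normal(len(species))
        blend = config.species_sd * (np.sqrt(lam) * bm_z + np.sqrt(1.0 - lam) * white)
        base[code] = dict(zip(species, blend))

    module_of: dict[str, str] = {}
    if config.module_spec:
        for module, members in config.module_spec.items():
            for code in members:
                module_of[code] = module

    rng_noise = np.random.default_rng(s_noise)
    rows = []
    for sp in species:
        is_eph = sp in ephemeral
        for band, ekm in zip(config.elevations_m, elev_km):
            for rep in range(1, config.n_replicates + 1):
                factors = {m: rng_noise.standard_normal() for m in (config.module_spec or {})}
                row = {
                    "species": sp,
                    "plant_type": "ephemeral" if is_eph else "non_ephemeral",
                    "elevation_m": float(band),
                    "replicate": f"r{rep}",
                }
                for code in codes:
                    mean = base[code][sp]
                    mean += config.type_offsets.get(code, 0.0) * is_eph
                    mean += config.elevation_slopes.get(code, 0.0) * (ekm - center)
                    mean += config.interaction_slopes.get(code, 0.0) * (ekm - center) * is_eph
                    eps = rng_noise.standard_normal()
                    if code in module_of:
                        rho = config.loading_for(module_of[code])
                        noise = rho * factors[module_of[code]] + np.sqrt(1.0 - rho**2) * eps
                    else:
                        noise = eps
                    row[code] = mean + config.noise_sd * noise
                rows.append(row)

    table = TraitTable(pd.DataFrame(rows), config.catalog)
    env = default_environments(config.elevations_m)
    truth = {
        "species": species,
        "ephemeral_species": sorted(ephemeral),
        "signal_lambda": {c: config.lambda_for(c) for c in codes},
        "module_spec": {m: list(v) for m, v in (config.module_spec or {}).items()},
        "module_loading": {m: config.loading_for(m) for m in (config.module_spec or {})},
        "type_offsets": dict(config.type_offsets),
        "elevation_slopes": dict(config.elevation_slopes),
        "interaction_slopes": dict(config.interaction_slopes),
        "species_sd": config.species_sd,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
        "elevation_center_km": float(center),
        "tree_newick": tree.to_newick(),
    }
    return table, tree, env, truth


def generate_survey(
    n_plots: int,
    n_quadrats: int,
    abundance_weights: Mapping[str, float],
    seed: int | None = None,
    individuals_per_quadrat: int = 30,
    cover_per_individual: float = 0.02,
):
    """Simulate a quadrat survey: multinomial counts, count-proportional cover.

    Per quadrat, ``individuals_per_quadrat`` individuals are allocated to
    species by a multinomial draw on the normalized abundance weights;
    cover is proportional to counts with lognormal noise.
    """
    from .survey import QuadratSurvey

    if n_quadrats < 1:
        raise TraitnetError("n_quadrats must be >= 1")
    if n_plots < 1:
        raise TraitnetError("n_plots must be >= 1")
    species = sorted(abundance_weights)
    w = np.array([abundance_weights[s] for s in species], dtype=float)
    if (w < 0).any() or w.sum() == 0:
        raise TraitnetError("abundance weights must be nonnegative and not all zero")
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    records = []
    for plot in range(1, n_plots + 1):
        for quad in range(1, n_quadrats + 1):
            counts = rng.multinomial(individuals_per_quadrat, p)
            for sp, c in zip(species, counts):
                if c == 0:
                    continue
                cover = c * cover_per_individual * rng.lognormal(0.0, 0.25)
                records.append(
                    {
                        "plot": f"p{plot}",
                        "quadrat": f"q{quad}",
                        "species": sp,
                        "count": int(c),
                        "cover": float(min(cover, 1.0)),
                    }
                )
    return QuadratSurvey(pd.DataFrame(records))
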