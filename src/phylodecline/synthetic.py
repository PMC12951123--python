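"""Synthetic inputs with the statistical structure the analysis assumes.

Generates a birth-death phylogeny, equal-area gridded climate layers with a
land mask and a polar exclusion band, contiguous per-species ranges, body size
evolved by Brownian motion on the tree, and binary decline/stable trend labels
from a probit liability-threshold model with a phylogenetic random effect:

    liability_i = x_i' beta + u_i + e_i,   u ~ N(0, sigma2_p * A),  e ~ N(0, 1)
    decline_i   = 1{liability_i > 0}

where A is the correlation-scaled phylogenetic covariance and x_i is built by
exactly the same summary code (geo, prevalence) the analysis pipeline uses.
Every generated dataset carries a TruthRecord sufficient to regenerate it
bit-identically and to score parameter recovery.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.ndimage import gaussian_filter

from . import geo, prevalence as prev_mod
from .trees import PhyloTree, vcv

EARTH_AREA_KM2 = 510_072_000.0

#: default generating coefficients (intercept + the 8 canonical predictors,
#: on the centered/scaled design): decline driven mainly by small range size,
#: secondarily by warm temperature, low seasonality and low latitude.
DEFAULT_BETA = (0.5, 0.0, -0.8, -0.4, 0.5, -0.5, 0.2, 0.0, 0.0)
DEFAULT_SIGMA2_P = 1.0


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-component sub-seeds (kept below 2**31)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


def gen_tree(n_tips: int, birth: float = 1.0, death: float = 0.3,
             seed: int = 0, max_retries: int = 20) -> PhyloTree:
    """Birth-death tree conditioned on n extant tips, rescaled to unit height.

    Tips are relabeled s0001..sNNNN in tree traversal order.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if not birth > death >= 0:
        raise ValueError("need birth > death >= 0")
    rng = _random.Random(seed)
    dtree = None
    for _ in range(max_retries):
        try:
            dtree = treesim.birth_death_tree(
                birth_rate=birth,
                death_rate=death,
                num_extant_tips=n_tips,
                rng=rng,
                repeat_until_success=False,
            )
            break
        except Exception:
            continue
    if dtree is None:
        raise RuntimeError(
            f"birth-death simulation failed {max_retries} times"
        )
    width = max(4, len(str(n_tips)))
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"s{i:0{width}d}"
    dtree.seed_node.edge.length = None  # drop the stem edge
    tree = PhyloTree(dtree)
    return tree.rescale_height(1.0)


def brownian_trait(tree: PhyloTree, sigma: float, root_value: float,
                   seed: int) -> pd.Series:
    """Trait values at the tips under Brownian motion with rate sigma^2."""
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree._tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_value
        else:
            bl = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + rng.normal(
                0.0, sigma * np.sqrt(bl)
            )
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out, name="trait")


def assign_families(tree: PhyloTree, max_size: int) -> pd.Series:
    """Label clades of at most ``max_size`` tips as synthetic families."""
    labels: dict[str, str] = {}
    counter = [0]

    def walk(node):
        leaves = node.leaf_nodes()
        if node.is_leaf() or len(leaves) <= max_size:
            counter[0] += 1
            fam = f"F{counter[0]:03d}"
            for leaf in leaves:
                labels[leaf.taxon.label] = fam
        else:
            for child in node.child_nodes():
                walk(child)

    walk(tree._tree.seed_node)
    return pd.Series(labels, name="family")


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------


@dataclass
class ClimateWorld:
    """Equal-area gridded climate layers plus a land mask.

    Rows are equally spaced in sin(latitude) (cylindrical equal-area), row 0
    northernmost; ``cell_area_km2`` is constant by construction. Masked cells
    (ocean or the polar exclusion band) are NaN in every layer.
    """

    cell_area_km2: float
    lat_centers: np.ndarray             # degrees, per row
    layers: dict[str, np.ndarray]       # amt (degC), tar (degC), cmi
    land_mask: np.ndarray               # bool

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.land_mask.shape

    def land_cells(self) -> list[tuple[int, int]]:
        rows, cols = np.nonzero(self.land_mask)
        return list(zip(rows.tolist(), cols.tolist()))


def equal_area_latitudes(nrows: int) -> np.ndarray:
    """Cell-center latitudes for rows equally spaced in sin(latitude)."""
    edges = np.linspace(1.0, -1.0, nrows + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return np.degrees(np.arcsin(centers))


def gen_climate(grid_shape: tuple[int, int], seed: int = 0,
                land_fraction: float = 0.4,
                polar_mask_lat: float = -60.0) -> ClimateWorld:
    """Synthetic AMT/TAR/CMI layers on an equal-area grid.

    Temperature decreases from equator to pole, seasonality (TAR) increases
    with latitude, and moisture is spatially autocorrelated noise; all values
    stay inside the fixed prevalence-binning supports. Land is a smoothed
    random field thresholded to ``land_fraction``; rows south of
    ``polar_mask_lat`` are masked out entirely (the Antarctica analogue).
    """
    nrows, ncols = grid_shape
    if nrows < 4 or ncols < 4:
        raise ValueError("grid must be at least 4x4")
    rng = np.random.default_rng(seed)
    lats = equal_area_latitudes(nrows)
    lat_rad = np.radians(lats)[:, None]

    def smooth(sigma):
        return gaussian_filter(rng.standard_normal((nrows, ncols)),
                               sigma=sigma, mode="wrap")

    amt = -21.0 + 48.0 * np.cos(lat_rad) + 4.0 * smooth(2.0)
    amt = np.clip(amt, *prev_mod.SUPPORTS["amt"])
    tar = 4.0 + 38.0 * np.abs(np.sin(lat_rad)) + 3.0 * smooth(2.0)
    tar = np.clip(tar, 0.5, 65.0)
    cmi_field = smooth(3.0)
    sd = cmi_field.std()
    cmi = 40.0 + 140.0 * (cmi_field / (sd if sd > 0 else 1.0))
    cmi = np.clip(cmi, *prev_mod.SUPPORTS["cmi"])

    land_field = smooth(3.0) + 0.15 * rng.standard_normal((nrows, ncols))
    thresh = np.quantile(land_field, 1.0 - land_fraction)
    land = land_field > thresh
    land &= (lats >= polar_mask_lat)[:, None]
    if not land.any():
        land = land_field >= np.max(land_field)  # keep at least one cell

    layers = {"amt": amt, "tar": tar, "cmi": cmi}
    for name, layer in layers.items():
        layer[~land] = np.nan
    return ClimateWorld(
        cell_area_km2=EARTH_AREA_KM2 / (nrows * ncols),
        lat_centers=lats,
        layers=layers,
        land_mask=land,
    )


# ---------------------------------------------------------------------------
# Ranges
# ---------------------------------------------------------------------------


@dataclass
class SpeciesRange:
    """A species' occupied grid cells, or a sub-cell (unresolvable) range.

    ``cells`` is empty when the range is below grid resolution; ``area_km2``
    is then the polygon-analogue area (smaller than one cell), and ``anchor``
    the cell containing it (used only as latent truth by the generator).
    """

    cells: list[tuple[int, int]]
    unresolvable: bool
    area_km2: float
    anchor: tuple[int, int]


def _grow_patch(world: ClimateWorld, target: int,
                rng: np.random.Generator) -> list[tuple[int, int]]:
    """Grow a contiguous 4-neighborhood patch of land cells."""
    land = world.land_cells()
    start = land[int(rng.integers(len(land)))]
    nrows, ncols = world.grid_shape
    cells = {start}
    frontier: list[tuple[int, int]] = []

    def push_neighbors(cell):
        r, c = cell
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if (
                0 <= rr < nrows
                and 0 <= cc < ncols
                and world.land_mask[rr, cc]
                and (rr, cc) not in cells
                and (rr, cc) not in frontier
            ):
                frontier.append((rr, cc))

    push_neighbors(start)
    while len(cells) < target and frontier:
        frontier.sort()
        nxt = frontier.pop(int(rng.integers(len(frontier))))
        cells.add(nxt)
        push_neighbors(nxt)
    return sorted(cells)


def gen_ranges(world: ClimateWorld, tree: PhyloTree,
               size_dist: tuple[float, float] = (2.0, 1.2),
               subcell_fraction: float = 0.05,
               seed: int = 0) -> dict[str, SpeciesRange]:
    """Contiguous lognormal-sized ranges grown from random land seed cells.

    ``size_dist`` is (mu, sigma) of the lognormal cell-count distribution. A
    fraction ``subcell_fraction`` of species receive ranges smaller than one
    cell: no grid cells, a polygon-analogue area below the cell area, and an
    anchor cell carrying their latent location.
    """
    mu, sigma = size_dist
    if sigma <= 0:
        raise ValueError("size_dist sigma must be positive")
    species = tree.tips
    n = len(species)
    land = world.land_cells()
    if len(land) < 4:
        raise ValueError("land mask too small to place ranges")
    rng = np.random.default_rng(seed)
    n_sub = int(round(subcell_fraction * n))
    sub_idx = set(
        rng.choice(n, size=n_sub, replace=False).tolist()
    ) if n_sub else set()
    max_cells = max(1, len(land) // 3)
    out: dict[str, SpeciesRange] = {}
    for i, sp in enumerate(species):
        if i in sub_idx:
            anchor = land[int(rng.integers(len(land)))]
            area = float(rng.uniform(0.05, 0.8) * world.cell_area_km2)
            out[sp] = SpeciesRange([], True, area, anchor)
            continue
        target = int(np.clip(round(rng.lognormal(mu, sigma)), 1, max_cells))
        cells = _grow_patch(world, target, rng)
        out[sp] = SpeciesRange(
            cells, False, len(cells) * world.cell_area_km2, cells[0]
        )
    return out


# ---------------------------------------------------------------------------
# Traits, trends, truth
# ---------------------------------------------------------------------------


@dataclass
class TruthRecord:
    """Ground truth and generator settings for one synthetic dataset."""

    beta_true: list[float]
    sigma2_p_true: float
    seed: int
    link: str
    missing_fractions: dict[str, float]
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        return cls(**json.loads(text))


def _latent_predictor_table(tree, world, ranges, bm_sigma, bm_root, bm_seed):
    """Raw (untransformed) predictor values for every species, no missingness.

    Sub-cell species use their anchor cell as latent climate/location truth.
    """
    log_bs = brownian_trait(tree, bm_sigma, bm_root, bm_seed)
    amt_prof = prev_mod.climate_prevalence(
        world.layers["amt"], world.land_mask, "amt")
    cmi_prof = prev_mod.climate_prevalence(
        world.layers["cmi"], world.land_mask, "cmi")
    rows = []
    for sp in tree.tips:
        rg = ranges[sp]
        cells = rg.cells if rg.cells else [rg.anchor]
        amt, tar, cmi = geo.climate_means(cells, world)
        rows.append(
            {
                "species": sp,
                "body_size_mm": float(np.exp(log_bs[sp])),
                "range_size_km2": rg.area_km2,
                "abs_lat_mid": geo.lat_midpoint(cells, world),
                "amt_mean": amt,
                "tar_mean": tar,
                "cmi_mean": cmi,
                "prev_amt": prev_mod.species_prevalence(amt, amt_prof),
                "prev_cmi": prev_mod.species_prevalence(cmi, cmi_prof),
                "range_unresolvable": rg.unresolvable,
                "n_cells": len(rg.cells),
            }
        )
    return pd.DataFrame(rows).set_index("species"), (amt_prof, cmi_prof)


def gen_traits_and_trends(
    tree: PhyloTree,
    world: ClimateWorld,
    ranges: dict[str, SpeciesRange],
    beta_true=DEFAULT_BETA,
    sigma2_p_true: float = DEFAULT_SIGMA2_P,
    seed: int = 0,
    frac_increasing: float = 0.005,
    frac_unknown: float = 0.25,
    missing_fractions: dict[str, float] | None = None,
    bm_sigma: float = 0.6,
    bm_root: float = 3.9,
    dd_fraction: float = 0.10,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate traits, trends and threat categories under the liability model.

    Body size is Brownian motion on the tree (exponentiated to mm); the binary
    decline label comes from the probit liability with phylogenetic random
    effect; a small fraction of labels is recoded increasing, a larger one
    unknown; missingness masks hide body size, extra moisture values, and the
    climate summaries of sub-cell species (their range is below resolution).
    """
    beta_true = np.asarray(beta_true, dtype=float)
    if beta_true.shape != (9,):
        raise ValueError("beta_true must have length 9 (intercept + 8)")
    missing = {"body_size": 0.14, "cmi": 0.002}
    if missing_fractions:
        missing.update(missing_fractions)
    seeds = _child_seeds(seed, 4)
    latent, _profiles = _latent_predictor_table(
        tree, world, ranges, bm_sigma, bm_root, seeds[0]
    )

    pm = geo.build_predictors(latent)
    x = np.column_stack(
        [np.ones(len(latent))] + [pm.data[c].to_numpy() for c in geo.PREDICTOR_ORDER]
    )

    rng = np.random.default_rng(seeds[1])
    a = vcv(tree).correlation()
    amat = a.matrix[np.ix_(
        [a.labels.index(s) for s in latent.index],
        [a.labels.index(s) for s in latent.index],
    )]
    try:
        chol = np.linalg.cholesky(amat)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular phylogenetic correlation; jittering diagonal")
        chol = np.linalg.cholesky(amat + 1e-8 * np.eye(len(amat)))
    u = np.sqrt(sigma2_p_true) * (chol @ rng.standard_normal(len(latent)))
    e = rng.standard_normal(len(latent))
    liability = x @ beta_true + u + e
    decline = liability > 0

    n = len(latent)
    table = latent.copy()
    table["trend"] = np.where(decline, "decreasing", "stable")
    table["liability_true"] = liability
    table["u_true"] = u

    # inject increasing / unknown labels
    rng_lab = np.random.default_rng(seeds[2])
    order = rng_lab.permutation(n)
    n_inc = int(round(frac_increasing * n))
    n_unk = int(round(frac_unknown * n))
    inc_idx = order[:n_inc]
    unk_idx = order[n_inc:n_inc + n_unk]
    trend = table["trend"].to_numpy(dtype=object)
    trend[inc_idx] = "increasing"
    trend[unk_idx] = "unknown"
    table["trend"] = trend

    # threat categories: ordinal in the liability plus noise, with a DD slice
    score = liability + 2.0 * rng_lab.standard_normal(n)
    qcuts = np.quantile(score, [0.50, 0.70, 0.85, 0.95])
    cat = np.select(
        [score <= qcuts[0], score <= qcuts[1], score <= qcuts[2],
         score <= qcuts[3]],
        ["LC", "NT", "VU", "EN"],
        default="CR",
    ).astype(object)
    dd = rng_lab.random(n) < dd_fraction
    cat[dd] = "DD"
    table["threat_category"] = cat

    table["family"] = assign_families(tree, max(5, n // 15)).reindex(table.index)

    # missingness
    rng_miss = np.random.default_rng(seeds[3])
    bs_mask = rng_miss.random(n) < missing["body_size"]
    table.loc[bs_mask, "body_size_mm"] = np.nan
    cmi_mask = rng_miss.random(n) < missing["cmi"]
    table.loc[cmi_mask, ["cmi_mean", "prev_cmi"]] = np.nan
    sub = table["range_unresolvable"].to_numpy(dtype=bool)
    table.loc[sub, ["amt_mean", "tar_mean", "prev_amt"]] = np.nan

    truth = TruthRecord(
        beta_true=[float(b) for b in beta_true],
        sigma2_p_true=float(sigma2_p_true),
        seed=int(seed),
        link="probit",
        missing_fractions={k: float(v) for k, v in missing.items()},
        config={
            "frac_increasing": frac_increasing,
            "frac_unknown": frac_unknown,
            "bm_sigma": bm_sigma,
            "bm_root": bm_root,
            "dd_fraction": dd_fraction,
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------


@dataclass
class WorldConfig:
    """Parameters of one synthetic study; defaults define the test conditions."""

    n_tips: int = 200
    grid_shape: tuple[int, int] = (40, 40)
    birth: float = 1.0
    death: float = 0.3
    land_fraction: float = 0.4
    polar_mask_lat: float = -60.0
    range_size_dist: tuple[float, float] = (2.0, 1.2)
    subcell_fraction: float = 0.05
    beta_true: tuple = DEFAULT_BETA
    sigma2_p_true: float = DEFAULT_SIGMA2_P
    frac_increasing: float = 0.005
    frac_unknown: float = 0.25
    missing_fractions: dict = field(
        default_factory=lambda: {"body_size": 0.14, "cmi": 0.002}
    )
    seed: int = 0


@dataclass
class SyntheticDataset:
    tree: PhyloTree
    world: ClimateWorld
    ranges: dict[str, SpeciesRange]
    table: pd.DataFrame
    truth: TruthRecord
    config: WorldConfig


def generate_dataset(config: WorldConfig) -> SyntheticDataset:
    """Generate tree, climate, ranges, traits and trends from one master seed.

    Each component consumes its own derived sub-seed, so regenerating from the
    recorded configuration reproduces every table bit-identically.
    """
    s_tree, s_clim, s_rng, s_traits = _child_seeds(config.seed, 4)
    tree = gen_tree(config.n_tips, config.birth, config.death, seed=s_tree)
    world = gen_climate(
        config.grid_shape, seed=s_clim,
        land_fraction=config.land_fraction,
        polar_mask_lat=config.polar_mask_lat,
    )
    ranges = gen_ranges(
        world, tree, size_dist=config.range_size_dist,
        subcell_fraction=config.subcell_fraction, seed=s_rng,
    )
    table, truth = gen_traits_and_trends(
        tree, world, ranges,
        beta_true=config.beta_true,
        sigma2_p_true=config.sigma2_p_true,
        seed=s_traits,
        frac_increasing=config.frac_increasing,
        frac_unknown=config.frac_unknown,
        missing_fractions=config.missing_fractions,
    )
    truth.seed = config.seed
    truth.config.update(
        {
            "n_tips": config.n_tips,
            "grid_shape": list(config.grid_shape),
            "birth": config.birth,
            "death": config.death,
            "land_fraction": config.land_fraction,
            "polar_mask_lat": config.polar_mask_lat,
            "range_size_dist": list(config.range_size_dist),
            "subcell_fraction": config.subcell_fraction,
        }
    )
    return SyntheticDataset(tree, world, ranges, table, truth, config)


def regenerate(truth: TruthRecord) -> SyntheticDataset:
    """Rebuild the full dataset recorded in a TruthRecord."""
    cfg = truth.config
    config = WorldConfig(
        n_tips=cfg["n_tips"],
        grid_shape=tuple(cfg["grid_shape"]),
        birth=cfg["birth"],
        death=cfg["death"],
        land_fraction=cfg["land_fraction"],
        polar_mask_lat=cfg["polar_mask_lat"],
        range_size_dist=tuple(cfg["range_size_dist"]),
        subcell_fraction=cfg["subcell_fraction"],
        beta_true=tuple(truth.beta_true),
        sigma2_p_true=truth.sigma2_p_true,
        frac_increasing=cfg["frac_increasing"],
        frac_unknown=cfg["frac_unknown"],
        missing_fractions=truth.missing_fractions,
        seed=truth.seed,
    )
    return generate_dataset(config)
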