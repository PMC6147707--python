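"""Synthetic forest-inventory data with known ground truth.

Emulates a national-inventory-like dataset: circular sample plots at the
intersections of a 1-km grid carrying a spatially autocorrelated canopy-cover
percentage, per-species stem counts that are Poisson given cover with
species-specific parameters (M_j, C_j), and a dated pure-birth phylogeny on
which the response parameter C_j descends from a Brownian-motion trait — so
every downstream stage (landscape averaging, occurrence modelling, signal
estimation) has a parameter-recovery test against the generating values.

Sparsity is created by structural-zero thinning: each species is forced
absent from a random subset of plots until its occupied fraction matches the
target occupancy, mimicking range limits and habitat filters that the
occurrence model itself ignores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from ._poisson import RATE_FLOOR, check_link
from .phylosignal import Phylogeny, vcv_matrix

logger = logging.getLogger(__name__)

# index of the per-operation RNG stream within the master seed
_STREAM_COVER, _STREAM_TREE, _STREAM_COUNTS = 0, 1, 2


@dataclass
class SyntheticConfig:
    """Generation settings; identical config + seed gives identical output.

    Defaults describe a mid-size inventory: a 60 x 60 km lattice, cover
    autocorrelated over ~3 km, 40 species occupying ~10% of plots each, with
    baseline rates M_j in [1, 3] stems/plot and cover slopes C_j spanning
    [-0.02, 0.02] per % cover (|C| * 100% cover comparable to M, i.e. strong
    but realistic responses of both signs).
    """

    grid_nx: int = 60
    grid_ny: int = 60
    cover_smoothing_scale: float = 3.0  # km, correlation length of cover
    n_species: int = 40
    tree_birth_rate: float = 0.05  # speciations per lineage per Myr
    bm_sigma2: float = 1.0  # Brownian rate of the response trait per Myr
    m_range: tuple[float, float] = (1.0, 3.0)
    c_range: tuple[float, float] = (-0.02, 0.02)
    occupancy: float = 0.10  # target fraction of plots occupied per species
    link: str = "identity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx < 1 or self.grid_ny < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in (0, 1]")
        if self.tree_birth_rate <= 0:
            raise ValueError("tree_birth_rate must be > 0")
        if self.bm_sigma2 < 0:
            raise ValueError("bm_sigma2 must be >= 0")
        if self.cover_smoothing_scale < 0:
            raise ValueError("cover_smoothing_scale must be >= 0")
        if self.m_range[0] > self.m_range[1] or self.c_range[0] > self.c_range[1]:
            raise ValueError("parameter ranges must be (low, high)")
        check_link(self.link)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Generating parameters: one row per species, plus the tree that made them."""

    params: pd.DataFrame = field(repr=False)  # species, M, C, trait, clade
    tree: Phylogeny = field(repr=False)

    @property
    def species(self) -> list[str]:
        return list(self.params["species"])

    def __post_init__(self) -> None:
        if set(self.species) != set(self.tree.tip_labels):
            raise ValueError("ground-truth species do not match tree tips")


def simulate_cover_field(config: SyntheticConfig) -> pd.DataFrame:
    """Spatially autocorrelated canopy cover sampled at grid intersections.

    Smoothed Gaussian white noise (periodic boundaries, sigma =
    ``cover_smoothing_scale`` in km) mapped through the normal CDF onto
    [0, 100], so the cover histogram is roughly uniform while neighbouring
    plots stay correlated.  A smoothing scale of 0 gives uncorrelated cover.
    """
    rng = config.rng(_STREAM_COVER)
    z = rng.standard_normal((config.grid_ny, config.grid_nx))
    if config.cover_smoothing_scale > 0:
        z = gaussian_filter(z, sigma=config.cover_smoothing_scale, mode="wrap")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    cover = 100.0 * norm.cdf(z)

    iy, ix = np.meshgrid(np.arange(config.grid_ny), np.arange(config.grid_nx),
                         indexing="ij")
    n = config.grid_nx * config.grid_ny
    return pd.DataFrame(
        {
            "plot_id": [f"P{i:06d}" for i in range(n)],
            "x_km": ix.ravel(),
            "y_km": iy.ravel(),
            "cover_pct": cover.ravel(),
        }
    )


def _yule_tree(n_tips: int, birth_rate: float,
               rng: np.random.Generator) -> dendropy.Tree:
    """Pure-birth tree: exponential waiting times, uniform lineage choice.

    All pending lineages are extended to the present after one final waiting
    interval, so the tree is exactly ultrametric.
    """
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active: list[tuple[dendropy.Node, float]] = [(c1, 0.0), (c2, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node, born = active[k]
        node.edge.length = t - born
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        active[k] = (a, t)
        active.append((b, t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    width = len(str(n_tips))
    for i, (node, born) in enumerate(active):
        node.edge.length = t - born
        node.taxon = taxa.new_taxon(label=f"S{i + 1:0{width}d}")
    return tree


def simulate_tree_and_traits(config: SyntheticConfig
                             ) -> tuple[Phylogeny, GroundTruth]:
    """Dated pure-birth tree plus Brownian response traits and (M_j, C_j).

    The trait evolves under Brownian motion with rate ``bm_sigma2`` from a
    root state of 0; C_j is an affine map of the tip trait onto ``c_range``
    (affine maps preserve phylogenetic signal), and M_j is uniform on
    ``m_range``.  The two children of the root define two labelled clades
    ('cladeA', 'cladeB') standing in for major lineages such as angiosperms
    and gymnosperms.
    """
    if config.n_species < 3:
        raise ValueError("need n_species >= 3 (lambda not estimable below 3 tips)")
    rng = config.rng(_STREAM_TREE)
    tree = _yule_tree(config.n_species, config.tree_birth_rate, rng)

    phylo = Phylogeny(tree)
    labels, V = vcv_matrix(phylo)
    if config.bm_sigma2 > 0:
        L = np.linalg.cholesky(V)
        trait = np.sqrt(config.bm_sigma2) * (L @ rng.standard_normal(len(labels)))
    else:
        trait = np.zeros(len(labels))
    trait_s = pd.Series(trait, index=labels)

    lo, hi = config.c_range
    span = np.ptp(trait)
    if span > 0:
        C = lo + (trait - trait.min()) / span * (hi - lo)
    else:
        C = np.full(len(labels), (lo + hi) / 2.0)
    M = rng.uniform(config.m_range[0], config.m_range[1], size=len(labels))

    children = tree.seed_node.child_nodes()
    clades: dict[str, str] = {}
    for name, child in zip(("cladeA", "cladeB"), children):
        for leaf in child.leaf_iter():
            clades[leaf.taxon.label] = name
    phylo.clades = clades

    params = pd.DataFrame(
        {
            "species": labels,
            "M": M,
            "C": C,
            "trait": trait_s.reindex(labels).to_numpy(),
            "clade": [clades[s] for s in labels],
        }
    )
    return phylo, GroundTruth(params=params, tree=phylo)


def simulate_counts(plots: pd.DataFrame, truth: GroundTruth,
                    config: SyntheticConfig) -> pd.DataFrame:
    """Draw per-species Poisson stem counts given cover, then thin to occupancy.

    The rate is M_j + C_j * F (clipped below at 1e-10) under the identity
    link, or exp(M_j + C_j * F) under the log link.  If the identity-link
    rate would go negative anywhere on F in [0, 100] a warning notes that the
    generating model leaves identity-link support.  Thinning zeroes randomly
    chosen occupied plots per species until the occupied fraction matches the
    target occupancy (structural zeros).
    """
    rng = config.rng(_STREAM_COUNTS)
    F = plots["cover_pct"].to_numpy(float)
    n = len(plots)
    out = plots.copy()
    n_target = int(round(config.occupancy * n))
    for _, row in truth.params.iterrows():
        M, C, sp = float(row["M"]), float(row["C"]), str(row["species"])
        eta = M + C * F
        if config.link == "identity":
            if min(M, M + 100.0 * C) < 0:
                logger.warning(
                    "species %s: identity-link rate negative somewhere on "
                    "F in [0, 100]; clipped at %g during generation", sp, RATE_FLOOR)
            lam = np.maximum(eta, RATE_FLOOR)
        else:
            lam = np.exp(eta)
        counts = rng.poisson(lam)
        occ = np.flatnonzero(counts > 0)
        if config.occupancy < 1.0 and occ.size > n_target:
            drop = rng.choice(occ, size=occ.size - n_target, replace=False)
            counts[drop] = 0
        out[sp] = counts
    return out


def simulate_dataset(config: SyntheticConfig
                     ) -> tuple[pd.DataFrame, Phylogeny, GroundTruth]:
    """Full synthetic bundle: plot table with counts, phylogeny, ground truth."""
    plots = simulate_cover_field(config)
    phylo, truth = simulate_tree_and_traits(config)
    plots = simulate_counts(plots, truth, config)
    return plots, phylo, truth
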