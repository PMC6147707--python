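"""Pagel's lambda phylogenetic signal for species response traits.

Under Brownian motion on a rooted, dated tree, trait values at the tips are
multivariate normal with covariance proportional to shared branch length
(root-to-MRCA depth).  Pagel's lambda rescales the off-diagonal entries of
that matrix: lambda = 1 keeps pure Brownian covariances (strong signal),
lambda = 0 removes them entirely (a star phylogeny, no signal).  lambda is
estimated by maximum likelihood, profiling out the ancestral mean (GLS) and
the Brownian rate (ML variance, divisor n), and tested against lambda = 0 by
a likelihood-ratio test referred to the upper tail of chi-square with 1 df —
the convention of the standard reference implementations, slightly
conservative because lambda may sit on the boundary of its [0, 1] range.

Uncertainty in the response trait (Omega bootstrap CIs) is propagated by
redrawing, in each of n_iter iterations, one Omega per species uniformly from
its CI, refitting lambda, and reporting medians across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

logger = logging.getLogger(__name__)

DEFAULT_N_ITER = 1000
_COARSE_GRID = np.linspace(0.0, 1.0, 21)


class Phylogeny:
    """Rooted tree with branch lengths in Myr and optional tip clade labels."""

    def __init__(self, tree: dendropy.Tree, clades: dict[str, str] | None = None):
        self.tree = tree
        self.clades = dict(clades) if clades else {}
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        for leaf in tree.leaf_node_iter():
            for e in leaf.ancestor_iter(inclusive=True):
                if e.edge.length is not None and e.edge.length < 0:
                    raise ValueError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @classmethod
    def from_newick(cls, source: str, clades: dict[str, str] | None = None,
                    is_path: bool = True) -> "Phylogeny":
        kwargs = {"path": source} if is_path else {"data": source}
        tree = dendropy.Tree.get(schema="newick", **kwargs)
        return cls(tree, clades)

    def write_newick(self, path: str) -> None:
        self.tree.write(path=path, schema="newick", suppress_rooting=True)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True)

    def tip_depths(self) -> dict[str, float]:
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {leaf.taxon.label: leaf.root_distance
                for leaf in self.tree.leaf_node_iter()}

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = np.array(list(self.tip_depths().values()))
        span = depths.max() - depths.min()
        return bool(span <= rel_tol * max(depths.max(), 1e-300))

    def prune_to(self, tips: list[str]) -> "Phylogeny":
        """Subtree spanning ``tips``; path lengths to the original root kept."""
        missing = set(tips) - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        if len(set(tips)) < 2:
            raise ValueError("cannot prune a tree to fewer than 2 tips")
        t = self.tree.clone(depth=1)
        keep = [tax for tax in t.taxon_namespace if tax.label in set(tips)]
        t.retain_taxa(keep)
        clades = {s: c for s, c in self.clades.items() if s in set(tips)}
        return Phylogeny(t, clades)


def vcv_matrix(phylo: Phylogeny, tip_subset: list[str] | None = None
               ) -> tuple[list[str], np.ndarray]:
    """Phylogenetic variance-covariance matrix.

    Entry (a, b) is the root-to-MRCA path length of tips a and b; the diagonal
    is the root-to-tip depth.  When ``tip_subset`` is given the tree is pruned
    first (which preserves depths to the original root), so the result equals
    the corresponding submatrix of the full-tree VCV.
    """
    if tip_subset is not None:
        phylo = phylo.prune_to(list(tip_subset))
    tree = phylo.tree
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    labels = phylo.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    # post-order: tips below different children of a node share its depth
    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[id(node)] = [index[node.taxon.label]]
            V[tipsets[id(node)][0], tipsets[id(node)][0]] = node.root_distance
            continue
        child_sets = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
        depth = node.root_distance or 0.0
        for i, si in enumerate(child_sets):
            for sj in child_sets[i + 1:]:
                for a in si:
                    V[a, sj] = depth
                    V[sj, a] = depth
        tipsets[id(node)] = [a for s in child_sets for a in s]
    return labels, V


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Multiply off-diagonal phylogenetic covariances by ``lam`` in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    out = V * lam
    np.fill_diagonal(out, np.diag(V))
    return out


@dataclass
class LambdaResult:
    lambda_hat: float
    loglik: float
    loglik0: float
    lrt_stat: float
    p_value: float
    n_tips: int
    n_iter: int = 1
    median_lambda: float | None = None
    median_p: float | None = None
    iterations: pd.DataFrame | None = field(default=None, repr=False)


def profile_loglik(y: np.ndarray, V: np.ndarray, lam: float) -> float:
    """Log-likelihood at ``lam`` with mean and variance profiled out.

    mu is the GLS mean, sigma^2 the ML variance (divisor n); returns -inf for
    a numerically singular transformed covariance.
    """
    n = y.size
    Vl = lambda_transform(V, lam)
    try:
        cf = cho_factor(Vl, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ones = np.ones(n)
    Vi1 = cho_solve(cf, ones)
    Viy = cho_solve(cf, y)
    denom = ones @ Vi1
    if denom <= 0:
        return -np.inf
    mu = (ones @ Viy) / denom
    r = y - mu
    q = r @ cho_solve(cf, r)
    if q <= 0:
        return -np.inf
    s2 = q / n
    return float(-0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n))


def _optimize_lambda(y: np.ndarray, V: np.ndarray, xatol: float = 1e-8
                     ) -> tuple[float, float]:
    """Maximize the profiled likelihood over lambda in [0, 1].

    A coarse grid brackets the optimum before a bounded scalar search, and
    the interval endpoints are always candidates, so boundary optima at 0 or
    1 are found exactly.
    """
    grid_ll = np.array([profile_loglik(y, V, g) for g in _COARSE_GRID])
    k = int(np.nanargmax(grid_ll))
    lo = _COARSE_GRID[max(k - 1, 0)]
    hi = _COARSE_GRID[min(k + 1, len(_COARSE_GRID) - 1)]
    res = minimize_scalar(lambda g: -profile_loglik(y, V, g),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    candidates = [(float(res.x), float(-res.fun)), (0.0, float(grid_ll[0])),
                  (1.0, float(grid_ll[-1])), (float(_COARSE_GRID[k]), float(grid_ll[k]))]
    lam, ll = max(candidates, key=lambda t: t[1])
    return lam, ll


def fit_lambda(trait: "pd.Series | dict[str, float]", phylo: Phylogeny,
               V: np.ndarray | None = None,
               tip_order: list[str] | None = None) -> LambdaResult:
    """ML estimate of Pagel's lambda with a chi-square(1) LRT against 0.

    ``trait`` maps tip labels to values; the tree is pruned to the trait's
    species.  ``V``/``tip_order`` may carry a precomputed covariance to avoid
    recomputation in iterated runs.
    """
    tr = pd.Series(trait, dtype=float)
    if V is None:
        tip_order, V = vcv_matrix(phylo, list(tr.index))
    y = tr.reindex(tip_order).to_numpy()
    if np.any(~np.isfinite(y)):
        raise ValueError("trait has missing values after matching tips")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 tips to estimate lambda")
    if np.ptp(y) == 0:
        raise ValueError("constant trait: variance estimate is zero")

    lam, ll = _optimize_lambda(y, V)
    ll0 = profile_loglik(y, V, 0.0)
    lrt = max(0.0, 2.0 * (ll - ll0))
    p = float(chi2.sf(lrt, df=1))
    return LambdaResult(lambda_hat=lam, loglik=ll, loglik0=ll0,
                        lrt_stat=lrt, p_value=p, n_tips=n)


def lambda_with_uncertainty(
    omega_cis: pd.DataFrame,
    phylo: Phylogeny,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> LambdaResult:
    """Propagate Omega CI uncertainty into the lambda estimate.

    ``omega_cis`` needs columns ``species, ci_low, ci_high``.  Each iteration
    draws one Omega per species uniformly on [ci_low, ci_high] and refits
    lambda; the reported lambda and p are medians over iterations, and the
    full per-iteration values are retained for histogramming.  Species with
    non-finite CIs are pruned with a log message.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    df = omega_cis.set_index("species")[["ci_low", "ci_high"]].astype(float)
    finite = np.isfinite(df).all(axis=1)
    dropped = sorted(df.index[~finite])
    if dropped:
        logger.info("pruning %d species without finite Omega CIs: %s",
                    len(dropped), dropped)
    df = df.loc[finite]
    usable = [s for s in df.index if s in set(phylo.tip_labels)]
    if len(usable) < 3:
        raise ValueError(f"only {len(usable)} species with usable Omega CIs")
    df = df.loc[usable]
    tip_order, V = vcv_matrix(phylo, usable)
    lo = df.reindex(tip_order)["ci_low"].to_numpy()
    hi = df.reindex(tip_order)["ci_high"].to_numpy()

    lams = np.empty(n_iter)
    ps = np.empty(n_iter)
    for i in range(n_iter):
        rng = np.random.default_rng([int(seed), i])
        y = rng.uniform(lo, hi)
        if np.ptp(y) == 0:  # all CIs zero-width and equal: jitter-free fallback
            y = lo
        res_i = fit_lambda(pd.Series(y, index=tip_order), phylo,
                           V=V, tip_order=tip_order)
        lams[i] = res_i.lambda_hat
        ps[i] = res_i.p_value

    iters = pd.DataFrame({"iteration": np.arange(n_iter),
                          "lambda": lams, "p_value": ps})
    med_lam = float(np.median(lams))
    med_p = float(np.median(ps))
    # point fit at the CI midpoints for the headline likelihoods
    mid = pd.Series((lo + hi) / 2.0, index=tip_order)
    point = fit_lambda(mid, phylo, V=V, tip_order=tip_order)
    return LambdaResult(lambda_hat=point.lambda_hat, loglik=point.loglik,
                        loglik0=point.loglik0, lrt_stat=point.lrt_stat,
                        p_value=point.p_value, n_tips=len(tip_order),
                        n_iter=n_iter, median_lambda=med_lam, median_p=med_p,
                        iterations=iters)


def clade_subset_signal(
    omega_cis: pd.DataFrame,
    phylo: Phylogeny,
    clade_labels: dict[str, str] | None = None,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> dict[str, LambdaResult | None]:
    """Signal for all species together and within each labelled clade.

    Returns a mapping scope -> LambdaResult, with ``'all'`` first; a clade
    with fewer than 3 usable species maps to ``None`` (not estimable) rather
    than failing the whole run.
    """
    clade_labels = clade_labels if clade_labels is not None else phylo.clades
    out: dict[str, LambdaResult | None] = {}
    out["all"] = lambda_with_uncertainty(omega_cis, phylo, n_iter=n_iter, seed=seed)
    for clade in sorted(set(clade_labels.values())):
        members = {s for s, c in clade_labels.items() if c == clade}
        sub = omega_cis[omega_cis["species"].isin(members)]
        tips = [s for s in sub["species"] if s in set(phylo.tip_labels)]
        if len(tips) < 3:
            logger.info("clade %r not estimable: only %d usable species",
                        clade, len(tips))
            out[clade] = None
            continue
        try:
            sub_tree = phylo.prune_to(tips)
            out[clade] = lambda_with_uncertainty(sub, sub_tree,
                                                 n_iter=n_iter, seed=seed)
        except ValueError as exc:
            logger.info("clade %r not estimable: %s", clade, exc)
            out[clade] = None
    return out
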