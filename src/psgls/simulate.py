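"""Synthetic trees, coordinates, covariates and traits with known truth.

Every stage of the analysis is testable without external data: pure-birth
(Yule) trees stand in for the language phylogeny at desk scale, uniform
coordinates in a Eurasia-sized box stand in for capital cities, and traits
are drawn from the model's own multivariate normal with covariance
sigma2 * V(lambda, phi), so the generating weights and fixed effects are
known exactly.  A synthetic "posterior sample" of trees is produced by
perturbing branch lengths with lognormal multipliers.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .model import (
    CovarianceWeights,
    _lrt_p,
    combine_covariance,
    derived_weights,
    profile_grid_fit,
)
from .phylo import Phylogeny, normalize_covariance, phylo_covariance_matrix
from .spatial import GeoPoints, distance_matrix, spatial_similarity

__all__ = [
    "SyntheticDataset",
    "identifiability_experiment",
    "make_dataset",
    "perturb_branch_lengths",
    "simulate_coordinates",
    "simulate_trait",
    "simulate_tree",
]

#: lat_min, lat_max, lon_min, lon_max of the default coordinate box,
#: roughly the Eurasian span of the motivating study
DEFAULT_BOUNDS = (5.0, 65.0, -10.0, 90.0)


@dataclass
class SyntheticDataset:
    """One simulated dataset plus the parameters that generated it."""

    trees: list[Phylogeny]
    points: GeoPoints
    X: np.ndarray
    y: np.ndarray
    weights: CovarianceWeights
    beta: np.ndarray
    sigma2: float
    seed: int
    sigma_star: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    w: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def taxa(self) -> list[str]:
        return list(self.points.taxa)


def simulate_tree(n_tips: int, model: str = "yule", seed: int | None = None) -> Phylogeny:
    """Ultrametric pure-birth tree with tips labeled t01, t02, ...

    Reproducible per seed: the same seed yields an identical Newick string.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be at least 2")
    if model != "yule":
        raise ValueError(f"unknown tree model {model!r}")
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    width = len(str(n_tips))
    ns = dendropy.TaxonNamespace()
    # relabel in a fixed traversal order so labels are deterministic
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = ns.new_taxon(label=f"t{i:0{width}d}")
    tree.taxon_namespace = ns
    return Phylogeny(tree=tree)


def perturb_branch_lengths(phy: Phylogeny, sd: float = 0.1, seed: int | None = None) -> Phylogeny:
    """Clone a tree with every branch scaled by a lognormal(1) multiplier.

    Emulates tree-to-tree variation in a posterior sample; multipliers
    have unit mean (mu = -sd^2/2), so expected depths are preserved.  The
    result is generally no longer exactly ultrametric, which the
    unit-diagonal covariance normalization handles.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    rng = np.random.default_rng(seed)
    clone = phy.tree.clone(depth=1)
    for edge in clone.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length) * float(
                rng.lognormal(mean=-0.5 * sd**2, sigma=sd)
            )
    return Phylogeny(tree=clone)


def simulate_coordinates(
    n: int,
    bounds: tuple[float, float, float, float] = DEFAULT_BOUNDS,
    seed: int | None = None,
    taxa: list[str] | None = None,
) -> GeoPoints:
    """Uniform coordinates in a (lat_min, lat_max, lon_min, lon_max) box."""
    if n < 1:
        raise ValueError("need at least one point")
    lat_min, lat_max, lon_min, lon_max = bounds
    if lat_min >= lat_max or lon_min >= lon_max:
        raise ValueError(f"inverted bounds {bounds}")
    rng = np.random.default_rng(seed)
    lat = rng.uniform(lat_min, lat_max, n)
    lon = rng.uniform(lon_min, lon_max, n)
    if taxa is None:
        width = len(str(n))
        taxa = [f"t{i:0{width}d}" for i in range(1, n + 1)]
    return GeoPoints(taxa=list(taxa), lat=lat, lon=lon)


def simulate_trait(
    sigma_star: np.ndarray,
    w: np.ndarray | None,
    weights: CovarianceWeights,
    X: np.ndarray,
    beta: np.ndarray,
    sigma2: float,
    seed: int | None = None,
) -> np.ndarray:
    """Draw y ~ N(X beta, sigma2 * V(lambda, phi)); sigma2 = 0 returns X beta."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(beta, dtype=float).ravel()
    mean = X @ beta
    if sigma2 == 0.0:
        return mean
    v = combine_covariance(weights, sigma_star, w)
    L = np.linalg.cholesky(v + 1e-12 * np.eye(v.shape[0]))
    rng = np.random.default_rng(seed)
    return mean + np.sqrt(sigma2) * (L @ rng.standard_normal(v.shape[0]))


def make_dataset(
    n_tips: int = 44,
    lam: float = 0.9,
    phi: float = 0.0,
    beta: np.ndarray | float = 0.0,
    sigma2: float = 1.0,
    seed: int | None = None,
    n_trees: int = 1,
    tree_perturb_sd: float = 0.1,
    X: np.ndarray | None = None,
    bounds: tuple[float, float, float, float] = DEFAULT_BOUNDS,
) -> SyntheticDataset:
    """Generate a complete dataset: tree(s), coordinates, design, trait.

    The first tree is the generating tree; additional trees are
    branch-length perturbations of it, emulating a posterior sample.  The
    trait is drawn on the generating tree.  ``X`` defaults to an
    intercept-only design; ``beta`` is broadcast to its width.
    """
    ss = np.random.SeedSequence(seed)
    s_tree, s_coord, s_trait, s_perturb = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    tree = simulate_tree(n_tips, seed=s_tree)
    points = simulate_coordinates(n_tips, bounds=bounds, seed=s_coord, taxa=tree.tips)
    sigma_star = normalize_covariance(phylo_covariance_matrix(tree, points.taxa)).sigma
    w = spatial_similarity(distance_matrix(points), taxa=points.taxa).w
    if X is None:
        X = np.ones((n_tips, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.broadcast_to(np.atleast_1d(np.asarray(beta, dtype=float)), (X.shape[1],)).copy()
    weights = derived_weights(lam, phi)
    y = simulate_trait(sigma_star, w, weights, X, beta, sigma2, seed=s_trait)
    trees = [tree]
    rng = np.random.default_rng(s_perturb)
    for _ in range(n_trees - 1):
        trees.append(
            perturb_branch_lengths(tree, sd=tree_perturb_sd, seed=int(rng.integers(2**31)))
        )
    return SyntheticDataset(
        trees=trees,
        points=points,
        X=X,
        y=y,
        weights=weights,
        beta=beta,
        sigma2=sigma2,
        seed=seed if seed is not None else -1,
        sigma_star=sigma_star,
        w=w,
    )


def latitude_gradient_trait(
    points: GeoPoints, noise_sd: float = 0.3, seed: int | None = None
) -> np.ndarray:
    """Archetypal geographically autocorrelated trait (temperature-like).

    A smooth function of latitude — cos(lat), warm at the equator, cold
    toward the poles — standardized and jittered with iid noise.  Because
    it is generated from coordinates alone, a correct fit should assign
    it to the spatial component (high phi, negligible lambda'), whatever
    the phylogeny looks like.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    y = np.cos(np.radians(points.lat))
    sd = y.std()
    if sd > 0:
        y = (y - y.mean()) / sd
    rng = np.random.default_rng(seed)
    return y + noise_sd * rng.standard_normal(y.size)


def identifiability_experiment(
    truths: list[tuple[float, float]],
    reps: int = 200,
    n_tips: int = 44,
    sigma2: float = 1.0,
    step: float = 0.02,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Recovery of (lambda, phi) across replicate simulated datasets.

    For each true weight pair, ``reps`` datasets are generated (fresh tree
    and coordinates each time), fit by the full grid search, and
    summarized: mean/sd of the estimates and rejection rates of the
    single-parameter likelihood-ratio tests (each sub-model against the
    independence model, df = 1) and the joint test (df = 2) at ``alpha``.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    ss = np.random.SeedSequence(seed)
    rows = []
    for lam_true, phi_true in truths:
        child = ss.spawn(1)[0]
        rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(reps)]
        lam_hat = np.empty(reps)
        phi_hat = np.empty(reps)
        p_lam = np.empty(reps)
        p_phi = np.empty(reps)
        p_joint = np.empty(reps)
        for r, s in enumerate(rep_seeds):
            ds = make_dataset(
                n_tips=n_tips, lam=lam_true, phi=phi_true, sigma2=sigma2, seed=s
            )
            res = profile_grid_fit(ds.y, ds.X, ds.sigma_star, ds.w, step=step, mode="both")
            lam_hat[r] = res.weights.lam
            phi_hat[r] = res.weights.phi
            surface = res.surface
            # single-parameter LRTs read off the same exhaustive surface
            ll0 = float(surface[0, 0])
            p_lam[r] = _lrt_p(float(np.max(surface[:, 0])), ll0, 1)
            p_phi[r] = _lrt_p(float(np.max(surface[0, :])), ll0, 1)
            p_joint[r] = res.lrt_p["joint"]
        rows.append(
            {
                "lam_true": lam_true,
                "phi_true": phi_true,
                "reps": reps,
                "mean_lam_hat": lam_hat.mean(),
                "sd_lam_hat": lam_hat.std(ddof=1) if reps > 1 else 0.0,
                "mean_phi_hat": phi_hat.mean(),
                "sd_phi_hat": phi_hat.std(ddof=1) if reps > 1 else 0.0,
                "reject_lambda": float(np.mean(p_lam < alpha)),
                "reject_phi": float(np.mean(p_phi < alpha)),
                "reject_joint": float(np.mean(p_joint < alpha)),
            }
        )
    return pd.DataFrame(rows)
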