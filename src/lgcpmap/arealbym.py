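"""Areal Besag–York–Mollié comparator.

The point-process analysis is cross-checked against the classical areal
approach: cases and expected counts are aggregated to contiguous
pseudo-municipalities (rectangular blocks of grid cells) and modelled as

    y_a ~ Poisson(E_a exp(beta_0 + x_a beta + u_a + v_a)),

with u an intrinsic CAR (ICAR) spatially structured effect under a
sum-to-zero constraint and v an independent Gaussian unstructured
effect.  Both random-effect standard deviations get penalised-complexity
(exponential) priors, and the fit uses the same Laplace-on-a-hyper-grid
machinery as the LGCP: the ICAR improperness is handled by
parameterising u in an orthonormal basis of the sum-zero subspace, where
its prior is proper and full rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln

from .lgcpfit import (
    _LOG_SD_GUMBEL,
    PosteriorSamples,
    FitSettings,
    HyperGrid,
    _log_posterior_terms,
    _newton_mode,
)
from ._linalg import Chol
from .spdecore import PCPriorSigma
from .synthdata import CovariateSet, ExpectedSurface, GridSpec

__all__ = [
    "ArealPartition",
    "ArealData",
    "BymPriors",
    "BymFit",
    "block_partition",
    "aggregate",
    "fit_bym",
    "posterior_samples_bym",
]


@dataclass
class ArealPartition:
    """Cells grouped into contiguous areas with a shared-edge adjacency graph."""

    labels: np.ndarray          # (K,) area index per cell, 0..n_areas-1
    edges: list                 # [(a, b), ...] with a < b, shared-edge rule
    n_areas: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if set(np.unique(self.labels)) != set(range(self.n_areas)):
            raise ValueError("every area must contain at least one cell")
        for a, b in self.edges:
            if a == b:
                raise ValueError("adjacency must not contain self-loops")

    def adjacency_matrix(self) -> sp.csr_matrix:
        n = self.n_areas
        if not self.edges:
            return sp.csr_matrix((n, n))
        a, b = np.array(self.edges).T
        W = sp.coo_matrix(
            (np.ones(2 * len(self.edges)),
             (np.concatenate([a, b]), np.concatenate([b, a]))),
            shape=(n, n),
        )
        return W.tocsr()

    def is_connected(self) -> bool:
        n = self.n_areas
        W = self.adjacency_matrix()
        seen = np.zeros(n, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            i = stack.pop()
            for j in W[i].indices:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        return bool(seen.all())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"k": np.arange(self.labels.size),
                      "area": self.labels}).to_csv(path, index=False)

    def edges_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.edges, columns=["a", "b"]).to_csv(path, index=False)


def block_partition(grid: GridSpec, block_size: int) -> ArealPartition:
    """Pseudo-municipalities: rectangular blocks of ``block_size`` cells a side."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    xmin, ymin, _, _ = grid.bounds
    h = grid.cell_size
    bx = ((grid.centroids[:, 0] - xmin) / h).astype(int) // block_size
    by = ((grid.centroids[:, 1] - ymin) / h).astype(int) // block_size
    nbx = bx.max() + 1
    raw = by * nbx + bx
    # re-index compactly (non-rectangular windows can skip blocks)
    uniq, labels = np.unique(raw, return_inverse=True)
    pos = {u: (u % nbx, u // nbx) for u in uniq}
    idx = {u: i for i, u in enumerate(uniq)}
    edges = set()
    for u in uniq:
        x, y = pos[u]
        for v in (u + 1 if (u + 1) in idx and pos[u + 1][1] == y else None,
                  u + nbx if (u + nbx) in idx else None):
            if v is not None:
                edges.add((min(idx[u], idx[v]), max(idx[u], idx[v])))
    return ArealPartition(labels=labels, edges=sorted(edges), n_areas=len(uniq))


@dataclass
class ArealData:
    """Counts, offsets and covariates aggregated to areas."""

    counts: np.ndarray
    offset: np.ndarray
    design: CovariateSet
    partition: ArealPartition


def aggregate(cell_counts: np.ndarray, expected: ExpectedSurface,
              covariates: CovariateSet, partition: ArealPartition,
              weights: np.ndarray | None = None) -> ArealData:
    """Aggregate cell-level data to areas.

    Counts and expected counts are summed; continuous covariates are
    population-weighted means (uniform weights if none given);
    categorical covariates take the modal level over the area's cells.
    """
    K = expected.E.size
    if partition.labels.size != K:
        raise ValueError("partition does not cover the cell index")
    lab = partition.labels
    n = partition.n_areas
    if weights is None:
        weights = np.ones(K)
    weights = np.asarray(weights, dtype=float)

    counts_a = np.bincount(lab, weights=np.asarray(cell_counts, float),
                           minlength=n)
    E_a = np.bincount(lab, weights=expected.E, minlength=n)
    wsum = np.bincount(lab, weights=weights, minlength=n)

    cols, names = [], []
    meta = {}
    cat_groups: dict[str, list] = {}
    for ci, name in enumerate(covariates.columns):
        m = covariates.meta[name]
        if m.get("type") == "indicator":
            cat_groups.setdefault(m["covariate"], []).append((ci, name))
    for ci, name in enumerate(covariates.columns):
        m = covariates.meta[name]
        if m.get("type") == "indicator":
            continue  # handled per categorical block below
        col = covariates.design[:, ci]
        if name == "intercept":
            cols.append(np.ones(n))
        else:
            cols.append(np.bincount(lab, weights=weights * col, minlength=n)
                        / np.maximum(wsum, 1e-300))
        names.append(name)
        meta[name] = dict(m)
    for cov, members in cat_groups.items():
        # level per cell: 0 = reference, 1.. = the indicator columns in order
        ind = np.stack([covariates.design[:, ci] for ci, _ in members])
        level = np.where(ind.sum(axis=0) > 0, np.argmax(ind, axis=0) + 1, 0)
        modal = np.zeros(n, dtype=int)
        for a in range(n):
            lv = level[lab == a]
            modal[a] = np.bincount(lv).argmax()
        for li, (ci, name) in enumerate(members, start=1):
            cols.append((modal == li).astype(float))
            names.append(name)
            meta[name] = dict(covariates.meta[name])
    design = CovariateSet(np.column_stack(cols), names, meta)
    return ArealData(
        counts=counts_a,
        offset=E_a,
        design=design,
        partition=partition,
    )


@dataclass
class BymPriors:
    """PC priors for the two random-effect SDs and the beta variance."""

    sigma_u_prior: tuple[float, float] = (1.0, 0.01)  # P(sigma_u > 1) = 0.01
    sigma_v_prior: tuple[float, float] = (1.0, 0.01)
    beta_variance: float = 10.0


@dataclass
class BymFit:
    """BYM fit: hyper grid over (sigma_u, sigma_v) with Gaussian conditionals."""

    data: ArealData
    priors: BymPriors
    settings: FitSettings
    hyper: HyperGrid
    modes: list = field(repr=False)
    factors: list = field(repr=False)
    basis: np.ndarray = None   # (n_areas, n_areas-1) sum-zero basis S
    n_areas: int = 0

    @property
    def n_coef(self) -> int:
        return self.modes[0].size - (2 * self.n_areas - 1)


def _sum_zero_basis(n: int) -> np.ndarray:
    """Orthonormal basis of the subspace {u : sum u = 0} in R^n."""
    A = np.eye(n) - np.full((n, n), 1.0 / n)
    # eigenvectors of the centring projector with eigenvalue 1
    vals, vecs = np.linalg.eigh(A)
    return vecs[:, vals > 0.5]


def fit_bym(data: ArealData, priors: BymPriors | None = None,
            settings: FitSettings | None = None) -> BymFit:
    """Fit the BYM model by Laplace approximation on a (sigma_u, sigma_v) grid.

    The latent vector is (w, v, beta) with u = S w, S an orthonormal
    basis of the sum-to-zero subspace; the ICAR prior on u becomes a
    proper Gaussian on w with precision S' (D - W) S / sigma_u^2.
    """
    priors = priors or BymPriors()
    settings = settings or FitSettings()
    part = data.partition
    if not part.is_connected():
        raise ValueError("adjacency graph is disconnected; split per component")
    n = part.n_areas
    W = part.adjacency_matrix()
    R = sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W  # graph Laplacian
    S = _sum_zero_basis(n)
    Ru = S.T @ (R @ S)  # (n-1, n-1), full rank for a connected graph
    logdet_Ru = Chol(Ru).logdet()

    X = data.design.design
    p = X.shape[1]
    y, E = np.asarray(data.counts, float), np.asarray(data.offset, float)
    B = sp.hstack([sp.csr_matrix(S), sp.identity(n, format="csr"),
                   sp.csr_matrix(X)]).tocsr()

    pu = PCPriorSigma(*priors.sigma_u_prior)
    pv = PCPriorSigma(*priors.sigma_v_prior)
    g = settings.grid_size
    span = settings.grid_span_sds * _LOG_SD_GUMBEL
    offsets = np.linspace(-span, span, g) if g > 1 else np.array([0.0])
    lu = np.log(pu.median) + offsets
    lv = np.log(pv.median) + offsets
    LU, LV = np.meshgrid(lu, lv, indexing="ij")
    su, sv = np.exp(LU.ravel()), np.exp(LV.ravel())
    G = su.size

    const = -float(gammaln(y + 1.0).sum())
    u0 = np.zeros(2 * n - 1 + p)
    icpt = data.design.columns.index("intercept")
    if y.sum() > 0 and E.sum() > 0:
        u0[2 * n - 1 + icpt] = np.log(y.sum() / E.sum())

    log_marg = np.empty(G)
    modes, factors = [], []
    warm = u0
    logdet_P_beta = -p * np.log(priors.beta_variance)
    for gi in range(G):
        Pw = Ru / su[gi] ** 2
        P = sp.block_diag([
            sp.csr_matrix(Pw),
            sp.identity(n) / sv[gi] ** 2,
            sp.identity(p) / priors.beta_variance,
        ]).tocsr()
        logdet_P = (logdet_Ru - 2 * (n - 1) * np.log(su[gi])
                    - 2 * n * np.log(sv[gi]) + logdet_P_beta)
        mode, ch = _newton_mode(B, y, E, P, warm, settings.newton_tol,
                                settings.newton_max_iter)
        obj, _ = _log_posterior_terms(mode, B, y, E, P)
        log_marg[gi] = (const + obj + 0.5 * logdet_P - 0.5 * ch.logdet()
                        + pu.logpdf(su[gi]) + pv.logpdf(sv[gi])
                        + np.log(su[gi]) + np.log(sv[gi]))
        modes.append(mode)
        factors.append(ch)
        warm = mode

    w = np.exp(log_marg - log_marg.max())
    w /= w.sum()
    wgrid = w.reshape(g, g)
    if g > 2:
        edge = np.concatenate([wgrid[0], wgrid[-1],
                               wgrid[1:-1, 0], wgrid[1:-1, -1]])
        edge_warn = bool(np.any(edge >= 0.01))
    else:
        edge_warn = False
    hyper = HyperGrid(sigma=su, rho=sv, log_marginals=log_marg, weights=w,
                      shape=(g, g), edge_mass_warning=edge_warn)
    return BymFit(data=data, priors=priors, settings=settings, hyper=hyper,
                  modes=modes, factors=factors, basis=S, n_areas=n)


def posterior_samples_bym(fit: BymFit, n: int, seed: int = 0,
                          split: bool = False):
    """Joint draws of (beta, u+v per area, sigma_u, sigma_v).

    Returned in the same container the posterior module consumes, with
    ``z_cells`` holding the total area-level random effect u + v.  With
    ``split`` the structured and unstructured components are also
    returned separately (u draws satisfy the sum-to-zero constraint).
    """
    if n <= 0:
        raise ValueError("number of draws must be positive")
    rng = np.random.default_rng(seed)
    na, p = fit.n_areas, fit.n_coef
    idx = rng.choice(fit.hyper.weights.size, size=n, p=fit.hyper.weights)
    beta = np.empty((n, p))
    u = np.empty((n, na))
    v = np.empty((n, na))
    for g in np.unique(idx):
        sel = np.where(idx == g)[0]
        draws = fit.factors[g].sample(rng, n=sel.size, mean=fit.modes[g])
        u[sel] = draws[:, : na - 1] @ fit.basis.T
        v[sel] = draws[:, na - 1: 2 * na - 1]
        beta[sel] = draws[:, 2 * na - 1:]
    samples = PosteriorSamples(
        beta=beta, z_cells=u + v,
        sigma=fit.hyper.sigma[idx], rho=fit.hyper.rho[idx],
        columns=list(fit.data.design.columns),
        design=fit.data.design.design,
    )
    if split:
        return samples, u, v
    return samples
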