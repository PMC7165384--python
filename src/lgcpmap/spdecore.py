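"""Matérn field machinery: mesh, correlation, SPDE precision, projectors, PC priors.

The latent spatial field is a zero-mean Gaussian random field with
Matérn covariance, smoothness fixed at nu = 1.  It is represented on a
triangulation by piecewise-linear finite elements: the field is
``Z(s) = sum_i psi_i(s) Z_i`` where the node weights Z form a Gaussian
Markov random field with sparse precision Q(rho, sigma).

Range convention
----------------
The range ``rho`` is defined as the distance at which the correlation of
the field falls to 0.10.  For nu = 1 the Matérn correlation is
``c(d) = (kappa d) K_1(kappa d)``; ``kappa`` is calibrated by
root-finding so that ``c(rho) = 0.10`` exactly.  This differs from the
widespread convention ``rho = sqrt(8 nu)/kappa`` (which has
c(rho) ≈ 0.139 for nu = 1); the sqrt(8)/kappa-equivalent range is
recorded in :class:`MaternParams` metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.special import kv

__all__ = [
    "save_sparse_coo",
    "load_sparse_coo",
    "Mesh",
    "MaternParams",
    "PriorSpec",
    "PCPriorSigma",
    "PCPriorRange",
    "build_mesh",
    "matern_correlation",
    "matern_kappa",
    "spde_precision",
    "make_projector",
    "pc_prior_sigma",
    "pc_prior_range",
]


def save_sparse_coo(mat: sp.spmatrix, path: str | Path) -> None:
    """Coordinate-format text serialisation of a sparse matrix."""
    coo = mat.tocoo()
    pd.DataFrame({"row": coo.row, "col": coo.col, "value": coo.data}).to_csv(
        path, index=False)


def load_sparse_coo(path: str | Path, shape: tuple[int, int]) -> sp.csr_matrix:
    df = pd.read_csv(path)
    return sp.coo_matrix(
        (df["value"], (df["row"], df["col"])), shape=shape).tocsr()


# --------------------------------------------------------------------------
# parameters and priors
# --------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _xstar_corr010() -> float:
    """Solve x*K_1(x) = 0.10; kappa = xstar / rho under the 0.10 convention."""
    f = lambda x: x * kv(1, x) - 0.10
    return brentq(f, 1e-6, 20.0, xtol=1e-13)


def matern_kappa(rho: float) -> float:
    """Matérn (nu=1) scale parameter for range ``rho`` (correlation 0.10 at rho)."""
    if rho <= 0:
        raise ValueError(f"range must be positive, got {rho}")
    return _xstar_corr010() / rho


@dataclass(frozen=True)
class MaternParams:
    """Hyperparameters of the Matérn (nu = 1) field.

    sigma : marginal standard deviation of the field
    rho   : range in km (correlation 0.10 at distance rho)
    """

    sigma: float
    rho: float
    nu: int = 1

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.rho <= 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if self.nu != 1:
            raise ValueError("only nu = 1 is supported")

    @property
    def kappa(self) -> float:
        return matern_kappa(self.rho)

    @property
    def rho_sqrt8(self) -> float:
        """Range under the common sqrt(8 nu)/kappa convention, for reference."""
        return np.sqrt(8.0) / self.kappa


def matern_correlation(d, params: MaternParams):
    """Matérn nu=1 correlation at distance ``d`` (km).

    c(d) = (kappa d) K_1(kappa d), with c(0) = 1 by continuity.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    x = params.kappa * d
    with np.errstate(invalid="ignore"):
        c = np.where(x > 0, x * kv(1, np.maximum(x, 1e-300)), 1.0)
    return c if c.ndim else float(c)


class PCPriorSigma:
    """Penalised-complexity prior for a standard-deviation parameter.

    Exponential with rate lambda = -ln(alpha)/u, so that
    P(sigma > u) = alpha; shrinks towards the base model sigma = 0.
    """

    def __init__(self, u: float, alpha: float) -> None:
        if not 0 < alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        if u <= 0:
            raise ValueError(f"u must be positive, got {u}")
        self.u, self.alpha = u, alpha
        self.rate = -np.log(alpha) / u

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(x >= 0, np.log(self.rate) - self.rate * x, -np.inf)
        return out if out.ndim else float(out)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(x > 0, 1.0 - np.exp(-self.rate * x), 0.0)
        return out if out.ndim else float(out)

    def ppf(self, p):
        p = np.asarray(p, dtype=float)
        out = -np.log1p(-p) / self.rate
        return out if out.ndim else float(out)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.exponential(scale=1.0 / self.rate, size=n)

    @property
    def median(self) -> float:
        return self.ppf(0.5)


class PCPriorRange:
    """Penalised-complexity prior for the range of a 2-d Matérn field.

    The base model is rho = infinity; the prior density is
    pi(rho) = lam * rho^{-2} * exp(-lam / rho) with lam = -ln(alpha)*rho0,
    i.e. an inverse-exponential, giving P(rho < rho0) = alpha exactly.
    """

    def __init__(self, rho0: float, alpha: float) -> None:
        if not 0 < alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        if rho0 <= 0:
            raise ValueError(f"rho0 must be positive, got {rho0}")
        self.rho0, self.alpha = rho0, alpha
        self.lam = -np.log(alpha) * rho0

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            out = np.where(
                x > 0, np.log(self.lam) - 2.0 * np.log(x) - self.lam / x, -np.inf
            )
        return out if out.ndim else float(out)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            out = np.where(x > 0, np.exp(-self.lam / x), 0.0)
        return out if out.ndim else float(out)

    def ppf(self, p):
        p = np.asarray(p, dtype=float)
        out = -self.lam / np.log(p)
        return out if out.ndim else float(out)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.ppf(rng.uniform(size=n))

    @property
    def median(self) -> float:
        return self.ppf(0.5)


@dataclass(frozen=True)
class PriorSpec:
    """Prior block of the model.

    sigma_prior : (u_sigma, alpha_sigma), contract P(sigma > u) = alpha.
    range_prior : (rho0, alpha_rho), contract P(rho < rho0) = alpha.
    beta_variance : prior variance (not SD) of each regression coefficient.
    """

    sigma_prior: tuple[float, float] = (1.0, 0.01)
    range_prior: tuple[float, float] = (60.0, 0.5)
    beta_variance: float = 10.0

    def __post_init__(self):
        for u, a in (self.sigma_prior, self.range_prior):
            if not 0 < a < 1:
                raise ValueError(f"prior tail probability must be in (0,1), got {a}")
            if u <= 0:
                raise ValueError(f"prior threshold must be positive, got {u}")
        if self.beta_variance <= 0:
            raise ValueError("beta_variance must be positive")


def pc_prior_sigma(spec: PriorSpec) -> PCPriorSigma:
    u, alpha = spec.sigma_prior
    return PCPriorSigma(u, alpha)


def pc_prior_range(spec: PriorSpec) -> PCPriorRange:
    rho0, alpha = spec.range_prior
    return PCPriorRange(rho0, alpha)


# --------------------------------------------------------------------------
# mesh
# --------------------------------------------------------------------------

@dataclass
class Mesh:
    """Structured triangular lattice over the extended observation window.

    nodes     : (M, 2) planar coordinates in km
    triangles : (T, 3) vertex indices, counter-clockwise
    spacing   : lattice spacing in km
    extension : buffer width beyond the window (km)
    shape     : (ny, nx) node-lattice dimensions
    """

    nodes: np.ndarray
    triangles: np.ndarray
    spacing: float
    extension: float
    shape: tuple[int, int]
    origin: np.ndarray = field(default=None)  # lower-left node

    def __post_init__(self):
        if self.origin is None:
            self.origin = self.nodes[0].copy()

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def to_csv(self, nodes_path: str | Path, triangles_path: str | Path) -> None:
        pd.DataFrame(self.nodes, columns=["x_km", "y_km"]).to_csv(
            nodes_path, index_label="node"
        )
        pd.DataFrame(self.triangles, columns=["v0", "v1", "v2"]).to_csv(
            triangles_path, index_label="triangle"
        )


def build_mesh(grid, node_spacing: float, buffer: float) -> Mesh:
    """Triangulate the grid's window extended by ``buffer`` km.

    A regular lattice of nodes at ``node_spacing`` covers the buffered
    bounding box (centred, so the lattice may overhang slightly when the
    extent is not a multiple of the spacing); each lattice square is
    split into two triangles.  The buffer mitigates the variance
    inflation the SPDE boundary condition induces near the mesh edge.
    """
    if node_spacing <= 0:
        raise ValueError("node_spacing must be positive")
    if buffer < 0:
        raise ValueError("buffer must be non-negative")
    xmin, ymin, xmax, ymax = grid.bounds
    xmin -= buffer
    ymin -= buffer
    xmax += buffer
    ymax += buffer
    ext_x, ext_y = xmax - xmin, ymax - ymin
    if node_spacing > max(ext_x, ext_y):
        raise ValueError(
            f"node_spacing {node_spacing} exceeds window extent {max(ext_x, ext_y)}"
        )
    nx = int(np.ceil(ext_x / node_spacing - 1e-9)) + 1
    ny = int(np.ceil(ext_y / node_spacing - 1e-9)) + 1
    # centre the lattice on the buffered box
    x0 = 0.5 * (xmin + xmax) - 0.5 * (nx - 1) * node_spacing
    y0 = 0.5 * (ymin + ymax) - 0.5 * (ny - 1) * node_spacing
    xs = x0 + node_spacing * np.arange(nx)
    ys = y0 + node_spacing * np.arange(ny)
    X, Y = np.meshgrid(xs, ys)
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    tris = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            b = a + 1
            c = a + nx
            d = c + 1
            # split along the b-c anti-diagonal, matching make_projector
            tris.append((a, b, c))
            tris.append((b, d, c))
    triangles = np.asarray(tris, dtype=np.int64)
    return Mesh(
        nodes=nodes,
        triangles=triangles,
        spacing=node_spacing,
        extension=buffer,
        shape=(ny, nx),
        origin=np.array([x0, y0]),
    )


# --------------------------------------------------------------------------
# finite-element matrices and the SPDE precision
# --------------------------------------------------------------------------

def fem_matrices(mesh: Mesh) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Lumped mass matrix C (diagonal) and stiffness matrix G of the mesh.

    Cached on the mesh object: Q(rho, sigma) is reassembled per
    hyperparameter grid point but C and G depend on the mesh only.
    """
    cached = getattr(mesh, "_fem_cache", None)
    if cached is not None:
        return cached
    pts = mesh.nodes
    tri = mesh.triangles
    p0, p1, p2 = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
    e1 = p1 - p0
    e2 = p2 - p0
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    if np.any(np.abs(det) < 1e-12):
        raise ValueError("mesh contains degenerate triangles")
    area = 0.5 * np.abs(det)

    # gradients of the three barycentric basis functions on each triangle
    # grad lambda_i = rot(edge opposite i) / (2 * signed area)
    def _grad(pa, pb):
        d = pb - pa
        return np.column_stack([-d[:, 1], d[:, 0]]) / det[:, None]

    g0 = _grad(p1, p2)
    g1 = _grad(p2, p0)
    g2 = _grad(p0, p1)
    grads = [g0, g1, g2]

    M = mesh.n_nodes
    rows, cols, vals = [], [], []
    for a in range(3):
        for b in range(3):
            rows.append(tri[:, a])
            cols.append(tri[:, b])
            vals.append(area * np.sum(grads[a] * grads[b], axis=1))
    G = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(M, M),
    ).tocsr()

    c_diag = np.zeros(M)
    for a in range(3):
        np.add.at(c_diag, tri[:, a], area / 3.0)
    C = sp.diags(c_diag).tocsr()
    mesh._fem_cache = (C, G)
    return C, G


def spde_precision(mesh: Mesh, params: MaternParams) -> sp.csr_matrix:
    """Sparse GMRF precision Q(rho, sigma) of the SPDE-approximated field.

    Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G) with the lumped mass
    matrix C; tau is set from the stationary Matérn variance
    sigma^2 = 1 / (4 pi kappa^2 tau^2) for nu = 1 in two dimensions.
    """
    C, G = fem_matrices(mesh)
    kappa = params.kappa
    tau2 = 1.0 / (4.0 * np.pi * kappa**2 * params.sigma**2)
    Cinv = sp.diags(1.0 / C.diagonal())
    Q = tau2 * (kappa**4 * C + 2.0 * kappa**2 * G + G @ Cinv @ G)
    Q = (Q + Q.T) * 0.5  # exact symmetry against round-off
    return Q.tocsr()


def make_projector(mesh: Mesh, points: np.ndarray) -> sp.csr_matrix:
    """Sparse barycentric projector A: rows = points, columns = mesh nodes.

    Row r holds the piecewise-linear basis weights of point r in its
    containing triangle, so (A z)_r = Z*(s_r).  Points outside the
    extended mesh raise an error naming the first offender.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    h = mesh.spacing
    ny, nx = mesh.shape
    loc = (pts - mesh.origin) / h
    eps = 1e-9
    inside = (
        (loc[:, 0] >= -eps)
        & (loc[:, 0] <= nx - 1 + eps)
        & (loc[:, 1] >= -eps)
        & (loc[:, 1] <= ny - 1 + eps)
    )
    if not np.all(inside):
        bad = pts[~inside][0]
        raise ValueError(f"point ({bad[0]:.3f}, {bad[1]:.3f}) lies outside the mesh")
    ix = np.clip(np.floor(loc[:, 0] - eps).astype(int), 0, nx - 2)
    iy = np.clip(np.floor(loc[:, 1] - eps).astype(int), 0, ny - 2)
    u = loc[:, 0] - ix
    v = loc[:, 1] - iy
    base = iy * nx + ix
    n = pts.shape[0]
    rows = np.repeat(np.arange(n), 3)
    cols = np.empty((n, 3), dtype=np.int64)
    wts = np.empty((n, 3))
    lower = u + v <= 1.0
    # lower triangle (a, b, d=... see build_mesh): vertices (a, a+1, a+nx)
    cols[lower, 0] = base[lower]
    cols[lower, 1] = base[lower] + 1
    cols[lower, 2] = base[lower] + nx
    wts[lower, 0] = 1.0 - u[lower] - v[lower]
    wts[lower, 1] = u[lower]
    wts[lower, 2] = v[lower]
    up = ~lower
    # upper triangle: vertices (a+1+nx, a+nx, a+1)
    cols[up, 0] = base[up] + nx + 1
    cols[up, 1] = base[up] + nx
    cols[up, 2] = base[up] + 1
    wts[up, 0] = u[up] + v[up] - 1.0
    wts[up, 1] = 1.0 - u[up]
    wts[up, 2] = 1.0 - v[up]
    A = sp.coo_matrix(
        (wts.ravel(), (rows, cols.ravel())), shape=(n, mesh.n_nodes)
    ).tocsr()
    return A
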