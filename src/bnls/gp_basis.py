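"""Truncated eigen-basis of the Gaussian-process prior on the level-set field.

The level-set function phi is given a mean-zero GP prior with a squared-
exponential covariance kernel.  On the fixed voxel grid the prior is a
p-dimensional Gaussian whose covariance is the kernel matrix K; phi is
represented by the truncated Karhunen-Loeve expansion

    phi(v_j) = sum_l beta_l psi_l(v_j),   beta_l ~ N(0, lambda_l),

where (lambda_l, psi_l) are the leading eigenpairs of K and the truncation
order L is the smallest integer whose cumulative eigenvalue share reaches a
target proportion alpha (typically 0.7-0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid",
    "KernelSpec",
    "BasisExpansion",
    "kernel_eval",
    "build_basis",
    "sample_gp_field",
]

# Numerical-eigenvalue floor, relative to the largest eigenvalue.  PSD kernels
# routinely produce tiny negative eigenvalues in floating point; anything below
# this is clipped before truncation.
EIGVAL_CLIP_REL = 1e-10

# Dense eigendecomposition is used up to this many voxels for irregular point
# sets; larger problems fall back to a Nystrom approximation.
DENSE_EIG_MAX_P = 10_000
NYSTROM_LANDMARKS = 2_000
NYSTROM_SEED = 0


@dataclass(frozen=True)
class Grid:
    """Regular voxel grid with centers mapped affinely into [-1, 1]^dim.

    ``coords`` holds the p voxel-center coordinates in C order (last axis
    fastest); ``axes`` holds the per-axis coordinate vectors when the grid is a
    tensor product (None for irregular point sets read from a mask).
    """

    shape: tuple[int, ...]
    coords: np.ndarray
    axes: tuple[np.ndarray, ...] | None = None

    @property
    def dim(self) -> int:
        return len(self.shape)

    @property
    def p(self) -> int:
        return self.coords.shape[0]

    @staticmethod
    def regular(shape) -> "Grid":
        """Build a full regular grid with cell-center coordinates.

        Axis i of length n has centers ``-1 + (2j+1)/n`` for j = 0..n-1.
        """
        shape = tuple(int(s) for s in shape)
        if len(shape) not in (2, 3):
            raise ValueError(f"grid must be 2D or 3D, got shape {shape}")
        if any(s < 1 for s in shape):
            raise ValueError(f"grid axes must be positive, got {shape}")
        axes = tuple(-1.0 + (2.0 * np.arange(n) + 1.0) / n for n in shape)
        mesh = np.meshgrid(*axes, indexing="ij")
        coords = np.column_stack([m.ravel(order="C") for m in mesh])
        return Grid(shape=shape, coords=coords, axes=axes)

    @staticmethod
    def from_points(coords: np.ndarray) -> "Grid":
        """Irregular voxel set (e.g. the voxels of a brain-region mask)."""
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise ValueError("coords must be (p, dim) with dim in {2, 3}")
        return Grid(shape=(coords.shape[0],), coords=coords, axes=None)


@dataclass(frozen=True)
class KernelSpec:
    """Squared-exponential kernel kappa(v, v') = variance * exp(-inverse_scale * ||v - v'||^2).

    ``inverse_scale`` defaults to the value used in the simulation studies.
    """

    inverse_scale: float = 10.0
    variance: float = 1.0
    family: str = "squared-exponential"

    def __post_init__(self):
        if self.family != "squared-exponential":
            raise ValueError(f"unknown kernel family {self.family!r}")
        if not (self.inverse_scale > 0 and self.variance > 0):
            raise ValueError("inverse_scale and variance must be positive")


@dataclass
class BasisExpansion:
    """Truncated KL basis: eigenvalues, evaluated eigenvectors and bookkeeping.

    ``Psi`` is p x L with orthonormal columns (unit Euclidean norm on the voxel
    grid); ``eigenvalues`` is nonincreasing and positive.  ``Lambda`` (the
    prior covariance of beta) is ``diag(eigenvalues)``.
    """

    eigenvalues: np.ndarray
    Psi: np.ndarray
    alpha: float
    total_variance: float
    grid: Grid = field(repr=False)

    @property
    def L(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def Lambda(self) -> np.ndarray:
        return np.diag(self.eigenvalues)


def kernel_eval(points_a, points_b, spec: KernelSpec) -> np.ndarray:
    """Kernel matrix K[a, b] = kappa(v_a, v_b) between two coordinate sets."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"coordinate dimension mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    sq = (
        np.sum(a * a, axis=1)[:, None]
        - 2.0 * (a @ b.T)
        + np.sum(b * b, axis=1)[None, :]
    )
    np.maximum(sq, 0.0, out=sq)
    return spec.variance * np.exp(-spec.inverse_scale * sq)


def _truncate(eigvals: np.ndarray, alpha: float, total: float) -> int:
    """Smallest L with cumulative eigenvalue share >= alpha."""
    cum = np.cumsum(eigvals)
    L = int(np.searchsorted(cum, alpha * total, side="left")) + 1
    return min(L, eigvals.shape[0])


def _eig_tensor(grid: Grid, spec: KernelSpec):
    """Exact eigenpairs via the Kronecker structure of a separable kernel on a
    tensor grid: K = variance * K_1 (x) ... (x) K_d, so eigenvalues are products
    of per-axis eigenvalues and eigenvectors are Kronecker products."""
    axis_eigs = []
    for ax in grid.axes:
        K1 = np.exp(-spec.inverse_scale * (ax[:, None] - ax[None, :]) ** 2)
        lam, vec = np.linalg.eigh(K1)
        axis_eigs.append((lam[::-1].copy(), vec[:, ::-1].copy()))
    lams = [e[0] for e in axis_eigs]
    prod = lams[0]
    for l in lams[1:]:
        prod = np.multiply.outer(prod, l)
    flat = spec.variance * prod.ravel()
    order = np.argsort(-flat, kind="stable")
    return flat, order, axis_eigs, prod.shape


def _psi_from_tensor(order, axis_eigs, tshape, L, p):
    Psi = np.empty((p, L))
    idx = np.unravel_index(order[:L], tshape)
    for l in range(L):
        col = axis_eigs[0][1][:, idx[0][l]]
        for d in range(1, len(axis_eigs)):
            col = np.multiply.outer(col, axis_eigs[d][1][:, idx[d][l]])
        Psi[:, l] = col.ravel(order="C")
    return Psi


def build_basis(grid: Grid, spec: KernelSpec, alpha: float) -> BasisExpansion:
    """Eigendecompose the kernel on the grid and truncate at variance share alpha.

    Returns the minimal L such that (sum of the leading L eigenvalues) /
    (sum of all eigenvalues) >= alpha.  For regular tensor grids the exact
    Kronecker factorization of the separable kernel is used; irregular point
    sets use a dense symmetric eigendecomposition (p <= 10,000) or a Nystrom
    approximation with 2,000 landmark voxels above that.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    p = grid.p
    if p == 0:
        raise ValueError("empty grid")

    if grid.axes is not None:
        flat, order, axis_eigs, tshape = _eig_tensor(grid, spec)
        clip = EIGVAL_CLIP_REL * flat[order[0]]
        total = float(np.sum(np.maximum(flat, clip)))
        sorted_vals = np.maximum(flat[order], clip)
        L = _truncate(sorted_vals, alpha, total)
        Psi = _psi_from_tensor(order, axis_eigs, tshape, L, p)
        eigvals = sorted_vals[:L]
    elif p <= DENSE_EIG_MAX_P:
        K = kernel_eval(grid.coords, grid.coords, spec)
        lam, vec = np.linalg.eigh(K)
        lam, vec = lam[::-1].copy(), vec[:, ::-1].copy()
        clip = EIGVAL_CLIP_REL * lam[0]
        if np.any(lam < -clip):
            import warnings

            warnings.warn(
                "kernel matrix has negative eigenvalues beyond tolerance; "
                "clipping", RuntimeWarning,
            )
        lam = np.maximum(lam, clip)
        total = float(lam.sum())
        L = _truncate(lam, alpha, total)
        eigvals, Psi = lam[:L], vec[:, :L]
    else:
        rng = np.random.default_rng(NYSTROM_SEED)
        land = np.sort(rng.choice(p, size=NYSTROM_LANDMARKS, replace=False))
        Kmm = kernel_eval(grid.coords[land], grid.coords[land], spec)
        Kpm = kernel_eval(grid.coords, grid.coords[land], spec)
        lam_m, U = np.linalg.eigh(Kmm)
        lam_m, U = lam_m[::-1].copy(), U[:, ::-1].copy()
        keep = lam_m > EIGVAL_CLIP_REL * lam_m[0]
        lam_m, U = lam_m[keep], U[:, keep]
        # Nystrom feature map F with K ~= F F^T; exact eigenpairs of the
        # approximant via the small Gram matrix F^T F.
        F = Kpm @ (U / np.sqrt(lam_m))
        s, V = np.linalg.eigh(F.T @ F)
        s, V = s[::-1].copy(), V[:, ::-1].copy()
        clip = EIGVAL_CLIP_REL * s[0]
        keep2 = s > clip
        s, V = s[keep2], V[:, keep2]
        total = p * spec.variance  # exact trace of K
        L = _truncate(s, alpha, total)
        eigvals, Psi = s[:L], (F @ V[:, :L]) / np.sqrt(s[:L])

    return BasisExpansion(
        eigenvalues=np.asarray(eigvals, dtype=float),
        Psi=np.ascontiguousarray(Psi, dtype=float),
        alpha=float(alpha),
        total_variance=float(total),
        grid=grid,
    )


def sample_gp_field(basis: BasisExpansion, seed) -> np.ndarray:
    """Draw phi = Psi beta with beta_l ~ N(0, lambda_l) (truncated GP prior).

    ``seed`` may be an int or a numpy Generator; a fixed int seed gives a
    deterministic field.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta = rng.standard_normal(basis.L) * np.sqrt(basis.eigenvalues)
    return basis.Psi @ beta
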