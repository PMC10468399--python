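"""PCA of latent vectors, ensemble density maps and overlap scoring.

Latent window embeddings are projected onto the first two principal
components of a reference set (by design, the protein or synthetic-protein
windows; polymer ensembles are projected into that fixed space).  Sign
conventions make the axes interpretable: PC1 is oriented so its score
correlates non-negatively with predicted HLB — more hydrophobic segments
sit at *lower* PC1 — and PC2 so its skewness over the reference set is
non-negative.

Each ensemble's occupied region of the (PC1, PC2) plane is summarized by
a Gaussian kernel density estimate (Scott's-rule bandwidth) on a shared
regular grid.  Pairwise similarity between ensembles is quantified by the
Bhattacharyya coefficient sum(sqrt(p*q)) over grid cells — a bounded,
symmetric overlap score equal to 1 iff the densities coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .latent_model import LatentEmbedding

__all__ = [
    "PcaBasis",
    "PcaProjection",
    "DensityGrid",
    "fit_pca",
    "project",
    "kde_map",
    "shared_grid",
    "overlap_score",
    "overlap_matrix",
    "occupied_area",
    "convergence_curve",
]


@dataclass
class PcaBasis:
    """Top-2 principal axes of a reference embedding set."""

    mean: np.ndarray                 # (d,)
    components: np.ndarray           # (2, d) orthonormal rows
    explained_variance_ratio: np.ndarray  # (2,)
    sign_convention: dict[str, str]

    def __post_init__(self) -> None:
        g = self.components @ self.components.T
        if not np.allclose(g, np.eye(2), atol=1e-8):
            raise ValueError("components must be orthonormal")


@dataclass
class PcaProjection:
    """(PC1, PC2) coordinates of one ensemble's windows."""

    coords: np.ndarray   # (n, 2)
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite projection coordinates")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def pc1(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def pc2(self) -> np.ndarray:
        return self.coords[:, 1]


@dataclass
class DensityGrid:
    """Normalized 2D KDE on a regular grid, plus the two marginals."""

    x: np.ndarray          # (nx,) grid centres
    y: np.ndarray          # (ny,)
    density: np.ndarray    # (ny, nx), cell-weighted sum = 1
    bandwidth: float       # KDE scaling factor used
    marginal_x: np.ndarray
    marginal_y: np.ndarray

    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))


def fit_pca(latents: LatentEmbedding | np.ndarray,
            predicted_hlb: np.ndarray | None = None) -> PcaBasis:
    """Fit the 2-component PCA basis on a reference embedding set.

    Sign conventions: PC1 is flipped if needed so corr(PC1 score,
    predicted HLB) >= 0 (hydrophilic right, hydrophobic left); PC2 is
    flipped so the skewness of its reference scores is >= 0.
    """
    if isinstance(latents, LatentEmbedding):
        z = latents.z
        if predicted_hlb is None:
            predicted_hlb = latents.predicted_hlb
    else:
        z = np.asarray(latents, dtype=float)
    if len(z) < 3:
        raise ValueError("need at least 3 vectors to fit a PCA basis")
    if np.allclose(z.var(axis=0), 0.0):
        raise ValueError("degenerate covariance: all vectors identical")

    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(z)
    components = pca.components_.copy()
    convention = {"pc1": "none", "pc2": "none"}

    if predicted_hlb is not None and np.std(predicted_hlb) > 0:
        r = np.corrcoef(scores[:, 0], predicted_hlb)[0, 1]
        if r < 0:
            components[0] *= -1
            scores[:, 0] *= -1
            convention["pc1"] = "flipped"
    convention["pc1"] += " (corr with HLB >= 0)"

    if stats.skew(scores[:, 1]) < 0:
        components[1] *= -1
        convention["pc2"] = "flipped"
    convention["pc2"] += " (skewness >= 0)"

    return PcaBasis(
        mean=pca.mean_,
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        sign_convention=convention,
    )


def project(latents: LatentEmbedding | np.ndarray, basis: PcaBasis,
            label: str = "") -> PcaProjection:
    """Project embeddings into a fitted (PC1, PC2) space."""
    z = latents.z if isinstance(latents, LatentEmbedding) else np.asarray(latents, float)
    z = np.atleast_2d(z)
    return PcaProjection((z - basis.mean) @ basis.components.T, label=label)


def shared_grid(projections: Sequence[PcaProjection], resolution: int = 256,
                pad_bandwidths: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """A common grid covering every ensemble, padded by ~3 bandwidths.

    All densities to be compared must live on one grid so the overlap
    score is well defined.
    """
    pts = np.vstack([p.coords for p in projections])
    # Scott's-rule bandwidth of the pooled cloud sets the padding scale
    n = len(pts)
    scott = n ** (-1.0 / 6.0)
    pad = pad_bandwidths * scott * pts.std(axis=0, ddof=1)
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    x = np.linspace(lo[0], hi[0], resolution)
    y = np.linspace(lo[1], hi[1], resolution)
    return x, y


def kde_map(points: PcaProjection, grid: tuple[np.ndarray, np.ndarray] | None = None,
            resolution: int = 256) -> DensityGrid:
    """Gaussian KDE of one ensemble on a regular grid, plus 1D marginals.

    Bandwidth follows Scott's rule.  The 2D density and both marginals are
    normalized so their cell/bin-weighted sums equal 1.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points for a KDE")
    if grid is None:
        grid = shared_grid([points], resolution=resolution)
    x, y = grid
    kde = stats.gaussian_kde(points.coords.T, bw_method="scott")
    xx, yy = np.meshgrid(x, y)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(len(y), len(x))
    cell = (x[1] - x[0]) * (y[1] - y[0])
    dens /= dens.sum() * cell

    kx = stats.gaussian_kde(points.pc1, bw_method="scott")
    ky = stats.gaussian_kde(points.pc2, bw_method="scott")
    mx = kx(x)
    mx /= mx.sum() * (x[1] - x[0])
    my = ky(y)
    my /= my.sum() * (y[1] - y[0])

    return DensityGrid(
        x=x, y=y, density=dens, bandwidth=float(kde.factor),
        marginal_x=mx, marginal_y=my,
    )


def overlap_score(a: DensityGrid, b: DensityGrid) -> float:
    """Bhattacharyya coefficient between two densities on the same grid.

    Bounded in [0, 1], symmetric, and 1 iff the densities are identical.
    (The score is this package's quantification of ensemble overlap; the
    underlying comparison is otherwise qualitative.)
    """
    if a.density.shape != b.density.shape or not (
        np.allclose(a.x, b.x) and np.allclose(a.y, b.y)
    ):
        raise ValueError("densities must share an identical grid")
    cell = a.cell_area()
    bc = float(np.sqrt(a.density * b.density).sum() * cell)
    return min(bc, 1.0)


def overlap_matrix(projections: Sequence[PcaProjection],
                   resolution: int = 256) -> tuple[np.ndarray, list[str]]:
    """Pairwise overlap coefficients between ensembles on a shared grid."""
    grid = shared_grid(projections, resolution=resolution)
    grids = [kde_map(p, grid=grid) for p in projections]
    n = len(grids)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = overlap_score(grids[i], grids[j])
    labels = [p.label or str(i) for i, p in enumerate(projections)]
    return m, labels


def occupied_area(points: PcaProjection, mass: float = 0.95,
                  grid: tuple[np.ndarray, np.ndarray] | None = None,
                  resolution: int = 128) -> float:
    """Area of the KDE's highest-density region containing ``mass``.

    "Occupied PCA space" is defined here as the 95% highest-density
    region of the ensemble's kernel density estimate.
    """
    dg = kde_map(points, grid=grid, resolution=resolution)
    cell = dg.cell_area()
    p = np.sort(dg.density.ravel())[::-1] * cell
    csum = np.cumsum(p)
    k = int(np.searchsorted(csum, mass)) + 1
    return k * cell


def convergence_curve(coords: np.ndarray, sample_sizes: Sequence[int],
                      seed: int = 0, mass: float = 0.95,
                      resolution: int = 128) -> tuple[list[tuple[int, float]], int]:
    """Occupied area versus sample size, and the convergence point.

    Subsamples of increasing size are drawn (nested, seeded) from the
    projected ensemble; the returned convergence n is the smallest sample
    size whose occupied area is within 5% of the area at the largest n.
    """
    coords = np.asarray(coords, dtype=float)
    rng = np.random.default_rng(seed)
    sizes = sorted(set(int(n) for n in sample_sizes))
    if sizes[-1] > len(coords):
        raise ValueError("largest sample size exceeds available points")
    order = rng.permutation(len(coords))
    full = PcaProjection(coords[order[:sizes[-1]]])
    grid = shared_grid([full], resolution=resolution)
    table = []
    for n in sizes:
        sub = PcaProjection(coords[order[:n]])
        table.append((n, occupied_area(sub, mass=mass, grid=grid)))
    a_max = table[-1][1]
    n_conv = sizes[-1]
    for n, a in table:
        if abs(a - a_max) <= 0.05 * a_max:
            n_conv = n
            break
    return table, n_conv
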