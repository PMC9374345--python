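"""Two-dimensional diel trait spectra.

For each diel niche, the five transformed and standardized traits are reduced
to a 2-D ordination by PCA (covariance PCA on standardized traits, equal to
correlation PCA on the raw transforms).  A bivariate kernel density estimate
with an unconstrained (full-matrix) bandwidth describes the occurrence
probability of trait combinations across the spectrum; highest-density-region
contour levels are taken at the 0.5, 0.95 and 0.99 quantiles of the density
evaluated at the species themselves, so the q-region encloses a fraction q of
species.

Under a functional-extinction scenario, the density of the surviving species
is refit (with its own bandwidth) on the same grid, both surfaces are
max-normalized, and two statistics summarize the reorganization inside the
full spectrum's 0.99 region:

* ``mean_abs_density_change`` — mean absolute difference of the normalized
  densities over cells in the full 0.99 region;
* ``volume_loss`` — the fraction of full-0.99 cells falling outside the
  survivors' 0.99 region (trait combinations whose boundary support is lost).

A randomization null removes the same number of species uniformly from the
niche and rebuilds both statistics, yielding a 95% interval against which the
observed, threat-ordered removal is compared.

Bandwidth selection follows the 2-stage unconstrained plug-in family with a
single SAMSE (sum of asymptotic mean-squared error) scalar pilot estimated on
sphered data; a closed-form normal-scale selector ``H = n^(-1/3) * Sigma`` is
available as a fast, robust alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import eval_hermitenorm

from .traits import TransformedTraits

__all__ = [
    "SpectrumBasis",
    "GridSpec",
    "DensityGrid",
    "ChangeResult",
    "NullResult",
    "fit_pca",
    "plugin_bandwidth",
    "normal_scale_bandwidth",
    "fit_kde",
    "hdr_levels",
    "density_change",
    "spectrum_null",
    "spectrum_scenario_stats",
]

HDR_QUANTILES = (0.5, 0.95, 0.99)


# ---------------------------------------------------------------------------
# PCA basis
# ---------------------------------------------------------------------------

@dataclass
class SpectrumBasis:
    """2-D PCA basis of a diel niche's trait space."""

    loadings: pd.DataFrame  # traits × PCs (all components kept)
    scores: pd.DataFrame  # species × first two PCs
    pct_variation: np.ndarray  # per component, sums to 100
    center: pd.Series

    def project(self, traits: TransformedTraits) -> np.ndarray:
        """Project (possibly a subset of) species onto the first two PCs."""
        X = traits.values[self.center.index].to_numpy(float) - self.center.to_numpy()
        return X @ self.loadings.to_numpy()[:, :2]


def fit_pca(traits: TransformedTraits, ids=None) -> SpectrumBasis:
    """Covariance PCA of the transformed traits of one niche.

    Component signs are fixed so the body-mass loading is non-negative
    (falling back to the largest-magnitude loading for components where it is
    zero), making score orientation reproducible.  Rank deficiency produces a
    warning, not an error.
    """
    tt = traits if ids is None else traits.subset(ids)
    if len(tt.values) < 3:
        raise ValueError("PCA needs at least 3 species")
    X = tt.matrix()
    center = tt.values.mean()
    Xc = X - center.to_numpy()
    C = np.cov(Xc, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    if eigval[1] <= 1e-12 * max(eigval[0], 1.0):
        warnings.warn("rank-deficient trait matrix; spectrum may be degenerate")

    cols = list(tt.values.columns)
    mass_row = cols.index("log10_body_mass")
    for j in range(eigvec.shape[1]):
        pivot = eigvec[mass_row, j]
        if abs(pivot) < 1e-12:
            pivot = eigvec[np.argmax(np.abs(eigvec[:, j])), j]
        if pivot < 0:
            eigvec[:, j] *= -1.0
    pct = 100.0 * eigval / eigval.sum()
    loadings = pd.DataFrame(
        eigvec, index=cols, columns=[f"PC{i + 1}" for i in range(len(cols))]
    )
    scores = pd.DataFrame(
        Xc @ eigvec[:, :2], index=tt.values.index, columns=["PC1", "PC2"]
    )
    return SpectrumBasis(loadings, scores, pct, center)


# ---------------------------------------------------------------------------
# Bandwidth selection
# ---------------------------------------------------------------------------

def normal_scale_bandwidth(scores: np.ndarray) -> np.ndarray:
    """Normal-reference bandwidth matrix for d = 2: ``H = n^(-1/3) Sigmâ``.

    This is the AMISE-optimal bandwidth when the underlying density is
    bivariate normal (the constant ``(4/(d+2))^(2/(d+4))`` equals 1 at d=2).
    """
    X = np.asarray(scores, dtype=float)
    n = len(X)
    S = np.cov(X, rowvar=False, ddof=1)
    if np.linalg.det(S) <= 0:
        raise ValueError("singular score covariance; jitter the scores")
    return n ** (-1.0 / 3.0) * S


def _norm_deriv0(r: tuple[int, int]) -> float:
    """D^r of the standard bivariate normal density at the origin."""

    def he0(k: int) -> float:
        if k % 2:
            return 0.0
        # He_k(0) = (-1)^(k/2) (k-1)!!
        out = 1.0
        for m in range(1, k, 2):
            out *= m
        return (-1.0) ** (k // 2) * out

    return (-1.0) ** sum(r) * he0(r[0]) * he0(r[1]) / (2.0 * math.pi)


def _psi_normal(r: tuple[int, int], sigma2: float = 1.0) -> float:
    """psi_r functional for f = N(0, sigma2 * I): (-1)^|r| D^r phi_{2 sigma2 I}(0)."""
    s = math.sqrt(2.0 * sigma2)
    # product form: each 1-D factor sigma^-(k+1) phi^(k)(0), joint carries 1/(2 pi)
    def fac(k: int) -> float:
        if k % 2:
            return 0.0
        df = 1.0
        for m in range(1, k, 2):
            df *= m
        return (-1.0) ** (k // 2) * df / s**k

    val = fac(r[0]) * fac(r[1]) / (2.0 * math.pi * s**2)
    return (-1.0) ** sum(r) * val


def _psi_hat_batch(
    X: np.ndarray, rs: list[tuple[int, int]], g: float, block: int = 256
) -> dict[tuple[int, int], float]:
    """Kernel estimators psi_r(g) = n^-2 sum_ij D^r phi_{g^2 I}(X_i - X_j).

    All requested multi-indices share one pass over the pairwise differences.
    """
    n = len(X)
    orders = sorted({k for r in rs for k in r})
    totals = {r: 0.0 for r in rs}
    for i0 in range(0, n, block):
        d = (X[i0 : i0 + block, None, :] - X[None, :, :]) / g
        phi = np.exp(-0.5 * (d**2).sum(axis=-1)) / (2.0 * math.pi)
        he = {
            (ax, k): eval_hermitenorm(k, d[..., ax]) for ax in (0, 1) for k in orders
        }
        for r in rs:
            sign = (-1.0) ** (r[0] + r[1])
            totals[r] += sign * float(
                (he[(0, r[0])] * he[(1, r[1])] * phi).sum()
            ) * g ** (-(2 + r[0] + r[1]))
    return {r: t / n**2 for r, t in totals.items()}


def _samse_pilot(n: int, psi6: dict[tuple[int, int], float]) -> float:
    """Common scalar pilot g minimizing the summed asymptotic MSE of the
    fourth-order functional estimates (Duong-Hazelton SAMSE family)."""
    r4 = [(4, 0), (3, 1), (2, 2), (1, 3), (0, 4)]

    def crit(logg: float) -> float:
        g = math.exp(logg)
        total = 0.0
        for r in r4:
            diag = _norm_deriv0(r) * g ** (-(2 + 4)) / n
            bias = 0.5 * g**2 * (
                psi6[(r[0] + 2, r[1])] + psi6[(r[0], r[1] + 2)]
            )
            total += (diag + bias) ** 2
        return total

    res = minimize_scalar(crit, bounds=(math.log(1e-3), math.log(10.0)), method="bounded")
    return math.exp(res.x)


def plugin_bandwidth(scores: np.ndarray, method: str = "plugin") -> np.ndarray:
    """Unconstrained bandwidth matrix for a 2-D KDE.

    ``method="plugin"`` runs the 2-stage plug-in: the data are sphered, sixth-
    order density functionals are taken at their normal-scale values, a single
    SAMSE-optimal scalar pilot estimates the five fourth-order functionals,
    and the asymptotic MISE surrogate is minimized over symmetric positive-
    definite H (Cholesky parametrization, normal-scale start).  The result is
    mapped back to the original scale.  ``method="normal_scale"`` returns the
    closed-form normal-reference matrix.
    """
    X = np.asarray(scores, dtype=float)
    n = len(X)
    if n < 10:
        raise ValueError("bandwidth selection needs at least 10 points")
    if method == "normal_scale":
        return normal_scale_bandwidth(X)
    if method != "plugin":
        raise ValueError(f"unknown bandwidth method {method!r}")

    S = np.cov(X, rowvar=False, ddof=1)
    if np.linalg.det(S) <= 0:
        raise ValueError("singular score covariance; jitter the scores")
    eigval, eigvec = np.linalg.eigh(S)
    S_half = eigvec @ np.diag(np.sqrt(eigval)) @ eigvec.T
    S_invhalf = eigvec @ np.diag(1.0 / np.sqrt(eigval)) @ eigvec.T
    Z = (X - X.mean(axis=0)) @ S_invhalf  # sphered: unit covariance

    # stage 1: normal-scale 6th-order functionals on sphered data
    psi6 = {
        r: _psi_normal(r)
        for r in ((6, 0), (5, 1), (4, 2), (3, 3), (2, 4), (1, 5), (0, 6))
    }
    g = _samse_pilot(n, psi6)

    # stage 2: estimate 4th-order functionals with the common pilot
    r4 = [(4, 0), (3, 1), (2, 2), (1, 3), (0, 4)]
    psi4 = _psi_hat_batch(Z, r4, g)

    inv4pi = 1.0 / (4.0 * math.pi)

    def pi_crit(theta: np.ndarray) -> float:
        a, b, c = theta
        l11, l22 = math.exp(a), math.exp(c)
        h11 = l11 * l11
        h12 = l11 * b
        h22 = b * b + l22 * l22
        det = h11 * h22 - h12 * h12
        if det <= 0:
            return np.inf
        bias = (
            h11**2 * psi4[(4, 0)]
            + 4.0 * h12**2 * psi4[(2, 2)]
            + h22**2 * psi4[(0, 4)]
            + 4.0 * h11 * h12 * psi4[(3, 1)]
            + 2.0 * h11 * h22 * psi4[(2, 2)]
            + 4.0 * h12 * h22 * psi4[(1, 3)]
        )
        return inv4pi / (n * math.sqrt(det)) + 0.25 * bias

    h0 = n ** (-1.0 / 3.0)  # normal-scale start on sphered scale
    x0 = np.array([0.5 * math.log(h0), 0.0, 0.5 * math.log(h0)])
    res = minimize(pi_crit, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    a, b, c = res.x
    l11, l22 = math.exp(a), math.exp(c)
    Hs = np.array(
        [[l11 * l11, l11 * b], [l11 * b, b * b + l22 * l22]]
    )
    H = S_half @ Hs @ S_half
    return (H + H.T) / 2.0


# ---------------------------------------------------------------------------
# KDE on a grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Regular evaluation grid (cell centers) for the spectrum surface."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    nx: int = 151
    ny: int = 151

    @classmethod
    def from_scores(cls, scores: np.ndarray, expand: float = 0.1, n: int = 151) -> "GridSpec":
        """Grid spanning the score range expanded by ``expand`` per side."""
        X = np.asarray(scores, dtype=float)
        lo, hi = X.min(axis=0), X.max(axis=0)
        pad = (hi - lo) * expand
        pad = np.where(pad > 0, pad, 1.0)
        return cls(lo[0] - pad[0], hi[0] + pad[0], lo[1] - pad[1], hi[1] + pad[1], n, n)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.xmin, self.xmax, self.nx)

    @property
    def y(self) -> np.ndarray:
        return np.linspace(self.ymin, self.ymax, self.ny)

    @property
    def cell_area(self) -> float:
        dx = (self.xmax - self.xmin) / (self.nx - 1)
        dy = (self.ymax - self.ymin) / (self.ny - 1)
        return dx * dy

    def points(self) -> np.ndarray:
        gx, gy = np.meshgrid(self.x, self.y, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    def covers(self, scores: np.ndarray) -> bool:
        X = np.asarray(scores, dtype=float)
        return bool(
            (X[:, 0] >= self.xmin).all()
            and (X[:, 0] <= self.xmax).all()
            and (X[:, 1] >= self.ymin).all()
            and (X[:, 1] <= self.ymax).all()
        )


def _kde_eval(points: np.ndarray, data: np.ndarray, H: np.ndarray, block: int = 256) -> np.ndarray:
    """Gaussian KDE f̂(x) = n^-1 sum_i phi_H(x - X_i) at arbitrary points."""
    data = np.asarray(data, dtype=float)
    points = np.asarray(points, dtype=float)
    n = len(data)
    Hinv = np.linalg.inv(H)
    norm = 1.0 / (2.0 * math.pi * math.sqrt(np.linalg.det(H)))
    out = np.empty(len(points))
    for i0 in range(0, len(points), block):
        d = points[i0 : i0 + block, None, :] - data[None, :, :]
        q = (
            Hinv[0, 0] * d[..., 0] ** 2
            + 2.0 * Hinv[0, 1] * d[..., 0] * d[..., 1]
            + Hinv[1, 1] * d[..., 1] ** 2
        )
        out[i0 : i0 + block] = np.exp(-0.5 * q).sum(axis=1)
    return out * norm / n


@dataclass
class DensityGrid:
    """KDE of a spectrum evaluated on a regular grid."""

    grid: GridSpec
    density: np.ndarray  # shape (nx, ny), indexed [ix, iy]
    bandwidth: np.ndarray  # 2×2 SPD
    data: np.ndarray  # the n×2 scores the KDE was fitted on
    levels: dict[float, float] = field(default_factory=dict)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        return _kde_eval(points, self.data, self.bandwidth)

    @property
    def integral(self) -> float:
        return float(self.density.sum() * self.grid.cell_area)

    def to_frame(self) -> pd.DataFrame:
        pts = self.grid.points()
        ix, iy = np.meshgrid(
            np.arange(self.grid.nx), np.arange(self.grid.ny), indexing="ij"
        )
        return pd.DataFrame(
            {
                "x_index": ix.ravel(),
                "y_index": iy.ravel(),
                "x": pts[:, 0],
                "y": pts[:, 1],
                "value": self.density.ravel(),
            }
        )


def fit_kde(scores: np.ndarray, H: np.ndarray, grid: GridSpec) -> DensityGrid:
    """Evaluate the Gaussian KDE with full bandwidth matrix H on a grid.

    The grid must cover all scores, otherwise boundary statistics downstream
    would silently truncate the spectrum.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("scores must be n×2")
    if len(X) == 0:
        raise ValueError("cannot fit a spectrum on an empty species set")
    if not grid.covers(X):
        raise ValueError("grid does not cover all scores")
    H = np.asarray(H, dtype=float)
    dens = _kde_eval(grid.points(), X, H).reshape(grid.nx, grid.ny)
    return DensityGrid(grid, dens, H, X)


def hdr_levels(
    kde: DensityGrid, scores: np.ndarray | None = None, quantiles=HDR_QUANTILES
) -> dict[float, float]:
    """Highest-density-region contour levels.

    The level for mass q is the (1 - q) empirical quantile of the density
    evaluated at the sample points themselves, so the region
    {x : f̂(x) >= level} contains a fraction ~q of species.  Levels are
    non-increasing in q.
    """
    X = kde.data if scores is None else np.asarray(scores, dtype=float)
    for q in quantiles:
        if not 0.0 < q < 1.0:
            raise ValueError(f"HDR quantile {q} outside (0, 1)")
    dens_at = kde.evaluate(X)
    levels = {float(q): float(np.quantile(dens_at, 1.0 - q)) for q in quantiles}
    kde.levels.update(levels)
    return levels


# ---------------------------------------------------------------------------
# Change statistics and null model
# ---------------------------------------------------------------------------

@dataclass
class ChangeResult:
    """Reorganization of a spectrum between the full and survivor KDEs."""

    delta: np.ndarray  # per-cell survivor - full (max-normalized), NaN outside
    boundary_loss_mask: np.ndarray  # inside full 0.99, outside survivor 0.99
    mean_abs_density_change: float
    volume_loss: float


def density_change(
    full: DensityGrid,
    survivors: DensityGrid,
    boundary_quantile: float = 0.99,
    relative: str = "difference",
) -> ChangeResult:
    """Density-difference statistics inside the full spectrum's 0.99 region.

    Both surfaces are converted to proportions of their own maximum; the
    per-cell change is their difference (``relative="ratio"`` instead divides
    the difference by the full-spectrum proportion).  ``volume_loss`` is the
    fraction of full-0.99 cells that fall outside the survivors' 0.99 region.
    Both grids must share the same :class:`GridSpec` and carry HDR levels for
    the boundary quantile (computed on demand from their own data).
    """
    if full.grid != survivors.grid:
        raise ValueError("full and survivor KDEs must share one grid")
    q = float(boundary_quantile)
    for g in (full, survivors):
        if q not in g.levels:
            hdr_levels(g, quantiles=(q,))
    p_full = full.density / full.density.max()
    p_surv = survivors.density / survivors.density.max()
    region = full.density >= full.levels[q]
    if relative == "difference":
        d = p_surv - p_full
    elif relative == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(p_full > 0, (p_surv - p_full) / p_full, 0.0)
    else:
        raise ValueError(f"unknown relative mode {relative!r}")
    delta = np.where(region, d, np.nan)
    lost = region & (survivors.density < survivors.levels[q])
    n_region = int(region.sum())
    mean_abs = float(np.abs(d[region]).mean()) if n_region else 0.0
    vol = float(lost.sum() / n_region) if n_region else 0.0
    return ChangeResult(delta, lost, mean_abs, vol)


@dataclass
class NullResult:
    """An observed statistic against its randomization null distribution."""

    observed: float
    null_values: np.ndarray
    seed: int
    reps: int

    @property
    def interval(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.null_values, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def exceeds_upper(self) -> bool:
        return self.observed > self.interval[1]

    @property
    def inside(self) -> bool:
        lo, hi = self.interval
        return lo <= self.observed <= hi


def _change_stats(
    scores: np.ndarray,
    survivor_idx: np.ndarray,
    full_kde: DensityGrid,
    bandwidth: str,
    relative: str = "difference",
) -> ChangeResult:
    surv_scores = scores[survivor_idx]
    H = plugin_bandwidth(surv_scores, method=bandwidth)
    surv_kde = fit_kde(surv_scores, H, full_kde.grid)
    return density_change(full_kde, surv_kde, relative=relative)


def spectrum_null(
    scores: np.ndarray,
    removed_mask: np.ndarray,
    reps: int = 100,
    seed: int = 0,
    bandwidth: str = "plugin",
    grid: GridSpec | None = None,
    relative: str = "difference",
) -> dict[str, NullResult]:
    """Observed spectrum-change statistics vs a random-removal null.

    Each of ``reps`` repetitions removes ``removed_mask.sum()`` species drawn
    uniformly without replacement from the niche, then recomputes both change
    statistics against the same full-spectrum KDE, grid, and 0.99 reference
    region.  Reproducible given ``seed`` (per-repetition substreams are
    spawned from a single master seed).
    """
    scores = np.asarray(scores, dtype=float)
    removed_mask = np.asarray(removed_mask, dtype=bool)
    n = len(scores)
    n_removed = int(removed_mask.sum())
    if n_removed >= n:
        raise ValueError("cannot remove every species from the spectrum")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    if grid is None:
        grid = GridSpec.from_scores(scores)
    H_full = plugin_bandwidth(scores, method=bandwidth)
    full_kde = fit_kde(scores, H_full, grid)
    hdr_levels(full_kde)

    observed = _change_stats(scores, ~removed_mask, full_kde, bandwidth, relative)
    obs_change = observed.mean_abs_density_change
    obs_vol = observed.volume_loss

    master = np.random.SeedSequence(seed)
    null_change = np.empty(reps)
    null_vol = np.empty(reps)
    for r, child in enumerate(master.spawn(reps)):
        rng = np.random.default_rng(child)
        if n_removed == 0:
            null_change[r] = 0.0
            null_vol[r] = 0.0
            continue
        rm = rng.choice(n, size=n_removed, replace=False)
        keep = np.ones(n, dtype=bool)
        keep[rm] = False
        res = _change_stats(scores, keep, full_kde, bandwidth, relative)
        null_change[r] = res.mean_abs_density_change
        null_vol[r] = res.volume_loss
    return {
        "mean_abs_density_change": NullResult(obs_change, null_change, seed, reps),
        "volume_loss": NullResult(obs_vol, null_vol, seed, reps),
        "observed_change": observed,
    }


def spectrum_scenario_stats(
    scores: np.ndarray,
    removed_mask: np.ndarray,
    bandwidth: str = "plugin",
    grid: GridSpec | None = None,
    relative: str = "difference",
) -> ChangeResult:
    """Observed change statistics for one (niche, scenario) without the null."""
    scores = np.asarray(scores, dtype=float)
    removed_mask = np.asarray(removed_mask, dtype=bool)
    if removed_mask.sum() >= len(scores):
        raise ValueError("cannot remove every species from the spectrum")
    if grid is None:
        grid = GridSpec.from_scores(scores)
    full_kde = fit_kde(scores, plugin_bandwidth(scores, bandwidth), grid)
    hdr_levels(full_kde)
    surv = scores[~removed_mask]
    surv_kde = fit_kde(surv, plugin_bandwidth(surv, bandwidth), grid)
    return density_change(full_kde, surv_kde, relative=relative)
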