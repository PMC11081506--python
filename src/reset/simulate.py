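"""Synthetic scRNA-seq count matrices with a planted informative block.

Counts are independent negative binomial draws with fixed dispersion and
per-gene means from a shifted exponential (mean_j = base + Exp(rate)). One
rectangle of the matrix — the informative genes crossed with the
informative cells — receives inflated means and exchangeable pairwise
correlation, induced through a Gaussian copula whose latent correlation is
Monte-Carlo calibrated so the realized count-scale Pearson correlation
matches the requested value.

Four designs are supported:

block
    One gene set; its genes get inflated, correlated counts in a subset of
    cells. Ground truth for sample-level classification.
complex
    The first set is split into two halves with distinct structure: the
    first half is correlated across *all* cells (an uninformative dominant
    component), the second half carries the inflated, correlated block in
    the informative cells. The label signal therefore sits on the set
    sub-matrix's second principal component, not its first.
self_contained
    A single set containing every gene; all genes are informative for the
    informative cells.
competitive
    Every cell is informative for the first of several disjoint equally
    sized sets; detecting it requires comparing scores across sets.

Defaults emulate a 2,000-cell x 500-gene matrix with a 50-gene set,
200 informative cells, 3x mean inflation, pairwise correlation 0.2, unit
baseline mean, unit exponential rate and NB dispersion theta = 1
(variance mu + mu^2/theta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse, stats
from scipy.special import ndtr

from .core import ExpressionMatrix
from .genesets import AnnotationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationDesign",
    "SimulatedDataset",
    "draw_gene_means",
    "simulate_counts",
    "log_normalize",
]

_DESIGNS = ("block", "complex", "self_contained", "competitive")


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one simulated data set. See the module docstring."""

    design: str = "block"
    n_cells: int = 2000
    n_genes: int = 500
    set_size: int = 50
    n_sets: int | None = None  # resolved: 1 (block/complex/self_contained), 5 (competitive)
    mean_inflation: float = 3.0
    correlation: float = 0.2
    n_informative_cells: int = 200
    nb_mean: float = 1.0  # baseline NB mean for the informative genes
    background_mean: float = 1.0
    exp_rate: float = 1.0
    nb_dispersion: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.design not in _DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; expected one of {_DESIGNS}")
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("correlation must be in [0, 1)")
        if self.design != "competitive" and self.n_informative_cells > self.n_cells:
            # competitive ignores the field: every cell is informative
            raise ValueError("n_informative_cells exceeds n_cells")
        if self.resolved_n_sets * self.set_size > self.n_genes and self.design != "self_contained":
            raise ValueError("disjoint sets need n_sets * set_size <= n_genes")
        if self.mean_inflation <= 0 or self.nb_mean <= 0 or self.background_mean <= 0:
            raise ValueError("means and inflation must be positive")
        if self.exp_rate <= 0 or self.nb_dispersion <= 0:
            raise ValueError("exp_rate and nb_dispersion must be positive")

    @property
    def resolved_n_sets(self) -> int:
        if self.n_sets is not None:
            return self.n_sets
        return 5 if self.design == "competitive" else 1


@dataclass
class SimulatedDataset:
    """Counts plus ground truth: which cells and sets carry signal."""

    counts: ExpressionMatrix
    annotation: AnnotationMatrix
    informative_cells: np.ndarray
    informative_sets: np.ndarray
    design: SimulationDesign


def draw_gene_means(
    n_genes: int, base: float, exp_rate: float, rng: np.random.Generator | int | None
) -> np.ndarray:
    """Shifted-exponential gene means: ``mean_j = base + Exp(rate)``."""
    if base <= 0 or exp_rate <= 0:
        raise ValueError("base and exp_rate must be positive")
    rng = np.random.default_rng(rng)
    return base + rng.exponential(scale=1.0 / exp_rate, size=n_genes)


def _nb_n_p(mean: np.ndarray | float, theta: float):
    """scipy parameterization of NB(mean mu, dispersion theta)."""
    mean = np.asarray(mean, dtype=float)
    return theta, theta / (theta + mean)


def _nb_quantile(u: np.ndarray, mean: float, theta: float) -> np.ndarray:
    """NB quantile function via a precomputed CDF table (fast, exact)."""
    var = mean + mean * mean / theta
    hi = int(np.ceil(mean + 40.0 * np.sqrt(var))) + 10
    n, p = _nb_n_p(mean, theta)
    cdf = stats.nbinom.cdf(np.arange(hi + 1), n, p)
    return np.searchsorted(cdf, u, side="left")


_CAL_CACHE: dict[tuple[float, float, float], float] = {}


def _calibrate_latent_corr(
    mean: float, theta: float, rho: float, n_mc: int = 60_000, tol: float = 1e-3
) -> float:
    """Latent Gaussian correlation giving count-scale Pearson ``rho``.

    Bisection on the latent correlation; at each candidate a fixed-seed
    Monte-Carlo sample of count pairs measures the realized correlation.
    The NB quantile map shrinks correlation, so the latent value bracketing
    starts at ``[rho, 1)``. Results are cached per rounded
    ``(mean, theta, rho)``.
    """
    key = (round(float(mean), 3), round(float(theta), 3), round(float(rho), 3))
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    cal_seed = (1_000_003 * key_hash(key)) % (2**31)
    rng = np.random.default_rng(cal_seed)
    z = rng.standard_normal((n_mc, 2))

    def realized(rho_lat: float) -> float:
        a = np.sqrt(rho_lat)
        b = np.sqrt(1.0 - rho_lat)
        w = rng_w
        z1 = a * w + b * z[:, 0]
        z2 = a * w + b * z[:, 1]
        u1 = np.clip(ndtr(z1), 1e-12, 1.0 - 1e-12)
        u2 = np.clip(ndtr(z2), 1e-12, 1.0 - 1e-12)
        x1 = _nb_quantile(u1, mean, theta)
        x2 = _nb_quantile(u2, mean, theta)
        return float(np.corrcoef(x1, x2)[0, 1])

    rng_w = rng.standard_normal(n_mc)
    lo, hi = rho, 0.999
    if realized(hi) < rho:  # unreachable target; use the ceiling
        _CAL_CACHE[key] = hi
        return hi
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if hi - lo < tol:
            break
        if realized(mid) < rho:
            lo = mid
        else:
            hi = mid
    out = 0.5 * (lo + hi)
    _CAL_CACHE[key] = out
    return out


def key_hash(key: tuple) -> int:
    """Stable small-int hash of a parameter tuple (process-independent)."""
    h = 17
    for x in key:
        h = (h * 1_000_193 + int(round(float(x) * 1000.0))) % (2**31 - 1)
    return h


def _correlated_nb_block(
    rng: np.random.Generator,
    n_rows: int,
    means: np.ndarray,
    theta: float,
    rho: float,
) -> np.ndarray:
    """Exchangeably correlated NB counts via a single-factor Gaussian copula."""
    g = means.shape[0]
    if rho == 0.0 or g == 1:
        n, p = _nb_n_p(means, theta)
        return rng.negative_binomial(n, p, size=(n_rows, g))
    rho_lat = _calibrate_latent_corr(float(means.mean()), theta, rho)
    w = rng.standard_normal((n_rows, 1))
    eps = rng.standard_normal((n_rows, g))
    z = np.sqrt(rho_lat) * w + np.sqrt(1.0 - rho_lat) * eps
    u = np.clip(ndtr(z), 1e-12, 1.0 - 1e-12)
    out = np.empty((n_rows, g), dtype=np.int64)
    for j in range(g):
        out[:, j] = _nb_quantile(u[:, j], float(means[j]), theta)
    return out


def _disjoint_annotation(design: SimulationDesign) -> tuple[AnnotationMatrix, np.ndarray]:
    gene_ids = [f"g{j + 1}" for j in range(design.n_genes)]
    m = design.resolved_n_sets
    if design.design == "self_contained":
        membership = np.ones((1, design.n_genes), dtype=np.int8)
        names = ["set1"]
    else:
        membership = np.zeros((m, design.n_genes), dtype=np.int8)
        names = [f"set{i + 1}" for i in range(m)]
        for i in range(m):
            membership[i, i * design.set_size : (i + 1) * design.set_size] = 1
    informative_sets = np.zeros(membership.shape[0], dtype=bool)
    informative_sets[0] = True
    ann = AnnotationMatrix(membership=membership, set_names=names, gene_ids=gene_ids)
    return ann, informative_sets


def simulate_counts(design: SimulationDesign) -> SimulatedDataset:
    """Draw one data set under ``design``; deterministic given its seed."""
    rng = np.random.default_rng(design.seed)
    n, p = design.n_cells, design.n_genes
    theta = design.nb_dispersion
    ann, informative_sets = _disjoint_annotation(design)

    if design.design == "self_contained":
        info_genes = np.arange(p)
    else:
        info_genes = ann.indices(0)
    info_gene_mask = np.zeros(p, dtype=bool)
    info_gene_mask[info_genes] = True

    # Gene means: shifted exponential; informative genes use the design's
    # baseline NB mean as the shift, background genes the background mean.
    means = draw_gene_means(p, design.background_mean, design.exp_rate, rng)
    means[info_gene_mask] = draw_gene_means(
        info_genes.size, design.nb_mean, design.exp_rate, rng
    )

    # Background: every entry independent NB at the gene's mean.
    nb_n, nb_p = _nb_n_p(means, theta)
    counts = rng.negative_binomial(nb_n, nb_p, size=(n, p))

    if design.design == "competitive":
        info_cells = np.ones(n, dtype=bool)
    else:
        info_cells = np.zeros(n, dtype=bool)
        info_cells[: design.n_informative_cells] = True
    rows = np.flatnonzero(info_cells)

    if design.design == "complex":
        # Half 1: correlated across all cells, no inflation (dominant PC);
        # half 2: inflated + correlated only in the informative cells (PC 2).
        half = info_genes.size // 2
        h1, h2 = info_genes[:half], info_genes[half:]
        counts[:, h1] = _correlated_nb_block(
            rng, n, means[h1], theta, design.correlation
        )
        block = _correlated_nb_block(
            rng, rows.size, means[h2] * design.mean_inflation, theta, design.correlation
        )
        counts[np.ix_(rows, h2)] = block
    else:
        block = _correlated_nb_block(
            rng,
            rows.size,
            means[info_genes] * design.mean_inflation,
            theta,
            design.correlation,
        )
        counts[np.ix_(rows, info_genes)] = block

    cell_ids = [f"cell{i + 1}" for i in range(n)]
    X = ExpressionMatrix(
        values=counts.astype(np.float64),
        sample_ids=cell_ids,
        gene_ids=list(ann.gene_ids),
    )
    return SimulatedDataset(
        counts=X,
        annotation=ann,
        informative_cells=info_cells,
        informative_sets=informative_sets,
        design=design,
    )


def log_normalize(
    X: ExpressionMatrix, scale_factor: float = 1e4
) -> ExpressionMatrix:
    """Per-cell log-normalization: ``log(1 + c_ij * scale_factor / total_i)``.

    Natural log; zeros map to zeros, so sparse input stays sparse. Cells
    with zero total counts produce a zero row (with a logged warning).
    """
    V = X.values
    if sparse.issparse(V):
        V = V.tocsr().astype(np.float64)
        totals = np.asarray(V.sum(axis=1)).ravel()
        zero = totals == 0
        if zero.any():
            logger.warning("%d cells have zero total counts; rows left zero", zero.sum())
        inv = np.where(zero, 0.0, scale_factor / np.where(zero, 1.0, totals))
        D = sparse.diags(inv)
        out = D @ V
        out.data = np.log1p(out.data)
    else:
        V = np.asarray(V, dtype=np.float64)
        totals = V.sum(axis=1, keepdims=True)
        zero = totals[:, 0] == 0
        if zero.any():
            logger.warning("%d cells have zero total counts; rows left zero", zero.sum())
        denom = np.where(totals == 0, 1.0, totals)
        out = np.log1p(V * (scale_factor / denom))
        out[zero] = 0.0
    return ExpressionMatrix(
        values=out, sample_ids=list(X.sample_ids), gene_ids=list(X.gene_ids)
    )
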