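"""Shuffled Complex Evolution Metropolis (SCEM-UA) global search.

Population MCMC: draw s points from the uniform prior box, rank them by
posterior density, stripe them into q complexes, evolve one Metropolis
sequence per complex (the SEM step), shuffle the complexes back together,
and repeat until the Gelman-Rubin statistic of the parallel sequences
drops below a threshold.  The scheme combines the global coverage of a
ranked, periodically reshuffled population with the local adaptivity of a
covariance-scaled random-walk Metropolis sampler.

"Parallel" sequences are a logical contract: evolution is sequential and
fully determined by the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .posterior import ParamBounds

__all__ = [
    "PopulationArray",
    "Complex",
    "ComplexSet",
    "SequenceChain",
    "SCEMConfig",
    "GRDiagnostic",
    "SCEMResult",
    "sample_prior",
    "rank_population",
    "partition_complexes",
    "sem_update",
    "shuffle_back",
    "gelman_rubin",
    "run_scem",
    "write_chain_trace_csv",
]

GR_NOT_CONVERGED = math.inf  # sentinel for zero within-chain variance


@dataclass
class PopulationArray:
    """The s x (n+1) array D: parameter points plus their log densities."""

    points: np.ndarray  # (s, n)
    log_densities: np.ndarray  # (s,)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.log_densities = np.asarray(self.log_densities, dtype=float)
        if len(self.points) != len(self.log_densities):
            raise ValueError("points and log_densities must have equal length")

    @property
    def size(self) -> int:
        return len(self.points)


@dataclass
class Complex:
    """One complex: m points with their log densities."""

    points: np.ndarray
    log_densities: np.ndarray


@dataclass
class ComplexSet:
    complexes: list[Complex]


@dataclass
class SequenceChain:
    """One Metropolis sequence: the chain of visited (point, density) states."""

    points: list[np.ndarray] = field(default_factory=list)
    log_densities: list[float] = field(default_factory=list)
    n_proposed: int = 0
    n_accepted: int = 0

    def append(self, point: np.ndarray, log_density: float) -> None:
        self.points.append(np.asarray(point, dtype=float).copy())
        self.log_densities.append(float(log_density))

    @property
    def current_point(self) -> np.ndarray:
        return self.points[-1]

    @property
    def current_log_density(self) -> float:
        return self.log_densities[-1]

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else 1.0


@dataclass(frozen=True)
class SCEMConfig:
    """Sampler controls.

    population_size s and n_complexes q fix the complex size m = s/q;
    steps_per_shuffle L defaults to m; jump_scale c_n defaults to the
    optimal normal random-walk scale 2.4/sqrt(n); density_ratio_threshold T
    and min_accept_rate AR_min trigger re-centring the proposal on the
    complex mean when a sequence is stuck far below its complex or mixing
    poorly.
    """

    seed: int
    population_size: int = 50
    n_complexes: int = 5
    steps_per_shuffle: int | None = None  # default: complex size m
    density_ratio_threshold: float = 1e6
    min_accept_rate: float = 0.1
    jump_scale: float | None = None  # default: 2.4 / sqrt(n_params)
    gr_threshold: float = 1.2
    max_shuffles: int = 60
    burn_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.population_size % self.n_complexes != 0:
            raise ValueError("population_size must be divisible by n_complexes")
        if self.steps_per_shuffle is not None and self.steps_per_shuffle < 1:
            raise ValueError("steps_per_shuffle must be >= 1")
        if not 0 < self.min_accept_rate < 1:
            raise ValueError("min_accept_rate must be in (0, 1)")
        if self.jump_scale is not None and not self.jump_scale > 0:
            raise ValueError("jump_scale must be > 0")
        if not self.gr_threshold > 1:
            raise ValueError("gr_threshold must be > 1")
        if not 0 <= self.burn_fraction < 1:
            raise ValueError("burn_fraction must be in [0, 1)")
        if not self.density_ratio_threshold > 0:
            raise ValueError("density_ratio_threshold must be > 0")

    @property
    def complex_size(self) -> int:
        return self.population_size // self.n_complexes

    def resolved_steps(self) -> int:
        return self.steps_per_shuffle if self.steps_per_shuffle else self.complex_size

    def resolved_jump_scale(self, n_params: int) -> float:
        return self.jump_scale if self.jump_scale else 2.4 / math.sqrt(n_params)


@dataclass(frozen=True)
class GRDiagnostic:
    """Per-parameter Gelman-Rubin R-hat; +inf marks degenerate (constant) chains."""

    r_hat: np.ndarray

    def converged(self, threshold: float) -> bool:
        return bool(np.all(self.r_hat < threshold))


@dataclass
class SCEMResult:
    best_theta: np.ndarray
    best_log_density: float
    chains: list[SequenceChain]
    n_shuffles: int
    converged: bool
    r_hat: np.ndarray


def sample_prior(b: ParamBounds, s: int, objective, rng) -> PopulationArray:
    """Draw s points uniformly on the prior box and evaluate their densities."""
    if s < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(rng)
    points = rng.uniform(b.lower, b.upper, size=(s, b.n_params))
    dens = np.array([objective(p) for p in points])
    return PopulationArray(points=points, log_densities=dens)


def rank_population(p: PopulationArray) -> PopulationArray:
    """Sort rows by decreasing log density; stable in the original order on ties."""
    order = np.argsort(-p.log_densities, kind="stable")
    return PopulationArray(points=p.points[order], log_densities=p.log_densities[order])


def partition_complexes(p: PopulationArray, q: int) -> ComplexSet:
    """Stripe the ranked population: complex k gets ranks k, k+q, k+2q, ...

    With s = 6, q = 2 this gives complex 1 the ranks {1, 3, 5} and complex 2
    the ranks {2, 4, 6}, so every complex spans the full density range.
    """
    if p.size % q != 0:
        raise ValueError("population size must be divisible by the number of complexes")
    complexes = [
        Complex(points=p.points[k::q].copy(), log_densities=p.log_densities[k::q].copy())
        for k in range(q)
    ]
    return ComplexSet(complexes=complexes)


def shuffle_back(c: ComplexSet) -> PopulationArray:
    """Merge all complexes back into one ranked population."""
    points = np.vstack([cx.points for cx in c.complexes])
    dens = np.concatenate([cx.log_densities for cx in c.complexes])
    return rank_population(PopulationArray(points=points, log_densities=dens))


def _complex_covariance(cx: Complex, bounds: ParamBounds) -> np.ndarray:
    """Sample covariance of the complex, jittered against degeneracy."""
    pts = cx.points
    if len(pts) >= 2:
        cov = np.cov(pts, rowvar=False)
        cov = np.atleast_2d(cov)
    else:
        cov = np.zeros((pts.shape[1], pts.shape[1]))
    jitter = 1e-10 * bounds.width**2
    return cov + np.diag(jitter)


def sem_update(
    seq: SequenceChain,
    cx: Complex,
    cfg: SCEMConfig,
    objective,
    rng,
    bounds: ParamBounds,
    n_steps: int | None = None,
) -> None:
    """Run L Metropolis steps of one sequence against its complex (in place).

    Proposals are multivariate normal with covariance c_n^2 * cov(complex),
    centred on the current draw — or on the complex mean when the sequence
    density has fallen below the complex mean density by more than a factor
    T, or its acceptance rate is below AR_min (the stuck-chain escape of
    the shuffled-complex scheme).  The covariance is refreshed from the
    evolving complex every m steps (once per call in the classical L = m
    usage).  Accepted points replace the worst member of the complex, so
    the best density in the complex never decreases.
    """
    rng = np.random.default_rng(rng)
    n_steps = cfg.resolved_steps() if n_steps is None else n_steps
    scale = cfg.resolved_jump_scale(bounds.n_params)
    log_t = math.log(cfg.density_ratio_threshold)
    refresh = max(len(cx.points), 1)
    chol = None
    for step in range(n_steps):
        if step % refresh == 0:
            cov = _complex_covariance(cx, bounds) * scale**2
            chol = np.linalg.cholesky(cov)
        finite = np.isfinite(cx.log_densities)
        mean_log_density = (
            float(np.mean(cx.log_densities[finite])) if finite.any() else -math.inf
        )
        current = seq.current_point
        current_density = seq.current_log_density
        stuck = (mean_log_density - current_density > log_t) or (
            seq.n_proposed >= n_steps and seq.acceptance_rate < cfg.min_accept_rate
        )
        center = cx.points.mean(axis=0) if stuck else current
        candidate = center + chol @ rng.standard_normal(bounds.n_params)
        cand_density = float(objective(candidate))
        if math.isnan(cand_density):
            raise RuntimeError(f"objective returned NaN at theta={candidate!r}")
        seq.n_proposed += 1
        log_ratio = cand_density - current_density
        if log_ratio >= 0 or math.log(rng.uniform()) < log_ratio:
            seq.n_accepted += 1
            seq.append(candidate, cand_density)
            worst = int(np.argmin(cx.log_densities))
            cx.points[worst] = candidate
            cx.log_densities[worst] = cand_density
        else:
            seq.append(current, current_density)


def gelman_rubin(chains: list[SequenceChain] | list[np.ndarray], burn_fraction: float = 0.5) -> GRDiagnostic:
    """Per-parameter Gelman-Rubin statistic over parallel sequences.

    After discarding the first ``burn_fraction`` of each chain and
    truncating to a common length n:

        W = mean within-chain variance, B = n * variance of chain means,
        R-hat = sqrt(((n-1)/n * W + B/n) / W)

    Chains with zero within-chain variance yield the +inf not-converged
    sentinel rather than a spurious 1.
    """
    arrays = [
        np.atleast_2d(np.asarray(c.points if isinstance(c, SequenceChain) else c, dtype=float))
        for c in chains
    ]
    if len(arrays) < 2:
        raise ValueError("need at least 2 chains")
    kept = []
    for a in arrays:
        start = int(math.floor(len(a) * burn_fraction))
        kept.append(a[start:])
    n = min(len(a) for a in kept)
    if n < 2:
        raise ValueError("need at least 2 retained draws per chain")
    stacked = np.stack([a[-n:] for a in kept])  # (q, n, n_params)
    within = stacked.var(axis=1, ddof=1).mean(axis=0)  # W
    means = stacked.mean(axis=1)  # (q, n_params)
    between = n * means.var(axis=0, ddof=1)  # B
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (n - 1) / n * within + between / n
        r_hat = np.sqrt(var_hat / within)
    r_hat = np.where(within > 0, r_hat, GR_NOT_CONVERGED)
    return GRDiagnostic(r_hat=r_hat)


def run_scem(objective, b: ParamBounds, cfg: SCEMConfig) -> SCEMResult:
    """Full SCEM-UA loop: sample, rank, partition, evolve, shuffle, check R-hat.

    ``objective(theta) -> log density`` need not know the bounds; points
    outside the box are assigned -inf here (uniform prior support).
    Returns the highest-density point ever evaluated, whether or not the
    Gelman-Rubin criterion was met within ``max_shuffles``.
    """
    best: dict = {"theta": None, "logp": -math.inf}

    def bounded(theta: np.ndarray) -> float:
        if not b.contains(theta):
            return -math.inf
        v = float(objective(theta))
        if not math.isnan(v) and v > best["logp"]:
            best["logp"] = v
            best["theta"] = np.asarray(theta, dtype=float).copy()
        return v

    rng = np.random.default_rng(cfg.seed)
    pop = rank_population(
        sample_prior(b, cfg.population_size, bounded, rng.spawn(1)[0])
    )
    chains = [SequenceChain() for _ in range(cfg.n_complexes)]
    for k, chain in enumerate(chains):
        chain.append(pop.points[k], pop.log_densities[k])

    converged = False
    r_hat = np.full(b.n_params, GR_NOT_CONVERGED)
    n_shuffles = 0
    for n_shuffles in range(1, cfg.max_shuffles + 1):
        complexes = partition_complexes(pop, cfg.n_complexes)
        for k, chain in enumerate(chains):
            sem_update(chain, complexes.complexes[k], cfg, bounded, rng.spawn(1)[0], b)
        pop = shuffle_back(complexes)
        if min(len(c.points) for c in chains) >= 4:
            r_hat = gelman_rubin(chains, cfg.burn_fraction).r_hat
            if np.all(r_hat < cfg.gr_threshold):
                converged = True
                break

    if best["theta"] is None:  # every evaluated point was out of bounds
        idx = int(np.argmax(pop.log_densities))
        best["theta"] = pop.points[idx].copy()
        best["logp"] = float(pop.log_densities[idx])
    return SCEMResult(
        best_theta=best["theta"],
        best_log_density=best["logp"],
        chains=chains,
        n_shuffles=n_shuffles,
        converged=converged,
        r_hat=r_hat,
    )


def write_chain_trace_csv(path, chains: list[SequenceChain], param_names=("alpha", "beta")) -> None:
    """Chain trace export with header ``shuffle,chain,<params...>,log_density``."""
    import pandas as pd

    rows = []
    for k, chain in enumerate(chains):
        for i, (pt, ld) in enumerate(zip(chain.points, chain.log_densities)):
            row = {"shuffle": i, "chain": k}
            row.update({name: v for name, v in zip(param_names, pt)})
            row["log_density"] = ld
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
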