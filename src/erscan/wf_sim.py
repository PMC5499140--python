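"""Forward Wright-Fisher simulation of independent loci with pool-seq noise.

Provides the matched neutral null for cutoff calibration and the backbone of
the synthetic-data generator.  Each locus drifts independently as a binomial
Wright-Fisher chain of 2*Ne gene copies; genic selection (coefficient s) is
applied deterministically before each drift step.  Observation mimics
pool-seq: a pool of S chromosomes is drawn from the population frequency,
then R reads from the pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass
class CoverageModel:
    """Read-depth generator for one (time point) library.

    Either resamples an empirical depth pool (the default when observed
    depths exist) or draws Poisson depths around a mean.  Depths of zero are
    bumped to one read so every site stays observable.
    """

    mean: float | None = None
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=np.int64)
            if self.depths.size == 0:
                raise ValueError("empirical depth pool is empty")
        elif self.mean is None:
            raise ValueError("coverage model needs a mean or an empirical depth pool")

    def draw(self, size, rng: np.random.Generator) -> np.ndarray:
        if self.depths is not None:
            out = rng.choice(self.depths, size=size, replace=True)
        else:
            out = rng.poisson(self.mean, size=size)
        return np.maximum(out, 1)


@dataclass
class SimulationSpec:
    """Parameters of one forward simulation matched to an experiment."""

    n_loci: int
    p0: np.ndarray | Callable[[int, np.random.Generator], np.ndarray]
    ne: int
    generations: int
    replicates: int = 3
    n_census: int = 1000
    founder_coverage: CoverageModel = field(default_factory=lambda: CoverageModel(mean=259))
    evolved_coverage: CoverageModel = field(default_factory=lambda: CoverageModel(mean=100))
    pool_size_founder: int = 2000
    pool_size_evolved: int = 2000
    selection: float | np.ndarray = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ne < 2:
            raise ValueError("ne must be >= 2")
        if self.generations < 1 or self.replicates < 1:
            raise ValueError("generations and replicates must be >= 1")
        if np.any(np.asarray(self.selection) <= -1):
            raise ValueError("selection coefficients must exceed -1")


@dataclass
class PoolSeqCounts:
    """Observed pool-seq counts at the two time points, (n_loci, K) arrays.

    ``a``/``b``: focal/other allele reads in the founder; ``c``/``d``: the
    same in the evolved sample — directly the CMH table entries.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    p0: np.ndarray

    @property
    def founder_freq(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    @property
    def evolved_freq(self) -> np.ndarray:
        return self.c / (self.c + self.d)


def sample_founder_spectrum(
    n: int,
    rng: np.random.Generator,
    alpha: float = 0.2,
    beta: float = 0.2,
    n_census: int = 1000,
) -> np.ndarray:
    """Founder allele frequencies from a Beta(alpha, beta) spectrum.

    Beta(0.2, 0.2) is strongly U-shaped, emulating a rare-variant-skewed
    site frequency spectrum; draws are conditioned on polymorphism by
    rejection outside [1/(2*N_census), 1 - 1/(2*N_census)].
    """
    lo = 1.0 / (2.0 * n_census)
    hi = 1.0 - lo
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.beta(alpha, beta, size=n - filled)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def simulate_trajectories(
    p0: np.ndarray,
    ne: int,
    generations: int,
    replicates: int,
    rng: np.random.Generator,
    selection: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Drift (and optional genic selection) trajectories of independent loci.

    Returns true frequencies shaped (n_loci, generations + 1, replicates);
    generation 0 equals ``p0`` in every replicate, after which each
    replicate drifts independently: p' = p(1+s)/(1+s*p), then
    Binomial(2*ne, p')/(2*ne).  Frequencies 0 and 1 are absorbing.
    """
    p0 = np.asarray(p0, dtype=float)
    n_loci = p0.shape[0]
    s = np.broadcast_to(np.asarray(selection, dtype=float), (n_loci,))[:, None]
    two_ne = 2 * ne
    traj = np.empty((n_loci, generations + 1, replicates))
    p = np.broadcast_to(p0[:, None], (n_loci, replicates)).copy()
    traj[:, 0, :] = p
    for g in range(1, generations + 1):
        p_sel = p * (1.0 + s) / (1.0 + s * p)
        p = rng.binomial(two_ne, p_sel) / two_ne
        traj[:, g, :] = p
    return traj


def observe_poolseq(
    freqs: np.ndarray,
    pool_size: int,
    coverage: CoverageModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage pool-seq observation of true frequencies.

    A pool of ``pool_size`` chromosomes is binomially drawn from each true
    frequency, then a read depth from the coverage model and binomial reads
    from the pool frequency.  Returns ``(focal_reads, depth)`` with the
    shape of ``freqs``; the read frequency has sampling variance
    p(1-p) * (1/S + 1/R - 1/(S*R)) around the true p.
    """
    freqs = np.asarray(freqs, dtype=float)
    p_pool = rng.binomial(pool_size, freqs) / pool_size
    depth = coverage.draw(freqs.shape, rng)
    reads = rng.binomial(depth, p_pool)
    return reads, depth


def simulate_poolseq_experiment(spec: SimulationSpec, rng: np.random.Generator | None = None):
    """Run a spec end to end: trajectories plus founder/evolved observation.

    The founder is itself sequenced, so generation-0 frequencies are
    observed with independent pool-seq noise per replicate.  Returns
    ``(traj, PoolSeqCounts)``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    p0 = spec.p0(spec.n_loci, rng) if callable(spec.p0) else np.asarray(spec.p0, float)
    if p0.shape[0] != spec.n_loci:
        raise ValueError("p0 length does not match n_loci")
    traj = simulate_trajectories(
        p0, spec.ne, spec.generations, spec.replicates, rng, selection=spec.selection
    )
    a, r0 = observe_poolseq(traj[:, 0, :], spec.pool_size_founder, spec.founder_coverage, rng)
    c, rt = observe_poolseq(traj[:, -1, :], spec.pool_size_evolved, spec.evolved_coverage, rng)
    counts = PoolSeqCounts(a=a, b=r0 - a, c=c, d=rt - c, p0=p0)
    return traj, counts


def neutral_cohort(
    founder_freqs: np.ndarray,
    n_loci: int,
    ne: int,
    generations: int,
    replicates: int,
    founder_coverage: CoverageModel,
    evolved_coverage: CoverageModel,
    pool_size_founder: int,
    pool_size_evolved: int,
    rng: np.random.Generator,
) -> PoolSeqCounts:
    """Neutral drift cohort matched to observed data, for cutoff calibration.

    Starting frequencies are resampled with replacement from the observed
    founder spectrum; depths come from the coverage models (pass empirical
    pools to mirror the observed depth distributions); every locus is
    strictly neutral.
    """
    founder_freqs = np.asarray(founder_freqs, dtype=float)
    founder_freqs = founder_freqs[np.isfinite(founder_freqs)]
    if founder_freqs.size == 0:
        raise ValueError("no founder frequencies to resample from")
    p0 = rng.choice(founder_freqs, size=n_loci, replace=True)
    spec = SimulationSpec(
        n_loci=n_loci,
        p0=p0,
        ne=ne,
        generations=generations,
        replicates=replicates,
        founder_coverage=founder_coverage,
        evolved_coverage=evolved_coverage,
        pool_size_founder=pool_size_founder,
        pool_size_evolved=pool_size_evolved,
        selection=0.0,
    )
    _, counts = simulate_poolseq_experiment(spec, rng)
    return counts
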