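"""Single-cell multifork replication states and run-out populations.

Each cell in a steady-state culture follows the same deterministic
Cooper-Helmstetter schedule: a new round of replication initiates on every
origin at ages ``a_k = (k + 1) * tau - (C + D)`` (one initiation per
doubling; rounds whose ``a_k`` is negative were inherited from the mother
cell), every round takes ``C`` minutes to complete, and division follows
termination by ``D`` minutes.  A cell's instantaneous state is therefore a
function of its age alone; sampling ages from the exponential-culture age
distribution reproduces all population averages of
:mod:`orichron.cell_cycle` -- the central cross-check between the simulator
and the closed forms.

"Run-out" emulates rifampicin + cephalexin treatment before flow cytometry:
no new initiations, no division, all active rounds complete.  Every origin
present at drug addition then ends up on its own fully replicated
chromosome, so the measured fluorescence histogram counts origins at the
time of drug addition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell_cycle import (
    CellCycleParams,
    age_distribution_cdf,
    genome_equivalents,
    sample_ages,
)
from .errors import ConfigurationError, EmptyInputError, ParameterError


@dataclass(frozen=True)
class ReplicationRound:
    """One active round: when it initiated (cell age, minutes; negative if
    inherited), per-arm fork progress in [0, 1], and how many chromosome
    copies it is duplicating."""

    t_init: float
    fraction: float
    multiplicity: int


@dataclass(frozen=True)
class ReplicationState:
    """A single cell's replication state.

    Under within-cell synchrony ``origins == completed_chromosomes *
    2 ** len(rounds)``; states produced by asynchrony injection may carry a
    smaller origin count.
    """

    age: float
    rounds: tuple[ReplicationRound, ...]
    completed_chromosomes: int
    origins: int

    def __post_init__(self):
        for r in self.rounds:
            if not 0 <= r.fraction <= 1:
                raise ParameterError(f"fork fraction {r.fraction} outside [0, 1]")


@dataclass
class OriginHistogram:
    """Distribution of origins per cell after run-out."""

    counts: dict[int, float]
    n_cells: int

    def frequencies(self) -> dict[int, float]:
        total = sum(self.counts.values())
        if total <= 0:
            raise EmptyInputError("histogram has no mass")
        return {k: v / total for k, v in sorted(self.counts.items())}

    def to_frame(self) -> pd.DataFrame:
        freq = self.frequencies()
        return pd.DataFrame(
            {"origin_count": list(freq), "frequency": list(freq.values())}
        )


def _event_ages(params: CellCycleParams, horizon: float) -> np.ndarray:
    """Scheduled initiation ages a_k = (k+1) tau - (C + D) up to ``horizon``."""
    C, D, tau = params.C, params.D, params.tau
    n = max(0, int(math.floor((horizon + C + D) / tau)))
    return (np.arange(n) + 1) * tau - (C + D)


def state_at_age(
    age: float,
    params: CellCycleParams,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ReplicationState:
    """Reconstruct the deterministic replication state of a cell of given age.

    With ``jitter_sd > 0`` each scheduled initiation age receives independent
    Gaussian noise (biological initiation-timing variability)."""
    C, tau = params.C, params.tau
    if not 0 <= age <= tau:
        raise ParameterError(f"age {age} outside [0, tau={tau}]")
    events = _event_ages(params, horizon=age + (6.0 * jitter_sd if jitter_sd else 0.0))
    if jitter_sd > 0.0:
        rng = rng if rng is not None else np.random.default_rng()
        events = events + rng.normal(0.0, jitter_sd, size=events.shape)
        events = np.sort(events)
    past = events[events <= age]
    n_done = int(np.sum(past <= age - C))  # rounds already terminated
    active = past[past > age - C]
    completed = 1 << n_done
    rounds = tuple(
        ReplicationRound(
            t_init=float(t),
            fraction=min((age - float(t)) / C, 1.0),
            multiplicity=completed << i,
        )
        for i, t in enumerate(active)
    )
    origins = completed << len(active)
    return ReplicationState(
        age=age, rounds=rounds, completed_chromosomes=completed, origins=origins
    )


def sample_population(
    n: int,
    params: CellCycleParams,
    init_cv: float = 0.0,
    seed: int | None = None,
    stratified: bool = False,
) -> list[ReplicationState]:
    """Sample ``n`` cells from the steady-state age distribution.

    ``init_cv`` is the coefficient of variation of initiation timing
    (Gaussian jitter with sd ``init_cv * tau``).  ``stratified=True`` uses
    deterministic mid-point age quantiles (requires ``init_cv == 0``), making
    population fractions exact to O(1/n).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if init_cv < 0:
        raise ParameterError("init_cv must be >= 0")
    rng = np.random.default_rng(seed)
    ages = sample_ages(n, params.tau, rng=rng, stratified=stratified)
    sd = init_cv * params.tau
    return [state_at_age(a, params, jitter_sd=sd, rng=rng) for a in ages]


def run_out(state: ReplicationState) -> int:
    """Origins present at drug addition == chromosomes after run-out."""
    return state.origins


def origin_distribution(population: list[ReplicationState]) -> OriginHistogram:
    """Histogram of run-out origin counts over a population."""
    if not population:
        raise EmptyInputError("empty population")
    counts: dict[int, float] = {}
    for s in population:
        k = run_out(s)
        counts[k] = counts.get(k, 0) + 1
    return OriginHistogram(counts=counts, n_cells=len(population))


def origin_distribution_exact(params: CellCycleParams) -> OriginHistogram:
    """Analytic noiseless run-out distribution from the age CDF.

    Origin number is ``2 ** floor((a + C + D) / tau)`` for a cell of age
    ``a``; integrating the age density between consecutive initiation ages
    gives the exact population fractions (only powers of two appear).
    """
    C, D, tau = params.C, params.D, params.tau
    j0 = int(math.floor((C + D) / tau))
    j1 = int(math.floor((tau + C + D) / tau - 1e-12))
    counts: dict[int, float] = {}
    prev_cdf = 0.0
    for j in range(j0, j1 + 1):
        upper = min((j + 1) * tau - (C + D), tau)
        cdf = age_distribution_cdf(upper, tau)
        frac = cdf - prev_cdf
        if frac > 1e-15:
            counts[2**j] = frac
        prev_cdf = cdf
    return OriginHistogram(counts=counts, n_cells=0)


def dna_content(state: ReplicationState, params: CellCycleParams) -> float:
    """DNA amount in one cell, in genome equivalents."""
    return state.completed_chromosomes + sum(
        r.multiplicity * r.fraction for r in state.rounds
    )


def locus_copies(state: ReplicationState, x: float) -> int:
    """Copies of a locus at arm fraction ``x`` in one cell: a replicating
    chromosome carries the extra copy once its fork has passed ``x``."""
    if not 0 <= x <= 1:
        raise ParameterError(f"arm fraction x must be in [0, 1], got {x}")
    return state.completed_chromosomes + sum(
        r.multiplicity for r in state.rounds if r.fraction >= x
    )


def population_means(
    population: list[ReplicationState],
    params: CellCycleParams,
    x: float | None = None,
) -> dict[str, float]:
    """Monte-Carlo means of origins, DNA content and (optionally) locus
    copies, with standard errors -- the oracle side of the closed forms."""
    if not population:
        raise EmptyInputError("empty population")
    n = len(population)
    ori = np.array([s.origins for s in population], dtype=float)
    dna = np.array([dna_content(s, params) for s in population])
    out = {
        "origins": float(ori.mean()),
        "origins_se": float(ori.std(ddof=1) / math.sqrt(n)),
        "dna": float(dna.mean()),
        "dna_se": float(dna.std(ddof=1) / math.sqrt(n)),
    }
    if x is not None:
        cp = np.array([locus_copies(s, x) for s in population], dtype=float)
        out["copies"] = float(cp.mean())
        out["copies_se"] = float(cp.std(ddof=1) / math.sqrt(n))
    return out


def genome_equivalents_by_quadrature(params: CellCycleParams, n_nodes: int = 4096) -> float:
    """Integrate single-cell DNA content over the age density (the
    independent oracle for the closed-form G)."""
    from scipy.integrate import fixed_quad

    def f(ages):
        dens = np.array(
            [
                dna_content(state_at_age(a, params), params)
                for a in np.atleast_1d(ages)
            ]
        )
        from .cell_cycle import age_distribution_pdf

        return dens * age_distribution_pdf(np.atleast_1d(ages), params.tau)

    # piecewise-smooth integrand: split at scheduled initiation/termination ages
    breaks = {0.0, params.tau}
    for t in _event_ages(params, horizon=params.tau):
        if 0 < t < params.tau:
            breaks.add(float(t))
        if 0 < t + params.C < params.tau:
            breaks.add(float(t + params.C))
    edges = sorted(breaks)
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = fixed_quad(f, lo, hi, n=max(16, n_nodes // len(edges)))
        total += float(val)
    return total


def mass_proxy(state: ReplicationState, params: CellCycleParams) -> float:
    """Relative cell mass 2**(age/tau): exponential single-cell growth,
    newborn mass 1.  Interpreted as the light-scatter signal."""
    return 2.0 ** (state.age / params.tau)


def raw_origins_per_mass(
    population: list[ReplicationState], params: CellCycleParams
) -> float:
    """Mean origins divided by mean mass proxy (unnormalised)."""
    if not population:
        raise EmptyInputError("empty population")
    ori = np.mean([s.origins for s in population])
    mass = np.mean([mass_proxy(s, params) for s in population])
    return float(ori / mass)


def origins_per_mass(
    population: list[ReplicationState],
    params: CellCycleParams,
    baseline: float | None = None,
) -> float:
    """Origin concentration relative to a designated baseline run.

    ``baseline`` is the raw origins-per-mass of the reference (wild-type)
    population from :func:`raw_origins_per_mass`; by construction a
    population measured against itself gives 1.
    """
    if baseline is None:
        raise ConfigurationError(
            "origins_per_mass needs the raw baseline value of a reference run"
        )
    return raw_origins_per_mass(population, params) / baseline


def flow_histogram(
    origin_counts: OriginHistogram,
    cv: float,
    channels: int = 256,
    seed: int | None = None,
    n_cells: int | None = None,
) -> pd.DataFrame:
    """Channelised fluorescence histogram from a run-out origin distribution.

    Each cell's signal is Gaussian with mean equal to its origin count and
    sd ``cv * count`` (instrument noise proportional to signal).  Returns a
    frame with channel index, channel-centre signal and cell count.
    """
    if cv < 0:
        raise ParameterError("cv must be >= 0")
    if channels < 10:
        raise ParameterError("need at least 10 channels")
    freq = origin_counts.frequencies()
    rng = np.random.default_rng(seed)
    n = n_cells if n_cells is not None else max(origin_counts.n_cells, 1)
    ks = np.array(list(freq), dtype=float)
    draws = rng.multinomial(n, np.array(list(freq.values())))
    signals = np.concatenate(
        [
            k + rng.normal(0.0, cv * k, size=m) if cv > 0 else np.full(m, k)
            for k, m in zip(ks, draws)
        ]
    )
    hi = ks.max() * (1.0 + 4.0 * cv) + 1.0
    edges = np.linspace(0.0, hi, channels + 1)
    counts, _ = np.histogram(signals, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame(
        {"channel": np.arange(channels), "signal": centres, "count": counts}
    )


def count_peaks(flow: pd.DataFrame, min_frac: float = 0.02, smooth: int = 5) -> int:
    """Number of resolvable peaks in a channelised histogram: local maxima
    of the smoothed profile with height and prominence above ``min_frac`` of
    the tallest peak."""
    from scipy.signal import find_peaks

    y = flow["count"].to_numpy(dtype=float)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        y = np.convolve(y, kernel, mode="same")
    if y.max() <= 0:
        return 0
    thresh = min_frac * y.max()
    peaks, _ = find_peaks(y, height=thresh, prominence=thresh)
    return int(len(peaks))
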