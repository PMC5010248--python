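"""Closed-form Cooper-Helmstetter cell-cycle quantities.

In steady-state exponential growth a bacterial culture is described by three
times: the replication period ``C`` (fork birth to termination), the
post-termination period ``D`` (termination to division) and the doubling
time ``tau``.  When ``C + D > tau`` replication rounds overlap (multifork
replication) and gene copy number depends on chromosomal position.

The two classical closed forms implemented here are

* the replication-associated gene dosage of a locus at arm fraction ``x``::

      X(x) = 2 ** ((C * (1 - x) + D) / tau)

  the population-average copies per cell, with ``X(0)`` the mean number of
  origins and ``X(1)`` the mean number of termini; and

* the mean DNA content per cell in genome equivalents::

      G = tau / (C * ln 2) * (2 ** ((C + D) / tau) - 2 ** (D / tau))

Both follow from averaging the single-cell replication schedule over the
steady-state age distribution ``phi(a) = (2 ln2 / tau) * 2 ** (-a / tau)``,
which is also exposed here and serves as the simulation oracle's sampling
density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

LN2 = math.log(2.0)

#: C and D measured for E. coli K-12 at generation times below 60 min.
DEFAULT_C = 42.0
DEFAULT_D = 33.0


@dataclass(frozen=True)
class CellCycleParams:
    """Replication period C, post-termination period D and doubling time tau,
    all in minutes."""

    C: float = DEFAULT_C
    D: float = DEFAULT_D
    tau: float = 40.0

    def __post_init__(self):
        if not self.C > 0:
            raise ParameterError(f"C must be > 0, got {self.C}")
        if self.D < 0:
            raise ParameterError(f"D must be >= 0, got {self.D}")
        if not self.tau > 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")
        if self.tau >= 60 and self.C == DEFAULT_C and self.D == DEFAULT_D:
            warnings.warn(
                "default C=42, D=33 are measured for doubling times below "
                f"60 min; tau={self.tau} is outside that regime",
                stacklevel=3,
            )


def gene_dosage(x: float, params: CellCycleParams) -> float:
    """Average copies per cell of a locus at arm fraction ``x`` in [0, 1]."""
    if not 0 <= x <= 1:
        raise ParameterError(f"arm fraction x must be in [0, 1], got {x}")
    return 2.0 ** ((params.C * (1.0 - x) + params.D) / params.tau)


def origins_per_cell(params: CellCycleParams) -> float:
    """Average origins per cell; the gene dosage at the origin (x = 0)."""
    return gene_dosage(0.0, params)


def genome_equivalents(params: CellCycleParams) -> float:
    """Average DNA content per cell, in whole-chromosome units.

    Bounded between the terminus dosage ``2**(D/tau)`` and the origin dosage
    ``2**((C+D)/tau)``.
    """
    C, D, tau = params.C, params.D, params.tau
    return tau / (C * LN2) * (2.0 ** ((C + D) / tau) - 2.0 ** (D / tau))


def copies_per_genome_equivalent(x: float, params: CellCycleParams) -> float:
    """Gene dosage normalised by the mean DNA content, X(x) / G."""
    return gene_dosage(x, params) / genome_equivalents(params)


def age_distribution_pdf(a, tau: float):
    """Steady-state cell-age density ``(2 ln2 / tau) * 2**(-a/tau)`` on [0, tau].

    Accepts scalars or arrays; ages outside [0, tau] raise.
    """
    if tau <= 0:
        raise ParameterError(f"tau must be > 0, got {tau}")
    arr = np.asarray(a, dtype=float)
    if np.any(arr < 0) or np.any(arr > tau):
        raise ParameterError("age outside [0, tau]")
    out = (2.0 * LN2 / tau) * 2.0 ** (-arr / tau)
    return float(out) if np.isscalar(a) else out


def age_distribution_cdf(a, tau: float):
    """P(age < a) = 2 * (1 - 2**(-a/tau)) for the steady-state age density."""
    if tau <= 0:
        raise ParameterError(f"tau must be > 0, got {tau}")
    arr = np.asarray(a, dtype=float)
    if np.any(arr < 0) or np.any(arr > tau):
        raise ParameterError("age outside [0, tau]")
    out = 2.0 * (1.0 - 2.0 ** (-arr / tau))
    return float(out) if np.isscalar(a) else out


def sample_ages(n: int, tau: float, rng: np.random.Generator | None = None,
                stratified: bool = False) -> np.ndarray:
    """Draw ``n`` ages from the steady-state age distribution.

    ``stratified=True`` uses mid-point quantiles instead of random draws,
    giving a deterministic low-discrepancy sample (population fractions are
    then exact to O(1/n)).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if stratified:
        u = (np.arange(n) + 0.5) / n
    else:
        rng = rng if rng is not None else np.random.default_rng()
        u = rng.random(n)
    # inverse of the age CDF
    return -tau * np.log2(1.0 - u / 2.0)


def plasmid_copies_per_cell(
    G: float, copies_per_genome_equivalent_range: tuple[float, float]
) -> tuple[float, float]:
    """Per-cell plasmid copy range from a per-genome-equivalent range.

    The F plasmid carries 1-2 copies per genome equivalent, so a culture with
    G genome equivalents per cell carries ``[G, 2G]`` plasmids per cell.
    """
    lo, hi = copies_per_genome_equivalent_range
    if G <= 0:
        raise ParameterError(f"G must be > 0, got {G}")
    if lo < 0 or hi < lo:
        raise ParameterError(f"need 0 <= lo <= hi, got ({lo}, {hi})")
    return (lo * G, hi * G)
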