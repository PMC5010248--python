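"""Asynchrony index over run-out origin distributions.

Synchronously initiating cells fire every origin in the same instant, so
after run-out their origin numbers are powers of two (2, 4, 8, ...).  Cells
that fail to fire some origins produce intermediate counts (3, 5, 6, 7,
...).  The index ``A`` measures the fraction of such off-ladder cells among
cells with at least two origins; a population is classified asynchronous
when ``A > 0.1`` (strictly).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .cell_cycle import CellCycleParams
from .errors import ParameterError, UndefinedIndexError
from .multifork import OriginHistogram, ReplicationState, _event_ages

#: Strict classification threshold: asynchronous when A > ASYNC_THRESHOLD.
ASYNC_THRESHOLD = 0.1


def _is_power_of_two(k: int) -> bool:
    return k > 0 and (k & (k - 1)) == 0


def _default_numerator(k: int) -> bool:
    """Off-ladder counts: >= 3 and not a power of two."""
    return k >= 3 and not _is_power_of_two(k)


@dataclass(frozen=True)
class AsynchronyResult:
    A: float
    classification: str  # "synchronous" | "asynchronous"

    @property
    def asynchronous(self) -> bool:
        return self.classification == "asynchronous"


def asynchrony_index(
    hist: OriginHistogram,
    numerator: Callable[[int], bool] = _default_numerator,
    threshold: float = ASYNC_THRESHOLD,
) -> AsynchronyResult:
    """Compute A and classify the population.

    ``A`` is the summed frequency of origin counts flagged by ``numerator``
    (by default: counts >= 3 that are not powers of two) divided by the
    summed frequency of counts >= 2.  Cells with a single origin are treated
    as slow or quiescent and excluded from the denominator.  The numerator
    predicate is injectable so alternative weightings can be swapped in
    without touching callers.
    """
    freq = hist.frequencies()
    denom = sum(f for k, f in freq.items() if k >= 2)
    if denom <= 0:
        raise UndefinedIndexError(
            "asynchrony index undefined: no cells with >= 2 origins"
        )
    num = sum(f for k, f in freq.items() if numerator(k))
    A = num / denom
    cls = "asynchronous" if A > threshold else "synchronous"
    return AsynchronyResult(A=A, classification=cls)


def inject_asynchrony(
    population: list[ReplicationState],
    p_fail: float,
    params: CellCycleParams,
    seed: int | None = None,
) -> list[ReplicationState]:
    """Re-run each cell's post-birth initiation events with per-origin
    failures.

    At every scheduled initiation since the cell's birth each origin fires
    independently with probability ``1 - p_fail``; failed origins do not
    duplicate.  Events inherited from the mother (negative schedule ages)
    are kept intact, so ``p_fail = 1`` leaves every cell at its newborn
    origin count.  This is a test fixture for the index, not a mechanistic
    model -- the regulatory model in :mod:`orichron.dnaa_cycle` produces
    asynchrony from DnaA dynamics instead.
    """
    if not 0 <= p_fail <= 1:
        raise ParameterError(f"p_fail must be in [0, 1], got {p_fail}")
    if p_fail == 0:
        return list(population)
    rng = np.random.default_rng(seed)
    out = []
    for state in population:
        events = _event_ages(params, horizon=state.age)
        n = 1 << int(np.sum(events <= 0))  # newborn origins, inherited intact
        for t in events[(events > 0) & (events <= state.age)]:
            n += int(rng.binomial(n, 1.0 - p_fail))
        out.append(replace(state, origins=n))
    return out
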