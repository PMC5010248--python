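"""Mechanistic DnaA ATP/ADP cycle coupled to multifork replication.

The initiator protein DnaA is active only in its ATP-bound form.  Four
processes move the cell between the two forms:

* **synthesis** -- new DnaA is made ATP-bound, at a rate proportional to the
  copy number of the *dnaA* gene (which sits next to *oriC* and is therefore
  duplicated early);
* **RIDA** -- replisome-coupled hydrolysis of DnaA-ATP, proportional to the
  number of active fork pairs, so RIDA accelerates during the initiation
  cascade as new forks are assembled;
* **DDAH** -- *datA*-dependent hydrolysis, proportional to the current
  *datA* copy number, so its strength tracks the locus' replication-
  associated gene dosage (early duplication near *oriC* doubles it early);
* **rejuvenation** at *DARS1* (constitutive) and *DARS2* (gated to a time
  window immediately preceding the next initiation, standing in for
  cell-cycle-regulated IHF binding), both proportional to locus copy number.

Initiation fires when free DnaA-ATP reaches a per-origin threshold.  Origins
then fire in a short cascade: each firing origin consumes a burst of
DnaA-ATP (released as DnaA-ADP, the pool *datA* and RIDA act on) and loads a
new fork pair.  When the remaining pool cannot cover the next origin's
requirement that origin fails stochastically -- this is the model's route to
initiation asynchrony, and the gated *DARS2* inflow during the cascade is
what normally prevents it.  A sequestration period after each event (the
SeqA/Dam eclipse) blocks immediate re-initiation, so failed origins stay
un-fired for an appreciable part of the cycle and show up as off-ladder
run-out counts.

Because the chromosomal position of a locus enters only through its
replication-associated copy number (plus, for *DARS2*, the interaction of
dosage with the gating window), relocating or deleting *datA* / *DARS1* /
*DARS2* in the genotype reproduces the directional phenotypes of the
relocation experiments: more *datA* dosage lowers origin concentration,
more *DARS* dosage raises it, and a weakened *DARS2* burst produces
asynchrony.

All rate constants are free model parameters (the underlying biology is
qualitative); :func:`calibrate` tunes them so the wild type initiates once
per doubling time with synchronous initiations, and genotype phenotypes are
read out relative to that calibrated wild type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .cell_cycle import CellCycleParams, gene_dosage
from .errors import (
    CalibrationError,
    ConfigurationError,
    ParameterError,
    StepSizeError,
    UndefinedIndexError,
)
from .multifork import OriginHistogram, locus_copies, ReplicationState
from .asynchrony import ASYNC_THRESHOLD, AsynchronyResult, asynchrony_index

# wild-type arm positions (symmetric mode, terminus antipodal to oriC)
X_DATA = 0.20
X_DARS1 = 0.66
X_DARS2 = 0.42
X_DNAA = 0.02  # the dnaA gene sits just counterclockwise of oriC

CONSTITUTIVE = "constitutive"
PRE_INITIATION_WINDOW = "pre_initiation_window"


@dataclass(frozen=True)
class RegulatoryLocus:
    """A chromosomal regulatory locus.

    ``copies_modifier`` is the number of identical copies placed at the same
    arm position (a second copy at a different position is a second locus
    entry).  ``activity`` in [0, 1] scales the locus' rate; 0 models
    inactivation by transcription through the region.  ``gating`` selects
    whether the locus acts throughout the cycle or only in the
    pre-initiation window (*DARS2*-like, IHF-dependent).
    """

    name: str
    x: float
    copies_modifier: int = 1
    activity: float = 1.0
    gating: str = CONSTITUTIVE

    def __post_init__(self):
        if not 0 <= self.x <= 1:
            raise ParameterError(f"arm position {self.x} outside [0, 1]")
        if not 0 <= self.activity <= 1:
            raise ParameterError(f"activity {self.activity} outside [0, 1]")
        if self.copies_modifier < 0:
            raise ParameterError("copies_modifier must be >= 0")
        if self.gating not in (CONSTITUTIVE, PRE_INITIATION_WINDOW):
            raise ParameterError(f"unknown gating {self.gating!r}")


@dataclass(frozen=True)
class Genotype:
    """Which regulatory loci exist, where, and at what activity."""

    loci: tuple[RegulatoryLocus, ...]
    dnaa_x: float = X_DNAA

    def named(self, name: str) -> tuple[RegulatoryLocus, ...]:
        return tuple(l for l in self.loci if l.name == name)

    def without(self, name: str) -> "Genotype":
        """Deletion of every locus with the given name."""
        return replace(self, loci=tuple(l for l in self.loci if l.name != name))

    def relocated(self, name: str, x: float) -> "Genotype":
        """Move every locus with the given name to a new arm position."""
        return replace(
            self,
            loci=tuple(
                replace(l, x=x) if l.name == name else l for l in self.loci
            ),
        )

    def with_activity(self, name: str, activity: float) -> "Genotype":
        return replace(
            self,
            loci=tuple(
                replace(l, activity=activity) if l.name == name else l
                for l in self.loci
            ),
        )

    def with_extra(self, locus: RegulatoryLocus) -> "Genotype":
        return replace(self, loci=self.loci + (locus,))

    def ungated(self) -> "Genotype":
        """Make every locus constitutive (drops the DARS2 gating)."""
        return replace(
            self, loci=tuple(replace(l, gating=CONSTITUTIVE) for l in self.loci)
        )


def wild_type() -> Genotype:
    return Genotype(
        loci=(
            RegulatoryLocus("datA", x=X_DATA),
            RegulatoryLocus("DARS1", x=X_DARS1),
            RegulatoryLocus("DARS2", x=X_DARS2, gating=PRE_INITIATION_WINDOW),
        )
    )


@dataclass(frozen=True)
class RegulatoryParams:
    """Rates (molecules/min), thresholds (molecules) and timing constants
    (minutes) of the DnaA cycle.

    ``theta`` is the free DnaA-ATP required per origin to trigger an event;
    ``init_cost`` the DnaA-ATP consumed by each firing origin (slightly above
    ``theta`` so the cascade depends on inflow during the event);
    ``window`` the length of the DARS2 gating interval that ends at the
    expected initiation (one doubling after the previous one); ``seq_dur``
    the post-initiation sequestration period; ``cascade_span`` the total
    duration of the firing cascade within one event (shared by however many
    origins fire, so per-origin replenishment scales with locus copy number
    exactly as per-origin demand scales with origin number).
    """

    k_syn: float = 4.9          # DnaA-ATP synthesis per unit cell mass
    k_rida: float = 2.5         # ATP->ADP per active fork pair
    k_datA: float = 2.0         # ATP->ADP per datA copy
    k_dars1: float = 2.0        # ADP->ATP per DARS1 copy
    k_dars2: float = 40.0       # ADP->ATP per DARS2 copy, inside the window
    window: float = 1.5         # min, DARS2 gating interval
    theta: float = 100.0        # free DnaA-ATP per origin at initiation
    init_cost: float = 180.0    # DnaA-ATP consumed per firing origin
    k_m_inact: float = 30.0     # molecules, half-saturation of RIDA/DDAH in DnaA-ATP
    seq_dur: float = 10.0       # min, sequestration after an event
    cascade_span: float = 2.0   # min, total duration of the firing cascade
    dt: float = 0.25            # min, integration step

    def __post_init__(self):
        for name in ("k_syn", "k_rida", "k_datA", "k_dars1", "k_dars2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.theta <= 0:
            raise ParameterError("theta must be > 0")
        if self.init_cost <= 0:
            raise ParameterError("init_cost must be > 0")
        if self.seq_dur < 0 or self.window < 0:
            raise ParameterError("durations must be >= 0")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")

    def rescaled(self, factor: float) -> "RegulatoryParams":
        """Rescale all times by ``factor`` (rates by 1/factor); with cell-
        cycle times rescaled identically the dynamics are invariant."""
        return replace(
            self,
            k_syn=self.k_syn / factor,
            k_rida=self.k_rida / factor,
            k_datA=self.k_datA / factor,
            k_dars1=self.k_dars1 / factor,
            k_dars2=self.k_dars2 / factor,
            window=self.window * factor,
            seq_dur=self.seq_dur * factor,
            cascade_span=self.cascade_span * factor,
            dt=self.dt * factor,
        )


def instantaneous_copies(locus: RegulatoryLocus, state: ReplicationState) -> int:
    """Copies of a regulatory locus in a multifork replication state."""
    return locus.copies_modifier * locus_copies(state, locus.x)


class _Cell:
    """Mutable per-cell simulation state (single lineage; at division the
    simulation follows one daughter)."""

    __slots__ = (
        "mass", "atp", "adp", "g0", "rounds", "t_last_init", "seq_until",
        "divisions", "n_events", "event_times", "pending",
    )

    def __init__(self, mass: float, atp: float, adp: float, phase: float):
        self.mass = mass
        self.atp = atp
        self.adp = adp
        self.g0 = 1                      # chromosomes without active forks
        self.rounds: list[list] = []     # [multiplicity, fraction], oldest first
        self.t_last_init = -phase
        self.seq_until = 0.0
        self.divisions: list[float] = []
        self.n_events = 0
        self.event_times: list[float] = []
        self.pending = 0  # origins that failed at the last event

    @property
    def origins(self) -> int:
        return self.g0 + sum(m for m, _ in self.rounds)

    @property
    def forks(self) -> int:
        return sum(m for m, _ in self.rounds)

    def copies(self, x: float) -> int:
        return self.g0 + sum(m for m, f in self.rounds if f >= x)


def _stochastic_round(value: float, rng: np.random.Generator) -> int:
    base = int(math.floor(value))
    return base + (1 if rng.random() < value - base else 0)


def _fluxes(cell: _Cell, genotype: Genotype, reg: RegulatoryParams,
            cc: CellCycleParams, gate_open: bool):
    """Per-minute source terms (synthesis, inactivation, rejuvenation).

    Synthesis scales with cell mass (total biosynthetic capacity -- the
    negative feedback that couples initiation to mass growth) modulated by
    the instantaneous dnaA gene copy number relative to its cycle-average
    dosage, so early duplication of dnaA still advances DnaA accumulation.
    """
    dosage_mod = cell.copies(genotype.dnaa_x) / gene_dosage(genotype.dnaa_x, cc)
    syn = reg.k_syn * cell.mass * dosage_mod
    inact = reg.k_rida * cell.forks
    rejuv = 0.0
    for locus in genotype.loci:
        if locus.activity == 0.0 or locus.copies_modifier == 0:
            continue
        cp = locus.copies_modifier * cell.copies(locus.x) * locus.activity
        if locus.name == "datA":
            inact += reg.k_datA * cp
        elif locus.name == "DARS1":
            rejuv += reg.k_dars1 * cp
        elif locus.name == "DARS2":
            if locus.gating != PRE_INITIATION_WINDOW or gate_open:
                rejuv += reg.k_dars2 * cp
        else:  # custom loci act as constitutive rejuvenators at the DARS1 rate
            rejuv += reg.k_dars1 * cp
    return syn, inact, rejuv


def _apply_chemistry(cell: _Cell, syn: float, inact: float, rejuv: float,
                     dt: float, k_m: float):
    """Advance the two pools by one step.  Inactivation (RIDA + DDAH) is
    enzymatic: saturated in DnaA-ATP above ``k_m`` and first-order below it,
    so a depleted pool is not pinned at zero."""
    cell.atp += syn * dt
    sat = cell.atp / (cell.atp + k_m) if cell.atp > 0 else 0.0
    h = min(cell.atp, inact * sat * dt)
    cell.atp -= h
    cell.adp += h
    r = min(cell.adp, rejuv * dt)
    cell.adp -= r
    cell.atp += r


def _cascade(
    cell: _Cell,
    n_fire: int,
    genotype: Genotype,
    reg: RegulatoryParams,
    cc: CellCycleParams,
    rng: np.random.Generator,
) -> int:
    """Fire up to ``n_fire`` origins sequentially within one cascade.

    The cascade lasts ``cascade_span`` minutes in total; before each firing
    attempt the chemistry advances by ``cascade_span / n_fire`` (with the
    DARS2 gate open and RIDA already loading onto the new forks), then the
    origin consumes ``init_cost`` DnaA-ATP, failing stochastically when the
    pool cannot cover it.  Returns the number of origins fired."""
    fired = 0
    dt_sub = reg.cascade_span / n_fire
    for _ in range(n_fire):
        # replenishment during the cascade; RIDA already sees the new forks
        syn, inact, rejuv = _fluxes(cell, genotype, reg, cc, gate_open=True)
        _apply_chemistry(cell, syn, inact + reg.k_rida * fired, rejuv, dt_sub,
                         reg.k_m_inact)
        p = min(1.0, cell.atp / reg.init_cost)
        if rng.random() < p:
            take = min(cell.atp, reg.init_cost)
            cell.atp -= take
            cell.adp += take
            fired += 1
    return fired


def _step_cell(
    cell: _Cell,
    t: float,
    genotype: Genotype,
    reg: RegulatoryParams,
    cc: CellCycleParams,
    rng: np.random.Generator,
) -> None:
    dt = reg.dt
    # fork progression and terminations (division D minutes later)
    still = []
    for r in cell.rounds:
        r[1] += dt / cc.C
        if r[1] >= 1.0:
            cell.g0 += r[0]
            cell.divisions.append(t + cc.D)
        else:
            still.append(r)
    cell.rounds = still
    # divisions due: follow one daughter
    while cell.divisions and cell.divisions[0] <= t:
        cell.divisions.pop(0)
        cell.mass *= 0.5
        cell.atp *= 0.5
        cell.adp *= 0.5
        cell.g0 = _stochastic_round(cell.g0 / 2.0, rng)
        cell.rounds = [
            [m2, f]
            for m, f in cell.rounds
            if (m2 := _stochastic_round(m / 2.0, rng)) > 0
        ]
        cell.pending = min(_stochastic_round(cell.pending / 2.0, rng), cell.g0)
        if cell.g0 == 0 and not cell.rounds:
            cell.g0 = 1
            cell.pending = 0
    # mass growth and chemistry
    cell.mass *= 2.0 ** (dt / cc.tau)
    gate_open = (t - cell.t_last_init) >= (cc.tau - reg.window)
    syn, inact, rejuv = _fluxes(cell, genotype, reg, cc, gate_open)
    _apply_chemistry(cell, syn, inact, rejuv, dt, reg.k_m_inact)
    # initiation: a full event when the pool reaches the per-origin
    # threshold, or a catch-up of previously failed origins (they fire as
    # soon as the recovering pool can serve them, restoring synchrony)
    if t >= cell.seq_until:
        n_ori = cell.origins
        if cell.atp >= reg.theta * n_ori:
            fired = _cascade(cell, n_ori, genotype, reg, cc, rng)
            if fired > 0:
                cell.rounds.append([fired, 0.0])
                cell.n_events += 1
                cell.event_times.append(t)
            cell.pending = n_ori - fired
            cell.t_last_init = t
            cell.seq_until = t + reg.seq_dur
        elif cell.pending > 0 and cell.atp >= reg.theta * cell.pending:
            fired = _cascade(cell, cell.pending, genotype, reg, cc, rng)
            if fired > 0:
                cell.rounds.append([fired, 0.0])
                cell.pending -= fired
                cell.seq_until = t + reg.seq_dur


def _validate_dt(reg: RegulatoryParams, cc: CellCycleParams) -> None:
    if reg.dt > cc.tau / 20 or reg.dt > cc.C / 20:
        raise StepSizeError(
            f"dt={reg.dt} min is too coarse for tau={cc.tau}, C={cc.C}; "
            "use dt <= min(tau, C)/20"
        )


def simulate(
    genotype: Genotype,
    reg: RegulatoryParams,
    cc: CellCycleParams,
    duration: float,
    seed: int | None = None,
    record: bool = True,
):
    """Simulate one cell lineage; returns a trajectory dictionary with
    arrays ``t``, ``atp``, ``adp``, ``origins``, ``mass``, ``dna`` and the
    list of initiation event times."""
    _validate_dt(reg, cc)
    rng = np.random.default_rng(seed)
    cell = _Cell(mass=1.0, atp=0.5 * reg.theta, adp=reg.theta, phase=0.0)
    n_steps = int(round(duration / reg.dt))
    traj = {k: [] for k in ("t", "atp", "adp", "origins", "mass", "dna")}
    for i in range(n_steps):
        t = i * reg.dt
        _step_cell(cell, t, genotype, reg, cc, rng)
        if record:
            traj["t"].append(t)
            traj["atp"].append(cell.atp)
            traj["adp"].append(cell.adp)
            traj["origins"].append(cell.origins)
            traj["mass"].append(cell.mass)
            traj["dna"].append(cell.g0 + sum(m * f for m, f in cell.rounds))
    out = {k: np.asarray(v) for k, v in traj.items()}
    out["events"] = np.asarray(cell.event_times)
    return out


def _run_ensemble(
    genotype: Genotype,
    reg: RegulatoryParams,
    cc: CellCycleParams,
    n_cells: int,
    duration: float,
    rng: np.random.Generator,
):
    """Simulate ``n_cells`` independent desynchronised lineages; returns
    final (origins, mass) samples and initiation intervals from the last
    third of the run."""
    _validate_dt(reg, cc)
    n_steps = int(round(duration / reg.dt))
    origins = np.empty(n_cells, dtype=int)
    masses = np.empty(n_cells)
    intervals: list[float] = []
    t_tail = duration * 2.0 / 3.0
    for i in range(n_cells):
        cell = _Cell(
            mass=2.0 ** rng.random(),
            atp=reg.theta * (0.3 + 0.4 * rng.random()),
            adp=reg.theta,
            phase=rng.random() * cc.tau,
        )
        for j in range(n_steps):
            _step_cell(cell, j * reg.dt, genotype, reg, cc, rng)
        origins[i] = cell.origins
        masses[i] = cell.mass
        ev = [t for t in cell.event_times if t >= t_tail]
        intervals.extend(np.diff(ev))
    return origins, masses, np.asarray(intervals)


@dataclass(frozen=True)
class Phenotype:
    """Genotype read-out: origin concentration relative to wild type, the
    asynchrony index, and the raw quantities behind them."""

    origins_per_mass_rel: float
    asynchrony: AsynchronyResult
    raw_origins_per_mass: float
    mean_origins: float
    mean_initiation_interval: float
    histogram: OriginHistogram

    @property
    def A(self) -> float:
        return self.asynchrony.A


def phenotype(
    genotype: Genotype,
    reg: RegulatoryParams,
    cc: CellCycleParams,
    n_cells: int = 150,
    seed: int | None = None,
    duration: float | None = None,
    baseline: float | None = None,
) -> Phenotype:
    """Simulate a genotype to steady state and measure origin concentration
    (relative to the wild-type ``baseline``, a raw origins-per-mass value)
    and the asynchrony index of the run-out origin histogram.

    The ensemble samples each lineage once after a burn-in of several
    doubling times; sampling the end of a long run stands in for drug
    run-out, since every origin present is counted.
    """
    if baseline is None:
        raise ConfigurationError(
            "phenotype needs the wild-type raw origins-per-mass baseline; "
            "compute it with raw_phenotype(wild_type(), ...)"
        )
    raw = raw_phenotype(genotype, reg, cc, n_cells=n_cells, seed=seed, duration=duration)
    return replace(raw, origins_per_mass_rel=raw.raw_origins_per_mass / baseline)


def raw_phenotype(
    genotype: Genotype,
    reg: RegulatoryParams,
    cc: CellCycleParams,
    n_cells: int = 150,
    seed: int | None = None,
    duration: float | None = None,
) -> Phenotype:
    """Like :func:`phenotype` but unnormalised (used for the baseline run)."""
    rng = np.random.default_rng(seed)
    duration = duration if duration is not None else 14.0 * cc.tau
    origins, masses, intervals = _run_ensemble(
        genotype, reg, cc, n_cells, duration, rng
    )
    counts: dict[int, float] = {}
    for k in origins:
        counts[int(k)] = counts.get(int(k), 0) + 1
    hist = OriginHistogram(counts=counts, n_cells=len(origins))
    try:
        asyn = asynchrony_index(hist)
    except UndefinedIndexError:
        # starved ensemble (all cells single-origin): no index to report
        asyn = AsynchronyResult(A=math.nan, classification="undefined")
    raw_opm = float(origins.mean() / masses.mean())
    mii = float(intervals.mean()) if len(intervals) else math.inf
    return Phenotype(
        origins_per_mass_rel=1.0,
        asynchrony=asyn,
        raw_origins_per_mass=raw_opm,
        mean_origins=float(origins.mean()),
        mean_initiation_interval=mii,
        histogram=hist,
    )


def calibrate(
    cc: CellCycleParams,
    reg0: RegulatoryParams | None = None,
    period_tol: float = 0.05,
    a_max: float = ASYNC_THRESHOLD,
    origin_tol: float = 0.15,
    n_cells: int = 60,
    seed: int = 0,
    max_iter: int = 10,
) -> RegulatoryParams:
    """Tune wild-type parameters to a periodic, synchronous steady state.

    Because DnaA synthesis is coupled to mass growth, the initiation period
    locks to the doubling time on its own; what ``k_syn`` sets is the
    initiation mass, i.e. the steady-state origin number.  The procedure
    therefore (i) adjusts ``k_syn`` until the wild-type mean origin number
    matches the Cooper-Helmstetter expectation ``2**((C+D)/tau)`` within
    ``origin_tol``, (ii) verifies the mean initiation interval is within
    ``period_tol`` of ``tau``, and (iii) verifies the wild-type asynchrony
    index is below ``a_max``, raising the DARS2 burst rate and retrying when
    it is not.  Deterministic given ``seed``.
    """
    from .cell_cycle import origins_per_cell

    reg = reg0 if reg0 is not None else RegulatoryParams()
    wt = wild_type()
    target_ori = origins_per_cell(cc)

    def measure(r: RegulatoryParams) -> Phenotype:
        return raw_phenotype(wt, r, cc, n_cells=n_cells, seed=seed,
                             duration=14.0 * cc.tau)

    best: tuple[float, Phenotype] | None = None
    for attempt in range(4):
        ph = measure(reg)
        for _ in range(max_iter):
            ratio = target_ori / ph.mean_origins
            if abs(ratio - 1.0) <= origin_tol:
                break
            reg = replace(reg, k_syn=reg.k_syn * min(max(ratio, 0.6), 1.8))
            ph = measure(reg)
        period_err = abs(ph.mean_initiation_interval / cc.tau - 1.0)
        if period_err <= period_tol and ph.A < a_max:
            return reg
        score = period_err + ph.A
        if best is None or score < best[0]:
            best = (score, ph)
        if ph.A >= a_max:
            if reg.k_dars2 <= 0:
                break  # no rejuvenation burst available to restore synchrony
            reg = replace(reg, k_dars2=reg.k_dars2 * 1.6)
    ph = best[1] if best else None
    raise CalibrationError(
        "could not reach a periodic synchronous wild type"
        + (
            f": best residual period error "
            f"{abs(ph.mean_initiation_interval / cc.tau - 1.0):.3f}, A = {ph.A:.3f}"
            if ph is not None
            else ""
        )
    )
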