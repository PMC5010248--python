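# Methods

This note documents the models behind `orichron`: what is computed, which
choices were genuinely open, what the synthetic data do and do not emulate,
and the known limitations.

## Coordinates and relative distance

The chromosome is a circle of 100 map minutes (4,641,652 bp); minutes are
floats on `[0, 100)`, base-pair coordinates 0-based half-open.  The
relative distance between two positions is the shorter circular arc divided
by the map length, so it is symmetric, rotation-invariant and bounded by
0.5.  Rounded to two decimals this reproduces the conventional published
distances of the regulatory loci and of the Tn10 marker sites used for
relocations (datA 0.10, DARS2 0.21, DARS1 0.33, …) with one known
off-by-rounding cell: the site at 33.3 min computes to 0.487, which rounds
half-up to 0.49 where 0.48 has historically been printed.  We round only at
presentation; internal values keep full precision.

The arm fraction `x` (0 at *oriC*, 1 at *terC*) defaults to *symmetric*
mode, `x = min(2·RD, 1)`, i.e. the terminus is taken antipodal to the
origin.  Since the real terminus region is only "around 36 min", an
`explicit_ter` mode measures the arc along whichever replichore carries the
locus, for sensitivity analysis.

## Cooper–Helmstetter quantities

`gene_dosage` implements `X(x) = 2^((C(1−x)+D)/τ)` and
`genome_equivalents` implements `G = τ/(C ln2)·(2^((C+D)/τ) − 2^(D/τ))`.
These are the standard steady-state readings; both follow from averaging
the single-cell schedule over the age density
`φ(a) = (2 ln2/τ)·2^(−a/τ)`.  Defaults `C = 42`, `D = 33` minutes are the
constants measured for K-12 at doubling times below 60 min; constructing
parameters with the default periods and `τ ≥ 60` emits a warning rather
than an error.

At `τ = 40` these give `X(0) = 3.668` origins per cell and `G = 2.606`
genome equivalents.  Worked values of 1.66 copies/cell for a locus at the
*DARS2* position and `G = 1.82` have circulated for the same parameter set;
they are not reproducible from the formulas above (which give 2.70 and
2.61, and `2^(D/τ) = 1.77` is a hard lower bound on `G`), so the package
documents both and does not force-fit.  The F-plasmid range calculation
(1–2 copies per genome equivalent) therefore accepts `G` as an input;
with the conventional `G = 1.82` it returns 1.82–3.64 plasmids per cell.

Both normalisations of dosage are exposed (`X` per cell and `X/G`) because
in-text copy numbers in the experimental literature are sometimes
per-genome-equivalent-like.

## Multifork simulator and run-out

Each cell follows the deterministic schedule: initiations at ages
`a_k = (k+1)τ − (C+D)` (negative ages are rounds inherited from the
mother), rounds complete after `C`, division follows termination by `D`.
Sampling ages from `φ` and evaluating origins, DNA content and locus
copies per cell reproduces the closed forms — the module's central oracle,
tested to 3 Monte-Carlo standard errors at n = 10⁵ and, for DNA content,
by piecewise Gaussian quadrature to relative error < 10⁻⁴.  A `stratified`
sampling option uses mid-point age quantiles, making population fractions
deterministic to O(1/n); this is how the exact run-out split at τ = 40
(2 origins: `2 − 2^(1−5/40)` = 0.166) is reported.

Run-out counts the origins present at drug addition (`origins` of the
state): rifampicin blocks new initiations, cephalexin blocks division, and
every ongoing round completes, so each origin ends up on a fully
replicated chromosome.  Initiation-timing noise (`init_cv`, Gaussian jitter
of the schedule) and per-origin initiation failures
(`inject_asynchrony`) are available as explicit perturbations; the
default population is noiseless and perfectly synchronous.

The flow-cytometry model draws each cell's signal from a Gaussian with
mean equal to its origin count and sd `cv·count`, then bins into channels.
The mass proxy for origin concentration is `2^(age/τ)` (exponential
single-cell growth, newborn mass 1), our reading of "average light
scatter"; origin concentrations are always reported relative to a
designated baseline population, so the proxy's absolute scale cancels.

## Asynchrony index

`A` = (summed frequency of origin counts ≥ 3 that are not powers of two) /
(summed frequency of counts ≥ 2); classification is asynchronous when
`A > 0.1`, strictly — a population at exactly 0.1 is synchronous.  The
exact historical formula lives in the flow-cytometry literature and is not
restated in the relocation studies; this definition was chosen because it
is zero exactly on the synchronous support `{2, 4, 8, …}` and reproduces
the qualitative ordering of published strain tables.  Cells with one
origin are excluded from the denominator (slow or quiescent cells), which
keeps `A = 0` for non-overlapping wild-type-like cycles.  The numerator
predicate is an injectable strategy so alternative weightings (e.g. by
distance to the nearest 2ⁿ) can be swapped in without touching callers.

## The DnaA ATP/ADP cycle model

The regulatory model is a per-cell discrete-time simulation (default
`dt = 0.25` min) of two pools, DnaA·ATP and DnaA·ADP, coupled to the
replication state (chromosome units, active fork rounds, per-round fork
fractions).  A locus' influence scales with its *instantaneous copy
number*: `copies(x) = g₀ + Σ_j m_j·[f_j ≥ x]`, which time-averages to the
Cooper–Helmstetter dosage (tested against that oracle).

Fluxes per minute:

| process | form | default | units |
|---|---|---|---|
| synthesis | `k_syn · mass · copies(dnaA)/X(dnaA)` | `k_syn = 4.9` | molecules·min⁻¹ per unit newborn mass |
| RIDA | `k_rida · forks`, saturating in ATP (`K_m = 30`) | 2.5 | molecules·min⁻¹ per fork pair |
| DDAH | `k_datA · datA copies`, same saturation | 2.0 | molecules·min⁻¹ per copy |
| DARS1 | `k_dars1 · copies` | 2.0 | molecules·min⁻¹ per copy |
| DARS2 | `k_dars2 · copies`, only in the gate | 40.0 | molecules·min⁻¹ per copy |

Initiation fires when free DnaA·ATP reaches `θ = 100` molecules per
origin.  Origins then fire in a cascade of total length
`cascade_span = 2` min; each firing consumes `init_cost = 180` molecules
(converted to ADP — the pool DDAH and RIDA act on) and loads a fork pair,
and an origin fails stochastically with probability `1 − min(1, pool/cost)`
when the pool cannot cover it.  Because `init_cost > θ`, completing the
cascade depends on replenishment *during* the event; the gated *DARS2*
burst supplies most of it, so halving *DARS2*'s copy number (relocation to
the terminus) or deleting it produces partial firing — the model's
mechanism for asynchrony.  The per-firing sub-step is `cascade_span/n`, so
cascade supply and demand scale together with origin number.  After an
event a sequestration period (`seq_dur = 10` min, the SeqA/Dam eclipse)
blocks re-initiation; origins that failed fire as a catch-up as soon as
the recovering pool can serve them, which is what keeps wild-type run-out
histograms on the 2ⁿ ladder while leaving a detectable off-ladder fraction
when failures are frequent.

The *DARS2* gate is a time window (`window = 1.5` min) ending at the
expected initiation — open when the time since the last event exceeds
`τ − window`, and during the cascade itself — standing in for
cell-cycle-regulated IHF binding; growth-phase (Fis) dependence is
collapsed into the locus `activity` multiplier (exponential phase = 1,
and `activity = 0` models transcription through the locus, which
phenocopies deletion exactly).  Division is binary fission `D` minutes
after a round terminates, halving mass and pools, with stochastic rounding
of odd chromosome counts; the simulation follows one daughter.

Design rationale for the two structural choices that were genuinely open:

* **Mass-coupled synthesis.**  Coupling DnaA synthesis to cell mass (with
  the instantaneous *dnaA* dosage as a modulation) is what locks the
  initiation period to the doubling time and makes "initiation mass" the
  free variable a genotype can shift; making synthesis purely
  copy-number-proportional leaves the system scale-invariant with no
  stable origin concentration.
* **Saturating inactivation.**  RIDA/DDAH are enzymatic
  (Michaelis-type in DnaA·ATP): saturated near the initiation threshold,
  first-order when the pool is depleted.  A hard availability cap would
  pin the pool at zero early in the cycle and erase the *datA* dosage
  dependence.

All rates are free model parameters: the underlying biology is
qualitative, so no published magnitude constrains them.  `calibrate`
adjusts `k_syn` until the wild-type mean origin number matches the
schedule expectation `2^((C+D)/τ)` (±15%), then verifies the mean
initiation interval is within 5% of `τ` and wild-type `A < 0.1`, raising
the *DARS2* burst and retrying if synchrony fails.  Phenotypes are
reported relative to a wild-type baseline simulated under identical
parameters.  Under the calibrated defaults the directional pattern of the
relocation experiments emerges: *datA* deletion raises origin
concentration (≈ 1.2×) and relocation to the terminus raises it less; a
second terminus-proximal *datA* copy restores it to approximately
wild-type level (0.97–1.03 across seeds — the rescue is real but
marginal, as the double-copy time-averaged dosage only slightly exceeds
the wild-type value); *DARS1*/*DARS2* deletions lower it; and only
*DARS2* perturbations (deletion, terminus relocation) produce `A > 0.1`.
Magnitudes are **not** calibration targets — they depend on rate constants
the biology does not constrain — only signs and orderings are asserted.
Rescaling all rates by `1/s` and all times by `s` leaves phenotypes
bit-identical (verified), so the parameter set is really
dimensionless-shape plus one time unit.

Ensembles use 150–200 independent desynchronised lineages simulated for
14 doubling times (burn-in included), sampling each lineage once at the
end; these sizes keep the full directional panel under a minute on one
core while keeping the seed-to-seed spread of origin-concentration ratios
near ±0.03.  Lineage sampling weights cells differently from the
population age distribution; since phenotypes are ratios to a baseline
measured the same way, the bias cancels.

## Transposon-pool evolution

Serial passage is modelled as deterministic exponential growth within a
transfer cycle — clone *i* multiplies by `(1+s_i)^10` per 10-generation
cycle — with multinomial resampling at each transfer bottleneck (default
10⁶ cells; the real dilution factor is not published, so it is exposed as
a parameter, and `None` gives the infinite-population limit).  Frequencies
are recorded at 100-generation samples over 700 generations.  Blot-style
clonality is the number of clones above a detection threshold (default
5%).  Pairwise competitions report log₁₀ CFU ratios on a 10-generation
sampling grid with per-interval dilution back to the inoculum scale; with
`Δs = 0.043` the 80-generation log difference is 1.46.  Fitness values can
be supplied directly or via a pluggable `fitness_map(position)` hook when
generating pools — mapping replication phenotypes to fitness is explicitly
a model choice, not a measured relation.

## Junction-read insertion calling

Reads are assumed to span the transposon–genome junction.  The caller
finds the transposon end in the read (last exact occurrence, or bounded
edit distance via edlib; reads consisting only of transposon sequence end
up with an empty flank and are skipped and counted), extracts the genomic
flank (≥ `min_seed` = 20 bp, else skipped and counted) and locates it by
exact substring search on both strands of the circularly extended
reference, falling back to edlib infix alignment (edit distance ≤ 10% of
the flank length) for reads with errors.  Reported positions are 0-based:
the first reference base after the junction on the + strand.  Flanks with
multiple equally good reference locations are flagged ambiguous, never
silently assigned.  Calls within 3 bp on the same strand are merged onto
the best-supported position.  On synthetic fixtures the caller achieves
exact recovery on error-free reads and ≥ 95% recall (in practice ≈ 100%)
at 1% substitution error.

## Synthetic data

Generators emulate (i) a random-sequence circular genome (default 1/10
scale, 464,165 bp, GC 0.508) with the 13 named map features at their
minute positions, (ii) junction reads (fixed-length transposon tag +
genomic flank, uniform substitution errors, constant Phred 40 qualities),
(iii) uniform neutral insertion pools, and (iv) run-out origin histograms
with instrument noise.  They do **not** emulate indels, quality-score
profiles, library-prep or GC bias, coverage fluctuations, real genome
sequence composition, macrodomain structure, or growth-condition effects
beyond the (C, D, τ) triple — so passing tests demonstrate correctness of
the algorithms under the stated generative assumptions, not robustness to
every artefact of real sequencing or cytometry data.  Every generator is
byte-reproducible under a fixed seed and writes a JSON truth file.

## Numerical notes and limitations

* Time step: `dt` must satisfy `dt ≤ min(τ, C)/20` (guarded); pools are
  updated with clipped forward-Euler steps that cannot go negative.
* Stochastic rounding at division keeps chromosome counts integral; the
  clamp to at least one chromosome is reachable only in pathological
  parameter regimes.
* The asynchrony index is undefined for populations without ≥ 2-origin
  cells; ensemble measurements report it as NaN ("undefined") rather than
  failing, so calibration can traverse starved parameter regions.
* The regulatory model reproduces signs and orderings, not measured
  origin-concentration magnitudes; fitting rate constants to measured
  tables is possible in principle but out of scope.
* The evolution simulator ignores mutation, clonal interference from *de
  novo* variants, and frequency-dependent effects; clone fitnesses are
  constants.
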