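# orichron

Modelling how the *chromosomal position* of replication-control loci shapes
the *E. coli* cell cycle.

Chromosome replication in *E. coli* starts at a single origin, *oriC*, and
is controlled by the nucleotide state of the initiator protein DnaA: only
DnaA·ATP triggers initiation.  Three non-coding loci tune the
DnaA·ATP/DnaA·ADP balance — *datA* (promotes ATP hydrolysis, DDAH),
*DARS1* (constitutive reactivation of DnaA·ADP) and *DARS2* (reactivation
gated by IHF/Fis to a window just before initiation).  Because a locus
close to *oriC* is duplicated early and therefore has a higher
replication-associated copy number, *where* these loci sit on the circular
map is itself a regulatory parameter.  `orichron` provides the
computational toolkit for studying exactly that: coordinate arithmetic on
the circular map, the Cooper–Helmstetter copy-number algebra, a multifork
run-out/flow-cytometry simulator, the asynchrony index, a mechanistic
DnaA-cycle model in which genotypes (deletions, relocations, extra copies,
transcriptional inactivation of loci) produce origin-concentration and
synchrony phenotypes, and a serial-passage transposon-pool evolution
simulator with a junction-read insertion-site caller.

It is aimed at bacterial cell-cycle researchers who want a tested,
reproducible desk counterpart to flow-cytometry run-out experiments and
transposon relocation/selection screens.

## The core quantities

With replication period `C`, post-termination period `D` and doubling time
`τ` (minutes), a locus at arm fraction `x` (0 at *oriC*, 1 at *terC*) has
population-average copy number

    X(x) = 2^((C(1−x) + D)/τ)

so the mean origins per cell is `X(0)` and the mean DNA content in genome
equivalents is

    G = τ/(C ln 2) · (2^((C+D)/τ) − 2^(D/τ)).

Run-out (rifampicin + cephalexin) lets every active round finish without
new initiations or division, so flow cytometry counts the origins present
at drug addition; synchronously initiating cells show only 2ⁿ origins.
The asynchrony index `A` is the fraction of cells with ≥ 3, non-power-of-two
origins among cells with ≥ 2 origins; a strain is called asynchronous when
`A > 0.1` (strictly).

The DnaA-cycle model couples these pieces: synthesis (mass-coupled,
modulated by *dnaA* gene dosage), RIDA (per replisome), DDAH (per *datA*
copy), *DARS1*/*DARS2* reactivation (per copy; *DARS2* only in a short
pre-initiation window), a per-origin DnaA·ATP threshold, and a firing
cascade in which origins fail stochastically when the pool cannot cover
them — the model's route to asynchrony.  See `docs/methods.md` for the full
model description and parameter table.

## Worked example

```python
from orichron import (
    CellCycleParams, gene_dosage, genome_equivalents, origins_per_cell,
    relative_distance, sample_population, origin_distribution,
    asynchrony_index,
)

cc = CellCycleParams(C=42, D=33, tau=40)   # glucose + casamino acids, 37 °C

# datA sits at 94.6 min, oriC at 84.6 min on the 100-min map
rd = relative_distance(94.6, 84.6)          # -> 0.10
x = 2 * rd                                   # arm fraction, terC antipodal
print(round(rd, 2), round(gene_dosage(x, cc), 2))
# 0.1 3.17        (datA: relative distance 0.10, ~3.17 copies per cell)

print(round(origins_per_cell(cc), 3), round(genome_equivalents(cc), 3))
# 3.668 2.606     (mean origins per cell and genome equivalents)

pop = sample_population(100_001, cc, stratified=True)
freq = origin_distribution(pop).frequencies()
print({k: round(v, 3) for k, v in freq.items()})
# {2: 0.166, 4: 0.834}   (run-out: 16.6% of cells with 2 origins, rest 4)

print(asynchrony_index(origin_distribution(pop)))
# AsynchronyResult(A=0.0, classification='synchronous')
```

The regulatory model turns genotypes into phenotypes relative to a
calibrated wild type:

```python
from orichron import dnaa_cycle as dc

reg = dc.calibrate(cc, seed=0)
wt = dc.wild_type()
base = dc.raw_phenotype(wt, reg, cc, n_cells=150, seed=1)
ph = dc.phenotype(wt.without("DARS2"), reg, cc, n_cells=150, seed=7,
                  baseline=base.raw_origins_per_mass)
print(round(ph.origins_per_mass_rel, 2), round(ph.A, 2))
# 0.52 0.35       (DARS2 deletion: lower origin concentration, asynchronous)
```

A command-line interface mirrors the main operations
(`orichron distance`, `dosage`, `runout`, `flow-hist`, `asynchrony`,
`evolve`, `map-insertions`, `orichron synth …`); every subcommand takes
`--seed` where randomness is involved.

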