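"""Seeded generators for every input the pipeline consumes.

Each generator is deterministic under a fixed seed and writes a JSON "truth"
file next to its output, so downstream exact-recovery tests never have to
parse logs.  The default synthetic genome is a 1/10-scale stand-in for the
MG1655 chromosome (464,165 bp) carrying the origin, terminus and regulatory
loci at their map-minute positions; full-scale generation is supported by
setting ``genome_length_bp``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_cycle import CellCycleParams
from .errors import ConfigurationError, ParameterError, ValidationError
from .genome_map import DEFAULT_LOCI
from .multifork import (
    OriginHistogram,
    flow_histogram,
    origin_distribution,
    sample_population,
)
from .asynchrony import inject_asynchrony

#: 24 bp of the IS10-right end of the Tn10-derived mini-transposon family;
#: synthetic stand-in used as the junction tag of generated reads.
DEFAULT_TN_END = "CTGATGAATCCCCTAATGATTTTG"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic data-generating process."""

    seed: int = 0
    genome_length_bp: int = 464_165
    gc_fraction: float = 0.508
    loci: dict = field(default_factory=lambda: dict(DEFAULT_LOCI))
    read_length: int = 100
    error_rate: float = 0.0
    n_cells: int = 30_000
    init_cv: float = 0.0
    pool_size: int = 70_000

    def __post_init__(self):
        if not 0 <= self.error_rate < 1:
            raise ParameterError("error_rate must be in [0, 1)")
        if not 0 < self.gc_fraction < 1:
            raise ParameterError("gc_fraction must be in (0, 1)")
        if self.genome_length_bp < 1000:
            raise ParameterError("genome must be at least 1 kb")


def _write_truth(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, default=str) + "\n")


def make_reference(spec: SyntheticSpec, out_dir: str | Path):
    """Random-sequence circular reference with the regulatory-locus map.

    Writes ``reference.fa``, ``loci.csv`` (genome_map CSV format) and
    ``reference.truth.json``; returns their paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=spec.genome_length_bp, p=probs))

    for name, pos in spec.loci.items():
        if not 0 <= pos < 100.0:
            raise ValidationError(f"locus {name!r} at {pos} min is off the map")

    fasta = out_dir / "reference.fa"
    with fasta.open("w") as fh:
        fh.write(">synthetic_chromosome circular\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")

    loci_csv = out_dir / "loci.csv"
    with loci_csv.open("w") as fh:
        fh.write("name,position,unit\n")
        for name, pos in spec.loci.items():
            fh.write(f"{name},{pos},min\n")

    truth = out_dir / "reference.truth.json"
    _write_truth(
        truth,
        {
            "seed": spec.seed,
            "genome_length_bp": spec.genome_length_bp,
            "gc_fraction": spec.gc_fraction,
            "loci_min": spec.loci,
        },
    )
    return fasta, loci_csv, truth


def _load_or_pass_seq(reference) -> str:
    from .evolution import _single_seq

    return _single_seq(reference)


def make_junction_reads(
    reference,
    insertions: list[tuple[int, str, float]],
    out_fastq: str | Path,
    tn_end: str = DEFAULT_TN_END,
    read_length: int = 100,
    n_reads: int = 1000,
    error_rate: float = 0.0,
    min_flank: int = 30,
    seed: int = 0,
):
    """Junction-spanning FASTQ reads for a set of planted insertions.

    ``insertions`` is a list of ``(position_bp, strand, weight)``; weights
    must sum to 1.  Every read is the transposon end followed by
    ``read_length - len(tn_end)`` genomic bases at the insertion point (on
    the insertion's strand; the genome is treated as circular), with
    independent substitution errors at ``error_rate``.  A truth JSON is
    written next to the FASTQ.
    """
    seq = _load_or_pass_seq(reference)
    L = len(seq)
    flank_len = read_length - len(tn_end)
    if flank_len < 2 * min_flank:
        raise ConfigurationError(
            f"read_length={read_length} leaves a {flank_len} bp flank; "
            f"need at least 2 * min_flank = {2 * min_flank}"
        )
    weights = np.array([w for _, _, w in insertions], dtype=float)
    if len(insertions) and not math.isclose(weights.sum(), 1.0, rel_tol=1e-6):
        raise ParameterError(f"insertion weights sum to {weights.sum()}, not 1")
    for pos, strand, _ in insertions:
        if not 0 <= pos < L:
            raise ParameterError(f"insertion at {pos} outside genome of {L} bp")
        if strand not in "+-":
            raise ParameterError(f"bad strand {strand!r}")

    from .evolution import revcomp

    rng = np.random.default_rng(seed)
    out_fastq = Path(out_fastq)
    out_fastq.parent.mkdir(parents=True, exist_ok=True)
    bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    doubled = seq + seq  # circular flanks
    with out_fastq.open("w") as fh:
        if n_reads > 0:
            choices = rng.choice(len(insertions), size=n_reads, p=weights)
            for i, idx in enumerate(choices):
                pos, strand, _ = insertions[idx]
                if strand == "+":
                    flank = doubled[pos : pos + flank_len]
                else:
                    flank = revcomp(doubled[pos - flank_len + L : pos + L])
                read = tn_end + flank
                if error_rate > 0:
                    arr = np.array(list(read))
                    hit = rng.random(len(arr)) < error_rate
                    if hit.any():
                        arr[hit] = bases[rng.integers(0, 4, size=int(hit.sum()))]
                    read = "".join(arr)
                fh.write(
                    f"@junction_{i} insertion={pos}{strand}\n{read}\n+\n"
                    f"{'I' * len(read)}\n"
                )
    truth = out_fastq.with_suffix(".truth.json")
    _write_truth(
        truth,
        {
            "seed": seed,
            "tn_end": tn_end,
            "read_length": read_length,
            "n_reads": n_reads,
            "error_rate": error_rate,
            "insertions": [
                {"position_bp": p, "strand": s, "weight": w}
                for p, s, w in insertions
            ],
        },
    )
    return out_fastq, truth


def make_pool(spec: SyntheticSpec, out_csv: str | Path, fitness_map=None):
    """Uniform random insertion pool (one clone per insertion).

    ``fitness_map`` is an optional ``f(position_bp) -> s`` hook; the default
    pool is neutral.  Writes a clone CSV plus truth JSON; returns the paths.
    """
    if spec.pool_size < 1:
        raise ParameterError("pool_size must be >= 1")
    rng = np.random.default_rng(spec.seed)
    pos = np.sort(rng.integers(0, spec.genome_length_bp, size=spec.pool_size))
    strand = np.where(rng.random(spec.pool_size) < 0.5, "+", "-")
    fitness = (
        np.array([fitness_map(int(p)) for p in pos], dtype=float)
        if fitness_map is not None
        else np.zeros(spec.pool_size)
    )
    df = pd.DataFrame(
        {
            "position_bp": pos,
            "strand": strand,
            "fitness": fitness,
            "frequency": np.full(spec.pool_size, 1.0 / spec.pool_size),
        }
    )
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_csv, index=False)
    _write_truth(
        out_csv.with_suffix(".truth.json"),
        {
            "seed": spec.seed,
            "pool_size": spec.pool_size,
            "genome_length_bp": spec.genome_length_bp,
            "neutral": fitness_map is None,
        },
    )
    return out_csv, out_csv.with_suffix(".truth.json")


def make_flow_sample(
    cc: CellCycleParams,
    n_cells: int = 30_000,
    p_fail: float = 0.0,
    init_cv: float = 0.0,
    cv: float = 0.05,
    channels: int = 256,
    seed: int = 0,
    out_dir: str | Path | None = None,
):
    """Synthetic run-out flow-cytometry sample.

    Composes the population sampler, optional per-origin initiation-failure
    injection, run-out and the channelised instrument model.  Returns the
    origin histogram and the channelised frame; with ``out_dir`` both are
    also written as CSV together with a truth JSON.
    """
    pop = sample_population(n_cells, cc, init_cv=init_cv, seed=seed)
    if p_fail > 0:
        pop = inject_asynchrony(pop, p_fail, cc, seed=seed + 1)
    hist = origin_distribution(pop)
    flow = flow_histogram(hist, cv=cv, channels=channels, seed=seed + 2)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        hist.to_frame().to_csv(out_dir / "origin_histogram.csv", index=False)
        flow.to_csv(out_dir / "flow_histogram.csv", index=False)
        _write_truth(
            out_dir / "flow.truth.json",
            {
                "seed": seed,
                "n_cells": n_cells,
                "p_fail": p_fail,
                "init_cv": init_cv,
                "cv": cv,
                "C": cc.C,
                "D": cc.D,
                "tau": cc.tau,
            },
        )
    return hist, flow


def read_origin_histogram(path: str | Path) -> OriginHistogram:
    """Read an ``origin_count,frequency`` CSV back into a histogram."""
    df = pd.read_csv(path)
    counts = dict(
        zip(df["origin_count"].astype(int), df["frequency"].astype(float))
    )
    return OriginHistogram(counts=counts, n_cells=0)
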