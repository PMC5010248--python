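"""Pooled-transposon culture evolution and junction-read insertion mapping.

Emulates a serial-passage competition: a pool of ~70,000 clones, each
carrying a mini-transposon insertion at a random chromosomal position, is
grown in batch and diluted every ~10 generations for 700 generations.
Growth within a transfer cycle is deterministic exponential (clone *i*
multiplies by ``(1 + s_i) ** transfer_every``); genetic drift enters only at
the transfer bottleneck, where the new population is a multinomial sample of
``bottleneck_cells`` individuals.  Southern-blot style clonality is
summarised by :func:`band_count` (clones above a detection threshold), and
head-to-head fitness by :func:`pairwise_competition` (log10 CFU
difference trajectories).

Insertion sites are recovered from junction-spanning reads: each read is the
known transposon end followed by the genomic flank at the insertion point.
:func:`call_insertion_sites` finds the transposon end in each read (exact
match, or bounded edit distance as a fallback), extracts the flank and
locates it in the reference on either strand -- exact substring search
first, approximate infix alignment (edlib) for reads with sequencing
errors.  Flanks matching more than one reference position are reported as
ambiguous, never silently assigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import EmptyInputError, ParameterError

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class InsertionClone:
    """One transposon-insertion clone in the pool."""

    position_bp: int
    strand: str = "+"
    fitness: float = 0.0  # relative per-generation growth advantage s
    frequency: float = 0.0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ParameterError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.frequency <= 1:
            raise ParameterError("frequency outside [0, 1]")


@dataclass
class PassageTrajectory:
    """Clone frequencies across a serial-passage experiment."""

    generations: np.ndarray          # sampling times, multiples of transfer interval
    frequencies: np.ndarray          # (n_clones, n_samples); columns sum to 1
    clones: pd.DataFrame             # position_bp, strand, fitness

    def at(self, generation: float) -> np.ndarray:
        """Frequency vector at a sampled generation."""
        idx = np.where(np.isclose(self.generations, generation))[0]
        if len(idx) == 0:
            raise ParameterError(
                f"generation {generation} was not sampled; have {self.generations}"
            )
        return self.frequencies[:, idx[0]]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"gen_{int(g)}": self.frequencies[:, i]
                for i, g in enumerate(self.generations)}
        return pd.concat([self.clones.reset_index(drop=True), pd.DataFrame(cols)], axis=1)


def simulate_competition(
    pool: Sequence[InsertionClone] | pd.DataFrame,
    total_gens: int = 700,
    transfer_every: int = 10,
    bottleneck_cells: int | None = 1_000_000,
    sample_every: int = 100,
    seed: int | None = None,
) -> PassageTrajectory:
    """Serial-passage competition of an insertion pool.

    ``bottleneck_cells=None`` gives the deterministic (infinite-population)
    limit.  Frequencies are recorded at ``sample_every``-generation
    intervals (including generation 0 and the final generation).
    """
    clones = _as_frame(pool)
    if len(clones) == 0:
        raise EmptyInputError("empty insertion pool")
    if bottleneck_cells is not None and bottleneck_cells < 1:
        raise ParameterError("bottleneck_cells must be >= 1")
    if total_gens % transfer_every != 0:
        raise ParameterError("total_gens must be a multiple of transfer_every")
    freq = clones["frequency"].to_numpy(dtype=float)
    if freq.sum() <= 0:
        freq = np.full(len(clones), 1.0 / len(clones))
    freq = freq / freq.sum()
    growth = (1.0 + clones["fitness"].to_numpy(dtype=float)) ** transfer_every
    rng = np.random.default_rng(seed)

    sample_gens = [0]
    samples = [freq.copy()]
    for cycle in range(total_gens // transfer_every):
        freq = freq * growth
        freq = freq / freq.sum()
        if bottleneck_cells is not None:
            counts = rng.multinomial(bottleneck_cells, freq)
            freq = counts / bottleneck_cells
        gen = (cycle + 1) * transfer_every
        if gen % sample_every == 0 or gen == total_gens:
            sample_gens.append(gen)
            samples.append(freq.copy())
    return PassageTrajectory(
        generations=np.asarray(sample_gens, dtype=float),
        frequencies=np.column_stack(samples),
        clones=clones[["position_bp", "strand", "fitness"]].copy(),
    )


def _as_frame(pool) -> pd.DataFrame:
    if isinstance(pool, pd.DataFrame):
        df = pool.copy()
        if "frequency" not in df:
            df["frequency"] = 1.0 / max(len(df), 1)
        for col, default in (("strand", "+"), ("fitness", 0.0)):
            if col not in df:
                df[col] = default
        return df
    return pd.DataFrame(
        [
            {
                "position_bp": c.position_bp,
                "strand": c.strand,
                "fitness": c.fitness,
                "frequency": c.frequency,
            }
            for c in pool
        ]
    )


def heterozygosity(freq: np.ndarray) -> float:
    """Probability that two random individuals are different clones."""
    f = np.asarray(freq, dtype=float)
    return float(1.0 - np.sum(f * f))


def band_count(frequencies: np.ndarray, detection_threshold: float = 0.05) -> int:
    """Number of clones visible as separate bands on a blot: clones whose
    frequency reaches the detection threshold."""
    if not 0 < detection_threshold < 1:
        raise ParameterError("detection_threshold must be in (0, 1)")
    f = np.asarray(frequencies, dtype=float)
    return int(np.sum(f >= detection_threshold))


def pairwise_competition(
    s_a: float,
    s_b: float,
    gens: int = 80,
    start_cfu_per_ml: float = 1e7,
    sample_every: int = 10,
    bottleneck_cells: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Head-to-head competition of two strains, sampled by plate counts.

    Returns a frame with generation, CFU/ml of each competitor and the
    log10 ratio A/B.  Deterministic unless a transfer bottleneck is given.
    With equal inoculum the log10 difference after ``g`` generations is
    ``g * log10((1 + s_a) / (1 + s_b))``.
    """
    if gens % sample_every != 0:
        raise ParameterError("gens must be a multiple of sample_every")
    rng = np.random.default_rng(seed)
    n_a = n_b = float(start_cfu_per_ml)
    rows = [
        {"generation": 0, "cfu_a": n_a, "cfu_b": n_b, "log10_ratio": 0.0}
    ]
    extinct = False
    for step in range(gens // sample_every):
        n_a *= (1.0 + s_a) ** sample_every
        n_b *= (1.0 + s_b) ** sample_every
        # dilute back to the inoculum scale each sampling interval
        total = n_a + n_b
        scale = 2.0 * start_cfu_per_ml / total
        n_a, n_b = n_a * scale, n_b * scale
        if bottleneck_cells is not None:
            draw = rng.binomial(
                int(bottleneck_cells), n_a / (n_a + n_b)
            )
            frac_a = draw / bottleneck_cells
            n_a = 2.0 * start_cfu_per_ml * frac_a
            n_b = 2.0 * start_cfu_per_ml * (1.0 - frac_a)
        gen = (step + 1) * sample_every
        if n_a <= 0 or n_b <= 0:
            extinct = True
            rows.append(
                {"generation": gen, "cfu_a": n_a, "cfu_b": n_b,
                 "log10_ratio": math.inf if n_b <= 0 else -math.inf}
            )
            break
        rows.append(
            {
                "generation": gen,
                "cfu_a": n_a,
                "cfu_b": n_b,
                "log10_ratio": math.log10(n_a / n_b),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["extinct"] = extinct
    return out


# ---------------------------------------------------------------------------
# junction-read insertion-site calling
# ---------------------------------------------------------------------------


@dataclass
class InsertionCallSet:
    """Result of mapping junction reads: one row per called site plus
    bookkeeping counters."""

    calls: pd.DataFrame         # position_bp, strand, support, ambiguous
    n_reads: int
    skipped_short_flank: int
    skipped_no_transposon: int

    def unambiguous(self) -> pd.DataFrame:
        return self.calls[~self.calls["ambiguous"]].reset_index(drop=True)


def _read_seqs(reads) -> list[str]:
    if isinstance(reads, (str, Path)):
        return [str(rec.seq) for rec in SeqIO.parse(str(reads), "fastq")]
    out = []
    for r in reads:
        out.append(str(r[1]) if isinstance(r, tuple) else str(r))
    return out


def _single_seq(ref) -> str:
    looks_like_path = (
        isinstance(ref, Path)
        or (isinstance(ref, str) and len(ref) < 256 and "\n" not in ref)
    )
    try:
        is_file = looks_like_path and Path(str(ref)).exists()
    except OSError:
        is_file = False
    if is_file:
        recs = list(SeqIO.parse(str(ref), "fasta"))
        if not recs:
            raise EmptyInputError(f"no sequences in {ref}")
        return str(recs[0].seq).upper()
    return str(ref).upper()


def _find_all(needle: str, haystack: str) -> list[int]:
    hits, start = [], haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def _locate_tn_end(read: str, tn_end: str, max_edits: int) -> tuple[int, str] | None:
    """Return (flank start in read, orientation) or None.

    Orientation 'F': read runs transposon-end -> genomic flank; 'R': the
    read is the reverse complement of that layout.
    """
    pos = read.rfind(tn_end)  # last occurrence: the flank must be genomic
    if pos != -1:
        return pos + len(tn_end), "F"
    rc = revcomp(tn_end)
    pos = read.find(rc)
    if pos != -1:
        return pos, "R"
    if max_edits > 0:
        res = edlib.align(tn_end, read, mode="HW", task="locations", k=max_edits)
        if res["editDistance"] != -1 and res["locations"]:
            return res["locations"][0][1] + 1, "F"
        res = edlib.align(rc, read, mode="HW", task="locations", k=max_edits)
        if res["editDistance"] != -1 and res["locations"]:
            return res["locations"][0][0], "R"
    return None


def _locate_flank(flank: str, ref: str, ref_rc: str, max_edits: int, ext: int):
    """Locate a genomic flank on either strand of a circular reference.

    Both strands are searched on the reference extended by ``ext`` bases of
    its own start (so junctions spanning the coordinate origin are found);
    hit coordinates are folded modulo the genome length.  Returns
    (position, strand, ambiguous) or None; the position is the first
    reference base after the junction on the + strand.
    """
    L = len(ref)
    ref_ext = ref + ref[:ext]
    ref_rc_ext = ref_rc + ref_rc[:ext]
    fwd = {h % L for h in _find_all(flank, ref_ext)}
    rev = {h % L for h in _find_all(flank, ref_rc_ext)}
    n_exact = len(fwd) + len(rev)
    if n_exact >= 1:
        if fwd:
            return min(fwd), "+", n_exact > 1
        return (L - min(rev)) % L, "-", n_exact > 1
    if max_edits <= 0:
        return None
    best = None
    for target, strand in ((ref_ext, "+"), (ref_rc_ext, "-")):
        res = edlib.align(flank, target, mode="HW", task="locations", k=max_edits)
        if res["editDistance"] == -1:
            continue
        starts = {l[0] % L for l in res["locations"]}
        pos = min(starts) if strand == "+" else (L - min(starts)) % L
        if best is None or res["editDistance"] < best[0]:
            best = (res["editDistance"], pos, strand, len(starts) > 1)
        elif res["editDistance"] == best[0]:
            best = (best[0], best[1], best[2], True)
    if best is None:
        return None
    return best[1], best[2], best[3]


def call_insertion_sites(
    reads,
    transposon_end: str,
    reference,
    min_seed: int = 20,
    max_edit_frac: float = 0.1,
    cluster_tolerance: int = 3,
) -> InsertionCallSet:
    """Call transposon insertion sites from junction-spanning reads.

    ``reads`` may be a FASTQ path or an iterable of sequences; ``reference``
    a FASTA path or a sequence string.  Reads whose genomic flank is shorter
    than ``min_seed`` are skipped (and counted); flanks matching multiple
    reference positions are reported with ``ambiguous=True``.  Calls within
    ``cluster_tolerance`` bp on the same strand are merged onto the
    best-supported position.
    """
    tn = str(transposon_end).upper()
    if len(tn) < min_seed:
        raise ParameterError(
            f"transposon end ({len(tn)} bp) shorter than min_seed={min_seed}"
        )
    ref = _single_seq(reference)
    ref_rc = revcomp(ref)
    seqs = _read_seqs(reads)
    tn_edits = max(1, round(max_edit_frac * len(tn)))
    raw: dict[tuple[int, str, bool], int] = {}
    skipped_short = skipped_no_tn = 0
    for seq in seqs:
        seq = seq.upper()
        hit = _locate_tn_end(seq, tn, tn_edits)
        if hit is None:
            skipped_no_tn += 1
            continue
        cut, orient = hit
        flank = seq[cut:] if orient == "F" else revcomp(seq[:cut])
        if len(flank) < min_seed:
            skipped_short += 1
            continue
        loc = _locate_flank(
            flank, ref, ref_rc,
            max_edits=max(1, round(max_edit_frac * len(flank))),
            ext=len(seq),
        )
        if loc is None:
            skipped_no_tn += 1
            continue
        pos, strand, ambiguous = loc
        key = (pos, strand, ambiguous)
        raw[key] = raw.get(key, 0) + 1

    calls = _cluster_calls(raw, cluster_tolerance)
    return InsertionCallSet(
        calls=calls,
        n_reads=len(seqs),
        skipped_short_flank=skipped_short,
        skipped_no_transposon=skipped_no_tn,
    )


def _cluster_calls(raw: dict, tolerance: int) -> pd.DataFrame:
    rows = [
        {"position_bp": pos, "strand": strand, "support": n, "ambiguous": amb}
        for (pos, strand, amb), n in raw.items()
    ]
    if not rows:
        return pd.DataFrame(
            columns=["position_bp", "strand", "support", "ambiguous"]
        ).astype({"position_bp": int, "support": int, "ambiguous": bool})
    df = pd.DataFrame(rows).sort_values(
        ["strand", "position_bp"], kind="stable"
    )
    merged = []
    for (strand,), grp in df.groupby(["strand"]):
        grp = grp.sort_values("position_bp")
        cluster: list[dict] = []
        for _, row in grp.iterrows():
            if cluster and row["position_bp"] - cluster[-1]["position_bp"] > tolerance:
                merged.append(_merge_cluster(cluster))
                cluster = []
            cluster.append(row.to_dict())
        if cluster:
            merged.append(_merge_cluster(cluster))
    out = pd.DataFrame(merged).sort_values(
        ["position_bp", "strand"], ignore_index=True
    )
    return out.astype(
        {"position_bp": int, "support": int, "ambiguous": bool}
    )


def _merge_cluster(cluster: list[dict]) -> dict:
    best = max(cluster, key=lambda r: r["support"])
    return {
        "position_bp": best["position_bp"],
        "strand": best["strand"],
        "support": int(sum(r["support"] for r in cluster)),
        "ambiguous": bool(any(r["ambiguous"] for r in cluster)),
    }


def insertion_density(n_insertions: int, genome_length_bp: int) -> float:
    """Mean base pairs per insertion for a pool of the given size."""
    if n_insertions < 1:
        raise ParameterError("n_insertions must be >= 1")
    return genome_length_bp / n_insertions
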