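"""Synthetic small-RNA datasets with machine-readable ground truth.

Generates a random genome with planted features mirroring the statistical
structure of reproductive 24-nt phasiRNA data:

* **PHAS loci** — a 22-nt miRNA target site whose predicted cleavage
  position sets the phase register, followed by 24-nt duplex reads at
  successive Dicer cycles on both strands (2-nt 3' overhang offset). A read
  is in-register with probability ``phased_fraction``; the rest fall at
  uniform positions inside the locus.
* **hc-siRNA loci** — abundant but unphased 24-nt reads at uniform
  positions/strands, the main confounder of 24-nt PHAS detection.
* **MIR clusters** — polycistrons of 2-6 perfect stem-loops (mature + loop
  + reverse-complement arm) separated by tens of nucleotides, emitting
  mature and star reads.
* **degradome** — a count spike at every true cleavage position plus
  uniform low-level noise.
* **stage series** — an ordered tissue series whose phasiRNA and miRNA
  abundances follow a unimodal profile peaking at a meiotic-like stage;
  hc-siRNA and background abundances stay flat.

Identical seeds produce byte-identical outputs. Every emitted read traces
to exactly one truth record or to background.

The cis-propagation simulator models the hypothesized origin of 12-nt
phasing: either strand of a 24-nt phasiRNA duplex can direct a cis cleavage
whose downstream fragment seeds secondary phasiRNAs shifted by 12 nt, so
after two or more generations the register spectrum concentrates on two
registers 12 apart. How such a feedback loop initiates in vivo is an open
question; the simulator starts it from the primary register by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from .core_io import (
    CollapsedRead,
    DegradomeTable,
    GenomeSequence,
    SrnaAlignment,
    revcomp,
    write_fasta,
)
from .quantify import LibraryInfo

logger = logging.getLogger(__name__)

DEFAULT_STAGES = (
    "MDS_I", "MDS_II", "MDS_III", "MDS_IV", "MDS_V",
    "MFB_I", "MFB_II", "MFB_III", "MFB_IV",
    "FFB_I", "FFB_II", "FFB_III",
)
# unimodal, ephemeral profile peaking sharply at the meiotic-like stage
# MDS_V, falling off through male flower-bud stages and low in female buds.
# The peak must dominate its neighbors even after reads-per-ten-million
# normalization, whose denominator itself swells at the peak stage.
DEFAULT_MULTIPLIERS = (0.02, 0.05, 0.12, 0.30, 1.00, 0.40, 0.25, 0.12, 0.06, 0.15, 0.08, 0.04)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset. ``seed`` is mandatory."""

    seed: int
    genome_length: int = 200_000
    n_phas_loci: int = 8
    n_hc_loci: int = 30
    n_cis_loci: int = 0
    n_mir_clusters: int = 2
    hairpins_per_cluster: tuple[int, int] = (2, 6)
    cluster_gap_range: tuple[int, int] = (30, 120)
    loop_range: tuple[int, int] = (8, 15)
    P: int = 24
    cycles: int = 20
    phased_fraction: float = 0.8
    strand_balance: float = 0.5
    locus_depth: int = 400
    hc_positions: int = 40
    hc_depth: int = 200
    background_reads: int = 300
    mirna_family_size: int = 4
    mir_read_depth: int = 60
    degradome_spike: int = 40
    degradome_noise: int = 100
    stage_labels: tuple[str, ...] = DEFAULT_STAGES
    stage_multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS
    stage_noise_sigma: float = 0.15
    cis_generations: int = 3
    cis_trigger_prob: float = 0.5
    cis_decay: float = 0.5
    cis_cycles: int = 10
    cis_secondary_cycles: int = 4
    cis_base_count: int = 10
    feature_margin: int = 700

    def __post_init__(self) -> None:
        if not (0.0 <= self.phased_fraction <= 1.0):
            raise ValueError("phased_fraction must be in [0, 1]")
        if len(self.stage_labels) != len(self.stage_multipliers):
            raise ValueError("stage_labels and stage_multipliers must align")


@dataclass
class TruthRecord:
    """Ground truth for one planted feature."""

    feature_id: str
    kind: str  # PHAS | HC | MIR_cluster | PHAS_CIS
    chrom: str
    start: int
    end: int
    strand: str
    register: int | None = None
    registers_12: tuple[int, int] | None = None
    trigger_name: str | None = None
    trigger_seq: str | None = None
    trigger_site: tuple[int, int] | None = None
    cleavage_pos: int | None = None
    mature_seqs: tuple[str, ...] = ()
    hairpin_spans: tuple[tuple[int, int], ...] = ()
    stage_abundance: dict = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: list[GenomeSequence]
    libraries: dict[str, list[CollapsedRead]]  # stage label -> collapsed reads
    degradome: DegradomeTable
    truth: list[TruthRecord]
    mirnas: dict[str, str]

    def library_info(self) -> list[LibraryInfo]:
        """Stage metadata with genome-matched totals (all simulated reads map)."""
        return [
            LibraryInfo(
                lib_id=stage,
                stage=stage,
                order=i,
                total_mapped=sum(r.count for r in self.libraries[stage]),
            )
            for i, stage in enumerate(self.config.stage_labels)
        ]


class PlacementError(RuntimeError):
    pass


def _place(rng, length: int, occupied: list[tuple[int, int]], genome_length: int,
           margin: int, retries: int = 500) -> int:
    for _ in range(retries):
        start = int(rng.integers(margin, genome_length - length - margin))
        if all(start >= e + margin or start + length + margin <= s for s, e in occupied):
            occupied.append((start, start + length))
            return start
    raise PlacementError(
        "could not place a feature without overlap; increase genome_length"
    )


def _rand_seq(rng, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


def _read_seq(genome_seq: str, pos5: int, strand: str, length: int) -> str:
    if strand == "+":
        return genome_seq[pos5 : pos5 + length]
    return revcomp(genome_seq[pos5 - length + 1 : pos5 + 1])


def _mirna_family(rng, size: int) -> dict[str, str]:
    """A family of distinct 22-nt matures within Hamming distance 3 of a base."""
    base = _rand_seq(rng, 22)
    family = {"mir2275-sim1": base}
    i = 2
    while len(family) < size:
        n_sub = int(rng.integers(1, 4))
        seq = list(base)
        for p in rng.choice(22, size=n_sub, replace=False):
            choices = [b for b in "ACGT" if b != seq[p]]
            seq[p] = choices[int(rng.integers(0, 3))]
        cand = "".join(seq)
        if cand not in family.values():
            family[f"mir2275-sim{i}"] = cand
            i += 1
    return family


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a genome, staged read libraries, degradome, and truth table."""
    rng = np.random.default_rng(config.seed)
    P, cycles = config.P, config.cycles
    chrom = "chr1"
    genome_arr = _BASES[rng.integers(0, 4, size=config.genome_length)].copy()

    mirnas = _mirna_family(rng, config.mirna_family_size)
    mirna_items = list(mirnas.items())

    occupied: list[tuple[int, int]] = []
    truth: list[TruthRecord] = []
    # emissions: (feature_id, pos5, strand, length, base_count, staged)
    emissions: list[tuple[str, int, str, int, int, bool]] = []

    def plant(start: int, seq: str) -> None:
        genome_arr[start : start + len(seq)] = np.frombuffer(seq.encode(), dtype=np.uint8)

    # --- PHAS loci with planted triggers -----------------------------------
    env_len = P * cycles
    for i in range(config.n_phas_loci):
        name, mseq = mirna_items[i % len(mirna_items)]
        block = 22 + env_len + 10
        b = _place(rng, block, occupied, config.genome_length, config.feature_margin)
        site = (b, b + 22)
        plant(b, revcomp(mseq))  # perfect target site on the plus (transcript) strand
        cleavage = b + 12
        register = cleavage % P
        env = (cleavage, cleavage + env_len)
        fid = f"phas{i + 1}"

        n_phased = int(round(config.locus_depth * config.phased_fraction))
        n_unphased = config.locus_depth - n_phased
        # duplex positions: plus 5' ends at cleavage + j*P, minus partners at +P-3
        plus_pos = [cleavage + j * P for j in range(cycles)]
        minus_pos = [x + P - 3 for x in plus_pos]
        positions = [(x, "+") for x in plus_pos] + [(x, "-") for x in minus_pos]
        probs = np.full(len(positions), 1.0 / len(positions))
        probs[: cycles] *= 2 * config.strand_balance
        probs[cycles:] *= 2 * (1 - config.strand_balance)
        probs /= probs.sum()
        counts = rng.multinomial(n_phased, probs)
        for (pos5, strand), c in zip(positions, counts):
            if c > 0:
                emissions.append((fid, pos5, strand, P, int(c), True))
        for _ in range(n_unphased):
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                pos5 = int(rng.integers(env[0], env[1] - P))
            else:
                pos5 = int(rng.integers(env[0] + P - 1, env[1]))
            emissions.append((fid, pos5, strand, P, 1, True))
        truth.append(
            TruthRecord(
                feature_id=fid, kind="PHAS", chrom=chrom, start=env[0], end=env[1],
                strand="+", register=register, trigger_name=name, trigger_seq=mseq,
                trigger_site=site, cleavage_pos=cleavage,
            )
        )

    # --- cis-propagation loci (no trigger; two registers 12 nt apart) -------
    for i in range(config.n_cis_loci):
        block = P * config.cis_cycles + 12
        b = _place(rng, block, occupied, config.genome_length, config.feature_margin)
        fid = f"cis{i + 1}"
        r = b % P
        rec = TruthRecord(
            feature_id=fid, kind="PHAS_CIS", chrom=chrom, start=b, end=b + block,
            strand="+", register=r,
            registers_12=(min(r, (r + 12) % P), max(r, (r + 12) % P)),
        )
        alns = simulate_cis_propagation(rec, config.cis_generations, config, rng=rng)
        for a in alns:
            emissions.append((fid, a.pos5, a.strand, a.length, a.count, True))
        truth.append(rec)

    # --- hc-siRNA loci ------------------------------------------------------
    hc_span = P * cycles
    for i in range(config.n_hc_loci):
        b = _place(rng, hc_span, occupied, config.genome_length, config.feature_margin)
        fid = f"hc{i + 1}"
        counts = rng.multinomial(config.hc_depth, np.full(config.hc_positions, 1.0 / config.hc_positions))
        for c in counts:
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                pos5 = int(rng.integers(b, b + hc_span - P))
            else:
                pos5 = int(rng.integers(b + P - 1, b + hc_span))
            if c > 0:
                emissions.append((fid, pos5, strand, P, int(c), False))
        truth.append(
            TruthRecord(feature_id=fid, kind="HC", chrom=chrom, start=b, end=b + hc_span, strand="+")
        )

    # --- MIR polycistrons ---------------------------------------------------
    for i in range(config.n_mir_clusters):
        lo, hi = config.hairpins_per_cluster
        n_h = int(rng.integers(lo, hi + 1))
        loops = [int(rng.integers(*config.loop_range)) for _ in range(n_h)]
        gaps = [int(rng.integers(*config.cluster_gap_range)) for _ in range(n_h - 1)] + [0]
        block = sum(22 + lp + 22 for lp in loops) + sum(gaps)
        b = _place(rng, block, occupied, config.genome_length, config.feature_margin)
        fid = f"mir_cluster{i + 1}"
        pos = b
        spans = []
        matures = []
        for j in range(n_h):
            name, mseq = mirna_items[j % len(mirna_items)]  # round-robin reuse
            loop_seq = _rand_seq(rng, loops[j])
            hp = mseq + loop_seq + revcomp(mseq)
            plant(pos, hp)
            spans.append((pos, pos + len(hp)))
            matures.append(mseq)
            emissions.append((fid, pos, "+", 22, config.mir_read_depth, True))
            star_pos5 = pos + len(hp) - 22
            emissions.append((fid, star_pos5, "+", 22, max(1, config.mir_read_depth // 3), True))
            pos += len(hp) + gaps[j]
        truth.append(
            TruthRecord(
                feature_id=fid, kind="MIR_cluster", chrom=chrom, start=b, end=pos,
                strand="+", mature_seqs=tuple(matures), hairpin_spans=tuple(spans),
            )
        )

    # --- background ---------------------------------------------------------
    for _ in range(config.background_reads):
        L = int(rng.choice([21, 22, 23, 24]))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            pos5 = int(rng.integers(0, config.genome_length - L))
        else:
            pos5 = int(rng.integers(L - 1, config.genome_length))
        emissions.append(("background", pos5, strand, L, int(rng.integers(1, 3)), False))

    genome_seq = bytes(genome_arr).decode()
    genome = [GenomeSequence(name=chrom, seq=genome_seq)]

    # --- stage series -------------------------------------------------------
    staged_features = sorted({e[0] for e in emissions if e[5]})
    noise = {
        (fid, stage): float(np.exp(rng.normal(0.0, config.stage_noise_sigma)))
        for fid in staged_features
        for stage in config.stage_labels
    }
    libraries: dict[str, list[CollapsedRead]] = {}
    stage_abundance: dict[str, dict[str, int]] = {t.feature_id: {} for t in truth}
    for stage, mult in zip(config.stage_labels, config.stage_multipliers):
        merged: dict[str, int] = {}
        totals: dict[str, int] = {}
        for fid, pos5, strand, L, base, staged in emissions:
            if staged:
                c = int(round(base * mult * noise[(fid, stage)]))
            else:
                c = base
            if c <= 0:
                continue
            seq = _read_seq(genome_seq, pos5, strand, L)
            merged[seq] = merged.get(seq, 0) + c
            totals[fid] = totals.get(fid, 0) + c
        libraries[stage] = [CollapsedRead(seq=s, count=c) for s, c in sorted(merged.items())]
        for t in truth:
            stage_abundance[t.feature_id][stage] = totals.get(t.feature_id, 0)
    for t in truth:
        t.stage_abundance = stage_abundance[t.feature_id]

    # --- degradome ----------------------------------------------------------
    degradome = DegradomeTable()
    for t in truth:
        if t.cleavage_pos is not None:
            degradome.add(t.chrom, t.cleavage_pos, "+", config.degradome_spike)
    for _ in range(config.degradome_noise):
        pos = int(rng.integers(0, config.genome_length))
        strand = "+" if rng.random() < 0.5 else "-"
        degradome.add(chrom, pos, strand, int(rng.integers(1, 4)))

    return SimulatedDataset(
        config=config, genome=genome, libraries=libraries,
        degradome=degradome, truth=truth, mirnas=mirnas,
    )


def simulate_cis_propagation(
    truth: TruthRecord,
    generations: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SrnaAlignment]:
    """Reads from cis-triggered secondary phasing at one 24-nt locus.

    Generation 0 emits primary-register duplex reads across
    ``config.cis_cycles`` cycles. In each later generation every existing
    duplex, with probability ``cis_trigger_prob``, directs a cis cleavage
    whose downstream fragment seeds phased duplexes shifted +12 nt, at
    abundance decayed by ``cis_decay`` per generation. All emitted reads
    therefore occupy registers r and (r+12) mod 24; with two or more
    generations both registers carry abundance.
    """
    if config.P != 24:
        raise ValueError("cis propagation is defined for P=24 loci")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    P = 24
    env_lo = truth.start
    env_hi = truth.start + P * config.cis_cycles + 12
    chrom = truth.chrom

    counts: dict[tuple[int, str], int] = {}

    def emit(x: int, c: int) -> None:
        # duplex: plus-strand 5' at x, minus partner 5' at x + P - 3
        if x + P <= env_hi:
            counts[(x, "+")] = counts.get((x, "+"), 0) + c
            counts[(x + P - 3, "-")] = counts.get((x + P - 3, "-"), 0) + c

    parents = [env_lo + j * P for j in range(config.cis_cycles)]
    for x in parents:
        emit(x, config.cis_base_count)
    for g in range(1, generations + 1):
        c_g = max(1, int(round(config.cis_base_count * config.cis_decay**g)))
        new_parents = []
        for x in parents:
            if rng.random() < config.cis_trigger_prob:
                s = x + 12  # cleavage downstream fragment start, register r+12
                for j in range(config.cis_secondary_cycles):
                    y = s + j * P
                    if y + P <= env_hi:
                        emit(y, c_g)
                        new_parents.append(y)
        parents = new_parents
        if not parents:
            break
    return [
        SrnaAlignment(chrom=chrom, pos5=pos, strand=strand, length=P, count=c)
        for (pos, strand), c in sorted(counts.items())
    ]


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write genome FASTA, per-stage collapsed FASTA, degradome, stage
    metadata, and the truth table under ``outdir`` (deterministic bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.genome, outdir / "genome.fa")
    for stage in dataset.config.stage_labels:
        with open(outdir / f"reads_{stage}.fa", "w") as fh:
            for i, r in enumerate(dataset.libraries[stage], start=1):
                fh.write(f">r{i}_{r.count}\n{r.seq}\n")
    with open(outdir / "degradome.tsv", "w") as fh:
        for (chrom, pos, strand), c in sorted(dataset.degradome.counts.items()):
            fh.write(f"{chrom}\t{pos}\t{strand}\t{c}\n")
    with open(outdir / "stages.tsv", "w") as fh:
        fh.write("lib_id\tstage\torder\ttotal_mapped\n")
        for lib in dataset.library_info():
            fh.write(f"{lib.lib_id}\t{lib.stage}\t{lib.order}\t{lib.total_mapped}\n")
    with open(outdir / "mirnas.fa", "w") as fh:
        for name, seq in dataset.mirnas.items():
            fh.write(f">{name}\n{seq}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        cols = [
            "feature_id", "kind", "chrom", "start", "end", "strand", "register",
            "trigger_name", "trigger_seq", "trigger_site_start", "trigger_site_end",
            "cleavage_pos", "n_hairpins", "n_unique_mature", "stage_abundance",
        ]
        fh.write("\t".join(cols) + "\n")
        for t in dataset.truth:
            site = t.trigger_site or ("", "")
            ab = ",".join(f"{s}:{c}" for s, c in t.stage_abundance.items())
            row = [
                t.feature_id, t.kind, t.chrom, str(t.start), str(t.end), t.strand,
                "" if t.register is None else str(t.register),
                t.trigger_name or "", t.trigger_seq or "",
                str(site[0]), str(site[1]),
                "" if t.cleavage_pos is None else str(t.cleavage_pos),
                str(len(t.hairpin_spans)), str(len(set(t.mature_seqs))), ab,
            ]
            fh.write("\t".join(row) + "\n")


def align_dataset(dataset: SimulatedDataset, max_hits: int = 10) -> dict[str, list[SrnaAlignment]]:
    """Per-stage alignments computed from one placement pass over the union
    of read sequences (placements are identical across stages)."""
    from .core_io import align_libraries

    return align_libraries(dataset.libraries, dataset.genome, max_hits=max_hits)
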