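"""MIR2275-family locus discovery: homology search, hairpin evaluation,
polycistronic clusters.

The miR2275 family is a set of 22-nt mature miRNAs processed from short
stem-loop precursors; MIR2275 loci characteristically occur as polycistrons,
with several stem-loops separated by tens of nucleotides on one transcript.
Candidate loci are found by mismatch-tolerant scanning for the mature
sequence, then validated by locating the star arm with an antiparallel
duplex alignment against the flanks and requiring a plausible Dicer duplex
(most mature bases paired, few mismatches, small bulges).

The built-in folder maximizes base pairs (Watson-Crick plus G:U, minimum
3-nt hairpin loop) with a deterministic traceback and reports the hairpin's
dot-bracket structure; ``evaluate_precursor`` takes the folder as an
argument so a thermodynamic folder can be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .core_io import GenomeSequence, revcomp

logger = logging.getLogger(__name__)

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
MIN_LOOP = 3
MAX_FOLD_LEN = 450  # O(L^3) fold bound; ample for short MIR-scale hairpins

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass(frozen=True)
class MatureQuery:
    """A mature miRNA to search for (miR2275 family members are 22 nt)."""

    name: str
    seq: str
    max_mismatch: int = 3

    def __post_init__(self) -> None:
        if set(self.seq) - set("ACGT"):
            raise ValueError(f"query '{self.name}' contains non-ACGT characters")


@dataclass(frozen=True)
class HomologHit:
    chrom: str
    pos: int  # 0-based leftmost genomic coordinate of the site
    strand: str
    mismatches: int
    query: MatureQuery


@dataclass
class MirnaPrecursor:
    """An accepted miRNA hairpin with its mature/star duplex."""

    chrom: str
    start: int
    end: int
    strand: str
    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    mature_seq: str
    structure: str
    duplex_mismatches: int
    duplex_bulged_nt: int
    arm: str  # 5p or 3p
    homology_mismatches: int = 0  # Hamming distance of the founding query hit
    truncated_flank: bool = False


@dataclass(frozen=True)
class PrecursorRejection:
    """Machine-readable reason a homology hit failed hairpin validation."""

    hit: HomologHit
    reason: str  # unpaired_mature | duplex_mismatches | duplex_bulges
    detail: str = ""


@dataclass
class MirCluster:
    """Two or more hairpins chained within max_cluster_gap on one strand."""

    chrom: str
    strand: str
    members: list[MirnaPrecursor]
    span: tuple[int, int]
    n_unique_mature: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.translate(str.maketrans("ACGTN", "\x00\x01\x02\x03\x04")).encode("latin1"), dtype=np.uint8)


def find_mature_homologs(
    genome: Iterable[GenomeSequence],
    query: MatureQuery,
) -> list[HomologHit]:
    """All genomic windows within Hamming distance max_mismatch of the query.

    Both strands are scanned; N in the genome never matches. Overlapping
    hits on the same chromosome and strand are deduplicated by keeping the
    lowest-distance (then leftmost) hit of each overlapping run.
    """
    L = len(query.seq)
    q_plus = _encode(query.seq)
    q_minus = _encode(revcomp(query.seq))
    hits: list[HomologHit] = []
    for g in genome:
        if len(g.seq) < L:
            continue
        arr = _encode(g.seq)
        n_win = len(arr) - L + 1
        for strand, q in (("+", q_plus), ("-", q_minus)):
            mism = np.zeros(n_win, dtype=np.int32)
            for d in range(L):
                col = arr[d : d + n_win]
                mism += (col != q[d]) | (col == 4)  # N never matches
            for i in np.nonzero(mism <= query.max_mismatch)[0]:
                hits.append(HomologHit(g.name, int(i), strand, int(mism[i]), query))

    # collapse overlapping runs per (chrom, strand): keep lowest distance, then leftmost
    hits.sort(key=lambda h: (h.chrom, h.strand, h.pos))
    out: list[HomologHit] = []
    run: list[HomologHit] = []
    for h in hits:
        if run and h.chrom == run[-1].chrom and h.strand == run[-1].strand and h.pos < run[-1].pos + L:
            run.append(h)
        else:
            if run:
                out.append(min(run, key=lambda x: (x.mismatches, x.pos)))
            run = [h]
    if run:
        out.append(min(run, key=lambda x: (x.mismatches, x.pos)))
    out.sort(key=lambda h: (h.chrom, h.pos, h.strand))
    return out


def fold_hairpin(seq: str, min_loop: int = MIN_LOOP) -> tuple[int, list[tuple[int, int]], str]:
    """Maximum base-pairing secondary structure (Nussinov recurrence).

    Watson-Crick and G:U pairs are allowed, with at least ``min_loop``
    unpaired bases inside any hairpin loop. Among co-optimal structures the
    traceback deterministically pairs each base with its nearest compatible
    partner; this local preference keeps tandem near-identical stem-loops
    (the MIR2275 polycistron arrangement) folded as separate hairpins
    instead of crossing arms between copies. Returns (pair count, pair
    list, dot-bracket string).
    """
    n = len(seq)
    if n > MAX_FOLD_LEN:
        raise ValueError(f"sequence of {n} nt exceeds folder bound of {MAX_FOLD_LEN}")
    non_acgt = sum(1 for ch in seq if ch not in "ACGT")
    if n > 0 and non_acgt / n > 0.10:
        raise ValueError("more than 10% non-ACGT characters; refusing to fold")
    if n == 0:
        return 0, [], ""

    enc = _encode(seq)
    pairable = np.zeros((n, n), dtype=bool)
    for (a, b) in _PAIRS:
        pairable |= (enc[:, None] == _ENC[a]) & (enc[None, :] == _ENC[b])
    tri = np.triu(np.ones((n, n), dtype=bool), k=min_loop + 1)
    pairable &= tri
    pair_ks = [np.nonzero(pairable[:, j])[0] for j in range(n)]

    # M[i, j+1] = max pairs over s[i..j]; M[:, 0] = 0 and M[i, j+1] = 0 for j < i
    M = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i, j]  # j unpaired
            ks = pair_ks[j]
            ks = ks[ks >= i]
            if len(ks):
                vals = M[i, ks] + M[ks + 1, j] + 1
                v = int(vals.max())
                if v > best:
                    best = v
            M[i, j + 1] = best

    def cell(i: int, j: int) -> int:  # dp over s[i..j], 0 when empty
        return int(M[i, j + 1]) if i <= j else 0

    dp = M[:, 1:]  # dp[i, j] view over s[i..j] for the traceback

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i, j] == 0:
            continue
        # pair j with its nearest co-optimal partner (largest k); leave j
        # unpaired only when no pairing achieves the optimum
        paired_j = False
        for k in range(j - min_loop - 1, i - 1, -1):
            if pairable[k, j] and cell(i, k - 1) + cell(k + 1, j - 1) + 1 == dp[i, j]:
                pairs.append((k, j))
                stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                paired_j = True
                break
        if not paired_j:
            stack.append((i, j - 1))
    pairs.sort()
    db = ["."] * n
    for a, b in pairs:
        db[a], db[b] = "(", ")"
    return len(pairs), pairs, "".join(db)


def duplex_align(
    mature: str,
    window: str,
    wc_score: int = 2,
    gu_score: int = 1,
    mismatch_score: int = -1,
    gap_score: int = -2,
):
    """Best antiparallel duplex between the mature and a substring of window.

    Local alignment of the mature (5'->3') against the *reversed* window,
    so aligned columns are candidate base pairs of an antiparallel duplex.
    Watson-Crick pairs score ``wc_score``, G:U pairs ``gu_score``,
    non-pairing columns ``mismatch_score``, bulged nucleotides
    ``gap_score`` each. Ties resolve pair > mismatch > mature-gap >
    window-gap, then the earliest end cell, so the result is deterministic.

    Returns (score, columns, (w_lo, w_hi), (m_lo, m_hi)) where ``columns``
    is a list of (mature_idx, window_idx, kind) with kind in
    {"pair", "gu", "mismatch"}; window coordinates are in the *forward*
    orientation of ``window``; (m_lo, m_hi) is the aligned mature range.
    """
    L, W = len(mature), len(window)
    rw = window[::-1]
    H = np.zeros((L + 1, W + 1), dtype=np.int32)
    move = np.zeros((L + 1, W + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up(mature gap-less...), 3 left
    best, bi, bj = 0, 0, 0
    for i in range(1, L + 1):
        mb = mature[i - 1]
        for j in range(1, W + 1):
            pb = rw[j - 1]
            if (mb, pb) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
                sub = wc_score
            elif (mb, pb) in (("G", "T"), ("T", "G")):
                sub = gu_score
            else:
                sub = mismatch_score
            diag = H[i - 1, j - 1] + sub
            up = H[i - 1, j] + gap_score   # mature base bulged out
            left = H[i, j - 1] + gap_score  # window base bulged out
            v = max(0, diag, up, left)
            H[i, j] = v
            if v == 0:
                move[i, j] = 0
            elif v == diag:
                move[i, j] = 1
            elif v == up:
                move[i, j] = 2
            else:
                move[i, j] = 3
            if v > best:
                best, bi, bj = v, i, j
    if best == 0:
        return 0, [], (0, 0), (0, 0)
    columns = []
    i, j = bi, bj
    while i > 0 and j > 0 and move[i, j] != 0 and H[i, j] > 0:
        if move[i, j] == 1:
            mb, pb = mature[i - 1], rw[j - 1]
            if (mb, pb) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
                kind = "pair"
            elif (mb, pb) in (("G", "T"), ("T", "G")):
                kind = "gu"
            else:
                kind = "mismatch"
            columns.append((i - 1, W - j, kind))
            i, j = i - 1, j - 1
        elif move[i, j] == 2:
            i -= 1
        else:
            j -= 1
    columns.reverse()
    m_lo, m_hi = i, bi
    w_lo, w_hi = W - bj, W - j
    return int(best), columns, (w_lo, w_hi), (m_lo, m_hi)


def evaluate_precursor(
    genome: Sequence[GenomeSequence] | dict[str, GenomeSequence],
    hit: HomologHit,
    flank: int = 100,
    min_mature_paired: int = 16,
    max_duplex_mismatches: int = 5,
    max_duplex_bulged_nt: int = 3,
    min_loop: int = MIN_LOOP,
    folder: Callable[[str], tuple[int, list[tuple[int, int]], str]] | None = None,
) -> MirnaPrecursor | PrecursorRejection:
    """Evaluate a homology hit as a miRNA stem-loop precursor.

    The star arm is located by antiparallel duplex alignment of the mature
    against the up- and downstream flank windows (on the hit's transcript
    strand); the better-scoring side defines the arm. Acceptance requires
    (i) at least ``min_mature_paired`` mature bases paired in the duplex,
    (ii) duplex mismatches <= ``max_duplex_mismatches``, (iii) bulged
    nucleotides <= ``max_duplex_bulged_nt``. The mature 3' 2-nt overhang
    (last two bases) is excluded from defect counting, as in a Dicer
    duplex. The hairpin span is folded (``folder``, default the built-in
    maximum-pairing folder) only to report the secondary structure string.
    Hits closer than ``flank`` to a contig end are evaluated with a
    truncated flank and flagged.
    """
    folder = folder or fold_hairpin
    chrom_map = genome if isinstance(genome, dict) else {g.name: g for g in genome}
    g = chrom_map[hit.chrom]
    L = len(hit.query.seq)
    lo = max(0, hit.pos - flank)
    hi = min(len(g.seq), hit.pos + L + flank)
    truncated = lo > hit.pos - flank or hi < hit.pos + L + flank

    # flank windows on the transcript strand, excluding a minimal loop
    if hit.strand == "+":
        mature = g.seq[hit.pos : hit.pos + L]
        down = g.seq[hit.pos + L + min_loop : hi]          # candidate 3' arm (mature = 5p)
        up = g.seq[lo : max(lo, hit.pos - min_loop)]       # candidate 5' arm (mature = 3p)
    else:
        mature = revcomp(g.seq[hit.pos : hit.pos + L])
        down = revcomp(g.seq[lo : max(lo, hit.pos - min_loop)])
        up = revcomp(g.seq[hit.pos + L + min_loop : hi])

    res_down = duplex_align(mature, down)
    res_up = duplex_align(mature, up)
    arm = "5p" if res_down[0] >= res_up[0] else "3p"
    score, columns, (w_lo, w_hi), (m_lo, m_hi) = res_down if arm == "5p" else res_up

    n_paired = sum(1 for _, _, kind in columns if kind != "mismatch")
    if n_paired < min_mature_paired:
        return PrecursorRejection(
            hit, "unpaired_mature", f"{n_paired}/{L} mature bases paired in the best duplex"
        )

    # defects over the duplex range: mature indices 0 .. L-3 (3' overhang excluded)
    dup_hi = L - 3
    mism = sum(1 for midx, _, kind in columns if kind == "mismatch" and midx <= dup_hi)
    mism += max(0, m_lo - 0)  # unaligned 5' mature bases
    mism += max(0, dup_hi - (m_hi - 1))  # unaligned mature bases before the overhang
    bulged = 0
    cols_in = [c for c in columns if c[0] <= dup_hi]
    for (i1, p1, _), (i2, p2, _) in zip(cols_in, cols_in[1:]):
        bulged += abs((i2 - i1 - 1) - (abs(p1 - p2) - 1))
    if mism > max_duplex_mismatches:
        return PrecursorRejection(hit, "duplex_mismatches", f"{mism} > {max_duplex_mismatches}")
    if bulged > max_duplex_bulged_nt:
        return PrecursorRejection(hit, "duplex_bulges", f"{bulged} nt > {max_duplex_bulged_nt}")

    # map the aligned star window back to genomic coordinates
    if hit.strand == "+":
        if arm == "5p":
            star_g = (hit.pos + L + min_loop + w_lo, hit.pos + L + min_loop + w_hi)
        else:
            star_g = (lo + w_lo, lo + w_hi)
        mature_g = (hit.pos, hit.pos + L)
    else:
        # transcript coordinates run antiparallel to the genome on '-'
        if arm == "5p":  # star is genomically upstream of the mature
            star_g = (hit.pos - min_loop - w_hi, hit.pos - min_loop - w_lo)
        else:  # star genomically downstream
            star_g = (hi - w_hi, hi - w_lo)
        mature_g = (hit.pos, hit.pos + L)
    hp_start = min(mature_g[0], star_g[0])
    hp_end = max(mature_g[1], star_g[1])

    hairpin_seq = g.seq[hp_start:hp_end] if hit.strand == "+" else revcomp(g.seq[hp_start:hp_end])
    try:
        _, _, structure = folder(hairpin_seq)
    except ValueError:
        structure = ""
    return MirnaPrecursor(
        chrom=hit.chrom,
        start=hp_start,
        end=hp_end,
        strand=hit.strand,
        mature_span=mature_g,
        star_span=star_g,
        mature_seq=hit.query.seq,
        structure=structure,
        duplex_mismatches=mism,
        duplex_bulged_nt=bulged,
        arm=arm,
        homology_mismatches=hit.mismatches,
        truncated_flank=truncated,
    )


def dedupe_precursors(precursors: list[MirnaPrecursor]) -> list[MirnaPrecursor]:
    """Collapse precursors with overlapping hairpin spans to one call.

    A stem-loop is its own reverse complement as a structure, so a hairpin
    found via the mature arm on one strand reappears via the star arm on the
    other; overlapping calls are reduced to the homology-closest one
    (ties: fewest duplex defects, plus strand, then leftmost).
    """
    prs = sorted(precursors, key=lambda p: (p.chrom, p.start, p.end))
    out: list[MirnaPrecursor] = []
    group: list[MirnaPrecursor] = []

    def flush():
        if group:
            out.append(min(group, key=lambda p: (
                p.homology_mismatches, p.duplex_mismatches, p.strand != "+", p.start)))

    for p in prs:
        if group and p.chrom == group[-1].chrom and p.start < max(q.end for q in group):
            group.append(p)
        else:
            flush()
            group = [p]
    flush()
    out.sort(key=lambda p: (p.chrom, p.start))
    return out



def detect_polycistronic_clusters(
    precursors: Iterable[MirnaPrecursor],
    max_cluster_gap: int = 1000,
) -> list[MirCluster]:
    """Chain same-chromosome, same-strand hairpins into polycistrons.

    Consecutive hairpins join a cluster when the gap between their spans is
    at most ``max_cluster_gap`` (default 1 kb, the scale on which MIR2275
    stem-loops cluster). Singletons are not clusters. Output is invariant to
    input ordering.
    """
    prs = sorted(precursors, key=lambda p: (p.chrom, p.strand, p.start, p.end))
    clusters: list[MirCluster] = []
    chain: list[MirnaPrecursor] = []

    def flush() -> None:
        if len(chain) >= 2:
            clusters.append(
                MirCluster(
                    chrom=chain[0].chrom,
                    strand=chain[0].strand,
                    members=list(chain),
                    span=(chain[0].start, max(p.end for p in chain)),
                    n_unique_mature=len({p.mature_seq for p in chain}),
                )
            )

    for p in prs:
        if chain and p.chrom == chain[-1].chrom and p.strand == chain[-1].strand and \
                p.start - max(q.end for q in chain) <= max_cluster_gap:
            chain.append(p)
        else:
            flush()
            chain = [p]
    flush()
    return clusters


def mature_family_pfm(seqs: Iterable[str]):
    """Position-frequency matrix of a mature-miRNA family alignment.

    All sequences must share one length (the miR2275 family is 22 nt);
    returns a pandas DataFrame with rows A/C/G/T and one column per position.
    """
    import pandas as pd

    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty family")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("family members must share one length")
    counts = np.zeros((4, L), dtype=int)
    rows = "ACGT"
    for s in seqs:
        for j, ch in enumerate(s):
            counts[rows.index(ch), j] += 1
    return pd.DataFrame(counts, index=list(rows), columns=range(1, L + 1))
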