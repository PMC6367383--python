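"""miRNA target-site scoring, cleavage prediction, and PARE validation.

A 22-nt miR2275 pairs antiparallel to a 22-nt target window on the PHAS
transcript. Scoring follows standard plant-miRNA penalty practice: 0 for a
Watson-Crick match, 0.5 for a G:U wobble, 1.0 for a mismatch, with
penalties doubled at miRNA positions 2-13 (the 5' core that governs
AGO-directed slicing); sites scoring at most ``max_score`` (default 6.0)
are reported.

Cleavage coordinate convention
------------------------------
AGO slices the target between the bases paired to miRNA positions 10 and
11; ``cleavage_pos`` is the first nucleotide of the downstream (3')
fragment, i.e. the base paired to miRNA position 10. With a plus-strand
site at [s, s+22) the miRNA 5' end pairs the site's 3'-terminal base
(s+21), miRNA position i pairs target base s + 22 - i, so cleavage_pos =
s + 12. On a minus-strand site the arithmetic mirrors: cleavage_pos =
s + 22 - 1 - 12 = s + 9 in genomic coordinates. The downstream fragment's
first base fixes the phase register of the phasiRNAs it seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core_io import DegradomeTable, GenomeSequence, revcomp
from .phasing import PhasLocus

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_WOBBLE = {("G", "T"), ("T", "G")}  # miRNA base vs target base (RNA G:U)


@dataclass
class TargetSite:
    """A scored miRNA:target alignment on the genome."""

    chrom: str
    start: int  # 0-based half-open 22-nt target span
    end: int
    strand: str  # transcript strand carrying the site
    mirna_name: str
    score: float
    alignment: str  # three-line pairing depiction
    cleavage_pos: int


def score_target_site(mirna: str, target: str) -> tuple[float, str]:
    """Penalty score of a gapless antiparallel miRNA:target alignment.

    ``target`` is given 5'->3' on the transcript strand. miRNA position i
    (1-based from the miRNA 5' end) faces target base ``target[22 - i]``.
    Penalties: match 0, G:U 0.5, mismatch 1.0, doubled at miRNA positions
    2-13. Returns (score, three-line alignment string).
    """
    if len(mirna) != 22 or len(target) != 22:
        raise ValueError("gapless scoring requires a 22-nt miRNA and a 22-nt target window")
    score = 0.0
    marks = []
    for i in range(1, 23):  # miRNA position, 5'->3'
        mb = mirna[i - 1]
        tb = target[22 - i]
        if _COMP.get(mb) == tb:
            penalty, mark = 0.0, "|"
        elif (mb, tb) in _WOBBLE:
            penalty, mark = 0.5, "o"
        else:
            penalty, mark = 1.0, " "
        if 2 <= i <= 13:
            penalty *= 2.0
        score += penalty
        marks.append(mark)
    # depict target 5'->3' on top, miRNA 3'->5' beneath
    aln = (
        f"target 5' {target} 3'\n"
        f"          {''.join(reversed(marks))}\n"
        f"miRNA  3' {mirna[::-1]} 5'"
    )
    return score, aln


def predict_cleavage(start: int, end: int, strand: str) -> int:
    """First base of the downstream cleavage fragment for a site at [start, end)."""
    if strand == "+":
        return start + 12
    return end - 1 - 12


def find_target_sites(
    mirna_name: str,
    mirna: str,
    genome: Sequence[GenomeSequence] | dict[str, GenomeSequence],
    chrom: str,
    start: int,
    end: int,
    max_score: float = 6.0,
) -> list[TargetSite]:
    """Score every 22-nt window on both strands of a region.

    Returns sites with score <= max_score, sorted by ascending score then
    coordinate. Regions shorter than 22 nt yield an empty list with a
    warning.
    """
    chrom_map = genome if isinstance(genome, dict) else {g.name: g for g in genome}
    g = chrom_map[chrom]
    start = max(0, start)
    end = min(len(g.seq), end)
    if end - start < 22:
        logger.warning("region %s:%d-%d shorter than 22 nt; no target scan", chrom, start, end)
        return []
    sites: list[TargetSite] = []
    for s in range(start, end - 21):
        window = g.seq[s : s + 22]
        if "N" in window:
            continue
        for strand, target in (("+", window), ("-", revcomp(window))):
            score, aln = score_target_site(mirna, target)
            if score <= max_score:
                sites.append(
                    TargetSite(
                        chrom=chrom,
                        start=s,
                        end=s + 22,
                        strand=strand,
                        mirna_name=mirna_name,
                        score=score,
                        alignment=aln,
                        cleavage_pos=predict_cleavage(s, s + 22, strand),
                    )
                )
    sites.sort(key=lambda t: (t.score, t.start, t.strand))
    return sites


def check_register_initiation(site: TargetSite, locus: PhasLocus) -> bool:
    """Does the predicted cleavage seed phasiRNAs in the locus register?

    The first phasiRNA 5' end sits at ``cleavage_pos`` on the site's
    transcript strand; its register follows the strand-aware register rule
    (+3 shift on the minus strand).
    """
    if site.strand == "+":
        reg = site.cleavage_pos % locus.P
    else:
        reg = (site.cleavage_pos + 3) % locus.P
    return reg == locus.register


def validate_with_pare(
    site: TargetSite,
    degradome: DegradomeTable,
    window: int = 20,
) -> tuple[bool, float]:
    """Test the predicted cleavage position against degradome 5' ends.

    peak_found is True when the degradome count at (chrom, cleavage_pos,
    transcript strand) is the maximum within +/- ``window`` nt and at least
    5 reads; peak_fraction is that count over the window total (0.0 for an
    empty window).
    """
    counts = [
        degradome.get(site.chrom, p, site.strand)
        for p in range(site.cleavage_pos - window, site.cleavage_pos + window + 1)
    ]
    total = sum(counts)
    at_site = degradome.get(site.chrom, site.cleavage_pos, site.strand)
    if total == 0:
        return False, 0.0
    peak_found = at_site >= 5 and at_site == max(counts)
    return peak_found, at_site / total


def annotate_loci_with_triggers(
    loci: Iterable[PhasLocus],
    mirnas: dict[str, str],
    genome,
    search_flank: int = 500,
    max_score: float = 6.0,
    degradome: DegradomeTable | None = None,
):
    """Best trigger site per locus, with register-initiation and PARE checks.

    Scans each locus envelope +/- ``search_flank`` with every query miRNA;
    keeps the best-scoring site (ties: first by coordinate). Returns a list
    of (locus, site-or-None, register_match, pare) tuples, where ``pare`` is
    (peak_found, peak_fraction) or None when no degradome was supplied.
    """
    results = []
    for locus in loci:
        best: TargetSite | None = None
        for name, seq in mirnas.items():
            sites = find_target_sites(
                name, seq, genome, locus.chrom,
                locus.start - search_flank, locus.end + search_flank,
                max_score=max_score,
            )
            if sites and (best is None or sites[0].score < best.score):
                best = sites[0]
        reg_ok = check_register_initiation(best, locus) if best else False
        pare = validate_with_pare(best, degradome) if best and degradome is not None else None
        results.append((locus, best, reg_ok, pare))
    return results
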