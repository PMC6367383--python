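"""Input/output and read placement.

Reads genomes and collapsed small-RNA libraries, places reads on the genome
by exact matching, and writes locus annotations as BED6/GFF3. All internal
coordinates are 0-based half-open; conversion to 1-based happens only at the
GFF3 boundary. On the minus strand, ``pos5`` of an alignment is the
*rightmost* genomic base covered by the read — its 5' nucleotide — because
phasing geometry is defined on Dicer-product 5' ends.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_IUPAC_OK = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome: uppercase text over {A,C,G,T,N}."""

    name: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CollapsedRead:
    """One distinct small-RNA sequence with its raw library abundance."""

    seq: str
    count: int


@dataclass(frozen=True)
class SrnaAlignment:
    """A collapsed read placed on the genome.

    ``pos5`` is the genomic coordinate of the read's 5' nucleotide: the
    leftmost covered base on '+', the rightmost covered base on '-'.
    """

    chrom: str
    pos5: int
    strand: str
    length: int
    count: int
    n_hits: int = 1

    @property
    def start(self) -> int:
        """Leftmost covered genomic coordinate (0-based)."""
        return self.pos5 if self.strand == "+" else self.pos5 - self.length + 1

    @property
    def end(self) -> int:
        """One past the rightmost covered genomic coordinate."""
        return self.pos5 + self.length if self.strand == "+" else self.pos5 + 1


@dataclass
class DegradomeTable:
    """Degradome/PARE 5'-end counts keyed by (chrom, pos, strand)."""

    counts: dict = field(default_factory=dict)

    def get(self, chrom: str, pos: int, strand: str) -> int:
        return self.counts.get((chrom, pos, strand), 0)

    def add(self, chrom: str, pos: int, strand: str, count: int) -> None:
        if count < 0:
            raise FormatError(f"negative degradome count at {chrom}:{pos}{strand}")
        key = (chrom, pos, strand)
        self.counts[key] = self.counts.get(key, 0) + count

    def __len__(self) -> int:
        return len(self.counts)


def _find_bad_char_line(path: str | Path, record_name: str, bad: str) -> int:
    """Locate the first line of a FASTA record containing a bad character."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == record_name if line[1:].strip() else False
                continue
            if in_record and bad in line.upper().replace("U", "T"):
                return lineno
    return -1


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records.

    Sequences are uppercased and U is converted to T. Duplicate record
    names and non-IUPAC characters are format errors; an empty file yields
    an empty list with a warning.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if not name:
            raise FormatError(f"{path}: record with empty header")
        if name in seen:
            raise FormatError(f"{path}: duplicate sequence name '{name}'")
        seen.add(name)
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _IUPAC_OK
        if bad:
            ch = sorted(bad)[0]
            lineno = _find_bad_char_line(path, name, ch)
            raise FormatError(
                f"{path}: non-IUPAC character '{ch}' in record '{name}'"
                + (f" (line {lineno})" if lineno > 0 else "")
            )
        if not seq:
            raise FormatError(f"{path}: empty sequence for record '{name}'")
        records.append(GenomeSequence(name=name, seq=seq))
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def read_collapsed_srna(path: str | Path, dialect: str = "underscore_count") -> list[CollapsedRead]:
    """Read a collapsed small-RNA library.

    dialects:
      * ``underscore_count`` — FASTA where the final underscore-delimited
        header token is the raw count (e.g. ``>r1_57``).
      * ``tab_table`` — plain text lines ``SEQ<TAB>COUNT``.

    Identical sequences are merged by summing counts.
    """
    merged: dict[str, int] = {}
    if dialect == "underscore_count":
        for rec in SeqIO.parse(str(path), "fasta"):
            token = rec.id.rsplit("_", 1)
            if len(token) != 2 or not token[1].isdigit():
                raise FormatError(f"{path}: header '>{rec.id}' has no trailing count token")
            count = int(token[1])
            seq = str(rec.seq).upper().replace("U", "T")
            merged[seq] = merged.get(seq, 0) + count
    elif dialect == "tab_table":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: expected 'SEQ<TAB>COUNT'")
                seq, token = parts
                try:
                    count = int(token)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-integer count '{token}'") from None
                seq = seq.upper().replace("U", "T")
                merged[seq] = merged.get(seq, 0) + count
    else:
        raise ValueError(f"unknown dialect '{dialect}'")
    reads = [CollapsedRead(seq=s, count=c) for s, c in merged.items()]
    total = sum(r.count for r in reads)
    logger.info("%s: %d distinct reads, total abundance %d", path, len(reads), total)
    return reads


def align_reads(
    reads: Iterable[CollapsedRead],
    genome: Iterable[GenomeSequence],
    max_hits: int = 10,
) -> list[SrnaAlignment]:
    """Place reads on the genome by exact matching on both strands.

    Every exact occurrence of a read (plus strand) and of its reverse
    complement (minus strand) is reported; reads with more than ``max_hits``
    total placements are dropped and tallied in the log. Genomic windows
    containing N never match.
    """
    reads = list(reads)
    genome = list(genome)
    targets: set[str] = set()
    for r in reads:
        targets.add(r.seq)
        targets.add(revcomp(r.seq))
    lengths = sorted({len(r.seq) for r in reads})

    # occurrence[seq] = list of (chrom, leftmost offset)
    occurrence: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for g in genome:
        s = g.seq
        for L in lengths:
            for i in range(len(s) - L + 1):
                sub = s[i : i + L]
                if sub in targets:
                    occurrence[sub].append((g.name, i))

    alignments: list[SrnaAlignment] = []
    n_dropped = 0
    n_unplaced = 0
    for r in reads:
        L = len(r.seq)
        plus = occurrence.get(r.seq, [])
        minus = occurrence.get(revcomp(r.seq), [])
        # palindromic reads: a site can appear in both lists; count both
        n_hits = len(plus) + len(minus)
        if n_hits == 0:
            n_unplaced += 1
            continue
        if n_hits > max_hits:
            n_dropped += 1
            continue
        for chrom, i in plus:
            alignments.append(
                SrnaAlignment(chrom=chrom, pos5=i, strand="+", length=L, count=r.count, n_hits=n_hits)
            )
        for chrom, i in minus:
            alignments.append(
                SrnaAlignment(
                    chrom=chrom, pos5=i + L - 1, strand="-", length=L, count=r.count, n_hits=n_hits
                )
            )
    logger.info(
        "aligned %d reads: %d alignments, %d unplaced, %d dropped (> %d hits)",
        len(reads), len(alignments), n_unplaced, n_dropped, max_hits,
    )
    alignments.sort(key=lambda a: (a.chrom, a.pos5, a.strand, a.length))
    return alignments


def align_libraries(
    reads_by_lib: dict[str, list[CollapsedRead]],
    genome: Iterable[GenomeSequence],
    max_hits: int = 10,
) -> dict[str, list[SrnaAlignment]]:
    """Per-library alignments from one placement pass over the sequence union.

    Libraries from one experiment share most distinct sequences, and a
    sequence's genomic placements do not depend on its count, so the genome
    is indexed once.
    """
    genome = list(genome)
    union: set[str] = set()
    for reads in reads_by_lib.values():
        union.update(r.seq for r in reads)
    placed = align_reads([CollapsedRead(seq=s, count=1) for s in sorted(union)], genome, max_hits)
    chrom_seq = {g.name: g.seq for g in genome}
    placements: dict[str, list[SrnaAlignment]] = {}
    for a in placed:
        s = chrom_seq[a.chrom]
        seq = s[a.pos5 : a.pos5 + a.length] if a.strand == "+" else revcomp(s[a.pos5 - a.length + 1 : a.pos5 + 1])
        placements.setdefault(seq, []).append(a)
    out: dict[str, list[SrnaAlignment]] = {}
    for lib, reads in reads_by_lib.items():
        alns = [
            SrnaAlignment(chrom=a.chrom, pos5=a.pos5, strand=a.strand,
                          length=a.length, count=r.count, n_hits=a.n_hits)
            for r in reads
            for a in placements.get(r.seq, [])
        ]
        alns.sort(key=lambda a: (a.chrom, a.pos5, a.strand, a.length))
        out[lib] = alns
    return out


def write_loci(loci, path: str | Path, fmt: str = "BED6") -> None:
    """Write PHAS loci as BED6 (0-based half-open) or GFF3 (1-based inclusive).

    BED column 5 carries the phasing score capped to an integer in [0, 1000];
    the locus register is encoded in the name. GFF3 uses type ``siRNA_locus``
    with phase_length, register, p_value and twelve_nt attributes.
    """
    loci = list(loci)
    lines: list[str] = []
    if fmt == "BED6":
        lines.append('track name="PHAS_loci" description="phased siRNA loci"')
        for lc in loci:
            score = int(round(min(max(lc.best_score, 0.0), 1000.0)))
            name = f"PHAS{lc.P}_{lc.chrom}_{lc.start}_r{lc.register}"
            lines.append(f"{lc.chrom}\t{lc.start}\t{lc.end}\t{name}\t{score}\t.")
    elif fmt == "GFF3":
        lines.append("##gff-version 3")
        for lc in loci:
            attrs = (
                f"ID=PHAS{lc.P}_{lc.chrom}_{lc.start}_r{lc.register};"
                f"phase_length={lc.P};register={lc.register};"
                f"p_value={lc.best_pvalue:.6g};twelve_nt={str(lc.twelve_nt).lower()}"
            )
            lines.append(
                f"{lc.chrom}\tphasikit\tsiRNA_locus\t{lc.start + 1}\t{lc.end}\t"
                f"{lc.best_score:.3f}\t.\t.\t{attrs}"
            )
    else:
        raise ValueError(f"unknown locus format '{fmt}' (use BED6 or GFF3)")
    Path(path).write_text("\n".join(lines) + "\n")


def read_degradome(path: str | Path) -> DegradomeTable:
    """Read a tab-separated degradome table: chrom, 0-based pos, strand, count.

    Duplicate (chrom, pos, strand) keys are summed; negative counts are a
    format error.
    """
    table = DegradomeTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated fields")
            chrom, pos_s, strand, count_s = parts
            try:
                pos = int(pos_s)
                count = int(count_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer position or count") from None
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count {count}")
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: strand must be + or -")
            table.add(chrom, pos, strand, count)
    return table


def write_fasta(records: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    """Write sequences as FASTA with fixed line wrapping (deterministic bytes)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
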