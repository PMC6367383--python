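# Methods

## The phasing model

Reproductive 24-nt phasiRNAs are Dicer products laid down in fixed 24-nt
increments from a defined initiation point on a double-stranded precursor.
Because every duplex carries a 2-nt 3′ overhang, all products of one
initiation event share a *register*: the residue class (mod P) of the 5′
coordinate, with minus-strand 5′ ends corrected by +3 — the minus partner
of a plus read starting at x has its 5′ nucleotide at x + P − 3, and
(x + P − 3 + 3) mod P = x mod P for any P. The same geometry gives the
register rules for P = 21 and the 12-nt re-analysis.

### Window statistic

A window of W = P·c nucleotides (defaults P = 24, c = 9) contains N = 2W
candidate 5′ positions (both strands) of which m = 2c lie in a given
register. With n distinct occupied positions (P-nt reads only) and k of
them in the best register, the window p-value is the hypergeometric upper
tail P(X ≥ k), X ~ Hypergeometric(N, m, n), evaluated by
`scipy.stats.hypergeom.sf` and checked in the test suite against exhaustive
occupancy-configuration enumeration for all N ≤ 20. Windows at p ≤ α
(0.001) with the same register merge into loci across gaps of at most one
cycle; the locus envelope runs from the first to the last in-register
occupied position. The phasing score,
score = (k − 2)·ln(1 + 10·phased/(1 + unphased)) for k ≥ 3 and 0 otherwise,
summarizes both position occupancy and the abundance ratio for display
along a locus.

### Why the locus filter requires 8 phased positions

Each window reports the best of P registers, so the nominal p-value is
anti-conservative by up to a factor of P at window level: at realistic
hc-siRNA densities (tens of occupied positions per window), 4–6 in-register
positions reach p ≤ 10⁻³ somewhere among 24 registers purely by chance.
Measured on simulated data, a minimum of 4 distinct in-register positions
admits several false hc-siRNA loci per 200-kb run, while genuine loci
occupy tens of in-register positions. The locus filter therefore demands at
least 8 distinct in-register 5′ positions (`min_phased_positions`,
config-exposed); with it, no false hc calls occurred in 40 independent
simulated runs and recovery of true loci was unaffected. The window
p-value is calibrated only in the sparse regime (roughly ≤ 2 occupied
positions per window, the genomic background); specificity at dense loci
is carried by this filter, not by α.

### 12-nt phasing

A locus is re-scored over its envelope at a 12-nt register using its 24-nt
reads. It is flagged `twelve_nt` when (i) the 12-nt p-value is ≤ α,
(ii) the top two 24-nt registers lie exactly 12 apart and jointly hold
≥ 60% of the register spectrum, and (iii) the weaker register alone holds
≥ 15%. Condition (iii) exists because any single-register locus trivially
satisfies (i) — all its positions share one residue mod 12 — and satisfies
(ii) spuriously whenever a near-empty second register happens to sit 12
away; requiring genuine abundance in both registers removes those cases
without affecting true two-register loci, whose minor register carries
30–50% of reads. Overlapping locus calls whose registers differ by exactly
12 are consolidated into one locus (dominant register, union envelope)
before flagging, since a 12-nt locus occupies two 24-nt registers and
would otherwise be reported twice.

## Trigger analysis

miR2275:target complementarity is scored with the standard plant penalty
scheme over a gapless antiparallel 22-nt alignment: match 0, G:U 0.5,
mismatch 1.0, penalties doubled at miRNA positions 2–13, cutoff 6.0
(all config-exposed). AGO slices between the target bases paired to miRNA
positions 10 and 11; with a plus-strand site at [s, s+22) and the miRNA 5′
end pairing the site's 3′-terminal base, miRNA position i pairs target base
s + 22 − i, so the downstream fragment starts at cleavage_pos = s + 12
(mirrored to s + 9 on a minus-strand site). The first base of the
downstream fragment fixes the register the cleavage initiates:
cleavage_pos mod P on the plus strand, (cleavage_pos + 3) mod P through
the minus-strand rule. Degradome support requires the 5′-end count at the
predicted position to be the maximum within ±20 nt and at least 5 reads.

A note on symmetry: the penalty score is *not* invariant under reverse
complementation of both sequences — G:U pairs map to non-pairing C:A and
the 5′-anchored core weighting does not commute with reversal. The
meaningful invariant, verified in tests, is strand symmetry of the site
scan: scanning the reverse complement of a region returns the same site
scores with strands swapped.

## Hairpin discovery

Candidate MIR2275 loci come from a Hamming-distance scan (≤ 3 mismatches
by default, no indels) for each mature query on both strands. For each
hit, the star arm is located by a deterministic antiparallel local
alignment of the mature against the upstream and downstream flank windows
(default 100 nt) on the hit's transcript strand: Watson-Crick pairs +2,
G:U +1, mismatches −1, bulged nucleotides −2, with a fixed tie order. The
better-scoring side defines the arm; acceptance requires ≥ 16 of 22 mature
bases paired, ≤ 5 mismatch columns, and ≤ 3 bulged nucleotides, the mature
3′ 2-nt overhang excluded, mirroring the bulged-but-paired duplexes
characteristic of the family. This alignment, not the fold, supplies the
duplex metrics: a maximum-base-pairing fold has massive co-optimal
degeneracy (any tie-break can route a terminal mature base into the loop
or a neighboring hairpin's arm), which made fold-derived mismatch/bulge
counts unstable on tandem near-identical stem-loops. The built-in
Nussinov-style folder (Watson-Crick + G:U, minimum 3-nt loop, traceback
preferring the nearest co-optimal partner so tandem hairpins stay locally
folded) is retained to report the dot-bracket structure and is verified
against exhaustive structure enumeration; a thermodynamic folder can be
substituted through the `folder` argument.

Because a stem-loop is structurally its own reverse complement, every
hairpin validates from both strands; overlapping calls are collapsed to
the homology-closest one before clustering. Same-strand hairpins chain
into polycistronic clusters across gaps of at most 1 kb (the scale on
which MIR2275 stem-loops cluster); singletons are not clusters.

## Quantification

RPTM = 10⁷ × (feature abundance) / (library's total genome-matched
abundance). The denominator is the genome-matched total rather than the
sequenced total, since only the former is computable inside the pipeline.
PHAS rows count 24-nt reads by default (`phase_length_only`); a log2(x+1)
transform is available for display. The peak stage of a row is the argmax
of stage-summed RPTM, ties resolving to the earliest stage in the declared
order and all-zero rows reporting "none".

## The synthetic-data generator

The generator emulates the statistical structure of staged reproductive
small-RNA libraries, with every read traceable to a truth record:

* **PHAS loci** (default 8 in 200 kb): a perfect 22-nt target site for one
  of four simulated miR2275-family matures is planted on the plus strand;
  its predicted cleavage position sets the register; 24-nt duplex reads
  (2-nt 3′-overhang geometry) cover 20 cycles, with `phased_fraction`
  (0.8) of the locus abundance (400 raw reads at peak) multinomially
  spread over in-register positions and the rest uniform in the envelope.
* **hc-siRNA loci** (default 30): 200 reads at 40 uniform positions and
  strands over a 480-nt span — abundant, unphased, the pipeline's
  principal confounder.
* **MIR clusters**: 2–6 perfect stem-loops (mature + 8–15-nt loop +
  reverse-complement arm) with 30–120-nt gaps, matures assigned
  round-robin from the family so a six-hairpin cluster encodes four
  distinct matures; mature and star reads are emitted.
* **Degradome**: a 40-count spike at each true cleavage position plus
  uniform noise.
* **Stage series**: twelve ordered stages (five pre-differentiation, four
  male, three female) with a sharp, ephemeral unimodal multiplier profile
  peaking at the meiotic-like fifth stage. The profile must dominate its
  neighbors *after* RPTM normalization — the denominator itself swells at
  the peak stage, compressing contrast — so the shoulder stages sit at
  ≤ 0.4 of the peak. Per-locus, per-stage lognormal noise (σ = 0.15)
  models biological variation; hc-siRNA and background reads stay flat
  across stages. With these defaults the configured peak is the realized
  RPTM argmax for ≈ 99.5% of loci.
* **Background**: uniform reads of 21–24 nt exercising the length filter.

All randomness flows from one mandatory seed; identical seeds give
byte-identical FASTA/TSV outputs.

The **cis-propagation simulator** implements the hypothesis that either
strand of a 24-nt phasiRNA duplex can direct a cis cleavage whose
downstream fragment seeds secondary phasiRNAs shifted by +12 nt.
Generation 0 emits primary-register duplexes; each later generation lets
every duplex trigger with probability 0.5 at half the parent abundance.
All reads land in registers r and (r+12) mod 24 by construction, so from
two generations on the spectrum concentrates on two registers 12 apart —
the 12-nt pattern. How such a loop initiates in vivo is unresolved; the
simulator starts it from a primary register by fiat and the package treats
that as hypothesis, not established mechanism.

What the generator does **not** model: sequencing error, adapter artifacts,
mismatch-tolerant alignment, transcriptome context, structure-dependent
read biases, or multi-chromosome genomes. Passing tests therefore
demonstrate correctness of the statistics and geometry on idealized data,
not end-to-end performance on real libraries.

## Problem sizes and numerics

Default test and acceptance runs use a 200-kb genome (8 PHAS + 30 hc loci),
an 11,000-window null, and a 1.2-Mb, 40-locus series for peak-stage
recovery — sizes at which every documented property is measurable in
seconds. The p-value is computed in log space inside scipy; register ties
resolve to the smallest index; window slide defaults to one cycle (P nt);
empty windows are omitted; chromosomes shorter than one window are skipped
with a warning. Raw p-values are compared to α as-is by default, with
Benjamini–Hochberg available behind `PhasingParams(fdr=True)`. Multi-mapped
reads keep full counts at up to 10 placements (no fractional splitting,
keeping the hypergeometric occupancy integral); reads beyond 10 placements
are dropped and logged. N bases never match. Exact matching only: the
statistic is defined on 5′ ends, and at these read lengths mismatch
tolerance mainly imports multi-mapping ambiguity.

## Known limitations

* The window statistic's anti-conservatism under best-register selection
  is controlled by the phased-position filter, not corrected analytically;
  a selection-adjusted p-value would be the principled upgrade.
* Hairpin evaluation is gapless with respect to homology search (indel
  divergence in the mature is invisible) and the bulge model is additive
  per nucleotide without loop-size energetics.
* The 113-of-178-style trigger split on real data depends on the exact
  target-score cutoff, which is config-exposed precisely because published
  counts cannot pin it down.
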