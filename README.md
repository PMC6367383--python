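# phasikit

Detection and characterization of reproductive 24-nt phased siRNAs
(phasiRNAs) from small-RNA sequencing data: *PHAS* locus annotation with a
hypergeometric phasing statistic, miR2275 trigger-site and cleavage-registry
analysis with degradome (PARE) validation, *MIR2275* stem-loop and
polycistronic-cluster discovery, stage-resolved RPTM quantification, and a
fully seeded synthetic-data generator — including a cis-propagation
simulator for the 12-nt phasing pattern — so the entire pipeline is
testable without external downloads.

**Who it is for.** Plant small-RNA researchers annotating 24-nt (or 21-nt)
*PHAS* loci in a genome from collapsed sRNA libraries, asking which loci
carry a miR2275-family trigger whose cleavage initiates the phasing
register, whether any loci show the 12-nt pattern characteristic of
trigger-less Solanaceae-type loci, and how locus abundance tracks flower
development.

## The statistic

Dicer lays phasiRNAs down in fixed increments of P nt (24 here) from a
defined initiation point, each duplex carrying a 2-nt 3′ overhang. All
products of one initiation event share a **register** — the 5′ coordinate
mod P, with minus-strand 5′ ends shifted by +3 to account for the duplex
overhang. In a scan window of W = P·c nt there are N = 2W candidate 5′
positions (both strands), m = 2c of them in a given register. With n
distinct occupied positions and k in the best register, the window p-value
is the hypergeometric upper tail

P(X ≥ k) = Σ_{j=k}^{min(n,m)} C(m, j)·C(N−m, n−j) / C(N, n),
X ~ Hypergeometric(N, m, n).

Windows at p ≤ 0.001 merge into loci (same register, ≤ 1 cycle gap), which
must retain at least 8 distinct in-register 5′ positions. A trigger site is
a 22-nt window scoring ≤ 6.0 under plant-miRNA penalty rules (match 0,
G:U 0.5, mismatch 1, doubled at miRNA positions 2–13); its predicted
cleavage between the bases facing miRNA positions 10/11 must land in the
locus register, and a degradome peak at that exact coordinate confirms it.
See `docs/methods.md` for the full model, parameter rationale, and
limitations.

## Worked example

Simulate a staged study and run the full analysis in one command:

```bash
phasikit run-all --seed 11 -o demo
```

which prints

```
simulated 40 features into demo/sim
run-all complete under demo
```

`demo/sim` holds the genome, twelve staged collapsed read libraries
(`reads_MDS_I.fa` … `reads_FFB_III.fa`), the degradome table, the mature
miRNA queries, and `truth.tsv`. The scan step recovers all eight planted
24-*PHAS* loci; `demo/scan/loci.tsv` begins

```
locus_id                chrom  start  end    P   register  best_pvalue
PHAS24_chr1_72225_r9    chr1   72225  72703  24  9         2.44e-19
PHAS24_chr1_76610_r2    chr1   76610  77088  24  2         9.41e-20
```

Every locus's best trigger site scores 0.0 (a planted perfect site), its
predicted cleavage initiates the called register (`register_match 1`), and
the degradome peak sits exactly on the predicted coordinate
(`pare_fraction 1.0000`) — `demo/triggers/targets.tsv`:

```
locus_id              mirna         site_start  score  cleavage_pos  register_match  pare_peak  pare_fraction
PHAS24_chr1_72225_r9  mir2275-sim4  72213       0.00   72225         1               1          1.0000
```

`demo/mir/clusters.tsv` reports the two planted polycistrons — for seed 11
a five- and a six-hairpin cluster, the latter encoding four distinct mature
sequences within ~700 nt:

```
cluster  chrom  strand  start  end    n_members  n_unique_mature
1        chr1   +       70301  70923  5          4
2        chr1   +       92390  93078  6          4
```

and `demo/quant/peak_stages.tsv` places every locus's RPTM peak at the
meiotic-like stage MDS_V. Reads per ten million (RPTM) is
10⁷ × abundance / total genome-matched abundance of the library.

The same machinery is scriptable:

```python
import phasikit as pk

ds = pk.simulate_dataset(pk.SimConfig(seed=11))
alns = pk.align_dataset(ds)["MDS_V"]
params = pk.PhasingParams()           # P=24, c=9, alpha=1e-3
windows = pk.scan_phas(alns, ds.genome, params)
loci = pk.merge_windows_to_loci(windows, alns, params)
loci = [pk.detect_12nt(lc, alns, params) for lc in loci]
```

## Layout

| module | contents |
|---|---|
| `phasikit.core_io` | FASTA/collapsed-read/degradome parsing, exact-match read placement, BED6/GFF3 writers |
| `phasikit.phasing` | registers, hypergeometric p-value, phasing score, window scan, locus merging, 12-nt detection |
| `phasikit.hairpin` | mature homology search, duplex alignment, max-pairing folder, precursor evaluation, polycistron clustering |
| `phasikit.targets` | target-site scoring, cleavage prediction, register initiation, PARE validation |
| `phasikit.quantify` | RPTM matrices, stage metadata, peak-stage calls |
| `phasikit.simulate` | seeded genome/read/degradome/stage-series generator with truth table; cis-propagation simulator |
| `phasikit.cli` | `phasikit simulate / scan / annotate-triggers / find-mir / quantify / run-all` |
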