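import numpy as np
import pytest

from conftest import hypergeom_tail_enum

from phasikit.core_io import SrnaAlignment
from phasikit.phasing import (
    PhasingParams,
    assign_register,
    detect_12nt,
    merge_windows_to_loci,
    phasing_pvalue,
    phasing_score,
    scan_phas,
)


def aln(pos5, strand="+", length=24, count=1, chrom="chr1"):
    return SrnaAlignment(chrom=chrom, pos5=pos5, strand=strand, length=length, count=count)


def duplex(x, P=24, count=1, chrom="chr1"):
    """Both members of the Dicer duplex whose plus-strand 5' end is x."""
    return [
        aln(x, "+", P, count, chrom),
        aln(x + P - 3, "-", P, count, chrom),
    ]


class TestAssignRegister:
    @pytest.mark.parametrize(
        "pos5,strand,P,expected",
        [(48, "+", 24, 0), (69, "-", 24, 0), (48, "+", 12, 0), (69, "-", 12, 0)],
    )
    def test_duplex_partners_share_register(self, pos5, strand, P, expected):
        assert assign_register(aln(pos5, strand, P), P) == expected

    @pytest.mark.parametrize("P", [12, 21, 24])
    def test_any_duplex_maps_to_one_register(self, P):
        rng = np.random.default_rng(5)
        for x in rng.integers(0, 10_000, size=200):
            plus, minus = duplex(int(x), P)
            assert assign_register(plus, P) == assign_register(minus, P)


class TestPhasingPvalue:
    def test_zero_in_register_is_certain(self):
        assert phasing_pvalue(432, 18, 5, 0) == 1.0

    def test_exact_combinatorial_value(self):
        # all four occupied positions in one register: 1 / C(48, 4)
        assert phasing_pvalue(48, 4, 4, 4) == pytest.approx(1 / 194580, rel=1e-9)

    def test_all_positions_in_register_is_certain(self):
        assert phasing_pvalue(10, 10, 3, 3) == 1.0

    def test_bounds_violation_rejected(self):
        with pytest.raises(ValueError):
            phasing_pvalue(10, 4, 3, 4)

    @pytest.mark.parametrize("N,m", [(8, 2), (10, 4), (12, 6), (12, 3)])
    def test_matches_subset_enumeration(self, N, m):
        for n in range(0, N + 1):
            for k in range(0, min(n, m) + 1):
                assert phasing_pvalue(N, m, n, k) == pytest.approx(
                    hypergeom_tail_enum(N, m, n, k), abs=1e-9
                )

    def test_monotone_nonincreasing_in_k(self):
        p = [phasing_pvalue(432, 18, 12, k) for k in range(0, 13)]
        assert all(a >= b for a, b in zip(p, p[1:]))


class TestPhasingScore:
    def test_pure_signal(self):
        assert phasing_score(100, 0, 5) == pytest.approx(3 * np.log(1001), rel=1e-12)

    def test_below_three_positions_scores_zero(self):
        assert phasing_score(500, 0, 2) == 0.0

    def test_zero_signal_scores_zero(self):
        assert phasing_score(0, 50, 5) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            phasing_score(-1, 0, 3)


class TestScanPhas:
    def test_perfectly_phased_window_statistics(self):
        alignments = [aln(24 * j) for j in range(9)]  # 0, 24, ..., 192
        (w,) = scan_phas(alignments, {"chr1": 216}, PhasingParams())
        assert (w.n, w.k, w.register, w.N, w.m) == (9, 9, 0, 432, 18)
        assert w.pvalue == pytest.approx(phasing_pvalue(432, 18, 9, 9), rel=1e-12)

    def test_empty_alignments_yield_no_windows(self):
        assert scan_phas([], {"chr1": 5000}, PhasingParams()) == []

    def test_short_chromosome_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert scan_phas([aln(0)], {"tiny": 100}, PhasingParams()) == []
        assert "shorter than one window" in caplog.text

    def test_only_phase_length_reads_counted(self):
        alignments = [aln(24 * j, length=21) for j in range(9)]
        assert scan_phas(alignments, {"chr1": 216}, PhasingParams()) == []


class TestMergeWindows:
    def _phased_run(self, start, cycles, register_offset=0, P=24):
        out = []
        for j in range(cycles):
            out += duplex(start + register_offset + j * P, P)
        return out

    def test_adjacent_same_register_windows_merge(self):
        alignments = self._phased_run(0, 20)
        params = PhasingParams()
        loci = merge_windows_to_loci(scan_phas(alignments, {"chr1": 2000}, params), alignments, params)
        assert len(loci) == 1
        assert loci[0].register == 0

    def test_different_registers_stay_separate(self):
        alignments = self._phased_run(0, 12, register_offset=3) + self._phased_run(
            480 + 7, 12, register_offset=0
        )
        params = PhasingParams(min_phased_positions=8)
        loci = merge_windows_to_loci(scan_phas(alignments, {"chr1": 2000}, params), alignments, params)
        assert len(loci) == 2
        assert sorted(lc.register for lc in loci) == [3, 7]

    def test_min_phased_positions_filter(self):
        # 3 occupied positions, all in register: significant window, thin locus
        alignments = [aln(0), aln(24), aln(48)]
        params = PhasingParams(min_phased_positions=4)
        windows = scan_phas(alignments, {"chr1": 216}, params)
        assert windows[0].pvalue <= params.alpha
        assert merge_windows_to_loci(windows, alignments, params) == []

    @pytest.mark.parametrize("P", [21, 24])
    def test_perfect_locus_always_recovered_with_true_register(self, P):
        rng = np.random.default_rng(7)
        params = PhasingParams(P=P)
        for _ in range(10):
            start = int(rng.integers(0, 3000))
            alignments = []
            for j in range(12):
                alignments += duplex(start + j * P, P)
            windows = scan_phas(alignments, {"chr1": 6000}, params)
            assert min(w.pvalue for w in windows) <= 1e-5
            loci = merge_windows_to_loci(windows, alignments, params)
            assert len(loci) == 1 and loci[0].register == start % P

    def test_register_spectrum_conserves_abundance(self, default_dataset, peak_alignments, default_loci):
        for lc in default_loci:
            assert lc.register_spectrum.sum() == lc.total_abundance
            in_env = [
                a.count
                for a in peak_alignments
                if a.chrom == lc.chrom and a.length == 24 and lc.start <= a.pos5 < lc.end
            ]
            assert lc.total_abundance == sum(in_env)


class TestDetect12nt:
    def _locus_from(self, alignments, params=None):
        params = params or PhasingParams()
        windows = scan_phas(alignments, {"chr1": 20_000}, params)
        (locus,) = merge_windows_to_loci(windows, alignments, params)
        return locus

    def test_two_registers_twelve_apart_flagged(self):
        alignments = []
        for j in range(10):
            alignments += duplex(4995 + 24 * j, count=10)  # register 3
            alignments += duplex(4995 + 12 + 24 * j, count=10)  # register 15
        locus = self._locus_from(alignments)
        flagged = detect_12nt(locus, alignments, PhasingParams())
        assert flagged.twelve_nt
        assert flagged.registers_12 == (3, 15)

    def test_single_register_not_flagged(self):
        alignments = []
        for j in range(10):
            alignments += duplex(5005 + 24 * j, count=10)
        locus = self._locus_from(alignments)
        assert not detect_12nt(locus, alignments, PhasingParams()).twelve_nt

    def test_requires_24nt_phase(self):
        alignments = []
        for j in range(12):
            alignments += duplex(5000 + 21 * j, P=21)
        params = PhasingParams(P=21)
        locus = self._locus_from(alignments, params)
        with pytest.raises(ValueError, match="P=24"):
            detect_12nt(locus, alignments, params)
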