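import numpy as np
import pytest

from conftest import enum_max_pairs

from phasikit.core_io import GenomeSequence, revcomp
from phasikit.hairpin import (
    MatureQuery,
    MirnaPrecursor,
    PrecursorRejection,
    dedupe_precursors,
    detect_polycistronic_clusters,
    duplex_align,
    evaluate_precursor,
    find_mature_homologs,
    fold_hairpin,
    mature_family_pfm,
)

MATURE = "AGTCAGCGTTAGCAATCGGTAC"  # 22 nt, mixed composition
LOOP = "TTCAAGTCTT"
FLANK = "CCAACCAACCAACCAACCAACCAACCAACCAACCAACCAA"  # A/C only: cannot pair itself


def perfect_hairpin_genome(mature=MATURE, loop=LOOP, flank=FLANK):
    seq = flank + mature + loop + revcomp(mature) + flank
    return [GenomeSequence("c", seq)], len(flank)


def mutate_star(star: str, mature: str, k: int) -> str:
    """Introduce k non-pairing substitutions at spread interior positions.

    Star index s faces mature index 21 - s; the replacement base neither
    Watson-Crick pairs nor wobbles with the mature base it faces.
    """
    no_pair = {"A": "C", "C": "A", "G": "A", "T": "C"}
    star = list(star)
    # interior duplex positions (avoid star positions facing the mature 3' overhang)
    slots = [3, 6, 9, 12, 15, 18][:k]
    for s in slots:
        star[s] = no_pair[mature[21 - s]]
    return "".join(star)


class TestFoldHairpin:
    @pytest.mark.parametrize(
        "seq,n_pairs", [("GGGAAACCC", 3), ("AAAAAA", 0), ("GAAAC", 1)]
    )
    def test_small_forced_structures(self, seq, n_pairs):
        n, pairs, db = fold_hairpin(seq)
        assert n == n_pairs == len(pairs)

    def test_clean_stem_dotbracket(self):
        _, _, db = fold_hairpin("GGGAAACCC")
        assert db == "(((...)))"

    def test_pair_count_matches_enumeration_on_random_sequences(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            L = int(rng.integers(4, 13))
            seq = "".join(rng.choice(list("ACGT"), L))
            assert fold_hairpin(seq)[0] == enum_max_pairs(seq)

    def test_rejects_heavy_ambiguity(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            fold_hairpin("ACGTNNNN")

    def test_rejects_over_length(self):
        with pytest.raises(ValueError, match="exceeds folder bound"):
            fold_hairpin("A" * 500)

    def test_pairs_are_non_crossing_and_valid(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), 80))
        _, pairs, _ = fold_hairpin(seq)
        for (i, j) in pairs:
            assert j - i > 3
            assert (seq[i], seq[j]) in {("A", "T"), ("T", "A"), ("G", "C"),
                                        ("C", "G"), ("G", "T"), ("T", "G")}
        for (i, j) in pairs:
            for (a, b) in pairs:
                assert not (i < a < j < b)  # no pseudoknots


class TestFindMatureHomologs:
    def test_planted_verbatim_hit(self):
        genome, off = perfect_hairpin_genome()
        hits = find_mature_homologs(genome, MatureQuery("m", MATURE))
        plus = [h for h in hits if h.strand == "+"]
        assert any(h.pos == off and h.mismatches == 0 for h in plus)

    def test_minus_strand_hit_coordinates(self):
        rng = np.random.default_rng(2)
        g = "".join(rng.choice(list("ACGT"), 300))
        site = 120
        g = g[:site] + revcomp(MATURE) + g[site + 22 :]
        hits = find_mature_homologs([GenomeSequence("c", g)], MatureQuery("m", MATURE))
        assert any(h.strand == "-" and h.pos == site and h.mismatches == 0 for h in hits)

    def test_distance_threshold(self):
        genome = [GenomeSequence("c", "A" * 200)]
        assert find_mature_homologs(genome, MatureQuery("m", "C" * 22, max_mismatch=3)) == []

    def test_query_with_n_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            MatureQuery("m", "ACGTN" + "A" * 17)


class TestDuplexAlign:
    def test_perfect_duplex_all_pairs(self):
        score, cols, (w_lo, w_hi), (m_lo, m_hi) = duplex_align(MATURE, revcomp(MATURE))
        assert len(cols) == 22
        assert all(kind == "pair" for _, _, kind in cols)
        assert (w_lo, w_hi) == (0, 22) and (m_lo, m_hi) == (0, 22)

    def test_unpairable_window_scores_zero(self):
        score, cols, _, _ = duplex_align("ACACACACACACACACACACAC", "AAACCCAAACCC")
        assert score == 0 and cols == []


class TestEvaluatePrecursor:
    def test_perfect_hairpin_accepted(self):
        genome, off = perfect_hairpin_genome()
        hit = next(
            h for h in find_mature_homologs(genome, MatureQuery("m", MATURE))
            if h.strand == "+" and h.pos == off
        )
        res = evaluate_precursor(genome, hit)
        assert isinstance(res, MirnaPrecursor)
        assert res.duplex_mismatches == 0 and res.duplex_bulged_nt == 0
        assert res.arm == "5p"
        assert res.star_span == (off + 22 + len(LOOP), off + 22 + len(LOOP) + 22)
        assert res.mature_span == (off, off + 22)

    def test_unpairable_context_rejected_unpaired_mature(self):
        mature = "ACACACACACACACACACACAC"  # A/C only: nothing in an A/C flank pairs it
        genome = [GenomeSequence("c", FLANK + mature + FLANK)]
        hit = next(h for h in find_mature_homologs(genome, MatureQuery("m", mature)) if h.strand == "+")
        res = evaluate_precursor(genome, hit)
        assert isinstance(res, PrecursorRejection)
        assert res.reason == "unpaired_mature"

    @pytest.mark.parametrize("k", [0, 1, 2, 3, 4, 5, 6])
    def test_mismatch_boundary_exact(self, k):
        star = mutate_star(revcomp(MATURE), MATURE, k)
        genome = [GenomeSequence("c", FLANK + MATURE + LOOP + star + FLANK)]
        hit = next(
            h for h in find_mature_homologs(genome, MatureQuery("m", MATURE))
            if h.strand == "+" and h.pos == len(FLANK)
        )
        res = evaluate_precursor(genome, hit)
        if k <= 5:
            assert isinstance(res, MirnaPrecursor)
            assert res.duplex_mismatches == k
        else:
            assert isinstance(res, PrecursorRejection)
            assert res.reason == "duplex_mismatches"

    @pytest.mark.parametrize("b", [0, 1, 2, 3, 4])
    def test_bulge_boundary_exact(self, b):
        star = revcomp(MATURE)
        # insert b single-nt bulges at spread positions (unpairable vs neighbors)
        for i, pos in enumerate([4, 9, 14, 19][:b]):
            star = star[: pos + i] + "C" + star[pos + i :]
        genome = [GenomeSequence("c", FLANK + MATURE + LOOP + star + FLANK)]
        hit = next(
            h for h in find_mature_homologs(genome, MatureQuery("m", MATURE))
            if h.strand == "+" and h.pos == len(FLANK)
        )
        res = evaluate_precursor(genome, hit)
        if b <= 3:
            assert isinstance(res, MirnaPrecursor)
            assert res.duplex_bulged_nt == b
        else:
            assert isinstance(res, PrecursorRejection)
            assert res.reason == "duplex_bulges"

    def test_minus_strand_hit_evaluates(self):
        genome, off = perfect_hairpin_genome()
        hit = next(h for h in find_mature_homologs(genome, MatureQuery("m", MATURE)) if h.strand == "-")
        res = evaluate_precursor(genome, hit)
        assert isinstance(res, MirnaPrecursor)
        assert res.duplex_mismatches == 0

    def test_contig_edge_truncated_flag(self):
        genome = [GenomeSequence("c", MATURE + LOOP + revcomp(MATURE))]
        hit = next(
            h for h in find_mature_homologs(genome, MatureQuery("m", MATURE))
            if h.strand == "+" and h.pos == 0
        )
        res = evaluate_precursor(genome, hit)
        assert isinstance(res, MirnaPrecursor) and res.truncated_flank


def _precursor(start, end, strand="+", mature="A" * 22, chrom="c"):
    return MirnaPrecursor(
        chrom=chrom, start=start, end=end, strand=strand,
        mature_span=(start, start + 22), star_span=(end - 22, end),
        mature_seq=mature, structure="", duplex_mismatches=0, duplex_bulged_nt=0,
        arm="5p",
    )


class TestClusters:
    def test_gapped_chain_forms_one_cluster(self):
        prs = [_precursor(0, 54), _precursor(94, 148), _precursor(208, 262)]
        (cluster,) = detect_polycistronic_clusters(prs)
        assert len(cluster.members) == 3
        assert cluster.span == (0, 262)

    def test_distant_hairpins_do_not_cluster(self):
        prs = [_precursor(0, 54), _precursor(2054, 2108)]
        assert detect_polycistronic_clusters(prs) == []

    def test_singletons_are_not_clusters(self):
        assert detect_polycistronic_clusters([_precursor(0, 54)]) == []

    def test_order_invariance(self):
        prs = [_precursor(0, 54, mature="A" * 22), _precursor(94, 148, mature="C" * 22),
               _precursor(208, 262, mature="A" * 22), _precursor(2000, 2054, mature="G" * 22)]
        a = detect_polycistronic_clusters(prs)
        b = detect_polycistronic_clusters(list(reversed(prs)))
        assert [(c.span, len(c.members), c.n_unique_mature) for c in a] == [
            (cs.span, len(cs.members), cs.n_unique_mature) for cs in b
        ]
        assert a[0].n_unique_mature == 2

    def test_strand_duplicates_collapse_to_one_call(self):
        plus = _precursor(100, 154, "+")
        minus = _precursor(100, 154, "-")
        assert dedupe_precursors([minus, plus]) == [plus]

    def test_simulated_polycistron_k_hairpins_one_cluster(self):
        import phasikit as pk

        for k in (2, 4, 6):
            cfg = pk.SimConfig(seed=17, n_phas_loci=0, n_hc_loci=0, n_mir_clusters=1,
                               hairpins_per_cluster=(k, k), genome_length=20_000,
                               background_reads=0)
            ds = pk.simulate_dataset(cfg)
            pre = []
            for name, seq in ds.mirnas.items():
                for hit in find_mature_homologs(ds.genome, MatureQuery(name, seq)):
                    r = evaluate_precursor(ds.genome, hit)
                    if isinstance(r, MirnaPrecursor):
                        pre.append(r)
            (cluster,) = detect_polycistronic_clusters(dedupe_precursors(pre))
            assert len(cluster.members) == k


class TestFamilyPfm:
    def test_column_sums_equal_family_size(self):
        pfm = mature_family_pfm(["ACGT", "ACGA", "ACTT"])
        assert (pfm.sum(axis=0) == 3).all()
        assert pfm.loc["A", 1] == 3 and pfm.loc["T", 4] == 2

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="share one length"):
            mature_family_pfm(["ACGT", "ACG"])
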