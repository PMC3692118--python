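import numpy as np
import pytest

from conftest import enumeration_pvalue, random_pfm
from regvar3d.binding_affinity import (
    SCORE_GRID,
    NullDistribution,
    build_null,
    empirical_pvalue,
    extract_windows,
    load_motifs,
    paired_lod,
    pfm_to_pwm,
    scan_pwm,
    score_affinity_change,
)
from regvar3d.errors import (
    GenomeMismatchError,
    NullDistributionError,
    ValidationError,
)
from regvar3d.variant_io import Variant


class TestPfmToPwm:
    def test_uniform_column_uniform_background_gives_zero_weights(self):
        m = pfm_to_pwm(np.full((3, 4), 0.25))
        np.testing.assert_allclose(m.pwm, 0.0, atol=1e-12)

    def test_deterministic_column_weight(self):
        # log2(((1 + 0.01*0.25)/1.01)/0.25) with pseudocount 0.01
        m = pfm_to_pwm(np.array([[1.0, 0.0, 0.0, 0.0]]), pseudocount=0.01)
        expected = np.log2(((1.0 + 0.01 * 0.25) / 1.01) / 0.25)
        assert m.pwm[0, 0] == pytest.approx(expected, rel=1e-12)
        assert m.pwm[0, 0] == pytest.approx(1.98925, abs=1e-5)

    def test_consensus_base_has_max_weight_per_column(self):
        rng = np.random.default_rng(5)
        pfm = rng.dirichlet(np.ones(4), size=6)
        m = pfm_to_pwm(pfm)
        assert np.array_equal(m.pwm.argmax(axis=1), pfm.argmax(axis=1))

    def test_larger_pseudocount_shrinks_weights_toward_zero(self):
        pfm = np.array([[0.9, 0.04, 0.03, 0.03]])
        small = pfm_to_pwm(pfm, pseudocount=0.01).pwm
        large = pfm_to_pwm(pfm, pseudocount=0.1).pwm
        assert np.all(np.abs(large) <= np.abs(small) + 1e-12)

    def test_zero_sum_column_fatal(self):
        with pytest.raises(ValidationError):
            pfm_to_pwm(np.array([[0.0, 0.0, 0.0, 0.0]]))

    def test_library_parsing_both_orientations(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text(
            ">wide FAMX\n"  # 4 x L (base-major, width 5)
            + "\n".join(" ".join("0.25" for _ in range(5)) for _ in range(4))
            + "\n>tall FAMY\n"  # L x 4 (width 3)
            + "\n".join("0.7 0.1 0.1 0.1" for _ in range(3))
            + "\n"
        )
        motifs = load_motifs(p)
        assert [(m.name, m.length, m.family) for m in motifs] == [
            ("wide", 5, "FAMX"), ("tall", 3, "FAMY"),
        ]


class TestScanExactness:
    def test_dp_pvalues_equal_enumeration_for_all_dimers(self):
        rng = np.random.default_rng(11)
        motif = pfm_to_pwm(random_pfm(rng, 2), name="dimer")
        dist = motif.distribution()
        for a in range(4):
            for b in range(4):
                s = int(motif.iwm[0, a] + motif.iwm[1, b])
                assert dist.pvalue(s) == pytest.approx(
                    enumeration_pvalue(motif, s), abs=1e-12
                )

    @pytest.mark.parametrize("width", [3, 5, 8])
    def test_dp_matches_enumeration_random_pwms(self, width):
        rng = np.random.default_rng(width)
        for _ in range(5):
            motif = pfm_to_pwm(random_pfm(rng, width), name="r")
            dist = motif.distribution()
            # probe at a spread of observed scores
            probes = np.quantile(
                np.arange(dist.lo, dist.hi + 1), [0.0, 0.3, 0.6, 0.9, 1.0]
            ).astype(int)
            for s in probes:
                assert dist.pvalue(int(s)) == pytest.approx(
                    enumeration_pvalue(motif, int(s)), abs=1e-6
                )

    def test_consensus_scores_maximally_and_min_score_has_p_one(self, sharp_motif):
        site = scan_pwm("ACGT", sharp_motif)
        assert site.score == pytest.approx(sharp_motif.iwm.max(axis=1).sum() * SCORE_GRID)
        dist = sharp_motif.distribution()
        assert dist.pvalue(dist.lo) == pytest.approx(1.0)

    def test_best_site_found_on_reverse_strand(self, sharp_motif):
        # reverse complement of consensus ACGT is ACGT itself; use an
        # asymmetric motif instead
        pfm = np.full((3, 4), 0.01)
        pfm[:, 0] = 0.97  # consensus AAA
        motif = pfm_to_pwm(pfm, name="polyA")
        fwd = scan_pwm("GGAAAGG", motif)
        rev = scan_pwm("GGTTTGG", motif)
        assert rev.strand == "-"
        assert rev.pvalue == fwd.pvalue and rev.score == fwd.score

    def test_sequence_shorter_than_motif_is_no_site(self, sharp_motif):
        assert scan_pwm("AC", sharp_motif) is None


class TestWindows:
    GENOME = {"chr1": "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"}

    def test_snv_window_length_is_two_flanks_plus_one(self):
        v = Variant(chrom="chr1", pos=20, ref_allele="T", alt_alleles=("A",))
        w = extract_windows(self.GENOME, v, flank=10)
        assert len(w.ref_seq) == 21
        assert w.ref_seq[w.variant_offset] == "T"
        assert w.alt_seqs[0][w.variant_offset] == "A"

    def test_window_truncated_at_chromosome_start(self):
        v = Variant(chrom="chr1", pos=3, ref_allele="G", alt_alleles=("A",))
        w = extract_windows(self.GENOME, v, flank=10)
        assert w.window_start == 0 and len(w.ref_seq) == 13

    def test_deletion_alt_window_shorter(self):
        v = Variant(chrom="chr1", pos=9, ref_allele="ACG", alt_alleles=("A",))
        w = extract_windows(self.GENOME, v, flank=5)
        assert len(w.ref_seq) - len(w.alt_seqs[0]) == 2

    def test_reference_mismatch_raises(self):
        v = Variant(chrom="chr1", pos=20, ref_allele="C", alt_alleles=("A",))
        with pytest.raises(GenomeMismatchError):
            extract_windows(self.GENOME, v, flank=5)


class TestLod:
    def test_variant_outside_best_site_gives_zero_lod(self, sharp_motif):
        # the exact consensus elsewhere in the window dominates both alleles;
        # neither G nor C in a poly-A context can complete a better site
        genome = {"chr1": "A" * 10 + "ACGT" + "A" * 6 + "G" + "A" * 12}
        v = Variant(chrom="chr1", pos=21, ref_allele="G", alt_alleles=("C",))
        res = score_affinity_change(v, [sharp_motif], genome, flank=12)
        assert res[0].lod == 0.0

    def test_antisymmetry_under_allele_swap(self, sharp_motif):
        # swapping p_ref/p_alt roles negates the log-odds exactly
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = rng.uniform(1e-8, 1.0, size=2)
            assert paired_lod(a, b) == -paired_lod(b, a)

    def test_disrupting_consensus_gives_positive_eligible_lod(self, sharp_motif):
        genome = {"chr1": "TTTTTTTTTTACGTTTTTTTTTTT"}
        v = Variant(chrom="chr1", pos=12, ref_allele="C", alt_alleles=("T",))
        # a width-4 motif cannot go below p = 4^-4, so widen the threshold
        res = score_affinity_change(v, [sharp_motif], genome, flank=10,
                                    scan_threshold=0.005)
        (r,) = res
        assert r.lod > 0 and r.eligible
        # hand check: p_alt/p_ref ratio matches the scanned site p-values
        assert r.lod == pytest.approx(np.log(r.alt_site.pvalue / r.ref_site.pvalue))

    def test_strand_flip_of_window_preserves_site_pvalues(self, bundle):
        from pyfaidx import Fasta

        from regvar3d.variant_io import VariantCatalog

        motifs = load_motifs(bundle.motifs)
        genome = Fasta(str(bundle.genome), sequence_always_upper=True)
        cat = VariantCatalog.from_tsv(bundle.catalog)
        comp = str.maketrans("ACGT", "TGCA")
        for v in cat.variants()[:50]:
            w = extract_windows(genome, v)
            for motif in motifs:
                fwd = scan_pwm(w.ref_seq, motif)
                rc = scan_pwm(w.ref_seq.translate(comp)[::-1], motif)
                assert fwd.pvalue == rc.pvalue
                assert fwd.score == pytest.approx(rc.score)

    def test_motif_longer_than_window_skipped(self, sharp_motif):
        genome = {"chr1": "ACGTACGTAC"}
        v = Variant(chrom="chr1", pos=5, ref_allele="A", alt_alleles=("G",))
        long_pfm = np.full((30, 4), 0.25)
        long_motif = pfm_to_pwm(long_pfm, name="long")
        res = score_affinity_change(v, [long_motif], genome, flank=2)
        assert res == []


class TestEmpiricalNull:
    def test_rank_count_with_add_one_smoothing(self):
        null = NullDistribution(np.array([0.0, 1.0, 1.0, 3.0, 3.0]), seed=0,
                                scan_threshold=1e-3)
        assert empirical_pvalue(2.0, null) == pytest.approx((1 + 2) / 6)

    def test_extreme_lod_hits_floor(self):
        null = NullDistribution(np.arange(999, dtype=float), seed=0, scan_threshold=1e-3)
        assert empirical_pvalue(1e9, null) == pytest.approx(1 / 1000)

    def test_zero_lod_has_p_one(self):
        null = NullDistribution(np.abs(np.random.default_rng(0).normal(size=50)),
                                seed=0, scan_threshold=1e-3)
        assert empirical_pvalue(0.0, null) == pytest.approx(1.0)

    def test_matches_naive_rank_oracle_and_is_monotone(self):
        rng = np.random.default_rng(8)
        null = NullDistribution(rng.exponential(size=400), seed=0, scan_threshold=1e-3)
        qs = np.sort(rng.uniform(-6, 6, size=300))
        ps = [empirical_pvalue(q, null) for q in qs]
        for q, p in zip(qs, ps):
            naive = (1 + int(np.sum(null.sorted_lods >= abs(q)))) / (null.n + 1)
            assert p == naive
        # non-increasing in |lod| for positive queries
        pos = [p for q, p in zip(qs, ps) if q >= 0]
        assert all(a >= b for a, b in zip(pos, pos[1:]))

    def test_build_null_deterministic_and_order_independent(self, bundle):
        from pyfaidx import Fasta

        from regvar3d.variant_io import VariantCatalog

        motifs = load_motifs(bundle.motifs)
        genome = Fasta(str(bundle.genome), sequence_always_upper=True)
        variants = VariantCatalog.from_tsv(bundle.catalog).variants()
        a = build_null(variants, motifs, genome, n=300, seed=5)
        b = build_null(variants[::-1], motifs, genome, n=300, seed=5)
        np.testing.assert_array_equal(a.sorted_lods, b.sorted_lods)
        c = build_null(variants, motifs, genome, n=300, seed=6)
        assert not np.array_equal(a.sorted_lods, c.sorted_lods)

    def test_null_round_trips_through_serialization(self, bundle, tmp_path):
        from pyfaidx import Fasta

        from regvar3d.variant_io import VariantCatalog

        motifs = load_motifs(bundle.motifs)
        genome = Fasta(str(bundle.genome), sequence_always_upper=True)
        variants = VariantCatalog.from_tsv(bundle.catalog).variants()
        null = build_null(variants, motifs, genome, n=300, seed=5)
        path = tmp_path / "null.tsv"
        null.save(path)
        loaded = NullDistribution.load(path)
        np.testing.assert_array_equal(null.sorted_lods, loaded.sorted_lods)
        assert (loaded.seed, loaded.scan_threshold) == (5, null.scan_threshold)
        for q in (0.0, 1.7, 12.0):
            assert empirical_pvalue(q, null) == empirical_pvalue(q, loaded)

    def test_no_eligible_lods_is_fatal(self, sharp_motif):
        # uniform motif never reaches the 1e-3 site threshold
        flat = pfm_to_pwm(np.full((4, 4), 0.25), name="flat")
        genome = {"chr1": "ACGT" * 30}
        variants = [
            Variant(chrom="chr1", pos=p, ref_allele="ACGT"[(p - 1) % 4],
                    alt_alleles=("ACGT"[p % 4],))
            for p in range(40, 60)
        ]
        with pytest.raises(NullDistributionError):
            build_null(variants, [flat], genome, n=100, seed=0)

    def test_batch_path_agrees_with_per_variant_scan(self, bundle):
        from pyfaidx import Fasta

        from regvar3d.variant_io import VariantCatalog

        motifs = load_motifs(bundle.motifs)
        genome = Fasta(str(bundle.genome), sequence_always_upper=True)
        variants = VariantCatalog.from_tsv(bundle.catalog).variants()
        null = build_null(variants, motifs, genome, n=500, seed=9)
        # recompute the same sample's |LOD|s through the scan API
        rng = np.random.default_rng(9)
        picks = rng.integers(0, len(variants), size=500)
        slow = []
        for i in picks:
            res = score_affinity_change(variants[i], motifs, genome)
            slow.extend(abs(r.lod) for r in res if r.eligible)
        np.testing.assert_allclose(np.sort(slow), null.sorted_lods, rtol=0, atol=0)
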