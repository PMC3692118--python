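import numpy as np
import pytest

from regvar3d.errors import UnknownCellTypeError, ValidationError
from regvar3d.regulatory_signals import (
    ContactMatrix,
    GenomicInterval,
    RegulatorySignal,
    SignalIndex,
    annotate_signals,
    call_interaction_anchors,
    filter_to_signal_variants,
    ice_normalize,
    load_bed_track,
    load_bedpe_track,
    load_tracks,
)
from regvar3d.variant_io import Variant


def make_index(intervals, cell_type="cellA", mark="H3K27ac"):
    index = SignalIndex()
    for chrom, start, end in intervals:
        index.add(
            RegulatorySignal(mark_class=mark, cell_type=cell_type,
                             interval=GenomicInterval(chrom, start, end))
        )
    return index


class TestTracks:
    def test_manifest_loads_bed_and_bedpe(self, tmp_path):
        (tmp_path / "enh.bed").write_text("chr1\t100\t200\nchr2\t5\t50\n")
        (tmp_path / "loops.bedpe").write_text("chr1\t10\t20\tchr1\t500\t600\tl1\t3.5\n")
        manifest = tmp_path / "tracks.yaml"
        manifest.write_text(
            "- {mark_class: H3K27ac, cell_type: cellA, path: enh.bed}\n"
            "- {mark_class: interaction_anchor, cell_type: cellA, path: loops.bedpe}\n"
        )
        index = load_tracks(manifest)
        assert set(index.cell_types) == {"cellA", "merged"}
        hits = index.query_point("cellA", "chr1", 150)
        assert [h.mark_class for h in hits] == ["H3K27ac"]

    def test_bedpe_yields_two_anchors_with_partners(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr1\t10\t20\tchr2\t500\t600\tl1\t3.5\n")
        signals = load_bedpe_track(p, "cellA")
        assert len(signals) == 2
        left, right = signals
        assert left.partner == right.interval and right.partner == left.interval
        assert left.intensity == 3.5

    def test_chromhmm_strong_filter(self, tmp_path):
        p = tmp_path / "hmm.bed"
        p.write_text(
            "chr1\t0\t10\t11_Strong_Enhancer\nchr1\t10\t20\t7_Weak_Enhancer\n"
        )
        signals = load_bed_track(p, "chromhmm_enhancer", "cellA", name_filter="Strong")
        assert len(signals) == 1 and signals[0].interval.start == 0

    def test_inverted_bed_interval_fatal(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t50\t50\n")
        with pytest.raises(ValidationError):
            load_bed_track(p, "DHS", "cellA")

    def test_partner_only_on_interaction_anchor(self):
        with pytest.raises(ValidationError):
            RegulatorySignal(mark_class="DHS", cell_type="c",
                             interval=GenomicInterval("chr1", 0, 10),
                             partner=GenomicInterval("chr1", 20, 30))


class TestAnnotate:
    def test_containment_and_half_open_boundaries(self):
        index = make_index([("chr1", 100, 200)])
        # 1-based pos 101 -> 0-based 100: first covered base, always hits
        assert annotate_signals(Variant(chrom="chr1", pos=101), index, "cellA")
        # 1-based pos 200 -> 0-based 199: last covered base of [100,200)
        assert annotate_signals(Variant(chrom="chr1", pos=200), index, "cellA")
        # 1-based pos 201 -> 0-based 200: the end coordinate never hits
        assert not annotate_signals(Variant(chrom="chr1", pos=201), index, "cellA")

    def test_unknown_cell_type_lists_available(self):
        index = make_index([("chr1", 0, 10)])
        with pytest.raises(UnknownCellTypeError, match="cellA"):
            annotate_signals(Variant(chrom="chr1", pos=5), index, "HepG2")

    def test_merged_pseudo_cell_type_unions_tracks(self):
        index = make_index([("chr1", 0, 10)], cell_type="cellB")
        v = Variant(chrom="chr1", pos=5)
        assert not annotate_signals(v, make_index([("chr2", 0, 1)]), "cellA")
        assert annotate_signals(v, index, "merged")

    def test_user_promoter_regions_count_as_signal(self):
        index = make_index([("chr9", 0, 1)])
        v = Variant(chrom="chr1", pos=150)
        hits = annotate_signals(
            v, index, "cellA", promoter_regions=[GenomicInterval("chr1", 100, 200)]
        )
        assert [h.mark_class for h in hits] == ["user_promoter"]

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(42)
        intervals = [
            ("chr1", int(s), int(s + w))
            for s, w in zip(rng.integers(0, 900, 60), rng.integers(1, 60, 60))
        ]
        index = make_index(intervals)
        for pos1 in rng.integers(1, 1001, 200):
            point = int(pos1) - 1
            expected = sum(1 for _, s, e in intervals if s <= point < e)
            hits = annotate_signals(Variant(chrom="chr1", pos=int(pos1)), index, "cellA")
            assert len(hits) == expected

    def test_filter_keeps_only_signal_variants_and_side_reports(self):
        index = make_index([("chr1", 100, 200)])
        inside = Variant(chrom="chr1", pos=150, id="rsin")
        outside = Variant(chrom="chr1", pos=900, id="rsout")
        proxies = {"L1": [(inside, 1.0), (outside, 0.9)], "L2": [(outside, 1.0)]}
        surviving, no_signal = filter_to_signal_variants(proxies, index, "cellA")
        assert list(surviving) == ["L1"]
        assert [v.key for v, _, _ in surviving["L1"]] == ["rsin"]
        assert no_signal == ["L2"]

    def test_merged_retains_variant_single_cell_type_drops(self):
        index = make_index([("chr1", 100, 200)], cell_type="cellB")
        v = Variant(chrom="chr1", pos=150, id="rs1")
        proxies = {"L": [(v, 1.0)]}
        _, no_signal_a = filter_to_signal_variants(proxies, index, "cellA") \
            if "cellA" in index.cell_types else ({}, ["L"])
        surviving_m, _ = filter_to_signal_variants(proxies, index, "merged")
        assert no_signal_a == ["L"]
        assert list(surviving_m) == ["L"]


def sinkhorn_oracle(M, iters=5_000):
    """Independent alternating row/column normalization run to convergence."""
    c = np.ones(M.shape[1])
    for _ in range(iters):
        r = 1.0 / (M @ c)
        c = 1.0 / (M.T @ r)
    return np.diag(r) @ M @ np.diag(c)


class TestIce:
    def test_symmetric_two_by_two_is_fixed_point(self):
        m = ContactMatrix(
            bins=[GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 20)],
            counts=np.array([[0.0, 2.0], [2.0, 0.0]]),
        )
        out = ice_normalize(m)
        assert out.balanced
        np.testing.assert_allclose(out.counts, m.counts, rtol=1e-6)

    def test_heavy_row_is_flattened_and_matches_oracle(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(0.5, 2.0, size=(3, 3))
        M = (M + M.T) / 2
        M[0] *= 10; M[:, 0] *= 10
        bins = [GenomicInterval("chr1", i * 10, (i + 1) * 10) for i in range(3)]
        out = ice_normalize(ContactMatrix(bins=bins, counts=M), tol=1e-8)
        rs = out.counts.sum(axis=1)
        assert np.max(np.abs(rs / rs.mean() - 1)) < 1e-7
        oracle = sinkhorn_oracle(M)
        np.testing.assert_allclose(
            out.counts / out.counts.sum(), oracle / oracle.sum(), atol=1e-8
        )

    def test_zero_row_masked_and_others_balanced(self):
        M = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
        bins = [GenomicInterval("chr1", i, i + 1) for i in range(3)]
        out = ice_normalize(ContactMatrix(bins=bins, counts=M))
        assert np.all(out.counts[2] == 0) and np.all(out.counts[:, 2] == 0)
        rs = out.counts[:2].sum(axis=1)
        assert np.max(np.abs(rs / rs.mean() - 1)) < 1e-5

    def test_scaling_input_scales_output(self):
        rng = np.random.default_rng(1)
        M = rng.uniform(0.1, 1.0, size=(5, 5))
        M = M + M.T
        bins = [GenomicInterval("chr1", i, i + 1) for i in range(5)]
        a = ice_normalize(ContactMatrix(bins=bins, counts=M), tol=1e-9)
        b = ice_normalize(ContactMatrix(bins=bins, counts=3.0 * M), tol=1e-9)
        np.testing.assert_allclose(3.0 * a.counts, b.counts, rtol=1e-6)

    def test_asymmetric_and_all_zero_inputs_fatal(self):
        bins = [GenomicInterval("chr1", i, i + 1) for i in range(2)]
        with pytest.raises(ValidationError):
            ice_normalize(ContactMatrix(bins=bins, counts=np.array([[0.0, 1.0], [2.0, 0.0]])))
        with pytest.raises(ValidationError):
            ice_normalize(ContactMatrix(bins=bins, counts=np.zeros((2, 2))))


def test_contact_matrix_loads_from_dense_text_and_bin_bed(tmp_path):
    (tmp_path / "bins.bed").write_text("chr1\t0\t100\nchr1\t100\t200\n")
    (tmp_path / "m.txt").write_text("0 3\n3 0\n")
    cm = ContactMatrix.from_files(tmp_path / "m.txt", tmp_path / "bins.bed")
    assert len(cm.bins) == 2 and cm.counts[0, 1] == 3.0 and not cm.balanced
    with pytest.raises(ValidationError):
        ContactMatrix(bins=cm.bins, counts=np.ones((3, 3)))


class TestAnchors:
    def make_balanced(self, counts):
        n = counts.shape[0]
        bins = [GenomicInterval("chr1", i * 100, (i + 1) * 100) for i in range(n)]
        return ContactMatrix(bins=bins, counts=counts, balanced=True)

    def test_single_nonzero_pair_called_at_quantile_zero(self):
        C = np.zeros((3, 3)); C[0, 2] = C[2, 0] = 5.0
        signals = call_interaction_anchors(self.make_balanced(C), 0.0)
        assert len(signals) == 2
        assert {s.interval.start for s in signals} == {0, 200}
        assert all(s.intensity == 5.0 for s in signals)

    def test_quantile_one_gives_empty(self):
        C = np.zeros((3, 3)); C[0, 1] = C[1, 0] = 5.0; C[1, 2] = C[2, 1] = 1.0
        assert call_interaction_anchors(self.make_balanced(C), 1.0) == []

    def test_planted_top_pair_called(self):
        rng = np.random.default_rng(3)
        C = rng.uniform(0.1, 1.0, size=(8, 8)); C = (C + C.T) / 2
        C[2, 6] = C[6, 2] = 50.0
        iu = np.triu_indices(8, k=1)
        top = np.argsort(C[iu])[-1]
        assert (iu[0][top], iu[1][top]) == (2, 6)
        signals = call_interaction_anchors(self.make_balanced(C), 0.99)
        starts = {(s.interval.start, s.partner.start) for s in signals}
        assert (200, 600) in starts and (600, 200) in starts
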