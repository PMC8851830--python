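import math

import numpy as np
import pytest

from snp3d.genomic import ElementIndex, SNP
from snp3d.tads import (
    ContactMatrix,
    binsignal,
    boundary_pvalue,
    call_tads,
    candidate_boundaries,
    classify_tads,
    expected_normalize,
    matrix_from_contacts,
    tad_group_summary,
)
from .conftest import contact_frame, contact_row, make_element

RES = 10_000


def two_block_matrix(n=20, split=10, high=50.0, rng=None):
    """Block-diagonal fixture: dense within blocks, empty across."""
    m = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a != b and (a < split) == (b < split):
                m[a, b] = high
    if rng is not None:
        noise = rng.poisson(high, size=(n, n)).astype(float)
        noise = np.triu(noise, 1)
        mask = np.zeros((n, n), dtype=bool)
        for a in range(n):
            for b in range(a + 1, n):
                mask[a, b] = (a < split) == (b < split)
        m = np.where(mask, noise, 0.0)
        m = m + m.T
    return ContactMatrix("chr1", RES, m)


class TestBinsignal:
    def test_uniform_matrix_gives_constant_signal(self):
        m = ContactMatrix("chr1", RES, np.full((10, 10), 3.0))
        assert {binsignal(m, i, 2) for i in range(9)} == {3.0}

    def test_direct_submatrix_mean(self):
        counts = np.zeros((4, 4))
        counts[0, 2], counts[0, 3], counts[1, 2], counts[1, 3] = 1, 2, 3, 4
        counts = counts + counts.T
        m = ContactMatrix("chr1", RES, counts)
        assert binsignal(m, 1, 2) == pytest.approx(2.5)

    def test_edge_truncation(self):
        counts = np.zeros((4, 4))
        counts[0, 1], counts[0, 2] = 5, 7
        counts = counts + counts.T
        m = ContactMatrix("chr1", RES, counts)
        # boundary 0 with w=2: only row 0, cols 1..2 available
        assert binsignal(m, 0, 2) == pytest.approx(6.0)

    def test_scales_linearly_with_matrix(self):
        rng = np.random.default_rng(3)
        c = rng.poisson(5, size=(12, 12)).astype(float)
        c = np.triu(c, 1)
        c = c + c.T
        m1 = ContactMatrix("chr1", RES, c)
        m3 = ContactMatrix("chr1", RES, 3 * c)
        for i in range(11):
            assert binsignal(m3, i, 3) == pytest.approx(3 * binsignal(m1, i, 3))


class TestCandidateBoundaries:
    def test_v_shape_unique_minimum(self):
        sig = [5, 4, 3, 2, 1, 0, 1, 2, 3, 4, 5]
        assert candidate_boundaries(sig, 2) == [5]

    def test_plateau_keeps_leftmost(self):
        sig = [5, 4, 3, 1, 1, 3, 4, 5]
        assert candidate_boundaries(sig, 2) == [3]

    def test_monotone_signal_has_only_end_minimum(self):
        sig = list(range(10, 0, -1))
        assert candidate_boundaries(sig, 3) == [9]


class TestBoundaryPvalue:
    def test_identical_distributions_not_significant(self):
        m = ContactMatrix("chr1", RES, np.full((12, 12), 4.0))
        assert boundary_pvalue(m, 5, 3) >= 0.5

    def test_complete_separation_matches_exact_tail(self):
        # all 9 cross cells zero, all 6 within cells positive (w=3):
        # exact one-sided rank-sum tail = 1 / C(15, 6)
        n, w, i = 12, 3, 5
        counts = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                same_side = (a <= i) == (b <= i)
                if i - w + 1 <= a <= i + w and i - w + 1 <= b <= i + w:
                    counts[a, b] = 10.0 + a + b if same_side else 0.0
        counts = counts + counts.T
        m = ContactMatrix("chr1", RES, counts)
        assert boundary_pvalue(m, i, w) == pytest.approx(1 / math.comb(15, 6))

    def test_degenerate_window_returns_one(self):
        m = ContactMatrix("chr1", RES, np.full((4, 4), 2.0))
        assert boundary_pvalue(m, 0, 1) == 1.0


class TestCallTads:
    def test_uniform_matrix_single_tad(self):
        m = ContactMatrix("chr1", RES, np.full((30, 30), 5.0))
        tads = call_tads(m, w=3)
        assert len(tads) == 1
        assert (tads[0].start, tads[0].end) == (0, 30 * RES)

    def test_two_block_matrix_single_internal_boundary(self):
        rng = np.random.default_rng(11)
        m = two_block_matrix(n=20, split=10, high=50.0, rng=rng)
        tads = call_tads(m, w=3, normalize="raw")
        assert len(tads) == 2
        assert tads[0].end == 10 * RES and tads[1].start == 10 * RES

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        m = two_block_matrix(n=24, split=12, high=40.0, rng=rng)
        a = call_tads(m, w=3)
        b = call_tads(m, w=3)
        assert [(t.start, t.end) for t in a] == [(t.start, t.end) for t in b]

    def test_boundary_calls_invariant_under_global_scaling(self):
        rng = np.random.default_rng(9)
        m = two_block_matrix(n=24, split=12, high=40.0, rng=rng)
        scaled = ContactMatrix(m.chrom, m.resolution, m.counts * 7.5)
        assert [(t.start, t.end) for t in call_tads(m, w=3)] == [
            (t.start, t.end) for t in call_tads(scaled, w=3)
        ]

    def test_tiny_chromosome_yields_whole_chromosome_tad(self):
        m = ContactMatrix("chr1", RES, np.full((6, 6), 2.0))
        tads = call_tads(m, w=5)
        assert len(tads) == 1 and tads[0].end == 6 * RES

    def test_tads_partition_chromosome(self):
        rng = np.random.default_rng(21)
        n = 60
        counts = np.triu(rng.poisson(8, size=(n, n)).astype(float), 1)
        counts = counts + counts.T
        tads = call_tads(ContactMatrix("chr1", RES, counts), w=4)
        assert tads[0].start == 0 and tads[-1].end == n * RES
        for prev, cur in zip(tads, tads[1:]):
            assert prev.end == cur.start

    def test_expected_normalize_removes_distance_trend(self):
        n = 40
        iu, ju = np.triu_indices(n, 1)
        counts = np.zeros((n, n))
        counts[iu, ju] = 100.0 / (ju - iu)
        counts = counts + counts.T
        norm = expected_normalize(ContactMatrix("chr1", RES, counts))
        off_diag = norm.counts[iu, ju]
        assert off_diag == pytest.approx(np.ones_like(off_diag))


class TestClassifyTads:
    def _tads(self):
        m = ContactMatrix("chr1", RES, np.full((30, 30), 5.0))
        return call_tads(m, w=3)

    def test_contained_snp_marks_snp_rich(self):
        tads = classify_tads(self._tads(), [SNP("rs1", "chr1", 50_000, 1e-9)])
        assert tads[0].label == "snp_rich" and tads[0].snps[0].id == "rs1"

    def test_outside_snp_leaves_control(self):
        tads = classify_tads(self._tads(), [SNP("rs1", "chr2", 50_000, 1e-9)])
        assert tads[0].label == "control"

    def test_boundary_snp_belongs_to_exactly_one_tad(self):
        counts = np.zeros((30, 30))
        tads = [t for t in call_tads(ContactMatrix("chr1", RES, np.full((30, 30), 5.0)), w=3)]
        # split manually into two abutting TADs sharing the 150 kb boundary
        from snp3d.tads import TAD

        tads = [TAD("a", "chr1", 0, 150_000), TAD("b", "chr1", 150_000, 300_000)]
        snp = SNP("rs1", "chr1", 150_001, 1e-9)  # pos0 = 150000, first base of TAD b
        labeled = classify_tads(tads, [snp])
        assert [t.label for t in labeled] == ["control", "snp_rich"]


class TestTadGroupSummary:
    def test_per_tad_median_and_group_quantiles(self):
        from snp3d.tads import TAD

        rich = TAD("r", "chr1", 0, 100_000, label="snp_rich",
                   elements=(make_element("e1", start=10, end=20, da=5.0),
                             make_element("e2", start=30, end=40, da=6.0)))
        controls = [
            TAD(f"c{i}", "chr1", 100_000 * (i + 1), 100_000 * (i + 2), label="control",
                elements=(make_element(f"ce{i}", start=0, end=10, da=da),))
            for i, da in enumerate([4.55, 4.75, 4.90])
        ]
        summ = tad_group_summary([rich] + controls)
        assert summ["snp_rich"]["enhancer"].q2 == pytest.approx(5.5)
        assert summ["control"]["enhancer"].q2 == pytest.approx(4.75)
        assert "tf" not in summ["control"]  # no TFs anywhere: class absent

    def test_empty_group_absent_not_error(self):
        from snp3d.tads import TAD

        only = TAD("t", "chr1", 0, 50_000, label="control",
                   elements=(make_element("e", start=0, end=10, da=1.0),))
        summ = tad_group_summary([only])
        assert set(summ) == {"control"}

    def test_unclassified_tads_rejected(self):
        from snp3d.tads import TAD

        with pytest.raises(ValueError):
            tad_group_summary([TAD("t", "chr1", 0, 50_000)])


class TestMatrixFromContacts:
    def test_densify_is_symmetric_and_matches_counts(self):
        df = contact_frame(
            [contact_row("chr1", 0, "chr1", 2, 7), contact_row("chr1", 1, "chr1", 3, 4)]
        )
        m = matrix_from_contacts(df, "chr1", RES)
        assert m.n_bins == 4
        assert m.counts[0, 2] == m.counts[2, 0] == 7
        assert m.counts[1, 3] == 4
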