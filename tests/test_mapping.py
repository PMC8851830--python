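import itertools

import numpy as np
import pytest

from snp3d.genomic import Bin, ElementIndex, Gene, SNP, overlaps, window_around
from snp3d.mapping import (
    CandidateFragment,
    candidate_fragments,
    map_1d,
    map_3d,
    select_fragment,
    select_high_risk,
)
from .conftest import contact_frame, contact_row, make_element

RES = 10_000


def brute_force_1d(snp, elements, resolution):
    win = window_around(snp, resolution)
    return {el.id for el in elements if overlaps(el.interval, win)}


def random_elements(rng, n, chrom_len=2_000_000):
    els = []
    for k in range(n):
        start = int(rng.integers(0, chrom_len - 2000))
        length = int(rng.integers(50, 2000))
        kind = "enhancer" if rng.random() < 0.7 else "tfbs"
        els.append(
            make_element(
                f"el{k:05d}", start=start, end=start + length, kind=kind,
                da=float(rng.uniform(0, 10)),
            )
        )
    return els


class TestSelectHighRisk:
    @pytest.mark.parametrize(
        "pvalue, kept",
        [
            (5.0e-8, True),   # genome-wide threshold itself is retained
            (5.5e-9, True),   # rs4752575-like association
            (1.0e-7, False),
        ],
    )
    def test_threshold_inclusivity(self, pvalue, kept):
        snps = [SNP("rs1", "chr1", 100, pvalue)]
        assert (len(select_high_risk(snps)) == 1) is kept


class TestMap1D:
    def test_contains_and_excludes_by_half_open_window(self):
        snp = SNP("rs1", "chr1", 100_000, 1e-9)
        win = window_around(snp, RES)  # [94999, 104999)
        inside = make_element("in", start=95_000, end=95_100)
        abutting = make_element("out", start=win.end, end=win.end + 500)
        idx = ElementIndex([inside, abutting])
        mapping = map_1d(snp, idx, RES)
        assert [el.id for el in mapping.enhancers] == ["in"]
        assert mapping.mode == "1D" and mapping.selected_fragments == ()

    def test_empty_element_set_yields_empty_mapping(self):
        mapping = map_1d(SNP("rs1", "chr1", 100, 1e-9), ElementIndex([]), RES)
        assert mapping.is_empty and mapping.median_da_enhancer is None

    def test_matches_brute_force_on_random_fixture(self, rng):
        elements = random_elements(rng, 1000)
        idx = ElementIndex(elements)
        for _ in range(20):
            snp = SNP("rs", "chr1", int(rng.integers(1, 2_000_000)), 1e-9)
            got = {el.id for el in map_1d(snp, idx, RES).enhancers} | {
                el.id for el in map_1d(snp, idx, RES).tfbs
            }
            assert got == brute_force_1d(snp, elements, RES)


class TestCandidateFragments:
    def _fixture(self):
        snp = SNP("rs1", "chr1", 5 * RES + 1, 1e-9)  # bin 5
        elements = ElementIndex(
            [
                make_element("enh", start=10 * RES + 10, end=10 * RES + 500),
                make_element("tf", start=20 * RES + 10, end=20 * RES + 30, kind="tfbs"),
            ]
        )
        sig = contact_frame(
            [
                contact_row("chr1", 5, "chr1", 10, 9, qvalue=0.01),   # F1: enhancer
                contact_row("chr1", 5, "chr1", 15, 9, qvalue=0.001),  # F2: empty
                contact_row("chr1", 5, "chr1", 20, 9, qvalue=0.04),   # F3: tfbs
            ]
        )
        return snp, sig, elements

    def test_empty_fragments_excluded(self):
        snp, sig, elements = self._fixture()
        cands = candidate_fragments(snp, sig, elements, RES)
        assert {c.bin.index for c in cands} == {10, 20}

    def test_kind_filter(self):
        snp, sig, elements = self._fixture()
        cands = candidate_fragments(snp, sig, elements, RES, kind_filter="enhancer")
        assert [c.bin.index for c in cands] == [10]

    def test_snp_with_no_contacts(self):
        snp, sig, elements = self._fixture()
        lonely = SNP("rs2", "chr1", 500 * RES, 1e-9)
        assert candidate_fragments(lonely, sig, elements, RES) == []

    def test_snp_bin_found_on_either_side_of_pair(self):
        snp, _, elements = self._fixture()
        sig = contact_frame([contact_row("chr1", 10, "chr1", 5, 9, qvalue=0.02)])
        cands = candidate_fragments(snp, sig, elements, RES)
        assert [c.bin.index for c in cands] == [10]


class TestSelectFragment:
    def test_lowest_q_dominates_distance(self):
        f1 = CandidateFragment(Bin("chr1", 20, RES), 0.01, 200_000.0)
        f2 = CandidateFragment(Bin("chr1", 80, RES), 0.02, 800_000.0)
        assert select_fragment([f1, f2]) is f1

    def test_tie_broken_toward_longest_range(self):
        f1 = CandidateFragment(Bin("chr1", 20, RES), 0.01, 200_000.0)
        f2 = CandidateFragment(Bin("chr1", 80, RES), 0.01, 800_000.0)
        assert select_fragment([f1, f2]) is f2

    def test_inter_chromosomal_outranks_any_intra_on_ties(self):
        f1 = CandidateFragment(Bin("chr1", 90, RES), 0.01, 900_000.0)
        f2 = CandidateFragment(Bin("chr2", 3, RES), 0.01, None)
        assert select_fragment([f1, f2]) is f2

    def test_empty_candidates(self):
        assert select_fragment([]) is None

    def test_total_order_invariant_under_permutation(self, rng):
        cands = [
            CandidateFragment(
                Bin("chr1", int(i), RES),
                float(q),
                None if i % 5 == 0 else float(i) * RES,
            )
            for i, q in enumerate(rng.choice([0.01, 0.02, 0.03], size=8))
        ]
        results = set()
        for perm in itertools.permutations(range(len(cands)), len(cands)):
            chosen = select_fragment([cands[i] for i in perm])
            results.add(chosen.bin.index)
            if len(results) > 1:
                break
        assert len(results) == 1


class TestMap3D:
    def test_single_partner_single_enhancer_and_gene(self, tiny_genes):
        snp = SNP("rs1", "chr1", 5 * RES + 1, 1e-9)
        elements = ElementIndex(
            [make_element("e1", start=10 * RES, end=10 * RES + 400, da=3.0,
                          targets=("GENE_A",))]
        )
        sig = contact_frame([contact_row("chr1", 5, "chr1", 10, 9, qvalue=0.01)])
        m = map_3d(snp, sig, elements, RES, tiny_genes)
        assert [el.id for el in m.enhancers] == ["e1"]
        assert [g.symbol for g in m.target_genes] == ["GENE_A"]
        assert m.median_da_targets == pytest.approx(2.0)

    def test_enhancer_contact_targeting_known_gene(self, tiny_genes):
        # an enhancer in the contacted fragment targets MAP3K1 (DA 5.3)
        snp = SNP("rs7714232", "chr5", 56_011_357, 1e-9)
        partner_bin = 5650
        elements = ElementIndex(
            [
                make_element(
                    "119861",
                    chrom="chr5",
                    start=partner_bin * RES + 100,
                    end=partner_bin * RES + 900,
                    da=4.2,
                    targets=("MAP3K1",),
                )
            ]
        )
        sig = contact_frame(
            [contact_row("chr5", 5601, "chr5", partner_bin, 12, qvalue=0.004)]
        )
        m = map_3d(snp, sig, elements, RES, tiny_genes)
        assert m.median_da_targets == pytest.approx(5.3)

    def test_no_significant_contacts_yields_empty_mapping(self):
        snp = SNP("rs1", "chr1", 5 * RES + 1, 1e-9)
        sig = contact_frame([contact_row("chr1", 50, "chr1", 60, 9, qvalue=0.01)])
        m = map_3d(snp, sig, ElementIndex([]), RES)
        assert m.is_empty and m.selected_fragments == ()

    def test_joint_vs_per_class_scopes(self):
        # the minimal-q fragment holds only a tfbs; per_class still finds the
        # best enhancer-bearing fragment, joint does not
        snp = SNP("rs1", "chr1", 5 * RES + 1, 1e-9)
        elements = ElementIndex(
            [
                make_element("tf", start=10 * RES, end=10 * RES + 20, kind="tfbs"),
                make_element("enh", start=20 * RES, end=20 * RES + 400),
            ]
        )
        sig = contact_frame(
            [
                contact_row("chr1", 5, "chr1", 10, 9, qvalue=0.001),
                contact_row("chr1", 5, "chr1", 20, 9, qvalue=0.02),
            ]
        )
        joint = map_3d(snp, sig, elements, RES, selection_scope="joint")
        per_class = map_3d(snp, sig, elements, RES, selection_scope="per_class")
        assert joint.enhancers == () and [el.id for el in joint.tfbs] == ["tf"]
        assert [el.id for el in per_class.enhancers] == ["enh"]
        assert [el.id for el in per_class.tfbs] == ["tf"]

    def test_reported_elements_overlap_selected_fragment(self, rng):
        elements = random_elements(rng, 400)
        idx = ElementIndex(elements)
        rows = []
        for i in range(30):
            rows.append(
                contact_row("chr1", int(rng.integers(0, 100)),
                            "chr1", int(rng.integers(100, 200)), 9,
                            qvalue=float(rng.uniform(0, 0.05)))
            )
        sig = contact_frame(rows)
        for _ in range(20):
            snp = SNP("rs", "chr1", int(rng.integers(1, 100 * RES)), 1e-9)
            m = map_3d(snp, sig, idx, RES)
            for frag in m.selected_fragments:
                hits = {el.id for el in idx.query_bin(frag.bin)}
                for el in m.enhancers + m.tfbs:
                    if el.id in hits:
                        assert overlaps(el.interval, frag.bin.interval)
            if m.selected_fragments:
                assert not m.is_empty
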