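"""RCM discovery: alignment correctness, eligibility and BSJ profiles."""

import numpy as np
import pandas as pd
import pytest
from Bio import Align

from arcirc import (AlignScoring, SimConfig, editing_density_profile,
                    eligible_circs, find_rcms, make_genome,
                    rcm_coverage_profile, revcomp, smith_waterman)
from arcirc.align import alignment_score_from_columns
from arcirc.rcm import scan_circs, site_bsj_offsets


def biopython_sw(scoring: AlignScoring) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestAlignment:
    def test_perfect_reverse_complement_block_scores_its_length(self):
        rng = np.random.default_rng(1)
        up = random_seq(rng, 400)
        block = up[120:220]
        down = random_seq(rng, 150) + revcomp(block) + random_seq(rng, 150)
        rcms = find_rcms(up, down)
        top = rcms[0]
        assert top.is_top and top.score >= 100
        # the planted block is contained in the top arm (chance flanking
        # matches may extend it by a base or two)
        assert top.up_start <= 120 and top.up_end >= 219

    def test_top_score_equals_independent_smith_waterman(self):
        """Cross-check against Bio.Align.PairwiseAligner on random pairs."""
        sc = AlignScoring()
        oracle = biopython_sw(sc)
        rng = np.random.default_rng(2)
        for _ in range(40):
            a = random_seq(rng, int(rng.integers(20, 300)))
            b = random_seq(rng, int(rng.integers(20, 300)))
            mine = smith_waterman(a, b, sc)
            assert (mine.score if mine else 0) == oracle.score(a, b)

    def test_score_recomputation_from_columns_matches(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = random_seq(rng, 150), random_seq(rng, 150)
            aln = smith_waterman(a + b[:40], b)
            if aln:
                assert alignment_score_from_columns(aln, a + b[:40], b) == aln.score

    def test_role_swap_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            up, down = random_seq(rng, 200), random_seq(rng, 200)
            s1 = find_rcms(up, down, min_score=1)[0].score
            s2 = find_rcms(down, up, min_score=1)[0].score
            assert s1 == s2

    def test_all_n_sequence_yields_no_rcm(self):
        assert find_rcms("N" * 100, "N" * 100) == []

    def test_secondary_rcms_do_not_overlap_the_top(self):
        rng = np.random.default_rng(5)
        up = random_seq(rng, 500)
        down = (random_seq(rng, 50) + revcomp(up[50:130]) + random_seq(rng, 60)
                + revcomp(up[300:350]) + random_seq(rng, 50))
        rcms = find_rcms(up, down, min_score=30)
        assert len(rcms) == 2 and rcms[0].score > rcms[1].score
        assert (rcms[0].up_end < rcms[1].up_start
                or rcms[1].up_end < rcms[0].up_start)


def test_simulator_top_rcm_equals_planted_arms(bundle):
    rcms = scan_circs(bundle)
    circs = bundle.circs.set_index("circ_id")
    for cid, rl in rcms.items():
        circ = circs.loc[cid]
        top = [r for r in rl if r.is_top][0]
        if circ["strand"] == "+":
            g_up = (circ["up_intron_start"] + top.up_start,
                    circ["up_intron_start"] + top.up_end)
            g_dn = (circ["down_intron_start"] + top.down_start,
                    circ["down_intron_start"] + top.down_end)
        else:
            g_up = (circ["up_intron_end"] - top.up_end,
                    circ["up_intron_end"] - top.up_start)
            g_dn = (circ["down_intron_end"] - top.down_end,
                    circ["down_intron_end"] - top.down_start)
        assert g_up == (circ["up_arm_start"], circ["up_arm_end"]), cid
        assert g_dn == (circ["down_arm_start"], circ["down_arm_end"]), cid


class TestEligibility:
    def _bundle_with_intron_lengths(self, up_len, down_len):
        circs = pd.DataFrame([{
            "circ_id": "c1", "gene_id": "g1", "chrom": "chr1", "start": 5000,
            "end": 6000, "strand": "+",
            "up_intron_start": 5000 - up_len, "up_intron_end": 4999,
            "down_intron_start": 6001, "down_intron_end": 6000 + down_len,
            "up_arm_start": 0, "up_arm_end": 0, "down_arm_start": 0,
            "down_arm_end": 0}])
        import arcirc.genome as g

        return g.GenomeBundle(seqs={}, genes=pd.DataFrame(), exons=pd.DataFrame(),
                              introns=pd.DataFrame(), circs=circs)

    def test_short_intron_excluded_at_1499(self):
        b = self._bundle_with_intron_lengths(1499, 3000)
        from arcirc.rcm import RCM

        rcms = {"c1": [RCM(0, 10, 0, 10, 11, is_top=True)]}
        out = eligible_circs(b, rcms)
        assert not out.iloc[0]["eligible"]
        assert "1500" in out.iloc[0]["reason"]

    def test_boundary_1500_is_eligible(self):
        b = self._bundle_with_intron_lengths(1500, 1500)
        from arcirc.rcm import RCM

        rcms = {"c1": [RCM(0, 10, 0, 10, 11, is_top=True)]}
        assert eligible_circs(b, rcms).iloc[0]["eligible"]

    def test_no_rcm_above_threshold_excluded(self):
        b = self._bundle_with_intron_lengths(2000, 2000)
        out = eligible_circs(b, {"c1": []})
        assert not out.iloc[0]["eligible"]
        assert "no RCM" in out.iloc[0]["reason"]


class TestProfiles:
    def test_single_arm_covers_exactly_its_positions(self, bundle):
        from arcirc.rcm import RCM

        circ = bundle.circs.iloc[0]
        up_len = int(circ["up_intron_end"] - circ["up_intron_start"] + 1)
        # up arm occupying BSJ offsets -120..-21, down arm +31..+80
        rcm = RCM(up_start=up_len - 120, up_end=up_len - 21,
                  down_start=30, down_end=79, score=100, is_top=True)
        cov = rcm_coverage_profile(bundle, {circ["circ_id"]: [rcm]})
        assert (cov.loc[-120:-21] == 1).all()
        assert (cov.loc[31:80] == 1).all()
        assert cov.sum() == 150

    def test_total_mass_equals_clipped_arm_lengths(self, bundle):
        rcms = scan_circs(bundle)
        cov = rcm_coverage_profile(bundle, rcms)
        expect = sum(
            (r.up_end - r.up_start + 1) + (r.down_end - r.down_start + 1)
            for rl in rcms.values() for r in rl if r.is_top)
        assert cov.sum() == expect

    def test_planted_arm_coverage_concentrates_near_bsj(self, bundle):
        rcms = scan_circs(bundle)
        cov = rcm_coverage_profile(bundle, rcms)
        proximal = cov.loc[-500:500].sum()
        assert proximal / cov.sum() >= 0.9

    def test_uniform_offsets_give_flat_density(self):
        rng = np.random.default_rng(0)
        offs = rng.integers(-1500, 1501, size=20000)
        offs = offs[offs != 0]
        df = pd.DataFrame({"circ_id": "c", "chrom": "chr1", "pos": 1,
                           "offset": offs})
        dens = editing_density_profile(df)
        assert dens["density"].sum() * 50 == pytest.approx(1.0, abs=1e-9)
        expected = 1.0 / 3000
        assert np.all(np.abs(dens["density"] - expected) < 0.35 * expected)

    def test_point_mass_gives_single_bin_spike(self):
        df = pd.DataFrame({"circ_id": "c", "chrom": "chr1", "pos": 1,
                           "offset": [-75] * 10})
        dens = editing_density_profile(df)
        hot = dens[dens["count"] > 0]
        assert len(hot) == 1 and hot.iloc[0]["density"] == pytest.approx(1 / 50)

    def test_empty_offsets_flagged(self):
        with pytest.raises(ValueError, match="empty density"):
            editing_density_profile(pd.DataFrame(columns=["offset"]))

    def test_site_offsets_respect_strand(self, bundle, evidence_and_truth):
        _, truth = evidence_and_truth
        sites = truth[truth["is_true"]][["chrom", "pos", "strand", "circ_id"]]
        offs = site_bsj_offsets(bundle, sites)
        assert len(offs) == len(sites)
        merged = offs.merge(sites, on=["chrom", "pos"])
        assert (merged["circ_id_x"] == merged["circ_id_y"]).all()
        assert merged["offset"].between(-1500, 1500).all()
        assert (merged["offset"] != 0).all()
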