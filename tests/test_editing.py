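"""Editing-site candidate calling, filter cascade and summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from arcirc import (GenomeBundle, annotate_flags, call_candidates, context_ppm,
                    filter_cascade, high_confidence, mismatch_spectrum,
                    summarize_sites)
from arcirc.editing import FLAG_NAMES, run_length_at


def evidence_row(chrom="chr1", pos=50, strand="+", ref="A", sample="OE",
                 cov=10, alt_G=0, alt_C=0, alt_T=0, alt_A=0, first6=0):
    return {"chrom": chrom, "pos": pos, "strand": strand, "ref": ref,
            "sample": sample, "cov": cov, "alt_A": alt_A, "alt_C": alt_C,
            "alt_G": alt_G, "alt_T": alt_T, "alt_first6": first6}


def toy_bundle(seq: str, strand="+", alu=(), simple=()):
    """Single-gene genome: one exon [11,20], intron [21, L-30], exon to end."""
    L = len(seq)
    genes = pd.DataFrame([{"gene_id": "g1", "chrom": "chr1", "strand": strand,
                           "start": 11, "end": L - 10}])
    exons = pd.DataFrame([
        {"chrom": "chr1", "start": 11, "end": 20, "name": "e1", "strand": strand},
        {"chrom": "chr1", "start": L - 29, "end": L - 10, "name": "e2",
         "strand": strand}])
    introns = pd.DataFrame([{"chrom": "chr1", "start": 21, "end": L - 30,
                             "name": "i1", "strand": strand}])
    tracks = {
        "alu": pd.DataFrame([{"chrom": "chr1", "start": s, "end": e,
                              "name": "alu", "strand": strand} for s, e in alu],
                            columns=["chrom", "start", "end", "name", "strand"]),
        "simple_repeat": pd.DataFrame(
            [{"chrom": "chr1", "start": s, "end": e, "name": "rep",
              "strand": strand} for s, e in simple],
            columns=["chrom", "start", "end", "name", "strand"]),
    }
    return GenomeBundle(seqs={"chr1": seq}, genes=genes, exons=exons,
                        introns=introns,
                        circs=pd.DataFrame(columns=["circ_id"]), tracks=tracks)


class TestCandidates:
    def test_single_read_support_is_not_a_candidate(self):
        ev = pd.DataFrame([evidence_row(alt_G=1)])
        assert call_candidates(ev).empty

    def test_two_reads_make_a_candidate_with_level(self):
        ev = pd.DataFrame([evidence_row(alt_G=2, cov=10)])
        cand = call_candidates(ev)
        assert len(cand) == 1
        assert cand.iloc[0]["level"] == pytest.approx(0.2)
        assert cand.iloc[0]["ref_gs"] == "A" and cand.iloc[0]["alt_gs"] == "G"

    def test_minus_strand_candidates_report_gene_strand_bases(self):
        ev = pd.DataFrame([evidence_row(ref="T", strand="-", alt_C=3)])
        cand = call_candidates(ev)
        assert cand.iloc[0]["ref_gs"] == "A" and cand.iloc[0]["alt_gs"] == "G"

    def test_alt_exceeding_coverage_is_a_data_error(self):
        ev = pd.DataFrame([evidence_row(alt_G=11, cov=10)])
        with pytest.raises(ValueError, match="exceeds coverage"):
            call_candidates(ev)


class TestFlags:
    def test_homopolymer_run_detected_at_center(self):
        seq = "C" * 30 + "AAAAA" + "C" * 45
        b = toy_bundle(seq)
        flags = annotate_flags(b, pd.DataFrame([{"chrom": "chr1", "pos": 33}]))
        assert flags.iloc[0]["homopolymer"]
        assert run_length_at(seq, 33) == 5

    def test_splice_proximity_is_strictly_within_four_bases(self):
        seq = "ACGT" * 30
        b = toy_bundle(seq)
        flags = annotate_flags(
            b, pd.DataFrame([{"chrom": "chr1", "pos": 24},   # 4th intron base
                             {"chrom": "chr1", "pos": 25}]))  # 5th intron base
        by_pos = flags.set_index("pos")
        assert by_pos.at[24, "near_splice_intronic"]
        assert not by_pos.at[25, "near_splice_intronic"]

    def test_non_unique_flag_agrees_with_brute_force_kmer_count(self):
        rng = np.random.default_rng(0)
        core = "".join(rng.choice(list("ACGT"), 200))
        dup = core[40:100]  # 60-mer duplicated elsewhere
        seq = core + "GTCA" * 5 + dup + "".join(rng.choice(list("ACGT"), 60))
        b = toy_bundle(seq)
        sites = pd.DataFrame([{"chrom": "chr1", "pos": p} for p in (71, 150)])
        flags = annotate_flags(b, sites).set_index("pos")
        for pos in (71, 150):
            w = seq[pos - 25 : pos + 25]
            from arcirc.genome import revcomp
            brute = sum(seq[i : i + 50] in (w, revcomp(w))
                        for i in range(len(seq) - 49))
            assert flags.at[pos, "non_unique"] == (brute > 1)
        assert flags.at[71, "non_unique"]  # inside the duplicated segment

    def test_site_outside_genome_is_an_error(self):
        b = toy_bundle("ACGT" * 30)
        with pytest.raises(ValueError, match="outside genome"):
            annotate_flags(b, pd.DataFrame([{"chrom": "chr1", "pos": 1000}]))


class TestCascade:
    def _flags(self, pos=50, **overrides):
        base = {name: False for name in FLAG_NAMES}
        base.update(overrides)
        return pd.DataFrame([{"chrom": "chr1", "pos": pos, **base}])

    def _cand(self, **kw):
        return call_candidates(pd.DataFrame([evidence_row(**kw)]))

    def test_snp_position_removed_at_snp_step(self):
        cand = self._cand(alt_G=5)
        snps = pd.DataFrame([{"chrom": "chr1", "pos": 50, "ref": "A", "alt": "G"}])
        sites, audit = filter_cascade(cand, snps, self._flags())
        assert sites.empty
        audit = audit.set_index("step")["n_sites"]
        assert audit["candidates"] == 1 and audit["snp_removed"] == 0

    def test_first6_only_support_removed(self):
        cand = self._cand(alt_G=3, first6=2)  # 3 - 2 < 2
        sites, _ = filter_cascade(cand, pd.DataFrame(columns=["chrom", "pos"]),
                                  self._flags())
        assert sites.empty

    def test_alu_site_in_homopolymer_is_retained(self):
        cand = self._cand(alt_G=5)
        flags = self._flags(in_alu=True, homopolymer=True)
        sites, _ = filter_cascade(cand, pd.DataFrame(columns=["chrom", "pos"]), flags)
        assert len(sites) == 1

    def test_non_alu_regional_flags_remove_site(self):
        for flag in ("near_splice_intronic", "homopolymer", "simple_repeat",
                     "non_unique"):
            sites, _ = filter_cascade(self._cand(alt_G=5),
                                      pd.DataFrame(columns=["chrom", "pos"]),
                                      self._flags(**{flag: True}))
            assert sites.empty, flag

    def test_only_gene_strand_a_to_g_kept(self):
        cand = self._cand(alt_T=5)  # A>T on gene strand
        sites, _ = filter_cascade(cand, pd.DataFrame(columns=["chrom", "pos"]),
                                  self._flags())
        assert sites.empty

    def test_missing_flag_is_an_error(self):
        cand = self._cand(alt_G=5)
        bad = self._flags().drop(columns=["homopolymer"])
        with pytest.raises(ValueError, match="homopolymer"):
            filter_cascade(cand, pd.DataFrame(columns=["chrom", "pos"]), bad)

    def test_cascade_equals_conjunction_of_filters(self, bundle, clean_cfg,
                                                   evidence_and_truth):
        evidence, _ = evidence_and_truth
        cand = call_candidates(evidence)
        flags = annotate_flags(bundle, cand)
        sites, _ = filter_cascade(cand, bundle.snps, flags)
        got = set(zip(sites["chrom"], sites["pos"]))
        # independent conjunction over per-site predicates
        merged = cand.merge(flags, on=["chrom", "pos"])
        snp_pos = set(zip(bundle.snps["chrom"], bundle.snps["pos"]))
        expect = set()
        for r in merged.itertuples():
            if (r.chrom, r.pos) in snp_pos:
                continue
            if r.n_alt - r.alt_first6 < 2:
                continue
            if not r.in_alu and (r.near_splice_intronic or r.homopolymer
                                 or r.simple_repeat or r.non_unique):
                continue
            if r.ref_gs != "A" or r.alt_gs != "G":
                continue
            expect.add((r.chrom, r.pos))
        assert got == expect


class TestHighConfidence:
    def _sites(self, cov_ev, cov_oe, lev_ev, lev_oe):
        return pd.DataFrame([{"chrom": "chr1", "pos": 50, "strand": "+",
                              "cov_EV": cov_ev, "cov_OE": cov_oe,
                              "level_EV": lev_ev, "level_OE": lev_oe}])

    @pytest.mark.parametrize("cov_ev,cov_oe,lev_ev,lev_oe,kept", [
        (50, 50, 0.05, 0.25, True),    # delta 0.20, covered
        (50, 50, 0.20, 0.28, False),   # delta 0.08
        (9, 9, 0.05, 0.50, False),     # never >= 10 reads
        (9, 10, 0.05, 0.25, True),     # one sample reaches 10
        (50, 50, 0.05, 0.15, False),   # delta exactly 0.10 is not > 10%
    ])
    def test_coverage_and_delta_rules(self, cov_ev, cov_oe, lev_ev, lev_oe, kept):
        out = high_confidence(self._sites(cov_ev, cov_oe, lev_ev, lev_oe))
        assert (len(out) == 1) is kept


class TestSpectrum:
    def test_pure_a_to_g_candidates(self):
        cand = call_candidates(pd.DataFrame([evidence_row(alt_G=5)]))
        spec = mismatch_spectrum(cand)
        assert spec["A>G"] == 1.0 and spec.sum() == pytest.approx(1.0)

    def test_planted_mix_recovered_within_three_se(self):
        rng = np.random.default_rng(11)
        n = 2000
        rows = []
        for i in range(n):
            a2g = rng.random() < 0.9
            rows.append(evidence_row(pos=i + 1, alt_G=3) if a2g
                        else evidence_row(pos=i + 1, alt_C=3))
        spec = mismatch_spectrum(call_candidates(pd.DataFrame(rows)))
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(spec["A>G"] - 0.9) < 3 * se
        assert spec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_candidates_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            mismatch_spectrum(pd.DataFrame(columns=["ref_gs", "alt_gs"]))


class TestContextPPM:
    def test_single_site_context_is_deterministic(self):
        seq = "C" * 47 + "TAGCA" + "C" * 48  # site at pos 50, context TAGCA
        b = toy_bundle(seq)
        sites = pd.DataFrame([{"chrom": "chr1", "pos": 50, "strand": "+"}])
        ppm = context_ppm(sites, b)
        for off, base in zip(range(-2, 3), "TAGCA"):
            assert ppm.at[base, off] == 1.0
        assert np.allclose(ppm.sum(axis=0), 1.0)

    def test_minus_strand_context_is_reverse_complemented(self):
        seq = "C" * 47 + "TGCTA" + "C" * 48  # revcomp = TAGCA; site pos 50 = T
        b = toy_bundle(seq, strand="-")
        sites = pd.DataFrame([{"chrom": "chr1", "pos": 50, "strand": "-"}])
        ppm = context_ppm(sites, b)
        for off, base in zip(range(-2, 3), "TAGCA"):
            assert ppm.at[base, off] == 1.0

    def test_planted_neighbor_asymmetry_is_reproduced(self):
        # 5' G depleted, 3' G enriched around the edited A
        rng = np.random.default_rng(5)
        rows, chunks = [], []
        for i in range(300):
            five = rng.choice(list("ACT"))  # no G at -1
            three = "G" if rng.random() < 0.8 else rng.choice(list("ACT"))
            chunks.append(f"{rng.choice(list('ACGT'))}{five}A{three}{rng.choice(list('ACGT'))}")
            rows.append({"chrom": "chr1", "pos": 5 * i + 3, "strand": "+"})
        b = toy_bundle("".join(chunks) + "C" * 40)
        ppm = context_ppm(pd.DataFrame(rows), b)
        assert ppm.at["G", -1] == 0.0
        assert ppm.at["G", 1] > 0.6
        assert ppm.at["A", 0] == 1.0


def test_summarize_sites_reports_per_sample_levels(bundle, evidence_and_truth):
    evidence, truth = evidence_and_truth
    cand = call_candidates(evidence)
    flags = annotate_flags(bundle, cand)
    sites, _ = filter_cascade(cand, bundle.snps, flags)
    summary = summarize_sites(sites, evidence)
    levels = truth.set_index(["chrom", "pos"])
    for r in summary.itertuples():
        want = levels.loc[(r.chrom, r.pos)]
        assert r.level_OE == pytest.approx(want["level_oe"], abs=0.02)
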