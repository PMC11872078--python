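import math

import numpy as np
import pandas as pd
import pytest

from ampedit.alignment import revcomp
from ampedit.synthetic_reads import (
    IndelClass,
    SimConfig,
    SimConfigError,
    apply_read_errors,
    sample_nhej_indel,
    simulate_cdna_reads,
    simulate_gdna_reads,
)

NOERR = dict(sub_rate=0.0, del_rate=0.0, ins_rate=0.0, strand_flip_prob=0.0)


class TestSimConfig:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(SimConfigError, match="sum"):
            SimConfig(n_reads=10, mixture={"WT_unedited": 0.6, "MUT_unedited": 0.6})

    def test_rates_bounded(self):
        with pytest.raises(SimConfigError):
            SimConfig(n_reads=10, mixture={"WT_unedited": 1.0}, sub_rate=1.5)

    def test_n_reads_positive(self):
        with pytest.raises(SimConfigError):
            SimConfig(n_reads=0, mixture={"WT_unedited": 1.0})

    def test_tract_coverage_prob(self):
        cfg = SimConfig(n_reads=1, mixture={"WT_unedited": 1.0}, tract_decay=10.0)
        assert cfg.tract_coverage_prob(0) == 1.0
        assert cfg.tract_coverage_prob(1) == pytest.approx(0.9)
        assert cfg.tract_coverage_prob(2) == pytest.approx(0.81)


class TestGdnaSimulation:
    def test_zero_error_reads_are_exact_allele_copies(self, het_locus, het_alleles):
        locus, _, _ = het_locus
        cfg = SimConfig(
            n_reads=1000,
            mixture={"WT_unedited": 0.5, "MUT_unedited": 0.5},
            seed=42,
            **NOERR,
        )
        reads, truth = simulate_gdna_reads(het_alleles, locus, cfg)
        assert len(reads) == 1000
        marker = locus.marker_snp
        mk_wt = het_alleles.marker_pos_per_allele["WT"]
        mk_mut = het_alleles.marker_pos_per_allele["MUT"]
        wt_read = (
            het_alleles.wt_seq[:mk_wt]
            + marker.base_on_wt_allele
            + het_alleles.wt_seq[mk_wt + 1 :]
        )
        mut_read = (
            het_alleles.mut_seq[:mk_mut]
            + marker.base_on_mut_allele
            + het_alleles.mut_seq[mk_mut + 1 :]
        )
        for r, src in zip(reads, truth["source_allele"]):
            assert r.seq == (wt_read if src == "WT_unedited" else mut_read)
        # multinomial draw: counts near 500/500
        n_wt = (truth["source_allele"] == "WT_unedited").sum()
        assert abs(n_wt - 500) < 4 * math.sqrt(1000 * 0.25)

    def test_determinism_under_seed(self, het_locus, het_alleles):
        locus, _, _ = het_locus
        cfg = SimConfig(
            n_reads=300,
            mixture={"WT_unedited": 0.3, "HDR_perfect": 0.4, "MUT_NHEJ": 0.3},
            seed=7,
        )
        r1, t1 = simulate_gdna_reads(het_alleles, locus, cfg)
        r2, t2 = simulate_gdna_reads(het_alleles, locus, cfg)
        assert [x.seq for x in r1] == [x.seq for x in r2]
        pd.testing.assert_frame_equal(t1, t2)

    def test_mean_error_count_matches_rate(self, het_locus, het_alleles):
        locus, _, _ = het_locus
        cfg = SimConfig(
            n_reads=2000,
            mixture={"WT_unedited": 1.0},
            sub_rate=0.01,
            del_rate=0.0,
            ins_rate=0.0,
            strand_flip_prob=0.0,
            seed=3,
        )
        reads, truth = simulate_gdna_reads(het_alleles, locus, cfg)
        L = len(het_alleles.wt_seq)
        mean = truth["n_errors"].mean()
        sigma = math.sqrt(L * 0.01 * 0.99 / 2000)
        assert abs(mean - L * 0.01) < 4 * sigma
        # n_errors equals the true Hamming-style count for pure substitutions
        mk = het_alleles.marker_pos_per_allele["WT"]
        base = list(het_alleles.wt_seq)
        base[mk] = locus.marker_snp.base_on_wt_allele
        base = "".join(base)
        for r, n in zip(reads[:100], truth["n_errors"][:100]):
            observed = sum(1 for a, b in zip(r.seq, base) if a != b)
            assert observed == n

    def test_truth_category_frequencies_converge(self, het_locus, het_alleles):
        locus, _, _ = het_locus
        mixture = {
            "WT_unedited": 0.3,
            "MUT_unedited": 0.2,
            "WT_NHEJ": 0.1,
            "MUT_NHEJ": 0.1,
            "HDR_perfect": 0.2,
            "HDR_partial": 0.1,
        }
        n = 5000
        cfg = SimConfig(n_reads=n, mixture=mixture, seed=11)
        _, truth = simulate_gdna_reads(het_alleles, locus, cfg)
        freqs = truth["source_allele"].value_counts(normalize=True)
        for cat, p in mixture.items():
            sigma = math.sqrt(p * (1 - p) / n)
            assert abs(freqs[cat] - p) < 3 * sigma, cat

    def test_strand_flip(self, het_locus, het_alleles):
        locus, _, _ = het_locus
        cfg = SimConfig(
            n_reads=200,
            mixture={"WT_unedited": 1.0},
            sub_rate=0.0,
            del_rate=0.0,
            ins_rate=0.0,
            strand_flip_prob=1.0,
            seed=5,
        )
        reads, _ = simulate_gdna_reads(het_alleles, locus, cfg)
        mk = het_alleles.marker_pos_per_allele["WT"]
        base = list(het_alleles.wt_seq)
        base[mk] = locus.marker_snp.base_on_wt_allele
        expected = revcomp("".join(base))
        assert all(r.seq == expected for r in reads)

    def test_hdr_with_empty_template_rejected(self, het_locus):
        from ampedit.locus_model import HdrTemplateSpec, build_allele_set

        locus, mut, _ = het_locus
        bare = build_allele_set(locus, mut, HdrTemplateSpec(correction=mut))
        cfg = SimConfig(n_reads=10, mixture={"HDR_perfect": 1.0})
        with pytest.raises(SimConfigError, match="programmed SNPs"):
            simulate_gdna_reads(bare, locus, cfg)

    def test_tract_conversion_monotone_with_distance(self, het_locus, het_alleles):
        locus, _, _ = het_locus
        n = 10000
        cfg = SimConfig(
            n_reads=n, mixture={"HDR_partial": 1.0}, tract_decay=15.0, seed=9, **NOERR
        )
        _, truth = simulate_gdna_reads(het_alleles, locus, cfg)
        conv = np.array([[int(c) for c in v] for v in truth["converted_snps"]])
        rate = conv.mean(axis=0)
        cut = het_alleles.cut_sites_per_allele["WT"][0]
        dists = [
            (cut - p) if p < cut else (p - cut + 1) for p in het_alleles.snp_positions
        ]
        order = np.argsort(dists)
        sorted_rates = rate[order]
        # monotone non-increasing with distance (allow 3 sigma sampling noise)
        for a, b in zip(sorted_rates, sorted_rates[1:]):
            assert b <= a + 3 * math.sqrt(0.25 / n)
        # and within 3 sigma of the analytic geometric coverage probability
        for i, d in enumerate(dists):
            p = cfg.tract_coverage_prob(d)
            sigma = math.sqrt(p * (1 - p) / n)
            assert abs(rate[i] - p) < 3 * sigma, (d, rate[i], p)

    def test_large_deletion_reads(self, nickase_locus, nickase_alleles):
        locus, _, _ = nickase_locus
        cfg = SimConfig(
            n_reads=50, mixture={"large_deletion": 1.0}, large_del_size=350,
            seed=2, **NOERR,
        )
        reads, truth = simulate_gdna_reads(nickase_alleles, locus, cfg)
        for r, src_len in zip(reads, truth["indel_size"]):
            assert src_len == 350
        lengths = {len(r.seq) for r in reads}
        assert lengths == {600 - 350, 600 - 11 - 350}

    def test_large_deletion_too_big_rejected(self, het_locus, het_alleles):
        locus, _, _ = het_locus
        cfg = SimConfig(
            n_reads=10, mixture={"large_deletion": 1.0}, large_del_size=350
        )
        with pytest.raises(SimConfigError, match="amplicon"):
            simulate_gdna_reads(het_alleles, locus, cfg)


class TestNhejSpectrum:
    def test_degenerate_single_entry_spectrum(self, het_locus, het_alleles):
        locus, _, _ = het_locus
        spectrum = (IndelClass("ins", 1, 1, 1.0, seq="T"),)
        cfg = SimConfig(
            n_reads=100,
            mixture={"WT_NHEJ": 1.0},
            nhej_spectrum=spectrum,
            seed=1,
            **NOERR,
        )
        reads, truth = simulate_gdna_reads(het_alleles, locus, cfg)
        cut = het_alleles.cut_sites_per_allele["WT"][0]
        mk = het_alleles.marker_pos_per_allele["WT"]
        base = list(het_alleles.wt_seq)
        base[mk] = locus.marker_snp.base_on_wt_allele
        base = "".join(base)
        expected = base[:cut] + "T" + base[cut:]
        assert all(r.seq == expected for r in reads)
        assert set(truth["indel_type"]) == {"ins"}
        assert set(truth["indel_size"]) == {1}

    def test_class_frequencies_within_3_sigma(self):
        rng = np.random.default_rng(0)
        spectrum = (
            IndelClass("ins", 1, 1, 0.6, seq="T"),
            IndelClass("del", 1, 9, 0.3),
            IndelClass("del", 10, 50, 0.1),
        )
        cfg = SimConfig(
            n_reads=1, mixture={"WT_unedited": 1.0}, nhej_spectrum=spectrum
        )
        n = 10000
        counts = {"ins": 0, "del_small": 0, "del_mid": 0}
        for _ in range(n):
            size, kind, _ = sample_nhej_indel(cfg, rng)
            if kind == "ins":
                counts["ins"] += 1
            elif size <= 9:
                counts["del_small"] += 1
            else:
                counts["del_mid"] += 1
        for key, p in (("ins", 0.6), ("del_small", 0.3), ("del_mid", 0.1)):
            sigma = math.sqrt(p * (1 - p) / n)
            assert abs(counts[key] / n - p) < 3 * sigma

    def test_deletion_shortens_read_by_size(self, het_locus, het_alleles):
        locus, _, _ = het_locus
        spectrum = (IndelClass("del", 7, 7, 1.0),)
        cfg = SimConfig(
            n_reads=20,
            mixture={"WT_NHEJ": 1.0},
            nhej_spectrum=spectrum,
            seed=4,
            **NOERR,
        )
        reads, _ = simulate_gdna_reads(het_alleles, locus, cfg)
        assert all(len(r.seq) == len(het_alleles.wt_seq) - 7 for r in reads)


class TestErrorEngine:
    def test_zero_rates_identity(self):
        cfg = SimConfig(n_reads=1, mixture={"WT_unedited": 1.0}, **NOERR)
        rng = np.random.default_rng(0)
        seq = "ACGT" * 50
        out, n = apply_read_errors(seq, cfg, rng)
        assert out == seq and n == 0

    def test_deletion_only(self):
        cfg = SimConfig(
            n_reads=1,
            mixture={"WT_unedited": 1.0},
            sub_rate=0.0,
            del_rate=0.05,
            ins_rate=0.0,
        )
        rng = np.random.default_rng(1)
        seq = "ACGT" * 250
        out, n = apply_read_errors(seq, cfg, rng)
        assert len(out) == len(seq) - n

    def test_insertion_only(self):
        cfg = SimConfig(
            n_reads=1,
            mixture={"WT_unedited": 1.0},
            sub_rate=0.0,
            del_rate=0.0,
            ins_rate=0.05,
        )
        rng = np.random.default_rng(1)
        seq = "ACGT" * 250
        out, n = apply_read_errors(seq, cfg, rng)
        assert len(out) == len(seq) + n


class TestCdnaSimulation:
    def test_pure_full_length_zero_error(self, transcript_setup):
        _, _, _, _, model = transcript_setup
        cfg = SimConfig(n_reads=50, mixture={"WT_unedited": 1.0}, seed=1, **NOERR)
        reads, truth = simulate_cdna_reads(model, {"full_length|WT": 1.0}, cfg)
        ref = model.references["full_length|WT"]
        assert all(r.seq == ref for r in reads)
        assert set(truth["isoform"]) == {"full_length"}

    def test_mixture_within_3_sigma(self, transcript_setup):
        _, _, _, _, model = transcript_setup
        n = 5000
        cfg = SimConfig(n_reads=n, mixture={"WT_unedited": 1.0}, seed=8)
        mixture = {"exon_skipped|na": 0.4, "full_length|HDR": 0.6}
        _, truth = simulate_cdna_reads(model, mixture, cfg)
        frac_skip = (truth["isoform"] == "exon_skipped").mean()
        sigma = math.sqrt(0.4 * 0.6 / n)
        assert abs(frac_skip - 0.4) < 3 * sigma

    def test_aberrant_reads_120nt_shorter(self, transcript_setup):
        _, _, _, _, model = transcript_setup
        cfg = SimConfig(n_reads=20, mixture={"WT_unedited": 1.0}, seed=2, **NOERR)
        full, _ = simulate_cdna_reads(model, {"full_length|WT": 1.0}, cfg)
        aberr, _ = simulate_cdna_reads(model, {"aberrant_acceptor|WT": 1.0}, cfg)
        assert len(full[0].seq) - len(aberr[0].seq) == 120

    def test_unknown_label_rejected(self, transcript_setup):
        _, _, _, _, model = transcript_setup
        cfg = SimConfig(n_reads=5, mixture={"WT_unedited": 1.0})
        with pytest.raises(SimConfigError, match="not in the transcript model"):
            simulate_cdna_reads(model, {"nope": 1.0}, cfg)
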