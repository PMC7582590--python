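"""Generator contracts: determinism, planted-structure fidelity, NB moments."""

import numpy as np
import pandas as pd
import pytest

from ribopulse import simulate
from ribopulse.simulate import (SimTruth, Transcript, make_transcriptome,
                                plant_mirna_targets, plant_modes,
                                random_baseline, seed_site, simulate_counts,
                                simulate_rpf_reads, simulate_tsrna_reads)


class TestTranscriptome:
    def test_cds_invariants_hold_for_every_gene(self):
        for t in make_transcriptome(30, cds_codons=(10, 40), seed=1):
            assert t.cds.startswith("ATG")
            assert t.cds[-3:] in simulate.STOP_CODONS
            assert len(t.cds) % 3 == 0
            internal = [t.cds[i:i + 3] for i in range(3, len(t.cds) - 3, 3)]
            assert not set(internal) & set(simulate.STOP_CODONS)

    def test_deterministic_given_seed(self):
        a = make_transcriptome(50, seed=7)
        b = make_transcriptome(50, seed=7)
        assert all(x.seq == y.seq for x, y in zip(a, b))
        c = make_transcriptome(50, seed=8)
        assert any(x.seq != y.seq for x, y in zip(a, c))

    @pytest.mark.parametrize("target", [0.3, 0.5, 0.7])
    def test_realized_gc_tracks_target(self, target):
        ts = make_transcriptome(5, utr3_length=(1000, 1000),
                                gc={"utr5": 0.5, "cds": 0.5, "utr3": target},
                                seed=3)
        for t in ts:
            gc = (t.utr3.count("G") + t.utr3.count("C")) / len(t.utr3)
            assert abs(gc - target) <= 0.1

    def test_invalid_gc_target_rejected(self):
        with pytest.raises(ValueError, match="GC target"):
            make_transcriptome(2, gc={"utr5": 0.9, "cds": 0.5, "utr3": 0.5})

    def test_invalid_lengths_rejected(self):
        with pytest.raises(ValueError, match="length range"):
            make_transcriptome(2, utr5_length=(10, 5))


class TestModes:
    def test_pure_stable_means_zero_fold_changes(self):
        m = plant_modes([f"g{i}" for i in range(20)], {"stable": 1.0})
        assert (m["mrna_log2fc"] == 0).all() and (m["rpf_log2fc"] == 0).all()

    def test_transcriptional_map_is_forced(self):
        m = plant_modes([f"g{i}" for i in range(50)],
                        {"transcriptional": 1.0}, effect_size=1.0, seed=2)
        assert (m["mrna_log2fc"].abs() == 1.0).all()
        assert (m["rpf_log2fc"] == 0).all()

    def test_mode_labels_consistent_with_effect_map(self):
        m = plant_modes([f"g{i}" for i in range(500)],
                        simulate.DEFAULT_MODE_MIX_0H, effect_size=0.8, seed=3)
        for _, row in m.iterrows():
            sign = 1 if row["mrna_log2fc"] >= 0 and row["rpf_log2fc"] >= 0 \
                else -1
            got = simulate.mode_effects(row["mode"], sign, 0.8)
            assert {abs(row["mrna_log2fc"]), abs(row["rpf_log2fc"])} == \
                {abs(got[0]), abs(got[1])}

    def test_realized_mix_within_multinomial_band(self):
        n = 2000
        mix = simulate.DEFAULT_MODE_MIX_0H
        m = plant_modes([f"g{i}" for i in range(n)], mix, seed=4)
        for mode, frac in mix.items():
            count = (m["mode"] == mode).sum()
            sd = np.sqrt(n * frac * (1 - frac))
            assert abs(count - n * frac) < 2.6 * sd  # ~99% multinomial band

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError, match="negative fraction"):
            plant_modes(["a"], {"stable": 1.2, "transcriptional": -0.2})


class TestCounts:
    @pytest.mark.parametrize("phi,band", [(0.0, (0.99, 1.01)),
                                          (0.1, (1045, 1155))])
    def test_nb_moment_identity(self, phi, band):
        # var = mean + phi * mean^2; at mean 100 that is 100 (Poisson)
        # or 1100; 1e6 draws pin the ratio/variance inside the band
        rng = np.random.default_rng(5)
        draws = simulate._draw_nb(rng, np.full(10 ** 6, 100.0),
                                  np.full(10 ** 6, phi))
        if phi == 0:
            assert band[0] < draws.var() / draws.mean() < band[1]
        else:
            assert band[0] < draws.var() < band[1]

    def test_same_seed_identical_matrices(self):
        genes = [f"g{i}" for i in range(30)]
        truth = SimTruth(genes=genes, baseline=random_baseline(genes),
                         modes={"0h": plant_modes(genes, {"stable": 1.0})})
        a = simulate_counts(truth, seed=9)["mRNA"].counts
        b = simulate_counts(truth, seed=9)["mRNA"].counts
        assert a.equals(b)


class TestRpfReads:
    def test_full_fidelity_keeps_all_psites_in_frame_zero(
            self, small_transcriptome):
        reads = simulate_rpf_reads(small_transcriptome, None,
                                   frame_fidelity=1.0, leakage=0.0,
                                   n_reads=2000, seed=1)
        starts = {t.gene_id: t.cds_start for t in small_transcriptome}
        psite = reads["pos5"] + 12
        frames = (psite - reads["gene_id"].map(starts)) % 3
        assert (frames == 0).all()

    def test_frame_fractions_match_uniform_fidelity(self, small_transcriptome):
        reads = simulate_rpf_reads(small_transcriptome, None,
                                   frame_fidelity=1 / 3, leakage=0.0,
                                   n_reads=100_000, seed=2)
        starts = {t.gene_id: t.cds_start for t in small_transcriptome}
        frames = (reads["pos5"] + 12 - reads["gene_id"].map(starts)) % 3
        fracs = frames.value_counts(normalize=True)
        # frame 0 gets f = 1/3, frames 1-2 split (1-f)/2 = 1/3 each
        assert np.allclose(fracs.sort_index(), 1 / 3, atol=0.02)

    def test_zero_leakage_keeps_psites_in_cds(self, small_transcriptome):
        reads = simulate_rpf_reads(small_transcriptome, None, leakage=0.0,
                                   n_reads=5000, seed=3)
        bounds = {t.gene_id: (t.cds_start, t.cds_end)
                  for t in small_transcriptome}
        psite = reads["pos5"] + 12
        lo = reads["gene_id"].map(lambda g: bounds[g][0])
        hi = reads["gene_id"].map(lambda g: bounds[g][1])
        assert ((psite >= lo) & (psite < hi)).all()

    def test_reads_stay_inside_transcripts(self, small_transcriptome):
        reads = simulate_rpf_reads(small_transcriptome, None, n_reads=5000,
                                   seed=4)
        length = {t.gene_id: t.length for t in small_transcriptome}
        assert (reads["pos5"] >= 0).all()
        assert (reads["pos5"] + reads["length"]
                <= reads["gene_id"].map(length)).all()

    def test_offset_larger_than_read_length_rejected(self,
                                                     small_transcriptome):
        with pytest.raises(ValueError, match="offset"):
            simulate_rpf_reads(small_transcriptome, None, offset=40,
                               n_reads=10)


class TestMirnaPlanting:
    def test_planted_site_sequence_is_seed_reverse_complement(self):
        # RNA seed AACCGGU (nt 2-8) plants DNA site ACCGGTT
        assert seed_site("AAACCGGUUUUUUUUUUUUUUU") == "ACCGGTT"

    def test_recount_covers_planted_sites(self):
        ts = make_transcriptome(40, utr3_length=(300, 400), seed=6)
        mirnas = simulate.random_mirnas(4, seed=7)
        planted_ts, planted, recount = plant_mirna_targets(
            ts, mirnas, site_count_probs=(0.2, 0.3, 0.3, 0.2), seed=8)
        assert (recount.to_numpy() >= planted.to_numpy()).all()
        assert planted.to_numpy().sum() > 0

    def test_zero_site_probability_leaves_only_chance_matches(self):
        ts = make_transcriptome(20, seed=9)
        mirnas = simulate.random_mirnas(3, seed=10)
        planted_ts, planted, recount = plant_mirna_targets(
            ts, mirnas, site_count_probs=(1.0,), seed=11)
        assert (planted.to_numpy() == 0).all()
        assert all(a.utr3 == b.utr3 for a, b in zip(ts, planted_ts))


class TestTsrnaReads:
    def test_cut_coordinates_respect_landmarks(self, trna_catalog):
        refs, lm = trna_catalog
        reads = simulate_tsrna_reads(refs, lm, n_reads=800, seed=12)
        for _, r in reads.iterrows():
            row = lm.loc[r["ref_id"]]
            if r["origin"] == "5p_mature":
                assert r["start"] == row["mature_start"]
            elif r["origin"] == "3p_mature":
                assert r["start"] + r["length"] == row["mature_end"]
            elif r["origin"] == "5p_precursor":
                assert r["start"] + r["length"] <= row["leader_len"]
            assert refs[r["ref_id"]][r["start"]:r["start"] + r["length"]] \
                == r["seq"]

    def test_single_origin_cut_plan(self, trna_catalog):
        refs, lm = trna_catalog
        reads = simulate_tsrna_reads(refs, lm, cut_plan={"3p_mature": 1.0},
                                     n_reads=100, seed=13)
        assert (reads["origin"] == "3p_mature").all()

    def test_missing_landmark_errors_with_trna_name(self, trna_catalog):
        refs, lm = trna_catalog
        missing = list(refs)[0]
        with pytest.raises(ValueError, match=missing):
            simulate_tsrna_reads(refs, lm.drop(index=missing), n_reads=10)
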