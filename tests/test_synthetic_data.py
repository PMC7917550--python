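"""Generator contracts: determinism, planted structure, parameter geometry."""

import numpy as np
import pytest
from scipy import stats

from pirnaterm import annotation_io as aio
from pirnaterm import length_analysis as la
from pirnaterm import precursor_quant as pq
from pirnaterm import synthetic_data as sd

SMALL = sd.SimulationConfig(n_loci=100, seed=7, n_background_ctss=200)


class TestSimulateLoci:
    def test_motif_dependent_count_and_motif_planted(self):
        genome, loci = sd.simulate_loci(SMALL)
        md = [l for l in loci if l.motif_class == "motif_dependent"]
        assert len(md) == 80
        for locus in md:
            motif = aio.fetch_sense_window(
                genome, locus, (sd.MOTIF_OFFSET, sd.MOTIF_OFFSET + 5), frame="tss"
            )
            assert motif == sd.MOTIF

    def test_same_seed_reproduces_genome_and_loci(self):
        g1, l1 = sd.simulate_loci(SMALL)
        g2, l2 = sd.simulate_loci(SMALL)
        assert g1 == g2
        assert l1 == l2

    def test_recomputed_scores_match_intended(self):
        genome, loci = sd.simulate_loci(SMALL)
        for locus in loci:
            intended = locus.signal_score
            recomputed = aio.compute_termination_signal(locus, genome, window=sd.SIGNAL_WINDOW)
            assert abs(recomputed - intended) <= 0.02

    def test_scores_span_dynamic_range(self, loci):
        scores = np.array([l.signal_score for l in loci])
        assert scores.min() < 0.3 and scores.max() > 0.9

    def test_too_dense_loci_error(self):
        with pytest.raises(ValueError, match="pitch"):
            sd.simulate_loci(sd.SimulationConfig(n_loci=10, locus_pitch=50, seed=0))


class TestCappedReads:
    def test_strong_signal_with_extreme_coupling_suppresses_pause2(self):
        cfg = sd.SimulationConfig(n_loci=50, seed=3, signal_coupling=-60.0)
        _, loci = sd.simulate_loci(cfg)
        strong = [l for l in loci if l.signal_score >= 0.9]
        assert strong
        reads = sd.simulate_capped_reads(loci, cfg, "wild_type", "chromatin")
        ids = {l.locus_id for l in strong}
        recs = pq.identify_precursors(reads, loci)
        long_reads = sum(r.count for r in recs if r.locus_id in ids and r.length >= 40)
        total = sum(r.count for r in recs if r.locus_id in ids)
        assert long_reads / total < 0.01

    def test_nucleoplasm_mode_at_pause1(self, config, loci, wt_nucleoplasm_records):
        dist = la.length_distribution(wt_nucleoplasm_records, weight_by="reads")
        assert abs(dist.mode - config.peak1_pos) <= 1

    def test_tfiis_chromatin_second_mode_shifts_to_51(self, config, loci):
        reads = sd.simulate_capped_reads(loci, config, "tfiis", "chromatin")
        recs = pq.identify_precursors(reads, loci)
        dist = la.length_distribution(recs, weight_by="reads")
        upper = dist.as_series(normalized=False).loc[40:60]
        assert abs(int(upper.idxmax()) - 51) <= 1

    def test_unknown_compartment_errors(self, config, loci):
        with pytest.raises(ValueError, match="compartment"):
            sd.simulate_capped_reads(loci, config, "wild_type", "cytoplasm")

    def test_pause2_fraction_decreases_with_signal(self, config, loci, wt_chromatin_records):
        per_locus = {}
        for r in wt_chromatin_records:
            tot, lng = per_locus.get(r.locus_id, (0, 0))
            per_locus[r.locus_id] = (tot + r.count, lng + (r.count if r.length >= 40 else 0))
        scores, fracs = [], []
        by_id = {l.locus_id: l for l in loci}
        for lid, (tot, lng) in per_locus.items():
            if tot >= 10:
                scores.append(by_id[lid].signal_score)
                fracs.append(lng / tot)
        rho = stats.spearmanr(scores, fracs).statistic
        assert rho < -0.5


class TestFivePrimeReads:
    def test_fragment_rate_zero_leaves_window_empty(self):
        cfg = sd.SimulationConfig(n_loci=100, seed=7, fragment_rate=0.0)
        _, loci = sd.simulate_loci(cfg)
        reads = sd.simulate_5p_reads(loci, cfg, "wild_type")
        by_id = {l.locus_id: l for l in loci}
        for r in reads:
            for locus in by_id.values():
                off = aio.to_offset(r, locus, "tss")
                if off is not None and 25 <= off[0] < 50:
                    raise AssertionError(f"fragment-like read at offset {off[0]}")

    def test_fragment_five_offset_mode_38(self, config, loci):
        reads = sd.simulate_5p_reads(loci, config, "wild_type")
        window = {}  # (strand, genomic 5' pos) -> tss-frame offset
        for locus in loci:
            step = 1 if locus.strand == "+" else -1
            for off in range(25, 50):
                window[(locus.strand, locus.tss_pos + step * off)] = off
        offs = {}
        for r in reads:
            if r.chrom != sd.MAIN_CONTIG:
                continue
            o = window.get((r.strand, r.five_prime))
            if o is not None:
                offs[o] = offs.get(o, 0) + r.count
        assert sum(offs.values()) >= 5000
        assert abs(max(offs, key=offs.get) - 38) <= 1

    def test_fragment_median_length_20(self, fivep_pipeline):
        frags = fivep_pipeline["fragments"]
        med = la.weighted_median([f.length for f in frags], [f.count for f in frags])
        assert abs(med - 20) <= 1

    def test_mirna_background_present(self, config, loci):
        reads = sd.simulate_5p_reads(loci, config, "wild_type")
        mir = [r for r in reads if r.chrom == sd.MIRNA_CONTIG]
        assert len(mir) == config.mirna_count
        assert all(r.length == 22 for r in mir)


class TestCagePairs:
    def test_readthrough_factor_zero_silences_motif_dependent(self):
        cfg = sd.SimulationConfig(n_loci=100, seed=7, n_background_ctss=0, cage_indep_frac=0.0)
        _, loci = sd.simulate_loci(cfg)
        preset = sd.GenotypePreset("silent", readthrough_factor=0.0)
        assert sd.simulate_cage_pairs(loci, cfg, preset) == []

    def test_rank_frequency_log_log_linear(self, config, loci):
        pairs = sd.simulate_cage_pairs(loci, config, "wild_type")
        from pirnaterm.cage_readthrough import ctss_from_reads

        counts = np.sort(ctss_from_reads(pairs)["count"].to_numpy())[::-1]
        ranks = np.arange(1, counts.size + 1)
        keep = counts >= 2
        r = np.corrcoef(np.log(ranks[keep]), np.log(counts[keep]))[0, 1]
        assert r < -0.9

    def test_same_seed_identical_pairs(self, config, loci):
        p1 = sd.simulate_cage_pairs(loci, config, "wild_type")
        p2 = sd.simulate_cage_pairs(loci, config, "wild_type")
        assert p1 == p2


class TestFixtureSet:
    CFG = sd.SimulationConfig(n_loci=40, seed=11, n_background_ctss=50)

    def test_manifest_lists_all_samples(self, tmp_path):
        manifest = sd.write_fixture_set(tmp_path / "fx", self.CFG)
        assert len(manifest["samples"]) == 2 * 4 * 3
        libs = {s["library"] for s in manifest["samples"]}
        assert libs == {"capped_short", "fivep_small", "cage"}

    def test_replicate_seeds_differ(self, tmp_path):
        manifest = sd.write_fixture_set(tmp_path / "fx", self.CFG)
        for preset in ("wild_type", "tfiis"):
            seeds = {
                s["seed"] for s in manifest["samples"] if s["preset"] == preset
            }
            assert len(seeds) == 2

    def test_rerun_is_byte_identical(self, tmp_path):
        sd.write_fixture_set(tmp_path / "a", self.CFG, presets=("wild_type",))
        sd.write_fixture_set(tmp_path / "b", self.CFG, presets=("wild_type",))
        for name in ("genome.fa", "loci.bed", "wild_type_rep1_capped_chromatin.bed",
                     "wild_type_rep2_5p.bed", "wild_type_rep1_cage.bed"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_nonempty_outdir_requires_force(self, tmp_path):
        out = tmp_path / "fx"
        out.mkdir()
        (out / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            sd.write_fixture_set(out, self.CFG, presets=("wild_type",))
        sd.write_fixture_set(out, self.CFG, presets=("wild_type",), force=True)
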