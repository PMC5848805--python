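"""Tests for the synthetic-data generators and fixture bundle."""

import json

import numpy as np
import pytest
from scipy import stats as sps

from serumcmp import io as pkg_io
from serumcmp.synthetic_data import (
    SimulationConfig,
    simulate_alignments,
    simulate_dhs,
    simulate_expression,
    write_fixture_bundle,
)


class TestConfigValidation:
    def test_bad_dispersion(self):
        with pytest.raises(ValueError):
            SimulationConfig(nb_dispersion=0.0)

    def test_sharing_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                frac_shared_windows=0.5, frac_speciesA_only=0.5, frac_speciesB_only=0.5
            )

    def test_selection_multiplier_below_one_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_selected=0.1, promoter_rate_multiplier=0.5)


class TestSimulateExpression:
    def test_frac_de_zero_means_no_planted_genes(self):
        cfg = SimulationConfig(n_genes=200, frac_de=0.0, seed=1)
        _, truth = simulate_expression(cfg)
        assert truth.genes["is_de"].sum() == 0
        assert (truth.genes["true_log2fc"] == 0).all()

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=150, seed=9)
        cm1, t1 = simulate_expression(cfg)
        cm2, t2 = simulate_expression(SimulationConfig(n_genes=150, seed=9))
        np.testing.assert_array_equal(cm1.counts, cm2.counts)
        assert t1.genes.equals(t2.genes)

    def test_marginal_mean_near_configured(self):
        # grand mean tracks the drawn per-gene baselines (whose own mean is
        # the configured baseline) to within 5% across NB sampling noise
        cfg = SimulationConfig(
            n_genes=3000, frac_de=0.0, frac_csr_up=0.0, frac_csr_down=0.0, seed=2
        )
        cm, truth = simulate_expression(cfg)
        expected = truth.genes["base_mean"].mean()
        assert abs(cm.counts.mean() - expected) / expected < 0.05
        # and the baseline draw itself is centered on the configured value
        assert abs(expected - cfg.baseline_mean) / cfg.baseline_mean < 0.10

    def test_truth_class_proportions_within_binomial_ci(self):
        cfg = SimulationConfig(n_genes=2000, frac_de=0.1, seed=3)
        _, truth = simulate_expression(cfg)
        n_de = truth.genes["is_de"].sum()
        lo, hi = sps.binom.interval(0.99, 2000, 0.1)
        assert lo <= n_de <= hi


class TestSimulateDHS:
    def test_degenerate_single_class(self):
        cfg = SimulationConfig(
            n_windows=80,
            frac_shared_windows=0.0,
            frac_speciesA_only=1.0,
            frac_speciesB_only=0.0,
            seed=4,
        )
        _, _, truth = simulate_dhs(cfg)
        assert set(truth.windows["sharing_class"]) == {"human_specific"}

    def test_jitter_free_single_sample_round_trip(self):
        from serumcmp.dhs_windows import build_windows

        cfg = SimulationConfig(
            n_windows=60,
            jitter_bp=0,
            frac_opening=0.0,
            frac_closing=0.0,
            frac_shared_windows=1.0,
            frac_speciesA_only=0.0,
            frac_speciesB_only=0.0,
            design=[("human", "T0", "H1")],
            seed=5,
        )
        peaks, _, truth = simulate_dhs(cfg)
        wins = build_windows(peaks)
        got = [(w.chrom, w.start, w.end) for w in wins]
        expect = [
            (r.chrom, r.start, r.end) for r in truth.windows.itertuples()
        ]
        assert got == sorted(expect)

    def test_all_peak_scores_at_or_above_threshold(self):
        cfg = SimulationConfig(n_windows=100, seed=6)
        peaks, _, _ = simulate_dhs(cfg)
        assert all(p.score >= cfg.peak_score_threshold for p in peaks)

    def test_placement_error_when_chroms_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_dhs(SimulationConfig(n_windows=5000, chrom_sizes={"chr1": 10000}))

    def test_species_specific_windows_silent_in_other_species(self):
        cfg = SimulationConfig(n_windows=100, seed=7)
        peaks, _, truth = simulate_dhs(cfg)
        human_only = {
            (r.chrom, r.start, r.end)
            for r in truth.windows.itertuples()
            if r.sharing_class == "human_specific"
        }
        for p in peaks:
            if p.sample[0] == "chimpanzee":
                mid = (p.start + p.end) / 2
                for c, s, e in human_only:
                    assert not (p.chrom == c and s - 50 <= mid <= e + 50)


class TestSimulateAlignments:
    def test_zero_rate_identical_taxa(self):
        cfg = SimulationConfig(
            n_alignment_genes=5, neutral_sub_rate=0.0, frac_selected=0.0, seed=8
        )
        aln, _ = simulate_alignments(cfg)
        for regs in aln.values():
            for region in ("promoter", "intron"):
                seqs = set(regs[region].values())
                assert len(seqs) == 1

    def test_selected_genes_have_elevated_promoter_divergence(self):
        from serumcmp.selection import lineage_substitution_counts

        cfg = SimulationConfig(
            n_alignment_genes=40, frac_selected=0.5, promoter_rate_multiplier=5.0, seed=9
        )
        aln, truth = simulate_alignments(cfg)
        sel = truth.promoters.set_index("gene")["promoter_selected"]
        rates = {True: [], False: []}
        for g, regs in aln.items():
            bc = lineage_substitution_counts(
                regs["promoter"]["human"],
                regs["promoter"]["chimpanzee"],
                regs["promoter"]["macaque"],
                g,
                "promoter",
            )
            rates[bool(sel[g])].append(bc.rate)
        assert np.mean(rates[True]) > 3 * np.mean(rates[False])

    def test_determinism(self):
        a1, _ = simulate_alignments(SimulationConfig(n_alignment_genes=4, seed=10))
        a2, _ = simulate_alignments(SimulationConfig(n_alignment_genes=4, seed=10))
        assert a1 == a2


class TestFixtureBundle:
    def test_round_trips_and_manifest(self, tmp_path, small_config):
        manifest = write_fixture_bundle(tmp_path, small_config)
        # every listed file exists and its checksum matches
        import hashlib

        for rel, digest in manifest["files"].items():
            data = (tmp_path / rel).read_bytes()
            assert hashlib.sha256(data).hexdigest() == digest

        cm, _ = simulate_expression(small_config)
        cm_read = pkg_io.parse_counts(tmp_path / "counts.tsv")
        np.testing.assert_array_equal(cm.counts, cm_read.counts)
        assert cm_read.genes == cm.genes and cm_read.samples == cm.samples

        peaks, _, _ = simulate_dhs(small_config)
        sample = sorted({p.sample for p in peaks})[0]
        path = tmp_path / "peaks" / ("_".join(sample) + ".bed")
        got = pkg_io.parse_peaks_bed(path, sample)
        expect = sorted(
            (p for p in peaks if p.sample == sample),
            key=lambda p: (p.chrom, p.start, p.end),
        )
        assert [(p.chrom, p.start, p.end) for p in got] == [
            (p.chrom, p.start, p.end) for p in expect
        ]
        # scores preserved to 4 decimals through BED
        assert all(
            abs(a.score - round(b.score, 4)) < 1e-9 for a, b in zip(got, expect)
        )

    def test_identical_config_identical_bundle(self, tmp_path):
        cfg = SimulationConfig(n_genes=100, n_windows=60, n_alignment_genes=10, seed=12)
        m1 = write_fixture_bundle(tmp_path / "a", cfg)
        m2 = write_fixture_bundle(tmp_path / "b", cfg)
        assert m1["files"] == m2["files"]

    def test_manifest_is_valid_json_listing_all_files(self, tmp_path, small_config):
        write_fixture_bundle(tmp_path, small_config)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        on_disk = {
            str(p.relative_to(tmp_path))
            for p in tmp_path.rglob("*")
            if p.is_file() and p.name != "manifest.json"
        }
        assert set(manifest["files"]) == on_disk
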