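import hashlib

import numpy as np
import pandas as pd
import pytest

from pioneerclass.core import ValidationError, tn5_cut_sites
from pioneerclass.io import read_chrom_sizes, read_fragments, read_peaks
from pioneerclass.profiles import bin_offsets
from pioneerclass.simulate import (
    SimulationConfig,
    dyad_template,
    expected_mnase_profile,
    plant_layout,
    simulate_atac,
    simulate_chip,
    simulate_mnase,
    solve_center_weight,
    write_dataset,
    _template_grid,
)


def truth_hash(layout):
    return hashlib.sha256(
        layout.truth.to_csv(index=False).encode()
    ).hexdigest()


class TestPlantLayout:
    def test_deterministic_for_seed(self, small_config):
        a = plant_layout(small_config)
        b = plant_layout(small_config)
        assert truth_hash(a) == truth_hash(b)
        pd.testing.assert_frame_equal(a.peaks.df, b.peaks.df)

    def test_different_seed_different_layout(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        assert truth_hash(plant_layout(other)) != truth_hash(plant_layout(small_config))

    def test_zero_count_class_absent(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_config, n_peaks_per_class={"G1": 5, "G2": 5, "G3": 5, "G4": 0}
        )
        layout = plant_layout(cfg)
        assert not (layout.truth["class"] == "G4").any()
        assert len(layout.truth) == 15

    def test_midpoints_away_from_chromosome_ends(self, small_layout, small_config):
        mids = small_layout.truth["midpoint"]
        assert (mids >= 5000).all()
        assert (mids <= small_config.genome_length - 5000).all()

    def test_overcrowded_genome_rejected(self):
        with pytest.raises(ValidationError, match="overcrowded"):
            plant_layout(SimulationConfig(genome_length=100_000, n_peaks_per_class=200))

    def test_architectures_do_not_overlap(self, small_layout):
        mids = np.sort(small_layout.truth["midpoint"].to_numpy())
        assert np.diff(mids).min() >= 2100


class TestEvictionInversion:
    def test_noiseless_score_matches_planted_fraction(self, small_config):
        w = solve_center_weight(small_config)
        assert 0 < w < 1
        from pioneerclass.dynamics import eviction_score

        ctrl = expected_mnase_profile(small_config, "G1", "control", w)
        treat = expected_mnase_profile(small_config, "G1", "treated", w)
        assert eviction_score(ctrl, treat) == pytest.approx(
            small_config.eviction_fraction, abs=1e-4
        )

    def test_g2_template_depleted_at_center(self, small_config):
        grid = _template_grid()
        tpl = dyad_template(small_config, "G2", "control", 0.5)
        center = np.abs(grid) <= 60
        flanks = np.abs(np.abs(grid) - 190) <= 30
        assert tpl[center].max() < 0.1 * tpl[flanks].max()


class TestSimulateMnase:
    def test_g2_fragment_midpoints_dip_at_center(self, small_layout, small_config):
        frags = simulate_mnase(small_layout, "control", depth=300_000)
        mids = ((frags.df["start"] + frags.df["end"]) // 2).to_numpy()
        g2 = small_layout.truth[small_layout.truth["class"] == "G2"]
        center_mass = edge_mass = 0
        for peak_mid in g2["midpoint"]:
            off = mids - peak_mid
            center_mass += np.sum(np.abs(off) <= 60)
            edge_mass += np.sum(np.abs(np.abs(off) - 190) <= 60)
        assert center_mass < 0.3 * edge_mass

    def test_depth_doubling_within_poisson(self, small_layout, small_config):
        n1 = simulate_mnase(small_layout, "control", depth=50_000).total_count
        n2 = simulate_mnase(small_layout, "control", depth=100_000).total_count
        assert abs(n2 - 2 * n1) < 3 * np.sqrt(2 * n1 + 4 * n1)

    def test_zero_background_leaves_empty_regions_empty(self, small_layout):
        frags = simulate_mnase(small_layout, "control", depth=100_000, background=False)
        mids = ((frags.df["start"] + frags.df["end"]) // 2).to_numpy()
        # nothing within the first 3 kb: the closest planted window starts
        # at edge_margin - 1.2 kb
        assert np.sum(mids < 3000) == 0

    def test_empirical_profile_matches_generative_landscape(self, small_config):
        """Fragment-midpoint histograms converge to the planted landscape."""
        import dataclasses

        cfg = dataclasses.replace(small_config, n_peaks_per_class={"G1": 0, "G2": 10,
                                                                   "G3": 0, "G4": 0})
        layout = plant_layout(cfg)
        frags = simulate_mnase(layout, "control", depth=1_200_000)
        mids = ((frags.df["start"] + frags.df["end"]) // 2).to_numpy()
        grid = _template_grid()
        tpl = dyad_template(cfg, "G2", "control", layout.center_weight)
        # pooled 10 bp-binned midpoint histogram over all planted windows
        hist = np.zeros(200)
        for peak_mid in layout.truth["midpoint"]:
            off = mids - peak_mid
            sel = (off >= -1000) & (off < 1000)
            hist += np.histogram(off[sel], bins=200, range=(-1000, 1000))[0]
        hist /= hist.sum()
        expected = tpl[(grid >= -1000) & (grid < 1000)].reshape(200, -1).sum(axis=1)
        occ_total = len(layout.truth) * tpl.sum()
        bg_per_bin = (
            cfg.mnase_background / (1 - cfg.mnase_background)
            * occ_total * 10 / cfg.genome_length
        )
        expected = expected + bg_per_bin
        expected /= expected.sum()
        assert np.max(np.abs(hist - expected)) < 0.15 * expected.max()


class TestSimulateAtac:
    def test_offset_correction_recovers_planted_open_center(self, small_layout,
                                                            small_config):
        cfg = small_config
        genome = {cfg.chrom: cfg.genome_length}
        track_c = tn5_cut_sites(simulate_atac(small_layout, "control"), genome)
        track_t = tn5_cut_sites(simulate_atac(small_layout, "treated"), genome)
        truth = small_layout.truth

        def central(track, mids):
            return np.array([
                track.counts_in_windows(cfg.chrom, [m], 60)[0] for m in mids
            ])

        g1 = truth[truth["class"] == "G1"]["midpoint"]
        g3 = truth[truth["class"] == "G3"]["midpoint"]
        ratio_g1 = central(track_t, g1).sum() / max(central(track_c, g1).sum(), 1)
        ratio_g3 = central(track_t, g3).sum() / max(central(track_c, g3).sum(), 1)
        assert ratio_g1 > 0.5 * cfg.accessibility_fold
        assert 0.5 < ratio_g3 < 2.0

    def test_plus_and_minus_reads_recover_same_cut_sites(self, small_layout,
                                                         small_config):
        cfg = small_config
        frags = simulate_atac(small_layout, "treated", depth=50_000)
        genome = {cfg.chrom: cfg.genome_length}
        plus = frags.df[frags.df["strand"] == "+"]
        minus = frags.df[frags.df["strand"] == "-"]
        # reconstruct cut sites strand-wise; both strands sample the same
        # accessibility landscape, so central masses agree
        cut_plus = plus["start"].to_numpy() + 4
        cut_minus = minus["end"].to_numpy() - 5
        mid = small_layout.truth["midpoint"].iloc[0]
        in_p = np.sum(np.abs(cut_plus - mid) <= 1000)
        in_m = np.sum(np.abs(cut_minus - mid) <= 1000)
        assert in_p + in_m > 0
        assert abs(in_p - in_m) < 4 * np.sqrt(in_p + in_m + 1)


class TestSimulateChip:
    def test_tf_enrichment_ratio_g1_vs_g3(self, small_layout, small_config):
        cfg = small_config
        frags = simulate_chip(small_layout, "TF", "treated", depth=200_000)
        mids = ((frags.df["start"] + frags.df["end"]) // 2).to_numpy()
        truth = small_layout.truth

        def mean_count(cls):
            sub = truth[truth["class"] == cls]["midpoint"]
            return np.mean([np.sum(np.abs(mids - m) <= 100) for m in sub])

        assert mean_count("G1") / mean_count("G3") == pytest.approx(
            1 / cfg.g3_tf_multiplier, rel=0.25
        )

    def test_cofactor_absent_outside_treated_g1(self, small_layout):
        frags = simulate_chip(small_layout, "cofactor", "treated", depth=100_000)
        mids = ((frags.df["start"] + frags.df["end"]) // 2).to_numpy()
        truth = small_layout.truth
        g1 = truth[truth["class"] == "G1"]["midpoint"]
        g3 = truth[truth["class"] == "G3"]["midpoint"]
        n_g1 = sum(np.sum(np.abs(mids - m) <= 200) for m in g1)
        n_g3 = sum(np.sum(np.abs(mids - m) <= 200) for m in g3)
        # G3 windows carry background only
        assert n_g3 < 0.05 * n_g1

    def test_invalid_factor_rejected(self, small_layout):
        with pytest.raises(ValidationError):
            simulate_chip(small_layout, "H3K9me3", "treated")


class TestWriteDataset:
    def test_same_seed_byte_identical_truth(self, small_config, tmp_path):
        write_dataset(small_config, tmp_path / "a")
        write_dataset(small_config, tmp_path / "b")
        assert (tmp_path / "a" / "truth.tsv").read_bytes() == (
            tmp_path / "b" / "truth.tsv"
        ).read_bytes()

    def test_refuses_nonempty_dir_without_force(self, small_config, tmp_path):
        out = tmp_path / "d"
        out.mkdir()
        (out / "sentinel").write_text("x")
        with pytest.raises(ValidationError, match="not empty"):
            write_dataset(small_config, out)
        write_dataset(small_config, out, force=True)  # force path succeeds

    def test_files_parse_back_through_readers(self, small_config, tmp_path):
        out = tmp_path / "ds"
        manifest = write_dataset(small_config, out)
        genome = read_chrom_sizes(out / "chrom.sizes")
        assert genome == {small_config.chrom: small_config.genome_length}
        peaks = read_peaks(out / "peaks.bed")
        assert len(peaks) == small_config.n_peaks
        atac = read_fragments(out / "atac_control.bed", "ATAC", "control")
        assert not atac.is_paired and atac.total_count > 0
        mnase = read_fragments(out / "mnase_control.bedpe", "MNASE", "control")
        assert mnase.is_paired and mnase.total_count > 0
        truth = pd.read_csv(out / "truth.tsv", sep="\t")
        assert set(truth["class"]) == {"G1", "G2", "G3", "G4"}
        assert "dataset.yaml" in manifest
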