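"""Synthetic dataset generator: catalog contents, duration law, frame
motifs, texts and manifest structure."""

import numpy as np
import pandas as pd
import pytest

import surgphase as sp
from surgphase.exceptions import ConfigurationError
from surgphase.synthdata import PHASE_TABLE


class TestPhaseCatalog:
    def test_seven_phases_in_canonical_order(self, catalog):
        assert len(catalog) == 7
        assert catalog[0].name == "preparation"
        assert catalog[1].name == "calot's triangle dissection"
        assert catalog[6].name == "gallbladder retraction"
        assert [p.phase_id for p in catalog.phases] == list(range(7))

    def test_published_duration_statistics(self, catalog):
        assert (catalog[1].duration_mean, catalog[1].duration_sd) == (954, 538)
        assert (catalog[0].duration_mean, catalog[0].duration_sd) == (125, 95)
        assert (catalog[3].duration_mean, catalog[3].duration_sd) == (857, 551)
        for p in catalog.phases:
            assert p.duration_mean > 0 and p.duration_sd > 0

    def test_canonical_texts_unique_and_contain_keyword(self, catalog):
        texts = [p.canonical_text for p in catalog.phases]
        assert len(set(texts)) == 7
        for p in catalog.phases:
            assert p.keyword in p.canonical_text

    def test_unknown_motif_scheme_rejected(self):
        with pytest.raises(ConfigurationError):
            sp.build_phase_catalog("cubist")


class TestDurations:
    def test_strictly_positive_and_seed_deterministic(self, catalog):
        d1 = sp.sample_phase_durations(catalog, 2, 500, seed=9)
        d2 = sp.sample_phase_durations(catalog, 2, 500, seed=9)
        assert (d1 > 0).all()
        np.testing.assert_array_equal(d1, d2)

    def test_invalid_arguments(self, catalog):
        with pytest.raises(IndexError):
            sp.sample_phase_durations(catalog, 99, 10, seed=0)
        with pytest.raises(ValueError):
            sp.sample_phase_durations(catalog, 0, 0, seed=0)

    @pytest.mark.parametrize("phase_id", range(7))
    def test_moment_recovery_within_monte_carlo_error(self, catalog, phase_id):
        """Gamma moment matching: sample mean/sd recover the published
        mean +- sd within 4 standard errors at n = 1e5."""
        n = 100_000
        d = sp.sample_phase_durations(catalog, phase_id, n, seed=phase_id + 1)
        mean, sd = PHASE_TABLE[phase_id][1], PHASE_TABLE[phase_id][2]
        se_mean = sd / np.sqrt(n)
        assert abs(d.mean() - mean) < 4 * se_mean
        # SE of the sd for a gamma (via the fourth moment): bounded loosely
        assert abs(d.std(ddof=1) - sd) < 0.05 * sd

    def test_gamma_parameterization_for_calot_phase(self, catalog):
        # shape = (954/538)^2, scale = 538^2/954 -- checked via the
        # distribution's analytic moments rather than sampling
        shape = 954**2 / 538**2
        scale = 538**2 / 954
        assert shape == pytest.approx(910116 / 289444, abs=1e-12)
        assert scale == pytest.approx(289444 / 954, abs=1e-12)
        assert shape * scale == pytest.approx(954)
        assert np.sqrt(shape) * scale == pytest.approx(538)


class TestRenderFrame:
    def test_deterministic_without_nuisance(self):
        f1 = sp.render_frame(3, 0.0)
        f2 = sp.render_frame(3, 0.0)
        np.testing.assert_array_equal(f1, f2)

    @pytest.mark.parametrize("noise", [0.0, 0.1, 0.5])
    def test_values_always_within_unit_interval(self, noise, rng):
        f = sp.render_frame(5, noise, tools=True, smoke=True, rng=rng)
        assert f.min() >= 0.0 and f.max() <= 1.0

    def test_phase_motifs_differ(self):
        frames = [sp.render_frame(p, 0.0) for p in range(7)]
        for p in range(6):
            diff = np.abs(frames[p] - frames[p + 1]).mean()
            assert diff > 0.01

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            sp.render_frame(0, -0.1)


class TestComposeText:
    def test_zero_variability_returns_canonical(self, catalog):
        for p in range(7):
            assert sp.compose_text(p, 0.0) == catalog[p].canonical_text

    def test_always_contains_phase_keyword(self, catalog):
        rng = np.random.default_rng(5)
        for p in range(7):
            for _ in range(10):
                assert catalog[p].keyword in sp.compose_text(p, 0.9, rng)

    def test_seeded_determinism(self):
        t1 = sp.compose_text(2, 0.5, np.random.default_rng(7))
        t2 = sp.compose_text(2, 0.5, np.random.default_rng(7))
        assert t1 == t2


class TestGenerateDataset:
    def test_every_video_covers_all_phases_in_order(self, tiny_dataset):
        for vid, grp in tiny_dataset.manifest.groupby("video_id"):
            phases = grp.sort_values("frame_index")["phase_id"].to_numpy()
            assert (np.diff(phases) >= 0).all()
            assert set(phases) == set(range(7))

    def test_same_seed_reproduces_manifest_and_frames(self):
        a = sp.generate_dataset(2, 0.01, seed=5)
        b = sp.generate_dataset(2, 0.01, seed=5)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        for key in a.frames:
            np.testing.assert_array_equal(a.frames[key], b.frames[key])

    def test_default_split_ratio_mirrors_50_30(self):
        ds = sp.generate_dataset(8, 0.005, seed=1)
        split = ds.manifest.groupby("video_id")["split"].first()
        assert (split == "train").sum() == 5
        assert (split == "test").sum() == 3

    def test_frame_level_split_option(self):
        ds = sp.generate_dataset(2, 0.01, seed=1, split_mode="frame")
        n = len(ds.manifest)
        assert (ds.manifest["split"] == "train").sum() == int(round(0.625 * n))

    def test_keys_unique_and_paths_formatted(self, tiny_dataset):
        m = tiny_dataset.manifest
        assert not m.duplicated(["video_id", "frame_index"]).any()
        assert (m["path"].str.endswith(".png")).all()

    def test_zero_noise_dataset_is_centroid_separable(self, tiny_dataset):
        """The learnability guarantee: nearest class-centroid on raw pixels
        is a perfect classifier when noise and nuisance are off."""
        ds = tiny_dataset
        X = np.stack(
            [ds.frame(r.video_id, r.frame_index)
             for r in ds.manifest.itertuples()]
        ).reshape(len(ds.manifest), -1)
        y = ds.manifest["phase_id"].to_numpy()
        centroids = np.stack([X[y == p].mean(axis=0) for p in range(7)])
        pred = ((X[:, None, :] - centroids[None]) ** 2).sum(-1).argmin(1)
        assert (pred == y).mean() == 1.0

    def test_save_load_round_trip(self, tmp_path):
        ds = sp.generate_dataset(2, 0.008, seed=3, out_dir=tmp_path / "d")
        back = sp.SyntheticDataset.load(tmp_path / "d")
        pd.testing.assert_frame_equal(ds.manifest, back.manifest)
        key = next(iter(ds.frames))
        # PNG storage quantizes to 8 bits
        assert np.abs(ds.frames[key] - back.frames[key]).max() <= 1 / 255 + 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sp.generate_dataset(0, 1.0)
        with pytest.raises(ValueError):
            sp.generate_dataset(1, 0.0)
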