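"""Synthetic generator: planted structure, determinism, round-trips."""

import numpy as np
import pytest

from eventrsa import (
    DEFAULT_ROI_PROFILES,
    GeneratorConfig,
    ROIProfile,
    encoding_similarity_matrix,
    generate_dataset,
    read_dataset,
    write_dataset,
)


class TestConfigValidation:
    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ROIProfile(w_person=-0.1)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_subjects=0)
        with pytest.raises(ValueError):
            GeneratorConfig(recall_attenuation=1.5)

    def test_gain_length_checked(self):
        with pytest.raises(ValueError, match="epoch_gain"):
            GeneratorConfig(
                roi_profiles={"r": ROIProfile(w_episodic=1)},
                epoch_gain={"r": np.ones(10)},
                n_tr_per_event=33,
            )


class TestPlantedStructure:
    def test_pure_context_noise_free(self, design):
        """With only a context component and no noise, same-context patterns
        are identical and different-context patterns near-orthogonal."""
        cfg = GeneratorConfig(
            n_subjects=2, n_voxels=400, seed=3, noise_sd=0.0,
            roi_profiles={"ctx": ROIProfile(w_context=1.0)},
        )
        ds = generate_dataset(cfg)
        enc = ds.encoding["ctx"][0]
        for i in range(8):
            for j in range(8):
                same = design.events[i].context == design.events[j].context
                r = np.corrcoef(enc[0, i], enc[1, j])[0, 1]
                if same:
                    assert r == pytest.approx(1.0, abs=1e-10)
                else:
                    assert abs(r) < 0.2

    def test_structureless_mean_correlation_shrinks_with_voxels(self):
        means = []
        for nv in (50, 3000):
            cfg = GeneratorConfig(
                n_subjects=1, n_voxels=nv, seed=4,
                roi_profiles={"null": ROIProfile()},
            )
            ds = generate_dataset(cfg)
            sim = encoding_similarity_matrix(ds.encoding["null"][0])
            means.append(np.abs(sim.values).mean())
        assert means[1] < means[0]
        assert means[1] < 0.05

    def test_context_profile_wins_in_replicates(self, design, models):
        """A context-dominant profile makes the Context model the best fit in
        nearly all replicate datasets."""
        from eventrsa import group_fit

        wins = 0
        n_rep = 40
        for rep in range(n_rep):
            cfg = GeneratorConfig(
                n_subjects=5, n_voxels=150, seed=2000 + rep,
                roi_profiles={
                    "pm": ROIProfile(w_context=1.0, w_schema=0.4, w_episodic=0.4)
                },
            )
            ds = generate_dataset(cfg)
            sims = [
                encoding_similarity_matrix(ds.encoding["pm"][s]).values
                for s in range(5)
            ]
            fits = {k: group_fit(sims, m).r for k, m in models.items()}
            wins += max(fits, key=fits.get) == "context"
        assert wins / n_rep >= 0.95

    def test_recall_weaker_than_encoding(self):
        cfg = GeneratorConfig(n_subjects=4, n_voxels=200, seed=6)
        ds = generate_dataset(cfg)
        from eventrsa import recall_similarity_matrix

        for s in range(4):
            enc = encoding_similarity_matrix(ds.encoding["HPC"][s]).values
            rec = recall_similarity_matrix(
                ds.encoding["HPC"][s], ds.recall["HPC"][s]
            ).values
            assert np.diagonal(rec).mean() < np.diagonal(enc).mean()
            assert np.diagonal(rec).mean() > rec[~np.eye(8, dtype=bool)].mean()


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = dict(n_subjects=3, n_voxels=40, seed=42)
        a = generate_dataset(GeneratorConfig(**cfg))
        b = generate_dataset(GeneratorConfig(**cfg))
        for roi in a.rois:
            np.testing.assert_array_equal(a.encoding[roi], b.encoding[roi])
            np.testing.assert_array_equal(a.recall[roi], b.recall[roi])
        assert a.behavior.equals(b.behavior)

    def test_different_seed_differs(self):
        a = generate_dataset(GeneratorConfig(n_subjects=2, n_voxels=40, seed=1))
        b = generate_dataset(GeneratorConfig(n_subjects=2, n_voxels=40, seed=2))
        assert not np.allclose(a.encoding["PM"], b.encoding["PM"])

    def test_adding_subjects_preserves_existing(self):
        small = generate_dataset(GeneratorConfig(n_subjects=3, n_voxels=30, seed=9))
        big = generate_dataset(GeneratorConfig(n_subjects=5, n_voxels=30, seed=9))
        np.testing.assert_array_equal(
            small.encoding["PM"], big.encoding["PM"][:3]
        )


class TestBehaviorCoupling:
    def test_fidelity_drives_details(self):
        cfg = GeneratorConfig(
            n_subjects=40, n_voxels=30, seed=12, behavior_coupling=20.0,
            roi_profiles={"HPC": DEFAULT_ROI_PROFILES["HPC"]},
        )
        ds = generate_dataset(cfg)
        f = np.asarray(ds.truth["fidelity"])
        r = np.corrcoef(f, ds.behavior["details_total"])[0, 1]
        assert r > 0.9

    def test_zero_coupling_details_flat(self):
        cfg = GeneratorConfig(
            n_subjects=30, n_voxels=30, seed=13, behavior_coupling=0.0,
            roi_profiles={"HPC": DEFAULT_ROI_PROFILES["HPC"]},
        )
        ds = generate_dataset(cfg)
        assert ds.behavior["details_total"].std() < 3


class TestDiskRoundTrip:
    def test_write_read_equality(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=2, n_voxels=15, seed=21)
        ds = generate_dataset(cfg)
        write_dataset(ds, tmp_path / "data")
        back = read_dataset(tmp_path / "data")
        for roi in ds.rois:
            np.testing.assert_allclose(ds.encoding[roi], back.encoding[roi])
            np.testing.assert_allclose(ds.recall[roi], back.recall[roi])
        assert back.design == ds.design
        assert back.behavior["details_total"].tolist() == (
            ds.behavior["details_total"].tolist()
        )

    def test_file_counts_and_manifest(self, tmp_path):
        import json

        cfg = GeneratorConfig(
            n_subjects=3, n_voxels=10, seed=22,
            roi_profiles={k: DEFAULT_ROI_PROFILES[k] for k in ("PM", "HPC")},
        )
        ds = generate_dataset(cfg)
        manifest_path = write_dataset(ds, tmp_path / "d")
        manifest = json.loads(manifest_path.read_text())
        pattern_files = [f for f in manifest["files"] if f.startswith("patterns/")]
        # 3 subjects x 2 ROIs x (3 encoding runs + 1 recall)
        assert len(pattern_files) == 3 * 2 * 4
        for rel in manifest["files"]:
            assert (tmp_path / "d" / rel).exists()
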