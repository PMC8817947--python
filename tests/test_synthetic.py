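import numpy as np
import pandas as pd
import pytest

from earseg.image_stack import CHANNEL_NAMES
from earseg.synthetic import (
    MASK_EAR,
    SceneParams,
    generate_canopy,
    generate_experiment,
    truth_annotations,
)


class TestGenerateCanopy:
    def test_same_seed_bit_identical(self):
        p = SceneParams(height=128, width=128, ear_fraction=0.1, seed=5)
        img1, truth1 = generate_canopy(p)
        img2, truth2 = generate_canopy(p)
        for ch in CHANNEL_NAMES:
            np.testing.assert_array_equal(img1.channels[ch], img2.channels[ch])
        np.testing.assert_array_equal(truth1.mask, truth2.mask)
        np.testing.assert_array_equal(truth1.instances, truth2.instances)

    def test_different_seed_differs(self):
        img1, _ = generate_canopy(SceneParams(height=128, width=128, seed=1))
        img2, _ = generate_canopy(SceneParams(height=128, width=128, seed=2))
        assert any((img1.channels[ch] != img2.channels[ch]).any()
                   for ch in CHANNEL_NAMES)

    @pytest.mark.parametrize("target", [0.08, 0.20])
    def test_ear_fraction_within_tolerance(self, target):
        _, truth = generate_canopy(
            SceneParams(height=256, width=256, ear_fraction=target, seed=3))
        assert abs(truth.ear_ratio - target) <= 0.02

    def test_instances_live_inside_ear_mask(self, diffuse_scene):
        _, truth = diffuse_scene
        assert ((truth.instances > 0) == (truth.mask == MASK_EAR)).all()

    def test_all_channels_present_8bit(self, diffuse_scene):
        img, _ = diffuse_scene
        assert set(img.channels) == set(CHANNEL_NAMES)
        assert all(v.dtype == np.uint8 for v in img.channels.values())

    def test_infeasible_fraction_rejected(self):
        with pytest.raises(ValueError):
            SceneParams(ear_fraction=0.7)

    def test_full_similarity_merges_signatures(self):
        p = SceneParams(height=96, width=96, ear_fraction=0.1,
                        stage_similarity=1.0, seed=4)
        img, truth = generate_canopy(p)
        ear_px = img.channels["R"][truth.mask == 2].astype(float)
        leaf_px = img.channels["R"][truth.mask == 1].astype(float)
        # identical class signatures: means differ only through organ-level
        # and sampling noise, far less than the mature-stage gap (~150)
        assert abs(ear_px.mean() - leaf_px.mean()) < 20


def _cv_accuracy_at(sim, seeds, organ_level_sd=15.0, min_plant_fraction=0.5,
                    balance=False):
    from earseg.classification import standardize, tune_hyperparameters
    from earseg.superpixels import SlicParams
    from earseg.workflow import labelled_feature_table, regions_from_truth

    tables = []
    for seed in seeds:
        img, truth = generate_canopy(
            SceneParams(height=256, width=256, ear_fraction=0.15,
                        stage_similarity=sim, organ_level_sd=organ_level_sd,
                        seed=seed))
        tables.append(labelled_feature_table(
            img, regions_from_truth(truth.mask, erosion_radius=2),
            SlicParams(n_segments=150), scale_segments=False,
            min_plant_fraction=min_plant_fraction))
    table = pd.concat(tables, ignore_index=True)
    if balance:
        ear = table[table["class"] == "ear"]
        leaf = table[table["class"] == "leaf"].sample(len(ear), random_state=0)
        table = pd.concat([ear, leaf], ignore_index=True)
    (scaled,), _ = standardize(table)
    cols = [c for c in scaled.columns
            if c not in ("image_id", "superpixel", "class", "das", "ct")]
    _, acc = tune_hyperparameters(
        "SVM", scaled, {"kernel": ["rbf"], "C": [100.0], "gamma": [0.1]},
        feature_columns=cols, seed=0)
    return acc


class TestStageSimilarityDegradesSeparability:
    def test_classifier_accuracy_degrades_with_similarity(self):
        """CV accuracy is near-perfect at mature colors and degrades
        (non-strictly) as the ear signature approaches the leaf one."""
        accs = [_cv_accuracy_at(sim, (21, 22)) for sim in (0.2, 0.8, 1.0)]
        assert accs[0] >= 0.95
        assert accs[0] >= accs[1] - 0.05 and accs[1] >= accs[2] - 0.05

    def test_identical_signatures_give_chance_accuracy(self):
        """With organ-level variation off and identical class signatures,
        per-organ feature vectors carry no class signal: CV accuracy is at
        chance. Organs themselves serve as regions so that the control
        isolates the color signal from any oversegmentation geometry."""
        from earseg.classification import standardize, tune_hyperparameters
        from earseg.features import build_feature_table
        from earseg.superpixels import SlicParams, SuperpixelMap

        rng = np.random.default_rng(77)
        tables = []
        for seed in (31, 32):
            img, truth = generate_canopy(
                SceneParams(height=256, width=256, ear_fraction=0.15,
                            stage_similarity=1.0, organ_level_sd=0.0,
                            seed=seed), image_id=f"ctl{seed}")
            # 100 single-pixel regions per class: identical geometry, so the
            # class-conditional feature distributions coincide exactly
            labels = np.zeros(truth.mask.shape, int)
            cls_of_region = {}
            next_id = 1
            for value, name in ((MASK_EAR, "ear"), (1, "leaf")):
                rows, cols_ = np.nonzero(truth.mask == value)
                pick = rng.choice(len(rows), size=100, replace=False)
                for i in pick:
                    labels[rows[i], cols_[i]] = next_id
                    cls_of_region[next_id] = name
                    next_id += 1
            sp = SuperpixelMap(labels=labels, n_regions=next_id,
                               params=SlicParams(n_segments=next_id))
            table = build_feature_table(img, sp, (truth.mask > 0).astype(np.uint8),
                                        ct=0.9, min_plant_fraction=0.95)
            table["class"] = table["superpixel"].map(cls_of_region)
            tables.append(table.dropna(subset=["class"]))
        balanced = pd.concat(tables, ignore_index=True)
        (scaled,), _ = standardize(balanced)
        cols = [c for c in scaled.columns
                if c not in ("image_id", "superpixel", "class", "das", "ct")]
        _, acc = tune_hyperparameters(
            "SVM", scaled, {"kernel": ["rbf"], "C": [100.0], "gamma": [0.1]},
            feature_columns=cols, seed=0)
        assert 0.25 <= acc <= 0.75


class TestGenerateExperiment:
    def test_shape_and_sidecar(self, tmp_path):
        recs = generate_experiment(n_dates=2, n_plots=2, seed=0,
                                   height=96, width=96, out_dir=tmp_path)
        assert len(recs) == 4
        sidecar = pd.read_csv(tmp_path / "sidecar.csv")
        assert len(sidecar) == 4
        assert {"image_id", "DAS", "E", "z", "nitrogen"} <= set(sidecar.columns)
        stacks = list((tmp_path / "stacks").glob("*.png"))
        assert len(stacks) == 4 * 9

    def test_zero_nitrogen_has_lower_ear_ratio_every_date(self):
        recs = generate_experiment(n_dates=3, n_plots=4,
                                   nitrogen_levels=[0.0, 180.0],
                                   seed=1, height=128, width=128)
        frame = pd.DataFrame([{"das": r["meta_row"]["DAS"],
                               "n": r["meta_row"]["nitrogen"],
                               "ratio": r["truth"].ear_ratio} for r in recs])
        by = frame.groupby(["das", "n"])["ratio"].mean().unstack()
        assert (by[0.0] < by[180.0]).all()

    def test_fixed_seed_reproducible(self):
        r1 = generate_experiment(n_dates=2, n_plots=2, seed=9, height=96, width=96)
        r2 = generate_experiment(n_dates=2, n_plots=2, seed=9, height=96, width=96)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a["image"].channels["R"],
                                          b["image"].channels["R"])
            np.testing.assert_array_equal(a["truth"].mask, b["truth"].mask)

    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            generate_experiment(n_dates=0, n_plots=2)


class TestTruthAnnotations:
    def test_classes_read_off_mask(self, diffuse_scene):
        _, truth = diffuse_scene
        coords = [(0, 0), (10, 10), (100, 100)]
        anns = truth_annotations(truth, coords, "img")
        for a in anns:
            expected = 2 if truth.mask[a.row, a.col] == MASK_EAR else 1
            assert a.cls == expected
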