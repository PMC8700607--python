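"""Generator tests: templates, sequences, datasets, pooling, mixing."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import teafp
from teafp.containers import Chromatogram
from teafp.synthetic import (
    DriftModel,
    GeneratorConfig,
    build_default_templates,
    build_injection_sequence,
    generate_chromatogram,
    generate_dataset,
    make_pooled_qc,
    mix_fingerprints,
    time_grid,
)

TEAS = ("black", "green", "oolong", "red", "white_a", "white_b")


class TestTemplates:
    def test_every_tea_has_marker_peak_near_11_min(self):
        templates = build_default_templates()
        for tea in TEAS:
            assert any(
                10.5 <= p.rt_min <= 11.5 and p.amp_uv > 0
                for p in templates[tea].peaks
            ), tea

    def test_chicory_uv_peak_rich_but_100_fold_weaker(self):
        t = build_default_templates()
        assert all(t["chicory"].n_peaks("uv") > t[tea].n_peaks("uv") for tea in TEAS)
        weakest_tea_max = min(t[tea].max_amp("uv") for tea in TEAS)
        assert t["chicory"].max_amp("uv") <= 0.01 * weakest_tea_max
        assert t["chicory"].n_peaks("uv") > t["black"].n_peaks("uv")

    def test_channel_intensity_and_richness_ordering(self):
        t = build_default_templates()
        # white most intense in UV
        whites = min(t["white_a"].max_amp("uv"), t["white_b"].max_amp("uv"))
        assert whites > max(t[c].max_amp("uv") for c in ("black", "green", "oolong", "red"))
        # black and green most intense in FLD
        bg = min(t["black"].max_amp("fld"), t["green"].max_amp("fld"))
        assert bg > max(
            t[c].max_amp("fld") for c in ("oolong", "red", "white_a", "white_b")
        )
        # red and chicory carry the most FLD peaks
        rich = min(t["red"].n_peaks("fld"), t["chicory"].n_peaks("fld"))
        assert rich > max(
            t[c].n_peaks("fld") for c in ("black", "green", "oolong", "white_a", "white_b")
        )


class TestGenerateChromatogram:
    def test_deterministic_trace_equals_gaussian_sum(self):
        """With every stochastic term off the trace is the exact peak sum."""
        t = build_default_templates()["black"]
        from dataclasses import replace

        t = replace(t, amp_cv=0.0, rt_jitter_sd=0.0)
        chrom = generate_chromatogram(
            t, "uv", 1, DriftModel(0.0, 0.0), seed=5, noise_frac=0.0, baseline_frac=0.0
        )
        time = time_grid()
        expected = np.zeros_like(time)
        for p in t.peaks:
            expected += p.amp_uv * np.exp(-0.5 * ((time - p.rt_min) / p.width_min) ** 2)
        np.testing.assert_allclose(chrom.intensity, expected, atol=1e-12)

    def test_same_seed_same_trace(self):
        t = build_default_templates()["green"]
        a = generate_chromatogram(t, "fld", 3, DriftModel(), seed=7, n_injections=10)
        b = generate_chromatogram(t, "fld", 3, DriftModel(), seed=7, n_injections=10)
        assert np.array_equal(a.intensity, b.intensity)

    def test_drift_slope_scales_peak_heights(self):
        """slope -0.15 without walk: last injection peaks at 85% of first."""
        from dataclasses import replace

        t = replace(build_default_templates()["oolong"], amp_cv=0.0, rt_jitter_sd=0.0)
        drift = DriftModel(slope=-0.15, walk_sd=0.0)
        n = 50
        kw = dict(noise_frac=0.0, baseline_frac=0.0, n_injections=n, seed=3)
        first = generate_chromatogram(t, "uv", 1, drift, **kw)
        last = generate_chromatogram(t, "uv", n, drift, **kw)
        assert drift.factors(n, 3)[-1] == pytest.approx(0.85)
        ratio = last.intensity.max() / first.intensity.max()
        assert ratio == pytest.approx(0.85, rel=1e-9)

    def test_positive_sensitivity_enforced(self):
        with pytest.raises(ValueError):
            DriftModel(slope=-1.5, walk_sd=0.0).factors(10, 0)


class TestInjectionSequence:
    def test_ten_samples_one_block(self):
        seq = build_injection_sequence([f"s{i}" for i in range(10)], seed=0)
        assert list(seq.roles) == ["qc"] + ["sample"] * 10 + ["blank", "qc"]

    def test_single_sample(self):
        seq = build_injection_sequence(["only"], seed=0)
        assert list(seq.roles) == ["qc", "sample", "blank", "qc"]

    def test_twenty_five_samples_counts(self):
        seq = build_injection_sequence([f"s{i}" for i in range(25)], seed=1)
        roles = seq.roles
        assert int(np.sum(roles == "blank")) == 3
        assert int(np.sum(roles == "qc")) == 4

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_injection_sequence(["a", "b", "a"], seed=0)

    def test_qc_opens_and_blocks_capped_at_ten(self):
        seq = build_injection_sequence([f"s{i}" for i in range(37)], seed=2)
        roles = list(seq.roles)
        assert roles[0] == "qc"
        run = 0
        for role in roles[1:]:
            if role == "sample":
                run += 1
                assert run <= 10
            else:
                run = 0


class TestGenerateDataset:
    def test_default_design(self, default_dataset):
        meta = default_dataset.uv.meta
        assert int((meta["role"] == "sample").sum()) == 107
        counts = default_dataset.truth["class_label"].value_counts().to_dict()
        assert counts == {
            "black": 35, "green": 20, "chicory": 20, "red": 12, "oolong": 10, "white": 10,
        }
        assert int((meta["role"] == "qc").sum()) == int(np.ceil(107 / 10)) + 1 == 12
        subtypes = default_dataset.truth.query("class_label == 'white'")["subtype"]
        assert sorted(subtypes.value_counts().to_dict().items()) == [
            ("white_a", 5), ("white_b", 5),
        ]

    def test_empty_config_gives_empty_dataset(self):
        cfg = GeneratorConfig(class_counts={})
        ds = generate_dataset(cfg, seed=0)
        assert ds.uv.X.shape[0] == 0
        assert len(ds.sequence) == 0

    def test_bit_identical_for_same_seed(self):
        cfg = GeneratorConfig(class_counts={"oolong": 3, "chicory": 2})
        a = generate_dataset(cfg, seed=11)
        b = generate_dataset(cfg, seed=11)
        assert np.array_equal(a.uv.X, b.uv.X)
        assert np.array_equal(a.fld.X, b.fld.X)
        assert a.uv.meta.equals(b.uv.meta)
        c = generate_dataset(cfg, seed=12)
        assert not np.array_equal(a.uv.X, c.uv.X)


class TestPooledQc:
    def test_single_and_two_sample_pooling(self, default_dataset):
        samples = default_dataset.uv.samples_only()
        one = samples.rows(np.arange(len(samples.meta)) == 0)
        np.testing.assert_array_equal(make_pooled_qc(one), one.X[0])
        two = samples.rows(np.arange(len(samples.meta)) < 2)
        np.testing.assert_allclose(make_pooled_qc(two), (two.X[0] + two.X[1]) / 2)

    def test_dataset_qc_ideal_is_column_mean_of_sample_ideals(self, default_dataset):
        ds = default_dataset
        is_sample = (ds.uv.meta["role"] == "sample").to_numpy()
        is_qc = (ds.uv.meta["role"] == "qc").to_numpy()
        for ch in ("uv", "fld"):
            mean_ideal = ds.ideal[ch][is_sample].mean(axis=0)
            for qc_row in ds.ideal[ch][is_qc]:
                np.testing.assert_allclose(qc_row, mean_ideal, rtol=1e-10)

    def test_empty_pool_rejected(self, default_dataset):
        empty = default_dataset.uv.rows(
            np.zeros(len(default_dataset.uv.meta), dtype=bool)
        )
        with pytest.raises(ValueError):
            make_pooled_qc(empty)


class TestMixing:
    @pytest.fixture()
    def extracts(self, default_dataset):
        grid = default_dataset.uv.time
        is_sample = (default_dataset.uv.meta["role"] == "sample").to_numpy()
        labels = default_dataset.uv.meta.loc[is_sample, "class_label"].to_numpy()
        ideals = default_dataset.ideal["uv"][is_sample]
        tea = Chromatogram(grid, ideals[labels == "black"][0], "uv", "tea")
        chic = Chromatogram(grid, ideals[labels == "chicory"][0], "uv", "chicory")
        return tea, chic

    def test_endpoints_and_midpoint(self, extracts):
        tea, chic = extracts
        np.testing.assert_array_equal(mix_fingerprints(tea, chic, 0).intensity, tea.intensity)
        np.testing.assert_array_equal(
            mix_fingerprints(tea, chic, 100).intensity, chic.intensity
        )
        np.testing.assert_allclose(
            mix_fingerprints(tea, chic, 50).intensity,
            (tea.intensity + chic.intensity) / 2,
        )

    def test_out_of_range_percentage_rejected(self, extracts):
        tea, chic = extracts
        for bad in (-1, 100.5):
            with pytest.raises(ValueError):
                mix_fingerprints(tea, chic, bad)

    @given(pct=st.floats(0, 100))
    def test_area_conservation(self, pct):
        grid = time_grid(0.05)
        tea = Chromatogram(grid, np.exp(-0.5 * ((grid - 11) / 0.1) ** 2), "uv", "t")
        chic = Chromatogram(grid, np.exp(-0.5 * ((grid - 5) / 0.1) ** 2), "uv", "c")
        mixed = mix_fingerprints(tea, chic, pct)
        area = np.trapezoid(mixed.intensity, grid)
        expected = (1 - pct / 100) * np.trapezoid(tea.intensity, grid) + (
            pct / 100
        ) * np.trapezoid(chic.intensity, grid)
        assert area == pytest.approx(expected, rel=1e-9)


class TestDatasetStatisticalStructure:
    def test_classes_separate_in_pca_score_space(self, default_dataset):
        """Low-noise defaults: within-class distances stay below
        between-class distances for every class pair in PCA scores."""
        from teafp.chemometrics import Pca
        from teafp.preprocess import autoscale

        samples = default_dataset.uv.samples_only()
        scaled, _, _ = autoscale(samples.X)
        scores = Pca(5).fit(scaled).scores_
        labels = samples.meta["class_label"].to_numpy()
        classes = sorted(set(labels))

        def mean_dist(a, b):
            d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
            return d.mean()

        for i, ca in enumerate(classes):
            for cb in classes[i + 1 :]:
                a, b = scores[labels == ca], scores[labels == cb]
                within = (mean_dist(a, a) + mean_dist(b, b)) / 2
                assert within < mean_dist(a, b), (ca, cb)

    def test_drift_disperses_raw_qcs(self):
        """With the default -15% sensitivity drift the QC total-signal RSD
        exceeds three times the noise-only RSD."""
        counts = {"black": 20, "green": 15, "chicory": 15}

        def qc_rsd(drift):
            ds = generate_dataset(GeneratorConfig(class_counts=counts, drift=drift), seed=4)
            is_qc = (ds.uv.meta["role"] == "qc").to_numpy()
            totals = ds.uv.X[is_qc].sum(axis=1)
            return totals.std(ddof=1) / totals.mean()

        drifted = qc_rsd(DriftModel(slope=-0.15, walk_sd=0.005))
        flat = qc_rsd(DriftModel(slope=0.0, walk_sd=0.0))
        assert drifted > 3 * flat
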