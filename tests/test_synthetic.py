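"""Synthetic cohort generator: structure, determinism, calibration."""

import collections

import numpy as np
import pytest

from semdepth.features import extract_features
from semdepth.synthetic import (
    CohortConfig,
    calibrate_depth_preference,
    default_taxonomy,
    gen_frequency_lexicon,
    gen_taxonomy,
    gen_thickness,
    gen_transcripts,
    simulate_cohort,
)
from semdepth.taxonomy import load_taxonomy
from semdepth.transcripts import merge_speaker, read_transcripts
from semdepth.features import FrequencyLexicon
from semdepth.neuro import read_thickness


class TestGenTaxonomy:
    def test_complete_binary_tree_size(self):
        t = gen_taxonomy(seed=0, n_roots=1, branching=2, max_depth=3)
        assert len(t) == 15  # 2^4 - 1
        assert len(t.roots["noun"]) == 1
        depths = collections.Counter(t.depth(s) for s in t.synsets)
        assert depths == {0: 1, 1: 2, 2: 4, 3: 8}

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError, match="max_depth"):
            gen_taxonomy(seed=0, max_depth=0)

    def test_same_seed_identical(self):
        t1 = gen_taxonomy(seed=42, max_depth=4)
        t2 = gen_taxonomy(seed=42, max_depth=4)
        assert sorted(t1.edges) == sorted(t2.edges)
        assert {s.lemmas for s in t1.synsets.values()} == \
            {s.lemmas for s in t2.synsets.values()}


class TestCalibration:
    def test_token_level_hits_target(self):
        tax = default_taxonomy(0)
        for target in (3.0, 4.5):
            theta = calibrate_depth_preference(tax, target)
            # recompute the expectation at the solved theta
            again = calibrate_depth_preference(tax, target)
            assert theta == pytest.approx(again)
        assert calibrate_depth_preference(tax, 3.0) < \
            calibrate_depth_preference(tax, 4.5)

    def test_unreachable_target_rejected(self):
        tax = gen_taxonomy(seed=0, max_depth=2)
        with pytest.raises(ValueError, match="achievable"):
            calibrate_depth_preference(tax, 40.0, {"noun": 1.0})

    def test_depth_preference_monotone_in_theta(self):
        """Larger theta -> deeper expected word choices (empirically,
        over a grid, type-weighted as downstream)."""
        tax = default_taxonomy(0)
        lex = None
        means = []
        for theta in (-2.0, -0.5, 1.0):
            cfg = CohortConfig(
                seed=3, n_sv=0, n_lv=0, n_hc=8,
                depth_preference={"svPPA": 0.0, "lvPPA": 0.0, "HC": theta},
                link_rois=(),
            )
            ts = gen_transcripts(cfg, tax)
            vals = []
            for sp, g in cfg.roster():
                mine = [t for t in ts if t.speaker_id == sp]
                p = extract_features(merge_speaker(mine, sp), tax, lex)
                vals.append(float(p.mean_sdi))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestGenTranscripts:
    def test_group_depth_ordering(self):
        """With theta_sv < theta_lv and matched token budgets, the svPPA
        group's mean SDI falls below the lvPPA group's."""
        tax = default_taxonomy(1)
        lex = gen_frequency_lexicon(1, tax)
        rates = {g: dict(v) for g, v in
                 CohortConfig().feature_rates.items()}
        # matched budgets isolate the depth-preference effect
        for g in rates:
            rates[g]["open_tokens_mean"] = 200.0
            rates[g]["open_tokens_sd"] = 30.0
        diffs = []
        for seed in range(10):
            cfg = CohortConfig(
                seed=seed, n_sv=12, n_lv=12, n_hc=0,
                depth_preference={"svPPA": -1.2, "lvPPA": -0.5, "HC": 0.0},
                feature_rates=rates, link_rois=(),
            )
            ts = gen_transcripts(cfg, tax)
            by_g = collections.defaultdict(list)
            for sp, g in cfg.roster():
                mine = [t for t in ts if t.speaker_id == sp]
                p = extract_features(merge_speaker(mine, sp), tax, lex)
                by_g[g].append(float(p.mean_sdi))
            diffs.append(np.mean(by_g["svPPA"]) < np.mean(by_g["lvPPA"]))
        assert np.mean(diffs) >= 0.99

    def test_transcripts_validate_and_have_all_tasks(self):
        tax = default_taxonomy(2)
        cfg = CohortConfig(seed=2, n_sv=1, n_lv=1, n_hc=1)
        ts = gen_transcripts(cfg, tax)
        speakers = {t.speaker_id for t in ts}
        assert speakers == {"sv01", "lv01", "hc01"}
        tasks = {t.task for t in ts if t.speaker_id == "sv01"}
        assert len(tasks) == 5


class TestGenThickness:
    def test_hc_mean_near_published_baseline(self):
        """Generated control left-entorhinal thickness lands within 3
        standard errors of the 3.20 mm published mean (n=30)."""
        cfg = CohortConfig(seed=11, n_sv=0, n_lv=0, n_hc=30, link_rois=())
        tt = gen_thickness(cfg)
        vals = tt.values_for("entorhinal", "left", group="HC")
        se = 0.42 / np.sqrt(30)
        assert abs(vals.mean() - 3.20) < 3 * se

    def test_zero_noise_link_gives_perfect_correlation(self, toy_tax):
        """As the residual share vanishes (|r| -> 1), the sample
        correlation in designated ROIs approaches 1."""
        from semdepth.neuro import correlate_sdi_thickness
        from conftest import make_transcript

        profiles = []
        for i, (lemma, n) in enumerate(
            [("animal", 1), ("dog", 3), ("cat", 2), ("animal", 2),
             ("dog", 1), ("cat", 1)] * 2
        ):
            t = make_transcript([(lemma, "noun")] * n, speaker=f"sv{i+1:02d}"
                                if i < 6 else f"lv{i-5:02d}")
            profiles.append(extract_features(t, toy_tax))
        cfg = CohortConfig(seed=4, n_sv=6, n_lv=6, n_hc=0,
                           link_mode="pooled", link_r=0.9999,
                           link_rois=(("entorhinal", "left"),))
        tt = gen_thickness(cfg, profiles)
        out = correlate_sdi_thickness(
            profiles, tt, rois=(("entorhinal", "left"),)
        )
        assert out.loc[0, "r"] > 0.999

    def test_group_anchored_preserves_group_means(self):
        cfg = CohortConfig(seed=9, n_sv=0, n_lv=0, n_hc=4, link_rois=())
        tt = gen_thickness(cfg)
        assert set(tt.data["group"]) == {"HC"}
        assert len(tt.data) == 4 * 68

    def test_profiles_required_when_link_active(self):
        cfg = CohortConfig(seed=0)
        with pytest.raises(ValueError, match="profiles"):
            gen_thickness(cfg, None)


class TestDeterminismAndValidation:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = CohortConfig(seed=7, n_sv=2, n_lv=3, n_hc=2)
        p1 = simulate_cohort(cfg, tmp_path / "a")
        p2 = simulate_cohort(CohortConfig(seed=7, n_sv=2, n_lv=3, n_hc=2),
                             tmp_path / "b")
        for name in ("taxonomy", "transcripts", "frequency", "thickness"):
            assert p1[name].read_bytes() == p2[name].read_bytes(), name

    def test_different_seed_differs(self, tmp_path):
        p1 = simulate_cohort(CohortConfig(seed=1, n_sv=2, n_lv=2, n_hc=1),
                             tmp_path / "a")
        p2 = simulate_cohort(CohortConfig(seed=2, n_sv=2, n_lv=2, n_hc=1),
                             tmp_path / "b")
        assert p1["transcripts"].read_bytes() != p2["transcripts"].read_bytes()

    def test_generated_files_pass_readers(self, tmp_path):
        import warnings

        paths = simulate_cohort(CohortConfig(seed=5, n_sv=2, n_lv=3, n_hc=2),
                                tmp_path / "c")
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            tax = load_taxonomy(paths["taxonomy"])
            ts = read_transcripts(paths["transcripts"])
            lex = FrequencyLexicon.read(paths["frequency"])
            tt = read_thickness(paths["thickness"])
        assert len(tax) > 0 and len(ts) > 0 and len(lex) > 0
        assert len(tt.data) == 7 * 68
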