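"""Feature-profile extraction and group summaries."""

from fractions import Fraction

import numpy as np
import pytest

from semdepth.datasets import load_individual_sdi_scores
from semdepth.features import (
    FEATURE_COLUMNS,
    FrequencyLexicon,
    extract_features,
    group_summary,
    profile_table,
)
from semdepth.transcripts import Token, Transcript, TranscriptError, Utterance

from conftest import make_transcript


class TestExtraction:
    def test_hand_computed_example(self, toy_tax):
        """cat,cat,dog (depths 10 and 8): 2 noun types, 3 open tokens,
        mean occurrences 1.5, type-weighted mean SDI 9."""
        t = make_transcript([("cat", "noun"), ("cat", "noun"), ("dog", "noun")])
        p = extract_features(t, toy_tax)
        assert p.n_noun_types == 2
        assert p.n_open_tokens == 3
        assert p.mean_occurrences == Fraction(3, 2)
        assert p.mean_sdi == Fraction(9)
        assert p.sdi_coverage == 1.0

    def test_token_weighting(self, toy_tax):
        t = make_transcript([("cat", "noun"), ("cat", "noun"), ("dog", "noun")])
        p = extract_features(t, toy_tax, sdi_weighting="token")
        assert p.mean_sdi == Fraction(10 + 10 + 8, 3)

    def test_type_weighting_invariant_to_repetition(self, toy_tax):
        once = make_transcript([("cat", "noun"), ("dog", "noun")])
        many = make_transcript([("cat", "noun")] * 7 + [("dog", "noun")] * 2)
        assert (
            extract_features(once, toy_tax).mean_sdi
            == extract_features(many, toy_tax).mean_sdi
        )

    def test_closed_only_transcript(self, toy_tax):
        t = make_transcript([("the", "closed"), ("of", "closed")])
        p = extract_features(t, toy_tax)
        assert p.mean_sdi is None
        assert p.sdi_coverage == 0.0
        assert p.n_closed_tokens == 2

    def test_root_child_scores_one(self, toy_tax):
        t = make_transcript([("animal", "noun")])
        assert extract_features(t, toy_tax).mean_sdi == Fraction(1)

    def test_missing_words_skipped_not_imputed(self, toy_tax):
        t = make_transcript([("cat", "noun"), ("unicorn", "noun")])
        p = extract_features(t, toy_tax)
        assert p.mean_sdi == Fraction(10)  # unicorn skipped
        assert p.sdi_coverage == 0.5

    def test_excluded_tokens_not_counted(self, toy_tax):
        toks = (
            Token(surface="cat", lemma="cat", word_class="noun"),
            Token(surface="uh", lemma="uh", word_class="filler"),
            Token(surface="ca-", lemma="cat", word_class="noun",
                  error_tags=frozenset({"false_start"})),
        )
        t = Transcript(speaker_id="s1", group="svPPA", task="picnic",
                       utterances=(Utterance(tokens=toks, well_formed=True),))
        p = extract_features(t, toy_tax)
        assert p.n_open_tokens == 1

    def test_event_and_error_counters(self, toy_tax):
        toks = (
            Token(surface="cat", lemma="cat", word_class="noun",
                  error_tags=frozenset({"phonemic_paraphasia"})),
            Token(surface="dog", lemma="dog", word_class="noun",
                  error_tags=frozenset({"semantic_paraphasia"})),
        )
        utt = Utterance(tokens=toks, well_formed=False,
                        events=("anomic_pause", "cda", "cda"))
        t = Transcript(speaker_id="s1", group="svPPA", task="picnic",
                       utterances=(utt,))
        p = extract_features(t, toy_tax)
        assert (p.n_phonemic_paraphasias, p.n_semantic_paraphasias) == (1, 1)
        assert (p.n_anomic_pauses, p.n_cda) == (1, 2)
        assert p.n_correct_sentences == 0

    def test_empty_transcript_rejected(self, toy_tax):
        t = Transcript(speaker_id="s1", group="svPPA", task="picnic",
                       utterances=())
        with pytest.raises(TranscriptError, match="empty"):
            extract_features(t, toy_tax)

    @pytest.mark.parametrize("seed", range(4))
    def test_occurrence_identity(self, toy_tax, seed):
        """mean_occurrences x open types == open tokens, exactly."""
        rng = np.random.default_rng(seed)
        pool = ["cat", "dog", "animal", "bank", "unicorn"]
        lemmas = [(pool[i], "noun") for i in rng.integers(0, 5, size=30)]
        p = extract_features(make_transcript(lemmas), toy_tax)
        assert p.mean_occurrences * p.n_open_types == p.n_open_tokens

    def test_frequency_lexicon_lookup_and_mean(self, toy_tax, tmp_path):
        fl = FrequencyLexicon({("cat", "noun"): 30.0, ("dog", None): 10.0})
        t = make_transcript(
            [("cat", "noun"), ("dog", "noun"), ("animal", "noun")]
        )
        p = extract_features(t, toy_tax, fl)
        assert p.mean_fu == pytest.approx(20.0)  # animal missing, skipped
        assert p.fu_coverage == pytest.approx(2 / 3)
        path = tmp_path / "f.tsv"
        fl.write(path)
        fl2 = FrequencyLexicon.read(path)
        assert fl2.lookup("cat", "noun") == 30.0
        assert fl2.lookup("dog", "verb") == 10.0  # pos-blind fallback


class TestTables:
    def test_profile_table_shape_and_order(self, toy_tax):
        ps = [
            extract_features(make_transcript([("cat", "noun")], speaker=s),
                             toy_tax)
            for s in ("a", "b")
        ]
        df = profile_table(ps)
        assert list(df.columns[2:15]) == list(FEATURE_COLUMNS)
        assert len(df) == 2

    def test_duplicate_speaker_rejected(self, toy_tax):
        p = extract_features(make_transcript([("cat", "noun")]), toy_tax)
        with pytest.raises(ValueError, match="duplicate"):
            profile_table([p, p])

    def test_group_summary_small(self, toy_tax):
        ps = [
            extract_features(
                make_transcript([("cat", "noun")] * n, speaker=f"s{n}"),
                toy_tax,
            )
            for n in (3, 5)
        ]
        gs = group_summary(ps, "svPPA")
        assert gs.loc["n_open_tokens", "mean"] == pytest.approx(4.0)
        assert gs.loc["n_open_tokens", "sd"] == pytest.approx(np.sqrt(2))

    def test_group_summary_absent_group(self, toy_tax):
        p = extract_features(make_transcript([("cat", "noun")]), toy_tax)
        with pytest.raises(ValueError, match="no profiles"):
            group_summary([p], "lvPPA")


class TestReferenceScores:
    def test_published_group_statistics_reproduced(self):
        """The bundled synthetic per-patient SDI scores reproduce the
        published group means and SDs to printed precision."""
        scores = load_individual_sdi_scores()
        sv, lv = scores["svPPA"], scores["lvPPA"]
        assert (len(sv), len(lv)) == (6, 16)
        assert round(float(np.mean(sv)), 2) == 3.99
        assert round(float(np.std(sv, ddof=1)), 2) == 0.32
        assert round(float(np.mean(lv)), 2) == 4.42
        assert round(float(np.std(lv, ddof=1)), 2) == 0.37
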