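"""Cleaning, negation-aware extraction, dot separating and integration."""

import re

import pytest
from hypothesis import given, settings, strategies as st

import lettertriage as lt
from lettertriage.preprocess import (NO_SYMPTOM_PLACEHOLDER, SymptomMention,
                                     join_symptoms_nodot, split_symptoms)
from conftest import R51_COMPLAINT, G40_COMPLAINT


class TestCleanText:
    def test_junk_and_greeting_removed(self):
        assert lt.clean_text("Dear Dr XXX, $$ sudden onset headache **") == \
            "sudden onset headache"

    def test_plain_text_unchanged_up_to_whitespace(self):
        assert lt.clean_text("sudden   onset\nheadache ") == "sudden onset headache"

    def test_idempotent_on_synthetic_corpus(self, noisy_letters):
        for letter in noisy_letters:
            once = lt.clean_text(letter.complaint)
            assert lt.clean_text(once) == once

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.text(alphabet=st.sampled_from("abc .,$*Å?X "), max_size=60))
    def test_idempotent_on_arbitrary_text(self, text):
        once = lt.clean_text(text)
        assert lt.clean_text(once) == once

    def test_empty_output_allowed(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            assert lt.clean_text("$$ ** ??") == ""


class TestExtractSymptoms:
    def test_published_r51_letter(self, r51_cleaned_mentions):
        cleaned, mentions = r51_cleaned_mentions
        positives = {m.canonical for m in mentions if not m.negated}
        negated = {m.canonical for m in mentions if m.negated}
        assert {"falling down", "dizziness", "pass out", "headache",
                "tunnel vision", "diplopia"} <= positives
        assert "lose consciousness" in negated

    def test_published_g40_letter(self, lexicon):
        cleaned = lt.clean_text(G40_COMPLAINT)
        mentions = lt.extract_symptoms(cleaned, lexicon)
        positives = {m.canonical for m in mentions if not m.negated}
        assert {"tonic-colonic seizures", "left-sided weakness", "fatigued"} <= positives
        # "has not had a seizure in 3 years" is a negated mention
        assert any(m.canonical == "seizure" and m.negated for m in mentions)

    def test_same_phrase_positive_then_negated(self, lexicon):
        mentions = lt.extract_symptoms("headache. no headache later", lexicon)
        assert [m.negated for m in mentions if m.canonical == "headache"] == \
            [False, True]

    def test_negation_does_not_cross_sentence_boundary(self, lexicon):
        mentions = lt.extract_symptoms("no improvement seen; headache persists",
                                       lexicon)
        (m,) = [m for m in mentions if m.canonical == "headache"]
        assert not m.negated

    def test_trigger_outside_window_is_ignored(self, lexicon):
        text = "not sure but over the last three days severe headache"
        mentions = lt.extract_symptoms(text, lexicon)
        (m,) = [m for m in mentions if m.canonical == "headache"]
        assert not m.negated

    def test_longest_match_wins(self, lexicon):
        mentions = lt.extract_symptoms("she had tonic-colonic seizures today", lexicon)
        assert [m.canonical for m in mentions] == ["tonic-colonic seizures"]

    def test_span_matches_surface_case_insensitively(self, noisy_letters, lexicon):
        for letter in noisy_letters:
            cleaned = lt.clean_text(letter.complaint)
            for m in lt.extract_symptoms(cleaned, lexicon):
                assert cleaned[m.span[0]:m.span[1]].lower() == m.phrase.lower()
                assert m.span[0] < m.span[1]

    def test_no_match_gives_empty_list(self, lexicon):
        assert lt.extract_symptoms("entirely unrelated text", lexicon) == []

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            lt.extract_symptoms("headache", [])


def _mention(canonical, negated=False):
    return SymptomMention(phrase=canonical, canonical=canonical,
                          span=(0, max(1, len(canonical))), negated=negated)


class TestDotSeparate:
    def test_join_format(self):
        ms = [_mention("falling down"), _mention("dizziness"), _mention("pass out")]
        assert lt.dot_separate(ms) == "falling down. dizziness. pass out."

    def test_negated_phrases_excluded(self):
        ms = [_mention("headache"), _mention("lose consciousness", negated=True)]
        assert lt.dot_separate(ms) == "headache."

    def test_empty_gives_placeholder(self):
        assert lt.dot_separate([]) == NO_SYMPTOM_PLACEHOLDER

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(
        st.sampled_from([p for code, ps in lt.builtin_lexicon().items() for p in ps]),
        st.booleans()), max_size=8))
    def test_split_recovers_positive_sequence(self, pairs):
        ms = [_mention(p.lower(), neg) for p, neg in pairs]
        positives = [m.canonical for m in ms if not m.negated]
        text = lt.dot_separate(ms)
        if positives:
            assert split_symptoms(text) == positives
        else:
            assert text == NO_SYMPTOM_PLACEHOLDER

    def test_nodot_ablation_joins_with_spaces(self):
        ms = [_mention("falling down"), _mention("dizziness")]
        assert join_symptoms_nodot(ms) == "falling down dizziness"


class TestIntegrate:
    def test_order_and_separator(self):
        assert lt.integrate("sudden onset headache", "headache.") == \
            "sudden onset headache [SEP] headache."

    def test_placeholder_passthrough(self):
        assert lt.integrate("a", "[NOSYM]") == "a [SEP] [NOSYM]"

    def test_exactly_one_sep(self, noisy_letters, lexicon):
        records, _ = lt.build_variants(list(noisy_letters), lexicon)
        for r in records:
            assert r.integration_text.count("[SEP]") == 1


class TestBuildVariants:
    def test_counts_and_labels_preserved(self, noisy_letters, lexicon):
        records, variants = lt.build_variants(list(noisy_letters), lexicon)
        assert len(records) == len(noisy_letters)
        for name in ("Symptoms", "Complaints", "Integration"):
            assert len(variants[name].records) == len(noisy_letters)
            assert [lab for _, lab in variants[name].records] == \
                [l.label for l in noisy_letters]

    def test_negated_phrases_never_reach_symptoms_text(self, noisy_letters, lexicon):
        records, _ = lt.build_variants(list(noisy_letters), lexicon)
        for r in records:
            for m in r.mentions:
                if m.negated and not any(
                        m2.canonical == m.canonical and not m2.negated
                        for m2 in r.mentions):
                    assert m.canonical not in r.symptoms_text

    def test_zero_noise_symptoms_variant_is_pure(self, separable_letters, lexicon):
        """With all noise off, symptom texts contain only lexicon phrases,
        dots and spaces."""
        records, variants = lt.build_variants(list(separable_letters), lexicon)
        allowed = {e.canonical for e in lexicon}
        for text, _ in variants["Symptoms"].records:
            assert text != NO_SYMPTOM_PLACEHOLDER
            for part in split_symptoms(text):
                assert part in allowed

    def test_variant_texts_match_record_fields(self, separable_letters, lexicon):
        records, variants = lt.build_variants(list(separable_letters), lexicon)
        assert [t for t, _ in variants["Complaints"].records] == \
            [r.cleaned_complaint for r in records]
        assert [t for t, _ in variants["Integration"].records] == \
            [r.integration_text for r in records]


class TestLexiconIO:
    def test_tsv_round_trip(self, tmp_path, lexicon):
        from lettertriage.preprocess import read_lexicon, write_lexicon
        path = tmp_path / "lex.tsv"
        write_lexicon(lexicon, path)
        assert read_lexicon(path) == lexicon
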