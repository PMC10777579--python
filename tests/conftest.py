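import pytest

import lettertriage as lt

# A published example referral letter for R51 (headache): the classic worked
# input for the preprocessing pipeline — positive symptoms plus one negated
# mention ("did not lose consciousness").
R51_COMPLAINT = (
    "We would be grateful if you could review this 56-year-old gentleman. "
    "He was admitted on 27-11-18 after falling down the stairs. Preceding "
    "dizziness where he felt he would pass out but did not lose consciousness. "
    "2 weeks ago, states developed sudden onset headache - vice-like, severity "
    "at start 8-10. Not positional. Right eyes have tunnel vision. On "
    "examination had reduced abduction right eye and diplopia. The case was "
    "discussed with Dr xxx who suggested MRI. The MRI report is as below and "
    "suggests a neurology review."
)

G40_COMPLAINT = (
    "We would be grateful for your assessment of this 47-year-old lady. She "
    "has known Epilepsy post-head-injury ten years ago and has not had a "
    "seizure in 3 years. She presented last week with 3 x tonic-colonic "
    "seizures, each of which terminated with Diazepam. She still has a "
    "residual left-sided weakness. She is still very fatigued and sleeping "
    "much of the day."
)


def zero_noise_config(**overrides):
    """All noise sources off: junk, distractors, negations and paraphrases."""
    base = dict(n_per_class=10, seed=3, junk_token_rate=0.0, distractor_rate=0.0,
                negated_phrases_per_letter=0, paraphrase_rate=0.0)
    base.update(overrides)
    return lt.SynthConfig(**base)


@pytest.fixture(scope="session")
def lexicon():
    return lt.default_lexicon_entries()


@pytest.fixture(scope="session")
def separable_letters():
    return lt.generate_corpus(zero_noise_config())


@pytest.fixture(scope="session")
def noisy_letters():
    return lt.generate_corpus(lt.SynthConfig(n_per_class=10, seed=7))


@pytest.fixture(scope="session")
def r51_cleaned_mentions(lexicon):
    cleaned = lt.clean_text(R51_COMPLAINT)
    return cleaned, lt.extract_symptoms(cleaned, lexicon)
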