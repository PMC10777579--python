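"""Preprocess one referral letter: cleaning, negation-aware symptom
extraction, dot separating and complaint-symptoms integration.

The input is a headache (R51) referral: the patient reports several positive
symptoms, and one symptom — losing consciousness — is explicitly denied, so
it must be excluded from the symptoms representation.
"""

import lettertriage as lt

LETTER = (
    "Dear Dr XXX, we would be grateful if you could review this 56-year-old "
    "gentleman. He was admitted after falling down the stairs. Preceding "
    "dizziness where he felt he would pass out but did not lose consciousness. "
    "$$ Two weeks ago developed sudden onset headache. Right eye has tunnel "
    "vision and diplopia on examination. **"
)

cleaned = lt.clean_text(LETTER)
print("cleaned complaint:")
print(" ", cleaned)

mentions = lt.extract_symptoms(cleaned, lt.default_lexicon_entries())
print("\nextracted mentions (negated symptoms are excluded downstream):")
for m in mentions:
    tag = "NEGATED " if m.negated else "positive"
    print(f"  [{tag}] {m.canonical!r} at {m.span}")

symptoms = lt.dot_separate(mentions)
print("\ndot-separated symptoms (CNN-friendly, no spurious word adjacency):")
print(" ", symptoms)

print("\nintegration text (network input: context + [SEP] + key symptoms):")
print(" ", lt.integrate(cleaned, symptoms))
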