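"""Synthetic GP referral-letter corpus for four neurological ICD classes.

The real letters this package targets are clinical free text written by a
general practitioner to a neurology specialist, labelled with the ICD code
of the specialist's final diagnosis: G40 (epilepsy-recurrent seizures),
R51 (headache), M54 (dorsalgia) and I63 (cerebral infarction). No such
corpus can be redistributed, so this module generates letters with the same
statistical skeleton: long complaint narratives carrying class-indicative
multi-word symptom phrases, explicitly negated mentions of *other* classes'
symptoms, greeting/closing boilerplate, and OCR-style junk tokens.

Every draw goes through a single seeded generator, so a config is a complete
description of its corpus.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

JUNK_TOKENS = ("$$", "**", "Å", "??", "XXX")

#: Negation triggers shared with the extractor, so injected negations are
#: detectable downstream.
NEGATION_TRIGGERS = ("no", "not", "did not", "denies", "without", "never")


@dataclass(frozen=True)
class DiseaseLabel:
    """One of the four admissible ICD-coded diagnoses."""

    code: str
    name: str


LABELS: tuple[DiseaseLabel, ...] = (
    DiseaseLabel("G40", "epilepsy-recurrent seizures"),
    DiseaseLabel("R51", "headache"),
    DiseaseLabel("M54", "dorsalgia"),
    DiseaseLabel("I63", "cerebral infarction"),
)

CODE_TO_LABEL = {lab.code: lab for lab in LABELS}
CODE_TO_INDEX = {lab.code: i for i, lab in enumerate(LABELS)}


def label_for(code: str) -> DiseaseLabel:
    try:
        return CODE_TO_LABEL[code]
    except KeyError:
        raise ValueError(
            f"unknown disease code {code!r}; admissible: {sorted(CODE_TO_LABEL)}"
        ) from None


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; defaults are the package's study conditions."""

    n_per_class: int = 64
    signal_phrases_per_letter: int = 3
    negated_phrases_per_letter: int = 1
    junk_token_rate: float = 0.05
    distractor_rate: float = 0.3
    paraphrase_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.signal_phrases_per_letter < 1:
            raise ValueError("signal_phrases_per_letter must be >= 1")
        if self.negated_phrases_per_letter < 0:
            raise ValueError("negated_phrases_per_letter must be >= 0")
        for name in ("junk_token_rate", "distractor_rate", "paraphrase_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")


@dataclass(frozen=True)
class ReferralLetter:
    id: str
    complaint: str
    label: DiseaseLabel

    def __post_init__(self):
        if not self.complaint:
            raise ValueError("complaint must be nonempty")
        if self.label.code not in CODE_TO_LABEL:
            raise ValueError(f"inadmissible label {self.label.code!r}")


# -- lexicon ------------------------------------------------------------------

#: Class-indicative multi-word symptom phrases. Class lists are pairwise
#: disjoint; "shared" holds distractor phrases that carry no class signal
#: (investigations and administrativa common to every clinic letter).
_BUILTIN: dict[str, list[str]] = {
    "G40": [
        "tonic-colonic seizures",
        "seizure",
        "left-sided weakness",
        "fatigued",
        "sleeping much of the day",
        "epilepsy",
        "post-ictal confusion",
    ],
    "R51": [
        "tunnel vision",
        "pass out",
        "falling down",
        "dizziness",
        "diplopia",
        "headache",
        "lose consciousness",
        "vice-like pain",
    ],
    "M54": [
        "back pain",
        "leg pain",
        "numbness in the thighs",
        "decreased sensation",
        "unable to flex the hips",
        "sciatica",
        "lumbar tenderness",
    ],
    "I63": [
        "left arm weakness",
        "muscular dystrophy",
        "subdural haematomas",
        "volume loss",
        "slurred speech",
        "facial droop",
        "transient ischaemic attack",
    ],
    "shared": [
        "mri scan",
        "ct scan",
        "blood test",
        "physiotherapy referral",
    ],
}


def builtin_lexicon() -> dict[str, list[str]]:
    """Symptom phrase lists keyed by disease code, plus a "shared" distractor
    list. Class lists are pairwise disjoint by construction."""
    return {k: list(v) for k, v in _BUILTIN.items()}


#: Paraphrased renderings of the lexicon phrases. Real extractors miss
#: reworded symptoms, so letters sometimes describe a symptom in words the
#: lexicon cannot match; the class signal then survives only in the
#: complaint (and hence the integration) text. None of these contains any
#: lexicon surface form.
_PARAPHRASES: dict[str, str] = {
    "tonic-colonic seizures": "convulsive episodes with jerking of all four limbs",
    "seizure": "a witnessed convulsion",
    "left-sided weakness": "weakness down the left side",
    "fatigued": "profoundly tired",
    "sleeping much of the day": "somnolent for most of the day",
    "epilepsy": "known fits since childhood",
    "post-ictal confusion": "prolonged confusion after the episodes",
    "tunnel vision": "constricted peripheral fields",
    "pass out": "nearly blacking out",
    "falling down": "a tumble down the stairs",
    "dizziness": "light-headedness",
    "diplopia": "double vision",
    "headache": "severe pain in the head",
    "lose consciousness": "loss of awareness",
    "vice-like pain": "a crushing band-like sensation",
    "back pain": "an aching lumbar region",
    "leg pain": "aching in both legs",
    "numbness in the thighs": "reduced feeling over the thighs",
    "decreased sensation": "dulled sensation distally",
    "unable to flex the hips": "restricted hip flexion",
    "sciatica": "shooting pains radiating down the legs",
    "lumbar tenderness": "tenderness over the lower spine",
    "left arm weakness": "reduced power in the left arm",
    "muscular dystrophy": "a long-standing muscle-wasting condition",
    "subdural haematomas": "bleeding over the brain surface",
    "volume loss": "generalised shrinkage on imaging",
    "slurred speech": "indistinct speech",
    "facial droop": "asymmetry of the lower face",
    "transient ischaemic attack": "a brief stroke-like episode",
}

#: Class-indicative context cues (medications, investigations, management)
#: that no symptom lexicon would list. They emulate the complaint-only class
#: signal real referral letters carry beyond their symptom mentions.
_CONTEXT_CUES: dict[str, tuple[str, ...]] = {
    "G40": ("Carbamazepine 400mg BD was restarted on the ward.",
            "Clobazam was given as cover for the next ten days.",
            "An EEG has been requested by the admitting team."),
    "R51": ("Sumatriptan gave only partial relief.",
            "Fundoscopy in clinic was unremarkable.",
            "A lumbar puncture was considered and deferred."),
    "M54": ("An MRI of the lumbar spine is awaited.",
            "Naproxen provides little relief by her account.",
            "Straight leg raise was limited on the left."),
    "I63": ("The stroke team started Clopidogrel on discharge.",
            "A carotid doppler has been requested.",
            "A CT head was performed on admission."),
}


# -- letter assembly ----------------------------------------------------------

_GREETINGS = (
    "Dear Dr XXX, we would be grateful if you could review this patient.",
    "Dear Dr XXX, many thanks for seeing this patient in your clinic.",
    "Dear Dr XXX, we would be grateful for your assessment of this patient.",
)

_DEMOGRAPHICS = (
    "This {age}-year-old {sex} was admitted on the medical take last week.",
    "The patient is a {age}-year-old {sex} with a long past medical history.",
    "A {age}-year-old {sex} presented to the surgery earlier this month.",
)

_SYMPTOM_TEMPLATES = (
    "The patient reports {p}.",
    "She describes {p} over the last fortnight.",
    "He presented with {p} of sudden onset.",
    "On examination there is clear evidence of {p}.",
    "The history is dominated by {p}.",
)

_NEGATION_TEMPLATES = (
    "She denies {p}.",
    "He did not report {p}.",
    "There was no {p}.",
    "The patient is without {p}.",
    "She has never experienced {p}.",
)

_DISTRACTOR_TEMPLATES = (
    "An {p} has been arranged for next week.",
    "A routine {p} was requested by the ward team.",
)

_CLOSINGS = (
    "Many thanks for your review.",
    "Yours sincerely, Dr XXX.",
    "Kind regards, the practice team.",
)


def _inject_junk(text: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return text
    out = []
    for tok in text.split(" "):
        out.append(tok)
        if rng.random() < rate:
            out.append(JUNK_TOKENS[rng.integers(len(JUNK_TOKENS))])
    return " ".join(out)


def generate_corpus(cfg: SynthConfig) -> list[ReferralLetter]:
    """Generate ``4 * n_per_class`` labelled letters, deterministic in ``cfg``."""
    lex = builtin_lexicon()
    rng = np.random.default_rng(cfg.seed)
    letters: list[ReferralLetter] = []
    for label in LABELS:
        own = lex[label.code]
        other = [p for lab in LABELS if lab.code != label.code for p in lex[lab.code]]
        for j in range(cfg.n_per_class):
            sentences = [
                _GREETINGS[rng.integers(len(_GREETINGS))],
                _DEMOGRAPHICS[rng.integers(len(_DEMOGRAPHICS))].format(
                    age=int(rng.integers(18, 90)),
                    sex=["gentleman", "lady"][rng.integers(2)],
                ),
            ]
            picks = rng.choice(len(own), size=min(cfg.signal_phrases_per_letter, len(own)),
                               replace=False)
            for p in picks:
                tpl = _SYMPTOM_TEMPLATES[rng.integers(len(_SYMPTOM_TEMPLATES))]
                phrase = own[p]
                if rng.random() < cfg.paraphrase_rate:
                    phrase = _PARAPHRASES.get(phrase, phrase)
                sentences.append(tpl.format(p=phrase))
            cues = _CONTEXT_CUES[label.code]
            sentences.append(cues[rng.integers(len(cues))])
            neg_picks = rng.choice(len(other), size=min(cfg.negated_phrases_per_letter,
                                                        len(other)), replace=False)
            for p in neg_picks:
                tpl = _NEGATION_TEMPLATES[rng.integers(len(_NEGATION_TEMPLATES))]
                sentences.append(tpl.format(p=other[p]))
            for p in lex["shared"]:
                if rng.random() < cfg.distractor_rate:
                    tpl = _DISTRACTOR_TEMPLATES[rng.integers(len(_DISTRACTOR_TEMPLATES))]
                    sentences.append(tpl.format(p=p))
            sentences.append(_CLOSINGS[rng.integers(len(_CLOSINGS))])
            # keep greeting first and closing last; shuffle the clinical middle
            middle = sentences[2:-1]
            rng.shuffle(middle)
            body = " ".join(sentences[:2] + middle + sentences[-1:])
            body = _inject_junk(body, cfg.junk_token_rate, rng)
            letters.append(
                ReferralLetter(id=f"{label.code}-{j:04d}", complaint=body, label=label)
            )
    return letters


def lexicon_overlap_label(complaint: str, lexicon: dict[str, list[str]] | None = None
                          ) -> DiseaseLabel:
    """Brute-force oracle: the class whose phrase list has the most hits.

    Ignores negation entirely; intended for separability checks on noise-free
    corpora, not as a classifier. Ties break by class order G40,R51,M54,I63.
    """
    lexicon = lexicon if lexicon is not None else builtin_lexicon()
    low = complaint.lower()
    counts = []
    for lab in LABELS:
        c = 0
        for phrase in lexicon[lab.code]:
            c += len(re.findall(r"(?<!\w)" + re.escape(phrase.lower()) + r"(?!\w)", low))
        counts.append(c)
    return LABELS[int(np.argmax(counts))]


# -- file IO ------------------------------------------------------------------

class CorpusParseError(ValueError):
    pass


def write_corpus(letters: list[ReferralLetter], path: str | Path) -> None:
    """Write letters as CSV/TSV (by extension) or JSON-lines (.jsonl). UTF-8."""
    path = Path(path)
    if path.suffix == ".jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for let in letters:
                fh.write(json.dumps(
                    {"id": let.id, "complaint": let.complaint, "label": let.label.code},
                    ensure_ascii=False) + "\n")
        return
    delim = "\t" if path.suffix in (".tsv", ".tab") else ","
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["id", "complaint", "label"])
        for let in letters:
            writer.writerow([let.id, let.complaint, let.label.code])


def read_corpus(path: str | Path) -> list[ReferralLetter]:
    """Read a corpus file written by :func:`write_corpus` (or hand-made in the
    same dialects). Malformed rows raise :class:`CorpusParseError` naming the
    line number; an empty file yields an empty list with a logged warning."""
    path = Path(path)
    letters: list[ReferralLetter] = []
    if path.suffix == ".jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for ln, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                    letters.append(ReferralLetter(
                        id=str(rec["id"]), complaint=rec["complaint"],
                        label=label_for(rec["label"])))
                except (KeyError, ValueError) as exc:
                    raise CorpusParseError(f"{path} line {ln}: {exc}") from exc
    else:
        delim = "\t" if path.suffix in (".tsv", ".tab") else ","
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter=delim)
            header = next(reader, None)
            if header is not None and [h.strip().lower() for h in header] != [
                    "id", "complaint", "label"]:
                raise CorpusParseError(
                    f"{path} line 1: expected header id{delim}complaint{delim}label")
            for ln, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) != 3:
                    raise CorpusParseError(f"{path} line {ln}: expected 3 fields, got {len(row)}")
                try:
                    letters.append(ReferralLetter(
                        id=row[0], complaint=row[1], label=label_for(row[2])))
                except ValueError as exc:
                    raise CorpusParseError(f"{path} line {ln}: {exc}") from exc
    if not letters:
        logger.warning("corpus file %s is empty", path)
    return letters
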