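"""Four-stage preprocessing of referral-letter complaints.

1. *Cleaning* — strip OCR/email junk tokens ($$, **, Å, ??, XXX) and standard
   greeting boilerplate, collapse whitespace.
2. *Symptom extraction* — deterministic longest-match lexicon matching with a
   NegEx-style negation rule: a mention is negated when a trigger ("no",
   "not", "did not", "denies", "without", "never") occurs within a five-token
   window before it inside the same sentence.
3. *Symptom dot separating* — join the positive (non-negated) canonical
   phrases with a dot separator, so adjacent multi-word symptoms form no
   spurious word-to-word dependencies when fed to a sequence model.
4. *Complaint–symptoms integration* — concatenate the cleaned complaint and
   the dot-separated symptoms around a single "[SEP]" marker, keeping the
   narrative context while highlighting the key clinical information.

From one corpus the module derives three dataset variants — Symptoms,
Complaints and Integration — plus a no-dot ablation of the Symptoms variant.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .corpus import (CODE_TO_INDEX, DiseaseLabel, JUNK_TOKENS, ReferralLetter,
                     builtin_lexicon)

logger = logging.getLogger(__name__)

NO_SYMPTOM_PLACEHOLDER = "[NOSYM]"
SEP_TOKEN = "[SEP]"

NEGATION_TRIGGERS = ("no", "not", "did not", "denies", "without", "never")
NEGATION_WINDOW = 5  # tokens between trigger and symptom onset
SENTENCE_BOUNDARY = ".;?!"

DEFAULT_GREETINGS = (
    "dear dr",
    "we would be grateful if you could review",
    "we would be grateful for your assessment of",
    "many thanks for seeing",
    "many thanks for your review",
    "thank you for seeing",
    "yours sincerely",
    "kind regards",
)


# -- Step 1: cleaning ---------------------------------------------------------

def clean_text(raw: str, greetings: tuple[str, ...] = DEFAULT_GREETINGS) -> str:
    """Remove junk tokens and greeting phrases; normalise whitespace.

    Removal is case-insensitive and purely by character matching; apart from
    stray punctuation orphaned at the very start of the text, no other
    characters are altered. Idempotent.
    """
    def one_pass(text: str) -> str:
        for junk in JUNK_TOKENS:
            text = re.sub(re.escape(junk), " ", text, flags=re.IGNORECASE)
        text = re.sub(r"\s+", " ", text)
        for phrase in greetings:
            text = re.sub(re.escape(phrase), " ", text, flags=re.IGNORECASE)
        text = re.sub(r"\s+", " ", text).strip()
        # punctuation left dangling at the start by a removed greeting
        return re.sub(r"^[,;:. ]+", "", text)

    # a junk token can split a greeting phrase, so iterate to a fixpoint
    text = one_pass(raw)
    for _ in range(8):
        again = one_pass(text)
        if again == text:
            break
        text = again
    if not text:
        logger.warning("clean_text produced empty output")
    return text


# -- Step 2: extraction -------------------------------------------------------

@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    canonical: str
    class_hint: str = ""  # disease code, or "" for shared/neutral phrases


def default_lexicon_entries() -> list[LexiconEntry]:
    """Flatten the built-in class lexicon into extractor entries.

    Canonical forms are the lower-cased headwords; the class hint is kept for
    the corpus generator and is irrelevant to extraction.
    """
    entries = []
    for code, phrases in builtin_lexicon().items():
        hint = "" if code == "shared" else code
        for p in phrases:
            entries.append(LexiconEntry(surface=p, canonical=p.lower(), class_hint=hint))
    return entries


def read_lexicon(path: str | Path) -> list[LexiconEntry]:
    """Read a TSV lexicon with columns surface_phrase, canonical[, class_hint]."""
    entries = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        for ln, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path} line {ln}: need surface and canonical columns")
            entries.append(LexiconEntry(
                surface=row[0].strip(), canonical=row[1].strip(),
                class_hint=row[2].strip() if len(row) > 2 else ""))
    return entries


def write_lexicon(entries: list[LexiconEntry], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["surface_phrase", "canonical", "class_hint"])
        for e in entries:
            writer.writerow([e.surface, e.canonical, e.class_hint])


@dataclass(frozen=True)
class SymptomMention:
    phrase: str            # surface text as matched
    canonical: str         # lexicon headword
    span: tuple[int, int]  # [start, end) into the cleaned complaint
    negated: bool

    def __post_init__(self):
        if not self.span[0] < self.span[1]:
            raise ValueError("span must satisfy start < end")


_TOKEN_RE = re.compile(r"[^\s" + re.escape(SENTENCE_BOUNDARY) + r"]+")


def _is_negated(cleaned: str, start: int) -> bool:
    """Trigger within NEGATION_WINDOW tokens before position `start`, same sentence."""
    sent_start = 0
    for m in re.finditer("[" + re.escape(SENTENCE_BOUNDARY) + "]", cleaned[:start]):
        sent_start = m.end()
    preceding = _TOKEN_RE.findall(cleaned[sent_start:start])
    window = [t.lower().strip(",:()") for t in preceding[-NEGATION_WINDOW:]]
    return any(t in ("no", "not", "denies", "without", "never") for t in window)


def extract_symptoms(cleaned: str, lexicon: list[LexiconEntry]) -> list[SymptomMention]:
    """All longest, non-overlapping, case-insensitive lexicon matches, left to
    right, each flagged negated when a negation trigger precedes it within the
    window inside the same sentence."""
    if not lexicon:
        raise ValueError("lexicon must be nonempty")
    candidates: list[tuple[int, int, LexiconEntry]] = []
    for entry in lexicon:
        pat = r"(?<!\w)" + re.escape(entry.surface) + r"(?!\w)"
        for m in re.finditer(pat, cleaned, flags=re.IGNORECASE):
            candidates.append((m.start(), m.end(), entry))
    # prefer earliest start, then longest match
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
    mentions: list[SymptomMention] = []
    cursor = 0
    for start, end, entry in candidates:
        if start < cursor:
            continue
        mentions.append(SymptomMention(
            phrase=cleaned[start:end], canonical=entry.canonical,
            span=(start, end), negated=_is_negated(cleaned, start)))
        cursor = end
    return mentions


# -- Steps 3 & 4: dot separating and integration ------------------------------

def dot_separate(mentions: list[SymptomMention]) -> str:
    """Join positive canonical phrases with ". " and a trailing "."; the
    placeholder stands in when nothing positive was found."""
    positives = [m.canonical for m in mentions if not m.negated]
    if not positives:
        return NO_SYMPTOM_PLACEHOLDER
    return ". ".join(positives) + "."


def join_symptoms_nodot(mentions: list[SymptomMention]) -> str:
    """Ablation form of Step 3: positive phrases joined by spaces only."""
    positives = [m.canonical for m in mentions if not m.negated]
    return " ".join(positives) if positives else NO_SYMPTOM_PLACEHOLDER


def split_symptoms(symptoms_text: str) -> list[str]:
    """Inverse of :func:`dot_separate` for non-placeholder output."""
    if symptoms_text == NO_SYMPTOM_PLACEHOLDER:
        return []
    return [p.strip() for p in symptoms_text.split(".") if p.strip()]


def integrate(cleaned: str, symptoms_text: str) -> str:
    """Cleaned complaint, one "[SEP]", then the symptoms text."""
    return f"{cleaned} {SEP_TOKEN} {symptoms_text}"


# -- full records and dataset variants ----------------------------------------

@dataclass(frozen=True)
class ProcessedRecord:
    id: str
    label: DiseaseLabel
    cleaned_complaint: str
    mentions: tuple[SymptomMention, ...]
    symptoms_text: str
    integration_text: str

    @property
    def symptoms_nodot_text(self) -> str:
        return join_symptoms_nodot(list(self.mentions))

    @property
    def label_index(self) -> int:
        return CODE_TO_INDEX[self.label.code]


VARIANT_NAMES = ("Symptoms", "Complaints", "Integration")


@dataclass(frozen=True)
class DatasetVariant:
    name: str
    records: tuple[tuple[str, DiseaseLabel], ...]  # (text, label)


def process_letter(letter: ReferralLetter, lexicon: list[LexiconEntry],
                   greetings: tuple[str, ...] = DEFAULT_GREETINGS) -> ProcessedRecord:
    cleaned = clean_text(letter.complaint, greetings)
    mentions = extract_symptoms(cleaned, lexicon)
    symptoms = dot_separate(mentions)
    return ProcessedRecord(
        id=letter.id, label=letter.label, cleaned_complaint=cleaned,
        mentions=tuple(mentions), symptoms_text=symptoms,
        integration_text=integrate(cleaned, symptoms))


def build_variants(letters: list[ReferralLetter], lexicon: list[LexiconEntry] | None = None,
                   greetings: tuple[str, ...] = DEFAULT_GREETINGS
                   ) -> tuple[list[ProcessedRecord], dict[str, DatasetVariant]]:
    """Process every letter and assemble the three dataset variants (plus the
    SymptomsNoDot ablation) with labels preserved."""
    if not letters:
        raise ValueError("letters must be nonempty")
    lexicon = lexicon if lexicon is not None else default_lexicon_entries()
    records = [process_letter(let, lexicon, greetings) for let in letters]
    variants = {
        "Symptoms": DatasetVariant(
            "Symptoms", tuple((r.symptoms_text, r.label) for r in records)),
        "Complaints": DatasetVariant(
            "Complaints", tuple((r.cleaned_complaint, r.label) for r in records)),
        "Integration": DatasetVariant(
            "Integration", tuple((r.integration_text, r.label) for r in records)),
        "SymptomsNoDot": DatasetVariant(
            "SymptomsNoDot", tuple((r.symptoms_nodot_text, r.label) for r in records)),
    }
    return records, variants


def write_records_jsonl(records: list[ProcessedRecord], path: str | Path) -> None:
    import json
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps({
                "id": r.id, "label": r.label.code,
                "cleaned_complaint": r.cleaned_complaint,
                "mentions": [
                    {"phrase": m.phrase, "canonical": m.canonical,
                     "span": list(m.span), "negated": m.negated}
                    for m in r.mentions],
                "symptoms_text": r.symptoms_text,
                "integration_text": r.integration_text,
            }, ensure_ascii=False) + "\n")


def write_variant(variant: DatasetVariant, path: str | Path) -> None:
    """Variant corpora reuse the corpus CSV/TSV dialect (id,complaint,label)."""
    import csv as _csv
    path = Path(path)
    delim = "\t" if path.suffix in (".tsv", ".tab") else ","
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = _csv.writer(fh, delimiter=delim)
        writer.writerow(["id", "complaint", "label"])
        for i, (text, label) in enumerate(variant.records):
            writer.writerow([f"{variant.name.lower()}-{i:04d}", text, label.code])
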