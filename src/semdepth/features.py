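"""Per-speaker microlinguistic feature profile of a narrative transcript.

The profile row holds, per speaker: distinct-lemma (type) counts for
nouns, verbs and adjectives; token counts for open- and closed-class
words; well-formed sentence count; paraphasia and word-finding event
counts; mean number of occurrences (open tokens / open types); mean
lexical frequency of use (FU, occurrences per million); and the mean
Semantic Depth Index over scored open-class words.

Counting conventions: noun/verb/adjective counters are type counts keyed
by (lemma, class); open/closed counters are token counts over non-excluded
tokens; adverbs count toward open-class tokens and types but have no
dedicated type counter.  ``mean_occurrences`` is kept as an exact Fraction
so the identity mean_occurrences x open types = open tokens holds exactly.
Words missing from the taxonomy or the frequency lexicon are skipped (and
surfaced via ``sdi_coverage`` / ``fu_coverage``), never imputed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .taxonomy import Taxonomy, sdi_for_word
from .transcripts import OPEN_WORD_CLASSES, Transcript, TranscriptError

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureProfile",
    "FrequencyLexicon",
    "extract_features",
    "profile_table",
    "group_summary",
]

# fixed output column order (mirrors the group-comparison table row order)
FEATURE_COLUMNS = (
    "n_noun_types",
    "n_verb_types",
    "n_adj_types",
    "n_open_tokens",
    "n_closed_tokens",
    "n_correct_sentences",
    "n_phonemic_paraphasias",
    "n_semantic_paraphasias",
    "n_anomic_pauses",
    "n_cda",
    "mean_occurrences",
    "mean_sdi",
    "mean_fu",
)


class FrequencyLexicon:
    """Corpus frequency-of-use norms: (lemma, pos) -> occurrences per million.

    The two-column dialect (``lemma<TAB>fpm``) stores pos-blind entries;
    the three-column dialect (``lemma<TAB>pos<TAB>fpm``) is pos-specific.
    Lookup tries the pos-specific entry first, then the pos-blind one.
    """

    def __init__(self, entries: dict[tuple[str, str | None], float]):
        for (lemma, _pos), f in entries.items():
            if f < 0:
                raise ValueError(f"negative frequency for {lemma!r}")
        self._entries = {
            (lemma.casefold(), pos): f for (lemma, pos), f in entries.items()
        }

    def lookup(self, lemma: str, pos: str) -> float | None:
        lemma = lemma.casefold()
        hit = self._entries.get((lemma, pos))
        if hit is None:
            hit = self._entries.get((lemma, None))
        return hit

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def read(cls, path: str | Path) -> "FrequencyLexicon":
        entries: dict[tuple[str, str | None], float] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) == 2:
                    lemma, pos, fpm = fields[0], None, fields[1]
                elif len(fields) == 3:
                    lemma, pos, fpm = fields[0], fields[1], fields[2]
                else:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 2 or 3 fields"
                    )
                entries[(lemma, pos)] = float(fpm)
        return cls(entries)

    def write(self, path: str | Path) -> None:
        lines = []
        for (lemma, pos) in sorted(
            self._entries, key=lambda k: (k[0], k[1] or "")
        ):
            f = self._entries[(lemma, pos)]
            if pos is None:
                lines.append(f"{lemma}\t{f!r}")
            else:
                lines.append(f"{lemma}\t{pos}\t{f!r}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class FeatureProfile:
    speaker_id: str
    group: str
    n_noun_types: int
    n_verb_types: int
    n_adj_types: int
    n_open_types: int
    n_open_tokens: int
    n_closed_tokens: int
    n_correct_sentences: int
    n_phonemic_paraphasias: int
    n_semantic_paraphasias: int
    n_anomic_pauses: int
    n_cda: int
    mean_occurrences: Fraction | None
    mean_fu: float | None
    mean_sdi: Fraction | None
    sdi_coverage: float
    fu_coverage: float


def extract_features(
    t: Transcript,
    tax: Taxonomy,
    fl: FrequencyLexicon | None = None,
    policy: str = "first_sense",
    sdi_weighting: str = "type",
) -> FeatureProfile:
    """Derive the feature profile of one (typically task-merged) transcript.

    ``sdi_weighting="type"`` averages the SDI over distinct open-class
    lemmas (each word counted once however often it recurs);  ``"token"``
    weights each lemma by its occurrence count.
    """
    if sdi_weighting not in ("type", "token"):
        raise ValueError(f"sdi_weighting must be 'type' or 'token', got {sdi_weighting!r}")
    if not t.utterances or not t.tokens:
        raise TranscriptError(f"empty transcript for speaker {t.speaker_id!r}")

    open_counts: Counter[tuple[str, str]] = Counter()  # (lemma, class) -> tokens
    n_closed = 0
    n_phon = n_sem = 0
    for tok in t.tokens:
        n_phon += "phonemic_paraphasia" in tok.error_tags
        n_sem += "semantic_paraphasia" in tok.error_tags
        if tok.excluded:
            continue
        if tok.word_class in OPEN_WORD_CLASSES:
            open_counts[(tok.lemma, tok.word_class)] += 1
        elif tok.word_class == "closed":
            n_closed += 1

    class_types = Counter(wc for (_, wc) in open_counts)
    n_open_types = len(open_counts)
    n_open_tokens = sum(open_counts.values())

    sdi_num = Fraction(0)
    sdi_wt = 0
    n_scored_types = 0
    fu_sum = 0.0
    fu_n = 0
    for (lemma, wc), n_occ in open_counts.items():
        w = n_occ if sdi_weighting == "token" else 1
        val = sdi_for_word(tax, lemma, wc, policy=policy)
        if val.found:
            sdi_num += Fraction(val.sdi) * w
            sdi_wt += w
            n_scored_types += 1
        if fl is not None:
            fpm = fl.lookup(lemma, wc)
            if fpm is not None:
                fu_sum += fpm
                fu_n += 1

    events = Counter(ev for utt in t.utterances for ev in utt.events)

    return FeatureProfile(
        speaker_id=t.speaker_id,
        group=t.group,
        n_noun_types=class_types["noun"],
        n_verb_types=class_types["verb"],
        n_adj_types=class_types["adjective"],
        n_open_types=n_open_types,
        n_open_tokens=n_open_tokens,
        n_closed_tokens=n_closed,
        n_correct_sentences=sum(u.well_formed for u in t.utterances),
        n_phonemic_paraphasias=n_phon,
        n_semantic_paraphasias=n_sem,
        n_anomic_pauses=events["anomic_pause"],
        n_cda=events["cda"],
        mean_occurrences=(
            Fraction(n_open_tokens, n_open_types) if n_open_types else None
        ),
        mean_fu=(fu_sum / fu_n) if fu_n else None,
        mean_sdi=(sdi_num / sdi_wt) if sdi_wt else None,
        sdi_coverage=(n_scored_types / n_open_types) if n_open_types else 0.0,
        fu_coverage=(fu_n / n_open_types) if n_open_types else 0.0,
    )


def profile_table(profiles: Sequence[FeatureProfile]) -> pd.DataFrame:
    """One row per speaker in the fixed FEATURE_COLUMNS order."""
    ids = [p.speaker_id for p in profiles]
    dupes = [s for s, c in Counter(ids).items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate speaker id(s): {sorted(dupes)}")
    rows = []
    for p in profiles:
        row: dict[str, object] = {"speaker": p.speaker_id, "group": p.group}
        for col in FEATURE_COLUMNS:
            v = getattr(p, col)
            row[col] = float(v) if isinstance(v, Fraction) else (
                math.nan if v is None else v
            )
        row["sdi_coverage"] = p.sdi_coverage
        rows.append(row)
    cols = ["speaker", "group", *FEATURE_COLUMNS, "sdi_coverage"]
    return pd.DataFrame(rows, columns=cols)


def group_summary(
    profiles: Sequence[FeatureProfile], group: str
) -> pd.DataFrame:
    """Per-feature mean and sample SD (n-1 denominator) within one group."""
    members = [p for p in profiles if p.group == group]
    if not members:
        raise ValueError(f"no profiles in group {group!r}")
    if len(members) < 2:
        raise ValueError(f"group {group!r} needs >= 2 profiles for an SD")
    table = profile_table(members)
    feats = table[list(FEATURE_COLUMNS)].astype(float)
    return pd.DataFrame(
        {"mean": feats.mean(), "sd": feats.std(ddof=1), "n": len(members)}
    )
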