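"""Data model and I/O for annotated narrative-speech transcripts.

Annotation (word class, paraphasia tags, sentence well-formedness,
anomic-pause / conduite-d'approche events) is *input*: the examiner codes
it, the pipeline consumes it.  Fillers and false starts are tokens flagged
``excluded`` so they never enter lexical counts; anomic pauses and CDA are
utterance-level events, not words.

Dialect (UTF-8, tab-separated, one row per token)::

    speaker  group  task  utt_id  well_formed  events  surface  lemma  word_class  error_tags

``events`` and ``error_tags`` are comma-joined, ``.`` for none; utterance
events appear on the utterance's first row only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "WORD_CLASSES",
    "OPEN_WORD_CLASSES",
    "ERROR_TAGS",
    "EVENT_TAGS",
    "TASKS",
    "Token",
    "Utterance",
    "Transcript",
    "TranscriptError",
    "TranscriptParseError",
    "read_transcripts",
    "write_transcripts",
    "merge_speaker",
]

WORD_CLASSES = ("noun", "verb", "adjective", "adverb", "closed", "filler")
OPEN_WORD_CLASSES = ("noun", "verb", "adjective", "adverb")
ERROR_TAGS = ("phonemic_paraphasia", "semantic_paraphasia", "false_start")
EVENT_TAGS = ("anomic_pause", "cda")
# canonical task order: two picture descriptions, two story topics, conversation
TASKS = ("cookie_theft", "picnic", "illness", "typical_day", "conversation")


class TranscriptError(ValueError):
    pass


class TranscriptParseError(TranscriptError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True, slots=True)
class Token:
    surface: str
    lemma: str
    word_class: str
    error_tags: frozenset[str] = frozenset()
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.word_class not in WORD_CLASSES:
            raise TranscriptError(f"unknown word_class {self.word_class!r}")
        bad = set(self.error_tags) - set(ERROR_TAGS)
        if bad:
            raise TranscriptError(f"unknown error tag(s) {sorted(bad)}")
        if self.word_class == "filler" and not self.excluded:
            object.__setattr__(self, "excluded", True)  # filler => excluded
        if "false_start" in self.error_tags and not self.excluded:
            object.__setattr__(self, "excluded", True)
        if not self.lemma and not self.excluded:
            raise TranscriptError("non-excluded token with empty lemma")


@dataclass(frozen=True, slots=True)
class Utterance:
    tokens: tuple[Token, ...]
    well_formed: bool = False
    events: tuple[str, ...] = ()  # multiset; repeats allowed

    def __post_init__(self) -> None:
        bad = set(self.events) - set(EVENT_TAGS)
        if bad:
            raise TranscriptError(f"unknown event tag(s) {sorted(bad)}")


@dataclass(frozen=True, slots=True)
class Transcript:
    speaker_id: str
    group: str
    task: str
    utterances: tuple[Utterance, ...]

    def __post_init__(self) -> None:
        if not self.speaker_id:
            raise TranscriptError("empty speaker_id")
        if self.task not in TASKS:
            raise TranscriptError(f"unknown task {self.task!r}")

    @property
    def tokens(self) -> list[Token]:
        return [tok for utt in self.utterances for tok in utt.tokens]


_HEADER = (
    "speaker\tgroup\ttask\tutt_id\twell_formed\tevents\t"
    "surface\tlemma\tword_class\terror_tags"
)


def _join(tags: Iterable[str]) -> str:
    tags = list(tags)
    return ",".join(tags) if tags else "."


def _split(fieldval: str) -> tuple[str, ...]:
    return () if fieldval == "." else tuple(fieldval.split(","))


def read_transcripts(path: str | Path) -> list[Transcript]:
    """Parse the transcript dialect into one Transcript per (speaker, task)."""
    transcripts: list[Transcript] = []
    cur_key: tuple[str, str, str] | None = None  # (speaker, group, task)
    cur_utts: list[Utterance] = []
    cur_uid: str | None = None
    cur_tokens: list[Token] = []
    cur_wf = False
    cur_events: tuple[str, ...] = ()

    def flush_utt() -> None:
        nonlocal cur_tokens
        if cur_uid is not None:
            cur_utts.append(
                Utterance(tokens=tuple(cur_tokens), well_formed=cur_wf,
                          events=cur_events)
            )
            cur_tokens = []

    def flush_transcript() -> None:
        nonlocal cur_utts
        if cur_key is not None:
            sp, grp, task = cur_key
            transcripts.append(
                Transcript(speaker_id=sp, group=grp, task=task,
                           utterances=tuple(cur_utts))
            )
            cur_utts = []

    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _HEADER:
            raise TranscriptParseError("bad or missing header row", 1)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise TranscriptParseError(
                    f"expected 10 fields, got {len(fields)}", lineno
                )
            (sp, grp, task, uid, wf, events, surface, lemma, wclass,
             etags) = fields
            key = (sp, grp, task)
            try:
                if key != cur_key:
                    flush_utt()
                    flush_transcript()
                    cur_key, cur_uid = key, None
                if uid != cur_uid:
                    flush_utt()
                    cur_uid = uid
                    if wf not in ("0", "1"):
                        raise TranscriptError(
                            f"well_formed must be 0/1, got {wf!r}"
                        )
                    cur_wf = wf == "1"
                    cur_events = _split(events)
                cur_tokens.append(
                    Token(
                        surface=surface,
                        lemma=lemma.casefold(),
                        word_class=wclass,
                        error_tags=frozenset(_split(etags)),
                        excluded=wclass == "filler"
                        or "false_start" in _split(etags),
                    )
                )
            except TranscriptError as exc:
                raise TranscriptParseError(str(exc), lineno) from exc
        flush_utt()
        flush_transcript()
    return transcripts


def write_transcripts(ts: Sequence[Transcript], path: str | Path) -> None:
    """Write the canonical dialect (utterances renumbered u0, u1, ...);
    bit-exact under write-read-write round trips."""
    lines = [_HEADER]
    for t in ts:
        for ui, utt in enumerate(t.utterances):
            for ti, tok in enumerate(utt.tokens):
                lines.append(
                    "\t".join(
                        [
                            t.speaker_id,
                            t.group,
                            t.task,
                            f"u{ui}",
                            "1" if utt.well_formed else "0",
                            _join(utt.events) if ti == 0 else ".",
                            tok.surface,
                            tok.lemma,
                            tok.word_class,
                            _join(sorted(tok.error_tags)),
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def merge_speaker(ts: Sequence[Transcript], speaker_id: str) -> Transcript:
    """Concatenate one speaker's transcripts in canonical task order.

    The merged record keeps the earliest task label present (the task enum
    has no dedicated "all" value); utterance order within a task is
    preserved.
    """
    mine = [t for t in ts if t.speaker_id == speaker_id]
    if not mine:
        raise TranscriptError(f"no transcripts for speaker {speaker_id!r}")
    others = [t.speaker_id for t in ts if t.speaker_id != speaker_id]
    if others:
        raise TranscriptError(
            f"mixed speaker ids: expected {speaker_id!r}, also got "
            f"{sorted(set(others))}"
        )
    if len(mine) == 1:
        return mine[0]
    mine.sort(key=lambda t: TASKS.index(t.task))
    utts = tuple(u for t in mine for u in t.utterances)
    return Transcript(
        speaker_id=speaker_id, group=mine[0].group, task=mine[0].task,
        utterances=utts,
    )
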