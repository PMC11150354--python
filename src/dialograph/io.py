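"""Reading, labelling and structural segmentation of two-speaker interview
transcripts.

Transcripts arrive as delimited text with one utterance per row (the
DAIC-WOZ transcript dialect: a speaker column plus a ``value`` column holding
the utterance, optionally start/stop times). A transcript carries a PHQ-8
score (0-24); the conventional clinical cut-off of 10 defines the binary
depressed / non-depressed label.

Structure is recovered in two steps: maximal same-speaker runs become
*turns*, and each therapist turn followed immediately by a patient turn
becomes a question-answer pair — the correspondence relation on which all
multi-view cross edges are built.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "Speaker", "Utterance", "Transcript", "Turn", "QAPair",
    "TranscriptFormatError", "EmptyTranscriptError", "LabelingError",
    "PHQ8_THRESHOLD", "DEFAULT_SPEAKER_ALIASES",
    "clean_text", "read_transcript", "write_transcript",
    "read_labels", "assign_label", "segment_turns",
    "pair_questions_answers", "split_views", "tokenize",
]

PHQ8_THRESHOLD = 10

DEFAULT_SPEAKER_ALIASES = {
    "ellie": "therapist",
    "therapist": "therapist",
    "interviewer_t": "therapist",
    "participant": "patient",
    "patient": "patient",
}

#: bracketed non-verbal annotations such as "<laughter>" or "(sighs)"
ANNOTATION_RE = re.compile(r"<[^>]*>|\([^)]*\)|\[[^\]]*\]")
_TOKEN_RE = re.compile(r"[a-z0-9_']+")


class TranscriptFormatError(ValueError):
    """Raised when a transcript file violates the expected dialect."""


class EmptyTranscriptError(ValueError):
    """Raised when no utterances survive cleaning."""


class LabelingError(ValueError):
    """Raised when neither a PHQ-8 score nor a label is available."""


class Speaker(Enum):
    THERAPIST = "therapist"
    PATIENT = "patient"


@dataclass(frozen=True)
class Utterance:
    index: int
    speaker: Speaker
    text: str
    start_time: Optional[float] = None
    stop_time: Optional[float] = None


@dataclass
class Transcript:
    id: str
    utterances: list[Utterance]
    phq8: Optional[int] = None
    label: Optional[int] = None  # 1 = depressed, 0 = non-depressed

    def texts(self) -> list[str]:
        return [u.text for u in self.utterances]


@dataclass(frozen=True)
class Turn:
    speaker: Speaker
    utterance_indices: tuple[int, ...]
    text: str


@dataclass(frozen=True)
class QAPair:
    question_turn: Turn
    answer_turn: Turn


def clean_text(raw: str, annotation_re: re.Pattern = ANNOTATION_RE) -> str:
    """Lowercase, strip bracketed annotations, collapse whitespace."""
    text = annotation_re.sub(" ", raw.lower())
    return " ".join(text.split())


def tokenize(text: str) -> list[str]:
    """Word tokens of cleaned text (keeps underscores, e.g. ``p_t_s_d``)."""
    return _TOKEN_RE.findall(text.lower())


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_transcript(
    path,
    transcript_id: Optional[str] = None,
    speaker_column: str = "speaker",
    text_column: str = "value",
    speaker_aliases: Optional[dict] = None,
    annotation_re: re.Pattern = ANNOTATION_RE,
) -> Transcript:
    """Read one delimited transcript file into a :class:`Transcript`.

    Rows whose text is empty after cleaning are dropped and the remaining
    utterances re-indexed contiguously from 0. Speaker strings are mapped
    case-insensitively through ``speaker_aliases`` (defaults cover the
    DAIC-WOZ "Ellie"/"Participant" convention).
    """
    path = Path(path)
    aliases = dict(DEFAULT_SPEAKER_ALIASES)
    if speaker_aliases:
        aliases.update({k.lower(): v for k, v in speaker_aliases.items()})

    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first:
            raise EmptyTranscriptError(f"{path}: file is empty")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or speaker_column not in reader.fieldnames \
                or text_column not in reader.fieldnames:
            raise TranscriptFormatError(
                f"{path}: required columns {speaker_column!r}, {text_column!r} "
                f"not found in header {reader.fieldnames}"
            )
        utterances: list[Utterance] = []
        for row_no, row in enumerate(reader, start=2):
            raw_speaker = (row[speaker_column] or "").strip().lower()
            if raw_speaker not in aliases:
                raise TranscriptFormatError(
                    f"{path}: unknown speaker {raw_speaker!r} at row {row_no}"
                )
            text = clean_text(row[text_column] or "", annotation_re)
            if not text:
                continue
            start = row.get("start_time") or None
            stop = row.get("stop_time") or None
            utterances.append(Utterance(
                index=len(utterances),
                speaker=Speaker(aliases[raw_speaker]),
                text=text,
                start_time=float(start) if start else None,
                stop_time=float(stop) if stop else None,
            ))
    if not utterances:
        raise EmptyTranscriptError(f"{path}: no utterances survive cleaning")
    return Transcript(id=transcript_id or path.stem, utterances=utterances)


def write_transcript(transcript: Transcript, path, delimiter: str = "\t") -> None:
    """Write a transcript in the same dialect :func:`read_transcript` reads."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["start_time", "stop_time", "speaker", "value"])
        for u in transcript.utterances:
            writer.writerow([
                "" if u.start_time is None else u.start_time,
                "" if u.stop_time is None else u.stop_time,
                u.speaker.value,
                u.text,
            ])


def read_labels(path) -> dict[str, dict]:
    """Read a two-column labels CSV: ``id,phq8`` or ``id,label``."""
    path = Path(path)
    out: dict[str, dict] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise TranscriptFormatError(f"{path}: labels file needs an 'id' column")
        for row in reader:
            entry = {}
            if row.get("phq8") not in (None, ""):
                entry["phq8"] = int(row["phq8"])
            if row.get("label") not in (None, ""):
                entry["label"] = int(row["label"])
            out[row["id"]] = entry
    return out


def assign_label(transcript: Transcript) -> Transcript:
    """Set the binary label from the PHQ-8 score (depressed iff score >= 10)."""
    if transcript.phq8 is not None:
        return replace_label(transcript, int(transcript.phq8 >= PHQ8_THRESHOLD))
    if transcript.label is not None:
        return transcript
    raise LabelingError(f"transcript {transcript.id}: neither phq8 nor label set")


def replace_label(transcript: Transcript, label: int) -> Transcript:
    return Transcript(id=transcript.id, utterances=transcript.utterances,
                      phq8=transcript.phq8, label=label)


def segment_turns(transcript: Transcript) -> list[Turn]:
    """Merge consecutive same-speaker utterances into maximal turns."""
    if not transcript.utterances:
        raise EmptyTranscriptError(f"transcript {transcript.id} has no utterances")
    turns: list[Turn] = []
    run: list[Utterance] = []
    for u in transcript.utterances:
        if run and u.speaker != run[-1].speaker:
            turns.append(_finish_turn(run))
            run = []
        run.append(u)
    turns.append(_finish_turn(run))
    return turns


def _finish_turn(run: Sequence[Utterance]) -> Turn:
    return Turn(
        speaker=run[0].speaker,
        utterance_indices=tuple(u.index for u in run),
        text=" ".join(u.text for u in run),
    )


def pair_questions_answers(turns: Sequence[Turn]) -> list[QAPair]:
    """Pair each therapist turn with the patient turn that immediately
    follows it. Leading patient turns and trailing therapist turns stay
    unpaired."""
    pairs: list[QAPair] = []
    for q, a in zip(turns, turns[1:]):
        if q.speaker is Speaker.THERAPIST and a.speaker is Speaker.PATIENT:
            pairs.append(QAPair(question_turn=q, answer_turn=a))
    return pairs


def split_views(transcript: Transcript) -> tuple[list[Utterance], list[Utterance]]:
    """Partition utterances into (therapist view, patient view), order kept."""
    therapist = [u for u in transcript.utterances if u.speaker is Speaker.THERAPIST]
    patient = [u for u in transcript.utterances if u.speaker is Speaker.PATIENT]
    return therapist, patient
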