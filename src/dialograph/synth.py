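"""Synthetic two-speaker interview corpora.

The generator emulates the statistical structure the graph classifiers
exploit in semi-structured clinical interviews, without any natural-language
modelling: a finite shared topic set, therapist questions and patient
answers built from topic vocabularies, label-dependent behaviour (depressed
cases give shorter answers and draw more therapist follow-up questions),
marker keywords (therapy / depression / p_t_s_d-like tokens) injected almost
exclusively into positive-class transcripts, conversation fillers, and a
~70/30 negative/positive class imbalance. PHQ-8 scores are sampled from
class-conditional ranges (negative 0-9, positive 10-24) so the >= 10
labelling rule is consistent by construction.

Everything is a pure function of the parameter seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import (PHQ8_THRESHOLD, Speaker, Transcript, Utterance,
                 write_transcript)

__all__ = ["GenParams", "SyntheticCorpus", "generate_corpus", "make_splits",
           "write_corpus", "DEFAULT_TOPIC_VOCABULARIES", "DEFAULT_MARKERS"]

DEFAULT_TOPIC_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "sleep": ("sleep", "insomnia", "tired", "rest", "night", "dreams",
              "awake", "bed", "nap", "fatigue"),
    "work": ("work", "job", "boss", "office", "career", "salary",
             "colleagues", "deadline", "projects", "shift"),
    "family": ("family", "mother", "father", "sister", "brother", "kids",
               "parents", "home", "dinner", "holidays"),
    "social": ("friends", "party", "social", "gathering", "neighbors",
               "club", "conversation", "visits", "invitations", "company"),
    "hobbies": ("hobbies", "reading", "painting", "music", "guitar",
                "garden", "cooking", "hiking", "photography", "chess"),
    "health": ("health", "exercise", "doctor", "appetite", "energy",
               "weight", "headaches", "checkup", "nutrition", "walking"),
    "mood": ("mood", "feelings", "happiness", "sadness", "worry",
             "stress", "calm", "hopeful", "lonely", "motivation"),
    "living": ("apartment", "city", "moving", "rent", "roommates",
               "neighborhood", "commute", "travel", "weather", "errands"),
}

DEFAULT_MARKERS: tuple[str, ...] = ("therapy", "depression", "p_t_s_d")
DEFAULT_FILLERS: tuple[str, ...] = ("mhm", "okay", "yeah", "right")

_QUESTION_STEMS = (
    "tell me about your",
    "how do you feel about your",
    "what can you say about your",
    "could you describe your",
)
_FOLLOWUP_STEMS = (
    "can you tell me more about",
    "why do you mention",
    "how does that relate to",
)


@dataclass(frozen=True)
class GenParams:
    n_transcripts: int = 100
    positive_rate: float = 0.3
    topic_vocabularies: dict = field(
        default_factory=lambda: dict(DEFAULT_TOPIC_VOCABULARIES))
    topics_per_transcript: int = 5
    marker_keywords: tuple = DEFAULT_MARKERS
    filler_words: tuple = DEFAULT_FILLERS
    #: mean patient answer length (tokens) per class: negatives elaborate,
    #: positives short and precise
    answer_len_mean: dict = field(default_factory=lambda: {0: 12, 1: 5})
    #: probability of a therapist follow-up question after an answer
    followup_rate: dict = field(default_factory=lambda: {0: 0.2, 1: 0.65})
    #: probability that a transcript of each class carries marker keywords
    marker_injection_rate: dict = field(default_factory=lambda: {0: 0.05, 1: 0.95})
    filler_rate: float = 0.3
    noise_rate: float = 0.05
    noise_vocabulary: tuple = ("hmm", "well", "maybe", "sometimes", "things")
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.positive_rate < 1:
            raise ValueError("positive_rate must lie in (0, 1)")
        for name, rate in (("filler_rate", self.filler_rate),
                           ("noise_rate", self.noise_rate)):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for d in (self.followup_rate, self.marker_injection_rate):
            for v in d.values():
                if not 0 <= v <= 1:
                    raise ValueError("rates must lie in [0, 1]")
        vocabs = [set(v) for v in self.topic_vocabularies.values()]
        for i in range(len(vocabs)):
            for j in range(i + 1, len(vocabs)):
                if vocabs[i] & vocabs[j]:
                    raise ValueError("topic vocabularies must be disjoint")
        if self.topics_per_transcript > len(self.topic_vocabularies):
            raise ValueError("topics_per_transcript exceeds available topics")
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be positive")


@dataclass
class SyntheticCorpus:
    transcripts: list[Transcript]
    splits: dict[str, list[str]]
    params: GenParams

    def by_id(self) -> dict[str, Transcript]:
        return {t.id: t for t in self.transcripts}

    def subset(self, split: str) -> list[Transcript]:
        lookup = self.by_id()
        return [lookup[i] for i in self.splits[split]]


def _sample_words(rng, vocab, n) -> list[str]:
    return [vocab[i] for i in rng.integers(0, len(vocab), size=n)]


def _make_transcript(tid: str, label: int, rng: np.random.Generator,
                     p: GenParams) -> Transcript:
    topics = list(p.topic_vocabularies)
    chosen = [topics[i] for i in rng.choice(len(topics),
                                            size=p.topics_per_transcript,
                                            replace=False)]
    inject_markers = rng.random() < p.marker_injection_rate[label]
    rows: list[tuple[Speaker, str]] = []

    def patient_answer(vocab, length: int) -> str:
        words = _sample_words(rng, vocab, max(2, length))
        if p.noise_rate and rng.random() < p.noise_rate:
            words.append(p.noise_vocabulary[rng.integers(len(p.noise_vocabulary))])
        if inject_markers and rng.random() < 0.25:
            words.extend(_sample_words(rng, p.marker_keywords, 1))
        return " ".join(words)

    for topic in chosen:
        vocab = p.topic_vocabularies[topic]
        stem = _QUESTION_STEMS[rng.integers(len(_QUESTION_STEMS))]
        q_words = _sample_words(rng, vocab, 2)
        rows.append((Speaker.THERAPIST, f"{stem} {q_words[0]} and {q_words[1]}"))
        mean_len = p.answer_len_mean[label]
        rows.append((Speaker.PATIENT,
                     patient_answer(vocab, int(rng.poisson(mean_len)))))
        n_followups = 0
        while n_followups < 2 and rng.random() < p.followup_rate[label]:
            stem = _FOLLOWUP_STEMS[rng.integers(len(_FOLLOWUP_STEMS))]
            w = vocab[rng.integers(len(vocab))]
            rows.append((Speaker.THERAPIST, f"{stem} {w}"))
            rows.append((Speaker.PATIENT,
                         patient_answer(vocab, max(2, int(rng.poisson(mean_len)) // 2))))
            n_followups += 1
        if rng.random() < p.filler_rate:
            rows.append((Speaker.THERAPIST,
                         p.filler_words[rng.integers(len(p.filler_words))]))
    # a trailing therapist filler would be an unpaired trailing turn; keep it —
    # downstream code must tolerate unpaired turns.
    if inject_markers:
        # dedicated treatment-history exchanges: one marker per answer, in a
        # shared stop-word frame, so marker keywords own mutually similar
        # sentence sets (the cluster structure seen in high-score interviews)
        order = rng.permutation(len(p.marker_keywords))
        for k in range(min(2, len(p.marker_keywords))):
            marker = p.marker_keywords[order[k]]
            rows.append((Speaker.THERAPIST,
                         "have you received treatment or a diagnosis before"))
            # frame words are all vectorizer stop words, so the marker is the
            # only keyword the answer can be assigned to
            rows.append((Speaker.PATIENT,
                         f"i have been through {marker} before"))
    if label == 1:
        phq8 = int(rng.integers(PHQ8_THRESHOLD, 25))
    else:
        phq8 = int(rng.integers(0, PHQ8_THRESHOLD))
    utterances = [Utterance(index=i, speaker=s, text=t)
                  for i, (s, t) in enumerate(rows)]
    return Transcript(id=tid, utterances=utterances, phq8=phq8, label=label)


def generate_corpus(params: GenParams = GenParams()) -> SyntheticCorpus:
    """Generate a labelled synthetic corpus, reproducible from params.seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    transcripts = []
    for i in range(params.n_transcripts):
        label = int(rng.random() < params.positive_rate)
        transcripts.append(_make_transcript(f"syn{i:04d}", label, rng, params))
    corpus = SyntheticCorpus(transcripts=transcripts, splits={}, params=params)
    corpus.splits = make_splits(corpus, seed=params.seed)
    return corpus


def make_splits(corpus: SyntheticCorpus,
                fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                stratified: bool = True,
                seed: int = 0) -> dict[str, list[str]]:
    """Disjoint, exhaustive train/dev/test id lists, optionally
    label-stratified."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    names = ("train", "dev", "test")

    def partition(ids: list[str]) -> dict[str, list[str]]:
        ids = list(ids)
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        n = len(ids)
        quotas = [f * n for f in fractions]
        sizes = [int(np.floor(q)) for q in quotas]
        # largest-remainder allocation keeps totals at the exact fractions
        remainders = np.argsort([s - q for s, q in zip(sizes, quotas)])
        for i in range(n - sum(sizes)):
            sizes[remainders[i]] += 1
        out, start = {}, 0
        for name, size in zip(names, sizes):
            out[name] = shuffled[start:start + size]
            start += size
        return out

    if stratified:
        splits = {n: [] for n in names}
        for label in (0, 1):
            ids = [t.id for t in corpus.transcripts if t.label == label]
            for name, part in partition(ids).items():
                splits[name].extend(part)
    else:
        splits = partition([t.id for t in corpus.transcripts])
    for name in names:
        if not splits[name]:
            raise ValueError(f"split {name!r} would receive no transcripts")
        splits[name].sort()
    return splits


def write_corpus(corpus: SyntheticCorpus, out_dir) -> None:
    """Write transcripts (TSV), labels CSV and splits JSON to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tdir = out_dir / "transcripts"
    tdir.mkdir(exist_ok=True)
    for t in corpus.transcripts:
        write_transcript(t, tdir / f"{t.id}.tsv")
    with (out_dir / "labels.csv").open("w", encoding="utf-8") as fh:
        fh.write("id,phq8,label\n")
        for t in corpus.transcripts:
            fh.write(f"{t.id},{t.phq8},{t.label}\n")
    with (out_dir / "splits.json").open("w", encoding="utf-8") as fh:
        json.dump(corpus.splits, fh, indent=1, sort_keys=True)
    meta = asdict(corpus.params)
    meta["topic_vocabularies"] = {k: list(v) for k, v in
                                  meta["topic_vocabularies"].items()}
    with (out_dir / "gen_params.json").open("w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True, default=list)
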