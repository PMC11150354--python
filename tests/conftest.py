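import numpy as np
import pytest

from dialograph.embeddings import EncoderSpec, make_encoder
from dialograph.io import Speaker, Transcript, Utterance
from dialograph.synth import GenParams, generate_corpus


def build_transcript(speakers, texts=None, tid="t0", phq8=None, label=None):
    """Assemble a transcript from a speaker pattern like "TPTP"."""
    mapping = {"T": Speaker.THERAPIST, "P": Speaker.PATIENT}
    if texts is None:
        texts = [f"utterance number {i} words" for i in range(len(speakers))]
    utts = [Utterance(index=i, speaker=mapping[s], text=t)
            for i, (s, t) in enumerate(zip(speakers, texts))]
    return Transcript(id=tid, utterances=utts, phq8=phq8, label=label)


@pytest.fixture(scope="session")
def transcript_factory():
    return build_transcript


@pytest.fixture(scope="session")
def encoder64():
    return make_encoder(EncoderSpec(dim=64))


@pytest.fixture(scope="session")
def default_corpus():
    """The default synthetic study corpus: 100 transcripts, 30% positive."""
    return generate_corpus(GenParams())


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(GenParams(n_transcripts=40, seed=1))


@pytest.fixture(scope="session")
def random_transcripts():
    """200 random synthetic transcripts for structural property checks."""
    corpus = generate_corpus(GenParams(n_transcripts=200, seed=7))
    return corpus.transcripts
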