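import numpy as np
import pytest

from semdepth.datasets import cat_taxonomy
from semdepth.taxonomy import Synset, Taxonomy
from semdepth.transcripts import Token, Transcript, Utterance


@pytest.fixture(scope="session")
def cat_tax() -> Taxonomy:
    return cat_taxonomy()


@pytest.fixture(scope="session")
def toy_tax() -> Taxonomy:
    """Small noun taxonomy: root -> animal(1) -> {dog(2)}, cat at depth 10
    via a chain; plus a polysemous lemma 'bank' at depths 1 and 3."""
    chain = ["root", "l1", "l2", "l3", "l4", "l5", "l6", "l7", "l8", "l9"]
    synsets = [Synset(id=c, pos="noun", lemmas=(c,)) for c in chain]
    edges = [(chain[i + 1], chain[i]) for i in range(len(chain) - 1)]
    synsets += [
        Synset(id="cat.n", pos="noun", lemmas=("cat",)),
        Synset(id="animal.n", pos="noun", lemmas=("animal",)),
        Synset(id="dog.n", pos="noun", lemmas=("dog",)),
        Synset(id="bank.1", pos="noun", lemmas=("bank",)),
        Synset(id="bank.2", pos="noun", lemmas=("bank",)),
    ]
    edges += [
        ("cat.n", "l9"),       # depth 10
        ("animal.n", "root"),  # depth 1
        ("dog.n", "l7"),       # depth 8
        ("bank.1", "root"),    # depth 1
        ("bank.2", "l2"),      # depth 3
    ]
    return Taxonomy(synsets, edges)


def make_transcript(
    lemmas: list[tuple[str, str]],
    speaker: str = "s1",
    group: str = "svPPA",
    task: str = "cookie_theft",
    well_formed: bool = True,
    events: tuple[str, ...] = (),
) -> Transcript:
    """One-utterance transcript from (lemma, word_class) pairs."""
    toks = tuple(
        Token(surface=lemma, lemma=lemma, word_class=wc) for lemma, wc in lemmas
    )
    return Transcript(
        speaker_id=speaker, group=group, task=task,
        utterances=(Utterance(tokens=toks, well_formed=well_formed,
                              events=events),),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240910)
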