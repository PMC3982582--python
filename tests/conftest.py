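import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from phenotissue.corpus_io import AnnotationCorpus
from phenotissue.ontology import build_graph


@pytest.fixture
def chain_graph():
    """retina part_of eye, eye is_a organ."""
    return build_graph(
        [("retina", "part_of", "eye"), ("eye", "is_a", "organ")]
    )


@pytest.fixture
def diamond_graph():
    """bottom -> {left, right} -> top, mixed relations."""
    return build_graph(
        [
            ("bottom", "is_a", "left"),
            ("bottom", "part_of", "right"),
            ("left", "part_of", "top"),
            ("right", "is_a", "top"),
        ]
    )


@pytest.fixture
def tiny_corpus():
    """3 genes over 2 tissues / 2 phenotypes, hand-countable."""
    return AnnotationCorpus(
        tissue_panel=["t1", "t2"],
        tissues_of={"g1": {"t1"}, "g2": {"t1", "t2"}},
        phenotypes_of={"g1": {"p1"}, "g3": {"p1", "p2"}},
    )
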