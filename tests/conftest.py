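import numpy as np
import pytest

from reset.genesets import AnnotationMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "SETA\tdesc\tG1\tG2\tG3\tG4\tG5\n"
        "SETB\tdesc\tG4\tG5\tG6\tG7\tG8\tG9\n"
        "TINY\tdesc\tG1\tG2\n"
    )
    return path


def make_annotation(p, sets):
    """Annotation over genes g1..gp from {name: [0-based indices]}."""
    membership = np.zeros((len(sets), p), dtype=np.int8)
    for i, idx in enumerate(sets.values()):
        membership[i, list(idx)] = 1
    return AnnotationMatrix(
        membership=membership,
        set_names=list(sets),
        gene_ids=[f"g{j + 1}" for j in range(p)],
    )


@pytest.fixture
def annotation_factory():
    return make_annotation
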