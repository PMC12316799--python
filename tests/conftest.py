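import pytest

from rnagenus import synthetic
from rnagenus.diagram_core import ChordDiagram


@pytest.fixture
def kissing_shadow() -> ChordDiagram:
    """The 6-point kissing-hairpin shadow: genus-1 by construction."""
    return ChordDiagram(n_points=6, arcs=frozenset({(1, 3), (2, 5), (4, 6)}))


@pytest.fixture
def kissing_hairpin():
    """Kissing hairpin with 3-pair stems and a designed sequence."""
    return synthetic.make_kissing_hairpin(stems=(3, 3, 3), design_sequence=True)
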