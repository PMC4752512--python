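import numpy as np
import pytest

from grnctx.network import GRN, Interaction
from grnctx.pwm import PWM


@pytest.fixture
def toy_pwm() -> PWM:
    """Length-7 PWM with an informative 5-position block flanked by uniform
    positions, so the core is interior and non-trivial."""
    freq = np.array(
        [
            [0.25, 0.25, 0.25, 0.25],
            [0.70, 0.10, 0.10, 0.10],
            [0.10, 0.70, 0.10, 0.10],
            [0.00, 0.00, 1.00, 0.00],
            [0.40, 0.40, 0.10, 0.10],
            [0.10, 0.10, 0.10, 0.70],
            [0.25, 0.25, 0.25, 0.25],
        ]
    )
    return PWM(tf_id="TOY", freq=freq)


def make_grn(edges, nodes=()):
    """edges: iterable of (source, target, sign[, provenance])."""
    grn = GRN(nodes=nodes)
    for e in edges:
        src, tgt, sign = e[0], e[1], e[2] if len(e) > 2 else "?"
        prov = frozenset(e[3]) if len(e) > 3 else frozenset({"literature"})
        grn.add(Interaction(src, tgt, sign, prov))
    return grn


@pytest.fixture
def diamond_grn():
    """S -> A -> T and S -> B -> T."""
    return make_grn([("S", "A", "+"), ("A", "T", "+"), ("S", "B", "+"), ("B", "T", "+")])
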