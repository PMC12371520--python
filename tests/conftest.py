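import numpy as np
import pytest

from chromsilence import ForceField, build_system, make_interaction_table


@pytest.fixture(scope="session")
def ff():
    return ForceField()


@pytest.fixture(scope="session")
def table_positive():
    return make_interaction_table("positive")


@pytest.fixture()
def small_system(ff):
    """A 12-bead chain with 2 TUs and 2+2 TFs in a small periodic box."""
    state = build_system(
        n_beads=12,
        tu_ids=[3, 9],
        n_active_tf=2,
        n_repressive_tf=2,
        n_on_each=1,
        box_length=12.0,
        seed=7,
        ff=ff,
    )
    return state


def interacting_system(ff, seed=0, n_beads=10, n_tf=4, box=14.0):
    """A compact configuration with TFs pulled next to the chain so that
    attractive, steric, bonded and bending terms are all active."""
    rng = np.random.default_rng(seed)
    st = build_system(
        n_beads=n_beads,
        tu_ids=[2, n_beads - 1],
        n_active_tf=n_tf // 2,
        n_repressive_tf=n_tf - n_tf // 2,
        n_on_each=n_tf // 4 or 1,
        box_length=box,
        seed=seed,
        ff=ff,
    )
    anchors = rng.integers(0, n_beads, st.n_tf)
    st.pos[n_beads:] = st.pos[anchors] + rng.normal(0.0, 0.7, (st.n_tf, 3))
    st.pos += rng.normal(0.0, 0.01, st.pos.shape)
    st.pos %= box
    return st
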