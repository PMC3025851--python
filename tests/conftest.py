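import numpy as np
import pytest

from corspec.simulate import AlignmentSimConfig, simulate_alignment

# The nine GR LBD alignment columns whose residues track mineralocorticoid
# sensitivity, as (column, sensitive-group residue, insensitive-group residue).
NINE_SITES = (
    (15, "A", "S"),
    (38, "R", "Q"),
    (49, "A", "S"),
    (129, "H", "Y"),
    (161, "S", "T"),
    (195, "H", "Q"),
    (203, "S", "Q"),
    (204, "F", "I"),
    (235, "A", "D"),
)

# GR1/GR2 duplicate-receptor tree: aldosterone sensitivity appears in both
# clades but in different species, so no single origin can explain it.
RECEPTOR_TREE = (
    "(((midshipman_GR1,daffodil_cichlid_GR1),trout_GR1),"
    "(midshipman_GR2,daffodil_cichlid_GR2));"
)
RECEPTOR_STATES = {
    "midshipman_GR2": "sensitive",
    "daffodil_cichlid_GR1": "sensitive",
    "midshipman_GR1": "insensitive",
    "daffodil_cichlid_GR2": "insensitive",
    "trout_GR1": "insensitive",
}


@pytest.fixture
def nine_site_alignment():
    """Four GR LBD-like sequences with the nine sensitivity columns planted."""
    cfg = AlignmentSimConfig(
        group_sizes=(2, 2),
        length=250,
        planted_sites=NINE_SITES,
        n_distractors=20,
        seed=42,
    )
    return simulate_alignment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
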