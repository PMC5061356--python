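import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_alignment():
    from cbcdelim.io import Alignment
    return Alignment([
        ("t1", "GCGAAACGC"),
        ("t2", "GCGAAACGC"),
        ("t3", "UCGAAACGA"),
    ])


@pytest.fixture
def hairpin_map():
    """One 3-pair hairpin projected onto a 9-column gap-free alignment."""
    from cbcdelim.structure import PairedColumnMap
    pairs = ((1, 9), (2, 8), (3, 7))
    return PairedColumnMap(
        region_label="ITS1", template_id="t1", paired_cols=pairs,
        unpaired_cols=(4, 5, 6),
        helix_of_pair={p: "I" for p in pairs},
        col_of_pos={i: i for i in range(1, 10)},
    )


@pytest.fixture
def quartet_tree():
    from cbcdelim.io import parse_newick
    return parse_newick("((A,B),(C,D));")
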