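"""Shared builders for randomized truth-log recovery checks."""

import numpy as np

from cbcdelim.io import parse_newick
from cbcdelim.simulate import (DeletionSpec, PlantedEvent, SimulationConfig,
                               TemplateParams, _newick_balanced,
                               _newick_caterpillar, _newick_yule)
from cbcdelim.substitutions import CBC, HCBC, INDEL, NONCBC, SINGLE


def random_recovery_config(seed: int, with_deletion: bool = True) -> SimulationConfig:
    """Random small simulation with clade-targeted planted events.

    Background substitutions are off so every event in the alignment is a
    planted one and recovery can be exact.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    names = [f"t{i}" for i in range(1, n + 1)]
    shape = ["balanced", "caterpillar", "random-yule"][int(rng.integers(3))]
    if shape == "balanced":
        nwk = _newick_balanced(names) + ";"
    elif shape == "caterpillar":
        nwk = _newick_caterpillar(names) + ";"
    else:
        nwk = _newick_yule(names, rng) + ";"
    tree = parse_newick(nwk)
    proper_clades = [
        frozenset(l.taxon.label for l in node.leaf_iter())
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    ]

    def clade():
        return proper_clades[int(rng.integers(len(proper_clades)))]

    planted = []
    planted.append(PlantedEvent(CBC, "ITS2", clade(),
                                count=int(rng.integers(0, 2))))
    for cat, region in [(HCBC, "ITS1"), (HCBC, "ITS2"), (NONCBC, "ITS1"),
                        (SINGLE, "ITS1"), (SINGLE, "ITS2"), (INDEL, "ITS2")]:
        planted.append(PlantedEvent(cat, region, clade(),
                                    count=int(rng.integers(0, 3))))
    deletions = ()
    if with_deletion and rng.random() < 0.5:
        deletions = (DeletionSpec("ITS1", "II", int(rng.integers(2, 5)), clade()),)
    return SimulationConfig(
        seed=int(rng.integers(2 ** 31)), n_taxa=n, newick=nwk,
        taxon_names=tuple(names),
        regions=(("ITS1", TemplateParams(4, 6, 4)),
                 ("ITS2", TemplateParams(4, 6, 4))),
        planted=tuple(planted), deletions=deletions,
        background_sub_rate=0.0,
    )


def expected_event_counts(log):
    """(region, category) event counts the analysis must reproduce.

    Planted substitutions map one-to-one to events; a deletion adds one
    paired-site indel event per lost pair and one unpaired indel event per
    gapped loop column.
    """
    expected = {}

    def bump(region, cat, k=1):
        expected[(region, cat)] = expected.get((region, cat), 0) + k

    for rec in log.records:
        if rec.category in (CBC, HCBC, NONCBC, SINGLE, INDEL):
            bump(rec.region, rec.category)
        elif rec.category == "deletion":
            bump(rec.region, INDEL, rec.n_pairs)  # paired sites
            n_loop = len(rec.site) - 2 * rec.n_pairs
            bump(rec.region, INDEL, n_loop)       # hairpin-loop columns
    return expected


def observed_event_counts(aln, log):
    from cbcdelim.substitutions import enumerate_site_events
    counts = {}
    for region, pcm in log.region_maps.items():
        for ev in enumerate_site_events(aln, pcm):
            key = (region, ev.category)
            counts[key] = counts.get(key, 0) + 1
    return {k: v for k, v in counts.items() if v}
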