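"""Simulator: trees, structured templates, and alignments with planted events.

Evolution is deliberately schematic — the generator's job is to produce data
whose *classification* is known exactly, not to model realistic sequence
evolution.  Each planted event (CBC / hCBC / nonCBC / single / indel) is
applied on a single edge of the tree (no homoplasy), turning the template
state into the category's derived state in every tip of the target clade;
structural deletions gap a chain of pairs at the top of one helix plus its
hairpin loop; background substitutions hit unpaired sites only, so planted
counts at paired sites stay exact.  A machine-readable truth log records
every change and can replay the alignment from the template.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import yaml

from .errors import ConfigError
from .io import (Alignment, SequenceRecord, parse_newick, write_alignment,
                 write_newick, write_vienna)
from .structure import (PairedColumnMap, SecondaryStructure, decompose_helices,
                        pairs_from_dotbracket)
from .substitutions import (CANONICAL_PAIRS, CBC, HCBC, INDEL, NONCBC, SINGLE,
                            PairState)

DELETION = "deletion"
BACKGROUND = "background"

_CANONICAL = sorted(CANONICAL_PAIRS)
# the unique single-position canonical -> wobble change per canonical pair
_HCBC_TARGET = {"GC": "GU", "CG": "UG", "AU": "GU", "UA": "UG"}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateParams:
    """Generator parameters for one region's template."""

    n_helices: int = 5
    helix_len: int = 6
    loop_len: int = 4


@dataclass(frozen=True)
class PlantedEvent:
    """One or more events of a category planted on the edge above a clade.

    ``clade`` is the taxon set receiving the derived state; it must be the
    tip set of one node of the tree.  ``helix_label`` and ``pair_index``
    (1-based from the helix base) optionally pin the site.
    """

    category: str
    region: str
    clade: FrozenSet[str]
    count: int = 1
    helix_label: Optional[str] = None
    pair_index: Optional[int] = None

    def __post_init__(self):
        if self.count < 0:
            raise ConfigError("planted event count must be >= 0")
        if self.category not in {CBC, HCBC, NONCBC, SINGLE, INDEL}:
            raise ConfigError(f"unknown planted category {self.category!r}")


@dataclass(frozen=True)
class DeletionSpec:
    """Loss of the top ``n_pairs`` pairs (and hairpin loop) of one helix."""

    region: str
    helix_label: str
    n_pairs: int
    taxa: FrozenSet[str]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_taxa: int = 8
    tree_shape: str = "random-yule"  # balanced | caterpillar | random-yule
    newick: Optional[str] = None
    taxon_names: Optional[Tuple[str, ...]] = None
    # region label -> TemplateParams or explicit (SequenceRecord, SecondaryStructure)
    regions: Tuple = (("ITS1", TemplateParams()), ("ITS2", TemplateParams()))
    planted: Tuple[PlantedEvent, ...] = ()
    deletions: Tuple[DeletionSpec, ...] = ()
    background_sub_rate: float = 0.0
    spacer_len: int = 12  # unpaired 5.8S-like spacer between regions

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ConfigError("n_taxa must be >= 2")
        if not 0.0 <= self.background_sub_rate <= 1.0:
            raise ConfigError("background_sub_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# template generation
# ---------------------------------------------------------------------------

def generate_template(seed: int, n_helices: int, helix_len: int,
                      loop_len: int) -> Tuple[SequenceRecord, SecondaryStructure]:
    """Random template folded into ``n_helices`` exterior-loop arms.

    Every pair is canonical; the same seed always yields the same template.
    """
    if n_helices < 0:
        raise ConfigError("n_helices must be >= 0")
    if n_helices > 0 and helix_len < 2:
        raise ConfigError("helix_len must be >= 2")
    if n_helices > 0 and loop_len < 3:
        raise ConfigError("loop_len must be >= 3 (minimum hairpin loop)")
    rng = np.random.default_rng(seed)
    arm = "(" * helix_len + "." * loop_len + ")" * helix_len
    db = ".." + "..".join([arm] * n_helices) + ".." if n_helices else "." * max(loop_len, 4)
    structure = pairs_from_dotbracket(db)
    seq = [""] * structure.length
    for (i, j) in sorted(structure.pairs):
        x, y = _CANONICAL[rng.integers(len(_CANONICAL))]
        seq[i - 1], seq[j - 1] = x, y
    for p in range(structure.length):
        if not seq[p]:
            seq[p] = "ACGU"[rng.integers(4)]
    record = SequenceRecord(id=f"template_seed{seed}", residues="".join(seq),
                            description="simulated template")
    return record, structure


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------

def _newick_balanced(names: Sequence[str]) -> str:
    if len(names) == 1:
        return names[0]
    mid = (len(names) + 1) // 2
    return f"({_newick_balanced(names[:mid])},{_newick_balanced(names[mid:])})"


def _newick_caterpillar(names: Sequence[str]) -> str:
    out = f"({names[0]},{names[1]})"
    for name in names[2:]:
        out = f"({out},{name})"
    return out


def _newick_yule(names: Sequence[str], rng: np.random.Generator) -> str:
    """Forward Yule process: split a uniformly chosen pending lineage."""
    lineages = [names[0]]
    pool = list(names[1:])
    rng.shuffle(pool)
    for name in pool:
        k = int(rng.integers(len(lineages)))
        lineages[k] = f"({lineages[k]},{name})"
    while len(lineages) > 1:
        b = lineages.pop()
        lineages[-1] = f"({lineages[-1]},{b})"
    return lineages[0]


def generate_tree(cfg: SimulationConfig, names: Sequence[str],
                  rng: np.random.Generator) -> dendropy.Tree:
    if cfg.newick:
        tree = parse_newick(cfg.newick)
    else:
        if cfg.tree_shape == "balanced":
            nwk = _newick_balanced(list(names))
        elif cfg.tree_shape == "caterpillar":
            nwk = _newick_caterpillar(list(names))
        elif cfg.tree_shape == "random-yule":
            nwk = _newick_yule(list(names), rng)
        else:
            raise ConfigError(f"unknown tree_shape {cfg.tree_shape!r}")
        tree = parse_newick(nwk + ";")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = round(float(rng.exponential(0.05)) + 0.005, 5)
    return tree


def _clade_tipsets(tree: dendropy.Tree) -> Dict[FrozenSet[str], dendropy.Node]:
    out = {}
    for node in tree.postorder_node_iter():
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        out[tips] = node
    return out


# ---------------------------------------------------------------------------
# truth log
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthRecord:
    category: str           # CBC/hCBC/nonCBC/single/indel/deletion/background
    region: str
    site: Tuple[int, ...]   # alignment columns (deletion: all gapped columns)
    helix_label: str
    from_state: str
    to_state: str
    taxa: FrozenSet[str]
    n_pairs: int = 0        # deletions only


@dataclass
class TruthLog:
    """Replayable record of everything the simulator did."""

    records: List[TruthRecord]
    tree: dendropy.Tree
    template: SequenceRecord
    region_structures: Dict[str, SecondaryStructure]
    region_offsets: Dict[str, int]
    region_maps: Dict[str, PairedColumnMap]
    template_taxon: str
    config: SimulationConfig

    def counts(self) -> Dict[Tuple[str, str], int]:
        """(region, category) → number of planted records."""
        out: Dict[Tuple[str, str], int] = {}
        for rec in self.records:
            key = (rec.region, rec.category)
            out[key] = out.get(key, 0) + 1
        return out

    def replay(self, taxon_order: Sequence[str]) -> Alignment:
        """Re-apply every record to the template; must equal the alignment."""
        rows = {t: list(self.template.residues) for t in taxon_order}
        for rec in self.records:
            for taxon in rec.taxa:
                if taxon not in rows:
                    continue
                for k, col in enumerate(rec.site):
                    rows[taxon][col - 1] = rec.to_state[k] if rec.category != DELETION else "-"
        return Alignment([(t, "".join(rows[t])) for t in taxon_order])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tregion\tsite_cols\thelix_label\tfrom_state"
                     "\tto_state\tn_pairs\ttaxa\n")
            for rec in self.records:
                fh.write("\t".join([
                    rec.category, rec.region,
                    ":".join(map(str, rec.site)), rec.helix_label,
                    rec.from_state, rec.to_state, str(rec.n_pairs),
                    ",".join(sorted(rec.taxa)),
                ]) + "\n")


# ---------------------------------------------------------------------------
# the simulator proper
# ---------------------------------------------------------------------------

def _deletion_chain(structure: SecondaryStructure, helix_label: str,
                    n_pairs: int) -> Tuple[List[Tuple[int, int]], List[int]]:
    """Pairs and loop positions lost when a helix top is deleted.

    Takes the 3'-most hairpin of the named arm and walks ``n_pairs`` pairs
    outward from it; the unpaired positions inside the innermost pair (the
    hairpin loop) are lost too.
    """
    arms = {a.label: a for a in decompose_helices(structure)}
    if helix_label not in arms:
        raise ConfigError(f"no helix {helix_label!r} in template structure")
    arm = arms[helix_label]
    pairs = sorted(arm.pairs)
    nested = {p: [q for q in pairs if p[0] < q[0] and q[1] < p[1]] for p in pairs}
    hairpins = [p for p in pairs if not nested[p]]
    start = max(hairpins)  # 3'-most hairpin pair
    chain = [start]
    while len(chain) < n_pairs:
        i, j = chain[-1]
        enclosing = [p for p in pairs if p[0] < i and j < p[1]]
        if not enclosing:
            raise ConfigError(
                f"helix {helix_label} has no chain of {n_pairs} pairs above its"
                " 3'-most hairpin"
            )
        chain.append(max(enclosing, key=lambda p: p[0]))  # directly enclosing
    paired_pos = structure.paired_positions
    loop = [p for p in range(start[0] + 1, start[1]) if p not in paired_pos]
    return chain, loop


def _derived_state(category: str, ancestral: str, rng: np.random.Generator) -> str:
    """Derived pair state for a planted paired-site event."""
    if category == CBC:
        options = [c for c in _CANONICAL if c != ancestral]  # both strands differ
        return options[int(rng.integers(len(options)))]
    if category == HCBC:
        if ancestral not in _HCBC_TARGET:
            raise ConfigError(f"hCBC needs a canonical ancestral pair, got {ancestral}")
        return _HCBC_TARGET[ancestral]
    if category == NONCBC:
        options = []
        for pos in (0, 1):
            for nt in "ACGU":
                if nt == ancestral[pos]:
                    continue
                cand = nt + ancestral[1] if pos == 0 else ancestral[0] + nt
                if PairState(*cand).klass == "noncanonical":
                    options.append(cand)
        return options[int(rng.integers(len(options)))]
    raise ConfigError(f"{category} is not a paired-site substitution category")


def simulate_alignment(cfg: SimulationConfig):
    """Run one simulation.

    Returns ``(Alignment, tree, TruthLog)``.  The same config (seed included)
    always produces byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.taxon_names) if cfg.taxon_names else [
        f"t{i}" for i in range(1, cfg.n_taxa + 1)
    ]
    if len(names) != cfg.n_taxa:
        raise ConfigError("taxon_names length != n_taxa")
    tree = generate_tree(cfg, names, rng)
    tipsets = _clade_tipsets(tree)

    # --- assemble the root template: regions joined by unpaired spacers ----
    region_records: Dict[str, SequenceRecord] = {}
    region_structs: Dict[str, SecondaryStructure] = {}
    for label, spec in cfg.regions:
        if isinstance(spec, TemplateParams):
            rec, st = generate_template(int(rng.integers(2 ** 31)),
                                        spec.n_helices, spec.helix_len,
                                        spec.loop_len)
        else:
            rec, st = spec
        region_records[label], region_structs[label] = rec, st

    spacer = "".join("ACGU"[rng.integers(4)] for _ in range(cfg.spacer_len))
    parts, offsets = [], {}
    pos = 0
    for label, _ in cfg.regions:
        if parts:
            parts.append(spacer)
            pos += len(spacer)
        offsets[label] = pos
        parts.append(region_records[label].residues)
        pos += len(region_records[label].residues)
    template = SequenceRecord(id="root_template", residues="".join(parts),
                              description="simulated root sequence")
    total_len = len(template.residues)

    # --- deletions first: their columns are off-limits for planted events --
    records: List[TruthRecord] = []
    deleted_cols: set = set()
    deletion_pairs: Dict[str, set] = {label: set() for label, _ in cfg.regions}
    for spec in cfg.deletions:
        if frozenset(spec.taxa) not in tipsets:
            raise ConfigError(f"deletion target {sorted(spec.taxa)} is not a clade")
        st = region_structs[spec.region]
        off = offsets[spec.region]
        chain, loop = _deletion_chain(st, spec.helix_label, spec.n_pairs)
        cols = sorted({c + off for p in chain for c in p} | {c + off for c in loop})
        deleted_cols.update(cols)
        deletion_pairs[spec.region].update(chain)
        records.append(TruthRecord(
            category=DELETION, region=spec.region, site=tuple(cols),
            helix_label=spec.helix_label,
            from_state="".join(template.residues[c - 1] for c in cols),
            to_state="-" * len(cols), taxa=frozenset(spec.taxa),
            n_pairs=spec.n_pairs,
        ))

    # --- site bookkeeping per region ---------------------------------------
    avail_paired: Dict[str, List[Tuple[int, int]]] = {}
    avail_unpaired: Dict[str, List[int]] = {}
    helix_of: Dict[str, Dict[Tuple[int, int], str]] = {}
    pair_rank: Dict[str, Dict[Tuple[str, int], Tuple[int, int]]] = {}
    for label, _ in cfg.regions:
        st = region_structs[label]
        arms = decompose_helices(st)
        hof = {}
        rank = {}
        for arm in arms:
            for r, p in enumerate(sorted(arm.pairs), start=1):
                hof[p] = arm.label
                rank[(arm.label, r)] = p
        helix_of[label] = hof
        pair_rank[label] = rank
        paired_pos = st.paired_positions
        avail_paired[label] = [
            p for p in sorted(st.pairs) if p not in deletion_pairs[label]
        ]
        off = offsets[label]
        avail_unpaired[label] = [
            p for p in range(1, st.length + 1)
            if p not in paired_pos and (p + off) not in deleted_cols
        ]

    def take_paired_site(ev: PlantedEvent) -> Tuple[int, int]:
        pool = avail_paired[ev.region]
        if ev.helix_label and ev.pair_index:
            p = pair_rank[ev.region].get((ev.helix_label, ev.pair_index))
            if p is None or p not in pool:
                raise ConfigError(
                    f"pair {ev.pair_index} of helix {ev.helix_label} unavailable"
                )
        elif ev.helix_label:
            cands = [p for p in pool if helix_of[ev.region][p] == ev.helix_label]
            if not cands:
                raise ConfigError(f"no free pairs left in helix {ev.helix_label}")
            p = cands[int(rng.integers(len(cands)))]
        else:
            if not pool:
                raise ConfigError(f"no free paired sites left in {ev.region}")
            p = pool[int(rng.integers(len(pool)))]
        pool.remove(p)
        return p

    def take_unpaired_site(ev: PlantedEvent) -> int:
        pool = avail_unpaired[ev.region]
        if not pool:
            raise ConfigError(f"no free unpaired sites left in {ev.region}")
        p = pool[int(rng.integers(len(pool)))]
        pool.remove(p)
        return p

    # --- plant the events ---------------------------------------------------
    rows = {t: list(template.residues) for t in names}
    used_unpaired_cols: set = set()
    for ev in cfg.planted:
        clade = frozenset(ev.clade)
        if clade not in tipsets:
            raise ConfigError(f"planted target {sorted(clade)} is not a clade")
        for _ in range(ev.count):
            if ev.category in (CBC, HCBC, NONCBC):
                i, j = take_paired_site(ev)
                off = offsets[ev.region]
                ci, cj = i + off, j + off
                anc = template.residues[ci - 1] + template.residues[cj - 1]
                der = _derived_state(ev.category, anc, rng)
                for taxon in clade:
                    rows[taxon][ci - 1] = der[0]
                    rows[taxon][cj - 1] = der[1]
                records.append(TruthRecord(
                    category=ev.category, region=ev.region, site=(ci, cj),
                    helix_label=helix_of[ev.region][(i, j)],
                    from_state=anc, to_state=der, taxa=clade,
                ))
            else:  # single or indel on an unpaired column
                p = take_unpaired_site(ev)
                col = p + offsets[ev.region]
                used_unpaired_cols.add(col)
                anc = template.residues[col - 1]
                if ev.category == SINGLE:
                    choices = [n for n in "ACGU" if n != anc]
                    der = choices[int(rng.integers(len(choices)))]
                else:
                    der = "-"
                for taxon in clade:
                    rows[taxon][col - 1] = der
                records.append(TruthRecord(
                    category=ev.category, region=ev.region, site=(col,),
                    helix_label="loop/junction", from_state=anc, to_state=der,
                    taxa=clade,
                ))

    # --- apply deletions ----------------------------------------------------
    for rec in records:
        if rec.category != DELETION:
            continue
        for taxon in rec.taxa:
            for col in rec.site:
                rows[taxon][col - 1] = "-"

    # --- background substitutions at untouched unpaired columns ------------
    if cfg.background_sub_rate > 0:
        bg_cols = sorted(
            col for label, _ in cfg.regions
            for p in avail_unpaired[label]
            if (col := p + offsets[label]) not in used_unpaired_cols
        )
        for taxon in names:
            for col in bg_cols:
                if rng.random() < cfg.background_sub_rate:
                    anc = rows[taxon][col - 1]
                    choices = [n for n in "ACGU" if n != anc]
                    der = choices[int(rng.integers(len(choices)))]
                    rows[taxon][col - 1] = der
                    region = next(
                        label for label, _ in cfg.regions
                        if offsets[label] < col <= offsets[label]
                        + region_structs[label].length
                    )
                    records.append(TruthRecord(
                        category=BACKGROUND, region=region, site=(col,),
                        helix_label="loop/junction", from_state=anc,
                        to_state=der, taxa=frozenset([taxon]),
                    ))

    leaf_order = [l.taxon.label for l in tree.leaf_node_iter()]
    aln = Alignment([(t, "".join(rows[t])) for t in leaf_order])
    template_taxon = next(t for t in leaf_order if "-" not in aln.row(t))

    region_maps = {}
    for label, _ in cfg.regions:
        st = region_structs[label]
        off = offsets[label]
        arms = decompose_helices(st)
        hof_pos = {p: a.label for a in arms for p in a.pairs}
        paired_cols = tuple((i + off, j + off) for (i, j) in sorted(st.pairs))
        helix_of_pair = {
            (i + off, j + off): hof_pos[(i, j)] for (i, j) in sorted(st.pairs)
        }
        paired_pos = st.paired_positions
        region_maps[label] = PairedColumnMap(
            region_label=label, template_id=template_taxon,
            paired_cols=paired_cols,
            unpaired_cols=tuple(p + off for p in range(1, st.length + 1)
                                if p not in paired_pos),
            helix_of_pair=helix_of_pair,
            col_of_pos={p: p + off for p in range(1, st.length + 1)},
            arms=tuple(arms),
        )

    log = TruthLog(records=records, tree=tree, template=template,
                   region_structures=region_structs, region_offsets=offsets,
                   region_maps=region_maps, template_taxon=template_taxon,
                   config=cfg)
    return aln, tree, log


# ---------------------------------------------------------------------------
# study-scale preset
# ---------------------------------------------------------------------------

#: taxon groups of the 19-sequence emulation: one clinical-type strain, three
#: rock strains of an unnamed sibling, two alpine strains, eight
#: deletion-lineage isolates, and three + one + one further rock taxa.
PRESET_GROUPS = {
    "onc": ("Bonc_1",),
    "sp2": ("Bsp2_1", "Bsp2_2", "Bsp2_3"),
    "alp": ("Balp_1", "Balp_2"),
    "gra": tuple(f"Bgra_{i}" for i in range(1, 9)),
    "sp1": ("Bsp1_1", "Bsp1_2", "Bsp1_3"),
    "sp3": ("Bsp3_1",),
    "sp4": ("Bsp4_1",),
}

_PRESET_NEWICK = (
    "((Balp_1,Balp_2),"
    "((Bonc_1,(Bsp2_1,(Bsp2_2,Bsp2_3))),"
    "((Bgra_1,(Bgra_2,(Bgra_3,(Bgra_4,(Bgra_5,(Bgra_6,(Bgra_7,Bgra_8))))))),"
    "(((Bsp1_1,(Bsp1_2,Bsp1_3)),Bsp3_1),Bsp4_1))));"
)


def study_scale_config(seed: int) -> SimulationConfig:
    """The 19-taxon configuration emulating the published dataset.

    One ITS2 CBC at pair 9 of helix II separating a two-species clade from
    the rest; three ITS1 hCBCs (two on helix III, one on helix IV); two ITS1
    non-CBCs (helices II and IV); two ITS2 hCBCs on helix III; and a 6-pair
    deletion of the upper right arm of ITS1 helix III confined to one
    8-member lineage.  The second CBC clade is paraphyletic on the tree.
    """
    from .refmodels import synthetic_its1_model, synthetic_its2_model

    g = PRESET_GROUPS
    clade_a = frozenset(g["onc"] + g["sp2"])
    clade_y = frozenset(g["gra"] + g["sp1"] + g["sp3"] + g["sp4"])
    names = tuple(t for grp in g.values() for t in grp)
    return SimulationConfig(
        seed=seed,
        n_taxa=19,
        newick=_PRESET_NEWICK,
        taxon_names=names,
        regions=(("ITS1", synthetic_its1_model()),
                 ("ITS2", synthetic_its2_model())),
        planted=(
            PlantedEvent(CBC, "ITS2", clade_a, helix_label="II", pair_index=9),
            PlantedEvent(HCBC, "ITS1", frozenset(g["sp2"]), helix_label="III"),
            PlantedEvent(HCBC, "ITS1", frozenset(g["sp4"]), helix_label="III"),
            PlantedEvent(HCBC, "ITS1", clade_y, helix_label="IV"),
            PlantedEvent(NONCBC, "ITS1", clade_y, helix_label="II"),
            PlantedEvent(NONCBC, "ITS1", clade_y, helix_label="IV"),
            PlantedEvent(HCBC, "ITS2", clade_y, helix_label="III", count=2),
        ),
        deletions=(DeletionSpec("ITS1", "III", 6, frozenset(g["gra"])),),
        background_sub_rate=0.02,
    )


def write_simulation(outdir, aln: Alignment, tree: dendropy.Tree,
                     log: TruthLog) -> Dict[str, Path]:
    """Write the four simulator outputs (FASTA, newick, Vienna, truth TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": outdir / "alignment.fasta",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.tsv",
    }
    write_alignment(aln, paths["alignment"])
    write_newick(tree, paths["tree"])
    log.to_tsv(paths["truth"])
    # Vienna templates carry the template taxon's own region sequence (its
    # row is gap-free), mirroring how a structure model is published for one
    # accession of the alignment.
    template_row = aln.row(log.template_taxon)
    for label, st in log.region_structures.items():
        p = outdir / f"{label.lower()}_template.vienna"
        off = log.region_offsets[label]
        rec = SequenceRecord(
            id=log.template_taxon,
            residues=template_row[off:off + st.length],
            description=f"{label} structure model of {log.template_taxon}",
        )
        write_vienna(rec, st, p)
        paths[f"vienna_{label}"] = p
    return paths
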