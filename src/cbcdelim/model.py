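"""Model/results interface tying the pipeline stages together.

`CbcDelimitation` is built from an alignment, one template secondary
structure per ITS region, and an optional rooted tree; `fit()` projects the
templates onto the alignment, classifies every substitution at paired and
unpaired sites, assembles the pairwise CBC matrix, delimits CBC clades and
subclades, detects structural deletions, maps events onto the tree, and
returns a `CbcDelimitationResults` with the tables and a `summary()`.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import pandas as pd

from . import clades as _clades
from .errors import ProjectionError, ValidationError
from .io import (Alignment, SequenceRecord, read_alignment, read_newick,
                 read_vienna, write_events_tsv)
from .structure import (PairedColumnMap, SecondaryStructure,
                        detect_structure_deletions, project_to_alignment)
from .substitutions import (CBC, HCBC, INDEL, NONCBC, OTHER_PAIRED, SINGLE,
                            CbcMatrix, cbc_matrix, count_site_patterns,
                            enumerate_site_events, events_frame)

#: literature constant: probability that two organisms without a CBC between
#: them are conspecific (reported verbatim in summaries, never recomputed)
CONSPECIFICITY_PROB_NO_CBC = 0.76


@dataclass(frozen=True)
class TemplateRegion:
    """One region's template structure and how to anchor it in the alignment.

    ``template_id`` names the alignment row carrying the template; the
    template may cover only part of that row (``pos_offset`` ungapped
    positions in).  When ``sequence`` is given and ``pos_offset`` is None the
    offset is located by substring search in the ungapped row.
    """

    region_label: str
    structure: SecondaryStructure
    template_id: str
    pos_offset: Optional[int] = None
    sequence: Optional[str] = None


class CbcDelimitation:
    """Structure-aware CBC species delimitation model.

    Parameters
    ----------
    alignment : Alignment
        ITS alignment over {A,C,G,U,N,-}.
    templates : sequence of TemplateRegion
        One entry per region (e.g. ITS1, ITS2).
    tree : dendropy.Tree, optional
        Rooted tree with tips matching alignment ids; enables event mapping
        and monophyly tests.
    precomputed_maps : mapping, optional
        Region label → PairedColumnMap; bypasses projection (used for
        simulator output where the maps are known exactly).
    """

    def __init__(self, alignment: Alignment,
                 templates: Sequence[TemplateRegion] = (),
                 tree: Optional[dendropy.Tree] = None,
                 precomputed_maps: Optional[Mapping[str, PairedColumnMap]] = None):
        self.alignment = alignment
        self.templates = list(templates)
        self.tree = tree
        self.precomputed_maps = dict(precomputed_maps) if precomputed_maps else None
        if tree is not None:
            tips = {l.taxon.label for l in tree.leaf_node_iter()}
            if not tips <= set(alignment.ids):
                raise ValidationError(
                    f"tree tips not in alignment: {sorted(tips - set(alignment.ids))}"
                )
        if not self.templates and not self.precomputed_maps:
            raise ValidationError("at least one template region is required")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_files(cls, alignment_path, structures: Sequence[Tuple[str, str]],
                   tree_path=None, template_id: Optional[str] = None):
        """Build from an aligned FASTA, Vienna files and an optional newick.

        ``structures`` is a sequence of (vienna_path, region_label).  The
        template row defaults to the id in each Vienna header when present in
        the alignment, else ``template_id`` must name the row.
        """
        aln = read_alignment(alignment_path)
        templates = []
        for vienna_path, region in structures:
            rec, st = read_vienna(vienna_path)
            tid = rec.id if rec.id in aln.ids else template_id
            if tid is None or tid not in aln.ids:
                raise ValidationError(
                    f"cannot anchor {region}: no alignment row named {rec.id!r}"
                    " and no --template-id given"
                )
            templates.append(TemplateRegion(
                region_label=region, structure=st, template_id=tid,
                sequence=rec.residues,
            ))
        tree = read_newick(tree_path) if tree_path else None
        return cls(aln, templates, tree=tree)

    @classmethod
    def from_simulation(cls, alignment: Alignment, tree: dendropy.Tree, log):
        """Build directly from simulator output (exact projection maps)."""
        return cls(alignment, templates=(), tree=tree,
                   precomputed_maps=log.region_maps)

    # -- fitting ------------------------------------------------------------

    def _resolve_offset(self, t: TemplateRegion) -> int:
        if t.pos_offset is not None:
            return t.pos_offset
        row = self.alignment.row(t.template_id).replace("-", "")
        if t.sequence is None:
            return 0
        at = row.find(t.sequence)
        if at < 0:
            raise ProjectionError(
                f"{t.region_label}: template sequence not found in row"
                f" {t.template_id!r}"
            )
        if row.find(t.sequence, at + 1) >= 0:
            warnings.warn(
                f"{t.region_label}: template sequence occurs more than once in"
                f" {t.template_id!r}; using the first occurrence",
                stacklevel=2,
            )
        return at

    def project(self) -> Dict[str, PairedColumnMap]:
        if self.precomputed_maps is not None:
            return dict(self.precomputed_maps)
        maps = {}
        for t in self.templates:
            maps[t.region_label] = _project_region(
                self.alignment, t, self._resolve_offset(t)
            )
        return maps

    def fit(self) -> "CbcDelimitationResults":
        aln = self.alignment
        maps = self.project()
        events, excluded = [], {}
        for region, pcm in maps.items():
            evs, excl = enumerate_site_events(aln, pcm, return_excluded=True)
            events.extend(evs)
            excluded[region] = excl
        matrix = cbc_matrix(aln, list(maps.values()))
        clades = _clades.cbc_clades(matrix, events)
        subclades = _clades.subclades(clades, events, self.tree)
        deletions = {
            region: detect_structure_deletions(pcm, aln)
            for region, pcm in maps.items()
        }
        edge_maps = {}
        monophyly = {}
        if self.tree is not None:
            for region, pcm in maps.items():
                edge_maps[region] = _clades.map_events_to_tree(aln, pcm, self.tree)
            for k, clade in enumerate(clades):
                monophyly[k] = _clades.check_monophyly(clade.members, self.tree)
        return CbcDelimitationResults(
            model=self, maps=maps, events=events, excluded_sites=excluded,
            matrix=matrix, clades=clades, subclades=subclades,
            deletions=deletions, edge_maps=edge_maps, monophyly=monophyly,
            n_site_patterns=count_site_patterns(aln),
        )


def _project_region(aln: Alignment, t: TemplateRegion, pos_offset: int) -> PairedColumnMap:
    """Project one region's structure through its (possibly longer) row."""
    row = aln.row(t.template_id)
    ungapped = row.replace("-", "")
    if pos_offset == 0 and len(ungapped) == t.structure.length:
        return project_to_alignment(aln, t.template_id, t.structure, t.region_label)
    if len(ungapped) < pos_offset + t.structure.length:
        raise ProjectionError(
            f"{t.region_label}: row {t.template_id!r} too short for template at"
            f" offset {pos_offset}"
        )
    # column of each ungapped position of the full row
    col_of_full = {}
    pos = 0
    for col, ch in enumerate(row, start=1):
        if ch != "-":
            pos += 1
            col_of_full[pos] = col
    sub_aln_cols = {
        p: col_of_full[p + pos_offset] for p in range(1, t.structure.length + 1)
    }
    from .structure import decompose_helices
    arms = decompose_helices(t.structure)
    hof_pos = {p: a.label for a in arms for p in a.pairs}
    paired_cols = tuple(
        (sub_aln_cols[i], sub_aln_cols[j]) for (i, j) in sorted(t.structure.pairs)
    )
    helix_of_pair = {
        (sub_aln_cols[i], sub_aln_cols[j]): hof_pos[(i, j)]
        for (i, j) in sorted(t.structure.pairs)
    }
    paired_pos = t.structure.paired_positions
    return PairedColumnMap(
        region_label=t.region_label, template_id=t.template_id,
        paired_cols=paired_cols,
        unpaired_cols=tuple(sub_aln_cols[p]
                            for p in range(1, t.structure.length + 1)
                            if p not in paired_pos),
        helix_of_pair=helix_of_pair, col_of_pos=sub_aln_cols, arms=tuple(arms),
    )


@dataclass
class CbcDelimitationResults:
    """Fitted results: event tables, CBC matrix, clades, diagnostics."""

    model: CbcDelimitation
    maps: Dict[str, PairedColumnMap]
    events: List
    excluded_sites: Dict[str, List]
    matrix: CbcMatrix
    clades: List
    subclades: List
    deletions: Dict[str, Dict[str, List]]
    edge_maps: Dict[str, object]
    monophyly: Dict[int, str]
    n_site_patterns: int

    # -- tabular views -------------------------------------------------------

    def events_table(self) -> pd.DataFrame:
        return events_frame(self.events)

    def event_counts(self) -> pd.DataFrame:
        """Events per region × category (zero-filled)."""
        cats = [CBC, HCBC, NONCBC, OTHER_PAIRED, SINGLE, INDEL]
        regions = list(self.maps)
        out = pd.DataFrame(0, index=regions, columns=cats)
        for ev in self.events:
            out.loc[ev.region, ev.category] += 1
        return out

    def clade_table(self) -> pd.DataFrame:
        rows = []
        for k, clade in enumerate(self.clades):
            rows.append({
                "clade": k + 1,
                "n_members": len(clade.members),
                "members": ",".join(sorted(clade.members)),
                "monophyly": self.monophyly.get(k, "n/a"),
            })
        return pd.DataFrame(rows)

    def subclade_table(self) -> pd.DataFrame:
        rows = []
        for sc in self.subclades:
            rows.append({
                "subclade": sc.label,
                "clade": sc.clade_index + 1,
                "n_members": len(sc.members),
                "members": ",".join(sorted(sc.members)),
                "n_diagnostic_events": len(sc.diagnostic_events),
            })
        return pd.DataFrame(rows)

    def deletion_table(self) -> pd.DataFrame:
        rows = []
        for region, per_taxon in self.deletions.items():
            for taxon, losses in per_taxon.items():
                for helix, n_lost, col_pairs in losses:
                    rows.append({
                        "region": region, "taxon": taxon, "helix": helix,
                        "n_lost_pairs": n_lost,
                        "col_pairs": ";".join(f"{i}:{j}" for i, j in col_pairs),
                    })
        return pd.DataFrame(rows, columns=[
            "region", "taxon", "helix", "n_lost_pairs", "col_pairs",
        ])

    def helix_table(self) -> pd.DataFrame:
        rows = []
        for region, pcm in self.maps.items():
            for arm in pcm.arms:
                rows.append({
                    "region": region, "helix": arm.label, "start": arm.start,
                    "end": arm.end, "n_nt": arm.n_nt, "n_pairs": arm.n_pairs,
                })
        return pd.DataFrame(rows)

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        aln = self.model.alignment
        lines = [
            "CBC species delimitation results",
            "=" * 48,
            f"taxa: {len(aln)}    alignment columns: {aln.n_cols}"
            f"    distinct site patterns: {self.n_site_patterns}",
            f"regions: {', '.join(self.maps)}",
            "",
            "Substitution events (region x category)",
            self.event_counts().to_string(),
            "",
            f"CBC clades: {len(self.clades)}   (taxa with no CBC between any"
            f" pair; P(conspecific | no CBC) ~ {CONSPECIFICITY_PROB_NO_CBC},"
            " literature value)",
        ]
        for k, clade in enumerate(self.clades):
            status = self.monophyly.get(k, "n/a")
            lines.append(f"  clade {k + 1} [{status}] "
                         f"({len(clade.members)}): "
                         + ",".join(sorted(clade.members)))
        lines += ["", f"Subclades: {len(self.subclades)}"]
        for sc in self.subclades:
            diag = f", {len(sc.diagnostic_events)} diagnostic events" \
                if sc.diagnostic_events else ""
            lines.append(f"  {sc.label} (clade {sc.clade_index + 1}, "
                         f"{len(sc.members)} taxa{diag}): "
                         + ",".join(sorted(sc.members)))
        del_tab = self.deletion_table()
        if len(del_tab):
            agg = del_tab.groupby(["region", "helix", "n_lost_pairs"])["taxon"] \
                .nunique().reset_index(name="n_taxa")
            lines += ["", "Structural deletions (pairs lost to gaps)",
                      agg.to_string(index=False)]
        excl = sum(len(v) for v in self.excluded_sites.values())
        if excl:
            lines += ["", f"Sites excluded for ambiguity (N): {excl}"]
        return "\n".join(lines)

    def save(self, outdir) -> Dict[str, Path]:
        """Write the TSV/JSON report files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def tsv(name: str, df: pd.DataFrame):
            p = outdir / name
            df.to_csv(p, sep="\t", index=False)
            paths[name] = p

        write_events_tsv(self.events, outdir / "events.tsv")
        paths["events.tsv"] = outdir / "events.tsv"
        self.matrix.to_tsv(outdir / "cbc_matrix.tsv")
        paths["cbc_matrix.tsv"] = outdir / "cbc_matrix.tsv"
        tsv("clades.tsv", self.clade_table())
        tsv("subclades.tsv", self.subclade_table())
        tsv("deletions.tsv", self.deletion_table())
        tsv("helices.tsv", self.helix_table())
        if self.edge_maps:
            rows = []
            for region, em in self.edge_maps.items():
                for (parent, child), evs in sorted(em.assignments.items()):
                    for ev in evs:
                        rows.append({
                            "region": region, "parent": parent, "child": child,
                            "site_cols": ":".join(map(str, ev.site)),
                            "helix": ev.helix_label, "category": ev.category,
                            "from_state": ev.from_state, "to_state": ev.to_state,
                            "ambiguous": ev.ambiguous,
                        })
            tsv("edge_events.tsv", pd.DataFrame(rows, columns=[
                "region", "parent", "child", "site_cols", "helix", "category",
                "from_state", "to_state", "ambiguous",
            ]))
        report = {
            "n_taxa": len(self.model.alignment),
            "n_columns": self.model.alignment.n_cols,
            "n_site_patterns": self.n_site_patterns,
            "event_counts": {
                region: {c: int(n) for c, n in row.items()}
                for region, row in self.event_counts().iterrows()
            },
            "n_cbc_clades": len(self.clades),
            "n_subclades": len(self.subclades),
            "monophyly": {str(k + 1): v for k, v in self.monophyly.items()},
            "provenance": self._provenance(),
        }
        p = outdir / "report.json"
        p.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        paths["report.json"] = p
        return paths

    def _provenance(self) -> Dict[str, str]:
        h = hashlib.sha256()
        for taxon, row in self.model.alignment.rows:
            h.update(taxon.encode())
            h.update(row.encode())
        for region, pcm in sorted(self.maps.items()):
            h.update(region.encode())
            h.update(str(sorted(pcm.paired_cols)).encode())
        from . import __version__
        return {"input_sha256": h.hexdigest(), "package_version": __version__}
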