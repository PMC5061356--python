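"""Readers and writers for the external formats the pipeline touches.

FASTA and aligned FASTA go through Biopython; newick trees through dendropy.
Sequences are normalised to RNA on input: lowercase is uppercased and T
becomes U (GenBank ITS records are DNA, the structure models are RNA); the
normalisation is logged once per file and is idempotent.  The only gap
character is ``-`` — a ``.`` in an alignment is rejected because it is
reserved for dot-bracket structure strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import dendropy
from Bio import SeqIO

from .errors import AlphabetError, FormatError, ValidationError
from .structure import SecondaryStructure, pairs_from_dotbracket

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGUN")
GAP = "-"


def normalize_residues(raw: str, *, allow_gaps: bool, context: str = "") -> str:
    """Uppercase, map T→U, validate against {A,C,G,U,N} (+ '-' if allowed)."""
    s = raw.upper().replace("T", "U")
    allowed = RNA_ALPHABET | ({GAP} if allow_gaps else set())
    bad = set(s) - allowed
    if bad:
        if "." in bad and allow_gaps:
            raise ValidationError(
                f"{context}: '.' is not a valid gap character (use '-')"
            )
        if bad <= {GAP, "."}:
            raise ValidationError(f"{context}: gap characters not allowed here")
        raise AlphabetError(f"{context}: invalid characters {sorted(bad)}")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """One ungapped RNA sequence with its FASTA id and description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"invalid sequence id {self.id!r}")
        if not self.residues:
            raise ValidationError(f"record {self.id!r} has an empty sequence")


class Alignment:
    """Ordered multiple sequence alignment over {A,C,G,U,N,-}.

    Rows are (id, gapped residues); all rows share ``n_cols`` columns and ids
    are unique.  Positions and columns are 1-based in every public method.
    """

    def __init__(self, rows: Sequence[Tuple[str, str]]):
        if len(rows) < 2:
            raise ValidationError("an alignment needs at least 2 rows")
        ids = [r[0] for r in rows]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate ids in alignment")
        lengths = {len(r[1]) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment rows: lengths {sorted(lengths)}")
        self._rows: List[Tuple[str, str]] = [(i, s) for i, s in rows]
        self._index = {i: s for i, s in rows}
        self.n_cols = lengths.pop()
        if self.n_cols == 0:
            raise ValidationError("alignment has zero columns")

    @property
    def ids(self) -> List[str]:
        return [i for i, _ in self._rows]

    @property
    def rows(self) -> List[Tuple[str, str]]:
        return list(self._rows)

    def row(self, taxon: str) -> str:
        return self._index[taxon]

    def column(self, col: int) -> List[str]:
        """Residues of 1-based column ``col`` in row order."""
        return [s[col - 1] for _, s in self._rows]

    def __len__(self) -> int:
        return len(self._rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, Alignment) and self._rows == other._rows


def read_fasta(path) -> List[SequenceRecord]:
    """Read ungapped FASTA; order preserved, DNA normalised to RNA."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    seen, out = set(), []
    normalised = False
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if "T" in raw or "t" in raw or raw != raw.upper():
            normalised = True
        residues = normalize_residues(raw, allow_gaps=False, context=f"{path}:{rec.id}")
        out.append(SequenceRecord(id=rec.id, residues=residues,
                                  description=rec.description))
    if normalised:
        logger.info("%s: input normalised to uppercase RNA (T->U)", path)
    return out


def read_alignment(path) -> Alignment:
    """Read aligned FASTA into an :class:`Alignment`."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    rows = []
    for rec in records:
        residues = normalize_residues(str(rec.seq), allow_gaps=True,
                                      context=f"{path}:{rec.id}")
        rows.append((rec.id, residues))
    return Alignment(rows)


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n{rec.residues}\n")


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in aln.rows:
            fh.write(f">{taxon}\n{seq}\n")


def parse_vienna(text: str):
    """Parse a 3-line Vienna record: header, sequence, dot-bracket.

    Returns ``(SequenceRecord, SecondaryStructure)``; the structure length
    must equal the sequence length.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if len(lines) != 3 or not lines[0].startswith(">"):
        raise FormatError("Vienna record must be: '>header', sequence, structure")
    header = lines[0][1:].strip()
    seq_id = header.split()[0] if header else ""
    residues = normalize_residues(lines[1], allow_gaps=False, context=seq_id or "vienna")
    if len(lines[2]) != len(residues):
        raise FormatError(
            f"structure length {len(lines[2])} != sequence length {len(residues)}"
        )
    structure = pairs_from_dotbracket(lines[2])
    return SequenceRecord(id=seq_id or "template", residues=residues,
                          description=header), structure


def read_vienna(path):
    return parse_vienna(Path(path).read_text())


def write_vienna(record: SequenceRecord, structure: SecondaryStructure, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.id}\n{record.residues}\n{structure.to_dotbracket()}\n")


def read_newick(path) -> dendropy.Tree:
    """Read a rooted newick tree; tip labels must be unique."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        if "uplicate taxon" in str(exc):
            raise ValidationError(f"{path}: duplicate tip labels") from exc
        raise FormatError(f"{path}: cannot parse newick ({exc})") from exc
    return _validate_tree(tree, str(path))


def parse_newick(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        if "uplicate taxon" in str(exc):
            raise ValidationError("duplicate tip labels") from exc
        raise FormatError(f"cannot parse newick ({exc})") from exc
    return _validate_tree(tree, "<string>")


def _validate_tree(tree: dendropy.Tree, context: str) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"{context}: duplicate tip labels {dupes}")
    if len(tree.seed_node.child_nodes()) < 2:
        # a unifurcating seed node usually means an unrooted reading
        tree.suppress_unifurcations()
        if len(tree.seed_node.child_nodes()) < 2:
            raise ValidationError(f"{context}: root must have >= 2 children")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


EVENT_TSV_COLUMNS = [
    "site_cols", "region_label", "helix_label", "category",
    "from_state", "to_state", "taxa_or_edge",
]


def write_events_tsv(events, path) -> None:
    """Write classified substitution events as a TSV table.

    An empty event list still produces the header line, so downstream tools
    can rely on the schema.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(EVENT_TSV_COLUMNS) + "\n")
        for ev in events:
            fh.write("\t".join(ev.as_tsv_row()) + "\n")
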