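"""RNA secondary structures, helix decomposition, projection and consensus folding.

A structure is a pseudoknot-free set of base pairs over a sequence of known
length.  Helices ("arms") are the children of the exterior loop, numbered with
roman numerals in 5'→3' order — the convention used for the ITS1/ITS2 common
core, where internal loops, bulges and three-way junctions stay *inside* one
named helix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ProjectionError, StructureError, ValidationError

MIN_HAIRPIN_LOOP = 3

# canonical Watson-Crick plus the G·U wobble, used by the consensus fold
_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}
_PAIRABLE = _CANONICAL | _WOBBLE

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "XI", "XII", "XIII", "XIV", "XV",
]


def roman(n: int) -> str:
    """Roman numeral for small n (helix labels)."""
    if 1 <= n <= len(_ROMAN):
        return _ROMAN[n - 1]
    return str(n)


def _validate_pair(i: int, j: int, min_loop: int = MIN_HAIRPIN_LOOP) -> None:
    if not (1 <= i < j):
        raise StructureError(f"base pair ({i},{j}) must satisfy 1 <= i < j")
    if j - i - 1 < min_loop:
        raise StructureError(
            f"base pair ({i},{j}) encloses a loop of {j - i - 1} < {min_loop} nt"
        )


@dataclass(frozen=True)
class SecondaryStructure:
    """Pseudoknot-free base-pair set over a sequence of ``length`` residues.

    Positions are 1-based.  Each position occurs in at most one pair and no
    two pairs cross.
    """

    length: int
    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.length < 1:
            raise StructureError("structure length must be positive")
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        seen = set()
        for (i, j) in self.pairs:
            _validate_pair(i, j)
            if j > self.length:
                raise StructureError(f"pair ({i},{j}) outside length {self.length}")
            for p in (i, j):
                if p in seen:
                    raise StructureError(f"position {p} occurs in more than one pair")
                seen.add(p)
        ordered = sorted(self.pairs)
        for a, (i, j) in enumerate(ordered):
            for (k, l) in ordered[a + 1:]:
                if k > j:
                    break
                if i < k <= j < l:
                    raise StructureError(
                        f"pairs ({i},{j}) and ({k},{l}) cross (pseudoknot)"
                    )

    @property
    def partner(self) -> dict:
        """Map position → paired position (both directions)."""
        d = {}
        for (i, j) in self.pairs:
            d[i] = j
            d[j] = i
        return d

    @property
    def paired_positions(self) -> set:
        return {p for pair in self.pairs for p in pair}

    def to_dotbracket(self) -> str:
        db = ["."] * self.length
        for (i, j) in self.pairs:
            db[i - 1] = "("
            db[j - 1] = ")"
        return "".join(db)

    def __len__(self) -> int:
        return self.length


def pairs_from_dotbracket(db: str, min_loop: int = MIN_HAIRPIN_LOOP) -> SecondaryStructure:
    """Parse single-bracket dot-bracket notation into a structure.

    Raises :class:`StructureError` on unbalanced brackets or a hairpin loop
    shorter than ``min_loop``.
    """
    bad = set(db) - {".", "(", ")"}
    if bad:
        raise StructureError(f"unexpected characters in dot-bracket: {sorted(bad)}")
    stack, pairs = [], set()
    for pos, c in enumerate(db, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            i = stack.pop()
            _validate_pair(i, pos, min_loop)
            pairs.add((i, pos))
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(length=len(db), pairs=frozenset(pairs))


@dataclass(frozen=True)
class HelixArm:
    """One stem-loop emanating from the exterior loop.

    ``n_nt`` counts every nucleotide the arm spans, hairpin loop and internal
    loops included (end − start + 1).
    """

    label: str
    start: int
    end: int
    pairs: frozenset

    @property
    def n_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def decompose_helices(s: SecondaryStructure) -> list:
    """Split a structure into its exterior-loop arms, labelled I, II, … 5'→3'.

    An arm is the region enclosed by one outermost pair; every pair of the
    structure belongs to exactly one arm.  A structure with no pairs yields an
    empty list.
    """
    outer = []
    ordered = sorted(s.pairs)
    enclosing_end = 0
    for (i, j) in ordered:
        if i > enclosing_end:  # not nested inside the previous outermost pair
            outer.append((i, j))
            enclosing_end = j
    arms = []
    for n, (i, j) in enumerate(outer, start=1):
        inside = frozenset(p for p in s.pairs if i <= p[0] and p[1] <= j)
        arms.append(HelixArm(label=roman(n), start=i, end=j, pairs=inside))
    return arms


@dataclass(frozen=True)
class PairedColumnMap:
    """Template structure projected onto alignment columns (all 1-based).

    ``paired_cols`` holds (colI, colJ) per template base pair, 5'→3';
    ``unpaired_cols`` the columns of unpaired template positions;
    ``helix_of_pair`` maps each column pair to its helix label ('junction'
    is never paired, so unpaired columns carry no label here).
    """

    region_label: str
    template_id: str
    paired_cols: tuple
    unpaired_cols: tuple
    helix_of_pair: Mapping
    col_of_pos: Mapping  # template position -> alignment column
    arms: tuple = ()

    def __post_init__(self):
        cols = [c for pc in self.paired_cols for c in pc] + list(self.unpaired_cols)
        if len(cols) != len(set(cols)):
            raise ValidationError("a column appears more than once in the map")
        for (i, j) in self.paired_cols:
            if not i < j:
                raise ValidationError(f"paired columns ({i},{j}) must satisfy colI < colJ")

    def unproject(self) -> SecondaryStructure:
        """Map paired columns back to ungapped template coordinates."""
        pos_of_col = {c: p for p, c in self.col_of_pos.items()}
        pairs = frozenset(
            (pos_of_col[ci], pos_of_col[cj]) for (ci, cj) in self.paired_cols
        )
        return SecondaryStructure(length=len(self.col_of_pos), pairs=pairs)


def project_to_alignment(aln, template_id: str, s: SecondaryStructure,
                         region_label: str, col_offset: int = 0) -> PairedColumnMap:
    """Project a template structure through its (gapped) alignment row.

    The template's i-th residue sits in some alignment column; each template
    base pair (i, j) becomes the column pair holding those residues.
    ``col_offset`` shifts all columns (used when the alignment is a slice of a
    longer one).
    """
    try:
        row = aln.row(template_id)
    except KeyError:
        raise ProjectionError(f"template id {template_id!r} not in alignment") from None
    col_of_pos = {}
    pos = 0
    for col, ch in enumerate(row, start=1):
        if ch != "-":
            pos += 1
            col_of_pos[pos] = col + col_offset
    if pos != s.length:
        raise ProjectionError(
            f"ungapped template length {pos} != structure length {s.length}"
        )
    arms = decompose_helices(s)
    helix_of_pos = {}
    for arm in arms:
        for p in arm.pairs:
            helix_of_pos[p] = arm.label
    paired_cols, helix_of_pair = [], {}
    for (i, j) in sorted(s.pairs):
        cp = (col_of_pos[i], col_of_pos[j])
        paired_cols.append(cp)
        helix_of_pair[cp] = helix_of_pos[(i, j)]
    paired_pos = s.paired_positions
    unpaired_cols = tuple(
        col_of_pos[p] for p in range(1, s.length + 1) if p not in paired_pos
    )
    return PairedColumnMap(
        region_label=region_label,
        template_id=template_id,
        paired_cols=tuple(paired_cols),
        unpaired_cols=unpaired_cols,
        helix_of_pair=helix_of_pair,
        col_of_pos=col_of_pos,
        arms=tuple(arms),
    )


# ---------------------------------------------------------------------------
# covariation-aware consensus folding (Nussinov-style dynamic programme)
# ---------------------------------------------------------------------------

def _column_pair_score(cols_i: Sequence[str], cols_j: Sequence[str],
                       pair_threshold: float, covariation_bonus: float):
    """Score for pairing two alignment columns, or None if below threshold.

    score = pairing fraction + bonus × (distinct compatible pair types − 1).
    Rows with a gap at either column count against the fraction.
    """
    n = len(cols_i)
    types = set()
    ok = 0
    for x, y in zip(cols_i, cols_j):
        if (x, y) in _PAIRABLE:
            ok += 1
            types.add((x, y))
    frac = ok / n
    if frac < pair_threshold or ok == 0:
        return None
    return frac + covariation_bonus * (len(types) - 1)


def consensus_fold(aln, min_loop: int = MIN_HAIRPIN_LOOP,
                   pair_threshold: float = 0.5,
                   covariation_bonus: float = 1.0) -> SecondaryStructure:
    """Fold a consensus structure for an alignment by covariation-scored
    Nussinov dynamic programming.

    Maximises the sum of column-pair scores over all pseudoknot-free
    structures; ties are broken deterministically in favour of the structure
    whose 5'-most differing position is paired (smaller partner preferred).
    This is a deliberately simple stand-in for thermodynamic/SCFG consensus
    folders: it captures conservation and compensatory covariation, not free
    energy.

    ``aln`` may also be a plain sequence string, folded as a one-row
    alignment (every canonical/wobble pair then scores 1).
    """
    if isinstance(aln, str):
        n = len(aln)
        cols = [[ch] for ch in aln]
    else:
        n = aln.n_cols
        cols = [aln.column(c) for c in range(1, n + 1)]
    score = [[None] * (n + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(i + min_loop + 1, n + 1):
            score[i][j] = _column_pair_score(
                cols[i - 1], cols[j - 1], pair_threshold, covariation_bonus
            )

    # M[i][j] = best total score on columns i..j (1-based, inclusive)
    M = [[0.0] * (n + 2) for _ in range(n + 2)]
    for span in range(min_loop + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            best = M[i][j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if score[k][j] is None:
                    continue
                left = M[i][k - 1] if k > i else 0.0
                inner = M[k + 1][j - 1]
                cand = left + score[k][j] + inner
                if cand > best:
                    best = cand
            M[i][j] = best

    eps = 1e-9
    pairs = []

    def trace(i: int, j: int) -> None:
        # decide the status of position i first: lexicographic tie-break
        while i <= j:
            if j - i <= min_loop:
                return
            target = M[i][j]
            chosen = None
            for k in range(i + min_loop + 1, j + 1):  # smallest partner first
                if score[i][k] is None:
                    continue
                rest = M[k + 1][j] if k < j else 0.0
                if abs(score[i][k] + M[i + 1][k - 1] + rest - target) < eps:
                    chosen = k
                    break
            if chosen is None:
                i += 1  # i unpaired in every optimal structure reachable here
                continue
            pairs.append((i, chosen))
            trace(i + 1, chosen - 1)
            i = chosen + 1

    trace(1, n)
    return SecondaryStructure(length=n, pairs=frozenset(pairs))


def detect_structure_deletions(pcm: PairedColumnMap, aln) -> dict:
    """Per-taxon structural deletions: template pairs lost to gaps.

    A pair is lost in a taxon when at least one of its two columns is a gap in
    that taxon's row.  Returns ``{taxon: [(helix_label, n_lost, [col_pairs])]}``
    with gap-free taxa mapped to empty lists.
    """
    out = {}
    for taxon in aln.ids:
        row = aln.row(taxon)
        per_helix = {}
        for cp in pcm.paired_cols:
            ci, cj = cp
            if row[ci - 1] == "-" or row[cj - 1] == "-":
                per_helix.setdefault(pcm.helix_of_pair[cp], []).append(cp)
        out[taxon] = [
            (label, len(lost), lost) for label, lost in sorted(per_helix.items())
        ]
    return out
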