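"""Classification of substitutions at structure-projected sites.

At a paired site the joint state of the two columns is a *pair state*:
canonical (A-U, U-A, G-C, C-G), wobble (G·U, U·G), noncanonical (any other
gap-free combination) or incomplete (a gap or N on either side).  A change
between two taxa is then

* **CBC** — both positions substituted, both end states canonical
  (e.g. C=G → U-A): pairing preserved by double-sided compensation;
* **hCBC** — exactly one position substituted, canonical ↔ wobble
  (e.g. G=C → G·U): pairing preserved one-sidedly;
* **nonCBC** — a canonical or wobble pair replaced by a noncanonical one:
  the stem is disrupted;
* **other_paired** — the remaining changed cases (double-sided
  canonical↔wobble, wobble↔wobble, noncanonical↔noncanonical), outside the
  three-way taxonomy above but still recorded, with a subtype tag.

Classification is symmetric: polarity needs a rooted tree and is assigned
only by the tree-mapping step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import AlphabetError, ValidationError
from .io import Alignment
from .structure import PairedColumnMap

NUCLEOTIDES = "ACGU"
CANONICAL_PAIRS = {"AU", "UA", "GC", "CG"}
WOBBLE_PAIRS = {"GU", "UG"}

CANONICAL = "canonical"
WOBBLE = "wobble"
NONCANONICAL = "noncanonical"
INCOMPLETE = "incomplete"

CBC = "CBC"
HCBC = "hCBC"
NONCBC = "nonCBC"
OTHER_PAIRED = "other_paired"
SINGLE = "single"
INDEL = "indel"


@dataclass(frozen=True)
class PairState:
    """Joint state of the two strands of one paired site."""

    x: str
    y: str

    def __post_init__(self):
        for c in (self.x, self.y):
            if c not in "ACGUN-":
                raise AlphabetError(f"invalid pair-state character {c!r}")

    @property
    def klass(self) -> str:
        if self.x in "N-" or self.y in "N-":
            return INCOMPLETE
        s = self.x + self.y
        if s in CANONICAL_PAIRS:
            return CANONICAL
        if s in WOBBLE_PAIRS:
            return WOBBLE
        return NONCANONICAL

    def __str__(self) -> str:
        return self.x + self.y


def classify_pair_state(x: str, y: str) -> PairState:
    """Build the :class:`PairState` for nucleotides at (colI, colJ)."""
    return PairState(x, y)


def classify_transition(p: PairState, q: PairState) -> Optional[str]:
    """Category of the change between two gap-free pair states (symmetric).

    Returns ``None`` for identical states.  Incomplete states are a contract
    violation here — gaps and Ns are handled upstream as indels/exclusions.
    """
    if INCOMPLETE in (p.klass, q.klass):
        raise ValidationError("classify_transition requires gap-free pair states")
    if (p.x, p.y) == (q.x, q.y):
        return None
    kp, kq = p.klass, q.klass
    n_changed = (p.x != q.x) + (p.y != q.y)
    if kp == CANONICAL and kq == CANONICAL:
        # two distinct canonical pairs always differ on both strands
        return CBC
    if {kp, kq} == {CANONICAL, WOBBLE}:
        return HCBC if n_changed == 1 else OTHER_PAIRED
    if NONCANONICAL in (kp, kq) and kp != kq:
        # one side noncanonical, the other canonical or wobble
        return NONCBC
    return OTHER_PAIRED  # wobble<->wobble or noncanonical<->noncanonical


def transition_subtype(p: PairState, q: PairState) -> Optional[str]:
    """Subtype tag for ``other_paired`` transitions, else None."""
    if classify_transition(p, q) != OTHER_PAIRED:
        return None
    kinds = frozenset((p.klass, q.klass))
    if kinds == {CANONICAL, WOBBLE}:
        return "double_sided_canonical_wobble"
    if kinds == {WOBBLE}:
        return "wobble_wobble"
    return "noncanonical_noncanonical"


@dataclass(frozen=True)
class SubstitutionEvent:
    """One classified change at a site, between two taxon sets or on an edge.

    ``site`` is (colI, colJ) for paired sites or (col,) for single columns,
    1-based alignment coordinates.  ``between`` is either a pair of frozensets
    of taxon ids (unordered comparison) or an (parent, child) edge label pair
    from the tree mapping.
    """

    region: str
    site: Tuple[int, ...]
    helix_label: str
    category: str
    from_state: str
    to_state: str
    between: Tuple
    subtype: Optional[str] = None
    ambiguous: bool = False

    def as_tsv_row(self) -> List[str]:
        site_cols = ":".join(str(c) for c in self.site)
        if self.between and isinstance(self.between[0], frozenset):
            taxa = "|".join(",".join(sorted(s)) for s in self.between)
        else:
            taxa = "->".join(str(b) for b in self.between)
        return [site_cols, self.region, self.helix_label, self.category,
                self.from_state, self.to_state, taxa]


def _canonical_event_order(a: str, b: str):
    """Deterministic unordered presentation: smaller state string first."""
    return (a, b) if a <= b else (b, a)


def enumerate_site_events(aln: Alignment, pcm: PairedColumnMap,
                          return_excluded: bool = False):
    """Collect every distinct-state event the alignment shows at mapped sites.

    Per paired site the distinct gap-free pair states across taxa are
    gathered and one event is emitted per unordered pair of distinct states,
    carrying the taxon sets on each side; unpaired columns yield ``single``
    events the same way.  Any state containing a gap adds an ``indel`` event
    (one per distinct gapped state at the site); sites where any taxon shows
    an N are excluded from classification and reported.
    """
    events: List[SubstitutionEvent] = []
    excluded: List[Tuple[int, ...]] = []

    def site_states(cols: Tuple[int, ...]):
        states: Dict[str, List[str]] = {}
        for taxon in aln.ids:
            row = aln.row(taxon)
            state = "".join(row[c - 1] for c in cols)
            states.setdefault(state, []).append(taxon)
        return states

    for cp in pcm.paired_cols:
        states = site_states(cp)
        if any("N" in s for s in states):
            excluded.append(cp)
            continue
        helix = pcm.helix_of_pair[cp]
        complete = sorted(s for s in states if "-" not in s)
        gapped = sorted(s for s in states if "-" in s)
        for ai in range(len(complete)):
            for bi in range(ai + 1, len(complete)):
                a, b = _canonical_event_order(complete[ai], complete[bi])
                cat = classify_transition(PairState(*a), PairState(*b))
                sub = transition_subtype(PairState(*a), PairState(*b))
                events.append(SubstitutionEvent(
                    region=pcm.region_label, site=cp, helix_label=helix,
                    category=cat, from_state=a, to_state=b,
                    between=(frozenset(states[a]), frozenset(states[b])),
                    subtype=sub,
                ))
        for g in gapped:
            others = frozenset(t for s in complete for t in states[s])
            events.append(SubstitutionEvent(
                region=pcm.region_label, site=cp, helix_label=helix,
                category=INDEL, from_state=complete[0] if complete else "--",
                to_state=g,
                between=(others, frozenset(states[g])),
            ))

    for col in pcm.unpaired_cols:
        states = site_states((col,))
        if "N" in states:
            excluded.append((col,))
            continue
        complete = sorted(s for s in states if s != "-")
        for ai in range(len(complete)):
            for bi in range(ai + 1, len(complete)):
                a, b = complete[ai], complete[bi]
                events.append(SubstitutionEvent(
                    region=pcm.region_label, site=(col,), helix_label="loop/junction",
                    category=SINGLE, from_state=a, to_state=b,
                    between=(frozenset(states[a]), frozenset(states[b])),
                ))
        if "-" in states:
            others = frozenset(t for s in complete for t in states[s])
            events.append(SubstitutionEvent(
                region=pcm.region_label, site=(col,), helix_label="loop/junction",
                category=INDEL, from_state=complete[0] if complete else "-",
                to_state="-",
                between=(others, frozenset(states["-"])),
            ))

    if return_excluded:
        return events, excluded
    return events


@dataclass
class CbcMatrix:
    """Symmetric pairwise CBC counts over an ordered taxon list."""

    taxa: List[str]
    counts: np.ndarray

    def __post_init__(self):
        n = len(self.taxa)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (n, n):
            raise ValidationError("CBC matrix shape does not match taxa")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValidationError("CBC matrix must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ValidationError("CBC matrix diagonal must be zero")
        if np.any(self.counts < 0):
            raise ValidationError("CBC counts must be non-negative")

    def count(self, a: str, b: str) -> int:
        ia, ib = self.taxa.index(a), self.taxa.index(b)
        return int(self.counts[ia, ib])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.taxa)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="taxon")


def cbc_matrix(aln: Alignment, maps: Sequence[PairedColumnMap]) -> CbcMatrix:
    """Pairwise CBC counts summed over every paired site of every map.

    Gapped or N-containing states never contribute (they are incomplete, not
    substitutions), so missing data cannot create spurious CBCs.
    """
    taxa = aln.ids
    idx = {t: k for k, t in enumerate(taxa)}
    counts = np.zeros((len(taxa), len(taxa)), dtype=int)
    for pcm in maps:
        for ev in enumerate_site_events(aln, pcm):
            if ev.category != CBC:
                continue
            left, right = ev.between
            for a in left:
                for b in right:
                    counts[idx[a], idx[b]] += 1
                    counts[idx[b], idx[a]] += 1
    return CbcMatrix(taxa=list(taxa), counts=counts)


def count_site_patterns(aln: Alignment) -> int:
    """Number of distinct alignment columns, the gap counting as a 5th state."""
    return len({tuple(aln.column(c)) for c in range(1, aln.n_cols + 1)})


def events_frame(events: Iterable[SubstitutionEvent]) -> pd.DataFrame:
    """Tabulate events for reporting."""
    rows = []
    for ev in events:
        rows.append({
            "site_cols": ":".join(map(str, ev.site)),
            "region": ev.region,
            "helix": ev.helix_label,
            "category": ev.category,
            "from_state": ev.from_state,
            "to_state": ev.to_state,
            "subtype": ev.subtype or "",
            "ambiguous": ev.ambiguous,
            "taxa_or_edge": ev.as_tsv_row()[-1],
        })
    return pd.DataFrame(rows, columns=[
        "site_cols", "region", "helix", "category", "from_state", "to_state",
        "subtype", "ambiguous", "taxa_or_edge",
    ])
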