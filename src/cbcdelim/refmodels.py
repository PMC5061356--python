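"""Synthetic ITS1/ITS2 secondary-structure reference models.

These are *synthetic stand-ins*, built in code, that reproduce the published
geometry of the chaetothyrialean ITS fold rather than any real sequence:

* ITS1 — five exterior-loop helices I–V; helix III is the longest and folds
  into a three-way junction whose right-hand subhelix carries a 6-pair upper
  stem and hairpin loop (the unit lost in the deletion lineage);
* ITS2 — the eukaryotic common core: four main helices plus a short fifth
  near the 3' end, with helix II spanning 32 nt and helix III 67 nt.

They serve as folding templates for the simulator and as fixtures for the
helix-decomposition checks.  Sequences are generated deterministically with
all template pairs canonical.
"""

from __future__ import annotations

from .io import SequenceRecord
from .structure import SecondaryStructure, pairs_from_dotbracket

# 143 nt, five arms; arm III = 45..99 (55 nt) with a three-way junction
ITS1_DOTBRACKET = (
    "..."
    "(((((((......)))))))"            # I   : 4..23
    "."
    "(((((((....)))))))"              # II  : 25..42
    ".."
    "((((("                           # III : 45..99, outer stem
    "."
    "(((((((....)))))))"              #   left subhelix
    "."
    "((((((((((....))))))))))"        #   right subhelix (upper 6 pairs deletable)
    "."
    ")))))"
    "."
    "((((((((......))))))))"          # IV  : 101..122
    ".."
    "((((((....))))))"                # V   : 125..140
    "..."
)

# 171 nt, four main arms + short arm V; arm II = 28..59 (32 nt), III = 61..127 (67 nt)
ITS2_DOTBRACKET = (
    "..."
    "((((((((......))))))))"          # I   : 4..25
    ".."
    "((((((((((((((....))))))))))))))"  # II : 28..59 (14 pairs, 4-nt loop)
    "."
    "((((((((((...((((((((((((((((((((....))))))))))))))))))))))))))))))"  # III: 61..127
    ".."
    "(((((((((......)))))))))"        # IV  : 130..153
    ".."
    "((((.....))))"                   # V   : 156..168
    "..."
)

_CANONICAL_CYCLE = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]
_LOOP_CYCLE = "AUCAG"


def _sequence_for(db: str) -> str:
    """Deterministic sequence whose template pairs are all canonical."""
    structure = pairs_from_dotbracket(db)
    seq = [""] * len(db)
    for k, (i, j) in enumerate(sorted(structure.pairs)):
        x, y = _CANONICAL_CYCLE[k % len(_CANONICAL_CYCLE)]
        seq[i - 1], seq[j - 1] = x, y
    loop_k = 0
    for p in range(len(db)):
        if not seq[p]:
            seq[p] = _LOOP_CYCLE[loop_k % len(_LOOP_CYCLE)]
            loop_k += 1
    return "".join(seq)


def synthetic_its1_model():
    """Synthetic ITS1 template: (SequenceRecord, SecondaryStructure)."""
    record = SequenceRecord(
        id="ITS1_template_synthetic",
        residues=_sequence_for(ITS1_DOTBRACKET),
        description="synthetic ITS1 model, five helices, 3WJ helix III",
    )
    return record, pairs_from_dotbracket(ITS1_DOTBRACKET)


def synthetic_its2_model():
    """Synthetic ITS2 template: (SequenceRecord, SecondaryStructure)."""
    record = SequenceRecord(
        id="ITS2_template_synthetic",
        residues=_sequence_for(ITS2_DOTBRACKET),
        description="synthetic ITS2 common-core model, helix II 32 nt / III 67 nt",
    )
    return record, pairs_from_dotbracket(ITS2_DOTBRACKET)
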