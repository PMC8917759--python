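"""Anchored classification of BIR (Baculovirus IAP Repeat) domains.

Each oyster BIR sequence is anchored to a bundled reference BIR backbone by
global pairwise alignment (BLOSUM62, affine gaps, free end gaps), giving a
monotone map from query residues to canonical alignment positions.  Residues
at the nine diagnostic positions (34, 57, 60, 76, 77, 80, 81, 82, 84) are then
read off and a rule-based classifier assigns one of seven types:

* Type I      — H77, hydrophobic V/L at 80, C84 (TRAF/TAB-binding groove)
* Type II     — E76 or Q76, H77, W80 or H80, C84 (IBM/caspase-binding groove)
* Type I-like — hydrophobic I/V/L at 80 and/or S81, short of the full Type I
* Type II-like— E76 preceding the conserved H77, short of the full Type II
* Type X      — G80 + R82 substitutions (novel, predicted shortened alpha-3)
* Type Y      — three-residue deletion spanning position 80 (novel)
* NZBIR       — T at the first zinc-coordinating cysteine C57 (novel,
                predicted non-zinc-binding)

Rules are applied in a fixed precedence order, most diagnostic first:
NZBIR > TypeY > TypeX > TypeII > TypeI > TypeII_like > TypeI_like.

The bundled reference alignment is a synthetic stand-in backbone: it carries
the canonical numbering and the 15 conserved model-organism positions
(including zinc-coordinating C57, C60, H77, C84 and G34) but is not derived
from any real model-organism sequence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .config import PACKAGE_DATA_DIR
from .io_formats import read_fasta

GAP = "-"


class BirType(str, Enum):
    TypeI = "TypeI"
    TypeII = "TypeII"
    TypeI_like = "TypeI_like"
    TypeII_like = "TypeII_like"
    TypeX = "TypeX"
    TypeY = "TypeY"
    NZBIR = "NZBIR"
    Unclassified = "Unclassified"


#: architecture token emitted for each type
TYPE_TOKENS = {
    BirType.TypeI: "TI",
    BirType.TypeII: "TII",
    BirType.TypeI_like: "TI_like",
    BirType.TypeII_like: "TII_like",
    BirType.TypeX: "TX",
    BirType.TypeY: "TY",
    BirType.NZBIR: "NZBIR",
    BirType.Unclassified: "BIR_STAR",
}

KEY_POSITIONS = (34, 57, 60, 76, 77, 80, 81, 82, 84)


class UnanchorableError(ValueError):
    """Query could not be aligned to the reference above the score floor."""


@dataclass(frozen=True)
class ReferenceAlignment:
    """Bundled reference backbone with canonical position bookkeeping."""

    consensus: str
    organism_sequences: dict[str, str]
    key_positions: tuple[int, ...]
    conserved_positions: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class KeyResidues:
    """Residue observed at each canonical key position (GAP if deleted)."""

    residues: dict[int, str]
    deletion_span_over_80: bool = False

    def __getitem__(self, pos: int) -> str:
        return self.residues.get(pos, GAP)


@dataclass(frozen=True)
class BirCall:
    protein_id: str
    bir_index: int           # 1-based, N-terminal order
    span: tuple[int, int]    # 0-based half-open on the protein
    key_residues: KeyResidues
    bir_type: BirType
    cdd_confirmed: bool = True
    alignment_score: float = 0.0

    @property
    def token(self) -> str:
        if not self.cdd_confirmed:
            return "BIR_STAR"
        return TYPE_TOKENS[self.bir_type]


@lru_cache(maxsize=1)
def load_reference() -> ReferenceAlignment:
    records = read_fasta(PACKAGE_DATA_DIR / "bir_reference_synthetic.fasta")
    consensus = next(r.residues for r in records if r.id == "consensus")
    organisms = {r.id: r.residues for r in records if r.id != "consensus"}
    key, conserved = [], []
    with open(PACKAGE_DATA_DIR / "bir_reference_positions.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pos = int(row["position"])
            roles = row["role"].split(",")
            if "key" in roles:
                key.append(pos)
            if "conserved" in roles:
                conserved.append(pos)
    ref = ReferenceAlignment(consensus, organisms, tuple(key), tuple(conserved))
    assert ref.key_positions == KEY_POSITIONS
    assert len(ref.conserved_positions) == 15
    return ref


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # affine gap: open 10, extend 1 (first gap residue costs 11)
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # free end gaps so N/C-terminal flanks do not shift the anchoring
    aligner.end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def anchor_to_reference(
    query: str,
    ref: ReferenceAlignment | None = None,
    min_score_fraction: float = 0.35,
) -> tuple[dict[int, int], float]:
    """Map query residue indices (0-based) to canonical positions (1-based).

    The map is produced by global alignment with affine gaps and free end
    gaps against the reference consensus; it is monotone by construction.
    Canonical positions absent from the map are deletions in the query.

    Returns (position_map, alignment_score).  Raises UnanchorableError when
    the score falls below ``min_score_fraction`` of the reference self-score.
    """
    if ref is None:
        ref = load_reference()
    if len(query) < 20:
        raise UnanchorableError(f"query too short ({len(query)} residues)")
    aligner = _make_aligner()
    floor = min_score_fraction * aligner.score(ref.consensus, ref.consensus)
    alignment = aligner.align(ref.consensus, query)[0]
    if alignment.score < floor:
        raise UnanchorableError(
            f"alignment score {alignment.score:.1f} below floor {floor:.1f}")
    position_map: dict[int, int] = {}
    for (tstart, tend), (qstart, qend) in zip(*alignment.aligned):
        for offset in range(tend - tstart):
            position_map[qstart + offset] = tstart + offset + 1
    return position_map, float(alignment.score)


def extract_key_residues(
    query: str,
    position_map: dict[int, int],
    ref: ReferenceAlignment | None = None,
) -> KeyResidues:
    """Read the residues at the canonical key positions.

    Positions with no aligned query residue are reported as GAP, and a run of
    three or more consecutive deleted canonical positions covering position 80
    sets ``deletion_span_over_80``.
    """
    if ref is None:
        ref = load_reference()
    inverse = {pos: query[i] for i, pos in position_map.items()}
    residues = {pos: inverse.get(pos, GAP) for pos in ref.key_positions}
    deleted = [p for p in range(1, ref.length + 1) if p not in inverse]
    deletion_over_80 = False
    if deleted:
        run: list[int] = []
        for p in deleted:
            if run and p == run[-1] + 1:
                run.append(p)
            else:
                run = [p]
            if len(run) >= 3 and run[0] <= 80 <= run[-1]:
                deletion_over_80 = True
    return KeyResidues(residues, deletion_over_80)


def classify_bir(k: KeyResidues) -> BirType:
    """Assign a BIR type from key residues; pure and total.

    Precedence (first match wins): the three single-diagnostic novel types,
    then the full conserved patterns, then the relaxed *-like patterns.
    """
    if k[57] == "T":
        return BirType.NZBIR
    if k.deletion_span_over_80:
        return BirType.TypeY
    if k[80] == "G" and k[82] == "R":
        return BirType.TypeX
    if k[76] in ("E", "Q") and k[77] == "H" and k[80] in ("W", "H") \
            and k[84] == "C":
        return BirType.TypeII
    if k[77] == "H" and k[80] in ("V", "L") and k[84] == "C":
        return BirType.TypeI
    if k[76] == "E" and k[77] == "H":
        return BirType.TypeII_like
    if k[80] in ("I", "V", "L") or k[81] == "S":
        return BirType.TypeI_like
    return BirType.Unclassified


def type_bir_sequence(
    query: str,
    ref: ReferenceAlignment | None = None,
) -> tuple[BirType, KeyResidues, float]:
    """Anchor, extract key residues and classify in one call."""
    position_map, score = anchor_to_reference(query, ref)
    key = extract_key_residues(query, position_map, ref)
    return classify_bir(key), key, score


def census_conserved_positions(
    calls: list[KeyResidues] | list[dict[int, str]],
    positions: tuple[int, ...] | None = None,
) -> set[int]:
    """Canonical positions at which every input shares one non-GAP residue.

    ``calls`` may be KeyResidues or plain position->residue mappings covering
    the 15 canonical conserved positions.
    """
    if not calls:
        raise ValueError("census requires at least one call")
    if positions is None:
        positions = load_reference().conserved_positions
    out: set[int] = set()
    for pos in positions:
        residues = {
            (c[pos] if isinstance(c, KeyResidues) else c.get(pos, GAP))
            for c in calls
        }
        if len(residues) == 1 and GAP not in residues:
            out.add(pos)
    return out
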