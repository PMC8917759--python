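"""Domain-architecture typing of IAP transcripts.

A transcript's scan hits are reduced to an ordered N-to-C token string (typed
BIR tokens from bir_typing, non-BIR tokens via the accession map), matched
against an ordered rule table of architecture types (BIRC2/3-like, BIRC5-like,
... plus the novel BIRC9-BIRC12), and summarized per bootstrap-supported
phylogenetic cluster containing both oyster species.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy

from .bir_typing import BirCall
from .config import (BIR_ACCESSIONS, BIR_TOKEN_CLASS,
                     DEFAULT_ARCHITECTURE_RULES, TOKEN_MAP)
from .io_formats import DomainHit

NOVEL = "NOVEL"


@dataclass(frozen=True)
class Token:
    name: str
    start: int
    end: int

    @property
    def is_other(self) -> bool:
        return self.name.startswith("OTHER(")


@dataclass(frozen=True)
class ArchitectureCall:
    transcript_id: str
    tokens: tuple[str, ...]
    matched_type: str
    cluster_id: str | None = None


@dataclass(frozen=True)
class CladeCluster:
    cluster_id: str
    members: tuple[str, ...]
    support: float
    species: frozenset[str]


# ---------------------------------------------------------------------------
# Tokenization

def tokenize_architecture(
    hits: list[DomainHit],
    bir_calls: list[BirCall],
    token_map: dict[str, str] | None = None,
) -> list[Token]:
    """Ordered N-to-C token string for one transcript.

    BIR-accession hits are represented by their typed calls (or BIR_STAR when
    the call lacks CDD confirmation); other hits map through ``token_map``,
    unmapped accessions becoming OTHER(accession).  Overlapping hits of the
    same token are merged into one token whose span is their union.
    """
    token_map = TOKEN_MAP if token_map is None else token_map
    protein_ids = {h.protein_id for h in hits} | {c.protein_id for c in bir_calls}
    if len(protein_ids) > 1:
        raise ValueError(f"hits/calls span multiple proteins: {protein_ids}")
    bir_hits = [h for h in hits if h.accession in BIR_ACCESSIONS]
    for call in bir_calls:
        covered = any(h.start < call.span[1] and call.span[0] < h.end
                      for h in bir_hits)
        if not covered:
            raise ValueError(
                f"BIR call {call.protein_id}#{call.bir_index} has no covering "
                f"scan hit")
    raw: list[Token] = [
        Token(call.token, call.span[0], call.span[1]) for call in bir_calls
    ]
    for h in hits:
        if h.accession in BIR_ACCESSIONS:
            continue
        name = token_map.get(h.accession, f"OTHER({h.accession})")
        raw.append(Token(name, h.start, h.end))
    merged: list[Token] = []
    for tok in sorted(raw, key=lambda t: (t.name, t.start, t.end)):
        if (merged and merged[-1].name == tok.name
                and tok.start < merged[-1].end):
            prev = merged.pop()
            merged.append(Token(tok.name, prev.start, max(prev.end, tok.end)))
        else:
            merged.append(tok)
    return sorted(merged, key=lambda t: (t.start, t.end, t.name))


# ---------------------------------------------------------------------------
# Rule matching

def _atom_matches(atom: str, token: str) -> bool:
    if atom == "BIR_ANY":
        return token in BIR_TOKEN_CLASS
    if "|" in atom:
        return token in atom.split("|")
    return token == atom


def _match_pattern(pattern: tuple[str, ...], tokens: tuple[str, ...]) -> bool:
    """Full-sequence match of the small pattern DSL against a token list."""

    def rec(pi: int, ti: int) -> bool:
        if pi == len(pattern):
            return ti == len(tokens)
        atom = pattern[pi]
        if atom.endswith("?"):
            base = atom[:-1]
            if ti < len(tokens) and _atom_matches(base, tokens[ti]) \
                    and rec(pi + 1, ti + 1):
                return True
            return rec(pi + 1, ti)
        if atom.endswith("+"):
            base = atom[:-1]
            if ti >= len(tokens) or not _atom_matches(base, tokens[ti]):
                return False
            ti += 1
            # one-or-more: try consuming as many as possible, backtracking
            while True:
                if rec(pi + 1, ti):
                    return True
                if ti < len(tokens) and _atom_matches(base, tokens[ti]):
                    ti += 1
                else:
                    return False
        if ti < len(tokens) and _atom_matches(atom, tokens[ti]):
            return rec(pi + 1, ti + 1)
        return False

    return rec(0, 0)


def classify_architecture(
    tokens: list[Token] | list[str],
    rules: tuple[tuple[str, tuple[tuple[str, ...], ...]], ...] | None = None,
) -> str:
    """First rule (table order) whose pattern equals the token list after
    dropping OTHER tokens; NOVEL when nothing matches."""
    if not tokens:
        raise ValueError("empty token list")
    rules = DEFAULT_ARCHITECTURE_RULES if rules is None else rules
    names = tuple(
        t.name if isinstance(t, Token) else t
        for t in tokens
    )
    names = tuple(n for n in names if not n.startswith("OTHER("))
    if not names:
        return NOVEL
    for rule_name, patterns in rules:
        for pattern in patterns:
            if _match_pattern(pattern, names):
                return rule_name
    return NOVEL


# ---------------------------------------------------------------------------
# Tree clusters

def default_species_of(leaf_label: str) -> str:
    """Species tag convention: the prefix before the first underscore."""
    return leaf_label.split("_", 1)[0]


def extract_supported_clusters(
    tree: dendropy.Tree,
    support_min: float = 90.0,
    require_species: frozenset[str] = frozenset({"Cv", "Cg"}),
    species_of=default_species_of,
) -> list[CladeCluster]:
    """Maximal clades with bootstrap support strictly above ``support_min``
    containing at least one leaf of every required species.

    Clusters are non-nested: the outermost qualifying clade wins.  Leaves
    whose label yields an empty species tag raise ValueError.
    """
    clusters: list[CladeCluster] = []
    counter = 0

    def qualify(node) -> CladeCluster | None:
        nonlocal counter
        support = getattr(node, "support", None)
        if node.is_leaf() or support is None or not support > support_min:
            return None
        leaves = [leaf.taxon.label for leaf in node.leaf_iter()]
        species = set()
        for label in leaves:
            tag = species_of(label)
            if not tag:
                raise ValueError(f"leaf {label!r} has no species tag")
            species.add(tag)
        if not require_species <= species:
            return None
        counter += 1
        return CladeCluster(f"cluster{counter}", tuple(sorted(leaves)),
                            float(support), frozenset(species))

    # validate all leaves up front so unlabelled species always error
    for leaf in tree.leaf_node_iter():
        if not species_of(leaf.taxon.label):
            raise ValueError(f"leaf {leaf.taxon.label!r} has no species tag")

    def walk(node) -> None:
        cluster = qualify(node)
        if cluster is not None:
            clusters.append(cluster)
            return  # outermost qualifying clade wins; do not descend
        for child in node.child_nodes():
            walk(child)

    walk(tree.seed_node)
    return clusters


def cluster_consensus(
    cluster: CladeCluster,
    calls: dict[str, ArchitectureCall],
) -> tuple[str, bool]:
    """Consensus architecture of a cluster.

    Returns (type, conserved).  conserved is True when every member shares one
    type; otherwise the majority type is returned with conserved False, and
    ties are reported as ``mixed(<type1>,<type2>,...)``.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    missing = [m for m in cluster.members if m not in calls]
    if missing:
        raise ValueError(f"members without architecture calls: {missing}")
    types = Counter(calls[m].matched_type for m in cluster.members)
    if len(types) == 1:
        return next(iter(types)), True
    top = max(types.values())
    leaders = sorted(t for t, n in types.items() if n == top)
    if len(leaders) > 1:
        return "mixed(" + ",".join(leaders) + ")", False
    return leaders[0], False
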