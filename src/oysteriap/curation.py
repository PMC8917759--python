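"""Curation of an IAP gene set from domain-scan evidence and gene models.

The funnel mirrors a standard gene-family curation workflow: HMM candidate
filtering (E-value < 0.001), confirmation by a CDD BIR hit, collapse of
identical protein sequences, removal of suspected haplotigs (assembly
artifacts at > 95% identity with less than half the read coverage of their
cluster), and annotation flags for intronless genes, tandem arrays and
retroposition/transposition machinery.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import edlib
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .config import (BIR_ACCESSIONS, CDD_SOURCE, RT_ACCESSIONS,
                     TC1_ACCESSIONS, CurationConfig)
from .io_formats import DomainHit, GeneModel, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class GeneRecord:
    """A curated gene with its transcripts and curation flags."""

    gene_id: str
    chromosome: str
    span: tuple[int, int]
    transcripts: tuple[str, ...]
    is_iap: bool = False
    is_intronless: bool = False
    is_haplotig: bool = False
    collapse_target: str | None = None
    tandem_array_id: str | None = None
    retroposition_flags: frozenset[str] = frozenset()
    read_coverage: float | None = None


# ---------------------------------------------------------------------------
# Candidate filtering

def filter_iap_candidates(
    hmm_hits: list[tuple[str, float]],
    scan: list[DomainHit],
    cfg: CurationConfig | None = None,
) -> set[str]:
    """Retain candidates below the HMM E-value cutoff that carry at least one
    CDD-sourced BIR hit; candidates absent from the scan are dropped and
    logged (no CDD evidence)."""
    cfg = cfg or CurationConfig()
    scanned = {h.protein_id for h in scan}
    cdd_bir = {
        h.protein_id for h in scan
        if h.source_db == CDD_SOURCE and h.accession in BIR_ACCESSIONS
    }
    kept: set[str] = set()
    for protein_id, e_value in hmm_hits:
        if not e_value < cfg.hmm_evalue_max:
            continue
        if protein_id not in scanned:
            logger.warning("candidate %s absent from domain scan; dropped",
                           protein_id)
            continue
        if protein_id in cdd_bir:
            kept.add(protein_id)
    return kept


# ---------------------------------------------------------------------------
# Identical-sequence collapse

def collapse_identical(
    records: list[SequenceRecord],
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """One representative per identical residue string.

    The representative is the lexicographically smallest id so the collapse
    is deterministic regardless of input order.  Returns the kept records (in
    input order of their representatives) and a map collapsed_id -> kept_id.
    """
    by_seq: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        by_seq.setdefault(rec.residues, []).append(rec)
    collapse_map: dict[str, str] = {}
    keep_ids: set[str] = set()
    for group in by_seq.values():
        rep = min(group, key=lambda r: r.id)
        keep_ids.add(rep.id)
        for rec in group:
            if rec.id != rep.id:
                collapse_map[rec.id] = rep.id
    kept = [r for r in records if r.id in keep_ids]
    return kept, collapse_map


# ---------------------------------------------------------------------------
# Haplotig collapse

_identity_aligner: Align.PairwiseAligner | None = None


def _get_identity_aligner() -> Align.PairwiseAligner:
    global _identity_aligner
    if _identity_aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        aligner.mode = "global"
        _identity_aligner = aligner
    return _identity_aligner


def global_identity(a: str, b: str) -> float:
    """Global pairwise identity: matching columns over alignment length."""
    alignment = _get_identity_aligner().align(a, b)[0]
    matches = 0
    for (ts, te), (qs, _qe) in zip(*alignment.aligned):
        matches += sum(
            1 for off in range(te - ts) if a[ts + off] == b[qs + off])
    return matches / alignment.length


def pairwise_identity_matrix(
    records: list[SequenceRecord],
    min_identity: float = 0.9,
) -> dict[tuple[str, str], float]:
    """Sparse symmetric identity map for pairs plausibly above min_identity.

    Pairs are prescreened by edit distance (a cheap upper bound on identity);
    survivors get an exact global-alignment identity.  Pairs below the screen
    are omitted (treated as identity 0 downstream).
    """
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            la, lb = len(a.residues), len(b.residues)
            longer = max(la, lb)
            # identity <= 1 - dist/longer; skip pairs that cannot reach the bar
            max_dist = int((1 - min_identity) * longer) + 1
            res = edlib.align(a.residues, b.residues, task="distance",
                              k=max_dist)
            if res["editDistance"] == -1:
                continue
            ident = global_identity(a.residues, b.residues)
            out[(a.id, b.id)] = ident
            out[(b.id, a.id)] = ident
    return out


def _single_linkage_clusters(
    ids: list[str],
    identity: dict[tuple[str, str], float],
    threshold: float,
) -> list[list[str]]:
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), ident in identity.items():
        if a in parent and b in parent and ident > threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    clusters: dict[str, list[str]] = {}
    for i in ids:
        clusters.setdefault(find(i), []).append(i)
    return [sorted(members) for members in clusters.values()]


def collapse_haplotigs(
    records: list[SequenceRecord],
    pairwise_identity: dict[tuple[str, str], float],
    coverage: dict[str, float],
    cfg: CurationConfig | None = None,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Remove suspected haplotigs inside high-identity clusters.

    Within each single-linkage cluster at identity > haplotig_identity_min, a
    member is removed iff its read coverage is strictly below
    haplotig_coverage_ratio x the cluster maximum; removed members map to the
    highest-coverage member (their "parent"), so downstream read counts can be
    re-assigned to it.
    """
    cfg = cfg or CurationConfig()
    ids = [r.id for r in records]
    removed: dict[str, str] = {}
    for cluster in _single_linkage_clusters(
            ids, pairwise_identity, cfg.haplotig_identity_min):
        if len(cluster) < 2:
            continue
        missing = [m for m in cluster if m not in coverage]
        if missing:
            raise ValueError(
                f"missing read coverage for clustered proteins: {missing}")
        cmax = max(coverage[m] for m in cluster)
        parent_id = min(
            (m for m in cluster if coverage[m] == cmax))
        for member in cluster:
            if coverage[member] < cfg.haplotig_coverage_ratio * cmax:
                removed[member] = parent_id
    kept = [r for r in records if r.id not in removed]
    return kept, removed


def apply_collapse_to_counts(
    counts: pd.DataFrame, collapse_map: dict[str, str]
) -> pd.DataFrame:
    """Add the count rows of removed ids onto their parents (sum-preserving)."""
    out = counts.copy()
    for removed_id, parent_id in collapse_map.items():
        if removed_id not in out.index:
            continue
        if parent_id in out.index:
            out.loc[parent_id] = out.loc[parent_id] + out.loc[removed_id]
        else:
            out.loc[parent_id] = out.loc[removed_id]
        out = out.drop(index=removed_id)
    return out


# ---------------------------------------------------------------------------
# Structural flags

def detect_intronless(genes: list[GeneModel]) -> set[str]:
    """Genes whose every transcript has exactly one exon."""
    return {
        g.gene_id for g in genes
        if g.transcripts and all(t.exon_count == 1 for t in g.transcripts)
    }


def detect_tandem_arrays(
    iap_gene_ids: set[str],
    genes_by_chromosome: dict[str, list[tuple[str, int, int]]],
    cfg: CurationConfig | None = None,
) -> dict[str, str]:
    """Assign shared array ids to maximal runs of >= 2 IAP genes.

    ``genes_by_chromosome`` maps chromosome -> list of (gene_id, start, end)
    for *all* genes, ordered by start.  Consecutive IAP genes extend a run iff
    at most ``tandem_max_intervening`` non-IAP genes separate them and the
    genomic gap is at most ``tandem_max_gap_bp``.
    """
    cfg = cfg or CurationConfig()
    assignment: dict[str, str] = {}
    for chrom, genes in genes_by_chromosome.items():
        ordered = sorted(genes, key=lambda g: (g[1], g[2]))
        run: list[tuple[str, int, int]] = []
        n_arrays = 0

        def flush(run: list, n_arrays: int) -> int:
            if len(run) >= 2:
                n_arrays += 1
                for gid, _s, _e in run:
                    assignment[gid] = f"{chrom}:array{n_arrays}"
            return n_arrays

        intervening = 0
        for gid, start, end in ordered:
            if gid not in iap_gene_ids:
                intervening += 1
                continue
            if run and (intervening > cfg.tandem_max_intervening
                        or start - run[-1][2] > cfg.tandem_max_gap_bp):
                n_arrays = flush(run, n_arrays)
                run = []
            run.append((gid, start, end))
            intervening = 0
        flush(run, n_arrays)
    return assignment


def flag_retroposition(
    orf_scan_by_gene: dict[str, list[DomainHit]],
    rt_accessions: frozenset[str] = RT_ACCESSIONS,
) -> dict[str, frozenset[str]]:
    """Flag genes whose translated-ORF scan shows transposition machinery.

    transposase_tc1 fires on the three Tc1-like accessions; the
    reverse-transcriptase flag on any accession in the configured RT list or
    a hit description mentioning reverse transcriptase.
    """
    flags: dict[str, frozenset[str]] = {}
    for gene_id, hits in orf_scan_by_gene.items():
        found: set[str] = set()
        for h in hits:
            if h.accession in TC1_ACCESSIONS:
                found.add("transposase_tc1")
            if (h.accession in rt_accessions
                    or "reverse transcriptase" in h.description.lower()):
                found.add("reverse_transcriptase")
        flags[gene_id] = frozenset(found)
    return flags


# ---------------------------------------------------------------------------
# Apoptosis / regulated-cell-death annotation mining

def mine_rcd_annotations(
    products: list[tuple[str, str, str]],
    catalog: dict[str, tuple[str, ...]],
) -> pd.DataFrame:
    """Case-insensitive whole-word alias match against product names.

    ``products`` rows are (gene_id, transcript_id, product_name).  Each
    (transcript, target) match is recorded once, with the alias that fired
    first (catalog order).  Empty catalog is an error.
    """
    if not catalog:
        raise ValueError("empty target catalog")
    compiled = {
        target: [
            (alias, re.compile(rf"\b{re.escape(alias)}\b", re.IGNORECASE))
            for alias in aliases
        ]
        for target, aliases in catalog.items()
    }
    rows = []
    for gene_id, transcript_id, product in products:
        for target, alias_patterns in compiled.items():
            for alias, pattern in alias_patterns:
                if pattern.search(product):
                    rows.append({
                        "gene_id": gene_id,
                        "transcript_id": transcript_id,
                        "product": product,
                        "target": target,
                        "matched_alias": alias,
                    })
                    break
    return pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "product", "target",
                       "matched_alias"])
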