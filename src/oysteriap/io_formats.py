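"""Readers and writers for every external format the pipeline touches.

All genomic and protein intervals are held internally as 0-based half-open
spans; GFF3 and domain-scan tables (1-based inclusive on disk) are converted
at this boundary and nowhere else.  Tabular formats are tab-separated and
require a header line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class FormatError(ValueError):
    """Malformed or internally inconsistent input file."""


VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


# ---------------------------------------------------------------------------
# Coordinate conversion (external 1-based inclusive <-> internal 0-based
# half-open).  Kept as named functions so the involution is testable.

def to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    return start_1based - 1, end_inclusive


def to_external(start0: int, end0: int) -> tuple[int, int]:
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# Domain types

@dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    residues: str


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    @property
    def span(self) -> tuple[int, int]:
        starts = [e[0] for t in self.transcripts for e in t.exons]
        ends = [e[1] for t in self.transcripts for e in t.exons]
        return min(starts), max(ends)


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    source_db: str
    accession: str
    description: str
    start: int  # 0-based half-open
    end: int
    e_value: float | None = None


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA; residues are uppercased and terminal stop
    symbols (``*``) stripped.  Duplicate ids and empty files are errors."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().strip("*")
        if not residues:
            raise FormatError(f"empty sequence for id {rec.id!r} in {path}")
        records.append(SequenceRecord(rec.id, rec.description, residues))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id,
                      description=r.description[len(r.id):].strip()
                      if r.description.startswith(r.id) else r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = 9


def _prevalidate_gff3(path: str | Path) -> None:
    """Line-level checks so coordinate errors carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _GFF_COLS:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start or start < 1:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {start}..{end}")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon features linked by ID/Parent into GeneModels.

    GFF3 1-based inclusive coordinates become 0-based half-open.  An exon
    whose Parent is not a declared transcript, or a feature with end < start,
    raises FormatError.
    """
    import gffutils

    _prevalidate_gff3(path)
    db = gffutils.create_db(str(path), dbfn=":memory:", keep_order=True,
                            merge_strategy="create_unique")
    transcript_types = ("mRNA", "transcript")
    known_transcripts = {
        f.id for ft in transcript_types for f in db.features_of_type(ft)}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or not set(parents) & known_transcripts:
            raise FormatError(
                f"exon {exon.id} has no parent transcript in {path}")
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        tms = []
        for mrna in db.children(gene, featuretype=transcript_types,
                                order_by="start"):
            exons = sorted(
                to_internal(e.start, e.end)
                for e in db.children(mrna, featuretype="exon"))
            if not exons:
                raise FormatError(f"transcript {mrna.id} has no exons")
            for (_s1, e1), (s2, _e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise FormatError(
                        f"transcript {mrna.id} has overlapping exons")
            tms.append(TranscriptModel(mrna.id, tuple(exons)))
        models.append(
            GeneModel(gene.id, gene.seqid, gene.strand, tuple(tms)))
    return models


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Emit the minimal gene/mRNA/exon GFF3 the synthetic generator needs."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = g.span
            s1, e1 = to_external(gs, ge)
            fh.write(f"{g.chromosome}\toysteriap\tgene\t{s1}\t{e1}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for t in g.transcripts:
                ts = min(e[0] for e in t.exons)
                te = max(e[1] for e in t.exons)
                s1, e1 = to_external(ts, te)
                fh.write(f"{g.chromosome}\toysteriap\tmRNA\t{s1}\t{e1}\t.\t"
                         f"{g.strand}\t.\tID={t.transcript_id};"
                         f"Parent={g.gene_id}\n")
                for i, (es, ee) in enumerate(t.exons, 1):
                    s1, e1 = to_external(es, ee)
                    fh.write(f"{g.chromosome}\toysteriap\texon\t{s1}\t{e1}\t.\t"
                             f"{g.strand}\t.\tID={t.transcript_id}.exon{i};"
                             f"Parent={t.transcript_id}\n")


# ---------------------------------------------------------------------------
# Domain-scan table (InterProScan-style, with a header line)

SCAN_COLUMNS = ["protein_id", "source_db", "accession", "description",
                "start", "end", "e_value"]


def read_domain_scan(path: str | Path) -> list[DomainHit]:
    """Read a tab-separated domain-scan table into DomainHits.

    Hits are returned grouped per protein (input order of first appearance)
    and sorted by start within each protein.  ``-`` in the E-value column
    means missing; anything else non-numeric raises with the line number.
    """
    hits_by_protein: dict[str, list[DomainHit]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SCAN_COLUMNS:
            raise FormatError(
                f"{path}: expected header {SCAN_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(SCAN_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected "
                                  f"{len(SCAN_COLUMNS)} columns")
            pid, src, acc, desc, start_s, end_s, ev_s = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            if start < 1 or end < start:
                raise FormatError(
                    f"{path}:{lineno}: invalid span {start}..{end}")
            if ev_s == "-":
                e_value = None
            else:
                try:
                    e_value = float(ev_s)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: malformed E-value {ev_s!r}") from exc
                if e_value < 0:
                    raise FormatError(f"{path}:{lineno}: negative E-value")
            s0, e0 = to_internal(start, end)
            hits_by_protein.setdefault(pid, []).append(
                DomainHit(pid, src, acc, desc, s0, e0, e_value))
    out: list[DomainHit] = []
    for pid, hits in hits_by_protein.items():
        out.extend(sorted(hits, key=lambda h: (h.start, h.end, h.accession)))
    return out


def write_domain_scan(hits: list[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SCAN_COLUMNS) + "\n")
        for h in hits:
            s1, e1 = to_external(h.start, h.end)
            ev = "-" if h.e_value is None else repr(h.e_value)
            fh.write(f"{h.protein_id}\t{h.source_db}\t{h.accession}\t"
                     f"{h.description}\t{s1}\t{e1}\t{ev}\n")


# ---------------------------------------------------------------------------
# Newick trees

def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Read a single Newick tree; internal-node labels are bootstrap supports.

    Returns a dendropy Tree whose internal nodes carry ``.support`` (float or
    None).  Duplicate leaf labels and syntax errors raise FormatError.
    """
    src = str(path_or_string)
    if src.lstrip().startswith("(") or src.lstrip().startswith(";"):
        data = src
    else:
        data = Path(src).read_text()
    try:
        tree = dendropy.Tree.get(
            data=data, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon" in str(exc):
            raise FormatError(f"duplicate leaf labels: {exc}") from exc
        raise FormatError(f"failed to parse Newick tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf labels: {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        support = None
        if not node.is_leaf() and node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = None
            if support is not None and not 0 <= support <= 100:
                raise FormatError(
                    f"bootstrap support {support} outside [0,100]")
        node.support = support
    return tree


# ---------------------------------------------------------------------------
# DE tables and expression matrices

DE_COLUMNS = ["transcript_id", "comparison_id", "lfc", "padj"]


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Differential-expression results: one row per transcript x comparison."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing DE columns {missing}")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise FormatError(f"{path}: padj outside [0,1]")
    if df.duplicated(["transcript_id", "comparison_id"]).any():
        raise FormatError(f"{path}: duplicate transcript x comparison rows")
    return df[DE_COLUMNS].copy()


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes/transcripts x samples matrix with ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate row ids")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return df


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata with at least sample_id and trait columns."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "trait"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df.set_index("sample_id")
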