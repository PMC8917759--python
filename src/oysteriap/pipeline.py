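"""End-to-end orchestration of the characterization and expression stages.

``run_characterize`` executes the curation funnel in its canonical order —
HMM filter, CDD prune, identical-sequence collapse, haplotig collapse, BIR
typing, architecture typing, tree clusters — and writes provenance-carrying
TSV reports.  ``run_expression`` applies the haplotig collapse map to count
matrices, classifies per-experiment expression statuses, and runs the
co-expression network per experiment.  Every numeric threshold in use is
serialized into the run manifest; stages are skipped on re-run when the
manifest's config hash matches and the outputs exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import architecture, bir_typing, curation, expression, io_formats, network
from .config import (BIR_ACCESSIONS, CDD_SOURCE, RunConfig, config_as_dict)

logger = logging.getLogger(__name__)


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps({
        "curation": config_as_dict(cfg.curation),
        "expression": config_as_dict(cfg.expression),
        "network": {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in config_as_dict(cfg.network).items()},
        "seed": cfg.seed,
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, stage: str, counts: dict) -> None:
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    path = cfg.output_dir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest["config_hash"] = _config_hash(cfg)
    manifest["thresholds"] = {
        "curation": config_as_dict(cfg.curation),
        "expression": config_as_dict(cfg.expression),
        "network": {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in config_as_dict(cfg.network).items()},
    }
    manifest.setdefault("stages", {})[stage] = counts
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _stage_cached(cfg: RunConfig, stage: str, outputs: list[Path]) -> bool:
    path = cfg.output_dir / "manifest.json"
    if not path.exists():
        return False
    manifest = json.loads(path.read_text())
    return (manifest.get("config_hash") == _config_hash(cfg)
            and stage in manifest.get("stages", {})
            and all(p.exists() for p in outputs))


# ---------------------------------------------------------------------------
# Characterization

def _merged_bir_spans(hits: list[io_formats.DomainHit]) -> list[tuple[tuple[int, int], bool]]:
    """Union of overlapping BIR-accession hits, with CDD-confirmation flag."""
    bir_hits = sorted((h for h in hits if h.accession in BIR_ACCESSIONS),
                      key=lambda h: (h.start, h.end))
    merged: list[list] = []
    for h in bir_hits:
        if merged and h.start < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], h.end)
            merged[-1][2] |= h.source_db == CDD_SOURCE
        else:
            merged.append([h.start, h.end, h.source_db == CDD_SOURCE])
    return [((s, e), cdd) for s, e, cdd in merged]


def call_birs(protein: io_formats.SequenceRecord,
              hits: list[io_formats.DomainHit]) -> list[bir_typing.BirCall]:
    """Type every (merged) BIR span of one protein."""
    calls = []
    for idx, ((start, end), cdd) in enumerate(_merged_bir_spans(hits), 1):
        seq = protein.residues[start:end]
        bir_type, key, score = bir_typing.type_bir_sequence(seq)
        calls.append(bir_typing.BirCall(
            protein.id, idx, (start, end), key, bir_type,
            cdd_confirmed=cdd, alignment_score=score))
    return calls


def run_characterize(cfg: RunConfig) -> dict:
    """Curate, type and architecture-classify a family; write reports.

    Expects the input directory layout the synthetic generator writes
    (proteins.fasta, annotation.gff3, domain_scan.tsv, orf_scan.tsv,
    hmm_candidates.tsv, coverage.tsv, optionally tree.nwk).
    """
    out = cfg.output_dir
    outputs = [out / "curated_genes.tsv", out / "collapse_map.tsv",
               out / "bir_calls.tsv", out / "architecture_calls.tsv"]
    indir = cfg.input_dir
    proteins = io_formats.read_fasta(indir / "proteins.fasta")
    genes = io_formats.read_gff3(indir / "annotation.gff3")
    scan = io_formats.read_domain_scan(indir / "domain_scan.tsv")
    orf_scan = (io_formats.read_domain_scan(indir / "orf_scan.tsv")
                if (indir / "orf_scan.tsv").exists() else [])
    hmm = pd.read_csv(indir / "hmm_candidates.tsv", sep="\t")
    coverage = pd.read_csv(indir / "coverage.tsv", sep="\t") \
        .set_index("protein_id")["coverage"].to_dict()

    funnel: dict[str, int] = {"candidates": len(hmm)}
    # stage order: E-value filter + CDD prune -> identical collapse ->
    # haplotig collapse -> flags -> typing -> architecture
    kept_ids = curation.filter_iap_candidates(
        list(hmm.itertuples(index=False, name=None)), scan, cfg.curation)
    funnel["cdd_confirmed"] = len(kept_ids)
    records = [p for p in proteins if p.id in kept_ids]
    records, identical_map = curation.collapse_identical(records)
    funnel["after_identical_collapse"] = len(records)
    identity = curation.pairwise_identity_matrix(
        records, min_identity=cfg.curation.haplotig_identity_min - 0.02)
    records, haplotig_map = curation.collapse_haplotigs(
        records, identity, coverage, cfg.curation)
    funnel["after_haplotig_collapse"] = len(records)

    protein_gene = {}
    transcript_of = {}
    for g in genes:
        for t in g.transcripts:
            pid = t.transcript_id.replace(".t", ".p")
            protein_gene[pid] = g.gene_id
            transcript_of[pid] = t.transcript_id
    iap_gene_ids = {protein_gene[r.id] for r in records}
    iap_genes = [g for g in genes if g.gene_id in iap_gene_ids]

    intronless = curation.detect_intronless(iap_genes)
    genes_by_chrom: dict[str, list[tuple[str, int, int]]] = {}
    for g in genes:
        s, e = g.span
        genes_by_chrom.setdefault(g.chromosome, []).append((g.gene_id, s, e))
    arrays = curation.detect_tandem_arrays(
        iap_gene_ids, genes_by_chrom, cfg.curation)
    orf_by_gene: dict[str, list] = {}
    for h in orf_scan:
        orf_by_gene.setdefault(h.protein_id, []).append(h)
    retro = curation.flag_retroposition(orf_by_gene)

    hits_by_protein: dict[str, list] = {}
    for h in scan:
        hits_by_protein.setdefault(h.protein_id, []).append(h)
    bir_calls: dict[str, list[bir_typing.BirCall]] = {}
    arch_calls: dict[str, architecture.ArchitectureCall] = {}
    for rec in records:
        calls = call_birs(rec, hits_by_protein.get(rec.id, []))
        bir_calls[rec.id] = calls
        tokens = architecture.tokenize_architecture(
            hits_by_protein.get(rec.id, []), calls)
        arch = architecture.classify_architecture(tokens)
        arch_calls[rec.id] = architecture.ArchitectureCall(
            transcript_of.get(rec.id, rec.id),
            tuple(t.name for t in tokens), arch)

    clusters: list[architecture.CladeCluster] = []
    consensus: dict[str, tuple[str, bool]] = {}
    tree_path = indir / "tree.nwk"
    if tree_path.exists():
        tree = io_formats.read_newick(tree_path)
        clusters = architecture.extract_supported_clusters(tree)
        by_label = {c.transcript_id: c for c in arch_calls.values()}
        for cl in clusters:
            members_with_calls = {
                m: by_label[m] for m in cl.members if m in by_label}
            if members_with_calls:
                sub = architecture.CladeCluster(
                    cl.cluster_id, tuple(sorted(members_with_calls)),
                    cl.support, cl.species)
                consensus[cl.cluster_id] = architecture.cluster_consensus(
                    sub, members_with_calls)

    # ---- reports
    out.mkdir(parents=True, exist_ok=True)
    provenance = f"input={indir.name};evalue<{cfg.curation.hmm_evalue_max};" \
                 f"identity>{cfg.curation.haplotig_identity_min};" \
                 f"coverage<{cfg.curation.haplotig_coverage_ratio}x"
    gene_rows = []
    for rec in sorted(records, key=lambda r: r.id):
        gid = protein_gene[rec.id]
        gene_rows.append({
            "gene_id": gid, "protein_id": rec.id,
            "transcript_id": transcript_of.get(rec.id, ""),
            "is_iap": True,
            "is_intronless": gid in intronless,
            "tandem_array_id": arrays.get(gid, ""),
            "retroposition_flags": ",".join(sorted(retro.get(gid, []))),
            "read_coverage": coverage.get(rec.id, ""),
            "n_bir_domains": len(bir_calls[rec.id]),
            "architecture": arch_calls[rec.id].matched_type,
            "provenance": provenance,
        })
    gene_columns = ["gene_id", "protein_id", "transcript_id", "is_iap",
                    "is_intronless", "tandem_array_id", "retroposition_flags",
                    "read_coverage", "n_bir_domains", "architecture",
                    "provenance"]
    pd.DataFrame(gene_rows, columns=gene_columns).to_csv(
        out / "curated_genes.tsv", sep="\t", index=False)
    collapse_rows = (
        [{"removed_id": k, "kept_id": v, "reason": "identical"}
         for k, v in sorted(identical_map.items())]
        + [{"removed_id": k, "kept_id": v, "reason": "haplotig"}
           for k, v in sorted(haplotig_map.items())])
    pd.DataFrame(collapse_rows,
                 columns=["removed_id", "kept_id", "reason"]) \
        .to_csv(out / "collapse_map.tsv", sep="\t", index=False)
    bir_rows = []
    for pid in sorted(bir_calls):
        for c in bir_calls[pid]:
            row = {"protein_id": pid, "bir_index": c.bir_index,
                   "start": c.span[0], "end": c.span[1],
                   "bir_type": c.bir_type.value,
                   "cdd_confirmed": c.cdd_confirmed}
            row.update({f"pos{p}": c.key_residues[p]
                        for p in bir_typing.KEY_POSITIONS})
            bir_rows.append(row)
    bir_columns = (["protein_id", "bir_index", "start", "end", "bir_type",
                    "cdd_confirmed"]
                   + [f"pos{p}" for p in bir_typing.KEY_POSITIONS])
    pd.DataFrame(bir_rows, columns=bir_columns).to_csv(
        out / "bir_calls.tsv", sep="\t", index=False)
    arch_rows = [
        {"transcript_id": call.transcript_id,
         "tokens": "-".join(call.tokens),
         "architecture": call.matched_type}
        for _pid, call in sorted(arch_calls.items())]
    pd.DataFrame(arch_rows,
                 columns=["transcript_id", "tokens", "architecture"]) \
        .to_csv(out / "architecture_calls.tsv", sep="\t", index=False)
    if consensus:
        pd.DataFrame(
            [{"cluster_id": cid, "consensus": c, "conserved": flag}
             for cid, (c, flag) in sorted(consensus.items())]) \
            .to_csv(out / "cluster_consensus.tsv", sep="\t", index=False)
    _write_manifest(cfg, "characterize", funnel)
    return {
        "funnel": funnel,
        "records": records,
        "collapse_map": {**identical_map, **haplotig_map},
        "haplotig_map": haplotig_map,
        "intronless": intronless,
        "tandem_arrays": arrays,
        "retro_flags": retro,
        "bir_calls": bir_calls,
        "architecture_calls": arch_calls,
        "clusters": clusters,
        "cluster_consensus": consensus,
    }


# ---------------------------------------------------------------------------
# Expression + network

def run_expression(
    cfg: RunConfig,
    experiments: dict[str, dict],
    architecture_of: dict[str, str] | None = None,
    haplotig_map: dict[str, str] | None = None,
    iap_ids: set[str] | None = None,
    apoptosis_ids: set[str] | None = None,
) -> dict:
    """Classify expression statuses and run the network per experiment.

    ``experiments`` maps experiment id to a dict with keys ``de`` (DE table),
    ``counts`` (count matrix), ``gene_transcripts``, and optionally ``expr``
    (transformed matrix for the network) and ``trait``.  The haplotig collapse
    map (transcript level) is applied to counts before classification, so
    totals are conserved.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    statuses: dict[str, list[expression.ExpressionStatus]] = {}
    deg_sets: dict[str, set[str]] = {}
    deg_transcripts: dict[str, set[str]] = {}
    networks: dict[str, network.CoexprNetwork] = {}
    for exp_id in sorted(experiments):
        bundle = experiments[exp_id]
        counts = bundle["counts"]
        if haplotig_map:
            counts = curation.apply_collapse_to_counts(counts, haplotig_map)
        de = bundle["de"]
        missing = set(de["transcript_id"]) - set(counts.index)
        if missing:
            raise ValueError(
                f"{exp_id}: gene ids mismatch between stages: "
                f"{sorted(missing)}")
        st = expression.classify_expression_status(
            de, counts, bundle["gene_transcripts"], cfg.expression, exp_id)
        statuses[exp_id] = st
        deg_sets[exp_id] = {
            s.gene_id for s in st if s.status in ("differential", "mixed")}
        sig = set(de.loc[de["padj"] <= cfg.expression.padj_max,
                         "transcript_id"])
        present = {t for g in bundle["gene_transcripts"].values() for t in g}
        deg_transcripts[exp_id] = sig & present
        pd.DataFrame(
            [{"gene_id": s.gene_id, "status": s.status,
              "transcripts": ";".join(f"{t}:{k}"
                                      for t, k in s.transcript_statuses)}
             for s in st]).to_csv(out / f"status_{exp_id}.tsv", sep="\t",
                                  index=False)
        if "expr" in bundle:
            net = network.build_network(
                bundle["expr"], bundle["trait"],
                iap_ids or set(), apoptosis_ids or set(), cfg.network)
            networks[exp_id] = net
            pd.DataFrame({"gene_id": net.gene_ids,
                          "module": net.labels}).to_csv(
                out / f"modules_{exp_id}.tsv", sep="\t", index=False)
            if len(net.trait_stats):
                net.trait_stats.to_csv(out / f"module_trait_{exp_id}.tsv",
                                       sep="\t")
            net.edges.to_csv(out / f"edges_{exp_id}.tsv", sep="\t",
                             index=False)
    sharing = None
    if len(deg_sets) >= 2 and any(deg_sets.values()):
        sharing = {
            "shared_ge2_over_union": expression.shared_deg_fraction(deg_sets),
            "shared_all_over_union":
                expression.shared_deg_fraction_all(deg_sets),
        }
        pd.DataFrame([sharing]).to_csv(out / "sharing_summary.tsv", sep="\t",
                                       index=False)
    usage = None
    if architecture_of is not None:
        usage = expression.architecture_usage(deg_transcripts, architecture_of)
        usage.to_csv(out / "architecture_usage.tsv", sep="\t", index=False)
    _write_manifest(cfg, "expression",
                    {e: len(s) for e, s in statuses.items()})
    return {"statuses": statuses, "deg_sets": deg_sets, "sharing": sharing,
            "architecture_usage": usage, "networks": networks}
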