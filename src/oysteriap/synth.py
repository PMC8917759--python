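"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emits the exact formats the readers consume — protein FASTA,
GFF3 gene models, domain-scan and HMM-candidate tables, coverage tables, DE
tables, count matrices and expression matrices — while recording a sidecar
truth object that fully determines the expected output of every downstream
stage.  All randomness flows from a single integer seed through
numpy's Generator, so outputs are byte-identical across runs and platforms.

Realism notes: protein sequences are concatenations of domain templates with
low-complexity random linkers; only the BIR key positions and the scan-table
domain spans need to be faithful, because classification depends on those
alone.  Expression is generated directly on a log-like transformed scale;
counts for the DE generator use simple overdispersed draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .bir_typing import BirType, load_reference
from .config import TOKEN_MAP
from .io_formats import (DomainHit, GeneModel, SequenceRecord,
                         TranscriptModel, write_domain_scan, write_fasta,
                         write_gff3)

AA = "ACDEFGHIKLMNPQRSTVWY"

#: canonical key positions that type-defining rules read
_KEY = (34, 57, 60, 76, 77, 80, 81, 82, 84)

#: key-position residue overrides per BIR type (on the reference backbone)
_TYPE_EDITS: dict[BirType, dict[int, str]] = {
    BirType.TypeI: {76: "A", 80: "V", 81: "A"},
    BirType.TypeII: {76: "E", 80: "W", 81: "A"},
    BirType.TypeI_like: {76: "A", 77: "A", 80: "I", 81: "S", 84: "A"},
    BirType.TypeII_like: {76: "E", 80: "A", 81: "A", 84: "A"},
    BirType.TypeX: {76: "A", 80: "G", 81: "A", 82: "R"},
    BirType.TypeY: {},   # deletion handled separately
    BirType.NZBIR: {57: "T", 76: "E", 80: "W", 81: "A"},
}


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


def gen_bir(
    bir_type: BirType | str,
    n_flank: int = 0,
    n_mutations_nonkey: int = 0,
    seed: int | np.random.Generator = 0,
) -> tuple[str, dict]:
    """A BIR residue string of the requested type, with known truth.

    The core is the bundled reference backbone with the type's key-position
    residues installed (Type Y deletes canonical 79-81); mutations are placed
    only at non-key core positions; flanks are random sequence of length
    ``n_flank`` on each side.
    """
    bir_type = BirType(bir_type)
    if bir_type == BirType.Unclassified:
        raise ValueError("cannot generate an Unclassified BIR")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ref = load_reference()
    core = list(ref.consensus)
    for pos, res in _TYPE_EDITS[bir_type].items():
        core[pos - 1] = res
    key_set = set(_KEY)
    if n_mutations_nonkey:
        candidates = [p for p in range(1, ref.length + 1) if p not in key_set]
        for pos in rng.choice(candidates, size=n_mutations_nonkey,
                              replace=False):
            current = core[pos - 1]
            core[pos - 1] = rng.choice([a for a in AA if a != current])
    if bir_type == BirType.TypeY:
        del core[78:81]  # canonical 79-81, covering position 80
    seq = (_random_protein(rng, n_flank) + "".join(core)
           + _random_protein(rng, n_flank))
    truth = {
        "bir_type": bir_type.value,
        "core_span": (n_flank, n_flank + len(core)),
        "n_mutations_nonkey": int(n_mutations_nonkey),
    }
    return seq, truth


# ---------------------------------------------------------------------------
# Family generation

#: non-BIR domain template lengths; template residues are fixed at import
_DOMAIN_LENGTHS = {"RING": 46, "DD": 86, "UBA": 42, "UBC": 150,
                   "BIRC6_DOMAIN": 120, "WD40": 40}

_template_rng = np.random.default_rng(714025)
DOMAIN_TEMPLATES: dict[str, str] = {
    name: _random_protein(_template_rng, length)
    for name, length in sorted(_DOMAIN_LENGTHS.items())
}

#: representative scan accession per token (first entry of the token map)
_ACCESSION_OF = {}
for acc, tok in TOKEN_MAP.items():
    _ACCESSION_OF.setdefault(tok, acc)

#: concrete token exemplars per architecture type; only variants carrying at
#: least one CDD-confirmed BIR are planted, so the curation funnel keeps them
ARCHITECTURE_EXEMPLARS: dict[str, tuple[tuple[str, ...], ...]] = {
    "BIRC2/3-like": (("TI", "TII", "DD", "RING"),
                     ("TI", "TII", "DD", "UBA", "RING"),
                     ("NZBIR", "TII", "UBA", "DD", "RING")),
    "BIRC6-like": (("TII", "BIRC6_DOMAIN", "UBC"),
                   ("TI", "TII", "BIRC6_DOMAIN", "WD40", "UBC")),
    "BIRC4-like": (("TI", "TI", "TII", "UBA", "RING"),),
    "BIRC9": (("TX", "TII", "RING"),),
    "BIRC12": (("TII", "BIR_STAR", "RING"),),
    "BIRC11": (("TII", "DD", "RING"),),
    "DIAP1-like": (("TI", "TII", "RING"),),
    "BIRC10": (("TII", "DD"),),
    "BIRC7-like": (("TII", "RING"),),
    "BIRC5-like": (("TII",), ("TI",)),
}

_BIR_TOKEN_TO_TYPE = {
    "TI": BirType.TypeI, "TII": BirType.TypeII, "TI_like": BirType.TypeI_like,
    "TII_like": BirType.TypeII_like, "TX": BirType.TypeX, "TY": BirType.TypeY,
    "NZBIR": BirType.NZBIR,
}


def _mutate(seq: str, fraction: float, rng: np.random.Generator) -> str:
    n = max(0, int(round(fraction * len(seq))))
    if n == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        out[pos] = rng.choice([a for a in AA if a != out[pos]])
    return "".join(out)


def _build_protein(
    tokens: tuple[str, ...],
    rng: np.random.Generator,
    protein_id: str,
    n_bir_mutations: int = 6,
    template_mutation_fraction: float = 0.10,
) -> tuple[str, list[DomainHit], list[dict]]:
    """Concatenate domain instances with random linkers; emit true scan hits."""
    pieces: list[str] = [_random_protein(rng, int(rng.integers(8, 16)))]
    offset = len(pieces[0])
    hits: list[DomainHit] = []
    domains: list[dict] = []
    for token in tokens:
        if token in _BIR_TOKEN_TO_TYPE or token == "BIR_STAR":
            bir_type = _BIR_TOKEN_TO_TYPE.get(token, BirType.TypeII)
            seq, _truth = gen_bir(bir_type, n_flank=0,
                                  n_mutations_nonkey=n_bir_mutations, seed=rng)
            span = (offset, offset + len(seq))
            if token == "BIR_STAR":
                hits.append(DomainHit(protein_id, "PFAM", "PF00653",
                                      "BIR repeat", span[0], span[1], 1e-8))
            else:
                hits.append(DomainHit(protein_id, "CDD", "cd00022",
                                      "BIR repeat", span[0], span[1], 1e-10))
                hits.append(DomainHit(protein_id, "PFAM", "PF00653",
                                      "BIR repeat", span[0], span[1], 1e-8))
            domains.append({"token": token, "span": span,
                            "bir_type": bir_type.value})
        else:
            seq = _mutate(DOMAIN_TEMPLATES[token],
                          template_mutation_fraction, rng)
            span = (offset, offset + len(seq))
            hits.append(DomainHit(protein_id, "INTERPRO", _ACCESSION_OF[token],
                                  token, span[0], span[1], 1e-6))
            domains.append({"token": token, "span": span})
        pieces.append(seq)
        offset += len(seq)
        linker = _random_protein(rng, int(rng.integers(8, 16)))
        pieces.append(linker)
        offset += len(linker)
    return "".join(pieces), hits, domains


@dataclass
class FamilyBundle:
    """In-memory synthetic family plus its ground truth."""

    proteins: list[SequenceRecord]
    genes: list[GeneModel]
    scan: list[DomainHit]
    orf_scan: list[DomainHit]
    hmm_candidates: list[tuple[str, float]]
    coverage: dict[str, float]
    truth: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, out / "proteins.fasta")
        write_gff3(self.genes, out / "annotation.gff3")
        write_domain_scan(self.scan, out / "domain_scan.tsv")
        write_domain_scan(self.orf_scan, out / "orf_scan.tsv")
        with open(out / "hmm_candidates.tsv", "w") as fh:
            fh.write("protein_id\te_value\n")
            for pid, ev in self.hmm_candidates:
                fh.write(f"{pid}\t{ev!r}\n")
        with open(out / "coverage.tsv", "w") as fh:
            fh.write("protein_id\tcoverage\n")
            for pid in sorted(self.coverage):
                fh.write(f"{pid}\t{self.coverage[pid]!r}\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def gen_family(
    n_genes: int = 40,
    architecture_mix: dict[str, float] | None = None,
    haplotig_fraction: float = 0.1,
    intronless_fraction: float = 0.1,
    tandem_arrays: tuple[int, ...] = (4, 3),
    n_retro_tc1: int = 2,
    n_retro_rt: int = 2,
    n_decoy_evalue: int = 2,
    n_decoy_noncdd: int = 2,
    seed: int = 0,
) -> FamilyBundle:
    """A synthetic IAP family with planted curation features.

    ``n_genes`` counts true IAP genes including haplotig copies; decoys are
    extra.  Haplotigs are 97%-identity copies of a parent gene at 0.3x its
    read coverage.  Tandem arrays are placed on dedicated chromosomes with at
    most two intervening non-IAP filler genes; remaining genes are singletons
    separated by enough fillers that no spurious array can form.
    """
    if not 0 <= haplotig_fraction <= 1 or not 0 <= intronless_fraction <= 1:
        raise ValueError("fractions must be in [0,1]")
    n_haplotigs = int(round(haplotig_fraction * n_genes))
    n_primary = n_genes - n_haplotigs
    if sum(tandem_arrays) > n_primary:
        raise ValueError("tandem arrays larger than the number of genes")
    if n_haplotigs > n_primary:
        raise ValueError("more haplotigs than available parents")
    rng = np.random.default_rng(seed)
    if architecture_mix is None:
        names = sorted(ARCHITECTURE_EXEMPLARS)
        architecture_mix = {name: 1.0 / len(names) for name in names}
    arch_names = sorted(architecture_mix)
    probs = np.array([architecture_mix[a] for a in arch_names], dtype=float)
    probs = probs / probs.sum()

    proteins: list[SequenceRecord] = []
    scan: list[DomainHit] = []
    coverage: dict[str, float] = {}
    hmm: list[tuple[str, float]] = []
    truth_genes: dict[str, dict] = {}

    def add_protein(gene_id: str, residues: str, hits: list[DomainHit],
                    cov: float, e_value: float) -> tuple[str, str]:
        tid, pid = f"{gene_id}.t1", f"{gene_id}.p1"
        rehomed = [DomainHit(pid, h.source_db, h.accession, h.description,
                             h.start, h.end, h.e_value) for h in hits]
        proteins.append(SequenceRecord(pid, pid, residues))
        scan.extend(rehomed)
        coverage[pid] = cov
        hmm.append((pid, e_value))
        return tid, pid

    # --- primary IAP genes
    gene_arch = rng.choice(len(arch_names), size=n_primary, p=probs)
    primary_ids = [f"G{i:04d}" for i in range(1, n_primary + 1)]
    for gid, arch_idx in zip(primary_ids, gene_arch):
        arch = arch_names[arch_idx]
        variants = ARCHITECTURE_EXEMPLARS[arch]
        tokens = variants[int(rng.integers(0, len(variants)))]
        residues, hits, domains = _build_protein(tokens, rng, f"{gid}.p1")
        cov = float(np.round(rng.uniform(22, 38), 3))
        e_value = float(10.0 ** rng.uniform(-30, -5))
        tid, pid = add_protein(gid, residues, hits, cov, e_value)
        truth_genes[gid] = {
            "is_iap": True, "architecture": arch, "tokens": list(tokens),
            "domains": domains, "transcript_id": tid, "protein_id": pid,
            "coverage": cov, "haplotig_parent": None,
        }

    # --- haplotig copies (97% identity, 0.3x parent coverage)
    parents = [primary_ids[i] for i in
               rng.choice(n_primary, size=n_haplotigs, replace=False)]
    haplotig_ids = []
    for j, parent_gid in enumerate(sorted(parents), 1):
        gid = f"H{j:04d}"
        haplotig_ids.append(gid)
        parent = truth_genes[parent_gid]
        parent_seq = next(
            p.residues for p in proteins if p.id == parent["protein_id"])
        residues = _mutate(parent_seq, 0.03, rng)
        hits = [DomainHit(f"{gid}.p1", h.source_db, h.accession,
                          h.description, h.start, h.end, h.e_value)
                for h in scan if h.protein_id == parent["protein_id"]]
        cov = float(np.round(0.3 * parent["coverage"], 3))
        tid, pid = add_protein(gid, residues, hits, cov,
                               float(10.0 ** rng.uniform(-30, -5)))
        truth_genes[gid] = {
            "is_iap": True, "architecture": parent["architecture"],
            "tokens": parent["tokens"], "domains": parent["domains"],
            "transcript_id": tid, "protein_id": pid, "coverage": cov,
            "haplotig_parent": parent["protein_id"],
        }

    # --- decoys: fail the E-value filter, or lack a CDD BIR hit
    decoy_ids = []
    for j in range(1, n_decoy_evalue + 1):
        gid = f"DEV{j:02d}"
        decoy_ids.append(gid)
        residues, hits, _ = _build_protein(("TII",), rng, f"{gid}.p1")
        add_protein(gid, residues, hits,
                    float(np.round(rng.uniform(22, 38), 3)),
                    float(rng.uniform(0.002, 0.5)))
        truth_genes[gid] = {"is_iap": False, "decoy": "evalue",
                            "protein_id": f"{gid}.p1",
                            "transcript_id": f"{gid}.t1",
                            "haplotig_parent": None}
    for j in range(1, n_decoy_noncdd + 1):
        gid = f"DNC{j:02d}"
        decoy_ids.append(gid)
        residues, hits, _ = _build_protein(("BIR_STAR",), rng, f"{gid}.p1")
        add_protein(gid, residues, hits,
                    float(np.round(rng.uniform(22, 38), 3)),
                    float(10.0 ** rng.uniform(-20, -5)))
        truth_genes[gid] = {"is_iap": False, "decoy": "no_cdd_bir",
                            "protein_id": f"{gid}.p1",
                            "transcript_id": f"{gid}.t1",
                            "haplotig_parent": None}

    # --- genomic placement
    intronless = set(
        primary_ids[i] for i in rng.choice(
            n_primary, size=int(round(intronless_fraction * n_primary)),
            replace=False))
    array_members: dict[str, str] = {}
    remaining = [g for g in primary_ids]
    genes: list[GeneModel] = []
    filler_counter = 0

    def protein_length(gid: str) -> int:
        pid = truth_genes[gid]["protein_id"]
        return len(next(p.residues for p in proteins if p.id == pid))

    def make_gene(gid: str, chrom: str, start: int) -> tuple[GeneModel, int]:
        nonlocal filler_counter
        plen = protein_length(gid) if gid in truth_genes else 300
        cds = plen * 3
        if gid in intronless:
            exons = ((start, start + cds),)
        else:
            n_exons = int(rng.integers(2, 5))
            cuts = sorted(rng.choice(
                range(1, cds), size=n_exons - 1, replace=False))
            bounds = [0, *cuts, cds]
            exons_list = []
            pos = start
            for a, b in zip(bounds, bounds[1:]):
                exons_list.append((pos, pos + (b - a)))
                pos += (b - a) + int(rng.integers(200, 1500))
            exons = tuple(exons_list)
        strand = "+" if rng.integers(0, 2) else "-"
        tid = truth_genes.get(gid, {}).get("transcript_id", f"{gid}.t1")
        model = GeneModel(gid, chrom, strand,
                          (TranscriptModel(tid, exons),))
        return model, exons[-1][1]

    def add_filler(chrom: str, start: int) -> tuple[GeneModel, int]:
        nonlocal filler_counter
        filler_counter += 1
        gid = f"FILLER{filler_counter:04d}"
        length = int(rng.integers(900, 3000))
        model = GeneModel(
            gid, chrom, "+",
            (TranscriptModel(f"{gid}.t1", ((start, start + length),)),))
        return model, start + length

    truth_arrays: dict[str, list[str]] = {}
    for a_idx, size in enumerate(tandem_arrays, 1):
        chrom = f"chr{5 + a_idx}"  # arrays on chr6, chr7, ...
        pos = int(rng.integers(10_000, 50_000))
        members = [remaining.pop(0) for _ in range(size)]
        truth_arrays[f"{chrom}:array1"] = members
        for m_idx, gid in enumerate(members):
            model, end = make_gene(gid, chrom, pos)
            genes.append(model)
            array_members[gid] = f"{chrom}:array1"
            if m_idx < size - 1:
                pos = end + int(rng.integers(2_000, 15_000))
                for _ in range(int(rng.integers(0, 3))):  # <= 2 fillers
                    fmodel, fend = add_filler(chrom, pos)
                    genes.append(fmodel)
                    pos = fend + int(rng.integers(1_000, 5_000))

    # singletons (and decoys, and haplotigs) spread with >= 3 fillers between
    single_chroms = ["chr1", "chr2", "chr3", "chr4", "chr5"]
    positions = {c: int(rng.integers(10_000, 30_000)) for c in single_chroms}
    spread = remaining + decoy_ids + haplotig_ids
    for i, gid in enumerate(spread):
        chrom = single_chroms[i % len(single_chroms)]
        model, end = make_gene(gid, chrom, positions[chrom])
        genes.append(model)
        pos = end + int(rng.integers(5_000, 20_000))
        for _ in range(3):
            fmodel, fend = add_filler(chrom, pos)
            genes.append(fmodel)
            pos = fend + int(rng.integers(2_000, 10_000))
        positions[chrom] = pos + int(rng.integers(250_000, 400_000))

    for gid in truth_genes:
        truth_genes[gid]["intronless"] = gid in intronless
        truth_genes[gid]["tandem_array"] = array_members.get(gid)

    # --- retroposition machinery on translated ORFs
    orf_scan: list[DomainHit] = []
    retro_pool = [g for g in primary_ids if g not in intronless]
    picks = list(rng.choice(retro_pool, size=n_retro_tc1 + n_retro_rt,
                            replace=False))
    for gid in picks[:n_retro_tc1]:
        acc = ["IPR002492", "IPR027805", "IPR038717"][int(rng.integers(0, 3))]
        orf_scan.append(DomainHit(gid, "INTERPRO", acc,
                                  "Transposase Tc1-like", 10, 210, 1e-6))
        truth_genes[gid].setdefault("retro_flags", []).append("transposase_tc1")
    for gid in picks[n_retro_tc1:]:
        orf_scan.append(DomainHit(gid, "INTERPRO", "IPR000477",
                                  "Reverse transcriptase domain", 10, 310, 1e-6))
        truth_genes[gid].setdefault("retro_flags", []).append(
            "reverse_transcriptase")
    for gid in truth_genes:
        truth_genes[gid].setdefault("retro_flags", [])

    truth = {
        "seed": int(seed),
        "n_genes": int(n_genes),
        "genes": truth_genes,
        "tandem_arrays": truth_arrays,
        "haplotigs": {
            truth_genes[g]["protein_id"]: truth_genes[g]["haplotig_parent"]
            for g in haplotig_ids},
        "intronless": sorted(intronless),
    }
    genes.sort(key=lambda g: (g.chromosome, g.span[0], g.gene_id))
    return FamilyBundle(proteins, genes, scan, orf_scan, hmm, coverage, truth)


# ---------------------------------------------------------------------------
# Expression generation

def gen_expression(
    n_genes: int,
    n_samples: int,
    module_sizes: tuple[int, ...],
    within_correlation: float | tuple[float, ...] = 0.7,
    trait_r: float | tuple[float, ...] = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Expression matrix with planted correlated modules and a trait effect.

    Module genes load on a shared latent factor (pairwise correlation
    ``within_correlation``); the factor itself correlates with a balanced
    binary challenge trait at ``trait_r``.  Leftover genes are independent
    noise.  Returns (expr genes x samples, trait, truth labels with 0 = no
    module).
    """
    if sum(module_sizes) > n_genes:
        raise ValueError("module sizes exceed n_genes")
    n_modules = len(module_sizes)
    w = (np.full(n_modules, within_correlation)
         if np.isscalar(within_correlation) else np.asarray(within_correlation))
    r = (np.full(n_modules, trait_r)
         if np.isscalar(trait_r) else np.asarray(trait_r, dtype=float))
    if (np.abs(r) > 1).any() or (w < 0).any() or (w > 1).any():
        raise ValueError("correlations must lie in [-1,1] / [0,1]")
    rng = np.random.default_rng(seed)
    trait = np.zeros(n_samples)
    trait[n_samples // 2:] = 1.0
    t_std = (trait - trait.mean()) / trait.std()
    X = np.empty((n_genes, n_samples))
    labels = np.zeros(n_genes, dtype=int)
    row = 0
    for m, (size, w_m, r_m) in enumerate(zip(module_sizes, w, r), start=1):
        eps = rng.standard_normal(n_samples)
        eps = (eps - eps.mean()) / eps.std()
        factor = r_m * t_std + np.sqrt(1 - r_m ** 2) * eps
        for _ in range(size):
            noise = rng.standard_normal(n_samples) * noise_sd
            X[row] = np.sqrt(w_m) * factor + np.sqrt(max(0.0, 1 - w_m)) * noise
            labels[row] = m
            row += 1
    for _ in range(n_genes - row):
        X[row] = rng.standard_normal(n_samples) * noise_sd
        row += 1
    index = [f"gene{i:04d}" for i in range(1, n_genes + 1)]
    cols = [f"S{j:02d}" for j in range(1, n_samples + 1)]
    expr = pd.DataFrame(X, index=index, columns=cols)
    return expr, pd.Series(trait, index=cols, name="trait"), labels


# ---------------------------------------------------------------------------
# DE-table generation

def gen_shared_status_maps(
    experiments: tuple[str, ...],
    n_shared: int,
    n_unique_per_experiment: int,
    n_constitutive: int = 3,
    n_mixed: int = 2,
    n_silent: int = 2,
) -> tuple[dict[str, dict[str, str]], float]:
    """Status maps with a planted shared-DEG fraction.

    ``n_shared`` genes are differential in every experiment; each experiment
    additionally gets ``n_unique_per_experiment`` private DEGs and
    ``n_mixed`` private mixed genes (mixed genes carry a significant
    transcript, so they count as DEGs).  The planted shared fraction (genes
    differentially expressed in >= 2 experiments over the DEG union) is
    returned alongside the maps.
    """
    statuses: dict[str, dict[str, str]] = {e: {} for e in experiments}
    shared = [f"SH{i:03d}" for i in range(n_shared)]
    for exp_i, exp in enumerate(experiments):
        for g in shared:
            statuses[exp][g] = "differential"
        for j in range(n_unique_per_experiment):
            statuses[exp][f"UQ_{exp_i}_{j:03d}"] = "differential"
        for j in range(n_constitutive):
            statuses[exp][f"CG{j:03d}"] = "constitutive"
        for j in range(n_mixed):
            statuses[exp][f"MX_{exp_i}_{j:03d}"] = "mixed"
        for j in range(n_silent):
            statuses[exp][f"NE{j:03d}"] = "not_expressed"
    union = n_shared + len(experiments) * (n_unique_per_experiment + n_mixed)
    planted_fraction = n_shared / union
    return statuses, planted_fraction


def gen_de_tables(
    statuses: dict[str, dict[str, str]],
    n_samples: int = 6,
    comparisons: tuple[str, ...] = ("challenge_vs_control",),
    seed: int = 0,
) -> dict[str, dict]:
    """Per-experiment DE tables and count matrices realizing planted statuses.

    differential genes get one transcript with padj drawn below 0.05 in one
    comparison; constitutive ones a transcript with padj above 0.1 detected in
    every sample; mixed genes one of each; not_expressed genes a transcript
    whose total count falls under the standard prefilter (10 reads).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {}
    samples = [f"S{j:02d}" for j in range(1, n_samples + 1)]
    for exp_id in sorted(statuses):
        de_rows: list[dict] = []
        count_rows: dict[str, np.ndarray] = {}
        gene_transcripts: dict[str, list[str]] = {}

        def sig_counts() -> np.ndarray:
            # overdispersed draw; total guaranteed past the 10-read prefilter
            c = rng.negative_binomial(2, 0.05, size=n_samples)
            c[int(rng.integers(0, n_samples))] += 15
            return c

        def constit_counts() -> np.ndarray:
            return 1 + rng.negative_binomial(3, 0.08, size=n_samples)

        def add_de(tid: str, significant: bool) -> None:
            hot = int(rng.integers(0, len(comparisons)))
            for ci, comp in enumerate(comparisons):
                if significant and ci == hot:
                    padj = float(rng.uniform(1e-8, 0.049))
                    lfc = float(rng.uniform(1.0, 4.0) * rng.choice([-1, 1]))
                else:
                    padj = float(rng.uniform(0.1, 0.95))
                    lfc = float(rng.uniform(-0.5, 0.5))
                de_rows.append({"transcript_id": tid, "comparison_id": comp,
                                "lfc": lfc, "padj": padj})

        for gene_id in sorted(statuses[exp_id]):
            status = statuses[exp_id][gene_id]
            if status == "differential":
                tid = f"{gene_id}.t1"
                gene_transcripts[gene_id] = [tid]
                count_rows[tid] = sig_counts()
                add_de(tid, True)
            elif status == "constitutive":
                tid = f"{gene_id}.t1"
                gene_transcripts[gene_id] = [tid]
                count_rows[tid] = constit_counts()
                add_de(tid, False)
            elif status == "mixed":
                t1, t2 = f"{gene_id}.t1", f"{gene_id}.t2"
                gene_transcripts[gene_id] = [t1, t2]
                count_rows[t1] = sig_counts()
                add_de(t1, True)
                count_rows[t2] = constit_counts()
                add_de(t2, False)
            elif status == "not_expressed":
                tid = f"{gene_id}.t1"
                gene_transcripts[gene_id] = [tid]
                c = np.zeros(n_samples, dtype=int)
                c[int(rng.integers(0, n_samples))] = int(rng.integers(0, 10))
                count_rows[tid] = c
            else:
                raise ValueError(f"unknown planted status {status!r}")
        de = pd.DataFrame(
            de_rows, columns=["transcript_id", "comparison_id", "lfc", "padj"])
        counts = pd.DataFrame.from_dict(
            count_rows, orient="index", columns=samples).sort_index()
        out[exp_id] = {"de": de, "counts": counts,
                       "gene_transcripts": gene_transcripts,
                       "truth": dict(statuses[exp_id])}
    return out
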