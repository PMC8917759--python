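"""Expression-status classification of IAP genes across immune challenges.

Works strictly downstream of a differential-expression model: inputs are
per-experiment DE tables (transcript, comparison, log2 fold change, adjusted
p) and raw count matrices.  Transcripts under the count prefilter are removed
entirely; the remainder are significant (padj <= padj_max in any comparison)
or constitutive (never significant, detected in every sample).  Gene status
aggregates transcript statuses into differential / constitutive / mixed /
not_expressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import ExpressionConfig


@dataclass(frozen=True)
class ExpressionStatus:
    gene_id: str
    experiment_id: str
    status: str  # differential | constitutive | mixed | not_expressed
    transcript_statuses: tuple[tuple[str, str], ...]


def classify_expression_status(
    de: pd.DataFrame,
    counts: pd.DataFrame,
    gene_transcripts: dict[str, list[str]],
    cfg: ExpressionConfig | None = None,
    experiment_id: str = "",
) -> list[ExpressionStatus]:
    """Classify each gene's expression status in one experiment.

    A transcript is *significant* iff padj <= padj_max in at least one
    comparison; *constitutive* iff it is never significant, passes the
    min_total_count prefilter and is detected (count >= detection_min_count)
    in every sample.  Transcripts failing the prefilter are excluded from the
    analysis entirely.  Gene status: differential iff >= 1 significant
    transcript and none constitutive; constitutive iff >= 1 constitutive and
    none significant; mixed iff both; not_expressed otherwise.
    """
    cfg = cfg or ExpressionConfig()
    in_de = set(de["transcript_id"])
    missing = sorted(in_de - set(counts.index))
    if missing:
        raise ValueError(
            f"transcripts in DE table but absent from counts: {missing}")
    sig_transcripts = set(
        de.loc[de["padj"] <= cfg.padj_max, "transcript_id"])
    statuses: list[ExpressionStatus] = []
    for gene_id, transcript_ids in gene_transcripts.items():
        t_statuses: list[tuple[str, str]] = []
        for tid in transcript_ids:
            if tid not in counts.index:
                t_statuses.append((tid, "excluded"))
                continue
            row = counts.loc[tid]
            if row.sum() < cfg.min_total_count:
                t_statuses.append((tid, "excluded"))
                continue
            if tid in sig_transcripts:
                t_statuses.append((tid, "significant"))
            elif (row >= cfg.detection_min_count).all():
                t_statuses.append((tid, "constitutive"))
            else:
                t_statuses.append((tid, "not_expressed"))
        kinds = {s for _t, s in t_statuses}
        if "significant" in kinds and "constitutive" in kinds:
            status = "mixed"
        elif "significant" in kinds:
            status = "differential"
        elif "constitutive" in kinds:
            status = "constitutive"
        else:
            status = "not_expressed"
        statuses.append(ExpressionStatus(
            gene_id, experiment_id, status, tuple(t_statuses)))
    return statuses


def shared_deg_fraction(deg_sets: dict[str, set[str]]) -> float:
    """Fraction of the DEG union differentially expressed in >= 2 experiments."""
    if len(deg_sets) < 2:
        raise ValueError("sharing requires >= 2 experiments")
    union = set().union(*deg_sets.values())
    if not union:
        raise ValueError("empty DEG union")
    shared = {
        g for g in union
        if sum(g in degs for degs in deg_sets.values()) >= 2
    }
    return len(shared) / len(union)


def shared_deg_fraction_all(deg_sets: dict[str, set[str]]) -> float:
    """Stricter alternative: fraction of the union shared by *all* experiments.

    Emitted alongside the default because the source statistic's denominator
    convention is ambiguous; reports should state which was used.
    """
    if len(deg_sets) < 2:
        raise ValueError("sharing requires >= 2 experiments")
    union = set().union(*deg_sets.values())
    if not union:
        raise ValueError("empty DEG union")
    inter = set.intersection(*(set(s) for s in deg_sets.values()))
    return len(inter) / len(union)


def architecture_usage(
    deg_transcripts_by_experiment: dict[str, set[str]],
    architecture_of: dict[str, str],
) -> pd.DataFrame:
    """Counts of distinct differentially expressed transcripts per
    architecture type per experiment, plus the distinct-type count.

    Every expressed transcript must have an architecture call.
    """
    rows = []
    for exp_id, transcripts in sorted(deg_transcripts_by_experiment.items()):
        missing = sorted(t for t in transcripts if t not in architecture_of)
        if missing:
            raise ValueError(
                f"{exp_id}: transcripts without architecture calls: {missing}")
        per_type: dict[str, int] = {}
        for t in transcripts:
            per_type[architecture_of[t]] = per_type.get(architecture_of[t], 0) + 1
        for arch, n in sorted(per_type.items()):
            rows.append({"experiment_id": exp_id, "architecture": arch,
                         "n_transcripts": n, "n_types": len(per_type)})
    return pd.DataFrame(
        rows, columns=["experiment_id", "architecture", "n_transcripts",
                       "n_types"])
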