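"""Weighted co-expression network analysis, written from scratch.

The pipeline follows the standard weighted-network recipe for small designs:
biweight midcorrelation (a robust correlation that down-weights outliers via
Tukey biweights around the median), signed-hybrid adjacency a_ij = cor^beta
for positive correlations and 0 otherwise, soft-threshold selection by fit to
scale-free topology with a sample-size fallback (beta = 9 below 30 samples),
topological overlap, average-linkage hierarchical clustering with a static
tree cut, module eigengenes, module-trait significance, and extraction of
direct IAP-apoptosis edges inside significant modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .config import NetworkConfig


# ---------------------------------------------------------------------------
# Biweight midcorrelation

def _bicor_normalize(X: np.ndarray) -> np.ndarray:
    """Per-row biweight normalization so that bicor = U @ U.T.

    Rows with zero MAD (or zero weighted norm) fall back to the Pearson
    normalization for every pair involving them; all-constant rows yield a
    zero vector (correlation reported as 0, with a warning upstream).
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    ok = mad[:, 0] > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * mad)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    a = (X - med) * w
    norm = np.sqrt((a ** 2).sum(axis=1, keepdims=True))
    ok &= norm[:, 0] > 0
    U = np.zeros_like(X)
    U[ok] = a[ok] / norm[ok]
    # Pearson fallback for zero-MAD / degenerate-weight rows
    for i in np.where(~ok)[0]:
        centered = X[i] - X[i].mean()
        sd = np.sqrt((centered ** 2).sum())
        if sd > 0:
            U[i] = centered / sd
        else:
            warnings.warn(
                f"constant gene at row {i}: correlations reported as 0",
                RuntimeWarning, stacklevel=3)
    return U


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two vectors, clamped to [-1, 1]."""
    U = _bicor_normalize(np.vstack([x, y]))
    return float(np.clip(U[0] @ U[1], -1.0, 1.0))


def bicor_matrix(expr: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Gene x gene biweight midcorrelation matrix (rows = genes).

    Requires >= 4 samples.  Constant genes get zero correlation to everything
    (unit diagonal retained) with a warning.
    """
    values = expr.values if isinstance(expr, pd.DataFrame) else np.asarray(expr)
    if values.shape[1] < 4:
        raise ValueError("bicor requires >= 4 samples")
    U = _bicor_normalize(values)
    C = np.clip(U @ U.T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    if isinstance(expr, pd.DataFrame):
        return pd.DataFrame(C, index=expr.index, columns=expr.index)
    return C


# ---------------------------------------------------------------------------
# Adjacency and soft-threshold selection

def adjacency(cor: np.ndarray, beta: int,
              network_type: str = "signed_hybrid") -> np.ndarray:
    """Signed-hybrid adjacency: cor^beta for positive correlations, else 0."""
    if network_type != "signed_hybrid":
        raise ValueError(f"unsupported network type {network_type!r}")
    cor = np.asarray(cor, dtype=float)
    A = np.where(cor > 0, cor, 0.0) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log regression of the connectivity histogram.

    Connectivities are binned into ``n_bins`` equal-width bins of log10(k);
    log10 p(k) is regressed on log10(mean k) over non-empty bins.  The R^2 is
    signed by the negated slope so scale-free (decreasing) fits are positive.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size == 0:
        raise ValueError("all connectivities are zero")
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        xs.append(np.log10(np.mean(k[mask])))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    x, y = np.array(xs), np.array(ys)
    slope, _intercept = np.polyfit(x, y, 1)
    yhat = np.polyval(np.polyfit(x, y, 1), x)
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(
    expr: pd.DataFrame | np.ndarray | None = None,
    cfg: NetworkConfig | None = None,
    cor: np.ndarray | None = None,
    n_samples: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Smallest candidate power with scale-free signed R^2 >= the threshold.

    When no candidate reaches the threshold and the design has fewer than 30
    samples, the sample-size fallback power (default 9) is returned; with
    >= 30 samples the best-fitting power is returned and flagged in the table.
    Either ``expr`` (genes x samples) or a precomputed correlation matrix
    ``cor`` (with ``n_samples``) may be supplied.
    """
    cfg = cfg or NetworkConfig()
    if cor is None:
        if expr is None:
            raise ValueError("supply expr or cor")
        values = expr.values if isinstance(expr, pd.DataFrame) else np.asarray(expr)
        n_samples = values.shape[1]
        cor = np.asarray(bicor_matrix(values))
    elif n_samples is None:
        raise ValueError("n_samples required with a precomputed cor matrix")
    rows = []
    chosen: int | None = None
    for power in cfg.candidate_powers:
        A = adjacency(cor, power, cfg.network_type)
        k = A.sum(axis=0) - 1.0  # exclude the unit diagonal
        if not (k > 0).any():
            raise ValueError("all connectivities are zero")
        r2 = scale_free_fit(k)
        rows.append({"power": power, "signed_r2": r2, "mean_k": float(k.mean()),
                     "max_k": float(k.max())})
        if chosen is None and r2 >= cfg.scale_free_r2_min:
            chosen = power
    table = pd.DataFrame(rows)
    table["selected"] = False
    if chosen is None:
        if n_samples < 30:
            chosen = cfg.fallback_power
            table.attrs["fallback"] = True
        else:
            chosen = int(table.loc[table["signed_r2"].idxmax(), "power"])
            table.attrs["fallback"] = False
            table.attrs["best_fit_only"] = True
    table.loc[table["power"] == chosen, "selected"] = True
    return int(chosen), table


# ---------------------------------------------------------------------------
# Topological overlap and module detection

def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix of an adjacency matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with L = A@A over
    off-diagonal entries; TOM_ii = 1.
    """
    A = np.asarray(A, dtype=float)
    Aoff = A.copy()
    np.fill_diagonal(Aoff, 0.0)
    L = Aoff @ Aoff
    k = Aoff.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - Aoff
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + Aoff) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def module_eigengene(expr_block: np.ndarray) -> np.ndarray:
    """First principal component of a module's standardized expression,
    sign-aligned so it correlates positively with mean expression."""
    X = np.asarray(expr_block, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    _u, _s, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    if np.corrcoef(eig, Z.mean(axis=0))[0, 1] < 0:
        eig = -eig
    return eig


def detect_modules(
    A: np.ndarray,
    expr: pd.DataFrame | np.ndarray,
    cfg: NetworkConfig | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Static-cut module detection on topological-overlap dissimilarity.

    Average-linkage hierarchical clustering of 1 - TOM is cut at the fixed
    height ``cfg.cut_height``; clusters smaller than ``min_module_size`` are
    unassigned (label 0).  Modules whose eigengenes correlate above
    1 - merge_height are merged iteratively.  Returns (labels, eigengenes)
    with eigengenes as a modules x samples DataFrame indexed by label.
    """
    cfg = cfg or NetworkConfig()
    values = expr.values if isinstance(expr, pd.DataFrame) else np.asarray(expr)
    n = values.shape[0]
    if n < cfg.min_module_size:
        return np.zeros(n, dtype=int), pd.DataFrame()
    tom = tom_similarity(A)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=cfg.cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = [(np.sum(raw == c), -raw[raw == c][0], c)
             for c in np.unique(raw)]
    next_label = 1
    for size, _tiebreak, c in sorted(sizes, reverse=True):
        if size >= cfg.min_module_size:
            labels[raw == c] = next_label
            next_label += 1
    labels = _merge_similar_modules(labels, values, cfg)
    eigengenes = _eigengene_table(labels, values, expr)
    return labels, eigengenes


def _eigengene_table(labels, values, expr) -> pd.DataFrame:
    mods = sorted(set(labels) - {0})
    rows = {m: module_eigengene(values[labels == m]) for m in mods}
    cols = (expr.columns if isinstance(expr, pd.DataFrame)
            else range(values.shape[1]))
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _merge_similar_modules(labels, values, cfg: NetworkConfig) -> np.ndarray:
    labels = labels.copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        eigs = {m: module_eigengene(values[labels == m]) for m in mods}
        best = None
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1:]:
                r = float(np.corrcoef(eigs[m1], eigs[m2])[0, 1])
                if r > 1.0 - cfg.merge_height and (best is None or r > best[0]):
                    best = (r, m1, m2)
        if best is None:
            break
        _r, m1, m2 = best
        labels[labels == m2] = m1
        # renumber to consecutive labels by size
        out = np.zeros_like(labels)
        remaining = sorted(set(labels) - {0},
                           key=lambda m: (-np.sum(labels == m), m))
        for new, old in enumerate(remaining, start=1):
            out[labels == old] = new
        labels = out
    return labels


# ---------------------------------------------------------------------------
# Module-trait statistics and direct edges

def module_trait_significance(
    eigengenes: pd.DataFrame,
    trait: np.ndarray | pd.Series,
    cfg: NetworkConfig | None = None,
    iap_count: dict[int, int] | None = None,
    apoptosis_count: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with the trait.

    p-values come from t = r sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom.
    A module is significant iff p <= module_trait_p_max AND it contains at
    least one IAP transcript AND more than one apoptosis-related transcript
    (membership counts supplied by the caller; omitted counts default to
    passing so the statistic can be used standalone).
    """
    cfg = cfg or NetworkConfig()
    y = np.asarray(trait, dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("constant trait vector")
    n = y.size
    rows = []
    for module, eig in eigengenes.iterrows():
        if eig.size != n:
            raise ValueError("trait length must equal sample count")
        r = float(np.corrcoef(eig.values, y)[0, 1])
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t_stat = r * np.sqrt(n - 2) / np.sqrt(1 - r ** 2)
            p = float(2 * t_dist.sf(abs(t_stat), df=n - 2))
        n_iap = (iap_count or {}).get(module, 1)
        n_apo = (apoptosis_count or {}).get(module, 2)
        significant = bool(p <= cfg.module_trait_p_max
                           and n_iap >= 1 and n_apo > 1)
        rows.append({"module": module, "r": r, "p": p,
                     "n_iap": n_iap, "n_apoptosis": n_apo,
                     "significant": significant})
    return pd.DataFrame(
        rows, columns=["module", "r", "p", "n_iap", "n_apoptosis",
                       "significant"]).set_index("module")


def extract_direct_edges(
    adjacency_df: pd.DataFrame,
    labels: np.ndarray,
    significant_modules: set[int],
    iap_ids: set[str],
    apoptosis_ids: set[str],
    cfg: NetworkConfig | None = None,
) -> pd.DataFrame:
    """IAP-apoptosis gene pairs sharing an edge inside a significant module.

    An edge is reported iff both endpoints carry the same significant module
    label and their adjacency is >= edge_adjacency_min.  Output is sorted by
    (iap_id, partner_id) so it is invariant to gene ordering.
    """
    cfg = cfg or NetworkConfig()
    genes = list(adjacency_df.index)
    unknown = (iap_ids | apoptosis_ids) - set(genes)
    if unknown:
        raise ValueError(f"ids not in the network: {sorted(unknown)}")
    label_of = dict(zip(genes, labels))
    rows = []
    for iap in sorted(iap_ids):
        m = label_of[iap]
        if m == 0 or m not in significant_modules:
            continue
        for partner in sorted(apoptosis_ids):
            if partner == iap or label_of[partner] != m:
                continue
            weight = float(adjacency_df.at[iap, partner])
            if weight >= cfg.edge_adjacency_min:
                rows.append({"iap_id": iap, "partner_id": partner,
                             "module": m, "adjacency": weight})
    return pd.DataFrame(
        rows, columns=["iap_id", "partner_id", "module", "adjacency"])


# ---------------------------------------------------------------------------
# Convenience bundle

@dataclass
class CoexprNetwork:
    gene_ids: list[str]
    beta: int
    correlation: pd.DataFrame
    adjacency: pd.DataFrame
    labels: np.ndarray
    eigengenes: pd.DataFrame
    trait_stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_network(
    expr: pd.DataFrame,
    trait: np.ndarray | pd.Series,
    iap_ids: set[str],
    apoptosis_ids: set[str],
    cfg: NetworkConfig | None = None,
) -> CoexprNetwork:
    """Run the full network flow for one experiment's expression matrix."""
    cfg = cfg or NetworkConfig()
    cor = bicor_matrix(expr)
    beta, _fit = pick_soft_threshold(cor=np.asarray(cor),
                                     n_samples=expr.shape[1], cfg=cfg)
    A = adjacency(np.asarray(cor), beta, cfg.network_type)
    A_df = pd.DataFrame(A, index=expr.index, columns=expr.index)
    labels, eigengenes = detect_modules(A, expr, cfg)
    iap_count: dict[int, int] = {}
    apo_count: dict[int, int] = {}
    for gene, label in zip(expr.index, labels):
        if label == 0:
            continue
        if gene in iap_ids:
            iap_count[label] = iap_count.get(label, 0) + 1
        if gene in apoptosis_ids:
            apo_count[label] = apo_count.get(label, 0) + 1
    if len(eigengenes):
        stats = module_trait_significance(
            eigengenes, trait, cfg,
            iap_count={m: iap_count.get(m, 0) for m in eigengenes.index},
            apoptosis_count={m: apo_count.get(m, 0) for m in eigengenes.index})
        significant = set(stats.index[stats["significant"]])
    else:
        stats = pd.DataFrame()
        significant = set()
    edges = extract_direct_edges(A_df, labels, significant, iap_ids,
                                 apoptosis_ids, cfg)
    return CoexprNetwork(list(expr.index), beta, cor, A_df, labels,
                         eigengenes, stats, edges)
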