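"""Per-cluster Wilcoxon rank-sum differential expression between conditions.

Semantics mirror the standard single-cell marker test: genes are prefiltered
on detection fraction (``max(pct_a, pct_b) >= min_pct``) and log fold change
(``|log_fc| >= logfc_threshold`` with
``log_fc = ln(mean(expm1(a)) + 1) - ln(mean(expm1(b)) + 1)`` on normalized
values), then tested with a two-sided Wilcoxon rank-sum.  Groups of at most
8 cells each are tested by exact enumeration of all label reassignments;
larger groups use the normal approximation with tie and continuity
correction.  Survivors are filtered on the raw p-value; a BH-adjusted column
is emitted but never used for filtering.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientCellsError
from .qc import NormalizedMatrix
from .screen import benjamini_hochberg

logger = logging.getLogger(__name__)

EXACT_MAX_GROUP = 8

DE_COLUMNS = ["gene", "log_fc", "pct_a", "pct_b", "p", "p_bh", "direction"]


def exact_ranksum_p(values: np.ndarray, n_a: int) -> float:
    """Two-sided rank-sum p by enumerating all assignments of group labels.

    ``values`` is the pooled sample with the first ``n_a`` entries belonging
    to group A.  Ties are handled through midranks.  This doubles as the
    small-sample path of :func:`wilcoxon_de` and the independent oracle for
    the asymptotic path.
    """
    n = values.size
    ranks = stats.rankdata(values)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    combos = np.array(list(combinations(range(n), n_a)))
    w_all = ranks[combos].sum(axis=1)
    return float(np.mean(np.abs(w_all - mu) >= abs(w_obs - mu) - 1e-9))


def _asymptotic_ranksum_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided normal-approximation rank-sum test per gene row.

    Tie correction and a 0.5 continuity correction are applied, matching the
    conventional Wilcoxon/Mann-Whitney asymptotic test.
    """
    n_a, n_b = a.shape[1], b.shape[1]
    n = n_a + n_b
    pooled = np.concatenate([a, b], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    w = ranks[:, :n_a].sum(axis=1)
    u = w - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    # tie correction: sum over tied groups of (t^3 - t)
    sorted_rows = np.sort(pooled, axis=1)
    tie_term = np.zeros(pooled.shape[0])
    for i in range(pooled.shape[0]):
        _, counts = np.unique(sorted_rows[i], return_counts=True)
        tie_term[i] = (counts ** 3 - counts).sum()
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u - mu) - 0.5) / sigma
    p = 2.0 * stats.norm.sf(z)
    p = np.clip(p, 0.0, 1.0)
    p[sigma == 0] = 1.0  # all values tied: no evidence
    return p


def log_fold_change(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    """ln(mean(expm1(a)) + 1) - ln(mean(expm1(b)) + 1), per gene row."""
    return np.log(np.expm1(norm_a).mean(axis=1) + 1.0) - np.log(
        np.expm1(norm_b).mean(axis=1) + 1.0
    )


def wilcoxon_de(
    normalized: NormalizedMatrix,
    annotation: pd.DataFrame,
    cluster: str | None,
    condition_a: str,
    condition_b: str,
    logfc_threshold: float = 0.25,
    min_pct: float = 0.2,
    p_cutoff: float = 0.05,
    return_all: bool = False,
) -> pd.DataFrame:
    """Differentially expressed genes between two conditions in one cluster.

    Direction ``up`` means higher in ``condition_a``.  With
    ``return_all=True`` the unfiltered per-gene table (prefilter-passing
    genes, no p cutoff) is returned instead of the survivors.
    """
    ann = annotation.reindex(normalized.cells)
    in_cluster = np.ones(normalized.n_cells, dtype=bool)
    if cluster is not None:
        in_cluster = (ann["cluster"] == cluster).to_numpy()
    cond = ann["condition"].to_numpy()
    idx_a = np.flatnonzero(in_cluster & (cond == condition_a))
    idx_b = np.flatnonzero(in_cluster & (cond == condition_b))
    for name, idx in ((condition_a, idx_a), (condition_b, idx_b)):
        if idx.size < 3:
            raise InsufficientCellsError(
                f"group {name!r} in cluster {cluster!r} has {idx.size} cell(s), need >= 3"
            )
    a = np.asarray(normalized.values[:, idx_a].todense())
    b = np.asarray(normalized.values[:, idx_b].todense())
    pct_a = (a > 0).mean(axis=1)
    pct_b = (b > 0).mean(axis=1)
    lfc = log_fold_change(a, b)
    keep = (np.maximum(pct_a, pct_b) >= min_pct) & (np.abs(lfc) >= logfc_threshold)
    if not keep.any():
        return pd.DataFrame(columns=DE_COLUMNS)
    rows = np.flatnonzero(keep)
    if idx_a.size <= EXACT_MAX_GROUP and idx_b.size <= EXACT_MAX_GROUP:
        p = np.array([
            exact_ranksum_p(np.concatenate([a[i], b[i]]), idx_a.size) for i in rows
        ])
    else:
        p = _asymptotic_ranksum_p(a[rows], b[rows])
    out = pd.DataFrame({
        "gene": [normalized.genes[i] for i in rows],
        "log_fc": lfc[rows],
        "pct_a": pct_a[rows],
        "pct_b": pct_b[rows],
        "p": p,
    })
    out["p_bh"] = benjamini_hochberg(out["p"].to_numpy())
    out["direction"] = np.where(out["log_fc"] > 0, "up", "down")
    if not return_all:
        out = out[out["p"] <= p_cutoff]
    return out.sort_values(["p", "gene"]).reset_index(drop=True)[DE_COLUMNS]


def deg_counts(results_by_cluster: dict) -> pd.DataFrame:
    """Per-cluster counts of up/down survivors (the DEG-count bar-chart table)."""
    rows = []
    for cluster, df in results_by_cluster.items():
        rows.append({
            "cluster": cluster,
            "n_up": int((df["direction"] == "up").sum()) if len(df) else 0,
            "n_down": int((df["direction"] == "down").sum()) if len(df) else 0,
        })
    return pd.DataFrame(rows, columns=["cluster", "n_up", "n_down"])
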