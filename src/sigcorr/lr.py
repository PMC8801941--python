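"""Permutation-based ligand-receptor pairing between cell clusters.

The score of a (ligand, receptor) pair for an ordered (sender, receiver)
cluster pair is the unweighted mean of the ligand's mean normalized
expression in the sender and the receptor's mean in the receiver.  The null
is built by shuffling cluster labels across all cells; the permutation
p-value uses the add-one rule, so it can never be below ``1/(n_perm + 1)``.
Cluster pairs are directional throughout (Lc->Im and Im->Lc are distinct).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientCellsError
from .qc import NormalizedMatrix

logger = logging.getLogger(__name__)

LR_COLUMNS = [
    "ligand", "receptor", "sender", "receiver",
    "score", "p_perm", "significant", "expressed_ok",
]


def lr_test(
    normalized: NormalizedMatrix,
    annotation: pd.DataFrame,
    pairs,
    sender: str,
    receiver: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_expr_frac: float = 0.1,
) -> pd.DataFrame:
    """Score ligand-receptor pairs for one ordered (sender, receiver) pair.

    ``pairs`` is an iterable of (ligand, receptor) gene tuples; all pairs
    share the same label permutations.  Pairs where either gene is expressed
    in fewer than ``min_expr_frac`` of its cluster's cells are still scored
    but flagged ``expressed_ok = False``.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1 (add-one rule undefined at 0)")
    ann = annotation.reindex(normalized.cells)
    labels = ann["cluster"].to_numpy()
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ConfigError("need >= 2 clusters to permute labels meaningfully")
    for name in (sender, receiver):
        if name not in uniq:
            raise ConfigError(f"cluster {name!r} not present in annotation")
    send_mask = labels == sender
    recv_mask = labels == receiver
    if send_mask.sum() == 0 or recv_mask.sum() == 0:
        raise InsufficientCellsError("empty sender or receiver cluster")

    gidx = normalized.gene_index()
    kept_pairs = []
    for lig, rec in pairs:
        if lig not in gidx or rec not in gidx:
            logger.warning("pair (%s, %s): gene not in matrix, skipped", lig, rec)
            continue
        kept_pairs.append((lig, rec))
    if not kept_pairs:
        return pd.DataFrame(columns=LR_COLUMNS)

    need = sorted({g for pair in kept_pairs for g in pair})
    need_idx = {g: i for i, g in enumerate(need)}
    x = np.asarray(normalized.values[[gidx[g] for g in need], :].todense())

    lig_rows = np.array([need_idx[l] for l, _ in kept_pairs])
    rec_rows = np.array([need_idx[r] for _, r in kept_pairs])

    m_send = x[:, send_mask].mean(axis=1)
    m_recv = x[:, recv_mask].mean(axis=1)
    obs = 0.5 * (m_send[lig_rows] + m_recv[rec_rows])

    frac_lig = (x[lig_rows][:, send_mask] > 0).mean(axis=1)
    frac_rec = (x[rec_rows][:, recv_mask] > 0).mean(axis=1)
    expressed_ok = (frac_lig >= min_expr_frac) & (frac_rec >= min_expr_frac)

    rng = np.random.default_rng(seed)
    n_cells = x.shape[1]
    n_send = int(send_mask.sum())
    n_recv = int(recv_mask.sum())
    ge = np.zeros(len(kept_pairs), dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n_cells)
        perm_send = perm[:n_send]          # shuffled labels: which cells become the sender
        perm_recv = perm[n_send:n_send + n_recv] if sender != receiver else perm_send
        null_score = 0.5 * (
            x[lig_rows][:, perm_send].mean(axis=1)
            + x[rec_rows][:, perm_recv].mean(axis=1)
        )
        ge += null_score >= obs - 1e-12
    p = (1.0 + ge) / (1.0 + n_perm)

    return pd.DataFrame({
        "ligand": [l for l, _ in kept_pairs],
        "receptor": [r for _, r in kept_pairs],
        "sender": sender,
        "receiver": receiver,
        "score": obs,
        "p_perm": p,
        "significant": p <= alpha,
        "expressed_ok": expressed_ok,
    })[LR_COLUMNS]


def pair_counts(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Count significant pairs per ordered (sender, receiver) cluster pair."""
    if not len(results):
        return pd.DataFrame(columns=["sender", "receiver", "n_significant"])
    sig = results[results["p_perm"] <= alpha]
    counts = (
        sig.groupby(["sender", "receiver"], sort=True)
        .size()
        .reindex(
            results.groupby(["sender", "receiver"], sort=True).size().index,
            fill_value=0,
        )
    )
    out = counts.rename("n_significant").reset_index()
    out["n_significant"] = out["n_significant"].astype(int)
    return out
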