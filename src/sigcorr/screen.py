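"""Pearson correlation screening of signature scores and gene expression.

This is the analytical core of the pipeline: per-cluster, per-condition
Pearson correlation of a target signature score against candidate pathway
scores, threshold-ranked screen tables, top-k transcription-factor ranking
against a target gene, and cross-condition correlation-shift detection.

Conventions fixed here (and documented):

* signature-signature screens run on percentage scores; TF-gene screens run
  on normalized expression;
* screens threshold on r only; p-values and a Benjamini-Hochberg column are
  emitted for transparency but never used for filtering;
* ties in every ranking are broken lexicographically by candidate name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateInputError, InsufficientCellsError
from .qc import NormalizedMatrix

logger = logging.getLogger(__name__)

DEFAULT_TF_EXCLUSIONS = ("Hmgb4", "Spz1", "Tfam")

SCREEN_COLUMNS = [
    "target", "candidate", "cluster", "condition",
    "r", "p", "p_bh", "n_cells", "low_n",
]


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


def pearson(x, y) -> PearsonResult:
    """Sample Pearson r with the two-sided t-transform p-value.

    p comes from ``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom.
    Degenerate inputs are errors, never a silent 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("pearson expects two equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise InsufficientCellsError(f"need >= 3 observations, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("zero variance: correlation undefined")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return PearsonResult(r=r, p=p, n=n)


def benjamini_hochberg(p) -> np.ndarray:
    """BH-adjusted p-values (step-up), emitted for transparency only."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class ScreenConfig:
    """Threshold and ranking parameters for every screening operation."""

    r_min_pos: float | None = None   # keep r >= this (must be > 0 when set)
    r_max_neg: float | None = None   # keep r <= this (must be < 0 when set)
    top_k: int = 20
    min_cells: int = 10              # soft floor; n >= 3 is the hard floor
    min_tf_mean_expr: float = 0.5
    tf_exclusions: tuple = DEFAULT_TF_EXCLUSIONS
    sign_flip_floor: float = 0.1

    def __post_init__(self):
        if self.r_min_pos is not None and not self.r_min_pos > 0:
            raise ConfigError("r_min_pos must be > 0 when set")
        if self.r_max_neg is not None and not self.r_max_neg < 0:
            raise ConfigError("r_max_neg must be < 0 when set")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")


def _subset_cells(table: pd.DataFrame, cluster: str | None, condition: str | None) -> pd.DataFrame:
    sub = table
    if cluster is not None:
        sub = sub[sub["cluster"] == cluster]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    return sub


def screen(
    scores: pd.DataFrame,
    target: str,
    candidates,
    cluster: str | None = None,
    condition: str | None = None,
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Correlate the target score against each candidate in one cell subset.

    Returns the screen table sorted by r descending (ties lexicographic by
    candidate).  Records pass the r bounds when set; with no bounds set every
    candidate is reported (the input for shift analysis).  Zero-variance
    candidates are reported with r = NaN and never pass a bound.
    """
    sub = _subset_cells(scores, cluster, condition)
    n = len(sub)
    if n < 3:
        raise InsufficientCellsError(
            f"cluster={cluster!r} condition={condition!r}: {n} cell(s), need >= 3"
        )
    low_n = n < config.min_cells
    if low_n:
        logger.warning("screen on %d cells (< min_cells=%d)", n, config.min_cells)
    if target not in sub.columns:
        raise ConfigError(f"target {target!r} not in score table")
    tvec = sub[target].to_numpy(dtype=float)
    rows = []
    for cand in candidates:
        if cand == target:
            logger.warning("candidate %r equals target; self-correlation excluded", cand)
            continue
        if cand not in sub.columns:
            raise ConfigError(f"candidate {cand!r} not in score table")
        try:
            res = pearson(tvec, sub[cand].to_numpy(dtype=float))
            r, p = res.r, res.p
        except DegenerateInputError:
            logger.warning("candidate %r: zero variance, correlation undefined", cand)
            r, p = np.nan, np.nan
        rows.append({"target": target, "candidate": cand, "cluster": cluster,
                     "condition": condition, "r": r, "p": p,
                     "n_cells": n, "low_n": low_n})
    df = pd.DataFrame(rows, columns=[c for c in SCREEN_COLUMNS if c != "p_bh"])
    if len(df):
        df["p_bh"] = benjamini_hochberg(df["p"].fillna(1.0).to_numpy())
    else:
        df["p_bh"] = pd.Series(dtype=float)
    df = df[SCREEN_COLUMNS]
    if config.r_min_pos is not None or config.r_max_neg is not None:
        keep = pd.Series(False, index=df.index)
        if config.r_min_pos is not None:
            keep |= df["r"] >= config.r_min_pos
        if config.r_max_neg is not None:
            keep |= df["r"] <= config.r_max_neg
        df = df[keep.fillna(False)]
    return df.sort_values(["r", "candidate"], ascending=[False, True]).reset_index(drop=True)


def tf_screen(
    normalized: NormalizedMatrix,
    annotation: pd.DataFrame,
    target_gene: str,
    tf_universe,
    config: ScreenConfig = ScreenConfig(),
    cluster: str | None = None,
    condition: str | None = None,
) -> tuple:
    """Rank TFs by correlation with a target gene on normalized expression.

    TFs must reach mean normalized expression >= ``min_tf_mean_expr`` in the
    cell subset, must not be excluded (default Hmgb4/Spz1/Tfam) and must not
    be the target.  Returns ``(positive, negative)`` DataFrames of at most
    ``top_k`` rows each (r descending / ascending, rank starting at 1); a
    shortfall is a logged warning, not an error.
    """
    ann = annotation.reindex(normalized.cells)
    mask = np.ones(normalized.n_cells, dtype=bool)
    if cluster is not None:
        mask &= (ann["cluster"] == cluster).to_numpy()
    if condition is not None:
        mask &= (ann["condition"] == condition).to_numpy()
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise InsufficientCellsError(f"{idx.size} cell(s) in subset, need >= 3")
    gidx = normalized.gene_index()
    if target_gene not in gidx:
        raise ConfigError(f"target gene {target_gene!r} not in matrix")
    sub = normalized.values[:, idx]
    tvec = np.asarray(sub[gidx[target_gene], :].todense()).ravel()
    if tvec.std() == 0:
        raise DegenerateInputError(f"target gene {target_gene!r} has zero variance in subset")
    excluded = set(config.tf_exclusions) | {target_gene}
    rows = []
    for tf in tf_universe:
        if tf in excluded or tf not in gidx:
            continue
        vec = np.asarray(sub[gidx[tf], :].todense()).ravel()
        if vec.mean() < config.min_tf_mean_expr:
            continue
        try:
            res = pearson(tvec, vec)
        except DegenerateInputError:
            continue
        rows.append({"target": target_gene, "tf": tf, "r": res.r, "p": res.p,
                     "n_cells": idx.size})
    df = pd.DataFrame(rows, columns=["target", "tf", "r", "p", "n_cells"])
    pos = df[df["r"] > 0].sort_values(["r", "tf"], ascending=[False, True]).head(config.top_k)
    neg = df[df["r"] < 0].sort_values(["r", "tf"], ascending=[True, True]).head(config.top_k)
    for name, part in (("positive", pos), ("negative", neg)):
        if len(part) < config.top_k:
            logger.warning("tf_screen %s list: only %d of top_k=%d survivors",
                           name, len(part), config.top_k)
    pos = pos.reset_index(drop=True)
    neg = neg.reset_index(drop=True)
    pos.insert(2, "direction", "positive")
    neg.insert(2, "direction", "negative")
    pos.insert(3, "rank", np.arange(1, len(pos) + 1))
    neg.insert(3, "rank", np.arange(1, len(neg) + 1))
    return pos, neg


def correlation_shift(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    floor: float = 0.1,
) -> pd.DataFrame:
    """Per-pair change in r between two conditions' screen tables.

    ``delta_r = r_B - r_A``; a sign flip requires opposite signs and both
    |r| strictly above the reportable floor.  Pairs present in only one table
    are skipped with a warning.
    """
    key = ["target", "candidate"]
    a = records_a.set_index(key)
    b = records_b.set_index(key)
    common = a.index.intersection(b.index)
    skipped = len(a.index.symmetric_difference(b.index))
    if skipped:
        logger.warning("correlation_shift: %d pair(s) missing in one condition, skipped", skipped)
    rows = []
    for tgt, cand in common:
        r_a = float(a.loc[(tgt, cand), "r"])
        r_b = float(b.loc[(tgt, cand), "r"])
        flip = bool(r_a * r_b < 0 and abs(r_a) > floor and abs(r_b) > floor)
        rows.append({"target": tgt, "candidate": cand, "r_a": r_a, "r_b": r_b,
                     "delta_r": r_b - r_a, "sign_flip": flip})
    return pd.DataFrame(rows, columns=["target", "candidate", "r_a", "r_b",
                                       "delta_r", "sign_flip"])
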