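"""Negative-binomial scRNA-seq simulator with planted correlation structure.

Counts are NB draws with

    mean = baseline_mean * gene_factor * library_factor
           * exp(loading * z - loading^2 / 2) * condition_shift

where ``z`` is a standard-normal per-cell latent factor shared by every
module with the same ``latent_factor_id``.  The ``- loading^2 / 2`` term
keeps the module's marginal mean independent of its loading, so loadings
steer correlations without shifting expression.  Modules sharing a factor
with same-sign loadings have positively correlated percentage scores;
opposite signs give negative correlation; condition-specific loading
overrides plant correlation flips between conditions.

The planted inter-module score correlation has no closed form at NB noise
levels, so it is defined operationally: the generator simulates a large
Monte-Carlo batch of cells per condition (``planted_mc_cells``) and stores
the resulting pairwise Pearson r values in the :class:`PlantedTruth` ledger.
Pairs with no shared factor (or a zero effective loading) are exactly 0 by
construction and skip the Monte Carlo.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError
from .matrix_io import CountMatrix, write_annotation, write_mtx

logger = logging.getLogger(__name__)

# fixed sub-seed tags so the independent RNG streams never collide
_SEED_GENES = 11
_SEED_CLUSTERS = 13
_SEED_COUNTS = 17
_SEED_PLANTED = 23


@dataclass
class ModuleSpec:
    """A gene module driven by a per-cell latent factor."""

    name: str
    n_genes: int
    loading: float = 0.0
    latent_factor_id: str | None = None
    condition_mean_shift: dict = field(default_factory=dict)
    condition_loading: dict = field(default_factory=dict)
    gene_names: list | None = None  # optional explicit symbols, len == n_genes

    def effective_loading(self, condition: str) -> float:
        return float(self.condition_loading.get(condition, self.loading))

    def mean_shift(self, condition: str) -> float:
        return float(self.condition_mean_shift.get(condition, 1.0))


@dataclass
class SyntheticConfig:
    n_genes: int
    n_cells_per_cluster: dict
    conditions: list
    baseline_mean: float = 2.0
    dispersion: float = 2.0        # NB size; variance = mu + mu^2 / size
    libsize_sigma: float = 0.25
    mito_genes: int = 10
    mito_fraction: float = 0.05
    modules: list = field(default_factory=list)
    seed: int = 0
    gene_sigma: float = 0.4        # log-normal spread of per-gene baseline factors
    cluster_sigma: float = 0.0     # per-cluster perturbation of background genes
    planted_mc_cells: int = 8000   # Monte-Carlo batch for planted correlations

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if not self.n_cells_per_cluster:
            raise ConfigError("need at least one cluster")
        for name, n in self.n_cells_per_cluster.items():
            if n <= 0:
                raise ConfigError(f"cluster {name!r} has {n} cells; must be positive")
        if not self.conditions:
            raise ConfigError("need at least one condition")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ConfigError("baseline_mean and dispersion must be positive")
        if self.libsize_sigma < 0 or self.gene_sigma < 0 or self.cluster_sigma < 0:
            raise ConfigError("sigmas must be nonnegative")
        if not 0.0 <= self.mito_fraction < 1.0:
            raise ConfigError("mito_fraction must be in [0, 1)")
        if self.mito_genes < 0:
            raise ConfigError("mito_genes must be nonnegative")
        if self.mito_fraction > 0 and self.mito_genes == 0:
            raise ConfigError("mito_fraction > 0 requires mito_genes > 0")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate module names")
        n_module_genes = 0
        seen_genes: set = set()
        for m in self.modules:
            if m.n_genes <= 0:
                raise ConfigError(f"module {m.name!r}: n_genes must be positive")
            if m.gene_names is not None:
                if len(m.gene_names) != m.n_genes:
                    raise ConfigError(f"module {m.name!r}: gene_names length mismatch")
                overlap = seen_genes & set(m.gene_names)
                if overlap:
                    raise ConfigError(f"module gene sets overlap: {sorted(overlap)}")
                seen_genes |= set(m.gene_names)
            n_module_genes += m.n_genes
            for cond in list(m.condition_mean_shift) + list(m.condition_loading):
                if cond not in self.conditions:
                    raise ConfigError(
                        f"module {m.name!r}: unknown condition {cond!r} in override"
                    )
        if n_module_genes + self.mito_genes > self.n_genes:
            raise ConfigError("module + mito genes exceed n_genes")

    def module(self, name: str) -> ModuleSpec:
        for m in self.modules:
            if m.name == name:
                return m
        raise ConfigError(f"unknown module {name!r}")


class GeneLayout(NamedTuple):
    names: list
    module_slices: dict   # module name -> slice of gene rows
    mito_rows: np.ndarray
    background_rows: np.ndarray


def _gene_layout(config: SyntheticConfig) -> GeneLayout:
    names: list[str] = []
    module_slices: dict[str, slice] = {}
    for m in config.modules:
        start = len(names)
        if m.gene_names is not None:
            names.extend(m.gene_names)
        else:
            names.extend(f"{m.name}_g{j + 1:02d}" for j in range(m.n_genes))
        module_slices[m.name] = slice(start, len(names))
    mito_start = len(names)
    names.extend(f"mt-Sim{j + 1}" for j in range(config.mito_genes))
    mito_rows = np.arange(mito_start, len(names))
    bg_start = len(names)
    names.extend(f"G{j + 1:05d}" for j in range(config.n_genes - len(names)))
    background_rows = np.arange(bg_start, len(names))
    if len(set(names)) != len(names):
        raise ConfigError("gene names collide (module gene_names vs generated names)")
    return GeneLayout(names, module_slices, mito_rows, background_rows)


def _gene_factors(config: SyntheticConfig, layout: GeneLayout) -> np.ndarray:
    """Per-gene mean multipliers; mito factors rescaled to hit mito_fraction."""
    rng = np.random.default_rng([config.seed, _SEED_GENES])
    s = config.gene_sigma
    gf = np.exp(rng.normal(-s * s / 2.0, s, config.n_genes)) if s > 0 else np.ones(config.n_genes)
    mito = np.zeros(config.n_genes, dtype=bool)
    mito[layout.mito_rows] = True
    if config.mito_genes > 0:
        e_nonmito = gf[~mito].sum()
        f = config.mito_fraction
        target_mito = f / (1.0 - f) * e_nonmito
        current = gf[mito].sum()
        gf[mito] *= target_mito / current if current > 0 else 0.0
    return gf


def _cell_layout(config: SyntheticConfig) -> pd.DataFrame:
    """Barcode / cluster / condition assignment; conditions split per cluster."""
    rows = []
    i = 0
    for cluster, n in config.n_cells_per_cluster.items():
        conds = np.concatenate([
            np.full(len(chunk), ci)
            for ci, chunk in enumerate(np.array_split(np.arange(n), len(config.conditions)))
        ])
        for j in range(n):
            rows.append({
                "barcode": f"C{i + 1:06d}",
                "cluster": cluster,
                "condition": config.conditions[int(conds[j])],
            })
            i += 1
    df = pd.DataFrame(rows).set_index("barcode")
    df["sample"] = df["condition"] + "_s1"
    return df


def _factor_ids(config: SyntheticConfig) -> list:
    seen = []
    for m in config.modules:
        if m.latent_factor_id is not None and m.latent_factor_id not in seen:
            seen.append(m.latent_factor_id)
    return seen


def _simulate(
    config: SyntheticConfig,
    layout: GeneLayout,
    gf: np.ndarray,
    cell_conditions: np.ndarray,
    rng: np.random.Generator,
    cluster_mult: np.ndarray | None = None,
    cluster_idx: np.ndarray | None = None,
) -> tuple:
    """Draw one NB count matrix.  Returns (counts, lib_factors, z_matrix)."""
    n_cells = cell_conditions.size
    if config.libsize_sigma > 0:
        s = config.libsize_sigma
        lib = np.exp(rng.normal(-s * s / 2.0, s, n_cells))
    else:
        lib = np.ones(n_cells)
    fids = _factor_ids(config)
    z = rng.standard_normal((len(fids), n_cells)) if fids else np.zeros((0, n_cells))
    fid_row = {f: i for i, f in enumerate(fids)}

    mean = config.baseline_mean * gf[:, None] * lib[None, :]
    if cluster_mult is not None and cluster_idx is not None:
        bg = layout.background_rows
        mean[bg, :] *= cluster_mult[:, bg].T[:, cluster_idx]

    # per-cell effective loading / shift vectors, resolved per condition once
    for m in config.modules:
        rows = layout.module_slices[m.name]
        l_eff = np.empty(n_cells)
        shift = np.empty(n_cells)
        for cond in np.unique(cell_conditions):
            mask = cell_conditions == cond
            l_eff[mask] = m.effective_loading(cond)
            shift[mask] = m.mean_shift(cond)
        if m.latent_factor_id is not None:
            zf = z[fid_row[m.latent_factor_id]]
            effect = shift * np.exp(l_eff * zf - 0.5 * l_eff * l_eff)
        else:
            effect = shift
        mean[rows, :] *= effect[None, :]

    size = config.dispersion
    p = size / (size + mean)
    counts = rng.negative_binomial(size, p)
    return counts, lib, z


def _pairwise_planted(
    config: SyntheticConfig, layout: GeneLayout, gf: np.ndarray
) -> dict:
    """Monte-Carlo planted score correlations: {condition: {(a, b): r}}."""
    out: dict[str, dict] = {}
    mod_names = [m.name for m in config.modules]
    for ci, cond in enumerate(config.conditions):
        pairs: dict[tuple, float] = {}
        needs_mc = []
        for i, a in enumerate(mod_names):
            for b in mod_names[i + 1:]:
                ma, mb = config.module(a), config.module(b)
                shared = (
                    ma.latent_factor_id is not None
                    and ma.latent_factor_id == mb.latent_factor_id
                    and ma.effective_loading(cond) != 0.0
                    and mb.effective_loading(cond) != 0.0
                )
                if shared:
                    needs_mc.append((a, b))
                else:
                    pairs[(a, b)] = 0.0
        if needs_mc:
            rng = np.random.default_rng([config.seed, _SEED_PLANTED, ci])
            conds = np.array([cond] * config.planted_mc_cells)
            counts, _, _ = _simulate(config, layout, gf, conds, rng)
            totals = counts.sum(axis=0).astype(float)
            totals[totals == 0] = np.nan
            scores = {
                name: 100.0 * counts[layout.module_slices[name], :].sum(axis=0) / totals
                for name in mod_names
            }
            for a, b in needs_mc:
                sa, sb = scores[a], scores[b]
                ok = np.isfinite(sa) & np.isfinite(sb)
                pairs[(a, b)] = float(np.corrcoef(sa[ok], sb[ok])[0, 1])
        out[cond] = pairs
    return out


@dataclass
class PlantedTruth:
    """The generator's ledger of everything it planted."""

    cells: pd.DataFrame    # barcode-indexed: cluster, condition, lib_factor, z_<factor>...
    genes: pd.DataFrame    # gene-indexed: module ("" = background), mito
    planted: dict          # {condition: {(module_a, module_b): r}}, unordered pairs

    def planted_r(self, module_a: str, module_b: str, condition: str) -> float:
        if module_a == module_b:
            return 1.0
        pairs = self.planted[condition]
        for key in ((module_a, module_b), (module_b, module_a)):
            if key in pairs:
                return pairs[key]
        raise ConfigError(f"no planted pair ({module_a}, {module_b})")

    def module_genes(self, module: str) -> list:
        sel = self.genes[self.genes["module"] == module]
        if not len(sel):
            raise ConfigError(f"unknown module {module!r}")
        return list(sel.index)

    def to_json(self, path) -> None:
        payload = {
            "cells": self.cells.reset_index().to_dict(orient="list"),
            "genes": self.genes.reset_index().to_dict(orient="list"),
            "planted": {
                cond: {f"{a}|{b}": r for (a, b), r in pairs.items()}
                for cond, pairs in self.planted.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        cells = pd.DataFrame(payload["cells"]).set_index("barcode")
        genes = pd.DataFrame(payload["genes"]).set_index("gene")
        planted = {
            cond: {tuple(k.split("|")): v for k, v in pairs.items()}
            for cond, pairs in payload["planted"].items()
        }
        return cls(cells=cells, genes=genes, planted=planted)


class SyntheticResult(NamedTuple):
    matrix: CountMatrix
    annotation: pd.DataFrame
    truth: PlantedTruth


def generate_counts(config: SyntheticConfig) -> SyntheticResult:
    """Generate the count matrix, cell annotation and planted-truth ledger.

    Identical config + seed reproduces the matrix bit-for-bit.
    """
    config.validate()
    layout = _gene_layout(config)
    gf = _gene_factors(config, layout)

    cluster_names = list(config.n_cells_per_cluster)
    cluster_mult = None
    if config.cluster_sigma > 0:
        crng = np.random.default_rng([config.seed, _SEED_CLUSTERS])
        s = config.cluster_sigma
        cluster_mult = np.exp(
            crng.normal(-s * s / 2.0, s, (len(cluster_names), config.n_genes))
        )

    ann = _cell_layout(config)
    cluster_idx = np.array([cluster_names.index(c) for c in ann["cluster"]])
    rng = np.random.default_rng([config.seed, _SEED_COUNTS])
    counts, lib, z = _simulate(
        config, layout, gf, ann["condition"].to_numpy(), rng,
        cluster_mult=cluster_mult, cluster_idx=cluster_idx,
    )

    matrix = CountMatrix(
        genes=layout.names, cells=list(ann.index), counts=sp.csr_matrix(counts)
    )

    gene_module = np.array([""] * config.n_genes, dtype=object)
    for name, sl in layout.module_slices.items():
        gene_module[sl] = name
    genes_df = pd.DataFrame({
        "gene": layout.names,
        "module": gene_module,
        "mito": matrix.mito_mask,
    }).set_index("gene")

    cells_df = ann.drop(columns=["sample"]).copy()
    cells_df["lib_factor"] = lib
    for i, fid in enumerate(_factor_ids(config)):
        cells_df[f"z_{fid}"] = z[i]

    truth = PlantedTruth(
        cells=cells_df,
        genes=genes_df,
        planted=_pairwise_planted(config, layout, gf),
    )
    return SyntheticResult(matrix=matrix, annotation=ann, truth=truth)


def planted_correlation(
    config: SyntheticConfig, module_a: str, module_b: str, condition: str
) -> float:
    """The generator's target score correlation for one module pair.

    Exactly 0.0 when the modules share no latent factor (or an effective
    loading is 0); otherwise the stored Monte-Carlo limit.
    """
    config.validate()
    ma, mb = config.module(module_a), config.module(module_b)
    if condition not in config.conditions:
        raise ConfigError(f"unknown condition {condition!r}")
    if (
        ma.latent_factor_id is None
        or ma.latent_factor_id != mb.latent_factor_id
        or ma.effective_loading(condition) == 0.0
        or mb.effective_loading(condition) == 0.0
    ):
        return 0.0
    layout = _gene_layout(config)
    gf = _gene_factors(config, layout)
    planted = _pairwise_planted(config, layout, gf)
    key = (module_a, module_b) if (module_a, module_b) in planted[condition] else (module_b, module_a)
    return planted[condition][key]


def write_synthetic(result: SyntheticResult, out_dir) -> None:
    """Emit the MTX triplet, annotation TSV and the truth JSON ledger."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mtx(result.matrix, out_dir)
    write_annotation(result.annotation, out_dir / "annotation.tsv")
    result.truth.to_json(out_dir / "planted_truth.json")
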