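"""Ready-made synthetic configurations used by tests, demos and acceptance runs.

Loadings here are calibrated only so that screens pass/fail informatively at
desk scale (no real-data effect sizes are available to match); the planted
truth recorded by the generator, not the nominal value, is always the oracle.
"""

from __future__ import annotations

from .synthetic import ModuleSpec, SyntheticConfig

#: loading values (equal on both modules of a pair) that land the planted
#: percentage-score correlation close to the named nominal value, for
#: 25-gene modules at baseline_mean=2, dispersion=2 (calibrated by MC).
PAIR_LOADINGS = {
    0.3: 0.150,
    0.6: 0.277,
    0.7: 0.342,
    0.9: 0.710,
}


def correlation_recovery_config(seed: int, n_cells: int = 800) -> SyntheticConfig:
    """Six independent module pairs planted near rho = -0.6 .. 0.9."""
    nominal = [-0.6, -0.3, 0.0, 0.3, 0.6, 0.9]
    modules = []
    for i, rho in enumerate(nominal):
        l = PAIR_LOADINGS[round(abs(rho), 1)] if rho != 0 else 0.0
        fid = f"f{i}" if rho != 0 else None
        sign = -1.0 if rho < 0 else 1.0
        modules.append(ModuleSpec(
            name=f"A{i}", n_genes=25, loading=l, latent_factor_id=fid))
        modules.append(ModuleSpec(
            name=f"B{i}", n_genes=25, loading=sign * l,
            latent_factor_id=fid if rho != 0 else None))
    return SyntheticConfig(
        n_genes=1000,
        n_cells_per_cluster={"Lc": n_cells},
        conditions=["Nt"],
        modules=modules,
        seed=seed,
    )


def recovery_pairs() -> list:
    """(module_a, module_b, nominal_rho) triples for the recovery config."""
    return [(f"A{i}", f"B{i}", rho)
            for i, rho in enumerate([-0.6, -0.3, 0.0, 0.3, 0.6, 0.9])]


def screen_demo_config(seed: int, n_cells: int = 800) -> SyntheticConfig:
    """A target signature and candidates planted near {0.7, 0.0, -0.6}."""
    modules = [
        ModuleSpec(name="Target", n_genes=25, loading=PAIR_LOADINGS[0.7],
                   latent_factor_id="f_pos"),
        ModuleSpec(name="CandPos", n_genes=25, loading=PAIR_LOADINGS[0.7],
                   latent_factor_id="f_pos"),
        ModuleSpec(name="CandNull", n_genes=25, loading=0.0),
        ModuleSpec(name="CandNeg", n_genes=25, loading=-PAIR_LOADINGS[0.6],
                   latent_factor_id="f_pos"),
    ]
    return SyntheticConfig(
        n_genes=800,
        n_cells_per_cluster={"Lc": n_cells},
        conditions=["Nt"],
        modules=modules,
        seed=seed,
    )


def null_pairs_config(seed: int, n_modules: int = 15, n_cells: int = 800) -> SyntheticConfig:
    """Independent low-abundance modules: every pairwise correlation planted 0.

    Modules are kept tiny (3 genes in 1500) so the shared compositional
    denominator contributes negligible negative correlation between scores.
    """
    modules = [ModuleSpec(name=f"M{i:02d}", n_genes=3, loading=0.0)
               for i in range(n_modules)]
    return SyntheticConfig(
        n_genes=1500,
        n_cells_per_cluster={"Lc": n_cells},
        conditions=["Nt"],
        modules=modules,
        seed=seed,
    )


def tf_screen_config(seed: int, n_cells: int = 500) -> SyntheticConfig:
    """A planted regulator driving a target gene through a shared factor.

    ``Tfreg1`` is the true regulator; ``Hmgb4`` is planted equally correlated
    to probe the exclusion rule; ``Lowtf`` is correlated but expressed too low
    to pass the mean-expression filter.
    """
    single = dict(n_genes=1, loading=1.0, latent_factor_id="freg")
    modules = [
        ModuleSpec(name="Star", gene_names=["Star"],
                   condition_mean_shift={"Nt": 10.0}, **single),
        ModuleSpec(name="Tfreg1", gene_names=["Tfreg1"],
                   condition_mean_shift={"Nt": 10.0}, **single),
        ModuleSpec(name="Hmgb4", gene_names=["Hmgb4"],
                   condition_mean_shift={"Nt": 10.0}, **single),
        ModuleSpec(name="Spz1", gene_names=["Spz1"],
                   condition_mean_shift={"Nt": 10.0}, **single),
        ModuleSpec(name="Tfam", gene_names=["Tfam"],
                   condition_mean_shift={"Nt": 10.0}, **single),
        ModuleSpec(name="Lowtf", gene_names=["Lowtf"],
                   condition_mean_shift={"Nt": 0.03}, **single),
    ]
    return SyntheticConfig(
        n_genes=200,
        n_cells_per_cluster={"Lc": n_cells},
        conditions=["Nt"],
        modules=modules,
        seed=seed,
        planted_mc_cells=2000,
    )


def tf_universe(config: SyntheticConfig, n_background: int = 100) -> list:
    """The planted TFs plus the first background genes as decoy TFs."""
    planted = ["Tfreg1", "Hmgb4", "Spz1", "Tfam", "Lowtf"]
    return planted + [f"G{j + 1:05d}" for j in range(n_background)]


def shift_flip_config(seed: int, n_cells_per_condition: int = 800) -> SyntheticConfig:
    """Planted sign flip: r(Target, Flip) > 0 in Nt, < 0 in O50t."""
    l = PAIR_LOADINGS[0.6]
    modules = [
        ModuleSpec(name="Target", n_genes=25, loading=l, latent_factor_id="f"),
        ModuleSpec(name="Flip", n_genes=25, loading=l, latent_factor_id="f",
                   condition_loading={"O50t": -l}),
        ModuleSpec(name="Stable", n_genes=25, loading=l, latent_factor_id="f"),
    ]
    return SyntheticConfig(
        n_genes=800,
        n_cells_per_cluster={"Lc": 2 * n_cells_per_condition},
        conditions=["Nt", "O50t"],
        modules=modules,
        seed=seed,
    )


def de_power_config(seed: int, n_cells_per_group: int = 300,
                    shift: float = 2.0) -> SyntheticConfig:
    """A 100-gene module with a planted mean shift in condition O50t."""
    modules = [ModuleSpec(name="Shifted", n_genes=100, loading=0.0,
                          condition_mean_shift={"O50t": shift})]
    return SyntheticConfig(
        n_genes=500,
        n_cells_per_cluster={"Lc": 2 * n_cells_per_group},
        conditions=["Nt", "O50t"],
        modules=modules,
        seed=seed,
    )


def de_null_config(seed: int, n_cells_per_group: int = 150) -> SyntheticConfig:
    """No condition effect anywhere: every rejection is a type-I error."""
    return SyntheticConfig(
        n_genes=300,
        n_cells_per_cluster={"Lc": 2 * n_cells_per_group},
        conditions=["Nt", "O50t"],
        seed=seed,
    )


def enrichment_corr_config(seed: int, n_cells: int = 200,
                           loading: float = 0.65) -> SyntheticConfig:
    """A 50-gene co-expressed set (shared factor), no condition effect.

    The loading targets a mean pairwise normalized-expression correlation
    around 0.2 inside the set.
    """
    modules = [ModuleSpec(name="CorrSet", n_genes=50, loading=loading,
                          latent_factor_id="f")]
    return SyntheticConfig(
        n_genes=500,
        n_cells_per_cluster={"Lc": n_cells},
        conditions=["Nt", "O50t"],
        modules=modules,
        seed=seed,
    )


def lr_null_config(seed: int, n_cells_per_cluster: int = 150,
                   n_genes: int = 450) -> SyntheticConfig:
    """Two clusters, uniform expression: every ligand-receptor pair is null."""
    return SyntheticConfig(
        n_genes=n_genes,
        n_cells_per_cluster={"Lc": n_cells_per_cluster, "Im": n_cells_per_cluster},
        conditions=["Nt"],
        seed=seed,
    )


def demo_config(seed: int = 0) -> SyntheticConfig:
    """Small end-to-end demo: clusters, conditions, correlated signatures."""
    l = PAIR_LOADINGS[0.6]
    modules = [
        ModuleSpec(name="Senescence_like", n_genes=10, loading=l,
                   latent_factor_id="f", condition_mean_shift={"O50t": 1.5}),
        ModuleSpec(name="Androgen_like", n_genes=10, loading=-l,
                   latent_factor_id="f"),
        ModuleSpec(name="Collagen_like", n_genes=10, loading=l,
                   latent_factor_id="f", condition_mean_shift={"O50t": 2.0}),
    ]
    return SyntheticConfig(
        n_genes=600,
        n_cells_per_cluster={"Lc": 400, "Sg": 200, "Im": 200},
        conditions=["Nt", "O50t"],
        modules=modules,
        seed=seed,
        cluster_sigma=0.3,
        planted_mc_cells=4000,
    )
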