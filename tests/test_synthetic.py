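import json

import numpy as np
import pytest

from sigcorr.errors import ConfigError
from sigcorr.matrix_io import read_mtx
from sigcorr.qc import percent_mt
from sigcorr.synthetic import (
    ModuleSpec,
    PlantedTruth,
    SyntheticConfig,
    generate_counts,
    planted_correlation,
    write_synthetic,
)


def basic_config(seed=0, **kw):
    defaults = dict(
        n_genes=300,
        n_cells_per_cluster={"Lc": 200},
        conditions=["Nt"],
        seed=seed,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_zero_cell_cluster_rejected(self):
        with pytest.raises(ConfigError, match="cells"):
            basic_config(n_cells_per_cluster={"Lc": 0}).validate()

    def test_overlapping_module_genes_rejected(self):
        cfg = basic_config(modules=[
            ModuleSpec("A", 2, gene_names=["x", "y"]),
            ModuleSpec("B", 2, gene_names=["y", "z"]),
        ])
        with pytest.raises(ConfigError, match="overlap"):
            cfg.validate()

    def test_mito_fraction_bounds(self):
        with pytest.raises(ConfigError, match="mito_fraction"):
            basic_config(mito_fraction=1.0).validate()

    def test_unknown_condition_in_override_rejected(self):
        cfg = basic_config(modules=[
            ModuleSpec("A", 2, condition_mean_shift={"O50t": 2.0}),
        ])
        with pytest.raises(ConfigError, match="unknown condition"):
            cfg.validate()

    def test_too_many_module_genes_rejected(self):
        cfg = basic_config(n_genes=10, modules=[ModuleSpec("A", 20)])
        with pytest.raises(ConfigError, match="exceed"):
            cfg.validate()

    def test_unknown_module_name(self):
        cfg = basic_config()
        with pytest.raises(ConfigError, match="unknown module"):
            planted_correlation(cfg, "A", "B", "Nt")


class TestDeterminism:
    def test_identical_mtx_bytes(self, tmp_path):
        cfg = basic_config(seed=7, modules=[ModuleSpec("A", 5, 0.3, "f"),
                                            ModuleSpec("B", 5, 0.3, "f")],
                           planted_mc_cells=500)
        for sub in ("run1", "run2"):
            write_synthetic(generate_counts(cfg), tmp_path / sub)
        for name in ("matrix.mtx", "features.tsv", "barcodes.tsv",
                     "annotation.tsv", "planted_truth.json"):
            assert (tmp_path / "run1" / name).read_bytes() == \
                   (tmp_path / "run2" / name).read_bytes(), name

    def test_different_seed_differs(self):
        a = generate_counts(basic_config(seed=1))
        b = generate_counts(basic_config(seed=2))
        assert (a.matrix.counts != b.matrix.counts).nnz > 0

    def test_every_cell_and_gene_once(self):
        res = generate_counts(basic_config(seed=3))
        assert sorted(res.truth.cells.index) == sorted(res.matrix.cells)
        assert sorted(res.truth.genes.index) == sorted(res.matrix.genes)

    def test_round_trips_through_mtx(self, tmp_path):
        res = generate_counts(basic_config(seed=4))
        write_synthetic(res, tmp_path)
        back = read_mtx(tmp_path)
        assert (back.counts != res.matrix.counts).nnz == 0


class TestNBMoments:
    def test_gene_means_match_closed_form(self):
        """No modules, flat gene factors, no library spread: empirical gene
        means over 20 replicate seeds must sit within 3 MC standard errors of
        the NB closed-form mean (and mito genes of their calibrated mean)."""
        n_cells, n_rep = 300, 20
        sums = None
        for seed in range(n_rep):
            cfg = basic_config(
                seed=seed, n_genes=100, n_cells_per_cluster={"Lc": n_cells},
                libsize_sigma=0.0, gene_sigma=0.0, mito_genes=5, mito_fraction=0.05,
                baseline_mean=2.0, dispersion=2.0,
            )
            counts = generate_counts(cfg).matrix.counts.toarray()
            sums = counts.sum(axis=1) + (sums if sums is not None else 0)
        emp_mean = sums / (n_cells * n_rep)
        # expected: background mean = 2.0; the 5 mito genes share
        # f/(1-f) * sum(non-mito) of expression -> each 2.0 * (0.05/0.95) * 95/5
        expected = np.full(100, 2.0)
        res = generate_counts(basic_config(
            seed=0, n_genes=100, libsize_sigma=0.0, gene_sigma=0.0,
            mito_genes=5, mito_fraction=0.05))
        is_mito = res.matrix.mito_mask
        expected[is_mito] = 2.0 * (0.05 / 0.95) * 95 / 5
        var = expected + expected ** 2 / 2.0
        se = np.sqrt(var / (n_cells * n_rep))
        dev = np.abs(emp_mean - expected)
        # ~0.3% of genes are expected beyond 3 SE by chance; none beyond 4.5
        assert np.mean(dev <= 3 * se) >= 0.95
        assert np.all(dev <= 4.5 * se)

    def test_variance_matches_nb(self):
        cfg = basic_config(seed=5, n_genes=50, n_cells_per_cluster={"Lc": 2000},
                           libsize_sigma=0.0, gene_sigma=0.0, mito_genes=0,
                           mito_fraction=0.0, baseline_mean=3.0, dispersion=2.0)
        counts = generate_counts(cfg).matrix.counts.toarray()
        emp_var = counts.var(axis=1, ddof=1)
        expected_var = 3.0 + 9.0 / 2.0
        # chi-square-ish spread: allow 20% relative wobble at n=2000
        assert np.all(np.abs(emp_var - expected_var) / expected_var < 0.25)


class TestPlantedCorrelation:
    def shared_cfg(self, la, lb, seed=0, **kw):
        return basic_config(
            seed=seed,
            n_genes=400,
            modules=[ModuleSpec("A", 20, la, "f"), ModuleSpec("B", 20, lb, "f")],
            planted_mc_cells=6000,
            **kw,
        )

    def test_no_shared_factor_is_exactly_zero(self):
        cfg = basic_config(modules=[ModuleSpec("A", 5, 0.5, "f1"),
                                    ModuleSpec("B", 5, 0.5, "f2")])
        assert planted_correlation(cfg, "A", "B", "Nt") == 0.0

    def test_zero_loading_is_exactly_zero(self):
        cfg = basic_config(modules=[ModuleSpec("A", 5, 0.0, "f"),
                                    ModuleSpec("B", 5, 0.5, "f")])
        assert planted_correlation(cfg, "A", "B", "Nt") == 0.0

    def test_positive_and_monotone_in_loading(self):
        rs = [planted_correlation(self.shared_cfg(l, l), "A", "B", "Nt")
              for l in (0.15, 0.35, 0.7)]
        assert all(0 < r <= 1 for r in rs)
        assert rs[0] < rs[1] < rs[2]

    def test_opposite_sign_loadings_mirror(self):
        pos = planted_correlation(self.shared_cfg(0.35, 0.35), "A", "B", "Nt")
        neg = planted_correlation(self.shared_cfg(0.35, -0.35), "A", "B", "Nt")
        assert neg < 0
        assert abs(abs(neg) - pos) < 0.05

    def test_condition_loading_flips_sign(self):
        cfg = basic_config(
            conditions=["Nt", "O50t"],
            n_genes=400,
            modules=[
                ModuleSpec("A", 20, 0.35, "f"),
                ModuleSpec("B", 20, 0.35, "f", condition_loading={"O50t": -0.35}),
            ],
            planted_mc_cells=4000,
        )
        r_nt = planted_correlation(cfg, "A", "B", "Nt")
        r_o = planted_correlation(cfg, "A", "B", "O50t")
        assert r_nt > 0 > r_o

    def test_recovered_r_in_fisher_interval_of_planted(self):
        cfg = self.shared_cfg(0.35, 0.35, seed=2,
                              n_cells_per_cluster={"Lc": 800})
        res = generate_counts(cfg)
        planted = res.truth.planted_r("A", "B", "Nt")
        counts = res.matrix.counts.toarray()
        mod_a = [res.matrix.genes.index(g) for g in res.truth.module_genes("A")]
        mod_b = [res.matrix.genes.index(g) for g in res.truth.module_genes("B")]
        totals = counts.sum(axis=0)
        sa = 100.0 * counts[mod_a].sum(axis=0) / totals
        sb = 100.0 * counts[mod_b].sum(axis=0) / totals
        r_hat = np.corrcoef(sa, sb)[0, 1]
        assert r_hat > 0
        z_gap = abs(np.arctanh(r_hat) - np.arctanh(planted))
        assert z_gap < 2.576 / np.sqrt(800 - 3)

    def test_opposite_sign_recovery_mirrors(self):
        cfg = self.shared_cfg(0.35, -0.35, seed=2, n_cells_per_cluster={"Lc": 800})
        res = generate_counts(cfg)
        assert res.truth.planted_r("A", "B", "Nt") < 0


class TestMitoAndTruth:
    def test_mean_mito_percent_near_target(self):
        cfg = basic_config(seed=8, n_cells_per_cluster={"Lc": 800},
                           mito_genes=10, mito_fraction=0.10)
        res = generate_counts(cfg)
        mean_pct = percent_mt(res.matrix).mean()
        assert abs(mean_pct - 10.0) <= 2.0

    def test_truth_json_round_trip(self, tmp_path):
        cfg = basic_config(seed=9, modules=[ModuleSpec("A", 5, 0.4, "f"),
                                            ModuleSpec("B", 5, 0.4, "f")],
                           planted_mc_cells=500)
        res = generate_counts(cfg)
        path = tmp_path / "truth.json"
        res.truth.to_json(path)
        back = PlantedTruth.from_json(path)
        assert back.planted_r("A", "B", "Nt") == pytest.approx(
            res.truth.planted_r("A", "B", "Nt"))
        assert list(back.cells.index) == list(res.truth.cells.index)
        json.loads(path.read_text())  # stays valid JSON

    def test_recovery_error_shrinks_with_n(self):
        """Median |r_hat - planted| over seeds decreases as n grows."""
        med_err = []
        for n in (200, 800, 3200):
            errs = []
            for seed in range(6):
                cfg = basic_config(
                    seed=seed, n_genes=300, n_cells_per_cluster={"Lc": n},
                    modules=[ModuleSpec("A", 20, 0.3, "f"),
                             ModuleSpec("B", 20, 0.3, "f")],
                    planted_mc_cells=6000,
                )
                res = generate_counts(cfg)
                counts = res.matrix.counts.toarray()
                totals = counts.sum(axis=0)
                idx = {m: [res.matrix.genes.index(g)
                           for g in res.truth.module_genes(m)] for m in "AB"}
                sa = 100.0 * counts[idx["A"]].sum(axis=0) / totals
                sb = 100.0 * counts[idx["B"]].sum(axis=0) / totals
                errs.append(abs(np.corrcoef(sa, sb)[0, 1]
                                - res.truth.planted_r("A", "B", "Nt")))
            med_err.append(np.median(errs))
        assert med_err[2] < med_err[0]
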