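"""Power-study machinery: effects, injection, thresholds, regions, windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pedgwas as pg
from pedgwas.power import (
    MAF_CLASSES,
    SimulationConfig,
    _window_min_p,
    QTLRecord,
    eligible_qtl_snps,
    run_power_grid,
)
from pedgwas.popsim import Pedigree


class TestQTLEffect:
    def test_worked_values(self):
        rng = np.random.default_rng(0)
        assert abs(pg.qtl_effect(0.5, 0.125, rng)) == pytest.approx(0.5)
        assert abs(pg.qtl_effect(0.1, 0.05, rng)) == pytest.approx(
            np.sqrt(0.05 / 0.18)
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0.01, 0.99), st.floats(0.001, 0.3))
    def test_variance_identity(self, p, h2):
        beta = pg.qtl_effect(p, h2, np.random.default_rng(1))
        assert 2 * p * (1 - p) * beta**2 == pytest.approx(h2, rel=1e-9)

    def test_both_signs_occur(self):
        rng = np.random.default_rng(2)
        signs = {np.sign(pg.qtl_effect(0.4, 0.05, rng)) for _ in range(50)}
        assert signs == {-1.0, 1.0}

    def test_invalid_inputs(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            pg.qtl_effect(0.0, 0.05, rng)
        with pytest.raises(ValueError):
            pg.qtl_effect(0.5, 0.0, rng)


class TestBasePhenotype:
    def test_zero_heritability_pure_noise(self):
        ped = pg.generate_pedigree([(5, 5), (10, 10)], seed=4)
        F = np.zeros(ped.n)
        y, u, e = pg.simulate_base_phenotype(ped, F, h2=0.0, seed=0,
                                             return_components=True)
        assert np.allclose(u, 0.0)
        assert np.allclose(y, e)

    def test_mendelian_sampling_variance_full_sibs(self):
        # one non-inbred pair with 10,000 offspring: Var(u - midparent) = 0.5 s2u
        rows = [("s", "0", "0", "male", 1), ("d", "0", "0", "female", 1)]
        rows += [(f"o{i}", "s", "d", "male", 2) for i in range(10_000)]
        ped = Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation"]))
        F = np.zeros(ped.n)
        _, u, _ = pg.simulate_base_phenotype(ped, F, h2=0.30, seed=5,
                                             return_components=True)
        dev = u[2:] - 0.5 * (u[0] + u[1])
        expected = 0.5 * 0.30
        assert dev.var() == pytest.approx(expected, rel=0.05)

    def test_fully_inbred_parents_no_sampling_variance(self):
        rows = [("s", "0", "0", "male", 1), ("d", "0", "0", "female", 1)]
        rows += [(f"o{i}", "s", "d", "male", 2) for i in range(100)]
        ped = Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation"]))
        F = np.concatenate([[1.0, 1.0], np.zeros(100)])
        _, u, _ = pg.simulate_base_phenotype(ped, F, h2=0.30, seed=6,
                                             return_components=True)
        assert np.allclose(u[2:], 0.5 * (u[0] + u[1]))

    def test_heritability_structure(self):
        ped = pg.generate_pedigree(seed=7)
        F = pg.inbreeding_meuwissen_luo(ped)
        y, u, e = pg.simulate_base_phenotype(ped, F, seed=8, return_components=True)
        assert y == pytest.approx(u + e)
        assert 0.15 < u.var() < 0.50 and 0.55 < e.var() < 0.90


class TestInjectQTL:
    def test_qtl_drawn_from_requested_class(self, population, hmm):
        panel = hmm["imputed"]
        for maf_class, (lo, hi) in MAF_CLASSES.items():
            idx = eligible_qtl_snps(panel, maf_class)
            maf = panel.maf()[idx]
            assert ((maf >= lo) & (maf <= hi)).all() and len(idx) > 10

    def test_injected_variance_tracks_qtl_h2(self, population, hmm):
        panel = hmm["imputed"]
        n = panel.n_animals
        u = np.zeros(n)
        contrib = []
        for s in range(60):
            y_new, rec = pg.inject_qtl(np.zeros(n), u, panel, "high", 0.05, seed=s)
            w = panel.dosage[:, rec.snp_idx].astype(float)
            contrib.append(np.var(rec.beta * w))
        # relatedness inflates realised dosage variance above 2p(1-p)
        assert 0.5 * 0.05 < np.mean(contrib) < 2.5 * 0.05

    def test_empty_class_raises(self):
        mmap = pd.DataFrame({"snp_id": ["a"], "chrom": 1, "pos_bp": [100],
                             "ref": "A", "alt": "B"})
        panel = pg.GenotypePanel(["x", "y"], mmap, np.array([[1], [1]], dtype=np.int8))
        with pytest.raises(ValueError):
            pg.inject_qtl(np.zeros(2), np.zeros(2), panel, "low", 0.05, seed=0)

    def test_additive_mode_literal(self, population, hmm):
        panel = hmm["imputed"]
        n = panel.n_animals
        y0 = np.random.default_rng(9).standard_normal(n)
        y_new, rec = pg.inject_qtl(y0, np.zeros(n), panel, "high", 0.05, seed=1,
                                   mode="additive")
        w = panel.dosage[:, rec.snp_idx].astype(float)
        assert np.allclose(y_new, y0 + rec.beta * w)


class TestBonferroni:
    def test_panel_size_threshold(self):
        thr = pg.bonferroni_threshold(38_128)
        assert f"{thr:.2e}" == "1.31e-06"

    def test_trivial_values(self):
        assert pg.bonferroni_threshold(1) == 0.05
        assert pg.bonferroni_threshold(1000, alpha=0.01) == pytest.approx(1e-5)

    def test_invalid(self):
        with pytest.raises(ValueError):
            pg.bonferroni_threshold(0)


def _brute_force_regions(snps, merge_dist):
    """Single-linkage clustering oracle over (pos, p) pairs on one chromosome."""
    snps = sorted(snps)
    clusters, cur = [], [snps[0]]
    for s in snps[1:]:
        if s[0] - cur[-1][0] <= merge_dist:
            cur.append(s)
        else:
            clusters.append(cur)
            cur = [s]
    clusters.append(cur)
    return [(c[0][0], c[-1][0], min(x[1] for x in c)) for c in clusters]


class TestCallRegions:
    def _scan(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos_bp", "snp_id", "p"])

    def test_no_hits_empty(self):
        scan = self._scan([(1, 100, "a", 0.5), (1, 200, "b", 0.9)])
        assert pg.call_regions(scan).empty

    def test_merge_rule(self):
        base = [(1, 1_000_000, "a", 1e-8)]
        one = pg.call_regions(self._scan(base + [(1, 1_800_000, "b", 1e-7)]))
        two = pg.call_regions(self._scan(base + [(1, 2_200_000, "b", 1e-7)]))
        assert len(one) == 1 and len(two) == 2

    def test_levels(self):
        scan = self._scan([(1, 100, "a", 1e-8), (2, 100, "b", 1e-5)])
        res = pg.call_regions(scan).set_index("top_snp")
        assert res.loc["a", "level"] == "significant"
        assert res.loc["b", "level"] == "suggestive"

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_clustering_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=n, replace=False))
        p = 10.0 ** rng.uniform(-9, -1, size=n)
        scan = self._scan([(1, int(pos[i]), f"s{i}", p[i]) for i in range(n)])
        res = pg.call_regions(scan)
        hits = [(int(pos[i]), p[i]) for i in range(n) if p[i] < 5e-5]
        if not hits:
            assert res.empty
            return
        oracle = _brute_force_regions(hits, 1_000_000)
        assert len(res) == len(oracle)
        for (start, end, top_p), (_, row) in zip(oracle, res.iterrows()):
            assert row["start"] == start and row["end"] == end
            assert row["top_p"] == pytest.approx(top_p)


@pytest.fixture(scope="module")
def tiny_inputs(small_population):
    pop = small_population
    _, dosages, imputed = pg.fit_haplotype_hmm(pop["panel"], K=4, n_em_iter=4, seed=0)
    return pop, dosages, imputed


class TestPowerGrid:
    def test_threshold_extremes(self, tiny_inputs):
        pop, dosages, imputed = tiny_inputs
        for thr, expected in ((1.5, 1.0), (0.0, 0.0)):
            cfg = SimulationConfig(
                qtl_h2_grid=(0.05,), maf_classes=("high",), methods=("snp",),
                n_replicates=4, genomewide_p=thr, seed=0,
            )
            grid = run_power_grid(cfg, imputed, pop["pedigree"], pop["rel"].F,
                                  eig=pop["eig"])
            w05 = grid.power[grid.power.window == "0.5Mb"]
            assert (w05["power"] == expected).all()

    def test_identical_seed_bit_reproducible(self, tiny_inputs):
        pop, dosages, imputed = tiny_inputs
        cfg = SimulationConfig(qtl_h2_grid=(0.10,), maf_classes=("high",),
                               methods=("snp", "hap"), n_replicates=3, seed=7)
        g1 = run_power_grid(cfg, imputed, pop["pedigree"], pop["rel"].F,
                            eig=pop["eig"], dosages=dosages)
        g2 = run_power_grid(cfg, imputed, pop["pedigree"], pop["rel"].F,
                            eig=pop["eig"], dosages=dosages)
        pd.testing.assert_frame_equal(g1.power, g2.power)
        pd.testing.assert_frame_equal(g1.replicates, g2.replicates)

    def test_window_union_accounting(self, population, hmm):
        cfg = SimulationConfig(qtl_h2_grid=(0.10,), maf_classes=("high",),
                               methods=("snp",), n_replicates=10, seed=3)
        pop = population
        grid = run_power_grid(cfg, hmm["imputed"], pop["pedigree"], pop["rel"].F,
                              eig=pop["eig"])
        reps = grid.replicates
        cols = [f"snp_min_p_{w}" for w, _, _ in cfg.windows]
        union_hits = (reps[cols] < cfg.genomewide_p).any(axis=1)
        powers = grid.power.set_index("window")["power"]
        # each window's power is the replicate fraction for that annulus, and
        # the union over the annuli is the hit rate within +/-2 Mb
        for label, _, _ in cfg.windows:
            assert powers.loc[label] == pytest.approx(
                (reps[f"snp_min_p_{label}"] < cfg.genomewide_p).mean()
            )
        assert union_hits.mean() >= powers.loc["0.5Mb"]


def test_window_min_p_annuli():
    scan = pd.DataFrame(
        {
            "chrom": [1, 1, 1, 2],
            "pos_bp": [1_000_000, 1_950_000, 2_600_000, 1_000_000],
            "p": [1e-3, 1e-5, 1e-7, 1e-9],
        }
    )
    rec = QTLRecord(0, "q", 1, 1_200_000, 0.3, 1.0, 0.05)
    out = _window_min_p(scan, rec, pg.SimulationConfig().windows)
    assert out["0.5Mb"] == pytest.approx(1e-3)  # d = 0.2 Mb
    assert out["0.5-1.0Mb"] == pytest.approx(1e-5)  # d = 0.75 Mb
    assert out["1.0-2.0Mb"] == pytest.approx(1e-7)  # d = 1.4 Mb; chrom 2 excluded
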