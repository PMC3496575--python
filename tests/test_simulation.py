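import numpy as np
import pytest

from twostagefdr.selection import SelectionRule, select_top_k
from twostagefdr.simulation import (
    ScenarioConfig,
    _correlated_noise,
    generate_dataset,
    improvement_pct,
    run_grid,
    run_scenario,
)
from twostagefdr.mtp import two_sided_p_from_z


def small_config(**kw):
    base = dict(m=100, pi0=0.9, delta=1.2, rule=SelectionRule.fns(10),
                n1=6, n2=12, n_runs=50, seed=42)
    base.update(kw)
    return ScenarioConfig(**base)


class TestNoiseGenerator:
    @staticmethod
    def draws(structure, rho, m=60, n=4000, seed=1):
        rng = np.random.default_rng(seed)
        return np.array([_correlated_noise(rng, m, structure, rho, 20)
                         for _ in range(n)])

    def test_zero_rho_is_independent(self):
        x = self.draws("equi", 0.0)
        c = np.corrcoef(x, rowvar=False)
        off = c[np.triu_indices_from(c, 1)]
        assert abs(off.mean()) < 3 / np.sqrt(4000)

    def test_equicorrelation_level(self):
        x = self.draws("equi", 0.5)
        c = np.corrcoef(x, rowvar=False)
        off = c[np.triu_indices_from(c, 1)]
        assert off.mean() == pytest.approx(0.5, abs=0.02)
        assert np.std(x, axis=0).mean() == pytest.approx(1.0, abs=0.05)

    def test_autoregressive_decay(self):
        x = self.draws("auto", 0.5)
        c = np.corrcoef(x, rowvar=False)
        for lag in (1, 2, 3):
            est = np.mean(np.diagonal(c, offset=lag))
            assert est == pytest.approx(0.5 ** lag, abs=0.05)

    def test_block_structure(self):
        x = self.draws("block", 0.5)
        c = np.corrcoef(x, rowvar=False)
        within = np.mean([c[i, j] for i in range(20) for j in range(i + 1, 20)])
        across = np.mean([c[i, j] for i in range(20) for j in range(20, 40)])
        assert within == pytest.approx(0.5, abs=0.03)
        assert across == pytest.approx(0.0, abs=0.03)


class TestGenerateDataset:
    def test_counts_and_labels(self):
        data = generate_dataset(small_config(), 0)
        assert data.m == 100
        assert int(data.is_alternative.sum()) == 10
        assert np.all(data.mu[data.is_alternative] == 1.2)
        assert np.all(data.mu[~data.is_alternative] == 0.0)

    @pytest.mark.parametrize("design, scale", [("one_sample", np.sqrt(6)),
                                               ("two_group", np.sqrt(3))])
    def test_alternative_mean_convention(self, design, scale):
        cfg = small_config(m=200, pi0=0.5, delta=1.0, design=design, n_runs=1)
        means = []
        for r in range(300):
            d = generate_dataset(cfg, r)
            means.append(d.z1[d.is_alternative].mean())
        est = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(est - scale) <= 3 * se

    def test_alternative_positions_rerandomized(self):
        cfg = small_config(correlation="equi", rho=0.5)
        a = generate_dataset(cfg, 0).is_alternative
        b = generate_dataset(cfg, 1).is_alternative
        assert not np.array_equal(a, b)

    def test_stage_noises_independent(self):
        cfg = small_config(m=2000, pi0=1.0, n_runs=1)
        d = generate_dataset(cfg, 3)
        assert abs(np.corrcoef(d.z1, d.z2)[0, 1]) < 3 / np.sqrt(2000)


class TestRunScenario:
    def test_seeded_reproducibility(self):
        a = run_scenario(small_config(), approach="integrated")["integrated"]
        b = run_scenario(small_config(), approach="integrated")["integrated"]
        assert a == b

    def test_single_run_has_undefined_se(self):
        s = run_scenario(small_config(n_runs=1), approach="pilot")["pilot"]
        assert np.isnan(s.fdr_se) and np.isnan(s.s_se)

    def test_fdrs_global_null_stop_rate(self):
        cfg = small_config(m=200, pi0=1.0, rule=SelectionRule.fdrs(0.2),
                           n_runs=2000)
        s = run_scenario(cfg, approach="pilot")["pilot"]
        se = np.sqrt(0.2 * 0.8 / 2000)
        assert abs(s.stop_rate - 0.8) <= 3 * se

    def test_invalid_approach(self):
        with pytest.raises(ValueError):
            run_scenario(small_config(), approach="nope")


def test_fns_threshold_concentrates_with_m():
    # the FNS data-dependent gamma1 = p_(m2) is an empirical quantile whose
    # across-run spread shrinks as m grows at fixed m2/m
    sds = []
    for m in (500, 2000, 8000):
        rng = np.random.default_rng(9)
        g = [select_top_k(rng.uniform(size=m), m // 10).gamma1_effective
             for _ in range(200)]
        sds.append(np.std(g, ddof=1))
    assert sds[0] > sds[1] > sds[2]


def test_common_random_numbers_reduce_paired_se():
    cfg = small_config(m=300, pi0=0.9, delta=1.0, n_runs=150,
                       rule=SelectionRule.fns(30))
    out = run_scenario(cfg, approach="both", keep_runs=True)
    x = out["integrated"].per_run["S"].to_numpy(float)
    y = out["pilot"].per_run["S"].to_numpy(float)
    paired_var = np.var(x - y, ddof=1)
    unpaired_var = np.var(x, ddof=1) + np.var(y, ddof=1)
    assert paired_var < unpaired_var
    imp, imp_se = improvement_pct(out)
    assert np.isfinite(imp) and np.isfinite(imp_se)


class TestRunGrid:
    def test_identical_configs_give_identical_rows(self):
        cfg = small_config(n_runs=20)
        table = run_grid([cfg, cfg], approach="integrated")
        assert len(table) == 2
        a, b = table.iloc[0], table.iloc[1]
        assert a["fdr_hat"] == b["fdr_hat"] and a["mean_S"] == b["mean_S"]

    def test_both_approaches_yield_two_rows_each(self):
        cfg = small_config(n_runs=20)
        table = run_grid([cfg, small_config(n_runs=20, delta=1.5)])
        assert len(table) == 4
        assert set(table["approach"]) == {"integrated", "pilot"}
        imp = table.loc[table["approach"] == "integrated", "improvement_pct"]
        assert np.isfinite(imp).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            run_grid([])


def test_config_validation():
    with pytest.raises(ValueError):
        small_config(pi0=1.5)
    with pytest.raises(ValueError):
        small_config(correlation="banana")
    with pytest.raises(ValueError):
        small_config(rho=1.0)
    with pytest.raises(ValueError):
        small_config(design="paired")
    cfg = small_config(pi0=0.955, m=200)
    assert cfg.m0 == 191 and cfg.m1 == 9
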