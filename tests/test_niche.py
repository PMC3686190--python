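"""Partitioned D2 fitting, scoring, HSI and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ecominima as em
from ecominima.layers import VariableTable
from ecominima.niche import ModelError, eigenvalue_ladder_diagnostics


def table_from_array(X):
    cols = [f"v{i}" for i in range(X.shape[1])]
    return VariableTable(data=pd.DataFrame(X, columns=cols),
                         provenance={c: (c, "point", 0.0) for c in cols})


def exact_corr_pair(n, r, seed=0):
    """Two columns whose sample correlation is exactly r."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(n, 2)) - 0.0)
    z = q[:, 0] - q[:, 0].mean()
    w = q[:, 1] - q[:, 1].mean()
    # re-orthogonalize after centering
    w = w - (w @ z) / (z @ z) * z
    z /= z.std(ddof=1)
    w /= w.std(ddof=1)
    return np.column_stack([z, r * z + np.sqrt(1 - r * r) * w])


class TestFitSingle:
    def test_uncorrelated_pair_eigvals_unit(self):
        X = exact_corr_pair(200, 0.0)
        m = em.fit_single(table_from_array(X))
        assert np.allclose(m.eigvals, [1.0, 1.0], atol=1e-10)

    def test_correlated_pair_closed_form(self):
        X = exact_corr_pair(200, 0.8)
        m = em.fit_single(table_from_array(X))
        assert np.allclose(m.eigvals, [1.8, 0.2], atol=1e-10)

    def test_trace_conservation(self, single_model):
        assert single_model.eigvals.sum() == pytest.approx(10.0, abs=1e-6)

    def test_unit_eigenvectors(self, single_model):
        norms = np.linalg.norm(single_model.eigvecs, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-10)

    def test_constant_column_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        X[:, 1] = 7.0
        with pytest.raises(ModelError, match="v1"):
            em.fit_single(table_from_array(X))

    def test_n_le_p_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 6))
        with pytest.raises(ModelError):
            em.fit_single(table_from_array(X))


class TestPartitions:
    def test_contributions_zero_at_mean(self, single_model):
        c = em.partition_contributions(single_model.mu, single_model)
        assert np.allclose(c, 0.0)

    def test_additivity_against_direct_inverse(self, gauss_table, single_model):
        """Sum of partitions equals z^T R^{-1} z computed independently."""
        X = gauss_table.values
        R = np.corrcoef(X, rowvar=False)
        Rinv = np.linalg.inv(R)
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(200, 10)) * X.std(axis=0) + X.mean(axis=0)
        for x in pts:
            z = (x - single_model.mu) / single_model.sigma
            direct = z @ Rinv @ z
            c = em.partition_contributions(x, single_model)
            assert c.sum() == pytest.approx(direct, abs=1e-8)

    def test_d2_k1_equals_full(self, single_model):
        rng = np.random.default_rng(8)
        x = single_model.mu + rng.normal(size=10)
        c = em.partition_contributions(x, single_model)
        assert em.d2_k(x, single_model, 1) == pytest.approx(c.sum())
        assert em.d2_k(x, single_model, 10) == pytest.approx(c[-1])

    def test_k_out_of_range(self, single_model):
        with pytest.raises(ModelError):
            em.d2_k(single_model.mu, single_model, 0)
        with pytest.raises(ModelError):
            em.d2_k(single_model.mu, single_model, 11)

    def test_single_partition_mode(self, single_model):
        m = single_model.with_k(4)
        m.mode = "single-partition"
        x = single_model.mu + 0.5
        c = em.partition_contributions(x, m)
        assert em.d2_k(x, m) == pytest.approx(c[3])
        assert m.df == 1


class TestHSI:
    def test_zero_d2_gives_one(self, single_model):
        assert em.hsi(0.0, single_model) == 1.0

    def test_chi2_quantile(self, single_model):
        m = single_model.with_k(10)  # df = 1
        assert em.hsi(3.841, m) == pytest.approx(0.05, abs=1e-3)

    def test_strictly_decreasing_and_tail_limit(self, single_model):
        d2 = np.linspace(0, 50, 200)
        h = em.hsi(d2, single_model)
        assert np.all(np.diff(h) < 0)
        assert em.hsi(1e6, single_model) < 1e-12

    def test_negative_d2_rejected(self, single_model):
        with pytest.raises(ModelError):
            em.hsi(-0.1, single_model)


class TestBootstrap:
    def _table(self, n=120, p=5, seed=3):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(p, p))
        X = rng.normal(size=(n, p)) @ A.T
        return table_from_array(X)

    def test_single_iteration_full_sample_equals_fit_single(self):
        tab = self._table(n=40)
        pops = np.zeros(40, dtype=int)
        boot = em.bootstrap_fit(tab, pops, n_boot=1, pop_cap=40, seed=0)
        single = em.fit_single(tab)
        assert np.allclose(boot.eigvals, single.eigvals, atol=1e-10)
        assert np.allclose(boot.mu, single.mu, atol=1e-10)
        assert np.allclose(np.abs(boot.eigvecs.T @ single.eigvecs),
                           np.eye(5), atol=1e-8)

    def test_population_cap_respected(self):
        tab = self._table(n=120)
        pops = np.repeat([0, 1], 60)
        boot = em.bootstrap_fit(tab, pops, n_boot=5, pop_cap=25, seed=1)
        assert boot.pop_cap == 25 and boot.n_boot == 5

    def test_averaged_eigvals_near_direct_fit(self):
        """Bootstrap averages stay within a few SE of the direct fit."""
        tab = self._table(n=1000, seed=9)
        pops = np.arange(1000) % 8
        single = em.fit_single(tab)
        boots = [em.bootstrap_fit(tab, pops, n_boot=200, pop_cap=25, seed=s)
                 for s in (1, 2)]
        assert not np.allclose(boots[0].eigvals, boots[1].eigvals)
        for b in boots:
            # a capped iteration uses 8 * 25 = 200 rows, whose eigenvalues
            # scatter by roughly lambda * sqrt(2 / 200)
            se = single.eigvals * np.sqrt(2.0 / 200)
            assert np.all(np.abs(b.eigvals - single.eigvals) < 3 * se)

    def test_orthogonality_deviation_reported(self):
        tab = self._table(n=200, seed=11)
        pops = np.arange(200) % 4
        boot = em.bootstrap_fit(tab, pops, n_boot=25, pop_cap=25, seed=2)
        assert boot.averaged
        assert 0 <= boot.orthogonality_dev < 0.5
        norms = np.linalg.norm(boot.eigvecs, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-12)


class TestSelectKAndDiagnostics:
    def test_select_k_eigenvalue_rule(self, ladder27):
        m = em.PartitionModel(mu=np.zeros(27), sigma=np.ones(27),
                              eigvals=ladder27, eigvecs=np.eye(27),
                              var_names=[f"v{i}" for i in range(27)])
        assert em.select_k(m) == 11  # first eigenvalue <= 1.0 in the ladder

    def test_ladder_diagnostics(self, ladder27):
        tab = eigenvalue_ladder_diagnostics(ladder27)
        assert tab.loc[tab["k"] == 10, "delta"].iloc[0] == pytest.approx(0.10)
        assert tab["eigval"].sum() == pytest.approx(27.00)
        deltas = tab["delta"].to_numpy()[1:]
        assert np.all(deltas >= -1e-9)  # non-increasing ladder

    def test_diagnostics_table(self, gauss_table, single_model):
        X = gauss_table.values
        diag = em.diagnostics(single_model, X[:100], X[100:200], X[200:250],
                              X[250:350])
        assert list(diag.table["k"]) == list(range(1, 11))
        assert np.all(diag.table["auc"].between(0, 1))
        # identical point sets give identical medians
        d2 = em.diagnostics(single_model, X[:100], X[:100], X[:100], X[250:350])
        assert np.allclose(d2.table["median_cal"], d2.table["median_eval"])

    def test_empty_set_rejected(self, gauss_table, single_model):
        X = gauss_table.values
        with pytest.raises(ModelError):
            em.diagnostics(single_model, X[:0], X[:10], X[:10], X[:10])


class TestMapHSI:
    def test_constant_stack_at_mean_maps_to_one(self, single_model):
        from ecominima.layers import EnvStack
        layers = {v: np.full((16, 16), single_model.mu[i])
                  for i, v in enumerate(single_model.var_names)}
        mask = np.zeros((16, 16), dtype=bool)
        mask[0, :] = True
        stack = EnvStack(layers=layers, nodata_mask=mask, cell_km=1.0)
        spec = {v: (v, "point", 0.0) for v in single_model.var_names}
        out = em.map_hsi(stack, spec, single_model)
        assert np.allclose(out[~mask], 1.0)
        assert np.all(np.isnan(out[mask]))

    def test_missing_variable_errors(self, single_model):
        from ecominima.layers import EnvStack
        layers = {"v0": np.zeros((16, 16))}
        stack = EnvStack(layers=layers,
                         nodata_mask=np.zeros((16, 16), dtype=bool), cell_km=1.0)
        with pytest.raises(ModelError, match="v1"):
            em.map_hsi(stack, {"v0": ("v0", "point", 0.0)}, single_model)

    def test_values_in_unit_interval(self, landscape, occurrences, single_model):
        _, _, _, stack = landscape
        spec = {f"v{i}": (n, "point", 0.0) for i, n in enumerate(stack.names)}
        out = em.map_hsi(stack, spec, single_model)
        vals = out[np.isfinite(out)]
        assert np.all((vals >= 0) & (vals <= 1))


def test_model_json_roundtrip(tmp_path, single_model):
    path = tmp_path / "model.json"
    single_model.to_json(path)
    back = em.PartitionModel.from_json(path)
    assert np.allclose(back.eigvals, single_model.eigvals)
    assert np.allclose(back.eigvecs, single_model.eigvecs)
    assert back.var_names == single_model.var_names
    assert back.k_selected == single_model.k_selected
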