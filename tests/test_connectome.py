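import math

import numpy as np
import pytest
from scipy.integrate import quad

import connlearn as cl
from connlearn.connectome import (
    build_connectome,
    correlation_pvalues,
    edge_list,
    effective_samples_bandlimited,
    fisher_z,
    pearson_matrix,
    read_connectome,
    write_connectome,
)


class TestPearson:
    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        data = np.column_stack([x, x, -x, rng.standard_normal(50)])
        r = pearson_matrix(data)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        assert np.allclose(r, r.T)
        assert np.abs(r).max() <= 1.0

    def test_matches_textbook_formula_on_four_samples(self):
        a = np.array([1.0, 3.0, 2.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0])
        # direct covariance / (sigma_a * sigma_b) oracle
        expected = (
            np.sum((a - a.mean()) * (b - b.mean()))
            / math.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        )
        r = pearson_matrix(np.column_stack([a, b]))
        assert r[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_column_warns_and_zeroes(self):
        data = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            r = pearson_matrix(data)
        assert r[0, 1] == 0.0
        assert r[1, 1] == 1.0


class TestCorrelationPvalues:
    def test_extremes(self):
        r = np.array([0.0, 1.0, -1.0])
        p = correlation_pvalues(r, T=20)
        assert p[0] == pytest.approx(1.0)
        assert p[1] == 0.0 and p[2] == 0.0

    def test_matches_t_density_quadrature(self):
        r, T = 0.5, 30
        nu = T - 2
        t_stat = r * math.sqrt(nu / (1 - r**2))

        def t_pdf(x):
            return (
                math.gamma((nu + 1) / 2)
                / (math.sqrt(nu * math.pi) * math.gamma(nu / 2))
                * (1 + x**2 / nu) ** (-(nu + 1) / 2)
            )

        tail, _ = quad(t_pdf, t_stat, np.inf)
        p = correlation_pvalues(np.array([r]), T=T)[0]
        assert p == pytest.approx(2 * tail, abs=1e-9)


class TestFisherZ:
    def test_closed_form_half(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3.0), abs=1e-12)

    def test_odd_symmetry_and_zero(self):
        assert fisher_z(0.0) == 0.0
        r = np.linspace(-0.99, 0.99, 21)
        assert np.allclose(fisher_z(-r), -fisher_z(r))

    def test_clipped_at_unity(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))


class TestBuildConnectome:
    def test_duplicated_columns_edge_survives_with_max_weight(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((60, 8))
        data[:, 1] = data[:, 0]
        conn = build_connectome(data)
        assert conn.weights[0, 1] == np.abs(conn.weights).max()
        assert conn.weights[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_q_zero_masks_everything(self):
        rng = np.random.default_rng(2)
        conn = build_connectome(rng.standard_normal((40, 10)), q=0.0)
        assert conn.n_edges() == 0

    def test_lowering_q_never_adds_edges(self, small_cohort):
        _, cohort = small_cohort
        ts = cohort[0]
        prev = None
        for q in (0.2, 0.05, 0.01, 0.001):
            edges = {
                (i, j)
                for i, j in zip(*np.nonzero(np.triu(build_connectome(ts, q=q).weights, 1)))
            }
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_roi_permutation_equivariance(self, small_cohort):
        _, cohort = small_cohort
        ts = cohort[0]
        perm = np.random.default_rng(3).permutation(ts.n_rois)
        direct = build_connectome(ts.data[:, perm]).weights
        permuted = build_connectome(ts.data).weights[np.ix_(perm, perm)]
        assert np.allclose(direct, permuted)

    def test_masked_count_matches_bh_rule(self, small_cohort):
        from statsmodels.stats.multitest import multipletests

        _, cohort = small_cohort
        ts = cohort[0]
        r = pearson_matrix(ts.data)
        p = correlation_pvalues(r, T=ts.n_scans)
        iu = np.triu_indices(ts.n_rois, 1)
        keep, _, _, _ = multipletests(p[iu], alpha=0.05, method="fdr_bh")
        conn = build_connectome(ts)
        assert conn.n_edges() == int(keep.sum())

    def test_symmetric_zero_diagonal_finite(self, small_connectomes):
        for conn in small_connectomes[:4]:
            W = conn.weights
            assert np.allclose(W, W.T)
            assert np.all(np.diag(W) == 0)
            assert np.isfinite(W).all()


def test_null_cohort_edge_retention_calibrated():
    """On pure-noise band-limited cohorts the dof-matched FDR mask retains
    at most a q fraction of edges on average."""
    rng = np.random.default_rng(77)
    spec0 = cl.CohortSpec()
    t_eff = effective_samples_bandlimited(150, 2.0, *spec0.bandpass_hz)
    fractions = []
    for _ in range(55):
        spec = cl.CohortSpec(
            n_subjects=1, n_rois=30, rho_within=0.0, rho_between_run1=0.0,
            rho_between_run2=0.0, condition="null", seed=int(rng.integers(0, 2**31 - 1)),
        )
        ts = cl.generate_cohort(spec)[0]
        conn = build_connectome(ts, q=0.05, effective_samples=t_eff)
        fractions.append(conn.n_edges() / (30 * 29 / 2))
    assert np.mean(fractions) <= 0.05


def test_connectome_io_roundtrip(tmp_path, small_connectomes):
    conn = small_connectomes[0]
    write_connectome(conn, tmp_path / "z.tsv")
    back = read_connectome(tmp_path / "z.tsv")
    assert np.allclose(back.weights, conn.weights)
    edges = edge_list(conn)
    assert len(edges) == conn.n_edges()
    assert (edges["roi_i"] < edges["roi_j"]).all()
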