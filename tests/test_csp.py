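"""Common spatial pattern estimation and filter selection."""

import numpy as np
import pytest

from minf.csp import CSPModel, apply_csp, fit_csp, select_filters
from minf.eeg_pipeline import EpochSet


def _epochs(data, label):
    return EpochSet(data, [label] * data.shape[0], (0.0, data.shape[2] / 500.0), 500.0)


def _separable_sets(rng, n=20, ns=500):
    """Class L variance only on channel 0, class R only on channel 1."""
    left = np.zeros((n, 2, ns))
    right = np.zeros((n, 2, ns))
    left[:, 0, :] = rng.standard_normal((n, ns))
    left[:, 1, :] = 1e-4 * rng.standard_normal((n, ns))
    right[:, 1, :] = rng.standard_normal((n, ns))
    right[:, 0, :] = 1e-4 * rng.standard_normal((n, ns))
    return _epochs(left, "left"), _epochs(right, "right")


def brute_force_generalized_eigs(cov_l, pooled):
    """Roots of det(cov_l - lambda * pooled) via the characteristic polynomial."""
    import sympy

    lam = sympy.symbols("lam")
    m = sympy.Matrix(cov_l) - lam * sympy.Matrix(pooled)
    roots = sympy.Poly(m.det(method="berkowitz"), lam).nroots()
    return sorted(float(sympy.re(r)) for r in roots)


class TestFitCSP:
    def test_separable_construction(self):
        left, right = _separable_sets(np.random.default_rng(0))
        model = fit_csp(left, right)
        assert model.eigenvalues[0] == pytest.approx(1.0, abs=1e-3)
        assert model.eigenvalues[-1] == pytest.approx(0.0, abs=1e-3)
        top = np.abs(model.filters[0]) / np.abs(model.filters[0]).max()
        bottom = np.abs(model.filters[-1]) / np.abs(model.filters[-1]).max()
        np.testing.assert_allclose(top, [1.0, 0.0], atol=5e-3)
        np.testing.assert_allclose(bottom, [0.0, 1.0], atol=5e-3)

    def test_identical_classes_give_half_eigenvalues(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((30, 3, 400))
        model = fit_csp(_epochs(data, "left"), _epochs(data, "right"))
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=1e-12)

    def test_matches_small_matrix_oracle(self):
        rng = np.random.default_rng(2)
        left = _epochs(rng.standard_normal((15, 4, 300)), "left")
        right = _epochs(rng.standard_normal((15, 4, 300)) * [[2.0], [1.0], [0.5], [1.5]],
                        "right")
        model = fit_csp(left, right)
        # independent oracle: characteristic polynomial of the same 4x4 problem
        cov = lambda ep: np.mean([x @ x.T / np.trace(x @ x.T) for x in ep.data], axis=0)
        cl, cr = cov(left), cov(right)
        pooled = cl + cr + 1e-9 * np.trace(cl + cr) * np.eye(4)
        expected = brute_force_generalized_eigs(cl, pooled)
        np.testing.assert_allclose(sorted(model.eigenvalues), expected, atol=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        l = rng.standard_normal((10, 3, 200))
        r = rng.standard_normal((10, 3, 200)) * [[1.0], [3.0], [0.3]]
        m1 = fit_csp(_epochs(l, "left"), _epochs(r, "right"))
        m2 = fit_csp(_epochs(7.0 * l, "left"), _epochs(7.0 * r, "right"))
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-10)
        for k in range(3):
            f1, f2 = m1.filters[k], m2.filters[k]
            cos = abs(f1 @ f2) / (np.linalg.norm(f1) * np.linalg.norm(f2))
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_left_right_eigenvalues_sum_to_one(self):
        rng = np.random.default_rng(4)
        l = rng.standard_normal((10, 3, 200)) * [[2.0], [1.0], [1.0]]
        r = rng.standard_normal((10, 3, 200))
        m_lr = fit_csp(_epochs(l, "left"), _epochs(r, "right"))
        m_rl = fit_csp(_epochs(r, "left"), _epochs(l, "right"))
        np.testing.assert_allclose(sorted(m_lr.eigenvalues),
                                   sorted(1.0 - m_rl.eigenvalues), atol=1e-9)

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((10, 1, 200))
        dup = np.repeat(base, 3, axis=1)  # 3 identical channels
        with pytest.raises(ValueError, match="rank"):
            fit_csp(_epochs(dup, "left"), _epochs(dup.copy(), "right"))

    def test_diagonalizes_pooled_covariance(self):
        rng = np.random.default_rng(6)
        l = rng.standard_normal((12, 4, 300)) * [[2.0], [1.0], [0.5], [1.0]]
        r = rng.standard_normal((12, 4, 300))
        m = fit_csp(_epochs(l, "left"), _epochs(r, "right"))
        cov = lambda ep: np.mean([x @ x.T / np.trace(x @ x.T) for x in ep.data], axis=0)
        pooled = cov(_epochs(l, "left")) + cov(_epochs(r, "right"))
        d = m.filters @ pooled @ m.filters.T
        off = d - np.diag(np.diag(d))
        assert np.abs(off).max() < 1e-8

    def test_patterns_invert_filters(self):
        rng = np.random.default_rng(7)
        l = rng.standard_normal((10, 3, 200)) * [[2.0], [1.0], [1.0]]
        r = rng.standard_normal((10, 3, 200))
        m = fit_csp(_epochs(l, "left"), _epochs(r, "right"))
        np.testing.assert_allclose(m.patterns @ m.filters, np.eye(3), atol=1e-8)


class TestSelectFilters:
    def test_fallback_returns_extreme_eigenvalue_components(self):
        rng = np.random.default_rng(8)
        l = rng.standard_normal((10, 4, 300)) * [[3.0], [1.0], [1.0], [0.4]]
        r = rng.standard_normal((10, 4, 300))
        m = fit_csp(_epochs(l, "left"), _epochs(r, "right"))
        w_left, w_right = select_filters(m)
        np.testing.assert_array_equal(w_left, m.filters[0])
        np.testing.assert_array_equal(w_right, m.filters[-1])

    def test_two_channel_model_warns_and_uses_all(self):
        rng = np.random.default_rng(9)
        left, right = _separable_sets(rng)
        m = fit_csp(left, right)
        with pytest.warns(UserWarning, match="fewer than 3"):
            w_left, w_right = select_filters(m)
        assert w_left.shape == (2,)

    def test_selected_patterns_peak_on_true_mixing_columns(self, small_session_sources):
        from minf import eeg_pipeline as ep
        from minf.session import MI_WINDOW

        rec, truth = small_session_sources
        filt = ep.fir_bandpass(rec, 8.0, 30.0)
        mi = ep.epoch(filt, MI_WINDOW)
        m = fit_csp(mi.by_class("left"), mi.by_class("right"))
        # the left-class-dominant pattern should peak where the suppressed-during-
        # right source mixes in, i.e. near the ipsilateral column of the truth
        pat_left = np.abs(m.patterns[:, 0])
        pat_right = np.abs(m.patterns[:, -1])
        peak_left = int(np.argmax(pat_left))
        peak_right = int(np.argmax(pat_right))
        true_peaks = {int(np.argmax(truth["mixing"][:, 0])),
                      int(np.argmax(truth["mixing"][:, 1]))}
        assert {peak_left, peak_right} == true_peaks


class TestApplyCSP:
    def test_one_hot_filter_returns_channel(self, small_session):
        out = apply_csp(small_session, np.array([[0.0] * 3 + [1.0] + [0.0] * 4]))
        np.testing.assert_array_equal(out[0], small_session.signal[3])

    def test_zero_filter_zero_output(self, small_session):
        out = apply_csp(small_session, np.zeros((1, 8)))
        assert np.all(out == 0)

    def test_dimension_mismatch_rejected(self, small_session):
        with pytest.raises(ValueError):
            apply_csp(small_session, np.ones((1, 5)))

    def test_variance_ratio_matches_eigenvalue(self):
        rng = np.random.default_rng(10)
        l = rng.standard_normal((40, 3, 500)) * [[2.0], [1.0], [1.0]]
        r = rng.standard_normal((40, 3, 500))
        left, right = _epochs(l, "left"), _epochs(r, "right")
        m = fit_csp(left, right)
        w = m.filters[0]
        vl = np.mean([np.var(w @ x) / np.trace(x @ x.T) for x in left.data])
        vr = np.mean([np.var(w @ x) / np.trace(x @ x.T) for x in right.data])
        lam = m.eigenvalues[0]
        assert vl / (vl + vr) == pytest.approx(lam, rel=0.10)


def test_model_json_roundtrip():
    rng = np.random.default_rng(11)
    l = rng.standard_normal((10, 3, 200)) * [[2.0], [1.0], [1.0]]
    r = rng.standard_normal((10, 3, 200))
    m = fit_csp(_epochs(l, "left"), _epochs(r, "right"), ["a", "b", "c"])
    m2 = CSPModel.from_json(m.to_json())
    np.testing.assert_allclose(m2.filters, m.filters)
    np.testing.assert_allclose(m2.eigenvalues, m.eigenvalues)
    assert m2.channel_labels == ["a", "b", "c"]
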