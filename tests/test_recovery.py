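import numpy as np
import pytest

from tdmom import recovery as rc
from tdmom.moments import MOMENT_SCALES, MomentTimeSeries
from tdmom.synth import (
    NoiseConfig,
    ProbeGeometry,
    make_hrf,
    make_stimulus_train,
    simulate_session,
)
from tdmom.transport import baseline_absorption, interp_two_layer


# ---------------------------------------------------------------------------
# scaled WLS estimator
# ---------------------------------------------------------------------------


def _well_conditioned_problem(rng, m=6, p=2):
    X = rng.normal(size=(m, p))
    root = rng.normal(size=(m, m))
    Z = root @ root.T + m * np.eye(m)
    return X, Z


def test_scaled_estimator_equals_textbook_wls(rng):
    X, Z = _well_conditioned_problem(rng)
    est = rc.scaled_wls_estimator(X, Z, k=np.ones(6))
    Zinv = np.linalg.inv(Z)
    textbook = np.linalg.inv(X.T @ Zinv @ X) @ X.T @ Zinv
    np.testing.assert_allclose(est, textbook, rtol=1e-10)


def test_scaling_leaves_estimator_unchanged(rng):
    X, Z = _well_conditioned_problem(rng)
    a = rc.scaled_wls_estimator(X, Z, k=np.ones(6))
    b = rc.scaled_wls_estimator(X, Z, k=np.array([1.0, 2.0, 0.5, 3.0, 1.5, 10.0]))
    np.testing.assert_allclose(a, b, rtol=1e-8)


def test_scaled_estimator_realistic_moment_scales_vs_longdouble(rng):
    """Oracle: plain WLS in extended precision on a realistically ill-scaled
    problem (moment variances spanning ~24 orders of magnitude)."""
    scales = np.repeat(MOMENT_SCALES, 2)  # two channels
    X = rng.normal(size=(6, 2)) / scales[:, None]
    root = rng.normal(size=(6, 6))
    Z = (root @ root.T + 6 * np.eye(6)) / np.outer(scales, scales)
    est = rc.scaled_wls_estimator(X, Z)  # default k = moment scales
    Xl = X.astype(np.longdouble)
    Zl = Z.astype(np.longdouble)
    Zinv = np.linalg.inv(Zl.astype(float))  # scipy/numpy longdouble inv unsupported
    Zinv = np.asarray(Zinv, np.longdouble)
    oracle = np.linalg.inv((Xl.T @ Zinv @ Xl).astype(float)) @ (Xl.T @ Zinv)
    np.testing.assert_allclose(est, np.asarray(oracle, float), rtol=1e-8)


def test_scaled_estimator_rejects_singular_covariance():
    X = np.eye(6)[:, :2]
    Z = np.zeros((6, 6))
    with pytest.raises(np.linalg.LinAlgError, match="singular"):
        rc.scaled_wls_estimator(X, Z)


def test_scaled_estimator_rejects_rank_deficient_design(rng):
    _, Z = _well_conditioned_problem(rng)
    X = np.ones((6, 2))  # two identical columns
    with pytest.raises(np.linalg.LinAlgError, match="rank"):
        rc.scaled_wls_estimator(X, Z, k=np.ones(6))


def test_scaled_estimator_input_validation(rng):
    X, Z = _well_conditioned_problem(rng)
    with pytest.raises(ValueError, match="must be 6x6"):
        rc.scaled_wls_estimator(X, Z[:4, :4])
    with pytest.raises(ValueError, match="positive diagonal"):
        rc.scaled_wls_estimator(X, Z, k=-np.ones(6))
    with pytest.raises(ValueError, match="3\\*Nc"):
        rc.scaled_wls_estimator(X[:4], Z[:4, :4])


# ---------------------------------------------------------------------------
# multidistance layer separation
# ---------------------------------------------------------------------------


def _forward_series(table, true_scalp, true_brain, lam=690.0):
    mua = baseline_absorption(lam)
    tl_ss = interp_two_layer(table, 8.0, mua, 13.0, wavelength=lam)
    tl_ls = interp_two_layer(table, 30.0, mua, 13.0, wavelength=lam)
    nt = true_scalp.size
    vals = np.zeros((2, 1, 3, nt))
    for c, tl in enumerate([tl_ss, tl_ls]):
        for n in range(3):
            vals[c, 0, n] = tl.scalp[n] * true_scalp + tl.brain[n] * true_brain
    series = MomentTimeSeries(
        values=vals,
        separations=[8.0, 30.0],
        wavelengths=[lam],
        sample_rate=7.0,
        detector_ids=[0, 0],
    )
    return series, tl_ss, tl_ls


@pytest.mark.parametrize("chset", ["SS", "LS", "LS+SS"])
def test_td_multidistance_exact_recovery(table, chset, rng):
    t = np.arange(64) / 7.0
    true_scalp = 1e-4 * np.sin(2 * np.pi * 0.2 * t)
    true_brain = 3e-5 * np.cos(2 * np.pi * 0.1 * t)
    series, tl_ss, tl_ls = _forward_series(table, true_scalp, true_brain)
    if chset == "SS":
        chs, sens, budgets = [0], [tl_ss], [1e6]
    elif chset == "LS":
        chs, sens, budgets = [1], [tl_ls], [1e5]
    else:
        chs, sens, budgets = [1, 0], [tl_ls, tl_ss], [1e5, 1e6]
    Z = rc.theoretical_moment_covariance(
        table, [series.separations[c] for c in chs], 690.0, budgets
    )
    las = rc.td_multidistance(series, chs, sens, Z)
    scale = np.abs(true_brain).max()
    np.testing.assert_allclose(
        las.brain, true_brain - true_brain.mean(), atol=1e-9 * scale
    )
    np.testing.assert_allclose(
        las.scalp, true_scalp - true_scalp.mean(), atol=1e-9 * np.abs(true_scalp).max()
    )
    assert las.wavelength == 690.0


def test_td_multidistance_validation(table):
    t = np.arange(10) / 7.0
    series, tl_ss, tl_ls = _forward_series(table, np.sin(t), np.cos(t))
    with pytest.raises(ValueError, match="per channel"):
        rc.td_multidistance(series, [0, 1], [tl_ss], np.eye(6))


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------


def test_epoch_average_single_epoch_exact():
    fs = 7.0
    nt = 7 * 40
    t = np.arange(nt) / fs
    h = make_hrf(1.0)
    onset = 10.0
    sig, _ = h.sample(t - onset)
    tb, avg, n = rc.epoch_average(sig, fs, [onset])
    assert n == 1
    truth, _ = h.sample(tb)
    np.testing.assert_allclose(avg, truth, atol=1e-12)


def test_epoch_average_periodic_template_exact():
    fs = 7.0
    t = np.arange(7 * 120) / fs
    h = make_hrf(1.0)
    onsets = np.arange(5.0, 100.0, 25.0)  # non-overlapping 20 s epochs
    sig = np.zeros_like(t)
    for o in onsets:
        sig += h.sample(t - o)[0]
    tb, avg, n = rc.epoch_average(sig, fs, onsets)
    assert n == len(onsets)
    np.testing.assert_allclose(avg, h.sample(tb)[0], atol=1e-12)


def test_epoch_average_noise_shrinks_like_sqrt_n(rng):
    fs = 7.0
    nt = 7 * 2000
    sig = rng.standard_normal(nt)
    onsets = np.arange(25.0, 1970.0, 25.0)  # 77 epochs
    tb, avg, n = rc.epoch_average(sig, fs, onsets)
    # residual std after averaging n unit-variance epochs ~ 1/sqrt(n)
    assert avg.std() < 3.0 / np.sqrt(n)
    assert avg.std() > 0.3 / np.sqrt(n)


def test_epoch_average_requires_complete_epoch():
    with pytest.raises(ValueError, match="no complete"):
        rc.epoch_average(np.zeros(70), 7.0, [50.0])  # 10 s recording


def test_epoch_average_off_grid_onsets():
    fs = 7.0
    t = np.arange(7 * 60) / fs
    sig = 2.0 * t  # linear signal: interpolation is exact
    tb, avg, n = rc.epoch_average(sig, fs, [21.3])
    base = tb <= 0.0
    truth = 2.0 * (21.3 + tb)
    truth = truth - truth[base].mean()
    np.testing.assert_allclose(avg, truth, atol=1e-9)


# ---------------------------------------------------------------------------
# CW methods
# ---------------------------------------------------------------------------


def test_lowpass_attenuates_above_cutoff(rng):
    fs = 7.0
    t = np.arange(int(fs * 120)) / fs
    slow = np.sin(2 * np.pi * 0.3 * t)
    fast = np.sin(2 * np.pi * 2.0 * t)
    out = rc._lowpass(slow + fast, fs)
    # the 0.3 Hz component survives, the 2 Hz component is suppressed
    assert np.abs(out - slow)[50:-50].max() < 0.05
    assert rc._lowpass(fast, fs)[50:-50].max() < 0.01
    # cutoff at/above Nyquist is a no-op
    np.testing.assert_array_equal(rc._lowpass(fast, fs, cutoff=3.5), fast)


def _cw_forward_series(table, hbo, hbr, sample_rate=7.0):
    """Series whose M0 follows the homogeneous CW model dM0 = L_eff * dmua."""
    from tdmom import chromophores

    wavelengths = np.array([690.0, 850.0])
    kappa = chromophores.molar_absorption_matrix(wavelengths)
    nt = hbo.size
    vals = np.zeros((2, 2, 3, nt))
    sens = []
    for wi, lam in enumerate(wavelengths):
        tl = interp_two_layer(
            table, 30.0, baseline_absorption(float(lam)), 13.0, wavelength=float(lam)
        )
        sens.append(tl)
        dmua = kappa[wi, 0] * hbo + kappa[wi, 1] * hbr
        vals[1, wi, 0] = tl.total[0] * dmua
    series = MomentTimeSeries(
        values=vals,
        separations=[8.0, 30.0],
        wavelengths=wavelengths,
        sample_rate=sample_rate,
        detector_ids=[0, 0],
    )
    return series, sens


def test_cw_block_average_exact_on_own_model(table):
    fs = 7.0
    t = np.arange(int(fs * 120)) / fs
    h = make_hrf(1.0)
    onsets = np.arange(5.0, 100.0, 25.0)
    hbo = np.zeros_like(t)
    hbr = np.zeros_like(t)
    for o in onsets:
        a, b = h.sample(t - o)
        hbo += a
        hbr += b
    series, sens = _cw_forward_series(table, hbo, hbr)
    # cutoff above Nyquist: the low-pass is the identity, so the method's own
    # forward model is inverted exactly
    rec = rc.cw_block_average(series, 1, onsets, sens, cutoff=np.inf)
    truth_o, truth_r = h.sample(rec.time_base)
    np.testing.assert_allclose(rec.hbo, truth_o, atol=1e-9)
    np.testing.assert_allclose(rec.hbr, truth_r, atol=1e-9)
    assert rec.method == "CW-BA"
    assert rec.meta["n_epochs"] == len(onsets)


def test_cw_glm_exact_recovery(table, rng):
    """LS M0 built as basis regressors times known coefficients plus a scalp
    term proportional to the SS M0 series: the GLM returns both exactly."""
    fs = 7.0
    nt = int(fs * 200)
    t = np.arange(nt) / fs
    onsets = np.arange(5.0, 180.0, 21.0)
    centers = rc.gaussian_basis()
    reg = rc.basis_regressors(t, onsets, centers)
    h = make_hrf(1.0)
    curves = rc._basis_curves(h.time_base, centers)
    # least-squares projection of the canonical HbO curve onto the basis
    beta_o, *_ = np.linalg.lstsq(curves.T, h.hbo, rcond=None)
    beta_r = -beta_o / 3.0

    from tdmom import chromophores

    wavelengths = np.array([690.0, 850.0])
    kappa = chromophores.molar_absorption_matrix(wavelengths)
    ss_m0 = np.sin(2 * np.pi * 0.11 * t) + 0.3 * rng.standard_normal(nt)
    vals = np.zeros((2, 2, 3, nt))
    sens = []
    scalp_coef = [0.7, -0.4]
    for wi, lam in enumerate(wavelengths):
        tl = interp_two_layer(
            table, 30.0, baseline_absorption(float(lam)), 13.0, wavelength=float(lam)
        )
        sens.append(tl)
        dmua = kappa[wi, 0] * (beta_o @ reg) + kappa[wi, 1] * (beta_r @ reg)
        vals[1, wi, 0] = tl.total[0] * dmua + scalp_coef[wi] * ss_m0
        vals[0, wi, 0] = ss_m0
    series = MomentTimeSeries(
        values=vals,
        separations=[8.0, 30.0],
        wavelengths=wavelengths,
        sample_rate=fs,
        detector_ids=[0, 0],
    )
    rec = rc.cw_glm(series, 1, 0, onsets, sens)
    tb = rec.time_base
    ec = rc._basis_curves(tb, centers)
    base = tb <= 0.0
    truth_o = beta_o @ ec
    truth_o = truth_o - truth_o[base].mean()
    truth_r = beta_r @ ec
    truth_r = truth_r - truth_r[base].mean()
    np.testing.assert_allclose(rec.hbo, truth_o, atol=1e-9)
    np.testing.assert_allclose(rec.hbr, truth_r, atol=1e-9)


def test_cw_glm_rank_deficient_design_raises(table):
    fs = 7.0
    nt = int(fs * 120)
    vals = np.zeros((2, 2, 3, nt))  # SS channel identically zero
    series = MomentTimeSeries(
        values=vals,
        separations=[8.0, 30.0],
        wavelengths=[690.0, 850.0],
        sample_rate=fs,
        detector_ids=[0, 0],
    )
    mua = [baseline_absorption(l) for l in (690.0, 850.0)]
    sens = [
        interp_two_layer(table, 30.0, m, 13.0, wavelength=l)
        for m, l in zip(mua, (690.0, 850.0))
    ]
    with pytest.raises(np.linalg.LinAlgError, match="rank-deficient"):
        rc.cw_glm(series, 1, 0, np.arange(5.0, 100.0, 21.0), sens)


# ---------------------------------------------------------------------------
# TD moment GLM
# ---------------------------------------------------------------------------


def _toy_glm_problem(rng, nt=20, nb=3):
    """Small random block system for the structured-vs-dense oracle."""
    blocks = [rng.normal(size=(nt, 2 + 2 * nb)) for _ in range(6)]
    root = rng.normal(size=(6, 6))
    Z = root @ root.T + 6 * np.eye(6)
    beta = rng.normal(size=2 + 2 * nb)
    y = [b @ beta for b in blocks]
    return blocks, y, Z, beta


def test_kronecker_solver_structured_equals_dense(rng):
    blocks, y, Z, _ = _toy_glm_problem(rng)
    b1 = rc.solve_kronecker_wls(blocks, y, Z, dense=False)
    b2 = rc.solve_kronecker_wls(blocks, y, Z, dense=True)
    np.testing.assert_allclose(b1, b2, rtol=1e-8)


def test_kronecker_solver_structured_equals_dense_with_row_scales(rng):
    blocks, y, Z, _ = _toy_glm_problem(rng)
    scales = np.repeat(MOMENT_SCALES, 2)
    Zs = Z / np.outer(scales, scales)  # realistic moment magnitudes
    ys = [yi / s for yi, s in zip(y, scales)]
    bl = [b / s for b, s in zip(blocks, scales)]
    b1 = rc.solve_kronecker_wls(bl, ys, Zs, dense=False, row_scales=scales)
    b2 = rc.solve_kronecker_wls(bl, ys, Zs, dense=True, row_scales=scales)
    np.testing.assert_allclose(b1, b2, rtol=1e-8)


def test_kronecker_solver_exact_recovery(rng):
    blocks, y, Z, beta = _toy_glm_problem(rng)
    got = rc.solve_kronecker_wls(blocks, y, Z)
    np.testing.assert_allclose(got, beta, rtol=1e-9, atol=1e-12)


def test_kronecker_solver_validation(rng):
    blocks, y, Z, _ = _toy_glm_problem(rng)
    with pytest.raises(ValueError, match="6x6"):
        rc.solve_kronecker_wls(blocks, y, Z[:4, :4])
    with pytest.raises(ValueError, match="row_scales"):
        rc.solve_kronecker_wls(blocks, y, Z, row_scales=np.ones(3))


def _glm_forward_session(table, rng, fs=7.0, duration=200.0):
    """Series whose LS moments follow the TD GLM forward model exactly."""
    nt = int(fs * duration)
    t = np.arange(nt) / fs
    onsets = np.arange(5.0, duration - 20.0, 21.0)
    wavelengths = np.array([690.0, 850.0])
    sens = {}
    for rho_key, rho in (("ss", 8.0), ("ls", 30.0)):
        sens[rho_key] = [
            interp_two_layer(
                table, rho, baseline_absorption(float(l)), 13.0, wavelength=float(l)
            )
            for l in wavelengths
        ]
    ss_m0 = np.sin(2 * np.pi * 0.09 * t) + 0.2 * rng.standard_normal(nt)
    vals = np.zeros((2, 2, 3, nt))
    vals[0, :, 0] = ss_m0  # both wavelengths share the SS trace for simplicity
    draft = MomentTimeSeries(
        values=vals,
        separations=[8.0, 30.0],
        wavelengths=wavelengths,
        sample_rate=fs,
        detector_ids=[0, 0],
    )
    blocks, _, centers = rc.td_glm_design(
        draft, 1, 0, onsets, sens["ls"], sens["ss"]
    )
    beta_true = rng.normal(size=blocks[0].shape[1])
    i = 0
    for n in range(3):
        for wi in range(2):
            vals[1, wi, n] = blocks[i] @ beta_true
            i += 1
    series = MomentTimeSeries(
        values=vals,
        separations=[8.0, 30.0],
        wavelengths=wavelengths,
        sample_rate=fs,
        detector_ids=[0, 0],
    )
    return series, onsets, sens, centers, beta_true


@pytest.mark.parametrize("cov", ["identity", "ZT"])
def test_td_glm_exact_recovery(table, rng, cov):
    series, onsets, sens, centers, beta_true = _glm_forward_session(table, rng)
    hrf, beta = rc.td_glm(
        series,
        1,
        0,
        onsets,
        sens["ls"],
        sens["ss"],
        covariance_source=cov,
        photon_budget=1e5,
        table=table,
    )
    scale = np.abs(beta_true).max()
    np.testing.assert_allclose(beta, beta_true, atol=1e-9 * scale)
    # the recovered curves equal the basis reconstruction of the true beta
    curves = rc._basis_curves(hrf.time_base, centers)
    base = hrf.time_base <= 0.0
    truth = beta_true[2::2] @ curves
    truth = truth - truth[base].mean()
    np.testing.assert_allclose(hrf.hbo, truth, atol=1e-9 * np.abs(truth).max())
    assert hrf.covariance_source == ("identity" if cov == "identity" else "ZT")


def test_td_glm_beta_layout(table, rng):
    series, onsets, sens, centers, beta_true = _glm_forward_session(table, rng)
    _, beta = rc.td_glm(
        series, 1, 0, onsets, sens["ls"], sens["ss"], covariance_source="identity"
    )
    assert beta.size == 2 + 2 * centers.size
    with pytest.raises(ValueError, match="unknown covariance source"):
        rc.td_glm(
            series, 1, 0, onsets, sens["ls"], sens["ss"], covariance_source="bogus"
        )


def test_td_glm_zt_needs_table(table, rng):
    series, onsets, sens, *_ = _glm_forward_session(table, rng, duration=60.0)
    with pytest.raises(ValueError, match="ZT needs"):
        rc.td_glm(series, 1, 0, onsets, sens["ls"], sens["ss"], covariance_source="ZT")


# ---------------------------------------------------------------------------
# channel selection and the method suite
# ---------------------------------------------------------------------------


def _series_with_separations(seps):
    nt = 10
    return MomentTimeSeries(
        values=np.zeros((len(seps), 2, 3, nt)),
        separations=seps,
        wavelengths=[690.0, 850.0],
        sample_rate=7.0,
        detector_ids=[0] * len(seps),
    )


def test_detector_channel_selection_ties():
    s = _series_with_separations([8.0, 29.0, 31.0])
    ss, ls = rc._detector_channels(s, 0)
    assert (ss, ls) == (0, 1)  # tie 29/31 -> smaller separation
    s = _series_with_separations([8.0, 28.0, 32.0])
    assert rc._detector_channels(s, 0) == (0, 1)
    s = _series_with_separations([6.0, 8.0, 34.0])
    ss, ls = rc._detector_channels(s, 0)
    assert ss == 0 and ls is None  # 34 mm excluded, smallest SS wins


def test_run_method_suite_basics(table):
    sess = simulate_session(
        table, ProbeGeometry(n_detectors=2), duration=60.0, seed=3
    )
    assert rc.run_method_suite(sess, table, methods=()) == []
    res = rc.run_method_suite(sess, table, methods=("TD-LS", "CW-BA", "NOPE"))
    by_method = {r.method: r for r in res if r.detector == 0}
    assert by_method["NOPE"].error is not None
    assert "unknown method" in by_method["NOPE"].error
    for m in ("TD-LS", "CW-BA"):
        assert by_method[m].error is None, by_method[m].error
        assert by_method[m].hrf is not None
        assert by_method[m].hrf.time_base[0] == pytest.approx(-2.0)


def test_run_method_suite_deterministic(table):
    sess = simulate_session(
        table, ProbeGeometry(n_detectors=1), duration=60.0, seed=5
    )
    a = rc.run_method_suite(sess, table, methods=("TD-GLM",))
    b = rc.run_method_suite(sess, table, methods=("TD-GLM",))
    np.testing.assert_array_equal(a[0].hrf.hbo, b[0].hrf.hbo)


def test_run_method_suite_all_methods_produce_hrfs(table):
    sess = simulate_session(
        table, ProbeGeometry(n_detectors=1), duration=120.0, seed=11
    )
    res = rc.run_method_suite(sess, table)
    assert len(res) == len(rc.METHODS)
    for r in res:
        assert r.error is None, (r.method, r.error)
        assert np.all(np.isfinite(r.hrf.hbo))
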