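"""Generator behaviour: geometry, feature identities, forward model."""

import numpy as np
import pandas as pd
import pytest

import wmbold as w
from wmbold.synthetic import ConfigError, _ar1, _narrowband


# ---------------------------------------------------------------------------
# config validation


def test_linearization_bound_rejects_large_susceptibility():
    with pytest.raises(ConfigError, match="linearization"):
        w.SyntheticConfig(beta_suscept=5.0)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(mwf_assoc_mean=1.5),
        dict(mwf_proj_sd=-0.1),
        dict(tr_s=0.0),
        dict(n_assoc_bundles=-1),
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigError):
        w.SyntheticConfig(**kwargs)


def test_config_yaml_round_trip(tmp_path):
    cfg = w.SyntheticConfig(seed=7, moderation_truth=(0.0, 0.5, -0.2, -0.3))
    cfg.to_yaml(tmp_path / "c.yaml")
    back = w.SyntheticConfig.from_yaml(tmp_path / "c.yaml")
    assert back == cfg


# ---------------------------------------------------------------------------
# parcellation


def test_parcellation_two_gm_parcels_exact_labels():
    cfg = w.SyntheticConfig(
        seed=0, grid_shape=(20, 20, 20), n_gm_parcels=2,
        n_pseudo_gm_parcels=0, n_assoc_bundles=1, n_proj_bundles=0,
    )
    parc = w.make_parcellation(cfg)
    assert set(np.unique(parc.labels)) == {0, 1, 2, parc.wm_label}
    assert parc.parcel_labels == frozenset({1, 2})


def test_parcellation_deterministic():
    cfg = w.SyntheticConfig(seed=5, grid_shape=(20, 20, 20), n_gm_parcels=4,
                            n_pseudo_gm_parcels=1)
    a = w.make_parcellation(cfg)
    b = w.make_parcellation(cfg)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_parcellation_sizing_error():
    cfg = w.SyntheticConfig(seed=0, grid_shape=(3, 3, 3), n_gm_parcels=10)
    with pytest.raises(ConfigError, match="too small"):
        w.make_parcellation(cfg)


def test_parcellation_has_interior_wm_and_pseudo_gm():
    cfg = w.SyntheticConfig(seed=0, grid_shape=(24, 24, 24), n_gm_parcels=4,
                            n_pseudo_gm_parcels=2)
    parc = w.make_parcellation(cfg)
    assert (parc.labels == parc.wm_label).sum() > 0
    assert len(parc.pseudo_gm_labels) == 2
    assert parc.pseudo_gm_labels <= parc.parcel_labels


# ---------------------------------------------------------------------------
# streamlines


def test_streamline_endpoints_inside_designated_parcels(small_geometry):
    _, parc, sls = small_geometry
    for sl, b in zip(sls.streamlines, sls.bundle_of_streamline):
        pair = set()
        for endpoint in (sl[0], sl[-1]):
            ijk = parc.world_to_voxel(endpoint)[0]
            pair.add(int(parc.labels[tuple(ijk)]))
        assert frozenset(pair) == sls.pairs[b]


def test_streamline_point_spacing_bounded(small_geometry):
    cfg, _, sls = small_geometry
    for sl in sls.streamlines:
        steps = np.linalg.norm(np.diff(sl, axis=0), axis=1)
        assert steps.max() <= cfg.voxel_size_mm + 1e-9


def test_projection_ground_truth_uses_pseudo_gm(small_geometry):
    _, parc, sls = small_geometry
    for pair, kind in zip(sls.pairs, sls.kinds):
        has_pseudo = bool(pair & parc.pseudo_gm_labels)
        assert (kind == "projection") == has_pseudo


def test_streamlines_deterministic(small_geometry):
    cfg, parc, sls = small_geometry
    again = w.make_streamlines(cfg, parc)
    for a, b in zip(sls.streamlines, again.streamlines):
        np.testing.assert_array_equal(a, b)


def test_tck_round_trip_preserves_coordinates(tmp_path, small_geometry):
    _, _, sls = small_geometry
    path = tmp_path / "fibers.tck"
    w.save_streamlines(sls.streamlines, path)
    back = w.load_streamlines(path)
    assert len(back) == len(sls.streamlines)
    for a, b in zip(sls.streamlines, back):
        np.testing.assert_allclose(a, b, atol=1e-5)  # float32 storage


# ---------------------------------------------------------------------------
# hemodynamic features


def test_direct_substitution_identities():
    feats = w.HemoFeatures.from_components(cbv=2.0, mtt=4.0, oef=0.4, alpha=1.0)
    assert feats.cbf == pytest.approx(0.5)
    assert feats.cmro2 == pytest.approx(0.2)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_emitted_tables_obey_identities_exactly(seed):
    cfg = w.SyntheticConfig(seed=seed, n_assoc_bundles=30, n_proj_bundles=10)
    df = w.simulate_hemo_features(cfg)
    np.testing.assert_allclose(df.cbf, df.cbv / df.mtt, rtol=1e-15)
    np.testing.assert_allclose(df.cmro2, cfg.alpha * df.oef * df.cbf, rtol=1e-15)
    assert (df.cbv > 0).all() and (df.mtt > 0).all()
    assert ((df.oef > 0) & (df.oef < 1)).all()


def test_degenerate_oef_gives_zero_cmro2():
    cfg = w.SyntheticConfig(seed=0, oef_mean=0.0, oef_sd=0.0,
                            n_assoc_bundles=10, n_proj_bundles=5)
    df = w.simulate_hemo_features(cfg)
    assert (df.cmro2 == 0).all()


def test_features_deterministic(default_config):
    a = w.simulate_hemo_features(default_config)
    b = w.simulate_hemo_features(default_config)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# BOLD forward model


def test_noise_free_constant_series(quiet_config):
    df = w.simulate_hemo_features(quiet_config)
    row = df.iloc[0]
    s = w.simulate_bold(row, quiet_config)
    expected = quiet_config.baseline * (
        1 - quiet_config.te_s * quiet_config.beta_suscept * row.oef * row.cbv
    )
    np.testing.assert_allclose(s.values, expected, rtol=1e-12)
    assert s.baseline == quiet_config.baseline


def test_bold_deterministic(default_config):
    df = w.simulate_hemo_features(default_config)
    a = w.simulate_bold(df.iloc[0], default_config)
    b = w.simulate_bold(df.iloc[0], default_config)
    np.testing.assert_array_equal(a.values, b.values)


def test_ar1_marginal_sd_and_timescale():
    rng = np.random.default_rng(0)
    x = _ar1(rng, 200_000, sd=0.05, tau_s=10.0, dt_s=0.72)
    assert x.std() == pytest.approx(0.05, rel=0.02)
    lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
    assert lag1 == pytest.approx(np.exp(-0.72 / 10.0), abs=0.01)


def test_narrowband_component_concentrates_at_target_frequency():
    rng = np.random.default_rng(1)
    x = _narrowband(rng, 1200, dt_s=0.72, f0_hz=0.055, width_hz=0.005, sd=0.05)
    assert x.std() == pytest.approx(0.05, rel=1e-9)
    freqs = np.fft.rfftfreq(1200, d=0.72)
    power = np.abs(np.fft.rfft(x)) ** 2
    f_dominant = freqs[np.argmax(power)]
    assert abs(f_dominant - 0.055) < 0.01


def test_bold_variance_matches_supply_prediction_over_seeds():
    """Monte-Carlo check of the first-order variance propagation: the
    variance of the recovered δR2* fluctuation matches
    β²(CBV²σ²_OEF + OEF²σ²_CBV) within 3 standard errors over seeds."""
    cfg = w.SyntheticConfig(seed=0, bump_amp=0.0, noise_sd=0.0)
    df = w.simulate_hemo_features(cfg)
    row = df.iloc[0]
    pred = w.predict_var_supply(row.oef, row.cbv, cfg.oef_fluct_sd**2,
                                cfg.cbv_fluct_sd**2, cfg.beta_suscept)
    true_mean = cfg.beta_suscept * row.oef * row.cbv
    per_seed = []
    for k in range(100):
        s = w.simulate_bold(row, cfg, rng=cfg.rng(stream=100 + k))
        dr2 = w.delta_r2star_from_signal(s)
        per_seed.append(np.mean((dr2 - true_mean) ** 2))
    per_seed = np.array(per_seed)
    se = per_seed.std(ddof=1) / np.sqrt(per_seed.size)
    assert abs(per_seed.mean() - pred) < 3 * se


def test_voxel_block_shares_bundle_signal(default_config):
    df = w.simulate_hemo_features(default_config)
    block = w.simulate_voxel_block(df.iloc[0], default_config, n_voxels=20)
    assert block.shape == (20, default_config.n_timepoints)
    # voxels differ only by i.i.d. noise around a common signal
    spread = block.std(axis=0)
    assert spread.mean() == pytest.approx(
        default_config.noise_sd * default_config.baseline, rel=0.1
    )


# ---------------------------------------------------------------------------
# moderation generator


def test_moderation_table_noise_free_recovery():
    truth = (0.0, 0.5, -0.2, -0.3)
    cfg = w.SyntheticConfig(seed=0, moderation_truth=truth,
                            moderation_resid_sd=0.0)
    table = w.simulate_moderation_table(cfg)
    assert len(table) == cfg.n_assoc_bundles + cfg.n_proj_bundles
    fit = w.fit_moderation(table, response="falff_z", predictor="predictor_z",
                           moderator="mwf_z", z_score=False)
    np.testing.assert_allclose(fit.beta, truth, atol=1e-10)


def test_moderation_table_null_truth_centred_on_zero():
    betas = []
    for k in range(100):
        cfg = w.SyntheticConfig(seed=k, moderation_truth=(0.0, 0.0, 0.0, 0.0),
                                moderation_resid_sd=1.0)
        t = w.simulate_moderation_table(cfg)
        fit = w.fit_moderation(t, response="falff_z", predictor="predictor_z",
                               moderator="mwf_z", z_score=False)
        betas.append(fit.beta)
    mean = np.array(betas).mean(axis=0)
    # standard error of each mean estimate is ~ 1/sqrt(160*100)
    assert np.all(np.abs(mean) < 3 / np.sqrt(160 * 100) * 1.5)


def test_moderation_requires_truth(default_config):
    with pytest.raises(ConfigError, match="moderation_truth"):
        w.simulate_moderation_table(default_config)


# ---------------------------------------------------------------------------
# HRF kernel


@pytest.mark.parametrize("depth", [0.0, 0.25, 0.5])
def test_hrf_kernel_dip_construction(depth):
    k = w.HrfKernel.double_gamma(dip_depth=depth)
    assert k.values[0] == 0.0
    assert k.values.max() == pytest.approx(1.0)
    pre_peak = k.time_grid_s < k.peak_time_s
    assert k.values[pre_peak].min() == pytest.approx(-depth, abs=1e-9)
    assert 0 < k.dip_time_s < k.peak_time_s


def test_task_run_block_locked_response(quiet_config):
    paradigm = w.paper_paradigm()
    run = w.simulate_task_run(quiet_config, paradigm, amplitude_pct=1.0,
                              noise_sd=0.0)
    on = paradigm.stimulus_mask()
    np.testing.assert_allclose(run.values[on], quiet_config.baseline * 1.01)
    np.testing.assert_allclose(run.values[~on], quiet_config.baseline)


def test_task_run_zero_amplitude_is_baseline_noise():
    """With no response, stimulus-on and stimulus-off samples are
    statistically indistinguishable (few rejections across seeds)."""
    from scipy import stats

    paradigm = w.paper_paradigm()
    on = paradigm.stimulus_mask()
    rejections = 0
    for seed in range(20):
        cfg = w.SyntheticConfig(seed=seed, noise_sd=0.002)
        run = w.simulate_task_run(cfg, paradigm, amplitude_pct=0.0)
        _, p = stats.ttest_ind(run.values[on], run.values[~on])
        rejections += p < 0.05
    assert rejections <= 4
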