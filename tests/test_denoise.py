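"""Strategy-level checks: thresholding primitives against closed forms,
each strategy against an independent re-implementation, and the
configuration contract."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tomowave import (DenoiseConfig, apply_w1, apply_w2, apply_w3, apply_w4,
                      denoise_image, denoise_slices, forward_ddwt,
                      inverse_ddwt, median_sigma, soft_threshold,
                      subband_threshold, subband_thresholds,
                      universal_threshold)
from tomowave.denoise import MAD_SCALE


# ---------------------------------------------------------------- primitives

def test_soft_threshold_three_cases():
    w = np.array([-2.0, -0.5, 0.0, 0.5, 3.0])
    assert np.array_equal(soft_threshold(w, 1.0), [-1.0, 0.0, 0.0, 0.0, 2.0])


def test_soft_threshold_degenerate_lambdas():
    w = np.array([[1.0, -2.0], [0.25, 0.0]])
    assert np.array_equal(soft_threshold(w, 0.0), w)
    assert np.array_equal(soft_threshold(w, np.inf), np.zeros_like(w))
    assert np.array_equal(soft_threshold(w, 10.0), np.zeros_like(w))
    with pytest.raises(ValueError):
        soft_threshold(w, -0.1)


@settings(derandomize=True, max_examples=50)
@given(hnp.arrays(np.float64, (7,), elements=st.floats(-50, 50)),
       st.floats(0, 20))
def test_soft_threshold_nonexpansive_and_odd(w, lam):
    out = soft_threshold(w, lam)
    assert np.all(np.abs(out) <= np.abs(w) + 1e-12)
    assert np.all(out * w >= 0)  # sign preserved or zeroed
    assert np.allclose(soft_threshold(-w, lam), -out)


def test_universal_threshold_closed_forms():
    assert universal_threshold(1.0, 1) == 0.0
    assert np.isclose(universal_threshold(2.0, np.e ** 2), 4.0)
    assert np.isclose(universal_threshold(1.0, 65536),
                      np.sqrt(2.0 * np.log(65536.0)))
    with pytest.raises(ValueError):
        universal_threshold(1.0, 0)
    with pytest.raises(ValueError):
        universal_threshold(-1.0, 10)


def test_median_sigma_small_samples():
    assert np.isclose(median_sigma(np.full((4, 4), -3.0)), 3.0 / MAD_SCALE)
    assert np.isclose(median_sigma(np.array([-1.0, 0.0, 1.0])), 1.0 / MAD_SCALE)
    # even count: mean of the two central order statistics
    assert np.isclose(median_sigma(np.array([1.0, 2.0, 3.0, 4.0])),
                      2.5 / MAD_SCALE)
    with pytest.raises(ValueError):
        median_sigma(np.array([]))


def test_median_sigma_pools_band_lists():
    a = np.array([1.0, 1.0])
    b = np.array([3.0])
    assert np.isclose(median_sigma([a, b]), 1.0 / MAD_SCALE)


def test_subband_threshold_quotient_and_degenerates():
    assert subband_threshold(1.0, 2.0) == 0.5
    assert subband_threshold(0.0, 2.0) == 0.0
    assert np.isinf(subband_threshold(1.0, 0.0))
    with pytest.raises(ValueError):
        subband_threshold(-1.0, 1.0)


# ---------------------------------------------------------------- strategies

def test_w1_matches_flat_reimplementation(bank, rng):
    x = rng.normal(size=(32, 32)) + np.linspace(0, 4, 32)[None, :]
    cfg = DenoiseConfig(strategy="w1", noise_sigma=0.5)
    pyr = forward_ddwt(x, 3, bank)
    out = apply_w1(pyr, cfg)
    lam = 0.5 * np.sqrt(2.0 * np.log(x.size))
    for key, band in pyr.details.items():
        expect = np.sign(band) * np.maximum(np.abs(band) - lam, 0.0)
        assert np.allclose(out.details[key], expect, atol=1e-12)
    assert np.array_equal(out.approximation, pyr.approximation)


def test_w1_zero_lambda_is_identity(bank, rng):
    pyr = forward_ddwt(rng.normal(size=(16, 16)), 2, bank)
    out = apply_w1(pyr, DenoiseConfig(strategy="w1", lam=0.0))
    for key in pyr.details:
        assert np.array_equal(out.details[key], pyr.details[key])


def test_w2_zero_all_levels_gives_pure_approximation(bank, rng):
    x = rng.normal(size=(32, 32))
    pyr = forward_ddwt(x, 3, bank)
    cfg = DenoiseConfig(strategy="w2", zero_levels=frozenset({1, 2, 3}))
    with pytest.warns(UserWarning, match="approximation"):
        out = apply_w2(pyr, cfg)
    approx_only = pyr.copy()
    for key in approx_only.details:
        approx_only.details[key] = np.zeros_like(approx_only.details[key])
    assert np.allclose(inverse_ddwt(out, bank),
                       inverse_ddwt(approx_only, bank), atol=1e-12)


def test_w2_noise_free_config_is_identity(bank, rng):
    pyr = forward_ddwt(rng.normal(size=(16, 16)), 2, bank)
    cfg = DenoiseConfig(strategy="w2", levels=2, zero_levels=frozenset(),
                        noise_sigma=0.0)
    out = apply_w2(pyr, cfg)
    for key in pyr.details:
        assert np.array_equal(out.details[key], pyr.details[key])


def test_w2_zeroing_is_idempotent(bank, rng):
    pyr = forward_ddwt(rng.normal(size=(32, 32)), 3, bank)
    cfg = DenoiseConfig(strategy="w2", noise_sigma=0.1)
    once = apply_w2(pyr, cfg)
    for d in (1, 2):
        assert np.array_equal(once.band(1, d), np.zeros((32, 32)))
    twice = apply_w2(once, cfg)
    for d in (1, 2):
        assert np.array_equal(twice.band(1, d), np.zeros((32, 32)))


def test_w2_nonexpansive(bank, rng):
    pyr = forward_ddwt(rng.normal(size=(32, 32)), 3, bank)
    out = apply_w2(pyr, DenoiseConfig())
    for key in pyr.details:
        assert np.all(np.abs(out.details[key])
                      <= np.abs(pyr.details[key]) + 1e-12)


def test_w2_thresholds_follow_subband_formula(bank, rng):
    pyr = forward_ddwt(rng.normal(size=(32, 32)), 3, bank)
    cfg = DenoiseConfig(strategy="w2")
    ts = subband_thresholds(pyr, cfg)
    for j in (2, 3):
        pooled = np.concatenate([pyr.band(j, d).ravel() for d in (1, 2)])
        sig = np.median(np.abs(pooled)) / MAD_SCALE
        assert np.isclose(ts.sigma_per_level[j], sig)
        for d in (1, 2):
            assert np.isclose(ts.per_band[(j, d)],
                              sig ** 2 / np.std(pyr.band(j, d)))
    assert all(np.isinf(ts.per_band[(1, d)]) for d in (1, 2))


def test_w3_constant_band_unchanged(bank):
    pyr = forward_ddwt(np.linspace(0, 1, 64).reshape(8, 8), 1, bank)
    pyr.details[(1, 1)] = np.full((8, 8), 0.7)
    cfg = DenoiseConfig(strategy="w3", levels=1, zero_levels=frozenset(),
                        modify_levels=frozenset({1}), neighborhood=3)
    out = apply_w3(pyr, cfg)
    assert np.allclose(out.band(1, 1), 0.7)


def test_w3_matches_double_loop_mean(bank, rng):
    pyr = forward_ddwt(rng.normal(size=(9, 9)), 1, bank)
    cfg = DenoiseConfig(strategy="w3", levels=1, zero_levels=frozenset(),
                        modify_levels=frozenset({1}), neighborhood=5)
    out = apply_w3(pyr, cfg)
    band = pyr.band(1, 2)
    padded = np.pad(band, 2, mode="reflect")
    expect = np.empty_like(band)
    for i in range(9):
        for j in range(9):
            expect[i, j] = padded[i:i + 5, j:j + 5].mean()
    assert np.allclose(out.band(1, 2), expect, atol=1e-12)


def test_w3_impulse_spreads_over_window(bank):
    pyr = forward_ddwt(np.zeros((15, 15)) + np.eye(15), 1, bank)
    band = np.zeros((15, 15))
    band[7, 7] = 25.0
    pyr.details[(1, 2)] = band
    cfg = DenoiseConfig(strategy="w3", levels=1, zero_levels=frozenset(),
                        modify_levels=frozenset({1}), neighborhood=5)
    out = apply_w3(pyr, cfg)
    assert np.allclose(out.band(1, 2)[5:10, 5:10], 1.0)
    assert np.allclose(out.band(1, 2)[0:3], 0.0)


def test_w3_neighborhood_too_large(bank, rng):
    pyr = forward_ddwt(rng.normal(size=(8, 8)), 1, bank)
    cfg = DenoiseConfig(strategy="w3", levels=1, zero_levels=frozenset(),
                        modify_levels=frozenset({1}), neighborhood=9)
    with pytest.raises(ValueError, match="neighborhood"):
        apply_w3(pyr, cfg)


def _literal_csr(pyr, modify_levels):
    """Step-by-step modulus/direction/normalize/multiply/project chain."""
    out = pyr.copy()
    for j in sorted(modify_levels, reverse=True):
        bands = out.level_bands(j)
        mod = np.sqrt(sum(b ** 2 for b in bands))
        safe = np.where(mod == 0, 1.0, mod)
        unit = [np.where(mod == 0, 0.0, b / safe) for b in bands]
        coarse = np.sqrt(sum(b ** 2 for b in out.level_bands(j + 1)))
        norm = coarse / coarse.max()
        mod_tilde = norm * mod
        for d, u in enumerate(unit, start=1):
            out.details[(j, d)] = mod_tilde * u
    return out


def test_w4_fused_equals_literal_chain(bank, rng):
    x = rng.normal(size=(16, 16))
    pyr = forward_ddwt(x, 3, bank)
    pyr.details[(1, 1)][3:5, 3:5] = 0.0  # exercise the 0/0 positions
    pyr.details[(1, 2)][3:5, 3:5] = 0.0
    cfg = DenoiseConfig(strategy="w4", modify_levels=frozenset({1, 2}))
    fused = apply_w4(pyr, cfg)
    literal = _literal_csr(pyr, {1, 2})
    for key in pyr.details:
        assert np.max(np.abs(fused.details[key] - literal.details[key])) <= 1e-10


def test_w4_constant_coarse_modulus_is_identity(bank):
    pyr = forward_ddwt(np.linspace(0, 1, 256).reshape(16, 16), 2, bank)
    pyr.details[(2, 1)] = np.full((16, 16), 3.0)
    pyr.details[(2, 2)] = np.full((16, 16), 4.0)
    cfg = DenoiseConfig(strategy="w4", levels=2, modify_levels=frozenset({1}))
    out = apply_w4(pyr, cfg)
    for d in (1, 2):
        assert np.allclose(out.band(1, d), pyr.band(1, d), atol=1e-12)


def test_w4_zero_coarse_position_zeroes_fine(bank, rng):
    pyr = forward_ddwt(rng.normal(size=(16, 16)), 2, bank)
    pyr.details[(2, 1)][5, 5] = 0.0
    pyr.details[(2, 2)][5, 5] = 0.0
    cfg = DenoiseConfig(strategy="w4", levels=2, modify_levels=frozenset({1}))
    out = apply_w4(pyr, cfg)
    assert out.band(1, 1)[5, 5] == 0.0
    assert out.band(1, 2)[5, 5] == 0.0


def test_w4_blank_coarse_level_warns_and_zeroes(bank, rng):
    pyr = forward_ddwt(rng.normal(size=(16, 16)), 2, bank)
    pyr.details[(2, 1)] = np.zeros((16, 16))
    pyr.details[(2, 2)] = np.zeros((16, 16))
    cfg = DenoiseConfig(strategy="w4", levels=2, modify_levels=frozenset({1}))
    with pytest.warns(UserWarning, match="identically zero"):
        out = apply_w4(pyr, cfg)
    assert np.array_equal(out.band(1, 1), np.zeros((16, 16)))


def test_w4_rejects_coarsest_level(bank, rng):
    pyr = forward_ddwt(rng.normal(size=(16, 16)), 2, bank)
    cfg = DenoiseConfig(strategy="w4", levels=2, modify_levels=frozenset({2}))
    with pytest.raises(ValueError, match="coarser"):
        apply_w4(pyr, cfg)


# ------------------------------------------------------------- whole filter

def test_denoise_noop_roundtrip(rng):
    x = rng.normal(size=(32, 32))
    out = denoise_image(x, DenoiseConfig(strategy="w1", lam=0.0))
    assert np.max(np.abs(out - x)) <= 1e-8


def test_denoise_slices_equals_per_slice_loop(rng):
    vol = rng.normal(size=(16, 6, 16))
    cfg = DenoiseConfig(strategy="w2", levels=2, zero_levels=frozenset({1}))
    out = denoise_slices(vol, cfg, axis=1)
    for y in range(6):
        assert np.allclose(out[:, y, :], denoise_image(vol[:, y, :], cfg),
                           atol=1e-12)


def test_default_config_is_modified_shrinkage_filter():
    cfg = DenoiseConfig()
    assert cfg.strategy == "w2"
    assert cfg.levels == 3
    assert cfg.zero_levels == frozenset({1})
    assert cfg.threshold_mode == "subband"
    assert cfg.label == "w2_1"


def test_config_labels():
    assert DenoiseConfig(strategy="w2",
                         zero_levels=frozenset({1, 2})).label == "w2_12"
    assert DenoiseConfig(strategy="w3", zero_levels=frozenset(),
                         modify_levels=frozenset({1})).label == "w3_1"
    assert DenoiseConfig(strategy="w1").label == "w1"


def test_config_validation():
    with pytest.raises(ValueError):
        DenoiseConfig(strategy="w9")
    with pytest.raises(ValueError):
        DenoiseConfig(zero_levels=frozenset({4}))
    with pytest.raises(ValueError):
        DenoiseConfig(neighborhood=4)
    with pytest.raises(ValueError):
        DenoiseConfig(threshold_mode="hard")


def test_config_yaml_roundtrip():
    cfg = DenoiseConfig(strategy="w3", zero_levels=frozenset(),
                        modify_levels=frozenset({1, 2}), neighborhood=7,
                        boundary="mirror")
    assert DenoiseConfig.from_yaml(cfg.to_yaml()) == cfg


def test_denoise_improves_snr_on_noisy_phantom_slice(rng):
    """2-D sanity run of the flagship filter on one noisy phantom slice."""
    from tomowave import add_noise_to_snr, make_phantom, snr, support_mask

    ph = make_phantom()
    sl = ph[:, 32, :]
    mask = support_mask(ph)[:, 32, :]
    noisy = add_noise_to_snr(sl, 0.1, seed=7, mask=mask)
    den = denoise_image(noisy, DenoiseConfig())
    assert snr(den, sl, mask) > snr(noisy, sl, mask)
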