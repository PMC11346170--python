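"""Copula machinery, marginal fitting and cohort generation."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from ivcm_dryeye import scoring
from ivcm_dryeye.cohort import (
    LATENT_VARS,
    generate_cohort,
    generate_cohort_frame,
    records_to_frame,
)
from ivcm_dryeye.config import ConfigError, config_from_dict, default_config
from ivcm_dryeye.copula import (
    CalibrationError,
    calibrate_latent_correlation,
    latent_from_spearman_continuous,
    nearest_positive_definite,
)
from ivcm_dryeye.marginals import MarginalError, fit_binned_lognorm, fit_truncnorm


# --- nearest correlation matrix -------------------------------------------

def test_nearest_psd_identity_unchanged():
    eye = np.eye(4)
    assert np.allclose(nearest_positive_definite(eye), eye, atol=1e-10)


def test_nearest_psd_idempotent_on_valid_correlation():
    r = np.array([[1.0, 0.3], [0.3, 1.0]])
    assert np.allclose(nearest_positive_definite(r), r, atol=1e-8)


def test_nearest_psd_repairs_indefinite_matrix():
    # an impossible correlation pattern: three mutually strong negatives
    bad = np.array(
        [[1.0, -0.9, -0.9], [-0.9, 1.0, -0.9], [-0.9, -0.9, 1.0]]
    )
    assert np.linalg.eigvalsh(bad).min() < 0
    fixed = nearest_positive_definite(bad)
    w = np.linalg.eigvalsh(fixed)
    assert w.min() >= -1e-10
    assert np.allclose(np.diag(fixed), 1.0)
    assert np.allclose(fixed, fixed.T)


def test_nearest_psd_rejects_bad_input():
    with pytest.raises(ValueError):
        nearest_positive_definite(np.ones((2, 3)))
    with pytest.raises(ValueError):
        nearest_positive_definite(np.array([[1.0, 0.5], [0.1, 1.0]]))


# --- latent-correlation calibration ---------------------------------------

def test_calibrate_zero_target_returns_near_zero():
    latent = calibrate_latent_correlation(0.0, n_calib=20_000, seed=1)
    assert abs(latent) <= 0.02


def test_calibrate_continuous_recovers_sine_formula():
    latent = calibrate_latent_correlation(0.3, n_calib=100_000, seed=2)
    assert abs(latent - latent_from_spearman_continuous(0.3)) <= 0.02


def test_calibrate_binned_target_inflates_latent_and_resimulates():
    margin = fit_binned_lognorm(1.7, 0.7)

    def binned(z):
        return scoring.ic_subscore_values(margin.from_z(z))

    latent = calibrate_latent_correlation(0.3, binned, None, n_calib=100_000, seed=3)
    assert latent > 0.3  # discretisation attenuates, so the latent must inflate
    # independent re-simulation at the returned latent value
    rng = np.random.default_rng(99)
    z1 = rng.standard_normal(200_000)
    z2 = latent * z1 + np.sqrt(1 - latent**2) * rng.standard_normal(200_000)
    rho = sps.spearmanr(binned(z1), z2).statistic
    assert abs(rho - 0.3) <= 0.03


def test_calibrate_unreachable_target_names_the_ceiling():
    # two heavily asymmetric binary margins cap the rank correlation far below 0.5
    rare = lambda z: (z > sps.norm.ppf(0.95)).astype(int)
    common = lambda z: (z > sps.norm.ppf(0.05)).astype(int)
    with pytest.raises(CalibrationError, match="achievable"):
        calibrate_latent_correlation(0.5, rare, common, n_calib=50_000, seed=4)


def test_calibrate_validates_preconditions():
    with pytest.raises(ValueError):
        calibrate_latent_correlation(0.96)
    with pytest.raises(ValueError):
        calibrate_latent_correlation(0.3, n_calib=5_000)


# --- marginal fitting edge cases ------------------------------------------

def test_truncnorm_infeasible_moments_raise():
    with pytest.raises(MarginalError):
        fit_truncnorm(6.0, 5.0, 0.0, 12.0)  # SD above the uniform limit
    with pytest.raises(MarginalError):
        fit_truncnorm(5.0, -1.0, 0.0)


# --- cohort generation -----------------------------------------------------

def test_default_cohort_sizes(single_cohort):
    counts = single_cohort["group"].value_counts()
    assert len(single_cohort) == 214
    assert counts["AIDED"] == 63
    assert counts["NAIDED"] == 151


def test_empty_cohort_from_zero_sized_groups(small_config):
    empty = dataclasses.replace(
        small_config,
        name="test_empty",
        groups=tuple(dataclasses.replace(g, n=0) for g in small_config.groups),
    )
    assert generate_cohort(empty, seed=0) == []


def test_cohort_seed_determinism(small_config):
    a = generate_cohort_frame(small_config, seed=5)
    b = generate_cohort_frame(small_config, seed=5)
    c = generate_cohort_frame(small_config, seed=6)
    assert a.to_csv(sep="\t", index=False) == b.to_csv(sep="\t", index=False)
    assert a.to_csv(sep="\t", index=False) != c.to_csv(sep="\t", index=False)


def test_generated_records_satisfy_scoring_invariants(default_config):
    records = generate_cohort(default_config, seed=77)
    for r in records:
        s = r.score
        assert s.total == s.ic_sub + s.nd_sub + s.nm_sub
        assert 0 <= s.total <= 6
        assert s.ic_code == f"IC-{s.ic_sub}"
        assert s.nd_code == ("ND-1" if s.nd_sub == 0 else "ND-2")
        assert 0 <= r.osdi_total <= 100
        assert r.schirmer_mm >= 0 and r.tbut_s > 0
        assert r.oxford in range(6)
        assert r.hla_dr_auf >= 0
        assert r.morphometry.mean_tortuosity >= 1.0
    frame = records_to_frame(records)
    assert list(frame["tivcm"]) == [r.score.total for r in records]


def test_marginal_recovery_across_replicates(default_config, replicate_cohorts):
    """Group sample means stay within 3*SD/sqrt(n) of the configured means
    in at least 95% of (replicate, variable, group) checks."""
    checks = []
    for frame in replicate_cohorts:
        for group in default_config.groups:
            sub = frame[frame["group"] == group.name]
            for var in ("age", "osdi_total", "schirmer_mm", "tbut_s", "oxford",
                        "hla_dr_auf", "osdi_symptoms", "osdi_vision"):
                spec = group.clinical[var]
                bound = 3 * spec.sd / np.sqrt(group.n)
                checks.append(abs(sub[var].mean() - spec.mean) <= bound)
    assert np.mean(checks) >= 0.95


def test_subscore_means_recover_published_values(replicate_cohorts):
    pooled = np.concatenate([f["ic_sub"].to_numpy() for f in replicate_cohorts])
    assert abs(pooled.mean() - 1.7) < 0.1
    pooled_nd = np.concatenate([f["nd_sub"].to_numpy() for f in replicate_cohorts])
    assert abs(pooled_nd.mean() - 0.4) < 0.1
    pooled_nm = np.concatenate([f["nm_sub"].to_numpy() for f in replicate_cohorts])
    assert abs(pooled_nm.mean() - 1.47) < 0.1


def test_sex_ratio_matches_group_config(replicate_cohorts, default_config):
    for group in default_config.groups:
        fractions = [
            (f[f["group"] == group.name]["sex"] == "F").mean() for f in replicate_cohorts
        ]
        assert abs(np.mean(fractions) - group.female_fraction) < 0.05


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        config_from_dict({"groups": {}})
    cfg = default_config()
    with pytest.raises(ConfigError):
        dataclasses.replace(cfg.groups[0], female_fraction=1.5)


def test_latent_variable_order_is_stable():
    # downstream code indexes the copula by this order; a silent reorder
    # would scramble every planted correlation
    assert LATENT_VARS[0] == "age"
    assert LATENT_VARS[-1] == "hla_dr_auf"
    assert set(("ic_density", "nerve_density", "tortuosity", "reflectivity")) < set(
        LATENT_VARS
    )
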