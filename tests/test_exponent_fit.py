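import math

import numpy as np
import pytest

import focalcbs as f
from conftest import corr_forward, hf_forward


def grid_search_alpha(observations, grid):
    """Dense-grid oracle for the mean-field exponent (vectorized)."""
    e2 = np.array([o.energies[0] for o in observations])
    e3 = np.array([o.energies[1] for o in observations])
    ref = np.array([o.reference for o in observations])
    a = grid[:, None]
    w2, w3 = np.exp(a * math.sqrt(2)), np.exp(a * math.sqrt(3))
    pred = (w3 * e2 - w2 * e3) / (w3 - w2)
    rss = ((pred - ref) ** 2).sum(axis=1)
    return grid[int(np.argmin(rss))]


def grid_search_corr(observations, grid, fixed_beta=None):
    """Dense-grid oracle for the correlation exponents."""
    ref = np.array([o.reference for o in observations])
    b = grid[:, None]

    def extrap(lo, hi, expo):
        w2, w3 = 2.0**-expo, 3.0**-expo
        return (w3 * lo - w2 * hi) / (w3 - w2)

    if fixed_beta is None:
        lo = np.array([o.energies[0] for o in observations])
        hi = np.array([o.energies[1] for o in observations])
        pred = extrap(lo, hi, b)
    else:
        cc_lo = np.array([o.energies[0] for o in observations])
        cc_hi = np.array([o.energies[1] for o in observations])
        m_lo = np.array([o.energies[2] for o in observations])
        m_hi = np.array([o.energies[3] for o in observations])
        pred = extrap(cc_lo, cc_hi, b) - extrap(m_lo, m_hi, fixed_beta)
    rss = ((pred - ref) ** 2).sum(axis=1)
    return grid[int(np.argmin(rss))]


def make_hf_obs(rng, n, alpha, noise=0.0):
    # amplitudes sized so the double-zeta mean-field error is tens of
    # millihartree, as for real small-dimer absolute energies
    obs = []
    for i in range(n):
        a = rng.uniform(5.0, 60.0)
        e_cbs = rng.uniform(-600.0, -40.0)
        obs.append(
            f.FitObservation(
                f"s{i}",
                (hf_forward(e_cbs, a, alpha, 2), hf_forward(e_cbs, a, alpha, 3)),
                e_cbs + (rng.normal(0.0, noise) if noise else 0.0),
            )
        )
    return obs


def make_corr_obs(rng, n, beta, noise=0.0):
    # double-zeta correlation errors of a few tenths of a hartree
    obs = []
    for i in range(n):
        a = rng.uniform(0.5, 3.0)
        e_cbs = rng.uniform(-3.0, -0.3)
        obs.append(
            f.FitObservation(
                f"s{i}",
                (corr_forward(e_cbs, a, beta, 2), corr_forward(e_cbs, a, beta, 3)),
                e_cbs + (rng.normal(0.0, noise) if noise else 0.0),
            )
        )
    return obs


def make_post_obs(rng, n, gamma, beta, noise=0.0):
    obs = []
    for i in range(n):
        a_cc, a_m = rng.uniform(0.002, 0.01, size=2)
        cbs_cc, cbs_m = rng.uniform(-0.02, -0.001, size=2)
        obs.append(
            f.FitObservation(
                f"s{i}",
                (
                    corr_forward(cbs_cc, a_cc, gamma, 2),
                    corr_forward(cbs_cc, a_cc, gamma, 3),
                    corr_forward(cbs_m, a_m, beta, 2),
                    corr_forward(cbs_m, a_m, beta, 3),
                ),
                cbs_cc - cbs_m + (rng.normal(0.0, noise) if noise else 0.0),
            )
        )
    return obs


class TestNoiselessRecovery:
    def test_alpha_zero_residual(self):
        e_cbs, a = -100.0, 1.0
        obs = [
            f.FitObservation(
                "s",
                (hf_forward(e_cbs, a, -4.473, 2), hf_forward(e_cbs, a, -4.473, 3)),
                e_cbs,
            )
        ]
        res = f.fit_alpha(f.FitProblem("hf", obs))
        assert res.value == pytest.approx(-4.473, abs=1e-6)
        assert res.converged and not res.rank_deficient
        assert res.rss == pytest.approx(0.0, abs=1e-18)
        assert res.value_rounded == -4.473

    def test_beta_zero_residual(self):
        obs = [
            f.FitObservation(
                "s",
                (corr_forward(-1.0, 0.2, 2.796, 2), corr_forward(-1.0, 0.2, 2.796, 3)),
                -1.0,
            )
        ]
        res = f.fit_beta(f.FitProblem("mp2", obs))
        assert res.value == pytest.approx(2.796, abs=1e-6)

    def test_gamma_zero_residual(self):
        rng = np.random.default_rng(0)
        obs = make_post_obs(rng, 1, gamma=2.741, beta=2.796)
        res = f.fit_gamma(f.FitProblem("postmp2", obs, fixed_beta=2.796))
        assert res.value == pytest.approx(2.741, abs=1e-6)

    @pytest.mark.parametrize("n", [1, 5, 58])
    def test_exact_recovery_any_size(self, n):
        rng = np.random.default_rng(n)
        res = f.fit_alpha(f.FitProblem("hf", make_hf_obs(rng, n, -4.5)))
        assert res.value == pytest.approx(-4.5, abs=1e-6)


class TestNoisyRecovery:
    def test_alpha_under_noise_vs_grid_oracle(self):
        rng = np.random.default_rng(42)
        obs = make_hf_obs(rng, 58, alpha=-4.5, noise=1e-5)
        res = f.fit_alpha(f.FitProblem("hf", obs))
        assert res.value == pytest.approx(-4.5, abs=0.05)
        oracle = grid_search_alpha(obs, np.arange(-10.0, -1.0, 1e-4))
        assert res.value == pytest.approx(oracle, abs=1e-4)

    def test_beta_under_noise_vs_grid_oracle(self):
        rng = np.random.default_rng(43)
        obs = make_corr_obs(rng, 58, beta=2.8, noise=1e-5)
        res = f.fit_beta(f.FitProblem("mp2", obs))
        assert res.value == pytest.approx(2.8, abs=0.05)
        oracle = grid_search_corr(obs, np.arange(1.0, 6.0, 1e-4))
        assert res.value == pytest.approx(oracle, abs=1e-4)

    def test_gamma_under_noise_vs_grid_oracle(self):
        rng = np.random.default_rng(44)
        obs = make_post_obs(rng, 22, gamma=2.7, beta=2.796, noise=1e-5)
        res = f.fit_gamma(f.FitProblem("postmp2", obs, fixed_beta=2.796))
        assert res.value == pytest.approx(2.7, abs=0.1)
        oracle = grid_search_corr(obs, np.arange(1.0, 6.0, 1e-4), fixed_beta=2.796)
        assert res.value == pytest.approx(oracle, abs=1e-3)

    def test_conflicting_observations_match_grid_minimum(self):
        # two observations implying different exponents: the compromise
        # minimum must match the brute-force oracle
        obs = [
            f.FitObservation("a", (hf_forward(-50.0, 0.1, -4.0, 2),
                                   hf_forward(-50.0, 0.1, -4.0, 3)), -50.0),
            f.FitObservation("b", (hf_forward(-70.0, 0.1, -5.0, 2),
                                   hf_forward(-70.0, 0.1, -5.0, 3)), -70.0),
        ]
        res = f.fit_alpha(f.FitProblem("hf", obs))
        oracle = grid_search_alpha(obs, np.arange(-10.0, -1.0, 1e-4))
        assert res.value == pytest.approx(oracle, abs=1e-4)


class TestInvariances:
    def test_observation_order_irrelevant(self):
        rng = np.random.default_rng(5)
        obs = make_corr_obs(rng, 20, beta=2.9, noise=1e-5)
        a = f.fit_beta(f.FitProblem("mp2", obs))
        b = f.fit_beta(f.FitProblem("mp2", obs[::-1]))
        assert a.value == pytest.approx(b.value, abs=1e-8)

    def test_gamma_fit_shift_invariant(self):
        # a global energy shift on every record of one system cancels in
        # the post-MP2 difference
        rng = np.random.default_rng(6)
        obs = make_post_obs(rng, 10, gamma=2.7, beta=2.796, noise=1e-6)
        shifted = [
            f.FitObservation(
                o.system_id,
                tuple(e + 0.5 for e in o.energies[:2])
                + tuple(e + 0.5 for e in o.energies[2:]),
                o.reference,
            )
            for o in obs
        ]
        a = f.fit_gamma(f.FitProblem("postmp2", obs, fixed_beta=2.796))
        b = f.fit_gamma(f.FitProblem("postmp2", shifted, fixed_beta=2.796))
        assert a.value == pytest.approx(b.value, abs=1e-8)


class TestDegenerateProblems:
    def test_converged_observations_rank_deficient(self):
        obs = [f.FitObservation("s", (-1.5, -1.5), -1.5)]
        res = f.fit_beta(f.FitProblem("mp2", obs))
        assert res.rank_deficient

    def test_zero_fixed_beta_rejected(self):
        obs = [f.FitObservation("s", (-1.0, -1.0, -1.0, -1.0), 0.0)]
        with pytest.raises(f.InvalidRecordError):
            f.FitProblem("postmp2", obs, fixed_beta=0.0)

    def test_empty_problem_rejected(self):
        with pytest.raises(f.InvalidRecordError):
            f.FitProblem("hf", [])

    def test_wrong_arity_rejected(self):
        with pytest.raises(f.InvalidRecordError):
            f.FitProblem("hf", [f.FitObservation("s", (-1.0,), -1.0)])


def test_fit_csv_round_trip(tmp_path):
    import pandas as pd

    rng = np.random.default_rng(9)
    obs = make_hf_obs(rng, 5, alpha=-4.3)
    df = pd.DataFrame(
        {
            "system_id": [o.system_id for o in obs],
            "e_lo": [o.energies[0] for o in obs],
            "e_hi": [o.energies[1] for o in obs],
            "e_ref": [o.reference for o in obs],
        }
    )
    path = tmp_path / "train.csv"
    df.to_csv(path, index=False)
    problem = f.read_fit_csv(path, "hf")
    res = f.fit_alpha(problem)
    assert res.value == pytest.approx(-4.3, abs=1e-6)
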