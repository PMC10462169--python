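"""Langevin generator: drift, discretization, noise laws, snapshots."""

import numpy as np
import pytest

from sgnc.codec import MoleculeRecord, make_codebook_codec
from sgnc.exceptions import ConfigError, DomainError
from sgnc.generator import (
    GeneratorConfig,
    ReferenceSet,
    Trajectory,
    drift,
    generate_candidates,
    simulate,
    snapshot_indices,
    step,
)


@pytest.fixture
def refs3(rng):
    return ReferenceSet(
        references=[rng.normal(size=5) for _ in range(3)],
        weights=[0.5, 0.3, 0.2],
    )


class TestReferenceSet:
    def test_default_weights_uniform(self, rng):
        rs = ReferenceSet(references=[rng.normal(size=4) for _ in range(4)])
        assert rs.weights == pytest.approx([0.25] * 4)

    @pytest.mark.parametrize(
        "weights", [[0.5, 0.6], [1.0, -0.0001], [0.2, 0.2]]
    )
    def test_bad_weights_rejected(self, rng, weights):
        with pytest.raises(ConfigError):
            ReferenceSet(references=[rng.normal(size=3) for _ in range(2)], weights=weights)

    def test_centroid_is_weighted_mean(self, refs3):
        m = refs3.centroid()
        manual = sum(a * x for a, x in zip(refs3.weights, refs3.references))
        assert np.allclose(m, manual)


class TestDrift:
    def test_centroid_is_fixed_point(self, refs3):
        assert np.allclose(drift(refs3.centroid(), refs3, alpha=1.7), 0.0)

    def test_single_reference_direct_substitution(self):
        rs = ReferenceSet(references=[np.ones(3)], weights=[1.0])
        assert np.allclose(drift(np.zeros(3), rs, alpha=1.0), np.ones(3))

    def test_matches_double_loop_oracle(self, rng, refs3):
        x = rng.normal(size=5)
        alpha = 0.8
        expected = np.zeros(5)
        for a_k, x_k in zip(refs3.weights, refs3.references):
            for j in range(5):
                expected[j] += alpha * a_k * (x_k[j] - x[j])
        assert np.allclose(drift(x, refs3, alpha), expected, atol=1e-12)

    def test_dimension_mismatch(self, refs3):
        with pytest.raises(DomainError):
            drift(np.zeros(4), refs3, alpha=1.0)


class TestStep:
    def test_one_step_hand_evaluation(self):
        # x' = x + dt*alpha*(X1 - x) with no noise: 0 + 0.1*1*(1-0) = 0.1
        rs = ReferenceSet(references=[np.ones(1)], weights=[1.0])
        cfg = GeneratorConfig(alpha=1.0, dt=0.1, n_steps=1, noise_amplitude=0.0)
        out = step(np.zeros(1), rs, cfg, np.random.default_rng(0))
        assert out == pytest.approx([0.1])

    def test_centroid_fixed_without_noise(self, refs3):
        cfg = GeneratorConfig(alpha=1.0, dt=0.05, n_steps=1, noise_amplitude=0.0)
        m = refs3.centroid()
        assert np.allclose(step(m, refs3, cfg, np.random.default_rng(0)), m)

    def test_uniform_noise_is_bounded(self, refs3):
        cfg = GeneratorConfig(
            alpha=1.0, dt=0.05, n_steps=1, noise_law="uniform", noise_amplitude=0.1
        )
        rng = np.random.default_rng(42)
        x = refs3.centroid()  # drift term vanishes: displacement is pure noise
        for _ in range(10_000):
            eta = step(x, refs3, cfg, rng) - x
            assert np.all(np.abs(eta) <= 0.1)

    def test_clipped_gaussian_is_bounded(self, refs3):
        cfg = GeneratorConfig(
            alpha=1.0, dt=0.05, n_steps=1, noise_law="clipped-gaussian", noise_amplitude=0.02
        )
        rng = np.random.default_rng(42)
        x = refs3.centroid()
        draws = np.array([step(x, refs3, cfg, rng) - x for _ in range(2000)])
        assert np.all(np.abs(draws) <= 0.02)

    def test_step_cap_rescales_displacement(self):
        rs = ReferenceSet(references=[np.full(4, 100.0)], weights=[1.0])
        cfg = GeneratorConfig(alpha=1.0, dt=0.5, n_steps=1, noise_amplitude=0.0, step_cap=0.25)
        out = step(np.zeros(4), rs, cfg, np.random.default_rng(0))
        assert np.linalg.norm(out) == pytest.approx(0.25)


class TestGeneratorConfig:
    def test_unstable_discretization_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(alpha=10.0, dt=0.2, n_steps=10)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dt": -0.1},
            {"noise_law": "levy"},
            {"noise_amplitude": -1.0},
            {"burn_in": 10, "n_steps": 10},
            {"snapshot_every": 0},
            {"step_cap": 0.0},
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            GeneratorConfig(**{"n_steps": 20, **kwargs})


class TestSimulate:
    def test_zero_noise_matches_closed_form(self, refs3, rng):
        # deterministic solution: m + (x0 - m) * exp(-alpha * t)
        alpha, dt, n = 1.0, 0.01, 100  # horizon 1/alpha
        cfg = GeneratorConfig(alpha=alpha, dt=dt, n_steps=n, noise_amplitude=0.0)
        x0 = rng.normal(size=5) * 3
        traj = simulate(x0, refs3, cfg)
        m = refs3.centroid()
        tol = 5 * alpha**2 * dt * np.linalg.norm(x0 - m)
        for k in (10, 50, 100):
            exact = m + (x0 - m) * np.exp(-alpha * k * dt)
            assert np.linalg.norm(traj.states[k] - exact) <= tol

    def test_halving_dt_roughly_halves_discretization_error(self, refs3, rng):
        x0 = rng.normal(size=5) * 3
        m = refs3.centroid()
        errors = []
        for dt, n in [(0.04, 25), (0.02, 50), (0.01, 100)]:
            cfg = GeneratorConfig(alpha=1.0, dt=dt, n_steps=n, noise_amplitude=0.0)
            traj = simulate(x0, refs3, cfg)
            exact = m + (x0 - m) * np.exp(-1.0)
            errors.append(np.linalg.norm(traj.states[-1] - exact))
        assert errors[0] / errors[1] == pytest.approx(2.0, rel=0.2)
        assert errors[1] / errors[2] == pytest.approx(2.0, rel=0.2)

    def test_zero_noise_distance_to_centroid_non_increasing(self, refs3, rng):
        cfg = GeneratorConfig(alpha=1.0, dt=0.05, n_steps=200, noise_amplitude=0.0)
        traj = simulate(rng.normal(size=5) * 2, refs3, cfg)
        dists = np.linalg.norm(traj.states - refs3.centroid(), axis=1)
        assert np.all(np.diff(dists) <= 1e-12)
        assert dists[-1] < 1e-3 * dists[0]

    def test_same_seed_identical_trajectories(self, refs3, rng):
        cfg = GeneratorConfig(alpha=1.0, dt=0.01, n_steps=50, seed=99)
        x0 = rng.normal(size=5)
        t1 = simulate(x0, refs3, cfg)
        t2 = simulate(x0, refs3, cfg)
        assert np.array_equal(t1.states, t2.states)

    def test_alpha_zero_no_noise_is_frozen(self, refs3):
        cfg = GeneratorConfig(alpha=0.0, dt=0.01, n_steps=30, noise_amplitude=0.0)
        x0 = np.arange(5.0)
        traj = simulate(x0, refs3, cfg)
        assert np.all(traj.states == x0)

    def test_gaussian_stationary_moments(self):
        # OU stationary law: mean = centroid, variance = sigma^2 / (2 alpha)
        alpha, dt, sigma, d = 1.0, 0.01, 0.2, 4
        n_steps, burn = 100_000, 10_000
        rs = ReferenceSet(references=[np.full(d, 1.5), np.full(d, -0.5)], weights=[0.5, 0.5])
        cfg = GeneratorConfig(
            alpha=alpha, dt=dt, n_steps=n_steps, noise_law="gaussian",
            noise_amplitude=sigma, seed=2024,
        )
        traj = simulate(rs.centroid(), rs, cfg)
        tail = traj.states[burn:]
        target_var = sigma**2 / (2 * alpha)
        # effective sample size discounts the ~1/(alpha dt)-step autocorrelation
        n_eff = tail.shape[0] * alpha * dt / 2
        se = np.sqrt(target_var / n_eff)
        assert np.all(np.abs(tail.mean(axis=0) - rs.centroid()) < 4 * se)
        assert tail.var() == pytest.approx(target_var, rel=0.10)


class TestGenerateCandidates:
    @pytest.fixture
    def codec4(self, rng):
        mols = [MoleculeRecord(smiles="C" * (i + 1), id=f"m{i}") for i in range(4)]
        centers = [np.array([float(i), 0.0]) * 10 for i in range(4)]
        return make_codebook_codec(mols, centers), mols

    def test_frozen_trajectory_yields_single_candidate(self, codec4):
        codec, _ = codec4
        cfg = GeneratorConfig(alpha=1.0, dt=0.01, n_steps=10, noise_amplitude=0.0)
        traj = Trajectory(np.zeros((11, 2)))
        cands = generate_candidates(traj, codec, cfg)
        assert len(cands) == 1

    def test_snapshot_index_arithmetic(self):
        cfg = GeneratorConfig(alpha=1.0, dt=0.01, n_steps=10, burn_in=2, snapshot_every=8)
        assert snapshot_indices(cfg) == [2, 10]

    def test_candidates_match_cell_visits(self, codec4):
        codec, mols = codec4
        cfg = GeneratorConfig(alpha=1.0, dt=0.01, n_steps=5, snapshot_every=1)
        # visit cells 0, 2, 2, 1, 0, 3 at snapshot times
        xs = np.array([[0.0, 0], [20, 0], [21, 0], [11, 0], [1, 0], [30, 0]])
        cands = generate_candidates(Trajectory(xs), codec, cfg)
        brute_cells = []
        for x in xs:
            c = int(np.argmin([np.linalg.norm(x - codec.centers[i]) for i in range(4)]))
            if c not in brute_cells:
                brute_cells.append(c)
        assert [m.smiles for m, _ in cands] == [mols[c].smiles for c in brute_cells]

    def test_candidates_carry_source_latent(self, codec4):
        codec, _ = codec4
        cfg = GeneratorConfig(alpha=1.0, dt=0.01, n_steps=2, snapshot_every=1)
        xs = np.array([[0.0, 0], [20, 0], [30, 0]])
        cands = generate_candidates(Trajectory(xs), codec, cfg)
        assert np.array_equal(cands[1][1], xs[1])

    def test_dimension_mismatch_rejected(self, codec4):
        codec, _ = codec4
        cfg = GeneratorConfig(alpha=1.0, dt=0.01, n_steps=2)
        with pytest.raises(DomainError):
            generate_candidates(Trajectory(np.zeros((3, 5))), codec, cfg)
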