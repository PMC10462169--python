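"""Multi-reference Langevin dynamics in latent space.

The generator evolves a latent vector X under

    dX/dt = α · Σ_k a_k (X_k − X) + ξ(t)

where the X_k are latent vectors of K reference molecules, the a_k are
positive weights summing to 1, α > 0 sets the drift strength, and ξ is a
small noise term. The drift pulls X toward the weighted reference centroid
m = Σ_k a_k X_k; with Gaussian ξ the process is an Ornstein–Uhlenbeck
process centered on m, whose zero-noise solution

    X(t) = m + (X(0) − m) · e^(−αt)

and stationary law  X ~ N(m, σ²/(2α) · I)  serve as analytic checks on the
discretization.

Integration is explicit Euler–Maruyama with step Δt:

    x' = x + Δt · α Σ_k a_k (X_k − x) + η

Stability of the deterministic part requires αΔt < 1 (enforced). Three
noise laws are exposed. ``gaussian`` draws η ~ N(0, (A√Δt)²) per coordinate
— the theoretically clean choice whose stationary moments are known in
closed form. ``uniform`` draws η ~ U[−A, A] per coordinate, matching the
practice of bounding the per-step perturbation to a small box (default
A = 0.1); ``clipped-gaussian`` draws the Gaussian and clips it to [−A, A].
``uniform`` is the default: bounded noise is what keeps edited vectors
inside the thin region of latent space the codec can decode. An optional
Euclidean cap on the per-step displacement is available as a further guard.

Snapshots of the trajectory taken every ``snapshot_every`` steps after a
burn-in are decoded into candidate molecules and deduplicated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from sgnc.codec import Codec, MoleculeRecord
from sgnc.exceptions import ConfigError, DomainError

NoiseLaw = Literal["gaussian", "uniform", "clipped-gaussian"]


@dataclass
class ReferenceSet:
    """K reference latent vectors X_k with positive weights a_k, Σ a_k = 1."""

    references: list[np.ndarray]
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.references) == 0:
            raise ConfigError("at least one reference vector is required")
        self.references = [np.asarray(r, dtype=float) for r in self.references]
        d = self.references[0].shape
        if len(d) != 1 or any(r.shape != d for r in self.references):
            raise ConfigError("reference vectors must be 1-D and share one dimension")
        if self.weights is None:
            self.weights = [1.0 / len(self.references)] * len(self.references)
        if len(self.weights) != len(self.references):
            raise ConfigError("weights and references differ in length")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0):
            raise ConfigError("all reference weights must be positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError(f"reference weights must sum to 1, got {w.sum()!r}")

    @property
    def dimension(self) -> int:
        return self.references[0].shape[0]

    def centroid(self) -> np.ndarray:
        """Weighted centroid m = Σ_k a_k X_k — the fixed point of the drift."""
        w = np.asarray(self.weights, dtype=float)
        return w @ np.vstack(self.references)


@dataclass
class GeneratorConfig:
    """Parameters of the discretized Langevin generator.

    alpha           drift strength α (1/time); larger pulls harder to the
                    centroid, 0 switches the drift off (pure noise)
    dt              Euler–Maruyama step Δt; αΔt < 1 required for stability
    n_steps         number of integration steps
    noise_law       "gaussian" | "uniform" | "clipped-gaussian"
    noise_amplitude A: Gaussian scale, or the uniform/clip bound (default 0.1)
    step_cap        optional max Euclidean per-step displacement (None = off)
    burn_in         steps discarded before snapshots are taken
    snapshot_every  snapshot stride after burn-in
    seed            RNG seed; the whole trajectory is deterministic given it
    """

    alpha: float = 1.0
    dt: float = 0.01
    n_steps: int = 1000
    noise_law: NoiseLaw = "uniform"
    noise_amplitude: float = 0.1
    step_cap: float | None = None
    burn_in: int = 0
    snapshot_every: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigError("alpha must be non-negative")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.alpha * self.dt >= 1:
            raise ConfigError(
                f"explicit Euler requires alpha*dt < 1 for stability, got {self.alpha * self.dt}"
            )
        if self.n_steps < 1:
            raise ConfigError("n_steps must be a positive integer")
        if self.noise_law not in ("gaussian", "uniform", "clipped-gaussian"):
            raise ConfigError(f"unknown noise law {self.noise_law!r}")
        if self.noise_amplitude < 0:
            raise ConfigError("noise_amplitude must be non-negative")
        if self.step_cap is not None and self.step_cap <= 0:
            raise ConfigError("step_cap must be positive or None")
        if self.burn_in < 0 or self.burn_in >= self.n_steps:
            raise ConfigError("burn_in must satisfy 0 <= burn_in < n_steps")
        if self.snapshot_every < 1:
            raise ConfigError("snapshot_every must be a positive integer")


@dataclass
class Trajectory:
    """Ordered latent states of one generator run; states[0] is the initial state."""

    states: np.ndarray  # (n_steps + 1, d)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2:
            raise DomainError("trajectory states must form a 2-D (steps, dim) array")

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def dimension(self) -> int:
        return self.states.shape[1]


def drift(x: np.ndarray, refs: ReferenceSet, alpha: float) -> np.ndarray:
    """Deterministic drift α·Σ_k a_k (X_k − x); zero exactly at the centroid."""
    x = np.asarray(x, dtype=float)
    if x.shape != (refs.dimension,):
        raise DomainError(f"state has shape {x.shape}, references have dimension {refs.dimension}")
    return alpha * (refs.centroid() - x)


def _draw_noise(cfg: GeneratorConfig, d: int, rng: np.random.Generator) -> np.ndarray:
    a = cfg.noise_amplitude
    if a == 0:
        return np.zeros(d)
    if cfg.noise_law == "gaussian":
        return rng.normal(0.0, a * np.sqrt(cfg.dt), size=d)
    if cfg.noise_law == "uniform":
        return rng.uniform(-a, a, size=d)
    # clipped-gaussian: Gaussian scale as above, support forced into [−A, A]
    return np.clip(rng.normal(0.0, a * np.sqrt(cfg.dt), size=d), -a, a)


def step(
    x: np.ndarray, refs: ReferenceSet, cfg: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """One Euler–Maruyama update x' = x + Δt·drift(x) + η, with optional step cap."""
    x = np.asarray(x, dtype=float)
    displacement = cfg.dt * drift(x, refs, cfg.alpha) + _draw_noise(cfg, x.shape[0], rng)
    if cfg.step_cap is not None:
        norm = float(np.linalg.norm(displacement))
        if norm > cfg.step_cap:
            displacement = displacement * (cfg.step_cap / norm)
    return x + displacement


def simulate(x0: np.ndarray, refs: ReferenceSet, cfg: GeneratorConfig) -> Trajectory:
    """Integrate the generator for cfg.n_steps from x0; deterministic given cfg.seed."""
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (refs.dimension,):
        raise DomainError(
            f"initial state has shape {x0.shape}, references have dimension {refs.dimension}"
        )
    rng = np.random.default_rng(cfg.seed)
    states = np.empty((cfg.n_steps + 1, refs.dimension))
    states[0] = x0
    x = x0
    for n in range(cfg.n_steps):
        x = step(x, refs, cfg, rng)
        states[n + 1] = x
    return Trajectory(states)


def snapshot_indices(cfg: GeneratorConfig) -> list[int]:
    """Trajectory indices decoded into candidates: burn_in, burn_in+stride, ... ≤ n_steps."""
    return list(range(cfg.burn_in, cfg.n_steps + 1, cfg.snapshot_every))


def generate_candidates(
    traj: Trajectory, codec: Codec, cfg: GeneratorConfig
) -> list[tuple[MoleculeRecord, np.ndarray]]:
    """Decode trajectory snapshots into unique candidate molecules.

    Snapshots at :func:`snapshot_indices` are decoded; duplicates (by decoded
    SMILES) are dropped keeping the first occurrence, preserving order. Each
    candidate is returned with the latent vector it was decoded from.
    """
    if traj.dimension != codec.dimension:
        raise DomainError(
            f"trajectory dimension {traj.dimension} != codec dimension {codec.dimension}"
        )
    seen: set[str] = set()
    out: list[tuple[MoleculeRecord, np.ndarray]] = []
    for idx in snapshot_indices(cfg):
        z = traj.states[idx]
        smiles = codec.decode(z)
        if smiles in seen:
            continue
        seen.add(smiles)
        out.append(
            (MoleculeRecord(smiles=smiles, id=f"gen-{idx:06d}"), z.copy())
        )
    return out
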