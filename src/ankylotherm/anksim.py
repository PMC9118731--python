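"""Charged coupled-oscillator model of ankyrin-domain fluctuation.

A reduced stand-in for all-atom dynamics of the ankyrin stack: each
33-residue repeat is one effective particle displacing along the domain's
long axis (the soft direction of the ankyrin fold).  Particles feel

* a stiff on-site spring (k_intra) for the internal helix bundle, softened
  in proportion to the square of the repeat's surface charge — the
  like-charge self-repulsion of a clustered acidic surface destabilizes
  the repeat's own fold,
* soft springs to neighbours (k_link) for the hairpin connectors,
* screened Coulomb repulsion between charged repeats (the acidic clusters
  of repeats 3-6 in the Notch preset), which shifts the equilibrium and
  couples neighbours anharmonically, and
* Langevin thermostatting at the requested temperature.

Integration is the deterministic BAOAB splitting scheme with Gaussian
kicks drawn from a counter-based Philox stream keyed by the seed, so a
trajectory is bit-reproducible from (chain, T, steps, dt, seed).  Model
units throughout: masses 1, lattice spacing 1; absolute fluctuation
magnitudes are not comparable to all-atom RMSF — only orderings (warmer
vs cooler, charged vs discharged) are meaningful, which is precisely what
the temperature- and mutation-response claims require.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import root

__all__ = [
    "OscillatorChain",
    "Trajectory",
    "RMSFProfile",
    "build_chain",
    "notch_preset",
    "simulate",
    "simulate_ensemble",
    "rmsf_profile",
    "ensemble_rmsf",
    "mutate_charge",
    "max_stable_dt",
]

#: Boltzmann factor in model energy units per kelvin: k_B*T ~= 1 at ~300 K.
KB_MODEL = 1.0 / 300.0


@dataclass
class OscillatorChain:
    n: int
    masses: np.ndarray
    k_intra: float = 100.0
    k_link: float = 5.0
    charges: np.ndarray = None
    friction: float = 1.0
    spacing: float = 1.0
    coulomb_k: float = 5.0      # Coulomb prefactor, model energy * length
    screening: float = 1.0      # Debye-type screening length, model units
    charge_softening: float = 20.0   # on-site stiffness lost per e^2
    kb: float = KB_MODEL

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("chain needs n >= 1")
        self.masses = np.asarray(self.masses, float)
        if self.charges is None:
            self.charges = np.zeros(self.n)
        self.charges = np.asarray(self.charges, float)
        if self.masses.shape != (self.n,) or self.charges.shape != (self.n,):
            raise ValueError("masses and charges must have length n")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.k_intra < 0 or self.k_link < 0:
            raise ValueError("spring constants must be >= 0")
        if self.k_link > self.k_intra:
            raise ValueError("k_link must not exceed k_intra (soft connectors)")
        if np.any(self.k_onsite <= 0):
            raise ValueError(
                "charge softening exceeds k_intra: repeat would be unstable"
            )

    @property
    def lattice(self) -> np.ndarray:
        return self.spacing * np.arange(self.n)

    @property
    def k_onsite(self) -> np.ndarray:
        """Per-repeat on-site stiffness after charge softening."""
        return self.k_intra - self.charge_softening * self.charges**2

    def forces(self, x: np.ndarray) -> np.ndarray:
        """Force on each site for displacements x (batched: (..., n))."""
        f = -self.k_onsite * x
        if self.n > 1 and self.k_link > 0:
            d = np.diff(x, axis=-1)                    # x[i+1] - x[i]
            f[..., :-1] += self.k_link * d
            f[..., 1:] -= self.k_link * d
        if np.any(self.charges != 0):
            s = self.lattice + x                       # absolute positions
            sep = s[..., None, :] - s[..., :, None]    # s_j - s_i
            r = np.abs(sep)
            qq = self.charges[:, None] * self.charges[None, :]
            eye = np.eye(self.n, dtype=bool)
            r_safe = np.where(eye, 1.0, r)
            mag = self.coulomb_k * qq * np.exp(-r_safe / self.screening) * (
                1.0 / r_safe**2 + 1.0 / (self.screening * r_safe)
            )
            mag = np.where(eye, 0.0, mag)
            # force on i from j points from j toward i for repulsion (qq > 0)
            f += -(np.sign(sep) * mag).sum(axis=-1)
        return f

    def equilibrium(self) -> np.ndarray:
        """Static equilibrium displacements (zero-force configuration)."""
        if not np.any(self.charges != 0):
            return np.zeros(self.n)
        sol = root(lambda x: self.forces(x), np.zeros(self.n), tol=1e-12)
        if not sol.success:
            raise RuntimeError(f"equilibrium solve failed: {sol.message}")
        return sol.x


@dataclass
class Trajectory:
    samples: np.ndarray      # (n_samples, n) displacements about the lattice
    dt: float
    stride: int
    temperature: float
    seed: int

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class RMSFProfile:
    rmsf: np.ndarray
    temperature: float


def build_chain(
    n: int = 7,
    masses: float | np.ndarray = 1.0,
    k_intra: float = 100.0,
    k_link: float = 5.0,
    charges: np.ndarray | None = None,
    friction: float = 1.0,
    **kw,
) -> OscillatorChain:
    if n < 1:
        raise ValueError("n must be >= 1")
    m = np.full(n, float(masses)) if np.isscalar(masses) else np.asarray(masses, float)
    return OscillatorChain(n=n, masses=m, k_intra=k_intra, k_link=k_link,
                           charges=charges, friction=friction, **kw)


def notch_preset(charge: float = -1.0) -> OscillatorChain:
    """Seven-repeat chain with charges on repeats 3-6 (the acidic clusters)."""
    q = np.zeros(7)
    q[2:6] = charge
    return build_chain(n=7, charges=q)


def max_stable_dt(chain: OscillatorChain) -> float:
    """Conservative step bound 0.1 / omega_max for the stiff on-site mode."""
    omega_max = np.sqrt((chain.k_intra + 4 * chain.k_link) / chain.masses.min())
    return 0.1 / omega_max


def _run(
    chain: OscillatorChain,
    temperature: float,
    steps: int,
    dt: float,
    seeds: list[int],
    stride: int,
    x0: np.ndarray,
) -> np.ndarray:
    """Batched BAOAB; returns samples of shape (n_samples, n_seeds, n)."""
    n, b = chain.n, len(seeds)
    m = chain.masses
    gamma = chain.friction
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1)) * np.sqrt(chain.kb * temperature / m)

    gens = [np.random.Generator(np.random.Philox(s)) for s in seeds]
    x = np.tile(x0, (b, 1))
    v = np.zeros((b, n))
    f = chain.forces(x)
    out = np.empty((steps // stride, b, n))
    k_out = 0
    chunk = 4096
    done = 0
    while done < steps:
        this = min(chunk, steps - done)
        noise = np.stack([g.standard_normal((this, n)) for g in gens], axis=1)
        for t in range(this):
            v += 0.5 * dt * f / m
            x += 0.5 * dt * v
            v = c1 * v + c2 * noise[t]
            x += 0.5 * dt * v
            f = chain.forces(x)
            v += 0.5 * dt * f / m
            step_idx = done + t + 1
            if step_idx % stride == 0 and k_out < len(out):
                out[k_out] = x
                k_out += 1
        done += this
    return out[:k_out]


def simulate(
    chain: OscillatorChain,
    temperature: float,
    steps: int,
    dt: float = 0.005,
    seed: int = 0,
    stride: int = 10,
) -> Trajectory:
    """Langevin trajectory at the given temperature (kelvin).

    Identical inputs give bit-identical trajectories.  Starts from the
    static equilibrium of the (possibly charged) chain with zero
    velocities, so a T = 0 run stays put.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    bound = max_stable_dt(chain)
    if dt > bound:
        raise ValueError(
            f"dt = {dt} unstable for k_intra = {chain.k_intra}; "
            f"use dt <= {bound:.3g}"
        )
    x0 = chain.equilibrium()
    samples = _run(chain, temperature, steps, dt, [seed], stride, x0)[:, 0, :]
    return Trajectory(samples, dt, stride, temperature, seed)


def simulate_ensemble(
    chain: OscillatorChain,
    temperature: float,
    steps: int,
    dt: float = 0.005,
    seeds: list[int] | None = None,
    stride: int = 10,
) -> list[Trajectory]:
    """Independent trajectories for several seeds, integrated batched.

    Each member is identical to the corresponding single-seed
    :func:`simulate` call (each seed draws from its own Philox stream).
    """
    seeds = list(seeds if seeds is not None else range(10))
    bound = max_stable_dt(chain)
    if dt > bound:
        raise ValueError(f"dt = {dt} unstable; use dt <= {bound:.3g}")
    x0 = chain.equilibrium()
    samples = _run(chain, temperature, steps, dt, seeds, stride, x0)
    return [
        Trajectory(samples[:, i, :].copy(), dt, stride, temperature, s)
        for i, s in enumerate(seeds)
    ]


def rmsf_profile(trajectory: Trajectory, burn_in: float = 0.2) -> RMSFProfile:
    """Per-repeat RMSF about the post-burn-in mean displacement."""
    if not 0 <= burn_in < 1:
        raise ValueError("burn_in must be a fraction in [0, 1)")
    start = int(burn_in * trajectory.n_samples)
    post = trajectory.samples[start:]
    if len(post) < 100:
        raise ValueError(
            f"only {len(post)} post-burn-in samples; need >= 100 "
            "(increase steps or reduce stride/burn_in)"
        )
    rmsf = np.sqrt(np.mean((post - post.mean(axis=0)) ** 2, axis=0))
    return RMSFProfile(rmsf, trajectory.temperature)


def ensemble_rmsf(
    chain: OscillatorChain,
    temperature: float,
    steps: int,
    dt: float = 0.005,
    seeds: list[int] | None = None,
    stride: int = 10,
    burn_in: float = 0.2,
) -> np.ndarray:
    """Seed-averaged per-repeat RMSF."""
    trajs = simulate_ensemble(chain, temperature, steps, dt, seeds, stride)
    return np.mean([rmsf_profile(t, burn_in).rmsf for t in trajs], axis=0)


def mutate_charge(chain: OscillatorChain, repeat_index: int,
                  new_charge: float) -> OscillatorChain:
    """Copy of the chain with one repeat's charge changed (1-based index).

    The model analogue of a charge-removal point mutation such as D1989N.
    """
    if not 1 <= repeat_index <= chain.n:
        raise IndexError(f"repeat_index {repeat_index} outside 1..{chain.n}")
    q = chain.charges.copy()
    q[repeat_index - 1] = new_charge
    return replace(chain, charges=q, masses=chain.masses.copy())
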