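"""Closed-form denoising-diffusion mathematics.

Gaussian diffusion on coordinates:

    q(x_t | x_{t-1}) = N(x_t; sqrt(1-beta_t) x_{t-1}, beta_t I)
    q(x_t | x_0)     = N(x_t; sqrt(abar_t) x_0, (1-abar_t) I)
    q(x_{t-1} | x_t, x_0) = N(mu~, btilde_t I)
    mu~ = sqrt(abar_{t-1}) beta_t / (1-abar_t) * x_0
        + sqrt(alpha_t) (1-abar_{t-1}) / (1-abar_t) * x_t

with abar_0 = 1 by convention (so the t=1 posterior collapses onto the
predicted clean coordinates with zero variance). The posterior variance is
btilde_t = (1-abar_{t-1}) / (1-abar_t) * beta_t; a strict-paper flag drops
the beta_t factor to reproduce a printed variant that omits it.

Uniform categorical diffusion on K atom types:

    q(v_t | v_0)  = Cat(abar_t v_0 + (1-abar_t)/K)
    q(v_{t-1} | v_t, v_0) = Cat(theta* / sum theta*),
    theta* = [alpha_t v_t + (1-alpha_t)/K] * [abar_{t-1} v_0 + (1-abar_{t-1})/K]

The four training losses: squared-error on nuclei coordinates, squared-error
on manifold mesh coordinates, KL between the type posteriors under the true
and the predicted clean types, and the manifold-radius regularizer
sum_ij | ||x^N_i - x^M_ij|| - R_i | over assigned nucleus/mesh pairs at
(possibly different) timesteps.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .mesh import MeshPointAssignment

__all__ = ["VarianceSchedule", "NoisyState", "CategoricalDiffusionParams", "LossBreakdown",
           "build_schedule", "forward_sample_coords", "forward_step_coords", "posterior_coords",
           "forward_sample_types", "posterior_types", "loss_coords", "loss_mesh",
           "loss_types", "loss_reg", "total_loss"]


@dataclasses.dataclass
class VarianceSchedule:
    """beta/alpha/abar table for T steps; 1-indexed access via helpers."""

    T: int
    beta: np.ndarray        # (T,), beta[t-1] is beta_t
    strict_paper_variance: bool = False

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.T,):
            raise ValueError("beta must have shape (T,)")
        if np.any(self.beta <= 0) or np.any(self.beta >= 1):
            raise ValueError("betas must lie strictly in (0, 1)")
        self.alpha = 1.0 - self.beta
        self.alpha_bar = np.cumprod(self.alpha)
        if np.any(np.diff(self.alpha_bar) >= 0):
            raise ValueError("alpha_bar must be strictly decreasing")

    def beta_t(self, t: int) -> float:
        self._check(t)
        return float(self.beta[t - 1])

    def alpha_t(self, t: int) -> float:
        self._check(t)
        return float(self.alpha[t - 1])

    def alpha_bar_t(self, t: int) -> float:
        if t == 0:
            return 1.0
        self._check(t)
        return float(self.alpha_bar[t - 1])

    def posterior_var(self, t: int) -> float:
        """btilde_t; zero at t=1 by the abar_0 = 1 convention."""
        self._check(t)
        num = 1.0 - self.alpha_bar_t(t - 1)
        den = 1.0 - self.alpha_bar_t(t)
        if self.strict_paper_variance:
            return num / den
        return num / den * self.beta_t(t)

    def _check(self, t: int) -> None:
        if not 1 <= t <= self.T:
            raise ValueError(f"timestep {t} outside 1..{self.T}")


@dataclasses.dataclass
class NoisyState:
    """A corrupted ligand at timestep t: coordinates plus type rows."""

    coords: np.ndarray
    types: np.ndarray  # (n, K) rows summing to 1 (one-hot or distribution)
    t: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self.types = np.asarray(self.types, float)
        if not np.allclose(self.types.sum(axis=-1), 1.0):
            raise ValueError("type rows must sum to 1")
        if self.t < 1:
            raise ValueError("t must be >= 1")


@dataclasses.dataclass(frozen=True)
class CategoricalDiffusionParams:
    n_types: int

    def __post_init__(self):
        if self.n_types < 2:
            raise ValueError("need at least 2 type classes")


@dataclasses.dataclass
class LossBreakdown:
    loss_coords_N: float
    loss_types_N: float
    loss_coords_M: float
    loss_reg: float

    @property
    def total(self) -> float:
        return self.loss_coords_N + self.loss_types_N + self.loss_coords_M + self.loss_reg


def build_schedule(T: int, kind: str = "linear", beta_1: float = 1e-4, beta_T: float = 2e-2,
                   strict_paper_variance: bool = False) -> VarianceSchedule:
    """Variance schedule over T steps: linear in beta, or squared-cosine in abar."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if kind == "linear":
        if not 0 < beta_1 <= beta_T < 1:
            raise ValueError("need 0 < beta_1 <= beta_T < 1")
        beta = np.linspace(beta_1, beta_T, T)
    elif kind == "cosine":
        s = 0.008
        steps = np.arange(T + 1, dtype=float)
        f = np.cos((steps / T + s) / (1 + s) * np.pi / 2) ** 2
        abar = f / f[0]
        beta = np.clip(1 - abar[1:] / abar[:-1], 1e-8, 0.999)
    else:
        raise ValueError(f"unknown schedule kind: {kind}")
    return VarianceSchedule(T, beta, strict_paper_variance)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def forward_sample_coords(x0: np.ndarray, t: int, schedule: VarianceSchedule, noise_seed=0) -> np.ndarray:
    """Draw x_t ~ q(x_t|x_0) = N(sqrt(abar_t) x_0, (1-abar_t) I)."""
    x0 = np.asarray(x0, float)
    abar = schedule.alpha_bar_t(t)
    eps = _rng(noise_seed).standard_normal(x0.shape)
    return np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * eps


def forward_step_coords(x_prev: np.ndarray, t: int, schedule: VarianceSchedule, noise_seed=0) -> np.ndarray:
    """Single forward step x_t ~ q(x_t|x_{t-1}); used by consistency checks."""
    b = schedule.beta_t(t)
    eps = _rng(noise_seed).standard_normal(np.shape(x_prev))
    return np.sqrt(1.0 - b) * np.asarray(x_prev, float) + np.sqrt(b) * eps


def posterior_coords(xt: np.ndarray, x0_hat: np.ndarray, t: int,
                     schedule: VarianceSchedule) -> tuple[np.ndarray, float]:
    """Mean and scalar variance of q(x_{t-1} | x_t, x_0=x0_hat)."""
    xt = np.asarray(xt, float)
    x0_hat = np.asarray(x0_hat, float)
    abar_t = schedule.alpha_bar_t(t)
    abar_prev = schedule.alpha_bar_t(t - 1)
    beta = schedule.beta_t(t)
    alpha = schedule.alpha_t(t)
    c0 = np.sqrt(abar_prev) * beta / (1.0 - abar_t)
    ct = np.sqrt(alpha) * (1.0 - abar_prev) / (1.0 - abar_t)
    return c0 * x0_hat + ct * xt, schedule.posterior_var(t)


def forward_sample_types(v0: np.ndarray, t: int, schedule: VarianceSchedule, K: int | None = None,
                         seed=0) -> np.ndarray:
    """Draw one-hot v_t rows from Cat(abar_t v_0 + (1-abar_t)/K)."""
    v0 = np.atleast_2d(np.asarray(v0, float))
    K = K or v0.shape[1]
    abar = schedule.alpha_bar_t(t)
    probs = abar * v0 + (1.0 - abar) / K
    rng = _rng(seed)
    out = np.zeros_like(v0)
    for i, p in enumerate(probs):
        out[i, rng.choice(K, p=p / p.sum())] = 1.0
    return out


def posterior_types(vt: np.ndarray, v0_hat: np.ndarray, t: int, schedule: VarianceSchedule,
                    K: int | None = None) -> np.ndarray:
    """Posterior type rows theta_c = theta*/sum(theta*) of q(v_{t-1}|v_t, v_0=v0_hat)."""
    vt = np.atleast_2d(np.asarray(vt, float))
    v0_hat = np.atleast_2d(np.asarray(v0_hat, float))
    K = K or vt.shape[1]
    alpha = schedule.alpha_t(t)
    abar_prev = schedule.alpha_bar_t(t - 1)
    theta = (alpha * vt + (1.0 - alpha) / K) * (abar_prev * v0_hat + (1.0 - abar_prev) / K)
    norm = theta.sum(axis=-1, keepdims=True)
    if np.any(norm <= 0):
        raise ValueError("degenerate type posterior (all-zero unnormalized mass)")
    return theta / norm


def loss_coords(x0: np.ndarray, x0_hat: np.ndarray) -> float:
    """Squared-error denoising loss ||x_0 - x^_0||^2 on nuclei coordinates."""
    x0 = np.asarray(x0, float)
    x0_hat = np.asarray(x0_hat, float)
    if x0.shape != x0_hat.shape:
        raise ValueError(f"shape mismatch: {x0.shape} vs {x0_hat.shape}")
    return float(np.sum((x0 - x0_hat) ** 2))


def loss_mesh(x0M: np.ndarray, x0M_hat: np.ndarray) -> float:
    """Squared-error denoising loss on manifold mesh-point coordinates."""
    return loss_coords(x0M, x0M_hat)


def loss_types(vt: np.ndarray, v0: np.ndarray, v0_hat: np.ndarray, t: int,
               schedule: VarianceSchedule) -> float:
    """KL( q(v_{t-1}|v_t,v_0) || q(v_{t-1}|v_t,v^_0) ), summed over atoms."""
    p = posterior_types(vt, v0, t, schedule)
    q = posterior_types(vt, v0_hat, t, schedule)
    eps = 1e-30
    return float(np.sum(p * (np.log(p + eps) - np.log(q + eps))))


def loss_reg(x0N_hat: np.ndarray, x0M_hat: np.ndarray,
             assignments: Sequence[MeshPointAssignment]) -> float:
    """Manifold-radius regularizer: sum_i sum_j | ||x^N_i - x^M_ij|| - R_i |.

    ``x0M_hat`` holds the predicted mesh points in assignment order
    (concatenated per nucleus); nucleus and mesh predictions may come from
    different corruption timesteps — the loss is purely geometric.
    """
    x0N_hat = np.asarray(x0N_hat, float)
    x0M_hat = np.asarray(x0M_hat, float).reshape(-1, 3)
    expected = sum(len(a.points) for a in assignments)
    if len(x0M_hat) != expected:
        raise ValueError(f"{len(x0M_hat)} mesh predictions for {expected} assigned points")
    total = 0.0
    offset = 0
    for a in assignments:
        c = len(a.points)
        pts = x0M_hat[offset:offset + c]
        d = np.linalg.norm(pts - x0N_hat[a.nucleus_index][None, :], axis=1)
        total += float(np.sum(np.abs(d - a.target_radius)))
        offset += c
    return total


def total_loss(parts: LossBreakdown, weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)) -> float:
    """Weighted sum of the four objective terms (unit weights by default)."""
    return (weights[0] * parts.loss_coords_N + weights[1] * parts.loss_types_N
            + weights[2] * parts.loss_coords_M + weights[3] * parts.loss_reg)
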