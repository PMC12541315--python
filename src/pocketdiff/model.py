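"""Reference denoiser, training loop, and reverse-diffusion sampler.

The denoiser is a deliberately small message-passing network over the graph
of ligand nuclei, manifold mesh points (training only), and pocket atoms.
Coordinates are canonicalized to the pocket center of mass; pocket atoms act
as fixed geometric anchors, so the coordinate readout — a learned
combination of difference vectors to graph neighbors — can express
pocket-frame positions while staying permutation-equivariant over atoms.
Mesh points carry a dedicated type token; nuclei carry their (noisy)
categorical type rows.

Training assembles the four-term objective: squared error on nuclei
coordinates and on mesh coordinates, KL on type posteriors, and the
manifold-radius regularizer, with nuclei and mesh corrupted at
independently drawn timesteps. Inference ignores the mesh head entirely and
anneals nuclei coordinates/types through the learned posteriors from pure
noise.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chem import ComplexRecord, DEFAULT_ATOM_VOCABULARY, LigandStructure, PocketStructure, lookup_radii
from .diffusion import (VarianceSchedule, build_schedule, forward_sample_coords,
                        forward_sample_types, posterior_coords, posterior_types)
from .mesh import MeshParams, MeshPointAssignment, assign_mesh_points, molecular_surface
from .synth import SizeDistribution

__all__ = ["DenoiserHyperparams", "TrainConfig", "SampleConfig", "ReferenceDenoiser",
           "prepare_training_complex", "train", "reverse_sample", "generate_set",
           "save_checkpoint", "load_checkpoint"]


@dataclasses.dataclass(frozen=True)
class DenoiserHyperparams:
    n_types: int = len(DEFAULT_ATOM_VOCABULARY)
    hidden: int = 48
    n_layers: int = 2
    k_intra: int = 6    # neighbors among nuclei+mesh nodes
    k_pocket: int = 6   # pocket-atom anchors per node
    t_embed: int = 8
    n_slots: int = 12   # learned pose slots for the matching readout
    init_seed: int = 0


@dataclasses.dataclass
class TrainConfig:
    T: int = 100
    schedule_kind: str = "linear"
    learning_rate: float = 5e-3
    n_steps: int = 1000
    reg_weight: float = 1.0
    loss_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    seed: int = 0
    mesh_points_per_nucleus: int = 4

    def __post_init__(self):
        if min(self.T, self.n_steps, self.mesh_points_per_nucleus) < 1 or self.learning_rate <= 0:
            raise ValueError("positive values required")


@dataclasses.dataclass
class SampleConfig:
    n_samples: int = 1
    T: int | None = None     # defaults to the training schedule's T
    correction: str | None = None  # None | 'parallelogram' | 'circle'
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def _mlp_params(rng, sizes, prefix):
    params = {}
    for k, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        params[f"{prefix}_W{k}"] = Tensor.param(rng.normal(0, np.sqrt(1.0 / n_in), (n_in, n_out)))
        params[f"{prefix}_b{k}"] = Tensor.param(np.zeros(n_out))
    return params


def _mlp(params, prefix, x, n_layers):
    for k in range(n_layers):
        x = x @ params[f"{prefix}_W{k}"] + params[f"{prefix}_b{k}"]
        if k < n_layers - 1:
            x = ad.silu(x)
    return x


# feature normalization scales (Angstrom): keep MLP inputs O(1)
_COORD_SCALE = 8.0
_DIST2_SCALE = 25.0


def _t_embedding(t: int, T: int, dim: int) -> np.ndarray:
    freqs = 2.0 ** np.arange(dim // 2)
    angle = freqs * np.pi * (t / T)
    return np.concatenate([np.sin(angle), np.cos(angle)])


class ReferenceDenoiser:
    """Small EGNN-flavored denoiser fulfilling the network contract.

    Callable as ``denoiser(xtN, vtN, xtM, t_n, t_m, pocket)`` returning
    ``(x0N_hat, v0N_hat, x0M_hat)`` as numpy arrays (``x0M_hat`` is None when
    no mesh points are passed). ``forward_tensors`` exposes the same
    computation as autodiff tensors for training.
    """

    # node-feature channels: [type vocab | mesh token | pocket token |
    #                         canonical xyz | t-embed]
    # Canonical (pocket-centered) coordinates enter as plain features: the
    # net is translation-invariant through the canonical frame but makes no
    # claim to rotational equivariance, which lets it memorize pocket-frame
    # poses — necessary on a near-symmetric synthetic shell whose atoms are
    # otherwise indistinguishable.
    def __init__(self, hp: DenoiserHyperparams = DenoiserHyperparams(),
                 schedule: VarianceSchedule | None = None):
        self.hp = hp
        self.schedule = schedule if schedule is not None else build_schedule(100)
        rng = np.random.default_rng(hp.init_seed)
        feat = hp.n_types + 2 + 3 + hp.t_embed
        H = hp.hidden
        self.params: dict[str, Tensor] = {}
        self.params.update(_mlp_params(rng, (feat, H), "embed"))
        for layer in range(hp.n_layers):
            self.params.update(_mlp_params(rng, (2 * H + 1, H, H), f"msg{layer}"))
            self.params.update(_mlp_params(rng, (2 * H, H, H), f"upd{layer}"))
        self.params.update(_mlp_params(rng, (2 * H + 1, H, 1), "coord"))
        self.params.update(_mlp_params(rng, (2 * H + 1, H, 1), "attn"))
        self.params.update(_mlp_params(rng, (H, H, 1), "gate"))
        self.params.update(_mlp_params(rng, (2 * H + 1, H, 1), "refine"))
        self.params.update(_mlp_params(rng, (H, H, hp.n_types), "type"))
        # learned pose slots (canonical pocket frame) + matching head
        self.params["slots"] = Tensor.param(rng.normal(0, 2.0, (hp.n_slots, 3)))
        self.params.update(_mlp_params(rng, (H, H, hp.n_slots), "slot_logit"))
        self.params.update(_mlp_params(rng, (H, H, 1), "slot_gate"))

    # ------------------------------------------------------------------
    def _edges(self, coords: np.ndarray, n_model: int, n_pocket: int):
        """Directed edges into each model node: k_intra nearest model nodes
        plus k_pocket nearest pocket anchors (pocket nodes receive none)."""
        src, dst = [], []
        model = coords[:n_model]
        pocket = coords[n_model:]
        for i in range(n_model):
            d = np.linalg.norm(model - model[i][None, :], axis=1)
            d[i] = np.inf
            k = min(self.hp.k_intra, n_model - 1)
            for j in np.argsort(d, kind="stable")[:k]:
                src.append(int(j)); dst.append(i)
            dp = np.linalg.norm(pocket - model[i][None, :], axis=1)
            for j in np.argsort(dp, kind="stable")[:min(self.hp.k_pocket, n_pocket)]:
                src.append(n_model + int(j)); dst.append(i)
        return np.array(src, int), np.array(dst, int)

    def forward_tensors(self, xtN: np.ndarray, vtN, xtM: np.ndarray | None,
                        t_n: int, t_m: int | None, pocket: PocketStructure):
        hp = self.hp
        vtN = np.atleast_2d(np.asarray(vtN, float))
        n, m, p = len(xtN), (0 if xtM is None else len(xtM)), len(pocket)
        center = pocket.coords.mean(axis=0)
        coords = np.concatenate([np.asarray(xtN, float) - center]
                                + ([np.asarray(xtM, float) - center] if m else [])
                                + [pocket.coords - center])
        # node features
        feats = np.zeros((n + m + p, hp.n_types + 2 + 3 + hp.t_embed))
        feats[:n, :hp.n_types] = vtN
        feats[:n, -hp.t_embed:] = _t_embedding(t_n, self.schedule.T, hp.t_embed)
        if m:
            feats[n:n + m, hp.n_types] = 1.0  # mesh token
            feats[n:n + m, -hp.t_embed:] = _t_embedding(t_m, self.schedule.T, hp.t_embed)
        feats[n + m:, hp.n_types + 1] = 1.0   # pocket token
        feats[:, hp.n_types + 2:hp.n_types + 5] = coords / _COORD_SCALE
        src, dst = self._edges(coords, n + m, p)
        dist2 = np.sum((coords[src] - coords[dst]) ** 2, axis=1, keepdims=True) / _DIST2_SCALE

        h = _mlp(self.params, "embed", Tensor(feats), 1)
        n_nodes = n + m + p
        deg_inv = None
        for layer in range(hp.n_layers):
            h_src, h_dst = ad.gather(h, src), ad.gather(h, dst)
            msg_in = ad.concat([h_dst, h_src, Tensor(dist2)], axis=1)
            msg = _mlp(self.params, f"msg{layer}", msg_in, 2)
            if deg_inv is None:
                counts = np.zeros(n_nodes)
                np.add.at(counts, dst, 1.0)
                deg_inv = Tensor(1.0 / np.maximum(counts, 1.0)[:, None])
            agg = ad.scatter_add(msg, dst, n_nodes) * deg_inv  # mean aggregation
            h = h + _mlp(self.params, f"upd{layer}", ad.concat([h, agg], axis=1), 2)
            h = ad.tanh(h * 0.25) * 4.0  # soft clamp keeps hidden states O(1)
        # coordinate readout: gated blend of (i) an anchor-attention pose
        # (convex combination of pocket positions: reaches any in-pocket
        # location) and (ii) the noisy position plus a local EGNN correction.
        h_src, h_dst = ad.gather(h, src), ad.gather(h, dst)
        w = ad.tanh(_mlp(self.params, "coord", ad.concat([h_dst, h_src, Tensor(dist2)], axis=1), 2) * 0.5) * 4.0
        moves = w * Tensor(coords[src] - coords[dst])
        deg = np.zeros(n_nodes)
        np.add.at(deg, dst, 1.0)
        delta = ad.scatter_add(moves, dst, n_nodes) * Tensor(1.0 / np.maximum(deg, 1.0)[:, None])
        # scale local corrections by the forward-noise magnitude sqrt(1-abar):
        # near t=0 the noisy position is already the answer and corrections
        # vanish; at high t full-size moves are allowed
        noise_mag = np.ones((n + m, 1)) * np.sqrt(1.0 - self.schedule.alpha_bar_t(t_n))
        if m:
            noise_mag[n:] = np.sqrt(1.0 - self.schedule.alpha_bar_t(t_m))
        local = Tensor(coords[:n + m]) + ad.gather(delta, np.arange(n + m)) * Tensor(noise_mag)
        # attention of each model node over every pocket anchor
        mi = np.repeat(np.arange(n + m), p)
        ai = np.tile(np.arange(n + m, n_nodes), n + m)
        ad2 = np.sum((coords[mi] - coords[ai]) ** 2, axis=1, keepdims=True) / _DIST2_SCALE
        logits = _mlp(self.params, "attn",
                      ad.concat([ad.gather(h, mi), ad.gather(h, ai), Tensor(ad2)], axis=1),
                      2).reshape(n + m, p)
        attn = ad.softmax(logits, axis=1)
        anchored = attn @ Tensor(coords[n + m:])
        # gate prior follows the corruption signal-to-noise: at low t the
        # noisy position is almost the answer (gate -> 0, identity path); at
        # high t it carries no signal (gate -> 1, anchored pose). The MLP
        # learns residual modulation around this analytic prior.
        def snr_logit(t):
            abar = self.schedule.alpha_bar_t(t)
            return float(np.log((1.0 - abar) / max(abar, 1e-12)))
        prior = np.zeros((n + m, 1))
        prior[:n] = snr_logit(t_n)
        if m:
            prior[n:] = snr_logit(t_m)
        gate = ad.sigmoid(_mlp(self.params, "gate", ad.gather(h, np.arange(n + m)), 2) + Tensor(prior))
        xyz = gate * anchored + (1.0 - gate) * local
        # nuclei bypass the anchored path: their global pose memory is the
        # slot-matching readout below (if both paths are offered, optimization
        # parks the pose in the per-atom anchored path, which cannot
        # coordinate slot assignment between atoms)
        local_n = ad.gather(local, np.arange(n))
        # matching readout: soft assignment of nuclei to learned pose slots,
        # Sinkhorn-normalized so atoms compete for slots (a per-atom readout
        # lets two atoms claim the same site; column competition forbids it)
        slots = self.params["slots"]
        S = slots.shape[0]  # may be below hp.n_slots after data-driven init
        h_n = ad.gather(h, np.arange(n))
        si = np.repeat(np.arange(n), S)
        sj = np.tile(np.arange(S), n)
        # Bayes form of the assignment under Gaussian corruption of a point
        # template: logit_ik = -|x_i - sqrt(abar) mu_k|^2 / (2 (1-abar)),
        # plus a learned per-slot bias from the node embedding (type/time
        # awareness). Sharpness capped for numerical sanity at tiny noise.
        abar_n = self.schedule.alpha_bar_t(t_n)
        diff_sl = Tensor(coords[si]) - ad.gather(slots, sj) * np.sqrt(abar_n)
        d2_sl = (diff_sl * diff_sl).sum(axis=1, keepdims=True)
        sharp = 1.0 / (2.0 * (1.0 - abar_n) + 0.02)
        bias = _mlp(self.params, "slot_logit", h_n, 2)
        if S < self.hp.n_slots:
            bias = ad.take_cols(bias, S)
        logits = (d2_sl * (-sharp)).reshape(n, S) + bias
        beta = ad.softmax(logits, axis=1)
        for _ in range(2):  # Sinkhorn rounds: column competition, row re-normalize
            beta = beta / (beta.sum(axis=0, keepdims=True) + 1e-9)
            beta = beta / (beta.sum(axis=1, keepdims=True) + 1e-9)
        matched = beta @ slots
        g2 = ad.sigmoid(_mlp(self.params, "slot_gate", h_n, 2) + Tensor(prior[:n]))
        xyz_n = g2 * matched + (1.0 - g2) * local_n
        # pairwise refinement: short-range repulsion (never attraction — an
        # attractive term learns the centroid local optimum and collapses
        # sampling) separating nuclei that compete for one site; scaled by
        # the noise magnitude so the low-t identity behavior is untouched
        if n > 1:
            pi, pj = np.nonzero(~np.eye(n, dtype=bool))
            dvec = ad.gather(xyz_n, pi) - ad.gather(xyz_n, pj)
            pd2 = (dvec * dvec).sum(axis=1, keepdims=True)
            amp = ad.sigmoid(_mlp(self.params, "refine",
                                  ad.concat([ad.gather(h, pi), ad.gather(h, pj), pd2], axis=1), 2))
            rep = amp * ad.exp(-1.0 * pd2)
            push = ad.scatter_add(rep * dvec, pi, n) * Tensor(np.full((n, 1), 1.0 / (n - 1)))
            xyz_n = xyz_n + push * Tensor(noise_mag[:n])
        x0N = xyz_n + Tensor(center)
        x0M = ad.gather(xyz, np.arange(n, n + m)) + Tensor(center) if m else None
        v0N = ad.softmax(_mlp(self.params, "type", ad.gather(h, np.arange(n)), 2))
        return x0N, v0N, x0M

    def __call__(self, xtN, vtN, xtM, t_n, t_m, pocket):
        x0N, v0N, x0M = self.forward_tensors(xtN, vtN, xtM, t_n, t_m, pocket)
        return x0N.data, v0N.data, None if x0M is None else x0M.data


# ---------------------------------------------------------------------------
# Training


def prepare_training_complex(complex_: ComplexRecord, vocabulary=DEFAULT_ATOM_VOCABULARY,
                             c: int = 4, mesh_params: MeshParams | None = None):
    """Precompute one training item: one-hot types, mesh-point assignments,
    and flattened mesh targets (assignment order)."""
    lig = complex_.ligand
    vocab = {s: i for i, s in enumerate(vocabulary)}
    v0 = np.zeros((len(lig), len(vocabulary)))
    for i, s in enumerate(lig.symbols):
        if s not in vocab:
            raise ValueError(f"element {s} outside the type vocabulary {vocabulary}")
        v0[i, vocab[s]] = 1.0
    params = mesh_params if mesh_params is not None else MeshParams(subdivision_level=1)
    surface = molecular_surface(lig, params)
    assignments = assign_mesh_points(lig, surface, c)
    x0M = np.concatenate([a.points for a in assignments])
    return {"complex": complex_, "v0": v0, "assignments": assignments, "x0M": x0M}


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.zero_grad()


def _losses_tensor(denoiser: ReferenceDenoiser, item: dict, t_n: int, t_m: int,
                   rng: np.random.Generator, schedule: VarianceSchedule, reg_weight: float):
    complex_, v0, x0M = item["complex"], item["v0"], item["x0M"]
    x0N = complex_.ligand.coords
    xtN = forward_sample_coords(x0N, t_n, schedule, rng)
    vtN = forward_sample_types(v0, t_n, schedule, seed=rng)
    xtM = forward_sample_coords(x0M, t_m, schedule, rng)
    x0N_hat, v0N_hat, x0M_hat = denoiser.forward_tensors(xtN, vtN, xtM, t_n, t_m, complex_.pocket)

    diff_n = x0N_hat - Tensor(x0N)
    l_coords = (diff_n * diff_n).sum()
    diff_m = x0M_hat - Tensor(x0M)
    l_mesh = (diff_m * diff_m).sum()
    # KL(posterior(vt, v0) || posterior(vt, v0_hat)) in tensor form
    K = v0.shape[1]
    alpha = schedule.alpha_t(t_n)
    abar_prev = schedule.alpha_bar_t(t_n - 1)
    p = posterior_types(vtN, v0, t_n, schedule)
    a_const = alpha * vtN + (1.0 - alpha) / K
    theta = Tensor(a_const) * (v0N_hat * abar_prev + (1.0 - abar_prev) / K)
    theta_n = theta / theta.sum(axis=1, keepdims=True)
    l_types = Tensor(p * np.log(p + 1e-30)).sum() - (Tensor(p) * ad.log(theta_n + 1e-30)).sum()
    # manifold-radius regularizer on predictions (decoupled timesteps)
    assignments: Sequence[MeshPointAssignment] = item["assignments"]
    nucleus_idx = np.concatenate([[a.nucleus_index] * len(a.points) for a in assignments]).astype(int)
    radii = np.concatenate([[a.target_radius] * len(a.points) for a in assignments])
    diff = ad.gather(x0N_hat, nucleus_idx) - x0M_hat
    dist = ad.sqrt((diff * diff).sum(axis=1) + 1e-12)
    l_reg = ad.absval(dist - Tensor(radii)).sum()
    total = l_coords + l_types + l_mesh + l_reg * reg_weight
    return total, {"loss_coords_N": float(l_coords.data), "loss_types_N": float(l_types.data),
                   "loss_coords_M": float(l_mesh.data), "loss_reg": float(l_reg.data)}


def _init_slots_from_data(denoiser: ReferenceDenoiser, dataset: list[dict], seed: int) -> None:
    """k-means initialization of the pose slots from the training ligands'
    pocket-frame coordinates (the usual mixture-model warm start; random
    slot initialization tends to collapse toward the data centroid)."""
    from scipy.cluster.vq import kmeans2

    pts = np.concatenate([
        item["complex"].ligand.coords - item["complex"].pocket.coords.mean(axis=0)
        for item in dataset
    ])
    S = denoiser.hp.n_slots
    n_unique = len(np.unique(np.round(pts, 6), axis=0))
    k_eff = min(S, n_unique)
    centers, _ = kmeans2(pts, k_eff, minit="++", seed=abs(seed) + 1)
    # the readout sizes itself from this parameter, so surplus slots are
    # simply dropped (duplicated in-pocket slots would split one site's
    # assignment; far-away padding slots poison the high-noise pose average)
    denoiser.params["slots"].data = centers


def train(dataset: list[dict], denoiser: ReferenceDenoiser, cfg: TrainConfig):
    """Stochastic training over prepared complexes; returns the loss history.

    One complex per step (cycled in seeded shuffled order); nuclei and mesh
    timesteps drawn independently and uniformly from 1..T. Per-step RNG
    streams are derived from (seed, step), so an interrupted-and-resumed run
    replays the uninterrupted one exactly. Raises on NaN loss.
    """
    schedule = denoiser.schedule
    _init_slots_from_data(denoiser, dataset, cfg.seed)
    opt = _Adam(denoiser.params, cfg.learning_rate)
    history = []
    lr_min = cfg.learning_rate / 12.0
    order = np.random.default_rng(cfg.seed).permutation(len(dataset))
    for step in range(cfg.n_steps):
        # cosine learning-rate decay to lr/12
        opt.lr = lr_min + 0.5 * (cfg.learning_rate - lr_min) * (1 + np.cos(np.pi * step / cfg.n_steps))
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, step]))
        item = dataset[int(order[step % len(dataset)])]
        t_n = int(rng.integers(1, cfg.T + 1))
        t_m = int(rng.integers(1, cfg.T + 1))
        total, parts = _losses_tensor(denoiser, item, t_n, t_m, rng, schedule, cfg.reg_weight)
        if not np.isfinite(total.data):
            raise RuntimeError(f"NaN/inf loss at step {step}: {parts}")
        total.backward()
        opt.step()
        parts["total"] = float(total.data)
        parts["step"] = step
        history.append(parts)
    return history


def save_checkpoint(denoiser: ReferenceDenoiser, cfg: TrainConfig, path, extra: dict | None = None):
    """Checkpoint = directory with JSON metadata + npz weight blob."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {"hyperparams": dataclasses.asdict(denoiser.hp),
            "train_config": dataclasses.asdict(cfg),
            "schedule": {"T": denoiser.schedule.T, "beta": denoiser.schedule.beta.tolist(),
                         "strict_paper_variance": denoiser.schedule.strict_paper_variance},
            "extra": extra or {}}
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    np.savez(path / "weights.npz", **{k: p.data for k, p in denoiser.params.items()})


def load_checkpoint(path) -> tuple[ReferenceDenoiser, TrainConfig, dict]:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    hp = DenoiserHyperparams(**meta["hyperparams"])
    sched = VarianceSchedule(meta["schedule"]["T"], np.array(meta["schedule"]["beta"]),
                             meta["schedule"]["strict_paper_variance"])
    tc = meta["train_config"]
    tc["loss_weights"] = tuple(tc["loss_weights"])
    cfg = TrainConfig(**tc)
    denoiser = ReferenceDenoiser(hp, sched)
    weights = np.load(path / "weights.npz")
    for k in denoiser.params:
        denoiser.params[k].data = weights[k]
    return denoiser, cfg, meta["extra"]


# ---------------------------------------------------------------------------
# Sampling


def reverse_sample(pocket: PocketStructure, n_atoms: int, denoiser: ReferenceDenoiser,
                   schedule: VarianceSchedule | None = None, seed: int = 0,
                   vocabulary=DEFAULT_ATOM_VOCABULARY):
    """Reverse diffusion from noise to a ligand in the given pocket.

    Nuclei coordinates start from a standard normal around the pocket center
    and types from uniform; each step predicts clean data and samples the
    Gaussian/categorical posteriors. At t=1 the posterior mean is returned
    and types are decoded by argmax. Mesh points are ignored at inference.
    Returns ``(ligand, trajectory)`` where ``trajectory[k]`` holds the
    coordinates after k inference steps (length T+1).
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    schedule = schedule if schedule is not None else denoiser.schedule
    K = denoiser.hp.n_types
    rng = np.random.default_rng(seed)
    center = pocket.coords.mean(axis=0)
    x = center + rng.standard_normal((n_atoms, 3))
    v = np.zeros((n_atoms, K))
    v[np.arange(n_atoms), rng.integers(0, K, n_atoms)] = 1.0
    trajectory = [x.copy()]
    for t in range(schedule.T, 0, -1):
        x0_hat, v0_hat, _ = denoiser(x, v, None, t, None, pocket)
        mean, var = posterior_coords(x, x0_hat, t, schedule)
        x = mean if t == 1 else mean + np.sqrt(var) * rng.standard_normal(mean.shape)
        probs = posterior_types(v, v0_hat, t, schedule, K)
        if t == 1:
            v = np.zeros_like(probs)
            v[np.arange(n_atoms), probs.argmax(axis=1)] = 1.0
        else:
            nxt = np.zeros_like(probs)
            for i, p in enumerate(probs):
                nxt[i, rng.choice(K, p=p / p.sum())] = 1.0
            v = nxt
        trajectory.append(x.copy())
    elements = [lookup_radii(vocabulary[int(k)]) for k in v.argmax(axis=1)]
    ligand = LigandStructure(elements, x)
    return ligand, trajectory


def generate_set(pockets: Sequence[PocketStructure], denoiser: ReferenceDenoiser,
                 size_dist: SizeDistribution, cfg: SampleConfig = SampleConfig()) -> list[ComplexRecord]:
    """Sample ``cfg.n_samples`` ligands per pocket, sizes from ``size_dist``;
    optional post-correction; provenance records all seeds."""
    from .collisions import CollisionConfig
    from .geometry import correct_complex

    schedule = denoiser.schedule
    out = []
    for pi, pocket in enumerate(pockets):
        sizes = size_dist.sample(cfg.n_samples, np.random.default_rng(
            np.random.SeedSequence([cfg.seed, pi])))
        for si in range(cfg.n_samples):
            sample_seed = int(np.random.SeedSequence([cfg.seed, pi, si]).generate_state(1)[0] % (2**31))
            ligand, _ = reverse_sample(pocket, int(sizes[si]), denoiser, schedule, sample_seed)
            rec = ComplexRecord(ligand, pocket,
                                provenance=f"sample(pocket={pi},i={si},seed={sample_seed})")
            if cfg.correction:
                rec, _, _ = correct_complex(rec, CollisionConfig(K=min(10, len(pocket))),
                                            method=cfg.correction, seed=cfg.seed)
                rec.provenance += f"|corrected({cfg.correction})"
            out.append(rec)
    return out
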