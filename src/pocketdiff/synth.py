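"""Seeded generator of toy pocket-ligand complexes and toy training sets.

The generator stands in for a docked-complex corpus: each complex is a
spherical shell of backbone-like pocket atoms enclosing a small connected
ligand cluster near the shell center. Steric clashes can be injected at a
controlled fraction so that collision metrics and post-corrections have
non-vacuous inputs. Everything is a pure function of the config, seed
included.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np

from .chem import (
    ComplexRecord,
    LigandStructure,
    PocketStructure,
    k_nearest_pocket_atoms,
    lookup_radii,
    pair_threshold,
)

__all__ = [
    "SynthConfig",
    "SizeDistribution",
    "make_pocket_shell",
    "make_ligand_template",
    "inject_collisions",
    "make_training_set",
    "write_dataset",
]

_JITTER = 0.2  # radial jitter bound on shell atoms, Angstrom


@dataclasses.dataclass
class SynthConfig:
    """Parameters of the synthetic world.

    Defaults mirror the desk-scale benchmark: 50 complexes in an 8 A shell of
    40 pocket atoms, ligand sizes uniform over 6..10 atoms, no clashes unless
    requested.
    """

    seed: int = 7
    n_complexes: int = 50
    pocket_radius: float = 8.0
    pocket_atom_count: int = 40
    ligand_size_distribution: dict[int, float] = dataclasses.field(
        default_factory=lambda: {n: 0.2 for n in range(6, 11)}
    )
    clash_fraction: float = 0.0
    element_palette: tuple[str, ...] = ("C", "N", "O")

    def __post_init__(self):
        if not 0.0 <= self.clash_fraction <= 1.0:
            raise ValueError("clash_fraction must lie in [0, 1]")
        total = sum(self.ligand_size_distribution.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("ligand size distribution must sum to 1")


class SizeDistribution:
    """Empirical ligand-size distribution; supports seeded sampling.

    Mirrors drawing generated-molecule sizes from the size distribution
    observed in a training set.
    """

    def __init__(self, probs: dict[int, float]):
        self.sizes = np.array(sorted(probs), dtype=int)
        self.probs = np.array([probs[s] for s in self.sizes], dtype=float)
        self.probs = self.probs / self.probs.sum()

    @classmethod
    def from_counts(cls, sizes) -> "SizeDistribution":
        vals, counts = np.unique(np.asarray(sizes, dtype=int), return_counts=True)
        return cls({int(v): c / counts.sum() for v, c in zip(vals, counts)})

    def sample(self, n: int, seed: int | np.random.Generator) -> np.ndarray:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return rng.choice(self.sizes, size=n, p=self.probs)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Unit-sphere Fibonacci lattice: near-uniform n points."""
    i = np.arange(n, dtype=float)
    phi = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / phi
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def make_pocket_shell(cfg: SynthConfig, rng: np.random.Generator | None = None) -> PocketStructure:
    """Pocket atoms on a jittered sphere of radius ``cfg.pocket_radius``.

    Backbone-like N/CA/C/O element cycling; radial jitter is bounded by 0.2 A
    so every atom radius stays within [R - 0.2, R + 0.2].
    """
    if cfg.pocket_atom_count < 4:
        raise ValueError("pocket_atom_count must be >= 4")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    directions = _fibonacci_sphere(cfg.pocket_atom_count)
    radii = cfg.pocket_radius + rng.uniform(-_JITTER, _JITTER, size=cfg.pocket_atom_count)
    coords = directions * radii[:, None]
    backbone = ["N", "C", "C", "O"]
    names = ["N", "CA", "C", "O"]
    elements = [lookup_radii(backbone[i % 4]) for i in range(cfg.pocket_atom_count)]
    atom_names = [names[i % 4] for i in range(cfg.pocket_atom_count)]
    labels = [(i // 4 + 1, "GLY") for i in range(cfg.pocket_atom_count)]
    return PocketStructure(elements, coords, labels, atom_names)


def make_ligand_template(n_atoms: int, palette=("C", "N", "O"), seed: int | np.random.Generator = 0,
                         max_attempts: int = 1000) -> LigandStructure:
    """A connected, internally clash-free ligand cluster centered at the origin.

    Atoms are grown one at a time: each new atom is bonded to a random
    existing atom at 1.15x the covalent-radius sum and accepted only if every
    pairwise distance stays at or above the corresponding covalent sums.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    elements = [lookup_radii(str(rng.choice(palette))) for _ in range(n_atoms)]
    coords = np.zeros((n_atoms, 3))
    bonds: list[tuple[int, int]] = []
    for i in range(1, n_atoms):
        placed = False
        for _ in range(max_attempts):
            anchor = int(rng.integers(i))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            bond_len = 1.15 * pair_threshold(elements[anchor], elements[i])
            candidate = coords[anchor] + bond_len * direction
            dists = np.linalg.norm(coords[:i] - candidate[None, :], axis=1)
            thresholds = np.array([pair_threshold(elements[j], elements[i]) for j in range(i)])
            if np.all(dists >= thresholds):
                coords[i] = candidate
                bonds.append((anchor, i))
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not place atom {i} in {max_attempts} attempts")
    coords -= coords.mean(axis=0)
    return LigandStructure(elements, coords, bonds)


def inject_collisions(complex_: ComplexRecord, fraction: float,
                      seed: int | np.random.Generator = 0) -> ComplexRecord:
    """Move a seeded subset of ligand atoms to within < D_ij of a pocket atom.

    ``ceil(fraction * n_atoms)`` atoms are displaced (at least one whenever
    fraction > 0), each to a point strictly inside the covalent-sum threshold
    of its nearest pocket atom, on the inward side of the shell. Placement
    keeps the ligand internally clash-free where geometrically possible
    (seeded rejection sampling over the inward hemisphere), falling back to
    the straight inward ray. The input complex is left untouched.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    ligand, pocket = complex_.ligand, complex_.pocket
    if len(ligand) == 0:
        raise ValueError("empty ligand")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_move = max(1, math.ceil(fraction * len(ligand)))
    targets = rng.choice(len(ligand), size=n_move, replace=False)
    coords = ligand.coords.copy()
    center = pocket.coords.mean(axis=0)
    for i in np.sort(targets):
        j = int(k_nearest_pocket_atoms(coords[i], pocket, 1)[0])
        d_ij = pair_threshold(ligand.elements[i], pocket.elements[j])
        inward = center - pocket.coords[j]
        norm = np.linalg.norm(inward)
        inward = inward / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        others = [k for k in range(len(ligand)) if k != i]
        thresholds = np.array([pair_threshold(ligand.elements[k], ligand.elements[i]) for k in others])
        candidate = None
        for _ in range(200):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            if direction @ inward < 0.3:  # stay on the inward hemisphere
                continue
            trial = pocket.coords[j] + direction * (float(rng.uniform(0.5, 0.9)) * d_ij)
            if np.all(np.linalg.norm(coords[others] - trial[None, :], axis=1) >= thresholds):
                candidate = trial
                break
        if candidate is None:  # geometrically crowded: accept an intra-ligand clash
            candidate = pocket.coords[j] + inward * (float(rng.uniform(0.5, 0.9)) * d_ij)
        coords[i] = candidate
    new_ligand = ligand.with_coords(coords)
    return ComplexRecord(new_ligand, pocket, provenance=complex_.provenance + f"|clash({fraction})")


_WALL_GAP = 1.6  # clearance (A) between the outermost ligand atom and the shell


def _make_complex(cfg: SynthConfig, index: int, rng: np.random.Generator,
                  size_dist: SizeDistribution) -> ComplexRecord:
    pocket = make_pocket_shell(cfg, rng)
    n_atoms = int(size_dist.sample(1, rng)[0])
    ligand = make_ligand_template(n_atoms, cfg.element_palette, rng)
    # ligands bind at the pocket surface: offset the cluster toward the wall,
    # leaving enough clearance that the complex stays clash-free
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    extent = float(np.linalg.norm(ligand.coords, axis=1).max())
    offset = max(cfg.pocket_radius - _JITTER - extent - _WALL_GAP, 0.0)
    ligand = ligand.with_coords(ligand.coords + offset * direction)
    rec = ComplexRecord(ligand, pocket, provenance=f"synth(seed={cfg.seed},i={index})")
    if cfg.clash_fraction > 0:
        rec = inject_collisions(rec, cfg.clash_fraction, rng)
    return rec


def make_training_set(cfg: SynthConfig) -> tuple[list[ComplexRecord], SizeDistribution]:
    """Generate ``cfg.n_complexes`` complexes plus the empirical size distribution.

    A single global seed drives a splittable stream per complex, so the
    output is bit-identical for identical configs regardless of how many
    complexes are consumed.
    """
    if cfg.n_complexes < 1:
        raise ValueError("n_complexes must be >= 1")
    size_dist = SizeDistribution(cfg.ligand_size_distribution)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_complexes)
    complexes = [
        _make_complex(cfg, i, np.random.default_rng(s), size_dist)
        for i, s in enumerate(streams)
    ]
    empirical = SizeDistribution.from_counts([len(c.ligand) for c in complexes])
    return complexes, empirical


def dataset_hash(complexes: list[ComplexRecord]) -> str:
    """Stable content hash of a dataset (coordinates to 1e-9, symbols, bonds)."""
    h = hashlib.sha256()
    for c in complexes:
        h.update(np.round(c.ligand.coords, 9).tobytes())
        h.update(",".join(c.ligand.symbols).encode())
        h.update(json.dumps(c.ligand.bonds).encode())
        h.update(np.round(c.pocket.coords, 9).tobytes())
        h.update(",".join(c.pocket.symbols).encode())
    return h.hexdigest()


def write_dataset(complexes: list[ComplexRecord], out_dir) -> dict:
    """Write PDB+SDF pairs plus a manifest JSON; returns the manifest."""
    from .chem import write_ligand, write_pocket

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, c in enumerate(complexes):
        pdb = out_dir / f"complex_{i:04d}_pocket.pdb"
        sdf = out_dir / f"complex_{i:04d}_ligand.sdf"
        write_pocket(c.pocket, pdb)
        write_ligand(c.ligand, sdf)
        entries.append({"pocket": pdb.name, "ligand": sdf.name, "provenance": c.provenance,
                        "n_ligand_atoms": len(c.ligand), "n_pocket_atoms": len(c.pocket)})
    manifest = {"n_complexes": len(complexes), "entries": entries,
                "dataset_hash": dataset_hash(complexes)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
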