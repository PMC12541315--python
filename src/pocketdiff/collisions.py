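"""Atomic-collision detection and collision-ratio metrics.

A ligand-protein atom pair collides when its distance falls below the sum of
the two covalent radii, D_ij = d_i + d_j. The pairwise-level collision ratio
(PLCR) counts colliding pairs among each ligand atom's K nearest pocket
atoms, normalized by K times the total ligand atom count:

    PLCR = sum_{k in mols, i in atoms_k, j in knn(i)} 1(||x_i - x_j|| < D_ij)
           / (K * sum_k N_atom^k)

The indicator is strict by default (the operational definition); a non-strict
variant (<=) is available. Atom- and molecule-level granularities are
coarser readings: the fraction of ligand atoms, or of complexes, with at
least one colliding pair in their K-neighborhoods. These two are this
package's own granularity definitions, not canonical ones.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .chem import AtomRecord, ComplexRecord, LigandStructure, PocketStructure, k_nearest_pocket_atoms, pair_threshold

__all__ = ["CollisionConfig", "CollisionReport", "is_collision", "plcr",
           "collision_granularity", "collision_trajectory"]


@dataclasses.dataclass(frozen=True)
class CollisionConfig:
    """K-nearest neighborhood size and inequality strictness for clash tests."""

    K: int = 10
    strict: bool = True

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclasses.dataclass
class CollisionReport:
    colliding_pairs: int
    denominator: int
    plcr: float
    per_molecule: list[int]
    granularity: str = "pairwise"

    def __post_init__(self):
        if not 0.0 <= self.plcr <= 1.0:
            raise ValueError("ratio out of [0, 1]")


def is_collision(ligand_atom: AtomRecord, pocket_atom: AtomRecord, cfg: CollisionConfig = CollisionConfig()) -> bool:
    """True iff the pair is closer than its covalent-sum threshold."""
    d = float(np.linalg.norm(ligand_atom.coordinate - pocket_atom.coordinate))
    thr = pair_threshold(ligand_atom.element, pocket_atom.element)
    return d < thr if cfg.strict else d <= thr


def _complex_pair_flags(ligand: LigandStructure, pocket: PocketStructure, cfg: CollisionConfig):
    """Yield (ligand_index, pocket_index, colliding) over each atom's K-neighborhood."""
    for i in range(len(ligand)):
        neighbors = k_nearest_pocket_atoms(ligand.coords[i], pocket, cfg.K)
        d = np.linalg.norm(pocket.coords[neighbors] - ligand.coords[i][None, :], axis=1)
        for j, dist in zip(neighbors, d):
            thr = pair_threshold(ligand.elements[i], pocket.elements[int(j)])
            hit = dist < thr if cfg.strict else dist <= thr
            yield i, int(j), bool(hit)


def colliding_pairs_of(complex_: ComplexRecord, cfg: CollisionConfig = CollisionConfig()) -> list[tuple[int, int]]:
    """The (ligand_index, pocket_index) pairs that collide, in deterministic order."""
    pairs = [(i, j) for i, j, hit in _complex_pair_flags(complex_.ligand, complex_.pocket, cfg) if hit]
    return sorted(pairs)


def plcr(complexes: Sequence[ComplexRecord] | ComplexRecord, cfg: CollisionConfig = CollisionConfig()) -> CollisionReport:
    """Pairwise-level collision ratio over a set of complexes."""
    if isinstance(complexes, ComplexRecord):
        complexes = [complexes]
    per_molecule = []
    total_atoms = 0
    for idx, c in enumerate(complexes):
        if cfg.K > len(c.pocket):
            raise ValueError(f"K={cfg.K} exceeds pocket size {len(c.pocket)} in complex {idx} ({c.provenance!r})")
        hits = sum(hit for _, _, hit in _complex_pair_flags(c.ligand, c.pocket, cfg))
        per_molecule.append(int(hits))
        total_atoms += len(c.ligand)
    numerator = int(sum(per_molecule))
    denominator = cfg.K * total_atoms
    return CollisionReport(numerator, denominator, numerator / denominator, per_molecule, "pairwise")


def collision_granularity(complexes: Sequence[ComplexRecord] | ComplexRecord,
                          cfg: CollisionConfig = CollisionConfig(),
                          granularity: str = "atom") -> CollisionReport:
    """Coarser collision ratios: per ligand atom or per complex."""
    if granularity not in ("atom", "molecule"):
        raise ValueError("granularity must be 'atom' or 'molecule'")
    if isinstance(complexes, ComplexRecord):
        complexes = [complexes]
    per_molecule = []
    hits = 0
    denom = 0
    for idx, c in enumerate(complexes):
        if cfg.K > len(c.pocket):
            raise ValueError(f"K={cfg.K} exceeds pocket size {len(c.pocket)} in complex {idx} ({c.provenance!r})")
        atom_hit = np.zeros(len(c.ligand), dtype=bool)
        for i, _, hit in _complex_pair_flags(c.ligand, c.pocket, cfg):
            atom_hit[i] |= hit
        per_molecule.append(int(atom_hit.sum()))
        if granularity == "atom":
            hits += int(atom_hit.sum())
            denom += len(c.ligand)
        else:
            hits += int(atom_hit.any())
            denom += 1
    return CollisionReport(hits, denom, hits / denom, per_molecule, granularity)


def collision_trajectory(states: Sequence[np.ndarray], ligand_template: LigandStructure,
                         pocket: PocketStructure, cfg: CollisionConfig = CollisionConfig(),
                         stride: int = 100) -> list[tuple[int, CollisionReport]]:
    """Evaluate PLCR along a sampling trajectory at steps 0, stride, 2*stride, ..., T.

    ``states[t]`` holds the ligand coordinates after inference step t
    (states[0] is the initial noise, states[T] the final ligand). A full
    1000-step trajectory at stride 100 yields 11 reports.
    """
    T = len(states) - 1
    if T < 0:
        raise ValueError("empty trajectory")
    steps = sorted(set(list(range(0, T + 1, stride)) + [T]))
    out = []
    for t in steps:
        lig = ligand_template.with_coords(np.asarray(states[t], dtype=float))
        out.append((t, plcr(ComplexRecord(lig, pocket), cfg)))
    return out
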