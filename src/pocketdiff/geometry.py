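"""Minimum-distance post-correction of steric clashes by exact intersection
geometry.

Both schemes relocate a colliding ligand atom ``b`` (too close to protein
atom ``a``) while preserving its distance to its nearest ligand neighbor
``c``, so local ligand geometry survives the move:

* parallelogram: ``b`` slides along the line through ``a`` and ``b`` to the
  second intersection of that line with the sphere centered at ``c`` of
  radius ``|c-b|``.
* circle: intersect the sphere centered at ``a`` with radius ``D_ab``
  (the covalent-sum clash threshold) with the sphere centered at ``c`` of
  radius ``|c-b|``; sample a point on the resulting circle with a
  predetermined random seed (default 42). The corrected pair distance is
  then exactly ``D_ab``, never a strict collision.

`correct_complex` iterates pair corrections in deterministic order until the
complex is clash-free or a round limit is hit; protein atoms never move.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .chem import AtomRecord, ComplexRecord, LigandStructure, pair_threshold
from .collisions import CollisionConfig, colliding_pairs_of

__all__ = ["CollidingPair", "IntersectionCircle", "TangentPoint", "CorrectionOutcome",
           "nearest_ligand_neighbor", "line_sphere_second_intersection",
           "sphere_sphere_intersection", "sample_on_circle", "correct_pair",
           "correct_complex"]

_TANGENT_TOL = 1e-12
# Safety margin added to the clash-threshold sphere in the circle method so the
# corrected pair distance is robustly (not just to the last ULP) above D_ab.
_SAFETY = 1e-10


@dataclasses.dataclass
class CollidingPair:
    protein_atom: AtomRecord
    ligand_atom: AtomRecord
    ligand_index: int
    threshold: float  # D_ab in Angstrom

    def __post_init__(self):
        d = float(np.linalg.norm(self.protein_atom.coordinate - self.ligand_atom.coordinate))
        if not d < self.threshold:
            raise ValueError(f"pair at {d:.3f} A is not a collision under threshold {self.threshold:.3f} A")


@dataclasses.dataclass
class IntersectionCircle:
    center: np.ndarray
    radius: float
    normal: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        self.normal = np.asarray(self.normal, float)
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if not np.isclose(np.linalg.norm(self.normal), 1.0):
            raise ValueError("normal must be a unit vector")


@dataclasses.dataclass
class TangentPoint:
    point: np.ndarray


@dataclasses.dataclass
class CorrectionOutcome:
    new_position: np.ndarray | None
    status: str  # corrected | tangent | no_intersection | invalid
    method: str  # parallelogram | circle
    ligand_index: int | None = None

    def __post_init__(self):
        has_pos = self.new_position is not None
        if has_pos != (self.status in ("corrected", "tangent")):
            raise ValueError("new_position present iff status is corrected/tangent")


def nearest_ligand_neighbor(ligand: LigandStructure, b_index: int) -> int:
    """Index of the ligand atom closest to atom ``b_index`` (tie: lowest index)."""
    if len(ligand) < 2:
        raise ValueError("single-atom ligand has no neighbor")
    d = np.linalg.norm(ligand.coords - ligand.coords[b_index][None, :], axis=1)
    d[b_index] = np.inf
    return int(np.argmin(d))  # argmin returns the first (lowest-index) minimum


def line_sphere_second_intersection(a, b, center, r: float) -> CorrectionOutcome:
    """Second intersection of the line through a, b with the sphere (center, r).

    ``b`` is assumed to lie on the sphere (|center-b| = r), so t=1 is a root
    of the quadratic |a + t(b-a) - center|^2 = r^2 and the other root is
    recovered from the product of roots. A double root at b means the line is
    tangent there.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    center = np.asarray(center, float)
    d = b - a
    A = float(d @ d)
    if A == 0.0:
        raise ValueError("degenerate direction: a == b")
    C = float((a - center) @ (a - center)) - r * r
    t2 = C / A  # product of roots; the known root is t=1
    if abs(t2 - 1.0) < 1e-9:
        return CorrectionOutcome(b.copy(), "tangent", "parallelogram")
    return CorrectionOutcome(a + t2 * d, "corrected", "parallelogram")


def sphere_sphere_intersection(a, ra: float, c, rc: float):
    """Intersection of spheres (a, ra) and (c, rc).

    Returns an :class:`IntersectionCircle` for proper intersection, a
    :class:`TangentPoint` at (internal or external) tangency, or ``None``
    when the spheres do not meet.
    """
    if ra <= 0 or rc <= 0:
        raise ValueError("radii must be positive")
    a = np.asarray(a, float)
    c = np.asarray(c, float)
    axis = c - a
    d = float(np.linalg.norm(axis))
    if d == 0.0:
        raise ValueError("concentric spheres")
    n = axis / d
    h = (d * d + ra * ra - rc * rc) / (2.0 * d)  # signed offset of plane from a
    if abs(d - (ra + rc)) < _TANGENT_TOL or abs(d - abs(ra - rc)) < _TANGENT_TOL:
        return TangentPoint(a + h * n)
    if d > ra + rc or d < abs(ra - rc):
        return None
    r_circ = float(np.sqrt(max(ra * ra - h * h, 0.0)))
    return IntersectionCircle(a + h * n, r_circ, n)


def _circle_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the circle plane: Gram-Schmidt of
    the canonical axis least aligned with the normal."""
    k = int(np.argmin(np.abs(normal)))
    e = np.zeros(3)
    e[k] = 1.0
    u = e - (e @ normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def sample_on_circle(circle: IntersectionCircle, seed: int = 42) -> np.ndarray:
    """Uniform seeded point on a 3-D circle (deterministic in-plane basis)."""
    if circle.radius <= 0:
        raise ValueError("cannot sample on a zero-radius circle")
    u, v = _circle_basis(circle.normal)
    theta = np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi)
    return circle.center + circle.radius * (np.cos(theta) * u + np.sin(theta) * v)


def correct_pair(complex_: ComplexRecord, pair: CollidingPair, method: str = "circle",
                 seed: int = 42) -> CorrectionOutcome:
    """Relocate the colliding ligand atom of ``pair`` by one of the two schemes.

    Both preserve the distance from the moved atom to its neighbor atom c;
    the circle method additionally lands the pair on the clash threshold
    D_ab (to within a 1e-10 safety margin on the non-colliding side). The
    circle method requires |a-b| < |a-c|; its neighbor c is therefore chosen
    as the ligand atom closest to b among those satisfying that condition.
    """
    ligand = complex_.ligand
    a = pair.protein_atom.coordinate
    b = pair.ligand_atom.coordinate
    if method == "parallelogram":
        # Candidate sphere centers by ascending distance from b. The scheme
        # presumes the second intersection clears the clash; for deep clashes
        # with the nearest neighbor's sphere nearly centered on the pair this
        # can be unsatisfiable (both roots stay inside D_ab), so fall through
        # to the nearest ligand atom whose constraint is satisfiable, else
        # return the canonical nearest-neighbor outcome.
        if len(ligand) < 2:
            raise ValueError("single-atom ligand has no neighbor")
        d_to_b = np.linalg.norm(ligand.coords - b[None, :], axis=1)
        d_to_b[pair.ligand_index] = np.inf
        order = np.argsort(d_to_b, kind="stable")[: len(ligand) - 1]
        fallback = None
        for c_idx in order:
            c = ligand.coords[int(c_idx)]
            out = line_sphere_second_intersection(a, b, c, float(np.linalg.norm(c - b)))
            if fallback is None:
                fallback = out
            if out.new_position is not None and \
                    np.linalg.norm(out.new_position - a) >= pair.threshold:
                return dataclasses.replace(out, ligand_index=pair.ligand_index)
        return dataclasses.replace(fallback, ligand_index=pair.ligand_index)
    if method == "circle":
        if len(ligand) < 2:
            raise ValueError("single-atom ligand has no neighbor")
        d_ab = float(np.linalg.norm(a - b))
        d_to_b = np.linalg.norm(ligand.coords - b[None, :], axis=1)
        d_to_b[pair.ligand_index] = np.inf
        d_to_a = np.linalg.norm(ligand.coords - a[None, :], axis=1)
        # |a-c| > |a-b| (the stated condition) and |a-c| + |c-b| > D_ab so the
        # sphere around c is not swallowed by the threshold sphere around a
        admissible = np.where((d_ab < d_to_a) & (d_to_a + d_to_b > pair.threshold + 2 * _SAFETY))[0]
        admissible = admissible[admissible != pair.ligand_index]
        if len(admissible) == 0:
            raise ValueError("circle method requires a neighbor c with |a-b| < |a-c|")
        c_idx = int(admissible[np.argmin(d_to_b[admissible])])
        c = ligand.coords[c_idx]
        r_c = float(np.linalg.norm(c - b))
        inter = sphere_sphere_intersection(a, pair.threshold + _SAFETY, c, r_c)
        if inter is None:
            return CorrectionOutcome(None, "no_intersection", "circle", pair.ligand_index)
        if isinstance(inter, TangentPoint):
            return CorrectionOutcome(inter.point, "tangent", "circle", pair.ligand_index)
        return CorrectionOutcome(sample_on_circle(inter, seed), "corrected", "circle", pair.ligand_index)
    raise ValueError(f"unknown method: {method}")


def _intra_ligand_clash(ligand: LigandStructure, idx: int) -> bool:
    """Does atom ``idx`` sit strictly inside the covalent-sum distance of any other atom?"""
    for j in range(len(ligand)):
        if j == idx:
            continue
        d = float(np.linalg.norm(ligand.coords[idx] - ligand.coords[j]))
        if d < pair_threshold(ligand.elements[idx], ligand.elements[j]):
            return True
    return False


def correct_complex(complex_: ComplexRecord, cfg: CollisionConfig = CollisionConfig(),
                    method: str = "circle", seed: int = 42,
                    max_rounds: int = 10) -> tuple[ComplexRecord, list[CorrectionOutcome], bool]:
    """Iteratively eliminate every K-neighborhood collision in a complex.

    Each round scans colliding pairs, corrects them in ascending
    (ligand index, pocket index) order against the current coordinates, and
    re-scans; stops when clash-free or after ``max_rounds``. Validity goes
    false when a correction fails (no intersection / violated precondition)
    or a corrected atom lands in an intra-ligand clash. Circle-method
    sampling seeds are derived deterministically from ``seed`` per correction
    event, so runs are bit-reproducible.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    ligand = complex_.ligand
    outcomes: list[CorrectionOutcome] = []
    valid = True
    event = 0
    for _ in range(max_rounds):
        current = ComplexRecord(ligand, complex_.pocket, complex_.provenance)
        pairs = colliding_pairs_of(current, cfg)
        if not pairs:
            break
        for i, j in pairs:
            # earlier corrections this round may have resolved the pair;
            # recheck with the same scan used for detection
            still = set(colliding_pairs_of(ComplexRecord(ligand, complex_.pocket), cfg))
            if (i, j) not in still:
                continue
            b = ligand.coords[i]
            a = complex_.pocket.coords[j]
            thr = pair_threshold(ligand.elements[i], complex_.pocket.elements[j])
            pair_seed = int(np.random.SeedSequence([seed, event]).generate_state(1)[0] % (2**31))
            event += 1
            try:
                pair = CollidingPair(AtomRecord(complex_.pocket.elements[j], a),
                                     AtomRecord(ligand.elements[i], b), i, thr)
                out = correct_pair(ComplexRecord(ligand, complex_.pocket), pair, method, pair_seed)
            except ValueError:
                outcomes.append(CorrectionOutcome(None, "invalid", method, i))
                valid = False
                continue
            outcomes.append(out)
            if out.new_position is None:
                valid = False
                continue
            coords = ligand.coords.copy()
            coords[i] = out.new_position
            d_others = np.delete(np.linalg.norm(coords - out.new_position[None, :], axis=1), i)
            if np.any(d_others == 0.0):
                valid = False  # coincident with another atom: unrepresentable, leave b in place
                continue
            ligand = ligand.with_coords(coords)
            if _intra_ligand_clash(ligand, i):
                valid = False
    final = ComplexRecord(ligand, complex_.pocket, complex_.provenance)
    if colliding_pairs_of(final, cfg):
        valid = False
    return final, outcomes, valid
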