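# Methods

## Scope and model

`pocketdiff` models the conditional distribution `p(v^N, x^N, x^M | v^P, x^P)`
of ligand nuclei types, nuclei coordinates, and manifold mesh points given a
fixed protein pocket. The generative backbone is a denoising diffusion
probabilistic model with `T` steps (default 1000) and a variance schedule
`β_t` (default linear, 1e-4 → 2e-2; squared-cosine available):

* coordinates: `q(x_t|x_{t−1}) = N(√(1−β_t) x_{t−1}, β_t I)`, giving the
  closed-form marginal `q(x_t|x_0) = N(√ᾱ_t x_0, (1−ᾱ_t) I)` with
  `ᾱ_t = Π_s α_s`, `α_s = 1−β_s`, and the Gaussian posterior
  `q(x_{t−1}|x_t,x_0)` with mean
  `√ᾱ_{t−1} β_t/(1−ᾱ_t)·x_0 + √α_t (1−ᾱ_{t−1})/(1−ᾱ_t)·x_t` and variance
  `β̃_t = (1−ᾱ_{t−1})/(1−ᾱ_t)·β_t`. A `strict_paper_variance` flag drops
  the `β_t` factor to reproduce a printed variant of `β̃_t`; the default
  keeps it, matching the standard DDPM derivation (the printed form is not
  dimensionally consistent as a variance).
* types: uniform categorical diffusion over `K` classes,
  `q(v_t|v_0) = Cat(ᾱ_t v_0 + (1−ᾱ_t)/K)`, posterior
  `θ* = [α_t v_t + (1−α_t)/K] ⊙ [ᾱ_{t−1} v_0 + (1−ᾱ_{t−1})/K]` normalized.
  The type loss is implemented as a proper KL divergence between the
  posterior under the true `v_0` and under the predicted `v̂_0` (a printed
  variant omits the logarithm; we treat the text's "KL" as authoritative).

The training objective sums four terms at unit weights (configurable):
nuclei coordinate MSE, type KL, mesh coordinate MSE, and the
manifold-radius regularizer `Σ_i Σ_j |‖x̂^N_i − x̂^M_ij‖ − R_i|`, where
`R_i` is the nucleus element's van der Waals radius and the sums run over
each nucleus's assigned mesh points. Nuclei and mesh points are corrupted
at independently drawn uniform timesteps `t_n, t_m` (decoupled corruption);
the regularizer is purely geometric, so mixing timesteps is well-defined.

At inference the mesh heads are ignored: nuclei coordinates start from a
standard normal in the pocket frame, types from uniform, and both are
annealed through the learned posteriors; the `t=1` step returns the
posterior mean and the argmax type.

## Manifold discretization

The molecular surface is a union of per-atom icospheres inflated by the
probe radius (default 1.5 Å), with vertices buried inside any other atom's
inflated sphere removed and the mesh cleaned (duplicate-vertex merge at
1e-6 Å, degenerate-face and orphan-vertex removal; cleaning is idempotent).
Sampling density (default 3.0 vertices/Å²) is mapped to the nearest
icosphere subdivision level in log space — the icosphere ladder only
provides densities in ×4 steps. A true rolling-probe solvent-excluded
surface is out of scope; externally produced meshes can be imported via
OBJ/PLY and used interchangeably.

Each nucleus receives the `c` mesh vertices minimizing `| ‖v − x_i‖ − R_i |`
(ties by vertex index; vertices may serve several nuclei). `c` defaults to
8 for analysis and 4 in training items; the count is not prescribed by the
problem and is configurable. Because the surface is probe-inflated, the
assigned points sit above `R_i` for an isolated atom — the regularizer's
target is the R-shell, and the training loss pulls predicted mesh points
onto it.

## Collision metrics

The clash threshold for a pair is the covalent-radius sum (Cordero radii;
van der Waals radii from Bondi). The indicator is strict (`<`) by default —
the formula's operational definition — with a lenient (`≤`) flag. The
pairwise ratio normalizes colliding pairs by `K · Σ N_atoms` with K = 10
nearest pocket atoms per ligand atom; K is an inference from published
denominators (210 000 pairs for 1000 ligands at ≈ 21 atoms each), not a
stated value, and is configurable. The atom-level and molecule-level ratios
(fraction of ligand atoms, or complexes, with at least one colliding pair)
are this package's own readings of the coarser granularities and are
labeled non-canonical.

## Minimum-distance corrections

Both schemes fix a colliding pair `(a, b)` (protein atom `a`, ligand atom
`b`, `‖a−b‖ < D_ab`) while preserving `‖b′−c‖ = ‖b−c‖` for a neighbor atom
`c` in the ligand:

* **parallelogram**: `b′` is the second intersection of the line through
  `a, b` with the sphere centered at `c` of radius `‖c−b‖`, recovered from
  the product of quadratic roots (the known root is `b` itself). For deep
  clashes the construction can be unsatisfiable with the nearest neighbor —
  when `a` lies essentially on the sphere around `c`, both roots stay
  within `D_ab` and iterating the construction cycles with period 2. The
  implementation therefore selects the closest ligand atom for which the
  constraint is satisfiable (`‖b′−a‖ ≥ D_ab`), falling back to the nearest
  neighbor's outcome when none is.
* **circle**: intersect the spheres `(a, D_ab)` and `(c, ‖c−b‖)` and sample
  a point on the intersection circle with a predetermined seed (42),
  using a deterministic Gram–Schmidt basis of the circle plane for
  cross-platform reproducibility. `c` is the closest ligand atom satisfying
  the scheme's stated condition `‖a−b‖ < ‖a−c‖` plus the reachability
  condition `‖a−c‖ + ‖c−b‖ > D_ab` (without it the candidate sphere can lie
  entirely inside the threshold sphere). The threshold sphere radius
  carries a +1e-10 safety margin so the corrected distance is robustly on
  the non-colliding side in floating point; tangency (tolerance 1e-12)
  returns the tangent point.

`correct_complex` iterates: scan colliding pairs under the K-nearest
metric, correct in ascending (ligand, pocket) index order — rechecking each
pair against the current coordinates with the same scan used for detection —
and repeat until clash-free or `max_rounds` (default 10). Validity goes
false on any failed construction or when a corrected atom lands within the
covalent-sum distance of another ligand atom. Protein atoms never move.
Circle-method sampling seeds are derived per correction event from the base
seed, so repeated corrections of a stubborn pair explore different angles
deterministically.

## Reference denoiser

The denoiser is a deliberately small message-passing network (default two
rounds, 48 hidden units; the single-template study below uses three rounds
and 64 units) over ligand nuclei, mesh points (training only, carrying a
dedicated mesh token), and pocket atoms. Coordinates are canonicalized to
the pocket center of mass; the network is translation-invariant through
that frame and makes **no claim to rotational equivariance** — canonical
coordinates enter as node features, which is what lets a small network
memorize pocket-frame poses on a synthetic shell whose atoms are otherwise
nearly indistinguishable. Messages carry squared-distance features
(normalized), aggregation is by mean, and hidden states are softly clamped
(±4 via tanh) — with sum aggregation and unbounded residuals, activations
grow by roughly the node degree per layer and saturate every gate.

The coordinate readout blends three mechanisms, each with an analytic
signal-to-noise prior so that behavior at the extremes is built in rather
than learned:

1. a **local path**, `x + √(1−ᾱ_t)·Δ`, where `Δ` is an EGNN-style
   combination of difference vectors to graph neighbors. The `√(1−ᾱ_t)`
   factor mirrors the noise-prediction parametrization: at `t→0` the noisy
   position is already the answer and corrections vanish.
2. a **slot-matching path**: learned 3-D pose slots `μ_k` (pocket frame),
   assigned to nuclei by the Bayes factor of the corruption model,
   `logit_ik = −‖x_i − √ᾱ_t μ_k‖² / (2(1−ᾱ_t))` plus a learned bias, then
   two Sinkhorn normalization rounds so atoms *compete* for slots — a
   per-atom readout lets two atoms claim the same site, which is the
   dominant failure mode of small point-cloud denoisers. Slots are
   initialized by k-means over the training ligands' pocket-frame
   coordinates (the usual mixture-model warm start; random initialization
   collapses toward the data centroid, and padding slots far away poisons
   the high-noise pose average — surplus slots are simply dropped).
   A sigmoid gate with prior `logit((1−ᾱ_t)/ᾱ_t)` hands prediction from the
   local path (low noise) to the slot path (high noise).
3. a **short-range pairwise repulsion** among predicted nuclei,
   `sigmoid(·)·exp(−d²)·(x̂_i−x̂_j)`, scaled by `√(1−ᾱ_t)`. It is
   deliberately repulsive-only: a learnable attractive term finds the
   centroid local optimum (predict every atom at the mean) and collapses
   sampling to a single point.

Mesh points use an attention readout over pocket anchors (convex
combinations of anchor positions reach any in-pocket location). The type
head is a softmax MLP on the final node embeddings.

Training is stochastic over complexes (one per step, seeded shuffle), Adam
with cosine learning-rate decay to 1/12 of the initial rate, per-step RNG
streams derived from `(seed, step)` so an interrupted run can be replayed
exactly. NaN loss aborts with diagnostics. The whole stack runs on a
minimal reverse-mode autodiff engine over numpy (`pocketdiff.autodiff`),
verified against finite differences.

## Synthetic world

The generator emulates the unit of structure-based drug design data — a
binding pocket with a docked small molecule — at the minimum complexity
that exercises conditioning, metrics, corrections, and training:

* pockets are jittered Fibonacci-lattice shells (default radius 8 Å, 40
  atoms, N/CA/C/O backbone cycling, radial jitter ≤ 0.2 Å), not folded
  proteins;
* ligands are connected clusters grown at 1.15× covalent-sum bond lengths,
  internally clash-free, with elements from a configurable palette
  (default C/N/O) and sizes drawn from a configurable distribution (default
  uniform over 6–10 atoms, echoing sampling sizes from a training-set
  distribution);
* ligands are placed **against the pocket wall** (1.6 Å clearance), not
  floating at the center: surface binding is the realistic pose, and it is
  the regime in which post-corrections actually operate — a clashing atom
  retains a nearby ligand neighbor, as in real molecules;
* clash injection moves `ceil(fraction · n)` atoms (at least one) to
  0.5–0.9× the covalent-sum distance of their nearest pocket atom, choosing
  inward directions by rejection sampling so intra-ligand spacing is
  preserved where geometrically possible. Stacking two displaced atoms on
  one ray — the naive construction — yields chemically impossible ligands
  and artificial correction deadlocks.

Everything is a pure function of the config (a single seed drives split
SeedSequence streams per complex), so datasets hash identically across
runs. What a green test on this world does *not* establish: behavior on
real pocket geometry and chemistry, docking-quality binding poses, or any
property requiring bond orders, protonation, or conformational strain.

## Evaluating sampled ligands

Generated atom clouds carry no canonical atom order, so template-recovery
comparisons minimize per-atom RMSD jointly over proper rotations,
translation, and atom correspondence (`pocketdiff.align.matched_rmsd`):
exact permutation enumeration with Kabsch alignment up to 8 atoms,
multi-start ICP with Hungarian assignment beyond. Plain ICP from a single
initialization systematically overestimates RMSD on permuted point sets
(rotation local minima).

## Numerical choices

* Strict `<` collision indicator; boundary pairs at exactly `D_ij` do not
  collide by default.
* K-nearest neighborhoods break distance ties by lower atom index (stable
  sort), making all metrics deterministic.
* Mesh cleaning tolerances: 1e-6 Å vertex merge, 1e-12 face area.
* Sphere-intersection tangency tolerance 1e-12; circle correction safety
  margin 1e-10.
* `t = 1` reverse step returns the posterior mean (zero added noise) and
  argmax types; `ᾱ_0 ≡ 1` so the `t = 1` posterior collapses onto the
  prediction with zero variance.
* Schedules for scaled-down `T` must scale `β` accordingly (e.g. linear
  1e-3 → 0.2 at `T = 100`); reusing the `T = 1000` betas leaves `ᾱ_T ≈ 0.37`
  and the noise prior mismatches the forward endpoint.

## Known limitations

* The reference denoiser memorizes pocket-frame poses; it does not
  generalize across rotations and is not intended to. The denoiser contract
  accepts any callable, so an equivariant network can be substituted.
* Ancestral sampling with posterior-mean feedback underdisperses early on
  strongly multimodal targets; even an oracle denoiser occasionally
  misassigns one atom of a template at desk scale. The slot-competition and
  repulsion mechanisms mitigate but do not abolish this.
* The union-of-spheres surface is an approximation of a solvent-excluded
  surface; interior seams at atom overlaps are removed by burial testing,
  not by re-triangulation.
* Parallelogram corrections can move an atom far along the line when the
  neighbor sphere is large; validity flags, not energies, are the only
  guard on the resulting geometry (no force-field relaxation).
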