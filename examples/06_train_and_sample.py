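"""Train the manifold-constrained denoiser and sample ligands into a pocket.

Desk-scale run: a few toy complexes, a few hundred optimization steps. The
trained model is sampled by reverse diffusion from pure noise; the per-step
collision trajectory is evaluated and written as CSV. Takes about a minute
on one CPU.
"""

import numpy as np

from pocketdiff.collisions import CollisionConfig, collision_trajectory, plcr
from pocketdiff.diffusion import build_schedule
from pocketdiff.model import (DenoiserHyperparams, ReferenceDenoiser, SampleConfig,
                              TrainConfig, generate_set, prepare_training_complex,
                              reverse_sample, train)
from pocketdiff.pipeline import emit_trajectory_csv
from pocketdiff.synth import SynthConfig, make_training_set

complexes, size_dist = make_training_set(SynthConfig(seed=11, n_complexes=4))
dataset = [prepare_training_complex(c, c=4) for c in complexes]

sched = build_schedule(T=1000)
den = ReferenceDenoiser(DenoiserHyperparams(init_seed=0), sched)
history = train(dataset, den, TrainConfig(T=1000, n_steps=300, learning_rate=6e-3, seed=0))
first = np.mean([h["loss_coords_N"] for h in history[:20]])
last = np.mean([h["loss_coords_N"] for h in history[-20:]])
print(f"nuclei coordinate loss: {first:.1f} (early) -> {last:.1f} (late)")

ligand, trajectory = reverse_sample(complexes[0].pocket, 7, den, sched, seed=3)
print(f"sampled a {len(ligand)}-atom ligand: elements {ligand.symbols}")

reports = collision_trajectory(trajectory, ligand, complexes[0].pocket,
                               CollisionConfig(K=10), stride=100)
df = emit_trajectory_csv(reports)
print("collision trajectory (inference step vs colliding pairs):")
print(df.to_string(index=False))

samples = generate_set([c.pocket for c in complexes], den, size_dist,
                       SampleConfig(n_samples=2, seed=5))
rep = plcr(samples, CollisionConfig(K=10))
print(f"8 generated ligands: PLCR = {rep.colliding_pairs}/{rep.denominator}")
# Step-0 is pure noise, step-1000 the final ligand; the mesh points used in
# training are ignored at inference — only nuclei are sampled.
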