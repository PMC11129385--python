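"""Knowledge sharing across patients: meta-learned vs decoupled fits.

Generates 12 related tasks (20 variables, 90% shared mechanism, only 50
samples each), meta-trains the shared initialization on 9 of them, and
compares test-task recovery against fitting each test task from scratch.
"""

import numpy as np

import metadag as md
from metadag.meta import MetaConfig, meta_adapt, meta_train

cfg = md.SimulationConfig(
    d=20, n_samples=50, n_tasks=12, task_similarity=0.9, seed=1
)
coll = md.generate_task_collection(cfg, train_fraction=0.75)
print(f"{len(coll.train)} training tasks, {len(coll.test)} test tasks, "
      f"{coll.n_vars} variables, {cfg.n_samples} samples per task")

meta_cfg = MetaConfig(meta_lr=0.1, outer_steps=5, task_order_seed=1)
state = meta_train(coll.train, meta_cfg)
print(f"meta-training done: {len(state.history)} Reptile updates")

shd_cold, shd_warm = [], []
for task in coll.test:
    truth = md.threshold_graph(task.truth, 0.0)
    cold = md.fit_notears_l1(task)  # decoupled: zero initialization
    warm = meta_adapt(state, task, meta_cfg)  # warm start at W_meta
    shd_cold.append(md.structural_hamming_distance(
        md.threshold_graph(cold.graph, 0.3), truth))
    shd_warm.append(md.structural_hamming_distance(
        md.threshold_graph(warm.graph, 0.3), truth))

print(f"decoupled test SHD:   {shd_cold} (mean {np.mean(shd_cold):.1f})")
print(f"meta-warm test SHD:   {shd_warm} (mean {np.mean(shd_warm):.1f})")
print()
print("With only 50 samples per 20-variable task, the decoupled learner")
print("cannot pin down the dense shared mechanism; warm-starting from the")
print("meta-learned initialization recovers it far more accurately.")
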