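# metadag

Meta-learning for **personalized causal graph learning**: learn one causal
DAG per patient (task) from small observation matrices by sharing a
meta-learned initialization across related structure-learning problems.

In biomedicine each patient's variables (genes, proteins, phenotypes,
risk factors) interact through an individual causal graph, but per-patient
sample sizes are far too small to learn a graph from scratch.  `metadag`
treats each patient as one score-based structure-learning task

    min_W  1/(2N) ||X − X W||_F² + λ ||W||₁   s.t.  G(W) ∈ DAGs,

solved by continuous acyclicity-constrained optimization
(`h(W) = tr(e^{W∘W}) − D = 0`, augmented Lagrangian, L-BFGS-B inner
solves), and shares knowledge across tasks with a first-order (Reptile)
outer loop: after solving each training task warm-started at the shared
initialization `W_meta`, the initialization moves a fraction `lr` toward
the solution,

    W_meta ← W_meta + lr · (W_task − W_meta).

At test time an unseen patient's graph is learned by warm-starting from
the frozen `W_meta`.  `lr = 0` recovers decoupled single-task learning,
`lr = 1` continual fine-tuning.

The package ships the full study harness: a synthetic multi-task
benchmark (ER / scale-free ground-truth DAGs, linear-Gaussian SEM
sampling, controllable cross-task similarity), decoupled and joint
multi-task baselines, directed edge-classification metrics
(FDR/TPR/FPR/SHD/NNZ), benchmark and sweep protocols, and a thin CLI.

## Worked example

```python
import metadag as md
from metadag.meta import MetaConfig, meta_train, meta_adapt

# a cohort of 12 related 20-variable tasks, 50 samples each,
# sharing 90% of their causal mechanism
cfg = md.SimulationConfig(d=20, n_samples=50, n_tasks=12,
                          task_similarity=0.9, seed=1)
coll = md.generate_task_collection(cfg, train_fraction=0.75)

state = meta_train(coll.train, MetaConfig(meta_lr=0.1, outer_steps=5,
                                          task_order_seed=1))

for task in coll.test:
    truth = md.threshold_graph(task.truth, 0.0)
    cold = md.fit_notears_l1(task)              # decoupled baseline
    warm = meta_adapt(state, task)              # warm start at W_meta
    print(md.structural_hamming_distance(md.threshold_graph(cold.graph, 0.3), truth),
          md.structural_hamming_distance(md.threshold_graph(warm.graph, 0.3), truth))
```

Running this (see `examples/02_meta_learning_gain.py`) prints

```
decoupled test SHD:   [54, 29, 29] (mean 37.3)
meta-warm test SHD:   [23, 18, 26] (mean 22.3)
```

— per test task, the number of edge edits (insertions, deletions, flips)
separating the learned structure from the truth, first for the decoupled
solver, then warm-started from the meta-initialization.  With 50 samples
per 20-variable task the decoupled learner misses much of the dense
shared mechanism; the meta-learned warm start recovers it substantially
better.  The other scripts in `examples/` demonstrate single-task
fitting, the meta-learning-rate sweep, and the on-disk task-collection
format shared with the CLI (`metadag simulate | fit | meta-train |
meta-adapt | evaluate | benchmark | sweep | plot`).

`docs/methods.md` documents the model, the solvers, the benchmark
generator and its deliberate simplifications, and all numerical choices.

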