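# otfrm

Quantifying how well a task-labeled embedding space is organized — and
how transferable it is — with optimal transport.

When one pretrained representation (of proteins, molecules, documents,
…) serves many downstream tasks, two practical questions arise: *how
much does each task benefit from each training stage*, and *which tasks
transfer well to which*? This package answers both from the geometry of
the embeddings alone, with no access to the model: each task is treated
as an empirical distribution of sample embeddings, and tasks are
compared by entropic optimal transport under a cosine ground cost.

## The measure

For a feature space of K tasks, task k with samples
x\_1 … x\_{m\_k}:

- **intra-task similarity** — mean cosine similarity over all unique
  sample pairs within the task:
  `intra(k) = 2/(m_k(m_k−1)) Σ_{i<j} cos(x_i, x_j)`
- **OT similarity** between two tasks — `OTsim(C_k, C_l) = 1 − W_p`,
  where `W_p` is the p-Wasserstein distance under the ground cost
  `c(x, y) = (1 − cos(x, y))^p` (default p = 1), computed with entropic
  regularization ε = 0.1 by a log-domain Sinkhorn solver (an exact LP
  solver is available and doubles as a test oracle);
- **inter-task similarity** — `inter(k) = 1/(K−1) Σ_{l≠k} OTsim(C_k, C_l)`;
- **OTFRM** (optimal-transport feature-space representation measure) —
  `OTFRM(k) = intra(k) / inter(k)`.

Both components lie in [−1, 1]; a score above 1 means the task's
samples cohere more than the task's distribution resembles the others'.
Tracking the score across training stages (randomly initialized →
pretrained → fine-tuned) quantifies stage-wise transferability; the K×K
matrix of pairwise `W_p` distances predicts task-to-task adaptability
(nearer tasks transfer better) and ranks candidate source tasks.

The package also includes the surrounding toolkit used in this setting:
BIOES tagging of protein motif/domain/region span annotations with
long-tail category merging, the equalized focal loss for long-tailed
classification objectives, standard evaluation metrics (RMSE, Pearson R,
accuracy/precision/recall/MCC), and seeded synthetic generators so every
analysis runs end to end without external data.

## Worked example

```python
from otfrm import OTConfig, SyntheticSpaceSpec, generate_feature_space, otfrm_report

spec = SyntheticSpaceSpec(K=4, m=50, d=16, delta=4.0, sigma=1.0, seed=11)
fs = generate_feature_space(spec)          # 4 Gaussian task clusters
report = otfrm_report(fs, OTConfig(epsilon=0.1, p=1.0))
for tid, e in report.per_task.items():
    print(tid, round(e["intra_sim"], 4), round(e["inter_sim"], 4), round(e["otfrm"], 4))
```

prints

```
task1 0.409 0.3241 1.2618
task2 0.4232 0.3434 1.2325
task3 0.4029 0.3261 1.2355
task4 0.4512 0.3366 1.3407
```

With cluster means 4σ apart, every task's within-task cosine similarity
(≈ 0.41) exceeds its mean OT similarity to the other tasks (≈ 0.33), so
all OTFRM scores are above 1 — tight, well-separated task
distributions. At separation 0 the same tasks score well below 1, and
the stage comparison (`examples/stage_dynamics.py`) shows the scores
rising monotonically through separations 0 → 1 → 4 with stage ratios
PT/RI ≈ 1.1–1.3 and FT/PT ≈ 2.6–3.9.

Each script in `examples/` demonstrates one capability: scoring a
space, stage dynamics, transfer ranking plus the distance–adaptability
correlation, BIOES tagging, and the loss formulas. The same operations
are reachable from the `otfrm` command-line tool
(`otfrm simulate embeddings … | otfrm otfrm … | otfrm pairwise …`,
`otfrm bioes encode|decode|merge`, `otfrm metrics`, `otfrm stages`);
run `otfrm --help`.

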