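# metacross

Mechanistic modeling of metabolite production and signaling-circuit
activity from gene expression, and analysis of the crosstalk between the
two layers — for computational biologists who want to ask whether the
production of specific metabolites drives the activity of specific
signaling circuits in a tumor cohort.

## What it computes

**Metabolite production.** Each metabolite's producing **sub-pathway** (all
pathway nodes from which it is reachable, product out-edges removed) is
extracted once by reverse breadth-first search. Gene expression, rescaled to
[0, 1], acts as enzyme capacity `a(r)` (gene rules: AND → min, OR → max) and
a normalized flux is propagated from the sub-pathway's starting nodes:

    w(m_s, r_i) = m_s · a(r_i) / Σ_j a(r_j)          substrate distribution
    w(r_i, m_p) = a(r_i) · min_s w(m_s, r_i)          reaction rate
    m_p ← (m_p + Σ_i w(r_i, m_p)) / (indeg + 1)       product update

iterated to convergence (tolerance 1e-6); the converged product value in
[0, 1] is the production activity of that metabolite in that sample.

**Circuit activity.** A signaling circuit connects a receptor to an effector
through signed edges; the transmitted signal is
`S_n = v_n (1 − Π_a(1 − S_a)) Π_i(1 − S_i)` and the effector's signal is the
circuit activity.

**Crosstalk.** Paired tumor/normal t-tests with Benjamini–Hochberg FDR flag
differentially produced metabolites. A sparse variational multi-task GP
(shared RBF+linear kernel, identity mixing, 50 inducing points) regresses
circuit activities on metabolite productions; 100×5-fold cross-validation
scores each circuit (task-wise R²/MSE), Shapley values computed on held-out
samples rank metabolites per circuit, and a circuit is annotated only when
its mean test R² exceeds 0.5. A Fisher exact test on {relevant,
non-relevant} × {shared genes, none} discards the trivial explanation that
predictive metabolite/circuit pairs simply share genes.

A synthetic-study generator plants all three kinds of signal (differential
production, metabolite→circuit links, gene sharing) at controllable effect
sizes, so every stage has a ground truth. See `docs/methods.md` for models,
defaults and limitations.

## Worked example

```python
from metacross import (make_study, write_study, PipelineConfig,
                       run_pipeline, annotated_pairs)
import pandas as pd

study = make_study(n_pathways=3, n_metabolites=4, n_reactions=3,
                   n_circuits=4, circuit_nodes=4, n_pairs=100, seed=7)
write_study(study, "demo_study")
manifest = run_pipeline(PipelineConfig(study_dir="demo_study",
                                       out_dir="demo_out",
                                       cv_reps=2, seed=7))
print("planted links:", sorted(study.planted_links))
print("significant DPMs:", manifest["n_significant_dpms"])
print("Fisher control p:", manifest["fisher_p"])
rel = pd.read_csv("demo_out/relevance.tsv", sep="\t")
print("annotated pairs:", sorted(annotated_pairs(rel, top_k=1)))
```

prints

```
planted links: [('pw1:M4', 'circ1'), ('pw2:M4', 'circ2'), ('pw3:M4', 'circ3')]
significant DPMs: 9
Fisher control p: 1.0
annotated pairs: [('pw1:M4', 'circ1'), ('pw2:M4', 'circ2'), ('pw3:M4', 'circ3')]
```

All nine producible metabolites sit downstream of a planted enzyme shift, so
all nine are flagged as differentially produced. The three planted
metabolite→circuit links are recovered exactly: each planted metabolite is
the top-ranked Shapley feature of its circuit and the circuit clears the
R² > 0.5 relevance gate, while the fourth (unlinked) circuit is not
annotated. With no shared genes the Fisher control finds no enrichment
(p = 1).

The same stages are available as a CLI:
`metacross {simulate,preprocess,decompose,produce,signal,diff,relevance,crosstalk,run}`.

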