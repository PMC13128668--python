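# protlife

Sequence-based classification of bacterial proteins as **short-lived**
(half-life < 1 h) or **long-lived** — aimed at metabolic engineers who
need to spot enzymes whose rapid turnover makes them pathway
bottlenecks, and at anyone studying proteolytic stability determinants
in *E. coli*-like hosts.

## The model

A protein sequence is encoded three ways and fused:

* a residue-level embedding matrix (d_local × L, zero-padded to a fixed
  width) projected to a 1-D vector by two Conv2D → AveragePooling2D →
  dropout blocks;
* a sequence-level embedding vector reduced by PCA to the components
  explaining ≥ 95 % of training variance;
* physicochemical descriptors (CKSAAP, DDE, CTD, Moran autocorrelation,
  SOCN), z-scored, then filtered by a per-feature one-way ANOVA between
  the classes (keep iff p ≤ 0.01).

The concatenation feeds a fully connected network ending in a sigmoid
P(long-lived); a query is long-lived iff P ≥ 0.5. Performance is
summarised by ACC, SEN, SPE, PPV, NPV and

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with *long-lived* the positive class; MCC drives hyperparameter
selection (grid of 1,296 configurations, stratified 10-fold CV) because
it stays informative under the ~12:1 class imbalance typical of
bacterial turnover data. Everything — including the convolutional
network and Adam — runs on numpy, deterministically under one seed. A
built-in synthetic embedder makes the whole pipeline runnable without
downloading language-model weights; see `docs/methods.md` for the full
model description and its limitations.

## Worked example

```python
import numpy as np
from protlife import (HalfLifeModel, DEFAULT_CONFIG, SyntheticSpec,
                      generate, make_embedder)

spec = SyntheticSpec(n_long=150, n_short=50, length_range=(50, 150),
                     p_motif=0.9, effect_size=2.0, seed=101)
dataset = generate(spec)                       # 200 labeled sequences
embedder = make_embedder(spec, d_local=24, d_global=64, L_padded=160)
model = HalfLifeModel(dataset.records, embedder)
result = model.fit(DEFAULT_CONFIG.replace(max_epochs=5, seed=1),
                   val_fraction=0.25)
print(result.summary())
```

prints (abridged):

```
Half-life classification model
==============================================
records                      200  (long 150, short 50)
descriptors kept (ANOVA)     117
PCA components                51
network input dim            448
...
stopped at epoch               3
best val loss             0.1230
validation metrics      ACC 0.980  SEN 1.000  SPE 0.917  PPV 0.974  NPV 1.000  MCC 0.945
```

The planted degron-like motif (and its embedding-level effect) separates
the classes, and the fitted classifier recovers that signal on held-out
validation sequences: 49 of 50 correct here, MCC 0.945. On real data
the same objects are built from files:

```python
model = HalfLifeModel.from_fasta("train.fasta", "half_lives.tsv",
                                 embedder, unit="minutes")
```

A `protlife` command-line tool wraps the same pipeline:
`simulate`, `encode`, `embed`, `train`, `predict`, `eval`, `ablate`
(see `protlife --help`). `predict` enforces the input contract
(standard residues, length 50–1655) per record and keeps going on
failures; `train --full-grid` guards the 1,296-configuration search
behind a confirmation flag.

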