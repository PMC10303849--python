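# explainn

Interpretable, transparent neural networks for DNA sequence-to-activity
modeling — an implementation of the ExplaiNN architecture (a neural additive
model over sequence) with its interpretation machinery, de novo motif
discovery, motif-database filter initialization, and motif cooperativity
analysis.

## Who this is for

Computational biologists modeling TF binding (ChIP-seq), chromatin
accessibility (ATAC-seq), in vitro selection (HT-SELEX, PBM, SMiLE-seq), or
enhancer activity who want a model whose predictions can be read off like a
regression: which motifs matter, for which task, and by how much.

## The model

The prediction for a one-hot encoded sequence *x* is a linear combination of
*U* independent units:

```
ŷ_t = Σ_u  w_{u,t} · f_u(x)  +  b_t
```

Each unit *f_u* sees the sequence through exactly one convolutional filter
(a 19-bp PWM-like scanner):

```
conv(1 filter, 4×19) → batch norm → exp → max pool(7,7)
  → FC(100) → batch norm → ReLU → dropout(0.3)
  → FC(1)  → batch norm → ReLU
```

Because the final layer is linear and units share no parameters, the model is
its own explanation:

- **Global interpretation** — the final-layer weight matrix `w` (U×T) reads
  like regression coefficients; each unit's filter is rendered as a PFM/PWM
  from the subsequences that activate it at ≥ 50% of its maximum in
  correctly predicted sequences, and annotated against a motif database.
- **Local interpretation** — the *unit importance* of unit *u* for task *t*
  is the median over qualifying sequences of `f_u(x) · w_{u,t}`; by
  linearity this equals (minus) the exact prediction change from nullifying
  the unit.

The compute core (forward pass, backpropagation, Adam) is implemented
directly in NumPy; the architecture is small and fixed, so no deep-learning
framework is required.

## Worked example

```python
import numpy as np
from explainn import (PlantSpec, generate, ExplaiNNClassifier,
                      annotate_units)
from explainn.benchmarks import make_pwm

# synthetic ground truth: 8-bp motif planted in half the sequences
pwm = make_pwm("GATTAAGC", dominance=0.95, id="planted")
spec = PlantSpec(motifs={"A": pwm}, n=2000, length=100,
                 label_rule="presence_binary", embed_prob={"A": 1.0}, seed=0)
dataset, ledger, _ = generate(spec)

clf = ExplaiNNClassifier(num_units=10, max_epochs=20, random_state=0)
clf.fit(dataset.sequences, dataset.labels[:, 0])

pwms = clf.filter_pwms(dataset.sequences, dataset.labels)
imp = clf.unit_importances(dataset.sequences, dataset.labels)
top = int(np.nanargmax(imp.medians[:, 0]))
hits = annotate_units([pwms[top]], [pwm], threshold=0.8)
print(top, round(float(imp.medians[top, 0]), 2), hits[0].motif_ids)
```

prints (for this seed)

```
5 2.12 ['planted']
```

i.e. unit 5 carries the highest importance (median contribution 2.12 to the
pre-sigmoid logit), and its filter's PWM matches the planted motif at
probability-column correlation ≥ 0.8 — the model recovered the ground-truth
motif and says so in its own weights.

The same library drives de novo motif discovery (`explainn.discovery`),
JASPAR-profile filter initialization with optional freezing
(`explainn.filters_init`), and motif cooperativity distance profiles
(`explainn.coop`). A CLI mirrors these:
`explainn simulate|train|interpret|discover|init-filters|coop|evaluate`.

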