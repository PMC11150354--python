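# dialograph

Graph-based representations of two-speaker clinical interview transcripts
for binary depression-status classification, with a synthetic interview
corpus generator and clinician-readable graph visualisation.

## The problem

Screening interviews between a therapist and a patient are the standard
instrument for assessing depression; the PHQ-8 questionnaire score (0–24,
with ≥ 10 conventionally marking depression) provides the label. Most
automated approaches encode the transcript as a flat sentence sequence and
ignore its discourse structure. This package instead represents each
interview as a graph and classifies the graph:

- **Sentence similarity graphs** — each utterance is a node carrying its
  sentence embedding; an edge between utterances *i, j* carries
  cos(eᵢ, eⱼ) and is kept when it reaches a sparsity threshold τ (a tuned
  hyper-parameter).
- **Keyword correlation graphs (KCG)** — an NMF topic model over the
  training-split sentences (one sentence = one TF-IDF document) scores word
  importance per transcript; the top-50 keywords become nodes, every
  utterance is assigned to the keyword it is most related to, and an edge
  between keywords *u, v* carries the mean pairwise cosine between their
  sentence-embedding sets.
- **Multi-view (MV) variants** — the transcript is split into the therapist
  view and the patient view, each with its own graph (and, for KCG, its own
  topic model); *cross edges* join each question to the patient turn that
  answers it (similarity-MV) or the keyword nodes holding a corresponding
  question/answer pair (KCG-MV).

Classification runs graph convolutions
H⁽ˡ⁺¹⁾ = ReLU(D̃^{-1/2}(A+I)D̃^{-1/2} H⁽ˡ⁾ W⁽ˡ⁾) over the weighted
adjacency, pools with multi-head attention (KCG node features are
themselves attention-pooled sentence sets), fuses the two views with
bidirectional cross-attention averaged elementwise ("inter-view attention,
mean"), and applies a logistic head. Training uses Adam (lr 5 × 10⁻⁴) with
class-weighted binary cross entropy (wᶜ = N/2Nᶜ) against the ≈ 70/30
negative/positive imbalance, selects the epoch with the best
development-set macro-F1, and reports macro-F1, UAR (unweighted average
recall), accuracy and macro precision as mean ± std over 5 seeds.

The real clinical corpus this family of models is evaluated on is
access-restricted, so the package ships a **synthetic corpus generator**
that reproduces the structure the method exploits: a finite shared topic
set, shorter patient answers and more therapist follow-up questioning for
depressed cases, marker keywords (*therapy*, *depression*, *p_t_s_d*)
almost exclusively in positive transcripts, conversation fillers, and
PHQ-8 scores consistent with the ≥ 10 rule. Sentence encodings come from a
pluggable backend: a production sentence-transformer (all-mpnet-base-v2)
or a deterministic hash-token encoder requiring no downloads.

## Worked example

```python
from dialograph import (DepressionGraphModel, GenParams, TrainConfig,
                        generate_corpus)

corpus = generate_corpus(GenParams(n_transcripts=100, seed=0))
model = DepressionGraphModel.from_corpus(corpus, variant="similarity_mv")
results = model.fit(TrainConfig(max_epochs=20, seeds=(0, 1, 2),
                                similarity_threshold_grid=(0.5,)))
print(results.summary())
print("majority-class baseline:", round(results.majority_baseline()["macro_f1"], 3))
```

prints

```
DepressionGraphModel  variant=similarity_mv  seeds=[0, 1, 2]  threshold=0.5
split          metric  mean  std
  dev        macro_f1 0.937  0.0
  dev             uar 0.967  0.0
  dev        accuracy 0.950  0.0
  dev macro_precision 0.917  0.0
 test        macro_f1 0.937  0.0
 test             uar 0.967  0.0
 test        accuracy 0.950  0.0
 test macro_precision 0.917  0.0

majority-class baseline: 0.429
```

A macro-F1 of 0.937 against a 0.429 majority-class baseline means the
multi-view similarity-graph classifier recovers the planted class signal
(marker keywords and answer-length/follow-up structure) almost perfectly
and identically across the three seeds; the dev and test rows agree because
the generator plants the same signal in every split.

The same pipeline is scriptable from the shell:

```bash
dialograph simulate --n-transcripts 100 --seed 0 --out data/
dialograph train --data-dir data/ --variant similarity_mv --out runs/mv
dialograph visualize --data-dir data/ --transcript-id syn0000 --out figs/
```

`visualize` writes DOT files in which dashed blue edges are weak
correlations, solid black edges strong ones (relative to the weak/strong
cutoff), orange edges are question–answer cross connections, and clusters
of conversation fillers are highlighted; for KCG renderings a marker-keyword
cluster report is written alongside.

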