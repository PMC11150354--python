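# Methods

## Transcript model

A transcript is an ordered list of cleaned utterances, each tagged
therapist or patient. Cleaning lowercases, strips bracketed non-verbal
annotations (`<laughter>`, `(sighs)`, `[...]`) via a configurable regex and
collapses whitespace; rows left empty are dropped and the rest re-indexed.
The utterance row is the sentence unit throughout — no further sentence
splitting is applied, matching the convention that each transcript row is
one document for the topic model. The binary label is `phq8 >= 10`.

Discourse structure is recovered as maximal same-speaker runs (*turns*);
question–answer correspondence is defined as adjacency of a therapist turn
and the patient turn immediately following it. This definition is robust to
back-to-back utterances by one speaker and deterministic; leading patient
turns and trailing therapist turns remain unpaired and simply contribute no
cross edges.

## Sentence encoders

Two interchangeable backends. The production backend wraps a
sentence-transformer (all-mpnet-base-v2, 768-d); it requires a downloaded
model and is never exercised by the tests. The deterministic backend maps
each token to a unit vector drawn from a generator seeded by a hash of
(seed, token), sums token vectors and L2-normalises. It is a pure function
of (text, dim, seed), so every pipeline stage is exactly reproducible, and
token overlap raises expected cosine similarity — the property all graph
builders rely on. Embeddings are L2-normalised by default so cosine equals
dot product. Synthetic-corpus experiments use dim = 64: large enough that
unrelated token vectors are near-orthogonal, small enough to keep
desk-scale training fast.

## Graph construction

**Similarity (baseline).** Complete graph over utterances; edge (i, j)
kept iff cos(eᵢ, eⱼ) ≥ τ, carrying the cosine as weight. τ introduces
sparsity and is a tuned hyper-parameter (default grid 0.3–0.7, default
value 0.5). Weights are retained as GCN edge weights rather than binarised.

**Similarity (multi-view).** One thresholded similarity graph per speaker
view plus cross edges expanding each turn-level question–answer pair to all
(question utterance, answer utterance) combinations. Cross edges are
structural, not similarity-based: they are never thresholded and carry
weight 1.0 with `edge_type="cross"` (the cosine-weighted alternative is
noted but not default). Self-loops are not stored; the GCN layer adds them.

**KCG.** The topic model is scikit-learn NMF (`init="nndsvd"`, seeded, 500
iterations) over a TF-IDF sentence-term matrix with English stop-word
removal and min document frequency 2, fitted on *training-split* sentences
only. Defaults: 10 topics per model, 50 keywords per transcript. Word
importance within a transcript is the non-negative projection (NMF
transform) of the transcript's aggregated term vector onto the fixed topic
basis, contracted with each word's topic profile, restricted to words
occurring in the transcript; ties break by training document frequency then
lexicographically. Each utterance is assigned to exactly one keyword: the
highest-ranked keyword it contains, else the keyword with maximal embedding
cosine (ties by rank). Nodes with empty sentence sets are dropped (their
edge weights would be a mean over an empty set). Edge weight is the mean
pairwise cosine between the two nodes' sentence-embedding sets; the KCG
edge threshold defaults to 0.0 (keep all non-negative correlations) and is
deliberately untuned. The multi-view form fits one NMF per view and adds a
cross edge (u, v) iff some question–answer pair has its question utterance
in u's sentence set and the paired answer utterance in v's; KCG cross edges
carry weight 1.0.

## Architectures

All four variants share: input projection to a hidden dimension (default
128), a stack of GCN layers (default 2) computing
ReLU(D̃^{-1/2}(A+I)D̃^{-1/2} X W) with edge weights as adjacency entries and
degrees floored at 1e-8, dropout 0.2 between layers, and a logistic head.
Multi-view variants run the GCN over the joint block adjacency (both views
plus cross edges), then split node features by view. Attention blocks are
single transformer-style multi-head attention layers (default 4 heads)
without positional encoding:

- *readout* (baselines): self-attention over nodes, mean-pooled;
- *node encoder* (KCG): self-attention over a keyword's sentence-embedding
  set, mean-pooled to the node feature (per-view encoders in the MV form);
- *inter-view fusion* (MV): per-view self-attention, cross-attention in
  both directions (each view's encoding queries the other's keys/values),
  and the elementwise mean of the two attended summaries. An empty view
  contributes a zero row, so fusion degrades gracefully to the surviving
  view's constant-path output.

The networks run on an in-package numpy reverse-mode autodiff engine
(float64). Initialisation is Glorot-uniform from a generator seeded by the
model seed, so a run is a pure function of (data, configuration, seed).

## Training protocol

Adam at 5 × 10⁻⁴; class-weighted binary cross entropy with w_c = N/(2 N_c),
which equalises the weighted class masses (for a 76/31 split:
76·107/152 = 31·107/62); probabilities clamped to (1e-7, 1−1e-7); decision
threshold fixed at 0.5. Batches of 8 transcripts, at most 100 epochs with
early stopping after 20 epochs without development-set macro-F1
improvement; the checkpoint with the best dev macro-F1 is restored. The
multi-seed protocol trains once per seed (default seeds 0–4), chooses the
similarity threshold by the best mean dev macro-F1 over the grid (once,
not per seed), and reports per-seed and mean ± std dev/test metrics.
Metrics are macro-F1, UAR, accuracy and macro precision; a class absent
from the reference labels contributes 0 to its per-class terms.

## Synthetic corpus

The generator emulates the statistics the classifiers exploit, not natural
language: utterances are template-based token sequences, sufficient for the
deterministic encoder and the topic model. Defaults (chosen once as the
study conditions): 100 transcripts; positive rate 0.3; eight disjoint
ten-word topic vocabularies of which five are discussed per interview;
Poisson patient-answer lengths with mean 12 (negative) vs 5 (positive)
tokens; follow-up-question probability 0.2 vs 0.65 per class (at most two
per topic); therapist filler utterances at rate 0.3; noise-token rate 0.05;
PHQ-8 sampled uniformly from 0–9 (negative) or 10–24 (positive).

Marker keywords (*therapy*, *depression*, *p_t_s_d*) are injected at the
transcript level with probability 0.95 (positive) vs 0.05 (negative). A
marker-carrying transcript receives two dedicated treatment-history
exchanges — a therapist question and a patient answer framing one marker in
stop words ("i have been through *therapy* before") — plus occasional
single-token marker mentions inside topic answers. The stop-word frame
matters: it makes the marker the only vocabulary word in the answer, so the
marker keyword owns a coherent sentence set and distinct markers form
strong mutual edges, reproducing the marker-cluster phenomenon in
positive-class keyword graphs. Splits are stratified with largest-remainder
allocation (0.6/0.2/0.2 of 100 → 60/20/20).

What the generator does *not* model: real lexical variety, paraphrase,
disfluency, topic drift, or any audio/visual channel. Passing end-to-end
tests therefore certifies the pipeline (graph construction, leakage
isolation, optimisation, selection and evaluation), not clinical
performance; the planted signal is deliberately strong enough that a
bag-of-marker-words rule already reaches ≥ 0.9 accuracy, and the end-to-end
tests check that the graph classifiers recover at least that recoverable
signal.

## Visualization

Clusters are operationalised as connected components of the strong-edge
subgraph (weight ≥ the weak/strong cutoff, default 0.5); community
detection is a noted alternative, not the default. A cluster is annotated
"filler" when at least half its members are single-token utterances or in
the editable filler vocabulary. DOT output is bit-stable (nodes sorted,
edges lexicographic); GraphML round-trips through networkx. PNG/SVG require
an external graphviz layout engine and are never needed by tests.

## Numerical and scope choices

- float64 throughout; cosine computations guard zero norms; NMF convergence
  warnings on tiny corpora are suppressed (the factors are still the
  converged-to-tolerance-or-max-iter output).
- Problem sizes in tests and the acceptance script: 100-transcript default
  corpus, 30-epoch single runs, two-seed reduced-epoch protocol runs —
  desk-scale settings chosen so a full from-scratch reproduction runs in
  about a minute on one CPU.
- Out of scope: regression on the raw PHQ-8 score, GAT/GIN layer variants,
  encoder fine-tuning, audio/visual modalities, and tuning KCG
  configurations for task performance.

## Known limitations

- The transformer encoder backend is interface-tested only; numerical
  behaviour with production embeddings is unverified here.
- Turn-level correspondence assumes the interview alternates question and
  answer; monologue-style transcripts yield few or no cross edges.
- With very small development splits, macro-F1 model selection is coarse
  (many epochs tie), so early epochs are often selected; the restored
  checkpoint is the first best.
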