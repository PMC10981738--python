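# Methods

## The search model

The package ranks target proteins for each query by a predicted structural
similarity computed purely from sequence-derived embeddings.

**Embeddings.** An encoder maps a length-m sequence to an m×d per-residue
matrix; the per-protein vector *z* is its column-wise mean. Pooling is a
plain mean with no masking — sequences carry no padding in this design.
The encoder is pluggable; the shipped mock encoder is a pure function of
(sequence, seed) with two modes:

* `context_free`: each residue letter has a fixed profile, a one-hot vector
  over the 21-letter alphabet (20 amino acids + X) plus optional Gaussian
  jitter. With zero jitter and d ≥ 21 the dot product of two rows is an
  exact identity indicator, which reduces the embedding aligner to textbook
  match/mismatch alignment — the basis of an oracle test.
* `planted`: the matrix is a supplied per-protein vector broadcast over
  residues, so pooling returns it exactly; used to plant fold structure for
  end-to-end benchmarks.

**Similarity.** Three scores over pooled vectors p, q:

* reciprocal Euclidean: 1/(‖p−q‖₂+1) ∈ (0,1];
* cosine: p·q / max(‖p‖‖q‖, ε) with ε = 10⁻⁸ (the floor only matters for
  zero vectors);
* the bilinear predictor z₁ᵀWz₂ with a learned d×d matrix W, clamped to
  [0,1] at prediction time. TM-scores are bounded in [0,1] and the
  combination rule multiplies the prediction by a cosine, so clamping keeps
  the combined score in range; the trainer uses the unclamped form in its
  loss so gradients never die.

The ranking score is cosine itself when cosine **strictly** exceeds 0.995,
else (predicted TM) × cosine. The threshold branch exists because a
predictor trained only on pairs below 40% sequence identity cannot order
near-duplicate sequences, where cosine is reliable. The batch form computes
the full score matrix in one pass and equals the scalar rule to machine
precision (tested).

**Training.** W minimises mean squared error of z₁ᵀWz₂ against TM-score
labels by mini-batch Adam (β₁=0.9, β₂=0.999). Only W is trained; embeddings
are frozen inputs. Initialisation is 0.05·I + 0.01·N(0,1) with a seeded
generator, and the per-epoch shuffle is drawn from the same generator, so a
fixed seed gives a bit-identical model. The identity-biased start makes the
initial predictor cosine-like, which speeds convergence on embedding
geometries where similarity is roughly angular. The recorded default
hyperparameters (batch 100, learning rate 10⁻⁶, 200 epochs) suit
large-scale embeddings with ‖z‖ ≫ 1; the useful learning rate scales with
embedding magnitude, so the desk-scale fixtures train with lr 10⁻² for 50
epochs. No reweighting or undersampling happens inside the trainer — label
balancing is a dataset-level concern and lives in the fixture generator.

**Pre-filter.** Families are mapped to clans via the clan table; a family
with no clan stands in for itself. A pair is retained iff the clan sets
intersect. Two retain-all rules guarantee every query gets results: queries
with no domain, and queries none of whose clans occur anywhere in the
target set (evaluated once against the precomputed target clan universe).
The one-directional nature of these fallbacks means the filter is symmetric
in all-vs-all searches only when every protein carries a domain; tests
state that precondition. Clan clustering is the transitive closure over
shared clans (connected components of the protein–clan bipartite graph):
the natural extension of "proteins with the same clan cluster together" to
multi-clan proteins, and identical to it when every protein has one clan.

**Alignment.** S[i,j] = E_q[i]·E_t[j] (raw dot product; rows are used as
provided — no cosine re-normalisation). Needleman–Wunsch (global) and
Smith–Waterman (local) run with a linear gap penalty g ≥ 0 in O(mn); the
row recurrence folds the in-row gap chain through a running maximum, so each
row is a vectorised pass. Traceback is recomputed from the score matrix
with precedence diagonal > up > left and a relative tolerance of 10⁻⁹ on
score equality (the vectorised forward pass can round intermediate sums
differently from the per-cell recurrence). The local traceback starts from
the maximum cell with the smallest (i, j) on ties. The default gap is 3.0
in embedding-score units, exposed as a parameter: no canonical constant
exists for dot-product substitution scores, and with unit-norm rows (where
a match scores ≈ 1) a gap of 3 strongly discourages gapping, which suits
reranking by global score. Alignment scores are reported raw by default; an
`aligned_length` normalisation is available because score-per-aligned-pair
is the other defensible reranking functional. Coordinates are 0-based and
end-exclusive in serialized output.

**Pipeline.** With a pre-filter active, similarity is computed only over
retained pairs (batched per query); `prefilter="none"` scores the full
matrix. Ties in ranking break by ascending target id, making output
invariant to input order. Self-hits in all-vs-all runs are kept in result
tables but flagged; metrics ignore them. Pairs with similarity strictly
above the alignment threshold (default 0.3) are aligned and reranked by
alignment score; candidates below the threshold are dropped from the
reranked list, trading a marginal recall loss for precision and a ~10×
smaller alignment workload.

## Evaluation protocol

TP/FP labels per level: family → same family; superfamily → same
superfamily but different family; fold → same fold but different
superfamily; different fold is always FP; a same-fold hit from an excluded
stratum is *ignore* and removed before computing any metric (tested: adding
or removing ignores never changes a metric). With TM-score ground truth,
TP iff TM > 0.5 strictly.

* Sensitivity to the first FP = (TPs ranked above the first FP) / (total
  TPs of that query); the mean over queries is reported as AUROC.
* Weighted PR: every judged pair of query q carries weight 1/|stratum(q)|
  at the evaluated level, so a stratum contributes linearly rather than
  quadratically with its size; AUPR is the trapezoid over achieved
  (recall, precision) points. Unit weights reduce exactly to classic PR.
* MAP and P@K: average precision over relevant ranks; P@K counts TPs in
  the top K (short lists count their missing tail as non-relevant).

Numerical conventions chosen where the protocol is underdetermined:
queries with zero true positives are excluded from AUROC/MAP means and
reported separately (counting them as 0 would conflate dataset composition
with ranking quality); score ties across the TP/FP boundary order the FP
first, making sensitivity conservative and deterministic.

## The synthetic generator

`FixtureSpec` plants a fold > superfamily > family hierarchy (defaults:
5 × 2 × 2, 5 proteins per family, 100 proteins, d = 32) and derives every
modality from it:

* **Sequences** descend from a random fold-ancestor (length 50–80) by 10%
  substitution per hierarchy branch, so within-fold identity stays ≈ 70%
  while cross-fold pairs are random — sequence signal for the aligner.
* **Pooled embeddings**: fold centroid ~ N(0, I_d), plus superfamily
  (σ = 0.15), family (σ = 0.10) and protein (σ_emb = 0.10) Gaussian
  offsets. Same-fold dot products concentrate near ‖centroid‖² ≈ d;
  cross-fold near 0.
* **TM labels**: clamp₀₁(z₁ᵀW*z₂ + N(0, σ_tm)) with the planted
  W* = (0.8/d)·I and σ_tm = 0.02, so same-fold pairs land near 0.8 and
  cross-fold pairs near 0 — the premise that structural similarity
  separates folds. Generating labels from the same bilinear family the
  model fits is deliberate: it makes parameter recovery a clean
  correctness surface. A `misspecified` option produces
  distance-decay labels instead for robustness checks. Optional balancing
  undersamples sub-0.5 pairs to a stated positive fraction, mirroring how
  scarce same-fold pairs are balanced at the dataset level in real
  training corpora.
* **Annotations**: each protein carries its family accession, mapped to one
  clan per fold; 30% additionally carry a promiscuous domain from a small
  set of big clans with power-law weights (tail exponent 1.5), reproducing
  the long-tailed clan-cluster distribution in which the largest one or two
  clusters dominate the pre-filtered pair count; 5% of proteins carry no
  domain (matching the ~5% of real benchmark queries with no detectable
  Pfam domain), exercising the retain-all fallback.

What passing tests on this fixture show — and what they do not: they verify
the machinery (filtering, batch prediction, ranking, DP optimality, metric
arithmetic, determinism) under geometry where fold structure is linearly
recoverable from embeddings. They do not certify sensitivity on real
remote-homology benchmarks, which depends on the geometry of a real PLM's
embedding space and on real domain annotations.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the full suite
completes in seconds while every statistical check is still sharp: 100
proteins end-to-end, 5000 training pairs for recovery (d = 8), 200 random
matrices up to 6×6 against the exhaustive alignment oracle, 100 random
sequence pairs (length ≤ 30) against textbook NW. The library itself is
vectorised over candidate sets and has no scale assumptions beyond memory.

## Known limitations

* No affine (open/extend) gap model; the linear-gap recurrences are the
  point of the O(mn) design.
* The combination rule is implemented exactly as the two-branch form;
  behaviour between cosine 0.995 and 1.0 is cosine by definition, with no
  interpolation.
* The store keeps one pooled and one per-residue array per protein in a
  single HDF5 file; no sharding for tens of millions of proteins.
* A real encoder adapter must supply embeddings through `EncoderSpec`/
  `get_encoder`; none ships with the package.
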