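# Methods

## Problem and scope

`mlenz` addresses main-class-level annotation of multi-functional enzymes:
given an enzyme's amino-acid sequence, decide whether it is mono- or
multi-functional and, if multi-functional, predict the subset of the six EC
main classes it belongs to. The package deliberately stops at the main
class: filling in EC digits 2–4 for each predicted class, and deciding
whether a protein is an enzyme at all, are jobs for a single-function
annotator and are represented only as a delegation note in the output.
Multi-functional enzymes whose functions diverge below the main class are
outside the model's assumptions.

## Input encodings

Three raw encodings feed the network; columns of the two `L × 20` matrices
follow the fixed alphabetical residue ordering `ACDEFGHIKLMNPQRSTVWY`.

* **One-hot** (`L × 20`): row *i* is the unit vector of residue *i*.
* **PSSM** (`L × 20`): per-position residue frequencies from an iterative
  homology search. The parser reads the PSI-BLAST ASCII dialect
  (`-out_ascii_pssm`) and uses the weighted-observed-percentage block
  divided by 100, giving entries in `[0, 1]` directly interpretable as
  frequencies. The log-odds block is parseable behind a flag and squashed
  to `[0, 1]` by the logistic function, but frequencies are the default
  because they match the profile's "appearance frequency" semantics
  without an arbitrary scale. When no profile file is available a
  *fallback profile* — the one-hot matrix reinterpreted as a degenerate
  profile with all mass on the observed residue — keeps the branch
  populated; its provenance is recorded in a `source` tag.
* **Domain presence** (length `D`): one bit per entry of a fixed, ordered
  domain vocabulary (e.g. Pfam accessions from an HMMER tblout file).
  The vocabulary is built from the training set's union of hits, sorted
  lexicographically, frozen at training time and serialized with the
  model; hits outside it are counted and warned about, never errors.

Sequences are upper-cased on read. Non-standard residue letters are
rejected by default; an opt-in mapping substitutes B→D, Z→E, U→C, O→K,
J→L ('X' always errors) to keep the 20-column contract exact.

## Network

Both `L × 20` encodings pass through a stack of valid 1-D convolutions
(defaults: windows 4 then 8, 32 channels each, ReLU) followed by global
max pooling, which erases the length dependence without padding-to-fixed-L;
sequences shorter than the stack's receptive field are zero-padded up to
it, deterministically and independently of batch composition, so scoring
is batch-invariant. The domain vector passes through one fully-connected
ReLU layer (default width 64). The three branch outputs are concatenated
and fed to a fully-connected head (default width 128, dropout 0.3) ending
in Q per-class logistic outputs — logistic, not softmax, because main-class
labels are not mutually exclusive.

The implementation is pure NumPy with hand-derived backpropagation and an
Adam optimizer (β₁ = 0.9, β₂ = 0.999, lr 1e-3): at desk scale the batched
linear algebra saturates one CPU core and keeps every run bit-reproducible
from a single integer seed (weight initialization, shuffling and dropout
all derive from it). Only the epoch count (40) is inherited from the
method's established training protocol; filter sizes, widths, pooling,
optimizer and learning rate are this package's defaults and are all
overridable in `ModelConfig`.

## Losses

* **Rank loss (multi-label level).** Per instance,
  `E_i = (1/(|L||L̄|)) Σ_{k∈L,q∈L̄} exp(−(l_k − l_q))`, applied to the
  post-logistic outputs. Empty or full label sets make the normalization
  undefined and are hard errors carrying the instance index — loaders and
  the generator never produce them. The training objective is the sum over
  instances; the optimizer steps on the batch mean and the history records
  the mean per-instance loss per epoch, a positive rescaling that leaves
  the optimum unchanged while making histories comparable across batch
  sizes. The analytic gradient is verified against central finite
  differences in the test suite.
* **Squared loss** `Σ_j (l_j − d_j)²` is provided as the independent-label
  baseline for contrast; it is not used by the pipeline.
* **Weighted binary cross-entropy (mono/multi level).** The positive-class
  term of class *j* is weighted by `(#negatives_j)/(#positives_j)` unless
  explicit weights are configured — the concrete reading of "penalize the
  model toward the rare class" for a ~20:1 imbalance. The unweighted
  baseline is obtained by fixing unit weights.

## Adaptive threshold

The per-instance count objective
`f(t) = |{k∈L : l_k ≤ t}| + |{q∈L̄ : l_q ≥ t}|` is piecewise constant, so
it is minimized exactly by evaluating one representative per open interval
between consecutive distinct scores plus the two unbounded end intervals.
The target threshold is the midpoint of the minimizing interval. Numerical
choices, all deterministic:

* several disjoint minimizing intervals (possible under inverted
  rankings): take the widest, tie-break toward the lower midpoint;
* unbounded end intervals: offset from the extreme score by half the mean
  adjacent-score gap (0.05 when only one distinct score exists);
* degenerate calibration label sets are tolerated — empty sets push the
  threshold above the maximum score, full sets below the minimum;
* boundary semantics: the count objective uses `≤`/`≥`, label assignment
  uses strict `l_j > t(x)`; the midpoint rule keeps `t` off the scores
  except in adversarial inputs, and exact ties at the threshold are
  excluded (falling back to top-1 if that empties the set).

`t(x) = w·l(x) + b` is fitted to the per-instance targets by SVD-based
least squares (`numpy.linalg.lstsq`), which returns the minimum-norm
solution on rank-deficient systems and matches the normal-equations
solution to 1e-8 on well-conditioned ones; no regularization is added. The
residual RMS is stored on the fitted model. An empty prediction falls back
to the top-scoring class with an auditable flag — an enzyme at this level
always has at least one main class.

## Metrics

Example-based: hamming loss `(1/N) Σ_i |pred_i Δ true_i|/Q` and subset
accuracy (exact set equality). Label-based: macro precision/recall are
unweighted per-class means; macro-F1 is the mean of the per-class harmonic
means (not the harmonic mean of the macro averages); micro metrics pool
TP/FP/FN across classes, micro-F1 being the harmonic mean of micro
precision and recall. Zero denominators define the affected rate as 0 and
set a per-class flag — conservative, never inflating macro averages. `Q`
is a parameter so the same suite serves the binary level.

## Synthetic data

The generator emulates the statistics the method is built around, at desk
scale:

* **Signal.** Each class *j* owns a distinct 6-mer motif (pairwise
  distinct, none a substring of another) spliced at non-overlapping random
  positions into a uniform-background sequence, and an indicator bit in a
  16-entry domain vocabulary set with probability 0.9 (off-class bits:
  0.02). Uniform background composition is intentional: the learning
  target is the motif, not residue composition, and it keeps the
  bag-of-motifs oracle exact.
* **Label structure.** Multi-label patterns are drawn with relative
  frequencies shaped like curated co-occurrence tables (pairs {2,3},
  {1,3}, {3,4} dominate; a few triples and one quadruple), singletons with
  frequencies shaped like the curated mono-functional class distribution,
  and the default multi-functional fraction is 1085/23253 ≈ 0.047, the
  curated mono/multi imbalance.
* **Noise.** `label_noise` flips one uniformly chosen class membership per
  affected instance, skipping flips that would create empty or full sets;
  the default is 0. Multi flags are recomputed after noise so the
  mono/multi target stays consistent with the label sets.
* Sequence lengths are uniform on 50–120 — long enough to host all six
  motifs, short enough for CPU training.

With `label_noise=0` a substring search reproduces every label
(information completeness), so end-to-end failures indict the model, not
the data. What the generator does *not* emulate: evolutionary profiles
(the PSSM fixtures are degenerate one-hot profiles), realistic domain
architectures, homology between instances, or length/composition biases.
Passing end-to-end tests therefore demonstrates that the machinery — 
encodings, loss, threshold, hierarchy — learns and composes correctly, not
that any particular accuracy transfers to real enzymes.

## Evaluation protocol

`evaluate` performs R independent random 70/30 train/test splits (the
protocol's convention is 30 repeats; tests use 2 for speed), retrains model
and threshold per split, and reports per-metric mean ± sd. Each split is a
pure function of (seed, run index, dataset ids) via a seed sequence over
the ids' CRC, so partitions are reproducible across processes. The
end-to-end checks in the test suite use n = 2000 instances and the default
40-epoch training — sizes chosen so the whole suite runs comfortably on a
single CPU while leaving the learning task non-trivial.

## Known limitations

* The NumPy network is sized for desk-scale experiments (thousands of
  sequences, minutes of CPU); it is not a GPU training stack.
* The architecture defaults are this package's choices; no hyperparameter
  search was performed.
* The two levels are independent models; no feature sharing.
* Checkpoints (`.npz`) round-trip weights bit-exactly but are not a
  cross-tool exchange format.
* Running PSI-BLAST/HMMER is out of the tested surface; the package parses
  their outputs and records the conventional search parameters
  (3 iterations, e-value 0.002) as data only.
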