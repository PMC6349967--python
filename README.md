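# mlenz

Hierarchical multi-label prediction of enzyme EC main classes from protein
sequence.

Most enzyme-function predictors assume one function per enzyme, yet a
growing fraction of characterized enzymes are multi-functional: they carry
several EC annotations that usually diverge already in the first digit (the
*main class* — oxidoreductase, transferase, hydrolase, lyase, isomerase,
ligase). `mlenz` is a desk-scale tool for annotating such enzymes in two
stages:

1. **Mono vs multi.** A binary classifier decides whether a query enzyme is
   mono- or multi-functional. Because real collections are heavily skewed
   toward mono-functional enzymes (roughly 20:1), it is trained with
   class-weighted cross-entropy.
2. **Main classes.** For multi-functional enzymes, a multi-label classifier
   predicts the *set* of main classes among the six.

Mono-functional enzymes, and the remaining EC digits of each predicted main
class, are delegated to a conventional single-function annotator; `mlenz`
records this hand-off in its output.

## The model

Each protein is represented by three raw encodings: an `L × 20` one-hot
matrix of the sequence, an `L × 20` PSSM profile (parsed from PSI-BLAST
ASCII output, percentage columns scaled to `[0, 1]`; a degenerate one-hot
profile is substituted when no profile is available), and a binary
domain-presence vector over a fixed vocabulary of functional domains (e.g.
Pfam hits from HMMER). A branched network applies convolutions and global
pooling to the two length-dependent encodings, a fully-connected branch to
the domain vector, and a fully-connected classifier to their concatenation,
ending in Q per-class logistic outputs `l(x) ∈ (0,1)^Q`.

The multi-label stage is trained with the pairwise rank-exponential loss
(BP-MLL): for an instance with true label set `L` and complement `L̄`,

    E_i = 1/(|L||L̄|) · Σ_{k∈L, q∈L̄} exp(−(l_k − l_q)),

which drives every true-label score above every false-label score. Labels
are then assigned with a *self-adapted threshold*: the per-instance optimal
threshold minimizes the misclassified-label count

    |{k ∈ L : l_k ≤ t}| + |{q ∈ L̄ : l_q ≥ t}|

(taking the middle of the minimizing interval — e.g. scores
`(0.9, 0.8, 0.3, 0.1, 0.1, 0.1)` with true set `{1, 2}` give `t = 0.55`),
and a linear function `t(x) = w·l(x) + b` is fitted to these targets by
least squares. Prediction assigns `{j : l_j > t(x)}`, falling back to the
top-scoring class when the set would be empty.

Evaluation covers the full multi-label suite: hamming loss, subset
accuracy, and macro-/micro-averaged precision, recall and F1.

Because no full-scale curated dataset ships with the package, a synthetic
generator (`mlenz.synthetic_data`) emulates the relevant statistics —
class-specific sequence motifs and domain bits, realistic main-class
co-occurrence shape, and the mono/multi imbalance — so every stage is
trainable and testable end to end.

## Worked example

```bash
mlenz simulate --n 400 --seed 7 --multi-fraction 0.3 --out data
printf 'model:\n  epochs: 12\n' > model.yaml
mlenz train --data-dir data --level multilabel --model multi.npz --config model.yaml --seed 7
mlenz train --data-dir data --level binary    --model binary.npz --config model.yaml --seed 7
mlenz predict --fasta data/sequences.fasta --binary-model binary.npz \
      --multilabel-model multi.npz --domains-dir data/domains --out annotations.tsv
```

This prints, among other lines:

```
wrote 400 records (114 multi-functional) to data
trained multilabel model: final epoch mean loss 0.418401 -> multi.npz
trained binary model: final epoch mean loss 0.114184 -> binary.npz
annotated 400 records (114 multi-functional) -> annotations.tsv
```

and `annotations.tsv` holds one row per sequence — the mono/multi decision
with its probability score, and for multi-functional enzymes the predicted
main-class set:

```
id        is_multifunctional  score     main_classes  fallback  notes
syn00000  0                   0.035048  -             0         EC digits 2-4 delegated to mono-functional annotator
syn00005  1                   0.950240  4,6           0         EC digits 2-4 delegated to mono-functional annotator
syn00006  1                   0.966817  2,3           0         EC digits 2-4 delegated to mono-functional annotator
```

`syn00005` is called multi-functional with probability 0.95 and assigned
main classes 4 and 6 (lyase + ligase); `fallback 0` means the adaptive
threshold produced a non-empty set on its own. Repeated-split evaluation
(`mlenz evaluate --data-dir data --splits 2 --seed 7 --config model.yaml
--out metrics.tsv`) reports mean ± sd per metric, here e.g.
`hamming_loss 0.0368 +/- 0.0007` and `subset_accuracy 0.8125 +/- 0.0042`
for the deliberately short 12-epoch demo run (the test suite trains the
default 40 epochs, which scores substantially higher on noiseless data).

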