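"""Two-level hierarchical annotation of enzyme main classes.

Level 1 decides whether an enzyme is mono- or multi-functional (a single
logistic output, trained with class-weighted cross-entropy because real
collections are heavily skewed toward mono-functional enzymes). Level 2
assigns the set of EC main classes to multi-functional enzymes with the
rank-loss-trained multi-label network and the adaptive threshold.

Upstream (enzyme vs non-enzyme) and downstream (filling in the remaining
EC digits of each predicted main class) stages are delegated to external
mono-functional annotation tooling; annotations carry a note to that
effect. Inputs here are assumed to be enzymes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from mlenz.ml_metrics import MetricsReport, binary_metrics, evaluate_predictions
from mlenz.net_core import (
    ModelConfig,
    TrainedModel,
    forward,
    forward_many,
    load_model,
    train,
)
from mlenz.rank_loss import LabelSet
from mlenz.seq_encoding import (
    EncodedProtein,
    ProteinRecord,
    domain_encode,
    fallback_pssm,
    one_hot_encode,
    parse_domain_hits,
    parse_pssm,
    read_fasta,
)
from mlenz.synthetic_data import SimDataset
from mlenz.threshold_calibration import (
    PredictedLabelSet,
    ThresholdModel,
    apply_threshold,
    fit_threshold_function,
)

DELEGATION_NOTE = "EC digits 2-4 delegated to mono-functional annotator"


@dataclass(frozen=True)
class PipelineConfig:
    """Run-time configuration of the two-level pipeline."""

    binary_model_path: str | Path | None = None
    multilabel_model_path: str | Path | None = None
    pssm_mode: str = "fallback"  # "parsed" requires pssm_dir
    pssm_dir: str | Path | None = None
    domains_dir: str | Path | None = None
    split: float = 0.70
    seed: int = 0
    binary_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.split < 1):
            raise ValueError(f"split must be in (0, 1), got {self.split}")
        if self.pssm_mode not in ("parsed", "fallback"):
            raise ValueError(f"pssm_mode must be 'parsed' or 'fallback', got {self.pssm_mode!r}")


@dataclass(frozen=True)
class Annotation:
    """Pipeline output for one input sequence."""

    id: str
    is_multifunctional: bool
    score: float
    main_classes: PredictedLabelSet | None = None
    notes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.is_multifunctional != (self.main_classes is not None):
            raise ValueError("main_classes must be present iff multi-functional")


# ---------------------------------------------------------------------------
# encoding plumbing


def encode_record(
    record: ProteinRecord,
    vocabulary: Sequence[str],
    config: PipelineConfig,
    domain_hits: Sequence[str] | None = None,
) -> EncodedProtein:
    """Encode one record according to the pipeline's encoding flags."""
    if config.pssm_mode == "parsed":
        if config.pssm_dir is None:
            raise ValueError("pssm_mode='parsed' requires pssm_dir")
        pssm = parse_pssm(Path(config.pssm_dir) / f"{record.id}.pssm", record)
    else:
        pssm = fallback_pssm(record)
    if domain_hits is None:
        if config.domains_dir is not None:
            hit_file = Path(config.domains_dir) / f"{record.id}.txt"
            domain_hits = parse_domain_hits(hit_file) if hit_file.exists() else []
        else:
            domain_hits = []
    return EncodedProtein(
        one_hot=one_hot_encode(record),
        pssm=pssm,
        domains=domain_encode(domain_hits, vocabulary),
    )


def encode_dataset(ds: SimDataset, pssm_mode: str = "fallback",
                   pssm_dir: str | Path | None = None) -> list[EncodedProtein]:
    """Encode every record of a synthetic dataset with its own vocabulary."""
    cfg = PipelineConfig(pssm_mode=pssm_mode, pssm_dir=pssm_dir)
    vocab = ds.truth.vocabulary
    return [
        encode_record(rec, vocab, cfg, domain_hits=hits)
        for rec, hits in zip(ds.records, ds.domain_hits)
    ]


# ---------------------------------------------------------------------------
# per-instance predictions


def predict_is_multifunctional(
    x: EncodedProtein, model: TrainedModel, cutoff: float = 0.5
) -> tuple[bool, float]:
    """Level-1 decision: multi-functional iff the logistic output exceeds
    the cutoff (strict '>'; a score exactly at the cutoff is mono)."""
    if model.config.q_classes != 1:
        raise ValueError(
            f"binary model must have q_classes=1, got {model.config.q_classes}"
        )
    score = float(forward(model, x)[0])
    return score > cutoff, score


def predict_main_classes(
    x: EncodedProtein, model: TrainedModel, tmodel: ThresholdModel
) -> PredictedLabelSet:
    """Level-2 decision: network scores thresholded by t(x) = w.l(x) + b."""
    return apply_threshold(forward(model, x), tmodel)


# ---------------------------------------------------------------------------
# reproducible splits


def split_indices(
    ids: Sequence[str], seed: int, run_index: int, train_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic train/test partition.

    A pure function of (seed, run index, dataset ids): the permutation is
    seeded from the seed, the run index and a CRC of the id list, so the
    same call always yields the same split regardless of process state.
    """
    id_digest = zlib.crc32("\n".join(ids).encode())
    rng = np.random.default_rng(np.random.SeedSequence([seed, run_index, id_digest]))
    n = len(ids)
    order = rng.permutation(n)
    n_train = max(1, min(n - 1, int(round(train_fraction * n))))
    return order[:n_train], order[n_train:]


# ---------------------------------------------------------------------------
# training + evaluation protocols


def train_multilabel(
    xs: Sequence[EncodedProtein],
    labels: Sequence[LabelSet],
    config: ModelConfig,
) -> tuple[TrainedModel, ThresholdModel]:
    """Train the level-2 model with the rank loss and fit the adaptive
    threshold function on the training scores."""
    from mlenz.net_core import build_model

    model = build_model(config, domain_dim=xs[0].domains.values.size,
                        domain_vocabulary=xs[0].domains.vocabulary)
    train(model, list(zip(xs, labels)), loss="bpmll", config=config)
    score_matrix = forward_many(model, xs)
    tmodel = fit_threshold_function(score_matrix, labels)
    return model, tmodel


def train_binary(
    xs: Sequence[EncodedProtein],
    flags: Sequence[bool],
    config: ModelConfig,
    weighted: bool = True,
) -> TrainedModel:
    """Train the level-1 mono/multi model with (optionally class-weighted)
    binary cross-entropy. ``weighted=False`` fixes unit weights, the
    unweighted baseline for imbalance experiments."""
    from mlenz.net_core import build_model

    config = replace(config, q_classes=1,
                     class_weights=None if weighted else (1.0,))
    model = build_model(config, domain_dim=xs[0].domains.values.size,
                        domain_vocabulary=xs[0].domains.vocabulary)
    labels = [LabelSet({1} if f else set(), q=1) for f in flags]
    train(model, list(zip(xs, labels)), loss="weighted-binary", config=config)
    return model


def evaluate(
    ds: SimDataset,
    config: ModelConfig,
    r_splits: int = 30,
    train_fraction: float = 0.70,
    seed: int = 0,
) -> tuple[list[MetricsReport], dict[str, tuple[float, float]]]:
    """Repeated random-split evaluation of the multi-label level.

    Performs ``r_splits`` independent train/test partitions (default 70/30),
    trains the model and the threshold function on each training part,
    evaluates on the held-out part, and reports per-metric mean and
    standard deviation across the repeats.
    """
    if len(ds) < 10:
        raise ValueError(f"dataset too small to evaluate ({len(ds)} < 10 instances)")
    xs = encode_dataset(ds)
    ids = [r.id for r in ds.records]
    reports = []
    for r in range(r_splits):
        train_idx, test_idx = split_indices(ids, seed, r, train_fraction)
        run_config = replace(config, seed=int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31)))
        model, tmodel = train_multilabel(
            [xs[i] for i in train_idx], [ds.labels[i] for i in train_idx], run_config
        )
        test_scores = forward_many(model, [xs[i] for i in test_idx])
        preds = [apply_threshold(row, tmodel) for row in test_scores]
        truths = [ds.labels[i] for i in test_idx]
        reports.append(evaluate_predictions(preds, truths, config.q_classes))
    summary = {}
    for key in reports[0].as_dict():
        vals = np.array([rep.as_dict()[key] for rep in reports])
        summary[key] = (float(vals.mean()), float(vals.std(ddof=0)))
    return reports, summary


def evaluate_binary(
    ds: SimDataset,
    config: ModelConfig,
    weighted: bool = True,
    train_fraction: float = 0.70,
    seed: int = 0,
    cutoff: float = 0.5,
) -> dict[str, float]:
    """Single-split evaluation of the mono/multi level.

    Returns accuracy, precision, recall and F1 of the multi-functional
    (positive) class on the held-out part.
    """
    xs = encode_dataset(ds)
    ids = [r.id for r in ds.records]
    train_idx, test_idx = split_indices(ids, seed, 0, train_fraction)
    model = train_binary(
        [xs[i] for i in train_idx], [ds.multi_flags[i] for i in train_idx],
        config, weighted=weighted,
    )
    scores = forward_many(model, [xs[i] for i in test_idx])[:, 0]
    preds = scores > cutoff
    truths = np.array([ds.multi_flags[i] for i in test_idx])
    tp = int((preds & truths).sum())
    fp = int((preds & ~truths).sum())
    fn = int((~preds & truths).sum())
    tn = int((~preds & ~truths).sum())
    accuracy, precision, recall, f1 = binary_metrics(tp, fp, tn, fn)
    return {
        "accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


# ---------------------------------------------------------------------------
# end-to-end annotation


class PartialFailure(RuntimeError):
    """Some records failed to encode or annotate; carries the partial
    results and the per-record errors."""

    def __init__(self, annotations: list[Annotation], errors: dict[str, str]):
        super().__init__(
            f"{len(errors)} of {len(errors) + len(annotations)} records failed: "
            + "; ".join(f"{k}: {v}" for k, v in list(errors.items())[:3])
        )
        self.annotations = annotations
        self.errors = errors


def annotate_records(
    records: Sequence[ProteinRecord],
    binary_model: TrainedModel,
    multilabel_model: TrainedModel,
    tmodel: ThresholdModel,
    config: PipelineConfig,
) -> list[Annotation]:
    """Annotate encoded-able records; collect per-record failures.

    Every record lands in exactly one branch: mono-functional annotations
    carry the delegation note, multi-functional ones carry a main-class
    set (never empty, thanks to the top-1 fallback).
    """
    annotations: list[Annotation] = []
    errors: dict[str, str] = {}
    vocab = multilabel_model.domain_vocabulary
    for record in records:
        try:
            x = encode_record(record, vocab, config)
            is_multi, score = predict_is_multifunctional(
                x, binary_model, cutoff=config.binary_cutoff
            )
            if is_multi:
                pred = predict_main_classes(x, multilabel_model, tmodel)
                notes = (DELEGATION_NOTE,) + (
                    ("threshold fallback used",) if pred.fallback_used else ()
                )
                annotations.append(
                    Annotation(id=record.id, is_multifunctional=True,
                               score=score, main_classes=pred, notes=notes)
                )
            else:
                annotations.append(
                    Annotation(id=record.id, is_multifunctional=False,
                               score=score, notes=(DELEGATION_NOTE,))
                )
        except Exception as exc:  # noqa: BLE001 - per-record isolation
            errors[record.id] = str(exc)
    if errors:
        raise PartialFailure(annotations, errors)
    return annotations


def run_pipeline(fasta: str | Path, config: PipelineConfig) -> list[Annotation]:
    """Annotate every record of a FASTA file with the two-level scheme.

    Model checkpoints are loaded from the paths in ``config``; the
    multi-label checkpoint must embed a fitted threshold function.
    """
    if config.binary_model_path is None or config.multilabel_model_path is None:
        raise ValueError("pipeline config must provide both model paths")
    binary_model, _ = load_model(config.binary_model_path)
    multilabel_model, tmodel = load_model(config.multilabel_model_path)
    if tmodel is None:
        raise ValueError(
            f"{config.multilabel_model_path}: checkpoint has no threshold function"
        )
    records = read_fasta(fasta)
    return annotate_records(records, binary_model, multilabel_model, tmodel, config)


def write_annotations_tsv(annotations: Sequence[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tis_multifunctional\tscore\tmain_classes\tfallback\tnotes\n")
        for ann in annotations:
            classes = (
                ",".join(str(j) for j in sorted(ann.main_classes.members))
                if ann.main_classes is not None else "-"
            )
            fallback = (
                "1" if ann.main_classes is not None and ann.main_classes.fallback_used
                else "0"
            )
            fh.write(
                f"{ann.id}\t{int(ann.is_multifunctional)}\t{ann.score:.6f}"
                f"\t{classes}\t{fallback}\t{';'.join(ann.notes)}\n"
            )
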