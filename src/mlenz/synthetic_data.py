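"""Synthetic enzyme datasets with planted, label-informative structure.

Real multi-functional enzyme collections have three statistical features the
method is built around: (i) a strong mono/multi imbalance (roughly 22 000
mono-functional vs 1 000 multi-functional sequences in curated sets), (ii)
a skewed distribution of main-class combinations in which a handful of
pairs (transferase+hydrolase, oxidoreductase+hydrolase, hydrolase+lyase)
dominate and triples/quadruples are rare, and (iii) sequence and domain
signals that carry the class information. The generator emulates all three
at desk scale: each class is associated with a distinct k-mer motif spliced
into an otherwise uniform random background sequence, and with an indicator
bit in a domain vocabulary; label sets are drawn from a configurable
pattern-frequency table shaped like the real co-occurrence statistics.

With ``label_noise=0`` and ``domain_signal=1`` the mapping from sequence to
label set is exact (a substring search recovers every label), so the
dataset is information-complete: end-to-end failures are attributable to
the model, not the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from mlenz.rank_loss import LabelSet
from mlenz.seq_encoding import AMINO_ACIDS, ProteinRecord

#: Default class motifs: one distinct 6-mer per EC main class. Chosen once,
#: pairwise distinct, none a substring of another.
DEFAULT_MOTIFS = ("WCHEYM", "KNDQRG", "FPVTIS", "HLAWYC", "MEKNDW", "GRFPVQ")

#: Default relative frequencies of multi-label patterns, shaped like the
#: co-occurrence structure of curated multi-functional enzymes: the pairs
#: {2,3}, {1,3} and {3,4} dominate, higher-order sets are rare.
DEFAULT_PAIR_WEIGHTS: dict[frozenset[int], float] = {
    frozenset(p): w
    for p, w in [
        ((1, 2), 147), ((1, 3), 841), ((1, 4), 63), ((1, 5), 37),
        ((2, 3), 1148), ((2, 4), 235), ((2, 5), 38), ((2, 6), 131),
        ((3, 4), 622), ((3, 5), 22), ((3, 6), 4),
        ((4, 5), 308), ((4, 6), 34),
        ((1, 2, 4), 215), ((1, 3, 6), 10), ((1, 4, 5), 211),
        ((1, 2, 3, 4), 10),
    ]
}

#: Default singleton weights for mono-functional instances, shaped like the
#: main-class distribution of curated mono-functional enzymes.
DEFAULT_MONO_WEIGHTS: dict[int, float] = {1: 3343, 2: 8517, 3: 5917, 4: 1532, 5: 1193, 6: 1666}

#: Default mono/multi imbalance: about 4.7% multi-functional, matching the
#: ratio of curated multi- to all enzymes (1085 / (1085 + 22168)).
DEFAULT_MULTI_FRACTION = 1085 / (1085 + 22168)


@dataclass(frozen=True)
class SimSpec:
    """Study conditions of one synthetic dataset draw."""

    n: int
    q: int = 6
    length_range: tuple[int, int] = (50, 120)
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    pair_weights: dict[frozenset[int], float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_WEIGHTS)
    )
    mono_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MONO_WEIGHTS)
    )
    multi_fraction: float = DEFAULT_MULTI_FRACTION
    label_noise: float = 0.0
    domain_dim: int = 16
    domain_signal: float = 0.9
    domain_offrate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1 (got {self.n})")
        if self.q < 2:
            raise ValueError(f"q must be >= 2 (got {self.q})")
        motifs = self.motifs[: self.q]
        if len(motifs) < self.q:
            raise ValueError(f"need {self.q} motifs, got {len(motifs)}")
        if len(set(motifs)) != len(motifs):
            raise ValueError("motifs must be pairwise distinct")
        for a in motifs:
            for b in motifs:
                if a != b and a in b:
                    raise ValueError(f"motif {a!r} is a substring of {b!r}")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if not (0 <= self.multi_fraction <= 1):
            raise ValueError("multi_fraction must be in [0, 1]")
        min_len = self.length_range[0]
        total_motif = sum(len(m) for m in motifs)
        if min_len < total_motif:
            raise ValueError(
                f"minimum length {min_len} cannot host all {self.q} motifs "
                f"({total_motif} residues)"
            )
        if self.domain_dim < self.q:
            raise ValueError("domain_dim must be >= q (one indicator bit per class)")

    @property
    def vocabulary(self) -> tuple[str, ...]:
        return tuple(f"PF{i + 1:05d}" for i in range(self.domain_dim))


@dataclass
class SimDataset:
    """A generated dataset plus the spec that produced it."""

    records: list[ProteinRecord]
    labels: list[LabelSet]
    multi_flags: list[bool]
    domain_hits: list[list[str]]
    truth: SimSpec

    def __len__(self) -> int:
        return len(self.records)


def _draw_label_set(rng: np.random.Generator, spec: SimSpec) -> frozenset[int]:
    if rng.random() < spec.multi_fraction:
        patterns = [p for p in spec.pair_weights if p <= frozenset(range(1, spec.q + 1))]
        weights = np.array([spec.pair_weights[p] for p in patterns], dtype=float)
        weights /= weights.sum()
        return patterns[rng.choice(len(patterns), p=weights)]
    classes = sorted(spec.mono_weights)
    classes = [c for c in classes if c <= spec.q]
    w = np.array([spec.mono_weights[c] for c in classes], dtype=float)
    w /= w.sum()
    return frozenset({classes[rng.choice(len(classes), p=w)]})


def _splice_motifs(
    rng: np.random.Generator, length: int, motifs: Sequence[str]
) -> str:
    """Uniform random background with each motif placed at a random
    position, rejection-sampled so that placements never overlap."""
    background = rng.integers(0, 20, size=length)
    seq = [AMINO_ACIDS[i] for i in background]
    occupied: list[tuple[int, int]] = []
    for motif in motifs:
        k = len(motif)
        for _attempt in range(1000):
            start = int(rng.integers(0, length - k + 1))
            if all(start + k <= a or start >= b for a, b in occupied):
                occupied.append((start, start + k))
                seq[start : start + k] = list(motif)
                break
        else:  # pragma: no cover - astronomically unlikely at default sizes
            raise RuntimeError("could not place motifs without overlap")
    return "".join(seq)


def _apply_label_noise(
    rng: np.random.Generator, members: frozenset[int], spec: SimSpec
) -> frozenset[int]:
    if rng.random() >= spec.label_noise:
        return members
    # flip one uniformly chosen class, skipping flips that would leave the
    # set empty or full (invalid for the rank loss)
    candidates = []
    for j in range(1, spec.q + 1):
        flipped = members ^ {j}
        if 0 < len(flipped) < spec.q:
            candidates.append(flipped)
    if not candidates:
        return members
    return candidates[rng.integers(0, len(candidates))]


def generate(spec: SimSpec) -> SimDataset:
    """Draw a dataset fully determined by ``spec.seed``.

    Per instance: draw a label set (singleton for mono-functional draws,
    a multi-class pattern otherwise), build a background sequence, splice
    in the motif of every labeled class at non-overlapping random
    positions, set each labeled class's domain indicator bit with
    probability ``domain_signal`` and every other bit with probability
    ``domain_offrate``, then apply label noise. Multi flags are recomputed
    after noise so that every multi-flagged instance has >= 2 labels.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5D]))
    vocab = spec.vocabulary
    records, labels, flags, hits_per_record = [], [], [], []
    lo, hi = spec.length_range
    for i in range(spec.n):
        members = _draw_label_set(rng, spec)
        length = int(rng.integers(lo, hi + 1))
        motifs = [spec.motifs[c - 1] for c in sorted(members)]
        seq = _splice_motifs(rng, length, motifs)
        hits = []
        for j in range(1, spec.domain_dim + 1):
            if j <= spec.q and j in members:
                if rng.random() < spec.domain_signal:
                    hits.append(vocab[j - 1])
            elif rng.random() < spec.domain_offrate:
                hits.append(vocab[j - 1])
        members = _apply_label_noise(rng, members, spec)
        records.append(ProteinRecord(id=f"syn{i:05d}", sequence=seq))
        labels.append(LabelSet(members, q=spec.q))
        flags.append(len(members) >= 2)
        hits_per_record.append(hits)
    return SimDataset(
        records=records,
        labels=labels,
        multi_flags=flags,
        domain_hits=hits_per_record,
        truth=spec,
    )


def motif_oracle_labels(ds: SimDataset) -> list[LabelSet]:
    """Bag-of-motifs reference classifier: label j iff motif j is a
    substring. With ``label_noise=0`` this reproduces the true labels
    exactly, certifying that the dataset is information-complete."""
    spec = ds.truth
    out = []
    for rec in ds.records:
        members = {
            j for j in range(1, spec.q + 1) if spec.motifs[j - 1] in rec.sequence
        }
        out.append(LabelSet(members, q=spec.q))
    return out


# ---------------------------------------------------------------------------
# file output


def write_pssm_fixture(record: ProteinRecord, path: str | Path) -> None:
    """Write a PSI-BLAST ASCII PSSM in the ``-out_ascii_pssm`` layout whose
    percentage block is the degenerate one-hot profile of the sequence.

    Synthetic: stands in for a real PSI-BLAST profile so the parser and the
    PSSM branch are exercisable without a homology search.
    """
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(AMINO_ACIDS) + "   " + "  ".join(AMINO_ACIDS),
    ]
    for pos, aa in enumerate(record.sequence, start=1):
        log_odds = ["-1"] * 20
        percents = ["0"] * 20
        col = AMINO_ACIDS.index(aa)
        log_odds[col] = "7"
        percents[col] = "100"
        lines.append(
            f"{pos:5d} {aa}  " + " ".join(log_odds) + "   " + " ".join(percents)
            + "  0.00 0.00"
        )
    lines += ["", "                      K         Lambda", ""]
    Path(path).write_text("\n".join(lines) + "\n")


def write_labels_tsv(
    ids: Sequence[str], labels: Sequence[LabelSet], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for rid, lab in zip(ids, labels):
            fh.write(f"{rid}\t{','.join(str(j) for j in sorted(lab.members))}\n")


def read_labels_tsv(path: str | Path, q: int) -> dict[str, LabelSet]:
    out: dict[str, LabelSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rid, classes = line.split("\t")
                members = frozenset(int(c) for c in classes.split(",") if c)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed label row") from exc
            out[rid] = LabelSet(members, q=q)
    return out


def write_dataset(ds: SimDataset, directory: str | Path, pssm_fixtures: bool = False) -> None:
    """Write the dataset in the same formats the encoders consume.

    Emits ``sequences.fasta``, ``labels.tsv``, ``vocabulary.txt`` and one
    plain-list domain-hit file per record under ``domains/``; with
    ``pssm_fixtures=True`` also one ASCII PSSM per record under ``pssm/``
    (degenerate one-hot profiles).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "sequences.fasta", "w") as fh:
        for rec in ds.records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
    write_labels_tsv([r.id for r in ds.records], ds.labels, directory / "labels.tsv")
    (directory / "vocabulary.txt").write_text(
        "".join(f"{d}\n" for d in ds.truth.vocabulary)
    )
    dom_dir = directory / "domains"
    dom_dir.mkdir(exist_ok=True)
    for rec, hits in zip(ds.records, ds.domain_hits):
        (dom_dir / f"{rec.id}.txt").write_text("".join(f"{h}\n" for h in hits))
    if pssm_fixtures:
        pssm_dir = directory / "pssm"
        pssm_dir.mkdir(exist_ok=True)
        for rec in ds.records:
            write_pssm_fixture(rec, pssm_dir / f"{rec.id}.pssm")
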