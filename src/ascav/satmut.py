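"""Model-agnostic in silico saturation mutagenesis and allele scoring.

Any multi-class sequence scorer — a trained neural network behind a
subprocess contract, or the PWM-based reference scorer shipped here —
can be plugged in.  For a length-L window the engine scores the
reference sequence plus all 3L single-base mutants (1,500 for the
default 500-bp window) and records per-class score deltas relative to
the reference.  The same machinery scores the two allele versions of a
peak sequence at a phased variant, giving the per-class delta prediction
score used to rank variants and to compute explained fractions at a
fixed false-positive rate.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.special import expit

from .motifs import PWM, best_site_score, explained_fraction_at_fpr

__all__ = [
    "SequenceScorer",
    "PwmReferenceScorer",
    "CommandScorer",
    "SatMutResult",
    "saturation_mutagenesis",
    "variant_delta",
    "explained_by_model",
    "write_delta_tsv",
]

BASES = "ACGT"


@runtime_checkable
class SequenceScorer(Protocol):
    """Deterministic scorer mapping a fixed-length DNA string to
    per-class scores in [0, 1]."""

    n_classes: int
    window_length: int

    def score(self, seq: str) -> np.ndarray: ...

    def score_batch(self, seqs: Sequence[str]) -> np.ndarray: ...


class _BatchMixin:
    def score_batch(self, seqs: Sequence[str]) -> np.ndarray:
        return np.stack([self.score(s) for s in seqs]) if seqs else np.empty((0, self.n_classes))


class PwmReferenceScorer(_BatchMixin):
    """Reference scorer: one class per PWM, logistic-squashed best-site score.

    class score = logistic(slope * best_site_score(seq, pwm) + offset).
    Deterministic and closed-form, so engine behavior can be verified
    exactly; it stands in for a trained enhancer model during testing
    and development.
    """

    def __init__(
        self,
        pwms: Sequence[PWM],
        slope: float = 1.0,
        offset: float = 0.0,
        window_length: int = 500,
    ):
        if not pwms:
            raise ValueError("at least one PWM required")
        self.pwms = list(pwms)
        self.slope = slope
        self.offset = offset
        self.window_length = window_length
        self.n_classes = len(self.pwms)
        self.class_names = [p.motif_id for p in self.pwms]

    def score(self, seq: str) -> np.ndarray:
        return expit(
            np.array([self.slope * best_site_score(seq, p) + self.offset for p in self.pwms])
        )


class ConstantScorer(_BatchMixin):
    """Scorer returning a fixed vector; useful as a degenerate control."""

    def __init__(self, values: Sequence[float], window_length: int = 500):
        self.values = np.asarray(values, float)
        self.n_classes = self.values.size
        self.window_length = window_length

    def score(self, seq: str) -> np.ndarray:
        return self.values.copy()


class CommandScorer(_BatchMixin):
    """External scorer behind a subprocess/file contract.

    The command is run as ``cmd <in.tsv> <out.tsv>``.  The input TSV has
    columns ``seq_id`` and ``sequence``; the output must echo a header
    ``seq_id class_0 ... class_{k-1}`` followed by one row per input
    sequence, same order.  This lets published trained models be plugged
    in without adding a deep-learning framework dependency here.
    """

    def __init__(self, command: Sequence[str], n_classes: int, window_length: int = 500):
        self.command = list(command)
        self.n_classes = n_classes
        self.window_length = window_length

    def score_batch(self, seqs: Sequence[str]) -> np.ndarray:
        with tempfile.TemporaryDirectory() as td:
            inp = Path(td) / "in.tsv"
            out = Path(td) / "out.tsv"
            with open(inp, "w") as fh:
                fh.write("seq_id\tsequence\n")
                for i, s in enumerate(seqs):
                    fh.write(f"s{i}\t{s}\n")
            subprocess.run([*self.command, str(inp), str(out)], check=True)
            rows = []
            with open(out) as fh:
                header = fh.readline().rstrip("\n").split("\t")
                if header[0] != "seq_id" or len(header) != self.n_classes + 1:
                    raise ValueError(f"bad scorer output header {header}")
                for line in fh:
                    rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
        arr = np.array(rows, float)
        if arr.shape != (len(seqs), self.n_classes):
            raise ValueError(f"scorer returned shape {arr.shape}, expected {(len(seqs), self.n_classes)}")
        return arr

    def score(self, seq: str) -> np.ndarray:
        return self.score_batch([seq])[0]


@dataclass
class SatMutResult:
    """All single-base substitution effects for one window.

    ``delta`` has shape (L, 4, n_classes) indexed by position and
    substituted base (ACGT); entries at the reference base are zero by
    construction, so exactly 3L informative mutants are covered.
    """

    seq_id: str
    sequence: str
    reference_scores: np.ndarray  # (n_classes,)
    delta: np.ndarray  # (L, 4, n_classes)
    class_names: list[str] = field(default_factory=list)

    @property
    def n_mutants(self) -> int:
        return 3 * len(self.sequence)

    def mutant_sequence(self, pos: int, base: str) -> str:
        return self.sequence[:pos] + base + self.sequence[pos + 1 :]

    def max_abs_delta(self) -> tuple[int, str, int, float]:
        """(position, base, class index, delta) of the largest |delta|."""
        i = int(np.abs(self.delta).argmax())
        pos, b, c = np.unravel_index(i, self.delta.shape)
        return int(pos), BASES[b], int(c), float(self.delta[pos, b, c])


def saturation_mutagenesis(seq: str, scorer: SequenceScorer, seq_id: str = "seq") -> SatMutResult:
    """Score every single-base mutant of `seq` against the scorer.

    The window length must match the scorer's configured length; 3L
    mutants plus the reference are scored (1,500 mutants at L = 500).
    """
    seq = seq.upper()
    L = len(seq)
    if L != scorer.window_length:
        raise ValueError(f"sequence length {L} != scorer window {scorer.window_length}")
    mutants: list[str] = []
    slots: list[tuple[int, int]] = []
    for pos in range(L):
        for bi, base in enumerate(BASES):
            if base == seq[pos]:
                continue
            mutants.append(seq[:pos] + base + seq[pos + 1 :])
            slots.append((pos, bi))
    scores = scorer.score_batch([seq, *mutants])
    ref = scores[0]
    delta = np.zeros((L, 4, scorer.n_classes))
    for (pos, bi), s in zip(slots, scores[1:]):
        delta[pos, bi] = s - ref
    return SatMutResult(
        seq_id=seq_id, sequence=seq, reference_scores=ref, delta=delta,
        class_names=list(getattr(scorer, "class_names", [])),
    )


def variant_delta(
    window_seq: str,
    offset: int,
    allele_a: str,
    allele_b: str,
    scorer: SequenceScorer,
) -> np.ndarray:
    """Per-class score difference between the two allele versions of a window.

    ``window_seq`` is the peak window in any backbone; the single-base
    alleles are substituted at ``offset`` (0-based within the window).
    Antisymmetric: swapping the alleles negates every class delta.
    """
    if not (0 <= offset < len(window_seq)):
        raise ValueError(f"variant offset {offset} outside window of {len(window_seq)} bp")
    if len(allele_a) != 1 or len(allele_b) != 1:
        raise ValueError("alleles must be single bases; re-extract windows for indels")
    seq_a = window_seq[:offset] + allele_a.upper() + window_seq[offset + 1 :]
    seq_b = window_seq[:offset] + allele_b.upper() + window_seq[offset + 1 :]
    scores = scorer.score_batch([seq_a, seq_b])
    return scores[0] - scores[1]


@dataclass
class ExplainedResult:
    threshold: float
    fraction: float
    explained_ids: list[str]
    above_detection: list[str]


def explained_by_model(
    event_deltas: Mapping[str, np.ndarray],
    control_deltas: Mapping[str, np.ndarray],
    class_subset: Sequence[int] | None = None,
    fpr: float = 0.05,
    detection_threshold: float = 0.05,
) -> ExplainedResult:
    """Fraction of event variants explained by the model at a given FPR.

    Each variant's score is the maximum |per-class delta| over the
    selected classes; the threshold is set so that at most `fpr` of the
    control variants exceed it.  Variants whose score also exceeds the
    absolute `detection_threshold` are flagged separately.
    """
    if class_subset is not None and len(class_subset) == 0:
        raise ValueError("class subset must be non-empty")

    def collapse(deltas: Mapping[str, np.ndarray]) -> dict[str, float]:
        out = {}
        for k, d in deltas.items():
            d = np.atleast_1d(np.asarray(d, float))
            sel = d if class_subset is None else d[list(class_subset)]
            out[k] = float(np.abs(sel).max())
        return out

    ev = collapse(event_deltas)
    ct = collapse(control_deltas)
    threshold, fraction = explained_fraction_at_fpr(list(ev.values()), list(ct.values()), fpr)
    explained = sorted(k for k, s in ev.items() if s > threshold)
    detected = sorted(k for k, s in ev.items() if s > detection_threshold)
    return ExplainedResult(
        threshold=threshold, fraction=fraction,
        explained_ids=explained, above_detection=detected,
    )


def write_delta_tsv(result: SatMutResult, path: str | Path, eps: float = 0.0) -> None:
    """Long-format dump: seq_id, pos, base, class, delta (|delta| > eps)."""
    names = result.class_names or [f"class_{i}" for i in range(result.delta.shape[2])]
    with open(path, "w") as fh:
        fh.write("seq_id\tpos\tbase\tclass\tdelta\n")
        L, _, C = result.delta.shape
        for pos in range(L):
            for bi, base in enumerate(BASES):
                if base == result.sequence[pos]:
                    continue
                for c in range(C):
                    d = result.delta[pos, bi, c]
                    if abs(d) > eps:
                        fh.write(f"{result.seq_id}\t{pos}\t{base}\t{names[c]}\t{d:.6g}\n")
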