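"""Delta-PWM scoring of allele pairs, motif enrichment, and
explained-fraction-at-FPR curves.

A peak's motif score is the best single-site log2-odds over all windows
on both strands.  The "delta" score of an allele-specific peak is the
difference between the score of the preferred-allele sequence (the
allele with the higher assay signal) and the other allele's sequence;
gains and losses of a binding site show up as large positive or negative
deltas.  Per motif, a one-sided Fisher's exact test compares how often
allele-specific peaks exceed a delta cutoff against a control set of
non-allele-specific peaks, with BH correction across motifs.  The
explained fraction at a false-positive rate f is the share of event
variants whose score exceeds the threshold at which only a fraction f
of control variants would be called.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .stats import bh_fdr

__all__ = [
    "PWM",
    "MotifDelta",
    "EnrichmentResult",
    "best_site_score",
    "delta_motif_score",
    "enrichment_test",
    "enrich_motifs",
    "explained_fraction_at_fpr",
    "label_shuffle_baseline",
    "read_pwms",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
NEG_INF = float("-inf")


@dataclass(frozen=True)
class PWM:
    """A position weight matrix with per-base background frequencies.

    `matrix` holds base probabilities (positions x ACGT); rows are
    normalized after adding a small pseudocount so log-odds are finite.
    """

    motif_id: str
    matrix: np.ndarray  # (L, 4) probabilities
    background: np.ndarray = None  # (4,)
    pseudocount: float = 1e-3  # added per cell before row normalization

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("PWM matrix must be (length >= 1) x 4")
        if np.any(m < 0):
            raise ValueError("PWM entries must be non-negative")
        m = m + self.pseudocount
        if np.any(m.sum(axis=1) <= 0):
            raise ValueError("PWM rows must have positive mass")
        m = m / m.sum(axis=1, keepdims=True)
        object.__setattr__(self, "matrix", m)
        bg = np.full(4, 0.25) if self.background is None else np.asarray(self.background, float)
        if bg.shape != (4,) or np.any(bg <= 0):
            raise ValueError("background must be 4 positive frequencies")
        object.__setattr__(self, "background", bg)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 4) log2(p / background)."""
        return np.log2(self.matrix / self.background)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        # matrix rows are already normalized; skip a second pseudocount
        return PWM(self.motif_id, self.matrix[::-1, ::-1], self.background[::-1], pseudocount=0.0)


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to base indices; N (or any ambiguity code) -> -1."""
    return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=np.int64)


def _strand_scores(idx: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Per-window sums of log-odds; windows containing N score -inf."""
    m = lom.shape[0]
    n_win = idx.size - m + 1
    wins = np.lib.stride_tricks.sliding_window_view(idx, m)  # (n_win, m)
    safe = np.where(wins < 0, 0, wins)
    scores = lom[np.arange(m), safe].sum(axis=1)
    scores[np.any(wins < 0, axis=1)] = NEG_INF
    return scores[:n_win]


def best_site_score(seq: str, pwm: PWM) -> float:
    """Best single-site log2-odds over all windows on both strands.

    Scanning the reverse strand is done by scoring the forward sequence
    with the reverse-complemented matrix (equivalent and cheaper).
    Windows containing any non-ACGT base score -inf; a sequence shorter
    than the motif raises.
    """
    if len(seq) < len(pwm):
        raise ValueError(f"sequence ({len(seq)} bp) shorter than motif {pwm.motif_id} ({len(pwm)} bp)")
    idx = encode(seq)
    fwd = _strand_scores(idx, pwm.log_odds)
    rev = _strand_scores(idx, pwm.reverse_complement().log_odds)
    return float(max(fwd.max(), rev.max()))


@dataclass(frozen=True)
class MotifDelta:
    peak_id: str
    motif_id: str
    score_preferred: float
    score_other: float

    @property
    def delta(self) -> float:
        return self.score_preferred - self.score_other


def delta_motif_score(
    seq_preferred: str, seq_other: str, pwm: PWM, peak_id: str = ""
) -> MotifDelta:
    """Delta between the preferred-allele and other-allele peak sequences."""
    return MotifDelta(
        peak_id=peak_id,
        motif_id=pwm.motif_id,
        score_preferred=best_site_score(seq_preferred, pwm),
        score_other=best_site_score(seq_other, pwm),
    )


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    threshold: float
    direction: str
    event_above: int
    event_below: int
    control_above: int
    control_below: int
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")


def _count_above(deltas: np.ndarray, threshold: float, direction: str) -> int:
    if direction == "greater":
        return int(np.sum(deltas > threshold))
    if direction == "less":
        return int(np.sum(deltas < -threshold))
    raise ValueError("direction must be 'greater' or 'less'")


def enrichment_test(
    event_deltas: Sequence[float],
    control_deltas: Sequence[float],
    motif_id: str = "",
    threshold: float = 3.0,
    direction: str = "greater",
) -> EnrichmentResult:
    """One-sided Fisher's exact test of delta exceedance in events vs controls.

    direction="greater" counts motif gains on the preferred allele
    (delta > threshold); "less" counts deltas below -threshold, covering
    motifs negatively associated with the signal (repressors).  The odds
    ratio is ad/bc with a Haldane 0.5 correction when any cell is zero.
    """
    ev = np.asarray(event_deltas, float)
    ct = np.asarray(control_deltas, float)
    if ev.size == 0 or ct.size == 0:
        raise ValueError("both delta lists must be non-empty")
    a = _count_above(ev, threshold, direction)
    b = ev.size - a
    c = _count_above(ct, threshold, direction)
    d = ct.size - c
    table = np.array([[a, b], [c, d]])
    p = float(fisher_exact(table, alternative="greater")[1])
    if min(a, b, c, d) == 0:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    return EnrichmentResult(
        motif_id=motif_id, threshold=threshold, direction=direction,
        event_above=a, event_below=b, control_above=c, control_below=d,
        odds_ratio=float(orr), p_value=p,
    )


def enrich_motifs(
    event_deltas_by_motif: Mapping[str, Sequence[float]],
    control_deltas_by_motif: Mapping[str, Sequence[float]],
    threshold: float = 3.0,
    direction: str = "greater",
) -> list[EnrichmentResult]:
    """Per-motif enrichment with BH correction across motifs."""
    motifs = sorted(event_deltas_by_motif)
    results = [
        enrichment_test(
            event_deltas_by_motif[m], control_deltas_by_motif[m],
            motif_id=m, threshold=threshold, direction=direction,
        )
        for m in motifs
    ]
    q = bh_fdr([r.p_value for r in results])
    return [
        EnrichmentResult(**{**r.__dict__, "q_value": float(qi)})
        for r, qi in zip(results, q)
    ]


def explained_fraction_at_fpr(
    event_scores: Sequence[float],
    control_scores: Sequence[float],
    fpr: float = 0.05,
) -> tuple[float, float]:
    """(threshold, explained fraction) at a control false-positive rate.

    The threshold is the smallest value t such that the fraction of
    control scores strictly above t is at most `fpr` (the empirical
    (1 - fpr)-quantile with the higher-value convention); the explained
    fraction is the share of event scores strictly above t.
    """
    if not (0 < fpr < 1):
        raise ValueError("fpr must lie in (0, 1)")
    ev = np.asarray(event_scores, float)
    ct = np.sort(np.asarray(control_scores, float))
    if ev.size == 0 or ct.size == 0:
        raise ValueError("both score lists must be non-empty")
    n = ct.size
    k = int(np.floor(fpr * n))  # controls allowed above the threshold
    threshold = ct[n - k - 1] if k < n else NEG_INF
    fraction = float(np.mean(ev > threshold))
    return float(threshold), fraction


def label_shuffle_baseline(
    event_scores: Sequence[float],
    control_scores: Sequence[float],
    fpr: float = 0.05,
    n_perm: int = 200,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null explained fractions from label-shuffled event/control pools."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ev = np.asarray(event_scores, float)
    ct = np.asarray(control_scores, float)
    pool = np.concatenate([ev, ct])
    out = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pool.size)
        out[i] = explained_fraction_at_fpr(pool[perm[: ev.size]], pool[perm[ev.size :]], fpr)[1]
    return out


# ---------------------------------------------------------------------------
# PWM file formats

def read_pwms(path: str | Path, fmt: str | None = None) -> list[PWM]:
    """Read PWMs from Cluster-Buster (.cb) or JASPAR text files.

    Cluster-Buster: ``>id`` then one line of 4 counts (A C G T) per
    position.  JASPAR: ``>id name`` then four rows ``A [ n n ... ]``.
    Format is sniffed from the first matrix line unless given.
    """
    text = Path(path).read_text()
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    if fmt is None:
        first_data = next((ln for ln in lines if not ln.startswith(">")), "")
        fmt = "jaspar" if any(ch in first_data for ch in "[]") or first_data[:1] in "ACGT" else "cb"
    if fmt == "cb":
        return _read_cb(lines)
    if fmt == "jaspar":
        return _read_jaspar(lines)
    raise ValueError(f"unknown PWM format {fmt!r}")


def _read_cb(lines: list[str]) -> list[PWM]:
    pwms, name, rows = [], None, []
    for ln in lines:
        if ln.startswith(">"):
            if name is not None and rows:
                pwms.append(PWM(name, np.array(rows, float)))
            name, rows = ln[1:].strip().split()[0], []
        else:
            rows.append([float(x) for x in ln.split()])
    if name is not None and rows:
        pwms.append(PWM(name, np.array(rows, float)))
    return pwms


def _read_jaspar(lines: list[str]) -> list[PWM]:
    pwms, name, rows = [], None, {}
    order = "ACGT"

    def flush():
        if name is not None and len(rows) == 4:
            mat = np.array([rows[b] for b in order], float).T
            pwms.append(PWM(name, mat))

    for ln in lines:
        if ln.startswith(">"):
            flush()
            name, rows = ln[1:].strip().split()[0], {}
        else:
            base = ln.strip()[0].upper()
            nums = ln.replace("[", " ").replace("]", " ").split()[1:]
            rows[base] = [float(x) for x in nums]
    flush()
    return pwms


def write_pwm_cb(pwms: Iterable[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id}\n")
            for row in p.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
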