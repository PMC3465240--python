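"""Position weight matrices and discriminative threshold optimization.

PWMs are log-odds matrices built from position frequency matrices with a
background-distributed pseudocount:

    w[b,j] = log2( (n[b,j] + p * q[b]) / ((N_j + p) * q[b]) )

where ``n[b,j]`` are the column counts, ``N_j`` the column sum, ``p`` the
pseudocount mass and ``q`` the background base distribution.  Window scores
are min-max normalized onto [0,1] (the consensus word scores exactly 1), so
thresholds behave as percentages and the downstream "optimal threshold minus
5%" relaxation is an absolute 0.05 step.

Instead of an information-content or p-value calibration, each PWM gets an
individual threshold that best *discriminates* the positive from the
negative promoter set: the threshold maximizing C+/C- subject to
C+ >= 0.75, C- <= 0.5 and F+/F- >= 2.  A PWM for which no attained score
satisfies all three conditions is excluded from the analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np

from .core import (CoverageStats, FeatureInstance, InputError, Sequence,
                   SequenceSet, revcomp)

__all__ = [
    "Pfm",
    "Pwm",
    "ScreeningBounds",
    "build_pwm",
    "scan",
    "scan_set",
    "optimize_threshold",
    "relax_threshold",
    "read_jaspar",
    "read_transfac",
    "estimate_background",
]

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

#: score assigned to windows containing N: guarantees they never reach any
#: threshold
_N_PENALTY = -1e9


@dataclass(frozen=True)
class Pfm:
    """Position frequency matrix: per-column base counts (rows A,C,G,T)."""

    id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.shape[0] != 4 or counts.ndim != 2:
            raise InputError(f"PFM {self.id!r}: counts must be 4 x L")
        if counts.shape[1] < 1:
            raise InputError(f"PFM {self.id!r}: empty matrix")
        if (counts < 0).any():
            raise InputError(f"PFM {self.id!r}: negative counts")
        if (counts.sum(axis=0) <= 0).any():
            raise InputError(f"PFM {self.id!r}: zero column")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def n_sites(self) -> float:
        """Effective number of aligned sites (mean column sum)."""
        return float(self.counts.sum(axis=0).mean())


@dataclass(frozen=True)
class Pwm:
    """Log-odds scoring matrix with an optional discriminative threshold."""

    id: str
    weights: np.ndarray  # 4 x L
    min_score: float
    max_score: float
    threshold: Optional[float] = None
    accepted: bool = False
    stats: Optional[CoverageStats] = None

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    def normalize(self, raw: np.ndarray) -> np.ndarray:
        """Map raw log-odds scores onto [0,1]; the consensus word maps to 1."""
        span = self.max_score - self.min_score
        if span <= 0:  # degenerate matrix: every word scores identically
            return np.ones_like(np.asarray(raw, dtype=float))
        return (np.asarray(raw, dtype=float) - self.min_score) / span


@dataclass(frozen=True)
class ScreeningBounds:
    """Boundary conditions for accepting a discriminative threshold."""

    c_pos_min: float = 0.75
    c_neg_max: float = 0.5
    f_ratio_min: float = 2.0


def estimate_background(*sets: SequenceSet) -> np.ndarray:
    """Base distribution of the union of sequence sets (N excluded)."""
    counts = np.zeros(4)
    for sset in sets:
        for seq in sset:
            for i, b in enumerate(BASES):
                counts[i] += seq.residues.count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def build_pwm(pfm: Pfm, pseudocount: float = 1.0,
              background: Optional[Iterable[float]] = None) -> Pwm:
    """Log-odds PWM from a PFM with background-distributed pseudocounts."""
    if pseudocount <= 0:
        raise InputError("pseudocount must be > 0")
    if background is None:
        bg = np.full(4, 0.25)
    else:
        bg = np.asarray(list(background), dtype=float)
        if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-6:
            raise InputError("background must be 4 strictly positive frequencies summing to 1")
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    weights = np.log2(
        (counts + pseudocount * bg[:, None]) / ((colsum + pseudocount) * bg[:, None])
    )
    min_score = float(weights.min(axis=0).sum())
    max_score = float(weights.max(axis=0).sum())
    return Pwm(id=pfm.id, weights=weights, min_score=min_score, max_score=max_score)


def _encode(residues: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and N -> 4."""
    table = np.full(128, 4, dtype=np.int8)
    for b, i in _BASE_IDX.items():
        table[ord(b)] = i
    return table[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def window_scores(pwm: Pwm, residues: str) -> np.ndarray:
    """Normalized scores of every forward-strand window (len(seq)-L+1 values).

    Windows containing N score below 0 and can never pass a threshold.
    """
    L = pwm.length
    n = len(residues)
    if n < L:
        return np.empty(0)
    enc = _encode(residues)
    # extended weight matrix with an N row
    w = np.vstack([pwm.weights, np.full((1, L), _N_PENALTY)])
    idx = np.lib.stride_tricks.sliding_window_view(enc, L)
    raw = w[idx, np.arange(L)].sum(axis=1)
    norm = pwm.normalize(raw)
    # windows containing N can never count as hits, whatever the matrix
    norm[(idx == 4).any(axis=1)] = -1.0
    return norm


def scan(pwm: Pwm, seq: Sequence, threshold: float,
         both_strands: bool = True) -> list[FeatureInstance]:
    """All windows with normalized score >= threshold, both strands.

    Reverse-strand hits are reported in forward coordinates with strand '-'.
    """
    if not (0.0 <= threshold <= 1.0):
        raise InputError("threshold must lie in [0,1]")
    L = pwm.length
    n = seq.length
    hits: list[FeatureInstance] = []
    eps = 1e-9
    fwd = window_scores(pwm, seq.residues)
    for i in np.flatnonzero(fwd >= threshold - eps):
        hits.append(FeatureInstance(seq=seq.id, start=int(i), end=int(i) + L,
                                    feature=pwm.id, strand="+",
                                    score=float(fwd[i])))
    if both_strands:
        rev = window_scores(pwm, revcomp(seq.residues))
        for i in np.flatnonzero(rev >= threshold - eps):
            start = n - int(i) - L
            hits.append(FeatureInstance(seq=seq.id, start=start, end=start + L,
                                        feature=pwm.id, strand="-",
                                        score=float(rev[i])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_set(pwm: Pwm, sset: SequenceSet, threshold: float,
             both_strands: bool = True) -> list[FeatureInstance]:
    out: list[FeatureInstance] = []
    for seq in sset:
        out.extend(scan(pwm, seq, threshold, both_strands=both_strands))
    return out


def _set_scores(pwm: Pwm, sset: SequenceSet, both_strands: bool) -> list[np.ndarray]:
    per_seq = []
    for seq in sset:
        s = window_scores(pwm, seq.residues)
        if both_strands:
            s = np.concatenate([s, window_scores(pwm, revcomp(seq.residues))])
        per_seq.append(s)
    return per_seq


def effective_negative_coverage(c_neg: float, n_neg: int) -> float:
    """C- with the half-count correction: a zero count becomes 1/(2 N)."""
    return c_neg if c_neg > 0 else 1.0 / (2 * n_neg)


def optimize_threshold(pwm: Pwm, pos: SequenceSet, neg: SequenceSet,
                       bounds: ScreeningBounds = ScreeningBounds(),
                       both_strands: bool = True) -> Pwm:
    """Find the threshold that best discriminates positives from negatives.

    Candidate thresholds are every distinct attained normalized window score
    (no grid).  Among candidates satisfying the boundary conditions, the one
    maximizing C+/C- wins; at equal ratio the higher (stricter) threshold is
    kept.  When C- = 0 the ratio uses the half-count 1/(2 N_neg).  If no
    candidate qualifies the PWM is returned unaccepted, threshold absent.
    """
    pos_scores = _set_scores(pwm, pos, both_strands)
    neg_scores = _set_scores(pwm, neg, both_strands)

    pos_max = np.array([s.max() if s.size else -np.inf for s in pos_scores])
    neg_max = np.array([s.max() if s.size else -np.inf for s in neg_scores])
    pos_all = np.sort(np.concatenate([s for s in pos_scores]) if pos_scores else np.empty(0))
    neg_all = np.sort(np.concatenate([s for s in neg_scores]) if neg_scores else np.empty(0))
    pos_max_sorted = np.sort(pos_max)
    neg_max_sorted = np.sort(neg_max)

    attained = np.unique(np.concatenate([pos_all, neg_all]))
    attained = attained[attained >= 0]  # N-window sentinel scores excluded
    if attained.size == 0:
        return replace(pwm, threshold=None, accepted=False, stats=None)

    n_pos, n_neg = pos.N, neg.N
    eps = 1e-9
    t = attained - eps  # count scores >= candidate, robust to float noise
    c_pos = (n_pos - np.searchsorted(pos_max_sorted, t, side="left")) / n_pos
    c_neg = (n_neg - np.searchsorted(neg_max_sorted, t, side="left")) / n_neg
    f_pos = (pos_all.size - np.searchsorted(pos_all, t, side="left")) / pos.total_bp
    f_neg = (neg_all.size - np.searchsorted(neg_all, t, side="left")) / neg.total_bp

    with np.errstate(divide="ignore", invalid="ignore"):
        f_ratio = np.where(f_neg > 0, f_pos / np.maximum(f_neg, 1e-300), np.inf)
        f_ratio = np.where(f_pos == 0, 0.0, f_ratio)
    ok = (
        (c_pos >= bounds.c_pos_min)
        & (c_neg <= bounds.c_neg_max)
        & (f_ratio >= bounds.f_ratio_min)
    )
    if not ok.any():
        return replace(pwm, threshold=None, accepted=False, stats=None)

    c_neg_eff = np.where(c_neg > 0, c_neg, 1.0 / (2 * n_neg))
    ratio = np.where(ok, c_pos / c_neg_eff, -np.inf)
    # max ratio; ties -> higher threshold (attained is ascending, argmax of
    # reversed array picks the last = highest qualifying score)
    best = attained.size - 1 - int(np.argmax(ratio[::-1]))
    stats = CoverageStats(
        c_pos=float(c_pos[best]),
        c_neg=float(c_neg[best]),
        f_pos=float(f_pos[best]),
        f_neg=float(f_neg[best]),
    )
    return replace(pwm, threshold=float(attained[best]), accepted=True, stats=stats)


def relax_threshold(pwm: Pwm, delta: float = 0.05) -> Pwm:
    """Lower an accepted PWM's threshold by ``delta`` (floored at 0).

    Used before the combinatorial search so weaker motif occurrences are
    included; lowering the threshold can only add instances, never remove
    any, so no coverage value decreases.
    """
    if not pwm.accepted or pwm.threshold is None:
        raise ValueError(f"PWM {pwm.id!r} has no accepted threshold to relax")
    return replace(pwm, threshold=max(0.0, pwm.threshold - delta))


# ---------------------------------------------------------------------------
# matrix file dialects


def read_jaspar(path_or_text: str) -> list[Pfm]:
    """Parse JASPAR-style PFMs.

    Accepts the 4-line letter format::

        >MA0001.1 NAME
        A [ 1  2  0 ]
        C [ 0  5  1 ]
        ...

    Letter prefixes and brackets are optional; rows must appear in A,C,G,T
    order when letters are absent.
    """
    text = path_or_text
    if "\n" not in path_or_text:
        with open(path_or_text) as fh:
            text = fh.read()
    pfms: list[Pfm] = []
    cur_id: Optional[str] = None
    rows: dict[str, list[float]] = {}
    order: list[str] = []

    def flush() -> None:
        nonlocal rows, order
        if cur_id is None:
            return
        if len(order) != 4:
            raise InputError(f"matrix {cur_id!r}: expected 4 rows, got {len(order)}")
        counts = np.array([rows[b] for b in BASES])
        pfms.append(Pfm(id=cur_id, counts=counts))
        rows, order = {}, []

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            cur_id = line[1:].split()[0]
            continue
        if cur_id is None:
            raise InputError("matrix data before any >ID header")
        m = re.match(r"^([ACGT])?\s*\[?([-\d.\s]+)\]?$", line)
        if not m:
            raise InputError(f"unparseable matrix line: {line!r}")
        letter = m.group(1) or BASES[len(order)]
        values = [float(x) for x in m.group(2).split()]
        if letter in rows:
            raise InputError(f"matrix {cur_id!r}: duplicate row {letter}")
        rows[letter] = values
        order.append(letter)
    flush()
    if not pfms:
        raise InputError("no matrices found")
    return pfms


def read_transfac(path_or_text: str) -> list[Pfm]:
    """Parse a minimal TRANSFAC-style table dialect (DE / P0 / numbered rows).

    Example::

        DE  M00001 my_motif
        P0      A      C      G      T
        01      5      0      3      2      R
        02      ...
        XX
        //
    """
    text = path_or_text
    if "\n" not in path_or_text:
        with open(path_or_text) as fh:
            text = fh.read()
    pfms: list[Pfm] = []
    cur_id: Optional[str] = None
    col_order: Optional[list[int]] = None
    cols: list[list[float]] = []

    def flush() -> None:
        nonlocal cur_id, col_order, cols
        if cur_id is not None and cols:
            counts = np.array(cols).T  # rows are positions -> transpose
            pfms.append(Pfm(id=cur_id, counts=counts))
        cur_id, col_order, cols = None, None, []

    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("XX"):
            continue
        if line.startswith("//"):
            flush()
            continue
        parts2 = line.split(None, 1)
        tag = parts2[0]
        rest = parts2[1].strip() if len(parts2) > 1 else ""
        if tag == "DE":
            flush()
            cur_id = rest.split()[0] if rest else None
        elif tag in ("P0", "PO"):
            letters = rest.split()
            if sorted(letters) != sorted(BASES):
                raise InputError(f"P0 line must list A C G T, got {letters}")
            col_order = [letters.index(b) for b in BASES]
        elif re.match(r"^\d+$", tag):
            if cur_id is None or col_order is None:
                raise InputError("matrix row before DE/P0 header")
            parts = rest.split()
            values = [float(x) for x in parts[:4]]
            cols.append([values[i] for i in col_order])
        else:
            raise InputError(f"unrecognized TRANSFAC line: {line!r}")
    flush()
    if not pfms:
        raise InputError("no matrices found")
    return pfms
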