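"""Built-in promoter sequence features beyond PWM motifs.

Implements compositional (AT-rich / GC-rich) regions, poly-A tracts and
exact direct/inverted repeats, plus import of externally computed feature
tracks (TSS predictions, duplex-destabilization regions, de novo motif
hits) from BED or GFF3.  The compositional bounds follow the three-sigma
rule: regions of at least ``min_len`` bp whose GC content falls below
mean - 3*SD or above mean + 3*SD of the per-sequence GC of the positive
set.  The repeat finder is a self-contained exact-match seed-and-extend
detector; repeat tracks produced by other programs remain importable via
:func:`import_track`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .core import (FeatureInstance, InputError, Sequence, SequenceSet,
                   revcomp)

__all__ = [
    "CompositionThresholds",
    "RepeatInstance",
    "composition_thresholds",
    "detect_composition_regions",
    "detect_poly_a",
    "detect_repeats",
    "repeats_to_instances",
    "import_track",
    "gc_fraction",
    "merge_intervals",
]

logger = logging.getLogger(__name__)


def gc_fraction(residues: str) -> float:
    """G+C fraction over determinate (non-N) bases."""
    acgt = sum(residues.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (residues.count("G") + residues.count("C")) / acgt


@dataclass(frozen=True)
class CompositionThresholds:
    """Three-sigma GC bounds derived from the positive set."""

    gc_mean: float
    gc_sd: float
    min_len: int = 100

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise InputError("min_len must be >= 1")
        if not (0.0 <= self.gc_mean <= 1.0) or self.gc_sd < 0:
            raise InputError("invalid GC statistics")

    @property
    def low(self) -> float:
        return self.gc_mean - 3.0 * self.gc_sd

    @property
    def high(self) -> float:
        return self.gc_mean + 3.0 * self.gc_sd

    @classmethod
    def from_stats(cls, gc_mean: float, gc_sd: float,
                   min_len: int = 100) -> "CompositionThresholds":
        return cls(gc_mean=gc_mean, gc_sd=gc_sd, min_len=min_len)


def composition_thresholds(pos: SequenceSet, min_len: int = 100,
                           pooled: bool = False) -> CompositionThresholds:
    """GC mean +/- three sigma bounds from the positive set.

    ``pooled=False`` (default) computes per-sequence GC fractions and takes
    their mean and sample SD; ``pooled=True`` would use a single pooled-bp
    GC with SD over sequences kept identical (both variants are reported by
    the CLI for comparison).
    """
    gcs = np.array([gc_fraction(s.residues) for s in pos])
    if gcs.size < 2:
        raise InputError("need >= 2 sequences to estimate GC dispersion")
    if pooled:
        mean = gc_fraction("".join(s.residues for s in pos))
    else:
        mean = float(gcs.mean())
    sd = float(gcs.std(ddof=1))
    return CompositionThresholds(gc_mean=mean, gc_sd=sd, min_len=min_len)


def merge_intervals(intervals: Iterable[tuple[int, int]],
                    gap: int = 0) -> list[tuple[int, int]]:
    """Merge intervals whose separation is <= gap (0 merges touching ones)."""
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def detect_composition_regions(seq: Sequence, thr: CompositionThresholds,
                               merge_gap: int = 0) -> list[FeatureInstance]:
    """Maximal AT-rich / GC-rich regions of length >= min_len.

    Every window of length ``min_len`` (step 1) is classified by its GC
    content: below ``thr.low`` -> at_rich, above ``thr.high`` -> gc_rich.
    Overlapping or adjacent qualifying windows of the same class merge into
    maximal regions.  N bases count as non-GC.
    """
    w = thr.min_len
    n = seq.length
    if n < w:
        return []
    is_gc = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(np.int32)
    csum = np.concatenate([[0], np.cumsum(is_gc)])
    window_gc = (csum[w:] - csum[:-w]) / w  # n - w + 1 values
    out: list[FeatureInstance] = []
    for feature, mask in (("at_rich", window_gc < thr.low),
                          ("gc_rich", window_gc > thr.high)):
        starts = np.flatnonzero(mask)
        regions = merge_intervals(((int(i), int(i) + w) for i in starts),
                                  gap=merge_gap)
        for s, e in regions:
            out.append(FeatureInstance(seq=seq.id, start=s, end=e,
                                       feature=feature, strand="+",
                                       score=None))
    out.sort(key=lambda i: (i.start, i.feature))
    return out


def detect_poly_a(seq: Sequence, k: int = 8, max_mismatch: int = 1,
                  merge: bool = False, include_t: bool = False,
                  feature: str = "poly_a") -> list[FeatureInstance]:
    """Poly-A tracts: k-mers within ``max_mismatch`` of A^k.

    With ``merge`` the overlapping raw windows collapse into maximal tracts;
    by default raw windows are reported.  ``include_t`` additionally reports
    (T)_k tracts (reverse-strand poly-A) with strand '-'.
    """
    if k < 1 or not (0 <= max_mismatch < k):
        raise InputError("require k >= 1 and 0 <= max_mismatch < k")
    out: list[FeatureInstance] = []
    for base, strand in (("A", "+"),) + ((("T", "-"),) if include_t else ()):
        arr = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
        mism = (arr != ord(base)).astype(np.int32)
        if seq.length < k:
            continue
        csum = np.concatenate([[0], np.cumsum(mism)])
        counts = csum[k:] - csum[:-k]
        hits = np.flatnonzero(counts <= max_mismatch)
        if merge:
            for s, e in merge_intervals(((int(i), int(i) + k) for i in hits)):
                out.append(FeatureInstance(seq=seq.id, start=s, end=e,
                                           feature=feature, strand=strand))
        else:
            for i in hits:
                out.append(FeatureInstance(
                    seq=seq.id, start=int(i), end=int(i) + k, feature=feature,
                    strand=strand, score=float(k - counts[i]) / k))
    out.sort(key=lambda i: (i.start, i.strand))
    return out


@dataclass(frozen=True)
class RepeatInstance:
    """An exact direct or inverted repeat: two non-overlapping arms."""

    kind: str  # direct | inverted
    seq: str
    arm1: tuple[int, int]
    arm2: tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "inverted"):
            raise InputError(f"invalid repeat kind {self.kind!r}")
        if self.arm1[1] > self.arm2[0]:
            raise InputError("repeat arms overlap")

    @property
    def arm_len(self) -> int:
        return self.arm1[1] - self.arm1[0]

    @property
    def spacer(self) -> int:
        return self.arm2[0] - self.arm1[1]


def classify_arm_gc(arm_seq: str) -> str:
    """GC class of a repeat arm: rich (>=0.75), poor (<=0.25), else neutral."""
    gc = gc_fraction(arm_seq)
    if gc >= 0.75:
        return "rich"
    if gc <= 0.25:
        return "poor"
    return "neutral"


def _seed_positions(residues: str, k: int) -> dict[str, list[int]]:
    table: dict[str, list[int]] = {}
    for i in range(len(residues) - k + 1):
        table.setdefault(residues[i:i + k], []).append(i)
    return table


def detect_repeats(seq: Sequence, min_arm: int = 10, max_spacer: int = 500,
                   kinds: tuple[str, ...] = ("direct", "inverted")
                   ) -> list[RepeatInstance]:
    """Maximal exact repeats with arm >= min_arm and spacer <= max_spacer.

    Seed-and-extend over exact ``min_arm``-mers.  A maximal match whose arms
    would overlap (tandem or center-spanning palindrome) is trimmed to the
    longest non-overlapping arms.  Arms never contain N (N != N by policy:
    ambiguous bases cannot evidence repetition).
    """
    if min_arm < 4:
        raise InputError("min_arm must be >= 4")
    s = seq.residues
    n = seq.length
    found: set[tuple[str, int, int, int]] = set()
    out: list[RepeatInstance] = []

    def match(a: str, b: str) -> bool:
        return a == b and a != "N"

    if "direct" in kinds:
        seeds = _seed_positions(s, min_arm)
        for kmer, positions in seeds.items():
            if "N" in kmer or len(positions) < 2:
                continue
            for ai in range(len(positions) - 1):
                for bi in range(ai + 1, len(positions)):
                    i, j = positions[ai], positions[bi]
                    # extend maximally
                    while i > 0 and j > 0 and match(s[i - 1], s[j - 1]):
                        i -= 1
                        j -= 1
                    L = min_arm + (positions[ai] - i)
                    while i + L < j + L < n and match(s[i + L], s[j + L]):
                        L += 1
                    key = ("direct", i, j, L)
                    if key in found:
                        continue
                    found.add(key)
                    La = min(L, j - i)  # non-overlapping arms
                    if La < min_arm:
                        continue
                    spacer = j - (i + La)
                    if spacer > max_spacer:
                        continue
                    out.append(RepeatInstance(kind="direct", seq=seq.id,
                                              arm1=(i, i + La),
                                              arm2=(j, j + La)))

    if "inverted" in kinds:
        r = revcomp(s)
        seeds_r = _seed_positions(r, min_arm)
        for i in range(n - min_arm + 1):
            kmer = s[i:i + min_arm]
            if "N" in kmer:
                continue
            for p in seeds_r.get(kmer, ()):
                # extend: s[i..i+L) == r[p..p+L)
                i0, p0 = i, p
                while i0 > 0 and p0 > 0 and match(s[i0 - 1], r[p0 - 1]):
                    i0 -= 1
                    p0 -= 1
                L = min_arm + (i - i0)
                while i0 + L < n and p0 + L < n and match(s[i0 + L], r[p0 + L]):
                    L += 1
                j_full = n - p0 - L  # start of arm2 in forward coords
                key = ("inverted", min(i0, j_full), max(i0, j_full), L)
                if key in found:
                    continue
                found.add(key)
                a, b = (i0, j_full) if i0 <= j_full else (j_full, i0)
                # trim so arms do not overlap: keep outer ends of the match
                La = min(L, (b + L - a) // 2)
                if La < min_arm:
                    continue
                arm1 = (a, a + La)
                arm2 = (b + L - La, b + L)
                spacer = arm2[0] - arm1[1]
                if spacer < 0 or spacer > max_spacer:
                    continue
                out.append(RepeatInstance(kind="inverted", seq=seq.id,
                                          arm1=arm1, arm2=arm2))

    # drop duplicates after trimming and sort deterministically
    uniq = {(rep.kind, rep.arm1, rep.arm2): rep for rep in out}
    return sorted(uniq.values(), key=lambda x: (x.arm1, x.arm2, x.kind))


def repeats_to_instances(seq: Sequence,
                         repeats: Iterable[RepeatInstance]) -> list[FeatureInstance]:
    """Repeats as located feature occurrences, typed by kind and GC class.

    Each repeat becomes one instance spanning both arms, with feature id
    ``{kind}_repeat_{gc_class}`` and the arm length as score.
    """
    out = []
    for rep in repeats:
        gc_class = classify_arm_gc(seq.residues[rep.arm1[0]:rep.arm1[1]])
        out.append(FeatureInstance(
            seq=seq.id, start=rep.arm1[0], end=rep.arm2[1],
            feature=f"{rep.kind}_repeat_{gc_class}", strand="+",
            score=float(rep.arm_len)))
    return out


def track_score_dispersion(instances: Iterable[FeatureInstance]) -> Optional[float]:
    """Sample SD of imported track scores (e.g. SIDD values), or None.

    Duplex-destabilization profiles discriminate functional promoters less
    by presence than by how *tight* their value range is, so the dispersion
    is reported descriptively alongside coverage whenever an imported track
    carries scores.  No destabilization physics is computed here.
    """
    scores = np.array([i.score for i in instances if i.score is not None])
    if scores.size < 2:
        return None
    return float(scores.std(ddof=1))


def screen_feature(instances: Iterable[FeatureInstance], pos: SequenceSet,
                   neg: SequenceSet, bounds=None):
    """Specificity screen for detector/imported features.

    Applies the same boundary conditions used for PWM thresholds
    (C+ >= 0.75, C- <= 0.5, F+/F- >= 2 by default) to a fixed instance
    list.  Returns ``(accepted, CoverageStats)``; thresholds are
    configurable because some useful features sit near the bounds (a
    poly-A track with C- around 0.47 still passes the default screen).
    """
    from .core import CoverageStats, feature_coverage, feature_frequency
    from .pwm import ScreeningBounds

    bounds = bounds or ScreeningBounds()
    insts = list(instances)
    on_pos = [i for i in insts if i.seq in pos]
    on_neg = [i for i in insts if i.seq in neg]
    stats = CoverageStats(
        c_pos=feature_coverage(on_pos, pos),
        c_neg=feature_coverage(on_neg, neg),
        f_pos=feature_frequency(on_pos, pos),
        f_neg=feature_frequency(on_neg, neg),
    )
    if stats.f_neg > 0:
        f_ratio = stats.f_pos / stats.f_neg
    else:
        f_ratio = float("inf") if stats.f_pos > 0 else 0.0
    accepted = (stats.c_pos >= bounds.c_pos_min
                and stats.c_neg <= bounds.c_neg_max
                and f_ratio >= bounds.f_ratio_min)
    return accepted, stats


def import_track(path: str, feature_id: Optional[str] = None,
                 known_ids: Optional[set[str]] = None) -> list[FeatureInstance]:
    """Load an external feature track (TSS, SIDD, de novo motif hits, ...).

    Format is chosen by extension: ``.bed`` is 0-based half-open, ``.gff``/
    ``.gff3`` 1-based closed.  ``feature_id`` overrides the per-record type
    (GFF3 ``source`` column / BED name column).  Records on sequence ids not
    in ``known_ids`` are skipped with a warning.
    """
    from .io import read_bed, read_gff3  # local import to avoid cycle

    lower = path.lower()
    if lower.endswith(".bed"):
        instances = read_bed(path, feature_id=feature_id)
    elif lower.endswith((".gff", ".gff3")):
        instances = read_gff3(path, feature_id=feature_id)
    else:
        raise InputError(f"unrecognized track format: {path!r} (use .bed/.gff3)")
    if known_ids is not None:
        kept = []
        for inst in instances:
            if inst.seq not in known_ids:
                logger.warning("skipping %s record on unknown sequence %r",
                               inst.feature, inst.seq)
                continue
            kept.append(inst)
        instances = kept
    return instances
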