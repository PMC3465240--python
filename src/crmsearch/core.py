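"""Core objects of the module-discovery model.

A *feature* is anything that places located occurrences on promoter
sequences: a PWM above its threshold, a compositional region, a poly-A
tract, a repeat, or an imported prediction track.  A *module* is a set of
feature types; on each sequence that carries at least one occurrence of
every member the module has a *support sequence* — the shortest interval
containing one full occurrence per member.  Coverage counts the fraction
of sequences of a set on which a feature (or a whole module) occurs, and
module overlap is the summed base-pair intersection of two modules'
support intervals across a sequence set.

All coordinates are 0-based, half-open.  GFF3 export (see :mod:`.io`)
converts to the 1-based closed convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence as TypingSequence

__all__ = [
    "Sequence",
    "SequenceSet",
    "FeatureType",
    "FeatureInstance",
    "CoverageStats",
    "Support",
    "Module",
    "InstanceIndex",
    "feature_coverage",
    "feature_frequency",
    "module_coverage",
    "min_support_interval",
    "module_overlap",
]

VALID_BASES = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return s.translate(COMPLEMENT)[::-1]


class InputError(ValueError):
    """Raised for invalid user-supplied data (sequences, instances, config)."""


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over the alphabet {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_BASES
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains invalid residues: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


class SequenceSet:
    """An ordered, id-unique collection of sequences (a promoter set).

    ``label`` is conventionally one of ``positive``/``negative``/``random``
    but any tag is allowed.
    """

    def __init__(self, label: str, sequences: Iterable[Sequence]):
        self.label = label
        self.sequences: list[Sequence] = list(sequences)
        self._by_id: dict[str, Sequence] = {}
        for seq in self.sequences:
            if seq.id in self._by_id:
                raise InputError(f"duplicate sequence id {seq.id!r} in set {label!r}")
            self._by_id[seq.id] = seq
        if not self.sequences:
            raise InputError(f"sequence set {label!r} is empty")

    @property
    def N(self) -> int:
        return len(self.sequences)

    @property
    def total_bp(self) -> int:
        return sum(s.length for s in self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def __getitem__(self, seq_id: str) -> Sequence:
        return self._by_id[seq_id]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SequenceSet({self.label!r}, N={self.N}, total_bp={self.total_bp})"


@dataclass(frozen=True)
class FeatureType:
    """A feature generator identity: PWM, built-in detector, or imported track."""

    id: str
    source: str = "imported"  # pwm | detector | imported
    params: tuple = ()


@dataclass(frozen=True, order=True)
class FeatureInstance:
    """One located occurrence of a feature type on a sequence.

    ``start``/``end`` are 0-based half-open on the forward strand; hits on
    the reverse strand are reported in forward coordinates with strand '-'.
    """

    seq: str
    start: int
    end: int
    feature: str
    strand: str = "+"
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid interval [{self.start},{self.end}) for {self.feature!r} "
                f"on {self.seq!r}"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageStats:
    """Coverage fractions and per-bp frequencies of a feature or module."""

    c_pos: float = 0.0
    c_neg: float = 0.0
    c_rand: Optional[float] = None
    f_pos: float = 0.0
    f_neg: float = 0.0


@dataclass(frozen=True)
class Support:
    """Minimal interval on one sequence containing a full module placement."""

    seq: str
    start: int
    end: int
    placement: tuple[FeatureInstance, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Module:
    """A set of feature types with per-sequence placements and statistics."""

    features: frozenset[str]
    supports: dict[str, Support] = field(default_factory=dict)
    stats: CoverageStats = field(default_factory=CoverageStats)
    fitness: float = 0.0
    pvalue: Optional[float] = None

    @property
    def k(self) -> int:
        return len(self.features)

    def sorted_features(self) -> tuple[str, ...]:
        return tuple(sorted(self.features))


class InstanceIndex:
    """Instances grouped by feature type and sequence, start-sorted.

    The per-sequence lists are the working representation for coverage and
    support-interval computations.
    """

    def __init__(self, instances: Iterable[FeatureInstance] = (),
                 sequence_set: Optional[SequenceSet] = None):
        self._by_feature: dict[str, dict[str, list[FeatureInstance]]] = {}
        self._set = sequence_set
        for inst in instances:
            self.add(inst)

    def add(self, inst: FeatureInstance) -> None:
        if self._set is not None:
            if inst.seq not in self._set:
                raise InputError(
                    f"instance references unknown sequence id {inst.seq!r}"
                )
            if inst.end > self._set[inst.seq].length:
                raise InputError(
                    f"instance [{inst.start},{inst.end}) exceeds length of "
                    f"sequence {inst.seq!r}"
                )
        self._by_feature.setdefault(inst.feature, {}).setdefault(inst.seq, []).append(inst)
        self._dirty = True

    def _sorted(self, feature: str, seq: str) -> list[FeatureInstance]:
        lst = self._by_feature.get(feature, {}).get(seq, [])
        lst.sort(key=lambda i: (i.start, i.end))
        return lst

    @property
    def features(self) -> list[str]:
        return sorted(self._by_feature)

    def instances_on(self, feature: str, seq: str) -> list[FeatureInstance]:
        return self._sorted(feature, seq)

    def all_instances(self, feature: Optional[str] = None) -> list[FeatureInstance]:
        feats = [feature] if feature is not None else self.features
        out: list[FeatureInstance] = []
        for f in feats:
            for seq in sorted(self._by_feature.get(f, {})):
                out.extend(self._sorted(f, seq))
        return out

    def seqs_with(self, feature: str) -> set[str]:
        return {s for s, lst in self._by_feature.get(feature, {}).items() if lst}

    def count(self, feature: Optional[str] = None) -> int:
        feats = [feature] if feature is not None else self.features
        return sum(
            len(lst)
            for f in feats
            for lst in self._by_feature.get(f, {}).values()
        )


def _check_instances(instances: Iterable[FeatureInstance], sset: SequenceSet) -> list[FeatureInstance]:
    out = []
    for inst in instances:
        if inst.seq not in sset:
            raise InputError(f"instance references unknown sequence id {inst.seq!r}")
        out.append(inst)
    return out


def feature_coverage(instances: Iterable[FeatureInstance], sset: SequenceSet) -> float:
    """Fraction of sequences in ``sset`` carrying at least one instance.

    The formal definition counts the maximal number of sequences each
    contributing a distinct occurrence; for a single feature this equals the
    plain count of distinct covered sequences divided by N.
    """
    insts = _check_instances(instances, sset)
    covered = {i.seq for i in insts}
    return len(covered) / sset.N


def feature_frequency(instances: Iterable[FeatureInstance], sset: SequenceSet) -> float:
    """Instance count per base pair of the set: F = |phi(S)| / sum |s_i|."""
    insts = _check_instances(instances, sset)
    return len(insts) / sset.total_bp


def module_coverage(features: Iterable[str], sset: SequenceSet,
                    index: InstanceIndex) -> float:
    """Fraction of sequences carrying >= 1 instance of *every* member feature."""
    feats = list(features)
    if not feats:
        raise InputError("module must contain at least one feature")
    covered_sets = [index.seqs_with(f) & set(sset.ids) for f in feats]
    common = set.intersection(*covered_sets)
    return len(common) / sset.N


def min_support_interval(features: Iterable[str], seq_id: str,
                         index: InstanceIndex) -> Optional[Support]:
    """Shortest interval on ``seq_id`` containing one full instance per member.

    Smallest-range-over-k-lists sweep: anchor the candidate left edge at every
    instance start; for each member pick the earliest-ending instance starting
    at or after the anchor.  Ties (equal length) resolve to the smallest start,
    so the leftmost minimal support is canonical.  Returns None if any member
    has no instance on the sequence.
    """
    feats = sorted(set(features))
    if not feats:
        raise InputError("module must contain at least one feature")
    lists = [index.instances_on(f, seq_id) for f in feats]
    if any(not lst for lst in lists):
        return None

    anchors = sorted({inst.start for lst in lists for inst in lst})
    best: Optional[tuple[int, int, tuple[FeatureInstance, ...]]] = None
    for a in anchors:
        picked: list[FeatureInstance] = []
        ok = True
        for lst in lists:
            # earliest-ending instance with start >= a
            cand = None
            for inst in lst:
                if inst.start >= a and (cand is None or inst.end < cand.end):
                    cand = inst
            if cand is None:
                ok = False
                break
            picked.append(cand)
        if not ok:
            continue
        start = min(i.start for i in picked)
        end = max(i.end for i in picked)
        key = (end - start, start)
        if best is None or key < (best[1] - best[0], best[0]):
            best = (start, end, tuple(picked))
    if best is None:
        return None
    return Support(seq=seq_id, start=best[0], end=best[1], placement=best[2])


def module_supports(features: Iterable[str], sset: SequenceSet,
                    index: InstanceIndex) -> dict[str, Support]:
    """Minimal support interval per covered sequence of the set."""
    feats = sorted(set(features))
    out: dict[str, Support] = {}
    for seq in sset:
        sup = min_support_interval(feats, seq.id, index)
        if sup is not None:
            out[seq.id] = sup
    return out


def module_overlap(supports1: Mapping[str, Support],
                   supports2: Mapping[str, Support]) -> int:
    """Summed bp intersection of two modules' support intervals.

    Supports on different sequences never overlap; the result is symmetric
    and non-negative.
    """
    total = 0
    for seq_id in supports1.keys() & supports2.keys():
        a, b = supports1[seq_id], supports2[seq_id]
        total += max(0, min(a.end, b.end) - max(a.start, b.start))
    return total
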