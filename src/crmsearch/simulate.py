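"""Synthetic promoter sets with planted regulatory modules.

Emulates the statistical structure of a promoter-trap library: fragment
lengths are drawn from a normal distribution (defaults 640 +/- 232 bp,
truncated at 100 bp), bases are i.i.d. at a set-specific GC content
(positives 0.488, negatives 0.532), and a *planted module* — several motif
types co-located within a short span — is inserted into a configurable
fraction of the positive sequences.  Planted motif occurrences are sampled
from their PFMs (not the consensus) so downstream threshold optimization is
non-trivial.

Two kinds of confounders make the benchmark honest:

* *decoy* feature types are embedded uniformly in every set (by default 2
  occurrences per sequence per type), so undiscriminating combinations are
  abundant;
* a fraction of the *negative* sequences carries a partial module — a
  proper subset of the planted motifs co-located within the same span, but
  never the complete set.  This mirrors inactive promoter fragments that
  lack one essential module component and makes every proper subset of the
  planted set measurably less specific than the full module.

Ground truth (every planted and decoy occurrence) is emitted as feature
instances for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import (FeatureInstance, InputError, Sequence, SequenceSet)
from .pwm import BASES, Pfm

__all__ = [
    "PlantedMotif",
    "DecoySpec",
    "FixtureConfig",
    "Fixture",
    "generate_sets",
    "fragment_genome",
    "random_high_ic_pfm",
    "benchmark_config",
]


@dataclass(frozen=True)
class PlantedMotif:
    """One member motif of the planted module.

    Occurrences are sampled per column from the PFM, *conditioned* on a
    minimum normalized PWM score (``min_score``): planted words vary — so
    downstream threshold optimization is non-trivial — but are always
    plausible binding sites, not the arbitrarily degenerate words that
    unconditional column sampling occasionally emits and that no real
    site collection would contain.
    """

    name: str
    pfm: Optional[Pfm] = None   # occurrences sampled per column from the PFM
    literal: Optional[str] = None  # or a fixed word
    min_score: float = 0.85     # normalized score floor for sampled sites

    def __post_init__(self) -> None:
        if (self.pfm is None) == (self.literal is None):
            raise InputError(f"motif {self.name!r}: give exactly one of pfm/literal")

    @property
    def length(self) -> int:
        return self.pfm.length if self.pfm is not None else len(self.literal)

    def _pwm(self):
        from .pwm import build_pwm

        return build_pwm(self.pfm)

    def sample(self, rng: np.random.Generator) -> str:
        if self.literal is not None:
            return self.literal
        probs = self.pfm.counts / self.pfm.counts.sum(axis=0, keepdims=True)
        pwm = self._pwm()
        consensus = "".join(BASES[i] for i in pwm.weights.argmax(axis=0))
        for _ in range(200):
            word = "".join(
                BASES[rng.choice(4, p=probs[:, j])] for j in range(self.pfm.length)
            )
            raw = sum(pwm.weights[BASES.index(b), j] for j, b in enumerate(word))
            if pwm.normalize(np.array([raw]))[0] >= self.min_score:
                return word
        return consensus


@dataclass(frozen=True)
class DecoySpec:
    """A decoy feature type: a literal word embedded in every set."""

    name: str
    word: str
    per_seq: int = 2  # occurrences embedded per sequence


@dataclass
class FixtureConfig:
    """Study conditions of the planted-module benchmark."""

    n_pos: int = 13
    n_neg: int = 115
    len_mean: float = 640.0
    len_sd: float = 232.0
    min_len: int = 100
    gc_pos: float = 0.488
    gc_neg: float = 0.532
    planted: list[PlantedMotif] = field(default_factory=list)
    span: int = 150            # planted module must fit in this window
    planted_fraction: float = 0.8
    partial_neg_fraction: float = 0.3  # negatives carrying an incomplete module
    decoys: list[DecoySpec] = field(default_factory=list)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise InputError("set sizes must be >= 1")
        if not (0 < self.gc_pos < 1 and 0 < self.gc_neg < 1):
            raise InputError("GC contents must lie in (0,1)")
        if not (0.0 <= self.planted_fraction <= 1.0):
            raise InputError("planted_fraction must lie in [0,1]")
        if not (0.0 <= self.partial_neg_fraction <= 1.0):
            raise InputError("partial_neg_fraction must lie in [0,1]")
        total = sum(m.length for m in self.planted)
        if self.planted and self.span < total:
            raise InputError(
                f"span {self.span} is shorter than the planted motifs ({total} bp)")


@dataclass
class Fixture:
    """Generated sets plus ground-truth instances and the planted PFMs."""

    pos: SequenceSet
    neg: SequenceSet
    truth: list[FeatureInstance]
    config: FixtureConfig

    @property
    def planted_feature_ids(self) -> frozenset[str]:
        return frozenset(m.name for m in self.config.planted)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _draw_length(rng: np.random.Generator, mean: float, sd: float,
                 floor: int) -> int:
    while True:
        val = int(round(rng.normal(mean, sd)))
        if val >= floor:
            return val


def _embed(arr: np.ndarray, pos: int, word: str) -> None:
    idx = np.array([BASES.index(b) for b in word])
    arr[pos:pos + len(word)] = idx


def _decode(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


def generate_sets(config: FixtureConfig,
                  rng: Optional[np.random.Generator] = None) -> Fixture:
    """Generate positive and negative sets with planted ground truth."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    motifs = list(config.planted)
    span = config.span
    floor = max(config.min_len, span + 10 if motifs else config.min_len)
    truth: list[FeatureInstance] = []

    def place_module(arr: np.ndarray, seq_id: str,
                     members: list[PlantedMotif]) -> None:
        """Insert the given motifs, in order, within one span-length window."""
        start = int(rng.integers(0, len(arr) - span + 1))
        # one slot per member keeps placements ordered and non-overlapping
        slot = span // len(members)
        for k, motif in enumerate(members):
            lo = start + k * slot
            off = int(rng.integers(0, slot - motif.length + 1))
            word = motif.sample(rng)
            _embed(arr, lo + off, word)
            truth.append(FeatureInstance(seq=seq_id, start=lo + off,
                                         end=lo + off + motif.length,
                                         feature=motif.name, strand="+"))

    def scatter_decoys(arr: np.ndarray, seq_id: str) -> None:
        for decoy in config.decoys:
            for _ in range(decoy.per_seq):
                pos = int(rng.integers(0, len(arr) - len(decoy.word) + 1))
                _embed(arr, pos, decoy.word)
                truth.append(FeatureInstance(seq=seq_id, start=pos,
                                             end=pos + len(decoy.word),
                                             feature=decoy.name, strand="+"))

    def build_set(label: str, n: int, gc: float,
                  full_idx: set[int], partial_idx: set[int]) -> SequenceSet:
        seqs = []
        for i in range(n):
            seq_id = f"{label}_{i + 1:03d}"
            length = _draw_length(rng, config.len_mean, config.len_sd, floor)
            arr = _random_bases(rng, length, gc)
            scatter_decoys(arr, seq_id)
            if i in full_idx and motifs:
                place_module(arr, seq_id, motifs)
            elif i in partial_idx and len(motifs) >= 2:
                # a proper subset lacking one member, co-located like the
                # real module
                drop = int(rng.integers(0, len(motifs)))
                members = [m for k, m in enumerate(motifs) if k != drop]
                place_module(arr, seq_id, members)
            seqs.append(Sequence(id=seq_id, residues=_decode(arr)))
        return SequenceSet(label, seqs)

    n_carry = int(round(config.planted_fraction * config.n_pos))
    full_pos = set(rng.choice(config.n_pos, size=n_carry, replace=False).tolist()) \
        if n_carry else set()
    n_partial = int(round(config.partial_neg_fraction * config.n_neg))
    partial_neg = set(rng.choice(config.n_neg, size=n_partial, replace=False).tolist()) \
        if n_partial else set()

    pos = build_set("pos", config.n_pos, config.gc_pos, full_pos, set())
    neg = build_set("neg", config.n_neg, config.gc_neg, set(), partial_neg)
    return Fixture(pos=pos, neg=neg, truth=truth, config=config)


def fragment_genome(genome: str, len_mean: float = 640.0, len_sd: float = 232.0,
                    rng_seed: int = 0, min_keep: int = 0,
                    label: str = "random") -> SequenceSet:
    """Split a genome into successive fragments with normal-distributed lengths.

    Fragments tile the genome exactly (their concatenation reconstructs it);
    with ``min_keep`` > 0 a trailing fragment shorter than that many bp is
    dropped, matching the random-set construction convention where only
    promoter-sized fragments are retained.
    """
    if not genome:
        raise InputError("empty genome")
    rng = np.random.default_rng(rng_seed)
    frags: list[Sequence] = []
    pos = 0
    i = 1
    n = len(genome)
    while pos < n:
        if len_sd > 0:
            length = _draw_length(rng, len_mean, len_sd, 1)
        else:
            length = max(1, int(round(len_mean)))
        frag = genome[pos:pos + length]
        pos += length
        if pos >= n and len(frag) < min_keep:
            break
        frags.append(Sequence(id=f"{label}_{i:05d}", residues=frag))
        i += 1
    if not frags:
        raise InputError("no fragments produced (genome shorter than min_keep)")
    return SequenceSet(label, frags)


def random_high_ic_pfm(name: str, length: int, rng: np.random.Generator,
                       n_sites: int = 20, dominance: float = 0.85) -> Pfm:
    """A random well-conserved PFM: one dominant base per column.

    ``dominance`` is the expected fraction of sites carrying the preferred
    base; the remainder is spread over the other three bases.
    """
    counts = np.zeros((4, length))
    for j in range(length):
        top = int(rng.integers(0, 4))
        rest = n_sites * (1 - dominance) / 3
        counts[:, j] = rest
        counts[top, j] = n_sites * dominance
    return Pfm(id=name, counts=counts)


def benchmark_config(rng_seed: int = 0, n_planted: int = 3, n_decoys: int = 20,
                     motif_len: int = 14) -> FixtureConfig:
    """The standard planted-module recovery benchmark.

    Thirteen positives and 115 negatives (promoter-trap scale); three
    well-conserved 14-bp motif types planted within a 150 bp span in 80% of
    positives; 20 decoy types embedded twice per sequence in every set; 30%
    of negatives carry a partial (incomplete) module.  The 14 bp length is
    TFBS-typical and keeps background hits at discriminative thresholds
    rare on promoter-sized fragments.
    """
    rng = np.random.default_rng(rng_seed)
    planted = [
        PlantedMotif(name=f"planted_{k + 1}",
                     pfm=random_high_ic_pfm(f"planted_{k + 1}", motif_len, rng))
        for k in range(n_planted)
    ]
    decoys = []
    for k in range(n_decoys):
        word = "".join(BASES[int(b)] for b in rng.integers(0, 4, size=8))
        decoys.append(DecoySpec(name=f"decoy_{k + 1:02d}", word=word))
    return FixtureConfig(planted=planted, decoys=decoys, rng_seed=rng_seed)
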