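"""File formats and run configuration.

FASTA reading goes through Biopython; writing is deterministic (60-column
wrapping) so identical runs produce byte-identical artifacts.  Feature
instances round-trip through GFF3 (feature type in the ``source`` column,
1-based closed coordinates) and BED (0-based half-open).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml
from Bio import SeqIO

from .core import (FeatureInstance, InputError, Sequence, SequenceSet)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "RunConfig",
    "write_manifest",
]


def read_fasta(path: str, label: str = "custom") -> SequenceSet:
    """Load a FASTA file; ids are the first header token, residues upper-cased."""
    path = str(path)
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise InputError(f"no sequences in {path!r}")
    seqs = [Sequence(id=r.id, residues=str(r.seq).upper()) for r in records]
    return SequenceSet(label, seqs)


def write_fasta(sset: SequenceSet, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sset:
            fh.write(f">{seq.id}\n")
            for i in range(0, seq.length, width):
                fh.write(seq.residues[i:i + width] + "\n")


def write_gff3(instances: Iterable[FeatureInstance], path: str,
               feature_kind: str = "region") -> None:
    """Instances as GFF3: source column = feature type id, 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for inst in instances:
            score = "." if inst.score is None else f"{inst.score:.6g}"
            fh.write("\t".join([
                inst.seq, inst.feature, feature_kind,
                str(inst.start + 1), str(inst.end), score, inst.strand,
                ".", f"ID={inst.feature}:{inst.seq}:{inst.start}",
            ]) + "\n")


def read_gff3(path: str, feature_id: Optional[str] = None) -> list[FeatureInstance]:
    out: list[FeatureInstance] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise InputError(f"{path}:{ln}: malformed GFF3 line")
            seq, source, _, start, end, score, strand = fields[:7]
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise InputError(f"{path}:{ln}: bad coordinates") from exc
            out.append(FeatureInstance(
                seq=seq, start=start_i, end=end_i,
                feature=feature_id or source,
                strand=strand if strand in "+-" else "+",
                score=None if score in (".", "") else float(score)))
    return out


def write_bed(instances: Iterable[FeatureInstance], path: str) -> None:
    with open(path, "w") as fh:
        for inst in instances:
            score = "0" if inst.score is None else f"{inst.score:.6g}"
            fh.write("\t".join([
                inst.seq, str(inst.start), str(inst.end), inst.feature,
                score, inst.strand]) + "\n")


def read_bed(path: str, feature_id: Optional[str] = None) -> list[FeatureInstance]:
    out: list[FeatureInstance] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{ln}: malformed BED line")
            seq, start, end = fields[:3]
            name = fields[3] if len(fields) > 3 else None
            score = fields[4] if len(fields) > 4 else None
            strand = fields[5] if len(fields) > 5 else "+"
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise InputError(f"{path}:{ln}: bad coordinates") from exc
            out.append(FeatureInstance(
                seq=seq, start=start_i, end=end_i,
                feature=feature_id or name or "imported",
                strand=strand if strand in "+-" else "+",
                score=float(score) if score not in (None, ".", "") else None))
    return out


@dataclass
class RunConfig:
    """Run configuration loaded from YAML.

    Screening bounds default to the standard boundary conditions
    (C+ >= 0.75, C- <= 0.5, F+/F- >= 2); ``strict`` tightens the negative
    bound to 0.25.
    """

    positive_fasta: str = ""
    negative_fasta: str = ""
    random_fasta: Optional[str] = None
    pfm_files: list[str] = field(default_factory=list)
    track_files: list[str] = field(default_factory=list)
    c_pos_min: float = 0.75
    c_neg_max: float = 0.5
    f_ratio_min: float = 2.0
    strict: bool = False
    relax_delta: float = 0.05
    output_dir: str = "crmsearch_out"
    log_level: str = "INFO"
    seed: int = 0
    ga: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strict:
            self.c_neg_max = min(self.c_neg_max, 0.25)
        for name in ("c_pos_min", "c_neg_max"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise InputError(f"{name} must lie in [0,1]")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for p in ([cfg.positive_fasta, cfg.negative_fasta, cfg.random_fasta]
                  + cfg.pfm_files + cfg.track_files):
            if p and not Path(p).exists():
                raise InputError(f"configured path does not exist: {p!r}")
        return cfg


def write_manifest(path: str, config: dict, seed: int) -> None:
    """Record everything needed for an exact re-run."""
    from . import __version__

    manifest = {"version": __version__, "seed": seed, "config": config}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
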