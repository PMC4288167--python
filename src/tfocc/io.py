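"""Readers and writers for the genomic text formats the tool touches.

Internal coordinates are 0-based half-open everywhere; BED shares that
convention, wiggle fixedStep is 1-based and converted at the boundary.
bedGraph is the primary track output (plain text, diffable).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("tfocc")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph_or_wig",
    "write_bedgraph",
    "write_wig",
    "read_pwm",
    "write_pwm",
    "Config",
    "load_config",
    "save_config",
]


# ---------------------------------------------------------------- sequences

def read_fasta(path) -> dict[str, str]:
    """Read a (multi-)FASTA into {name: uppercase sequence}."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- intervals

def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read BED3+ into {chrom: [(start, end), ...]} (0-based half-open)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid interval ({start}, {end})")
            out.setdefault(fields[0], []).append((start, end))
    return out


def write_bed(intervals: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in intervals.items():
            for start, end in ivs:
                fh.write(f"{chrom}\t{start}\t{end}\n")


# ------------------------------------------------------------------- tracks

def read_bedgraph_or_wig(path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Read a bedGraph or fixedStep wiggle into per-base arrays.

    ``lengths`` gives the expected chromosome lengths (usually from the
    FASTA); coordinates beyond them raise rather than silently truncating.
    Unspecified bases are 0.
    """
    tracks = {c: np.zeros(n) for c, n in lengths.items()}
    with open(path) as fh:
        first = fh.read(2048)
    is_wig = "fixedStep" in first or "variableStep" in first
    return _read_wig(path, tracks) if is_wig else _read_bedgraph(path, tracks)


def _check_chrom(chrom: str, tracks: dict, path, lineno: int) -> None:
    if chrom not in tracks:
        raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")


def _read_bedgraph(path, tracks: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: bedGraph line needs 4 fields")
            chrom = fields[0]
            _check_chrom(chrom, tracks, path, lineno)
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph fields") from exc
            if start < 0 or end > len(tracks[chrom]):
                raise ValueError(
                    f"{path}:{lineno}: interval ({start}, {end}) exceeds "
                    f"{chrom} length {len(tracks[chrom])}"
                )
            tracks[chrom][start:end] = value
    return tracks


def _read_wig(path, tracks: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    chrom, pos, step, span = None, 0, 1, 1
    mode = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                mode = line.split()[0]
                kv = dict(item.split("=") for item in line.split()[1:])
                chrom = kv.get("chrom")
                _check_chrom(chrom, tracks, path, lineno)
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                # wig is 1-based: start=1 maps to internal position 0
                pos = int(kv.get("start", 1)) - 1
                continue
            if chrom is None:
                raise ValueError(f"{path}:{lineno}: data before a wig declaration line")
            fields = line.split()
            if mode == "variableStep":
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: variableStep needs 'pos value'")
                pos = int(fields[0]) - 1
                value = float(fields[1])
            else:
                value = float(fields[0])
            if pos < 0 or pos + span > len(tracks[chrom]):
                raise ValueError(
                    f"{path}:{lineno}: position {pos + 1} (+span {span}) exceeds "
                    f"{chrom} length {len(tracks[chrom])}"
                )
            tracks[chrom][pos : pos + span] = value
            if mode == "fixedStep":
                pos += step
    return tracks


def write_bedgraph(tracks: dict[str, np.ndarray], path, precision: int = 6) -> None:
    """Write per-base tracks as run-length-encoded bedGraph (zeros skipped)."""
    with open(path, "w") as fh:
        for chrom, values in tracks.items():
            values = np.asarray(values, dtype=float)
            if len(values) == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v == 0.0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.{precision}g}\n")


def write_wig(tracks: dict[str, np.ndarray], path, step: int = 1) -> None:
    """fixedStep wiggle output (1-based starts)."""
    with open(path, "w") as fh:
        for chrom, values in tracks.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step={step}\n")
            for v in np.asarray(values, dtype=float)[::step]:
                fh.write(f"{v:.6g}\n")


# --------------------------------------------------------------------- PWMs

_BASES = "ACGT"


def read_pwm(path) -> tuple[np.ndarray, str]:
    """Read a JASPAR-style or plain 4-row count matrix.

    Accepts an optional '>name' header, optional leading base letters and
    JASPAR brackets ('A [ 1 2 3 ]'); rows must come in A, C, G, T order when
    unlabelled.  Returns (4 x m count matrix, name).
    """
    name = Path(str(path)).stem
    rows: dict[str, list[float]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] or name
                continue
            fields = line.replace("[", " ").replace("]", " ").split()
            base = None
            if fields and fields[0].upper() in _BASES and not _is_number(fields[0]):
                base = fields[0].upper()
                fields = fields[1:]
            try:
                values = [float(x) for x in fields]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed matrix row") from exc
            if not values:
                raise ValueError(f"{path}:{lineno}: empty matrix row")
            key = base if base is not None else _BASES[len(order)] if len(order) < 4 else None
            if key is None or key in rows:
                raise ValueError(f"{path}:{lineno}: unexpected extra matrix row")
            rows[key] = values
            order.append(key)
    if sorted(rows) != list(_BASES):
        raise ValueError(f"{path}: expected 4 rows (A, C, G, T), got {sorted(rows)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path}: matrix rows have unequal lengths")
    return np.array([rows[b] for b in _BASES]), name


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_pwm(counts: np.ndarray, path, name: str = "pwm") -> None:
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for b, row in zip(_BASES, counts):
            fh.write(f"{b} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


# ------------------------------------------------------------------- config

@dataclass
class Config:
    """All tunables with their defaults; round-trips losslessly through YAML."""

    pseudo_count: float = 1.0
    ploidy: int = 2
    threshold_fraction: float = 0.7
    threshold_mode: str = "absolute_range"
    fragment_mean: float = 200.0
    fragment_sd: float = 200.0
    smooth_window: int = 250
    n_grid: list = field(
        default_factory=lambda: [1, 10, 100, 500, 1000, 2000, 5000,
                                 10_000, 20_000, 50_000, 100_000, 1_000_000]
    )
    lambda_grid: list = field(default_factory=lambda: [0.25 * k for k in range(1, 21)])
    band_fraction: float = 0.12
    region_bp: int = 20_000
    background_mult: float = 1.0
    normalization: str = "nmse"
    loci_dilate: int = 500
    loci_background_mult: float = 1.0
    accessibility_scale: float = 2.0
    accessibility_midpoint: float | None = None
    log_level: str = "INFO"
    seed: int = 42

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> Config:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    return Config(**data)


def save_config(config: Config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
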