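"""Read counting, coverage estimation, quality filtering and coverage-capped
random subsampling.

A fosmid clone yields far more sequence than needed: the pipeline estimates
coverage as total sequenced bases over the nominal insert length (40 kb by
default) and randomly thins each read set down to a target coverage (300X by
default) before assembly.  Pairs are always kept or dropped together.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_EXPECTED_LEN = 40_000
DEFAULT_TARGET_COVERAGE = 300.0
DEFAULT_MIN_MEAN_Q = 20.0
DEFAULT_MAX_N_FRAC = 0.1
DEFAULT_MIN_LEN = 50

PHRED_OFFSET = 33


@dataclass
class Read:
    id: str
    seq: str
    qual: str

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    @property
    def mean_q(self) -> float:
        if not self.qual:
            return 0.0
        return sum(self.qual.encode("ascii")) / len(self.qual) - PHRED_OFFSET

    @property
    def n_frac(self) -> float:
        if not self.seq:
            return 0.0
        return self.seq.upper().count("N") / len(self.seq)


@dataclass
class ReadSet:
    """Single reads, or read pairs held as two parallel mate lists."""

    layout: str  # "single" | "paired"
    reads: list[Read] = field(default_factory=list)  # singles, or mate 1
    mates: list[Read] | None = None  # mate 2 for paired layout

    def __post_init__(self):
        if self.layout not in ("single", "paired"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.layout == "paired":
            if self.mates is None:
                raise ValueError("paired layout requires a mate list")
            if len(self.reads) != len(self.mates):
                raise ValueError(
                    f"unequal mate counts: {len(self.reads)} vs {len(self.mates)}"
                )
        elif self.mates is not None:
            raise ValueError("single layout must not carry mates")

    @property
    def n_reads(self) -> int:
        return len(self.reads) + (len(self.mates) if self.mates else 0)

    @property
    def n_units(self) -> int:
        """Sampling units: pairs count once."""
        return len(self.reads)

    def iter_all(self):
        if self.layout == "single":
            yield from self.reads
        else:
            for r1, r2 in zip(self.reads, self.mates):
                yield r1
                yield r2

    @property
    def total_bases(self) -> int:
        return sum(len(r.seq) for r in self.iter_all())


# ---------------------------------------------------------------------------
# FASTQ I/O (phred+33, transparent gzip)
# ---------------------------------------------------------------------------

def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> list[Read]:
    """Parse a FASTQ file into Read records; malformed records raise with
    their record index."""
    reads: list[Read] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 not in (0,) and lines and lines[-1] == "":
        lines = lines[:-1]
    for idx in range(0, len(lines), 4):
        rec = lines[idx : idx + 4]
        recno = idx // 4
        if len(rec) < 4 or not rec[0].startswith("@") or not rec[2].startswith("+"):
            raise ValueError(f"{path}: malformed FASTQ record #{recno}")
        rid = rec[0][1:].split()[0]
        try:
            reads.append(Read(rid, rec[1], rec[3]))
        except ValueError as exc:
            raise ValueError(f"{path}: record #{recno}: {exc}") from exc
    return reads


def write_fastq(reads, path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def write_readset(rs: ReadSet, out_prefix) -> list[Path]:
    """Write a ReadSet next to ``out_prefix`` as _single or _R1/_R2 files."""
    out_prefix = Path(out_prefix)
    if rs.layout == "single":
        p = out_prefix.parent / (out_prefix.name + "_single.fastq")
        write_fastq(rs.reads, p)
        return [p]
    p1 = out_prefix.parent / (out_prefix.name + "_R1.fastq")
    p2 = out_prefix.parent / (out_prefix.name + "_R2.fastq")
    write_fastq(rs.reads, p1)
    write_fastq(rs.mates, p2)
    return [p1, p2]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def estimate_coverage(reads: ReadSet, expected_len: int = DEFAULT_EXPECTED_LEN) -> float:
    """Total sequenced bases (both mates) over the expected insert length."""
    if expected_len <= 0:
        raise ValueError("expected_len must be positive")
    total = reads.total_bases
    if total == 0:
        warnings.warn("empty read set: coverage reported as 0.0", stacklevel=2)
        return 0.0
    return total / expected_len


def _passes(read: Read, min_mean_q: float, max_n_frac: float, min_len: int) -> bool:
    return (
        len(read.seq) >= min_len
        and read.n_frac <= max_n_frac
        and read.mean_q >= min_mean_q
    )


def filter_reads(
    reads: ReadSet,
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
    max_n_frac: float = DEFAULT_MAX_N_FRAC,
    min_len: int = DEFAULT_MIN_LEN,
) -> ReadSet:
    """Drop low-quality / N-rich / short reads; a pair is dropped if either
    mate fails, preserving pair integrity.  Input order is kept."""
    if min_mean_q < 0 or max_n_frac < 0 or min_len < 0:
        raise ValueError("filter thresholds must be non-negative")
    if reads.layout == "single":
        kept = [r for r in reads.reads if _passes(r, min_mean_q, max_n_frac, min_len)]
        return ReadSet("single", kept)
    r1s, r2s = [], []
    for r1, r2 in zip(reads.reads, reads.mates):
        if _passes(r1, min_mean_q, max_n_frac, min_len) and _passes(
            r2, min_mean_q, max_n_frac, min_len
        ):
            r1s.append(r1)
            r2s.append(r2)
    return ReadSet("paired", r1s, r2s)


def subsample_reads(
    reads: ReadSet,
    target_cov: float = DEFAULT_TARGET_COVERAGE,
    expected_len: int = DEFAULT_EXPECTED_LEN,
    seed: int = 0,
) -> ReadSet:
    """Uniform random subsampling (without replacement, pairs as units) down
    to the target coverage; a no-op when already at or below it.  The
    original relative order of the retained reads is preserved."""
    if target_cov <= 0:
        raise ValueError("target_cov must be positive")
    if estimate_coverage(reads, expected_len) <= target_cov:
        return reads
    target_bases = target_cov * expected_len
    if reads.layout == "single":
        unit_len = np.array([len(r.seq) for r in reads.reads])
    else:
        unit_len = np.array(
            [len(r1.seq) + len(r2.seq) for r1, r2 in zip(reads.reads, reads.mates)]
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unit_len))
    acc = np.cumsum(unit_len[order])
    n_keep = int(np.searchsorted(acc, target_bases) + 1)
    n_keep = min(n_keep, len(unit_len))
    sel = np.sort(order[:n_keep])
    if reads.layout == "single":
        return ReadSet("single", [reads.reads[i] for i in sel])
    return ReadSet(
        "paired",
        [reads.reads[i] for i in sel],
        [reads.mates[i] for i in sel],
    )
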