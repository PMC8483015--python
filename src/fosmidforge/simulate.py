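"""Fosmid construct and read simulation with known truth.

The simulator emulates the benchmark design used to validate the pipeline:
40 kb genomic chunks are cut from a source genome, the cloning vector is
inserted either at an extremity or at an internal position, and — because a
real fosmid clone is circular — an internal insertion duplicates the first
``overlap_len`` (default 500) bases of the linearised sequence at its end,
so a correct assembler can close the circle.  Reads are then drawn from the
linear reference: 150 bp singles, or 150 bp pairs from ~200 bp fragments,
with an optional per-base substitution error rate.

Every construct carries an explicit truth record (vector interval, mode,
overlap, genomic source) so that downstream assemblies and annotations can
be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._seq import decode, encode, random_dna, revcomp, validate_dna
from .readprep import Read, ReadSet

DEFAULT_CHUNK_LEN = 40_000
DEFAULT_OVERLAP_LEN = 500

MODES = ("extremity_left", "extremity_right", "internal")

_QUAL_CHAR = chr(33 + 37)  # constant Q37


@dataclass
class FosmidConstruct:
    """A simulated linear reference for one circular fosmid clone."""

    construct_id: str
    insert_seq: str
    vector_seq: str
    insertion_mode: str
    full_seq: str
    source: tuple[str, int, int]  # (genome_id, start, end) 0-based half-open
    insertion_pos: int | None = None  # internal mode only
    overlap_len: int = 0
    vector_interval: tuple[int, int] = (0, 0)  # vector span within full_seq

    def validate(self) -> None:
        li, lv, lf = len(self.insert_seq), len(self.vector_seq), len(self.full_seq)
        if self.insertion_mode == "internal":
            assert lf == li + lv + self.overlap_len
            if self.overlap_len:
                assert self.full_seq[-self.overlap_len :] == self.full_seq[: self.overlap_len]
        else:
            assert lf == li + lv
        s, e = self.vector_interval
        assert self.full_seq[s:e] == self.vector_seq

    def truth_record(self) -> dict:
        return {
            "construct_id": self.construct_id,
            "insertion_mode": self.insertion_mode,
            "insertion_pos": self.insertion_pos,
            "overlap_len": self.overlap_len,
            "vector_interval": list(self.vector_interval),
            "source": {
                "genome_id": self.source[0],
                "start": self.source[1],
                "end": self.source[2],
            },
            "insert_len": len(self.insert_seq),
            "vector_len": len(self.vector_seq),
            "full_len": len(self.full_seq),
        }


@dataclass
class ReadProfile:
    """Sequencing layout and error model for the simulator."""

    layout: str = "paired"
    read_len: int = 150
    fragment_mean: int = 200
    fragment_sd: int = 10
    coverage: float = 1000.0
    subst_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.layout not in ("single", "paired"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.read_len <= 0:
            raise ValueError("read_len must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.subst_error_rate < 1:
            raise ValueError("subst_error_rate must be in [0, 1)")
        if self.layout == "paired" and self.fragment_mean <= 0:
            raise ValueError("fragment_mean must be positive")


#: paired 150 bp reads from 200+-10 bp fragments (benchmark default)
PAIRED150 = ReadProfile(layout="paired", read_len=150, fragment_mean=200,
                        fragment_sd=10, coverage=1000.0)
#: 150 bp single reads at 500X (benchmark default)
SINGLE150 = ReadProfile(layout="single", read_len=150, coverage=500.0)


# ---------------------------------------------------------------------------
# Synthetic genomes
# ---------------------------------------------------------------------------

_SENSE_CODONS = None


def _sense_codons():
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        stops = {"TAA", "TAG", "TGA"}
        _SENSE_CODONS = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in stops
        ]
    return _SENSE_CODONS


def random_genome(
    genome_id: str,
    length: int,
    seed: int,
    gene_fraction: float = 0.7,
    mean_gene_aa: int = 280,
    sd_gene_aa: int = 90,
    min_gene_aa: int = 120,
) -> tuple[str, list[tuple[int, int, str]]]:
    """Random bacteria-like genome: stop-free genes (ATG .. stop) on either
    strand separated by random intergenic runs.

    Returns the sequence and the list of planted gene intervals
    (start, end, strand) — useful truth for annotation checks, though the
    pipeline itself never sees it.
    """
    rng = np.random.default_rng(seed)
    codons = _sense_codons()
    parts: list[str] = []
    genes: list[tuple[int, int, str]] = []
    pos = 0
    while pos < length:
        ig = int(rng.integers(60, 400))
        parts.append(random_dna(rng, ig))
        pos += ig
        if pos >= length or rng.random() > gene_fraction + 0.25:
            continue
        n_aa = max(min_gene_aa, int(rng.normal(mean_gene_aa, sd_gene_aa)))
        body = "".join(
            codons[i] for i in rng.integers(0, len(codons), size=n_aa - 1)
        )
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
        gene = "ATG" + body + stop
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            gene_seq = revcomp(gene)
        else:
            gene_seq = gene
        parts.append(gene_seq)
        genes.append((pos, pos + len(gene_seq), strand))
        pos += len(gene_seq)
    seq = "".join(parts)[:length]
    genes = [(s, e, st) for s, e, st in genes if e <= length]
    return seq, genes


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def extract_chunks(
    genome: tuple[str, str], n_chunks: int, chunk_len: int, seed: int
) -> list[tuple[str, tuple[str, int, int]]]:
    """Cut ``n_chunks`` substrings of exactly ``chunk_len`` bp at uniform
    random start positions (with replacement; chunks may overlap)."""
    genome_id, seq = genome
    seq = validate_dna(seq, f"genome {genome_id!r}")
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    if len(seq) < chunk_len:
        raise ValueError(
            f"genome {genome_id!r} is {len(seq)} bp, shorter than the "
            f"requested chunk length {chunk_len} bp"
        )
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(seq) - chunk_len + 1, size=n_chunks)
    return [
        (seq[s : s + chunk_len], (genome_id, int(s), int(s) + chunk_len))
        for s in starts
    ]


def build_construct(
    chunk: str,
    vector: str,
    mode: str = "random",
    overlap_len: int = DEFAULT_OVERLAP_LEN,
    seed: int = 0,
    insertion_pos: int | None = None,
    construct_id: str = "construct",
    source: tuple[str, int, int] = ("unknown", 0, 0),
) -> FosmidConstruct:
    """Insert the vector into a chunk at an extremity or internally.

    Internal mode appends a copy of the first ``overlap_len`` bases of the
    vector-carrying linear sequence to its end, mimicking the circular
    junction of a real clone.
    """
    if not chunk or not vector:
        raise ValueError("chunk and vector must be non-empty")
    if not 0 <= overlap_len <= len(chunk):
        raise ValueError(f"overlap_len {overlap_len} outside [0, {len(chunk)}]")
    rng = np.random.default_rng(seed)
    if mode == "random":
        mode = MODES[int(rng.integers(0, 3))]
    if mode not in MODES:
        raise ValueError(f"unknown insertion mode {mode!r}")
    if mode == "internal":
        p = insertion_pos
        if p is None:
            p = int(rng.integers(1, len(chunk)))
        if not 0 < p < len(chunk):
            raise ValueError(
                f"internal insertion position {p} must satisfy 0 < p < {len(chunk)}"
                " (boundary positions are extremity insertions)"
            )
        linear = chunk[:p] + vector + chunk[p:]
        if overlap_len > len(linear):
            raise ValueError("overlap_len exceeds linearised construct length")
        full = linear + linear[:overlap_len]
        vec_iv = (p, p + len(vector))
        ipos = p
        ov = overlap_len
    elif mode == "extremity_left":
        full = vector + chunk
        vec_iv = (0, len(vector))
        ipos, ov = None, 0
    else:  # extremity_right
        full = chunk + vector
        vec_iv = (len(chunk), len(chunk) + len(vector))
        ipos, ov = None, 0
    c = FosmidConstruct(
        construct_id=construct_id,
        insert_seq=chunk,
        vector_seq=vector,
        insertion_mode=mode,
        full_seq=full,
        source=source,
        insertion_pos=ipos,
        overlap_len=ov,
        vector_interval=vec_iv,
    )
    c.validate()
    return c


def _apply_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """In-place uniform substitutions on a 2D uint8 base-code matrix."""
    if rate <= 0:
        return
    mask = rng.random(mat.shape) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    mat[mask] = (mat[mask] + shift) % 4


def simulate_reads(construct: FosmidConstruct, profile: ReadProfile) -> ReadSet:
    """Draw reads from the construct's linear reference sequence.

    The read count n is the smallest satisfying n*read_len >= coverage*L
    (mates counted individually); fragment lengths for pairs follow a
    Normal(fragment_mean, fragment_sd) truncated to [read_len, L]; mate 2 is
    the reverse complement of the fragment end.  Deterministic per seed.
    """
    L = len(construct.full_seq)
    rl = profile.read_len
    if L < rl:
        raise ValueError(f"construct ({L} bp) shorter than read length {rl}")
    rng = np.random.default_rng(profile.seed)
    ref = encode(construct.full_seq)
    cid = construct.construct_id

    if profile.layout == "single":
        n = math.ceil(profile.coverage * L / rl)
        if n == 0:
            raise ValueError("coverage too low: zero reads requested")
        starts = rng.integers(0, L - rl + 1, size=n)
        strands = rng.random(n) < 0.5
        mat = np.empty((n, rl), dtype=np.uint8)
        for i, s in enumerate(starts):
            mat[i] = ref[s : s + rl]
        rc = (3 - mat[strands])[:, ::-1]
        mat[strands] = rc
        _apply_errors(mat, profile.subst_error_rate, rng)
        qual = _QUAL_CHAR * rl
        reads = [Read(f"{cid}_r{i}", decode(mat[i]), qual) for i in range(n)]
        return ReadSet("single", reads)

    n_pairs = math.ceil(profile.coverage * L / (2 * rl))
    if n_pairs == 0:
        raise ValueError("coverage too low: zero read pairs requested")
    frag = np.rint(
        rng.normal(profile.fragment_mean, profile.fragment_sd, size=n_pairs)
    ).astype(np.int64)
    lo, hi = rl, L
    for _ in range(100):
        bad = (frag < lo) | (frag > hi)
        if not bad.any():
            break
        frag[bad] = np.rint(
            rng.normal(profile.fragment_mean, profile.fragment_sd, size=int(bad.sum()))
        ).astype(np.int64)
    else:
        raise ValueError(
            f"fragment length Normal({profile.fragment_mean},{profile.fragment_sd}) "
            f"cannot be sampled within [{lo},{hi}]"
        )
    starts = (rng.random(n_pairs) * (L - frag + 1)).astype(np.int64)
    strands = rng.random(n_pairs) < 0.5
    m1 = np.empty((n_pairs, rl), dtype=np.uint8)
    m2 = np.empty((n_pairs, rl), dtype=np.uint8)
    for i in range(n_pairs):
        s, f = starts[i], frag[i]
        fragment = ref[s : s + f]
        if strands[i]:
            fragment = (3 - fragment)[::-1]
        m1[i] = fragment[:rl]
        m2[i] = (3 - fragment[-rl:])[::-1]
    _apply_errors(m1, profile.subst_error_rate, rng)
    _apply_errors(m2, profile.subst_error_rate, rng)
    qual = _QUAL_CHAR * rl
    r1 = [Read(f"{cid}_r{i}/1", decode(m1[i]), qual) for i in range(n_pairs)]
    r2 = [Read(f"{cid}_r{i}/2", decode(m2[i]), qual) for i in range(n_pairs)]
    return ReadSet("paired", r1, r2)


# ---------------------------------------------------------------------------
# Truth manifest and insert recovery
# ---------------------------------------------------------------------------

def write_manifest(constructs: list[FosmidConstruct], path) -> None:
    """JSON truth manifest, one record per construct, insert sequence included
    so evaluation never needs the source genome."""
    records = []
    for c in constructs:
        rec = c.truth_record()
        rec["insert_seq"] = c.insert_seq
        records.append(rec)
    Path(path).write_text(json.dumps({"constructs": records}, indent=1))


def read_manifest(path) -> list[dict]:
    return json.loads(Path(path).read_text())["constructs"]


def insert_from_construct(full_seq: str, record: dict) -> str:
    """Recover the vector-free insert from a construct sequence + truth record."""
    ov = record["overlap_len"]
    s, e = record["vector_interval"]
    linear = full_seq[: len(full_seq) - ov] if ov else full_seq
    return linear[:s] + linear[e:]
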