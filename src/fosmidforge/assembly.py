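"""Minimal de Bruijn graph assembler plus external-assembler ingestion.

Fosmid inserts are short (~40 kb), deeply covered and nearly repeat-free,
so a deliberately simple assembler suffices for a self-contained pipeline:
count canonical k-mers, drop those below an abundance floor, remove short
tips, and compact every unbranched path (or pure cycle — a correctly
closed circular fosmid is one) into a contig.  There is no bubble popping
and no greedy branch resolution: at a fork, extension stops.

The production path for real data is an external assembler whose FASTA
output is ingested by :func:`parse_assembler_fasta` / :func:`run_external_assembler`.
"""

from __future__ import annotations

import re
import shlex
import subprocess
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from numba import njit

from ._seq import encode, revcomp
from .readprep import ReadSet, write_readset

DEFAULT_K = 31
DEFAULT_MIN_COUNT = 8  # suited to the pipeline's ~300X post-subsampling coverage


@dataclass
class Contig:
    contig_id: str
    seq: str
    mean_cov: float

    @property
    def length(self) -> int:
        return len(self.seq)


ContigSet = list  # list[Contig]


# ---------------------------------------------------------------------------
# k-mer counting backends
# ---------------------------------------------------------------------------

def _rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    r = np.zeros_like(codes)
    tmp = codes.copy()
    two = np.uint64(2)
    three = np.uint64(3)
    for _ in range(k):
        r = (r << two) | (three - (tmp & three))
        tmp = tmp >> two
    return r


@njit(cache=True)
def _canonical_codes(arr, k):  # pragma: no cover - jitted
    """Rolling 2-bit canonical k-mer codes over a 4-separated byte array."""
    n = arr.shape[0]
    out = np.empty(n, dtype=np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1)
    shift = np.uint64(2 * (k - 1))
    f = np.uint64(0)
    r = np.uint64(0)
    run = 0
    m = 0
    for i in range(n):
        b = arr[i]
        if b > 3:
            run = 0
            continue
        f = ((f << np.uint64(2)) | np.uint64(b)) & mask
        r = (r >> np.uint64(2)) | (np.uint64(3 - b) << shift)
        run += 1
        if run >= k:
            out[m] = f if f < r else r
            m += 1
    return out[:m]


def _count_int(seqs, k: int, min_count: int):
    """Canonical k-mer counting over 2-bit codes (k <= 31)."""
    arr = encode("N".join(seqs))
    canon = _canonical_codes(arr, k)
    if canon.size == 0:
        return [], []
    codes, counts = np.unique(canon, return_counts=True)
    keep = counts >= min_count
    return codes[keep], counts[keep]


def _count_str(seqs, k: int, min_count: int):
    """Generic canonical k-mer counting for k > 31 (small inputs)."""
    cnt: Counter = Counter()
    acgt = set("ACGT")
    for s in seqs:
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if set(km) <= acgt:
                cnt[min(km, revcomp(km))] += 1
    items = [(km, c) for km, c in cnt.items() if c >= min_count]
    items.sort()
    return [km for km, _ in items], [c for _, c in items]


class _IntBackend:
    def __init__(self, k: int):
        self.k = k
        self.mask = (1 << (2 * k)) - 1
        self.shift = 2 * (k - 1)
        self._dec = "ACGT"

    def rc_all(self, codes):
        return _rc_codes(np.asarray(codes, dtype=np.uint64), self.k).tolist()

    def succs(self, u, nodes):
        base = (u << 2) & self.mask
        return [base | b for b in range(4) if (base | b) in nodes]

    def preds(self, u, nodes):
        base = u >> 2
        return [base | (b << self.shift) for b in range(4) if base | (b << self.shift) in nodes]

    def to_seq(self, path):
        first = path[0]
        bases = []
        for j in range(self.k):
            bases.append(self._dec[(first >> (2 * (self.k - 1 - j))) & 3])
        for u in path[1:]:
            bases.append(self._dec[u & 3])
        return "".join(bases)


class _StrBackend:
    def __init__(self, k: int):
        self.k = k

    def rc_all(self, kmers):
        return [revcomp(km) for km in kmers]

    def succs(self, u, nodes):
        base = u[1:]
        return [base + b for b in "ACGT" if base + b in nodes]

    def preds(self, u, nodes):
        base = u[:-1]
        return [b + base for b in "ACGT" if b + base in nodes]

    def to_seq(self, path):
        return path[0] + "".join(u[-1] for u in path[1:])


# ---------------------------------------------------------------------------
# graph compaction
# ---------------------------------------------------------------------------

def _walk_unitigs(nodes: dict, rc_map: dict, B):
    outdeg = {u: len(B.succs(u, nodes)) for u in nodes}

    def indeg(u):
        return outdeg[rc_map[u]]

    visited: set = set()
    paths = []

    def emit(path):
        for u in path:
            visited.add(u)
            visited.add(rc_map[u])
        paths.append(path)

    for u in nodes:
        if u in visited:
            continue
        if indeg(u) == 1:
            p = B.preds(u, nodes)
            if outdeg[p[0]] == 1:
                continue  # interior node
        path = [u]
        cur = u
        while outdeg[cur] == 1:
            nxt = B.succs(cur, nodes)[0]
            if indeg(nxt) != 1 or nxt == path[0]:
                break
            path.append(nxt)
            cur = nxt
        emit(path)

    # leftover nodes sit on pure cycles
    for u in nodes:
        if u in visited or outdeg[u] != 1:
            continue
        path = [u]
        cur = B.succs(u, nodes)[0]
        while cur != u:
            path.append(cur)
            cur = B.succs(cur, nodes)[0]
        emit(path)
    return paths, outdeg


def _compact(nodes: dict, rc_map: dict, B, k: int):
    """One round of unitig construction; returns (paths, is_cycle flags, outdeg)."""
    paths, outdeg = _walk_unitigs(nodes, rc_map, B)
    flags = []
    for path in paths:
        last = path[-1]
        first = path[0]
        cyc = (
            outdeg[last] == 1
            and B.succs(last, nodes)[0] == first
            and outdeg[rc_map[first]] == 1
        )
        flags.append(cyc and len(path) > 1)
    return paths, flags, outdeg


def _remove_tips(nodes: dict, rc_map: dict, B, k: int, max_rounds: int = 4):
    for _ in range(max_rounds):
        paths, flags, outdeg = _compact(nodes, rc_map, B, k)
        removed = False
        for path, cyc in zip(paths, flags):
            if cyc:
                continue
            dead_start = len(B.preds(path[0], nodes)) == 0
            dead_end = len(B.succs(path[-1], nodes)) == 0
            if dead_start != dead_end and len(path) + k - 1 < 2 * k:
                for u in path:
                    nodes.pop(u, None)
                    nodes.pop(rc_map[u], None)
                removed = True
        if not removed:
            break


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def assemble_reads(
    reads: ReadSet, k: int = DEFAULT_K, min_count: int = DEFAULT_MIN_COUNT
) -> ContigSet:
    """Assemble a read set into unitig contigs.

    Contigs are sorted by length (descending, ties by sequence) and given
    stable ids ``contig_1`` ...; ``mean_cov`` is the mean abundance of the
    path's k-mers.  A pure cycle (closed circular molecule) is emitted as a
    linear contig whose last k-1 bases repeat its first k-1.
    """
    if reads.n_reads == 0:
        raise ValueError("cannot assemble an empty read set")
    if k % 2 == 0 or not 15 <= k <= 127:
        raise ValueError(f"k must be odd and within [15, 127], got {k}")
    seqs = [r.seq.upper() for r in reads.iter_all()]
    if k <= 31:
        kmers, counts = _count_int(seqs, k, min_count)
        B = _IntBackend(k)
        kmers = [int(x) for x in kmers]
        counts = [int(c) for c in counts]
    else:
        kmers, counts = _count_str(seqs, k, min_count)
        B = _StrBackend(k)
    if not kmers:
        warnings.warn(
            f"no k-mer reached abundance {min_count}; empty assembly", stacklevel=2
        )
        return []
    rcs = B.rc_all(kmers)
    nodes: dict = {}
    rc_map: dict = {}
    for km, rc, c in zip(kmers, rcs, counts):
        nodes[km] = c
        nodes[rc] = c
        rc_map[km] = rc
        rc_map[rc] = km
    _remove_tips(nodes, rc_map, B, k)
    if not nodes:
        warnings.warn("all k-mers removed as tips; empty assembly", stacklevel=2)
        return []
    paths, flags, _ = _compact(nodes, rc_map, B, k)
    raw = []
    for path, cyc in zip(paths, flags):
        # a full-cycle path's spelling already wraps: its last k-1 bases
        # repeat its first k-1, so no extra bases are appended
        seq = B.to_seq(path)
        cov = float(np.mean([nodes[u] for u in path]))
        raw.append((seq, cov))
    raw.sort(key=lambda x: (-len(x[0]), x[0]))
    return [
        Contig(f"contig_{i + 1}", seq, cov) for i, (seq, cov) in enumerate(raw)
    ]


_NODE_RE = re.compile(r"NODE_(\S+?)_length_(\d+)_cov_([\d.eE+-]+)")


def parse_assembler_fasta(fasta) -> ContigSet:
    """Ingest external-assembler contigs; coverage parsed from
    ``NODE_<i>_length_<L>_cov_<C>`` headers when present, else NaN (flagged
    for downstream re-estimation)."""
    contigs = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        seq = str(rec.seq).upper()
        m = _NODE_RE.search(rec.description)
        if m:
            cid = f"NODE_{m.group(1)}"
            hdr_len = int(m.group(2))
            cov = float(m.group(3))
            if hdr_len != len(seq):
                warnings.warn(
                    f"{cid}: header length {hdr_len} != sequence length "
                    f"{len(seq)}; using sequence length",
                    stacklevel=2,
                )
        else:
            cid = rec.id
            cov = float("nan")
            warnings.warn(
                f"{cid}: no coverage in header; mean_cov set to NaN "
                "(re-estimate from read k-mer counts)",
                stacklevel=2,
            )
        contigs.append(Contig(cid, seq, cov))
    return contigs


def run_external_assembler(cmd_template: str, reads: ReadSet, workdir) -> ContigSet:
    """Execute a configured assembler command and ingest its contigs.

    The template receives FASTQ paths via ``{r1}``, ``{r2}``, ``{single}``
    and the output directory via ``{out}``; ``contigs.fasta`` or
    ``scaffolds.fasta`` in ``{out}`` is parsed afterwards (both are accepted).
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    files = write_readset(reads, workdir / "reads")
    mapping = {"out": str(workdir), "r1": "", "r2": "", "single": ""}
    if reads.layout == "paired":
        mapping["r1"], mapping["r2"] = str(files[0]), str(files[1])
    else:
        mapping["single"] = str(files[0])
    cmd = cmd_template.format(**mapping)
    subprocess.run(shlex.split(cmd), check=True)
    for name in ("contigs.fasta", "scaffolds.fasta"):
        out = workdir / name
        if out.exists():
            return parse_assembler_fasta(out)
    raise FileNotFoundError(
        f"external assembler produced neither contigs.fasta nor scaffolds.fasta in {workdir}"
    )
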