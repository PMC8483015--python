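"""Cloning-vector detection, masking, contig filtering and circularity-aware
contig re-organization — the pipeline's core stage.

A sequenced fosmid clone is a circular molecule: environmental insert plus
the known cloning vector (e.g., pCC1FOS).  After assembly the vector must be
located on each contig, masked or excised, and the vector-free flanks made
consistent with circularity: when the vector sits inside a contig, the two
flanks are joined if their extremities overlap (the assembler saw around the
circle) or the contig is split in two if they do not.

Vector detection is a native seed(k=15) – chain – extend local alignment
with match +1 / mismatch -2 / gap -3; small problems run the full
Smith–Waterman matrix so reported coordinates are exact optima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._align import LINEAR, _run_banded, align_global, align_local_full, seed_chains
from ._seq import encode, revcomp
from .assembly import Contig, ContigSet

DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_MIN_MATCH_LEN = 50
DEFAULT_MIN_CONTIG_LEN = 1000
DEFAULT_MIN_CONTIG_COV = 8.0
DEFAULT_END_SLACK = 10
DEFAULT_MIN_JOIN_OVERLAP = 20
DEFAULT_MIN_JOIN_IDENTITY = 0.95

_FULL_SW_CELLS = 8_000_000


@dataclass
class VectorMatch:
    """A located vector occurrence on a contig (forward-strand coordinates)."""

    contig_id: str
    start: int  # 0-based half-open on the contig
    end: int
    strand: str
    identity: float
    vector_span: tuple[int, int]  # forward coordinates on the vector

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ReorganizationOutcome:
    case: str  # no_vector | trimmed_extremity | joined_circular | split_two | multi_vector
    contigs_out: ContigSet
    join_overlap_len: int = 0
    flagged: bool = False


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _accept(aln, min_identity: float, min_match_len: int) -> bool:
    return (
        aln is not None
        and aln.n_cols >= 1
        and (aln.q_end - aln.q_start) >= min_match_len
        and aln.identity >= min_identity
    )


def _detect_small(contig_seq, oriented, min_identity, min_match_len, max_hits=20):
    """Iterated exact Smith–Waterman: accept the optimum, mask its contig
    span, repeat until the best remaining alignment fails the thresholds."""
    work = list(contig_seq)
    out = []
    for _ in range(max_hits):
        aln = align_local_full("".join(work), oriented, LINEAR)
        if not _accept(aln, min_identity, min_match_len):
            break
        out.append(aln)
        for i in range(aln.q_start, aln.q_end):
            work[i] = "X"
    return out


def _detect_large(contig_seq, oriented, min_identity, min_match_len):
    q = encode(contig_seq)
    t = encode(oriented)
    out = []
    for chain in seed_chains(contig_seq, oriented, min_seeds=3):
        pad = 48 + (chain["d_hi"] - chain["d_lo"])
        while True:
            aln, touched = _run_banded(
                q, t, chain["d_lo"] - pad, chain["d_hi"] + pad, LINEAR, True
            )
            if not touched or pad > len(contig_seq) + len(oriented):
                break
            pad *= 4
        if _accept(aln, min_identity, min_match_len):
            out.append(aln)
    return out


def detect_vector(
    contig: Contig,
    vector: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_match_len: int = DEFAULT_MIN_MATCH_LEN,
) -> list[VectorMatch]:
    """Locate maximal vector alignments (either strand) on a contig.

    Matches are sorted by contig start; overlapping same-strand matches are
    merged.  A contig shorter than ``min_match_len`` yields an empty list.
    """
    if not vector:
        raise ValueError("vector sequence is empty")
    if not 0.5 <= min_identity <= 1:
        raise ValueError("min_identity must be within [0.5, 1]")
    if len(contig.seq) < min_match_len:
        return []
    vlen = len(vector)
    small = len(contig.seq) * vlen <= _FULL_SW_CELLS
    matches: list[VectorMatch] = []
    for strand, oriented in (("+", vector.upper()), ("-", revcomp(vector.upper()))):
        alns = (
            _detect_small(contig.seq, oriented, min_identity, min_match_len)
            if small
            else _detect_large(contig.seq, oriented, min_identity, min_match_len)
        )
        for aln in alns:
            if strand == "+":
                vspan = (aln.t_start, aln.t_end)
            else:
                vspan = (vlen - aln.t_end, vlen - aln.t_start)
            matches.append(
                VectorMatch(
                    contig_id=contig.contig_id,
                    start=aln.q_start,
                    end=aln.q_end,
                    strand=strand,
                    identity=aln.identity,
                    vector_span=vspan,
                )
            )
    matches.sort(key=lambda m: (m.start, m.end))
    return _merge_matches(matches)


def _merge_matches(matches: list[VectorMatch]) -> list[VectorMatch]:
    merged: list[VectorMatch] = []
    for m in matches:
        if merged and m.start < merged[-1].end and m.strand == merged[-1].strand:
            prev = merged[-1]
            span = (
                min(prev.vector_span[0], m.vector_span[0]),
                max(prev.vector_span[1], m.vector_span[1]),
            )
            w1, w2 = prev.end - prev.start, m.end - m.start
            merged[-1] = VectorMatch(
                prev.contig_id,
                prev.start,
                max(prev.end, m.end),
                prev.strand,
                (prev.identity * w1 + m.identity * w2) / (w1 + w2),
                span,
            )
        else:
            merged.append(m)
    return merged


# ---------------------------------------------------------------------------
# masking and filtering
# ---------------------------------------------------------------------------

def _union(intervals) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def mask_vector(contig: Contig, matches: list[VectorMatch]) -> Contig:
    """Replace every base inside the union of match intervals by 'X'."""
    seq = list(contig.seq)
    for s, e in _union(m.interval for m in matches):
        if not 0 <= s <= e <= len(seq):
            raise ValueError(f"match interval ({s},{e}) outside contig")
        seq[s:e] = "X" * (e - s)
    return Contig(contig.contig_id, "".join(seq), contig.mean_cov)


def filter_contigs(
    contigs: ContigSet,
    min_len: int = DEFAULT_MIN_CONTIG_LEN,
    min_cov: float = DEFAULT_MIN_CONTIG_COV,
) -> ContigSet:
    """Retain contigs strictly longer than ``min_len`` with mean coverage
    strictly above ``min_cov``; NaN coverage is retained (unknown)."""
    kept = []
    for c in contigs:
        if np.isnan(c.mean_cov):
            kept.append(c)
            continue
        if c.length > min_len and c.mean_cov > min_cov:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# terminal overlap and re-organization
# ---------------------------------------------------------------------------

def detect_terminal_overlap(
    right_end: str,
    left_start: str,
    min_len: int = DEFAULT_MIN_JOIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_JOIN_IDENTITY,
    window: int = 1000,
) -> int | None:
    """Longest suffix-of-right / prefix-of-left overlap, or ``None``.

    Exact matches are tried first (longest wins); otherwise seed positions
    propose candidate lengths that are verified by global alignment.
    """
    r = right_end[-window:]
    l = left_start[:window]
    max_l = min(len(r), len(l))
    for L in range(max_l, min_len - 1, -1):
        if r[-L:] == l[:L]:
            return L
    # inexact: anchor prefixes of `l` inside `r` to propose overlap lengths
    k = 15
    cands: set[int] = set()
    for j in range(0, min(60, max(1, len(l) - k))):
        kmer = l[j : j + k]
        if len(kmer) < k:
            break
        pos = r.find(kmer)
        while pos != -1:
            L = len(r) - pos + j
            if min_len <= L <= max_l:
                cands.add(L)
            pos = r.find(kmer, pos + 1)
    for L in sorted(cands, reverse=True):
        aln = align_global(r[-L:], l[:L])
        if aln.n_cols and aln.n_match / aln.n_cols >= min_identity:
            return L
    return None


def _strip_x(seq: str) -> str:
    return seq.replace("X", "")


def reorganize_contig(
    contig: Contig,
    matches: list[VectorMatch],
    min_join_overlap: int = DEFAULT_MIN_JOIN_OVERLAP,
    min_join_identity: float = DEFAULT_MIN_JOIN_IDENTITY,
    end_slack: int = DEFAULT_END_SLACK,
) -> ReorganizationOutcome:
    """Excise the vector and restore circular consistency.

    * no match: contig returned unchanged;
    * match at a contig extremity (within ``end_slack``): vector excised,
      one contig remains (a short ragged terminal residue is dropped);
    * internal match: flanks joined when their extremities overlap
      (one copy of the duplicated overlap kept), else split in two;
    * two matches each touching an opposite extremity — a circular
      assembly linearised inside the vector — are both trimmed, one contig;
    * any other multiple-occurrence pattern is flagged: all spans excised,
      no join attempted.

    Works identically on masked and unmasked contigs: coordinates drive the
    excision and the vector spans are exactly what masking X-ed out.
    """
    L = contig.length
    ivs = _union(m.interval for m in matches)
    cid = contig.contig_id
    cov = contig.mean_cov

    if not ivs:
        return ReorganizationOutcome("no_vector", [contig])

    if len(ivs) == 1:
        s, e = ivs[0]
        at_start = s <= end_slack
        at_end = e >= L - end_slack
        if at_start and at_end:
            return ReorganizationOutcome("trimmed_extremity", [])
        if at_start or at_end:
            seq = contig.seq[e:] if at_start else contig.seq[:s]
            return ReorganizationOutcome(
                "trimmed_extremity", [Contig(cid, _strip_x(seq), cov)]
            )
        left = _strip_x(contig.seq[:s])
        right = _strip_x(contig.seq[e:])
        ov = detect_terminal_overlap(
            right, left, min_len=min_join_overlap, min_identity=min_join_identity
        )
        if ov is not None:
            joined = right + left[ov:]
            return ReorganizationOutcome(
                "joined_circular", [Contig(cid, joined, cov)], join_overlap_len=ov
            )
        return ReorganizationOutcome(
            "split_two",
            [Contig(f"{cid}.1", left, cov), Contig(f"{cid}.2", right, cov)],
        )

    # multiple disjoint occurrences
    first_s, first_e = ivs[0]
    last_s, last_e = ivs[-1]
    if (
        len(ivs) == 2
        and first_s <= end_slack
        and last_e >= L - end_slack
    ):
        # circular assembly broken inside the vector: trim both extremities
        mid = _strip_x(contig.seq[first_e:last_s])
        return ReorganizationOutcome("trimmed_extremity", [Contig(cid, mid, cov)])
    pieces = []
    prev = 0
    for s, e in ivs:
        if s > prev:
            pieces.append(contig.seq[prev:s])
        prev = e
    if prev < L:
        pieces.append(contig.seq[prev:])
    out = [
        Contig(f"{cid}.{i + 1}", _strip_x(p), cov)
        for i, p in enumerate(pieces)
        if _strip_x(p)
    ]
    return ReorganizationOutcome("multi_vector", out, flagged=True)
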