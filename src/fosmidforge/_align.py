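"""Banded affine-gap pairwise alignment kernel (numba-jitted) plus
seed-and-chain helpers.

One DP kernel serves every alignment need in the package:

* global (Needleman–Wunsch style) with affine gaps — assembly/annotation
  evaluation, terminal-overlap verification;
* local (Smith–Waterman style) — cloning-vector detection, contig-vs-
  reference block alignment.

Scoring is parameterised; a gap of length g costs ``open + g*extend`` so a
linear gap penalty is expressed as ``open=0``.  Tie-breaking is fixed and
documented so that an independent full-matrix DP reproduces the exact same
optimum: the combined matrix H prefers diagonal (match/mismatch) over a gap
in the query over a gap in the target; gap states prefer opening over
extending on ties; the best local cell is the first maximal one in row-major
order.

The band is a diagonal band ``d_lo <= j - i <= d_hi`` over the (query i,
target j) matrix.  Wrappers start from a narrow band (full matrix for small
problems) and double the padding whenever the traceback touches a band edge
away from the matrix border, so reported alignments are true optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._seq import encode, revcomp

NEG = -(1 << 30)

#: affine scheme used for evaluation alignments: match +1, mismatch -2,
#: gap open -4 for the first gap base, -1 for each further base.
AFFINE = (1, 2, 3, 1)
#: linear scheme used for vector detection: match +1, mismatch -2, gap -3/base.
LINEAR = (1, 2, 0, 3)


@njit(cache=True)
def _band_dp(q, t, d_lo, d_hi, ma, mm, go, ge, local):  # pragma: no cover - jitted
    n = q.shape[0]
    m = t.shape[0]
    W = d_hi - d_lo + 1
    tb = np.zeros((n + 1, W), dtype=np.uint8)
    Hprev = np.full(W, NEG, dtype=np.int64)
    Hcur = np.full(W, NEG, dtype=np.int64)
    Ixprev = np.full(W, NEG, dtype=np.int64)
    Ixcur = np.full(W, NEG, dtype=np.int64)
    Iyprev = np.full(W, NEG, dtype=np.int64)
    Iycur = np.full(W, NEG, dtype=np.int64)

    best = 0
    bi = 0
    bj = 0
    # row 0
    for c in range(W):
        j = d_lo + c
        if j < 0 or j > m:
            continue
        if j == 0 or local:
            Hprev[c] = 0
            tb[0, c] = 3
        else:
            Ixprev[c] = -(go + j * ge)
            Hprev[c] = Ixprev[c]
            bits = 1
            if j > 1:
                bits |= 4
            tb[0, c] = bits

    for i in range(1, n + 1):
        qa = q[i - 1]
        for c in range(W):
            Hcur[c] = NEG
            Ixcur[c] = NEG
            Iycur[c] = NEG
        for c in range(W):
            j = i + d_lo + c
            if j < 0 or j > m:
                continue
            if j == 0:
                if local:
                    Hcur[c] = 0
                    tb[i, c] = 3
                else:
                    Iycur[c] = -(go + i * ge)
                    Hcur[c] = Iycur[c]
                    bits = 2
                    if i > 1:
                        bits |= 8
                    tb[i, c] = bits
                continue
            hd = Hprev[c]  # H[i-1][j-1]
            if hd > NEG:
                if qa == t[j - 1] and qa < 4:
                    M = hd + ma
                else:
                    M = hd - mm
            else:
                M = NEG
            Ix = NEG
            ixext = 0
            if c >= 1:
                a1 = Hcur[c - 1] - go - ge
                a2 = Ixcur[c - 1] - ge
                if a2 > a1:
                    Ix = a2
                    ixext = 1
                else:
                    Ix = a1
            Iy = NEG
            iyext = 0
            if c + 1 < W:
                b1 = Hprev[c + 1] - go - ge
                b2 = Iyprev[c + 1] - ge
                if b2 > b1:
                    Iy = b2
                    iyext = 1
                else:
                    Iy = b1
            h = M
            hb = 0
            if Ix > h:
                h = Ix
                hb = 1
            if Iy > h:
                h = Iy
                hb = 2
            if local and h <= 0:
                h = 0
                hb = 3
            Hcur[c] = h
            Ixcur[c] = Ix
            Iycur[c] = Iy
            tb[i, c] = hb | (ixext << 2) | (iyext << 3)
            if local and h > best:
                best = h
                bi = i
                bj = j
        tmp = Hprev
        Hprev = Hcur
        Hcur = tmp
        tmp = Ixprev
        Ixprev = Ixcur
        Ixcur = tmp
        tmp = Iyprev
        Iyprev = Iycur
        Iycur = tmp

    if local:
        i = bi
        j = bj
        score = best
    else:
        i = n
        j = m
        c = m - n - d_lo
        score = Hprev[c] if 0 <= c < W else NEG
    qe = i
    te = j
    ops = np.empty(n + m + 2, dtype=np.uint8)
    nops = 0
    state = 0
    touched = False
    while True:
        c = j - i - d_lo
        if (c == 0 or c == W - 1) and 0 < i < n and 0 < j < m:
            touched = True
        b = tb[i, c]
        if state == 0:
            hb = b & 3
            if hb == 3:
                break
            if hb == 0:
                ops[nops] = 0
                nops += 1
                i -= 1
                j -= 1
            elif hb == 1:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[nops] = 1
            nops += 1
            if (b >> 2) & 1:
                state = 1
            else:
                state = 0
            j -= 1
        else:
            ops[nops] = 2
            nops += 1
            if (b >> 3) & 1:
                state = 2
            else:
                state = 0
            i -= 1
    return score, i, j, qe, te, ops[:nops][::-1].copy(), touched


@dataclass
class Alignment:
    """One pairwise alignment: half-open spans on query and target,
    identically-matching base count, column count and gapless blocks."""

    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    n_match: int
    n_cols: int
    strand: str = "+"
    blocks: list = field(default_factory=list)  # (q0, t0, length) diagonal runs
    matched_t: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def identity(self) -> float:
        return self.n_match / self.n_cols if self.n_cols else 0.0


def _summarize(q, t, score, qs, ts, qe, te, ops) -> Alignment:
    i, j = qs, ts
    n_match = 0
    blocks: list[tuple[int, int, int]] = []
    matched: list[int] = []
    run_q = run_t = run_len = -1
    for op in ops:
        if op == 0:
            if run_len < 0:
                run_q, run_t, run_len = i, j, 0
            run_len += 1
            if q[i] == t[j] and q[i] < 4:
                n_match += 1
                matched.append(j)
            i += 1
            j += 1
        else:
            if run_len > 0:
                blocks.append((run_q, run_t, run_len))
            run_len = -1
            if op == 1:
                j += 1
            else:
                i += 1
    if run_len > 0:
        blocks.append((run_q, run_t, run_len))
    return Alignment(
        score=int(score),
        q_start=qs,
        q_end=qe,
        t_start=ts,
        t_end=te,
        n_match=n_match,
        n_cols=len(ops),
        blocks=blocks,
        matched_t=np.asarray(matched, dtype=np.int64),
    )


def _run_banded(q, t, d_lo, d_hi, scoring, local) -> tuple[Alignment, bool]:
    ma, mm, go, ge = scoring
    score, qs, ts, qe, te, ops, touched = _band_dp(
        q, t, np.int64(d_lo), np.int64(d_hi), ma, mm, go, ge, local
    )
    return _summarize(q, t, score, qs, ts, qe, te, ops), touched


def align_global(query: str, target: str, scoring=AFFINE, pad: int = 32) -> Alignment:
    """Optimal global alignment; band grows until the optimum is certain."""
    if not query or not target:
        raise ValueError("align_global requires non-empty sequences")
    q = encode(query)
    t = encode(target)
    n, m = len(q), len(t)
    while True:
        d_lo = min(0, m - n) - pad
        d_hi = max(0, m - n) + pad
        full = d_lo <= -n and d_hi >= m
        aln, touched = _run_banded(q, t, d_lo, d_hi, scoring, False)
        if not touched or full:
            return aln
        pad *= 4


def align_local_full(query: str, target: str, scoring=LINEAR) -> Alignment:
    """Exact Smith–Waterman over the full matrix (small problems only)."""
    q = encode(query)
    t = encode(target)
    aln, _ = _run_banded(q, t, -len(q), len(t), scoring, True)
    return aln


def seed_chains(
    query: str,
    target: str,
    k: int = 15,
    max_diag_gap: int = 64,
    max_pos_gap: int = 2000,
    min_seeds: int = 3,
    max_kmer_hits: int = 8,
) -> list[dict]:
    """Cluster exact k-mer matches into co-linear chains.

    Returns chains as dicts with diagonal range and query/target spans,
    sorted by seed count (descending).  Only same-orientation matches are
    considered; callers handle reverse-complement by flipping one sequence.
    """
    index: dict[str, list[int]] = {}
    for j in range(len(target) - k + 1):
        kmer = target[j : j + k]
        hits = index.setdefault(kmer, [])
        if len(hits) < max_kmer_hits:
            hits.append(j)
    pairs: list[tuple[int, int, int]] = []  # (diag, qpos, tpos)
    for i in range(len(query) - k + 1):
        for j in index.get(query[i : i + k], ()):
            pairs.append((j - i, i, j))
    if not pairs:
        return []
    pairs.sort()
    chains: list[dict] = []
    cur: dict | None = None
    for d, i, j in pairs:
        if (
            cur is not None
            and d - cur["d_hi"] <= max_diag_gap
            and (abs(i - cur["q_hi"]) <= max_pos_gap or abs(j - cur["t_hi"]) <= max_pos_gap)
        ):
            cur["d_hi"] = d
            cur["q_lo"] = min(cur["q_lo"], i)
            cur["q_hi"] = max(cur["q_hi"], i + k)
            cur["t_lo"] = min(cur["t_lo"], j)
            cur["t_hi"] = max(cur["t_hi"], j + k)
            cur["n_seeds"] += 1
        else:
            cur = {
                "d_lo": d,
                "d_hi": d,
                "q_lo": i,
                "q_hi": i + k,
                "t_lo": j,
                "t_hi": j + k,
                "n_seeds": 1,
            }
            chains.append(cur)
    chains = [c for c in chains if c["n_seeds"] >= min_seeds]
    chains.sort(key=lambda c: -c["n_seeds"])
    return chains


_FULL_LOCAL_CELLS = 9_000_000
_MAX_MERGED_BAND = 4096


def _merge_colinear(chains: list[dict]) -> list[dict]:
    """Join chains that progress monotonically on both sequences (an indel —
    e.g., a collapsed repeat copy — moves the alignment to a new diagonal)
    so one band can span the whole path.  A repeat makes successive chains
    overlap by up to the repeat length, so overlap is allowed as long as
    both coordinates advance and the combined band stays bounded."""
    merged: list[dict] = []
    for c in sorted(chains, key=lambda c: (c["q_lo"], c["t_lo"])):
        if merged:
            p = merged[-1]
            d_lo = min(p["d_lo"], c["d_lo"])
            d_hi = max(p["d_hi"], c["d_hi"])
            if (
                c["q_hi"] >= p["q_hi"]
                and c["t_hi"] >= p["t_hi"]
                and c["q_lo"] >= p["q_lo"]
                and c["t_lo"] >= p["t_lo"]
                and d_hi - d_lo <= _MAX_MERGED_BAND
            ):
                p["d_lo"], p["d_hi"] = d_lo, d_hi
                p["q_hi"] = max(p["q_hi"], c["q_hi"])
                p["t_hi"] = max(p["t_hi"], c["t_hi"])
                p["n_seeds"] += c["n_seeds"]
                continue
        merged.append(dict(c))
    return merged


def align_local(query: str, target: str, scoring=LINEAR, pad: int = 48) -> Alignment | None:
    """Best local alignment; exact full DP when small, seeded+banded when large.

    Returns ``None`` when the sequences share no seed chain (large inputs
    only); the full DP path always returns an (possibly empty) alignment.
    """
    if not query or not target:
        raise ValueError("align_local requires non-empty sequences")
    if len(query) * len(target) <= _FULL_LOCAL_CELLS:
        return align_local_full(query, target, scoring)
    chains = seed_chains(query, target)
    if not chains:
        return None
    candidates = chains[:8] + [
        c for c in _merge_colinear(chains) if c["n_seeds"] > max(x["n_seeds"] for x in chains)
    ]
    q = encode(query)
    t = encode(target)
    best: Alignment | None = None
    for chain in candidates:
        p = pad + (chain["d_hi"] - chain["d_lo"])
        while True:
            aln, touched = _run_banded(
                q, t, chain["d_lo"] - p, chain["d_hi"] + p, scoring, True
            )
            if not touched or p > len(query) + len(target):
                break
            p *= 4
        if best is None or aln.score > best.score:
            best = aln
    return best


def align_best_strand(
    query: str, target: str, mode: str = "global", scoring=AFFINE
) -> Alignment:
    """Align query against target on both strands, keep the better score.

    On the minus strand the reported query coordinates refer to the
    reverse-complemented query; target coordinates are always forward.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    if mode == "global":
        fwd = align_global(query, target, scoring)
        rev = align_global(revcomp(query), target, scoring)
    else:
        fwd = align_local(query, target, scoring)
        rev = align_local(revcomp(query), target, scoring)
    if fwd is None and rev is None:
        return Alignment(0, 0, 0, 0, 0, 0, 0)
    if rev is None or (fwd is not None and fwd.score >= rev.score):
        fwd.strand = "+"
        return fwd
    rev.strand = "-"
    return rev
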