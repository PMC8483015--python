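"""Independent full-matrix dynamic-programming oracles for the tests.

Plain-Python Needleman–Wunsch / Smith–Waterman over the complete matrix —
no bands, no seeds, no chaining — with the documented tie-break rules
(diagonal over query-gap over target-gap; gap opening over extension on
ties; first maximal cell in row-major order for local alignment).
"""

NEG = -(1 << 30)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _enc(s):
    return [_CODE.get(ch, 4) for ch in s.upper()]


def dp_align(query, target, match=1, mismatch=2, gap_open=3, gap_extend=1,
             local=False):
    """Optimal alignment by full DP.

    A gap of length g costs ``gap_open + g*gap_extend``.  Returns a dict
    with score, query/target spans (0-based half-open) and the number of
    identically matching bases on the traced-back optimal path.
    """
    q = _enc(query)
    t = _enc(target)
    n, m = len(q), len(t)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    tbH = [[3] * (m + 1) for _ in range(n + 1)]
    tbIx = [[0] * (m + 1) for _ in range(n + 1)]
    tbIy = [[0] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0
    for j in range(1, m + 1):
        if local:
            H[0][j] = 0
        else:
            Ix[0][j] = -(gap_open + j * gap_extend)
            H[0][j] = Ix[0][j]
            tbH[0][j] = 1
            tbIx[0][j] = 1 if j > 1 else 0
    for i in range(1, n + 1):
        if local:
            H[i][0] = 0
        else:
            Iy[i][0] = -(gap_open + i * gap_extend)
            H[i][0] = Iy[i][0]
            tbH[i][0] = 2
            tbIy[i][0] = 1 if i > 1 else 0
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else -mismatch
            M = H[i - 1][j - 1] + s if H[i - 1][j - 1] > NEG else NEG
            a1 = H[i][j - 1] - gap_open - gap_extend
            a2 = Ix[i][j - 1] - gap_extend
            if a2 > a1:
                Ix[i][j] = a2
                tbIx[i][j] = 1
            else:
                Ix[i][j] = a1
            b1 = H[i - 1][j] - gap_open - gap_extend
            b2 = Iy[i - 1][j] - gap_extend
            if b2 > b1:
                Iy[i][j] = b2
                tbIy[i][j] = 1
            else:
                Iy[i][j] = b1
            h, hb = M, 0
            if Ix[i][j] > h:
                h, hb = Ix[i][j], 1
            if Iy[i][j] > h:
                h, hb = Iy[i][j], 2
            if local and h <= 0:
                h, hb = 0, 3
            H[i][j] = h
            tbH[i][j] = hb
            if local and h > best:
                best, bi, bj = h, i, j
    if local:
        i, j, score = bi, bj, best
    else:
        i, j, score = n, m, H[n][m]
    qe, te = i, j
    n_match = 0
    n_cols = 0
    state = 0
    while True:
        if state == 0:
            hb = tbH[i][j]
            if hb == 3:
                break
            if hb == 0:
                n_cols += 1
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    n_match += 1
                i -= 1
                j -= 1
            elif hb == 1:
                state = 1
            else:
                state = 2
        elif state == 1:
            n_cols += 1
            state = 1 if tbIx[i][j] else 0
            j -= 1
        else:
            n_cols += 1
            state = 2 if tbIy[i][j] else 0
            i -= 1
    return {
        "score": score,
        "q_start": i,
        "q_end": qe,
        "t_start": j,
        "t_end": te,
        "n_match": n_match,
        "n_cols": n_cols,
    }


def orf_scan_brute(seq, min_aa_len=100):
    """Brute-force six-frame ORF enumeration (forward coordinates),
    independent of the package: for every start codon, extend codon by
    codon to the first in-frame stop."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(seq))
    stops = {"TAA", "TAG", "TGA"}
    starts = {"ATG", "GTG", "TTG"}
    found = []
    L = len(seq)
    for strand, s in (("+", seq), ("-", rc)):
        # collect per frame, longest-per-stop (earliest start after prior stop)
        for frame in range(3):
            prev_stop_end = frame
            pos = frame
            while pos + 3 <= len(s):
                if s[pos : pos + 3] in starts and pos >= prev_stop_end:
                    end = None
                    p = pos
                    while p + 3 <= len(s):
                        if s[p : p + 3] in stops:
                            end = p + 3
                            break
                        p += 3
                    if end is not None:
                        aa = (end - pos) // 3 - 1
                        if aa >= min_aa_len:
                            if strand == "+":
                                found.append((pos, end, "+", frame))
                            else:
                                found.append((L - end, L - pos, "-", frame))
                        prev_stop_end = end
                pos += 3
    return sorted(set(found))
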