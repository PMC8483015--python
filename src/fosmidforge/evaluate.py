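"""Assembly and annotation precision/recall with a native alignment backend.

Definitions follow the benchmark convention of the pipeline:

* assembly precision  = matched nucleotides / contig length,
  assembly recall     = matched nucleotides / reference length,
  where matched bases come from the best alignment of each contig to the
  reference and every reference base is credited at most once across
  contigs.  The reference is the vector-free insert; because a correctly
  closed circular fosmid may assemble as an arbitrary rotation, contigs are
  aligned against the doubled reference and credit is taken modulo the
  reference length.

* annotation precision = true-positive CDS / reference CDS count,
  annotation recall    = true-positive CDS / detected CDS count.
  A detected CDS is a true positive when it aligns to a reference CDS
  covering that reference from its start to its end.  Note these two ratios
  are deliberately swapped relative to the usual convention — they are
  computed exactly as printed in the benchmark; ``conventional=True``
  restores the standard definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._align import AFFINE, Alignment, align_global, align_local
from ._seq import revcomp
from .annotate import CdsFeature
from .assembly import Contig, ContigSet


@dataclass
class AssemblyMetrics:
    contig_id: str
    matched_bases: int
    contig_len: int
    reference_len: int

    @property
    def precision(self) -> float:
        return self.matched_bases / self.contig_len if self.contig_len else 0.0

    @property
    def recall(self) -> float:
        return self.matched_bases / self.reference_len if self.reference_len else 0.0


@dataclass
class AnnotationMetrics:
    n_ref_cds: int
    n_detected: int
    n_true_positive: int
    conventional: bool = False

    @property
    def precision(self) -> float:
        denom = self.n_detected if self.conventional else self.n_ref_cds
        return self.n_true_positive / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.n_ref_cds if self.conventional else self.n_detected
        return self.n_true_positive / denom if denom else 0.0


# ---------------------------------------------------------------------------
# pairwise alignment entry point
# ---------------------------------------------------------------------------

def align_pair(query: str, target: str, mode: str = "global") -> Alignment:
    """Optimal pairwise alignment (affine: match +1 / mismatch -2 /
    gap open -4 / extend -1), better strand kept.

    Returns the alignment with its identically-matching base count, column
    count and gapless blocks; minus-strand query coordinates refer to the
    reverse-complemented query.
    """
    if not query or not target:
        raise ValueError("align_pair requires non-empty sequences")
    if mode == "global":
        fwd = align_global(query, target, AFFINE)
        rev = align_global(revcomp(query), target, AFFINE)
    elif mode == "local":
        fwd = align_local(query, target, AFFINE)
        rev = align_local(revcomp(query), target, AFFINE)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if fwd is None and rev is None:
        return Alignment(0, 0, 0, 0, 0, 0, 0)
    if rev is None or (fwd is not None and fwd.score >= rev.score):
        fwd.strand = "+"
        return fwd
    rev.strand = "-"
    return rev


# ---------------------------------------------------------------------------
# assembly metrics
# ---------------------------------------------------------------------------

def assembly_metrics(
    contigs: ContigSet, reference: str, circular: bool = True
) -> tuple[list[AssemblyMetrics], dict]:
    """Score contigs against the truth insert.

    Contigs are processed longest-first; each reference base is credited to
    at most one contig so aggregate recall can never exceed 1.  With
    ``circular`` (default) the reference is doubled so a rotated contig
    still aligns end-to-end; credit is taken modulo the reference length.
    """
    L = len(reference)
    if L == 0:
        raise ValueError("empty reference")
    if not contigs:
        warnings.warn("empty contig set: precision undefined, reported 0", stacklevel=2)
        return [], {
            "precision": 0.0,
            "recall": 0.0,
            "matched_bases": 0,
            "reference_len": L,
            "contig_bases": 0,
            "flag": "empty_contig_set",
        }
    target = reference + reference if circular else reference
    credited = np.zeros(L, dtype=bool)
    per: list[AssemblyMetrics] = []
    for contig in sorted(contigs, key=lambda c: (-c.length, c.contig_id)):
        best = align_pair(contig.seq, target, mode="local")
        pos = np.unique(best.matched_t % L) if best.n_match else np.empty(0, np.int64)
        new = pos[~credited[pos]]
        credited[new] = True
        per.append(
            AssemblyMetrics(
                contig_id=contig.contig_id,
                matched_bases=int(new.size),
                contig_len=contig.length,
                reference_len=L,
            )
        )
    total_matched = int(credited.sum())
    total_len = sum(m.contig_len for m in per)
    agg = {
        "precision": total_matched / total_len if total_len else 0.0,
        "recall": total_matched / L,
        "matched_bases": total_matched,
        "reference_len": L,
        "contig_bases": total_len,
    }
    return per, agg


# ---------------------------------------------------------------------------
# annotation metrics
# ---------------------------------------------------------------------------

def _full_cover_identity(det_seq: str, ref_seq: str) -> float | None:
    """Identity of the best local alignment of detected vs reference CDS,
    provided it covers the reference from start to end; else ``None``."""
    if det_seq == ref_seq or det_seq == revcomp(ref_seq):
        return 1.0
    best = align_pair(det_seq, ref_seq, mode="local")
    if best.n_cols == 0:
        return None
    if best.t_start != 0 or best.t_end != len(ref_seq):
        return None
    return best.n_match / best.n_cols


def _candidate_pairs(detected, reference_cds, k=31):
    index: dict[str, set[int]] = {}
    for ri, r in enumerate(reference_cds):
        s = r.seq
        for seq in (s, revcomp(s)):
            for i in range(0, max(1, len(seq) - k + 1), k):
                index.setdefault(seq[i : i + k], set()).add(ri)
    for di, d in enumerate(detected):
        s = d.seq
        cands: set[int] = set()
        for i in range(0, max(1, len(s) - k + 1)):
            hit = index.get(s[i : i + k])
            if hit:
                cands |= hit
        for ri in cands:
            yield di, ri


def annotation_metrics(
    detected: list[CdsFeature],
    reference_cds: list[CdsFeature],
    min_identity: float = 0.95,
    conventional: bool = False,
) -> AnnotationMetrics:
    """Count true-positive CDS by full-length alignment to the reference set.

    Each reference CDS is consumed at most once, greedily by identity.
    Both feature lists must carry nucleotide sequences (``seq``).
    """
    if not detected:
        warnings.warn("no detected CDS: recall undefined, reported 0", stacklevel=2)
        return AnnotationMetrics(len(reference_cds), 0, 0, conventional)
    if any(f.seq is None for f in detected) or any(f.seq is None for f in reference_cds):
        raise ValueError("annotation_metrics requires CDS nucleotide sequences")
    scored: list[tuple[float, int, int]] = []
    for di, ri in _candidate_pairs(detected, reference_cds):
        ident = _full_cover_identity(detected[di].seq, reference_cds[ri].seq)
        if ident is not None and ident >= min_identity:
            scored.append((ident, di, ri))
    scored.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_d: set[int] = set()
    used_r: set[int] = set()
    tp = 0
    for ident, di, ri in scored:
        if di in used_d or ri in used_r:
            continue
        used_d.add(di)
        used_r.add(ri)
        tp += 1
    return AnnotationMetrics(
        n_ref_cds=len(reference_cds),
        n_detected=len(detected),
        n_true_positive=tp,
        conventional=conventional,
    )
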