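"""CDS detection on vector-cleaned contigs and annotation output.

The built-in caller is a plain six-frame ORF scanner (ATG/GTG/TTG start to
stop, bacterial genetic code) intended as a self-contained stand-in; an
external gene caller can be plugged in through a command adapter.  Output is
GFF3 (1-based inclusive, CDS features, attributes percent-encoded) plus a
protein FASTA; externally computed homology hits can be merged into the GFF
attributes from a tab-separated table.
"""

from __future__ import annotations

import csv
import urllib.parse
from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import Seq

from ._seq import revcomp
from .assembly import Contig, ContigSet

DEFAULT_MIN_AA_LEN = 100
DEFAULT_GENETIC_CODE = 11

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class CdsFeature:
    contig_id: str
    start: int  # 0-based half-open, forward strand, stop codon included
    end: int
    strand: str
    frame: int  # 0|1|2: start offset modulo 3 on the reading strand
    translation: str
    cds_id: str
    seq: str | None = None  # nucleotide sequence on the coding strand

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _translate(orf: str, table: int) -> str:
    """Translate an ORF (stop codon included); the start codon becomes M."""
    aa = str(Seq(orf[:-3]).translate(table=table))
    return "M" + aa[1:] if aa else aa


def _scan_strand(seq: str, min_aa_len: int, table: int):
    """Yield (start, end, frame) ORFs on one strand, coordinates local to
    that strand.  Overlapping ORFs in a frame resolve to the longest (the
    first start after the previous stop)."""
    L = len(seq)
    for frame in range(3):
        pending = None  # first start codon since the last stop
        for pos in range(frame, L - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if pending is not None:
                    aa_len = (pos + 3 - pending) // 3 - 1
                    if aa_len >= min_aa_len:
                        yield pending, pos + 3, frame
                    pending = None
            elif pending is None and codon in START_CODONS:
                pending = pos


def find_orfs(
    contig: Contig,
    min_aa_len: int = DEFAULT_MIN_AA_LEN,
    genetic_code: int = DEFAULT_GENETIC_CODE,
) -> list[CdsFeature]:
    """Six-frame ORF scan; coordinates are forward-strand 0-based half-open,
    sorted by start."""
    seq = contig.seq.upper()
    if "X" in seq:
        raise ValueError(
            f"{contig.contig_id}: contig contains masked (X) bases; "
            "reorganize/clean before annotation"
        )
    L = len(seq)
    feats: list[CdsFeature] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for start, end, frame in _scan_strand(s, min_aa_len, genetic_code):
            orf = s[start:end]
            if strand == "+":
                iv = (start, end)
            else:
                iv = (L - end, L - start)
            feats.append(
                CdsFeature(
                    contig_id=contig.contig_id,
                    start=iv[0],
                    end=iv[1],
                    strand=strand,
                    frame=frame,
                    translation=_translate(orf, genetic_code),
                    cds_id="",
                    seq=orf,
                )
            )
    feats.sort(key=lambda f: (f.start, f.end, f.strand))
    for i, f in enumerate(feats):
        f.cds_id = f"{contig.contig_id}_cds{i + 1}"
    return feats


# ---------------------------------------------------------------------------
# GFF3 + protein FASTA
# ---------------------------------------------------------------------------

_GFF_SAFE = "".join(
    c for c in map(chr, range(33, 127)) if c not in ";=&,%\t"
)


def _gff_escape(value: str) -> str:
    return urllib.parse.quote(str(value), safe=_GFF_SAFE + " ")


def read_hits_table(path) -> dict[str, dict]:
    """Tab-separated external homology hits:
    query, subject, identity, evalue, bitscore, description.
    Keeps the best (first) hit per query."""
    hits: dict[str, dict] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or len(row) < 6:
                continue
            q = row[0]
            if q not in hits:
                hits[q] = {
                    "subject": row[1],
                    "identity": row[2],
                    "evalue": row[3],
                    "bitscore": row[4],
                    "description": row[5],
                }
    return hits


def write_annotation(
    contigs: ContigSet,
    features: list[CdsFeature],
    gff_path,
    faa_path=None,
    hits: dict[str, dict] | None = None,
) -> None:
    """Emit GFF3 (1-based inclusive, phase 0 for complete CDS) and protein
    FASTA; optional homology hits become extra GFF attributes."""
    lens = {c.contig_id: c.length for c in contigs}
    lines = ["##gff-version 3"]
    for cid in lens:
        lines.append(f"##sequence-region {cid} 1 {lens[cid]}")
    for f in features:
        if f.contig_id not in lens:
            raise ValueError(f"{f.cds_id}: unknown contig {f.contig_id!r}")
        if not 0 <= f.start < f.end <= lens[f.contig_id]:
            raise ValueError(
                f"{f.cds_id}: interval {f.interval} outside contig "
                f"{f.contig_id} (length {lens[f.contig_id]})"
            )
        attrs = [f"ID={_gff_escape(f.cds_id)}", f"frame={f.frame}"]
        if hits and f.cds_id in hits:
            h = hits[f.cds_id]
            attrs.append(f"subject={_gff_escape(h['subject'])}")
            attrs.append(f"pct_identity={_gff_escape(h['identity'])}")
            attrs.append(f"evalue={_gff_escape(h['evalue'])}")
            attrs.append(f"Note={_gff_escape(h['description'])}")
        lines.append(
            "\t".join(
                [
                    f.contig_id,
                    "fosmidforge",
                    "CDS",
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    "0",
                    ";".join(attrs),
                ]
            )
        )
    Path(gff_path).write_text("\n".join(lines) + "\n")
    if faa_path is not None:
        with open(faa_path, "w") as fh:
            for f in features:
                fh.write(f">{f.cds_id} {f.contig_id}:{f.start + 1}-{f.end}({f.strand})\n")
                fh.write(f.translation + "\n")


def read_annotation(gff_path, contigs: ContigSet | None = None) -> list[CdsFeature]:
    """Parse a GFF3 written by :func:`write_annotation` back into features;
    sequences and translations are recomputed when contigs are supplied."""
    seqs = {c.contig_id: c.seq for c in contigs} if contigs else {}
    feats: list[CdsFeature] = []
    for line in Path(gff_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9 or cols[2] != "CDS":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
        )
        start, end = int(cols[3]) - 1, int(cols[4])
        strand = cols[6]
        translation = ""
        nt = None
        if cols[0] in seqs:
            nt = seqs[cols[0]][start:end]
            if strand == "-":
                nt = revcomp(nt)
            translation = _translate(nt, DEFAULT_GENETIC_CODE)
        feats.append(
            CdsFeature(
                contig_id=cols[0],
                start=start,
                end=end,
                strand=strand,
                frame=int(attrs.get("frame", 0)),
                translation=translation,
                cds_id=urllib.parse.unquote(attrs.get("ID", "")),
                seq=nt,
            )
        )
    return feats
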