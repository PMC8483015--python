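"""Pipeline orchestration: configuration, per-sample execution, run manifest
and the self-contained HTML report.

Two invocations cover the whole analysis: ``assemble`` (filter reads,
subsample, assemble, locate/mask/remove the cloning vector, re-organize for
circularity, report) and ``annotate`` (ORF calling + GFF/FASTA + report).
All internal coordinates are 0-based half-open; every file format that
leaves the package (GFF3, report tables) is 1-based inclusive, converted at
the single writing point.
"""

from __future__ import annotations

import dataclasses
import hashlib
import html
import json
import tarfile
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from . import annotate as _annotate
from . import assembly as _assembly
from . import readprep as _readprep
from . import vectorops as _vectorops
from .assembly import Contig, ContigSet

__version__ = "0.1.0"


@dataclass
class Config:
    """Pipeline parameters; every value can be overridden from a YAML file
    or the command line and is echoed into the run manifest."""

    target_coverage: float = 300.0
    expected_len: int = 40_000
    min_mean_q: float = 20.0
    max_n_frac: float = 0.1
    min_read_len: int = 50
    assembler: str = "builtin"  # builtin | external
    external_cmd: str = ""
    k: int = 31
    min_count: int = 8
    min_identity: float = 0.9
    min_match_len: int = 50
    min_contig_len: int = 1000
    min_contig_cov: float = 8.0
    min_join_overlap: int = 20
    min_join_identity: float = 0.95
    end_slack: int = 10
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# sample discovery
# ---------------------------------------------------------------------------

_FASTQ_SUFFIXES = (".fastq", ".fq", ".fastq.gz", ".fq.gz")


def _strip_fastq_suffix(name: str) -> str:
    for suf in _FASTQ_SUFFIXES:
        if name.endswith(suf):
            return name[: -len(suf)]
    return name


def discover_samples(source, workdir=None) -> dict[str, dict[str, Path]]:
    """Map sample names to their FASTQ files from a directory or tar/zip
    archive of ``SAMPLE_R1/_R2/_single`` files."""
    source = Path(source)
    if source.is_dir():
        root = source
    else:
        root = Path(workdir or source.parent) / f"_extracted_{source.stem}"
        root.mkdir(parents=True, exist_ok=True)
        if tarfile.is_tarfile(source):
            with tarfile.open(source) as tf:
                tf.extractall(root, filter="data")
        elif zipfile.is_zipfile(source):
            with zipfile.ZipFile(source) as zf:
                zf.extractall(root)
        else:
            raise ValueError(f"{source}: not a directory, tar or zip archive")
    samples: dict[str, dict[str, Path]] = {}
    for p in sorted(root.rglob("*")):
        if not p.is_file() or not p.name.endswith(_FASTQ_SUFFIXES):
            continue
        stem = _strip_fastq_suffix(p.name)
        for tag, role in (("_R1", "r1"), ("_R2", "r2"), ("_single", "single")):
            if stem.endswith(tag):
                samples.setdefault(stem[: -len(tag)], {})[role] = p
                break
    return samples


def _load_sample(files: dict[str, Path]) -> list[_readprep.ReadSet]:
    sets = []
    if "r1" in files or "r2" in files:
        if "r1" not in files or "r2" not in files:
            raise ValueError("paired sample is missing one mate file")
        sets.append(
            _readprep.ReadSet(
                "paired",
                _readprep.read_fastq(files["r1"]),
                _readprep.read_fastq(files["r2"]),
            )
        )
    if "single" in files:
        sets.append(_readprep.ReadSet("single", _readprep.read_fastq(files["single"])))
    if not sets:
        raise ValueError("no FASTQ files found for sample")
    return sets


# ---------------------------------------------------------------------------
# per-sample pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def process_sample(
    name: str,
    read_sets: list[_readprep.ReadSet],
    vector: str,
    config: Config,
    outdir: Path,
) -> dict:
    """filter -> subsample -> assemble -> detect/mask -> filter_contigs ->
    reorganize for one sample; returns the manifest record."""
    outdir.mkdir(parents=True, exist_ok=True)
    record: dict = {"sample": name, "status": "ok"}
    n_in = sum(rs.n_reads for rs in read_sets)
    cov_in = sum(_readprep.estimate_coverage(rs, config.expected_len) for rs in read_sets)

    filtered = [
        _readprep.filter_reads(
            rs, config.min_mean_q, config.max_n_frac, config.min_read_len
        )
        for rs in read_sets
    ]
    share = config.target_coverage / len(filtered)
    sampled = [
        _readprep.subsample_reads(rs, share, config.expected_len, config.seed + i)
        for i, rs in enumerate(filtered)
    ]
    n_used = sum(rs.n_reads for rs in sampled)
    if n_used == 0:
        raise ValueError("all reads removed by filtering")
    cov_used = sum(_readprep.estimate_coverage(rs, config.expected_len) for rs in sampled)
    record.update(
        reads_in=n_in,
        reads_used=n_used,
        coverage_in=round(cov_in, 2),
        coverage_used=round(cov_used, 2),
    )

    pooled = _pool_readsets(sampled)
    if config.assembler == "external":
        contigs = _assembly.run_external_assembler(
            config.external_cmd, pooled, outdir / "asm"
        )
    else:
        contigs = _assembly.assemble_reads(pooled, k=config.k, min_count=config.min_count)
    record["contigs_raw"] = len(contigs)

    matches_per: dict[str, list] = {}
    masked: ContigSet = []
    for c in contigs:
        m = _vectorops.detect_vector(
            c, vector, config.min_identity, config.min_match_len
        )
        matches_per[c.contig_id] = m
        masked.append(_vectorops.mask_vector(c, m))
    masked_path = outdir / f"{name}_masked.fasta"
    _write_fasta(masked, masked_path)
    _write_vector_gff(matches_per, contigs, outdir / f"{name}_vector.gff3")

    kept = _vectorops.filter_contigs(
        contigs, config.min_contig_len, config.min_contig_cov
    )
    record["contigs_filtered"] = len(kept)

    finals: ContigSet = []
    cases = []
    for c in kept:
        outcome = _vectorops.reorganize_contig(
            c,
            matches_per[c.contig_id],
            config.min_join_overlap,
            config.min_join_identity,
            config.end_slack,
        )
        cases.append({"contig": c.contig_id, "case": outcome.case,
                      "join_overlap_len": outcome.join_overlap_len,
                      "flagged": outcome.flagged})
        finals.extend(outcome.contigs_out)
    finals = [
        Contig(f"{name}_contig{i + 1}", c.seq, c.mean_cov)
        for i, c in enumerate(finals)
        if c.seq
    ]
    final_path = outdir / f"{name}_assembled.fasta"
    _write_fasta(finals, final_path)
    record.update(
        vector_cases=cases,
        contigs_final=len(finals),
        final_contigs=[
            {"id": c.contig_id, "length": c.length, "mean_cov": round(c.mean_cov, 2)}
            for c in finals
        ],
        files={
            "masked_fasta": str(masked_path),
            "vector_gff": str(outdir / f"{name}_vector.gff3"),
            "assembled_fasta": str(final_path),
        },
    )
    record["checksums"] = {
        k: _sha256(Path(v)) for k, v in record["files"].items()
    }
    return record


def _pool_readsets(read_sets):
    """Pool mixed single/paired sets into one set for the assembler (the
    graph only consumes sequences, pairing is irrelevant to it)."""
    if len(read_sets) == 1:
        return read_sets[0]
    reads = [r for rs in read_sets for r in rs.iter_all()]
    return _readprep.ReadSet("single", reads)


def _write_fasta(contigs: ContigSet, path: Path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            cov = "NA" if c.mean_cov != c.mean_cov else f"{c.mean_cov:.1f}"
            fh.write(f">{c.contig_id} length={c.length} cov={cov}\n")
            for i in range(0, c.length, 80):
                fh.write(c.seq[i : i + 80] + "\n")


def _write_vector_gff(matches_per: dict, contigs: ContigSet, path: Path) -> None:
    lines = ["##gff-version 3"]
    for c in contigs:
        for m in matches_per.get(c.contig_id, []):
            lines.append(
                "\t".join(
                    [
                        c.contig_id,
                        "fosmidforge",
                        "vector_match",
                        str(m.start + 1),
                        str(m.end),
                        f"{m.identity:.4f}",
                        m.strand,
                        ".",
                        f"ID=vector_{c.contig_id}_{m.start + 1};"
                        f"vector_span={m.vector_span[0] + 1}-{m.vector_span[1]}",
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------

def run_assemble(samples_source, vector_fasta, config: Config, outdir) -> dict:
    """Run the assembly half of the pipeline over a batch of samples.

    A failing sample is recorded with its error and skipped; the batch
    continues.  Returns the manifest (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vec_recs = list(SeqIO.parse(str(vector_fasta), "fasta"))
    if not vec_recs:
        raise ValueError(f"{vector_fasta}: no sequence found")
    vector = str(vec_recs[0].seq).upper()
    samples = discover_samples(samples_source, workdir=outdir)
    manifest: dict = {
        "run": "assemble",
        "version": __version__,
        "parameters": config.to_dict(),
        "vector": {"id": vec_recs[0].id, "length": len(vector)},
        "samples": [],
    }
    pooled: ContigSet = []
    for name in sorted(samples):
        try:
            read_sets = _load_sample(samples[name])
            rec = process_sample(name, read_sets, vector, config, outdir / name)
            for rec_contig in SeqIO.parse(rec["files"]["assembled_fasta"], "fasta"):
                pooled.append(
                    Contig(rec_contig.id, str(rec_contig.seq), float("nan"))
                )
        except Exception as exc:  # failing sample must not kill the batch
            rec = {"sample": name, "status": "failed", "error": str(exc)}
        manifest["samples"].append(rec)
    _write_fasta(pooled, outdir / "assembled.fasta")
    manifest["pooled_fasta"] = str(outdir / "assembled.fasta")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    report = build_report(manifest)
    (outdir / "report.html").write_text(report)
    return manifest


def run_annotate(contigs_fasta, outdir, min_aa_len: int = 100,
                 hits_table=None) -> list:
    """Annotate assembled contigs: ORF calling, GFF3 + protein FASTA,
    HTML report section."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = [
        Contig(rec.id, str(rec.seq).upper(), float("nan"))
        for rec in SeqIO.parse(str(contigs_fasta), "fasta")
    ]
    feats = []
    for c in contigs:
        feats.extend(_annotate.find_orfs(c, min_aa_len=min_aa_len))
    hits = _annotate.read_hits_table(hits_table) if hits_table else None
    _annotate.write_annotation(
        contigs, feats, outdir / "annotation.gff3", outdir / "proteins.faa", hits
    )
    manifest = {
        "run": "annotate",
        "version": __version__,
        "parameters": {"min_aa_len": min_aa_len},
        "samples": [],
        "annotation": {
            "n_contigs": len(contigs),
            "n_cds": len(feats),
            "per_contig": [
                {
                    "contig": c.contig_id,
                    "length": c.length,
                    "cds": [
                        {
                            "id": f.cds_id,
                            "start": f.start + 1,
                            "end": f.end,
                            "strand": f.strand,
                            "aa_len": len(f.translation),
                        }
                        for f in feats
                        if f.contig_id == c.contig_id
                    ],
                }
                for c in contigs
            ],
        },
        "files": {
            "gff": str(outdir / "annotation.gff3"),
            "proteins": str(outdir / "proteins.faa"),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "report.html").write_text(build_report(manifest))
    return feats


# ---------------------------------------------------------------------------
# HTML report (self-contained: no remote assets, inline SVG graphics)
# ---------------------------------------------------------------------------

_CSS = """
body{font-family:sans-serif;margin:2em;color:#222}
h1{color:#205080}h2{border-bottom:1px solid #ccc;padding-bottom:.2em}
table{border-collapse:collapse;margin:1em 0}
td,th{border:1px solid #bbb;padding:.3em .6em;text-align:left}
th{background:#eef2f7}.failed{color:#a00}
"""


def _scatter_svg(points, width=520, height=340) -> str:
    """Coverage-vs-length scatter as inline SVG; one dot per final contig."""
    if not points:
        return "<p>No contigs to plot.</p>"
    pad = 45
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    xmax = max(xs) * 1.05 or 1
    ymax = max(ys) * 1.05 or 1
    parts = [
        f'<svg width="{width}" height="{height}" role="img" '
        f'xmlns="http://www.w3.org/2000/svg">',
        f'<rect width="{width}" height="{height}" fill="#fff"/>',
        f'<line x1="{pad}" y1="{height - pad}" x2="{width - 10}" '
        f'y2="{height - pad}" stroke="#444"/>',
        f'<line x1="{pad}" y1="{height - pad}" x2="{pad}" y2="10" stroke="#444"/>',
        f'<text x="{width // 2}" y="{height - 8}" font-size="12" '
        f'text-anchor="middle">contig length (bp)</text>',
        f'<text x="12" y="{height // 2}" font-size="12" text-anchor="middle" '
        f'transform="rotate(-90 12 {height // 2})">mean coverage (X)</text>',
    ]
    for label, frac in ((0, 0.0), (round(xmax), 1.0)):
        x = pad + frac * (width - 10 - pad)
        parts.append(
            f'<text x="{x:.0f}" y="{height - pad + 14}" font-size="10" '
            f'text-anchor="middle">{label}</text>'
        )
    for label, frac in ((0, 0.0), (round(ymax), 1.0)):
        y = height - pad - frac * (height - pad - 10)
        parts.append(
            f'<text x="{pad - 4}" y="{y:.0f}" font-size="10" '
            f'text-anchor="end">{label}</text>'
        )
    for x, y, name in points:
        px = pad + (x / xmax) * (width - 10 - pad)
        py = height - pad - (y / ymax) * (height - pad - 10)
        parts.append(
            f'<circle cx="{px:.1f}" cy="{py:.1f}" r="4" fill="#2a7" '
            f'fill-opacity="0.7"><title>{html.escape(name)}</title></circle>'
        )
    parts.append("</svg>")
    return "".join(parts)


def build_report(manifest: dict) -> str:
    """Render the run manifest as a single self-contained HTML page."""
    out = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>fosmidforge report</title>",
        f"<style>{_CSS}</style></head><body>",
        f"<h1>fosmidforge {html.escape(str(manifest.get('run', '')))} report</h1>",
        "<h2>Inputs and parameters</h2><table>",
    ]
    for key, val in (manifest.get("parameters") or {}).items():
        out.append(
            f"<tr><th>{html.escape(str(key))}</th>"
            f"<td>{html.escape(str(val))}</td></tr>"
        )
    out.append("</table>")
    if "vector" in manifest:
        v = manifest["vector"]
        out.append(
            f"<p>Cloning vector: <b>{html.escape(str(v['id']))}</b>, "
            f"{v['length']} bp</p>"
        )

    samples = manifest.get("samples", [])
    if manifest.get("run") == "assemble":
        out.append("<h2>Assembly and vector detection</h2>")
        if not samples:
            out.append("<p><i>No samples.</i></p>")
        else:
            out.append(
                "<table><tr><th>sample</th><th>status</th><th>reads in</th>"
                "<th>reads used</th><th>coverage</th><th>raw contigs</th>"
                "<th>final contigs</th><th>vector handling</th></tr>"
            )
            for s in samples:
                if s.get("status") != "ok":
                    out.append(
                        f"<tr class='failed'><td>{html.escape(s['sample'])}</td>"
                        f"<td>failed: {html.escape(s.get('error', ''))}</td>"
                        "<td></td><td></td><td></td><td></td><td></td><td></td></tr>"
                    )
                    continue
                cases = ", ".join(c["case"] for c in s.get("vector_cases", [])) or "-"
                out.append(
                    f"<tr><td>{html.escape(s['sample'])}</td><td>ok</td>"
                    f"<td>{s['reads_in']}</td><td>{s['reads_used']}</td>"
                    f"<td>{s['coverage_used']}X</td><td>{s['contigs_raw']}</td>"
                    f"<td>{s['contigs_final']}</td><td>{html.escape(cases)}</td></tr>"
                )
            out.append("</table>")
        out.append("<h2>Contig coverage vs length</h2>")
        points = [
            (fc["length"], 0.0 if fc["mean_cov"] != fc["mean_cov"] else fc["mean_cov"],
             fc["id"])
            for s in samples
            if s.get("status") == "ok"
            for fc in s.get("final_contigs", [])
        ]
        out.append(_scatter_svg(points))
        out.append("<h2>Download files</h2><table><tr><th>sample</th>"
                   "<th>file</th><th>path</th></tr>")
        for s in samples:
            for kind, path in (s.get("files") or {}).items():
                name = Path(path).name
                out.append(
                    f"<tr><td>{html.escape(s['sample'])}</td>"
                    f"<td>{html.escape(kind)}</td>"
                    f"<td><a href='{html.escape(name)}'>{html.escape(name)}</a>"
                    "</td></tr>"
                )
        if "pooled_fasta" in manifest:
            name = Path(manifest["pooled_fasta"]).name
            out.append(
                f"<tr><td>all</td><td>pooled</td>"
                f"<td><a href='{html.escape(name)}'>{html.escape(name)}</a></td></tr>"
            )
        out.append("</table>")

    if "annotation" in manifest:
        ann = manifest["annotation"]
        out.append(
            f"<h2>Annotation</h2><p>{ann['n_cds']} CDS over "
            f"{ann['n_contigs']} contig(s).</p>"
        )
        for pc in ann["per_contig"]:
            out.append(
                f"<h3>{html.escape(pc['contig'])} ({pc['length']} bp)</h3>"
                "<table><tr><th>CDS</th><th>start</th><th>end</th>"
                "<th>strand</th><th>aa</th></tr>"
            )
            for f in pc["cds"]:
                out.append(
                    f"<tr><td>{html.escape(f['id'])}</td><td>{f['start']}</td>"
                    f"<td>{f['end']}</td><td>{f['strand']}</td>"
                    f"<td>{f['aa_len']}</td></tr>"
                )
            out.append("</table>")
    out.append("</body></html>")
    return "".join(out)
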