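"""Batch pipeline orchestration, manifest, HTML report and CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from fosmidforge import build_construct, random_dna, simulate_reads
from fosmidforge.cli import main as cli_main
from fosmidforge.interface import Config, build_report, discover_samples, run_assemble
from fosmidforge.readprep import write_readset
from fosmidforge.simulate import ReadProfile


@pytest.fixture(scope="module")
def small_batch(tmp_path_factory):
    """Three small fosmid samples (6 kb inserts, 1.2 kb synthetic vector) and
    one unreadable sample, written as FASTQ files."""
    root = tmp_path_factory.mktemp("batch")
    rng = np.random.default_rng(424242)
    vector = random_dna(rng, 1200)
    (root / "vector.fasta").write_text(f">vec_synthetic\n{vector}\n")
    reads_dir = root / "reads"
    reads_dir.mkdir()
    truth = {}
    modes = ["internal", "extremity_left", "internal"]
    for i, mode in enumerate(modes):
        chunk = random_dna(rng, 6000)
        c = build_construct(
            chunk, vector, mode=mode, overlap_len=400 if mode == "internal" else 0,
            insertion_pos=2500 if mode == "internal" else None,
            construct_id=f"s{i}", source=("g", 0, 6000),
        )
        rs = simulate_reads(
            c, ReadProfile(layout="paired", coverage=80.0, seed=100 + i)
        )
        write_readset(rs, reads_dir / f"sample{i}")
        truth[f"sample{i}"] = chunk
    # a sample whose mate file is missing -> must fail gracefully
    rs_bad = simulate_reads(
        build_construct(random_dna(rng, 3000), vector, mode="extremity_right",
                        overlap_len=0, construct_id="bad", source=("g", 0, 3000)),
        ReadProfile(layout="paired", coverage=20.0, seed=999),
    )
    paths = write_readset(rs_bad, reads_dir / "broken")
    paths[1].unlink()  # drop R2
    return {"root": root, "reads": reads_dir, "vector": vector, "truth": truth}


@pytest.fixture(scope="module")
def batch_run(small_batch, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    cfg = Config(target_coverage=60.0, expected_len=6000, min_count=4, seed=7)
    manifest = run_assemble(
        small_batch["reads"], small_batch["root"] / "vector.fasta", cfg, out
    )
    return {"manifest": manifest, "out": out, **small_batch}


class TestDiscoverSamples:
    def test_directory_layout(self, small_batch):
        samples = discover_samples(small_batch["reads"])
        assert set(samples) == {"sample0", "sample1", "sample2", "broken"}
        assert set(samples["sample0"]) == {"r1", "r2"}

    def test_zip_archive(self, small_batch, tmp_path):
        import zipfile

        arch = tmp_path / "batch.zip"
        with zipfile.ZipFile(arch, "w") as zf:
            for p in small_batch["reads"].glob("sample0_*.fastq"):
                zf.write(p, p.name)
        samples = discover_samples(arch, workdir=tmp_path)
        assert set(samples) == {"sample0"}


class TestRunAssemble:
    def test_good_samples_yield_one_final_contig(self, batch_run):
        recs = {s["sample"]: s for s in batch_run["manifest"]["samples"]}
        for name in ("sample0", "sample1", "sample2"):
            assert recs[name]["status"] == "ok"
            assert recs[name]["contigs_final"] == 1

    def test_failing_sample_recorded_not_fatal(self, batch_run):
        recs = {s["sample"]: s for s in batch_run["manifest"]["samples"]}
        assert recs["broken"]["status"] == "failed"
        assert "mate" in recs["broken"]["error"]

    def test_final_contigs_recover_inserts(self, batch_run):
        from fosmidforge import revcomp

        recs = {s["sample"]: s for s in batch_run["manifest"]["samples"]}
        for name, chunk in batch_run["truth"].items():
            rec = recs[name]
            from Bio import SeqIO

            [contig] = list(SeqIO.parse(rec["files"]["assembled_fasta"], "fasta"))
            seq = str(contig.seq)
            doubled = chunk + chunk
            assert seq in doubled or revcomp(seq) in doubled

    def test_pooled_fasta_is_union(self, batch_run):
        from Bio import SeqIO

        pooled = list(SeqIO.parse(batch_run["out"] / "assembled.fasta", "fasta"))
        assert len(pooled) == 3

    def test_manifest_checksums_match_files(self, batch_run):
        import hashlib
        from pathlib import Path

        for s in batch_run["manifest"]["samples"]:
            if s["status"] != "ok":
                continue
            for kind, path in s["files"].items():
                digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
                assert s["checksums"][kind] == digest

    def test_manifest_json_round_trips(self, batch_run):
        on_disk = json.loads((batch_run["out"] / "manifest.json").read_text())
        assert on_disk["parameters"] == batch_run["manifest"]["parameters"]

    def test_rerun_is_deterministic(self, small_batch, tmp_path):
        cfg = Config(target_coverage=60.0, expected_len=6000, min_count=4, seed=7)
        outs = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            run_assemble(small_batch["reads"], small_batch["root"] / "vector.fasta",
                         cfg, out)
            outs.append((out / "assembled.fasta").read_bytes())
        assert outs[0] == outs[1]


class TestBuildReport:
    def test_report_structure(self, batch_run):
        html = (batch_run["out"] / "report.html").read_text()
        assert html.count("<tr><td>sample") >= 3
        assert "<svg" in html and "circle" in html
        assert "Inputs and parameters" in html

    def test_report_is_offline(self, batch_run):
        html = (batch_run["out"] / "report.html").read_text()
        assert "http://" not in html.replace("http://www.w3.org", "")
        assert "https://" not in html
        assert "<script src" not in html and "<link" not in html

    def test_empty_manifest_renders_notice(self):
        html = build_report({"run": "assemble", "parameters": {}, "samples": []})
        assert "No samples" in html


class TestCli:
    def test_simulate_then_assemble_then_annotate(self, tmp_path, rng):
        runner = CliRunner()
        genome = random_dna(rng, 30_000)
        vector = random_dna(rng, 1000)
        (tmp_path / "g.fa").write_text(f">g\n{genome}\n")
        (tmp_path / "v.fa").write_text(f">v_synthetic\n{vector}\n")
        sim = tmp_path / "sim"
        r = runner.invoke(cli_main, [
            "simulate", "--genome", str(tmp_path / "g.fa"),
            "--vector", str(tmp_path / "v.fa"), "--n-constructs", "2",
            "--chunk-len", "5000", "--overlap", "300", "--mode", "internal",
            "--coverage", "60", "--seed", "3", "--out", str(sim),
        ])
        assert r.exit_code == 0, r.output
        assert (sim / "truth_manifest.json").exists()

        asm = tmp_path / "asm"
        r = runner.invoke(cli_main, [
            "assemble", "--reads", str(sim), "--vector", str(tmp_path / "v.fa"),
            "--coverage", "60", "--seed", "3", "--out", str(asm),
        ])
        assert r.exit_code == 0, r.output
        assert "2/2 samples assembled" in r.output

        ann = tmp_path / "ann"
        r = runner.invoke(cli_main, [
            "annotate", "--contigs", str(asm / "assembled.fasta"),
            "--min-aa-len", "60", "--out", str(ann),
        ])
        assert r.exit_code == 0, r.output
        assert (ann / "annotation.gff3").exists()

        ev = tmp_path / "ev"
        r = runner.invoke(cli_main, [
            "evaluate", "--contigs", str(asm / "assembled.fasta"),
            "--truth", str(sim / "truth_manifest.json"), "--out", str(ev),
        ])
        assert r.exit_code == 0, r.output
        metrics = json.loads((ev / "assembly_metrics.json").read_text())
        assert len(metrics) == 2
        for agg in metrics.values():
            assert agg["precision"] > 0.99 and agg["recall"] > 0.99
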