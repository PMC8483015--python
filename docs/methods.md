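# Methods

## Scope and model

fosmidforge models the sequencing of a *circular* cloned molecule: an
environmental DNA insert (nominally 35–40 kb) plus a known vector
backbone. The central consequence of circularity is that a correct
assembly is only defined up to rotation and strand, and that the vector
can appear anywhere on the assembled contig — including split across the
two ends when the assembler linearises the circle inside the vector. All
pipeline stages downstream of assembly are written against this model.

Internal coordinates are 0-based half-open everywhere; GFF3 and report
tables are 1-based inclusive, converted only at the writing/parsing
points.

## Simulation

`extract_chunks` samples chunk start positions uniformly with
replacement; chunks may overlap. `build_construct` realises three
insertion modes: `vector+chunk`, `chunk+vector`, and internal insertion
`chunk[:p]+vector+chunk[p:]`; in the internal mode the first
`overlap_len` (default 500) bases of the linearised sequence are
duplicated at its end, which is how a circular clone presents itself to
an assembler reading a linear reference. Which end carries the
duplication is an arbitrary convention (the construct is circular);
duplicating the *start* at the *end* is recorded in the truth manifest.

Reads are drawn from the linear reference: `n = ceil(coverage·L /
read_len)` single reads (pairs: `ceil(coverage·L / 2·read_len)`
fragments of Normal(200, 10) length, resampled into `[read_len, L]`,
mate 2 reverse-complemented). Errors are uniform per-base substitutions;
qualities are a constant Q37. This deliberately ignores
platform-specific error spectra, indels, quality decay, PCR duplicates
and chimeras: the pipeline's decision points (abundance thresholds,
identity thresholds, overlap detection) see realistic *rates*, not
realistic *patterns*, so passing tests demonstrate correctness of the
pipeline logic, not robustness to every real-world artifact.

`random_genome` plants stop-free genes (ATG + sense codons + stop,
~280±90 aa, either strand) between short random intergenic runs,
approximating bacterial coding density so that annotation metrics are
exercised on gene-dense sequence. Real genomes additionally contain
repeats, skewed composition and operon structure that the generator does
not reproduce; the assembler's behaviour on long repeats is therefore
covered only by the dedicated collapsed-repeat evaluation test.

## Read preparation

Coverage is estimated as total bases over the *nominal insert length*
(default 40,000 bp, configurable); the vector contribution to read depth
is small and the estimate is only used to size the subsample.
Filtering drops reads with mean phred < 20, N fraction > 0.1 or length
< 50 (invented defaults, all configurable); a pair is dropped whole if
either mate fails. Subsampling permutes sampling units (pairs stay
together) and keeps the shortest prefix reaching
`target_coverage·expected_len` bases, preserving input order. Adapter
trimming is delegated to an external-tool hook; it is platform-specific
preprocessing, not part of the computation modelled here.

## Built-in assembler

Canonical k-mers (lexicographic min of k-mer and reverse complement,
odd k so no k-mer is its own reverse complement) are counted in a single
numba pass (2-bit rolling codes for k ≤ 31; a plain dictionary
otherwise). K-mers below `min_count` are discarded; unitigs are compacted
over the directed graph of both orientations, with each canonical node
emitted once. Tips (dead-ended unitigs shorter than 2k attached to a
branch) are clipped for up to four rounds. A pure cycle — the expected
shape for a correctly closed circular fosmid — is emitted as a linear
contig whose last k−1 bases repeat its first k−1. Contig coverage is the
mean k-mer abundance along the path.

There is no bubble popping and no greedy branch resolution: at a fork,
extension stops. This makes `min_count` the only defence against
recurrent sequencing errors forming bubble branches. At the pipeline's
default 300X with ~0.5% substitution errors, a specific error k-mer
recurs with Poisson(0.5) abundance, so `min_count = 8` keeps the
probability of a surviving bubble per fosmid below ~1%, while true
k-mers sit near 200–240X. The default is documented as suited to
deeply-covered fosmid data (≥100X); low-coverage use requires lowering
both `min_count` and expectations.

Terminal k-mers of a *linear* molecule are covered only by reads
starting at the very ends, so extremity-mode assemblies lose a few bases
(typically < 10 per end) to the abundance floor; internal-mode (circular)
assemblies do not, because the overlap-duplicated ends share k-mers with
well-covered interior sequence.

## Alignment kernel

One banded affine-gap DP kernel (numba) serves vector detection,
terminal-overlap verification and evaluation. A gap of length g costs
`open + g·extend`; the two scoring schemes are match +1 / mismatch −2
with linear gap −3 (vector detection) and with open −4 / extend −1
(evaluation). Tie-breaks are fixed — diagonal over query-gap over
target-gap, gap opening over extension, first maximal cell in row-major
order for local alignment — so an independent full-matrix DP reproduces
the identical optimum, which the test suite asserts on a fixture suite
of small instances. Problems up to ~9M cells run with a full band
(exact); larger ones are seeded with exact 15-mers, chained by diagonal,
and aligned in a band that doubles whenever the traceback touches a band
edge away from the matrix border. Co-linear chains on different
diagonals (a deletion such as a collapsed repeat copy shifts the
diagonal) are merged into one band of up to 4096 diagonals.

## Vector handling and circular re-organization

Detection reports maximal local alignments of either vector strand with
identity ≥ 0.9 over ≥ 50 contig bases (both configurable); on small
problems it iterates exact Smith–Waterman, masking each accepted span.
Masking is presentational (`X` over the union of spans); excision is
coordinate-driven, so masking then re-organizing equals re-organizing
directly.

Re-organization distinguishes: no match; a match within 10 bp
(`end_slack`) of a contig end — the vector span is excised and the
ragged ≤10 bp terminal residue dropped, since it belongs to the other
side of the circle; an internal match — flanks joined when
`detect_terminal_overlap` finds a suffix/prefix overlap ≥ 20 bp at
identity ≥ 0.95 (exact check first, then candidate lengths proposed by
15-mer anchors and verified by global alignment), keeping one copy of
the overlap, else split in two. Keeping one copy makes joined lengths
match the source insert exactly on simulated data. Two matches touching
opposite extremities are the circular-break-inside-the-vector case: both
are trimmed and the middle piece returned as `trimmed_extremity`. Any
other multi-occurrence pattern (chimeric assembly) is conservative:
every span is excised, nothing is joined, and the outcome is flagged
(`multi_vector`) — a fifth outcome case beyond the four regular ones,
added because the situation needs an honest label rather than a forced
fit.

## Annotation

The built-in caller scans all six frames for ORFs from the first
ATG/GTG/TTG after the previous stop to the next stop, keeping those with
≥ 100 codons (configurable); overlapping same-frame ORFs resolve to the
longest, nested opposite-strand ORFs are both reported. Translation uses
the bacterial genetic code (table 11) with the start codon rendered as
M. This is a stand-in with no sensitivity claims against trained gene
callers — an external caller adapter is the production path. GFF3 output
carries phase 0 (complete CDS), percent-encoded attributes, and
round-trips through the bundled parser.

## Evaluation

`assembly_metrics` aligns each contig (longest first, better strand) to
the *doubled* reference insert so rotations align end-to-end, and
credits matched reference positions (modulo the reference length) once
across all contigs; precision divides by contig length, recall by
reference length. The reference is the vector-free insert, since the
pipeline's outputs are vector-cleaned; the truth manifest retains enough
information to rebuild the vector-included reference if wanted.
`annotation_metrics` declares a detected CDS a true positive when it
aligns to an unconsumed reference CDS covering it start to end (0 bp
tolerance) at identity ≥ 0.95 (floor invented, configurable), consuming
references greedily by identity. The two ratios are computed exactly as
the benchmark prints them — precision over the reference count, recall
over the detected count, i.e., swapped relative to convention —
implemented verbatim rather than second-guessed, with a
`conventional=True` switch for the standard definitions.

## Acceptance study sizes

The acceptance suite and `scripts/acceptance.py` run 20 constructs of
40 kb from three synthetic 200 kb genomes at 300X paired coverage, half
error-free and half at 0.5% substitutions — the conditions the rest of
the toolkit defaults to — which completes in well under a minute per
stage on one CPU. The oracle-equivalence suite uses ≥ 50 instances of
≤ 2 kb so the pure-Python full-matrix oracles stay fast.

## Known limitations

* The built-in assembler targets deeply covered, essentially
  repeat-free fosmid-scale molecules; repeats longer than k collapse or
  split contigs (by design, mirrored in the collapsed-repeat metric
  test), and there is no scaffolding or error correction.
* The error model is substitution-only; indel-rich platforms need the
  external assembler path.
* Homology annotation (nr/SwissProt/COG searches, taxonomic binning) is
  out of scope; externally computed hits can be attached to the report
  via a tabular importer.
* The ORF caller over-calls relative to trained gene finders on real
  genomes (no RBS model, no start refinement); the swapped benchmark
  metric definitions make its printed "recall" sensitive to that
  over-calling.
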