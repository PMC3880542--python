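# Methods

## Screening model

The screen treats a one-colour microarray experiment as a gene-by-sample
matrix of non-negative intensities with a two-level condition label
(control vs treated). Three modelling commitments define the
differential-expression stage:

1. **Per-chip percentile normalization.** Each array is divided by its own
   50th-percentile intensity, so all chips share median 1. This removes
   global chip effects (labelling efficiency, scanner gain) and is exactly
   invariant to per-array scale factors. The percentile is configurable in
   (0, 100]; an array whose reference percentile is not positive (e.g. all
   zeros) is rejected outright rather than silently propagating infinities.
2. **Signed fold change on arithmetic means of normalized linear
   intensities.** For ratio r = mean(treated)/mean(control), the signed
   value is r if r ≥ 1 and −1/r otherwise. Magnitudes are therefore never
   in (−1, 1), antisymmetry holds under condition swap
   (FC(x→y) = −FC(y→x)), and a ratio of exactly 1 is reported +1. Genes
   with a zero control mean admit no ratio and are reported in a rejection
   list with a diagnostic, never dropped silently; a zero treated mean is
   reported as −∞ (unbounded down-regulation). No variance filter or
   moderated statistic is applied — the screen is fold-change-only by
   design, and the cutoff comparison is inclusive (|FC| ≥ τ, default
   τ = 1.3).
3. **Probe collapsing** (real-data mode only) takes the per-gene median over
   probes, which is robust and order-independent.

Partitions (up/down/unchanged) are returned in a deterministic order —
|FC| descending, ties broken by gene identifier — so all downstream files
are byte-reproducible.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P(X ≥ k) ("at least k" convention, computed via the survival function, never
a normal approximation) and Benjamini–Hochberg step-up adjustment. Two
choices affect p_adj and are deliberate:

- the universe defaults to every gene in the annotation table, but any
  explicit reference set (e.g. all genes on the array) can be supplied; the
  pipeline passes the full synthetic gene set;
- terms with zero overlap are suppressed, and the BH family is the set of
  *tested* (k ≥ 1) terms. This mirrors how over-representation web tools
  report, and makes the family size data-dependent; with a fixed annotation
  the choice is conservative in the null simulations below.

No GO-graph (true-path) propagation is performed; annotations are taken as
given.

## Promoter windows and coordinates

Windows are anchored at the transcription start site with the "+1"
convention: positions …, −2, −1, +1, +2, … and no position 0, the TSS base
being +1. The default window spans 500 nt upstream and 100 nt downstream of
the TSS base — 601 nt in total, written `-500..+101` in FASTA headers. The
proximal-promoter default reflects where the conserved bHLH signatures of
the hypothalamic Notch targets sit (within ~600 bp of the TSS); both extents
are configurable. Internally all arithmetic is 0-based half-open with
converters at the boundaries; truncated windows (record shorter than the
requested window) keep their TSS anchor and emit a warning; a TSS outside
the record is an error. Minus-strand genes get the reverse complement of
the appropriate slice so windows always read 5'→3' on the coding strand.

Free-standing sequences scanned without a TSS anchor (ad-hoc windows) are
reported with plain 1-based positions.

## Motif scanning and conservation

Matching is strict IUPAC consensus matching — a position matches iff the
observed base is in the code's base set — not PSSM scoring. The motif set
follows the screen's signatures: E-box `CANNTG`, N-box `CACNAG`, and the
strict antagonist 7-mers MHAM `CACCTGC` and MNAM `GCAGCTG`. The strict
7-mers carry the conservation analysis because their background rate on
random sequence is 4^−7 per position per strand (expected
2·(L−6)·4^−7 ≈ 0.073 hits per 601-nt window), whereas the degenerate E-box
matches ~4.6 times per window by chance and is reported for annotation
only.

Both strands are scanned by default (bHLH factors bind double-stranded
DNA and the E-box pattern class is reverse-complement symmetric); minus-
strand hits are reported at the plus-strand position of their 5'-most base
with the matched sequence read on the minus strand. Overlapping hits are
all reported, in deterministic (position, strand) order.

Consensus derivation is columnwise: each alignment column is encoded by the
IUPAC letter for exactly the set of observed bases, so the result is the
narrowest consensus every input site matches, is order-invariant, and never
widens a column beyond what was observed (e.g. four sites with third-column
bases {A,C,G,T} give `CANCTG`, not `CANNTG`).

Conservation is presence-based: a gene×motif combination is conserved when
hits exist in ≥ m distinct species (default m = the whole panel). The
maximum pairwise spread of hit positions is reported but not used as a
filter — the underlying comparative data give no positional tolerance, so
stricter positional post-filters are left to the caller. Per-gene promoter
reports additionally annotate nesting (an E-box hit lying inside an MHAM
hit at the same location is flagged `within=MHAM`).

## Synthetic study conditions

The generator reproduces the study design with known ground truth:

- **Design.** 4 control + 4 treated arrays (each emulating a pooled-embryo
  RNA sample), 2000 genes by default.
- **Planted effects.** The 34 published signed fold changes (11 Notch
  pathway components, from Hes5 −56.83 to Mfng +3.15, and the 23
  upregulated nervous-system-development genes, Neurog1 +8.85 … Chrdl1
  +1.30) are the default planted truth.
- **Noise.** Multiplicative log-normal intensity noise (default sd 0.1 on
  the log scale), the standard positivity-preserving model for one-colour
  arrays. Pooling variance and array noise are not separated; a single
  noise knob covers both.
- **Scale factors.** Per-array global factors drawn log-uniform in
  [0.5, 2], so percentile normalization is exercised and matters.
- **Baselines.** Bulk genes are log-normal around median 100 (log-sd 0.8).
  Planted genes draw baselines from a high-expression stratum, 200–2000×
  the bulk median. This choice makes noise-free recovery exact through the
  normalization stage: even the strongest down-regulation (÷56.83) leaves a
  planted gene above the per-array median, so no value crosses the median,
  the central order statistics are identical in both conditions, and the
  planted ratio is recovered to machine precision. It is also biologically
  reasonable — the screen's anchor genes are strongly expressed
  transcripts.
- **GO annotation.** One term annotates 10 genes of which 8 are
  planted-upregulated; the remaining terms annotate uniform random gene
  sets of size 5–30.
- **Promoters.** Background i.i.d. uniform ACGT (GC configurable); MHAM
  planted in the Hes5, Dll1, Chga and Chrdl1 windows and MNAM in Robo2 and
  Tagln3, in all four panel species (human, mouse, rat, chick), at fixed
  proximal offsets. Ambiguous consensus positions are resolved randomly at
  planting time.

What the generator does **not** emulate: probe-level array structure,
background subtraction and flagging, dye effects, correlated (batch)
noise, real promoter base composition and repeat structure, and true
orthologous alignment — conservation in the fixture is presence by
construction. Passing tests therefore demonstrate correctness of the
computational chain under the stated model, not performance on real arrays
or real genomes; the real-data entry points (series-matrix reader, probe
collapsing, genome+TSS window extraction) are exercised on synthetic
fixtures only.

All generators take explicit integer seeds (no global RNG state) and are
bit-reproducible: the same seed yields identical matrices and FASTA bytes.

## Pipeline and numerical choices

The orchestrated run (synthesize → screen → enrich → scan → summarize)
writes TSV/FASTA outputs with commented headers carrying the package
version and full parameter set; identical config+seed gives byte-identical
files. The final summary joins upregulated genes to their conserved strict
motifs; the consistency check compares fold-change *signs* (up: FC > 1,
down: FC < −1) — not the screening cutoff — against the direction pattern
implied by the lateral-inhibition model under Notch blockade, so borderline
genes are judged by direction alone, and genes absent from the data are
listed as untestable rather than failing.

Default problem sizes (2000 genes; 100 seeds for direction-recovery rates;
20 seeds for conservation recovery; 200 null queries over a 40-term,
800-gene annotation) were chosen to estimate each quantity stably while
keeping a full verification run in the seconds-to-a-minute range.

## Known limitations

- Exact re-derivation of the published up/down list sizes from the public
  accession depends on unstated probe filtering in the original
  vendor-software analysis; the real-data mode reports its own counts and
  the discrepancy rather than asserting equality.
- Printed enrichment p-values from the original web-tool analysis depend on
  a historical annotation snapshot and are not reproduced by design.
- Strict-7-mer conservation on short random-background windows has a small
  chance rate (≈0.073 hits/window/species); at m = all-species the
  resulting false conserved-call probability is ≈2×10⁻⁵ per gene×motif and
  is reported, not suppressed.
- The regulatory model is a static sign-propagation table; no dynamical
  simulation of lateral inhibition is attempted.
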