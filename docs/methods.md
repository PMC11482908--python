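# Methods

This note documents the models and procedures mirkit implements, the
defaults it ships, and the choices made where the conventions of the
field leave room.

## Seed-site model

Target recognition is modelled purely by Watson–Crick complementarity to
the miRNA seed (mature positions 2–7), the standard canonical-site
hierarchy: 8mer, 7mer-m8, 7mer-A1, offset-6mer and 6mer. No pairing
thermodynamics, conservation, context scoring or 3'-compensatory sites
are considered — the scanner reproduces exact-string curation, not a
prediction algorithm.

Scanning proceeds core-first: every occurrence of the 6mer core (the
reverse complement of the seed) is located, then classified by two flank
checks — the base 5' of the core against the complement of miRNA
position 8, and the base 3' of it against a literal A. Exactly one type
is reported per core occurrence, the most specific applicable one, so a
transcript substring is never double-counted as both an 8mer and the
7mers it contains. Offset-6mer occurrences (complementary to positions
3–8) are located separately and reported unless their span lies inside
an already-reported 8mer/7mer-m8, where they are redundant evidence.
Two further conventions:

* a flank outside the transcript counts as non-matching, so a core at a
  transcript end is reported as the less-specific type (conservative:
  truncated evidence is not upgraded);
* IUPAC ambiguity codes are accepted in transcripts but never match
  (exact-string semantics); they are rejected in mature miRNAs, where a
  single ambiguous base would poison every derived site.

Sequences are handled internally as uppercase RNA; DNA input (T) is
converted on read, and a flag emits DNA-alphabet output. Coordinates are
1-based inclusive on the transcript sense strand; transcripts are
assumed to be sense-strand sequences already, so no reverse-strand scan
is performed.

Group comparisons of site prevalence use a two-sided Fisher exact test
on the 2×2 with/without-site table (scipy), with the sample
cross-product odds ratio reported and flagged when a cell is zero.

## Genomic-context classification

The classifier assigns each miRNA gene exactly one of: exonic, intronic,
intergenic, or co-transcribed up/downstream of a neighbour. Decision
order encodes "containment beats adjacency":

1. **exonic** if the miRNA span overlaps any exon of a non-miRNA host
   transcript;
2. **intronic** if it is contained in a host transcript span without
   exon overlap;
3. **co-transcribed** if the nearest same-strand non-miRNA gene lies
   within `threshold_bp` (default 2000 bp, configurable): downstream-of-
   neighbour when the neighbour is 5' of the miRNA in transcription
   orientation, upstream-of-neighbour symmetrically; the smaller gap
   wins, ties resolved toward downstream-of-neighbour;
4. **intergenic** otherwise, with the nearest gene of any strand
   reported for context.

Distances are nearest-facing-edge gaps (`start − end − 1`; 0 when
abutting or contained). The 2 kb default threshold comfortably covers
the ~1.7 kb *Peony*→*miR-317* gap that motivates the co-transcribed
category while staying below typical fly intergenic spacing; there is no
community-standard value, so it is exposed as a parameter. Antisense
containment is still called exonic/intronic but flagged
`same_strand = False` — the containment information is preserved without
inventing an extra category. Among multiple candidate hosts the smallest
transcript span wins (most specific, and deterministic). Genes without
transcript children act as their own host spans so sparse annotations
classify sensibly.

## Target integration

Prediction lists are unioned with per-gene source provenance after
whitespace trimming; identifiers are otherwise matched verbatim
(FlyBase-style stable ids are case-stable, and case-folding ids like
`rn` vs `Rn` would create false joins). The merge reports the count of
genes per source-multiplicity and checks the counting identity
`n_unique = Σ|list_i| − #(exactly 2) − 2·#(exactly 3)`.

Candidate filtering keeps predicted genes with `padj < padj_max` and
`log2FC` beyond `min_log2fc` in the chosen direction; both inequalities
are strict, matching the convention of candidate tables stated as
"p<0.05 and log2FC>0.5". Output is ordered by descending |log2FC| with
gene-id tie-breaks so it is invariant to input row order. Prediction ids
absent from the DE table are returned/written explicitly, never dropped
silently. Dysregulation summaries count a gene with log2FC exactly 0 as
neither up nor down and warn, since a real DE table cannot produce one.

## qPCR

ΔΔCt: technical replicates are averaged on the Ct scale (the standard
practice; averaging linearised quantities would bias low-Ct replicates),
then `ΔCt = Ct(target) − Ct(control amplicon)` per sample,
`ΔΔCt = ΔCt − mean ΔCt(reference condition)`, `FC = 2^−ΔΔCt`. The
amplification efficiency is fixed at 2.0 (100%) by default with a
per-call override, since the plain 2-fold form is what the assay design
assumes.

Two-amplicon ratio: within one sample,
`ratio(a:b) = 2^(Ct_b − Ct_a)`, assuming equal amplification efficiency
for both amplicons (a documented assumption of the method, not a tested
one). Condition-level ratios are geometric means of per-sample ratios
and dispersion is the sd of per-sample log2 ratios, because ratios are
log-scale quantities. Group comparison is a two-sided Student's t-test
on per-sample log2 ratios (equal-variance by default, Welch by flag),
with the degenerate constant-groups case defined as t = 0, p = 1 (equal)
rather than 0/0. Replicate outliers are never removed automatically; a
replicate Ct spread above 0.5 cycles is logged as a warning only.

## Synthetic data: what it emulates, and what it does not

The study that motivated this toolkit published summary tables but not
its raw sequencing or Ct data, so generators supply inputs whose truth is
known exactly. Defaults are the study conditions:

* **transcripts** — 192 sequences of 300–2000 nt at GC 0.45 (fly-like),
  with planted sites summing to 56; the `make_lncrna_cohort` wrapper
  plants 38/140 upregulated and 18/52 downregulated site carriers. The
  background is rejection-sampled to contain neither the 6mer core nor
  the offset-6mer string, and each assembled transcript is verified by
  naive string search (occurrence sets plus flank checks), so planted
  counts, positions and types are exact and recall/precision assertions
  are sharp.
* **annotation** — 264 miRNA genes on one synthetic chromosome, 118
  intronic, 46 co-transcribed (23 per orientation, gaps uniform in
  [0, threshold]), and the remaining 100 split evenly between exonic and
  intergenic (the survey this mirrors quantified only the intronic and
  co-transcribed classes; the even split is an arbitrary, documented
  choice). Each miRNA occupies its own 20 kb block so contexts cannot
  interact.
* **DE tables** — 13232 genes, 1844 dysregulated, 59.1% down, 192
  dysregulated lncRNAs of which 140 up. Fractions are realised by
  deterministic allocation (nearest integer, logged when inexact), not
  Bernoulli sampling, so count-based tests are exact. Dysregulated
  |log2FC| is 0.05 + |N(0.7, 0.5)| with allocated sign and padj drawn
  below 0.05 on a log-uniform scale; null genes get N(0, 0.1) fold
  changes and padj in [0.05, 1). `make_target_study` additionally draws
  prediction lists (975/102/31 with 74 two-way and 2 three-way overlaps,
  union 1030) from the table's truth strata so that 919 are detected,
  142 dysregulated (88 down / 54 up) and 15 pass the strong-up filter.
* **Ct tables** — per condition, 6 biological samples × 3 technical
  replicates, replicate noise sd 0.2 cycles, between-sample base-Ct
  jitter sd 0.5; true ratios default to 52 (head), 8.5 (testis) and 15.3
  (slow-elongation testis). The ratio is encoded within-sample, so
  between-sample jitter cancels and zero replicate noise recovers the
  truth exactly.

What the generators do **not** emulate: realistic expression-level and
count-noise structure (DE tables carry no counts and their p-values are
decorative, not products of a test), linked splicing/isoform structure,
sequence composition beyond a single GC fraction, amplification-
efficiency differences between amplicons, and inter-plate qPCR effects.
Passing tests therefore demonstrate correctness of the computations
under their stated assumptions, not robustness to every artefact of
real data.

## Numerical and I/O choices

Exact string comparison throughout the scanner (no floating point);
Fisher p-values from scipy's exact routine, cross-checked in tests
against rational-arithmetic enumeration to 1e-12. Ratios and fold
changes are computed in log2 space and exponentiated once. Tables are
TSV with `.` for missing, floats at 6 significant digits and percentages
at one decimal; writers are deterministic. Every CLI run writes a JSON
manifest with parameter values, SHA-256 input digests, package version
and seed. All generator randomness flows through one
`numpy.random.Generator` with a mandatory integer seed; identical seeds
give byte-identical outputs.

## Known limitations

* The scanner operates on supplied transcript sequences; whether
  isoforms are collapsed per gene is the caller's decision, and
  gene-level prevalence counts depend on it.
* A transcript-boundary core is reported as a 6mer by fiat; curation
  done by eye might have counted it differently.
* The co-transcribed threshold is a modelling knob; published
  category counts from other annotations may not be re-derivable at any
  single cutoff.
* A gene partially overlapping a miRNA without exon overlap or
  containment falls through to the proximity/intergenic rules (distance
  0); such arrangements are rare in practice but the convention is
  arbitrary.
* Degenerate seeds whose offset-6mer equals their 6mer core (e.g. mono-
  nucleotide repeats) can report both types at one position; real
  mature miRNAs do not have such seeds.
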