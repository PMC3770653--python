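# Methods

This note documents the models, parameter choices and numerical conventions
behind `rearrangemap`, what the synthetic data does and does not emulate,
and the known limitations.

## Coordinates and junction representation

All coordinates are 1-based inclusive genomic positions; a locus carries an
`offset` so a chromosome sub-region can be analysed in genomic coordinates
throughout, with half-open 0-based conversion only at BED I/O. A deletion
junction is the pair (`bp5`, `bp3`) of the last retained base before the
join and the first retained base after it; the deleted interval is
`[bp5+1, bp3-1]` and the event size is `end − start + 1`. A tandem
duplication reuses the same fields with `bp3 ≤ bp5` (`bp5` = end of the
duplicated interval, `bp3` = its start), so in both cases the derived
allele around the junction is `…seq[..bp5] | insertion | seq[bp3..]…`.

**Microhomology.** When the two joined flanks share sequence at the join,
every split position inside the shared stretch writes the same derived
allele, so a single reported breakpoint is a convention, not a biological
fact. The microhomology length is computed analytically as (longest common
suffix of the flanks ending at the two join points) + (longest common
prefix starting after them); the test suite checks this against an
independent exhaustive junction-shift oracle that literally tries every
shifted junction and compares reconstructed alleles.

**Leftmost normalization.** Every junction — simulator truth, per-read
split, annotated call — is reduced to the smallest-coordinate equivalent
placement. For insertion junctions the representation is first made
minimal: insertion bases identical to the adjoining reference flank are
reassigned to the flank (trailing bases first, then leading bases), and an
emptied insertion falls back to plain leftmost sliding. Normalization is
idempotent and preserves the derived allele (property-tested). Fixing one
canonical form is what makes exact parameter-recovery comparisons
meaningful.

## Synthetic data

The generator emulates a repeat-dense disease locus and the assays used to
screen and characterize rearrangements in it.

* **Reference loci** — i.i.d. random background with `n_repeats`
  non-overlapping copies of a fixed ~300 bp Alu-like consensus (embedded as
  a constant; includes the diagnostic A-tail), each mutated at per-base
  rate `repeat_divergence` (default 0.08 in the event battery — the scale
  of divergence between genomic Alu copies) and placed on a random strand
  with a random subfamily label. Annotation coordinates are exact.
* **NAHR deletions** — the junction is placed inside a stretch of the
  requested length (10–60 bp, matching the observed range for
  repeat-mediated junctions) forced identical between two same-orientation
  repeats by copy-paste before joining; the bases flanking the stretch are
  forced to differ so the planted microhomology is exact, and all edits
  fall inside the deleted interval, leaving the derived allele untouched.
  Requests naming opposite-strand or different-superfamily repeats are
  rejected, mirroring the biological constraint that recombining elements
  are co-oriented.
* **NHEJ deletions** — blunt joins (junction flanks verified to share
  < 5 bp) or joins with a short untemplated insertion whose boundary bases
  are required to differ from the adjoining flank (otherwise the minimal
  representation would differ from the request and recovery comparisons
  would be ill-defined; callers resample on rejection).
* **Reads** — uniform-start, fixed-length (default 400 bp, amplicon-style)
  with independent per-base substitution errors and a constant quality
  line. Real pyrosequencing data adds homopolymer indel errors and a
  length distribution; neither is modelled, so passing tests demonstrate
  correctness of the junction logic under substitution noise, not
  robustness to indel-heavy chemistry.
* **MLPA** — one probe per exon plus 8 diploid reference probes; peak area
  = probe-specific base area × (CN/2) × lognormal(σ = `noise_sd`) noise,
  two independent reactions per sample, ≥3 diploid controls.
* **aCGH** — probes every `probe_spacing` bp; log₂ ratio `log2(CN/2)` plus
  Gaussian noise.
* **Cohort** — per-individual Bernoulli tumor indicators at class-specific
  rates (defaults: colorectal 0.55/0.42 and endometrial 0.11/0.14 for
  rearrangement/point-mutation carriers, the observed frequencies), normal
  ages at onset (mean 43, sd 12, truncated at 18). No pedigree structure
  or within-family correlation is simulated.

The 20-event recovery battery (`standard_event_battery`) uses 15 kb loci —
large enough for kilobase-scale events with flanking sequence, small
enough for a desk-scale run — at depth 30, which yields ~20–30
junction-spanning reads per event, comfortably above the `min_support=3`
cluster threshold.

## Dosage screening

**MLPA dosage quotient.** `ratio(probe) = [area / Σ area over the
normalization probes] ÷ median over batch samples of the same quantity`.
The intrasample total is taken over the kit's diploid reference probes when
they are identified — then a noise-free copy number c gives the ratio c/2
*exactly* — and over all probes otherwise (the classical approximation,
exact only as the aberrant fraction of total signal vanishes). The batch
reference is a median, robust to one aberrant sample in the batch but blind
to an aberration shared by most of the batch; this blind spot is asserted
as documented behavior in the tests.

**Calling.** Strict thresholds (`< 0.7` deletion, `> 1.2` duplication;
boundary values call normal) applied per reaction; an exon is reported
aberrant only when two independent reactions agree on the same non-normal
state. A straddle (aberrant in one reaction only) reports normal with a
discordance flag; a probe missing from one reaction reports unconfirmed
with a warning. Contiguous runs of confirmed same-state exons become
candidate rearrangement intervals (`E11-16 del` style labels).

**aCGH segmentation** replaces a proprietary aberration statistic with a
documented simple procedure: estimate background scatter robustly
(1.4826·MAD), flag probes with |log₂| > `z_threshold`·SD (default 2.5),
merge consecutive same-sign flagged probes — tolerating up to one interior
sub-threshold probe per gap (`max_bridge=1`), since a single noisy dropout
must not split a real aberration — then discard runs below the
consecutive-probe minimum: 10 inside densely covered gene regions, 5
elsewhere. With the defaults, a CN=3 segment of ~40 probes at noise
σ = 0.1 is recovered with both boundaries within one probe in ≥ 95% of
replicates; 8-probe in-gene aberrations are filtered by construction.

## Breakpoint mapping

Anchoring: exact 20-mer seeds at up to three offsets from each read end
(so one sequencing error cannot lose an anchor), X-drop extension
(match +1, mismatch −3, drop 9) to score candidate diagonals, requiring
the anchor to reach within 3 bases of its read end and span ≥ `min_anchor`
(default 20 bp). Placements tying on score at different diagonals are
rejected with an ambiguity flag — reads lying wholly inside one of two
near-identical repeat copies are never silently assigned. Both read
orientations are tried, making detection strand-symmetric.

Split placement deserves care because an NAHR junction is flanked by
~85%-identical repeat copies: any heuristic that walks along match runs
drifts through the repeat. Given the two anchor diagonals, the mapper
scans *every* split position (and every untemplated-gap decomposition up
to 50 bp), minimizing total mismatches; a gapped decomposition is accepted
only at strictly lower cost, then minimal gap, then leftmost. For an
error-free read this provably returns the true junction: a clean junction
admits a zero-mismatch clean split, while the simulator's
insertion-boundary constraints guarantee an insertion junction admits no
zero-mismatch clean split but does admit the zero-mismatch true gap.
Per-read results are then leftmost-normalized against the reference.

Clustering is single-linkage over (bp5, bp3) with tolerance 10 bp per
coordinate, per orientation. Groups within 150 bp of a stronger
same-orientation group are absorbed into it before the `min_support`
filter: a read with an error exactly at the junction systematically
prefers a slightly displaced split (the minimal-mismatch decomposition
excises the error as a spurious gap), producing a halo of near-misses
around the true junction. The absorbed cluster reports the *modal*
(bp5, bp3, insertion) triple, which error-free reads dominate; the 150 bp
window is therefore the minimum resolvable distance between two
same-orientation junctions. `min_anchor=20`, `tol=10`, `min_support=3`
and the window are desk-scale defaults, all exposed as parameters.

Junction consensus is a per-column majority vote over the cluster's reads,
placed by their anchor diagonals on a template of reference flanks around
the join (±150 bp) with the cluster's insertion between them; uncovered
columns fall back to the template.

## Mechanism classification

`NAHR` requires junction microhomology ≥ `min_homology` (default 10 bp —
below the 15–48 bp observed for repeat-mediated junctions, above anything
expected by chance) *and* both breakpoints inside same-orientation repeats
of the same superfamily. `NHEJ` requires microhomology below
`short_homology_cap` (default 5 bp) and ignores repeat context entirely:
breakpoints landing inside an Alu are common at a locus where repeats
cover a large fraction of the sequence, and repeat overlap alone is not
evidence of homologous recombination. The intermediate zone (5–9 bp, or
long homology without a qualifying repeat pair) stays `unclassified`
rather than being forced into either class.

Pathogenicity flagging is rule-based metadata only: events overlapping
annotated exons are flagged as gene-disrupting; intronic events are not,
and an intronic event co-occurring with a pathogenic event on the same
allele is annotated as such. No clinical variant classifier is
implemented.

## Cohort statistics

Frequencies are percentages rounded half-up to one decimal (the convention
of the clinical tables reproduced); per-class tumor frequencies are
integer percentages, floor-rounded — the combination that reproduces the
published 10.8/20.5/10.4/11.4 and 55/11/42 values from their integer
counts. The primary 2×2 association test is the chi-square with continuity
correction, adopted because it reproduces the published P = 0.547 for the
affected/healthy table (and 0.993, 0.936 for two of the other tables); the
source never names its test, so Fisher's exact test and the uncorrected
chi-square are always reported alongside, and tables with an expected cell
below 1 fall back to Fisher only. Ages are compared by an equal-variance
two-sample t-test. No multiple-testing correction is applied (single-table
comparisons). Family-level variants flagged non-pathogenic (e.g. an
intronic deletion co-occurring with a pathogenic duplication) are excluded
from pathogenic-rearrangement counts.

## Problem sizes

The default test suite and the acceptance script use 10–15 kb loci,
kilobase-scale events, 400 bp reads at depth 30, 1000 random junction
pairs for the oracle comparison, 50 planted NAHR deletions, 20 end-to-end
events per error rate, 1000 MLPA samples and 100 aCGH replicates — sizes
chosen so the whole battery reruns from scratch in about a minute on a
single CPU while keeping every binomial check well-powered.

## Known limitations

* Substitution-only alignment: no indel handling in extension or split
  scoring; real 454-style homopolymer errors would require gapped
  alignment.
* Junctions closer than the satellite-absorption window (150 bp, same
  orientation) merge into one cluster.
* Insertions longer than 50 bp at a junction are not searched.
* The MLPA batch-median reference cannot see an aberration carried by most
  of the batch.
* aCGH segmentation assumes a flat diploid background when estimating
  scatter; highly aberrant genomes would need a different background
  model.
* The cohort simulator draws individuals independently; familial
  correlation, penetrance and censoring are out of scope.
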