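# Methods

This note documents the models and procedures implemented by
`varcurate`, the parameters that matter, what the synthetic data
generator does and does not emulate, and the numerical and design
choices taken where more than one was defensible.

## Variant tiering

The Variant Priority Index is a decision table over three inputs: the
harmonised consequence class, the maximum population allele frequency
(AF) over EVS / 1000 Genomes / ExAC, and the Condel conservation
score.

* The *maximum* AF is the binding statistic because the rarity
  criterion must hold in every database. A variant absent from all
  three is treated as novel and passes every frequency threshold —
  absence of evidence of commonness is treated as rarity, which is the
  clinically conservative direction (a curator sees it rather than
  not).
* All comparisons are strict (`AF < 0.01`, `AF < 0.0005`,
  `Condel > 0.07`), exactly as configured; the defaults are the
  standard printed cut-offs. The Condel cut-off of 0.07 is unusually
  low for a score on [0, 1]; it is implemented verbatim and is
  profile-configurable (`condel_threshold`).
* A missing Condel score can never reach tier 3: conservation is
  unproven, so the variant stays at tier 2. It is *not* demoted below
  tier 2 — missingness is not evidence against.
* Tier 4 (frameshift / truncating / splice) ignores population
  frequency by default: the tier is defined by consequence alone, and
  a common truncating variant is still worth a curator's glance in a
  small panel. Laboratories that disagree can set
  `apply_af_filter_to_vpi4=true` in the profile, which hides tier-4
  candidates at or above the rare threshold.
* Consequence vocabulary: both Annovar-style terms ("stopgain",
  "nonsynonymous SNV") and Sequence Ontology terms are mapped through
  one editable table; multiple `&`/`,`-joined terms collapse to the
  most severe, with severity order TRUNCATING > FRAMESHIFT > SPLICE >
  MISSENSE > INFRAME_INDEL > SYNONYMOUS > OTHER. Unknown terms map to
  OTHER and never error, so an annotation-tool upgrade cannot crash an
  analysis (it can only demote unrecognised terms, which the tests for
  surjectivity and totality make visible).

Gene categorisation is a pure precedence function: exclusion beats
every inclusion; among inclusions the maximum category wins
(target = 1, known causal = 2, in-silico = 3, clinician = 4). Max-wins
is the curator-favourable choice when lists overlap. Gene symbols are
compared case-insensitively after trimming; no alias resolution is
attempted (symbol drift is a data-governance problem upstream of this
package). Clinician/in-silico nominations outside the target panel
are clamped to it with a warning — the assay cannot report what it
does not capture.

## Allele normalisation

Variant identity (for the observation store and for record matching)
uses minimal anchored alleles: shared leading context is trimmed
first, advancing the position, then shared trailing context, always
keeping at least one base per allele (so `pos=100 CTT>CT` becomes
`pos=101 TT>T`). Pure context trimming cannot canonicalise across
repeat tracts — true left-alignment requires the reference sequence —
so input VCFs are expected to be reference-normalised upstream
(`bcftools norm` or equivalent); the trimming here then guarantees
padded re-representations of one allele collapse to one key. The test
suite verifies sequence-level equivalence of the trimmed form by
splicing both representations into a common reference string.

Coordinates are 1-based in VCF space and 0-based half-open in BED
space; conversions happen only at ingest boundaries. A splice-window
call requires the position to be strictly outside every exon of the
gene and within `splice_window_bp` bases of some exon edge (default
2 bp, the canonical donor/acceptor dinucleotides; profiles for assays
validated to deeper intronic coverage can widen it).

## Internal observation database

The store is a single SQLite file (`samples`, `observations` tables) —
an embedded store keeps deployment to a file copy, with SQLite's
locking providing single-writer safety. Semantics:

* presence-only: one observation per (variant key, sample); zygosity
  is deliberately not recorded.
* re-registering a sample id replaces its earlier contribution, so
  re-analyses do not inflate counts.
* the exclusion predicate fires when a variant has been seen in at
  least `min_other_cohort_samples` samples from *other* disease
  cohorts (default 3: recurrence across unrelated phenotypes is what
  marks an artefact or local polymorphism) or, optionally, when its
  overall internal frequency exceeds `max_internal_frequency`
  (disabled by default — no principled site-independent default
  exists; sites should calibrate it to their throughput). With fewer
  than two samples in the store there is no population to compare
  against and nothing is excluded.
* the analysed sample's own prior registration is excluded from its
  query; otherwise every variant would filter itself at its second
  analysis.
* within one batch, all samples are filtered against the store state
  at batch start and registered only after all reports are written, so
  batch composition cannot influence per-sample results.

The store is the one admitted source of drift between re-analyses;
snapshotting (SQLite backup-API copy plus a JSON manifest with sample
count and SHA-256 digest) before each analysis, and re-running from
the restored snapshot in no-timestamp mode, reproduces every report
file byte for byte. This is asserted end-to-end in the tests.

## Coverage QC

A gap is a maximal run of bases with depth strictly below the
threshold; depth equal to the threshold is covered ("below" means
below). The default threshold of 15× matches the depth at which
small-variant sensitivity on capture data becomes acceptable and is
profile-configurable. The three reports satisfy an exact integer
identity — per exon, the summed overlapping gap lengths equal the
below-threshold base count — which the acceptance suite checks on
random fixtures.

Gene traffic lights: GREEN requires ≥ 95 % of the gene's targeted
bases at/above threshold *and* no completely uncovered exon (a whole
missing exon is qualitatively worse than diffuse thinning at the same
base count, hence the veto); AMBER requires ≥ 80 %; otherwise RED. The
80/95 bounds are defaults, not doctrine, and are profile settings.

Medians of even-length depth arrays use the *lower* median, so every
reported depth is one that was observed. Target bases absent from the
coverage file are depth 0 (sequencing dropout), not an error; truly
malformed tracks (skipped offsets, negative depths) fail parsing with
a line number.

## Sample checks

Five gates: FASTQC flag check (fails iff any profile-listed metric
reports FAIL), median coverage (≥ limit), median fragment size
(inclusive range — a sample exactly at a validated bound is within
validation), duplicate rate (≤ limit), and sex consistency. Limits
the profile does not set yield SKIPPED, never silent passes. The
sample verdict is FAIL iff any gate fails.

Sex inference uses X- and Y-to-autosome mean-depth ratios
(rx = X/autosome, ry = Y/autosome): MALE iff ry ≥ 0.2 and rx ≤ 0.8;
FEMALE iff ry < 0.05 and rx ≥ 0.8; anything between is UNKNOWN. The
expected regimes are (rx, ry) ≈ (0.5, 0.5) for males and (1, 0) for
females; the wide dead zone means ±10 % noise cannot flip a call, only
abstain, and an abstention merely skips the consistency gate — for a
clinical gate a recoverable abstention is preferred over a confident
error. Y capture bleed-through in females (pseudo-autosomal regions,
mismapping) motivates the asymmetric 0.05 floor.

## Synthetic data generator

`fixtures.generate_batch` emulates the *inputs* to the clinical layer,
not the sequencing: annotated VCFs are written directly with
synthesised annotation, per-base coverage is piecewise-constant with
integer noise, and metrics are stated rather than measured. Defaults
model a production batch: 12 samples from four disease cohorts, a
24-gene panel (4–8 exons of 100–250 bp per gene), ~2,000 common
background coding variants per sample, ~100× coverage with ±10 %
noise, duplicate rate 0.10, fragment size 180 bp, and a 20-sample
historical store whose five planted artefact variants each appear in
six samples spread across cohorts.

Exactness guards: coverage noise is clamped ≥ threshold + 5 outside
planted dropouts and ≤ threshold − 5 inside them, so noise can neither
fabricate nor close a gap and truth coordinates are exact. Planted,
artefact and background positions are drawn from disjoint pools, so
expected fates never collide.

What passing on this generator shows: the decision logic, filtering,
counting, ordering and file contracts are correct under exactly
specified inputs. What it does not show: robustness to real-world
annotation noise (conflicting transcripts, malformed INFO fields),
alignment artefacts, capture-efficiency structure in coverage, or
allele-balance pathology — those live upstream of this layer's
contract and are not modelled. Problem sizes in the test and
acceptance runs (12 × 2,000 variants, 500 random gap tracks, 100-case
simulations) were chosen as the package's own desk-scale study
conditions; real deployments simply have bigger inputs, not different
code paths.

## Known limitations

* Single, unrelated samples only: no trio/family-aware filtering, no
  inheritance models, no joint calling awareness.
* No ACMG classification; the tiers order curation effort, they do not
  classify pathogenicity.
* No CNV/SV support: symbolic alternates pass through as OTHER and are
  never tiered.
* One consequence per record (the most severe across transcripts);
  transcript-resolved reporting is out of scope.
* The LOVD CSV follows a fixed documented column mapping; it is not an
  upload client.
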