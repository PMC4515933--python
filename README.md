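# varcurate

Variant prioritisation, cohort-aware artefact filtering and coverage QC
for diagnostic gene-panel and exome sequencing.

## The problem

A diagnostic laboratory running targeted or exome sequencing does not
struggle to *call* variants — it struggles to curate them. A single
exome yields tens of thousands of annotated variants, and the scarce
resource is the curator who must decide which handful are worth
clinical consideration. `varcurate` implements the bespoke clinical
layer that sits downstream of a standard alignment → variant-calling →
annotation workflow: it consumes an annotated VCF, per-base coverage
tracks and sample metrics, and produces a short, ranked, auditable
curation report, together with the QC evidence needed to trust (or
distrust) a negative result.

It is written for bioinformaticians operating clinical pipelines and
assumes annotation (population allele frequencies, Condel scores,
transcript consequences) has already been attached by Annovar, VEP or
similar.

## The prioritisation model

Each variant receives two indices.

**Variant Priority Index (VPI)** — four nested tiers driven by
population rarity, conservation and predicted protein impact. Writing
`AF` for the *maximum* allele frequency over the EVS, 1000 Genomes and
ExAC databases (the rarity criterion must hold in all of them, and a
variant absent from all three is "novel"):

| tier | criterion |
|------|-----------|
| VPI 1 | missense / in-frame indel, `AF < 0.01` ("rare") |
| VPI 2 | as above with `AF < 0.0005` or novel ("very rare or novel") |
| VPI 3 | VPI 2 and Condel `> 0.07` ("highly conserved") |
| VPI 4 | frameshift, truncating or splice-site (incl. intronic variants within a configurable window of an exon boundary) |

Tiers 1–3 are subsets of one another; variants below VPI 1 are hidden
from the report. All inequalities are strict.

**Gene Priority Index (GPI)** — an a-priori gene ranking from the
sample's *analysis profile*: 1 = anywhere on the target panel, 2 =
known disease gene for the patient group, 3 = prioritised in-silico
for this patient, 4 = nominated by the treating clinician. Excluded
genes are category 0 and never reported.

Retained variants are additionally screened against a site-local
**internal observation database** (an embedded SQLite file recording
every variant seen in every sample ever analysed): a variant observed
in ≥ *k* samples from *other* disease cohorts (default *k* = 3) is
almost certainly a local population variant or a pipeline artefact and
is filtered out. The report is sorted by (VPI desc, GPI desc,
karyotype position) so the most promising variants are at the top.

Coverage QC is reported at three resolutions — per-gene traffic
lights, per-exon FULL/PARTIAL/NONE status, and base-pair-exact gap
regions (maximal runs with depth strictly below a threshold, default
15×) — and five automated sample gates (FASTQC flags, median coverage,
fragment-size range, duplicate rate, declared-vs-inferred sex) guard
each sample.

## Worked example

Everything is testable without patient data: the `fixtures` module
generates a complete synthetic batch (annotated VCFs, coverage tracks,
exon BEDs, metrics, a profile and a population store) with a
`truth.json` manifest of what was planted.

```python
from pathlib import Path
from varcurate.fixtures import SimulationSpec, generate_batch, generate_population_store
from varcurate.reporting import run_batch

spec = SimulationSpec(seed=42, n_samples=2, background_variants_per_sample=200)
batch = Path("demo/batch")
generate_batch(spec, batch)
db = generate_population_store(spec, Path("demo/population.db"))
summary = run_batch(batch, db_path=db, no_timestamps=True)
for sid, info in summary.items():
    print(sid, "retained:", len(info["retained"]), "removed:", len(info["removed"]))
print((batch / "analysis/results/S001.variants.csv").read_text())
```

prints:

```
S001 retained: 5 removed: 211
S002 retained: 0 removed: 205

sample,gene,gpi,vpi,chrom,pos,ref,alt,consequence,af_evs,af_1000g,af_exac,condel,internal_count,internal_frequency,depth,qual
S001,G001,4,4,chr1,10442,G,GTT,FRAMESHIFT,,,,,0,0.000000,150,950.0
S001,G006,1,4,chr6,10158,G,T,OTHER,,,,,0,0.000000,110,800.0
S001,G002,2,3,chr2,10011,T,A,MISSENSE,,,,0.900000,0,0.000000,120,900.0
S001,G004,3,2,chr4,10011,T,A,MISSENSE,0.000100,0.000200,0.000400,0.050000,0,0.000000,120,900.0
S001,G007,1,1,chr1,17114,G,T,MISSENSE,0.005000,0.004000,0.008000,0.900000,0,0.000000,120,900.0
```

Of ~200 variants per sample, five survive filtering in S001 — exactly
the planted ones. The top row is the frameshift in the
clinician-nominated gene (GPI 4, VPI 4); the second is an intronic SNV
promoted to VPI 4 by the splice window; empty cells are genuinely
missing annotations (novel variants), never zeroes. S002 carried only
common background variants and recurrent cross-cohort artefacts, all
filtered. Each run also writes an LOVD-compatible CSV with identical
content, a removed-variant audit file with machine-readable reasons,
and a provenance manifest (SHA-256 digests of every input and output
plus the full effective settings).

The same flows are available from the shell:

```bash
varcurate simulate --out-dir demo --seed 42 --samples 2 --background 200
varcurate run --batch-dir demo --db demo/population.db --no-timestamps
varcurate qc  --batch-dir demo      # exit code 2 if any sample gate fails
varcurate db stats --db demo/population.db chr6:17561:C:G
```

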