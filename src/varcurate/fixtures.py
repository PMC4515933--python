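"""Seeded synthetic batch generator with a machine-readable truth manifest.

Generates everything a full analysis consumes — annotated VCFs,
per-base coverage tracks, exon/target BEDs, sample metadata and
metrics, an analysis profile, and a pre-populated observation store —
together with ``truth.json`` recording every planted variant's expected
priority indices and fate, every planted coverage gap's exact
coordinates, and every sample's true and declared sex.  The same seed
and spec always produce byte-identical output trees.

The defaults emulate a production diagnostic batch: 12 exome samples
drawn from four disease cohorts, a two-dozen-gene panel, ~2,000
background coding variants per sample (all common, hence filtered),
~100x mean target coverage with +/-10 % integer noise, and a site
observation database of 20 historical samples carrying a handful of
recurrent cross-cohort artefact variants.  Variants are written
directly as annotated VCF records (annotation synthesised); read-level
simulation and alignment are deliberately not modelled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .obsdb import ObservationStore
from .prioritise import chromosome_sort_key
from .variant_ingest import VariantKey

__all__ = [
    "SimulationSpec",
    "GeneModel",
    "PlantedVariant",
    "build_gene_models",
    "default_planted_variants",
    "artifact_variants",
    "generate_batch",
    "generate_population_store",
]

_BASES = "ACGT"


def _alleles(pos: int) -> tuple[str, str]:
    """Deterministic SNV ref/alt for a position (ref != alt)."""
    ref = _BASES[pos % 4]
    alt = _BASES[(pos + 1) % 4]
    return ref, alt


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open

    @property
    def exonic_positions(self) -> list[int]:
        """All 1-based positions inside the gene's exons."""
        out: list[int] = []
        for start, end in self.exons:
            out.extend(range(start + 1, end + 1))
        return out


@dataclass(frozen=True)
class PlantedVariant:
    """A variant written into a sample's VCF with a known expected fate."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str  # raw annotation term as written to the VCF
    af_evs: float | None
    af_1000g: float | None
    af_exac: float | None
    condel: float | None
    depth: int
    qual: float
    expected_vpi: int
    expected_gpi: int
    expected_retained: bool
    expected_reasons: tuple[str, ...] = ()


@dataclass
class SimulationSpec:
    """Conditions for one synthetic study batch (defaults = study scale)."""

    seed: int = 0
    n_samples: int = 12
    cohorts: tuple[str, ...] = ("CARDIO", "EPIL", "RENAL", "NEURO")
    n_genes: int = 24
    min_exons: int = 4
    max_exons: int = 8
    min_exon_len: int = 100
    max_exon_len: int = 250
    background_variants_per_sample: int = 2000
    coverage_mean: int = 100
    coverage_noise_frac: float = 0.10
    coverage_threshold: int = 15
    n_dropout_regions: int = 3
    n_artifact_variants: int = 5
    artifact_store_samples: int = 6
    store_n_samples: int = 20
    duplicate_rate: float = 0.10
    fragment_size: int = 180
    plant_sex_mismatch: bool = True
    profile_name: str = "SYNTH"

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]


def build_gene_models(spec: SimulationSpec) -> list[GeneModel]:
    """Deterministic panel layout: genes over chr1-chr6 plus one
    off-target gene (OFFT1) that is captured but absent from the panel."""
    rng = np.random.default_rng([spec.seed, 101])
    names = [f"G{i + 1:03d}" for i in range(spec.n_genes)] + ["OFFT1"]
    chroms = [f"chr{c}" for c in range(1, 7)]
    cursors = {c: 10_000 for c in chroms}
    models: list[GeneModel] = []
    for i, name in enumerate(names):
        chrom = chroms[i % len(chroms)]
        n_exons = int(rng.integers(spec.min_exons, spec.max_exons + 1))
        exons = []
        pos = cursors[chrom]
        for _ in range(n_exons):
            length = int(rng.integers(spec.min_exon_len, spec.max_exon_len + 1))
            exons.append((pos, pos + length))
            pos += length + 200  # intron
        cursors[chrom] = pos + 5_000  # intergenic spacing
        models.append(GeneModel(name, chrom, tuple(exons)))
    return models


def _role_genes(models: list[GeneModel]) -> dict[str, str]:
    """Fixed role assignment over the panel genes (by index)."""
    g = [m.name for m in models]
    return {
        "clinician": g[0],
        "known_a": g[1],
        "known_b": g[2],
        "insilico": g[3],
        "excluded": g[4],
        "splice_host": g[5],
        "rare_host": g[6],
        "synonymous_host": g[7],
        "common_host": g[8],
        "low_depth_host": g[9],
        "low_qual_host": g[10],
        "off_target": "OFFT1",
    }


def _exon_first_pos(model: GeneModel, exon_index: int, offset: int = 10) -> int:
    start, end = model.exons[exon_index % len(model.exons)]
    return min(start + offset, end - 1) + 1  # 1-based


def default_planted_variants(spec: SimulationSpec) -> list[PlantedVariant]:
    """The standard plant set, all in the first sample.

    Covers every tier and every removal reason: a frameshift in the
    clinician-nominated gene (the expected top report row), an intronic
    splice-window SNV, missense variants at each rarity tier, and one
    planted example of each filter (hidden, excluded gene, off-target
    gene, low depth, low quality).
    """
    models = {m.name: m for m in build_gene_models(spec)}
    roles = _role_genes(list(models.values()))
    sid = spec.sample_ids()[0]

    def snv(gene_role, exon_i, csq, afs, condel, vpi, gpi, retained, reasons=(),
            depth=120, qual=900.0):
        gene = roles[gene_role]
        m = models[gene]
        pos = _exon_first_pos(m, exon_i)
        ref, alt = _alleles(pos)
        return PlantedVariant(
            sid, gene, m.chrom, pos, ref, alt, csq,
            afs[0], afs[1], afs[2], condel, depth, qual,
            vpi, gpi, retained, tuple(reasons),
        )

    novel = (None, None, None)
    plants = [
        # frameshift in the GPI-4 gene: expected first row of the report
        PlantedVariant(
            sid, roles["clinician"], models[roles["clinician"]].chrom,
            _exon_first_pos(models[roles["clinician"]], 1),
            _alleles(_exon_first_pos(models[roles["clinician"]], 1))[0],
            _alleles(_exon_first_pos(models[roles["clinician"]], 1))[0] + "TT",
            "frameshift_variant", None, None, None, None, 150, 950.0,
            4, 4, True,
        ),
        # intronic SNV inside the splice window (1 bp past an exon end)
        PlantedVariant(
            sid, roles["splice_host"], models[roles["splice_host"]].chrom,
            models[roles["splice_host"]].exons[0][1] + 1,
            *_alleles(models[roles["splice_host"]].exons[0][1] + 1),
            "intron_variant", None, None, None, None, 110, 800.0,
            4, 1, True,
        ),
        snv("known_a", 0, "missense_variant", novel, 0.9, 3, 2, True),
        snv("insilico", 0, "missense_variant",
            (0.0001, 0.0002, 0.0004), 0.05, 2, 3, True),
        snv("rare_host", 0, "missense_variant",
            (0.005, 0.004, 0.008), 0.9, 1, 1, True),
        snv("synonymous_host", 0, "synonymous_variant", novel, None,
            0, 1, False, ["HIDDEN_BELOW_VPI1"]),
        snv("common_host", 0, "missense_variant",
            (0.05, 0.04, 0.06), 0.9, 0, 1, False, ["HIDDEN_BELOW_VPI1"]),
        snv("excluded", 0, "missense_variant", novel, 0.9,
            3, 0, False, ["GENE_EXCLUDED"]),
        snv("off_target", 0, "missense_variant", novel, 0.9,
            3, 0, False, ["GENE_OFF_TARGET"]),
        snv("low_depth_host", 0, "missense_variant", novel, 0.9,
            3, 1, False, ["LOW_DEPTH"], depth=5),
        snv("low_qual_host", 0, "missense_variant", novel, 0.9,
            3, 1, False, ["LOW_QUAL"], qual=10.0),
    ]
    return plants


def artifact_variants(spec: SimulationSpec) -> list[dict]:
    """Recurrent cross-cohort artefact variants.

    Written into *every* batch sample's VCF and registered in the
    population store across enough other-cohort samples to trip the
    default internal-database policy.
    """
    models = build_gene_models(spec)
    hosts = [m for m in models if m.name.startswith("G")][11 : 11 + spec.n_artifact_variants]
    out = []
    for i, m in enumerate(hosts):
        pos = _exon_first_pos(m, 1, offset=25 + i)
        ref, alt = _alleles(pos)
        out.append({
            "gene": m.name, "chrom": m.chrom, "pos": pos, "ref": ref, "alt": alt,
            "consequence": "missense_variant", "condel": 0.9,
            "expected_reasons": ["INTERNAL_DB_COMMON"],
        })
    return out


def _planted_positions(spec: SimulationSpec) -> set[tuple[str, int]]:
    taken = {(p.chrom, p.pos) for p in default_planted_variants(spec)}
    taken |= {(a["chrom"], a["pos"]) for a in artifact_variants(spec)}
    return taken


def _vcf_header(models: list[GeneModel]) -> str:
    max_pos: dict[str, int] = {}
    for m in models:
        max_pos[m.chrom] = max(max_pos.get(m.chrom, 0), m.exons[-1][1] + 10_000)
    lines = ["##fileformat=VCFv4.2", "##source=varcurate-fixtures"]
    for chrom in sorted(max_pos, key=chromosome_sort_key):
        lines.append(f"##contig=<ID={chrom},length={max_pos[chrom]}>")
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Transcript consequence">',
        '##INFO=<ID=AF_EVS,Number=A,Type=Float,Description="EVS allele frequency">',
        '##INFO=<ID=AF_1000G,Number=A,Type=Float,Description="1000 Genomes allele frequency">',
        '##INFO=<ID=AF_EXAC,Number=A,Type=Float,Description="ExAC allele frequency">',
        '##INFO=<ID=CONDEL,Number=1,Type=Float,Description="Condel consensus deleteriousness score">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    return "\n".join(lines) + "\n"


def _info_str(gene, csq, afs, condel, depth) -> str:
    parts = [f"GENE={gene}", f"CSQ={csq}"]
    for key, val in zip(("AF_EVS", "AF_1000G", "AF_EXAC"), afs):
        if val is not None:
            parts.append(f"{key}={val:g}")
    if condel is not None:
        parts.append(f"CONDEL={condel:g}")
    parts.append(f"DP={depth}")
    return ";".join(parts)


def _write_vcf(path: Path, models: list[GeneModel], rows: list[dict]) -> None:
    rows = sorted(rows, key=lambda r: (chromosome_sort_key(r["chrom"]), r["pos"],
                                       r["alt"]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_vcf_header(models))
        for r in rows:
            fh.write(
                f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t"
                f"{r['qual']:.1f}\tPASS\t"
                + _info_str(r["gene"], r["csq"], r["afs"], r["condel"], r["depth"])
                + "\n"
            )


def _background_rows(
    spec: SimulationSpec,
    sample_index: int,
    pool: list[tuple[str, int, str]],
) -> list[dict]:
    """Common (AF >= 0.011) coding background variants; all are expected
    to be hidden below VPI 1."""
    rng = np.random.default_rng([spec.seed, 7, sample_index])
    n = min(spec.background_variants_per_sample, len(pool))
    idx = rng.choice(len(pool), size=n, replace=False)
    rows = []
    for i in idx:
        chrom, pos, gene = pool[int(i)]
        ref, alt = _alleles(pos)
        af = float(rng.uniform(0.011, 0.5))
        csq = "missense_variant" if rng.random() < 0.7 else "synonymous_variant"
        rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "gene": gene,
            "csq": csq,
            "afs": (round(af, 6), round(af * 0.9, 6), round(af * 1.1, 6)),
            "condel": round(float(rng.uniform(0, 1)), 3),
            "depth": int(rng.integers(50, 200)),
            "qual": round(float(rng.uniform(100, 1000)), 1),
        })
    return rows


def _coverage_rows(
    spec: SimulationSpec,
    sample_index: int,
    models: list[GeneModel],
    dropouts: list[dict],
) -> list[str]:
    """Per-base depth lines over every exon of every captured gene.

    Depth is ``coverage_mean`` with +/- ``coverage_noise_frac`` integer
    noise, clamped to stay at least 5x above the QC threshold so noise
    can never fabricate a gap; planted dropout bases stay at least 5x
    below it so noise can never close one (exact-truth guard bands).
    """
    rng = np.random.default_rng([spec.seed, 13, sample_index])
    noise = max(1, int(spec.coverage_mean * spec.coverage_noise_frac))
    floor = spec.coverage_threshold + 5
    drop_hi = max(1, spec.coverage_threshold - 5)
    by_exon: dict[tuple[str, int, int], list[dict]] = {}
    for d in dropouts:
        by_exon.setdefault((d["chrom"], d["exon_start"], d["exon_end"]), []).append(d)
    lines: list[str] = []
    for m in models:
        for rank, (start, end) in enumerate(m.exons, start=1):
            length = end - start
            depths = spec.coverage_mean + rng.integers(-noise, noise + 1, size=length)
            depths = np.maximum(depths, floor)
            for d in by_exon.get((m.chrom, start, end), ()):
                lo, hi = d["start"] - start, d["end"] - start
                depths[lo:hi] = rng.integers(0, drop_hi, size=hi - lo)
            name = f"{m.name}_exon{rank}"
            for offset in range(length):
                lines.append(
                    f"{m.chrom}\t{start}\t{end}\t{name}\t{offset + 1}\t{int(depths[offset])}"
                )
    return lines


def _plan_dropouts(spec: SimulationSpec, models: list[GeneModel]) -> list[dict]:
    """Dropout regions for the first sample, each inside a distinct exon."""
    rng = np.random.default_rng([spec.seed, 17])
    hosts = [m for m in models if m.name.startswith("G")][-spec.n_dropout_regions:]
    dropouts = []
    for m in hosts:
        start, end = m.exons[0]
        length = int(rng.integers(10, 41))
        g_start = int(rng.integers(start + 5, end - length - 5))
        dropouts.append({
            "chrom": m.chrom, "gene": m.name,
            "exon_start": start, "exon_end": end,
            "start": g_start, "end": g_start + length,
        })
    return dropouts


def _sex_plan(spec: SimulationSpec) -> list[dict]:
    sids = spec.sample_ids()
    plan = []
    for i, sid in enumerate(sids):
        true_sex = "MALE" if i % 2 == 0 else "FEMALE"
        declared = true_sex
        mismatch = spec.plant_sex_mismatch and i == len(sids) - 1
        if mismatch:
            declared = "FEMALE" if true_sex == "MALE" else "MALE"
        plan.append({
            "sample_id": sid,
            "cohort": spec.cohorts[i % len(spec.cohorts)],
            "true_sex": true_sex,
            "declared_sex": declared,
            "sex_check_expected": "FAIL" if mismatch else "PASS",
        })
    return plan


def _write_profile(spec: SimulationSpec, models: list[GeneModel], data_dir: Path) -> None:
    roles = _role_genes(models)
    panel = sorted(m.name for m in models if m.name != roles["off_target"])
    (data_dir / "target_genes.txt").write_text(
        "\n".join(panel) + "\n", encoding="utf-8"
    )
    lines = [
        f"name={spec.profile_name}",
        "target_genes=@target_genes.txt",
        f"known_causal_genes={roles['known_a']},{roles['known_b']}",
        f"insilico_genes={roles['insilico']}",
        f"clinician_genes={roles['clinician']}",
        f"excluded_genes={roles['excluded']}",
        "splice_window_bp=2",
        "min_variant_coverage=15",
        "min_variant_qual=50",
        "rare_af_threshold=0.01",
        "very_rare_af_threshold=0.0005",
        "condel_threshold=0.07",
        f"coverage_qc_threshold={spec.coverage_threshold}",
        "median_coverage_min=50",
        "fragment_size_range=150,250",
        "max_duplicate_rate=0.25",
        "fastqc_fail_metrics=per_base_sequence_quality",
        "min_other_cohort_samples=3",
    ]
    (data_dir / "profile.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")


def generate_batch(spec: SimulationSpec, out_dir: str | Path) -> Path:
    """Write a complete synthetic batch under ``out_dir``.

    Produces ``data/`` (VCFs, coverage TSVs, BEDs, samples.tsv,
    metrics.tsv, profile + gene list) and ``truth.json``.  Refuses a
    non-empty destination rather than clobbering it.  Same spec + seed
    gives a byte-identical tree.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        raise FileExistsError(f"refusing to write into non-empty {out_dir}")
    data_dir = out_dir / "data"
    data_dir.mkdir(parents=True, exist_ok=True)

    models = build_gene_models(spec)
    plants = default_planted_variants(spec)
    artifacts = artifact_variants(spec)
    taken = _planted_positions(spec)
    pool = [
        (m.chrom, pos, m.name)
        for m in models
        if m.name != "OFFT1"
        for pos in m.exonic_positions
        if (m.chrom, pos) not in taken
    ]

    # BED files: exons (with gene_exonN names) and the merged target
    exon_lines, target_lines = [], []
    for m in sorted(models, key=lambda m: (chromosome_sort_key(m.chrom), m.exons[0][0])):
        for rank, (start, end) in enumerate(m.exons, start=1):
            exon_lines.append(f"{m.chrom}\t{start}\t{end}\t{m.name}_exon{rank}\t0\t+")
            target_lines.append(f"{m.chrom}\t{start}\t{end}\t{m.name}")
    (data_dir / "exons.bed").write_text("\n".join(exon_lines) + "\n", encoding="utf-8")
    (data_dir / "target.bed").write_text("\n".join(target_lines) + "\n", encoding="utf-8")

    sex_plan = _sex_plan(spec)
    dropouts = _plan_dropouts(spec, models)

    # per-sample VCF and coverage
    for i, entry in enumerate(sex_plan):
        sid = entry["sample_id"]
        rows = _background_rows(spec, i, pool)
        for a in artifacts:
            rows.append({
                "chrom": a["chrom"], "pos": a["pos"], "ref": a["ref"],
                "alt": a["alt"], "gene": a["gene"], "csq": a["consequence"],
                "afs": (None, None, None), "condel": a["condel"],
                "depth": 100, "qual": 500.0,
            })
        if i == 0:
            for p in plants:
                rows.append({
                    "chrom": p.chrom, "pos": p.pos, "ref": p.ref, "alt": p.alt,
                    "gene": p.gene, "csq": p.consequence,
                    "afs": (p.af_evs, p.af_1000g, p.af_exac),
                    "condel": p.condel, "depth": p.depth, "qual": p.qual,
                })
        _write_vcf(data_dir / f"{sid}.vcf", models, rows)

        sample_dropouts = dropouts if i == 0 else []
        cov_lines = _coverage_rows(spec, i, models, sample_dropouts)
        (data_dir / f"{sid}.cov.tsv").write_text(
            "\n".join(cov_lines) + "\n", encoding="utf-8"
        )

    # metadata and metrics
    rng = np.random.default_rng([spec.seed, 23])
    meta_lines = ["sample_id\tcohort\tsex\tprofile"]
    metric_lines = [
        "sample_id\tmedian_coverage\tmedian_fragment_size\tduplicate_rate"
        "\tmean_depth_x\tmean_depth_y\tmean_depth_autosome\tdeclared_sex"
        "\tfastqc_per_base_sequence_quality"
    ]
    for entry in sex_plan:
        auto = spec.coverage_mean * float(rng.uniform(0.95, 1.05))
        if entry["true_sex"] == "MALE":
            x, y = 0.5 * auto, 0.45 * auto
        else:
            x, y = 0.98 * auto, 0.005 * auto
        meta_lines.append(
            f"{entry['sample_id']}\t{entry['cohort']}\t{entry['declared_sex']}"
            f"\t{spec.profile_name}"
        )
        metric_lines.append(
            f"{entry['sample_id']}\t{spec.coverage_mean}\t{spec.fragment_size}"
            f"\t{spec.duplicate_rate}\t{x:.2f}\t{y:.2f}\t{auto:.2f}"
            f"\t{entry['declared_sex']}\tPASS"
        )
    (data_dir / "samples.tsv").write_text("\n".join(meta_lines) + "\n", encoding="utf-8")
    (data_dir / "metrics.tsv").write_text("\n".join(metric_lines) + "\n", encoding="utf-8")

    _write_profile(spec, models, data_dir)

    truth = {
        "seed": spec.seed,
        "coverage_threshold": spec.coverage_threshold,
        "samples": sex_plan,
        "planted_variants": [dataclasses.asdict(p) for p in plants],
        "artifact_variants": [
            {**a, "sample_ids": spec.sample_ids(),
             "store_samples": spec.artifact_store_samples}
            for a in artifacts
        ],
        "planted_gaps": [
            {"sample_id": spec.sample_ids()[0], "chrom": d["chrom"],
             "gene": d["gene"], "start": d["start"], "end": d["end"]}
            for d in dropouts
        ],
        "top_variant": {
            "sample_id": plants[0].sample_id, "chrom": plants[0].chrom,
            "pos": plants[0].pos, "ref": plants[0].ref, "alt": plants[0].alt,
        },
    }
    (out_dir / "truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return out_dir


def generate_population_store(spec: SimulationSpec, out_path: str | Path) -> Path:
    """Build the historical observation store the batch filters against.

    ``store_n_samples`` past samples spread round-robin over the spec's
    cohorts.  Each artefact variant is registered in the first
    ``artifact_store_samples`` of them (so it spans several cohorts and
    trips the default other-cohort policy for any querying cohort);
    each sample additionally carries a couple of private variants that
    must never trip it.
    """
    out_path = Path(out_path)
    if out_path.exists():
        out_path.unlink()
    models = build_gene_models(spec)
    artifacts = artifact_variants(spec)
    taken = _planted_positions(spec)
    rng = np.random.default_rng([spec.seed, 31])
    # private-variant pool: exonic, never colliding with plants/artifacts
    pool = [
        (m.chrom, pos)
        for m in models
        for pos in m.exonic_positions
        if (m.chrom, pos) not in taken
    ]
    with ObservationStore(out_path) as store:
        for i in range(spec.store_n_samples):
            sid = f"POP{i + 1:03d}"
            cohort = spec.cohorts[i % len(spec.cohorts)]
            keys = []
            if i < spec.artifact_store_samples:
                keys += [
                    VariantKey(a["chrom"], a["pos"], a["ref"], a["alt"])
                    for a in artifacts
                ]
            for _ in range(2):  # private singletons/doubletons
                chrom, pos = pool[int(rng.integers(0, len(pool)))]
                ref, alt = _alleles(pos)
                keys.append(VariantKey(chrom, pos, ref, alt))
            store.register_sample(sid, cohort, keys)
    return out_path
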