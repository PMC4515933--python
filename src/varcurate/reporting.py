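"""Curation outputs: ranked variant report, LOVD-compatible CSV,
coverage/QC report files, provenance manifest, and the batch layout.

Each analysis lives in a self-contained batch directory::

    batch/
      data/        raw inputs (read-only: VCFs, coverage, BEDs, metadata)
      design/      profile + gene lists, copied at first run, then frozen
      analysis/
        fastqc/ align/ variants/ qc/
        results/   every generated report

Design files are copied into ``design/`` before first use so a re-run
years later uses exactly the settings of the original analysis.  All
numeric output uses fixed precision (frequencies to six decimals) so
that identical inputs produce byte-identical report files; with
timestamps disabled the provenance manifest is byte-stable too.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

from . import __version__
from .coverage_qc import (
    ExonCoverageRow,
    GapRegion,
    GeneCoverageRow,
    exon_report,
    find_gaps,
    gene_report,
    read_exon_bed,
    read_per_base_coverage,
)
from .errors import ConfigurationError
from .obsdb import ObservationStore, sha256_file, snapshot
from .prioritise import (
    PriorityDecision,
    annotate_priorities,
    apply_filters,
    sort_for_report,
)
from .profiles import AnalysisProfile, parse_profile, serialize_profile
from .sample_checks import CheckResult, overall_verdict, read_metrics_tsv, run_all_checks
from .variant_ingest import VariantRecord, read_annotated_vcf

__all__ = [
    "REPORT_COLUMNS",
    "LOVD_COLUMNS",
    "BatchLayout",
    "write_variant_report",
    "write_removed_report",
    "write_lovd_csv",
    "write_provenance",
    "write_gap_report",
    "write_exon_report",
    "write_gene_report",
    "write_check_report",
    "run_batch",
    "run_qc",
]

#: stable column order of the main curation report
REPORT_COLUMNS = [
    "sample", "gene", "gpi", "vpi", "chrom", "pos", "ref", "alt",
    "consequence", "af_evs", "af_1000g", "af_exac", "condel",
    "internal_count", "internal_frequency", "depth", "qual",
]

#: LOVD-style column mapping (same content, remapped names/layout)
LOVD_COLUMNS = [
    "chromosome", "position_g_start", "position_g_end", "allele_ref",
    "allele_alt", "gene_symbol", "effect_reported", "frequency_evs",
    "frequency_1000g", "frequency_exac", "condel_score",
    "variant_priority_index", "gene_priority_index", "sample_id",
]


def _fmt_frac(value: float | None) -> str:
    """Fractions at fixed 6-decimal precision; absent stays empty."""
    return "" if value is None else f"{value:.6f}"


def _fmt_int(value: int | None) -> str:
    return "" if value is None else str(value)


def write_variant_report(records: list[VariantRecord], out_path: str | Path) -> Path:
    """Write the ranked curation spreadsheet (CSV).

    Row order is the input order — callers pass the output of
    :func:`varcurate.prioritise.sort_for_report`.  Absent annotations
    are empty cells, never zero-filled.
    """
    out_path = Path(out_path)
    with open(out_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for r in records:
            writer.writerow([
                r.sample_id,
                r.gene or "",
                r.gpi,
                r.vpi,
                r.chrom,
                r.pos,
                r.ref,
                r.alt,
                r.consequence.value,
                _fmt_frac(r.af_evs),
                _fmt_frac(r.af_1000g),
                _fmt_frac(r.af_exac),
                _fmt_frac(r.condel),
                _fmt_int(r.internal_count),
                _fmt_frac(r.internal_frequency),
                r.depth,
                f"{r.qual:.1f}",
            ])
    return out_path


def write_removed_report(
    removed: list[tuple[VariantRecord, PriorityDecision]], out_path: str | Path
) -> Path:
    """Audit file of hidden/filtered variants with their reasons."""
    out_path = Path(out_path)
    with open(out_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(REPORT_COLUMNS + ["filter_reasons"])
        for r, decision in removed:
            writer.writerow([
                r.sample_id, r.gene or "", r.gpi, r.vpi, r.chrom, r.pos,
                r.ref, r.alt, r.consequence.value,
                _fmt_frac(r.af_evs), _fmt_frac(r.af_1000g), _fmt_frac(r.af_exac),
                _fmt_frac(r.condel), _fmt_int(r.internal_count),
                _fmt_frac(r.internal_frequency), r.depth, f"{r.qual:.1f}",
                ";".join(decision.filter_reasons),
            ])
    return out_path


def write_lovd_csv(records: list[VariantRecord], out_path: str | Path) -> Path:
    """Write the same retained variants in LOVD import layout.

    Content is identical to the main report, remapped to LOVD-style
    columns; row count and multiset of variants always match.
    """
    out_path = Path(out_path)
    with open(out_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(LOVD_COLUMNS)
        for r in records:
            writer.writerow([
                r.chrom,
                r.pos,
                r.pos + len(r.ref) - 1,
                r.ref,
                r.alt,
                r.gene or "",
                r.consequence.value,
                _fmt_frac(r.af_evs),
                _fmt_frac(r.af_1000g),
                _fmt_frac(r.af_exac),
                _fmt_frac(r.condel),
                r.vpi,
                r.gpi,
                r.sample_id,
            ])
    return out_path


def _profile_settings_dict(profile: AnalysisProfile) -> dict:
    out: dict = {}
    for f in dataclasses.fields(profile):
        value = getattr(profile, f.name)
        if isinstance(value, frozenset):
            value = sorted(value)
        elif f.name == "internal_db_policy":
            value = dataclasses.asdict(value)
        elif isinstance(value, tuple):
            value = list(value)
        out[f.name] = value
    return out


def write_provenance(
    inputs: list[str | Path],
    profile: AnalysisProfile,
    outputs: list[str | Path],
    out_path: str | Path,
    timestamp: bool = True,
) -> Path:
    """Record what was analysed, with what settings, producing what.

    Every listed file is captured as (path, byte size, SHA-256 digest);
    a missing file is an error naming it.  With ``timestamp=False`` the
    manifest is byte-identical across reruns on identical inputs.
    """
    from datetime import datetime, timezone

    def describe(paths: list[str | Path]) -> list[dict]:
        entries = []
        for p in paths:
            p = Path(p)
            if not p.exists():
                raise FileNotFoundError(f"provenance input missing: {p}")
            entries.append(
                {"path": p.name, "size": p.stat().st_size, "sha256": sha256_file(p)}
            )
        return entries

    manifest = {
        "tool": "varcurate",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat() if timestamp else None,
        "settings": _profile_settings_dict(profile),
        "inputs": describe(inputs),
        "outputs": describe(outputs),
    }
    out_path = Path(out_path)
    out_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return out_path


# -- coverage / check report files --------------------------------------


def _write_tsv(out_path: Path, header: list[str], rows: list[list]) -> Path:
    with open(out_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)
    return out_path


def write_gap_report(gaps: list[GapRegion], out_path: str | Path) -> Path:
    return _write_tsv(
        Path(out_path),
        ["chrom", "start", "end", "length", "min_depth", "median_depth",
         "gene", "exon_rank"],
        [[g.chrom, g.start, g.end, g.length, g.min_depth, g.median_depth,
          g.gene or "", _fmt_int(g.exon_rank)] for g in gaps],
    )


def write_exon_report(rows: list[ExonCoverageRow], out_path: str | Path) -> Path:
    return _write_tsv(
        Path(out_path),
        ["gene", "exon_rank", "chrom", "start", "end",
         "fraction_below_threshold", "median_depth", "status"],
        [[r.gene, _fmt_int(r.exon_rank), r.chrom, r.start, r.end,
          f"{r.fraction_below_threshold:.6f}", r.median_depth, r.status]
         for r in rows],
    )


def write_gene_report(rows: list[GeneCoverageRow], out_path: str | Path) -> Path:
    return _write_tsv(
        Path(out_path),
        ["gene", "median_depth", "fraction_targeted_bases_ok", "n_exons",
         "n_exons_partial_or_none", "colour"],
        [[r.gene, r.median_depth, f"{r.fraction_targeted_bases_ok:.6f}",
          r.n_exons, r.n_exons_partial_or_none, r.colour] for r in rows],
    )


def write_check_report(
    results_by_sample: dict[str, list[CheckResult]],
    tsv_path: str | Path,
    json_path: str | Path,
) -> None:
    rows = []
    payload = {}
    for sample_id in sorted(results_by_sample):
        results = results_by_sample[sample_id]
        payload[sample_id] = {
            "verdict": overall_verdict(results),
            "checks": [dataclasses.asdict(r) for r in results],
        }
        for r in results:
            rows.append([
                sample_id, r.check_name, r.status,
                "" if r.observed is None else str(r.observed),
                "" if r.limit is None else str(r.limit),
                r.message,
            ])
    _write_tsv(
        Path(tsv_path),
        ["sample_id", "check", "status", "observed", "limit", "message"],
        rows,
    )
    Path(json_path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )


# -- batch layout and orchestration -------------------------------------


@dataclasses.dataclass(frozen=True)
class BatchLayout:
    """Standard directory structure for one analysis batch."""

    batch_dir: Path

    @property
    def data_dir(self) -> Path:
        return self.batch_dir / "data"

    @property
    def design_dir(self) -> Path:
        return self.batch_dir / "design"

    @property
    def analysis_dir(self) -> Path:
        return self.batch_dir / "analysis"

    @property
    def qc_dir(self) -> Path:
        return self.analysis_dir / "qc"

    @property
    def results_dir(self) -> Path:
        return self.analysis_dir / "results"

    @classmethod
    def create(cls, batch_dir: str | Path) -> "BatchLayout":
        layout = cls(Path(batch_dir))
        for sub in ("fastqc", "align", "variants", "qc", "results"):
            (layout.analysis_dir / sub).mkdir(parents=True, exist_ok=True)
        layout.data_dir.mkdir(parents=True, exist_ok=True)
        layout.design_dir.mkdir(parents=True, exist_ok=True)
        return layout

    def freeze_design(self, profile_path: str | Path) -> Path:
        """Copy the profile (with gene-list sidecars) into design/ once.

        Already-frozen design files are never overwritten, so re-runs
        use the settings in force at the first analysis.
        """
        profile_path = Path(profile_path)
        frozen = self.design_dir / profile_path.name
        if not frozen.exists():
            profile = parse_profile(profile_path)
            # serialise with inline gene lists: self-contained design copy
            serialize_profile(profile, frozen)
        return frozen


def _read_samples_tsv(path: Path) -> list[dict]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cohort"}
    if not required <= set(df.columns):
        raise ConfigurationError(
            f"{path}: sample metadata needs columns {sorted(required)}"
        )
    return df.to_dict("records")


def run_batch(
    batch_dir: str | Path,
    db_path: str | Path | None = None,
    no_timestamps: bool = False,
) -> dict[str, dict]:
    """Run ingest -> prioritise -> filter -> reports for a whole batch.

    Expects under ``data/``: one ``<sample>.vcf`` per sample,
    ``exons.bed``, ``samples.tsv`` and ``profile.txt``.  The observation
    store (if given) is snapshotted first, every sample is filtered
    against that pre-analysis state, and the batch's samples are
    registered only after all reports are written — within one batch no
    sample filters another.
    """
    layout = BatchLayout.create(batch_dir)
    profile = parse_profile(layout.freeze_design(layout.data_dir / "profile.txt"))
    samples = _read_samples_tsv(layout.data_dir / "samples.tsv")
    exons = read_exon_bed(layout.data_dir / "exons.bed")
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    for exon in exons:
        exons_by_gene.setdefault(exon.gene, []).append((exon.start, exon.end))

    store = ObservationStore(db_path) if db_path is not None else None
    if store is not None:
        snapshot(
            store, layout.qc_dir / "obsdb.snapshot.sqlite",
            timestamp=not no_timestamps,
        )

    summary: dict[str, dict] = {}
    to_register: list[tuple[str, str, list]] = []
    outputs: list[Path] = []
    for row in sorted(samples, key=lambda r: r["sample_id"]):
        sid, cohort = row["sample_id"], row["cohort"]
        vcf_path = layout.data_dir / f"{sid}.vcf"
        records = list(read_annotated_vcf(vcf_path, sample_id=sid))
        annotate_priorities(records, profile, exons_by_gene)
        retained, removed = apply_filters(
            records, profile, store=store, querying_cohort=cohort
        )
        ordered = sort_for_report(retained)
        out_main = write_variant_report(
            ordered, layout.results_dir / f"{sid}.variants.csv"
        )
        out_lovd = write_lovd_csv(ordered, layout.results_dir / f"{sid}.lovd.csv")
        out_removed = write_removed_report(
            removed, layout.results_dir / f"{sid}.removed.csv"
        )
        outputs += [out_main, out_lovd, out_removed]
        to_register.append((sid, cohort, [r.key for r in records]))
        summary[sid] = {
            "retained": ordered,
            "removed": removed,
            "report": out_main,
            "lovd": out_lovd,
        }

    if store is not None:
        for sid, cohort, keys in to_register:
            store.register_sample(sid, cohort, keys)

    inputs = [layout.data_dir / "exons.bed", layout.data_dir / "samples.tsv"] + [
        layout.data_dir / f"{row['sample_id']}.vcf" for row in samples
    ]
    write_provenance(
        inputs, profile, outputs,
        layout.results_dir / "provenance.json",
        timestamp=not no_timestamps,
    )
    return summary


def run_qc(batch_dir: str | Path) -> dict[str, str]:
    """Coverage reports plus automated sample checks for a batch.

    Expects ``data/<sample>.cov.tsv`` per-base coverage files,
    ``data/exons.bed`` and ``data/metrics.tsv``.  Writes gap/exon/gene
    TSVs and the check report under ``analysis/qc``; returns the
    per-sample verdicts.
    """
    layout = BatchLayout.create(batch_dir)
    profile = parse_profile(layout.freeze_design(layout.data_dir / "profile.txt"))
    exons = read_exon_bed(layout.data_dir / "exons.bed")
    threshold = profile.coverage_qc_threshold

    for cov_path in sorted(layout.data_dir.glob("*.cov.tsv")):
        sid = cov_path.name.split(".")[0]
        track = read_per_base_coverage(cov_path, sample_id=sid)
        write_gap_report(
            find_gaps(track, threshold, exons), layout.qc_dir / f"{sid}.gaps.tsv"
        )
        write_exon_report(
            exon_report(track, exons, threshold), layout.qc_dir / f"{sid}.exons.tsv"
        )
        write_gene_report(
            gene_report(track, exons, threshold,
                        profile.green_min_ok, profile.amber_min_ok),
            layout.qc_dir / f"{sid}.genes.tsv",
        )

    verdicts: dict[str, str] = {}
    metrics_path = layout.data_dir / "metrics.tsv"
    if metrics_path.exists():
        results_by_sample = {}
        for metrics in read_metrics_tsv(metrics_path):
            results = run_all_checks(metrics, profile)
            results_by_sample[metrics.sample_id] = results
            verdicts[metrics.sample_id] = overall_verdict(results)
        write_check_report(
            results_by_sample,
            layout.qc_dir / "checks.tsv",
            layout.qc_dir / "checks.json",
        )
    return verdicts
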