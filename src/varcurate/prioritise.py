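"""Variant and gene prioritisation, filtering, and report ordering.

The Variant Priority Index (VPI) places each variant in one of four
tiers using population rarity, conservation and predicted protein
impact:

* VPI 1 — "rare": missense or in-frame indel with allele frequency
  below 0.01 in every population database (EVS, 1000 Genomes, ExAC);
* VPI 2 — "very rare or novel": as above but below 0.0005, or absent
  from all databases;
* VPI 3 — additionally "highly conserved": Condel score above 0.07;
* VPI 4 — frameshift, truncating and splice-site variants.

Tiers 1-3 are nested subsets.  Variants below VPI 1 are hidden from the
curation report.  The Gene Priority Index (GPI) is the a-priori gene
category from the analysis profile (see :mod:`varcurate.profiles`).
Retained variants are ordered so the most promising rise to the top:
VPI descending, then GPI descending, then karyotype position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import profiles as _profiles
from .obsdb import ObservationStore, internal_filter_decision
from .profiles import AnalysisProfile
from .variant_ingest import (
    ConsequenceClass,
    VariantRecord,
    classify_splice_region,
    max_population_af,
)

__all__ = [
    "PriorityDecision",
    "assign_vpi",
    "assign_gpi",
    "apply_filters",
    "sort_for_report",
    "chromosome_sort_key",
    "FILTER_REASONS",
]

#: stable public vocabulary of removal reasons written to reports
FILTER_REASONS = (
    "HIDDEN_BELOW_VPI1",
    "GENE_EXCLUDED",
    "GENE_OFF_TARGET",
    "LOW_DEPTH",
    "LOW_QUAL",
    "INTERNAL_DB_COMMON",
)

_VPI4_CLASSES = frozenset(
    {ConsequenceClass.FRAMESHIFT, ConsequenceClass.TRUNCATING, ConsequenceClass.SPLICE}
)
_MISSENSE_LIKE = frozenset(
    {ConsequenceClass.MISSENSE, ConsequenceClass.INFRAME_INDEL}
)


@dataclass
class PriorityDecision:
    """Outcome of prioritisation and filtering for one variant."""

    vpi: int
    gpi: int
    retained: bool
    filter_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.retained and self.filter_reasons:
            raise ValueError("retained decision must carry no filter reasons")
        if not self.retained and not self.filter_reasons:
            raise ValueError("removed decision must carry at least one reason")


def assign_vpi(
    record: VariantRecord, profile: AnalysisProfile, is_splice: bool = False
) -> int:
    """Variant Priority Index, 0 (hidden) to 4.

    Frameshift, truncating and splice-site consequences (or an intronic
    position inside the profile's splice window) are tier 4 regardless
    of population frequency, unless the profile opts in to applying the
    rare-frequency cut there too.  Missense and in-frame indels enter
    the nested rarity tiers with strict inequalities; a variant absent
    from every population database counts below every threshold.  A
    missing Condel score never reaches tier 3 (conservation unproven).
    """
    max_af = max_population_af(record)
    if record.consequence in _VPI4_CLASSES or is_splice:
        if (
            profile.apply_af_filter_to_vpi4
            and max_af is not None
            and max_af >= profile.rare_af_threshold
        ):
            return 0
        return 4
    if record.consequence not in _MISSENSE_LIKE:
        return 0
    below_rare = max_af is None or max_af < profile.rare_af_threshold
    below_very_rare = max_af is None or max_af < profile.very_rare_af_threshold
    conserved = record.condel is not None and record.condel > profile.condel_threshold
    if below_very_rare and conserved:
        return 3
    if below_very_rare:
        return 2
    if below_rare:
        return 1
    return 0


def assign_gpi(record: VariantRecord, profile: AnalysisProfile) -> int:
    """Gene Priority Index: the profile's category for the variant's gene."""
    return _profiles.gene_category(profile, record.gene)


def annotate_priorities(
    records: list[VariantRecord],
    profile: AnalysisProfile,
    exons_by_gene: dict[str, list[tuple[int, int]]] | None = None,
) -> list[VariantRecord]:
    """Assign VPI and GPI in place on every record; returns the list.

    ``exons_by_gene`` supplies 0-based half-open exon intervals used for
    splice-window classification; without it no positional splice calls
    are made (explicit splice consequences still reach VPI 4).
    """
    for rec in records:
        is_splice = False
        if exons_by_gene and rec.gene:
            exons = exons_by_gene.get(rec.gene.upper())
            if exons:
                is_splice = classify_splice_region(
                    rec.pos, exons, profile.splice_window_bp
                )
        rec.vpi = assign_vpi(rec, profile, is_splice=is_splice)
        rec.gpi = assign_gpi(rec, profile)
    return records


def apply_filters(
    records: list[VariantRecord],
    profile: AnalysisProfile,
    store: ObservationStore | None = None,
    querying_cohort: str | None = None,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, PriorityDecision]]]:
    """Partition records into (retained, removed-with-decision).

    A record is removed, with every applicable reason recorded, when it
    is below VPI 1, its gene is off-target or excluded, it fails the
    profile's depth or quality gates, or the internal-database policy
    excludes it.  The analysed sample's own prior registration is never
    counted against it.  Every input record lands in exactly one of the
    two outputs.
    """
    retained: list[VariantRecord] = []
    removed: list[tuple[VariantRecord, PriorityDecision]] = []
    for rec in records:
        reasons: list[str] = []
        if rec.vpi == 0:
            reasons.append("HIDDEN_BELOW_VPI1")
        if rec.gpi == 0:
            gene = rec.gene.upper() if rec.gene else None
            if gene is not None and gene in profile.excluded_genes:
                reasons.append("GENE_EXCLUDED")
            else:
                reasons.append("GENE_OFF_TARGET")
        if rec.depth < profile.min_variant_coverage:
            reasons.append("LOW_DEPTH")
        if rec.qual < profile.min_variant_qual:
            reasons.append("LOW_QUAL")
        if store is not None:
            stats = store.observation_stats(
                rec.key,
                querying_cohort=querying_cohort,
                exclude_sample=rec.sample_id,
            )
            rec.internal_count = stats.count_total
            rec.internal_frequency = stats.internal_frequency
            if internal_filter_decision(stats, profile.internal_db_policy):
                reasons.append("INTERNAL_DB_COMMON")
        rec.filter_reasons = reasons
        if reasons:
            removed.append(
                (rec, PriorityDecision(rec.vpi, rec.gpi, False, reasons))
            )
        else:
            retained.append(rec)
    return retained, removed


_KARYOTYPE = {str(i): i for i in range(1, 23)}
_KARYOTYPE.update({"X": 23, "Y": 24, "MT": 25, "M": 25})


def chromosome_sort_key(chrom: str) -> tuple[int, str]:
    """Karyotype order: 1..22, X, Y, MT, then other contigs lexically."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    rank = _KARYOTYPE.get(name.upper())
    return (rank, "") if rank is not None else (26, name)


def sort_for_report(records: list[VariantRecord]) -> list[VariantRecord]:
    """Order retained variants with the most promising first.

    Stable sort on (VPI desc, GPI desc, karyotype chromosome, position,
    alternate allele); output is invariant under input permutation
    because the key tuple is a total order over distinct variants.
    """
    return sorted(
        records,
        key=lambda r: (
            -r.vpi,
            -r.gpi,
            chromosome_sort_key(r.chrom),
            r.pos,
            r.alt,
            r.ref,
            r.sample_id,
        ),
    )
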