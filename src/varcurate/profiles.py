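"""Analysis profiles: per-patient-group analysis settings.

A profile bundles the gene lists and thresholds that customise every
downstream stage for one patient group: the target gene panel, the
narrower curated gene categories used for gene prioritisation, allele
frequency and conservation cut-offs for variant tiering, variant-level
quality gates, coverage-QC thresholds and the internal-database
exclusion policy.  Profiles are plain ``key=value`` text files so that a
laboratory can version, review and accredit each one independently.

Gene priority categories (GPI):

1. gene is anywhere in the profile's target region,
2. gene is commonly known to be causal for the disease group,
3. gene was prioritised for this patient by in-silico tools,
4. gene was nominated by the treating clinician.

A gene on the excluded list is never reported, regardless of any other
membership.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import ConfigurationError

__all__ = [
    "AnalysisProfile",
    "InternalFilterPolicy",
    "parse_profile",
    "serialize_profile",
    "gene_category",
]

#: keys whose values are gene lists (inline comma-separated or @file sidecar)
_GENE_LIST_KEYS = (
    "target_genes",
    "known_causal_genes",
    "insilico_genes",
    "clinician_genes",
    "excluded_genes",
)

_INT_KEYS = (
    "splice_window_bp",
    "min_variant_coverage",
    "coverage_qc_threshold",
    "median_coverage_min",
    "min_other_cohort_samples",
)

_FLOAT_KEYS = (
    "min_variant_qual",
    "rare_af_threshold",
    "very_rare_af_threshold",
    "condel_threshold",
    "max_duplicate_rate",
    "max_internal_frequency",
    "green_min_ok",
    "amber_min_ok",
)


@dataclass(frozen=True)
class InternalFilterPolicy:
    """Policy for excluding variants seen repeatedly in the local database.

    A variant is excluded when it has been observed in at least
    ``min_other_cohort_samples`` samples belonging to *other* disease
    cohorts, or when its overall internal observation frequency exceeds
    ``max_internal_frequency`` (disabled when ``None``).  The policy is
    inert while the store holds fewer than two samples.
    """

    min_other_cohort_samples: int = 3
    max_internal_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.min_other_cohort_samples < 1:
            raise ConfigurationError(
                "min_other_cohort_samples must be >= 1, got "
                f"{self.min_other_cohort_samples}"
            )
        if self.max_internal_frequency is not None:
            f = self.max_internal_frequency
            if not math.isfinite(f) or not 0 < f <= 1:
                raise ConfigurationError(
                    f"max_internal_frequency must be a fraction in (0,1], got {f}"
                )


def _norm_gene(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class AnalysisProfile:
    """Validated per-sample analysis settings.

    Thresholds default to the tiering cut-offs used throughout:
    rare AF < 0.01, very rare AF < 0.0005, Condel conservation > 0.07,
    and a 15x coverage-QC depth threshold.  Sample-level QC limits
    (median coverage, fragment-size range, duplicate rate, FASTQC
    metrics) have no default: a check whose limit is unset is skipped.
    """

    name: str
    target_genes: frozenset[str] = frozenset()
    known_causal_genes: frozenset[str] = frozenset()
    insilico_genes: frozenset[str] = frozenset()
    clinician_genes: frozenset[str] = frozenset()
    excluded_genes: frozenset[str] = frozenset()
    splice_window_bp: int = 2
    min_variant_coverage: int = 0
    min_variant_qual: float = 0.0
    rare_af_threshold: float = 0.01
    very_rare_af_threshold: float = 0.0005
    condel_threshold: float = 0.07
    coverage_qc_threshold: int = 15
    median_coverage_min: int | None = None
    fragment_size_range: tuple[int, int] | None = None
    max_duplicate_rate: float | None = None
    fastqc_fail_metrics: frozenset[str] = frozenset()
    green_min_ok: float = 0.95
    amber_min_ok: float = 0.80
    apply_af_filter_to_vpi4: bool = False
    internal_db_policy: InternalFilterPolicy = field(
        default_factory=InternalFilterPolicy
    )
    extra_settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("profile must have a non-empty name")
        if not 0 < self.rare_af_threshold <= 1:
            raise ConfigurationError(
                f"rare_af_threshold must be in (0,1], got {self.rare_af_threshold}"
            )
        if not 0 < self.very_rare_af_threshold <= 1:
            raise ConfigurationError(
                "very_rare_af_threshold must be in (0,1], got "
                f"{self.very_rare_af_threshold}"
            )
        if self.very_rare_af_threshold > self.rare_af_threshold:
            raise ConfigurationError(
                f"very_rare_af_threshold ({self.very_rare_af_threshold}) must not "
                f"exceed rare_af_threshold ({self.rare_af_threshold})"
            )
        if self.splice_window_bp < 0:
            raise ConfigurationError("splice_window_bp must be >= 0")
        if self.min_variant_coverage < 0 or self.min_variant_qual < 0:
            raise ConfigurationError("variant quality/coverage gates must be >= 0")
        if self.coverage_qc_threshold <= 0:
            raise ConfigurationError("coverage_qc_threshold must be > 0")
        if self.fragment_size_range is not None:
            lo, hi = self.fragment_size_range
            if lo >= hi:
                raise ConfigurationError(
                    f"fragment_size_range low ({lo}) must be < high ({hi})"
                )
        if not self.amber_min_ok < self.green_min_ok:
            raise ConfigurationError(
                "amber_min_ok must be strictly below green_min_ok"
            )

    def validated(self) -> "AnalysisProfile":
        """Return a copy with gene lists reconciled against the target panel.

        In-silico and clinician nominations outside the target region are
        clamped to it (with a warning): a gene the assay does not capture
        cannot be prioritised.  Genes both excluded and clinician-nominated
        are dropped from the clinician list — exclusion dominates.
        """
        prof = self
        for key in ("insilico_genes", "clinician_genes"):
            genes = getattr(prof, key)
            off_target = genes - prof.target_genes
            if off_target:
                warnings.warn(
                    f"profile {prof.name!r}: {key} outside target panel "
                    f"ignored: {sorted(off_target)}",
                    stacklevel=2,
                )
                prof = replace(prof, **{key: genes & prof.target_genes})
        conflict = prof.clinician_genes & prof.excluded_genes
        if conflict:
            warnings.warn(
                f"profile {prof.name!r}: excluded genes removed from the "
                f"clinician list: {sorted(conflict)}",
                stacklevel=2,
            )
            prof = replace(prof, clinician_genes=prof.clinician_genes - conflict)
        return prof


def gene_category(profile: AnalysisProfile, gene: str | None) -> int:
    """Gene priority category (GPI) of ``gene`` under ``profile``, 0-4.

    0 when the gene is absent, off-target or excluded; otherwise the
    highest category among the lists containing it (target=1, known
    causal=2, in-silico=3, clinician=4).  Symbols compare
    case-insensitively after trimming.  Total: never raises.
    """
    if gene is None:
        return 0
    g = _norm_gene(gene)
    if not g or g not in profile.target_genes or g in profile.excluded_genes:
        return 0
    cat = 1
    if g in profile.known_causal_genes:
        cat = 2
    if g in profile.insilico_genes:
        cat = 3
    if g in profile.clinician_genes:
        cat = 4
    return cat


def _parse_gene_value(value: str, base_dir: Path) -> frozenset[str]:
    value = value.strip()
    if not value:
        return frozenset()
    if value.startswith("@"):
        list_path = base_dir / value[1:]
        if not list_path.exists():
            raise ConfigurationError(f"gene list file not found: {list_path}")
        symbols = list_path.read_text(encoding="utf-8").splitlines()
    else:
        symbols = value.split(",")
    return frozenset(_norm_gene(s) for s in symbols if _norm_gene(s))


def parse_profile(path: str | Path) -> AnalysisProfile:
    """Parse an analysis profile from a flat ``key=value`` text file.

    Lines starting with ``#`` and blank lines are ignored.  Gene-list
    values are either inline comma-separated symbols or ``@file``
    references to one-symbol-per-line sidecar files resolved relative to
    the profile.  Unknown keys are preserved verbatim in
    ``extra_settings``, never rejected.  A missing ``name`` or a
    non-numeric threshold is a :class:`ConfigurationError`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"profile file not found: {path}")
    base_dir = path.parent

    fields: dict = {}
    extra: dict[str, str] = {}
    policy_kwargs: dict = {}
    for lineno, raw in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(
                f"{path}:{lineno}: expected key=value, got {raw!r}"
            )
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key in _GENE_LIST_KEYS:
            fields[key] = _parse_gene_value(value, base_dir)
        elif key in _INT_KEYS or key in _FLOAT_KEYS:
            caster = int if key in _INT_KEYS else float
            try:
                cast = caster(value)
            except ValueError:
                raise ConfigurationError(
                    f"{path}:{lineno}: non-numeric value for {key!r}: {value!r}"
                ) from None
            if key in ("min_other_cohort_samples", "max_internal_frequency"):
                policy_kwargs[key] = cast
            else:
                fields[key] = cast
        elif key == "fragment_size_range":
            parts = value.split(",")
            try:
                lo, hi = (int(p) for p in parts)
            except ValueError:
                raise ConfigurationError(
                    f"{path}:{lineno}: fragment_size_range must be two "
                    f"comma-separated integers, got {value!r}"
                ) from None
            fields[key] = (lo, hi)
        elif key == "fastqc_fail_metrics":
            fields[key] = frozenset(
                m.strip() for m in value.split(",") if m.strip()
            )
        elif key == "apply_af_filter_to_vpi4":
            fields[key] = value.lower() in ("1", "true", "yes", "on")
        elif key == "name":
            fields[key] = value
        else:
            extra[key] = value

    if "name" not in fields or not fields["name"]:
        raise ConfigurationError(f"{path}: profile is missing required key 'name'")

    try:
        profile = AnalysisProfile(
            internal_db_policy=InternalFilterPolicy(**policy_kwargs),
            extra_settings=extra,
            **fields,
        )
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigurationError(f"{path}: {exc}") from exc
    return profile.validated()


def serialize_profile(profile: AnalysisProfile, path: str | Path) -> Path:
    """Write ``profile`` back to ``key=value`` text; inverse of parse.

    Gene lists are written inline (sorted, comma-separated) so the file
    is self-contained.  ``parse_profile(serialize_profile(p)) == p`` for
    any validated profile.
    """
    path = Path(path)
    lines = [f"name={profile.name}"]
    for key in _GENE_LIST_KEYS:
        genes: frozenset[str] = getattr(profile, key)
        lines.append(f"{key}={','.join(sorted(genes))}")
    for key in (
        "splice_window_bp",
        "min_variant_coverage",
        "min_variant_qual",
        "rare_af_threshold",
        "very_rare_af_threshold",
        "condel_threshold",
        "coverage_qc_threshold",
        "green_min_ok",
        "amber_min_ok",
    ):
        lines.append(f"{key}={getattr(profile, key)!r}")
    if profile.median_coverage_min is not None:
        lines.append(f"median_coverage_min={profile.median_coverage_min}")
    if profile.fragment_size_range is not None:
        lo, hi = profile.fragment_size_range
        lines.append(f"fragment_size_range={lo},{hi}")
    if profile.max_duplicate_rate is not None:
        lines.append(f"max_duplicate_rate={profile.max_duplicate_rate!r}")
    if profile.fastqc_fail_metrics:
        lines.append(
            "fastqc_fail_metrics=" + ",".join(sorted(profile.fastqc_fail_metrics))
        )
    lines.append(
        f"apply_af_filter_to_vpi4={'true' if profile.apply_af_filter_to_vpi4 else 'false'}"
    )
    pol = profile.internal_db_policy
    lines.append(f"min_other_cohort_samples={pol.min_other_cohort_samples}")
    if pol.max_internal_frequency is not None:
        lines.append(f"max_internal_frequency={pol.max_internal_frequency!r}")
    for key, value in sorted(profile.extra_settings.items()):
        lines.append(f"{key}={value}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
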