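"""Automated per-sample QC gates.

Five checks run before a sample's variants are released for curation:
raw-read quality flags (a configurable list of FASTQC metrics), overall
median coverage, median fragment size (inclusive range), PCR duplicate
rate, and consistency of the bioinformatically inferred sex with the
sex declared on the sample sheet.  Each check yields a structured
PASS / FAIL / SKIPPED result; a check whose limit the profile does not
configure is SKIPPED.  The overall sample verdict fails iff any single
check fails.

Sex is inferred from X and Y mean depth relative to autosomal depth.
Let rx = X/autosome and ry = Y/autosome: a male sample (one X, one Y)
shows ry well above zero and rx near 0.5; a female sample shows
essentially no Y coverage and rx near 1.  Ratios between those regimes
fall in a dead zone and return UNKNOWN rather than risking a wrong
call — for a clinical gate an abstention is recoverable, a confidently
wrong sex is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .profiles import AnalysisProfile

__all__ = [
    "SampleMetrics",
    "CheckResult",
    "run_threshold_checks",
    "infer_sex",
    "check_sex",
    "run_all_checks",
    "overall_verdict",
    "read_metrics_tsv",
]

MALE, FEMALE, UNKNOWN = "MALE", "FEMALE", "UNKNOWN"

# inference cut-offs on depth ratios (see module docstring)
Y_RATIO_MALE_MIN = 0.2
Y_RATIO_FEMALE_MAX = 0.05
X_RATIO_MALE_MAX = 0.8
X_RATIO_FEMALE_MIN = 0.8


@dataclass(frozen=True)
class SampleMetrics:
    """Per-sample summary metrics consumed by the QC gates."""

    sample_id: str
    median_coverage: float
    median_fragment_size: float
    duplicate_rate: float
    mean_depth_x: float
    mean_depth_y: float
    mean_depth_autosome: float
    declared_sex: str = UNKNOWN
    fastqc_flags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.duplicate_rate <= 1:
            raise ValueError(
                f"duplicate_rate must be in [0,1], got {self.duplicate_rate}"
            )
        for name in ("median_coverage", "mean_depth_x", "mean_depth_y",
                     "mean_depth_autosome"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CheckResult:
    check_name: str
    status: str  # PASS | FAIL | SKIPPED
    observed: object = None
    limit: object = None
    message: str = ""

    def __post_init__(self) -> None:
        if self.status == "FAIL" and not self.message:
            raise ValueError("FAIL results must carry a message")


def _result(name, ok: bool, observed, limit, fail_msg: str) -> CheckResult:
    if ok:
        return CheckResult(name, "PASS", observed, limit)
    return CheckResult(name, "FAIL", observed, limit, fail_msg)


def run_threshold_checks(
    metrics: SampleMetrics, profile: AnalysisProfile
) -> list[CheckResult]:
    """Run the FASTQC, coverage, fragment-size and duplicate-rate gates.

    Limits come from the profile; an unset limit yields SKIPPED.  The
    fragment-size range is inclusive at both ends.  The FASTQC gate
    fails iff any profile-listed metric reports FAIL.
    """
    results: list[CheckResult] = []

    if profile.fastqc_fail_metrics:
        failing = sorted(
            m for m in profile.fastqc_fail_metrics
            if metrics.fastqc_flags.get(m, "PASS") == "FAIL"
        )
        results.append(
            _result(
                "fastqc", not failing, failing or None,
                sorted(profile.fastqc_fail_metrics),
                f"FASTQC metrics failed: {', '.join(failing)}",
            )
        )
    else:
        results.append(
            CheckResult("fastqc", "SKIPPED", message="no FASTQC metrics configured")
        )

    if profile.median_coverage_min is not None:
        results.append(
            _result(
                "median_coverage",
                metrics.median_coverage >= profile.median_coverage_min,
                metrics.median_coverage,
                profile.median_coverage_min,
                f"median coverage {metrics.median_coverage} below required "
                f"{profile.median_coverage_min}",
            )
        )
    else:
        results.append(
            CheckResult("median_coverage", "SKIPPED", message="no limit configured")
        )

    if profile.fragment_size_range is not None:
        lo, hi = profile.fragment_size_range
        ok = lo <= metrics.median_fragment_size <= hi
        results.append(
            _result(
                "fragment_size", ok, metrics.median_fragment_size, (lo, hi),
                f"median fragment size {metrics.median_fragment_size} outside "
                f"[{lo}, {hi}]",
            )
        )
    else:
        results.append(
            CheckResult("fragment_size", "SKIPPED", message="no range configured")
        )

    if profile.max_duplicate_rate is not None:
        results.append(
            _result(
                "duplicate_rate",
                metrics.duplicate_rate <= profile.max_duplicate_rate,
                metrics.duplicate_rate,
                profile.max_duplicate_rate,
                f"duplicate rate {metrics.duplicate_rate} above allowed "
                f"{profile.max_duplicate_rate}",
            )
        )
    else:
        results.append(
            CheckResult("duplicate_rate", "SKIPPED", message="no limit configured")
        )
    return results


def infer_sex(metrics: SampleMetrics) -> str:
    """Infer genetic sex from X/Y-to-autosome mean-depth ratios.

    Returns MALE, FEMALE or — whenever the ratios sit in the dead zone
    between the two regimes, or autosomal depth is zero — UNKNOWN.
    """
    if metrics.mean_depth_autosome <= 0:
        return UNKNOWN
    rx = metrics.mean_depth_x / metrics.mean_depth_autosome
    ry = metrics.mean_depth_y / metrics.mean_depth_autosome
    if ry >= Y_RATIO_MALE_MIN and rx <= X_RATIO_MALE_MAX:
        return MALE
    if ry < Y_RATIO_FEMALE_MAX and rx >= X_RATIO_FEMALE_MIN:
        return FEMALE
    return UNKNOWN


def check_sex(inferred: str, declared: str) -> CheckResult:
    """Compare inferred and declared sex; unknowable on either side skips."""
    if UNKNOWN in (inferred, declared):
        return CheckResult(
            "sex", "SKIPPED", inferred, declared,
            "sex could not be compared (inferred or declared unknown)",
        )
    return _result(
        "sex", inferred == declared, inferred, declared,
        f"inferred sex {inferred} inconsistent with declared {declared}",
    )


def run_all_checks(
    metrics: SampleMetrics, profile: AnalysisProfile
) -> list[CheckResult]:
    """All five gates for one sample: thresholds plus the sex check."""
    results = run_threshold_checks(metrics, profile)
    results.append(check_sex(infer_sex(metrics), metrics.declared_sex))
    return results


def overall_verdict(results: list[CheckResult]) -> str:
    """FAIL iff any individual check failed, else PASS."""
    return "FAIL" if any(r.status == "FAIL" for r in results) else "PASS"


def read_metrics_tsv(path: str | Path) -> list[SampleMetrics]:
    """Read one-row-per-sample metrics from TSV.

    Required columns: sample_id, median_coverage, median_fragment_size,
    duplicate_rate, mean_depth_x, mean_depth_y, mean_depth_autosome,
    declared_sex.  Columns named ``fastqc_<metric>`` carry PASS / WARN /
    FAIL flags.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: list[SampleMetrics] = []
    for _, row in df.iterrows():
        flags = {
            col[len("fastqc_"):]: str(row[col])
            for col in df.columns
            if col.startswith("fastqc_") and pd.notna(row[col])
        }
        out.append(
            SampleMetrics(
                sample_id=str(row["sample_id"]),
                median_coverage=float(row["median_coverage"]),
                median_fragment_size=float(row["median_fragment_size"]),
                duplicate_rate=float(row["duplicate_rate"]),
                mean_depth_x=float(row["mean_depth_x"]),
                mean_depth_y=float(row["mean_depth_y"]),
                mean_depth_autosome=float(row["mean_depth_autosome"]),
                declared_sex=str(row.get("declared_sex", UNKNOWN)),
                fastqc_flags=flags,
            )
        )
    return out
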