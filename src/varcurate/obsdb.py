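"""Internal variant-observation database.

Every variant seen in every sample ever analysed by a deployment is
recorded in a single embedded SQLite file.  The observation frequency in
this local store complements public allele frequencies: variants that
recur across samples from unrelated disease cohorts are almost always
local population variants or pipeline artefacts rather than causal
candidates, and can be excluded from curation.

The store accumulates over time, so a sample re-analysed later can see
different internal frequencies.  To make any analysis exactly
reproducible, the file can be snapshotted (byte copy plus a JSON
manifest) before each run and the snapshot restored later.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, NamedTuple

from .errors import StoreBusyError
from .profiles import InternalFilterPolicy
from .variant_ingest import VariantKey

__all__ = [
    "ObservationStore",
    "ObservationStats",
    "internal_filter_decision",
    "snapshot",
    "sha256_file",
]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS samples (
    sample_id TEXT PRIMARY KEY,
    cohort    TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS observations (
    chrom     TEXT NOT NULL,
    pos       INTEGER NOT NULL,
    ref       TEXT NOT NULL,
    alt       TEXT NOT NULL,
    sample_id TEXT NOT NULL REFERENCES samples(sample_id),
    PRIMARY KEY (chrom, pos, ref, alt, sample_id)
);
CREATE INDEX IF NOT EXISTS idx_obs_key ON observations(chrom, pos, ref, alt);
"""


class ObservationStats(NamedTuple):
    """Observation summary for one variant key.

    ``internal_frequency`` is observations over total samples in the
    store (0.0 for an empty store).
    """

    count_total: int
    count_other_cohorts: int
    total_samples: int
    internal_frequency: float


class ObservationStore:
    """Single-file store of per-sample variant observations.

    Presence-only: genotype and zygosity are not recorded, and a sample
    contributes at most one observation per variant key.  Writes take an
    exclusive lock; a held lock surfaces as :class:`StoreBusyError`.
    """

    def __init__(self, path: str | Path, timeout: float = 5.0) -> None:
        self.path = Path(path)
        self._conn = sqlite3.connect(str(self.path), timeout=timeout)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "ObservationStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- writes ---------------------------------------------------------

    def register_sample(
        self, sample_id: str, cohort: str, variants: Iterable[VariantKey]
    ) -> None:
        """Record one analysed sample and all its variant keys.

        Idempotent on repeat: re-registering a sample id replaces its
        previous contribution entirely (cohort and observations).
        """
        keys = {VariantKey(*k) for k in variants}
        try:
            with self._conn:
                self._conn.execute(
                    "DELETE FROM observations WHERE sample_id = ?", (sample_id,)
                )
                self._conn.execute(
                    "INSERT OR REPLACE INTO samples(sample_id, cohort) VALUES (?, ?)",
                    (sample_id, cohort),
                )
                self._conn.executemany(
                    "INSERT INTO observations(chrom, pos, ref, alt, sample_id) "
                    "VALUES (?, ?, ?, ?, ?)",
                    [(k.chrom, k.pos, k.ref, k.alt, sample_id) for k in keys],
                )
        except sqlite3.OperationalError as exc:
            if "locked" in str(exc) or "busy" in str(exc):
                raise StoreBusyError(str(exc)) from exc
            raise

    # -- reads ----------------------------------------------------------

    @property
    def total_samples(self) -> int:
        (n,) = self._conn.execute("SELECT COUNT(*) FROM samples").fetchone()
        return n

    def samples(self) -> list[tuple[str, str]]:
        return list(
            self._conn.execute("SELECT sample_id, cohort FROM samples ORDER BY sample_id")
        )

    def observation_stats(
        self,
        key: VariantKey,
        querying_cohort: str | None = None,
        exclude_sample: str | None = None,
    ) -> ObservationStats:
        """Summarise how often ``key`` has been observed.

        ``querying_cohort`` splits the count into own- versus
        other-cohort observations (unknown cohort counts everything as
        "other").  ``exclude_sample`` removes one sample — normally the
        sample currently being analysed — from both the observation
        counts and the denominator, so a variant can never be filtered
        by its own earlier registration.
        """
        key = VariantKey(*key)
        rows = self._conn.execute(
            "SELECT o.sample_id, s.cohort FROM observations o "
            "JOIN samples s USING (sample_id) "
            "WHERE o.chrom=? AND o.pos=? AND o.ref=? AND o.alt=?",
            key,
        ).fetchall()
        total_samples = self.total_samples
        if exclude_sample is not None:
            registered = self._conn.execute(
                "SELECT COUNT(*) FROM samples WHERE sample_id=?", (exclude_sample,)
            ).fetchone()[0]
            total_samples -= registered
            rows = [r for r in rows if r[0] != exclude_sample]
        count_total = len(rows)
        count_other = sum(
            1 for _, cohort in rows
            if querying_cohort is None or cohort != querying_cohort
        )
        freq = count_total / total_samples if total_samples > 0 else 0.0
        return ObservationStats(count_total, count_other, total_samples, freq)

    def all_keys(self) -> list[VariantKey]:
        return [
            VariantKey(*row)
            for row in self._conn.execute(
                "SELECT DISTINCT chrom, pos, ref, alt FROM observations "
                "ORDER BY chrom, pos, ref, alt"
            )
        ]


def internal_filter_decision(
    stats: ObservationStats, policy: InternalFilterPolicy
) -> bool:
    """True when the policy says to exclude the variant from curation.

    Either arm suffices: seen in at least ``min_other_cohort_samples``
    samples from other cohorts, or internal frequency strictly above
    ``max_internal_frequency`` (when enabled).  With fewer than two
    samples in the store there is no population to compare against and
    nothing is excluded.
    """
    if stats.total_samples < 2:
        return False
    if stats.count_other_cohorts >= policy.min_other_cohort_samples:
        return True
    if (
        policy.max_internal_frequency is not None
        and stats.internal_frequency > policy.max_internal_frequency
    ):
        return True
    return False


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def snapshot(
    store: ObservationStore, out_path: str | Path, timestamp: bool = True
) -> Path:
    """Archive the store to ``out_path`` with a JSON manifest sidecar.

    Uses the SQLite backup API so a consistent copy is taken even with
    the connection open.  The manifest (``<out_path>.manifest.json``)
    records sample count, content digest and optionally a UTC
    timestamp; restoring the copy reproduces identical observation
    statistics for every key.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    dest = sqlite3.connect(str(out_path))
    try:
        store._conn.backup(dest)
    finally:
        dest.close()
    manifest = {
        "source": str(store.path),
        "snapshot": out_path.name,
        "total_samples": store.total_samples,
        "sha256": sha256_file(out_path),
        "timestamp": (
            datetime.now(timezone.utc).isoformat() if timestamp else None
        ),
    }
    manifest_path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return out_path
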