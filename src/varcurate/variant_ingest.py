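"""Ingest annotated VCFs into normalised variant records.

Annotation (population allele frequencies, Condel score, gene symbol,
transcript consequence) is produced upstream by tools such as Annovar or
VEP and carried in VCF INFO fields; a small *schema* mapping tells the
reader which INFO key holds which logical field.  Multi-allelic sites
are split into one record per alternate allele, indel alleles are
trimmed to their minimal left-anchored form, and missing annotations
stay missing — absence of a population frequency means "novel", never
frequency zero.

Coordinate conventions: VCF positions are 1-based; exon/target
intervals are 0-based half-open (BED).  Conversions happen only at the
ingest boundary.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import pysam

from .errors import ParseError

__all__ = [
    "ConsequenceClass",
    "VariantKey",
    "VariantRecord",
    "normalize_allele",
    "normalize_consequence",
    "most_severe_consequence",
    "read_annotated_vcf",
    "classify_splice_region",
    "max_population_af",
    "DEFAULT_SCHEMA",
]


class ConsequenceClass(enum.Enum):
    """Harmonised transcript-consequence classes, most severe first."""

    TRUNCATING = "TRUNCATING"
    FRAMESHIFT = "FRAMESHIFT"
    SPLICE = "SPLICE"
    MISSENSE = "MISSENSE"
    INFRAME_INDEL = "INFRAME_INDEL"
    SYNONYMOUS = "SYNONYMOUS"
    OTHER = "OTHER"


#: severity rank: lower = more severe (used to pick one consequence per record)
_SEVERITY = {c: i for i, c in enumerate(ConsequenceClass)}

# Editable vocabulary table: Annovar-style terms and Sequence Ontology
# terms both appear in the wild; lookup is case-insensitive on a
# canonicalised token (spaces -> underscores).
CONSEQUENCE_VOCABULARY: dict[str, ConsequenceClass] = {
    # truncating / stop & start changes
    "stopgain": ConsequenceClass.TRUNCATING,
    "stopgain_snv": ConsequenceClass.TRUNCATING,
    "stoploss": ConsequenceClass.TRUNCATING,
    "stop_gained": ConsequenceClass.TRUNCATING,
    "stop_lost": ConsequenceClass.TRUNCATING,
    "start_lost": ConsequenceClass.TRUNCATING,
    "startloss": ConsequenceClass.TRUNCATING,
    "start_loss": ConsequenceClass.TRUNCATING,
    "transcript_ablation": ConsequenceClass.TRUNCATING,
    # frameshift
    "frameshift": ConsequenceClass.FRAMESHIFT,
    "frameshift_variant": ConsequenceClass.FRAMESHIFT,
    "frameshift_insertion": ConsequenceClass.FRAMESHIFT,
    "frameshift_deletion": ConsequenceClass.FRAMESHIFT,
    "frameshift_substitution": ConsequenceClass.FRAMESHIFT,
    # splice
    "splicing": ConsequenceClass.SPLICE,
    "splice_acceptor_variant": ConsequenceClass.SPLICE,
    "splice_donor_variant": ConsequenceClass.SPLICE,
    "splice_region_variant": ConsequenceClass.SPLICE,
    "splice_site_variant": ConsequenceClass.SPLICE,
    # missense
    "missense_variant": ConsequenceClass.MISSENSE,
    "missense": ConsequenceClass.MISSENSE,
    "nonsynonymous_snv": ConsequenceClass.MISSENSE,
    "nonsynonymous": ConsequenceClass.MISSENSE,
    # in-frame indels
    "inframe_insertion": ConsequenceClass.INFRAME_INDEL,
    "inframe_deletion": ConsequenceClass.INFRAME_INDEL,
    "nonframeshift_insertion": ConsequenceClass.INFRAME_INDEL,
    "nonframeshift_deletion": ConsequenceClass.INFRAME_INDEL,
    "nonframeshift_substitution": ConsequenceClass.INFRAME_INDEL,
    "inframe_indel": ConsequenceClass.INFRAME_INDEL,
    # synonymous
    "synonymous_variant": ConsequenceClass.SYNONYMOUS,
    "synonymous_snv": ConsequenceClass.SYNONYMOUS,
    "synonymous": ConsequenceClass.SYNONYMOUS,
    "stop_retained_variant": ConsequenceClass.SYNONYMOUS,
}


def normalize_consequence(raw: str | None) -> ConsequenceClass:
    """Map an annotation-tool consequence string onto one class.

    Total and deterministic: unrecognised or missing input maps to
    :attr:`ConsequenceClass.OTHER`, never an error.
    """
    if raw is None:
        return ConsequenceClass.OTHER
    token = raw.strip().lower().replace(" ", "_")
    if token in CONSEQUENCE_VOCABULARY:
        return CONSEQUENCE_VOCABULARY[token]
    # annotation tools often glue several terms with '&' or ','
    if "&" in token or "," in token:
        parts = token.replace(",", "&").split("&")
        classes = [normalize_consequence(p) for p in parts if p]
        if classes:
            return min(classes, key=_SEVERITY.__getitem__)
    return ConsequenceClass.OTHER


def most_severe_consequence(raw_terms: Iterable[str]) -> ConsequenceClass:
    """Collapse several transcript annotations to the most severe class."""
    classes = [normalize_consequence(t) for t in raw_terms]
    if not classes:
        return ConsequenceClass.OTHER
    return min(classes, key=_SEVERITY.__getitem__)


class VariantKey(NamedTuple):
    """Normalisation-canonical identity of one biallelic variant."""

    chrom: str
    pos: int
    ref: str
    alt: str


def normalize_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim a padded REF/ALT pair to its minimal left-anchored form.

    Shared leading context is removed first (advancing ``pos``), then
    shared trailing context, always leaving at least one base on each
    allele.  Alleles are upper-cased.  Two padded representations of the
    same allele therefore yield an identical (pos, ref, alt) key.
    Left-alignment across repeat tracts would require the reference
    sequence and is out of scope; VCFs are expected pre-normalised at
    that level.
    """
    ref = ref.upper()
    alt = alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return pos, ref, alt


@dataclass
class VariantRecord:
    """One normalised biallelic variant with its clinical annotations."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str | None = None
    consequence: ConsequenceClass = ConsequenceClass.OTHER
    af_evs: float | None = None
    af_1000g: float | None = None
    af_exac: float | None = None
    condel: float | None = None
    depth: int = 0
    qual: float = 0.0
    vpi: int = 0
    gpi: int = 0
    filter_reasons: list[str] = field(default_factory=list)
    internal_count: int | None = None
    internal_frequency: float | None = None

    def __post_init__(self) -> None:
        self.pos, self.ref, self.alt = normalize_allele(self.pos, self.ref, self.alt)
        if self.ref == self.alt:
            raise ParseError(
                f"{self.chrom}:{self.pos} ref and alt identical after "
                f"normalisation ({self.ref})"
            )
        if self.pos < 1:
            raise ParseError(f"position must be >= 1, got {self.pos}")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


def max_population_af(record: VariantRecord) -> float | None:
    """Maximum allele frequency across the population databases.

    The rarity criterion must hold in *every* database, so the binding
    comparison is against the maximum.  ``None`` (all absent) means the
    variant is novel and passes any frequency threshold.
    """
    present = [
        af for af in (record.af_evs, record.af_1000g, record.af_exac) if af is not None
    ]
    return max(present) if present else None


def classify_splice_region(
    pos: int, exons: Sequence[tuple[int, int]], window_bp: int
) -> bool:
    """True iff a 1-based position is intronic but near an exon boundary.

    ``exons`` are 0-based half-open intervals for the variant's gene.
    The position must fall strictly outside every exon yet within
    ``window_bp`` bases of some exon edge.  An empty exon set warns and
    returns False.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if not exons:
        warnings.warn("classify_splice_region called with no exons", stacklevel=2)
        return False
    pos0 = pos - 1
    near = False
    for start, end in exons:
        if start <= pos0 < end:
            return False  # exonic, not a splice-region call
        dist = start - pos0 if pos0 < start else pos0 - end + 1
        if dist <= window_bp:
            near = True
    return near


#: default INFO-key schema written by the synthetic batch generator
DEFAULT_SCHEMA: dict[str, str] = {
    "gene": "GENE",
    "consequence": "CSQ",
    "af_evs": "AF_EVS",
    "af_1000g": "AF_1000G",
    "af_exac": "AF_EXAC",
    "condel": "CONDEL",
    "depth": "DP",
}


def _info_per_allele(value, allele_index: int, n_alts: int):
    """Pick the value for one alternate allele from an INFO entry."""
    if isinstance(value, tuple):
        if len(value) == n_alts:
            return value[allele_index]
        return value[0] if value else None
    return value


def read_annotated_vcf(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sample_id: str | None = None,
) -> Iterator[VariantRecord]:
    """Stream normalised :class:`VariantRecord` objects from a VCF.

    ``schema`` maps logical fields (``gene``, ``consequence``,
    ``af_evs``, ``af_1000g``, ``af_exac``, ``condel``, ``depth``) to the
    INFO keys that carry them; :data:`DEFAULT_SCHEMA` matches the
    synthetic fixtures.  Multi-allelic sites yield one record per
    alternate, in ALT order.  Missing annotations stay ``None``.
    Symbolic/structural alternates are passed through with consequence
    OTHER (they never reach a priority tier here).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)

    with pysam.VariantFile(str(path)) as vcf:
        if sample_id is None:
            sample_id = list(vcf.header.samples)[0] if vcf.header.samples else path.stem
        for rec in vcf:
            alts = rec.alts or ()
            n_alts = len(alts)
            for i, alt in enumerate(alts):
                info = rec.info

                def get(field_name: str):
                    key = schema.get(field_name)
                    if key is None or key not in info:
                        return None
                    return _info_per_allele(info[key], i, n_alts)

                raw_csq = get("consequence")
                if isinstance(raw_csq, bytes):
                    raw_csq = raw_csq.decode()
                consequence = normalize_consequence(
                    raw_csq if isinstance(raw_csq, str) else None
                )
                symbolic = alt.startswith("<") or any(c in alt for c in "[]")
                if symbolic:
                    # structural alternates carry no small-variant meaning here
                    yield VariantRecord(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        consequence=ConsequenceClass.OTHER,
                        qual=rec.qual or 0.0,
                    )
                    continue

                def as_float(v):
                    return float(v) if v is not None else None

                depth = get("depth")
                yield VariantRecord(
                    sample_id=sample_id,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    gene=(str(get("gene")) if get("gene") is not None else None),
                    consequence=consequence,
                    af_evs=as_float(get("af_evs")),
                    af_1000g=as_float(get("af_1000g")),
                    af_exac=as_float(get("af_exac")),
                    condel=as_float(get("condel")),
                    depth=int(depth) if depth is not None else 0,
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                )
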