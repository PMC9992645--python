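"""Hard-filter QC cascade for trio VCFs and de novo candidate calling.

The cascade mirrors the standard GATK-style post-calling workflow for
trio exome data: population-frequency rarity, site-level hard filters
(MQ, QD, FS, SOR, rank sums), genotype-level filters (allele balance,
depth, genotype quality) for every trio member, a de novo configuration
check (child heterozygous, both parents homozygous reference), and a
consequence filter keeping loss-of-function variants and missense
variants above a CADD cutoff.

Conventions for the filter directions follow GATK hard-filtering
practice: a site is kept when MQ >= 35, QD > 2, FS <= 60, SOR <= 3,
MQRankSum >= -12.5 and ReadPosRankSum > -8.  A missing site metric
passes that single criterion (rank sums are only emitted when
computable, and discarding absent values would throw away valid sites).
Missing population frequency is treated as 0 (absent from the database
means rare).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd
import pysam

from .errors import ConfigurationError, DataError, SchemaError

#: Consequence classes retained unconditionally (loss of function).
LOF_CLASSES = frozenset({"stop_gain", "frameshift", "splice"})

REQUIRED_INFO = ("MQ", "QD", "FS", "SOR", "MQRankSum", "ReadPosRankSum",
                 "AF_nonneuro", "CSQ_class", "CADD")
REQUIRED_FORMAT = ("GT", "AD", "DP", "GQ")


@dataclass
class QCThresholds:
    """All filter cutoffs of the QC cascade, with hard-filter defaults.

    Sites are kept when MQ >= ``mq_min``, QD > ``qd_min``, FS <=
    ``fs_max``, SOR <= ``sor_max``, MQRankSum >= ``mq_rank_sum_min`` and
    ReadPosRankSum > ``read_pos_rank_sum_min``.  Heterozygous genotypes
    are kept when ``ab_low`` < AB < ``ab_high``, DP > ``dp_min`` and GQ >
    ``gq_min``; homozygous-reference genotypes replace the AB window by
    AB <= ``parent_ab_max`` (which defaults to ``ab_low``).  Candidates
    must have population allele frequency
    < ``af_max`` and be loss-of-function or missense with CADD >
    ``cadd_min``.
    """

    mq_min: float = 35.0
    qd_min: float = 2.0
    fs_max: float = 60.0
    sor_max: float = 3.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0
    ab_low: float = 0.25
    ab_high: float = 0.75
    dp_min: int = 10
    gq_min: int = 25
    cadd_min: float = 20.0
    af_max: float = 0.001
    #: parental hom-ref purity cutoff; defaults to ``ab_low`` when None
    parent_ab_max: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.ab_low < self.ab_high:
            raise ConfigurationError("ab_low must be < ab_high")
        for name in ("mq_min", "qd_min", "fs_max", "sor_max",
                     "mq_rank_sum_min", "read_pos_rank_sum_min",
                     "ab_low", "ab_high", "cadd_min", "af_max"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"threshold {name} must be finite")
        if not 0 < self.af_max <= 1:
            raise ConfigurationError("af_max must lie in (0, 1]")
        if self.parent_ab_max is not None and not (
            0 <= self.parent_ab_max <= 1 and math.isfinite(self.parent_ab_max)
        ):
            raise ConfigurationError("parent_ab_max must lie in [0, 1]")

    @property
    def homref_ab_max(self) -> float:
        return self.ab_low if self.parent_ab_max is None else self.parent_ab_max

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "QCThresholds":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ConfigurationError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**known)


@dataclass(frozen=True)
class SiteRecord:
    """One bi-allelic VCF site with its QC metrics and annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    mq: Optional[float] = None
    qd: Optional[float] = None
    fs: Optional[float] = None
    sor: Optional[float] = None
    mq_rank_sum: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None
    af_nonneuro: Optional[float] = None
    consequence_class: str = "other"
    cadd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DataError("ref and alt alleles are identical")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class MemberGenotype:
    """Genotype call of one trio member with its QC fields."""

    gt: tuple[Optional[int], Optional[int]]
    dp: int
    gq: int
    ad: tuple[int, int]  # (ref depth, alt depth)

    @property
    def total_depth(self) -> int:
        return self.ad[0] + self.ad[1]

    @property
    def ab(self) -> Optional[float]:
        """Allele balance: alt depth / total AD depth; None without coverage."""
        tot = self.total_depth
        return None if tot == 0 else self.ad[1] / tot

    @property
    def is_het(self) -> bool:
        return sorted(a for a in self.gt if a is not None) == [0, 1]

    @property
    def is_hom_ref(self) -> bool:
        return self.gt == (0, 0)

    @property
    def is_missing(self) -> bool:
        return any(a is None for a in self.gt)


@dataclass(frozen=True)
class TrioGenotype:
    proband: MemberGenotype
    father: MemberGenotype
    mother: MemberGenotype


def _passes(value: Optional[float], ok) -> bool:
    """Missing-metric policy: absent values pass the single criterion."""
    return True if value is None else ok(value)


def site_pass(record: SiteRecord, t: QCThresholds) -> bool:
    """Site-level hard filters (GATK-convention directions)."""
    return (
        _passes(record.mq, lambda v: v >= t.mq_min)
        and _passes(record.qd, lambda v: v > t.qd_min)
        and _passes(record.fs, lambda v: v <= t.fs_max)
        and _passes(record.sor, lambda v: v <= t.sor_max)
        and _passes(record.mq_rank_sum, lambda v: v >= t.mq_rank_sum_min)
        and _passes(record.read_pos_rank_sum, lambda v: v > t.read_pos_rank_sum_min)
    )


def genotype_pass(g: MemberGenotype, t: QCThresholds) -> bool:
    """Genotype-level QC for one member.

    Heterozygous calls require the open AB window; homozygous-reference
    calls require AB <= ``parent_ab_max`` (``ab_low`` unless overridden);
    homozygous-alt calls require AB >= ``ab_high``.  All calls require
    DP > ``dp_min`` and GQ > ``gq_min``.  Zero coverage fails.
    """
    if g.is_missing:
        return False
    ab = g.ab
    if ab is None:
        return False  # no coverage
    if not (g.dp > t.dp_min and g.gq > t.gq_min):
        return False
    if g.is_het:
        return t.ab_low < ab < t.ab_high
    if g.is_hom_ref:
        return ab <= t.homref_ab_max
    return ab >= t.ab_high


def rare_and_consequence_pass(record: SiteRecord, t: QCThresholds) -> bool:
    """Rarity plus consequence filter (LoF, or missense with CADD > cutoff)."""
    return rare_pass(record, t) and consequence_pass(record, t)


def rare_pass(record: SiteRecord, t: QCThresholds) -> bool:
    af = record.af_nonneuro
    return af is None or af < t.af_max


def consequence_pass(record: SiteRecord, t: QCThresholds) -> bool:
    if record.consequence_class in LOF_CLASSES:
        return True
    if record.consequence_class == "missense":
        return record.cadd is not None and record.cadd > t.cadd_min
    return False


def call_denovo(trio: TrioGenotype, t: QCThresholds) -> bool:
    """De novo configuration: child het-alt, both parents clean hom-ref.

    A missing parental genotype makes inheritance unknown, never de novo.
    """
    if trio.father.is_missing or trio.mother.is_missing:
        return False
    return (
        trio.proband.is_het
        and genotype_pass(trio.proband, t)
        and trio.father.is_hom_ref
        and genotype_pass(trio.father, t)
        and trio.mother.is_hom_ref
        and genotype_pass(trio.mother, t)
    )


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------


def _info_float(rec, key: str) -> Optional[float]:
    v = rec.info.get(key)
    if v is None:
        return None
    if isinstance(v, tuple):
        v = v[0]
    return None if v is None else float(v)


def _member(sample) -> MemberGenotype:
    gt = sample.get("GT")
    if gt is None:
        gt = (None, None)
    ad = sample.get("AD")
    if ad is None or any(a is None for a in ad):
        ad = (0, 0)
    dp = sample.get("DP")
    gq = sample.get("GQ")
    return MemberGenotype(
        gt=tuple(gt),
        dp=0 if dp is None else int(dp),
        gq=0 if gq is None else int(gq),
        ad=(int(ad[0]), int(ad[1])),
    )


def read_trio_vcf(
    vcf_path: str | Path,
    proband: str = "proband",
    father: str = "father",
    mother: str = "mother",
) -> Iterator[tuple[SiteRecord, TrioGenotype]]:
    """Stream (site, trio genotype) pairs from a VCF.

    Raises :class:`SchemaError` when a required INFO/FORMAT definition or
    a sample is missing, and :class:`DataError` on multi-allelic lines
    (inputs must be pre-split and normalized).
    """
    vcf = pysam.VariantFile(str(vcf_path))
    for key in REQUIRED_INFO:
        if key not in vcf.header.info:
            raise SchemaError(f"VCF header lacks required INFO field {key!r}")
    for key in REQUIRED_FORMAT:
        if key not in vcf.header.formats:
            raise SchemaError(f"VCF header lacks required FORMAT field {key!r}")
    samples = list(vcf.header.samples)
    for name in (proband, father, mother):
        if name not in samples:
            raise SchemaError(f"VCF lacks sample {name!r} (has {samples})")
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            raise DataError(
                f"multi-allelic or ALT-less record at {rec.chrom}:{rec.pos}; "
                "split and normalize the VCF first"
            )
        csq = rec.info.get("CSQ_class")
        site = SiteRecord(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alt=rec.alts[0],
            mq=_info_float(rec, "MQ"),
            qd=_info_float(rec, "QD"),
            fs=_info_float(rec, "FS"),
            sor=_info_float(rec, "SOR"),
            mq_rank_sum=_info_float(rec, "MQRankSum"),
            read_pos_rank_sum=_info_float(rec, "ReadPosRankSum"),
            af_nonneuro=_info_float(rec, "AF_nonneuro"),
            consequence_class=str(csq) if csq is not None else "other",
            cadd=_info_float(rec, "CADD"),
        )
        trio = TrioGenotype(
            proband=_member(rec.samples[proband]),
            father=_member(rec.samples[father]),
            mother=_member(rec.samples[mother]),
        )
        yield site, trio


def classify_vcf(
    vcf_path: str | Path,
    t: QCThresholds | None = None,
    proband: str = "proband",
    father: str = "father",
    mother: str = "mother",
) -> pd.DataFrame:
    """Per-record QC labels for every record of a trio VCF.

    Returns a DataFrame indexed by variant key with boolean columns
    ``site_pass``, ``genotype_pass`` (all three members), ``is_denovo``,
    ``is_rare`` and ``consequence_pass``.
    """
    t = t or QCThresholds()
    rows = {}
    for site, trio in read_trio_vcf(vcf_path, proband, father, mother):
        rows[site.key] = {
            "site_pass": site_pass(site, t),
            "genotype_pass": all(
                genotype_pass(m, t) for m in (trio.proband, trio.father, trio.mother)
            ),
            "is_denovo": call_denovo(trio, t),
            "is_rare": rare_pass(site, t),
            "consequence_pass": consequence_pass(site, t),
        }
    df = pd.DataFrame.from_dict(rows, orient="index").astype(bool)
    df.index.name = "key"
    return df


def run_qc_pipeline(
    vcf_path: str | Path,
    t: QCThresholds | None = None,
    proband: str = "proband",
    father: str = "father",
    mother: str = "mother",
) -> tuple[pd.DataFrame, dict]:
    """Run the full cascade and return surviving de novo candidates + funnel.

    Stage order: rarity -> site filters -> genotype filters -> de novo
    configuration -> consequence.  The funnel reports records in, records
    removed at each stage (each record is charged to the first stage it
    fails), and records out; counts always conserve.
    """
    t = t or QCThresholds()
    stages = ["rarity", "site", "genotype", "denovo", "consequence"]
    removed = dict.fromkeys(stages, 0)
    survivors = []
    n_in = 0
    for site, trio in read_trio_vcf(vcf_path, proband, father, mother):
        n_in += 1
        if not rare_pass(site, t):
            removed["rarity"] += 1
            continue
        if not site_pass(site, t):
            removed["site"] += 1
            continue
        if not all(genotype_pass(m, t) for m in (trio.proband, trio.father, trio.mother)):
            removed["genotype"] += 1
            continue
        if not call_denovo(trio, t):
            removed["denovo"] += 1
            continue
        if not consequence_pass(site, t):
            removed["consequence"] += 1
            continue
        survivors.append(
            {
                "sample_id": proband,
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "function": site.consequence_class,
                "cadd": site.cadd,
                "af_nonneuro": site.af_nonneuro,
                "inheritance": "de novo",
                "source": "this_study",
            }
        )
    table = pd.DataFrame(
        survivors,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "function",
                 "cadd", "af_nonneuro", "inheritance", "source"],
    )
    funnel = {
        "records_in": n_in,
        "removed": removed,
        "records_out": len(table),
    }
    return table, funnel
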