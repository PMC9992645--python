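"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators produce everything the pipeline consumes, so the whole
analysis is testable without any external download:

* a developmental expression atlas (gene x sample RPKM grid over brain
  regions and ages) containing one latent co-expression module and a set
  of genes with a planted prenatal expression ramp;
* disease gene sets drawn with a configurable overlap with the latent
  module;
* de novo vs "private" variant cohorts with shifted deleteriousness
  score distributions;
* a trio VCF whose records span every QC threshold, together with a
  truth table of expected per-record filter labels.

Noise model: RPKM values are latent trajectories with multiplicative
log-normal noise (mean-corrected, so the latent mean is preserved);
expression is non-negative and right-skewed like real RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import ALL_REGIONS, ExpressionAtlas, GeneSet
from .denovo_table import DenovoEvent
from .errors import ConfigurationError
from .trajectory import BIRTH_DAYS, age_to_days, period_of
from .trio_qc import QCThresholds

#: Default age grid: 6 prenatal and 6 postnatal time points spanning
#: 8 post-conceptional weeks to 40 years.
DEFAULT_AGE_GRID: tuple[tuple[float, str], ...] = (
    (8, "pcw"), (12, "pcw"), (16, "pcw"), (21, "pcw"), (24, "pcw"), (37, "pcw"),
    (4, "months"), (10, "months"), (1, "years"), (8, "years"),
    (18, "years"), (40, "years"),
)


@dataclass
class AtlasConfig:
    """Settings of the synthetic developmental expression atlas."""

    n_genes: int = 500
    n_module_genes: int = 50
    n_ramp_genes: int = 10
    regions: tuple[str, ...] = ALL_REGIONS
    age_grid: tuple[tuple[float, str], ...] = DEFAULT_AGE_GRID
    noise_sd: float = 0.4          # log-scale SD of multiplicative noise
    module_loading: float = 0.7    # in [0, 1]; strength of the latent module
    prenatal_slope: float = 0.05   # RPKM per post-conceptional day
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not 0 <= self.n_module_genes <= self.n_genes:
            raise ConfigurationError("n_module_genes must lie in [0, n_genes]")
        if self.n_ramp_genes < 0 or self.n_module_genes + self.n_ramp_genes > self.n_genes:
            raise ConfigurationError("module and ramp genes must fit in n_genes")
        if not self.regions:
            raise ConfigurationError("regions must be non-empty")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.module_loading <= 1:
            raise ConfigurationError("module_loading must lie in [0, 1]")
        days = [age_to_days(v, u) for v, u in self.age_grid]
        periods = {period_of(d) for d in days}
        if periods != {"prenatal", "postnatal"}:
            raise ConfigurationError("age_grid must span prenatal and postnatal ages")


def gen_expression_atlas(config: AtlasConfig) -> ExpressionAtlas:
    """Generate a seeded RPKM atlas with one latent module and ramp genes.

    One sample per (region, age) cell.  Module genes share a latent
    per-sample factor scaled by ``module_loading``; ramp genes follow a
    linear prenatal trajectory of slope ``prenatal_slope`` (RPKM/day)
    that plateaus at birth.  All values carry mean-corrected log-normal
    noise of log-scale SD ``noise_sd``.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    module = genes[: config.n_module_genes]
    ramp = genes[config.n_module_genes: config.n_module_genes + config.n_ramp_genes]

    meta_rows = []
    for region in config.regions:
        for value, unit in config.age_grid:
            days = age_to_days(value, unit)
            meta_rows.append(
                {
                    "sample_id": f"{region}_{value:g}{unit}",
                    "region": region,
                    "age_value": value,
                    "age_unit": unit,
                    "age_days": days,
                    "period": period_of(days),
                }
            )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    n_samples = len(meta)

    # latent per-sample module factor, shared by all module genes
    latent = rng.standard_normal(n_samples)
    base = np.exp(rng.normal(1.5, 1.2, size=config.n_genes))  # median ~4.5 RPKM
    eps = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))

    log_expr = np.log(base)[:, None] + eps - config.noise_sd**2 / 2.0
    loading_scale = 1.0  # latent factor enters the log scale directly
    log_expr[: config.n_module_genes] += (
        config.module_loading * loading_scale * latent[None, :]
    )
    rpkm = np.exp(log_expr)

    # planted prenatal ramps, additive in RPKM space with the same
    # mean-corrected multiplicative noise
    if ramp:
        days = meta["age_days"].to_numpy()
        ramp_mean = np.clip(
            1.0 + config.prenatal_slope * np.minimum(days, BIRTH_DAYS), 0.0, None
        )
        i0 = config.n_module_genes
        for k in range(len(ramp)):
            noise = np.exp(
                rng.normal(0.0, config.noise_sd, size=n_samples)
                - config.noise_sd**2 / 2.0
            )
            rpkm[i0 + k] = ramp_mean * noise

    df = pd.DataFrame(rpkm, index=pd.Index(genes, name="gene"), columns=meta.index)
    return ExpressionAtlas(rpkm=df, samples=meta,
                           module_genes=list(module), ramp_genes=list(ramp))


def gen_gene_sets(
    atlas: ExpressionAtlas,
    sizes: dict[str, int],
    in_module_fraction: Optional[float] = None,
    seed: int = 0,
) -> list[GeneSet]:
    """Draw disease gene sets from the atlas universe.

    With ``in_module_fraction`` set, that fraction of each set is drawn
    from the atlas's latent module and the rest from non-module genes;
    with ``None`` members are drawn uniformly from the whole universe
    (so module overlap follows the hypergeometric law).
    """
    rng = np.random.default_rng(seed)
    universe = list(atlas.genes)
    module = set(atlas.module_genes or [])
    non_module = [g for g in universe if g not in module]
    sets = []
    for name, size in sizes.items():
        if size > len(universe):
            raise ConfigurationError(
                f"set {name!r} size {size} exceeds the {len(universe)}-gene universe"
            )
        if in_module_fraction is None:
            members = rng.choice(universe, size=size, replace=False)
        else:
            if not 0 <= in_module_fraction <= 1:
                raise ConfigurationError("in_module_fraction must lie in [0, 1]")
            n_in = round(size * in_module_fraction)
            if n_in > len(module) or size - n_in > len(non_module):
                raise ConfigurationError(
                    f"cannot draw {n_in} module genes for set {name!r}"
                )
            members = np.concatenate([
                rng.choice(sorted(module), size=n_in, replace=False),
                rng.choice(non_module, size=size - n_in, replace=False),
            ])
        sets.append(GeneSet(name=name, members=frozenset(members.tolist())))
    return sets


def default_gene_sets(
    atlas: ExpressionAtlas, seed: int = 0, fraction: float = 0.5
) -> list[GeneSet]:
    """IS/EE/DD-sized sets with as close to ``fraction`` module overlap as
    the atlas's module and universe sizes allow."""
    n_genes = len(atlas.genes)
    n_mod = len(atlas.module_genes or [])
    n_non = n_genes - n_mod
    sizes = {"IS": min(37, n_genes), "EE": min(126, n_genes),
             "DD": min(789, n_genes)}
    sets = []
    for i, (name, size) in enumerate(sizes.items()):
        n_in = min(round(size * fraction), n_mod)
        n_in = max(n_in, size - n_non)
        sets.extend(gen_gene_sets(atlas, {name: size},
                                  in_module_fraction=n_in / size, seed=seed + i))
    return sets


# ---------------------------------------------------------------------------
# Variant cohorts
# ---------------------------------------------------------------------------


@dataclass
class VariantCohortConfig:
    """Settings for the de novo vs private missense cohorts.

    Defaults place the de novo CADD distribution well above the private
    one, with de novo events mostly predicted damaging — the contrast
    the deleteriousness comparisons are designed to detect.
    """

    n_denovo: int = 100
    n_private: int = 100
    denovo_cadd_mean: float = 26.0
    denovo_cadd_sd: float = 3.0
    private_cadd_mean: float = 18.0
    private_cadd_sd: float = 5.0
    damaging_fraction_denovo: float = 0.9
    damaging_fraction_private: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_denovo < 0 or self.n_private < 0:
            raise ConfigurationError("cohort sizes must be >= 0")
        if self.denovo_cadd_sd <= 0 or self.private_cadd_sd <= 0:
            raise ConfigurationError("CADD standard deviations must be > 0")
        for f in (self.damaging_fraction_denovo, self.damaging_fraction_private):
            if not 0 <= f <= 1:
                raise ConfigurationError("damaging fractions must lie in [0, 1]")


_LOCUS_START = 66_370_000  # synthetic positions on chr5, hg19-style
_LOCUS_END = 66_470_000


def _draw_cohort(
    rng: np.random.Generator,
    n: int,
    cadd_mean: float,
    cadd_sd: float,
    damaging_fraction: float,
    prefix: str,
    source: str,
    positions: np.ndarray,
) -> list[DenovoEvent]:
    # CADD ~ Normal truncated at 0
    a = (0.0 - cadd_mean) / cadd_sd
    cadd = stats.truncnorm.rvs(a, np.inf, loc=cadd_mean, scale=cadd_sd,
                               size=n, random_state=rng)
    damaging = rng.random(n) < damaging_fraction
    bases = np.array(list("ACGT"))
    events = []
    for i in range(n):
        ref, alt = rng.choice(bases, size=2, replace=False)
        poly = "D" if damaging[i] else rng.choice(["P", "B"])
        events.append(
            DenovoEvent(
                sample_id=f"{prefix}{i + 1:04d}",
                gdna_change=f"g.{positions[i]}{ref} > {alt}",
                function="missense",
                sift_bin="D" if damaging[i] else "T",
                polyphen_bin=poly,
                cadd=float(cadd[i]),
                inheritance="de novo" if prefix == "DN" else "unknown",
                source=source,
            )
        )
    return events


def gen_variant_cohorts(
    config: VariantCohortConfig,
) -> tuple[list[DenovoEvent], list[DenovoEvent]]:
    """Generate (de novo, private) missense cohorts with shifted scores."""
    rng = np.random.default_rng(config.seed)
    total = config.n_denovo + config.n_private
    positions = rng.choice(
        np.arange(_LOCUS_START, _LOCUS_END), size=total, replace=False
    )
    denovo = _draw_cohort(
        rng, config.n_denovo, config.denovo_cadd_mean, config.denovo_cadd_sd,
        config.damaging_fraction_denovo, "DN", "synthetic_cohort",
        positions[: config.n_denovo],
    )
    private = _draw_cohort(
        rng, config.n_private, config.private_cadd_mean, config.private_cadd_sd,
        config.damaging_fraction_private, "PV", "synthetic_gnomad_nonneuro",
        positions[config.n_denovo:],
    )
    return denovo, private


# ---------------------------------------------------------------------------
# Trio VCF with truth table
# ---------------------------------------------------------------------------

_NOMINAL_INFO = dict(MQ=60.0, QD=20.0, FS=5.0, SOR=1.0,
                     MQRankSum=0.0, ReadPosRankSum=0.0)
_NOMINAL_CHILD = dict(gt="0/1", ad=(15, 15), dp=30, gq=99)
_NOMINAL_PARENT = dict(gt="0/0", ad=(30, 0), dp=30, gq=80)


def _truth_site(info: dict, t: QCThresholds) -> bool:
    # independent restatement of the site rules used by the generator
    checks = [
        ("MQ", lambda v: v >= t.mq_min),
        ("QD", lambda v: v > t.qd_min),
        ("FS", lambda v: v <= t.fs_max),
        ("SOR", lambda v: v <= t.sor_max),
        ("MQRankSum", lambda v: v >= t.mq_rank_sum_min),
        ("ReadPosRankSum", lambda v: v > t.read_pos_rank_sum_min),
    ]
    return all(info.get(k) is None or ok(info[k]) for k, ok in checks)


def _truth_member(m: dict, t: QCThresholds) -> bool:
    gt = m["gt"]
    if "." in gt:
        return False
    ref_d, alt_d = m["ad"]
    tot = ref_d + alt_d
    if tot == 0:
        return False
    ab = alt_d / tot
    if not (m["dp"] > t.dp_min and m["gq"] > t.gq_min):
        return False
    if gt in ("0/1", "1/0"):
        return t.ab_low < ab < t.ab_high
    if gt == "0/0":
        return ab <= (t.ab_low if t.parent_ab_max is None else t.parent_ab_max)
    return ab >= t.ab_high


def _truth_row(rec: dict, t: QCThresholds) -> dict:
    info = rec["info"]
    members = [rec["child"], rec["father"], rec["mother"]]
    gpass = all(_truth_member(m, t) for m in members)
    denovo = (
        rec["child"]["gt"] in ("0/1", "1/0")
        and rec["father"]["gt"] == "0/0"
        and rec["mother"]["gt"] == "0/0"
        and gpass
    )
    af = info.get("AF_nonneuro")
    csq = info.get("CSQ_class", "other")
    cadd = info.get("CADD")
    cons = csq in ("stop_gain", "frameshift", "splice") or (
        csq == "missense" and cadd is not None and cadd > t.cadd_min
    )
    return {
        "site_pass": _truth_site(info, t),
        "genotype_pass": gpass,
        "is_denovo": denovo,
        "is_rare": af is None or af < t.af_max,
        "consequence_pass": cons,
    }


def _boundary_records(t: QCThresholds) -> list[dict]:
    """Records straddling and sitting exactly on every QC threshold."""
    recs: list[dict] = []

    def rec(info_over=None, child=None, father=None, mother=None):
        info = dict(_NOMINAL_INFO, CSQ_class="missense", CADD=30.0)
        info.update(info_over or {})
        recs.append(
            {
                "info": info,
                "child": dict(_NOMINAL_CHILD, **(child or {})),
                "father": dict(_NOMINAL_PARENT, **(father or {})),
                "mother": dict(_NOMINAL_PARENT, **(mother or {})),
            }
        )

    eps = 0.1
    # site metrics: strictly below / exactly at / strictly above
    for key, thr in [("MQ", t.mq_min), ("QD", t.qd_min), ("FS", t.fs_max),
                     ("SOR", t.sor_max), ("MQRankSum", t.mq_rank_sum_min),
                     ("ReadPosRankSum", t.read_pos_rank_sum_min)]:
        for v in (thr - eps, thr, thr + eps):
            rec(info_over={key: round(v, 3)})
        rec(info_over={key: None})  # missing metric passes
    # child allele balance: AD picked to land exactly on the window edges
    for ad in [(15, 5), (12, 8), (10, 10), (5, 15), (4, 16)]:  # AB .25 .4 .5 .75 .8
        rec(child={"ad": ad, "dp": sum(ad)})
    # depth and genotype quality boundaries (child)
    for dp in (t.dp_min - 1, t.dp_min, t.dp_min + 1):
        rec(child={"dp": dp, "ad": (dp - dp // 2, dp // 2)})
    for gq in (t.gq_min - 1, t.gq_min, t.gq_min + 1):
        rec(child={"gq": gq})
    # parental purity: AB below / exactly at / above ab_low
    for ad in [(29, 1), (15, 5), (22, 8)]:
        rec(father={"ad": ad, "dp": sum(ad)})
    # inheritance configurations
    rec(father={"gt": "0/1", "ad": (15, 15)})          # inherited, not de novo
    rec(father={"gt": "./.", "ad": (0, 0), "dp": 0})   # unknown inheritance
    rec(child={"gt": "1/1", "ad": (1, 29)})            # hom-alt child
    rec(child={"gt": "0/0", "ad": (30, 0)})            # no variant in child
    # rarity boundaries (af_max default 0.001)
    for af in (t.af_max * 0.9, t.af_max, t.af_max * 1.1):
        rec(info_over={"AF_nonneuro": af})
    # consequence classes and the CADD cutoff
    for csq in ("stop_gain", "frameshift", "splice", "synonymous", "other"):
        rec(info_over={"CSQ_class": csq, "CADD": None})
    for cadd in (t.cadd_min - eps, t.cadd_min, t.cadd_min + eps):
        rec(info_over={"CADD": round(cadd, 3)})
    return recs


def _random_record(rng: np.random.Generator, t: QCThresholds) -> dict:
    def maybe_missing(v, p=0.1):
        return None if rng.random() < p else v

    info = {
        "MQ": maybe_missing(round(float(rng.uniform(t.mq_min - 10, 60)), 2)),
        "QD": maybe_missing(round(float(rng.uniform(0, 30)), 2)),
        "FS": maybe_missing(round(float(rng.uniform(0, t.fs_max * 1.5)), 2)),
        "SOR": maybe_missing(round(float(rng.uniform(0, t.sor_max * 2)), 2)),
        "MQRankSum": maybe_missing(round(float(rng.uniform(-15, 5)), 2)),
        "ReadPosRankSum": maybe_missing(round(float(rng.uniform(-10, 5)), 2)),
        "AF_nonneuro": maybe_missing(
            round(float(rng.uniform(0, t.af_max * 3)), 6), p=0.5
        ),
        "CSQ_class": str(rng.choice(
            ["missense", "stop_gain", "frameshift", "splice", "synonymous", "other"],
            p=[0.5, 0.1, 0.1, 0.1, 0.1, 0.1],
        )),
        "CADD": maybe_missing(round(float(rng.uniform(5, 40)), 1), p=0.15),
    }

    def member(gt_choices, p_gt):
        gt = str(rng.choice(gt_choices, p=p_gt))
        dp = int(rng.integers(0, 60))
        if gt in ("0/1", "1/0"):
            alt = int(rng.binomial(dp, rng.uniform(0.1, 0.9))) if dp else 0
        elif gt == "0/0":
            alt = int(rng.binomial(dp, rng.uniform(0.0, 0.4))) if dp else 0
        else:
            alt = int(rng.binomial(dp, rng.uniform(0.6, 1.0))) if dp else 0
        return {"gt": gt, "ad": (dp - alt, alt), "dp": dp,
                "gq": int(rng.integers(0, 100))}

    return {
        "info": info,
        "child": member(["0/1", "0/0", "1/1"], [0.7, 0.2, 0.1]),
        "father": member(["0/0", "0/1", "./."], [0.7, 0.2, 0.1]),
        "mother": member(["0/0", "0/1", "./."], [0.7, 0.2, 0.1]),
    }


_VCF_HEADER = """\
##fileformat=VCFv4.1
##contig=<ID=chr5,length=181538259>
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mean mapping quality of reads">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Strand odds ratio">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">
##INFO=<ID=AF_nonneuro,Number=1,Type=Float,Description="Population allele frequency, non-neuro subset">
##INFO=<ID=CSQ_class,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=CADD,Number=1,Type=Float,Description="Scaled CADD score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tproband\tfather\tmother
"""


def _fmt_info(info: dict) -> str:
    parts = []
    for k, v in info.items():
        if v is None:
            continue
        parts.append(f"{k}={v}")
    return ";".join(parts) if parts else "."


def _fmt_member(m: dict) -> str:
    return f"{m['gt']}:{m['ad'][0]},{m['ad'][1]}:{m['dp']}:{m['gq']}"


def gen_trio_vcf(
    path: str | Path,
    n_sites: int = 500,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a three-sample VCF (v4.1) and return its truth table.

    The first records place at least one site strictly on each side of
    every threshold and one exactly at the boundary; the remainder are
    random records whose metrics straddle the thresholds.  The returned
    DataFrame is indexed by variant key with boolean columns
    ``site_pass``, ``genotype_pass``, ``is_denovo``, ``is_rare`` and
    ``consequence_pass``.
    """
    t = thresholds or QCThresholds()
    rng = np.random.default_rng(seed)
    records = _boundary_records(t)
    if n_sites < len(records):
        raise ConfigurationError(
            f"n_sites must be >= {len(records)} to cover every threshold boundary"
        )
    while len(records) < n_sites:
        records.append(_random_record(rng, t))

    bases = np.array(list("ACGT"))
    truth = {}
    lines = [_VCF_HEADER]
    pos = 66_400_000
    for rec in records:
        pos += int(rng.integers(1, 50))
        ref, alt = rng.choice(bases, size=2, replace=False)
        key = f"chr5:{pos}:{ref}:{alt}"
        truth[key] = _truth_row(rec, t)
        lines.append(
            "\t".join(
                [
                    "chr5", str(pos), ".", str(ref), str(alt), ".", ".",
                    _fmt_info(rec["info"]), "GT:AD:DP:GQ",
                    _fmt_member(rec["child"]),
                    _fmt_member(rec["father"]),
                    _fmt_member(rec["mother"]),
                ]
            )
            + "\n"
        )
    Path(path).write_text("".join(lines))
    df = pd.DataFrame.from_dict(truth, orient="index").astype(bool)
    df.index.name = "key"
    return df
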