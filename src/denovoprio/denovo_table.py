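"""Integrated de novo event table: cohort merging and recurrent-site detection.

Events live in a fixed TSV schema (one row per proband-variant
observation, with deleteriousness annotations such as SIFT/PolyPhen/CADD
carried as input columns).  The package bundles the nine published MAST4
de novo events observed in neurodevelopmental-disorder probands — four
from a clinical infantile-spasm cohort and five from published
developmental-disorder sequencing studies — which serve as the worked
example throughout.

Variant identity is the genomic key (chrom, pos, ref, alt) parsed from
the gDNA change column; protein-level nomenclature is stored verbatim
but never used for matching, because published protein labels are not
always internally consistent.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import DataError, SchemaError

#: Column order of the event TSV schema.
TABLE_COLUMNS = [
    "Sample ID", "gDNA change", "Function", "Coding change", "Protein change",
    "SIFT", "Polyphen", "CADD", "MutationTaster", "PROVEAN", "M-CAP",
    "VEST4", "GERP", "phyloP", "ExAC", "1000 genomes", "gnomAD",
    "Inheritance", "PMID", "Cohort Size", "Primary diagnosis",
]

_GDNA_RE = re.compile(r"g\.(\d+)\s*([ACGT]+)\s*>\s*([ACGT]+)")


@dataclass(frozen=True)
class DenovoEvent:
    """One proband-variant observation in the integrated event table."""

    sample_id: str
    gdna_change: str
    function: str  # "missense" | "stop_gain"
    coding_change: str = ""
    protein_change: str = ""
    sift_bin: Optional[str] = None      # D / T
    polyphen_bin: Optional[str] = None  # D / P / B
    cadd: Optional[float] = None
    mutation_taster: Optional[str] = None
    provean: Optional[str] = None
    mcap: Optional[str] = None
    vest4: Optional[float] = None
    gerp: Optional[float] = None
    phylop: Optional[float] = None
    exac: Optional[float] = None
    thousand_genomes: Optional[float] = None
    gnomad: Optional[float] = None
    inheritance: str = "de novo"
    source: str = "this_study"
    cohort_size: Optional[str] = None
    primary_diagnosis: Optional[str] = None
    chrom: str = "chr5"

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, alt) parsed from the gDNA change string."""
        m = _GDNA_RE.search(self.gdna_change)
        if not m:
            raise DataError(f"cannot parse gDNA change {self.gdna_change!r}")
        return (self.chrom, int(m.group(1)), m.group(2), m.group(3))


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_NUMERIC = {"CADD": "cadd", "VEST4": "vest4", "GERP": "gerp", "phyloP": "phylop",
            "ExAC": "exac", "1000 genomes": "thousand_genomes", "gnomAD": "gnomad"}
_CATEG = {"SIFT": "sift_bin", "Polyphen": "polyphen_bin",
          "MutationTaster": "mutation_taster", "PROVEAN": "provean", "M-CAP": "mcap"}

_FUNCTION_MAP = {"missense": "missense", "stop gain": "stop_gain",
                 "stop_gain": "stop_gain", "nonsense": "stop_gain"}


def _norm_function(raw: str) -> str:
    key = raw.strip().lower()
    if key not in _FUNCTION_MAP:
        raise DataError(f"unknown Function value {raw!r}")
    return _FUNCTION_MAP[key]


def read_events_tsv(path: str | Path) -> list[DenovoEvent]:
    """Read events from a TSV in the fixed column schema."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"event table lacks columns: {missing}")
    events = []
    for _, row in df.iterrows():
        kwargs: dict = {
            "sample_id": row["Sample ID"].strip(),
            "gdna_change": row["gDNA change"].strip(),
            "function": _norm_function(row["Function"]),
            "coding_change": row["Coding change"].strip(),
            "protein_change": row["Protein change"].strip(),
            "inheritance": row["Inheritance"].strip().lower().replace("*", ""),
            "source": ("this_study" if row["PMID"].strip().lower() == "this study"
                       else row["PMID"].strip()),
            "cohort_size": row["Cohort Size"].strip() or None,
            "primary_diagnosis": row["Primary diagnosis"].strip() or None,
        }
        for col, attr in _CATEG.items():
            v = row[col].strip()
            kwargs[attr] = v or None
        for col, attr in _NUMERIC.items():
            v = row[col].strip()
            kwargs[attr] = float(v) if v else None
        events.append(DenovoEvent(**kwargs))
    return events


def write_events_tsv(events: Iterable[DenovoEvent], path: str | Path) -> None:
    """Write events as a TSV in the fixed column schema."""
    rows = []
    for e in events:
        rows.append({
            "Sample ID": e.sample_id,
            "gDNA change": e.gdna_change,
            "Function": "Stop gain" if e.function == "stop_gain" else "Missense",
            "Coding change": e.coding_change,
            "Protein change": e.protein_change,
            "SIFT": e.sift_bin or "",
            "Polyphen": e.polyphen_bin or "",
            "CADD": "" if e.cadd is None else e.cadd,
            "MutationTaster": e.mutation_taster or "",
            "PROVEAN": e.provean or "",
            "M-CAP": e.mcap or "",
            "VEST4": "" if e.vest4 is None else e.vest4,
            "GERP": "" if e.gerp is None else e.gerp,
            "phyloP": "" if e.phylop is None else e.phylop,
            "ExAC": "" if e.exac is None else e.exac,
            "1000 genomes": "" if e.thousand_genomes is None else e.thousand_genomes,
            "gnomAD": "" if e.gnomad is None else e.gnomad,
            "Inheritance": "De novo" if e.inheritance == "de novo" else e.inheritance,
            "PMID": "This study" if e.source == "this_study" else e.source,
            "Cohort Size": e.cohort_size or "",
            "Primary diagnosis": e.primary_diagnosis or "",
        })
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def load_mast4_events() -> list[DenovoEvent]:
    """The nine bundled MAST4 de novo events (study + published cohorts)."""
    with resources.as_file(
        resources.files("denovoprio.data") / "mast4_denovo_events.tsv"
    ) as p:
        events = read_events_tsv(p)
    assert len(events) == 9
    return events


# ---------------------------------------------------------------------------
# Analytics
# ---------------------------------------------------------------------------


def integrate_cohorts(
    study_events: Sequence[DenovoEvent],
    published_events: Sequence[DenovoEvent],
) -> list[DenovoEvent]:
    """Concatenate cohorts, rejecting duplicate (proband, variant) pairs.

    Output order is stable by genomic position.
    """
    merged = list(study_events) + list(published_events)
    seen: set[tuple] = set()
    for e in merged:
        pair = (e.sample_id, e.variant_key)
        if pair in seen:
            raise DataError(
                f"duplicate proband-variant pair: {e.sample_id} at {e.gdna_change}"
            )
        seen.add(pair)
    return sorted(merged, key=lambda e: e.variant_key)


def count_by_function(events: Sequence[DenovoEvent]) -> dict[str, int]:
    """Event counts per function class; counts partition the input."""
    return dict(Counter(e.function for e in events))


@dataclass(frozen=True)
class RecurrentSite:
    """A genomic variant carried by two or more distinct probands."""

    variant_key: tuple[str, int, str, str]
    proband_count: int
    probands: tuple[str, ...]
    protein_change: str

    def __post_init__(self) -> None:
        assert self.proband_count == len(set(self.probands)) >= 2


def find_recurrent_sites(events: Sequence[DenovoEvent]) -> list[RecurrentSite]:
    """Sites shared by >=2 distinct probands, sorted by descending multiplicity."""
    by_key: dict[tuple, list[DenovoEvent]] = {}
    for e in events:
        by_key.setdefault(e.variant_key, []).append(e)
    sites = []
    for key, evs in by_key.items():
        probands = sorted({e.sample_id for e in evs})
        if len(probands) >= 2:
            sites.append(
                RecurrentSite(
                    variant_key=key,
                    proband_count=len(probands),
                    probands=tuple(probands),
                    protein_change=evs[0].protein_change,
                )
            )
    return sorted(sites, key=lambda s: (-s.proband_count, s.variant_key))


def per_proband_scores(
    events: Sequence[DenovoEvent],
    score: str = "cadd",
    exclude_functions: Sequence[str] = ("stop_gain",),
) -> tuple[list[float], list[float]]:
    """Per-proband score values split by recurrent-site membership.

    Every proband contributes one value (so a recurrent site contributes
    its score once per carrier).  Stop-gain rows are excluded by default
    because SIFT/PolyPhen/CADD comparisons are made among missense
    events.  Returns ``(recurrent_values, non_recurrent_values)``.
    """
    if score not in DenovoEvent.__dataclass_fields__:
        raise DataError(f"unknown score column {score!r}")
    kept = [e for e in events if e.function not in set(exclude_functions)]
    values = [getattr(e, score) for e in kept]
    if any(not isinstance(v, (int, float)) for v in values if v is not None):
        raise DataError(f"score column {score!r} is not numeric")
    recurrent_keys = {s.variant_key for s in find_recurrent_sites(kept)}
    rec, nonrec = [], []
    for e, v in zip(kept, values):
        if v is None:
            continue
        (rec if e.variant_key in recurrent_keys else nonrec).append(float(v))
    return rec, nonrec
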