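"""Co-expression ranking of a target gene against known disease gene sets.

The statistic implemented here ranks a candidate gene among all
cortex-expressed genes by its mean Spearman correlation with a known
disease gene set (e.g. infantile-spasm, epileptic-encephalopathy or
developmental-disorder genes), measured across a developmental brain
expression atlas.  A low percentile means the candidate co-expresses with
the known set more strongly than most genes in the cortex-expressed
universe, which is circumstantial evidence for shared biology.

The expression container mirrors the layout of the BrainSpan developmental
transcriptome: an RPKM gene x sample matrix plus per-sample metadata
(brain region code, age, and prenatal/postnatal period).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

#: Neocortical region codes treated as "developing cortex" tissue.
NEOCORTEX_REGIONS: tuple[str, ...] = (
    "A1C", "DFC", "IPC", "ITC", "M1C", "MFC",
    "OFC", "S1C", "STC", "V1C", "VFC",
)

#: All region codes of the developmental atlas (neocortex plus amygdala,
#: cerebellar cortex, hippocampus, mediodorsal thalamus and striatum).
ALL_REGIONS: tuple[str, ...] = (
    "A1C", "AMY", "CBC", "DFC", "HIP", "IPC", "ITC", "M1C",
    "MD", "MFC", "OFC", "S1C", "STC", "STR", "V1C", "VFC",
)

_META_COLUMNS = ["sample_id", "region", "age_value", "age_unit", "age_days", "period"]


@dataclass
class ExpressionAtlas:
    """Gene x sample RPKM matrix with per-sample developmental metadata.

    Parameters
    ----------
    rpkm
        DataFrame of non-negative RPKM values, genes as rows, samples as
        columns.
    samples
        DataFrame indexed by ``sample_id`` with columns ``region``,
        ``age_value``, ``age_unit``, ``age_days`` (post-conceptional days)
        and ``period`` ("prenatal" / "postnatal").
    module_genes, ramp_genes
        Simulation ground truth (latent co-expression module members and
        genes carrying a planted prenatal ramp).  ``None`` for real data.
    """

    rpkm: pd.DataFrame
    samples: pd.DataFrame
    module_genes: list[str] | None = None
    ramp_genes: list[str] | None = None

    def __post_init__(self) -> None:
        vals = self.rpkm.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise DataError("RPKM matrix contains non-finite values")
        if (vals < 0).any():
            raise DataError("RPKM matrix contains negative values")
        missing = [c for c in ("region", "age_days", "period") if c not in self.samples.columns]
        if missing:
            raise DataError(f"sample metadata lacks columns: {missing}")
        if not self.rpkm.columns.equals(self.samples.index):
            # allow same set in different order
            if set(self.rpkm.columns) != set(self.samples.index):
                raise DataError("rpkm columns and sample metadata index disagree")
            self.samples = self.samples.loc[self.rpkm.columns]
        if (self.samples["age_days"] <= 0).any():
            raise DataError("age_days must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.rpkm.index

    @property
    def n_samples(self) -> int:
        return self.rpkm.shape[1]

    def region_samples(self, regions: Iterable[str]) -> pd.Index:
        regions = set(regions)
        mask = self.samples["region"].isin(regions)
        return self.samples.index[mask]

    # --- TSV round trip (expression matrix + columns metadata) ------------

    def save(self, expr_path: str | Path, meta_path: str | Path) -> None:
        self.rpkm.to_csv(expr_path, sep="\t", index_label="gene")
        meta = self.samples.reset_index().rename(columns={"index": "sample_id"})
        if "sample_id" not in meta.columns:
            meta.insert(0, "sample_id", self.samples.index)
        meta[_META_COLUMNS].to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def load(cls, expr_path: str | Path, meta_path: str | Path) -> "ExpressionAtlas":
        rpkm = pd.read_csv(expr_path, sep="\t", index_col="gene")
        meta = pd.read_csv(meta_path, sep="\t")
        missing = [c for c in _META_COLUMNS if c not in meta.columns]
        if missing:
            raise DataError(f"metadata file lacks columns: {missing}")
        meta = meta.set_index("sample_id")
        return cls(rpkm=rpkm, samples=meta)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (IS / EE / DD / custom)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(sorted(self.members)) + "\n")

    @classmethod
    def load(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        p = Path(path)
        members = frozenset(
            line.strip() for line in p.read_text().splitlines() if line.strip()
        )
        return cls(name=name or p.stem, members=members)


@dataclass(frozen=True)
class PercentileResult:
    """Rank of a gene's mean set correlation within the expressed universe.

    ``percentile`` runs from 0 (strongest co-expression with the set in the
    whole universe) to 100; ties contribute half a count.
    """

    gene: str
    set_name: str
    mean_abs_rho: float
    percentile: float
    universe_size: int


def cortex_expressed_genes(
    atlas: ExpressionAtlas,
    rpkm_min: float = 0.5,
    fraction: float = 0.5,
    cortex_regions: Sequence[str] = NEOCORTEX_REGIONS,
) -> list[str]:
    """Genes with RPKM > ``rpkm_min`` in at least ``fraction`` of cortex samples.

    The comparison against ``rpkm_min`` is strict; the sample-fraction
    requirement is inclusive (>=).
    """
    cols = atlas.region_samples(cortex_regions)
    if len(cols) == 0:
        raise DataError("no samples from the requested cortex regions")
    expressed = (atlas.rpkm[cols] > rpkm_min).mean(axis=1) >= fraction
    return list(atlas.genes[expressed])


def _rank_rows(mat: np.ndarray) -> np.ndarray:
    """Average-rank transform of each row (Spearman pre-processing)."""
    return np.apply_along_axis(stats.rankdata, 1, mat)


def _standardize_rows(ranks: np.ndarray) -> np.ndarray:
    """Center and scale rows to unit norm; constant rows become NaN."""
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = centered / norms
    out[np.isclose(norms[:, 0], 0.0)] = np.nan
    return out


def _mean_set_corr_matrix(
    atlas: ExpressionAtlas,
    universe: Sequence[str],
    members_in_universe: Sequence[str],
    absolute: bool,
) -> pd.Series:
    """Mean (absolute) Spearman rho of every universe gene with the set.

    Self-correlation is excluded for genes that are themselves members.
    Constant-expression pairs are skipped; a gene whose every pair is
    skipped gets NaN.
    """
    sub = atlas.rpkm.loc[list(universe)].to_numpy(dtype=float)
    z = _standardize_rows(_rank_rows(sub))
    idx = pd.Index(universe)
    member_pos = idx.get_indexer(list(members_in_universe))
    corr = z @ z[member_pos].T  # universe x members, NaN where either constant
    # drop self-correlation for member genes
    for j, gpos in enumerate(member_pos):
        corr[gpos, j] = np.nan
    if absolute:
        corr = np.abs(corr)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(corr, axis=1)
    return pd.Series(means, index=idx)


def mean_set_correlation(
    gene: str,
    gene_set: GeneSet,
    atlas: ExpressionAtlas,
    universe: Sequence[str] | None = None,
    absolute: bool = True,
) -> float:
    """Mean |Spearman rho| between ``gene`` and the members of ``gene_set``.

    Correlations are computed across all atlas samples with average-rank
    tie handling.  ``gene`` itself is excluded if it belongs to the set.
    Members outside ``universe`` (default: all atlas genes) are ignored.
    """
    if universe is None:
        universe = list(atlas.genes)
    if gene not in set(universe):
        raise DataError(f"gene {gene!r} is not in the correlation universe")
    members = sorted(g for g in gene_set.members if g in set(universe) and g != gene)
    if not members:
        raise DataError(f"no usable members of set {gene_set.name!r} in the universe")
    sub = atlas.rpkm.loc[[gene] + members].to_numpy(dtype=float)
    z = _standardize_rows(_rank_rows(sub))
    rhos = z[0] @ z[1:].T
    rhos = rhos[np.isfinite(rhos)]
    if rhos.size == 0:
        raise DataError("all correlation pairs skipped (constant expression)")
    return float(np.mean(np.abs(rhos)) if absolute else np.mean(rhos))


def percentile_of_gene(
    target: str,
    gene_set: GeneSet,
    atlas: ExpressionAtlas,
    rpkm_min: float = 0.5,
    fraction: float = 0.5,
    cortex_regions: Sequence[str] = NEOCORTEX_REGIONS,
    absolute: bool = True,
    universe: Sequence[str] | None = None,
) -> PercentileResult:
    """Percentile of ``target``'s mean set correlation in the expressed universe.

    The universe defaults to the cortex-expressed genes of the atlas.  The
    percentile is ``100 * (#genes with strictly greater mean + 0.5 * #ties)
    / universe size`` — 0 means the target tops the ranking.
    """
    if universe is None:
        universe = cortex_expressed_genes(atlas, rpkm_min, fraction, cortex_regions)
    if target not in set(universe):
        raise DataError(f"target {target!r} is not cortex-expressed")
    members = sorted(g for g in gene_set.members if g in set(universe))
    if not members:
        raise DataError(f"no members of {gene_set.name!r} are cortex-expressed")
    means = _mean_set_corr_matrix(atlas, universe, members, absolute)
    if means.isna().all():
        raise DataError("all correlation pairs skipped (constant expression)")
    target_mean = means[target]
    if np.isnan(target_mean):
        raise DataError(f"mean correlation undefined for target {target!r}")
    others = means.drop(target).to_numpy()
    others = others[np.isfinite(others)]
    greater = int(np.sum(others > target_mean))
    ties = int(np.sum(others == target_mean))
    percentile = 100.0 * (greater + 0.5 * ties) / len(universe)
    return PercentileResult(
        gene=target,
        set_name=gene_set.name,
        mean_abs_rho=float(target_mean),
        percentile=float(percentile),
        universe_size=len(universe),
    )


def percentile_table(
    target: str,
    gene_sets: Iterable[GeneSet],
    atlas: ExpressionAtlas,
    **kwargs,
) -> pd.DataFrame:
    """Percentile of one target against several gene sets, as a DataFrame."""
    rows = []
    for gs in gene_sets:
        r = percentile_of_gene(target, gs, atlas, **kwargs)
        rows.append(
            {
                "gene": r.gene,
                "set": r.set_name,
                "mean_abs_rho": r.mean_abs_rho,
                "percentile": r.percentile,
                "universe_size": r.universe_size,
            }
        )
    return pd.DataFrame(rows)
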