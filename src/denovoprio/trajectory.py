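"""Prenatal/postnatal expression-trajectory regression for a target gene.

Fits ordinary least squares of RPKM on post-conceptional age (in days)
within a region group and developmental period, the standard way of
asking whether a gene is up-regulated during embryonic brain development
(steep prenatal slope, high R^2) versus after birth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .coexpression import NEOCORTEX_REGIONS, ExpressionAtlas
from .errors import ConfigurationError, DataError

#: Post-conceptional day of birth (40 gestational weeks).
BIRTH_DAYS: float = 280.0
DAYS_PER_MONTH: float = 30.4375  # calendar-average month
DAYS_PER_YEAR: float = 365.25

#: Cerebral-cortex aggregate: the neocortical region codes.
CC_REGIONS: tuple[str, ...] = NEOCORTEX_REGIONS
#: Prefrontal-cortex aggregate.
FC_REGIONS: tuple[str, ...] = ("DFC", "MFC", "OFC", "VFC")

REGION_GROUPS: dict[str, tuple[str, ...]] = {"CC": CC_REGIONS, "FC": FC_REGIONS}


def age_to_days(age_value: float, age_unit: str) -> float:
    """Convert an age to post-conceptional days.

    ``pcw`` counts from conception (7 days per week); ``months`` and
    ``years`` count from birth, which is fixed at 280 post-conceptional
    days.
    """
    if age_value <= 0:
        raise ConfigurationError(f"age_value must be positive, got {age_value}")
    if age_unit == "pcw":
        return age_value * 7.0
    if age_unit == "months":
        return BIRTH_DAYS + age_value * DAYS_PER_MONTH
    if age_unit == "years":
        return BIRTH_DAYS + age_value * DAYS_PER_YEAR
    raise ConfigurationError(f"unknown age unit {age_unit!r}")


def period_of(age_days: float) -> str:
    """Developmental period: prenatal strictly before 280 days, else postnatal."""
    return "prenatal" if age_days < BIRTH_DAYS else "postnatal"


@dataclass(frozen=True)
class TrajectoryFit:
    """One univariate regression of expression on age.

    ``slope`` is in RPKM per post-conceptional day; ``p_value`` is the
    two-sided slope p-value from the t distribution with n-2 df.
    """

    gene: str
    region_group: str
    period: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def fit_trajectory(
    atlas: ExpressionAtlas,
    gene: str,
    region_group: str | Sequence[str] = "CC",
    period: str = "prenatal",
    log1p: bool = False,
) -> TrajectoryFit:
    """OLS of ``gene``'s RPKM on age_days in a (region group, period) stratum.

    ``region_group`` may be "CC", "FC", or an explicit list of region
    codes.  RPKM enters the regression untransformed unless ``log1p``.
    """
    if isinstance(region_group, str):
        try:
            regions = REGION_GROUPS[region_group]
        except KeyError:
            raise ConfigurationError(
                f"unknown region group {region_group!r}; use 'CC', 'FC' or a region list"
            ) from None
        group_name = region_group
    else:
        regions = tuple(region_group)
        group_name = ",".join(regions)
    if period not in ("prenatal", "postnatal"):
        raise ConfigurationError(f"period must be prenatal/postnatal, got {period!r}")
    if gene not in atlas.genes:
        raise DataError(f"gene {gene!r} not in atlas")

    cols = atlas.region_samples(regions)
    cols = cols[atlas.samples.loc[cols, "period"] == period]
    if len(cols) < 3:
        raise DataError(
            f"need >=3 samples in ({group_name}, {period}), found {len(cols)}"
        )
    x = atlas.samples.loc[cols, "age_days"].to_numpy(dtype=float)
    y = atlas.rpkm.loc[gene, cols].to_numpy(dtype=float)
    if log1p:
        y = np.log1p(y)
    if np.isclose(np.var(x), 0.0):
        raise DataError("zero age variance in the selected stratum")
    if np.isclose(np.var(y), 0.0):
        # flat expression: slope 0, no explained variance
        return TrajectoryFit(gene, group_name, period, 0.0, float(y[0]), 0.0, 1.0, len(x))
    res = stats.linregress(x, y)
    return TrajectoryFit(
        gene=gene,
        region_group=group_name,
        period=period,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


def slope_standard_error(fit_x: np.ndarray, fit_y: np.ndarray) -> float:
    """Closed-form OLS slope standard error (used by simulation checks)."""
    res = stats.linregress(fit_x, fit_y)
    return float(res.stderr)


def plot_trajectory(
    atlas: ExpressionAtlas,
    gene: str,
    region_group: str | Sequence[str],
    out_path: str,
) -> None:
    """Scatter RPKM vs age with per-period regression lines and a birth line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(region_group, str):
        regions = REGION_GROUPS.get(region_group, (region_group,))
    else:
        regions = tuple(region_group)
    cols = atlas.region_samples(regions)
    x = atlas.samples.loc[cols, "age_days"].to_numpy(dtype=float)
    y = atlas.rpkm.loc[gene, cols].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(x, y, s=12, alpha=0.6)
    for period in ("prenatal", "postnatal"):
        try:
            fit = fit_trajectory(atlas, gene, region_group, period)
        except DataError:
            continue
        mask = (x < BIRTH_DAYS) if period == "prenatal" else (x >= BIRTH_DAYS)
        if mask.sum() >= 2:
            xs = np.linspace(x[mask].min(), x[mask].max(), 50)
            ax.plot(xs, fit.intercept + fit.slope * xs,
                    label=f"{period}: R²={fit.r_squared:.3f}")
    ax.axvline(BIRTH_DAYS, linestyle="--", color="grey")
    ax.set_xscale("log")
    ax.set_xlabel("post-conceptional age (days)")
    ax.set_ylabel(f"{gene} RPKM")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
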