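"""Plate-level screening statistics: Z-scores, hit tiers, Z' factor.

The screen looks for compounds that INCREASE ciliation, so hit calling
is one-sided above the population mean: a compound whose well value is
at least 2 population standard deviations above the mean of all
screened wells is a hit, and at least 3 SD a top-tier hit.  Z-scores
use the population SD (divide by N), the usual convention when the
plate itself defines the null population; the control-arm SDs entering
the Z' factor are sample SDs (divide by n-1).  Both choices are
switchable via ``ddof``.

Z' (Zhang et al.'s assay-quality factor) is

    Z' = 1 - 3 * (sd_pos + sd_neg) / |mean_pos - mean_neg|

and approaches 1 as the control distributions separate; values above
~0.5 indicate a robust assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TIER_NONE = "none"
TIER_2SD = "hit_2sd"
TIER_3SD = "hit_3sd"


@dataclass
class PlateStats:
    """Population statistics of one screened plate."""

    population_mean: float
    population_sd: float
    n_wells: int
    z_prime: Optional[float] = None


@dataclass
class HitCall:
    """Per-compound Z-score and hit tier."""

    compound: str
    value: float
    z_score: float
    tier: str


def _tier(z: float) -> str:
    if z >= 3.0:
        return TIER_3SD
    if z >= 2.0:
        return TIER_2SD
    return TIER_NONE


def z_scores(
    values: Sequence[tuple[str, float]],
    ddof: int = 0,
) -> list[HitCall]:
    """Score every screened well against the population of all wells.

    ``values`` pairs a compound identifier with its percent-ciliated
    readout.  z_i = (x_i - mean) / sd with the population SD by default
    (``ddof=0``).  Tiers are one-sided above the mean: z >= 3 is
    ``hit_3sd``, 2 <= z < 3 is ``hit_2sd``.  Raises ``ValueError`` for
    fewer than two wells or a zero-variance (degenerate) plate.
    """
    if len(values) < 2:
        raise ValueError("z_scores requires at least two wells")
    x = np.asarray([v for _, v in values], dtype=float)
    mean = float(x.mean())
    sd = float(x.std(ddof=ddof))
    if sd == 0:
        raise ValueError("degenerate plate: zero standard deviation across wells")
    out = []
    for (compound, value), z in zip(values, (x - mean) / sd):
        out.append(HitCall(compound=compound, value=float(value), z_score=float(z),
                           tier=_tier(float(z))))
    return out


def plate_stats(
    values: Sequence[float],
    pos: Optional[Sequence[float]] = None,
    neg: Optional[Sequence[float]] = None,
    ddof: int = 0,
) -> PlateStats:
    """Population mean/SD of a plate, with Z' when both control arms are
    provided."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("plate_stats requires at least two wells")
    zp = None
    if pos is not None and neg is not None and len(pos) >= 2 and len(neg) >= 2:
        zp = z_prime(pos, neg)
    return PlateStats(
        population_mean=float(x.mean()),
        population_sd=float(x.std(ddof=ddof)),
        n_wells=int(x.size),
        z_prime=zp,
    )


def z_prime(pos: Sequence[float], neg: Sequence[float], ddof: int = 1) -> float:
    """Z' = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|.

    Control-arm SDs are sample SDs by default.  At most 1, reached only
    when both arms have zero variance.  Raises ``ValueError`` when an
    arm has fewer than two wells or the control means coincide (the
    separation band is undefined).
    """
    p = np.asarray(pos, dtype=float)
    n = np.asarray(neg, dtype=float)
    if p.size < 2 or n.size < 2:
        raise ValueError("z_prime requires at least two wells per control arm")
    sep = abs(float(p.mean()) - float(n.mean()))
    if sep == 0:
        raise ValueError("z_prime undefined: control means are equal")
    return 1.0 - 3.0 * (float(p.std(ddof=ddof)) + float(n.std(ddof=ddof))) / sep


def dose_response_table(wells: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/n of percent ciliated per (compound, dose).

    ``wells`` needs columns ``compound``, ``dose`` and a percent column
    (``percent_ciliated_pooled`` or ``percent_ciliated``).  Returns one
    row per (compound, dose) ordered by compound then ascending dose,
    with columns compound, dose, mean_percent_ciliated,
    sd_percent_ciliated, n_wells.  Empty input yields an empty table.
    """
    cols = ["compound", "dose", "mean_percent_ciliated", "sd_percent_ciliated", "n_wells"]
    if len(wells) == 0:
        return pd.DataFrame(columns=cols)
    value_col = None
    for cand in ("percent_ciliated_pooled", "percent_ciliated"):
        if cand in wells.columns:
            value_col = cand
            break
    if value_col is None:
        raise ValueError("no percent-ciliated column found in the well table")
    g = wells.groupby(["compound", "dose"], dropna=False)[value_col]
    out = g.agg(mean_percent_ciliated="mean",
                sd_percent_ciliated=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
                n_wells="count").reset_index()
    out = out.sort_values(["compound", "dose"], kind="stable").reset_index(drop=True)
    return out[cols]
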