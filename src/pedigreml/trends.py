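"""Genetic and phenotypic trends across generations.

The genetic trend is the regression of the mean estimated breeding value
(EBV) on generation, by default over the females that contributed progeny
to the next generation (dams of record); the slope is the genetic gain per
generation in trait units.  The phenotypic trend applies the same weighted
regression to raw generation means of the records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .pedigree import UNKNOWN, Pedigree


@dataclass
class TrendResult:
    by_generation: pd.DataFrame   # generation, n, mean, se
    slope: float
    slope_se: float
    intercept: float
    p: float


def _weighted_trend(gen, values) -> TrendResult:
    df = pd.DataFrame({"generation": gen, "y": values})
    g = (df.groupby("generation")["y"]
           .agg(n="size", mean="mean", sd="std").reset_index())
    g["se"] = g["sd"] / np.sqrt(g["n"])
    if len(g) < 3:
        raise ValueError("need at least 3 generations with records")
    X = sm.add_constant(g["generation"].to_numpy(dtype=float))
    wls = sm.WLS(g["mean"].to_numpy(), X, weights=g["n"].to_numpy()).fit()
    slope = float(wls.params[1])
    se = float(wls.bse[1])
    # a perfect (or constant) fit has zero residual variance: the t test is
    # degenerate, so report p = 1 for a zero slope and p = 0 otherwise
    if not np.isfinite(se) or se == 0:
        p = 1.0 if abs(slope) < 1e-12 else 0.0
    else:
        p = float(wls.pvalues[1])
    return TrendResult(by_generation=g.drop(columns="sd"), slope=slope,
                       slope_se=se, intercept=float(wls.params[0]), p=p)


def contributing_females(ped: Pedigree) -> np.ndarray:
    """Mask of female animals that appear as the dam of at least one
    animal of a later generation."""
    mask = np.zeros(ped.n, dtype=bool)
    dams = ped.dam[ped.dam != UNKNOWN]
    mask[np.unique(dams)] = True
    if (ped.sex != None).any():  # noqa: E711 — object array comparison
        mask &= (ped.sex == "F") | (ped.sex == None)  # noqa: E711
    return mask


def genetic_trend(ebv: pd.DataFrame, ped: Pedigree,
                  subset: str = "contributing-females") -> TrendResult:
    """Weighted regression of per-generation mean EBV on generation.

    ``subset`` is ``"contributing-females"`` (dams of next-generation
    animals) or ``"all"`` (every animal with an EBV).
    """
    df = ebv.copy()
    if subset == "contributing-females":
        mask = contributing_females(ped)
        keep = {ped.ids[i] for i in np.where(mask)[0]}
        df = df[df["animal"].isin(keep)]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    return _weighted_trend(df["generation"].to_numpy(), df["ebv"].to_numpy())


def phenotypic_trend(records: pd.DataFrame, trait: str) -> TrendResult:
    """Weighted regression of raw generation means of one trait."""
    rec = records.loc[records[trait].notna()]
    return _weighted_trend(rec["generation"].to_numpy(),
                           rec[trait].to_numpy())
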