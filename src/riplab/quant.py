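"""Semiquantitative immunoblot and qPCR quantification.

Immunoblots are quantified from serial-dilution series: each sample is
loaded at several relative loads (e.g. 1/2, 1/4, 1/6) and both the
antibody chemiluminescent signal and a stain-free total-protein signal are
recorded per lane.  Because both channels are proportional to the amount
loaded, each is summarized by a least-squares slope through the origin
against relative load, and the normalized protein level is the ratio of
the two slopes — invariant to joint rescaling of the channels and to the
particular dilution ladder used.

Relative qPCR expression uses the ddCt method with amplification
efficiency fixed at 2, and IP yield is expressed as percent of input with
an adjustment for the fraction of lysate used for the input measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "DilutionSeries",
    "RelativeLevel",
    "normalized_level",
    "percent_of_input",
    "relative_expression_ddct",
    "relative_level",
]


@dataclass(frozen=True)
class DilutionSeries:
    """One blot's dilution ladder for one sample.

    ``lanes`` are (relative_load in (0, 1], chemi_signal >= 0,
    total_protein_signal > 0) triples.
    """

    genotype: str
    fraction: str
    lanes: tuple[tuple[float, float, float], ...]
    replicate: str = "1"

    def __post_init__(self) -> None:
        if len({load for load, _, _ in self.lanes}) < 2:
            raise InputError(
                f"series {self.genotype}/{self.fraction}/{self.replicate}: "
                "need >= 2 lanes with distinct loads"
            )
        for load, chemi, total in self.lanes:
            if load <= 0:
                raise InputError(f"non-positive relative load {load}")
            if chemi < 0 or total <= 0:
                raise InputError(
                    f"invalid signals (chemi={chemi}, total={total}) at load {load}"
                )


@dataclass(frozen=True)
class RelativeLevel:
    ratio_mut_over_wt: float
    levels_mut: tuple[float, ...]
    levels_wt: tuple[float, ...]
    t_statistic: float
    p_value: float


def _slope_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    # argmin_b sum (y - b x)^2  =>  b = sum(xy) / sum(x^2)
    return float(np.dot(x, y) / np.dot(x, x))


def normalized_level(series: DilutionSeries) -> float:
    """Chemiluminescent slope over total-protein slope, both through the origin."""
    lanes = np.asarray(series.lanes, dtype=float)
    loads, chemi, total = lanes[:, 0], lanes[:, 1], lanes[:, 2]
    slope_total = _slope_through_origin(loads, total)
    if slope_total == 0:
        raise InputError(
            f"series {series.genotype}/{series.fraction}/{series.replicate}: "
            "total-protein slope is zero"
        )
    return _slope_through_origin(loads, chemi) / slope_total


def relative_level(
    mut: Sequence[DilutionSeries],
    wt: Sequence[DilutionSeries],
    test: Literal["welch", "pooled"] = "welch",
) -> RelativeLevel:
    """Mutant-over-WT ratio of mean normalized levels, with a two-sample t-test.

    Each biological replicate contributes one normalized level per genotype;
    the t-test (Welch by default) compares the per-replicate levels.
    """
    if len(mut) < 2 or len(wt) < 2:
        raise InputError("need >= 2 replicates per genotype")
    fractions_mut = {s.fraction for s in mut}
    fractions_wt = {s.fraction for s in wt}
    if fractions_mut != fractions_wt:
        raise InputError(
            f"fraction labels differ between arms: {fractions_mut} vs {fractions_wt}"
        )
    levels_mut = tuple(normalized_level(s) for s in mut)
    levels_wt = tuple(normalized_level(s) for s in wt)
    tstat, pval = stats.ttest_ind(
        levels_mut, levels_wt, equal_var=(test == "pooled")
    )
    return RelativeLevel(
        ratio_mut_over_wt=float(np.mean(levels_mut) / np.mean(levels_wt)),
        levels_mut=levels_mut,
        levels_wt=levels_wt,
        t_statistic=float(tstat),
        p_value=float(pval),
    )


def relative_expression_ddct(table: pd.DataFrame, calibrator: str) -> pd.Series:
    """2^-ddCt relative expression per sample, efficiency fixed at 2.

    ``table`` needs columns ``sample``, ``ct_target``, ``ct_reference``;
    dCt = Ct_target - Ct_reference, ddCt is relative to the calibrator
    sample's dCt.
    """
    required = {"sample", "ct_target", "ct_reference"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"Ct table lacks column(s) {sorted(missing)}")
    if table[["ct_target", "ct_reference"]].isna().any().any():
        raise InputError("Ct table contains missing Ct values")
    dct = (
        table.set_index("sample")["ct_target"]
        - table.set_index("sample")["ct_reference"]
    )
    if calibrator not in dct.index:
        raise InputError(f"calibrator sample {calibrator!r} absent from table")
    ddct = dct - dct.loc[calibrator]
    return np.power(2.0, -ddct).rename("relative_expression")


def percent_of_input(
    ct_ip: float,
    ct_input: float,
    input_fraction: float = 0.05,
) -> float:
    """IP yield as percent of input.

    ``input_fraction`` is the fraction of the lysate used for the input
    measurement (default 0.05, i.e. 100 uL of 2 mL); the input Ct is first
    adjusted by -log2(input_fraction), then
    yield% = 100 * input_fraction * 2^(Ct_input_adj - Ct_ip).
    """
    if input_fraction <= 0:
        raise InputError("input_fraction must be > 0")
    if not (np.isfinite(ct_ip) and np.isfinite(ct_input)):
        raise InputError("Ct values must be finite")
    ct_input_adj = ct_input - log2(input_fraction)
    return 100.0 * input_fraction * 2.0 ** (ct_input_adj - ct_ip)
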