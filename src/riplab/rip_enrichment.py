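"""Control-calibrated RIP-seq target calling.

Gene-level read counts from three libraries — Input (total lysate RNA), an
experimental IP (anti-GFP pull-down of the tagged RNA-binding protein) and a
mock IP (pre-immune IgG) — are normalized to counts per million (CPM).  Two
enrichment ratios are computed per gene, IP/Input and IP/mock-IP, and a gene
is called a target when it is detected in both Input and IP, is
protein-coding, and both ratios are at least as large as the smallest value
observed for three positive-control transcripts (by default *orb2*, *act5C*
and *tub56D*), which are known to be bound and therefore calibrate what
"enriched" means for the library at hand.

Counts are pandas DataFrames indexed by gene id with columns ``input``,
``ip`` and ``mock_ip``; biotypes are a pandas Series aligned on gene id with
values ``protein_coding`` / ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, InputError

__all__ = [
    "FilterThresholds",
    "SAMPLE_COLUMNS",
    "DEFAULT_CONTROLS",
    "call_targets",
    "call_targets_from_counts",
    "calibrate_thresholds",
    "compute_cpm",
    "detect_genes",
    "enrichment_table",
]

SAMPLE_COLUMNS = ("input", "ip", "mock_ip")
DEFAULT_CONTROLS = ("orb2", "act5C", "tub56D")


@dataclass(frozen=True)
class FilterThresholds:
    """Per-ratio pass thresholds: the minimum ratio over the calibrating controls."""

    min_ratio_ip_input: float
    min_ratio_ip_mock: float
    control_ids: tuple[str, ...]


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.empty:
        raise InputError("count matrix is empty")
    missing = [c for c in SAMPLE_COLUMNS if c not in counts.columns]
    if missing:
        raise InputError(f"count matrix lacks sample column(s) {missing}")
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate gene ids: {dupes[:5]}")
    values = counts[list(SAMPLE_COLUMNS)]
    if (values < 0).any().any():
        raise InputError("counts must be non-negative")
    return values


def compute_cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Counts-per-million with a pseudocount added to every count.

    cpm(g, s) = 1e6 * (count(g, s) + pseudocount) / sum_g'(count(g', s) + pseudocount),
    so every column sums to exactly one million.  The default pseudocount of
    0.5 keeps downstream enrichment ratios finite for genes absent from one
    library; pseudocount 0 recovers exact count proportions.
    """
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    values = _validate_counts(counts).astype(float) + pseudocount
    totals = values.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise InputError(
            f"column(s) {bad} sum to zero; use a positive pseudocount"
        )
    return 1e6 * values / totals


def detect_genes(counts: pd.DataFrame, min_count: int = 1) -> set[str]:
    """Genes with raw count >= min_count in both Input and IP (mock IP ignored)."""
    if min_count < 1:
        raise InputError("min_count must be a positive integer")
    values = _validate_counts(counts)
    mask = (values["input"] >= min_count) & (values["ip"] >= min_count)
    return set(counts.index[mask])


def enrichment_table(
    cpm: pd.DataFrame,
    detected: set[str],
    biotypes: pd.Series,
) -> pd.DataFrame:
    """Per-gene enrichment ratios IP/Input and IP/mock-IP, plus detection flags.

    The ``passes`` column is left unset (NA) until :func:`call_targets`.
    """
    if (cpm[list(SAMPLE_COLUMNS)] <= 0).any().any():
        raise InputError(
            "CPM contains zeros; compute with a positive pseudocount so "
            "enrichment ratios are finite"
        )
    bt = biotypes.reindex(cpm.index).fillna("other")
    table = pd.DataFrame(
        {
            "biotype": bt,
            "detected": cpm.index.isin(list(detected)),
            "ratio_ip_input": cpm["ip"] / cpm["input"],
            "ratio_ip_mock": cpm["ip"] / cpm["mock_ip"],
            "passes": pd.Series(pd.NA, index=cpm.index, dtype="boolean"),
        },
        index=cpm.index,
    )
    return table


def calibrate_thresholds(
    table: pd.DataFrame,
    control_ids: tuple[str, str, str] = DEFAULT_CONTROLS,
) -> FilterThresholds:
    """Thresholds = minimum of each ratio over the three positive controls."""
    if len(control_ids) != 3:
        raise CalibrationError(
            f"exactly three calibrating controls required, got {len(control_ids)}"
        )
    for gid in control_ids:
        if gid not in table.index:
            raise CalibrationError(f"control gene {gid!r} absent from table")
        if not bool(table.loc[gid, "detected"]):
            raise CalibrationError(f"control gene {gid!r} not detected in Input and IP")
    controls = table.loc[list(control_ids)]
    return FilterThresholds(
        min_ratio_ip_input=float(controls["ratio_ip_input"].min()),
        min_ratio_ip_mock=float(controls["ratio_ip_mock"].min()),
        control_ids=tuple(control_ids),
    )


def call_targets(
    table: pd.DataFrame,
    thresholds: FilterThresholds,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the calibrated discard rule and return the called-target list.

    A gene passes iff it is detected, protein-coding, and BOTH ratios are >=
    their control-calibrated thresholds (ties pass, so the controls
    themselves always pass their own calibration).  The list is sorted by
    descending IP/mock ratio with gene id as tie-break.
    """
    annotated = table.copy()
    passes = (
        annotated["detected"]
        & (annotated["biotype"] == "protein_coding")
        & (annotated["ratio_ip_input"] >= thresholds.min_ratio_ip_input)
        & (annotated["ratio_ip_mock"] >= thresholds.min_ratio_ip_mock)
    )
    annotated["passes"] = passes.astype("boolean")
    hits = annotated[passes]
    order = sorted(hits.index, key=lambda g: (-hits.at[g, "ratio_ip_mock"], g))
    return order, annotated


def call_targets_from_counts(
    counts: pd.DataFrame,
    biotypes: pd.Series,
    control_ids: tuple[str, str, str] = DEFAULT_CONTROLS,
    pseudocount: float = 0.5,
    min_count: int = 1,
) -> tuple[list[str], pd.DataFrame, FilterThresholds]:
    """Full rule chain: CPM -> detection -> ratios -> calibration -> calls."""
    cpm = compute_cpm(counts, pseudocount=pseudocount)
    detected = detect_genes(counts, min_count=min_count)
    table = enrichment_table(cpm, detected, biotypes)
    thresholds = calibrate_thresholds(table, control_ids)
    called, annotated = call_targets(table, thresholds)
    return called, annotated, thresholds
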