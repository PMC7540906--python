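"""Per-sample quality control and phylum-level composition summaries.

A sample (one nematode specimen, one amplified region) is retained when it
yields more than ``min_reads`` nematode-derived reads AND the relative
abundance of nematode-derived SVs exceeds ``min_nem_frac`` of total reads.
Minor nematode SVs count toward the abundance criterion only when each
individually exceeds the polymorphic-SV floor (7% relative abundance); the
most abundant nematode SV always counts.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "relative_abundance",
    "aggregate_phylum",
    "select_nematode_samples",
    "pcr_success_rate",
    "round_half_up",
]

NEMATODE_PHYLUM = "Nematoda"


def round_half_up(numerator: float, denominator: float = 1.0,
                  scale: float = 1.0, ndigits: int = 1) -> float:
    """Round ``scale * numerator / denominator`` half-away-from-zero."""
    q = Decimal(str(scale)) * Decimal(str(numerator)) / Decimal(str(denominator))
    exp = Decimal(1).scaleb(-ndigits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def _check_counts(table: pd.DataFrame) -> None:
    if (table["count"] < 0).any():
        raise ValueError("negative counts in feature table")


def relative_abundance(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample SV proportions.

    Returns (long-format proportion table with a ``frac`` column, list of
    zero-total sample ids).  Zero-total samples are flagged and dropped from
    the proportion table rather than divided.
    """
    _check_counts(table)
    totals = table.groupby("sample_id")["count"].sum()
    zero = sorted(totals.index[totals == 0])
    out = table[~table["sample_id"].isin(zero)].copy()
    out["frac"] = out["count"] / out["sample_id"].map(totals)
    return out, zero


def aggregate_phylum(
    proportions: pd.DataFrame,
    min_frac: float = 0.01,
) -> pd.DataFrame:
    """Phylum composition per sample: same-phylum SV fractions summed, then
    phyla strictly below ``min_frac`` removed (a phylum at exactly the
    threshold is retained).  Unassigned SVs aggregate under ``"NA"``."""
    df = proportions.copy()
    df["phylum"] = df["phylum"].fillna("NA")
    agg = (df.groupby(["sample_id", "phylum"], as_index=False)["frac"].sum())
    return agg[agg["frac"] >= min_frac].reset_index(drop=True)


def select_nematode_samples(
    table: pd.DataFrame,
    min_reads: int = 1000,
    min_nem_frac: float = 0.65,
    minor_floor: float = 0.07,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the two per-sample selection rules (strict inequalities).

    Returns (sorted retained sample ids, QC report with one row per sample:
    total reads, nematode reads, counted nematode fraction, per-criterion
    flags and failure reasons).
    """
    _check_counts(table)
    records = []
    for sample, grp in table.groupby("sample_id"):
        total = int(grp["count"].sum())
        nem = grp[grp["phylum"] == NEMATODE_PHYLUM]
        nem_reads = int(nem["count"].sum())
        if total > 0 and len(nem):
            fracs = nem["count"] / total
            top = fracs.idxmax()
            counted = fracs[(fracs > minor_floor) | (fracs.index == top)].sum()
        else:
            counted = 0.0
        pass_reads = nem_reads > min_reads
        pass_frac = counted > min_nem_frac
        reasons = []
        if not pass_reads:
            reasons.append("nematode reads")
        if not pass_frac:
            reasons.append("nematode fraction")
        records.append((sample, total, nem_reads, float(counted),
                        pass_reads, pass_frac, pass_reads and pass_frac,
                        ";".join(reasons)))
    report = pd.DataFrame(records, columns=[
        "sample_id", "total_reads", "nematode_reads", "nematode_frac",
        "pass_reads", "pass_frac", "passed", "reasons",
    ])
    retained = sorted(report.loc[report["passed"], "sample_id"])
    return retained, report


def pcr_success_rate(n_poor: int, n_total: int) -> float:
    """Percentage of reactions with visible product, to one decimal
    (half-away-from-zero)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_poor <= n_total:
        raise ValueError("n_poor must lie in [0, n_total]")
    return round_half_up(n_total - n_poor, n_total, scale=100)
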