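"""Six-way temporal classification from the two DE contrasts.

Contrast A is exposure vs untreated (Ni-E vs UT), contrast B is
post-exposure vs untreated (Ni-W vs UT).  A gene is "up" in a contrast
when its fold change is at least ``fold_threshold`` and the BH-adjusted p
is below ``alpha``; "reverted to basal levels" is operationalized as
not significant in contrast B.  Genes significant in opposite directions
across the two contrasts get their own "discordant" label rather than
being silently binned.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .core import ALL_LABELS
from .errors import ValidationError

__all__ = ["call_de_status", "classify_temporal", "category_summary", "summarize_counts"]

#: (status in Ni-E vs UT, status in Ni-W vs UT) -> temporal category.
RULE_TABLE: dict[tuple[str, str], str] = {
    ("up", "ns"): "TU",
    ("down", "ns"): "TD",
    ("up", "up"): "PU-A",
    ("ns", "up"): "PU-B",
    ("down", "down"): "PD-A",
    ("ns", "down"): "PD-B",
    ("ns", "ns"): "none",
    ("up", "down"): "discordant",
    ("down", "up"): "discordant",
}


def _status(table: pd.DataFrame, fold_threshold: float, alpha: float) -> pd.Series:
    lfc_cut = math.log2(fold_threshold)
    lfc = table["log2fc"].to_numpy(float)
    sig = table["padj"].to_numpy(float) < alpha
    out = np.where(sig & (lfc >= lfc_cut), "up", np.where(sig & (lfc <= -lfc_cut), "down", "ns"))
    return pd.Series(out, index=table["gene_id"].to_numpy())


def call_de_status(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    fold_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene 3-valued status (up/down/ns) in each contrast.

    Both tables must cover the same gene universe.
    """
    if not fold_threshold > 1:
        raise ValidationError("fold_threshold must be > 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    genes_a = set(de_a["gene_id"])
    genes_b = set(de_b["gene_id"])
    if genes_a != genes_b:
        only_a = sorted(genes_a - genes_b)[:5]
        only_b = sorted(genes_b - genes_a)[:5]
        raise ValidationError(
            f"gene universes differ between contrasts (only in A: {only_a}, only in B: {only_b})"
        )
    sa = _status(de_a, fold_threshold, alpha)
    sb = _status(de_b, fold_threshold, alpha).reindex(sa.index)
    return pd.DataFrame({"gene_id": sa.index, "status_A": sa.to_numpy(), "status_B": sb.to_numpy()})


def classify_temporal(status: pd.DataFrame) -> pd.DataFrame:
    """Map each (status_A, status_B) pair through the 9-cell rule table."""
    cats = [RULE_TABLE[(a, b)] for a, b in zip(status["status_A"], status["status_B"])]
    return pd.DataFrame({"gene_id": status["gene_id"].to_numpy(), "category": cats})


def _pct(num: int, den: int) -> float | None:
    """Percentage rounded half-up to one decimal; None for a 0 denominator."""
    if den == 0:
        return None
    q = (Decimal(num) * 100 / Decimal(den)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


def summarize_counts(counts: dict[str, int]) -> dict:
    """Totals and shares from per-category gene counts.

    Shares are quoted relative to their group (PU-A and PU-B over all PU,
    PD-A and PD-B over all PD); the post-exposure share is the fraction of
    persistently changed genes whose change appeared only after exposure
    ended, (PU-B + PD-B) / (PU + PD).
    """
    c = {label: int(counts.get(label, 0)) for label in ALL_LABELS}
    pu = c["PU-A"] + c["PU-B"]
    pd_total = c["PD-A"] + c["PD-B"]
    persistent = pu + pd_total
    return {
        "counts": c,
        "pu_total": pu,
        "pd_total": pd_total,
        "persistent_total": persistent,
        "pu_a_share_pct": _pct(c["PU-A"], pu),
        "pu_b_share_pct": _pct(c["PU-B"], pu),
        "pd_a_share_pct": _pct(c["PD-A"], pd_total),
        "pd_b_share_pct": _pct(c["PD-B"], pd_total),
        "post_exposure_share_pct": _pct(c["PU-B"] + c["PD-B"], persistent),
    }


def category_summary(assignments: pd.DataFrame | pd.Series) -> dict:
    """Summary of a per-gene assignment table (``gene_id, category``)."""
    if isinstance(assignments, pd.DataFrame):
        series = assignments["category"]
    else:
        series = assignments
    if len(series) == 0:
        raise ValidationError("assignments are empty")
    bad = set(series.unique()) - set(ALL_LABELS)
    if bad:
        raise ValidationError(f"unknown category labels: {sorted(bad)}")
    return summarize_counts(series.value_counts().to_dict())
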