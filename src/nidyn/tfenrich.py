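"""Transcription-factor enrichment on a DNase-hypersensitive-site catalog.

The candidate cis-regulatory universe is a set of union DNase I
hypersensitive sites (UDHS).  Each TF gets a binary profile over the UDHS
(1 iff any of its ChIP peaks overlaps the site by >= 1 bp, half-open
coordinates).  For a query gene set, the foreground is the UDHS
overlapping the set's promoter windows and the background is the rest of
the all-genes promoter UDHS universe; each TF is scored with a one-sided
(enrichment) Fisher's exact test on the 2x2 bound/unbound x
foreground/background table and ranked by -log10 p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import DEFAULT_FLANK, validate_annotation
from .errors import ValidationError

__all__ = [
    "build_binary_profiles",
    "map_promoters_to_udhs",
    "tf_fisher_enrichment",
    "fisher_greater_pvalues",
]


def _validate_udhs(udhs: pd.DataFrame) -> pd.DataFrame:
    for col in ("chrom", "start", "end", "udhs_id"):
        if col not in udhs.columns:
            raise ValidationError(f"UDHS catalog missing column {col!r}")
    if (udhs["start"] >= udhs["end"]).any():
        raise ValidationError("UDHS catalog has intervals with start >= end")
    if udhs["udhs_id"].duplicated().any():
        raise ValidationError("UDHS ids are not unique")
    return udhs


def _udhs_trees(udhs: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in udhs.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].astype(int), sub["end"].astype(int), sub["udhs_id"])
        )
    return trees


def build_binary_profiles(
    udhs: pd.DataFrame, peaks: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Binary TF x UDHS matrix: 1 iff any peak overlaps the site by >= 1 bp."""
    _validate_udhs(udhs)
    trees = _udhs_trees(udhs)
    ids = udhs["udhs_id"].tolist()
    col_of = {u: i for i, u in enumerate(ids)}
    mat = np.zeros((len(peaks), len(ids)), dtype=np.int8)
    for row, (tf, pk) in enumerate(peaks.items()):
        if len(pk) and (pk["start"] >= pk["end"]).any():
            raise ValidationError(f"peak set for {tf!r} has start >= end")
        for chrom, sub in pk.groupby("chrom") if len(pk) else []:
            tree = trees.get(chrom)
            if tree is None:
                continue
            for s, e in zip(sub["start"].astype(int), sub["end"].astype(int)):
                for hit in tree.overlap(s, e):
                    mat[row, col_of[hit.data]] = 1
    return pd.DataFrame(mat, index=pd.Index(peaks.keys(), name="tf_id"), columns=ids)


def map_promoters_to_udhs(
    annotation: pd.DataFrame,
    udhs: pd.DataFrame,
    gene_set,
    flank: int = DEFAULT_FLANK,
) -> set[str]:
    """UDHS ids overlapping (>= 1 bp) any promoter window of ``gene_set``."""
    validate_annotation(annotation)
    _validate_udhs(udhs)
    ann = annotation.set_index("gene_id")
    gene_set = list(gene_set)
    unknown = [g for g in gene_set if g not in ann.index]
    if unknown:
        raise ValidationError(f"genes missing from annotation: {unknown[:5]}")
    trees = _udhs_trees(udhs)
    hits: set[str] = set()
    for gene in gene_set:
        row = ann.loc[gene]
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        for hit in tree.overlap(int(row["tss"]) - flank, int(row["tss"]) + flank):
            hits.add(hit.data)
    return hits


def fisher_greater_pvalues(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Vectorized one-sided Fisher p for tables [[a, b], [c, d]].

    The one-sided (enrichment) Fisher p equals the upper hypergeometric
    tail P(X >= a) with population N = a+b+c+d, K = a+c successes and
    n = a+b draws.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if np.any((a < 0) | (b < 0) | (c < 0) | (d < 0)):
        raise ValidationError("contingency counts must be non-negative")
    total = a + b + c + d
    return np.clip(stats.hypergeom.sf(a - 1, total, a + c, a + b), 0.0, 1.0)


def tf_fisher_enrichment(
    profiles: pd.DataFrame, foreground: set[str], universe: set[str]
) -> pd.DataFrame:
    """Rank TFs by one-sided Fisher enrichment of binding in the foreground.

    ``foreground`` must be a subset of ``universe``; the background is
    ``universe - foreground`` so the 2x2 cells are disjoint.  Output rows
    are sorted by ascending p with ties broken by descending odds ratio
    then tf_id, and carry the contingency counts, the sample odds ratio,
    the score (-log10 p) and a BH-adjusted p (supplementary; the ranking
    uses the raw p).
    """
    foreground = set(foreground)
    universe = set(universe)
    if not foreground <= universe:
        raise ValidationError("foreground UDHS must be a subset of the universe")
    if len(universe - foreground) < 1:
        raise ValidationError("background (universe minus foreground) is empty")
    missing = universe - set(profiles.columns)
    if missing:
        raise ValidationError(f"universe UDHS missing from profiles: {sorted(missing)[:5]}")
    fg_cols = sorted(foreground)
    bg_cols = sorted(universe - foreground)
    fg = profiles[fg_cols].to_numpy()
    bg = profiles[bg_cols].to_numpy()
    a = fg.sum(axis=1).astype(np.int64)
    b = len(fg_cols) - a
    c = bg.sum(axis=1).astype(np.int64)
    d = len(bg_cols) - c
    p = fisher_greater_pvalues(a, b, c, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where(b * c > 0, (a * d) / (b * c), np.where(a * d > 0, np.inf, np.nan))
        score = -np.log10(p)
    from .expression import bh_adjust

    out = pd.DataFrame(
        {
            "tf_id": profiles.index.to_numpy(),
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "odds_ratio": odds,
            "pvalue": p,
            "neglog10p": score,
            "padj_bh": bh_adjust(p),
        }
    )
    out = out.sort_values(
        by=["pvalue", "odds_ratio", "tf_id"],
        ascending=[True, False, True],
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
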