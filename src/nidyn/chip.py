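"""Promoter histone-mark quantification and the chromatin dynamic score.

Signal is quantified without peak calling: reads are deduplicated (one
copy per (chrom, 5'-start, strand)), a read is assigned to a gene when its
5' position falls in the promoter window [TSS - flank, TSS + flank), and
the window count is normalized to RPKM using the window length and the
sample's genome-wide deduplicated read total.

The chromatin dynamic score for gene *i* between a treatment sample t and
a control sample c is::

    CDS_i = sqrt(RPKM_i^t / RPKM_median^t) - sqrt(RPKM_i^c / RPKM_median^c)

with the median taken over all annotated promoters in the respective
sample.  The square-root of the median-ratio makes the score symmetric
under swapping treatment and control (sign flip) and invariant to
per-sample depth rescaling.  Gene-set comparisons use one-tailed
two-sample Student t-tests (equal variance by default, Welch optional).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DEFAULT_FLANK,
    GroupTestResult,
    PromoterSignal,
    check_direction,
    validate_annotation,
)
from .errors import ValidationError

__all__ = [
    "dedup_reads",
    "promoter_signal",
    "chromatin_dynamic_score",
    "compare_cds",
    "compare_enrichment",
    "qpcr_group_test",
    "star_annotation",
]


def dedup_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Retain one copy per (chrom, start, strand); stable order."""
    if len(reads) == 0:
        return reads.copy()
    return reads.drop_duplicates(subset=["chrom", "start", "strand"], keep="first").reset_index(
        drop=True
    )


def five_prime_positions(reads: pd.DataFrame) -> np.ndarray:
    """5' position per read: start on the + strand, end-1 on the - strand."""
    return np.where(
        reads["strand"].to_numpy() == "-",
        reads["end"].to_numpy() - 1,
        reads["start"].to_numpy(),
    )


def promoter_signal(
    reads: dict[str, pd.DataFrame],
    annotation: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
) -> PromoterSignal:
    """Promoter RPKM per gene per sample from (deduplicated) reads.

    ``reads`` maps sample name -> BED6 frame.  The window is
    [TSS - flank, TSS + flank) in genomic coordinates regardless of gene
    strand; a read counts for every gene whose window contains its 5'
    position.  RPKM uses the window length (2*flank) and the sample's
    total read count as denominators; a sample with zero reads is an
    explicit error.
    """
    validate_annotation(annotation)
    if flank <= 0:
        raise ValidationError("flank must be > 0")
    genes = annotation["gene_id"].to_numpy()
    lo = (annotation["tss"] - flank).to_numpy()
    hi = (annotation["tss"] + flank).to_numpy()
    chroms = annotation["chrom"].to_numpy()
    cols = {}
    totals = {}
    for sample, df in reads.items():
        total = len(df)
        if total == 0:
            raise ValidationError(f"sample {sample!r} has zero reads")
        totals[sample] = total
        counts = np.zeros(len(genes), dtype=int)
        five = five_prime_positions(df)
        read_chroms = df["chrom"].to_numpy()
        for chrom in np.unique(chroms):
            pos = np.sort(five[read_chroms == chrom])
            mask = chroms == chrom
            counts[mask] = np.searchsorted(pos, hi[mask], side="left") - np.searchsorted(
                pos, lo[mask], side="left"
            )
        cols[sample] = counts / (2 * flank / 1e3) / (total / 1e6)
    rpkm = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    return PromoterSignal(rpkm=rpkm, totals=totals, flank=flank)


def _mean_rpkm(signal: PromoterSignal, samples: str | list[str]) -> np.ndarray:
    if isinstance(samples, str):
        samples = [samples]
    missing = [s for s in samples if s not in signal.rpkm.columns]
    if missing:
        raise ValidationError(f"unknown samples: {missing}")
    return signal.rpkm[samples].mean(axis=1).to_numpy(float)


def chromatin_dynamic_score(
    signal: PromoterSignal,
    treatment: str | list[str],
    control: str | list[str],
) -> pd.DataFrame:
    """Per-gene chromatin dynamic score for a treatment-vs-control contrast.

    Replicate samples are averaged at the RPKM level before the formula.
    The per-sample median is taken over all annotated promoters; a zero
    median is an explicit error (include background regions or filter the
    annotation first).
    """
    t = _mean_rpkm(signal, treatment)
    c = _mean_rpkm(signal, control)
    med_t = float(np.median(t))
    med_c = float(np.median(c))
    if med_t <= 0 or med_c <= 0:
        raise ValidationError(
            "median promoter RPKM is zero; the score is undefined — include more "
            "genes/background in the promoter universe or filter empty samples"
        )
    cds = np.sqrt(t / med_t) - np.sqrt(c / med_c)
    return pd.DataFrame({"gene_id": signal.rpkm.index.to_numpy(), "cds": cds})


def _one_tailed_t(
    a: np.ndarray, b: np.ndarray, direction: str, equal_var: bool = True
) -> tuple[float, float]:
    """One-tailed two-sample t; identical degenerate samples give (0, 0.5)."""
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 0.5
        higher = a.mean() > b.mean()
        return (np.inf, 0.0) if higher == (direction == "greater") else (-np.inf, 1.0)
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=direction)
    return float(res.statistic), float(res.pvalue)


def _group_test(
    values: pd.Series,
    gene_set,
    background_set,
    direction: str,
    equal_var: bool,
) -> GroupTestResult:
    check_direction(direction)
    gene_set = list(gene_set)
    background_set = list(background_set)
    if len(gene_set) < 2 or len(background_set) < 2:
        raise ValidationError("both gene set and background need at least 2 genes")
    missing = [g for g in gene_set + background_set if g not in values.index]
    if missing:
        raise ValidationError(f"genes without values: {missing[:5]}")
    a = values.loc[gene_set].to_numpy(float)
    b = values.loc[background_set].to_numpy(float)
    t, p = _one_tailed_t(a, b, direction, equal_var)
    return GroupTestResult(
        statistic=t,
        pvalue=p,
        n_set=len(a),
        n_background=len(b),
        mean_set=float(a.mean()),
        mean_background=float(b.mean()),
        direction=direction,
    )


def compare_cds(
    cds: pd.DataFrame,
    gene_set,
    background_set,
    direction: str,
    equal_var: bool = True,
) -> GroupTestResult:
    """One-tailed Student t-test of gene-set CDS against a background set."""
    values = cds.set_index("gene_id")["cds"]
    return _group_test(values, gene_set, background_set, direction, equal_var)


def compare_cds_against_zero(cds: pd.DataFrame, gene_set, direction: str) -> GroupTestResult:
    """One-sample alternative: gene-set CDS against zero (one-tailed)."""
    check_direction(direction)
    values = cds.set_index("gene_id")["cds"]
    a = values.loc[list(gene_set)].to_numpy(float)
    if len(a) < 2:
        raise ValidationError("gene set needs at least 2 genes")
    res = stats.ttest_1samp(a, 0.0, alternative=direction)
    return GroupTestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_set=len(a),
        n_background=0,
        mean_set=float(a.mean()),
        mean_background=0.0,
        direction=direction,
    )


def compare_enrichment(
    signal: PromoterSignal,
    sample: str,
    gene_set,
    background_set,
    direction: str,
    equal_var: bool = True,
) -> GroupTestResult:
    """As :func:`compare_cds`, on absolute promoter RPKM in one sample."""
    if sample not in signal.rpkm.columns:
        raise ValidationError(f"unknown sample {sample!r}")
    return _group_test(signal.rpkm[sample], gene_set, background_set, direction, equal_var)


#: Significance bands: (upper p bound, annotation), checked in order.
STAR_BANDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def star_annotation(pvalue: float) -> str:
    """Map a p-value to the conventional star annotation (else ``n.s.``)."""
    for bound, stars in STAR_BANDS:
        if pvalue < bound:
            return stars
    return "n.s."


def qpcr_group_test(
    qpcr: pd.DataFrame,
    gene: str,
    cond_a: str,
    cond_b: str,
    direction: str,
    equal_var: bool = True,
) -> GroupTestResult:
    """One-tailed t-test on fold-enrichment replicates of one gene.

    Tests ``cond_a`` vs ``cond_b`` in the stated direction and attaches
    the star annotation.
    """
    check_direction(direction)
    sub = qpcr[qpcr["gene_id"] == gene]
    if len(sub) == 0:
        raise ValidationError(f"gene {gene!r} absent from qPCR table")
    groups = {}
    for cond in (cond_a, cond_b):
        vals = sub.loc[sub["condition"] == cond, "fold_enrichment"].to_numpy(float)
        if len(vals) < 2:
            raise ValidationError(f"condition {cond!r} has < 2 replicates for gene {gene!r}")
        groups[cond] = vals
    t, p = _one_tailed_t(groups[cond_a], groups[cond_b], direction, equal_var)
    return GroupTestResult(
        statistic=t,
        pvalue=p,
        n_set=len(groups[cond_a]),
        n_background=len(groups[cond_b]),
        mean_set=float(groups[cond_a].mean()),
        mean_background=float(groups[cond_b].mean()),
        direction=direction,
        stars=star_annotation(p),
    )
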