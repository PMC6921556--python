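"""Expression quantification (RPKM), differential expression and the
heatmap normalization.

RPKM follows the classical definition::

    RPKM_gs = count_gs / (exonic_length_g / 1e3) / (library_size_s / 1e6)

with the library size taken as the raw column sum.

The built-in differential test is a per-gene negative-binomial Wald test:
counts are normalized to a common library scale, group means and variances
are estimated by moments, the NB dispersion ``alpha`` (``Var = mu +
alpha*mu**2``) is estimated per gene pooled across both groups and then
shrunk toward the across-gene median (an empirical-Bayes moderation in the
spirit of common-dispersion estimators), and the Wald statistic is referred
to a Student t with the residual degrees of freedom.  It is a stand-in with
the same contract (log2FC, p, BH-adjusted p) as a full DE package;
externally computed tables can be supplied instead via ``method="external"``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CATEGORIES, CONDITIONS, CountMatrix
from .errors import ValidationError

__all__ = [
    "compute_rpkm",
    "differential_expression",
    "bh_adjust",
    "heatmap_matrix",
]

logger = logging.getLogger(__name__)

#: Prior degrees of freedom for dispersion moderation toward the
#: across-gene median.  Chosen for calibration of the null at small
#: replicate numbers while keeping power against strong fold changes.
DISPERSION_PRIOR_DF = 10.0


def compute_rpkm(counts: CountMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    """Reads per kilobase of exonic length per million mapped reads.

    Raises a keyed :class:`ValidationError` if a counted gene lacks an
    annotation, and an explicit error for a zero library size.
    """
    ann = annotation.set_index("gene_id")
    missing = counts.gene_ids.difference(ann.index)
    if len(missing) > 0:
        raise ValidationError(f"genes missing from annotation: {list(missing[:5])}")
    lengths = ann.loc[counts.gene_ids, "exonic_length"].to_numpy(float)
    lib = counts.counts.sum(axis=0).to_numpy(float)
    if (lib == 0).any():
        zero = [s for s, tot in zip(counts.counts.columns, lib) if tot == 0]
        raise ValidationError(f"zero library size in samples: {zero}")
    rpkm = counts.counts.to_numpy(float) / (lengths[:, None] / 1e3) / (lib[None, :] / 1e6)
    return pd.DataFrame(rpkm, index=counts.gene_ids, columns=counts.counts.columns)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    counts: CountMatrix,
    treatment: str,
    control: str,
    method: str = "builtin-nb",
    external_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression for ``treatment`` vs ``control``.

    Returns a frame with columns ``gene_id, log2fc, pvalue, padj``.
    Genes with zero counts in every sample of both groups are reported
    with ``log2fc = 0`` and ``p = 1``.  ``method="external"`` validates
    and passes through a pre-computed table.
    """
    if method == "external":
        if external_table is None:
            raise ValidationError("method='external' requires external_table")
        return _validate_de_table(external_table)
    if method != "builtin-nb":
        raise ValidationError(f"unknown DE method {method!r}")

    t_samples = counts.samples_for(treatment)
    c_samples = counts.samples_for(control)
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValidationError(
            f"builtin DE needs >=2 replicates per group "
            f"(got {len(t_samples)} for {treatment!r}, {len(c_samples)} for {control!r})"
        )
    used = t_samples + c_samples
    mat = counts.counts[used].to_numpy(float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        raise ValidationError("zero library size in a DE sample")
    scale = lib / lib.mean()
    q = mat / scale[None, :]
    nt, nc = len(t_samples), len(c_samples)
    qt, qc = q[:, :nt], q[:, nt:]
    mt, mc = qt.mean(axis=1), qc.mean(axis=1)
    vt = qt.var(axis=1, ddof=1)
    vc = qc.var(axis=1, ddof=1)

    allzero = (mt == 0) & (mc == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_alpha = (vt - mt + vc - mc) / (mt**2 + mc**2)
    informative = np.isfinite(raw_alpha) & ~allzero
    alpha0 = float(np.median(raw_alpha[informative])) if informative.any() else 0.0
    alpha0 = max(alpha0, 0.0)
    resid_df = (nt - 1) + (nc - 1)
    alpha = np.where(informative, raw_alpha, alpha0)
    alpha = (DISPERSION_PRIOR_DF * alpha0 + resid_df * alpha) / (DISPERSION_PRIOR_DF + resid_df)
    alpha = np.clip(alpha, 0.0, None)

    var_mean = (mt + alpha * mt**2) / nt + (mc + alpha * mc**2) / nc
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mt - mc) / np.sqrt(var_mean)
    # Moderated-t: the dispersion prior contributes its df to the reference,
    # as in empirical-Bayes variance moderation.
    pvalue = 2.0 * stats.t.sf(np.abs(z), df=resid_df + DISPERSION_PRIOR_DF)
    pvalue[allzero] = 1.0
    log2fc = np.log2((mt + 0.5) / (mc + 0.5))
    log2fc[allzero] = 0.0
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
        }
    ).reset_index(drop=True)


def _validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    required = ("gene_id", "log2fc", "pvalue", "padj")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"external DE table missing columns: {missing}")
    for col in ("pvalue", "padj"):
        v = table[col].to_numpy(float)
        if np.any((v < 0) | (v > 1) | ~np.isfinite(v)):
            raise ValidationError(f"external DE table has {col} outside [0, 1]")
    if table["gene_id"].duplicated().any():
        raise ValidationError("external DE table has duplicate gene ids")
    return table[list(required)].copy()


def heatmap_matrix(
    expr: pd.DataFrame,
    design: dict[str, str],
    assignments: pd.Series,
    pseudocount: float = 1.0,
    category_order: tuple[str, ...] = CATEGORIES,
) -> tuple[pd.DataFrame, list[str]]:
    """Normalized display matrix: ``log2(RPKM + pseudocount)``, per-sample
    median-centered then per-gene mean-centered; within each category rows
    are ordered by decreasing variance of the per-condition mean values.

    ``assignments`` maps gene_id -> category for the genes to plot; empty
    categories are skipped with a logged warning.  Returns the reordered
    matrix and the row order.
    """
    v = np.log2(expr.to_numpy(float) + pseudocount)
    v = v - np.median(v, axis=0, keepdims=True)
    v = v - v.mean(axis=1, keepdims=True)
    norm = pd.DataFrame(v, index=expr.index, columns=expr.columns)
    cond_means = pd.DataFrame(
        {
            cond: norm[[s for s in norm.columns if design.get(s) == cond]].mean(axis=1)
            for cond in CONDITIONS
        }
    )
    variance = cond_means.var(axis=1, ddof=0)
    order: list[str] = []
    for cat in category_order:
        genes = assignments.index[assignments == cat]
        genes = [g for g in genes if g in norm.index]
        if not genes:
            logger.warning("heatmap: category %s is empty, skipped", cat)
            continue
        order.extend(variance.loc[genes].sort_values(ascending=False).index.tolist())
    return norm.loc[order], order
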