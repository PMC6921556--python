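"""Shared containers, constants and validators.

The pipeline models a three-condition exposure design: untreated cells
(``UT``), cells sampled during exposure (``Ni-E``) and cells sampled after
the termination of exposure (``Ni-W``).  Genes are classified into six
temporal categories from the two contrasts against ``UT``:

========  =====================================================
label     meaning
========  =====================================================
TU / TD   transiently up-/down-regulated (during exposure only)
PU-A      persistently upregulated starting during exposure
PU-B      upregulated only after the termination of exposure
PD-A      persistently downregulated starting during exposure
PD-B      downregulated only after the termination of exposure
========  =====================================================

Genomic coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The three experimental conditions, in design order.
CONDITIONS = ("UT", "Ni-E", "Ni-W")

#: The six temporal expression categories, in display order.
CATEGORIES = ("TU", "PU-A", "PU-B", "TD", "PD-A", "PD-B")

#: All assignable labels (the six categories plus the two fall-throughs).
ALL_LABELS = CATEGORIES + ("none", "discordant")

#: Promoter half-width in bp: promoters are [TSS - flank, TSS + flank).
DEFAULT_FLANK = 2000

ANNOTATION_COLUMNS = ("gene_id", "chrom", "tss", "strand", "exonic_length", "description")
BED6_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a gene-annotation frame and return it unchanged.

    Required columns: ``gene_id, chrom, tss, strand, exonic_length``
    (``description`` is optional).  Gene ids must be unique, TSS
    coordinates non-negative, exonic lengths >= 1 and strands in {+, -}.
    """
    required = ("gene_id", "chrom", "tss", "strand", "exonic_length")
    missing = [c for c in required if c not in annotation.columns]
    if missing:
        raise ValidationError(f"annotation is missing columns: {missing}")
    if annotation["gene_id"].duplicated().any():
        dups = annotation.loc[annotation["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"duplicate gene ids in annotation: {dups[:5]}")
    if (annotation["tss"] < 0).any():
        raise ValidationError("annotation contains negative TSS coordinates")
    if (annotation["exonic_length"] < 1).any():
        raise ValidationError("annotation contains exonic_length < 1")
    bad = set(annotation["strand"]) - {"+", "-"}
    if bad:
        raise ValidationError(f"annotation strands must be '+' or '-', got {sorted(bad)}")
    return annotation


@dataclass
class CountMatrix:
    """Integer RNA-seq counts (genes x samples) with a sample->condition design."""

    counts: pd.DataFrame  # index: gene_id, columns: sample ids, integer
    design: dict[str, str]  # sample id -> condition

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        unmapped = [s for s in self.counts.columns if s not in self.design]
        if unmapped:
            raise ValidationError(f"samples missing from design: {unmapped}")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.design[s] == condition]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index


@dataclass
class PromoterSignal:
    """Per-gene, per-sample promoter ChIP RPKM plus per-sample read totals.

    ``rpkm`` is indexed by gene_id with one column per sample; ``totals``
    holds the genome-wide deduplicated read count used as the per-million
    denominator; ``flank`` is the promoter half-width in bp.
    """

    rpkm: pd.DataFrame
    totals: dict[str, int]
    flank: int = DEFAULT_FLANK


@dataclass
class GroupTestResult:
    """A one-tailed two-sample comparison between a gene set and a background."""

    statistic: float
    pvalue: float
    n_set: int
    n_background: int
    mean_set: float
    mean_background: float
    direction: str
    stars: str = field(default="")

    def as_dict(self) -> dict:
        return {
            "t": self.statistic,
            "p": self.pvalue,
            "n_set": self.n_set,
            "n_background": self.n_background,
            "mean_set": self.mean_set,
            "mean_background": self.mean_background,
            "direction": self.direction,
            "stars": self.stars,
        }


def check_direction(direction: str) -> str:
    if direction not in ("greater", "less"):
        raise ValidationError(f"direction must be 'greater' or 'less', got {direction!r}")
    return direction
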