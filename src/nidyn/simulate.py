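"""Synthetic-data generators with planted temporal-category structure.

Every generator is a pure function of a :class:`SimulationConfig` and the
master seed it carries.  Sub-streams are derived from the master seed with
fixed labelled spawn keys, so adding a generator never perturbs the draws
of another.

The planted structure mirrors the biology the pipeline is built to detect:

* RNA-seq counts are negative binomial (``Var = mu + alpha * mu**2``) under
  a three-condition design (UT, Ni-E, Ni-W); each planted gene's condition
  means are scaled by ``fold_change`` according to its temporal category
  (e.g. a PU-B gene is elevated in Ni-W only).
* Promoter H3K4me3 ChIP reads are 50-bp single-end reads whose expected
  promoter pileup follows per-category multipliers: genes induced only
  after exposure ends (PU-B) gain promoter signal in Ni-W, genes silenced
  after exposure ends (PD-B) lose it, transiently induced genes (TU) start
  from an elevated baseline that decays after washout, and the remaining
  categories stay flat.
* The toy DNase-hypersensitivity catalog places one UDHS per promoter plus
  intergenic distractors; "target" TFs overlap planted-category promoter
  UDHS at a high rate and everything else at a low rate, null TFs bind at
  one uniform rate.
* qPCR tables emulate H3K27me3 fold enrichment over IgG, with persistently
  upregulated genes losing the mark after washout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CATEGORIES, CONDITIONS, DEFAULT_FLANK, CountMatrix
from .errors import SizingError, ValidationError

__all__ = [
    "SimulationConfig",
    "DEFAULT_CHIP_LEVELS",
    "make_genome_annotation",
    "simulate_counts",
    "simulate_chip_reads",
    "simulate_tf_catalog",
    "simulate_qpcr",
]

#: Fixed labelled spawn keys for seed sub-streams (never renumber).
_STREAMS = {"annotation": 0, "counts": 1, "chip": 2, "tf": 3, "qpcr": 4}

#: Relative promoter H3K4me3 intensity per category and condition.
#: Encodes the narratives the pipeline must recover: loss after washout for
#: TU and PD-B, gain after washout for PU-B, flat (high) for the open-
#: chromatin PU-A / PD-A promoters, flat for TD and unplanted genes.
DEFAULT_CHIP_LEVELS: dict[str, dict[str, float]] = {
    "TU": {"UT": 4.0, "Ni-E": 4.0, "Ni-W": 1.0},
    "TD": {"UT": 2.0, "Ni-E": 2.0, "Ni-W": 2.0},
    "PU-A": {"UT": 4.0, "Ni-E": 4.0, "Ni-W": 4.0},
    "PU-B": {"UT": 1.0, "Ni-E": 1.0, "Ni-W": 4.0},
    "PD-A": {"UT": 4.0, "Ni-E": 4.0, "Ni-W": 4.0},
    "PD-B": {"UT": 4.0, "Ni-E": 4.0, "Ni-W": 1.0},
    "none": {"UT": 1.0, "Ni-E": 1.0, "Ni-W": 1.0},
}

#: H3K27me3 qPCR fold-enrichment (over IgG) true means per category.
#: Persistently upregulated promoters lose the repressive mark after
#: washout; the other categories are flat.
DEFAULT_QPCR_LEVELS: dict[str, dict[str, float]] = {
    "PU-A": {"UT": 4.0, "Ni-W": 1.0},
    "PU-B": {"UT": 4.0, "Ni-W": 1.0},
    "PD-A": {"UT": 2.0, "Ni-W": 2.0},
    "PD-B": {"UT": 2.0, "Ni-W": 2.0},
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study design the pipeline targets: two
    biological replicates per condition, 50-bp single-end ChIP reads, a
    single chromosome sized so that 4-kb promoter windows tile without
    overlap.
    """

    n_genes: int = 1000
    genome_length: int = 5_000_000
    chrom: str = "chrS"
    n_per_category: dict[str, int] = field(
        default_factory=lambda: {c: 20 for c in CATEGORIES}
    )
    baseline_mean: float = 100.0
    nb_dispersion: float = 0.05
    fold_change: float = 4.0
    library_size: int | None = None  # None -> emergent (n_genes * baseline_mean)
    n_replicates: int = 2
    seed: int = 0
    flank: int = DEFAULT_FLANK
    promoter_gap: int = 100  # bp between adjacent promoter windows
    read_length: int = 50
    chip_reads_per_sample: int = 200_000
    chip_background_fraction: float = 0.3
    chip_levels: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CHIP_LEVELS.items()}
    )
    # TF catalog
    n_target_tfs: int = 1
    n_null_tfs: int = 20
    tf_f_fg: float = 0.8
    tf_f_bg: float = 0.1
    tf_null_rate: float = 0.2
    tf_target_categories: tuple[str, ...] | None = None  # None -> all planted
    n_distractor_udhs: int = 0
    udhs_halfwidth: int = 300
    # qPCR
    qpcr_n_replicates: int = 3
    qpcr_noise_sd: float = 0.1  # sigma of the multiplicative log-normal noise
    qpcr_genes_per_category: int = 3
    qpcr_levels: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_QPCR_LEVELS.items()}
    )

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.genome_length < 1:
            raise ValidationError("genome_length must be >= 1")
        if self.baseline_mean <= 0:
            raise ValidationError("baseline_mean must be > 0")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        if self.fold_change < 1:
            raise ValidationError("fold_change must be >= 1")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.qpcr_n_replicates < 2:
            raise ValidationError("qpcr_n_replicates must be >= 2")
        unknown = set(self.n_per_category) - set(CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown categories in n_per_category: {sorted(unknown)}")
        if any(v < 0 for v in self.n_per_category.values()):
            raise ValidationError("n_per_category counts must be >= 0")
        if sum(self.n_per_category.values()) > self.n_genes:
            raise ValidationError("sum of category counts exceeds n_genes")
        if not 0 <= self.chip_background_fraction < 1:
            raise ValidationError("chip_background_fraction must be in [0, 1)")
        for rate in (self.tf_f_fg, self.tf_f_bg, self.tf_null_rate):
            if not 0 <= rate <= 1:
                raise ValidationError("TF overlap rates must be in [0, 1]")
        if self.qpcr_noise_sd < 0:
            raise ValidationError("qpcr_noise_sd must be >= 0")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(config: SimulationConfig, stream: str, *extra: int) -> np.random.Generator:
    key = (_STREAMS[stream],) + tuple(extra)
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


# ---------------------------------------------------------------------------
# annotation


def make_genome_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Lay out ``n_genes`` genes with non-overlapping promoter windows.

    TSSs are placed on a regular grid with ``2*flank`` windows separated by
    ``promoter_gap`` bp, so that promoter-signal attribution is unambiguous.
    Strands are drawn uniformly and exonic lengths log-normally (median
    ~1.5 kb), both deterministically from the master seed.

    Raises
    ------
    SizingError
        If the genome cannot hold all windows.
    """
    step = 2 * config.flank + config.promoter_gap
    required = config.n_genes * step
    if required > config.genome_length:
        raise SizingError(
            f"genome_length={config.genome_length} too short for {config.n_genes} "
            f"promoter windows of {2 * config.flank} bp plus {config.promoter_gap} bp "
            f"gaps (needs >= {required} bp)"
        )
    rng = _rng(config, "annotation")
    idx = np.arange(config.n_genes)
    tss = config.flank + idx * step
    strand = rng.choice(np.array(["+", "-"]), size=config.n_genes)
    lengths = np.exp(rng.normal(math.log(1500.0), 0.5, size=config.n_genes))
    lengths = np.clip(np.round(lengths), 200, 20000).astype(int)
    width = len(str(config.n_genes))
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:0{width}d}" for i in idx],
            "chrom": config.chrom,
            "tss": tss,
            "strand": strand,
            "exonic_length": lengths,
            "description": "synthetic",
        }
    )


# ---------------------------------------------------------------------------
# counts + truth


def _category_fold_signs(category: str) -> tuple[int, int]:
    """(sign in Ni-E vs UT, sign in Ni-W vs UT) for a planted category."""
    return {
        "TU": (1, 0),
        "TD": (-1, 0),
        "PU-A": (1, 1),
        "PU-B": (0, 1),
        "PD-A": (-1, -1),
        "PD-B": (0, -1),
        "none": (0, 0),
    }[category]


def build_truth_table(annotation: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Assign planted categories to genes and tabulate the ground truth.

    Category membership is a seeded random draw over genes; the table
    records the planted per-contrast log2 fold changes and the per-condition
    promoter ChIP intensity multipliers used by the read generator.
    """
    rng = _rng(config, "counts")
    n = len(annotation)
    labels = np.array(["none"] * n, dtype=object)
    order = rng.permutation(n)
    pos = 0
    for cat in CATEGORIES:
        k = config.n_per_category.get(cat, 0)
        labels[order[pos : pos + k]] = cat
        pos += k
    lfc = math.log2(config.fold_change)
    rows = []
    for gene, cat in zip(annotation["gene_id"], labels):
        sa, sb = _category_fold_signs(cat)
        levels = config.chip_levels[cat]
        rows.append(
            {
                "gene_id": gene,
                "category": cat,
                "planted_log2fc_A": sa * lfc,
                "planted_log2fc_B": sb * lfc,
                "chip_UT": levels["UT"],
                "chip_Ni-E": levels["Ni-E"],
                "chip_Ni-W": levels["Ni-W"],
            }
        )
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion alpha.

    ``Var = mu + alpha * mu**2``; alpha == 0 degenerates to Poisson.
    """
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def condition_means(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Expected count per gene per condition implied by the planted truth."""
    base = config.baseline_mean
    if config.library_size is not None:
        base = base * config.library_size / (config.n_genes * config.baseline_mean)
    means = pd.DataFrame(
        base, index=truth["gene_id"], columns=list(CONDITIONS), dtype=float
    )
    means["Ni-E"] *= np.exp2(truth["planted_log2fc_A"].to_numpy())
    means["Ni-W"] *= np.exp2(truth["planted_log2fc_B"].to_numpy())
    return means


def simulate_counts(
    annotation: pd.DataFrame, config: SimulationConfig
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw the three-condition count matrix and its truth table.

    Samples are named ``<condition>_r<k>``.  Counts are NB(mean, alpha)
    with condition means scaled by the planted fold change per category.
    """
    truth = build_truth_table(annotation, config)
    means = condition_means(truth, config)
    rng = _rng(config, "counts", 1)
    cols = {}
    design = {}
    for cond in CONDITIONS:
        mu = means[cond].to_numpy()
        for r in range(1, config.n_replicates + 1):
            name = f"{cond}_r{r}"
            cols[name] = _nb_draw(rng, mu, config.nb_dispersion)
            design[name] = cond
    counts = pd.DataFrame(cols, index=pd.Index(annotation["gene_id"], name="gene_id"))
    return CountMatrix(counts=counts, design=design), truth


# ---------------------------------------------------------------------------
# ChIP reads


def _reads_from_five_prime(
    chrom: str,
    five: np.ndarray,
    strand: np.ndarray,
    read_length: int,
    genome_length: int,
    name_prefix: str,
) -> pd.DataFrame:
    """Build BED6 records from 5' positions; reads are clipped at bounds."""
    plus = strand == "+"
    start = np.where(plus, five, five - (read_length - 1))
    end = np.where(plus, five + read_length, five + 1)
    start = np.clip(start, 0, None)
    end = np.clip(end, None, genome_length)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start.astype(int),
            "end": end.astype(int),
            "name": [f"{name_prefix}{i}" for i in range(len(five))],
            "score": 0,
            "strand": strand,
        }
    )


def simulate_chip_reads(
    annotation: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    mark: str = "H3K4me3",
) -> dict[str, pd.DataFrame]:
    """Simulate one ChIP sample (BED6 reads) per condition for ``mark``.

    Per gene, promoter reads are Poisson with mean
    ``lambda0 * multiplier`` where ``lambda0`` is a condition-independent
    per-gene base rate, so expected promoter count ratios between
    conditions equal the planted multiplier ratios exactly.  5' positions
    are uniform in the promoter window; a uniform genome-wide background
    accounts for ``chip_background_fraction`` of the target depth.
    """
    if mark != "H3K4me3":
        raise ValidationError(f"unsupported mark {mark!r}")
    last_end = int(annotation["tss"].max()) + config.flank
    if last_end > config.genome_length:
        raise SizingError("promoter window extends past the chromosome end")
    tss = annotation["tss"].to_numpy()
    # Condition-independent base rate so expected promoter count ratios
    # between conditions equal the planted multiplier ratios exactly; the
    # average multiplier over genes x conditions normalizes the grand total
    # to ~chip_reads_per_sample.
    mult_all = truth[[f"chip_{c}" for c in CONDITIONS]].to_numpy(float)
    lam0 = (
        config.chip_reads_per_sample
        * (1 - config.chip_background_fraction)
        / (len(annotation) * mult_all.mean())
    )
    out: dict[str, pd.DataFrame] = {}
    for ci, cond in enumerate(CONDITIONS):
        rng = _rng(config, "chip", ci)
        mult = truth[f"chip_{cond}"].to_numpy(float)
        counts = rng.poisson(lam0 * mult)
        lo = np.repeat(tss - config.flank, counts)
        five = lo + rng.integers(0, 2 * config.flank, size=lo.size)
        n_bg = rng.poisson(config.chip_background_fraction * config.chip_reads_per_sample)
        five_bg = rng.integers(0, config.genome_length, size=n_bg)
        five_all = np.concatenate([five, five_bg])
        strand = rng.choice(np.array(["+", "-"]), size=five_all.size)
        out[cond] = _reads_from_five_prime(
            config.chrom, five_all, strand, config.read_length, config.genome_length,
            name_prefix=f"{cond}.",
        )
    return out


# ---------------------------------------------------------------------------
# TF catalog


def simulate_tf_catalog(
    annotation: pd.DataFrame, truth: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Build a toy UDHS catalog and per-TF peak sets.

    One UDHS is centered on every promoter; ``n_distractor_udhs`` extra
    intergenic sites are tiled beyond the gene region.  Target TFs overlap
    planted-category promoter UDHS with probability ``tf_f_fg`` and all
    other UDHS with ``tf_f_bg``; null TFs overlap everything at
    ``tf_null_rate``.
    """
    if config.n_target_tfs < 1 or config.n_null_tfs < 1:
        raise ValidationError("need at least one target TF and one null TF")
    rng = _rng(config, "tf")
    half = config.udhs_halfwidth
    starts = (annotation["tss"] - half).to_numpy()
    ends = (annotation["tss"] + half).to_numpy()
    chroms = annotation["chrom"].tolist()
    gene_region_end = int(annotation["tss"].max()) + config.flank
    d_width = 2 * half
    d_step = d_width + 100
    d_starts = gene_region_end + 1000 + np.arange(config.n_distractor_udhs) * d_step
    if config.n_distractor_udhs and d_starts[-1] + d_width > config.genome_length:
        raise SizingError("genome too short for the requested distractor UDHS")
    udhs = pd.DataFrame(
        {
            "chrom": chroms + [config.chrom] * config.n_distractor_udhs,
            "start": np.concatenate([starts, d_starts]).astype(int),
            "end": np.concatenate([ends, d_starts + d_width]).astype(int),
            "udhs_id": [f"u{i:05d}" for i in range(len(annotation) + config.n_distractor_udhs)],
        }
    )
    targets = config.tf_target_categories
    if targets is None:
        targets = tuple(c for c in CATEGORIES if config.n_per_category.get(c, 0) > 0)
    planted = set(truth.loc[truth["category"].isin(targets), "gene_id"])
    is_fg = np.array(
        [gid in planted for gid in annotation["gene_id"]] + [False] * config.n_distractor_udhs
    )
    peaks: dict[str, pd.DataFrame] = {}

    def _peakset(mask: np.ndarray, prefix: str) -> pd.DataFrame:
        sub = udhs.loc[mask]
        return pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "start": sub["start"].to_numpy(),
                "end": sub["end"].to_numpy(),
                "name": [f"{prefix}{i}" for i in range(int(mask.sum()))],
                "score": 0,
                "strand": ".",
            }
        )

    for t in range(1, config.n_target_tfs + 1):
        rate = np.where(is_fg, config.tf_f_fg, config.tf_f_bg)
        bound = rng.random(len(udhs)) < rate
        peaks[f"TF_target{t}"] = _peakset(bound, f"pt{t}.")
    for t in range(1, config.n_null_tfs + 1):
        bound = rng.random(len(udhs)) < config.tf_null_rate
        peaks[f"TF_null{t:02d}"] = _peakset(bound, f"pn{t}.")
    return udhs, peaks


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Simulate H3K27me3 ChIP-qPCR fold enrichment over IgG.

    For each profiled category a seeded sample of candidate genes gets
    ``qpcr_n_replicates`` replicate values per condition; replicates are
    the true mean times log-normal noise ``exp(sd * z)`` so that ``sd=0``
    reproduces the mean exactly.
    """
    rng = _rng(config, "qpcr")
    rows = []
    for cat, levels in config.qpcr_levels.items():
        genes = truth.loc[truth["category"] == cat, "gene_id"].to_numpy()
        if genes.size == 0:
            continue
        k = min(config.qpcr_genes_per_category, genes.size)
        chosen = rng.choice(genes, size=k, replace=False)
        for gene in chosen:
            for cond, mean in levels.items():
                noise = rng.normal(0.0, 1.0, size=config.qpcr_n_replicates)
                values = mean * np.exp(config.qpcr_noise_sd * noise)
                for r, v in enumerate(values, start=1):
                    rows.append(
                        {
                            "gene_id": gene,
                            "condition": cond,
                            "replicate": r,
                            "fold_enrichment": float(v),
                        }
                    )
    return pd.DataFrame(rows)
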