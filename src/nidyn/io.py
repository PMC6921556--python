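"""Readers and writers for the interchange formats.

All tables are TSV with a header row; reads and peaks are BED6 with
0-based half-open coordinates (the annotation TSS column is 0-based too).
Readers validate schemas and raise :class:`ParseError` with the offending
line number; writers always emit headers, so read(write(x)) == x.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .core import ANNOTATION_COLUMNS, BED6_COLUMNS, CountMatrix, validate_annotation
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


# -- BED ---------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """Read a BED6 file; comment/track/browser lines are skipped (counted)."""
    rows = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                skipped += 1
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"expected >= 6 BED fields, got {len(fields)}", str(path), lineno
                )
            chrom, start, end, name, score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError("non-integer BED coordinates", str(path), lineno) from None
            if start_i >= end_i:
                raise ParseError(f"start >= end ({start_i} >= {end_i})", str(path), lineno)
            if start_i < 0:
                raise ParseError("negative start coordinate", str(path), lineno)
            rows.append((chrom, start_i, end_i, name, score, strand))
    if skipped:
        logger.info("read_bed(%s): skipped %d comment/track lines", path, skipped)
    return pd.DataFrame(rows, columns=list(BED6_COLUMNS))


def write_bed(reads: pd.DataFrame, path) -> None:
    reads[list(BED6_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)


# -- annotation --------------------------------------------------------------


def read_annotation(path) -> pd.DataFrame:
    df = _read_tsv(path, required=("gene_id", "chrom", "tss", "strand", "exonic_length"))
    if "description" not in df.columns:
        df["description"] = ""
    return validate_annotation(df[list(ANNOTATION_COLUMNS)])


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def write_annotation_gtf(annotation: pd.DataFrame, path) -> None:
    """Gene-feature-only GTF export (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for row in annotation.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}";'
            fh.write(
                f"{row.chrom}\tnidyn\tgene\t{row.tss + 1}\t{row.tss + 1}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


# -- generic TSV -------------------------------------------------------------


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # malformed file
        raise ParseError(f"cannot parse TSV: {exc}", str(path)) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", str(path), line=1)
    return df


# -- counts + design ---------------------------------------------------------


def write_counts(counts: CountMatrix, counts_path, design_path) -> None:
    counts.counts.to_csv(counts_path, sep="\t", index=True, index_label="gene_id")
    pd.DataFrame(
        {"sample": list(counts.design), "condition": list(counts.design.values())}
    ).to_csv(design_path, sep="\t", index=False)


def read_counts(counts_path, design_path) -> CountMatrix:
    df = _read_tsv(counts_path, required=("gene_id",))
    df = df.set_index("gene_id")
    design_df = _read_tsv(design_path, required=("sample", "condition"))
    design = dict(zip(design_df["sample"], design_df["condition"]))
    try:
        df = df.astype(int)
    except ValueError as exc:
        raise ParseError(f"non-integer counts: {exc}", str(counts_path)) from exc
    return CountMatrix(counts=df, design=design)


# -- DE / assignment / signal tables ----------------------------------------


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_de_table(path) -> pd.DataFrame:
    from .expression import _validate_de_table

    df = _read_tsv(path, required=("gene_id", "log2fc", "pvalue", "padj"))
    try:
        return _validate_de_table(df)
    except ValidationError as exc:
        raise ParseError(str(exc), str(path)) from exc


def read_assignments(path) -> pd.DataFrame:
    return _read_tsv(path, required=("gene_id", "category"))


def read_qpcr(path) -> pd.DataFrame:
    df = _read_tsv(path, required=("gene_id", "condition", "replicate", "fold_enrichment"))
    if (df["fold_enrichment"] <= 0).any():
        raise ParseError("fold_enrichment must be > 0", str(path))
    return df


def read_udhs(path) -> pd.DataFrame:
    """UDHS catalog from BED (name column becomes the udhs_id)."""
    bed = read_bed(path)
    udhs = bed.rename(columns={"name": "udhs_id"})[["chrom", "start", "end", "udhs_id"]]
    if udhs["udhs_id"].duplicated().any():
        raise ParseError("duplicate UDHS ids", str(path))
    return udhs


def write_udhs(udhs: pd.DataFrame, path) -> None:
    out = udhs.copy()
    out["score"] = 0
    out["strand"] = "."
    out = out.rename(columns={"udhs_id": "name"})
    write_bed(out, path)


def read_peak_dir(directory) -> dict[str, pd.DataFrame]:
    """Load every ``*.bed`` in a directory as one TF peak set (stem = tf id)."""
    directory = Path(directory)
    peaks = {}
    for bed in sorted(directory.glob("*.bed")):
        peaks[bed.stem] = read_bed(bed)
    if not peaks:
        raise ValidationError(f"no .bed peak files found in {directory}")
    return peaks
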