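"""Readers and writers for every on-disk format the pipeline touches.

All coordinates held in memory are 0-based half-open.  Files keep their
native conventions: cytosine reports and GFF3 are 1-based inclusive, BED is
0-based half-open.  Every conversion between the two happens in this module
and nowhere else.

The canonical cytosine-report dialect is the Bismark-style "CX report":
``chrom  pos(1-based)  strand  count_methylated  count_unmethylated
context  trinucleotide`` with context tokens ``CG``/``CpG``, ``CHG`` and
``CHH``.  Other column orders can be read by passing an explicit column
mapping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_CONTEXTS = ("CpG", "CHG", "CHH")

#: context-token spellings accepted on input, normalised to VALID_CONTEXTS
_CONTEXT_ALIASES = {
    "CG": "CpG",
    "CPG": "CpG",
    "CpG": "CpG",
    "CHG": "CHG",
    "CHH": "CHH",
}

#: default (Bismark CX) column order of a cytosine report
REPORT_COLUMNS = (
    "chrom",
    "pos",
    "strand",
    "n_meth",
    "n_unmeth",
    "context",
    "trinucleotide",
)


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass(frozen=True)
class CytosineReportRecord:
    """One reference cytosine as read from a per-cytosine report.

    ``pos`` is 0-based (already converted from the file's 1-based column).
    """

    chrom: str
    pos: int
    strand: str
    count_methylated: int
    count_unmethylated: int
    context: str
    trinucleotide: str | None = None

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated


@dataclass(frozen=True)
class GeneModel:
    """A gene's transcript span, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(
                f"gene {self.gene_id}: tx_start {self.tx_start} >= tx_end {self.tx_end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


def read_cytosine_report(
    path: str | Path,
    min_coverage: int = 1,
    columns: Sequence[str] = REPORT_COLUMNS,
) -> pd.DataFrame:
    """Read a per-cytosine methylation report into a data frame.

    Parameters
    ----------
    path:
        Tab-separated file; ``#``-prefixed lines are ignored.
    min_coverage:
        Sites with ``n_meth + n_unmeth < min_coverage`` are dropped.
    columns:
        Names assigned to the file's columns, in file order.  Must contain
        the six mandatory names of :data:`REPORT_COLUMNS`; extra names are
        kept as passthrough columns.  Use this to read methratio-style
        layouts.

    Returns
    -------
    DataFrame with columns ``chrom, pos, strand, n_meth, n_unmeth, context,
    trinucleotide``, ``pos`` 0-based, sorted by (chrom, pos).
    """
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    missing = set(REPORT_COLUMNS[:6]) - set(columns)
    if missing:
        raise ValueError(f"column mapping lacks required names: {sorted(missing)}")

    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=list(columns),
            usecols=range(len(columns)),
            dtype={"chrom": str, "strand": str, "context": str, "trinucleotide": str},
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: malformed cytosine report: {exc}") from exc

    if "trinucleotide" not in df.columns:
        df["trinucleotide"] = None

    for col in ("pos", "n_meth", "n_unmeth"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(f"{path}: line {line}: non-integer value in column '{col}'")
        df[col] = converted.astype(int)

    for col, low in (("pos", 1), ("n_meth", 0), ("n_unmeth", 0)):
        bad = df[col] < low
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(f"{path}: line {line}: column '{col}' below {low}")

    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(bad_strand.idxmax()) + 1
        raise ParseError(f"{path}: line {line}: strand must be '+' or '-'")

    normalised = df["context"].map(_CONTEXT_ALIASES)
    bad_ctx = normalised.isna()
    if bad_ctx.any():
        line = int(bad_ctx.idxmax()) + 1
        token = df["context"].iloc[int(bad_ctx.idxmax())]
        raise ParseError(f"{path}: line {line}: unknown context token {token!r}")
    df["context"] = normalised

    df["pos"] = df["pos"] - 1  # file 1-based -> internal 0-based

    chrom_sorted = df["chrom"].is_monotonic_increasing
    pos_sorted = df.groupby("chrom", sort=False)["pos"].is_monotonic_increasing.all()
    if not (chrom_sorted and pos_sorted):
        logger.info("%s: input not (chrom, pos) sorted; sorting", path)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    keep = (df["n_meth"] + df["n_unmeth"]) >= min_coverage
    df = df.loc[keep].reset_index(drop=True)
    return df[list(REPORT_COLUMNS)]


def report_records(df: pd.DataFrame) -> list[CytosineReportRecord]:
    """Materialise report rows as :class:`CytosineReportRecord` objects."""
    return [
        CytosineReportRecord(
            chrom=row.chrom,
            pos=int(row.pos),
            strand=row.strand,
            count_methylated=int(row.n_meth),
            count_unmethylated=int(row.n_unmeth),
            context=row.context,
            trinucleotide=None if pd.isna(row.trinucleotide) else row.trinucleotide,
        )
        for row in df.itertuples(index=False)
    ]


def write_cytosine_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write a report data frame back to the canonical on-disk dialect.

    Inverse of :func:`read_cytosine_report`: positions are re-emitted
    1-based, contexts as ``CpG``/``CHG``/``CHH``.
    """
    out = df.copy()
    out["pos"] = out["pos"] + 1
    out["trinucleotide"] = out["trinucleotide"].fillna(".")
    out[list(REPORT_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def read_gene_models(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 or BED (first six columns used).

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    If a GFF3 file has no ``gene`` features, transcript features (``mRNA``,
    ``transcript``) are aggregated per parent gene using the union span.
    A missing strand or a duplicated gene id is an error.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "bed" if suffix == ".bed" else "gff3"
    if format == "gff3":
        genes = _read_gff3_genes(path)
    elif format == "bed":
        genes = _read_bed_genes(path)
    else:
        raise ValueError(f"unknown gene-model format {format!r}")

    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ParseError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def _read_gff3_genes(path: Path) -> list[GeneModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises plain ValueError on dup IDs
        raise ParseError(f"{path}: cannot parse GFF3: {exc}") from exc

    genes = list(db.features_of_type("gene"))
    models: list[GeneModel] = []
    if genes:
        for feat in genes:
            if feat.strand not in ("+", "-"):
                raise ParseError(f"{path}: gene {feat.id}: missing strand")
            models.append(
                GeneModel(
                    gene_id=feat.id,
                    chrom=feat.seqid,
                    strand=feat.strand,
                    tx_start=feat.start - 1,  # GFF3 1-based incl -> 0-based
                    tx_end=feat.end,
                )
            )
        return models

    # no gene features: union transcripts per parent gene id
    spans: dict[str, list] = {}
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent", [feat.id])
            for parent in parents:
                spans.setdefault(parent, []).append(feat)
    for gene_id, feats in spans.items():
        strands = {f.strand for f in feats}
        if strands - {"+", "-"} or len(strands) != 1:
            raise ParseError(f"{path}: gene {gene_id}: missing or conflicting strand")
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feats[0].seqid,
                strand=strands.pop(),
                tx_start=min(f.start for f in feats) - 1,
                tx_end=max(f.end for f in feats),
            )
        )
    return models


def _read_bed_genes(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: BED gene models need >= 6 columns "
                    "(strand required)"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: missing strand")
            models.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=int(start),
                    tx_end=int(end),
                )
            )
    return models


# ---------------------------------------------------------------------------
# DMR BED
# ---------------------------------------------------------------------------

DMR_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\tcontext\tlevel_A\tlevel_B"
    "\tfold_change\tp_value"
)

_SCORE_CAP = 1000.0


def _bed_score(p_value: float) -> float:
    if p_value <= 0.0:
        return _SCORE_CAP
    return min(_SCORE_CAP, -math.log10(p_value))


def write_dmr_bed(dmrs: Iterable, path: str | Path) -> None:
    """Write DMRs as BED6+ (0-based half-open).

    name = direction (hyper/hypo), score = -log10(P) capped at 1000, extra
    columns: context, pooled level in each group, fold change and raw P.
    """
    with open(path, "w") as fh:
        fh.write(DMR_BED_HEADER + "\n")
        for d in dmrs:
            fh.write(
                "\t".join(
                    (
                        d.chrom,
                        str(d.start),
                        str(d.end),
                        d.direction,
                        f"{_bed_score(d.p_value):g}",
                        ".",
                        d.context,
                        f"{d.level_a:.6g}",
                        f"{d.level_b:.6g}",
                        f"{d.fold_change:.6g}",
                        f"{d.p_value:.6g}",
                    )
                )
                + "\n"
            )


def read_dmr_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6+ DMR file written by :func:`write_dmr_bed`."""
    names = [
        "chrom",
        "start",
        "end",
        "direction",
        "score",
        "strand",
        "context",
        "level_a",
        "level_b",
        "fold_change",
        "p_value",
    ]
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=names, dtype={"chrom": str}
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names)
    return df


# ---------------------------------------------------------------------------
# DMG / expression tables
# ---------------------------------------------------------------------------

DMG_COLUMNS = ("gene_id", "region_class", "direction", "n_supporting_dmrs", "dmr_ids")


def write_dmg_table(records: Iterable, path: str | Path) -> None:
    """Write DMR-associated gene records as TSV."""
    rows = [
        {
            "gene_id": r.gene_id,
            "region_class": r.region_class,
            "direction": r.direction,
            "n_supporting_dmrs": len(r.supporting_dmrs),
            "dmr_ids": ",".join(r.supporting_dmrs),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(DMG_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_dmg_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "dmr_ids": str})
    missing = set(DMG_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: DMG table lacks columns {sorted(missing)}")
    return df
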