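"""Cross-generation and cross-omics integration.

Builds shared DMR-associated gene (DMG) sets between two methylome
comparisons (e.g. sperm and embryo), filters differential-expression and
differential-protein tables by fold change and adjusted significance, and
assembles a per-gene direction-concordance table across the three layers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import pandas as pd

from .annotate import DmgRecord

DEG_FC_THRESHOLD = 2.0
DEG_Q_THRESHOLD = 0.001
DEP_FC_THRESHOLD = 1.3
DEP_ALPHA = 0.05


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fold_change: float
    q_value: float
    direction: str  # up | down


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    fold_change: float
    adj_p: float
    direction: str
    gene_id: str | None = None


@dataclass(frozen=True)
class ConcordanceRow:
    gene_id: str
    sperm_meth: str  # up | down | mixed | none
    embryo_meth: str
    mrna: str
    protein: str = "none"
    region_notes: str = ""


class SharedSets(NamedTuple):
    shared: set[str]
    only_a: set[str]
    only_b: set[str]


def _direction_from_fc(fold_change: float, fc_threshold: float) -> str | None:
    if fold_change >= fc_threshold:
        return "up"
    if fold_change <= 1.0 / fc_threshold:
        return "down"
    return None


def _load_table(table, required: Sequence[str]) -> pd.DataFrame:
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table, sep="\t")
    missing = set(required) - set(table.columns)
    if missing:
        raise ValueError(f"table lacks required columns {sorted(missing)}")
    return table


def filter_degs(
    table,
    fc_threshold: float = DEG_FC_THRESHOLD,
    q_threshold: float = DEG_Q_THRESHOLD,
    log2: bool = False,
) -> list[ExpressionRecord]:
    """Keep genes passing both the fold-change and Q-value thresholds.

    ``fold_change`` is treated/control; a value <= 1/fc_threshold is a
    down-regulated gene.  Set ``log2=True`` if the column holds log2 fold
    changes.
    """
    df = _load_table(table, ["gene_id", "fold_change", "q_value"])
    fc = df["fold_change"].astype(float)
    if log2:
        fc = 2.0 ** fc
    if (fc <= 0).any():
        raise ValueError("fold_change must be positive")
    out = []
    for gene_id, f, q in zip(df["gene_id"], fc, df["q_value"].astype(float)):
        if q > q_threshold:
            continue
        direction = _direction_from_fc(f, fc_threshold)
        if direction is None:
            continue
        out.append(ExpressionRecord(str(gene_id), float(f), float(q), direction))
    return out


def filter_deps(
    table,
    fc_threshold: float = DEP_FC_THRESHOLD,
    alpha: float = DEP_ALPHA,
    protein_gene_map=None,
    log2: bool = False,
) -> tuple[list[ProteinRecord], list[str]]:
    """Keep proteins passing |fold change| and adjusted-P thresholds.

    ``protein_gene_map`` is an optional TSV/frame with columns
    ``protein_id, gene_id``.  Returns (significant records, protein ids
    that could not be mapped to a gene) — unmapped proteins are reported,
    never silently dropped.
    """
    df = _load_table(table, ["protein_id", "fold_change", "adj_p"])
    fc = df["fold_change"].astype(float)
    if log2:
        fc = 2.0 ** fc
    if (fc <= 0).any():
        raise ValueError("fold_change must be positive")

    mapping: dict[str, str] = {}
    if protein_gene_map is not None:
        mdf = _load_table(protein_gene_map, ["protein_id", "gene_id"])
        mapping = dict(zip(mdf["protein_id"].astype(str), mdf["gene_id"].astype(str)))
    elif "gene_id" in df.columns:
        mapping = dict(zip(df["protein_id"].astype(str), df["gene_id"].astype(str)))

    records, unmapped = [], []
    for protein_id, f, p in zip(df["protein_id"], fc, df["adj_p"].astype(float)):
        if p > alpha:
            continue
        direction = _direction_from_fc(f, fc_threshold)
        if direction is None:
            continue
        protein_id = str(protein_id)
        gene_id = mapping.get(protein_id)
        if gene_id is None:
            unmapped.append(protein_id)
        records.append(ProteinRecord(protein_id, float(f), float(p), direction, gene_id))
    return records, unmapped


def shared_dmgs(set_a: set[str], set_b: set[str]) -> SharedSets:
    """Partition two DMG sets of the same stratum for a Venn summary."""
    return SharedSets(set_a & set_b, set_a - set_b, set_b - set_a)


def venn_summary(
    records_a: Iterable[DmgRecord],
    records_b: Iterable[DmgRecord],
    label_a: str = "sperm",
    label_b: str = "embryo",
) -> pd.DataFrame:
    """Shared/unique DMG counts for every (region class, direction) stratum."""
    from .annotate import dmg_sets

    records_a, records_b = list(records_a), list(records_b)
    rows = []
    for region_class in ("gene_body", "promoter"):
        for direction in ("hyper", "hypo"):
            parts = shared_dmgs(
                dmg_sets(records_a, region_class, direction),
                dmg_sets(records_b, region_class, direction),
            )
            rows.append(
                {
                    "region_class": region_class,
                    "direction": direction,
                    f"only_{label_a}": len(parts.only_a),
                    "shared": len(parts.shared),
                    f"only_{label_b}": len(parts.only_b),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# concordance table
# ---------------------------------------------------------------------------


def _gene_meth_direction(
    records: Iterable[DmgRecord],
) -> dict[str, tuple[str, str]]:
    """Per gene: (up/down/mixed, region note).

    gene_body records take precedence; promoter-only genes fall back to
    their promoter direction with a region note.  A layer where the gene
    carries both hyper and hypo records is 'mixed'.
    """
    by_gene: dict[str, dict[str, set[str]]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, {}).setdefault(r.region_class, set()).add(
            r.direction
        )
    out = {}
    for gene_id, classes in by_gene.items():
        if "gene_body" in classes:
            directions, note_class = classes["gene_body"], "gene_body"
        else:
            directions, note_class = classes["promoter"], "promoter"
        if len(directions) > 1:
            out[gene_id] = ("mixed", note_class)
            continue
        direction = "up" if directions == {"hyper"} else "down"
        meth_word = "hyper" if direction == "up" else "hypo"
        out[gene_id] = (direction, f"{note_class} {meth_word}")
    return out


@dataclass
class ConcordanceResult:
    rows: list[ConcordanceRow]
    mixed: list[ConcordanceRow]

    def to_frame(self) -> pd.DataFrame:
        cols = ["gene_id", "sperm_meth", "embryo_meth", "mrna", "protein", "region_notes"]
        return pd.DataFrame(
            [
                {c: getattr(r, c) for c in cols}
                for r in self.rows
            ],
            columns=cols,
        )


def concordance_table(
    sperm_dmgs: Iterable[DmgRecord],
    embryo_dmgs: Iterable[DmgRecord],
    degs: Iterable[ExpressionRecord],
    deps: Iterable[ProteinRecord] | None = None,
    loose: bool = False,
) -> ConcordanceResult:
    """Per-gene direction concordance across methylation and expression.

    Strict mode keeps exactly the genes present in all of: sperm DMGs,
    embryo DMGs and DEGs.  Loose mode keeps genes present in any two of the
    three layers.  Genes whose methylation carries both directions in one
    layer are returned separately as ``mixed``.
    """
    sperm_dir = _gene_meth_direction(sperm_dmgs)
    embryo_dir = _gene_meth_direction(embryo_dmgs)
    deg_dir = {r.gene_id: r.direction for r in degs}
    dep_dir: dict[str, str] = {}
    if deps is not None:
        for r in deps:
            if r.gene_id is not None:
                dep_dir[r.gene_id] = r.direction

    layers = (set(sperm_dir), set(embryo_dir), set(deg_dir))
    if loose:
        genes = {
            g
            for g in set().union(*layers)
            if sum(g in layer for layer in layers) >= 2
        }
    else:
        genes = layers[0] & layers[1] & layers[2]

    rows, mixed = [], []
    for gene_id in sorted(genes):
        sperm = sperm_dir.get(gene_id, ("none", ""))
        embryo = embryo_dir.get(gene_id, ("none", ""))
        notes = []
        if sperm[1]:
            notes.append(f"sperm {sperm[1]}")
        if embryo[1]:
            notes.append(f"embryo {embryo[1]}")
        row = ConcordanceRow(
            gene_id=gene_id,
            sperm_meth=sperm[0],
            embryo_meth=embryo[0],
            mrna=deg_dir.get(gene_id, "none"),
            protein=dep_dir.get(gene_id, "none"),
            region_notes="; ".join(notes),
        )
        if "mixed" in (row.sperm_meth, row.embryo_meth):
            mixed.append(row)
        else:
            rows.append(row)
    return ConcordanceResult(rows=rows, mixed=mixed)


def write_concordance(result: ConcordanceResult, path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)


def dmg_records_from_table(df: pd.DataFrame) -> list[DmgRecord]:
    """Rebuild DmgRecord objects from a DMG TSV frame."""
    out = []
    for row in df.itertuples(index=False):
        dmr_ids = [] if pd.isna(row.dmr_ids) or row.dmr_ids == "" else str(row.dmr_ids).split(",")
        out.append(
            DmgRecord(
                gene_id=str(row.gene_id),
                region_class=row.region_class,
                direction=row.direction,
                supporting_dmrs=dmr_ids,
            )
        )
    return out
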