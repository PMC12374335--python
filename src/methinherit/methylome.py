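"""Per-site and global methylation arithmetic.

A methylation level is the mC/C ratio of a reference cytosine: methylated
reads over total reads covering it.  Contexts are CpG, CHG and CHH
(H = A, C or T), read in 5'->3' orientation of the cytosine's strand.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .io_formats import REPORT_COLUMNS, VALID_CONTEXTS

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ContextUndeterminedError(ValueError):
    """Sequence context cannot be resolved (chromosome edge or ambiguous base)."""


@dataclass(frozen=True)
class CytosineSite:
    """One reference cytosine with its read counts (0-based position)."""

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_meth <= self.n_total:
            raise ValueError(f"invalid counts {self.n_meth}/{self.n_total}")

    @property
    def level(self) -> float:
        """mC/C ratio; only defined for covered sites."""
        if self.n_total == 0:
            raise ValueError("level undefined for an uncovered site")
        return self.n_meth / self.n_total


@dataclass(frozen=True)
class ContextSummary:
    context: str
    n_sites_covered: int
    pooled_level: float | None  # sum(n_meth) / sum(n_total)
    mean_site_level: float | None  # mean of per-site levels

    @property
    def defined(self) -> bool:
        return self.n_sites_covered > 0


class MethylomeSample:
    """A named collection of cytosine sites for one condition/generation.

    Sites are stored as a data frame (columns ``chrom, pos, strand, context,
    n_meth, n_total``) sorted by (chrom, pos); ``sites()`` yields them as
    :class:`CytosineSite` objects.
    """

    def __init__(self, sample_id: str, group: str, df: pd.DataFrame):
        required = {"chrom", "pos", "strand", "context", "n_meth", "n_total"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"site frame lacks columns {sorted(missing)}")
        df = df[["chrom", "pos", "strand", "context", "n_meth", "n_total"]]
        self.sample_id = sample_id
        self.group = group
        self.df = (
            df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        )

    @classmethod
    def from_report(
        cls, report: pd.DataFrame, sample_id: str, group: str
    ) -> "MethylomeSample":
        """Build a sample from an :mod:`io_formats` cytosine-report frame."""
        df = report[["chrom", "pos", "strand", "context"]].copy()
        df["n_meth"] = report["n_meth"]
        df["n_total"] = report["n_meth"] + report["n_unmeth"]
        return cls(sample_id, group, df)

    @classmethod
    def from_sites(
        cls, sites: Iterable[CytosineSite], sample_id: str, group: str
    ) -> "MethylomeSample":
        rows = [
            (s.chrom, s.pos, s.strand, s.context, s.n_meth, s.n_total) for s in sites
        ]
        df = pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
        )
        return cls(sample_id, group, df)

    def sites(self) -> Iterator[CytosineSite]:
        for row in self.df.itertuples(index=False):
            yield CytosineSite(
                chrom=row.chrom,
                pos=int(row.pos),
                strand=row.strand,
                context=row.context,
                n_meth=int(row.n_meth),
                n_total=int(row.n_total),
            )

    def __len__(self) -> int:
        return len(self.df)

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Slice a chromosome from a dict of strings or a pyfaidx.Fasta."""
    seq = reference[chrom][max(start, 0) : end]
    return str(seq).upper()


def classify_context(
    reference,
    chrom: str,
    pos: int,
    strand: str,
    end_policy: str = "error",
) -> str:
    """Classify the sequence context of a position on one strand.

    Returns ``"CpG"``, ``"CHG"``, ``"CHH"`` or ``"not_cytosine"``.  The base
    at ``pos`` is read in the strand's 5'->3' orientation (reverse
    complement for ``-``) together with the two following bases.

    When the context cannot be determined because the required following
    bases run off the chromosome end, a
    :class:`ContextUndeterminedError` is raised unless
    ``end_policy="truncate_as_CHH"``, in which case a non-CpG site at the
    edge is reported as CHH.  An ambiguous (N) base always raises.
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    if end_policy not in ("error", "truncate_as_CHH"):
        raise ValueError(f"unknown end_policy {end_policy!r}")

    chrom_len = len(reference[chrom])
    if not 0 <= pos < chrom_len:
        raise IndexError(f"{chrom}:{pos} outside chromosome of length {chrom_len}")

    if strand == "+":
        window = _fetch(reference, chrom, pos, pos + 3)
    else:
        window = _fetch(reference, chrom, pos - 2, pos + 1)[::-1].translate(_COMPLEMENT)

    base = window[0]
    if base != "C":
        return "not_cytosine"
    nxt = window[1] if len(window) > 1 else None
    nxt2 = window[2] if len(window) > 2 else None

    if nxt == "G":
        return "CpG"
    if nxt is None or nxt == "N":
        if end_policy == "truncate_as_CHH" and nxt is None:
            return "CHH"
        raise ContextUndeterminedError(f"{chrom}:{pos}{strand}: next base unresolved")
    # nxt is H
    if nxt2 == "G":
        return "CHG"
    if nxt2 is None or nxt2 == "N":
        if end_policy == "truncate_as_CHH" and nxt2 is None:
            return "CHH"
        raise ContextUndeterminedError(
            f"{chrom}:{pos}{strand}: second following base unresolved"
        )
    return "CHH"


# ---------------------------------------------------------------------------
# strand merging and summaries
# ---------------------------------------------------------------------------


def merge_cpg_strands(sample: MethylomeSample) -> MethylomeSample:
    """Collapse complementary CpG site pairs to single sites.

    A ``+`` CpG at p and a ``-`` CpG at p+1 become one site at p (strand
    ``+``) with summed counts; unpaired CpG sites and all CHG/CHH sites are
    untouched.  Total methylated and total reads are conserved.
    """
    df = sample.df
    cpg = df[df["context"] == "CpG"]
    other = df[df["context"] != "CpG"]
    plus = cpg[cpg["strand"] == "+"]
    minus = cpg[cpg["strand"] == "-"].copy()
    minus["partner_pos"] = minus["pos"] - 1

    merged = plus.merge(
        minus[["chrom", "partner_pos", "n_meth", "n_total"]],
        left_on=["chrom", "pos"],
        right_on=["chrom", "partner_pos"],
        how="left",
        suffixes=("", "_minus"),
    )
    merged["n_meth"] = merged["n_meth"] + merged["n_meth_minus"].fillna(0).astype(int)
    merged["n_total"] = (
        merged["n_total"] + merged["n_total_minus"].fillna(0).astype(int)
    )
    merged = merged[["chrom", "pos", "strand", "context", "n_meth", "n_total"]]

    anti = minus.merge(
        plus[["chrom", "pos"]].rename(columns={"pos": "partner_pos"}),
        on=["chrom", "partner_pos"],
        how="left",
        indicator=True,
    )
    unpaired_minus = anti.loc[
        anti["_merge"] == "left_only",
        ["chrom", "pos", "strand", "context", "n_meth", "n_total"],
    ]

    out = pd.concat([merged, unpaired_minus, other], ignore_index=True)
    return MethylomeSample(sample.sample_id, sample.group, out)


def context_summaries(sample: MethylomeSample) -> list[ContextSummary]:
    """Pooled and mean-of-site levels for each context.

    pooled_level = sum(n_meth)/sum(n_total) over covered sites of the
    context; mean_site_level averages per-site mC/C ratios.  A context with
    no covered sites yields an undefined (None-level) summary.
    """
    df = sample.df[sample.df["n_total"] > 0]
    out = []
    for context in VALID_CONTEXTS:
        sub = df[df["context"] == context]
        if len(sub) == 0:
            out.append(ContextSummary(context, 0, None, None))
            continue
        pooled = float(sub["n_meth"].sum() / sub["n_total"].sum())
        mean_site = float((sub["n_meth"] / sub["n_total"]).mean())
        out.append(ContextSummary(context, len(sub), pooled, mean_site))
    return out


def conversion_rate(sample: MethylomeSample, control_chroms: set[str]) -> float:
    """Bisulfite conversion rate from designated unmethylated control contigs.

    Returns ``1 - sum(n_meth)/sum(n_total)`` over all covered sites (all
    contexts) on the control chromosomes.
    """
    sub = sample.df[sample.df["chrom"].isin(control_chroms)]
    total = int(sub["n_total"].sum())
    if total == 0:
        raise ValueError(
            f"no covered sites on control chromosomes {sorted(control_chroms)}"
        )
    return 1.0 - float(sub["n_meth"].sum()) / total


def write_sample_summary(
    sample: MethylomeSample,
    path,
    control_chroms: set[str] | None = None,
) -> pd.DataFrame:
    """Emit the per-sample summary TSV (context, covered sites, levels,
    optional conversion rate) and return it as a frame."""
    rows = []
    for s in context_summaries(sample):
        rows.append(
            {
                "sample_id": sample.sample_id,
                "context": s.context,
                "n_sites_covered": s.n_sites_covered,
                "pooled_level": "" if s.pooled_level is None else f"{s.pooled_level:.6g}",
                "mean_site_level": (
                    "" if s.mean_site_level is None else f"{s.mean_site_level:.6g}"
                ),
            }
        )
    df = pd.DataFrame(rows)
    if control_chroms:
        df["conversion_rate"] = f"{conversion_rate(sample, control_chroms):.6g}"
    df.to_csv(path, sep="\t", index=False)
    return df
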