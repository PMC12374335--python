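"""Map DMRs onto gene bodies and promoters to derive DMR-associated genes.

The gene body is the full transcript span; the promoter is a fixed-size
interval at the transcription start site (upstream-only by default, 1 kb).
Overlap is >= 1 bp on half-open intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .io_formats import GeneModel

logger = logging.getLogger(__name__)

DEFAULT_PROMOTER_SIZE = 1000

RegionClass = Literal["gene_body", "promoter"]


@dataclass(frozen=True)
class PromoterInterval:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class DmgRecord:
    """A (gene, region class, direction) methylation association supported
    by one or more overlapping DMRs."""

    gene_id: str
    region_class: str
    direction: str
    supporting_dmrs: list[str] = field(default_factory=list)


def promoter_interval(
    gene: GeneModel,
    promoter_size: int = DEFAULT_PROMOTER_SIZE,
    mode: Literal["upstream", "both"] = "upstream",
    chrom_size: int | None = None,
) -> PromoterInterval:
    """Promoter interval at the gene's TSS, clipped to the chromosome.

    upstream mode: ``+`` strand -> [tx_start - size, tx_start);
    ``-`` strand -> [tx_end, tx_end + size).  both mode extends
    ``promoter_size`` on each side of the TSS.
    """
    if promoter_size <= 0:
        raise ValueError("promoter_size must be > 0")
    if mode not in ("upstream", "both"):
        raise ValueError(f"unknown promoter mode {mode!r}")
    tss = gene.tx_start if gene.strand == "+" else gene.tx_end
    if mode == "upstream":
        if gene.strand == "+":
            start, end = tss - promoter_size, tss
        else:
            start, end = tss, tss + promoter_size
    else:
        start, end = tss - promoter_size, tss + promoter_size
    start = max(start, 0)
    if chrom_size is not None:
        end = min(end, chrom_size)
    end = max(end, start)
    return PromoterInterval(gene.gene_id, gene.chrom, start, end, gene.strand)


class _IntervalIndex:
    """Per-chromosome interval lookup: sorted starts with a running maximum
    of ends, queried by binary search."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]]):
        # (chrom, start, end, payload)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        buckets: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, payload in intervals:
            buckets.setdefault(chrom, []).append((start, end, payload))
        for chrom, items in buckets.items():
            items.sort()
            starts = np.array([i[0] for i in items], dtype=np.int64)
            ends = np.array([i[1] for i in items], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, [i[2] for i in items])

    def overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """Payloads of intervals overlapping [start, end) by >= 1 bp."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, payloads = entry
        hi = int(np.searchsorted(starts, end, side="left"))  # starts < end
        if hi == 0:
            return []
        hits = np.flatnonzero(ends[:hi] > start)
        return [payloads[i] for i in hits]

    def chroms(self) -> set[str]:
        return set(self._by_chrom)


def assign_dmrs_to_genes(
    dmrs: Sequence,
    genes: Sequence[GeneModel],
    promoter_size: int = DEFAULT_PROMOTER_SIZE,
    mode: Literal["upstream", "both"] = "upstream",
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[DmgRecord]:
    """Assign each DMR to the gene bodies and promoters it overlaps.

    Yields one record per (gene, region_class, direction), de-duplicated
    with supporting DMR ids accumulated.  DMRs on chromosomes absent from
    the gene set trigger a warning and stay unassigned.
    """
    body_index = _IntervalIndex(
        (g.chrom, g.tx_start, g.tx_end, g.gene_id) for g in genes
    )
    promoters = [
        promoter_interval(
            g, promoter_size, mode,
            None if chrom_sizes is None else chrom_sizes.get(g.chrom),
        )
        for g in genes
    ]
    prom_index = _IntervalIndex(
        (p.chrom, p.start, p.end, p.gene_id) for p in promoters if p.end > p.start
    )
    known_chroms = body_index.chroms() | prom_index.chroms()

    records: dict[tuple[str, str, str], DmgRecord] = {}
    for d in dmrs:
        dmr_id = getattr(d, "dmr_id", None) or f"{d.chrom}:{d.start}-{d.end}:{d.context}"
        if d.chrom not in known_chroms:
            logger.warning("DMR %s on unknown chromosome; unassigned", dmr_id)
            continue
        for region_class, index in (("gene_body", body_index), ("promoter", prom_index)):
            for gene_id in index.overlapping(d.chrom, d.start, d.end):
                key = (gene_id, region_class, d.direction)
                rec = records.setdefault(
                    key, DmgRecord(gene_id, region_class, d.direction)
                )
                if dmr_id not in rec.supporting_dmrs:
                    rec.supporting_dmrs.append(dmr_id)
    return sorted(
        records.values(), key=lambda r: (r.gene_id, r.region_class, r.direction)
    )


def dmg_sets(
    records: Iterable[DmgRecord], region_class: str, direction: str
) -> set[str]:
    """Gene ids in one (region class, direction) stratum."""
    return {
        r.gene_id
        for r in records
        if r.region_class == region_class and r.direction == direction
    }
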