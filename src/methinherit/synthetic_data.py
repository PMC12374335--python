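"""Synthetic bisulfite-methylome generator.

Produces a complete, self-consistent test dataset: a random reference
genome with gene models and an unmethylated control contig, paired
fresh/stored methylomes with planted differential windows, an embryo
generation inheriting a configurable fraction of those windows, and
coupled differential-expression / differential-protein tables.  The ground
truth is emitted alongside the data so any caller can be scored without
re-reading it.

Counts follow a beta-binomial observation model: per-site methylation
probability drawn from Beta with mean = true level and overdispersion
``rho`` (rho = 0 degenerates to exact binomial), coverage Poisson, and an
optional bisulfite conversion-failure rate adding false methylated calls
on unmethylated molecules.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotate, io_formats
from .dmr import Dmr
from .io_formats import GeneModel

DEFAULT_BASELINE_LEVELS = {"CpG": 0.93, "CHG": 0.014, "CHH": 0.04}

_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


@dataclass
class GenomeConfig:
    n_chroms: int = 2
    chrom_length: int = 500_000
    gc_fraction: float = 0.42
    control_length: int = 20_000
    control_chrom: str = "ctrl"


@dataclass
class DegCouplingConfig:
    n_degs: int = 40
    p_coupled_to_dmr: float = 0.5
    fc_range: tuple[float, float] = (2.5, 6.0)
    #: direction of expression change implied by a methylation change
    concordance_rule: Mapping[str, str] = field(
        default_factory=lambda: {
            "gene_body hyper": "up",
            "gene_body hypo": "down",
            "promoter hyper": "down",
            "promoter hypo": "up",
        }
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    n_genes: int = 100
    baseline_levels: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_LEVELS)
    )
    coverage_mean: float = 30.0
    dispersion: float = 0.05  # beta-binomial rho
    conversion_failure: float = 0.005
    n_planted_hyper: int = 50
    n_planted_hypo: int = 50
    planted_width: int = 1000
    min_cg_per_dmr: int = 5  # CG dinucleotides => 2x sites per strand pair
    hyper_levels: tuple[float, float] = (0.2, 0.8)  # (fresh, stored)
    hypo_levels: tuple[float, float] = (0.93, 0.25)
    #: fraction of planted DMRs biased onto gene/promoter-overlapping windows
    #: (keeps the DMG -> DEG coupling pool populated)
    gene_bias: float = 0.7
    inheritance_fraction: float = 0.6
    deg_coupling: DegCouplingConfig = field(default_factory=DegCouplingConfig)

    def __post_init__(self) -> None:
        for name, value in (
            ("gc_fraction", self.genome.gc_fraction),
            ("dispersion", self.dispersion),
            ("conversion_failure", self.conversion_failure),
            ("inheritance_fraction", self.inheritance_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dispersion >= 1.0:
            raise ValueError("dispersion must be < 1")
        for level in self.baseline_levels.values():
            if not 0.0 <= level <= 1.0:
                raise ValueError("baseline levels must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        raw = dict(raw)
        if "genome" in raw:
            raw["genome"] = GenomeConfig(**raw["genome"])
        if "deg_coupling" in raw:
            raw["deg_coupling"] = DegCouplingConfig(**raw["deg_coupling"])
        for key in ("hyper_levels", "hypo_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["deg_coupling"]["concordance_rule"] = dict(
            self.deg_coupling.concordance_rule
        )
        return d


@dataclass(frozen=True)
class PlantedDmr:
    """A planted differential window (truth)."""

    chrom: str
    start: int
    end: int
    context: str
    level_a: float  # fresh
    level_b: float  # stored

    @property
    def direction(self) -> str:
        return "hyper" if self.level_b > self.level_a else "hypo"

    @property
    def dmr_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.context}"


@dataclass
class Reference:
    sequences: dict[str, str]
    genes: list[GeneModel]
    control_chrom: str

    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


@dataclass
class SimulationTruth:
    config: SimulationConfig
    sperm_dmrs: list[PlantedDmr]
    embryo_dmrs: list[PlantedDmr]  # inherited subset
    degs: list[dict]
    deps: list[dict]

    def to_json(self) -> str:
        payload = {
            "config": self.config.to_dict(),
            "baseline_levels": dict(self.config.baseline_levels),
            "control_chrom": self.config.genome.control_chrom,
            "sperm_dmrs": [
                {**dataclasses.asdict(d), "direction": d.direction}
                for d in self.sperm_dmrs
            ],
            "embryo_dmrs": [
                {**dataclasses.asdict(d), "direction": d.direction}
                for d in self.embryo_dmrs
            ],
            "inherited_dmr_ids": [d.dmr_id for d in self.embryo_dmrs],
            "degs": self.degs,
            "deps": self.deps,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Reference:
    """Random genome at the requested GC with non-overlapping gene models
    and one unmethylated control contig (present in FASTA, not in GFF3)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = config.genome
    gc = g.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    alphabet = np.frombuffer(b"ACGT", dtype="S1")

    sequences: dict[str, str] = {}
    for i in range(g.n_chroms):
        bases = rng.choice(alphabet, size=g.chrom_length, p=probs)
        sequences[f"chr{i + 1}"] = bases.tobytes().decode()
    bases = rng.choice(alphabet, size=g.control_length, p=probs)
    sequences[g.control_chrom] = bases.tobytes().decode()

    genes = _place_genes(config, rng)
    return Reference(sequences=sequences, genes=genes, control_chrom=g.control_chrom)


def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    g = config.genome
    per_chrom = [config.n_genes // g.n_chroms] * g.n_chroms
    for i in range(config.n_genes % g.n_chroms):
        per_chrom[i] += 1

    genes: list[GeneModel] = []
    idx = 0
    gap = 2500  # leaves room for a 1-kb promoter between neighbours
    for c, count in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        if count == 0:
            continue
        lengths = rng.integers(2000, 8001, size=count)
        need = int(lengths.sum()) + gap * (count + 1)
        if need > g.chrom_length:
            raise ValueError(
                f"cannot place {count} genes on {chrom}: need {need} bp, "
                f"have {g.chrom_length}"
            )
        slack = g.chrom_length - need
        extra = np.sort(rng.integers(0, slack + 1, size=count))
        cursor = gap
        prev_extra = 0
        for j in range(count):
            cursor += int(extra[j]) - prev_extra
            prev_extra = int(extra[j])
            start = cursor
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{idx:04d}", chrom, strand, start, end))
            idx += 1
            cursor = end + gap
    return genes


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    (
                        g.chrom,
                        "methinherit_sim",
                        "gene",
                        str(g.tx_start + 1),  # 0-based half-open -> GFF3 1-based
                        str(g.tx_end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


def plant_dmrs(
    reference: Reference,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[PlantedDmr]:
    """Choose non-overlapping window-aligned regions with enough CpG
    dinucleotides, assigning hyper/hypo level pairs."""
    width = config.planted_width
    candidates: list[tuple[str, int, int]] = []
    for chrom, seq in reference.sequences.items():
        if chrom == reference.control_chrom:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        cg_cum = np.concatenate([[0], np.cumsum(is_cg)])
        for start in range(0, len(seq) - width + 1, width):
            n_cg = int(cg_cum[min(start + width, len(is_cg))] - cg_cum[start])
            if n_cg >= config.min_cg_per_dmr:
                candidates.append((chrom, start, start + width))

    n_total = config.n_planted_hyper + config.n_planted_hypo
    if n_total > len(candidates):
        raise ValueError(
            f"cannot plant {n_total} DMRs: only {len(candidates)} windows have "
            f">= {config.min_cg_per_dmr} CpG dinucleotides"
        )

    # bias a fraction of the planted windows onto gene/promoter territory so
    # downstream DMG/DEG coupling has genes to draw from
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    pad = annotate.DEFAULT_PROMOTER_SIZE
    for g in reference.genes:
        gene_spans.setdefault(g.chrom, []).append((g.tx_start - pad, g.tx_end + pad))

    def in_gene(c: tuple[str, int, int]) -> bool:
        return any(
            c[1] < end and start < c[2] for start, end in gene_spans.get(c[0], [])
        )

    genic = [i for i, c in enumerate(candidates) if in_gene(c)]
    intergenic = [i for i in range(len(candidates)) if i not in set(genic)]
    n_genic = min(len(genic), int(round(config.gene_bias * n_total)))
    chosen = [int(genic[j]) for j in rng.choice(len(genic), size=n_genic, replace=False)] if n_genic else []
    n_rest = n_total - n_genic
    pool_rest = intergenic if len(intergenic) >= n_rest else sorted(
        set(range(len(candidates))) - set(chosen)
    )
    chosen += [
        int(pool_rest[j]) for j in rng.choice(len(pool_rest), size=n_rest, replace=False)
    ]
    planted = []
    for rank, i in enumerate(sorted(chosen)):
        chrom, start, end = candidates[i]
        levels = (
            config.hyper_levels if rank < config.n_planted_hyper else config.hypo_levels
        )
        planted.append(PlantedDmr(chrom, start, end, "CpG", levels[0], levels[1]))
    return planted


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------


def _enumerate_cytosines(seq: str) -> pd.DataFrame:
    """All cytosines of both strands with contexts and trinucleotides.

    Sites within 2 bp of the strand-oriented sequence end are skipped
    (context undeterminable).
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    C, G = ord("C"), ord("G")

    frames = []
    # plus strand: C at p, context from p+1, p+2
    pos = np.flatnonzero(arr[: n - 2] == C)
    if len(pos):
        nxt, nxt2 = arr[pos + 1], arr[pos + 2]
        context = np.where(
            nxt == G, "CpG", np.where(nxt2 == G, "CHG", "CHH")
        )
        tri = (
            arr[pos[:, None] + np.arange(3)].copy().view("S3").ravel().astype("U3")
        )
        frames.append(
            pd.DataFrame(
                {"pos": pos, "strand": "+", "context": context, "trinucleotide": tri}
            )
        )
    # minus strand: G at p, oriented next bases are complement(p-1), complement(p-2)
    pos = np.flatnonzero(arr[2:] == G) + 2
    if len(pos):
        prv, prv2 = arr[pos - 1], arr[pos - 2]
        context = np.where(
            prv == C, "CpG", np.where(prv2 == C, "CHG", "CHH")
        )
        tri = (
            _COMP[arr[pos[:, None] - np.arange(3)]].copy().view("S3").ravel().astype("U3")
        )
        frames.append(
            pd.DataFrame(
                {"pos": pos, "strand": "-", "context": context, "trinucleotide": tri}
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["pos", "strand", "context", "trinucleotide"]
    )
    return df.sort_values("pos", kind="mergesort").reset_index(drop=True)


def simulate_methylome(
    reference: Reference,
    config: SimulationConfig,
    condition: Literal["A", "B"],
    planted: Sequence[PlantedDmr],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw a cytosine report for one condition.

    True levels are the per-context baselines, overridden inside planted
    regions (matching context only) by the region's condition level; the
    control contig is fully unmethylated.  Returns an
    :mod:`io_formats`-style report frame (0-based positions).
    """
    reports = []
    for chrom, seq in reference.sequences.items():
        sites = _enumerate_cytosines(seq)
        level = (
            sites["context"].map(config.baseline_levels).to_numpy(dtype=float)
        )
        if chrom == reference.control_chrom:
            level[:] = 0.0
        else:
            pos = sites["pos"].to_numpy()
            ctx = sites["context"].to_numpy()
            for p in planted:
                if p.chrom != chrom:
                    continue
                target = p.level_a if condition == "A" else p.level_b
                mask = (pos >= p.start) & (pos < p.end) & (ctx == p.context)
                level[mask] = target

        n = len(sites)
        coverage = rng.poisson(config.coverage_mean, size=n)
        rho = config.dispersion
        if rho > 0:
            shape = (1.0 - rho) / rho
            p_site = np.empty(n)
            interior = (level > 0) & (level < 1)
            p_site[~interior] = level[~interior]
            if interior.any():
                p_site[interior] = rng.beta(
                    level[interior] * shape, (1.0 - level[interior]) * shape
                )
        else:
            p_site = level
        meth = rng.binomial(coverage, p_site)
        if config.conversion_failure > 0:
            meth = meth + rng.binomial(coverage - meth, config.conversion_failure)

        reports.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": sites["pos"].to_numpy(),
                    "strand": sites["strand"].to_numpy(),
                    "n_meth": meth,
                    "n_unmeth": coverage - meth,
                    "context": sites["context"].to_numpy(),
                    "trinucleotide": sites["trinucleotide"].to_numpy(),
                }
            )
        )
    return pd.concat(reports, ignore_index=True)


def simulate_inherited_embryo(
    sperm_planted: Sequence[PlantedDmr],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[PlantedDmr]:
    """Sample without replacement the floor(f * n) sperm DMRs the embryo
    inherits; the rest revert to baseline in the embryo."""
    n = len(sperm_planted)
    k = int(np.floor(config.inheritance_fraction * n))
    if k == 0:
        return []
    chosen = sorted(int(i) for i in rng.choice(n, size=k, replace=False))
    return [sperm_planted[i] for i in chosen]


# ---------------------------------------------------------------------------
# expression / protein simulation
# ---------------------------------------------------------------------------


def _planted_to_dmrs(planted: Sequence[PlantedDmr]) -> list[Dmr]:
    out = []
    for p in planted:
        out.append(
            Dmr(
                chrom=p.chrom,
                start=p.start,
                end=p.end,
                context=p.context,
                n_sites_a=0,
                n_sites_b=0,
                meth_a=0,
                unmeth_a=0,
                meth_b=0,
                unmeth_b=0,
                level_a=p.level_a,
                level_b=p.level_b,
                fold_change=float("nan"),
                p_value=0.0,
                direction=p.direction,
            )
        )
    return out


def simulate_expression(
    genes: Sequence[GeneModel],
    inherited: Sequence[PlantedDmr],
    config: SimulationConfig,
    rng: np.random.Generator,
    deg_q_threshold: float = 0.001,
    dep_fc_threshold: float = 1.3,
    dep_alpha: float = 0.05,
    all_planted: Sequence[PlantedDmr] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[dict], list[dict]]:
    """Simulate DEG and DEP tables coupled to inherited methylation.

    Returns (deg table over all genes, dep table, protein->gene map,
    planted DEG truth, planted DEP truth).  Coupled differential genes are
    drawn from genes carrying an inherited DMR with a single methylation
    direction; their expression direction follows the configured
    concordance rule.  Planted rows receive q-values below the thresholds,
    all other genes above.
    """
    cfg = config.deg_coupling
    if cfg.n_degs > len(genes):
        raise ValueError(f"n_degs {cfg.n_degs} exceeds n_genes {len(genes)}")

    records = annotate.assign_dmrs_to_genes(_planted_to_dmrs(inherited), genes)
    by_gene: dict[str, dict[str, set[str]]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, {}).setdefault(r.region_class, set()).add(
            r.direction
        )
    # directions over ALL planted DMRs (sperm side): a gene touched by
    # opposite-direction regions anywhere would come out "mixed" downstream,
    # so it is excluded from the coupling pool
    dirs_everywhere: dict[str, set[str]] = {}
    for r in annotate.assign_dmrs_to_genes(
        _planted_to_dmrs(all_planted if all_planted is not None else inherited), genes
    ):
        dirs_everywhere.setdefault(r.gene_id, set()).add(r.direction)

    coupled_pool: dict[str, str] = {}  # gene -> expression direction
    for gene_id, classes in sorted(by_gene.items()):
        if any(len(dirs) > 1 for dirs in classes.values()):
            continue  # mixed methylation: ambiguous coupling
        if len({next(iter(d)) for d in classes.values()}) > 1:
            continue
        if len(dirs_everywhere.get(gene_id, set())) > 1:
            continue
        region_class = "gene_body" if "gene_body" in classes else "promoter"
        meth_dir = next(iter(classes[region_class]))
        coupled_pool[gene_id] = cfg.concordance_rule[f"{region_class} {meth_dir}"]

    n_coupled = sum(rng.random() < cfg.p_coupled_to_dmr for _ in range(cfg.n_degs))
    if n_coupled > len(coupled_pool):
        raise ValueError(
            f"requested {n_coupled} coupled DEGs but only {len(coupled_pool)} "
            "genes carry an unambiguous inherited DMR"
        )
    pool_ids = sorted(coupled_pool)
    coupled_genes = [
        pool_ids[int(i)]
        for i in rng.choice(len(pool_ids), size=n_coupled, replace=False)
    ]
    uncoupled_candidates = sorted(
        {g.gene_id for g in genes} - set(by_gene) - set(coupled_genes)
    )
    n_uncoupled = cfg.n_degs - n_coupled
    if n_uncoupled > len(uncoupled_candidates):
        raise ValueError("not enough DMR-free genes for uncoupled DEGs")
    uncoupled_genes = [
        uncoupled_candidates[int(i)]
        for i in rng.choice(
            len(uncoupled_candidates), size=n_uncoupled, replace=False
        )
    ]

    planted_degs: list[dict] = []
    fc_lo, fc_hi = cfg.fc_range
    direction_of: dict[str, str] = {}
    for gene_id in coupled_genes:
        direction_of[gene_id] = coupled_pool[gene_id]
    for gene_id in uncoupled_genes:
        direction_of[gene_id] = "up" if rng.random() < 0.5 else "down"

    rows = []
    for g in genes:
        if g.gene_id in direction_of:
            fc = float(rng.uniform(fc_lo, fc_hi))
            if direction_of[g.gene_id] == "down":
                fc = 1.0 / fc
            q = float(rng.uniform(1e-8, deg_q_threshold * 0.5))
            planted_degs.append(
                {
                    "gene_id": g.gene_id,
                    "fold_change": fc,
                    "q_value": q,
                    "direction": direction_of[g.gene_id],
                    "coupled": g.gene_id in coupled_pool
                    and g.gene_id in set(coupled_genes),
                }
            )
        else:
            fc = float(rng.uniform(0.8, 1.25))
            q = float(rng.uniform(0.05, 1.0))
        rows.append({"gene_id": g.gene_id, "fold_change": fc, "q_value": q})
    deg_df = pd.DataFrame(rows)

    # proteins mirror the DEG construction at the protein threshold
    planted_deps: list[dict] = []
    prot_rows = []
    for g in genes:
        protein_id = f"prot_{g.gene_id}"
        if g.gene_id in direction_of:
            fc = float(rng.uniform(max(dep_fc_threshold * 1.1, 1.4), 3.0))
            if direction_of[g.gene_id] == "down":
                fc = 1.0 / fc
            p = float(rng.uniform(1e-6, dep_alpha * 0.5))
            planted_deps.append(
                {
                    "protein_id": protein_id,
                    "gene_id": g.gene_id,
                    "fold_change": fc,
                    "adj_p": p,
                    "direction": direction_of[g.gene_id],
                }
            )
        else:
            fc = float(rng.uniform(0.85, 1.15))
            p = float(rng.uniform(0.1, 1.0))
        prot_rows.append({"protein_id": protein_id, "fold_change": fc, "adj_p": p})
    dep_df = pd.DataFrame(prot_rows)
    map_df = pd.DataFrame(
        {"protein_id": [f"prot_{g.gene_id}" for g in genes],
         "gene_id": [g.gene_id for g in genes]}
    )
    return deg_df, dep_df, map_df, planted_degs, planted_deps


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> SimulationTruth:
    """Generate the full dataset under ``outdir`` and return the truth.

    Files written: ``reference.fa``, ``genes.gff3``, four cytosine reports
    (``sperm_fresh``, ``sperm_stored``, ``embryo_fresh``, ``embryo_stored``
    with suffix ``.cx.tsv``), ``degs.tsv``, ``deps.tsv``,
    ``protein_map.tsv`` and ``truth.json``.  Outputs are byte-identical for
    identical seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    reference = simulate_reference(config, rng)
    write_fasta(reference.sequences, outdir / "reference.fa")
    write_gff3(reference.genes, outdir / "genes.gff3")

    planted = plant_dmrs(reference, config, rng)
    inherited = simulate_inherited_embryo(planted, config, rng)

    for name, condition, regions in (
        ("sperm_fresh", "A", planted),
        ("sperm_stored", "B", planted),
        ("embryo_fresh", "A", inherited),
        ("embryo_stored", "B", inherited),
    ):
        report = simulate_methylome(reference, config, condition, regions, rng)
        io_formats.write_cytosine_report(report, outdir / f"{name}.cx.tsv")

    deg_df, dep_df, map_df, planted_degs, planted_deps = simulate_expression(
        reference.genes, inherited, config, rng, all_planted=planted
    )
    deg_df.to_csv(outdir / "degs.tsv", sep="\t", index=False, float_format="%.8g")
    dep_df.to_csv(outdir / "deps.tsv", sep="\t", index=False, float_format="%.8g")
    map_df.to_csv(outdir / "protein_map.tsv", sep="\t", index=False)

    truth = SimulationTruth(
        config=config,
        sperm_dmrs=planted,
        embryo_dmrs=inherited,
        degs=planted_degs,
        deps=planted_deps,
    )
    (outdir / "truth.json").write_text(truth.to_json())
    return truth
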