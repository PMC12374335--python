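import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methinherit import io_formats
from methinherit.integrate import concordance_table, filter_degs
from methinherit.methylome import MethylomeSample, context_summaries, conversion_rate
from methinherit.synthetic_data import (
    DegCouplingConfig,
    GenomeConfig,
    SimulationConfig,
    plant_dmrs,
    simulate_dataset,
    simulate_expression,
    simulate_inherited_embryo,
    simulate_methylome,
    simulate_reference,
)


def small_config(**overrides):
    defaults = dict(
        seed=11,
        genome=GenomeConfig(n_chroms=2, chrom_length=100_000, control_length=8_000),
        n_genes=16,
        n_planted_hyper=8,
        n_planted_hypo=8,
        deg_coupling=DegCouplingConfig(n_degs=6, p_coupled_to_dmr=0.5),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="module")
def reference():
    cfg = small_config()
    return cfg, simulate_reference(cfg)


class TestSimulateReference:
    def test_gene_spans_disjoint(self, reference):
        _, ref = reference
        by_chrom = {}
        for g in ref.genes:
            by_chrom.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_gene_count(self, reference):
        cfg, ref = reference
        assert len(ref.genes) == cfg.n_genes

    def test_gc_within_3se(self):
        cfg = small_config(genome=GenomeConfig(
            n_chroms=1, chrom_length=100_000, gc_fraction=0.5, control_length=5_000),
            n_genes=8)
        ref = simulate_reference(cfg)
        seq = ref.sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        se = math.sqrt(0.5 * 0.5 / len(seq))
        assert abs(gc - 0.5) <= 3 * se

    def test_control_contig_in_fasta_not_gff(self, reference, tmp_path):
        from methinherit.synthetic_data import write_fasta, write_gff3

        _, ref = reference
        write_fasta(ref.sequences, tmp_path / "r.fa")
        write_gff3(ref.genes, tmp_path / "g.gff3")
        assert f">{ref.control_chrom}" in (tmp_path / "r.fa").read_text()
        assert ref.control_chrom not in (tmp_path / "g.gff3").read_text()

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="cannot place"):
            simulate_reference(small_config(n_genes=40))

    def test_fasta_round_trips_through_pyfaidx(self, reference, tmp_path):
        from pyfaidx import Fasta

        from methinherit.synthetic_data import write_fasta

        _, ref = reference
        write_fasta(ref.sequences, tmp_path / "r.fa")
        fa = Fasta(str(tmp_path / "r.fa"))
        assert str(fa["chr1"][:100]) == ref.sequences["chr1"][:100]


class TestPlantDmrs:
    def test_counts_and_non_overlap(self, reference, rng):
        cfg, ref = reference
        planted = plant_dmrs(ref, cfg, rng)
        assert len(planted) == cfg.n_planted_hyper + cfg.n_planted_hypo
        seen = set()
        for p in planted:
            key = (p.chrom, p.start)
            assert key not in seen
            seen.add(key)
            assert p.chrom != ref.control_chrom

    def test_min_cg_guaranteed(self, reference, rng):
        cfg, ref = reference
        for p in plant_dmrs(ref, cfg, rng):
            seq = ref.sequences[p.chrom][p.start:p.end]
            assert seq.count("CG") >= cfg.min_cg_per_dmr

    def test_direction_split(self, reference, rng):
        cfg, ref = reference
        planted = plant_dmrs(ref, cfg, rng)
        assert sum(p.direction == "hyper" for p in planted) == cfg.n_planted_hyper
        assert sum(p.direction == "hypo" for p in planted) == cfg.n_planted_hypo


class TestSimulateMethylome:
    def test_binomial_levels_within_3se(self, rng):
        cfg = small_config(dispersion=0.0, conversion_failure=0.0)
        ref = simulate_reference(cfg)
        report = simulate_methylome(ref, cfg, "A", [], rng)
        report = report[report["chrom"] != ref.control_chrom]
        sample = MethylomeSample.from_report(
            report.assign(n_unmeth=report["n_unmeth"]), "s", "g"
        )
        for summary in context_summaries(sample):
            level = cfg.baseline_levels[summary.context]
            sub = sample.df[sample.df["context"] == summary.context]
            se = math.sqrt(level * (1 - level) / sub["n_total"].sum())
            assert abs(summary.pooled_level - level) <= 3 * se, summary.context

    def test_planted_level_in_condition_b(self, rng):
        cfg = small_config(dispersion=0.0, conversion_failure=0.0)
        ref = simulate_reference(cfg)
        planted = plant_dmrs(ref, cfg, rng)
        hypo = [p for p in planted if p.direction == "hypo"][0]
        report = simulate_methylome(ref, cfg, "B", planted, rng)
        sub = report[
            (report["chrom"] == hypo.chrom)
            & (report["pos"] >= hypo.start)
            & (report["pos"] < hypo.end)
            & (report["context"] == "CpG")
        ]
        observed = sub["n_meth"].sum() / (sub["n_meth"] + sub["n_unmeth"]).sum()
        se = math.sqrt(hypo.level_b * (1 - hypo.level_b) / (sub["n_meth"] + sub["n_unmeth"]).sum())
        assert abs(observed - hypo.level_b) <= 4 * se

    def test_control_contig_conversion_rate(self, rng):
        cfg = small_config(dispersion=0.0, conversion_failure=0.005)
        ref = simulate_reference(cfg)
        report = simulate_methylome(ref, cfg, "A", [], rng)
        sample = MethylomeSample.from_report(report, "s", "g")
        est = conversion_rate(sample, {ref.control_chrom})
        n_reads = int(
            sample.df.loc[sample.df["chrom"] == ref.control_chrom, "n_total"].sum()
        )
        se = math.sqrt(0.005 * 0.995 / n_reads)
        assert abs(est - 0.995) <= 3 * se

    def test_contexts_match_classifier(self, rng):
        # vectorised enumeration must agree with the scalar classifier
        from methinherit.methylome import classify_context

        cfg = small_config(genome=GenomeConfig(
            n_chroms=1, chrom_length=5_000, control_length=2_000), n_genes=0)
        ref = simulate_reference(cfg)
        report = simulate_methylome(ref, cfg, "A", [], rng)
        sub = report[report["chrom"] == "chr1"].sample(400, random_state=0)
        for row in sub.itertuples(index=False):
            assert (
                classify_context(ref.sequences, "chr1", int(row.pos), row.strand)
                == row.context
            )

    def test_chi_square_gof_binomial(self, rng):
        # with rho = 0, counts at each fixed coverage are exactly binomial;
        # accumulate a goodness-of-fit chi-square across coverage classes
        cfg = small_config(dispersion=0.0, conversion_failure=0.0)
        ref = simulate_reference(cfg)
        report = simulate_methylome(ref, cfg, "A", [], rng)
        p = cfg.baseline_levels["CpG"]
        sub = report[
            (report["context"] == "CpG") & (report["chrom"] != ref.control_chrom)
        ].copy()
        sub["n_total"] = sub["n_meth"] + sub["n_unmeth"]

        chi2 = 0.0
        dof = 0
        n_sites_used = 0
        for n, group in sub.groupby("n_total"):
            if len(group) < 600 or n == 0:
                continue
            obs = np.bincount(group["n_meth"].to_numpy(), minlength=n + 1)
            exp = stats.binom.pmf(np.arange(n + 1), n, p) * len(group)
            # merge adjacent cells until each expected count is >= 5
            cells_o, cells_e, acc_o, acc_e = [], [], 0.0, 0.0
            for o, e in zip(obs, exp):
                acc_o, acc_e = acc_o + o, acc_e + e
                if acc_e >= 5:
                    cells_o.append(acc_o)
                    cells_e.append(acc_e)
                    acc_o = acc_e = 0.0
            if acc_e > 0 and cells_e:
                cells_o[-1] += acc_o
                cells_e[-1] += acc_e
            cells_o, cells_e = np.array(cells_o), np.array(cells_e)
            chi2 += float(((cells_o - cells_e) ** 2 / cells_e).sum())
            dof += len(cells_o) - 1
            n_sites_used += len(group)

        assert n_sites_used >= 10_000
        assert stats.chi2.sf(chi2, df=dof) > 0.01

    def test_overdispersed_counts_have_larger_variance(self, rng):
        cfg0 = small_config(dispersion=0.0, conversion_failure=0.0)
        ref = simulate_reference(cfg0)
        r0 = simulate_methylome(ref, cfg0, "A", [], rng)
        cfg1 = small_config(dispersion=0.3, conversion_failure=0.0)
        r1 = simulate_methylome(ref, cfg1, "A", [], rng)

        def site_level_var(rep):
            sub = rep[(rep["context"] == "CpG") & (rep["chrom"] != "ctrl")]
            tot = sub["n_meth"] + sub["n_unmeth"]
            keep = tot >= 20
            return float(np.var(sub.loc[keep, "n_meth"] / tot[keep]))

        assert site_level_var(r1) > 2 * site_level_var(r0)


class TestInheritance:
    def test_full_inheritance(self, reference, rng):
        cfg, ref = reference
        planted = plant_dmrs(ref, cfg, rng)
        cfg_full = small_config(inheritance_fraction=1.0)
        assert simulate_inherited_embryo(planted, cfg_full, rng) == planted

    def test_no_inheritance(self, reference, rng):
        cfg, ref = reference
        planted = plant_dmrs(ref, cfg, rng)
        cfg_none = small_config(inheritance_fraction=0.0)
        assert simulate_inherited_embryo(planted, cfg_none, rng) == []

    def test_exact_fraction_count(self, reference, rng):
        cfg, ref = reference
        planted = plant_dmrs(ref, cfg, rng)  # 16 planted
        cfg_f = small_config(inheritance_fraction=0.6)
        inherited = simulate_inherited_embryo(planted, cfg_f, rng)
        assert len(inherited) == int(0.6 * len(planted))
        assert all(p in planted for p in inherited)


class TestSimulateExpression:
    def test_full_coupling(self, reference, rng):
        cfg, ref = reference
        planted = plant_dmrs(ref, cfg, rng)
        cfg_c = small_config(
            deg_coupling=DegCouplingConfig(n_degs=4, p_coupled_to_dmr=1.0)
        )
        deg_df, dep_df, map_df, planted_degs, planted_deps = simulate_expression(
            ref.genes, planted, cfg_c, rng
        )
        assert all(d["coupled"] for d in planted_degs)
        assert len(planted_degs) == 4

    def test_planted_degs_pass_filter(self, reference, rng):
        cfg, ref = reference
        planted = plant_dmrs(ref, cfg, rng)
        deg_df, *_ , planted_degs, _ = (
            simulate_expression(ref.genes, planted, cfg, rng)
        )
        kept = {r.gene_id for r in filter_degs(deg_df)}
        assert kept == {d["gene_id"] for d in planted_degs}

    def test_too_many_degs_raises(self, reference, rng):
        cfg, ref = reference
        cfg_bad = small_config(deg_coupling=DegCouplingConfig(n_degs=999))
        with pytest.raises(ValueError, match="n_degs"):
            simulate_expression(ref.genes, [], cfg_bad, rng)


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    cfg = small_config()
    truth = simulate_dataset(cfg, outdir)
    return cfg, outdir, truth


class TestSimulateDataset:
    def test_all_files_written(self, dataset):
        _, outdir, _ = dataset
        expected = {
            "reference.fa", "genes.gff3", "sperm_fresh.cx.tsv",
            "sperm_stored.cx.tsv", "embryo_fresh.cx.tsv", "embryo_stored.cx.tsv",
            "degs.tsv", "deps.tsv", "protein_map.tsv", "truth.json",
        }
        assert expected <= {p.name for p in Path(outdir).iterdir()}

    def test_truth_json_well_formed(self, dataset):
        cfg, outdir, truth = dataset
        payload = json.loads((Path(outdir) / "truth.json").read_text())
        assert len(payload["sperm_dmrs"]) == cfg.n_planted_hyper + cfg.n_planted_hypo
        assert len(payload["embryo_dmrs"]) == int(
            cfg.inheritance_fraction * len(payload["sperm_dmrs"])
        )
        assert payload["control_chrom"] == cfg.genome.control_chrom

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = small_config(seed=42)
        simulate_dataset(cfg, tmp_path / "a")
        simulate_dataset(small_config(seed=42), tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_different_seed_differs(self, tmp_path):
        simulate_dataset(small_config(seed=1), tmp_path / "a")
        simulate_dataset(small_config(seed=2), tmp_path / "b")
        assert (
            (tmp_path / "a" / "sperm_fresh.cx.tsv").read_bytes()
            != (tmp_path / "b" / "sperm_fresh.cx.tsv").read_bytes()
        )

    def test_reports_readable(self, dataset):
        _, outdir, _ = dataset
        df = io_formats.read_cytosine_report(Path(outdir) / "sperm_fresh.cx.tsv")
        assert set(df["context"]) == {"CpG", "CHG", "CHH"}


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = small_config(seed=5)
        path = tmp_path / "sim.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        loaded = SimulationConfig.from_yaml(path)
        assert loaded.seed == 5
        assert loaded.genome.chrom_length == cfg.genome.chrom_length
        assert loaded.deg_coupling.n_degs == cfg.deg_coupling.n_degs

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(inheritance_fraction=1.5)
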