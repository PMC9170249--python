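"""End-to-end orchestration: simulate, quantify, segment, integrate, report.

Each stage is a plain function over an in-memory :class:`SimulatedDataset`
(or the files a previous stage wrote), so stages are re-runnable in
isolation; ``run_all`` chains them and returns a machine-readable run
report with per-stage record counts, the parameter echo and the seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import chip as chipmod
from . import enrichment, genes as genemod, methylome, segments
from .regions import read_bedgraph, read_chrom_sizes, read_site_table, write_tsv, reciprocal_overlap_match
from .simulate import (
    GENOTYPES,
    BinnedSignal,
    SimulatedDataset,
    SimulationConfig,
    simulate_dataset,
    simulate_genome,
    write_dataset,
)

log = logging.getLogger("methylchrom")


class PipelineError(RuntimeError):
    pass


def run_simulate(config: SimulationConfig, outdir: str | Path | None = None) -> SimulatedDataset:
    dataset = simulate_dataset(config)
    if outdir is not None:
        write_dataset(dataset, outdir)
    log.info(
        "simulated %d methylomes, %d chip tracks, %d genes (seed=%d)",
        len(dataset.methylomes), len(dataset.chip), len(dataset.gene_models),
        config.seed,
    )
    return dataset


def load_dataset(outdir: str | Path) -> SimulatedDataset:
    """Reload a simulated dataset from the files ``run_simulate`` wrote.

    The genome's CG/CH registries are rebuilt deterministically from the
    stored config (same seed, same registries); count tables and tracks
    are read back from disk.
    """
    outdir = Path(outdir)
    config = SimulationConfig.from_yaml(outdir / "config.yaml")
    genome = simulate_genome(config)
    stored = read_chrom_sizes(outdir / "genome.chrom.sizes")
    if stored.chrom_sizes != genome.chrom_sizes:
        raise PipelineError("stored chrom.sizes disagree with the stored config")
    methylomes = {}
    for stage in config.stages:
        for genotype in GENOTYPES:
            for rep in range(1, config.n_replicates + 1):
                path = outdir / f"allc_{genotype}_{stage.label}_rep{rep}.tsv"
                sites = read_site_table(path)
                methylomes[(genotype, stage.label, rep)] = methylome.MethylomeSample(
                    sites=sites, ncr=config.ncr,
                    meta={"genotype": genotype, "stage": stage.label, "replicate": rep},
                )
    chip_tracks = {}
    for stage in config.stages:
        for genotype in GENOTYPES:
            for rep in range(1, config.n_replicates + 1):
                for mark in ("H3K27me3", "IgG"):
                    path = outdir / f"chip_{mark}_{genotype}_{stage.label}_rep{rep}.bedgraph"
                    frame = read_bedgraph(path)
                    chip_tracks[(mark, genotype, stage.label, rep)] = (
                        BinnedSignal.from_bedgraph_frame(
                            frame, genome, config.chip.bin_size
                        )
                    )
    from .simulate import TruthTable

    truth = TruthTable(
        dmrs=pd.read_csv(outdir / "truth_dmrs.tsv", sep="\t"),
        dmvs=pd.read_csv(outdir / "truth_dmvs.tsv", sep="\t"),
        chip_peaks=pd.read_csv(outdir / "truth_chip_peaks.tsv", sep="\t"),
        genes=pd.read_csv(outdir / "truth_genes.tsv", sep="\t"),
        severity={},
        background={},
    )
    gene_models = pd.read_csv(outdir / "gene_models.tsv", sep="\t")
    gene_counts = pd.read_csv(outdir / "gene_counts.tsv", sep="\t").set_index("gene_id")
    return SimulatedDataset(
        config=config, genome=genome, methylomes=methylomes, truth=truth,
        chip=chip_tracks, gene_models=gene_models, gene_counts=gene_counts,
    )


def run_methylome(dataset: SimulatedDataset, outdir: str | Path | None = None) -> dict:
    """Global and binned methylation levels for every sample."""
    rows = []
    for (genotype, stage, rep), sample in dataset.methylomes.items():
        for context in ("CG", "CH"):
            rows.append(
                {
                    "genotype": genotype, "stage": stage, "replicate": rep,
                    "context": context,
                    "level_raw": methylome.global_level(sample, context, adjusted=False),
                    "level_adj": methylome.global_level(sample, context, adjusted=True),
                }
            )
    table = pd.DataFrame(rows)
    adult = dataset.config.adult_stage
    ctrl = methylome.pool_samples(
        [dataset.methylomes[("control", adult, r)]
         for r in range(1, dataset.config.n_replicates + 1)]
    )
    cko = methylome.pool_samples(
        [dataset.methylomes[("cKO", adult, r)]
         for r in range(1, dataset.config.n_replicates + 1)]
    )
    deltas = {}
    for context in ("CG", "CH"):
        a = methylome.binned_levels(ctrl, dataset.genome, context)
        b = methylome.binned_levels(cko, dataset.genome, context)
        d = a.copy()
        d["level"] = b["level"] - a["level"]
        deltas[context] = d
    r, p = methylome.delta_track_correlation(deltas["CG"], deltas["CH"])
    if outdir is not None:
        write_tsv(table, Path(outdir) / "global_levels.tsv")
    return {"global_levels": table, "delta_tracks": deltas,
            "delta_spearman_r": r, "delta_spearman_p": p}


def _adult_groups(dataset: SimulatedDataset):
    adult = dataset.config.adult_stage
    reps = range(1, dataset.config.n_replicates + 1)
    ctrl = [dataset.methylomes[("control", adult, r)] for r in reps]
    cko = [dataset.methylomes[("cKO", adult, r)] for r in reps]
    return ctrl, cko


def run_dmr(
    dataset: SimulatedDataset,
    fdr: float = 0.01,
    min_delta: float = 30.0,
    drop_hyper: bool = True,
    outdir: str | Path | None = None,
) -> dict:
    """Adult-stage knockout-vs-control DMS and DMR calling."""
    ctrl, cko = _adult_groups(dataset)
    dms = segments.call_dms(ctrl, cko, context="CG", fdr=fdr)
    candidates = segments.segment_dmrs(dms)
    dmrs = segments.filter_dmrs(
        candidates, min_delta=min_delta, fdr=fdr, drop_hyper=drop_hyper
    )
    if outdir is not None:
        write_tsv(dmrs, Path(outdir) / "dmrs.tsv")
    return {"dms": dms, "candidates": candidates, "dmrs": dmrs}


def run_dmv(
    dataset: SimulatedDataset, m: float = 0.3, outdir: str | Path | None = None
) -> dict:
    """Per-condition UMR/DMV calling and six-way cross-condition comparison."""
    ctrl, cko = _adult_groups(dataset)
    pooled = {"control": methylome.pool_samples(ctrl), "cKO": methylome.pool_samples(cko)}
    umrs = {g: segments.segment_low_methylation(s, m=m) for g, s in pooled.items()}
    dmvs = {g: segments.call_dmvs(u) for g, u in umrs.items()}
    table, summary = segments.compare_dmv_sets(dmvs["cKO"], dmvs["control"])
    if outdir is not None:
        write_tsv(table, Path(outdir) / "dmv_categories.tsv")
        write_tsv(summary, Path(outdir) / "dmv_summary.tsv")
    return {"umrs": umrs, "dmvs": dmvs, "categories": table, "summary": summary}


def run_chip(
    dataset: SimulatedDataset, fdr: float = 0.05, outdir: str | Path | None = None
) -> dict:
    """Island calling per condition plus differential H3K27me3 regions."""
    adult = dataset.config.adult_stage
    fetal = dataset.config.stages[0].label
    reps = range(1, dataset.config.n_replicates + 1)

    def pooled_track(mark, genotype, stage):
        tracks = [dataset.chip[(mark, genotype, stage, r)] for r in reps]
        counts = {
            c: sum(t.counts[c] for t in tracks) for c in dataset.genome.chroms
        }
        return BinnedSignal(
            genome=dataset.genome, bin_size=tracks[0].bin_size, counts=counts,
            library_size=sum(t.library_size for t in tracks),
        )

    peaks = {}
    for genotype in GENOTYPES:
        treat = pooled_track("H3K27me3", genotype, adult)
        igg = pooled_track("IgG", genotype, adult)
        peaks[genotype] = chipmod.call_islands(treat, igg, gaps_allowed=3)
    from .regions import merge_intervals

    universe = merge_intervals(
        pd.concat([peaks["control"], peaks["cKO"]], ignore_index=True)[
            ["chrom", "start", "end"]
        ]
    )
    samples = [("control", r) for r in reps] + [("cKO", r) for r in reps]
    counts = np.column_stack(
        [
            chipmod.region_counts(dataset.chip[("H3K27me3", g, adult, r)], universe)
            for g, r in samples
        ]
    )
    condition = np.array([g for g, _ in samples])
    dm = chipmod.call_dm_regions(universe, counts, condition, fdr=fdr)
    dm_sig = dm[dm["significant"]].reset_index(drop=True)

    # developmental DM sets: fetal vs adult within the control genotype
    dev_counts = np.column_stack(
        [
            chipmod.region_counts(dataset.chip[("H3K27me3", "control", st, r)], universe)
            for st in (fetal, adult) for r in reps
        ]
    )
    dev_condition = np.array([fetal] * len(list(reps)) + [adult] * len(list(reps)))
    dev = chipmod.call_dm_regions(universe, dev_counts, dev_condition, fdr=fdr)
    dev_sig = dev[dev["significant"]]
    dev_loss = dev_sig[dev_sig["log2fc"] < 0].reset_index(drop=True)
    dev_gain = dev_sig[dev_sig["log2fc"] > 0].reset_index(drop=True)
    grouped = chipmod.assign_peak_groups(universe, dev_loss, dev_gain, dm_sig)
    if outdir is not None:
        for g, frame in peaks.items():
            write_tsv(frame, Path(outdir) / f"peaks_{g}.tsv")
        write_tsv(dm, Path(outdir) / "dm_regions.tsv")
    return {
        "peaks": peaks, "universe": universe, "dm": dm, "dm_significant": dm_sig,
        "dev_loss": dev_loss, "dev_gain": dev_gain, "grouped": grouped,
    }


def run_enrich(
    dataset: SimulatedDataset,
    dmrs: pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> dict:
    """CG-weighted enrichment of called DMRs in planted features."""
    features = {
        "planted_dmrs": dataset.truth.dmrs[["chrom", "start", "end"]],
        "planted_dmvs": dataset.truth.dmv_set("control"),
        "chip_peaks": dataset.truth.chip_peaks[["chrom", "start", "end"]],
        "gene_bodies": dataset.truth.genes[["chrom", "start", "end"]],
    }
    table = enrichment.enrichment_table(
        dmrs[["chrom", "start", "end"]], features, dataset.genome
    )
    perm = None
    if len(dmrs):
        perm = enrichment.permutation_overlap_test(
            dmrs[["chrom", "start", "end"]],
            dataset.truth.dmrs[["chrom", "start", "end"]],
            dataset.genome, n_perm=max(n_perm, 100), seed=seed,
        )
        perm = {k: v for k, v in perm.items() if k != "null"}
    if outdir is not None:
        write_tsv(table, Path(outdir) / "enrichment.tsv")
    return {"enrichment": table, "permutation": perm}


def run_integrate(dataset: SimulatedDataset, outdir: str | Path | None = None) -> dict:
    """DE calling plus methylation/expression integration statistics."""
    norm = genemod.filter_and_normalize(dataset.gene_counts)
    condition = np.array(
        [c.split("_rep")[0] for c in dataset.gene_counts.columns]
    )
    de = genemod.call_de(
        norm["counts"], condition,
        effective_lib_sizes=norm["effective_lib_sizes"],
    )
    ctrl, cko = _adult_groups(dataset)
    pooled_ctrl = methylome.pool_samples(ctrl)
    pooled_cko = methylome.pool_samples(cko)
    gm = dataset.gene_models.set_index("gene_id").loc[de.index].reset_index()
    delta_mch = genemod.delta_gene_body(gm, pooled_ctrl, pooled_cko, "CH")
    decile = genemod.decile_fc_curve(delta_mch, de["log2fc"])
    if outdir is not None:
        write_tsv(de.reset_index(), Path(outdir) / "de_genes.tsv")
        write_tsv(decile, Path(outdir) / "decile_curve.tsv")
    return {"de": de, "delta_mch": delta_mch, "decile_curve": decile, "norm": norm}


def recovery_report(
    predicted: pd.DataFrame, truth: pd.DataFrame, min_frac: float = 0.5
) -> dict:
    """Sensitivity / precision / mean Jaccard at reciprocal-overlap matching.

    Precision is NaN (flagged) when nothing was predicted.
    """
    if len(truth) == 0:
        raise ValueError("empty truth set")
    matches = reciprocal_overlap_match(
        predicted.reset_index(drop=True), truth.reset_index(drop=True), min_frac
    )
    sens = len(matches) / len(truth)
    prec = len(matches) / len(predicted) if len(predicted) else float("nan")
    jac = float(matches["jaccard"].mean()) if len(matches) else 0.0
    return {
        "n_truth": len(truth), "n_predicted": len(predicted),
        "n_matched": len(matches), "sensitivity": sens,
        "precision": prec, "mean_jaccard": jac,
    }


def run_all(
    config: SimulationConfig, outdir: str | Path, n_perm: int = 200
) -> dict:
    """Chain every stage; returns (and writes) the run report."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = run_simulate(config, outdir / "data")
    meth = run_methylome(dataset, outdir)
    dmr = run_dmr(dataset, outdir=outdir)
    dmv = run_dmv(dataset, outdir=outdir)
    chip_res = run_chip(dataset, outdir=outdir)
    enrich = run_enrich(dataset, dmr["dmrs"], n_perm=n_perm, seed=config.seed, outdir=outdir)
    integ = run_integrate(dataset, outdir=outdir)
    recovery = {
        "dmrs": recovery_report(dmr["dmrs"], dataset.truth.hypo_dmr_truth()),
        "dmvs_control": recovery_report(
            dmv["dmvs"]["control"], dataset.truth.dmv_set("control")
        ),
        "peaks_control": recovery_report(
            chip_res["peaks"]["control"],
            dataset.truth.chip_peaks[
                dataset.truth.chip_peaks["group"].isin(["stable", "DevGain", "cKOgain"])
            ][["chrom", "start", "end"]],
        ),
    }
    report = {
        "seed": config.seed,
        "n_sites_tested": int(dmr["dms"]["p"].notna().sum()),
        "n_dms": int(dmr["dms"]["significant"].sum()),
        "n_dmrs": len(dmr["dmrs"]),
        "dmv_counts": {
            g: len(frame) for g, frame in dmv["dmvs"].items()
        },
        "dmv_category_counts": dmv["summary"]
        .groupby("category")["count"].sum().to_dict(),
        "n_peaks": {g: len(p) for g, p in chip_res["peaks"].items()},
        "n_dm_regions": len(chip_res["dm_significant"]),
        "n_de_genes": int((integ["de"]["status"] != "non-DE").sum()),
        "delta_spearman_r": meth["delta_spearman_r"],
        "recovery": recovery,
        "wall_clock_s": round(time.time() - t0, 2),
    }
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
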