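"""Synthetic methylome / ChIP / expression data with planted ground truth.

The generator emulates a two-genotype (control vs conditional knockout of a
de-novo DNA methyltransferase), multi-stage (fetal, newborn, adult), two-
replicate neuronal epigenome study:

* genome-wide mCG is high at every stage in the control (~73%) but reduced
  in the adult knockout (~60%), with the deficit varying smoothly along the
  genome (a per-10-kb "severity" field);
* mCH is near zero before birth in both genotypes, accumulates to ~2% by
  the adult stage in the control only, and its local level follows the same
  severity field — so the knockout's mCG and mCH losses are spatially
  coupled, as they are in real neurons;
* planted DMRs are developmental gain-of-methylation regions whose gain is
  blocked in the knockout (fetal-like level at the adult stage, a >= 30
  percentage-point deficit);
* planted DMVs are large (>= 5 kb) very-low-mCG valleys present in both
  genotypes, a subset of which widens in the adult knockout;
* H3K27me3 tracks carry island-shaped peaks over a flat background; at the
  adult stage the knockout's peak enrichment responds to the local mCG loss
  through a negative coupling coefficient, and a subset of peaks receives
  an additional strong planted gain (the differential-binding truth);
* gene expression counts encode a negative gene-body-mCH -> expression
  coupling plus a few planted DE genes.

Everything is deterministic under (seed, config): replicates share the
per-site true levels and differ only in count sampling.  Planted feature
classes are mutually disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chip import BinnedSignal
from .methylome import MethylomeSample
from .regions import (
    Genome,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_site_table,
    write_tsv,
)

GENOTYPES = ("control", "cKO")


@dataclass
class StageParams:
    """Target genome-wide levels (percent) for one developmental stage."""

    label: str
    control_mcg: float
    cko_mcg: float
    control_mch: float
    cko_mch: float


@dataclass
class GenomeParams:
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    cg_spacing: float = 100.0  # mean bp between CG dinucleotides (exponential)
    ch_density: float = 0.4  # CH sites per bp (both strands combined)


@dataclass
class DmrParams:
    n: int = 60
    length_min: int = 1000
    length_max: int = 2000
    fetal_level_min: float = 20.0
    fetal_level_max: float = 35.0
    gain_min: float = 35.0
    gain_max: float = 55.0
    min_cg_sites: int = 5
    max_cg_gap: int = 400  # planted DMRs must be recoverable under the gap rule


@dataclass
class DmvParams:
    n: int = 12
    length_min: int = 6000
    length_max: int = 10_000
    level: float = 8.0
    n_expanded: int = 4
    expansion: int = 2000
    min_cg_sites: int = 40


@dataclass
class ChipParams:
    bin_size: int = 200
    background_per_bin: float = 10.0
    peak_length_min: int = 2000
    peak_length_max: int = 5000
    enrichment: float = 6.0
    n_stable: int = 15
    n_dev_loss: int = 8
    n_dev_gain: int = 8
    n_cko_gain: int = 12
    coupling: float = -0.04  # log2 H3K27me3 change per %mCG excess change
    # planted extra mCG loss (beyond the uniform background deficit) at
    # cKO-gain peaks; the H3K27me3 gain is coupling * that excess loss
    mcg_loss_min: float = 25.0
    mcg_loss_max: float = 40.0


@dataclass
class GeneParams:
    n: int = 120
    length_min: int = 3000
    length_max: int = 6000
    beta_mch: float = -0.15  # log2 expression FC per %-point gene-body mCH change
    de_fraction: float = 0.08
    de_log2fc: float = 1.0
    mean_count: float = 500.0
    count_log_sd: float = 1.0
    nb_dispersion: float = 0.01  # BCV 0.1, typical for inbred-mouse RNA-seq


@dataclass
class SimulationConfig:
    seed: int = 1
    genome: GenomeParams = field(default_factory=GenomeParams)
    stages: list[StageParams] = field(
        default_factory=lambda: [
            StageParams("E14", 71.0, 71.0, 0.02, 0.02),
            StageParams("P0", 73.1, 73.1, 0.05, 0.05),
            StageParams("P39", 72.6, 60.1, 1.98, 0.05),
        ]
    )
    n_replicates: int = 2
    dmr: DmrParams = field(default_factory=DmrParams)
    dmv: DmvParams = field(default_factory=DmvParams)
    chip: ChipParams = field(default_factory=ChipParams)
    genes: GeneParams = field(default_factory=GeneParams)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0  # NB size parameter (larger = less overdispersed)
    ncr: float = 0.005  # bisulfite non-conversion rate (fraction)
    site_sd: float = 8.0  # per-CG-site level deviation (percentage points)
    mch_site_shape: float = 2.0  # gamma shape of per-CH-site multipliers
    block_size: int = 10_000
    block_shape: float = 4.0  # gamma shape of the severity field
    # control-adult mCH is elevated at regions of planted knockout mCG
    # loss (de-novo-methyltransferase-dependent regions accumulate both
    # marks), which couples the two losses along the genome
    mch_loss_coupling: float = 0.05  # relative mCH weight per %-point planted loss
    # the knockout's background mCG deficit is nearly uniform along the
    # genome (unlike mCH); the severity field modulates it only mildly
    mcg_deficit_damping: float = 0.15
    feature_margin: int = 1000
    edge_margin: int = 20_000

    def __post_init__(self) -> None:
        for s in self.stages:
            for v in (s.control_mcg, s.cko_mcg, s.control_mch, s.cko_mch):
                if not (0.0 <= v <= 100.0):
                    raise ValueError(f"stage level {v} outside [0, 100]")
        if not (0.0 <= self.ncr < 1.0):
            raise ValueError("ncr must be in [0, 1)")

    @property
    def adult_stage(self) -> str:
        return self.stages[-1].label

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        if "genome" in raw:
            raw["genome"] = GenomeParams(**raw["genome"])
        if "stages" in raw:
            raw["stages"] = [StageParams(**s) for s in raw["stages"]]
        for key, klass in (
            ("dmr", DmrParams), ("dmv", DmvParams),
            ("chip", ChipParams), ("genes", GeneParams),
        ):
            if key in raw:
                raw[key] = klass(**raw[key])
        return cls(**raw)


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    """A reduced configuration for fast tests: one 400 kb chromosome."""
    cfg = SimulationConfig(
        seed=seed,
        genome=GenomeParams(n_chroms=1, chrom_length=400_000),
        dmr=DmrParams(n=10),
        dmv=DmvParams(n=3, n_expanded=1),
        chip=ChipParams(n_stable=4, n_dev_loss=2, n_dev_gain=2, n_cko_gain=4),
        genes=GeneParams(n=20),
        feature_margin=500,
        edge_margin=10_000,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class TruthTable:
    """Planted-feature records with true effect sizes and coordinates."""

    dmrs: pd.DataFrame
    dmvs: pd.DataFrame
    chip_peaks: pd.DataFrame
    genes: pd.DataFrame
    severity: dict[str, np.ndarray]
    background: dict[tuple[str, str], float]

    def hypo_dmr_truth(self) -> pd.DataFrame:
        """All planted adult-stage knockout-hypo intervals.

        Planted DMRs plus the extension zones of expanded valleys (low in
        the adult knockout where the control stays at background) — every
        interval a correct hypo-DMR caller should report.
        """
        rows = [self.dmrs[["chrom", "start", "end"]]]
        if "extra_mcg_loss" in self.chip_peaks.columns:
            loss = self.chip_peaks[self.chip_peaks["extra_mcg_loss"] > 0]
            rows.append(loss[["chrom", "start", "end"]])
        exp = self.dmvs[self.dmvs["expanded"]]
        for _, r in exp.iterrows():
            if r["cko_start"] < r["start"]:
                rows.append(pd.DataFrame({"chrom": [r["chrom"]],
                                          "start": [r["cko_start"]],
                                          "end": [r["start"]]}))
            if r["cko_end"] > r["end"]:
                rows.append(pd.DataFrame({"chrom": [r["chrom"]],
                                          "start": [r["end"]],
                                          "end": [r["cko_end"]]}))
        return pd.concat(rows, ignore_index=True)

    def dmv_set(self, condition: str, stage_is_adult: bool = True) -> pd.DataFrame:
        """Planted valley intervals as they exist in one condition."""
        if condition == "cKO" and stage_is_adult:
            return pd.DataFrame(
                {
                    "chrom": self.dmvs["chrom"],
                    "start": self.dmvs["cko_start"],
                    "end": self.dmvs["cko_end"],
                }
            )
        return pd.DataFrame(
            {
                "chrom": self.dmvs["chrom"],
                "start": self.dmvs["start"],
                "end": self.dmvs["end"],
            }
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        write_tsv(self.dmrs, outdir / "truth_dmrs.tsv")
        write_tsv(self.dmvs, outdir / "truth_dmvs.tsv")
        write_tsv(self.chip_peaks, outdir / "truth_chip_peaks.tsv")
        write_tsv(self.genes, outdir / "truth_genes.tsv")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig) -> Genome:
    """Chromosomes with CG and CH site registries.

    CG dinucleotide positions follow a Poisson (exponential-spacing)
    process at the configured mean spacing; CH sites are uniform with the
    configured per-bp density and a random strand each.
    """
    g = config.genome
    if g.chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    rng = np.random.default_rng([config.seed, 11])
    sizes: dict[str, int] = {}
    cg: dict[str, np.ndarray] = {}
    ch: dict[str, np.ndarray] = {}
    ch_strand: dict[str, np.ndarray] = {}
    for i in range(g.n_chroms):
        chrom = f"chr{i + 1}"
        sizes[chrom] = g.chrom_length
        n_exp = int(g.chrom_length / g.cg_spacing * 1.3) + 10
        gaps = rng.exponential(g.cg_spacing, n_exp)
        pos = np.cumsum(np.maximum(gaps, 2.0)).astype(np.int64)
        cg[chrom] = pos[pos < g.chrom_length - 1]
        n_ch = rng.binomial(g.chrom_length, g.ch_density)
        chp = np.sort(rng.choice(g.chrom_length, size=n_ch, replace=False))
        ch[chrom] = chp.astype(np.int64)
        ch_strand[chrom] = np.where(rng.random(n_ch) < 0.5, "+", "-")
    return Genome(chrom_sizes=sizes, cg_sites=cg, ch_sites=ch, ch_strands=ch_strand)


# ---------------------------------------------------------------------------
# feature layout
# ---------------------------------------------------------------------------


def _place_features(
    rng: np.random.Generator,
    genome: Genome,
    lengths: list[int],
    occupied: list[tuple[str, int, int]],
    margin: int,
    edge_margin: int,
    accept=None,
    max_attempts: int = 2000,
    align: int = 1,
) -> list[tuple[str, int, int]]:
    """Uniformly place non-overlapping features, with an acceptance predicate."""
    placed = []
    chroms = genome.chroms
    weights = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for length in lengths:
        ok = False
        for _ in range(max_attempts):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            hi = genome.chrom_sizes[chrom] - edge_margin - length
            lo = edge_margin
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            if align > 1:
                start = (start // align) * align
            end = start + length
            clash = any(
                c == chrom and start - margin < e and end + margin > s
                for c, s, e in occupied
            )
            if clash:
                continue
            if accept is not None and not accept(chrom, start, end):
                continue
            occupied.append((chrom, start, end))
            placed.append((chrom, start, end))
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place a {length} bp feature after {max_attempts} attempts"
            )
    return placed


def _layout(config: SimulationConfig, genome: Genome, rng: np.random.Generator):
    """Place all planted feature classes, mutually disjoint."""

    def cg_count(chrom, start, end):
        pos = genome.cg_sites[chrom]
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))

    occupied: list[tuple[str, int, int]] = []
    dmv_cfg, dmr_cfg, chip_cfg, gene_cfg = (
        config.dmv, config.dmr, config.chip, config.genes,
    )
    # valleys first (largest); reserve the expansion flanks too
    dmv_lengths = [
        int(rng.integers(dmv_cfg.length_min, dmv_cfg.length_max + 1))
        for _ in range(dmv_cfg.n)
    ]
    dmv_placed = _place_features(
        rng, genome, dmv_lengths, occupied,
        margin=config.feature_margin + dmv_cfg.expansion,
        edge_margin=config.edge_margin,
        accept=lambda c, s, e: cg_count(c, s, e) >= dmv_cfg.min_cg_sites,
    )
    expanded = np.zeros(dmv_cfg.n, dtype=bool)
    if dmv_cfg.n_expanded:
        expanded[rng.choice(dmv_cfg.n, size=dmv_cfg.n_expanded, replace=False)] = True
    dmvs = pd.DataFrame(
        {
            "chrom": [c for c, _, _ in dmv_placed],
            "start": [s for _, s, _ in dmv_placed],
            "end": [e for _, _, e in dmv_placed],
            "expanded": expanded,
            "level": dmv_cfg.level,
        }
    )
    dmvs["cko_start"] = np.where(expanded, dmvs["start"] - dmv_cfg.expansion, dmvs["start"])
    dmvs["cko_end"] = np.where(expanded, dmvs["end"] + dmv_cfg.expansion, dmvs["end"])

    # peaks on the ChIP bin grid
    bs = chip_cfg.bin_size
    groups = (
        ["stable"] * chip_cfg.n_stable
        + ["DevLoss"] * chip_cfg.n_dev_loss
        + ["DevGain"] * chip_cfg.n_dev_gain
        + ["cKOgain"] * chip_cfg.n_cko_gain
    )
    peak_lengths = [
        int(rng.integers(chip_cfg.peak_length_min // bs, chip_cfg.peak_length_max // bs + 1)) * bs
        for _ in groups
    ]

    def peak_ok(chrom, start, end):
        # peaks carrying planted mCG loss must be recoverable as DMRs
        pos = genome.cg_sites[chrom]
        inside = pos[(pos >= start) & (pos < end)]
        if len(inside) < dmr_cfg.min_cg_sites:
            return False
        edges = np.concatenate(([start], inside, [end]))
        return int(np.diff(edges).max()) <= dmr_cfg.max_cg_gap

    peak_placed = _place_features(
        rng, genome, peak_lengths, occupied,
        margin=config.feature_margin, edge_margin=config.edge_margin, align=bs,
        accept=peak_ok,
    )
    peaks = pd.DataFrame(
        {
            "chrom": [c for c, _, _ in peak_placed],
            "start": [s for _, s, _ in peak_placed],
            "end": [e for _, _, e in peak_placed],
            "group": groups,
        }
    )
    peaks["extra_mcg_loss"] = np.where(
        peaks["group"] == "cKOgain",
        rng.uniform(chip_cfg.mcg_loss_min, chip_cfg.mcg_loss_max, len(peaks)),
        0.0,
    )

    # DMRs: developmental gain regions, gain blocked in the knockout
    dmr_lengths = [
        int(rng.integers(dmr_cfg.length_min, dmr_cfg.length_max + 1))
        for _ in range(dmr_cfg.n)
    ]
    def dmr_ok(chrom, start, end):
        pos = genome.cg_sites[chrom]
        inside = pos[(pos >= start) & (pos < end)]
        if len(inside) < dmr_cfg.min_cg_sites:
            return False
        edges = np.concatenate(([start], inside, [end]))
        return int(np.diff(edges).max()) <= dmr_cfg.max_cg_gap

    dmr_placed = _place_features(
        rng, genome, dmr_lengths, occupied,
        margin=config.feature_margin, edge_margin=config.edge_margin,
        accept=dmr_ok,
    )
    dmrs = pd.DataFrame(
        {
            "chrom": [c for c, _, _ in dmr_placed],
            "start": [s for _, s, _ in dmr_placed],
            "end": [e for _, _, e in dmr_placed],
            "fetal_level": rng.uniform(
                dmr_cfg.fetal_level_min, dmr_cfg.fetal_level_max, dmr_cfg.n
            ),
            "gain": rng.uniform(dmr_cfg.gain_min, dmr_cfg.gain_max, dmr_cfg.n),
        }
    )
    dmrs["adult_control_level"] = np.minimum(
        dmrs["fetal_level"] + dmrs["gain"], 95.0
    )
    dmrs["delta"] = dmrs["fetal_level"] - dmrs["adult_control_level"]

    # genes
    gene_lengths = [
        int(rng.integers(gene_cfg.length_min, gene_cfg.length_max + 1))
        for _ in range(gene_cfg.n)
    ]
    gene_placed = _place_features(
        rng, genome, gene_lengths, occupied,
        margin=config.feature_margin, edge_margin=config.edge_margin,
    )
    strands = np.where(rng.random(gene_cfg.n) < 0.5, "+", "-")
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i + 1:04d}" for i in range(gene_cfg.n)],
            "chrom": [c for c, _, _ in gene_placed],
            "start": [s for _, s, _ in gene_placed],
            "end": [e for _, _, e in gene_placed],
            "strand": strands,
        }
    )
    genes["tss"] = np.where(strands == "+", genes["start"], genes["end"])
    genes["tes"] = np.where(strands == "+", genes["end"], genes["start"])
    genes["length"] = genes["end"] - genes["start"]
    return dmrs, dmvs, peaks, genes


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------


def _severity_field(config: SimulationConfig, genome: Genome) -> dict[str, np.ndarray]:
    """Per-block (default 10 kb) severity multipliers, mean-normalised to 1."""
    rng = np.random.default_rng([config.seed, 13])
    sev = {}
    raw_all = []
    for chrom, length in genome.chrom_sizes.items():
        n = int(np.ceil(length / config.block_size))
        raw = rng.gamma(config.block_shape, 1.0 / config.block_shape, n)
        # keep unplanted background deficits well below planted effects
        raw = np.clip(raw, 0.25, 1.6)
        sev[chrom] = raw
        raw_all.append(raw)
    mean = float(np.concatenate(raw_all).mean())
    return {c: v / mean for c, v in sev.items()}


def _interval_mask(pos: np.ndarray, frame: pd.DataFrame, chrom: str, start_col="start", end_col="end"):
    mask = np.zeros(len(pos), dtype=bool)
    values = np.zeros(len(pos))
    sub = frame[frame["chrom"] == chrom]
    for _, row in sub.iterrows():
        sel = (pos >= row[start_col]) & (pos < row[end_col])
        mask |= sel
        values[sel] = row.get("_value", 0.0)
    return mask


def _expected_cg_levels(
    config: SimulationConfig,
    genome: Genome,
    severity: dict[str, np.ndarray],
    dmrs: pd.DataFrame,
    dmvs: pd.DataFrame,
    peaks: pd.DataFrame,
    eps: dict[str, np.ndarray],
) -> dict[tuple[str, str], dict[str, np.ndarray]]:
    """Per-site expected %mCG for every (stage, genotype), calibrated.

    The free background level (control) and the mean knockout deficit are
    solved so that the genome-wide site-average equals the configured stage
    targets exactly in expectation, given the planted overrides.
    """
    out: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    adult = config.adult_stage
    n_total = genome.n_cg()
    loss_peaks = peaks[peaks["extra_mcg_loss"] > 0]
    for stage in config.stages:
        is_adult = stage.label == adult
        # planted extra knockout loss per CG site (adult stage only)
        extra = {}
        for chrom, pos in genome.cg_sites.items():
            vec = np.zeros(len(pos))
            if is_adult:
                for _, r in loss_peaks[loss_peaks["chrom"] == chrom].iterrows():
                    vec[(pos >= r["start"]) & (pos < r["end"])] = r["extra_mcg_loss"]
            extra[chrom] = vec
        # per-chrom override values and masks (genotype-dependent at adult)
        masks = {}
        for chrom, pos in genome.cg_sites.items():
            dmr_sub = dmrs[dmrs["chrom"] == chrom]
            dmv_sub = dmvs[dmvs["chrom"] == chrom]
            ov_ctrl = np.full(len(pos), np.nan)
            ov_cko = np.full(len(pos), np.nan)
            for _, r in dmr_sub.iterrows():
                sel = (pos >= r["start"]) & (pos < r["end"])
                ov_ctrl[sel] = r["adult_control_level"] if is_adult else r["fetal_level"]
                ov_cko[sel] = r["fetal_level"]
            for _, r in dmv_sub.iterrows():
                sel = (pos >= r["start"]) & (pos < r["end"])
                ov_ctrl[sel] = r["level"]
                ov_cko[sel] = r["level"]
                if is_adult and r["expanded"]:
                    ext = ((pos >= r["cko_start"]) & (pos < r["start"])) | (
                        (pos >= r["end"]) & (pos < r["cko_end"])
                    )
                    ov_cko[ext] = r["level"]
            masks[chrom] = (ov_ctrl, ov_cko)

        # control background solves the stage target exactly
        sum_ov_ctrl = sum(np.nansum(m[0]) for m in masks.values())
        n_ov_ctrl = sum(int(np.sum(~np.isnan(m[0]))) for m in masks.values())
        n_bg_ctrl = n_total - n_ov_ctrl
        bg_ctrl = (stage.control_mcg * n_total - sum_ov_ctrl) / max(n_bg_ctrl, 1)
        # knockout: background = control background minus a severity-scaled deficit
        sum_ov_cko = sum(np.nansum(m[1]) for m in masks.values())
        d = config.mcg_deficit_damping
        sev_sum = 0.0
        extra_sum = 0.0
        for chrom, pos in genome.cg_sites.items():
            bg_sel = np.isnan(masks[chrom][1])
            blocks = (pos[bg_sel] // config.block_size).astype(int)
            sev_sum += float((1.0 + d * (severity[chrom][blocks] - 1.0)).sum())
            extra_sum += float(extra[chrom][bg_sel].sum())
        n_ov_cko = sum(int(np.sum(~np.isnan(m[1]))) for m in masks.values())
        n_bg_cko = n_total - n_ov_cko
        dbar = (
            n_bg_cko * bg_ctrl + sum_ov_cko - extra_sum - stage.cko_mcg * n_total
        ) / max(sev_sum, 1.0)
        dbar = max(dbar, 0.0)

        lv_ctrl: dict[str, np.ndarray] = {}
        lv_cko: dict[str, np.ndarray] = {}
        for chrom, pos in genome.cg_sites.items():
            ov_ctrl, ov_cko = masks[chrom]
            blocks = (pos // config.block_size).astype(int)
            base_c = np.where(np.isnan(ov_ctrl), bg_ctrl, ov_ctrl)
            damped = 1.0 + d * (severity[chrom][blocks] - 1.0)
            base_k = np.where(
                np.isnan(ov_cko),
                bg_ctrl - dbar * damped - extra[chrom],
                ov_cko,
            )
            lv_ctrl[chrom] = np.clip(base_c + eps[chrom], 0.0, 100.0)
            lv_cko[chrom] = np.clip(base_k + eps[chrom], 0.0, 100.0)
        out[(stage.label, "control")] = lv_ctrl
        out[(stage.label, "cKO")] = lv_cko
    return out


def _planted_loss_field(
    config: SimulationConfig,
    genome: Genome,
    dmrs: pd.DataFrame,
    dmvs: pd.DataFrame,
    peaks: pd.DataFrame,
    positions: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Expected adult knockout mCG loss (pp) per position from planted features."""
    out = {}
    for chrom, pos in positions.items():
        vec = np.zeros(len(pos))
        for _, r in dmrs[dmrs["chrom"] == chrom].iterrows():
            sel = (pos >= r["start"]) & (pos < r["end"])
            vec[sel] = r["adult_control_level"] - r["fetal_level"]
        for _, r in peaks[(peaks["chrom"] == chrom) & (peaks["extra_mcg_loss"] > 0)].iterrows():
            sel = (pos >= r["start"]) & (pos < r["end"])
            vec[sel] = r["extra_mcg_loss"]
        exp = dmvs[(dmvs["chrom"] == chrom) & dmvs["expanded"]]
        for _, r in exp.iterrows():
            sel = ((pos >= r["cko_start"]) & (pos < r["start"])) | (
                (pos >= r["end"]) & (pos < r["cko_end"])
            )
            vec[sel] = 40.0
        out[chrom] = vec
    return out


def _expected_ch_levels(
    config: SimulationConfig,
    genome: Genome,
    severity: dict[str, np.ndarray],
    gmult: dict[str, np.ndarray],
    loss: dict[str, np.ndarray],
) -> dict[tuple[str, str], dict[str, np.ndarray]]:
    """Per-site expected %mCH per (stage, genotype), calibrated to targets."""
    weights = {}
    total = 0.0
    count = 0
    for chrom, pos in genome.ch_sites.items():
        blocks = (pos // config.block_size).astype(int)
        w = (
            severity[chrom][blocks]
            * gmult[chrom]
            * (1.0 + config.mch_loss_coupling * np.minimum(loss[chrom], 40.0))
        )
        weights[chrom] = w
        total += float(w.sum())
        count += len(w)
    wmean = total / max(count, 1)
    out = {}
    for stage in config.stages:
        for genotype, target in (
            ("control", stage.control_mch), ("cKO", stage.cko_mch),
        ):
            scale = target / wmean
            out[(stage.label, genotype)] = {
                c: np.clip(scale * w, 0.0, 100.0) for c, w in weights.items()
            }
    return out


def _sample_counts(
    rng: np.random.Generator,
    p_percent: np.ndarray,
    config: SimulationConfig,
    strands: int = 1,
):
    # a strand-collapsed CG dinucleotide accumulates basecalls from both
    # strands, so its depth is twice the per-strand genome coverage
    k = config.coverage_dispersion * strands
    mu = config.coverage_mean * strands
    h = rng.negative_binomial(k, k / (k + mu), len(p_percent))
    p_obs = (p_percent / 100.0) * (1.0 - config.ncr) + config.ncr
    m = rng.binomial(h, p_obs)
    return m, h


def simulate_methylomes(
    config: SimulationConfig, genome: Genome
) -> tuple[dict[tuple[str, str, int], MethylomeSample], TruthTable]:
    """Per-(genotype, stage, replicate) bisulfite count tables + truth.

    Returns (samples, truth); samples are keyed (genotype, stage_label,
    replicate) with replicate starting at 1.  Replicates share per-site
    true levels and differ only in coverage and basecall sampling.
    """
    layout_rng = np.random.default_rng([config.seed, 17])
    dmrs, dmvs, peaks, genes = _layout(config, genome, layout_rng)
    for frame in (dmrs, dmvs, peaks, genes):
        for _, row in frame.iterrows():
            if row["end"] > genome.chrom_sizes[row["chrom"]] or row["start"] < 0:
                raise ValueError("planted region outside genome")
    severity = _severity_field(config, genome)

    noise_rng = np.random.default_rng([config.seed, 19])
    eps = {
        chrom: noise_rng.normal(0.0, config.site_sd, len(pos))
        for chrom, pos in genome.cg_sites.items()
    }
    gmult = {
        chrom: noise_rng.gamma(config.mch_site_shape, 1.0 / config.mch_site_shape, len(pos))
        for chrom, pos in genome.ch_sites.items()
    }

    cg_levels = _expected_cg_levels(config, genome, severity, dmrs, dmvs, peaks, eps)
    ch_loss = _planted_loss_field(config, genome, dmrs, dmvs, peaks, genome.ch_sites)
    ch_levels = _expected_ch_levels(config, genome, severity, gmult, ch_loss)

    # record true per-feature levels at the adult stage
    adult = config.adult_stage
    def region_mean(levels, chrom, start, end, sites):
        pos = sites[chrom]
        sel = (pos >= start) & (pos < end)
        return float(levels[chrom][sel].mean()) if sel.any() else np.nan

    for label, frame in (("dmr", dmrs), ("peak", peaks), ("gene", genes)):
        ctrl = cg_levels[(adult, "control")]
        cko = cg_levels[(adult, "cKO")]
        frame["mcg_control_true"] = [
            region_mean(ctrl, c, s, e, genome.cg_sites)
            for c, s, e in zip(frame["chrom"], frame["start"], frame["end"])
        ]
        frame["mcg_cko_true"] = [
            region_mean(cko, c, s, e, genome.cg_sites)
            for c, s, e in zip(frame["chrom"], frame["start"], frame["end"])
        ]
        frame["delta_mcg_true"] = frame["mcg_cko_true"] - frame["mcg_control_true"]
    ch_ctrl = ch_levels[(adult, "control")]
    ch_cko = ch_levels[(adult, "cKO")]
    genes["mch_control_true"] = [
        region_mean(ch_ctrl, c, s, e, genome.ch_sites)
        for c, s, e in zip(genes["chrom"], genes["start"], genes["end"])
    ]
    genes["mch_cko_true"] = [
        region_mean(ch_cko, c, s, e, genome.ch_sites)
        for c, s, e in zip(genes["chrom"], genes["start"], genes["end"])
    ]
    genes["delta_mch_true"] = genes["mch_cko_true"] - genes["mch_control_true"]

    truth = TruthTable(
        dmrs=dmrs, dmvs=dmvs, chip_peaks=peaks, genes=genes,
        severity=severity,
        background={
            (s.label, g): float("nan") for s in config.stages for g in GENOTYPES
        },
    )

    samples: dict[tuple[str, str, int], MethylomeSample] = {}
    combo_idx = 0
    for stage in config.stages:
        for genotype in GENOTYPES:
            for rep in range(1, config.n_replicates + 1):
                rng = np.random.default_rng([config.seed, 1000 + combo_idx, rep])
                frames = []
                for chrom in genome.chroms:
                    cg_pos = genome.cg_sites[chrom]
                    m, h = _sample_counts(
                        rng, cg_levels[(stage.label, genotype)][chrom], config,
                        strands=2,
                    )
                    frames.append(
                        pd.DataFrame(
                            {
                                "chrom": chrom,
                                "pos": cg_pos,
                                "strand": "+",
                                "context": "CG",
                                "m": m,
                                "h": h,
                            }
                        )
                    )
                    ch_pos = genome.ch_sites[chrom]
                    m, h = _sample_counts(
                        rng, ch_levels[(stage.label, genotype)][chrom], config
                    )
                    frames.append(
                        pd.DataFrame(
                            {
                                "chrom": chrom,
                                "pos": ch_pos,
                                "strand": genome.ch_strands[chrom],
                                "context": "CH",
                                "m": m,
                                "h": h,
                            }
                        )
                    )
                sites = (
                    pd.concat(frames, ignore_index=True)
                    .sort_values(["chrom", "pos"], kind="mergesort")
                    .reset_index(drop=True)
                )
                samples[(genotype, stage.label, rep)] = MethylomeSample(
                    sites=sites,
                    ncr=config.ncr,
                    meta={"genotype": genotype, "stage": stage.label, "replicate": rep},
                )
            combo_idx += 1
    return samples, truth


# ---------------------------------------------------------------------------
# ChIP tracks
# ---------------------------------------------------------------------------


def simulate_chip(
    config: SimulationConfig, genome: Genome, truth: TruthTable
) -> dict[tuple[str, str, str, int], BinnedSignal]:
    """Poisson bin-count tracks for H3K27me3 and IgG per (genotype, stage, rep).

    Peak enrichment by group: ``stable`` peaks are enriched everywhere;
    ``DevLoss`` only at the first (fetal) stage; ``DevGain`` only at the
    final (adult) stage; ``cKOgain`` everywhere, with an extra strong gain
    in the adult knockout.  In the adult knockout every peak additionally
    responds to the local planted mCG change through the (negative)
    coupling coefficient, producing the genome-wide anti-correlation
    between H3K27me3 fold-change and mCG change.
    """
    cfg = config.chip
    peaks = truth.chip_peaks
    adult = config.adult_stage
    fetal = config.stages[0].label
    adult_params = config.stages[-1]
    bg_delta = adult_params.cko_mcg - adult_params.control_mcg
    expected_fc = np.zeros(len(peaks))
    tracks: dict[tuple[str, str, str, int], BinnedSignal] = {}
    track_idx = 0
    for stage in config.stages:
        for genotype in GENOTYPES:
            # per-peak enrichment factor at this (stage, genotype)
            factors = np.ones(len(peaks))
            for i, row in peaks.iterrows():
                group = row["group"]
                enriched = (
                    group == "stable"
                    or (group == "DevLoss" and stage.label == fetal)
                    or (group == "DevGain" and stage.label == adult)
                    or group == "cKOgain"
                )
                f = cfg.enrichment if enriched else 1.0
                excess = row["delta_mcg_true"] - bg_delta
                if stage.label == adult and genotype == "cKO":
                    f *= 2.0 ** (cfg.coupling * excess)
                factors[i] = f
                if stage.label == adult and genotype == "control":
                    expected_fc[i] = cfg.coupling * excess
            for rep in range(1, config.n_replicates + 1):
                for mark in ("H3K27me3", "IgG"):
                    rng = np.random.default_rng(
                        [config.seed, 2000 + track_idx, rep, 0 if mark == "IgG" else 1]
                    )
                    counts = {}
                    for chrom, length in genome.chrom_sizes.items():
                        n = int(np.ceil(length / cfg.bin_size))
                        lam = np.full(n, cfg.background_per_bin)
                        if mark == "H3K27me3":
                            sub = peaks[peaks["chrom"] == chrom]
                            for i, row in sub.iterrows():
                                b0 = int(row["start"]) // cfg.bin_size
                                b1 = int(row["end"]) // cfg.bin_size
                                lam[b0:b1] = cfg.background_per_bin * factors[i]
                        counts[chrom] = rng.poisson(lam).astype(float)
                    tracks[(mark, genotype, stage.label, rep)] = BinnedSignal(
                        genome=genome,
                        bin_size=cfg.bin_size,
                        counts=counts,
                        library_size=int(sum(v.sum() for v in counts.values())),
                        meta={
                            "mark": mark, "genotype": genotype,
                            "stage": stage.label, "replicate": rep,
                        },
                    )
            track_idx += 1
    truth.chip_peaks["expected_log2fc"] = expected_fc
    truth.chip_peaks["is_dm"] = truth.chip_peaks["group"] == "cKOgain"
    return tracks


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig, genome: Genome, truth: TruthTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene models and an adult-stage count matrix (2 genotypes x replicates).

    log2 mean expression in the knockout is the control value plus
    beta * (gene-body delta-mCH, percentage points) plus planted DE
    effects; counts are negative-binomial per replicate.
    """
    cfg = config.genes
    genes = truth.genes
    rng = np.random.default_rng([config.seed, 29])
    base = rng.lognormal(np.log(cfg.mean_count), cfg.count_log_sd, len(genes))
    de_status = np.array(["non-DE"] * len(genes), dtype=object)
    de_effect = np.zeros(len(genes))
    n_de = int(round(cfg.de_fraction * len(genes)))
    if n_de:
        idx = rng.choice(len(genes), size=n_de, replace=False)
        signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
        de_effect[idx] = signs * cfg.de_log2fc
        de_status[idx] = np.where(signs > 0, "up", "down")
    log2fc = cfg.beta_mch * genes["delta_mch_true"].to_numpy() + de_effect

    cols = {}
    k = 1.0 / cfg.nb_dispersion
    for genotype in GENOTYPES:
        for rep in range(1, config.n_replicates + 1):
            rep_rng = np.random.default_rng(
                [config.seed, 3000, 0 if genotype == "control" else 1, rep]
            )
            depth = rep_rng.lognormal(0.0, 0.1)
            mu = base * depth * (2.0 ** log2fc if genotype == "cKO" else 1.0)
            cols[f"{genotype}_rep{rep}"] = rep_rng.negative_binomial(
                k, k / (k + mu)
            )
    counts = pd.DataFrame(cols, index=genes["gene_id"])
    genes["base_mean"] = base
    rate = base / genes["length"].to_numpy()
    genes["tpm"] = rate / rate.sum() * 1e6
    genes["de_status"] = de_status
    genes["de_log2fc"] = de_effect
    genes["log2fc_total"] = log2fc
    gene_models = genes[
        ["gene_id", "chrom", "strand", "tss", "tes", "start", "end", "length"]
    ].copy()
    return gene_models, counts


# ---------------------------------------------------------------------------
# one-call dataset + emission
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: Genome
    methylomes: dict[tuple[str, str, int], MethylomeSample]
    truth: TruthTable
    chip: dict[tuple[str, str, str, int], BinnedSignal]
    gene_models: pd.DataFrame
    gene_counts: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: genome, methylomes, ChIP tracks, expression."""
    genome = simulate_genome(config)
    methylomes, truth = simulate_methylomes(config, genome)
    chip = simulate_chip(config, genome, truth)
    gene_models, gene_counts = simulate_expression(config, genome, truth)
    return SimulatedDataset(
        config=config, genome=genome, methylomes=methylomes, truth=truth,
        chip=chip, gene_models=gene_models, gene_counts=gene_counts,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Emit the dataset as plain-text files usable by every pipeline stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.config.to_yaml(outdir / "config.yaml")
    write_chrom_sizes(dataset.genome, outdir / "genome.chrom.sizes")
    for (genotype, stage, rep), sample in dataset.methylomes.items():
        write_site_table(
            sample.sites, outdir / f"allc_{genotype}_{stage}_rep{rep}.tsv"
        )
    for (mark, genotype, stage, rep), track in dataset.chip.items():
        write_bedgraph(
            track.to_bedgraph_frame(),
            outdir / f"chip_{mark}_{genotype}_{stage}_rep{rep}.bedgraph",
        )
    dataset.truth.write(outdir)
    for name, frame in (
        ("dmrs", dataset.truth.dmrs),
        ("dmvs", dataset.truth.dmvs),
        ("chip_peaks", dataset.truth.chip_peaks),
    ):
        write_bed(frame[["chrom", "start", "end"]], outdir / f"truth_{name}.bed")
    write_tsv(dataset.gene_models, outdir / "gene_models.tsv")
    dataset.gene_counts.reset_index().to_csv(
        outdir / "gene_counts.tsv", sep="\t", index=False
    )
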