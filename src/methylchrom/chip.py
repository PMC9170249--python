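"""ChIP-seq signal: island peak calling, normalization and differential binding.

Broad repressive marks such as H3K27me3 form domains rather than point
peaks, so calling works island-style: the genome is tiled into fixed bins
(default 200 bp), each bin is scored against a scaled control (IgG) by a
Poisson upper tail, and enriched bins are chained into islands while
tolerating a bounded number of consecutive gap bins (3 for H3K27me3, 1 for
the sharp marks).  Differential regions between conditions are tested with
a negative-binomial Wald test on per-replicate region counts with
median-of-ratios size factors and a method-of-moments common dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import Genome, _merged_lookup, covered_bp_single


@dataclass
class BinnedSignal:
    """Fixed-bin fragment counts for one track."""

    genome: Genome
    bin_size: int
    counts: dict[str, np.ndarray]
    library_size: int
    meta: dict = field(default_factory=dict)

    def n_bins(self, chrom: str) -> int:
        return int(np.ceil(self.genome.chrom_sizes[chrom] / self.bin_size))

    def total_count(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    def to_bedgraph_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, vec in self.counts.items():
            starts = np.arange(len(vec)) * self.bin_size
            ends = np.minimum(starts + self.bin_size, self.genome.chrom_sizes[chrom])
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "value": vec}
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_bedgraph_frame(
        cls, frame: pd.DataFrame, genome: Genome, bin_size: int
    ) -> "BinnedSignal":
        counts = {}
        for chrom, length in genome.chrom_sizes.items():
            n = int(np.ceil(length / bin_size))
            vec = np.zeros(n)
            sub = frame[frame["chrom"] == chrom]
            if len(sub):
                idx = (sub["start"].to_numpy() // bin_size).astype(int)
                vec[idx] = sub["value"].to_numpy()
            counts[chrom] = vec
        return cls(
            genome=genome,
            bin_size=bin_size,
            counts=counts,
            library_size=int(round(sum(v.sum() for v in counts.values()))),
        )


def bin_fragments(
    fragments: pd.DataFrame, genome: Genome, bin_size: int = 200
) -> BinnedSignal:
    """Count fragments into fixed bins by fragment midpoint.

    ``fragments`` is an interval frame; each fragment lands in exactly one
    bin, so the bin counts sum to the library size.
    """
    counts = {
        chrom: np.zeros(int(np.ceil(length / bin_size)))
        for chrom, length in genome.chrom_sizes.items()
    }
    for chrom, sub in fragments.groupby("chrom", sort=False):
        if chrom not in counts:
            raise ValueError(f"fragment on unknown chromosome {chrom}")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts < 0).any() or (ends > genome.chrom_sizes[chrom]).any():
            raise ValueError(f"fragment outside chromosome {chrom}")
        mid = (starts + ends) // 2
        idx = (mid // bin_size).astype(int)
        np.add.at(counts[chrom], idx, 1)
    return BinnedSignal(
        genome=genome,
        bin_size=bin_size,
        counts=counts,
        library_size=int(len(fragments)),
    )


def call_islands(
    treatment: BinnedSignal,
    control: BinnedSignal,
    gaps_allowed: int = 3,
    p_bin: float = 0.01,
    island_fdr: float = 0.05,
) -> pd.DataFrame:
    """Island-style broad peak calling against a scaled control track.

    A bin is eligible when its treatment count beats a Poisson upper tail
    at rate lambda = library-ratio-scaled control, where the control rate is
    floored at the genome-wide control mean so that sparse control bins do
    not produce spurious eligibility.  Eligible bins at most
    ``gaps_allowed + 1`` bins apart chain into one island; the island score
    is the summed -log10 bin p over eligible members, and island
    significance is a Poisson test of the island's total treatment count
    against its total expected rate, BH-corrected across islands.
    """
    if treatment.bin_size != control.bin_size:
        raise ValueError("treatment and control bin grids differ")
    lib_t = max(treatment.library_size, 1)
    lib_c = control.total_count()
    if lib_c == 0:
        # degenerate control: estimate a flat background from the treatment
        n_total = sum(len(v) for v in treatment.counts.values())
        lam_flat = treatment.total_count() / max(n_total, 1)
        control_counts = {
            c: np.full_like(v, lam_flat) for c, v in treatment.counts.items()
        }
        ratio = 1.0
        c_mean = lam_flat
    else:
        control_counts = control.counts
        ratio = lib_t / lib_c
        n_total = sum(len(v) for v in control.counts.values())
        c_mean = lib_c / max(n_total, 1)

    rows = []
    for chrom, tvec in treatment.counts.items():
        cvec = control_counts.get(chrom)
        if cvec is None or len(cvec) != len(tvec):
            raise ValueError(f"bin grids differ on {chrom}")
        lam = ratio * np.maximum(cvec, c_mean)
        pvals = stats.poisson.sf(tvec - 1, lam)
        eligible = np.where(pvals < p_bin)[0]
        if len(eligible) == 0:
            continue
        breaks = np.where(np.diff(eligible) > gaps_allowed + 1)[0]
        bounds = np.concatenate(([0], breaks + 1, [len(eligible)]))
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            first, last = int(eligible[b0]), int(eligible[b1 - 1])
            start = first * treatment.bin_size
            end = min(
                (last + 1) * treatment.bin_size, treatment.genome.chrom_sizes[chrom]
            )
            member = eligible[b0:b1]
            score = float(-np.log10(np.clip(pvals[member], 1e-300, 1.0)).sum())
            total = float(tvec[first : last + 1].sum())
            lam_total = float(lam[first : last + 1].sum())
            p_island = float(stats.poisson.sf(total - 1, lam_total))
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "score": score,
                    "n_eligible": len(member),
                    "p": p_island,
                }
            )
    islands = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "score", "n_eligible", "p"]
    )
    if len(islands) == 0:
        islands["q"] = pd.Series(dtype=float)
        return islands
    # Bin-level pre-selection makes island p-values selection-biased, so BH
    # across islands alone would not control the false-island rate; correct
    # with the total number of genome bins as the effective test count.
    n_tests = sum(len(v) for v in treatment.counts.values())
    p = islands["p"].to_numpy()
    order = np.argsort(p)
    q_sorted = p[order] * n_tests / (np.arange(len(p)) + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    islands["q"] = q
    islands = islands[islands["q"] < island_fdr]
    return islands.sort_values(["chrom", "start"]).reset_index(drop=True)


def region_counts(signal: BinnedSignal, regions: pd.DataFrame) -> np.ndarray:
    """Fragment count per region, prorating bins by bp overlap."""
    out = np.zeros(len(regions))
    bs = signal.bin_size
    for i, (chrom, s, e) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"])
    ):
        vec = signal.counts.get(chrom)
        if vec is None:
            continue
        b0 = int(s) // bs
        b1 = (int(e) - 1) // bs
        total = 0.0
        for b in range(b0, min(b1, len(vec) - 1) + 1):
            bin_start, bin_end = b * bs, min((b + 1) * bs, len(vec) * bs)
            ov = min(bin_end, int(e)) - max(bin_start, int(s))
            if ov > 0:
                total += vec[b] * ov / (bin_end - bin_start)
        out[i] = total
    return out


def rpkm(signal: BinnedSignal, regions: pd.DataFrame, pseudocount: float = 0.5):
    counts = region_counts(signal, regions) + pseudocount
    kb = (regions["end"] - regions["start"]).to_numpy() / 1000.0
    millions = max(signal.library_size, 1) / 1e6
    return counts / (kb * millions)


def rpkm_fold_enrichment(
    signal: BinnedSignal,
    igg: BinnedSignal,
    regions: pd.DataFrame,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Per-region RPKM of the mark over RPKM of the IgG control.

    A pseudocount (default 0.5 fragments) stabilises both numerators.
    """
    return rpkm(signal, regions, pseudocount) / rpkm(igg, regions, pseudocount)


def metaprofile(
    regions: pd.DataFrame,
    signal: BinnedSignal,
    igg: BinnedSignal,
    flank: int = 5000,
    bin_size: int = 200,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean fold-enrichment profile centred on region midpoints.

    Offsets run from -flank to +flank in ``bin_size`` steps; regions whose
    window would truncate at a chromosome edge are dropped.  Bootstrap
    resampling across regions gives a 95% CI per offset (skipped when
    ``n_boot`` = 0).
    """
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    offsets = np.arange(-flank, flank, bin_size)
    windows = []
    for chrom, s, e in zip(regions["chrom"], regions["start"], regions["end"]):
        mid = (int(s) + int(e)) // 2
        w_start, w_end = mid - flank, mid + flank
        if w_start < 0 or w_end > signal.genome.chrom_sizes[chrom]:
            continue
        sub = pd.DataFrame(
            {
                "chrom": chrom,
                "start": mid + offsets,
                "end": mid + offsets + bin_size,
            }
        )
        fe = rpkm_fold_enrichment(signal, igg, sub)
        windows.append(fe)
    if not windows:
        raise ValueError("no usable regions (all truncated at chromosome edges)")
    mat = np.vstack(windows)
    mean = mat.mean(axis=0)
    out = pd.DataFrame({"offset": offsets, "mean": mean})
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, mat.shape[1]))
        for b in range(n_boot):
            idx = rng.integers(0, mat.shape[0], mat.shape[0])
            boots[b] = mat[idx].mean(axis=0)
        out["ci_low"] = np.quantile(boots, 0.025, axis=0)
        out["ci_high"] = np.quantile(boots, 0.975, axis=0)
    return out


# ---------------------------------------------------------------------------
# differential binding
# ---------------------------------------------------------------------------


def _size_factors(mat: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios size factors (columns = samples)."""
    with np.errstate(divide="ignore"):
        log = np.log(mat)
    ref = log.mean(axis=1)
    ok = np.isfinite(ref)
    if ok.sum() == 0:
        return mat.sum(axis=0) / max(mat.sum(axis=0).mean(), 1.0)
    sf = np.exp(np.median(log[ok] - ref[ok, None], axis=0))
    return sf


def call_dm_regions(
    regions: pd.DataFrame,
    counts: np.ndarray,
    condition: np.ndarray,
    fdr: float = 0.05,
    min_total: int = 1,
) -> pd.DataFrame:
    """Differentially modified regions between two conditions.

    ``counts`` is regions x samples; ``condition`` labels each sample
    column (exactly two levels, >= 2 replicates each).  Counts are
    normalised by median-of-ratios size factors; a common negative-binomial
    dispersion is estimated by method of moments across regions, and each
    region gets a Wald test on the difference of log group means.  Regions
    whose total count is below ``min_total`` are left untested.

    Returns the regions with mean_a, mean_b (normalised), log2fc
    (second condition over first), p, q and ``significant``.
    """
    levels = pd.unique(condition)
    if len(levels) != 2:
        raise ValueError("exactly two condition levels required")
    ia = np.where(condition == levels[0])[0]
    ib = np.where(condition == levels[1])[0]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("need >= 2 replicates per condition")
    counts = np.asarray(counts, dtype=float)
    sf = _size_factors(counts)
    norm = counts / sf

    # method-of-moments common dispersion from within-group moments
    mu = np.concatenate([norm[:, ia].mean(axis=1), norm[:, ib].mean(axis=1)])
    var = np.concatenate(
        [norm[:, ia].var(axis=1, ddof=1), norm[:, ib].var(axis=1, ddof=1)]
    )
    ok = mu > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        phis = (var[ok] - mu[ok]) / mu[ok] ** 2
    phis = phis[np.isfinite(phis)]
    # per-region moment estimates are noisy at 2 replicates and clipping
    # them at zero before averaging would inflate the common value; trim
    # symmetrically instead and clip only the pooled estimate
    common = stats.trim_mean(phis, 0.1) if len(phis) > 4 else np.mean(phis)
    phi = float(np.clip(common, 1e-6, 10.0))

    mean_a = norm[:, ia].mean(axis=1)
    mean_b = norm[:, ib].mean(axis=1)
    pc = 0.5
    log2fc = np.log2((mean_b + pc) / (mean_a + pc))
    # delta-method variance of log mean under NB(mu, phi)
    var_log_a = (1.0 / np.maximum(mean_a, pc) + phi) / len(ia)
    var_log_b = (1.0 / np.maximum(mean_b, pc) + phi) / len(ib)
    z = (np.log(mean_b + pc) - np.log(mean_a + pc)) / np.sqrt(var_log_a + var_log_b)
    p = 2.0 * stats.norm.sf(np.abs(z))

    tested = counts.sum(axis=1) >= min_total
    out = regions.reset_index(drop=True).copy()
    out["mean_a"] = mean_a
    out["mean_b"] = mean_b
    out["log2fc"] = log2fc
    out["p"] = np.where(tested, p, np.nan)
    out["q"] = np.nan
    out["significant"] = False
    if tested.any():
        _, q, _, _ = multipletests(p[tested], method="fdr_bh")
        out.loc[tested, "q"] = q
        out.loc[tested, "significant"] = q < fdr
    return out


# ---------------------------------------------------------------------------
# peak grouping and promoter classes
# ---------------------------------------------------------------------------


def assign_peak_groups(
    peaks: pd.DataFrame,
    dev_loss: pd.DataFrame,
    dev_gain: pd.DataFrame,
    cko_dm: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each peak to DevLoss / DevGain / cKO / other.

    DevLoss and DevGain are developmental differential sets (mark lost or
    gained between fetal and adult stages); cKO is the genotype
    differential set at the adult stage.  A peak overlapping several sets
    goes to cKO first (genotype effect takes precedence), then to the
    developmental sets; assignment conflicts are counted in the ``meta``
    attribute of the result.
    """
    lookups = {
        "cKO": _merged_lookup(cko_dm) if len(cko_dm) else {},
        "DevLoss": _merged_lookup(dev_loss) if len(dev_loss) else {},
        "DevGain": _merged_lookup(dev_gain) if len(dev_gain) else {},
    }
    groups = []
    n_conflict = 0
    for chrom, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"]):
        hits = [
            name
            for name, lk in lookups.items()
            if covered_bp_single(chrom, int(s), int(e), lk) > 0
        ]
        if len(hits) > 1:
            n_conflict += 1
        groups.append(hits[0] if hits else "other")
    out = peaks.reset_index(drop=True).copy()
    out["group"] = groups
    out.attrs["n_group_conflicts"] = n_conflict
    return out


def log10_cpm(signal: BinnedSignal, regions: pd.DataFrame) -> np.ndarray:
    """Per-region log10(CPM + 1)."""
    counts = region_counts(signal, regions)
    cpm = counts / (max(signal.library_size, 1) / 1e6)
    return np.log10(cpm + 1.0)


def peak_group_summary(
    peaks_with_group: pd.DataFrame, value_columns: list[str]
) -> pd.DataFrame:
    """Per-group means of the given per-peak delta columns."""
    return (
        peaks_with_group.groupby("group")[value_columns]
        .agg(["mean", "count"])
        .reset_index()
    )


def classify_cgi_promoters(
    promoters: pd.DataFrame,
    cgi: pd.DataFrame,
    k4_peaks: pd.DataFrame,
    k27_peaks: pd.DataFrame,
) -> pd.DataFrame:
    """Classify CGI promoters as bivalent / active / other.

    A promoter (TSS +/- 2 kb window, already built strand-aware by the
    caller) is a CGI promoter when it overlaps at least one CpG island.
    Bivalent: overlaps both H3K4me3 and H3K27me3 peaks; active: H3K4me3
    only; everything else (including H3K27me3-only): other.  Non-CGI
    promoters are dropped.
    """
    cgi_lk = _merged_lookup(cgi) if len(cgi) else {}
    k4_lk = _merged_lookup(k4_peaks) if len(k4_peaks) else {}
    k27_lk = _merged_lookup(k27_peaks) if len(k27_peaks) else {}
    rows = []
    for _, row in promoters.iterrows():
        c, s, e = row["chrom"], int(row["start"]), int(row["end"])
        if covered_bp_single(c, s, e, cgi_lk) == 0:
            continue
        has_k4 = covered_bp_single(c, s, e, k4_lk) > 0
        has_k27 = covered_bp_single(c, s, e, k27_lk) > 0
        if has_k4 and has_k27:
            klass = "bivalent"
        elif has_k4:
            klass = "active"
        else:
            klass = "other"
        rows.append({**row.to_dict(), "promoter_class": klass})
    return pd.DataFrame(rows, columns=list(promoters.columns) + ["promoter_class"])


def correlate_fc_vs_deltamc(
    log2fc: np.ndarray, delta_mcg: np.ndarray, n_bins: int = 20
):
    """Spearman correlation of per-peak signal fold-change vs mCG change.

    Returns (r, p, curve) where curve is a frame of quantile-bin means of
    both variables — a smooth-line stand-in for display.  Requires >= 10
    peaks and non-constant inputs.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    delta_mcg = np.asarray(delta_mcg, dtype=float)
    ok = np.isfinite(log2fc) & np.isfinite(delta_mcg)
    log2fc, delta_mcg = log2fc[ok], delta_mcg[ok]
    if len(log2fc) < 10:
        raise ValueError("need at least 10 peaks")
    if np.ptp(log2fc) == 0 or np.ptp(delta_mcg) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.spearmanr(log2fc, delta_mcg)
    order = np.argsort(delta_mcg, kind="mergesort")
    edges = np.array_split(order, min(n_bins, len(order)))
    curve = pd.DataFrame(
        {
            "delta_mcg_mean": [delta_mcg[idx].mean() for idx in edges],
            "log2fc_mean": [log2fc[idx].mean() for idx in edges],
            "n": [len(idx) for idx in edges],
        }
    )
    return float(r), float(p), curve
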