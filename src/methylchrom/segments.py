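"""Methylome segmentation: DMS/DMR calling, low-methylation segments, DMVs.

Differentially methylated regions (DMRs) are built bottom-up: a per-CG-site
exact test on pooled replicate counts marks differentially methylated sites
(DMS); same-direction significant sites within a gap limit are chained into
regions; regions must contain a minimum number of DMS and pass region-level
effect-size and FDR filters.

DNA methylation valleys (DMVs) come from the opposite direction: maximal
runs of consecutive low-methylation CG sites form undermethylated (UMR) /
low-methylated (LMR) segments, and UMRs at least 5 kb long with mean mCG
at most 15% are valleys.  Valleys called in two conditions are compared by
a six-way topological classification (consistent / expanded / shrunken /
overhang / unique to either condition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylome import MethylomeSample, adjust_ncr, pool_samples
from .regions import _merged_lookup, covered_bp_single

CG_SITE_WIDTH = 2  # CG dinucleotide; registry is strand-collapsed

DMV_CATEGORIES = (
    "consistent",
    "expanded",
    "shrunken",
    "overhang",
    "cKO_unique",
    "control_unique",
)


# ---------------------------------------------------------------------------
# DMS / DMR
# ---------------------------------------------------------------------------


def call_dms(
    group_a: list[MethylomeSample],
    group_b: list[MethylomeSample],
    context: str = "CG",
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Per-site differential methylation between two sample groups.

    Replicate counts are pooled within each group; each site covered in
    both groups gets a two-sided Fisher exact test on the 2x2 table
    [[m_a, u_a], [m_b, u_b]] of methylated vs unmethylated basecalls.
    Benjamini-Hochberg across all tested sites; ``significant`` iff
    q < ``fdr``.  Sites covered in only one group are left untested
    (NaN p/q).

    Returns chrom, pos, m_a, h_a, m_b, h_b, level_a, level_b, p, q,
    significant, direction ("hyper" when group_b is higher, "hypo" lower).
    """
    pooled_a = pool_samples(group_a)
    pooled_b = pool_samples(group_b)
    sa = pooled_a.context_sites(context)[["chrom", "pos", "m", "h"]]
    sb = pooled_b.context_sites(context)[["chrom", "pos", "m", "h"]]
    merged = pd.merge(sa, sb, on=["chrom", "pos"], how="outer", suffixes=("_a", "_b"))
    for col in ("m_a", "h_a", "m_b", "h_b"):
        merged[col] = merged[col].fillna(0).astype(np.int64)
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    tested = (merged["h_a"] > 0) & (merged["h_b"] > 0)

    ma = merged.loc[tested, "m_a"].to_numpy()
    ha = merged.loc[tested, "h_a"].to_numpy()
    mb = merged.loc[tested, "m_b"].to_numpy()
    hb = merged.loc[tested, "h_b"].to_numpy()
    p = _fisher_two_sided(ma, ha, mb, hb)

    merged["p"] = np.nan
    merged["q"] = np.nan
    merged["significant"] = False
    merged.loc[tested, "p"] = p
    if tested.any():
        _, q, _, _ = multipletests(p, method="fdr_bh")
        merged.loc[tested, "q"] = q
        merged.loc[tested, "significant"] = q < fdr
    with np.errstate(invalid="ignore", divide="ignore"):
        merged["level_a"] = 100.0 * merged["m_a"] / merged["h_a"].replace(0, np.nan)
        merged["level_b"] = 100.0 * merged["m_b"] / merged["h_b"].replace(0, np.nan)
    merged["direction"] = np.where(
        merged["level_b"] >= merged["level_a"], "hyper", "hypo"
    )
    return merged


def _fisher_two_sided(ma, ha, mb, hb) -> np.ndarray:
    """Vectorised two-sided Fisher exact p for tables [[ma, ha-ma], [mb, hb-mb]].

    Two-sided p is the hypergeometric mass of all outcomes no more probable
    than the observed one (the standard "minimum-likelihood" definition).
    """
    out = np.ones(len(ma))
    for i in range(len(ma)):
        k, n1, n2 = int(ma[i]), int(ha[i]), int(hb[i])
        K = k + int(mb[i])  # total methylated calls
        N = n1 + n2
        lo = max(0, K - n2)
        hi = min(K, n1)
        support = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(support, N, K, n1)
        obs = pmf[k - lo]
        out[i] = float(pmf[pmf <= obs * (1 + 1e-9)].sum())
    return np.clip(out, 0.0, 1.0)


def segment_dmrs(
    dms: pd.DataFrame,
    max_gap: int = 500,
    min_sites: int = 3,
    site_width: int = CG_SITE_WIDTH,
) -> pd.DataFrame:
    """Chain significant same-direction sites into candidate DMRs.

    Maximal runs of significant sites of one direction with consecutive
    member sites at most ``max_gap`` bp apart; runs with fewer than
    ``min_sites`` members are discarded.  Region boundaries span the first
    member site to the last (end exclusive = last position + site width).

    Region levels are pooled counts over *all tested* sites inside the
    span; the region q is the minimum member-site q (conservative), with a
    Stouffer-combined member p recorded alongside.
    """
    rows = []
    sig = dms[dms["significant"]].copy()
    for (chrom, direction), sub in sig.groupby(["chrom", "direction"], sort=False):
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        qs = sub["q"].to_numpy()[order]
        ps = sub["p"].to_numpy()[order]
        if len(pos) == 0:
            continue
        breaks = np.where(np.diff(pos) > max_gap)[0]
        bounds = np.concatenate(([0], breaks + 1, [len(pos)]))
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if b1 - b0 < min_sites:
                continue
            start = int(pos[b0])
            end = int(pos[b1 - 1]) + site_width
            members_q = qs[b0:b1]
            members_p = np.clip(ps[b0:b1], 1e-300, 1.0)
            z = stats.norm.isf(members_p / 2.0)  # one-sided evidence scale
            stouffer_p = float(stats.norm.sf(z.sum() / np.sqrt(len(z))))
            span = dms[
                (dms["chrom"] == chrom) & (dms["pos"] >= start) & (dms["pos"] < end)
            ]
            ha, hb = int(span["h_a"].sum()), int(span["h_b"].sum())
            level_a = 100.0 * span["m_a"].sum() / ha if ha else np.nan
            level_b = 100.0 * span["m_b"].sum() / hb if hb else np.nan
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_dms": int(b1 - b0),
                    "level_a": level_a,
                    "level_b": level_b,
                    "delta": level_b - level_a,
                    "q": float(members_q.min()),
                    "p_stouffer": stouffer_p,
                    "direction": direction,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n_dms", "level_a", "level_b",
            "delta", "q", "p_stouffer", "direction",
        ],
    )
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def filter_dmrs(
    candidates: pd.DataFrame,
    min_delta: float = 30.0,
    fdr: float = 0.01,
    drop_hyper: bool = False,
) -> pd.DataFrame:
    """Effect-size and FDR post-filter on candidate DMRs.

    Retained iff |delta| >= ``min_delta`` percentage points of mCG and
    region q < ``fdr``.  ``drop_hyper`` additionally discards regions where
    the second group gained methylation (used when gains are attributed to
    technical noise).
    """
    keep = (candidates["delta"].abs() >= min_delta) & (candidates["q"] < fdr)
    if drop_hyper:
        keep &= candidates["direction"] == "hypo"
    return candidates[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# UMR / LMR / DMV
# ---------------------------------------------------------------------------


def segment_low_methylation(
    sample: MethylomeSample,
    m: float = 0.3,
    n: int = 7,
    max_gap: int = 500,
    umr_min_cg: int = 30,
    site_width: int = CG_SITE_WIDTH,
) -> pd.DataFrame:
    """Undermethylated / low-methylated segment detection.

    A covered CG site is "low" when its NCR-adjusted level is at most
    ``100*m`` percent.  Maximal runs of low sites consecutive in site
    order (runs broken by any covered non-low site; zero-coverage sites
    are ignored) become segments spanning first to last member site.
    Adjacent segments at most ``max_gap`` bp apart are merged only when
    the merged span still satisfies the level cutoff as a pooled region —
    this tolerates an isolated noisy site inside a low region without
    ever bridging genuinely methylated stretches.  Segments with fewer
    than ``n`` low sites are dropped.  Class is UMR when the segment
    holds at least ``umr_min_cg`` low CG sites, else LMR.

    Returns chrom, start, end, n_cg, mean_mCG (pooled adjusted percent over
    all covered CG sites in the span), klass.
    """
    cg = sample.context_sites("CG")
    cg = cg[cg["h"] > 0]
    rows = []
    cutoff = 100.0 * m
    for chrom, sub in cg.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        mm = sub["m"].to_numpy().astype(float)
        hh = sub["h"].to_numpy().astype(float)
        level = adjust_ncr(100.0 * mm / hh, 100.0 * sample.ncr)
        low = level <= cutoff
        # maximal runs of consecutive low sites
        segs: list[tuple[int, int, int]] = []  # (first_idx, last_idx, n_low)
        i = 0
        while i < len(pos):
            if low[i]:
                j = i
                while j + 1 < len(pos) and low[j + 1]:
                    j += 1
                segs.append((i, j, j - i + 1))
                i = j + 1
            else:
                i += 1

        def span_level(a: int, b: int) -> float:
            sel = slice(a, b + 1)
            return float(
                adjust_ncr(
                    100.0 * mm[sel].sum() / hh[sel].sum(), 100.0 * sample.ncr
                )
            )

        merged: list[list[int]] = []
        for a, b, k in segs:
            if (
                merged
                and pos[a] - (pos[merged[-1][1]] + site_width) <= max_gap
                and span_level(merged[-1][0], b) <= cutoff
            ):
                merged[-1][1] = b
                merged[-1][2] += k
            else:
                merged.append([a, b, k])
        for a, b, k in merged:
            if k < n:
                continue
            start = int(pos[a])
            end = int(pos[b]) + site_width
            span = (pos >= start) & (pos < end)
            mean = float(
                adjust_ncr(
                    100.0 * mm[span].sum() / hh[span].sum(), 100.0 * sample.ncr
                )
            )
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_cg": int(k),
                    "mean_mCG": mean,
                    "klass": "UMR" if k >= umr_min_cg else "LMR",
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_cg", "mean_mCG", "klass"]
    )


def call_dmvs(
    umrs: pd.DataFrame,
    min_len: int = 5000,
    max_mean: float = 15.0,
    pmd_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """DNA methylation valleys: UMRs >= ``min_len`` bp with mean mCG <= ``max_mean``.

    An optional PMD mask (BED-style frame) removes valleys overlapping
    partially methylated domains.
    """
    dmv = umrs[
        (umrs["klass"] == "UMR")
        & ((umrs["end"] - umrs["start"]) >= min_len)
        & (umrs["mean_mCG"] <= max_mean)
    ].reset_index(drop=True)
    if pmd_mask is not None and len(pmd_mask) and len(dmv):
        lookup = _merged_lookup(pmd_mask)
        keep = [
            covered_bp_single(c, int(s), int(e), lookup) == 0
            for c, s, e in zip(dmv["chrom"], dmv["start"], dmv["end"])
        ]
        dmv = dmv[keep].reset_index(drop=True)
    return dmv


def _classify_pair(
    a_start: int, a_end: int, b_start: int, b_end: int, slack: int = 0
) -> str:
    """Six-way topology of a cKO valley (a) against a control valley (b)."""
    if max(a_start, b_start) >= min(a_end, b_end):
        return "cKO_unique"
    if abs(a_start - b_start) <= slack and abs(a_end - b_end) <= slack:
        return "consistent"
    if a_start <= b_start and a_end >= b_end:
        return "expanded"
    if b_start <= a_start and b_end >= a_end:
        return "shrunken"
    return "overhang"


def compare_dmv_sets(
    cko: pd.DataFrame, ctrl: pd.DataFrame, slack: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Six-category cross-condition DMV comparison.

    Each valley of either condition receives exactly one category:
    ``consistent`` (same interval in both, within ``slack`` bp per
    boundary), ``expanded`` (wider in cKO: the cKO valley contains its
    control partner), ``shrunken`` (wider in control), ``overhang``
    (partial overlap, neither contains the other), or unique to one
    condition.  When a valley overlaps several partners, the
    largest-overlap partner decides the category.

    Returns (per-valley table with ``condition`` and ``category`` columns,
    per-category summary with counts and total bp per condition).
    """
    for name, frame in (("cKO", cko), ("control", ctrl)):
        if len(frame) > 1:
            srt = frame.sort_values(["chrom", "start"])
            same = srt["chrom"].to_numpy()[1:] == srt["chrom"].to_numpy()[:-1]
            ov = srt["start"].to_numpy()[1:] < srt["end"].to_numpy()[:-1]
            if np.any(same & ov):
                raise ValueError(f"{name} DMV set contains overlapping intervals")

    def best_partner(row, other: pd.DataFrame):
        cand = other[
            (other["chrom"] == row["chrom"])
            & (other["start"] < row["end"])
            & (other["end"] > row["start"])
        ]
        if len(cand) == 0:
            return None
        ov = np.minimum(cand["end"], row["end"]) - np.maximum(cand["start"], row["start"])
        return cand.iloc[int(np.argmax(ov.to_numpy()))]

    rows = []
    for _, row in cko.iterrows():
        partner = best_partner(row, ctrl)
        if partner is None:
            cat = "cKO_unique"
        else:
            cat = _classify_pair(
                int(row["start"]), int(row["end"]),
                int(partner["start"]), int(partner["end"]), slack,
            )
        rows.append({**row[["chrom", "start", "end"]].to_dict(),
                     "condition": "cKO", "category": cat})
    for _, row in ctrl.iterrows():
        partner = best_partner(row, cko)
        if partner is None:
            cat = "control_unique"
        else:
            # classify from the cKO perspective with roles swapped back
            cat = _classify_pair(
                int(partner["start"]), int(partner["end"]),
                int(row["start"]), int(row["end"]), slack,
            )
        rows.append({**row[["chrom", "start", "end"]].to_dict(),
                     "condition": "control", "category": cat})
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "condition", "category"])
    summary_rows = []
    for cond in ("cKO", "control"):
        sub = table[table["condition"] == cond]
        for cat in DMV_CATEGORIES:
            cs = sub[sub["category"] == cat]
            summary_rows.append(
                {
                    "condition": cond,
                    "category": cat,
                    "count": len(cs),
                    "total_bp": int((cs["end"] - cs["start"]).sum()),
                }
            )
    return table, pd.DataFrame(summary_rows)


def annotate_and_sort_dmvs(
    dmvs: pd.DataFrame,
    dm_regions: pd.DataFrame | None = None,
    de_genes: pd.DataFrame | None = None,
    mcg_levels: pd.DataFrame | None = None,
    signal_means: pd.DataFrame | None = None,
    de_min_abs_logfc: float = 0.2,
    mcg_flag_cutoff: float = 30.0,
) -> pd.DataFrame:
    """Annotate valleys and order them for cross-condition display.

    Annotations: whether (and what fraction of their length) valleys
    overlap a differential-H3K27me3 region; whether they overlap an up- or
    down-regulated DE gene with |log2FC| > ``de_min_abs_logfc``; per-sample
    mean-mCG flags (> ``mcg_flag_cutoff`` percent); the mean log2FC of
    genes fully contained in each valley (NaN when none).  The sort is
    lexicographic on those keys (DM overlap first, then DE overlap, then
    mCG flags, then mean chromatin signal); valleys without contained genes
    sort after valleys with a defined mean logFC at equal keys.

    ``de_genes`` needs chrom, start, end, log2fc, status columns;
    ``mcg_levels``/``signal_means`` are per-valley columns aligned to
    ``dmvs`` by position.
    """
    out = dmvs.reset_index(drop=True).copy()
    n = len(out)
    length = (out["end"] - out["start"]).to_numpy() if n else np.array([])

    if dm_regions is not None and len(dm_regions):
        lookup = _merged_lookup(dm_regions)
        cov = np.array(
            [
                covered_bp_single(c, int(s), int(e), lookup)
                for c, s, e in zip(out["chrom"], out["start"], out["end"])
            ]
        )
        out["fraction_dm"] = cov / np.maximum(length, 1)
    else:
        out["fraction_dm"] = 0.0
    out["overlaps_dm"] = out["fraction_dm"] > 0

    out["overlaps_up_de"] = False
    out["overlaps_down_de"] = False
    out["mean_gene_logfc"] = np.nan
    if de_genes is not None and len(de_genes):
        strong = de_genes[de_genes["log2fc"].abs() > de_min_abs_logfc]
        for i in range(n):
            c, s, e = out.at[i, "chrom"], out.at[i, "start"], out.at[i, "end"]
            hits = strong[
                (strong["chrom"] == c) & (strong["start"] < e) & (strong["end"] > s)
            ]
            out.at[i, "overlaps_up_de"] = bool((hits["status"] == "up").any())
            out.at[i, "overlaps_down_de"] = bool((hits["status"] == "down").any())
            contained = de_genes[
                (de_genes["chrom"] == c)
                & (de_genes["start"] >= s)
                & (de_genes["end"] <= e)
            ]
            if len(contained):
                out.at[i, "mean_gene_logfc"] = float(contained["log2fc"].mean())

    flag_cols: list[str] = []
    if mcg_levels is not None:
        for col in mcg_levels.columns:
            flag = f"mcg_gt_{col}"
            out[flag] = mcg_levels[col].to_numpy() > mcg_flag_cutoff
            flag_cols.append(flag)
    signal_cols: list[str] = []
    if signal_means is not None:
        for col in signal_means.columns:
            out[f"mean_{col}"] = signal_means[col].to_numpy()
            signal_cols.append(f"mean_{col}")

    out["_has_logfc"] = ~out["mean_gene_logfc"].isna()
    keys = (
        ["overlaps_dm", "overlaps_up_de", "overlaps_down_de"]
        + flag_cols
        + ["_has_logfc"]
        + signal_cols
    )
    out = out.sort_values(keys, ascending=[False] * len(keys), kind="mergesort")
    return out.drop(columns="_has_logfc").reset_index(drop=True)
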