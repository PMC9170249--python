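"""Gene-level methylation/expression integration.

Expression is handled as a genes x samples count matrix.  The differential
expression machinery is a documented negative-binomial stand-in for the
usual count-model packages: CPM filtering, a trimmed-mean-of-M-values
(TMM) scale-factor estimate, moment-based dispersion with shrinkage toward
a common value, and an exact conditional NB test on group totals.

Integration with the methylome side works on pooled-count gene-body
levels: per-gene methylation differences are related to expression
fold-changes via decile curves, flanking profiles around TSS/TES, an
explainable-variance decomposition against the replicate ceiling, and
expression-matched control gene selection by propensity score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from .methylome import MethylomeSample, adjust_ncr

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tes"]


def gene_body_bounds(gene: pd.Series) -> tuple[int, int]:
    """Genomic [start, end) of the gene body regardless of strand."""
    tss, tes = int(gene["tss"]), int(gene["tes"])
    if tss == tes:
        raise ValueError(f"gene {gene.get('gene_id')} has tss == tes")
    return (tss, tes) if tss < tes else (tes, tss)


# ---------------------------------------------------------------------------
# expression: filtering, normalisation, DE
# ---------------------------------------------------------------------------


def cpm(counts: pd.DataFrame, lib_sizes: np.ndarray | None = None) -> pd.DataFrame:
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).to_numpy()
    return counts / lib_sizes * 1e6


def filter_and_normalize(
    counts: pd.DataFrame,
    min_cpm: float = 2.0,
    min_samples: int = 2,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> dict:
    """Expression filter plus TMM-style scale factors.

    Genes are kept when their CPM exceeds ``min_cpm`` in at least
    ``min_samples`` samples.  Scale factors are trimmed means of per-gene
    log2 ratios (M values) against a reference sample, trimming the most
    extreme ``trim_m`` of M and ``trim_a`` of average-abundance values on
    each computation; factors are normalised to geometric mean 1 so the
    effective library size is ``lib * factor``.

    Returns dict with keys ``counts`` (kept genes), ``lib_sizes``,
    ``factors``, ``effective_lib_sizes``, ``cpm`` (normalised CPM).
    """
    lib = counts.sum(axis=0).to_numpy().astype(float)
    if (lib == 0).any():
        raise ValueError("all-zero sample in the count matrix")
    raw_cpm = cpm(counts)
    keep = (raw_cpm > min_cpm).sum(axis=1) >= min_samples
    kept = counts[keep]

    kcpm = cpm(kept, lib)
    # reference = sample whose upper quartile is closest to the mean UQ
    uq = kcpm.quantile(0.75, axis=0).to_numpy()
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = kcpm.iloc[:, ref_idx].to_numpy()
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        obs = kcpm.iloc[:, j].to_numpy()
        ok = (obs > 0) & (ref > 0)
        if ok.sum() < 10:
            continue
        m = np.log2(obs[ok] / ref[ok])
        a = 0.5 * np.log2(obs[ok] * ref[ok])
        m_lo, m_hi = np.quantile(m, [trim_m, 1 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1 - trim_a])
        sel = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if sel.sum():
            factors[j] = 2.0 ** np.mean(m[sel])
    factors = factors / np.exp(np.mean(np.log(factors)))
    eff = lib * factors
    return {
        "counts": kept,
        "lib_sizes": lib,
        "factors": factors,
        "effective_lib_sizes": eff,
        "cpm": kept / eff * 1e6,
    }


def _exact_nb_test(sa: int, sb: int, na: int, nb: int, phi: float) -> float:
    """Exact conditional NB test of equal means given the grand total.

    Group totals are NB with shape r = n/phi each; conditioned on
    sa + sb = S, the distribution of sa is negative hypergeometric and
    independent of the mean.  Two-sided p sums the probabilities of all
    outcomes no more likely than the observed split.
    """
    S = sa + sb
    if S == 0:
        return 1.0
    ra = na / max(phi, 1e-8)
    rb = nb / max(phi, 1e-8)
    k = np.arange(S + 1)
    logw = (
        gammaln(k + ra) - gammaln(k + 1) - gammaln(ra)
        + gammaln(S - k + rb) - gammaln(S - k + 1) - gammaln(rb)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    obs = w[sa]
    return float(np.clip(w[w <= obs * (1 + 1e-9)].sum(), 0.0, 1.0))


def estimate_dispersions(
    pseudo: np.ndarray, groups: list[np.ndarray], prior_weight: float = 20.0
) -> np.ndarray:
    """Per-gene NB dispersions: method of moments, shrunk to the common value."""
    mus, vars = [], []
    for idx in groups:
        mus.append(pseudo[:, idx].mean(axis=1))
        vars.append(pseudo[:, idx].var(axis=1, ddof=1))
    mu = np.mean(mus, axis=0)
    var = np.mean(vars, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (var - mu) / mu**2
    raw = np.where(np.isfinite(raw), np.clip(raw, 0.0, 5.0), 0.0)
    common = float(np.mean(stats.trim_mean(raw, 0.1))) if len(raw) > 4 else float(
        np.mean(raw)
    )
    n_obs = sum(len(g) for g in groups)
    shrunk = (prior_weight * common + n_obs * raw) / (prior_weight + n_obs)
    return np.clip(shrunk, 1e-6, 5.0)


def call_de(
    counts: pd.DataFrame,
    condition: np.ndarray,
    effective_lib_sizes: np.ndarray | None = None,
    fdr: float = 0.05,
    min_fc: float = 1.2,
) -> pd.DataFrame:
    """Differential expression between two conditions (>= 2 replicates each).

    Counts are equalised to a common effective library size (pseudo
    counts), dispersions are moment-estimated and shrunk toward the common
    value, and each gene gets an exact conditional NB test on group
    totals.  BH across genes; ``status`` is "up"/"down" iff q < ``fdr``
    and |FC| > ``min_fc`` (up = higher in the second condition level).
    """
    levels = pd.unique(condition)
    if len(levels) != 2:
        raise ValueError("exactly two condition levels required")
    ia = np.where(condition == levels[0])[0]
    ib = np.where(condition == levels[1])[0]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("need >= 2 replicates per condition")
    mat = counts.to_numpy(dtype=float)
    if effective_lib_sizes is None:
        effective_lib_sizes = mat.sum(axis=0)
    eff = np.asarray(effective_lib_sizes, dtype=float)
    common_lib = np.exp(np.mean(np.log(eff)))
    pseudo = np.rint(mat * (common_lib / eff)).astype(np.int64)

    phi = estimate_dispersions(pseudo.astype(float), [ia, ib])
    sa = pseudo[:, ia].sum(axis=1)
    sb = pseudo[:, ib].sum(axis=1)
    p = np.array(
        [
            _exact_nb_test(int(sa[g]), int(sb[g]), len(ia), len(ib), float(phi[g]))
            for g in range(len(sa))
        ]
    )
    mean_a = pseudo[:, ia].mean(axis=1)
    mean_b = pseudo[:, ib].mean(axis=1)
    pc = 0.5
    log2fc = np.log2((mean_b + pc) / (mean_a + pc))
    _, q, _, _ = multipletests(p, method="fdr_bh")
    status = np.where(
        (q < fdr) & (np.abs(log2fc) > np.log2(min_fc)),
        np.where(log2fc > 0, "up", "down"),
        "non-DE",
    )
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "status": status,
        }
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# gene-body methylation
# ---------------------------------------------------------------------------


def gene_body_level(
    gene: pd.Series, sample: MethylomeSample, context: str
) -> float:
    """Pooled-count NCR-adjusted percent level over the gene body.

    NaN when no covered site of the context falls inside the body; the
    result is strand-independent by construction.
    """
    start, end = gene_body_bounds(gene)
    sub = sample.context_sites(context)
    sub = sub[(sub["chrom"] == gene["chrom"]) & (sub["pos"] >= start) & (sub["pos"] < end)]
    h = int(sub["h"].sum())
    if h == 0:
        return float("nan")
    return float(adjust_ncr(100.0 * sub["m"].sum() / h, 100.0 * sample.ncr))


def delta_gene_body(
    genes: pd.DataFrame,
    sample_a: MethylomeSample,
    sample_b: MethylomeSample,
    context: str,
) -> pd.Series:
    """Per-gene gene-body level difference (b minus a), NaN where uncovered."""
    deltas = {}
    for _, gene in genes.iterrows():
        la = gene_body_level(gene, sample_a, context)
        lb = gene_body_level(gene, sample_b, context)
        deltas[gene["gene_id"]] = lb - la
    return pd.Series(deltas, name=f"delta_m{context}")


def flank_profile(
    genes: pd.DataFrame,
    sample: MethylomeSample,
    context: str,
    anchor: str = "tss",
    flank: int = 100_000,
    bin_size: int = 1000,
) -> pd.DataFrame:
    """Strand-oriented mean methylation profile around TSS or TES.

    Offsets are in bp relative to the anchor, negative = upstream in the
    gene's orientation.  Per-offset means are taken across genes with any
    coverage in that bin; the 95% CI is a normal approximation across
    genes (degenerate and flagged NaN when only one gene contributes).
    """
    if anchor not in ("tss", "tes"):
        raise ValueError("anchor must be 'tss' or 'tes'")
    offsets = np.arange(-flank, flank, bin_size)
    per_gene = []
    sub_all = sample.context_sites(context)
    for _, gene in genes.iterrows():
        a = int(gene[anchor])
        strand = gene["strand"]
        sub = sub_all[sub_all["chrom"] == gene["chrom"]]
        pos = sub["pos"].to_numpy()
        rel = (pos - a) if strand == "+" else (a - pos - 1)
        ok = (rel >= -flank) & (rel < flank)
        idx = ((rel[ok] + flank) // bin_size).astype(int)
        msum = np.zeros(len(offsets))
        hsum = np.zeros(len(offsets))
        np.add.at(msum, idx, sub["m"].to_numpy()[ok])
        np.add.at(hsum, idx, sub["h"].to_numpy()[ok])
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(hsum > 0, 100.0 * msum / hsum, np.nan)
        covered = ~np.isnan(level)
        level[covered] = adjust_ncr(level[covered], 100.0 * sample.ncr)
        per_gene.append(level)
    mat = np.vstack(per_gene)
    n = np.sum(~np.isnan(mat), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    half = np.where(n > 1, 1.96 * sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return pd.DataFrame(
        {
            "offset": offsets,
            "mean": mean,
            "ci_low": mean - half,
            "ci_high": mean + half,
            "n_genes": n,
        }
    )


# ---------------------------------------------------------------------------
# integration statistics
# ---------------------------------------------------------------------------


def decile_fc_curve(
    delta_mc: pd.Series, log2fc: pd.Series, n_bins: int = 10
) -> pd.DataFrame:
    """Mean +/- SEM expression fold-change in equal-count bins of delta-mC.

    Genes present in both inputs with finite values are ranked by
    delta-mC (ties broken by stable gene-id order) and split into
    ``n_bins`` bins whose sizes differ by at most one (larger bins first).
    """
    joined = pd.DataFrame({"delta": delta_mc, "logfc": log2fc}).dropna()
    if len(joined) < n_bins:
        raise ValueError(f"need at least {n_bins} genes with both values")
    joined = joined.sort_index(kind="mergesort")
    order = np.argsort(joined["delta"].to_numpy(), kind="mergesort")
    chunks = np.array_split(order, n_bins)
    rows = []
    for i, idx in enumerate(chunks):
        d = joined["delta"].to_numpy()[idx]
        f = joined["logfc"].to_numpy()[idx]
        rows.append(
            {
                "bin": i,
                "n": len(idx),
                "delta_lo": float(d.min()),
                "delta_hi": float(d.max()),
                "delta_mean": float(d.mean()),
                "logfc_mean": float(f.mean()),
                "logfc_sem": float(f.std(ddof=1) / np.sqrt(len(f))) if len(f) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def explainable_variance(
    logfc_rep1: pd.Series, logfc_rep2: pd.Series, delta_mc: pd.Series
) -> dict:
    """Variance of differential expression explained by delta-mC vs the ceiling.

    ``logfc_rep1``/``logfc_rep2`` are two independent per-replicate-pair
    fold-change estimates per gene.  R2_mc is the squared Pearson
    correlation between delta-mC and the pooled (mean) logFC; the ceiling
    is the squared Pearson correlation between the two replicate
    estimates — the reproducible fraction of differential expression that
    any covariate could at most explain.
    """
    joined = pd.DataFrame(
        {"r1": logfc_rep1, "r2": logfc_rep2, "d": delta_mc}
    ).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 genes")
    pooled = (joined["r1"] + joined["r2"]) / 2.0
    r_mc = stats.pearsonr(joined["d"], pooled)[0]
    r_rep = stats.pearsonr(joined["r1"], joined["r2"])[0]
    return {"R2_mc": float(r_mc**2), "R2_replicate_ceiling": float(r_rep**2)}


def match_expression_controls(
    target_tpm: pd.Series,
    pool_tpm: pd.Series,
    max_sd_distance: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression-matched control genes by propensity-score nearest neighbour.

    A logistic regression of target membership on log(TPM+1) yields a
    propensity score; targets are matched 1:1 without replacement to the
    nearest pool gene by propensity, in descending target-propensity
    order.  The match is rejected (ValueError, reporting the achieved
    value) when the standard deviation of matched-pair distances exceeds
    ``max_sd_distance``.
    """
    overlap = set(target_tpm.index) & set(pool_tpm.index)
    if overlap:
        raise ValueError("target and pool gene sets must be disjoint")
    if len(pool_tpm) < len(target_tpm):
        raise ValueError("pool smaller than target set")
    x = np.log1p(
        np.concatenate([target_tpm.to_numpy(float), pool_tpm.to_numpy(float)])
    ).reshape(-1, 1)
    y = np.concatenate([np.ones(len(target_tpm)), np.zeros(len(pool_tpm))])
    model = LogisticRegression(random_state=seed).fit(x, y)
    ps = model.predict_proba(x)[:, 1]
    ps_t = pd.Series(ps[: len(target_tpm)], index=target_tpm.index)
    ps_p = pd.Series(ps[len(target_tpm):], index=pool_tpm.index)
    available = ps_p.copy()
    rows = []
    for gid, score in ps_t.sort_values(ascending=False).items():
        dist = (available - score).abs()
        best = dist.idxmin()
        rows.append(
            {"target": gid, "control": best, "distance": float(dist.loc[best])}
        )
        available = available.drop(best)
    matched = pd.DataFrame(rows)
    sd = float(matched["distance"].std(ddof=1)) if len(matched) > 1 else 0.0
    if sd > max_sd_distance:
        raise ValueError(
            f"matched-pair distance sd {sd:.4g} exceeds {max_sd_distance}"
        )
    matched.attrs["distance_sd"] = sd
    return matched
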