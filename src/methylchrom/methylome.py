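"""Per-cytosine methylation quantification with non-conversion correction.

The substrate is a table of bisulfite basecall counts per cytosine: ``m``
methylated calls out of ``h`` total calls, in CG or CH (H = A/C/T)
context.  Levels are always *pooled-count* levels, 100 * sum(m) / sum(h) over
the sites in scope — never a mean of per-site levels — so deeply covered
sites carry proportionally more weight.

Bisulfite conversion is imperfect: a fraction ``ncr`` (the non-conversion
rate, estimated in real experiments from spiked-in unmethylated lambda
phage DNA) of unmethylated cytosines read out as methylated.  Raw levels
are corrected by inverting that inflation, and per-site methylation calls
test the observed counts against a Binomial(h, ncr) null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import Genome


@dataclass
class MethylomeSample:
    """A per-cytosine basecall-count table plus its non-conversion rate.

    ``sites`` has columns chrom, pos (0-based), strand, context ("CG"/"CH"),
    m, h; sorted by (chrom, pos).  ``ncr`` is a fraction in [0, 1).
    """

    sites: pd.DataFrame
    ncr: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.ncr < 1.0):
            raise ValueError(f"ncr must be in [0, 1), got {self.ncr}")
        if len(self.sites) and ((self.sites["m"] < 0) | (self.sites["m"] > self.sites["h"])).any():
            raise ValueError("require 0 <= m <= h at every site")

    def context_sites(self, context: str) -> pd.DataFrame:
        return self.sites[self.sites["context"] == context]


def raw_level(m, h):
    """Raw percent methylation 100*m/h; ``h`` must be positive (mask h=0)."""
    m = np.asarray(m, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("raw_level undefined at h == 0; mask uncovered sites")
    return 100.0 * m / h


def adjust_ncr(pmc, pncr: float):
    """Correct a percent methylation level for bisulfite non-conversion.

    %mC_adj = 100 * (%mC - %NCR) / (100 - %NCR), clipped to [0, 100].
    The correction inverts the inflation of apparent methylation caused by
    unconverted (falsely "methylated") cytosines; it is the identity at
    %NCR = 0 and maps any raw level at or below the NCR to 0.
    """
    if not (0.0 <= pncr < 100.0):
        raise ValueError(f"percent NCR must be in [0, 100), got {pncr}")
    pmc = np.asarray(pmc, dtype=float)
    adj = 100.0 * (pmc - pncr) / (100.0 - pncr)
    return np.clip(adj, 0.0, 100.0)


def call_methylated_sites(sample: MethylomeSample, fdr: float = 0.01) -> pd.DataFrame:
    """Per-site binomial test that methylation exceeds the non-conversion null.

    For each covered cytosine, p = P(X >= m) with X ~ Binomial(h, ncr);
    Benjamini-Hochberg across all covered sites of the sample; a site is
    called methylated iff q < ``fdr``.  Sites with h = 0 are excluded from
    testing and from the BH denominator.

    Returns the site table with added ``p``, ``q`` and boolean ``call``
    columns (NaN p/q and False call at uncovered sites).
    """
    out = sample.sites.copy()
    out["p"] = np.nan
    out["q"] = np.nan
    out["call"] = False
    covered = out["h"] > 0
    if covered.sum() == 0:
        return out
    m = out.loc[covered, "m"].to_numpy()
    h = out.loc[covered, "h"].to_numpy()
    # survival function at m-1 gives P(X >= m); m=0 -> p=1 exactly
    p = stats.binom.sf(m - 1, h, sample.ncr)
    p = np.clip(p, 0.0, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out.loc[covered, "p"] = p
    out.loc[covered, "q"] = q
    out.loc[covered, "call"] = q < fdr
    return out


def pooled_level(m_sum: float, h_sum: float, ncr: float = 0.0) -> float:
    """NCR-adjusted pooled-count percent level for one region/scope."""
    if h_sum <= 0:
        return float("nan")
    return float(adjust_ncr(100.0 * m_sum / h_sum, 100.0 * ncr))


def global_level(sample: MethylomeSample, context: str, adjusted: bool = True) -> float:
    """Genome-wide weighted percent methylation for one context.

    Pooled over every covered site of the context; NCR-adjusted unless
    ``adjusted=False``.
    """
    sub = sample.context_sites(context)
    h = int(sub["h"].sum())
    if h == 0:
        raise ValueError(f"no covered {context} sites")
    raw = 100.0 * float(sub["m"].sum()) / h
    if not adjusted:
        return raw
    return float(adjust_ncr(raw, 100.0 * sample.ncr))


def binned_levels(
    sample: MethylomeSample,
    genome: Genome,
    context: str,
    bin_size: int = 10_000,
    adjusted: bool = True,
) -> pd.DataFrame:
    """Per-bin pooled levels on a fixed genomic grid.

    Bins with zero covered basecalls are emitted with NaN level (missing,
    never 0%).  Returns chrom, start, end, m, h, level.
    """
    sub = sample.context_sites(context)
    rows = []
    for chrom, length in genome.chrom_sizes.items():
        n_bins = int(np.ceil(length / bin_size))
        msum = np.zeros(n_bins)
        hsum = np.zeros(n_bins)
        cs = sub[sub["chrom"] == chrom]
        if len(cs):
            idx = (cs["pos"].to_numpy() // bin_size).astype(int)
            np.add.at(msum, idx, cs["m"].to_numpy())
            np.add.at(hsum, idx, cs["h"].to_numpy())
        starts = np.arange(n_bins) * bin_size
        ends = np.minimum(starts + bin_size, length)
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(hsum > 0, 100.0 * msum / hsum, np.nan)
        if adjusted:
            ok = ~np.isnan(level)
            level[ok] = adjust_ncr(level[ok], 100.0 * sample.ncr)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "m": msum.astype(np.int64),
                    "h": hsum.astype(np.int64),
                    "level": level,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def delta_track_correlation(track_a: pd.DataFrame, track_b: pd.DataFrame):
    """Spearman correlation of two aligned per-bin delta tracks.

    Both frames must share the (chrom, start) grid; bins missing in either
    track are dropped pairwise.  Returns (r, p).
    """
    merged = pd.merge(
        track_a[["chrom", "start", "level"]],
        track_b[["chrom", "start", "level"]],
        on=["chrom", "start"],
        suffixes=("_a", "_b"),
    ).dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 shared covered bins")
    r, p = stats.spearmanr(merged["level_a"], merged["level_b"])
    return float(r), float(p)


def pool_samples(samples: list[MethylomeSample]) -> MethylomeSample:
    """Pool replicate count tables site-wise (sum m and h at shared keys).

    The pooled NCR is the coverage-weighted mean of the replicate NCRs.
    """
    if not samples:
        raise ValueError("no samples to pool")
    frames = [s.sites for s in samples]
    cat = pd.concat(frames, ignore_index=True)
    pooled = (
        cat.groupby(["chrom", "pos", "strand", "context"], sort=True, observed=True)[
            ["m", "h"]
        ]
        .sum()
        .reset_index()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    weights = np.array([max(int(s.sites["h"].sum()), 1) for s in samples], dtype=float)
    ncr = float(np.average([s.ncr for s in samples], weights=weights))
    return MethylomeSample(sites=pooled, ncr=ncr, meta={"pooled_from": len(samples)})
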