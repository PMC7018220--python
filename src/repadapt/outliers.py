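"""Resistance-association outlier scan with empirical-quantile criteria.

A SNP is an outlier when it simultaneously sits in the top 1% of a
differentiation score and the top 5% of |Spearman rho| between population
allele frequency and the resistance "environment".  The differentiation
score here is the pooled resistant-vs-susceptible Nei G_ST — a documented
stand-in for a Bayes-factor criterion from MCMC outlier software, keeping
the same joint top-1%-and-top-5% structure.  Scans run on a thinned SNP set
(one random SNP per kb) so the empirical quantiles are not driven by local
redundancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io_tables import GenotypeMatrix, PopulationPanel
from .popgen import group_counts, nei_gst, pop_allele_freqs

log = logging.getLogger(__name__)

SCORE_HEADER = (
    "# differentiation score = pooled R-vs-S Nei G_ST (empirical-quantile "
    "stand-in for an MCMC Bayes-factor criterion)"
)


@dataclass
class OutlierTable:
    table: pd.DataFrame  # chrom,pos,score,rho,score_q,rho_q,outlier
    top_score: float
    top_rho: float

    @property
    def outliers(self) -> pd.DataFrame:
        return self.table[self.table["outlier"]]


def thin_snps(gm: GenotypeMatrix, bp_window: int = 1000, seed: int = 0) -> GenotypeMatrix:
    """Keep exactly one uniformly chosen SNP per non-empty 1 kb bin."""
    rng = np.random.default_rng(seed)
    keep = []
    for chrom in pd.unique(gm.chrom):
        sites = np.flatnonzero(gm.chrom == chrom)
        bins = gm.pos[sites] // bp_window
        for b in np.unique(bins):
            members = sites[bins == b]
            keep.append(members[rng.integers(members.size)] if members.size > 1 else members[0])
    keep = np.sort(np.asarray(keep, dtype=np.int64))
    return gm.take_sites(keep)


def _spearman_vs_env(freqs: np.ndarray, env: np.ndarray) -> np.ndarray:
    """Per-SNP Spearman rho of population frequency against the environment.

    Vectorised as Pearson correlation of ranks; SNPs with constant
    frequency across populations come back NaN.
    """
    ranks = sstats.rankdata(freqs, axis=1, nan_policy="omit")
    env_r = sstats.rankdata(env)
    rc = ranks - np.nanmean(ranks, axis=1, keepdims=True)
    ec = env_r - env_r.mean()
    num = np.nansum(rc * ec, axis=1)
    den = np.sqrt(np.nansum(rc**2, axis=1) * np.nansum(ec**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def resistance_scan(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    env_coding: str = "binary",
    top_score: float = 0.01,
    top_rho: float = 0.05,
    classes: dict[str, str] | None = None,
) -> OutlierTable:
    """Joint differentiation / rank-correlation outlier scan.

    ``env_coding`` is "binary" (-1 susceptible, +1 resistant) or
    "survival" (the panel's survival proportions).  ``classes`` may
    override the panel's class labels (used by the randomized-grouping
    null).  SNPs whose population frequencies are constant have no defined
    rho and are excluded.  A SNP is flagged when its score reaches the top
    ``top_score`` empirical fraction AND |rho| the top ``top_rho`` fraction.
    """
    if len(panel) < 4:
        raise ValueError("need >= 4 populations")
    cls = classes if classes is not None else panel.classes()
    labels = [cls[p] for p in panel.populations]
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present")
    if env_coding == "binary":
        env = np.array([1.0 if c == "R" else -1.0 for c in labels])
    elif env_coding == "survival":
        env = np.array([panel.survival_of()[p] for p in panel.populations])
    else:
        raise ValueError(f"unknown env_coding {env_coding!r}")

    freqs = pop_allele_freqs(gm, panel).to_numpy(dtype=float)
    rho = _spearman_vs_env(freqs, env)

    idx_r = np.concatenate([gm.sample_indices(p) for p, c in zip(panel.populations, labels) if c == "R"])
    idx_s = np.concatenate([gm.sample_indices(p) for p, c in zip(panel.populations, labels) if c == "S"])
    pooled = []
    for idx in (idx_r, idx_s):
        alt, n = group_counts(gm, idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled.append(np.where(n > 0, alt / n, np.nan))
    score = nei_gst(np.stack(pooled, axis=1))

    ok = ~np.isnan(rho) & ~np.isnan(score)
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("resistance_scan: %d SNPs with undefined rho/score excluded", n_excluded)
    score_q = np.full(gm.n_sites, np.nan)
    rho_q = np.full(gm.n_sites, np.nan)
    score_q[ok] = sstats.rankdata(score[ok]) / ok.sum()
    rho_q[ok] = sstats.rankdata(np.abs(rho[ok])) / ok.sum()
    flag = ok & (score_q >= 1.0 - top_score) & (rho_q >= 1.0 - top_rho)

    table = pd.DataFrame(
        {
            "chrom": gm.chrom,
            "pos": gm.pos,
            "score": score,
            "rho": rho,
            "score_q": score_q,
            "rho_q": rho_q,
            "outlier": flag,
        }
    )
    return OutlierTable(table=table, top_score=top_score, top_rho=top_rho)


def admissible_splits(populations: list[str], true_r: frozenset[str]) -> list[frozenset[str]]:
    """All balanced two-group splits of the populations, excluding the true
    resistance split (and, implicitly, its complement)."""
    from itertools import combinations

    n = len(populations)
    half = n // 2
    seen = set()
    out = []
    for combo in combinations(populations, half):
        g = frozenset(combo)
        comp = frozenset(populations) - g
        if g in seen or comp in seen:
            continue
        seen.add(g)
        if g == true_r or comp == true_r:
            continue
        out.append(g)
    return out


def randomized_grouping_null(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    region_delimiter,
    n_rand: int = 100,
    seed: int = 0,
    env_coding: str = "binary",
    top_score: float = 0.01,
    top_rho: float = 0.05,
) -> dict:
    """Outlier scans under random balanced regroupings of the populations.

    Populations are randomly split 4+4 (never reproducing the true
    resistance grouping); each randomization is scanned and its outliers
    delimited into regions with ``region_delimiter(outlier_table) ->
    RegionSet``.  Returns per-randomization counts plus the fraction of
    randomizations reaching (a) at least the observed region count and
    (b) at least the observed outlier count.
    """
    true_r = frozenset(panel.of_class("R"))
    splits = admissible_splits(panel.populations, true_r)
    rng = np.random.default_rng(seed)
    if n_rand > len(splits):
        log.info(
            "n_rand=%d exceeds %d distinct admissible splits; sampling with replacement",
            n_rand,
            len(splits),
        )
        chosen = [splits[i] for i in rng.integers(0, len(splits), size=n_rand)]
    else:
        chosen = [splits[i] for i in rng.choice(len(splits), size=n_rand, replace=False)]

    observed = resistance_scan(
        gm, panel, env_coding=env_coding, top_score=top_score, top_rho=top_rho
    )
    obs_regions = len(region_delimiter(observed))
    obs_outliers = int(observed.table["outlier"].sum())

    recs = []
    for g in chosen:
        cls = {p: ("R" if p in g else "S") for p in panel.populations}
        tab = resistance_scan(
            gm, panel, env_coding=env_coding, top_score=top_score, top_rho=top_rho, classes=cls
        )
        recs.append(
            {
                "n_outliers": int(tab.table["outlier"].sum()),
                "n_regions": len(region_delimiter(tab)),
            }
        )
    null = pd.DataFrame(recs)
    return {
        "observed_outliers": obs_outliers,
        "observed_regions": obs_regions,
        "null": null,
        "frac_regions_ge_observed": float((null["n_regions"] >= obs_regions).mean()),
        "frac_outliers_ge_observed": float((null["n_outliers"] >= obs_outliers).mean()),
    }
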