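"""Diversity, differentiation and linkage statistics.

Statistics are computed from alt-allele dosages, missing-aware, either per
population or for samples pooled by resistance class (pooling trades
substructure for sample size; windowed diversity statistics are fairly
robust to moderate substructure).  Windows are SNP-count based (25 SNPs by
default), non-overlapping, within-chromosome, with trailing partial windows
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io_tables import MISSING, GenotypeMatrix, PopulationPanel, Region

log = logging.getLogger(__name__)

DEFAULT_WINDOW_SNPS = 25


# ---------------------------------------------------------------------------
# Per-site building blocks


def site_pi(alt_count, n_alleles):
    """Unbiased per-site heterozygosity 2 c (n - c) / (n (n - 1)).

    ``alt_count`` and ``n_alleles`` may be scalars or arrays; sites with
    fewer than two sampled alleles come back NaN (and are logged).
    """
    c = np.asarray(alt_count, dtype=float)
    n = np.asarray(n_alleles, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * c * (n - c) / (n * (n - 1.0)), np.nan)
    n_bad = int(np.sum(n < 2))
    if n_bad:
        log.info("site_pi: %d sites with < 2 sampled alleles skipped", n_bad)
    if np.isscalar(alt_count) and np.isscalar(n_alleles):
        return float(pi)
    return pi


def group_counts(gm: GenotypeMatrix, sample_idx: np.ndarray):
    """(alt allele count, non-missing allele count) per site for a sample set."""
    sub = gm.G[:, sample_idx]
    miss = sub == MISSING
    alt = np.where(miss, 0, sub).sum(axis=1)
    n = 2 * (~miss).sum(axis=1)
    return alt, n


def pop_allele_freqs(gm: GenotypeMatrix, panel: PopulationPanel) -> pd.DataFrame:
    """Alt-allele frequency per population per site (NaN where untyped)."""
    out = {}
    for pop in panel.populations:
        idx = gm.sample_indices(pop)
        alt, n = group_counts(gm, idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[pop] = np.where(n > 0, alt / n, np.nan)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Tajima's D and Fay & Wu's H


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's D for ``n`` sampled alleles."""
    if n < 2:
        raise ValueError("need n >= 2 alleles")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(theta_pi: float, S: int, n: int) -> float:
    """Tajima's D from window pairwise diversity, segregating sites and n."""
    if S == 0:
        return float("nan")
    k = tajima_constants(n)
    theta_w = S / k["a1"]
    denom = np.sqrt(k["e1"] * S + k["e2"] * S * (S - 1.0))
    if denom == 0:
        return float("nan")
    return float((theta_pi - theta_w) / denom)


def fay_wu_h(derived_counts: np.ndarray, n_alleles: np.ndarray) -> float:
    """Unnormalized Fay & Wu's H = theta_pi - theta_H over a set of sites.

    ``theta_H = sum 2 c_d^2 / (n (n - 1))`` weights high-frequency derived
    alleles; both sums run over the same sites (ancestral state required).
    """
    c = np.asarray(derived_counts, dtype=float)
    n = np.asarray(n_alleles, dtype=float)
    ok = n >= 2
    c, n = c[ok], n[ok]
    if c.size == 0 or np.all((c == 0) | (c == n)):
        return float("nan")
    th_pi = np.sum(2.0 * c * (n - c) / (n * (n - 1.0)))
    th_h = np.sum(2.0 * c**2 / (n * (n - 1.0)))
    return float(th_pi - th_h)


# ---------------------------------------------------------------------------
# G_ST and Weir-Cockerham theta


def nei_gst(freqs: np.ndarray) -> float | np.ndarray:
    """Nei's G_ST = 1 - H_S / H_T from per-population alt frequencies.

    ``freqs`` is either a length-K vector (one site) or (n_sites, K).
    H_S is the mean within-population expected heterozygosity, H_T the
    expected heterozygosity at the mean frequency.  Sites monomorphic
    overall return 0.  NaN frequencies (population untyped) are ignored.
    """
    p = np.atleast_2d(np.asarray(freqs, dtype=float))
    if p.shape[1] < 2:
        raise ValueError("G_ST needs at least two populations")
    hs = np.nanmean(2.0 * p * (1.0 - p), axis=1)
    pbar = np.nanmean(p, axis=1)
    ht = 2.0 * pbar * (1.0 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ht > 0, 1.0 - hs / ht, 0.0)
    return float(g[0]) if np.asarray(freqs).ndim == 1 else g


def wc_fst_components(p, het, n):
    """Weir-Cockerham (1984) variance components a, b, c for one site.

    ``p``: alt frequency per population; ``het``: observed heterozygote
    proportion per population; ``n``: diploid individuals typed per
    population.  Arrays may carry a leading site axis.
    """
    p = np.asarray(p, dtype=float)
    het = np.asarray(het, dtype=float)
    n = np.asarray(n, dtype=float)
    r = p.shape[-1]
    nbar = n.mean(axis=-1)
    nc = (r * nbar - (n**2).sum(axis=-1) / (r * nbar)) / (r - 1.0)
    pbar = (n * p).sum(axis=-1) / (r * nbar)
    s2 = (n * (p - pbar[..., None]) ** 2).sum(axis=-1) / ((r - 1.0) * nbar)
    hbar = (n * het).sum(axis=-1) / (r * nbar)
    inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    return a, b, c


def wc_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str, clamp: bool = True) -> np.ndarray:
    """Per-SNP Weir-Cockerham theta-hat for one population pair.

    Negative estimates (noise around zero differentiation) are clamped to
    0; sites where the total variance a+b+c is zero (monomorphic in both
    populations) come back NaN and should be excluded from averages.
    """
    ps, hets, ns = [], [], []
    for pop in (pop_a, pop_b):
        sub = gm.G[:, gm.sample_indices(pop)]
        miss = sub == MISSING
        typed = (~miss).sum(axis=1)
        alt = np.where(miss, 0, sub).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ps.append(np.where(typed > 0, alt / (2.0 * typed), np.nan))
            hets.append(np.where(typed > 0, (sub == 1).sum(axis=1) / typed, np.nan))
        ns.append(typed)
    p = np.stack(ps, axis=-1)
    het = np.stack(hets, axis=-1)
    n = np.stack(ns, axis=-1).astype(float)
    bad = (n < 1).any(axis=-1)
    a, b, c = wc_fst_components(p, het, n)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    theta[bad] = np.nan
    if clamp:
        theta = np.where(np.isnan(theta), np.nan, np.maximum(theta, 0.0))
    return theta


def group_mean_fst(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    group: str,
    n_boot: int = 1000,
    seed: int = 0,
    site_mask: np.ndarray | None = None,
) -> dict:
    """Mean pairwise theta-hat over all population pairs of a resistance
    class, with a locus-bootstrap percentile CI.

    Per SNP and pair the clamped Weir-Cockerham estimate is computed; the
    point estimate is the mean over all finite (pair, locus) values.  The
    95% CI is the 2.5/97.5 percentile of ``n_boot`` replicates in which
    loci are resampled with replacement.
    """
    pops = panel.of_class(group)
    if len(pops) < 2:
        raise ValueError(f"need >= 2 populations in class {group!r}")
    sub = gm if site_mask is None else gm.take_sites(np.flatnonzero(site_mask))
    cols = []
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            cols.append(wc_fst(sub, a, b))
    M = np.stack(cols, axis=1)  # (loci, pairs)
    mean = float(np.nanmean(M))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    n_loci = M.shape[0]
    for j in range(n_boot):
        idx = rng.integers(0, n_loci, size=n_loci)
        reps[j] = np.nanmean(M[idx])
    lo, hi = (np.percentile(reps, [2.5, 97.5]) if n_boot > 1 else (reps[0], reps[0]))
    return {"mean": mean, "ci": (float(lo), float(hi)), "n_pairs": M.shape[1], "n_loci": n_loci}


# ---------------------------------------------------------------------------
# Windowed statistics


@dataclass
class WindowStats:
    """Per-window pooled-group diversity and differentiation table."""

    table: pd.DataFrame
    window_snps: int


def window_stats(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    window: int = DEFAULT_WINDOW_SNPS,
) -> WindowStats:
    """Windowed pi, Tajima's D, Fay & Wu's H and G_ST for pooled R and S.

    Samples are pooled by resistance class; windows are ``window``
    consecutive SNPs within a chromosome, trailing partial windows dropped.
    Tajima's constants use n = the rounded mean non-missing allele count
    over the window's sites in that group.  Windows with no segregating
    sites report D and H as NaN, not 0.  The pi ratio column is
    log10(pi_S / pi_R), NaN when pi_R is 0.
    """
    groups = {g: np.concatenate([gm.sample_indices(p) for p in panel.of_class(g)]) for g in "RS"}
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("both resistance classes must have samples")
    counts = {g: group_counts(gm, idx) for g, idx in groups.items()}
    derived = gm.derived_is_alt()

    rows = []
    for chrom in pd.unique(gm.chrom):
        sites = np.flatnonzero(gm.chrom == chrom)
        n_win = len(sites) // window
        for w in range(n_win):
            widx = sites[w * window : (w + 1) * window]
            rec = {
                "chrom": chrom,
                "start": int(gm.pos[widx[0]]),
                "end": int(gm.pos[widx[-1]]) + 1,
                "n_snps": window,
            }
            for g in "RS":
                alt, n = (c[widx] for c in counts[g])
                ok = n >= 2
                pis = site_pi(alt[ok], n[ok])
                theta_pi = float(np.nansum(pis))
                seg = (alt[ok] > 0) & (alt[ok] < n[ok])
                S = int(seg.sum())
                n_mean = int(round(float(n[ok].mean()))) if ok.any() else 0
                rec[f"pi_{g}"] = theta_pi
                rec[f"D_{g}"] = tajimas_d(theta_pi, S, n_mean) if n_mean >= 2 else np.nan
                if derived is not None:
                    known = ok & ~np.isnan(derived[widx])
                    alt_k, n_k = (c[widx][known] for c in counts[g])
                    cd = np.where(derived[widx][known] == 1.0, alt_k, n_k - alt_k)
                    rec[f"H_{g}"] = fay_wu_h(cd, n_k)
                else:
                    rec[f"H_{g}"] = np.nan
            with np.errstate(invalid="ignore", divide="ignore"):
                rec["log10_pi_ratio"] = (
                    float(np.log10(rec["pi_S"] / rec["pi_R"]))
                    if rec["pi_R"] > 0 and rec["pi_S"] > 0
                    else np.nan
                )
            pr = _pooled_freq(counts["R"], widx)
            ps = _pooled_freq(counts["S"], widx)
            both = ~np.isnan(pr) & ~np.isnan(ps)
            rec["gst_mean"] = (
                float(np.nanmean(nei_gst(np.stack([pr[both], ps[both]], axis=1))))
                if both.any()
                else np.nan
            )
            rows.append(rec)
    return WindowStats(table=pd.DataFrame(rows), window_snps=window)


def _pooled_freq(counts, idx):
    alt, n = (c[idx] for c in counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, alt / n, np.nan)


# ---------------------------------------------------------------------------
# Linkage disequilibrium


@dataclass
class LDSummary:
    chrom: str
    mean_r2: float
    q3_r2: float
    n_snps: int
    window_table: pd.DataFrame  # window start/end/mean r2
    spans: list[tuple[int, int]]  # elevated-LD intervals, 0-based half-open
    region_means: dict[str, float] = field(default_factory=dict)


def _dosage_r2(sub: np.ndarray) -> np.ndarray:
    """Pairwise squared genotype correlation (composite LD), missing-aware."""
    X = np.asarray(sub, dtype=float)
    X[X == MISSING] = np.nan
    if np.isnan(X).any():
        Xm = np.ma.masked_invalid(X)
        corr = np.ma.corrcoef(Xm)
        corr = np.asarray(corr.filled(np.nan))
    else:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(X)
    return corr**2


def ld_r2(
    gm: GenotypeMatrix,
    chrom: str,
    maf_min: float = 0.05,
    max_missing: float = 0.20,
    max_dist: int | None = None,
    window_bp: int = 100_000,
    span_threshold: float = 0.25,
    regions: list[Region] | None = None,
) -> LDSummary:
    """Composite r-squared LD summary for one chromosome.

    Only biallelic SNPs passing the frequency and missingness thresholds
    enter; r^2 is the squared Pearson correlation of dosage vectors (the
    composite, phase-free estimate appropriate for called genotypes).
    Reports the chromosome mean and third quartile over all pairs within
    the optional ``max_dist`` band, plus "elevated spans": maximal runs of
    consecutive ``window_bp`` windows whose mean within-window pairwise
    r^2 exceeds ``span_threshold``.
    """
    from .io_tables import site_filter_mask

    on = gm.chrom == chrom
    keep = site_filter_mask(gm.G, maf_min=maf_min, max_missing=max_missing) & on
    # zero-variance guard
    sub = gm.G[keep].astype(float)
    sub[sub == MISSING] = np.nan
    var = np.nanvar(sub, axis=1)
    keep_idx = np.flatnonzero(keep)[var > 0]
    if keep_idx.size < 2:
        raise ValueError(f"fewer than 2 qualifying SNPs on {chrom}")
    pos = gm.pos[keep_idx]
    r2 = _dosage_r2(gm.G[keep_idx])
    iu = np.triu_indices(len(keep_idx), k=1)
    pair_r2 = r2[iu]
    if max_dist is not None:
        dist = np.abs(pos[iu[0]] - pos[iu[1]])
        pair_r2 = pair_r2[dist <= max_dist]
    pair_r2 = pair_r2[~np.isnan(pair_r2)]

    # windowed mean pairwise r2 and elevated spans
    w_of = pos // window_bp
    wins = np.unique(w_of)
    wrows = []
    for w in wins:
        in_w = np.flatnonzero(w_of == w)
        if in_w.size < 2:
            mean_w = np.nan
        else:
            block = r2[np.ix_(in_w, in_w)]
            mean_w = float(np.nanmean(block[np.triu_indices(in_w.size, k=1)]))
        wrows.append({"window": int(w), "start": int(w * window_bp), "end": int((w + 1) * window_bp), "mean_r2": mean_w})
    wtab = pd.DataFrame(wrows)
    spans = []
    run = None
    for rec in wrows:
        hot = (not np.isnan(rec["mean_r2"])) and rec["mean_r2"] > span_threshold
        if hot:
            if run is not None and rec["window"] == run[1]:
                run = (run[0], rec["window"] + 1)
            else:
                if run is not None:
                    spans.append((run[0] * window_bp, run[1] * window_bp))
                run = (rec["window"], rec["window"] + 1)
    if run is not None:
        spans.append((run[0] * window_bp, run[1] * window_bp))

    region_means = {}
    for reg in regions or []:
        if reg.chrom != chrom:
            continue
        in_r = np.flatnonzero((pos >= reg.start) & (pos < reg.end))
        if in_r.size >= 2:
            block = r2[np.ix_(in_r, in_r)]
            region_means[reg.region_id] = float(
                np.nanmean(block[np.triu_indices(in_r.size, k=1)])
            )
        else:
            region_means[reg.region_id] = float("nan")
    return LDSummary(
        chrom=chrom,
        mean_r2=float(np.mean(pair_r2)),
        q3_r2=float(np.percentile(pair_r2, 75)),
        n_snps=int(keep_idx.size),
        window_table=wtab,
        spans=spans,
        region_means=region_means,
    )


# ---------------------------------------------------------------------------
# Per-population summaries and candidate-gene association


def pop_summary_stats(gm: GenotypeMatrix, panel: PopulationPanel) -> pd.DataFrame:
    """Observed/expected heterozygosity and F_IS per population.

    Ho is the observed heterozygote fraction and He the (n/(n-1))-corrected
    expected heterozygosity, both averaged over sites polymorphic within
    the population; F_IS = 1 - Ho/He over those sites (NaN when a
    population has no polymorphic site).
    """
    if gm.n_sites < 1:
        raise ValueError("need at least one site")
    rows = []
    for pop in panel.populations:
        idx = gm.sample_indices(pop)
        sub = gm.G[:, idx]
        miss = sub == MISSING
        typed = (~miss).sum(axis=1)
        alt = np.where(miss, 0, sub).sum(axis=1)
        n_al = 2.0 * typed
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_al > 0, alt / n_al, np.nan)
        poly = (alt > 0) & (alt < n_al) & (typed > 1)
        if not poly.any():
            rows.append({"population": pop, "Ho": 0.0, "He": 0.0, "F_IS": np.nan, "n_poly": 0})
            continue
        ho = ((sub == 1).sum(axis=1) / typed)[poly]
        he = (2.0 * p * (1.0 - p) * n_al / (n_al - 1.0))[poly]
        Ho, He = float(ho.mean()), float(he.mean())
        rows.append(
            {
                "population": pop,
                "Ho": Ho,
                "He": He,
                "F_IS": 1.0 - Ho / He,
                "n_poly": int(poly.sum()),
            }
        )
    return pd.DataFrame(rows)


def candidate_gene_assoc(gm: GenotypeMatrix, panel: PopulationPanel) -> pd.DataFrame:
    """Per-SNP association of allele frequency with the resistance phenotype.

    For every SNP: a 2x2 allele-count chi-square test of pooled resistant
    vs susceptible classes (switching to Fisher's exact test when an
    expected cell drops below 1), the Pearson correlation of population
    allele frequency with population survival, and Benjamini-Hochberg
    adjusted p-values across SNPs for both tests.
    """
    for cls in "RS":
        if len(panel.of_class(cls)) < 2:
            raise ValueError(f"need >= 2 populations of class {cls}")
    idx_r = np.concatenate([gm.sample_indices(p) for p in panel.of_class("R")])
    idx_s = np.concatenate([gm.sample_indices(p) for p in panel.of_class("S")])
    alt_r, n_r = group_counts(gm, idx_r)
    alt_s, n_s = group_counts(gm, idx_s)
    freqs = pop_allele_freqs(gm, panel)
    surv = np.array([panel.survival_of()[p] for p in panel.populations])

    rows = []
    n_fisher = 0
    for i in range(gm.n_sites):
        table = np.array(
            [[alt_r[i], n_r[i] - alt_r[i]], [alt_s[i], n_s[i] - alt_s[i]]], dtype=float
        )
        if table.sum() == 0 or table.sum(axis=0).min() == 0:
            chi2, p_chi = np.nan, np.nan
        else:
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
            if expected.min() < 1.0:
                n_fisher += 1
                chi2 = np.nan
                p_chi = float(sstats.fisher_exact(table.astype(int))[1])
            else:
                res = sstats.chi2_contingency(table, correction=False)
                chi2, p_chi = float(res[0]), float(res[1])
        f = freqs.iloc[i].to_numpy(dtype=float)
        ok = ~np.isnan(f)
        if ok.sum() >= 3 and np.std(f[ok]) > 0 and np.std(surv[ok]) > 0:
            r, p_r = sstats.pearsonr(f[ok], surv[ok])
        else:
            r, p_r = np.nan, np.nan
        rows.append(
            {
                "chrom": gm.chrom[i],
                "pos": int(gm.pos[i]),
                "chi2": chi2,
                "p_chi2": p_chi,
                "pearson_r": float(r) if r == r else np.nan,
                "p_pearson": float(p_r) if p_r == p_r else np.nan,
            }
        )
    if n_fisher:
        log.info("candidate_gene_assoc: Fisher exact used at %d sparse sites", n_fisher)
    df = pd.DataFrame(rows)
    for col in ("p_chi2", "p_pearson"):
        adj = np.full(len(df), np.nan)
        ok = df[col].notna().to_numpy()
        if ok.any():
            adj[ok] = sstats.false_discovery_control(df.loc[ok, col].to_numpy(), method="bh")
        df[col.replace("p_", "q_")] = adj
    return df
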