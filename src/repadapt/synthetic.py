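"""Seeded synthetic datasets with known neutral structure and injected sweeps.

The generator mirrors the assumptions of the convergence-inference model
rather than a full coalescent: per site an ancestral frequency ``eps`` is
drawn, population frequencies are multivariate normal around ``eps`` with
covariance ``eps (1 - eps) F`` for a coancestry matrix ``F``, truncated to
[0.01, 0.99], and diploid genotypes are binomial draws under within-
population Hardy-Weinberg.  Sweep regions are produced by redrawing sites
near a selected position from the sweep-modified covariance ``F'(d)`` of
the corresponding convergence mode, so every downstream stage has exact
ground truth.  This is self-consistency by construction, not realism; in
particular the site-frequency spectrum is not the neutral coalescent one
(see the methods note).

The default scenario emulates the study design this pipeline is built
around: 8 populations (4 glyphosate-resistant, 4 susceptible), 10 diploid
individuals each, five chromosomes, one sweep region per convergence mode,
and a toy annotation carrying clustered detoxification-family genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .convergence import (
    DEFAULT_NE,
    DEFAULT_REC_RATE,
    CoancestryMatrix,
    SweepModelParams,
    modified_F,
    sweep_y,
)
from .io_tables import (
    GENE_FAMILIES,
    GeneRecord,
    GenotypeMatrix,
    PopulationPanel,
    PopulationRow,
)

#: Default population layout: four resistant populations whose survival
#: proportions average 0.885 and four susceptible ones averaging 0.1575,
#: matching the published phenotyping of the genotyped populations.
DEFAULT_POPULATIONS: tuple[tuple[str, float], ...] = (
    ("R1", 0.83),
    ("R2", 1.0),
    ("R3", 1.0),
    ("R4", 0.71),
    ("S1", 0.10),
    ("S2", 0.18),
    ("S3", 0.15),
    ("S4", 0.20),
)

CHROM_LENGTH = 30_000_000
N_CHROMS = 5
SNPS_PER_CHROM = 3000
CORE_SNPS = 800  # targeted-capture style dense markers around each sweep
CORE_SPAN = 800_000  # bp covered by the dense core
N_PER_POP = 10


def default_panel() -> PopulationPanel:
    return PopulationPanel(
        [
            PopulationRow(population=p, survival=s, usage=frozenset({"P"}))
            for p, s in DEFAULT_POPULATIONS
        ]
    )


def default_coancestry() -> CoancestryMatrix:
    """Moderately structured coancestry for the 8 default populations.

    Diagonals sit in the 0.12-0.20 range typical of patchy weed
    populations, resistant populations slightly more drifted; R1 and R2
    share extra coancestry (a connected pair of populations).
    """
    pops = [p for p, _ in DEFAULT_POPULATIONS]
    diag = np.array([0.18, 0.20, 0.16, 0.19, 0.12, 0.14, 0.13, 0.12])
    F = np.full((8, 8), 0.03)
    np.fill_diagonal(F, diag)
    F[0, 1] = F[1, 0] = 0.08
    return CoancestryMatrix(F=F, populations=pops)


@dataclass
class SyntheticTruth:
    """Everything needed to reconstruct and score a synthetic dataset."""

    seed: int
    F: CoancestryMatrix
    sweeps: list[SweepModelParams]
    sweep_chroms: list[str]
    eps: np.ndarray
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def sweep_for_chrom(self, chrom: str) -> SweepModelParams | None:
        for c, p in zip(self.sweep_chroms, self.sweeps):
            if c == chrom:
                return p
        return None


def _mvn_factor(F: np.ndarray) -> np.ndarray:
    """Square-root factor of a (possibly singular) covariance matrix."""
    w, V = np.linalg.eigh((F + F.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError(f"coancestry matrix not PSD (min eigenvalue {w.min():.3g})")
    return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_neutral_freqs(
    F: CoancestryMatrix,
    n_sites: int,
    eps_sampler=None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-population frequencies at neutral sites.

    Per site: ``eps ~ eps_sampler`` (default Uniform(0.05, 0.95)); the
    population frequency vector is multivariate normal with mean ``eps``
    and covariance ``eps (1 - eps) F``, truncated to [0.01, 0.99].

    Returns ``(freqs, eps)`` with ``freqs`` of shape (n_sites, K).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    eps = (
        rng.uniform(0.05, 0.95, size=n_sites)
        if eps_sampler is None
        else np.asarray(eps_sampler(rng, n_sites), dtype=float)
    )
    L = _mvn_factor(F.F)
    z = rng.standard_normal((n_sites, F.K))
    x = eps[:, None] + np.sqrt(eps * (1.0 - eps))[:, None] * (z @ L.T)
    return np.clip(x, 0.01, 0.99), eps


def inject_sweep(
    freqs: np.ndarray,
    eps: np.ndarray,
    positions: np.ndarray,
    F: CoancestryMatrix,
    params: SweepModelParams,
    seed: int = 0,
    y_floor: float = 1e-6,
) -> np.ndarray:
    """Redraw sites near a sweep from the sweep-modified covariance.

    Sites whose hitchhiking probability ``y`` falls below ``y_floor`` are
    untouched, so the sweep is local and the far background keeps its
    original (neutral) draw.  Returns a new frequency matrix.
    """
    positions = np.asarray(positions)
    if positions.size and not (positions.min() <= params.x0 <= positions.max()):
        import warnings

        warnings.warn(
            f"x0={params.x0} outside the span of positions; distances still computed",
            stacklevel=2,
        )
    d = np.abs(positions.astype(float) - float(params.x0))
    y = np.asarray(sweep_y(d, params), dtype=float)
    hot = np.flatnonzero(y >= y_floor)
    out = np.array(freqs, dtype=float, copy=True)
    if hot.size == 0:
        return out
    rng = np.random.default_rng(seed)
    Fp = modified_F(F, d[hot], params)  # (h, K, K)
    w, V = np.linalg.eigh(Fp)
    L = V * np.sqrt(np.clip(w, 0.0, None))[:, None, :]
    z = rng.standard_normal((hot.size, F.K))
    e = eps[hot]
    draw = e[:, None] + np.sqrt(e * (1.0 - e))[:, None] * np.einsum("nij,nj->ni", L, z)
    out[hot] = np.clip(draw, 0.01, 0.99)
    return out


def freqs_to_genotypes(
    freqs: np.ndarray,
    positions: np.ndarray,
    chrom: np.ndarray,
    populations: list[str],
    n_per_pop: int = N_PER_POP,
    seed: int = 0,
) -> GenotypeMatrix:
    """Sample diploid dosages binomial(2, x_k) under within-population HWE.

    The reference allele is recorded as the ancestral allele, so the alt
    allele is derived by construction.
    """
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.min() < 0 or freqs.max() > 1:
        raise ValueError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sites, K = freqs.shape
    cols = []
    samples = []
    pop_map = {}
    for k, pop in enumerate(populations):
        cols.append(rng.binomial(2, freqs[:, [k]], size=(n_sites, n_per_pop)))
        for i in range(n_per_pop):
            name = f"{pop}_{i + 1}"
            samples.append(name)
            pop_map[name] = pop
    G = np.concatenate(cols, axis=1).astype(np.int16)
    ref = np.full(n_sites, "A", dtype=object)
    alt = np.full(n_sites, "T", dtype=object)
    return GenotypeMatrix(
        samples=samples,
        populations=pop_map,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=ref,
        alt=alt,
        G=G,
        ancestral=ref.copy(),
    )


# ---------------------------------------------------------------------------
# Annotation


@dataclass(frozen=True)
class ClusterSpec:
    """A tandem gene cluster to place inside a fixed interval."""

    chrom: str
    start: int
    end: int
    family: str
    n_genes: int


def make_toy_annotation(
    chrom_lengths: dict[str, int],
    clusters: list[ClusterSpec] = (),
    n_background_per_chrom: int = 300,
    family_fraction: float = 0.03,
    gene_length: int = 4000,
    seed: int = 0,
) -> list[GeneRecord]:
    """Place background genes uniformly plus designated tandem clusters.

    Background genes get family labels at random: each detoxification
    family receives ``family_fraction`` of background genes, the rest are
    "other".  Cluster genes are laid down tandemly (equal spacing, no
    overlap) within their interval; a cluster that cannot fit raises.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    counter = 0
    fams = list(GENE_FAMILIES)
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n = n_background_per_chrom
        starts = np.sort(rng.integers(0, max(1, length - gene_length), size=n))
        labels = rng.choice(
            fams + ["other"],
            size=n,
            p=[family_fraction] * len(fams) + [1.0 - family_fraction * len(fams)],
        )
        for s, fam in zip(starts, labels):
            counter += 1
            genes.append(
                GeneRecord(
                    gene_id=f"g{counter:05d}",
                    chrom=chrom,
                    start=int(s),
                    end=int(s) + gene_length,
                    family=str(fam),
                )
            )
    for ci, cl in enumerate(clusters):
        span = cl.end - cl.start
        need = cl.n_genes * gene_length
        if need > span:
            raise ValueError(
                f"cluster of {cl.n_genes} x {gene_length} bp does not fit in "
                f"[{cl.start}, {cl.end}) on {cl.chrom}"
            )
        gap = (span - need) // max(1, cl.n_genes)
        pos = cl.start
        for j in range(cl.n_genes):
            counter += 1
            genes.append(
                GeneRecord(
                    gene_id=f"clu{ci + 1}_{j + 1}",
                    chrom=cl.chrom,
                    start=pos,
                    end=pos + gene_length,
                    family=cl.family,
                )
            )
            pos += gene_length + gap
    return genes


# ---------------------------------------------------------------------------
# Default end-to-end scenario


def default_sweeps() -> tuple[list[str], list[SweepModelParams]]:
    """One sweep region per convergence mode on chromosomes 2-4.

    The migration sweep (free migration, s = 0.65) plays the role of the
    strongly shared region; the standing sweep is an old, low-frequency
    standing variant (t = 3000, g = 1e-6), the regime that shadows
    independent mutation; the independent sweep uses s = 0.8.
    """
    r_pops = ("R1", "R2", "R3", "R4")
    x0 = CHROM_LENGTH // 2
    sweeps = [
        SweepModelParams(
            model="independent", s=0.8, x0=x0, selected_pops=r_pops
        ),
        SweepModelParams(
            model="migration", s=0.65, m=1.0, source="R1", x0=x0, selected_pops=r_pops
        ),
        SweepModelParams(
            model="standing", s=1.0, g=1e-6, t=3000.0, x0=x0, selected_pops=r_pops
        ),
    ]
    return ["chr2", "chr3", "chr4"], sweeps


def default_clusters() -> list[ClusterSpec]:
    """Detoxification-family clusters placed inside the sweep regions.

    The glycosyltransferase cluster is seven tandem genes within 42.3 kb of
    the shared (migration-mode) sweep; a cytochrome P450 cluster of nine
    genes and an ABC transporter cluster of four genes sit in the other two
    sweep regions.
    """
    x0 = CHROM_LENGTH // 2
    return [
        ClusterSpec("chr3", x0 - 21_150, x0 + 21_150, "glycosyltransferase", 7),
        ClusterSpec("chr2", x0 - 40_000, x0 + 40_000, "cytochrome P450", 9),
        ClusterSpec("chr4", x0 - 20_000, x0 + 20_000, "ABC transporter", 4),
    ]


def make_default_scenario(
    seed: int = 0,
    n_per_pop: int = N_PER_POP,
    snps_per_chrom: int = SNPS_PER_CHROM,
) -> tuple[GenotypeMatrix, PopulationPanel, list[GeneRecord], SyntheticTruth]:
    """Generate the full default scenario with ground truth.

    Five 30 Mb chromosomes with ``snps_per_chrom`` SNPs each; chromosomes
    1 and 5 are entirely neutral, chromosomes 2-4 carry one sweep each
    (independent, migration, standing) centred mid-chromosome.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=16)]
    panel = default_panel()
    F = default_coancestry()
    chrom_names = [f"chr{i + 1}" for i in range(N_CHROMS)]
    chrom_lengths = {c: CHROM_LENGTH for c in chrom_names}
    sweep_chroms, sweeps = default_sweeps()

    all_pos, all_chrom, all_freqs, all_eps = [], [], [], []
    for ci, chrom in enumerate(chrom_names):
        if chrom in sweep_chroms:
            # emulate targeted capture: a dense marker core around the
            # candidate region over a sparser chromosome-wide backbone
            x0 = sweeps[sweep_chroms.index(chrom)].x0
            n_core = min(CORE_SNPS, snps_per_chrom)
            core = rng.choice(
                np.arange(x0 - CORE_SPAN // 2, x0 + CORE_SPAN // 2),
                size=n_core,
                replace=False,
            )
            backbone = rng.choice(
                CHROM_LENGTH, size=snps_per_chrom - n_core, replace=False
            )
            pos = np.sort(np.unique(np.concatenate([core, backbone])))
        else:
            pos = np.sort(rng.choice(CHROM_LENGTH, size=snps_per_chrom, replace=False))
        freqs, eps = simulate_neutral_freqs(F, len(pos), seed=sub[ci])
        if chrom in sweep_chroms:
            params = sweeps[sweep_chroms.index(chrom)]
            freqs = inject_sweep(freqs, eps, pos, F, params, seed=sub[8 + ci])
        all_pos.append(pos)
        all_chrom.append(np.full(len(pos), chrom, dtype=object))
        all_freqs.append(freqs)
        all_eps.append(eps)

    freqs = np.vstack(all_freqs)
    gm = freqs_to_genotypes(
        freqs,
        np.concatenate(all_pos),
        np.concatenate(all_chrom),
        panel.populations,
        n_per_pop=n_per_pop,
        seed=sub[15],
    )
    genes = make_toy_annotation(chrom_lengths, default_clusters(), seed=sub[14])
    truth = SyntheticTruth(
        seed=seed,
        F=F,
        sweeps=sweeps,
        sweep_chroms=sweep_chroms,
        eps=np.concatenate(all_eps),
        chrom_lengths=chrom_lengths,
    )
    return gm, panel, genes, truth


def simulate_region(
    F: CoancestryMatrix,
    params: SweepModelParams,
    n_snps: int = 200,
    span: int = 500_000,
    n_per_pop: int = N_PER_POP,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate observed population frequencies for one sweep region.

    SNP positions are evenly spread over ``span`` bp centred on ``x0``;
    true frequencies are drawn from the sweep-modified covariance and then
    pushed through binomial sampling of ``n_per_pop`` diploids, so the
    output carries the same sampling noise the composite likelihood models.

    Returns ``(est_freqs, positions)``.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]
    positions = params.x0 - span // 2 + np.linspace(0, span, n_snps).astype(np.int64)
    freqs, eps = simulate_neutral_freqs(F, n_snps, seed=sub[0])
    freqs = inject_sweep(freqs, eps, positions, F, params, seed=sub[1])
    counts = np.random.default_rng(sub[2]).binomial(2 * n_per_pop, freqs)
    return counts / (2.0 * n_per_pop), positions
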