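"""Readers and writers for the standard formats the pipeline touches.

VCF genotypes come in through :func:`read_vcf` (cyvcf2), gene annotations
through :func:`read_gff` (gffutils), and the population panel — one row per
population with its glyphosate-survival phenotype — through
:func:`read_panel`.  Delimited outlier regions go out as BED.

Internally every coordinate is 0-based half-open; conversion to and from the
1-based conventions of VCF and GFF3 happens only at the file boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1  # sentinel dosage for a missing genotype call

#: Family keywords searched, in priority order, against gene attribute text.
#: GO:0009635 (response to herbicide), GO:0006979 (response to oxidative
#: stress) and GO:0055114 (oxidation-reduction) are treated as cytochrome
#: P450 style detoxification markers unless a more specific keyword hits.
DEFAULT_FAMILY_CONFIG: tuple[tuple[str, str], ...] = (
    ("cytochrome p450", "cytochrome P450"),
    ("glycosyltransferase", "glycosyltransferase"),
    ("abc transporter", "ABC transporter"),
    ("glutathione s-transferase", "glutathione S-transferase"),
    ("go:0009635", "cytochrome P450"),
    ("go:0006979", "glutathione S-transferase"),
    ("go:0055114", "cytochrome P450"),
)

GENE_FAMILIES = (
    "cytochrome P450",
    "glycosyltransferase",
    "ABC transporter",
    "glutathione S-transferase",
)


class VcfParseError(ValueError):
    pass


class PanelError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosage matrix with site and sample metadata.

    ``G`` has shape ``(n_sites, n_samples)`` with entries in ``{0, 1, 2}``
    or :data:`MISSING`.  Sites are sorted by ``(chrom, pos)``; ``pos`` is
    0-based.  ``ancestral`` holds the per-site ancestral allele (one of
    ref/alt) or ``None`` when no ancestral annotation is available.
    """

    samples: list[str]
    populations: dict[str, str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    G: np.ndarray
    ancestral: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int16)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.G.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"G shape {self.G.shape} does not match "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )
        missing_pop = [s for s in self.samples if s not in self.populations]
        if missing_pop:
            raise PanelError(f"samples without a population: {missing_pop[:5]}")
        order = np.lexsort((self.pos, _chrom_sort_key(self.chrom)))
        if not np.array_equal(order, np.arange(len(order))):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.ref = np.asarray(self.ref, dtype=object)[order]
            self.alt = np.asarray(self.alt, dtype=object)[order]
            self.G = self.G[order]
            if self.ancestral is not None:
                self.ancestral = np.asarray(self.ancestral, dtype=object)[order]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def population_of(self) -> np.ndarray:
        return np.array([self.populations[s] for s in self.samples], dtype=object)

    def sample_indices(self, population: str) -> np.ndarray:
        pops = self.population_of()
        return np.flatnonzero(pops == population)

    def derived_is_alt(self) -> np.ndarray | None:
        """Boolean per site: the alt allele is the derived allele.

        ``None`` entries of ``ancestral`` (or an ancestral allele matching
        neither ref nor alt) come back as NaN-like ``-1`` free mask pair:
        returns (known_mask, alt_is_derived) stacked is avoided — the
        return is a float array with NaN for unknown sites.
        """
        if self.ancestral is None:
            return None
        out = np.full(self.n_sites, np.nan)
        anc = self.ancestral
        out[anc == self.ref] = 1.0  # ancestral is ref -> alt derived
        out[anc == self.alt] = 0.0
        return out

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            populations=dict(self.populations),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=np.asarray(self.ref, dtype=object)[idx],
            alt=np.asarray(self.alt, dtype=object)[idx],
            G=self.G[idx],
            ancestral=None
            if self.ancestral is None
            else np.asarray(self.ancestral, dtype=object)[idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        samples = [self.samples[i] for i in idx]
        return GenotypeMatrix(
            samples=samples,
            populations={s: self.populations[s] for s in samples},
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=np.asarray(self.ref, dtype=object).copy(),
            alt=np.asarray(self.alt, dtype=object).copy(),
            G=self.G[:, idx],
            ancestral=None if self.ancestral is None else self.ancestral.copy(),
        )


def _chrom_sort_key(chroms: np.ndarray) -> np.ndarray:
    uniq = sorted(set(chroms.tolist()))
    lut = {c: i for i, c in enumerate(uniq)}
    return np.array([lut[c] for c in chroms])


@dataclass(frozen=True)
class PopulationRow:
    population: str
    survival: float
    usage: frozenset[str]

    @property
    def resistance_class(self) -> str:
        # survival strictly above 0.5 -> resistant; a population at exactly
        # 0.5 is classified susceptible (ties go to S, with a warning at read
        # time since the rule is a convention, not a measurement).
        return "R" if self.survival > 0.5 else "S"


@dataclass
class PopulationPanel:
    rows: list[PopulationRow]

    def __post_init__(self) -> None:
        for r in self.rows:
            if not 0.0 <= r.survival <= 1.0:
                raise PanelError(
                    f"population {r.population}: survival {r.survival} outside [0, 1]"
                )
        names = [r.population for r in self.rows]
        if len(set(names)) != len(names):
            raise PanelError("duplicate population ids in panel")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def populations(self) -> list[str]:
        return [r.population for r in self.rows]

    def classes(self) -> dict[str, str]:
        return {r.population: r.resistance_class for r in self.rows}

    def survival_of(self) -> dict[str, float]:
        return {r.population: r.survival for r in self.rows}

    def of_class(self, class_label: str) -> list[str]:
        return [r.population for r in self.rows if r.resistance_class == class_label]

    def subset(self, populations: list[str]) -> "PopulationPanel":
        keep = set(populations)
        return PopulationPanel([r for r in self.rows if r.population in keep])


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    family: str  # one of GENE_FAMILIES or "other"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} >= end {self.end}")


@dataclass(frozen=True)
class Region:
    region_id: str
    chrom: str
    start: int  # 0-based inclusive, first member outlier position
    end: int  # 0-based exclusive, one past last member outlier position
    n_outliers: int
    member_pos: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    regions: list[Region]
    max_gap: int | None = None
    min_outliers: int | None = None

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path,
    panel: PopulationPanel | None = None,
    maf_min: float = 0.02,
    max_missing: float = 0.20,
    min_depth: int | None = None,
    max_het: float | None = None,
    max_cov_factor: float | None = None,
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Sites with minor-allele frequency below ``maf_min`` or with more than
    ``max_missing`` of individuals missing are dropped (the two filters
    commute, so order is immaterial).  ``min_depth`` drops sites whose mean
    DP is at or below the cutoff, but only when the VCF carries DP; without
    the field the filter is skipped with a logged notice, since
    genotype-level QC belongs upstream.  ``max_het`` and ``max_cov_factor``
    optionally drop collapsed-duplicate sites (excess heterozygosity, or
    coverage above ``max_cov_factor`` times the site average).

    ``panel``, when given, is used to attach a population to every sample;
    a VCF sample absent from the panel raises :class:`PanelError`.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if panel is not None:
        known = {r.population for r in panel}
        sample_pop = {}
        for s in samples:
            pop = s.rsplit("_", 1)[0]
            if pop not in known:
                raise PanelError(f"sample {s!r}: population {pop!r} not in panel")
            sample_pop[s] = pop
    else:
        sample_pop = {s: s.rsplit("_", 1)[0] for s in samples}

    chroms, poss, refs, alts, ancs, rows = [], [], [], [], [], []
    depths = []
    have_anc = False
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        g = np.asarray(var.gt_types, dtype=np.int16)  # 0,1,2 alt dosage; 3 unknown
        g[g == 3] = MISSING
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)  # to 0-based
        refs.append(var.REF)
        alts.append(var.ALT[0])
        aa = var.INFO.get("AA")
        ancs.append(aa)
        if aa is not None:
            have_anc = True
        rows.append(g)
        if min_depth is not None:
            try:
                dp = var.format("DP")
            except Exception:
                dp = None
            depths.append(np.nan if dp is None else float(np.nanmean(dp)))

    if not rows:
        return GenotypeMatrix(
            samples=samples,
            populations=sample_pop,
            chrom=np.array([], dtype=object),
            pos=np.array([], dtype=np.int64),
            ref=np.array([], dtype=object),
            alt=np.array([], dtype=object),
            G=np.zeros((0, len(samples)), dtype=np.int16),
        )

    G = np.vstack(rows)
    gm = GenotypeMatrix(
        samples=samples,
        populations=sample_pop,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        G=G,
        ancestral=np.array(ancs, dtype=object) if have_anc else None,
    )

    keep = site_filter_mask(gm.G, maf_min=maf_min, max_missing=max_missing)
    if min_depth is not None:
        dp = np.asarray(depths)
        if np.all(np.isnan(dp)):
            log.info("DP absent from VCF; depth filter skipped")
        else:
            keep &= dp > min_depth
    if max_het is not None:
        het_frac = _site_het_fraction(gm.G)
        keep &= het_frac <= max_het
    if max_cov_factor is not None and min_depth is not None and not np.all(np.isnan(dp)):
        keep &= dp <= max_cov_factor * np.nanmean(dp)
    return gm.take_sites(np.flatnonzero(keep))


def site_filter_mask(G: np.ndarray, maf_min: float, max_missing: float) -> np.ndarray:
    """Keep mask for sites passing MAF and missingness thresholds."""
    miss = G == MISSING
    n_called = (~miss).sum(axis=1)
    miss_frac = miss.mean(axis=1)
    alt = np.where(miss, 0, G).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.minimum(p, 1.0 - p)
    keep = (miss_frac <= max_missing) & (n_called > 0) & (maf >= maf_min)
    return keep


def _site_het_fraction(G: np.ndarray) -> np.ndarray:
    called = (G != MISSING).sum(axis=1)
    het = (G == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, het / called, 0.0)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 file (text, uncompressed)."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(gm.chrom.tolist())):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        anc = gm.ancestral
        for i in range(gm.n_sites):
            info = "." if anc is None or anc[i] is None else f"AA={anc[i]}"
            gts = "\t".join(code[int(g)] for g in gm.G[i])
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i] + 1}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                f"\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path, family_config=DEFAULT_FAMILY_CONFIG) -> list[GeneRecord]:
    """Read gene features from a GFF3 file and label gene families.

    The family label is decided by the first ``(keyword, family)`` pair in
    ``family_config`` whose keyword occurs (case-insensitively) in the
    feature's attribute text; genes matching nothing are labelled "other".
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
        )
    except EmptyInputError:
        return []
    records = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        try:
            attr_text = " ".join(
                " ".join(v) if isinstance(v, (list, tuple)) else str(v)
                for v in feat.attributes.values()
            ).lower()
        except Exception as exc:
            raise ValueError(f"unparseable attributes for feature {feat.id}: {exc}") from exc
        family = "other"
        for keyword, fam in family_config:
            if keyword.lower() in attr_text:
                family = fam
                break
        records.append(
            GeneRecord(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF3 1-based inclusive -> 0-based
                end=feat.end,
                family=family,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Panel


def read_panel(path) -> PopulationPanel:
    """Read the population panel TSV (columns population, survival, usage)."""
    df = pd.read_csv(path, sep="\t", dtype={"population": str, "usage": str})
    required = {"population", "survival", "usage"}
    if not required.issubset(df.columns):
        raise PanelError(f"panel must have columns {sorted(required)}, got {list(df.columns)}")
    rows = []
    for rec in df.itertuples(index=False):
        usage = frozenset(
            u.strip() for u in str(rec.usage).replace(";", ",").split(",") if u.strip()
        )
        survival = float(rec.survival)
        if survival == 0.5:
            warnings.warn(
                f"population {rec.population}: survival exactly 0.5 classified as S "
                "(ties go to susceptible)",
                stacklevel=2,
            )
        rows.append(PopulationRow(population=str(rec.population), survival=survival, usage=usage))
    return PopulationPanel(rows)


def write_panel(panel: PopulationPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("population\tsurvival\tusage\n")
        for r in panel:
            fh.write(f"{r.population}\t{r.survival}\t{','.join(sorted(r.usage))}\n")


def summarize_panel(panel: PopulationPanel, usage_flag: str, class_label: str) -> int:
    """Mean survival, as an integer percent, over populations matching a
    usage flag and resistance class.

    Rounding is half-up (a mean of 0.885 reports 89), not banker's.
    """
    vals = [
        r.survival
        for r in panel
        if usage_flag in r.usage and r.resistance_class == class_label
    ]
    if not vals:
        raise PanelError(f"no populations with usage {usage_flag!r} and class {class_label!r}")
    pct = 100.0 * float(np.mean(vals))
    return int(np.floor(pct + 0.5))


# ---------------------------------------------------------------------------
# Regions / BED


def write_regions(regions: RegionSet, path) -> None:
    """Write regions as BED (0-based half-open) with id and outlier count."""
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                warnings.warn(
                    f"overlapping regions on {chrom}: {a.region_id} and {b.region_id}",
                    stacklevel=2,
                )
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tregion_id\tn_outliers\n")
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.n_outliers}\n")


def read_regions(path) -> RegionSet:
    regions = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, rid, n = line.rstrip("\n").split("\t")
            regions.append(
                Region(region_id=rid, chrom=chrom, start=int(start), end=int(end), n_outliers=int(n))
            )
    return RegionSet(regions)


def write_gff(genes: list[GeneRecord], path, chrom_lengths: dict[str, int] | None = None) -> None:
    """Write gene records as GFF3 (used by the synthetic annotation maker)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for c, length in sorted(chrom_lengths.items()):
                fh.write(f"##sequence-region {c} 1 {length}\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            note = g.family if g.family != "other" else "hypothetical protein"
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                f"ID={g.gene_id};Note={note} family\n"
            )
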