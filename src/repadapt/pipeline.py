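"""Orchestrate the stages into reproducible, seeded runs.

A run is driven by a :class:`RunConfig` (YAML-friendly dict): simulate or
load inputs, then scan -> regions -> enrich -> windows -> ld ->
haplogroups -> converge as toggled.  One global seed expands
deterministically into per-stage seeds; the manifest records seeds, stage
outputs and counts so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import convergence, haplogroups, io_tables, outliers, popgen, regions, synthetic

log = logging.getLogger(__name__)

STAGES = ("simulate", "scan", "regions", "enrich", "windows", "ld", "haplogroups", "converge")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "repadapt_run",
    "stages": {s: True for s in STAGES},
    "thresholds": {
        "window_snps": 25,
        "top_score": 0.01,
        "top_rho": 0.05,
        "max_gap": regions.DEFAULT_MAX_GAP,
        "min_outliers": regions.DEFAULT_MIN_OUTLIERS,
        "r2_threshold": 0.25,
        "n_resample": 1000,
        "n_rand": 100,
        "n_boot": 1000,
        "maf_min": 0.02,
        "max_missing": 0.20,
        "thin_bp": 1000,
    },
    "inputs": {"vcf": None, "gff": None, "panel": None},  # None -> simulate
    "converge": {"x0_stride": 10, "use_reduced_grids": True},
}

_BOUNDS = {
    "window_snps": (1, 10_000),
    "top_score": (0.0, 1.0),
    "top_rho": (0.0, 1.0),
    "max_gap": (1, None),
    "min_outliers": (1, None),
    "r2_threshold": (0.0, 1.0),
    "n_resample": (1, None),
    "n_rand": (1, None),
    "n_boot": (1, None),
    "maf_min": (0.0, 0.5),
    "max_missing": (0.0, 1.0),
    "thin_bp": (1, None),
}


def validate_config(config: dict) -> list[str]:
    """Check bounds and keys; returns a list of error strings (empty = ok)."""
    errors = []
    known_top = set(DEFAULT_CONFIG)
    for key in config:
        if key not in known_top:
            errors.append(f"unknown config key: {key}")
    th = config.get("thresholds", {})
    for key, val in th.items():
        if key not in _BOUNDS:
            errors.append(f"unknown threshold: {key}")
            continue
        lo, hi = _BOUNDS[key]
        if val is None or (lo is not None and val < lo) or (hi is not None and val > hi) or (
            key in ("window_snps", "min_outliers") and val == 0
        ):
            errors.append(f"threshold {key}={val} out of range [{lo}, {hi}]")
    for s in config.get("stages", {}):
        if s not in STAGES:
            errors.append(f"unknown stage: {s}")
    seed = config.get("seed")
    if seed is not None and not isinstance(seed, (int, np.integer)):
        errors.append(f"seed must be an integer, got {seed!r}")
    return errors


def merged_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and key in cfg:
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministically expand the global seed into per-stage seeds."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        s: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        for s, c in zip(STAGES, children)
    }


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_all(config: dict | None = None) -> dict:
    """Execute the toggled stages; returns (and writes) the run manifest."""
    cfg = merged_config(config)
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    th = cfg["thresholds"]
    seeds = stage_seeds(int(cfg["seed"]))
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(cfg["seed"]), "stage_seeds": seeds, "stages": {}, "outputs": {}}
    enabled = {s: bool(cfg["stages"].get(s, True)) for s in STAGES}

    def record(stage, status, **extra):
        manifest["stages"][stage] = {"status": status, **extra}

    # ---- inputs -----------------------------------------------------------
    gm = panel = genes = truth = None
    try:
        if cfg["inputs"]["vcf"] is not None:
            panel = io_tables.read_panel(cfg["inputs"]["panel"])
            gm = io_tables.read_vcf(
                cfg["inputs"]["vcf"],
                panel=panel,
                maf_min=th["maf_min"],
                max_missing=th["max_missing"],
            )
            genes = io_tables.read_gff(cfg["inputs"]["gff"]) if cfg["inputs"]["gff"] else []
            chrom_lengths = {
                c: int(gm.pos[gm.chrom == c].max()) + 1 for c in set(gm.chrom.tolist())
            }
            record("simulate", "skipped (external inputs)")
        elif enabled["simulate"]:
            gm, panel, genes, truth = synthetic.make_default_scenario(seed=seeds["simulate"])
            chrom_lengths = truth.chrom_lengths
            vcf_path = out / "synthetic.vcf"
            io_tables.write_vcf(gm, vcf_path)
            io_tables.write_panel(panel, out / "panel.tsv")
            io_tables.write_gff(genes, out / "annotation.gff3", chrom_lengths)
            manifest["outputs"]["vcf"] = str(vcf_path)
            manifest["outputs"]["panel"] = str(out / "panel.tsv")
            manifest["outputs"]["gff"] = str(out / "annotation.gff3")
            record("simulate", "ok", n_sites=gm.n_sites, n_samples=gm.n_samples)
        else:
            raise ValueError("no inputs: simulate disabled and no VCF given")
    except Exception as exc:
        record("simulate", f"failed: {exc}")
        manifest["stages"].update({s: {"status": "skipped (upstream failure)"} for s in STAGES[1:]})
        _write_manifest(manifest, out)
        return manifest

    thinned = outliers.thin_snps(gm, bp_window=th["thin_bp"], seed=seeds["scan"])
    log.info("thinning: %d -> %d SNPs", gm.n_sites, thinned.n_sites)

    scan_tab = None
    region_set = regions_obj = None

    if enabled["scan"]:
        scan_tab = outliers.resistance_scan(
            thinned, panel, top_score=th["top_score"], top_rho=th["top_rho"]
        )
        path = out / "outliers.tsv"
        with open(path, "w") as fh:
            fh.write(outliers.SCORE_HEADER + "\n")
            scan_tab.table.to_csv(fh, sep="\t", index=False)
        manifest["outputs"]["outliers"] = str(path)
        record("scan", "ok", n_snps=len(scan_tab.table), n_outliers=int(scan_tab.table["outlier"].sum()))
    else:
        record("scan", "disabled")

    if enabled["regions"] and scan_tab is not None:
        region_set = regions.delimit_regions(
            scan_tab, max_gap=th["max_gap"], min_outliers=th["min_outliers"]
        )
        path = out / "regions.bed"
        io_tables.write_regions(region_set, path)
        manifest["outputs"]["regions"] = str(path)
        frac = (
            regions.fraction_in_regions(scan_tab, region_set)
            if int(scan_tab.table["outlier"].sum())
            else float("nan")
        )
        record("regions", "ok", n_regions=len(region_set), fraction_outliers_inside=frac)
    else:
        record("regions", "disabled" if not enabled["regions"] else "skipped (no scan)")

    if enabled["enrich"] and region_set is not None and genes:
        enr = regions.family_enrichment(
            region_set,
            genes,
            list(io_tables.GENE_FAMILIES),
            chrom_lengths,
            n_resample=th["n_resample"],
            seed=seeds["enrich"],
        )
        df = pd.DataFrame([dataclasses.asdict(e) for e in enr])
        path = out / "enrichment.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"]["enrichment"] = str(path)
        record("enrich", "ok", families=len(enr))
    else:
        record("enrich", "disabled" if not enabled["enrich"] else "skipped")

    if enabled["windows"]:
        ws = popgen.window_stats(gm, panel, window=th["window_snps"])
        path = out / "windows.tsv"
        ws.table.to_csv(path, sep="\t", index=False)
        manifest["outputs"]["windows"] = str(path)
        record("windows", "ok", n_windows=len(ws.table))
    else:
        record("windows", "disabled")

    if enabled["ld"]:
        rows = []
        for chrom in sorted(set(gm.chrom.tolist())):
            s = popgen.ld_r2(
                gm,
                chrom,
                span_threshold=th["r2_threshold"],
                regions=list(region_set) if region_set else None,
            )
            rows.append(
                {
                    "chrom": chrom,
                    "mean_r2": s.mean_r2,
                    "q3_r2": s.q3_r2,
                    "n_snps": s.n_snps,
                    "n_spans": len(s.spans),
                    "spans": ";".join(f"{a}-{b}" for a, b in s.spans),
                }
            )
        path = out / "ld.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["ld"] = str(path)
        record("ld", "ok", n_chroms=len(rows))
    else:
        record("ld", "disabled")

    if enabled["haplogroups"] and region_set is not None and len(region_set):
        rows = []
        for reg in region_set:
            ga = haplogroups.haplotype_groups_for_region(
                gm, panel, reg, seed=seeds["haplogroups"]
            )
            for pop, prop in ga.r_proportion.items():
                rows.append(
                    {"region_id": reg.region_id, "chrom": reg.chrom, "population": pop, "r_proportion": prop, "ambiguous": ga.ambiguous}
                )
        path = out / "haplogroups.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["haplogroups"] = str(path)
        record("haplogroups", "ok", n_regions=len(region_set))
    else:
        record("haplogroups", "disabled" if not enabled["haplogroups"] else "skipped")

    if enabled["converge"] and region_set is not None and len(region_set):
        neutral_chroms = (
            [c for c in set(gm.chrom.tolist()) if c not in {r.chrom for r in region_set}]
            or sorted(set(gm.chrom.tolist()))
        )
        freqs_all = popgen.pop_allele_freqs(thinned, panel).to_numpy(dtype=float)
        neutral_mask = np.isin(thinned.chrom, list(neutral_chroms))
        ok = neutral_mask & ~np.isnan(freqs_all).any(axis=1)
        F = convergence.estimate_F(freqs_all[ok], panel.populations)
        selected = tuple(panel.of_class("R"))
        sizes = {
            p: max(1, len(gm.sample_indices(p))) for p in panel.populations
        }
        grids = (
            convergence.REDUCED_GRIDS
            if cfg["converge"]["use_reduced_grids"]
            else convergence.DEFAULT_GRIDS
        )
        rows = []
        for reg in region_set:
            in_r = (thinned.chrom == reg.chrom) & (thinned.pos >= reg.start) & (thinned.pos < reg.end)
            if in_r.sum() < 10:
                rows.append({"region_id": reg.region_id, "status": "too few SNPs"})
                continue
            rf = popgen.pop_allele_freqs(thinned.take_sites(np.flatnonzero(in_r)), panel)
            fits = convergence.grid_search(
                rf.to_numpy(dtype=float),
                thinned.pos[in_r],
                F,
                selected,
                sizes,
                grids=grids,
                x0_stride=int(cfg["converge"]["x0_stride"]),
            )
            ranking = convergence.rank_models(fits, t_grid_max=max(grids["t"]))
            best = fits[ranking[0]]
            rows.append(
                {
                    "region_id": reg.region_id,
                    "status": "ok",
                    "best_model": ranking[0],
                    "ranking": ">".join(ranking),
                    "max_ratio": best.max_ratio,
                    "x0_hat": best.x0_hat,
                    "s_hat": best.mle_params.s if best.mle_params else None,
                }
            )
        path = out / "convergence.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["convergence"] = str(path)
        record("converge", "ok", n_regions=len(rows))
    else:
        record("converge", "disabled" if not enabled["converge"] else "skipped")

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    for name, path in manifest["outputs"].items():
        manifest["outputs"][name] = {"path": path, "sha256_16": _hash_file(Path(path))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def load_config(path) -> dict:
    with open(path) as fh:
        return merged_config(yaml.safe_load(fh) or {})
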