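"""End-to-end orchestration of the four analysis stages.

A run is driven by a YAML config with one section per stage (``scan``,
``bootstrap``, ``concord``, ``annotate``, ``vbm``); stages are optional and
run in that order. Every run writes a manifest recording the package
version, the seeds, and the conventions in force (grid-m convention,
hemisphere policy), so a rerun with the same config reproduces every output
byte-for-byte apart from the manifest timestamp. Empty results (no
significant association, no cluster) exit successfully — only input errors
abort.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

import antagmap
from antagmap import annotation, concordance, enrichment_null, fdr_scan, sumstats_io, vbm
from antagmap.errors import ConfigError, InputError


@dataclass
class RunConfig:
    """Validated run configuration (one attribute per stage section)."""

    scan: Optional[dict] = None
    bootstrap: Optional[dict] = None
    concord: Optional[dict] = None
    annotate: Optional[dict] = None
    vbm: Optional[dict] = None
    output_dir: str = "antagmap_out"
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping, base: Optional[Path] = None) -> "RunConfig":
        known = {"scan", "bootstrap", "concord", "annotate", "vbm", "output_dir", "alpha"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        cfg = cls(
            scan=raw.get("scan"),
            bootstrap=raw.get("bootstrap"),
            concord=raw.get("concord"),
            annotate=raw.get("annotate"),
            vbm=raw.get("vbm"),
            output_dir=str(raw.get("output_dir", "antagmap_out")),
            alpha=float(raw.get("alpha", 0.05)),
        )
        if not (0.0 < cfg.alpha < 1.0):
            raise ConfigError("alpha must be in (0, 1)")
        cfg._validate_paths(base)
        return cfg

    def _validate_paths(self, base: Optional[Path]) -> None:
        """Fail before any stage runs if a referenced input is missing."""
        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() or base is None else base / p

        path_keys = {
            "scan": ("targets", "idp_catalog", "sumstats_dir"),
            "bootstrap": ("cross_disorder_table",),
            "concord": ("case_control",),
            "annotate": ("eqtl", "traits"),
            "vbm": ("mask", "covariates", "atlas", "atlas_lut"),
        }
        for section, keys in path_keys.items():
            cfg = getattr(self, section)
            if not cfg:
                continue
            for key in keys:
                if key in cfg and cfg[key] is not None:
                    p = resolve(cfg[key])
                    if not p.exists():
                        raise ConfigError(f"{section}.{key}: path {p} does not exist")
                    cfg[key] = str(p)
            if section == "vbm" and "images" in cfg:
                imgs = cfg["images"]
                imgs = [imgs] if isinstance(imgs, str) else list(imgs)
                resolved = [str(resolve(p)) for p in imgs]
                for p in resolved:
                    if not Path(p).exists():
                        raise ConfigError(f"vbm.images: path {p} does not exist")
                cfg["images"] = resolved if len(resolved) > 1 else resolved[0]


def _load_scan_inputs(cfg: dict):
    targets = sumstats_io.read_target_snps(cfg["targets"])
    idps = sumstats_io.read_idp_catalog(cfg["idp_catalog"])
    sumstats_dir = Path(cfg["sumstats_dir"])
    catalogs = {}
    for idp in idps:
        path = sumstats_dir / f"{idp.idp_id}.tsv"
        if not path.exists():
            continue  # absent table -> all its cells become missing
        result = sumstats_io.read_sumstats(path, cfg.get("column_map"))
        catalogs[idp.idp_id] = {r.snp_id: r for r in result.records}
    return targets, idps, catalogs


def run_scan(cfg: dict, alpha: float, outdir: Path) -> dict:
    targets, idps, catalogs = _load_scan_inputs(cfg)
    grid = fdr_scan.build_grid(
        targets,
        idps,
        catalogs,
        min_proxy_r2=float(cfg.get("min_proxy_r2", 0.8)),
        ambiguity_policy=cfg.get("ambiguity_policy", "warn"),
        count_missing_as_tests=bool(cfg.get("count_missing_as_tests", False)),
    )
    grid.adjust(m=cfg.get("m"), alpha=alpha)
    table = fdr_scan.significant_table(grid, targets=targets)
    fdr_scan.write_report(table, outdir / "significant_associations.tsv")
    with open(outdir / "grid.json", "w") as fh:
        json.dump(
            {
                "m": grid.m,
                "alpha": grid.alpha,
                "n_entries": len(grid.entries),
                "n_significant": int(grid.entries["significant"].sum()),
                "missing": [list(x) for x in grid.missing],
            },
            fh,
            indent=2,
        )
    return {
        "grid": grid,
        "targets": targets,
        "idps": idps,
        "significant": table,
        "n_significant": int(grid.entries["significant"].sum()),
    }


def run_bootstrap(cfg: dict, alpha: float, outdir: Path, scan_state: Optional[dict]) -> dict:
    if scan_state is None:
        raise InputError("bootstrap stage requires the scan stage in the same run")
    grid = scan_state["grid"]
    targets = scan_state["targets"]

    # pool over all SNPs shared by every per-IDP table of the scan
    _, idps, catalogs = _load_scan_inputs(scan_state["config"])
    if not catalogs:
        raise InputError("bootstrap: no summary-statistics tables found")
    common = set.intersection(*(set(c) for c in catalogs.values()))
    exclusions = {t.snp_id for t in targets} | {t.proxy_id for t in targets if t.proxy_id}

    cross_p = None
    if cfg.get("pool", "all") == "cross-disorder":
        tab = pd.read_csv(cfg["cross_disorder_table"], sep="\t")
        cross_p = dict(zip(tab["snp_id"].astype(str), tab["p"].astype(float)))
    pool = enrichment_null.define_pool(
        common,
        mode="cross_disorder" if cross_p is not None else "all_snps",
        cross_disorder_p=cross_p,
        exclusions=exclusions,
    )

    idp_order = [i.idp_id for i in idps if i.idp_id in catalogs]

    def grid_builder(snp_ids):
        return np.array(
            [catalogs[idp][s].pvalue for s in snp_ids for idp in idp_order], dtype=float
        )

    B = int(cfg.get("replicates", 10000))
    seed = int(cfg.get("seed", 0))
    set_size = int(cfg.get("set_size", len(targets)))
    null = enrichment_null.sample_null_counts(
        pool, set_size, B, grid_builder, seed=seed, alpha=alpha,
        pool_id=cfg.get("pool", "all"),
    )
    null.observed = scan_state["n_significant"]
    hist = np.bincount(null.counts)
    with open(outdir / "bootstrap.json", "w") as fh:
        json.dump(
            {
                "observed": null.observed,
                "B": null.B,
                "seed": seed,
                "pool_id": null.pool_id,
                "pool_size": len(pool),
                "empirical_p": null.empirical_p,
                "counts_histogram": {int(i): int(c) for i, c in enumerate(hist) if c},
            },
            fh,
            indent=2,
        )
    return {"null": null, "empirical_p": null.empirical_p}


def run_concord(cfg: dict, alpha: float, outdir: Path, scan_state: Optional[dict]) -> dict:
    if scan_state is None:
        raise InputError("concord stage requires the scan stage in the same run")
    cc = concordance.read_case_control(cfg["case_control"])
    policy = cfg.get("hemisphere_policy", "both-required")
    triplets = concordance.triangulate(
        scan_state["significant"], scan_state["targets"], cc, policy=policy, alpha=alpha
    )
    pairs = [
        (t.disorder_risk, t.disorder_protective) for t in scan_state["targets"]
    ]
    opposed = concordance.find_opposed_idps(
        scan_state["significant"], cc, pairs, policy=policy, alpha=alpha
    )
    frame = pd.DataFrame(
        [
            {
                "snp_id": t.snp_id,
                "idp_id": t.idp_id,
                "risk": t.disorder_risk,
                "protective": t.disorder_protective,
                "sign_snp_idp": t.sign_snp_idp,
                **{f"sign_{d}": s for d, s in t.sign_case_control.items()},
                "call": t.call,
                "reason": t.reason or "",
            }
            for t in triplets
        ]
    )
    frame.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    with open(outdir / "opposed_idps.json", "w") as fh:
        json.dump([{"idp_id": i, "disorders": list(p)} for i, p in opposed], fh, indent=2)
    return {"triplets": triplets, "opposed": opposed}


def run_annotate(cfg: dict, alpha: float, outdir: Path) -> dict:
    out = {}
    if "eqtl" in cfg:
        eqtl = annotation.read_eqtl(cfg["eqtl"])
        kept = annotation.eqtl_filter(
            eqtl,
            n_snps=int(cfg["n_snps"]),
            n_tissues=int(cfg["n_tissues"]),
            alpha=alpha,
            paper_compat=bool(cfg.get("paper_compat", False)),
        )
        kept.to_csv(outdir / "eqtl_significant.tsv", sep="\t", index=False)
        out["eqtl"] = kept
    if "traits" in cfg:
        traits = annotation.read_traits(cfg["traits"])
        kept = annotation.trait_filter(
            traits, threshold=float(cfg.get("trait_threshold", annotation.GENOME_WIDE_P))
        )
        kept.to_csv(outdir / "traits_retained.tsv", sep="\t", index=False)
        out["traits"] = kept
    return out


def run_vbm(cfg: dict, alpha: float, outdir: Path) -> dict:
    cohort = vbm.load_cohort(
        cfg["images"], cfg["mask"], cfg["covariates"], [cfg["snp"]]
    )
    directions = {
        "pos": ["positive"], "neg": ["negative"], "both": ["positive", "negative"],
    }[cfg.get("direction", "both")]
    result = vbm.fit_voxelwise_glm(cohort, cfg["snp"])
    all_clusters = []
    for direction in directions:
        clusters = vbm.threshold_clusters(
            result,
            direction=direction,
            p_cluster_forming=float(cfg.get("cf_p", 0.001)),
            k_min=int(cfg.get("k_min", 11)),
            connectivity=int(cfg.get("connectivity", 18)),
        )
        if clusters:
            vbm.permutation_peak_fwe(
                cohort, cfg["snp"], clusters,
                n_perm=int(cfg.get("n_perm", 1000)),
                seed=int(cfg.get("seed", 0)),
            )
        all_clusters.extend(clusters)
    if "atlas" in cfg and cfg.get("atlas"):
        import nibabel as nib

        atlas = nib.load(cfg["atlas"])
        lut = vbm.read_label_lookup(cfg["atlas_lut"])
        vbm.annotate_clusters(
            all_clusters, np.asarray(atlas.get_fdata()).astype(int), atlas.affine, lut
        )
    frame = vbm.clusters_to_frame(all_clusters)
    frame.to_csv(outdir / "vbm_clusters.tsv", sep="\t", index=False)
    return {"clusters": all_clusters, "df": result.df}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns per-stage results."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    scan_state = None
    stages = []
    if config.scan:
        stages.append("scan")
        scan_state = run_scan(config.scan, config.alpha, outdir)
        scan_state["config"] = config.scan
        results["scan"] = scan_state
    if config.bootstrap:
        stages.append("bootstrap")
        results["bootstrap"] = run_bootstrap(config.bootstrap, config.alpha, outdir, scan_state)
    if config.concord:
        stages.append("concord")
        results["concord"] = run_concord(config.concord, config.alpha, outdir, scan_state)
    if config.annotate:
        stages.append("annotate")
        results["annotate"] = run_annotate(config.annotate, config.alpha, outdir)
    if config.vbm:
        stages.append("vbm")
        results["vbm"] = run_vbm(config.vbm, config.alpha, outdir)

    manifest = {
        "package": "antagmap",
        "version": antagmap.__version__,
        "stages": stages,
        "alpha": config.alpha,
        "m_convention": (
            "explicit" if config.scan and config.scan.get("m") is not None
            else ("count-missing-as-tests" if config.scan and config.scan.get("count_missing_as_tests")
                  else "non-missing-entries")
        ) if config.scan else None,
        "hemisphere_policy": config.concord.get("hemisphere_policy", "both-required")
        if config.concord else None,
        "seeds": {
            "bootstrap": config.bootstrap.get("seed", 0) if config.bootstrap else None,
            "vbm": config.vbm.get("seed", 0) if config.vbm else None,
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results
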