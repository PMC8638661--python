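"""End-to-end orchestration: simulate/ingest -> encode -> impute -> thin
-> per-type kinship -> CV designs -> optional DiPR scan.

Every stage draws from a single configured seed; the run manifest
(config, seed, package version, stage decisions) suffices to regenerate
every output exactly.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as _io
from .crossval import (
    CVScheme,
    gblup_predictor,
    lineage_kfold_between,
    mccv_within,
    stratify_dw6,
)
from .dipr import dipr_scan
from .markers import impute, kinship, thin
from .model import fit_gblup
from .popsim import SimConfig, phenotype_means, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of one full analysis run.

    Exactly one of ``sim`` (synthetic mode) or ``tables`` (paths to the
    four delimited tables) must be given.
    """

    sim: SimConfig | None = None
    tables: dict | None = None  # keys: genotypes, map, phenotypes, lineage
    trait: str = "trait"
    impute_method: str = "column_mean"
    thin_r2: float = 0.90
    thin_before_impute: bool = False
    cv_design: str = "within"  # or "between"
    cv_k: int = 2
    cv_replicates: int = 100
    stratify_marker: str | None = None
    dipr: bool = False
    dipr_step: float = 0.01
    dipr_replicates: int = 10
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.tables is None):
            raise ValueError("exactly one of sim / tables must be configured")
        if self.cv_design not in ("within", "between"):
            raise ValueError(f"unknown cv_design {self.cv_design!r}")
        if self.cv_design == "between" and self.cv_k not in (2, 3, 4, 5):
            raise ValueError(f"cv_k must be one of 2, 3, 4, 5; got {self.cv_k!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        if sim is not None:
            sim = SimConfig(**sim)
        return cls(sim=sim, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analysis and write results under out_dir.

    Returns a result bundle (also written to disk): accuracy tables,
    fit summary, optionally the DiPR weight curve, and a run manifest.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "stages": {},
    }

    # --- ingest -----------------------------------------------------------
    if config.sim is not None:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        ds = simulate_dataset(sim_cfg)
        _io.write_dataset(ds, out / "simulated")
        gmap = ds.marker_map
        if config.cv_design == "within":
            gm_raw = ds.genotypes_f2
            pheno = ds.phenotypes[ds.phenotypes["line"].isin(gm_raw.index)]
        else:
            gm_raw = pd.concat([ds.genotypes_f2, ds.genotypes_ril]).reindex(
                columns=ds.common_markers
            )
            pheno = ds.phenotypes
        lineage = ds.lineage.set_index("line")["lineage"]
    else:
        gm_raw, gmap, pheno, lin = _io.read_tables(**config.tables)
        lineage = lin.set_index("line")["lineage"]
    if config.trait not in set(pheno["trait"]):
        raise ValueError(f"trait {config.trait!r} not present in the phenotype table")
    y = phenotype_means(pheno, config.trait)

    # --- marker pipeline --------------------------------------------------
    stage_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    if config.thin_before_impute:
        kept0 = thin(gm_raw.dropna(axis=1, how="any"), gmap, config.thin_r2)
        gm_raw = gm_raw[kept0]
    gm = impute(gm_raw, method=config.impute_method, rng=stage_rng, gmap=gmap)
    kept = thin(gm, gmap, config.thin_r2)
    manifest["stages"]["thin"] = {
        "input_markers": int(gm.shape[1]),
        "retained": len(kept),
        "r2_threshold": config.thin_r2,
    }
    gm = gm[kept]
    types = gmap.set_index("marker")["type"].loc[kept]
    dom = [m for m in kept if types[m] == "dominant"]
    cod = [m for m in kept if types[m] == "codominant"]
    K_all = kinship(gm)
    results: dict = {}

    # --- evaluation -------------------------------------------------------
    if config.cv_design == "within":
        scheme = CVScheme(
            kind="mccv_within",
            replicates=config.cv_replicates,
            seed=config.seed,
            stratify_dw6=config.stratify_marker is not None,
        )
        classes = (
            stratify_dw6(gm, config.stratify_marker)
            if config.stratify_marker
            else None
        )
        report = mccv_within(y, gblup_predictor(K_all), scheme, classes=classes)
        rows = [("within", config.trait, "All", report.aggregate, report.n_eff)]
        if report.strata:
            for label, sub in report.strata.items():
                if label == "All" or sub is None:
                    continue
                rows.append(("within", config.trait, label, sub.aggregate, sub.n_eff))
        acc = pd.DataFrame(
            rows, columns=["design", "trait", "stratum", "accuracy", "n_eff"]
        )
    else:
        early = y.index.intersection(lineage.index[lineage.index.str.startswith("F2")])
        ril = y.index.intersection(lineage.index[lineage.index.str.startswith("RIL")])
        scheme = CVScheme(
            kind="lineage_kfold",
            k=config.cv_k,
            replicates=config.cv_replicates,
            seed=config.seed,
        )
        report = lineage_kfold_between(
            y.loc[early], lineage.loc[early], y.loc[ril], lineage.loc[ril],
            gblup_predictor(K_all), scheme,
        )
        acc = pd.DataFrame(
            [
                ("between", config.trait, s, r.aggregate, r.n_eff)
                for s, r in report.strata.items()
            ],
            columns=["design", "trait", "stratum", "accuracy", "n_eff"],
        )
    acc.to_csv(out / "accuracy.csv", index=False)
    results["accuracy"] = acc

    reps = pd.DataFrame(
        {"replicate": range(len(report.replicate_r)), "r": report.replicate_r}
    )
    reps.to_csv(out / "replicates.csv", index=False)

    fit = fit_gblup(y.reindex(K_all.index), K_all)
    summary = {
        "sigma2_u": fit.sigma2_u,
        "sigma2_e": fit.sigma2_e,
        "lambda": fit.lambda_,
        "beta": fit.beta,
        "loglik": fit.loglik,
        "h2_reml": fit.sigma2_u / (fit.sigma2_u + fit.sigma2_e),
    }
    with open(out / "fit_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    results["fit_summary"] = summary

    # --- DiPR -------------------------------------------------------------
    if config.dipr:
        if not dom or not cod:
            raise ValueError("DiPR needs both dominant and codominant markers")
        K_dom = kinship(gm, dom)
        K_cod = kinship(gm, cod)
        scan = dipr_scan(
            y.reindex(K_all.index).dropna(),
            K_dom,
            K_cod,
            CVScheme(replicates=config.dipr_replicates, seed=config.seed),
            grid_step=config.dipr_step,
        )
        scan.to_frame().to_csv(out / "dipr_curve.csv", index=False)
        results["dipr"] = {"w_opt": scan.w_opt, "accuracy_opt": scan.accuracy_opt}
        manifest["stages"]["dipr"] = results["dipr"]

    manifest["stages"]["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
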