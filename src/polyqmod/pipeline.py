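"""Stage orchestration with plain-TSV hand-offs and a run manifest.

Every stage reads and writes inspectable TSV files under one output
directory, so a run can be audited or resumed stage by stage:

    simulate   -> genotypes.dosage.tsv, genotypes.vcf, phenotypes.tsv,
                  priors.tsv, truth.tsv
    qc         -> qc_report.tsv
    residualize-> onset_models.tsv, residuals.tsv, sex_check.tsv
    assoc      -> association.tsv
    combine    -> ld_matrix.tsv, combination.tsv, sensitivity.tsv,
                  proxy_pairs.tsv
    score      -> scores.tsv, score_quartiles.tsv
    run        -> all of the above + summary.txt + manifest.json

The manifest records the config snapshot, seed, a SHA-256 checksum of every
output, package versions and machine-readable warnings (AAO flooring,
score imputation, missing-LD fallbacks). Re-running with the same config
and seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cohort_io, combine, onset, qc, score
from .association import associate_all
from .containers import DISEASE_GROUPS
from .model import ModifierAnalysis
from .simulate import OnsetParams, SimConfig, simulate_cohort, study_config

logger = logging.getLogger("polyqmod")

FILENAMES = {
    "genotypes": "genotypes.dosage.tsv",
    "vcf": "genotypes.vcf",
    "phenotypes": "phenotypes.tsv",
    "priors": "priors.tsv",
    "truth": "truth.tsv",
    "qc": "qc_report.tsv",
    "onset_models": "onset_models.tsv",
    "residuals": "residuals.tsv",
    "sex_check": "sex_check.tsv",
    "association": "association.tsv",
    "ld": "ld_matrix.tsv",
    "combination": "combination.tsv",
    "sensitivity": "sensitivity.tsv",
    "proxy_pairs": "proxy_pairs.tsv",
    "scores": "scores.tsv",
    "score_quartiles": "score_quartiles.tsv",
    "summary": "summary.txt",
    "manifest": "manifest.json",
}


def load_config(path: str | Path) -> dict:
    """Load a flat YAML run config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValueError("config needs a 'simulate' block or an 'inputs' block")
    return cfg


def _sim_config(cfg: dict, seed: int) -> SimConfig:
    sim = dict(cfg.get("simulate") or {})
    preset = sim.pop("preset", "study")
    if preset != "study":
        raise ValueError(f"unknown simulation preset {preset!r}")
    eff = sim.pop("effect_sizes", 0.0)
    if isinstance(eff, list):
        eff = np.asarray(eff, dtype=float)
    return study_config(seed=seed, effect_sizes=eff, **sim)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _options(cfg: dict) -> dict:
    opts = {
        "residual_scale": "years",
        "hwe_threshold": qc.HWE_THRESHOLD_DEFAULT,
        "min_call_rate": 0.0,
        "cov_method": "polynomial",
        "ld_proxy_threshold": 0.8,
    }
    opts.update(cfg.get("options") or {})
    return opts


def stage_simulate(cfg: dict, out: Path, seed: int, warnings: list[dict]) -> None:
    sim = simulate_cohort(_sim_config(cfg, seed))
    cohort_io.write_dosage_tsv(sim.genotypes, out / FILENAMES["genotypes"])
    cohort_io.write_vcf(sim.genotypes, out / FILENAMES["vcf"])
    cohort_io.write_phenotypes(sim.phenotypes, out / FILENAMES["phenotypes"])
    cohort_io.write_priors(sim.priors, out / FILENAMES["priors"])
    _write_tsv(sim.truth.reset_index(drop=True), out / FILENAMES["truth"])
    if sim.n_floored:
        warnings.append({"code": "AAO_FLOORED", "count": sim.n_floored})


def _load_stage_inputs(cfg: dict, out: Path):
    if "inputs" in cfg:
        inp = cfg["inputs"]
        priors = cohort_io.read_priors(inp["priors"])
        geno = cohort_io.read_genotypes(
            inp["genotypes"], inp.get("genotype_format", "dosage-tsv"), priors
        )
        pheno = cohort_io.read_phenotypes(inp["phenotypes"])
    else:
        priors = cohort_io.read_priors(out / FILENAMES["priors"])
        geno = cohort_io.read_genotypes(out / FILENAMES["genotypes"], "dosage-tsv", priors)
        pheno = cohort_io.read_phenotypes(out / FILENAMES["phenotypes"])
    return geno, pheno, priors


def run_all(cfg: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run every stage under one config; returns the manifest dict.

    The headline table is the one-sided Brown combination over the eight
    disease groups with the 0.05/8 Bonferroni threshold.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    opts = _options(cfg)
    warnings: list[dict] = []
    manifest: dict = {
        "config": cfg,
        "seed": seed,
        "package_version": __version__,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages_completed": [],
        "warnings": warnings,
        "checksums": {},
    }
    try:
        if "simulate" in cfg:
            stage_simulate(cfg, out, seed, warnings)
            manifest["stages_completed"].append("simulate")

        geno, pheno, priors = _load_stage_inputs(cfg, out)
        analysis = ModifierAnalysis(
            geno, pheno, priors,
            hwe_threshold=float(opts["hwe_threshold"]),
            min_call_rate=float(opts["min_call_rate"]),
            residual_scale=str(opts["residual_scale"]),
        )
        res = analysis.fit(
            cov_method=str(opts["cov_method"]),
            seed=seed,
            ld_proxy_threshold=float(opts["ld_proxy_threshold"]),
        )

        _write_tsv(res.qc_report.reset_index(drop=True), out / FILENAMES["qc"])
        manifest["stages_completed"].append("qc")

        models_df = pd.DataFrame(
            [
                {"disease": d, "A": m.A, "B": m.B, "p_slope": m.p_slope,
                 "n": m.n, "r2": m.r2}
                for d, m in res.onset_models.items()
            ]
        )
        _write_tsv(models_df, out / FILENAMES["onset_models"])
        resid_out = res.residuals.rename(columns={"residual": f"residual_{res.residual_scale}"})
        _write_tsv(resid_out, out / FILENAMES["residuals"])
        _write_tsv(res.sex_check, out / FILENAMES["sex_check"])
        manifest["stages_completed"].append("residualize")

        _write_tsv(res.associations, out / FILENAMES["association"])
        manifest["stages_completed"].append("assoc")

        if res.ld is not None:
            ld_out = res.ld.r.copy()
            ld_out.insert(0, "snp_id", ld_out.index)
            _write_tsv(ld_out, out / FILENAMES["ld"])
        _write_tsv(res.combined, out / FILENAMES["combination"])
        _write_tsv(res.sensitivity, out / FILENAMES["sensitivity"])
        _write_tsv(res.proxy_pairs, out / FILENAMES["proxy_pairs"])
        manifest["stages_completed"].append("combine")
        n_missing_ld = int(res.combined["n_missing_ld"].sum()) if len(res.combined) else 0
        if n_missing_ld:
            warnings.append({"code": "LD_FALLBACK", "count": n_missing_ld})

        _write_tsv(res.score.scores, out / FILENAMES["scores"])
        _write_tsv(res.score.quartile_summary, out / FILENAMES["score_quartiles"])
        if res.score.n_imputed:
            warnings.append({"code": "SCORE_IMPUTED", "count": res.score.n_imputed})
        manifest["stages_completed"].append("score")

        (out / FILENAMES["summary"]).write_text(res.summary() + "\n")
        manifest["tiers"] = res.tiers
        manifest["score_r2"] = res.score.r2_score
        manifest["exit_status"] = 0
    except Exception as exc:  # manifest records partial completion
        manifest["exit_status"] = 1
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _finalize_manifest(manifest, out)
        raise
    _finalize_manifest(manifest, out)
    return manifest


def _finalize_manifest(manifest: dict, out: Path) -> None:
    for key, name in FILENAMES.items():
        path = out / name
        if key != "manifest" and path.exists():
            manifest["checksums"][name] = _sha256(path)
    with open(out / FILENAMES["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
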