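"""File formats, configuration and the end-to-end pipeline driver.

Summary statistics travel as tab-separated ``.ma``-style files (the
conditional-and-joint analysis dialect): columns ``SNP A1 A2 freq b se p N``
plus an optional ``INFO`` column. Positions in summary-statistic tables are
1-based; gene intervals use the BED convention (0-based, half-open); the
conversion lives in :func:`fnwpipe.gwas.annotate_nearest_gene`.

:func:`run_pipeline` chains every stage on synthetic data — simulate,
neck-width geometry, phenotype, association scan, conditional signal
selection, LD-score genetic correlation, (multivariable) Mendelian
randomization, genetic risk scores and grouped survival — and emits a JSON
report with filter bookkeeping and a truth-vs-estimate table. Rerunning
with the same configuration reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, grs, gwas, ldsc, mr, synth

__all__ = [
    "read_sumstats",
    "write_sumstats",
    "load_fnw_signals",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("fnwpipe")

_MA_COLUMNS = {"SNP": "snp", "A1": "EA", "A2": "OA", "freq": "EAF",
               "b": "beta", "se": "se", "p": "p", "N": "n"}


def write_sumstats(table: pd.DataFrame, path) -> None:
    """Write a summary-statistic table as a tab-separated ``.ma`` file."""
    out = pd.DataFrame(
        {
            "SNP": table["snp"],
            "A1": table["EA"],
            "A2": table["OA"],
            "freq": table["EAF"],
            "b": table["beta"],
            "se": table["se"],
            "p": table["p"],
            "N": table["n"],
        }
    )
    if "info" in table.columns:
        out["INFO"] = table["info"]
    for extra in ("chr", "pos"):
        if extra in table.columns:
            out[extra] = table[extra]
    out.to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    """Read a ``.ma``-style summary-statistic file with validation.

    Malformed rows are rejected with 1-based line numbers (header = line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    out = df.rename(columns={**_MA_COLUMNS, "INFO": "info"})
    numeric = ["EAF", "beta", "se", "p", "n"] + (["info"] if "info" in out else [])
    for col in numeric:
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() & out[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 to 1-based
            raise ValueError(f"non-numeric {col!r} on line {line}")
        out[col] = parsed
    checks = [
        ("EAF", (out["EAF"] <= 0) | (out["EAF"] >= 1)),
        ("se", out["se"] <= 0),
        ("p", (out["p"] <= 0) | (out["p"] > 1)),
    ]
    for col, bad in checks:
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(f"invalid {col!r} value on line {line}")
    for extra in ("chr", "pos"):
        if extra in out.columns:
            out[extra] = pd.to_numeric(out[extra])
    out["z"] = out["beta"] / out["se"]
    return out


def load_fnw_signals() -> pd.DataFrame:
    """The 71 conditionally independent FNW signals shipped with the package.

    Columns: SNP, chr, pos, closest_gene, distance_to_gene, EA, OA, EAF,
    beta, se, p — per-allele effects of each signal on standardized femoral
    neck width, with the closest gene and its distance in bp.
    """
    with importlib.resources.files("fnwpipe.data").joinpath(
        "fnw_cojo_signals.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_DEFAULT_THRESHOLDS = {
    "p_gws": 5e-8,
    "maf": 0.01,
    "info": 0.3,
    "prune_r2": 0.01,
    "collinearity_r2": 0.9,
    "ldsc_maf": 0.05,
    "cutoffs": [50, 25, 10],
}

_DEFAULT_SIZES = {
    "n_panel": 1000,
    "n_cohort": 20_000,
    "n_variants": 2000,
    "block_size": 10,
    "within_block_rho": 0.4,
    "followup_yr": 15.5,
    "n_fnw_signals": 71,
    "n_bmd_signals": 49,
    "ld_window_kb": 1000.0,
    "n_jackknife_blocks": 50,
    "discovery_fraction": 0.5,
}


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    seed: int = 1
    out_dir: str = "pipeline_out"
    thresholds: dict = field(default_factory=lambda: dict(_DEFAULT_THRESHOLDS))
    sizes: dict = field(default_factory=lambda: dict(_DEFAULT_SIZES))
    stages: dict = field(
        default_factory=lambda: {
            "geometry": True, "gwas": True, "ldsc": True, "mr": True, "grs": True,
        }
    )

    def __post_init__(self):
        for name, defaults, given in (
            ("thresholds", _DEFAULT_THRESHOLDS, self.thresholds),
            ("sizes", _DEFAULT_SIZES, self.sizes),
        ):
            unknown = set(given) - set(defaults)
            if unknown:
                raise ValueError(f"unknown {name} keys: {sorted(unknown)}")
            merged = dict(defaults)
            merged.update(given)
            setattr(self, name, merged)
        t = self.thresholds
        if not (0 < t["p_gws"] < 1 and 0 <= t["maf"] < 0.5 and 0 < t["prune_r2"] <= 1
                and 0 < t["collinearity_r2"] <= 1):
            raise ValueError("threshold out of range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"seed", "out_dir", "thresholds", "sizes", "stages"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------

def _round(x, nd=10):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return None if not np.isfinite(x) else round(float(x), nd)
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage end to end on synthetic data and write a report.

    Stage order: simulate -> neck-width geometry -> phenotype -> quantitative
    scan -> conditional signal selection -> LD-score genetic correlation ->
    MR / multivariable MR -> risk scores and Cox models -> binarized groups.
    The report records every filter's input/output counts and pairs each
    estimate with its simulated truth. Deterministic for a fixed config.
    """
    rng_seed = int(config.seed)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sz, th = config.sizes, config.thresholds
    report: dict = {"config": asdict(config), "stages": {}, "counts": {}, "truth_vs_estimate": []}

    stage = "simulate"
    try:
        panel = synth.simulate_reference_panel(
            n_individuals=sz["n_panel"],
            n_variants=sz["n_variants"],
            block_size=sz["block_size"],
            within_block_rho=sz["within_block_rho"],
            seed=rng_seed,
        )
        arch = synth.default_architecture(
            panel,
            n_fnw=sz["n_fnw_signals"],
            n_bmd=sz["n_bmd_signals"],
            seed=rng_seed + 1,
        )
        cohort = synth.simulate_cohort(
            panel, arch, n=sz["n_cohort"], followup_yr=sz["followup_yr"],
            discovery_fraction=sz["discovery_fraction"], seed=rng_seed + 2,
        )
        synth.write_truth(arch, out_dir / "truth.json")
        report["stages"][stage] = {
            "n_panel": panel.n_individuals,
            "n_variants": panel.n_variants,
            "n_cohort": cohort.n,
        }

        if config.stages.get("geometry", True):
            stage = "geometry"
            target = float(cohort.table["fnw_mm"].mean())
            ann = synth.simulate_shape_annotation(target, 0.5, jitter_sd=0.0, seed=rng_seed)
            width = geometry.compute_fnw(ann)
            report["stages"][stage] = {"target_mm": target, "recovered_mm": width.fnw_mm}
            report["truth_vs_estimate"].append(
                {"quantity": "fnw_mm_roundtrip", "truth": target, "estimate": width.fnw_mm}
            )

        stage = "phenotype"
        disc_mask = cohort.table["discovery_flag"] == 1
        discovery = cohort.subset(disc_mask) if disc_mask.sum() >= 200 else cohort
        pheno = gwas.prepare_phenotype(discovery)
        pheno_bmd = gwas.prepare_phenotype(discovery, trait="bmd_sd")
        report["stages"][stage] = {"n_discovery": discovery.n}

        if config.stages.get("gwas", True):
            stage = "gwas"
            ss_fnw = gwas.run_quant_gwas(
                discovery, pheno, maf_min=th["maf"], info_min=th["info"],
                variants_meta=panel.variants,
            )
            ss_bmd = gwas.run_quant_gwas(
                discovery, pheno_bmd, maf_min=th["maf"], info_min=th["info"],
                variants_meta=panel.variants,
            )
            write_sumstats(ss_fnw, out_dir / "fnw_gwas.ma")
            report["counts"]["variants_scanned"] = len(ss_fnw)

            selected = gwas.cojo_select(
                ss_fnw, panel, p_threshold=th["p_gws"],
                collinearity_r2=th["collinearity_r2"],
            )
            ve = gwas.variance_explained(selected) if len(selected) else 0.0
            maf_classes = gwas.classify_maf(selected) if len(selected) else {}
            report["stages"][stage] = {
                "n_selected_signals": len(selected),
                "variance_explained": ve,
                "maf_classes": maf_classes,
            }
            report["truth_vs_estimate"].append(
                {
                    "quantity": "fnw_variance_explained",
                    "truth": arch.target_fnw_variance,
                    "estimate": ve,
                }
            )
        else:
            ss_fnw = ss_bmd = None
            selected = None

        if config.stages.get("ldsc", True) and ss_fnw is not None:
            stage = "ldsc"
            ld = ldsc.compute_ld_scores(
                panel, window_kb=sz["ld_window_kb"], maf_min=th["ldsc_maf"]
            )
            ld.scores.to_csv(out_dir / "ld_scores.tsv", sep="\t", index=False)
            rg_res = ldsc.ldsc_rg(
                ss_fnw.rename(columns={"snp": "id"}),
                ss_bmd.rename(columns={"snp": "id"}),
                ld,
                n_blocks=sz["n_jackknife_blocks"],
            )
            true_rg = float(
                np.dot(arch.fnw_effects, arch.bmd_effects)
                / np.sqrt(np.sum(arch.fnw_effects**2) * np.sum(arch.bmd_effects**2))
            )
            report["stages"][stage] = {
                "h2_fnw": rg_res.h2_1,
                "h2_bmd": rg_res.h2_2,
                "rg": rg_res.rg,
                "se_rg": rg_res.se_rg,
                "error": rg_res.error,
            }
            report["truth_vs_estimate"].append(
                {"quantity": "rg_fnw_bmd", "truth": true_rg, "estimate": rg_res.rg}
            )

        if config.stages.get("mr", True) and ss_fnw is not None:
            stage = "mr"
            analysis = cohort.subset(~disc_mask.to_numpy()) if disc_mask.sum() >= 200 else cohort
            instr_fnw = mr.select_instruments(
                ss_fnw, panel, p_max=th["p_gws"], maf_min=th["maf"], r2_max=th["prune_r2"]
            )
            instr_bmd = mr.select_instruments(
                ss_bmd, panel, p_max=th["p_gws"], maf_min=th["maf"], r2_max=th["prune_r2"]
            )
            report["counts"]["instruments_fnw_selected"] = len(instr_fnw)
            report["counts"]["instruments_bmd_selected"] = len(instr_bmd)
            kept_fnw, kept_bmd, xres = mr.resolve_cross_exposure_ld(
                instr_fnw, instr_bmd, panel, ss_fnw, ss_bmd, r2_flag=th["prune_r2"]
            )
            report["counts"]["instruments_after_cross_ld"] = {
                "fnw": len(kept_fnw), "bmd": len(kept_bmd), "dropped": len(xres),
            }
            union = list(dict.fromkeys(kept_fnw + kept_bmd))
            mr_stage: dict = {}
            if len(union) >= 3:
                ss_out = gwas.run_binary_gwas(
                    analysis, "hip_any", include_prevalent=True,
                    variants_meta=panel.variants, variant_subset=union,
                )
                instr = mr.harmonize(
                    ss_fnw[ss_fnw["snp"].isin(union)],
                    ss_out.dropna(subset=["se"]),
                    second_exposure=ss_bmd[ss_bmd["snp"].isin(union)],
                    exposure_name="FNW",
                    second_exposure_name="FN-BMD",
                    outcome_name="hip_any",
                )
                report["counts"]["harmonization"] = instr.report
                if instr.n_instruments >= 3:
                    res_fnw, res_bmd = mr.mvmr(instr)
                    mr_stage["mvmr_fnw"] = res_fnw.as_dict()
                    mr_stage["mvmr_bmd"] = res_bmd.as_dict()
                    mr_stage["f_statistic_fnw"] = mr.instrument_strength(instr, 1)
                    report["truth_vs_estimate"] += [
                        {
                            "quantity": "mvmr_log_or_fnw_hip",
                            "truth": arch.causal_log_or["fnw"]["hip_any"],
                            "estimate": res_fnw.estimate,
                        },
                        {
                            "quantity": "mvmr_log_or_bmd_hip",
                            "truth": arch.causal_log_or["bmd"]["hip_any"],
                            "estimate": res_bmd.estimate,
                        },
                    ]
                    uni = instr.subset(
                        instr.table["snp"].isin(kept_fnw).to_numpy()
                    )
                    if uni.n_instruments >= 2:
                        mr_stage["ivw_fnw"] = mr.mr_ivw(uni).as_dict()
            report["stages"][stage] = mr_stage

        if config.stages.get("grs", True) and selected is not None and len(selected) >= 2:
            stage = "grs"
            analysis = cohort
            grs_fnw_def = grs.GRSDefinition(
                variant_ids=selected["snp"].tolist(),
                weights=selected["joint_beta"].to_numpy(),
                effect_alleles=selected["EA"].tolist(),
            )
            bmd_sel = gwas.cojo_select(
                ss_bmd, panel, p_threshold=th["p_gws"],
                collinearity_r2=th["collinearity_r2"],
            )
            grs_stage: dict = {}
            score_fnw = grs.compute_grs(analysis, grs_fnw_def)
            fit = grs.cox_fit(
                analysis, "hip_any", ["sex", "age", "grs_fnw"],
                covariate_values={"grs_fnw": score_fnw},
            )
            grs_stage["hr_per_sd_fnw_grs"] = fit.hr_of("grs_fnw")
            grs_stage["hr_ci95"] = fit.ci95("grs_fnw")
            grs_stage["n_events"] = fit.n_events
            if len(bmd_sel) >= 2:
                grs_bmd_def = grs.GRSDefinition(
                    variant_ids=bmd_sel["snp"].tolist(),
                    weights=bmd_sel["joint_beta"].to_numpy(),
                    effect_alleles=bmd_sel["EA"].tolist(),
                )
                score_bmd = grs.compute_grs(analysis, grs_bmd_def)
                groups_stage = {}
                for cut in th["cutoffs"]:
                    ga = grs.binarize_groups(score_fnw, score_bmd, cut)
                    try:
                        gfit = grs.group_hazard_ratios(analysis, ga, "hip_any")
                        groups_stage[str(cut)] = {
                            f"hr_group{k}": gfit.hr_of(f"group{k}") for k in (2, 3, 4)
                        }
                    except ValueError as exc:
                        groups_stage[str(cut)] = {"skipped": str(exc)}
                grs_stage["groups"] = groups_stage
            report["stages"][stage] = grs_stage
    except Exception as exc:  # persist partial outputs, then re-raise with stage
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (out_dir / "report.json").write_text(
            json.dumps(_round(report), indent=1, sort_keys=True)
        )
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    payload = json.dumps(_round(report), indent=1, sort_keys=True)
    (out_dir / "report.json").write_text(payload)
    report["report_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    log.info("pipeline complete; report at %s", out_dir / "report.json")
    return report
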