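"""Synthetic inputs with known ground truth for the FNW analysis chain.

This module generates every input the pipeline consumes:

* a genotype reference panel with block-structured linkage disequilibrium
  (latent-Gaussian-threshold haplotypes, AR(1) correlation within blocks);
* a cohort with two quantitative bone traits — femoral neck width (FNW) and
  femoral neck BMD (FN-BMD) — whose genetic architectures partially overlap
  and are mostly antagonistic, plus site-specific fracture survival times
  under a proportional-hazards model in which FNW raises hip/femoral-neck
  risk and FN-BMD lowers risk at every site;
* 85-point proximal-femur outline annotations with a controllable neck
  width, the input of :mod:`fnwpipe.geometry`;
* GWAS z-scores drawn directly from the summary-statistic sampling model,
  for heritability / genetic-correlation recovery experiments at variant
  counts where materialising genotypes would be wasteful.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    INFERIOR_NECK_IDX,
    N_LANDMARKS,
    SUPERIOR_NECK_IDX,
    ShapeAnnotation,
)

__all__ = [
    "CausalArchitecture",
    "ReferencePanel",
    "Cohort",
    "FRACTURE_SITES",
    "default_architecture",
    "simulate_reference_panel",
    "simulate_cohort",
    "simulate_shape_annotation",
    "simulate_sumstats_polygenic",
]

#: fracture sites; femoral-neck and trochanteric events imply an any-hip event
FRACTURE_SITES = ("hip_any", "fn", "trochanteric", "forearm")

# per-sex FNW distribution (mm): males 34.6 (2.4), females 29.0 (2.0)
FNW_MM_MALE = (34.6, 2.4)
FNW_MM_FEMALE = (29.0, 2.0)


@dataclass
class CausalArchitecture:
    """True genetic architecture of the two simulated bone traits.

    ``fnw_effects`` and ``bmd_effects`` are per-variant effects on the
    standardized trait (SD units per SD of genotype); a zero entry means the
    variant does not affect that trait. ``shared_inverse_ids`` are variants
    affecting both traits with opposite signs (the typical pattern);
    ``shared_positive_ids`` affect both with the same sign (the LRP5-like
    exception). ``causal_log_or`` holds per-site log hazard ratios per SD of
    each trait.
    """

    variant_ids: list
    fnw_effects: np.ndarray
    bmd_effects: np.ndarray
    shared_inverse_ids: list
    shared_positive_ids: list
    target_fnw_variance: float
    target_bmd_variance: float
    causal_log_or: dict  # {"fnw": {site: log HR}, "bmd": {site: log HR}}

    def __post_init__(self):
        self.fnw_effects = np.asarray(self.fnw_effects, dtype=float)
        self.bmd_effects = np.asarray(self.bmd_effects, dtype=float)
        k = len(self.variant_ids)
        if self.fnw_effects.shape != (k,) or self.bmd_effects.shape != (k,):
            raise ValueError("effect vectors need one entry per causal variant")
        if not 0 < self.target_fnw_variance < 1:
            raise ValueError("target_fnw_variance must be in (0, 1)")
        for trait in ("fnw", "bmd"):
            missing = set(FRACTURE_SITES) - set(self.causal_log_or[trait])
            if missing:
                raise ValueError(f"causal_log_or[{trait!r}] missing sites {missing}")

    def to_dict(self) -> dict:
        return {
            "variant_ids": list(self.variant_ids),
            "fnw_effects": self.fnw_effects.tolist(),
            "bmd_effects": self.bmd_effects.tolist(),
            "shared_inverse_ids": list(self.shared_inverse_ids),
            "shared_positive_ids": list(self.shared_positive_ids),
            "target_fnw_variance": self.target_fnw_variance,
            "target_bmd_variance": self.target_bmd_variance,
            "causal_log_or": self.causal_log_or,
        }


@dataclass
class ReferencePanel:
    """Dosage matrix plus variant metadata used as the LD reference."""

    dosages: np.ndarray  # (n_individuals, n_variants), values in [0, 2]
    variants: pd.DataFrame  # columns: id, chr, pos, EA, OA, EAF, INFO
    block_structure: list = field(default_factory=list)  # (start, stop) col slices
    within_block_rho: float = 0.0

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column_index(self, variant_ids) -> np.ndarray:
        lookup = pd.Index(self.variants["id"])
        idx = lookup.get_indexer(list(variant_ids))
        if (idx < 0).any():
            missing = [v for v, i in zip(variant_ids, idx) if i < 0]
            raise KeyError(f"variants absent from panel: {missing}")
        return idx

    def standardized_dosages(self, variant_ids=None) -> np.ndarray:
        cols = (
            self.dosages
            if variant_ids is None
            else self.dosages[:, self.column_index(variant_ids)]
        )
        mu = cols.mean(axis=0)
        sd = cols.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (cols - mu) / sd

    def correlation(self, variant_ids=None) -> np.ndarray:
        z = self.standardized_dosages(variant_ids)
        return (z.T @ z) / z.shape[0]


@dataclass
class Cohort:
    """Individual-level synthetic cohort.

    ``table`` holds one row per individual: sex (1 = male), age (yr),
    genotyping chip, 20 ancestry PCs (pc1..pc20), height (cm), weight (kg),
    bmi, fnw_mm, fnw_sd (latent standardized FNW), bmd_sd, per-site event
    indicators ``event_<site>`` and times ``time_<site>`` (years from
    baseline, censored at the follow-up horizon), ``prevalent_flag`` (hip
    fracture before baseline) and ``discovery_flag`` (member of the FNW
    discovery GWAS subsample).
    """

    table: pd.DataFrame
    dosages: np.ndarray
    variant_ids: list
    followup_yr: float
    architecture: CausalArchitecture | None = None
    #: {variant id: (EA, OA)} dosage coding, for effect-allele alignment
    variant_alleles: dict | None = None

    @property
    def n(self) -> int:
        return len(self.table)

    def dosage_of(self, variant_ids) -> np.ndarray:
        lookup = pd.Index(self.variant_ids)
        idx = lookup.get_indexer(list(variant_ids))
        if (idx < 0).any():
            missing = [v for v, i in zip(variant_ids, idx) if i < 0]
            raise KeyError(f"variants absent from cohort: {missing}")
        return self.dosages[:, idx]

    def subset(self, mask) -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        return Cohort(
            table=self.table[mask].reset_index(drop=True),
            dosages=self.dosages[mask],
            variant_ids=list(self.variant_ids),
            followup_yr=self.followup_yr,
            architecture=self.architecture,
            variant_alleles=self.variant_alleles,
        )


def default_architecture(
    panel: ReferencePanel,
    n_fnw: int = 71,
    n_bmd: int = 49,
    n_shared_inverse: int = 14,
    n_shared_positive: int = 1,
    target_fnw_variance: float = 0.076,
    target_bmd_variance: float = 0.15,
    seed: int = 0,
) -> CausalArchitecture:
    """Causal architecture mirroring the study's qualitative structure.

    71 FNW signals and 49 FN-BMD signals; a minority of variants affect both
    traits, mostly with opposite signs plus one LRP5-like same-sign variant.
    Causal variants are spread across LD blocks (one per block where
    possible) so that marginal and joint effects coincide approximately.
    Per-site hazard effects: FNW raises hip/FN risk only; FN-BMD is
    protective at all sites.
    """
    rng = np.random.default_rng(seed)
    n_shared = n_shared_inverse + n_shared_positive
    n_total = n_fnw + n_bmd - n_shared
    if n_total > panel.n_variants:
        raise ValueError("panel too small for requested architecture")
    # spread causal variants across blocks, at a random position within each
    # block (systematic edge placement would correlate causality with local
    # LD and bias LD-score analyses)
    block_reps = [int(rng.integers(s, t)) for s, t in panel.block_structure]
    rest = [j for j in range(panel.n_variants) if j not in set(block_reps)]
    spread = np.array(block_reps + rest)
    cols = np.sort(spread[:n_total])
    ids = panel.variants["id"].to_numpy()[cols]

    fnw_idx = np.arange(n_fnw)
    bmd_idx = np.arange(n_fnw - n_shared, n_total)  # overlap = last n_shared FNW ids
    shared = np.arange(n_fnw - n_shared, n_fnw)

    fnw_eff = np.zeros(n_total)
    bmd_eff = np.zeros(n_total)
    fnw_eff[fnw_idx] = rng.normal(0.0, 1.0, n_fnw) + np.sign(rng.normal(size=n_fnw)) * 0.5
    bmd_eff[bmd_idx] = rng.normal(0.0, 1.0, n_bmd) + np.sign(rng.normal(size=n_bmd)) * 0.5
    # antagonistic overlap: flip BMD sign against FNW for the inverse-shared set
    inv = shared[:n_shared_inverse]
    pos = shared[n_shared_inverse:]
    bmd_eff[inv] = -np.sign(fnw_eff[inv]) * np.abs(bmd_eff[inv])
    bmd_eff[pos] = np.sign(fnw_eff[pos]) * np.abs(bmd_eff[pos])

    fnw_eff *= np.sqrt(target_fnw_variance / np.sum(fnw_eff**2))
    bmd_eff *= np.sqrt(target_bmd_variance / np.sum(bmd_eff**2))

    log_or = {
        "fnw": {
            "hip_any": np.log(1.5),
            "fn": np.log(1.5),
            "trochanteric": 0.0,
            "forearm": 0.0,
        },
        "bmd": {
            "hip_any": np.log(0.45),
            "fn": np.log(0.45),
            "trochanteric": np.log(0.45),
            "forearm": np.log(0.6),
        },
    }
    return CausalArchitecture(
        variant_ids=list(ids),
        fnw_effects=fnw_eff,
        bmd_effects=bmd_eff,
        shared_inverse_ids=list(ids[inv]),
        shared_positive_ids=list(ids[pos]),
        target_fnw_variance=target_fnw_variance,
        target_bmd_variance=target_bmd_variance,
        causal_log_or=log_or,
    )


def simulate_reference_panel(
    n_individuals: int,
    n_variants: int,
    block_size: int = 10,
    within_block_rho: float = 0.0,
    eaf_range: tuple = (0.05, 0.5),
    seed: int = 0,
) -> ReferencePanel:
    """Block-LD genotype panel via latent-Gaussian-threshold haplotypes.

    Each haplotype is a latent standard-normal vector with AR(1) correlation
    ``rho**|i-j|`` within a block and independence across blocks; an allele
    is carried when the latent value falls below the allele-frequency
    quantile. Dosage = sum of two independent haplotypes, so dosages lie in
    {0, 1, 2} and column means approximate 2*EAF.
    """
    if n_individuals < 50:
        raise ValueError("n_individuals must be >= 50")
    if not 0 <= within_block_rho < 1:
        raise ValueError("within_block_rho must be in [0, 1)")
    lo, hi = float(eaf_range[0]), float(eaf_range[1])
    if not (0 < lo <= hi < 1) or (lo == hi and lo in (0.0, 1.0)):
        raise ValueError("eaf_range must be a sub-interval of (0, 1)")

    rng = np.random.default_rng(seed)
    eaf = rng.uniform(lo, hi, n_variants)
    thresh = stats.norm.ppf(eaf)

    def _haplotypes() -> np.ndarray:
        z = np.empty((n_individuals, n_variants))
        rho = within_block_rho
        innov_sd = np.sqrt(1.0 - rho**2)
        for start in range(0, n_variants, block_size):
            stop = min(start + block_size, n_variants)
            z[:, start] = rng.standard_normal(n_individuals)
            for j in range(start + 1, stop):
                z[:, j] = rho * z[:, j - 1] + innov_sd * rng.standard_normal(n_individuals)
        return (z < thresh).astype(np.int8)

    dosages = (_haplotypes() + _haplotypes()).astype(float)

    blocks = [
        (s, min(s + block_size, n_variants)) for s in range(0, n_variants, block_size)
    ]
    pos = np.sort(rng.choice(np.arange(1, 50_000_000), size=n_variants, replace=False))
    bases = np.array(["A", "C", "G", "T"])
    ea = rng.choice(bases, n_variants)
    oa = np.array([rng.choice(bases[bases != a]) for a in ea])
    variants = pd.DataFrame(
        {
            "id": [f"rs{i + 1}" for i in range(n_variants)],
            "chr": 1,
            "pos": pos,
            "EA": ea,
            "OA": oa,
            "EAF": eaf,
            "INFO": 1.0,
        }
    )
    return ReferencePanel(
        dosages=dosages,
        variants=variants,
        block_structure=blocks,
        within_block_rho=within_block_rho,
    )


def latent_dosage_r2(rho_latent: float, eaf_a: float, eaf_b: float) -> float:
    """Dosage-scale r² implied by the latent-Gaussian haplotype model.

    The allele indicators of two variants are thresholded bivariate normals;
    their correlation follows from the bivariate normal orthant probability,
    and dosage correlation equals haplotype-allele correlation because the
    two haplotypes are independent copies.
    """
    ta, tb = stats.norm.ppf(eaf_a), stats.norm.ppf(eaf_b)
    joint = stats.multivariate_normal.cdf(
        [ta, tb], mean=[0, 0], cov=[[1, rho_latent], [rho_latent, 1]]
    )
    cov = joint - eaf_a * eaf_b
    r = cov / np.sqrt(eaf_a * (1 - eaf_a) * eaf_b * (1 - eaf_b))
    return float(r**2)


def simulate_cohort(
    panel: ReferencePanel,
    arch: CausalArchitecture,
    n: int,
    followup_yr: float = 15.5,
    base_hazard: dict | None = None,
    prevalent_window_yr: float = 5.0,
    discovery_fraction: float = 0.1,
    body_size_loading: float = 0.25,
    age_loading: float = 0.05,
    seed: int = 0,
) -> Cohort:
    """Simulate a cohort with genetics, covariates, traits and fractures.

    Standardized FNW is the sum of the causal genetic value (variance scaled
    to ``arch.target_fnw_variance``), covariate contributions from a shared
    body-size latent factor and age, and Gaussian noise topping variance up
    to 1. FNW in mm applies the per-sex mm mean/SD (34.6/2.4 males, 29.0/2.0
    females). FN-BMD is built the same way from ``bmd_effects``.

    Fracture times per site are exponential proportional-hazards draws with
    log hazard ``log_or_fnw*FNW_sd + log_or_bmd*BMD_sd`` around a per-site
    baseline rate, censored administratively at ``followup_yr``; an any-hip
    event is the earlier of the femoral-neck and trochanteric events. A hip
    event drawn in the ``prevalent_window_yr`` years before baseline sets
    ``prevalent_flag``.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    missing = set(arch.variant_ids) - set(panel.variants["id"])
    if missing:
        raise ValueError(f"causal variants absent from panel: {sorted(missing)}")
    if base_hazard is None:
        # baseline yearly rates: hip subtypes rare, forearm more common
        base_hazard = {"fn": 6.5e-4, "trochanteric": 6.5e-4, "forearm": 2.0e-3}

    rng = np.random.default_rng(seed)
    cols = panel.column_index(arch.variant_ids)

    # draw the cohort's genotypes from the same generative process (and the
    # same allele frequencies) as the panel, so panel LD matches cohort LD
    thresh = stats.norm.ppf(panel.variants["EAF"].to_numpy())
    rho = panel.within_block_rho
    innov_sd = np.sqrt(1 - rho**2)

    def _haps() -> np.ndarray:
        z = np.empty((n, panel.n_variants))
        for start, stop in panel.block_structure:
            z[:, start] = rng.standard_normal(n)
            for j in range(start + 1, stop):
                z[:, j] = rho * z[:, j - 1] + innov_sd * rng.standard_normal(n)
        return (z < thresh).astype(np.int8)

    dosages = (_haps() + _haps()).astype(float)

    sd = dosages.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z_all = (dosages - dosages.mean(axis=0)) / sd
    z_causal = z_all[:, cols]

    g_fnw = z_causal @ arch.fnw_effects
    g_bmd = z_causal @ arch.bmd_effects

    def _trait(g: np.ndarray, target_var: float, u: np.ndarray, age_z: np.ndarray):
        vg = g.var()
        if vg > 0:
            g = g * np.sqrt(target_var / vg)  # realized genetic variance = target
        cov_part = body_size_loading * u + age_loading * age_z
        var_e = 1.0 - (target_var if vg > 0 else 0.0) - cov_part.var()
        var_e = max(var_e, 0.02)
        return g + cov_part + rng.normal(0.0, np.sqrt(var_e), n)

    sex = (rng.random(n) < 0.48).astype(int)  # 1 = male
    age = np.where(sex == 1, rng.normal(64.5, 7.6, n), rng.normal(63.1, 7.4, n))
    age = np.clip(age, 40.0, 85.0)
    age_z = (age - age.mean()) / age.std()
    chip = (rng.random(n) < 0.5).astype(int)
    pcs = rng.standard_normal((n, 20))
    u_body = rng.standard_normal(n)  # shared body-size factor

    fnw_sd_lat = _trait(g_fnw, arch.target_fnw_variance, u_body, age_z)
    bmd_sd_lat = _trait(g_bmd, arch.target_bmd_variance, -0.1 * u_body, age_z)

    fnw_mm = np.where(
        sex == 1,
        FNW_MM_MALE[0] + FNW_MM_MALE[1] * fnw_sd_lat,
        FNW_MM_FEMALE[0] + FNW_MM_FEMALE[1] * fnw_sd_lat,
    )
    height = np.where(sex == 1, 177.3 + 6.6 * (0.7 * u_body + rng.normal(0, 0.71, n)),
                      163.7 + 6.3 * (0.7 * u_body + rng.normal(0, 0.71, n)))
    weight = np.where(sex == 1, 83.3 + 13.4 * (0.6 * u_body + rng.normal(0, 0.8, n)),
                      68.2 + 12.8 * (0.6 * u_body + rng.normal(0, 0.8, n)))
    bmi = weight / (height / 100.0) ** 2

    table = {
        "id": [f"I{i:07d}" for i in range(n)],
        "sex": sex,
        "age": age,
        "chip": chip,
        "height": height,
        "weight": weight,
        "bmi": bmi,
        "fnw_mm": fnw_mm,
        "fnw_sd": fnw_sd_lat,
        "bmd_sd": bmd_sd_lat,
    }
    for k in range(20):
        table[f"pc{k + 1}"] = pcs[:, k]

    # site-specific exponential survival; fn/trochanteric feed hip_any
    times, events = {}, {}
    for site in ("fn", "trochanteric", "forearm"):
        lam = base_hazard[site] * np.exp(
            arch.causal_log_or["fnw"][site] * fnw_sd_lat
            + arch.causal_log_or["bmd"][site] * bmd_sd_lat
        )
        t = rng.exponential(1.0 / lam)
        events[site] = (t <= followup_yr).astype(int)
        times[site] = np.minimum(t, followup_yr)
    t_hip = np.minimum(times["fn"], times["trochanteric"])
    e_hip = np.maximum(events["fn"], events["trochanteric"])
    times["hip_any"], events["hip_any"] = t_hip, e_hip

    # prevalent hip fracture: an independent draw over the pre-baseline window
    lam_prev = base_hazard["fn"] * np.exp(
        arch.causal_log_or["fnw"]["fn"] * fnw_sd_lat
        + arch.causal_log_or["bmd"]["fn"] * bmd_sd_lat
    ) + base_hazard["trochanteric"] * np.exp(
        arch.causal_log_or["fnw"]["trochanteric"] * fnw_sd_lat
        + arch.causal_log_or["bmd"]["trochanteric"] * bmd_sd_lat
    )
    prevalent = (rng.random(n) < 1.0 - np.exp(-lam_prev * prevalent_window_yr)).astype(int)

    for site in FRACTURE_SITES:
        table[f"event_{site}"] = events[site]
        table[f"time_{site}"] = times[site]
    table["prevalent_flag"] = prevalent
    table["discovery_flag"] = (rng.random(n) < discovery_fraction).astype(int)

    return Cohort(
        table=pd.DataFrame(table),
        dosages=dosages,
        variant_ids=list(panel.variants["id"]),
        followup_yr=followup_yr,
        architecture=arch,
        variant_alleles={
            r.id: (r.EA, r.OA) for r in panel.variants.itertuples(index=False)
        },
    )


def simulate_shape_annotation(
    target_fnw_mm: float,
    pixel_spacing: float | tuple = 0.5,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> ShapeAnnotation:
    """An 85-point hip outline whose neck contours realize a known width.

    The inferior (points 6-12) and superior (points 32-38) neck contours are
    parabolic arcs bulging toward each other with vertically aligned apexes
    separated by exactly ``target_fnw_mm`` before jitter; the curvature makes
    the closest pair unique, so jitter perturbs the recovered width
    approximately symmetrically. The remaining 71 points trace a schematic
    femoral head / shaft outline whose geometry is irrelevant to the width.
    Gaussian jitter of SD ``jitter_sd`` (mm) is added to every coordinate of
    every landmark; coordinates are then converted to pixels.
    """
    if target_fnw_mm <= 0:
        raise ValueError("target_fnw_mm must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    if np.isscalar(pixel_spacing):
        sx = sy = float(pixel_spacing)
    else:
        sx, sy = (float(pixel_spacing[0]), float(pixel_spacing[1]))
    if sx <= 0 or sy <= 0:
        raise ValueError("pixel spacing must be positive")

    rng = np.random.default_rng(seed)
    points_mm = np.zeros((N_LANDMARKS, 2))

    xc, yc = 55.0, 50.0  # neck centre, mm; image y grows downward
    half = target_fnw_mm / 2.0
    curvature = 0.05  # mm^-1: apex neighbours sit ~0.45 mm farther out
    xs = xc + np.arange(-9.0, 9.1, 3.0)  # 7 points, apex at index 3

    inferior = np.column_stack([xs, yc + half + curvature * (xs - xc) ** 2])
    superior = np.column_stack([xs, yc - half - curvature * (xs - xc) ** 2])
    points_mm[np.array(INFERIOR_NECK_IDX) - 1] = inferior
    points_mm[np.array(SUPERIOR_NECK_IDX) - 1] = superior

    # filler outline: femoral head circle left of the neck, shaft to the right
    other = sorted(
        set(range(1, N_LANDMARKS + 1)) - set(INFERIOR_NECK_IDX) - set(SUPERIOR_NECK_IDX)
    )
    ang = np.linspace(0.0, 2.0 * np.pi, len(other), endpoint=False)
    points_mm[np.array(other) - 1, 0] = xc - 30.0 + 18.0 * np.cos(ang)
    points_mm[np.array(other) - 1, 1] = yc + 18.0 * np.sin(ang)

    if jitter_sd > 0:
        points_mm = points_mm + rng.normal(0.0, jitter_sd, points_mm.shape)

    points_px = points_mm / np.array([sx, sy])
    return ShapeAnnotation(points=points_px, pixel_spacing_x=sx, pixel_spacing_y=sy)


def simulate_sumstats_polygenic(
    panel_or_blocks,
    h2: float | tuple = 0.5,
    rg: float | None = None,
    n: int | tuple = 20_000,
    m: int | None = None,
    seed: int = 0,
):
    """GWAS z-scores drawn from the summary-statistic sampling model.

    Under an infinitesimal model with per-variant standardized effects
    b ~ N(0, h²/M) and LD correlation R, the marginal z-scores satisfy
    z = sqrt(n) * R b + e with e ~ N(0, R). For two traits, effects are
    drawn jointly with genetic correlation ``rg`` and independent sampling
    noise (no sample overlap). Block-diagonal R keeps this cheap at large M.

    ``panel_or_blocks`` is either a :class:`ReferencePanel` (its empirical
    block correlations are used) or a list of per-block correlation matrices
    tiled to cover ``m`` variants.

    Returns a DataFrame (one per trait if two) with columns id/chr/pos/EA/OA/
    EAF/z/n and the true per-variant standardized effects.
    """
    rng = np.random.default_rng(seed)
    two_traits = rg is not None
    h2s = (h2, h2) if np.isscalar(h2) else tuple(h2)
    ns = (n, n) if np.isscalar(n) else tuple(n)

    if isinstance(panel_or_blocks, ReferencePanel):
        panel = panel_or_blocks
        blocks = [
            panel.correlation(panel.variants["id"].iloc[s:t]) for s, t in panel.block_structure
        ]
        meta = panel.variants
        m = panel.n_variants
    else:
        blocks_proto = list(panel_or_blocks)
        if m is None:
            raise ValueError("m is required when passing raw block matrices")
        blocks, tot = [], 0
        while tot < m:
            b = blocks_proto[len(blocks) % len(blocks_proto)]
            k = min(b.shape[0], m - tot)
            blocks.append(np.asarray(b)[:k, :k])
            tot += k
        eaf = rng.uniform(0.05, 0.5, m)
        meta = pd.DataFrame(
            {
                "id": [f"rs{i + 1}" for i in range(m)],
                "chr": 1,
                "pos": np.arange(1, m + 1) * 1000,
                "EA": "A",
                "OA": "G",
                "EAF": eaf,
                "INFO": 1.0,
            }
        )

    if two_traits:
        cov = np.array(
            [
                [h2s[0] / m, rg * np.sqrt(h2s[0] * h2s[1]) / m],
                [rg * np.sqrt(h2s[0] * h2s[1]) / m, h2s[1] / m],
            ]
        )
        b = rng.multivariate_normal([0, 0], cov, size=m)  # (m, 2)
    else:
        b = rng.normal(0.0, np.sqrt(h2s[0] / m), size=(m, 1))

    zs = np.empty((m, b.shape[1]))
    start = 0
    for R in blocks:
        k = R.shape[0]
        L = np.linalg.cholesky(R + 1e-10 * np.eye(k))
        for t in range(b.shape[1]):
            noise = L @ rng.standard_normal(k)
            zs[start : start + k, t] = np.sqrt(ns[t]) * (R @ b[start : start + k, t]) + noise
        start += k
    assert start == m

    out = []
    for t in range(b.shape[1]):
        df = meta[["id", "chr", "pos", "EA", "OA", "EAF"]].copy()
        df["z"] = zs[:, t]
        df["n"] = ns[t]
        # allelic-scale beta/se for a standardized phenotype
        se = 1.0 / np.sqrt(
            2.0 * df["EAF"] * (1.0 - df["EAF"]) * df["n"]
        )
        df["beta"] = df["z"] * se
        df["se"] = se
        df["p"] = 2.0 * stats.norm.sf(np.abs(df["z"]))
        df["true_b"] = b[:, t]
        out.append(df)
    return out[0] if not two_traits else tuple(out)


# ---------------------------------------------------------------------------
# text-format writers (points CSV + sidecar JSON, cohort TSV, dosage TSV,
# truth JSON) — the formats the pipeline reads back
# ---------------------------------------------------------------------------

def write_annotation(annotation: ShapeAnnotation, points_path, sidecar_path) -> None:
    df = pd.DataFrame(
        {
            "index": np.arange(1, N_LANDMARKS + 1),
            "x": annotation.points[:, 0],
            "y": annotation.points[:, 1],
        }
    )
    df.to_csv(points_path, index=False)
    with open(sidecar_path, "w") as fh:
        json.dump(
            {
                "pixel_spacing_x_mm": annotation.pixel_spacing_x,
                "pixel_spacing_y_mm": annotation.pixel_spacing_y,
            },
            fh,
            indent=1,
        )


def read_annotation(points_path, sidecar_path) -> ShapeAnnotation:
    df = pd.read_csv(points_path).sort_values("index")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return ShapeAnnotation(
        points=df[["x", "y"]].to_numpy(),
        pixel_spacing_x=meta["pixel_spacing_x_mm"],
        pixel_spacing_y=meta["pixel_spacing_y_mm"],
    )


def write_cohort(cohort: Cohort, table_path, dosage_path=None) -> None:
    cohort.table.to_csv(table_path, sep="\t", index=False)
    if dosage_path is not None:
        pd.DataFrame(cohort.dosages, columns=cohort.variant_ids).to_csv(
            dosage_path, sep="\t", index=False
        )


def write_panel_dosages(panel: ReferencePanel, path) -> None:
    pd.DataFrame(panel.dosages, columns=panel.variants["id"]).to_csv(
        path, sep="\t", index=False
    )


def write_truth(arch: CausalArchitecture, path) -> None:
    with open(path, "w") as fh:
        json.dump(arch.to_dict(), fh, indent=1)
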