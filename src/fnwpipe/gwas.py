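"""Phenotype construction, association scans and conditional signal selection.

The analysis phenotype follows the sex-stratified residualization scheme:
within each sex, FNW is adjusted for age, genotyping chip and 20 ancestry
principal components by least squares; the residuals are standardized to
mean 0 / SD 1 per sex and concatenated. The quantitative scan is per-variant
simple least squares on that phenotype (a deliberate simplification of a
mixed model: the synthetic cohorts carry no relatedness or population
structure, so a random genetic effect would be superfluous). Binary scans
are per-variant logistic regressions adjusted for age and sex.

Conditionally independent signals are selected from summary statistics with
a stepwise conditional-and-joint procedure on the standardized-genotype
scale, using an LD correlation matrix from a reference panel: starting from
the smallest-p genome-wide-significant variant, each remaining variant's
effect conditional on the selected set is computed from
``b_joint = R^-1 b_marginal`` algebra, and the smallest conditional-p
variant is added while it stays below the significance threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synth import Cohort, ReferencePanel

__all__ = [
    "GWS_P",
    "prepare_phenotype",
    "run_quant_gwas",
    "run_binary_gwas",
    "cojo_select",
    "variance_explained",
    "classify_maf",
    "annotate_nearest_gene",
]

#: genome-wide significance threshold
GWS_P = 5e-8

_COVARIATES = ["age", "chip"] + [f"pc{i}" for i in range(1, 21)]


def prepare_phenotype(cohort: Cohort, trait: str = "fnw_mm") -> np.ndarray:
    """Sex-stratified covariate-adjusted standardized phenotype.

    Within each sex, the trait is regressed on age, genotyping chip and the
    first 20 ancestry principal components; residuals are standardized to
    mean 0, SD 1 per sex and returned in cohort order.
    """
    df = cohort.table
    missing_cols = [c for c in _COVARIATES + [trait, "sex"] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks columns: {missing_cols}")
    na_mask = df[_COVARIATES + [trait]].isna().any(axis=1)
    if na_mask.any():
        raise ValueError(
            f"missing covariate or trait values for ids: {list(df.loc[na_mask, 'id'])}"
        )

    out = np.empty(len(df))
    for sex_value in np.unique(df["sex"]):
        mask = (df["sex"] == sex_value).to_numpy()
        y = df.loc[mask, trait].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(mask.sum())] + [df.loc[mask, c].to_numpy(dtype=float) for c in _COVARIATES]
        )
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sd = resid.std()
        if sd < 1e-12:
            raise ValueError(f"zero residual variance within sex={sex_value}")
        out[mask] = (resid - resid.mean()) / sd
    return out


def run_quant_gwas(
    cohort: Cohort,
    phenotype: np.ndarray,
    maf_min: float = 0.01,
    info_min: float = 0.3,
    variants_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-variant least-squares scan of a quantitative phenotype.

    Returns one record per variant passing MAF >= ``maf_min`` and
    INFO > ``info_min``; beta/se/p come from simple regression of the
    phenotype on allele dosage (two-sided t test, n-2 df). Monomorphic
    variants are excluded, not errors.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != cohort.n:
        raise ValueError("phenotype not aligned to cohort")
    G = cohort.dosages
    n = len(y)

    eaf = G.mean(axis=0) / 2.0
    maf = np.minimum(eaf, 1.0 - eaf)
    if variants_meta is not None:
        meta = variants_meta.set_index("id").reindex(cohort.variant_ids)
        info = meta["INFO"].to_numpy(dtype=float) if "INFO" in meta else np.ones(G.shape[1])
    else:
        meta = None
        info = np.ones(G.shape[1])

    var_g = G.var(axis=0)
    keep = (maf >= maf_min) & (info > info_min) & (var_g > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} variants failing MAF/INFO/monomorphic filters",
            stacklevel=2,
        )

    Gk = G[:, keep]
    gc = Gk - Gk.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    syy = yc @ yc
    beta = sxy / sxx
    dof = n - 2
    s2 = np.maximum(syy - beta * sxy, 0.0) / dof
    se = np.sqrt(s2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    ids = np.asarray(cohort.variant_ids)[keep]
    out = pd.DataFrame(
        {
            "snp": ids,
            "chr": meta["chr"].to_numpy()[keep] if meta is not None else 1,
            "pos": meta["pos"].to_numpy()[keep]
            if meta is not None
            else np.flatnonzero(keep) + 1,
            "EA": meta["EA"].to_numpy()[keep] if meta is not None else "A",
            "OA": meta["OA"].to_numpy()[keep] if meta is not None else "G",
            "EAF": eaf[keep],
            "beta": beta,
            "se": se,
            "z": beta / se,
            "p": p,
            "n": n,
            "info": info[keep],
        }
    )
    return out


def run_binary_gwas(
    cohort: Cohort,
    event_site: str,
    include_prevalent: bool = True,
    maf_min: float = 0.01,
    variants_meta: pd.DataFrame | None = None,
    variant_subset: list | None = None,
) -> pd.DataFrame:
    """Per-variant logistic scan of fracture case status.

    Case status is the site's event indicator, optionally unioned with the
    prevalent (pre-baseline hip fracture) flag for hip sites; each variant is
    tested by logistic regression of case status on dosage adjusted for age
    and sex. Complete separation flags the record with an unusable SE (NaN).
    """
    df = cohort.table
    y = df[f"event_{event_site}"].to_numpy(dtype=float)
    if include_prevalent and event_site in ("hip_any", "fn", "trochanteric"):
        y = np.maximum(y, df["prevalent_flag"].to_numpy(dtype=float))
    if y.sum() < 10:
        raise ValueError(f"fewer than 10 cases for site {event_site!r}")

    G = cohort.dosages
    eaf = G.mean(axis=0) / 2.0
    maf = np.minimum(eaf, 1.0 - eaf)
    keep = (maf >= maf_min) & (G.var(axis=0) > 0)
    if variant_subset is not None:
        wanted = set(variant_subset)
        keep &= np.array([v in wanted for v in cohort.variant_ids])

    base = np.column_stack(
        [np.ones(cohort.n), df["age"].to_numpy(dtype=float), df["sex"].to_numpy(dtype=float)]
    )
    rows = []
    meta = (
        variants_meta.set_index("id").reindex(cohort.variant_ids)
        if variants_meta is not None
        else None
    )
    for j in np.flatnonzero(keep):
        X = np.column_stack([base, G[:, j]])
        beta = se = np.nan
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            beta = fit.params[-1]
            se = fit.bse[-1]
            if not np.isfinite(se) or se > 50:
                se = np.nan
        except Exception:
            pass
        p = 2.0 * stats.norm.sf(abs(beta / se)) if np.isfinite(se) else np.nan
        rows.append(
            {
                "snp": cohort.variant_ids[j],
                "chr": meta["chr"].iloc[j] if meta is not None else 1,
                "pos": meta["pos"].iloc[j] if meta is not None else j + 1,
                "EA": meta["EA"].iloc[j] if meta is not None else "A",
                "OA": meta["OA"].iloc[j] if meta is not None else "G",
                "EAF": eaf[j],
                "beta": beta,
                "se": se,
                "z": beta / se if np.isfinite(se) else np.nan,
                "p": p,
                "n": cohort.n,
                "n_cases": int(y.sum()),
                "info": 1.0,
            }
        )
    return pd.DataFrame(rows)


def _standardized_effects(sumstats: pd.DataFrame):
    """Marginal effects on the standardized-genotype scale (phenotype SD 1)."""
    eaf = sumstats["EAF"].to_numpy(dtype=float)
    scale = np.sqrt(2.0 * eaf * (1.0 - eaf))
    b = sumstats["beta"].to_numpy(dtype=float) * scale
    return b, scale


def cojo_select(
    sumstats: pd.DataFrame,
    panel: ReferencePanel,
    p_threshold: float = GWS_P,
    collinearity_r2: float = 0.9,
) -> pd.DataFrame:
    """Stepwise conditional-and-joint selection of independent signals.

    Effects are standardized (β·sqrt(2·EAF·(1−EAF)) on a unit-variance
    phenotype); selection starts from the smallest-p genome-wide-significant
    variant and repeatedly adds the variant with the smallest conditional p
    below ``p_threshold``, where the conditional effect given the selected
    set S is the joint coefficient of the candidate in the model S ∪ {t}
    computed from the panel's LD correlation matrix. Candidates whose r²
    with any selected variant exceeds ``collinearity_r2`` are ineligible.
    Reports joint betas/SEs (back-transformed to the allelic scale) and the
    conditional p at selection time. Row-order invariant: internal ordering
    is by (p, chr, pos).
    """
    ss = sumstats.copy()
    ss = ss.sort_values(["p", "chr", "pos"], kind="mergesort").reset_index(drop=True)
    gws = ss[ss["p"] <= p_threshold]
    if gws.empty:
        return _empty_selection()

    ids = ss["snp"].tolist()
    b_std, scale = _standardized_effects(ss)
    n = ss["n"].to_numpy(dtype=float)

    # standardized dosage matrix for all scanned variants present in panel
    Z = panel.standardized_dosages(ids)
    n_ref = Z.shape[0]

    gws_idx = np.flatnonzero(ss["p"].to_numpy() <= p_threshold)
    selected: list[int] = [int(gws_idx[0])]
    cond_p_at_selection = {selected[0]: float(ss["p"].iloc[selected[0]])}

    while True:
        S = np.array(selected)
        Zs = Z[:, S]
        R_S = (Zs.T @ Zs) / n_ref
        try:
            R_inv = np.linalg.inv(R_S + 1e-12 * np.eye(len(S)))
        except np.linalg.LinAlgError:
            warnings.warn("singular LD matrix; dropping most recent candidate", stacklevel=2)
            dropped = selected.pop()
            cond_p_at_selection.pop(dropped, None)
            continue

        remaining = np.setdiff1d(np.arange(len(ids)), S)
        if remaining.size == 0:
            break
        r_tS = (Z[:, remaining].T @ Zs) / n_ref  # (m_rem, |S|)
        max_r2 = (r_tS**2).max(axis=1)
        eligible = max_r2 <= collinearity_r2

        h = np.einsum("ij,jk,ik->i", r_tS, R_inv, r_tS)  # r' R^-1 r
        denom = np.maximum(1.0 - h, 1e-10)
        b_cond = (b_std[remaining] - r_tS @ (R_inv @ b_std[S])) / denom
        se_cond = np.sqrt(1.0 / (n[remaining] * denom))
        p_cond = 2.0 * stats.norm.sf(np.abs(b_cond / se_cond))
        p_cond = np.where(eligible, p_cond, np.inf)

        best = int(np.argmin(p_cond))
        if not np.isfinite(p_cond[best]) or p_cond[best] > p_threshold:
            break
        chosen = int(remaining[best])
        selected.append(chosen)
        cond_p_at_selection[chosen] = float(max(p_cond[best], np.finfo(float).tiny))

    S = np.array(sorted(selected, key=lambda i: (ss["chr"].iloc[i], ss["pos"].iloc[i])))
    Zs = Z[:, S]
    R_S = (Zs.T @ Zs) / n_ref
    R_inv = np.linalg.inv(R_S + 1e-12 * np.eye(len(S)))
    b_joint_std = R_inv @ b_std[S]
    sigma2_joint = max(1.0 - float(b_joint_std @ b_std[S]), 0.05)
    se_joint_std = np.sqrt(sigma2_joint * np.diag(R_inv) / n[S])

    sel = ss.iloc[S].reset_index(drop=True)
    sel["joint_beta"] = b_joint_std / scale[S]
    sel["joint_se"] = se_joint_std / scale[S]
    sel["conditional_p"] = [cond_p_at_selection[int(i)] for i in S]
    return sel


def _empty_selection() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "snp", "chr", "pos", "EA", "OA", "EAF", "beta", "se", "p", "n",
            "joint_beta", "joint_se", "conditional_p",
        ]
    )


def variance_explained(signals: pd.DataFrame) -> float:
    """Trait variance explained by a signal set on the standardized scale.

    Assuming a unit-variance phenotype and (near-)independent signals,
    returns sum over variants of ``2·EAF·(1−EAF)·β²``.
    """
    eaf = np.asarray(signals["EAF"], dtype=float)
    beta = np.asarray(signals["beta"], dtype=float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValueError("EAF outside (0, 1)")
    return float(np.sum(2.0 * eaf * (1.0 - eaf) * beta**2))


def classify_maf(signals: pd.DataFrame) -> dict:
    """Count common (MAF > 5%) and low-frequency (1% < MAF <= 5%) signals.

    Variants with MAF <= 1% should have been filtered upstream; they are
    counted under ``"filtered"`` with a warning.
    """
    eaf = np.asarray(signals["EAF"], dtype=float)
    maf = np.minimum(eaf, 1.0 - eaf)
    eps = 1e-9  # keep the 5% boundary inclusive under float rounding
    low = int(np.sum((maf > 0.01 + eps) & (maf <= 0.05 + eps)))
    common = int(np.sum(maf > 0.05 + eps))
    rare = int(np.sum(maf <= 0.01 + eps))
    counts = {"common": common, "low_frequency": low}
    if rare:
        warnings.warn(f"{rare} variants with MAF <= 1% present", stacklevel=2)
        counts["filtered"] = rare
    return counts


def annotate_nearest_gene(signals: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Annotate each signal with its closest gene and distance in bp.

    ``genes`` holds BED-convention intervals: columns chr, start (0-based),
    end (half-open), name. Signal positions are 1-based. Distance is 0 when
    the position falls inside the interval. Ties at equal distance prefer
    the upstream feature (interval ending before the position), then the
    smaller start coordinate, deterministically.
    """
    if genes is None or len(genes) == 0:
        raise ValueError("empty gene set")
    out = signals.copy()
    closest, distance = [], []
    for _, row in signals.iterrows():
        p0 = int(row["pos"]) - 1  # to 0-based
        sub = genes[genes["chr"] == row["chr"]]
        if sub.empty:
            closest.append(None)
            distance.append(np.nan)
            continue
        start = sub["start"].to_numpy(dtype=int)
        end = sub["end"].to_numpy(dtype=int)
        inside = (start <= p0) & (p0 < end)
        d = np.where(inside, 0, np.where(p0 < start, start - p0, p0 - end + 1))
        dmin = d.min()
        cand = np.flatnonzero(d == dmin)
        if len(cand) > 1:
            upstream = cand[end[cand] <= p0]
            pool = upstream if len(upstream) else cand
            cand = [pool[np.argmin(start[pool])]]
        k = int(cand[0])
        closest.append(sub["name"].iloc[k])
        distance.append(int(dmin))
    out["closest_gene"] = closest
    out["distance_to_gene"] = distance
    return out
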