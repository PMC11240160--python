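"""Two-sample univariable and multivariable Mendelian randomization.

Instruments are genome-wide-significant variants pruned to approximate
linkage equilibrium; exposure and outcome summary statistics are harmonized
to a common effect allele per variant, with ambiguous palindromic variants
removed. Estimators: inverse-variance-weighted (IVW) meta-analysis of Wald
ratios with fixed or multiplicative random effects chosen by Cochran's Q,
MR-Egger regression (intercept = directional pleiotropy test), the weighted
median, MR-LASSO (L1-penalized per-instrument intercepts flag outlier
instruments), and multivariable MR for the joint conditional effects of two
exposures. Estimates are on the outcome's log-odds scale per SD of
exposure; ORs are exp(estimate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth import ReferencePanel

__all__ = [
    "InstrumentSet",
    "MRResult",
    "select_instruments",
    "resolve_cross_exposure_ld",
    "harmonize",
    "steiger_filter",
    "instrument_strength",
    "wald_ratio",
    "mr_ivw",
    "mr_egger",
    "mr_weighted_median",
    "mr_lasso",
    "mvmr",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(ea: str, oa: str) -> bool:
    return (
        len(ea) == 1
        and len(oa) == 1
        and ea in _COMPLEMENT
        and _COMPLEMENT[ea] == oa
    )


@dataclass
class InstrumentSet:
    """Harmonized per-variant exposure and outcome effects.

    ``table`` columns: snp, gamma, se_gamma, Gamma, se_Gamma, EA, eaf and,
    for multivariable analyses, gamma2/se_gamma2 for the second exposure.
    """

    table: pd.DataFrame
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    second_exposure_name: str | None = None
    n_exp: int | None = None
    n_out: int | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        t = self.table
        if t["snp"].duplicated().any():
            raise ValueError("duplicate instrument ids")
        for c in ("se_gamma", "se_Gamma"):
            if c in t and (t[c] <= 0).any():
                raise ValueError(f"non-positive {c}")

    @property
    def n_instruments(self) -> int:
        return len(self.table)

    def subset(self, mask) -> "InstrumentSet":
        return InstrumentSet(
            table=self.table[mask].reset_index(drop=True),
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            second_exposure_name=self.second_exposure_name,
            n_exp=self.n_exp,
            n_out=self.n_out,
            report=dict(self.report),
        )


@dataclass
class MRResult:
    """A single causal-estimate record."""

    method: str
    estimate: float
    se: float
    n_snps: int
    effects_model: str = "fixed"
    cochran_q: float = np.nan
    q_p: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_p: float = np.nan
    outliers_removed: list = field(default_factory=list)
    exposure: str = "exposure"

    @property
    def ci95(self):
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)

    @property
    def or_(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def or_ci95(self):
        lo, hi = self.ci95
        return (float(np.exp(lo)), float(np.exp(hi)))

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.estimate / self.se)))

    def as_dict(self) -> dict:
        lo, hi = self.or_ci95
        return {
            "method": self.method,
            "exposure": self.exposure,
            "estimate": self.estimate,
            "se": self.se,
            "p": self.p,
            "or": self.or_,
            "or_ci_low": lo,
            "or_ci_high": hi,
            "q": self.cochran_q,
            "q_p": self.q_p,
            "effects_model": self.effects_model,
            "n_snps": self.n_snps,
            "outliers_removed": list(self.outliers_removed),
        }


# ---------------------------------------------------------------------------
# instrument selection and harmonization
# ---------------------------------------------------------------------------

def select_instruments(
    sumstats: pd.DataFrame,
    panel: ReferencePanel,
    p_max: float = 5e-8,
    maf_min: float = 0.01,
    r2_max: float = 0.01,
) -> list:
    """Greedy LD pruning of genome-wide-significant candidate instruments.

    Candidates (p <= ``p_max``, MAF > ``maf_min``) are ordered by ascending
    p; a candidate is accepted iff its panel r² with every already-accepted
    variant is below ``r2_max``. Variants absent from the panel are skipped
    with a warning.
    """
    ss = sumstats.copy()
    maf = np.minimum(ss["EAF"], 1 - ss["EAF"])
    ss = ss[(ss["p"] <= p_max) & (maf > maf_min)]
    ss = ss.sort_values(["p", "chr", "pos"], kind="mergesort")
    in_panel = ss["snp"].isin(panel.variants["id"])
    if (~in_panel).any():
        warnings.warn(
            f"{(~in_panel).sum()} candidate instruments absent from panel", stacklevel=2
        )
        ss = ss[in_panel]
    if ss.empty:
        return []
    Z = panel.standardized_dosages(ss["snp"].tolist())
    n_ref = Z.shape[0]
    accepted: list[int] = []
    for j in range(Z.shape[1]):
        if not accepted:
            accepted.append(j)
            continue
        r = (Z[:, accepted].T @ Z[:, j]) / n_ref
        if np.max(r**2) < r2_max:
            accepted.append(j)
    return ss["snp"].iloc[accepted].tolist()


def resolve_cross_exposure_ld(
    instr_exp1: list,
    instr_exp2: list,
    panel: ReferencePanel,
    sumstats_exp1: pd.DataFrame,
    sumstats_exp2: pd.DataFrame,
    r2_flag: float = 0.01,
    prefer: str = "exp2",
) -> tuple:
    """Resolve LD between instruments selected for two different exposures.

    For every cross-exposure pair with panel r² >= ``r2_flag``, exactly one
    variant of the pair is dropped. Under ``prefer="exp2"`` (the primary
    rule) the member with the stronger (smaller-p) second-exposure
    association is kept; ``prefer="exp1"`` is the sensitivity mode keeping
    the first-exposure-stronger member. Pairs are processed in descending
    r² order (ties by id) so multi-way clusters resolve deterministically.

    Returns (kept_exp1, kept_exp2, report).
    """
    if prefer not in ("exp1", "exp2"):
        raise ValueError("prefer must be 'exp1' or 'exp2'")
    ids = list(dict.fromkeys(list(instr_exp1) + list(instr_exp2)))
    if not ids:
        return list(instr_exp1), list(instr_exp2), []
    Z = panel.standardized_dosages(ids)
    R = (Z.T @ Z) / Z.shape[0]
    idx = {v: i for i, v in enumerate(ids)}

    p1 = sumstats_exp1.set_index("snp")["p"]
    p2 = sumstats_exp2.set_index("snp")["p"]

    pairs = []
    for a in instr_exp1:
        for b in instr_exp2:
            if a == b:
                continue
            r2 = R[idx[a], idx[b]] ** 2
            if r2 >= r2_flag:
                pairs.append((r2, a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    keep1, keep2 = set(instr_exp1), set(instr_exp2)
    report = []
    for r2, a, b in pairs:
        if a not in keep1 or b not in keep2:
            continue  # already resolved by an earlier, stronger pair
        pa2 = float(p2.get(a, np.inf))
        pb2 = float(p2.get(b, np.inf))
        pa1 = float(p1.get(a, np.inf))
        pb1 = float(p1.get(b, np.inf))
        if prefer == "exp2":
            drop_a = pb2 < pa2
        else:
            drop_a = pb1 < pa1
        if drop_a:
            keep1.discard(a)
            report.append({"r2": r2, "kept": b, "dropped": a, "dropped_from": "exp1"})
        else:
            keep2.discard(b)
            report.append({"r2": r2, "kept": a, "dropped": b, "dropped_from": "exp2"})
    kept1 = [v for v in instr_exp1 if v in keep1]
    kept2 = [v for v in instr_exp2 if v in keep2]
    return kept1, kept2, report


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    second_exposure: pd.DataFrame | None = None,
    palindrome_maf_max: float = 0.42,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    second_exposure_name: str | None = None,
) -> InstrumentSet:
    """Align exposure and outcome effects to a common effect allele.

    Per variant: matching alleles are kept as-is; swapped alleles flip the
    outcome beta and complement its EAF; strand-complement matches are
    resolved the same way after complementing. Palindromic single-base
    variants (A/T, C/G) are aligned by allele frequency when both tables'
    MAFs are below ``palindrome_maf_max``, otherwise removed as
    non-clear-strand. Irreconcilable allele pairs and variants missing from
    any table are dropped and counted in the report.
    """
    rep = {"missing": 0, "palindromic_removed": 0, "irreconcilable": 0, "kept": 0}
    out_ix = outcome.set_index("snp")
    exp2_ix = second_exposure.set_index("snp") if second_exposure is not None else None

    rows = []
    for _, e in exposure.iterrows():
        snp = e["snp"]
        if snp not in out_ix.index or (exp2_ix is not None and snp not in exp2_ix.index):
            rep["missing"] += 1
            continue

        def align(rec):
            """Return (beta_aligned, se, eaf_aligned) or None."""
            ea_e, oa_e = str(e["EA"]), str(e["OA"])
            ea_o, oa_o = str(rec["EA"]), str(rec["OA"])
            beta, se_o = float(rec["beta"]), float(rec["se"])
            eaf_o = float(rec["EAF"]) if "EAF" in rec and np.isfinite(rec["EAF"]) else np.nan

            if _is_palindromic(ea_e, oa_e):
                if {ea_o, oa_o} != {ea_e, oa_e}:
                    return "irreconcilable"
                eaf_e = float(e["EAF"])
                if not np.isfinite(eaf_o):
                    return "palindrome"
                if (
                    min(eaf_e, 1 - eaf_e) >= palindrome_maf_max
                    or min(eaf_o, 1 - eaf_o) >= palindrome_maf_max
                ):
                    return "palindrome"
                # frequency alignment: the outcome's effect allele is the one
                # whose frequency is on the same side of 0.5 as the exposure EAF
                if (eaf_e < 0.5) == (eaf_o < 0.5):
                    return beta, se_o, eaf_o
                return -beta, se_o, 1 - eaf_o

            if (ea_o, oa_o) == (ea_e, oa_e):
                return beta, se_o, eaf_o
            if (ea_o, oa_o) == (oa_e, ea_e):
                return -beta, se_o, 1 - eaf_o
            comp = {a: _COMPLEMENT.get(a, a) for a in (ea_o, oa_o)}
            if (comp[ea_o], comp[oa_o]) == (ea_e, oa_e):
                return beta, se_o, eaf_o
            if (comp[ea_o], comp[oa_o]) == (oa_e, ea_e):
                return -beta, se_o, 1 - eaf_o
            return "irreconcilable"

        res_out = align(out_ix.loc[snp])
        if res_out == "palindrome":
            rep["palindromic_removed"] += 1
            continue
        if res_out == "irreconcilable":
            rep["irreconcilable"] += 1
            continue
        row = {
            "snp": snp,
            "EA": e["EA"],
            "eaf": float(e["EAF"]),
            "gamma": float(e["beta"]),
            "se_gamma": float(e["se"]),
            "Gamma": res_out[0],
            "se_Gamma": res_out[1],
        }
        if exp2_ix is not None:
            res2 = align(exp2_ix.loc[snp])
            if res2 in ("palindrome", "irreconcilable"):
                rep["palindromic_removed" if res2 == "palindrome" else "irreconcilable"] += 1
                continue
            row["gamma2"] = res2[0]
            row["se_gamma2"] = res2[1]
        rows.append(row)
    rep["kept"] = len(rows)

    n_exp = int(exposure["n"].max()) if "n" in exposure else None
    n_out = int(outcome["n"].max()) if "n" in outcome else None
    return InstrumentSet(
        table=pd.DataFrame(rows),
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        second_exposure_name=second_exposure_name,
        n_exp=n_exp,
        n_out=n_out,
        report=rep,
    )


def steiger_filter(
    instr: InstrumentSet,
    n_exp: int | None = None,
    n_out: int | None = None,
    alpha: float = 0.05,
    outcome_case_fraction: float | None = None,
) -> tuple:
    """Remove instruments explaining more outcome than exposure variance.

    Per variant, exposure r² = γ²·2·EAF·(1−EAF) (standardized trait);
    outcome r² uses the observed-scale approximation for a logistic beta,
    Γ²·2·EAF·(1−EAF)·c·(1−c) with case fraction c, or the quantitative
    analogue when no case fraction is given. A variant is removed when its
    outcome correlation significantly exceeds its exposure correlation in a
    one-sided Fisher-z (Steiger) test at ``alpha``.

    Returns (filtered InstrumentSet, per-variant report DataFrame).
    """
    n_exp = n_exp or instr.n_exp
    n_out = n_out or instr.n_out
    if not n_exp or not n_out:
        raise ValueError("sample sizes n_exp and n_out are required")
    t = instr.table
    pq2 = 2.0 * t["eaf"] * (1.0 - t["eaf"])
    r2_exp = t["gamma"] ** 2 * pq2
    if outcome_case_fraction is not None:
        c = outcome_case_fraction
        r2_out = t["Gamma"] ** 2 * pq2 * c * (1 - c)
    else:
        r2_out = t["Gamma"] ** 2 * pq2
    r_exp = np.sqrt(np.clip(r2_exp, 0, 1 - 1e-12))
    r_out = np.sqrt(np.clip(r2_out, 0, 1 - 1e-12))
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    p_one_sided = stats.norm.cdf(z)  # small when r_out >> r_exp
    remove = p_one_sided < alpha
    report = pd.DataFrame(
        {
            "snp": t["snp"],
            "r2_exposure": r2_exp,
            "r2_outcome": r2_out,
            "steiger_z": z,
            "direction": np.where(r2_exp >= r2_out, "exposure->outcome", "reverse?"),
            "removed": remove,
        }
    )
    return instr.subset(~remove), report


def instrument_strength(instr: InstrumentSet, which_exposure: int = 1) -> float:
    """Mean-F instrument strength: mean over instruments of (γ/se_γ)²."""
    if instr.n_instruments == 0:
        raise ValueError("empty instrument set")
    g = instr.table["gamma" if which_exposure == 1 else "gamma2"]
    se = instr.table["se_gamma" if which_exposure == 1 else "se_gamma2"]
    return float(np.mean((g / se) ** 2))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(gamma: float, Gamma: float, se_Gamma: float) -> tuple:
    """Single-instrument causal estimate with first-order delta-method SE."""
    if gamma == 0:
        raise ValueError("zero exposure effect")
    return Gamma / gamma, se_Gamma / abs(gamma)


def _drop_null_gamma(instr: InstrumentSet) -> InstrumentSet:
    mask = instr.table["gamma"].to_numpy() != 0
    if (~mask).any():
        warnings.warn(f"excluding {(~mask).sum()} instruments with gamma = 0", stacklevel=3)
    return instr.subset(mask)


def mr_ivw(instr: InstrumentSet) -> MRResult:
    """Inverse-variance-weighted estimate with Q-driven effects model.

    Equivalent to a zero-intercept weighted regression of Γ on γ with
    weights 1/se(Γ)². Fixed-effects SE = 1/sqrt(Σ w_j); if Cochran's Q has
    p < 0.05 (χ², J−1 df), the SE is inflated multiplicatively by
    sqrt(Q/(J−1)), never below the fixed-effects SE.
    """
    instr = _drop_null_gamma(instr)
    t = instr.table
    J = len(t)
    if J < 2:
        raise ValueError("IVW needs at least 2 usable instruments")
    theta_j = (t["Gamma"] / t["gamma"]).to_numpy()
    w = (t["gamma"] ** 2 / t["se_Gamma"] ** 2).to_numpy()
    est = float(np.sum(w * theta_j) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (theta_j - est) ** 2))
    q_p = float(stats.chi2.sf(q, J - 1))
    if q_p < 0.05:
        se = se_fixed * max(1.0, np.sqrt(q / (J - 1)))
        model = "random"
    else:
        se, model = se_fixed, "fixed"
    return MRResult(
        method="ivw",
        estimate=est,
        se=se,
        n_snps=J,
        effects_model=model,
        cochran_q=q,
        q_p=q_p,
        exposure=instr.exposure_name,
    )


def mr_egger(instr: InstrumentSet) -> MRResult:
    """MR-Egger: weighted regression with intercept after orienting γ >= 0.

    The slope is the causal estimate; the intercept and its p-value index
    directional pleiotropy. Residual-heterogeneity SE inflation mirrors the
    IVW random-effects rule.
    """
    t = instr.table
    J = len(t)
    if J < 3:
        raise ValueError("Egger regression needs at least 3 instruments")
    flip = np.sign(t["gamma"].to_numpy())
    flip[flip == 0] = 1.0
    g = t["gamma"].to_numpy() * flip
    G = t["Gamma"].to_numpy() * flip
    w = 1.0 / t["se_Gamma"].to_numpy() ** 2
    X = np.column_stack([np.ones(J), g])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ G)
    resid = G - X @ coef
    q = float(np.sum(w * resid**2))
    q_p = float(stats.chi2.sf(q, J - 2))
    scale = max(1.0, np.sqrt(q / (J - 2))) if q_p < 0.05 else 1.0
    model = "random" if scale > 1.0 else "fixed"
    se = np.sqrt(np.diag(cov_unscaled)) * scale
    icpt_p = float(2.0 * stats.norm.sf(abs(coef[0] / se[0])))
    return MRResult(
        method="egger",
        estimate=float(coef[1]),
        se=float(se[1]),
        n_snps=J,
        effects_model=model,
        cochran_q=q,
        q_p=q_p,
        egger_intercept=float(coef[0]),
        egger_intercept_p=icpt_p,
        exposure=instr.exposure_name,
    )


def mr_weighted_median(instr: InstrumentSet, n_boot: int = 5000, seed: int = 0) -> MRResult:
    """Weighted median of Wald ratios; SE by parametric bootstrap.

    The estimate interpolates the ordered ratios at cumulative normalized
    weight 0.5 (s_j = (Σ_{k<=j} w_k − w_j/2)/Σw); the bootstrap resamples
    (γ_j, Γ_j) from their normal sampling errors.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    instr = _drop_null_gamma(instr)
    t = instr.table
    J = len(t)
    if J < 3:
        raise ValueError("weighted median needs at least 3 instruments")

    def wm(gam, Gam, w):
        theta = Gam / gam
        order = np.argsort(theta)
        theta = theta[order]
        w_o = w[order]
        s = (np.cumsum(w_o) - 0.5 * w_o) / np.sum(w_o)
        return float(np.interp(0.5, s, theta))

    gam = t["gamma"].to_numpy()
    Gam = t["Gamma"].to_numpy()
    w = gam**2 / t["se_Gamma"].to_numpy() ** 2
    est = wm(gam, Gam, w)

    rng = np.random.default_rng(seed)
    se_g = t["se_gamma"].to_numpy()
    se_G = t["se_Gamma"].to_numpy()
    boots = np.empty(n_boot)
    for b in range(n_boot):
        gb = gam + rng.standard_normal(J) * se_g
        Gb = Gam + rng.standard_normal(J) * se_G
        gb[gb == 0] = 1e-12
        wb = gb**2 / se_G**2
        boots[b] = wm(gb, Gb, wb)
    return MRResult(
        method="weighted_median",
        estimate=est,
        se=float(boots.std(ddof=1)),
        n_snps=J,
        exposure=instr.exposure_name,
    )


def mr_lasso(instr: InstrumentSet, n_lambda: int = 100) -> MRResult:
    """MR-LASSO: IVW after removing instruments with nonzero L1 intercepts.

    Fits Γ_j = θ·γ_j + α_j with an L1 penalty on the per-instrument
    intercepts α_j; λ is chosen by the heterogeneity stopping rule — the
    largest λ on a descending grid whose retained set (α_j = 0) passes
    Cochran's Q at p >= 0.05. The final estimate is plain IVW on the
    retained instruments.
    """
    instr = _drop_null_gamma(instr)
    t = instr.table
    J = len(t)
    if J < 4:
        raise ValueError("MR-LASSO needs at least 4 instruments")
    gam = t["gamma"].to_numpy()
    Gam = t["Gamma"].to_numpy()
    w = 1.0 / t["se_Gamma"].to_numpy() ** 2

    def fit_at(lam):
        theta = float(np.sum(w * gam * Gam) / np.sum(w * gam**2))
        alpha = np.zeros(J)
        for _ in range(500):
            r = Gam - theta * gam
            thr = lam / (2.0 * w)
            alpha_new = np.sign(r) * np.maximum(np.abs(r) - thr, 0.0)
            theta_new = float(
                np.sum(w * gam * (Gam - alpha_new)) / np.sum(w * gam**2)
            )
            if np.max(np.abs(alpha_new - alpha)) < 1e-12 and abs(theta_new - theta) < 1e-12:
                alpha, theta = alpha_new, theta_new
                break
            alpha, theta = alpha_new, theta_new
        return theta, alpha

    theta0 = float(np.sum(w * gam * Gam) / np.sum(w * gam**2))
    lam_max = float(np.max(2.0 * w * np.abs(Gam - theta0 * gam))) * 1.05 + 1e-12
    lambdas = lam_max * np.geomspace(1.0, 1e-4, n_lambda)

    chosen_mask = None
    for lam in lambdas:
        _, alpha = fit_at(lam)
        retained = alpha == 0.0
        if retained.sum() < 3:
            break
        sub = instr.subset(retained)
        res = mr_ivw(sub)
        if res.q_p >= 0.05:
            chosen_mask = retained
            break
    if chosen_mask is None:
        raise ValueError(
            "no admissible retained set with >= 3 instruments; MR-LASSO not advised"
        )
    outliers = t.loc[~chosen_mask, "snp"].tolist()
    final = mr_ivw(instr.subset(chosen_mask))
    return MRResult(
        method="lasso",
        estimate=final.estimate,
        se=final.se,
        n_snps=int(chosen_mask.sum()),
        effects_model=final.effects_model,
        cochran_q=final.cochran_q,
        q_p=final.q_p,
        outliers_removed=outliers,
        exposure=instr.exposure_name,
    )


def mvmr(instr: InstrumentSet) -> tuple:
    """Multivariable MR: joint conditional effects of two exposures.

    Zero-intercept weighted regression of Γ on (γ, γ2) with weights
    1/se(Γ)²; returns one MRResult per exposure, with Cochran's Q (J−2 df)
    and the same multiplicative random-effects SE inflation as IVW.
    """
    t = instr.table
    if "gamma2" not in t.columns:
        raise ValueError("instrument set lacks a second exposure")
    J = len(t)
    if J < 3:
        raise ValueError("MVMR needs at least 3 instruments")
    X = t[["gamma", "gamma2"]].to_numpy()
    y = t["Gamma"].to_numpy()
    w = 1.0 / t["se_Gamma"].to_numpy() ** 2
    live = [k for k in range(2) if np.any(X[:, k] != 0)]
    if len(live) < 2:
        # an identically-zero exposure column: its conditional effect is
        # undefined; fit the other exposure alone (univariable IVW)
        coef = np.full(2, np.nan)
        ses = np.full(2, np.nan)
        k = live[0] if live else 0
        x = X[:, k]
        coef[k] = float(np.sum(w * x * y) / np.sum(w * x**2))
        resid = y - coef[k] * x
        q = float(np.sum(w * resid**2))
        q_p = float(stats.chi2.sf(q, J - 1))
        scale = max(1.0, np.sqrt(q / (J - 1))) if q_p < 0.05 else 1.0
        ses[k] = float(np.sqrt(1.0 / np.sum(w * x**2))) * scale
        model = "random" if scale > 1.0 else "fixed"
    else:
        if np.linalg.matrix_rank(X) < 2:
            raise ValueError(
                f"collinear exposures: {instr.exposure_name}, {instr.second_exposure_name}"
            )
        XtW = X.T * w
        cov_unscaled = np.linalg.inv(XtW @ X)
        coef = cov_unscaled @ (XtW @ y)
        resid = y - X @ coef
        q = float(np.sum(w * resid**2))
        q_p = float(stats.chi2.sf(q, J - 2))
        scale = max(1.0, np.sqrt(q / (J - 2))) if q_p < 0.05 else 1.0
        model = "random" if scale > 1.0 else "fixed"
        ses = np.sqrt(np.diag(cov_unscaled)) * scale
    names = (instr.exposure_name, instr.second_exposure_name or "exposure2")
    return tuple(
        MRResult(
            method="mvmr",
            estimate=float(coef[k]),
            se=float(ses[k]),
            n_snps=J,
            effects_model=model,
            cochran_q=q,
            q_p=q_p,
            exposure=names[k],
        )
        for k in range(2)
    )
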