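"""Weighted genetic risk scores and proportional-hazards fracture models.

A genetic risk score (GRS) is the weighted sum of effect-allele dosages
(weights = effect sizes from the source GWAS), standardized to mean 0 / SD 1
over the analysis sample. Incident fracture is modelled with Cox
proportional-hazards regression (Efron tie handling) with sex and baseline
age as base covariates; hazard ratios are per SD of GRS. The module also
provides interaction tests with age-stratified companion fits, and the
binarized four-group additive-risk analysis (high-FNW-GRS yes/no x
low-BMD-GRS yes/no at 50/25/10% cutoffs, group 1 = no/no as reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .synth import Cohort

__all__ = [
    "GRSDefinition",
    "SurvivalFit",
    "GroupAssignment",
    "compute_grs",
    "cox_fit",
    "test_interaction",
    "binarize_groups",
    "group_hazard_ratios",
    "AGE_SPLIT_DEFAULT",
]

#: default age split for stratified fits: the study's median age at hip fracture
AGE_SPLIT_DEFAULT = 71.7


@dataclass
class GRSDefinition:
    """Variant ids, per-variant weights and effect alleles defining a GRS."""

    variant_ids: list
    weights: np.ndarray
    effect_alleles: list

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids in GRS definition")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite GRS weights")
        if len(self.weights) != len(self.variant_ids):
            raise ValueError("weights and variant ids differ in length")


@dataclass
class SurvivalFit:
    """Coefficients and hazard ratios from one proportional-hazards fit."""

    terms: list
    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: int
    n_events: int
    site: str

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    def ci95(self, term: str):
        k = self.terms.index(term)
        return (
            float(np.exp(self.coef[k] - 1.96 * self.se[k])),
            float(np.exp(self.coef[k] + 1.96 * self.se[k])),
        )

    def hr_of(self, term: str) -> float:
        return float(np.exp(self.coef[self.terms.index(term)]))

    def coef_of(self, term: str) -> float:
        return float(self.coef[self.terms.index(term)])

    def p_of(self, term: str) -> float:
        return float(self.p[self.terms.index(term)])


@dataclass
class GroupAssignment:
    """Four-group classification from two binarized GRSs."""

    group: np.ndarray  # values in {1,2,3,4}
    cutoff_pct: int
    definitions: dict = field(
        default_factory=lambda: {
            1: "high-FNW no / low-BMD no",
            2: "high-FNW yes / low-BMD no",
            3: "high-FNW no / low-BMD yes",
            4: "high-FNW yes / low-BMD yes",
        }
    )


def compute_grs(cohort: Cohort, grs_def: GRSDefinition, mask=None) -> np.ndarray:
    """Standardized weighted dosage score over the analysis sample.

    Effect alleles are aligned against the cohort's variant coding; where
    the stored effect allele is the cohort's other allele the dosage is
    flipped to ``2 - dosage``. Standardization (mean 0, SD 1) is over the
    rows selected by ``mask`` (default: all).
    """
    dosages = cohort.dosage_of(grs_def.variant_ids)
    # cohort dosages are coded on the panel's EA; flip where the GRS effect
    # allele differs
    coding = cohort.variant_alleles or {}
    flip = np.zeros(len(grs_def.variant_ids), dtype=bool)
    for k, (vid, ea) in enumerate(zip(grs_def.variant_ids, grs_def.effect_alleles)):
        if vid in coding:
            cohort_ea, cohort_oa = coding[vid]
            if ea == cohort_oa:
                flip[k] = True
            elif ea != cohort_ea:
                raise ValueError(f"effect allele {ea} unknown for variant {vid}")
    aligned = np.where(flip[None, :], 2.0 - dosages, dosages)
    raw = aligned @ grs_def.weights
    sel = np.ones(cohort.n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    mu, sd = raw[sel].mean(), raw[sel].std()
    if sd < 1e-12:
        raise ValueError("zero GRS variance")
    return (raw - mu) / sd


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str, terms: list) -> SurvivalFit:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df[[duration_col, event_col] + terms],
            duration_col=duration_col,
            event_col=event_col,
        )
    s = cph.summary
    return SurvivalFit(
        terms=list(s.index),
        coef=s["coef"].to_numpy(),
        se=s["se(coef)"].to_numpy(),
        p=s["p"].to_numpy(),
        n=len(df),
        n_events=int(df[event_col].sum()),
        site=event_col.replace("event_", ""),
    )


def _analysis_frame(
    cohort: Cohort, site: str, exclude_discovery: bool, extra: dict | None = None
) -> pd.DataFrame:
    df = cohort.table.copy()
    if extra:
        for name, values in extra.items():
            df[name] = values
    keep = df["prevalent_flag"] == 0  # incident analyses exclude prevalent cases
    if exclude_discovery:
        keep &= df["discovery_flag"] == 0
    df = df[keep]
    df = df[df[f"time_{site}"] > 0]
    return df


def cox_fit(
    cohort: Cohort,
    site: str,
    terms: list,
    exclude_discovery: bool = True,
    covariate_values: dict | None = None,
) -> SurvivalFit:
    """Proportional-hazards fit of incident fracture at one site.

    ``terms`` are column names of the model; scores or derived columns can
    be injected via ``covariate_values`` (full-cohort-length arrays, subset
    internally). Prevalent cases are always excluded; ``exclude_discovery``
    (default True) additionally removes the FNW-GWAS discovery subsample.
    Interaction terms may be written as ``"a:b"`` (product of columns).
    """
    df = _analysis_frame(cohort, site, exclude_discovery, covariate_values and {
        k: np.asarray(v) for k, v in covariate_values.items()
    })
    n_events = int(df[f"event_{site}"].sum())
    if n_events == 0:
        raise ValueError(f"no incident events for site {site!r}")
    if n_events < 10:
        warnings.warn(
            f"only {n_events} incident events for site {site!r}; estimates unstable",
            stacklevel=2,
        )
    model_terms = []
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            # centre before multiplying: with both mains in the model the
            # Wald test is unchanged and the fit is far better conditioned
            df[term] = (df[a] - df[a].mean()) * (df[b] - df[b].mean())
        model_terms.append(term)
    return _fit_cox(df, f"time_{site}", f"event_{site}", model_terms)


def test_interaction(
    cohort: Cohort,
    site: str,
    term_a: str,
    term_b: str,
    base_terms: list = ("age", "sex"),
    exclude_discovery: bool = True,
    covariate_values: dict | None = None,
    age_split: float | None = None,
):
    """Wald test of a product term, with stratified companion fits.

    Fits the model with both main effects, the base covariates and the
    ``term_a:term_b`` product; reports the interaction coefficient and p.
    When one term is age, companion fits stratify at ``age_split`` (default
    the median age at event, or 71.7 yr when the data cannot supply one).
    """
    terms = list(dict.fromkeys(list(base_terms) + [term_a, term_b]))
    full = cox_fit(
        cohort,
        site,
        terms + [f"{term_a}:{term_b}"],
        exclude_discovery=exclude_discovery,
        covariate_values=covariate_values,
    )
    inter = f"{term_a}:{term_b}"
    result = {
        "interaction_term": inter,
        "coef": full.coef_of(inter),
        "se": float(full.se[full.terms.index(inter)]),
        "p": full.p_of(inter),
        "fit": full,
    }

    if "age" in (term_a, term_b):
        other = term_b if term_a == "age" else term_a
        df = _analysis_frame(
            cohort, site, exclude_discovery,
            covariate_values and {k: np.asarray(v) for k, v in covariate_values.items()},
        )
        if age_split is None:
            ev = df[df[f"event_{site}"] == 1]
            age_at_event = ev["age"] + ev[f"time_{site}"]
            age_split = float(age_at_event.median()) if len(ev) else AGE_SPLIT_DEFAULT
        strata = {}
        for label, mask in (
            (f"age<={age_split:g}", df["age"] <= age_split),
            (f"age>{age_split:g}", df["age"] > age_split),
        ):
            sub = df[mask]
            if sub[f"event_{site}"].sum() >= 10:
                strata[label] = _fit_cox(
                    sub, f"time_{site}", f"event_{site}",
                    [c for c in dict.fromkeys(list(base_terms) + [other]) if c != "age"],
                )
        result["age_split"] = age_split
        result["stratified"] = strata
    return result


def binarize_groups(
    score_fnw: np.ndarray, score_bmd: np.ndarray, cutoff_pct: int, allow_any: bool = False
) -> GroupAssignment:
    """Four-group assignment from binarized FNW and FN-BMD risk scores.

    High FNW risk = top ``cutoff_pct``% of the FNW GRS; high BMD risk = the
    bottom ``cutoff_pct``% of the FN-BMD GRS (genetically low BMD). Groups:
    1 = no/no (reference), 2 = yes/no, 3 = no/yes, 4 = yes/yes.
    """
    if cutoff_pct not in (50, 25, 10):
        if not allow_any:
            raise ValueError("cutoff_pct must be one of 50, 25, 10 (or pass allow_any=True)")
        warnings.warn(f"non-standard cutoff {cutoff_pct}%", stacklevel=2)
    fnw = np.asarray(score_fnw, dtype=float)
    bmd = np.asarray(score_bmd, dtype=float)
    if fnw.shape != bmd.shape:
        raise ValueError("scores differ in length")
    hi_fnw = fnw >= np.quantile(fnw, 1.0 - cutoff_pct / 100.0)
    lo_bmd = bmd <= np.quantile(bmd, cutoff_pct / 100.0)
    group = np.select(
        [~hi_fnw & ~lo_bmd, hi_fnw & ~lo_bmd, ~hi_fnw & lo_bmd, hi_fnw & lo_bmd],
        [1, 2, 3, 4],
    )
    return GroupAssignment(group=group, cutoff_pct=int(cutoff_pct))


def group_hazard_ratios(
    cohort: Cohort,
    groups: GroupAssignment,
    site: str,
    exclude_discovery: bool = True,
) -> SurvivalFit:
    """Cox fit of group indicators (groups 2-4 vs group 1) plus sex and age."""
    g = np.asarray(groups.group)
    extra = {f"group{k}": (g == k).astype(float) for k in (2, 3, 4)}
    extra["group_label"] = g.astype(float)
    df = _analysis_frame(cohort, site, exclude_discovery, extra)
    for k in (1, 2, 3, 4):
        if df.loc[df["group_label"] == k, f"event_{site}"].sum() < 1:
            raise ValueError(f"group {k} has no events")
    return _fit_cox(
        df, f"time_{site}", f"event_{site}", ["sex", "age", "group2", "group3", "group4"]
    )
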