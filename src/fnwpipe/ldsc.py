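"""LD-score regression: heritability and cross-trait genetic correlation.

Per-variant LD scores are sums of bias-adjusted squared dosage correlations
over a physical window around each variant, computed from a reference panel
of n_ref individuals: ``l_j = sum_k r~²_jk`` with
``r~² = r² − (1 − r²)/(n_ref − 2)`` (the self term contributes exactly 1).

Heritability comes from the regression ``E[χ²_j] = 1 + n·h²·l_j / M``;
the cross-trait genetic covariance from
``E[z1_j·z2_j] = sqrt(n1·n2)·gencov·l_j / M + intercept`` (the intercept
absorbs sample overlap). Genetic correlation is
``rg = gencov / sqrt(h²_1·h²_2)``. All standard errors are delete-one
block jackknives over contiguous variant blocks; regression weights are
``1/l_j`` as a heteroskedasticity proxy, in a single pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import ReferencePanel

__all__ = ["LDScoreSet", "RgResult", "compute_ld_scores", "ldsc_h2", "ldsc_rg"]


@dataclass
class LDScoreSet:
    """Per-variant LD scores plus the regression bookkeeping constants."""

    scores: pd.DataFrame  # columns: id, chr, pos, L2
    window_kb: float
    n_ref: int

    @property
    def m(self) -> int:
        return len(self.scores)


@dataclass
class RgResult:
    h2_1: float
    h2_2: float
    gencov: float
    rg: float
    intercept_1: float
    intercept_2: float
    intercept_cross: float
    se_rg: float
    p_rg: float
    significant: bool
    #: set when rg is undefined (a non-positive heritability estimate)
    error: str | None = None


def compute_ld_scores(
    panel: ReferencePanel, window_kb: float = 1000.0, maf_min: float = 0.05
) -> LDScoreSet:
    """Bias-adjusted LD scores over a physical window.

    Only variants with MAF > ``maf_min`` (default 5%, mirroring the usual
    HapMap3 common-variant restriction) enter the score set, both as index
    variants and as tagged neighbours.
    """
    if panel.n_individuals <= 2:
        raise ValueError("reference panel must have more than 2 individuals")
    if window_kb < 0:
        raise ValueError("window_kb must be non-negative")

    var = panel.variants
    maf = np.minimum(var["EAF"], 1.0 - var["EAF"]).to_numpy()
    keep = maf > maf_min
    ids = var.loc[keep, "id"].tolist()
    chrom = var.loc[keep, "chr"].to_numpy()
    pos = var.loc[keep, "pos"].to_numpy(dtype=float)

    Z = panel.standardized_dosages(ids)
    n_ref = panel.n_individuals
    window_bp = window_kb * 1000.0

    m = len(ids)
    l2 = np.empty(m)
    for j in range(m):
        in_win = (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= window_bp)
        r = (Z[:, in_win].T @ Z[:, j]) / n_ref
        r2 = r**2
        adj = r2 - (1.0 - r2) / (n_ref - 2)
        # the self term (r² = 1) is exact: its adjustment is zero, so it
        # contributes exactly 1 to the sum
        l2[j] = adj.sum()
    scores = pd.DataFrame({"id": ids, "chr": chrom, "pos": pos.astype(int), "L2": l2})
    return LDScoreSet(scores=scores, window_kb=window_kb, n_ref=n_ref)


def _match(sumstats: pd.DataFrame, ld: LDScoreSet):
    ss = sumstats.drop_duplicates(subset="id" if "id" in sumstats else "snp")
    key = "id" if "id" in ss.columns else "snp"
    merged = ld.scores.merge(ss.rename(columns={key: "id"}), on="id", how="inner")
    if merged.empty:
        raise ValueError("no variants shared between summary statistics and LD scores")
    return merged


def _block_bounds(m: int, n_blocks: int) -> list:
    if m < n_blocks:
        warnings.warn(
            f"only {m} variants; reducing jackknife blocks from {n_blocks}", stacklevel=3
        )
        n_blocks = max(2, m // 2)
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n_blocks) if edges[i + 1] > edges[i]]


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    X = np.column_stack([np.ones_like(x), x])
    Xw = X * w[:, None]
    coef = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    return float(coef[0]), float(coef[1])


def ldsc_h2(sumstats: pd.DataFrame, ld: LDScoreSet, n_blocks: int = 200):
    """SNP heritability from LD-score regression of χ² statistics.

    Returns a dict with ``h2``, ``intercept``, ``se_h2`` (block jackknife)
    and the variant count ``m`` used.
    """
    merged = _match(sumstats, ld)
    z = merged["z"].to_numpy(dtype=float)
    n = merged["n"].to_numpy(dtype=float)
    l2 = merged["L2"].to_numpy(dtype=float)
    m = ld.m
    chi2 = z**2
    x = n * l2 / m
    w = 1.0 / np.maximum(l2, 1.0)

    blocks = _block_bounds(len(z), n_blocks)

    def estimate(mask):
        icpt, slope = _wls(x[mask], chi2[mask], w[mask])
        return slope, icpt

    full_mask = np.ones(len(z), bool)
    h2, intercept = estimate(full_mask)
    reps = []
    for a, b in blocks:
        mask = full_mask.copy()
        mask[a:b] = False
        reps.append(estimate(mask)[0])
    reps = np.array(reps)
    g = len(reps)
    se = np.sqrt((g - 1) / g * np.sum((reps - reps.mean()) ** 2))
    return {"h2": h2, "intercept": intercept, "se_h2": se, "m": m, "n_blocks": g}


def ldsc_rg(
    sumstats1: pd.DataFrame,
    sumstats2: pd.DataFrame,
    ld: LDScoreSet,
    n_blocks: int = 200,
    alpha: float = 0.05 / 3,
) -> RgResult:
    """Cross-trait LD-score regression genetic correlation.

    Both summary-statistic tables must already be harmonized to a common
    effect allele per variant. The jackknife SE and p-value for rg come from
    recomputing all three regressions on each leave-one-block-out sample.
    """
    key1 = "id" if "id" in sumstats1.columns else "snp"
    key2 = "id" if "id" in sumstats2.columns else "snp"
    s1 = sumstats1.rename(columns={key1: "id"}).drop_duplicates("id")
    s2 = sumstats2.rename(columns={key2: "id"}).drop_duplicates("id")
    merged = ld.scores.merge(
        s1[["id", "z", "n"]].rename(columns={"z": "z1", "n": "n1"}), on="id"
    ).merge(s2[["id", "z", "n"]].rename(columns={"z": "z2", "n": "n2"}), on="id")
    if merged.empty:
        raise ValueError("no shared variants after matching")

    z1 = merged["z1"].to_numpy(dtype=float)
    z2 = merged["z2"].to_numpy(dtype=float)
    n1 = merged["n1"].to_numpy(dtype=float)
    n2 = merged["n2"].to_numpy(dtype=float)
    l2 = merged["L2"].to_numpy(dtype=float)
    m = ld.m
    w = 1.0 / np.maximum(l2, 1.0)

    x1 = n1 * l2 / m
    x2 = n2 * l2 / m
    xc = np.sqrt(n1 * n2) * l2 / m

    def estimate(mask):
        i1, h2_1 = _wls(x1[mask], z1[mask] ** 2, w[mask])
        i2, h2_2 = _wls(x2[mask], z2[mask] ** 2, w[mask])
        ic, gencov = _wls(xc[mask], (z1 * z2)[mask], w[mask])
        if h2_1 <= 0 or h2_2 <= 0:
            return np.nan, h2_1, h2_2, gencov, i1, i2, ic
        return gencov / np.sqrt(h2_1 * h2_2), h2_1, h2_2, gencov, i1, i2, ic

    full = np.ones(len(z1), bool)
    rg, h2_1, h2_2, gencov, i1, i2, ic = estimate(full)
    if not np.isfinite(rg):
        return RgResult(
            h2_1=h2_1, h2_2=h2_2, gencov=gencov, rg=np.nan,
            intercept_1=i1, intercept_2=i2, intercept_cross=ic,
            se_rg=np.nan, p_rg=np.nan, significant=False,
            error="non-positive heritability estimate; rg undefined",
        )
    if abs(rg) > 1:
        warnings.warn(f"|rg| = {abs(rg):.3f} exceeds 1", stacklevel=2)

    reps = []
    for a, b in _block_bounds(len(z1), n_blocks):
        mask = full.copy()
        mask[a:b] = False
        reps.append(estimate(mask)[0])
    reps = np.array([r for r in reps if np.isfinite(r)])
    g = len(reps)
    se = np.sqrt((g - 1) / g * np.sum((reps - reps.mean()) ** 2))
    p = 2.0 * stats.norm.sf(abs(rg) / se) if se > 0 else np.nan
    return RgResult(
        h2_1=h2_1,
        h2_2=h2_2,
        gencov=gencov,
        rg=rg,
        intercept_1=i1,
        intercept_2=i2,
        intercept_cross=ic,
        se_rg=se,
        p_rg=p,
        significant=bool(p < alpha) if np.isfinite(p) else False,
    )
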