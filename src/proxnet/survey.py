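"""Psychometric scoring of self-report scales and correlation tables.

Item retention is assessed on first-principal-component loadings of the
item correlation matrix; retained items are scored for internal
consistency (Cronbach's alpha, McDonald's omega from a single-factor
maximum-likelihood fit) and averaged into composites.  Composites and
per-factor log centralities go into a Pearson correlation table with
pairwise deletion and three-level significance flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from proxnet import codebook

FLAG_LEVELS = ((0.01, "**"), (0.05, "*"), (0.10, "†"))


def _complete_cases(items: pd.DataFrame) -> pd.DataFrame:
    return items.dropna(axis=0, how="any")


def pca_first_loadings(items: pd.DataFrame) -> pd.Series:
    """First-principal-component loadings of the item correlation matrix.

    Loadings are the first eigenvector scaled by the square root of its
    eigenvalue (so they are item/component correlations); the sign is
    flipped if needed so the loading sum is positive.  Complete cases
    only; a zero-variance item raises with the item named.
    """
    if items.shape[1] < 2:
        raise ValueError("need at least 2 items")
    data = _complete_cases(items)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 complete respondents")
    stds = data.std(ddof=1)
    dead = stds[stds == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance item(s): {dead}")
    R = np.corrcoef(data.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    v = eigvecs[:, -1] * math.sqrt(max(eigvals[-1], 0.0))
    if v.sum() < 0:
        v = -v
    return pd.Series(v, index=items.columns, name="loading")


def retain_items(loadings: pd.Series, threshold: float = codebook.DEFAULT_LOADING_THRESHOLD,
                 manual_exclusions: list[str] | None = None) -> list[str]:
    """Items with loading >= threshold, minus the manual-exclusion list."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    excl = set(manual_exclusions or [])
    retained = [it for it in loadings.index
                if loadings[it] >= threshold and it not in excl]
    if not retained:
        raise ValueError("no items retained")
    return retained


def cronbach_alpha(items: pd.DataFrame) -> float:
    """alpha = k/(k-1) * (1 - sum of item variances / variance of sums)."""
    if items.shape[1] < 2:
        raise ValueError("alpha needs at least 2 items")
    data = _complete_cases(items).to_numpy(dtype=float)
    if data.shape[0] < 3:
        raise ValueError("alpha needs at least 3 complete respondents")
    k = data.shape[1]
    item_vars = data.var(axis=0, ddof=1)
    total_var = data.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance in total scores")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def _ml_single_factor(R: np.ndarray, lam0: np.ndarray) -> np.ndarray:
    """Standardized loadings of a one-factor ML fit to correlation matrix R."""
    p = R.shape[0]
    sign, logdet_R = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("item correlation matrix is not positive definite")

    def discrepancy(lam: np.ndarray) -> float:
        psi = 1.0 - lam * lam
        if np.any(psi <= 1e-10):
            return 1e12
        sigma = np.outer(lam, lam)
        np.fill_diagonal(sigma, 1.0)
        s_sign, logdet_s = np.linalg.slogdet(sigma)
        if s_sign <= 0:
            return 1e12
        return logdet_s + float(np.trace(np.linalg.solve(sigma, R))) - logdet_R - p

    res = scipy.optimize.minimize(discrepancy, lam0, method="L-BFGS-B",
                                  bounds=[(-0.999, 0.999)] * p)
    return res.x


def mcdonald_omega(items: pd.DataFrame) -> float:
    """omega = (sum lambda)^2 / ((sum lambda)^2 + sum(1 - lambda^2)).

    Loadings come from a maximum-likelihood single-factor fit to the item
    correlation matrix (standardized metric).  A Heywood case (|lambda|
    pinned at the unit bound) raises with a diagnostic.
    """
    if items.shape[1] < 2:
        raise ValueError("omega needs at least 2 items")
    data = _complete_cases(items)
    if data.shape[0] < 3:
        raise ValueError("omega needs at least 3 complete respondents")
    R = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    lam0 = pca_first_loadings(data).to_numpy().clip(-0.9, 0.9)
    lam = _ml_single_factor(R, lam0)
    if np.any(np.abs(lam) >= 0.999 - 1e-6):
        bad = [items.columns[i] for i in np.nonzero(np.abs(lam) >= 0.999 - 1e-6)[0]]
        raise ValueError(f"Heywood case: loading at unit bound for item(s) {bad}")
    if lam.sum() < 0:
        lam = -lam
    theta = 1.0 - lam * lam
    s = lam.sum()
    return float(s * s / (s * s + theta.sum()))


def composite_score(items: pd.DataFrame, retained: list[str]) -> pd.Series:
    """Per-participant mean of answered retained items.

    Missing when fewer than ``ceil(len(retained)/2)`` retained items are
    answered.
    """
    if not retained:
        raise ValueError("retained item list is empty")
    sub = items[retained]
    answered = sub.notna().sum(axis=1)
    need = math.ceil(len(retained) / 2)
    out = sub.mean(axis=1)
    out[answered < need] = np.nan
    return out


@dataclass
class ScaleResult:
    name: str
    items: list[str]
    loadings: pd.Series
    retained: list[str]
    alpha: float
    omega: float
    composite: pd.Series


def score_scales(survey: pd.DataFrame, scales: dict | None = None,
                 threshold: float = codebook.DEFAULT_LOADING_THRESHOLD,
                 use_published_retained: bool = False) -> dict[str, ScaleResult]:
    """Score every configured multi-item scale on a survey table.

    With ``use_published_retained`` the packaged retained-item sets are
    used verbatim; otherwise retention applies the loading threshold plus
    each scale's manual-exclusion list.
    """
    scales = scales or codebook.SCALES
    results: dict[str, ScaleResult] = {}
    for name, cfg in scales.items():
        sub = survey[cfg["items"]]
        loadings = pca_first_loadings(sub)
        if use_published_retained and "retained" in cfg:
            retained = list(cfg["retained"])
        else:
            retained = retain_items(loadings, threshold=threshold,
                                    manual_exclusions=cfg.get("manual_exclusions"))
        kept = survey[retained]
        results[name] = ScaleResult(
            name=name, items=list(cfg["items"]), loadings=loadings,
            retained=retained, alpha=cronbach_alpha(kept),
            omega=mcdonald_omega(kept),
            composite=composite_score(survey, retained),
        )
    return results


def describe(variables: pd.DataFrame) -> pd.DataFrame:
    """N, mean, median, SD (n-1 denominator), min, max per column.

    SD is reported missing for single-observation variables.
    """
    rows = []
    for col in variables.columns:
        x = variables[col].dropna()
        if x.empty:
            raise ValueError(f"variable {col!r} has no non-missing values")
        rows.append({
            "variable": col, "N": int(x.size), "mean": float(x.mean()),
            "median": float(x.median()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else np.nan,
            "min": float(x.min()), "max": float(x.max()),
        })
    return pd.DataFrame(rows).set_index("variable")


def significance_flag(p: float) -> str:
    if np.isnan(p):
        return ""
    for level, mark in FLAG_LEVELS:
        if p < level:
            return mark
    return ""


@dataclass
class CorrelationTable:
    """Pairwise Pearson correlations with p-values, n's and flags."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    @property
    def flags(self) -> pd.DataFrame:
        return self.p.map(significance_flag)

    def formatted(self, digits: int = 2) -> pd.DataFrame:
        """r rounded to ``digits`` with appended significance marks."""
        out = self.r.round(digits).astype(str) + self.flags
        return out.where(~self.r.isna(), "")


def correlate(table: pd.DataFrame) -> CorrelationTable:
    """Pairwise-deletion Pearson correlation table with two-tailed p's.

    p-values come from the t distribution with n-2 degrees of freedom.
    Pairs with fewer than 3 joint observations or zero variance are
    reported missing.
    """
    cols = list(table.columns)
    m = len(cols)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    n = np.zeros((m, m), dtype=int)
    for a in range(m):
        for b in range(a, m):
            x = table[cols[a]]
            y = table[cols[b]]
            mask = x.notna() & y.notna()
            nn = int(mask.sum())
            n[a, b] = n[b, a] = nn
            if a == b:
                if nn >= 1:
                    r[a, a] = 1.0
                    p[a, a] = 0.0
                continue
            if nn < 3:
                continue
            xv = x[mask].to_numpy(dtype=float)
            yv = y[mask].to_numpy(dtype=float)
            if xv.std() == 0 or yv.std() == 0:
                continue
            rr = float(np.corrcoef(xv, yv)[0, 1])
            rr = max(-1.0, min(1.0, rr))
            if abs(rr) == 1.0:
                pp = 0.0
            else:
                t = rr * math.sqrt((nn - 2) / (1.0 - rr * rr))
                pp = 2.0 * float(scipy.stats.t.sf(abs(t), df=nn - 2))
            r[a, b] = r[b, a] = rr
            p[a, b] = p[b, a] = pp
    idx = pd.Index(cols)
    return CorrelationTable(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )
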