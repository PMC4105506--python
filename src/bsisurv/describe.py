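"""Descriptive cohort statistics: positive-subset correlations, summary
tables and survival-group comparisons.

Because regional BSI values are heavily zero-inflated, Pearson
correlations between regions are computed on the subset of patients where
both members of the pair are positive (pairwise deletion); pairs involving
age or survival time with a region use the rows where that region is
positive, and the age-time pair uses all rows. An all-rows variant is
available behind a flag. Observed follow-up time enters the correlation
column for censored patients as-is (an interpretation, flagged here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bsi import REGIONS
from .cohort import Cohort
from .cox import five_year_rate, kaplan_meier, log_rank

#: Correlation-table variables in order: age, the twelve regions, survival time.
CORR_VARS: tuple[str, ...] = ("age", *REGIONS, "time")


@dataclass
class CorrelationResult:
    """14x14 Pearson matrix with p-values and per-pair effective n."""

    rho: np.ndarray
    p_value: np.ndarray
    effective_n: np.ndarray
    variables: tuple[str, ...] = CORR_VARS

    def pair(self, a: str, b: str) -> tuple[float, float, int]:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.rho[i, j]), float(self.p_value[i, j]), int(self.effective_n[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.variables, columns=self.variables)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson rho with a two-sided t-transform p-value."""
    n = x.shape[0]
    r = float(np.corrcoef(x, y)[0, 1])
    if not np.isfinite(r):
        return np.nan, np.nan
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def pairwise_correlations(cohort: Cohort, positive_subset: bool = True) -> CorrelationResult:
    """Correlations among age, the twelve regions and survival time.

    With ``positive_subset=True`` (default) region pairs are restricted to
    rows where both regions are positive; region-vs-age/time pairs to rows
    where the region is positive. Pairs with effective n < 3 are flagged
    not-estimable (NaN rho/p).
    """
    if cohort.n < 3:
        raise ValueError("need at least 3 patients")
    cols = {"age": cohort.age, "time": cohort.time}
    for r in REGIONS:
        cols[r] = cohort.region_column(r)
    k = len(CORR_VARS)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    eff = np.full((k, k), cohort.n, dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = CORR_VARS[i], CORR_VARS[j]
            mask = np.ones(cohort.n, dtype=bool)
            if positive_subset:
                if a in REGIONS:
                    mask &= cols[a] > 0
                if b in REGIONS:
                    mask &= cols[b] > 0
            m = int(mask.sum())
            eff[i, j] = eff[j, i] = m
            if m < 3:
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                continue
            r, p = _pearson(cols[a][mask], cols[b][mask])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return CorrelationResult(rho=rho, p_value=pval, effective_n=eff)


def flag_strong_pairs(
    result: CorrelationResult,
    rho_threshold: float = 0.7,
    alpha: float = 0.05,
) -> dict:
    """Region pairs with |rho| >= threshold and p < alpha, plus extremes.

    Returns the flagged pairs, the most-correlated region (most flagged
    pairs, ties by smaller mean |rho| losing) and the least-correlated
    region (smallest mean |rho| over estimable region pairs).
    """
    idx = [result.variables.index(r) for r in REGIONS]
    pairs = []
    flag_count = dict.fromkeys(REGIONS, 0)
    mean_abs = {}
    for ai, a in enumerate(REGIONS):
        rhos = []
        for bi, b in enumerate(REGIONS):
            if ai == bi:
                continue
            r = result.rho[idx[ai], idx[bi]]
            if np.isfinite(r):
                rhos.append(abs(r))
            if bi > ai:
                p = result.p_value[idx[ai], idx[bi]]
                if np.isfinite(r) and abs(r) >= rho_threshold and p < alpha:
                    pairs.append((a, b, float(r), float(p)))
                    flag_count[a] += 1
                    flag_count[b] += 1
        mean_abs[a] = float(np.mean(rhos)) if rhos else np.nan
    most = max(REGIONS, key=lambda r: (flag_count[r], mean_abs.get(r) or 0.0))
    least = min(REGIONS, key=lambda r: np.inf if np.isnan(mean_abs[r]) else mean_abs[r])
    return {
        "pairs": pairs,
        "n_flagged": len(pairs),
        "most_correlated": most,
        "least_correlated": least,
        "flag_count": flag_count,
        "mean_abs_rho": mean_abs,
    }


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Per-covariate mean/median/sd/%zeros/%unique plus follow-up facts.

    ``pct_unique`` is the number of distinct values over n — an
    interpretation of a conventionally unreported quantity, flagged here.
    Censored fraction and mean follow-up are attached as frame attrs.
    """
    rows = []
    cols = {"age": cohort.age, "total_bsi": cohort.total_bsi}
    for r in REGIONS:
        cols[r] = cohort.region_column(r)
    order = ["age", "total_bsi", *REGIONS]
    for name in order:
        x = cols[name]
        rows.append(
            {
                "covariate": name,
                "mean": float(np.mean(x)),
                "median": float(np.median(x)),
                "sd": float(np.std(x, ddof=1)),
                "pct_zeros": float(np.mean(x == 0) * 100.0),
                "pct_unique": float(np.unique(x).size / x.size * 100.0),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["censored_fraction"] = float(np.mean(cohort.event == 0))
    df.attrs["mean_followup_years"] = float(np.mean(cohort.time))
    return df


def survival_groups(
    cohort: Cohort,
    lesion_cutoff: int = 5,
    horizon: float = 5.0,
) -> dict:
    """Kaplan-Meier ``horizon``-year survival by metastatic-burden group.

    Groups: overall; no metastases (lesion count 0); metastases present;
    among those, at most ``lesion_cutoff`` lesions vs more. Log-rank
    p-values compare no-vs-any metastases and few-vs-many lesions. Empty
    groups are reported with a note instead of a rate.
    """
    if cohort.lesions is None:
        raise ValueError("cohort has no lesion counts")
    les = cohort.lesions
    masks = {
        "overall": np.ones(cohort.n, dtype=bool),
        "no_metastases": les == 0,
        "metastases": les > 0,
        f"lesions_le_{lesion_cutoff}": (les > 0) & (les <= lesion_cutoff),
        f"lesions_gt_{lesion_cutoff}": les > lesion_cutoff,
    }
    rows = []
    notes = []
    for name, mask in masks.items():
        m = int(mask.sum())
        if m == 0:
            notes.append(f"group {name} is empty; rate omitted")
            rows.append({"group": name, "n": 0, "events": 0, "rate": np.nan, "truncated": False})
            continue
        km = kaplan_meier(cohort.time[mask], cohort.event[mask])
        rate, truncated = five_year_rate(km, horizon)
        rows.append(
            {
                "group": name,
                "n": m,
                "events": int(cohort.event[mask].sum()),
                "rate": rate,
                "truncated": truncated,
            }
        )
    tests = {}
    for label, (ma, mb) in {
        "no_vs_any_metastases": (masks["no_metastases"], masks["metastases"]),
        "few_vs_many_lesions": (
            masks[f"lesions_le_{lesion_cutoff}"],
            masks[f"lesions_gt_{lesion_cutoff}"],
        ),
    }.items():
        if ma.sum() > 0 and mb.sum() > 0:
            chi2, p = log_rank(
                cohort.time[ma], cohort.event[ma], cohort.time[mb], cohort.event[mb]
            )
            tests[label] = {"chi2": chi2, "p": p}
    return {"table": pd.DataFrame(rows), "log_rank": tests, "notes": notes}
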