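"""Clinical scoring and correlation statistics.

MSFC-4: each subtest is z-scored against a reference population (by default
this cohort at the reference visit, the classic choice when no external
reference is named). Timed tests (25-foot walk, 9-hole peg) enter negated so
that higher always means better; the composite is the mean of the four
subscore z-scores. An alternative 9HPT convention (z of 1/time, unnegated)
is available behind a config switch.

Feature-score association: Spearman rank correlation with a two-sided
t-approximation p-value, t = rho sqrt((n-2) / (1-rho^2)) on n-2 degrees of
freedom, and Storey q-values for multiple-testing correction within each
clinical-measure column (one family = all features against one measure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .config import StatsConfig

MSFC_SUBSCORES = ("t25fw_s", "nhpt_s", "sdmt_correct", "lcva_correct")


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    clinical_measure: str
    n: int
    rho: float
    p: float
    q: float
    sig_p05: bool
    sig_p01: bool
    sig_q05: bool
    sig_q01: bool


# ---------------------------------------------------------------------------
# MSFC-4
# ---------------------------------------------------------------------------


def msfc4_scores(raw: pd.DataFrame, reference: pd.DataFrame | None = None,
                 config: StatsConfig | None = None) -> pd.DataFrame:
    """Append MSFC-4 z-scores and the composite to a raw clinical table.

    ``reference`` supplies the normalizing means/sds (columns as the raw
    table); omitted, the input table itself is the reference population.
    Output adds z_25fw, z_9hpt, z_sdmt, z_lcva and msfc4_composite.
    """
    config = config or StatsConfig()
    ref = reference if reference is not None else raw
    if len(ref) < 2:
        raise ValueError("reference population needs n >= 2")
    out = raw.copy()

    def zref(col: str, values: pd.Series) -> pd.Series:
        mean = ref[col].mean()
        sd = ref[col].std(ddof=1)
        if not sd > 0:
            raise ValueError(f"zero-variance reference for subscore {col!r}")
        return (values - mean) / sd

    out["z_25fw"] = -zref("t25fw_s", raw["t25fw_s"])
    if config.nhpt_mode == "neg_z":
        out["z_9hpt"] = -zref("nhpt_s", raw["nhpt_s"])
    elif config.nhpt_mode == "inv_time":
        inv_ref = 1.0 / ref["nhpt_s"]
        sd = inv_ref.std(ddof=1)
        if not sd > 0:
            raise ValueError("zero-variance reference for subscore 'nhpt_s'")
        out["z_9hpt"] = (1.0 / raw["nhpt_s"] - inv_ref.mean()) / sd
    else:
        raise ValueError(f"unknown nhpt_mode {config.nhpt_mode!r}")
    out["z_sdmt"] = zref("sdmt_correct", raw["sdmt_correct"])
    out["z_lcva"] = zref("lcva_correct", raw["lcva_correct"])
    out["msfc4_composite"] = out[["z_25fw", "z_9hpt", "z_sdmt", "z_lcva"]].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of midranks.

    Pairs with a missing value in either variable are deleted; a constant
    variable makes the correlation undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    rx = sp_stats.rankdata(x)   # average (mid) ranks for ties
    ry = sp_stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho at sample size n (t-approximation)."""
    if n < 4:
        raise ValueError("need n >= 4 for the t-approximation")
    if math.isnan(rho):
        return math.nan
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sp_stats.t.sf(abs(t), n - 2))


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

_LAMBDA_GRID = np.arange(0.0, 0.91, 0.05)


def estimate_pi0(pvalues: np.ndarray, lambdas: np.ndarray = _LAMBDA_GRID) -> float:
    """Storey's estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the lambda grid,
    extrapolated to lambda = 1 with a cubic smoother and clipped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coeffs, 1.0))
    return min(max(pi0, 1.0 / m), 1.0)


def storey_q(pvalues: np.ndarray, pi0: float | None = None,
             config: StatsConfig | None = None) -> np.ndarray:
    """Storey q-values for a family of p-values (original order preserved).

    q(p_(i)) = min_{j >= i} pi0 m p_(j) / j over the sorted p-values. With
    ``pi0`` forced to 1 (or config.qvalue_mode == "bh") this reduces to the
    Benjamini-Hochberg adjusted p-values.
    """
    config = config or StatsConfig()
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = 1.0 if config.qvalue_mode == "bh" else estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    m = p.size
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Correlation table
# ---------------------------------------------------------------------------


def correlation_table(features: pd.DataFrame, clinical: pd.DataFrame,
                      config: StatsConfig | None = None) -> pd.DataFrame:
    """All feature x clinical-measure Spearman correlations with q-values.

    Both tables are indexed by subject; q-values are computed per clinical
    measure (each measure's family = every feature tested against it). The
    per-row n reflects pairwise deletion of missing values.
    """
    config = config or StatsConfig()
    shared = features.index.intersection(clinical.index)
    if shared.empty:
        raise ValueError("no shared subjects between the two tables")
    f = features.loc[shared]
    c = clinical.loc[shared]
    rows: list[dict] = []
    for measure in c.columns:
        measure_rows = []
        for feat in f.columns:
            x = f[feat].to_numpy(dtype=float)
            y = c[measure].to_numpy(dtype=float)
            mask = ~(np.isnan(x) | np.isnan(y))
            n = int(mask.sum())
            if n < config.min_pairs:
                raise ValueError(
                    f"fewer than {config.min_pairs} complete pairs for "
                    f"{feat!r} x {measure!r}")
            rho = spearman_rho(x[mask], y[mask])
            p = spearman_pvalue(rho, n)
            measure_rows.append({"feature": feat, "clinical_measure": measure,
                                 "n": n, "rho": rho, "p": p})
        ps = np.array([r["p"] for r in measure_rows])
        ok = ~np.isnan(ps)
        qs = np.full(ps.size, np.nan)
        if ok.any():
            pi0 = 1.0 if config.qvalue_mode == "bh" else None
            qs[ok] = storey_q(ps[ok], pi0=pi0, config=config)
        for r, q in zip(measure_rows, qs):
            a05, a01 = config.alpha_levels
            r["q"] = q
            r["sig_p05"] = bool(r["p"] <= a05) if not np.isnan(r["p"]) else False
            r["sig_p01"] = bool(r["p"] <= a01) if not np.isnan(r["p"]) else False
            r["sig_q05"] = bool(q <= a05) if not np.isnan(q) else False
            r["sig_q01"] = bool(q <= a01) if not np.isnan(q) else False
            rows.append(r)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Variability of the k-day median
# ---------------------------------------------------------------------------


def variability_vs_days(daily: pd.DataFrame, k_grid: np.ndarray | list[int],
                        n_resamples: int = 100, seed: int | None = None,
                        value_col: str = "value",
                        subject_col: str = "subject") -> pd.DataFrame:
    """Standard error of the k-day median against the full-period median.

    For each subject and each k, ``n_resamples`` random contiguous k-day
    blocks are drawn; the curve value is the root-mean-square deviation of
    the block medians from that subject's full-period median. Returns
    per-subject rows plus a cohort-mean row per k (subject = "__cohort__").
    A k larger than a subject's available days is skipped.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sid, grp in daily.groupby(subject_col, sort=True):
        values = grp.sort_values("day_index")[value_col].to_numpy(dtype=float)
        values = values[~np.isnan(values)]
        full_median = np.median(values) if values.size else math.nan
        for k in k_grid:
            k = int(k)
            if k < 1 or k > values.size:
                continue
            starts = rng.integers(0, values.size - k + 1, n_resamples)
            meds = np.array([np.median(values[s:s + k]) for s in starts])
            rmse = float(np.sqrt(np.mean((meds - full_median) ** 2)))
            rows.append({subject_col: sid, "k_days": k, "se_median": rmse})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    cohort = (df.groupby("k_days")["se_median"].mean().reset_index())
    cohort[subject_col] = "__cohort__"
    return pd.concat([df, cohort], ignore_index=True)
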