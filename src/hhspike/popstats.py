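"""Population-level distribution characterization and inference.

Covers the study's statistical battery over units and pairs:

* Hartigan dip tests of unimodality for the firing-rate and burst-index
  distributions (:mod:`hhspike.dip`),
* Gaussian-mixture fits with the number of components chosen by successively
  adding a component until the Akaike information criterion stops improving,
* the slow/fast rate classification at the 2 sp/s boundary,
* an exact binomial test of the fraction of significant pairs against the
  chance level (the synchrony test's nominal false-positive rate),
* Fisher's exact test for enrichment of synchrony among fast-firing pairs,
* Pearson chi-square tests of heterogeneity of the synchronous-pair fraction
  between patients and between epochs within patients,
* ordinary-least-squares models of firing rate on anesthesia covariates with
  per-variable F-ratio tests, Benjamini-Hochberg control of the false
  discovery rate at q = 0.2, and a dip test on the residuals of the combined
  significant-covariate model.

Mixtures are fitted on the raw (not log) values, matching how the rate and
burst distributions are classified; non-finite burst indices are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .dip import DipResult, dip_test
from .metrics import RATE_CLASS_BOUNDARY

__all__ = [
    "MixtureFit",
    "GLMReport",
    "dip_test",
    "DipResult",
    "fit_gmm_aic",
    "classify_rates",
    "binomial_fraction_test",
    "fast_pair_enrichment",
    "heterogeneity_tests",
    "anesthesia_glm",
    "residual_multimodality",
    "covariate_frame",
]


# ---------------------------------------------------------------------------
# mixture fitting
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    n_components: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    aic: float
    assignments: np.ndarray        # most-likely component per finite observation
    component_medians: np.ndarray  # median of observations per component
    aic_path: list[float] = field(default_factory=list)


def fit_gmm_aic(
    values,
    max_components: int = 8,
    seed: int = 0,
    n_init: int = 10,
) -> MixtureFit:
    """One-dimensional Gaussian mixture with AIC-stopped component count.

    Components are added one at a time; fitting stops at the first count
    whose AIC fails to improve on the previous one (no slack), and the best
    preceding fit is returned.  Components are ordered by mean.  Non-finite
    observations are excluded; a degenerate (constant) sample yields a single
    component with a floored SD.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        raise ValueError("mixture fit requires at least 8 finite observations")
    X = x.reshape(-1, 1)
    if np.ptp(x) == 0.0:
        comp = np.zeros(x.size, dtype=int)
        return MixtureFit(1, np.array([1.0]), np.array([x[0]]),
                          np.array([1e-3]), float("nan"), comp, np.array([x[0]]))

    best: Optional[GaussianMixture] = None
    best_aic = np.inf
    aic_path: list[float] = []
    # a component needs a handful of observations to be estimable; without
    # this cap tiny samples let near-singular components win on likelihood
    max_components = min(max_components, max(1, x.size // 5))
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            reg_covar=1e-6,
        ).fit(X)
        aic = float(gm.aic(X))
        aic_path.append(aic)
        if aic >= best_aic:
            break
        best, best_aic = gm, aic

    assert best is not None
    order = np.argsort(best.means_.ravel())
    means = best.means_.ravel()[order]
    sds = np.sqrt(best.covariances_.ravel()[order])
    weights = best.weights_[order]
    raw_assign = best.predict(X)
    remap = np.empty_like(order)
    remap[order] = np.arange(order.size)
    assign = remap[raw_assign]
    medians = np.array(
        [np.median(x[assign == c]) if np.any(assign == c) else np.nan
         for c in range(means.size)]
    )
    return MixtureFit(
        n_components=int(means.size),
        weights=weights,
        means=means,
        sds=sds,
        aic=best_aic,
        assignments=assign,
        component_medians=medians,
        aic_path=aic_path,
    )


def classify_rates(rates) -> np.ndarray:
    """Label each rate 'slow' (< 2 sp/s) or 'fast' (>= 2 sp/s)."""
    r = np.asarray(rates, dtype=float)
    if r.size and r.min() < 0:
        raise ValueError("rates must be >= 0")
    return np.where(r < RATE_CLASS_BOUNDARY, "slow", "fast")


# ---------------------------------------------------------------------------
# pair-level inference
# ---------------------------------------------------------------------------


def binomial_fraction_test(k_significant: int, n_pairs: int, p0: float = 0.05) -> float:
    """Two-sided exact binomial p for ``k`` significant pairs out of ``n``.

    ``p0`` is the chance probability of a pair reaching significance — read
    as the synchrony test's nominal false-positive rate.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not (0 <= k_significant <= n_pairs):
        raise ValueError("k_significant must lie in [0, n_pairs]")
    return float(stats.binomtest(k_significant, n_pairs, p0).pvalue)


def fast_pair_enrichment(
    pairs: pd.DataFrame, rate_class_by_unit: dict[str, str]
) -> tuple[float, float, np.ndarray]:
    """Fisher exact test of synchrony enrichment among fast-firing pairs.

    Builds the 2x2 table (both units fast vs not) x (significant vs not) from
    a pairs table with ``unit_a, unit_b, significant`` columns.  Returns
    ``(p_value, odds_ratio, table)``.  Raises if either margin is empty.
    """
    both_fast = np.array(
        [
            rate_class_by_unit[a] == "fast" and rate_class_by_unit[b] == "fast"
            for a, b in zip(pairs["unit_a"], pairs["unit_b"])
        ]
    )
    sig = pairs["significant"].to_numpy(dtype=bool)
    table = np.array(
        [
            [np.sum(both_fast & sig), np.sum(both_fast & ~sig)],
            [np.sum(~both_fast & sig), np.sum(~both_fast & ~sig)],
        ]
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate margin in enrichment table")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), float(odds), table


def heterogeneity_tests(pairs: pd.DataFrame) -> dict[str, float]:
    """Pearson chi-square heterogeneity of the significant-pair fraction.

    ``between_patients``: independence of {significant, not} and patient over
    all pairs.  ``between_epochs_within_patients``: per-patient chi-square
    across that patient's epochs (patients with at least two epochs carrying
    pairs), statistics and degrees of freedom summed across patients.
    """
    if pairs["patient_id"].nunique() < 2:
        raise ValueError("heterogeneity test requires at least 2 patients")
    sig = pairs["significant"].astype(bool)
    tab = pd.crosstab(pairs["patient_id"], sig).reindex(
        columns=[False, True], fill_value=0
    )
    chi2, p_pat, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    total_stat, total_df = 0.0, 0
    for _, grp in pairs.groupby("patient_id"):
        if grp["epoch_id"].nunique() < 2:
            continue
        t = pd.crosstab(grp["epoch_id"], grp["significant"].astype(bool)).reindex(
            columns=[False, True], fill_value=0
        ).to_numpy()
        if (t.sum(axis=0) == 0).any():
            continue  # all pairs same outcome: no information
        s, _, df, _ = stats.chi2_contingency(t, correction=False)
        total_stat += s
        total_df += df
    p_epoch = float(stats.chi2.sf(total_stat, total_df)) if total_df else float("nan")
    return {
        "between_patients_chi2": float(chi2),
        "between_patients_p": float(p_pat),
        "between_epochs_chi2": float(total_stat),
        "between_epochs_df": int(total_df),
        "between_epochs_p": p_epoch,
    }


# ---------------------------------------------------------------------------
# anesthesia covariate models
# ---------------------------------------------------------------------------

#: covariate -> (columns builder kind); categorical variables enter the
#: F-test jointly through their dummy columns
_CATEGORICAL = {"fentanyl_use": ["induction", "intervals", "none"],
                "gas_carrier": ["air", "NO", "neither"]}
_CONTINUOUS = ["sevoflurane_pct", "temperature_c", "minutes_since_last_change"]
_FLAGS = ["midazolam_at_induction", "propofol_at_induction", "decadron_use"]


def covariate_frame(records: Sequence) -> pd.DataFrame:
    """Flat covariate table from per-unit anesthesia records."""
    return pd.DataFrame([r.to_dict() for r in records])


def _design_columns(cov: pd.DataFrame, name: str) -> Optional[np.ndarray]:
    """Design submatrix (n, q) for one covariate; None when degenerate."""
    if name in _CATEGORICAL:
        levels = _CATEGORICAL[name]
        vals = cov[name].astype(str)
        present = [lv for lv in levels if (vals == lv).any()]
        if len(present) < 2:
            return None
        cols = [(vals == lv).to_numpy(float) for lv in present[1:]]
        return np.column_stack(cols)
    col = cov[name]
    if col.dtype == bool or name in _FLAGS:
        v = col.astype(float).to_numpy()
    else:
        v = pd.to_numeric(col, errors="coerce").to_numpy(float)
    if np.unique(v[np.isfinite(v)]).size < 2:
        return None
    return v.reshape(-1, 1)


def _ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


@dataclass
class GLMReport:
    per_variable: pd.DataFrame        # variable, F, p, significant_after_fdr, ...
    total_variance_fraction: float    # R^2 of the combined significant model
    residuals: np.ndarray             # residuals of that combined model
    fdr_q: float = 0.2
    n: int = 0


def anesthesia_glm(
    rates,
    covariates: pd.DataFrame,
    fdr_q: float = 0.2,
) -> GLMReport:
    """Linear models of firing rate on each anesthesia covariate.

    Each covariate is tested by an F-ratio test of adding it alone to the
    intercept-only model (no interactions); the resulting p-values are
    corrected by Benjamini-Hochberg control of the false discovery rate at
    ``fdr_q``.  The report carries each variable's incremental fraction of
    variance (the univariate R^2), its effect estimate in sp/s, the combined
    significant-covariate model's total explained variance, and its
    residuals.
    """
    y = np.asarray(rates, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("anesthesia GLM requires at least 10 units")
    if len(covariates) != n:
        raise ValueError("rates and covariates must align")
    ones = np.ones((n, 1))
    _, rss0 = _ols_rss(y, ones)

    rows = []
    blocks: dict[str, np.ndarray] = {}
    for name in _CONTINUOUS + _FLAGS + list(_CATEGORICAL):
        cols = _design_columns(covariates, name)
        if cols is None:
            rows.append({"variable": name, "F": np.nan, "p_value": np.nan,
                         "df_num": 0, "effect": np.nan, "variance_fraction": np.nan,
                         "note": "constant covariate, skipped"})
            continue
        X = np.hstack([ones, cols])
        beta, rss1 = _ols_rss(y, X)
        q = cols.shape[1]
        df_den = n - X.shape[1]
        if df_den <= 0 or rss1 <= 0:
            F, p = np.nan, np.nan
        else:
            F = ((rss0 - rss1) / q) / (rss1 / df_den)
            p = float(stats.f.sf(F, q, df_den))
        effect = float(beta[1]) if q == 1 else float(np.max(np.abs(beta[1:])))
        rows.append({"variable": name, "F": float(F), "p_value": p, "df_num": q,
                     "effect": effect,
                     "variance_fraction": 1.0 - rss1 / rss0 if rss0 > 0 else np.nan,
                     "note": ""})
        blocks[name] = cols

    per_var = pd.DataFrame(rows)
    testable = per_var["p_value"].notna()
    sig = np.zeros(len(per_var), dtype=bool)
    if testable.any():
        rej, _, _, _ = multipletests(
            per_var.loc[testable, "p_value"], alpha=fdr_q, method="fdr_bh"
        )
        sig[np.flatnonzero(testable)] = rej
    per_var["significant_after_fdr"] = sig

    sig_names = per_var.loc[sig, "variable"].tolist()
    if sig_names:
        X_full = np.hstack([ones] + [blocks[nm] for nm in sig_names])
        beta_full, rss_full = _ols_rss(y, X_full)
        resid = y - X_full @ beta_full
        total_r2 = 1.0 - rss_full / rss0 if rss0 > 0 else np.nan
    else:
        resid = y - y.mean()
        total_r2 = 0.0
    return GLMReport(per_var, float(total_r2), resid, fdr_q, n)


def residual_multimodality(
    report: GLMReport, n_reference: int = 2000, seed: int = 0
) -> DipResult:
    """Dip test applied to the combined model's firing-rate residuals."""
    return dip_test(report.residuals, n_reference=n_reference, seed=seed)
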