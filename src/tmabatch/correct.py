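"""Value-level batch-effect correction methods.

Seven ways of handling between-batch (between-TMA) differences in a
biomarker, numbered as commonly presented in the batch-effect literature
for tissue microarrays:

1. ``uncorrected``        — pass-through baseline.
2. ``simple_means``       — subtract each batch's mean deviation from the
   pooled mean; assumes no true between-batch differences.
3. ``standardized_means`` — as 2, but the batch effects come from a linear
   model that adjusts for clinical covariates, so covariate-explained
   between-batch differences are retained (model-based standardization).
4. ``ipw_means``          — batch means estimated in a pseudopopulation
   re-weighted by stabilized inverse-probability-of-batch weights, letting
   covariate-biomarker associations differ between batches.
5. ``quantile_reg``       — location-scale correction from batch-specific
   quartiles estimated by quantile regression (unadjusted quartiles give
   the offset/scale; covariate-adjusted quartiles decide how much of the
   difference to remove).
6. ``quantile_norm``      — classic quantile normalization: within-batch
   ranks are kept and rank values are replaced by the cross-batch mean of
   the corresponding quantiles, so all batches share one distribution.
7. ``combat``             — empirical-Bayes location/scale adjustment
   pooling information across markers measured on the same batches
   (parametric normal / inverse-gamma priors).

Methods 2-4 equalize means only; 5-7 also address between-batch variance
differences.  All methods preserve the input row keys and, for the
rank-preserving methods (2, 3, 4, 6), within-batch rank order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .datamodel import BiomarkerTable, CovariateTable
from .errors import DesignError, EstimationError

CONTINUOUS_COVARIATES = {"diagnosis_year"}


@dataclass
class CorrectionResult:
    """Corrected values plus per-batch effect estimates and diagnostics."""

    method: str
    values: BiomarkerTable
    batch_effects: pd.DataFrame      # per (marker, batch): location, scale where applicable
    covariates_used: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def _merge_covariates(sub: pd.DataFrame, cov: CovariateTable, covariates) -> pd.DataFrame:
    merged = sub.merge(cov.df[["tumor_id", *covariates]], on="tumor_id", how="left", validate="m:1")
    missing = merged[list(covariates)].isna().any(axis=1)
    if missing.any():
        raise DesignError(
            f"{int(missing.sum())} rows lack covariate values; "
            "every tumor must appear in the covariate table"
        )
    return merged


def _covariate_formula(covariates) -> str:
    terms = []
    for c in covariates:
        terms.append(c if c in CONTINUOUS_COVARIATES else f"C({c})")
    return " + ".join(terms)


def _centered_effects(batch_means: pd.Series, weights: pd.Series) -> pd.Series:
    """Express per-batch locations as deviations from their weighted pooled mean."""
    w = weights / weights.sum()
    return batch_means - (batch_means * w).sum()


def _result(method, bm, sub, corrected, effects, covariates=None, diagnostics=None):
    out = sub.copy()
    out["value"] = np.asarray(corrected, dtype=float)
    keep = [c for c in out.columns if c in bm.df.columns]
    values = BiomarkerTable(out[keep].reset_index(drop=True), bm.value_scale)
    return CorrectionResult(
        method=method,
        values=values,
        batch_effects=effects,
        covariates_used=list(covariates or []),
        diagnostics=diagnostics or {},
    )


def correct_uncorrected(bm: BiomarkerTable, marker) -> CorrectionResult:
    """Approach 1: no correction (baseline for comparisons)."""
    sub = bm.subset_marker(marker)
    effects = pd.DataFrame(
        {"marker_id": marker, "batch_id": sorted(sub["batch_id"].unique()), "location": 0.0}
    )
    return _result("uncorrected", bm, sub, sub["value"].to_numpy(), effects)


def correct_simple_means(bm: BiomarkerTable, marker) -> CorrectionResult:
    """Approach 2: subtract batch mean deviations from the overall mean."""
    sub = bm.subset_marker(marker)
    batch_means = sub.groupby("batch_id")["value"].mean()
    counts = sub.groupby("batch_id")["value"].count()
    effects = _centered_effects(batch_means, counts.astype(float))
    corrected = sub["value"].to_numpy() - sub["batch_id"].map(effects).to_numpy()
    eff = effects.rename("location").reset_index()
    eff.insert(0, "marker_id", marker)
    return _result("simple_means", bm, sub, corrected, eff)


def correct_standardized_means(
    bm: BiomarkerTable, cov: CovariateTable, marker, covariates
) -> CorrectionResult:
    """Approach 3: batch effects from a covariate-adjusted linear model.

    Fits ``value ~ batch + covariates`` by OLS and subtracts the centered
    batch coefficients, so between-batch differences explained by the
    covariates are retained.  With an empty covariate list this reduces
    exactly to :func:`correct_simple_means`.
    """
    covariates = list(covariates)
    if not covariates:
        res = correct_simple_means(bm, marker)
        return CorrectionResult(
            "standardized_means", res.values, res.batch_effects, [], res.diagnostics
        )
    sub = bm.subset_marker(marker)
    merged = _merge_covariates(sub, cov, covariates)
    formula = "value ~ C(batch_id) + " + _covariate_formula(covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols(formula, data=merged).fit()
    if fit.df_model + 1 > np.linalg.matrix_rank(fit.model.exog):
        warnings.warn("rank-deficient design; aliased terms dropped by pinv")
    batches = sorted(merged["batch_id"].unique())
    coef = pd.Series(0.0, index=batches)
    for b in batches:
        name = f"C(batch_id)[T.{b}]"
        if name in fit.params.index:
            coef[b] = fit.params[name]
    counts = merged.groupby("batch_id")["value"].count().reindex(batches)
    effects = _centered_effects(coef, counts.astype(float))
    corrected = merged["value"].to_numpy() - merged["batch_id"].map(effects).to_numpy()
    eff = effects.rename("location").reset_index().rename(columns={"index": "batch_id"})
    eff.insert(0, "marker_id", marker)
    return _result("standardized_means", bm, sub, corrected, eff, covariates)


def _stabilized_weights(merged: pd.DataFrame, covariates, truncation):
    """P(batch) / P(batch | covariates) per row, from multinomial regression."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    X_parts = []
    for c in covariates:
        if c in CONTINUOUS_COVARIATES:
            X_parts.append(merged[[c]].to_numpy(dtype=float))
        else:
            X_parts.append(pd.get_dummies(merged[c], drop_first=True).to_numpy(dtype=float))
    X = np.hstack(X_parts)
    X = StandardScaler().fit_transform(X)
    y, batches = pd.factorize(merged["batch_id"], sort=True)
    clf = LogisticRegression(C=np.inf, tol=1e-10, max_iter=10000)
    clf.fit(X, y)
    p_cond = clf.predict_proba(X)[np.arange(len(y)), y]
    if (p_cond <= 0).any() or not np.isfinite(p_cond).all():
        raise EstimationError(
            "degenerate batch-membership probabilities (perfect separation?); "
            "consider coarsening covariates"
        )
    p_marg = np.bincount(y, minlength=len(batches)) / len(y)
    w = p_marg[y] / p_cond
    lo_pct, hi_pct = truncation
    lo, hi = np.percentile(w, [lo_pct, hi_pct])
    return np.clip(w, lo, hi), w


def correct_ipw_means(
    bm: BiomarkerTable,
    cov: CovariateTable,
    marker,
    covariates,
    truncation: tuple[float, float] = (2.5, 97.5),
) -> CorrectionResult:
    """Approach 4: batch means in an IPW pseudopopulation.

    Stabilized weights P(batch)/P(batch|C) from a multinomial logistic
    model of batch membership, truncated at the given percentiles of the
    weight distribution, feed a weighted linear model for batch means; the
    centered weighted means are subtracted as in approaches 2-3.
    """
    covariates = list(covariates)
    sub = bm.subset_marker(marker)
    if not covariates:
        res = correct_simple_means(bm, marker)
        return CorrectionResult("ipw_means", res.values, res.batch_effects, [], res.diagnostics)
    merged = _merge_covariates(sub, cov, covariates)
    w, w_raw = _stabilized_weights(merged, covariates, truncation)
    grp = pd.DataFrame({"batch_id": merged["batch_id"], "w": w, "wy": w * merged["value"]})
    agg = grp.groupby("batch_id").sum()
    weighted_means = agg["wy"] / agg["w"]
    effects = _centered_effects(weighted_means, agg["w"])
    corrected = merged["value"].to_numpy() - merged["batch_id"].map(effects).to_numpy()
    eff = effects.rename("location").reset_index()
    eff.insert(0, "marker_id", marker)
    diag = {"weights": w, "weights_untruncated": w_raw}
    return _result("ipw_means", bm, sub, corrected, eff, covariates, diag)


def correct_quantile_reg(
    bm: BiomarkerTable,
    cov: CovariateTable,
    marker,
    covariates=(),
    quantiles: tuple[float, float] = (0.25, 0.75),
    min_batch_size: int = 10,
) -> CorrectionResult:
    """Approach 5: location-scale correction from batch-specific quartiles.

    Quantile regressions with batch indicators (unadjusted, and adjusted
    for covariates) estimate each batch's lower/upper quartile.  Each value
    is offset by its batch's lower-quartile terms and rescaled by the ratio
    of the overall interquartile range to the batch's covariate-adjusted
    IQR:

        y* = (y - q_lo_j) * (Q_hi - Q_lo) / (q*_hi_j - q*_lo_j)
             + Q_lo - q*_lo_j + q_lo_j

    with q_j the unadjusted batch quantiles, q*_j the adjusted ones, and Q
    the overall sample quantiles.  Covariate-attributable quantile
    differences are thereby retained.
    """
    covariates = list(covariates)
    tau_lo, tau_hi = quantiles
    sub = bm.subset_marker(marker)
    counts = sub.groupby("batch_id")["value"].count()
    small = counts[counts < min_batch_size]
    if len(small):
        raise DesignError(
            f"batch(es) below the minimum size {min_batch_size} for quartile "
            f"estimation: {list(small.index)}"
        )
    merged = _merge_covariates(sub, cov, covariates) if covariates else sub.copy()
    batches = sorted(merged["batch_id"].unique())

    def batch_quantiles(formula: str) -> dict[float, pd.Series]:
        out = {}
        base = merged.drop_duplicates("batch_id").copy()
        for c in covariates:
            if c in CONTINUOUS_COVARIATES:
                base[c] = merged[c].mean()
            else:
                base[c] = merged[c].mode().iloc[0]
        for tau in (tau_lo, tau_hi):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.quantreg(formula, data=merged).fit(q=tau)
                pred = fit.predict(base)
            out[tau] = pd.Series(pred.to_numpy(), index=base["batch_id"]).reindex(batches)
        return out

    q_unadj = batch_quantiles("value ~ C(batch_id)")
    if covariates:
        q_adj = batch_quantiles("value ~ C(batch_id) + " + _covariate_formula(covariates))
    else:
        q_adj = q_unadj
    overall_lo, overall_hi = np.quantile(merged["value"], [tau_lo, tau_hi])
    iqr_adj = q_adj[tau_hi] - q_adj[tau_lo]
    floor = max(1e-8, 1e-6 * abs(overall_hi - overall_lo))
    bad = iqr_adj[iqr_adj <= floor]
    if len(bad):
        raise DesignError(f"degenerate adjusted IQR in batch(es): {list(bad.index)}")
    scale = (overall_hi - overall_lo) / iqr_adj

    b = merged["batch_id"]
    corrected = (
        (merged["value"].to_numpy() - b.map(q_unadj[tau_lo]).to_numpy())
        * b.map(scale).to_numpy()
        + overall_lo
        - b.map(q_adj[tau_lo]).to_numpy()
        + b.map(q_unadj[tau_lo]).to_numpy()
    )
    eff = pd.DataFrame(
        {
            "marker_id": marker,
            "batch_id": batches,
            "q_low_unadjusted": q_unadj[tau_lo].to_numpy(),
            "q_high_unadjusted": q_unadj[tau_hi].to_numpy(),
            "q_low_adjusted": q_adj[tau_lo].to_numpy(),
            "q_high_adjusted": q_adj[tau_hi].to_numpy(),
            "scale": scale.to_numpy(),
        }
    )
    diag = {"overall_quantiles": (float(overall_lo), float(overall_hi))}
    return _result("quantile_reg", bm, sub, corrected, eff, covariates, diag)


def correct_quantile_norm(bm: BiomarkerTable, marker) -> CorrectionResult:
    """Approach 6: quantile normalization across batches.

    Each value is mapped to its within-batch quantile position (ties
    averaged) and replaced by the mean, across batches, of the batch
    quantile functions at that position.  All batches end up with the same
    empirical distribution (up to interpolation for unequal batch sizes)
    while within-batch ranks are untouched.
    """
    from scipy.stats import rankdata

    sub = bm.subset_marker(marker)
    batches = sorted(sub["batch_id"].unique())
    if len(batches) < 2:
        raise DesignError("quantile normalization needs >= 2 batches")
    values_by_batch = {b: sub.loc[sub["batch_id"] == b, "value"].to_numpy() for b in batches}
    singletons = [b for b, v in values_by_batch.items() if len(v) == 1]
    if singletons:
        warnings.warn(f"single-observation batch(es) mapped to the median: {singletons}")

    positions = np.empty(len(sub))
    for b in batches:
        mask = (sub["batch_id"] == b).to_numpy()
        v = sub.loc[mask, "value"].to_numpy()
        n = len(v)
        positions[mask] = 0.5 if n == 1 else (rankdata(v, method="average") - 1) / (n - 1)

    uniq = np.unique(positions)
    ref = np.zeros_like(uniq)
    for v in values_by_batch.values():
        ref += np.quantile(v, uniq)
    ref /= len(batches)
    corrected = ref[np.searchsorted(uniq, positions)]

    eff = pd.DataFrame(
        {
            "marker_id": marker,
            "batch_id": batches,
            "location": [v.mean() - sub["value"].mean() for v in values_by_batch.values()],
            "scale": [
                v.std(ddof=1) / sub["value"].std(ddof=1) if len(v) > 1 else np.nan
                for v in values_by_batch.values()
            ],
        }
    )
    return _result("quantile_norm", bm, sub, corrected, eff)


# ---------------------------------------------------------------------------
# Approach 7: ComBat (parametric empirical Bayes), pooling across markers.
# ---------------------------------------------------------------------------


def _combat_fit_group(Y: np.ndarray, batch_idx: np.ndarray, X_cov: np.ndarray | None,
                      adjust_variance: bool, conv: float = 1e-6):
    """Parametric ComBat on a complete markers x samples matrix.

    Returns corrected matrix.  Y: (G markers, N samples); batch_idx in
    0..J-1; X_cov: (N, p) covariate design (no intercept) or None.
    """
    G, N = Y.shape
    J = batch_idx.max() + 1
    n_j = np.bincount(batch_idx, minlength=J).astype(float)
    B = np.zeros((N, J))
    B[np.arange(N), batch_idx] = 1.0
    X = B if X_cov is None else np.hstack([B, X_cov])

    theta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)   # (J+p, G)
    gamma_hat0 = theta[:J]                            # initial batch means
    alpha = (n_j / N) @ gamma_hat0                    # grand mean per marker (G,)
    cov_part = np.zeros((N, G)) if X_cov is None else X_cov @ theta[J:]
    resid = Y.T - X @ theta
    sigma2 = (resid**2).sum(axis=0) / N               # pooled variance per marker
    sigma = np.sqrt(sigma2)
    Z = (Y.T - alpha - cov_part) / sigma              # (N, G) standardized

    gamma_hat = np.vstack([Z[batch_idx == j].mean(axis=0) for j in range(J)])   # (J, G)
    delta_hat = np.vstack(
        [
            Z[batch_idx == j].var(axis=0, ddof=1) if n_j[j] > 1 else np.ones(G)
            for j in range(J)
        ]
    )
    if (n_j == 1).any():
        warnings.warn("batch with a single sample: scale estimate shrunk fully to the prior")

    gamma_bar = gamma_hat.mean(axis=1)                # per batch
    tau2 = gamma_hat.var(axis=1, ddof=1)
    V = delta_hat.mean(axis=1)
    S2 = delta_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (V**2 + 2 * S2) / S2                    # inverse-gamma shape
        theta_p = (V**3 + V * S2) / S2                # inverse-gamma scale

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for j in range(J):
        g_new = gamma_hat[j].copy()
        d_new = delta_hat[j].copy()
        Zj = Z[batch_idx == j]
        n = n_j[j]
        for _ in range(200):
            g_old, d_old = g_new, d_new
            g_new = (n * tau2[j] * gamma_hat[j] + d_old * gamma_bar[j]) / (
                n * tau2[j] + d_old
            )
            ssq = ((Zj - g_new) ** 2).sum(axis=0)
            d_new = (theta_p[j] + 0.5 * ssq) / (n / 2.0 + lam[j] - 1.0)
            change = max(
                np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
                np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
            )
            if change < conv:
                break
        gamma_star[j] = g_new
        delta_star[j] = d_new

    Zc = Z - gamma_star[batch_idx]
    if adjust_variance:
        Zc = Zc / np.sqrt(delta_star[batch_idx])
    Yc = Zc * sigma + alpha + cov_part
    effects = {"gamma_star": gamma_star, "delta_star": delta_star, "alpha": alpha}
    return Yc.T, effects


def correct_combat(
    bm: BiomarkerTable,
    cov: CovariateTable | None,
    markers=None,
    covariates=(),
    adjust_variance: bool = True,
) -> CorrectionResult:
    """Approach 7: empirical-Bayes (ComBat) location/scale batch adjustment.

    Markers are partitioned by the set of batches on which they were
    measured (markers missing on whole batches cannot share one run) and
    each group is adjusted jointly: per-marker standardization with
    covariate adjustment, per-batch location/scale estimates, parametric
    empirical-Bayes shrinkage across markers (normal prior for locations,
    inverse-gamma for scales), then back-transformation.  Requires >= 2
    markers per group, since shrinkage pools across markers.
    """
    covariates = list(covariates)
    markers = list(markers) if markers is not None else bm.markers
    if len(markers) < 2:
        raise DesignError(
            "ComBat pools information across markers; need >= 2 markers "
            "measured on the same batches"
        )
    df = bm.df[bm.df["marker_id"].isin(markers)].copy()

    coverage = df.groupby("marker_id")["batch_id"].agg(lambda s: frozenset(s))
    groups: dict[frozenset, list] = {}
    for m, batches in coverage.items():
        groups.setdefault(batches, []).append(m)

    corrected_frames = []
    all_effects = []
    for batches, group_markers in groups.items():
        if len(group_markers) < 2:
            raise DesignError(
                f"marker group {sorted(group_markers)} (batches {sorted(batches)}) has "
                "< 2 markers; ComBat cannot shrink across a single marker"
            )
        gdf = df[df["marker_id"].isin(group_markers)]
        wide = gdf.pivot_table(
            index=["tumor_id", "core_id", "batch_id"], columns="marker_id", values="value"
        )
        complete = wide.dropna()
        if len(complete) < len(wide):
            warnings.warn(
                f"{len(wide) - len(complete)} samples missing some markers; "
                "EB parameters estimated on complete samples, correction applied to all"
            )
        batch_codes = sorted({b for (_, _, b) in complete.index})
        code_of = {b: j for j, b in enumerate(batch_codes)}
        batch_idx = np.array([code_of[b] for (_, _, b) in complete.index])

        X_cov = None
        if covariates:
            if cov is None:
                raise DesignError("covariates requested but no covariate table given")
            meta = complete.index.to_frame(index=False).merge(
                cov.df[["tumor_id", *covariates]], on="tumor_id", how="left", validate="m:1"
            )
            parts = []
            for c in covariates:
                if c in CONTINUOUS_COVARIATES:
                    col = meta[c].to_numpy(dtype=float)
                    parts.append((col - col.mean())[:, None])
                else:
                    parts.append(pd.get_dummies(meta[c], drop_first=True).to_numpy(dtype=float))
            X_cov = np.hstack(parts)

        Y = complete.to_numpy().T  # markers x samples
        marker_order = list(complete.columns)
        Yc, eff = _combat_fit_group(Y, batch_idx, X_cov, adjust_variance)
        out = pd.DataFrame(
            Yc.T, index=complete.index, columns=pd.Index(marker_order, name="marker_id")
        )
        long = out.stack().rename("value").reset_index()
        corrected_frames.append(long)
        for j, b in enumerate(batch_codes):
            for gi, m in enumerate(marker_order):
                all_effects.append(
                    {
                        "marker_id": m,
                        "batch_id": b,
                        "location": eff["gamma_star"][j, gi],
                        "scale": np.sqrt(eff["delta_star"][j, gi]),
                    }
                )

    corrected = pd.concat(corrected_frames, ignore_index=True)
    merged = df.merge(
        corrected,
        on=["tumor_id", "core_id", "batch_id", "marker_id"],
        how="left",
        suffixes=("", "_corrected"),
    )
    # rows excluded from a complete-case fit keep their original value
    new_values = merged["value_corrected"].fillna(merged["value"])
    out_df = df.copy()
    out_df["value"] = new_values.to_numpy()
    values = BiomarkerTable(out_df.reset_index(drop=True), bm.value_scale)
    return CorrectionResult(
        method="combat",
        values=values,
        batch_effects=pd.DataFrame(all_effects),
        covariates_used=covariates,
        diagnostics={"adjust_variance": adjust_variance, "n_groups": len(groups)},
    )


#: Numbered registry used by the CLI and the plasmode engine.
METHODS = {
    1: "uncorrected",
    2: "simple_means",
    3: "standardized_means",
    4: "ipw_means",
    5: "quantile_reg",
    6: "quantile_norm",
    7: "combat",
}


def apply_method(
    number: int,
    bm: BiomarkerTable,
    cov: CovariateTable | None,
    marker,
    covariates=(),
    **kwargs,
) -> CorrectionResult:
    """Dispatch a correction by its conventional number (1-7)."""
    if number == 1:
        return correct_uncorrected(bm, marker)
    if number == 2:
        return correct_simple_means(bm, marker)
    if number == 3:
        return correct_standardized_means(bm, cov, marker, covariates)
    if number == 4:
        return correct_ipw_means(bm, cov, marker, covariates, **kwargs)
    if number == 5:
        return correct_quantile_reg(bm, cov, marker, covariates, **kwargs)
    if number == 6:
        return correct_quantile_norm(bm, marker)
    if number == 7:
        return correct_combat(bm, cov, covariates=covariates, **kwargs)
    raise DesignError(f"unknown correction method {number}")
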