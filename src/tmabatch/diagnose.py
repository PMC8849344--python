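"""Quantify and characterize between-batch variation.

The central quantity is the intraclass correlation coefficient (ICC): the
share of total biomarker variance attributable to the batch (TMA slide),
estimated from random-effects linear mixed models fit by REML.

* One-way model  Y_ij  = b0 + r_j + e_ij          (r_j: batch effect)
  ICC = var(r) / (var(r) + var(e))
* Two-way model  Y_ijk = b0 + r_j + s_i + e_ijk   (s_i: tumor effect),
  identifiable only when some tumors contribute cores to >= 2 batches;
  ICC = var(r) / (var(r) + var(s) + var(e)).

Confidence intervals come from a parametric bootstrap (simulate from the
fitted model, refit, percentile interval); a permutation null for the ICC
(shuffling tumors across batches, cores moving with their tumor) calibrates
how large an ICC chance alone produces.  The module also provides per-batch
location/scale summaries, a multiplicative effect-modification test, a PCA
embedding of the marker panel, and cross-method correlation of corrected
values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import BiomarkerTable, CovariateTable, gleason_score
from .errors import AlignmentError, DesignError
from .correct import CorrectionResult  # for method_correlation typing

__all__ = [
    "ICCResult",
    "BatchSummary",
    "EffectModificationResult",
    "icc_one_way",
    "icc_two_way",
    "icc_bootstrap_ci",
    "icc_permutation_null",
    "batch_summaries",
    "effect_modification_test",
    "pca_embedding",
    "method_correlation",
]


@dataclass
class ICCResult:
    marker_id: str
    grouping: str                      # "batch", "gleason", or "batch_within_tumor"
    var_between: float
    var_residual: float
    icc: float
    var_tumor: float | None = None     # two-way model only
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_bootstrap: int = 0
    converged: bool = True
    ci_reliable: bool = True
    beta0: float = 0.0
    groups: np.ndarray | None = field(default=None, repr=False)
    tumors: np.ndarray | None = field(default=None, repr=False)

    @property
    def total_variance(self) -> float:
        return self.var_between + (self.var_tumor or 0.0) + self.var_residual


def _fit_one_way(y: np.ndarray, groups: np.ndarray):
    """REML one-way random-intercept fit; returns (beta0, var_r, var_e, ok)."""
    ok = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, np.ones((len(y), 1)), groups=groups)
            res = model.fit(reml=True)
            var_r = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
            var_e = max(float(res.scale), 0.0)
            beta0 = float(np.asarray(res.params)[0])
            ok = bool(res.converged)
        except Exception:
            # boundary fit: fall back to the ANOVA decomposition
            beta0, var_r, var_e = _anova_one_way(y, groups)
            ok = False
    return beta0, var_r, var_e, ok


def _anova_one_way(y: np.ndarray, groups: np.ndarray):
    """Method-of-moments (one-way ANOVA) variance components, truncated at 0."""
    df = pd.DataFrame({"y": y, "g": groups})
    ns = df.groupby("g")["y"].count().to_numpy(dtype=float)
    means = df.groupby("g")["y"].mean().to_numpy()
    grand = y.mean()
    k, n = len(ns), len(y)
    msw = ((df["y"] - df.groupby("g")["y"].transform("mean")) ** 2).sum() / (n - k)
    msb = (ns * (means - grand) ** 2).sum() / (k - 1)
    n0 = (n - (ns**2).sum() / n) / (k - 1)
    var_r = max((msb - msw) / n0, 0.0)
    return float(grand), float(var_r), float(msw)


def icc_one_way(
    bm: BiomarkerTable, marker, grouping: str = "batch", groups: pd.Series | None = None
) -> ICCResult:
    """Between-group ICC for one marker from a one-way REML mixed model.

    ``grouping='batch'`` uses the TMA; pass an explicit per-row ``groups``
    series (aligned with the marker's rows) for other factors, e.g. Gleason
    grade group.
    """
    sub = bm.subset_marker(marker)
    g = sub["batch_id"] if groups is None else groups.loc[sub.index]
    counts = g.value_counts()
    if (counts >= 2).sum() < 2:
        raise DesignError(
            f"marker {marker!r}: need >= 2 groups with >= 2 observations for an ICC"
        )
    y = sub["value"].to_numpy(dtype=float)
    beta0, var_r, var_e, ok = _fit_one_way(y, g.to_numpy())
    total = var_r + var_e
    icc = var_r / total if total > 0 else 0.0
    return ICCResult(
        marker_id=marker,
        grouping=grouping,
        var_between=var_r,
        var_residual=var_e,
        icc=icc,
        converged=ok,
        beta0=beta0,
        groups=g.to_numpy(),
        tumors=sub["tumor_id"].to_numpy(),
    )


def _fit_two_way(y: np.ndarray, batch: np.ndarray, tumor: np.ndarray):
    """Crossed random effects via variance components on a single group."""
    df = pd.DataFrame({"value": y, "batch_id": batch, "tumor_id": tumor, "one": 1})
    vcf = {"batch": "0 + C(batch_id)", "tumor": "0 + C(tumor_id)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            "value ~ 1", groups="one", vc_formula=vcf, re_formula="0", data=df
        )
        res = model.fit(reml=True)
    names = model.exog_vc.names
    vcomp = dict(zip(names, np.maximum(res.vcomp, 0.0)))
    return (
        float(res.params.iloc[0]),
        float(vcomp["batch"]),
        float(vcomp["tumor"]),
        max(float(res.scale), 0.0),
        bool(res.converged),
    )


def icc_two_way(bm: BiomarkerTable, marker) -> ICCResult:
    """Batch ICC from the crossed two-way model on cross-batch duplicate cores."""
    sub = bm.subset_marker(marker)
    per_tumor = sub.groupby("tumor_id")["batch_id"].nunique()
    if (per_tumor >= 2).sum() == 0:
        raise DesignError(
            "no tumor appears on >= 2 batches; batch and tumor variance are confounded"
        )
    y = sub["value"].to_numpy(dtype=float)
    beta0, var_r, var_s, var_e, ok = _fit_two_way(
        y, sub["batch_id"].to_numpy(), sub["tumor_id"].to_numpy()
    )
    total = var_r + var_s + var_e
    icc = var_r / total if total > 0 else 0.0
    return ICCResult(
        marker_id=marker,
        grouping="batch_within_tumor",
        var_between=var_r,
        var_tumor=var_s,
        var_residual=var_e,
        icc=icc,
        converged=ok,
        beta0=beta0,
        groups=sub["batch_id"].to_numpy(),
        tumors=sub["tumor_id"].to_numpy(),
    )


def icc_bootstrap_ci(result: ICCResult, n_rep: int = 500, seed: int = 0) -> ICCResult:
    """Parametric-bootstrap percentile 95% CI for an ICC.

    Simulates ``n_rep`` datasets from the fitted variance components on the
    observed design, refits each, and takes the 2.5th/97.5th percentiles.
    Deterministic under a fixed seed.  If more than 20% of refits fail the
    interval is flagged unreliable, as is the degenerate ``n_rep=1`` case.
    """
    if n_rep < 1:
        raise DesignError("n_rep must be >= 1")
    if result.groups is None:
        raise DesignError("result carries no design; refit with icc_one_way/icc_two_way")
    rng = np.random.default_rng(seed)
    groups = np.asarray(result.groups)
    tumors = np.asarray(result.tumors)
    batch_codes, batch_idx = np.unique(groups, return_inverse=True)
    tumor_codes, tumor_idx = np.unique(tumors, return_inverse=True)
    two_way = result.var_tumor is not None

    iccs, failures = [], 0
    for _ in range(n_rep):
        r = rng.normal(0, np.sqrt(result.var_between), len(batch_codes))[batch_idx]
        e = rng.normal(0, np.sqrt(result.var_residual), len(groups))
        y = result.beta0 + r + e
        if two_way:
            y = y + rng.normal(0, np.sqrt(result.var_tumor), len(tumor_codes))[tumor_idx]
        try:
            if two_way:
                _, vr, vs, ve, _ = _fit_two_way(y, groups, tumors)
                tot = vr + vs + ve
            else:
                _, vr, ve, _ = _fit_one_way(y, groups)
                tot = vr + ve
            iccs.append(vr / tot if tot > 0 else 0.0)
        except Exception:
            failures += 1
    reliable = failures <= 0.2 * n_rep and n_rep > 1
    if not iccs:
        return replace(result, n_bootstrap=n_rep, ci_reliable=False)
    lo, hi = np.percentile(iccs, [2.5, 97.5])
    return replace(
        result, ci_low=float(lo), ci_high=float(hi), n_bootstrap=n_rep, ci_reliable=reliable
    )


def icc_permutation_null(
    bm: BiomarkerTable, marker, n_perm: int, seed: int = 0, quantile: float = 97.5
) -> float:
    """Upper quantile of the ICC's permutation null distribution.

    Tumor-to-batch assignments are permuted (all cores of a tumor move
    together, since cores of a tumor share a slide) and the one-way ICC is
    recomputed each time.  Returns the ``quantile``-th percentile of the
    null; an observed ICC above it indicates batch effects beyond chance.
    """
    if n_perm < 1:
        raise DesignError("n_perm must be >= 1")
    sub = bm.subset_marker(marker)
    if sub["batch_id"].nunique() < 2:
        raise DesignError("need >= 2 batches")
    rng = np.random.default_rng(seed)
    tumor_batch = sub.drop_duplicates("tumor_id").set_index("tumor_id")["batch_id"]
    tumor_ids = tumor_batch.index.to_numpy()
    batches = tumor_batch.to_numpy().copy()
    y = sub["value"].to_numpy(dtype=float)
    tumor_of_row = sub["tumor_id"].to_numpy()
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(batches)
        lookup = dict(zip(tumor_ids, perm))
        g = np.array([lookup[t] for t in tumor_of_row])
        _, vr, ve, _ = _fit_one_way(y, g)
        null[p] = vr / (vr + ve) if vr + ve > 0 else 0.0
    return float(np.percentile(null, quantile))


@dataclass
class BatchSummary:
    marker_id: str
    table: pd.DataFrame  # per batch: n, mean, variance, mean_diff, var_ratio


def batch_summaries(bm: BiomarkerTable, marker, reference: str = "overall") -> BatchSummary:
    """Per-batch mean/variance with differences and ratios vs a reference.

    ``reference='overall'`` compares each batch to the pooled mean/variance;
    passing a batch id compares to that batch (e.g. the first TMA).
    Batches with fewer than two observations are omitted.
    """
    sub = bm.subset_marker(marker)
    grp = sub.groupby("batch_id")["value"]
    tab = grp.agg(n="count", mean="mean", variance=lambda v: v.var(ddof=1))
    tab = tab[tab["n"] >= 2]
    if reference == "overall":
        ref_mean = sub["value"].mean()
        ref_var = sub["value"].var(ddof=1)
    else:
        if reference not in tab.index:
            raise DesignError(f"reference batch {reference!r} not present")
        ref_mean = tab.loc[reference, "mean"]
        ref_var = tab.loc[reference, "variance"]
    tab["mean_diff"] = tab["mean"] - ref_mean
    tab["var_ratio"] = tab["variance"] / ref_var
    return BatchSummary(marker_id=marker, table=tab.reset_index())


@dataclass
class EffectModificationResult:
    marker_id: str
    feature: str
    beta3: float
    se3: float
    p3: float


def effect_modification_test(
    bm: BiomarkerTable, cov: CovariateTable, marker, feature: str
) -> EffectModificationResult:
    """Test whether batch shifts scale with a clinical feature.

    Within-batch z-scores Z_ij are regressed on the feature A_i, the batch
    mean B_j of the raw values, and their product, with a batch random
    intercept; the interaction coefficient (with its normal-approximation
    p-value) measures multiplicative effect modification: whether tumors
    with particular grade/stage/era are differentially affected by
    high-mean batches.
    """
    sub = bm.subset_marker(marker)
    per_tumor = sub.groupby(["tumor_id", "batch_id"], as_index=False)["value"].mean()
    covdf = cov.df.set_index("tumor_id")
    if feature == "gleason_group":
        a = gleason_score(covdf["gleason_group"])
    elif feature == "stage_category":
        from .datamodel import STAGE_LEVELS

        a = covdf["stage_category"].map({s: i + 1 for i, s in enumerate(STAGE_LEVELS)})
    elif feature == "diagnosis_year":
        a = covdf["diagnosis_year"].astype(float)
    else:
        raise DesignError(f"unsupported feature {feature!r}")
    per_tumor["A"] = per_tumor["tumor_id"].map(a)
    if per_tumor["A"].nunique() < 2:
        raise DesignError(f"feature {feature!r} is constant")
    if per_tumor["batch_id"].nunique() < 2:
        raise DesignError("single batch: batch mean is constant")

    stats = per_tumor.groupby("batch_id")["value"].agg(["mean", "std"])
    degenerate = stats.index[(stats["std"] == 0) | stats["std"].isna()]
    if len(degenerate):
        warnings.warn(f"excluding zero-SD batch(es): {list(degenerate)}")
        per_tumor = per_tumor[~per_tumor["batch_id"].isin(degenerate)]
        stats = stats.drop(index=degenerate)
    per_tumor["B"] = per_tumor["batch_id"].map(stats["mean"])
    per_tumor["Z"] = (per_tumor["value"] - per_tumor["B"]) / per_tumor["batch_id"].map(
        stats["std"]
    )
    per_tumor["AB"] = per_tumor["A"] * per_tumor["B"]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            "Z ~ A + B + AB", groups="batch_id", data=per_tumor
        )
        res = model.fit(reml=True)
    beta3 = float(res.params["AB"])
    se3 = float(res.bse["AB"])
    from scipy import stats as sps

    p3 = float(2 * sps.norm.sf(abs(beta3 / se3))) if se3 > 0 else float("nan")
    return EffectModificationResult(marker, feature, beta3, se3, p3)


def pca_embedding(
    bm: BiomarkerTable, markers=None, impute: str = "complete"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project tumors onto the first two principal components of the panel.

    Values are aggregated to tumor level, pivoted to a tumors x markers
    matrix, column-standardized, and decomposed.  ``impute='complete'``
    keeps only tumors with every marker; ``impute='mean'`` fills gaps with
    the marker mean.  Returns (scores with tumor_id/batch_id/PC1/PC2,
    explained-variance fractions of the first two components).
    """
    markers = list(markers) if markers is not None else bm.markers
    if len(markers) < 2:
        raise DesignError("PCA needs >= 2 markers")
    sub = bm.df[bm.df["marker_id"].isin(markers)]
    per_tumor = sub.groupby(["tumor_id", "batch_id", "marker_id"])["value"].mean().reset_index()
    wide = per_tumor.pivot_table(index=["tumor_id", "batch_id"], columns="marker_id", values="value")
    if impute == "complete":
        wide = wide.dropna()
    elif impute == "mean":
        wide = wide.fillna(wide.mean())
    else:
        raise DesignError(f"unknown imputation {impute!r}")
    if len(wide) < 3:
        raise DesignError("fewer than 3 complete tumors")
    X = (wide - wide.mean()) / wide.std(ddof=1)
    from sklearn.decomposition import PCA

    pca = PCA(n_components=2)
    scores = pca.fit_transform(X.to_numpy())
    out = wide.index.to_frame(index=False)
    out["PC1"] = scores[:, 0]
    out["PC2"] = scores[:, 1]
    return out, pca.explained_variance_ratio_


def method_correlation(corrections: list[CorrectionResult]) -> pd.DataFrame:
    """Pearson correlation matrix between corrected-value vectors.

    All results must cover the same (tumor, core, marker) keys; rows are
    aligned on that key before correlating.
    """
    if len(corrections) < 2:
        raise DesignError("need >= 2 correction results")
    key = ["tumor_id", "core_id", "marker_id"]
    frames = []
    names = []
    for c in corrections:
        s = c.values.df.set_index(key)["value"].sort_index()
        frames.append(s)
        names.append(c.method)
    idx = frames[0].index
    for s in frames[1:]:
        if not s.index.equals(idx):
            raise AlignmentError("correction results cover different keys")
    mat = np.corrcoef(np.vstack([s.to_numpy() for s in frames]))
    return pd.DataFrame(mat, index=names, columns=names)
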