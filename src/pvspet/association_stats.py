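"""Cohort statistics for the PVS analysis.

Covers the shell-gradient test (repeated-measures ANOVA across penumbra
layers with Bonferroni-corrected paired t-tests), covariate-adjusted
Spearman and linear associations between PVS burden and regional kinetic
means, Benjamini-Hochberg FDR control, blood-biomarker preprocessing
(plate-median normalization and Shapiro-Wilk-driven transforms), PCA
summaries of the biomarker panel, and the joint proportional-odds /
multiple-linear models with PVS burden as the outcome.

Age and sex enter every association as covariates; sex is encoded 0/1
(male = 1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import signed_cube_root

__all__ = [
    "ShellComparison",
    "AssociationResult",
    "shell_gradient_test",
    "partial_spearman",
    "linear_assoc",
    "fdr_adjust",
    "biomarker_preprocess",
    "pca_summary",
    "ordinal_joint_model",
    "joint_linear_model",
    "pvs_association_table",
    "encode_sex",
]

logger = logging.getLogger(__name__)


def encode_sex(sex):
    """Encode sex as 0/1 (male = 1) for model design matrices."""
    s = pd.Series(sex)
    return s.map({"male": 1.0, "female": 0.0, 1: 1.0, 0: 0.0}).to_numpy()


# ---------------------------------------------------------------------------
# Shell gradient
# ---------------------------------------------------------------------------

@dataclass
class ShellComparison:
    """Repeated-measures ANOVA across penumbra layers plus all pairwise
    paired t-tests with Bonferroni correction."""

    anova_f: float
    anova_p: float
    df_effect: int
    df_error: int
    n_subjects: int
    pairwise: pd.DataFrame  # layer_a, layer_b, t, p_raw, p_bonferroni


def shell_gradient_test(layer_means: pd.DataFrame, value_col="value",
                        subject_col="subject", layer_col="layer"
                        ) -> ShellComparison:
    """Compare per-subject layer means across the PVS layer and its shells.

    One-way repeated-measures ANOVA (subjects as blocks): with subject i and
    layer j, F = MS_layer / MS_error where SS_error is the residual after
    removing subject and layer main effects. Subjects missing any layer are
    dropped (logged). All layer pairs are then compared by paired t-tests
    with the Bonferroni multiplier equal to the number of pairs.
    """
    wide = layer_means.pivot_table(index=subject_col, columns=layer_col,
                                   values=value_col)
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.info("shell_gradient_test: dropped %d subject(s) with "
                    "incomplete layers", dropped)
    n, k = complete.shape
    if n < 3:
        raise ValueError("need at least 3 subjects with complete layers")
    X = complete.to_numpy(dtype=float)
    grand = X.mean()
    ss_subject = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_layer = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_error = ss_total - ss_subject - ss_layer
    df_effect = k - 1
    df_error = (n - 1) * (k - 1)
    ms_layer = ss_layer / df_effect
    ms_error = ss_error / df_error
    scale = max(ss_total, 1.0)
    if ms_error > 1e-14 * scale:
        f = ms_layer / ms_error
    else:  # degenerate: no within-subject variability across layers
        f = 0.0 if ms_layer <= 1e-14 * scale else np.inf
    p = float(stats.f.sf(f, df_effect, df_error))

    pairs = list(itertools.combinations(complete.columns, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        t, p_raw = stats.ttest_rel(complete[a], complete[b])
        rows.append({"layer_a": a, "layer_b": b, "t": float(t),
                     "p_raw": float(p_raw),
                     "p_bonferroni": min(1.0, m * float(p_raw))})
    return ShellComparison(float(f), p, df_effect, df_error, n,
                           pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Covariate-adjusted associations
# ---------------------------------------------------------------------------

def _residualize(v, covariates):
    """Residual of v after OLS on covariates (with intercept)."""
    Z = np.column_stack([np.ones(len(v)), covariates])
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_spearman(x, y, covariates=None):
    """Spearman correlation of x and y adjusted for covariates.

    All variables (x, y and every covariate) are rank-transformed, x and y
    are residualized on the ranked covariates by OLS, and the Pearson
    correlation of the residuals is reported with a t-approximation p-value
    on n - 2 - #covariates degrees of freedom. Ranking the covariates too is
    what removes monotone (not merely linear) confounding; with no
    covariates this reduces to the classical Spearman rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    k = covariates.shape[1]
    if n < k + 3:
        raise ValueError(f"n={n} too small for {k} covariates")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant variable after rank transform")
    rcov = np.column_stack([stats.rankdata(covariates[:, j])
                            for j in range(k)]) if k else covariates
    ex = _residualize(rx, rcov)
    ey = _residualize(ry, rcov)
    denom = np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
    if denom == 0:
        raise ValueError("degenerate residuals")
    rho = float((ex * ey).sum() / denom)
    df = n - 2 - k
    rho_c = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
    t = rho_c * np.sqrt(df / (1.0 - rho_c ** 2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


def linear_assoc(outcome, predictor, covariates=None, names=None):
    """OLS association of an outcome with one predictor, adjusting for
    covariates.

    Returns a dict with the raw coefficient ``beta``, the standardized
    coefficient ``beta_std`` (predictor and outcome scaled to unit SD), its
    p-value and n. Raises on a rank-deficient design.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    n = len(y)
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    X = np.column_stack([x, covariates])
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient design: rank {rank} < {design.shape[1]} columns "
            "(a covariate duplicates the predictor or another covariate)")
    res = sm.OLS(y, design).fit()
    beta = float(res.params[1])
    p = float(res.pvalues[1])
    sd_x, sd_y = x.std(ddof=1), y.std(ddof=1)
    return {
        "beta": beta,
        "beta_std": beta * sd_x / sd_y if sd_y > 0 else np.nan,
        "se": float(res.bse[1]),
        "p": p,
        "n": n,
        "r_squared": float(res.rsquared),
    }


def fdr_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Biomarker panel
# ---------------------------------------------------------------------------

def biomarker_preprocess(panel: pd.DataFrame, plate_ids, alpha=0.05):
    """Plate-median normalization followed by normality transforms.

    Each marker is divided by its per-plate median (batch correction). A
    Shapiro-Wilk test at ``alpha`` then decides the transform: markers that
    pass are left as is; strictly positive non-normal markers get the log,
    the rest the signed cube root. Returns ``(transformed panel, log)``
    where the log records the transform chosen per marker.
    """
    plate_ids = np.asarray(plate_ids)
    if len(plate_ids) != len(panel):
        raise ValueError("plate_ids must match the panel rows")
    counts = pd.Series(plate_ids).value_counts()
    if (counts < 3).any():
        raise ValueError("each plate needs at least 3 subjects")

    out = panel.copy().astype(float)
    for plate in np.unique(plate_ids):
        sel = plate_ids == plate
        med = out.loc[sel].median(axis=0)
        if (med == 0).any():
            zeros = med.index[med == 0].tolist()
            raise ValueError(f"zero plate median for marker(s) {zeros} "
                             f"on plate {plate}")
        out.loc[sel] = out.loc[sel] / med

    log_rows = []
    for marker in out.columns:
        v = out[marker].to_numpy(dtype=float)
        w, p = stats.shapiro(v)
        if p >= alpha:
            transform = "none"
        elif np.all(v > 0):
            transform = "log"
            out[marker] = np.log(v)
        else:
            transform = "cube_root"
            out[marker] = signed_cube_root(v)
        log_rows.append({"marker": marker, "shapiro_w": float(w),
                         "shapiro_p": float(p), "transform": transform})
    return out, pd.DataFrame(log_rows)


def pca_summary(panel: pd.DataFrame, n_components=3):
    """Centered, unit-variance PCA of the biomarker panel.

    Missing values are excluded listwise (logged). Returns a dict with the
    first ``n_components`` component scores, loadings, and the full
    variance-explained fraction vector. Component signs are fixed so the
    loading of largest magnitude is positive, making the output
    deterministic. More markers than subjects is permitted (scores come from
    the SVD) but flagged via the ``n_lt_p`` entry.
    """
    complete = panel.dropna()
    dropped = len(panel) - len(complete)
    if dropped:
        logger.info("pca_summary: %d subject(s) with missing markers "
                    "excluded listwise", dropped)
    X = complete.to_numpy(dtype=float)
    n, p = X.shape
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(vt.shape[0]):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    var = s ** 2 / (n - 1)
    var_ratio = var / var.sum()
    scores = u[:, :n_components] * s[:n_components]
    return {
        "scores": pd.DataFrame(
            scores, index=complete.index,
            columns=[f"PC{j + 1}" for j in range(scores.shape[1])]),
        "loadings": pd.DataFrame(
            vt[:n_components].T, index=panel.columns,
            columns=[f"PC{j + 1}" for j in range(n_components)]),
        "variance_ratio": var_ratio,
        "n_lt_p": n < p,
    }


# ---------------------------------------------------------------------------
# Joint models
# ---------------------------------------------------------------------------

def _design_frame(df, predictors, covariates):
    cols = list(predictors) + list(covariates)
    X = df[cols].copy()
    if "sex" in X.columns:
        X["sex"] = encode_sex(X["sex"])
    X = X.astype(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    if rank < X.shape[1] + 1:
        raise ValueError("rank-deficient design (collinear predictors)")
    return X


def ordinal_joint_model(df: pd.DataFrame, outcome, predictors,
                        covariates=("age", "sex"), fdr_family=None
                        ) -> pd.DataFrame:
    """Proportional-odds cumulative-logit model for an ordinal PVS score.

    Maximum-likelihood fit with predictor-wise Wald z tests; FDR adjustment
    is applied across the predictor rows (or across ``fdr_family`` when the
    caller pools several models into one family). Complete separation is
    reported as an error rather than silent divergence.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    X = _design_frame(df, predictors, covariates)
    y_raw = df[outcome]
    cats = np.sort(pd.unique(y_raw))
    if len(cats) < 2:
        raise ValueError(f"outcome {outcome!r} has a single category")
    y = pd.Series(pd.Categorical(y_raw, categories=cats, ordered=True),
                  index=df.index)

    model = OrderedModel(y, X, distr="logit")
    import warnings

    with np.errstate(over="ignore"), warnings.catch_warnings():
        # convergence is re-checked explicitly below
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=1000, gtol=1e-8, disp=False)
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    if (not res.mle_retvals.get("converged", True)
            or np.any(~np.isfinite(params))
            or np.any(~np.isfinite(bse[: X.shape[1]]))
            or np.any(np.abs(params[: X.shape[1]]) > 50)):
        raise RuntimeError(
            f"cumulative-link fit for {outcome!r} did not converge "
            "(possible complete separation)")

    rows = []
    for j, name in enumerate(X.columns):
        rows.append({
            "outcome": outcome,
            "predictor": name,
            "coef": float(res.params.iloc[j]),
            "se": float(res.bse.iloc[j]),
            "z": float(res.tvalues.iloc[j]),
            "p": float(res.pvalues.iloc[j]),
        })
    table = pd.DataFrame(rows)
    fam = table["predictor"].isin(predictors) if fdr_family is None \
        else table["predictor"].isin(fdr_family)
    fdr = np.full(len(table), np.nan)
    fdr[fam.to_numpy()] = fdr_adjust(table.loc[fam, "p"])
    table["fdr_p"] = fdr
    table["n"] = len(X)
    return table


def joint_linear_model(df: pd.DataFrame, outcome, predictors,
                       covariates=("age", "sex"), fdr_family=None
                       ) -> pd.DataFrame:
    """Multiple linear regression with a PVS volume as the outcome and the
    kinetic means plus biomarker PCs as simultaneous predictors."""
    import statsmodels.api as sm

    X = _design_frame(df, predictors, covariates)
    y = df[outcome].to_numpy(dtype=float)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    rows = []
    for name in X.columns:
        rows.append({
            "outcome": outcome,
            "predictor": name,
            "coef": float(res.params[name]),
            "se": float(res.bse[name]),
            "t": float(res.tvalues[name]),
            "p": float(res.pvalues[name]),
        })
    table = pd.DataFrame(rows)
    fam = table["predictor"].isin(predictors) if fdr_family is None \
        else table["predictor"].isin(fdr_family)
    fdr = np.full(len(table), np.nan)
    fdr[fam.to_numpy()] = fdr_adjust(table.loc[fam, "p"])
    table["fdr_p"] = fdr
    table["n"] = len(X)
    return table


# ---------------------------------------------------------------------------
# Table-style association screen
# ---------------------------------------------------------------------------

PVS_MARKERS = (
    ("wm_pvs_score", "spearman"),
    ("bg_pvs_score", "spearman"),
    ("whole_pvs_volume_cm3", "linear"),
    ("wm_pvs_volume_cm3", "linear"),
    ("bg_pvs_volume_cm3", "linear"),
)


def pvs_association_table(df: pd.DataFrame, modality="mean_bpnd",
                          covariates=("age", "sex")) -> pd.DataFrame:
    """Association of each PVS marker with one regional kinetic mean.

    Visual scores use covariate-adjusted Spearman correlation; volumes
    (brain-volume-normalized, log-transformed) use linear regression with
    the signed-cube-root kinetic mean as the predictor. FDR is applied
    across the five rows of the table — one family per modality, mirroring
    a per-table correction.
    """
    cov = np.column_stack([df["age"].to_numpy(dtype=float),
                           encode_sex(df["sex"])])
    predictor = signed_cube_root(df[modality].to_numpy(dtype=float))
    brain = df["brain_volume_cm3"].to_numpy(dtype=float)
    rows = []
    for marker, method in PVS_MARKERS:
        if method == "spearman":
            rho, p = partial_spearman(
                df[marker].to_numpy(dtype=float), predictor, cov)
            rows.append({"pvs_marker": marker, "method": "partial_spearman",
                         "coefficient": rho, "p": p, "n": len(df)})
        else:
            vol = df[marker].to_numpy(dtype=float)
            ok = vol > 0
            y = np.log(vol[ok] / brain[ok])
            fit = linear_assoc(y, predictor[ok], cov[ok])
            rows.append({"pvs_marker": marker, "method": "linear",
                         "coefficient": fit["beta_std"], "p": fit["p"],
                         "n": fit["n"]})
    table = pd.DataFrame(rows)
    table["fdr_p"] = fdr_adjust(table["p"])
    table.insert(0, "modality", modality)
    return table
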