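"""Statistical comparison of the intervention conditions.

Per-class success rates (one value per class x condition; the random
condition enters as its replicate average) are analysed three ways:

* a linear mixed-effects model with random class intercepts and four
  orthogonal Helmert planned contrasts — (i) interventions vs control,
  (ii) centrality conditions vs random, (iii) betweenness + closeness vs
  in-degree, (iv) closeness vs betweenness — with Satterthwaite-corrected
  degrees of freedom;
* a repeated-measures ANOVA of the condition effect with Mauchly's
  sphericity test and the Huynh-Feldt epsilon correction;
* moderation models adding a standardized class-structure measure (density
  or a centralization) and its interactions with the contrasts;
* a correlation matrix of per-class intervention success rates against the
  structure measures.

The mixed models are fit by REML through statsmodels; the Satterthwaite
approximation is computed here from the fitted variance components (see
:func:`satterthwaite_df`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "CONDITION_ORDER",
    "STRUCTURE_MEASURES",
    "helmert_scheme",
    "satterthwaite_df",
    "fit_condition_model",
    "rm_anova_sphericity",
    "fit_moderation_model",
    "structure_correlations",
    "evaluate",
]

#: condition order used by the contrast scheme
CONDITION_ORDER = ("control", "random", "in_degree", "betweenness", "closeness")
STRUCTURE_MEASURES = (
    "density",
    "centralization_in_degree",
    "centralization_betweenness",
    "centralization_closeness",
)
CONTRAST_NAMES = (
    "interventions_vs_control",
    "centrality_vs_random",
    "betw_clos_vs_indegree",
    "closeness_vs_betweenness",
)


def helmert_scheme() -> pd.DataFrame:
    """The four planned contrasts as weights over the condition means.

    Rows sum to zero and are pairwise orthogonal; each estimate is the
    difference between the two group means it compares.
    """
    c = np.array(
        [
            [-1.0, 1 / 4, 1 / 4, 1 / 4, 1 / 4],
            [0.0, -1.0, 1 / 3, 1 / 3, 1 / 3],
            [0.0, 0.0, -1.0, 1 / 2, 1 / 2],
            [0.0, 0.0, 0.0, -1.0, 1.0],
        ]
    )
    return pd.DataFrame(c, index=list(CONTRAST_NAMES), columns=list(CONDITION_ORDER))


def _contrast_coding(scheme: pd.DataFrame) -> np.ndarray:
    """Coding matrix whose regression coefficients equal the contrasts.

    For contrast rows C (k-1 x k) with zero-sum rows, the design columns
    X = C'(CC')^-1 satisfy beta_j = C_j mu when paired with an intercept.
    """
    c = scheme.to_numpy()
    return c.T @ np.linalg.inv(c @ c.T)


def satterthwaite_df(x: np.ndarray, groups: np.ndarray, sigma2_e: float,
                     sigma2_b: float, contrast: np.ndarray) -> float:
    """Satterthwaite degrees of freedom for a fixed-effect contrast.

    For the random-intercept model y = X beta + Z b + e with
    V = sigma2_e I + sigma2_b Z Z', the df of t = c'beta_hat / se are
    2 g^2 / (grad g' A grad g), where g(theta) = c'(X'V^-1 X)^-1 c and A is
    the inverse REML information of theta = (sigma2_e, sigma2_b).
    """
    x = np.asarray(x, float)
    c = np.asarray(contrast, float)
    n = x.shape[0]
    z = pd.get_dummies(pd.Series(groups)).to_numpy(float)
    zzt = z @ z.T
    v = sigma2_e * np.eye(n) + sigma2_b * zzt
    vinv = np.linalg.inv(v)
    xtvx_inv = np.linalg.inv(x.T @ vinv @ x)
    g = float(c @ xtvx_inv @ c)
    # dg/dtheta_j = c' C X'V^-1 Vj V^-1 X C c  with C = (X'V^-1X)^-1
    grad = np.empty(2)
    for j, vj in enumerate((np.eye(n), zzt)):
        m = xtvx_inv @ (x.T @ vinv @ vj @ vinv @ x) @ xtvx_inv
        grad[j] = float(c @ m @ c)
    p_mat = vinv - vinv @ x @ xtvx_inv @ x.T @ vinv
    info = np.empty((2, 2))
    for j, vj in enumerate((np.eye(n), zzt)):
        for k, vk in enumerate((np.eye(n), zzt)):
            info[j, k] = 0.5 * np.trace(p_mat @ vj @ p_mat @ vk)
    try:
        a = np.linalg.inv(info)
        denom = float(grad @ a @ grad)
    except np.linalg.LinAlgError:
        denom = 0.0
    if denom <= 0:
        return float(n - x.shape[1])
    df = 2.0 * g * g / denom
    return float(min(df, n - x.shape[1]))


@dataclass
class MixedModelFit:
    """Per-contrast (or per-coefficient) summary of a mixed-effects fit."""

    table: pd.DataFrame
    sigma2_e: float
    sigma2_b: float
    converged: bool
    singular: bool


def _fit_mixed(y: np.ndarray, x: np.ndarray, groups: np.ndarray,
               names: list[str], contrasts: np.ndarray) -> MixedModelFit:
    """REML random-intercept fit plus Satterthwaite t-tests of contrasts.

    ``contrasts`` has one row per reported effect, expressed in the basis of
    the fixed-effect columns ``x``.
    """
    model = MixedLM(y, x, groups=groups)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(reml=True, method="lbfgs")
    except (np.linalg.LinAlgError, ValueError):
        # unidentifiable design (e.g. as many parameters as observations):
        # report the singular fit rather than crash
        table = pd.DataFrame(
            [{"effect": n, "estimate": np.nan, "se": np.nan, "df": np.nan,
              "t": np.nan, "p": np.nan} for n in names]
        ).set_index("effect")
        return MixedModelFit(table, np.nan, np.nan, False, True)
    sigma2_e = float(res.scale)
    sigma2_b = float(np.atleast_2d(res.cov_re)[0, 0])
    if not np.isfinite(sigma2_e) or sigma2_e <= 0:
        sigma2_e = max(float(np.var(y)), 1e-12)
    if not np.isfinite(sigma2_b):
        sigma2_b = 0.0
    singular = sigma2_b <= 1e-10 * max(sigma2_e, 1e-30)
    cov = np.asarray(res.cov_params())[: x.shape[1], : x.shape[1]]
    beta = np.asarray(res.fe_params)
    rows = []
    for name, c in zip(names, contrasts):
        est = float(c @ beta)
        var = float(c @ cov @ c)
        se = float(np.sqrt(var)) if var > 0 else np.nan
        try:
            df = satterthwaite_df(x, groups, max(sigma2_e, 1e-12),
                                  max(sigma2_b, 0.0), c)
        except np.linalg.LinAlgError:
            df = float(len(y) - x.shape[1])
        t = est / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        rows.append({"effect": name, "estimate": est, "se": se, "df": df,
                     "t": t, "p": p})
    return MixedModelFit(pd.DataFrame(rows).set_index("effect"),
                         sigma2_e, sigma2_b, bool(res.converged), singular)


def _check_results(results: pd.DataFrame) -> pd.DataFrame:
    missing = set(CONDITION_ORDER) - set(results["condition"])
    if missing:
        raise ValueError(f"conditions missing from results: {sorted(missing)}")
    if results["class_id"].nunique() < 2:
        raise ValueError("need at least 2 classes")
    return results


def fit_condition_model(results: pd.DataFrame,
                        scheme: pd.DataFrame | None = None) -> MixedModelFit:
    """Mixed-effects model of success rate on condition with planned contrasts.

    ``results`` is the long experiment table (class_id, condition,
    success_rate).  Returns per-contrast estimates, Satterthwaite df, t and
    two-sided p; singular fits are flagged, not dropped.
    """
    _check_results(results)
    if scheme is None:
        scheme = helmert_scheme()
    df = results.copy()
    df["condition"] = pd.Categorical(df["condition"], categories=CONDITION_ORDER)
    df = df.sort_values(["class_id", "condition"])
    # cell-means coding: one indicator per condition, no intercept;
    # a contrast of condition means is then the same contrast of coefficients
    x = pd.get_dummies(df["condition"]).to_numpy(float)
    y = df["success_rate"].to_numpy(float)
    groups = df["class_id"].to_numpy()
    return _fit_mixed(y, x, groups, list(scheme.index), scheme.to_numpy())


def rm_anova_sphericity(results: pd.DataFrame) -> dict:
    """Repeated-measures ANOVA of condition with sphericity diagnostics.

    Returns Mauchly's W and p, the Huynh-Feldt epsilon (clamped at 1), and
    the epsilon-corrected F-test of the condition effect.
    """
    _check_results(results)
    if results["condition"].nunique() < 3:
        raise ValueError("sphericity requires at least 3 conditions")
    long = results[["class_id", "condition", "success_rate"]]
    spher = pg.sphericity(long, dv="success_rate", within="condition",
                          subject="class_id")
    eps = float(pg.epsilon(long, dv="success_rate", within="condition",
                           subject="class_id", correction="hf"))
    eps = min(eps, 1.0)
    aov = pg.rm_anova(data=long, dv="success_rate", within="condition",
                      subject="class_id", correction=False)
    f = float(aov.loc[0, "F"])
    df1, df2 = float(aov.loc[0, "ddof1"]), float(aov.loc[0, "ddof2"])
    p_hf = float(stats.f.sf(f, eps * df1, eps * df2))
    return {
        "mauchly_w": float(spher.W),
        "mauchly_p": float(spher.pval),
        "epsilon_hf": eps,
        "F": f,
        "df1": eps * df1,
        "df2": eps * df2,
        "p": p_hf,
    }


def fit_moderation_model(results: pd.DataFrame,
                         moderator: str,
                         structure: pd.DataFrame,
                         scheme: pd.DataFrame | None = None) -> MixedModelFit:
    """Condition model plus a standardized class-structure moderator.

    Adds the moderator's main effect and its interaction with each planned
    contrast.  ``structure`` is the per-class structure table indexed by
    class_id; ``moderator`` is one of its columns.
    """
    _check_results(results)
    if moderator not in STRUCTURE_MEASURES:
        raise ValueError(f"unknown moderator {moderator!r}")
    if scheme is None:
        scheme = helmert_scheme()
    df = results.copy()
    df["condition"] = pd.Categorical(df["condition"], categories=CONDITION_ORDER)
    df = df.sort_values(["class_id", "condition"])
    mod_by_class = structure[moderator]
    if float(mod_by_class.std(ddof=0)) <= 1e-12 * max(1.0, float(mod_by_class.abs().max())):
        raise ValueError(f"moderator {moderator!r} has zero variance")
    z = (mod_by_class - mod_by_class.mean()) / mod_by_class.std(ddof=1)
    mod = df["class_id"].map(z).to_numpy(float)
    coding = _contrast_coding(scheme)  # (5, 4)
    cond_idx = df["condition"].cat.codes.to_numpy()
    xc = coding[cond_idx]  # contrast-coded condition columns
    x = np.column_stack([np.ones(len(df)), xc, mod, mod[:, None] * xc])
    y = df["success_rate"].to_numpy(float)
    groups = df["class_id"].to_numpy()
    names = (list(scheme.index) + [moderator]
             + [f"{moderator}:{c}" for c in scheme.index])
    contrasts = np.vstack([np.eye(10)[1:5], np.eye(10)[5:10]])
    return _fit_mixed(y, x, groups, names, contrasts)


def structure_correlations(results: pd.DataFrame,
                           structure: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations of per-class success rates with class structure.

    Rows are the four structure measures, columns the four intervention
    conditions (control excluded); returns (r, p) frames.
    """
    interventions = [c for c in CONDITION_ORDER if c != "control"]
    wide = results.pivot(index="class_id", columns="condition", values="success_rate")
    r = pd.DataFrame(index=list(STRUCTURE_MEASURES), columns=interventions, dtype=float)
    p = r.copy()
    for s in STRUCTURE_MEASURES:
        sv = structure.loc[wide.index, s].to_numpy(float)
        for cond in interventions:
            y = wide[cond].to_numpy(float)
            if np.std(sv) == 0 or np.std(y) == 0:
                r.loc[s, cond] = p.loc[s, cond] = np.nan
            else:
                rr, pp = stats.pearsonr(sv, y)
                r.loc[s, cond] = rr
                p.loc[s, cond] = pp
    return r, p


def evaluate(results: pd.DataFrame, structure: pd.DataFrame) -> dict:
    """Full evaluation report as a JSON-serialisable dict."""
    contrasts = fit_condition_model(results)
    anova = rm_anova_sphericity(results)
    moderation = {}
    for m in STRUCTURE_MEASURES:
        fit = fit_moderation_model(results, m, structure)
        moderation[m] = {
            "singular": fit.singular,
            "effects": fit.table.reset_index().to_dict(orient="records"),
        }
    r, p = structure_correlations(results, structure)
    cond_means = results.groupby("condition")["success_rate"].mean()
    return {
        "condition_means": cond_means.round(6).to_dict(),
        "planned_contrasts": {
            "singular": contrasts.singular,
            "converged": contrasts.converged,
            "sigma2_residual": contrasts.sigma2_e,
            "sigma2_class": contrasts.sigma2_b,
            "effects": contrasts.table.reset_index().to_dict(orient="records"),
        },
        "rm_anova": anova,
        "moderation": moderation,
        "structure_correlations": {
            "r": r.round(6).to_dict(),
            "p": p.round(6).to_dict(),
        },
    }
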