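"""Multi-site effect sizes, fixed-effects meta-analysis, and cross-disorder
GLMs for salience scores.

Pipeline reproduced here:

* per-site unbiased standardized mean difference (Hedges-corrected d) for
  patients vs controls, from a within-site regression of the score on
  group, age, and sex; the group coefficient is standardized by the
  residual SD, so with no covariates it reduces exactly to the textbook
  two-sample Hedges g;
* inverse-variance fixed-effects pooling of the per-site d's, with a
  normal z test;
* a cross-disorder general linear model (score ~ diagnosis + age + sex +
  site), an F test for the diagnosis main effect, estimated marginal
  means at a reference age of 35.75 years (sex and site averaged over
  their observed distribution, the SPSS EMMEANS convention), and
  Bonferroni-corrected pairwise contrasts among the five groups;
* Bonferroni-corrected Pearson correlation screens against symptom scales
  and medication dose.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices

Z95 = 1.959963984540054


def hedges_correction(df: int | float) -> float:
    """Small-sample bias correction J = 1 - 3 / (4 df - 1)."""
    return 1.0 - 3.0 / (4.0 * df - 1.0)


@dataclass(frozen=True)
class EffectSizeRecord:
    """Within-site unbiased d (patient minus control) with its SE."""

    site: str
    channel: str
    d: float
    se: float
    n_hc: int
    n_patient: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.d):
            raise ValueError("effect size is not finite")
        if self.se <= 0:
            raise ValueError("standard error must be positive")

    @property
    def ci(self) -> tuple[float, float]:
        return self.d - Z95 * self.se, self.d + Z95 * self.se


def _build_design(frame: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    """Intercept + numeric/dummy covariate columns, dropping any covariate
    without variation (e.g. a single-sex site) with a warning."""
    cols = [np.ones(len(frame))]
    names = ["intercept"]
    for cov in covariates:
        series = frame[cov]
        if series.nunique() < 2:
            warnings.warn(f"covariate {cov!r} has no variation here; dropped",
                          stacklevel=3)
            continue
        if series.dtype.kind in "ifu":
            cols.append(series.to_numpy(float))
            names.append(cov)
        else:
            levels = sorted(series.unique())
            for lev in levels[1:]:
                cols.append((series == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
    return np.column_stack(cols), names


def unbiased_d(
    scores: pd.DataFrame,
    score_col: str,
    site: str | None = None,
    groups: tuple[str, str] = ("HC", "SZ"),
    covariates: tuple[str, ...] = ("age", "sex"),
    group_col: str = "diagnosis",
    channel: str | None = None,
) -> EffectSizeRecord:
    """Covariate-adjusted unbiased d for one site.

    Fits ``score ~ group + covariates`` by least squares; d is the group
    coefficient divided by the residual SD, multiplied by the Hedges
    correction at the residual degrees of freedom. The SE uses the
    standard d-variance formula with those covariate-adjusted df.
    """
    frame = scores
    if site is not None:
        frame = frame[frame["site"] == site]
    frame = frame[frame[group_col].isin(groups)]
    n_hc = int((frame[group_col] == groups[0]).sum())
    n_pat = int((frame[group_col] == groups[1]).sum())
    if n_hc < 2 or n_pat < 2:
        raise ValueError(f"need >= 2 subjects per group (got {n_hc}/{n_pat})")
    y = frame[score_col].to_numpy(float)
    X_cov, names = _build_design(frame, covariates)
    g_ind = (frame[group_col] == groups[1]).to_numpy(float)
    X = np.column_stack([X_cov, g_ind])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - rank
    if dof <= 2:
        raise ValueError("not enough residual degrees of freedom")
    s = float(np.sqrt(resid @ resid / dof))
    if s <= 0:
        raise ValueError("zero residual variance; d undefined")
    d_raw = float(beta[-1]) / s
    J = hedges_correction(dof)
    var_d = (n_hc + n_pat) / (n_hc * n_pat) + d_raw**2 / (2 * dof)
    return EffectSizeRecord(
        site=site or "", channel=channel or score_col, d=J * d_raw,
        se=float(J * np.sqrt(var_d)), n_hc=n_hc, n_patient=n_pat,
    )


def per_site_effect_sizes(
    scores: pd.DataFrame, score_col: str, min_per_group: int = 2, **kw
) -> list[EffectSizeRecord]:
    """``unbiased_d`` for every site with enough subjects in both groups."""
    groups = kw.get("groups", ("HC", "SZ"))
    records = []
    for site in sorted(scores["site"].unique()):
        sub = scores[scores["site"] == site]
        counts = sub["diagnosis"].value_counts()
        if min(counts.get(groups[0], 0), counts.get(groups[1], 0)) < max(min_per_group, 2):
            continue
        records.append(unbiased_d(scores, score_col, site=site, **kw))
    return records


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effects (inverse-variance) pooled effect size."""

    channel: str
    d_overall: float
    se_overall: float
    z: float
    p: float
    records: tuple[EffectSizeRecord, ...]
    weights: tuple[float, ...]  # normalized to sum 1


def fixed_effects_meta(records: list[EffectSizeRecord],
                       channel: str | None = None) -> MetaResult:
    """Inverse-variance pooling: d = sum(d_i / se_i^2) / sum(1 / se_i^2),
    se = (sum 1/se_i^2)^(-1/2), two-sided normal p."""
    if not records:
        raise ValueError("meta-analysis needs at least one record")
    if any(r.se <= 0 for r in records):
        raise ValueError("all standard errors must be positive")
    w = np.array([1.0 / r.se**2 for r in records])
    d = np.array([r.d for r in records])
    d_bar = float((w * d).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = d_bar / se
    p = float(2 * sps.norm.sf(abs(z)))
    return MetaResult(
        channel=channel or records[0].channel, d_overall=d_bar, se_overall=se,
        z=float(z), p=p, records=tuple(records),
        weights=tuple(w / w.sum()),
    )


def forest_table(meta: MetaResult) -> pd.DataFrame:
    """Per-site and pooled rows with d, 95% CI, and weight percentages."""
    rows = []
    for rec, w in zip(meta.records, meta.weights):
        lo, hi = rec.ci
        rows.append({"site": rec.site, "d": rec.d, "se": rec.se,
                     "ci_low": lo, "ci_high": hi, "weight_pct": 100 * w,
                     "n_hc": rec.n_hc, "n_patient": rec.n_patient})
    lo = meta.d_overall - Z95 * meta.se_overall
    hi = meta.d_overall + Z95 * meta.se_overall
    rows.append({"site": "pooled", "d": meta.d_overall, "se": meta.se_overall,
                 "ci_low": lo, "ci_high": hi, "weight_pct": 100.0,
                 "n_hc": sum(r.n_hc for r in meta.records),
                 "n_patient": sum(r.n_patient for r in meta.records)})
    return pd.DataFrame(rows)


@dataclass
class GlmResult:
    """Cross-disorder GLM summary for one channel."""

    channel: str
    p_diagnosis: float      # F-test for the diagnosis main effect
    f_diagnosis: float
    emmeans: pd.DataFrame   # diagnosis, emmean, se, ci_low, ci_high, n
    pairwise: pd.DataFrame  # group_a, group_b, estimate, se, t, p_raw, p_bonf
    coefficients: pd.DataFrame
    residual_sd: float
    model: object = field(repr=False, default=None)


def bonferroni(p, n_tests: int):
    """min(1, p * n_tests), elementwise."""
    return np.minimum(1.0, np.asarray(p, float) * n_tests)


def cross_disorder_glm(
    scores: pd.DataFrame,
    score_col: str,
    ref_age: float = 35.75,
    channel: str | None = None,
) -> GlmResult:
    """GLM of a salience score on diagnosis, age, sex, and site.

    Marginal means are model predictions with age fixed at ``ref_age``
    and sex/site averaged over their observed joint distribution; all
    pairwise diagnosis contrasts are Bonferroni-adjusted (x n_pairs).
    """
    frame = scores.dropna(subset=[score_col]).copy()
    diagnoses = [d for d in ("HC", "SZ", "BD", "MDD", "ASD")
                 if d in set(frame["diagnosis"])]
    if len(diagnoses) < 2:
        raise ValueError("need at least two diagnostic groups")
    terms = ["C(diagnosis)", "age"]
    for fac in ("sex", "site"):
        if frame[fac].nunique() >= 2:
            terms.append(f"C({fac})")
        else:
            warnings.warn(f"factor {fac!r} has no variation; dropped", stacklevel=2)
    formula = f"{score_col} ~ " + " + ".join(terms)
    res = smf.ols(formula, data=frame).fit()
    anova = sm.stats.anova_lm(res, typ=2)
    f_val = float(anova.loc["C(diagnosis)", "F"])
    p_diag = float(anova.loc["C(diagnosis)", "PR(>F)"])

    design_info = res.model.data.design_info
    cov = np.asarray(res.cov_params())

    def emm_vector(diag: str) -> np.ndarray:
        mod = frame.copy()
        mod["diagnosis"] = diag
        mod["age"] = ref_age
        (X,) = build_design_matrices([design_info], mod)
        return np.asarray(X).mean(axis=0)

    L = {d: emm_vector(d) for d in diagnoses}
    emm_rows = []
    for d in diagnoses:
        est = float(L[d] @ res.params)
        se = float(np.sqrt(L[d] @ cov @ L[d]))
        emm_rows.append({"diagnosis": d, "emmean": est, "se": se,
                         "ci_low": est - Z95 * se, "ci_high": est + Z95 * se,
                         "n": int((frame["diagnosis"] == d).sum())})
    emmeans = pd.DataFrame(emm_rows)

    pairs = list(itertools.combinations(diagnoses, 2))
    pair_rows = []
    for a, b in pairs:
        contrast = L[a] - L[b]
        tt = res.t_test(contrast)
        pair_rows.append({
            "group_a": a, "group_b": b,
            "estimate": float(np.squeeze(tt.effect)),
            "se": float(np.squeeze(tt.sd)),
            "t": float(np.squeeze(tt.tvalue)),
            "p_raw": float(np.squeeze(tt.pvalue)),
        })
    pairwise = pd.DataFrame(pair_rows)
    pairwise["p_bonf"] = bonferroni(pairwise["p_raw"], len(pairs))

    coefficients = pd.DataFrame({
        "coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues,
    })
    return GlmResult(
        channel=channel or score_col, p_diagnosis=p_diag, f_diagnosis=f_val,
        emmeans=emmeans, pairwise=pairwise, coefficients=coefficients,
        residual_sd=float(np.sqrt(res.mse_resid)), model=res,
    )


def correlation_screen(
    scores: pd.DataFrame,
    score_cols: list[str],
    clinical_cols: list[str],
    subset: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson correlations between salience scores and clinical measures,
    Bonferroni-corrected over every test in the screen.

    Pairs with fewer than 3 complete observations or a zero-variance
    column yield NaN (with a warning) and still count toward the
    correction, mirroring a prespecified screen.
    """
    frame = scores if subset is None else scores[subset]
    n_tests = len(score_cols) * len(clinical_cols)
    rows = []
    for sc in score_cols:
        for cc in clinical_cols:
            pair = frame[[sc, cc]].dropna()
            r = p = np.nan
            if len(pair) < 3:
                warnings.warn(f"{sc} vs {cc}: fewer than 3 paired values",
                              stacklevel=2)
            elif pair[sc].std() == 0 or pair[cc].std() == 0:
                warnings.warn(f"{sc} vs {cc}: zero-variance column", stacklevel=2)
            else:
                r, p = sps.pearsonr(pair[sc], pair[cc])
            rows.append({"score": sc, "clinical": cc, "n": len(pair),
                         "r": r, "p_raw": p,
                         "p_bonf": min(1.0, p * n_tests) if np.isfinite(p) else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------


def forest_plot(meta: MetaResult, path) -> None:
    """Forest plot: per-site squares sized by weight, pooled diamond."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = forest_table(meta)
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(table) + 1.5))
    ys = np.arange(len(table))[::-1]
    for yy, row in zip(ys, table.itertuples()):
        if row.site == "pooled":
            ax.plot([row.ci_low, row.d, row.ci_high, row.d, row.ci_low],
                    [yy, yy + 0.25, yy, yy - 0.25, yy], color="navy")
        else:
            ax.plot([row.ci_low, row.ci_high], [yy, yy], color="k", lw=1)
            ax.plot(row.d, yy, "s", color="k",
                    markersize=4 + 10 * row.weight_pct / 100)
    ax.axvline(0, color="gray", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels(table["site"])
    ax.set_xlabel("standardized effect size (patient - control)")
    ax.set_title(f"{meta.channel}: pooled d = {meta.d_overall:.2f} "
                 f"+/- {meta.se_overall:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def emm_plot(results: dict[str, GlmResult], path) -> None:
    """Marginal-mean panels (one per channel) with 95% CIs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(results), figsize=(3.2 * len(results), 3.2),
                             squeeze=False)
    for ax, (ch, res) in zip(axes[0], results.items()):
        emm = res.emmeans
        xs = np.arange(len(emm))
        ax.errorbar(xs, emm["emmean"], yerr=Z95 * emm["se"], fmt="o", color="k")
        hc = emm.loc[emm["diagnosis"] == "HC", "emmean"]
        if len(hc):
            ax.axhline(float(hc.iloc[0]), color="gray", ls="--", lw=0.8)
        ax.set_xticks(xs)
        ax.set_xticklabels(emm["diagnosis"])
        ax.set_title(f"{ch} (p = {res.p_diagnosis:.2g})")
    axes[0][0].set_ylabel("estimated marginal mean score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
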