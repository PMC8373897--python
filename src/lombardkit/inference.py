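"""The analysis ladder: multicollinearity screen, random-structure
selection, likelihood-ratio tests, family choice, marginal-means contrasts,
interaction and modality-frequency analyses, and outlier sensitivity.

The ladder for one feature:

1. choose the null random structure: participant intercept always; the
   item intercept is kept iff it improves the fit by likelihood ratio;
2. fit the full model (noise condition as fixed effect) with condition
   random slopes for each retained grouping factor; on a singular fit the
   slope with the smaller variance is dropped, and if the fit is still
   singular, intercepts only;
3. test the condition effect: the primary likelihood-ratio test compares
   the full model against a null with the *same* random structure (df = 2
   for a three-level factor), which keeps the test calibrated; the
   comparison against the intercepts-only null (random structures differ,
   larger df) is also computed and logged, mirroring how such ladders are
   often reported;
4. for a significant effect, pairwise condition contrasts from estimated
   marginal means with Tukey adjustment (ratios on log-link scales).

Every decision lands in a trace list so a report can reconstruct the path.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import (
    CUMLOGIT,
    GAMMA_LOG,
    GAUSSIAN,
    POISSON,
    FitResult,
    RandomTerm,
    fit_mixed,
)
from .types import GESTURE_ONLY, MULTIMODAL, SPEECH_ONLY

ALPHA = 0.05
VIF_CUTOFF = 3.0
OUTLIER_SD = 3.0


@dataclass
class LRTResult:
    chisq: float
    df: int
    p: float
    formula_null: str
    formula_full: str

    def __post_init__(self) -> None:
        if self.df < 0:
            raise ValueError("negative df: models are not nested as given")


@dataclass
class ContrastSet:
    """Pairwise condition contrasts from estimated marginal means."""

    rows: pd.DataFrame  # contrast, estimate, ratio, se, stat, p_adj
    scale: str  # "difference" | "ratio"


@dataclass
class VIFReport:
    vif: dict[str, float]
    excluded: list[str]
    n_complete: int


@dataclass
class LadderResult:
    """Everything the ladder produced for one response."""

    response: str
    family: str
    null_fit: FitResult
    full_fit: FitResult
    lrt: LRTResult
    lrt_vs_intercept_null: LRTResult
    contrasts: ContrastSet | None
    trace: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# multicollinearity


def vif_screen(table: pd.DataFrame, features: list[str]) -> VIFReport:
    """Variance inflation factors over complete cases; VIF > 3 is excluded.

    VIF_j = 1 / (1 - R^2_j) from regressing feature j on the others;
    perfect collinearity reports an infinite VIF.
    """
    if len(features) < 2:
        raise ValueError("need at least two features to screen")
    data = table[features].dropna()
    n = len(data)
    if n < len(features) + 2:
        raise ValueError("not enough complete cases for the VIF screen")
    X = data.to_numpy(dtype=float)
    vifs: dict[str, float] = {}
    for j, name in enumerate(features):
        yj = X[:, j]
        Xo = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, res, rank, _ = np.linalg.lstsq(Xo, yj, rcond=None)
        fitted = Xo @ coef
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        ss_res = float(np.sum((yj - fitted) ** 2))
        if ss_tot <= 0:
            vifs[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    excluded = [f for f, v in vifs.items() if v > VIF_CUTOFF]
    return VIFReport(vif=vifs, excluded=excluded, n_complete=n)


# ---------------------------------------------------------------------------
# likelihood-ratio comparison


def lrt_compare(null_fit: FitResult, full_fit: FitResult) -> LRTResult:
    """Chi-square difference test of two nested ML fits on the same data."""
    if null_fit.n != full_fit.n:
        raise ValueError(
            f"fits use different data (n={null_fit.n} vs {full_fit.n})"
        )
    if null_fit.family != full_fit.family:
        raise ValueError("fits use different families; not nested")
    df = full_fit.n_params - null_fit.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters than the null")
    chisq = max(0.0, 2.0 * (full_fit.loglik - null_fit.loglik))
    p = float(stats.chi2.sf(chisq, df))
    return LRTResult(chisq, df, p, null_fit.formula, full_fit.formula)


# ---------------------------------------------------------------------------
# family choice


def choose_family(
    table: pd.DataFrame,
    response: str,
    candidates: tuple[str, ...],
    fixed: tuple[str, ...] = ("condition",),
    random: tuple[RandomTerm, ...] = (RandomTerm("participant"), RandomTerm("item")),
    condition_levels: list[str] | None = None,
) -> tuple[str, pd.DataFrame]:
    """Pick the response family by AIC over otherwise-identical fits.

    A reproducible surrogate for eyeballing residual plots: the comparison
    record carries AIC, log-likelihood, and Pearson-residual skewness for
    the report.
    """
    records = []
    for fam in candidates:
        fit = fit_mixed(table, response, fam, fixed, random,
                        condition_levels=condition_levels)
        aic = 2 * fit.n_params - 2 * fit.loglik
        records.append(
            {"family": fam, "aic": aic, "loglik": fit.loglik,
             "n_params": fit.n_params, "resid_skew": _resid_skew(table, response, fit)}
        )
    rec = pd.DataFrame(records).sort_values("aic").reset_index(drop=True)
    return str(rec.loc[0, "family"]), rec


def _resid_skew(table: pd.DataFrame, response: str, fit: FitResult) -> float:
    y = table[response].dropna().to_numpy(dtype=float)
    if fit.family == GAUSSIAN:
        mu = float(np.mean(y))
        r = (y - mu)
    else:
        mu = float(np.mean(y))
        r = (y - mu) / math.sqrt(max(mu, 1e-9))
    return float(stats.skew(r))


# ---------------------------------------------------------------------------
# random-structure selection


def select_random_structure(
    table: pd.DataFrame,
    response: str,
    family: str,
    condition_levels: list[str] | None = None,
    alpha: float = ALPHA,
) -> tuple[tuple[RandomTerm, ...], tuple[RandomTerm, ...], list[dict]]:
    """Deterministic ladder; returns (null_random, full_random, trace).

    Step 1 keeps the item intercept iff it improves the null by LRT.
    Step 2 adds condition slopes for the retained factors, dropping the
    smaller-variance slope on singularity (participant slope dropped on an
    exact tie, since the item structure is sparser), falling back to
    intercepts only. No randomness is involved anywhere.
    """
    trace: list[dict] = []
    base: tuple[RandomTerm, ...] = (RandomTerm("participant"),)
    with_item = base + (RandomTerm("item"),)
    null_p = fit_mixed(table, response, family, (), base, condition_levels=condition_levels)
    null_pi = fit_mixed(table, response, family, (), with_item, condition_levels=condition_levels)
    item_lrt = lrt_compare(null_p, null_pi)
    keep_item = item_lrt.p < alpha
    null_random = with_item if keep_item else base
    trace.append(
        {"step": "null_random_structure", "item_lrt_chisq": item_lrt.chisq,
         "item_lrt_df": item_lrt.df, "item_lrt_p": item_lrt.p,
         "item_intercept_kept": bool(keep_item)}
    )

    slopes = tuple(RandomTerm(rt.factor, slope=True) for rt in null_random)
    candidates = null_random + slopes
    fit = fit_mixed(table, response, family, ("condition",), candidates,
                    condition_levels=condition_levels)
    dropped: list[str] = []
    while fit.singular and any(rt.slope for rt in candidates):
        slope_terms = [rt for rt in candidates if rt.slope]
        sds = {rt.name: fit.vc.get(rt.name, 0.0) for rt in slope_terms}
        # drop the slope with the smaller variance; participant on a tie
        drop_name = min(
            sorted(sds, key=lambda nm: (nm != "participant_slope",)),
            key=lambda nm: sds[nm],
        )
        candidates = tuple(rt for rt in candidates if rt.name != drop_name)
        dropped.append(drop_name)
        fit = fit_mixed(table, response, family, ("condition",), candidates,
                        condition_levels=condition_levels)
    full_random = candidates
    trace.append(
        {"step": "random_slopes", "attempted": [rt.name for rt in slopes],
         "dropped_for_singularity": dropped,
         "kept": [rt.name for rt in full_random if rt.slope]}
    )
    return null_random, full_random, trace


# ---------------------------------------------------------------------------
# estimated marginal means and Tukey contrasts


def _cell_row(fit: FitResult, assignment: dict[str, str]) -> np.ndarray:
    """Fixed-effect design row for one cell, averaging unspecified factors."""
    other = [f for f in fit.factors if f not in assignment]
    grids: list[dict[str, str]] = [dict(assignment)]
    for f in other:
        grids = [dict(g, **{f: l}) for g in grids for l in fit.factors[f]]
    rows = []
    for g in grids:
        row = []
        for spec in fit.colspecs:
            val = 1.0
            for fac, lvl in spec:
                val *= 1.0 if g.get(fac) == lvl else 0.0
            row.append(val)
        rows.append(row)
    x = np.mean(np.asarray(rows, dtype=float), axis=0)
    if fit.n_thresholds == 0 and fit.family != CUMLOGIT:
        return x
    return x  # ordinal: colspecs already exclude the intercept


def emm_contrasts(
    fit: FitResult,
    factor: str = "condition",
    within: dict[str, str] | None = None,
) -> ContrastSet:
    """Pairwise Tukey-adjusted contrasts of the factor's marginal means.

    Marginal predictions hold the random effects at zero (population
    level) and average over the levels of any other fixed factor unless
    pinned by ``within``. On a log link the estimates are differences of
    log means; the exponential is reported as a ratio.
    """
    if not fit.converged:
        raise ValueError("cannot form contrasts from a non-converged fit")
    levels = fit.factors.get(factor)
    if not levels or len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs at least two levels in the fit")
    beta = fit.beta
    cov = fit.cov[fit.n_thresholds :, fit.n_thresholds :]
    x_rows = {}
    for lv in levels:
        assign = dict(within or {})
        assign[factor] = lv
        x_rows[lv] = _cell_row(fit, assign)
    k = len(levels)
    log_link = fit.family in (POISSON, GAMMA_LOG)
    df_resid = max(fit.n - len(beta), 2) if fit.family == GAUSSIAN else math.inf
    recs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[j], levels[i]  # later level vs earlier (e.g. babble8 - clear)
            d = x_rows[a] - x_rows[b]
            est = float(d @ beta)
            se = float(np.sqrt(max(d @ cov @ d, 0.0)))
            stat = est / se if se > 0 else np.nan
            q = abs(stat) * math.sqrt(2.0)
            p_adj = float(stats.studentized_range.sf(q, k, min(df_resid, 1e5)))
            recs.append(
                {
                    "contrast": f"{a} - {b}",
                    "estimate": est,
                    "ratio": math.exp(est) if log_link else np.nan,
                    "se": se,
                    "stat": stat,
                    "p_adj": p_adj,
                }
            )
    return ContrastSet(rows=pd.DataFrame(recs), scale="ratio" if log_link else "difference")


# ---------------------------------------------------------------------------
# the per-feature ladder


def noise_effect_analysis(
    table: pd.DataFrame,
    response: str,
    family: str,
    condition_levels: list[str] | None = None,
    alpha: float = ALPHA,
) -> LadderResult:
    """Run the full selection + test ladder for one feature."""
    null_random, full_random, trace = select_random_structure(
        table, response, family, condition_levels, alpha
    )
    full_fit = fit_mixed(table, response, family, ("condition",), full_random,
                         condition_levels=condition_levels)
    null_matched = fit_mixed(table, response, family, (), full_random,
                             condition_levels=condition_levels)
    null_intercepts = fit_mixed(table, response, family, (), null_random,
                                condition_levels=condition_levels)
    lrt = lrt_compare(null_matched, full_fit)
    lrt_vs_intercepts = lrt_compare(null_intercepts, full_fit)
    trace.append(
        {"step": "condition_lrt", "chisq": lrt.chisq, "df": lrt.df, "p": lrt.p,
         "vs_intercept_null_chisq": lrt_vs_intercepts.chisq,
         "vs_intercept_null_df": lrt_vs_intercepts.df,
         "vs_intercept_null_p": lrt_vs_intercepts.p}
    )
    contrasts = None
    if lrt.p < alpha and family != CUMLOGIT:
        contrasts = emm_contrasts(full_fit, "condition")
    elif family == CUMLOGIT:
        # ordinal models are assessed on their coefficients directly
        contrasts = emm_contrasts(full_fit, "condition")
    return LadderResult(
        response=response, family=family, null_fit=null_matched,
        full_fit=full_fit, lrt=lrt, lrt_vs_intercept_null=lrt_vs_intercepts,
        contrasts=contrasts, trace=trace,
    )


# ---------------------------------------------------------------------------
# interaction analysis (noise x modality)


@dataclass
class InteractionResult:
    response: str
    family: str
    lrt: LRTResult  # modality + interaction vs noise-only null (df = 3)
    lrt_interaction_only: LRTResult  # interaction vs main-effects model (df = 2)
    full_fit: FitResult
    simple_effects: dict[str, ContrastSet]  # per modality level


def interaction_analysis(
    table: pd.DataFrame,
    response: str,
    family: str,
    unimodal_level: str,
    condition_levels: list[str] | None = None,
    random: tuple[RandomTerm, ...] = (RandomTerm("participant"), RandomTerm("item")),
) -> InteractionResult:
    """Noise x modality interaction for a feature with a main noise effect.

    The table is restricted to the two modalities in which the feature is
    defined (speech features: speech-only vs multimodal; gesture features:
    gesture-only vs multimodal). The primary test compares the model with
    modality, noise, and modality x noise terms against the noise-only
    null (df = 3 for the 3 x 2 design: one modality dummy plus two
    interaction terms); the stricter interaction-only comparison against
    the main-effects model (df = 2) is reported alongside. Simple-effect
    condition contrasts are given within each modality.
    """
    sub = table[table["modality"].isin([unimodal_level, MULTIMODAL])]
    sub = sub.dropna(subset=[response])
    present = set(sub["modality"])
    if unimodal_level not in present or MULTIMODAL not in present:
        missing = {unimodal_level, MULTIMODAL} - present
        raise ValueError(f"modality level(s) {sorted(missing)} absent for {response}")
    factors = {"modality": [unimodal_level, MULTIMODAL]}
    null_noise = fit_mixed(sub, response, family, ("condition",), random,
                           factors=factors, condition_levels=condition_levels)
    main = fit_mixed(sub, response, family, ("condition", "modality"), random,
                     factors=factors, condition_levels=condition_levels)
    full = fit_mixed(sub, response, family,
                     ("condition", "modality", "condition:modality"), random,
                     factors=factors, condition_levels=condition_levels)
    lrt = lrt_compare(null_noise, full)
    lrt_io = lrt_compare(main, full)
    simple = {
        lv: emm_contrasts(full, "condition", within={"modality": lv})
        for lv in (unimodal_level, MULTIMODAL)
    }
    return InteractionResult(response, family, lrt, lrt_io, full, simple)


# ---------------------------------------------------------------------------
# modality frequency


def modality_frequency_analysis(
    table: pd.DataFrame,
    condition_levels: list[str] | None = None,
) -> FitResult:
    """Does more noise shift attempts from unimodal to multimodal?

    Modality is collapsed to a two-level ordinal (unimodal < multimodal)
    and fit as a cumulative-link mixed model with noise as the predictor
    and participant and item random intercepts; a two-level CLMM is a
    mixed logistic regression, and the per-level z statistics against the
    clear condition carry the inference.
    """
    data = table.copy()
    data["is_multimodal"] = (data["modality"] == MULTIMODAL).astype(int)
    return fit_mixed(
        data, "is_multimodal", CUMLOGIT, ("condition",),
        (RandomTerm("participant"), RandomTerm("item")),
        condition_levels=condition_levels,
    )


# ---------------------------------------------------------------------------
# outlier sensitivity


@dataclass
class SensitivityResult:
    response: str
    n_removed: int
    full_all: FitResult
    lrt_all: LRTResult
    full_trimmed: FitResult
    lrt_trimmed: LRTResult
    pattern_agrees: bool


def outlier_sensitivity(
    table: pd.DataFrame,
    response: str,
    family: str,
    full_random: tuple[RandomTerm, ...],
    condition_levels: list[str] | None = None,
    alpha: float = ALPHA,
    sd_multiplier: float = OUTLIER_SD,
) -> SensitivityResult:
    """Re-run the condition test with responses beyond mean + 3 SD removed.

    Both fits (all data, trimmed data) are reported along with whether the
    significance pattern of the condition effect agrees.
    """
    vals = table[response].dropna()
    cutoff = vals.mean() + sd_multiplier * vals.std()
    trimmed = table[~(table[response] > cutoff)]
    n_removed = int((table[response] > cutoff).sum())

    def run(data: pd.DataFrame) -> tuple[FitResult, LRTResult]:
        full = fit_mixed(data, response, family, ("condition",), full_random,
                         condition_levels=condition_levels)
        null = fit_mixed(data, response, family, (), full_random,
                         condition_levels=condition_levels)
        return full, lrt_compare(null, full)

    full_all, lrt_all = run(table)
    full_trim, lrt_trim = run(trimmed)
    agrees = (lrt_all.p < alpha) == (lrt_trim.p < alpha)
    return SensitivityResult(
        response=response, n_removed=n_removed, full_all=full_all,
        lrt_all=lrt_all, full_trimmed=full_trim, lrt_trimmed=lrt_trim,
        pattern_agrees=bool(agrees),
    )
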