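"""Visual-grading statistics and artifact-metric regression models.

Covers score tallying (count of readers scoring >= 3 per question, summed to
VG_SUM), intraclass correlation for inter-/intra-reader reliability,
baseline-category multinomial logit models of the ordinal scores, Spearman
correlation matrices with pairwise-complete deletion, and (log-)linear
regressions of the four artifact metrics on acquisition/reconstruction
covariates with optional bidirectional stepwise AIC selection.

ICC conventions
---------------
Inter-reader reliability is the two-way random-effects, average-measures
*consistency* form ICC(C,k) = (MS_R - MS_E) / MS_R.  Intra-reader
reliability is the two-way random-effects, average-measures *absolute
agreement* form ICC(A,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E)/n), with
MS_R the between-subject, MS_C the between-rater and MS_E the residual mean
square from the two-way ANOVA decomposition of the complete case x rater
matrix.  Significance is the F test MS_R/MS_E on (n-1, (n-1)(k-1)) degrees
of freedom; confidence intervals follow the standard F-inversion
constructions for these two forms.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import CaseRecord, QUESTIONS, ReaderScoreTable, cases_to_dataframe

__all__ = [
    "tally_scores",
    "AnovaDecomposition",
    "anova_decomposition",
    "ICCResult",
    "icc_inter",
    "icc_intra",
    "OrdinalFitResult",
    "fit_ordinal_model",
    "fit_multinomial",
    "CorrelationMatrix",
    "spearman_matrix",
    "MetricModelFit",
    "fit_metric_model",
    "stepwise_aic",
    "coefficients_as_percent_change",
]


# --------------------------------------------------------------------------
# tallying

def tally_scores(scores: ReaderScoreTable, threshold: int = 3) -> pd.DataFrame:
    """Per-case counts of readers scoring >= ``threshold`` for each question.

    Returns a DataFrame indexed by case_id with columns q1..q6, ``vg_sum``
    (the row sum), ``n_readers`` (readers contributing to the case) and
    ``complete`` (False where some (reader, question) entry is missing, in
    which case the tally counts over the available readers only).
    """
    if not scores.scores:
        raise ValueError("empty score table")
    readers = scores.reader_ids
    rows = {}
    for cid in scores.case_ids:
        counts = {}
        present = 0
        expected = 0
        for qi, q in enumerate(QUESTIONS, start=1):
            c = 0
            for rid in readers:
                expected += 1
                s = scores.scores.get((cid, rid, q))
                if s is not None:
                    present += 1
                    if s >= threshold:
                        c += 1
            counts[f"q{qi}"] = c
        counts["vg_sum"] = sum(counts[f"q{i}"] for i in range(1, 7))
        counts["n_readers"] = len(readers)
        counts["complete"] = present == expected
        rows[cid] = counts
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "case_id"
    if not out["complete"].all():
        warnings.warn("some (case, reader, question) entries are missing; tallies use available readers")
    return out


# --------------------------------------------------------------------------
# intraclass correlation

@dataclass(frozen=True)
class AnovaDecomposition:
    """Two-way ANOVA mean squares of a complete subjects x raters matrix."""

    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_raters: int

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_raters < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if min(self.ms_rows, self.ms_cols, self.ms_error) < -1e-9:
            raise ValueError("mean squares must be non-negative")


def anova_decomposition(matrix: np.ndarray | pd.DataFrame) -> AnovaDecomposition:
    """Mean squares for subjects (rows), raters (columns) and residual."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D subjects x raters matrix")
    if np.isnan(x).any():
        raise ValueError("ICC requires a complete matrix (no missing scores)")
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    return AnovaDecomposition(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=ss_err / ((n - 1) * (k - 1)),
        n_subjects=n,
        n_raters=k,
    )


@dataclass(frozen=True)
class ICCResult:
    icc: float
    p_value: float
    ci_low: float
    ci_high: float
    anova: AnovaDecomposition
    form: str
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            f"ICC ({self.form}) = {self.icc:.3f}",
            f"95% CI ({self.ci_low:.3f}, {self.ci_high:.3f}), p = {self.p_value:.3g}",
            f"n subjects = {self.anova.n_subjects}, raters = {self.anova.n_raters}",
        ]
        if self.degenerate:
            lines.append("note: degenerate variance decomposition")
        return "\n".join(lines)


def _f_pvalue(an: AnovaDecomposition) -> float:
    n, k = an.n_subjects, an.n_raters
    if an.ms_error == 0:
        return 0.0
    f = an.ms_rows / an.ms_error
    return float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))


def icc_inter(matrix: np.ndarray | pd.DataFrame, alpha: float = 0.05) -> ICCResult:
    """Inter-reader ICC(C,k): two-way random effects, average-measures consistency."""
    an = anova_decomposition(matrix)
    n, k = an.n_subjects, an.n_raters
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if an.ms_rows == 0:
        return ICCResult(0.0, 1.0, np.nan, np.nan, an, "C,k", degenerate=True)
    if an.ms_error == 0:
        return ICCResult(1.0, 0.0, 1.0, 1.0, an, "C,k", degenerate=False)
    icc = (an.ms_rows - an.ms_error) / an.ms_rows
    f = an.ms_rows / an.ms_error
    fl = f / sps.f.ppf(1 - alpha / 2, df1, df2)
    fu = f * sps.f.ppf(1 - alpha / 2, df2, df1)
    return ICCResult(float(icc), _f_pvalue(an), float(1 - 1 / fl), float(1 - 1 / fu), an, "C,k")


def icc_intra(matrix: np.ndarray | pd.DataFrame, alpha: float = 0.05) -> ICCResult:
    """Intra-reader ICC(A,k): two-way random effects, average-measures agreement.

    ``matrix`` is cases x reading occasions for one reader.
    """
    an = anova_decomposition(matrix)
    n, k = an.n_subjects, an.n_raters
    denom = an.ms_rows + (an.ms_cols - an.ms_error) / n
    if an.ms_rows == 0 or denom <= 0:
        return ICCResult(0.0, 1.0, np.nan, np.nan, an, "A,k", degenerate=True)
    icc = (an.ms_rows - an.ms_error) / denom
    if an.ms_error == 0 and an.ms_cols == 0:
        return ICCResult(1.0, 0.0, 1.0, 1.0, an, "A,k")
    # F-inversion bounds for the single-measure ICC(A,1), then Spearman-Brown
    # step-up to average measures (McGraw & Wong construction).
    r1 = (an.ms_rows - an.ms_error) / (an.ms_rows + (k - 1) * an.ms_error + k * (an.ms_cols - an.ms_error) / n)
    a = k * r1 / (n * (1 - r1)) if r1 < 1 else np.inf
    b = 1 + k * r1 * (n - 1) / (n * (1 - r1)) if r1 < 1 else np.inf
    if np.isfinite(a) and (an.ms_cols > 0 or an.ms_error > 0):
        num = (a * an.ms_cols + b * an.ms_error) ** 2
        den = (a * an.ms_cols) ** 2 / (k - 1) + (b * an.ms_error) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else (n - 1) * (k - 1)
        f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (an.ms_rows - f1 * an.ms_error) / (
            f1 * (k * an.ms_cols + (k * n - k - n) * an.ms_error) + n * an.ms_rows
        )
        hi1 = n * (f2 * an.ms_rows - an.ms_error) / (
            k * an.ms_cols + (k * n - k - n) * an.ms_error + n * f2 * an.ms_rows
        )
        lo = k * lo1 / (1 + (k - 1) * lo1)
        hi = k * hi1 / (1 + (k - 1) * hi1)
    else:
        lo = hi = np.nan
    return ICCResult(float(icc), _f_pvalue(an), float(lo), float(hi), an, "A,k")


# --------------------------------------------------------------------------
# multinomial log-odds model of the ordinal scores

#: reference levels of the non-ordered factors in the score model
ORDINAL_REFERENCE_LEVELS = {"imar": "None", "vmi": "40", "kernel": "Qr36f"}


@dataclass
class OrdinalFitResult:
    """Baseline-category multinomial logit fit of reader scores.

    ``coefficients``/``p_values``/``std_errors`` are DataFrames indexed by
    model term with one column per non-reference response category; the
    reference response category is score 1 (or the lowest observed score)
    and reference factor levels carry coefficient 0 by treatment coding.
    """

    coefficients: pd.DataFrame
    std_errors: pd.DataFrame
    p_values: pd.DataFrame
    log_likelihood: float
    reference_levels: dict[str, str]
    reference_category: int
    observed_categories: tuple[int, ...]
    missing_categories: tuple[int, ...]
    dropped_terms: tuple[str, ...]
    converged: bool
    n_obs: int
    _sm_results: object = field(repr=False, default=None)

    def summary(self) -> str:
        if self._sm_results is not None:
            return str(self._sm_results.summary())
        return str(self.coefficients)


def fit_multinomial(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    maxiter: int = 200,
) -> OrdinalFitResult:
    """Fit a baseline-category multinomial logit with the given formula terms.

    ``terms`` are patsy right-hand-side terms (e.g. ``"kvp"`` or
    ``"C(imar, Treatment('None'))"``).  Zero-variance terms are dropped with
    a warning; response categories never observed are flagged.  Complete
    separation surfaces as non-convergence (``converged=False``) with
    unbounded coefficients left as fitted.
    """
    import statsmodels.formula.api as smf

    df = data.copy()
    levels = sorted(df[response].unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 observed response categories")
    missing = tuple(c for c in range(1, 6) if c not in levels)
    if missing:
        warnings.warn(f"response categories {missing} not observed; excluded from the fit")

    kept, dropped = [], []
    for t in terms:
        col = _term_main_column(t)
        if col is not None and col in df.columns and df[col].nunique() <= 1:
            dropped.append(t)
        else:
            kept.append(t)
    if dropped:
        warnings.warn(f"dropping zero-variance terms: {dropped}")
    rhs = " + ".join(kept) if kept else "1"
    # map response to 0..J-1 with the lowest score as the baseline category
    df["_cat"] = df[response].map({lvl: i for i, lvl in enumerate(levels)})
    model = smf.mnlogit(f"_cat ~ {rhs}", data=df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=maxiter, disp=False)
        except np.linalg.LinAlgError:
            # singular Hessian (aliased design or separation): quasi-Newton
            res = model.fit(method="bfgs", maxiter=max(maxiter, 500), disp=False)
    cols = [f"{levels[j + 1]}_vs_{levels[0]}" for j in range(len(levels) - 1)]
    coefs = pd.DataFrame(np.asarray(res.params), index=model.exog_names, columns=cols)
    bse = pd.DataFrame(np.asarray(res.bse), index=model.exog_names, columns=cols)
    pvals = pd.DataFrame(np.asarray(res.pvalues), index=model.exog_names, columns=cols)
    return OrdinalFitResult(
        coefficients=coefs,
        std_errors=bse,
        p_values=pvals,
        log_likelihood=float(res.llf),
        reference_levels=dict(ORDINAL_REFERENCE_LEVELS),
        reference_category=int(levels[0]),
        observed_categories=tuple(int(l) for l in levels),
        missing_categories=missing,
        dropped_terms=tuple(dropped),
        converged=bool(res.mle_retvals.get("converged", True)),
        n_obs=len(df),
        _sm_results=res,
    )


def _term_main_column(term: str) -> str | None:
    """Column name underlying a simple term; None for interactions/functions we keep."""
    if ":" in term:
        return None
    if term.startswith("C("):
        inner = term[2:].split(",")[0].rstrip(") ")
        return inner.strip()
    return term


def fit_ordinal_model(
    scores: ReaderScoreTable, question: str, maxiter: int = 200
) -> OrdinalFitResult:
    """Multinomial log-odds model of one question's scores on the covariates.

    Each reader x case score is one observation.  kVp, IQ and slice
    thickness enter as numeric terms; iMAR, VMI (keV) and kernel as
    non-ordered factors with reference levels iMAR=None, keV=40,
    kernel=Qr36f.  Log-odds are relative to the reference response category,
    score 1.
    """
    if question not in QUESTIONS:
        raise ValueError(f"unknown question {question!r}")
    rows = []
    for (cid, rid, q), s in scores.scores.items():
        if q != question:
            continue
        meta = scores.metadata.get(cid)
        if meta is None:
            raise ValueError(f"no covariate metadata for case {cid}")
        rows.append({"case_id": cid, "reader_id": rid, "score": int(s), **meta})
    if not rows:
        raise ValueError(f"no scores for question {question}")
    df = pd.DataFrame(rows)
    terms = [
        "kvp",
        "iq",
        "slice_mm",
        "C(vmi, Treatment('40'))",
        "C(imar, Treatment('None'))",
        "C(kernel, Treatment('Qr36f'))",
    ]
    return fit_multinomial(df, "score", terms, maxiter=maxiter)


# --------------------------------------------------------------------------
# Spearman correlation matrix

@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rho / p / n with pairwise-complete deletion."""

    variables: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame
    n_used: pd.DataFrame
    constant_flags: tuple[str, ...] = ()

    def summary(self) -> str:
        with pd.option_context("display.width", 200, "display.precision", 3):
            out = [f"Spearman correlation ({len(self.variables)} variables)", str(self.rho)]
        if self.constant_flags:
            out.append(f"constant (rho undefined): {', '.join(self.constant_flags)}")
        return "\n".join(out)


def spearman_matrix(
    cases: Iterable[CaseRecord] | pd.DataFrame, variables: Sequence[str]
) -> CorrelationMatrix:
    """Spearman rank correlation with average ranks for ties.

    Missing values are removed pairwise, so each cell uses its own complete
    sample; two-sided p-values come from the t approximation on
    ``n_used - 2`` degrees of freedom.  A column constant within a pair's
    complete sample yields an undefined (NaN) rho and is flagged.
    """
    df = cases if isinstance(cases, pd.DataFrame) else cases_to_dataframe(cases)
    if len(df) < 4:
        raise ValueError("need at least 4 cases for a correlation matrix")
    variables = tuple(variables)
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.nan, index=variables, columns=variables)
    n_used = pd.DataFrame(0, index=variables, columns=variables, dtype=int)
    np.fill_diagonal(n_used.values, df[list(variables)].notna().sum().reindex(variables))
    flags = set()
    for a, b in itertools.combinations(variables, 2):
        sub = df[[a, b]].dropna()
        n = len(sub)
        n_used.loc[a, b] = n_used.loc[b, a] = n
        if n < 3 or sub[a].nunique() <= 1 or sub[b].nunique() <= 1:
            if n >= 3:
                flags.update(c for c in (a, b) if sub[c].nunique() <= 1)
            rho.loc[a, b] = rho.loc[b, a] = np.nan
            continue
        r, pv = sps.spearmanr(sub[a], sub[b])
        rho.loc[a, b] = rho.loc[b, a] = r
        p.loc[a, b] = p.loc[b, a] = pv
    return CorrelationMatrix(variables, rho, p, n_used, tuple(sorted(flags)))


# --------------------------------------------------------------------------
# (log-)linear artifact-metric models with stepwise AIC

#: reference levels for factor coding in the metric models
METRIC_REFERENCE_LEVELS = {"imar": "None", "kernel": "Qr36f"}

DEFAULT_MAIN_TERMS = ("kvp", "iq", "kev", "slice_mm", "imar", "kernel")
DEFAULT_INTERACTIONS = ("imar:kernel", "kernel:kev")


@dataclass
class MetricModelFit:
    """OLS fit of one artifact metric on the study covariates.

    Under the log link the response and the numeric covariates are
    log-transformed (a power-law model); a signed response is fitted on its
    absolute value, recorded in ``response_transform``.  ``residual_sd`` is
    the standard deviation of the (log-scale) residual term.
    """

    response: str
    link: Literal["linear", "log"]
    terms: tuple[str, ...]
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    residual_sd: float
    adjusted_r2: float
    aic: float
    n_used: int
    excluded_cases: tuple[str, ...]
    response_transform: str
    dropped_aliased: tuple[str, ...] = ()
    _sm_results: object = field(repr=False, default=None)

    def summary(self) -> str:
        if self._sm_results is not None:
            return str(self._sm_results.summary())
        return str(self.coefficients)


def _metric_design(cases: Iterable[CaseRecord] | pd.DataFrame, response: str, link: str):
    df = cases if isinstance(cases, pd.DataFrame) else cases_to_dataframe(cases)
    df = df.copy()
    excluded: list[str] = []
    # numeric keV: the poly-energetic (T3D) and SPP levels have no stated
    # numeric encoding and are excluded from the numeric-mode models
    kev = pd.to_numeric(df["vmi"], errors="coerce")
    non_numeric = df.index[kev.isna()]
    excluded.extend(str(i) for i in non_numeric)
    df = df.loc[kev.notna()].copy()
    df["kev"] = kev.loc[df.index]
    df = df[df[response].notna()].copy()
    transform = "identity"
    y = df[response].astype(float)
    if link == "log":
        if (y < 0).any():
            transform = "absolute value"
            y = y.abs()
        if (y <= 0).any():
            raise ValueError(f"log link requires strictly positive {response} values")
        df["_y"] = np.log(y)
        for c in ("kvp", "iq", "kev", "slice_mm"):
            df[f"log_{c}"] = np.log(df[c].astype(float))
        transform = f"log({transform})" if transform != "identity" else "log"
    else:
        df["_y"] = y
    return df, tuple(excluded), transform


def _term_to_patsy(term: str, link: str) -> str:
    def one(t: str) -> str:
        t = t.strip()
        if t in ("kvp", "iq", "kev", "slice_mm"):
            return f"log_{t}" if link == "log" else t
        if t in METRIC_REFERENCE_LEVELS:
            return f"C({t}, Treatment('{METRIC_REFERENCE_LEVELS[t]}'))"
        if t == "vmi":
            return "C(vmi, Treatment('40'))"
        return t

    return ":".join(one(p) for p in term.split(":"))


def _fit_ols(df: pd.DataFrame, terms: Sequence[str], link: str):
    import statsmodels.formula.api as smf

    rhs = " + ".join(_term_to_patsy(t, link) for t in terms) if terms else "1"
    model = smf.ols(f"_y ~ {rhs}", data=df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


def stepwise_aic(
    df: pd.DataFrame,
    start_terms: Sequence[str],
    candidate_terms: Sequence[str],
    link: str,
    max_steps: int = 50,
) -> tuple[tuple[str, ...], object]:
    """Bidirectional AIC search over the candidate terms.

    Starts from ``start_terms``; at each step the single add or drop with
    the lowest AIC wins, ties resolve toward the smaller model, and an
    interaction is only eligible while both parent main effects are present
    (marginality).  Stops when no move improves AIC.
    """
    current = list(start_terms)
    best = _fit_ols(df, current, link)
    for _ in range(max_steps):
        moves: list[tuple[float, int, list[str]]] = []
        for t in candidate_terms:
            if t in current:
                continue
            if ":" in t and not all(p in current for p in t.split(":")):
                continue
            trial = current + [t]
            moves.append((_fit_ols(df, trial, link).aic, len(trial), trial))
        for t in list(current):
            if ":" not in t and any(":" in c and t in c.split(":") for c in current):
                continue  # keep parents of retained interactions
            trial = [c for c in current if c != t]
            moves.append((_fit_ols(df, trial, link).aic, len(trial), trial))
        if not moves:
            break
        moves.sort(key=lambda m: (round(m[0], 10), m[1]))
        best_aic, _, best_terms = moves[0]
        if best_aic < best.aic - 1e-10:
            current = best_terms
            best = _fit_ols(df, current, link)
        else:
            break
    return tuple(current), best


def fit_metric_model(
    cases: Iterable[CaseRecord] | pd.DataFrame,
    response: str,
    link: Literal["linear", "log"] = "log",
    candidate_terms: Sequence[str] | None = None,
    selection: Literal["none", "stepwise_aic"] = "none",
) -> MetricModelFit:
    """OLS model of one artifact metric (Diff_HU, SD_ARTIFACT, BloomVol or
    AmplitudeLowFreq) on the acquisition/reconstruction covariates.

    Under the log link, numeric covariates (kVp, keV, IQ, slice thickness)
    enter log-transformed, giving a power-law model whose factor
    coefficients are log fold-changes; the linear link fits the raw
    response.  Cases without a numeric keV (T3D / SPP levels) and cases
    missing the response are excluded and listed.  ``selection`` enables
    bidirectional stepwise AIC from the main-effects model over
    ``candidate_terms`` (default: main effects plus the iMAR:kernel and
    kernel:keV interactions).
    """
    df, excluded, transform = _metric_design(cases, response, link)
    main = [t for t in DEFAULT_MAIN_TERMS if df[_main_col(t)].nunique() > 1]
    if candidate_terms is None:
        candidate_terms = list(main) + [
            t for t in DEFAULT_INTERACTIONS if all(p in main for p in t.split(":"))
        ]
    if selection == "stepwise_aic":
        terms, res = stepwise_aic(df, main, candidate_terms, link)
    else:
        terms, res = tuple(candidate_terms), _fit_ols(df, candidate_terms, link)

    aliased = tuple(n for n, v in res.params.items() if not np.isfinite(v))
    return MetricModelFit(
        response=response,
        link=link,
        terms=terms,
        coefficients=res.params,
        std_errors=res.bse,
        p_values=res.pvalues,
        residual_sd=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
        adjusted_r2=float(res.rsquared_adj),
        aic=float(res.aic),
        n_used=int(res.nobs),
        excluded_cases=excluded,
        response_transform=transform,
        dropped_aliased=aliased,
        _sm_results=res,
    )


def _main_col(term: str) -> str:
    return term


def coefficients_as_percent_change(fit: MetricModelFit) -> pd.Series:
    """Per-term effect sizes: percent change under the log link, raw units otherwise.

    For a log-link fit each coefficient beta maps to ``(exp(beta) - 1) * 100``,
    the percent change in the predicted metric for that factor level (or per
    unit of a log-covariate) with everything else held constant.  For a
    linear fit the coefficients are returned unchanged (response units); the
    Series name records which convention applies.
    """
    if fit.link == "log":
        out = (np.exp(fit.coefficients) - 1.0) * 100.0
        out.name = "percent_change"
    else:
        out = fit.coefficients.copy()
        out.name = f"{fit.response}_units"
    return out
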