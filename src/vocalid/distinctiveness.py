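"""Individual distinctiveness statistics.

The question answered here: given repeated calls of one call type from each
of several callers, how reliably can a call be assigned to its caller, and
is that assignment better than chance?

Pipeline per call type:

1. forward-stepwise linear discriminant analysis (Wilks' lambda criterion,
   F-to-enter / F-to-remove thresholds) selects the discriminating subset of
   acoustic parameters and fits the canonical discriminant functions;
2. resubstitution and leave-one-out (U-method) correct-classification rates
   quantify the separation (equal priors; chance = 100/g for g callers);
3. a permuted DFA attaches p-values to both rates: caller labels are
   permuted (at sequence-block level when call segments are nested in
   sequences) and, for unbalanced designs, rates are averaged over repeated
   balanced subset selections, P = (b + 1) / (m + 1);
4. mixed models with caller as fixed effect and sequence as random
   intercept test each parameter loading strongly on the discriminant
   functions, with Hochberg's step-up correction across the tested set;
5. arcsine-transformed leave-one-out proportions are compared across call
   types with a caller-random-intercept mixed model.

All classification is linear discriminant analysis with a pooled
within-group covariance and equal priors; ties break toward the
lexicographically smallest caller ID.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .features import FEATURE_NAMES

__all__ = [
    "DFAResult",
    "PDFAResult",
    "stepwise_dfa",
    "loo_classification",
    "pdfa",
    "hochberg_adjust",
    "lmm_parameter_significance",
    "compare_call_types",
]

F_TO_ENTER = 3.84
F_TO_REMOVE = 2.71


# ---------------------------------------------------------------------------
# linear discriminant core
# ---------------------------------------------------------------------------

def _design(table: pd.DataFrame, parameters) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Extract (X, integer labels, sorted caller ids) with listwise deletion."""
    cols = list(parameters)
    sub = table.dropna(subset=cols)
    callers = sorted(sub["caller_id"].astype(str).unique())
    codes = sub["caller_id"].astype(str).map({c: i for i, c in enumerate(callers)})
    return sub[cols].to_numpy(dtype=np.float64), codes.to_numpy(), callers


def _scatter(X: np.ndarray, y: np.ndarray, g: int):
    """Class counts, class means, within-group and total scatter matrices."""
    n, p = X.shape
    counts = np.bincount(y, minlength=g).astype(float)
    means = np.zeros((g, p))
    for k in range(g):
        means[k] = X[y == k].mean(axis=0)
    Xw = X - means[y]
    Sw = Xw.T @ Xw
    Xt = X - X.mean(axis=0)
    St = Xt.T @ Xt
    return counts, means, Sw, St


def _wilks(X: np.ndarray, y: np.ndarray, g: int, cols: list[int]) -> float:
    """Wilks' lambda det(W)/det(T) for a column subset; NaN if degenerate."""
    Xs = X[:, cols]
    _, _, Sw, St = _scatter(Xs, y, g)
    sign_w, logdet_w = np.linalg.slogdet(Sw)
    sign_t, logdet_t = np.linalg.slogdet(St)
    if sign_w <= 0 or sign_t <= 0:
        return float("nan")
    lam = np.exp(logdet_w - logdet_t)
    if not np.isfinite(lam) or lam <= 0 or lam > 1 + 1e-9:
        return float("nan")
    return float(min(lam, 1.0))


def _lda_predict(X, y, g, X_new):
    """Equal-prior linear discriminant prediction of X_new from a fit on (X, y)."""
    counts, means, Sw, _ = _scatter(X, y, g)
    Sinv = np.linalg.pinv(Sw)  # scale of the covariance cancels under equal priors
    Wm = means @ Sinv  # g x p
    scores = X_new @ Wm.T - 0.5 * np.einsum("ij,ij->i", means, Wm)
    return np.argmax(scores, axis=1)


def _resubstitution(X, y, g) -> np.ndarray:
    return _lda_predict(X, y, g, X)


def _loo_predict(X, y, g) -> np.ndarray:
    """Leave-one-out predictions via rank-one downdates of the within scatter.

    Equivalent to refitting the discriminant with each call held out (the
    pooled-scatter downdate and Sherman-Morrison identity are exact). A fold
    whose removal would leave the held-out call's caller with fewer than two
    calls is skipped (prediction -1).
    """
    n, p = X.shape
    counts, means, Sw, _ = _scatter(X, y, g)
    Sinv = np.linalg.pinv(Sw)
    preds = np.full(n, -1, dtype=int)
    for i in range(n):
        k = y[i]
        nk = counts[k]
        if nk - 1 < 2:
            continue
        u = X[i] - means[k]
        c = nk / (nk - 1.0)
        Su = Sinv @ u
        denom = 1.0 - c * float(u @ Su)
        m_i = means.copy()
        m_i[k] = (nk * means[k] - X[i]) / (nk - 1.0)
        if abs(denom) < 1e-12:
            Sw_i = Sw - c * np.outer(u, u)
            Sinv_i = np.linalg.pinv(Sw_i)
            Wm = m_i @ Sinv_i
        else:
            base = m_i @ Sinv
            Wm = base + (c / denom) * np.outer(m_i @ Su, Su)
        scores = X[i] @ Wm.T - 0.5 * np.einsum("ij,ij->i", m_i, Wm)
        preds[i] = int(np.argmax(scores))
    return preds


def _rates(y, preds, g) -> tuple[float, np.ndarray]:
    """Overall and per-class % correct over evaluated (pred >= 0) samples."""
    per = np.full(g, np.nan)
    ok = preds >= 0
    for k in range(g):
        mask = (y == k) & ok
        if mask.any():
            per[k] = 100.0 * np.mean(preds[mask] == k)
    overall = 100.0 * np.mean(preds[ok] == y[ok]) if ok.any() else float("nan")
    return overall, per


# ---------------------------------------------------------------------------
# stepwise DFA
# ---------------------------------------------------------------------------

@dataclass
class DFAResult:
    """Stepwise discriminant analysis of one call type."""

    call_type: str
    callers: list[str]
    n_per_caller: dict[str, int]
    selected_parameters: list[str]
    n_functions: int
    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # parameter x function pooled within-group correlations
    wilks_lambda: float
    chi2: float
    df: int
    p: float
    resub_overall: float
    resub_per_caller: dict[str, float]
    loo_overall: float
    loo_per_caller: dict[str, float]
    chance: float
    scores: pd.DataFrame  # discriminant scores per call, with caller_id

    @property
    def n_total(self) -> int:
        return sum(self.n_per_caller.values())


def stepwise_dfa(
    table: pd.DataFrame,
    parameters=FEATURE_NAMES,
    call_type: str = "",
    f_to_enter: float = F_TO_ENTER,
    f_to_remove: float = F_TO_REMOVE,
) -> DFAResult:
    """Forward-stepwise DFA with Wilks' lambda selection.

    At each step the candidate parameter minimising the model's Wilks'
    lambda enters if its partial F exceeds ``f_to_enter``; after every entry,
    included parameters whose F-to-remove falls below ``f_to_remove`` leave
    again. Parameters that make the within-group scatter singular are
    skipped with a warning.
    """
    parameters = [p for p in parameters if p in table.columns]
    X, y, callers = _design(table, parameters)
    g = len(callers)
    n, p_all = X.shape
    if g < 2:
        raise ValueError("stepwise_dfa requires at least 2 callers")
    if min(np.bincount(y, minlength=g)) < 2:
        raise ValueError("every caller needs at least 2 complete feature rows")

    selected: list[int] = []
    lam_current = 1.0
    seen: set[frozenset[int]] = set()
    while True:
        state = frozenset(selected)
        if state in seen:  # entry/removal cycle: stop at the revisited model
            break
        seen.add(state)
        changed = False
        # forward step
        best_j, best_lam = -1, np.inf
        for j in range(p_all):
            if j in selected:
                continue
            lam = _wilks(X, y, g, selected + [j])
            if np.isnan(lam):
                continue
            if lam < best_lam:
                best_lam, best_j = lam, j
        if best_j >= 0 and best_lam > 0:
            p_cur = len(selected)
            f_enter = (lam_current / best_lam - 1.0) * (n - g - p_cur) / (g - 1)
            if f_enter >= f_to_enter and n - g - p_cur > 0:
                selected.append(best_j)
                lam_current = best_lam
                changed = True
        # backward steps
        removed = True
        while removed and len(selected) > 1:
            removed = False
            p_cur = len(selected)
            for j in list(selected):
                rest = [c for c in selected if c != j]
                lam_rest = _wilks(X, y, g, rest)
                if np.isnan(lam_rest):
                    continue
                f_rem = (lam_rest / lam_current - 1.0) * (n - g - p_cur + 1) / (g - 1)
                if f_rem < f_to_remove:
                    selected.remove(j)
                    lam_current = lam_rest
                    removed = True
                    changed = True
                    break
        if not changed:
            break

    if not selected:
        raise ValueError("no discriminating parameters pass the entry criterion")

    sel_names = [parameters[j] for j in selected]
    Xs = X[:, selected]
    counts, means, Sw, St = _scatter(Xs, y, g)
    Sb = St - Sw
    p_sel = len(selected)
    n_funcs = min(g - 1, p_sel)

    # canonical functions: generalized eigenproblem Sb v = lambda Sw v
    evals, evecs = linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1][:n_funcs]
    evals = np.clip(evals[order], 0.0, None)
    V = evecs[:, order]
    # scale so pooled within-group variance of each function is 1
    V = V * np.sqrt(n - g)
    scores = (Xs - Xs.mean(axis=0)) @ V

    wilks = float(np.prod(1.0 / (1.0 + evals)))
    chi2 = -(n - 1 - (p_sel + g) / 2.0) * np.log(max(wilks, 1e-300))
    df = p_sel * (g - 1)
    p_val = float(stats.chi2.sf(chi2, df))

    # structure matrix: pooled within-group correlations, all parameters
    Xw_all = X - np.array([X[y == k].mean(axis=0) for k in range(g)])[y]
    scores_w = Xw_all[:, selected] @ V
    load = np.zeros((p_all, n_funcs))
    s_sd = scores_w.std(axis=0, ddof=1)
    for j in range(p_all):
        x_sd = Xw_all[:, j].std(ddof=1)
        if x_sd > 0:
            for f in range(n_funcs):
                if s_sd[f] > 0:
                    load[j, f] = np.cov(Xw_all[:, j], scores_w[:, f], ddof=1)[0, 1] / (
                        x_sd * s_sd[f]
                    )
    loadings = pd.DataFrame(
        load, index=parameters, columns=[f"function_{i+1}" for i in range(n_funcs)]
    )

    resub_overall, resub_per = _rates(y, _resubstitution(Xs, y, g), g)
    loo_overall, loo_per = _rates(y, _loo_predict(Xs, y, g), g)

    score_df = pd.DataFrame(scores, columns=loadings.columns)
    score_df.insert(0, "caller_id", [callers[k] for k in y])

    return DFAResult(
        call_type=call_type,
        callers=callers,
        n_per_caller={c: int(counts[i]) for i, c in enumerate(callers)},
        selected_parameters=sel_names,
        n_functions=n_funcs,
        eigenvalues=evals,
        loadings=loadings,
        wilks_lambda=wilks,
        chi2=float(chi2),
        df=df,
        p=p_val,
        resub_overall=resub_overall,
        resub_per_caller={c: float(resub_per[i]) for i, c in enumerate(callers)},
        loo_overall=loo_overall,
        loo_per_caller={c: float(loo_per[i]) for i, c in enumerate(callers)},
        chance=100.0 / g,
        scores=score_df,
    )


def loo_classification(
    table: pd.DataFrame, selected_parameters
) -> tuple[float, dict[str, float]]:
    """Leave-one-out correct-classification rates for a fixed parameter set.

    Each call is classified by a linear discriminant refit on all other
    calls (equal priors). Returns (overall %, per-caller %).
    """
    X, y, callers = _design(table, selected_parameters)
    g = len(callers)
    if g < 2:
        raise ValueError("need at least 2 callers")
    overall, per = _rates(y, _loo_predict(X, y, g), g)
    return overall, {c: float(per[i]) for i, c in enumerate(callers)}


# ---------------------------------------------------------------------------
# permuted DFA
# ---------------------------------------------------------------------------

@dataclass
class PDFAResult:
    """Permutation test for observed classification rates of one call type."""

    call_type: str
    observed_fitting: float
    observed_cv: float
    null_fitting: np.ndarray
    null_cv: np.ndarray
    p1: float  # fitting DFA
    p2: float  # cross-validated DFA
    n_selections: int
    n_permutations: int
    seed: int | None
    balanced: bool
    n_per_selection: int


def _subset_rates(X, y, g, rng, n_min, balanced) -> tuple[float, float]:
    """(resubstitution %, leave-one-out %) on one balanced subset (or all data)."""
    if balanced:
        idx = np.arange(len(y))
    else:
        parts = [rng.choice(np.nonzero(y == k)[0], size=n_min, replace=False) for k in range(g)]
        idx = np.concatenate(parts)
    Xs, ys = X[idx], y[idx]
    fit, _ = _rates(ys, _resubstitution(Xs, ys, g), g)
    cv_rate, _ = _rates(ys, _loo_predict(Xs, ys, g), g)
    return fit, cv_rate


def pdfa(
    table: pd.DataFrame,
    parameters=FEATURE_NAMES,
    n_selections: int = 100,
    n_permutations: int = 1000,
    seed: int | None = None,
    call_type: str = "",
) -> PDFAResult:
    """Permuted DFA: p-values for the fitting and cross-validated rates.

    The parameter set is fixed throughout (no per-permutation re-selection).
    For unbalanced designs the observed rates are averaged over
    ``n_selections`` random balanced subsets (the minimum per-caller n from
    each caller); each null permutation uses one balanced subset. Caller
    labels are permuted at sequence-block level when a ``sequence_id``
    column with non-singleton blocks is present, so repeated segments of one
    vocalization stay together. P = (count(null >= observed) + 1) /
    (n_permutations + 1).
    """
    if n_permutations < 100:
        warnings.warn("n_permutations < 100 gives a coarse p-value resolution", stacklevel=2)
    parameters = [p for p in parameters if p in table.columns]
    sub = table.dropna(subset=parameters)
    X, y, callers = _design(sub, parameters)
    g = len(callers)
    if g < 2:
        raise ValueError("pdfa requires at least 2 callers")
    counts = np.bincount(y, minlength=g)
    n_min = int(counts.min())
    if n_min < 2:
        raise ValueError("minimum per-caller sample size must be at least 2")
    balanced = bool(np.all(counts == n_min))
    rng = np.random.default_rng(seed)

    if balanced:
        obs_fit, obs_cv = _subset_rates(X, y, g, rng, n_min, True)
    else:
        pairs = [_subset_rates(X, y, g, rng, n_min, False) for _ in range(n_selections)]
        obs_fit = float(np.mean([a for a, _ in pairs]))
        obs_cv = float(np.mean([b for _, b in pairs]))

    # permutation blocks: sequences when present, else single rows
    if "sequence_id" in sub.columns:
        block_ids = sub["sequence_id"].astype(str).to_numpy()
    else:
        block_ids = np.arange(len(y)).astype(str)
    uniq, block_of_row = np.unique(block_ids, return_inverse=True)
    block_label = np.full(len(uniq), -1, dtype=int)
    for row, b in enumerate(block_of_row):
        block_label[b] = y[row]

    null_fit = np.empty(n_permutations)
    null_cv = np.empty(n_permutations)
    for m in range(n_permutations):
        for _attempt in range(50):
            perm = rng.permutation(block_label)
            y_perm = perm[block_of_row]
            c_perm = np.bincount(y_perm, minlength=g)
            if c_perm.min() >= max(2, n_min if not balanced else 2):
                break
        bal_perm = bool(np.all(c_perm == c_perm.min())) and c_perm.min() == n_min
        null_fit[m], null_cv[m] = _subset_rates(
            X, y_perm, g, rng, min(n_min, int(c_perm.min())), bal_perm
        )

    p1 = (np.sum(null_fit >= obs_fit - 1e-12) + 1.0) / (n_permutations + 1.0)
    p2 = (np.sum(null_cv >= obs_cv - 1e-12) + 1.0) / (n_permutations + 1.0)
    return PDFAResult(
        call_type=call_type,
        observed_fitting=obs_fit,
        observed_cv=obs_cv,
        null_fitting=null_fit,
        null_cv=null_cv,
        p1=float(p1),
        p2=float(p2),
        n_selections=n_selections,
        n_permutations=n_permutations,
        seed=seed,
        balanced=balanced,
        n_per_selection=n_min,
    )


# ---------------------------------------------------------------------------
# multiple testing and mixed models
# ---------------------------------------------------------------------------

def hochberg_adjust(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Hochberg's step-up procedure.

    Order the m p-values ascending; reject hypotheses 1..k for the largest k
    with p_(k) <= alpha / (m - k + 1). Returns (reject flags, adjusted
    p-values) in the input order.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="simes-hochberg")
    return reject, p_adj


def _lrt_caller(sub: pd.DataFrame, param: str) -> float:
    """Likelihood-ratio p for a caller effect on one parameter.

    Mixed model with caller identity as fixed effect and sequence as random
    intercept, ML fits; falls back to plain linear-model LRT when the random
    intercept cannot be estimated.
    """
    y = sub[param].to_numpy(dtype=np.float64)
    if np.std(y) == 0:
        return float("nan")
    callers = sorted(sub["caller_id"].astype(str).unique())
    g = len(callers)
    dummies = pd.get_dummies(sub["caller_id"].astype(str), drop_first=True).to_numpy(float)
    X_full = np.column_stack([np.ones(len(y)), dummies])
    X_null = np.ones((len(y), 1))
    groups = sub["sequence_id"].astype(str).to_numpy() if "sequence_id" in sub.columns else None

    def _ols_lrt() -> float:
        llf = []
        for Xd in (X_full, X_null):
            beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            resid = y - Xd @ beta
            n = len(y)
            sigma2 = float(resid @ resid) / n
            llf.append(-0.5 * n * (np.log(2 * np.pi * sigma2) + 1))
        lr = 2.0 * (llf[0] - llf[1])
        return float(stats.chi2.sf(max(lr, 0.0), g - 1))

    if groups is None or len(np.unique(groups)) == len(y):
        return _ols_lrt()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            full = MixedLM(y, X_full, groups=groups).fit(reml=False)
            null = MixedLM(y, X_null, groups=groups).fit(reml=False)
        lr = 2.0 * (full.llf - null.llf)
        if not np.isfinite(lr):
            raise ValueError("non-finite likelihood")
        return float(stats.chi2.sf(max(lr, 0.0), g - 1))
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn(
            f"mixed model for {param!r} did not converge; using a fixed-effects fit",
            stacklevel=2,
        )
        return _ols_lrt()


def lmm_parameter_significance(
    table: pd.DataFrame, parameters, alpha: float = 0.05
) -> pd.DataFrame:
    """Caller-effect significance of each parameter, Hochberg-corrected.

    ``parameters`` is typically the set loading > 0.45 on the discriminant
    functions. Returns a DataFrame with p_raw, p_hochberg and reject;
    parameters with degenerate fits get missing p-values and are excluded
    from the correction.
    """
    parameters = list(parameters)
    if not parameters:
        raise ValueError("empty parameter set")
    if table["caller_id"].nunique() < 2:
        raise ValueError("need at least 2 callers")
    raw = {}
    for param in parameters:
        sub = table.dropna(subset=[param])
        raw[param] = _lrt_caller(sub, param)
    out = pd.DataFrame({"p_raw": pd.Series(raw)})
    out["p_hochberg"] = np.nan
    out["reject"] = False
    valid = out["p_raw"].notna()
    if valid.any():
        rej, adj = hochberg_adjust(out.loc[valid, "p_raw"].to_numpy(), alpha=alpha)
        out.loc[valid, "p_hochberg"] = adj
        out.loc[valid, "reject"] = rej
    return out


def compare_call_types(accuracy: pd.DataFrame) -> tuple[float, tuple[int, int], float]:
    """Do leave-one-out assignment rates differ across call types?

    ``accuracy`` has one row per (caller, call type) with columns
    ``caller_id``, ``call_type``, ``proportion`` (correct-assignment
    proportion in [0, 1]) and ``n_calls``. The proportions are arcsine-
    square-root transformed and modelled with call type as fixed factor, a
    caller random intercept, and (centred) log n_calls as covariate to absorb
    sample-size effects. Returns (F, (df_num, df_den), p) for the call-type
    factor (Wald test).
    """
    required = {"caller_id", "call_type", "proportion", "n_calls"}
    if not required.issubset(accuracy.columns):
        raise ValueError(f"accuracy table needs columns {sorted(required)}")
    if accuracy["call_type"].nunique() < 2:
        raise ValueError("need at least 2 call types")
    y = np.arcsin(np.sqrt(np.clip(accuracy["proportion"].to_numpy(float), 0, 1)))
    ct = pd.get_dummies(accuracy["call_type"].astype(str), drop_first=True).to_numpy(float)
    k = ct.shape[1]
    logn = np.log(accuracy["n_calls"].to_numpy(float))
    logn = logn - logn.mean()
    X = np.column_stack([np.ones(len(y)), ct, logn])
    df_den = max(len(y) - X.shape[1] - 1, 1)
    if np.std(y) == 0:
        return 0.0, (k, df_den), 1.0
    groups = accuracy["caller_id"].astype(str).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = MixedLM(y, X, groups=groups).fit(reml=False)
            cov = res.cov_params()[1 : 1 + k, 1 : 1 + k]
            beta = res.params[1 : 1 + k]
        except (np.linalg.LinAlgError, ValueError):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            sigma2 = float(resid @ resid) / df_den
            cov = sigma2 * np.linalg.pinv(X.T @ X)[1 : 1 + k, 1 : 1 + k]
            beta = beta[1 : 1 + k]
    chi2 = float(np.asarray(beta) @ np.linalg.pinv(np.asarray(cov)) @ np.asarray(beta))
    f_stat = chi2 / k
    p = float(stats.f.sf(f_stat, k, df_den))
    return f_stat, (k, df_den), p
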