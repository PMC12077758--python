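"""Model comparison: polynomial ladders, collinearity screening, all-subsets
AICc ranking, Akaike weights, and full model averaging.

Two selection rules appear throughout.  The *ladder* rule (polynomial order
0..4 against latitude): the lowest-AIC model wins outright only if it leads
by more than ``delta``; when several models sit within ``delta`` of the
minimum, the least complex of them is chosen.  The *driver* analysis screens
environmental covariates for collinearity (Pearson |r| and VIF), builds
candidate variable sets excluding one member of each collinear pair, ranks
every subset of each retained set by AICc, and averages coefficients over the
top set (delta AICc < 2) with Burnham–Anderson unconditional standard errors.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from latdiv.mixedmodel import (
    DesignSpec,
    LMMFit,
    OLSFit,
    StandardScale,
    fit_lmm_ml,
    fit_ols,
    information_criteria,
    polynomial_design,
    r2_nakagawa,
    zscore,
)

logger = logging.getLogger(__name__)

CI_MULTIPLIER = 1.96  # normal-approximation 95% interval


@dataclass
class LadderResult:
    rows: pd.DataFrame
    selected_order: int
    selection_reason: str
    fits: dict[int, Any]
    scale: StandardScale | None
    mixed: bool


@dataclass
class CollinearityReport:
    pearson: pd.DataFrame
    vif: dict[str, float]
    flagged_pairs: list[tuple[str, str]]
    flagged_vars: list[str]
    candidate_sets: list[list[str]]


@dataclass
class SubsetRanking:
    """All-subsets AICc table; ``weight`` is over the full ranking."""

    table: pd.DataFrame
    fits: dict[tuple[str, ...], LMMFit]
    variables: list[str]

    @property
    def top_set(self) -> pd.DataFrame:
        return self.table[self.table["delta_AICc"] < 2.0]


@dataclass
class AveragedModel:
    table: pd.DataFrame
    mode: str
    n_models: int


@dataclass
class DriverReport:
    metric: str
    screen: CollinearityReport
    global_fits: dict[str, dict]
    retained_sets: list[str]
    rankings: dict[str, SubsetRanking]
    averaged: dict[str, AveragedModel]
    thresholds: dict[str, float]


def select_by_delta_rule(
    ic_by_label: Mapping[Any, float], delta: float = 2.0
) -> tuple[Any, str]:
    """Lowest information criterion with the parsimony tie-break.

    Labels must sort by model complexity (e.g. polynomial order).  The
    minimum-IC model is selected when every other model trails by at least
    ``delta``; otherwise the least complex label within ``delta`` of the
    minimum wins.
    """
    if not ic_by_label:
        raise ValueError("no models to select from")
    finite = {k: v for k, v in ic_by_label.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("no model has a finite information criterion")
    best_ic = min(finite.values())
    close = [k for k, v in finite.items() if v - best_ic < delta]
    if len(close) == 1:
        return close[0], "unique best by delta rule"
    return min(close), "parsimony among close set"


def akaike_weights(ics: Sequence[float]) -> np.ndarray:
    """w_m = exp(-delta_m/2) / sum exp(-delta/2) over the given model set."""
    ics = np.asarray(ics, dtype=float)
    delta = ics - np.nanmin(ics)
    w = np.exp(-0.5 * delta)
    return w / np.nansum(w)


def polynomial_ladder(
    y,
    band_latitudes,
    groups=None,
    max_order: int = 4,
    mixed: bool | None = None,
    delta: float = 2.0,
) -> LadderResult:
    """Fit polynomial orders 0..max_order of z-scored latitude and select.

    Mixed (species random intercept) fits for the pooled analysis, OLS for
    intraspecific trends.  Orders whose design is rank deficient or leaves no
    residual degrees of freedom are skipped with a log entry; non-converged
    mixed fits are excluded from the comparison.
    """
    y = np.asarray(y, dtype=float)
    lats = np.asarray(band_latitudes, dtype=float)
    if mixed is None:
        mixed = groups is not None
    if mixed and groups is None:
        raise ValueError("mixed ladder requires group labels")
    scale: StandardScale | None = None
    z = None
    try:
        z, scale = zscore(lats)
    except ValueError:
        logger.warning("constant latitudes: only the null model is estimable")
    rows, fits = [], {}
    for order in range(max_order + 1):
        row = {"order": order, "k": np.nan, "loglik": np.nan, "AIC": np.nan,
               "converged": False, "note": ""}
        try:
            if order == 0:
                X = np.ones((len(y), 1))
            elif z is None:
                raise ValueError("no latitude variation")
            else:
                X = polynomial_design(z, order)
            names = ["intercept"] + [f"z^{j}" for j in range(1, order + 1)]
            if mixed:
                fit = fit_lmm_ml(DesignSpec(y, X, np.asarray(groups), names))
                if not fit.converged:
                    row["note"] = "non-converged"
                    logger.warning("ladder order %d: mixed fit did not converge", order)
                    rows.append(row)
                    continue
            else:
                fit = fit_ols(y, X, names)
        except ValueError as exc:
            row["note"] = str(exc)
            logger.info("ladder order %d skipped: %s", order, exc)
            rows.append(row)
            continue
        row.update(k=fit.k, loglik=fit.loglik,
                   AIC=-2.0 * fit.loglik + 2.0 * fit.k, converged=True)
        fits[order] = fit
        rows.append(row)
    table = pd.DataFrame(rows)
    usable = {int(r["order"]): float(r["AIC"]) for _, r in table.iterrows()
              if bool(r["converged"])}
    if not usable:
        raise ValueError("no polynomial order could be fitted")
    selected, reason = select_by_delta_rule(usable, delta=delta)
    return LadderResult(
        rows=table,
        selected_order=int(selected),
        selection_reason=reason,
        fits=fits,
        scale=scale,
        mixed=bool(mixed),
    )


def collinearity_screen(
    env: pd.DataFrame, r_max: float = 0.7, vif_max: float = 5.0
) -> CollinearityReport:
    """Pearson/VIF collinearity screen with candidate-set construction.

    VIF_j = 1/(1 - R^2_j) from regressing variable j on all the others.
    Candidate sets are built by excluding one member of each |r|-flagged pair
    in every combination; perfectly collinear pairs yield infinite VIF and
    are handled the same way.
    """
    if env.shape[1] < 2:
        raise ValueError("collinearity screen needs at least 2 variables")
    if len(env) < 3:
        raise ValueError("collinearity screen needs at least 3 rows")
    variables = list(env.columns)
    X = env.to_numpy(dtype=float)
    pearson = env.corr(method="pearson")
    vif: dict[str, float] = {}
    for j, name in enumerate(variables):
        others = np.column_stack(
            [np.ones(len(X))] + [X[:, i] for i in range(len(variables)) if i != j]
        )
        yj = X[:, j]
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
        vif[name] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    flagged_pairs = [
        (variables[i], variables[j])
        for i in range(len(variables))
        for j in range(i + 1, len(variables))
        if abs(pearson.iloc[i, j]) > r_max
    ]
    flagged_vars = [v for v in variables if vif[v] > vif_max]
    if flagged_pairs:
        candidates: list[list[str]] = []
        for choice in itertools.product(*flagged_pairs):
            dropped = set(choice)
            cand = [v for v in variables if v not in dropped]
            if cand not in candidates:
                candidates.append(cand)
        # a set strictly contained in another offers nothing extra
        candidates = [
            c for c in candidates
            if not any(set(c) < set(o) for o in candidates)
        ]
    else:
        candidates = [list(variables)]
    return CollinearityReport(
        pearson=pearson,
        vif=vif,
        flagged_pairs=flagged_pairs,
        flagged_vars=flagged_vars,
        candidate_sets=candidates,
    )


def compare_global_sets(
    set_fits: list[tuple[str, LMMFit]], delta: float = 2.0
) -> list[str]:
    """Retain candidate variable sets by global-model AIC.

    The best set is kept alone when it leads by more than ``delta``;
    otherwise every set within ``delta`` of the best is carried forward.
    """
    if not set_fits:
        raise ValueError("no global fits to compare")
    aics = {name: -2.0 * fit.loglik + 2.0 * fit.k for name, fit in set_fits}
    best = min(aics.values())
    close = [name for name, a in aics.items() if a - best < delta]
    return close


def all_subsets(y, env: pd.DataFrame, groups, max_p: int = 12) -> SubsetRanking:
    """Exhaustive subset ranking of a global mixed model by AICc.

    Every subset of the supplied (pre-standardized) variables, including the
    intercept-only model, is fitted with a species random intercept; models
    are ranked by AICc with Akaike weights over the full ranking.
    Non-convergent subsets are dropped with a logged warning.
    """
    variables = list(env.columns)
    if len(variables) > max_p:
        raise ValueError(f"too many variables for exhaustive search ({len(variables)})")
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    N = len(y)
    rows, fits = [], {}
    for r in range(len(variables) + 1):
        for combo in itertools.combinations(variables, r):
            X = np.column_stack(
                [np.ones(N)] + [env[v].to_numpy(dtype=float) for v in combo]
            )
            names = ["intercept"] + list(combo)
            fit = fit_lmm_ml(DesignSpec(y, X, groups, names))
            if not fit.converged:
                logger.warning("subset %s did not converge; dropped", combo)
                continue
            ic = information_criteria(fit.loglik, fit.k, N)
            rows.append({"terms": combo, "k": fit.k, "loglik": fit.loglik,
                         "AICc": ic["AICc"]})
            fits[combo] = fit
    if not rows:
        raise ValueError("no subset converged")
    table = pd.DataFrame(rows).sort_values("AICc", kind="mergesort").reset_index(drop=True)
    table["delta_AICc"] = table["AICc"] - table["AICc"].min()
    table["weight"] = akaike_weights(table["AICc"].to_numpy())
    return SubsetRanking(table=table, fits=fits, variables=variables)


def average_terms(
    weights: Sequence[float],
    coef_maps: Sequence[Mapping[str, tuple[float, float]]],
    terms: Sequence[str] | None = None,
    mode: str = "full",
) -> pd.DataFrame:
    """Model-average per-term coefficients over a weighted model set.

    ``coef_maps[m]`` maps term -> (estimate, se) for model m; weights must be
    normalized over the set.  Full averaging substitutes estimate 0 (se 0)
    where a term is absent; the unconditional variance per Burnham–Anderson
    is sum_m w_m (se_m^2 + (est_m - avg)^2).  Conditional averaging restricts
    to the models containing the term, renormalizing their weights.
    """
    w = np.asarray(weights, dtype=float)
    if not math.isclose(float(w.sum()), 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError("weights must be normalized over the model set")
    if terms is None:
        seen: list[str] = []
        for cm in coef_maps:
            for t in cm:
                if t not in seen:
                    seen.append(t)
        terms = seen
    rows = []
    for term in terms:
        present = np.array([term in cm for cm in coef_maps])
        importance = float(w[present].sum())
        if mode == "full":
            est = np.array([cm.get(term, (0.0, 0.0))[0] for cm in coef_maps])
            se = np.array([cm.get(term, (0.0, 0.0))[1] for cm in coef_maps])
            ww = w
        elif mode == "conditional":
            if not present.any():
                rows.append((term, np.nan, np.nan, np.nan, np.nan, importance, False))
                continue
            est = np.array([cm[term][0] for cm, p in zip(coef_maps, present) if p])
            se = np.array([cm[term][1] for cm, p in zip(coef_maps, present) if p])
            ww = w[present] / w[present].sum()
        else:
            raise ValueError(f"unknown averaging mode {mode!r}")
        avg = float(np.sum(ww * est))
        var = float(np.sum(ww * (se**2 + (est - avg) ** 2)))
        se_u = math.sqrt(var)
        lo, hi = avg - CI_MULTIPLIER * se_u, avg + CI_MULTIPLIER * se_u
        rows.append((term, avg, se_u, lo, hi, importance, lo > 0 or hi < 0))
    return pd.DataFrame(
        rows,
        columns=["term", "estimate", "se", "ci_low", "ci_high",
                 "importance", "ci_excludes_zero"],
    )


def model_average(
    ranking: SubsetRanking, mode: str = "full", delta: float = 2.0
) -> AveragedModel:
    """Average coefficients over the delta-AICc top set of a subset ranking.

    Weights are renormalized over the top set; a term's importance is the
    summed renormalized weight of top-set models containing it (and equals 1
    exactly when the term is in every top-set model).  The importance over
    the full ranking is also reported per term.
    """
    top = ranking.table[ranking.table["delta_AICc"] < delta]
    if top.empty:
        raise ValueError("empty top set")
    w_top = top["weight"].to_numpy(dtype=float)
    w_top = w_top / w_top.sum()
    coef_maps = []
    for terms in top["terms"]:
        fit = ranking.fits[terms]
        cm = {name: (float(b), float(s))
              for name, b, s in zip(fit.names, fit.beta, fit.se_beta)
              if name != "intercept"}
        coef_maps.append(cm)
    table = average_terms(w_top, coef_maps, terms=ranking.variables, mode=mode)
    full_imp = {
        v: float(sum(w for terms, w in zip(ranking.table["terms"],
                                           ranking.table["weight"])
                     if v in terms))
        for v in ranking.variables
    }
    table["importance_full"] = table["term"].map(full_imp)
    return AveragedModel(table=table, mode=mode, n_models=len(top))


def driver_analysis(
    diversity_table: pd.DataFrame,
    env_table: pd.DataFrame,
    metric: str,
    r_max: float = 0.7,
    vif_max: float = 5.0,
    delta_aic: float = 2.0,
    delta_aicc: float = 2.0,
    mode: str = "full",
) -> DriverReport:
    """Environmental-driver inference for pooled (total) genetic diversity.

    Joins band-level diversity estimates to per-band environmental means,
    z-scores the covariates, screens for collinearity, fits the global mixed
    model of each candidate set, retains sets by AIC, then ranks all subsets
    of each retained set by AICc and model-averages the top set.
    """
    env_vars = [c for c in env_table.columns if c not in ("band", "lat", "lon")]
    if "band" not in env_table.columns:
        raise ValueError("env_table must carry a 'band' column")
    div = diversity_table.drop(
        columns=[c for c in env_vars if c in diversity_table.columns]
    )
    merged = div.merge(env_table[["band"] + env_vars], on="band", how="inner")
    if merged.empty:
        raise ValueError("no overlap between diversity bands and env table")
    scaled = pd.DataFrame(index=merged.index)
    for v in env_vars:
        z, _ = zscore(merged[v].to_numpy(dtype=float))
        scaled[v] = z
    y = merged[metric].to_numpy(dtype=float)
    groups = merged["species_id"].to_numpy()
    screen = collinearity_screen(scaled, r_max=r_max, vif_max=vif_max)
    set_names = [f"set{i + 1}" for i in range(len(screen.candidate_sets))]
    global_fits: dict[str, dict] = {}
    named_fits: list[tuple[str, LMMFit]] = []
    for name, variables in zip(set_names, screen.candidate_sets):
        X = np.column_stack(
            [np.ones(len(y))] + [scaled[v].to_numpy() for v in variables]
        )
        fit = fit_lmm_ml(DesignSpec(y, X, groups, ["intercept"] + variables))
        aic = -2.0 * fit.loglik + 2.0 * fit.k
        global_fits[name] = {"variables": variables, "AIC": aic,
                             "converged": fit.converged}
        if fit.converged:
            named_fits.append((name, fit))
    retained = compare_global_sets(named_fits, delta=delta_aic)
    rankings: dict[str, SubsetRanking] = {}
    averaged: dict[str, AveragedModel] = {}
    for name in retained:
        variables = global_fits[name]["variables"]
        ranking = all_subsets(y, scaled[variables], groups)
        rankings[name] = ranking
        averaged[name] = model_average(ranking, mode=mode, delta=delta_aicc)
    return DriverReport(
        metric=metric,
        screen=screen,
        global_fits=global_fits,
        retained_sets=retained,
        rankings=rankings,
        averaged=averaged,
        thresholds={"r_max": r_max, "vif_max": vif_max,
                    "delta_aic": delta_aic, "delta_aicc": delta_aicc},
    )


def intraspecific_trends(
    diversity_table: pd.DataFrame,
    metrics: tuple[str, ...] = ("pi", "hd"),
    max_order: int = 4,
    delta: float = 2.0,
) -> pd.DataFrame:
    """Per-species OLS polynomial ladders of diversity against latitude.

    No band filtering is applied here (species-specific trends use every
    band).  Orders are capped so the residual degrees of freedom stay >= 1;
    adjusted R^2 is reported only when a non-null order is selected.  Species
    where nothing beyond the null model is estimable are skipped with a log
    entry, not failed.
    """
    rows = []
    for sp, sub in diversity_table.groupby("species_id", sort=True):
        lats = sub["band"].to_numpy(dtype=float)
        for metric in metrics:
            y = sub[metric].to_numpy(dtype=float)
            cap = min(max_order, len(y) - 2)
            if cap < 1 or len(np.unique(lats)) < 2:
                logger.info("species %s (%s): only null estimable; skipped",
                            sp, metric)
                continue
            ladder = polynomial_ladder(y, lats, mixed=False,
                                       max_order=cap, delta=delta)
            sel = ladder.selected_order
            adj_r2 = (float(ladder.fits[sel].adj_r2) if sel > 0 else np.nan)
            rows.append((sp, metric, len(y), sel, ladder.selection_reason,
                         adj_r2))
    return pd.DataFrame(
        rows,
        columns=["species_id", "metric", "n_bands", "selected_order",
                 "selection_reason", "adj_r2"],
    )
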