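"""The comparison layer: ANCOVA/ANOVA with a model-reduction protocol,
covariate-adjusted group means, and Tukey pairwise contrasts.

Shape follows the statsmodels convention: an :class:`Ancova` model object is
built from a DataFrame, ``fit()`` returns :class:`AncovaResults` carrying
coefficients, a term-level F table, AIC and residuals, and the results
object exposes ``adjusted_means()``, ``tukey()`` and ``summary()``.

Reduction protocol: the full declared model is fitted, then non-significant
interaction terms are removed one at a time (highest order first, then
largest p), refitting after each removal, until every retained interaction
is significant at ``alpha``. Main effects and covariates are never removed
by this loop; covariate retention is a separate three-part check
(:func:`covariate_retention_check`): term significance, AIC on removal, and
a regression of final-model residuals on the candidate.

Term tests use Type II sums of squares (with no retained interaction in a
balanced design this coincides with Types I/III); the choice is recorded on
the results object.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy.stats import studentized_range

from .errors import EstimationError, ValidationError


@dataclass
class ModelSpec:
    """Declarative model description.

    ``factors`` are treated as categorical, ``covariates`` as continuous.
    ``interactions`` is a list of tuples of declared term names; by default
    all pairwise factor interactions are declared. ``log10_response`` only
    records whether the response column is already log-transformed (used
    for back-transformed reporting).
    """

    response: str
    factors: list[str]
    covariates: list[str] = field(default_factory=list)
    interactions: Optional[list[tuple[str, ...]]] = None
    alpha: float = 0.05
    log10_response: bool = False

    def __post_init__(self) -> None:
        if self.interactions is None:
            self.interactions = [
                tuple(pair) for pair in itertools.combinations(self.factors, 2)
            ]
        declared = set(self.factors) | set(self.covariates)
        for inter in self.interactions:
            unknown = set(inter) - declared
            if unknown:
                raise ValidationError(
                    f"interaction {inter} references undeclared terms {sorted(unknown)}"
                )


def _term_label(name: str, factors: Sequence[str]) -> str:
    return f"C({name})" if name in factors else name


def _interaction_label(inter: tuple[str, ...], factors: Sequence[str]) -> str:
    return ":".join(_term_label(t, factors) for t in inter)


@dataclass
class AncovaResults:
    """Fitted ANCOVA/ANOVA with its reduction trail and diagnostics."""

    results: sm.regression.linear_model.RegressionResultsWrapper
    anova_table: pd.DataFrame
    formula: str
    spec: ModelSpec
    data: pd.DataFrame
    removal_trail: list[tuple[str, float]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    ss_type: int = 2

    @property
    def aic(self) -> float:
        return float(self.results.aic)

    @property
    def residuals(self) -> pd.Series:
        return self.results.resid

    def term_p(self, term: str) -> float:
        """p-value of a declared term (factor or covariate name)."""
        label = _term_label(term, self.spec.factors)
        if label not in self.anova_table.index:
            raise KeyError(f"term {term!r} not in the fitted model")
        return float(self.anova_table.loc[label, "PR(>F)"])

    def summary(self) -> str:
        """Human-readable fit report: formula, reduction trail, term table."""
        lines = [f"Model: {self.formula}", f"AIC: {self.aic:.2f}  (Type {self.ss_type} SS)"]
        for label, p in self.removal_trail:
            lines.append(f"  removed {label} (p = {p:.3f})")
        for note in self.notes:
            lines.append(f"  note: {note}")
        lines.append(self.term_table().to_string(index=False))
        return "\n".join(lines)

    def term_table(self) -> pd.DataFrame:
        """Effect / F / df / P table (reporting layout)."""
        tab = self.anova_table
        out = pd.DataFrame(
            {
                "effect": tab.index,
                "F": tab["F"].round(4),
                "df": [
                    f"{int(tab.loc[i, 'df'])}, {int(tab.loc['Residual', 'df'])}"
                    if i != "Residual"
                    else ""
                    for i in tab.index
                ],
                "p": tab["PR(>F)"].round(4),
            }
        )
        return out[out["effect"] != "Residual"].reset_index(drop=True)

    # ---------------------------------------------------------------- means
    def _reference_grid(
        self, at_covariates: Optional[dict[str, float]] = None
    ) -> pd.DataFrame:
        levels = {
            f: sorted(self.data[f].unique()) for f in self.spec.factors
        }
        grid = pd.DataFrame(
            list(itertools.product(*levels.values())), columns=list(levels.keys())
        )
        at_covariates = dict(at_covariates or {})
        for cov in self.spec.covariates:
            if cov in self._dropped_covariates():
                continue
            value = at_covariates.get(cov, float(self.data[cov].mean()))
            lo, hi = self.data[cov].min(), self.data[cov].max()
            if not (lo <= value <= hi):
                warnings.warn(
                    f"adjusted means extrapolate: {cov}={value} outside "
                    f"observed range [{lo}, {hi}]",
                    stacklevel=3,
                )
            grid[cov] = value
        return grid

    def _dropped_covariates(self) -> set[str]:
        return {n.split()[-1] for n in self.notes if n.startswith("dropped zero-variance covariate")}

    def adjusted_means(
        self,
        at_covariates: Optional[dict[str, float]] = None,
        by: Optional[Sequence[str]] = None,
        backtransform: bool = False,
    ) -> pd.DataFrame:
        """Model-predicted group means at a common covariate value.

        ``by`` restricts the table to a subset of factors (marginal LS
        means, averaged over the omitted factors' levels with equal
        weight). ``backtransform`` adds a 10**mean column when the response
        was log10-transformed; SEMs stay on the model (log) scale.
        """
        grid = self._reference_grid(at_covariates)
        pred = self.results.get_prediction(grid)
        out = grid[self.spec.factors].copy()
        out["adjusted_mean"] = pred.predicted_mean
        out["sem"] = pred.se_mean
        if by is not None:
            by = list(by)
            # equal-weight average over omitted factor levels, with the SE of
            # the averaged linear combination
            X = _design_rows(self.results, grid)
            V = self.results.cov_params().to_numpy()
            rows = []
            for keys, sub in out.groupby(by, sort=True):
                idx = sub.index.to_numpy()
                c = X[idx].mean(axis=0)
                mean = float(c @ self.results.params.to_numpy())
                se = float(np.sqrt(c @ V @ c))
                rec = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
                rec.update(adjusted_mean=mean, sem=se)
                rows.append(rec)
            out = pd.DataFrame(rows)
        if backtransform and self.spec.log10_response:
            out["adjusted_mean_backtransformed"] = 10 ** out["adjusted_mean"]
        return out

    # ---------------------------------------------------------------- tukey
    def tukey(
        self,
        factor: str,
        at_covariates: Optional[dict[str, float]] = None,
        alpha: Optional[float] = None,
    ) -> pd.DataFrame:
        """All pairwise contrasts of a factor's adjusted means.

        p-values use the studentized range distribution (Tukey HSD) on
        model-based LS means; a compact letter display is attached (levels
        sharing a letter do not differ at ``alpha``).
        """
        alpha = self.spec.alpha if alpha is None else alpha
        if factor not in self.spec.factors:
            raise ValidationError(f"{factor!r} is not a declared factor")
        levels = sorted(self.data[factor].unique())
        if len(levels) < 2:
            raise EstimationError(f"factor {factor!r} has < 2 levels")
        grid = self._reference_grid(at_covariates)
        X = _design_rows(self.results, grid)
        beta = self.results.params.to_numpy()
        V = self.results.cov_params().to_numpy()
        df_resid = float(self.results.df_resid)
        k = len(levels)

        rowvec = {}
        for lev in levels:
            idx = grid.index[grid[factor] == lev].to_numpy()
            rowvec[lev] = X[idx].mean(axis=0)

        rows = []
        sig = {}
        for a, b in itertools.combinations(levels, 2):
            c = rowvec[b] - rowvec[a]
            diff = float(c @ beta)
            se = float(np.sqrt(c @ V @ c))
            if se == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se * np.sqrt(2.0)
                p = float(studentized_range.sf(q, k, df_resid))
            rows.append({"level_1": a, "level_2": b, "estimate": diff, "se": se, "p_tukey": p})
            sig[(a, b)] = sig[(b, a)] = p < alpha
        table = pd.DataFrame(rows)
        letters = _letter_display(levels, {lev: float(rowvec[lev] @ beta) for lev in levels}, sig)
        table.attrs["letters"] = letters
        return table


def _design_rows(results, grid: pd.DataFrame) -> np.ndarray:
    design_info = results.model.data.design_info
    return np.asarray(build_design_matrices([design_info], grid)[0])


def _letter_display(levels, means, sig) -> dict:
    """Compact letter display: levels sharing a letter are not separable."""
    order = sorted(levels, key=lambda lev: means[lev])
    groups: list[list] = []
    for i, lev in enumerate(order):
        run = [lev]
        for other in order[i + 1 :]:
            if any(sig[(m, other)] for m in run):
                break
            run.append(other)
        if not any(set(run) <= set(g) for g in groups):
            groups.append(run)
    letters = {lev: "" for lev in levels}
    for gi, grp in enumerate(groups):
        ch = chr(ord("a") + gi)
        for lev in grp:
            letters[lev] += ch
    return letters


class Ancova:
    """ANCOVA/ANOVA model builder (statsmodels-style Model object).

    Parameters
    ----------
    data : DataFrame with the response, factor and covariate columns.
    spec : ModelSpec (or use ``from_columns``).
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        missing = [
            c
            for c in [spec.response, *spec.factors, *spec.covariates]
            if c not in data.columns
        ]
        if missing:
            raise ValidationError(f"data is missing columns {missing}")
        self.data = data.dropna(subset=[spec.response, *spec.factors, *spec.covariates]).copy()
        self.spec = spec
        self.notes: list[str] = []
        # a constant covariate is aliased with the intercept; drop with a note
        self._covariates = []
        for cov in spec.covariates:
            if self.data[cov].nunique() <= 1:
                self.notes.append(f"dropped zero-variance covariate {cov}")
            else:
                self._covariates.append(cov)

    @classmethod
    def from_columns(
        cls,
        data: pd.DataFrame,
        response: str,
        factors: Sequence[str],
        covariates: Sequence[str] = (),
        interactions: Optional[list[tuple[str, ...]]] = None,
        alpha: float = 0.05,
        log10_response: bool = False,
    ) -> "Ancova":
        return cls(
            data,
            ModelSpec(
                response=response,
                factors=list(factors),
                covariates=list(covariates),
                interactions=interactions,
                alpha=alpha,
                log10_response=log10_response,
            ),
        )

    # ------------------------------------------------------------------ fit
    def _formula(self, interactions: list[tuple[str, ...]]) -> str:
        terms = [_term_label(f, self.spec.factors) for f in self.spec.factors]
        terms += self._covariates
        terms += [_interaction_label(i, self.spec.factors) for i in interactions]
        return f"{self.spec.response} ~ " + " + ".join(terms) if terms else f"{self.spec.response} ~ 1"

    def _fit_formula(self, formula: str):
        res = smf.ols(formula, data=self.data).fit()
        rank = np.linalg.matrix_rank(res.model.exog)
        if rank < res.model.exog.shape[1] or res.df_resid <= 0:
            names = res.model.exog_names
            bad = [n for n, p in zip(names, res.params) if not np.isfinite(p)]
            raise EstimationError(
                "rank-deficient design (no residual degrees of freedom or aliased "
                f"terms {bad or names}); model: {formula}"
            )
        return res

    def fit(self, reduce_interactions: bool = True) -> AncovaResults:
        """Fit the declared model, sequentially pruning ns interactions."""
        interactions = [
            i for i in self.spec.interactions if all(t in self.spec.factors or t in self._covariates for t in i)
        ]
        trail: list[tuple[str, float]] = []
        while True:
            formula = self._formula(interactions)
            res = self._fit_formula(formula)
            table = sm.stats.anova_lm(res, typ=2)
            if not reduce_interactions or not interactions:
                break
            cand = []
            for inter in interactions:
                label = _interaction_label(inter, self.spec.factors)
                p = float(table.loc[label, "PR(>F)"])
                if p >= self.spec.alpha:
                    cand.append((len(inter), p, inter, label))
            if not cand:
                break
            # highest order first, then largest p
            cand.sort(key=lambda c: (-c[0], -c[1]))
            _, p, inter, label = cand[0]
            trail.append((label, p))
            interactions = [i for i in interactions if i != inter]
        return AncovaResults(
            results=res,
            anova_table=table,
            formula=formula,
            spec=self.spec,
            data=self.data,
            removal_trail=trail,
            notes=list(self.notes),
        )


def fit_reduced_model(data: pd.DataFrame, spec: ModelSpec) -> AncovaResults:
    """Convenience wrapper: build an :class:`Ancova` and fit with reduction."""
    return Ancova(data, spec).fit(reduce_interactions=True)


@dataclass(frozen=True)
class CovariateDecision:
    covariate: str
    drop: bool
    term_p: Optional[float]
    interaction_p_min: Optional[float]
    delta_aic: Optional[float]  # AIC(without) - AIC(with); <= threshold supports dropping
    residual_p: Optional[float]
    note: str = ""


def covariate_retention_check(
    data: pd.DataFrame,
    spec: ModelSpec,
    covariate: str,
    alpha: float = 0.05,
    aic_threshold: float = 2.0,
) -> CovariateDecision:
    """Three-part drop/keep decision for a precautionary covariate.

    Drop when (i) the covariate and its interactions with the factors are
    non-significant, (ii) removing it improves or does not meaningfully
    change AIC (within ``aic_threshold``), and (iii) residuals of the
    reduced model show no dependence on it.
    """
    if data[covariate].nunique() <= 1:
        return CovariateDecision(covariate, True, None, None, None, None,
                                 note="zero-variance (degenerate) covariate")

    covs_with = [c for c in spec.covariates if c != covariate] + [covariate]
    inter_with = list(spec.interactions or []) + [(f, covariate) for f in spec.factors]
    spec_with = ModelSpec(
        response=spec.response, factors=list(spec.factors), covariates=covs_with,
        interactions=inter_with, alpha=alpha, log10_response=spec.log10_response,
    )
    fit_with = Ancova(data, spec_with).fit(reduce_interactions=False)
    term_p = fit_with.term_p(covariate)
    inter_ps = []
    for f in spec.factors:
        label = _interaction_label((f, covariate), spec.factors)
        if label in fit_with.anova_table.index:
            inter_ps.append(float(fit_with.anova_table.loc[label, "PR(>F)"]))
    inter_p_min = min(inter_ps) if inter_ps else None

    spec_without = ModelSpec(
        response=spec.response, factors=list(spec.factors),
        covariates=[c for c in spec.covariates if c != covariate],
        interactions=list(spec.interactions or []), alpha=alpha,
        log10_response=spec.log10_response,
    )
    fit_without = Ancova(data, spec_without).fit(reduce_interactions=False)
    delta_aic = fit_without.aic - Ancova(data, ModelSpec(
        response=spec.response, factors=list(spec.factors), covariates=covs_with,
        interactions=list(spec.interactions or []), alpha=alpha,
        log10_response=spec.log10_response,
    )).fit(reduce_interactions=False).aic

    resid = fit_without.residuals
    x = sm.add_constant(data.loc[resid.index, covariate].to_numpy(dtype=float))
    resid_p = float(sm.OLS(resid.to_numpy(), x).fit().pvalues[1])

    crit_i = term_p >= alpha and (inter_p_min is None or inter_p_min >= alpha)
    crit_ii = delta_aic <= aic_threshold
    crit_iii = resid_p >= alpha
    return CovariateDecision(
        covariate=covariate,
        drop=bool(crit_i and crit_ii and crit_iii),
        term_p=term_p,
        interaction_p_min=inter_p_min,
        delta_aic=float(delta_aic),
        residual_p=resid_p,
    )


def ctmax_anova(
    data: pd.DataFrame,
    response: str = "ctmax_c",
    factors: Sequence[str] = ("habitat", "acclim_temp_c"),
    candidate_covariates: Sequence[str] = ("tl_cm", "mass_g", "acclim_days"),
    alpha: float = 0.05,
) -> AncovaResults:
    """CTmax comparison: covariate screen, then factorial ANOVA (or ANCOVA).

    Each candidate covariate is screened in an additive ANCOVA; if none is
    significant at ``alpha`` the factorial ANOVA (with the usual interaction
    reduction) is fitted. Significant covariates are retained and the
    ANCOVA path taken instead. The screen outcome is recorded in
    ``notes``.
    """
    screen: dict[str, float] = {}
    for cov in candidate_covariates:
        if cov not in data.columns or data[cov].nunique() <= 1:
            continue
        spec = ModelSpec(
            response=response, factors=list(factors), covariates=[cov],
            interactions=[], alpha=alpha,
        )
        screen[cov] = Ancova(data, spec).fit(reduce_interactions=False).term_p(cov)
    keep = [c for c, p in screen.items() if p < alpha]
    spec = ModelSpec(response=response, factors=list(factors), covariates=keep, alpha=alpha)
    out = Ancova(data, spec).fit(reduce_interactions=True)
    out.notes.append(
        "covariate screen: "
        + (", ".join(f"{c} p={p:.3g}" for c, p in screen.items()) or "none testable")
        + ("; ANCOVA path" if keep else "; factorial ANOVA path")
    )
    return out
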