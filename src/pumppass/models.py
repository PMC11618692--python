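"""Cohort statistics layer: trees, logistic/multinomial models, rank tests.

Every analysis is exposed statsmodels-style: a Model class built from coded
fish records (``from_records``) whose ``fit()`` returns a Results object
carrying estimates, uncertainties and a ``summary()`` table.

The layer covers:

* one-way ANOVA of fish length across scenarios with Tukey HSD post-hocs
  (checks whether scenarios received comparable fish);
* CART survival trees (Gini impurity, conservative split sizes and cost-
  complexity pruning) over species, passage type, rpm and length;
* per-species Bernoulli logistic survival models with rpm (discrete),
  length (continuous) and their interaction, reduced by stepwise AIC;
  strata with 100% survival are excluded before fitting because their
  coefficients and standard errors diverge (complete separation);
* a random-intercept (per release sample) logistic check — if the
  random-effect variance fits to zero (singular), plain logistic models are
  the recommendation;
* multinomial injury-class/injury-code models with stepwise AIC and
  delta-method confidence bands on category probabilities;
* a three-scenario pump comparison (fish-friendly pump at two rotation
  speeds versus the conventional pump) with and without length adjustment;
* Kruskal–Wallis omnibus tests on sensor parameters with pairwise
  Wilcoxon rank-sum post-hocs under Bonferroni correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, stats
from sklearn.tree import DecisionTreeClassifier

from .errors import (
    InsufficientData,
    MissingScenario,
    SingleCategory,
)

__all__ = [
    "p_stars",
    "stepwise_aic",
    "LengthAnovaModel",
    "LengthAnovaResults",
    "SurvivalTreeModel",
    "TreeFit",
    "SurvivalLogitModel",
    "SurvivalLogitResults",
    "mixed_model_check",
    "InjuryMultinomialModel",
    "InjuryMultinomialResults",
    "PumpComparisonModel",
    "PumpComparisonResults",
    "nonparametric_bds",
]


def p_stars(p: float) -> str:
    """Significance stars binned as printed in the figure captions."""
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    if p > 0.0001:
        return "***"
    return "****"


# ---------------------------------------------------------------------------
# stepwise AIC over formula terms
# ---------------------------------------------------------------------------

def _respects_hierarchy(terms: set[str]) -> bool:
    for t in terms:
        if ":" in t:
            if any(part not in terms for part in t.split(":")):
                return False
    return True


def stepwise_aic(fit_fn, terms: list[str], data: pd.DataFrame):
    """Bidirectional stepwise search minimizing AIC.

    ``fit_fn(term_list, data)`` must return a fitted statsmodels results
    object exposing ``.aic``. Starts from the full model and greedily adds or
    drops one term at a time, never breaking marginality (an interaction is
    only kept while both main effects are present). Returns
    ``(best_fit, best_terms)``; the selected model's AIC is never above the
    full or null model's.
    """
    current = set(terms)
    best = fit_fn(sorted(current, key=terms.index), data)
    improved = True
    while improved:
        improved = False
        candidates: list[set[str]] = []
        for t in list(current):
            trial = current - {t}
            if _respects_hierarchy(trial):
                candidates.append(trial)
        for t in terms:
            if t not in current:
                trial = current | {t}
                if _respects_hierarchy(trial):
                    candidates.append(trial)
        for trial in candidates:
            try:
                f = fit_fn(sorted(trial, key=terms.index), data)
            except Exception:  # separation/singularity on a candidate subset
                continue
            if f.aic < best.aic - 1e-9:
                best, current, improved = f, trial, True
    return best, sorted(current, key=terms.index)


# ---------------------------------------------------------------------------
# length ANOVA
# ---------------------------------------------------------------------------

@dataclass
class LengthAnovaResults:
    species: str
    f_stat: float
    p_value: float
    tukey: pd.DataFrame | None  # populated only when the omnibus test rejects

    def summary(self) -> str:
        lines = [
            f"Length ANOVA — {self.species}",
            f"F = {self.f_stat:.3f}, p = {self.p_value:.4g} ({p_stars(self.p_value)})",
        ]
        if self.tukey is not None:
            lines += ["Tukey HSD pairwise comparisons:", self.tukey.to_string(index=False)]
        else:
            lines.append("No post-hoc comparisons (omnibus p >= 0.05).")
        return "\n".join(lines)


class LengthAnovaModel:
    """One-way ANOVA of fish length across scenarios, per species."""

    def __init__(self, data: pd.DataFrame, species: str, alpha: float = 0.05):
        self.data = data[(data["species"] == species) & data["length_mm"].notna()]
        self.species = species
        self.alpha = alpha

    @classmethod
    def from_records(cls, records: pd.DataFrame, species: str) -> "LengthAnovaModel":
        return cls(records, species)

    def fit(self) -> LengthAnovaResults:
        counts = self.data.groupby("scenario")["length_mm"].count()
        if (counts >= 2).sum() < 2:
            raise InsufficientData(
                f"{self.species}: need >= 2 scenarios with >= 2 lengths"
            )
        ols = smf.ols("length_mm ~ C(scenario)", data=self.data).fit()
        table = sm.stats.anova_lm(ols, typ=2)
        f_stat = float(table.loc["C(scenario)", "F"])
        p = float(table.loc["C(scenario)", "PR(>F)"])
        tukey = None
        if p < self.alpha:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            res = pairwise_tukeyhsd(
                self.data["length_mm"].to_numpy(),
                self.data["scenario"].to_numpy(),
                alpha=self.alpha,
            )
            tukey = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
        return LengthAnovaResults(self.species, f_stat, p, tukey)


# ---------------------------------------------------------------------------
# decision trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    node_id: int
    depth: int
    split_variable: str | None  # None for leaves
    split_point: float | None
    n: int
    coverage_pct: float
    prop_dead: float
    prop_alive: float
    label: str  # "Dead" if prop_dead > 0.5 else "Alive"
    children: tuple[int, int] | None


@dataclass
class TreeFit:
    nodes: list[TreeNode]
    feature_names: list[str]
    response: str
    estimator: DecisionTreeClassifier | None = None

    @property
    def has_splits(self) -> bool:
        return len(self.nodes) > 1

    def summary(self) -> str:
        if not self.has_splits:
            root = self.nodes[0]
            return (
                f"No tree could be developed for response {self.response!r}: "
                f"no split passed the complexity control "
                f"(root: {root.label}, {root.prop_dead:.0%} dead)."
            )
        out = [f"Decision tree — response {self.response!r}"]
        for node in self.nodes:
            indent = "  " * node.depth
            head = (
                f"{indent}[{node.node_id}] {node.label} "
                f"({node.prop_dead:.2f}/{node.prop_alive:.2f}, {node.coverage_pct:.0f}%)"
            )
            if node.split_variable is not None:
                head += f" split: {node.split_variable} <= {node.split_point:.3g}"
            out.append(head)
        return "\n".join(out)

    def to_records(self) -> list[dict]:
        return [vars(n) for n in self.nodes]


class SurvivalTreeModel:
    """CART tree over coded fish records.

    Categorical predictors (species, type) are one-hot encoded, so a split
    reads e.g. ``species_bream <= 0.5`` ("is the fish a bream?"). Defaults
    are conservative (min 20 records per split, cost-complexity pruning with
    alpha 0.01) because the published trees are small; when no split survives
    pruning the fit degenerates to a labelled root, reported as "no tree".
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str = "survival",
        predictors: tuple[str, ...] = ("species", "type", "rpm", "length_mm"),
        min_samples_split: int = 20,
        ccp_alpha: float = 0.01,
        random_state: int = 0,
    ):
        self.response = response
        self.predictors = [p for p in predictors if p in data.columns]
        sub = data.dropna(subset=[response] + self.predictors)
        self.y = sub[response].astype(int).to_numpy()
        X = pd.get_dummies(
            sub[self.predictors],
            columns=[p for p in self.predictors if sub[p].dtype == object],
        )
        self.X = X.astype(float)
        self.min_samples_split = min_samples_split
        self.ccp_alpha = ccp_alpha
        self.random_state = random_state

    @classmethod
    def from_records(cls, records: pd.DataFrame, **kw) -> "SurvivalTreeModel":
        return cls(records, **kw)

    def fit(self) -> TreeFit:
        est = DecisionTreeClassifier(
            criterion="gini",
            min_samples_split=self.min_samples_split,
            ccp_alpha=self.ccp_alpha,
            random_state=self.random_state,
        )
        est.fit(self.X.to_numpy(), self.y)
        tree = est.tree_
        names = list(self.X.columns)
        total = self.y.size
        # dead = response 0; class order in tree.value follows est.classes_
        classes = list(est.classes_)
        nodes: list[TreeNode] = []

        def walk(i: int, depth: int) -> None:
            counts = tree.value[i][0] * tree.weighted_n_node_samples[i]
            n = int(round(tree.weighted_n_node_samples[i]))
            by_class = dict(zip(classes, counts))
            n_dead = by_class.get(0, 0.0)
            prop_dead = n_dead / max(n, 1)
            is_leaf = tree.children_left[i] == -1
            nodes.append(
                TreeNode(
                    node_id=i,
                    depth=depth,
                    split_variable=None if is_leaf else names[tree.feature[i]],
                    split_point=None if is_leaf else float(tree.threshold[i]),
                    n=n,
                    coverage_pct=100.0 * n / total,
                    prop_dead=prop_dead,
                    prop_alive=1.0 - prop_dead,
                    label="Dead" if prop_dead > 0.5 else "Alive",
                    children=None
                    if is_leaf
                    else (int(tree.children_left[i]), int(tree.children_right[i])),
                )
            )
            if not is_leaf:
                walk(int(tree.children_left[i]), depth + 1)
                walk(int(tree.children_right[i]), depth + 1)

        walk(0, 0)
        return TreeFit(nodes=nodes, feature_names=names, response=self.response,
                       estimator=est)


# ---------------------------------------------------------------------------
# logistic survival models
# ---------------------------------------------------------------------------

def _glm_logit(formula: str, data: pd.DataFrame):
    return smf.glm(formula, data=data, family=sm.families.Binomial()).fit()


def _exclude_separated_strata(
    data: pd.DataFrame, response: str, stratum: str
) -> tuple[pd.DataFrame, list[str]]:
    """Drop strata in which the response never varies (100% one outcome)."""
    excluded = []
    keep = pd.Series(True, index=data.index)
    for level, sub in data.groupby(stratum):
        if sub[response].nunique() < 2:
            excluded.append(str(level))
            keep.loc[sub.index] = False
    return data.loc[keep], excluded


@dataclass
class SurvivalLogitResults:
    species: str
    fit: object  # statsmodels GLMResults
    selected_terms: list[str]
    excluded_strata: list[str]
    reference_length: float
    scenario_predictions: pd.DataFrame

    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def bse(self) -> pd.Series:
        return self.fit.bse

    @property
    def pvalues(self) -> pd.Series:
        return self.fit.pvalues

    @property
    def aic(self) -> float:
        return float(self.fit.aic)

    def summary(self) -> str:
        lines = [
            f"Logistic survival model — {self.species}",
            f"selected terms: {self.selected_terms or ['(intercept only)']}",
            f"AIC = {self.aic:.2f}",
        ]
        if self.excluded_strata:
            lines.append(
                "excluded strata (single outcome, coefficients would diverge): "
                + ", ".join(self.excluded_strata)
            )
        coef = pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.pvalues}
        )
        coef["stars"] = coef["p"].map(p_stars)
        lines += [coef.to_string(), "", "Scenario predictions "
                  f"(at reference length {self.reference_length:.0f} mm):",
                  self.scenario_predictions.to_string(index=False)]
        return "\n".join(lines)

    def plot_scenarios(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sp = self.scenario_predictions
        x = np.arange(len(sp))
        ax.errorbar(
            x, sp["survival"],
            yerr=[sp["survival"] - sp["lo95"], sp["hi95"] - sp["survival"]],
            fmt="o", capsize=4,
        )
        ax.set_xticks(x, sp["scenario"])
        ax.set_ylabel("predicted survival probability")
        ax.set_ylim(0, 1)
        ax.set_title(self.species)
        return ax


class SurvivalLogitModel:
    """Per-species Bernoulli logistic survival model.

    Full model: rpm (discrete), length (continuous, centered at the species
    mean) and their interaction, reduced by bidirectional stepwise AIC when
    ``selection="stepwise_aic"``. Strata (scenarios) with a single outcome
    are excluded before fitting. Scenario-level predicted survival with 95%
    confidence bands is evaluated at a reference length (the species mean by
    default), using the asymptotic covariance on the link scale.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        species: str,
        predictors: tuple[str, ...] = ("rpm", "length_mm"),
        interaction: bool = True,
        reference_length: float | None = None,
    ):
        sub = data[(data["species"] == species) & (data["type"] == "pump")]
        sub = sub.dropna(subset=["survival"]).copy()
        self.species = species
        self.data = sub
        self.predictors = predictors
        self.interaction = interaction
        self.reference_length = reference_length

    @classmethod
    def from_records(cls, records: pd.DataFrame, species: str, **kw):
        return cls(records, species, **kw)

    def _terms(self) -> list[str]:
        terms = []
        if "rpm" in self.predictors:
            terms.append("C(rpm)")
        if "length_mm" in self.predictors:
            terms.append("length_c")
        if self.interaction and len(terms) == 2:
            terms.append("C(rpm):length_c")
        return terms

    def fit(self, selection: str = "stepwise_aic") -> SurvivalLogitResults:
        data, excluded = _exclude_separated_strata(self.data, "survival", "scenario")
        if data.empty or data["survival"].nunique() < 2:
            raise InsufficientData(
                f"{self.species}: no variation in survival after exclusions"
            )
        need_len = "length_mm" in self.predictors
        if need_len:
            data = data.dropna(subset=["length_mm"]).copy()
            ref = (
                self.reference_length
                if self.reference_length is not None
                else float(data["length_mm"].mean())
            )
            data["length_c"] = data["length_mm"] - ref
        else:
            ref = float("nan")
        terms = self._terms()

        def fit_fn(term_list, d):
            rhs = " + ".join(term_list) if term_list else "1"
            return _glm_logit(f"survival ~ {rhs}", d)

        if selection == "stepwise_aic":
            best, selected = stepwise_aic(fit_fn, terms, data)
        else:
            best, selected = fit_fn(terms, data), terms
        preds = self._scenario_predictions(best, data, ref)
        return SurvivalLogitResults(
            species=self.species,
            fit=best,
            selected_terms=selected,
            excluded_strata=excluded,
            reference_length=ref,
            scenario_predictions=preds,
        )

    @staticmethod
    def _scenario_predictions(fit, data: pd.DataFrame, ref: float) -> pd.DataFrame:
        rows = []
        for scen, sub in data.groupby("scenario"):
            new = pd.DataFrame(
                {"rpm": [sub["rpm"].iloc[0]], "length_c": [0.0], "scenario": [scen]}
            )
            pr = fit.get_prediction(new)
            sf = pr.summary_frame(alpha=0.05)
            rows.append(
                {
                    "scenario": scen,
                    "n": len(sub),
                    "survival": float(sf["mean"].iloc[0]),
                    "lo95": float(sf["mean_ci_lower"].iloc[0]),
                    "hi95": float(sf["mean_ci_upper"].iloc[0]),
                }
            )
        return pd.DataFrame(rows).sort_values("scenario").reset_index(drop=True)


# ---------------------------------------------------------------------------
# random-intercept logistic check (singular-fit fallback)
# ---------------------------------------------------------------------------

def _relogit_loglik(
    params: np.ndarray, X: np.ndarray, y: np.ndarray, groups: np.ndarray,
    gh_x: np.ndarray, gh_w: np.ndarray,
) -> float:
    """Negative marginal log-likelihood of a random-intercept logistic model.

    The per-group likelihood integrates the Bernoulli likelihood over a
    Gaussian random intercept by Gauss–Hermite quadrature:
    u = sqrt(2)·sigma·t_k, weight w_k / sqrt(pi).
    """
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    eta = X @ beta
    ll = 0.0
    for g in np.unique(groups):
        m = groups == g
        eta_g, y_g = eta[m], y[m]
        # (n_nodes, n_obs) linear predictors
        shift = np.sqrt(2.0) * sigma * gh_x
        lp = eta_g[None, :] + shift[:, None]
        logp = -np.logaddexp(0.0, -lp)  # log expit
        log1mp = -np.logaddexp(0.0, lp)
        contrib = (y_g[None, :] * logp + (1 - y_g[None, :]) * log1mp).sum(axis=1)
        mx = contrib.max()
        ll += mx + np.log((gh_w * np.exp(contrib - mx)).sum() / np.sqrt(np.pi))
    return -ll


def fit_random_intercept_logit(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, n_nodes: int = 21
) -> dict:
    """Maximum-likelihood random-intercept logistic fit (Gauss–Hermite).

    Returns the fixed effects, the random-intercept SD on the logit scale
    and both marginal and fixed-only log-likelihoods.
    """
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_nodes)
    start_beta = np.zeros(X.shape[1])
    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    start_beta = np.asarray(glm.params, dtype=float)
    res = optimize.minimize(
        _relogit_loglik,
        np.concatenate([start_beta, [np.log(0.5)]]),
        args=(X, y, groups, gh_x, gh_w),
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(np.log(1e-6), np.log(20.0))],
    )
    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    return {
        "beta": beta,
        "sigma_u": sigma,
        "loglik": -float(res.fun),
        "glm_loglik": float(glm.llf),
        "converged": bool(res.success),
    }


def mixed_model_check(
    records: pd.DataFrame,
    sample_col: str = "sample_id",
    response: str = "survival",
    min_per_sample: int = 6,
    singular_tol: float = 1e-2,
) -> dict:
    """Decide between mixed and simple logistic models.

    Fits a random-intercept (release sample) logistic model on samples with
    at least ``min_per_sample`` fish. If the fitted random-effect SD is
    essentially zero (singular fit) — or no sample is large enough to
    attempt the mixed model — plain logistic models are recommended.
    """
    counts = records.groupby(sample_col)[response].count()
    eligible = counts[counts >= min_per_sample].index
    sub = records[records[sample_col].isin(eligible)].dropna(subset=[response])
    if sub.empty or sub[response].nunique() < 2:
        return {
            "decision": "simple",
            "reason": "mixed model not attempted (no eligible samples)",
            "sigma_u": None,
            "n_samples_used": 0,
        }
    X = np.column_stack([np.ones(len(sub))])
    fitres = fit_random_intercept_logit(
        X, sub[response].to_numpy(float), sub[sample_col].to_numpy()
    )
    singular = fitres["sigma_u"] < singular_tol
    return {
        "decision": "simple" if singular else "mixed",
        "reason": "singular fit (random-effect variance ~ 0)"
        if singular
        else "between-sample variance retained",
        "sigma_u": fitres["sigma_u"],
        "loglik_mixed": fitres["loglik"],
        "loglik_simple": fitres["glm_loglik"],
        "n_samples_used": int(len(eligible)),
    }


# ---------------------------------------------------------------------------
# multinomial injury models
# ---------------------------------------------------------------------------

@dataclass
class InjuryMultinomialResults:
    species: str
    fit: object  # statsmodels MNLogitResults
    selected_terms: list[str]
    categories: list
    scenario_probabilities: pd.DataFrame

    @property
    def aic(self) -> float:
        return float(self.fit.aic)

    def predict_probs(self, new: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.fit.predict(new))

    def summary(self) -> str:
        lines = [
            f"Multinomial injury model — {self.species}",
            f"categories (reference first): {self.categories}",
            f"selected terms: {self.selected_terms or ['(intercept only)']}",
            f"AIC = {self.aic:.2f}",
            "Scenario category probabilities (95% CI):",
            self.scenario_probabilities.to_string(index=False),
        ]
        return "\n".join(lines)


class InjuryMultinomialModel:
    """Multinomial model for injury class (or code) versus rpm and length.

    The reference category is "no injury" (class 1) when present; reported
    per-category probabilities do not depend on that choice. Confidence
    bands on scenario-level category probabilities come from the delta
    method on the fitted parameter covariance.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        species: str,
        response: str = "injury_class",
        predictors: tuple[str, ...] = ("rpm", "length_mm"),
        interaction: bool = False,
        drop_uninjured_dead: bool = True,
    ):
        sub = data[(data["species"] == species) & (data["type"] == "pump")].copy()
        if drop_uninjured_dead and "survival" in sub.columns:
            # dead fish without any external injury carry no injury signal
            sub = sub[~((sub["survival"] == 0) & (sub[response].astype(str) == "1"))]
        self.data = sub.dropna(subset=[response])
        self.species = species
        self.response = response
        self.predictors = predictors
        self.interaction = interaction

    @classmethod
    def from_records(cls, records: pd.DataFrame, species: str, **kw):
        return cls(records, species, **kw)

    def _terms(self) -> list[str]:
        terms = []
        if "rpm" in self.predictors:
            terms.append("C(rpm)")
        if "length_mm" in self.predictors:
            terms.append("length_c")
        if self.interaction and len(terms) == 2:
            terms.append("C(rpm):length_c")
        return terms

    def fit(self, selection: str = "stepwise_aic") -> InjuryMultinomialResults:
        data = self.data.copy()
        cats = sorted(data[self.response].astype(str).unique(), key=str)
        if len(cats) < 2:
            raise SingleCategory(
                f"{self.species}: only one {self.response} category present"
            )
        if "1" in cats:  # no-injury first => MNLogit reference category
            cats = ["1"] + [c for c in cats if c != "1"]
        data["_cat"] = pd.Categorical(
            data[self.response].astype(str), categories=cats, ordered=False
        ).codes
        if "length_mm" in self.predictors:
            data = data.dropna(subset=["length_mm"])
            data["length_c"] = data["length_mm"] - data["length_mm"].mean()
        terms = self._terms()

        def fit_fn(term_list, d):
            rhs = " + ".join(term_list) if term_list else "1"
            return smf.mnlogit(f"_cat ~ {rhs}", data=d).fit(disp=0, maxiter=200)

        if selection == "stepwise_aic":
            best, selected = stepwise_aic(fit_fn, terms, data)
        else:
            best, selected = fit_fn(terms, data), terms
        probs = self._scenario_probabilities(best, data, cats)
        return InjuryMultinomialResults(
            species=self.species,
            fit=best,
            selected_terms=selected,
            categories=cats,
            scenario_probabilities=probs,
        )

    @staticmethod
    def _scenario_probabilities(fit, data: pd.DataFrame, cats: list[str]) -> pd.DataFrame:
        from patsy import dmatrix

        cov = np.asarray(fit.cov_params())
        params = np.asarray(fit.params)  # (k_exog, J-1)
        k, jm1 = params.shape
        design_info = fit.model.data.design_info
        rows = []
        for scen, sub in data.groupby("scenario"):
            new = pd.DataFrame(
                {"rpm": [sub["rpm"].iloc[0]], "length_c": [0.0], "scenario": [scen]}
            )
            exog = np.asarray(dmatrix(design_info, new, return_type="matrix"))

            def probs_at(theta: np.ndarray) -> np.ndarray:
                # cov_params orders coefficients per equation (column-major)
                return np.asarray(
                    fit.model.predict(theta.reshape((jm1, k)).T, exog)
                )[0]

            theta0 = params.T.ravel()
            base = probs_at(theta0)
            jac = np.empty((len(cats), theta0.size))
            h = 1e-6
            for j in range(theta0.size):
                tp = theta0.copy()
                tp[j] += h
                jac[:, j] = (probs_at(tp) - base) / h
            var = np.einsum("ij,jk,ik->i", jac, cov, jac)
            se = np.sqrt(np.clip(var, 0.0, None))
            for c, p, s in zip(cats, base, se):
                rows.append(
                    {
                        "scenario": scen,
                        "category": c,
                        "prob": float(p),
                        "lo95": float(max(p - 1.959964 * s, 0.0)),
                        "hi95": float(min(p + 1.959964 * s, 1.0)),
                        "n": len(sub),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pump comparison (fish-friendly vs conventional)
# ---------------------------------------------------------------------------

@dataclass
class PumpComparisonResults:
    fit_with_length: object
    fit_without_length: object
    contrasts: pd.DataFrame
    length_imbalance_p: float

    def summary(self) -> str:
        lines = ["Pump comparison (scenario contrasts on survival)"]
        if self.length_imbalance_p < 0.05:
            lines.append(
                f"WARNING: fish length differs between scenarios "
                f"(ANOVA p = {self.length_imbalance_p:.3g}); length-adjusted "
                "contrasts are the safer read."
            )
        lines.append(self.contrasts.to_string(index=False))
        return "\n".join(lines)


class PumpComparisonModel:
    """Three-scenario survival comparison for one species (default roach).

    Scenarios: the fish-friendly pump at its two rotation speeds and the
    conventional pump. Fits logistic models with and without length
    adjustment and reports pairwise scenario contrasts (log-odds difference,
    SE, p) from each.
    """

    def __init__(self, data: pd.DataFrame, species: str = "roach",
                 scenarios: tuple[str, ...] = ("FNAFP_468", "FNAFP_550", "CAFP_585")):
        sub = data[
            (data["species"] == species)
            & (data["type"] == "pump")
            & (data["scenario"].isin(scenarios))
        ].dropna(subset=["survival", "length_mm"]).copy()
        present = set(sub["scenario"])
        missing = [s for s in scenarios if s not in present]
        if missing:
            raise MissingScenario(f"missing scenario level(s): {missing}")
        self.data = sub
        self.scenarios = scenarios
        self.species = species

    @classmethod
    def from_records(cls, records: pd.DataFrame, **kw):
        return cls(records, **kw)

    def fit(self) -> PumpComparisonResults:
        d = self.data.copy()
        d["length_c"] = d["length_mm"] - d["length_mm"].mean()
        with_len = _glm_logit("survival ~ C(scenario) + length_c", d)
        without = _glm_logit("survival ~ C(scenario)", d)
        anova_p = float(
            sm.stats.anova_lm(
                smf.ols("length_mm ~ C(scenario)", data=d).fit(), typ=2
            ).loc["C(scenario)", "PR(>F)"]
        )
        rows = []
        for model_name, fit in (("with_length", with_len), ("without_length", without)):
            names = list(fit.params.index)
            for a, b in itertools.combinations(self.scenarios, 2):
                vec = np.zeros(len(names))
                for scen, sign in ((a, 1.0), (b, -1.0)):
                    col = f"C(scenario)[T.{scen}]"
                    if col in names:
                        vec[names.index(col)] += sign
                tt = fit.t_test(vec)
                rows.append(
                    {
                        "model": model_name,
                        "contrast": f"{a} - {b}",
                        "log_odds_diff": float(np.squeeze(tt.effect)),
                        "se": float(np.squeeze(tt.sd)),
                        "p": float(np.squeeze(tt.pvalue)),
                        "stars": p_stars(float(np.squeeze(tt.pvalue))),
                    }
                )
        return PumpComparisonResults(
            fit_with_length=with_len,
            fit_without_length=without,
            contrasts=pd.DataFrame(rows),
            length_imbalance_p=anova_p,
        )


# ---------------------------------------------------------------------------
# nonparametric tests on sensor parameters
# ---------------------------------------------------------------------------

def nonparametric_bds(
    values_by_scenario: dict[str, np.ndarray] | pd.DataFrame,
    value_col: str | None = None,
    alpha: float = 0.05,
) -> dict:
    """Kruskal–Wallis omnibus test with Bonferroni-corrected rank-sum post-hocs.

    Deployments are unpaired across scenarios, so the pairwise tests are
    two-sample Wilcoxon rank-sum (Mann–Whitney) tests; their raw p-values
    are Bonferroni-multiplied by the number of pairs actually tested.
    Post-hocs run only when the omnibus test is significant.
    """
    if isinstance(values_by_scenario, pd.DataFrame):
        if value_col is None:
            raise ValueError("value_col required with a DataFrame input")
        groups = {
            str(k): v[value_col].to_numpy(float)
            for k, v in values_by_scenario.groupby("scenario")
        }
    else:
        groups = {str(k): np.asarray(v, float) for k, v in values_by_scenario.items()}
    groups = {k: v for k, v in groups.items() if v.size > 0}
    if len(groups) < 2:
        raise InsufficientData("need >= 2 scenarios for the omnibus test")
    samples = list(groups.values())
    if all(np.array_equal(samples[0], s) for s in samples[1:]):
        kw_stat, kw_p = 0.0, 1.0  # identical samples carry no rank signal
    else:
        kw_stat, kw_p = stats.kruskal(*samples)
    pairwise = []
    if kw_p < alpha:
        pairs = list(itertools.combinations(sorted(groups), 2))
        m = len(pairs)
        for a, b in pairs:
            stat, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            p_adj = min(1.0, m * p)
            pairwise.append(
                {
                    "a": a,
                    "b": b,
                    "u_stat": float(stat),
                    "p_raw": float(p),
                    "p_bonferroni": float(p_adj),
                    "stars": p_stars(p_adj),
                }
            )
    return {
        "kw_stat": float(kw_stat),
        "kw_p": float(kw_p),
        "kw_stars": p_stars(float(kw_p)),
        "pairwise": pd.DataFrame(pairwise),
        "n_per_scenario": {k: int(v.size) for k, v in groups.items()},
    }
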