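"""Mixed-effects inference linking semantic structure to word recognition.

The response is the trial-level log-gaze proportion ratio; fixed effects are
the three structure metrics (global clustering coefficient, target-word
degree, category density) and median-split vocabulary group with all
structure x group interactions; the single random effect is an intercept per
item (target word).  Categorical predictors are sum coded (High = -0.5,
Low = +0.5), continuous predictors standardized within the modeled subset.
Conditions (semantically related / unrelated) are always modeled separately.

The estimation surface follows the statsmodels idiom: :class:`LogGazeModel`
is built from a coded design table, ``fit()`` returns a
:class:`LogGazeResults` carrying estimates, standard errors, z-based
p-values, the fixed-effect correlation matrix and a ``summary()`` panel.
The numerical optimisation is delegated to ``statsmodels`` ``MixedLM``
(REML).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import StructureMetrics
from .vocab import DensityAssignment, VocabGroupAssignment

SUM_CODE = {"High": -0.5, "Low": 0.5}

#: fixed-effect display labels in printed order
TERM_LABELS = {
    "Intercept": "(Intercept)",
    "group_code": "Vocabulary Group",
    "density_code": "Semantic Category Density",
    "degree_z": "Word Degree",
    "gcc_z": "Global Cluster Coefficient",
    "group_code:density_code": "Voc. Grp x Semantic Category Density",
    "group_code:degree_z": "Voc. Grp x Word Degree",
    "group_code:gcc_z": "Voc. Grp x GCC",
}
FULL_TERMS = [
    "Intercept", "group_code", "density_code", "degree_z", "gcc_z",
    "group_code:density_code", "group_code:degree_z", "group_code:gcc_z",
]
GROUP_TERMS = ["Intercept", "density_code", "degree_z", "gcc_z"]


def build_design(
    retained,
    metrics: dict[str, StructureMetrics],
    density: dict[str, DensityAssignment],
    groups: VocabGroupAssignment,
    item_categories: dict[str, str],
) -> pd.DataFrame:
    """Assemble the raw (uncoded) trial-level design table.

    ``retained`` is a list of (GazeTrial, TrialAccuracy) pairs surviving the
    exclusion filters.  Each row carries the response and the child's raw
    structure metrics for the trial's target word; coding and standardization
    happen per modeled subset in :func:`code_predictors`.
    """
    missing = sorted(
        {t.trial_id for t, _ in retained
         if t.child_id not in metrics or t.child_id not in density
         or t.child_id not in groups.group}
    )
    if missing:
        raise ValueError(f"missing metrics/assignments for trials: {missing}")
    rows = []
    for trial, acc in retained:
        m = metrics[trial.child_id]
        dens = density[trial.child_id]
        cat = item_categories[trial.target]
        rows.append(
            {
                "trial_id": trial.trial_id,
                "child_id": trial.child_id,
                "condition": trial.condition,
                "item": trial.target,
                "log_gaze": acc.log_gaze,
                "gcc": m.gcc,
                "degree": m.degree[trial.target],
                "density_level": dens.condition[cat],
                "group_level": groups.group[trial.child_id],
            }
        )
    return pd.DataFrame(rows)


def code_predictors(
    design: pd.DataFrame,
    condition: str | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Subset to the modeled scope and code/standardize predictors.

    Continuous predictors are z-scored with the sample SD (ddof=1) within
    the subset; High levels of density and vocabulary group code to -0.5 and
    Low to +0.5.  Degenerate (zero-variance) continuous predictors are
    rejected.
    """
    sub = design
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    if group is not None:
        sub = sub[sub["group_level"] == group]
    sub = sub.copy()
    if sub.empty:
        raise ValueError(f"no trials in scope condition={condition} group={group}")
    for col, zcol in (("gcc", "gcc_z"), ("degree", "degree_z")):
        x = sub[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"degenerate predictor {col!r}: zero variance in subset")
        sub[zcol] = (x - x.mean()) / sd
    sub["density_code"] = sub["density_level"].map(SUM_CODE)
    sub["group_code"] = sub["group_level"].map(SUM_CODE)
    return sub


@dataclass
class LogGazeResults:
    """Fitted fixed effects with uncertainties and diagnostics."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fe_corr: pd.DataFrame
    re_var: float
    scale: float
    converged: bool
    n_trials: int
    n_items: int
    grouping: str
    model_label: str = ""

    def term_frame(self) -> pd.DataFrame:
        """Tidy per-term table with significance flags."""
        df = pd.DataFrame(
            {
                "term": [TERM_LABELS.get(t, t) for t in self.params.index],
                "estimate": self.params.values,
                "std_error": self.bse.values,
                "t_value": self.tvalues.values,
                "p_value": self.pvalues.values,
            }
        )
        df["significant"] = df["p_value"] < 0.05
        df["marginal"] = (df["p_value"] >= 0.05) & (df["p_value"] < 0.1)
        return df

    def summary(self) -> str:
        lines = []
        title = self.model_label or "Log-gaze mixed model"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(
            f"n_trials={self.n_trials}  n_items={self.n_items}  "
            f"random effects: {self.grouping}  converged={self.converged}"
        )
        lines.append(
            f"item intercept variance={self.re_var:.4f}  residual={self.scale:.4f}"
        )
        lines.append(f"{'term':<40}{'Estimate':>10}{'Std.Err':>10}"
                     f"{'t-value':>10}{'p-value':>10}")
        for _, r in self.term_frame().iterrows():
            mark = "*" if r["significant"] else ("." if r["marginal"] else " ")
            lines.append(
                f"{r['term']:<40}{r['estimate']:>10.3f}{r['std_error']:>10.3f}"
                f"{r['t_value']:>10.2f}{r['p_value']:>10.3g} {mark}"
            )
        lines.append("Correlation of fixed effects:")
        lines.append(self.fe_corr.round(3).to_string())
        lines.append("p-values: normal approximation on t (z-test).")
        return "\n".join(lines)


class LogGazeModel:
    """Linear mixed model for trial-level log-gaze accuracy.

    Parameters
    ----------
    design
        Coded design table from :func:`code_predictors`.
    terms
        Fixed-effect term names; ``a:b`` denotes a product.  Defaults to the
        full structure x vocabulary-group specification.
    participants
        ``"drop"`` (default) uses items as the only random effect;
        ``"vc"`` re-adds a crossed child intercept through variance
        components as a sensitivity analysis (slower).
    """

    def __init__(
        self,
        design: pd.DataFrame,
        terms: list[str] | None = None,
        participants: str = "drop",
    ) -> None:
        self.design = design.reset_index(drop=True)
        self.terms = list(terms) if terms is not None else list(FULL_TERMS)
        if self.terms[0] != "Intercept":
            self.terms = ["Intercept"] + self.terms
        if participants not in ("drop", "vc"):
            raise ValueError("participants must be 'drop' or 'vc'")
        self.participants = participants
        self.endog = self.design["log_gaze"].to_numpy(dtype=float)
        self.exog = self._build_exog(self.design)

    @classmethod
    def from_design(
        cls,
        design: pd.DataFrame,
        condition: str | None = None,
        group: str | None = None,
        **kwargs,
    ) -> "LogGazeModel":
        """Code predictors for the given scope and build the model.

        With ``group`` set, the fixed effects reduce to the three structure
        terms (the vocabulary-group factor is constant in the subset).
        """
        coded = code_predictors(design, condition=condition, group=group)
        terms = GROUP_TERMS if group is not None else FULL_TERMS
        return cls(coded, terms=terms, **kwargs)

    def _build_exog(self, df: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for t in self.terms:
            if t == "Intercept":
                cols[t] = np.ones(len(df))
            elif ":" in t:
                a, b = t.split(":")
                cols[t] = df[a].to_numpy(float) * df[b].to_numpy(float)
            else:
                cols[t] = df[t].to_numpy(float)
        return pd.DataFrame(cols, index=df.index)

    def fit(self, reml: bool = True, maxiter: int = 200) -> LogGazeResults:
        """Estimate by (restricted) maximum likelihood via MixedLM."""
        import statsmodels.regression.mixed_linear_model as mlm

        items = self.design["item"].to_numpy()
        n_items = len(np.unique(items))
        if np.ptp(self.endog) == 0.0:
            return self._degenerate_results(n_items)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.participants == "drop":
                model = mlm.MixedLM(self.endog, self.exog, groups=items)
                grouping = "(1 | item)"
            else:
                # crossed item + child intercepts as variance components of a
                # single all-encompassing group (sensitivity analysis)
                df = self.exog.copy()
                df.columns = [f"x{i}" for i in range(len(self.terms))]
                df["log_gaze"] = self.endog
                df["item"] = items
                df["child_id"] = self.design["child_id"].to_numpy()
                df["_one"] = 1
                vcf = {"item": "0 + C(item)", "child": "0 + C(child_id)"}
                rhs = " + ".join(f"x{i}" for i in range(len(self.terms)))
                model = mlm.MixedLM.from_formula(
                    f"log_gaze ~ 0 + {rhs}",
                    groups="_one",
                    vc_formula=vcf,
                    data=df,
                )
                grouping = "(1 | item) + (1 | child) [variance components]"
            fitted = model.fit(reml=reml, maxiter=maxiter)
        converged = bool(getattr(fitted, "converged", True))
        if not converged:
            warnings.warn("mixed model did not converge; results flagged",
                          stacklevel=2)
        k = len(self.terms)
        params = pd.Series(np.asarray(fitted.fe_params)[:k], index=self.terms)
        cov = np.asarray(fitted.cov_params())[:k, :k]
        bse = pd.Series(np.sqrt(np.diag(cov)), index=self.terms)
        tvals = params / bse.replace(0.0, np.nan)
        tvals = tvals.fillna(0.0)
        pvals = pd.Series(
            2.0 * stats.norm.sf(np.abs(tvals.to_numpy())), index=self.terms
        )
        d = np.sqrt(np.diag(cov))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        labels = [TERM_LABELS.get(t, t) for t in self.terms]
        fe_corr = pd.DataFrame(corr, index=labels, columns=labels)
        re_var = float(np.asarray(fitted.cov_re).ravel()[0]) if fitted.cov_re.size else 0.0
        return LogGazeResults(
            params=params,
            bse=bse,
            tvalues=tvals,
            pvalues=pvals,
            fe_corr=fe_corr,
            re_var=re_var,
            scale=float(fitted.scale),
            converged=converged,
            n_trials=len(self.endog),
            n_items=n_items,
            grouping=grouping,
        )

    def _degenerate_results(self, n_items: int) -> LogGazeResults:
        # constant response: every coefficient is exactly its OLS value 0
        # (save the intercept, equal to the constant) with no uncertainty
        const = float(self.endog[0])
        params = pd.Series(0.0, index=self.terms)
        params["Intercept"] = const
        zeros = pd.Series(0.0, index=self.terms)
        pvals = pd.Series(1.0, index=self.terms)
        labels = [TERM_LABELS.get(t, t) for t in self.terms]
        fe_corr = pd.DataFrame(
            np.eye(len(self.terms)), index=labels, columns=labels
        )
        return LogGazeResults(
            params=params, bse=zeros, tvalues=zeros, pvalues=pvals,
            fe_corr=fe_corr, re_var=0.0, scale=0.0, converged=True,
            n_trials=len(self.endog), n_items=n_items, grouping="(1 | item)",
        )


def fit_condition_model(
    design: pd.DataFrame, condition: str, participants: str = "drop"
) -> LogGazeResults:
    """Full structure x vocabulary-group model for one condition."""
    model = LogGazeModel.from_design(
        design, condition=condition, participants=participants
    )
    res = model.fit()
    res.model_label = f"{condition} trials, all participants"
    return res


def fit_group_model(
    design: pd.DataFrame, condition: str, group: str, participants: str = "drop"
) -> LogGazeResults:
    """Structure-only model on one vocabulary group within a condition."""
    model = LogGazeModel.from_design(
        design, condition=condition, group=group, participants=participants
    )
    res = model.fit()
    res.model_label = f"{condition} trials, {group} vocabulary group"
    return res


def model_report(results: list[LogGazeResults]) -> tuple[pd.DataFrame, str]:
    """Combined tidy table and printed panels for a set of fitted models.

    One panel per model in the order given, terms in printed order,
    fixed-effect correlations appended; ``significant`` flags p < .05 and
    ``marginal`` .05 <= p < .1.
    """
    if not results:
        raise ValueError("no results to report")
    frames = []
    panels = []
    for res in results:
        tf = res.term_frame()
        tf.insert(0, "model", res.model_label or "model")
        frames.append(tf)
        panels.append(res.summary())
    return pd.concat(frames, ignore_index=True), "\n\n".join(panels)
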