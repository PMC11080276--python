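"""Model/Results objects presenting the network analysis statsmodels-style.

``DiscreteBNModel`` is built from a fully discrete table (typically a
discretized case-control cohort); ``fit()`` runs tabu-search structure
learning followed by maximum-likelihood parameter learning and returns a
``DiscreteBNResults`` carrying the learned network, its BIC score,
diagnostics and query methods.  ``CaseControlPipeline`` wires the whole
published analysis together for one disease: univariate screening ->
forward-LR stepwise logistic selection -> discretization -> stratified
70/30 split -> network learning -> hold-out validation -> sensitivity
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesnet import BayesNet
from .codebook import GROUP_COLUMN, Codebook, default_codebook, discretize
from .evaluation import evaluate_holdout
from .inference import diagnostic_profile, predictive_probability, query
from .logistic import (
    LogisticFit,
    StepwiseStep,
    build_design,
    stepwise_forward_lr,
)
from .parameters import fit_cpts, network_loglik
from .screening import screen_variables, selected_variables
from .sensitivity import sensitivity_table
from .structure import (
    BICScorer,
    EdgeConstraints,
    ScoredDAG,
    SearchParams,
    immutable_blacklist,
    tabu_search,
    train_test_split,
)


class DiscreteBNModel:
    """Discrete Bayesian network learned from a rectangular data table.

    Parameters
    ----------
    data : DataFrame
        Fully discrete table; every column becomes a node (a ``group``
        column, if present, is dropped).
    constraints : EdgeConstraints, optional
        Expert priors: forced and forbidden edges.
    search : SearchParams, optional
        Tabu-search settings (tenure 10, max 1000 iterations, stop after
        50 non-improving moves).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        constraints: EdgeConstraints | None = None,
        search: SearchParams | None = None,
    ):
        self.data = data.drop(columns=[GROUP_COLUMN], errors="ignore")
        self.constraints = constraints or EdgeConstraints()
        self.search = search or SearchParams()
        self.scorer = BICScorer(self.data)

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        disease: str,
        variables: list[str],
        codebook: Codebook | None = None,
        **kwargs,
    ) -> "DiscreteBNModel":
        """Build from an encoded cohort: discretize and add the disease node."""
        codebook = codebook or default_codebook()
        sub = cohort[cohort[GROUP_COLUMN].isin(["control", disease])]
        table = discretize(sub[variables + [GROUP_COLUMN]], codebook)
        table = table.copy()
        table[disease] = (table[GROUP_COLUMN] == disease).astype(int)
        table = table.drop(columns=[GROUP_COLUMN])
        if "constraints" not in kwargs:
            kwargs["constraints"] = immutable_blacklist(table.columns)
        return cls(table, **kwargs)

    def fit(self, *, smooth: float = 0.0) -> "DiscreteBNResults":
        """Learn structure (tabu/BIC) then parameters (MLE CPTs)."""
        scored = tabu_search(
            self.data,
            self.constraints,
            self.search,
            scorer=self.scorer,
        )
        states = {
            n: self.scorer.state_values[n] for n in scored.dag.nodes
        }
        net = fit_cpts(scored.dag, self.data, states=states, smooth=smooth)
        return DiscreteBNResults(model=self, scored=scored, net=net)


@dataclass
class DiscreteBNResults:
    """Learned network with its score and inference/reporting methods."""

    model: DiscreteBNModel
    scored: ScoredDAG
    net: BayesNet

    @property
    def dag(self):
        return self.scored.dag

    @property
    def bic(self) -> float:
        return self.scored.score

    def loglik(self, data: pd.DataFrame | None = None) -> float:
        return network_loglik(
            self.net, data if data is not None else self.model.data
        )

    def query(self, target: str, evidence: dict | None = None) -> pd.Series:
        return query(self.net, target, evidence)

    def predict_proba(
        self, disease: str, evidence: dict | None = None
    ) -> float:
        return predictive_probability(self.net, disease, evidence)

    def diagnostic_profile(self, disease: str, state=1) -> pd.DataFrame:
        return diagnostic_profile(self.net, disease, state)

    def sensitivity(self, target: str, **kwargs) -> pd.DataFrame:
        return sensitivity_table(self.net, target, **kwargs)

    def summary(self) -> str:
        dag = self.scored.dag
        lines = [
            "Discrete Bayesian network (tabu search, BIC)",
            "=" * 44,
            f"nodes:            {len(dag.nodes)}",
            f"directed edges:   {len(dag.edges)}",
            f"BIC score:        {self.scored.score:.3f}",
            f"sample size:      {self.model.scorer.n}",
            "",
            "edges:",
        ]
        for u, v in sorted(dag.edges):
            lines.append(f"  {u} -> {v}")
        return "\n".join(lines)


@dataclass
class PipelineResults:
    """Every stage's output for one disease analysis."""

    disease: str
    screening_report: pd.DataFrame
    logistic_fit: LogisticFit
    logistic_trace: list[StepwiseStep]
    selected: list[str]
    bn_results: DiscreteBNResults
    evaluation: dict
    sensitivity: pd.DataFrame
    train: pd.DataFrame = field(repr=False, default=None)
    test: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        m = self.evaluation["metrics"]
        cm = self.evaluation["confusion"]
        roc = self.evaluation["roc"]
        lines = [
            f"Case-control BN analysis: {self.disease} vs control",
            "=" * 48,
            f"screened variables (P<0.05): "
            f"{int(self.screening_report['selected'].sum())} of "
            f"{len(self.screening_report)}",
            f"stepwise-selected variables: {len(self.selected)}",
            f"  {', '.join(self.selected)}",
            "",
            self.bn_results.summary(),
            "",
            "hold-out validation (30% test set):",
            f"  confusion: TP={cm.tp} FP={cm.fp} FN={cm.fn} TN={cm.tn}",
            f"  accuracy:    {m.accuracy:.4f}",
            f"  precision:   {m.precision:.4f}",
            f"  sensitivity: {m.sensitivity:.4f}",
            f"  specificity: {m.specificity:.4f}",
            f"  AUC: {roc.auc:.3f} (95% CI {roc.ci_low:.3f} ~ "
            f"{roc.ci_high:.3f})",
            "",
            "top sensitivity (variance reduction %):",
        ]
        for _, row in self.sensitivity.head(5).iterrows():
            lines.append(
                f"  {row['variable']:<14s} "
                f"{row['variance_reduction_pct']:6.2f}"
            )
        return "\n".join(lines)


class CaseControlPipeline:
    """The full published analysis for one disease vs the control group."""

    def __init__(
        self,
        cohort: pd.DataFrame,
        disease: str,
        codebook: Codebook | None = None,
        *,
        alpha: float = 0.05,
        p_enter: float = 0.05,
        p_remove: float = 0.10,
        train_fraction: float = 0.7,
        search: SearchParams | None = None,
        constraints: EdgeConstraints | None = None,
    ):
        self.cohort = cohort
        self.disease = disease
        self.codebook = codebook or default_codebook()
        self.alpha = alpha
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.train_fraction = train_fraction
        self.search = search
        self.constraints = constraints

    def fit(self, seed: int = 0, *, smooth: float = 0.0) -> PipelineResults:
        cohort, disease, codebook = self.cohort, self.disease, self.codebook
        report = screen_variables(cohort, disease, codebook, self.alpha)
        screened = selected_variables(report)

        design = build_design(cohort, disease, screened, codebook)
        logit_fit, trace = stepwise_forward_lr(
            design, p_enter=self.p_enter, p_remove=self.p_remove
        )
        selected = [
            v for v in design.terms
            if any(c in logit_fit.params.index for c in design.terms[v])
        ]
        if not selected:  # degenerate null data: keep the screened set
            selected = screened

        sub = cohort[cohort[GROUP_COLUMN].isin(["control", disease])]
        table = discretize(sub[selected + [GROUP_COLUMN]], codebook)
        table[disease] = (table[GROUP_COLUMN] == disease).astype(int)
        train, test = train_test_split(table, self.train_fraction, seed)
        train = train.drop(columns=[GROUP_COLUMN])
        test = test.drop(columns=[GROUP_COLUMN])

        constraints = self.constraints or immutable_blacklist(train.columns)
        model = DiscreteBNModel(
            train, constraints=constraints, search=self.search
        )
        bn_results = model.fit(smooth=smooth)
        evaluation = evaluate_holdout(bn_results.net, test, disease)
        sens = sensitivity_table(bn_results.net, disease)
        return PipelineResults(
            disease=disease,
            screening_report=report,
            logistic_fit=logit_fit,
            logistic_trace=trace,
            selected=selected,
            bn_results=bn_results,
            evaluation=evaluation,
            sensitivity=sens,
            train=train,
            test=test,
        )
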