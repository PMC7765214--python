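"""Model/Results layer over the learners, in the style of statsmodels.

A model is constructed from data plus the name of the (binary) target
variable; ``fit()`` learns a structure and its CPT parameters and returns
a :class:`BayesResults` carrying the network, fit diagnostics, parameter
standard errors and a text ``summary()``.  Posterior queries, what-if
analysis, genetic explanation search, prediction and cross-validation all
hang off the results object.

    >>> model = SonsAndSpouses(data, target="depression")
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.what_if({"subjective_health": "very_bad"})
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatable import DataTable, exclude_incomplete
from .exceptions import ConfigurationError
from .learning import (
    LearnerConfig,
    cpt_standard_errors,
    family_bic,
    learn_naive_bayes,
    learn_sons_and_spouses,
    learn_tan,
    select_features,
)
from .metrics import arc_force_report, target_report
from .mre import ExplanationResult, GAConfig, run_ga, whatif
from .network import BayesianNetwork, DiscreteVariable, posterior


class DiscreteBayesModel:
    """Base class: discrete Bayesian classifier around a binary target."""

    _learn = None
    _method = "base"

    def __init__(
        self,
        data: DataTable,
        target: str,
        config: LearnerConfig | None = None,
    ) -> None:
        if target not in {v.name for v in data.variables}:
            raise ConfigurationError(f"target column {target!r} not in data")
        self.data = data
        self.target = target
        self.config = config or LearnerConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        target: str,
        config: LearnerConfig | None = None,
        state_orders: dict[str, Sequence[str]] | None = None,
    ) -> "DiscreteBayesModel":
        """Build from a raw DataFrame; states default to sorted uniques."""
        state_orders = state_orders or {}
        variables = []
        for col in df.columns:
            if col in state_orders:
                states = tuple(state_orders[col])
            else:
                uniq = df[col].dropna().astype(str)
                uniq = uniq[uniq != ""]
                states = tuple(sorted(uniq.unique()))
            role = "target" if col == target else "feature"
            variables.append(DiscreteVariable(col, states, role))
        table = DataTable.from_strings(variables, df.astype(object))
        return cls(table, target, config)

    def fit(self) -> "BayesResults":
        net = type(self)._learn(self.data, self.target, self.config)
        return BayesResults(self, net)


class NaiveBayes(DiscreteBayesModel):
    """All features are children of the target."""

    _learn = staticmethod(learn_naive_bayes)
    _method = "nb"


class TreeAugmentedNB(DiscreteBayesModel):
    """Naive Bayes augmented with a feature tree (max conditional MI)."""

    _learn = staticmethod(learn_tan)
    _method = "tan"


class SonsAndSpouses(DiscreteBayesModel):
    """Target neighbourhood learner with built-in feature selection."""

    _learn = staticmethod(learn_sons_and_spouses)
    _method = "ss"


class BayesResults:
    """Fitted network plus diagnostics."""

    def __init__(self, model: DiscreteBayesModel, network: BayesianNetwork):
        self.model = model
        self.network = network
        cleaned, report = exclude_incomplete(
            model.data, model.config.max_missing_fraction
        )
        self.n_obs = report.retained
        self.n_excluded = report.excluded
        self._cleaned = cleaned

    # -- diagnostics --------------------------------------------------------

    @property
    def selected_features(self) -> set[str]:
        return select_features(self.network, self.model.target)

    @property
    def sons(self) -> tuple[str, ...]:
        return self.network.structure.children(self.model.target)

    def bic(self) -> float:
        return sum(
            family_bic(self._cleaned, name, self.network.structure.parents(name))
            for name in self.network.variables
        )

    def param_standard_errors(self) -> dict[str, np.ndarray]:
        return cpt_standard_errors(self.network, self._cleaned)

    def arc_forces(self, smoothing: float | None = None) -> pd.DataFrame:
        s = self.model.config.smoothing if smoothing is None else smoothing
        return arc_force_report(self.network, self._cleaned, smoothing=s)

    def target_report(self) -> pd.DataFrame:
        return target_report(self.network, self._cleaned, self.model.target)

    # -- queries ------------------------------------------------------------

    def posterior(self, query: str, evidence: dict[str, str] | None = None):
        return posterior(self.network, query, evidence or {})

    def what_if(self, evidence: dict[str, str], target_state: str | None = None):
        return whatif(self.network, evidence, self.model.target, target_state)

    def most_probable_cause(
        self,
        target_state: str | None = None,
        candidates: list[str] | None = None,
        ga_config: GAConfig | None = None,
    ) -> list[ExplanationResult]:
        """GA search for the explanation with the largest GBF for the
        hypothesis that the target is in ``target_state``."""
        tvar = self.network.variable(self.model.target)
        state = target_state or tvar.states[-1]
        cands = candidates or sorted(
            n for n in self.network.variables if n != self.model.target
        )
        return run_ga(self.network, {self.model.target: state}, cands, ga_config)

    def predict(self, data: DataTable) -> pd.DataFrame:
        from .evaluation import classify

        rows = []
        for i in range(data.n_rows):
            record = {k: v for k, v in data.record(i).items()
                      if k != self.model.target}
            pred, score, fallback = classify(self.network, record, self.model.target)
            rows.append({"prediction": pred, "score": score,
                         "prior_fallback": fallback})
        return pd.DataFrame(rows)

    def cross_validate(self, k: int = 10, seed: int = 0):
        from .evaluation import evaluate_cv

        return evaluate_cv(
            self.model.data, type(self.model)._method, k=k, seed=seed,
            config=self.model.config, target=self.model.target,
        )

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        net = self.network
        lines = []
        title = f"{type(self.model).__name__} results"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"Target:              {self.model.target}")
        lines.append(f"Observations used:   {self.n_obs} "
                      f"(excluded {self.n_excluded})")
        lines.append(f"Variables in model:  {len(net.variables)}")
        lines.append(f"Arcs:                {len(net.structure.arcs)}")
        lines.append(f"Direct children:     {len(self.sons)} "
                      f"({', '.join(self.sons) if self.sons else '-'})")
        spouses = sorted(self.selected_features - set(self.sons))
        lines.append(f"Spouses:             {len(spouses)} "
                      f"({', '.join(spouses) if spouses else '-'})")
        lines.append(f"BIC:                 {self.bic():.2f}")
        rep = self.target_report()
        if len(rep):
            lines.append("")
            lines.append("Strength of direct and indirect factors")
            lines.append("-" * 40)
            cols = ["node", "relative_binary_mi_pct", "posterior_mean_value"]
            lines.append(rep[cols].to_string(
                index=False, float_format=lambda x: f"{x:.4f}"))
        return "\n".join(lines)

    def plot_structure(self, ax=None):
        """Draw the DAG with the target highlighted."""
        import matplotlib.pyplot as plt
        import networkx as nx

        g = self.network.structure.to_digraph()
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 6))
        pos = nx.spring_layout(g, seed=0)
        colors = ["#d62728" if n == self.model.target else "#1f77b4"
                  for n in g.nodes]
        nx.draw_networkx(g, pos=pos, ax=ax, node_color=colors,
                         font_size=8, node_size=900, edge_color="gray")
        ax.set_axis_off()
        return ax
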