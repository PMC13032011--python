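"""High-level modelling interface: one model object, one results object.

:class:`UnitCausalAttribution` is built from a cohort table and ``fit()``
runs the whole workflow — train the feedforward classifier, discover the
causal graph over the input features, classify every input unit as
Isolated / Pure / Confounded, and estimate each unit's causal effect on
both output classes with the engine matching its category.  The returned
:class:`UnitCausalAttributionResults` carries the estimates and
diagnostics and renders a ``summary()`` table; refutation runs hang off
the results object.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import attribution as attr
from . import confounded as conf
from . import refutation as refut
from .cohort import CohortTable, OUTCOME_NAME
from .discovery import discover
from .graph import CausalGraph, UnitCategory, classify_units
from .nn import FeedforwardClassifier, Hyperparams, evaluate, split_metrics, train_fnn

__all__ = ["UnitCausalAttribution", "UnitCausalAttributionResults"]


class UnitCausalAttribution:
    """Unit-level causal attribution model for a tabular cohort.

    Parameters
    ----------
    cohort
        The typed feature table with binary outcome.
    alpha
        Significance level for the conditional-independence tests of the
        discovery stage.
    hyperparams
        Classifier training configuration.
    grid_num
        Number of intervention values per attribution grid.
    bins_k
        Number of discretization groups for Confounded units.
    ensemble_weights
        Convex weights of the (GBDT, RF) treatment-effect ensemble.
    """

    def __init__(self, cohort: CohortTable, alpha: float = 0.05,
                 hyperparams: Hyperparams | None = None,
                 grid_num: int = 10, bins_k: int = 10,
                 ensemble_weights: tuple[float, float] = conf.DEFAULT_ENSEMBLE_WEIGHTS,
                 use_pca: bool = False) -> None:
        self.cohort = cohort
        self.alpha = alpha
        self.hyperparams = hyperparams or Hyperparams()
        self.grid_num = grid_num
        self.bins_k = bins_k
        self.ensemble_weights = ensemble_weights
        self.use_pca = use_pca

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kw) -> "UnitCausalAttribution":
        return cls(CohortTable(frame), **kw)

    @classmethod
    def from_csv(cls, path, **kw) -> "UnitCausalAttribution":
        return cls(CohortTable.from_csv(path), **kw)

    def fit(self, seed: int = 0, graph: CausalGraph | None = None,
            metric_splits: int = 5,
            confounded_strategies: Sequence[str] = ("equal_width",),
            attribute: bool = True) -> "UnitCausalAttributionResults":
        """Run the full attribution workflow.

        A pre-specified ``graph`` skips discovery (useful for analyzing a
        published structure); otherwise the graph is learned from the
        cohort.  Leftover undirected edges are dropped (with a warning)
        before unit classification, which needs a finalized DAG.
        """
        predictor = train_fnn(self.cohort, self.hyperparams, seed=seed)
        metrics = split_metrics(self.cohort, self.hyperparams,
                                n_splits=metric_splits, seed=seed)
        if graph is None:
            graph = discover(self.cohort, alpha=self.alpha,
                             use_pca=self.use_pca)
        if graph.undirected_edges:
            warnings.warn("dropping undirected edges before unit "
                          "classification")
            graph = CausalGraph(graph.nodes, graph.directed_edges)
        categories = classify_units(graph, self.cohort.feature_names)
        summary = attr.fit_gaussian_summary(self.cohort)
        coeffs = attr.fit_edge_coefficients(self.cohort, graph)

        curves: dict[str, dict[str, attr.AttributionCurve]] = {}
        confounded_curves: dict[tuple[str, str, str], conf.ConfoundedCurve] = {}
        if attribute:
            for unit, cat in categories.items():
                grid = attr.InterventionGrid.from_cohort(
                    self.cohort, unit, num=self.grid_num)
                if cat == UnitCategory.ISOLATED:
                    curves[unit] = {
                        label: attr.ace_isolated(predictor, summary, grid, ci)
                        for ci, label in enumerate(attr.CLASS_LABELS)
                    }
                elif cat == UnitCategory.PURE:
                    curves[unit] = {
                        label: attr.ace_pure(predictor, self.cohort, graph,
                                             unit, grid, ci, summary=summary,
                                             coeffs=coeffs)
                        for ci, label in enumerate(attr.CLASS_LABELS)
                    }
                else:
                    for strategy in confounded_strategies:
                        for ci, label in enumerate(attr.CLASS_LABELS):
                            confounded_curves[(unit, strategy, label)] = \
                                conf.ace_confounded(
                                    predictor, self.cohort, graph, unit, ci,
                                    strategy=strategy, k=self.bins_k,
                                    ensemble_weights=self.ensemble_weights,
                                    seed=seed)
        return UnitCausalAttributionResults(
            model=self, predictor=predictor, graph=graph,
            categories=categories, gaussian_summary=summary,
            edge_coefficients=coeffs, metrics=metrics, curves=curves,
            confounded_curves=confounded_curves, seed=seed,
        )


@dataclasses.dataclass
class UnitCausalAttributionResults:
    """Fitted attribution results: graph, categories, effects, diagnostics."""

    model: UnitCausalAttribution
    predictor: FeedforwardClassifier
    graph: CausalGraph
    categories: Mapping[str, UnitCategory]
    gaussian_summary: attr.GaussianSummary
    edge_coefficients: Mapping[tuple[str, str], float]
    metrics: Mapping[str, tuple[float, float]]
    curves: Mapping[str, Mapping[str, attr.AttributionCurve]]
    confounded_curves: Mapping[tuple, conf.ConfoundedCurve]
    seed: int

    # -- tables ------------------------------------------------------------
    def category_counts(self) -> dict[str, int]:
        out = {c.value: 0 for c in UnitCategory}
        for cat in self.categories.values():
            out[cat.value] += 1
        return out

    def unit_table(self) -> pd.DataFrame:
        rows = []
        for unit, cat in self.categories.items():
            row = {"unit": unit, "category": cat.value}
            if unit in self.curves:
                yes = self.curves[unit]["Yes"]
                row["span_effect_yes"] = yes.span_effect
                row["ace_level_yes"] = yes.ace
            for key, curve in self.confounded_curves.items():
                if key[0] == unit and key[2] == "Yes":
                    row[f"cumulative_yes_{key[1]}"] = curve.cumulative[-1]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Unit-level causal attribution", "=" * 34]
        lines.append(f"records: {len(self.model.cohort)}   "
                     f"features: {len(self.model.cohort.feature_names)}")
        m = self.metrics
        lines.append("classifier (mean ± SD over splits): "
                     + "  ".join(f"{k}={v[0]:.3f}±{v[1]:.3f}"
                                 for k, v in m.items()))
        lines.append(f"causal graph: {len(self.graph.directed_edges)} directed "
                     f"edge(s); categories: "
                     + ", ".join(f"{k}={v}"
                                 for k, v in self.category_counts().items()))
        lines.append("")
        lines.append(self.unit_table().to_string(index=False,
                                                 float_format="%.4f"))
        return "\n".join(lines)

    # -- refutation --------------------------------------------------------
    def refute_edge(self, edge: tuple[str, str], reps: int = 20,
                    seed: int | None = None) -> list[refut.RefutationReport]:
        """Falsify one fitted edge coefficient (Pure-unit path machinery).

        The estimator is the partial OLS slope of the child on its parents;
        placebo permutes the parent column, dummy replaces the child.
        """
        parent, child = edge
        if edge not in self.edge_coefficients:
            raise KeyError(f"{edge} is not a fitted edge")
        graph = self.graph

        def estimator(frame: pd.DataFrame, seed: int = 0) -> float:
            cols = [c for c in frame.columns if c != OUTCOME_NAME]
            return attr.fit_edge_coefficients(frame[cols], graph)[edge]

        return refut.refutation_suite(
            estimator, self.model.cohort.frame, reps=reps,
            seed=self.seed if seed is None else seed,
            treatment=parent, outcome=child,
        )

    def refute_confounded(self, unit: str, class_index: int = 1,
                          pair: int | None = None, strategy: str = "equal_width",
                          reps: int = 10, seed: int | None = None
                          ) -> list[refut.RefutationReport]:
        """Falsify one adjacent-group ACE of a Confounded unit.

        The estimator re-runs the backdoor-adjusted meta-learner on the
        perturbed data; ARCC noise columns join the adjustment set.
        """
        cohort = self.model.cohort
        gz = conf.graph_with_outcome(self.graph)
        from .graph import backdoor_set
        Z = sorted(backdoor_set(gz, unit, "Myopia"))
        binning = conf.discretize(cohort.frame[unit].to_numpy(float),
                                  strategy, self.model.bins_k)
        j = binning.k // 2 if pair is None else pair
        X = cohort.features.to_numpy(dtype=float)
        frame = cohort.features.copy()
        frame["__treat__"] = (binning.assignment == j + 1).astype(int)
        frame["__y__"] = self.predictor.predict_proba(X)[:, class_index]
        mask = (binning.assignment == j) | (binning.assignment == j + 1)
        frame = frame.loc[mask].reset_index(drop=True)

        def estimator(df: pd.DataFrame, seed: int = 0) -> float:
            z = Z + [c for c in df.columns
                     if c.startswith("_random_common_cause_")]
            m = conf.fit_meta_learner(df, df["__treat__"].to_numpy(int),
                                      df["__y__"].to_numpy(float), z,
                                      ensemble_weights=self.model.ensemble_weights,
                                      seed=seed)
            return m.ate

        return refut.refutation_suite(
            estimator, frame, reps=reps,
            seed=self.seed if seed is None else seed,
            treatment="__treat__", outcome="__y__",
        )

    # -- plotting / export -------------------------------------------------
    def plot_curve(self, unit: str, ax=None):
        """Centered attribution curves of one unit (both classes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, curve in self.curves[unit].items():
            ax.plot(curve.alphas, curve.centered, label=label)
        ax.axhline(0.0, ls=":", c="k", lw=0.8)
        ax.set_xlabel(f"intervention value of {unit}")
        ax.set_ylabel("centered intervention expectation")
        ax.legend()
        return ax

    def to_report(self, directory) -> dict:
        """Write a JSON + markdown bundle of the run; return the JSON dict."""
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = {
            "seed": self.seed,
            "n_records": len(self.model.cohort),
            "alpha": self.model.alpha,
            "metrics": {k: {"mean": v[0], "sd": v[1]}
                        for k, v in self.metrics.items()},
            "n_directed_edges": len(self.graph.directed_edges),
            "categories": {u: c.value for u, c in self.categories.items()},
            "category_counts": self.category_counts(),
            "edge_coefficients": {f"{u}->{v}": c for (u, v), c
                                  in sorted(self.edge_coefficients.items())},
            "curves": {
                unit: {label: {"alphas": c.alphas.tolist(),
                               "expectation": c.expectation.tolist(),
                               "ace": c.ace, "span_effect": c.span_effect}
                       for label, c in per_class.items()}
                for unit, per_class in self.curves.items()
            },
            "confounded": {
                f"{u}|{s}|{lab}": {"edges": c.edges.tolist(),
                                   "ace": c.ace.tolist(),
                                   "cumulative": c.cumulative.tolist()}
                for (u, s, lab), c in self.confounded_curves.items()
            },
        }
        with open(directory / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        with open(directory / "report.md", "w") as fh:
            fh.write("# Unit-level causal attribution report\n\n```\n")
            fh.write(self.summary())
            fh.write("\n```\n")
        from .graph import write_edgelist
        write_edgelist(self.graph, directory / "graph.tsv",
                       orientation_column=True)
        return payload
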