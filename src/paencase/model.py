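"""Model/Results interface over the full diagnostic analysis.

``EncasementDiagnosticModel`` is built from a validated cohort (or a CSV /
DataFrame in the package dialect); ``fit()`` runs the whole battery —
contingency table with exclusions, exact test, odds ratios against the
penetration baseline, degree summaries and rank-sum comparison, empirical
ROC with Youden cutoff and confusion metrics, and inter-observer kappa when
two observers' labels are present — and returns an
``EncasementDiagnosticResults`` whose ``summary()`` renders the report.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import roc as roc_mod
from . import stats as stats_mod
from .core import (
    ANALYZABLE_RELATIONS,
    Cohort,
    RelationType,
    read_cohort,
    write_report,
)
from .scoring import dominant_relation

__all__ = ["EncasementDiagnosticModel", "EncasementDiagnosticResults"]

_KAPPA_CATEGORIES = tuple(RelationType)


def _kappa_label(relations: frozenset) -> RelationType | None:
    """Single category per lesion for the agreement table."""
    if not relations:
        return None
    dom = dominant_relation(relations)
    if dom is not None:
        return dom
    if RelationType.IN_MARGIN in relations:
        return RelationType.IN_MARGIN
    return RelationType.DISCONNECTION


@dataclass
class EncasementDiagnosticResults:
    """Estimates, uncertainties and diagnostics from a fitted model."""

    cohort: Cohort
    relation_table: stats_mod.RelationTable
    fisher_p: float | None
    odds_ratios: dict  # exposure -> OddsRatioResult
    group_summaries: dict
    wilcoxon: tuple[float, float] | None  # (U, p) on degrees
    roc: roc_mod.RocCurve | None
    cutoff: float | None
    confusion: roc_mod.ConfusionMetrics | None
    kappa: stats_mod.KappaResult | None
    notes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        """Deterministically ordered mapping for report rendering."""
        out: dict = {}
        t = self.relation_table
        for g in stats_mod.GROUPS:
            cells = "/".join(str(t.count(r, g)) for r in ANALYZABLE_RELATIONS)
            out[f"{g}: enc/disp/pen records"] = cells
            out[f"{g}: analyzed lesions"] = str(t.analyzed(g))
            out[f"{g}: excluded (in margin/disconnection)"] = str(t.excluded[g])
            out[f"{g}: dual-relationship lesions"] = str(t.dual_count[g])
        if self.fisher_p is not None:
            out["Fisher exact P (relation x diagnosis)"] = (
                "<0.001" if self.fisher_p < 0.001 else f"{self.fisher_p:.3f}")
        for name, res in self.odds_ratios.items():
            out[f"OR {name} vs {res.baseline}"] = res
        for g in stats_mod.GROUPS:
            s = self.group_summaries.get(g)
            if s is not None and s.degree_mean is not None:
                sd = f" +/- {s.degree_sd:.1f}" if s.degree_sd is not None else ""
                out[f"{g}: degree of encasement (%)"] = f"{s.degree_mean:.1f}{sd}"
        if self.wilcoxon is not None:
            out["Wilcoxon rank-sum P (degrees)"] = float(self.wilcoxon[1])
        if self.roc is not None:
            out["AUC (degree of encasement)"] = float(self.roc.auc)
            out["Best cutoff (Youden, %)"] = f"{self.roc.best_cutoff:.1f}"
        if self.confusion is not None and self.cutoff is not None:
            out[f"Confusion at cutoff {self.cutoff:.1f}%"] = self.confusion
        if self.kappa is not None:
            out["Inter-observer kappa"] = self.kappa
        return out

    def summary(self) -> str:
        """Human-readable report of the fitted analysis."""
        _, md = write_report(self.as_dict())
        return md

    def report_tsv(self) -> str:
        tsv, _ = write_report(self.as_dict())
        return tsv


class EncasementDiagnosticModel:
    """Diagnostic-evaluation model for a lesion cohort.

    Parameters
    ----------
    cohort : Cohort
        Validated lesion records.
    cutoff : float, optional
        Degree cutoff (%) for the confusion metrics; defaults to the
        Youden-optimal cutoff of the fitted ROC.
    welch : bool
        Use Welch's t instead of the pooled two-sample t for ages.
    continuity : bool
        Apply the Haldane-Anscombe +0.5 correction in odds ratios.
    """

    def __init__(self, cohort: Cohort, *, cutoff: float | None = None,
                 welch: bool = False, continuity: bool = False) -> None:
        if len(cohort) == 0:
            raise ValueError("cohort is empty; nothing to analyze")
        self.cohort = cohort
        self.cutoff = cutoff
        self.welch = welch
        self.continuity = continuity

    @classmethod
    def from_csv(cls, path, **kwargs) -> "EncasementDiagnosticModel":
        return cls(read_cohort(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "EncasementDiagnosticModel":
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(read_cohort(buf), **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> EncasementDiagnosticResults:
        notes: list[str] = []
        cohort = self.cohort
        table = stats_mod.build_relation_table(cohort)
        matrix = table.matrix()

        fisher_p = None
        if matrix.sum() > 0 and (matrix.sum(axis=1) > 0).all():
            fisher_p = stats_mod.fisher_exact(matrix)
        else:
            notes.append("contingency table degenerate; Fisher test skipped")

        odds = {}
        E, D, P = ANALYZABLE_RELATIONS
        for rel in (E, D):
            a = table.count(rel, "malignant")
            b = table.count(rel, "benign")
            c = table.count(P, "malignant")
            d = table.count(P, "benign")
            try:
                odds[rel.value] = stats_mod.odds_ratio_vs_baseline(
                    a, b, c, d, exposure=rel.value, continuity=self.continuity)
            except ValueError as exc:
                notes.append(f"odds ratio {rel.value}: {exc}")

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summaries = stats_mod.group_summary(cohort)

        deg_b = [r.degree for r in cohort.subset("benign") if r.degree is not None]
        deg_m = [r.degree for r in cohort.subset("malignant") if r.degree is not None]
        wilcoxon = None
        roc = None
        cutoff = self.cutoff
        confusion = None
        if deg_b and deg_m:
            wilcoxon = stats_mod.wilcoxon_rank_sum(deg_b, deg_m)
            degrees = np.array(deg_b + deg_m)
            labels = np.array([0] * len(deg_b) + [1] * len(deg_m))
            roc = roc_mod.empirical_roc(degrees, labels)
            if cutoff is None:
                cutoff = roc.best_cutoff
            confusion = roc_mod.confusion_metrics(degrees, labels, cutoff)
        else:
            notes.append("encasement degrees absent in a group; ROC skipped")

        kappa = self._fit_kappa(notes)
        return EncasementDiagnosticResults(
            cohort=cohort, relation_table=table, fisher_p=fisher_p,
            odds_ratios=odds, group_summaries=summaries, wilcoxon=wilcoxon,
            roc=roc, cutoff=cutoff, confusion=confusion, kappa=kappa,
            notes=notes,
        )

    def _fit_kappa(self, notes: list) -> stats_mod.KappaResult | None:
        pairs = [(r.obs1_relations, r.obs2_relations) for r in self.cohort.records
                 if r.obs1_relations and r.obs2_relations]
        if len(pairs) < 2:
            notes.append("fewer than 2 dual-observer lesions; kappa skipped")
            return None
        k = len(_KAPPA_CATEGORIES)
        index = {c: i for i, c in enumerate(_KAPPA_CATEGORIES)}
        confusion = np.zeros((k, k), dtype=int)
        for o1, o2 in pairs:
            confusion[index[_kappa_label(o1)], index[_kappa_label(o2)]] += 1
        try:
            return stats_mod.cohens_kappa(confusion)
        except ValueError as exc:
            notes.append(f"kappa: {exc}")
            return None
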