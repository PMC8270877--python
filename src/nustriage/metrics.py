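"""Diagnostic-performance statistics for the FNA triage analysis.

The operational dichotomy throughout is:

* **outcome-positive** — positive cytology (TIR3B/TIR4/TIR5 or pre-2014
  Thy3+), i.e. the nodule was referred for surgical consideration;
* **test-positive** — the scoring system indicates FNA for the nodule
  (risk class combined with the class's size threshold).

Point estimates use Wald (normal-approximation) confidence intervals with no
continuity correction; the ordinal ROC area uses the rank-based concordance
estimator with ties counted one half and the Hanley-McNeil variance for its
interval; interobserver agreement uses unweighted Cohen's kappa with the
Landis-Koch interpretation bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .classifiers import (
    MacroRisk,
    NusAssignment,
    NusSystem,
    RuleSet,
    UNCLASSIFIABLE,
    classify,
)
from .domain import CytologyOutcomeValue, NoduleRecord, dichotomize_cytology

Z_975 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def scaled(self, k: int) -> "ContingencyTable":
        return ContingencyTable(self.tp * k, self.fp * k, self.fn * k, self.tn * k)


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion, AUC or kappa with its 95% interval.

    ``value`` is None when the metric is undefined (empty margin or
    degenerate expected agreement); the bounds are then None too.
    """

    value: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n: int
    label: Optional[str] = None

    @property
    def ci_half_width(self) -> Optional[float]:
        if self.value is None or self.ci_high is None or self.ci_low is None:
            return None
        return (self.ci_high - self.ci_low) / 2.0


@dataclass(frozen=True)
class ClassSummary:
    system: NusSystem
    class_label: str
    n_negative: int
    n_positive: int
    positive_rate: Optional[float]
    expected_band: Optional[str] = None

    @property
    def total(self) -> int:
        return self.n_negative + self.n_positive


@dataclass(frozen=True)
class SparingClassEntry:
    class_label: str
    n_observed: int
    n_expected: int
    n_spared: int
    spared_negative: int
    spared_positive: int
    included_in_totals: bool


@dataclass(frozen=True)
class SparingReport:
    system: NusSystem
    per_class: tuple[SparingClassEntry, ...]
    n_observed_total: int
    n_expected_total: int
    n_spared_total: int
    spared_negative_total: int
    spared_positive_total: int
    n_unclassifiable: int

    @property
    def spared_fraction(self) -> float:
        return self.n_spared_total / self.n_observed_total


@dataclass
class SystemObservations:
    """Per-nodule (class, outcome, FNA-indicated) triples for one system.

    The canonical in-memory input to the table-level operations; built
    either from classified nodule records or from the packaged printed-count
    fixtures. ATA-unclassifiable nodules are held separately: they are
    excluded from per-class statistics, sparing and ROC but reported as a
    pseudo-class.
    """

    system: NusSystem
    class_labels: list[str] = field(default_factory=list)
    outcomes: list[bool] = field(default_factory=list)  # True = positive cytology
    fna_indicated: list[bool] = field(default_factory=list)
    ordinal_ranks: list[int] = field(default_factory=list)
    unclassifiable_outcomes: list[bool] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.class_labels)

    @property
    def n_unclassifiable(self) -> int:
        return len(self.unclassifiable_outcomes)

    def add(self, class_label: str, outcome: bool, indicated: bool, rank: int) -> None:
        self.class_labels.append(class_label)
        self.outcomes.append(outcome)
        self.fna_indicated.append(indicated)
        self.ordinal_ranks.append(rank)


def observe_cohort(
    records: Iterable[NoduleRecord],
    system: NusSystem,
    ruleset: Optional[RuleSet] = None,
    on_unresolved: str = "error",
) -> SystemObservations:
    """Classify and dichotomize a cohort into one system's observations.

    Records whose cytology outcome is unresolved or nondiagnostic either
    raise (``on_unresolved="error"``) or are dropped (``"drop"``).
    """
    ruleset = ruleset or RuleSet.default()
    obs = SystemObservations(system=system)
    for rec in records:
        outcome = dichotomize_cytology(rec.cytology_history).value
        if outcome not in (CytologyOutcomeValue.POSITIVE, CytologyOutcomeValue.NEGATIVE):
            if on_unresolved == "drop":
                continue
            raise ValueError(
                f"nodule {rec.nodule_id}: cytology outcome {outcome.value} is not "
                "resolvable; filter the cohort first")
        positive = outcome is CytologyOutcomeValue.POSITIVE
        a: NusAssignment = classify(rec.features, system, ruleset)
        if not a.is_classifiable:
            obs.unclassifiable_outcomes.append(positive)
            continue
        assert a.ordinal_rank is not None and a.fna_indicated is not None
        obs.add(a.class_label, positive, a.fna_indicated, a.ordinal_rank)
    return obs


# ---------------------------------------------------------------------------
# Table-level operations
# ---------------------------------------------------------------------------

def class_summary(obs: SystemObservations,
                  ruleset: Optional[RuleSet] = None) -> list[ClassSummary]:
    """Per-class negative/positive counts and malignancy (positive-cytology)
    rates; appends a pseudo-class for ATA-unclassifiable nodules when any
    are present."""
    if obs.n == 0 and obs.n_unclassifiable == 0:
        raise ValueError("no resolvable records")
    rules = (ruleset or RuleSet.default())[obs.system]
    out = []
    for cls in rules.classes:
        pos = sum(1 for c, o in zip(obs.class_labels, obs.outcomes) if c == cls and o)
        neg = sum(1 for c, o in zip(obs.class_labels, obs.outcomes) if c == cls and not o)
        rate = pos / (pos + neg) if pos + neg else None
        out.append(ClassSummary(system=obs.system, class_label=cls,
                                n_negative=neg, n_positive=pos, positive_rate=rate))
    if obs.n_unclassifiable:
        pos = sum(obs.unclassifiable_outcomes)
        neg = obs.n_unclassifiable - pos
        out.append(ClassSummary(system=obs.system, class_label=UNCLASSIFIABLE,
                                n_negative=neg, n_positive=pos,
                                positive_rate=pos / obs.n_unclassifiable))
    return out


def sparing_report(obs: SystemObservations,
                   include_benign_class: bool = False,
                   ruleset: Optional[RuleSet] = None) -> SparingReport:
    """Expected-vs-observed FNA accounting per class.

    Every cohort nodule underwent FNA (observed); a nodule is *expected*
    when its class and size indicate FNA, and *spared* otherwise. Classes
    marked as sparing-excluded in the rule table (the ATA benign class) are
    reported but left out of the spared totals unless
    ``include_benign_class`` is set; the spared fraction is always over the
    full classified observed count.
    """
    rules = (ruleset or RuleSet.default())[obs.system]
    entries = []
    spared_tot = spared_neg_tot = spared_pos_tot = exp_tot = 0
    for cls in rules.classes:
        idx = [i for i, c in enumerate(obs.class_labels) if c == cls]
        n_obs = len(idx)
        n_exp = sum(1 for i in idx if obs.fna_indicated[i])
        sp_neg = sum(1 for i in idx if not obs.fna_indicated[i] and not obs.outcomes[i])
        sp_pos = sum(1 for i in idx if not obs.fna_indicated[i] and obs.outcomes[i])
        included = include_benign_class or cls not in rules.sparing_excluded_classes
        entries.append(SparingClassEntry(
            class_label=cls, n_observed=n_obs, n_expected=n_exp,
            n_spared=n_obs - n_exp, spared_negative=sp_neg, spared_positive=sp_pos,
            included_in_totals=included))
        if included:
            spared_tot += n_obs - n_exp
            spared_neg_tot += sp_neg
            spared_pos_tot += sp_pos
            exp_tot += n_exp
    return SparingReport(
        system=obs.system, per_class=tuple(entries),
        n_observed_total=obs.n, n_expected_total=exp_tot,
        n_spared_total=spared_tot, spared_negative_total=spared_neg_tot,
        spared_positive_total=spared_pos_tot,
        n_unclassifiable=obs.n_unclassifiable)


def fna_triage_confusion(obs: SystemObservations) -> ContingencyTable:
    """2x2 of FNA indication against cytology outcome."""
    tp = fp = fn = tn = 0
    for ind, pos in zip(obs.fna_indicated, obs.outcomes):
        if ind and pos:
            tp += 1
        elif ind:
            fp += 1
        elif pos:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def wald_proportion(k: int, n: int, alpha: float = 0.05) -> MetricEstimate:
    """Binomial proportion with a Wald interval, clipped to [0, 1]."""
    if n == 0:
        return MetricEstimate(value=None, ci_low=None, ci_high=None, n=0)
    p = k / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(p * (1 - p) / n)
    return MetricEstimate(value=p, ci_low=max(0.0, p - half),
                          ci_high=min(1.0, p + half), n=n)


def diagnostic_metrics(t: ContingencyTable,
                       alpha: float = 0.05) -> dict[str, MetricEstimate]:
    """Sensitivity, specificity, PPV and NPV with Wald intervals.

    Each metric's interval uses its own denominator (e.g. PPV over the
    test-positive count). A zero margin leaves that metric undefined.
    """
    return {
        "sensitivity": wald_proportion(t.tp, t.tp + t.fn, alpha),
        "specificity": wald_proportion(t.tn, t.tn + t.fp, alpha),
        "ppv": wald_proportion(t.tp, t.tp + t.fp, alpha),
        "npv": wald_proportion(t.tn, t.tn + t.fn, alpha),
    }


def auc_ordinal(scores: Sequence[float], outcomes: Sequence[int],
                alpha: float = 0.05) -> MetricEstimate:
    """ROC area for an ordinal (or point) score against a binary outcome.

    Rank-based concordance estimator (ties count one half), equivalent to
    the Mann-Whitney statistic; the interval uses the Hanley-McNeil
    variance approximation.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if len(scores) != len(y):
        raise ValueError("scores and outcomes must have equal length")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = stats.rankdata(scores)
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc * auc)
           + (n0 - 1) * (q2 - auc * auc)) / (n1 * n0)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    return MetricEstimate(value=float(auc), ci_low=max(0.0, auc - half),
                          ci_high=min(1.0, auc + half), n=n1 + n0)


#: Landis-Koch agreement bands (upper bound -> label).
_KAPPA_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost_perfect"),
)


def kappa_band(kappa: float) -> str:
    if kappa < 0:
        return "poor"
    for upper, label in _KAPPA_BANDS:
        if kappa <= upper + 1e-12:
            return label
    return "almost_perfect"


def cohens_kappa(ratings_a: Sequence[str], ratings_b: Sequence[str],
                 alpha: float = 0.05) -> MetricEstimate:
    """Unweighted Cohen's kappa between two raters, with a Wald interval
    and the Landis-Koch band label."""
    if len(ratings_a) != len(ratings_b):
        raise ValueError("rating vectors must have equal length")
    n = len(ratings_a)
    if n < 2:
        raise ValueError("kappa requires at least two rated items")
    labels = sorted(set(ratings_a) | set(ratings_b))
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for a, b in zip(ratings_a, ratings_b):
        table[index[a], index[b]] += 1
    p = table / n
    po = float(np.trace(p))
    pe = float(p.sum(axis=1) @ p.sum(axis=0))
    if abs(1.0 - pe) < 1e-12:
        return MetricEstimate(value=None, ci_low=None, ci_high=None, n=n,
                              label="undefined")
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(po * (1 - po) / n) / (1 - pe)
    z = stats.norm.ppf(1 - alpha / 2)
    return MetricEstimate(value=kappa, ci_low=max(-1.0, kappa - z * se),
                          ci_high=min(1.0, kappa + z * se), n=n,
                          label=kappa_band(kappa))


# ---------------------------------------------------------------------------
# Macro-risk pooling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MacroGroupResult:
    group: MacroRisk
    n_negative: int
    n_positive: int
    positive_rate: Optional[float]
    confusion: ContingencyTable
    metrics: dict[str, MetricEstimate]


def _macro_breakdown(groups: Sequence[MacroRisk],
                     outcomes: Sequence[bool]) -> dict[MacroRisk, MacroGroupResult]:
    out = {}
    for g in MacroRisk:
        tp = sum(1 for gg, o in zip(groups, outcomes) if gg is g and o)
        fp = sum(1 for gg, o in zip(groups, outcomes) if gg is g and not o)
        fn = sum(1 for gg, o in zip(groups, outcomes) if gg is not g and o)
        tn = sum(1 for gg, o in zip(groups, outcomes) if gg is not g and not o)
        t = ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)
        rate = tp / (tp + fp) if tp + fp else None
        out[g] = MacroGroupResult(group=g, n_negative=fp, n_positive=tp,
                                  positive_rate=rate, confusion=t,
                                  metrics=diagnostic_metrics(t))
    return out


def macro_metrics(
    observations: Sequence[SystemObservations],
    pooling: str = "pooled_pairs",
    ruleset: Optional[RuleSet] = None,
):
    """Metrics over the three macro-risk groups.

    ``per_system``: each system analysed separately after mapping classes to
    macro groups (returns a dict keyed by system). ``pooled_pairs``: every
    (nodule, system) assignment contributes one observation to its macro
    group across all systems (returns one dict keyed by group). Membership
    of a group is treated as test-positive for that group's 2x2.
    """
    ruleset = ruleset or RuleSet.default()
    if pooling == "per_system":
        result = {}
        for obs in observations:
            rules = ruleset[obs.system]
            groups = [rules.macro_risk[c] for c in obs.class_labels]
            result[obs.system] = _macro_breakdown(groups, obs.outcomes)
        return result
    if pooling == "pooled_pairs":
        groups: list[MacroRisk] = []
        outcomes: list[bool] = []
        for obs in observations:
            rules = ruleset[obs.system]
            groups.extend(rules.macro_risk[c] for c in obs.class_labels)
            outcomes.extend(obs.outcomes)
        return _macro_breakdown(groups, outcomes)
    raise ValueError(f"unknown pooling mode {pooling!r}")


def macro_sparing(observations: Sequence[SystemObservations],
                  ruleset: Optional[RuleSet] = None) -> dict[MacroRisk, float]:
    """Pooled-pairs spared-FNA fraction per macro-risk group."""
    ruleset = ruleset or RuleSet.default()
    n_obs = {g: 0 for g in MacroRisk}
    n_spared = {g: 0 for g in MacroRisk}
    for obs in observations:
        rules = ruleset[obs.system]
        for cls, ind in zip(obs.class_labels, obs.fna_indicated):
            g = rules.macro_risk[cls]
            n_obs[g] += 1
            n_spared[g] += 0 if ind else 1
    return {g: n_spared[g] / n_obs[g] for g in MacroRisk if n_obs[g]}


def chi_squared_independence(table) -> tuple[float, float, int]:
    """Pearson chi-squared test of independence (no continuity correction).

    Returns (statistic, p-value, degrees of freedom).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.size == 0 or (arr < 0).any() or arr.sum() <= 0:
        raise ValueError("need a non-empty r x c table of non-negative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-squared is undefined with a zero margin")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)
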