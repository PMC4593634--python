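"""Univariate feature filtering: per-feature two-sample t-tests, the
n1/n2/n3 candidate-set quota, and single-feature leave-one-out accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features.extract import FeatureDescriptor, FeatureTable

__all__ = ["UnivariateRecord", "CandidateSet", "ttest_all",
           "build_candidate_set", "single_feature_jackknife"]


@dataclass
class UnivariateRecord:
    descriptor: FeatureDescriptor
    t_statistic: float
    p_value: float
    class_means: tuple
    single_feature_accuracy: float | None = None

    @property
    def name(self) -> str:
        return self.descriptor.name


@dataclass
class CandidateSet:
    members: list  # list[UnivariateRecord]
    quota: tuple  # (n1, n2, n3)

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def names(self) -> list:
        return [m.name for m in self.members]


def _two_classes(table: FeatureTable) -> tuple[str, str]:
    classes = sorted(table.labels.unique())
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    for c in classes:
        if (table.labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    return classes[0], classes[1]


def ttest_all(table: FeatureTable, equal_var: bool = True) -> list[UnivariateRecord]:
    """Two-sided two-sample t-test per feature, sorted by ascending p-value.

    Pooled-variance (Student) by default; ``equal_var=False`` gives Welch.
    Zero-variance features receive ``t = 0, p = 1``.  Ties in p are broken
    by descriptor name so the ranking is deterministic.
    """
    c0, c1 = _two_classes(table)
    A = table.X[table.labels == c0].to_numpy()
    B = table.X[table.labels == c1].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant features trigger scipy precision warnings; they are
        # resolved below by the p = 1 convention
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t) | ~np.isfinite(p)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    records = [
        UnivariateRecord(
            descriptor=d, t_statistic=float(t[k]), p_value=float(p[k]),
            class_means=(float(A[:, k].mean()), float(B[:, k].mean())))
        for k, d in enumerate(table.descriptors)
    ]
    records.sort(key=lambda r: (r.p_value, r.name))
    return records


def build_candidate_set(records: list[UnivariateRecord], n1: int = 15,
                        n2: int = 20, n3: int = 5) -> CandidateSet:
    """Quota-based candidate pool: the ``n1`` globally best features by
    p-value, the ``n2`` best among category == interpretable, and the ``n3``
    neuronal features (included unconditionally).  Overlaps are de-duplicated
    and backfilled by the next-best global p so the set always has exactly
    ``n1 + n2 + n3`` members.
    """
    target = n1 + n2 + n3
    ranked = sorted(records, key=lambda r: (r.p_value, r.name))
    neuronal = sorted((r for r in ranked if r.descriptor.category == "neuronal"),
                      key=lambda r: (r.p_value, r.name))
    interpretable = [r for r in ranked if r.descriptor.category == "interpretable"]
    if len(neuronal) < n3:
        raise ValueError(f"need {n3} neuronal features, found {len(neuronal)}")
    if len(interpretable) < n2:
        raise ValueError(f"need {n2} interpretable features, found {len(interpretable)}")
    if len(ranked) < target:
        raise ValueError(f"need {target} features total, found {len(ranked)}")

    chosen: dict[str, UnivariateRecord] = {}
    for r in neuronal[:n3]:
        chosen[r.name] = r
    for r in interpretable[:n2]:
        chosen.setdefault(r.name, r)
    for r in ranked[:n1]:
        chosen.setdefault(r.name, r)
    for r in ranked:  # backfill duplicates with next-best global p
        if len(chosen) >= target:
            break
        chosen.setdefault(r.name, r)
    if len(chosen) < target:
        raise ValueError(f"only {len(chosen)} unique features available, need {target}")
    members = sorted(chosen.values(), key=lambda r: (r.p_value, r.name))
    return CandidateSet(members=members, quota=(n1, n2, n3))


def records_to_frame(records: list[UnivariateRecord]) -> pd.DataFrame:
    """Ranked records as a DataFrame (for CSV reports)."""
    return pd.DataFrame({
        "name": [r.name for r in records],
        "family": [r.descriptor.family for r in records],
        "category": [r.descriptor.category for r in records],
        "t": [r.t_statistic for r in records],
        "p": [r.p_value for r in records],
        "accuracy": [r.single_feature_accuracy for r in records],
    })


def single_feature_jackknife(table: FeatureTable, name: str,
                             gamma_grid=None, cost_grid=None) -> float:
    """Leave-one-out accuracy of an RBF-SVM trained on a single feature.

    A constant (zero-variance) feature is flagged at the 0.5 baseline.
    """
    from .model_eval import jackknife  # late import to avoid cycle

    col = table.X[name].to_numpy()
    if np.ptp(col) == 0:
        return 0.5
    report = jackknife(table, [name], param_policy="grid",
                       gamma_grid=gamma_grid, cost_grid=cost_grid)
    return report.accuracy
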