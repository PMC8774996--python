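"""Two-stage nonparametric feature screening and set composition.

For each pair of classes the per-descriptor distributions (pooled over
sub-segments and segments) are compared twice: first with the two-sample
Kolmogorov–Smirnov test (stage 1), then with the two-sided Mann–Whitney U
test (stage 2), both at significance level α = 0.05 with no
multiple-testing correction.  A descriptor survives under the default
``"stage2"`` combination rule iff its Mann–Whitney p-value is ≤ α — this is
the rule that exactly reproduces the published final feature sets for the
Bonn pairwise problems (see :data:`REFERENCE_SELECTED_FEATURES`); the
stricter ``"both"`` rule (both tests significant) is available via config.

Multi-class problems compose the per-pair surviving sets with set algebra:
two comparison classes intersect their sets, three or more take the union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidArgumentError, SchemaError
from .features import DESCRIPTOR_NAMES, descriptor_columns

logger = logging.getLogger("covdet")

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# The two tests
# ---------------------------------------------------------------------------

def _check_samples(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidArgumentError("samples must be finite")
    return x, y


def ks_two_sample(x, y, method: str = "asymptotic") -> float:
    """Two-sided two-sample Kolmogorov–Smirnov p-value.

    The statistic is ``D = sup |ECDF_x - ECDF_y|``.  ``method`` is
    ``"asymptotic"`` (Kolmogorov distribution, default), ``"exact"``
    (exact null distribution of D, appropriate for small samples) or
    ``"auto"``.
    """
    x, y = _check_samples(x, y)
    scipy_method = {"asymptotic": "asymp", "exact": "exact", "auto": "auto"}.get(method)
    if scipy_method is None:
        raise InvalidArgumentError(f"unknown method {method!r}")
    res = stats.ks_2samp(x, y, alternative="two-sided", method=scipy_method)
    return float(min(res.pvalue, 1.0))


def ks_statistic(x, y) -> float:
    """The KS statistic ``D = sup |ECDF_x - ECDF_y|`` alone."""
    x, y = _check_samples(x, y)
    return float(stats.ks_2samp(x, y, alternative="two-sided", method="asymp").statistic)


def mwu_test(x, y, method: str = "asymptotic") -> float:
    """Two-sided Mann–Whitney U p-value.

    The U statistic uses midranks for ties; the default p-value comes from
    the tie-corrected normal approximation (with continuity correction),
    ``method="exact"`` from the exact null distribution (no ties only).
    Two identical constant samples carry no ordering information and
    return p = 1.
    """
    x, y = _check_samples(x, y)
    if method not in ("asymptotic", "exact", "auto"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def mwu_statistic(x, y) -> float:
    """The U statistic of x over y (midranks for ties)."""
    x, y = _check_samples(x, y)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").statistic)


# ---------------------------------------------------------------------------
# Two-stage screening
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Per-descriptor p-values of both stages and the surviving set."""

    p_kst: dict[str, float]
    p_mwut: dict[str, float]
    alpha: float
    combination: str

    def pass_kst(self, name: str) -> bool:
        return self.p_kst[name] <= self.alpha

    def pass_mwut(self, name: str) -> bool:
        return self.p_mwut[name] <= self.alpha

    def selected(self, name: str) -> bool:
        return name in self.selected_set()

    def selected_set(self) -> set[str]:
        return select_from_pvalues(self.p_kst, self.p_mwut, self.alpha,
                                   self.combination)

    def to_frame(self) -> pd.DataFrame:
        names = list(self.p_kst)
        sel = self.selected_set()
        return pd.DataFrame({
            "descriptor": names,
            "p_kst": [self.p_kst[n] for n in names],
            "p_mwut": [self.p_mwut[n] for n in names],
            "pass_kst": [self.pass_kst(n) for n in names],
            "pass_mwut": [self.pass_mwut(n) for n in names],
            "selected": [n in sel for n in names],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def select_from_pvalues(p_kst: Mapping[str, float], p_mwut: Mapping[str, float],
                        alpha: float = DEFAULT_ALPHA,
                        combination: str = "stage2") -> set[str]:
    """Apply the threshold/combination rule to per-descriptor p-values.

    ``"stage2"`` (default): selected ⇔ p_mwut ≤ α.
    ``"both"``: selected ⇔ p_kst ≤ α and p_mwut ≤ α.
    """
    if not (0 < alpha < 1):
        raise InvalidArgumentError("alpha must be in (0, 1)")
    if set(p_kst) != set(p_mwut):
        raise SchemaError("stage-1 and stage-2 p-value maps differ in descriptors")
    if combination == "stage2":
        return {n for n in p_mwut if p_mwut[n] <= alpha}
    if combination == "both":
        return {n for n in p_mwut if p_mwut[n] <= alpha and p_kst[n] <= alpha}
    raise InvalidArgumentError(f"unknown combination rule {combination!r}")


def _pooled_descriptor_samples(table: pd.DataFrame) -> dict[str, np.ndarray]:
    cols = descriptor_columns(table)
    if not cols:
        raise SchemaError("table has no descriptor columns")
    out = {}
    for desc in DESCRIPTOR_NAMES:
        dcols = [c for c in cols if c.startswith(desc + "_r")]
        if dcols:
            out[desc] = table[dcols].to_numpy(dtype=float).ravel()
    return out


def run_two_stage(features_pos: pd.DataFrame, features_neg: pd.DataFrame,
                  alpha: float = DEFAULT_ALPHA, combination: str = "stage2",
                  method: str = "asymptotic") -> SelectionReport:
    """Screen every descriptor between two class feature tables.

    For each descriptor the samples are its values pooled across all
    sub-segment columns and all segments of a class (one p-value per
    descriptor type, not per column).
    """
    cols_pos = set(descriptor_columns(features_pos))
    cols_neg = set(descriptor_columns(features_neg))
    if cols_pos != cols_neg:
        raise SchemaError("feature tables do not share descriptor columns")
    sx = _pooled_descriptor_samples(features_pos)
    sy = _pooled_descriptor_samples(features_neg)
    p_kst = {d: ks_two_sample(sx[d], sy[d], method) for d in sx}
    p_mwut = {d: mwu_test(sx[d], sy[d], method) for d in sx}
    report = SelectionReport(p_kst=p_kst, p_mwut=p_mwut, alpha=alpha,
                             combination=combination)
    logger.info("two-stage screening: %d/%d descriptors selected (alpha=%g, %s)",
                len(report.selected_set()), len(p_kst), alpha, combination)
    return report


# ---------------------------------------------------------------------------
# Multi-class composition
# ---------------------------------------------------------------------------

@dataclass
class ProblemSpec:
    """A binary classification problem: some class set vs. one comparator.

    ``composition`` is ``"intersection"`` or ``"union"`` over the per-pair
    surviving sets ``(c vs negative_class)`` for c in ``positive_classes``;
    a single-pair problem is the identity either way.
    """

    name: str
    positive_classes: tuple[str, ...]
    negative_class: str
    composition: str = "intersection"

    def __post_init__(self) -> None:
        if not self.positive_classes:
            raise InvalidArgumentError("positive_classes must be non-empty")
        if self.composition not in ("intersection", "union"):
            raise InvalidArgumentError(
                f"unknown composition {self.composition!r}")


def compose_problem(problem: ProblemSpec,
                    per_pair_sets: Mapping[str, set[str]]) -> set[str]:
    """Evaluate the problem's set expression left-to-right over per-pair sets.

    ``per_pair_sets`` maps each class c of ``problem.positive_classes`` to
    the surviving descriptor set of the pair (c vs. the comparator class).
    """
    missing = [c for c in problem.positive_classes if c not in per_pair_sets]
    if missing:
        raise InvalidArgumentError(f"missing per-pair sets for {missing}")
    result = set(per_pair_sets[problem.positive_classes[0]])
    for c in problem.positive_classes[1:]:
        if problem.composition == "intersection":
            result &= per_pair_sets[c]
        else:
            result |= per_pair_sets[c]
    return result


# ---------------------------------------------------------------------------
# Published reference values (Bonn pairwise screening)
# ---------------------------------------------------------------------------

#: Published per-descriptor p-values for the four Bonn single-pair
#: comparisons (each non-ictal set A–D against the ictal set E), as reported
#: for this screening procedure; used to validate the selection rule.
REFERENCE_SCREENING_PVALUES: dict[str, dict[str, dict[str, float]]] = {
    "kst": {
        "A": {"mean": 3.6964e-12, "maximum": 9.4812e-44, "minimum": 1.2251e-44,
              "mode": 5.6969e-10, "median": 3.6951e-9, "range": 1.2251e-44,
              "variance": 1.2251e-44, "standard_deviation": 1.5506e-45,
              "skewness": 0.19, "kurtosis": 0.786},
        "B": {"mean": 1.4660e-9, "maximum": 2.9582e-32, "minimum": 1.9582e-32,
              "mode": 2.9582e-32, "median": 1.2116e-7, "range": 5.1128e-33,
              "variance": 5.1128e-33, "standard_deviation": 8.8103e-38,
              "skewness": 0.6742, "kurtosis": 0.5521},
        "C": {"mean": 4.2607e-13, "maximum": 9.4812e-44, "minimum": 2.7628e-40,
              "mode": 9.4812e-44, "median": 5.2233e-8, "range": 7.1865e-43,
              "variance": 9.500e-44, "standard_deviation": 1.9277e-39,
              "skewness": 0.0874, "kurtosis": 0.3219},
        "D": {"mean": 5.6969e-10, "maximum": 2.3304e-35, "minimum": 1.6754e-31,
              "mode": 2.3304e-35, "median": 1.4670e-9, "range": 8.6551e-34,
              "variance": 8.6551e-34, "standard_deviation": 5.1128e-33,
              "skewness": 0.7410, "kurtosis": 0.2770},
    },
    "mwut": {
        "A": {"mean": 0.14364, "maximum": 0.00001, "minimum": 0.00001,
              "mode": 0.0, "median": 0.22789, "range": 0.0,
              "variance": 0.00001, "standard_deviation": 0.00001,
              "skewness": 0.067418, "kurtosis": 0.73874},
        "B": {"mean": 0.84789, "maximum": 0.0, "minimum": 0.0,
              "mode": 0.00001, "median": 0.18177, "range": 0.0,
              "variance": 0.00001, "standard_deviation": 0.00001,
              "skewness": 0.79658, "kurtosis": 0.7871},
        "C": {"mean": 0.13836, "maximum": 0.0, "minimum": 0.00001,
              "mode": 0.00001, "median": 0.39448, "range": 0.00001,
              "variance": 0.0, "standard_deviation": 0.0,
              "skewness": 0.21952, "kurtosis": 0.0099791},
        "D": {"mean": 0.26889, "maximum": 0.00001, "minimum": 0.00001,
              "mode": 0.0, "median": 0.20432, "range": 0.00001,
              "variance": 0.00001, "standard_deviation": 0.0,
              "skewness": 0.076688, "kurtosis": 0.023436},
    },
}

_BASE6 = {"maximum", "minimum", "mode", "range", "variance", "standard_deviation"}

#: Published final per-pair feature sets the default rule must reproduce.
REFERENCE_SELECTED_FEATURES: dict[str, set[str]] = {
    "A": set(_BASE6),
    "B": set(_BASE6),
    "C": _BASE6 | {"kurtosis"},
    "D": _BASE6 | {"kurtosis"},
}


def reference_pair_sets(alpha: float = DEFAULT_ALPHA,
                        combination: str = "stage2") -> dict[str, set[str]]:
    """Selection rule applied to the published reference p-values."""
    return {pair: select_from_pvalues(REFERENCE_SCREENING_PVALUES["kst"][pair],
                                      REFERENCE_SCREENING_PVALUES["mwut"][pair],
                                      alpha, combination)
            for pair in REFERENCE_SCREENING_PVALUES["kst"]}
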