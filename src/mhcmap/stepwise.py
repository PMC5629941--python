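"""Forward stepwise selection of independent MHC signals and interaction tests.

Each round re-tests every unselected marker group conditional on all
previously selected groups (their non-reference dosage columns join the
covariates of both the null and full models) and selects the most significant
group, stopping when nothing passes the Bonferroni-corrected threshold.
Because MHC LD is extreme, a proxy of an already-selected signal loses its
significance once conditioned, so each independent effect is represented
exactly once in the trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import (
    LN10,
    conditional_association,
    fit_logistic,
    wald_log10_p,
)
from .catalog import DosageMatrix, MarkerGroup

#: imputed dosage above which a sample counts as a carrier under dominant coding
DOMINANT_CARRIER_THRESHOLD = 0.5


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold alpha / n_markers."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_markers


@dataclass
class StepwiseRound:
    selected_group_id: str
    log10_p_at_selection: float
    threshold_log10: float
    n_groups_tested: int


@dataclass
class StepwiseTrace:
    """Ordered record of selected groups and per-round omnibus p-values."""

    rounds: list[StepwiseRound] = field(default_factory=list)
    terminated_reason: str = "below_threshold_exhausted"

    @property
    def selected_group_ids(self) -> list[str]:
        return [r.selected_group_id for r in self.rounds]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "round": i + 1,
                    "selected_group_id": r.selected_group_id,
                    "log10_p_at_selection": r.log10_p_at_selection,
                    "threshold_log10": r.threshold_log10,
                    "n_groups_tested": r.n_groups_tested,
                }
                for i, r in enumerate(self.rounds)
            ]
        )


def forward_stepwise(
    groups: list[MarkerGroup],
    dosages: DosageMatrix,
    y: pd.Series,
    covariates: pd.DataFrame | None,
    threshold: float,
    max_rounds: int = 10,
    control_samples: list[str] | None = None,
) -> StepwiseTrace:
    """Forward stepwise conditional omnibus scan.

    Each round runs :func:`conditional_association` of every unselected
    group on all previously selected groups and selects the minimum-p group
    if its p-value beats ``threshold``; otherwise the scan stops.  Ties on
    log10 p break by control MAF descending, then group id lexicographic, so
    the trace is deterministic given the data.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    threshold_log10 = math.log10(threshold)
    trace = StepwiseTrace()
    if not groups:
        return trace

    if control_samples is None:
        control_samples = [s for s, v in y.items() if v == 0]
    ctrl_freq = dosages.allele_frequencies(control_samples)

    def group_maf(g: MarkerGroup) -> float:
        f = [ctrl_freq.get(m.marker_id, 0.0) for m in g.members]
        f = [min(x, 1.0 - x) for x in f if np.isfinite(x)]
        return max(f) if f else 0.0

    by_id = {g.group_id: g for g in groups}
    selected: list[MarkerGroup] = []
    for _ in range(max_rounds):
        remaining = [g for g in groups if g.group_id not in
                     {s.group_id for s in selected}]
        if not remaining:
            trace.terminated_reason = "below_threshold_exhausted"
            return trace
        results = []
        for g in remaining:
            res = conditional_association(
                g, dosages, y, covariates, selected,
                control_samples=control_samples,
            )
            results.append((res.p_omnibus_log10, -group_maf(g), g.group_id))
        results.sort()
        best_log10p, _, best_id = results[0]
        if best_log10p >= threshold_log10:
            trace.terminated_reason = "below_threshold_exhausted"
            return trace
        trace.rounds.append(
            StepwiseRound(best_id, best_log10p, threshold_log10, len(remaining))
        )
        selected.append(by_id[best_id])
    trace.terminated_reason = "max_rounds"
    return trace


def dominant_coding(dosage: np.ndarray) -> np.ndarray:
    """Carrier indicator from an imputed dosage (1 if dosage > 0.5 else 0)."""
    dosage = np.asarray(dosage, dtype=float)
    out = np.where(dosage > DOMINANT_CARRIER_THRESHOLD, 1.0, 0.0)
    out[np.isnan(dosage)] = np.nan
    return out


def interaction_test(
    primary: np.ndarray,
    snp: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Dominant x additive interaction test.

    The model is ``covariates + dominant(primary) + additive(snp) +
    dominant(primary) x additive(snp)`` — the coding used for HLA-B*27 x SNP
    interaction scans — and the returned p is the Wald test on the product
    term.  Returns ``(beta, se, log10_p)``.

    Raises
    ------
    ValueError
        If either vector is constant or a carrier cell is empty.
    """
    primary = np.asarray(primary, dtype=float)
    snp = np.asarray(snp, dtype=float)
    y = np.asarray(y, dtype=float)
    dom = dominant_coding(primary)
    obs = ~(np.isnan(dom) | np.isnan(snp) | np.isnan(y))
    if np.nanstd(dom[obs]) < 1e-12:
        cell = "carrier" if np.nanmax(dom[obs], initial=0) == 0 else "non-carrier"
        raise ValueError(f"empty {cell} cell: dominant term is constant")
    if np.nanstd(snp[obs]) < 1e-12:
        raise ValueError("SNP dosage is constant")

    cols = [np.ones_like(y), dom, snp, dom * snp]
    names = ["intercept", "dominant", "snp", "interaction"]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != y.shape[0]:
            covariates = covariates.T
        for j in range(covariates.shape[1]):
            cols.insert(1 + j, covariates[:, j])
            names.insert(1 + j, f"covar{j}")
    X = np.column_stack(cols)
    fit = fit_logistic(y, X, names=names)
    if "interaction" not in fit.names:
        raise ValueError(
            "interaction term collinear with main effects: empty cell in the "
            "carrier x genotype table"
        )
    beta = fit.coef("interaction")
    se = fit.se("interaction")
    return beta, se, wald_log10_p(beta, se)


def interaction_report(
    results: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Annotate an interaction scan table with a significance verdict.

    Adds a ``significant`` column (log10 p below log10(alpha)); interaction
    claims failing this are reported as unsupported rather than suppressed.
    """
    out = results.copy()
    out["significant"] = out["log10_p"] < math.log10(alpha)
    return out
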