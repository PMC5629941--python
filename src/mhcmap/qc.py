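"""Marker-level quality control for imputed dosage matrices.

Filters mirror common post-imputation practice for MHC association scans:
imputation info score, minor allele frequency computed from mean dosage,
per-marker call rate, and (when hard genotype calls are available) a
chi-square test for Hardy-Weinberg deviation in controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import DosageMatrix


@dataclass(frozen=True)
class QcThresholds:
    """Retention thresholds; a marker must meet every one to survive.

    Defaults: info >= 0.9 and MAF >= 0.1 for imputed-dosage association,
    call rate >= 0.99, and Hardy-Weinberg deviation p >= 7.5e-8.
    """

    maf_min: float = 0.1
    info_min: float = 0.9
    call_rate_min: float = 0.99
    hwe_p_min: float = 7.5e-8

    def __post_init__(self) -> None:
        for name in ("maf_min", "info_min", "call_rate_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value for Hardy-Weinberg equilibrium.

    Expected genotype counts come from the sample allele frequency.
    Monomorphic markers return p = 1 by convention.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("at least one genotype required")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    q = 1.0 - p
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def filter_markers(
    dosages: DosageMatrix,
    thresholds: QcThresholds = QcThresholds(),
    hard_calls: dict[str, tuple[int, int, int]] | None = None,
) -> tuple[DosageMatrix, pd.DataFrame]:
    """Apply marker filters; return the surviving matrix and an exclusion log.

    MAF is the folded frequency min(f, 1-f) with f = mean(dosage)/2 over
    non-missing samples.  The Hardy-Weinberg rule only applies to markers
    with supplied hard genotype calls (dosage-only markers are not testable);
    callers following standard practice supply control-only counts.  The log
    has one row per removed marker naming the first failed rule, checked in
    the order info, maf, call_rate, hwe.
    """
    if dosages.n_markers == 0:
        raise ValueError("empty dosage matrix")
    keep: list[str] = []
    records: list[dict] = []
    freqs = dosages.allele_frequencies()
    for j, marker in enumerate(dosages.markers):
        col = dosages.dosage[:, j]
        call_rate = float(np.mean(~np.isnan(col)))
        f = freqs.iloc[j]
        maf = min(f, 1.0 - f) if np.isfinite(f) else 0.0
        info = float(dosages.info[j])
        failed, value = None, None
        if info < thresholds.info_min:
            failed, value = "info", info
        elif maf < thresholds.maf_min:
            failed, value = "maf", maf
        elif call_rate < thresholds.call_rate_min:
            failed, value = "call_rate", call_rate
        elif hard_calls is not None and marker.marker_id in hard_calls:
            p_hwe = hwe_test(*hard_calls[marker.marker_id])
            if p_hwe < thresholds.hwe_p_min:
                failed, value = "hwe", p_hwe
        if failed is None:
            keep.append(marker.marker_id)
        else:
            records.append(
                {"marker_id": marker.marker_id, "rule": failed, "value": value}
            )
    log = pd.DataFrame(records, columns=["marker_id", "rule", "value"])
    return dosages.select_markers(keep), log
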