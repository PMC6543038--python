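"""Corticosterone (CORT) response quantification.

Plasma CORT is sampled immediately before scent exposure (0 min, baseline) and
30, 60 and 120 min after. The total CORT response sums the baseline-subtracted
amplitude over the post-exposure time points, integrating both the amplitude
and the duration of the hypothalamic-pituitary-adrenal output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import TestResult, pearson_with_p

CORT_TIMES_MIN = (0, 30, 60, 120)

__all__ = ["CORT_TIMES_MIN", "CortProfile", "total_cort_response", "cort_behavior_correlations"]


@dataclass(frozen=True)
class CortProfile:
    """A four-point plasma corticosterone time course (ng/ml)."""

    subject_id: str
    conc_ng_ml: tuple[float, float, float, float]
    t_min: tuple[int, int, int, int] = CORT_TIMES_MIN

    def __post_init__(self) -> None:
        if tuple(self.t_min) != CORT_TIMES_MIN:
            raise ValueError(f"time points must be {CORT_TIMES_MIN} min")
        conc = np.asarray(self.conc_ng_ml, dtype=float)
        if conc.shape != (4,) or not np.all(np.isfinite(conc)):
            raise ValueError("profile requires exactly four finite concentrations")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def total_response(self) -> float:
        return total_cort_response(self)


def total_cort_response(profile: CortProfile) -> float:
    """Sum of baseline-subtracted CORT over the 30/60/120 min samples (ng/ml).

    The 0-min term is identically zero after baseline subtraction, so the sum
    runs over the post-exposure points only. May be negative if CORT falls
    below baseline.
    """
    conc = np.asarray(profile.conc_ng_ml, dtype=float)
    return float(np.sum(conc[1:] - conc[0]))


@dataclass(frozen=True)
class CortCorrelationReport:
    vs_freezing: TestResult
    vs_epm: TestResult | None
    total_responses: dict[str, float] = field(default_factory=dict)


def cort_behavior_correlations(
    profiles: dict[str, CortProfile],
    freezing: dict[str, float],
    epm: dict[str, float] | None = None,
) -> CortCorrelationReport:
    """Pearson correlations of the total CORT response with behavior.

    ``freezing`` (and optionally ``epm``) map subject id -> score; only
    subjects present in both mappings enter each correlation (>= 3 required).
    """
    totals = {sid: total_cort_response(p) for sid, p in profiles.items()}

    def _paired(scores: dict[str, float]) -> TestResult:
        ids = sorted(set(totals) & set(scores))
        if len(ids) < 3:
            raise ValueError("need >= 3 subjects with both CORT and behavior scores")
        return pearson_with_p([scores[i] for i in ids], [totals[i] for i in ids])

    return CortCorrelationReport(
        vs_freezing=_paired(freezing),
        vs_epm=_paired(epm) if epm is not None else None,
        total_responses=totals,
    )
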