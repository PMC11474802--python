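"""Extracted-ion chromatograms and reaction-efficiency reporting.

A run of the oxidation/conjugation chemistry leaves a peptide in one of
three forms — unreacted hydroxylysine, periodate-oxidized aldehyde, or
methoxyamine conjugate — each with its own precursor m/z.  Integrating a
narrow XIC window around each form and expressing the three peak areas as
percentages of their sum gives the reaction efficiencies: oxidation
efficiency is the oxidized plus conjugated share (everything that reacted),
conjugation efficiency the conjugated share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .spectra import SpectrumRecord

__all__ = ["XICTrace", "EfficiencyReport", "extract_xic", "integrate_peak",
           "reaction_efficiency"]


@dataclass(frozen=True)
class XICTrace:
    """Summed intensity per MS1 scan inside an inclusive m/z window."""

    run_id: str
    mz_lo: float
    mz_hi: float
    times: np.ndarray  # seconds, strictly ascending
    intensities: np.ndarray

    def __post_init__(self):
        if self.mz_lo >= self.mz_hi:
            raise ValueError("window must satisfy lo < hi")
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times and intensities differ in length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("retention times must be strictly ascending")
        if np.any(y < 0):
            raise ValueError("negative intensities")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class EfficiencyReport:
    """Peak-area partition of the three reaction forms, in percent."""

    area_unreacted: float
    area_oxidized: float
    area_conjugated: float
    pct_unreacted: float
    pct_oxidized: float
    pct_conjugated: float
    oxidation_efficiency: float  # oxidized% + conjugated%
    conjugation_efficiency: float


def extract_xic(
    run: Iterable[SpectrumRecord],
    mz_window: tuple[float, float],
    rt_range: Optional[tuple[float, float]] = None,
) -> XICTrace:
    """Sum MS1 peak intensities within an inclusive m/z window per scan."""
    lo, hi = mz_window
    if lo >= hi:
        raise ValueError("window must satisfy lo < hi")
    if rt_range is not None and rt_range[0] > rt_range[1]:
        raise ValueError("rt range must satisfy lo <= hi")
    times, vals = [], []
    run_id = "run"
    for spec in run:
        run_id = spec.run_id
        if spec.ms_level != 1:
            continue
        if rt_range is not None and not (rt_range[0] <= spec.rt <= rt_range[1]):
            continue
        a = np.searchsorted(spec.mz, lo, side="left")
        b = np.searchsorted(spec.mz, hi, side="right")
        times.append(spec.rt)
        vals.append(float(spec.intensity[a:b].sum()))
    return XICTrace(run_id, lo, hi, np.asarray(times), np.asarray(vals))


def integrate_peak(trace: XICTrace, subtract_baseline: bool = False) -> float:
    """Trapezoidal area of a trace; optional constant-baseline subtraction.

    The baseline, when requested, is the trace minimum.  Traces with fewer
    than two points have zero area (warned, not an error).
    """
    if len(trace) < 2:
        if len(trace) == 1:
            warnings.warn("single-point trace has zero area", stacklevel=2)
        return 0.0
    y = trace.intensities
    if subtract_baseline:
        y = y - y.min()
    return float(np.trapezoid(y, trace.times))


def reaction_efficiency(
    area_unreacted: float,
    area_oxidized: float,
    area_conjugated: float,
    conjugation_of_reacted: bool = False,
) -> EfficiencyReport:
    """Percent partition of the three form areas and the derived efficiencies.

    ``conjugation_of_reacted`` switches the conjugation denominator from
    the three-form total (default) to oxidized + conjugated only.
    """
    areas = (area_unreacted, area_oxidized, area_conjugated)
    if any(a < 0 for a in areas):
        raise ValueError("areas must be non-negative")
    total = sum(areas)
    if total == 0:
        raise ValueError("no signal in any form window")
    pct = [100.0 * a / total for a in areas]
    reacted = area_oxidized + area_conjugated
    conj_eff = (
        100.0 * area_conjugated / reacted
        if conjugation_of_reacted and reacted > 0
        else pct[2]
    )
    return EfficiencyReport(
        area_unreacted=area_unreacted,
        area_oxidized=area_oxidized,
        area_conjugated=area_conjugated,
        pct_unreacted=pct[0],
        pct_oxidized=pct[1],
        pct_conjugated=pct[2],
        oxidation_efficiency=pct[1] + pct[2],
        conjugation_efficiency=conj_eff,
    )
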