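"""Sliding-window repeatability and the habituation-length recommendation.

Repeatability is re-estimated on every window of ``width`` adjacent trial
days (days 1..7 at width 3 give the five windows 1-3, 2-4, ..., 5-7) with a
single random grouping factor per series.  The window trajectory is then
scanned for the first *stable* window: R at least ``rho_min``, bootstrap CI
excluding zero, and all later windows within ``delta`` of it.  The first
stable window converts into the habituation recommendation: if individual
differences are stable from window [s, s+width-1], at least s-1 habituation
days are needed before measurements become repeatable, and measuring from
the window's last day onward (s+width-2 habituation days) keeps the whole
observation period inside the stable regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .behavior_io import BehaviorTable
from .errors import ConfigurationError
from .repeatability import (
    RepeatabilityResult,
    ResamplingSettings,
    _assemble,
    bootstrap_samples,
)
from .vc_lmm import ModelSpec, fit_vc_lmm

logger = logging.getLogger(__name__)

DEFAULT_WIDTH = 3
DEFAULT_RHO_MIN = 0.4
DEFAULT_DELTA = 0.15


@dataclass(frozen=True)
class Window:
    """A block of ``width`` consecutive trial days starting at ``start_day``."""

    start_day: int
    width: int

    def __post_init__(self):
        if self.width < 2:
            raise ConfigurationError("window width must be >= 2")
        if self.start_day < 1:
            raise ConfigurationError("start_day must be >= 1")

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(range(self.start_day, self.start_day + self.width))

    @property
    def end_day(self) -> int:
        return self.start_day + self.width - 1


@dataclass
class WindowSeries:
    """Per-window repeatability results for one measure and grouping factor."""

    measure: str
    factor: str
    width: int
    windows: list[Window]
    results: list[RepeatabilityResult]
    failures: dict[int, str] = field(default_factory=dict)

    def trajectory(self) -> list[float]:
        return [r.R for r in self.results]


@dataclass
class MeasureRecommendation:
    measure: str
    first_repeatable_day: int | None
    minimum_habituation_days: int | None
    recommended_habituation_days: int | None

    @property
    def stable(self) -> bool:
        return self.first_repeatable_day is not None


@dataclass
class HabituationReport:
    """Data-driven habituation-length recommendation across measures."""

    per_measure: dict[str, MeasureRecommendation]
    rho_min: float
    delta: float
    require_ci_excludes_zero: bool
    overall_recommended_days: int | None
    extend_habituation: bool


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def sliding_windows(days: Iterable[int], width: int = DEFAULT_WIDTH) -> list[Window]:
    """All maximal-overlap windows of ``width`` consecutive observed days.

    Candidate windows that would span a gap in the observed day set are
    excluded (and logged).
    """
    day_list = sorted(set(int(d) for d in days))
    if width < 2:
        raise ConfigurationError("window width must be >= 2")
    if width > len(day_list):
        raise ConfigurationError(
            f"window width {width} exceeds the {len(day_list)} available days")
    present = set(day_list)
    windows, skipped = [], []
    for start in day_list:
        if start + width - 1 > day_list[-1]:
            break
        wanted = range(start, start + width)
        if all(d in present for d in wanted):
            windows.append(Window(start_day=start, width=width))
        else:
            skipped.append(start)
    if skipped:
        logger.warning("windows starting at day(s) %s span gaps in the observed "
                       "days and were excluded", skipped)
    if not windows:
        raise ConfigurationError("no gap-free window of the requested width exists")
    return windows


def window_repeatability(table: BehaviorTable, response: str, factor: str,
                         width: int = DEFAULT_WIDTH,
                         settings: ResamplingSettings = ResamplingSettings()
                         ) -> WindowSeries:
    """Single-random-factor repeatability (CI, LRT, permutation) per window.

    Identical resampling settings are applied to every window; each window's
    resampling seed is ``settings.seed + window_index`` so per-window draws
    are independent yet reproducible.  Windows whose fit fails are recorded
    in ``failures`` and skipped; the series is still returned.
    """
    windows = sliding_windows(table.days(response), width)
    spec = ModelSpec(response=response, random_factors=(factor,))
    kept, results, failures = [], [], {}
    for i, w in enumerate(windows):
        sub = table.subset(response, days=w.days)
        w_settings = replace(settings, seed=settings.seed + i)
        try:
            fit = fit_vc_lmm(sub, spec)
            samples, n_failed = bootstrap_samples(fit, w_settings, (factor,))
            res = _assemble(sub, spec, factor, fit, samples[factor], n_failed, w_settings)
        except Exception as exc:
            failures[w.start_day] = f"{type(exc).__name__}: {exc}"
            logger.warning("window %s-%s failed: %s", w.start_day, w.end_day, exc)
            continue
        kept.append(w)
        results.append(res)
    return WindowSeries(measure=response, factor=factor, width=width,
                        windows=kept, results=results, failures=failures)


# ---------------------------------------------------------------------------
# Recommendation
# ---------------------------------------------------------------------------

def _first_stable_index(series: WindowSeries, rho_min: float, delta: float,
                        require_ci_excludes_zero: bool) -> int | None:
    rs = series.trajectory()
    for i, res in enumerate(series.results):
        if rs[i] < rho_min:
            continue
        if require_ci_excludes_zero and res.ci[0] <= 0.0:
            continue
        if all(abs(rs[i] - rs[j]) <= delta for j in range(i + 1, len(rs))):
            return i
    return None


def recommend_start_day(series_by_measure: Mapping[str, WindowSeries],
                        rho_min: float = DEFAULT_RHO_MIN,
                        delta: float = DEFAULT_DELTA,
                        require_ci_excludes_zero: bool = True) -> HabituationReport:
    """Derive a habituation-length recommendation from window trajectories.

    For each measure the first stable window (see module docstring) with
    start day s and width k yields first_repeatable_day = s,
    minimum_habituation_days = s - 1 and recommended_habituation_days =
    s + k - 2.  The overall recommendation is the maximum over measures; if
    any measure has no stable window the report flags that habituation
    should be extended and the overall recommendation is undefined.
    """
    if not (0.0 <= rho_min <= 1.0) or delta < 0:
        raise ConfigurationError("rho_min must be in [0,1] and delta >= 0")
    per_measure: dict[str, MeasureRecommendation] = {}
    for measure, series in series_by_measure.items():
        if len(series.results) < 2:
            raise ConfigurationError(
                f"series for {measure!r} has fewer than 2 windows")
        idx = _first_stable_index(series, rho_min, delta, require_ci_excludes_zero)
        if idx is None:
            per_measure[measure] = MeasureRecommendation(measure, None, None, None)
        else:
            w = series.windows[idx]
            per_measure[measure] = MeasureRecommendation(
                measure=measure,
                first_repeatable_day=w.start_day,
                minimum_habituation_days=w.start_day - 1,
                recommended_habituation_days=w.start_day + series.width - 2,
            )
    recs = [m.recommended_habituation_days for m in per_measure.values()]
    if any(r is None for r in recs):
        overall, extend = None, True
    else:
        overall, extend = max(recs), False
    return HabituationReport(
        per_measure=per_measure,
        rho_min=rho_min,
        delta=delta,
        require_ci_excludes_zero=require_ci_excludes_zero,
        overall_recommended_days=overall,
        extend_habituation=extend,
    )
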