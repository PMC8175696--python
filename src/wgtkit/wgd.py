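"""Peak detection in Ks age distributions, relative placement of a
whole-genome duplication against speciation events, and absolute dating
by substitution-rate calibration.

A WGD leaves a peak in the paranome/anchor Ks distribution; ortholog Ks
distributions against related species place speciation events on the
same Ks axis. Ordering the WGD peak among the speciation peaks gives its
phylogenetic position; dividing each speciation peak by its known
divergence time gives a per-lineage synonymous substitution rate
λ = Ks / time, and the WGD age follows as T = Ks_WGD / λ.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .errors import InputError
from .ks import KsDistribution

DEFAULT_ANCHOR_RANGE = (0.4, 1.0)
DEFAULT_GLOBAL_RANGE = (0.05, 3.0)


@dataclasses.dataclass(frozen=True)
class Mode:
    ks_mode: float
    density_height: float
    prominence: float


@dataclasses.dataclass(frozen=True)
class PeakSet:
    """Detected density modes, ascending in Ks, all inside search_range."""

    modes: tuple[Mode, ...]
    search_range: tuple[float, float]
    bandwidth: float | None
    n_values: int
    diagnostic: str = ""

    @property
    def primary(self) -> Mode | None:
        """The highest-density mode, or None when nothing was detected."""
        if not self.modes:
            return None
        return max(self.modes, key=lambda m: m.density_height)


@dataclasses.dataclass(frozen=True)
class DivergenceEvent:
    """A speciation event located on the Ks axis, optionally dated."""

    species_pair: tuple[str, str]
    ks_peak: float
    time: float | None = None

    def __post_init__(self) -> None:
        if self.ks_peak <= 0:
            raise InputError("ks_peak must be positive")
        if self.time is not None and self.time <= 0:
            raise InputError("divergence time must be positive")


@dataclasses.dataclass(frozen=True)
class WgdPlacement:
    """Relative position of a WGD among speciation events.

    ``older_than`` collects events with a smaller Ks peak (the WGD
    predates those splits); ``younger_than`` is the closest event with a
    larger peak. Events indistinguishable from the WGD peak within the
    tie tolerance are reported as ``unresolved`` rather than assigned.
    """

    wgd_ks: float
    younger_than: DivergenceEvent | None
    older_than: tuple[DivergenceEvent, ...]
    unresolved: tuple[DivergenceEvent, ...] = ()
    interval: tuple[float | None, float | None] = (None, None)


@dataclasses.dataclass(frozen=True)
class WgdDatingResult:
    """Per-species rate calibrations and the implied WGD ages (Mya)."""

    per_species: tuple[tuple[str, float, float], ...]  # (species, lambda, age)
    age_min: float
    age_max: float
    age_mean: float
    age_range_midpoint: float


def detect_peaks(
    dist: KsDistribution | np.ndarray | Sequence[float],
    search_range: tuple[float, float] = DEFAULT_GLOBAL_RANGE,
    bandwidth: str | float = "silverman",
    grid_size: int = 512,
    prominence_frac: float = 0.05,
) -> PeakSet:
    """Find density modes of a Ks distribution.

    A Gaussian kernel density is estimated on log-transformed values
    (Silverman bandwidth by default) over a ``grid_size``-point grid
    spanning the search range, extended by three bandwidths on each side
    so boundary-adjacent maxima are not clipped. Local maxima with
    prominence above ``prominence_frac`` of the peak density are mapped
    back to the Ks scale; only modes inside the search range are kept.
    For a lognormal component the log-scale mode is the component median,
    so a component planted at location m is recovered at Ks = m.
    """
    values = dist.values if isinstance(dist, KsDistribution) else np.asarray(dist, float)
    lo, hi = search_range
    if not 0 < lo < hi:
        raise InputError(f"search range {search_range} must satisfy 0 < lo < hi")
    sel = values[(values >= lo) & (values <= hi)]
    if sel.size == 0:
        return PeakSet((), search_range, None, 0, diagnostic="no values in search range")
    logv = np.log(sel)
    if np.ptp(logv) < 1e-9:
        # degenerate point mass: the mode is the common value
        mode = float(np.exp(logv[0]))
        return PeakSet(
            (Mode(mode, math.inf, math.inf),), search_range, 0.0, int(sel.size),
            diagnostic="point mass",
        )
    kde = gaussian_kde(logv, bw_method=bandwidth)
    bw = float(kde.factor * logv.std(ddof=1))
    grid = np.linspace(math.log(lo) - 3 * bw, math.log(hi) + 3 * bw, grid_size)
    density = kde(grid)
    idx, props = find_peaks(density, prominence=prominence_frac * density.max())
    modes = []
    for i, prom in zip(idx, props["prominences"]):
        ks_mode = float(np.exp(grid[i]))
        if lo <= ks_mode <= hi:
            modes.append(Mode(ks_mode, float(density[i]), float(prom)))
    modes.sort(key=lambda m: m.ks_mode)
    return PeakSet(tuple(modes), search_range, bw, int(sel.size))


def place_wgd(
    wgd_peak: float,
    events: Sequence[DivergenceEvent],
    tol: float = 0.02,
) -> WgdPlacement:
    """Order a WGD peak among speciation-event peaks.

    Events are partitioned into strictly younger (larger Ks than the WGD)
    and strictly older sides; an event within ``tol`` of the WGD peak is
    flagged unresolved instead of being assigned a side.
    """
    peaks = [e.ks_peak for e in events]
    if len(set(peaks)) != len(peaks):
        raise InputError("divergence events must have distinct ks_peak values")
    older, younger, unresolved = [], [], []
    for event in events:
        if abs(event.ks_peak - wgd_peak) < tol:
            unresolved.append(event)
        elif event.ks_peak < wgd_peak:
            older.append(event)
        else:
            younger.append(event)
    older.sort(key=lambda e: e.ks_peak)
    younger.sort(key=lambda e: e.ks_peak)
    interval = (
        older[-1].ks_peak if older else None,
        younger[0].ks_peak if younger else None,
    )
    return WgdPlacement(
        wgd_ks=wgd_peak,
        younger_than=younger[0] if younger else None,
        older_than=tuple(older),
        unresolved=tuple(unresolved),
        interval=interval,
    )


def date_wgd(wgd_ks: float, events: Sequence[DivergenceEvent]) -> WgdDatingResult:
    """Date a WGD by per-species rate calibration.

    For each dated divergence event, λ_i = ks_i / t_i (Ks per Mya) and
    T_i = wgd_ks / λ_i. The summary reports the min, max and mean of the
    per-species ages, plus the midpoint of the range.
    """
    if not events:
        raise InputError("at least one dated divergence event is required")
    rows = []
    for event in events:
        if event.time is None or event.time <= 0:
            raise InputError(f"event {event.species_pair} lacks a positive time")
        lam = event.ks_peak / event.time
        rows.append((event.species_pair[1], lam, wgd_ks / lam))
    ages = [age for _, _, age in rows]
    return WgdDatingResult(
        per_species=tuple(rows),
        age_min=min(ages),
        age_max=max(ages),
        age_mean=float(np.mean(ages)),
        age_range_midpoint=(min(ages) + max(ages)) / 2.0,
    )


def events_from_frame(df: pd.DataFrame, reference: str = "L.barbarum") -> list[DivergenceEvent]:
    """Build divergence events from a (species, ks_peak, time_mya) table."""
    return [
        DivergenceEvent((reference, str(r.species)), float(r.ks_peak), float(r.time_mya))
        for r in df.itertuples()
    ]


def rate_similarity(
    dists: Mapping[str, KsDistribution],
    search_range: tuple[float, float] = DEFAULT_GLOBAL_RANGE,
    threshold: float = 0.1,
    bandwidth: str | float = "silverman",
) -> tuple[pd.DataFrame, bool]:
    """Compare synonymous substitution rates via ortholog-peak positions.

    Each distribution (every species against the same outgroup) is
    reduced to its primary density mode; the table of pairwise mode
    differences is returned with a flag that is True when the largest
    absolute difference does not exceed ``threshold`` — the condition
    under which ortholog and paralog Ks distributions can be compared
    without rate correction.
    """
    if len(dists) < 2:
        raise InputError("need ortholog distributions for >= 2 species")
    modes: dict[str, float] = {}
    for species, dist in dists.items():
        peak = detect_peaks(dist, search_range=search_range, bandwidth=bandwidth).primary
        if peak is None:
            raise InputError(f"no density mode found for {species}")
        modes[species] = peak.ks_mode
    names = sorted(modes)
    rows = [
        {"species_a": a, "species_b": b, "mode_a": modes[a], "mode_b": modes[b],
         "delta": abs(modes[a] - modes[b])}
        for i, a in enumerate(names) for b in names[i + 1 :]
    ]
    table = pd.DataFrame(rows, columns=["species_a", "species_b", "mode_a", "mode_b", "delta"])
    comparable = bool(table["delta"].max() <= threshold) if len(table) else True
    return table, comparable
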