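"""Genotype calling from fluorescence readouts: TaqMan endpoint and HRM.

Instrument software normally performs these calls; this module provides
transparent, deterministic stand-ins with the same call semantics.

TaqMan endpoint genotyping reads two end-cycle fluorescence channels — the
wild-type(G)-probe channel ``fx`` and the mutant(T)-probe channel ``fy`` —
and assigns each well to the genotype cluster (Allele X = G/G, both =
G/T, Allele Y = T/T) of the nearest configured centroid in the (fx, fy)
plane. Wells with no appreciable signal in either channel are UNKNOWN
(failed amplification: repeat the experiment).

HRM genotyping normalizes the melt curve with a two-point linear rescale
(pre-melt window mean -> 1, post-melt window mean -> 0) and assigns the
genotype of the nearest normalized reference curve by mean absolute
difference. Curves too far from every catalogued genotype are flagged
VARIANT_SUSPECTED — the amplicon may carry another mutation. A sample-level
genotype is accepted only when at least ``min_replicates`` replicate wells
agree (default 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError, SiteConfigError
from .genotype import GENOTYPES, GenotypeCall, HRM, TAQMAN, UNKNOWN, VARIANT_SUSPECTED

#: Default no-amplification threshold for endpoint calls (fluorescence units).
DEFAULT_MIN_SIGNAL = 5.0
#: Default maximum mean absolute difference to the nearest HRM reference.
#: Calibrated on the synthetic fixtures: concordant replicate wells sit near
#: 0.003 at default noise, off-catalog melt transitions above ~0.025.
DEFAULT_MAX_DISTANCE = 0.02
#: Replicate-well concordance rule: at least three agreeing wells per sample.
DEFAULT_MIN_REPLICATES = 3


@dataclass(frozen=True)
class EndpointSignal:
    """End-cycle two-channel fluorescence of one well."""

    well_id: str
    sample_id: str
    fx: float  # wild-type (G) probe channel
    fy: float  # mutant (T) probe channel

    def __post_init__(self) -> None:
        if not (math.isfinite(self.fx) and math.isfinite(self.fy)):
            raise InputError(f"well {self.well_id!r}: non-finite fluorescence")
        if self.fx < 0 or self.fy < 0:
            raise InputError(f"well {self.well_id!r}: negative fluorescence")


@dataclass
class MeltCurve:
    """Fluorescence vs temperature over the melt ramp of one well."""

    well_id: str
    sample_id: str
    temps: np.ndarray
    fluor: np.ndarray

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.fluor = np.asarray(self.fluor, dtype=float)
        if self.temps.shape != self.fluor.shape or self.temps.ndim != 1:
            raise InputError(f"well {self.well_id!r}: temps/fluor shape mismatch")
        if self.temps.size < 10:
            raise InputError(f"well {self.well_id!r}: need >= 10 readings")
        if not np.all(np.diff(self.temps) > 0):
            raise InputError(f"well {self.well_id!r}: temperatures not strictly increasing")


@dataclass
class HRMReference:
    """Normalized reference melt curve of one catalogued genotype."""

    genotype: str
    temps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.temps.shape != self.values.shape:
            raise InputError(f"reference {self.genotype}: grid/value shape mismatch")


def call_endpoint(
    signal: EndpointSignal,
    centroids: Mapping[str, tuple[float, float]],
    min_signal: float = DEFAULT_MIN_SIGNAL,
    site_label: str = "NT-26",
) -> GenotypeCall:
    """Nearest-centroid genotype call in the (fx, fy) fluorescence plane."""
    missing = [g for g in GENOTYPES if g not in centroids]
    if missing:
        raise SiteConfigError(f"endpoint centroids missing for {missing}")
    if max(signal.fx, signal.fy) < min_signal:
        genotype = UNKNOWN
    else:
        genotype = min(
            GENOTYPES,
            key=lambda g: math.hypot(
                signal.fx - centroids[g][0], signal.fy - centroids[g][1]
            ),
        )
    return GenotypeCall(
        sample_id=signal.sample_id,
        site_label=site_label,
        genotype=genotype,
        method=TAQMAN,
    )


def _window_mean(curve: MeltCurve, window: tuple[float, float]) -> float:
    lo, hi = window
    mask = (curve.temps >= lo) & (curve.temps <= hi)
    if not mask.any():
        raise InputError(
            f"well {curve.well_id!r}: window {window} contains no readings "
            f"(ramp {curve.temps[0]:.1f}-{curve.temps[-1]:.1f} degC)"
        )
    return float(curve.fluor[mask].mean())


def normalize_melt(
    curve: MeltCurve,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
) -> MeltCurve:
    """Two-point linear normalization of a melt curve.

    The mean fluorescence over the pre-melt window maps to 1 and the mean over
    the post-melt window to 0, with a linear rescale in between. Affine
    transformations of the raw signal (gain and offset) therefore normalize to
    the identical curve, and an already-normalized curve is a fixed point.
    """
    lo_pre, hi_pre = pre_window
    lo_post, hi_post = post_window
    if lo_pre >= hi_pre or lo_post >= hi_post:
        raise InputError("normalization windows must be non-empty intervals")
    if hi_pre >= lo_post:
        raise InputError("pre-melt window must lie entirely below the post-melt window")
    top = _window_mean(curve, pre_window)
    bottom = _window_mean(curve, post_window)
    if top <= bottom:
        raise InputError(
            f"well {curve.well_id!r}: pre-melt signal not above post-melt signal; "
            "windows likely misplaced"
        )
    values = (curve.fluor - bottom) / (top - bottom)
    return MeltCurve(
        well_id=curve.well_id, sample_id=curve.sample_id, temps=curve.temps, fluor=values
    )


def resample_curve(curve: MeltCurve, grid: Sequence[float]) -> MeltCurve:
    """Linear interpolation of a curve onto a common temperature grid."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < curve.temps[0] - 1e-9 or grid[-1] > curve.temps[-1] + 1e-9:
        raise InputError(
            f"well {curve.well_id!r}: target grid extends beyond acquired ramp"
        )
    values = np.interp(grid, curve.temps, curve.fluor)
    return MeltCurve(
        well_id=curve.well_id, sample_id=curve.sample_id, temps=grid, fluor=values
    )


def call_hrm(
    curve: MeltCurve,
    references: Sequence[HRMReference],
    max_distance: float = DEFAULT_MAX_DISTANCE,
    site_label: str = "NT-26",
) -> GenotypeCall:
    """Nearest-reference genotype call for one normalized melt curve.

    Distance is the mean absolute difference on the references' common grid
    (the curve is resampled by linear interpolation). If the nearest catalogued
    genotype is farther than ``max_distance``, the call is UNKNOWN with the
    ``VARIANT_SUSPECTED`` flag set.
    """
    covered = {r.genotype for r in references}
    missing = [g for g in GENOTYPES if g not in covered]
    if missing:
        raise SiteConfigError(f"HRM references missing for {missing}")
    grid = references[0].temps
    for ref in references[1:]:
        if ref.temps.shape != grid.shape or not np.allclose(ref.temps, grid):
            raise InputError("HRM references are not on a common temperature grid")
    query = resample_curve(curve, grid)
    dists = {
        ref.genotype: float(np.mean(np.abs(query.fluor - ref.values)))
        for ref in references
    }
    best = min(dists, key=dists.get)
    if dists[best] <= max_distance:
        genotype, flag = best, None
    else:
        genotype, flag = UNKNOWN, VARIANT_SUSPECTED
    return GenotypeCall(
        sample_id=curve.sample_id,
        site_label=site_label,
        genotype=genotype,
        method=HRM,
        flag=flag,
    )


def replicate_consensus(
    calls: Sequence[GenotypeCall],
    min_replicates: int = DEFAULT_MIN_REPLICATES,
) -> GenotypeCall:
    """Sample-level genotype from replicate wells under the concordance rule.

    Fewer than ``min_replicates`` informative (non-UNKNOWN) wells, or any
    disagreement among them, yields UNKNOWN: the experiment must be repeated.
    """
    if not calls:
        raise InputError("replicate_consensus requires at least one call")
    sample_ids = {c.sample_id for c in calls}
    methods = {c.method for c in calls}
    sites = {c.site_label for c in calls}
    if len(sample_ids) > 1 or len(methods) > 1 or len(sites) > 1:
        raise InputError(
            "replicate calls must share sample_id, method and site "
            f"(got samples={sorted(sample_ids)}, methods={sorted(methods)})"
        )
    informative = {c.genotype for c in calls if c.genotype != UNKNOWN}
    n_informative = sum(1 for c in calls if c.genotype != UNKNOWN)
    if n_informative >= min_replicates and len(informative) == 1:
        genotype = informative.pop()
    else:
        genotype = UNKNOWN
    return GenotypeCall(
        sample_id=calls[0].sample_id,
        site_label=calls[0].site_label,
        genotype=genotype,
        method=calls[0].method,
    )
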