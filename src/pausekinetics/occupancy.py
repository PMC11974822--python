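"""Calibration of signal units to absolute RNA polymerase occupancy.

A fully occupied pause region holds one polymerase, and some genes approach
full occupancy, so the ranked per-gene pause sums should saturate.  Real
libraries show an artifactual uptick at the very top (multicopy genes,
mapping ambiguity), so saturation is estimated by fitting

    y = A * tanh(B * x) + C

to log10 pause sums ``y`` against rank ``x``; the saturation
``10**(A + C)`` is taken as the signal of one full polymerase.  The fit is
trustworthy only when PCR duplicates were removed (UMI libraries); without
UMIs the pause sum at a high percentile (default 90th) stands in.  The
stability of incremental fits (70th..100th percentile of ranked sums) serves
as a diagnostic: UMI libraries vary a few-fold, non-UMI ones by orders of
magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InvalidParameterError, SaturationFitError

logger = logging.getLogger(__name__)

__all__ = [
    "SaturationFit",
    "fit_saturation",
    "incremental_saturation_stability",
    "max_occupancy",
    "scale_to_occupancy",
]

MIN_GENES_FOR_FIT = 100


@dataclass(frozen=True)
class SaturationFit:
    """Result of the occupancy calibration.

    ``max_occupancy_signal`` is the pause-sum signal corresponding to one
    polymerase per pause region; densities divided by it are occupancies.
    """

    method: str  # "tanh_fit" or "percentile"
    max_occupancy_signal: float
    A: float | None = None
    B: float | None = None
    C: float | None = None
    log_base: float = 10.0
    n_genes: int = 0

    @property
    def saturation_log(self) -> float | None:
        if self.A is None or self.C is None:
            return None
        return self.A + self.C

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "method": self.method,
                "A": self.A,
                "B": self.B,
                "C": self.C,
                "log_base": self.log_base,
                "saturation_log": self.saturation_log,
                "max_occupancy_signal": self.max_occupancy_signal,
                "n_genes": self.n_genes,
            }]
        )


def _tanh_model(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.tanh(b * x) + c


def fit_saturation(pause_sums: Sequence[float]) -> SaturationFit:
    """Fit the tanh saturation curve to ranked log10 pause sums.

    Requires at least 100 positive pause sums.  Raises SaturationFitError on
    non-convergence or a degenerate (flat) input; callers typically fall back
    to the percentile method.
    """
    sums = np.sort(np.asarray(pause_sums, dtype=float))
    sums = sums[sums > 0]
    n = sums.size
    if n < MIN_GENES_FOR_FIT:
        raise InvalidParameterError(
            f"saturation fit needs >= {MIN_GENES_FOR_FIT} positive pause sums, got {n}"
        )
    y = np.log10(sums)
    x = np.arange(1, n + 1, dtype=float)
    if np.ptp(y) == 0:
        raise SaturationFitError("all pause sums equal: no curvature to fit")
    # tanh fits are initialization-sensitive: start half-range amplitude,
    # mean offset, and a rate putting the bend mid-rank
    p0 = [np.ptp(y) / 2.0, 2.0 / n, float(np.mean(y))]
    try:
        popt, _ = curve_fit(
            _tanh_model, x, y, p0=p0,
            bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise SaturationFitError(f"tanh saturation fit failed: {exc}") from exc
    a, b, c = (float(v) for v in popt)
    if a + c > 300.0:  # would overflow float64: the plateau is unconstrained
        raise SaturationFitError(f"saturation 10^{a + c:.3g} diverged")
    saturation = float(10.0 ** (a + c))
    return SaturationFit(
        method="tanh_fit",
        max_occupancy_signal=saturation,
        A=a, B=b, C=c, n_genes=n,
    )


def incremental_saturation_stability(
    pause_sums: Sequence[float],
    percentiles: Sequence[float] = (70, 75, 80, 85, 90, 95, 100),
) -> float:
    """Fold variation (max/min) of saturation across incremental fits.

    Each fit uses only genes up to the given percentile of ranked pause
    sums.  A stable value (roughly 1.5-4x) indicates duplicate-free (UMI)
    data; orders-of-magnitude variation indicates the uncorrected
    exponential uptick of non-UMI libraries.
    """
    for q in percentiles:
        if not 0 < q <= 100:
            raise InvalidParameterError(f"percentile {q} outside (0, 100]")
    sums = np.sort(np.asarray(pause_sums, dtype=float))
    sums = sums[sums > 0]
    sats = []
    for q in percentiles:
        k = int(np.ceil(q / 100.0 * sums.size))
        fit = fit_saturation(sums[:k])
        sats.append(fit.max_occupancy_signal)
    return float(max(sats) / min(sats))


def max_occupancy(
    pause_sums: Sequence[float],
    has_umis: bool,
    percentile: float = 90.0,
) -> SaturationFit:
    """Maximum-occupancy signal for a dataset.

    UMI data: tanh-fit saturation over all expressed genes, falling back to
    the percentile order statistic (with a warning) if the fit fails or its
    saturation drops below the median pause sum.  Non-UMI data: the pause
    sum at ``percentile`` of the ranked expressed-gene pause sums.
    """
    sums = np.asarray(pause_sums, dtype=float)
    sums = sums[sums > 0]
    if sums.size == 0:
        raise InvalidParameterError("no positive pause sums")
    if has_umis:
        try:
            fit = fit_saturation(sums)
            # a plateau below the median or far above every observed pause
            # sum is an extrapolation artifact, not a saturation
            if np.median(sums) <= fit.max_occupancy_signal <= 1e3 * sums.max():
                return fit
            logger.warning(
                "tanh saturation %.3g outside the plausible range; "
                "falling back to percentile", fit.max_occupancy_signal,
            )
        except (SaturationFitError, InvalidParameterError) as exc:
            logger.warning("saturation fit failed (%s); falling back to percentile", exc)
    value = float(np.percentile(sums, percentile))
    return SaturationFit(
        method="percentile", max_occupancy_signal=value, n_genes=sums.size
    )


def scale_to_occupancy(densities: pd.DataFrame, fit: SaturationFit) -> pd.DataFrame:
    """Scale pause sums and body means to absolute occupancies.

    Adds ``p_occ`` (RNAP per pause region, clipped to <= 1), ``b_occ``
    (RNAP/bp) and a ``clipped_occupancy`` flag.  Pause sums above saturation
    are attributed to multicopy/mapping artifacts and clipped rather than
    dropped.
    """
    if fit.max_occupancy_signal <= 0:
        raise InvalidParameterError("max_occupancy_signal must be > 0")
    out = densities.copy()
    raw = out["pause_sum"] / fit.max_occupancy_signal
    out["p_occ"] = np.minimum(raw, 1.0)
    out["b_occ"] = out["body_mean"] / fit.max_occupancy_signal
    out["clipped_occupancy"] = raw > 1.0
    n_clip = int(out["clipped_occupancy"].sum())
    if n_clip:
        logger.info("%d genes above saturation clipped to occupancy 1", n_clip)
    return out
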