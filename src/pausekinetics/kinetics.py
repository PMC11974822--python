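"""Core kinetics of the two-compartment pausing model.

A gene is modelled as two compartments: the promoter-proximal pause region,
with polymerase density ``p``, and the gene body, with mean per-bp density
``b``.  Four first-order rate constants connect them:

* ``k_init`` — initiation (entry into the pause region), RNAP/min
* ``k_pre`` — premature termination of paused polymerases, 1/min
* ``k_rel`` — release of paused polymerases into the body, 1/min
* ``k_elong`` — elongation through the body, bp/min

The densities evolve as the coupled linear system

    dp/dt = k_init - (k_pre + k_rel) * p
    db/dt = k_rel * p - k_elong * b

whose steady state is ``p = k_init / (k_pre + k_rel)`` and
``b = (k_rel / k_elong) * p``.  Everything downstream — fold changes between
two conditions, bounds on the change in initiation, the premature-termination
to pause-release ratio, absolute rates and paused-polymerase half-lives —
follows algebraically from these two relations.

Internal time unit is minutes; half-lives are reported in seconds.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .errors import (
    DegenerateSteadyStateError,
    InvalidParameterError,
    UnscaledDensityError,
)

__all__ = [
    "RateSet",
    "SteadyState",
    "FoldChangeRecord",
    "Boundary",
    "TerminationReleaseRatio",
    "simulate_ode",
    "steady_state",
    "fold_change_pause_release",
    "fold_change_initiation_bounds",
    "fold_change_initiation_given_ratio",
    "pause_release_rate",
    "initiation_rate",
    "effective_pause_release",
    "polymerase_spacing",
    "termination_release_ratio",
    "pause_half_life",
]

#: Relative tolerance used to detect the zero/undefined boundaries of the
#: termination/release ratio.  Tight enough not to mask genuinely
#: near-boundary genes.
BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class RateSet:
    """The four rate constants for one gene in one condition.

    Units: ``k_init`` RNAP/min, ``k_pre`` and ``k_rel`` 1/min,
    ``k_elong`` bp/min.  All must be non-negative.
    """

    k_init: float
    k_pre: float
    k_rel: float
    k_elong: float

    def __post_init__(self) -> None:
        for name in ("k_init", "k_pre", "k_rel", "k_elong"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise InvalidParameterError(
                    f"{name} must be finite and >= 0, got {value!r}"
                )

    @property
    def k_exit(self) -> float:
        """Total exit rate from the pause region, ``k_pre + k_rel`` (1/min)."""
        return self.k_pre + self.k_rel


@dataclass(frozen=True)
class SteadyState:
    """Pause density ``p`` and mean body density ``b`` for one gene.

    ``scaled`` marks whether the densities are in absolute occupancy units
    (RNAP per pause region / RNAP per bp) rather than arbitrary signal units.
    """

    p: float
    b: float
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.p < 0 or self.b < 0:
            raise InvalidParameterError("densities must be >= 0")
        if self.scaled and self.p > 1:
            raise InvalidParameterError(
                "occupancy-scaled pause density must be <= 1 RNAP"
            )


class Regime(str, enum.Enum):
    """Which limit of the premature-termination / pause-release balance applies."""

    KPRE_DOMINANT = "kpre_dominant"
    KREL_DOMINANT = "krel_dominant"
    RATIO_R = "ratio_r"


@dataclass
class FoldChangeRecord:
    """Treatment/control fold changes for one gene.

    ``X`` is the ratio fold_change(k_init) / fold_change(p), the pivot
    quantity of the termination/release relation.
    """

    fc_p: float
    fc_b: float
    fc_krel: float
    fc_kinit_lower: float
    fc_kinit_upper: float
    fc_kinit_assigned: float | None = None
    X: float | None = None
    regime: Regime = Regime.RATIO_R
    flags: set[str] = field(default_factory=set)


class Boundary(str, enum.Enum):
    """Sentinels for the degenerate limits of the termination/release ratio."""

    ZERO_BOUNDARY = "zero_boundary"  # fc_kinit == fc_b: ratio -> 0
    UNDEFINED_BOUNDARY = "undefined_boundary"  # fc_kinit == fc_p: ratio undefined


@dataclass(frozen=True)
class TerminationReleaseRatio:
    """k_pre / k_rel(control) for one gene, or a boundary sentinel.

    ``negative`` flags a finite but physically inadmissible (negative) value,
    which arises when the supplied initiation fold change lies outside its
    admissible bounds.
    """

    value: float | None
    boundary: Boundary | None = None
    negative: bool = False

    @property
    def is_finite(self) -> bool:
        return self.value is not None and not self.negative


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise InvalidParameterError(
                f"{name} must be finite and > 0, got {value!r}"
            )


def steady_state(rates: RateSet) -> SteadyState:
    """Steady-state pause and body densities implied by a rate set.

    Raises
    ------
    DegenerateSteadyStateError
        If ``k_pre + k_rel == 0`` (the pause compartment never empties).
    InvalidParameterError
        If ``k_elong == 0`` (body density undefined).
    """
    if rates.k_exit == 0:
        raise DegenerateSteadyStateError(
            "steady state undefined: k_pre + k_rel must be > 0"
        )
    if rates.k_elong == 0:
        raise InvalidParameterError("k_elong must be > 0 for a body density")
    p = rates.k_init / rates.k_exit
    b = (rates.k_rel / rates.k_elong) * p
    return SteadyState(p=p, b=b)


def simulate_ode(
    rates: RateSet,
    p0: float,
    b0: float,
    duration: float,
    step: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trajectory of the pause/body system from (p0, b0).

    The system is linear with constant coefficients, so the trajectory is
    computed exactly via the matrix exponential of the affine-augmented
    system; ``step`` only sets the reporting grid.

    Returns ``(t, p, b)`` arrays including t=0 and t=duration.
    """
    if duration <= 0 or step <= 0:
        raise InvalidParameterError("duration and step must be > 0")
    if p0 < 0 or b0 < 0:
        raise InvalidParameterError("initial densities must be >= 0")

    n_steps = int(math.ceil(duration / step))
    t = np.minimum(np.arange(n_steps + 1, dtype=float) * step, float(duration))
    # affine augmentation: d/dt [p, b, 1] = M [p, b, 1]
    m = np.array(
        [
            [-rates.k_exit, 0.0, rates.k_init],
            [rates.k_rel, -rates.k_elong, 0.0],
            [0.0, 0.0, 0.0],
        ]
    )
    state = np.array([p0, b0, 1.0])
    propagator = expm(m * step)
    p = np.empty_like(t)
    b = np.empty_like(t)
    p[0], b[0] = p0, b0
    for i in range(1, n_steps + 1):
        if t[i] - t[i - 1] != step:  # final partial step
            state = expm(m * (t[i] - t[i - 1])) @ state
        else:
            state = propagator @ state
        p[i], b[i] = state[0], state[1]
    return t, p, b


def fold_change_pause_release(fc_b: float, fc_p: float) -> float:
    """Fold change in the pause-release rate, ``fc_b / fc_p``.

    This is the inverse of the fold change in pausing index and is invariant
    to any common rescaling of the densities.
    """
    _check_positive(fc_b=fc_b, fc_p=fc_p)
    return fc_b / fc_p


def fold_change_initiation_bounds(fc_p: float, fc_b: float) -> tuple[float, float]:
    """Bounds on the initiation fold change, ``(min, max)`` of (fc_p, fc_b).

    The k_pre >> k_rel limit gives fc_kinit -> fc_p; the k_pre << k_rel limit
    gives fc_kinit -> fc_b.  Which bound is lower depends on the gene.
    """
    _check_positive(fc_p=fc_p, fc_b=fc_b)
    return (min(fc_p, fc_b), max(fc_p, fc_b))


def fold_change_initiation_given_ratio(fc_p: float, fc_krel: float, r: float) -> float:
    """Initiation fold change for a known ratio ``r = k_pre / k_rel(control)``.

    fc_kinit = fc_p * (r + fc_krel) / (r + 1).  The limits r -> inf and
    r -> 0 reproduce the fc_p and fc_b bounds.
    """
    _check_positive(fc_p=fc_p, fc_krel=fc_krel)
    if r < 0 or not math.isfinite(r):
        if math.isinf(r) and r > 0:
            return fc_p
        raise InvalidParameterError(f"r must be >= 0, got {r!r}")
    return fc_p * (r + fc_krel) / (r + 1.0)


def pause_release_rate(k_elong: float, p: float, b: float) -> float:
    """Absolute pause-release rate ``k_rel = k_elong * b / p`` (1/min).

    Depends only on the body-to-pause density ratio, hence invariant to any
    common rescaling of ``p`` and ``b``.
    """
    _check_positive(k_elong=k_elong)
    if p <= 0:
        raise InvalidParameterError("pause density must be > 0 to define k_rel")
    if b < 0:
        raise InvalidParameterError("body density must be >= 0")
    return k_elong * b / p


def initiation_rate(
    p: float, b: float, k_pre: float, k_elong: float, *, scaled: bool = True
) -> float:
    """Absolute initiation rate ``k_init = p * k_pre + k_elong * b`` (RNAP/min).

    Requires occupancy-scaled densities (RNAP per pause region and RNAP/bp);
    on arbitrary signal units an absolute rate is meaningless.
    """
    if not scaled:
        raise UnscaledDensityError(
            "absolute initiation rate requires occupancy-scaled densities"
        )
    if p < 0 or b < 0:
        raise InvalidParameterError("densities must be >= 0")
    if k_pre < 0:
        raise InvalidParameterError("k_pre must be >= 0")
    _check_positive(k_elong=k_elong)
    return p * k_pre + k_elong * b


def effective_pause_release(k_rel: float, p: float) -> float:
    """Polymerases entering the body per minute, ``k_rel * p`` (RNAP/min).

    ``p`` must be occupancy-scaled (0..1 RNAP per pause region).
    """
    if not 0 <= p <= 1:
        raise UnscaledDensityError(
            f"effective release needs occupancy-scaled p in [0, 1], got {p!r}"
        )
    if k_rel < 0:
        raise InvalidParameterError("k_rel must be >= 0")
    return k_rel * p


def polymerase_spacing(b: float) -> float:
    """Mean spacing between gene-body polymerases, ``1 / b`` bp.

    ``b`` must be occupancy-scaled (RNAP/bp).  Returns ``inf`` for an empty
    body.
    """
    if b < 0:
        raise InvalidParameterError("body density must be >= 0")
    if b == 0:
        return math.inf
    return 1.0 / b


def termination_release_ratio(
    fc_krel: float,
    fc_kinit: float,
    fc_p: float,
    tol: float = BOUNDARY_TOL,
) -> TerminationReleaseRatio:
    """Ratio k_pre / k_rel(control) implied by the fold changes.

    With X = fc_kinit / fc_p the ratio is (fc_krel - X) / (X - 1).  The
    boundary X == fc_krel (fc_kinit == fc_b) maps to the ZERO_BOUNDARY
    sentinel and X == 1 (fc_kinit == fc_p) to UNDEFINED_BOUNDARY, detected at
    relative tolerance ``tol``.  A finite negative value is returned flagged
    as physically inadmissible rather than clipped.
    """
    _check_positive(fc_krel=fc_krel, fc_kinit=fc_kinit, fc_p=fc_p)
    x = fc_kinit / fc_p
    if abs(x - fc_krel) <= tol * max(abs(x), abs(fc_krel)):
        return TerminationReleaseRatio(value=None, boundary=Boundary.ZERO_BOUNDARY)
    if abs(x - 1.0) <= tol * max(abs(x), 1.0):
        return TerminationReleaseRatio(
            value=None, boundary=Boundary.UNDEFINED_BOUNDARY
        )
    value = (fc_krel - x) / (x - 1.0)
    return TerminationReleaseRatio(value=value, negative=value < 0)


def pause_half_life(k_pre: float, k_rel: float) -> float:
    """Half-life of a paused polymerase, ``60 * ln2 / (k_pre + k_rel)`` seconds.

    Returns ``inf`` when the total exit rate is zero.
    """
    if k_pre < 0 or k_rel < 0:
        raise InvalidParameterError("rates must be >= 0")
    total = k_pre + k_rel
    if total == 0:
        return math.inf
    return 60.0 * math.log(2.0) / total
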