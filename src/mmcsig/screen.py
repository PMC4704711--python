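"""Balancer-screen genetics: forward mutation frequency and three-factor mapping.

A reciprocal-translocation balancer suppresses recombination over part of a
chromosome, so a recessive lethal induced there can be kept as a stable
heterozygote.  Two statistics summarise such a screen:

* the **forward mutation frequency** — lethal mutations recovered per F1
  animal screened, in percent, a potency measure for the mutagen; and
* the **three-factor map position** of each lethal relative to two linked
  visible markers (here *dpy-5* and *unc-13* on chromosome I), estimated from
  brood phenotype counts.

The mapping cross scores surviving progeny as wild-type-appearing, Dpy-Unc,
Dpy, or Unc.  With recombination fraction ``p`` between the lethal and the
marker pair, Dpy-Unc recombinants survive with zygote probability
``p/2 - p^2/4`` while ``((1-p)/2)^2`` of zygotes die (lethal homozygotes) and
are never counted.  Writing ``R = 2*DpyUnc / ((4/3)*WT)`` — the 4/3 factor
reconstructs total surviving progeny from the wild-type class — gives
``E[R] = p - p^2/2`` and hence the phase-known estimator

    p = 1 - sqrt(1 - 2R),

which is exact because ``1 - 2(p - p^2/2) = (1 - p)^2``.  One map unit is 1%
recombination, so the map distance is ``100 p``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BroodCount",
    "MapEstimate",
    "ScreenTally",
    "ZoneClassification",
    "forward_mutation_frequency",
    "estimate_map_distance",
    "classify_positions",
    "p_from_R",
]


@dataclass(frozen=True)
class BroodCount:
    """Phenotype counts from one mapping cross brood (surviving animals only).

    The estimator uses only ``wt`` and ``dpy_unc``; the single-marker
    recombinant classes are recorded but unused.
    """

    wt: int
    dpy_unc: int
    dpy: int = 0
    unc: int = 0

    def __post_init__(self) -> None:
        for name in ("wt", "dpy_unc", "dpy", "unc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class MapEstimate:
    """Three-factor map-distance estimate with 95% confidence limits.

    ``R`` is the recombinant fraction, ``p`` the recombination frequency and
    ``map_units = 100 p``.  ``clamped`` flags broods whose raw ``R`` exceeded
    0.5 (outside the estimator's domain) and was clamped.
    """

    R: float
    p: float
    map_units: float
    ci_low: float
    ci_high: float
    clamped: bool = False

    def covers(self, map_units: float) -> bool:
        return self.ci_low <= map_units <= self.ci_high


@dataclass(frozen=True)
class ScreenTally:
    """One row of a forward-screen tally: F1s tested and lethals recovered."""

    n_f1: int
    n_lethal: int
    dose: float = float("nan")  # µM
    batch: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.n_lethal <= self.n_f1:
            raise ValueError("need 0 <= n_lethal <= n_f1")


def forward_mutation_frequency(tally: ScreenTally) -> float:
    """Lethal mutations per F1 screened, in percent.

    Computed as ``100 * n_lethal / n_f1``; round to one decimal for
    reporting.
    """
    if tally.n_f1 == 0:
        raise ValueError("no F1 animals tested")
    return 100.0 * tally.n_lethal / tally.n_f1


def p_from_R(R: float) -> float:
    """Recombination frequency from the recombinant fraction, p = 1 - sqrt(1 - 2R).

    Monotone increasing on [0, 0.5] with p(0) = 0 and p(0.5) = 1.
    """
    if R < 0:
        raise ValueError("R must be >= 0")
    return 1.0 - float(np.sqrt(max(0.0, 1.0 - 2.0 * R)))


def estimate_map_distance(brood: BroodCount, confidence: float = 0.95) -> MapEstimate:
    """Estimate the lethal's map distance from one brood.

    ``R = 2 dpy_unc / ((4/3) wt)``; ``p = 1 - sqrt(1 - 2R)``; map units are
    ``100 p``.  Confidence limits use the exact Clopper–Pearson binomial
    interval on ``dpy_unc`` successes out of ``round((4/3) wt)`` trials
    (recombinant counts here are small, where normal approximations fail),
    with each bound pushed through the same ``R -> p`` transform.
    """
    if brood.wt == 0:
        raise ValueError("wild-type count is zero; cannot normalise progeny total")
    trials = int(round(brood.wt * 4.0 / 3.0))
    R = 2.0 * brood.dpy_unc / (brood.wt * 4.0 / 3.0)
    clamped = False
    if R > 0.5:
        warnings.warn(
            f"recombinant fraction R={R:.3f} > 0.5; clamping to 0.5 (unlinked or mis-scored brood)",
            stacklevel=2,
        )
        R = 0.5
        clamped = True
    p = p_from_R(R)

    alpha = 1.0 - confidence
    k = min(brood.dpy_unc, trials)
    if k == 0:
        lo = 0.0
    else:
        lo = float(stats.beta.ppf(alpha / 2.0, k, trials - k + 1))
    if k == trials:
        hi = 1.0
    else:
        hi = float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, trials - k))
    # the binomial proportion is dpy_unc/trials = R/2, so bounds transform via R' = 2*bound
    p_lo = p_from_R(min(0.5, 2.0 * lo))
    p_hi = p_from_R(min(0.5, 2.0 * hi))
    return MapEstimate(
        R=R,
        p=p,
        map_units=100.0 * p,
        ci_low=100.0 * p_lo,
        ci_high=100.0 * p_hi,
        clamped=clamped,
    )


@dataclass(frozen=True)
class ZoneClassification:
    """Counts and one-decimal percentages of map positions per marker zone."""

    n_left: int
    n_between: int
    n_right: int

    @property
    def total(self) -> int:
        return self.n_left + self.n_between + self.n_right

    @property
    def percentages(self) -> tuple[float, float, float]:
        if self.total == 0:
            return (0.0, 0.0, 0.0)
        return tuple(round(100.0 * n / self.total, 1) for n in (self.n_left, self.n_between, self.n_right))  # type: ignore[return-value]


def classify_positions(
    positions: list[float] | np.ndarray,
    left_marker: float,
    right_marker: float,
) -> ZoneClassification:
    """Partition signed map positions against two marker positions.

    A position strictly below ``left_marker`` is "left", strictly above
    ``right_marker`` is "right"; anything else — including positions exactly
    on a marker — is "between" (deterministic tie-break).
    """
    if left_marker > right_marker:
        raise ValueError("left_marker must be <= right_marker")
    pos = np.asarray(positions, dtype=float)
    n_left = int(np.sum(pos < left_marker))
    n_right = int(np.sum(pos > right_marker))
    n_between = int(pos.size) - n_left - n_right
    return ZoneClassification(n_left=n_left, n_between=n_between, n_right=n_right)
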