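"""Staged selection probabilities, household design weights, diagnostics.

In the two relevant stages of the design, the probability that PSU i of
stratum h enters the sample is P1 = k * n_hi / N_h (an expected-hit rate
under with-replacement PPS; it can exceed 1 for certainty units), and the
probability of a given household within a selected PSU is P2 = 1 / m_hi,
where m_hi is the household count per SSU.  The design weight of an
interviewed household is the inverse of its overall selection
probability, w = 1 / (P1 * P2), with P1 capped at 1 inside the weight —
a certainty unit's inclusion probability is 1.

SSU plans follow three field rules: a PSU with fewer than 12 structures
is not segmented (one SSU); 12–150 structures give the standard 12 SSUs;
above 150 structures, ceil(n_structures / 12) SSUs of ~12 buildings each
are delineated; and a PSU hit t times in the PPS draw has its SSU count
scaled by t.  One household is interviewed per SSU.

`weight_diagnostics` reports the dispersion measures that drive the
weighting component of the design effect: the max/min weight ratio, the
relvariance cv²(w) = n Σw² / (Σw)² − 1, and the Kish unequal-weighting
effect deff_w = 1 + cv²(w).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "PSUProbability",
    "SSUPlan",
    "WeightRecord",
    "WeightDiagnostics",
    "psu_probability",
    "ssu_plan",
    "household_weight",
    "weight_diagnostics",
]

logger = logging.getLogger(__name__)

STANDARD_N_SSU = 12  # SSUs per PSU in the general case
SMALL_PSU_STRUCTURES = 12  # below this, the PSU is not segmented
LARGE_PSU_STRUCTURES = 150  # above this, delineate ceil(n/12) SSUs


class PSUProbability(NamedTuple):
    """First-stage expected-hit rate; is_certainty flags values above 1."""

    value: float
    is_certainty: bool


@dataclass(frozen=True)
class SSUPlan:
    """Segmentation plan for one selected PSU."""

    n_structures: int
    multiplicity: int
    n_ssu: int
    households_selected: int  # one interview per SSU


@dataclass(frozen=True)
class WeightRecord:
    household_id: str
    P1: float
    P2: float
    weight: float
    certainty_capped: bool = False


@dataclass(frozen=True)
class WeightDiagnostics:
    n: int
    ratio_max_min: float
    relvariance: float  # cv²(w) = n Σw²/(Σw)² − 1
    deff_w: float  # Kish unequal-weighting effect, 1 + cv²(w)


def psu_probability(pop_i: float, N_h: float, k: int) -> PSUProbability:
    """P1 = k * pop_i / N_h; flagged when it exceeds 1 (certainty unit)."""
    if pop_i == 0:
        raise ValueError("a zero-population unit cannot have been selected")
    if not 0 < pop_i <= N_h:
        raise ValueError("need 0 < pop_i <= N_h")
    if k < 1:
        raise ValueError("k must be >= 1")
    p = k * pop_i / N_h
    return PSUProbability(p, p > 1)


def ssu_plan(n_structures: int, multiplicity: int = 1) -> SSUPlan:
    """Apply the three segmentation rules, scaled by selection multiplicity."""
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    if n_structures < SMALL_PSU_STRUCTURES:
        base = 1
    elif n_structures <= LARGE_PSU_STRUCTURES:
        base = STANDARD_N_SSU
    else:
        base = math.ceil(n_structures / STANDARD_N_SSU)
    n_ssu = base * multiplicity
    return SSUPlan(n_structures, multiplicity, n_ssu, households_selected=n_ssu)


def household_weight(
    P1: float | PSUProbability,
    plan: SSUPlan,
    households_in_psu: int,
    household_id: str = "",
) -> WeightRecord:
    """Compose the two staged probabilities into a design weight.

    m = households_in_psu / n_ssu, P2 = 1/m, w = 1 / (min(P1, 1) * P2).
    Replacement PSUs pass the original PSU's P1 (their own population does
    not enter the weight).
    """
    p1 = P1.value if isinstance(P1, PSUProbability) else float(P1)
    if p1 <= 0:
        raise ValueError("P1 must be positive")
    if households_in_psu < plan.n_ssu:
        raise ValueError("households_in_psu must be >= the number of SSUs")
    capped = p1 > 1
    if capped:
        logger.info("P1 %.4f capped at 1 (certainty unit)", p1)
    p1_eff = min(p1, 1.0)
    m = households_in_psu / plan.n_ssu
    p2 = 1.0 / m
    return WeightRecord(
        household_id=household_id,
        P1=p1,
        P2=p2,
        weight=1.0 / (p1_eff * p2),
        certainty_capped=capped,
    )


def weight_diagnostics(weights: Sequence[float]) -> WeightDiagnostics:
    """Dispersion summary of a set of design weights (all > 0, n >= 2)."""
    w = np.asarray(weights, dtype=np.float64)
    if w.size < 2:
        raise ValueError("need at least two weights")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    deff = float(w.size * np.sum(w**2) / np.sum(w) ** 2)
    return WeightDiagnostics(
        n=int(w.size),
        ratio_max_min=float(w.max() / w.min()),
        relvariance=deff - 1.0,
        deff_w=deff,
    )
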