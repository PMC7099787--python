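"""PSU and household selection.

First stage: with-replacement systematic sampling with probability
proportional to size (PPS).  Units with positive population are cumulated
in frame order; with total T and k draws the selection interval is
I = T / k, a single uniform start u ~ U[0, I) is drawn, and the hit
positions u + j*I (j = 0..k-1) are mapped through the cumulative totals.
A unit whose population exceeds I is selected with certainty and may be
hit two or three times (multiplicity).  A separate, independently seeded
systematic pass of ceil(rate * k) draws provides the replacement list used
when a selected PSU turns out to hold no population.

Last stage: within a secondary sampling unit (SSU) a structure is chosen
uniformly at random, then one household uniformly within the structure —
the tablet-driven selection that keeps enumerator discretion out of the
field.  The probability of a given household is therefore
1 / (n_structures * n_households_in_its_structure).

All randomness flows from one user-supplied master seed through a
documented splitting scheme (`derive_seed`); every selection record
carries the derived seed that produced it, so any draw is replayable.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .quadtree import Frame

__all__ = [
    "SelectionRecord",
    "HouseholdSelection",
    "derive_seed",
    "pps_systematic",
    "replacement_sample",
    "select_household",
    "apply_exclusions",
]


@dataclass(frozen=True)
class SelectionRecord:
    """One selected PSU (possibly hit more than once)."""

    unit_id: str
    stratum_id: str
    multiplicity: int
    expected_hits: float  # k * p_i
    is_replacement: bool
    seed: int
    random_start: float


@dataclass(frozen=True)
class HouseholdSelection:
    """The structure/household drawn in one SSU."""

    ssu_index: int
    structure_index: int | None
    household_index: int | None
    needs_replacement: bool = False


def derive_seed(master_seed: int, *labels: str) -> int:
    """Derive a stream seed (< 2**31) from the master seed and a label path."""
    entropy = [int(master_seed)] + [zlib.crc32(lab.encode()) for lab in labels]
    state = np.random.SeedSequence(entropy).generate_state(1)[0]
    return int(state) % (2**31)


def _systematic_hits(pops: np.ndarray, k: int, start: float) -> np.ndarray:
    """Multiplicity per unit for a systematic pass from a fixed start."""
    cum = np.cumsum(pops)
    total = cum[-1]
    interval = total / k
    if not 0 <= start < interval:
        raise ValueError("start must lie in [0, interval)")
    positions = start + interval * np.arange(k)
    idx = np.searchsorted(cum, positions, side="right")
    return np.bincount(idx, minlength=len(pops))


def _pps_pass(
    frame: Frame, k: int, seed: int, is_replacement: bool
) -> list[SelectionRecord]:
    if k < 1:
        raise ValueError("k must be >= 1")
    eligible = [u for u in frame if u.population > 0]
    if not eligible:
        raise ValueError("frame has no unit with positive population")
    pops = np.array([u.population for u in eligible], dtype=np.float64)
    total = pops.sum()
    interval = total / k
    rng = np.random.default_rng(seed)
    start = float(rng.uniform(0.0, interval))
    hits = _systematic_hits(pops, k, start)
    records = []
    for i in np.flatnonzero(hits):
        u = eligible[i]
        records.append(
            SelectionRecord(
                unit_id=u.unit_id,
                stratum_id=u.stratum_id,
                multiplicity=int(hits[i]),
                expected_hits=float(k * pops[i] / total),
                is_replacement=is_replacement,
                seed=seed,
                random_start=start,
            )
        )
    return records


def pps_systematic(frame: Frame, k: int, seed: int) -> list[SelectionRecord]:
    """Main-sample systematic PPS draw of ``k`` hits from a frame.

    Zero-population units are excluded from the cumulation (selection
    probability 0).  The sum of multiplicities is exactly ``k`` and the
    draw is deterministic given ``seed``.
    """
    return _pps_pass(frame, k, derive_seed(seed, "pps-main"), is_replacement=False)


def replacement_sample(
    frame: Frame, k: int, rate: float = 0.2, seed: int = 0
) -> list[SelectionRecord]:
    """Independent systematic draw of ceil(rate * k) replacement PSUs."""
    if not 0 < rate:
        raise ValueError("rate must be positive")
    r = math.ceil(rate * k)
    return _pps_pass(frame, r, derive_seed(seed, "pps-replacement"), is_replacement=True)


def select_household(
    structures_per_ssu: Sequence[int],
    households_per_structure: Sequence[Sequence[int]],
    seed: int = 0,
) -> list[HouseholdSelection]:
    """Tablet-style two-stage uniform draw: one household per SSU.

    ``households_per_structure[i][s]`` is the household count of structure
    ``s`` in SSU ``i``.  An SSU with no structures is marked for
    replacement rather than raising.
    """
    if len(structures_per_ssu) != len(households_per_structure):
        raise ValueError("structures_per_ssu and households_per_structure disagree")
    rng = np.random.default_rng(derive_seed(seed, "household"))
    out = []
    for i, (n_struct, hh_counts) in enumerate(
        zip(structures_per_ssu, households_per_structure)
    ):
        if n_struct != len(hh_counts):
            raise ValueError(f"SSU {i}: structure count does not match household list")
        if n_struct == 0:
            out.append(HouseholdSelection(i, None, None, needs_replacement=True))
            continue
        if any(h < 1 for h in hh_counts):
            raise ValueError(f"SSU {i}: every structure must hold >= 1 household")
        s = int(rng.integers(n_struct))
        h = int(rng.integers(hh_counts[s]))
        out.append(HouseholdSelection(i, s, h))
    return out


def apply_exclusions(
    main: list[SelectionRecord],
    replacements: list[SelectionRecord],
    exclude_unit_ids: Sequence[str],
) -> list[SelectionRecord]:
    """Substitute excluded PSUs (e.g. no visible structures) from the
    replacement list, in list order.

    The substitute inherits the *original* PSU's selection probability
    (``expected_hits``): an empty PSU is out of scope, so the swap is
    unbiased only under that convention.  Runs out of replacements ->
    error.
    """
    exclude = set(exclude_unit_ids)
    pool = [r for r in replacements if r.unit_id not in exclude]
    out = []
    for rec in main:
        if rec.unit_id not in exclude:
            out.append(rec)
            continue
        if not pool:
            raise ValueError("replacement list exhausted while substituting")
        sub = pool.pop(0)
        out.append(
            SelectionRecord(
                unit_id=sub.unit_id,
                stratum_id=rec.stratum_id,
                multiplicity=rec.multiplicity,
                expected_hits=rec.expected_hits,  # original PSU's probability
                is_replacement=False,
                seed=sub.seed,
                random_start=sub.random_start,
            )
        )
    return out


def selections_to_dataframe(records: list[SelectionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in records],
            "stratum_id": [r.stratum_id for r in records],
            "multiplicity": [r.multiplicity for r in records],
            "expected_hits": [r.expected_hits for r in records],
            "is_replacement": [r.is_replacement for r in records],
            "seed": [r.seed for r in records],
            "random_start": [r.random_start for r in records],
        }
    )


def write_selections_csv(records: list[SelectionRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    selections_to_dataframe(records).to_csv(path, index=False)
    return path
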