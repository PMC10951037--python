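"""Two-phase developmental trajectory of a gene's relative cerebellar z-score.

The trajectory analysis fits no a-priori curve; it reports, per
developmental phase, the Pearson correlation between age (days post
conception, linear) and the target gene's cerebellar-relative z-score,
together with per-specimen elevation flags (z strictly above a normal
two-sided critical value, 1.96 by default).

Default phase windows: phase 1 covers foetal life through the first
postnatal year, phase 2 all postnatal specimens.  Whether first-year
infants belong to phase 2 as well is a convention; both are available
(see :func:`default_phases`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ages import BIRTH_DAYS, DAYS_PER_YEAR
from .relative import RelativeZMatrix

ELEVATION_THRESHOLD = 1.96


class InsufficientDataError(ValueError):
    """Raised when a phase window holds fewer than 3 usable specimens."""


@dataclass(frozen=True)
class PhaseDefinition:
    """Half-open age window [start_days, end_days) on the post-conception scale."""

    name: str
    start_days: float
    end_days: float  # math.inf for an unbounded window

    def __post_init__(self) -> None:
        if not self.start_days < self.end_days:
            raise ValueError(f"empty phase window {self.name!r}")

    def contains(self, days: float) -> bool:
        return self.start_days <= days < self.end_days


def default_phases(infants_in_phase2: bool = True) -> list[PhaseDefinition]:
    """The standard early/late windows.

    Phase 1: conception through the first postnatal year.  Phase 2: all
    postnatal specimens; with ``infants_in_phase2=False`` it instead
    starts at one postnatal year, so first-year infants appear only in
    phase 1.
    """
    first_year_end = BIRTH_DAYS + DAYS_PER_YEAR
    phase2_start = BIRTH_DAYS if infants_in_phase2 else first_year_end
    return [
        PhaseDefinition("early", 0.0, first_year_end),
        PhaseDefinition("late", phase2_start, math.inf),
    ]


@dataclass
class TrajectoryFit:
    phase: PhaseDefinition
    n: int
    pearson_r: float
    p_value: float
    elevation_threshold: float
    #: per-specimen table: donor_id, age_days, z, elevated
    specimens: pd.DataFrame


def fit_phase(
    zm: RelativeZMatrix,
    target_gene: str,
    phase: PhaseDefinition,
    elevation_threshold: float = ELEVATION_THRESHOLD,
) -> TrajectoryFit:
    """Pearson correlation of the target's z against age within one phase.

    The p-value is two-sided, from the t reference distribution with
    n - 2 degrees of freedom.  Elevation is strict: z must exceed the
    threshold; z equal to it is not elevated.
    """
    if target_gene not in zm.z.index:
        raise KeyError(f"target gene {target_gene!r} not in z-matrix")
    ages = zm.age_days()
    z = zm.z.loc[target_gene]
    usable = z.notna() & ages.apply(phase.contains)
    n = int(usable.sum())
    if n < 3:
        raise InsufficientDataError(
            f"phase {phase.name!r}: {n} specimens with usable z (need >= 3)"
        )
    x = ages[usable].to_numpy(float)
    y = z[usable].to_numpy(float)
    r, p = stats.pearsonr(x, y)
    table = pd.DataFrame(
        {
            "donor_id": z.index[usable],
            "age_days": x,
            "z": y,
            "elevated": y > elevation_threshold,
        }
    ).sort_values("age_days", ignore_index=True)
    return TrajectoryFit(phase, n, float(r), float(p), elevation_threshold, table)


def two_phase_report(
    zm: RelativeZMatrix,
    target_gene: str,
    phases: list[PhaseDefinition] | None = None,
    elevation_threshold: float = ELEVATION_THRESHOLD,
) -> tuple[list[TrajectoryFit], pd.DataFrame]:
    """Fit every phase and assemble a combined per-specimen table.

    Returns the per-phase fits plus one row per specimen with age, z,
    elevation, and a boolean membership column per phase (windows may
    overlap, so a specimen can belong to several phases).
    """
    phases = default_phases() if phases is None else phases
    fits = [fit_phase(zm, target_gene, ph, elevation_threshold) for ph in phases]
    ages = zm.age_days()
    z = zm.z.loc[target_gene]
    combined = pd.DataFrame(
        {
            "donor_id": zm.donor_ids,
            "age_days": ages.to_numpy(float),
            "z": z.to_numpy(float),
            "elevated": z.to_numpy(float) > elevation_threshold,
        }
    )
    for ph in phases:
        combined[f"in_{ph.name}"] = [ph.contains(a) for a in combined["age_days"]]
    return fits, combined.sort_values("age_days", ignore_index=True)


def write_trajectory_report(
    fits: list[TrajectoryFit], combined: pd.DataFrame, fits_path, specimens_path
) -> None:
    pd.DataFrame(
        [
            {
                "phase": f.phase.name,
                "start_days": f.phase.start_days,
                "end_days": f.phase.end_days,
                "n": f.n,
                "pearson_r": f.pearson_r,
                "p_value": f.p_value,
            }
            for f in fits
        ]
    ).to_csv(fits_path, sep="\t", index=False)
    combined.to_csv(specimens_path, sep="\t", index=False)
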