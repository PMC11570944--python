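"""Peptide-level deuteration: observable sites, uptake sums, and %BX.

Digestion converts the backbone amide of a peptide's first residue into an
amine, and the amide of residue 2 back-exchanges essentially completely
during processing, so bottom-up MS reads deuterium only from residue 3
onward (Pro positions excluded). The peptide deuterium content is the plain
sum of the per-residue occupancies over those observable sites, and the
maximum ideal deuteration of a Pro-free peptide of N residues is N - 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .intrinsic import validate_sequence
from .kinetics import (
    UptakeTrajectory,
    Workflow,
    fully_deuterated_start,
    simulate_workflow,
)
from .rate_table import RateParameterTable

__all__ = [
    "PeptideRegion",
    "PeptideUptake",
    "observable_sites",
    "peptide_uptake",
    "percent_back_exchange",
]

#: Side chains bulky/hydrophobic enough for partial residue-2 deuterium
#: retention in rare cases. Flagged with a warning, not modeled.
BULKY_HYDROPHOBIC = frozenset("WLVI")


@dataclass(frozen=True)
class PeptideRegion:
    """A proteolytic peptide mapped onto its parent sequence.

    Coordinates are 1-based and inclusive on both ends.
    """

    parent_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))
        if self.start < 1 or self.end < self.start:
            raise ValueError("need 1 <= start <= end")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("end - start + 1 must equal the peptide length")
        if any(aa in BULKY_HYDROPHOBIC for aa in self.sequence[:2]):
            warnings.warn(
                f"peptide {self.parent_id}[{self.start}-{self.end}] starts "
                "with a bulky hydrophobic residue (W/L/V/I); partial "
                "deuterium retention at residue 2 is possible but not modeled",
                stacklevel=2,
            )

    @classmethod
    def from_parent(
        cls, parent_sequence: str, start: int, end: int, parent_id: str = "protein"
    ) -> "PeptideRegion":
        parent = validate_sequence(parent_sequence)
        if end > len(parent):
            raise ValueError(
                f"peptide end {end} exceeds parent length {len(parent)}"
            )
        return cls(parent_id, start, end, parent[start - 1 : end])

    @property
    def N(self) -> int:
        """Peptide length in residues."""
        return len(self.sequence)

    @property
    def capacity(self) -> int:
        """Maximum ideal deuteration: N - 2 minus Pro among positions 3..N."""
        return len(observable_sites(self))


def observable_sites(peptide: PeptideRegion) -> list[int]:
    """Local (1-based) positions whose deuterium survives processing.

    Positions 3..N, excluding Pro. A tripeptide has exactly one observable
    site; shorter peptides have none and are rejected.
    """
    if peptide.N < 3:
        raise ValueError(
            f"peptide of length {peptide.N} has no observable sites "
            "(deuteration is only measurable from residue 3 onward)"
        )
    sites = [i for i in range(3, peptide.N + 1) if peptide.sequence[i - 1] != "P"]
    if not sites:
        raise ValueError("peptide has no observable sites (all of 3..N are Pro)")
    return sites


@dataclass(frozen=True)
class PeptideUptake:
    """Summed peptide deuterium content over a time grid (in deuterons)."""

    peptide: PeptideRegion
    times: np.ndarray
    d_pep: np.ndarray
    variant: str  # "raw" | "ideal"

    @property
    def capacity(self) -> int:
        return self.peptide.capacity


def peptide_uptake(
    trajectory: UptakeTrajectory, peptide: PeptideRegion, variant: str = "raw"
) -> PeptideUptake:
    """Sum the trajectory's occupancies over the peptide's observable sites.

    The trajectory must cover the peptide's parent coordinates with a
    matching sequence; `variant` is carried as metadata ("ideal" implies the
    trajectory came from a workflow without back-exchange stages).
    """
    if variant not in ("raw", "ideal"):
        raise ValueError("variant must be 'raw' or 'ideal'")
    if peptide.end > len(trajectory.sequence):
        raise ValueError("trajectory does not cover the peptide's coordinates")
    local = trajectory.sequence[peptide.start - 1 : peptide.end]
    if local != peptide.sequence:
        raise ValueError(
            f"trajectory sequence {local!r} at {peptide.start}-{peptide.end} "
            f"does not match peptide sequence {peptide.sequence!r}"
        )
    cols = [peptide.start - 1 + i - 1 for i in observable_sites(peptide)]
    d_pep = np.nansum(trajectory.occupancy[:, cols], axis=1)
    return PeptideUptake(peptide=peptide, times=trajectory.times, d_pep=d_pep, variant=variant)


def percent_back_exchange(
    workflow: Workflow,
    peptide: PeptideRegion,
    table: RateParameterTable | None = None,
) -> float:
    """Back-exchange level of a workflow, from a fully deuterated control.

    Starts the peptide at occupancy 1.0 on every exchanging site (the m100
    control entering the workflow at the quench point), applies only the
    unprotected post-quench stages plus the electrospray retention factor,
    sums the observable sites to D_pep_max_RAW, and returns
    ``100 * (1 - D_pep_max_RAW / capacity)``.

    Rates are evaluated in the peptide's own context, i.e. with terminal
    factors at the termini created by digestion.
    """
    bx_stages = workflow.back_exchange_stages
    if not bx_stages and workflow.esi_retention == 1.0:
        raise ValueError(
            "workflow has no back-exchange stages and no electrospray loss; "
            "%BX is undefined (trivially 0)"
        )
    capacity = peptide.capacity
    if capacity == 0:
        raise ValueError("peptide has zero deuteration capacity")
    if not bx_stages:
        return 100.0 * (1.0 - workflow.esi_retention)
    post = Workflow(stages=bx_stages, esi_retention=workflow.esi_retention)
    traj = simulate_workflow(
        peptide.sequence,
        protection=None,
        workflow=post,
        table=table,
        points_per_stage=2,
        start=fully_deuterated_start(peptide.sequence),
    )
    cols = [i - 1 for i in observable_sites(peptide)]  # trajectory is local
    d_max_raw = float(np.nansum(traj.final_occupancy[cols]))
    return 100.0 * (1.0 - d_max_raw / capacity)
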