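"""Per-residue deuteration kinetics through a multi-stage workflow.

Within the EX2 limit of the Linderstrom-Lang picture, each backbone amide
exchanges as a first-order relaxation toward the solvent's equilibrium
deuterium occupancy: during labeling in D2O an unlabeled site follows
``D(t) = 1 - exp(-k_HDX t)`` with ``k_HDX = k_ch / P`` (P = protection
factor), and during back exchange in H2O a deuterated site decays as
``D(t) = D0 * exp(-k_BX t)`` with ``k_BX = k_ch`` for an unprotected,
quenched peptide. A bottom-up workflow is an ordered list of such stages
(labeling, digestion, LC, ...), each with its own conditions, plus a single
terminal electrospray retention factor that multiplies all occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditions import ExchangeConditions
from .intrinsic import IntrinsicRateProfile, intrinsic_rate_profile, validate_sequence
from .rate_table import RateParameterTable

__all__ = [
    "ProtectionProfile",
    "ObservedRateProfile",
    "WorkflowStage",
    "Workflow",
    "UptakeTrajectory",
    "observed_rates",
    "relax_occupancy",
    "stage_rates",
    "simulate_workflow",
    "fully_deuterated_start",
]


@dataclass(frozen=True)
class ProtectionProfile:
    """Per-residue log10 protection factors.

    log P = 0 is an unprotected site (observed rate equals the intrinsic
    rate); strongly H-bonded sites in rigid secondary structure reach
    log P > 6. Values must be non-negative: within EX2, protection can only
    slow exchange.
    """

    log_p: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "log_p", np.asarray(self.log_p, dtype=float))
        if self.log_p.ndim != 1:
            raise ValueError("log_p must be one-dimensional")
        if np.any(self.log_p < 0):
            raise ValueError("log10 protection factors must be >= 0 (P >= 1)")

    @classmethod
    def uniform(cls, log_p: float, length: int) -> "ProtectionProfile":
        return cls(np.full(length, float(log_p)))

    def __len__(self) -> int:
        return len(self.log_p)


@dataclass(frozen=True)
class ObservedRateProfile:
    """Per-residue observed EX2 rates k_HDX = k_ch / P, in s^-1 (NaN = no amide)."""

    sequence: str
    rates: np.ndarray


def observed_rates(
    intrinsic: IntrinsicRateProfile, protection: ProtectionProfile
) -> ObservedRateProfile:
    """Slow each intrinsic rate by its protection factor (k_ch / 10**logP)."""
    if len(protection) != len(intrinsic.sequence):
        raise ValueError(
            f"protection profile length {len(protection)} does not match "
            f"sequence length {len(intrinsic.sequence)}"
        )
    return ObservedRateProfile(
        sequence=intrinsic.sequence,
        rates=intrinsic.rates / 10.0 ** protection.log_p,
    )


def relax_occupancy(start, rate, duration: float, target) -> np.ndarray | float:
    """First-order relaxation of deuterium occupancy toward `target`.

    ``target + (start - target) * exp(-rate * duration)`` — the closed form
    for both labeling (target 1) and back exchange (target 0). Accepts
    scalars or arrays; NaN rates (non-exchanging sites) propagate NaN.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if np.any(np.asarray(rate) < 0):
        raise ValueError("rate must be >= 0")
    return target + (start - target) * np.exp(-np.asarray(rate) * duration)


@dataclass(frozen=True)
class WorkflowStage:
    """One step of a bottom-up workflow.

    ``protected=True`` means the native protein is still folded and the
    protection profile applies; ``protected=False`` models quenched,
    unprotected peptide exchange (k_BX = k_ch). ``target_occupancy`` is the
    equilibrium occupancy imposed by the solvent: 1 for labeling in D2O,
    0 for processing in H2O.
    """

    label: str
    duration_s: float
    conditions: ExchangeConditions
    protected: bool
    target_occupancy: float

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError("stage duration must be >= 0")
        if not 0.0 <= self.target_occupancy <= 1.0:
            raise ValueError("target_occupancy must lie in [0, 1]")


@dataclass(frozen=True)
class Workflow:
    """Ordered stages plus a terminal electrospray retention factor."""

    stages: tuple[WorkflowStage, ...]
    esi_retention: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        if not self.stages:
            raise ValueError("a workflow needs at least one stage")
        if not 0.0 < self.esi_retention <= 1.0:
            raise ValueError("esi_retention must lie in (0, 1]")

    @property
    def labeling_stages(self) -> tuple[WorkflowStage, ...]:
        return tuple(s for s in self.stages if s.protected)

    @property
    def back_exchange_stages(self) -> tuple[WorkflowStage, ...]:
        return tuple(s for s in self.stages if not s.protected)


@dataclass(frozen=True)
class UptakeTrajectory:
    """Per-residue occupancy D_j(t) sampled over the workflow timeline.

    Times are measured from the start of the first stage and include every
    stage boundary; the electrospray retention factor produces the single
    allowed discontinuity, recorded as a duplicated final time point labeled
    ``"esi"``.
    """

    sequence: str
    times: np.ndarray
    occupancy: np.ndarray  # shape (n_times, n_residues), NaN at non-amide sites
    stage_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        defined = self.occupancy[:, ~np.isnan(self.occupancy).all(axis=0)]
        if defined.size and (np.nanmin(defined) < -1e-12 or np.nanmax(defined) > 1 + 1e-12):
            raise ValueError("occupancies must lie in [0, 1]")

    @property
    def final_occupancy(self) -> np.ndarray:
        return self.occupancy[-1]

    def to_frame(self):
        """Long-format table (time_s, position, residue, occupancy, stage_label)."""
        import pandas as pd

        n_t, n_r = self.occupancy.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, n_r),
                "position": np.tile(np.arange(1, n_r + 1), n_t),
                "residue": list(self.sequence) * n_t,
                "occupancy": self.occupancy.ravel(),
                "stage_label": np.repeat(self.stage_labels, n_r),
            }
        )


def fully_deuterated_start(sequence: str) -> np.ndarray:
    """Occupancy vector of a fully deuterated chain: 1.0 at every exchanging
    backbone amide, NaN at residue 1 and at Pro positions."""
    seq = validate_sequence(sequence)
    occ = np.ones(len(seq))
    occ[0] = np.nan
    occ[[i for i, aa in enumerate(seq) if aa == "P"]] = np.nan
    return occ


def stage_rates(
    sequence: str,
    stage: WorkflowStage,
    protection: ProtectionProfile | None,
    table: RateParameterTable | None = None,
) -> np.ndarray:
    """Per-residue first-order rates (s^-1) that apply during one stage.

    Protected stages divide the intrinsic rates by the protection factors;
    unprotected (quenched) stages use the intrinsic rates directly.
    """
    intrinsic = intrinsic_rate_profile(sequence, stage.conditions, table)
    if stage.protected:
        if protection is None:
            raise ValueError(
                f"stage {stage.label!r} is protected but no protection "
                "profile was supplied"
            )
        return observed_rates(intrinsic, protection).rates
    return intrinsic.rates


def _stage_grid(duration: float, points: int) -> np.ndarray:
    """Relative sample times within a stage: geometric interior + boundaries."""
    if duration == 0 or points <= 2:
        return np.array([duration])
    interior = np.geomspace(duration * 1e-4, duration, points - 1)
    return np.unique(np.concatenate([interior, [duration]]))


def simulate_workflow(
    sequence: str,
    protection: ProtectionProfile | None,
    workflow: Workflow,
    table: RateParameterTable | None = None,
    points_per_stage: int = 50,
    start: np.ndarray | None = None,
) -> UptakeTrajectory:
    """Propagate per-residue occupancies through every workflow stage.

    Each stage relaxes the occupancies toward its ``target_occupancy`` with
    rates recomputed for that stage's conditions (closed-form, exact for
    piecewise-constant conditions); the electrospray retention factor is
    applied once, after the final stage.

    Parameters
    ----------
    start : ndarray, optional
        Initial occupancies; defaults to an undeuterated chain (0 at every
        exchanging site). Use :func:`fully_deuterated_start` for an m100
        control entering the workflow at the quench point.
    """
    seq = validate_sequence(sequence)
    if protection is not None and len(protection) != len(seq):
        raise ValueError("protection profile length does not match sequence")

    occ = fully_deuterated_start(seq) * 0.0 if start is None else np.array(start, dtype=float)
    times = [0.0]
    labels = [workflow.stages[0].label]
    snapshots = [occ.copy()]
    t0 = 0.0
    for stage in workflow.stages:
        rates = stage_rates(seq, stage, protection, table)
        for t_rel in _stage_grid(stage.duration_s, points_per_stage):
            # NaN rates (residue 1, Pro) propagate NaN occupancies by themselves
            snapshots.append(relax_occupancy(occ, rates, t_rel, stage.target_occupancy))
            times.append(t0 + t_rel)
            labels.append(stage.label)
        occ = snapshots[-1].copy()
        t0 += stage.duration_s
    # terminal electrospray loss: the single allowed discontinuity
    snapshots.append(occ * workflow.esi_retention)
    times.append(t0)
    labels.append("esi")

    return UptakeTrajectory(
        sequence=seq,
        times=np.asarray(times),
        occupancy=np.vstack(snapshots),
        stage_labels=tuple(labels),
    )
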