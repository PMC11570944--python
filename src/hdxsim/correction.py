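"""The classic back-exchange correction and how badly it can distort kinetics.

The standard correction rescales a measured uptake curve by the fully
deuterated control,

    D_pep_CORR(t) = D_pep_RAW(t) / D_pep_max_RAW * (N - 2),

the occupancy-level form of (m - m0)/(m100 - m0) * (N - 2). It is exact when
every observable site loses deuterium at the same rate — a single observable
site (tripeptide) or a homopolymer — because the common exp(-k_BX t_BX)
factor cancels. For heterogeneous peptides the per-site decay factors do not
cancel, and the corrected curve deviates from the back-exchange-free ideal;
this module quantifies that deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditions import AcidityScale, Direction, ExchangeConditions
from .kinetics import ProtectionProfile, Workflow, WorkflowStage, stage_rates
from .peptides import PeptideRegion, observable_sites
from .rate_table import RateParameterTable

__all__ = [
    "CorrectionInputs",
    "CorrectionAssessment",
    "classic_correction",
    "assess_correction",
    "bx_protection_sweep",
    "QUENCH_CONDITIONS",
]

#: Quench-pipeline conditions used for single-stage back-exchange scenarios:
#: pH 2.5 in H2O at 0 degrees C.
QUENCH_CONDITIONS = ExchangeConditions(
    acidity_value=2.5,
    acidity_scale=AcidityScale.PH_IN_H2O,
    temperature=273.15,
    direction=Direction.D_TO_H,
)


@dataclass(frozen=True)
class CorrectionInputs:
    """Measured quantities entering the classic correction."""

    d_raw: np.ndarray  # D_pep_RAW(t_HDX), i.e. m(t) - m0, in deuterons
    d_max_raw: float  # fully deuterated control level, m100 - m0
    capacity: float  # maximum ideal deuteration, N - 2 convention

    def __post_init__(self) -> None:
        object.__setattr__(self, "d_raw", np.asarray(self.d_raw, dtype=float))
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")


def classic_correction(inputs: CorrectionInputs) -> np.ndarray:
    """Pointwise rescaling D_RAW / D_max_RAW * capacity."""
    if inputs.d_max_raw == 0:
        raise ZeroDivisionError(
            "fully deuterated control retained no deuterium (D_pep_max_RAW = 0); "
            "the classic correction is undefined — the workflow back-exchanges "
            "everything"
        )
    return inputs.d_raw / inputs.d_max_raw * inputs.capacity


@dataclass(frozen=True)
class CorrectionAssessment:
    """Raw, corrected, and ideal uptake curves plus distortion metrics."""

    scenario: str
    peptide: PeptideRegion
    t_hdx: np.ndarray
    d_raw: np.ndarray
    d_corr: np.ndarray
    d_ideal: np.ndarray
    d_max_raw: float
    percent_bx: float
    bias: np.ndarray  # signed d_corr - d_ideal per time point

    @property
    def max_abs_dev(self) -> float:
        return float(np.max(np.abs(self.bias)))

    @property
    def rmsd(self) -> float:
        return float(np.sqrt(np.mean(self.bias**2)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_hdx_s": self.t_hdx,
                "d_raw": self.d_raw,
                "d_corr": self.d_corr,
                "d_ideal": self.d_ideal,
            }
        )

    def summary(self) -> dict:
        return {
            "scenario": self.scenario,
            "percent_bx": self.percent_bx,
            "max_abs_dev": self.max_abs_dev,
            "rmsd": self.rmsd,
        }


def _split_workflow(workflow: Workflow) -> tuple[WorkflowStage, tuple[WorkflowStage, ...]]:
    """A correction scenario = one leading labeling stage + H2O processing."""
    first, rest = workflow.stages[0], workflow.stages[1:]
    if not first.protected:
        raise ValueError(
            "the first workflow stage must be the (protected) labeling stage"
        )
    if any(s.protected for s in rest):
        raise ValueError("labeling must precede all back-exchange stages")
    if any(s.target_occupancy != 0.0 for s in rest):
        raise ValueError("post-quench stages must relax toward occupancy 0 (H2O)")
    return first, rest


def assess_correction(
    sequence: str,
    protection: ProtectionProfile,
    workflow: Workflow,
    table: RateParameterTable | None = None,
    t_hdx: np.ndarray | None = None,
    scenario: str = "assessment",
) -> CorrectionAssessment:
    """Compare the classic correction against the back-exchange-free ideal.

    The workflow's first stage defines the labeling conditions (its duration
    is ignored — the labeling time is swept over `t_hdx`); the remaining
    stages and the electrospray retention factor define the processing
    pipeline. For each labeling duration the raw, ideal, and corrected
    peptide uptake values are computed in closed form, together with the
    distortion of the corrected curve.
    """
    if t_hdx is None:
        t_hdx = np.geomspace(1.0, 7200.0, 40)
    t_hdx = np.asarray(t_hdx, dtype=float)
    if t_hdx.size == 0:
        raise ValueError("t_hdx grid is empty")

    peptide = PeptideRegion.from_parent(sequence, 1, len(sequence))
    labeling, post = _split_workflow(workflow)

    cols = np.array([i - 1 for i in observable_sites(peptide)])
    k_lab = stage_rates(peptide.sequence, labeling, protection, table)[cols]
    decay = np.full(cols.shape, workflow.esi_retention)
    for stage in post:
        k_bx = stage_rates(peptide.sequence, stage, None, table)[cols]
        decay *= np.exp(-k_bx * stage.duration_s)

    # site-level labeling curves, shape (n_times, n_sites)
    d_site_ideal = labeling.target_occupancy * (1.0 - np.exp(-np.outer(t_hdx, k_lab)))
    d_ideal = d_site_ideal.sum(axis=1)
    d_raw = (d_site_ideal * decay).sum(axis=1)
    d_max_raw = float(decay.sum())

    d_corr = classic_correction(
        CorrectionInputs(d_raw=d_raw, d_max_raw=d_max_raw, capacity=peptide.capacity)
    )
    return CorrectionAssessment(
        scenario=scenario,
        peptide=peptide,
        t_hdx=t_hdx,
        d_raw=d_raw,
        d_corr=d_corr,
        d_ideal=d_ideal,
        d_max_raw=d_max_raw,
        percent_bx=100.0 * (1.0 - d_max_raw / peptide.capacity),
        bias=d_corr - d_ideal,
    )


def bx_protection_sweep(
    sequence: str,
    protections: list[tuple[str, ProtectionProfile]],
    bx_durations_s: list[float],
    labeling_conditions: ExchangeConditions,
    table: RateParameterTable | None = None,
    t_hdx: np.ndarray | None = None,
    quench_conditions: ExchangeConditions = QUENCH_CONDITIONS,
) -> tuple[list[list[CorrectionAssessment]], pd.DataFrame]:
    """Factorial sweep of protection sets against back-exchange durations.

    Each cell models a single unprotected back-exchange stage of the given
    duration under `quench_conditions` with no electrospray loss, mirroring
    the way %BX levels are usually dialed in by LC time.

    Returns
    -------
    grid : list of list of CorrectionAssessment
        Indexed ``[i_protection][j_duration]``.
    summary : pandas.DataFrame
        One row per cell: protection label, t_bx_s, percent_bx,
        max_abs_dev, rmsd.
    """
    if not protections or not bx_durations_s:
        raise ValueError("need at least one protection set and one duration")
    grid: list[list[CorrectionAssessment]] = []
    rows = []
    for label, profile in protections:
        row = []
        for t_bx in bx_durations_s:
            workflow = Workflow(
                stages=(
                    WorkflowStage(
                        "labeling", 0.0, labeling_conditions, True, 1.0
                    ),
                    WorkflowStage("back-exchange", t_bx, quench_conditions, False, 0.0),
                ),
                esi_retention=1.0,
            )
            a = assess_correction(
                sequence, profile, workflow, table, t_hdx,
                scenario=f"{label}/t_bx={t_bx:g}s",
            )
            row.append(a)
            rows.append(
                {
                    "protection": label,
                    "t_bx_s": t_bx,
                    "percent_bx": a.percent_bx,
                    "max_abs_dev": a.max_abs_dev,
                    "rmsd": a.rmsd,
                }
            )
        grid.append(row)
    return grid, pd.DataFrame(rows)
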