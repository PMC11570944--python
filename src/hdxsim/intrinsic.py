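"""Sequence-dependent intrinsic (unprotected) amide exchange rates.

The chemical exchange rate constant of the backbone amide of residue *j* is
modeled as the sum of acid-, base-, and water-catalyzed pathways,

    k_ch_j = kA * FA_j * [cat+]  +  kB * FB_j * [cat-]  +  kW * FB_j,

where the catalyst concentrations follow from the acidity and the solvent
autoionization constant, each reference rate is Arrhenius-scaled from the
table's reference temperature, and FA_j / FB_j collect the multiplicative
side-chain perturbation factors of residue *j* itself ("own") and of residue
*j*-1 ("next", i.e. its effect on the following amide). Free termini
contribute additional factors: the alpha-ammonium group to the amide of
residue 2 and the alpha-carboxyl group to the amide of the final residue.

Residue 1 (no backbone amide after digestion converts it to an amine) and Pro
(no backbone NH) are marked not-exchanging with NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conditions import ExchangeConditions
from .rate_table import STANDARD_AA, RateParameterTable, load_default_table

__all__ = ["IntrinsicRateProfile", "intrinsic_rate_profile", "validate_sequence"]


def validate_sequence(sequence: str) -> str:
    """Upper-case and validate a one-letter amino-acid sequence.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a non-standard code; the message
        names the 1-based position of the first offending character.
    """
    if not sequence:
        raise ValueError("sequence is empty")
    seq = sequence.upper()
    for i, aa in enumerate(seq, start=1):
        if aa not in STANDARD_AA:
            raise ValueError(
                f"unknown residue code {aa!r} at position {i}; only the 20 "
                "standard one-letter codes are supported"
            )
    return seq


@dataclass(frozen=True)
class IntrinsicRateProfile:
    """Per-residue chemical exchange rate constants for one condition set.

    ``rates`` is in s^-1, aligned with ``sequence`` (index 0 = residue 1);
    NaN marks non-exchanging positions (residue 1 and Pro).
    """

    sequence: str
    conditions: ExchangeConditions
    rates: np.ndarray

    def __post_init__(self) -> None:
        if len(self.rates) != len(self.sequence):
            raise ValueError("rates length does not match sequence length")

    @property
    def exchanging(self) -> np.ndarray:
        """Boolean mask of positions that carry an exchanging backbone amide."""
        return ~np.isnan(self.rates)


def intrinsic_rate_profile(
    sequence: str,
    conditions: ExchangeConditions,
    table: RateParameterTable | None = None,
    include_cterm_factor: bool = False,
) -> IntrinsicRateProfile:
    """Compute k_ch for every backbone amide of `sequence` under `conditions`.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid sequence (chain with free termini).
    conditions : ExchangeConditions
        Acidity, temperature, and isotope direction.
    table : RateParameterTable, optional
        Defaults to the packaged, checksummed parameter table.
    include_cterm_factor : bool, optional
        Also apply the alpha-carboxyl perturbation to the final residue's
        amide. Off by default: the free-amine factor at the new N-terminus
        only touches residue 2 (never observable after digestion), whereas a
        C-terminal perturbation would make the last observable site of a
        homopolymer exchange at its own rate, contradicting the uniform-rate
        exactness of the classic correction for poly-X peptides. The table
        carries the carboxyl factors for callers who want them.

    Returns
    -------
    IntrinsicRateProfile
        Rates in s^-1; NaN at residue 1 and at Pro positions.
    """
    table = table or load_default_table()
    seq = validate_sequence(sequence)
    n = len(seq)
    acidity = conditions.effective_acidity
    direction = conditions.direction

    ref = table.reference_rates(direction)
    cat_acid = 10.0 ** (-acidity)
    cat_base = 10.0 ** (acidity - ref.pK_solvent)
    # min^-1 prefactors, Arrhenius-scaled per pathway, converted to s^-1 at the end
    pre_acid = 10.0 ** ref.log_kA * cat_acid * table.arrhenius("acid", conditions.temperature)
    pre_base = 10.0 ** ref.log_kB * cat_base * table.arrhenius("base", conditions.temperature)
    pre_water = 10.0 ** ref.log_kW * table.arrhenius("water", conditions.temperature)

    # factors[i] = [acid_own, acid_next, base_own, base_next] for residue i+1
    factors = np.stack([table.mixed_factors(aa, acidity, direction) for aa in seq])
    nterm = table.mixed_factors("Nterm", acidity, direction)
    cterm = table.mixed_factors("Cterm", acidity, direction)

    rates = np.full(n, np.nan)
    for j in range(1, n):  # 0-based index of residue j+1; residue 1 has no amide
        if not table.exchanges(seq[j]):
            continue
        fa = factors[j, 0] * factors[j - 1, 1]
        fb = factors[j, 2] * factors[j - 1, 3]
        if j == 1:  # amide of residue 2 feels the free alpha-amino group
            fa *= nterm[1]
            fb *= nterm[3]
        if include_cterm_factor and j == n - 1:
            fa *= cterm[0]
            fb *= cterm[2]
        rates[j] = (pre_acid * fa + (pre_base + pre_water) * fb) / 60.0

    return IntrinsicRateProfile(sequence=seq, conditions=conditions, rates=rates)
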