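"""Packaged rate-parameter table for intrinsic amide exchange.

The table bundles the poly-DL-alanine reference rate constants for the acid-,
base-, and water-catalyzed exchange pathways (per isotope direction), their
activation energies, the solvent autoionization constants, and the per-residue
side-chain perturbation factors from the classic NMR dipeptide calibration.
It ships as a checksummed TSV under ``hdxsim/data`` and loads bit-identically.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .conditions import Direction

__all__ = ["RateParameterTable", "ResidueFactors", "load_default_table"]

#: Gas constant in cal mol^-1 K^-1 (the activation energies are tabulated in cal).
R_CAL = 1.98720425864083

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: SHA-256 of the packaged rate_params.tsv; guards against silent edits.
PACKAGED_TABLE_SHA256 = (
    "49d9f78a3ab95654a0391214a035f3c637d90c932d5a0eeb4939ac37fcf0e8b7"
)


@dataclass(frozen=True)
class ResidueFactors:
    """log10 perturbation factors of one side chain (one protonation state).

    ``*_own`` acts on the residue's own backbone amide, ``*_next`` on the
    amide of the following residue. The water pathway reuses the base factors.
    """

    acid_own: float
    acid_next: float
    base_own: float
    base_next: float


@dataclass(frozen=True)
class _ResidueEntry:
    exchanges: bool
    protonated: ResidueFactors
    deprotonated: ResidueFactors | None = None
    pK_H2O: float | None = None
    pK_D2O: float | None = None


@dataclass(frozen=True)
class PathwayConstants:
    """Reference rates (log10) and solvent pK for one isotope direction."""

    log_kA: float  # M^-1 min^-1 at the reference temperature
    log_kB: float  # M^-1 min^-1
    log_kW: float  # min^-1
    pK_solvent: float


@dataclass
class RateParameterTable:
    """In-memory form of the packaged exchange-rate parameter file.

    Attributes
    ----------
    reference_temperature : float
        Temperature (K) at which the reference rates are tabulated.
    activation_energies : dict
        cal/mol per pathway, keys ``acid``/``base``/``water``. These are
        constant-acidity effective barriers: the base-pathway value folds in
        the solvent ionization enthalpy, so catalyst concentrations are
        always evaluated with the reference-temperature pK.
    checksum : str
        SHA-256 hex digest of the source file.
    """

    reference_temperature: float
    pathways: dict[Direction, PathwayConstants]
    activation_energies: dict[str, float]
    residues: dict[str, _ResidueEntry]
    checksum: str
    source: str = "packaged"

    # ---------------------------------------------------------------- loading

    @classmethod
    def from_file(cls, path: str | Path) -> "RateParameterTable":
        data = Path(path).read_bytes()
        return cls.from_bytes(data, source=str(path))

    @classmethod
    def from_bytes(cls, data: bytes, source: str = "<bytes>") -> "RateParameterTable":
        checksum = hashlib.sha256(data).hexdigest()
        scalars: dict[str, float] = {}
        rows: list[list[str]] = []
        header: list[str] | None = None
        for raw in data.decode("utf-8").splitlines():
            line = raw.rstrip("\n")
            if line.startswith("#!"):
                key, value = line[2:].split("\t")
                scalars[key.strip()] = float(value)
            elif line.startswith("#") or not line.strip():
                continue
            elif header is None:
                header = line.split("\t")
            else:
                rows.append(line.split("\t"))

        required = {
            "reference_temperature_K",
            "log_kA_HD", "log_kB_HD", "log_kW_HD", "pK_solvent_HD",
            "log_kA_DH", "log_kB_DH", "log_kW_DH", "pK_solvent_DH",
            "Ea_acid_cal_mol", "Ea_base_cal_mol", "Ea_water_cal_mol",
        }
        missing = required - scalars.keys()
        if missing:
            raise ValueError(f"rate table is missing scalar constants: {sorted(missing)}")

        cols = {name: i for i, name in enumerate(header or [])}
        entries: dict[str, dict[str, tuple[ResidueFactors, bool, float | None, float | None]]] = {}
        for row in rows:
            res = row[cols["residue"]]
            variant = row[cols["variant"]]
            factors = ResidueFactors(
                acid_own=float(row[cols["acid_own"]]),
                acid_next=float(row[cols["acid_next"]]),
                base_own=float(row[cols["base_own"]]),
                base_next=float(row[cols["base_next"]]),
            )
            exchanges = row[cols["exchanges"]] == "1"
            pk_h = row[cols["pK_H2O"]]
            pk_d = row[cols["pK_D2O"]]
            entries.setdefault(res, {})[variant] = (
                factors,
                exchanges,
                None if pk_h == "." else float(pk_h),
                None if pk_d == "." else float(pk_d),
            )

        residues: dict[str, _ResidueEntry] = {}
        for res, variants in entries.items():
            if "-" in variants:
                fac, exch, _, _ = variants["-"]
                residues[res] = _ResidueEntry(exchanges=exch, protonated=fac)
            else:
                fac_p, exch, pk_h, pk_d = variants["prot"]
                fac_d = variants["deprot"][0] if "deprot" in variants else None
                residues[res] = _ResidueEntry(
                    exchanges=exch, protonated=fac_p, deprotonated=fac_d,
                    pK_H2O=pk_h, pK_D2O=pk_d,
                )

        missing_aa = sorted(set(STANDARD_AA) - residues.keys())
        if missing_aa:
            raise ValueError(f"rate table lacks standard residues: {missing_aa}")
        if residues["P"].exchanges:
            raise ValueError("rate table must flag Pro as lacking a backbone NH")

        return cls(
            reference_temperature=scalars["reference_temperature_K"],
            pathways={
                Direction.H_TO_D: PathwayConstants(
                    scalars["log_kA_HD"], scalars["log_kB_HD"],
                    scalars["log_kW_HD"], scalars["pK_solvent_HD"],
                ),
                Direction.D_TO_H: PathwayConstants(
                    scalars["log_kA_DH"], scalars["log_kB_DH"],
                    scalars["log_kW_DH"], scalars["pK_solvent_DH"],
                ),
            },
            activation_energies={
                "acid": scalars["Ea_acid_cal_mol"],
                "base": scalars["Ea_base_cal_mol"],
                "water": scalars["Ea_water_cal_mol"],
            },
            residues=residues,
            checksum=checksum,
            source=source,
        )

    # ---------------------------------------------------------------- queries

    def exchanges(self, residue: str) -> bool:
        return self._entry(residue).exchanges

    def _entry(self, residue: str) -> _ResidueEntry:
        try:
            return self.residues[residue]
        except KeyError:
            raise KeyError(f"residue code {residue!r} not in rate table") from None

    def mixed_factors(self, residue: str, acidity: float, direction: Direction) -> np.ndarray:
        """Multiplicative (linear) perturbation factors at a given acidity.

        For ionizable side chains the protonated and deprotonated factors are
        population-averaged on the linear scale, using the model-compound pK
        for the solvent implied by `direction`.

        Returns
        -------
        numpy.ndarray
            ``[acid_own, acid_next, base_own, base_next]`` as multiplicative
            factors (10**log10).
        """
        entry = self._entry(residue)
        prot = np.array(
            [entry.protonated.acid_own, entry.protonated.acid_next,
             entry.protonated.base_own, entry.protonated.base_next]
        )
        if entry.deprotonated is None:
            return 10.0 ** prot
        deprot = np.array(
            [entry.deprotonated.acid_own, entry.deprotonated.acid_next,
             entry.deprotonated.base_own, entry.deprotonated.base_next]
        )
        pk = entry.pK_D2O if direction is Direction.H_TO_D else entry.pK_H2O
        frac_prot = 1.0 / (1.0 + 10.0 ** (acidity - pk))
        return frac_prot * 10.0 ** prot + (1.0 - frac_prot) * 10.0 ** deprot

    def arrhenius(self, pathway: str, temperature: float) -> float:
        """Rate scale factor for `pathway` at `temperature` vs. the reference."""
        ea = self.activation_energies[pathway]
        t0 = self.reference_temperature
        return math.exp(-(ea / R_CAL) * (1.0 / temperature - 1.0 / t0))

    def reference_rates(self, direction: Direction) -> PathwayConstants:
        try:
            return self.pathways[direction]
        except KeyError:  # pragma: no cover - both directions always packaged
            raise ValueError(f"no reference rates for direction {direction}") from None


_DEFAULT_TABLE: RateParameterTable | None = None


def load_default_table() -> RateParameterTable:
    """Load (and cache) the packaged parameter table, verifying its checksum."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        data = (resources.files("hdxsim.data") / "rate_params.tsv").read_bytes()
        table = RateParameterTable.from_bytes(data, source="hdxsim/data/rate_params.tsv")
        if PACKAGED_TABLE_SHA256 is not None and table.checksum != PACKAGED_TABLE_SHA256:
            raise RuntimeError(
                "packaged rate_params.tsv checksum mismatch: expected "
                f"{PACKAGED_TABLE_SHA256}, got {table.checksum}; the data file "
                "has been modified"
            )
        _DEFAULT_TABLE = table
    return _DEFAULT_TABLE
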