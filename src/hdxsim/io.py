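"""Standard-format I/O: FASTA sequences, tabular outputs, workflow configs.

All CSV output uses a fixed dialect (comma separator, ``.`` decimal, header
row, UTF-8) at 12 significant digits so result bundles round-trip losslessly.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .conditions import AcidityScale, Direction, ExchangeConditions
from .intrinsic import IntrinsicRateProfile, validate_sequence
from .kinetics import ProtectionProfile, Workflow, WorkflowStage
from .peptides import PeptideRegion
from .rate_table import STANDARD_AA

__all__ = [
    "read_fasta",
    "sequence_from_arg",
    "write_fasta",
    "read_protection_table",
    "read_peptide_table",
    "load_workflow_config",
    "workflow_to_config",
    "rates_frame",
    "write_csv",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.12g"


def read_fasta(source: str | Path) -> list[tuple[str, str]]:
    """Parse a (possibly multi-record, line-wrapped) FASTA file.

    Residue letters are case-insensitive; anything outside the 20 standard
    codes is rejected with the record id, sequence position, and file line.
    """
    path = Path(source)
    text = path.read_text()
    if not text.lstrip().startswith(">"):
        first_bad = text.splitlines()[0] if text.splitlines() else ""
        raise ValueError(
            f"{path}: not a FASTA file (line 1 does not start with '>'): "
            f"{first_bad[:40]!r}"
        )
    records = []
    for record in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {record.id!r} has an empty sequence")
        for i, aa in enumerate(seq, start=1):
            if aa not in STANDARD_AA:
                line = _locate_fasta_line(text, record.id, i)
                raise ValueError(
                    f"{path}:{line}: record {record.id!r} has invalid residue "
                    f"{aa!r} at sequence position {i}"
                )
        records.append((record.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _locate_fasta_line(text: str, record_id: str, seq_pos: int) -> int:
    """Map a 1-based residue position in a record to its file line number."""
    in_record = False
    count = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            in_record = line[1:].split()[0] == record_id if line[1:].split() else False
            continue
        if in_record:
            count += len(line.strip())
            if count >= seq_pos:
                return lineno
    return 0


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def sequence_from_arg(arg: str) -> str:
    """Resolve a CLI sequence argument: a FASTA path or an inline sequence."""
    path = Path(arg)
    if path.exists():
        records = read_fasta(path)
        return records[0][1]
    return validate_sequence(arg)


def read_protection_table(path: str | Path, length: int | None = None) -> ProtectionProfile:
    """Read per-residue log10 protection factors (CSV/TSV: position, log_p)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    df = df.sort_values(df.columns[0])
    log_p = df[df.columns[1]].to_numpy(dtype=float)
    if length is not None and len(log_p) != length:
        raise ValueError(
            f"protection table has {len(log_p)} rows, expected {length}"
        )
    return ProtectionProfile(log_p)


def read_peptide_table(path: str | Path, parent_sequence: str) -> list[PeptideRegion]:
    """Read peptide boundaries (parent_id, start, end; 1-based inclusive)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    return [
        PeptideRegion.from_parent(
            parent_sequence, int(row["start"]), int(row["end"]),
            str(row.get("parent_id", "protein")),
        )
        for _, row in df.iterrows()
    ]


# ------------------------------------------------------------------ workflows

def _stage_from_dict(d: dict) -> WorkflowStage:
    scale = AcidityScale(d["scale"])
    direction = d.get("direction")
    if direction is None:
        direction = (
            Direction.D_TO_H if scale is AcidityScale.PH_IN_H2O else Direction.H_TO_D
        )
    conditions = ExchangeConditions(
        acidity_value=float(d["acidity"]),
        acidity_scale=scale,
        temperature=float(d["temp_K"]),
        direction=Direction(direction),
    )
    return WorkflowStage(
        label=str(d["label"]),
        duration_s=float(d["duration_s"]),
        conditions=conditions,
        protected=bool(d["protected"]),
        target_occupancy=float(d["target_occupancy"]),
    )


def load_workflow_config(path: str | Path) -> Workflow:
    """Load a workflow from a YAML or JSON config file.

    Schema::

        esi_retention: 0.95
        stages:
          - {label: labeling, duration_s: 600, acidity: 7.4, scale: pD,
             temp_K: 295.15, protected: true, target_occupancy: 1.0}
          - {label: digestion, duration_s: 40, acidity: 2.5, scale: pH_in_H2O,
             temp_K: 288.15, protected: false, target_occupancy: 0.0}
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    try:
        stages = tuple(_stage_from_dict(s) for s in data["stages"])
        return Workflow(stages=stages, esi_retention=float(data.get("esi_retention", 1.0)))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid workflow config {path}: {exc}") from exc


def workflow_to_config(workflow: Workflow) -> dict:
    return {
        "esi_retention": workflow.esi_retention,
        "stages": [
            {
                "label": s.label,
                "duration_s": s.duration_s,
                "acidity": s.conditions.acidity_value,
                "scale": s.conditions.acidity_scale.value,
                "temp_K": s.conditions.temperature,
                "direction": s.conditions.direction.value,
                "protected": s.protected,
                "target_occupancy": s.target_occupancy,
            }
            for s in workflow.stages
        ],
    }


# ------------------------------------------------------------------- outputs

def rates_frame(profile: IntrinsicRateProfile) -> pd.DataFrame:
    """Tabulate an intrinsic-rate profile (position, residue, k_ch, flag)."""
    return pd.DataFrame(
        {
            "position": range(1, len(profile.sequence) + 1),
            "residue": list(profile.sequence),
            "k_ch_per_s": profile.rates,
            "exchanging": profile.exchanging,
        }
    )


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
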