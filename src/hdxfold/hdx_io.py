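"""Peptide-level HDX-MS state-data parsing and bookkeeping conventions.

The on-disk dialect is a delimited text table (comma or tab, sniffed from the
header line) with one row per centroid measurement:

======================  =====================================================
column                  meaning
======================  =====================================================
protein                 protein identifier matching the FASTA record
start, end              1-based inclusive residue numbers, protein coordinates
sequence                peptide amino-acid sequence
state                   biochemical state label (e.g. ``Cl``, ``HEPES``)
condition               labeling-condition label (ties to ExchangeConditions)
row_type                ``uptake`` | ``nd`` | ``inx`` | ``fd`` (labeled point,
                        non-deuterated, in-exchange, maximally labeled)
time_s                  labeling time in s on the native condition axis
                        (0 for control rows)
replicate               replicate identifier
uptake_da               centroid deuterium uptake above non-deuterated, Da
======================  =====================================================

Coordinates are 1-based inclusive throughout.  Uptake is stored in Da; %D is
a derived view (uptake / exchangeable residue count).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "PeptideRecord",
    "ControlSet",
    "StateData",
    "StateTableError",
    "exchangeable_count",
    "exchangeable_positions",
    "region_label",
    "read_fasta",
    "read_state_table",
    "write_state_table",
    "REQUIRED_COLUMNS",
    "CONTROL_ROW_TYPES",
]

REQUIRED_COLUMNS = [
    "protein",
    "start",
    "end",
    "sequence",
    "state",
    "condition",
    "row_type",
    "time_s",
    "replicate",
    "uptake_da",
]

CONTROL_ROW_TYPES = ("nd", "inx", "fd")

#: Column aliases accepted for common vendor exports.
DEFAULT_ALIASES = {
    "protein": "protein",
    "start": "start",
    "end": "end",
    "sequence": "sequence",
    "state": "state",
    "condition": "condition",
    "row_type": "row_type",
    "exposure": "time_s",
    "time_s": "time_s",
    "replicate": "replicate",
    "file": "replicate",
    "uptake": "uptake_da",
    "uptake_da": "uptake_da",
    "center": "uptake_da",
}


class StateTableError(ValueError):
    """Validation failure in a state-data table; message lists offending rows."""


@dataclass(frozen=True)
class PeptideRecord:
    """A proteolytic peptide located in protein coordinates (1-based inclusive)."""

    protein_id: str
    start: int
    end: int
    sequence: str
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"{self.protein_id} {self.start}-{self.end}: span length "
                f"{self.end - self.start + 1} != sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def name(self) -> str:
        return f"Peptide_{self.start}-{self.end}"


@dataclass(frozen=True)
class ControlSet:
    """Per-peptide control centroids, in Da above the non-deuterated centroid."""

    nondeuterated: float
    in_exchange: float
    full_d: float

    def __post_init__(self) -> None:
        if not self.nondeuterated <= self.in_exchange <= self.full_d:
            raise ValueError(
                "controls must satisfy nondeuterated <= in-exchange <= full-D "
                f"(got {self.nondeuterated}, {self.in_exchange}, {self.full_d})"
            )


@dataclass
class StateData:
    """A validated state-data table plus per-peptide controls."""

    measurements: pd.DataFrame
    controls: dict[tuple[int, int], ControlSet]
    peptides: list[PeptideRecord]


def exchangeable_count(p: PeptideRecord) -> int:
    """Number of residues whose deuterium content the centroid reports.

    The first two residues are excluded (their amide protons exchange so fast
    that the label is lost to back-exchange during quench/digestion) as are
    prolines at peptide positions >= 3, which carry no amide proton.
    """
    if p.length < 3:
        raise ValueError(f"{p.name}: no reportable amides (length < 3)")
    return p.length - 2 - p.sequence[2:].upper().count("P")


def exchangeable_positions(p: PeptideRecord) -> list[int]:
    """Protein-coordinate indices of the exchange-competent residues."""
    if p.length < 3:
        raise ValueError(f"{p.name}: no reportable amides (length < 3)")
    return [
        p.start + i
        for i in range(2, p.length)
        if p.sequence[i].upper() != "P"
    ]


def region_label(p: PeptideRecord) -> str:
    """Region name for a peptide: the span from its third residue to its end."""
    if p.length < 3:
        raise ValueError(f"{p.name}: region undefined (length < 3)")
    return f"Region_{p.start + 2}-{p.end}"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_state_table(
    path: str | Path,
    fasta: str | Path | dict[str, str],
    column_map: dict[str, str] | None = None,
) -> StateData:
    """Parse and validate a state-data table against the protein FASTA.

    Rows failing coordinate/sequence checks are collected and reported with
    their (0-based) row indices in a single :class:`StateTableError`.
    Missing controls produce a warning-level note via the returned object's
    ``controls`` dict simply lacking that peptide.
    """
    sequences = fasta if isinstance(fasta, dict) else read_fasta(fasta)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    aliases = dict(DEFAULT_ALIASES)
    if column_map:
        aliases.update({k.lower(): v for k, v in column_map.items()})
    df.columns = [aliases.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StateTableError(f"missing required columns: {missing}")
    df = df[REQUIRED_COLUMNS].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["sequence"] = df["sequence"].str.upper()

    errors: list[str] = []
    for idx, row in df.iterrows():
        span_len = row["end"] - row["start"] + 1
        if span_len != len(row["sequence"]):
            errors.append(
                f"row {idx}: span {row['start']}-{row['end']} length {span_len} "
                f"!= sequence length {len(row['sequence'])}"
            )
            continue
        prot = sequences.get(row["protein"])
        if prot is None:
            errors.append(f"row {idx}: protein {row['protein']!r} not in FASTA")
            continue
        if row["end"] > len(prot):
            errors.append(f"row {idx}: end {row['end']} beyond protein length {len(prot)}")
            continue
        ref = prot[row["start"] - 1 : row["end"]]
        if ref != row["sequence"]:
            errors.append(
                f"row {idx}: sequence {row['sequence']} != FASTA slice {ref} "
                f"at {row['start']}-{row['end']}"
            )
        if row["row_type"] == "uptake" and row["time_s"] <= 0:
            errors.append(f"row {idx}: labeled point with non-positive time {row['time_s']}")
        if row["uptake_da"] < 0:
            errors.append(f"row {idx}: negative uptake {row['uptake_da']}")
    if errors:
        raise StateTableError("state-table validation failed:\n" + "\n".join(errors))

    peptides_df = df[["protein", "start", "end", "sequence"]].drop_duplicates()
    peptides = [
        PeptideRecord(r.protein, int(r.start), int(r.end), r.sequence)
        for r in peptides_df.itertuples()
    ]

    controls: dict[tuple[int, int], ControlSet] = {}
    ctrl = df[df["row_type"].isin(CONTROL_ROW_TYPES)]
    for (start, end), grp in ctrl.groupby(["start", "end"]):
        vals = grp.groupby("row_type")["uptake_da"].mean()
        if all(t in vals.index for t in CONTROL_ROW_TYPES):
            controls[(int(start), int(end))] = ControlSet(
                nondeuterated=float(vals["nd"]),
                in_exchange=float(vals["inx"]),
                full_d=float(vals["fd"]),
            )

    measurements = df[df["row_type"] == "uptake"].reset_index(drop=True)
    return StateData(measurements=measurements, controls=controls, peptides=peptides)


def write_state_table(data: StateData | pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a state-data table in the dialect :func:`read_state_table` reads.

    Accepts either a full :class:`StateData` (controls re-emitted as control
    rows) or a bare measurements DataFrame.
    """
    if isinstance(data, StateData):
        frames = [data.measurements]
        pep_by_span = {(p.start, p.end): p for p in data.peptides}
        rows = []
        for (start, end), cs in data.controls.items():
            p = pep_by_span.get((start, end))
            if p is None:
                continue
            for row_type, val in (
                ("nd", cs.nondeuterated),
                ("inx", cs.in_exchange),
                ("fd", cs.full_d),
            ):
                rows.append(
                    {
                        "protein": p.protein_id,
                        "start": start,
                        "end": end,
                        "sequence": p.sequence,
                        "state": "control",
                        "condition": "control",
                        "row_type": row_type,
                        "time_s": 0.0,
                        "replicate": "ctrl",
                        "uptake_da": val,
                    }
                )
        if rows:
            frames.append(pd.DataFrame(rows))
        df = pd.concat(frames, ignore_index=True)
    else:
        df = data
    df.to_csv(path, sep=sep, index=False)


def state_table_to_string(df: pd.DataFrame, sep: str = ",") -> str:
    buf = io.StringIO()
    df.to_csv(buf, sep=sep, index=False)
    return buf.getvalue()
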