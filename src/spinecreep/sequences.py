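"""Cycle sequences — the unit of training data — and their CSV round trip.

A :class:`CycleSequence` holds the ordered ten-parameter loop descriptions of
every retained cycle of one 30-minute loading block, plus metadata (specimen,
loading direction FE/LB/AR, temperature group BT/RT, block index 1–6, whether
it is a sagittal-symmetry flipped copy) and the environmental input feature
τ_t (group Kendall τ × total testing time in hours).

The on-disk format is a flat CSV with one row per cycle.  Because published
per-cycle parameter tables come with arbitrary headers, the reader accepts a
user-supplied column map from our canonical names to file columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .hysteresis import HysteresisParams

__all__ = ["CycleSequence", "DatasetSplit", "read_sequences", "write_sequences"]

#: Canonical CSV columns: sequence keys, metadata, then the ten parameters.
KEY_COLUMNS = ("sequence_id", "cycle_index")
META_COLUMNS = ("specimen_id", "direction", "temperature", "sequence_index", "flipped", "tau_t")
PARAM_COLUMNS = HysteresisParams.FIELDS

DIRECTIONS = ("FE", "LB", "AR")
TEMPERATURES = ("BT", "RT")


@dataclass
class CycleSequence:
    """Ordered per-cycle hysteresis parameters of one loading block."""

    sequence_id: str
    specimen_id: str
    direction: str
    temperature: str
    sequence_index: int
    tau_t: float
    cycles: list[HysteresisParams]
    cycle_indices: list[int]
    flipped: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.temperature not in TEMPERATURES:
            raise ValueError(f"temperature must be one of {TEMPERATURES}")
        if len(self.cycles) != len(self.cycle_indices):
            raise ValueError("cycles and cycle_indices must align")
        if len(self.cycles) < 2:
            raise ValueError("a sequence needs at least 2 cycles")
        idx = np.asarray(self.cycle_indices)
        if np.any(np.diff(idx) <= 0):
            raise ValueError("cycle indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.cycles)

    def params_matrix(self) -> np.ndarray:
        """(n_cycles, 10) array of the hysteresis parameters."""
        return np.vstack([p.to_vector() for p in self.cycles])

    def rom_trace(self, moment: float = 7.5, branch: str = "upper") -> np.ndarray:
        """Per-cycle absolute RoM evaluated at ``moment`` (degrees)."""
        return np.array([p.rom_at(moment, branch) for p in self.cycles])

    def with_tau_t(self, tau_t: float) -> "CycleSequence":
        return replace(self, tau_t=float(tau_t))


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/test/validation partition of sequence ids."""

    train: tuple[str, ...]
    test: tuple[str, ...]
    validation: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = [set(self.train), set(self.test), set(self.validation)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split groups must be disjoint")

    @property
    def all_ids(self) -> set[str]:
        return set(self.train) | set(self.test) | set(self.validation)


def write_sequences(sequences: list[CycleSequence], path) -> None:
    """Write sequences to CSV, one row per cycle, canonical headers."""
    rows = []
    for seq in sequences:
        for params, k in zip(seq.cycles, seq.cycle_indices):
            row = {
                "sequence_id": seq.sequence_id,
                "cycle_index": k,
                "specimen_id": seq.specimen_id,
                "direction": seq.direction,
                "temperature": seq.temperature,
                "sequence_index": seq.sequence_index,
                "flipped": seq.flipped,
                "tau_t": seq.tau_t,
            }
            row.update({f: v for f, v in zip(PARAM_COLUMNS, params.to_vector())})
            row.update(seq.extra)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sequences(path, column_map: dict[str, str] | None = None) -> list[CycleSequence]:
    """Read a per-cycle parameter CSV into :class:`CycleSequence` objects.

    ``column_map`` maps canonical names (``A``, ``B``, ``a1_u`` … plus
    ``sequence_id``/``cycle_index`` and optional metadata) to the file's
    actual headers; identity by default.  Unknown file columns are preserved
    in ``extra`` (constant per sequence) or dropped otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items() if v in df.columns}
    df = df.rename(columns=rename)

    required = list(KEY_COLUMNS) + list(PARAM_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sequence CSV is missing required column(s): {missing}")
    for col in PARAM_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in column {col!r} at row {int(np.flatnonzero(bad)[0])}"
            )
        df[col] = values

    known = set(required) | set(META_COLUMNS)
    extra_cols = [c for c in df.columns if c not in known]

    sequences = []
    for seq_id, grp in df.groupby("sequence_id", sort=False):
        grp = grp.sort_values("cycle_index")
        cycles = [HysteresisParams.from_vector(row) for row in grp[list(PARAM_COLUMNS)].to_numpy()]
        meta = grp.iloc[0]
        sequences.append(
            CycleSequence(
                sequence_id=str(seq_id),
                specimen_id=str(meta.get("specimen_id", "")),
                direction=str(meta.get("direction", "FE")),
                temperature=str(meta.get("temperature", "BT")),
                sequence_index=int(meta.get("sequence_index", 1)),
                tau_t=float(meta.get("tau_t", 0.0)),
                cycles=cycles,
                cycle_indices=[int(k) for k in grp["cycle_index"]],
                flipped=bool(meta.get("flipped", False)),
                extra={c: meta[c] for c in extra_cols},
            )
        )
    return sequences
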