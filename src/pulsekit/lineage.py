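"""Lineage data model and serialization for tracked microcolonies.

A tracked movie is represented as a :class:`Colony`: a forest of
:class:`CellRecord` objects, one per tracked cell segment ("schnitz",
birth to division or movie end), each carrying per-frame length and
mean-fluorescence-intensity series.  The module also provides the two
lineage operations the downstream rate and pulse stages need:

* :func:`backward_lineages` — trace every cell alive in the last frame
  back to its founder, yielding one founder-to-focal chain per final cell;
* :func:`extend_series` — stitch a cell's length or intensity series
  across division events so that sliding-window regressions can span a
  cell's birth and division.

Lengths are extended by summing the two daughters (after division) and by
taking the fraction L0/(L0 + L0_sister) of the mother (before birth), where
L0 and L0_sister are the birth lengths of the cell and its sister.  Mean
intensities are extended with the average of the daughters after division
and the mother's value before birth (intensity is a per-unit-length
concentration and is continuous across division).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellRecord",
    "Colony",
    "ExtendedLineage",
    "SchemaError",
    "backward_lineages",
    "cells_per_frame",
    "extend_series",
    "read_colonies",
    "read_colony",
    "write_colonies",
    "write_colony",
]

Quantity = Literal["length", "log_length", "intensity"]


class SchemaError(ValueError):
    """A lineage table violates the documented schema."""


@dataclass
class CellRecord:
    """One tracked cell from birth to division (or movie end)."""

    cell_id: int
    parent_id: int | None
    daughter_ids: tuple[int, ...]
    frames: np.ndarray
    time_min: np.ndarray
    length: np.ndarray
    mean_intensity: np.ndarray
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        self.daughter_ids = tuple(self.daughter_ids)
        if self.frames.size == 0:
            raise SchemaError(f"cell {self.cell_id}: no frames")
        if np.any(np.diff(self.frames) != 1):
            raise SchemaError(f"cell {self.cell_id}: frames not contiguous")
        n = self.frames.size
        for name in ("time_min", "length", "mean_intensity"):
            if getattr(self, name).size != n:
                raise SchemaError(f"cell {self.cell_id}: {name} length mismatch")
        if len(self.daughter_ids) not in (0, 2):
            raise SchemaError(f"cell {self.cell_id}: non-binary division "
                              f"({len(self.daughter_ids)} daughters)")

    @property
    def first_frame(self) -> int:
        return int(self.frames[0])

    @property
    def last_frame(self) -> int:
        return int(self.frames[-1])

    def value_at(self, frame: int, quantity: str) -> float:
        arr = self.length if quantity in ("length", "log_length") else self.mean_intensity
        i = frame - self.first_frame
        if i < 0 or i >= self.frames.size:
            raise IndexError(f"cell {self.cell_id} not observed at frame {frame}")
        return float(arr[i])


@dataclass
class Colony:
    """A lineage forest of tracked cells imaged at a fixed frame interval."""

    colony_id: str
    dt: float
    n_frames: int
    cells: dict[int, CellRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for cell in self.cells.values():
            if cell.parent_id is not None and cell.parent_id not in self.cells:
                raise SchemaError(
                    f"cell {cell.cell_id}: unknown parent_id {cell.parent_id}")
            for d in cell.daughter_ids:
                if d not in self.cells:
                    raise SchemaError(f"cell {cell.cell_id}: unknown daughter {d}")
            if cell.daughter_ids:
                first = min(self.cells[d].first_frame for d in cell.daughter_ids)
                if cell.last_frame >= first:
                    raise SchemaError(
                        f"cell {cell.cell_id}: last frame {cell.last_frame} not "
                        f"strictly before daughters' first frame {first}")
        # forest: in-degree <= 1 is structural (single parent_id); check acyclicity
        for cell in self.cells.values():
            seen = set()
            cur: int | None = cell.cell_id
            while cur is not None:
                if cur in seen:
                    raise SchemaError(f"lineage cycle through cell {cur}")
                seen.add(cur)
                cur = self.cells[cur].parent_id

    @property
    def founders(self) -> list[CellRecord]:
        return [c for c in self.cells.values() if c.parent_id is None]

    def sister_of(self, cell_id: int) -> CellRecord | None:
        cell = self.cells[cell_id]
        if cell.parent_id is None:
            return None
        sibs = [d for d in self.cells[cell.parent_id].daughter_ids if d != cell_id]
        return self.cells[sibs[0]] if sibs else None


@dataclass
class ExtendedLineage:
    """Founder-to-focal chain for one cell alive in the last frame.

    ``cell_at_frame[i]`` names the chain cell observed at global frame
    ``frames[i]``; consecutive chain members are parent and daughter.
    """

    colony_id: str
    chain: tuple[int, ...]
    frames: np.ndarray
    cell_at_frame: np.ndarray

    @property
    def focal_cell(self) -> int:
        return int(self.chain[-1])


def backward_lineages(colony: Colony) -> list[ExtendedLineage]:
    """Trace all cells alive in the last frame backward to their founders.

    Returns exactly one lineage per final-frame cell; lineages through a
    common ancestor share that prefix.
    """
    last = colony.n_frames - 1
    out = []
    for cell in sorted(colony.cells.values(), key=lambda c: c.cell_id):
        if cell.last_frame != last:
            continue
        chain = [cell.cell_id]
        while colony.cells[chain[-1]].parent_id is not None:
            chain.append(colony.cells[chain[-1]].parent_id)
        chain.reverse()
        frames = []
        owner = []
        for cid in chain:
            rec = colony.cells[cid]
            frames.extend(rec.frames.tolist())
            owner.extend([cid] * rec.frames.size)
        out.append(ExtendedLineage(colony.colony_id, tuple(chain),
                                   np.asarray(frames), np.asarray(owner)))
    return out


def cells_per_frame(colony: Colony) -> np.ndarray:
    """Number of cells present at each frame (the n_i of the pulse-frequency
    denominator)."""
    n = np.zeros(colony.n_frames, dtype=int)
    for cell in colony.cells.values():
        n[cell.first_frame:cell.last_frame + 1] += 1
    return n


def _birth_fraction(colony: Colony, cell_id: int) -> float:
    """L0 / (L0 + L0_sister): the cell's share of its mother's length."""
    cell = colony.cells[cell_id]
    sister = colony.sister_of(cell_id)
    l0 = cell.length[0]
    l0s = sister.length[0] if sister is not None else l0
    return float(l0 / (l0 + l0s))


def _value_before_birth(colony: Colony, cell_id: int, frame: int,
                        quantity: str) -> float | None:
    """Extended value at a frame before the cell's birth, via its ancestry."""
    frac = 1.0
    cur = colony.cells[cell_id]
    while cur.first_frame > frame:
        if cur.parent_id is None:
            return None
        if quantity == "length":
            frac *= _birth_fraction(colony, cur.cell_id)
        cur = colony.cells[cur.parent_id]
    val = cur.value_at(frame, quantity)
    return frac * val if quantity == "length" else val


def _value_after_division(colony: Colony, cell_id: int, frame: int,
                          quantity: str) -> float | None:
    """Extended value at a frame after the cell's division, via descendants."""
    cell = colony.cells[cell_id]
    if not cell.daughter_ids:
        return None
    vals = []
    for d in cell.daughter_ids:
        drec = colony.cells[d]
        if frame <= drec.last_frame:
            if frame < drec.first_frame:  # division gap (should not occur)
                return None
            vals.append(drec.value_at(frame, quantity))
        else:
            v = _value_after_division(colony, d, frame, quantity)
            if v is None:
                return None
            vals.append(v)
    return float(sum(vals)) if quantity == "length" else float(np.mean(vals))


def extend_series(colony: Colony, cell_id: int, quantity: Quantity,
                  n_extend: int = 11) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame series for one cell, extended across birth and division.

    Returns ``(frames, values)`` spanning up to ``n_extend`` frames beyond
    the cell's first and last observed frames.  The series simply ends where
    no relative exists to extend it (movie boundary, founder birth, or an
    undivided leaf).
    """
    base = "length" if quantity in ("length", "log_length") else "intensity"
    cell = colony.cells[cell_id]
    frames = list(range(max(0, cell.first_frame - n_extend),
                        min(colony.n_frames - 1, cell.last_frame + n_extend) + 1))
    out_frames, out_vals = [], []
    for f in frames:
        if f < cell.first_frame:
            v = _value_before_birth(colony, cell_id, f, base)
        elif f > cell.last_frame:
            v = _value_after_division(colony, cell_id, f, base)
        else:
            v = cell.value_at(f, base)
        if v is not None:
            out_frames.append(f)
            out_vals.append(v)
    vals = np.asarray(out_vals, dtype=float)
    if quantity == "log_length":
        if np.any(vals <= 0):
            raise ValueError(f"cell {cell_id}: nonpositive length in series")
        vals = np.log(vals)
    return np.asarray(out_frames), vals


# ---------------------------------------------------------------------------
# serialization

_CSV_COLUMNS = ["colony_id", "cell_id", "parent_id", "frame", "time_min",
                "length", "mean_intensity", "x", "y"]


def _colony_to_frame(colony: Colony) -> pd.DataFrame:
    rows = []
    for cell in sorted(colony.cells.values(), key=lambda c: c.cell_id):
        for i, f in enumerate(cell.frames):
            rows.append({
                "colony_id": colony.colony_id,
                "cell_id": cell.cell_id,
                "parent_id": cell.parent_id if cell.parent_id is not None else "",
                "frame": int(f),
                "time_min": cell.time_min[i],
                "length": cell.length[i],
                "mean_intensity": cell.mean_intensity[i],
                "x": cell.x[i] if cell.x is not None else "",
                "y": cell.y[i] if cell.y is not None else "",
            })
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def _colony_from_frame(df: pd.DataFrame, colony_id: str, dt: float | None,
                       n_frames: int | None) -> Colony:
    missing = [c for c in _CSV_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    cells: dict[int, CellRecord] = {}
    parent_of: dict[int, int | None] = {}
    for cid, grp in df.groupby("cell_id"):
        grp = grp.sort_values("frame")
        pid_raw = grp["parent_id"].iloc[0]
        pid = None if (pd.isna(pid_raw) or pid_raw == "") else int(pid_raw)
        parent_of[int(cid)] = pid
        has_xy = "x" in grp.columns and not grp["x"].replace("", np.nan).isna().all()
        cells[int(cid)] = dict(
            cell_id=int(cid), parent_id=pid,
            frames=grp["frame"].to_numpy(int),
            time_min=grp["time_min"].to_numpy(float),
            length=grp["length"].to_numpy(float),
            mean_intensity=grp["mean_intensity"].to_numpy(float),
            x=grp["x"].to_numpy(float) if has_xy else None,
            y=grp["y"].to_numpy(float) if has_xy else None,
        )
    for cid, pid in parent_of.items():
        if pid is not None and pid not in cells:
            raise SchemaError(f"cell {cid}: unknown parent_id {pid}")
    daughters: dict[int, list[int]] = {cid: [] for cid in cells}
    for cid, pid in parent_of.items():
        if pid is not None:
            daughters[pid].append(cid)
    for pid, ds in daughters.items():
        if len(ds) not in (0, 2):
            raise SchemaError(f"cell {pid}: non-binary division ({len(ds)} daughters)")
    records = {cid: CellRecord(daughter_ids=tuple(sorted(daughters[cid])), **kw)
               for cid, kw in cells.items()}
    if n_frames is None:
        n_frames = max(r.last_frame for r in records.values()) + 1
    if dt is None:
        times = np.concatenate([r.time_min for r in records.values()])
        frames = np.concatenate([r.frames for r in records.values()])
        dt = float(np.median(np.diff(np.unique(times)))) if len(np.unique(frames)) > 1 else 1.0
    return Colony(colony_id=str(colony_id), dt=float(dt), n_frames=int(n_frames),
                  cells=records)


def write_colonies(colonies: Iterable[Colony], path: str | Path,
                   format: str = "csv") -> None:
    path = Path(path)
    colonies = list(colonies)
    if format == "csv":
        df = pd.concat([_colony_to_frame(c) for c in colonies], ignore_index=True)
        df.to_csv(path, index=False, float_format="%.12g")
    elif format == "json":
        doc = {}
        for c in colonies:
            doc[c.colony_id] = {
                "dt": c.dt, "n_frames": c.n_frames,
                "cells": {
                    str(cell.cell_id): {
                        "parent_id": cell.parent_id,
                        "frames": cell.frames.tolist(),
                        "time_min": cell.time_min.tolist(),
                        "length": cell.length.tolist(),
                        "mean_intensity": cell.mean_intensity.tolist(),
                        **({"x": cell.x.tolist(), "y": cell.y.tolist()}
                           if cell.x is not None else {}),
                    } for cell in sorted(c.cells.values(), key=lambda r: r.cell_id)
                },
            }
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")


def write_colony(colony: Colony, path: str | Path, format: str = "csv") -> None:
    write_colonies([colony], path, format=format)


def read_colonies(path: str | Path, format: str = "csv",
                  dt: float | None = None,
                  n_frames: int | None = None) -> list[Colony]:
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path, keep_default_na=True)
        return [_colony_from_frame(grp, str(cid), dt, n_frames)
                for cid, grp in df.groupby("colony_id", sort=True)]
    elif format == "json":
        doc = json.loads(path.read_text())
        out = []
        for cid, cdoc in doc.items():
            records = {}
            daughters: dict[int, list[int]] = {}
            for k, cd in cdoc["cells"].items():
                pid = cd["parent_id"]
                if pid is not None:
                    daughters.setdefault(int(pid), []).append(int(k))
            for k, cd in cdoc["cells"].items():
                ds = daughters.get(int(k), [])
                if len(ds) not in (0, 2):
                    raise SchemaError(f"cell {k}: non-binary division")
                if cd["parent_id"] is not None and str(cd["parent_id"]) not in cdoc["cells"]:
                    raise SchemaError(f"cell {k}: unknown parent_id {cd['parent_id']}")
                records[int(k)] = CellRecord(
                    cell_id=int(k), parent_id=cd["parent_id"],
                    daughter_ids=tuple(sorted(ds)),
                    frames=cd["frames"], time_min=cd["time_min"],
                    length=cd["length"], mean_intensity=cd["mean_intensity"],
                    x=np.asarray(cd["x"]) if "x" in cd else None,
                    y=np.asarray(cd["y"]) if "y" in cd else None)
            out.append(Colony(colony_id=str(cid), dt=float(cdoc["dt"]),
                              n_frames=int(cdoc["n_frames"]), cells=records))
        return out
    raise ValueError(f"unknown format {format!r}")


def read_colony(path: str | Path, format: str = "csv", **kw) -> Colony:
    colonies = read_colonies(path, format=format, **kw)
    if len(colonies) != 1:
        raise SchemaError(f"expected one colony in {path}, found {len(colonies)}")
    return colonies[0]
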