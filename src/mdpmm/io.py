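"""Trajectory readers/writers.

Two dialects are supported for both the perturbing-environment trajectory
and the chromophore trajectory:

* **extended XYZ with charges** — repeated blocks of::

      <n_atoms>
      frame=<i> units=<nm|angstrom> [key=value ...]
      <element> <x> <y> <z> <charge>
      ...

  Coordinates default to nm (the MD convention this pipeline uses
  internally); a ``units=angstrom`` comment key switches the block.

* **GRO stream plus charge table** — a multi-frame GRO file (read through
  MDAnalysis, natively nm) and a separate one-column text file with one
  charge per atom, matched by atom order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from . import units
from .electronic import SchemaError
from .pmm import PerturbingFrame

__all__ = [
    "read_xyz_frames",
    "write_xyz_frames",
    "read_gro_frames",
    "read_charge_table",
    "iter_perturbing_frames",
]

_XYZ_LENGTH = {"nm": 1.0, "angstrom": units.ANGSTROM_NM}


def read_xyz_frames(path: str | Path
                    ) -> Iterator[tuple[list[str], np.ndarray, np.ndarray]]:
    """Yield ``(elements, positions_nm, charges)`` per extended-XYZ block."""
    with open(path) as fh:
        frame = 0
        while True:
            header = fh.readline()
            if not header.strip():
                if not header:
                    return
                continue
            try:
                n = int(header)
            except ValueError:
                raise SchemaError(
                    f"{path}: expected atom count, got {header.strip()!r}")
            comment = fh.readline()
            keys = dict(tok.split("=", 1) for tok in comment.split()
                        if "=" in tok)
            unit = keys.get("units", "nm").lower()
            if unit not in _XYZ_LENGTH:
                raise SchemaError(f"{path}: unknown units '{unit}'")
            factor = _XYZ_LENGTH[unit]
            elements, pos, chg = [], np.empty((n, 3)), np.empty(n)
            for i in range(n):
                parts = fh.readline().split()
                if len(parts) != 5:
                    raise SchemaError(
                        f"{path} frame {frame} atom {i}: expected "
                        f"'element x y z charge', got {len(parts)} fields")
                elements.append(parts[0])
                pos[i] = [float(v) for v in parts[1:4]]
                chg[i] = float(parts[4])
            yield elements, pos * factor, chg
            frame += 1


def write_xyz_frames(path: str | Path,
                     elements: Sequence[str],
                     frames: np.ndarray,
                     charges: np.ndarray,
                     extra_comment: str = "") -> None:
    """Write frames (F, N, 3) nm with per-atom charges as extended XYZ."""
    frames = np.atleast_3d(np.asarray(frames, float))
    charges = np.asarray(charges, float)
    with open(path, "w") as fh:
        for f, x in enumerate(frames):
            fh.write(f"{len(elements)}\n")
            fh.write(f"frame={f} units=nm {extra_comment}".rstrip() + "\n")
            for el, r, q in zip(elements, x, charges):
                fh.write(f"{el} {r[0]:.9f} {r[1]:.9f} {r[2]:.9f} {q:.6f}\n")


def read_charge_table(path: str | Path) -> np.ndarray:
    """One charge per line (e); comments with ``#``."""
    vals = [float(line.split()[0])
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.lstrip().startswith("#")]
    if not vals:
        raise SchemaError(f"empty charge table: {path}")
    return np.array(vals)


def read_gro_frames(path: str | Path, charges: np.ndarray
                    ) -> Iterator[tuple[list[str], np.ndarray, np.ndarray]]:
    """Yield ``(names, positions_nm, charges)`` per frame of a GRO stream."""
    import MDAnalysis as mda

    u = mda.Universe(str(path), str(path))
    charges = np.asarray(charges, float)
    if len(charges) != len(u.atoms):
        raise SchemaError(
            f"charge table has {len(charges)} entries for "
            f"{len(u.atoms)} atoms")
    names = list(u.atoms.names)
    for _ in u.trajectory:
        # MDAnalysis positions are Angstrom regardless of source format
        yield names, u.atoms.positions * units.ANGSTROM_NM, charges


def iter_perturbing_frames(env_path: str | Path,
                           qc_path: str | Path,
                           fmt: str = "xyz",
                           env_charges_path: str | Path | None = None,
                           qc_charges_path: str | Path | None = None,
                           ) -> Iterator[PerturbingFrame]:
    """Pair an environment trajectory with a QC trajectory frame-by-frame.

    ``fmt`` selects the dialect (``"xyz"`` or ``"gro"``; GRO requires the
    charge-table paths).  If the QC trajectory has a single frame (frozen
    chromophore), it is reused for every environment frame.
    """
    if fmt == "xyz":
        env_iter = read_xyz_frames(env_path)
        qc_iter = read_xyz_frames(qc_path)
    elif fmt == "gro":
        if env_charges_path is None or qc_charges_path is None:
            raise SchemaError("GRO input requires charge tables")
        env_iter = read_gro_frames(env_path, read_charge_table(env_charges_path))
        qc_iter = read_gro_frames(qc_path, read_charge_table(qc_charges_path))
    else:
        raise SchemaError(f"unknown trajectory format '{fmt}'")

    qc_frames = list(qc_iter)
    frozen = len(qc_frames) == 1
    for i, (_, env_pos, env_q) in enumerate(env_iter):
        if frozen:
            qc_pos = qc_frames[0][1]
        else:
            if i >= len(qc_frames):
                raise SchemaError(
                    f"QC trajectory ended at frame {len(qc_frames)} but "
                    f"environment continues")
            qc_pos = qc_frames[i][1]
        yield PerturbingFrame(env_positions=env_pos, env_charges=env_q,
                              qc_positions=qc_pos, frame_index=i)
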