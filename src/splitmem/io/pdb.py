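"""Minimal PDB subset: ATOM/HETATM and CRYST1 records; coordinates are
converted between A (file) and nm (toolkit)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from splitmem.core import AtomTable, SystemFrame
from splitmem.io._util import ParseError, open_text

__all__ = ["read_pdb", "write_pdb"]


def read_pdb(path) -> SystemFrame:
    path = Path(path)
    names, resnames, resids = [], [], []
    positions = []
    box = None
    with open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6].strip()
            if rec == "CRYST1":
                try:
                    a, b, c = float(raw[6:15]), float(raw[15:24]), float(raw[24:33])
                    alpha = float(raw[33:40])
                    beta = float(raw[40:47])
                    gamma = float(raw[47:54])
                except ValueError:
                    raise ParseError(path, lineno, "bad CRYST1 record") from None
                if not (abs(alpha - 90) < 1e-6 and abs(beta - 90) < 1e-6
                        and abs(gamma - 90) < 1e-6):
                    raise ParseError(path, lineno,
                                     "triclinic cell not supported (angles != 90)")
                box = np.array([a, b, c]) / 10.0
            elif rec in ("ATOM", "HETATM"):
                try:
                    names.append(raw[12:16].strip())
                    resnames.append(raw[17:21].strip())
                    resids.append(int(raw[22:26]))
                    positions.append(
                        [float(raw[30:38]), float(raw[38:46]), float(raw[46:54])]
                    )
                except ValueError as exc:
                    raise ParseError(path, lineno, f"bad ATOM record: {exc}") from None
    if not names:
        raise ParseError(path, 1, "no ATOM/HETATM records found")
    if box is None:
        box = np.array([1.0, 1.0, 1.0]) * max(
            1.0, float(np.ptp(np.asarray(positions), axis=0).max() / 10.0 + 1.0)
        )
    table = AtomTable(names=names, resnames=resnames, resids=resids)
    return SystemFrame(table, np.asarray(positions) / 10.0, box)


def write_pdb(frame: SystemFrame, path) -> None:
    t = frame.table
    lines = [
        f"CRYST1{frame.box[0] * 10:9.3f}{frame.box[1] * 10:9.3f}"
        f"{frame.box[2] * 10:9.3f}  90.00  90.00  90.00 P 1           1"
    ]
    for i in range(frame.n_atoms):
        x, y, z = frame.positions[i] * 10.0
        name = str(t.names[i])[:4]
        lines.append(
            f"ATOM  {(i + 1) % 100000:5d} {name:<4s} {str(t.resnames[i])[:4]:<4s}"
            f"{int(t.resids[i]) % 10000:5d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"  1.00  0.00"
        )
    lines.append("END")
    with open_text(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")
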