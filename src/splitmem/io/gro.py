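"""Fixed-column GRO reader/writer.

Atom lines follow the standard layout ``resid %5d, resname %-5s, atomname
%5s, atomnr %5d, x/y/z %8.3f`` with optional ``%8.4f`` velocities.  Multiple
concatenated frames yield a :class:`~splitmem.core.Trajectory`; frame times
are taken from a ``t=`` field in the title line when present (interpreted in
ns, the toolkit's time unit) and otherwise default to the frame index.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from splitmem.core import AtomTable, SystemFrame, Trajectory
from splitmem.io._util import ParseError, open_text

__all__ = ["read_gro", "write_gro"]

_TIME_RE = re.compile(r"\bt\s*=\s*([-+0-9.eE]+)")


def _parse_frame(lines, start: int, path):
    """Parse one frame at ``lines[start]``; returns (frame, title, time, next)."""
    title = lines[start].rstrip("\n")
    try:
        n_atoms = int(lines[start + 1].strip())
    except (IndexError, ValueError):
        raise ParseError(path, start + 2, "expected atom count") from None
    first_atom = start + 2
    box_lineno = first_atom + n_atoms
    if box_lineno >= len(lines):
        raise ParseError(
            path,
            len(lines),
            f"truncated frame: declared {n_atoms} atoms but file ends early",
        )

    names, resnames, resids = [], [], []
    positions = np.empty((n_atoms, 3))
    velocities = np.zeros((n_atoms, 3))
    has_vel = False
    for i in range(n_atoms):
        line = lines[first_atom + i].rstrip("\n")
        lineno = first_atom + i + 1
        if len(line) < 44:
            raise ParseError(path, lineno, f"atom line too short ({len(line)} chars)")
        try:
            resids.append(int(line[0:5]))
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            int(line[15:20])  # atom serial; regenerated on write
            positions[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        except ValueError as exc:
            raise ParseError(path, lineno, f"column misalignment: {exc}") from None
        if len(line) >= 68:
            try:
                velocities[i] = [
                    float(line[44:52]),
                    float(line[52:60]),
                    float(line[60:68]),
                ]
                has_vel = True
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad velocity field: {exc}") from None

    box_fields = lines[box_lineno].split()
    try:
        box_vals = [float(x) for x in box_fields]
    except ValueError:
        raise ParseError(path, box_lineno + 1, "bad box line") from None
    if len(box_vals) < 3:
        raise ParseError(path, box_lineno + 1, "box line needs >= 3 components")
    if len(box_vals) > 3 and any(abs(v) > 1e-9 for v in box_vals[3:]):
        raise ParseError(
            path, box_lineno + 1, "triclinic box not supported (off-diagonal != 0)"
        )

    m = _TIME_RE.search(title)
    time = float(m.group(1)) if m else None

    table = AtomTable(names=names, resnames=resnames, resids=resids)
    frame = SystemFrame(
        table,
        positions,
        box_vals[:3],
        time=0.0 if time is None else time,
        velocities=velocities if has_vel else None,
    )
    return frame, title, time, box_lineno + 1


def read_gro(path) -> SystemFrame | Trajectory:
    """Read a GRO file; concatenated frames produce a :class:`Trajectory`."""
    path = Path(path)
    with open_text(path) as fh:
        lines = fh.readlines()
    # drop trailing blank lines
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise ParseError(path, 1, "empty file")

    frames: list[SystemFrame] = []
    titles: list[str] = []
    pos = 0
    idx = 0
    while pos < len(lines):
        frame, title, time, pos = _parse_frame(lines, pos, path)
        if time is None:
            frame.time = float(idx)
        frame.title = title  # preserved for round-tripping
        frames.append(frame)
        titles.append(title)
        idx += 1

    if len(frames) == 1:
        return frames[0]
    return Trajectory(frames)


def _format_frame(frame: SystemFrame, title: str | None) -> str:
    if title is None:
        title = getattr(frame, "title", None)
    if title is None:
        title = "written by splitmem"
        if frame.time:
            title += f" t= {frame.time:.5f}"
    out = [title, f"{frame.n_atoms:5d}"]
    t = frame.table
    pos = frame.positions
    if np.any(np.abs(pos) >= 10000) or np.any(frame.box >= 100000):
        raise ValueError("coordinate overflows %8.3f field width")
    vel = frame.velocities
    for i in range(frame.n_atoms):
        name = str(t.names[i])
        resname = str(t.resnames[i])
        if len(name) > 5 or len(resname) > 5:
            raise ValueError(f"atom/residue name longer than 5 chars: {name} {resname}")
        line = (
            f"{int(t.resids[i]) % 100000:5d}{resname:<5s}{name:>5s}"
            f"{(i + 1) % 100000:5d}"
            f"{pos[i, 0]:8.3f}{pos[i, 1]:8.3f}{pos[i, 2]:8.3f}"
        )
        if vel is not None:
            line += f"{vel[i, 0]:8.4f}{vel[i, 1]:8.4f}{vel[i, 2]:8.4f}"
        out.append(line)
    out.append(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}")
    return "\n".join(out) + "\n"


def write_gro(frame_or_traj, path, title: str | None = None) -> None:
    """Write a frame or trajectory as (multi-frame) GRO."""
    path = Path(path)
    if isinstance(frame_or_traj, Trajectory):
        chunks = []
        for f in frame_or_traj:
            ftitle = title or getattr(f, "title", None)
            if ftitle is None:
                ftitle = f"written by splitmem t= {f.time:.5f}"
            elif "t=" not in ftitle:
                ftitle = f"{ftitle} t= {f.time:.5f}"
            chunks.append(_format_frame(f, ftitle))
        text = "".join(chunks)
    else:
        text = _format_frame(frame_or_traj, title)
    with open_text(path, "wt") as fh:
        fh.write(text)
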