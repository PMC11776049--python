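"""GROMACS NDX index-group writer/reader (15 indices per line)."""

from __future__ import annotations

import warnings
from pathlib import Path

from splitmem.io._util import open_text

__all__ = ["read_ndx", "write_ndx"]


def write_ndx(groups: dict[str, list[int]], path) -> None:
    """Write named 1-based index groups in standard NDX format.

    Empty groups are written (header only) with a warning.
    """
    out: list[str] = []
    for name, indices in groups.items():
        if not indices:
            warnings.warn(f"NDX group {name!r} is empty", stacklevel=2)
        out.append(f"[ {name} ]")
        idx = sorted(int(i) for i in indices)
        for start in range(0, len(idx), 15):
            out.append(" ".join(str(i) for i in idx[start : start + 15]))
    with open_text(path, "wt") as fh:
        fh.write("\n".join(out) + ("\n" if out else ""))


def read_ndx(path) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    current: str | None = None
    with open_text(Path(path)) as fh:
        for raw in fh:
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1].strip()
                groups[current] = []
            elif current is not None:
                groups[current].extend(int(x) for x in line.split())
    return groups
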