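"""Shared helpers for the format readers/writers."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO


class ParseError(ValueError):
    """Format violation, annotated with file and line number."""

    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def open_text(path, mode: str = "rt") -> IO[str]:
    """Open a text file, transparently handling a ``.gz`` suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)
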