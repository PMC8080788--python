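"""Shared low-level I/O helpers: transparent gzip text opening and checksums."""

from __future__ import annotations

import gzip
import hashlib
import io
import os
from pathlib import Path
from typing import IO, Union

PathLike = Union[str, os.PathLike]


def open_text(source: Union[PathLike, IO[str]], mode: str = "rt") -> IO[str]:
    """Open ``source`` as a text stream; ``.gz`` paths are decompressed on the fly.

    Already-open text handles are passed through unchanged (caller keeps
    ownership and is responsible for closing them).
    """
    if hasattr(source, "read") or hasattr(source, "write"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, mode.replace("t", "") + "b"))  # type: ignore[arg-type]
    return open(path, mode)


def sha256_of_file(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_of_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()
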