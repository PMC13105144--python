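"""Low-level sequence file I/O.

FASTQ records travel through the demultiplexer by the million, so the
reader/writer here is a minimal 4-line-record implementation rather than a
generic parser. Compression is selected from the filename extension:
``.gz`` (gzip), ``.zst`` (Zstandard, optional dependency), anything else is
plain text.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from typing import IO, Iterator


def open_text(path: str | os.PathLike, mode: str = "rt") -> IO[str]:
    """Open a possibly-compressed text file based on its extension."""
    path = os.fspath(path)
    if "b" in mode:
        raise ValueError("open_text only supports text modes")
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    if path.endswith(".zst"):
        try:
            import zstandard
        except ImportError as exc:  # pragma: no cover - optional dep
            raise ImportError(
                "reading/writing .zst files requires the 'zstandard' package "
                "(pip install naptrap[zstd])"
            ) from exc
        if "r" in mode:
            fh = zstandard.ZstdDecompressor().stream_reader(open(path, "rb"))
            return io.TextIOWrapper(fh)
        fh = zstandard.ZstdCompressor().stream_writer(open(path, "wb"))
        return io.TextIOWrapper(fh)
    return open(path, mode)


@dataclass
class FastqRecord:
    name: str  # without the leading '@', including any '#UMI' suffix
    seq: str
    qual: str

    def format(self) -> str:
        return f"@{self.name}\n{self.seq}\n+\n{self.qual}\n"


def read_fastq(path: str | os.PathLike) -> Iterator[FastqRecord]:
    """Iterate 4-line FASTQ records. Raises on truncated files."""
    with open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(f"truncated FASTQ record in {path!r}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record in {path!r}: {header!r}")
            yield FastqRecord(header[1:].rstrip("\n"), seq.rstrip("\n"), qual.rstrip("\n"))


def write_fastq(path: str | os.PathLike, records) -> int:
    """Write records to *path*; returns the number written."""
    n = 0
    with open_text(path, "wt") as fh:
        for rec in records:
            fh.write(rec.format())
            n += 1
    return n
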