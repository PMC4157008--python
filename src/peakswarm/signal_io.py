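"""Reading, writing and splitting sampled signals and their peak annotations.

File formats are plain delimited text. A signal file holds one amplitude per
row; it may start with a ``# fs: <Hz>`` comment and/or a single header row of
column names. An annotation file holds one 0-based sample index per row.
Internally all indexing is 0-based half-open; only human-readable CLI echoes
use 1-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Signal",
    "AnnotationSet",
    "SignalParseError",
    "read_signal",
    "write_signal",
    "read_annotations",
    "write_annotations",
    "split_recording",
]


class SignalParseError(ValueError):
    """A signal or annotation file could not be parsed."""


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples
        Amplitude values (assumed µV; nothing numeric depends on the unit).
    fs
        Sampling frequency in Hz, strictly positive.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("signal must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        if not (float(self.fs) > 0):
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / fs)."""
        return len(self) / self.fs


@dataclass(frozen=True)
class AnnotationSet:
    """Ground-truth peak locations as strictly increasing 0-based indices."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64).reshape(-1)
        if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0):
            raise ValueError("annotation indices must be non-negative and strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)

    def __iter__(self) -> Iterator[int]:
        return iter(self.indices.tolist())

    def validate_against(self, signal_length: int) -> None:
        """Raise if any index falls outside ``[0, signal_length)``."""
        if self.indices.size and (self.indices[-1] >= signal_length):
            bad = int(self.indices[self.indices >= signal_length][0])
            raise ValueError(
                f"annotation index {bad} out of range for signal of length {signal_length}"
            )


def _tokenize(line: str) -> list[str]:
    return line.replace(",", " ").split()


def _is_float(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def read_signal(
    path: str | Path,
    fs: float | None = None,
    column: str | int | None = None,
) -> Signal:
    """Read a delimited-text signal file.

    ``fs`` overrides any ``# fs: <Hz>`` header comment; one of the two must be
    present. ``column`` selects a column by header name or 0-based position
    when the file has more than one column.
    """
    path = Path(path)
    header_fs: float | None = None
    names: list[str] | None = None
    rows: list[list[str]] = []
    row_lines: list[int] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                for sep in (":", "="):
                    if body.lower().startswith("fs") and sep in body:
                        try:
                            header_fs = float(body.split(sep, 1)[1])
                        except ValueError:
                            raise SignalParseError(
                                f"{path}: line {lineno}: malformed fs header {line!r}"
                            ) from None
                        break
                continue
            toks = _tokenize(line)
            if not rows and names is None and not all(_is_float(t) for t in toks):
                names = toks
                continue
            rows.append(toks)
            row_lines.append(lineno)
    if not rows:
        raise SignalParseError(f"{path}: no samples found")

    if isinstance(column, str):
        if names is None or column not in names:
            raise SignalParseError(f"{path}: no column named {column!r}")
        col = names.index(column)
    elif isinstance(column, int):
        col = column
    else:
        widths = {len(r) for r in rows}
        if widths != {1}:
            raise SignalParseError(
                f"{path}: multiple columns present; specify which one to read"
            )
        col = 0

    values = np.empty(len(rows), dtype=float)
    for i, (toks, lineno) in enumerate(zip(rows, row_lines)):
        if col >= len(toks) or not _is_float(toks[col]):
            raise SignalParseError(
                f"{path}: line {lineno}: non-numeric or missing value in column {col}"
            )
        values[i] = float(toks[col])

    effective_fs = fs if fs is not None else header_fs
    if effective_fs is None:
        raise SignalParseError(
            f"{path}: sampling frequency not given (no '# fs:' header and no fs argument)"
        )
    return Signal(values, effective_fs)


def write_signal(path: str | Path, signal: Signal) -> None:
    """Write one sample per line, preceded by a ``# fs:`` header comment."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs: {signal.fs:g}\n")
        for v in signal.samples:
            fh.write(f"{float(v)!r}\n")


def read_annotations(path: str | Path, signal_length: int) -> AnnotationSet:
    """Read one integer index per line; sort, deduplicate and bound-check."""
    path = Path(path)
    indices: list[int] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                indices.append(int(line.split()[0]))
            except ValueError:
                raise SignalParseError(
                    f"{path}: line {lineno}: expected an integer index, got {line!r}"
                ) from None
    unique = np.unique(np.asarray(indices, dtype=np.int64))
    ann = AnnotationSet(unique)
    ann.validate_against(signal_length)
    if unique.size and unique[0] < 0:
        raise ValueError(f"annotation index {int(unique[0])} is negative")
    return ann


def write_annotations(path: str | Path, annotations: AnnotationSet) -> None:
    Path(path).write_text("".join(f"{int(i)}\n" for i in annotations.indices))


def split_recording(
    signal: Signal,
    annotations: AnnotationSet,
    boundary: int,
) -> tuple[tuple[Signal, AnnotationSet], tuple[Signal, AnnotationSet]]:
    """Split at ``boundary`` into train = [0, boundary) and test = [boundary, L).

    Test annotations are re-based to the test partition's origin. Both
    partitions must be non-empty.
    """
    L = len(signal)
    if not (0 < boundary < L):
        raise ValueError(f"split boundary must lie strictly inside (0, {L}), got {boundary}")
    annotations.validate_against(L)
    idx = annotations.indices
    train = Signal(signal.samples[:boundary], signal.fs)
    test = Signal(signal.samples[boundary:], signal.fs)
    train_ann = AnnotationSet(idx[idx < boundary])
    test_ann = AnnotationSet(idx[idx >= boundary] - boundary)
    return (train, train_ann), (test, test_ann)
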