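"""Core data types and session/report I/O.

A :class:`FeatureSession` is a labeled matrix of per-window feature vectors
(PSD band powers in arbitrary units) recorded at a fixed cadence.  Feature
indices are 1-based on every user-facing surface, following the channel-major
layout of the 8-channel / 12-band montage; internal storage is 0-based numpy.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CHANNELS",
    "BANDS_HZ",
    "ChannelBandIndex",
    "FeatureSession",
    "SelectionResult",
    "SessionFormatError",
    "feature_index",
    "feature_to_channel_band",
    "load_feature_session",
    "write_feature_session",
    "write_selection_report",
    "load_selection_report",
]

#: Channel order of the precomputed competition sets (channel-major layout).
CHANNELS: tuple[str, ...] = ("C3", "Cz", "C4", "CP1", "CP2", "P3", "Pz", "P4")

#: Band centers in Hz, 8-30 Hz at 2 Hz resolution.
BANDS_HZ: tuple[int, ...] = tuple(range(8, 31, 2))


class SessionFormatError(ValueError):
    """Raised when a session file violates the declared dialect or invariants."""


class ChannelBandIndex:
    """Bijection between (channel, band) pairs and 1-based feature indices.

    Layout is channel-major: index(c, b) = (row(c) - 1) * n_bands + col(b).
    """

    def __init__(
        self,
        channels: Sequence[str] = CHANNELS,
        bands_hz: Sequence[int] = BANDS_HZ,
    ) -> None:
        self.channels = tuple(channels)
        self.bands_hz = tuple(bands_hz)
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names")
        if len(set(self.bands_hz)) != len(self.bands_hz):
            raise ValueError("duplicate band frequencies")

    @property
    def n_features(self) -> int:
        return len(self.channels) * len(self.bands_hz)

    def index(self, channel: str, freq_hz: float) -> int:
        """1-based feature index of (channel, band)."""
        try:
            row = self.channels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None
        try:
            col = self.bands_hz.index(freq_hz)
        except ValueError:
            raise KeyError(f"unknown band {freq_hz!r} Hz") from None
        return row * len(self.bands_hz) + col + 1

    def channel_band(self, index: int) -> tuple[str, int]:
        """Inverse of :meth:`index` — (channel, band_hz) of a 1-based index."""
        if not 1 <= index <= self.n_features:
            raise KeyError(f"feature index {index} out of range 1..{self.n_features}")
        row, col = divmod(index - 1, len(self.bands_hz))
        return self.channels[row], self.bands_hz[col]


_DEFAULT_INDEX = ChannelBandIndex()


def feature_index(channel: str, freq_hz: float) -> int:
    """1-based index of (channel, freq_hz) in the default 8x12 layout."""
    return _DEFAULT_INDEX.index(channel, freq_hz)


def feature_to_channel_band(index: int) -> tuple[str, int]:
    """(channel, band_hz) of a 1-based feature index in the default layout."""
    return _DEFAULT_INDEX.channel_band(index)


@dataclasses.dataclass
class FeatureSession:
    """Labeled matrix of per-window feature vectors.

    Parameters
    ----------
    features : ndarray, shape (n_windows, n_features)
        Nonnegative finite reals (PSD power, arbitrary units).
    labels : ndarray, shape (n_windows,)
        Integer task code per window (e.g. {2, 3, 7} for the competition
        scheme: 2=LEFT, 3=RIGHT, 7=WORD).
    vectors_per_second : int
        Feature-vector cadence (16 for the competition data).
    session_id : str
    """

    features: np.ndarray
    labels: np.ndarray
    vectors_per_second: int = 16
    session_id: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise SessionFormatError("features must be a 2-D matrix")
        if self.labels.ndim != 1 or len(self.labels) != self.features.shape[0]:
            raise SessionFormatError(
                f"label count {self.labels.size} != row count {self.features.shape[0]}"
            )
        if not np.all(np.isfinite(self.features)):
            raise SessionFormatError("non-finite feature value")
        if np.any(self.features < 0):
            raise SessionFormatError("negative feature value")
        if self.vectors_per_second <= 0:
            raise SessionFormatError("vectors_per_second must be positive")

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def label_set(self) -> tuple[int, ...]:
        return tuple(sorted(np.unique(self.labels).tolist()))

    def restrict(self, feature_indices: Sequence[int]) -> "FeatureSession":
        """Sub-session keeping only the given 1-based feature indices (in order)."""
        idx = np.asarray(list(feature_indices), dtype=int)
        if idx.size == 0:
            raise ValueError("empty feature subset")
        if np.any(idx < 1) or np.any(idx > self.n_features):
            raise IndexError("feature index out of range")
        return FeatureSession(
            features=self.features[:, idx - 1],
            labels=self.labels,
            vectors_per_second=self.vectors_per_second,
            session_id=self.session_id,
        )


@dataclasses.dataclass
class SelectionResult:
    """Outcome of one selection run.

    ``method`` is "<criterion>_<wrapper>" with criterion in {statistic, fuzzy}
    and wrapper in {order, gmdh}.  ``candidates`` are score-ordered 1-based
    feature indices; ``selected`` is the chosen subset; ``trace`` holds the
    per-step evaluation values in percent.
    """

    method: str
    candidates: list[int]
    scores: list[int]
    selected: list[int]
    trace: list[float]
    K: int
    rho: float

    def __post_init__(self) -> None:
        if not set(self.selected) <= set(self.candidates):
            raise ValueError("selected features must be a subset of candidates")
        if any(not (0.0 <= v <= 100.0) for v in self.trace):
            raise ValueError("trace values must lie in [0, 100]")


# ---------------------------------------------------------------------------
# Session file I/O
#
# competition_ascii: one window per line, n_features whitespace-separated
# floats followed by one integer label.  csv: header "f1,...,fN,label".
# ---------------------------------------------------------------------------

def load_feature_session(
    path: str | Path,
    dialect: str = "competition_ascii",
    vectors_per_second: int = 16,
    session_id: str | None = None,
) -> FeatureSession:
    """Read a labeled session file.

    Raises
    ------
    SessionFormatError
        On a malformed row (wrong arity, unparseable field, negative feature),
        naming the offending line number.
    """
    path = Path(path)
    if dialect not in ("competition_ascii", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[list[float]] = []
    labels: list[int] = []
    arity: int | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if dialect == "csv":
        if not lines:
            raise SessionFormatError(f"{path}: empty file")
        start = 1  # header
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split(",") if dialect == "csv" else line.split()
        if arity is None:
            if len(fields) < 2:
                raise SessionFormatError(f"{path}:{lineno}: need >=1 feature + label")
            arity = len(fields)
        if len(fields) != arity:
            raise SessionFormatError(
                f"{path}:{lineno}: expected {arity} fields, got {len(fields)}"
            )
        try:
            values = [float(v) for v in fields[:-1]]
            label = int(float(fields[-1]))
        except ValueError as exc:
            raise SessionFormatError(f"{path}:{lineno}: {exc}") from None
        if any(v < 0 for v in values):
            raise SessionFormatError(f"{path}:{lineno}: negative feature value")
        if any(not np.isfinite(v) for v in values):
            raise SessionFormatError(f"{path}:{lineno}: non-finite feature value")
        rows.append(values)
        labels.append(label)
    if not rows:
        raise SessionFormatError(f"{path}: no data rows")
    return FeatureSession(
        features=np.array(rows, dtype=float),
        labels=np.array(labels, dtype=int),
        vectors_per_second=vectors_per_second,
        session_id=session_id if session_id is not None else path.stem,
    )


def write_feature_session(
    session: FeatureSession, path: str | Path, dialect: str = "competition_ascii"
) -> None:
    """Write a session in one of the two text dialects (full precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "csv":
            header = ",".join(f"f{j + 1}" for j in range(session.n_features))
            fh.write(header + ",label\n")
            sep = ","
        elif dialect == "competition_ascii":
            sep = " "
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        for row, label in zip(session.features, session.labels):
            fh.write(sep.join(repr(float(v)) for v in row))
            fh.write(f"{sep}{int(label)}\n")


# ---------------------------------------------------------------------------
# Selection report I/O (JSON)
# ---------------------------------------------------------------------------

def write_selection_report(
    result: SelectionResult, path: str | Path, extra: dict | None = None
) -> None:
    """Persist a SelectionResult as JSON, with channel/band names resolved."""
    doc = {
        "method": result.method,
        "rho": result.rho,
        "K": result.K,
        "candidates": list(result.candidates),
        "scores": list(result.scores),
        "selected": list(result.selected),
        "selected_channels": [
            "{}-{}Hz".format(*feature_to_channel_band(i)) for i in result.selected
        ],
        "trace": list(result.trace),
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_selection_report(path: str | Path) -> SelectionResult:
    with open(path) as fh:
        doc = json.load(fh)
    return SelectionResult(
        method=doc["method"],
        candidates=list(doc["candidates"]),
        scores=list(doc["scores"]),
        selected=list(doc["selected"]),
        trace=list(doc["trace"]),
        K=doc["K"],
        rho=doc["rho"],
    )
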