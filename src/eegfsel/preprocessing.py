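"""Raw-EEG preprocessing chain: surface Laplacian + sliding-window PSD.

Reproduces the competition precomputation: a Hjorth-style nearest-neighbour
surface Laplacian followed by Welch/periodogram band powers on 1 s windows
hopped every 32 samples (93.75% overlap at 512 Hz, 16 vectors per second).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .session import FeatureSession

__all__ = [
    "RawRecording",
    "DEFAULT_NEIGHBORS",
    "band_grid",
    "surface_laplacian",
    "psd_features",
]

#: Nearest-neighbour map for the 8-channel 10-20 subset used by the
#: competition precomputation.  Neighbours are the adjacent electrodes of the
#: montage grid restricted to the retained channels.
DEFAULT_NEIGHBORS: dict[str, tuple[str, ...]] = {
    "C3": ("Cz", "CP1", "P3"),
    "Cz": ("C3", "C4", "CP1", "CP2"),
    "C4": ("Cz", "CP2", "P4"),
    "CP1": ("C3", "Cz", "CP2", "P3", "Pz"),
    "CP2": ("Cz", "C4", "CP1", "Pz", "P4"),
    "P3": ("C3", "CP1", "Pz"),
    "Pz": ("CP1", "CP2", "P3", "P4"),
    "P4": ("C4", "CP2", "Pz"),
}


@dataclasses.dataclass
class RawRecording:
    """Multichannel raw EEG: samples [n_samples x n_channels] in microvolts."""

    samples: np.ndarray
    fs_hz: float
    channel_names: tuple[str, ...]
    neighbor_map: Mapping[str, Sequence[str]] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.samples.ndim != 2:
            raise ValueError("samples must be [n_samples x n_channels]")
        if self.samples.shape[1] != len(self.channel_names):
            raise ValueError("channel count mismatch")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.neighbor_map is not None:
            known = set(self.channel_names)
            for ch, neigh in self.neighbor_map.items():
                unknown = set(neigh) - known
                if unknown:
                    raise ValueError(f"neighbor map for {ch} references unknown {unknown}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


def load_neighbor_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a JSON montage neighbour map {channel: [neighbours...]}."""
    with open(path) as fh:
        doc = json.load(fh)
    return {ch: tuple(neigh) for ch, neigh in doc.items()}


def band_grid(band_lo: float, band_hi: float, res_hz: float) -> np.ndarray:
    """Inclusive arithmetic grid of band centers; (8, 30, 2) -> 12 bands."""
    if band_lo >= band_hi:
        raise ValueError("band_lo must be below band_hi")
    span = band_hi - band_lo
    n_steps = span / res_hz
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"resolution {res_hz} does not divide span {span}")
    return band_lo + res_hz * np.arange(int(round(n_steps)) + 1)


def surface_laplacian(rec: RawRecording) -> RawRecording:
    """Hjorth small Laplacian: out[c] = in[c] - mean(in[neighbors(c)])."""
    neighbor_map = rec.neighbor_map if rec.neighbor_map is not None else DEFAULT_NEIGHBORS
    pos = {name: i for i, name in enumerate(rec.channel_names)}
    out = np.empty_like(rec.samples)
    for c, name in enumerate(rec.channel_names):
        neigh = [n for n in neighbor_map.get(name, ()) if n in pos]
        if not neigh:
            raise ValueError(f"channel {name} has no neighbors in the recording")
        cols = [pos[n] for n in neigh]
        out[:, c] = rec.samples[:, c] - rec.samples[:, cols].mean(axis=1)
    return RawRecording(
        samples=out,
        fs_hz=rec.fs_hz,
        channel_names=rec.channel_names,
        neighbor_map=rec.neighbor_map,
    )


def psd_features(
    rec: RawRecording,
    win_s: float = 1.0,
    hop_samples: int = 32,
    band_lo: float = 8.0,
    band_hi: float = 30.0,
    res_hz: float = 2.0,
    labels: np.ndarray | None = None,
    session_id: str = "",
) -> FeatureSession:
    """Sliding-window band powers ordered channel-major per the feature layout.

    Each window is a single Hann-tapered periodogram of ``win_s`` seconds;
    the band power at center ``b`` is the mean of the PSD bins whose center
    lies in the half-open interval [b - res/2, b + res/2).  Window count is
    floor((n_samples - fs*win_s)/hop) + 1 and the cadence is fs/hop vectors
    per second (16 for fs=512, hop=32).
    """
    nwin = int(round(rec.fs_hz * win_s))
    if rec.n_samples < nwin:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{nwin}-sample window"
        )
    centers = band_grid(band_lo, band_hi, res_hz)
    n_windows = (rec.n_samples - nwin) // hop_samples + 1
    starts = np.arange(n_windows) * hop_samples

    # [n_windows, n_channels, nwin] view of all analysis windows
    windows = np.lib.stride_tricks.sliding_window_view(rec.samples, nwin, axis=0)
    windows = windows[starts]

    freqs, psd = signal.periodogram(
        windows, fs=rec.fs_hz, window="hann", detrend="constant", axis=-1
    )
    half = res_hz / 2.0
    feats = np.empty((n_windows, rec.n_channels, len(centers)))
    for k, b in enumerate(centers):
        mask = (freqs >= b - half) & (freqs < b + half)
        if not mask.any():
            raise ValueError(f"no PSD bins in band {b} Hz (resolution too coarse)")
        feats[:, :, k] = psd[:, :, mask].mean(axis=-1)
    features = feats.reshape(n_windows, rec.n_channels * len(centers))

    cadence = rec.fs_hz / hop_samples
    if labels is None:
        labels = np.zeros(n_windows, dtype=int)
    else:
        labels = np.asarray(labels, dtype=int)[:n_windows]
    return FeatureSession(
        features=features,
        labels=labels,
        vectors_per_second=int(round(cadence)),
        session_id=session_id,
    )
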