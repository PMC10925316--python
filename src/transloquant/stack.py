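"""The in-memory container for multi-channel time-lapse stacks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masking import Optics

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A time x channel x row x column grid of non-negative intensities.

    ``data`` has dimension order (T, C, Y, X). ``optics`` carries the
    acquisition metadata the masking stage needs (pixel size, emission
    wavelength of the marker, numerical aperture); ``frame_interval_s`` and
    ``stim_frame`` locate frames in time and mark the stimulation event.
    """

    data: np.ndarray
    optics: Optics
    frame_interval_s: float
    stim_frame: int | None = None
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"stack must be 4-D (T,C,Y,X), got shape {self.data.shape}")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.stim_frame is not None and not (0 <= self.stim_frame < self.n_frames):
            raise ValueError("stim_frame out of range")
        if self.channel_names and len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match channel axis")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def times_s(self) -> np.ndarray:
        """Frame times in seconds from the first frame."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def channel_index(self, name_or_index) -> int:
        if isinstance(name_or_index, (int, np.integer)):
            idx = int(name_or_index)
            if not (0 <= idx < self.n_channels):
                raise KeyError(f"channel index {idx} out of range (stack has {self.n_channels})")
            return idx
        if name_or_index in self.channel_names:
            return self.channel_names.index(name_or_index)
        raise KeyError(f"no channel named {name_or_index!r}; have {self.channel_names}")

    def frame(self, t: int, channel) -> np.ndarray:
        return self.data[t, self.channel_index(channel)]
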