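"""Core in-memory containers shared by every stage of the pipeline.

Three containers carry all signals through the analysis:

``TimeSeries``
    A uniformly sampled 1-D signal (LFP, MUA, EMG, ripple power, ROI
    traces) with its sampling rate and start time.
``ImageStack``
    A T x H x W sequence of mesoscale imaging frames with its frame rate
    (raw fluorescence, dF/F0, or z-scored activity).
``RegionAtlas``
    A labeled H x W mask mapping pixels to named neocortical regions,
    plus the partition of regions into four structural subnetworks
    (medial, visual, auditory, somatomotor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeries",
    "ImageStack",
    "RegionAtlas",
    "CORTICAL_REGIONS",
    "SUBNETWORKS",
    "grid_atlas",
]

#: Named regions of the dorsal-cortex imaging window, medial to lateral.
CORTICAL_REGIONS = [
    "RSC", "AC/M2", "M1", "PtA", "V2M", "V1", "V2L", "A1",
    "BCS1", "FLS1", "HLS1", "ULpS1", "S2", "TrS1", "ShNcS1",
]

#: Structural subnetwork membership of each named region.
SUBNETWORKS = {
    "RSC": "medial", "AC/M2": "medial", "V2M": "medial", "PtA": "medial",
    "V1": "visual", "V2L": "visual",
    "A1": "auditory",
    "M1": "somatomotor", "BCS1": "somatomotor", "FLS1": "somatomotor",
    "HLS1": "somatomotor", "ULpS1": "somatomotor", "S2": "somatomotor",
    "TrS1": "somatomotor", "ShNcS1": "somatomotor",
}


@dataclass
class TimeSeries:
    """Uniformly sampled 1-D signal.

    Parameters
    ----------
    samples : ndarray
        Signal values, one per sample.
    rate : float
        Sampling rate in Hz. Must be positive.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("TimeSeries samples must be 1-D")
        if self.samples.size < 1:
            raise ValueError("TimeSeries must contain at least one sample")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("TimeSeries samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds."""
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (seconds)."""
        i = int(round((t - self.t0) * self.rate))
        if i < 0 or i >= self.samples.size:
            raise IndexError(f"time {t} s outside recording")
        return i


@dataclass
class ImageStack:
    """T x H x W frame sequence with frame-rate metadata."""

    frames: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("ImageStack frames must be T x H x W")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def duration(self) -> float:
        return self.frames.shape[0] / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.frames.shape[0]) / self.rate

    def frame_at(self, t: float) -> int:
        """Index of the frame nearest to time ``t`` (seconds)."""
        i = int(round((t - self.t0) * self.rate))
        if i < 0 or i >= self.frames.shape[0]:
            raise IndexError(f"time {t} s outside stack")
        return i


@dataclass
class RegionAtlas:
    """Labeled mask mapping pixels to named cortical regions.

    ``labels`` is an H x W integer image; 0 marks unassigned pixels and
    each positive label corresponds to one entry of ``names``.
    """

    labels: np.ndarray
    names: dict[int, str]
    subnetworks: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("atlas labels must be a 2-D mask")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        if not self.subnetworks:
            self.subnetworks = {
                n: SUBNETWORKS.get(n, "other") for n in self.names.values()
            }

    @property
    def region_names(self) -> list[str]:
        return [self.names[k] for k in sorted(self.names)]

    def _label_of(self, region: str) -> int:
        for lbl, name in self.names.items():
            if name == region:
                return lbl
        raise KeyError(f"region {region!r} not in atlas")

    def mask(self, region: str) -> np.ndarray:
        """Boolean H x W mask of a named region."""
        m = self.labels == self._label_of(region)
        if not m.any():
            raise KeyError(f"region {region!r} has no pixels in the mask")
        return m

    def centroid(self, region: str) -> tuple[int, int]:
        """Pixel (row, col) of the region's center of mass."""
        rows, cols = np.nonzero(self.mask(region))
        return int(round(rows.mean())), int(round(cols.mean()))


def grid_atlas(shape: tuple[int, int] = (48, 48),
               regions: list[str] | None = None) -> RegionAtlas:
    """Tile an imaging window into rectangular named regions.

    A stand-in for a registered cortical parcellation: the window is
    divided into a near-square grid with one cell per region, left to
    right then top to bottom.  Useful for synthetic stacks where only
    the pixel-to-region mapping matters, not its anatomy.
    """
    if regions is None:
        regions = list(CORTICAL_REGIONS)
    h, w = shape
    n = len(regions)
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    labels = np.zeros(shape, dtype=int)
    row_edges = np.linspace(0, h, nrows + 1).astype(int)
    col_edges = np.linspace(0, w, ncols + 1).astype(int)
    names: dict[int, str] = {}
    for i, name in enumerate(regions):
        r, c = divmod(i, ncols)
        labels[row_edges[r]:row_edges[r + 1],
               col_edges[c]:col_edges[c + 1]] = i + 1
        names[i + 1] = name
    return RegionAtlas(labels=labels, names=names)
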