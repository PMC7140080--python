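"""Confocal z-stack pre-processing.

Separates the coverslip-adherent ("glass") signal from the free-floating
scaffold signal in two-channel (DiO membrane dye / DAPI nuclear stain)
z-stacks.  The rule is intensity-profile based: each slice is summed per
channel, outlying sums are flagged with Tukey's inner fences, and any slice
that lies above the highest slice attaining the absolute-maximum voxel
intensity *and* has an outlying sum is removed.  The lowest removed index is
recorded as the dividing line between the 2D-on-glass and 3D-in-scaffold
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "SliceProfile",
    "sum_slice_intensities",
    "tukey_inner_fences",
    "max_intensity_slice",
    "crop_stack",
    "read_stack",
    "write_stack",
]

DEFAULT_CHANNELS = ("DiO", "DAPI")


@dataclass
class ImageStack:
    """Two-channel 3D voxel array with physical voxel dimensions.

    Parameters
    ----------
    channels
        Mapping of channel name to a ``(z, y, x)`` array of non-negative
        intensities.  All channels must share one shape.
    voxel_size_zyx
        Physical voxel size in micrometres per axis ``(z, y, x)``.
    """

    channels: dict[str, np.ndarray]
    voxel_size_zyx: tuple[float, float, float] = (2.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("empty stack: no channels")
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 3:
            raise ValueError(f"channel arrays must be 3D (z, y, x); got shape {first}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channels disagree on shape: {shapes}")
        for ch, a in self.channels.items():
            a = np.asarray(a)
            if np.issubdtype(a.dtype, np.signedinteger) and a.min() < 0:
                raise ValueError(f"negative intensities in channel {ch!r}")
            self.channels[ch] = a

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_slices(self) -> int:
        return self.shape[0]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_zyx))

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class SliceProfile:
    """Per-slice intensity bookkeeping produced while cropping a stack."""

    sums: pd.DataFrame                       # index = z, columns = channels
    fences: dict[str, tuple[float, float]]   # channel -> (lower, upper)
    max_slice: dict[str, int]                # channel -> highest slice at global max
    reference_slice: int                     # max over channels of max_slice
    removed: tuple[int, ...]                 # removed z indices, ascending
    dividing_slice: int | None               # lowest removed index, or None

    def __post_init__(self) -> None:
        for ch, (lo, hi) in self.fences.items():
            if lo > hi:
                raise ValueError(f"fences inverted for channel {ch!r}: {(lo, hi)}")
        if any(z <= self.reference_slice for z in self.removed):
            raise ValueError("removed slice at or below the reference slice")

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: sums plus outlier/removed flags per slice."""
        df = self.sums.copy()
        for ch, (lo, hi) in self.fences.items():
            df[f"{ch}_outlying"] = (df[ch] < lo) | (df[ch] > hi)
        df["removed"] = df.index.isin(self.removed)
        return df

    def to_json_dict(self) -> dict:
        return {
            "fences": {ch: list(map(float, f)) for ch, f in self.fences.items()},
            "max_slice": {ch: int(i) for ch, i in self.max_slice.items()},
            "reference_slice": int(self.reference_slice),
            "removed": [int(z) for z in self.removed],
            "dividing_slice": None if self.dividing_slice is None else int(self.dividing_slice),
        }


def sum_slice_intensities(stack: ImageStack) -> pd.DataFrame:
    """Sum voxel intensities per slice, one column per channel.

    Sums are exact integer arithmetic for integer inputs (accumulated in
    int64), one value per slice per channel.
    """
    if stack.n_slices == 0:
        raise ValueError("empty stack")
    data = {}
    for ch, a in stack.channels.items():
        acc = np.int64 if np.issubdtype(a.dtype, np.integer) else np.float64
        data[ch] = a.sum(axis=(1, 2), dtype=acc)
    return pd.DataFrame(data, index=pd.RangeIndex(stack.n_slices, name="z"))


def tukey_inner_fences(values: Sequence[float]) -> tuple[float, float]:
    """Tukey's inner fences ``(Q1 - 1.5 IQR, Q3 + 1.5 IQR)``.

    Quartiles use linear interpolation between order statistics (the
    "type 7" convention).  A value is outlying iff it falls strictly
    outside ``[lower, upper]``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        v = v.ravel()
    if v.size < 4:
        raise ValueError("insufficient slices: Tukey fences need at least 4 values")
    q1, q3 = np.quantile(v, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def max_intensity_slice(stack: ImageStack) -> dict[str, int]:
    """Highest z-index containing a voxel at each channel's global maximum."""
    if stack.n_slices == 0:
        raise ValueError("empty stack")
    out = {}
    for ch, a in stack.channels.items():
        peak = a.max()
        hit = np.flatnonzero(a.max(axis=(1, 2)) == peak)
        out[ch] = int(hit[-1])
    return out


def crop_stack(stack: ImageStack) -> tuple[ImageStack, SliceProfile]:
    """Remove glass-layer slices from a two-channel stack.

    A slice is removed iff (a) its z-index is strictly above the reference
    slice -- the larger, across channels, of the highest slice attaining
    the channel's absolute-maximum intensity -- and (b) its summed intensity
    is outlying (outside the Tukey inner fences) in either channel.  Fences
    are computed once from all slices; removal is a single pass.
    """
    if stack.n_slices < 4:
        raise ValueError("insufficient slices: need at least 4 to compute fences")
    sums = sum_slice_intensities(stack)
    fences = {ch: tukey_inner_fences(sums[ch].to_numpy()) for ch in sums.columns}
    max_slices = max_intensity_slice(stack)
    reference = max(max_slices.values())

    outlying = np.zeros(stack.n_slices, dtype=bool)
    for ch, (lo, hi) in fences.items():
        s = sums[ch].to_numpy()
        outlying |= (s < lo) | (s > hi)
    z = np.arange(stack.n_slices)
    removed = tuple(int(i) for i in z[(z > reference) & outlying])
    keep = np.setdiff1d(z, removed)
    if keep.size == 0:
        raise ValueError("no scaffold region: every slice was removed")

    cropped = ImageStack(
        channels={ch: a[keep] for ch, a in stack.channels.items()},
        voxel_size_zyx=stack.voxel_size_zyx,
    )
    profile = SliceProfile(
        sums=sums,
        fences=fences,
        max_slice=max_slices,
        reference_slice=reference,
        removed=removed,
        dividing_slice=min(removed) if removed else None,
    )
    return cropped, profile


def read_stack(
    paths: Mapping[str, str | Path],
    voxel_size_zyx: tuple[float, float, float] = (2.0, 1.0, 1.0),
) -> ImageStack:
    """Read one multi-page TIFF per channel (z as pages)."""
    channels = {}
    for ch, p in paths.items():
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"missing channel {ch!r}: {p}")
        channels[ch] = tifffile.imread(p)
    return ImageStack(channels=channels, voxel_size_zyx=voxel_size_zyx)


def write_stack(stack: ImageStack, out_dir: str | Path, prefix: str = "stack") -> dict[str, Path]:
    """Write one multi-page TIFF per channel; returns channel -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for ch, a in stack.channels.items():
        p = out_dir / f"{prefix}_{ch}.tif"
        tifffile.imwrite(p, a)
        paths[ch] = p
    return paths
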