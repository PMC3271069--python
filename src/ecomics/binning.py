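"""Digitization of 1D/2D NMR spectra into bin matrices and region pies.

Binning partitions a ppm region of interest into ``n_bins`` equal-width
intervals and aggregates the intensities of all grid points falling in
each interval. Intervals are half-open ``[low, high)`` with the most
downfield bin closed at its upper edge, so the region's top boundary
point is counted exactly once. Aggregation is by SUM, which preserves
total in-region intensity (``mode="mean"`` is available); bins are
ordered downfield -> upfield (high ppm first), the convention of the
bin-table text format.

The chemical-shift-region summary (:func:`region_fractions`) condenses a
spectrum into the fractional intensity of ``n_regions`` equal-width
regions (default 20 regions over -1..9 ppm, i.e. 0.5 ppm each), the
quantity shown as red-to-green pie charts: red marks the upfield (-1 ppm)
end and green the downfield (9 ppm) end. Negative intensities are
clipped to zero before the fractions are formed, so the result is a
proper distribution even for signed 2D spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import SampleMatrix, SpectrumGrid

__all__ = [
    "BinSpec",
    "BinMatrix",
    "RegionFractions",
    "bin_spectrum_1d",
    "bin_spectrum_2d",
    "batch_bin",
    "region_fractions",
]


@dataclass(frozen=True)
class BinSpec:
    """Region of interest and resolution for one binning axis.

    ppm_low / ppm_high bound the region (low < high); n_bins >= 1 equal
    intervals; ``mode`` is the in-bin aggregation ("sum" or "mean").
    """

    ppm_low: float
    ppm_high: float
    n_bins: int
    mode: str = "sum"

    def __post_init__(self) -> None:
        if not self.ppm_low < self.ppm_high:
            raise ValueError(f"ppm_low must be < ppm_high, got ({self.ppm_low}, {self.ppm_high})")
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")
        if self.mode not in ("sum", "mean"):
            raise ValueError(f"unknown aggregation mode {self.mode!r}")

    @property
    def width(self) -> float:
        return (self.ppm_high - self.ppm_low) / self.n_bins

    def centers_downfield(self) -> np.ndarray:
        """Bin-center ppm values, downfield (high ppm) first."""
        k = np.arange(self.n_bins)
        asc = self.ppm_low + (k + 0.5) * self.width
        return asc[::-1]


@dataclass
class BinMatrix:
    """One binned spectrum per row, all rows sharing one BinSpec grid."""

    bin_labels: list[str]
    spectrum_labels: list[str]
    values: np.ndarray
    spec: tuple[BinSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.spectrum_labels), len(self.bin_labels)):
            raise ValueError("bin matrix shape does not match its labels")

    def to_sample_matrix(self, block_label: str | None = None) -> SampleMatrix:
        """View the bin table as a SampleMatrix (rows = spectra, columns = bins)."""
        return SampleMatrix(
            row_ids=list(self.spectrum_labels),
            sample_labels=list(self.bin_labels),
            values=self.values,
            block_label=block_label,
        )


def _bin_index(ppm: np.ndarray, spec: BinSpec) -> np.ndarray:
    """Ascending-interval index per point; -1 marks out-of-region points.

    Interval k (ascending) is [low + k*w, low + (k+1)*w), except the last
    which also contains the exact upper boundary.
    """
    ppm = np.asarray(ppm, dtype=float)
    idx = np.floor((ppm - spec.ppm_low) / spec.width).astype(int)
    idx[ppm == spec.ppm_high] = spec.n_bins - 1  # closed top edge
    outside = (ppm < spec.ppm_low) | (ppm > spec.ppm_high)
    idx[outside] = -1
    return idx


def _aggregate(idx: np.ndarray, weights: np.ndarray, spec: BinSpec) -> np.ndarray:
    inside = idx >= 0
    sums = np.bincount(idx[inside], weights=weights[inside], minlength=spec.n_bins)
    if spec.mode == "mean":
        counts = np.bincount(idx[inside], minlength=spec.n_bins)
        with np.errstate(invalid="ignore"):
            sums = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return sums


def bin_spectrum_1d(spectrum: SpectrumGrid, spec: BinSpec) -> np.ndarray:
    """Bin a 1D spectrum; returns one value per bin, downfield first."""
    if spectrum.ndim != 1:
        raise ValueError("bin_spectrum_1d requires a 1D spectrum")
    ppm = spectrum.axes[0]
    if ppm.max() < spec.ppm_low or ppm.min() > spec.ppm_high:
        raise ValueError(
            f"region ({spec.ppm_low}, {spec.ppm_high}) ppm is disjoint from the "
            f"spectrum axis [{ppm.min():g}, {ppm.max():g}]"
        )
    idx = _bin_index(ppm, spec)
    asc = _aggregate(idx, spectrum.intensities, spec)
    return asc[::-1]


def bin_spectrum_2d(spectrum: SpectrumGrid, spec_f1: BinSpec, spec_f2: BinSpec) -> np.ndarray:
    """Bin a 2D spectrum on a rectangular grid; flattened row-major.

    F1 (13C) is the outer axis, F2 (1H) the inner, both downfield first.
    Negative intensities are preserved (2D cross peaks can be signed).
    """
    if spectrum.ndim != 2:
        raise ValueError("bin_spectrum_2d requires a 2D spectrum")
    for ax, spec, name in ((0, spec_f1, "F1"), (1, spec_f2, "F2")):
        ppm = spectrum.axes[ax]
        if ppm.max() < spec.ppm_low or ppm.min() > spec.ppm_high:
            raise ValueError(
                f"{name} region ({spec.ppm_low}, {spec.ppm_high}) ppm is disjoint "
                f"from the spectrum axis"
            )
    i1 = _bin_index(spectrum.axes[0], spec_f1)
    i2 = _bin_index(spectrum.axes[1], spec_f2)
    if spec_f1.mode != spec_f2.mode:
        raise ValueError("F1 and F2 BinSpecs must share one aggregation mode")
    grid = np.zeros((spec_f1.n_bins, spec_f2.n_bins))
    inside1, inside2 = i1 >= 0, i2 >= 0
    flat = (
        i1[inside1][:, None] * spec_f2.n_bins + i2[inside2][None, :]
    ).ravel()
    vals = spectrum.intensities[np.ix_(inside1, inside2)].ravel()
    sums = np.bincount(flat, weights=vals, minlength=grid.size)
    if spec_f1.mode == "mean":
        counts = np.bincount(flat, minlength=grid.size)
        with np.errstate(invalid="ignore"):
            sums = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    grid = sums.reshape(spec_f1.n_bins, spec_f2.n_bins)
    # ascending-index grid -> downfield-first on both axes
    return grid[::-1, ::-1].ravel()


def _labels_1d(spec: BinSpec) -> list[str]:
    return [f"{c:.3f}" for c in spec.centers_downfield()]


def _labels_2d(spec_f1: BinSpec, spec_f2: BinSpec) -> list[str]:
    return [
        f"C{c1:.3f}_H{c2:.3f}"
        for c1 in spec_f1.centers_downfield()
        for c2 in spec_f2.centers_downfield()
    ]


def batch_bin(
    spectra: list[SpectrumGrid],
    spec: BinSpec,
    spec_f2: BinSpec | None = None,
) -> BinMatrix:
    """Bin a batch of spectra onto one shared grid (one row per spectrum).

    For 1D input pass a single BinSpec; for 2D pass the F1 spec as ``spec``
    and the F2 (1H) spec as ``spec_f2``. Mixing 1D and 2D spectra is an
    error. The resulting BinMatrix writes (via
    :func:`ecomics.io_formats.write_sample_matrix`) as one tab-delimited
    bin spectrum per line with a header of bin-position labels — for 2D
    bins the header token ``C{13C}_H{1H}`` encodes both plane coordinates.
    """
    if not spectra:
        raise ValueError("empty spectrum batch")
    ndims = {s.ndim for s in spectra}
    if len(ndims) > 1:
        raise ValueError("mixed 1D/2D spectra in one batch")
    ndim = ndims.pop()
    if ndim == 1:
        if spec_f2 is not None:
            raise ValueError("spec_f2 given for a 1D batch")
        rows = [bin_spectrum_1d(s, spec) for s in spectra]
        labels = _labels_1d(spec)
        used: tuple[BinSpec, ...] = (spec,)
    else:
        if spec_f2 is None:
            raise ValueError("2D batch requires both F1 and F2 BinSpecs")
        rows = [bin_spectrum_2d(s, spec, spec_f2) for s in spectra]
        labels = _labels_2d(spec, spec_f2)
        used = (spec, spec_f2)
    names = [s.label or f"spectrum{i + 1}" for i, s in enumerate(spectra)]
    return BinMatrix(labels, names, np.vstack(rows), spec=used)


@dataclass
class RegionFractions:
    """Fractional intensity of equal-width chemical-shift regions.

    Regions are ordered downfield -> upfield. ``palette_position`` gives,
    per region, the position on the red(upfield)->green(downfield) scale
    as a number in [0, 1] with 0 = red/upfield and 1 = green/downfield.
    ``empty`` flags a spectrum with no positive intensity (fractions all
    zero rather than an exception).
    """

    fractions: np.ndarray
    region_bounds: list[tuple[float, float]]
    palette_position: np.ndarray
    empty: bool

    def labels(self) -> list[str]:
        return [f"{hi:g}..{lo:g} ppm" for lo, hi in self.region_bounds]


def region_fractions(
    spectrum: SpectrumGrid | np.ndarray,
    region_low: float = -1.0,
    region_high: float = 9.0,
    n_regions: int = 20,
    *,
    ppm: np.ndarray | None = None,
) -> RegionFractions:
    """Summarize a spectrum into per-region intensity fractions.

    Accepts a 1D SpectrumGrid or a raw intensity vector with an explicit
    ``ppm`` axis. Negative intensities are clipped at zero; fractions sum
    to 1 whenever any positive intensity lies in the region.
    """
    spec = BinSpec(region_low, region_high, n_regions)
    if isinstance(spectrum, SpectrumGrid):
        if spectrum.ndim != 1:
            raise ValueError("region_fractions expects a 1D spectrum")
        axis, values = spectrum.axes[0], spectrum.intensities
    else:
        if ppm is None:
            raise ValueError("raw intensity input requires an explicit ppm axis")
        axis, values = np.asarray(ppm, dtype=float), np.asarray(spectrum, dtype=float)
    clipped = np.clip(values, 0.0, None)
    idx = _bin_index(axis, spec)
    sums = _aggregate(idx, clipped, BinSpec(region_low, region_high, n_regions))[::-1]
    total = sums.sum()
    empty = not total > 0
    fractions = sums / total if not empty else np.zeros(n_regions)
    asc_edges = region_low + spec.width * np.arange(n_regions + 1)
    bounds = [
        (asc_edges[k], asc_edges[k + 1]) for k in range(n_regions)
    ][::-1]  # downfield first
    centers = spec.centers_downfield()
    span = region_high - region_low
    palette = (centers - region_low) / span  # 1 at downfield/green, 0 at upfield/red
    return RegionFractions(fractions, bounds, palette, empty)
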