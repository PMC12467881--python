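"""Domain containers and preprocessing for LIBS emission spectra.

A :class:`Spectrum` is a single wavelength-indexed intensity trace with
instrument provenance; a :class:`LabeledSpectrumSet` is an ordered collection
of spectra sharing one wavelength grid, with a class label per spectrum.
Preprocessing follows common LIBS practice for shot-resolved acquisitions:
consecutive shots are block-averaged per sample, low-resolution traces are
Savitzky-Golay smoothed, and every spectrum is max-min normalized to [0, 1]
before modeling.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "LabeledSpectrumSet",
    "InstrumentMeta",
    "read_spectra",
    "write_spectra",
    "average_blocks",
    "savgol_smooth",
    "minmax_normalize",
]


class SpectrumError(ValueError):
    """Raised for contract violations on spectral inputs."""


def _validate_grid(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise SpectrumError("wavelength grid must be 1-D with length >= 2")
    if not np.all(np.isfinite(wl)):
        raise SpectrumError("wavelength grid contains NaN/inf")
    if np.any(np.diff(wl) <= 0):
        bad = int(np.argmax(np.diff(wl) <= 0))
        raise SpectrumError(
            f"wavelengths must be strictly increasing (violation near index {bad})"
        )
    return wl


@dataclass
class Spectrum:
    """One emission spectrum: strictly increasing nm grid + intensities.

    Intensities are in arbitrary detector units (counts); they may be negative
    after background subtraction or noise, hence no sign constraint.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    instrument_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = _validate_grid(self.wavelengths)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.wavelengths.shape:
            raise SpectrumError(
                f"intensities length {self.intensities.size} != "
                f"wavelengths length {self.wavelengths.size}"
            )

    def __len__(self) -> int:
        return self.wavelengths.size

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.wavelengths.copy(),
            self.intensities.copy(),
            self.instrument_id,
            copy.deepcopy(self.meta),
        )


@dataclass
class InstrumentMeta:
    """Nominal spectrometer characteristics (range, resolution band, detector)."""

    range_nm: tuple[float, float]
    resolution_nm: tuple[float, float]
    detector: str = ""

    def __post_init__(self) -> None:
        for lo, hi in (self.range_nm, self.resolution_nm):
            if not lo < hi:
                raise SpectrumError(f"invalid interval ({lo}, {hi}): need lo < hi")


class LabeledSpectrumSet:
    """Ordered set of spectra on one shared grid, with one class label each.

    Internally stores an (n_spectra, n_points) intensity matrix; order is
    acquisition order, which the 7:3 ordered split relies on.
    """

    def __init__(
        self,
        wavelengths: np.ndarray,
        intensities: np.ndarray,
        labels: Sequence[str],
        instrument_id: str = "",
        meta: Sequence[dict] | None = None,
    ) -> None:
        self.wavelengths = _validate_grid(wavelengths)
        self.intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
        if self.intensities.shape[1] != self.wavelengths.size:
            raise SpectrumError(
                "intensity matrix column count does not match wavelength grid"
            )
        self.labels = list(labels)
        if len(self.labels) != self.intensities.shape[0]:
            raise SpectrumError("one label per spectrum required")
        self.instrument_id = instrument_id
        self.meta = [dict(m) for m in meta] if meta is not None else [
            {} for _ in self.labels
        ]
        if len(self.meta) != len(self.labels):
            raise SpectrumError("one meta dict per spectrum required")

    @classmethod
    def from_spectra(
        cls, spectra: Sequence[Spectrum], labels: Sequence[str], instrument_id: str = ""
    ) -> "LabeledSpectrumSet":
        if len(spectra) != len(labels):
            raise SpectrumError("len(labels) must equal len(spectra)")
        if not spectra:
            raise SpectrumError("empty spectrum set")
        grid = spectra[0].wavelengths
        for i, s in enumerate(spectra):
            if s.wavelengths.shape != grid.shape or not np.allclose(
                s.wavelengths, grid, rtol=0, atol=1e-9
            ):
                raise SpectrumError(f"spectrum {i} is not on the shared grid")
        mat = np.vstack([s.intensities for s in spectra])
        return cls(grid, mat, labels, instrument_id, [s.meta for s in spectra])

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(
            self.wavelengths, self.intensities[i], self.instrument_id, self.meta[i]
        )

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield self[i]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def subset(self, idx) -> "LabeledSpectrumSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return LabeledSpectrumSet(
            self.wavelengths,
            self.intensities[idx],
            [self.labels[i] for i in idx],
            self.instrument_id,
            [self.meta[i] for i in idx],
        )

    def class_mean(self, label: str) -> np.ndarray:
        mask = np.array([l == label for l in self.labels])
        if not mask.any():
            raise SpectrumError(f"no spectra labeled {label!r}")
        return self.intensities[mask].mean(axis=0)

    def copy(self) -> "LabeledSpectrumSet":
        return LabeledSpectrumSet(
            self.wavelengths.copy(),
            self.intensities.copy(),
            list(self.labels),
            self.instrument_id,
            [dict(m) for m in self.meta],
        )


# ---------------------------------------------------------------------------
# Tabular I/O.
#
# Long CSV: wavelength_nm, intensity, spectrum_id, label, instrument_id.
# Wide CSV: wavelength_nm + one column per spectrum; labels in a sidecar YAML
# ({column: label}) or passed directly.
# ---------------------------------------------------------------------------

def read_spectra(
    path: str | Path,
    fmt: str = "wide",
    labels: Sequence[str] | str | Path | None = None,
    instrument_id: str | None = None,
) -> LabeledSpectrumSet:
    """Read a labeled spectrum set from a long- or wide-format CSV file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "long":
        df = pd.read_csv(path)
        required = {"wavelength_nm", "intensity", "spectrum_id", "label"}
        missing = required - set(df.columns)
        if missing:
            raise SpectrumError(f"{path}: missing columns {sorted(missing)}")
        if df["wavelength_nm"].isna().any():
            row = int(df["wavelength_nm"].isna().idxmax())
            raise SpectrumError(f"{path}: NaN wavelength at row {row}")
        spectra, labs = [], []
        inst = instrument_id
        grid = None
        for sid, grp in df.groupby("spectrum_id", sort=False):
            wl = grp["wavelength_nm"].to_numpy(float)
            if grid is not None and wl.size != grid.size:
                raise SpectrumError(
                    f"{path}: spectrum {sid!r} has ragged length {wl.size}"
                )
            grid = wl
            if inst is None and "instrument_id" in grp:
                inst = str(grp["instrument_id"].iloc[0])
            spectra.append(
                Spectrum(wl, grp["intensity"].to_numpy(float), inst or "",
                         {"spectrum_id": sid})
            )
            labs.append(str(grp["label"].iloc[0]))
        return LabeledSpectrumSet.from_spectra(spectra, labs, inst or "")
    if fmt == "wide":
        df = pd.read_csv(path)
        if "wavelength_nm" not in df.columns:
            raise SpectrumError(f"{path}: first column must be wavelength_nm")
        if df["wavelength_nm"].isna().any():
            row = int(df["wavelength_nm"].isna().idxmax())
            raise SpectrumError(f"{path}: NaN wavelength at row {row}")
        wl = df["wavelength_nm"].to_numpy(float)
        cols = [c for c in df.columns if c != "wavelength_nm"]
        if labels is None:
            raise SpectrumError("wide format requires labels (sequence or sidecar)")
        if isinstance(labels, (str, Path)):
            with open(labels) as fh:
                mapping = yaml.safe_load(fh)
            labs = [str(mapping[c]) for c in cols]
        else:
            labs = [str(l) for l in labels]
            if len(labs) != len(cols):
                raise SpectrumError("label count does not match spectrum columns")
        mat = df[cols].to_numpy(float).T
        meta = [{"spectrum_id": c} for c in cols]
        return LabeledSpectrumSet(wl, mat, labs, instrument_id or "", meta)
    raise ValueError(f"unknown format {fmt!r} (expected 'long' or 'wide')")


def write_spectra(sset: LabeledSpectrumSet, path: str | Path, fmt: str = "wide") -> None:
    """Write a labeled spectrum set to CSV (inverse of :func:`read_spectra`)."""
    path = Path(path)
    if fmt == "long":
        frames = []
        for i, s in enumerate(sset):
            sid = s.meta.get("spectrum_id", f"s{i:05d}")
            frames.append(
                pd.DataFrame(
                    {
                        "wavelength_nm": s.wavelengths,
                        "intensity": s.intensities,
                        "spectrum_id": sid,
                        "label": sset.labels[i],
                        "instrument_id": sset.instrument_id,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        return
    if fmt == "wide":
        data = {"wavelength_nm": sset.wavelengths}
        mapping = {}
        for i in range(len(sset)):
            col = str(sset.meta[i].get("spectrum_id", f"s{i:05d}"))
            data[col] = sset.intensities[i]
            mapping[col] = sset.labels[i]
        pd.DataFrame(data).to_csv(path, index=False)
        with open(path.with_suffix(".labels.yaml"), "w") as fh:
            yaml.safe_dump(mapping, fh, sort_keys=False)
        return
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def average_blocks(
    sset: LabeledSpectrumSet, block: int, on_remainder: str = "error"
) -> LabeledSpectrumSet:
    """Average consecutive blocks of shots within each (sample, label) group.

    Shots are grouped by the ``sample`` meta key (falling back to the label
    when absent) in acquisition order; each run of ``block`` consecutive
    spectra is replaced by its pointwise mean, shrinking counts by ``block``.

    Parameters
    ----------
    block
        Number of consecutive shots per average (e.g. 4).
    on_remainder
        ``"error"`` (default) raises when a group size is not divisible by
        ``block``; ``"drop"`` discards the trailing remainder with a warning.
    """
    if block < 1 or int(block) != block:
        raise ValueError("block must be a positive integer")
    block = int(block)
    groups: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    for i, (lab, m) in enumerate(zip(sset.labels, sset.meta)):
        key = (lab, m.get("sample", lab))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
    out_rows, out_labels, out_meta = [], [], []
    for key in order:
        idx = groups[key]
        rem = len(idx) % block
        if rem:
            if on_remainder == "error":
                raise SpectrumError(
                    f"group {key} has {len(idx)} spectra, not divisible by {block}"
                )
            if on_remainder == "drop":
                import warnings

                warnings.warn(
                    f"group {key}: dropping {rem} trailing spectra "
                    f"(size {len(idx)} not divisible by {block})"
                )
                idx = idx[: len(idx) - rem]
            else:
                raise ValueError("on_remainder must be 'error' or 'drop'")
        for j in range(0, len(idx), block):
            chunk = idx[j : j + block]
            out_rows.append(sset.intensities[chunk].mean(axis=0))
            out_labels.append(sset.labels[chunk[0]])
            m = dict(sset.meta[chunk[0]])
            m["n_averaged"] = block
            out_meta.append(m)
    return LabeledSpectrumSet(
        sset.wavelengths, np.vstack(out_rows), out_labels, sset.instrument_id, out_meta
    )


def savgol_smooth(obj, window: int = 11, polyorder: int = 3):
    """Savitzky-Golay smoothing: local least-squares polynomial fit.

    Each point is replaced by the value of a degree-``polyorder`` polynomial
    fit over a ``window``-point moving window. At the boundaries the fit
    polynomial of the terminal window is evaluated directly (no padding).
    Accepts a :class:`Spectrum` or a :class:`LabeledSpectrumSet`.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if isinstance(obj, Spectrum):
        if window > len(obj):
            raise ValueError("window exceeds spectrum length")
        out = obj.copy()
        out.intensities = savgol_filter(
            obj.intensities, window, polyorder, mode="interp"
        )
        return out
    if isinstance(obj, LabeledSpectrumSet):
        if window > obj.wavelengths.size:
            raise ValueError("window exceeds spectrum length")
        out = obj.copy()
        out.intensities = savgol_filter(
            obj.intensities, window, polyorder, axis=1, mode="interp"
        )
        return out
    raise TypeError("expected Spectrum or LabeledSpectrumSet")


def minmax_normalize(obj):
    """Max-min normalization y = (x - min x) / (max x - min x), per spectrum.

    The min and max are per-spectrum scalars, so each output trace spans
    exactly [0, 1]. A constant spectrum (max == min) is a degenerate input
    and raises rather than emitting NaN.
    """
    if isinstance(obj, Spectrum):
        x = obj.intensities
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise SpectrumError("cannot normalize a constant spectrum (max == min)")
        out = obj.copy()
        out.intensities = (x - lo) / (hi - lo)
        return out
    if isinstance(obj, LabeledSpectrumSet):
        x = obj.intensities
        lo = x.min(axis=1, keepdims=True)
        hi = x.max(axis=1, keepdims=True)
        flat = np.flatnonzero((hi - lo).ravel() == 0)
        if flat.size:
            raise SpectrumError(
                f"cannot normalize constant spectra at rows {flat[:5].tolist()}"
            )
        out = obj.copy()
        out.intensities = (x - lo) / (hi - lo)
        return out
    raise TypeError("expected Spectrum or LabeledSpectrumSet")
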