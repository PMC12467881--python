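"""Peak features, cross-instrument matching, and ANOVA F-value ranking.

Feature selection runs on the low-resolution (training) instrument only:
peaks of the class-mean spectra above an absolute intensity threshold form
the base feature set, and a one-way ANOVA F statistic ranks every candidate
wavelength by class discriminative power. The same features are then read
off the other instrument's spectra by point-to-point matching that tolerates
a small rigid wavelength registration shift between instruments.

The F value for a candidate wavelength with intensities x_ij (class i,
spectrum j; k classes, N spectra total) is the between/within mean-square
ratio

    F = MSB / MSW = [SSB / (k-1)] / [SSW / (N-k)],
    SSB = sum_i n_i (xbar_i - xbar)^2,   SSW = sum_i sum_j (x_ij - xbar_i)^2.

A larger F marks a more class-informative wavelength; F is used purely as a
ranking score, not as a hypothesis test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .simulate import LineList
from .spectra import LabeledSpectrumSet

__all__ = [
    "PeakFeature",
    "FeatureTable",
    "AnovaRanking",
    "detect_peaks",
    "extract_features",
    "match_peaks",
    "anova_rank",
    "candidate_wavelengths",
    "select_incremental",
    "features_to_frame",
]


def features_to_frame(features: Sequence["PeakFeature"]) -> pd.DataFrame:
    """Serializable view of a feature set (wavelength, species, origin, F)."""
    return pd.DataFrame(
        {
            "wavelength_nm": [f.wavelength_nm for f in features],
            "species": [f.species for f in features],
            "origin": [f.origin for f in features],
            "f_value": [f.f_value for f in features],
        }
    )


@dataclass(frozen=True)
class PeakFeature:
    """One feature wavelength on the reference (low-resolution) grid."""

    wavelength_nm: float
    species: str | None = None
    origin: str = "peak-set"  # or "anova-added"
    f_value: float | None = None


@dataclass
class FeatureTable:
    """Spectra x features intensity matrix with labels and provenance."""

    features: list[PeakFeature]
    matrix: np.ndarray
    labels: list[str]
    instrument_id: str = ""
    meta: list[dict] = field(default_factory=list)
    match_rates: np.ndarray | None = None  # per feature, in [0, 1]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.features):
            raise ValueError("matrix column count != number of features")
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("matrix row count != number of labels")
        if not self.meta:
            self.meta = [{} for _ in self.labels]

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([f.wavelength_nm for f in self.features])

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    def subset_columns(self, idx: Sequence[int]) -> "FeatureTable":
        idx = list(idx)
        return FeatureTable(
            [self.features[i] for i in idx],
            self.matrix[:, idx],
            list(self.labels),
            self.instrument_id,
            [dict(m) for m in self.meta],
            None if self.match_rates is None else self.match_rates[idx],
        )

    def subset_rows(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureTable(
            list(self.features),
            self.matrix[idx],
            [self.labels[i] for i in idx],
            self.instrument_id,
            [dict(self.meta[i]) for i in idx],
            self.match_rates,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.matrix, columns=[f"{f.wavelength_nm:.2f}" for f in self.features]
        )
        df.insert(0, "label", self.labels)
        return df


@dataclass
class AnovaRanking:
    """Candidate wavelengths sorted by descending F value."""

    wavelengths_nm: np.ndarray
    f_values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.f_values = np.asarray(self.f_values, dtype=float)
        order = np.argsort(-self.f_values, kind="stable")
        self.wavelengths_nm = self.wavelengths_nm[order]
        self.f_values = self.f_values[order]

    def __len__(self) -> int:
        return self.f_values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength_nm": self.wavelengths_nm, "f_value": self.f_values}
        )


# ---------------------------------------------------------------------------
# Peak detection and matching
# ---------------------------------------------------------------------------

def _local_maxima(y: np.ndarray, halfwin: int) -> np.ndarray:
    """Indices that are strict maxima of y over a (2*halfwin+1)-point window."""
    n = y.size
    idx = np.arange(halfwin, n - halfwin)
    keep = np.ones(idx.size, dtype=bool)
    for off in range(1, halfwin + 1):
        keep &= (y[idx] > y[idx - off]) & (y[idx] > y[idx + off])
    return idx[keep]


def detect_peaks(
    sset: LabeledSpectrumSet,
    threshold: float = 1500.0,
    line_list: LineList | None = None,
    exclude_species: Sequence[str] = ("O", "H"),
    window: int = 5,
    annotate_tol_nm: float = 0.3,
) -> list[PeakFeature]:
    """Detect peak features from the class-mean spectra of a set.

    A feature is a strict local maximum of any class-mean spectrum over a
    ``window``-point neighborhood whose intensity exceeds ``threshold`` (in
    pre-normalization detector counts). Peaks found in several classes are
    merged (within one grid step). If a line list is given, each peak is
    annotated with the nearest line within ``annotate_tol_nm``, and peaks of
    excluded species (atmospheric O and H by default) are dropped.
    """
    halfwin = window // 2
    step = float(np.median(np.diff(sset.wavelengths)))
    found: list[tuple[float, float]] = []  # (wavelength, height)
    for label in sset.classes:
        mean = sset.class_mean(label)
        for i in _local_maxima(mean, halfwin):
            if mean[i] > threshold:
                found.append((float(sset.wavelengths[i]), float(mean[i])))
    if not found:
        import warnings

        warnings.warn(f"no peak exceeds threshold {threshold}")
        return []
    # merge across classes: cluster by wavelength within one grid step
    found.sort()
    merged: list[float] = []
    for wl, _h in found:
        if not merged or wl - merged[-1] > step * (1 + 1e-9):
            merged.append(wl)
    feats = []
    drop = set(exclude_species)
    for wl in merged:
        species = None
        if line_list is not None and len(line_list):
            lw = line_list.wavelengths()
            j = int(np.argmin(np.abs(lw - wl)))
            if abs(lw[j] - wl) <= annotate_tol_nm:
                species = line_list.species()[j]
        if species is not None and species in drop:
            continue
        feats.append(PeakFeature(wl, species, "peak-set"))
    return feats


def extract_features(
    sset: LabeledSpectrumSet, features: Sequence[PeakFeature]
) -> FeatureTable:
    """Read feature values off a set on its own grid (no matching): the
    intensity at the grid point nearest each feature wavelength."""
    idx = [
        int(np.argmin(np.abs(sset.wavelengths - f.wavelength_nm))) for f in features
    ]
    return FeatureTable(
        list(features),
        sset.intensities[:, idx],
        list(sset.labels),
        sset.instrument_id,
        [dict(m) for m in sset.meta],
        match_rates=np.ones(len(features)),
    )


def _window(grid: np.ndarray, step: float, center: float, half_nm: float):
    j = int(round((center - grid[0]) / step))
    pad = int(np.ceil(half_nm / step)) + 1
    return max(j - pad, 0), min(j + pad + 1, grid.size)


def estimate_shift(
    centers: np.ndarray,
    other: LabeledSpectrumSet,
    tol_nm: float,
    n_strong: int = 5,
) -> float:
    """Rigid wavelength registration offset of ``other`` vs the reference.

    Uses the few strongest reference features (largest window maxima): on a
    strong emission line the window argmax is the line apex, so the median
    of (apex wavelength - nominal wavelength) over spectra and features is a
    robust estimate of the instrument-wide shift.
    """
    grid = other.wavelengths
    step = float(np.median(np.diff(grid)))
    half = tol_nm + 0.2  # generous: shift + reference-grid quantization
    strengths, offs = [], []
    for c in centers:
        a, b = _window(grid, step, c, half)
        if b - a < 3:
            strengths.append(-np.inf)
            offs.append(None)
            continue
        seg = other.intensities[:, a:b]
        strengths.append(float(np.median(seg.max(axis=1))))
        offs.append(grid[a:b][np.argmax(seg, axis=1)] - c)
    order = np.argsort(strengths)[::-1][:n_strong]
    pooled = np.concatenate([offs[i] for i in order if offs[i] is not None])
    return float(np.median(pooled)) if pooled.size else 0.0


def match_peaks(
    ref_features: Sequence[PeakFeature],
    other: LabeledSpectrumSet,
    tol_nm: float = 0.3,
    noise_k: float = 10.0,
    shift_nm: float | None = None,
) -> FeatureTable:
    """Extract reference features from another instrument's spectra by
    point-to-point peak matching.

    The rigid inter-instrument registration shift is first calibrated from
    the strongest features (pass ``shift_nm`` to override). Then, for each
    feature and each spectrum, the nearest strict local maximum within
    +-``tol_nm`` of the shift-corrected nominal wavelength is located; to
    reject noise wiggles, a candidate maximum must rise at least ``noise_k``
    robust noise sigmas (estimated from local first differences) above the
    window minimum. Exact distance ties resolve to the lower wavelength.
    The feature value is the intensity at the matched point. When no
    qualifying maximum exists, the fallback value is the intensity
    interpolated at the shift-corrected nominal wavelength, and the
    feature's match rate drops below 1.
    """
    if tol_nm <= 0:
        raise ValueError("tol_nm must be > 0")
    grid = other.wavelengths
    step = float(np.median(np.diff(grid)))
    centers = np.array([f.wavelength_nm for f in ref_features])
    if shift_nm is None:
        shift_nm = estimate_shift(centers, other, tol_nm)
    n_spec, n_feat = len(other), len(ref_features)
    values = np.empty((n_spec, n_feat))
    matched = np.zeros((n_spec, n_feat), dtype=bool)

    X = other.intensities
    for f, c in enumerate(centers):
        target = c + shift_nm
        a, b = _window(grid, step, target, tol_nm)
        seg = X[:, a:b]
        lam = grid[a:b]
        if seg.shape[1] < 3:
            j = int(np.clip(round((target - grid[0]) / step), 0, grid.size - 1))
            values[:, f] = X[:, j]
            continue
        # local baseline and noise scale from a wider side window; the
        # q84 - median spread estimates the noise sigma robustly even when
        # the trace is floored at zero (clipped lower tail) or rides on a
        # baseline offset, and the peak occupies too little of the wide
        # window to pollute the quantiles
        na, nb = _window(grid, step, target, 3.0 * tol_nm + 0.1)
        noise_win = X[:, na:nb]
        baseline = np.median(noise_win, axis=1)
        sigma = np.quantile(noise_win, 0.8413, axis=1) - baseline
        floor = noise_k * sigma
        interior = seg[:, 1:-1]
        is_max = (interior > seg[:, :-2]) & (interior > seg[:, 2:])
        lam_int = lam[1:-1]
        dist = np.abs(lam_int - target)
        in_tol = dist <= tol_nm
        qualified = (
            is_max & in_tol[None, :] & (interior - baseline[:, None] >= floor[:, None])
        )
        # nearest wins, exact tie -> lower wavelength: scan columns in
        # (distance, wavelength) order and take the first qualifying one
        order = np.lexsort((lam_int, dist))
        q_ord = qualified[:, order]
        any_q = q_ord.any(axis=1)
        first = np.argmax(q_ord, axis=1)
        cols = order[first]
        rows = np.arange(n_spec)
        values[:, f] = np.where(any_q, interior[rows, cols], 0.0)
        matched[:, f] = any_q
        if not any_q.all():
            fb = np.clip(target, grid[0], grid[-1])
            miss = ~any_q
            # per-spectrum linear interpolation at the fallback wavelength
            j = np.searchsorted(grid, fb)
            j = min(max(j, 1), grid.size - 1)
            w = (fb - grid[j - 1]) / (grid[j] - grid[j - 1])
            values[miss, f] = (1 - w) * X[miss, j - 1] + w * X[miss, j]
    return FeatureTable(
        list(ref_features),
        values,
        list(other.labels),
        other.instrument_id,
        [dict(m) for m in other.meta],
        match_rates=matched.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# ANOVA ranking
# ---------------------------------------------------------------------------

def f_values_matrix(X: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """One-way ANOVA F statistic for every column of X, vectorized.

    Degenerate columns follow the ranking convention: SSW == 0 with SSB > 0
    gives +inf (perfectly separated feature, ranked first); SSB == SSW == 0
    gives 0 (constant feature).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    k, N = classes.size, X.shape[0]
    if k < 2:
        raise ValueError("ANOVA requires at least 2 classes")
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for c in classes:
        block = X[labels == c]
        if block.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 spectra")
        m = block.mean(axis=0)
        ssb += block.shape[0] * (m - grand) ** 2
        ssw += ((block - m) ** 2).sum(axis=0)
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    F[(ssw == 0) & (ssb > 0)] = np.inf
    F[(ssw == 0) & (ssb == 0)] = 0.0
    return F


def anova_rank(
    sset: LabeledSpectrumSet, candidates: Sequence[float]
) -> AnovaRanking:
    """Rank candidate wavelengths of a labeled set by one-way ANOVA F value."""
    candidates = np.asarray(candidates, dtype=float)
    idx = [int(np.argmin(np.abs(sset.wavelengths - c))) for c in candidates]
    F = f_values_matrix(sset.intensities[:, idx], sset.labels)
    return AnovaRanking(candidates, F)


def candidate_wavelengths(
    raw_set: LabeledSpectrumSet,
    threshold: float = 1500.0,
    restrict_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Grid points whose class-mean intensity exceeds ``threshold`` in any
    class, in pre-normalization detector counts (the ANOVA candidate pool)."""
    peak_env = np.max(
        [raw_set.class_mean(c) for c in raw_set.classes], axis=0
    )
    mask = peak_env > threshold
    if restrict_range is not None:
        lo, hi = restrict_range
        mask &= (raw_set.wavelengths >= lo) & (raw_set.wavelengths <= hi)
    return raw_set.wavelengths[mask]


# ---------------------------------------------------------------------------
# Incremental feature-count selection
# ---------------------------------------------------------------------------

def select_incremental(
    base: Sequence[PeakFeature],
    ranking: AnovaRanking,
    train_source: Callable[[Sequence[PeakFeature]], FeatureTable],
    test_source: Callable[[Sequence[PeakFeature]], FeatureTable],
    evaluate_fn: Callable[[FeatureTable, FeatureTable], float],
    max_added: int = 12,
    min_sep_nm: float | None = None,
) -> tuple[list[PeakFeature], pd.DataFrame]:
    """Grow the feature set by descending F value and keep the best count.

    Starting from ``base``, ranked candidate wavelengths are appended one at
    a time — skipping any candidate within ``min_sep_nm`` of an already
    selected feature (overlap deduplication) — the classifier is retrained
    at each step via ``evaluate_fn(train_table, test_table) -> accuracy``,
    and the feature set with maximal test accuracy is returned (ties favor
    fewer features), together with the full accuracy-vs-count curve.
    """
    if max_added < 0:
        raise ValueError("max_added must be >= 0")
    base = list(base)
    if min_sep_nm is None:
        # default: one step of the ranking's wavelength spacing, if inferable
        uw = np.unique(ranking.wavelengths_nm)
        min_sep_nm = float(np.min(np.diff(uw))) * 1.5 if uw.size > 1 else 0.0
    chosen_wl = [f.wavelength_nm for f in base]
    added: list[PeakFeature] = []
    for wl, fv in zip(ranking.wavelengths_nm, ranking.f_values):
        if len(added) >= max_added:
            break
        if any(abs(wl - w) <= min_sep_nm for w in chosen_wl):
            continue  # overlaps an existing feature: excluded, not double-counted
        added.append(PeakFeature(float(wl), None, "anova-added", float(fv)))
        chosen_wl.append(float(wl))

    all_features = base + added
    train_full = train_source(all_features)
    test_full = test_source(all_features)

    counts, accs = [], []
    for n_add in range(len(added) + 1):
        cols = list(range(len(base) + n_add))
        acc = evaluate_fn(
            train_full.subset_columns(cols), test_full.subset_columns(cols)
        )
        counts.append(len(cols))
        accs.append(float(acc))
    curve = pd.DataFrame({"n_features": counts, "accuracy": accs})
    best_i = int(np.argmax(accs))  # first occurrence: ties -> fewer features
    best = all_features[: len(base) + best_i]
    return list(best), curve
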