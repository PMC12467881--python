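"""End-to-end orchestration of the cross-instrument experiment protocols.

Five protocols are supported, mirroring the study designs the package
implements:

* ``single-L`` — train and test on the low-resolution instrument (ordered
  7:3 split per class, 20-peak base features);
* ``single-H`` — the same on the high-resolution instrument;
* ``cross-raw`` — train on low-res, test on high-res with no harmonization;
* ``cross-scfs`` — standard-lamp response correction of the high-res test
  set, then ANOVA-ranked incremental feature augmentation (spectral
  correction + feature selection);
* ``cross-scfs-pp`` — cross-scfs plus DBSCAN screening of abnormal test
  spectra before evaluation (post-processing).

A single :class:`PipelineConfig` (one YAML file) drives everything; every
stage's randomness derives from the one pipeline seed, so a report is
reproducible bit-identically from (config, seed, inputs).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    ClassificationReport,
    ForestConfig,
    evaluate,
    fit_forest,
    predict,
    split_protocol,
)
from .correction import build_transfer, correct_set, estimate_response
from .features import (
    FeatureTable,
    PeakFeature,
    anova_rank,
    candidate_wavelengths,
    detect_peaks,
    extract_features,
    match_peaks,
    select_incremental,
)
from .postprocess import DbscanConfig, dbscan_filter, kdistance
from .simulate import (
    default_class_profiles,
    default_line_list,
    draw_shift,
    high_res_instrument,
    lamp_reference,
    low_res_instrument,
    simulate_dataset,
    simulate_lamp,
)
from .spectra import (
    LabeledSpectrumSet,
    Spectrum,
    average_blocks,
    minmax_normalize,
    savgol_smooth,
)

log = logging.getLogger("libsbridge")

PROTOCOLS = ("single-L", "single-H", "cross-raw", "cross-scfs", "cross-scfs-pp")

__all__ = [
    "PipelineConfig",
    "ExperimentBundle",
    "RunReport",
    "simulate_bundle",
    "run_protocol",
    "run_all",
    "compare_protocols",
    "PROTOCOLS",
]


@dataclass
class PreprocessConfig:
    block: int = 4  # consecutive low-res shots averaged together
    sg_window: int = 11
    sg_polyorder: int = 3


@dataclass
class CorrectionConfig:
    range_nm: tuple[float, float] = (350.0, 850.0)
    smooth_response: bool = True
    smooth_window_nm: float = 1.0
    lamp_noise_rel: float = 0.002


@dataclass
class FeatureConfig:
    threshold: float = 1500.0  # peak/candidate intensity gate, detector counts
    tol_nm: float = 0.3  # matching tolerance for inter-instrument shifts
    max_added: int = 8  # cap on ANOVA-added features
    exclude_species: tuple[str, ...] = ("O", "H")


@dataclass
class DbscanBlock:
    min_points: int = 15
    k: int = 15  # neighbor order of the K-Distance Graph
    eps: float | None = None  # None -> automated elbow


@dataclass
class SimulationConfig:
    n_per_class: int = 500  # spectra per class per instrument (post-averaging)
    outlier_fraction: float = 0.1  # planted in the high-res (test) set
    n_samples_per_class: int = 10


@dataclass
class PipelineConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    dbscan: DbscanBlock = field(default_factory=DbscanBlock)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs: dict = {"seed": int(d.get("seed", 0))}
        blocks = {
            "simulation": SimulationConfig,
            "preprocess": PreprocessConfig,
            "correction": CorrectionConfig,
            "features": FeatureConfig,
            "forest": ForestConfig,
            "dbscan": DbscanBlock,
        }
        for key, klass in blocks.items():
            sub = dict(d.get(key, {}))
            for name, val in list(sub.items()):
                if isinstance(val, list):
                    sub[name] = tuple(val)
            kwargs[key] = klass(**sub)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ExperimentBundle:
    """Everything one experiment needs: the two instrument datasets (raw
    detector counts, acquisition order), the lamp triple, and the line list."""

    low_res_raw: LabeledSpectrumSet  # shot-resolved, pre-averaging
    high_res_raw: LabeledSpectrumSet
    lamp_reference: Spectrum
    lamp_low: Spectrum
    lamp_high: Spectrum
    line_list: object


def simulate_bundle(cfg: PipelineConfig, seed: int | None = None) -> ExperimentBundle:
    """Generate the default two-instrument experiment from one seed.

    The low-res set is shot-resolved (block x n_per_class shots per class,
    10 samples) so the averaging stage operates as in a real acquisition;
    the high-res set carries the planted outlier fraction. The high-res
    registration shift is drawn from [0.05, 0.3] nm (random sign).
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))
    lines = default_line_list()
    profiles = default_class_profiles()
    model_l = low_res_instrument()
    model_h = high_res_instrument(shift_nm=draw_shift(rng))
    sim = cfg.simulation
    low = simulate_dataset(
        profiles,
        model_l,
        n_per_class=sim.n_per_class * cfg.preprocess.block,
        outlier_fraction=0.0,
        seed=sub(),
        n_samples_per_class=sim.n_samples_per_class,
        line_list=lines,
    )
    high = simulate_dataset(
        profiles,
        model_h,
        n_per_class=sim.n_per_class,
        outlier_fraction=sim.outlier_fraction,
        seed=sub(),
        n_samples_per_class=sim.n_samples_per_class,
        line_list=lines,
    )
    ref = lamp_reference()
    lamp_l = simulate_lamp(model_l, ref, cfg.correction.lamp_noise_rel, seed=sub())
    lamp_h = simulate_lamp(model_h, ref, cfg.correction.lamp_noise_rel, seed=sub())
    return ExperimentBundle(low, high, ref, lamp_l, lamp_h, lines)


@dataclass
class RunReport:
    """Reproducible record of one protocol run."""

    protocol: str
    seed: int
    report: ClassificationReport
    n_features_used: int
    feature_wavelengths: list[float]
    accuracy_curve: list[dict] | None
    n_test_total: int
    n_test_retained: int
    n_test_removed: int
    retained_per_class: dict[str, int]
    outlier_precision: float | None
    outlier_recall: float | None
    test_instrument: str
    config: dict
    version: str = __version__

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    def to_dict(self) -> dict:
        d = asdict(self)
        d["report"] = self.report.to_dict()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1, default=str)


class _Workspace:
    """Lazily cached shared stages for one (bundle, config) pair, so running
    several protocols does not redo preprocessing, correction or matching."""

    def __init__(self, bundle: ExperimentBundle, cfg: PipelineConfig):
        self.bundle = bundle
        self.cfg = cfg
        self._cache: dict[str, object] = {}

    def _get(self, key: str, build):
        if key not in self._cache:
            t0 = time.perf_counter()
            self._cache[key] = build()
            log.info("stage %-22s %.2fs", key, time.perf_counter() - t0)
        return self._cache[key]

    # --- low-res chain -----------------------------------------------------
    def low_averaged(self) -> LabeledSpectrumSet:
        """Block-averaged shots in raw detector counts (pre-smoothing).

        Peak detection and the intensity-threshold candidate gate run on
        this set: the unsmoothed traces localize narrow blended peaks best,
        and the threshold is defined in raw counts.
        """
        return self._get(
            "low_averaged",
            lambda: average_blocks(self.bundle.low_res_raw, self.cfg.preprocess.block),
        )

    def low_smoothed(self) -> LabeledSpectrumSet:
        """Savitzky-Golay-smoothed averaged spectra, floored at zero.

        Emission intensities are non-negative; the filter's negative side
        lobes ring below zero at the foot of sharp peaks, and letting that
        artifact set the Eq.-style normalization minimum would shift every
        normalized feature by an instrument-specific offset. All pipeline
        traces are therefore clipped at zero before normalization.
        """

        def build():
            pp = self.cfg.preprocess
            out = savgol_smooth(self.low_averaged(), pp.sg_window, pp.sg_polyorder)
            np.maximum(out.intensities, 0.0, out=out.intensities)
            return out

        return self._get("low_smoothed", build)

    def low_normalized(self) -> LabeledSpectrumSet:
        return self._get(
            "low_normalized", lambda: minmax_normalize(self.low_smoothed())
        )

    def base_features(self) -> list[PeakFeature]:
        def build():
            fc = self.cfg.features
            feats = detect_peaks(
                self.low_averaged(),
                fc.threshold,
                self.bundle.line_list,
                fc.exclude_species,
            )
            if not feats:
                raise RuntimeError("no base peak features detected")
            return feats

        return self._get("base_features", build)

    # --- high-res chain ----------------------------------------------------
    def high_normalized_raw(self) -> LabeledSpectrumSet:
        def build():
            clipped = self.bundle.high_res_raw.copy()
            np.maximum(clipped.intensities, 0.0, out=clipped.intensities)
            return minmax_normalize(clipped)

        return self._get("high_normalized_raw", build)

    def transfer_function(self):
        def build():
            cc = self.cfg.correction
            r_l = estimate_response(
                self.bundle.lamp_reference,
                self.bundle.lamp_low,
                smooth=cc.smooth_response,
                smooth_window_nm=cc.smooth_window_nm,
            )
            r_h = estimate_response(
                self.bundle.lamp_reference,
                self.bundle.lamp_high,
                smooth=cc.smooth_response,
                smooth_window_nm=cc.smooth_window_nm,
            )
            return build_transfer(r_l, r_h, cc.range_nm)

        return self._get("transfer_function", build)

    def high_corrected_normalized(self) -> LabeledSpectrumSet:
        def build():
            corr = correct_set(self.bundle.high_res_raw, self.transfer_function())
            np.maximum(corr.intensities, 0.0, out=corr.intensities)
            return minmax_normalize(corr)

        return self._get("high_corrected_normalized", build)

    # --- feature tables ----------------------------------------------------
    def low_table(self, features: Sequence[PeakFeature]) -> FeatureTable:
        return extract_features(self.low_normalized(), features)

    def high_table(
        self, features: Sequence[PeakFeature], corrected: bool
    ) -> FeatureTable:
        key = (
            "high_table",
            corrected,
            tuple(round(f.wavelength_nm, 9) for f in features),
        )
        if key not in self._cache:
            src = (
                self.high_corrected_normalized()
                if corrected
                else self.high_normalized_raw()
            )
            t0 = time.perf_counter()
            self._cache[key] = match_peaks(
                features, src, tol_nm=self.cfg.features.tol_nm
            )
            log.info(
                "stage match(%d feats,%s)    %.2fs",
                len(features),
                "corr" if corrected else "raw",
                time.perf_counter() - t0,
            )
        return self._cache[key]

    def ranking(self):
        def build():
            cand = candidate_wavelengths(
                self.low_averaged(),
                self.cfg.features.threshold,
                self.cfg.correction.range_nm,
            )
            return anova_rank(self.low_normalized(), cand)

        return self._get("anova_ranking", build)

    def scfs_selection(self) -> tuple[list[PeakFeature], pd.DataFrame]:
        def build():
            cfg = self.cfg
            step = float(np.median(np.diff(self.low_normalized().wavelengths)))

            def eval_fn(train: FeatureTable, test: FeatureTable) -> float:
                model = fit_forest(train, cfg.forest)
                rep = evaluate(test.labels, predict(model, test), model.classes)
                return rep.accuracy

            return select_incremental(
                self.base_features(),
                self.ranking(),
                train_source=self.low_table,
                test_source=lambda feats: self.high_table(feats, corrected=True),
                evaluate_fn=eval_fn,
                max_added=cfg.features.max_added,
                min_sep_nm=step,
            )

        return self._get("scfs_selection", build)


def _outlier_metrics(
    meta: Sequence[dict], removed_idx: np.ndarray
) -> tuple[float | None, float | None]:
    truth = np.array([bool(m.get("outlier", False)) for m in meta])
    flagged = np.zeros(len(meta), dtype=bool)
    flagged[removed_idx] = True
    tp = int((truth & flagged).sum())
    precision = tp / flagged.sum() if flagged.sum() else None
    recall = tp / truth.sum() if truth.sum() else None
    return precision, recall


def run_protocol(
    bundle: ExperimentBundle,
    cfg: PipelineConfig,
    protocol: str,
    workspace: _Workspace | None = None,
) -> RunReport:
    """Execute one protocol end to end and return its reproducible report."""
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    ws = workspace or _Workspace(bundle, cfg)
    base = ws.base_features()
    curve_records = None
    outlier_p = outlier_r = None

    if protocol in ("single-L", "single-H"):
        table = (
            ws.low_table(base)
            if protocol == "single-L"
            else ws.high_table(base, corrected=False)
        )
        train, test = split_protocol(table, "single")
        features_used = base
    elif protocol == "cross-raw":
        train = ws.low_table(base)
        test = ws.high_table(base, corrected=False)
        train, test = split_protocol(train, "cross", other=test)
        features_used = base
    else:  # cross-scfs / cross-scfs-pp
        features_used, curve = ws.scfs_selection()
        curve_records = curve.to_dict("records")
        train = ws.low_table(features_used)
        test = ws.high_table(features_used, corrected=True)
        train, test = split_protocol(train, "cross", other=test)

    n_test_total = test.n_spectra
    removed = np.array([], dtype=int)
    if protocol == "cross-scfs-pp":
        db = cfg.dbscan
        eps = db.eps
        if eps is None:
            eps = kdistance(test, db.k).suggested_eps
        pre_meta = test.meta
        test, removed = dbscan_filter(
            test, DbscanConfig(eps=eps, min_points=db.min_points)
        )
        outlier_p, outlier_r = _outlier_metrics(pre_meta, removed)
    model = fit_forest(train, cfg.forest)
    pred = predict(model, test)
    report = evaluate(test.labels, pred, model.classes)

    labels_arr = np.asarray(test.labels)
    retained_per_class = {
        c: int((labels_arr == c).sum()) for c in sorted(set(test.labels))
    }
    return RunReport(
        protocol=protocol,
        seed=cfg.seed,
        report=report,
        n_features_used=len(features_used),
        feature_wavelengths=[round(f.wavelength_nm, 6) for f in features_used],
        accuracy_curve=curve_records,
        n_test_total=n_test_total,
        n_test_retained=test.n_spectra,
        n_test_removed=int(removed.size),
        retained_per_class=retained_per_class,
        outlier_precision=outlier_p,
        outlier_recall=outlier_r,
        test_instrument=test.instrument_id,
        config=cfg.to_dict(),
    )


def run_all(
    bundle: ExperimentBundle,
    cfg: PipelineConfig,
    protocols: Sequence[str] = PROTOCOLS,
) -> dict[str, RunReport]:
    """Run several protocols sharing one cached workspace."""
    ws = _Workspace(bundle, cfg)
    return {p: run_protocol(bundle, cfg, p, workspace=ws) for p in protocols}


def compare_protocols(reports: Sequence[RunReport]) -> pd.DataFrame:
    """Summary accuracy/precision/recall table across protocols.

    All reports must evaluate on the same test instrument; comparing, say, a
    low-res single-instrument run against cross-instrument runs would not be
    apples to apples.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    sources = {r.test_instrument for r in reports}
    if len(sources) > 1:
        raise ValueError(
            f"mismatched test provenance: reports evaluate on {sorted(sources)}"
        )
    rows = []
    for r in reports:
        row: dict = {
            "protocol": r.protocol,
            "accuracy": r.report.accuracy,
            "n_features": r.n_features_used,
            "n_evaluated": r.report.n_evaluated,
        }
        for c in r.report.classes:
            row[f"precision_{c}"] = r.report.precision[c]
            row[f"recall_{c}"] = r.report.recall[c]
        rows.append(row)
    return pd.DataFrame(rows)
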