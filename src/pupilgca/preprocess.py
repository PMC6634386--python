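"""Pupil preprocessing: raw sample streams to baseline-corrected 200 ms bins.

Stages, applied in fixed order per trial:

1. convert arbitrary tracker units to mm (calibration scale);
2. exclude participants and trials with > 30% missing samples;
3. remove implausible samples (outside 2-8 mm, then outside trial
   mean +/- 3 SD);
4. widen every missing run by 100 ms on each side (blink padding) and
   linearly interpolate across gaps;
5. remove dilation-speed outliers via a median-absolute-deviation
   threshold and re-interpolate;
6. smooth with a centered 5-point moving average;
7. subtract the median pupil diameter of the 500 ms before word-pair
   onset (subtractive baseline correction);
8. epoch the 0-4200 ms analysis window into 200 ms bins.

Every sample's fate is tracked in a provenance array so removal and
interpolation counts can be audited against simulator ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import RawPupilSeries

__all__ = [
    "PreprocessConfig",
    "CleanTrial",
    "ExclusionReport",
    "PupilPreprocessor",
    "convert_au_to_mm",
    "missingness_fraction",
    "apply_exclusions",
    "filter_implausible_samples",
    "extend_and_interpolate_blinks",
    "mad_speed_filter",
    "smooth_moving_average",
    "baseline_correct",
    "window_and_bin",
    "run_preprocessing",
]

# provenance codes
OBSERVED, INTERPOLATED, REMOVED_RANGE, REMOVED_SD, REMOVED_MAD = range(5)
PROVENANCE_LABELS = ("observed", "interpolated", "removed-range", "removed-sd", "removed-mad")


@dataclass
class PreprocessConfig:
    """All tunable constants of the preprocessing pipeline.

    Defaults are the emulated study's published values; ``au_to_mm_scale``
    is a tracker calibration constant with no universal value (default
    1000 au/mm in diameter mode; area-mode trackers report pupil area, in
    which case mm = 2*sqrt(au / (scale * pi))).
    """

    au_to_mm_scale: float = 1000.0
    au_mode: str = "diameter"  # or "area"
    missing_trial_max: float = 0.30
    missing_participant_max: float = 0.30
    plausible_mm: tuple[float, float] = (2.0, 8.0)
    trial_sd_k: float = 3.0
    blink_pad_ms: float = 100.0
    mad_multiplier: float = 16.0
    smooth_window: int = 5
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0)
    baseline_stat: str = "median"
    analysis_window_ms: tuple[float, float] = (0.0, 4200.0)
    bin_ms: float = 200.0
    bin_stat: str = "mean"  # or "median"

    def validate(self) -> None:
        if self.au_to_mm_scale <= 0:
            raise ValueError("au_to_mm_scale must be > 0")
        if self.au_mode not in ("diameter", "area"):
            raise ValueError("au_mode must be 'diameter' or 'area'")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd sample count")
        lo, hi = self.plausible_mm
        if not lo < hi:
            raise ValueError("plausible_mm interval is degenerate")
        if self.bin_ms <= 0 or self.blink_pad_ms < 0:
            raise ValueError("durations must be positive")
        if self.baseline_stat not in ("median", "mean"):
            raise ValueError("baseline_stat must be 'median' or 'mean'")

    @property
    def n_bins(self) -> int:
        lo, hi = self.analysis_window_ms
        return int(math.ceil((hi - lo) / self.bin_ms))


@dataclass
class CleanTrial:
    """A preprocessed, baseline-corrected trial with per-sample provenance."""

    participant_id: int
    trial_id: int
    condition: str
    time_ms: np.ndarray
    pupil_mm: np.ndarray
    provenance: np.ndarray  # int codes, see PROVENANCE_LABELS
    baseline_mm: float


@dataclass
class ExclusionReport:
    """Per-stage accounting of everything the pipeline removed."""

    n_trials_in: int = 0
    n_samples_in: int = 0
    trials_excluded_missing: int = 0
    participants_excluded: list = field(default_factory=list)
    trials_excluded_with_participants: int = 0
    trials_excluded_no_baseline: int = 0
    samples_removed_by_rule: dict = field(
        default_factory=lambda: {"removed-range": 0, "removed-sd": 0, "removed-mad": 0}
    )
    interpolated_samples: int = 0
    observed_samples: int = 0
    n_trials_out: int = 0

    @property
    def trial_exclusion_fraction(self) -> float:
        return self.trials_excluded_missing / self.n_trials_in if self.n_trials_in else 0.0

    @property
    def interpolated_fraction(self) -> float:
        n = self.observed_samples + self.interpolated_samples + sum(
            self.samples_removed_by_rule.values()
        )
        return self.interpolated_samples / n if n else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("trials_in", self.n_trials_in),
            ("trials_excluded_missing", self.trials_excluded_missing),
            ("trial_exclusion_fraction", self.trial_exclusion_fraction),
            ("participants_excluded", len(self.participants_excluded)),
            ("trials_excluded_with_participants", self.trials_excluded_with_participants),
            ("trials_excluded_no_baseline", self.trials_excluded_no_baseline),
            ("trials_out", self.n_trials_out),
            ("observed_samples", self.observed_samples),
            ("interpolated_samples", self.interpolated_samples),
            ("interpolated_fraction", self.interpolated_fraction),
        ] + [(k, v) for k, v in self.samples_removed_by_rule.items()]
        return pd.DataFrame(rows, columns=["quantity", "value"])


class PipelineError(RuntimeError):
    """Raised when a preprocessing stage leaves nothing to analyse."""

    def __init__(self, msg, report: ExclusionReport | None = None):
        super().__init__(msg)
        self.report = report


# --- stage operations ------------------------------------------------------


def convert_au_to_mm(series: RawPupilSeries, config: PreprocessConfig) -> RawPupilSeries:
    """Convert tracker arbitrary units to mm; identity if already in mm."""
    config.validate()
    if series.unit == "mm":
        return series
    out = series.copy()
    if config.au_mode == "diameter":
        out.pupil = out.pupil / config.au_to_mm_scale
    else:
        out.pupil = 2.0 * np.sqrt(np.maximum(out.pupil, 0.0) / (config.au_to_mm_scale * np.pi))
    out.unit = "mm"
    return out


def missingness_fraction(series: RawPupilSeries) -> float:
    """Fraction of samples flagged invalid, before any interpolation."""
    if len(series.valid) == 0:
        raise ValueError("empty series")
    return float(np.mean(~series.valid))


def apply_exclusions(
    trials: list[RawPupilSeries], config: PreprocessConfig
) -> tuple[list[RawPupilSeries], ExclusionReport]:
    """Drop over-threshold participants, then over-threshold trials.

    Both rules use raw validity flags, before any interpolation, and are
    strictly 'greater than' (a trial or participant at exactly 30% is
    kept).  Participant-level missingness is the fraction of all that
    participant's samples that are missing; flagged participants lose
    all their trials, and the per-trial rule is then applied to the
    remaining participants' trials.
    """
    config.validate()
    report = ExclusionReport(
        n_trials_in=len(trials), n_samples_in=sum(len(t.pupil) for t in trials)
    )
    by_part: dict[int, list[RawPupilSeries]] = {}
    for t in trials:
        by_part.setdefault(t.participant_id, []).append(t)
    for p, ts in by_part.items():
        n_missing = sum(int(np.sum(~t.valid)) for t in ts)
        n_total = sum(len(t.valid) for t in ts)
        if n_total and n_missing / n_total > config.missing_participant_max:
            report.participants_excluded.append(p)
            report.trials_excluded_with_participants += len(ts)
    excluded = set(report.participants_excluded)
    kept = []
    for t in trials:
        if t.participant_id in excluded:
            continue
        if missingness_fraction(t) > config.missing_trial_max:
            report.trials_excluded_missing += 1
        else:
            kept.append(t)
    if not kept:
        raise PipelineError("all trials excluded by the missingness rule", report)
    return kept, report


def filter_implausible_samples(
    series: RawPupilSeries, config: PreprocessConfig, provenance: np.ndarray | None = None
) -> RawPupilSeries:
    """Remove out-of-range samples, then per-trial 3 SD outliers.

    Samples outside the plausible interval (default 2-8 mm) are set
    missing first; the trial mean and SD are then computed from the
    remaining valid samples and samples beyond mean +/- k*SD are removed.
    """
    config.validate()
    out = series.copy()
    lo, hi = config.plausible_mm
    with np.errstate(invalid="ignore"):
        bad_range = out.valid & ((out.pupil < lo) | (out.pupil > hi))
    out.valid &= ~bad_range
    out.pupil[bad_range] = np.nan
    remaining = out.pupil[out.valid]
    bad_sd = np.zeros_like(out.valid)
    if remaining.size:
        m, s = float(np.mean(remaining)), float(np.std(remaining))
        if s > 0:
            with np.errstate(invalid="ignore"):
                bad_sd = out.valid & (np.abs(out.pupil - m) > config.trial_sd_k * s)
            out.valid &= ~bad_sd
            out.pupil[bad_sd] = np.nan
    if provenance is not None:
        provenance[bad_range] = REMOVED_RANGE
        provenance[bad_sd] = REMOVED_SD
    return out


def _widen_invalid_runs(valid: np.ndarray, pad: int) -> np.ndarray:
    """Valid mask with every maximal invalid run widened by pad samples per side."""
    if pad == 0 or valid.all():
        return valid.copy()
    invalid = ~valid
    # binary dilation with a (2*pad + 1) window
    kernel = np.ones(2 * pad + 1, dtype=int)
    widened = np.convolve(invalid.astype(int), kernel, mode="same") > 0
    return ~widened


def extend_and_interpolate_blinks(
    series: RawPupilSeries, config: PreprocessConfig, provenance: np.ndarray | None = None
) -> RawPupilSeries:
    """Pad missing runs by blink_pad_ms per side, then linearly interpolate.

    Interior gaps are interpolated between the nearest valid anchors;
    runs at the series edges (only one anchor) are filled by nearest-value
    extension.  If no valid sample exists the series is returned
    unchanged (the trial is excluded downstream).
    """
    config.validate()
    out = series.copy()
    pad = int(round(config.blink_pad_ms / out.step_ms))
    new_valid = _widen_invalid_runs(out.valid, pad)
    out.pupil[~new_valid] = np.nan
    if not new_valid.any():
        out.valid = new_valid
        return out
    filled = ~new_valid
    out.pupil[filled] = np.interp(
        out.time_ms[filled], out.time_ms[new_valid], out.pupil[new_valid]
    )
    if provenance is not None:
        provenance[filled & (provenance == OBSERVED)] = INTERPOLATED
    out.valid = np.ones_like(out.valid)
    return out


def dilation_speed(pupil: np.ndarray, time_ms: np.ndarray) -> np.ndarray:
    """Per-sample dilation speed: max of backward and forward |slope|."""
    dt = np.diff(time_ms)
    slope = np.abs(np.diff(pupil)) / dt
    d = np.zeros_like(pupil)
    d[0] = slope[0]
    d[-1] = slope[-1]
    d[1:-1] = np.maximum(slope[:-1], slope[1:])
    return d


def mad_speed_filter(
    series: RawPupilSeries, config: PreprocessConfig, provenance: np.ndarray | None = None
) -> RawPupilSeries:
    """Remove rapid-dilation artifacts by a MAD threshold and re-interpolate.

    Threshold = median(d) + multiplier * MAD(d) over the trial's
    dilation-speed profile d; samples strictly above threshold are set
    missing (so a constant trial, where MAD = 0 and all d = 0, loses
    nothing) and refilled by linear interpolation.
    """
    config.validate()
    if len(series.pupil) < 3:
        raise ValueError("MAD speed filter needs at least 3 samples")
    out = series.copy()
    d = dilation_speed(out.pupil, out.time_ms)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    threshold = med + config.mad_multiplier * mad
    bad = d > threshold
    if provenance is not None:
        provenance[bad] = REMOVED_MAD
    if bad.any():
        good = ~bad
        if good.any():
            out.pupil[bad] = np.interp(out.time_ms[bad], out.time_ms[good], out.pupil[good])
    return out


def smooth_moving_average(series: RawPupilSeries, config: PreprocessConfig) -> RawPupilSeries:
    """Centered moving average, window shrinking at the series edges."""
    config.validate()
    if config.smooth_window > len(series.pupil):
        raise ValueError("smoothing window larger than series")
    out = series.copy()
    out.pupil = (
        pd.Series(out.pupil)
        .rolling(config.smooth_window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return out


def baseline_correct(
    series: RawPupilSeries,
    config: PreprocessConfig,
    provenance: np.ndarray | None = None,
) -> CleanTrial:
    """Subtract the pre-onset baseline (median over [-500, 0) ms by default).

    Raises
    ------
    PipelineError
        If the baseline window contains no usable samples.
    """
    config.validate()
    lo, hi = config.baseline_window_ms
    sel = (series.time_ms >= lo) & (series.time_ms < hi)
    vals = series.pupil[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise PipelineError(
            f"trial {series.participant_id}/{series.trial_id}: baseline window entirely missing"
        )
    stat = np.median if config.baseline_stat == "median" else np.mean
    baseline = float(stat(vals))
    if provenance is None:
        provenance = np.zeros(len(series.pupil), dtype=np.int8)
    return CleanTrial(
        participant_id=series.participant_id,
        trial_id=series.trial_id,
        condition=series.condition,
        time_ms=series.time_ms.copy(),
        pupil_mm=series.pupil - baseline,
        provenance=provenance,
        baseline_mm=baseline,
    )


def window_and_bin(trial: CleanTrial, config: PreprocessConfig) -> pd.DataFrame:
    """Partition the analysis window into bins and aggregate each bin.

    Bins are left-closed right-open; the bin value is the mean (or
    median) of the samples it contains.  Bins with no samples (e.g. a
    trial that ended early) are absent rather than zero-filled.
    """
    config.validate()
    lo, hi = config.analysis_window_ms
    sel = (trial.time_ms >= lo) & (trial.time_ms < hi) & ~np.isnan(trial.pupil_mm)
    t = trial.time_ms[sel]
    p = trial.pupil_mm[sel]
    idx = ((t - lo) // config.bin_ms).astype(int)
    agg = pd.Series(p).groupby(idx).median() if config.bin_stat == "median" else pd.Series(p).groupby(idx).mean()
    return pd.DataFrame(
        {
            "participant": trial.participant_id,
            "trial": trial.trial_id,
            "condition": trial.condition,
            "bin": agg.index.to_numpy(),
            "time_ms": lo + config.bin_ms * (agg.index.to_numpy() + 0.5),
            "pupil": agg.to_numpy(),
        }
    )


# --- full pipeline ---------------------------------------------------------


def preprocess_trial(
    series: RawPupilSeries, config: PreprocessConfig, report: ExclusionReport
) -> CleanTrial | None:
    """Stages 3-7 for one retained trial; None if the trial is unusable."""
    provenance = np.zeros(len(series.pupil), dtype=np.int8)
    provenance[~series.valid] = INTERPOLATED  # raw missing, to be filled
    t = filter_implausible_samples(series, config, provenance)
    t = extend_and_interpolate_blinks(t, config, provenance)
    if not t.valid.any() or np.isnan(t.pupil).all():
        report.trials_excluded_no_baseline += 1
        return None
    t = mad_speed_filter(t, config, provenance)
    t = smooth_moving_average(t, config)
    try:
        clean = baseline_correct(t, config, provenance)
    except PipelineError:
        report.trials_excluded_no_baseline += 1
        return None
    for code, key in ((REMOVED_RANGE, "removed-range"), (REMOVED_SD, "removed-sd"), (REMOVED_MAD, "removed-mad")):
        report.samples_removed_by_rule[key] += int(np.sum(provenance == code))
    report.interpolated_samples += int(np.sum(provenance == INTERPOLATED))
    report.observed_samples += int(np.sum(provenance == OBSERVED))
    return clean


def run_preprocessing(
    trials: list[RawPupilSeries], config: PreprocessConfig | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Run the full preprocessing pipeline over a dataset of trials.

    Returns the tidy binned-trial table (participant, trial, condition,
    bin, time_ms, pupil) and the aggregated exclusion report.
    """
    if config is None:
        config = PreprocessConfig()
    config.validate()
    converted = [convert_au_to_mm(t, config) for t in trials]
    kept, report = apply_exclusions(converted, config)
    frames = []
    for t in kept:
        clean = preprocess_trial(t, config, report)
        if clean is not None:
            frames.append(window_and_bin(clean, config))
            report.n_trials_out += 1
    if not frames:
        raise PipelineError("no trials survived preprocessing", report)
    return pd.concat(frames, ignore_index=True), report


class PupilPreprocessor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`run_preprocessing`.

    Parameters mirror :class:`PreprocessConfig`.  ``transform`` accepts a
    list of :class:`RawPupilSeries` and returns the binned-trial table;
    the exclusion report of the last transform is kept in ``report_``.
    """

    def __init__(
        self,
        au_to_mm_scale: float = 1000.0,
        au_mode: str = "diameter",
        missing_trial_max: float = 0.30,
        missing_participant_max: float = 0.30,
        plausible_mm: tuple = (2.0, 8.0),
        trial_sd_k: float = 3.0,
        blink_pad_ms: float = 100.0,
        mad_multiplier: float = 16.0,
        smooth_window: int = 5,
        baseline_window_ms: tuple = (-500.0, 0.0),
        baseline_stat: str = "median",
        analysis_window_ms: tuple = (0.0, 4200.0),
        bin_ms: float = 200.0,
        bin_stat: str = "mean",
    ):
        self.au_to_mm_scale = au_to_mm_scale
        self.au_mode = au_mode
        self.missing_trial_max = missing_trial_max
        self.missing_participant_max = missing_participant_max
        self.plausible_mm = plausible_mm
        self.trial_sd_k = trial_sd_k
        self.blink_pad_ms = blink_pad_ms
        self.mad_multiplier = mad_multiplier
        self.smooth_window = smooth_window
        self.baseline_window_ms = baseline_window_ms
        self.baseline_stat = baseline_stat
        self.analysis_window_ms = analysis_window_ms
        self.bin_ms = bin_ms
        self.bin_stat = bin_stat

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            au_to_mm_scale=self.au_to_mm_scale,
            au_mode=self.au_mode,
            missing_trial_max=self.missing_trial_max,
            missing_participant_max=self.missing_participant_max,
            plausible_mm=tuple(self.plausible_mm),
            trial_sd_k=self.trial_sd_k,
            blink_pad_ms=self.blink_pad_ms,
            mad_multiplier=self.mad_multiplier,
            smooth_window=self.smooth_window,
            baseline_window_ms=tuple(self.baseline_window_ms),
            baseline_stat=self.baseline_stat,
            analysis_window_ms=tuple(self.analysis_window_ms),
            bin_ms=self.bin_ms,
            bin_stat=self.bin_stat,
        )

    def fit(self, X, y=None):
        self._config().validate()
        self.n_trials_seen_ = len(X)
        return self

    def transform(self, X) -> pd.DataFrame:
        binned, report = run_preprocessing(list(X), self._config())
        self.report_ = report
        return binned
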