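"""Synthetic task-evoked pupillary response (TEPR) experiments.

Generates complete experiments — pupil sample streams plus behavioral
records — with known ground truth, so every downstream stage
(preprocessing, growth curve analysis, behavioral models) can be tested
for exact recovery without any external data.

The generating pupil trajectory is parameterized directly on the same
orthogonal polynomial basis used by the analysis model, evaluated at the
analysis bin midpoints and interpolated to the sample grid.  This makes
parameter recovery well-posed: the binned expectation of a simulated
trial is (up to a negligible within-bin averaging term) the generating
coefficient vector applied to the analysis basis.  Measurement noise is
stationary AR(1) at the sample rate; blinks, spikes, and dropout are
injected on top and flagged so filters can be validated against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .basis import PolyBasis, orthogonal_poly_basis
from .design import (
    CONDITIONS,
    ArtifactRates,
    DesignSpec,
    StimulusPair,
    condition_codes,
    generate_stimulus_set,
)

__all__ = [
    "RawPupilSeries",
    "SimulatedExperiment",
    "bin_midpoints",
    "trial_basis",
    "simulate_trial_pupil",
    "inject_artifacts",
    "simulate_behavior",
    "simulate_dataset",
    "simulate_binned_means",
    "behavior_truth_neg_inv_rt",
]


@dataclass
class RawPupilSeries:
    """One trial's timestamped pupil samples.

    ``time_ms`` is relative to word-pair onset (negative during the
    fixation epoch).  ``pupil`` is NaN exactly where ``valid`` is False
    (blinks and dropout read as missing, mirroring tracker output).
    ``truth`` retains the noiseless generating trajectory for recovery
    tests; it is never touched by artifact injection.
    """

    participant_id: int
    trial_id: int
    item_id: int
    condition: str
    time_ms: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray
    truth: np.ndarray | None = None
    unit: str = "mm"
    artifacts: dict | None = None  # injection log: blink_runs, spike_idx, dropout_idx

    def __post_init__(self):
        if len(self.time_ms) != len(self.pupil) or len(self.pupil) != len(self.valid):
            raise ValueError("time_ms, pupil, valid must have equal length")
        steps = np.diff(self.time_ms)
        if len(steps) and (steps.min() <= 0 or not np.allclose(steps, steps[0])):
            raise ValueError("time_ms must be strictly increasing with a constant step")

    @property
    def step_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    def copy(self) -> "RawPupilSeries":
        return replace(
            self,
            time_ms=self.time_ms.copy(),
            pupil=self.pupil.copy(),
            valid=self.valid.copy(),
            truth=None if self.truth is None else self.truth.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        d = dict(
            participant=self.participant_id,
            trial=self.trial_id,
            item=self.item_id,
            condition=self.condition,
            time_ms=self.time_ms,
            pupil=self.pupil,
            valid=self.valid,
        )
        if self.truth is not None:
            d["truth"] = self.truth
        return pd.DataFrame(d)


def bin_midpoints(spec_or_window, bin_ms: float | None = None) -> np.ndarray:
    """Midpoints of the analysis bins (left-closed, right-open partition)."""
    if isinstance(spec_or_window, DesignSpec):
        lo, hi = spec_or_window.analysis_window_ms
        bin_ms = spec_or_window.bin_ms
    else:
        lo, hi = spec_or_window
    n = int(np.ceil((hi - lo) / bin_ms))
    return lo + bin_ms * np.arange(n) + bin_ms / 2.0


def trial_basis(spec: DesignSpec) -> PolyBasis:
    """The analysis-grid orthogonal basis the generator parameterizes on."""
    return orthogonal_poly_basis(bin_midpoints(spec), order=spec.poly_order)


def _ar1(n: int, rho: float, sd: float, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Stationary AR(1) noise, shape (size, n); sd is the marginal SD."""
    if sd == 0:
        return np.zeros((size, n))
    e = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=(size, n))
    e[:, 0] = rng.normal(0.0, sd, size=size)
    return lfilter([1.0], [1.0, -rho], e, axis=1)


def draw_participant_effects(spec: DesignSpec, rng: np.random.Generator) -> dict:
    """Per-participant random effects for every term of the GCA structure."""
    return {k: float(rng.normal(0.0, spec.random_sd[k])) for k in spec.RANDOM_TERMS}


def _trajectory_coefficients(condition: str, spec: DesignSpec, effects: dict) -> tuple[np.ndarray, float]:
    """(time-term coefficient vector, constant condition shift) for one trial."""
    fe = np.asarray(spec.true_fixed_effects, dtype=float)
    ct, cs = condition_codes(condition)
    ci = ct * cs
    coef = fe[:, 0] + ct * fe[:, 1] + cs * fe[:, 2] + ci * fe[:, 3]
    coef = coef + np.array(
        [effects["intercept"], effects["poly1"], effects["poly2"], effects["poly3"]]
    )[: spec.poly_order + 1]
    shift = ct * effects["type"] + cs * effects["strength"] + ci * effects["type:strength"]
    return coef, shift


def simulate_trial_pupil(
    condition: str,
    spec: DesignSpec,
    participant_effects: dict,
    rng: np.random.Generator,
    baseline_mm: float | None = None,
    participant_id: int = 0,
    trial_id: int = 1,
    item_id: int = 0,
    basis: PolyBasis | None = None,
) -> RawPupilSeries:
    """Simulate one trial's noiseless truth and AR(1)-noised observation.

    During fixation (t < 0) the truth holds the participant's baseline
    level; from word-pair onset it follows baseline + basis(t) @ beta
    where beta combines the generating fixed effects (via the condition's
    sum codes) with the participant's random effects.  The pupil is a
    continuous physical quantity, so the last ``onset_ramp_ms`` of
    fixation ramp linearly from baseline into the trajectory's onset
    value.  Artifacts are not injected here; see :func:`inject_artifacts`.
    """
    if condition != "filler" and condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if baseline_mm is None:
        baseline_mm = spec.baseline_mm_mean
    if basis is None:
        basis = trial_basis(spec)
    n = spec.samples_per_trial
    time_ms = -spec.fixation_ms + spec.sample_step_ms * np.arange(n)
    coef, shift = _trajectory_coefficients(condition, spec, participant_effects)
    truth = np.full(n, baseline_mm, dtype=float)
    post = time_ms >= 0
    x = np.column_stack([np.ones(post.sum()), basis.evaluate(time_ms[post])])
    truth[post] += x @ coef + shift
    if spec.onset_ramp_ms > 0:
        onset_value = float(
            np.concatenate([[1.0], basis.evaluate(np.array([0.0]))[0]]) @ coef + shift
        )
        ramp = (time_ms < 0) & (time_ms >= -spec.onset_ramp_ms)
        truth[ramp] += onset_value * (1.0 + time_ms[ramp] / spec.onset_ramp_ms)
    pupil = truth + _ar1(n, spec.noise.rho, spec.noise.sd_mm, rng)[0]
    if spec.noise.trial_sd_mm > 0:
        # trial-level trajectory variability: per-bin draws, interpolated to the
        # sample grid, ramped in continuously like the trajectory itself
        mids = basis.times
        w = rng.normal(0.0, spec.noise.trial_sd_mm, len(mids))
        curve = np.zeros(n)
        curve[post] = np.interp(time_ms[post], mids, w)
        if spec.onset_ramp_ms > 0:
            ramp = (time_ms < 0) & (time_ms >= -spec.onset_ramp_ms)
            curve[ramp] = w[0] * (1.0 + time_ms[ramp] / spec.onset_ramp_ms)
        pupil = pupil + curve
    return RawPupilSeries(
        participant_id=participant_id,
        trial_id=trial_id,
        item_id=item_id,
        condition=condition,
        time_ms=time_ms,
        pupil=pupil,
        valid=np.ones(n, dtype=bool),
        truth=truth,
    )


def inject_artifacts(
    series: RawPupilSeries, rates: ArtifactRates, rng: np.random.Generator
) -> RawPupilSeries:
    """Inject blinks, spikes, and dropout into a pupil series.

    Blinks are contiguous runs flagged invalid (pupil set missing) with
    Poisson-count onsets and uniform durations; spikes are isolated valid
    samples offset by +/- ``spike_amp_mm``; dropout flags independent
    single samples invalid.  The stored truth trajectory is unchanged.
    """
    rates.validate()
    out = series.copy()
    out.truth = None if series.truth is None else series.truth.copy()
    n = len(out.pupil)
    step = out.step_ms
    dur_s = n * step / 1000.0
    log = {"blink_runs": [], "spike_idx": [], "dropout_idx": []}

    n_blinks = rng.poisson(rates.blink_rate_per_s * dur_s)
    for _ in range(n_blinks):
        dur = rng.uniform(*rates.blink_dur_ms)
        length = max(1, int(round(dur / step)))
        start = int(rng.integers(0, max(1, n - length)))
        out.valid[start : start + length] = False
        log["blink_runs"].append((start, length))

    n_spikes = rng.poisson(rates.spike_rate_per_s * dur_s)
    if n_spikes > 0:
        pos = rng.choice(n, size=min(n_spikes, n), replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(pos))
        out.pupil[pos] += signs * rates.spike_amp_mm
        log["spike_idx"] = sorted(int(i) for i in pos)

    if rates.dropout_prob > 0:
        drop = rng.random(n) < rates.dropout_prob
        out.valid &= ~drop
        log["dropout_idx"] = list(np.flatnonzero(drop))

    out.pupil[~out.valid] = np.nan
    out.artifacts = log
    return out


# --- behavior --------------------------------------------------------------


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _behavior_trial(
    spec: DesignSpec,
    condition: str,
    p_rt: float,
    p_acc: float,
    i_rt: float,
    i_acc: float,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """One trial's (rt_ms, accuracy) given participant/item intercepts."""
    b = spec.behavior
    ct, cs = condition_codes(condition)
    if condition == "filler":
        mu = b.rt_meanlog + p_rt + i_rt
        logit = b.filler_acc_logit_intercept + p_acc + i_acc
    else:
        mu = (
            b.rt_meanlog
            + p_rt
            + i_rt
            + ct * b.rt_condition_shifts["type"]
            + cs * b.rt_condition_shifts["strength"]
            + ct * cs * b.rt_condition_shifts["type:strength"]
        )
        logit = (
            b.acc_logit_intercept
            + p_acc
            + i_acc
            + ct * b.acc_logit_effects["type"]
            + cs * b.acc_logit_effects["strength"]
            + ct * cs * b.acc_logit_effects["type:strength"]
        )
    rt = b.rt_shift_ms + float(np.exp(rng.normal(mu, b.rt_sdlog)))
    acc = int(rng.random() < _logistic(logit))
    return rt, acc


def _item_table(spec: DesignSpec, stimuli: list[StimulusPair] | None = None) -> pd.DataFrame:
    """Item grid: one row per word pair with condition labels."""
    if stimuli is not None:
        conds = [s.label for s in stimuli]
        words = [(s.word_a, s.word_b) for s in stimuli]
    else:
        conds = [c for c in CONDITIONS for _ in range(spec.n_items_per_cell)]
        conds += ["filler"] * spec.n_fillers
        words = [("", "")] * len(conds)
    rows = []
    for i, c in enumerate(conds):
        if c == "filler":
            sem_type = strength = "filler"
        else:
            strength, sem_type = c.split("-")
        rows.append((i, c, sem_type, strength, words[i][0], words[i][1]))
    return pd.DataFrame(
        rows, columns=["item", "condition", "sem_type", "strength", "word_a", "word_b"]
    )


def simulate_behavior(
    spec: DesignSpec,
    rng: np.random.Generator,
    items: pd.DataFrame | None = None,
    item_effects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate RT/accuracy records for all participants and items.

    Reaction times are shifted lognormal with condition shifts plus
    participant and item intercepts on the log scale; accuracy is
    Bernoulli with logistic condition effects plus participant and item
    intercepts.  Returns a tidy frame with one row per participant x item.
    """
    spec.validate()
    if items is None:
        items = _item_table(spec)
    if item_effects is None:
        item_effects = draw_item_effects(spec, items, rng)
    rows = []
    for p in range(spec.n_participants):
        p_rt = rng.normal(0.0, spec.behavior.rt_participant_sdlog)
        p_acc = rng.normal(0.0, spec.behavior.acc_participant_sd)
        for it in items.itertuples(index=False):
            i_rt = item_effects.rt_intercept.iloc[it.item]
            i_acc = item_effects.acc_intercept.iloc[it.item]
            rt, acc = _behavior_trial(spec, it.condition, p_rt, p_acc, i_rt, i_acc, rng)
            rows.append((p, it.item, it.condition, it.sem_type, it.strength, rt, acc))
    return pd.DataFrame(
        rows,
        columns=["participant", "item", "condition", "sem_type", "strength", "rt_ms", "accuracy"],
    )


def draw_item_effects(
    spec: DesignSpec, items: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    b = spec.behavior
    return pd.DataFrame(
        {
            "item": items["item"].to_numpy(),
            "rt_intercept": rng.normal(0.0, b.rt_item_sdlog, len(items)),
            "acc_intercept": rng.normal(0.0, b.acc_item_sd, len(items)),
        }
    )


# --- full experiments ------------------------------------------------------


@dataclass
class SimulatedExperiment:
    """A complete synthetic experiment with its generating truth."""

    spec: DesignSpec
    stimuli: list[StimulusPair]
    items: pd.DataFrame
    pupil: list[RawPupilSeries]
    behavior: pd.DataFrame
    participants: pd.DataFrame = field(repr=False)  # truth: random effects per participant
    item_effects: pd.DataFrame = field(repr=False)

    def samples_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.pupil], ignore_index=True)

    def binned_truth(self, smooth_window: int | None = 5) -> pd.DataFrame:
        """Expected noiseless pipeline output: truth bins per trial.

        The noiseless trajectory is passed through the pipeline's
        deterministic value-preserving stages — the centered moving
        average (``smooth_window``; None skips it), subtractive baseline
        correction, and 200 ms binning — so the result is exactly what
        preprocessing should produce on artifact- and noise-free input.
        Pass ``smooth_window=None`` for the raw binned trajectory.
        """
        spec = self.spec
        lo, hi = spec.analysis_window_ms
        rows = []
        for s in self.pupil:
            truth = s.truth
            if smooth_window:
                truth = (
                    pd.Series(truth)
                    .rolling(smooth_window, center=True, min_periods=1)
                    .mean()
                    .to_numpy()
                )
            sel = (s.time_ms >= lo) & (s.time_ms < hi)
            base_sel = (s.time_ms >= -500.0) & (s.time_ms < 0.0)
            baseline = float(np.median(truth[base_sel]))
            idx = ((s.time_ms[sel] - lo) // spec.bin_ms).astype(int)
            vals = np.bincount(idx, weights=truth[sel] - baseline) / np.bincount(idx)
            for b, v in enumerate(vals):
                rows.append((s.participant_id, s.trial_id, s.condition, b, lo + spec.bin_ms * (b + 0.5), v))
        return pd.DataFrame(
            rows, columns=["participant", "trial", "condition", "bin", "time_ms", "pupil"]
        )


def simulate_dataset(spec: DesignSpec, with_artifacts: bool = True) -> SimulatedExperiment:
    """Generate a full synthetic experiment deterministically from spec.seed.

    A master seed sequence spawns independent child streams for the
    stimulus set, item effects, and each participant, so any participant
    subset is reproducible in isolation.
    """
    spec.validate()
    master = np.random.SeedSequence(spec.seed)
    ss_stim, ss_items, *ss_parts = master.spawn(2 + spec.n_participants)
    stim_rng = np.random.default_rng(ss_stim)
    stimuli = generate_stimulus_set(spec, stim_rng)
    items = _item_table(spec, stimuli)
    item_effects = draw_item_effects(spec, items, np.random.default_rng(ss_items))
    basis = trial_basis(spec)

    pupil: list[RawPupilSeries] = []
    behavior_rows = []
    part_rows = []
    for p, ss in enumerate(ss_parts):
        rng = np.random.default_rng(ss)
        baseline = float(rng.normal(spec.baseline_mm_mean, spec.baseline_mm_sd))
        effects = draw_participant_effects(spec, rng)
        p_rt = rng.normal(0.0, spec.behavior.rt_participant_sdlog)
        p_acc = rng.normal(0.0, spec.behavior.acc_participant_sd)
        part_rows.append(
            dict(participant=p, baseline_mm=baseline, rt_intercept=p_rt, acc_intercept=p_acc, **{f"b_{k}": v for k, v in effects.items()})
        )
        order = rng.permutation(len(items))
        for t_pos, item_idx in enumerate(order, start=1):
            it = items.iloc[int(item_idx)]
            item_id = int(it["item"])
            cond = str(it["condition"])
            series = simulate_trial_pupil(
                cond,
                spec,
                effects,
                rng,
                baseline_mm=baseline,
                participant_id=p,
                trial_id=t_pos,
                item_id=item_id,
                basis=basis,
            )
            if with_artifacts:
                series = inject_artifacts(series, spec.artifact_rates, rng)
            pupil.append(series)
            i_rt = item_effects.rt_intercept.iloc[item_id]
            i_acc = item_effects.acc_intercept.iloc[item_id]
            rt, acc = _behavior_trial(spec, cond, p_rt, p_acc, i_rt, i_acc, rng)
            behavior_rows.append(
                (p, item_id, t_pos, cond, it["sem_type"], it["strength"], rt, acc)
            )
    behavior = pd.DataFrame(
        behavior_rows,
        columns=["participant", "item", "trial", "condition", "sem_type", "strength", "rt_ms", "accuracy"],
    )
    return SimulatedExperiment(
        spec=spec,
        stimuli=stimuli,
        items=items,
        pupil=pupil,
        behavior=behavior,
        participants=pd.DataFrame(part_rows),
        item_effects=item_effects,
    )


def simulate_binned_means(spec: DesignSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Fast path: participant x condition x bin mean dilation trajectories.

    Generates exactly the trajectory + AR(1) sample-noise model of
    :func:`simulate_trial_pupil` for the experimental trials, but skips
    fixation, artifacts, and baseline estimation, and aggregates straight
    to the participant-by-condition bin means the growth curve model is
    fitted on.  Used for simulation studies (parameter recovery), where
    generating full sample streams for every replicate is unnecessary.
    """
    spec.validate()
    mids = bin_midpoints(spec)
    basis = trial_basis(spec)
    step = spec.sample_step_ms
    lo, hi = spec.analysis_window_ms
    n_samp = int(round((hi - lo) / step))
    per_bin = n_samp // len(mids)
    x_mid = np.column_stack([np.ones(len(mids)), basis.columns])
    rows = []
    for p in range(spec.n_participants):
        effects = draw_participant_effects(spec, rng)
        for cond in CONDITIONS:
            coef, shift = _trajectory_coefficients(cond, spec, effects)
            truth_mid = x_mid @ coef + shift
            noise = _ar1(n_samp, spec.noise.rho, spec.noise.sd_mm, rng, size=spec.n_items_per_cell)
            bin_noise = noise.reshape(spec.n_items_per_cell, len(mids), per_bin).mean(axis=2).mean(axis=0)
            if spec.noise.trial_sd_mm > 0:
                bin_noise = bin_noise + rng.normal(
                    0.0, spec.noise.trial_sd_mm, (spec.n_items_per_cell, len(mids))
                ).mean(axis=0)
            strength, sem_type = cond.split("-")
            for b, (m, v) in enumerate(zip(mids, truth_mid + bin_noise)):
                rows.append((p, cond, sem_type, strength, b, m, v))
    return pd.DataFrame(
        rows,
        columns=["participant", "condition", "sem_type", "strength", "bin", "time_ms", "pupil"],
    )


def behavior_truth_neg_inv_rt(spec: DesignSpec, n_mc: int = 200_000, seed: int = 0) -> dict:
    """Monte-Carlo truth for the RT model coefficients on the -1000/rt scale.

    The generator's condition shifts act on log RT, so the implied fixed
    effects on the analysis scale are not available in closed form; this
    evaluates the marginal cell means of -1000/rt by simulation and
    converts them to sum-coded model coefficients.
    """
    rng = np.random.default_rng(seed)
    b = spec.behavior
    cell_means = {}
    for cond in CONDITIONS:
        ct, cs = condition_codes(cond)
        mu = (
            b.rt_meanlog
            + ct * b.rt_condition_shifts["type"]
            + cs * b.rt_condition_shifts["strength"]
            + ct * cs * b.rt_condition_shifts["type:strength"]
        )
        total_sd = np.sqrt(b.rt_sdlog**2 + b.rt_participant_sdlog**2 + b.rt_item_sdlog**2)
        rt = b.rt_shift_ms + np.exp(rng.normal(mu, total_sd, n_mc))
        cell_means[cond] = float(np.mean(-1000.0 / rt))
    x = np.array([[1, *condition_codes(c), condition_codes(c)[0] * condition_codes(c)[1]] for c in CONDITIONS], dtype=float)
    y = np.array([cell_means[c] for c in CONDITIONS])
    beta = np.linalg.lstsq(x, y, rcond=None)[0]
    return {"Intercept": beta[0], "type": beta[1], "strength": beta[2], "type:strength": beta[3]}
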