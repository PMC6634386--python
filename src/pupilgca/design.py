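"""Experimental design: the 2x2 semantic relatedness judgement task.

The task crosses semantic relation type (taxonomic: shared features or
category membership, e.g. dog-wolf; thematic: co-occurrence in events,
e.g. dog-leash) with relatedness strength (high vs. low), plus unrelated
filler pairs.  Word pairs are characterised by taxonomic-similarity and
thematic-relatedness ratings on a 1-7 scale, and assigned to cells by
fixed screening windows on those ratings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SEM_TYPES",
    "STRENGTHS",
    "CONDITIONS",
    "Ar1Noise",
    "ArtifactRates",
    "BehaviorParams",
    "DesignSpec",
    "StimulusPair",
    "CodedFactor",
    "classify_pair",
    "sum_code",
    "condition_codes",
    "generate_stimulus_set",
]

SEM_TYPES = ("taxonomic", "thematic")
STRENGTHS = ("high", "low")
CONDITIONS = (
    "high-taxonomic",
    "low-taxonomic",
    "high-thematic",
    "low-thematic",
)

#: classification windows on the 1-7 rating scale
RATING_MIN, RATING_MAX = 1.0, 7.0
HIGH_DIFF_MIN = 1.75          # rating difference for a distinctive (high) pair
HIGH_NONDOMINANT_MAX = 3.5    # the non-dominant relation must be weak
LOW_DOMINANT_MAX = 4.5        # low pairs have a weaker dominant relation
LOW_DIFF_RANGE = (0.5, 1.75)  # still dichotomous, but less so


def classify_pair(taxonomic_rating: float, thematic_rating: float) -> str:
    """Assign a word pair to a design cell from its two ratings.

    High-strength pairs show a clear dichotomy (rating difference
    > 1.75) with a weak non-dominant relation (<= 3.5).  Low-strength
    pairs have a weaker dominant relation (<= 4.5) and a difference in
    [0.5, 1.75].  The dominant dimension is whichever rating is larger.

    Returns one of ``high-taxonomic``, ``low-taxonomic``,
    ``high-thematic``, ``low-thematic``, or ``unclassifiable``.

    Raises
    ------
    ValueError
        If either rating lies outside [1, 7].
    """
    for name, r in (("taxonomic", taxonomic_rating), ("thematic", thematic_rating)):
        if not (RATING_MIN <= r <= RATING_MAX):
            raise ValueError(f"{name} rating {r} outside [{RATING_MIN}, {RATING_MAX}]")
    diff = abs(taxonomic_rating - thematic_rating)
    if taxonomic_rating >= thematic_rating:
        dominant, nondom, dim = taxonomic_rating, thematic_rating, "taxonomic"
    else:
        dominant, nondom, dim = thematic_rating, taxonomic_rating, "thematic"
    if diff > HIGH_DIFF_MIN and nondom <= HIGH_NONDOMINANT_MAX:
        return f"high-{dim}"
    if dominant <= LOW_DOMINANT_MAX and LOW_DIFF_RANGE[0] <= diff <= LOW_DIFF_RANGE[1]:
        return f"low-{dim}"
    return "unclassifiable"


@dataclass(frozen=True)
class StimulusPair:
    """A word pair with its semantic norms and design-cell label."""

    word_a: str
    word_b: str
    taxonomic_rating: float
    thematic_rating: float
    label: str  # a condition, "filler", or "unclassifiable"


@dataclass(frozen=True)
class CodedFactor:
    """A two-level factor sum-coded as +1 / -1.

    Sum coding evaluates main effects at the factorial average: with a
    balanced design each coded column sums to zero, and the interaction
    code is the elementwise product of the main-effect codes.
    """

    name: str
    levels: tuple[str, str]
    codes: dict[str, int]

    def code(self, values) -> np.ndarray:
        return np.asarray([self.codes[v] for v in np.asarray(values, dtype=object)])


def sum_code(name: str, levels) -> CodedFactor:
    """Sum-code a two-level factor: first level +1, second level -1."""
    levels = tuple(levels)
    if len(levels) != 2:
        raise ValueError(f"sum coding requires exactly 2 levels, got {len(levels)}")
    return CodedFactor(name=name, levels=levels, codes={levels[0]: 1, levels[1]: -1})


#: package-wide coding convention (documented in docs/methods.md)
TYPE_FACTOR = sum_code("type", SEM_TYPES)       # taxonomic +1, thematic -1
STRENGTH_FACTOR = sum_code("strength", STRENGTHS)  # high +1, low -1


def condition_codes(condition: str) -> tuple[int, int]:
    """(type_code, strength_code) for a condition label; (0, 0) for fillers."""
    if condition == "filler":
        return (0, 0)
    strength, sem_type = condition.split("-")
    return (TYPE_FACTOR.codes[sem_type], STRENGTH_FACTOR.codes[strength])


@dataclass
class Ar1Noise:
    """Within-trial noise: AR(1) sample noise plus trial-level variability.

    ``rho``/``sd_mm`` parameterize stationary AR(1) measurement noise at
    the sample rate.  ``trial_sd_mm`` is trial-to-trial variability of
    the response trajectory, drawn independently per 200 ms analysis bin
    — the component that dominates the standard errors of the
    polynomial-by-condition terms in real task-evoked pupil data.
    """

    rho: float = 0.99
    sd_mm: float = 0.05
    trial_sd_mm: float = 0.35


@dataclass
class ArtifactRates:
    """Rates for the artifact classes the preprocessing pipeline removes."""

    blink_rate_per_s: float = 0.2
    blink_dur_ms: tuple[float, float] = (100.0, 300.0)
    spike_rate_per_s: float = 0.5
    spike_amp_mm: float = 1.0
    dropout_prob: float = 0.002

    def validate(self) -> None:
        for f in ("blink_rate_per_s", "spike_rate_per_s", "spike_amp_mm", "dropout_prob"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        lo, hi = self.blink_dur_ms
        if not (0 < lo <= hi):
            raise ValueError("blink_dur_ms must be a positive (low, high) range")


@dataclass
class BehaviorParams:
    """Generating model for per-trial reaction times and accuracy.

    Reaction times follow a shifted lognormal,
    ``rt = shift + exp(meanlog + participant + item + condition + eps)``,
    a standard positively skewed latency family.  Condition shifts are on
    the log scale; defaults were chosen so that the implied contrasts on
    the analysis scale (-1000/rt) match the magnitude of the reported
    behavioral effects.  Accuracy is Bernoulli with a logistic model on
    sum-coded condition effects plus participant and item intercepts.
    """

    rt_shift_ms: float = 200.0
    rt_meanlog: float = 7.0          # exp(7.0) ~ 1097 ms above the shift
    rt_sdlog: float = 0.25
    rt_participant_sdlog: float = 0.15
    rt_item_sdlog: float = 0.08
    # log-scale shifts per +1 unit of the sum code (taxonomic +1, high +1)
    rt_condition_shifts: dict = field(
        default_factory=lambda: {"type": 0.062, "strength": -0.074, "type:strength": 0.0}
    )
    acc_logit_intercept: float = 2.2  # ~90% correct overall
    acc_logit_effects: dict = field(
        default_factory=lambda: {"type": -0.202, "strength": 0.422, "type:strength": 0.0}
    )
    acc_participant_sd: float = 0.5
    acc_item_sd: float = 0.4
    filler_acc_logit_intercept: float = 2.6  # unrelated pairs are easier to reject


def _default_fixed_effects() -> np.ndarray:
    # rows: intercept, poly1 (linear), poly2 (quadratic), poly3 (cubic)
    # cols: overall, type (taxonomic +1), strength (high +1), type:strength
    return np.array(
        [
            [0.06, 0.000, 0.000, 0.000],
            [0.12, 0.010, -0.019, -0.018],
            [-0.07, -0.010, -0.014, -0.018],
            [0.01, 0.010, 0.004, 0.000],
        ]
    )


def _default_random_sd() -> dict:
    return {
        "intercept": 0.08,
        "poly1": 0.23,
        "poly2": 0.15,
        "poly3": 0.12,
        "type": 0.05,
        "strength": 0.05,
        "type:strength": 0.05,
    }


@dataclass
class DesignSpec:
    """Complete specification of a simulated experiment.

    Defaults reproduce the study conditions: 60 participants, 128 trials
    each (16 per experimental cell + 64 fillers), monocular 250 Hz
    sampling, a 1000 ms fixation epoch before word-pair onset, and
    response windows analysed out to 4200 ms.  ``true_fixed_effects`` is
    the 4x4 grid of generating coefficients (time terms x effect terms,
    mm on the unit-norm orthogonal basis); defaults are the reported
    pupillary effect sizes with the package's sign convention.
    """

    n_participants: int = 60
    n_items_per_cell: int = 16
    n_fillers: int = 64
    sampling_rate: float = 250.0
    fixation_ms: float = 1000.0
    onset_ramp_ms: float = 200.0  # continuous pre-onset transition into the response
    trial_max_ms: float = 5200.0
    analysis_window_ms: tuple[float, float] = (0.0, 4200.0)
    bin_ms: float = 200.0
    poly_order: int = 3
    true_fixed_effects: np.ndarray = field(default_factory=_default_fixed_effects)
    random_sd: dict = field(default_factory=_default_random_sd)
    baseline_mm_mean: float = 4.5
    baseline_mm_sd: float = 0.4
    noise: Ar1Noise = field(default_factory=Ar1Noise)
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    seed: int = 1234

    RANDOM_TERMS = ("intercept", "poly1", "poly2", "poly3", "type", "strength", "type:strength")

    @property
    def trials_per_participant(self) -> int:
        return 4 * self.n_items_per_cell + self.n_fillers

    @property
    def sample_step_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_max_ms / self.sample_step_ms))

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_items_per_cell < 1 or self.n_fillers < 0:
            raise ValueError("participant/item counts must be positive (fillers >= 0)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.fixation_ms <= 0 or self.trial_max_ms <= self.fixation_ms:
            raise ValueError("trial_max_ms must exceed fixation_ms > 0")
        if not (0 <= self.onset_ramp_ms <= self.fixation_ms):
            raise ValueError("onset_ramp_ms must lie within the fixation epoch")
        fe = np.asarray(self.true_fixed_effects, dtype=float)
        if fe.shape != (self.poly_order + 1, 4):
            raise ValueError(
                f"true_fixed_effects must be ({self.poly_order + 1}, 4): "
                "time terms x (overall, type, strength, type:strength)"
            )
        missing = [k for k in self.RANDOM_TERMS if k not in self.random_sd]
        if missing:
            raise ValueError(f"random_sd missing terms: {missing}")
        if any(v < 0 for v in self.random_sd.values()):
            raise ValueError("random-effect SDs must be >= 0")
        if self.noise.sd_mm < 0 or self.noise.trial_sd_mm < 0 or not (0 <= self.noise.rho < 1):
            raise ValueError("noise requires sd_mm, trial_sd_mm >= 0 and rho in [0, 1)")
        self.artifact_rates.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_fixed_effects"] = np.asarray(self.true_fixed_effects).tolist()
        return d


# --- stimulus generation ---------------------------------------------------

#: rating means/SDs per cell used by the rejection sampler (taxonomic, thematic),
#: taken from the stimulus norms of the emulated study
_CELL_RATING_PARAMS = {
    "high-taxonomic": ((5.11, 0.48), (3.05, 0.386)),
    "low-taxonomic": ((3.61, 0.345), (2.51, 0.354)),
    "high-thematic": ((2.59, 0.572), (4.87, 0.537)),
    "low-thematic": ((2.19, 0.749), (4.04, 0.309)),
}
_FILLER_RATING_PARAMS = ((1.6, 0.35), (1.6, 0.35))

def _pseudo_word(rng: np.random.Generator) -> str:
    cons = "bcdfghklmnprstvz"
    vow = "aeiou"
    n = int(rng.integers(2, 4))
    return "".join(
        cons[int(rng.integers(len(cons)))] + vow[int(rng.integers(len(vow)))]
        for _ in range(n)
    )


def generate_stimulus_set(
    spec: DesignSpec, rng: np.random.Generator, max_attempts: int = 10_000
) -> list[StimulusPair]:
    """Generate a stimulus list satisfying the cell-classification windows.

    Ratings are rejection-sampled from per-cell normal distributions
    (matched to the emulated norms) until ``classify_pair`` assigns the
    pair to the intended cell; filler pairs get low ratings on both
    dimensions and are not classified.

    Raises
    ------
    RuntimeError
        If a cell cannot be filled within ``max_attempts`` draws.
    """
    spec.validate()
    pairs: list[StimulusPair] = []
    for cell, ((mt, st), (mh, sh)) in _CELL_RATING_PARAMS.items():
        got = 0
        for _ in range(max_attempts):
            if got == spec.n_items_per_cell:
                break
            tax = float(np.clip(rng.normal(mt, st), RATING_MIN, RATING_MAX))
            them = float(np.clip(rng.normal(mh, sh), RATING_MIN, RATING_MAX))
            if classify_pair(tax, them) == cell:
                pairs.append(
                    StimulusPair(_pseudo_word(rng), _pseudo_word(rng), tax, them, cell)
                )
                got += 1
        if got < spec.n_items_per_cell:
            raise RuntimeError(
                f"could not generate {spec.n_items_per_cell} pairs for cell {cell} "
                f"within {max_attempts} attempts"
            )
    (mt, st), (mh, sh) = _FILLER_RATING_PARAMS
    got = 0
    for _ in range(max_attempts):
        if got == spec.n_fillers:
            break
        tax = float(np.clip(rng.normal(mt, st), RATING_MIN, RATING_MAX))
        them = float(np.clip(rng.normal(mh, sh), RATING_MIN, RATING_MAX))
        # fillers must not fall into any experimental window
        if classify_pair(tax, them) == "unclassifiable":
            pairs.append(StimulusPair(_pseudo_word(rng), _pseudo_word(rng), tax, them, "filler"))
            got += 1
    if got < spec.n_fillers:
        raise RuntimeError(f"could not generate {spec.n_fillers} filler pairs")
    return pairs
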