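"""Experiment designs and generative observer parameters.

The package targets a two-rubber-hand psychophysics paradigm: on every trial
one hand is tapped synchronously with the participant's hidden real hand and
the other at one of several visuotactile asynchronies.  The participant makes
a 2AFC body-ownership judgement ("which hand feels like mine?") followed by a
3-point Perceptual Awareness Scale (PAS) clarity rating.  Three experiment
templates are provided:

``exp1``
    five asynchronies (18, 31, 52, 88, 150 ms), 6 touches in 12 s,
    300 trials (six blocks of 60).
``exp2``
    adds a number-of-touches factor (3, 6, 9 touches).
``exp3``
    speeded variant: stimulation up to 30 s, responses as soon as ownership
    is detected, 480 trials; analysed with drift-diffusion models.
``control1``
    rotated-hands control: ownership abolished, sensitivity at chance.
``control2``
    wooden-block simultaneity judgement control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

__all__ = [
    "DesignSpec",
    "SDTObserverParams",
    "DDMObserverParams",
    "QuestionnaireScores",
    "ConfigurationError",
    "design_for_template",
    "sdt_params_for_template",
    "ddm_params_for_template",
    "TEMPLATES",
]

TEMPLATES = ("exp1", "exp2", "exp3", "control1", "control2")

#: Default generative type-1 sensitivity (2AFC d') per asynchrony in ms.
#: Chosen to mirror the empirical pattern of the paradigm: near-chance at
#: 18 ms, clearly above chance from ~30 ms, saturating towards d' ~ 1.7.
DEFAULT_DPRIME_BY_ASYNC = {18: 0.10, 31: 0.45, 52: 0.80, 88: 1.30, 150: 1.70}

#: Metacognitive efficiency typical for this paradigm (raw M-ratios cluster
#: in the 0.6-0.8 range).
DEFAULT_MRATIO = 0.7

#: Multiplicative gain of d' per number of touches (evidence accumulates with
#: repeated visuotactile stimulation; 6 touches is the reference condition).
DEFAULT_TOUCH_GAIN = {3: 0.65, 6: 1.0, 9: 1.15}


class ConfigurationError(ValueError):
    """Raised when a design/parameter combination violates its contract."""


class ValidationError(ValueError):
    """Raised when input data violate the documented schema."""


@dataclass(frozen=True)
class DesignSpec:
    """Trial-structure description of one experiment session.

    Parameters
    ----------
    asynchrony_levels_ms
        Strictly increasing visuotactile asynchronies in milliseconds.
    touches_levels
        Numbers of touches used to induce the illusion (one entry unless the
        design crosses asynchrony with touches).
    trials_per_condition
        Trials in each asynchrony x touches cell.
    n_subjects
        Number of simulated participants.
    speeded
        Speeded response mode: trials end at the 2AFC response and
        first-passage times are recorded (drift-diffusion analysis).
    max_stim_duration_s
        Stimulation ceiling in seconds; speeded trials that have not
        terminated by then are censored.
    seed
        Base seed for reproducible simulation.
    """

    asynchrony_levels_ms: tuple = (18, 31, 52, 88, 150)
    touches_levels: tuple = (6,)
    trials_per_condition: int = 60
    n_subjects: int = 32
    speeded: bool = False
    max_stim_duration_s: float = 12.0
    seed: int = 0

    def __post_init__(self):
        asyncs = tuple(self.asynchrony_levels_ms)
        touches = tuple(self.touches_levels)
        object.__setattr__(self, "asynchrony_levels_ms", asyncs)
        object.__setattr__(self, "touches_levels", touches)
        if any(a <= 0 for a in asyncs) or list(asyncs) != sorted(set(asyncs)):
            raise ConfigurationError(
                "asynchrony_levels_ms must be positive and strictly increasing"
            )
        if any(t <= 0 for t in touches):
            raise ConfigurationError("touches_levels must be positive")
        if self.trials_per_condition <= 0 or self.n_subjects <= 0:
            raise ConfigurationError("trials_per_condition and n_subjects must be positive")
        if self.max_stim_duration_s <= 0:
            raise ConfigurationError("max_stim_duration_s must be positive")

    @property
    def conditions(self):
        """All (asynchrony_ms, n_touches) cells in design order."""
        return [
            (a, t) for t in self.touches_levels for a in self.asynchrony_levels_ms
        ]

    @property
    def n_trials_total(self) -> int:
        return self.trials_per_condition * len(self.conditions)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["asynchrony_levels_ms"] = list(self.asynchrony_levels_ms)
        d["touches_levels"] = list(self.touches_levels)
        return d


@dataclass(frozen=True)
class SDTObserverParams:
    """Generative parameters of the equal-variance SDT observer.

    ``dprime_by_condition`` maps an (asynchrony_ms, n_touches) cell to the
    true 2AFC sensitivity.  The confidence (PAS) report is produced from a
    second evidence sample carrying extra metacognitive noise calibrated so
    the observer's effective type-2 sensitivity is ``mratio_true`` times the
    type-1 sensitivity.
    """

    dprime_by_condition: Mapping = field(default_factory=dict)
    criterion_c: float = 0.0
    mratio_true: float = DEFAULT_MRATIO
    type2_criteria: tuple = (0.5, 1.2)
    lapse_rate: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "type2_criteria", tuple(self.type2_criteria))
        t1, t2 = self.type2_criteria
        if not (0 < t1 < t2):
            raise ConfigurationError("type2_criteria must be positive and ordered")
        if self.mratio_true <= 0:
            raise ConfigurationError("mratio_true must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ConfigurationError("lapse_rate must lie in [0, 1]")
        if any(d < 0 for d in dict(self.dprime_by_condition).values()):
            raise ConfigurationError("d' values must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "dprime_by_condition": {str(k): v for k, v in dict(self.dprime_by_condition).items()},
            "criterion_c": self.criterion_c,
            "mratio_true": self.mratio_true,
            "type2_criteria": list(self.type2_criteria),
            "lapse_rate": self.lapse_rate,
        }


@dataclass(frozen=True)
class DDMObserverParams:
    """Generative parameters of the diffusion observer (scale s = 1).

    Decision stage: Wiener process with drift ``drift_by_condition[cond]``
    (signed toward the boundary of the synchronously tapped hand), boundary
    separation ``boundary``, relative start point ``start_point`` and
    nondecision time ``nondecision_t0``.  After the boundary is hit, evidence
    keeps accumulating for ``postdecision_duration`` seconds with drift
    ``postdecision_drift`` (same stimulus-defined sign); the terminal
    post-decisional evidence, measured toward the chosen boundary, is cut at
    ``confidence_cutpoints`` into PAS 1/2/3.
    """

    drift_by_condition: Mapping = field(default_factory=dict)
    boundary: float = 1.6
    start_point: float = 0.5
    nondecision_t0: float = 0.35
    postdecision_drift: float = 1.0
    postdecision_duration: float = 1.0
    confidence_cutpoints: tuple = (-0.2, 0.8)
    diffusion_scale: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "confidence_cutpoints", tuple(self.confidence_cutpoints))
        if self.boundary <= 0:
            raise ConfigurationError("boundary must be positive")
        if not 0.0 < self.start_point < 1.0:
            raise ConfigurationError("start_point must lie in (0, 1)")
        if self.nondecision_t0 < 0:
            raise ConfigurationError("nondecision_t0 must be nonnegative")
        if self.postdecision_duration <= 0:
            raise ConfigurationError("postdecision_duration must be positive")
        c1, c2 = self.confidence_cutpoints
        if not c1 < c2:
            raise ConfigurationError("confidence_cutpoints must be ordered")
        if self.diffusion_scale <= 0:
            raise ConfigurationError("diffusion_scale must be positive")

    def to_dict(self) -> dict:
        return {
            "drift_by_condition": {str(k): v for k, v in dict(self.drift_by_condition).items()},
            "boundary": self.boundary,
            "start_point": self.start_point,
            "nondecision_t0": self.nondecision_t0,
            "postdecision_drift": self.postdecision_drift,
            "postdecision_duration": self.postdecision_duration,
            "confidence_cutpoints": list(self.confidence_cutpoints),
            "diffusion_scale": self.diffusion_scale,
        }


@dataclass(frozen=True)
class QuestionnaireScores:
    """Illusion questionnaire: three ownership items and six control items."""

    ownership_items: tuple
    control_items: tuple
    scale_min: float = -3.0
    scale_max: float = 3.0

    def __post_init__(self):
        own = tuple(self.ownership_items)
        ctrl = tuple(self.control_items)
        object.__setattr__(self, "ownership_items", own)
        object.__setattr__(self, "control_items", ctrl)
        if len(own) != 3 or len(ctrl) != 6:
            raise ValidationError("expected 3 ownership items (Q1-Q3) and 6 control items (Q4-Q9)")
        items = own + ctrl
        if any(x is None for x in items):
            raise ValidationError("missing questionnaire item")
        if any(not (self.scale_min <= x <= self.scale_max) for x in items):
            raise ValidationError("questionnaire item outside the rating scale")


def _scaled_dprimes(design: DesignSpec, base: Mapping | None = None,
                    touch_gain: Mapping | None = None) -> dict:
    base = dict(base or DEFAULT_DPRIME_BY_ASYNC)
    gain = dict(touch_gain or DEFAULT_TOUCH_GAIN)
    out = {}
    for a, t in design.conditions:
        if a not in base:
            raise ConfigurationError(f"no default d' for asynchrony {a} ms")
        out[(a, t)] = base[a] * gain.get(t, 1.0)
    return out


def design_for_template(template: str, n_subjects: int = 32, seed: int = 0) -> DesignSpec:
    """Return the stock :class:`DesignSpec` for one of the experiment templates."""
    if template in ("exp1", "control1", "control2"):
        return DesignSpec(asynchrony_levels_ms=(18, 31, 52, 88, 150), touches_levels=(6,),
                          trials_per_condition=60, n_subjects=n_subjects, seed=seed)
    if template == "exp2":
        # four asynchronies crossed with three touch levels, 300 trials total
        return DesignSpec(asynchrony_levels_ms=(31, 52, 88, 150), touches_levels=(3, 6, 9),
                          trials_per_condition=25, n_subjects=n_subjects, seed=seed)
    if template == "exp3":
        return DesignSpec(asynchrony_levels_ms=(18, 31, 52, 88, 150), touches_levels=(15,),
                          trials_per_condition=96, n_subjects=n_subjects, speeded=True,
                          max_stim_duration_s=30.0, seed=seed)
    raise ConfigurationError(f"unknown template {template!r}; expected one of {TEMPLATES}")


def sdt_params_for_template(template: str, design: DesignSpec | None = None,
                            **overrides) -> SDTObserverParams:
    """Stock generative SDT observer for a template.

    ``control1`` (rotated hands) uses d' ~ 0 everywhere; ``control2``
    (simultaneity judgement on wooden blocks) keeps graded sensitivity but a
    lower metacognitive efficiency, reflecting weaker conscious access in the
    non-ownership task.
    """
    design = design or design_for_template(template)
    if template == "control1":
        dp = {cond: 0.0 for cond in design.conditions}
        base = dict(dprime_by_condition=dp, mratio_true=0.3)
    elif template == "control2":
        base_dp = {18: 0.45, 31: 0.9, 52: 1.2, 88: 1.5, 150: 1.7}
        dp = _scaled_dprimes(design, base=base_dp)
        base = dict(dprime_by_condition=dp, mratio_true=0.45)
    else:
        base = dict(dprime_by_condition=_scaled_dprimes(design), mratio_true=DEFAULT_MRATIO)
    base.update(overrides)
    return SDTObserverParams(**base)


def ddm_params_for_template(template: str = "exp3", design: DesignSpec | None = None,
                            **overrides) -> DDMObserverParams:
    """Stock diffusion observer: drift rate rises with asynchrony."""
    design = design or design_for_template(template)
    drifts = {18: 0.4, 31: 0.8, 52: 1.2, 88: 1.7, 150: 2.2}
    dbc = {}
    for a, t in design.conditions:
        if a not in drifts:
            raise ConfigurationError(f"no default drift for asynchrony {a} ms")
        dbc[(a, t)] = drifts[a]
    base = dict(drift_by_condition=dbc)
    base.update(overrides)
    return DDMObserverParams(**base)
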