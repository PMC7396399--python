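"""Synthetic study data: arterial inputs, brain TAC cohorts, protein-binding
assays and whole-body biodistribution.

The generators emulate the study conditions of a first-in-human brain PET
radioligand protocol: a 123-min brain acquisition (20 s × 9, 1 min × 3,
3 min × 5, 6 min × 17), arterial sampling at 1–120 min with ≈70% parent
fraction at 60 min, two-tissue kinetics at published gray-matter magnitudes,
test–retest sessions with controllable between-/within-subject variance,
and a 4-session whole-body acquisition with liver-dominant uptake,
hepatobiliary transfer and ≈10 %ID urinary excretion by 5.8 h.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np

from .blood import InputFunction, ParentFractionModel, build_input
from .curves import BloodSampleSeries, FrameSchedule, StudyRecord
from .dosimetry import OrganRetention
from .kinetics import KineticParams, simulate_tac

__all__ = [
    "BLOOD_SAMPLE_TIMES",
    "PF_SAMPLE_TIMES",
    "REGION_KINETICS",
    "InputSpec",
    "CohortSpec",
    "gen_input",
    "input_function_from_spec",
    "gen_cohort",
    "gen_biodistribution",
]

#: Manual arterial sample times (minutes) of the study protocol.
BLOOD_SAMPLE_TIMES = np.array([1, 2, 3, 4, 5, 6, 8, 10, 20, 30, 45, 60, 90, 120.0])
#: Radiometabolite (parent-fraction) sample times (minutes).
PF_SAMPLE_TIMES = np.array([2, 5, 10, 20, 30, 45, 60, 90, 120.0])

#: Reference frame duration (minutes) at which ``tac_noise_cv`` is defined:
#: the SD at the 1-min frames equals tac_noise_cv × TAC peak, and scales as
#: 1/sqrt(frame duration) elsewhere.
NOISE_REF_FRAME_MIN = 1.0

# Published per-region two-tissue population means: (K1, k2, k3, mean V_T).
# Because per-subject ratio means do not compose, the population k4 is derived
# from the target V_T:  k4 = k3 / (V_T·k2/K1 − 1), so that the population
# macro-parameter equals the published regional mean V_T.
_REGION_TABLE = {
    "CERCX": (0.202, 0.747, 0.718, 4.23),
    "CAU": (0.116, 0.149, 0.561, 4.56),
    "PUT": (0.159, 0.214, 0.625, 5.78),
    "THA": (0.157, 0.263, 0.454, 5.13),
    "LFC": (0.154, 0.242, 0.595, 5.16),
    "LTC": (0.163, 0.371, 0.629, 5.67),
    "HIP": (0.162, 0.320, 0.304, 5.28),
    "LOC": (0.167, 0.289, 0.518, 5.11),
    "LPC": (0.165, 0.378, 0.607, 5.23),
    "ACC": (0.150, 0.219, 0.445, 6.28),
    "PCC": (0.203, 0.634, 0.854, 5.44),
    "AMG": (0.132, 0.480, 0.540, 6.00),
}


def _derive_region_params() -> Dict[str, KineticParams]:
    out = {}
    for region, (k1, k2, k3, vt) in _REGION_TABLE.items():
        k4 = k3 / (vt * k2 / k1 - 1.0)
        out[region] = KineticParams(k1, k2, k3, k4)
    return out


#: Default population kinetic parameters for the 12 gray-matter regions.
REGION_KINETICS: Dict[str, KineticParams] = _derive_region_params()


@dataclass(frozen=True)
class InputSpec:
    """Shape of the synthetic arterial input.

    Plasma: linear rise from zero to ``peak_kbq_cc`` at ``t_peak_min``, then
    a tri-exponential decay (fractions sum to 1, rates in 1/min).  The peak
    default is calibrated so that the default whole-brain TAC peaks near
    SUV 1.8 for the default injected dose and body weight.  Parent fraction
    follows the Hill model with pf(60 min) = 0.70 by default.  Whole blood
    is plasma divided by a constant plasma-to-whole-blood ratio.
    """

    t_peak_min: float = 1.0
    peak_kbq_cc: float = 15.0
    decay_fracs: tuple = (0.85, 0.10, 0.05)
    decay_rates: tuple = (3.0, 0.15, 0.002)
    pf_a: float = 0.6
    pf_b: float = 2.0
    pf_c: float = 3600.0
    plasma_wb_ratio: float = 1.2

    def __post_init__(self):
        if not (0.5 <= self.t_peak_min <= 2.0):
            raise ValueError("t_peak_min must lie in [0.5, 2] min")
        if abs(sum(self.decay_fracs) - 1.0) > 1e-9:
            raise ValueError("decay fractions must sum to 1")
        if min(self.decay_rates) <= 0 or self.peak_kbq_cc <= 0:
            raise ValueError("rates and peak must be > 0")

    def plasma(self, t):
        """Noiseless plasma concentration (kBq·cm⁻³) at times t (min)."""
        t = np.asarray(t, dtype=float)
        rise = self.peak_kbq_cc * t / self.t_peak_min
        dt = t - self.t_peak_min
        decay = self.peak_kbq_cc * sum(
            f * np.exp(-r * np.clip(dt, 0.0, None))
            for f, r in zip(self.decay_fracs, self.decay_rates)
        )
        return np.where(t < self.t_peak_min, rise, decay)

    def parent_fraction_model(self) -> ParentFractionModel:
        return ParentFractionModel(self.pf_a, self.pf_b, self.pf_c)


def gen_input(
    spec: Optional[InputSpec] = None, seed: int = 0, noise_cv: float = 0.0
) -> Dict[str, BloodSampleSeries]:
    """Sampled blood series (plasma, whole blood, parent fraction) at the
    protocol sample times; deterministic given the seed."""
    spec = spec or InputSpec()
    rng = np.random.default_rng(seed)
    plasma = spec.plasma(BLOOD_SAMPLE_TIMES)
    if noise_cv > 0:
        plasma = plasma * np.clip(rng.normal(1.0, noise_cv, plasma.shape), 0.0, None)
    pf = spec.parent_fraction_model()(PF_SAMPLE_TIMES)
    if noise_cv > 0:
        pf = np.clip(pf * rng.normal(1.0, noise_cv, pf.shape), 0.0, 1.0)
    return {
        "plasma": BloodSampleSeries(BLOOD_SAMPLE_TIMES, plasma, "plasma"),
        "whole_blood": BloodSampleSeries(
            BLOOD_SAMPLE_TIMES, plasma / spec.plasma_wb_ratio, "whole_blood"
        ),
        "parent_fraction": BloodSampleSeries(PF_SAMPLE_TIMES, pf, "parent_fraction"),
    }


def input_function_from_spec(spec: Optional[InputSpec] = None) -> InputFunction:
    """Noiseless metabolite-corrected input built from an InputSpec's sampled series."""
    spec = spec or InputSpec()
    series = gen_input(spec, seed=0, noise_cv=0.0)
    return build_input(series["plasma"], spec.parent_fraction_model())


def _cv_map(cv: Union[float, Dict[str, float]]) -> Dict[str, float]:
    if isinstance(cv, dict):
        out = {k: 0.0 for k in ("K1", "k2", "k3", "k4")}
        out.update(cv)
    else:
        out = {k: float(cv) for k in ("K1", "k2", "k3", "k4")}
    if min(out.values()) < 0:
        raise ValueError("coefficients of variation must be >= 0")
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Test–retest cohort description.

    ``between_subject_cv`` / ``within_subject_cv`` apply log-normally to the
    rate constants (a scalar or a per-parameter dict); ``tac_noise_cv`` sets
    the frame-noise SD at the reference (longest, 6-min) frame as a fraction
    of the TAC peak, scaled by 1/sqrt(frame duration).
    """

    n_subjects: int = 8
    regions: Dict[str, KineticParams] = field(
        default_factory=lambda: dict(REGION_KINETICS)
    )
    between_subject_cv: Union[float, Dict[str, float]] = 0.15
    within_subject_cv: Union[float, Dict[str, float]] = 0.07
    tac_noise_cv: float = 0.05
    retest_interval_days: tuple = (5, 19)
    injected_dose_mbq: float = 122.0
    body_weight_kg: float = 70.0
    fp_mean: float = 0.095
    fp_between_cv: float = 0.2
    fp_within_cv: float = 0.1
    input_between_cv: float = 0.15
    input_within_cv: float = 0.06
    input_spec: InputSpec = field(default_factory=InputSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ValueError("need >= 3 subjects")
        if self.tac_noise_cv < 0:
            raise ValueError("tac_noise_cv must be >= 0")
        _cv_map(self.between_subject_cv)
        _cv_map(self.within_subject_cv)


def _lognormal_factor(rng, cv: float) -> float:
    """Multiplicative log-normal factor with unit median and natural-scale CV."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(rng.normal(0.0, sigma)))


def _perturb(params: KineticParams, rng, cvs: Dict[str, float]) -> KineticParams:
    """Log-normal variation of a parameter set.

    K1, k2 and k3 vary with their own CVs; the CV labelled ``k4`` is applied
    to the exchange ratio k3/k4 (with k4 derived), because V_T depends on
    the rates only through K1/k2 and k3/k4 — perturbing 1/k4 directly
    produces heavy V_T tails far outside the magnitudes being emulated.
    """
    K1 = params.K1 * _lognormal_factor(rng, cvs["K1"])
    k2 = params.k2 * _lognormal_factor(rng, cvs["k2"])
    k3 = params.k3 * _lognormal_factor(rng, cvs["k3"])
    if params.k4 > 0:
        ratio = (params.k3 / params.k4) * _lognormal_factor(rng, cvs["k4"])
        k4 = k3 / ratio
    else:
        k4 = 0.0
    return KineticParams(K1, k2, k3, k4, params.vB)


def draw_params(pop: KineticParams, cv: Union[float, Dict[str, float]],
                rng) -> KineticParams:
    """Public single-draw version of the cohort parameter variation."""
    return _perturb(pop, rng, _cv_map(cv))


def subject_session_params(spec: CohortSpec):
    """Draw per-subject and per-session kinetic parameters (no TAC noise).

    Returns {subject_id: {session: {region: KineticParams}}}; exposed so
    variance-component studies can reason about the generating values.
    """
    rng = np.random.default_rng(spec.seed)
    cv_b = _cv_map(spec.between_subject_cv)
    cv_w = _cv_map(spec.within_subject_cv)
    out = {}
    for i in range(spec.n_subjects):
        sid = f"S{i + 1:02d}"
        subject = {
            region: _perturb(p, rng, cv_b) for region, p in spec.regions.items()
        }
        out[sid] = {
            session: {
                region: _perturb(p, rng, cv_w) for region, p in subject.items()
            }
            for session in ("test", "retest")
        }
    return out


def gen_cohort(spec: Optional[CohortSpec] = None) -> List[StudyRecord]:
    """Simulate a full test–retest cohort (two sessions per subject).

    Per subject, rate constants are drawn log-normally around the population
    means with the between-subject CV; each session re-draws around the
    subject values with the within-subject CV.  TACs are forward-simulated
    and zero-mean Gaussian frame noise with SD ∝ 1/sqrt(frame duration) is
    added.  f_P is drawn log-normally around 0.095.
    """
    spec = spec or CohortSpec()
    schedule = FrameSchedule.default_brain()
    params_by_subject = subject_session_params(spec)
    rng = np.random.default_rng(spec.seed + 1)
    pf_model = spec.input_spec.parent_fraction_model()
    ref_dur = NOISE_REF_FRAME_MIN
    records = []
    for sid, sessions in params_by_subject.items():
        fp_subj = spec.fp_mean * _lognormal_factor(rng, spec.fp_between_cv)
        input_subj = _lognormal_factor(rng, spec.input_between_cv)
        for session, region_params in sessions.items():
            # session-specific arterial input: the population shape scaled by
            # subject- and session-level amplitude factors (V_T is a ratio and
            # is unaffected; the AUC diagnostics are not)
            scale = input_subj * _lognormal_factor(rng, spec.input_within_cv)
            blood = gen_input(spec.input_spec, seed=0, noise_cv=0.0)
            blood = {
                kind: (
                    BloodSampleSeries(s.t, s.value * scale, kind)
                    if kind in ("plasma", "whole_blood")
                    else s
                )
                for kind, s in blood.items()
            }
            input_fn = build_input(blood["plasma"], pf_model)
            tacs = {}
            for region, p in region_params.items():
                tac = simulate_tac(p, input_fn, schedule, region_id=region)
                if spec.tac_noise_cv > 0:
                    sd = (
                        spec.tac_noise_cv
                        * float(np.max(tac.conc))
                        * np.sqrt(ref_dur / tac.frame_duration)
                    )
                    tac = tac.with_conc(tac.conc + rng.normal(0.0, sd))
                tacs[region] = tac
            records.append(
                StudyRecord(
                    subject_id=sid,
                    session=session,
                    injected_dose_mbq=spec.injected_dose_mbq,
                    tacs=tacs,
                    blood=blood,
                    body_weight_kg=spec.body_weight_kg,
                    f_p=fp_subj * _lognormal_factor(rng, spec.fp_within_cv),
                )
            )
    return records


# --- whole-body biodistribution --------------------------------------------

#: Mid-times (hours) of the 4 whole-body PET sessions (3+2+2+1 passes).
BIODIST_TIMES_H = np.array([0.15, 0.45, 0.75, 1.725, 2.175, 3.725, 4.175, 5.8])
#: Urine void times (hours): during the three breaks and after the last session.
VOID_TIMES_H = np.array([1.2, 3.0, 4.9, 6.1])

_ORGAN_SHAPES = {
    # organ: (amplitude %ID, uptake time h, washout rate 1/h, volume cm3)
    "liver": (28.3, 0.10, 0.25, 1800.0),
    "lung": (13.5, 0.05, 0.50, 1000.0),
    "brain": (3.6, 0.08, 0.05, 1400.0),
    "heart_wall": (2.72, 0.04, 0.40, 320.0),
    "pancreas": (2.5, 0.04, 0.40, 100.0),
    "kidneys": (2.4, 0.04, 0.35, 300.0),
    "spleen": (1.6, 0.05, 0.30, 180.0),
    "stomach": (3.46, 0.80, 0.10, 150.0),
    "small_intestine": (11.7, 2.50, 0.0, 640.0),   # hepatobiliary inflow, rising
    "gall_bladder": (3.5, 2.00, 0.0, 60.0),        # rising
    "red_marrow": (1.0, 0.10, 0.05, 1100.0),
    "thyroid": (0.15, 0.05, 0.20, 20.0),
}

#: Total urinary excretion model: U(t) = amplitude·(1 − exp(−t/τ)), %ID.
_URINE_AMP, _URINE_TAU = 12.0, 3.5
#: Assumed overall recovery of the VOI analysis (fraction of injected dose
#: accounted for by organs + urine + remainder at any time).
_RECOVERY_PID = 98.0


def _organ_pid(t, amp, tau_up, washout):
    t = np.asarray(t, dtype=float)
    uptake = 1.0 - np.exp(-t / tau_up)
    return amp * uptake * np.exp(-washout * t)


def _urine_cumulative(t):
    return _URINE_AMP * (1.0 - np.exp(-np.asarray(t, dtype=float) / _URINE_TAU))


def gen_biodistribution(seed: int = 0, noise_cv: float = 0.03):
    """Whole-body organ %ID curves, urine voids, and the bladder VOI series.

    Returns a dict with keys ``organs`` (list of OrganRetention, including
    ``rest_of_body``), ``bladder_voi`` (OrganRetention: bladder content
    between voids), ``void_times_h``, ``void_pid`` and ``injected_mbq``.
    Activity is conserved by construction: organs + bladder + voided urine +
    remainder sum to the recovery constant at every session time.
    """
    rng = np.random.default_rng(seed)
    t = BIODIST_TIMES_H
    organs = []
    total = np.zeros_like(t)
    for organ, (amp, tau_up, washout, vol) in _ORGAN_SHAPES.items():
        pid = _organ_pid(t, amp, tau_up, washout)
        if noise_cv > 0:
            pid = np.clip(pid * rng.normal(1.0, noise_cv, pid.shape), 0.0, None)
        organs.append(OrganRetention(organ, t, pid, volume_cm3=vol))
        total += pid

    urine_cum = _urine_cumulative(t)
    void_pid = np.diff(np.concatenate([[0.0], _urine_cumulative(VOID_TIMES_H)]))
    last_void = np.array(
        [max([0.0] + [v for v in VOID_TIMES_H if v <= ti]) for ti in t]
    )
    bladder = urine_cum - _urine_cumulative(last_void)
    bladder_voi = OrganRetention("bladder", t, bladder, volume_cm3=200.0)

    remainder = _RECOVERY_PID - total - urine_cum
    if np.any(remainder < 0):
        raise RuntimeError("biodistribution noise exhausted the remainder")
    organs.append(OrganRetention("rest_of_body", t, remainder, volume_cm3=60000.0))
    return {
        "organs": organs,
        "bladder_voi": bladder_voi,
        "void_times_h": VOID_TIMES_H.copy(),
        "void_pid": void_pid,
        "injected_mbq": 111.0,
    }
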