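"""Synthetic actigraphy cohorts with dementia-like rest-activity rhythms.

Real nursing-home actigraphy cannot be shipped, so this module generates
cohorts with the statistical structure the downstream analysis assumes:

* anti-logistic base rhythms with a late, variable acrophase
  (Normal(15.35, 1.66) decimal hours — a phase-delayed dementia cohort);
* fragmentation via an hourly two-state (rest/active) Markov gate that
  multiplies the smooth curve, emulating daytime naps and night-time
  awakenings;
* multiplicative gamma noise (mean 1) so counts stay non-negative without
  truncation bias, plus a small additive floor;
* off-wrist gaps, cluster (nursing-home unit) structure with whole-cluster
  randomization, four assessment waves, per-wave dropout, and injectable
  week-by-condition effects on any generative parameter.

Everything is deterministic given the cohort seed: per-subject and
per-wave streams are spawned from one ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .actigraphy_io import EpochSeries, write_epoch_file
from .cosinor import CosinorParams, antilogistic_curve
from .errors import AccountingError, ParameterError

DEFAULT_SEED = 20170901  # trial start month


@dataclass(frozen=True)
class SubjectSpec:
    """Distributional description of one simulated population.

    Acrophase is drawn Normal(``acrophase_mean``, ``acrophase_sd``) and
    truncated to [0, 24); amplitude, minimum, alpha and beta are drawn
    uniformly on the given ranges. ``frag_p_rest`` / ``frag_p_active`` are
    the hourly Markov transition probabilities active->rest and
    rest->active; ``frag_attenuation`` is the activity multiplier in the
    rest state. ``noise_cv`` is the coefficient of variation of the
    multiplicative gamma noise (0 disables it). ``offwrist_daily_p`` is
    the probability that a given day contains an off-wrist gap of
    geometric mean length ``offwrist_mean_min`` minutes.
    """

    acrophase_mean: float = 15.35
    acrophase_sd: float = 1.66
    amplitude_range: tuple[float, float] = (40.0, 160.0)
    minimum_range: tuple[float, float] = (2.0, 20.0)
    alpha_range: tuple[float, float] = (-0.6, 0.4)
    beta_range: tuple[float, float] = (1.5, 10.0)
    frag_p_rest: float = 0.15
    frag_p_active: float = 0.5
    frag_attenuation: float = 0.1
    noise_cv: float = 0.6
    noise_floor: float = 1.0
    offwrist_daily_p: float = 0.05
    offwrist_mean_min: float = 45.0

    def __post_init__(self) -> None:
        for name in ("frag_p_rest", "frag_p_active", "offwrist_daily_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name}={v} must lie in [0, 1]")
        for name in ("noise_cv", "noise_floor", "offwrist_mean_min"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not 0 <= self.frag_attenuation <= 1:
            raise ParameterError("frag_attenuation must lie in [0, 1]")


def sample_subject_params(
    spec: SubjectSpec, rng: np.random.Generator
) -> CosinorParams:
    """Draw one subject's base rhythm parameters from the population spec."""
    phi = float(rng.normal(spec.acrophase_mean, spec.acrophase_sd)) % 24.0
    return CosinorParams(
        minimum=float(rng.uniform(*spec.minimum_range)),
        amplitude=float(rng.uniform(*spec.amplitude_range)),
        acrophase=phi,
        alpha=float(rng.uniform(*spec.alpha_range)),
        beta=float(rng.uniform(*spec.beta_range)),
    )


def _markov_gate(
    n_hours: int, spec: SubjectSpec, rng: np.random.Generator
) -> np.ndarray:
    """Hourly rest(0)/active(1) state path; starts active."""
    states = np.empty(n_hours, dtype=int)
    s = 1
    u = rng.random(n_hours)
    for h in range(n_hours):
        if s == 1 and u[h] < spec.frag_p_rest:
            s = 0
        elif s == 0 and u[h] < spec.frag_p_active:
            s = 1
        states[h] = s
    return states


def simulate_trace(
    params: CosinorParams,
    spec: SubjectSpec,
    days: int,
    rng: np.random.Generator,
    subject_id: str = "sim",
    wave: int = 0,
    epoch_length: int = 60,
    start_time: pd.Timestamp | str = "2017-09-01T00:00:00",
    fragmentation: bool = True,
    quantize: bool = True,
) -> EpochSeries:
    """Generate one recording from known rhythm parameters.

    counts = round(curve(t) x Markov gate x gamma noise + floor noise);
    off-wrist gaps are marked invalid in the mask. ``quantize=False``
    skips the integer rounding (continuous counts), useful for exact
    round-trip studies.
    """
    if days < 1:
        raise ParameterError("days must be >= 1")
    epochs_per_day = 86400 // epoch_length
    n = days * epochs_per_day
    t = np.arange(n) * epoch_length / 3600.0
    curve = antilogistic_curve(t % 24.0, params)

    if fragmentation and spec.frag_p_rest > 0:
        gate_h = _markov_gate(days * 24, spec, rng)
        gate = np.where(
            np.repeat(gate_h, epochs_per_day // 24), 1.0, spec.frag_attenuation
        )
    else:
        gate = 1.0

    signal = curve * gate
    if spec.noise_cv > 0:
        shape = 1.0 / spec.noise_cv**2
        signal = signal * rng.gamma(shape, 1.0 / shape, size=n)
    if spec.noise_floor > 0:
        signal = signal + rng.exponential(spec.noise_floor, size=n)
    counts = np.maximum(np.round(signal) if quantize else signal, 0.0)

    mask = np.ones(n, dtype=bool)
    if spec.offwrist_daily_p > 0:
        gap_days = np.nonzero(rng.random(days) < spec.offwrist_daily_p)[0]
        for d in gap_days:
            length = max(1, int(rng.geometric(1.0 / spec.offwrist_mean_min)))
            length = min(length * 60 // epoch_length, epochs_per_day)
            start = int(rng.integers(0, epochs_per_day - length + 1))
            i0 = d * epochs_per_day + start
            mask[i0 : i0 + length] = False
    counts = np.where(mask, counts, 0.0)

    return EpochSeries(
        subject_id=subject_id,
        wave=wave,
        start_time=pd.Timestamp(start_time),
        epoch_length=epoch_length,
        counts=counts,
        valid_mask=mask,
    )


def simulate_subject(
    spec: SubjectSpec, days: int, seed: int, **trace_kwargs
) -> EpochSeries:
    """Sample one subject from the population and generate its recording."""
    rng = np.random.default_rng(seed)
    params = sample_subject_params(spec, rng)
    return simulate_trace(params, spec, days, rng, **trace_kwargs)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated cluster-randomized trial.

    Whole clusters (nursing-home units) are assigned to one arm; the
    default is 8 clusters, 31 control + 30 intervention subjects, four
    waves at 0/8/16/24 weeks, 7-day recordings. ``injected_effects`` maps
    ``(parameter, wave)`` to an additive shift applied to the intervention
    arm's generative parameters at that wave (e.g. ``("acrophase", 16):
    -1.0`` advances the intervention acrophase one hour at week 16).
    """

    n_clusters: int = 8
    cluster_sizes: tuple[int, ...] = (8, 8, 8, 7, 8, 8, 7, 7)
    n_control_clusters: int = 4
    waves: tuple[int, ...] = (0, 8, 16, 24)
    days_per_wave: int = 7
    epoch_length: int = 60
    cluster_effect_sd: float = 0.3
    injected_effects: dict = field(default_factory=dict)
    dropout_hazard: float = 0.08
    subject_spec: SubjectSpec = field(default_factory=SubjectSpec)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if len(self.cluster_sizes) != self.n_clusters:
            raise ParameterError("cluster_sizes length must equal n_clusters")
        if not 0 <= self.dropout_hazard <= 1:
            raise ParameterError("dropout_hazard must lie in [0, 1]")
        if not 0 < self.n_control_clusters < self.n_clusters:
            raise ParameterError("need clusters in both arms")


_INJECTABLE = {"acrophase", "amplitude", "minimum", "alpha", "beta"}


def _apply_effects(
    params: CosinorParams, effects: dict, wave: int
) -> CosinorParams:
    out = params
    for (name, w), delta in effects.items():
        if w != wave:
            continue
        if name not in _INJECTABLE:
            raise ParameterError(f"cannot inject effect on {name!r}")
        value = getattr(out, name) + delta
        if name == "acrophase":
            value %= 24.0
        out = replace(out, **{name: value})
    return out


@dataclass(frozen=True)
class SimulatedTrial:
    """In-memory result of a trial simulation."""

    series: tuple[EpochSeries, ...]
    covariates: pd.DataFrame
    true_params: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        epochs = out / "epochs"
        epochs.mkdir(parents=True, exist_ok=True)
        for s in self.series:
            write_epoch_file(s, epochs / f"{s.subject_id}_wave{s.wave:02d}.csv")
        self.covariates.to_csv(out / "covariates.csv", index=False)


def simulate_trial(spec: CohortSpec) -> SimulatedTrial:
    """Simulate the full cohort: one recording per retained subject-wave
    plus the covariate table (cluster, condition, FAST, exposure, age, sex).
    """
    root = np.random.SeedSequence(spec.seed)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    base_date = pd.Timestamp("2017-09-01")

    all_series: list[EpochSeries] = []
    cov_rows: list[dict] = []
    param_rows: list[dict] = []
    sid = 0
    for ci, size in enumerate(spec.cluster_sizes):
        condition = "control" if ci < spec.n_control_clusters else "intervention"
        cluster_shift = float(
            cohort_rng.normal(0.0, spec.cluster_effect_sd)
        )
        for _ in range(size):
            sid += 1
            subject_id = f"S{sid:03d}"
            srng = np.random.default_rng(root.spawn(1)[0])
            base = sample_subject_params(spec.subject_spec, srng)
            base = replace(
                base, acrophase=(base.acrophase + cluster_shift) % 24.0
            )
            fast = int(
                srng.choice([4, 5, 6, 7], p=[0.05, 0.12, 0.75, 0.08])
            )
            age = int(np.clip(srng.normal(84, 7), 62, 101))
            sex = "F" if srng.random() < 0.71 else "M"
            if condition == "control":
                exposure = float(max(srng.normal(186.0, 84.0), 0.0))
            else:
                exposure = float(max(srng.normal(216.0, 96.0), 0.0))

            dropped = False
            for wave in spec.waves:
                if wave > 0 and srng.random() < spec.dropout_hazard:
                    dropped = True
                if dropped:
                    break
                params = base
                if condition == "intervention":
                    params = _apply_effects(
                        params, spec.injected_effects, wave
                    )
                series = simulate_trace(
                    params,
                    spec.subject_spec,
                    spec.days_per_wave,
                    srng,
                    subject_id=subject_id,
                    wave=wave,
                    epoch_length=spec.epoch_length,
                    start_time=base_date + pd.Timedelta(weeks=wave),
                )
                all_series.append(series)
                cov_rows.append(
                    {
                        "subject_id": subject_id,
                        "cluster": f"C{ci + 1}",
                        "condition": condition,
                        "wave": wave,
                        "FAST": fast,
                        "exposure_minutes": round(exposure, 1),
                        "age": age,
                        "sex": sex,
                    }
                )
                param_rows.append(
                    {
                        "subject_id": subject_id,
                        "wave": wave,
                        "acrophase": params.acrophase,
                        "amplitude": params.amplitude,
                        "minimum": params.minimum,
                        "alpha": params.alpha,
                        "beta": params.beta,
                    }
                )
    return SimulatedTrial(
        series=tuple(all_series),
        covariates=pd.DataFrame(cov_rows),
        true_params=pd.DataFrame(param_rows),
    )


def simulate_outcome_table(
    seed: int,
    n_per_arm: tuple[int, int] = (31, 30),
    n_clusters: int = 8,
    waves: tuple[int, ...] = (0, 8, 16, 24),
    outcomes: tuple[str, ...] = ("IS", "IV", "RA", "acrophase"),
    sd_subject: float = 1.0,
    sd_resid: float = 1.0,
    effects: dict | None = None,
    dropout_hazard: float = 0.0,
) -> pd.DataFrame:
    """Simulate a long outcome table directly from the mixed-model
    data-generating process (no actigraphy layer).

    Each outcome follows ``value = b_subject + effect + e`` with
    ``b ~ N(0, sd_subject^2)`` per subject-outcome and
    ``e ~ N(0, sd_resid^2)`` per observation; ``effects`` maps
    ``(outcome, wave)`` to an additive intervention-arm shift. Used for
    calibration studies of the modelling stage (type-I error, FDR), where
    re-simulating raw epochs per replicate adds nothing.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    sid = 0
    half = n_clusters // 2
    for arm, n_subj in zip(("control", "intervention"), n_per_arm):
        clusters = [f"{arm[:3]}{k}" for k in range(half)]
        for i in range(n_subj):
            sid += 1
            subject_id = f"S{sid:03d}"
            cluster = clusters[i % half]
            fast = int(rng.choice([4, 5, 6, 7], p=[0.05, 0.12, 0.75, 0.08]))
            intercepts = {oc: rng.normal(0.0, sd_subject) for oc in outcomes}
            n_waves = len(waves)
            if dropout_hazard > 0:
                drops = rng.random(n_waves - 1) < dropout_hazard
                n_waves = 1 + int(np.argmax(drops)) if drops.any() else n_waves
            for wave in waves[:n_waves]:
                for oc in outcomes:
                    delta = (
                        effects.get((oc, wave), 0.0)
                        if arm == "intervention"
                        else 0.0
                    )
                    rows.append(
                        {
                            "subject_id": subject_id,
                            "cluster": cluster,
                            "condition": arm,
                            "wave": wave,
                            "FAST": fast,
                            "exposure_minutes": 180.0,
                            "outcome": oc,
                            "value": intercepts[oc]
                            + delta
                            + rng.normal(0.0, sd_resid),
                        }
                    )
    return pd.DataFrame(rows)


def flow_accounting(
    screened: int, exclusions: list[tuple[str, int]]
) -> tuple[int, pd.DataFrame]:
    """Participant-flow arithmetic: screened minus staged exclusions.

    Returns the retained count and a per-stage table with running totals.
    """
    if screened < 0:
        raise AccountingError("screened count must be non-negative")
    rows = [{"stage": "screened", "excluded": 0, "remaining": screened}]
    remaining = screened
    for reason, count in exclusions:
        if count < 0:
            raise AccountingError(f"negative exclusion count for {reason!r}")
        remaining -= count
        if remaining < 0:
            raise AccountingError(
                f"exclusions exceed remaining participants at {reason!r}"
            )
        rows.append(
            {"stage": reason, "excluded": count, "remaining": remaining}
        )
    return remaining, pd.DataFrame(rows)
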