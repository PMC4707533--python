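"""Synthetic cohorts with known ground truth, and recovery experiments.

No behavioural data from the original study is deposited, so validation
runs on synthetic cohorts that reproduce its design: a shared stimulus set
(4 difficulty levels × 200 trials), per-participant randomized orderings of
the same trials, and responses simulated from the decision model under
known parameters.  Ground truth can be fixed, sampled from the fitting
priors (a well-specified calibration check), or taken from published
group-mean parameter estimates for this task (``truth_mode="reference"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decision_model import (
    ModelParams,
    Response,
    ndt_params_from_summary,
    simulate_response,
)
from .epabc import EPPosterior, FitSettings, fit
from .stimulus import CONDITION_OFFSETS, Trial, generate_session, shuffle_session
from .transforms import ModelSpec

__all__ = [
    "REFERENCE_FITS",
    "reference_params",
    "simulate_reference_condition",
    "CohortSpec",
    "Cohort",
    "make_cohort",
    "RecoveryReport",
    "recovery_experiment",
]

# Published group-mean parameter estimates for this task, per input mode and
# difficulty.  NDT is given as (mode, SD) of the log-normal in ms and
# converted to (ndt_mu, ndt_sigma) on use.
REFERENCE_FITS: dict[str, dict[str, dict[str, float]]] = {
    "ddm_equivalent": {
        "D1": dict(sigma_s=236.70, ndt_mode=563.26, ndt_sd=195.17,
                   bound=0.71, prior_left=0.46, lapse_p=0.03, lapse_to_p=0.24),
        "D2": dict(sigma_s=76.90, ndt_mode=453.31, ndt_sd=121.61,
                   bound=0.74, prior_left=0.46, lapse_p=0.03, lapse_to_p=0.16),
        "D3": dict(sigma_s=70.73, ndt_mode=431.24, ndt_sd=137.60,
                   bound=0.83, prior_left=0.46, lapse_p=0.02, lapse_to_p=0.18),
        "D4": dict(sigma_s=51.29, ndt_mode=430.51, ndt_sd=164.97,
                   bound=0.83, prior_left=0.43, lapse_p=0.03, lapse_to_p=0.14),
    },
    "exact": {
        "D1": dict(sigma_s=95.63, ndt_mode=520.73, ndt_sd=201.66,
                   bound=0.65, prior_left=0.47, lapse_p=0.02, lapse_to_p=0.24),
        "D2": dict(sigma_s=58.27, ndt_mode=415.96, ndt_sd=181.27,
                   bound=0.77, prior_left=0.47, lapse_p=0.02, lapse_to_p=0.17),
        "D3": dict(sigma_s=52.10, ndt_mode=382.16, ndt_sd=172.54,
                   bound=0.87, prior_left=0.44, lapse_p=0.02, lapse_to_p=0.18),
        "D4": dict(sigma_s=38.22, ndt_mode=399.35, ndt_sd=167.54,
                   bound=0.88, prior_left=0.42, lapse_p=0.02, lapse_to_p=0.15),
    },
}


def reference_params(mode: str, condition: str) -> ModelParams:
    """Group-mean reference parameters as a :class:`ModelParams`.

    The published NDT mode/SD pair is inverted to log-normal (μ, σ).
    """
    entry = REFERENCE_FITS[mode][condition]
    ndt_mu, ndt_sigma = ndt_params_from_summary(entry["ndt_mode"], entry["ndt_sd"])
    return ModelParams(
        sigma_s=entry["sigma_s"],
        ndt_mu=ndt_mu,
        ndt_sigma=ndt_sigma,
        bound=entry["bound"],
        prior_left=entry["prior_left"],
        lapse_p=entry["lapse_p"],
        lapse_to_p=entry["lapse_to_p"],
    )


def simulate_reference_condition(
    condition: str,
    mode: str = "exact",
    n_trials: int = 10_000,
    rng: np.random.Generator | None = None,
    variant: str = "standard",
) -> dict:
    """Predicted group behaviour at the published group-mean parameters.

    Simulates one response per freshly generated trial (sides alternating)
    and summarizes accuracy among non-timeout responses (percent) and their
    mean reaction time (ms).
    """
    from .decision_model import TIMEOUT, simulate_responses_batch
    from .stimulus import make_target_config, sample_trial

    if rng is None:
        rng = np.random.default_rng()
    params = reference_params(mode, condition)
    config = make_target_config(condition)
    n_correct = 0
    n_resp = 0
    rt_sum = 0.0
    for i in range(n_trials):
        side = "left" if i % 2 == 0 else "right"
        trial = sample_trial(config, side, rng)
        sim = simulate_responses_batch(
            trial, params, n=1, mode=mode, variant=variant, rng=rng
        )
        if sim.choice[0] == TIMEOUT:
            continue
        n_resp += 1
        label = "left" if sim.choice[0] == 0 else "right"
        n_correct += label == side
        rt_sum += float(sim.rt_ms[0])
    return {
        "condition": condition,
        "mode": mode,
        "n_trials": n_trials,
        "n_non_timeout": n_resp,
        "accuracy_pct": 100.0 * n_correct / n_resp,
        "mean_rt_ms": rt_sum / n_resp,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort."""

    n_participants: int = 24
    conditions: tuple[str, ...] = ("D1", "D2", "D3", "D4")
    trials_per_condition: int = 200  # split evenly left/right
    truth_mode: str = "reference"  # "fixed" | "sampled" | "reference"
    generator_mode: str = "exact"  # input mode of the generating model
    generator_variant: str = "standard"
    fixed_truth: ModelParams | None = None  # for truth_mode="fixed"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.trials_per_condition < 1:
            raise ValueError("counts must be positive")
        if self.truth_mode not in ("fixed", "sampled", "reference"):
            raise ValueError(f"unknown truth_mode {self.truth_mode!r}")
        if self.truth_mode == "fixed" and self.fixed_truth is None:
            raise ValueError("truth_mode='fixed' needs fixed_truth")
        for c in self.conditions:
            if c not in CONDITION_OFFSETS:
                raise ValueError(f"unknown condition {c!r}")


@dataclass
class Cohort:
    """One synthetic cohort: shared stimuli, orderings, responses, truth."""

    spec: CohortSpec
    trials: list[Trial]  # shared stimulus set, canonical order
    orderings: list[np.ndarray]  # per participant, indices into trials
    responses: list[dict[str, Response]]  # per participant: trial_id -> Response
    truth: list[dict[str, ModelParams]]  # per participant: condition -> params

    def participant_data(
        self, participant: int, condition: str
    ) -> tuple[list[Trial], list[Response]]:
        """Trial/response pairs of one participant-condition, in viewing order."""
        trials, resps = [], []
        for idx in self.orderings[participant]:
            tr = self.trials[idx]
            if tr.config.condition == condition:
                trials.append(tr)
                resps.append(self.responses[participant][tr.trial_id])
        return trials, resps


def _draw_truth(
    spec: CohortSpec, condition: str, model_spec: ModelSpec, rng: np.random.Generator
) -> ModelParams:
    if spec.truth_mode == "fixed":
        return spec.fixed_truth
    if spec.truth_mode == "reference":
        return reference_params(spec.generator_mode, condition)
    # sampled: draw from the same priors used for fitting
    z = rng.standard_normal(model_spec.n_params)
    return model_spec.to_model_params(z)


def make_cohort(spec: CohortSpec, rng: np.random.Generator | None = None) -> Cohort:
    """Generate a full synthetic cohort.

    One stimulus set is generated once and shared by all participants, each
    with their own randomized viewing order; responses are simulated from
    the generating model under each participant's ground-truth parameters.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    per_side = spec.trials_per_condition // 2
    design = {c: per_side for c in spec.conditions}
    trials = generate_session(design, rng)
    model_spec = ModelSpec(mode=spec.generator_mode, variant=spec.generator_variant)

    orderings, all_responses, all_truth = [], [], []
    for _ in range(spec.n_participants):
        order = rng.permutation(len(trials))
        truth = {
            c: _draw_truth(spec, c, model_spec, rng) for c in spec.conditions
        }
        responses: dict[str, Response] = {}
        for idx in order:
            tr = trials[idx]
            responses[tr.trial_id] = simulate_response(
                tr, truth[tr.config.condition],
                mode=spec.generator_mode, variant=spec.generator_variant, rng=rng,
                deadline_on_total_rt=model_spec.deadline_on_total_rt,
            )
        orderings.append(order)
        all_responses.append(responses)
        all_truth.append(truth)
    return Cohort(
        spec=spec, trials=trials, orderings=orderings,
        responses=all_responses, truth=all_truth,
    )


@dataclass
class RecoveryReport:
    """Aggregate parameter-recovery diagnostics across fitted cells."""

    param_names: tuple[str, ...]
    bias: dict[str, float] = field(default_factory=dict)
    rmse: dict[str, float] = field(default_factory=dict)
    coverage95: dict[str, float] = field(default_factory=dict)
    n_cells: int = 0
    n_failed: int = 0
    posteriors: list[EPPosterior] = field(default_factory=list)
    truths: list[ModelParams] = field(default_factory=list)


def _posterior_interval(
    posterior: EPPosterior, model_spec: ModelSpec, name: str,
    rng: np.random.Generator, n: int = 4000, level: float = 0.95,
) -> tuple[float, float, float]:
    """(lo, hi, mean) of one parameter's marginal, on the model scale."""
    z = posterior.sample(n, rng)
    x = model_spec.to_model_space(z)[name]
    lo, hi = np.quantile(x, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi), float(x.mean())


def recovery_experiment(
    cohort: Cohort,
    model_spec: ModelSpec,
    settings: FitSettings | None = None,
    rng: np.random.Generator | None = None,
    cells: list[tuple[int, str]] | None = None,
) -> RecoveryReport:
    """Fit each participant-condition cell and compare posteriors to truth.

    ``cells`` restricts the experiment to a subset of (participant,
    condition) pairs.  Failed fits are recorded, not fatal.  Fitting never
    reads the ground truth; it is consulted only afterwards for the report.
    """
    if settings is None:
        settings = FitSettings()
    if rng is None:
        rng = np.random.default_rng(cohort.spec.seed)
    if cells is None:
        cells = [
            (p, c)
            for p in range(cohort.spec.n_participants)
            for c in cohort.spec.conditions
        ]
    names = model_spec.param_names
    report = RecoveryReport(param_names=names)
    errors = {k: [] for k in names}
    covered = {k: [] for k in names}
    for participant, condition in cells:
        trials, resps = cohort.participant_data(participant, condition)
        fit_seed = int(rng.integers(2**31))
        try:
            post = fit(
                trials, resps, model_spec,
                settings=settings, rng=np.random.default_rng(fit_seed),
            )
        except Exception:
            report.n_failed += 1
            continue
        truth = cohort.truth[participant][condition]
        report.posteriors.append(post)
        report.truths.append(truth)
        report.n_cells += 1
        for name in names:
            true_val = getattr(truth, name)
            lo, hi, mean = _posterior_interval(post, model_spec, name, rng)
            errors[name].append(mean - true_val)
            covered[name].append(lo <= true_val <= hi)
    for name in names:
        if errors[name]:
            e = np.asarray(errors[name])
            report.bias[name] = float(e.mean())
            report.rmse[name] = float(np.sqrt((e**2).mean()))
            report.coverage95[name] = float(np.mean(covered[name]))
    return report
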