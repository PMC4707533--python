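"""Bayesian response model for the single-dot tracking task.

The observer holds beliefs (posterior probabilities) that the dot stream is
generated around the left or the right target.  After each observed dot the
beliefs are updated by Bayes' rule using the true stimulus generative
densities (isotropic Gaussians with SD ``sigma_stim`` at the two target
means) as the observer's internal generative models.  A decision is made the
first time either belief reaches a confidence bound; the reaction time is
the decision step times the dot duration plus a log-normal non-decision
time.  A lapse mixture adds stimulus-independent random responses and
timeouts.

Two input modes:

* ``exact`` — observations are the actual per-frame dot positions plus
  isotropic sensory noise of SD ``sigma_s`` (exact input model, ExaM).
* ``ddm_equivalent`` — observations are the constant true-target position
  plus the same noise; the resulting log-odds increments are i.i.d.
  Gaussian, which makes this mode mathematically equivalent to a pure
  drift-diffusion model.

Accumulation variants:

* ``standard`` — lossless Bayesian accumulation, fixed bound.
* ``leaky`` — the previous posterior enters the update raised to an
  exponent ``discount`` (λ ∈ [0, 1]; λ=1 recovers standard accumulation,
  λ=0 means no accumulation at all).
* ``collapsing`` — the bound decays over the trial from ``bound`` towards
  0.5, controlled by ``stretch`` (how far it falls) and ``shape`` (how
  early).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .stimulus import TargetConfig, Trial

__all__ = [
    "ModelParams",
    "BeliefState",
    "DecisionOutcome",
    "Response",
    "make_observation",
    "belief_update",
    "bound_value",
    "run_accumulation",
    "sample_ndt",
    "ndt_summary",
    "ndt_params_from_summary",
    "simulate_response",
    "simulate_responses_batch",
    "BatchResult",
]

BELIEF_FLOOR = 1e-12

VARIANTS = ("standard", "leaky", "collapsing")
INPUT_MODES = ("exact", "ddm_equivalent")

# integer choice codes used by the vectorized simulator
LEFT, RIGHT, TIMEOUT = 0, 1, -1
CHOICE_LABELS = {LEFT: "left", RIGHT: "right", TIMEOUT: "timeout"}


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the decision model, in natural units.

    sigma_s
        sensory-noise SD in pixels (corruption of the observations; the
        observer's generative densities keep the stimulus SD).
    ndt_mu, ndt_sigma
        location and scale of the log-normal non-decision time, on the
        log-millisecond scale.
    bound
        confidence bound on the posterior belief, in (0.5, 1].
    prior_left
        a-priori probability of the left target, in (0, 1).
    lapse_p
        probability a trial is a lapse (stimulus-independent response).
    lapse_to_p
        probability that a lapse trial times out.
    discount
        leak exponent λ on the previous posterior (leaky variant; 1 =
        lossless accumulation).
    stretch, shape
        collapsing-bound parameters: stretch s ∈ [0, 1] is the collapse
        fraction (0 = fixed bound, 1 = full collapse to 0.5 at the
        deadline); shape k > 0 times the collapse (k < 1 early, k > 1 late).
    """

    sigma_s: float
    ndt_mu: float
    ndt_sigma: float
    bound: float
    prior_left: float = 0.5
    lapse_p: float = 0.0
    lapse_to_p: float = 0.0
    discount: float = 1.0
    stretch: float = 0.0
    shape: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_s < 0:
            raise ValueError("sigma_s must be >= 0")
        if self.ndt_sigma < 0:
            raise ValueError("ndt_sigma must be >= 0")
        if not 0.5 < self.bound <= 1.0:
            raise ValueError("bound must be in (0.5, 1]")
        if not 0.0 < self.prior_left < 1.0:
            raise ValueError("prior_left must be in (0, 1)")
        for name in ("lapse_p", "lapse_to_p", "discount", "stretch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.shape <= 0:
            raise ValueError("shape must be > 0")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BeliefState:
    """Posterior beliefs over the two targets after ``t`` observed dots."""

    beliefs: tuple[float, float]  # (left, right)
    t: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.beliefs, dtype=float)
        if b.shape != (2,) or np.any(b < 0) or abs(b.sum() - 1.0) > 1e-9:
            raise ValueError("beliefs must be a normalized probability pair")
        b = np.clip(b, BELIEF_FLOOR, 1.0 - BELIEF_FLOOR)
        b = b / b.sum()
        object.__setattr__(self, "beliefs", (float(b[0]), float(b[1])))

    @property
    def belief_left(self) -> float:
        return self.beliefs[0]

    @property
    def belief_right(self) -> float:
        return self.beliefs[1]


@dataclass(frozen=True)
class DecisionOutcome:
    """Result of running the accumulator on one trial."""

    kind: str  # "decided" | "no_crossing"
    choice: str | None  # "left" | "right" | None
    t_d: int | None  # 1-based decision step
    trajectory: np.ndarray | None = field(default=None, repr=False)  # (t, 2)


@dataclass(frozen=True)
class Response:
    """Observed or simulated behaviour on one trial."""

    choice: str  # "left" | "right" | "timeout"
    rt_ms: float | None = None
    provenance: str | None = None  # "evidence" | "lapse_random" | "lapse_timeout"

    def __post_init__(self) -> None:
        if self.choice not in ("left", "right", "timeout"):
            raise ValueError(f"invalid choice {self.choice!r}")
        if self.choice == "timeout":
            if self.rt_ms is not None:
                raise ValueError("timeout responses carry no RT")
        else:
            if self.rt_ms is None or self.rt_ms <= 0:
                raise ValueError("non-timeout responses need rt_ms > 0")

    @property
    def is_timeout(self) -> bool:
        return self.choice == "timeout"


# ---------------------------------------------------------------------------
# observations and belief updates (scalar reference path)
# ---------------------------------------------------------------------------

def make_observation(
    trial: Trial,
    t: int,
    mode: str,
    sigma_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Observation entering the decision model at step ``t`` (1-based).

    ``exact``: the t-th dot position plus isotropic sensory noise;
    ``ddm_equivalent``: the constant true-target mean plus the same noise.
    """
    if not 1 <= t <= trial.n_dots:
        raise ValueError(f"step {t} out of range 1..{trial.n_dots}")
    if mode == "exact":
        mean = trial.dots[t - 1]
    elif mode == "ddm_equivalent":
        mean = trial.config.target_mean(trial.true_target)
    else:
        raise ValueError(f"unknown input mode {mode!r}")
    if sigma_s == 0.0:
        return np.array(mean, dtype=float)
    return mean + rng.normal(0.0, sigma_s, size=2)


def _log_likelihoods(obs: np.ndarray, config: TargetConfig) -> np.ndarray:
    """Unnormalized Gaussian log-likelihoods of ``obs`` under the two targets.

    The observer's generative densities are the stimulus densities:
    isotropic Gaussians at the target means with SD ``sigma_stim``.
    """
    s2 = config.sigma_stim**2
    d_left = obs - config.mu_left
    d_right = obs - config.mu_right
    return np.array(
        [-(d_left @ d_left) / (2 * s2), -(d_right @ d_right) / (2 * s2)]
    )


def belief_update(
    state: BeliefState,
    obs: np.ndarray,
    config: TargetConfig,
    discount: float = 1.0,
) -> BeliefState:
    """One recursive Bayes step: likelihood × previous belief^λ, renormalized.

    At t=0 the state holds the prior, so the first call implements the
    prior-initialized update.  Computation is in log space with a belief
    floor to keep log-probabilities finite under extreme observations.
    """
    obs = np.asarray(obs, dtype=float)
    if obs.shape != (2,) or not np.all(np.isfinite(obs)):
        raise ValueError("observation must be a finite 2-vector")
    prev = np.clip(state.beliefs, BELIEF_FLOOR, 1 - BELIEF_FLOOR)
    log_b = discount * np.log(prev) + _log_likelihoods(obs, config)
    log_b -= log_b.max()
    b = np.exp(log_b)
    b /= b.sum()
    return BeliefState(beliefs=(float(b[0]), float(b[1])), t=state.t + 1)


def bound_value(t: float, t_max: float, b0: float, s: float = 0.0, k: float = 1.0):
    """Time-varying confidence bound b(t) = b0 − s·(b0 − 0.5)·(t/t_max)^k.

    Monotonically non-increasing from b0 at t=0; s=0 keeps the bound fixed
    at b0, s=1 collapses it completely to 0.5 at t=t_max.  k < 1 front-loads
    the collapse (early drop), k > 1 delays it.  Never falls below 0.5.
    Accepts array ``t``.
    """
    if not 0.5 < b0 <= 1.0:
        raise ValueError("b0 must be in (0.5, 1]")
    if not 0.0 <= s <= 1.0:
        raise ValueError("stretch must be in [0, 1]")
    if k <= 0:
        raise ValueError("shape must be > 0")
    frac = np.clip(np.asarray(t, dtype=float) / t_max, 0.0, 1.0)
    return b0 - s * (b0 - 0.5) * frac**k


def run_accumulation(
    trial: Trial,
    params: ModelParams,
    mode: str = "exact",
    variant: str = "standard",
    rng: np.random.Generator | None = None,
    keep_trajectory: bool = False,
) -> DecisionOutcome:
    """Iterate observation + belief update until the first bound crossing.

    Returns the crossing target and 1-based decision step, or
    ``no_crossing`` if no belief reaches the bound within the trial.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if rng is None:
        rng = np.random.default_rng()
    discount = params.discount if variant == "leaky" else 1.0
    stretch = params.stretch if variant == "collapsing" else 0.0
    config = trial.config
    state = BeliefState(beliefs=(params.prior_left, 1 - params.prior_left), t=0)
    traj = [] if keep_trajectory else None
    for t in range(1, trial.n_dots + 1):
        obs = make_observation(trial, t, mode, params.sigma_s, rng)
        state = belief_update(state, obs, config, discount=discount)
        if traj is not None:
            traj.append(state.beliefs)
        b_t = float(
            bound_value(t, config.max_dots, params.bound, stretch, params.shape)
        )
        bl, br = state.beliefs
        if bl >= b_t or br >= b_t:
            if bl > br:
                choice = "left"
            elif br > bl:
                choice = "right"
            else:  # only possible at b_t == 0.5 with exactly equal beliefs
                choice = "left" if rng.random() < 0.5 else "right"
            return DecisionOutcome(
                kind="decided",
                choice=choice,
                t_d=t,
                trajectory=np.array(traj) if traj is not None else None,
            )
    return DecisionOutcome(
        kind="no_crossing",
        choice=None,
        t_d=None,
        trajectory=np.array(traj) if traj is not None else None,
    )


# ---------------------------------------------------------------------------
# non-decision time
# ---------------------------------------------------------------------------

def sample_ndt(
    ndt_mu: float, ndt_sigma: float, rng: np.random.Generator, size=None
):
    """Draw non-decision time(s) in ms from log-normal(ndt_mu, ndt_sigma)."""
    if ndt_sigma < 0:
        raise ValueError("ndt_sigma must be >= 0")
    if ndt_sigma == 0:
        val = math.exp(ndt_mu)
        return val if size is None else np.full(size, val)
    return rng.lognormal(mean=ndt_mu, sigma=ndt_sigma, size=size)


def ndt_summary(ndt_mu: float, ndt_sigma: float) -> tuple[float, float]:
    """Mode and SD (both ms) of the log-normal non-decision time.

    mode = exp(μ − σ²); sd = sqrt((exp(σ²) − 1)·exp(2μ + σ²)).
    """
    if ndt_sigma < 0:
        raise ValueError("ndt_sigma must be >= 0")
    s2 = ndt_sigma**2
    mode = math.exp(ndt_mu - s2)
    sd = math.sqrt((math.exp(s2) - 1.0) * math.exp(2 * ndt_mu + s2))
    return mode, sd


def ndt_params_from_summary(mode: float, sd: float) -> tuple[float, float]:
    """Invert :func:`ndt_summary`: (mode, sd) in ms → (ndt_mu, ndt_sigma).

    With m = mode and substituting μ = log m + σ², the SD identity reduces
    to (exp(σ²) − 1)·exp(3σ²) = (sd/m)², a scalar monotone root problem.
    """
    from scipy.optimize import brentq

    if mode <= 0:
        raise ValueError("mode must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return math.log(mode), 0.0
    ratio2 = (sd / mode) ** 2

    def f(s2: float) -> float:
        return math.expm1(s2) * math.exp(3 * s2) - ratio2

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 700:
            raise RuntimeError(
                f"ndt_params_from_summary failed to bracket a root for "
                f"mode={mode}, sd={sd}"
            )
    s2 = brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14)
    return math.log(mode) + s2, math.sqrt(s2)


# ---------------------------------------------------------------------------
# full response simulation
# ---------------------------------------------------------------------------

def simulate_response(
    trial: Trial,
    params: ModelParams,
    mode: str = "exact",
    variant: str = "standard",
    rng: np.random.Generator | None = None,
    deadline_on_total_rt: bool = False,
) -> Response:
    """Simulate one behavioural response for one trial.

    With probability ``lapse_p`` the trial is a lapse: it times out with
    probability ``lapse_to_p``, otherwise choice is a fair coin and RT is
    uniform on (0, deadline].  Otherwise the accumulator runs; no bound
    crossing within the trial is a timeout, and a decision at step t_d
    yields rt = t_d × dt_ms + a log-normal non-decision-time draw.  If
    ``deadline_on_total_rt`` the decision+NDT total is additionally
    truncated to timeout when it exceeds the deadline (off by default: the
    timeout rule applies to the decision variable).
    """
    if rng is None:
        rng = np.random.default_rng()
    deadline = trial.config.deadline_ms
    if params.lapse_p > 0 and rng.random() < params.lapse_p:
        if rng.random() < params.lapse_to_p:
            return Response(choice="timeout", provenance="lapse_timeout")
        choice = "left" if rng.random() < 0.5 else "right"
        rt = rng.uniform(0.0, deadline)
        while rt == 0.0:  # uniform on the half-open interval (0, deadline]
            rt = rng.uniform(0.0, deadline)
        return Response(choice=choice, rt_ms=rt, provenance="lapse_random")
    outcome = run_accumulation(trial, params, mode=mode, variant=variant, rng=rng)
    if outcome.kind == "no_crossing":
        return Response(choice="timeout", provenance="evidence")
    rt = outcome.t_d * trial.config.dt_ms + float(
        sample_ndt(params.ndt_mu, params.ndt_sigma, rng)
    )
    if deadline_on_total_rt and rt > deadline:
        return Response(choice="timeout", provenance="evidence")
    return Response(choice=outcome.choice, rt_ms=rt, provenance="evidence")


# ---------------------------------------------------------------------------
# vectorized batch simulation (hot path for inference and prediction)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BatchResult:
    """Vectorized simulation output: per-sample choice codes and RTs.

    ``choice`` uses integer codes (0 left, 1 right, −1 timeout); ``rt_ms``
    is NaN for timeouts.
    """

    choice: np.ndarray  # (n,) int8
    rt_ms: np.ndarray  # (n,) float, NaN for timeout

    @property
    def n(self) -> int:
        return self.choice.shape[0]

    def to_responses(self) -> list[Response]:
        out = []
        for c, rt in zip(self.choice, self.rt_ms):
            if c == TIMEOUT:
                out.append(Response(choice="timeout"))
            else:
                out.append(Response(choice=CHOICE_LABELS[int(c)], rt_ms=float(rt)))
        return out


def _param_arrays(params, n: int) -> dict[str, np.ndarray]:
    """Broadcast a ModelParams or dict-of-arrays to length-n float arrays."""
    names = (
        "sigma_s", "ndt_mu", "ndt_sigma", "bound", "prior_left",
        "lapse_p", "lapse_to_p", "discount", "stretch", "shape",
    )
    if isinstance(params, ModelParams):
        return {k: np.full(n, getattr(params, k), dtype=float) for k in names}
    out = {}
    for k in names:
        v = np.asarray(params.get(k, _PARAM_DEFAULTS[k]), dtype=float)
        out[k] = np.broadcast_to(v, (n,)).astype(float, copy=False)
    return out


_PARAM_DEFAULTS = {
    "prior_left": 0.5, "lapse_p": 0.0, "lapse_to_p": 0.0,
    "discount": 1.0, "stretch": 0.0, "shape": 1.0,
    "sigma_s": 0.0, "ndt_mu": 0.0, "ndt_sigma": 0.0, "bound": 1.0,
}


def simulate_responses_batch(
    trial: Trial,
    params,
    n: int | None = None,
    mode: str = "exact",
    variant: str = "standard",
    rng: np.random.Generator | None = None,
    deadline_on_total_rt: bool = False,
) -> BatchResult:
    """Simulate many responses to one trial, vectorized over parameter sets.

    ``params`` is either a single :class:`ModelParams` (replicated ``n``
    times) or a dict of per-sample parameter arrays.  The accumulator is run
    in log-posterior-odds space: with mirror-symmetric targets the log
    likelihood ratio of one observation depends only on its x-coordinate,
    llr_left(obs) = −2·offset·obs_x / sigma_stim², so a trial reduces to a
    1-D random walk with per-step thresholds ±logit(b(t)).  Exactly
    reproduces the distribution of :func:`simulate_response`.
    """
    if rng is None:
        rng = np.random.default_rng()
    if mode not in INPUT_MODES:
        raise ValueError(f"unknown input mode {mode!r}")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if isinstance(params, ModelParams):
        if n is None:
            raise ValueError("n required when params is a single ModelParams")
    else:
        n = len(np.asarray(params["sigma_s"]))
    P = _param_arrays(params, n)
    config = trial.config
    T = trial.n_dots
    a = config.offset
    s2 = config.sigma_stim**2

    discount = P["discount"] if variant == "leaky" else np.ones(n)
    stretch = P["stretch"] if variant == "collapsing" else np.zeros(n)

    if mode == "exact":
        mean_x = trial.dots[:, 0]  # (T,)
    else:
        mean_x = np.full(T, config.target_mean(trial.true_target)[0])

    # observations: only the x-coordinate carries evidence
    obs_x = mean_x[None, :] + P["sigma_s"][:, None] * rng.standard_normal((n, T))
    llr = -2.0 * a * obs_x / s2  # (n, T) log-odds increments for "left"

    # thresholds per step: logit of the (possibly collapsing) bound
    steps = np.arange(1, T + 1, dtype=float)
    b_t = (
        P["bound"][:, None]
        - stretch[:, None]
        * (P["bound"][:, None] - 0.5)
        * (steps[None, :] / config.max_dots) ** P["shape"][:, None]
    )  # (n, T)
    with np.errstate(divide="ignore"):
        theta = np.log(b_t) - np.log1p(-b_t)  # +inf where b_t == 1

    with np.errstate(divide="ignore"):  # prior exactly 0/1 → ∓inf log-odds
        logodds = np.log(P["prior_left"]) - np.log1p(-P["prior_left"])
    t_d = np.zeros(n, dtype=np.int64)  # 0 = not yet decided
    dec_choice = np.zeros(n, dtype=np.int8)
    for t in range(T):
        logodds = discount * logodds + llr[:, t]
        undecided = t_d == 0
        cross = undecided & (np.abs(logodds) >= theta[:, t])
        if np.any(cross):
            t_d[cross] = t + 1
            dec_choice[cross] = np.where(logodds[cross] > 0, LEFT, RIGHT)
            tie = cross & (logodds == 0.0) & (theta[:, t] == 0.0)
            if np.any(tie):
                dec_choice[tie] = np.where(
                    rng.random(int(tie.sum())) < 0.5, LEFT, RIGHT
                )

    choice = np.full(n, TIMEOUT, dtype=np.int8)
    rt = np.full(n, np.nan)
    decided = t_d > 0
    # extreme proposals may overflow to inf; an infinite RT simply never
    # matches anything downstream, which is the intended semantics
    with np.errstate(over="ignore"):
        ndt = np.where(
            P["ndt_sigma"] > 0,
            np.exp(P["ndt_mu"] + P["ndt_sigma"] * rng.standard_normal(n)),
            np.exp(P["ndt_mu"]),
        )
    choice[decided] = dec_choice[decided]
    rt[decided] = t_d[decided] * config.dt_ms + ndt[decided]
    if deadline_on_total_rt:
        late = decided & (rt > config.deadline_ms)
        choice[late] = TIMEOUT
        rt[late] = np.nan

    # lapse mixture overrides the evidence-based response
    u_lapse = rng.random(n)
    u_to = rng.random(n)
    coin = rng.random(n)
    u_rt = rng.uniform(0.0, config.deadline_ms, size=n)
    is_lapse = u_lapse < P["lapse_p"]
    lapse_to = is_lapse & (u_to < P["lapse_to_p"])
    lapse_resp = is_lapse & ~lapse_to
    choice[lapse_to] = TIMEOUT
    rt[lapse_to] = np.nan
    choice[lapse_resp] = np.where(coin[lapse_resp] < 0.5, LEFT, RIGHT)
    rt[lapse_resp] = u_rt[lapse_resp]
    return BatchResult(choice=choice, rt_ms=rt)
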