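"""Model comparison: posterior predictive likelihoods, point predictions,
choice match tables, and random-effects Bayesian model selection.

Per-trial posterior predictive likelihoods (PPLs) quantify how likely a
participant's response is under a fitted model: parameter sets are sampled
from the EP posterior, one response is simulated per set, and the PPL is
the fraction of simulated responses close to the observed one (same choice,
RT within ε).  Random-effects Bayesian model selection (RFX-BMS) treats the
model identity as a random effect across participants, estimating model
frequencies with a variational Dirichlet posterior from per-participant log
evidences, and reports exceedance and protected exceedance probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from .decision_model import LEFT, RIGHT, TIMEOUT, Response, simulate_responses_batch
from .epabc import EPPosterior, response_distance_ok
from .stimulus import Trial
from .transforms import ModelSpec

__all__ = [
    "PredictiveSet",
    "BMSResult",
    "posterior_predictive_likelihood",
    "point_prediction",
    "match_table",
    "rfx_bms",
]

N_PREDICTIVE_DEFAULT = 15000


@dataclass(frozen=True)
class PredictiveSet:
    """Simulated posterior-predictive responses for one trial."""

    trial_id: str
    choice: np.ndarray = field(repr=False)  # (n,) int codes
    rt_ms: np.ndarray = field(repr=False)  # (n,) NaN for timeout
    n: int = 0
    source: str = ""


def _simulate_predictive(
    trial: Trial,
    posterior: EPPosterior,
    spec: ModelSpec,
    n: int,
    rng: np.random.Generator,
) -> PredictiveSet:
    z = posterior.sample(n, rng)
    params = spec.to_model_space(z)
    sim = simulate_responses_batch(
        trial, params, mode=spec.mode, variant=spec.variant, rng=rng,
        deadline_on_total_rt=spec.deadline_on_total_rt,
    )
    return PredictiveSet(
        trial_id=trial.trial_id, choice=sim.choice, rt_ms=sim.rt_ms, n=n,
        source=f"{spec.mode}/{spec.variant}",
    )


def posterior_predictive_likelihood(
    trial: Trial,
    obs: Response,
    posterior: EPPosterior,
    spec: ModelSpec,
    n: int = N_PREDICTIVE_DEFAULT,
    eps_ms: float = 46.6,
    rng: np.random.Generator | None = None,
    floor_zero: bool = True,
) -> float:
    """Fraction of n posterior-predictive simulations close to ``obs``.

    One parameter set is drawn from the posterior per simulation.  A zero
    count is floored at 1/(n+1) so log-PPLs stay finite.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    pred = _simulate_predictive(trial, posterior, spec, n, rng)
    if obs.is_timeout:
        k = int((pred.choice == TIMEOUT).sum())
    else:
        code = LEFT if obs.choice == "left" else RIGHT
        with np.errstate(invalid="ignore"):
            k = int(
                ((pred.choice == code) & (np.abs(pred.rt_ms - obs.rt_ms) < eps_ms)).sum()
            )
    if k == 0 and floor_zero:
        return 1.0 / (n + 1)
    return k / n


def point_prediction(
    trial: Trial,
    posterior: EPPosterior,
    spec: ModelSpec,
    n: int = N_PREDICTIVE_DEFAULT,
    rng: np.random.Generator | None = None,
) -> Response:
    """Modal predicted response for one trial.

    Choice: the more frequent non-timeout alternative among n simulations
    (ties broken toward left).  RT: the centre of the most frequent
    dt_ms-wide bin among simulations with that choice (ties toward the
    earlier bin).  All-timeout simulations predict a timeout.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    pred = _simulate_predictive(trial, posterior, spec, n, rng)
    n_left = int((pred.choice == LEFT).sum())
    n_right = int((pred.choice == RIGHT).sum())
    if n_left == 0 and n_right == 0:
        return Response(choice="timeout")
    choice_code = LEFT if n_left >= n_right else RIGHT
    choice = "left" if choice_code == LEFT else "right"
    rts = pred.rt_ms[pred.choice == choice_code]
    dt = trial.config.dt_ms
    # dt-aligned histogram; argmax takes the first (earliest) maximal bin
    bins = np.floor(rts / dt).astype(int)
    counts = np.bincount(bins)
    modal_bin = int(counts.argmax())
    rt_hat = (modal_bin + 0.5) * dt
    return Response(choice=choice, rt_ms=rt_hat)


def match_table(
    predictions: list[Response],
    observed: list[Response],
    truth: list[str],
) -> dict:
    """2×2 confusion of model vs participant correctness, plus match rate.

    ``truth`` holds the true target per trial.  Proportions are over trials
    where both model and participant produced a non-timeout choice.
    """
    if not (len(predictions) == len(observed) == len(truth)):
        raise ValueError("predictions, observed and truth must align")
    if len(predictions) == 0:
        raise ValueError("empty input")
    table = np.zeros((2, 2))
    n_used = 0
    n_match = 0
    n_both = 0
    for pred, obs, t in zip(predictions, observed, truth):
        if pred.choice == obs.choice:
            n_match += 1
        if pred.is_timeout or obs.is_timeout:
            continue
        n_both += 1
        i = 0 if pred.choice == t else 1  # model correct / incorrect
        j = 0 if obs.choice == t else 1  # participant correct / incorrect
        table[i, j] += 1
        n_used += 1
    if n_used:
        table /= n_used
    return {
        "table": table,  # rows: model correct/incorrect; cols: participant
        "match_rate": n_match / len(predictions),
        "n_trials": len(predictions),
        "n_both_responded": n_both,
    }


@dataclass(frozen=True)
class BMSResult:
    """Random-effects Bayesian model selection output."""

    expected_frequencies: np.ndarray  # (M,) posterior model probabilities
    exceedance_p: np.ndarray  # (M,)
    protected_exceedance_p: np.ndarray  # (M,)
    bor: float  # Bayes omnibus risk
    alpha: np.ndarray  # (M,) Dirichlet posterior counts


def rfx_bms(
    log_evidence: np.ndarray,
    n_mc: int = 1_000_000,
    rng: np.random.Generator | None = None,
    alpha0: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> BMSResult:
    """Random-effects BMS over a (participants × models) log-evidence matrix.

    Variational Dirichlet estimation of population model frequencies
    (uniform Dirichlet(α₀=1) prior), exceedance probabilities by Monte
    Carlo over the Dirichlet posterior, and protected exceedance
    probabilities PXP = EP·(1−BOR) + BOR/M, where the Bayes omnibus risk
    BOR compares the random-effects model against the null hypothesis of
    equal frequencies.
    """
    if rng is None:
        rng = np.random.default_rng()
    lme = np.asarray(log_evidence, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 model columns")
    if not np.all(np.isfinite(lme)):
        n_bad, m_bad = np.argwhere(~np.isfinite(lme))[0]
        raise ValueError(
            f"non-finite log evidence for participant {n_bad}, model {m_bad}"
        )
    N, M = lme.shape
    a0 = np.full(M, float(alpha0))
    alpha = a0.copy()
    u = np.zeros((N, M))
    for _ in range(max_iter):
        e_ln_r = digamma(alpha) - digamma(alpha.sum())
        logu = lme + e_ln_r
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = a0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    freq = alpha / alpha.sum()
    # exceedance probabilities by Dirichlet Monte Carlo
    draws = rng.dirichlet(alpha, size=n_mc)
    winners = np.argmax(draws, axis=1)
    ep = np.bincount(winners, minlength=M) / n_mc

    # free energy of the RFX model (variational bound)
    e_ln_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy_u = -np.where(u > 0, u * np.log(u), 0.0).sum()
    f1 = (
        float((u * (lme + e_ln_r)).sum())
        + entropy_u
        + gammaln(a0.sum()) - gammaln(a0).sum()
        - gammaln(alpha.sum()) + gammaln(alpha).sum()
        + float(((a0 - alpha) * e_ln_r).sum())
    )
    # null model: all participants share equal model frequencies
    f0 = float(logsumexp(lme, axis=1).sum() - N * math.log(M))
    bor = 1.0 / (1.0 + math.exp(min(f1 - f0, 700.0)))
    pxp = ep * (1.0 - bor) + bor / M
    return BMSResult(
        expected_frequencies=freq,
        exceedance_p=ep,
        protected_exceedance_p=pxp,
        bor=bor,
        alpha=alpha,
    )
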