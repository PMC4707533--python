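"""Likelihood-free posterior inference via Expectation Propagation ABC.

The posterior over the unconstrained parameter vector z (standard-normal
prior) is approximated as a product of Gaussian factors, one "site" per
trial.  To update a site, parameter proposals are drawn from the cavity
(the approximation with that site removed), one response is simulated per
proposal, and proposals whose simulated response is close to the observed
one (same choice, RT within ε) are accepted.  Once a minimum number of
acceptances is reached, the global Gaussian is moment-matched to the
accepted samples and the site factor is set to the ratio of new global to
cavity.  The accumulated site normalizers yield the log model evidence.

The EP core is generic over a per-datum acceptance simulator, which allows
validating it on analytically tractable toy problems as well as running the
behavioural decision model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .decision_model import (
    LEFT,
    RIGHT,
    TIMEOUT,
    Response,
    simulate_responses_batch,
)
from .stimulus import Trial
from .transforms import ModelSpec

__all__ = [
    "FitSettings",
    "EPPosterior",
    "response_distance_ok",
    "ep_site_update",
    "fit",
    "rejection_abc",
    "FitError",
]

logger = logging.getLogger(__name__)

EPS_MS_DEFAULT = 46.6  # half the 93.2 ms dot duration

_CHOICE_CODE = {"left": LEFT, "right": RIGHT, "timeout": TIMEOUT}


class FitError(RuntimeError):
    """Raised when EP-ABC cannot produce a usable posterior."""


@dataclass(frozen=True)
class FitSettings:
    """EP-ABC run settings."""

    eps_ms: float = EPS_MS_DEFAULT
    min_accepted: int = 300
    passes: int = 4
    max_proposals_per_site: int | None = None  # default 200 × min_accepted
    #: if the proposal budget runs out with at least this many acceptances,
    #: the site is still updated with extra damping instead of being skipped
    min_accepted_partial: int = 50
    batch_size: int = 1024
    #: fractional site-update step; sequential moment matching with a few
    #: hundred accepted samples is a noisy fixed-point iteration, and full
    #: steps let that noise walk the posterior into absorbing corners on
    #: datasets of hundreds of trials
    damping: float = 0.35
    cavity_var_floor: float = 1e-8
    max_skip_fraction: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.eps_ms <= 0:
            raise ValueError("eps_ms must be > 0")
        if self.min_accepted < 1:
            raise ValueError("min_accepted must be >= 1")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must be in (0, 1]")

    @property
    def proposal_budget(self) -> int:
        if self.max_proposals_per_site is not None:
            return self.max_proposals_per_site
        return 200 * self.min_accepted


@dataclass
class EPPosterior:
    """Gaussian EP posterior in natural parameters, plus per-site factors.

    The global Gaussian is prior × ∏ sites; ``site_r``/``site_Q`` hold each
    site's natural parameters (precision-mean vector, precision matrix) and
    ``site_c`` its log normalizer contribution.  ``mean``/``cov`` are the
    moment parameters of the global Gaussian.
    """

    r: np.ndarray  # (d,) global precision-mean
    Q: np.ndarray  # (d, d) global precision
    site_r: np.ndarray  # (n_sites, d)
    site_Q: np.ndarray  # (n_sites, d, d)
    site_c: np.ndarray  # (n_sites,)
    settings_used: FitSettings | None = None
    n_skipped: int = 0

    @classmethod
    def from_prior(cls, n_params: int, n_sites: int,
                   settings: FitSettings | None = None) -> "EPPosterior":
        return cls(
            r=np.zeros(n_params),
            Q=np.eye(n_params),
            site_r=np.zeros((n_sites, n_params)),
            site_Q=np.zeros((n_sites, n_params, n_params)),
            site_c=np.zeros(n_sites),
            settings_used=settings,
        )

    @property
    def n_sites(self) -> int:
        return self.site_r.shape[0]

    @property
    def cov(self) -> np.ndarray:
        return np.linalg.inv(self.Q)

    @property
    def mean(self) -> np.ndarray:
        return np.linalg.solve(self.Q, self.r)

    @property
    def log_evidence(self) -> float:
        d = self.r.shape[0]
        return float(
            self.site_c.sum() + _log_partition(self.r, self.Q)
            - 0.5 * d * math.log(2 * math.pi)  # ψ of the standard-normal prior
        )

    def copy(self) -> "EPPosterior":
        return EPPosterior(
            r=self.r.copy(), Q=self.Q.copy(),
            site_r=self.site_r.copy(), site_Q=self.site_Q.copy(),
            site_c=self.site_c.copy(), settings_used=self.settings_used,
            n_skipped=self.n_skipped,
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n vectors from the global Gaussian."""
        cov = _ensure_psd(self.cov)
        return rng.multivariate_normal(self.mean, cov, size=n,
                                       method="cholesky")


def _log_partition(r: np.ndarray, Q: np.ndarray) -> float:
    """ψ(r, Q) = log ∫ exp(rᵀz − ½ zᵀQz) dz for positive-definite Q."""
    d = r.shape[0]
    L = np.linalg.cholesky(Q)
    half_logdet = np.log(np.diag(L)).sum()
    y = np.linalg.solve(L, r)
    return float(0.5 * (y @ y) + 0.5 * d * math.log(2 * math.pi) - half_logdet)


def _ensure_psd(M: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    if w.min() < floor:
        w = np.maximum(w, floor)
        M = (V * w) @ V.T
        M = 0.5 * (M + M.T)
    return M


def response_distance_ok(sim: Response, obs: Response, eps_ms: float) -> bool:
    """ABC distance criterion for a single trial.

    True iff the choices match and the RT difference is strictly below
    ``eps_ms``.  Timeout matches timeout regardless of RT (timeouts carry
    none).
    """
    if sim.choice != obs.choice:
        return False
    if obs.is_timeout:
        return True
    return abs(sim.rt_ms - obs.rt_ms) < eps_ms


def _acceptance_mask_behavioural(
    trial: Trial,
    obs: Response,
    spec: ModelSpec,
    z: np.ndarray,
    eps_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one response per proposal row of z; mask of ABC acceptances."""
    params = spec.to_model_space(z)
    sim = simulate_responses_batch(
        trial, params, mode=spec.mode, variant=spec.variant, rng=rng,
        deadline_on_total_rt=spec.deadline_on_total_rt,
    )
    obs_code = _CHOICE_CODE[obs.choice]
    if obs.is_timeout:
        return sim.choice == TIMEOUT
    with np.errstate(invalid="ignore"):
        return (sim.choice == obs_code) & (np.abs(sim.rt_ms - obs.rt_ms) < eps_ms)


@dataclass(frozen=True)
class _SiteProblem:
    """One EP data point: acceptance simulator + evidence window normalizer."""

    accept: object  # callable (z, rng) -> bool mask
    window_log_norm: float  # log of the ABC window volume (2ε for RT data)


def behavioural_site(trial: Trial, obs: Response, spec: ModelSpec,
                     eps_ms: float) -> _SiteProblem:
    window = 0.0 if obs.is_timeout else math.log(2.0 * eps_ms)
    return _SiteProblem(
        accept=lambda z, rng: _acceptance_mask_behavioural(
            trial, obs, spec, z, eps_ms, rng
        ),
        window_log_norm=window,
    )


#: cap on cavity variance, in units of the unit-variance prior; keeps
#: proposal distributions sane when site precisions turn negative
_CAVITY_VAR_CAP = 100.0


def _cavity(state: EPPosterior, i: int, var_floor: float):
    Q_cav = state.Q - state.site_Q[i]
    r_cav = state.r - state.site_r[i]
    # repair: cavity must be a proper distribution with bounded variance
    # (precision between 1/var_cap and 1/var_floor on every axis)
    Q_cav = 0.5 * (Q_cav + Q_cav.T)
    w, V = np.linalg.eigh(Q_cav)
    w = np.clip(w, 1.0 / _CAVITY_VAR_CAP, 1.0 / var_floor)
    Q_cav = (V * w) @ V.T
    Q_cav = 0.5 * (Q_cav + Q_cav.T)
    return r_cav, Q_cav


def _site_update_core(
    state: EPPosterior,
    i: int,
    problem: _SiteProblem,
    settings: FitSettings,
    rng: np.random.Generator,
) -> bool:
    """Update site i in place.  Returns False when the site was skipped."""
    d = state.r.shape[0]
    r_cav, Q_cav = _cavity(state, i, settings.cavity_var_floor)
    L = np.linalg.cholesky(Q_cav)
    mean_cav = np.linalg.solve(Q_cav, r_cav)

    accepted: list[np.ndarray] = []
    n_acc = 0
    n_prop = 0
    budget = settings.proposal_budget
    batch = settings.batch_size
    while n_acc < settings.min_accepted and n_prop < budget:
        m = min(batch, budget - n_prop)
        xi = rng.standard_normal((m, d))
        z = mean_cav + np.linalg.solve(L.T, xi.T).T  # Σ_cav = (LLᵀ)⁻¹
        mask = problem.accept(z, rng)
        n_prop += m
        k = int(mask.sum())
        if k:
            accepted.append(z[mask])
            n_acc += k
        # grow batches when acceptance is low to cut python overhead
        rate = max(n_acc, 1) / n_prop
        need = settings.min_accepted - n_acc
        batch = int(np.clip(1.2 * need / rate, settings.batch_size, 65536))

    acc_rate = n_acc / n_prop if n_prop else 0.0
    # evidence contribution uses the achieved acceptance rate (floored so a
    # zero-acceptance site stays finite)
    log_acc = math.log(max(acc_rate, 1.0 / (n_prop + 1)))
    psi_cav = _log_partition(r_cav, Q_cav)

    if n_acc < settings.min_accepted_partial:
        # proposal budget exhausted with too few acceptances for moment
        # estimates: keep the site factor, record evidence from the achieved
        # acceptance rate
        logger.warning(
            "site %d skipped: %d/%d accepted (< %d)",
            i, n_acc, n_prop, settings.min_accepted_partial,
        )
        state.site_c[i] = log_acc - problem.window_log_norm
        return False

    Z = np.concatenate(accepted, axis=0)
    Z = Z[np.all(np.isfinite(Z), axis=1)]
    n_eff = Z.shape[0]
    m_hat = Z.mean(axis=0)
    S_hat = np.atleast_2d(np.cov(Z, rowvar=False, bias=False))
    # invert by eigendecomposition with a relative eigenvalue floor so the
    # moment-matched precision is always well defined; the (n−d−2)/(n−1)
    # factor removes the inverse-Wishart bias of inv(S_hat), which otherwise
    # compounds over hundreds of site updates into variance collapse
    S_hat = 0.5 * (S_hat + S_hat.T)
    w, V = np.linalg.eigh(S_hat)
    w = np.clip(w, max(w.max(), 1.0) * 1e-12 + settings.cavity_var_floor, None)
    debias = max(n_eff - d - 2, 1) / max(n_eff - 1, 1)
    Q_new = debias * ((V * (1.0 / w)) @ V.T)
    Q_new = 0.5 * (Q_new + Q_new.T)
    r_new = Q_new @ m_hat

    dQ = Q_new - Q_cav
    dr = r_new - r_cav
    # under-sampled sites (budget ran out before min_accepted) get extra
    # damping in proportion to how incomplete their sample is
    eta = settings.damping * min(1.0, n_eff / settings.min_accepted)
    if eta < 1.0:
        dQ = (1 - eta) * state.site_Q[i] + eta * dQ
        dr = (1 - eta) * state.site_r[i] + eta * dr
    Q_glob = Q_cav + dQ
    r_glob = r_cav + dr
    Q_glob = _ensure_psd(Q_glob, floor=settings.cavity_var_floor)

    state.site_Q[i] = Q_glob - Q_cav
    state.site_r[i] = r_glob - r_cav
    state.Q = Q_glob
    state.r = r_glob
    state.site_c[i] = (
        log_acc - problem.window_log_norm + psi_cav - _log_partition(r_glob, Q_glob)
    )
    return True


def ep_site_update(
    state: EPPosterior,
    trial: Trial,
    obs: Response,
    spec: ModelSpec,
    settings: FitSettings,
    rng: np.random.Generator,
    site_index: int = 0,
) -> EPPosterior:
    """Functional single-site EP-ABC update (returns a new posterior)."""
    new = state.copy()
    ok = _site_update_core(
        new, site_index, behavioural_site(trial, obs, spec, settings.eps_ms),
        settings, rng,
    )
    if not ok:
        new.n_skipped += 1
    return new


def fit(
    trials: list[Trial],
    responses: list[Response],
    spec: ModelSpec,
    settings: FitSettings | None = None,
    rng: np.random.Generator | None = None,
    site_problems: list[_SiteProblem] | None = None,
    n_params: int | None = None,
) -> EPPosterior:
    """Fit the decision model to one participant-condition dataset.

    Runs ``settings.passes`` sweeps of single-site updates over all trials.
    An empty dataset returns the prior with zero log evidence.  Fully
    deterministic given (dataset, settings, seed).

    ``site_problems``/``n_params`` allow supplying custom data points
    (acceptance simulators) instead of trial/response pairs; used for
    validating the EP core on tractable toy problems.
    """
    if settings is None:
        settings = FitSettings()
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    if site_problems is None:
        if len(trials) != len(responses):
            raise ValueError("trials and responses must align")
        site_problems = [
            behavioural_site(tr, ob, spec, settings.eps_ms)
            for tr, ob in zip(trials, responses)
        ]
        n_params = spec.n_params
    if n_params is None:
        raise ValueError("n_params required with custom site problems")

    n_sites = len(site_problems)
    state = EPPosterior.from_prior(n_params, n_sites, settings)
    if n_sites == 0:
        return state

    n_skipped_last_pass = 0
    for p in range(settings.passes):
        n_skipped_last_pass = 0
        for i, problem in enumerate(site_problems):
            ok = _site_update_core(state, i, problem, settings, rng)
            if not ok:
                n_skipped_last_pass += 1
        logger.info(
            "EP-ABC pass %d/%d: %d/%d sites skipped",
            p + 1, settings.passes, n_skipped_last_pass, n_sites,
        )
    state.n_skipped = n_skipped_last_pass
    if n_skipped_last_pass > settings.max_skip_fraction * n_sites:
        raise FitError(
            f"{n_skipped_last_pass}/{n_sites} sites skipped in the final "
            "pass; posterior unusable"
        )
    return state


def rejection_abc(
    trials: list[Trial],
    responses: list[Response],
    spec: ModelSpec,
    eps_ms: float,
    n_samples: int,
    rng: np.random.Generator | None = None,
    batch_size: int = 4096,
) -> np.ndarray:
    """Brute-force rejection ABC over the whole (tiny) dataset.

    Draws ``n_samples`` vectors from the standard-normal prior, simulates
    every trial once per draw, and accepts a draw iff all trials pass the
    distance criterion.  Returns the accepted unconstrained vectors.
    Intended as an oracle for EP-ABC on datasets of a handful of trials.
    """
    if rng is None:
        rng = np.random.default_rng()
    if len(trials) != len(responses):
        raise ValueError("trials and responses must align")
    d = spec.n_params
    out = []
    done = 0
    while done < n_samples:
        m = min(batch_size, n_samples - done)
        z = rng.standard_normal((m, d))
        mask = np.ones(m, dtype=bool)
        for tr, ob in zip(trials, responses):
            mask &= _acceptance_mask_behavioural(tr, ob, spec, z, eps_ms, rng)
        if mask.any():
            out.append(z[mask])
        done += m
    if not out:
        raise FitError(
            f"rejection ABC: zero acceptances in {n_samples} prior draws"
        )
    return np.concatenate(out, axis=0)
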