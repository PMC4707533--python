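"""Single-dot tracking stimuli.

A trial shows one white dot jumping around one of two mirror-symmetric
targets placed at ±offset pixels from the screen centre on the horizontal
axis.  Every ``dt_ms`` the dot jumps to a fresh position drawn from an
isotropic 2-D Gaussian centred on the true target with per-axis SD
``sigma_stim``.  The observer must report the generating target within
``max_dots`` jumps.

Coordinate frame: origin at screen centre, x rightward positive, y downward
positive, units in pixels.  Targets sit on the centre row (y = 0); the task
defines only horizontal offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CONDITION_OFFSETS",
    "TargetConfig",
    "Trial",
    "make_target_config",
    "sample_trial",
    "generate_session",
    "shuffle_session",
]

#: Canonical difficulty labels mapped to horizontal target offsets (px).
#: D1 is hardest (targets nearly overlap), D4 easiest.
CONDITION_OFFSETS: dict[str, float] = {"D1": 10.0, "D2": 25.0, "D3": 40.0, "D4": 55.0}

SIGMA_STIM_DEFAULT = 70.0
DT_MS_DEFAULT = 93.2
MAX_DOTS_DEFAULT = 25


class ConfigurationError(ValueError):
    """Raised for invalid stimulus configuration."""


@dataclass(frozen=True)
class TargetConfig:
    """Geometry and timing of one difficulty condition."""

    condition: str
    offset: float
    sigma_stim: float = SIGMA_STIM_DEFAULT
    dt_ms: float = DT_MS_DEFAULT
    max_dots: int = MAX_DOTS_DEFAULT

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ConfigurationError(f"offset must be positive, got {self.offset}")
        if self.sigma_stim <= 0:
            raise ConfigurationError("sigma_stim must be positive")
        if self.dt_ms <= 0:
            raise ConfigurationError("dt_ms must be positive")
        if self.max_dots < 1:
            raise ConfigurationError("max_dots must be >= 1")

    @property
    def mu_left(self) -> np.ndarray:
        """Left target mean (px)."""
        return np.array([-self.offset, 0.0])

    @property
    def mu_right(self) -> np.ndarray:
        """Right target mean (px)."""
        return np.array([self.offset, 0.0])

    def target_mean(self, side: str) -> np.ndarray:
        if side == "left":
            return self.mu_left
        if side == "right":
            return self.mu_right
        raise ConfigurationError(f"unknown side {side!r}")

    @property
    def deadline_ms(self) -> float:
        """Trial deadline: max_dots × dot duration."""
        return self.max_dots * self.dt_ms


@dataclass(frozen=True)
class Trial:
    """One stimulus presentation: ordered dot positions around a true target."""

    trial_id: str
    config: TargetConfig
    true_target: str  # "left" | "right"
    dots: np.ndarray = field(repr=False)  # (n_dots, 2) float array, px

    def __post_init__(self) -> None:
        dots = np.asarray(self.dots, dtype=float)
        if dots.ndim != 2 or dots.shape[1] != 2:
            raise ConfigurationError("dots must be an (n, 2) array")
        if dots.shape[0] > self.config.max_dots:
            raise ConfigurationError("more dots than config.max_dots")
        if not np.all(np.isfinite(dots)):
            raise ConfigurationError("dot coordinates must be finite")
        if self.true_target not in ("left", "right"):
            raise ConfigurationError(f"invalid true_target {self.true_target!r}")
        object.__setattr__(self, "dots", dots)

    @property
    def n_dots(self) -> int:
        return self.dots.shape[0]


def make_target_config(
    condition: str,
    *,
    offset: float | None = None,
    sigma_stim: float = SIGMA_STIM_DEFAULT,
    dt_ms: float = DT_MS_DEFAULT,
    max_dots: int = MAX_DOTS_DEFAULT,
) -> TargetConfig:
    """Build the configuration for a difficulty condition.

    Canonical labels D1..D4 map to offsets 10/25/40/55 px.  A custom
    ``offset`` may be supplied with any label.
    """
    if offset is None:
        try:
            offset = CONDITION_OFFSETS[condition]
        except KeyError:
            raise ConfigurationError(
                f"unknown condition {condition!r}; expected one of "
                f"{sorted(CONDITION_OFFSETS)} or an explicit offset"
            ) from None
    return TargetConfig(
        condition=condition,
        offset=float(offset),
        sigma_stim=sigma_stim,
        dt_ms=dt_ms,
        max_dots=max_dots,
    )


def sample_trial(
    config: TargetConfig,
    true_target: str,
    rng: np.random.Generator,
    trial_id: str = "t0",
) -> Trial:
    """Draw one trial: max_dots i.i.d. dot positions around the true target."""
    mu = config.target_mean(true_target)
    dots = rng.normal(loc=mu, scale=config.sigma_stim, size=(config.max_dots, 2))
    return Trial(trial_id=trial_id, config=config, true_target=true_target, dots=dots)


def generate_session(
    design: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
    *,
    seed: int | None = None,
    sigma_stim: float = SIGMA_STIM_DEFAULT,
    dt_ms: float = DT_MS_DEFAULT,
    max_dots: int = MAX_DOTS_DEFAULT,
) -> list[Trial]:
    """Generate the full stimulus set for one session.

    ``design`` maps condition label -> trials per side (default: 100 per side
    for each of D1..D4, i.e. 800 trials total).  The returned order is the
    canonical one (by condition, then side, then index); use
    :func:`shuffle_session` for per-participant randomized orderings of the
    same set.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if design is None:
        design = {c: 100 for c in CONDITION_OFFSETS}
    trials: list[Trial] = []
    for condition in design:
        n_per_side = design[condition]
        if n_per_side < 0:
            raise ConfigurationError(f"negative trial count for {condition}")
        config = make_target_config(
            condition, sigma_stim=sigma_stim, dt_ms=dt_ms, max_dots=max_dots
        )
        for side in ("left", "right"):
            for i in range(n_per_side):
                tid = f"{condition}_{side}_{i:03d}"
                trials.append(sample_trial(config, side, rng, trial_id=tid))
    return trials


def shuffle_session(
    trials: list[Trial], rng: np.random.Generator
) -> list[Trial]:
    """A randomized ordering (permutation) of one shared trial set.

    The study reused identical stimuli across participants; each participant
    gets a fresh permutation of the same trials.
    """
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]
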