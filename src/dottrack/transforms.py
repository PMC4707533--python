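"""Parameter transforms between the unconstrained inference space and model space.

EP-ABC approximates the posterior with a multivariate Gaussian over an
unconstrained vector z with a standard-normal prior.  Constraints and
non-Gaussian priors are implemented by pushing z through element-wise
transforms:

* ``identity`` — affine, param = offset + scale·z (Gaussian prior).
* ``exponential`` — param = exp(offset + scale·z), mapping the real line to
  positives (log-normal prior).
* ``uniform`` — param = offset + range·Φ(z) with Φ the standard-normal CDF
  (uniform prior on [offset, offset + range]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = ["ParamTransform", "ModelSpec", "default_transforms", "PARAM_ORDER"]


@dataclass(frozen=True)
class ParamTransform:
    """One element-wise transform from the unconstrained space."""

    name: str
    kind: str  # "identity" | "exponential" | "uniform"
    offset: float = 0.0
    scale: float = 1.0  # identity / exponential
    range: float = 1.0  # uniform

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "exponential", "uniform"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "uniform" and self.range <= 0:
            raise ValueError("uniform transform needs range > 0")

    def forward(self, z):
        z = np.asarray(z, dtype=float)
        if self.kind == "identity":
            return self.offset + self.scale * z
        if self.kind == "exponential":
            return np.exp(self.offset + self.scale * z)
        return self.offset + self.range * ndtr(z)

    def inverse(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "identity":
            return (x - self.offset) / self.scale
        if self.kind == "exponential":
            if np.any(x <= 0):
                raise ValueError(f"{self.name}: exponential image is positive")
            return (np.log(x) - self.offset) / self.scale
        u = (x - self.offset) / self.range
        if np.any(u <= 0) or np.any(u >= 1):
            raise ValueError(
                f"{self.name}: value outside open interval "
                f"({self.offset}, {self.offset + self.range})"
            )
        return ndtri(u)


#: Parameter ordering per variant (standard has 7 core parameters).
PARAM_ORDER = {
    "standard": (
        "sigma_s", "ndt_mu", "ndt_sigma", "bound",
        "prior_left", "lapse_p", "lapse_to_p",
    ),
    "leaky": (
        "sigma_s", "ndt_mu", "ndt_sigma", "bound",
        "prior_left", "lapse_p", "lapse_to_p", "discount",
    ),
    "collapsing": (
        "sigma_s", "ndt_mu", "ndt_sigma", "bound",
        "prior_left", "lapse_p", "lapse_to_p", "stretch", "shape",
    ),
}

# Default priors, chosen wide enough to cover all plausible parameter values
# for this task while respecting hard constraints (positive SDs,
# probabilities in their ranges).  All are overridable per fit.
_DEFAULTS = {
    "sigma_s": ParamTransform("sigma_s", "exponential", offset=np.log(50.0), scale=1.0),
    "ndt_mu": ParamTransform("ndt_mu", "identity", offset=6.0, scale=0.5),
    "ndt_sigma": ParamTransform(
        "ndt_sigma", "exponential", offset=np.log(0.35), scale=0.7
    ),
    "bound": ParamTransform("bound", "uniform", offset=0.5, range=0.5),
    "prior_left": ParamTransform("prior_left", "uniform", offset=0.0, range=1.0),
    "lapse_p": ParamTransform("lapse_p", "uniform", offset=0.0, range=0.3),
    "lapse_to_p": ParamTransform("lapse_to_p", "uniform", offset=0.0, range=1.0),
    "discount": ParamTransform("discount", "uniform", offset=0.0, range=1.0),
    "stretch": ParamTransform("stretch", "uniform", offset=0.0, range=1.0),
    "shape": ParamTransform("shape", "exponential", offset=0.0, scale=0.7),
}


def default_transforms(
    variant: str = "standard",
    overrides: dict[str, ParamTransform] | None = None,
) -> list[ParamTransform]:
    """Default transform list (hence priors) for a model variant."""
    if variant not in PARAM_ORDER:
        raise ValueError(f"unknown variant {variant!r}")
    table = dict(_DEFAULTS)
    if overrides:
        table.update(overrides)
    return [table[name] for name in PARAM_ORDER[variant]]


@dataclass(frozen=True)
class ModelSpec:
    """Input mode + accumulation variant + parameter transforms.

    Fixes which free parameters exist, their order in the unconstrained
    vector, and the priors implied by the transforms.
    """

    mode: str  # "exact" | "ddm_equivalent"
    variant: str = "standard"
    transforms: tuple[ParamTransform, ...] = ()
    deadline_on_total_rt: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "ddm_equivalent"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.variant not in PARAM_ORDER:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not self.transforms:
            object.__setattr__(
                self, "transforms", tuple(default_transforms(self.variant))
            )
        if len(self.transforms) != len(PARAM_ORDER[self.variant]):
            raise ValueError(
                f"{self.variant} needs {len(PARAM_ORDER[self.variant])} "
                f"transforms, got {len(self.transforms)}"
            )

    @property
    def n_params(self) -> int:
        return len(self.transforms)

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_ORDER[self.variant]

    def to_model_space(self, z: np.ndarray) -> dict[str, np.ndarray]:
        """Map unconstrained vectors (n, d) or (d,) to named parameter arrays."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.n_params:
            raise ValueError(f"expected {self.n_params} columns, got {z.shape[1]}")
        return {
            name: tr.forward(z[:, j])
            for j, (name, tr) in enumerate(zip(self.param_names, self.transforms))
        }

    def to_model_params(self, z: np.ndarray):
        """Map one unconstrained vector to a :class:`ModelParams`."""
        from .decision_model import ModelParams

        d = self.to_model_space(np.asarray(z, dtype=float).reshape(1, -1))
        return ModelParams(**{k: float(v[0]) for k, v in d.items()})

    def from_model_space(self, params: dict[str, np.ndarray]) -> np.ndarray:
        """Exact inverse of :meth:`to_model_space` on the transform image."""
        cols = [
            np.atleast_1d(tr.inverse(params[name]))
            for name, tr in zip(self.param_names, self.transforms)
        ]
        return np.stack(cols, axis=1)
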