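"""File formats: trial/response CSV, posterior JSON, evidence and BMS files.

CSV dialect: UTF-8, comma-separated, mandatory header, '.' decimal
separator.  Trials are stored long-format (one row per dot) and round-trip
bit-exactly at 6 decimal places.  Structured artifacts (posteriors, BMS
results) are JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .comparison import BMSResult
from .decision_model import Response
from .epabc import EPPosterior, FitSettings
from .stimulus import Trial, make_target_config

__all__ = [
    "ParseError",
    "write_trials",
    "read_trials",
    "write_responses",
    "read_responses",
    "export_belief_trajectories",
    "write_posterior",
    "read_posterior",
    "write_bms_result",
    "read_evidence_matrix",
    "write_evidence_matrix",
    "derive_seed",
]

COORD_DECIMALS = 6


class ParseError(ValueError):
    """Malformed input file."""


def derive_seed(master_seed: int, stage: str) -> np.random.Generator:
    """Per-stage random stream derived by stable hashing of the stage name."""
    import zlib

    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

def write_trials(trials: list[Trial], path: str | Path) -> None:
    """Long-format CSV: trial_id, condition, true_target, dot_index, x_px, y_px."""
    rows = []
    for tr in trials:
        for j in range(tr.n_dots):
            rows.append(
                (
                    tr.trial_id,
                    tr.config.condition,
                    tr.true_target,
                    j + 1,
                    round(float(tr.dots[j, 0]), COORD_DECIMALS),
                    round(float(tr.dots[j, 1]), COORD_DECIMALS),
                )
            )
    df = pd.DataFrame(
        rows,
        columns=["trial_id", "condition", "true_target", "dot_index", "x_px", "y_px"],
    )
    df.to_csv(path, index=False, float_format=f"%.{COORD_DECIMALS}f")


def read_trials(
    path: str | Path,
    sigma_stim: float = 70.0,
    dt_ms: float = 93.2,
    max_dots: int = 25,
) -> list[Trial]:
    """Read a long-format trials CSV, preserving file order of trials."""
    try:
        df = pd.read_csv(path)
    except Exception as e:  # noqa: BLE001
        raise ParseError(f"{path}: cannot parse CSV ({e})") from e
    required = {"trial_id", "condition", "true_target", "dot_index", "x_px", "y_px"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col in ("dot_index", "x_px", "y_px"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[~df[col].apply(lambda v: isinstance(v, (int, float)))].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ParseError(f"{path}: non-numeric {col} near line {line}")
        if df[col].isna().any():
            line = int(df[df[col].isna()].index[0]) + 2
            raise ParseError(f"{path}: missing {col} at line {line}")
    trials: list[Trial] = []
    configs: dict[str, object] = {}
    for trial_id, g in df.groupby("trial_id", sort=False):
        idx = g["dot_index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise ParseError(f"{path}: duplicate dot_index in trial {trial_id}")
        expected = np.arange(1, len(idx) + 1)
        if not np.array_equal(np.sort(idx), expected):
            missing_idx = sorted(set(expected) - set(idx.tolist()))
            raise ParseError(
                f"{path}: trial {trial_id} dot_index not 1..{len(idx)} "
                f"(missing {missing_idx})"
            )
        g = g.sort_values("dot_index")
        condition = str(g["condition"].iloc[0])
        if condition not in configs:
            configs[condition] = make_target_config(
                condition, sigma_stim=sigma_stim, dt_ms=dt_ms, max_dots=max_dots
            )
        trials.append(
            Trial(
                trial_id=str(trial_id),
                config=configs[condition],
                true_target=str(g["true_target"].iloc[0]),
                dots=g[["x_px", "y_px"]].to_numpy(dtype=float),
            )
        )
    return trials


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------

def write_responses(
    responses: list[tuple[str, Response]], path: str | Path
) -> None:
    """CSV with columns trial_id, choice, rt_ms (empty for timeouts)."""
    rows = [
        (tid, r.choice, "" if r.is_timeout else r.rt_ms)
        for tid, r in responses
    ]
    pd.DataFrame(rows, columns=["trial_id", "choice", "rt_ms"]).to_csv(
        path, index=False
    )


def read_responses(
    path: str | Path,
    deadline_ms: float | None = None,
    strict_deadline: bool = False,
) -> list[tuple[str, Response]]:
    """Read a responses CSV; validates choice labels and RT ranges.

    RTs beyond ``deadline_ms`` raise (strict) or warn (default).
    """
    try:
        df = pd.read_csv(path)
    except Exception as e:  # noqa: BLE001
        raise ParseError(f"{path}: cannot parse CSV ({e})") from e
    required = {"trial_id", "choice", "rt_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out: list[tuple[str, Response]] = []
    for i, row in df.iterrows():
        line = int(i) + 2
        choice = str(row["choice"])
        rt = row["rt_ms"]
        has_rt = not (pd.isna(rt) or rt == "")
        if choice == "timeout":
            if has_rt:
                raise ParseError(f"{path}: line {line}: timeout row carries rt_ms")
            out.append((str(row["trial_id"]), Response(choice="timeout")))
            continue
        if choice not in ("left", "right"):
            raise ParseError(f"{path}: line {line}: invalid choice {choice!r}")
        if not has_rt:
            raise ParseError(f"{path}: line {line}: missing rt_ms")
        rt = float(rt)
        if rt <= 0:
            raise ParseError(f"{path}: line {line}: rt_ms must be > 0, got {rt}")
        if deadline_ms is not None and rt > deadline_ms:
            msg = f"{path}: line {line}: rt_ms {rt} exceeds deadline {deadline_ms}"
            if strict_deadline:
                raise ParseError(msg)
            warnings.warn(msg, stacklevel=2)
        out.append((str(row["trial_id"]), Response(choice=choice, rt_ms=rt)))
    return out


def export_belief_trajectories(
    trials: list[Trial],
    params,
    path: str | Path,
    mode: str = "exact",
    variant: str = "standard",
    rng: np.random.Generator | None = None,
) -> None:
    """Run the accumulator and write belief trajectories for plotting.

    One row per trial and step up to the decision (or the full trial if no
    bound crossing): trial_id, step, belief_left, bound.
    """
    from .decision_model import bound_value, run_accumulation

    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for tr in trials:
        out = run_accumulation(
            tr, params, mode=mode, variant=variant, rng=rng, keep_trajectory=True
        )
        stretch = params.stretch if variant == "collapsing" else 0.0
        for step, (b_left, _) in enumerate(out.trajectory, start=1):
            b = float(
                bound_value(step, tr.config.max_dots, params.bound, stretch,
                            params.shape)
            )
            rows.append((tr.trial_id, step, b_left, b))
    pd.DataFrame(
        rows, columns=["trial_id", "step", "belief_left", "bound"]
    ).to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# posteriors / evidence / BMS
# ---------------------------------------------------------------------------

def write_posterior(
    posterior: EPPosterior, path: str | Path, meta: dict | None = None
) -> None:
    settings = posterior.settings_used
    payload = {
        "mean": posterior.mean.tolist(),
        "cov": posterior.cov.tolist(),
        "site_r": posterior.site_r.tolist(),
        "site_Q": posterior.site_Q.tolist(),
        "site_c": posterior.site_c.tolist(),
        "log_evidence": posterior.log_evidence,
        "settings": None if settings is None else {
            "eps_ms": settings.eps_ms,
            "min_accepted": settings.min_accepted,
            "passes": settings.passes,
            "seed": settings.seed,
        },
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(payload))


def read_posterior(path: str | Path) -> EPPosterior:
    payload = json.loads(Path(path).read_text())
    cov = np.asarray(payload["cov"], dtype=float)
    mean = np.asarray(payload["mean"], dtype=float)
    Q = np.linalg.inv(cov)
    s = payload.get("settings")
    settings = None if s is None else FitSettings(
        eps_ms=s["eps_ms"], min_accepted=s["min_accepted"],
        passes=s["passes"], seed=s["seed"],
    )
    return EPPosterior(
        r=Q @ mean,
        Q=Q,
        site_r=np.asarray(payload["site_r"], dtype=float),
        site_Q=np.asarray(payload["site_Q"], dtype=float),
        site_c=np.asarray(payload["site_c"], dtype=float),
        settings_used=settings,
    )


def write_evidence_matrix(
    log_evidence: np.ndarray, model_names: list[str], path: str | Path
) -> None:
    """Rows = participants, columns = models."""
    pd.DataFrame(np.asarray(log_evidence), columns=model_names).to_csv(
        path, index_label="participant"
    )


def read_evidence_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


def write_bms_result(result: BMSResult, model_names: list[str],
                     path: str | Path) -> None:
    payload = {
        "models": model_names,
        "expected_frequencies": result.expected_frequencies.tolist(),
        "exceedance_p": result.exceedance_p.tolist(),
        "protected_exceedance_p": result.protected_exceedance_p.tolist(),
        "bor": result.bor,
        "alpha": result.alpha.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
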