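"""Review-log, parameter-file and configuration I/O.

The canonical review log is a headered comma-delimited file with one row
per review session::

    learner_id,item_id,t_days,session_seen,session_correct

Times are days since the (learner, item) pair's first exposure, written
with six decimal places so round-trips are byte-stable.  A reader for the
public Duolingo half-life-regression log dialect is included; it maps that
schema onto the canonical one.

The parameters file stores the fitted memory model: two global header
rows (alpha, beta) followed by one ``item_id,n0`` row per item.
Configuration is a flat TOML file; every tunable default of the package
appears in :func:`default_config`.
"""

from __future__ import annotations

import hashlib
import math
import sys
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    tomllib = None

from .estimation import HalfLifeRegressionResults

__all__ = [
    "CANONICAL_COLUMNS",
    "read_log",
    "write_log",
    "read_params",
    "write_params",
    "results_from_params",
    "default_config",
    "read_config",
    "write_config",
    "config_hash",
]

CANONICAL_COLUMNS = (
    "learner_id",
    "item_id",
    "t_days",
    "session_seen",
    "session_correct",
)

DUOLINGO_COLUMNS = (
    "p_recall",
    "timestamp",
    "delta",
    "user_id",
    "learning_language",
    "ui_language",
    "lexeme_id",
    "lexeme_string",
    "history_seen",
    "history_correct",
    "session_seen",
    "session_correct",
)

_SECONDS_PER_DAY = 86400.0


class LogFormatError(ValueError):
    """Malformed review log (bad row, bad header, or non-monotone times)."""


def _validate_canonical(df: pd.DataFrame, path: str) -> pd.DataFrame:
    for i, (seen, corr) in enumerate(
        zip(df["session_seen"].to_numpy(), df["session_correct"].to_numpy())
    ):
        line = i + 2  # header is line 1
        if seen < 1:
            raise LogFormatError(f"{path}:{line}: session_seen must be >= 1")
        if not 0 <= corr <= seen:
            raise LogFormatError(
                f"{path}:{line}: session_correct={corr} outside [0, {seen}]"
            )
        if df["t_days"].iat[i] < 0:
            raise LogFormatError(f"{path}:{line}: negative t_days")
    for (lid, iid), g in df.groupby(["learner_id", "item_id"], sort=False):
        t = g["t_days"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise LogFormatError(
                f"{path}: non-monotone review times for pair ({lid}, {iid})"
            )
    return df


def read_log(path: Union[str, Path], dialect: str = "canonical") -> pd.DataFrame:
    """Read a review log into the canonical DataFrame.

    ``dialect`` is ``"canonical"`` or ``"duolingo-hlr"``.  The Duolingo
    dialect converts epoch-second timestamps to days since each pair's
    first exposure (the first observed timestamp minus its recorded delta)
    and uses ``lexeme_id`` as the item identifier.  Malformed rows raise
    :class:`LogFormatError` with the offending line; non-monotone times
    name the (learner, item) pair.
    """
    path = Path(path)
    if dialect == "canonical":
        try:
            df = pd.read_csv(
                path,
                dtype={
                    "learner_id": str,
                    "item_id": str,
                    "t_days": float,
                    "session_seen": int,
                    "session_correct": int,
                },
            )
        except (ValueError, TypeError) as exc:
            raise LogFormatError(f"{path}: malformed log: {exc}") from exc
        missing = set(CANONICAL_COLUMNS) - set(df.columns)
        if missing:
            raise LogFormatError(f"{path}: missing columns {sorted(missing)}")
        return _validate_canonical(df, str(path))
    if dialect == "duolingo-hlr":
        df = pd.read_csv(path)
        missing = set(DUOLINGO_COLUMNS) - set(df.columns)
        if missing:
            raise LogFormatError(
                f"{path}: not a duolingo-hlr log, missing {sorted(missing)}"
            )
        df = df.sort_values(["user_id", "lexeme_id", "timestamp"], kind="stable")
        g = df.groupby(["user_id", "lexeme_id"], sort=False)
        exposure = g["timestamp"].transform("first") - g["delta"].transform("first")
        out = pd.DataFrame(
            {
                "learner_id": df["user_id"].astype(str),
                "item_id": df["lexeme_id"].astype(str),
                "t_days": (df["timestamp"] - exposure) / _SECONDS_PER_DAY,
                "session_seen": df["session_seen"].astype(int),
                "session_correct": df["session_correct"].astype(int),
            }
        ).reset_index(drop=True)
        return _validate_canonical(out, str(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_log(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a canonical review log (floats with six decimal places)."""
    missing = set(CANONICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"log is missing columns {sorted(missing)}")
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# parameters file


def write_params(results: HalfLifeRegressionResults, path: Union[str, Path]) -> None:
    """Write fitted memory parameters: alpha/beta header + item_id,n0 rows."""
    with open(path, "w") as fh:
        fh.write(f"alpha,{results.alpha:.10g}\n")
        fh.write(f"beta,{results.beta:.10g}\n")
        fh.write("item_id,n0\n")
        for item_id, n0 in results.n0.items():
            fh.write(f"{item_id},{n0:.10g}\n")


def read_params(path: Union[str, Path]) -> tuple[float, float, pd.Series]:
    """Read a parameters file; returns (alpha, beta, n0 series by item)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    try:
        alpha = float(lines[0].split(",")[1])
        beta = float(lines[1].split(",")[1])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed parameters header") from exc
    if lines[2] != "item_id,n0":
        raise ValueError(f"{path}: expected 'item_id,n0' header on line 3")
    items, n0s = [], []
    for ln in lines[3:]:
        item_id, n0 = ln.rsplit(",", 1)
        items.append(item_id)
        n0s.append(float(n0))
    return alpha, beta, pd.Series(n0s, index=pd.Index(items, name="item_id"), name="n0")


def results_from_params(
    alpha: float, beta: float, n0: pd.Series
) -> HalfLifeRegressionResults:
    """Wrap externally stored parameters as a results object."""
    return HalfLifeRegressionResults(
        alpha=alpha,
        beta=beta,
        n0=n0,
        loss_trace=np.array([]),
        converged=True,
        n_obs=0,
        n_items=len(n0),
        lam=math.nan,
        final_loss=math.nan,
    )


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(seed: int, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write small canned review logs used as golden test fixtures.

    One log per scheduler (50 sequences each: 10 learners x 5 items) plus
    a mixed log with all three schedules interleaved, all generated from
    ``seed`` and byte-reproducible.
    """
    from .schedulers import MemorizeScheduler, ThresholdScheduler, UniformScheduler
    from .simulate import PopulationConfig, SimulationWindow, simulate_population

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arms = {
        "memorize": MemorizeScheduler(q=1.0),
        "uniform": UniformScheduler(mu=0.25),
        "threshold": ThresholdScheduler(c=2.0, zeta=1.0, m_th=0.6),
    }
    paths: dict[str, Path] = {}

    def write(name: str, scheduler) -> None:
        config = PopulationConfig(
            n_learners=10,
            n_items=5,
            scheduler=scheduler,
            window=SimulationWindow(0.0, 30.0),
            n0_median=0.15,
            master_seed=seed,
        )
        path = out_dir / f"log_{name}.csv"
        write_log(simulate_population(config), path)
        paths[name] = path

    for name, sched in arms.items():
        write(name, sched)
    arm_list = list(arms.values())
    write("mixed", lambda li, ij: arm_list[(li + ij) % 3])
    return paths


# ---------------------------------------------------------------------------
# configuration


def default_config() -> dict:
    """All tunable defaults, as written to the shipped config file."""
    return {
        # simulation window (days; t=0 is first exposure)
        "t0": 0.0,
        "tf": 30.0,
        # population
        "n_learners": 30,
        "n_items": 30,
        "n0_median": 0.04,
        "n0_sigma": 1.0,
        "alpha": 0.3,
        "beta": 0.2,
        "attempts": 1,
        "scheduler": "memorize",
        # scheduler parameters
        "q": 1.0,
        "mu": 0.2,
        "c": 2.0,
        "zeta": 1.0,
        "m_th": 0.6,
        "delta_factor": 0.25,
        "discretize_hours": 1.0,
        # estimation
        "lam": 0.01,
        "m_hat_clamp": 1e-4,
        "min_events_per_learner": 30,
        "min_reviews_per_item": 30,
        "zeta_grid": [0.5, 1.0, 2.0, 4.0, 8.0, 16.0],
        "m_th_grid": [0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
        # evaluation
        "group_fraction": 0.25,
        "min_reviews_per_record": 3,
        "min_sequences_per_learner": 70,
        "t_center": 8.0,
        "t_halfwidth": 3.2,
    }


def write_config(config: dict, path: Union[str, Path]) -> None:
    """Write a flat TOML config (scalars and lists of scalars only)."""
    def fmt(v) -> str:
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        if isinstance(v, str):
            return f'"{v}"'
        if isinstance(v, (list, tuple)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        raise TypeError(f"unsupported config value {v!r}")

    with open(path, "w") as fh:
        for key, value in config.items():
            fh.write(f"{key} = {fmt(value)}\n")


def read_config(path: Union[str, Path]) -> dict:
    """Read a TOML config file on top of the defaults."""
    cfg = default_config()
    with open(path, "rb") as fh:
        cfg.update(tomllib.load(fh))
    return cfg


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration for run logging."""
    canon = ";".join(f"{k}={config[k]!r}" for k in sorted(config))
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:12]
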