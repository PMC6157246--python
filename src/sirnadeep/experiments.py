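"""Config-driven hyperparameter scans.

Each scan re-runs k-fold cross-validation over a one-dimensional grid —
flank length n, kernel height m, activation pairing or learning rate —
and returns a tidy table with one row per grid cell.  Every row is
independently reproducible from its (config, seed) cell.  Claims such as
"learning rate 0.1 beats 0.5" are tendencies over several seeds, never
per-seed guarantees, and are asserted that way in the test suite.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Optional, Sequence

import pandas as pd

from sirnadeep.evaluation import cross_validate
from sirnadeep.model import KERNEL_HEIGHT_MAX, KERNEL_HEIGHT_MIN, ModelConfig
from sirnadeep.thermo import NNParameterTable

DEFAULT_FLANK_VALUES = tuple(range(10, 31))
DEFAULT_KERNEL_VALUES = tuple(range(2, 21))
DEFAULT_LEARNING_RATES = (0.5, 0.1, 0.01, 0.001)
ACTIVATION_PAIRS = (
    ("relu", "sigmoid"),
    ("relu", "relu"),
    ("sigmoid", "sigmoid"),
    ("sigmoid", "relu"),
)


def _with(config: ModelConfig, **overrides) -> ModelConfig:
    kwargs = asdict(config)
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


def _cv_row(records, cfg, params, k, seed):
    res = cross_validate(records, cfg, params, k=k, seed=seed)
    return {"mean_cv_pcc": res.mean_pcc, "mean_cv_auc": res.mean_auc}


def scan_flank_length(
    records,
    config: ModelConfig,
    params: NNParameterTable,
    n_values: Sequence[int] = DEFAULT_FLANK_VALUES,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV performance as a function of the flank length n (default 10–30)."""
    rows = []
    for n in n_values:
        cfg = _with(config, flank_n=int(n))
        rows.append({"n": int(n), **_cv_row(records, cfg, params, k, seed)})
    return pd.DataFrame(rows)


def scan_kernel_height(
    records,
    config: ModelConfig,
    params: NNParameterTable,
    m_values: Sequence[int] = DEFAULT_KERNEL_VALUES,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV performance of single-height networks, 22 − m kernels of height m."""
    for m in m_values:
        if not (KERNEL_HEIGHT_MIN <= m <= KERNEL_HEIGHT_MAX):
            raise ValueError(
                f"kernel height {m} outside [{KERNEL_HEIGHT_MIN}, {KERNEL_HEIGHT_MAX}]"
            )
    rows = []
    for m in m_values:
        cfg = _with(config, kernel_heights=[int(m)], kernels_per_height=22 - int(m))
        rows.append({"m": int(m), **_cv_row(records, cfg, params, k, seed)})
    return pd.DataFrame(rows)


def scan_activations(
    records,
    config: ModelConfig,
    params: NNParameterTable,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV performance of the four {ReLU, sigmoid}² activation pairings."""
    rows = []
    for conv_act, dnn_act in ACTIVATION_PAIRS:
        cfg = _with(config, conv_activation=conv_act, dnn_activation=dnn_act)
        rows.append(
            {
                "conv_activation": conv_act,
                "dnn_activation": dnn_act,
                **_cv_row(records, cfg, params, k, seed),
            }
        )
    return pd.DataFrame(rows)


def scan_learning_rate(
    records,
    config: ModelConfig,
    params: NNParameterTable,
    rates: Sequence[float] = DEFAULT_LEARNING_RATES,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV performance over a set of learning rates (default 0.5/0.1/0.01/0.001)."""
    if not list(rates):
        raise ValueError("rates must not be empty")
    rows = []
    for lr in rates:
        cfg = _with(config, learning_rate=float(lr))
        rows.append({"learning_rate": float(lr), **_cv_row(records, cfg, params, k, seed)})
    return pd.DataFrame(rows)
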