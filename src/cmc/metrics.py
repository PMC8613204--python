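"""Force-tracing task performance: MVC, motor precision and variability.

Precision is the reverse-coded root-mean-squared error from the horizontal
target line (0 is perfect, more negative is worse); variability is the
coefficient of variation (SD/mean) of the produced force.  Both are
log-transformable for downstream group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import ForceTrace


@dataclass(frozen=True)
class PerformanceResult:
    precision: float         # -RMSE, force units; <= 0
    variability: float       # CV = SD/mean, dimensionless fraction
    rmse: float
    log_rmse: float
    log_variability: float


def compute_mvc(trials: list[np.ndarray]) -> float:
    """Maximal voluntary contraction: the maximum force over all trials."""
    if not trials:
        raise ValueError("need at least one MVC trial")
    return float(max(np.max(np.asarray(t, float)) for t in trials))


def performance_metrics(trace: ForceTrace, trim_seconds: float = 0.0) -> PerformanceResult:
    """Reverse-coded RMSE and CV of a force trace against its target.

    ``trim_seconds`` optionally drops that much from each end (task on/offset
    transients); default keeps the full record.  SD uses the n-1 denominator.
    """
    x = np.asarray(trace.samples, float)
    if trim_seconds > 0:
        k = int(round(trim_seconds * trace.fs))
        if 2 * k >= len(x):
            raise ValueError("trim longer than the trace")
        x = x[k:len(x) - k]
    if len(x) == 0:
        raise ValueError("empty force trace")
    mean = float(x.mean())
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean force")
    rmse = float(np.sqrt(np.mean((x - trace.target) ** 2)))
    cv = float(x.std(ddof=1) / mean) if len(x) > 1 else 0.0
    return PerformanceResult(
        precision=-rmse, variability=cv, rmse=rmse,
        log_rmse=float(np.log(rmse)) if rmse > 0 else -np.inf,
        log_variability=float(np.log(cv)) if cv > 0 else -np.inf,
    )
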