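"""Cost decomposition and break-even analysis: amortised NPE vs exchange.

Fitting one network with the exchange algorithm costs roughly

    C_BERGM ~ c * S * C1(I_aux)

where ``C1`` is the wall-clock cost of one auxiliary network simulation at
chain length ``I_aux``, ``S`` the number of posterior draws, and ``c > 0``
a dimensionless overhead factor absorbing batching and implementation
efficiencies.  Amortised posterior estimation instead pays

    C_NPE = B * C1(I_aux) + C2(B, H, L) + J * S * C3(H, L)

(simulation + training + per-draw forward passes over J networks).
Equating total costs over J networks gives the break-even count

    J = (B * C1 + C2) / (S * (c * C1 - C3)),

beyond which amortisation is strictly cheaper.  Only the arithmetic and
rank behaviour is contractual here; wall-clock numbers are
hardware-dependent and the timing harness records them without targets.
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass


class CostError(ValueError):
    pass


@dataclass(frozen=True)
class CostInputs:
    """Empirical timing inputs for the two cost models (seconds)."""

    C1: float  # one auxiliary network simulation at the chosen I_aux
    C2: float  # flow training at (B, H, L)
    C3: float  # one posterior draw at (H, L)
    c: float  # dimensionless exchange overhead factor
    B: int  # training pairs
    S: int  # posterior draws per network

    def __post_init__(self) -> None:
        if min(self.C1, self.C2, self.C3) < 0 or self.B < 0 or self.S < 0:
            raise CostError("cost inputs must be non-negative")
        if self.c <= 0:
            raise CostError("overhead factor c must be > 0")


def overhead_factor(total_bergm_seconds: float, S: int, C1: float) -> float:
    """Overhead ``c = total / (S * C1)`` from one measured exchange fit."""
    if S <= 0 or C1 <= 0:
        raise CostError("S and C1 must be positive")
    return float(total_bergm_seconds) / (float(S) * float(C1))


def bergm_cost(inputs: CostInputs) -> float:
    """Exchange-fit cost per network, ``c * S * C1``."""
    return inputs.c * inputs.S * inputs.C1


def npe_cost(inputs: CostInputs, J: float) -> float:
    """Total amortised-NPE cost over J networks."""
    return inputs.B * inputs.C1 + inputs.C2 + J * inputs.S * inputs.C3


def break_even_networks(inputs: CostInputs) -> float:
    """Network count at which amortisation pays off (callers round up).

    Raises when ``c * C1 <= C3``: if one exchange draw is no more expensive
    than one flow forward pass, amortisation never breaks even.
    """
    denom = inputs.S * (inputs.c * inputs.C1 - inputs.C3)
    if denom <= 0:
        raise CostError(
            "no finite break-even: c * C1 <= C3 (per-draw surrogate cost "
            "exceeds the per-draw exchange cost)"
        )
    return (inputs.B * inputs.C1 + inputs.C2) / denom


@dataclass
class TimingSummary:
    task: str
    repetitions: int
    mean_seconds: float
    sd_seconds: float
    times: list[float]
    environment: str

    def as_dict(self) -> dict:
        return {
            "task": self.task,
            "repetitions": self.repetitions,
            "mean_seconds": self.mean_seconds,
            "sd_seconds": self.sd_seconds,
            "times": list(self.times),
            "environment": self.environment,
        }


def timing_harness(task: str, fn, repetitions: int = 10) -> TimingSummary:
    """Wall-clock ``fn()`` over repetitions; records machine provenance."""
    if repetitions < 1:
        raise CostError("repetitions must be >= 1")
    times = []
    for _ in range(repetitions):
        t0 = time.perf_counter()
        fn()
        times.append(time.perf_counter() - t0)
    import numpy as np

    arr = np.asarray(times)
    return TimingSummary(
        task=task,
        repetitions=repetitions,
        mean_seconds=float(arr.mean()),
        sd_seconds=float(arr.std(ddof=1)) if repetitions > 1 else 0.0,
        times=times,
        environment=f"{platform.platform()} / python {platform.python_version()}",
    )
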