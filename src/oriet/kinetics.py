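"""Receptor-level kinetic race models and a stochastic receptor-cycle simulator.

Tunnelling is nanosecond-fast, yet smell operates on milliseconds; what the
brain sees is set by the slower machinery around the tunnelling step.  Two
race pictures capture this:

* **Frustration** — while an odorant is docked and the donor holds an
  electron, tunnelling (characteristic time τ_M for the right molecule, τ_W
  for the wrong one) races a competing process (electron lost from the donor,
  odorant leaving) with characteristic time τ_R.  Both races are memoryless,
  so a docking produces an ion influx with probability τ_R/(τ_R + τ_X); the
  right:wrong success ratio is (τ_R + τ_W)/(τ_R + τ_M).

* **Delay** — the competing process only postpones signalling: after a failed
  attempt the donor must be re-armed, which takes τ_D.  The effective
  transfer time becomes τ′ = τ_D (1 + τ_X/τ_R), amplifying the right/wrong
  time separation by τ_D/τ_R.

The simulator realizes the frustration picture docking-by-docking with
exponential holding times and is checked against the analytic success
probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticsScenario",
    "CycleTrace",
    "success_probability",
    "frustration_ratio",
    "delayed_transfer_time",
    "signal_separation",
    "simulate_receptor_cycle",
]

# Defaults: tunnel times are the representative elastic/inelastic channel
# times (87 ns / 0.15 ns); the window and replenishment times default to the
# geometric midpoint of the 1 us - 1 ms range typical of the slow transport
# steps in the receptor cycle.
_TABLE_MIDPOINT_S = math.sqrt(1e-6 * 1e-3)  # 31.6 us


@dataclass(frozen=True)
class KineticsScenario:
    """Timescales of one receptor cycle (all in seconds).

    ``tunnel_time_right``/``tunnel_time_wrong`` are the characteristic
    tunnelling times τ_M, τ_W for discriminating and non-discriminating
    odorants; ``window_time`` τ_R is the window of opportunity before a
    competing process aborts the attempt; ``replenish_time`` τ_D is the time
    to re-arm the donor; ``integration_window`` is the period over which the
    neural system counts influxes (default 1 ms).
    """

    tunnel_time_right: float = 1.542e-10
    tunnel_time_wrong: float = 8.735e-8
    window_time: float = _TABLE_MIDPOINT_S
    replenish_time: float = _TABLE_MIDPOINT_S
    integration_window: float = 1e-3

    def __post_init__(self) -> None:
        for name in (
            "tunnel_time_right",
            "tunnel_time_wrong",
            "window_time",
            "replenish_time",
            "integration_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tunnel_time_right > self.tunnel_time_wrong:
            warnings.warn(
                "tunnel_time_right exceeds tunnel_time_wrong: the 'right' "
                "molecule is slower than the 'wrong' one",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CycleTrace:
    """Outcome of a simulated batch of dockings (right and wrong molecules)."""

    seed: int
    n_dockings: int
    influx_events_right: int
    influx_events_wrong: int
    mode: str = "single_shot"
    event_log: tuple = field(default=(), repr=False)

    @property
    def fraction_right(self) -> float:
        return self.influx_events_right / self.n_dockings

    @property
    def fraction_wrong(self) -> float:
        return self.influx_events_wrong / self.n_dockings


def success_probability(tunnel_time: float, window_time: float) -> float:
    """Probability that tunnelling beats the competing process: τ_R/(τ_R + τ_X).

    Both processes are constant-hazard, so the faster-on-average one wins with
    odds inversely proportional to its characteristic time.
    """
    if tunnel_time <= 0 or window_time <= 0:
        raise ValueError("times must be positive")
    return window_time / (window_time + tunnel_time)


def frustration_ratio(scenario: KineticsScenario) -> float:
    """Right:wrong ratio of dockings that produce an influx, (τ_R+τ_W)/(τ_R+τ_M)."""
    s = scenario
    return (s.window_time + s.tunnel_time_wrong) / (s.window_time + s.tunnel_time_right)


def delayed_transfer_time(
    replenish_time: float, tunnel_time: float, window_time: float
) -> float:
    """Effective transfer time τ′ = τ_D (1 + τ_X/τ_R) in the delay model.

    Each failed window costs a donor re-arming time τ_D; the expected number
    of attempts is 1 + τ_X/τ_R.
    """
    if min(replenish_time, tunnel_time, window_time) <= 0:
        raise ValueError("times must be positive")
    return replenish_time * (1.0 + tunnel_time / window_time)


def signal_separation(scenario: KineticsScenario) -> float:
    """Delay-model separation τ′_W − τ′_M = (τ_W − τ_M)·τ_D/τ_R, seconds.

    With τ_D ≫ τ_R this can be far larger than the bare difference in
    tunnelling times — the slow replenishment step amplifies discrimination.
    """
    s = scenario
    return (s.tunnel_time_wrong - s.tunnel_time_right) * s.replenish_time / s.window_time


def _simulate_one_kind(
    rng: np.random.Generator,
    tunnel_time: float,
    scenario: KineticsScenario,
    n_dockings: int,
    mode: str,
    log: list | None,
    kind: str,
) -> int:
    """Count influxes over ``n_dockings`` for one odorant kind."""
    influxes = 0
    if mode == "single_shot":
        # vectorized: one exponential race per docking
        t_tun = rng.exponential(tunnel_time, size=n_dockings)
        t_win = rng.exponential(scenario.window_time, size=n_dockings)
        wins = t_tun < t_win
        influxes = int(np.count_nonzero(wins))
        if log is not None:
            for i in range(n_dockings):
                log.append((float(min(t_tun[i], t_win[i])), kind, "influx" if wins[i] else "frustrated"))
        return influxes
    # multi_shot: repeated attempts per docking, each gated by donor
    # replenishment, until the window closes or the integration window ends
    for _ in range(n_dockings):
        t = 0.0
        t_win = rng.exponential(scenario.window_time)
        while t < scenario.integration_window:
            t_tun = rng.exponential(tunnel_time)
            if t + t_tun >= t_win or t + t_tun >= scenario.integration_window:
                break
            t += t_tun
            influxes += 1
            if log is not None:
                log.append((t, kind, "influx"))
            t += rng.exponential(scenario.replenish_time)
    return influxes


def simulate_receptor_cycle(
    scenario: KineticsScenario,
    n_dockings: int,
    seed: int,
    mode: str = "single_shot",
    record_events: bool = False,
) -> CycleTrace:
    """Stochastic realization of the frustration race for right and wrong odorants.

    Per docking, an exponential tunnelling time (mean τ_M or τ_W) races an
    exponential window (mean τ_R).  ``single_shot`` allows at most one influx
    per docking, so the influx fraction estimates τ_R/(τ_R + τ_X);
    ``multi_shot`` lets a docked molecule fire repeatedly, each repeat gated
    by an exponential donor-replenishment wait (mean τ_D), within the neural
    integration window.  Identical seeds give identical traces.
    """
    if n_dockings < 1:
        raise ValueError("n_dockings must be at least 1")
    if mode not in ("single_shot", "multi_shot"):
        raise ValueError(f"unknown mode {mode!r}; use 'single_shot' or 'multi_shot'")
    rng = np.random.default_rng(seed)
    log: list | None = [] if record_events else None
    n_right = _simulate_one_kind(
        rng, scenario.tunnel_time_right, scenario, n_dockings, mode, log, "right"
    )
    n_wrong = _simulate_one_kind(
        rng, scenario.tunnel_time_wrong, scenario, n_dockings, mode, log, "wrong"
    )
    return CycleTrace(
        seed=seed,
        n_dockings=n_dockings,
        influx_events_right=n_right,
        influx_events_wrong=n_wrong,
        mode=mode,
        event_log=tuple(log) if log is not None else (),
    )
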