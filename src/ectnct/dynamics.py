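"""Simulation of the discrete linear network model.

These routines roll the system ``x(t+1) = A x(t)`` forward from an impulse
and measure the cumulative output power ``sum_t ||x(t)||^2`` (identity
observation map). They provide the mechanically checkable core of the
controllability <-> seizure-power link: for an impulse at node *i* the
cumulative power equals ``trace(W_i)``, the node's average controllability,
and across networks the whole-brain means AC-bar and MC-bar track the power
of a generalized (uniform) stimulus with opposite signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .controllability import StableSystem, controllability_profile

__all__ = [
    "Trajectory",
    "simulate_impulse",
    "cumulative_output_power",
    "controllability_power_association",
]

DEFAULT_HORIZON = 10_000


@dataclass(frozen=True)
class Trajectory:
    """State rollout of a linear system after an impulse.

    ``states`` holds ``x(0) .. x(T-1)`` row-wise; ``states[0]`` is the
    applied impulse and no further input enters after time 0.
    """

    states: np.ndarray = field(repr=False)
    input_node: int | str = "custom"
    horizon: int = 0

    def __post_init__(self) -> None:
        st = np.asarray(self.states, dtype=float)
        if st.ndim != 2:
            raise ValueError("states must be a T x N matrix")
        if not np.all(np.isfinite(st)):
            raise ValueError("non-finite states in trajectory")
        object.__setattr__(self, "states", st)
        object.__setattr__(self, "horizon", st.shape[0])


def simulate_impulse(
    s: StableSystem, impulse: np.ndarray, horizon: int = DEFAULT_HORIZON
) -> Trajectory:
    """Roll out ``x(0) = impulse``, ``x(t+1) = A x(t)`` for ``horizon`` steps.

    Returns the trajectory ``x(0) .. x(horizon-1)``. For a Schur-stable
    system the states decay geometrically, so the default horizon captures
    the impulse energy to ~1e-8 relative accuracy for spectral radius <= 0.95.
    """
    x0 = np.asarray(impulse, dtype=float).ravel()
    if x0.shape[0] != s.n_nodes:
        raise ValueError(
            f"impulse length {x0.shape[0]} does not match system size {s.n_nodes}"
        )
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if not np.all(np.isfinite(x0)):
        raise ValueError("non-finite impulse")
    states = np.empty((horizon, s.n_nodes))
    states[0] = x0
    x = x0
    A = s.A
    for t in range(1, horizon):
        x = A @ x
        states[t] = x
    node = int(np.argmax(x0)) if np.count_nonzero(x0) == 1 and x0.max() == 1.0 else "custom"
    return Trajectory(states=states, input_node=node)


def cumulative_output_power(traj: Trajectory) -> float:
    """Total output power ``sum_t ||x(t)||^2`` of a trajectory."""
    return float(np.sum(traj.states**2))


def _uniform_impulse(n: int) -> np.ndarray:
    return np.full(n, 1.0 / np.sqrt(n))


def controllability_power_association(
    systems: Sequence[StableSystem],
    horizon: int = DEFAULT_HORIZON,
    input_mode: Literal["uniform", "per-node-mean"] = "uniform",
) -> dict:
    """Relate whole-brain controllability to simulated stimulus power.

    For each system, computes AC-bar and MC-bar and the cumulative output
    power after a control input, then reports the Spearman rank correlation
    of each controllability mean with power across systems. ``uniform``
    applies a unit-norm all-ones impulse (a generalized, whole-brain
    stimulus); ``per-node-mean`` averages the simulated impulse energy over
    all single-node impulses.
    """
    systems = list(systems)
    if len(systems) < 3:
        raise ValueError("need at least 3 systems")
    n = systems[0].n_nodes
    if any(s.n_nodes != n for s in systems):
        raise ValueError("systems must share the same size")

    ac_means, mc_means, powers = [], [], []
    for s in systems:
        prof = controllability_profile(s)
        ac_means.append(prof.ac_mean)
        mc_means.append(prof.mc_mean)
        if input_mode == "uniform":
            p = cumulative_output_power(simulate_impulse(s, _uniform_impulse(n), horizon))
        elif input_mode == "per-node-mean":
            # batch rollout of all N basis impulses: M_t = A^t, power = sum ||M_t||_F^2 / N
            M = np.eye(n)
            total = float(n)
            for _ in range(1, horizon):
                M = s.A @ M
                total += float(np.sum(M**2))
            p = total / n
        else:
            raise ValueError(f"unknown input_mode {input_mode!r}")
        powers.append(p)

    ac_means = np.asarray(ac_means)
    mc_means = np.asarray(mc_means)
    powers = np.asarray(powers)
    if np.ptp(ac_means) == 0.0:
        raise ValueError("zero variance in AC-bar across systems")
    rho_ac = stats.spearmanr(ac_means, powers)
    rho_mc = stats.spearmanr(mc_means, powers)
    return {
        "n_systems": len(systems),
        "input_mode": input_mode,
        "horizon": horizon,
        "ac_mean": ac_means,
        "mc_mean": mc_means,
        "power": powers,
        "rho_ac_power": float(rho_ac.statistic),
        "rho_mc_power": float(rho_mc.statistic),
        "p_ac_power": float(rho_ac.pvalue),
        "p_mc_power": float(rho_mc.pvalue),
    }
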