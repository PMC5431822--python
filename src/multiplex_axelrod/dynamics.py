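"""Layered and classical cultural dynamics with optional cultural drift.

Each agent carries ``F`` cultural features, each holding one of ``q``
nominal traits.  In *layered* social influence an interacting pair can
only exchange traits on features whose layer links them, and the
interaction probability is the layered cultural overlap

    ``omega_ij = (1/F) sum_f a_ij^[f] delta(s_i^[f], s_j^[f])``,

bounded above by the pair's edge overlap ``o_ij``.  In the *classical*
mode the same schedule runs on the aggregate graph with the full-profile
similarity ``(1/F) sum_f delta(s_i^[f], s_j^[f])`` and any differing
feature may be copied.  Dynamics freeze (an absorbing state) when every
connected pair has ``omega_ij = 0`` or ``omega_ij = o_ij``: connected
agents may stably share only part of their profile, which the classical
model cannot do.

*Cultural drift* is spontaneous mutation: after each elementary
agent-update, with probability ``r`` one uniform agent resets one uniform
feature to a uniform trait (the current value is allowed, so the effective
mutation rate is ``r (1 - 1/q)``).  With ``r > 0`` there is no absorbing
state; runs last ``max_epochs`` and report time-averages over the second
half (a quasi-stationary measurement).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import numpy as np
import pandas as pd

from . import _kernels
from .multiplex import MultiplexNetwork
from .observables import consensus_profile

MODES = ("layered", "classical")


@dataclass
class CultureState:
    """``N x F`` trait matrix with entries in ``{1..q}``."""

    traits: np.ndarray
    q: int

    def __post_init__(self) -> None:
        self.traits = np.asarray(self.traits, dtype=np.int64)
        if self.traits.ndim != 2:
            raise ValueError("traits must be an N x F matrix")
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.traits.size and (self.traits.min() < 1 or self.traits.max() > self.q):
            raise ValueError(f"traits must lie in 1..{self.q}")

    def copy(self) -> "CultureState":
        return CultureState(self.traits.copy(), self.q)


@dataclass
class ModelConfig:
    """Run contract: mode, trait count, drift rate, budget and seed."""

    q: int
    mode: str = "layered"
    r: float = 0.0
    max_epochs: int = 100_000
    absorption_check_interval: int = 100
    seed: int | None = None
    allow_noop_features: bool = False
    record_trajectory: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.r < 0:
            raise ValueError("drift rate r must be >= 0")
        if self.max_epochs < 1 or self.absorption_check_interval < 1:
            raise ValueError("max_epochs and absorption_check_interval must be >= 1")
        if self.q < 1:
            raise ValueError("q must be >= 1")


@dataclass
class RunResult:
    """Final state plus bookkeeping of a single run."""

    state: CultureState
    absorbed: bool
    epochs_run: int
    trajectory: pd.DataFrame | None = None
    tail_mean_S: float | None = None
    tail_mean_sd_Sf: float | None = None


def init_culture(N: int, F: int, q: int, seed=None) -> CultureState:
    """I.i.d. uniform traits on ``{1..q}`` for ``N`` agents and ``F`` features."""
    if q < 1:
        raise ValueError("q must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return CultureState(rng.integers(1, q + 1, size=(N, F)), q)


def cultural_overlap(net: MultiplexNetwork, state: CultureState, u: Hashable, v: Hashable) -> float:
    """Layered cultural overlap ``omega_ij``; always ``<= edge_overlap(u, v)``."""
    a, b = net.index_of(u), net.index_of(v)
    if a == b:
        raise ValueError("cultural overlap is undefined for a node with itself")
    adj, _, _ = net.as_arrays()
    t = state.traits
    return float(np.sum(adj[:, a, b] * (t[a] == t[b]))) / net.F


def _kernel_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] & 0x7FFFFFFF)


def _check_shapes(net: MultiplexNetwork, state: CultureState) -> None:
    if state.traits.shape != (net.N, net.F):
        raise ValueError(
            f"state shape {state.traits.shape} does not match multiplex (N={net.N}, F={net.F})"
        )


def epoch_layered(
    net: MultiplexNetwork,
    state: CultureState,
    seed: int | None = None,
    allow_noop_features: bool = False,
) -> tuple[CultureState, int]:
    """One layered epoch in place; returns ``(state, number of trait changes)``.

    If ``seed`` is given the kernel RNG is reseeded first; otherwise the
    stream continues from its current position.
    """
    return _one_epoch(net, state, layered=True, seed=seed, allow_noop=allow_noop_features)


def epoch_classical(net: MultiplexNetwork, state: CultureState, seed: int | None = None) -> tuple[CultureState, int]:
    """One classical epoch on the aggregate graph; see :func:`epoch_layered`."""
    return _one_epoch(net, state, layered=False, seed=seed, allow_noop=False)


def _one_epoch(net, state, *, layered, seed, allow_noop):
    _check_shapes(net, state)
    adj, indptr, indices = net.as_arrays()
    if seed is not None:
        _kernels.seed_rng(_kernel_seed(np.random.SeedSequence(seed)))
    changed = _kernels.run_epochs(
        adj, indptr, indices, state.traits, state.q, layered, allow_noop, 0.0, 1
    )
    return state, int(changed)


def apply_drift(state: CultureState, r: float, rng: np.random.Generator, n_updates: int = 1) -> CultureState:
    """Apply the drift channel of ``n_updates`` elementary updates in place.

    Each update triggers, with probability ``r``, one single-feature
    randomisation of a uniform agent (the drawn trait may equal the current
    one).  This mirrors the in-kernel drift used by :func:`run` and exists
    so the event-rate convention can be tested in isolation.
    """
    if r < 0:
        raise ValueError("drift rate r must be >= 0")
    N, F = state.traits.shape
    n_events = int(rng.binomial(n_updates, r)) if r > 0 else 0
    for _ in range(n_events):
        a = int(rng.integers(N))
        f = int(rng.integers(F))
        state.traits[a, f] = int(rng.integers(1, state.q + 1))
    return state


def is_absorbed(net: MultiplexNetwork, state: CultureState, mode: str = "layered") -> bool:
    """True iff no aggregate-connected pair can still change (frozen dynamics)."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    _check_shapes(net, state)
    adj, indptr, indices = net.as_arrays()
    return bool(_kernels.absorbed_scan(adj, indptr, indices, state.traits, mode == "layered"))


def run(net: MultiplexNetwork, config: ModelConfig, initial_state: CultureState | None = None) -> RunResult:
    """Run the configured dynamics on ``net``.

    With ``r = 0`` the loop stops at the first absorption check that finds
    the state frozen (or at ``max_epochs``, flagged ``absorbed=False``).
    With ``r > 0`` the full epoch budget is always used and ``tail_mean_S``
    / ``tail_mean_sd_Sf`` average the trajectory samples from the second
    half of the run.  A single seed drives initialisation and every
    stochastic choice of the dynamics, so equal configs give bit-identical
    results.
    """
    ss = np.random.SeedSequence(config.seed)
    init_ss, kernel_ss = ss.spawn(2)
    if initial_state is None:
        state = init_culture(net.N, net.F, config.q, np.random.default_rng(init_ss))
    else:
        if initial_state.q != config.q:
            raise ValueError("initial_state.q does not match config.q")
        state = initial_state.copy()
    _check_shapes(net, state)

    adj, indptr, indices = net.as_arrays()
    _kernels.seed_rng(_kernel_seed(kernel_ss))
    layered = config.mode == "layered"

    rows: list[dict] = []
    epochs = 0
    absorbed = config.r == 0 and bool(
        _kernels.absorbed_scan(adj, indptr, indices, state.traits, layered)
    )
    if config.record_trajectory:
        rows.append(_sample_row(net, state, epochs, 0))

    while not absorbed and epochs < config.max_epochs:
        chunk = min(config.absorption_check_interval, config.max_epochs - epochs)
        changed = _kernels.run_epochs(
            adj, indptr, indices, state.traits, config.q,
            layered, config.allow_noop_features, config.r, chunk,
        )
        epochs += chunk
        if config.record_trajectory:
            rows.append(_sample_row(net, state, epochs, int(changed)))
        if config.r == 0:
            absorbed = bool(_kernels.absorbed_scan(adj, indptr, indices, state.traits, layered))

    trajectory = pd.DataFrame(rows) if config.record_trajectory else None
    tail_S = tail_sd = None
    if config.r > 0 and trajectory is not None:
        tail = trajectory[trajectory["epoch"] > config.max_epochs / 2]
        if len(tail):
            tail_S = float(tail["S"].mean())
            tail_sd = float(tail["sd_Sf"].mean())
    return RunResult(
        state=state,
        absorbed=absorbed,
        epochs_run=epochs,
        trajectory=trajectory,
        tail_mean_S=tail_S,
        tail_mean_sd_Sf=tail_sd,
    )


def _sample_row(net, state, epoch, changed):
    profile = consensus_profile(net, state)
    return {
        "epoch": epoch,
        "changed": changed,
        "S": profile.S,
        "mean_Sf": profile.mean_Sf,
        "sd_Sf": profile.sd_Sf,
    }
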