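"""Phase-diagram sweeps: replicate management, seeding, tidy result tables.

A sweep runs the dynamics over a parameter grid (any of ``mode``, ``q``,
``p`` or ``beta``, ``r``) with a fresh synthetic multiplex per replicate,
and records one tidy row per (cell, replicate): the cell parameters, the
overlap *measured* on the generated instance, the order parameters, the
absorbed flag and the seeds.  Seeds derive deterministically from
``base_seed`` and the (cell, replicate) coordinates, so identical specs
give identical tables, rows are independent (embarrassingly parallel in
principle), and interrupted sweeps resume without recomputing finished
rows.
"""

from __future__ import annotations

import itertools
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .dynamics import ModelConfig, run
from .generators import TwoDensitySpec, identical_er_multiplex, rewire_layers, two_density_multiplex
from .observables import ConsensusProfile, consensus_profile

logger = logging.getLogger(__name__)

GRID_KEYS = ("mode", "q", "p", "beta", "r")

_COLUMNS = [
    "cell", "replicate", "mode", "q", "p", "beta", "r", "N", "F",
    "o_measured", "S", "mean_Sf", "sd_Sf", "S_f", "absorbed",
    "epochs_run", "seed", "error",
]


@dataclass
class SweepSpec:
    """Grid definition plus fixed structural and run parameters.

    ``kind`` selects the generator family: ``"rewired"`` (identical ER
    layers, grid key ``p``) or ``"two_density"`` (grid key ``beta``).
    ``grid`` maps a subset of ``mode``/``q``/``p``/``beta``/``r`` to value
    lists; parameters not in the grid take the scalar defaults below.
    """

    kind: str
    N: int
    grid: dict = field(default_factory=dict)
    F: int = 10
    k_mean: float = 4.0
    F_low: int = 5
    F_high: int = 5
    k_low: float = 4.0
    k_high: float = 8.0
    mode: str = "layered"
    q: int = 2
    p: float = 0.0
    beta: float = 0.0
    r: float = 0.0
    replicates: int = 20
    max_epochs: int = 100_000
    absorption_check_interval: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("rewired", "two_density"):
            raise ValueError(f"unknown sweep kind {self.kind!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        bad = set(self.grid) - set(GRID_KEYS)
        if bad:
            raise ValueError(f"unknown grid keys {sorted(bad)}; allowed: {GRID_KEYS}")
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid value lists must be non-empty")

    def cells(self) -> list[dict]:
        """Grid cells in deterministic order, merged with the scalar defaults."""
        keys = [k for k in GRID_KEYS if k in self.grid]
        base = {k: getattr(self, k) for k in GRID_KEYS}
        out = []
        for values in itertools.product(*(self.grid[k] for k in keys)):
            cell = dict(base)
            cell.update(dict(zip(keys, values)))
            out.append(cell)
        return out


def sweep_spec_from_file(path) -> SweepSpec:
    """Load a :class:`SweepSpec` from a YAML (or JSON) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SweepSpec(**data)


def _build_network(spec: SweepSpec, cell: dict, seeds: np.ndarray):
    if spec.kind == "rewired":
        net = identical_er_multiplex(spec.N, spec.F, spec.k_mean, seed=int(seeds[0]))
        if cell["p"] > 0:
            net = rewire_layers(net, cell["p"], seed=int(seeds[1]))
        return net
    return two_density_multiplex(
        TwoDensitySpec(
            N=spec.N, F_low=spec.F_low, F_high=spec.F_high,
            k_low=spec.k_low, k_high=spec.k_high,
            beta=cell["beta"], seed=int(seeds[0]),
        )
    )


def _run_row(spec: SweepSpec, cell_idx: int, cell: dict, rep: int) -> dict:
    seeds = np.random.SeedSequence([spec.base_seed, cell_idx, rep]).generate_state(3)
    row = {
        "cell": cell_idx, "replicate": rep, "mode": cell["mode"], "q": cell["q"],
        "p": cell["p"] if spec.kind == "rewired" else np.nan,
        "beta": cell["beta"] if spec.kind == "two_density" else np.nan,
        "r": cell["r"], "N": spec.N,
        "F": spec.F if spec.kind == "rewired" else spec.F_low + spec.F_high,
        "seed": int(seeds[2] & 0x7FFFFFFF), "error": "",
    }
    try:
        net = _build_network(spec, cell, seeds)
        row["o_measured"] = net.structural_overlap()
        config = ModelConfig(
            q=cell["q"], mode=cell["mode"], r=cell["r"],
            max_epochs=spec.max_epochs,
            absorption_check_interval=spec.absorption_check_interval,
            seed=row["seed"], record_trajectory=cell["r"] > 0,
        )
        result = run(net, config)
        profile = consensus_profile(net, result.state)
        row["S"] = result.tail_mean_S if cell["r"] > 0 else profile.S
        row["mean_Sf"] = profile.mean_Sf
        row["sd_Sf"] = result.tail_mean_sd_Sf if cell["r"] > 0 else profile.sd_Sf
        row["S_f"] = json.dumps([round(x, 6) for x in profile.S_f])
        row["absorbed"] = result.absorbed
        row["epochs_run"] = result.epochs_run
    except Exception as exc:  # noqa: BLE001 - a failed cell must not abort the sweep
        logger.exception("sweep cell %d replicate %d failed", cell_idx, rep)
        row.update({"o_measured": np.nan, "S": np.nan, "mean_Sf": np.nan,
                    "sd_Sf": np.nan, "S_f": "[]", "absorbed": False,
                    "epochs_run": 0, "error": f"{type(exc).__name__}: {exc}"})
    return row


def run_sweep(spec: SweepSpec, out=None, resume: bool = True) -> pd.DataFrame:
    """Execute the sweep; return (and optionally write/append) the tidy table.

    When ``out`` exists and ``resume`` is true, rows already present (keyed
    by cell and replicate) are kept as-is and only missing rows are
    computed and appended; re-running a finished sweep leaves the file
    byte-identical.
    """
    cells = spec.cells()
    done: set[tuple[int, int]] = set()
    previous = None
    if out is not None and resume and os.path.exists(out):
        previous = pd.read_csv(out)
        done = set(zip(previous["cell"].astype(int), previous["replicate"].astype(int)))
        logger.info("resuming sweep: %d rows already present", len(previous))

    new_rows: list[dict] = []
    header_needed = previous is None or len(previous) == 0
    for cell_idx, cell in enumerate(cells):
        for rep in range(spec.replicates):
            if (cell_idx, rep) in done:
                continue
            row = _run_row(spec, cell_idx, cell, rep)
            new_rows.append(row)
            if out is not None:
                pd.DataFrame([row], columns=_COLUMNS).to_csv(
                    out, mode="a", header=header_needed, index=False
                )
                header_needed = False
        logger.info("sweep cell %d/%d done (%s)", cell_idx + 1, len(cells),
                    {k: cell[k] for k in GRID_KEYS if k in spec.grid})

    new_df = pd.DataFrame(new_rows, columns=_COLUMNS)
    if previous is not None and len(previous):
        if not len(new_df):
            return previous
        return pd.concat([previous, new_df], ignore_index=True)
    return new_df


def phase_classify(profile: ConsensusProfile, eps: float = 0.1) -> str:
    """Label a consensus profile: globalised / fragmented / mixed / borderline.

    Globalised: ``S >= 1 - eps``.  Fragmented: every ``S^[f] <= eps``.
    Mixed (feature-level consensus): some layers globalised and some
    fragmented.  Anything else is borderline.
    """
    if not 0 < eps < 0.5:
        raise ValueError("eps must be in (0, 0.5)")
    if profile.S >= 1 - eps:
        return "globalised"
    if np.all(profile.S_f <= eps):
        return "fragmented"
    if np.any(profile.S_f >= 1 - eps) and np.any(profile.S_f <= eps):
        return "mixed"
    return "borderline"
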