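"""Pressure-chamber protocols on a discretized root.

Two protocols are simulated, both assuming a steady state at every
recorded point (the experimental flows are stable):

* ``Jv(P)`` sweep — basal sap outflow of the de-topped root at a
  sequence of relative pressures applied to the bathing solution;
* cut-and-flow — Jv at a fixed operating pressure while the root is
  progressively excised from the tip; every cut opens xylem faces
  through which bath fluid (including PEG, with its viscosity) enters.

Positions in cut-and-flow series are razor-blade distances from the
intact primary tip (anatomical coordinates); the intact-root point is
recorded at x = 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .architecture import REVGraph
from .media import BathSolution
from .solver import SolverError, TransportParams, solve_steady_state

__all__ = [
    "PRESSURE_STEPS",
    "ExperimentSeries",
    "default_cut_schedule",
    "CutFlowSimulator",
    "simulate_jvp",
    "simulate_cut_and_flow",
    "linearity_gap",
    "add_measurement_noise",
    "read_experiment",
    "write_experiment",
]

#: Typical successive relative pressure steps of a Jv(P) recording, MPa.
PRESSURE_STEPS = (0.00, 0.05, 0.15, 0.10, 0.25, 0.20, 0.35, 0.30, 0.45, 0.50, 0.25, 0.00)

EXPERIMENT_COLUMNS = ["kind", "x", "Jv_ul_per_s", "operating_pressure_MPa"]


@dataclass
class ExperimentSeries:
    """A measured or simulated protocol curve.

    ``x`` is the applied relative pressure (MPa) for ``kind='jvp'`` or
    the blade distance-to-tip (m, 0 = intact) for ``kind='cutflow'``;
    ``Jv`` is the basal sap flow in µl s⁻¹.
    """

    kind: str
    x: np.ndarray
    Jv: np.ndarray
    bath: BathSolution = field(default_factory=BathSolution)
    operating_pressure: Optional[float] = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.Jv = np.asarray(self.Jv, dtype=float)
        if self.kind not in ("jvp", "cutflow"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if self.x.shape != self.Jv.shape:
            raise ValueError("x and Jv must have the same length")
        if self.kind == "jvp" and np.any(self.x < 0):
            raise ValueError("jvp pressures must be >= 0 (relative)")

    @property
    def J0(self) -> Optional[float]:
        """Spontaneous exudation Jv(Pe = 0), µl s⁻¹, if recorded."""
        at0 = np.isclose(self.x, 0.0)
        return float(self.Jv[at0][0]) if self.kind == "jvp" and at0.any() else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": self.kind,
                "x": self.x,
                "Jv_ul_per_s": self.Jv,
                "operating_pressure_MPa": np.nan if self.operating_pressure is None else self.operating_pressure,
            },
            columns=EXPERIMENT_COLUMNS,
        )


def write_experiment(series: ExperimentSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_experiment(path, bath: Optional[BathSolution] = None) -> ExperimentSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EXPERIMENT_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"missing experiment columns: {missing}")
    op = None
    if "operating_pressure_MPa" in df.columns and df["operating_pressure_MPa"].notna().any():
        op = float(df["operating_pressure_MPa"].dropna().iloc[0])
    return ExperimentSeries(
        kind=str(df["kind"].iloc[0]),
        x=df["x"].to_numpy(float),
        Jv=df["Jv_ul_per_s"].to_numpy(float),
        bath=bath or BathSolution(),
        operating_pressure=op,
    )


def simulate_jvp(
    g: REVGraph,
    params: TransportParams,
    bath: BathSolution,
    pressure_steps: Sequence[float] = PRESSURE_STEPS,
    C0=None,
    Cpeg0=None,
    **solver_opts,
) -> ExperimentSeries:
    """Simulate a Jv(P) sweep: one steady-state solve per pressure step.

    Consecutive steps warm-start from the previous concentration
    fields (``C0``/``Cpeg0`` seed the first step). At Pe = 0 the series
    reproduces the spontaneous exudation rate J0 of
    :func:`rootflow.solver.solve_steady_state` exactly.
    """
    steps = np.asarray(pressure_steps, dtype=float)
    if steps.size < 4:
        raise ValueError("a usable Jv(P) protocol needs at least 4 pressure steps")
    Jv = np.empty(steps.size)
    for i, Pe in enumerate(steps):
        st = solve_steady_state(
            g, params, bath.replace(Pe=float(Pe)), C0=C0, Cpeg0=Cpeg0, **solver_opts
        )
        Jv[i] = st.Jv_base_ul
        C0, Cpeg0 = st.C, st.C_peg
    return ExperimentSeries(kind="jvp", x=steps, Jv=Jv, bath=bath)


def default_cut_schedule(
    primary_length: float,
    first_cut: float = 0.083,
    subsequent: float = 0.043,
    final_remainder: float = 0.052,
) -> list[float]:
    """Blade positions (m from the intact primary tip) emulating the
    experimental schedule: a first cut of ~8.3 cm, subsequent cuts of
    ~4.3 cm, leaving a basal remainder of ~5.2 cm."""
    if primary_length <= first_cut + final_remainder:
        raise ValueError("primary root too short for the default cut schedule")
    positions = []
    x = first_cut
    while x <= primary_length - final_remainder + 1e-12:
        positions.append(round(x, 9))
        x += subsequent
    return positions


class CutFlowSimulator:
    """Cut-and-flow protocol with the cut graph sequence precomputed.

    Cutting is purely geometric, so the successive cut architectures
    can be reused across parameter evaluations during inversion.
    """

    def __init__(
        self,
        g: REVGraph,
        cut_positions: Sequence[float],
        operating_pressure: Optional[float] = None,
        bath: Optional[BathSolution] = None,
    ):
        self.bath = bath or BathSolution()
        if operating_pressure is None:
            # experimental defaults: 0.3 MPa in PEG baths, 0.2 MPa otherwise
            operating_pressure = 0.3 if self.bath.w_peg > 0 else 0.2
        self.operating_pressure = float(operating_pressure)
        positions = sorted(float(x) for x in cut_positions)
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate cut positions")
        self.cut_positions = positions
        graphs = [g]
        for x in positions:
            graphs.append(graphs[-1].cut_at_distance(x))
        self.graphs = graphs
        self.x = np.array([0.0] + positions)
        self._warm: dict = {}

    def simulate(
        self,
        params: TransportParams,
        bath: Optional[BathSolution] = None,
        warm_start: bool = False,
        **solver_opts,
    ) -> ExperimentSeries:
        """Solve all points; ``warm_start`` reuses each point's last
        converged concentration fields (useful across the many nearby
        parameter sets an optimizer evaluates)."""
        bath = (bath or self.bath).replace(Pe=self.operating_pressure)
        Jv = np.empty(len(self.graphs))
        for i, gi in enumerate(self.graphs):
            init = self._warm.get(i) if warm_start else None
            kw = dict(solver_opts)
            if init is not None:
                kw["C0"], kw["Cpeg0"], kw["dt0"] = init
            try:
                st = solve_steady_state(gi, params, bath, **kw)
            except SolverError:
                if init is None:
                    raise
                # stale warm start (parameters moved too far): retry cold
                st = solve_steady_state(gi, params, bath, **solver_opts)
            Jv[i] = st.Jv_base_ul
            if warm_start:
                self._warm[i] = (st.C, st.C_peg, st.final_dt)
        return ExperimentSeries(
            kind="cutflow", x=self.x, Jv=Jv, bath=bath,
            operating_pressure=self.operating_pressure,
        )


def simulate_cut_and_flow(
    g: REVGraph,
    params: TransportParams,
    bath: BathSolution,
    cut_positions: Sequence[float],
    operating_pressure: Optional[float] = None,
    **solver_opts,
) -> ExperimentSeries:
    """Simulate a cut-and-flow experiment.

    The first point is the intact root at the operating pressure
    (x = 0); each subsequent point is the steady state after cutting at
    the given blade position, with open-face boundary conditions. In a
    PEG bath, PEG intrusion through the faces and the resulting local
    viscosity increase are fully coupled.
    """
    sim = CutFlowSimulator(g, cut_positions, operating_pressure, bath)
    return sim.simulate(params, **solver_opts)


def linearity_gap(series: ExperimentSeries) -> float:
    """Maximal deviation of the min–max normalized curve from the
    bisector, in [0, 1]; 0 for an exactly linear series.

    Both axes are normalized to [0, 1] by their minima and maxima, so
    the statistic is invariant under affine rescaling of either axis
    and comparable between roots with very different absolute flows.
    """
    x, y = series.x, series.Jv
    if len(np.unique(x)) < 3:
        raise ValueError("linearity gap needs at least 3 distinct points")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("linearity gap undefined for a constant series")
    xn = (x - x.min()) / np.ptp(x)
    yn = (y - y.min()) / np.ptp(y)
    return float(np.max(np.abs(yn - xn)))


def add_measurement_noise(
    series: ExperimentSeries,
    noise_sd: float,
    seed: Optional[int] = None,
    relative: bool = False,
) -> ExperimentSeries:
    """Reproducible Gaussian perturbation of the flows.

    ``noise_sd`` is in µl s⁻¹, or a fraction of each flow when
    ``relative`` (multiplicative noise).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if relative:
        Jv = series.Jv * (1.0 + noise_sd * rng.standard_normal(series.Jv.shape))
    else:
        Jv = series.Jv + noise_sd * rng.standard_normal(series.Jv.shape)
    return ExperimentSeries(
        kind=series.kind, x=series.x.copy(), Jv=Jv, bath=series.bath,
        operating_pressure=series.operating_pressure,
    )
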