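"""Time-dependent integration of the receptor model.

Dynamics evolve the pooled quantities (Rc+RcG, RcGt, RnGt, RnGN, Rn+RnG):
the two loose-binding steps are instantaneous equilibria, so within each
pool the bound/free split is algebraic in the instantaneous free
concentration G(t).  The right-hand side is generated from the canonical
edge list in :func:`grkin.model.reaction_scheme`, which keeps the ODE and
the steady-state solver consistent by construction and makes total receptor
conservation structural.

Integration is stiff-aware (the rate constants span 1.7e-3 to 10 min^-1)
with relative tolerance 1e-8 and absolute 1e-12; discontinuous forcing
(dose steps, chase additions) is handled by restarting the solver at the
profile's breakpoints rather than by smoothing.

Also provided: the two-ligand labeled/unlabeled competition variant used to
model cold-chase dissociation experiments, in which both species share the
free receptor pools and the loose pools partition between species in
proportion to their concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    LigandParams,
    RateConstants,
    ReceptorState,
    pooled_rate_matrix,
    pools_to_state,
    state_to_pools,
    rngn_max,
    STATE_NAMES,
    NUCLEAR_STATES,
)
from .profiles import ConcentrationProfile

__all__ = ["SimProtocol", "ChaseProtocol", "Trajectory", "ChaseResult",
           "simulate", "activity_series", "chase_simulate"]

RTOL = 1e-8
ATOL = 1e-12


@dataclass(frozen=True)
class SimProtocol:
    """One simulation run: forcing profile, time window, initial condition."""

    profile: ConcentrationProfile
    t_start: float = 0.0
    t_end: float = 1440.0
    initial_state: ReceptorState | Literal["all-cytoplasmic"] = "all-cytoplasmic"
    output_step: float = 1.0
    burn_in_days: int = 1

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.output_step <= 0:
            raise ValueError("output step must be positive")


@dataclass(frozen=True)
class ChaseProtocol:
    """Cold-chase competition protocol.

    Labeled ligand at ``labeled_conc`` is present from t = 0; at
    ``label_duration`` an unlabeled excess ``chase_conc`` of the same ligand
    is added and both persist to ``total_duration``.
    """

    labeled_conc: float = 100.0
    label_duration: float = 100.0
    chase_conc: float = 20000.0      # 200-fold excess of the 100 nM label
    total_duration: float = 250.0

    def __post_init__(self) -> None:
        if min(self.labeled_conc, self.chase_conc) < 0:
            raise ValueError("concentrations must be >= 0")
        if not 0 < self.label_duration < self.total_duration:
            raise ValueError("need 0 < label_duration < total_duration")


class Trajectory:
    """Receptor trajectory on a regular output grid."""

    def __init__(self, time: np.ndarray, states: np.ndarray,
                 G: np.ndarray, ligand: LigandParams, rates: RateConstants):
        self.time = time
        self.states = states          # (n_time, 7), columns = STATE_NAMES
        self.G = G
        self.ligand = ligand
        self.rates = rates

    def __len__(self) -> int:
        return len(self.time)

    def state_at(self, i: int) -> ReceptorState:
        return ReceptorState(**dict(zip(STATE_NAMES, self.states[i])),
                             time=float(self.time[i]))

    @property
    def total(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def f_rngn(self) -> np.ndarray:
        return self.states[:, STATE_NAMES.index("RnGN")] / self.ligand.Rtot

    @property
    def relative_activity(self) -> np.ndarray:
        return self.f_rngn / rngn_max(self.rates)

    @property
    def nuclear_fraction(self) -> np.ndarray:
        cols = [STATE_NAMES.index(n) for n in NUCLEAR_STATES]
        return self.states[:, cols].sum(axis=1) / self.ligand.Rtot

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_min", self.time)
        df["fRnGN"] = self.f_rngn
        df["relative_activity"] = self.relative_activity
        df["nuclear_fraction"] = self.nuclear_fraction
        df["G_nM"] = self.G
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _integrate_segments(rhs, y0: np.ndarray, edges: np.ndarray,
                        grid: np.ndarray) -> np.ndarray:
    """Integrate ``rhs`` over consecutive [edge, edge] segments, sampling
    ``grid`` (which must include the first and last edge)."""
    out = np.empty((len(grid), len(y0)))
    out[0] = y0
    y = np.asarray(y0, dtype=float)
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (grid > a) & (grid <= b)
        t_eval = grid[mask]
        sol = solve_ivp(rhs, (a, b), y, method="LSODA",
                        t_eval=t_eval if len(t_eval) else None,
                        rtol=RTOL, atol=ATOL, dense_output=False)
        if not sol.success:
            last = sol.t[-1] if len(sol.t) else a
            raise RuntimeError(
                f"ODE integration failed at t = {last:.3f} min: {sol.message}")
        if len(t_eval):
            out[mask] = sol.y.T
            y = sol.y[:, -1].copy()
        else:
            sol2 = solve_ivp(rhs, (a, b), y, method="LSODA",
                             rtol=RTOL, atol=ATOL)
            if not sol2.success:
                raise RuntimeError(
                    f"ODE integration failed at t = {sol2.t[-1]:.3f} min: {sol2.message}")
            y = sol2.y[:, -1].copy()
    return out


def simulate(ligand: LigandParams, rates: RateConstants,
             protocol: SimProtocol) -> Trajectory:
    """Integrate the receptor model under the protocol's forcing profile."""
    prof = protocol.profile
    if protocol.initial_state == "all-cytoplasmic":
        y0 = np.array([ligand.Rtot, 0.0, 0.0, 0.0, 0.0])
    else:
        y0 = state_to_pools(protocol.initial_state)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return pooled_rate_matrix(ligand, rates, float(prof(t))) @ y

    grid = np.arange(protocol.t_start, protocol.t_end + protocol.output_step / 2,
                     protocol.output_step)
    edges = prof.segment_edges(protocol.t_start, protocol.t_end)
    pools = _integrate_segments(rhs, y0, edges, grid)
    G = np.asarray(prof(grid), dtype=float)
    states = np.empty((len(grid), 7))
    for i, (t, p, g) in enumerate(zip(grid, pools, G)):
        states[i] = pools_to_state(p, ligand, g, time=t).as_array()
    return Trajectory(grid, states, G, ligand, rates)


def activity_series(trajectory: Trajectory) -> pd.Series:
    """Relative transcriptional activity fRnGN(t)/RnGNmax along a trajectory."""
    return pd.Series(trajectory.relative_activity, index=trajectory.time,
                     name="relative_activity")


# ---------------------------------------------------------------------------
# Two-species (labeled / unlabeled) competition


class ChaseResult:
    """Trajectory of the labeled/unlabeled competition simulation.

    ``labeled_nuclear`` is the experimentally tracked signal: the fraction
    of receptor tightly bound to *labeled* ligand in the nucleus
    (RnGt* + RnGN*).
    """

    _COLS = ["Pc", "RcGt_a", "RcGt_b", "RnGt_a", "RnGt_b",
             "RnGN_a", "RnGN_b", "Pn"]

    def __init__(self, time: np.ndarray, y: np.ndarray,
                 Ga: np.ndarray, Gb: np.ndarray, ligand: LigandParams,
                 rates: RateConstants):
        self.time = time
        self.y = y
        self.Ga = Ga
        self.Gb = Gb
        self.ligand = ligand
        self.rates = rates

    @property
    def total(self) -> np.ndarray:
        return self.y.sum(axis=1)

    @property
    def labeled_nuclear(self) -> np.ndarray:
        i = self._COLS.index
        return (self.y[:, i("RnGt_a")] + self.y[:, i("RnGN_a")]) / self.ligand.Rtot

    @property
    def unlabeled_nuclear(self) -> np.ndarray:
        i = self._COLS.index
        return (self.y[:, i("RnGt_b")] + self.y[:, i("RnGN_b")]) / self.ligand.Rtot

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=self._COLS)
        df.insert(0, "time_min", self.time)
        df["labeled_nuclear"] = self.labeled_nuclear
        df["G_labeled_nM"] = self.Ga
        df["G_unlabeled_nM"] = self.Gb
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _two_species_rhs(ligand: LigandParams, rates: RateConstants):
    k, Kc, Kn = rates, ligand.Kc, ligand.Kn

    def rhs(t, y, Ga, Gb):
        Pc, RcGt_a, RcGt_b, RnGt_a, RnGt_b, RnGN_a, RnGN_b, Pn = y
        Rc = Pc / (1.0 + (Ga + Gb) / Kc)
        Rn = Pn / (1.0 + (Ga + Gb) / Kn)
        RcG_a, RcG_b = Rc * Ga / Kc, Rc * Gb / Kc
        RnG_a, RnG_b = Rn * Ga / Kn, Rn * Gb / Kn
        return np.array([
            k.k5 * Rn - k.k1 * (RcG_a + RcG_b),
            k.k1 * RcG_a - k.k2 * RcGt_a,
            k.k1 * RcG_b - k.k2 * RcGt_b,
            k.k2 * RcGt_a + k.k6 * RnG_a - k.k3 * RnGt_a,
            k.k2 * RcGt_b + k.k6 * RnG_b - k.k3 * RnGt_b,
            k.k3 * RnGt_a - k.k4 * RnGN_a,
            k.k3 * RnGt_b - k.k4 * RnGN_b,
            k.k4 * (RnGN_a + RnGN_b) - k.k5 * Rn - k.k6 * (RnG_a + RnG_b),
        ])

    return rhs


def chase_simulate(ligand: LigandParams, rates: RateConstants,
                   protocol: ChaseProtocol,
                   output_step: float = 1.0) -> ChaseResult:
    """Simulate a cold-chase competition experiment.

    The labeled and unlabeled species are chemically identical (same Kc, Kn
    and rate constants) and share the free receptor pools; the loose-bound
    pools partition between species in proportion to the free
    concentrations.  With one species at zero concentration the system
    reduces to the single-ligand model.
    """
    rhs2 = _two_species_rhs(ligand, rates)
    grid = np.arange(0.0, protocol.total_duration + output_step / 2, output_step)
    y = np.zeros(8)
    y[0] = ligand.Rtot                      # drug-naive, all receptor in Rc
    out = np.empty((len(grid), 8))
    out[0] = y

    segments = [(0.0, protocol.label_duration, protocol.labeled_conc, 0.0),
                (protocol.label_duration, protocol.total_duration,
                 protocol.labeled_conc, protocol.chase_conc)]
    for a, b, Ga, Gb in segments:
        mask = (grid > a) & (grid <= b)
        sol = solve_ivp(rhs2, (a, b), y, args=(Ga, Gb), method="LSODA",
                        t_eval=grid[mask], rtol=RTOL, atol=ATOL)
        if not sol.success:
            raise RuntimeError(f"chase integration failed: {sol.message}")
        out[mask] = sol.y.T
        y = sol.y[:, -1].copy()

    Ga = np.full_like(grid, protocol.labeled_conc)
    Gb = np.where(grid >= protocol.label_duration, protocol.chase_conc, 0.0)
    return ChaseResult(grid, out, Ga, Gb, ligand, rates)


def decay_half_time(time: np.ndarray, signal: np.ndarray,
                    t_from: float) -> float:
    """Time for ``signal`` to fall to half its value at ``t_from`` (min)."""
    mask = time >= t_from
    t, s = time[mask], signal[mask]
    s0 = s[0]
    below = np.nonzero(s <= 0.5 * s0)[0]
    if len(below) == 0:
        return float("inf")
    i = below[0]
    if i == 0:
        return 0.0
    # linear interpolation between the straddling samples
    frac = (0.5 * s0 - s[i - 1]) / (s[i] - s[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]) - t[0])
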