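"""Seven-state glucocorticoid receptor (GR) trafficking model.

The receptor cycles through seven states: free cytoplasmic receptor ``Rc``,
loosely ligand-bound cytoplasmic ``RcG``, tightly bound cytoplasmic ``RcGt``,
tightly bound nuclear ``RnGt``, the DNA-binding-competent activated form
``RnGN``, free nuclear ``Rn``, and loosely bound nuclear ``RnG``.  Two loose
binding steps (Rc = RcG with dissociation constant ``Kc``; Rn = RnG with
``Kn``) are treated as instantaneous equilibria; six irreversible first-order
conversions ``k1``-``k6`` (tight binding, nuclear import/export, activation,
ligand release) carry the fluxes.  A defining feature of GR kinetics is fast
nuclear import (``k2``, ~5 min) against extremely slow export (``k5``,
~10 h), so that almost all receptor is nuclear except at vanishing ligand
concentration, and the activated pool is sustained by an intranuclear recycle
RnGN -> Rn -> RnG -> RnGt -> RnGN that never visits the cytoplasm.

This module holds the parameter and state containers, the canonical reaction
scheme (the single source of truth for both the steady-state solver and the
ODE right-hand side used by :mod:`grkin.dynamics`), the analytic steady
state, and the two Michaelis-Menten reductions of the steady state: a
high-concentration form (receptor fully nuclear; ``Km = Kn / C`` with
``C = 1 + k6/k3 + k6/k4``) and a very-low-concentration form whose apparent
``Km`` is thousands of times smaller than the experimentally measured
transcriptional EC50.

Units are fixed package-wide: concentrations in nM, time in minutes, rates
in min^-1.  ``Rtot`` is a pure scale factor, default 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STATE_NAMES",
    "NUCLEAR_STATES",
    "RateConstants",
    "LigandParams",
    "ReceptorState",
    "MMParams",
    "Reaction",
    "reaction_scheme",
    "steady_state",
    "f_rngn",
    "rngn_max",
    "nuclear_fraction",
    "relative_activity",
    "mm_high",
    "mm_low",
    "mm_experimental",
    "kn_from_kmt",
    "mm_activity",
    "dose_response",
]

STATE_NAMES = ("Rc", "RcG", "RcGt", "RnGt", "RnGN", "Rn", "RnG")
NUCLEAR_STATES = ("RnGt", "RnGN", "Rn", "RnG")


def _packaged_yaml(name: str) -> dict:
    with resources.files("grkin.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


_REFERENCE = _packaged_yaml("ligands.yaml")
_K_DEFAULT = _REFERENCE["rate_constants"]
_RTOT_DEFAULT = float(_REFERENCE["Rtot"])


@dataclass(frozen=True)
class RateConstants:
    """The six shared first-order rate constants, min^-1.

    Defaults are the reference parameter set (assumed ligand-independent;
    only ``Kc``/``Kn`` differ between glucocorticoids).
    """

    k1: float = _K_DEFAULT["k1"]
    k2: float = _K_DEFAULT["k2"]
    k3: float = _K_DEFAULT["k3"]
    k4: float = _K_DEFAULT["k4"]
    k5: float = _K_DEFAULT["k5"]
    k6: float = _K_DEFAULT["k6"]

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5", "k6"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"rate constant {name} must be positive and finite, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in ("k1", "k2", "k3", "k4", "k5", "k6")}


@dataclass(frozen=True)
class LigandParams:
    """Equilibrium parameters of one glucocorticoid.

    Kc, Kn : dissociation constants (nM) of the loose cytoplasmic and
        nuclear binding steps.
    KmT : experimentally measured transcriptional EC50 (nM); reference value,
        optional.
    Rtot : total receptor amount (arbitrary scale).
    """

    name: str
    Kc: float
    Kn: float
    KmT: float | None = None
    Rtot: float = _RTOT_DEFAULT

    def __post_init__(self) -> None:
        if not (self.Kc > 0 and self.Kn > 0 and self.Rtot > 0):
            raise ValueError(f"Kc, Kn and Rtot must be positive for ligand {self.name!r}")
        if self.KmT is not None and self.KmT <= 0:
            raise ValueError("KmT, when given, must be positive")


_NEG_TOL = 1e-9


@dataclass(frozen=True)
class ReceptorState:
    """Occupancies of the seven receptor states (same scale as Rtot)."""

    Rc: float
    RcG: float
    RcGt: float
    RnGt: float
    RnGN: float
    Rn: float
    RnG: float
    time: float | None = None

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            v = getattr(self, name)
            if v < -_NEG_TOL:
                raise ValueError(f"state {name} is negative: {v}")
            if v < 0:  # clip solver round-off
                object.__setattr__(self, name, 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES])

    @property
    def total(self) -> float:
        return float(sum(getattr(self, n) for n in STATE_NAMES))

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in STATE_NAMES}


@dataclass(frozen=True)
class MMParams:
    """One Michaelis-Menten reduction of the steady-state dose-response.

    ``activity = Vmax * G / (Km + G)``.  ``denom_const`` is the dimensionless
    constant multiplying G in the un-normalised denominator of the reduction
    (called C in the high-concentration regime and D in the low one);
    ``regime`` tags which limit the parameters describe.
    """

    Vmax: float
    Km: float
    denom_const: float
    regime: Literal["experimental", "high", "low"]

    def __post_init__(self) -> None:
        if not (0 < self.Vmax <= 1):
            raise ValueError(f"Vmax must lie in (0, 1], got {self.Vmax}")
        if self.Km <= 0:
            raise ValueError("Km must be positive")
        if self.denom_const < 1:
            raise ValueError("denominator constant must be >= 1")


# ---------------------------------------------------------------------------
# Reaction scheme


@dataclass(frozen=True)
class Reaction:
    """One edge of the kinetic scheme.

    ``kind`` is "kinetic" for an irreversible first-order conversion (with
    rate ``constant`` in min^-1) or "equilibrium" for an instantaneous loose
    binding step (with dissociation ``constant`` in nM).
    """

    source: str
    target: str
    kind: Literal["kinetic", "equilibrium"]
    constant: float
    label: str


def reaction_scheme(ligand: LigandParams, rates: RateConstants) -> list[Reaction]:
    """Canonical edge list of the 7-state scheme.

    Single source of truth: both the numeric steady-state solver and the ODE
    right-hand side in :mod:`grkin.dynamics` are generated from this list.
    """
    return [
        Reaction("Rc", "RcG", "equilibrium", ligand.Kc, "Kc"),
        Reaction("RcG", "RcGt", "kinetic", rates.k1, "k1"),
        Reaction("RcGt", "RnGt", "kinetic", rates.k2, "k2"),
        Reaction("RnGt", "RnGN", "kinetic", rates.k3, "k3"),
        Reaction("RnGN", "Rn", "kinetic", rates.k4, "k4"),
        Reaction("Rn", "Rc", "kinetic", rates.k5, "k5"),
        Reaction("Rn", "RnG", "equilibrium", ligand.Kn, "Kn"),
        Reaction("RnG", "RnGt", "kinetic", rates.k6, "k6"),
    ]


# Pooled representation: the two equilibrium edges merge (Rc, RcG) and
# (Rn, RnG) into pools whose internal split is set algebraically by G.
POOL_NAMES = ("Pc", "RcGt", "RnGt", "RnGN", "Pn")
_POOL_OF = {"Rc": "Pc", "RcG": "Pc", "RcGt": "RcGt", "RnGt": "RnGt",
            "RnGN": "RnGN", "Rn": "Pn", "RnG": "Pn"}


def _bound_fraction(state: str, ligand: LigandParams, G: float) -> float:
    """Fraction of the pool holding ``state`` that is in ``state`` at G."""
    if state == "Rc":
        return ligand.Kc / (ligand.Kc + G)
    if state == "RcG":
        return G / (ligand.Kc + G)
    if state == "Rn":
        return ligand.Kn / (ligand.Kn + G)
    if state == "RnG":
        return G / (ligand.Kn + G)
    return 1.0


def pooled_rate_matrix(ligand: LigandParams, rates: RateConstants, G: float) -> np.ndarray:
    """Linear operator M(G) with d(pools)/dt = M @ pools.

    Built from :func:`reaction_scheme`; every kinetic edge contributes a flux
    ``k * fraction(source, G) * pool(source)``.  Columns of M sum to zero
    (mass conservation is structural).
    """
    idx = {n: i for i, n in enumerate(POOL_NAMES)}
    M = np.zeros((len(POOL_NAMES), len(POOL_NAMES)))
    for r in reaction_scheme(ligand, rates):
        if r.kind != "kinetic":
            continue
        src, tgt = _POOL_OF[r.source], _POOL_OF[r.target]
        rate = r.constant * _bound_fraction(r.source, ligand, G)
        if src == tgt:
            continue  # intra-pool conversion carries no pooled flux
        M[idx[src], idx[src]] -= rate
        M[idx[tgt], idx[src]] += rate
    return M


def pools_to_state(pools: Sequence[float], ligand: LigandParams, G: float,
                   time: float | None = None) -> ReceptorState:
    """Expand the 5 pooled quantities into the 7 receptor states at G."""
    Pc, RcGt, RnGt, RnGN, Pn = pools
    return ReceptorState(
        Rc=Pc * _bound_fraction("Rc", ligand, G),
        RcG=Pc * _bound_fraction("RcG", ligand, G),
        RcGt=RcGt,
        RnGt=RnGt,
        RnGN=RnGN,
        Rn=Pn * _bound_fraction("Rn", ligand, G),
        RnG=Pn * _bound_fraction("RnG", ligand, G),
        time=time,
    )


def state_to_pools(state: ReceptorState) -> np.ndarray:
    return np.array([state.Rc + state.RcG, state.RcGt, state.RnGt,
                     state.RnGN, state.Rn + state.RnG])


# ---------------------------------------------------------------------------
# Steady state


def _steady_state_closed_form(ligand: LigandParams, rates: RateConstants,
                              G: float) -> ReceptorState:
    k = rates
    if G == 0.0:
        return ReceptorState(Rc=ligand.Rtot, RcG=0, RcGt=0, RnGt=0,
                             RnGN=0, Rn=0, RnG=0)
    # Occupancies relative to free nuclear receptor Rn, from flux balance
    # with the loose binding steps at equilibrium.
    x = G / ligand.Kn
    feed = k.k5 + k.k6 * x           # flux per Rn into the tight nuclear path
    rel = {
        "Rc": k.k5 * ligand.Kc / (k.k1 * G),
        "RcG": k.k5 / k.k1,
        "RcGt": k.k5 / k.k2,
        "Rn": 1.0,
        "RnG": x,
        "RnGt": feed / k.k3,
        "RnGN": feed / k.k4,
    }
    scale = ligand.Rtot / sum(rel.values())
    return ReceptorState(**{n: scale * rel[n] for n in STATE_NAMES})


def _steady_state_linear(ligand: LigandParams, rates: RateConstants,
                         G: float) -> ReceptorState:
    """Numeric flux-balance solve of the pooled scheme (cross-check oracle)."""
    M = pooled_rate_matrix(ligand, rates, G)
    A = M.copy()
    A[-1, :] = 1.0                       # replace one balance row by conservation
    b = np.zeros(len(POOL_NAMES))
    b[-1] = ligand.Rtot
    pools = np.linalg.solve(A, b)
    return pools_to_state(pools, ligand, G)


def steady_state(ligand: LigandParams, rates: RateConstants, G: float,
                 method: Literal["closed_form", "linear"] = "closed_form") -> ReceptorState:
    """Steady-state receptor distribution at free concentration ``G`` (nM).

    ``method="closed_form"`` evaluates the analytic solution of the
    flux-balance equations; ``method="linear"`` solves the pooled linear
    system built from :func:`reaction_scheme` numerically.  The two agree to
    round-off and the latter serves as the independent oracle in the tests.
    """
    if not math.isfinite(G) or G < 0:
        raise ValueError(f"concentration G must be finite and >= 0, got {G}")
    if method == "closed_form":
        return _steady_state_closed_form(ligand, rates, G)
    if method == "linear":
        return _steady_state_linear(ligand, rates, G)
    raise ValueError(f"unknown method {method!r}")


def f_rngn(state: ReceptorState, Rtot: float | None = None) -> float:
    """Fraction of total receptor in the activated (DNA-binding) state."""
    total = state.total if Rtot is None else Rtot
    return state.RnGN / total


def rngn_max(rates: RateConstants) -> float:
    """Activated fraction at infinite ligand concentration.

    In the infinite-concentration limit the receptor is confined to the
    nuclear recycle loop RnG -> RnGt -> RnGN and the occupancies are set by
    the transit times 1/k6, 1/k3, 1/k4, giving
    ``1 / (1 + k4/k3 + k4/k6)`` independent of the ligand.
    """
    k = rates
    return 1.0 / (1.0 + k.k4 / k.k3 + k.k4 / k.k6)


def nuclear_fraction(state: ReceptorState) -> float:
    """Fraction of total receptor located in the nucleus."""
    return sum(getattr(state, n) for n in NUCLEAR_STATES) / state.total


def relative_activity(state: ReceptorState, rates: RateConstants) -> float:
    """Transcriptional activity relative to the infinite-dose maximum."""
    return f_rngn(state) / rngn_max(rates)


# ---------------------------------------------------------------------------
# Michaelis-Menten reductions

MMForm = Literal["printed", "derived"]


def _C_const(rates: RateConstants) -> float:
    return 1.0 + rates.k6 / rates.k3 + rates.k6 / rates.k4


def mm_high(ligand: LigandParams, rates: RateConstants,
            form: MMForm = "printed") -> MMParams:
    """High-concentration Michaelis-Menten reduction.

    With the receptor taken as 100 % nuclear the steady state collapses to
    ``Vmax * G / (Km + G)`` with ``Km = Kn / C``, ``C = 1 + k6/k3 + k6/k4``.
    ``C`` and ``Km`` depend only on nuclear parameters.

    Two conventions for ``Vmax`` are published and they differ by ~5 %:

    * ``form="derived"`` - the plateau of the reduction itself, which equals
      the infinite-dose maximum :func:`rngn_max` and is independent of every
      cytoplasmic parameter (Kc, k1, k2, k5);
    * ``form="printed"`` (default) - the reference tables' value, which
      carries a small export-transit correction
      ``k5 * (1/k1 + 1/k2 + 1/k3 + 1/k4)`` in the denominator and therefore
      is not cytoplasm-independent.

    See docs/methods.md for the discrepancy analysis.
    """
    k = rates
    C = _C_const(rates)
    Km = ligand.Kn / C
    if form == "derived":
        Vmax = rngn_max(rates)
    elif form == "printed":
        Vmax = 1.0 / (1.0 + k.k4 / k.k3 + k.k4 / k.k6
                      + k.k5 * (1 / k.k1 + 1 / k.k2 + 1 / k.k3 + 1 / k.k4))
    else:
        raise ValueError(f"unknown form {form!r}")
    return MMParams(Vmax=Vmax, Km=Km, denom_const=C, regime="high")


def mm_low(ligand: LigandParams, rates: RateConstants,
           form: MMForm = "printed") -> MMParams:
    """Very-low-concentration Michaelis-Menten reduction.

    When nuclear rebinding of released ligand is negligible (``k6*G/Kn <<
    k5``) every receptor transits the chain RcG -> RcGt -> RnGt -> RnGN ->
    Rn -> Rc once per cycle, and the steady state again collapses to a
    Michaelis-Menten form — with an apparent affinity ``KmL`` thousands of
    times higher than the experimental EC50 (``KmL`` scales as ``Kc / k1``),
    but a maximum ``VmaxL`` of only a few per cent of the high-regime one.

    ``form="printed"`` (default) reproduces the reference tables:
    ``D = C + k4*(1/k2 + 1/k3 + 1/k6) + k5*(1/k2 + 1/k3 + 1/k4)``,
    ``VmaxL = 1/D``, ``KmL = Kc*k4*(1 + k4/k3 + k4/k6) / (k1*D)``.
    ``form="derived"`` is the self-consistent asymptotic reduction of the
    full steady state:
    ``E0 = 1 + k5*(1/k1 + 1/k2 + 1/k3 + 1/k4)``, ``VmaxL = (k5/k4)/E0``,
    ``KmL = Kc*k5/(k1*E0)``, ``D = k4*E0/k5``.
    The two differ by ~25 % in Vmax; see docs/methods.md.
    """
    k = rates
    if form == "printed":
        D = (_C_const(rates)
             + k.k4 * (1 / k.k2 + 1 / k.k3 + 1 / k.k6)
             + k.k5 * (1 / k.k2 + 1 / k.k3 + 1 / k.k4))
        Vmax = 1.0 / D
        Km = ligand.Kc * k.k4 * (1.0 + k.k4 / k.k3 + k.k4 / k.k6) / (k.k1 * D)
    elif form == "derived":
        E0 = 1.0 + k.k5 * (1 / k.k1 + 1 / k.k2 + 1 / k.k3 + 1 / k.k4)
        D = k.k4 * E0 / k.k5
        Vmax = (k.k5 / k.k4) / E0
        Km = ligand.Kc * k.k5 / (k.k1 * E0)
    else:
        raise ValueError(f"unknown form {form!r}")
    return MMParams(Vmax=Vmax, Km=Km, denom_const=D, regime="low")


def mm_experimental(ligand: LigandParams) -> MMParams:
    """The empirical transcription dose-response, ``activity = G/(KmT+G)``."""
    if ligand.KmT is None:
        raise ValueError(f"ligand {ligand.name!r} has no reference KmT")
    return MMParams(Vmax=1.0, Km=ligand.KmT, denom_const=1.0, regime="experimental")


def kn_from_kmt(KmT: float, rates: RateConstants) -> float:
    """Invert the high-concentration reduction: ``Kn = KmT * C``.

    This is how the nuclear dissociation constant is inferred from a
    measured transcriptional EC50 (there are no direct Kn measurements).
    """
    if KmT <= 0:
        raise ValueError("KmT must be positive")
    return KmT * _C_const(rates)


def mm_activity(mm: MMParams, G: float | np.ndarray,
                relative: bool = False) -> float | np.ndarray:
    """Michaelis-Menten activity ``Vmax*G/(Km+G)`` (or ``G/(Km+G)`` relative)."""
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("concentration must be >= 0")
    vmax = 1.0 if relative or mm.regime == "experimental" else mm.Vmax
    out = vmax * G / (mm.Km + G)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Tabulated dose-response export


def dose_response(ligand: LigandParams, rates: RateConstants,
                  G_values: Iterable[float]) -> pd.DataFrame:
    """Steady-state dose-response table.

    Columns: ``G_nM``, ``fRnGN``, ``relative_activity``, ``nuclear_fraction``.
    """
    rows = []
    rmax = rngn_max(rates)
    for G in G_values:
        st = steady_state(ligand, rates, float(G))
        fr = f_rngn(st)
        rows.append({"G_nM": float(G), "fRnGN": fr,
                     "relative_activity": fr / rmax,
                     "nuclear_fraction": nuclear_fraction(st)})
    return pd.DataFrame(rows)
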