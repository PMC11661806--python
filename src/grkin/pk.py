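"""Pharmacokinetics: dosing regimens to free plasma concentration profiles.

Dexamethasone and methylprednisolone follow linear two-compartment
kinetics with first-order oral absorption and a constant free plasma
fraction; profiles are propagated exactly (matrix exponential over a
1-minute grid), so superposition of doses holds to machine precision.

Prednisone is the oral prodrug of prednisolone and is nonlinear: the two
species interconvert continuously, and prednisolone binds the plasma
protein transcortin (corticosteroid-binding globulin), a high-affinity
carrier with limited capacity, on top of a linear albumin-like component.
As the concentration rises the transcortin sites saturate and the unbound
free fraction increases, which makes clearance, distribution and the plasma
prednisolone/prednisone ratio dose-dependent and breaks superposition.  The
model output used for pharmacodynamics is the free prednisolone
concentration.

The numeric parameter values shipped in ``data/pk_defaults.yaml`` are
literature-plausible placeholder sets flagged ``authoritative: false``
except for the constants the receptor-model source itself prints (DEX oral
bioavailability 0.59, free fraction 0.23 for DEX and MP, molecular weights
392.5 / 472.4 for DEX / DEX-phosphate); structure and contracts are fixed
so an authoritative set drops in without code changes.

Units: mg for dose inputs (converted to nmol via molecular weight), L and
L/min for volumes and clearances, min^-1 for rates, nM for concentrations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .model import _packaged_yaml
from .profiles import ConcentrationProfile, from_samples, MINUTES_PER_DAY

__all__ = [
    "DoseEvent", "Regimen", "LinearPKParams", "PrednisonePKParams",
    "load_pk_params", "regimen_builder", "parse_regimen_line",
    "free_concentration", "prednisolone_free_fraction",
]

Route = Literal["IV", "oral"]
_PK_DATA = _packaged_yaml("pk_defaults.yaml")["drugs"]


@dataclass(frozen=True)
class DoseEvent:
    """A single dose: drug, route, amount (mg) and clock time within the day."""

    drug: str
    route: Route
    amount_mg: float
    time_min: float = 480.0          # 08:00 default administration time
    salt: str | None = None

    def __post_init__(self) -> None:
        if self.amount_mg <= 0:
            raise ValueError("dose amount must be positive")
        if not 0 <= self.time_min < MINUTES_PER_DAY:
            raise ValueError("dose clock time must lie in [0, 1440) min")
        if self.route not in ("IV", "oral"):
            raise ValueError(f"unsupported route {self.route!r}")


@dataclass(frozen=True)
class Regimen:
    """A daily-repeating schedule of dose events."""

    events: tuple[DoseEvent, ...]
    days: int = 2

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("regimen needs at least one dose event")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        drugs = {e.drug for e in self.events}
        if len(drugs) > 1:
            raise ValueError(f"one regimen, one drug; got {sorted(drugs)}")

    @property
    def drug(self) -> str:
        return self.events[0].drug

    def dose_times(self) -> list[tuple[float, DoseEvent]]:
        """Absolute (minute, event) pairs over the whole horizon."""
        out = []
        for d in range(self.days):
            for e in self.events:
                out.append((d * MINUTES_PER_DAY + e.time_min, e))
        return sorted(out, key=lambda p: p[0])

    def describe(self) -> str:
        parts = [f"{e.amount_mg:g} mg {e.route} @{int(e.time_min)//60:02d}:"
                 f"{int(e.time_min) % 60:02d}" for e in self.events]
        return f"{self.drug} " + " + ".join(parts)


@dataclass(frozen=True)
class LinearPKParams:
    """Two-compartment linear PK with first-order oral absorption."""

    drug: str
    CL: float                 # clearance, L/min
    Vc: float                 # central volume, L
    Q: float                  # intercompartmental clearance, L/min
    Vp: float                 # peripheral volume, L
    ka: float                 # absorption rate, min^-1
    F: float                  # oral bioavailability
    fu: float                 # free (unbound) plasma fraction
    MW_drug: float            # g/mol
    salt_mw: dict = field(default_factory=dict)
    iv_salt_default: str | None = None
    authoritative: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.F <= 1 and 0 < self.fu <= 1):
            raise ValueError("F and fu must lie in (0, 1]")
        for name in ("CL", "Vc", "Q", "Vp", "ka", "MW_drug"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def dose_nmol(self, event: DoseEvent) -> float:
        """Active-drug nmol delivered systemically by one dose event."""
        mw = self.MW_drug
        if event.route == "IV":
            salt = event.salt or self.iv_salt_default
            if salt:
                if salt not in self.salt_mw:
                    raise ValueError(f"unknown salt {salt!r} for {self.drug}")
                # dose is weighed as the salt ester; convert to drug equivalents
                return event.amount_mg / self.salt_mw[salt] * 1e6
            return event.amount_mg / mw * 1e6
        return self.F * event.amount_mg / mw * 1e6


@dataclass(frozen=True)
class PrednisonePKParams:
    """Interconverting prednisone/prednisolone model with nonlinear binding."""

    drug: str
    ka: float
    F: float
    MW_drug: float
    MW_active: float
    V_pn: float
    V_pl: float
    CL_pn_free: float         # elimination clearances acting on free conc.
    CL_pl_free: float
    CL_pn_to_pl: float        # interconversion clearances (free conc.)
    CL_pl_to_pn: float
    first_pass_to_active: float      # fraction converted to prednisolone on absorption
    fu_pn_albumin_ratio: float       # bound/free ratio, linear prednisone binding
    Bmax_nM: float                   # transcortin capacity
    Kd_nM: float                     # transcortin dissociation constant
    albumin_ratio: float             # linear component of prednisolone binding
    authoritative: bool = False

    def __post_init__(self) -> None:
        for name in ("ka", "MW_drug", "MW_active", "V_pn", "V_pl",
                     "CL_pn_free", "CL_pl_free", "CL_pn_to_pl", "CL_pl_to_pn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.Bmax_nM < 0 or self.Kd_nM <= 0 or self.albumin_ratio < 0:
            raise ValueError("binding parameters out of range")
        if not 0 <= self.first_pass_to_active <= 1:
            raise ValueError("first-pass conversion fraction must lie in [0, 1]")

    @property
    def fu_pn(self) -> float:
        return 1.0 / (1.0 + self.fu_pn_albumin_ratio)


def load_pk_params(drug: str) -> LinearPKParams | PrednisonePKParams:
    """Load the packaged PK parameter set for a drug."""
    key = drug.strip().lower()
    if key in ("dex",):
        key = "dexamethasone"
    if key in ("mp",):
        key = "methylprednisolone"
    if key not in _PK_DATA:
        raise KeyError(f"no PK parameters for {drug!r}; "
                       f"available: {', '.join(sorted(_PK_DATA))}")
    raw = _PK_DATA[key]
    if raw["model"] == "linear2c":
        return LinearPKParams(
            drug=key, CL=raw["CL"], Vc=raw["Vc"], Q=raw["Q"], Vp=raw["Vp"],
            ka=raw["ka"], F=raw["F"], fu=raw["fu"], MW_drug=raw["MW_drug"],
            salt_mw={k: v["MW_salt"] for k, v in (raw.get("salts") or {}).items()},
            iv_salt_default=raw.get("iv_salt_default"),
            authoritative=bool(raw.get("authoritative", False)),
        )
    b = raw["prednisolone_binding"]
    return PrednisonePKParams(
        drug=key, ka=raw["ka"], F=raw["F"], MW_drug=raw["MW_drug"],
        MW_active=raw["MW_active"], V_pn=raw["V_pn"], V_pl=raw["V_pl"],
        CL_pn_free=raw["CL_pn_free"], CL_pl_free=raw["CL_pl_free"],
        CL_pn_to_pl=raw["CL_pn_to_pl"], CL_pl_to_pn=raw["CL_pl_to_pn"],
        first_pass_to_active=raw["first_pass_to_active"],
        fu_pn_albumin_ratio=raw["fu_pn_albumin_ratio"],
        Bmax_nM=b["Bmax_nM"], Kd_nM=b["Kd_nM"], albumin_ratio=b["albumin_ratio"],
        authoritative=bool(raw.get("authoritative", False)),
    )


def regimen_builder(drug: str, total_daily_mg: float,
                    schedule: str, route: Route,
                    days: int = 2, clock_min: float = 480.0) -> Regimen:
    """Build a q.d./b.i.d. regimen from a total daily dose.

    q.d. gives the whole dose as one morning event; b.i.d. splits it into
    two equal doses 12 h apart.
    """
    drug = drug.strip().lower()
    if drug == "prednisone" and route == "IV":
        raise ValueError("prednisone is administered orally only")
    token = schedule.strip().lower().replace(".", "")
    if token == "qd":
        events = (DoseEvent(drug, route, total_daily_mg, clock_min),)
    elif token == "bid":
        half = total_daily_mg / 2.0
        events = (DoseEvent(drug, route, half, clock_min),
                  DoseEvent(drug, route, half,
                            (clock_min + MINUTES_PER_DAY / 2) % MINUTES_PER_DAY))
    else:
        raise ValueError(f"unknown schedule {schedule!r} (use 'q.d.' or 'b.i.d.')")
    return Regimen(events=events, days=days)


_LINE_RE = re.compile(
    r"^\s*(?P<drug>[a-zA-Z]+)\s+(?P<mg>[\d.]+)\s*mg\s+(?P<route>iv|oral)"
    r"\s+(?P<sched>q\.?d\.?|b\.?i\.?d\.?)\s*$", re.IGNORECASE)


def parse_regimen_line(line: str, days: int = 2) -> Regimen:
    """Parse compact regimen syntax, e.g. ``"prednisone 100mg oral b.i.d."``."""
    m = _LINE_RE.match(line)
    if not m:
        raise ValueError(f"cannot parse regimen {line!r}")
    route: Route = "IV" if m.group("route").upper() == "IV" else "oral"
    return regimen_builder(m.group("drug"), float(m.group("mg")),
                           m.group("sched"), route, days=days)


# ---------------------------------------------------------------------------
# Profile generation


def _linear_profile(regimen: Regimen, p: LinearPKParams) -> ConcentrationProfile:
    # states: gut amount, central amount, peripheral amount (nmol)
    M = np.array([
        [-p.ka, 0.0, 0.0],
        [p.ka, -(p.CL + p.Q) / p.Vc, p.Q / p.Vp],
        [0.0, p.Q / p.Vc, -p.Q / p.Vp],
    ])
    dt = 1.0
    P = expm(M * dt)
    horizon = int(regimen.days * MINUTES_PER_DAY)
    t = np.arange(0.0, horizon + dt / 2, dt)
    y = np.zeros(3)
    doses = {int(round(tm)): [] for tm, _ in regimen.dose_times()}
    for tm, e in regimen.dose_times():
        doses[int(round(tm))].append(e)
    amounts = np.zeros((len(t), 3))
    for i, ti in enumerate(t):
        for e in doses.get(int(ti), []):
            nmol = p.dose_nmol(e)
            if e.route == "IV":
                y[1] += nmol
            else:
                y[0] += nmol            # F already applied in dose_nmol
        amounts[i] = y
        y = P @ y
    free = p.fu * amounts[:, 1] / p.Vc   # nmol/L = nM
    return from_samples(t, free, breakpoints=[tm for tm, _ in regimen.dose_times()])


def prednisolone_free_fraction(total_nM: float, params: PrednisonePKParams) -> float:
    """Unbound fraction of prednisolone at a given total concentration.

    Solves the binding equilibrium ``total = free*(1 + N) + Bmax*free /
    (Kd + free)`` (N = linear albumin-like bound/free ratio) for the free
    concentration.  The fraction rises from ``1/(1 + N + Bmax/Kd)`` at
    trace levels towards ``1/(1 + N)`` once transcortin saturates.
    """
    if total_nM < 0:
        raise ValueError("total concentration must be >= 0")
    a = 1.0 + params.albumin_ratio
    if params.Bmax_nM == 0:
        return 1.0 / a
    if total_nM == 0:
        return 1.0 / (a + params.Bmax_nM / params.Kd_nM)
    # a*f^2 + (a*Kd + Bmax - total)*f - total*Kd = 0
    b = a * params.Kd_nM + params.Bmax_nM - total_nM
    c = -total_nM * params.Kd_nM
    free = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
    return float(free / total_nM)


def _prednisone_profile(regimen: Regimen,
                        p: PrednisonePKParams,
                        with_species: bool = False):
    def free_pl_conc(A_pl: float) -> float:
        total = A_pl / p.V_pl
        return total * prednisolone_free_fraction(total, p)

    def rhs(t, y):
        Agut, A_pn, A_pl = y
        free_pn = p.fu_pn * A_pn / p.V_pn
        free_pl = free_pl_conc(A_pl)
        absorb = p.ka * Agut
        fp = p.first_pass_to_active
        return [
            -absorb,
            (1.0 - fp) * absorb - (p.CL_pn_free + p.CL_pn_to_pl) * free_pn
            + p.CL_pl_to_pn * free_pl,
            fp * absorb + p.CL_pn_to_pl * free_pn
            - (p.CL_pl_free + p.CL_pl_to_pn) * free_pl,
        ]

    horizon = regimen.days * MINUTES_PER_DAY
    t = np.arange(0.0, horizon + 0.5, 1.0)
    dose_list = regimen.dose_times()
    edges = sorted({0.0, horizon} | {tm for tm, _ in dose_list})
    y = np.zeros(3)
    out = np.empty((len(t), 3))
    out[0] = y
    for a, b in zip(edges[:-1], edges[1:]):
        for tm, e in dose_list:
            if tm == a:
                y[0] += p.F * e.amount_mg / p.MW_drug * 1e6
        mask = (t > a) & (t <= b)
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=t[mask],
                        rtol=1e-8, atol=1e-9)
        if not sol.success:
            raise RuntimeError(f"prednisone PK integration failed: {sol.message}")
        out[mask] = sol.y.T
        y = sol.y[:, -1].copy()

    total_pl = out[:, 2] / p.V_pl
    free_pl = np.array([c * prednisolone_free_fraction(c, p) for c in total_pl])
    profile = from_samples(t, free_pl,
                           breakpoints=[tm for tm, _ in dose_list])
    if not with_species:
        return profile
    total_pn = out[:, 1] / p.V_pn
    return profile, {"time_min": t, "total_prednisolone_nM": total_pl,
                     "total_prednisone_nM": total_pn,
                     "free_prednisolone_nM": free_pl}


def free_concentration(regimen: Regimen,
                       params: LinearPKParams | PrednisonePKParams,
                       with_species: bool = False):
    """Free active-species concentration profile (nM) for a regimen.

    For DEX/MP this is the free parent drug; for prednisone regimens it is
    free prednisolone, the pharmacodynamically active species.  Raises for
    mismatched drug/params or unsupported routes.
    """
    if regimen.drug != params.drug:
        raise ValueError(
            f"regimen drug {regimen.drug!r} does not match params for {params.drug!r}")
    if isinstance(params, PrednisonePKParams):
        for e in regimen.events:
            if e.route != "oral":
                raise ValueError("prednisone supports oral dosing only")
        return _prednisone_profile(regimen, params, with_species=with_species)
    if with_species:
        raise ValueError("species breakdown is only available for prednisone")
    return _linear_profile(regimen, params)
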