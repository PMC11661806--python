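"""Self-validation battery: derived vs published reference values.

Recomputes, from the packaged parameter sets, every desk-scale quantity the
source publication prints for the receptor model — the Michaelis-Menten
reduction constants, the infinite-dose maximum, the nadir-cortisol activity
anchors, the nuclear-localisation threshold, the cold-chase half-time band
and the calibrated endogenous-cortisol transcription quotient — and reports
pass/fail per row.  Dose-regimen transcription quotients are additionally
reported but are conditional on authoritative PK parameter sets: with the
shipped placeholder PK defaults those rows are reported as skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import model as m
from .ligands import get_ligand, default_rates
from .dynamics import ChaseProtocol, chase_simulate, decay_half_time
from .profiles import synthetic_cortisol
from .gtq import compute_gtq, regimen_gtq
from .pk import load_pk_params, regimen_builder
from .model import _packaged_yaml


@dataclass(frozen=True)
class CheckRow:
    check: str
    derived: float | None
    reference: float | None
    tolerance: str
    status: str  # pass | fail | skipped

    def as_dict(self) -> dict:
        return {"check": self.check, "derived": self.derived,
                "reference": self.reference, "tolerance": self.tolerance,
                "status": self.status}


def _cmp(name: str, derived: float, printed: float, abs_tol: float) -> CheckRow:
    ok = abs(derived - printed) <= abs_tol
    return CheckRow(name, derived, printed, f"±{abs_tol:g}",
                    "pass" if ok else "fail")


def model_constant_checks() -> list[CheckRow]:
    """Closed-form constants of the reductions vs their printed values."""
    rates = default_rates()
    dex = get_ligand("dexamethasone").params
    cort = get_ligand("cortisol").params
    hi = m.mm_high(dex, rates)
    lo = m.mm_low(dex, rates)
    lo_slow = m.mm_low(dex, m.RateConstants(k1=1.0))
    rows = [
        _cmp("high-regime denominator constant C", hi.denom_const, 31.0, 0.5),
        _cmp("high-regime VmaxH", hi.Vmax, 0.769, 0.0005),
        _cmp("dexamethasone Kn from KmT=5", m.kn_from_kmt(5.0, rates), 155.0, 0.5),
        _cmp("cortisol Kn from KmT=50", m.kn_from_kmt(50.0, rates), 1550.0, 5.0),
        _cmp("prednisolone/MP Kn from KmT=15", m.kn_from_kmt(15.0, rates), 465.0, 0.5),
        _cmp("low-regime denominator constant D", lo.denom_const, 31.5, 0.05),
        _cmp("low-regime VmaxL", lo.Vmax, 0.0317, 5e-5),
        _cmp("dexamethasone KmL (nM)", lo.Km, 0.000787, 5e-7),
        _cmp("dexamethasone KmL at k1=1 (nM)", lo_slow.Km, 0.0079, 5e-5),
        _cmp("cortisol KmL (nM)", m.mm_low(cort, rates).Km, 0.0118, 5e-5),
        _cmp("infinite-dose maximum RnGNmax", m.rngn_max(rates), 0.806, 5e-4),
    ]
    st = m.steady_state(cort, rates, 1.45)
    rows.append(_cmp("full-model relative activity at 1.45 nM cortisol",
                     m.relative_activity(st, rates), 0.074, 0.002))
    rows.append(_cmp("empirical MM relative activity at 1.45 nM (KmT=50)",
                     float(m.mm_activity(m.mm_experimental(cort), 1.45)),
                     0.028, 0.001))
    nuc = m.nuclear_fraction(m.steady_state(get_ligand("dexamethasone").params,
                                            rates, 0.01))
    rows.append(CheckRow("nuclear fraction at 0.01 nM DEX >= 0.90",
                         nuc, 0.90, ">=", "pass" if nuc >= 0.90 else "fail"))
    return rows


def chase_checks() -> list[CheckRow]:
    rates = default_rates()
    dex = get_ligand("dexamethasone").params
    res = chase_simulate(dex, rates, ChaseProtocol())
    half = decay_half_time(res.time, res.labeled_nuclear, t_from=100.0)
    ok = 15.0 <= half <= 30.0
    return [CheckRow("cold-chase labeled-nuclear decay half-time (min)",
                     half, 25.0, "15-30 band", "pass" if ok else "fail")]


def cortisol_checks() -> list[CheckRow]:
    rates = default_rates()
    cort = get_ligand("cortisol").params
    prof = synthetic_cortisol()
    res = compute_gtq(cort, rates, prof, method="dynamic")
    from .dynamics import SimProtocol, simulate
    traj = simulate(cort, rates, SimProtocol(profile=prof, t_end=2880.0))
    peak = float(traj.relative_activity[traj.time >= 1440.0].max())
    return [
        _cmp("endogenous-cortisol GTQ (calibrated curve)", res.value, 0.17, 0.02),
        _cmp("endogenous-cortisol peak relative activity", peak, 0.39, 0.02),
    ]


def dose_table_checks() -> list[CheckRow]:
    """Dose-regimen GTQ rows; skipped unless the PK set is authoritative."""
    rates = default_rates()
    rows: list[CheckRow] = []
    ref = _packaged_yaml("regimen_gtq_reference.yaml")["rows"]
    ligand_of = {"dexamethasone": "dexamethasone",
                 "methylprednisolone": "methylprednisolone",
                 "prednisone": "prednisolone"}
    for r in ref:
        name = (f"GTQ {r['drug']} {r['dose_mg']} mg {r['route']} {r['schedule']}")
        pk = load_pk_params(r["drug"])
        if not pk.authoritative:
            rows.append(CheckRow(name, None, r["gtq"], "±0.01",
                                 "skipped: awaiting supplementary parameters"))
            continue
        reg = regimen_builder(r["drug"], r["dose_mg"], r["schedule"], r["route"])
        res = regimen_gtq(reg, pk, get_ligand(ligand_of[r["drug"]]).params, rates)
        rows.append(_cmp(name, res.value, r["gtq"], 0.01))
    return rows


def validate_against_paper(include_dose_table: bool = True) -> pd.DataFrame:
    """Run the full battery and return a tidy pass/fail report."""
    rows = model_constant_checks() + chase_checks() + cortisol_checks()
    if include_dose_table:
        rows += dose_table_checks()
    return pd.DataFrame([r.as_dict() for r in rows])
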