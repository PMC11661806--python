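"""Curated glucocorticoid parameter library.

Packaged reference data for the four modeled glucocorticoids (dexamethasone,
cortisol, prednisolone, methylprednisolone) plus the cell-line EC50 survey
kept for documentation and sensitivity work.  The library is immutable at
runtime; accessors hand out copies.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import pandas as pd

from .model import LigandParams, RateConstants, _REFERENCE, _packaged_yaml, kn_from_kmt, mm_low

__all__ = ["LigandRecord", "LIGAND_NAMES", "get_ligand", "default_rates",
           "cell_line_survey", "consistency_report"]

LIGAND_NAMES = tuple(_REFERENCE["ligands"])


@dataclass(frozen=True)
class LigandRecord:
    """One library entry: model parameters plus the printed reference values."""

    ligand: str
    params: LigandParams
    KmT_reference: float
    KmL_reference: float          # low-regime Km as printed in the source table
    KmL_suspected_erratum: bool
    source: str


def default_rates() -> RateConstants:
    """The shared reference rate constants k1-k6."""
    return RateConstants()


def get_ligand(name: str) -> LigandRecord:
    """Look up a packaged glucocorticoid parameter set by name."""
    key = name.strip().lower()
    aliases = {"dex": "dexamethasone", "mp": "methylprednisolone",
               "hydrocortisone": "cortisol"}
    key = aliases.get(key, key)
    if key not in _REFERENCE["ligands"]:
        raise KeyError(
            f"unknown ligand {name!r}; available: {', '.join(sorted(LIGAND_NAMES))}")
    raw = copy.deepcopy(_REFERENCE["ligands"][key])
    params = LigandParams(name=key, Kc=float(raw["Kc_nM"]), Kn=float(raw["Kn_nM"]),
                          KmT=float(raw["KmT_nM"]), Rtot=float(_REFERENCE["Rtot"]))
    return LigandRecord(
        ligand=key,
        params=params,
        KmT_reference=float(raw["KmT_nM"]),
        KmL_reference=float(raw["KmL_printed_nM"]),
        KmL_suspected_erratum=bool(raw.get("KmL_suspected_erratum", False)),
        source=str(raw.get("source", "")),
    )


def cell_line_survey() -> pd.DataFrame:
    """Cell-culture KmT survey (reference data; feeds no default computation)."""
    return pd.DataFrame(_packaged_yaml("cell_lines.yaml")["cell_lines"])


def _round_to_printed(value: float, printed: float) -> float:
    """Round ``value`` to the decimal precision of the printed literal."""
    s = f"{printed:.10f}".rstrip("0")
    decimals = len(s.split(".")[1]) if "." in s else 0
    return round(value, decimals)


def consistency_report(rates: RateConstants | None = None) -> pd.DataFrame:
    """Recompute the derived constants for every ligand and diff vs printed.

    For each packaged glucocorticoid, recomputes ``Kn`` (from ``KmT`` via the
    high-concentration reduction) and ``KmL`` (low-concentration reduction)
    from the model and compares them with the printed reference values at the
    printed precision.  ``status`` is "pass" where they agree and "flag"
    where they do not (the prednisolone ``KmL`` row is the known outlier:
    its printed value is inconsistent with ``KmL`` scaling proportionally
    with ``Kc``).
    """
    rates = rates or default_rates()
    rows = []
    for name in LIGAND_NAMES:
        rec = get_ligand(name)
        derived_kn = kn_from_kmt(rec.KmT_reference, rates)
        rows.append({"ligand": name, "quantity": "Kn_nM",
                     "derived": derived_kn, "printed": rec.params.Kn,
                     "status": "pass" if derived_kn == rec.params.Kn else "flag"})
        kml = mm_low(rec.params, rates, form="printed").Km
        agree = _round_to_printed(kml, rec.KmL_reference) == rec.KmL_reference
        rows.append({"ligand": name, "quantity": "KmL_nM",
                     "derived": kml, "printed": rec.KmL_reference,
                     "status": "pass" if agree else "flag"})
    return pd.DataFrame(rows)
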