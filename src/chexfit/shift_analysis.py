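"""Chemical-shift analytics: CSP, temperature coefficients, state correlations
and secondary-shift propensity profiles.

The chemical-shift perturbation between two conditions combines amide 1H
and 15N changes as CSP = sqrt(dH^2 + (dN/10)^2), the 15N change down-scaled
by its larger shift dispersion.  State correlations (e.g. bound-state
versus ground- or excited-state 15N shifts) are ordinary least-squares
regressions with per-residue residuals for outlier mapping.  Secondary
shifts are deviations from random-coil reference values; their weighted
combination scores local helix (positive) versus strand (negative)
propensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ResidueID, ShiftTable

__all__ = [
    "CSPRecord",
    "CorrelationReport",
    "csp",
    "temperature_coefficients",
    "state_correlation",
    "secondary_shift_profile",
    "load_random_coil_table",
]

# weights for the combined secondary-shift propensity score; CA and CO move
# downfield and CB/HA upfield in helices, N is down-weighted for its large
# non-structural spread
SECONDARY_WEIGHTS = {"CA": 1.0, "CB": -1.0, "C": 1.0, "N": -0.25, "HA": -4.0}
SECONDARY_ATOMS = tuple(SECONDARY_WEIGHTS)


@dataclass(frozen=True)
class CSPRecord:
    residue: ResidueID
    delta_h: float      # ppm
    delta_n: float      # ppm
    csp: float          # ppm


@dataclass
class CorrelationReport:
    slope: float
    intercept: float
    r_squared: float
    n_pairs: int
    residuals: dict = field(default_factory=dict)   # ResidueID -> residual
    excluded: dict = field(default_factory=dict)    # ResidueID -> reason


def _amide_h(table: ShiftTable, rid: ResidueID) -> float | None:
    for atom in ("H", "HN"):
        if (rid, atom) in table:
            return table[(rid, atom)]
    return None


def csp(table_a: ShiftTable, table_b: ShiftTable) -> list[CSPRecord]:
    """Per-residue chemical-shift perturbations between two conditions.

    CSP = sqrt(dH^2 + (dN/10)^2) over residues with amide 1H and 15N
    entries in both tables; residues missing either assignment are reported
    with a warning (they typically mark exchange-broadened amides).
    """
    records = []
    missing = []
    residues = sorted(set(table_a.residues()) | set(table_b.residues()),
                      key=lambda r: (r.chain, r.number))
    for rid in residues:
        ha, hb = _amide_h(table_a, rid), _amide_h(table_b, rid)
        na = table_a[(rid, "N")] if (rid, "N") in table_a else None
        nb = table_b[(rid, "N")] if (rid, "N") in table_b else None
        if None in (ha, hb, na, nb):
            missing.append(rid)
            continue
        dh = hb - ha
        dn = nb - na
        records.append(CSPRecord(rid, dh, dn, float(np.hypot(dh, dn / 10.0))))
    if missing:
        warnings.warn(
            f"{len(missing)} residue(s) missing amide assignments in one "
            f"condition: {', '.join(str(r) for r in missing[:8])}", stacklevel=2)
    if not records:
        warnings.warn("no residues shared between the two shift tables",
                      stacklevel=2)
    return records


def temperature_coefficients(tables: list[ShiftTable],
                             atoms: tuple[str, ...] = ("N", "H")
                             ) -> pd.DataFrame:
    """Per-residue amide shift temperature coefficients in ppb/K.

    Fits a line to shift versus temperature for every (residue, atom)
    assigned at >= 3 temperatures; residues observed at fewer temperatures
    are skipped and reported in the ``skipped`` column semantics via a
    warning.
    """
    if len({t.temperature for t in tables}) < 3:
        raise ValueError("need shift tables at >= 3 distinct temperatures")
    rows, skipped = [], []
    keys = sorted({(rid, atom) for t in tables for (rid, atom) in t.entries
                   if atom in atoms or (atom == "HN" and "H" in atoms)},
                  key=lambda k: (k[0].chain, k[0].number, k[1]))
    for rid, atom in keys:
        temps, shifts = [], []
        for t in tables:
            if (rid, atom) in t:
                temps.append(t.temperature)
                shifts.append(t[(rid, atom)])
        if len(set(temps)) < 3:
            skipped.append((rid, atom))
            continue
        res = stats.linregress(temps, shifts)
        rows.append({
            "residue_number": rid.number, "residue_name": rid.name,
            "atom": atom,
            "coeff_ppb_per_K": res.slope * 1e3,
            "coeff_err_ppb_per_K": (res.stderr * 1e3
                                    if np.isfinite(res.stderr) else np.nan),
            "intercept_ppm": res.intercept,
        })
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} residue/atom pairs with < 3 temperatures",
            stacklevel=2)
    return pd.DataFrame(rows)


def state_correlation(table_a: ShiftTable, table_b: ShiftTable,
                      atom: str = "N",
                      exclusions: set[int] | None = None) -> CorrelationReport:
    """OLS correlation of one nucleus's shifts between two states/conditions.

    Returns slope, intercept, R-squared and per-residue residuals (state B
    regressed on state A).  Residues in ``exclusions`` or missing in either
    table are reported with their reason.
    """
    exclusions = exclusions or set()
    pairs, report = [], CorrelationReport(np.nan, np.nan, np.nan, 0)
    residues = sorted(set(table_a.residues()) | set(table_b.residues()),
                      key=lambda r: (r.chain, r.number))
    for rid in residues:
        if rid.number in exclusions:
            report.excluded[rid] = "excluded by caller"
            continue
        if (rid, atom) not in table_a or (rid, atom) not in table_b:
            report.excluded[rid] = f"missing {atom} assignment"
            continue
        pairs.append((rid, table_a[(rid, atom)], table_b[(rid, atom)]))
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 shared residues, got {len(pairs)}")
    x = np.array([a for _, a, _ in pairs])
    y = np.array([b for _, _, b in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance: R^2 undefined")
    res = stats.linregress(x, y)
    report.slope = float(res.slope)
    report.intercept = float(res.intercept)
    report.r_squared = float(res.rvalue**2)
    report.n_pairs = len(pairs)
    for (rid, a, b) in pairs:
        report.residuals[rid] = float(b - (res.slope * a + res.intercept))
    return report


def load_random_coil_table(path: str | Path | None = None) -> pd.DataFrame:
    """Random-coil reference shifts (ppm), indexed by three-letter code."""
    if path is None:
        ref = resources.files("chexfit").joinpath("data/random_coil_shifts.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return df.set_index("residue_name")


def secondary_shift_profile(table: ShiftTable,
                            reference: pd.DataFrame | None = None,
                            neighbor_corrections: dict | None = None,
                            weights: dict | None = None) -> pd.DataFrame:
    """Secondary shifts ddelta = delta_obs - delta_rc and a propensity score.

    ``neighbor_corrections`` optionally maps (neighbor residue name, atom,
    position) with position in {-1, +1} to an additive ppm correction of the
    random-coil value (the published correction sets differ; none is
    applied by default).  The combined score is the weighted sum of the
    per-atom secondary shifts with ``SECONDARY_WEIGHTS``; positive values
    indicate helical propensity.
    """
    reference = reference if reference is not None else load_random_coil_table()
    weights = weights or SECONDARY_WEIGHTS
    residues = table.residues()
    by_number = {r.number: r for r in residues}
    rows, skipped = [], []
    for rid in residues:
        if rid.name not in reference.index:
            skipped.append(rid)
            continue
        row = {"residue_number": rid.number, "residue_name": rid.name}
        score, wsum = 0.0, 0.0
        for atom in SECONDARY_ATOMS:
            if (rid, atom) not in table:
                continue
            rc = reference.loc[rid.name, atom]
            if pd.isna(rc):
                continue
            rc = float(rc)
            if neighbor_corrections:
                for pos in (-1, +1):
                    nb = by_number.get(rid.number + pos)
                    if nb is not None:
                        rc += neighbor_corrections.get((nb.name, atom, pos), 0.0)
            dd = table[(rid, atom)] - rc
            row[f"dd_{atom}"] = dd
            score += weights[atom] * dd
            wsum += abs(weights[atom])
        row["propensity"] = score / wsum if wsum else np.nan
        rows.append(row)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} residue(s) absent from the reference table",
            stacklevel=2)
    return pd.DataFrame(rows)
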