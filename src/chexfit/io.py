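"""Readers and writers for the tabular, NMR-STAR and PDB formats the pipeline touches.

Tabular schemas
---------------
intensity TSV (all relaxation-type experiments share one schema)::

    residue_number  residue_name  experiment  parameter  value  intensity  error

where ``experiment`` is one of ``T1``, ``T2``, ``hetnoe-sat``, ``hetnoe-ref``,
``cpmg`` or ``cest-<B1>hz`` (e.g. ``cest-15hz``), and ``parameter``/``value``
hold the independent variable: relaxation delay in s, ``nu_cpmg`` in Hz
(``value`` 0 marks the reference spectrum recorded without the constant-time
block) or saturation ``offset`` in ppm (CEST intensities are stored already
normalized to the no-saturation reference).

shift TSV:  ``residue_number  residue_name  atom  shift_ppm``
RDC TSV:    ``residue_number  d_hz  error_hz``

NMR-STAR support is limited to the atom-chemical-shift loop of v3 files, the
only loop the analysis consumes.  Coordinate ensembles are multi-MODEL PDB
files read through Bio.PDB; alternate locations keep the highest occupancy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .datamodel import (
    AMINO3,
    CESTProfile,
    ConformerEnsemble,
    RDCRecord,
    RelaxationSeries,
    ResidueID,
    ShiftTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ParseError",
    "FormatError",
    "CPMGIntensities",
    "read_intensity_table",
    "write_intensity_table",
    "read_shift_table",
    "write_shift_table",
    "read_rdc_table",
    "write_rdc_table",
    "read_ensemble",
    "write_ensemble",
]

INTENSITY_COLUMNS = [
    "residue_number", "residue_name", "experiment", "parameter",
    "value", "intensity", "error",
]


class SchemaError(ValueError):
    """A required column is missing or mislabelled."""


class ParseError(ValueError):
    """A cell could not be parsed; the message carries the location."""


class FormatError(ValueError):
    """A structured file (NMR-STAR, PDB) lacks the expected content."""


@dataclass
class CPMGIntensities:
    """Raw CPMG peak intensities for one residue, prior to R2,eff conversion.

    Duplicate ``nu_cpmg`` values are preserved for error estimation; the
    reference intensity is the spectrum recorded without the CPMG block.
    """

    residue: ResidueID
    nu_cpmg: np.ndarray
    intensities: np.ndarray
    errors: np.ndarray
    reference: float
    reference_error: float = 0.0


def _residue_id(number: int, name: str, chain: str = "A") -> ResidueID:
    name = str(name).upper()
    if name not in AMINO3:
        name = "UNK"
    return ResidueID(chain, int(number), name)


def _load_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        warnings.warn(f"{path} is empty", stacklevel=3)
        return pd.DataFrame(columns=required)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def _numeric(df: pd.DataFrame, columns: list[str], path: Path | str) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0]) + 2  # header + 1-based
            raise ParseError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} "
                f"in column {col!r} at row {row}"
            )
        df[col] = converted
    return df


def read_intensity_table(
    path: str | Path,
    kind: str,
    *,
    with_report: bool = False,
):
    """Read a per-residue intensity table for one experiment kind.

    ``kind`` selects the schema: ``T1``/``T2``/``hetnoe`` return
    :class:`RelaxationSeries`, ``cpmg`` returns :class:`CPMGIntensities`
    and ``cest`` returns :class:`CESTProfile` (one per residue and B1 field).
    Rows whose ``experiment`` tag does not match ``kind`` are skipped and
    reported; nothing is dropped silently.
    """
    df = _load_tsv(path, INTENSITY_COLUMNS)
    report: dict[str, int] = {"total": len(df), "parsed": 0, "skipped": 0}
    if df.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return ([], report) if with_report else []

    df = _numeric(df, ["residue_number", "value", "intensity", "error"], path)

    if kind == "hetnoe":
        keep = df["experiment"].isin(["hetnoe-sat", "hetnoe-ref"])
    elif kind == "cest":
        keep = df["experiment"].str.startswith("cest")
    else:
        keep = df["experiment"] == kind
    report["skipped"] = int((~keep).sum())
    if report["skipped"]:
        logger.warning("%s: skipped %d rows of other experiment kinds",
                       path, report["skipped"])
    df = df[keep]
    report["parsed"] = len(df)

    records: list = []
    if kind in ("T1", "T2"):
        for (num, name), grp in df.groupby(["residue_number", "residue_name"], sort=True):
            records.append(RelaxationSeries(
                residue=_residue_id(num, name),
                delays=grp["value"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                errors=grp["error"].to_numpy(),
                kind=kind,
            ))
    elif kind == "hetnoe":
        for (num, name, exp), grp in df.groupby(
                ["residue_number", "residue_name", "experiment"], sort=True):
            records.append(RelaxationSeries(
                residue=_residue_id(num, name),
                delays=grp["value"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                errors=grp["error"].to_numpy(),
                kind=exp,
            ))
    elif kind == "cpmg":
        for (num, name), grp in df.groupby(["residue_number", "residue_name"], sort=True):
            ref = grp[grp["value"] == 0.0]
            pts = grp[grp["value"] > 0.0]
            if ref.empty:
                raise FormatError(
                    f"{path}: residue {int(num)} lacks a reference row (value = 0)")
            records.append(CPMGIntensities(
                residue=_residue_id(num, name),
                nu_cpmg=pts["value"].to_numpy(),
                intensities=pts["intensity"].to_numpy(),
                errors=pts["error"].to_numpy(),
                reference=float(ref["intensity"].iloc[0]),
                reference_error=float(ref["error"].iloc[0]),
            ))
    elif kind == "cest":
        for (num, name, exp), grp in df.groupby(
                ["residue_number", "residue_name", "experiment"], sort=True):
            try:
                b1 = float(str(exp).removeprefix("cest-").removesuffix("hz"))
            except ValueError:
                raise FormatError(f"{path}: cannot parse B1 from experiment tag {exp!r}")
            grp = grp.sort_values("value", ascending=False)
            records.append(CESTProfile(
                residue=_residue_id(num, name),
                offsets=grp["value"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                errors=grp["error"].to_numpy(),
                b1_hz=b1,
            ))
    else:
        raise ValueError(f"unknown experiment kind {kind!r}")

    return (records, report) if with_report else records


def write_intensity_table(records, path: str | Path) -> None:
    """Write relaxation-type records back to the shared intensity schema."""
    rows = []
    for rec in records:
        if isinstance(rec, RelaxationSeries):
            for d, i, e in zip(rec.delays, rec.intensities, rec.errors):
                rows.append((rec.residue.number, rec.residue.name, rec.kind,
                             "delay", d, i, e))
        elif isinstance(rec, CPMGIntensities):
            rows.append((rec.residue.number, rec.residue.name, "cpmg",
                         "nu_cpmg", 0.0, rec.reference, rec.reference_error))
            for nu, i, e in zip(rec.nu_cpmg, rec.intensities, rec.errors):
                rows.append((rec.residue.number, rec.residue.name, "cpmg",
                             "nu_cpmg", nu, i, e))
        elif isinstance(rec, CESTProfile):
            tag = f"cest-{rec.b1_hz:g}hz"
            for o, i, e in zip(rec.offsets, rec.intensities, rec.errors):
                rows.append((rec.residue.number, rec.residue.name, tag,
                             "offset", o, i, e))
        else:
            raise TypeError(f"cannot serialize {type(rec).__name__}")
    df = pd.DataFrame(rows, columns=INTENSITY_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# chemical shifts

def read_shift_table(path: str | Path, dialect: str | None = None,
                     field_mhz: float = 800.13,
                     temperature: float = 291.0) -> ShiftTable:
    """Read chemical shifts from TSV or from an NMR-STAR v3 shift loop.

    The dialect is inferred from the extension (.str/.star -> NMR-STAR)
    unless given explicitly.  Out-of-range amide shifts are kept and
    reported through :meth:`ShiftTable.out_of_range`.
    """
    path = Path(path)
    if dialect is None:
        dialect = "star" if path.suffix.lower() in (".str", ".star") else "tsv"
    table = ShiftTable(field_mhz=field_mhz, temperature=temperature)
    if dialect == "tsv":
        df = _load_tsv(path, ["residue_number", "residue_name", "atom", "shift_ppm"])
        df = _numeric(df, ["residue_number", "shift_ppm"], path)
        for _, row in df.iterrows():
            rid = _residue_id(row["residue_number"], row["residue_name"])
            key = (rid, str(row["atom"]).strip())
            if key in table:
                raise FormatError(f"{path}: duplicate shift entry for {key}")
            table[key] = row["shift_ppm"]
    elif dialect == "star":
        for seq, comp, atom, val in _iter_star_shift_loop(path):
            key = (_residue_id(seq, comp), atom)
            if key in table:
                raise FormatError(f"{path}: duplicate shift entry for {key}")
            table[key] = val
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    flagged = table.out_of_range()
    if flagged:
        logger.warning("%s: %d shift(s) outside expected amide ranges: %s",
                       path, len(flagged),
                       ", ".join(f"{r}{a}={v}" for r, a, v in flagged[:5]))
    return table


def _iter_star_shift_loop(path: Path):
    """Yield (seq_id, comp_id, atom_id, value) from the first atom-shift loop."""
    tokens_per_loop: list[tuple[list[str], list[list[str]]]] = []
    tags: list[str] = []
    data: list[list[str]] = []
    state = None  # None | 'tags' | 'data'
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "loop_":
                tags, data, state = [], [], "tags"
                continue
            if state == "tags":
                if line.startswith("_"):
                    tags.append(line.split()[0])
                    continue
                state = "data"
            if state == "data":
                if line == "stop_":
                    tokens_per_loop.append((tags, data))
                    state = None
                    continue
                if line.startswith("_") or line.startswith("save_"):
                    state = None
                    continue
                data.append(line.split())
    for tags, data in tokens_per_loop:
        if not any(t.startswith("_Atom_chem_shift.") for t in tags):
            continue
        names = [t.split(".", 1)[1] for t in tags]

        def col(*candidates: str) -> int:
            for c in candidates:
                if c in names:
                    return names.index(c)
            raise FormatError(f"{path}: shift loop lacks any of {candidates}")

        i_seq = col("Seq_ID", "Comp_index_ID")
        i_comp = col("Comp_ID")
        i_atom = col("Atom_ID")
        i_val = col("Val")
        for row in data:
            if len(row) != len(tags):
                continue
            yield int(row[i_seq]), row[i_comp], row[i_atom], float(row[i_val])
        return
    raise FormatError(f"{path}: no atom chemical-shift loop found")


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    rows = [(rid.number, rid.name, atom, ppm)
            for (rid, atom), ppm in sorted(table.entries.items(),
                                           key=lambda kv: (kv[0][0].number, kv[0][1]))]
    pd.DataFrame(rows, columns=["residue_number", "residue_name", "atom", "shift_ppm"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# RDCs

def read_rdc_table(path: str | Path) -> list[RDCRecord]:
    df = _load_tsv(path, ["residue_number", "d_hz", "error_hz"])
    df = _numeric(df, ["residue_number", "d_hz", "error_hz"], path)
    name_col = df["residue_name"] if "residue_name" in df.columns else None
    out = []
    for i, row in df.iterrows():
        name = name_col.iloc[i] if name_col is not None else "UNK"
        out.append(RDCRecord(
            residue=_residue_id(row["residue_number"], name),
            d_hz=float(row["d_hz"]),
            error_hz=float(row["error_hz"]),
        ))
    return out


def write_rdc_table(records: list[RDCRecord], path: str | Path) -> None:
    rows = [(r.residue.number, r.residue.name, r.d_hz, r.error_hz) for r in records]
    pd.DataFrame(rows, columns=["residue_number", "residue_name", "d_hz", "error_hz"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# coordinate ensembles

def read_ensemble(path: str | Path,
                  residues: set[int] | None = None,
                  atom_names: set[str] | None = None,
                  chain: str | None = None) -> ConformerEnsemble:
    """Read a (multi-MODEL) PDB file into a :class:`ConformerEnsemble`.

    The atom set is defined by the first model after selection filtering;
    models missing any selected atom are rejected and reported.  Alternate
    locations keep the highest-occupancy conformer.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(path))
    models = list(structure)
    if not models:
        raise FormatError(f"{path}: no models found")

    def model_atoms(model):
        atoms: dict[tuple[ResidueID, str], np.ndarray] = {}
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for res in ch:
                hetflag, resseq, _ = res.id
                if hetflag.strip():
                    continue
                if residues is not None and resseq not in residues:
                    continue
                name3 = res.get_resname() if res.get_resname() in AMINO3 else "UNK"
                rid = ResidueID(ch.id, resseq, name3)
                for atom in res:
                    if atom.is_disordered():
                        atom = max(atom, key=lambda a: a.get_occupancy() or 0.0)
                    if atom_names is not None and atom.get_name() not in atom_names:
                        continue
                    atoms[(rid, atom.get_name())] = atom.get_coord().astype(float)
        return atoms

    first = model_atoms(models[0])
    if not first:
        missing = sorted(residues)[:5] if residues else []
        raise FormatError(
            f"{path}: selection matches no atoms"
            + (f" (residues {missing}...)" if missing else ""))
    keys = list(first.keys())
    frames, rejected = [], []
    for mi, model in enumerate(models):
        atoms = model_atoms(model)
        try:
            frames.append(np.stack([atoms[k] for k in keys]))
        except KeyError as exc:
            rejected.append(mi)
            logger.warning("%s: model %d missing selected atom %s; rejected",
                           path, mi, exc)
    if not frames:
        raise FormatError(f"{path}: no complete models after selection filtering")
    if rejected:
        warnings.warn(f"{path}: rejected models {rejected} (missing selected atoms)",
                      stacklevel=2)
    return ConformerEnsemble(keys, np.stack(frames))


def write_ensemble(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-MODEL PDB file (amide/backbone naming)."""
    with open(path, "w") as fh:
        for mi in range(ensemble.n_models):
            fh.write(f"MODEL     {mi + 1:4d}\n")
            serial = 1
            for (rid, name), xyz in zip(ensemble.atoms, ensemble.coords[mi]):
                element = name.strip()[0]
                fh.write(
                    f"ATOM  {serial:5d} {name:^4s} {rid.name:>3s} {rid.chain:1s}"
                    f"{rid.number:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n")
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")
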