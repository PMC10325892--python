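"""Domain types shared by all analysis stages.

The pipeline revolves around a two-state conformational equilibrium
GS ⇌ ES between a dominant ground state and a sparsely populated excited
state.  Per-residue observables (exponential relaxation series, CPMG
dispersion profiles, CEST saturation profiles, RDCs) are represented as
small frozen dataclasses; coordinate ensembles as arrays of conformer
coordinate maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ResidueID",
    "ShiftTable",
    "RelaxationSeries",
    "CPMGProfile",
    "CESTProfile",
    "TwoStateModel",
    "RDCRecord",
    "ConformerEnsemble",
    "GAMMA_RATIO_15N",
    "AMINO3",
]

# |gamma(15N)/gamma(1H)|: converts a 1H spectrometer frequency in MHz to the
# 15N Larmor frequency (Hz per ppm).
GAMMA_RATIO_15N = 0.10136901

AMINO3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL UNK".split()
)


@dataclass(frozen=True, order=True)
class ResidueID:
    """A residue in author numbering, e.g. V122 -> ResidueID('A', 122, 'VAL')."""

    chain: str
    number: int
    name: str = "UNK"

    def __post_init__(self) -> None:
        if self.name not in AMINO3:
            raise ValueError(f"unknown residue name {self.name!r}")

    def __str__(self) -> str:  # V122-style label
        return f"{self.name}{self.number}"


def nitrogen_hz_per_ppm(field_mhz: float) -> float:
    """15N frequency in Hz per ppm at a given 1H spectrometer field (MHz)."""
    return field_mhz * GAMMA_RATIO_15N


@dataclass
class ShiftTable:
    """Chemical shifts keyed by (residue, atom name), in ppm.

    Amide 15N shifts are expected within 90-140 ppm and amide protons within
    5-12 ppm; entries outside these windows are kept but reported by
    :meth:`out_of_range`.
    """

    entries: dict[tuple[ResidueID, str], float] = field(default_factory=dict)
    field_mhz: float = 800.13
    temperature: float = 291.0

    N15_RANGE = (90.0, 140.0)
    H1_RANGE = (5.0, 12.0)

    def __setitem__(self, key: tuple[ResidueID, str], value: float) -> None:
        self.entries[key] = float(value)

    def __getitem__(self, key: tuple[ResidueID, str]) -> float:
        return self.entries[key]

    def __contains__(self, key: tuple[ResidueID, str]) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def residues(self) -> list[ResidueID]:
        return sorted({rid for rid, _ in self.entries}, key=lambda r: (r.chain, r.number))

    def out_of_range(self) -> list[tuple[ResidueID, str, float]]:
        """Entries whose amide 15N/1H shifts fall outside the expected windows."""
        flagged = []
        for (rid, atom), ppm in self.entries.items():
            if atom == "N" and not self.N15_RANGE[0] <= ppm <= self.N15_RANGE[1]:
                flagged.append((rid, atom, ppm))
            elif atom in ("H", "HN") and not self.H1_RANGE[0] <= ppm <= self.H1_RANGE[1]:
                flagged.append((rid, atom, ppm))
        return flagged


@dataclass
class RelaxationSeries:
    """Peak intensity versus relaxation delay for one residue.

    ``kind`` is one of ``T1``, ``T2``, ``hetnoe-sat``, ``hetnoe-ref``; the
    heteronuclear-NOE kinds carry exactly one point each (intensity with and
    without proton saturation).
    """

    residue: ResidueID
    delays: np.ndarray
    intensities: np.ndarray
    errors: np.ndarray
    kind: str = "T1"

    KINDS = ("T1", "T2", "hetnoe-sat", "hetnoe-ref")

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        if not (len(self.delays) == len(self.intensities) == len(self.errors)):
            raise ValueError("delays/intensities/errors length mismatch")
        if np.any(self.delays <= 0):
            raise ValueError("relaxation delays must be strictly positive")
        if len(np.unique(self.delays)) != len(self.delays):
            raise ValueError("relaxation delays must be unique")
        if self.kind.startswith("hetnoe") and len(self.delays) != 1:
            raise ValueError("hetNOE series carry exactly one intensity")


@dataclass
class CPMGProfile:
    """R2,eff versus refocusing frequency for one residue.

    Duplicate ``nu_cpmg`` entries (the repeated 750 and 50 Hz points) are
    preserved: they are the only source of the per-point error estimate.
    """

    residue: ResidueID
    nu_cpmg: np.ndarray          # Hz, duplicates allowed
    r2eff: np.ndarray            # s^-1
    r2eff_err: np.ndarray        # s^-1
    t_cp: float = 0.040          # constant-time delay, s
    field_mhz: float = 800.13
    temperature: float = 291.0
    reference_intensity: float = 1.0

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        self.r2eff_err = np.asarray(self.r2eff_err, dtype=float)
        if np.any(self.nu_cpmg <= 0):
            raise ValueError("nu_cpmg must be positive")
        if self.t_cp <= 0:
            raise ValueError("constant-time delay must be positive")

    def pulse_counts(self) -> np.ndarray:
        """Number of refocusing pulses per point, n = 2 nu T_CP (nearest even)."""
        n = 2.0 * self.nu_cpmg * self.t_cp
        return np.maximum(2, 2 * np.round(n / 2.0)).astype(int)


@dataclass
class CESTProfile:
    """Normalized intensity versus 15N saturation offset for one residue."""

    residue: ResidueID
    offsets: np.ndarray          # ppm, monotone
    intensities: np.ndarray      # I/I0
    errors: np.ndarray
    b1_hz: float = 30.0
    t_sat: float = 0.4           # saturation time, s
    field_mhz: float = 800.13
    temperature: float = 283.0

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        d = np.diff(self.offsets)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("offsets must be monotone")
        if self.b1_hz <= 0:
            raise ValueError("B1 must be positive")


@dataclass
class TwoStateModel:
    """Parameters of the GS ⇌ ES exchange process for one residue.

    kex = k_GE + k_EG is the total exchange rate; p_es the excited-state
    population (minor state by convention, p_es <= 0.5); delta_omega_ppm the
    15N shift difference δ_ES − δ_GS.
    """

    kex: float                   # s^-1
    p_es: float                  # fraction
    delta_omega_ppm: float = 0.0
    r2_0: float = 10.0           # exchange-free transverse rate, s^-1
    r1: float = 1.5              # s^-1
    delta_gs_ppm: float = 118.0  # ground-state 15N shift
    r2_es: float | None = None   # optional distinct ES transverse rate

    def __post_init__(self) -> None:
        if self.kex < 0:
            raise ValueError("kex must be non-negative")
        if not 0.0 <= self.p_es <= 0.5:
            raise ValueError("p_es must lie in [0, 0.5] (ES is the minor state)")

    @property
    def delta_es_ppm(self) -> float:
        return self.delta_gs_ppm + self.delta_omega_ppm

    @property
    def k_ge(self) -> float:
        return self.kex * self.p_es

    @property
    def k_eg(self) -> float:
        return self.kex * (1.0 - self.p_es)


@dataclass(frozen=True)
class RDCRecord:
    """One measured residual dipolar coupling (amide N-H by default)."""

    residue: ResidueID
    d_hz: float
    error_hz: float = 1.0
    bond: str = "N-H"


class ConformerEnsemble:
    """Multi-model coordinate set with a common atom list.

    ``coords`` has shape (n_models, n_atoms, 3) in Å; ``atoms`` is the
    parallel list of (ResidueID, atom name) keys.
    """

    def __init__(self, atoms: Sequence[tuple[ResidueID, str]], coords: np.ndarray):
        self.atoms = list(atoms)
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom list does not match coordinate array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self._index: dict[tuple[ResidueID, str], int] = {
            key: i for i, key in enumerate(self.atoms)
        }
        if len(self._index) != len(self.atoms):
            raise ValueError("duplicate atoms in ensemble")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, residue: ResidueID, atom: str) -> int:
        try:
            return self._index[(residue, atom)]
        except KeyError:
            raise KeyError(f"atom {atom} of residue {residue} not in ensemble") from None

    def select(self, residues: set[int] | None = None,
               atom_names: set[str] | None = None) -> "ConformerEnsemble":
        """Sub-ensemble restricted to given residue numbers / atom names."""
        idx = [
            i for i, (rid, name) in enumerate(self.atoms)
            if (residues is None or rid.number in residues)
            and (atom_names is None or name in atom_names)
        ]
        if not idx:
            raise ValueError("selection matches no atoms")
        return ConformerEnsemble([self.atoms[i] for i in idx], self.coords[:, idx, :])

    def residues(self) -> list[ResidueID]:
        seen: dict[ResidueID, None] = {}
        for rid, _ in self.atoms:
            seen.setdefault(rid)
        return list(seen)
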