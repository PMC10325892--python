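"""Synthetic two-state exchange datasets emulating the study's acquisition design.

Every generator draws from a seeded :class:`numpy.random.Generator`, writes
plain TSV tables in the shared intensity schema plus a JSON ground-truth
sidecar, and is bit-reproducible for a fixed configuration.  Defaults
reproduce the acquisition grids of the underlying experiments:

* CPMG: nine refocusing frequencies 50-2000 Hz with repeats at 750 and
  50 Hz, constant-time delay 40 ms, 800.13 MHz;
* CEST: 64 offsets from 134 to 99 ppm at B1 = 15 and 30 Hz, 0.4 s
  saturation;
* T1: eight recovery delays evenly covering 50-1100 ms; T2: delays
  5, 20, 35, 50, 70, 90 ms;
* multi-temperature series follow an Arrhenius law for kex (default
  activation energy 9.5 kcal/mol) anchored at the configured temperature.

Noise is additive Gaussian on intensities at a configurable fraction of the
reference intensity (default 1%, which puts the duplicate-derived
sigma(R2,eff) near 0.3-0.5 1/s); with ``noise=0`` the full pipeline is an
exact inverse problem.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cest as cest_mod
from . import cpmg as cpmg_mod
from .datamodel import (
    CESTProfile,
    ConformerEnsemble,
    RDCRecord,
    RelaxationSeries,
    ResidueID,
    TwoStateModel,
)
from .io import (
    CPMGIntensities,
    write_ensemble,
    write_intensity_table,
    write_rdc_table,
)
from .rdc import AlignmentTensor, predict_rdc
from .thermokinetics import arrhenius_rate

__all__ = [
    "ScenarioConfig",
    "SCENARIOS",
    "residue_set",
    "draw_truth",
    "gen_cpmg_dataset",
    "gen_cest_dataset",
    "gen_relaxation_dataset",
    "gen_rdc_dataset",
    "gen_ensemble",
    "toy_backbone",
]

_ONE2THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# residue sets used for global exchange analysis
WT_GLOBAL_SET = "K107 Q110 R111 F157 V159 T160"
TAN_GLOBAL_SET = ("G103 T105 T109 Q110 R111 K112 S113 G114 S116 A117 G118 "
                  "Y120 D121 Y123 I125 G129 K130 A131 F132 R133 N134 E137 "
                  "L138 A140 Y141 F142 V145 G146 T148 S149 N153")


def residue_set(name: str) -> list[ResidueID]:
    """The wt (6-residue) or TAN (31-residue) global-fit residue set."""
    sets = {"wt": WT_GLOBAL_SET, "tan": TAN_GLOBAL_SET}
    try:
        tokens = sets[name.lower()].split()
    except KeyError:
        raise ValueError(f"unknown residue set {name!r} (use 'wt' or 'tan')")
    return [ResidueID("A", int(tok[1:]), _ONE2THREE[tok[0]]) for tok in tokens]


@dataclass
class ScenarioConfig:
    """Ground-truth kinetics plus acquisition geometry for one scenario."""

    residues: list = field(default_factory=lambda: residue_set("wt"))
    kex: float = 5207.0            # total exchange rate at `temperature`, 1/s
    p_es: float = 0.02
    dw_bounds_ppm: tuple = (0.5, 6.0)   # |delta_omega| drawn log-uniform
    dw_signed: bool = True
    delta_gs_bounds_ppm: tuple = (108.0, 126.0)
    r2_0_bounds: tuple = (8.0, 15.0)
    r1_bounds: tuple = (1.2, 2.0)
    temperature: float = 291.0
    temperatures: tuple = (278.0, 283.0, 291.0)   # multi-T series
    ea_kcal: float = 9.5
    field_mhz: float = 800.13
    noise: float = 0.01            # fractional intensity sigma
    seed: int = 0
    # separate noise stream so repeated noise realizations of the same
    # ground truth are possible; defaults to a seed-derived stream
    noise_seed: int | None = None
    # acquisition grids
    t_cp: float = 0.040
    nu_grid: tuple = tuple(cpmg_mod.DEFAULT_NU_GRID)
    nu_duplicates: tuple = cpmg_mod.DEFAULT_DUPLICATES
    cest_offsets: tuple = tuple(cest_mod.DEFAULT_OFFSETS)
    cest_b1: tuple = cest_mod.DEFAULT_B1_FIELDS
    t_sat: float = cest_mod.DEFAULT_T_SAT
    t1_delays: tuple = tuple(np.linspace(0.050, 1.100, 8))
    t2_delays: tuple = (0.005, 0.020, 0.035, 0.050, 0.070, 0.090)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for name in ("kex", "noise", "t_cp", "t_sat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


def _scenarios() -> dict[str, ScenarioConfig]:
    return {
        # wild-type reader, modest fast exchange; shift differences of the
        # few dispersing residues drawn from 1-4 ppm
        "wt-291K": ScenarioConfig(residues=residue_set("wt"),
                                  kex=5207.0, p_es=0.02, temperature=291.0,
                                  dw_bounds_ppm=(1.0, 4.0)),
        # evolved hmC/mC reader, slower and more extensive exchange
        "tan-291K": ScenarioConfig(residues=residue_set("tan"),
                                   kex=1240.0, p_es=0.03, temperature=291.0),
        "tan-283K": ScenarioConfig(residues=residue_set("tan"),
                                   kex=458.0, p_es=0.03, temperature=283.0),
        # CEST reference kinetics at 283 K
        "tan-cest-283K": ScenarioConfig(residues=residue_set("tan")[:5],
                                        kex=572.0, p_es=0.03,
                                        temperature=283.0),
    }


SCENARIOS = _scenarios()


def draw_truth(config: ScenarioConfig) -> dict[ResidueID, TwoStateModel]:
    """Per-residue ground-truth models with seeded shift/baseline draws."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.dw_bounds_ppm
    truth = {}
    for rid in config.residues:
        mag = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        sign = float(rng.choice([-1.0, 1.0])) if config.dw_signed else 1.0
        truth[rid] = TwoStateModel(
            kex=config.kex, p_es=config.p_es,
            delta_omega_ppm=sign * mag,
            r2_0=float(rng.uniform(*config.r2_0_bounds)),
            r1=float(rng.uniform(*config.r1_bounds)),
            delta_gs_ppm=float(rng.uniform(*config.delta_gs_bounds_ppm)),
        )
    return truth


def _truth_sidecar(config: ScenarioConfig,
                   truth: dict[ResidueID, TwoStateModel],
                   extra: dict | None = None) -> dict:
    doc = {
        "kex": config.kex, "p_es": config.p_es,
        "temperature": config.temperature, "field_mhz": config.field_mhz,
        "noise": config.noise, "seed": config.seed,
        "residues": {
            str(rid): {
                "number": rid.number,
                "delta_omega_ppm": m.delta_omega_ppm,
                "delta_gs_ppm": m.delta_gs_ppm,
                "r2_0": m.r2_0, "r1": m.r1,
            } for rid, m in truth.items()
        },
    }
    doc.update(extra or {})
    return doc


def _write(out_dir, stem, records, sidecar):
    if out_dir is None:
        return
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_intensity_table(records, out_dir / f"{stem}.tsv")
    (out_dir / f"{stem}.truth.json").write_text(json.dumps(sidecar, indent=1))


def gen_cpmg_dataset(config: ScenarioConfig, out_dir: str | Path | None = None
                     ) -> tuple[list[CPMGIntensities], dict]:
    """CPMG intensity tables I(nu) = I0 exp(-R2,eff(nu) T_CP) + noise.

    Duplicate points at the configured repeat frequencies are included for
    error estimation.  Returns the raw records and the truth sidecar.
    """
    rng = np.random.default_rng(config.seed + 1 if config.noise_seed is None
                                else config.noise_seed)
    truth = draw_truth(config)
    nu = np.concatenate([np.asarray(config.nu_grid, dtype=float),
                         np.asarray(config.nu_duplicates, dtype=float)])
    records = []
    for rid, model in truth.items():
        r2eff = cpmg_mod.simulate_dispersion(model, nu, config.t_cp,
                                             config.field_mhz)
        i0 = 1.0
        ints = i0 * np.exp(-r2eff * config.t_cp)
        # noise scales with the local peak intensity, which makes the
        # duplicate-derived sigma(R2,eff) roughly uniform across the grid
        # (~0.3-0.5 1/s at the default 1% level)
        sigmas = config.noise * ints
        if config.noise > 0:
            ints = ints + rng.normal(0.0, 1.0, size=len(ints)) * sigmas
            ref = i0 + rng.normal(0.0, config.noise * i0)
        else:
            ref = i0
        records.append(CPMGIntensities(
            residue=rid, nu_cpmg=nu, intensities=ints,
            errors=sigmas,
            reference=float(ref), reference_error=config.noise * i0))
    sidecar = _truth_sidecar(config, truth, {"t_cp": config.t_cp,
                                             "experiment": "cpmg"})
    _write(out_dir, "cpmg", records, sidecar)
    return records, sidecar


def gen_cest_dataset(config: ScenarioConfig,
                     out_dir: str | Path | None = None,
                     multi_temperature: bool = False):
    """CEST profiles at the configured B1 fields (and optionally temperatures).

    With ``multi_temperature`` the ground-truth kex is Arrhenius-scaled from
    the anchor temperature with the configured activation energy and one
    dataset per temperature is produced (populations held fixed: the study
    design varies only the rate).  Returns ``(profiles, sidecar)`` or a
    ``{temperature: (profiles, sidecar)}`` mapping.
    """
    if multi_temperature:
        out = {}
        for t in config.temperatures:
            kex_t = float(arrhenius_rate(t, config.ea_kcal,
                                         config.temperature, config.kex))
            sub = config.replace(kex=kex_t, temperature=t,
                                 seed=config.seed)  # same shifts across T
            out[t] = gen_cest_dataset(sub, out_dir=None)
            if out_dir is not None:
                _write(out_dir, f"cest_{int(round(t))}K", out[t][0], out[t][1])
        return out

    rng = np.random.default_rng(config.seed + 2 if config.noise_seed is None
                                else config.noise_seed)
    truth = draw_truth(config)
    offsets = np.asarray(config.cest_offsets, dtype=float)
    profiles = []
    for rid, model in truth.items():
        for b1 in config.cest_b1:
            curve = cest_mod.simulate_cest(model, offsets, b1, config.t_sat,
                                           config.field_mhz)
            if config.noise > 0:
                curve = curve + rng.normal(0.0, config.noise, size=len(curve))
            profiles.append(CESTProfile(
                residue=rid, offsets=offsets, intensities=curve,
                errors=np.full(len(offsets), config.noise),
                b1_hz=b1, t_sat=config.t_sat,
                field_mhz=config.field_mhz, temperature=config.temperature))
    sidecar = _truth_sidecar(config, truth, {"t_sat": config.t_sat,
                                             "b1_hz": list(config.cest_b1),
                                             "experiment": "cest"})
    _write(out_dir, "cest", profiles, sidecar)
    return profiles, sidecar


def gen_relaxation_dataset(config: ScenarioConfig,
                           out_dir: str | Path | None = None):
    """T1, T2 and hetNOE intensity series for the configured residues."""
    rng = np.random.default_rng(config.seed + 3 if config.noise_seed is None
                                else config.noise_seed)
    truth = draw_truth(config)
    t1 = np.asarray(config.t1_delays)
    t2 = np.asarray(config.t2_delays)
    series = []
    truths = {}
    for rid, model in truth.items():
        r1, r2 = model.r1, model.r2_0
        noe = float(rng.uniform(0.6, 0.85))
        truths[str(rid)] = {"r1": r1, "r2": r2, "hetnoe": noe}
        for kind, delays, rate in (("T1", t1, r1), ("T2", t2, r2)):
            ints = np.exp(-rate * delays)
            if config.noise > 0:
                ints = ints + rng.normal(0.0, config.noise, size=len(delays))
            series.append(RelaxationSeries(
                residue=rid, delays=delays, intensities=ints,
                errors=np.full(len(delays), config.noise), kind=kind))
        for kind, value in (("hetnoe-sat", noe), ("hetnoe-ref", 1.0)):
            v = value + (rng.normal(0.0, config.noise) if config.noise else 0.0)
            series.append(RelaxationSeries(
                residue=rid, delays=np.array([1.0]),
                intensities=np.array([v]),
                errors=np.array([config.noise]), kind=kind))
    sidecar = {"seed": config.seed, "noise": config.noise, "residues": truths}
    _write(out_dir, "relaxation", series, sidecar)
    return series, sidecar


def gen_rdc_dataset(tensor: AlignmentTensor,
                    vectors: dict[ResidueID, np.ndarray],
                    noise_hz: float = 0.0, seed: int = 0,
                    out_path: str | Path | None = None
                    ) -> tuple[list[RDCRecord], dict]:
    """Synthetic N-H RDCs from a known alignment tensor and bond vectors."""
    rng = np.random.default_rng(seed)
    pred = predict_rdc(tensor, vectors)
    records = []
    for rid, d in pred.items():
        dv = d + (rng.normal(0.0, noise_hz) if noise_hz > 0 else 0.0)
        records.append(RDCRecord(residue=rid, d_hz=float(dv),
                                 error_hz=max(noise_hz, 1e-6)))
    truth = {"saupe": tensor.saupe.tolist(), "d_max_hz": tensor.d_max_hz,
             "noise_hz": noise_hz, "seed": seed}
    if out_path is not None:
        write_rdc_table(records, out_path)
        Path(str(out_path) + ".truth.json").write_text(json.dumps(truth, indent=1))
    return records, truth


def toy_backbone(n_residues: int, start: int = 101,
                 with_amide_h: bool = False) -> ConformerEnsemble:
    """Idealized single-model helical backbone (N, CA, C, O per residue).

    Geometry is a regular helix with plausible bond offsets -- sufficient
    for superposition/RMSF/distance tests, not for chemistry.
    """
    atoms, coords = [], []
    rise, turn, radius = 1.5, np.deg2rad(100.0), 2.3
    offsets = {"N": np.array([-0.5, -0.8, -0.4]),
               "CA": np.zeros(3),
               "C": np.array([0.9, 0.6, 0.4]),
               "O": np.array([1.1, 1.6, 0.2])}
    if with_amide_h:
        offsets["H"] = np.array([-1.2, -1.3, -0.6])
    for i in range(n_residues):
        rid = ResidueID("A", start + i, "ALA")
        theta = i * turn
        ca = np.array([radius * np.cos(theta), radius * np.sin(theta), i * rise])
        for name, off in offsets.items():
            atoms.append((rid, name))
            coords.append(ca + off)
    return ConformerEnsemble(atoms, np.asarray(coords)[None, :, :])


def gen_ensemble(base: ConformerEnsemble,
                 sigma_by_residue: dict[int, float] | float = 0.0,
                 n_models: int = 20, seed: int = 0,
                 out_path: str | Path | None = None) -> ConformerEnsemble:
    """Multi-model ensemble: base geometry plus isotropic per-residue jitter.

    ``sigma_by_residue`` maps residue number to an isotropic Gaussian
    displacement sigma in A (scalar = uniform across residues); with
    sigma 0 every model equals the base and all fluctuation metrics vanish.
    """
    rng = np.random.default_rng(seed)
    base_xyz = base.coords[0]
    if np.isscalar(sigma_by_residue):
        sig = np.full(base.n_atoms, float(sigma_by_residue))
    else:
        sig = np.array([float(sigma_by_residue.get(rid.number, 0.0))
                        for rid, _ in base.atoms])
    frames = base_xyz[None, :, :] + rng.normal(
        0.0, 1.0, size=(n_models, base.n_atoms, 3)) * sig[None, :, None]
    ens = ConformerEnsemble(base.atoms, frames)
    if out_path is not None:
        write_ensemble(ens, out_path)
    return ens
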