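"""Two-state Bloch-McConnell simulation and fitting of 15N CEST profiles.

A weak B1 field is stepped across the 15N spectral width; when it touches
the resonance of either exchange state, saturation is transferred to the
observed ground-state signal.  The major dip sits at the ground-state shift
and a minor dip at the excited-state shift, so CEST reads out delta_ES with
its sign -- unlike CPMG -- together with kex and p_ES.

The forward model propagates the 6-component magnetization (x, y, z for
each state) under the homogeneous two-state Bloch-McConnell generator
(offset precession, B1 nutation about x, R1/R2 relaxation, exchange
k_GE = kex p_ES and k_EG = kex (1 - p_ES)) over the saturation time via a
matrix exponential, and reports ground-state z-magnetization normalized to
the no-saturation reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares

from .datamodel import CESTProfile, ResidueID, TwoStateModel, nitrogen_hz_per_ppm

__all__ = [
    "CESTFitResult",
    "simulate_cest",
    "detect_dips",
    "fit_cest",
    "fit_cest_group",
    "DEFAULT_OFFSETS",
    "DEFAULT_B1_FIELDS",
]

# 64 saturation offsets from 134 down to 99 ppm; B1 at 15 and 30 Hz
DEFAULT_OFFSETS = np.linspace(134.0, 99.0, 64)
DEFAULT_B1_FIELDS = (15.0, 30.0)
DEFAULT_T_SAT = 0.4

KEX_BOUNDS = (1.0, 2e4)
PES_BOUNDS = (1e-6, 0.5)


def _bm_generator(offsets_hz: np.ndarray, shift_g_hz: float, shift_e_hz: float,
                  b1_hz: float, r1: float, r2_g: float, r2_e: float,
                  k_ge: float, k_eg: float) -> np.ndarray:
    """Batched 6x6 Bloch-McConnell generators, one per saturation offset."""
    n = len(offsets_hz)
    w1 = 2.0 * np.pi * b1_hz
    om_g = 2.0 * np.pi * (shift_g_hz - offsets_hz)
    om_e = 2.0 * np.pi * (shift_e_hz - offsets_hz)
    K = np.zeros((n, 6, 6))
    for base, om, r2, k_out, k_in in (
            (0, om_g, r2_g, k_ge, k_eg), (3, om_e, r2_e, k_eg, k_ge)):
        other = 3 - base
        K[:, base + 0, base + 0] = -r2 - k_out
        K[:, base + 0, base + 1] = om
        K[:, base + 1, base + 0] = -om
        K[:, base + 1, base + 1] = -r2 - k_out
        K[:, base + 1, base + 2] = w1
        K[:, base + 2, base + 1] = -w1
        K[:, base + 2, base + 2] = -r1 - k_out
        for c in range(3):
            K[:, base + c, other + c] = k_in
    return K


def _propagate_z(K: np.ndarray, t: float, m0: np.ndarray) -> np.ndarray:
    """Ground-state z-magnetization after time t, batched over generators.

    Uses a batched eigendecomposition with a per-offset ``expm`` fallback
    for defective or ill-conditioned generators.
    """
    try:
        w, v = np.linalg.eig(K)
        m0b = np.broadcast_to(m0, (K.shape[0], 6)).astype(complex)
        coef = np.linalg.solve(v, m0b[:, :, None])[:, :, 0]
        mt = np.einsum("nij,nj->ni", v, np.exp(w * t) * coef)
        out = mt[:, 2]
        if np.all(np.isfinite(out)) and np.max(np.abs(out.imag)) < 1e-8:
            return out.real
    except np.linalg.LinAlgError:
        pass
    out = np.empty(K.shape[0])
    for i in range(K.shape[0]):
        out[i] = (expm(K[i] * t) @ m0)[2]
    return out


def simulate_cest(model: TwoStateModel, offsets_ppm=DEFAULT_OFFSETS,
                  b1_hz: float = 30.0, t_sat: float = DEFAULT_T_SAT,
                  field_mhz: float = 800.13) -> np.ndarray:
    """Normalized CEST intensity profile I(offset)/I0 for a two-state model.

    I0 is the reference recorded without the saturation period, so at
    B1 = 0 the profile is flat at exp(-R1 t_sat).
    """
    if not np.all(np.isfinite([model.kex, model.p_es, model.r1, model.r2_0])):
        raise ValueError("non-finite model parameters")
    hz_per_ppm = nitrogen_hz_per_ppm(field_mhz)
    offsets_hz = np.asarray(offsets_ppm, dtype=float) * hz_per_ppm
    r2_e = model.r2_0 if model.r2_es is None else model.r2_es
    K = _bm_generator(
        offsets_hz,
        model.delta_gs_ppm * hz_per_ppm,
        model.delta_es_ppm * hz_per_ppm,
        b1_hz, model.r1, model.r2_0, r2_e,
        model.k_ge, model.k_eg)
    p_g = 1.0 - model.p_es
    m0 = np.array([0.0, 0.0, p_g, 0.0, 0.0, model.p_es])
    return _propagate_z(K, t_sat, m0) / p_g


# ---------------------------------------------------------------------------
# dip detection

def detect_dips(profile: CESTProfile, depth_sigma: float = 3.0) -> list[float]:
    """Candidate state shifts (ppm) from local minima of a CEST profile.

    Minima deeper than ``depth_sigma`` times the baseline scatter (estimated
    robustly from first differences, or taken from the stored errors) are
    refined by parabolic interpolation and returned sorted by depth, deepest
    first.  An empty list is a valid result for flat/noise-only profiles.
    """
    if len(profile.offsets) < 16:
        raise ValueError("need >= 16 offsets for dip detection")
    x = profile.offsets
    y = profile.intensities
    if np.any(profile.errors > 0):
        sigma = float(np.median(profile.errors[profile.errors > 0]))
    else:
        sigma = float(np.median(np.abs(np.diff(y))) / (np.sqrt(2) * 0.6745))
        sigma = max(sigma, 1e-12)
    baseline = float(np.median(y))
    dips: list[tuple[float, float]] = []  # (depth, position)
    for i in range(1, len(y) - 1):
        if y[i] <= y[i - 1] and y[i] <= y[i + 1]:
            depth = baseline - y[i]
            if depth < depth_sigma * sigma:
                continue
            # genuine saturation dips span several offsets; require the
            # deeper flank to dip as well, which rejects one-point noise
            flank_depth = baseline - min(y[i - 1], y[i + 1])
            if flank_depth < 0.5 * depth_sigma * sigma:
                continue
            # parabolic refinement through the three points
            denom = (y[i - 1] - 2 * y[i] + y[i + 1])
            pos = x[i]
            if denom > 0:
                shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
                shift = float(np.clip(shift, -1.0, 1.0))
                pos = x[i] + shift * (x[min(i + 1, len(x) - 1)] - x[i])
            dips.append((depth, float(pos)))
    # merge near-coincident minima (keep the deeper)
    dips.sort(reverse=True)
    step = float(np.median(np.abs(np.diff(x))))
    kept: list[tuple[float, float]] = []
    for depth, pos in dips:
        if all(abs(pos - p) > 1.5 * step for _, p in kept):
            kept.append((depth, pos))
    return [pos for _, pos in kept]


# ---------------------------------------------------------------------------
# fitting

@dataclass
class CESTFitResult:
    residue: ResidueID
    delta_gs_ppm: float
    delta_es_ppm: float
    kex: float
    p_es: float
    r1: float
    r2: float
    errors: dict = field(default_factory=dict)
    chi2: float = 0.0
    chi2_per_residue: dict = field(default_factory=dict)
    dips_ppm: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    @property
    def dw_ppm(self) -> float:
        return self.delta_es_ppm - self.delta_gs_ppm


def _pack_profiles(profiles: list[CESTProfile]):
    res = {p.residue for p in profiles}
    if len(res) != 1:
        raise ValueError("fit_cest expects profiles of a single residue")
    temps = {p.temperature for p in profiles}
    fields = {p.field_mhz for p in profiles}
    if len(temps) > 1 or len(fields) > 1:
        raise ValueError("profiles must share temperature and spectrometer field")
    return res.pop(), profiles[0].field_mhz


def _cest_model_curve(x, profile: CESTProfile, field_mhz: float):
    d_gs, d_es, lnkex, p_es, r1, r2 = x
    model = TwoStateModel(
        kex=float(np.exp(lnkex)), p_es=float(p_es),
        delta_omega_ppm=float(d_es - d_gs), r2_0=float(r2), r1=float(r1),
        delta_gs_ppm=float(d_gs))
    return simulate_cest(model, profile.offsets, profile.b1_hz,
                         profile.t_sat, field_mhz)


def fit_cest(profiles: list[CESTProfile],
             delta_es_init: float | None = None,
             n_starts: int = 4, seed: int = 0) -> CESTFitResult:
    """Joint weighted least-squares CEST fit over one or more B1 fields.

    Initial state shifts come from :func:`detect_dips` (deepest dip = GS,
    second = ES) unless ``delta_es_init`` overrides the ES start.  Profiles
    whose dip search finds only the ground state are still fitted but the
    result is flagged degenerate: kex and p_ES are not separable from a
    single dip.
    """
    residue, field_mhz = _pack_profiles(profiles)
    flags: list[str] = []
    dips: list[float] = []
    for p in sorted(profiles, key=lambda q: -q.b1_hz):
        d = detect_dips(p)
        if len(d) > len(dips):
            dips = d
    if not dips:
        flags.append("no dip detected; fit unconstrained")
        d_gs0 = float(np.median([np.median(p.offsets) for p in profiles]))
    else:
        d_gs0 = dips[0]
    if delta_es_init is not None:
        d_es_starts = [float(delta_es_init)]
    elif len(dips) >= 2:
        # the secondary dip may be a noise artifact: also try its mirror
        # image and generic starts on both sides of the ground state
        d_es_starts = [dips[1], 2 * d_gs0 - dips[1],
                       d_gs0 + 2.0, d_gs0 - 2.0]
    else:
        # the minor dip is buried: try excited-state starts on both sides
        d_es_starts = [d_gs0 + 2.0, d_gs0 - 2.0]
        flags.append("single dip: kex/p_es weakly identifiable")

    lo = min(float(p.offsets.min()) for p in profiles)
    hi = max(float(p.offsets.max()) for p in profiles)
    errs = np.concatenate([np.where(p.errors > 0, p.errors, 1.0) for p in profiles])

    def residuals(x):
        out = []
        for p, e0 in zip(profiles, np.split(errs, np.cumsum(
                [len(p.offsets) for p in profiles]))[:-1]):
            out.append((_cest_model_curve(x, p, field_mhz) - p.intensities) / e0)
        return np.concatenate(out)

    lb = [lo - 2, lo - 10, np.log(KEX_BOUNDS[0]), PES_BOUNDS[0], 0.01, 0.2]
    ub = [hi + 2, hi + 10, np.log(KEX_BOUNDS[1]), PES_BOUNDS[1], 20.0, 200.0]
    rng = np.random.default_rng(seed)
    kex_starts = [300.0, 60.0, 1000.0, 3000.0][:n_starts]
    kex_starts += list(10 ** rng.uniform(1.5, 3.5, max(0, n_starts - 4)))
    best = None
    for kex0 in kex_starts:
        for d_es0 in d_es_starts:
            x0 = np.clip([d_gs0, d_es0, np.log(kex0), 0.03, 1.5, 10.0], lb, ub)
            try:
                sol = least_squares(residuals, x0, bounds=(lb, ub), max_nfev=300)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError(f"{residue}: CEST fit failed for all starts")

    n_pts = sum(len(p.offsets) for p in profiles)
    chi2 = float(2 * best.cost)
    dof = max(n_pts - 6, 1)
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * max(chi2 / dof, 1e-12)
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        perr = np.full(6, np.nan)
    d_gs, d_es, lnkex, p_es, r1, r2 = best.x
    if p_es > 0.98 * PES_BOUNDS[1] or p_es < 2 * PES_BOUNDS[0]:
        flags.append("p_es pinned at bound")
    kex = float(np.exp(lnkex))
    return CESTFitResult(
        residue=residue,
        delta_gs_ppm=float(d_gs), delta_es_ppm=float(d_es),
        kex=kex, p_es=float(p_es), r1=float(r1), r2=float(r2),
        errors={
            "delta_gs_ppm": float(perr[0]), "delta_es_ppm": float(perr[1]),
            "kex": float(kex * perr[2]), "p_es": float(perr[3]),
            "r1": float(perr[4]), "r2": float(perr[5]),
        },
        chi2=chi2, dips_ppm=dips, flags=flags)


def fit_cest_group(profiles_by_residue: list[list[CESTProfile]],
                   n_starts: int = 4, seed: int = 0) -> CESTFitResult:
    """Group CEST fit sharing (kex, p_ES) across residues.

    Each residue keeps its own state shifts and relaxation baselines.  The
    fit starts from per-residue individual fits (median shared kinetics) and
    polishes jointly; per-residue chi-square is reported so that residues
    inconsistent with the shared kinetics are visible rather than silently
    averaged.  A group of one reduces exactly to :func:`fit_cest`.
    """
    if not profiles_by_residue:
        raise ValueError("empty residue group")
    singles = [fit_cest(profs, n_starts=n_starts, seed=seed)
               for profs in profiles_by_residue]
    if len(profiles_by_residue) == 1:
        s = singles[0]
        s.chi2_per_residue = {s.residue: s.chi2}
        return s

    field_mhz = profiles_by_residue[0][0].field_mhz
    lnkex0 = float(np.log(np.median([s.kex for s in singles])))
    pes0 = float(np.median([s.p_es for s in singles]))

    # x = [lnkex, p_es, (d_gs, d_es, r1, r2) per residue]
    x0, lb, ub = [lnkex0, pes0], [np.log(KEX_BOUNDS[0]), PES_BOUNDS[0]], \
        [np.log(KEX_BOUNDS[1]), PES_BOUNDS[1]]
    for s, profs in zip(singles, profiles_by_residue):
        lo = min(float(p.offsets.min()) for p in profs)
        hi = max(float(p.offsets.max()) for p in profs)
        x0 += [s.delta_gs_ppm, s.delta_es_ppm, s.r1, s.r2]
        lb += [lo - 2, lo - 10, 0.01, 0.2]
        ub += [hi + 2, hi + 10, 20.0, 200.0]
    x0 = np.clip(np.array(x0), lb, ub)

    def residuals(x):
        out = []
        for i, profs in enumerate(profiles_by_residue):
            d_gs, d_es, r1, r2 = x[2 + 4 * i: 6 + 4 * i]
            xi = [d_gs, d_es, x[0], x[1], r1, r2]
            for p in profs:
                e = np.where(p.errors > 0, p.errors, 1.0)
                out.append((_cest_model_curve(xi, p, field_mhz) - p.intensities) / e)
        return np.concatenate(out)

    sol = least_squares(residuals, x0, bounds=(lb, ub), max_nfev=500)
    chi2 = float(2 * sol.cost)
    n_pts = sum(len(p.offsets) for profs in profiles_by_residue for p in profs)
    dof = max(n_pts - len(sol.x), 1)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * max(chi2 / dof, 1e-12)
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        perr = np.full(len(sol.x), np.nan)

    kex = float(np.exp(sol.x[0]))
    p_es = float(sol.x[1])
    result = CESTFitResult(
        residue=singles[0].residue,
        delta_gs_ppm=float(sol.x[2]), delta_es_ppm=float(sol.x[3]),
        kex=kex, p_es=p_es, r1=float(sol.x[4]), r2=float(sol.x[5]),
        errors={"kex": float(kex * perr[0]), "p_es": float(perr[1])},
        chi2=chi2,
        dips_ppm=singles[0].dips_ppm,
        flags=[f for s in singles for f in s.flags])
    for i, profs in enumerate(profiles_by_residue):
        d_gs, d_es, r1, r2 = sol.x[2 + 4 * i: 6 + 4 * i]
        xi = [d_gs, d_es, sol.x[0], sol.x[1], r1, r2]
        c = 0.0
        for p in profs:
            e = np.where(p.errors > 0, p.errors, 1.0)
            c += float(np.sum(
                ((_cest_model_curve(xi, p, field_mhz) - p.intensities) / e) ** 2))
        result.chi2_per_residue[profs[0].residue] = c
    return result
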