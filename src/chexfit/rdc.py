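"""Residual dipolar couplings: SVD alignment-tensor fitting and agreement stats.

A measured N-H RDC reports the orientation of the bond vector relative to
the molecular alignment tensor:  D = D_max  b^T S b  with S the traceless
symmetric Saupe order matrix (five independent elements) and b the unit
bond vector.  Fitting measured couplings against a structural model is a
linear least-squares problem solved directly by singular-value
decomposition of the direction-cosine design matrix; agreement is
summarized by R^2 and the Q-factor rms(D_meas - D_pred)/rms(D_meas).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import ConformerEnsemble, RDCRecord, ResidueID

__all__ = [
    "AlignmentTensor",
    "RDCFitResult",
    "D_MAX_NH",
    "extract_nh_vectors",
    "svd_fit_tensor",
    "predict_rdc",
    "correlate_rdc_subsets",
]

# static N-H dipolar interaction constant (r_NH = 1.04 A), Hz; only relative
# agreement statistics depend on this choice
D_MAX_NH = 21700.0


@dataclass
class AlignmentTensor:
    """Saupe order matrix with derived principal-frame quantities."""

    saupe: np.ndarray           # 3x3 traceless symmetric
    d_max_hz: float = D_MAX_NH

    def __post_init__(self) -> None:
        s = np.asarray(self.saupe, dtype=float)
        if not np.allclose(s, s.T, atol=1e-12):
            raise ValueError("Saupe matrix must be symmetric")
        if abs(np.trace(s)) > 1e-10 * max(np.abs(s).max(), 1e-30):
            raise ValueError("Saupe matrix must be traceless")
        self.saupe = s

    def principal_frame(self) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues, eigenvectors) ordered |Sxx| <= |Syy| <= |Szz|."""
        vals, vecs = np.linalg.eigh(self.saupe)
        order = np.argsort(np.abs(vals))        # |Sxx| <= |Syy| <= |Szz|
        return vals[order], vecs[:, order]

    @property
    def axial(self) -> float:
        vals, _ = self.principal_frame()
        return float(vals[2])

    @property
    def rhombicity(self) -> float:
        """R = (2/3) (Syy - Sxx)/Szz, in [0, 2/3]."""
        vals, _ = self.principal_frame()
        szz = vals[2]
        if szz == 0:
            return 0.0
        return float(abs((2.0 / 3.0) * (vals[1] - vals[0]) / szz))

    def euler_angles(self) -> tuple[float, float, float]:
        """z-y-z Euler angles (radians) of the principal axis frame."""
        _, vecs = self.principal_frame()
        r = vecs
        if np.linalg.det(r) < 0:
            r = r * np.array([1.0, 1.0, -1.0])
        beta = float(np.arccos(np.clip(r[2, 2], -1, 1)))
        if abs(np.sin(beta)) > 1e-10:
            alpha = float(np.arctan2(r[1, 2], r[0, 2]))
            gamma = float(np.arctan2(r[2, 1], -r[2, 0]))
        else:
            alpha = float(np.arctan2(r[1, 0], r[0, 0]))
            gamma = 0.0
        return alpha, beta, gamma


@dataclass
class RDCFitResult:
    tensor: AlignmentTensor
    predicted: dict = field(default_factory=dict)    # ResidueID -> Hz
    measured: dict = field(default_factory=dict)
    r_squared: float = np.nan
    q_factor: float = np.nan
    rms_hz: float = np.nan
    skipped: list = field(default_factory=list)


def extract_nh_vectors(ensemble: ConformerEnsemble, model_index: int = 0
                       ) -> dict[ResidueID, np.ndarray]:
    """Unit amide N->H bond vectors per residue from one ensemble model.

    Residues lacking an amide proton (H or HN) are skipped with a warning;
    a coincident N/H pair is an error.
    """
    vectors: dict[ResidueID, np.ndarray] = {}
    skipped = []
    for rid in ensemble.residues():
        try:
            i_n = ensemble.atom_index(rid, "N")
        except KeyError:
            skipped.append(rid)
            continue
        i_h = None
        for name in ("H", "HN"):
            try:
                i_h = ensemble.atom_index(rid, name)
                break
            except KeyError:
                continue
        if i_h is None:
            skipped.append(rid)
            continue
        v = ensemble.coords[model_index, i_h] - ensemble.coords[model_index, i_n]
        norm = np.linalg.norm(v)
        if norm < 1e-6:
            raise ValueError(f"{rid}: zero-length N-H vector")
        vectors[rid] = v / norm
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} residue(s) without amide H: "
            f"{', '.join(str(r) for r in skipped[:8])}", stacklevel=2)
    return vectors


def _design_row(b: np.ndarray) -> np.ndarray:
    x, y, z = b
    return np.array([y * y - x * x, z * z - x * x,
                     2 * x * y, 2 * x * z, 2 * y * z])


def _saupe_from_params(p: np.ndarray) -> np.ndarray:
    syy, szz, sxy, sxz, syz = p
    sxx = -syy - szz
    return np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]])


def predict_rdc(tensor: AlignmentTensor,
                vectors: dict[ResidueID, np.ndarray]) -> dict[ResidueID, float]:
    return {rid: float(tensor.d_max_hz * b @ tensor.saupe @ b)
            for rid, b in vectors.items()}


def svd_fit_tensor(vectors: dict[ResidueID, np.ndarray],
                   rdcs: list[RDCRecord],
                   d_max_hz: float = D_MAX_NH) -> RDCFitResult:
    """Least-squares Saupe tensor from measured RDCs and bond vectors.

    Solves the direction-cosine design system by SVD (minimum-norm
    least squares); requires >= 5 couplings with non-degenerate vector
    geometry (design rank 5).
    """
    by_number = {rid.number: rid for rid in vectors}
    used, skipped = [], []
    for rec in rdcs:
        rid = by_number.get(rec.residue.number)
        if rid is None:
            skipped.append(rec.residue)
            continue
        used.append((rid, vectors[rid], rec.d_hz))
    if skipped:
        warnings.warn(
            f"{len(skipped)} RDC(s) without a matching bond vector", stacklevel=2)
    if len(used) < 5:
        raise ValueError(f"need >= 5 couplings with vectors, got {len(used)}")
    A = np.stack([_design_row(b) for _, b, _ in used]) * d_max_hz
    d = np.array([dv for _, _, dv in used])
    if np.linalg.matrix_rank(A, tol=1e-8 * np.abs(A).max()) < 5:
        raise ValueError("degenerate bond-vector geometry: design rank < 5")
    params, *_ = np.linalg.lstsq(A, d, rcond=None)
    tensor = AlignmentTensor(_saupe_from_params(params), d_max_hz)
    pred = predict_rdc(tensor, {rid: b for rid, b, _ in used})
    meas = {rid: dv for rid, _, dv in used}
    d_pred = np.array([pred[rid] for rid, _, _ in used])
    resid = d - d_pred
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan
    rms_meas = float(np.sqrt(np.mean(d**2)))
    q = float(np.sqrt(np.mean(resid**2)) / rms_meas) if rms_meas > 0 else np.nan
    return RDCFitResult(
        tensor=tensor, predicted=pred, measured=meas,
        r_squared=r2, q_factor=q,
        rms_hz=float(np.sqrt(np.mean(resid**2))),
        skipped=skipped)


def correlate_rdc_subsets(fit: RDCFitResult,
                          subsets: dict[str, set[int]]) -> dict[str, dict]:
    """Per-subset agreement (R^2, Q, n) between measured and predicted RDCs.

    Subsets are named residue-number sets (e.g. ``{"helix-a1": set(range(135,
    146))}``); subsets with fewer than 3 matched couplings are reported as
    undersized rather than given a meaningless R^2.
    """
    out = {}
    for name, numbers in subsets.items():
        rids = [rid for rid in fit.measured if rid.number in numbers]
        if len(rids) < 3:
            out[name] = {"n": len(rids), "undersized": True}
            continue
        d = np.array([fit.measured[r] for r in rids])
        p = np.array([fit.predicted[r] for r in rids])
        resid = d - p
        ss_tot = float(np.sum((d - d.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan
        rms = float(np.sqrt(np.mean(d**2)))
        out[name] = {
            "n": len(rids),
            "undersized": False,
            "r_squared": r2,
            "q_factor": float(np.sqrt(np.mean(resid**2)) / rms) if rms else np.nan,
        }
    return out
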