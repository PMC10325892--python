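"""Coordinate-ensemble analytics: Kabsch superposition, ensemble precision,
per-residue RMSF and atom-pair distance distributions.

Ensemble precision follows the common structure-validation convention:
models are superposed iteratively onto their running mean structure and
the mean per-model RMSD to that mean is reported.  A pairwise-mean
alternative is available since deposition statistics do not always state
which convention was used.  Backbone means {N, CA, C, O}; heavy atoms are
all non-hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ConformerEnsemble, ResidueID

__all__ = [
    "SuperpositionResult",
    "DistanceDistribution",
    "BACKBONE_ATOMS",
    "kabsch_superpose",
    "superpose_ensemble",
    "ensemble_precision",
    "rmsf",
    "distance_series",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O"}


@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # 3x3 proper rotation applied to the mobile set
    translation: np.ndarray    # applied after rotation
    rmsd: float                # A
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class DistanceDistribution:
    pair: tuple                # ((ResidueID, atom), (ResidueID, atom))
    distances: np.ndarray      # per model, A
    bin_edges: np.ndarray
    probabilities: np.ndarray  # sums to 1

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray
                     ) -> SuperpositionResult:
    """Optimal proper rotation/translation of ``mobile`` onto ``reference``.

    Uses the SVD of the coordinate covariance with the determinant
    correction that excludes improper rotations; returns the minimal RMSD.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate arrays must share shape (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("need >= 3 atoms for superposition")
    cm_ref = ref.mean(axis=0)
    cm_mob = mob.mean(axis=0)
    p = mob - cm_mob
    q = ref - cm_ref
    if np.linalg.matrix_rank(q, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) reference geometry")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    fitted = p @ rot.T + cm_ref
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return SuperpositionResult(
        rotation=rot, translation=cm_ref - rot @ cm_mob, rmsd=rmsd, n_atoms=n)


def superpose_ensemble(coords: np.ndarray, tol: float = 1e-6,
                       max_iter: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superpose all models onto their mean structure.

    Returns (superposed coordinates, mean structure).  At least two
    refinement passes are performed; iteration stops when the mean
    structure moves by less than ``tol`` A RMS.
    """
    x = np.array(coords, dtype=float)
    mean = x[0].copy()
    for it in range(max_iter):
        for m in range(x.shape[0]):
            sup = kabsch_superpose(mean, x[m])
            x[m] = sup.apply(x[m])
        new_mean = x.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if it >= 1 and shift < tol:
            break
    return x, mean


def ensemble_precision(ensemble: ConformerEnsemble,
                       residues: set[int] | None = None,
                       atom_names: set[str] | None = None,
                       method: str = "to-mean") -> float:
    """Ensemble precision: mean RMSD of models to the refined mean structure.

    Restrict to a residue range and/or atom-name set (e.g. ``BACKBONE_ATOMS``
    for the backbone statistic; omit ``atom_names`` for all atoms in the
    ensemble, which for heavy-atom-only input gives the heavy-atom
    statistic).  ``method="pairwise"`` reports half the mean pairwise RMSD,
    which coincides with the to-mean value for two-model ensembles.
    """
    sub = ensemble.select(residues, atom_names) \
        if (residues is not None or atom_names is not None) else ensemble
    if sub.n_models < 2:
        raise ValueError("need >= 2 models for a precision estimate")
    sup, mean = superpose_ensemble(sub.coords)
    if method == "to-mean":
        rmsds = np.sqrt(np.mean(np.sum((sup - mean) ** 2, axis=2), axis=1))
        return float(np.mean(rmsds))
    if method == "pairwise":
        vals = []
        for i in range(sub.n_models):
            for j in range(i + 1, sub.n_models):
                vals.append(kabsch_superpose(sup[i], sup[j]).rmsd)
        return float(np.mean(vals) / 2.0)
    raise ValueError(f"unknown method {method!r}")


def rmsf(ensemble: ConformerEnsemble,
         residues: set[int] | None = None,
         atom_names: set[str] | None = None) -> dict[ResidueID, float]:
    """Per-residue root-mean-square fluctuation about the mean structure (A).

    Models are superposed onto their iteratively refined mean first, so
    rigid-body motion of the whole ensemble does not register as
    fluctuation.  Defaults to CA atoms.
    """
    atom_names = atom_names if atom_names is not None else {"CA"}
    sub = ensemble.select(residues, atom_names)
    if sub.n_models < 2:
        raise ValueError("need >= 2 models for RMSF")
    sup, mean = superpose_ensemble(sub.coords)
    msd = np.mean(np.sum((sup - mean) ** 2, axis=2), axis=0)  # per atom
    out: dict[ResidueID, list[float]] = {}
    for (rid, _), v in zip(sub.atoms, msd):
        out.setdefault(rid, []).append(float(v))
    return {rid: float(np.sqrt(np.mean(vals))) for rid, vals in out.items()}


def distance_series(ensemble: ConformerEnsemble,
                    pairs: list[tuple[ResidueID, str, ResidueID, str]],
                    bins: np.ndarray | int = 50) -> list[DistanceDistribution]:
    """Per-model atom-pair distances with normalized histograms.

    Each requested pair must exist in every model; a missing atom raises an
    error naming it.
    """
    out = []
    for rid_a, atom_a, rid_b, atom_b in pairs:
        ia = ensemble.atom_index(rid_a, atom_a)
        ib = ensemble.atom_index(rid_b, atom_b)
        d = np.linalg.norm(ensemble.coords[:, ia, :] - ensemble.coords[:, ib, :],
                           axis=1)
        counts, edges = np.histogram(d, bins=bins)
        probs = counts / counts.sum() if counts.sum() else counts.astype(float)
        out.append(DistanceDistribution(
            pair=((rid_a, atom_a), (rid_b, atom_b)),
            distances=d, bin_edges=edges, probabilities=probs))
    return out
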