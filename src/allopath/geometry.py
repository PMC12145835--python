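"""Geometric descriptors of conformational ensembles.

Dihedral angles, residue-pair distance series, Kabsch superposition,
RMSD/RMSF profiles, neighbor-counting (GROMOS-style) conformational
clustering and Cartesian principal component analysis.  Angles are degrees
in ``[-180, 180)`` externally; coordinates Angstrom throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InputError, SelectionError
from .structure_io import ResidueKey, StructureModel, Trajectory

__all__ = [
    "wrap_angle",
    "dihedral",
    "dihedral_series",
    "distance_series",
    "superpose",
    "rmsd",
    "rmsd_series",
    "rmsf",
    "cluster_conformations",
    "pca_ca",
    "DistanceSeries",
    "FluctuationProfile",
    "ClusterResult",
    "PCAResult",
]

_COLLINEAR_TOL = 1e-8


def wrap_angle(deg):
    """Wrap angle(s) in degrees to ``[-180, 180)``; +180 maps to -180."""
    return (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees, IUPAC convention) of four points.

    Raises :class:`GeometryError` for collinear triples, for which the
    dihedral is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise GeometryError("dihedral undefined: three consecutive points collinear")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def dihedral_series(traj: Trajectory, atom_indices) -> np.ndarray:
    """Per-frame dihedral (degrees) over four atom indices, vectorized."""
    i, j, k, l = atom_indices
    p = traj.coords
    b1 = p[:, j] - p[:, i]
    b2 = p[:, k] - p[:, j]
    b3 = p[:, l] - p[:, k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norms1 = np.linalg.norm(n1, axis=1)
    norms2 = np.linalg.norm(n2, axis=1)
    if np.any(norms1 < _COLLINEAR_TOL) or np.any(norms2 < _COLLINEAR_TOL):
        bad = int(np.argmax((norms1 < _COLLINEAR_TOL) | (norms2 < _COLLINEAR_TOL)))
        raise GeometryError(f"dihedral undefined at frame {bad}: collinear points")
    b2u = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2u)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

DISTANCE_MODES = ("min_sidechain_heavy", "ca", "min_heavy")


@dataclass
class DistanceSeries:
    pair: tuple[ResidueKey, ResidueKey]
    mode: str
    values: np.ndarray  # Angstrom, one per frame


def _mode_atoms(model: StructureModel, key: ResidueKey, mode: str) -> np.ndarray:
    idx = model.residue_atoms(key)
    if mode == "ca":
        return np.asarray([model.ca_index(key)])
    heavy = model.heavy_atom_mask()[idx]
    if mode == "min_heavy":
        sel = idx[heavy]
    else:  # min_sidechain_heavy: CB and outward
        backbone = np.isin(model.atom_names[idx], ("N", "CA", "C", "O", "OXT"))
        sel = idx[heavy & ~backbone]
    if len(sel) == 0:
        raise SelectionError(
            f"residue {key} ({model.residue_name(key)}) has no atoms under mode "
            f"{mode!r}; consider mode='ca'"
        )
    return sel


def distance_series(
    traj: Trajectory,
    pair: tuple[ResidueKey, ResidueKey],
    mode: str = "min_sidechain_heavy",
) -> DistanceSeries:
    """Per-frame residue-pair distance (minimum over mode-selected atoms)."""
    if mode not in DISTANCE_MODES:
        raise InputError(f"unknown distance mode {mode!r}")
    a = _mode_atoms(traj.model, pair[0], mode)
    b = _mode_atoms(traj.model, pair[1], mode)
    diff = traj.coords[:, a, None, :] - traj.coords[:, None, b, :]
    d = np.sqrt(np.einsum("fijk,fijk->fij", diff, diff))
    return DistanceSeries(pair=pair, mode=mode, values=d.min(axis=(1, 2)))


# ---------------------------------------------------------------------------
# Superposition / RMSD / RMSF
# ---------------------------------------------------------------------------


@dataclass
class Transform:
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> Transform:
    """Least-squares rotation+translation mapping mobile onto reference."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return Transform(rotation=rot, translation=rc - rot @ mc)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting) between equal-shape coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError("coordinate sets differ in shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit: np.ndarray | None = None,
) -> tuple[Transform, np.ndarray, float]:
    """Optimal rigid superposition (Kabsch) of ``mobile`` onto ``reference``.

    ``fit`` selects the atoms used to determine the transform; all mobile
    atoms are transformed.  Returns ``(transform, fitted_coords, rmsd)``
    where the RMSD is measured over the fit selection after the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    fit_idx = np.arange(len(mobile)) if fit is None else np.asarray(fit, dtype=int)
    if len(fit_idx) < 3:
        raise GeometryError("superposition needs >= 3 fit atoms")
    ref_fit = reference[fit_idx]
    centered = ref_fit - ref_fit.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError("fit atoms are (near-)collinear; superposition degenerate")
    t = _kabsch(mobile[fit_idx], ref_fit)
    fitted = t.apply(mobile)
    return t, fitted, rmsd(fitted[fit_idx], ref_fit)


def rmsd_series(
    traj: Trajectory,
    reference: StructureModel | np.ndarray,
    fit: np.ndarray,
    measure: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD: each frame is superposed on ``fit``, measured on
    ``measure`` (defaults to the fit selection)."""
    ref = reference.coords if isinstance(reference, StructureModel) else np.asarray(reference)
    fit = np.asarray(fit, dtype=int)
    measure = fit if measure is None else np.asarray(measure, dtype=int)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, fitted, _ = superpose(traj.coords[f], ref, fit)
        out[f] = rmsd(fitted[measure], ref[measure])
    return out


@dataclass
class FluctuationProfile:
    """Per-entity RMSF after ensemble superposition."""

    entity_keys: list  # atom indices or residue keys
    values: np.ndarray  # Angstrom
    per: str  # "atom" | "residue"


def _aligned_coords(traj: Trajectory, reference: np.ndarray, fit: np.ndarray):
    """Two-pass alignment: to the reference, then to the ensemble mean."""
    pass1 = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        _, pass1[f], _ = superpose(traj.coords[f], reference, fit)
    mean = pass1.mean(axis=0)
    pass2 = np.empty_like(pass1)
    for f in range(traj.n_frames):
        _, pass2[f], _ = superpose(pass1[f], mean, fit)
    return pass2


def rmsf(
    traj: Trajectory,
    fit: np.ndarray,
    per: str = "residue",
    measure: np.ndarray | None = None,
) -> FluctuationProfile:
    """Root-mean-square fluctuation about the mean structure.

    Frames are aligned to the reference on ``fit``, then re-aligned to the
    resulting mean structure; RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|^2).
    Residue mode averages the atomic RMSF over each residue's measured atoms.
    """
    if traj.n_frames < 2:
        raise InputError("RMSF undefined for fewer than 2 frames")
    if per not in ("atom", "residue"):
        raise InputError(f"per must be 'atom' or 'residue', got {per!r}")
    fit = np.asarray(fit, dtype=int)
    measure = (
        np.arange(traj.model.n_atoms) if measure is None else np.asarray(measure, int)
    )
    aligned = _aligned_coords(traj, traj.model.coords, fit)
    mean = aligned.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    if per == "atom":
        return FluctuationProfile(
            entity_keys=list(measure), values=per_atom[measure], per="atom"
        )
    keys: list[ResidueKey] = []
    vals: list[float] = []
    mset = set(int(i) for i in measure)
    for key in traj.model.residue_keys:
        idx = [i for i in traj.model.residue_atoms(key) if int(i) in mset]
        if idx:
            keys.append(key)
            vals.append(float(per_atom[idx].mean()))
    return FluctuationProfile(entity_keys=keys, values=np.asarray(vals), per="residue")


# ---------------------------------------------------------------------------
# Conformational clustering (neighbor counting at an RMSD cutoff)
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    cutoff: float
    clusters: list[list[int]]  # frame indices, ordered by descending size
    representatives: list[int]  # centroid frame of each cluster

    @property
    def assignments(self) -> dict[int, int]:
        """frame index -> cluster rank (0 = largest)."""
        out: dict[int, int] = {}
        for rank, members in enumerate(self.clusters):
            for f in members:
                out[f] = rank
        return out


def pairwise_rmsd_matrix(traj: Trajectory, selection: np.ndarray) -> np.ndarray:
    """All-vs-all fitted RMSD over a selection (per-pair optimal fit)."""
    sel = np.asarray(selection, dtype=int)
    n = traj.n_frames
    sub = traj.coords[:, sel]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, fitted, r = superpose(sub[j], sub[i])
            mat[i, j] = mat[j, i] = r
    return mat


def cluster_conformations(
    traj: Trajectory, selection: np.ndarray, cutoff: float
) -> ClusterResult:
    """Neighbor-counting clustering: repeatedly take the unassigned frame
    with the most unassigned neighbors within ``cutoff`` (fitted RMSD) as a
    centroid, assign it and its neighbors to a cluster, and recurse.

    Ties break to the lowest frame index; the output is sorted by
    descending cluster size (ties: lowest member frame index).
    """
    if cutoff <= 0:
        raise InputError("RMSD cutoff must be positive")
    mat = pairwise_rmsd_matrix(traj, selection)
    n = traj.n_frames
    adj = mat <= cutoff
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    raw: list[tuple[int, list[int]]] = []
    while alive.any():
        counts = np.where(alive, (adj & alive[None, :]).sum(axis=1), -1)
        center = int(np.argmax(counts))  # argmax returns lowest index on ties
        members = [center] + [int(j) for j in np.flatnonzero(adj[center] & alive)]
        raw.append((center, sorted(members)))
        alive[members] = False
    raw.sort(key=lambda cm: (-len(cm[1]), cm[1][0]))
    return ClusterResult(
        cutoff=float(cutoff),
        clusters=[m for _, m in raw],
        representatives=[c for c, _ in raw],
    )


# ---------------------------------------------------------------------------
# Principal component analysis on selected coordinates
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending, A^2
    variance_fractions: np.ndarray
    eigenvectors: np.ndarray  # (3n_sel, n_components), columns
    projections: np.ndarray  # (n_frames, n_components)
    mean: np.ndarray = field(repr=False)  # (3n_sel,)
    extremes: np.ndarray = field(repr=False)  # (n_extreme, n_sel, 3)
    selection: np.ndarray = field(repr=False)


def pca_ca(
    traj: Trajectory,
    reference: StructureModel | np.ndarray,
    selection: np.ndarray,
    n_extreme_frames: int = 30,
    component: int = 0,
) -> PCAResult:
    """PCA of the selected (typically C-alpha) coordinates.

    Frames are superposed to the reference on the selection, the 3N
    covariance is diagonalized, and the extreme-conformation set linearly
    interpolates between the minimum- and maximum-projection conformations
    along ``component`` in ``n_extreme_frames`` steps.
    """
    if traj.n_frames < 2:
        raise InputError("PCA needs >= 2 frames")
    sel = np.asarray(selection, dtype=int)
    if len(sel) == 0:
        raise SelectionError("PCA selection is empty")
    ref = reference.coords if isinstance(reference, StructureModel) else np.asarray(reference)
    n = traj.n_frames
    flat = np.empty((n, 3 * len(sel)))
    for f in range(n):
        _, fitted, _ = superpose(traj.coords[f], ref, sel)
        flat[f] = fitted[sel].ravel()
    mean = flat.mean(axis=0)
    centered = flat - mean
    if n - 1 < 3 * len(sel):
        warnings.warn(
            f"only {n} frames for {3 * len(sel)} coordinates: spectrum is "
            f"rank-limited to {n - 1}",
            stacklevel=2,
        )
    cov = centered.T @ centered / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    proj = centered @ evecs
    p = proj[:, component]
    lo, hi = float(p.min()), float(p.max())
    steps = np.linspace(lo, hi, n_extreme_frames)
    extremes = (mean[None, :] + steps[:, None] * evecs[:, component][None, :]).reshape(
        n_extreme_frames, len(sel), 3
    )
    return PCAResult(
        eigenvalues=evals,
        variance_fractions=fractions,
        eigenvectors=evecs,
        projections=proj,
        mean=mean,
        extremes=extremes,
        selection=sel,
    )
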