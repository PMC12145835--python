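"""Interface contact detection, snapshot contact frequencies and pairwise
nonbonded interaction energies.

A contact is decided at residue-pair granularity.  The default criterion is
an untyped heavy-atom distance cutoff (4.5 A); a typed mode approximating
interaction-type criteria (van der Waals overlap, polar-pair, salt-bridge
distances on heavy atoms, no hydrogen placement needed) is available via
``ContactCriterion(mode="typed")``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InputError, ParameterError
from .structure_io import ResidueKey, StructureModel, Trajectory

#: Coulomb constant, kJ mol^-1 nm e^-2
COULOMB_CONSTANT = 138.935458

_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
_VDW_DEFAULT = 1.70
_VDW_PAD = 0.5  # A added to the radius sum in typed vdw criterion

_POLAR_ELEMENTS = ("N", "O", "S")
_POLAR_CUTOFF = 3.5  # A, heavy donor-acceptor proxy
_SALT_CUTOFF = 4.0  # A

_CATIONIC = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
             ("HIS", "ND1"), ("HIS", "NE2"), ("HSP", "ND1"), ("HSP", "NE2")}
_ANIONIC = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


@dataclass(frozen=True)
class ContactCriterion:
    """How a residue-residue contact is decided on one frame."""

    mode: str = "heavy"  # "heavy" (untyped distance) | "typed"
    cutoff: float = 4.5  # A; used by the untyped mode

    def __post_init__(self) -> None:
        if self.mode not in ("heavy", "typed"):
            raise InputError(f"unknown contact mode {self.mode!r}")
        if self.cutoff <= 0:
            raise InputError("contact cutoff must be positive")


@dataclass
class ContactRow:
    residue_a: ResidueKey
    label_a: str
    residue_b: ResidueKey
    label_b: str
    frequency: float  # percent of frames
    n_present: int
    n_total: int


@dataclass
class ContactFrequencyTable:
    rows: list[ContactRow]
    n_frames: int
    n_residues_a: int = field(init=False)
    n_residues_b: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_residues_a = len({r.residue_a for r in self.rows})
        self.n_residues_b = len({r.residue_b for r in self.rows})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chain_a": r.residue_a[0],
                    "resid_a": r.residue_a[1],
                    "label_a": r.label_a,
                    "chain_b": r.residue_b[0],
                    "resid_b": r.residue_b[1],
                    "label_b": r.label_b,
                    "frequency": r.frequency,
                    "n_present": r.n_present,
                    "n_total": r.n_total,
                }
                for r in self.rows
            ]
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def _group_atom_indices(
    model: StructureModel, residues: list[ResidueKey]
) -> tuple[np.ndarray, np.ndarray]:
    """Heavy-atom indices of a residue group + parallel residue ordinals."""
    heavy = model.heavy_atom_mask()
    idx: list[int] = []
    owner: list[int] = []
    for ordno, key in enumerate(residues):
        for i in model.residue_atoms(key):
            if heavy[i]:
                idx.append(int(i))
                owner.append(ordno)
    return np.asarray(idx, dtype=int), np.asarray(owner, dtype=int)


def _typed_pair_ok(model: StructureModel, i: int, j: int, d: float) -> bool:
    """Typed heavy-atom criterion: vdW overlap, polar pair or salt bridge."""
    ei = str(model.elements[i]).upper()
    ej = str(model.elements[j]).upper()
    ri = _VDW_RADII.get(ei, _VDW_DEFAULT)
    rj = _VDW_RADII.get(ej, _VDW_DEFAULT)
    if d <= ri + rj + _VDW_PAD:
        return True
    if ei in _POLAR_ELEMENTS and ej in _POLAR_ELEMENTS and d <= _POLAR_CUTOFF:
        return True
    ai = (str(model.res_names[i]), str(model.atom_names[i]))
    aj = (str(model.res_names[j]), str(model.atom_names[j]))
    if d <= _SALT_CUTOFF and (
        (ai in _CATIONIC and aj in _ANIONIC) or (ai in _ANIONIC and aj in _CATIONIC)
    ):
        return True
    return False


def detect_contacts(
    model: StructureModel,
    coords: np.ndarray,
    group_a: list[ResidueKey],
    group_b: list[ResidueKey],
    criterion: ContactCriterion = ContactCriterion(),
) -> set[tuple[ResidueKey, ResidueKey]]:
    """Residue pairs ``(a in A, b in B)`` in contact on one frame.

    A pair is a contact iff the minimum heavy-atom distance satisfies the
    criterion.  The two groups must be disjoint.
    """
    if set(group_a) & set(group_b):
        raise InputError("contact groups overlap")
    idx_a, own_a = _group_atom_indices(model, group_a)
    idx_b, own_b = _group_atom_indices(model, group_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        return set()
    # typed mode needs the widest possible distance to test (salt 4.0,
    # polar 3.5, vdw <= 1.8+1.8+0.5 = 4.1)
    search = criterion.cutoff if criterion.mode == "heavy" else max(
        _SALT_CUTOFF, _POLAR_CUTOFF, 2 * _VDW_RADII["S"] + _VDW_PAD
    )
    tree_b = cKDTree(coords[idx_b])
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    hits = tree_b.query_ball_point(coords[idx_a], r=search)
    for ia, neighbor_list in enumerate(hits):
        for ib in neighbor_list:
            pair = (group_a[own_a[ia]], group_b[own_b[ib]])
            if pair in pairs:
                continue
            if criterion.mode == "heavy":
                pairs.add(pair)
            else:
                d = float(np.linalg.norm(coords[idx_a[ia]] - coords[idx_b[ib]]))
                if _typed_pair_ok(model, int(idx_a[ia]), int(idx_b[ib]), d):
                    pairs.add(pair)
    return pairs


def contact_frequency(
    traj: Trajectory,
    group_a: list[ResidueKey],
    group_b: list[ResidueKey],
    criterion: ContactCriterion = ContactCriterion(),
) -> ContactFrequencyTable:
    """Percentage of frames in which each cross-group residue pair is in
    contact.  One row per pair ever observed; frequency = 100 * n/N exactly."""
    if traj.n_frames < 1:
        raise InputError("contact frequency needs >= 1 frame")
    counts: dict[tuple[ResidueKey, ResidueKey], int] = {}
    for f in range(traj.n_frames):
        for pair in detect_contacts(traj.model, traj.coords[f], group_a, group_b, criterion):
            counts[pair] = counts.get(pair, 0) + 1
    model = traj.model
    rows = [
        ContactRow(
            residue_a=a,
            label_a=model.label_of(a) or "",
            residue_b=b,
            label_b=model.label_of(b) or "",
            frequency=100.0 * n / traj.n_frames,
            n_present=n,
            n_total=traj.n_frames,
        )
        for (a, b), n in sorted(counts.items())
    ]
    return ContactFrequencyTable(rows=rows, n_frames=traj.n_frames)


def filter_frequency(
    table: ContactFrequencyTable, cutoff_percent: float
) -> ContactFrequencyTable:
    """Rows with frequency >= cutoff (inclusive)."""
    if not 0 <= cutoff_percent <= 100:
        raise InputError("frequency cutoff must be in [0, 100]")
    kept = [r for r in table.rows if r.frequency >= cutoff_percent]
    return ContactFrequencyTable(rows=kept, n_frames=table.n_frames)


# ---------------------------------------------------------------------------
# Nonbonded pairwise interaction energies
# ---------------------------------------------------------------------------


@dataclass
class NonbondedParams:
    """Per-atom charge (e), LJ sigma (nm) and epsilon (kJ/mol).

    Keys are ``(chain_id, res_id, icode, atom_name)``; :meth:`resolve` maps
    them onto a model's atom indices and reports any uncovered atoms.
    """

    table: dict[tuple[str, int, str, str], tuple[float, float, float]]
    cutoff_nm: float = 1.2

    def __post_init__(self) -> None:
        for key, (q, sigma, eps) in self.table.items():
            if eps < 0:
                raise ParameterError(f"negative epsilon for {key}")
            if eps > 0 and sigma <= 0:
                raise ParameterError(f"non-positive sigma with epsilon > 0 for {key}")

    @classmethod
    def from_csv(cls, path: str | os.PathLike, cutoff_nm: float = 1.2):
        df = pd.read_csv(path, dtype={"chain": str, "icode": str})
        need = {"chain", "resid", "atom", "charge", "sigma", "epsilon"}
        missing = need - set(df.columns)
        if missing:
            raise ParameterError(f"parameter CSV missing columns: {sorted(missing)}")
        table = {}
        for r in df.itertuples():
            icode = "" if "icode" not in df.columns or pd.isna(getattr(r, "icode", "")) else str(r.icode)
            table[(str(r.chain), int(r.resid), icode, str(r.atom))] = (
                float(r.charge),
                float(r.sigma),
                float(r.epsilon),
            )
        return cls(table=table, cutoff_nm=cutoff_nm)

    def resolve(self, model: StructureModel, atom_indices: np.ndarray):
        q = np.empty(len(atom_indices))
        sigma = np.empty(len(atom_indices))
        eps = np.empty(len(atom_indices))
        missing = []
        for n, i in enumerate(atom_indices):
            key = (
                str(model.chain_ids[i]),
                int(model.res_ids[i]),
                str(model.icodes[i]),
                str(model.atom_names[i]),
            )
            try:
                q[n], sigma[n], eps[n] = self.table[key]
            except KeyError:
                missing.append(key)
        if missing:
            raise ParameterError(
                f"nonbonded parameters missing for {len(missing)} atoms, "
                f"e.g. {missing[:5]}"
            )
        return q, sigma, eps


@dataclass
class EnergyResult:
    coulomb: np.ndarray  # kJ/mol per frame
    lj: np.ndarray  # kJ/mol per frame
    total: np.ndarray  # kJ/mol per frame
    mean: float
    sd: float


def interaction_energy(
    traj: Trajectory,
    group_a: list[ResidueKey],
    group_b: list[ResidueKey],
    params: NonbondedParams,
) -> EnergyResult:
    """Cross-group Coulomb + Lennard-Jones energy per frame.

    Plain truncation at ``params.cutoff_nm`` (no switching, no mesh term),
    Lorentz-Berthelot combining: sigma arithmetic mean, epsilon geometric
    mean.  Symmetric in group order and additive over disjoint partitions
    of either group.
    """
    model = traj.model
    idx_a = np.concatenate([model.residue_atoms(k) for k in group_a])
    idx_b = np.concatenate([model.residue_atoms(k) for k in group_b])
    if np.intersect1d(idx_a, idx_b).size:
        raise InputError("energy groups overlap")
    qa, sa, ea = params.resolve(model, idx_a)
    qb, sb, eb = params.resolve(model, idx_b)
    cutoff_a = params.cutoff_nm * 10.0
    n_frames = traj.n_frames
    coul = np.zeros(n_frames)
    lj = np.zeros(n_frames)
    for f in range(n_frames):
        xa = traj.coords[f, idx_a]
        xb = traj.coords[f, idx_b]
        tree = cKDTree(xb)
        hits = tree.query_ball_point(xa, r=cutoff_a)
        for i, neighbors in enumerate(hits):
            if not neighbors:
                continue
            j = np.asarray(neighbors, dtype=int)
            r_nm = np.linalg.norm(xb[j] - xa[i], axis=1) / 10.0
            coul[f] += COULOMB_CONSTANT * qa[i] * np.sum(qb[j] / r_nm)
            eps_ij = np.sqrt(ea[i] * eb[j])
            live = eps_ij > 0
            if np.any(live):
                sig_ij = 0.5 * (sa[i] + sb[j][live])
                sr6 = (sig_ij / r_nm[live]) ** 6
                lj[f] += np.sum(4.0 * eps_ij[live] * (sr6**2 - sr6))
    total = coul + lj
    return EnergyResult(
        coulomb=coul,
        lj=lj,
        total=total,
        mean=float(total.mean()),
        sd=float(total.std(ddof=1)) if n_frames > 1 else 0.0,
    )
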