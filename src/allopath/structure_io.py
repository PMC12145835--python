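"""Structure/ensemble data model, PDB readers and writers, residue selection.

The in-memory model is deliberately small: flat numpy arrays of per-atom
annotations plus an ``(n_atoms, 3)`` coordinate block, and a trajectory is a
reference model plus an ``(n_frames, n_atoms, 3)`` coordinate stack.  All
coordinates are in Angstrom.  Residue identity is the triple
``(chain_id, res_id, insertion_code)``; generic residue labels (e.g. GPCRdb
``"3.50"`` or CGN ``"G.H5.13"``) are aliases attached via
:func:`apply_labels`, never primary keys.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InputError,
    LabelError,
    SelectionError,
    TopologyError,
)

#: residue identity: (chain_id, res_id, insertion_code)
ResidueKey = tuple[str, int, str]

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})
_BACKBONE_EXTRA = frozenset({"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA"})


@dataclass
class StructureModel:
    """A single conformation: per-atom annotations + coordinates (Angstrom)."""

    atom_names: np.ndarray
    elements: np.ndarray
    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    icodes: np.ndarray
    coords: np.ndarray
    labels: dict[ResidueKey, str] = field(default_factory=dict)
    _label_index: dict[str, ResidueKey] = field(default_factory=dict, repr=False)
    _residue_atoms: dict[ResidueKey, np.ndarray] | None = field(
        default=None, repr=False
    )
    _residue_order: list[ResidueKey] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError("coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("non-finite coordinates in structure")

    # -- residue bookkeeping -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def _build_residue_index(self) -> None:
        order: list[ResidueKey] = []
        atoms: dict[ResidueKey, list[int]] = {}
        for i in range(self.n_atoms):
            key = (str(self.chain_ids[i]), int(self.res_ids[i]), str(self.icodes[i]))
            if key not in atoms:
                atoms[key] = []
                order.append(key)
            atoms[key].append(i)
        self._residue_order = order
        self._residue_atoms = {k: np.asarray(v, dtype=int) for k, v in atoms.items()}

    @property
    def residue_keys(self) -> list[ResidueKey]:
        """Residue keys in file order (stable across reads of the same file)."""
        if self._residue_order is None:
            self._build_residue_index()
        return list(self._residue_order)

    def residue_atoms(self, key: ResidueKey) -> np.ndarray:
        """Atom indices of one residue (file order)."""
        if self._residue_atoms is None:
            self._build_residue_index()
        try:
            return self._residue_atoms[key]
        except KeyError:
            raise SelectionError(f"residue {key} not in model") from None

    def residue_name(self, key: ResidueKey) -> str:
        return str(self.res_names[self.residue_atoms(key)[0]])

    def heavy_atom_mask(self) -> np.ndarray:
        return ~np.isin(np.char.upper(self.elements.astype(str)), ("H", "D"))

    def ca_index(self, key: ResidueKey) -> int:
        idx = self.residue_atoms(key)
        hits = idx[self.atom_names[idx] == "CA"]
        if len(hits) == 0:
            raise SelectionError(f"residue {key} has no CA atom")
        return int(hits[0])

    def find_atom(self, key: ResidueKey, name: str) -> int | None:
        idx = self.residue_atoms(key)
        hits = idx[self.atom_names[idx] == name]
        return int(hits[0]) if len(hits) else None

    # -- generic labels ------------------------------------------------------

    def label_of(self, key: ResidueKey) -> str | None:
        return self.labels.get(key)

    def residue_by_label(self, label: str) -> ResidueKey:
        try:
            return self._label_index[label]
        except KeyError:
            raise LabelError(f"no residue carries label {label!r}") from None

    def copy(self) -> "StructureModel":
        return StructureModel(
            atom_names=self.atom_names.copy(),
            elements=self.elements.copy(),
            chain_ids=self.chain_ids.copy(),
            res_ids=self.res_ids.copy(),
            res_names=self.res_names.copy(),
            icodes=self.icodes.copy(),
            coords=self.coords.copy(),
            labels=dict(self.labels),
            _label_index=dict(self._label_index),
        )


@dataclass
class Trajectory:
    """A conformational ensemble over a fixed topology."""

    model: StructureModel
    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    dt_ps: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError("trajectory coordinates must be (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.model.n_atoms:
            raise TopologyError(
                f"trajectory has {self.coords.shape[1]} atoms per frame, "
                f"topology has {self.model.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise InputError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _from_atom_array(arr) -> StructureModel:
    return StructureModel(
        atom_names=np.asarray(arr.atom_name, dtype="U6"),
        elements=np.asarray(arr.element, dtype="U2"),
        chain_ids=np.asarray(arr.chain_id, dtype="U4"),
        res_ids=np.asarray(arr.res_id, dtype=int),
        res_names=np.asarray(arr.res_name, dtype="U5"),
        icodes=np.asarray(arr.ins_code, dtype="U1"),
        coords=np.asarray(arr.coord, dtype=float),
    )


def _to_atom_array(model: StructureModel, coords: np.ndarray):
    import biotite.structure as struc

    n = model.n_atoms
    arr = struc.AtomArray(n)
    arr.atom_name = model.atom_names.astype("U6")
    arr.element = model.elements.astype("U2")
    arr.chain_id = model.chain_ids.astype("U4")
    arr.res_id = model.res_ids.astype(int)
    arr.res_name = model.res_names.astype("U5")
    arr.ins_code = model.icodes.astype("U1")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.coord = np.asarray(coords, dtype=np.float32)
    return arr


def read_structure(path: str | os.PathLike, format: str = "pdb") -> StructureModel:
    """Read a single-conformation structure.

    Altloc records are resolved to the highest-occupancy alternative (ties:
    first listed).  For multi-model files the first model is returned.
    """
    if format != "pdb":
        raise InputError(f"unsupported structure format {format!r}")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    if os.path.getsize(path) == 0:
        raise InputError(f"empty structure file: {path}")
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(path)
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except InputError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise InputError(f"no atoms in structure file: {path}")
    return _from_atom_array(arr)


def write_structure(
    model: StructureModel, path: str | os.PathLike, coords: np.ndarray | None = None
) -> None:
    """Write a model (optionally with replacement coordinates) as PDB."""
    from biotite.structure.io.pdb import PDBFile

    arr = _to_atom_array(model, model.coords if coords is None else coords)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(os.fspath(path))


def read_trajectory(
    path: str | os.PathLike,
    topology: StructureModel,
    format: str | None = None,
    dt_ps: float | None = None,
) -> Trajectory:
    """Read a conformational ensemble against a topology.

    Multi-model PDB is read natively; ``dcd``/``xtc``/``trr`` are handed to
    MDAnalysis when it is importable.  Frame atom counts must match the
    topology exactly.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").lower() or "pdb"
    if format == "pdb":
        from biotite.structure.io.pdb import PDBFile

        try:
            pdb = PDBFile.read(path)
            stack = pdb.get_structure(model=None, altloc="occupancy")
        except Exception as exc:
            raise FormatError(f"cannot parse multi-model PDB {path}: {exc}") from exc
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
    elif format in ("dcd", "xtc", "trr"):
        coords = _read_binary_trajectory(path, topology, format)
    else:
        raise InputError(f"unsupported trajectory format {format!r}")
    if coords.shape[1] != topology.n_atoms:
        raise TopologyError(
            f"trajectory frames have {coords.shape[1]} atoms, "
            f"topology has {topology.n_atoms}"
        )
    return Trajectory(model=topology, coords=coords, dt_ps=dt_ps)


def _read_binary_trajectory(path: str, topology: StructureModel, format: str):
    import tempfile

    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - env dependent
        raise InputError(
            f"reading {format} trajectories requires MDAnalysis"
        ) from exc
    with tempfile.NamedTemporaryFile(suffix=".pdb", delete=False) as tmp:
        tmp_path = tmp.name
    try:
        write_structure(topology, tmp_path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(tmp_path, path)
            frames = [u.atoms.positions.astype(float).copy() for _ in u.trajectory]
    finally:
        os.unlink(tmp_path)
    return np.stack(frames)


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write an ensemble as a multi-model PDB."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arrays = [_to_atom_array(traj.model, traj.coords[i]) for i in range(traj.n_frames)]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(os.fspath(path))


# ---------------------------------------------------------------------------
# Residue labels
# ---------------------------------------------------------------------------


@dataclass
class ResidueLabelMap:
    """Rows of ``(chain_id, res_id, label)``; keys unique, labels nonempty."""

    rows: list[tuple[str, int, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for chain, resid, label in self.rows:
            if not label:
                raise LabelError(f"empty label for residue ({chain}, {resid})")
            if (chain, resid) in seen:
                raise LabelError(f"duplicate key ({chain}, {resid}) in label map")
            seen.add((chain, resid))

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "ResidueLabelMap":
        df = pd.read_csv(path, dtype={"chain": str, "resid": int, "label": str})
        missing = {"chain", "resid", "label"} - set(df.columns)
        if missing:
            raise FormatError(f"label CSV missing columns: {sorted(missing)}")
        return cls(rows=[(r.chain, int(r.resid), r.label) for r in df.itertuples()])

    def to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(self.rows, columns=["chain", "resid", "label"]).to_csv(
            path, index=False
        )


def apply_labels(
    model: StructureModel, labels: ResidueLabelMap
) -> tuple[StructureModel, list[str]]:
    """Attach generic labels; returns (labeled model, unmatched-key warnings).

    Raises :class:`LabelError` if one label string is mapped to two distinct
    residues.  Unmatched map keys are reported, not fatal.
    """
    out = model.copy()
    present = {(c, r): (c, r, i) for (c, r, i) in model.residue_keys}
    unmatched: list[str] = []
    label_index: dict[str, ResidueKey] = dict(out._label_index)
    for chain, resid, label in labels.rows:
        key = present.get((chain, resid))
        if key is None:
            unmatched.append(f"label {label!r}: residue ({chain}, {resid}) not in model")
            continue
        if label in label_index and label_index[label] != key:
            raise LabelError(
                f"label {label!r} assigned to both {label_index[label]} and {key}"
            )
        out.labels[key] = label
        label_index[label] = key
    out._label_index = label_index
    return out, unmatched


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

QUALIFIERS = ("all", "backbone", "calpha", "sidechain_heavy", "heavy")


@dataclass(frozen=True)
class SelectionSpec:
    """Named residue-range union plus an atom-subset qualifier.

    ``groups`` maps a group name (e.g. ``"TM1"``) to residue ranges
    ``(chain_id, first_res_id, last_res_id)``, bounds inclusive.  Ranges
    within one group must not overlap.
    """

    groups: Mapping[str, Sequence[tuple[str, int, int]]]
    qualifier: str = "all"

    def __post_init__(self) -> None:
        if self.qualifier not in QUALIFIERS:
            raise SelectionError(
                f"unknown qualifier {self.qualifier!r}; expected one of {QUALIFIERS}"
            )
        for name, ranges in self.groups.items():
            by_chain: dict[str, list[tuple[int, int]]] = {}
            for chain, lo, hi in ranges:
                if lo > hi:
                    raise SelectionError(f"group {name!r}: range {lo}-{hi} inverted")
                by_chain.setdefault(chain, []).append((lo, hi))
            for chain, spans in by_chain.items():
                spans.sort()
                for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                    if b0 <= a1:
                        raise SelectionError(
                            f"group {name!r}: overlapping ranges on chain {chain}"
                        )


# TM helix boundaries of the receptor, as shipped defaults (author numbering).
TM_RANGES: dict[str, tuple[int, int]] = {
    "TM1": (132, 165),
    "TM2": (173, 199),
    "TM3": (221, 254),
    "TM4": (264, 288),
    "TM5": (305, 334),
    "TM6": (343, 367),
    "TM7": (377, 400),
}


def tm_backbone_spec(chain: str = "R", qualifier: str = "backbone") -> SelectionSpec:
    """Default TM-helix selection over the shipped helix boundary table."""
    return SelectionSpec(
        groups={name: [(chain, lo, hi)] for name, (lo, hi) in TM_RANGES.items()},
        qualifier=qualifier,
    )


def _qualifier_mask(model: StructureModel, qualifier: str) -> np.ndarray:
    names = model.atom_names
    if qualifier == "all":
        return np.ones(model.n_atoms, dtype=bool)
    if qualifier == "backbone":
        return np.isin(names, tuple(_BACKBONE_NAMES))
    if qualifier == "calpha":
        return names == "CA"
    heavy = model.heavy_atom_mask()
    if qualifier == "heavy":
        return heavy
    # sidechain_heavy: heavy atoms beyond the backbone (CB and outward)
    return heavy & ~np.isin(names, tuple(_BACKBONE_EXTRA))


def select(
    model: StructureModel,
    spec: SelectionSpec,
    groups: Iterable[str] | None = None,
) -> np.ndarray:
    """Resolve a selection to sorted atom indices.

    Raises :class:`SelectionError` when the result is empty — an empty
    selection is never returned silently.
    """
    wanted = list(spec.groups) if groups is None else list(groups)
    unknown = [g for g in wanted if g not in spec.groups]
    if unknown:
        raise SelectionError(f"unknown selection groups: {unknown}")
    residue_mask = np.zeros(model.n_atoms, dtype=bool)
    for g in wanted:
        for chain, lo, hi in spec.groups[g]:
            residue_mask |= (
                (model.chain_ids == chain)
                & (model.res_ids >= lo)
                & (model.res_ids <= hi)
            )
    mask = residue_mask & _qualifier_mask(model, spec.qualifier)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise SelectionError(
            f"selection over groups {wanted} with qualifier "
            f"{spec.qualifier!r} resolves to zero atoms"
        )
    return idx


def chain_residues(model: StructureModel, chain: str) -> list[ResidueKey]:
    """All residue keys of one chain, in file order."""
    keys = [k for k in model.residue_keys if k[0] == chain]
    if not keys:
        raise SelectionError(f"no residues on chain {chain!r}")
    return keys
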