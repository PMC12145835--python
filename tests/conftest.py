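"""Shared fixtures: hand-built structures, a NeRF backbone builder and
small deterministic random systems."""

from __future__ import annotations

import math

import numpy as np
import pytest

from allopath.structure_io import StructureModel, Trajectory


def make_model(records) -> StructureModel:
    """Build a StructureModel from (name, element, chain, resid, resname,
    icode, (x, y, z)) tuples."""
    return StructureModel(
        atom_names=np.asarray([r[0] for r in records], dtype="U6"),
        elements=np.asarray([r[1] for r in records], dtype="U2"),
        chain_ids=np.asarray([r[2] for r in records], dtype="U4"),
        res_ids=np.asarray([r[3] for r in records], dtype=int),
        res_names=np.asarray([r[4] for r in records], dtype="U5"),
        icodes=np.asarray([r[5] for r in records], dtype="U1"),
        coords=np.asarray([r[6] for r in records], dtype=float),
    )


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (both degrees, IUPAC sign)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phis, psis, chain: str = "A", resname: str = "ALA", with_o: bool = True
) -> StructureModel:
    """Polypeptide backbone (N, CA, C[, O]) with prescribed phi/psi, built
    by sequential NeRF placement (omega fixed at 180).

    ``phis[0]`` is unused (no preceding C); lengths must match.
    """
    n_res = len(phis)
    assert len(psis) == n_res
    # seed triad for residue 0
    coords = {
        (0, "N"): np.array([0.0, 0.0, 0.0]),
        (0, "CA"): np.array([1.458, 0.0, 0.0]),
    }
    coords[(0, "C")] = place_atom(
        np.array([0.0, 1.0, 0.0]), coords[(0, "N")], coords[(0, "CA")],
        1.525, 111.2, phis[0] if phis[0] is not None else -57.0,
    )
    for i in range(n_res):
        if i > 0:
            coords[(i, "C")] = place_atom(
                coords[(i - 1, "C")], coords[(i, "N")], coords[(i, "CA")],
                1.525, 111.2, phis[i],
            )
        if i + 1 < n_res:
            coords[(i + 1, "N")] = place_atom(
                coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
                1.329, 116.2, psis[i],
            )
            coords[(i + 1, "CA")] = place_atom(
                coords[(i, "CA")], coords[(i, "C")], coords[(i + 1, "N")],
                1.458, 121.7, 180.0,  # omega
            )
    records = []
    for i in range(n_res):
        for name in ("N", "CA", "C"):
            records.append(
                (name, name[0], chain, i + 1, resname, "", tuple(coords[(i, name)]))
            )
        if with_o and (i, "C") in coords and (i + 1, "N") in coords:
            o = place_atom(
                coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
                1.231, 120.5, psis[i] + 180.0,
            )
            records.append(("O", "O", chain, i + 1, resname, "", tuple(o)))
    return make_model(records)


def static_trajectory(model: StructureModel, n_frames: int) -> Trajectory:
    return Trajectory(
        model=model, coords=np.repeat(model.coords[None], n_frames, axis=0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_residue_model():
    return make_model(
        [
            ("N", "N", "A", 1, "GLY", "", (0.0, 0.0, 0.0)),
            ("CA", "C", "A", 1, "GLY", "", (1.458, 0.0, 0.0)),
            ("C", "C", "A", 1, "GLY", "", (2.0, 1.4, 0.0)),
            ("O", "O", "A", 1, "GLY", "", (1.5, 2.4, 0.0)),
            ("N", "N", "A", 2, "ALA", "", (3.3, 1.4, 0.1)),
            ("CA", "C", "A", 2, "ALA", "", (4.1, 2.6, 0.2)),
            ("C", "C", "A", 2, "ALA", "", (5.5, 2.3, 0.7)),
            ("O", "O", "A", 2, "ALA", "", (5.8, 1.2, 1.2)),
            ("CB", "C", "A", 2, "ALA", "", (4.2, 3.4, -1.1)),
        ]
    )
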