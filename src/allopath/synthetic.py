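"""Synthetic fixture generators with planted, serializable ground truth.

Two generators cover the package's input space without any MD run:

* :func:`generate_torsion_system` — per-residue torsion time series where an
  ordered relay chain of residues co-switches between two rotamer states
  (von Mises noise around state centers) driven by a shared latent two-state
  Markov chain, with imperfect per-residue coupling; background residues
  switch independently.
* :func:`generate_cartesian_system` — an idealized C-alpha helix-bundle
  ensemble with per-residue Gaussian fluctuation amplitudes, scheduled
  on/off interface contacts and an optional planted collective mode.

All randomness flows from the single spec seed.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .allostery import TorsionSeries
from .errors import SpecError
from .geometry import wrap_angle
from .structure_io import ResidueKey, StructureModel, Trajectory

ResiduePair = tuple[ResidueKey, ResidueKey]


def _key_str(key: ResidueKey) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}"


def _key_parse(s: str) -> ResidueKey:
    chain, resid, icode = s.split(":")
    return (chain, int(resid), icode)


@dataclass
class GroundTruth:
    """What was planted, for recovery oracles downstream."""

    relay_chain: list[ResidueKey] = field(default_factory=list)
    expected_high_mi_pairs: list[ResiduePair] = field(default_factory=list)
    contact_occupancy: dict[ResiduePair, float] = field(default_factory=dict)
    sigma: dict[ResidueKey, float] = field(default_factory=dict)
    mode_vector: np.ndarray | None = None  # (n_atoms, 3) or None
    seed: int = 0

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "relay_chain": [_key_str(k) for k in self.relay_chain],
            "expected_high_mi_pairs": [
                [_key_str(a), _key_str(b)] for a, b in self.expected_high_mi_pairs
            ],
            "contact_occupancy": {
                f"{_key_str(a)}|{_key_str(b)}": v
                for (a, b), v in self.contact_occupancy.items()
            },
            "sigma": {_key_str(k): v for k, v in self.sigma.items()},
            "mode_vector": None
            if self.mode_vector is None
            else self.mode_vector.tolist(),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            relay_chain=[_key_parse(s) for s in payload["relay_chain"]],
            expected_high_mi_pairs=[
                (_key_parse(a), _key_parse(b))
                for a, b in payload["expected_high_mi_pairs"]
            ],
            contact_occupancy={
                tuple(_key_parse(p) for p in k.split("|")): v
                for k, v in payload["contact_occupancy"].items()
            },
            sigma={_key_parse(k): v for k, v in payload["sigma"].items()},
            mode_vector=None
            if payload["mode_vector"] is None
            else np.asarray(payload["mode_vector"]),
            seed=payload["seed"],
        )


# ---------------------------------------------------------------------------
# Torsion system
# ---------------------------------------------------------------------------


@dataclass
class TorsionSystemSpec:
    n_residues: int = 60
    n_frames: int = 5000
    relay: tuple[int, ...] = ()  # 0-based residue indices, ordered
    flip_prob: float = 0.02  # latent two-state Markov switching probability
    background_flip_prob: float = 0.5  # memoryless by default: iid states
    coupling: float = 0.9  # P(relay residue follows its upstream state)
    kappa: float = 50.0  # von Mises concentration
    state_centers: tuple[float, float] = (-60.0, 180.0)  # degrees
    chain_id: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.relay)) != len(self.relay):
            raise SpecError("relay indices must be distinct")
        if any(i < 0 or i >= self.n_residues for i in self.relay):
            raise SpecError("relay index out of range")
        if len(self.relay) > self.n_residues:
            raise SpecError("relay longer than residue count")
        if not 0.0 <= self.coupling <= 1.0:
            raise SpecError("coupling must be in [0, 1]")
        if self.kappa <= 0:
            raise SpecError("kappa must be positive")
        if not 0.0 < self.flip_prob < 1.0:
            raise SpecError("flip probability must be in (0, 1)")
        if not 0.0 < self.background_flip_prob <= 1.0:
            raise SpecError("background flip probability must be in (0, 1]")


def _two_state_chain(rng: np.random.Generator, n: int, flip_prob: float) -> np.ndarray:
    state = np.empty(n, dtype=int)
    state[0] = rng.integers(2)
    flips = rng.random(n - 1) < flip_prob
    for t in range(1, n):
        state[t] = state[t - 1] ^ int(flips[t - 1])
    return state


def generate_torsion_system(
    spec: TorsionSystemSpec,
) -> tuple[list[TorsionSeries], GroundTruth]:
    """Planted-relay chi1 series for every residue plus the ground truth.

    The relay is a cascade: the first relay residue copies the latent
    two-state chain with probability ``coupling`` per frame, and every
    subsequent relay residue copies the *displayed* state of its
    predecessor with probability ``coupling`` (otherwise drawing an
    independent fair state).  Per-residue corruption therefore accumulates
    along the chain, giving adjacent relay pairs the strongest MI and a
    monotone MI gradient with relay distance — pathway ordering downstream
    is non-trivial.  Background residues follow their own independent
    two-state chains (memoryless by default, so their pairwise MI obeys
    the iid plug-in bias bound).  Angles are von Mises around the state
    center, wrapped to [-180, 180).
    """
    rng = np.random.default_rng(spec.seed)
    latent = _two_state_chain(rng, spec.n_frames, spec.flip_prob)
    centers = np.asarray(spec.state_centers, dtype=float)
    keys: list[ResidueKey] = [
        (spec.chain_id, i + 1, "") for i in range(spec.n_residues)
    ]
    states: dict[int, np.ndarray] = {}
    upstream = latent
    for i in spec.relay:
        follow = rng.random(spec.n_frames) < spec.coupling
        own = rng.integers(2, size=spec.n_frames)
        states[i] = np.where(follow, upstream, own)
        upstream = states[i]
    series: list[TorsionSeries] = []
    for i in range(spec.n_residues):
        state = states.get(i)
        if state is None:
            if spec.background_flip_prob >= 0.5:
                state = rng.integers(2, size=spec.n_frames)
            else:
                state = _two_state_chain(rng, spec.n_frames, spec.background_flip_prob)
        mu = np.radians(centers[state])
        angles = rng.vonmises(mu, spec.kappa)
        series.append(
            TorsionSeries(
                residue=keys[i], name="chi1", values=wrap_angle(np.degrees(angles))
            )
        )
    relay_keys = [keys[i] for i in spec.relay]
    truth = GroundTruth(
        relay_chain=relay_keys,
        expected_high_mi_pairs=[
            (a, b) for a, b in zip(relay_keys, relay_keys[1:])
        ],
        seed=spec.seed,
    )
    return series, truth


def ca_chain_structure(
    n_residues: int, chain_id: str = "A", spacing: float = 3.8
) -> StructureModel:
    """A minimal C-alpha-only chain laid out on a gentle helix so that every
    residue pair has a well-defined, monotone-with-sequence separation."""
    idx = np.arange(n_residues)
    # wide, slowly turning spiral: consecutive CA ~ spacing apart
    turn = 2.0 * math.pi / 120.0
    radius = 40.0
    z_rise = math.sqrt(max(spacing**2 - (2 * radius * math.sin(turn / 2)) ** 2, 1.0))
    coords = np.stack(
        [
            radius * np.cos(idx * turn),
            radius * np.sin(idx * turn),
            z_rise * idx,
        ],
        axis=1,
    )
    n = n_residues
    return StructureModel(
        atom_names=np.full(n, "CA", dtype="U6"),
        elements=np.full(n, "C", dtype="U2"),
        chain_ids=np.full(n, chain_id, dtype="U4"),
        res_ids=idx + 1,
        res_names=np.full(n, "ALA", dtype="U5"),
        icodes=np.full(n, "", dtype="U1"),
        coords=coords,
    )


# ---------------------------------------------------------------------------
# Cartesian system
# ---------------------------------------------------------------------------


@dataclass
class CartesianSystemSpec:
    n_helices: int = 4
    helix_length: int = 20
    n_frames: int = 50
    sigma: float | dict[ResidueKey, float] = 0.0  # A, Gaussian jitter per axis
    contact_schedule: dict[ResiduePair, tuple[int, ...]] = field(default_factory=dict)
    collective_amplitude: float = 0.0  # A, planted-mode amplitude
    contact_distance: float = 4.0  # A, planted closest-atom distance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1 or self.helix_length < 2:
            raise SpecError("need >= 1 helix of >= 2 residues")
        for pair, frames in self.contact_schedule.items():
            if pair[0][0] == pair[1][0]:
                raise SpecError(f"contact pair {pair} must span two chains")
            if any(f < 0 or f >= self.n_frames for f in frames):
                raise SpecError(f"contact schedule for {pair} has out-of-range frames")


def _helix_center(spec: CartesianSystemSpec, chain_index: int) -> np.ndarray:
    h = spec.n_helices
    bundle_r = 10.0 if h == 1 else max(10.0, 10.0 / (2 * math.sin(math.pi / h)))
    phi = 2 * math.pi * chain_index / h
    return np.array([bundle_r * math.cos(phi), bundle_r * math.sin(phi), 0.0])


def _bundle_reference(spec: CartesianSystemSpec) -> StructureModel:
    rise, twist, helix_r = 1.5, math.radians(100.0), 2.3
    h = spec.n_helices
    bundle_r = 10.0 if h == 1 else max(10.0, 10.0 / (2 * math.sin(math.pi / h)))
    names, elements, chains, resids, resnames, icodes, coords = [], [], [], [], [], [], []
    for hi in range(h):
        phi = 2 * math.pi * hi / h
        cx, cy = bundle_r * math.cos(phi), bundle_r * math.sin(phi)
        for i in range(spec.helix_length):
            names.append("CA")
            elements.append("C")
            chains.append(chr(ord("A") + hi))
            resids.append(i + 1)
            resnames.append("ALA")
            icodes.append("")
            coords.append(
                (
                    cx + helix_r * math.cos(i * twist),
                    cy + helix_r * math.sin(i * twist),
                    rise * i,
                )
            )
    return StructureModel(
        atom_names=np.asarray(names, dtype="U6"),
        elements=np.asarray(elements, dtype="U2"),
        chain_ids=np.asarray(chains, dtype="U4"),
        res_ids=np.asarray(resids, dtype=int),
        res_names=np.asarray(resnames, dtype="U5"),
        icodes=np.asarray(icodes, dtype="U1"),
        coords=np.asarray(coords, dtype=float),
    )


def _planted_mode(rng: np.random.Generator, reference: np.ndarray) -> np.ndarray:
    """Random unit mode vector orthogonalized against rigid-body motions."""
    n = len(reference)
    m = rng.normal(size=(n, 3))
    centered = reference - reference.mean(axis=0)
    basis = []
    for ax in range(3):  # translations
        v = np.zeros((n, 3))
        v[:, ax] = 1.0
        basis.append(v.ravel())
    for ax in range(3):  # infinitesimal rotations r x e_ax
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(centered, e).ravel())
    flat = m.ravel()
    for b in basis:
        nb = np.linalg.norm(b)
        if nb > 0:
            flat = flat - np.dot(flat, b) / nb**2 * b
    flat /= np.linalg.norm(flat)
    return flat.reshape(n, 3)


def generate_cartesian_system(
    spec: CartesianSystemSpec,
) -> tuple[StructureModel, Trajectory, GroundTruth]:
    """Idealized C-alpha helix-bundle ensemble with planted signals.

    Frame 0 equals the reference exactly.  Scheduled contact pairs are
    placed at ``contact_distance`` (default 4.0 A) on their scheduled
    frames by moving the second residue of the pair; all other inter-helix
    separations stay above 10 A, so downstream contact frequencies
    reproduce the schedule occupancies exactly at the default criterion.
    """
    rng = np.random.default_rng(spec.seed)
    reference = _bundle_reference(spec)
    n_atoms = reference.n_atoms
    keys = reference.residue_keys
    if isinstance(spec.sigma, dict):
        sigma = np.array([spec.sigma.get(k, 0.0) for k in keys])
    else:
        sigma = np.full(len(keys), float(spec.sigma))
    for pair in spec.contact_schedule:
        for key in pair:
            if key not in set(keys):
                raise SpecError(f"scheduled residue {key} not in bundle")
    mode = None
    if spec.collective_amplitude > 0:
        mode = _planted_mode(rng, reference.coords)
    coords = np.repeat(reference.coords[None, :, :], spec.n_frames, axis=0)
    # per-atom jitter (here 1 atom per residue); frame 0 stays exact
    jitter = rng.normal(size=(spec.n_frames, n_atoms, 3)) * sigma[None, :, None]
    jitter[0] = 0.0
    coords = coords + jitter
    if mode is not None:
        t = np.arange(spec.n_frames)
        amp = spec.collective_amplitude * np.sin(2 * math.pi * 3 * t / spec.n_frames)
        coords = coords + amp[:, None, None] * mode[None, :, :]
    # contact overrides: pin the partner at the planted distance, displaced
    # radially outward from the host helix axis so no incidental contact
    # with sequence neighbors of the host residue can arise
    moved: dict[tuple[int, ResidueKey], ResiduePair] = {}
    for (key_a, key_b), frames in spec.contact_schedule.items():
        ia = reference.residue_atoms(key_a)[0]
        ib = reference.residue_atoms(key_b)[0]
        center = _helix_center(spec, ord(key_a[0]) - ord("A"))
        radial = reference.coords[ia] - center
        radial[2] = 0.0
        radial /= np.linalg.norm(radial)
        for f in frames:
            prior = moved.get((f, key_b))
            if prior is not None:
                raise SpecError(
                    f"residue {key_b} scheduled as moved partner of both "
                    f"{prior} and {(key_a, key_b)} on frame {f}"
                )
            moved[(f, key_b)] = (key_a, key_b)
            coords[f, ib] = coords[f, ia] + spec.contact_distance * radial
    truth = GroundTruth(
        contact_occupancy={
            pair: 100.0 * len(frames) / spec.n_frames
            for pair, frames in spec.contact_schedule.items()
        },
        sigma={k: float(s) for k, s in zip(keys, sigma)},
        mode_vector=mode,
        seed=spec.seed,
    )
    return reference, Trajectory(model=reference, coords=coords), truth
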