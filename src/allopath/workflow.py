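"""Configuration-driven orchestration and report assembly.

Ties the analysis stages together per configured system: torsions -> MI ->
graph -> pathways -> pipelines -> hub scores (:func:`run_allostery`), and
the descriptor battery: RMSD/RMSF, conformational clustering, contact
frequency tables, interaction energies, microswitch metrics and PCA
(:func:`run_descriptors`).  Every run writes a manifest that references all
emitted files; reruns with identical inputs are byte-identical (no
timestamps in deterministic outputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import allostery as allo
from . import contacts as con
from . import geometry as geo
from . import structure_io as sio
from .errors import ConfigError
from .structure_io import ResidueKey, StructureModel, Trajectory

FLOAT_FMT = "%.6f"


def parse_residue_spec(spec: str, model: StructureModel) -> ResidueKey:
    """``"chain:resid[:icode]"`` or a generic label attached to the model."""
    if ":" in spec:
        parts = spec.split(":")
        chain, resid = parts[0], int(parts[1])
        icode = parts[2] if len(parts) > 2 else ""
        key = (chain, resid, icode)
        if key not in set(model.residue_keys):
            raise ConfigError(f"residue {spec!r} not present in structure")
        return key
    return model.residue_by_label(spec)


@dataclass
class WorkflowConfig:
    """All knobs of a run; see the class body for defaults."""

    structure: str = ""
    trajectories: list[str] = field(default_factory=list)
    torsion_table: str | None = None  # wide CSV alternative to trajectories
    label_map: str | None = None
    nonbonded_params: str | None = None
    output_dir: str = "allopath_out"
    seed: int = 0
    stride: int = 1

    # selections (residue specs are "chain:resid" strings or labels)
    receptor_chain: str = "R"
    partner_chain: str | None = None  # e.g. the G-protein alpha chain
    tm_ranges: dict[str, list[int]] = field(
        default_factory=lambda: {k: list(v) for k, v in sio.TM_RANGES.items()}
    )
    sources: list[str] = field(default_factory=list)
    sinks: list[str] | None = None
    snp_positions: list[str] = field(default_factory=list)
    microswitches: list[dict] = field(default_factory=list)

    # allostery parameters
    mi_bins: int = 24
    mi_aggregation: str = "max"
    min_sequence_separation: int = 3
    top_fraction: float = 0.10
    min_separation: float = 10.0
    pipeline_proximity: float = 7.0
    top_pipelines: int = 5

    # descriptor parameters
    contact_mode: str = "heavy"
    contact_distance: float = 4.5
    contact_cutoffs: list[float] = field(default_factory=lambda: [40.0, 10.0])
    cluster_cutoffs: list[float] = field(default_factory=lambda: [1.2, 0.85])
    pca_n_extreme: int = 30

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "WorkflowConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ConfigError("top_fraction must be in (0, 1]")
        if self.min_separation < 0 or self.pipeline_proximity <= 0:
            raise ConfigError("separation/proximity must be positive")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")
        for p in [self.structure, *self.trajectories]:
            if p and not os.path.exists(p):
                raise ConfigError(f"input file missing: {p}")


@dataclass
class ReportBundle:
    output_dir: str
    manifest: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    objects: dict[str, object] = field(default_factory=dict)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _write_manifest(outdir: str, config: WorkflowConfig, warnings: list[str]) -> dict:
    files = sorted(
        f for f in os.listdir(outdir)
        if f != "manifest.json" and os.path.isfile(os.path.join(outdir, f))
    )
    manifest = {
        "parameters": dataclasses.asdict(config),
        "warnings": warnings,
        "files": {f: _sha256(os.path.join(outdir, f)) for f in files},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _load_model(config: WorkflowConfig) -> tuple[StructureModel, list[str]]:
    model = sio.read_structure(config.structure)
    warnings: list[str] = []
    if config.label_map:
        labels = sio.ResidueLabelMap.from_csv(config.label_map)
        model, unmatched = sio.apply_labels(model, labels)
        warnings.extend(unmatched)
    return model, warnings


def _load_trajectory(config: WorkflowConfig, model: StructureModel) -> Trajectory:
    """Concatenate all configured replicate trajectories (strided)."""
    blocks = []
    for path in config.trajectories:
        traj = sio.read_trajectory(path, model)
        blocks.append(traj.coords[:: config.stride])
    if not blocks:
        raise ConfigError("no trajectories configured")
    return Trajectory(model=model, coords=np.concatenate(blocks, axis=0))


def _load_torsion_table(path: str) -> list[allo.TorsionSeries]:
    df = pd.read_csv(path)
    out = []
    for col in df.columns:
        chain, resid, icode, name = col.split(":")
        out.append(
            allo.TorsionSeries(
                residue=(chain, int(resid), icode),
                name=name,
                values=df[col].to_numpy(dtype=float),
            )
        )
    return out


def _key_str(key: ResidueKey) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}"


# ---------------------------------------------------------------------------
# Allostery pipeline
# ---------------------------------------------------------------------------


def run_allostery(config: WorkflowConfig) -> ReportBundle:
    config.validate()
    if not config.sources:
        raise ConfigError("allostery run requires a non-empty source set")
    model, warn = _load_model(config)
    os.makedirs(config.output_dir, exist_ok=True)
    out = config.output_dir

    if config.torsion_table:
        torsions = _load_torsion_table(config.torsion_table)
        skipped: list[str] = []
    else:
        traj = _load_trajectory(config, model)
        torsions, skipped = allo.extract_torsions(traj)
    warn.extend(skipped)

    mi = allo.residue_mi_matrix(
        torsions,
        aggregation=config.mi_aggregation,
        min_sequence_separation=config.min_sequence_separation,
        bins=config.mi_bins,
    )
    graph = allo.build_graph(mi, top_fraction=config.top_fraction)
    sources = [parse_residue_spec(s, model) for s in config.sources]
    sinks = (
        None
        if config.sinks is None
        else [parse_residue_spec(s, model) for s in config.sinks]
    )
    paths, unreachable = allo.allosteric_paths(
        graph, sources, model, sinks=sinks, min_separation=config.min_separation
    )
    if unreachable:
        warn.append(f"{unreachable} admissible source-sink pairs unreachable in graph")
    pipelines = allo.cluster_pipelines(
        paths, model, proximity=config.pipeline_proximity
    ) if paths else []
    hubs = allo.hub_scores(paths)

    # ---- outputs
    res_strs = [_key_str(k) for k in mi.residues]
    mi_df = pd.DataFrame(mi.values, index=res_strs, columns=res_strs)
    mi_df.to_csv(os.path.join(out, "mi_matrix.csv"), float_format=FLOAT_FMT)
    iu = np.triu_indices(len(mi.residues), k=1)
    long = pd.DataFrame(
        {
            "residue_a": [res_strs[i] for i in iu[0]],
            "residue_b": [res_strs[j] for j in iu[1]],
            "mi": mi.values[iu],
            "eligible": mi.eligible[iu],
        }
    )
    long.to_csv(os.path.join(out, "mi_long.csv"), index=False, float_format=FLOAT_FMT)

    paths_payload = [
        {
            "source": _key_str(p.source),
            "sink": _key_str(p.sink),
            "residues": [_key_str(k) for k in p.residues],
            "labels": [model.label_of(k) or "" for k in p.residues],
            "total_weight": round(p.total_weight, 9),
            "total_mi": round(p.total_mi, 9),
            "ca_separation": round(p.ca_separation, 6),
        }
        for p in paths
    ]
    with open(os.path.join(out, "pathways.json"), "w") as fh:
        json.dump(paths_payload, fh, indent=1, sort_keys=True)

    pipe_rows = []
    for c in pipelines[: config.top_pipelines]:
        rep = paths[c.representative]
        pipe_rows.append(
            {
                "rank": c.rank,
                "population": c.population,
                "total_mi": c.total_mi,
                "representative_source": _key_str(rep.source),
                "representative_sink": _key_str(rep.sink),
                "n_residues": len(
                    {k for m in c.members for k in paths[m].residues}
                ),
            }
        )
    pd.DataFrame(
        pipe_rows,
        columns=[
            "rank", "population", "total_mi",
            "representative_source", "representative_sink", "n_residues",
        ],
    ).to_csv(os.path.join(out, "pipelines.csv"), index=False, float_format=FLOAT_FMT)

    hub_rows = [
        {
            "residue": _key_str(k),
            "label": model.label_of(k) or "",
            "hub_score": hubs.score(k),
        }
        for k in model.residue_keys
    ]
    hub_df = pd.DataFrame(hub_rows, columns=["residue", "label", "hub_score"])
    hub_df.to_csv(os.path.join(out, "hub_scores.csv"), index=False)

    # hub scores in the B-factor column for structure viewers
    _write_bfactor_pdb(model, hubs, os.path.join(out, "hub_scores.pdb"))

    if config.snp_positions:
        ranked = hub_df.sort_values(
            ["hub_score", "residue"], ascending=[False, True]
        ).reset_index(drop=True)
        rank_of = {r.residue: i + 1 for i, r in ranked.iterrows()}
        top_sets = [
            {k for m in c.members for k in paths[m].residues}
            for c in pipelines[: config.top_pipelines]
        ]
        snp_rows = []
        for spec in config.snp_positions:
            key = parse_residue_spec(spec, model)
            member = [i for i, s in enumerate(top_sets) if key in s]
            snp_rows.append(
                {
                    "position": spec,
                    "residue": _key_str(key),
                    "hub_score": hubs.score(key),
                    "hub_rank": rank_of[_key_str(key)],
                    "in_top_pipelines": ";".join(str(i) for i in member),
                }
            )
        pd.DataFrame(snp_rows).to_csv(
            os.path.join(out, "snp_lookup.csv"), index=False
        )

    manifest = _write_manifest(out, config, warn)
    return ReportBundle(
        output_dir=out,
        manifest=manifest,
        tables={"hub_scores": hub_df, "mi_long": long},
        objects={
            "mi": mi, "graph": graph, "paths": paths,
            "pipelines": pipelines, "hubs": hubs,
        },
    )


def _write_bfactor_pdb(model: StructureModel, hubs, path: str) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arr = sio._to_atom_array(model, model.coords)
    bfac = np.zeros(model.n_atoms)
    for key in model.residue_keys:
        bfac[model.residue_atoms(key)] = hubs.score(key)
    arr.set_annotation("b_factor", bfac)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(path)


# ---------------------------------------------------------------------------
# Descriptor battery
# ---------------------------------------------------------------------------


def run_descriptors(config: WorkflowConfig) -> ReportBundle:
    config.validate()
    model, warn = _load_model(config)
    traj = _load_trajectory(config, model)
    os.makedirs(config.output_dir, exist_ok=True)
    out = config.output_dir
    tables: dict[str, pd.DataFrame] = {}

    # selection: configured TM ranges where present, else all backbone/CA
    chain = config.receptor_chain
    chains_present = set(model.chain_ids)
    if chain not in chains_present:
        chain = sorted(chains_present)[0]
        warn.append(f"receptor chain {config.receptor_chain!r} absent; using {chain!r}")
    fit_idx = _fit_selection(model, config, chain)

    rmsd_vals = geo.rmsd_series(traj, model, fit_idx)
    rmsd_df = pd.DataFrame({"frame": np.arange(traj.n_frames), "rmsd": rmsd_vals})
    rmsd_df.to_csv(os.path.join(out, "rmsd.csv"), index=False, float_format=FLOAT_FMT)
    tables["rmsd"] = rmsd_df

    if traj.n_frames >= 2:
        prof = geo.rmsf(traj, fit_idx, per="residue")
        rmsf_df = pd.DataFrame(
            {
                "residue": [_key_str(k) for k in prof.entity_keys],
                "rmsf": prof.values,
            }
        )
        rmsf_df.to_csv(
            os.path.join(out, "rmsf.csv"), index=False, float_format=FLOAT_FMT
        )
        tables["rmsf"] = rmsf_df

    for cutoff in config.cluster_cutoffs:
        cres = geo.cluster_conformations(traj, fit_idx, cutoff)
        rows = [
            {"frame": f, "cluster": rank, "is_representative": f in cres.representatives}
            for rank, members in enumerate(cres.clusters)
            for f in members
        ]
        df = pd.DataFrame(rows).sort_values("frame").reset_index(drop=True)
        name = f"clusters_{cutoff:g}".replace(".", "p")
        df.to_csv(os.path.join(out, name + ".csv"), index=False)
        tables[name] = df

    if config.partner_chain and config.partner_chain in chains_present:
        ga = sio.chain_residues(model, chain)
        gb = sio.chain_residues(model, config.partner_chain)
        criterion = con.ContactCriterion(
            mode=config.contact_mode, cutoff=config.contact_distance
        )
        table = con.contact_frequency(traj, ga, gb, criterion)
        for cutoff in config.contact_cutoffs:
            filtered = con.filter_frequency(table, cutoff)
            name = f"contacts_{cutoff:g}".replace(".", "p")
            filtered.to_csv(os.path.join(out, name + ".csv"))
            tables[name] = filtered.to_dataframe()
        if config.nonbonded_params:
            params = con.NonbondedParams.from_csv(config.nonbonded_params)
            energy = con.interaction_energy(traj, ga, gb, params)
            edf = pd.DataFrame(
                {
                    "frame": np.arange(traj.n_frames),
                    "coulomb": energy.coulomb,
                    "lj": energy.lj,
                    "total": energy.total,
                }
            )
            edf.to_csv(
                os.path.join(out, "energies.csv"), index=False, float_format=FLOAT_FMT
            )
            with open(os.path.join(out, "energy_summary.json"), "w") as fh:
                json.dump(
                    {"mean": energy.mean, "sd": energy.sd}, fh, indent=1, sort_keys=True
                )
            tables["energies"] = edf

    if config.microswitches:
        ms = _microswitch_panel(traj, model, config.microswitches)
        ms.to_csv(
            os.path.join(out, "microswitches.csv"), index=False, float_format=FLOAT_FMT
        )
        tables["microswitches"] = ms

    if traj.n_frames >= 2:
        ca_idx = np.flatnonzero(
            (model.atom_names == "CA") & (model.chain_ids == chain)
        )
        if len(ca_idx):
            pca = geo.pca_ca(
                traj, model, ca_idx, n_extreme_frames=config.pca_n_extreme
            )
            k = min(10, len(pca.eigenvalues))
            pdf = pd.DataFrame(
                {
                    "component": np.arange(1, k + 1),
                    "eigenvalue": pca.eigenvalues[:k],
                    "variance_fraction": pca.variance_fractions[:k],
                }
            )
            pdf.to_csv(
                os.path.join(out, "pca.csv"), index=False, float_format=FLOAT_FMT
            )
            tables["pca"] = pdf
            _write_extremes(model, ca_idx, pca, os.path.join(out, "pca_extremes.pdb"))

    manifest = _write_manifest(out, config, warn)
    return ReportBundle(output_dir=out, manifest=manifest, tables=tables)


def _fit_selection(model, config: WorkflowConfig, chain: str) -> np.ndarray:
    try:
        spec = sio.SelectionSpec(
            groups={
                name: [(chain, int(lo), int(hi))]
                for name, (lo, hi) in config.tm_ranges.items()
            },
            qualifier="backbone",
        )
        return sio.select(model, spec)
    except Exception:
        # fixture systems rarely carry the receptor numbering; fall back to
        # all backbone atoms (or all atoms for CA-only models) of the chain
        mask = model.chain_ids == chain
        bb = mask & np.isin(model.atom_names, ("N", "CA", "C", "O"))
        idx = np.flatnonzero(bb if bb.any() else mask)
        return idx


def _microswitch_panel(traj, model, specs: list[dict]) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"frame": np.arange(traj.n_frames)}
    for item in specs:
        name = item.get("name", "metric")
        if "pair" in item:
            pair = tuple(parse_residue_spec(s, model) for s in item["pair"])
            mode = item.get("mode", "min_sidechain_heavy")
            cols[name] = geo.distance_series(traj, pair, mode=mode).values
        elif "torsion" in item:
            res_spec, tors_name = item["torsion"]
            key = parse_residue_spec(res_spec, model)
            torsions, _ = allo.extract_torsions(traj)
            match = [t for t in torsions if t.residue == key and t.name == tors_name]
            if not match:
                raise ConfigError(f"torsion {tors_name} undefined for {res_spec}")
            cols[name] = match[0].values
        else:
            raise ConfigError(f"microswitch entry needs 'pair' or 'torsion': {item}")
    return pd.DataFrame(cols)


def _write_extremes(model, ca_idx, pca, path: str) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    sub = StructureModel(
        atom_names=model.atom_names[ca_idx],
        elements=model.elements[ca_idx],
        chain_ids=model.chain_ids[ca_idx],
        res_ids=model.res_ids[ca_idx],
        res_names=model.res_names[ca_idx],
        icodes=model.icodes[ca_idx],
        coords=model.coords[ca_idx],
    )
    arrays = [sio._to_atom_array(sub, frame) for frame in pca.extremes]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)
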