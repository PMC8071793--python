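"""Readers and writers for the package's on-disk formats.

Structures travel as (multi-model) PDB files, nonbonded parameters as a
delimited table keyed by atom serial, stress/observable series as TSV
matrices, PLS models and validation reports as JSON, and synthetic
ensembles as one TSV per replica plus a JSON manifest. All coordinates
are nm in memory and Angstrom on disk (PDB convention).
"""

from __future__ import annotations

import json
from pathlib import Path

import biotite.structure as struc
import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile

from .forces import PunctualStressSeries
from .observable import DifferenceVectorSeries
from .pls import PLSModel
from .synthetic import SyntheticEnsemble, SyntheticEnsembleSpec, spec_to_dict
from .system import LIPID, PROTEIN, ToySystem
from .validation import ReplicaResult, ValidationReport

_NM_TO_ANG = 10.0
_CHAIN_NONE = "X"


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def _atom_name(i_within: int) -> str:
    return f"C{i_within + 1}"


def _template(system: ToySystem, bfactors_per_residue=None) -> struc.AtomArray:
    n = system.n_atoms
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(system.positions, dtype=float) * _NM_TO_ANG
    res = system.residue_index
    atoms.res_id = res + 1
    atoms.chain_id = np.array(
        [system.chain_tag[r] if system.chain_tag[r] != "none" else _CHAIN_NONE
         for r in res], dtype="U4")
    atoms.res_name = np.where(system.group_tag == PROTEIN, "TOY", "LIP")
    within = np.zeros(n, dtype=int)
    counts: dict[int, int] = {}
    for i, r in enumerate(res):
        within[i] = counts.get(r, 0)
        counts[r] = within[i] + 1
    atoms.atom_name = np.array([_atom_name(w) for w in within], dtype="U6")
    atoms.element = np.full(n, "C", dtype="U2")
    atoms.hetero = system.group_tag == LIPID
    atoms.box = np.diag(np.asarray(system.box, dtype=float) * _NM_TO_ANG)
    if bfactors_per_residue is not None:
        values = dict(bfactors_per_residue)
        atoms.set_annotation("b_factor", np.array(
            [values.get(int(r), 0.0) for r in res], dtype=float))
    return atoms


def write_system_pdb(system: ToySystem, path,
                     bfactors_per_residue=None) -> None:
    """Single-model PDB of a toy system; optionally colour residues by a
    value written into the B-factor column (e.g. stress or coefficients)."""
    pdb = PDBFile()
    pdb.set_structure(_template(system, bfactors_per_residue))
    pdb.write(str(path))


def write_trajectory_pdb(system: ToySystem, frames, path) -> None:
    """Multi-model PDB with one MODEL per frame (coordinates in nm)."""
    template = _template(system)
    frames = np.asarray(frames, dtype=float)
    stack = struc.stack([template] * len(frames))
    stack.coord = frames * _NM_TO_ANG
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_coordinates(path) -> tuple[np.ndarray, struc.AtomArray]:
    """First model of a PDB as (N, 3) nm coordinates + atom annotations."""
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    return atoms.coord / _NM_TO_ANG, atoms


def read_trajectory(path) -> np.ndarray:
    """All models of a multi-model PDB as (frames, N, 3) nm coordinates."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    coord = stack.coord
    if coord.ndim == 2:
        coord = coord[None]
    return coord / _NM_TO_ANG


PARAM_COLUMNS = ["atom_serial", "charge_e", "sigma_nm", "epsilon_kJmol",
                 "group", "molecule_id"]


def write_parameter_table(system: ToySystem, path) -> None:
    pd.DataFrame({
        "atom_serial": np.arange(1, system.n_atoms + 1),
        "charge_e": system.charges,
        "sigma_nm": system.lj_sigma,
        "epsilon_kJmol": system.lj_epsilon,
        "group": system.group_tag,
        "molecule_id": system.molecule_index,
    }).to_csv(path, sep="\t", index=False)


def read_system(pdb_path, params_path) -> ToySystem:
    """Reassemble a ToySystem from its PDB + parameter table."""
    coords, atoms = read_coordinates(pdb_path)
    params = pd.read_csv(params_path, sep="\t")
    missing = set(PARAM_COLUMNS) - set(params.columns)
    if missing:
        raise ValueError(f"parameter table misses columns: {sorted(missing)}")
    params = params.sort_values("atom_serial")
    if len(params) != len(coords):
        raise ValueError("parameter table and PDB atom counts differ")
    if atoms.box is None:
        raise ValueError("PDB lacks a CRYST1 box record")
    box = np.diag(atoms.box) / _NM_TO_ANG
    res = atoms.res_id - 1
    n_res = int(res.max()) + 1
    chain = np.array(["none"] * n_res, dtype=object)
    for r, c in zip(res, atoms.chain_id):
        chain[r] = "none" if c == _CHAIN_NONE else str(c)
    return ToySystem(
        positions=coords,
        charges=params["charge_e"].to_numpy(float),
        lj_sigma=params["sigma_nm"].to_numpy(float),
        lj_epsilon=params["epsilon_kJmol"].to_numpy(float),
        residue_index=res,
        molecule_index=params["molecule_id"].to_numpy(int),
        group_tag=params["group"].to_numpy(object),
        chain_tag=chain,
        box=box,
    )


# ---------------------------------------------------------------------------
# series tables
# ---------------------------------------------------------------------------

def write_stress_series(series: PunctualStressSeries, path) -> None:
    frame = pd.DataFrame(series.values, columns=series.residue_ids)
    frame.insert(0, "time_ps", series.frame_times)
    frame.to_csv(path, sep="\t", index=False)


def read_stress_series(path) -> PunctualStressSeries:
    frame = pd.read_csv(path, sep="\t")
    times = frame.pop("time_ps").to_numpy(float)
    return PunctualStressSeries(frame.to_numpy(float),
                                list(frame.columns), times)


def write_difference_series(series: DifferenceVectorSeries, path) -> None:
    pd.DataFrame({
        "frame": np.arange(len(series.x)),
        "time_ps": series.frame_times,
        "x": series.x,
        "label": series.labels,
    }).to_csv(path, sep="\t", index=False)


def read_difference_series(path, threshold: float = 0.0) -> DifferenceVectorSeries:
    frame = pd.read_csv(path, sep="\t")
    return DifferenceVectorSeries(frame["x"].to_numpy(float),
                                  frame["label"].to_numpy(int),
                                  frame["time_ps"].to_numpy(float),
                                  threshold)


# ---------------------------------------------------------------------------
# PLS model / validation report
# ---------------------------------------------------------------------------

def write_pls_model(model: PLSModel, path, metadata: dict | None = None) -> None:
    payload = {
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weight_vectors": model.weight_vectors.tolist(),
        "loadings": model.loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "n_components": model.n_components,
        "coefficient_vector": model.coefficient_vector.tolist(),
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload))


def read_pls_model(path) -> PLSModel:
    payload = json.loads(Path(path).read_text())
    return PLSModel(x_mean=np.asarray(payload["x_mean"]),
                    y_mean=float(payload["y_mean"]),
                    weight_vectors=np.asarray(payload["weight_vectors"]),
                    loadings=np.asarray(payload["loadings"]),
                    y_loadings=np.asarray(payload["y_loadings"]),
                    n_components=int(payload["n_components"]))


def write_validation_report(report: ValidationReport, json_path,
                            summary_path=None) -> None:
    payload = {
        "n_components": report.n_components,
        "threshold": report.threshold,
        "per_replica": [vars(r) for r in report.per_replica],
        "ensemble_vector": report.ensemble_vector.tolist(),
        "vector_similarity": report.vector_similarity.tolist(),
        "first_component_contribution": report.first_component_contribution,
    }
    Path(json_path).write_text(json.dumps(payload))
    if summary_path is not None:
        report.summary_frame().to_csv(summary_path, sep="\t", index=False)


def read_validation_report(json_path) -> ValidationReport:
    payload = json.loads(Path(json_path).read_text())
    return ValidationReport(
        per_replica=[ReplicaResult(**r) for r in payload["per_replica"]],
        ensemble_vector=np.asarray(payload["ensemble_vector"]),
        vector_similarity=np.asarray(payload["vector_similarity"]),
        first_component_contribution=payload["first_component_contribution"],
        n_components=int(payload["n_components"]),
        threshold=float(payload["threshold"]),
    )


def write_coefficient_table(residue_ids, coefficients, path) -> None:
    pd.DataFrame({"residue_id": residue_ids,
                  "coefficient": np.asarray(coefficients, float)}
                 ).to_csv(path, sep="\t", index=False)


def read_chain_pairing(path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValueError("chain pairing needs two columns (chain A id, "
                         "chain B id)")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))


# ---------------------------------------------------------------------------
# synthetic ensembles
# ---------------------------------------------------------------------------

def write_ensemble(ensemble: SyntheticEnsemble, directory) -> Path:
    """One TSV per replica (observable, label, features) + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i in range(ensemble.n_replicas):
        name = f"replica_{i:02d}.tsv"
        frame = pd.DataFrame(ensemble.features[i],
                             columns=ensemble.residue_ids())
        frame.insert(0, "label", ensemble.state_labels[i])
        frame.insert(0, "observable", ensemble.observable[i])
        frame.to_csv(directory / name, sep="\t", index=False,
                     float_format="%.10g")
        files.append(name)
    manifest = {
        "spec": spec_to_dict(ensemble.spec),
        "replica_files": files,
        "replica_kind": ensemble.replica_kind,
        "true_coefficients": ensemble.true_coefficients.tolist(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest))
    return directory / "manifest.json"


def read_ensemble(directory) -> SyntheticEnsemble:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec_dict = dict(manifest["spec"])
    spec_dict["transition_window"] = tuple(spec_dict["transition_window"])
    spec = SyntheticEnsembleSpec(**spec_dict)
    features, observable, labels = [], [], []
    for name in manifest["replica_files"]:
        frame = pd.read_csv(directory / name, sep="\t")
        observable.append(frame.pop("observable").to_numpy(float))
        labels.append(frame.pop("label").to_numpy(int))
        features.append(frame.to_numpy(float))
    return SyntheticEnsemble(spec, features, observable, labels,
                             np.asarray(manifest["true_coefficients"]),
                             list(manifest["replica_kind"]))
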