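"""Readers and writers for meshes, basis fields, labels and result tables.

Meshes come in as Gmsh MSH (v2 ASCII, the surface format written by common
head-modelling pipelines) or PLY; region labels as a two-column TSV
(node_index, label) keyed 0-based; basis fields as an HDF5 container
(``/fields/{ER1,EC1,ER2}`` as N-by-3 arrays with ``Io``/``f`` attributes on
``/meta``) or as a wide TSV with a JSON metadata sidecar.  Synthetic and
externally simulated inputs are interchangeable: the generator writes the
same containers these readers consume.  Node indexing is 0-based internally
and converted from the 1-based MSH convention on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import trimesh

from .geometry import CorticalSheet
from .superposition import BasisFieldSet
from .thresholding import ThresholdMask

__all__ = [
    "read_msh", "write_msh", "read_ply", "write_ply",
    "read_labels_tsv", "write_labels_tsv",
    "read_basis_h5", "write_basis_h5", "read_basis_tsv", "write_basis_tsv",
    "write_mask_tsv", "write_table", "write_json", "load_sheet",
]

_FIELD_KEYS = ("ER1", "EC1", "ER2")


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def read_msh(path) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and triangles from a Gmsh MSH v2 ASCII file.

    Only 3-node triangle elements (type 2) are read; node ids may be
    arbitrary and are remapped to dense 0-based indices in file order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    it = iter(lines)
    coords: list[list[float]] = []
    id_map: dict[int, int] = {}
    triangles: list[list[int]] = []
    for line in it:
        tag = line.strip()
        if tag == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                id_map[int(parts[0])] = len(coords)
                coords.append([float(x) for x in parts[1:4]])
        elif tag == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                if etype != 2:
                    continue
                n_tags = int(parts[2])
                nodes = [int(p) for p in parts[3 + n_tags: 6 + n_tags]]
                triangles.append([id_map[v] for v in nodes])
    if not coords:
        raise ValueError(f"no $Nodes section found in {path}")
    return np.asarray(coords, dtype=float), np.asarray(triangles, dtype=np.intp)


def write_msh(path, node_coords: np.ndarray, triangles: np.ndarray) -> None:
    """Write a surface mesh as Gmsh MSH v2 ASCII (1-based node ids)."""
    node_coords = np.asarray(node_coords, dtype=float)
    triangles = np.asarray(triangles, dtype=np.intp)
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{len(node_coords)}\n")
        for i, (x, y, z) in enumerate(node_coords, start=1):
            fh.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{len(triangles)}\n")
        for i, (a, b, c) in enumerate(triangles, start=1):
            fh.write(f"{i} 2 2 0 0 {a + 1} {b + 1} {c + 1}\n")
        fh.write("$EndElements\n")


def read_ply(path) -> tuple[np.ndarray, np.ndarray]:
    mesh = trimesh.load(str(path), file_type="ply", process=False)
    return np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=np.intp)


def write_ply(path, node_coords: np.ndarray, triangles: np.ndarray) -> None:
    mesh = trimesh.Trimesh(vertices=node_coords, faces=triangles, process=False)
    Path(path).write_bytes(mesh.export(file_type="ply", encoding="ascii"))


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def read_labels_tsv(path, n_nodes: int | None = None) -> np.ndarray:
    """Per-node integer labels from a (node_index, label) TSV; unlisted
    nodes get -1 (requires ``n_nodes``)."""
    df = pd.read_csv(path, sep="\t")
    if not {"node_index", "label"}.issubset(df.columns):
        raise ValueError("labels TSV needs columns 'node_index' and 'label'")
    size = n_nodes if n_nodes is not None else int(df["node_index"].max()) + 1
    labels = np.full(size, -1, dtype=int)
    labels[df["node_index"].to_numpy()] = df["label"].to_numpy()
    return labels


def write_labels_tsv(path, labels: np.ndarray) -> None:
    pd.DataFrame(
        {"node_index": np.arange(len(labels)), "label": np.asarray(labels, dtype=int)}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# basis fields
# ---------------------------------------------------------------------------

def write_basis_h5(path, basis: BasisFieldSet) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("fields")
        for key, arr in zip(_FIELD_KEYS, (basis.e_r1, basis.e_c1, basis.e_r2)):
            grp.create_dataset(key, data=arr)
        meta = fh.create_group("meta")
        meta.attrs["Io"] = basis.io_amp
        meta.attrs["f"] = basis.f
        meta.attrs["montage_id"] = basis.montage_id
        meta.attrs["individual_id"] = basis.individual_id


def read_basis_h5(path) -> BasisFieldSet:
    with h5py.File(path, "r") as fh:
        fields = [fh["fields"][k][()] for k in _FIELD_KEYS]
        meta = fh["meta"].attrs
        return BasisFieldSet(
            *fields,
            io_amp=float(meta["Io"]),
            f=float(meta["f"]),
            montage_id=str(meta.get("montage_id", "")),
            individual_id=str(meta.get("individual_id", "")),
        )


def write_basis_tsv(path, basis: BasisFieldSet) -> None:
    """Wide TSV (one row per node) plus a ``<path>.meta.json`` sidecar."""
    cols = {"node_index": np.arange(basis.n_nodes)}
    for key, arr in zip(_FIELD_KEYS, (basis.e_r1, basis.e_c1, basis.e_r2)):
        for ax, name in enumerate("xyz"):
            cols[f"{key}_{name}"] = arr[:, ax]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "Io": basis.io_amp, "f": basis.f,
        "montage_id": basis.montage_id, "individual_id": basis.individual_id,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_basis_tsv(path) -> BasisFieldSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip").sort_values("node_index")
    fields = [
        df[[f"{key}_{ax}" for ax in "xyz"]].to_numpy(dtype=float) for key in _FIELD_KEYS
    ]
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return BasisFieldSet(
        *fields,
        io_amp=float(meta.get("Io", 2.0)),
        f=float(meta.get("f", 20.0)),
        montage_id=str(meta.get("montage_id", "")),
        individual_id=str(meta.get("individual_id", "")),
    )


# ---------------------------------------------------------------------------
# derived outputs
# ---------------------------------------------------------------------------

def write_mask_tsv(path, mask: ThresholdMask) -> None:
    status = np.where(mask.excluded, "excluded", np.where(mask.zeroed, "zeroed", "kept"))
    pd.DataFrame({"node_index": np.arange(len(status)), "status": status}).to_csv(
        path, sep="\t", index=False
    )


def write_table(path, table: pd.DataFrame) -> None:
    """Tidy TSV with stable row order and float formatting (byte-identical
    across repeated runs of the same configuration)."""
    table = table.sort_values(list(table.columns)).reset_index(drop=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_sheet(
    mesh_path,
    labels_path=None,
    region_sets: dict[str, frozenset[int]] | None = None,
) -> CorticalSheet:
    """Sheet from a mesh file (MSH or PLY by extension) plus optional labels."""
    mesh_path = Path(mesh_path)
    if mesh_path.suffix == ".msh":
        coords, tris = read_msh(mesh_path)
    elif mesh_path.suffix == ".ply":
        coords, tris = read_ply(mesh_path)
    else:
        raise ValueError(f"unsupported mesh format {mesh_path.suffix!r} (use .msh or .ply)")
    labels = read_labels_tsv(labels_path, n_nodes=len(coords)) if labels_path else None
    return CorticalSheet.from_mesh(coords, tris, labels, region_sets)
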