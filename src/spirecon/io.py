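"""Readers and writers: PDB/mmCIF atomic models, MRC/CCP4 maps (via gemmi)."""

from __future__ import annotations

import numpy as np

import gemmi

from .scatter import AtomicModel, DensityMap, FourierVolume

__all__ = ["read_model", "write_model", "write_map", "read_map"]


def read_model(path: str, include_waters: bool = False) -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    Atom weights are atomic numbers; waters are skipped by default; only the
    first model of multi-model files is used.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    weights: list[float] = []
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    for chain in st[0]:
        for residue in chain:
            if not include_waters and residue.is_water():
                continue
            for atom in residue:
                el = atom.element
                elements.append(el.name)
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
                weights.append(float(el.atomic_number))
    if not coords:
        raise ValueError(f"no atoms read from {path}")
    return AtomicModel(elements=tuple(elements), coords=np.array(coords),
                       weights=np.array(weights))


def write_model(model: AtomicModel, path: str) -> None:
    """Write an atomic model as a minimal single-chain PDB file."""
    st = gemmi.Structure()
    st.name = "phantom"
    md = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (el, xyz) in enumerate(zip(model.elements, model.coords)):
        res = gemmi.Residue()
        res.name = "UNK"
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = el
        atom.element = gemmi.Element(el)
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


def write_map(map_or_volume: DensityMap | FourierVolume | np.ndarray,
              path: str, voxel_pitch: float | None = None) -> None:
    """Write a cubic 3D grid as a CCP4/MRC map (float32, X fastest).

    The voxel pitch is recorded through the unit cell (cell edge = pitch *
    dimension); accepts a :class:`DensityMap`, a :class:`FourierVolume`
    (its intensity or |F|^2) or a raw array plus ``voxel_pitch``.
    """
    if isinstance(map_or_volume, DensityMap):
        values, pitch = map_or_volume.values, map_or_volume.voxel_pitch
    elif isinstance(map_or_volume, FourierVolume):
        values, _ = map_or_volume.matching_values()
        pitch = map_or_volume.voxel_pitch_q
    else:
        if voxel_pitch is None:
            raise ValueError("voxel_pitch required for raw arrays")
        values, pitch = np.asarray(map_or_volume), voxel_pitch
    if values.ndim != 3 or len(set(values.shape)) != 1:
        raise ValueError("expected a cubic 3D grid")
    n = values.shape[0]
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(values, dtype=np.float32))
    ccp4.grid.unit_cell = gemmi.UnitCell(pitch * n, pitch * n, pitch * n, 90, 90, 90)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_map(path: str) -> DensityMap:
    """Read a CCP4/MRC map back into a :class:`DensityMap`."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    values = np.array(ccp4.grid, copy=True)
    n = values.shape[0]
    pitch = ccp4.grid.unit_cell.a / n
    return DensityMap(values=values.astype(float), voxel_pitch=pitch)
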