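"""Structure and trajectory I/O.

Structures are read from PDB files into a backbone-centric
:class:`StructureModel` (author residue numbering, N/CA/C coordinates in Å,
per-atom B-factors).  Trajectories are frames of the same backbone topology
with strictly increasing frame times in picoseconds; multi-model PDB and
GROMACS XTC are supported on both read and write.  Parsing is delegated to
biotite; this module only shapes the result for the analysis layers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from biotite.sequence import ProteinSequence

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C")
#: analysis convention: one saved conformation per 100 ps of simulation
DEFAULT_STRIDE_PS = 100.0


class MissingChainError(ValueError):
    pass


class TopologyMismatchError(ValueError):
    pass


@dataclass
class StructureModel:
    """Backbone model of one protein chain.

    Attributes
    ----------
    residue_numbers : (n,) int array
        Author residue numbers, strictly increasing.
    residue_codes : (n,) str array
        One-letter amino-acid codes ('X' for non-standard residues).
    coords : (n, 3, 3) float array
        Å coordinates of (N, CA, C) per residue; NaN where an atom is absent.
    bfactors : (n, 3) float array
        Per-atom B-factors (Å²) in the same atom order; NaN where absent.
    flagged : (n,) bool array
        Residues marked as rebuilt/completed by modelling (metadata carried
        into reports, e.g. side chains completed in the deposited structure).
    chain : str
    """

    residue_numbers: np.ndarray
    residue_codes: np.ndarray
    coords: np.ndarray
    bfactors: np.ndarray | None = None
    flagged: np.ndarray | None = None
    chain: str = "A"

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.residue_codes = np.asarray(self.residue_codes, dtype="<U1")
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_numbers)
        if self.coords.shape != (n, 3, 3):
            raise ValueError(f"coords must be (n, 3, 3); got {self.coords.shape}")
        if n > 1 and not np.all(np.diff(self.residue_numbers) > 0):
            raise ValueError("residue numbers must be strictly increasing")
        if self.bfactors is None:
            self.bfactors = np.full((n, 3), np.nan)
        else:
            self.bfactors = np.asarray(self.bfactors, dtype=float).reshape(n, 3)
        if self.flagged is None:
            self.flagged = np.zeros(n, dtype=bool)
        else:
            self.flagged = np.asarray(self.flagged, dtype=bool)

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)

    @property
    def complete(self) -> np.ndarray:
        """Mask of residues with all three backbone atoms present."""
        return ~np.any(np.isnan(self.coords), axis=(1, 2))

    def slice(self, span: tuple[int, int]) -> "StructureModel":
        """Restrict to author residue numbers in the closed interval span."""
        start, end = span
        mask = (self.residue_numbers >= start) & (self.residue_numbers <= end)
        return StructureModel(
            residue_numbers=self.residue_numbers[mask],
            residue_codes=self.residue_codes[mask],
            coords=self.coords[mask],
            bfactors=self.bfactors[mask],
            flagged=self.flagged[mask],
            chain=self.chain,
        )


@dataclass
class Trajectory:
    """Frames of backbone coordinates over a fixed topology.

    coords has shape (n_frames, n_residues, 3 atoms, 3); times_ps is strictly
    increasing.
    """

    coords: np.ndarray
    times_ps: np.ndarray
    topology: StructureModel = field(repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 3:
            self.coords = self.coords[None]
        F = self.coords.shape[0]
        if self.coords.shape[1:] != (self.topology.n_residues, 3, 3):
            raise TopologyMismatchError(
                f"frame shape {self.coords.shape[1:]} does not match topology "
                f"({self.topology.n_residues} residues x 3 backbone atoms)"
            )
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        if self.times_ps.shape != (F,):
            raise ValueError("one time per frame required")
        if F > 1 and not np.all(np.diff(self.times_ps) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def ca_coords(self) -> np.ndarray:
        """(n_frames, n_residues, 3) Cα coordinates."""
        return self.coords[:, :, 1, :]

    def discard_before(self, time_ps: float) -> "Trajectory":
        """Drop equilibration frames with time <= time_ps."""
        keep = self.times_ps > time_ps
        if not np.any(keep):
            raise ValueError(f"discarding {time_ps} ps leaves no frames")
        return Trajectory(self.coords[keep], self.times_ps[keep], self.topology)


def _three_to_one(res_name: str) -> str:
    try:
        return ProteinSequence.convert_letter_3to1(res_name)
    except KeyError:
        return "X"


def read_structure(
    path,
    chain: str = "A",
    span: tuple[int, int] | None = None,
    model: int = 1,
) -> StructureModel:
    """Read one chain of a PDB file into a backbone StructureModel.

    Alternate locations resolve to the highest-occupancy conformer; insertion
    codes are rejected (the analysis relies on unambiguous author numbering).
    Residues missing any backbone atom are kept with NaN coordinates, logged,
    and excluded from the dihedral-capable set downstream.
    """
    pdb_file = pdbio.PDBFile.read(str(path))
    atoms = pdbio.get_structure(
        pdb_file, model=model, altloc="occupancy", extra_fields=["b_factor"]
    )
    atoms = atoms[struc.filter_amino_acids(atoms)]
    chains = np.unique(atoms.chain_id)
    if chain not in chains:
        raise MissingChainError(f"chain {chain!r} not found (available: {list(chains)})")
    atoms = atoms[atoms.chain_id == chain]
    if np.any(atoms.ins_code != ""):
        raise ValueError("insertion codes are not supported")

    resids = []
    codes = []
    coords = []
    bfactors = []
    for resid in np.unique(atoms.res_id):
        res = atoms[atoms.res_id == resid]
        xyz = np.full((3, 3), np.nan)
        bf = np.full(3, np.nan)
        for j, name in enumerate(BACKBONE_ATOMS):
            hit = res[res.atom_name == name]
            if len(hit) > 0:
                xyz[j] = hit.coord[0]
                bf[j] = hit.b_factor[0]
        if np.any(np.isnan(xyz)):
            logger.warning(
                "residue %d in chain %s lacks a backbone atom; excluded from "
                "dihedral-capable set", resid, chain,
            )
        resids.append(int(resid))
        codes.append(_three_to_one(res.res_name[0]))
        coords.append(xyz)
        bfactors.append(bf)

    model_out = StructureModel(
        residue_numbers=np.array(resids),
        residue_codes=np.array(codes),
        coords=np.array(coords),
        bfactors=np.array(bfactors),
        chain=chain,
    )
    if span is not None:
        model_out = model_out.slice(span)
    return model_out


def _backbone_atom_array(topology: StructureModel, coords: np.ndarray) -> struc.AtomArray:
    n = topology.n_residues
    arr = struc.AtomArray(n * 3)
    arr.coord = coords.reshape(n * 3, 3)
    arr.chain_id = np.repeat(topology.chain, n * 3)
    arr.res_id = np.repeat(topology.residue_numbers, 3)
    three = [
        ProteinSequence.convert_letter_1to3(c) if c != "X" else "UNK"
        for c in topology.residue_codes
    ]
    arr.res_name = np.repeat(three, 3)
    arr.atom_name = np.tile(np.array(BACKBONE_ATOMS), n)
    arr.element = np.tile(np.array(["N", "C", "C"]), n)
    arr.hetero = np.zeros(n * 3, dtype=bool)
    bf = topology.bfactors
    arr.set_annotation("b_factor", np.nan_to_num(bf.reshape(-1), nan=0.0))
    return arr


def write_structure(model: StructureModel, path) -> None:
    """Write the backbone model as a single-model PDB file."""
    arr = _backbone_atom_array(model, model.coords)
    pdb_file = pdbio.PDBFile()
    pdbio.set_structure(pdb_file, arr)
    pdb_file.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write frames as multi-model PDB (.pdb) or GROMACS XTC (.xtc)."""
    path = str(path)
    if path.endswith(".xtc"):
        from biotite.structure.io.xtc import XTCFile

        xtc = XTCFile()
        xtc.set_coord(traj.coords.reshape(traj.n_frames, -1, 3))
        xtc.set_time(traj.times_ps)
        xtc.write(path)
    elif path.endswith(".pdb"):
        template = _backbone_atom_array(traj.topology, traj.topology.coords)
        stack = struc.from_template(
            template, traj.coords.reshape(traj.n_frames, -1, 3)
        )
        pdb_file = pdbio.PDBFile()
        pdbio.set_structure(pdb_file, stack)
        pdb_file.write(path)
    else:
        raise ValueError(f"unsupported trajectory format: {path}")


def read_trajectory(
    path,
    topology: StructureModel,
    stride_ps: float = DEFAULT_STRIDE_PS,
) -> Trajectory:
    """Read a backbone trajectory (multi-model PDB or XTC) over a topology.

    The file must contain exactly the topology's backbone atoms in N/CA/C
    order.  Frame times come from the file when stored (XTC); otherwise they
    default to a uniform stride of ``stride_ps`` starting at ``stride_ps``.
    """
    path = str(path)
    n_atoms_expected = topology.n_residues * 3
    times = None
    if path.endswith(".xtc"):
        from biotite.structure.io.xtc import XTCFile

        xtc = XTCFile.read(path)
        coord = xtc.get_coord()
        file_times = xtc.get_time()
        if file_times is not None and len(file_times) and np.all(np.diff(file_times) > 0):
            times = np.asarray(file_times, dtype=float)
    elif path.endswith(".pdb"):
        pdb_file = pdbio.PDBFile.read(path)
        stack = pdbio.get_structure(pdb_file, model=None)
        coord = stack.coord
    else:
        raise ValueError(f"unsupported trajectory format: {path}")

    if coord.shape[1] != n_atoms_expected:
        raise TopologyMismatchError(
            f"trajectory has {coord.shape[1]} atoms but topology expects "
            f"{n_atoms_expected} (={topology.n_residues} residues x 3)"
        )
    F = coord.shape[0]
    if times is None:
        times = stride_ps * np.arange(1, F + 1)
    coords = coord.reshape(F, topology.n_residues, 3, 3)
    return Trajectory(coords=coords, times_ps=times, topology=topology)


def bfactor_profile(model: StructureModel, convention: str = "ca"):
    """Per-residue crystallographic B-factor series (Å²).

    convention 'ca' takes the Cα atom's value (comparable with Cα-only RMSF);
    'backbone_mean' averages N/CA/C.  Returns (residue_numbers, values,
    flagged) with NaN where the convention's atoms are absent.
    """
    if convention == "ca":
        values = model.bfactors[:, 1]
    elif convention == "backbone_mean":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            values = np.nanmean(model.bfactors, axis=1)
    else:
        raise ValueError(f"unknown B-factor convention: {convention!r}")
    finite = values[np.isfinite(values)]
    if finite.size and np.allclose(finite, 0.0):
        logger.warning("all B-factors are zero; the input file was likely stripped")
    return model.residue_numbers.copy(), values.astype(float), model.flagged.copy()


def write_profile_tsv(path, residue_numbers, values, header: str = "value",
                      metadata: dict | None = None) -> None:
    """Emit a per-residue profile as `residue<TAB>value` TSV."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write(f"residue\t{header}\n")
        for resid, value in zip(residue_numbers, values):
            fh.write(f"{resid}\t{value:.6g}\n")
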