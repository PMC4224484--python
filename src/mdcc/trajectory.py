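"""Trajectory container, file I/O, atom selection and rigid-body superposition.

Coordinates are stored as a dense ``(T, N, 3)`` float array in Angstrom.
Reading and writing of PDB/DCD/XTC goes through MDAnalysis; the container
itself is format-agnostic so the synthetic generators can build trajectories
directly in memory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

ATOM_COLUMNS = ["atom_name", "element", "residue_seq", "residue_name",
                "chain_id", "is_heavy"]


class FormatError(ValueError):
    """Topology and coordinate inputs are inconsistent or unreadable."""


class EmptyInputError(ValueError):
    """No frames (or no atoms) remain after skip/stride/selection."""


class SelectionError(ValueError):
    """An atom selection resolved to the empty set."""


class DegenerateFitError(ValueError):
    """Too few / collinear atoms for a rigid-body least-squares fit."""


@dataclass
class Trajectory:
    """Frame-indexed coordinates plus a per-atom topology table.

    Parameters
    ----------
    coords
        Array of shape ``(T, N, 3)``, Angstrom.
    atoms
        DataFrame with one row per atom (columns :data:`ATOM_COLUMNS`),
        indexed by the 0-based internal atom id.  Residue identifiers from
        the source file are preserved verbatim for reporting.
    frame_times
        Optional per-frame times in ps.
    source
        Provenance string (file path or generator description).
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    frame_times: Optional[np.ndarray] = None
    source: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError(f"coords must be (T, N, 3), got {self.coords.shape}")
        if self.n_frames < 2:
            raise EmptyInputError("a trajectory needs at least two frames")
        if self.n_atoms < 1:
            raise EmptyInputError("a trajectory needs at least one atom")
        if not np.isfinite(self.coords).all():
            raise FormatError("coordinates contain non-finite values")
        if len(self.atoms) != self.n_atoms:
            raise FormatError(
                f"atom table has {len(self.atoms)} rows for {self.n_atoms} atoms")
        triples = self.atoms[["chain_id", "residue_seq", "atom_name"]]
        if triples.duplicated().any():
            raise FormatError("(chain_id, residue_seq, atom_name) triples not unique")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_coords(self, atom_id: int) -> np.ndarray:
        """``(T, 3)`` coordinate series of one atom."""
        return self.coords[:, atom_id, :]

    def residue_labels(self) -> list[str]:
        """Per-atom ``chain:resid`` labels (file order)."""
        return [f"{c}:{r}" for c, r in
                zip(self.atoms["chain_id"], self.atoms["residue_seq"])]


@dataclass
class AtomSelection:
    """Declarative atom predicate over the atom table.

    All criteria are conjunctive; ``None`` means "no constraint".
    """

    chains: Optional[Sequence[str]] = None
    residue_range: Optional[tuple[int, int]] = None   # inclusive
    heavy_only: bool = False
    names: Optional[Sequence[str]] = None
    atom_ids: Optional[Sequence[int]] = None
    _label: str = field(default="", repr=False)

    def describe(self) -> str:
        parts = []
        if self.chains is not None:
            parts.append(f"chain in {list(self.chains)}")
        if self.residue_range is not None:
            parts.append(f"resid in [{self.residue_range[0]}, {self.residue_range[1]}]")
        if self.heavy_only:
            parts.append("heavy only")
        if self.names is not None:
            parts.append(f"name in {list(self.names)}")
        if self.atom_ids is not None:
            parts.append(f"atom_id in {list(self.atom_ids)}")
        return " and ".join(parts) if parts else "all atoms"

    def resolve(self, atoms: pd.DataFrame) -> np.ndarray:
        """Sorted, duplicate-free atom id array; raises if empty."""
        mask = np.ones(len(atoms), dtype=bool)
        if self.chains is not None:
            mask &= atoms["chain_id"].isin(list(self.chains)).to_numpy()
        if self.residue_range is not None:
            lo, hi = self.residue_range
            rs = atoms["residue_seq"].to_numpy()
            mask &= (rs >= lo) & (rs <= hi)
        if self.heavy_only:
            mask &= atoms["is_heavy"].to_numpy()
        if self.names is not None:
            mask &= atoms["atom_name"].isin(list(self.names)).to_numpy()
        if self.atom_ids is not None:
            idmask = np.zeros(len(atoms), dtype=bool)
            idmask[np.asarray(list(self.atom_ids), dtype=int)] = True
            mask &= idmask
        ids = np.flatnonzero(mask)
        if ids.size == 0:
            raise SelectionError(f"selection matched no atoms: {self.describe()}")
        return ids


def _atom_table_from_universe(u) -> pd.DataFrame:
    import MDAnalysis as mda  # local import keeps module import cheap

    atoms = u.atoms
    names = atoms.names
    try:
        elements = atoms.elements
    except (AttributeError, mda.exceptions.NoDataError):
        try:
            u.guess_TopologyAttrs(to_guess=["elements"])
            elements = u.atoms.elements
        except Exception:  # pragma: no cover - very old topologies
            elements = np.array([n.strip()[:1] for n in names])
    elements = np.array([e if e else n.strip()[:1]
                         for e, n in zip(elements, names)])
    try:
        chains = atoms.chainIDs
    except (AttributeError, mda.exceptions.NoDataError):
        chains = atoms.segids
    table = pd.DataFrame({
        "atom_name": names,
        "element": elements,
        "residue_seq": atoms.resids,
        "residue_name": atoms.resnames,
        "chain_id": chains,
        "is_heavy": np.char.upper(elements.astype(str)) != "H",
    })
    table.index.name = "atom_id"
    return table


def load_trajectory(topology_path, coords_path=None, *, stride: int = 1,
                    skip_frames: int = 0) -> Trajectory:
    """Read a topology plus coordinate series into a :class:`Trajectory`.

    ``coords_path`` may be omitted when the topology file itself carries the
    frames (multi-model PDB).  Frames ``skip_frames, skip_frames+stride, ...``
    are retained.
    """
    import MDAnalysis as mda

    if stride < 1:
        raise ValueError("stride must be a positive integer")
    if skip_frames < 0:
        raise ValueError("skip_frames must be non-negative")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if coords_path is None:
                u = mda.Universe(str(topology_path))
            else:
                u = mda.Universe(str(topology_path), str(coords_path))
        except Exception as exc:  # MDAnalysis raises many concrete types
            raise FormatError(f"could not read trajectory: {exc}") from exc

        # drop alternate locations other than blank / 'A' for determinism
        keep = np.arange(len(u.atoms))
        try:
            altlocs = u.atoms.altLocs
            keep = np.flatnonzero(np.isin(altlocs, ["", " ", "A"]))
        except (AttributeError, mda.exceptions.NoDataError):
            pass
        group = u.atoms[keep]

        frames = []
        times = []
        for ts in u.trajectory[skip_frames::stride]:
            frames.append(group.positions.astype(float).copy())
            times.append(float(getattr(ts, "time", ts.frame)))
    if len(frames) == 0:
        raise EmptyInputError(
            f"no frames left after skip={skip_frames}, stride={stride}")
    if len(frames) < 2:
        raise EmptyInputError("fewer than two frames after skip/stride")
    table = _atom_table_from_universe(u).iloc[keep].reset_index(drop=True)
    table.index.name = "atom_id"
    return Trajectory(np.stack(frames), table, np.asarray(times),
                      source=str(topology_path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a multi-model PDB (one MODEL per frame)."""
    import MDAnalysis as mda

    atoms = traj.atoms
    reskeys = list(dict.fromkeys(
        zip(atoms["chain_id"], atoms["residue_seq"], atoms["residue_name"])))
    res_index = {k: i for i, k in enumerate(reskeys)}
    atom_resindex = [res_index[k] for k in
                     zip(atoms["chain_id"], atoms["residue_seq"],
                         atoms["residue_name"])]
    u = mda.Universe.empty(n_atoms=traj.n_atoms, n_residues=len(reskeys),
                           atom_resindex=atom_resindex,
                           n_segments=1, trajectory=True)
    u.add_TopologyAttr("names", atoms["atom_name"].tolist())
    u.add_TopologyAttr("elements", atoms["element"].tolist())
    u.add_TopologyAttr("resids", [k[1] for k in reskeys])
    u.add_TopologyAttr("resnames", [k[2] for k in reskeys])
    u.add_TopologyAttr("chainIDs", atoms["chain_id"].tolist())
    u.add_TopologyAttr("occupancies", np.ones(traj.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(traj.n_atoms))
    u.load_new(traj.coords, format="memory", order="fac")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def select_atoms(traj: Trajectory, sel: AtomSelection) -> Trajectory:
    """Sub-trajectory restricted to the selected atoms (order preserved)."""
    ids = sel.resolve(traj.atoms)
    table = traj.atoms.iloc[ids].reset_index(drop=True)
    table.index.name = "atom_id"
    return Trajectory(traj.coords[:, ids, :], table,
                      traj.frame_times,
                      source=f"{traj.source} [{sel.describe()}]")


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and centroids so that (x - cm) @ R.T + cr ≈ ref."""
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - cr, mobile - cm)
    return rot.as_matrix(), cm, cr


def superpose(traj: Trajectory, reference_frame: int = 0,
              fit_selection: Optional[AtomSelection] = None) -> Trajectory:
    """Rigid-body least-squares fit of every frame onto a reference frame.

    The rotation + translation (no scaling) is determined over
    ``fit_selection`` (default: heavy atoms) and applied to all atoms.
    """
    if fit_selection is None:
        fit_selection = AtomSelection(heavy_only=True)
    ids = fit_selection.resolve(traj.atoms)
    ref = traj.coords[reference_frame, ids, :]
    if ids.size < 3:
        raise DegenerateFitError("need at least 3 atoms for a rigid fit")
    centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DegenerateFitError("fit atoms are collinear")
    out = np.empty_like(traj.coords)
    for t in range(traj.n_frames):
        R, cm, cr = _kabsch(traj.coords[t, ids, :], ref)
        out[t] = (traj.coords[t] - cm) @ R.T + cr
    return Trajectory(out, traj.atoms.copy(), traj.frame_times,
                      source=f"{traj.source} [superposed on frame {reference_frame}]")
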