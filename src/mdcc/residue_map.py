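"""Residue-level correlation maps.

The residue map aggregates atom-pair results to symmetric residue x residue
matrices of the maximum mDCC and maximum DCC, recording for each cell the
maximising atom/mode pair and the Euclidean distance between the two mode
centers (the quantity later used as the network's contact criterion).
Focusing on the maximum emphasises highly positively correlated contacts
(typically side-chain pairs) without averaging them away.

A representative-atom variant restricts each residue to one backbone atom
(CA for amino acids, C5' for nucleotides), mirroring the classical
backbone-only correlation analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .correlation import all_pairs
from .modes import ModeModel

logger = logging.getLogger(__name__)

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "MSE",
}
NUCLEOTIDES = {
    "A", "C", "G", "T", "U", "DA", "DC", "DG", "DT", "DU",
    "ADE", "CYT", "GUA", "THY", "URA", "RA", "RC", "RG", "RU",
}


@dataclass
class ResidueCorrelationMap:
    """Symmetric residue-level max-mDCC / max-DCC matrices with provenance.

    ``residues`` lists ``chain:resid`` labels in file order; matrices use
    NaN for missing cells; the diagonal is 1.0 by convention.  ``argmax``
    maps an unordered residue-index pair ``(a, b)`` (a < b) to the
    maximising atom/mode pair and the distance between the two mode
    centers.
    """

    residues: list[str]
    mdcc: np.ndarray
    dcc: np.ndarray
    argmax: dict = field(default_factory=dict)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def index_of(self, label: str) -> int:
        return self.residues.index(label)

    def value(self, a: str, b: str, which: str = "mdcc") -> float:
        m = self.mdcc if which == "mdcc" else self.dcc
        return float(m[self.index_of(a), self.index_of(b)])


def _residue_index(atoms: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    labels = [f"{c}:{r}" for c, r in
              zip(atoms["chain_id"], atoms["residue_seq"])]
    order = list(dict.fromkeys(labels))
    pos = {lab: i for i, lab in enumerate(order)}
    return order, np.array([pos[lab] for lab in labels])


def residue_max_maps(pair_table: pd.DataFrame, atoms: pd.DataFrame,
                     models: Sequence[ModeModel]) -> ResidueCorrelationMap:
    """Max-mDCC and max-DCC residue maps from an atom-pair table."""
    residues, atom2res = _residue_index(atoms)
    R = len(residues)
    mdcc = np.full((R, R), np.nan)
    dcc = np.full((R, R), np.nan)
    np.fill_diagonal(mdcc, 1.0)
    np.fill_diagonal(dcc, 1.0)
    argmax: dict = {}
    by_atom = {m.atom_id: m for m in models}

    df = pair_table.copy()
    df["res_a"] = atom2res[df["atom_i"].to_numpy()]
    df["res_b"] = atom2res[df["atom_j"].to_numpy()]
    swap = df["res_a"] > df["res_b"]
    df.loc[swap, ["res_a", "res_b"]] = df.loc[swap, ["res_b", "res_a"]].to_numpy()

    for (a, b), grp in df.groupby(["res_a", "res_b"]):
        if a == b:
            continue
        pair_dcc = grp.drop_duplicates(["atom_i", "atom_j"])["dcc"]
        if pair_dcc.notna().any():
            dcc[a, b] = dcc[b, a] = float(pair_dcc.max())
        live = grp[~grp["omitted"] & grp["mdcc"].notna()]
        if live.empty:
            continue
        best = live.loc[live["mdcc"].idxmax()]
        mdcc[a, b] = mdcc[b, a] = float(best["mdcc"])
        mi = by_atom[int(best["atom_i"])]
        mj = by_atom[int(best["atom_j"])]
        ck = mi.modes[int(best["k"])].center
        cl = mj.modes[int(best["l"])].center
        argmax[(int(a), int(b))] = {
            "atom_i": int(best["atom_i"]), "atom_j": int(best["atom_j"]),
            "mode_k": int(best["k"]), "mode_l": int(best["l"]),
            "center_distance": float(np.linalg.norm(ck - cl)),
        }
    return ResidueCorrelationMap(residues, mdcc, dcc, argmax)


def representative_atoms(atoms: pd.DataFrame,
                         mapping: Optional[dict] = None) -> list[int]:
    """One representative atom id per residue (CA / C5'; first heavy fallback)."""
    mapping = mapping or {}
    ids = []
    for label, grp in atoms.groupby(
            [f"{c}:{r}" for c, r in zip(atoms["chain_id"],
                                        atoms["residue_seq"])], sort=False):
        resname = str(grp["residue_name"].iloc[0]).strip().upper()
        want = mapping.get(label)
        if want is None:
            if resname in AMINO_ACIDS:
                want = "CA"
            elif resname in NUCLEOTIDES:
                want = "C5'"
        hit = grp[grp["atom_name"] == want] if want else grp.iloc[0:0]
        if hit.empty:
            heavy = grp[grp["is_heavy"]]
            fallback = heavy.index[0] if not heavy.empty else grp.index[0]
            if want:
                logger.info("residue %s has no %s atom; using %s", label,
                            want, atoms.loc[fallback, "atom_name"])
            ids.append(int(fallback))
        else:
            ids.append(int(hit.index[0]))
    return ids


def representative_atom_map(traj, models: Sequence[ModeModel],
                            mapping: Optional[dict] = None, *,
                            min_mass: Optional[float] = None
                            ) -> ResidueCorrelationMap:
    """Residue map computed only from one representative atom per residue."""
    rep = representative_atoms(traj.atoms, mapping)
    table = all_pairs(traj, models, atom_subset=rep, min_mass=min_mass)
    return residue_max_maps(table, traj.atoms, models)


def export_matrix(rmap: ResidueCorrelationMap, path,
                  which: str = "mdcc") -> None:
    """Labelled symmetric matrix as TSV plus a JSON metadata sidecar.

    ``which`` selects ``mdcc``, ``dcc`` or their cellwise ``difference``
    (mdcc - dcc).  The sidecar (``<path>.meta.json``) carries the argmax
    provenance table.
    """
    if which == "mdcc":
        mat = rmap.mdcc
    elif which == "dcc":
        mat = rmap.dcc
    elif which == "difference":
        mat = rmap.mdcc - rmap.dcc
    else:
        raise ValueError(f"unknown matrix kind: {which!r}")
    frame = pd.DataFrame(mat, index=rmap.residues, columns=rmap.residues)
    frame.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")
    meta = {
        "which": which,
        "residues": rmap.residues,
        "argmax": [{"res_a": rmap.residues[a], "res_b": rmap.residues[b], **v}
                   for (a, b), v in sorted(rmap.argmax.items())],
    }
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_matrix(path) -> pd.DataFrame:
    """Parse back a matrix written by :func:`export_matrix`."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
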