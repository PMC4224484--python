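"""Conventional DCC and the multi-modal mode-pair correlation (mDCC).

DCC between atoms i and j is the normalised covariance of their
displacement vectors from the time-mean position::

    DCC(i,j) = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>)

mDCC generalises this to a pair of Gaussian modes (k of atom i, l of atom
j).  Deviations are measured from the mode centers and every frame is
weighted by the joint mode occupancy gamma_t = p_k(r_i(t)) * p_l(r_j(t)),
so the statistic is the cosine of the angle between the 3T-vectors
sqrt(gamma_t) * (r_i(t) - mu_k) and sqrt(gamma_t) * (r_j(t) - mu_l).  Mode
pairs whose co-occurrence mass (sum of gamma_t, the effective number of
co-occupied frames) falls below a floor are flagged as omitted: a cosine
over a handful of frames is noise, not correlation.

Undefined correlations (zero variance, zero co-occurrence) are reported as
missing values (NaN + flag), never coerced to 0 — zero is a meaningful
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .modes import ModeModel

#: minimum effective frames for a mode pair to be kept
MIN_MASS_FRAMES = 10
#: minimum co-occupied fraction of the trajectory for a mode pair
MIN_MASS_FRACTION = 0.05

PAIR_COLUMNS = ["atom_i", "atom_j", "dcc", "k", "l", "mdcc", "mass", "omitted"]


def mass_threshold(n_frames: int, min_frames: int = MIN_MASS_FRAMES,
                   min_fraction: float = MIN_MASS_FRACTION) -> float:
    """Co-occurrence mass below which a mode pair is omitted."""
    return max(float(min_frames), min_fraction * n_frames)


@dataclass
class ModePairCorrelation:
    """mDCC of one mode pair, with its co-occurrence mass."""

    atom_i: int
    atom_j: int
    mode_k: int
    mode_l: int
    mdcc: float            # NaN when omitted
    cooccurrence_mass: float
    omitted: bool


def dcc_atom_pair(traj, i: int, j: int) -> float:
    """Conventional DCC between two atoms; NaN for zero-variance atoms."""
    if i == j:
        return 1.0
    ri = traj.atom_coords(i)
    rj = traj.atom_coords(j)
    di = ri - ri.mean(axis=0)
    dj = rj - rj.mean(axis=0)
    vi = (di * di).sum(axis=1).mean()
    vj = (dj * dj).sum(axis=1).mean()
    if vi <= 0.0 or vj <= 0.0:
        return float("nan")
    return float((di * dj).sum(axis=1).mean() / np.sqrt(vi * vj))


def _weighted_cosine(gamma: np.ndarray, di: np.ndarray,
                     dj: np.ndarray) -> tuple[float, float]:
    mass = float(gamma.sum())
    ni = float((gamma * (di * di).sum(axis=1)).sum())
    nj = float((gamma * (dj * dj).sum(axis=1)).sum())
    if ni <= 0.0 or nj <= 0.0:
        return float("nan"), mass
    num = float((gamma * (di * dj).sum(axis=1)).sum())
    return num / np.sqrt(ni * nj), mass


def mdcc_mode_pair(traj, model_i: ModeModel, model_j: ModeModel,
                   k: int, l: int, *,
                   min_mass: Optional[float] = None,
                   resp_i: Optional[np.ndarray] = None,
                   resp_j: Optional[np.ndarray] = None) -> ModePairCorrelation:
    """mDCC of mode pair (k, l) between two atoms.

    ``resp_i``/``resp_j`` allow passing precomputed responsibility matrices
    when looping over many mode pairs.
    """
    ri = traj.atom_coords(model_i.atom_id)
    rj = traj.atom_coords(model_j.atom_id)
    if resp_i is None:
        resp_i = model_i.responsibility_matrix(ri)
    if resp_j is None:
        resp_j = model_j.responsibility_matrix(rj)
    if min_mass is None:
        min_mass = mass_threshold(traj.n_frames)
    gamma = resp_i[:, k] * resp_j[:, l]
    di = ri - model_i.modes[k].center
    dj = rj - model_j.modes[l].center
    value, mass = _weighted_cosine(gamma, di, dj)
    omitted = mass < min_mass or not np.isfinite(value)
    return ModePairCorrelation(model_i.atom_id, model_j.atom_id, k, l,
                               float("nan") if omitted else value,
                               mass, omitted)


def cooccurrence_mass(traj, model_i: ModeModel, model_j: ModeModel,
                      k: int, l: int) -> float:
    """Effective number of frames where modes k and l are co-occupied."""
    resp_i = model_i.responsibility_matrix(traj.atom_coords(model_i.atom_id))
    resp_j = model_j.responsibility_matrix(traj.atom_coords(model_j.atom_id))
    return float((resp_i[:, k] * resp_j[:, l]).sum())


def all_pairs(traj, models: Sequence[ModeModel],
              atom_subset: Optional[Sequence[int]] = None, *,
              min_mass: Optional[float] = None) -> pd.DataFrame:
    """DCC plus every K x L mode-pair mDCC for each atom pair.

    Returns a tidy table with one row per (atom_i, atom_j, k, l); the
    pair-level DCC is repeated on each of the pair's rows.  Only i < j is
    stored; mdcc(i,j;k,l) = mdcc(j,i;l,k) by symmetry.
    """
    if atom_subset is None:
        atom_subset = range(traj.n_atoms)
    atom_subset = sorted(atom_subset)
    by_atom = {m.atom_id: m for m in models}
    missing = [a for a in atom_subset if a not in by_atom]
    if missing:
        raise ValueError(f"no mode model for atoms {missing}")
    if min_mass is None:
        min_mass = mass_threshold(traj.n_frames)
    resp = {a: by_atom[a].responsibility_matrix(traj.atom_coords(a))
            for a in atom_subset}
    rows = []
    for ai_idx, i in enumerate(atom_subset):
        for j in atom_subset[ai_idx + 1:]:
            dcc = dcc_atom_pair(traj, i, j)
            mi, mj = by_atom[i], by_atom[j]
            for k in range(mi.n_modes):
                for l in range(mj.n_modes):
                    mp = mdcc_mode_pair(traj, mi, mj, k, l,
                                        min_mass=min_mass,
                                        resp_i=resp[i], resp_j=resp[j])
                    rows.append((i, j, dcc, k, l, mp.mdcc,
                                 mp.cooccurrence_mass, mp.omitted))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def max_mdcc(pair_table: pd.DataFrame, i: int, j: int) -> float:
    """Maximum mDCC over non-omitted mode pairs of one atom pair (NaN if none)."""
    if i > j:
        i, j = j, i
    sub = pair_table[(pair_table["atom_i"] == i) & (pair_table["atom_j"] == j)
                     & ~pair_table["omitted"]]
    if sub.empty:
        return float("nan")
    return float(sub["mdcc"].max())


def surviving_modes(pair_table: pd.DataFrame, atom_id: int) -> set[int]:
    """Modes of an atom that participate in at least one non-omitted pair."""
    live = pair_table[~pair_table["omitted"]]
    out: set[int] = set()
    out.update(live.loc[live["atom_i"] == atom_id, "k"].astype(int))
    out.update(live.loc[live["atom_j"] == atom_id, "l"].astype(int))
    return out


def write_pair_table(pair_table: pd.DataFrame, path) -> None:
    """Tab-separated atom-pair table (atom_i, atom_j, dcc, k, l, mdcc, mass, omitted)."""
    pair_table.to_csv(path, sep="\t", index=False, na_rep="NA",
                      float_format="%.12g")


def read_pair_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["omitted"] = df["omitted"].astype(bool)
    return df
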