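"""Cα flexibility metrics: RMSD, RMSF, and the three-metric profile.

RMSD and RMSF are computed on Cα atoms only, after least-squares rigid-body
superposition (Kabsch).  The per-residue profile juxtaposes three metrics of
different physical origin — crystallographic B-factor, MD mobility (RMSF) and
local conformational entropy (Neq) — and classifies residues by rank.  The
interesting discordant class is high-RMSF/low-Neq: a locally rigid stretch
carried inside a larger deformable loop, which moves a lot without changing
its own local conformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import StructureModel, Trajectory

logger = logging.getLogger(__name__)

CATEGORY_RIGID = "rigid"
CATEGORY_MOBILE = "mobile"  # high RMSF, high Neq
CATEGORY_DEFORMABLE = "deformable"  # low RMSF, high Neq
CATEGORY_RIGID_CORE = "rigid-core-in-deformable-loop"  # high RMSF, low Neq


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation matrix superposing centred mobile onto centred
    reference (least squares, proper rotation via SVD determinant fix)."""
    H = mobile.T @ reference
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares superpose a point set (n, 3) onto a reference (n, 3)."""
    if mobile.shape[0] < 3:
        raise ValueError("superposition requires at least 3 atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    R = kabsch_rotation(mobile - mc, reference - rc)
    return (mobile - mc) @ R.T + rc


def rmsd_series(traj: Trajectory, reference: StructureModel | np.ndarray | None = None,
                exclude_residues=None) -> np.ndarray:
    """Per-frame Cα RMSD (Å) after per-frame superposition onto a reference.

    ``reference`` defaults to the first frame; it may be a StructureModel or
    a raw (n, 3) Cα array.  ``exclude_residues`` (author numbers) are left
    out of both the fit and the RMSD, e.g. frayed terminal loops.
    """
    ca = traj.ca_coords()
    if reference is None:
        ref = ca[0]
    elif isinstance(reference, StructureModel):
        ref = reference.coords[:, 1, :]
    else:
        ref = np.asarray(reference, dtype=float)
    if ref.shape != ca.shape[1:]:
        raise ValueError("reference Cα set does not match trajectory")
    mask = np.ones(ca.shape[1], dtype=bool)
    if exclude_residues is not None:
        mask &= ~np.isin(traj.topology.residue_numbers, np.asarray(exclude_residues))
    if mask.sum() < 3:
        raise ValueError("fewer than 3 Cα atoms; superposition underdetermined")
    out = np.empty(traj.n_frames)
    ref_m = ref[mask]
    for f in range(traj.n_frames):
        fitted = superpose(ca[f, mask], ref_m)
        out[f] = np.sqrt(np.mean(np.sum((fitted - ref_m) ** 2, axis=1)))
    return out


def rmsf_profile(traj: Trajectory, discard_ps: float = 0.0) -> np.ndarray:
    """Per-residue Cα RMSF (Å) after discarding equilibration frames.

    Frames with time <= discard_ps are dropped; remaining frames are
    superposed on the first retained frame, the mean structure is formed, and
    the fit is iterated once onto that mean.  RMSF_i is the root mean square
    displacement of Cα_i around its mean position.
    """
    if discard_ps > 0:
        traj = traj.discard_before(discard_ps)
    ca = traj.ca_coords()
    fitted = np.stack([superpose(ca[f], ca[0]) for f in range(ca.shape[0])])
    mean = fitted.mean(axis=0)
    fitted = np.stack([superpose(fitted[f], mean) for f in range(ca.shape[0])])
    mean = fitted.mean(axis=0)
    disp2 = np.sum((fitted - mean) ** 2, axis=2)
    return np.sqrt(disp2.mean(axis=0))


def average_rmsf(runs) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean and standard deviation of per-run RMSF profiles."""
    runs = list(runs)
    if not runs:
        raise ValueError("at least one RMSF profile required")
    arr = np.asarray(runs, dtype=float)
    if arr.ndim != 2:
        raise ValueError("profiles must share residue sets")
    return arr.mean(axis=0), arr.std(axis=0, ddof=0)


@dataclass
class FlexibilityProfile:
    """Per-residue three-metric flexibility table."""

    residue_numbers: np.ndarray
    neq: np.ndarray
    rmsf: np.ndarray
    bfactor: np.ndarray | None = None
    region: np.ndarray | None = None
    category: np.ndarray | None = None

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        n = len(self.residue_numbers)
        self.neq = np.asarray(self.neq, dtype=float)
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if self.neq.shape != (n,) or self.rmsf.shape != (n,):
            raise ValueError("neq and rmsf must be per-residue")
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF must be non-negative")
        ok = np.isnan(self.neq) | ((self.neq >= 1.0 - 1e-9) & (self.neq <= 16.0 + 1e-9))
        if not np.all(ok):
            raise ValueError("Neq must lie in [1, 16] where defined")
        if self.bfactor is not None:
            self.bfactor = np.asarray(self.bfactor, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "residue": self.residue_numbers,
            "region": self.region if self.region is not None else "",
            "neq": self.neq,
            "rmsf_A": self.rmsf,
            "bfactor_A2": self.bfactor if self.bfactor is not None else np.nan,
            "category": self.category if self.category is not None else "",
        })
        return df


def classify(profile: FlexibilityProfile, rmsf_quantile: float = 0.80,
             neq_quantile: float = 0.80) -> np.ndarray:
    """Label residues by the 2×2 of (RMSF high/low) × (Neq high/low).

    "High" means above the given quantile of the defined values.  The
    discordant high-RMSF/low-Neq cell is labelled
    'rigid-core-in-deformable-loop'.  Classification depends only on ranks,
    so it is invariant under monotone rescaling of either metric.  A constant
    metric puts every residue in its low class (with a warning).
    """
    rmsf, neq_vals = profile.rmsf, profile.neq
    defined = np.isfinite(rmsf) & np.isfinite(neq_vals)
    labels = np.full(len(rmsf), "", dtype=object)
    if not np.any(defined):
        return labels.astype("<U40")
    rmsf_cut = np.quantile(rmsf[defined], rmsf_quantile)
    neq_cut = np.quantile(neq_vals[defined], neq_quantile)
    rmsf_high = rmsf > rmsf_cut
    neq_high = neq_vals > neq_cut
    for name, vals, cut in (("RMSF", rmsf, rmsf_cut), ("Neq", neq_vals, neq_cut)):
        if np.ptp(vals[defined]) == 0:
            logger.warning("%s is constant; no residue classified high", name)
    labels[defined & ~rmsf_high & ~neq_high] = CATEGORY_RIGID
    labels[defined & ~rmsf_high & neq_high] = CATEGORY_DEFORMABLE
    labels[defined & rmsf_high & neq_high] = CATEGORY_MOBILE
    labels[defined & rmsf_high & ~neq_high] = CATEGORY_RIGID_CORE
    out = labels.astype("<U40")
    profile.category = out
    return out
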