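"""Protein Block alphabet and per-frame assignment.

Protein Blocks (PBs) are a structural alphabet of 16 local-backbone prototypes,
labelled ``a`` … ``p``.  Each prototype is defined by 8 reference dihedral
angles spanning a five-residue window centred on the assigned residue::

    psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1), psi(i+1), phi(i+2)

A residue is assigned the letter of the prototype with the smallest RMSDA
(root mean square deviation of angles, computed on the circle) to its observed
window.  Residues whose window is incomplete — the two first and two last
positions of a chain, or any position next to an undefined torsion — receive
the uppercase placeholder ``Z``.

PBs ``m`` and ``d`` approximate the core of alpha-helices and central
beta-strands respectively; the remaining letters cover caps and coils.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:
    from .io import Trajectory

PB_LETTERS = "abcdefghijklmnop"
UNASSIGNED = "Z"

#: column layout of a dihedral window, relative to the central residue i
WINDOW_LAYOUT = (
    ("psi", -2), ("phi", -1), ("psi", -1), ("phi", 0),
    ("psi", 0), ("phi", 1), ("psi", 1), ("phi", 2),
)


def wrap_angle(angle):
    """Wrap angles (degrees) into the canonical interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -(((-a + 180.0) % 360.0) - 180.0)
    return wrapped


def angular_difference(a, b):
    """Signed circular difference a - b in degrees, in [-180, 180]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass(frozen=True)
class PBAlphabet:
    """The 16 Protein Block prototypes.

    Attributes
    ----------
    letters : str
        The 16 lowercase letters, alphabetically ordered.
    reference_angles : ndarray, shape (16, 8)
        Reference dihedrals (degrees) per prototype, in ``WINDOW_LAYOUT``
        order.
    """

    letters: str = PB_LETTERS
    reference_angles: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.reference_angles is None:
            object.__setattr__(self, "reference_angles", _load_reference_table())
        angles = np.asarray(self.reference_angles, dtype=float)
        if angles.shape != (len(self.letters), 8):
            raise ValueError(
                f"expected {(len(self.letters), 8)} reference angles, got {angles.shape}"
            )
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("prototype letters must be distinct")
        if not np.all((angles > -180.0) & (angles <= 180.0)):
            raise ValueError("reference angles must lie in (-180, 180]")
        if len(np.unique(angles, axis=0)) != len(self.letters):
            raise ValueError("prototypes must be pairwise distinct")
        object.__setattr__(self, "reference_angles", angles)

    @property
    def central_angles(self) -> np.ndarray:
        """(16, 2) array of each prototype's central (phi_i, psi_i)."""
        return self.reference_angles[:, [3, 4]]

    def index(self, letter: str) -> int:
        return self.letters.index(letter)


def _load_reference_table() -> np.ndarray:
    path = resources.files("pbflex.data").joinpath("pb_prototypes.tsv")
    rows = []
    with path.open() as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("pb\t"):
                continue
            fields = line.split("\t")
            rows.append((fields[0], [float(x) for x in fields[1:]]))
    rows.sort(key=lambda r: r[0])
    letters = "".join(r[0] for r in rows)
    if letters != PB_LETTERS:
        raise RuntimeError(f"corrupt prototype table: letters {letters!r}")
    return np.array([r[1] for r in rows], dtype=float)


_DEFAULT_ALPHABET: PBAlphabet | None = None


def default_alphabet() -> PBAlphabet:
    """The packaged reference alphabet (cached)."""
    global _DEFAULT_ALPHABET
    if _DEFAULT_ALPHABET is None:
        _DEFAULT_ALPHABET = PBAlphabet()
    return _DEFAULT_ALPHABET


def dihedral(p0, p1, p2, p3, degrees: bool = True):
    """Torsion angle of four points (IUPAC sign convention).

    Accepts arrays broadcastable to (..., 3); returns angles in (-180, 180]
    (degrees) or (-pi, pi] (radians).  Near-collinear triplets yield NaN.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1, axis=-1)
    x = np.sum(n1 * n2, axis=-1) * b1n
    y = np.sum(np.cross(n1, n2) * b1, axis=-1)
    angle = np.arctan2(y, x)
    # degenerate (collinear) geometry: zero-length normal
    bad = (np.linalg.norm(n1, axis=-1) < 1e-10) | (np.linalg.norm(n2, axis=-1) < 1e-10)
    angle = np.where(bad, np.nan, angle)
    if degrees:
        angle = np.degrees(angle)
        # map -180 to +180 so the canonical interval is (-180, 180]
        angle = np.where(np.isclose(angle, -180.0), 180.0, angle)
    return angle


@dataclass
class DihedralSeries:
    """Backbone phi/psi torsions per frame and residue.

    ``phi[f, i]`` is undefined (NaN) for the first residue, ``psi[f, i]`` for
    the last; both arrays have shape (n_frames, n_residues) in degrees.
    """

    phi: np.ndarray
    psi: np.ndarray
    residue_numbers: np.ndarray

    def __post_init__(self):
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi must share shape")
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]


def compute_dihedrals(traj: "Trajectory") -> DihedralSeries:
    """Compute phi/psi for every frame of a backbone trajectory.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    Residues with missing backbone atoms (NaN coordinates) propagate NaN into
    every torsion they participate in.
    """
    xyz = traj.coords  # (F, n, 3 atoms [N, CA, C], 3)
    n_res = xyz.shape[1]
    nan_col = np.full((xyz.shape[0],), np.nan)
    phi = np.empty((xyz.shape[0], n_res))
    psi = np.empty_like(phi)
    N, CA, C = xyz[:, :, 0], xyz[:, :, 1], xyz[:, :, 2]
    phi[:, 0] = nan_col
    if n_res > 1:
        phi[:, 1:] = dihedral(C[:, :-1], N[:, 1:], CA[:, 1:], C[:, 1:])
        psi[:, :-1] = dihedral(N[:, :-1], CA[:, :-1], C[:, :-1], N[:, 1:])
    psi[:, -1] = nan_col
    return DihedralSeries(phi=phi, psi=psi, residue_numbers=traj.topology.residue_numbers)


def rmsda(window, prototype) -> float:
    """Root mean square deviation of angles between two 8-angle windows.

    Differences are taken on the circle (wrapped to [-180, 180]); both inputs
    must be fully defined.
    """
    window = np.asarray(window, dtype=float)
    prototype = np.asarray(prototype, dtype=float)
    if window.shape[-1] != prototype.shape[-1]:
        raise ValueError("window and prototype must have equal length")
    if np.any(np.isnan(window)) or np.any(np.isnan(prototype)):
        raise ValueError("rmsda requires fully defined angle windows")
    diff = angular_difference(window, prototype)
    return np.sqrt(np.mean(diff * diff, axis=-1))


def dihedral_windows(series: DihedralSeries) -> np.ndarray:
    """Stack the 8-angle assignment window for every frame and residue.

    Returns shape (n_frames, n_residues, 8) with NaN wherever any window
    member is undefined (chain termini contribute NaN automatically).
    """
    F, n = series.phi.shape
    win = np.full((F, n, 8), np.nan)
    if n < 5:
        return win
    sl = slice(2, n - 2)
    cols = {"phi": series.phi, "psi": series.psi}
    for j, (kind, offset) in enumerate(WINDOW_LAYOUT):
        arr = cols[kind]
        win[:, sl, j] = arr[:, 2 + offset : n - 2 + offset]
    return win


def assign_pb(series: DihedralSeries, alphabet: PBAlphabet | None = None) -> np.ndarray:
    """Assign a PB letter to every residue of every frame.

    Returns an (n_frames, n_residues) array of single characters over
    {a…p, Z}.  The letter is the argmin-RMSDA prototype; exact ties break to
    the alphabetically lowest letter.  Positions without a fully defined
    window are 'Z'.
    """
    if alphabet is None:
        alphabet = default_alphabet()
    win = dihedral_windows(series)  # (F, n, 8)
    defined = ~np.any(np.isnan(win), axis=-1)
    filled = np.where(np.isnan(win), 0.0, win)  # masked out below
    diff = angular_difference(filled[..., None, :], alphabet.reference_angles)  # (F, n, 16, 8)
    dist = np.sqrt(np.mean(diff * diff, axis=-1))
    # np.argmin takes the first minimum -> alphabetical tie-break for free
    best = np.argmin(dist, axis=-1)
    letters = np.array(list(alphabet.letters))
    out = np.where(defined, letters[best], UNASSIGNED)
    return out.astype("<U1")
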