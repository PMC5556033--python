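"""Synthetic ensembles with planted ground truth.

Every pipeline stage can be verified without running molecular dynamics:

* per-position categorical PB distributions with a controlled equivalent
  number of states (``distribution_for_neq`` inverts the Neq formula for a
  two-level probability family);
* categorical PB ensembles sampled from planted rows, split into independent
  runs mirroring the study design (11 runs per system, 5 of 50 ns and 6 of
  100 ns at a 100 ps save stride, first 5 ns treated as equilibration);
* 3D backbone trajectories built from planted PB strings by sequential
  internal-coordinate (NeRF) placement with ideal bond geometry, so that
  dihedral computation and PB assignment can be closed-loop tested;
* noisy Cartesian trajectories with known per-residue RMSF (σ·√3 for
  isotropic per-axis Gaussian noise of width σ);
* wild-type/variant system pairs with planted repertoire edits at chosen
  positions, optionally leaving the nominal mutation site untouched to
  emulate a distal (allosteric) effect.

Frames are i.i.d. draws — a deliberate simplification of MD autocorrelation
that is adequate for testing estimators of per-position distributions.
All generators are deterministic functions of (scenario, seed, system, run).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .alphabet import (
    PB_LETTERS,
    UNASSIGNED,
    PBAlphabet,
    assign_pb,
    compute_dihedrals,
    default_alphabet,
    wrap_angle,
)
from .io import StructureModel, Trajectory
from .statistics import N_PB, PBEnsemble, neq

# ideal backbone geometry: only phi/psi vary, which suffices because PB
# assignment reads only phi/psi
BOND_N_CA = 1.458  # Å
BOND_CA_C = 1.525  # Å
BOND_C_N = 1.329  # Å
ANGLE_N_CA_C = 111.2  # degrees
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

#: the study's simulation plan: 11 independent runs per system,
#: 5 × 50 ns + 6 × 100 ns = 850 ns, saved every 100 ps
DEFAULT_RUN_PLAN_NS = (50, 50, 50, 50, 50, 100, 100, 100, 100, 100, 100)
DEFAULT_STRIDE_PS = 100.0
DEFAULT_DISCARD_NS = 5.0


def _child_rng(master_seed: int, *labels) -> np.random.Generator:
    """Deterministic per-(system, run, purpose) RNG below 2**31."""
    key = [int(master_seed) & 0x7FFFFFFF]
    key += [zlib.crc32(str(lab).encode()) & 0x7FFFFFFF for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(key))


def distribution_for_neq(target: float, support: int = 4,
                         seed: int | None = None,
                         alphabet_size: int = N_PB) -> np.ndarray:
    """A 16-vector whose Neq equals ``target`` to within 1e-6.

    Uses a two-level family: one dominant PB with probability p, the other
    ``support - 1`` members sharing (1-p) equally; p is solved by bisection.
    Which PBs form the support is drawn from ``seed`` (first 'support'
    letters if None).

    ``1 <= target <= support <= 16`` is required.
    """
    m = int(support)
    if not 1 <= target <= m <= alphabet_size:
        raise ValueError(f"need 1 <= target ({target}) <= support ({m}) <= {alphabet_size}")
    if seed is None:
        members = np.arange(m)
    else:
        members = _child_rng(seed, "support").choice(alphabet_size, size=m, replace=False)

    def family(p: float) -> np.ndarray:
        row = np.zeros(alphabet_size)
        row[members[0]] = p
        if m > 1:
            row[members[1:]] = (1.0 - p) / (m - 1)
        return row

    if m == 1 or target <= 1.0:
        return family(1.0)
    if target == m:  # entropy maximum: uniform, exactly
        return family(1.0 / m)
    lo, hi = 1.0 / m, 1.0 - 1e-15  # Neq: m at lo (uniform) … 1 at hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if neq(family(mid)) > target:
            lo = mid
        else:
            hi = mid
        if abs(neq(family(0.5 * (lo + hi))) - target) < 1e-9:
            break
    row = family(0.5 * (lo + hi))
    assert abs(neq(row) - target) < 1e-6
    return row


@dataclass
class SyntheticScenario:
    """Planted ground truth for one wild-type system and optional variants.

    rows : (n_residues, 16) planted per-position PB distributions (the WT
        truth).  Convenience constructors can build them from target Neq
        values.
    variant_edits : mapping variant label -> {residue number -> 16-vector}
        rows replaced in that variant; all other positions share the WT rows.
    run_plan_ns / stride_ps / discard_ns : the simulation design being
        emulated (defaults mirror the study: 5×50 + 6×100 ns, 100 ps stride,
        5 ns equilibration).
    """

    rows: np.ndarray
    residue_numbers: np.ndarray | None = None
    variant_edits: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)
    run_plan_ns: tuple = DEFAULT_RUN_PLAN_NS
    stride_ps: float = DEFAULT_STRIDE_PS
    discard_ns: float = DEFAULT_DISCARD_NS
    master_seed: int = 0

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != N_PB:
            raise ValueError("rows must be (n_residues, 16)")
        sums = self.rows.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("planted rows must sum to 1")
        if self.residue_numbers is None:
            self.residue_numbers = np.arange(1, len(self.rows) + 1)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        known = set(self.residue_numbers.tolist())
        for label, edits in self.variant_edits.items():
            for resid, row in edits.items():
                if resid not in known:
                    raise ValueError(f"variant {label!r} edits undefined residue {resid}")
                row = np.asarray(row, dtype=float)
                if row.shape != (N_PB,) or not np.isclose(row.sum(), 1.0, atol=1e-9):
                    raise ValueError(f"edit at residue {resid} is not a probability 16-vector")

    @classmethod
    def from_neq_targets(cls, targets, support: int = 4, seed: int = 0, **kwargs):
        """Build planted rows from per-position target Neq values."""
        rows = np.stack([
            distribution_for_neq(t, support=support, seed=seed * 100003 % (2**31) + i)
            for i, t in enumerate(targets)
        ])
        return cls(rows=rows, master_seed=seed, **kwargs)

    def frames_per_run(self) -> list[int]:
        return [int(round(ns * 1000.0 / self.stride_ps)) for ns in self.run_plan_ns]

    def system_rows(self, system: str) -> np.ndarray:
        rows = self.rows.copy()
        for resid, row in self.variant_edits.get(system, {}).items():
            rows[np.flatnonzero(self.residue_numbers == resid)[0]] = np.asarray(row, float)
        return rows


def sample_ensemble(scenario: SyntheticScenario, system: str, run: int,
                    n_frames: int | None = None) -> PBEnsemble:
    """Draw one run: i.i.d. categorical frames from the planted rows.

    Reproducible from (master seed, system, run).  Frame times follow the
    scenario stride starting at one stride.
    """
    rows = scenario.system_rows(system)
    if n_frames is None:
        n_frames = scenario.frames_per_run()[run % len(scenario.run_plan_ns)]
    rng = _child_rng(scenario.master_seed, system, run)
    n = rows.shape[0]
    letters = np.empty((n_frames, n), dtype="<U1")
    alphabet = np.array(list(PB_LETTERS))
    for i in range(n):
        draws = rng.choice(N_PB, size=n_frames, p=rows[i])
        letters[:, i] = alphabet[draws]
    times = scenario.stride_ps * np.arange(1, n_frames + 1)
    return PBEnsemble(system, f"run{run}", letters, scenario.residue_numbers, times)


def sample_system(scenario: SyntheticScenario, system: str,
                  n_frames: int | None = None) -> list[PBEnsemble]:
    """All runs of one system, per the scenario's run plan."""
    return [sample_ensemble(scenario, system, r, n_frames)
            for r in range(len(scenario.run_plan_ns))]


# ---------------------------------------------------------------------------
# internal-coordinate (NeRF) backbone construction

def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d given three predecessors, bond c-d, angle b-c-d and
    torsion a-b-c-d (natural extension of reference frame)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.cos(torsion) * np.sin(angle),
        np.sin(torsion) * np.sin(angle),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Build (n, 3, 3) backbone coordinates from per-residue phi/psi.

    ``phi[0]`` and ``psi[-1]`` are ignored (undefined at the termini); ideal
    bond lengths/angles and a trans peptide (ω = 180°) are used throughout.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(phi)
    if len(psi) != n:
        raise ValueError("phi and psi must have equal length")
    coords = np.empty((n, 3, 3))
    # first residue in a canonical pose
    coords[0, 0] = (0.0, 0.0, 0.0)  # N
    coords[0, 1] = (BOND_N_CA, 0.0, 0.0)  # CA
    ang = np.radians(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        N_prev, CA_prev, C_prev = coords[i - 1]
        N_i = _place_atom(N_prev, CA_prev, C_prev, BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA_i = _place_atom(CA_prev, C_prev, N_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C_i = _place_atom(C_prev, N_i, CA_i, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        coords[i] = (N_i, CA_i, C_i)
    return coords


def synthetic_topology(n_residues: int, start: int = 1,
                       chain: str = "A") -> StructureModel:
    """A featureless topology (alanines, canonical extended pose)."""
    phi = np.full(n_residues, -120.0)
    psi = np.full(n_residues, 130.0)
    coords = build_backbone(phi, psi)
    return StructureModel(
        residue_numbers=np.arange(start, start + n_residues),
        residue_codes=np.full(n_residues, "A"),
        coords=coords,
        chain=chain,
    )


def backbone_from_pb_string(pb_string: str, n_frames: int = 1,
                            noise_sigma_deg: float = 0.0,
                            seed: int = 0,
                            alphabet: PBAlphabet | None = None,
                            start: int = 1) -> Trajectory:
    """Trajectory whose residues adopt the central dihedrals of a PB string.

    Per frame, each residue's (phi, psi) is its planted letter's central
    reference pair plus wrapped Gaussian noise of width ``noise_sigma_deg``;
    the 3D backbone is then built by internal-coordinate placement.  At zero
    noise a self-consistent string (see :func:`plant_pb_string`) is recovered
    exactly by dihedral computation + PB assignment at all non-Z positions.
    """
    if alphabet is None:
        alphabet = default_alphabet()
    for letter in pb_string:
        if letter not in alphabet.letters:
            raise ValueError(f"unknown PB letter {letter!r}")
    idx = np.array([alphabet.index(c) for c in pb_string])
    central = alphabet.central_angles[idx]  # (n, 2): phi, psi
    n = len(pb_string)
    rng = _child_rng(seed, "backbone", pb_string[:8], n_frames)
    frames = np.empty((n_frames, n, 3, 3))
    for f in range(n_frames):
        noise = (rng.normal(0.0, noise_sigma_deg, size=(n, 2))
                 if noise_sigma_deg > 0 else np.zeros((n, 2)))
        phi = wrap_angle(central[:, 0] + noise[:, 0])
        psi = wrap_angle(central[:, 1] + noise[:, 1])
        frames[f] = build_backbone(phi, psi)
    topo = StructureModel(
        residue_numbers=np.arange(start, start + n),
        residue_codes=np.full(n, "A"),
        coords=frames[0],
    )
    times = DEFAULT_STRIDE_PS * np.arange(1, n_frames + 1)
    return Trajectory(coords=frames, times_ps=times, topology=topo)


def realized_string(pb_string: str, alphabet: PBAlphabet | None = None) -> str:
    """The PB string actually recovered from a zero-noise planted backbone."""
    traj = backbone_from_pb_string(pb_string, n_frames=1, alphabet=alphabet)
    letters = assign_pb(compute_dihedrals(traj), alphabet)
    return "".join(letters[0])


def plant_pb_string(n_residues: int, seed: int = 0,
                    alphabet: PBAlphabet | None = None,
                    max_rounds: int = 8) -> str:
    """A random PB string that is exactly recoverable at zero noise.

    A residue's assignment window overlaps its neighbours' dihedrals, so an
    arbitrary letter sequence need not reproduce itself once realized in 3D
    (real PB sequences are locally consistent in the same way).  Starting
    from a uniform random string, the planted string is iterated to the fixed
    point of build-then-assign; seeds are advanced until a fixed point exists.
    """
    if alphabet is None:
        alphabet = default_alphabet()
    for attempt in range(64):
        rng = _child_rng(seed, "plant", attempt)
        s = "".join(rng.choice(list(alphabet.letters), size=n_residues))
        for _ in range(max_rounds):
            realized = realized_string(s, alphabet)
            # termini are Z by construction; keep planted letters there
            merged = "".join(p if r == UNASSIGNED else r for p, r in zip(s, realized))
            if merged == s:
                return s
            s = merged
    raise RuntimeError("no self-consistent PB string found; widen max_rounds")


def noisy_cartesian_trajectory(model: StructureModel, sigma: float | np.ndarray,
                               n_frames: int, seed: int = 0,
                               stride_ps: float = DEFAULT_STRIDE_PS) -> Trajectory:
    """Reference coordinates plus i.i.d. per-axis Gaussian noise per residue.

    ``sigma`` is a scalar or per-residue array (Å); the ground-truth RMSF of
    residue i is σ_i·√3.  All three backbone atoms of a residue share its σ.
    """
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (model.n_residues,))
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    rng = _child_rng(seed, "cartesian", n_frames)
    noise = rng.normal(size=(n_frames, model.n_residues, 3, 3))
    noise *= sigma[None, :, None, None]
    coords = model.coords[None] + noise
    times = stride_ps * np.arange(1, n_frames + 1)
    return Trajectory(coords=coords, times_ps=times, topology=model)


@dataclass
class PlantedPair:
    """A WT/variant pair with its ground truth."""

    scenario: SyntheticScenario
    wt_label: str
    variant_label: str

    @property
    def edited_positions(self) -> list[int]:
        return sorted(self.scenario.variant_edits[self.variant_label])

    def true_delta_pb(self) -> np.ndarray:
        from .statistics import delta_pb

        wt = self.scenario.system_rows(self.wt_label)
        var = self.scenario.system_rows(self.variant_label)
        return delta_pb(wt, var)


def make_wt_variant_pair(scenario: SyntheticScenario, variant: str | None = None,
                         wt_label: str = "WT",
                         n_frames: int | None = None):
    """Sample full run sets for WT and one variant.

    Returns (wt_runs, variant_runs, PlantedPair).  The variant label defaults
    to the scenario's single edit set.  Positions not edited — including a
    nominal mutation site left out of ``variant_edits`` — share the WT rows,
    emulating a purely distal effect.
    """
    if variant is None:
        if len(scenario.variant_edits) != 1:
            raise ValueError("variant label required when scenario has several")
        variant = next(iter(scenario.variant_edits))
    if variant not in scenario.variant_edits:
        raise ValueError(f"unknown variant {variant!r}")
    wt_runs = sample_system(scenario, wt_label, n_frames)
    var_runs = sample_system(scenario, variant, n_frames)
    return wt_runs, var_runs, PlantedPair(scenario, wt_label, variant)
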