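"""Per-position statistics of PB-encoded conformational ensembles.

An ensemble is the PB encoding of one simulation: a frames × residues matrix
of letters over {a…p, Z}.  Pooling frames per position yields a frequency
matrix f_x over the 16 PBs, from which the statistics derive:

* ``Neq = exp(-Σ_x f_x ln f_x)`` — the equivalent number of PBs at a position
  (1 = a single local conformation, 16 = random over the alphabet);
* ``ΔNeq = |Neq_A - Neq_B|`` between two systems;
* ``ΔPB = Σ_x |f_x^A - f_x^B|`` — the L1 distance between PB repertoires
  (0 = identical, 2 = disjoint), which detects repertoire swaps that leave
  the entropy unchanged.

Unassignable positions (Z) are excluded from both numerator and denominator:
the statistics are defined over exactly the 16 PBs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import PB_LETTERS, UNASSIGNED

N_PB = len(PB_LETTERS)
_LETTER_INDEX = {c: i for i, c in enumerate(PB_LETTERS)}


@dataclass
class PBEnsemble:
    """PB letters for every frame and residue of one simulation."""

    system: str
    run: str
    letters: np.ndarray
    residue_numbers: np.ndarray
    times_ps: np.ndarray | None = None

    def __post_init__(self):
        self.letters = np.atleast_2d(np.asarray(self.letters, dtype="<U1"))
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if self.letters.shape[1] != len(self.residue_numbers):
            raise ValueError("one residue number per column required")
        valid = set(PB_LETTERS) | {UNASSIGNED}
        observed = set(np.unique(self.letters))
        if not observed <= valid:
            raise ValueError(f"invalid PB letters: {sorted(observed - valid)}")
        if self.times_ps is not None:
            self.times_ps = np.asarray(self.times_ps, dtype=float)
            if self.times_ps.shape != (self.letters.shape[0],):
                raise ValueError("one time per frame required")

    @property
    def n_frames(self) -> int:
        return self.letters.shape[0]

    @property
    def n_residues(self) -> int:
        return self.letters.shape[1]

    def discard_before(self, time_ps: float) -> "PBEnsemble":
        """Drop equilibration frames with time <= time_ps."""
        if self.times_ps is None:
            raise ValueError("ensemble has no frame times")
        keep = self.times_ps > time_ps
        if not np.any(keep):
            raise ValueError(f"discarding {time_ps} ps leaves no frames")
        return PBEnsemble(self.system, self.run, self.letters[keep],
                          self.residue_numbers, self.times_ps[keep])

    def trim_termini(self, n: int) -> "PBEnsemble":
        """Mask the first and last n residue columns to Z."""
        if n == 0:
            return self
        if 2 * n >= self.n_residues:
            raise ValueError(f"trimming {n} residues per terminus leaves nothing")
        letters = self.letters.copy()
        letters[:, :n] = UNASSIGNED
        letters[:, -n:] = UNASSIGNED
        return PBEnsemble(self.system, self.run, letters,
                          self.residue_numbers, self.times_ps)


@dataclass
class FrequencyMatrix:
    """Per-position probabilities over the 16 PBs.

    probabilities[i] is the distribution at position i (rows sum to 1), or
    all-NaN where no frame yielded an assignable letter; counts[i] is the
    number of contributing (non-Z) frames.
    """

    residue_numbers: np.ndarray
    probabilities: np.ndarray
    counts: np.ndarray
    letters: str = PB_LETTERS

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.residue_numbers)
        if self.probabilities.shape != (n, N_PB):
            raise ValueError("probabilities must be (n_residues, 16)")

    @property
    def defined(self) -> np.ndarray:
        return self.counts > 0

    def row(self, residue_number: int) -> np.ndarray:
        idx = np.flatnonzero(self.residue_numbers == residue_number)
        if idx.size == 0:
            raise KeyError(f"residue {residue_number} not in matrix")
        return self.probabilities[idx[0]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities, columns=list(self.letters))
        df.insert(0, "residue", self.residue_numbers)
        df["frames"] = self.counts
        return df


def frequency_matrix(ensembles) -> FrequencyMatrix:
    """Pool one or more ensembles into per-position PB frequencies.

    Pooling is frame-weighted: every non-Z letter of every frame of every
    ensemble counts once, so longer runs contribute proportionally more.
    All ensembles must share residue numbering.
    """
    if isinstance(ensembles, PBEnsemble):
        ensembles = [ensembles]
    ensembles = list(ensembles)
    if not ensembles:
        raise ValueError("at least one ensemble required")
    resnums = ensembles[0].residue_numbers
    for ens in ensembles[1:]:
        if not np.array_equal(ens.residue_numbers, resnums):
            raise ValueError(
                f"residue numbering mismatch between ensembles "
                f"({ens.system}/{ens.run} differs from {ensembles[0].system}/"
                f"{ensembles[0].run})"
            )
    n = len(resnums)
    counts = np.zeros((n, N_PB), dtype=np.int64)
    for ens in ensembles:
        # map letters to 0..15, Z to 16, and histogram per column
        codes = np.searchsorted(np.array(list(PB_LETTERS)), ens.letters)
        is_z = ens.letters == UNASSIGNED
        for col in range(n):
            c = codes[~is_z[:, col], col]
            counts[col] += np.bincount(c, minlength=N_PB)
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / total[:, None]
    probs[total == 0] = np.nan
    return FrequencyMatrix(resnums, probs, total)


def neq(probabilities) -> np.ndarray | float:
    """Equivalent number of PBs: exp of the Shannon entropy (natural log).

    Accepts a single 16-vector or an (n, 16) matrix of rows summing to 1;
    zero entries contribute 0 (0·ln 0 = 0).  Undefined (NaN) rows give NaN.
    """
    p = np.asarray(probabilities, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    defined = ~np.any(np.isnan(p), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    out = np.exp(-np.sum(plogp, axis=1))
    out = np.where(defined, out, np.nan)
    return float(out[0]) if single else out


def delta_neq(a, b):
    """Absolute Neq difference; NaN propagates."""
    return np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def delta_pb(row_a, row_b) -> np.ndarray | float:
    """L1 distance between PB probability rows: Σ_x |f_x^A − f_x^B| ∈ [0, 2]."""
    a = np.asarray(row_a, dtype=float)
    b = np.asarray(row_b, dtype=float)
    single = a.ndim == 1 and b.ndim == 1
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    out = np.sum(np.abs(a - b), axis=-1)
    return float(out[0]) if single else out


def pb_map(matrix: FrequencyMatrix, span: tuple[int, int] | None = None,
           min_frequency: float = 0.0) -> pd.DataFrame:
    """Ranked per-position PB table for map/logo rendering.

    For each position in ``span`` (closed residue-number interval; whole
    matrix if None) PBs are sorted by descending frequency, ties broken
    alphabetically.  Columns: residue, rank, pb, frequency.
    """
    if span is None:
        mask = np.ones(len(matrix.residue_numbers), dtype=bool)
    else:
        mask = (matrix.residue_numbers >= span[0]) & (matrix.residue_numbers <= span[1])
    rows = []
    letters = np.array(list(matrix.letters))
    for resid, probs, defined in zip(
        matrix.residue_numbers[mask], matrix.probabilities[mask], matrix.defined[mask]
    ):
        if not defined:
            continue
        # stable sort on -frequency keeps alphabetical order among ties
        order = np.argsort(-probs, kind="stable")
        rank = 0
        for idx in order:
            if probs[idx] <= min_frequency and rank > 0:
                break
            rank += 1
            rows.append((int(resid), rank, letters[idx], float(probs[idx])))
    return pd.DataFrame(rows, columns=["residue", "rank", "pb", "frequency"])


# ---------------------------------------------------------------------------
# PB-FASTA: FASTA-shaped records over the alphabet {a…p, Z}, one per frame,
# header `>system|run|frame|time_ps`.

def write_pb_fasta(ensemble: PBEnsemble, path) -> None:
    times = ensemble.times_ps
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            t = times[f] if times is not None else (f + 1) * 100.0
            fh.write(f">{ensemble.system}|{ensemble.run}|{f}|{t:g}\n")
            fh.write("".join(ensemble.letters[f]) + "\n")


def read_pb_fasta(path, residue_numbers=None) -> list[PBEnsemble]:
    """Read PB-FASTA into one PBEnsemble per (system, run) pair."""
    records: dict[tuple[str, str], list[tuple[str, float]]] = {}
    with open(path) as fh:
        header = None
        seq_parts: list[str] = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    _store(records, header, "".join(seq_parts))
                header = line[1:]
                seq_parts = []
            else:
                seq_parts.append(line)
        if header is not None:
            _store(records, header, "".join(seq_parts))
    out = []
    for (system, run), frames in records.items():
        seqs = [list(s) for s, _ in frames]
        times = np.array([t for _, t in frames])
        n = len(seqs[0])
        resnums = (np.arange(1, n + 1) if residue_numbers is None
                   else np.asarray(residue_numbers))
        out.append(PBEnsemble(system, run, np.array(seqs), resnums, times))
    return out


def _store(records, header, seq):
    parts = header.split("|")
    if len(parts) != 4:
        raise ValueError(f"malformed PB-FASTA header: >{header}")
    system, run, _frame, time_ps = parts
    records.setdefault((system, run), []).append((seq, float(time_ps)))
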