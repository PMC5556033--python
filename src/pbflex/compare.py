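"""Wild-type vs variant ensemble comparison.

Runs of each system are pooled frame-weighted into one frequency matrix per
system; per-position ΔNeq and ΔPB then localize where the conformational
repertoire differs.  Hotspot ranking and region summaries support the central
question: are the largest repertoire changes at the mutation site or distal
to it?
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .statistics import (
    FrequencyMatrix,
    PBEnsemble,
    delta_neq,
    delta_pb,
    frequency_matrix,
    neq,
)


@dataclass
class SystemSet:
    """All runs of one simulated system (e.g. WT, or variant L653R)."""

    label: str
    runs: list[PBEnsemble]
    mutation_site: int | None = None

    def __post_init__(self):
        if not self.runs:
            raise ValueError("a system needs at least one run")
        resnums = self.runs[0].residue_numbers
        for run in self.runs[1:]:
            if not np.array_equal(run.residue_numbers, resnums):
                raise ValueError(f"runs of {self.label!r} disagree on numbering")
        if (self.mutation_site is not None
                and self.mutation_site not in resnums.tolist()):
            raise ValueError(
                f"mutation site {self.mutation_site} outside residue range of "
                f"{self.label!r}"
            )

    @property
    def residue_numbers(self) -> np.ndarray:
        return self.runs[0].residue_numbers

    def pooled_matrix(self) -> FrequencyMatrix:
        return frequency_matrix(self.runs)


def preprocess(runs, label: str, discard_ps: float = 5000.0, trim: int = 2,
               mutation_site: int | None = None) -> SystemSet:
    """Standard conditioning of raw runs into an analysable SystemSet.

    Equilibration frames (time <= discard_ps) are dropped and the first/last
    ``trim`` residues are masked to Z (chain ends are artefactually mobile
    where the neighbouring domain is absent).
    """
    processed = []
    for run in runs:
        out = run.discard_before(discard_ps) if discard_ps > 0 else run
        out = out.trim_termini(trim)
        processed.append(out)
    return SystemSet(label=label, runs=processed, mutation_site=mutation_site)


@dataclass
class ComparisonProfile:
    """Per-position ΔNeq / ΔPB between two systems."""

    residue_numbers: np.ndarray
    neq_wt: np.ndarray
    neq_var: np.ndarray
    delta_neq: np.ndarray
    delta_pb: np.ndarray
    wt_label: str = "WT"
    var_label: str = "variant"
    mutation_site: int | None = None

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.delta_pb)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": self.residue_numbers,
            "neq_wt": self.neq_wt,
            "neq_var": self.neq_var,
            "delta_neq": self.delta_neq,
            "delta_pb": self.delta_pb,
        })


def compare_systems(wt: SystemSet, var: SystemSet) -> ComparisonProfile:
    """Pool each system and compute per-position ΔNeq and ΔPB.

    Positions undefined (all-Z) in either system propagate NaN.
    """
    if not np.array_equal(wt.residue_numbers, var.residue_numbers):
        raise ValueError(
            f"residue numbering mismatch between {wt.label!r} and {var.label!r}"
        )
    fm_wt = wt.pooled_matrix()
    fm_var = var.pooled_matrix()
    neq_wt = neq(fm_wt.probabilities)
    neq_var = neq(fm_var.probabilities)
    dpb = delta_pb(fm_wt.probabilities, fm_var.probabilities)
    return ComparisonProfile(
        residue_numbers=wt.residue_numbers.copy(),
        neq_wt=neq_wt,
        neq_var=neq_var,
        delta_neq=delta_neq(neq_wt, neq_var),
        delta_pb=dpb,
        wt_label=wt.label,
        var_label=var.label,
        mutation_site=var.mutation_site,
    )


def hotspots(profile: ComparisonProfile, k: int = 10) -> pd.DataFrame:
    """Top-k positions by ΔPB (ties: ΔNeq, then residue number).

    The mutation site's own rank (and metrics) is reported in the attrs of
    the returned frame, so distal effects are evident at a glance.  Positions
    with ΔPB = 0 are not hotspots; an all-zero profile yields an empty table.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    defined = profile.defined
    if not np.any(defined):
        raise ValueError("profile has no defined positions")
    resnums = profile.residue_numbers[defined]
    dpb = profile.delta_pb[defined]
    dneq = profile.delta_neq[defined]
    order = np.lexsort((resnums, -dneq, -dpb))
    order = order[dpb[order] > 0]
    top = order[:k]
    table = pd.DataFrame({
        "rank": np.arange(1, len(top) + 1),
        "residue": resnums[top],
        "delta_pb": dpb[top],
        "delta_neq": dneq[top],
    })
    if profile.mutation_site is not None:
        site = profile.mutation_site
        ranks = {int(resnums[i]): r + 1 for r, i in enumerate(order)}
        idx = np.flatnonzero(profile.residue_numbers == site)[0]
        table.attrs["mutation_site"] = site
        table.attrs["mutation_site_rank"] = ranks.get(site)  # None if ΔPB = 0
        table.attrs["mutation_site_delta_pb"] = float(profile.delta_pb[idx])
    return table


@dataclass
class RegionAnnotation:
    """Ordered, non-overlapping loop/strand spans in author numbering."""

    names: list[str]
    kinds: list[str]
    spans: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not (len(self.names) == len(self.kinds) == len(self.spans)):
            raise ValueError("names, kinds and spans must align")
        for kind in self.kinds:
            if kind not in ("loop", "strand"):
                raise ValueError(f"unknown region kind {kind!r}")
        last_end = None
        for name, (start, end) in zip(self.names, self.spans):
            if end < start:
                raise ValueError(f"region {name}: end < start")
            if last_end is not None and start <= last_end:
                raise ValueError(f"region {name} overlaps its predecessor")
            last_end = end

    def size(self, name: str) -> int:
        start, end = self.spans[self.names.index(name)]
        return end - start + 1

    def label_of(self, residue_number: int) -> str:
        for name, (start, end) in zip(self.names, self.spans):
            if start <= residue_number <= end:
                return name
        return "unannotated"

    def labels(self, residue_numbers) -> np.ndarray:
        return np.array([self.label_of(int(r)) for r in residue_numbers])


def calf1_regions() -> RegionAnnotation:
    """The packaged Calf-1 default annotation (10 loops, 9 strands)."""
    path = resources.files("pbflex.data").joinpath("calf1_regions.tsv")
    names, kinds, spans = [], [], []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            name, kind, start, end = line.split("\t")
            names.append(name)
            kinds.append(kind)
            spans.append((int(start), int(end)))
    return RegionAnnotation(names, kinds, spans)


def region_summary(residue_numbers, values, annotation: RegionAnnotation,
                   metric: str = "value") -> pd.DataFrame:
    """Per-region mean/max of a per-residue metric, plus the argmax residue.

    Residues falling outside every region go to an 'unannotated' bucket;
    undefined (NaN) values are ignored within a region.
    """
    residue_numbers = np.asarray(residue_numbers, dtype=int)
    values = np.asarray(values, dtype=float)
    labels = annotation.labels(residue_numbers)
    rows = []
    region_order = list(annotation.names) + ["unannotated"]
    kind_of = dict(zip(annotation.names, annotation.kinds))
    for name in region_order:
        mask = labels == name
        if not np.any(mask):
            continue
        vals = values[mask]
        res = residue_numbers[mask]
        finite = np.isfinite(vals)
        if np.any(finite):
            vmax_i = np.flatnonzero(finite)[np.argmax(vals[finite])]
            rows.append((name, kind_of.get(name, ""), int(mask.sum()),
                         float(np.nanmean(vals)), float(vals[vmax_i]),
                         int(res[vmax_i])))
        else:
            rows.append((name, kind_of.get(name, ""), int(mask.sum()),
                         np.nan, np.nan, -1))
    return pd.DataFrame(
        rows,
        columns=["region", "kind", "size", f"mean_{metric}", f"max_{metric}",
                 "argmax_residue"],
    )
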