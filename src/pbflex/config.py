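"""Run configuration: the declared simulation plan and analysis settings.

A run manifest declares, per system, the independent runs with their
durations; validation checks the totals before any analysis (the emulated
study design is 11 runs of 5×50 + 6×100 ns = 850 ns per system, saved every
100 ps, first 5 ns discarded, two residues trimmed at each terminus).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .synthetic import SyntheticScenario, distribution_for_neq


class ConfigError(ValueError):
    pass


@dataclass
class RunSpec:
    name: str
    duration_ns: float
    trajectory: str | None = None


@dataclass
class SystemSpec:
    label: str
    runs: list[RunSpec]
    mutation_site: int | None = None

    @property
    def total_ns(self) -> float:
        return sum(r.duration_ns for r in self.runs)


@dataclass
class RunConfig:
    """Parsed analysis configuration."""

    systems: dict[str, SystemSpec]
    stride_ps: float = 100.0
    discard_ns: float = 5.0
    trim: int = 2
    seed: int = 0
    structure: str | None = None
    chain: str = "A"
    span: tuple[int, int] | None = None
    out_dir: str = "."
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def config_hash(self) -> str:
        text = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def validate(self, expected_total_ns: float | None = None) -> list[str]:
        """Sanity-check the plan; returns human-readable findings.

        Raises ConfigError on violations (empty system, non-positive
        durations, inconsistent totals across systems, or a mismatch with an
        explicitly expected per-system total).
        """
        findings = []
        if not self.systems:
            raise ConfigError("config declares no systems")
        totals = {}
        for label, system in self.systems.items():
            if not system.runs:
                raise ConfigError(f"system {label!r} declares no runs")
            for run in system.runs:
                if run.duration_ns <= 0:
                    raise ConfigError(
                        f"system {label!r} run {run.name!r}: duration must be positive"
                    )
            totals[label] = system.total_ns
            frames = sum(int(round(r.duration_ns * 1000 / self.stride_ps))
                         for r in system.runs)
            findings.append(
                f"{label}: {len(system.runs)} runs, total {system.total_ns:g} ns "
                f"({frames} frames at {self.stride_ps:g} ps)"
            )
        if len(set(totals.values())) > 1:
            raise ConfigError(f"systems disagree on total simulated time: {totals}")
        total = next(iter(totals.values()))
        if expected_total_ns is not None and not np.isclose(total, expected_total_ns):
            raise ConfigError(
                f"per-system total {total:g} ns differs from expected "
                f"{expected_total_ns:g} ns"
            )
        if self.discard_ns * 1000 >= min(
            r.duration_ns * 1000 for s in self.systems.values() for r in s.runs
        ):
            raise ConfigError("discard time is not shorter than the shortest run")
        if self.trim < 0:
            raise ConfigError("trim must be non-negative")
        findings.append(f"per-system total: {total:g} ns")
        return findings


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    systems = {}
    for label, spec in (raw.get("systems") or {}).items():
        runs = [
            RunSpec(
                name=str(r.get("name", f"run{i}")),
                duration_ns=float(r["duration_ns"]),
                trajectory=r.get("trajectory"),
            )
            for i, r in enumerate(spec.get("runs", []))
        ]
        systems[label] = SystemSpec(
            label=label, runs=runs, mutation_site=spec.get("mutation_site")
        )
    span = raw.get("span")
    return RunConfig(
        systems=systems,
        stride_ps=float(raw.get("stride_ps", 100.0)),
        discard_ns=float(raw.get("discard_ns", 5.0)),
        trim=int(raw.get("trim", 2)),
        seed=int(raw.get("seed", 0)),
        structure=raw.get("structure"),
        chain=str(raw.get("chain", "A")),
        span=tuple(span) if span else None,
        out_dir=str(raw.get("out_dir", ".")),
        raw=raw,
    )


def load_scenario(path) -> SyntheticScenario:
    """Deserialize a synthetic scenario from YAML.

    Keys: n_residues, seed, support, neq_targets (list, or {min, max} drawn
    per position), run_plan_ns, stride_ps, discard_ns, variants
    (label -> {mutation_site, edits: {residue -> {neq, support} | {probs}}}).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    seed = int(raw.get("seed", 0))
    n = int(raw["n_residues"])
    support = int(raw.get("support", 4))
    targets = raw.get("neq_targets")
    if targets is None:
        rng = np.random.default_rng(seed)
        lo = float(raw.get("neq_min", 1.0))
        hi = float(raw.get("neq_max", float(support)))
        targets = rng.uniform(lo, hi, size=n).tolist()
    if len(targets) != n:
        raise ConfigError(f"neq_targets must have n_residues={n} entries")
    variant_edits = {}
    for label, vspec in (raw.get("variants") or {}).items():
        edits = {}
        for resid, espec in (vspec.get("edits") or {}).items():
            resid = int(resid)
            if "probs" in espec:
                row = np.asarray(espec["probs"], dtype=float)
            else:
                row = distribution_for_neq(
                    float(espec.get("neq", 2.0)),
                    support=int(espec.get("support", support)),
                    seed=int(espec.get("seed", seed + resid)),
                )
            edits[resid] = row
        variant_edits[label] = edits
    scenario = SyntheticScenario.from_neq_targets(
        targets,
        support=support,
        seed=seed,
        run_plan_ns=tuple(raw.get("run_plan_ns", (50,) * 5 + (100,) * 6)),
        stride_ps=float(raw.get("stride_ps", 100.0)),
        discard_ns=float(raw.get("discard_ns", 5.0)),
        variant_edits=variant_edits,
    )
    return scenario
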