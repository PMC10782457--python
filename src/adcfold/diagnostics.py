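"""Structured solver diagnostics: per-iteration records and counters."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

logger = logging.getLogger("adcfold")


@dataclass
class IterationRecord:
    solver: str  # 'cpp' or 'eigen'
    group: str
    iteration: int
    system: str
    residual: float
    subspace_dim: int
    new_vectors: int
    sigma_pairs_computed: int
    sigma_pairs_accounted: int
    converged: bool


@dataclass
class SolverDiagnostics:
    """Accumulates iteration records and global counters for one run."""

    records: list = field(default_factory=list)
    trial_vectors: int = 0
    sigma_pairs_computed: int = 0
    sigma_pairs_accounted: int = 0

    def record(self, **kwargs) -> None:
        rec = IterationRecord(**kwargs)
        self.records.append(rec)
        logger.debug(
            "solver=%s group=%s iter=%d system=%s residual=%.3e dim=%d",
            rec.solver, rec.group, rec.iteration, rec.system,
            rec.residual, rec.subspace_dim,
        )

    def merge(self, other: "SolverDiagnostics") -> None:
        self.records.extend(other.records)
        self.trial_vectors += other.trial_vectors
        self.sigma_pairs_computed += other.sigma_pairs_computed
        self.sigma_pairs_accounted += other.sigma_pairs_accounted

    # -- summaries ----------------------------------------------------------

    def iterations_to_convergence(self) -> dict:
        """system id -> iteration of convergence (or last seen, if never)."""
        out = {}
        for rec in self.records:
            key = rec.system
            if key not in out or not out[key][1]:
                out[key] = (rec.iteration, rec.converged)
            if rec.converged and not out[key][1]:
                out[key] = (rec.iteration, True)
        return {k: v[0] for k, v in out.items()}

    def per_frequency_iterations(self) -> dict:
        """frequency label -> iterations needed by the slowest component."""
        out = {}
        for system, iters in self.iterations_to_convergence().items():
            freq = system.split("@")[-1] if "@" in system else system
            out[freq] = max(out.get(freq, 0), iters)
        return out

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([
                "solver", "group", "iteration", "system", "residual",
                "subspace_dim", "new_vectors", "sigma_pairs_computed",
                "sigma_pairs_accounted", "converged",
            ])
            for r in self.records:
                writer.writerow([
                    r.solver, r.group, r.iteration, r.system,
                    f"{r.residual:.6e}", r.subspace_dim, r.new_vectors,
                    r.sigma_pairs_computed, r.sigma_pairs_accounted,
                    int(r.converged),
                ])


def replot_diagnostics(diag: SolverDiagnostics) -> dict:
    """Convergence summary: per-frequency iteration counts and cumulative
    trial-vector / sigma-pair curves; flags a truncated record stream."""
    per_iter = {}
    for rec in diag.records:
        d = per_iter.setdefault(rec.iteration, {"new_vectors": 0, "sigma": 0})
        d["new_vectors"] = max(d["new_vectors"], rec.new_vectors)
        d["sigma"] = max(d["sigma"], rec.sigma_pairs_computed)
    iters = sorted(per_iter)
    cumulative = []
    total = 0
    for it in iters:
        total += per_iter[it]["new_vectors"]
        cumulative.append((it, total))
    partial = bool(diag.records) and not all(
        rec.converged for rec in diag.records
        if rec.iteration == max(r.iteration for r in diag.records
                                if r.system == rec.system)
    )
    return {
        "per_frequency_iterations": diag.per_frequency_iterations(),
        "cumulative_trial_vectors": cumulative,
        "total_sigma_pairs": diag.sigma_pairs_computed,
        "total_sigma_pairs_accounted": diag.sigma_pairs_accounted,
        "partial": partial,
    }
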