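"""Run configuration: serializable description of a complete calculation.

A run is reproducible from its serialized configuration alone; the CLI is a
thin mirror of these keys.
"""

from __future__ import annotations

import configparser
import io
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .constants import convert_units


@dataclass
class RunConfig:
    """Everything needed to reproduce a calculation."""

    xyz_path: str = ""
    charge: int = 0
    basis: str = "sto-3g"
    mode: str = "cpp"  # cpp | states
    operators: tuple = ("dipole",)
    freq_start: float = 0.0  # in freq_unit
    freq_stop: float = 0.0
    freq_count: int = 0
    freq_step: float = 0.0  # used when freq_count == 0
    freq_unit: str = "au"
    gamma: float = 1000.0
    gamma_unit: str = "cm-1"
    strategy: str = "separate"  # common | separate
    threshold: float = 1e-4
    n_states: int = 5
    gauge: str = "velocity"
    output_prefix: str = "adcfold"
    verbosity: int = 1

    def gamma_au(self) -> float:
        return convert_units(self.gamma, self.gamma_unit, "hartree")

    def frequencies_au(self) -> np.ndarray:
        from .cpp import freq_grid

        if self.freq_count:
            grid = freq_grid(self.freq_start, self.freq_stop,
                             count=self.freq_count)
        else:
            grid = freq_grid(self.freq_start, self.freq_stop,
                             step=self.freq_step)
        return np.array([
            convert_units(w, self.freq_unit, "hartree") for w in grid
        ])

    # -- serialization ------------------------------------------------------

    def serialize(self) -> str:
        cp = configparser.ConfigParser()
        cp["run"] = {}
        for key, val in asdict(self).items():
            if isinstance(val, (tuple, list)):
                val = ",".join(val)
            cp["run"][key] = str(val)
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    @classmethod
    def parse(cls, text: str) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.read_string(text)
        sec = cp["run"]
        kwargs = {}
        for f_ in cls.__dataclass_fields__.values():
            if f_.name not in sec:
                continue
            raw = sec[f_.name]
            if f_.name == "operators":
                kwargs[f_.name] = tuple(x for x in raw.split(",") if x)
            elif f_.type in ("int",):
                kwargs[f_.name] = int(raw)
            elif f_.type in ("float",):
                kwargs[f_.name] = float(raw)
            else:
                kwargs[f_.name] = raw
        return cls(**kwargs)


def run(config: RunConfig) -> int:
    """Execute a configured run; writes spectra/state tables/diagnostics.

    Returns a nonzero status iff any response equation or root failed to
    converge.  No partial outputs are left behind on configuration errors.
    """
    import csv

    from .adc import AdcWorkspace
    from .constants import HARTREE_TO_EV
    from .moints import mo_integral_set
    from .mol import parse_xyz
    from .mp import t2_amplitudes
    from .properties import TransitionMomentBuilder
    from . import spectra as spectra_mod

    if not os.path.exists(config.xyz_path):
        raise FileNotFoundError(f"XYZ file not found: {config.xyz_path}")
    with open(config.xyz_path) as fh:
        molecule = parse_xyz(fh.read(), charge=config.charge)

    from .scf import build_reference

    ref = build_reference(molecule, config.basis)
    need_ops = set(config.operators) | {"dipole"}
    if config.mode != "cpp" or "magdip" in need_ops:
        need_ops |= {"linmom", "magdip"}
    ints = mo_integral_set(ref, operators=tuple(sorted(need_ops)))
    ws = AdcWorkspace(ints, t2_amplitudes(ints))
    builder = TransitionMomentBuilder(ws)
    prefix = config.output_prefix
    status = 0

    if config.mode == "cpp":
        omegas = config.frequencies_au()
        gamma = config.gamma_au()
        spec = spectra_mod.uvvis_cpp(
            ws, builder, omegas, gamma, strategy=config.strategy,
            threshold=config.threshold,
        )
        de = None
        if {"magdip", "linmom"} <= set(config.operators):
            ecd = spectra_mod.ecd_cpp(
                ws, builder, omegas, gamma, strategy=config.strategy,
                threshold=config.threshold,
            )
            de = ecd.delta_epsilon
            spec.diagnostics.merge(ecd.diagnostics)
        with open(f"{prefix}_spectrum.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["omega_au", "omega_ev", "sigma_au", "delta_epsilon"])
            for k, om in enumerate(omegas):
                w.writerow([
                    f"{om:.10f}", f"{om * HARTREE_TO_EV:.8f}",
                    f"{spec.sigma_au[k]:.12e}",
                    f"{de[k]:.12e}" if de is not None else "",
                ])
        spec.diagnostics.to_csv(f"{prefix}_diagnostics.csv")
        seen = {r.system for r in spec.diagnostics.records}
        done = {r.system for r in spec.diagnostics.records if r.converged}
        status = 0 if seen <= done else 1
    elif config.mode == "states":
        states, rows, diag = spectra_mod.excited_states_table(
            ws, builder, config.n_states
        )
        with open(f"{prefix}_states.json", "w") as fh:
            json.dump(rows, fh, indent=1)
        with open(f"{prefix}_states.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(list(rows[0].keys()))
            for r in rows:
                w.writerow(list(r.values()))
        diag.to_csv(f"{prefix}_diagnostics.csv")
        status = 0 if all(st.converged for st in states) else 1
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    return status
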