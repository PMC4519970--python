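"""Pipeline configuration: validated parameter blocks with experiment defaults.

An empty config runs the reference scenario of the Tb³⁺–TagRFP sensor:
τ_D = 0.33 ms, τ_D,R = 3.5 ms, J = 3.22591e15 M⁻¹·cm⁻¹·nm⁴, κ² = 2/3,
n = 1.4, a 19-bond freely jointed linker, a 1–50 µM titration with
K_d = 17 µM and I_max = 95 a.u., and a 100 µs delay / 1 ms gate.
Config files are YAML with one section per block; unknown keys are
rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .forster import FretParameters
from .gated_signal import GateWindow
from .synthetic_data import ChainModel, TitrationDesign

__all__ = ["PipelineConfig", "load_config", "DEFAULT_CONCENTRATIONS_UM"]

DEFAULT_CONCENTRATIONS_UM = (1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0)


@dataclass
class PipelineConfig:
    # photophysics
    tau_D: float = 0.33  # ms
    tau_DR: float = 3.5  # ms
    J: float = 3.22591e15  # M^-1 cm^-1 nm^4
    kappa2: float = 2.0 / 3.0
    n: float = 1.4
    # chain
    n_segments: int = 19
    bond_length: float = 0.38  # nm
    chain_model: str = "freely_jointed"
    persistence_length: float | None = None  # nm
    end_offsets: tuple[float, float] = (0.0, 0.0)
    n_distance_samples: int = 100_000
    # titration
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS_UM
    true_Kd: float = 17.0  # µM
    true_Imax: float = 95.0  # a.u.
    noise_sd: float = 4.75  # a.u., 5% of the plateau
    n_boot: int = 1000
    # gate
    gate_delay: float = 100.0  # µs
    gate_width: float = 1000.0  # µs
    # bookkeeping
    seed: int = 0
    outdir: str = "lumifret_out"

    def fret_parameters(self) -> FretParameters:
        return FretParameters(
            J=self.J, tau_D=self.tau_D, tau_DR=self.tau_DR,
            kappa2=self.kappa2, n=self.n,
        )

    def chain(self) -> ChainModel:
        return ChainModel(
            n_segments=self.n_segments,
            bond_length=self.bond_length,
            model=self.chain_model,
            persistence_length=self.persistence_length,
            end_offsets=tuple(self.end_offsets),
        )

    def titration_design(self, noise_sd: float | None = None) -> TitrationDesign:
        return TitrationDesign(
            concentrations=np.array(self.concentrations),
            true_Kd=self.true_Kd,
            true_Imax=self.true_Imax,
            noise_sd=self.noise_sd if noise_sd is None else noise_sd,
            seed=self.seed,
        )

    def gate(self) -> GateWindow:
        return GateWindow(delay=self.gate_delay, width=self.gate_width)

    def validate(self) -> None:
        """Run every owning type's invariant checks before any stage runs."""
        self.fret_parameters()
        self.chain()
        self.titration_design()
        self.gate()
        if self.n_distance_samples < 1:
            raise ValueError("n_distance_samples must be >= 1")
        if self.n_boot < 0:
            raise ValueError("n_boot must be nonnegative")

    def as_dict(self) -> dict:
        return asdict(self)


# section -> field names, mirroring the blocks above
_SECTIONS = {
    "photophysics": ("tau_D", "tau_DR", "J", "kappa2", "n"),
    "chain": (
        "n_segments", "bond_length", "chain_model", "persistence_length",
        "end_offsets", "n_distance_samples",
    ),
    "titration": ("concentrations", "true_Kd", "true_Imax", "noise_sd", "n_boot"),
    "gate": ("gate_delay", "gate_width"),
    "run": ("seed", "outdir"),
}


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a sectioned YAML config; missing keys fall back to defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping of sections")
    for section, payload in data.items():
        if section not in _SECTIONS:
            raise ValueError(f"{path}: unknown config section {section!r}")
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: section {section!r} must be a mapping")
        for key, value in payload.items():
            if key not in _SECTIONS[section]:
                raise ValueError(
                    f"{path}: unknown key {key!r} in section {section!r}"
                )
            if key in ("concentrations", "end_offsets"):
                value = tuple(float(v) for v in value)
            setattr(cfg, key, value)
    return cfg
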