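"""Run configuration with the documented defaults in one place."""

from __future__ import annotations

from dataclasses import dataclass, fields

from nucdock.errors import ContractViolation

KERNELS = ("gaussian", "paper_literal")
RESTRAINT_MODES = ("filter", "penalty")


@dataclass
class DockConfig:
    """All tunable parameters of the docking pipeline.

    Defaults are the normative parameter set: 15 degree rotation interval,
    1.2 A grid spacing, top-10 translation rescoring per rotation, 5 A
    ligand-RMSD cluster cutoff, 10 A interface cutoff, 5.0 A hit threshold,
    100 output models.
    """

    angle_interval: float = 15.0
    spacing: float = 1.2
    top_translations: int = 10
    n_models: int = 100
    cluster_cutoff: float = 5.0
    interface_cutoff: float = 10.0
    hit_threshold: float = 5.0
    kernel: str = "gaussian"
    kernel_cutoff: float = 2.0  # in grid spacings
    core_penalty: float = -15.0
    occupancy_radius: float = 2.6
    max_grid_cells: int = 256**3
    seed: int = 0
    restraint_mode: str = "filter"
    restraint_penalty: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "angle_interval",
            "spacing",
            "top_translations",
            "n_models",
            "cluster_cutoff",
            "interface_cutoff",
            "hit_threshold",
            "kernel_cutoff",
            "occupancy_radius",
            "max_grid_cells",
        ):
            if getattr(self, name) <= 0:
                raise ContractViolation(f"{name} must be positive")
        if self.kernel not in KERNELS:
            raise ContractViolation(f"kernel must be one of {KERNELS}")
        if self.restraint_mode not in RESTRAINT_MODES:
            raise ContractViolation(
                f"restraint_mode must be one of {RESTRAINT_MODES}"
            )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "DockConfig":
        """Build from a flat key=value mapping, coercing types from defaults."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for key, value in mapping.items():
            key = key.replace("-", "_")
            if key not in known:
                raise ContractViolation(f"unknown config key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = str(value).lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = str(value)
        return cls(**kwargs)


def load_config_file(path: str) -> dict:
    """Flat ``key = value`` config file; '#' starts a comment."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ContractViolation(f"malformed config line: {raw.rstrip()!r}")
            key, value = line.split("=", 1)
            mapping[key.strip()] = value.strip()
    return mapping
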