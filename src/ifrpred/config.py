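"""Run configuration: every tunable of the train/predict/evaluate workflow
in one flat record, with the package's standard defaults.

Config files are flat ``key = value`` text (TOML-style scalars, # comments);
command-line flags override file values, and every override is logged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .contacts import ContactCriteria
from .descriptors import DescriptorConfig
from .surface import DELTA_AREA, DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, EXPOSURE_MIN


@dataclass
class RunConfig:
    probe_radius: float = DEFAULT_PROBE_RADIUS  # Å, SASA water probe
    n_points: int = DEFAULT_N_POINTS            # SASA sampling points/atom
    delta_area: float = DELTA_AREA              # Å², IFR accessibility change
    exposure_min: float = EXPOSURE_MIN          # surface-residue threshold
    hydrophobic_cutoff: float = 3.9             # Å
    aromatic_cutoff: float = 5.0                # Å
    hbond_cutoff: float = 3.2                   # Å
    charged_cutoff: float = 6.0                 # Å
    disulfide_cutoff: float = 2.5               # Å
    wna_cutoff: float = 15.0                    # Å, neighbor horizon
    cpo_radius: float = 8.0                     # Å
    min_seq_separation: int = 30                # CLO/CPO long-range threshold
    correlation_threshold: float = 0.85         # |r| pruning threshold
    variance_target: float = 0.95               # PCA retained-variance target
    k_folds: int = 10
    decision_cutoff: float = 0.50
    seed: int = 0
    overrides: list[str] = field(default_factory=list, repr=False)

    def contact_criteria(self) -> ContactCriteria:
        return ContactCriteria(
            hydrophobic_cutoff=self.hydrophobic_cutoff,
            aromatic_cutoff=self.aromatic_cutoff,
            hbond_cutoff=self.hbond_cutoff,
            charged_cutoff=self.charged_cutoff,
            disulfide_cutoff=self.disulfide_cutoff,
        )

    def descriptor_config(self) -> DescriptorConfig:
        return DescriptorConfig(
            cpo_radius=self.cpo_radius,
            min_seq_separation=self.min_seq_separation,
            wna_cutoff=self.wna_cutoff,
            sasa_probe=self.probe_radius,
            sasa_points=self.n_points,
            contact_criteria=self.contact_criteria(),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("overrides", None)
        return d


def load_config(path: str | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional flat key=value file plus explicit
    overrides (CLI flags beat file values)."""
    cfg = RunConfig()
    applied: list[str] = []
    if path is not None:
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"malformed config line: {line!r}")
                key, val = (s.strip() for s in line.split("=", 1))
                _set(cfg, key, val)
                applied.append(f"file:{key}={val}")
    for key, val in overrides.items():
        if val is None:
            continue
        _set(cfg, key, val)
        applied.append(f"flag:{key}={val}")
    cfg.overrides = applied
    return cfg


def _set(cfg: RunConfig, key: str, val) -> None:
    if not hasattr(cfg, key) or key == "overrides":
        raise KeyError(f"unknown config key {key!r}")
    current = getattr(cfg, key)
    if isinstance(val, str):
        val = val.strip().strip('"').strip("'")
        val = type(current)(val) if not isinstance(current, bool) else (
            val.lower() in ("1", "true", "yes"))
    setattr(cfg, key, val)
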