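"""Run configuration: probe radius, virtual pH, cutoffs and thresholds.

The defaults reproduce the reference labelling protocol: probe radius
4.2 Å (the effective radius used for the NHS-ester ATRP initiator),
virtual pH 8.0, bare Coulomb dielectric (epsilon = 1) on PQR charges,
D-A <= 3.0 Å / D-H-A >= 150 deg hydrogen-bond geometry, and the
decision-tree thresholds 50 Å² (ESA), 10.3 (pKa) and 100 kcal/mol
(local-charge energy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from .errors import ConfigurationError


@dataclass
class ClassifierThresholds:
    """Branch thresholds of the reactivity decision tree.

    esa_reactive
        Residue exposed surface area (Å²) below which a site is
        non-reacting.  Exactly 50 Å² counts as reactive (non-strict).
    pka_branch
        Sites with pKa <= this value pass the fast-reacting branch;
        above it they are slow-reacting.
    charge_threshold
        Coulomb energy (kcal/mol) strictly above which the amine sits
        in an area of low positive charge.
    """

    esa_reactive: float = 50.0
    pka_branch: float = 10.3
    charge_threshold: float = 100.0

    def validate(self) -> None:
        for name in ("esa_reactive", "pka_branch", "charge_threshold"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"threshold {name!r} must be positive")


@dataclass
class RunConfig:
    """Full configuration of a scoring run."""

    probe_radius: float = 4.2
    ph: float = 8.0
    dielectric: float = 1.0
    chains: Optional[Sequence[str]] = None
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    hbond_distance: float = 3.0  # D-A cutoff, Å
    hbond_angle: float = 150.0  # D-H-A cutoff, degrees
    pka_backend: str = "builtin"
    # pKa heuristic constants (see pka module)
    pka_model_epsilon: float = 10.5
    pka_model_alpha: float = 8.0
    pka_burial_cutoff: float = 9.0
    pka_burial_baseline: int = 280
    pka_burial_coeff: float = 0.01
    pka_charge_cutoff: float = 7.0
    pka_charge_coeff: float = 0.5
    # electrostatics
    exclude_same_residue: bool = True
    # SASA
    sasa_algorithm: str = "lee-richards"  # or "shrake-rupley"
    sasa_resolution: int = 100
    keep_hetero: bool = False
    classifier_rules: Optional[str] = None  # path to a rules file

    def validate(self) -> None:
        for name in ("probe_radius", "ph", "dielectric", "hbond_distance", "hbond_angle"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"config field {name!r} must be positive")
        if self.sasa_resolution < 20:
            raise ConfigurationError("sasa_resolution must be >= 20")
        if self.sasa_algorithm not in ("lee-richards", "shrake-rupley"):
            raise ConfigurationError(f"unknown SASA algorithm {self.sasa_algorithm!r}")
        self.thresholds.validate()

    def with_probe_radius(self, r: float) -> "RunConfig":
        return replace(self, probe_radius=r)


_FLAT_KEYS = {
    "probe_radius": ("probe_radius", float),
    "ph": ("ph", float),
    "dielectric": ("dielectric", float),
    "charge.threshold": ("thresholds.charge_threshold", float),
    "classifier.esa": ("thresholds.esa_reactive", float),
    "classifier.pka": ("thresholds.pka_branch", float),
    "classifier.rules": ("classifier_rules", str),
    "hbond.distance": ("hbond_distance", float),
    "hbond.angle": ("hbond_angle", float),
    "pka.backend": ("pka_backend", str),
    "charge.exclude_same_residue": ("exclude_same_residue", lambda s: s in ("1", "true", "True", "yes")),
    "sasa.algorithm": ("sasa_algorithm", str),
    "sasa.resolution": ("sasa_resolution", int),
}


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a flat ``key = value`` or YAML file.

    Flat keys use dotted names (``charge.threshold = 100``).  A YAML
    file may nest the same names (``charge: {threshold: 100}``).
    """
    text = Path(path).read_text()
    cfg = RunConfig()
    pairs: dict[str, str] = {}
    if ":" in text and "=" not in text:
        import yaml

        data = yaml.safe_load(text) or {}
        _flatten(data, "", pairs)
    else:
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
            k, v = line.split("=", 1)
            pairs[k.strip()] = v.strip()
    for key, raw in pairs.items():
        if key not in _FLAT_KEYS:
            raise ConfigurationError(f"unknown config key {key!r}")
        dest, conv = _FLAT_KEYS[key]
        value = conv(raw)
        if dest.startswith("thresholds."):
            setattr(cfg.thresholds, dest.split(".", 1)[1], value)
        else:
            setattr(cfg, dest, value)
    cfg.validate()
    return cfg


def _flatten(data, prefix, out) -> None:
    for k, v in data.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            _flatten(v, key + ".", out)
        else:
            out[key] = str(v)
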