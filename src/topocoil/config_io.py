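"""Configuration serialization: one YAML/JSON document describing the
lattice, genes, topoisomerases, barriers, mechanics and run control.

Unknown keys are rejected (typos should fail loudly, not silently fall
back to defaults); derived quantities (k_drift from D, boundary target
from sigma_eq) are computed at load time and echoed in the dump, and a
dump -> load round trip reproduces the configuration exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import List, Optional, Tuple, Union

import yaml

from .engine import RunControl
from .state import (
    BP_PER_NM,
    BarrierSpec,
    ConfigurationError,
    GeneSpec,
    LatticeConfig,
    MechanicsParams,
    SimulationConfig,
    TopoSpec,
)

__all__ = [
    "load_config",
    "dump_config",
    "config_to_dict",
    "config_hash",
    "genes_from_bed",
]

_SECTION_TYPES = {
    "lattice": LatticeConfig,
    "genes": GeneSpec,
    "topoisomerases": TopoSpec,
    "barriers": BarrierSpec,
    "mechanics": MechanicsParams,
    "run": RunControl,
}
_LIST_SECTIONS = {"genes", "topoisomerases", "barriers"}
_KNOWN_SECTIONS = set(_SECTION_TYPES)


def _check_keys(d: dict, cls, where: str) -> None:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


def _build_lattice(d: dict) -> LatticeConfig:
    d = dict(d)
    _check_keys(d, LatticeConfig, "lattice")
    D = d.get("diffusion_coefficient")
    kd = d.get("k_drift")
    if D is not None and kd is not None:
        dx_um = d.get("segment_bp", 60) * BP_PER_NM * 1e-3
        implied = D / dx_um**2
        if abs(implied - kd) > 1e-6 * max(abs(implied), 1.0):
            raise ConfigurationError(
                f"diffusion_coefficient {D} and k_drift {kd} are inconsistent "
                f"(D/dx^2 = {implied:.6g} /s)"
            )
        d.pop("k_drift")
    return LatticeConfig(**d)


def load_config(path: Union[str, Path]) -> Tuple[SimulationConfig, Optional[RunControl]]:
    """Load and validate a full configuration document.

    Returns ``(SimulationConfig, RunControl or None)``.  All defaults are
    filled in; schema violations name the offending key.
    """
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration document must be a mapping")
    unknown = set(doc) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigurationError(
            f"unknown section(s) {sorted(unknown)}; allowed: {sorted(_KNOWN_SECTIONS)}"
        )
    if "lattice" not in doc:
        raise ConfigurationError("missing required section 'lattice'")
    lattice = _build_lattice(doc["lattice"])

    def build_list(section: str):
        out = []
        for i, item in enumerate(doc.get(section) or []):
            cls = _SECTION_TYPES[section]
            _check_keys(item, cls, f"{section}[{i}]")
            out.append(cls(**item))
        return out

    mech_d = doc.get("mechanics") or {}
    _check_keys(mech_d, MechanicsParams, "mechanics")
    cfg = SimulationConfig(
        lattice=lattice,
        genes=build_list("genes"),
        topos=build_list("topoisomerases"),
        barriers=build_list("barriers"),
        mechanics=MechanicsParams(**mech_d),
    )
    run = None
    if "run" in doc:
        rd = dict(doc["run"])
        _check_keys(rd, RunControl, "run")
        if "regions" in rd and rd["regions"] is not None:
            rd["regions"] = {k: list(v) for k, v in rd["regions"].items()}
        run = RunControl(**rd)
    return cfg, run


def config_to_dict(cfg: SimulationConfig, run: Optional[RunControl] = None) -> dict:
    doc = {
        "lattice": dataclasses.asdict(cfg.lattice),
        "genes": [dataclasses.asdict(g) for g in cfg.genes],
        "topoisomerases": [dataclasses.asdict(t) for t in cfg.topos],
        "barriers": [dataclasses.asdict(b) for b in cfg.barriers],
        "mechanics": dataclasses.asdict(cfg.mechanics),
    }
    if run is not None:
        doc["run"] = dataclasses.asdict(run)
    return doc


def dump_config(
    cfg: SimulationConfig, path: Union[str, Path], run: Optional[RunControl] = None
) -> None:
    """Write the fully resolved configuration (all defaults and derived
    quantities echoed) as YAML or JSON depending on the file suffix."""
    path = Path(path)
    doc = config_to_dict(cfg, run)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2, sort_keys=False))


def config_hash(cfg: SimulationConfig, run: Optional[RunControl] = None) -> str:
    """Content hash of the resolved configuration; changes iff any
    parameter changes."""
    doc = config_to_dict(cfg, run)
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def genes_from_bed(
    path: Union[str, Path],
    segment_bp: int = 60,
    k_max: float = 0.05,
    **gene_defaults,
) -> List[GeneSpec]:
    """Import gene layouts from a BED file (chrom ignored; start/end/strand
    used; the name column names the gene).

    bp coordinates are 0-based half-open; a gene's TSS segment is the
    segment containing its first transcribed bp (strand-aware).
    """
    genes: List[GeneSpec] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ConfigurationError(f"BED line {ln}: need at least chrom/start/end")
        start, end = int(parts[1]), int(parts[2])
        if end <= start:
            raise ConfigurationError(f"BED line {ln}: end must exceed start")
        name = parts[3] if len(parts) > 3 else f"gene{len(genes) + 1}"
        strand_sym = parts[5] if len(parts) > 5 else "+"
        first_seg = start // segment_bp
        last_seg = (end - 1) // segment_bp
        if strand_sym == "-":
            spec = GeneSpec(
                name=name,
                strand="reverse",
                tss_segment=last_seg,
                end_segment=first_seg,
                k_max=k_max,
                **gene_defaults,
            )
        else:
            spec = GeneSpec(
                name=name,
                strand="forward",
                tss_segment=first_seg,
                end_segment=last_seg,
                k_max=k_max,
                **gene_defaults,
            )
        genes.append(spec)
    return genes
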