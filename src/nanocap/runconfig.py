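"""Serializable run configuration for the command-line workflows.

A :class:`RunConfig` captures everything needed to re-execute a run
bit-identically: molecule sources (drug codes, file paths or fixture
specs), copies, tube radius or radius grid, force-field path, search
settings and seeds.  Configs load from and dump to YAML; command-line
flags override file values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fixtures import FixtureSpec, drug_molecule, make_fixture
from .forcefield import ForceField, default_forcefield
from .molecule import Molecule, load_molecule
from .search import SearchSettings

__all__ = ["RunConfig", "resolve_molecules", "load_forcefield"]


@dataclass
class RunConfig:
    molecules: list[str] = field(default_factory=list)  # drug code | path | fixture:...
    copies: int = 1
    radius: float | None = None
    radius_grid: list[float] | None = None  # explicit list or [start, stop, num]
    eta: float | None = None
    forcefield: str | None = None
    seeds: list[int] = field(default_factory=lambda: list(range(8)))
    population: int = 200
    offspring: int | None = None
    generations: int = 400
    out: str = "nanocap_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def search_settings(self) -> SearchSettings:
        return SearchSettings(
            population=self.population,
            offspring=self.offspring or self.population,
            generations=self.generations,
            seeds=tuple(self.seeds),
        )

    def grid(self) -> np.ndarray | None:
        if self.radius_grid is None:
            return None
        g = self.radius_grid
        if len(g) == 3 and float(g[2]) == int(g[2]) and int(g[2]) >= 6:
            return np.linspace(float(g[0]), float(g[1]), int(g[2]))
        return np.asarray(g, dtype=float)


def load_forcefield(path: str | None) -> ForceField:
    return ForceField.from_file(path) if path else default_forcefield()


def resolve_molecules(sources, forcefield: ForceField) -> list[Molecule]:
    """Turn molecule source strings into Molecule objects.

    Each source is a drug code/name (FU, proflavine, ...), a path to an
    XYZ/SDF file, or a fixture spec ``fixture:<kind>[:<element>[:<length>]]``.
    """
    from .fixtures import canonical_drug_name

    out: list[Molecule] = []
    for src in sources:
        if src.startswith("fixture:"):
            parts = src.split(":")[1:]
            kind = parts[0]
            element = parts[1] if len(parts) > 1 else "C"
            length = float(parts[2]) if len(parts) > 2 else 1.42
            out.append(make_fixture(FixtureSpec(kind, element, length),
                                    forcefield=forcefield))
            continue
        try:
            canonical_drug_name(src)
        except KeyError:
            pass
        else:
            out.append(drug_molecule(src, forcefield=forcefield))
            continue
        p = Path(src)
        if not p.exists():
            raise ValueError(
                f"molecule source {src!r} is neither a known drug, a "
                "fixture spec, nor an existing file"
            )
        out.append(load_molecule(p, forcefield=forcefield))
    return out
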