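"""Deterministic molecules for tests, examples and paper-scale runs.

Two tiers are provided:

- geometric fixtures (:func:`make_fixture`): a single atom, a dimer, a
  planar hexagon ring and a tetrahedron with exact programmatic
  coordinates, so every stage of the pipeline is testable offline;

- the four study drugs (:func:`drug_molecule`): fluorouracil (FU),
  proflavine (PF), methylene blue (MB, chloride salt) and doxorubicin
  (DOX).  Their 3D conformers are synthetic: built at run time from the
  drugs' SMILES by RDKit ETKDG distance-geometry embedding with a fixed
  seed followed by MMFF94 relaxation (UFF fallback), which makes them
  bit-reproducible and download-free.  A helper to fetch the reference
  PubChem 3D records is included for online use.
"""

from __future__ import annotations

import functools
import hashlib
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .forcefield import ForceField
from .molecule import Molecule

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "drug_molecule",
    "fetch_pubchem",
    "DRUG_SMILES",
    "DRUG_CIDS",
    "DRUG_FORMULAS",
]

#: isomeric SMILES of the four study drugs (MB as the chloride salt)
DRUG_SMILES = {
    "FU": "O=C1NC(=O)NC=C1F",
    "PF": "Nc1ccc2nc3ccc(N)cc3cc2c1",
    "MB": "C[N+](C)=C1C=CC2=NC3=CC=C(N(C)C)C=C3SC2=C1.[Cl-]",
    "DOX": (
        "CC1C(C(CC(O1)OC2CC(CC3=C2C(=C4C(=C3O)C(=O)C5=C(C4=O)C(=CC=C5)OC)O)"
        "(C(=O)CO)O)N)O"
    ),
}

#: PubChem compound identifiers of the reference records
DRUG_CIDS = {"FU": 3385, "PF": 7099, "MB": 6099, "DOX": 31703}

DRUG_FORMULAS = {
    "FU": "C4H3FN2O2",
    "PF": "C13H11N3",
    "MB": "C16H18ClN3S",
    "DOX": "C27H29NO11",
}

_ALIASES = {
    "fu": "FU", "fluorouracil": "FU", "5-fluorouracil": "FU",
    "pf": "PF", "proflavine": "PF",
    "mb": "MB", "methylene_blue": "MB", "methylene-blue": "MB",
    "dox": "DOX", "doxorubicin": "DOX",
}

#: fixed embedding seed per drug (conformers are fixtures, not samples)
_EMBED_SEEDS = {"FU": 1301, "PF": 1302, "MB": 1303, "DOX": 1304}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a geometric fixture molecule."""

    kind: str  # single_atom | dimer | hexagon_ring | tetrahedron
    element: str = "C"
    length: float = 1.42  # characteristic length, Angstrom
    seed: int = 0  # unused: fixtures are deterministic


def make_fixture(spec: FixtureSpec | str, element: str = "C",
                 length: float = 1.42,
                 forcefield: ForceField | None = None) -> Molecule:
    """Build a geometric fixture molecule with exact coordinates.

    ``spec`` may be a :class:`FixtureSpec` or just the kind string.
    """
    if isinstance(spec, str):
        spec = FixtureSpec(kind=spec, element=element, length=length)
    el, L = spec.element, spec.length
    if spec.kind == "single_atom":
        coords = [[0.0, 0.0, 0.0]]
        elements = [el]
    elif spec.kind == "dimer":
        coords = [[-L / 2, 0.0, 0.0], [L / 2, 0.0, 0.0]]
        elements = [el, el]
    elif spec.kind == "hexagon_ring":
        # regular hexagon of side L in the z=0 plane (circumradius = L)
        coords = [
            [L * math.cos(k * math.pi / 3), L * math.sin(k * math.pi / 3), 0.0]
            for k in range(6)
        ]
        elements = [el] * 6
    elif spec.kind == "tetrahedron":
        # regular tetrahedron with edge L
        s = L / math.sqrt(2.0) / 2.0
        coords = [[s, s, s], [s, -s, -s], [-s, s, -s], [-s, -s, s]]
        elements = [el] * 4
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    return Molecule(f"{spec.kind}({el})", elements, coords, forcefield=forcefield)


def canonical_drug_name(name: str) -> str:
    key = name.strip().lower().replace(" ", "_")
    if key in _ALIASES:
        return _ALIASES[key]
    if name.upper() in DRUG_SMILES:
        return name.upper()
    raise KeyError(f"unknown drug {name!r}; known: {sorted(DRUG_SMILES)}")


@functools.lru_cache(maxsize=None)
def _embedded_conformer(drug: str) -> tuple[tuple[str, ...], bytes]:
    """Lowest-energy synthetic conformer of a drug.

    Mirrors how public small-molecule databases produce their single 3D
    record: embed an ensemble of ETKDG conformers (count scaled with
    the number of rotatable bonds), relax each with MMFF94s with the
    Coulomb term disabled (vacuum electrostatics would fold flexible
    molecules into unrepresentative H-bonded balls), and keep the
    lowest-energy conformer.  Falls back to UFF when MMFF parameters
    are missing.  Deterministic for a fixed RDKit version.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem, rdMolDescriptors

    mol = Chem.MolFromSmiles(DRUG_SMILES[drug])
    mol = Chem.AddHs(mol)
    n_rot = rdMolDescriptors.CalcNumRotatableBonds(mol)
    n_confs = min(48, 8 + 5 * n_rot)
    params = AllChem.ETKDGv3()
    params.randomSeed = _EMBED_SEEDS[drug]
    params.numThreads = 1
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_confs, params=params)
    if len(conf_ids) == 0:
        raise RuntimeError(f"conformer embedding failed for {drug}")
    best_id, best_e = None, np.inf
    try:
        props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant="MMFF94s")
        props.SetMMFFEleTerm(False)
        for cid in conf_ids:
            field = AllChem.MMFFGetMoleculeForceField(mol, props, confId=cid)
            field.Minimize(maxIts=2000)
            e = field.CalcEnergy()
            if e < best_e:
                best_id, best_e = cid, e
    except Exception:
        best_id = None
    if best_id is None:  # MMFF cannot type this molecule: relax with UFF
        for cid in conf_ids:
            field = AllChem.UFFGetMoleculeForceField(mol, confId=cid)
            field.Minimize(maxIts=2000)
            e = field.CalcEnergy()
            if e < best_e:
                best_id, best_e = cid, e
    conf = mol.GetConformer(best_id)
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
          conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())]
    )
    return elements, coords.tobytes()


def drug_molecule(name: str, forcefield: ForceField | None = None) -> Molecule:
    """A study drug as a rigid :class:`Molecule` (synthetic conformer).

    Accepts short codes (FU, PF, MB, DOX) or full names.  The conformer
    is deterministic for a given RDKit version; see the module
    docstring for how it is generated.
    """
    drug = canonical_drug_name(name)
    elements, blob = _embedded_conformer(drug)
    coords = np.frombuffer(blob).reshape(len(elements), 3)
    return Molecule(drug, list(elements), coords, forcefield=forcefield)


def fetch_pubchem(cid: int, cache_dir: str | Path) -> Path:
    """Download (once) the PubChem 3D SDF for ``cid`` into ``cache_dir``.

    Only needed to rerun the reference workflows against the original
    database records; the test suite never requires network access.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    out = cache_dir / f"CID_{cid}.sdf"
    if out.exists():
        return out
    url = (
        "https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound/cid/"
        f"{cid}/record/SDF?record_type=3d"
    )
    try:
        from urllib.request import urlopen

        with urlopen(url, timeout=60) as resp:
            data = resp.read()
    except Exception as exc:
        raise RuntimeError(
            f"could not fetch PubChem CID {cid} ({exc}); download "
            f"{url} manually and save it as {out}"
        ) from exc
    out.write_bytes(data)
    digest = hashlib.sha256(data).hexdigest()
    (cache_dir / f"CID_{cid}.sha256").write_text(digest + "\n")
    return out
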