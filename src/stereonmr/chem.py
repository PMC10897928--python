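"""Molecular data model shared by every scoring stage.

Holds the formula arithmetic used to check an HRESIMS assignment, the
enumeration of relative configurations for a molecule with several unknown
stereocenters, Boltzmann weighting and population filtering of conformer
ensembles, and multi-record XYZ / SDF ensemble I/O.

A *relative* configuration fixes only the R*/S* pattern across centers: a
structure and its mirror image give identical isotropic and anisotropic NMR
observables, so for n centers there are 2**(n-1) distinguishable candidates,
obtained here by pinning the first center to R*.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import (
    COVALENT_RADIUS,
    DBE_DIVALENT,
    DBE_MONOVALENT,
    DBE_TETRAVALENT,
    DBE_TRIVALENT,
    ELECTRON_MASS_DA,
    MONOISOTOPIC_MASS,
    R_KCAL,
)

__all__ = [
    "MolecularFormula",
    "Atom",
    "Conformer",
    "ConformerEnsemble",
    "StereoConfiguration",
    "parse_formula",
    "monoisotopic_mass",
    "degrees_of_unsaturation",
    "enumerate_relative_configurations",
    "boltzmann_weights",
    "filter_low_population",
    "read_ensemble",
    "write_ensemble",
    "internuclear_vector",
    "bond_graph",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map; only known elements with positive counts."""

    element_counts: dict[str, int]

    def __post_init__(self) -> None:
        for el, n in self.element_counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if n <= 0:
                raise ValueError(f"non-positive count for {el}: {n}")

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C28H28O6N4"``."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        if not m.group(0):
            break
        el = m.group(1)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula | str, charge: int = 0) -> float:
    """Monoisotopic mass in Da (m/z for ``charge != 0``).

    Sums most-abundant-isotope atomic masses; for an ion the electron
    mass is added/removed per charge and the result divided by ``|charge|``,
    matching how high-resolution MS "calcd" values are reported.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in f.element_counts.items())
    if charge:
        mass -= charge * ELECTRON_MASS_DA
        mass /= abs(charge)
    return mass


def degrees_of_unsaturation(f: MolecularFormula | str) -> int:
    """Ring-plus-double-bond equivalents: DBE = C - H/2 - X/2 + N/2 + 1."""
    if isinstance(f, str):
        f = parse_formula(f)
    c = h = n = 0
    for el, cnt in f.element_counts.items():
        if el in DBE_TETRAVALENT:
            c += cnt
        elif el in DBE_MONOVALENT:
            h += cnt
        elif el in DBE_TRIVALENT:
            n += cnt
        elif el in DBE_DIVALENT:
            pass  # divalent atoms do not change DBE
        else:
            raise ValueError(f"no DBE valence rule for element {el}")
    dbe = c - h / 2 + n / 2 + 1
    if dbe < 0 or abs(dbe - round(dbe)) > 1e-9:
        raise ValueError(f"non-integral or negative DBE {dbe} for formula")
    return int(round(dbe))


@dataclass(frozen=True)
class StereoConfiguration:
    """An R*/S* parity pattern over named stereocenters.

    ``name`` follows the RC1..RCm convention used when candidates are
    enumerated; parities are relative (first enumerated center pinned R*).
    """

    center_labels: tuple[str, ...]
    parities: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.center_labels) != len(self.parities):
            raise ValueError("parities length must equal center count")
        bad = set(self.parities) - {"R*", "S*"}
        if bad:
            raise ValueError(f"parities must be 'R*'/'S*', got {bad}")

    def describe(self) -> str:
        body = ", ".join(
            f"{c}:{p}" for c, p in zip(self.center_labels, self.parities)
        )
        return f"{self.name or 'configuration'} ({body})"


def enumerate_relative_configurations(
    centers: list[str] | tuple[str, ...],
) -> list[StereoConfiguration]:
    """All 2**(n-1) relative configurations over ``centers``.

    The first center is pinned to R* (enantiomeric pairs collapse onto one
    candidate); the remaining centers run through MSB-first binary counting
    with 0 -> R* and 1 -> S*, so RC1 is all-R* and the last candidate has
    every free center S*.
    """
    centers = tuple(centers)
    if not centers:
        raise ValueError("at least one stereocenter required")
    n_free = len(centers) - 1
    out = []
    for i in range(2 ** n_free):
        bits = [(i >> (n_free - 1 - b)) & 1 for b in range(n_free)]
        parities = ("R*",) + tuple("S*" if b else "R*" for b in bits)
        out.append(StereoConfiguration(centers, parities, name=f"RC{i + 1}"))
    return out


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    position: np.ndarray  # Angstrom, shape (3,)
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, float))
        if not self.label:
            object.__setattr__(self, "label", f"{self.element}{self.index}")


@dataclass
class Conformer:
    atoms: list[Atom]
    relative_energy: float = 0.0  # kcal/mol
    label: str = ""

    def __post_init__(self) -> None:
        self._by_label = {a.label: a for a in self.atoms}
        if len(self._by_label) != len(self.atoms):
            raise ValueError("duplicate atom labels within conformer")

    def atom(self, label: str) -> Atom:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no atom labelled {label!r}") from None

    def has_atom(self, label: str) -> bool:
        return label in self._by_label

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def transformed(self, matrix: np.ndarray, label: str | None = None) -> "Conformer":
        """Apply a 3x3 linear map (rotation/reflection) to all coordinates."""
        atoms = [
            Atom(a.index, a.element, matrix @ a.position, a.label)
            for a in self.atoms
        ]
        return Conformer(atoms, self.relative_energy, label or self.label)


@dataclass
class ConformerEnsemble:
    """Weighted conformers of one candidate configuration.

    All conformers must share atom count, element sequence and index order;
    weights live on the probability simplex.
    """

    configuration: StereoConfiguration | None
    conformers: list[Conformer]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("ensemble needs at least one conformer")
        ref = [(a.index, a.element) for a in self.conformers[0].atoms]
        for c in self.conformers[1:]:
            if [(a.index, a.element) for a in c.atoms] != ref:
                raise ValueError(
                    "conformers differ in atom count, elements or index order"
                )
        if self.weights is None:
            self.weights = boltzmann_weights(
                [c.relative_energy for c in self.conformers]
            )
        self.weights = np.asarray(self.weights, float)
        if len(self.weights) != len(self.conformers):
            raise ValueError("weights length must equal conformer count")
        if np.any(self.weights < -1e-12) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be a probability simplex vector")

    def __len__(self) -> int:
        return len(self.conformers)

    def transformed(self, matrix: np.ndarray) -> "ConformerEnsemble":
        return ConformerEnsemble(
            self.configuration,
            [c.transformed(matrix) for c in self.conformers],
            self.weights.copy(),
        )


def boltzmann_weights(
    energies: list[float] | np.ndarray, temperature: float = 300.0
) -> np.ndarray:
    """Simplex weights w_i ∝ exp(-E_i / RT), energies in kcal/mol."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    e = np.asarray(energies, float)
    if e.size == 0:
        raise ValueError("empty energy list")
    w = np.exp(-(e - e.min()) / (R_KCAL * temperature))
    return w / w.sum()


def filter_low_population(
    ensemble: ConformerEnsemble, threshold: float = 0.05
) -> ConformerEnsemble:
    """Drop conformers with population <= threshold and renormalise."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    keep = ensemble.weights > threshold
    if not keep.any():
        raise ValueError("population filter removed every conformer")
    if keep.all():
        return ensemble
    w = ensemble.weights[keep]
    return ConformerEnsemble(
        ensemble.configuration,
        [c for c, k in zip(ensemble.conformers, keep) if k],
        w / w.sum(),
    )


def internuclear_vector(
    conformer: Conformer, i: str, j: str
) -> tuple[np.ndarray, float]:
    """Unit vector i->j and distance in Angstrom."""
    a, b = conformer.atom(i), conformer.atom(j)
    v = b.position - a.position
    r = float(np.linalg.norm(v))
    if r <= 0:
        raise ValueError(f"atoms {i} and {j} are coincident")
    return v / r, r


# ---------------------------------------------------------------------------
# ensemble I/O
# ---------------------------------------------------------------------------

_ENERGY_RE = re.compile(r"E\s*=\s*([-+0-9.eE]+)")


def _parse_xyz(path: Path) -> list[Conformer]:
    lines = path.read_text().splitlines()
    conformers: list[Conformer] = []
    pos = 0
    rec = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        natoms = int(lines[pos].strip())
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        m = _ENERGY_RE.search(comment)
        energy = float(m.group(1)) if m else 0.0
        atoms = []
        for k, ln in enumerate(lines[pos + 2 : pos + 2 + natoms], start=1):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"malformed XYZ atom line: {ln!r}")
            label = parts[4] if len(parts) > 4 else ""
            atoms.append(
                Atom(k, parts[0], [float(x) for x in parts[1:4]], label)
            )
        if len(atoms) != natoms:
            raise ValueError("truncated XYZ record")
        rec += 1
        label = comment.strip() or f"conf{rec}"
        # strip any E= clause from the label so round-trips stay stable
        label = _ENERGY_RE.sub("", label).strip() or f"conf{rec}"
        conformers.append(Conformer(atoms, energy, label))
        pos += 2 + natoms
    if not conformers:
        raise ValueError(f"no XYZ records in {path}")
    return conformers


def _parse_sdf(path: Path, energy_field: str) -> list[Conformer]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    conformers = []
    for rec, mol in enumerate(supplier, start=1):
        if mol is None:
            raise ValueError(f"unparsable SDF record {rec} in {path}")
        conf = mol.GetConformer()
        atoms = []
        for k, at in enumerate(mol.GetAtoms(), start=1):
            p = conf.GetAtomPosition(at.GetIdx())
            atoms.append(Atom(k, at.GetSymbol(), [p.x, p.y, p.z]))
        energy = 0.0
        if mol.HasProp(energy_field):
            energy = float(mol.GetProp(energy_field))
        label = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        conformers.append(Conformer(atoms, energy, label or f"conf{rec}"))
    if not conformers:
        raise ValueError(f"no SDF records in {path}")
    return conformers


def read_ensemble(
    path: str | Path,
    fmt: str | None = None,
    energies: str | Path | dict[str, float] | None = None,
    configuration: StereoConfiguration | None = None,
    temperature: float = 300.0,
    energy_field: str = "energy_kcal",
) -> ConformerEnsemble:
    """Read a multi-record XYZ or multi-molecule SDF conformer ensemble.

    Energies (kcal/mol) come from the XYZ comment line (``E=<value>``), the
    SDF property ``energy_field``, or an external 2-column CSV / mapping of
    conformer label -> energy; weights are Boltzmann at ``temperature``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() == ".sdf" else "xyz"
    fmt = fmt.lower()
    if fmt == "xyz":
        conformers = _parse_xyz(path)
    elif fmt == "sdf":
        conformers = _parse_sdf(path, energy_field)
    else:
        raise ValueError(f"unsupported ensemble format {fmt!r}")

    if energies is not None:
        if not isinstance(energies, dict):
            import pandas as pd

            tab = pd.read_csv(energies)
            energies = dict(zip(tab.iloc[:, 0].astype(str), tab.iloc[:, 1]))
        conformers = [
            replace_energy(c, float(energies[c.label])) for c in conformers
        ]
    ens = ConformerEnsemble(
        configuration,
        conformers,
        boltzmann_weights([c.relative_energy for c in conformers], temperature),
    )
    return ens


def replace_energy(c: Conformer, energy: float) -> Conformer:
    return Conformer(c.atoms, energy, c.label)


def write_ensemble(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write as multi-record XYZ with energies on the comment line.

    Non-default atom labels are preserved in a fifth column, which the
    reader restores; plain 4-column XYZ from other tools parses fine.
    """
    path = Path(path)
    out = []
    for c in ensemble.conformers:
        out.append(str(len(c.atoms)))
        out.append(f"{c.label}  E={c.relative_energy:.6f}")
        for a in c.atoms:
            x, y, z = a.position
            line = f"{a.element:<2s} {x:18.10f} {y:18.10f} {z:18.10f}"
            if a.label != f"{a.element}{a.index}":
                line += f" {a.label}"
            out.append(line)
    path.write_text("\n".join(out) + "\n")


def bond_graph(conformer: Conformer, scale: float = 1.3):
    """Covalent bond graph from a distance heuristic.

    Two atoms are bonded when their distance is below ``scale`` times the sum
    of their single-bond covalent radii. Returns a networkx Graph whose nodes
    are atom labels; used by the NOE bond-separation filter when no explicit
    connectivity (SDF) is available.
    """
    import networkx as nx

    g = nx.Graph()
    atoms = conformer.atoms
    g.add_nodes_from(a.label for a in atoms)
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            ri = COVALENT_RADIUS.get(atoms[i].element, 0.77)
            rj = COVALENT_RADIUS.get(atoms[j].element, 0.77)
            d = np.linalg.norm(atoms[i].position - atoms[j].position)
            if d < scale * (ri + rj):
                g.add_edge(atoms[i].label, atoms[j].label)
    return g


def mirror_matrix(axis: int = 0) -> np.ndarray:
    """Reflection through the plane normal to the given Cartesian axis."""
    m = np.eye(3)
    m[axis, axis] = -1.0
    return m
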