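"""Molecular structure model, PDB round-tripping and residue chemistry.

The coordinate model is deliberately small: an ordered hierarchy of
chains -> residues -> heavy atoms, in Angstrom, with author residue
numbering.  Hydrogens are dropped on input; every geometric criterion
downstream (surface area, hydrogen bonds, salt bridges, contacts) is
heavy-atom based.

Residue chemistry -- the polarity classification, the formal charge class
of side-chain atoms, van der Waals radii, hydrogen-bond donor/acceptor
roles and reference maximal accessible areas -- is loaded from the
versioned plain-text table shipped with the package
(``data/residue_chemistry.tsv``) so that alternative conventions are one
file edit away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "FormatError",
    "classify_residue",
    "charged_atoms",
    "one_letter",
    "three_letter",
    "vdw_radius",
    "read_pdb",
    "write_pdb",
    "read_fasta",
    "CHEMISTRY",
]


class FormatError(ValueError):
    """Raised for malformed or empty coordinate/sequence files."""


# ---------------------------------------------------------------------------
# chemistry tables
# ---------------------------------------------------------------------------

def _load_chemistry() -> dict[str, dict[str, str]]:
    tables: dict[str, dict[str, str]] = {}
    text = (
        resources.files("bundledock").joinpath("data/residue_chemistry.tsv").read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        table, key, value = line.split("\t")
        tables.setdefault(table, {})[key] = value
    return tables


CHEMISTRY = _load_chemistry()

#: fallback polarity class for non-standard residue names
FALLBACK_POLARITY = "nonpolar"
#: fallback van der Waals radius (Angstrom) for unlisted elements
FALLBACK_VDW = 1.70

_ONE = CHEMISTRY["one_letter"]
_THREE = {v: k for k, v in _ONE.items()}
STANDARD_RESIDUES = tuple(sorted(_ONE))


def one_letter(resname: str) -> str:
    """3-letter -> 1-letter code; 'X' for non-standard names."""
    return _ONE.get(resname.upper(), "X")


def three_letter(code: str) -> str:
    """1-letter -> 3-letter code."""
    return _THREE[code.upper()]


def vdw_radius(element: str) -> float:
    return float(CHEMISTRY["vdw"].get(element.upper(), FALLBACK_VDW))


def classify_residue(resname: str) -> str:
    """Polarity class of a residue name: 'polar', 'nonpolar' or 'charged'.

    The scheme is a declared convention (His charged, Gly polar), stored in
    the chemistry table; non-standard names fall back to 'nonpolar' with a
    warning.
    """
    cls = CHEMISTRY["polarity"].get(resname.upper())
    if cls is None:
        warnings.warn(
            f"unknown residue name {resname!r}; classified as {FALLBACK_POLARITY}",
            stacklevel=2,
        )
        return FALLBACK_POLARITY
    return cls


# ---------------------------------------------------------------------------
# coordinate model
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """A heavy atom: PDB name, element, coordinates (Angstrom)."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")

    @property
    def vdw_radius(self) -> float:
        return vdw_radius(self.element)

    @property
    def formal_charge_class(self) -> str:
        # set per-residue via charged_atoms(); an isolated Atom is neutral
        return "neutral"


@dataclass
class Residue:
    name: str
    seq_id: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def polarity_class(self) -> str:
        return classify_residue(self.name)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_id)


def charged_atoms(residue: Residue, terminal_charges: bool = False) -> list[tuple[Atom, int]]:
    """Side-chain atoms of ``residue`` carrying a formal charge, with sign.

    Asp/Glu carboxylate oxygens are negative; Lys NZ, Arg guanidinium
    nitrogens and (by declared convention) both His ring nitrogens are
    positive.  Chain-terminal N/OXT are neutral unless ``terminal_charges``.
    """
    table = CHEMISTRY["charge_atom"]
    out: list[tuple[Atom, int]] = []
    res = residue.name.upper()
    for atom in residue.atoms:
        sign = table.get(f"{res}:{atom.name}")
        if sign is not None:
            out.append((atom, +1 if sign == "+" else -1))
        elif terminal_charges and atom.name in ("OXT",):
            out.append((atom, -1))
    return out


class Structure:
    """Ordered chains of ordered residues; the carrier type of the package."""

    def __init__(self, chains: dict[str, list[Residue]] | None = None, metadata: str = ""):
        self.chains: dict[str, list[Residue]] = dict(chains or {})
        self.metadata = metadata
        self._validate()

    def _validate(self) -> None:
        for cid, residues in self.chains.items():
            seen: set[int] = set()
            for r in residues:
                if r.chain_id != cid:
                    raise ValueError(f"residue {r.seq_id} listed under chain {cid} but labelled {r.chain_id}")
                if r.seq_id in seen:
                    raise ValueError(f"duplicate seq_id {r.seq_id} in chain {cid}")
                seen.add(r.seq_id)

    # -- iteration ---------------------------------------------------------
    def residues(self, chain_ids: Iterable[str] | None = None) -> Iterator[Residue]:
        ids = list(chain_ids) if chain_ids is not None else list(self.chains)
        for cid in ids:
            yield from self.chains[cid]

    def atoms(self, chain_ids: Iterable[str] | None = None) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues(chain_ids):
            for atom in res.atoms:
                yield res, atom

    def coords(self, chain_ids: Iterable[str] | None = None) -> np.ndarray:
        pts = [a.coord for _, a in self.atoms(chain_ids)]
        return np.array(pts) if pts else np.empty((0, 3))

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.residues())

    # -- manipulation ------------------------------------------------------
    def copy(self) -> "Structure":
        chains = {
            cid: [
                Residue(r.name, r.seq_id, r.chain_id,
                        [Atom(a.name, a.element, a.coord.copy()) for a in r.atoms])
                for r in residues
            ]
            for cid, residues in self.chains.items()
        }
        return Structure(chains, self.metadata)

    def subset(self, chain_ids: Iterable[str]) -> "Structure":
        ids = list(chain_ids)
        missing = [c for c in ids if c not in self.chains]
        if missing:
            raise KeyError(f"chains not present: {missing}")
        sub = Structure({cid: self.chains[cid] for cid in ids}, self.metadata)
        return sub.copy()

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid transform x -> R x + t applied to a copy."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        out = self.copy()
        for res in out.residues():
            for atom in res.atoms:
                atom.coord = rotation @ atom.coord + translation
        return out

    def merged(self, other: "Structure") -> "Structure":
        """Combine chains of two structures (ids must not collide)."""
        overlap = set(self.chains) & set(other.chains)
        if overlap:
            raise ValueError(f"chain id collision: {sorted(overlap)}")
        out = self.copy()
        for cid, residues in other.copy().chains.items():
            out.chains[cid] = residues
        return out


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _pick_altloc(group: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved toward altloc 'A', then input order
    def rank(a: gemmi.Atom) -> tuple[float, int]:
        return (a.occ, 1 if a.altloc in ("", "A") else 0)

    best = group[0]
    for a in group[1:]:
        if rank(a) > rank(best):
            best = a
    return best


def read_pdb(path: str | Path, model_index: int = 0) -> Structure:
    """Read one MODEL of a PDB file into a :class:`Structure`.

    HETATM records and waters are excluded; hydrogens are dropped; altloc
    groups resolve to the highest-occupancy conformer (ties to 'A').
    Residues keep author numbering, ordered as in the file (insertion-code
    ordering is preserved by the parser).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if len(st) == 0:
        raise FormatError(f"{path}: no coordinates found")
    if not 0 <= model_index < len(st):
        raise IndexError(f"model_index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    chains: dict[str, list[Residue]] = {}
    warned: set[str] = set()
    for chain in model:
        for res in chain:
            if res.het_flag == "H" or res.name in _WATER_NAMES:
                continue
            if res.name not in _ONE and res.name not in warned:
                warnings.warn(f"unknown residue name {res.name!r}; kept with fallback chemistry")
                warned.add(res.name)
            groups: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.element.name == "H" or atom.name.startswith("H"):
                    continue
                groups.setdefault(atom.name, []).append(atom)
            atoms = []
            for name, group in groups.items():
                a = _pick_altloc(group)
                element = a.element.name if a.element.name else name[0]
                atoms.append(Atom(name, element, np.array([a.pos.x, a.pos.y, a.pos.z])))
            if atoms:
                chains.setdefault(chain.name, []).append(
                    Residue(res.name, res.seqid.num, chain.name, atoms)
                )
    if not any(chains.values()):
        raise FormatError(f"{path}: no ATOM records")
    return Structure(chains, metadata=f"read from {path.name}, model {model_index}")


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write fixed-column ATOM records, one TER per chain, END terminator."""
    if structure.n_atoms == 0:
        raise ValueError("refusing to write an empty structure")
    path = Path(path)
    lines = []
    serial = 0
    for cid, residues in structure.chains.items():
        if residues and any(r.seq_id > 9999 for r in residues):
            raise ValueError(f"chain {cid}: residue numbering exceeds PDB field width")
        last = None
        for res in residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial % 100000:5d} {name}{'':1s}{res.name:>3s} "
                    f"{cid:1s}{res.seq_id:4d}    "
                    f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
                )
            last = res
        serial += 1
        if last is not None:
            lines.append(f"TER   {serial % 100000:5d}      {last.name:>3s} {cid:1s}{last.seq_id:4d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader for chain sequences (ids -> 1-letter strings)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seqs: dict[str, str] = {}
    name = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name is not None:
            seqs[name] += line.upper()
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return seqs
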