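"""Protein structure parsing and the atom-typing contract.

Structures arrive as single-chain PDB files that are assumed to have been
cleaned externally (hydrogens added, common deposition errors fixed).  This
module validates that contract rather than re-implementing it: it warns when
a file looks un-protonated, drops waters/hetero-atoms and alternate
locations beyond 'A', and types every atom into one of the six element
channels (C, N, O, H, S, P) used by the voxel featurization.  Residue
numbering is always the author numbering from the file, never re-indexed,
so predictions can be joined against variant tables keyed by reference
numbering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger("stabscan.structure")

#: Fixed channel ordering used across the whole codebase.
ELEMENT_CHANNELS: dict[str, int] = {"C": 0, "N": 1, "O": 2, "H": 3, "S": 4, "P": 5}
N_CHANNELS = 6

#: Canonical 20 amino acids, alphabetical one-letter order (the label order
#: of every one-hot block and classifier output in the package).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Raised when a structure cannot satisfy the parsing contract."""


@dataclass
class AtomRecord:
    """One typed atom.  ``element`` keeps the raw element symbol; atoms whose
    element is outside the six channels carry ``channel=None`` and are ignored
    by featurization (but still serialized)."""

    atom_name: str
    element: str
    coords: np.ndarray          # (3,) float, Angstrom
    residue_index: int          # author numbering
    chain_id: str
    is_hetero: bool = False

    @property
    def channel(self) -> int | None:
        return ELEMENT_CHANNELS.get(self.element)


@dataclass
class Residue:
    chain_id: str
    residue_index: int
    res_name: str               # three-letter code as deposited
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def one_letter(self) -> str | None:
        return THREE_TO_ONE.get(self.res_name)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None


@dataclass
class ResidueSite:
    """A scannable residue: canonical type with a complete N/CA/C backbone."""

    chain_id: str
    residue_index: int
    wt_aa: str                  # one-letter, in AA_ALPHABET
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray


@dataclass
class Structure:
    """A parsed single chain: residues in file order with their typed atoms."""

    source_id: str
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]


def element_channel(atom: AtomRecord | str) -> int | None:
    """Map an atom (or bare element symbol) to its input channel 0..5.

    The ordering C, N, O, H, S, P is fixed package-wide.  Elements outside
    this alphabet (metals, selenium, ...) map to ``None``: they are dropped
    from featurization, which is a documented decision rather than inferred
    intent.
    """
    element = atom if isinstance(atom, str) else atom.element
    return ELEMENT_CHANNELS.get(element.upper())


def _guess_element(atom_name: str) -> str:
    """Fallback when the PDB element column is absent: first alphabetic
    character of the stripped atom name (adequate for C/N/O/H/S/P organics)."""
    for ch in atom_name.strip().lstrip("0123456789"):
        if ch.isalpha():
            return ch.upper()
    return ""


def read_structure(path: str | Path, chain: str | None = None) -> Structure:
    """Parse one chain of a PDB file into a :class:`Structure`.

    Waters and hetero-atoms are excluded; alternate locations other than
    ''/'A' are dropped; for multi-model (NMR-style) files only model 1 is
    used, with a warning.  Residues whose name has no canonical one-letter
    mapping are skipped entirely with a logged warning.  Raises
    :class:`StructureError` when the chain is missing or no residue is
    resolvable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        pdb = parser.get_structure(path.stem, str(path))

    models = list(pdb)
    if not models:
        raise StructureError(f"{path}: no models in file")
    if len(models) > 1:
        logger.warning("%s: %d models; using model 1 only", path.name, len(models))
    model = models[0]

    chain_ids = [c.id for c in model]
    if chain is None:
        if len(chain_ids) != 1:
            raise StructureError(
                f"{path}: multiple chains {chain_ids}; specify one explicitly"
            )
        chain = chain_ids[0]
    if chain not in chain_ids:
        raise StructureError(f"{path}: chain {chain!r} not found (has {chain_ids})")

    structure = Structure(source_id=path.stem, chain_id=chain)
    n_atoms = 0
    n_hydrogens = 0
    for res in model[chain]:
        hetflag, resseq, icode = res.id
        if hetflag != " ":
            logger.info("%s: skipping hetero/water residue %s %s", path.name,
                        res.resname, resseq)
            continue
        if res.resname not in THREE_TO_ONE:
            logger.warning("%s: residue %s %d has no canonical mapping; skipped",
                           path.name, res.resname, resseq)
            continue
        out = Residue(chain_id=chain, residue_index=resseq, res_name=res.resname)
        for atom in res.get_atoms():
            altloc = atom.get_altloc()
            if altloc not in (" ", "", "A"):
                logger.info("%s: dropping altloc %r of %s/%d", path.name, altloc,
                            atom.get_name(), resseq)
                continue
            element = (atom.element or "").strip().upper() or _guess_element(atom.get_name())
            coords = np.asarray(atom.get_coord(), dtype=float)
            if not np.all(np.isfinite(coords)):
                raise StructureError(
                    f"{path}: non-finite coordinates for atom {atom.get_name()} "
                    f"in residue {resseq}")
            rec = AtomRecord(atom_name=atom.get_name(), element=element,
                             coords=coords, residue_index=resseq, chain_id=chain)
            if rec.channel is None:
                logger.warning("%s: atom %s (element %r) outside the C/N/O/H/S/P "
                               "channel alphabet; excluded from featurization",
                               path.name, rec.atom_name, element)
            out.atoms.append(rec)
            n_atoms += 1
            if element == "H":
                n_hydrogens += 1
        if out.atoms:
            structure.residues.append(out)

    if not residue_sites(structure):
        raise StructureError(f"{path}: zero resolvable residues in chain {chain}")

    if n_atoms and n_hydrogens / n_atoms < 0.05:
        logger.warning(
            "%s: only %.1f%% of atoms are hydrogens — the file may not have "
            "been protonated; featurization assumes hydrogens are present",
            path.name, 100.0 * n_hydrogens / max(n_atoms, 1))

    return structure


def residue_sites(structure: Structure) -> list[ResidueSite]:
    """Sites eligible for scanning: canonical residues with a complete
    N/CA/C backbone, in file order.  Incomplete residues are skipped with a
    log entry."""
    sites: list[ResidueSite] = []
    for res in structure.residues:
        one = res.one_letter
        if one is None:
            continue
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        if n is None or ca is None or c is None:
            logger.info("residue %s %d: incomplete backbone, skipped",
                        res.res_name, res.residue_index)
            continue
        sites.append(ResidueSite(chain_id=res.chain_id,
                                 residue_index=res.residue_index, wt_aa=one,
                                 n=n.coords, ca=ca.coords, c=c.coords))
    return sites


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write ATOM records (PDB fixed-width, coordinates to 3 decimals)."""
    lines = []
    serial = 1
    for res in structure.residues:
        for a in res.atoms:
            name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
            x, y, z = a.coords
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {res.res_name:<3s} "
                f"{res.chain_id:1s}{res.residue_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{a.element:>2s}\n")
            serial += 1
    lines.append("END\n")
    Path(path).write_text("".join(lines))
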