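"""Typed PDB structure model for binding-site water analysis.

Crystal structures arrive as fixed-column PDB files carrying, per atom, the
three columns the downstream features depend on: coordinates, occupancy and
the temperature B-factor.  Parsing goes through :mod:`gemmi`; the result is
flattened into a list of :class:`AtomRecord` with an explicit *role*
(protein / ligand / water / other) so that pocket definition, density counts
and surface-area contexts never have to re-derive atom classes.

Waters are reduced to their oxygen atom: every water-water and water-protein
distance in the pipeline is an oxygen-oxygen or oxygen-heavy-atom distance.
Alternate conformations are collapsed to the highest-occupancy conformer
(ties broken by altloc identifier), and only the first MODEL of a
multi-model file is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

#: Residue names recognised as water by default (PDB dialects).
WATER_RESIDUES: frozenset[str] = frozenset({"HOH", "WAT", "DOD"})

ROLES = ("protein", "ligand", "water", "other")


class PDBParseError(ValueError):
    """A coordinate record could not be interpreted."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a crystal structure.

    ``position`` is in Å; ``occupancy`` is a fraction in [0, 1];
    ``b_factor`` is the crystallographic temperature factor in Å².
    """

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: tuple[float, float, float]
    occupancy: float
    b_factor: float
    role: str

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"atom {self.serial}: non-finite coordinates {self.position}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.serial}: occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0.0:
            raise ValueError(f"atom {self.serial}: negative B-factor {self.b_factor}")
        if self.role not in ROLES:
            raise ValueError(f"atom {self.serial}: unknown role {self.role!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class StructureModel:
    """A parsed crystal structure: an ordered atom list grouped by role."""

    structure_id: str
    atoms: list[AtomRecord]
    resolution: float | None = None

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(serials) != len(set(serials)):
            raise ValueError(f"{self.structure_id}: duplicate atom serial numbers")

    def atoms_with_role(self, role: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.role == role]

    @property
    def protein_atoms(self) -> list[AtomRecord]:
        return self.atoms_with_role("protein")

    @property
    def ligand_atoms(self) -> list[AtomRecord]:
        return self.atoms_with_role("ligand")

    @property
    def water_atoms(self) -> list[AtomRecord]:
        return self.atoms_with_role("water")

    def coords(self, role: str | None = None) -> np.ndarray:
        """(n, 3) coordinate array, optionally restricted to one role."""
        atoms = self.atoms if role is None else self.atoms_with_role(role)
        if not atoms:
            return np.empty((0, 3), dtype=float)
        return np.array([a.position for a in atoms], dtype=float)


@dataclass
class WaterSite:
    """A water oxygen with its (optional) conservation label.

    ``ned`` is the nearest Euclidean distance (Å) to any water oxygen of the
    superposed homolog; ``None`` until labeling has run, ``math.inf`` when the
    homolog contributes no partner water.  ``label`` is ``"CWM"`` (conserved),
    ``"FWM"`` (free) or ``"unlabeled"`` for waters outside the binding pocket.
    """

    source_id: str
    chain_id: str
    residue_number: int
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    ned: float | None = None
    label: str = "unlabeled"
    in_pocket: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.ned is not None and self.ned < 0:
            raise ValueError("ned must be non-negative")


def _ligand_matcher(selector: str):
    """Build a predicate from a ligand selector.

    Two forms are accepted: a bare residue name (``"LIG"``, ``"5PA"``) or a
    chain/residue-number pair (``"A/401"``).
    """
    selector = selector.strip()
    if "/" in selector:
        chain, resnum_s = selector.split("/", 1)
        try:
            resnum = int(resnum_s)
        except ValueError as exc:
            raise ValueError(f"bad ligand selector {selector!r}: residue number not an integer") from exc

        def match(residue_name: str, chain_id: str, residue_number: int) -> bool:
            return chain_id == chain and residue_number == resnum

    else:
        name = selector.upper()

        def match(residue_name: str, chain_id: str, residue_number: int) -> bool:
            return residue_name.upper() == name

    return match


def _scan_coordinate_lines(path: Path) -> int:
    """Pre-validate ATOM/HETATM records; return their count.

    gemmi is forgiving about malformed numeric fields, so the fixed columns
    holding coordinates, occupancy and B-factor are checked here to be able
    to report the offending line number.
    """
    n = 0
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            n += 1
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}: line {lineno}: truncated coordinate record")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                txt = line[lo:hi].strip()
                try:
                    float(txt)
                except ValueError:
                    raise PDBParseError(
                        f"{path}: line {lineno}: unparseable {what} coordinate {txt!r}"
                    ) from None
    return n


def _collapse_altlocs(atoms: Iterable[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, tie -> first altloc."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    order: list[str] = []
    for atom in atoms:
        if atom.name not in by_name:
            order.append(atom.name)
        by_name.setdefault(atom.name, []).append(atom)
    kept = []
    for name in order:
        group = sorted(by_name[name], key=lambda a: (-a.occ, a.altloc or "A"))
        kept.append(group[0])
    return kept


def parse_pdb(
    path: str | Path,
    ligand_selector: str | None = None,
    water_residues: frozenset[str] = WATER_RESIDUES,
    structure_id: str | None = None,
) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    ATOM records become role ``protein``; HETATM waters become ``water``
    (oxygen only — hydrogens and deuteriums of the water are dropped);
    HETATM matching *ligand_selector* become ``ligand``; everything else is
    ``other``.  Occupancy and B-factor columns are preserved verbatim.
    Only the first MODEL of a multi-model file is read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _scan_coordinate_lines(path) == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")

    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise PDBParseError(f"{path}: no coordinate model")
    model = st[0]

    match_ligand = _ligand_matcher(ligand_selector) if ligand_selector else None
    records: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            resname = residue.name.upper()
            is_het = residue.het_flag == "H"
            is_water = resname in water_residues
            for atom in _collapse_altlocs(residue):
                element = atom.element.name
                if is_water:
                    # retain the oxygen as the site position
                    if element not in ("O", "OX") and not atom.name.startswith("O"):
                        continue
                    role = "water"
                elif not is_het:
                    role = "protein"
                elif match_ligand and match_ligand(resname, chain.name, residue.seqid.num):
                    role = "ligand"
                else:
                    role = "other"
                records.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=element,
                        residue_name=resname,
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        position=tuple(round(c, 3) for c in atom.pos.tolist()),
                        occupancy=round(float(atom.occ), 2),
                        b_factor=round(float(atom.b_iso), 2),
                        role=role,
                    )
                )
    if not records:
        raise PDBParseError(f"{path}: no usable atoms")
    if ligand_selector is not None and not any(r.role == "ligand" for r in records):
        raise ValueError(f"{path}: ligand selector {ligand_selector!r} matched no atoms")
    resolution = float(st.resolution) if st.resolution else None
    return StructureModel(
        structure_id=structure_id or path.stem,
        atoms=records,
        resolution=resolution,
    )


def water_sites(model: StructureModel) -> list[WaterSite]:
    """One :class:`WaterSite` per water oxygen, ordered by (chain, residue number)."""
    sites = [
        WaterSite(
            source_id=model.structure_id,
            chain_id=a.chain_id,
            residue_number=a.residue_number,
            position=a.xyz,
            occupancy=a.occupancy,
            b_factor=a.b_factor,
        )
        for a in model.water_atoms
    ]
    sites.sort(key=lambda s: (s.chain_id, s.residue_number))
    return sites


# ---------------------------------------------------------------------------
# output


def write_report(
    rows: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    float_precision: int = 3,
) -> None:
    """Write tabular records as TSV with a fixed column order.

    Floats are formatted to *float_precision* decimals so that repeated runs
    with identical inputs are byte-identical.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}f")


_PDB_LINE = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resnum:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2s}\n"
)


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: element right-justified in columns 13-14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(model: StructureModel, path: str | Path, b_factor_override: Mapping[int, float] | None = None) -> None:
    """Serialise a :class:`StructureModel` back to fixed-column PDB.

    *b_factor_override* maps atom serials to replacement B-factors, used to
    encode labels into the B column for visualisation.
    """
    overrides = b_factor_override or {}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"REMARK   1 {model.structure_id}\n")
        for a in model.atoms:
            record = "ATOM" if a.role == "protein" else "HETATM"
            fh.write(
                _PDB_LINE.format(
                    record=record,
                    serial=a.serial,
                    name=_format_atom_name(a.name, a.element),
                    altloc=" ",
                    resname=a.residue_name,
                    chain=a.chain_id[:1] or "A",
                    resnum=a.residue_number,
                    icode=" ",
                    x=a.position[0],
                    y=a.position[1],
                    z=a.position[2],
                    occ=a.occupancy,
                    b=overrides.get(a.serial, a.b_factor),
                    element=a.element[:2],
                )
            )
        fh.write("END\n")


def transform_model(model: StructureModel, rotation: np.ndarray, translation: np.ndarray) -> StructureModel:
    """Return a copy of *model* with every atom mapped through x -> R x + t."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    atoms = [
        replace(a, position=tuple(rotation @ a.xyz + translation))
        for a in model.atoms
    ]
    return StructureModel(model.structure_id, atoms, model.resolution)
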