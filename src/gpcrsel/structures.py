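"""Atomic structures with generic residue numbers (GRNs).

This module owns the in-memory representation used by every geometric
computation in the package: an :class:`AnnotatedStructure` is an ordered set
of chains of :class:`ResidueRecord` objects, each residue optionally carrying
a Ballesteros-Weinstein generic residue number of the form ``helix.position``
(e.g. ``"5.50"``, the most conserved TM5 residue).  GRNs are attached from an
external table, never computed by alignment.

File parsing and writing go through gemmi; alternate locations are resolved
to the highest-occupancy conformer and waters are dropped on load.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import gemmi
import numpy as np

from .errors import (
    ChainLookupError,
    ConsistencyError,
    GrnLookupError,
    StructureFormatError,
)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# BW numbering runs with the sequence, which alternates direction through the
# membrane: odd-numbered helices (TM1, 3, 5, 7) enter from the extracellular
# side, even-numbered ones (TM2, 4, 6) from the cytosol.
def helix_ascending_is_cytosolic(helix: int) -> bool:
    """True if increasing GRN position moves toward the cytosol for ``helix``."""
    return helix % 2 == 1


def parse_grn(grn: str) -> tuple[int, int]:
    """Parse ``"t.nn"`` into ``(helix, position)``, validating ranges."""
    try:
        helix_str, pos_str = grn.split(".")
        helix, pos = int(helix_str), int(pos_str)
    except (ValueError, AttributeError) as exc:
        raise ConsistencyError(f"malformed GRN {grn!r}") from exc
    if not (1 <= helix <= 8 and 1 <= pos <= 99):
        raise ConsistencyError(f"GRN {grn!r} out of range (helix 1-8, position 1-99)")
    return helix, pos


@dataclass
class AtomRecord:
    """One atom: PDB atom name, element symbol, coordinates in angstroms."""

    atom_name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ConsistencyError(f"atom {self.atom_name!r}: coord must be a finite 3-vector")
        if not self.atom_name:
            raise ConsistencyError("atom_name must be non-empty")


@dataclass
class ResidueRecord:
    """One residue: author numbering, atoms keyed by name, optional GRN."""

    chain_id: str
    author_seq_id: int
    residue_name: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)
    icode: str = ""
    grn: Optional[str] = None

    def __post_init__(self) -> None:
        if self.grn is not None:
            parse_grn(self.grn)

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.author_seq_id, self.icode)

    @property
    def grn_helix(self) -> Optional[int]:
        return parse_grn(self.grn)[0] if self.grn else None

    @property
    def grn_position(self) -> Optional[int]:
        return parse_grn(self.grn)[1] if self.grn else None

    def atom(self, name: str) -> Optional[AtomRecord]:
        return self.atoms.get(name)

    def ca(self) -> Optional[AtomRecord]:
        return self.atoms.get("CA")


@dataclass
class AnnotatedStructure:
    """A receptor (and optionally its Galpha chain) with GRN annotations."""

    structure_id: str
    chains: dict[str, list[ResidueRecord]]
    receptor_chain: str
    galpha_chain: Optional[str] = None
    coupling_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.receptor_chain not in self.chains:
            raise ChainLookupError(f"receptor chain {self.receptor_chain!r} absent")
        for cid, residues in self.chains.items():
            seen: set[str] = set()
            for res in residues:
                if res.grn is not None:
                    if res.grn in seen:
                        raise ConsistencyError(f"duplicate GRN {res.grn} in chain {cid}")
                    seen.add(res.grn)

    @property
    def receptor_residues(self) -> list[ResidueRecord]:
        return self.chains[self.receptor_chain]

    def iter_atoms(self) -> Iterator[tuple[ResidueRecord, AtomRecord]]:
        for residues in self.chains.values():
            for res in residues:
                for atom in res.atoms.values():
                    yield res, atom

    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def find_grn(self, grn: str, chain_id: Optional[str] = None) -> ResidueRecord:
        """Return the residue carrying ``grn`` (receptor chain by default)."""
        cid = chain_id or self.receptor_chain
        if cid not in self.chains:
            raise ChainLookupError(f"chain {cid!r} absent from {self.structure_id}")
        for res in self.chains[cid]:
            if res.grn == grn:
                return res
        raise GrnLookupError(f"GRN {grn} not found in chain {cid} of {self.structure_id}")

    def copy(self) -> "AnnotatedStructure":
        chains = {
            cid: [
                replace(res, atoms={n: replace(a, coord=a.coord.copy()) for n, a in res.atoms.items()})
                for res in residues
            ]
            for cid, residues in self.chains.items()
        }
        return AnnotatedStructure(
            self.structure_id, chains, self.receptor_chain, self.galpha_chain, self.coupling_label
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AnnotatedStructure":
        """Return a copy with every coordinate mapped to ``R x + t``."""
        out = self.copy()
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        for _, atom in out.iter_atoms():
            atom.coord = rotation @ atom.coord + translation
        return out


@dataclass
class HelixSegment:
    """A contiguous run of one TM helix, ordered extracellular to cytosolic."""

    label: str
    residues: list[ResidueRecord]
    anchor_grn: str

    def __post_init__(self) -> None:
        parse_grn(self.anchor_grn)

    @property
    def helix(self) -> int:
        return parse_grn(self.anchor_grn)[0]

    def grn_positions(self) -> list[int]:
        return [r.grn_position for r in self.residues if r.grn is not None]


# ---------------------------------------------------------------------------
# reading / writing

def _convert_residue(chain_id: str, res: gemmi.Residue) -> ResidueRecord:
    atoms: dict[str, AtomRecord] = {}
    for atom in res:
        name = atom.name
        rec = AtomRecord(
            atom_name=name,
            element=atom.element.name,
            coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
            occupancy=atom.occ,
            b_factor=atom.b_iso,
        )
        # altloc policy: keep the highest-occupancy conformer, first wins ties
        if name in atoms and atoms[name].occupancy >= rec.occupancy:
            continue
        atoms[name] = rec
    icode = res.seqid.icode.strip()
    return ResidueRecord(
        chain_id=chain_id,
        author_seq_id=res.seqid.num,
        residue_name=res.name,
        atoms=atoms,
        icode=icode,
    )


def read_structure(
    path: str | Path,
    receptor_chain: str,
    galpha_chain: Optional[str] = None,
    fmt: Optional[str] = None,
    structure_id: Optional[str] = None,
    coupling_label: Optional[str] = None,
) -> AnnotatedStructure:
    """Load the named chains of a PDB or mmCIF file.

    Parameters
    ----------
    fmt
        ``"pdb"`` or ``"mmcif"``; inferred from the extension when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"no such file: {path}")
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        elif fmt.lower() == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt.lower() in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            raise ValueError(f"unknown format {fmt!r}")
        st.setup_entities()
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureFormatError(f"failed to parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path} contains no models")
    model = st[0]

    wanted = [receptor_chain] + ([galpha_chain] if galpha_chain else [])
    chains: dict[str, list[ResidueRecord]] = {}
    available = [ch.name for ch in model]
    for cid in wanted:
        if cid not in available:
            raise ChainLookupError(f"chain {cid!r} not in {path.name} (has {available})")
        residues = [
            _convert_residue(cid, res)
            for res in model[cid]
            if res.name not in _WATER_NAMES
        ]
        residues.sort(key=lambda r: (r.author_seq_id, r.icode))
        chains[cid] = residues

    return AnnotatedStructure(
        structure_id=structure_id or path.stem,
        chains=chains,
        receptor_chain=receptor_chain,
        galpha_chain=galpha_chain,
        coupling_label=coupling_label,
    )


def write_structure(s: AnnotatedStructure, path: str | Path) -> Path:
    """Write all chains of ``s`` as fixed-column PDB (1e-3 angstrom precision)."""
    if s.n_atoms() == 0:
        raise ValueError(f"refusing to write empty structure {s.structure_id}")
    st = gemmi.Structure()
    st.name = s.structure_id
    model = gemmi.Model("1")
    for cid, residues in s.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.residue_name
            gres.seqid = gemmi.SeqId(res.author_seq_id, res.icode or " ")
            for atom in res.atoms.values():
                ga = gemmi.Atom()
                ga.name = atom.atom_name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# GRN maps

GrnMap = Mapping[tuple[str, int, str], str]


def apply_grn_map(s: AnnotatedStructure, grn_map: GrnMap) -> AnnotatedStructure:
    """Return a copy of ``s`` with GRNs attached.

    Keys are ``(chain_id, author_seq_id, icode)``; every key must resolve to
    an existing residue, and no two residues of one chain may receive the
    same GRN.
    """
    out = s.copy()
    index = {res.residue_id: res for residues in out.chains.values() for res in residues}
    assigned: dict[str, set[str]] = {cid: set() for cid in out.chains}
    for residues in out.chains.values():
        for res in residues:
            if res.grn is not None:
                assigned[res.chain_id].add(res.grn)
    for key, grn in grn_map.items():
        parse_grn(grn)
        if key not in index:
            raise ConsistencyError(f"GRN map names nonexistent residue {key}")
        res = index[key]
        if grn in assigned[res.chain_id] and res.grn != grn:
            raise ConsistencyError(f"duplicate GRN {grn} in chain {res.chain_id}")
        if res.grn is not None and res.grn != grn:
            assigned[res.chain_id].discard(res.grn)
        res.grn = grn
        assigned[res.chain_id].add(grn)
    return out


def read_grn_table(path: str | Path) -> dict[tuple[str, int, str], str]:
    """Read a GRN sidecar TSV with header ``chain  author_seq_id  grn``.

    The residue number may carry a trailing insertion code (e.g. ``100A``).
    """
    mapping: dict[tuple[str, int, str], str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chain", "author_seq_id", "grn"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ConsistencyError(f"GRN table {path} must have columns {sorted(required)}")
        for row in reader:
            raw = row["author_seq_id"].strip()
            if raw and raw[-1].isalpha():
                num, icode = int(raw[:-1]), raw[-1]
            else:
                num, icode = int(raw), ""
            mapping[(row["chain"].strip(), num, icode)] = row["grn"].strip()
    return mapping


def write_grn_table(s: AnnotatedStructure, path: str | Path) -> Path:
    """Write the GRN assignments of ``s`` as the sidecar TSV format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["chain", "author_seq_id", "grn"])
        for cid, residues in s.chains.items():
            for res in residues:
                if res.grn is not None:
                    writer.writerow([cid, f"{res.author_seq_id}{res.icode}", res.grn])
    return path


# ---------------------------------------------------------------------------
# segment selection

def select_segment(
    s: AnnotatedStructure,
    label: str,
    grn_start: str,
    grn_end: str,
) -> HelixSegment:
    """Select the receptor-chain residues between two GRNs, inclusive.

    The result is ordered extracellular to cytosolic regardless of the
    sequence direction of the helix (odd helices descend into the membrane,
    even helices ascend).
    """
    h1, p1 = parse_grn(grn_start)
    h2, p2 = parse_grn(grn_end)
    if h1 != h2:
        raise ConsistencyError(f"segment bounds span helices {h1} and {h2}")
    # both bounds must resolve
    s.find_grn(grn_start)
    s.find_grn(grn_end)
    lo, hi = min(p1, p2), max(p1, p2)
    residues = [
        r
        for r in s.receptor_residues
        if r.grn_helix == h1 and lo <= r.grn_position <= hi
    ]
    residues.sort(key=lambda r: r.grn_position, reverse=not helix_ascending_is_cytosolic(h1))
    anchor_grn = f"{h1}.50"
    return HelixSegment(label=label, residues=residues, anchor_grn=anchor_grn)


def select_helix(s: AnnotatedStructure, helix: int, label: Optional[str] = None) -> HelixSegment:
    """Select every annotated residue of one helix, extracellular to cytosolic."""
    residues = [r for r in s.receptor_residues if r.grn_helix == helix]
    if not residues:
        raise GrnLookupError(f"no residues annotated on helix {helix} in {s.structure_id}")
    residues.sort(key=lambda r: r.grn_position, reverse=not helix_ascending_is_cytosolic(helix))
    return HelixSegment(label=label or f"TM{helix}", residues=residues, anchor_grn=f"{helix}.50")


# ---------------------------------------------------------------------------
# dataset manifest

@dataclass
class ManifestEntry:
    structure_id: str
    path: str
    receptor_chain: str
    galpha_chain: Optional[str] = None
    coupling_label: Optional[str] = None
    grn_table: Optional[str] = None


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a dataset manifest CSV.

    Required columns: ``structure_id, path, receptor_chain``; optional:
    ``galpha_chain, coupling_label, grn_table``.  Relative paths are resolved
    against the manifest's directory.
    """
    path = Path(path)
    base = path.parent
    entries: list[ManifestEntry] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"structure_id", "path", "receptor_chain"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ConsistencyError(f"manifest {path} must have columns {sorted(required)}")
        for row in reader:
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            grn_table = (row.get("grn_table") or "").strip() or None
            if grn_table is not None:
                gp = Path(grn_table)
                grn_table = str(gp if gp.is_absolute() else base / gp)
            entries.append(
                ManifestEntry(
                    structure_id=row["structure_id"].strip(),
                    path=str(p),
                    receptor_chain=row["receptor_chain"].strip(),
                    galpha_chain=(row.get("galpha_chain") or "").strip() or None,
                    coupling_label=(row.get("coupling_label") or "").strip() or None,
                    grn_table=grn_table,
                )
            )
    return entries


def write_manifest(entries: Sequence[ManifestEntry], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["structure_id", "path", "receptor_chain", "galpha_chain", "coupling_label", "grn_table"]
        )
        for e in entries:
            writer.writerow(
                [e.structure_id, e.path, e.receptor_chain, e.galpha_chain or "", e.coupling_label or "", e.grn_table or ""]
            )
    return path


def load_manifest_entry(entry: ManifestEntry) -> AnnotatedStructure:
    """Load one manifest row into an annotated structure (GRN table applied)."""
    s = read_structure(
        entry.path,
        receptor_chain=entry.receptor_chain,
        galpha_chain=entry.galpha_chain,
        structure_id=entry.structure_id,
        coupling_label=entry.coupling_label,
    )
    if entry.grn_table:
        s = apply_grn_map(s, read_grn_table(entry.grn_table))
    return s
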