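"""Canonical data model and readers/writers for every external format.

Positions are 1-based everywhere in the public API (matching ``A45C``
variant notation); conversion to 0-based indexing happens only inside
array code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA20_SET = frozenset(AA20)
AA_INDEX = {aa: i for i, aa in enumerate(AA20)}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class VariantParseError(ValueError):
    """Raised for a variant token outside the <letter><digits><letter> grammar."""


class FormatError(ValueError):
    """Raised for malformed input files (ragged alignments, empty structures...)."""


class QueryNotFoundError(KeyError):
    """Raised when the requested query id is absent from an alignment."""


@dataclass(frozen=True, order=True)
class Variant:
    """A single amino-acid substitution, e.g. A45C."""

    wt: str
    pos: int
    mut: str

    @property
    def is_identity(self) -> bool:
        return self.wt == self.mut

    def __str__(self) -> str:
        return f"{self.wt}{self.pos}{self.mut}"


_VARIANT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_variant(token: str) -> Variant:
    """Parse ``A45C``-style notation (case-insensitive) into a Variant.

    Raises VariantParseError for anything outside the grammar, for
    non-standard amino-acid letters (B, J, O, U, X, Z) and for position 0.
    """
    m = _VARIANT_RE.match(token.strip())
    if m is None:
        raise VariantParseError(f"malformed variant token: {token!r}")
    wt, pos_s, mut = m.group(1).upper(), m.group(2), m.group(3).upper()
    for letter in (wt, mut):
        if letter not in AA20_SET:
            raise VariantParseError(
                f"non-standard amino acid letter {letter!r} in token {token!r}"
            )
    pos = int(pos_s)
    if pos < 1:
        raise VariantParseError(f"position must be >= 1 in token {token!r}")
    return Variant(wt, pos, mut)


def parse_variant_list(text: str) -> list[Variant]:
    """Parse a comma/whitespace-separated list of variant tokens."""
    tokens = [t for t in re.split(r"[\s,;]+", text.strip()) if t]
    return [parse_variant(t) for t in tokens]


@dataclass
class Alignment:
    """A multiple sequence alignment with a designated query row."""

    query_id: str
    rows: list[tuple[str, str]]
    query_row_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment has no rows")
        length = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != length:
                raise FormatError(
                    f"ragged alignment: row {rid!r} has length {len(seq)}, "
                    f"expected {length}"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def query_aligned(self) -> str:
        return self.rows[self.query_row_index][1]

    @property
    def query_sequence(self) -> str:
        return self.query_aligned.replace("-", "").replace(".", "")

    def query_columns(self) -> list[int]:
        """0-based alignment column of each (1-based) query position."""
        return [
            c for c, ch in enumerate(self.query_aligned) if ch not in "-."
        ]

    def column(self, col: int) -> str:
        return "".join(seq[col] for _, seq in self.rows)


def read_alignment(path, query_id: str | None = None) -> Alignment:
    """Read an aligned FASTA file.

    The first record is the query unless ``query_id`` names another row.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    rows = [(rec.id, str(rec.seq).upper()) for rec in records]
    if query_id is None:
        qidx = 0
    else:
        ids = [rid for rid, _ in rows]
        if query_id not in ids:
            raise QueryNotFoundError(f"query id {query_id!r} not in {path}")
        qidx = ids.index(query_id)
    return Alignment(query_id=rows[qidx][0], rows=rows, query_row_index=qidx)


def write_alignment(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in alignment.rows:
            fh.write(f">{rid}\n{seq}\n")


def read_fasta_sequence(path) -> tuple[str, str]:
    """Read the first record of a FASTA file as (id, sequence)."""
    for rec in SeqIO.parse(str(path), "fasta"):
        return rec.id, str(rec.seq).upper()
    raise FormatError(f"no FASTA records in {path}")


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    seq_pos: int
    name: str  # three-letter code
    atoms: list[Atom] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coord for a in self.atoms if a.is_heavy]
        return np.asarray(coords, dtype=float).reshape(-1, 3)


@dataclass
class StructureModel:
    """One protein chain with typed atoms; residues ordered by number.

    ``seq_pos`` of each residue is the 1-based query-sequence position it
    maps to (PDB residue numbers by default, or an explicit mapping).
    """

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for res in self.residues:
            if res.seq_pos in seen:
                raise FormatError(
                    f"duplicate query position {res.seq_pos} in structure"
                )
            seen.add(res.seq_pos)
            for a in res.atoms:
                if not all(np.isfinite(a.coord)):
                    raise FormatError(
                        f"non-finite coordinate in residue {res.seq_pos}"
                    )
        self._by_pos = {r.seq_pos: r for r in self.residues}

    def residue_at(self, pos: int) -> Residue | None:
        return self._by_pos.get(pos)

    @property
    def positions(self) -> list[int]:
        return [r.seq_pos for r in self.residues]

    def all_heavy_coords(self) -> np.ndarray:
        blocks = [r.heavy_coords() for r in self.residues]
        blocks = [b for b in blocks if len(b)]
        if not blocks:
            return np.zeros((0, 3))
        return np.vstack(blocks)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body copy: x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        residues = []
        for res in self.residues:
            atoms = [
                Atom(a.name, a.element, tuple(rotation @ np.asarray(a.coord) + translation))
                for a in res.atoms
            ]
            residues.append(Residue(res.seq_pos, res.name, atoms))
        return StructureModel(self.chain_id, residues)


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "C"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    return name[0].upper() if name else "C"


def read_structure(
    path,
    chain_id: str | None = None,
    pos_map: dict[int, int] | None = None,
) -> StructureModel:
    """Parse a PDB file into a StructureModel.

    One chain is selected (``chain_id`` or the first chain); alternate
    locations are resolved to the highest-occupancy conformer (Biopython's
    default, first-seen on ties); HETATM records are ignored.  PDB residue
    numbers are taken as 1-based query positions unless ``pos_map``
    (pdb_resnum -> query_pos) overrides them.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    models = list(structure)
    if not models:
        raise FormatError(f"no ATOM records in {path}")
    chains = list(models[0])
    if not chains:
        raise FormatError(f"no ATOM records in {path}")
    if chain_id is not None:
        matching = [c for c in chains if c.id == chain_id]
        if not matching:
            raise FormatError(f"chain {chain_id!r} not found in {path}")
        chain = matching[0]
    else:
        chain = chains[0]

    residues: list[Residue] = []
    for res in chain:
        hetflag, resnum, _icode = res.id
        if hetflag.strip():  # skip HETATM / waters
            continue
        pos = pos_map.get(resnum) if pos_map is not None else resnum
        if pos is None:
            continue
        atoms = []
        for atom in res:  # disordered atoms yield the selected (highest-occ) child
            element = atom.element.strip() or _guess_element(atom.get_name())
            atoms.append(
                Atom(atom.get_name(), element.upper(), tuple(float(x) for x in atom.coord))
            )
        residues.append(Residue(pos, res.get_resname().strip(), atoms))
    if not residues:
        raise FormatError(f"no ATOM records in {path}")
    residues.sort(key=lambda r: r.seq_pos)
    return StructureModel(chain.id, residues)


def write_structure(structure: StructureModel, path) -> None:
    """Write a minimal single-chain PDB file (ATOM records + END)."""
    serial = 1
    lines = []
    for res in structure.residues:
        for atom in res.atoms:
            x, y, z = atom.coord
            name = atom.name
            # PDB convention: 1/2-letter element names start in column 14
            padded = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:>5d} {padded:<4s} {res.name:<3s} "
                f"{structure.chain_id:1s}{res.seq_pos:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass(frozen=True)
class SiteAnnotation:
    """An annotated functional site: ligand-binding or protein interface."""

    site_type: str  # "ligand" | "interface"
    residue_positions: frozenset[int]
    confidence_a: float = 0.0
    confidence_b: float = 0.0

    def __post_init__(self) -> None:
        if self.site_type not in ("ligand", "interface"):
            raise ValueError(f"unknown site type {self.site_type!r}")
        if not self.residue_positions:
            raise ValueError("site has no residue positions")
        if self.confidence_a < 0 or self.confidence_b < 0:
            raise ValueError("site confidences must be >= 0")


def read_sites(path) -> list[SiteAnnotation]:
    """Read site annotations from TSV: site_type, positions, conf_a, conf_b."""
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("site_type\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"expected 4 tab-separated columns, got: {line!r}")
            site_type, positions, conf_a, conf_b = parts
            sites.append(
                SiteAnnotation(
                    site_type=site_type,
                    residue_positions=frozenset(
                        int(p) for p in positions.split(",") if p
                    ),
                    confidence_a=float(conf_a),
                    confidence_b=float(conf_b),
                )
            )
    return sites


def write_sites(sites: list[SiteAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("site_type\tpositions\tconfidence_a\tconfidence_b\n")
        for s in sites:
            pos = ",".join(str(p) for p in sorted(s.residue_positions))
            fh.write(f"{s.site_type}\t{pos}\t{s.confidence_a!r}\t{s.confidence_b!r}\n")


@dataclass(frozen=True)
class LabelledVariant:
    """A variant with its protein of origin and a binary label.

    label 1 = functional/pathogenic, 0 = non-functional/neutral.
    """

    variant: Variant
    protein_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def read_labelled_variants(path) -> list[LabelledVariant]:
    """Read labelled variants from TSV: protein_id, variant, label."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            protein_id, token, label = line.split("\t")
            out.append(LabelledVariant(parse_variant(token), protein_id, int(label)))
    return out


def write_labelled_variants(lvs: list[LabelledVariant], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tvariant\tlabel\n")
        for lv in lvs:
            fh.write(f"{lv.protein_id}\t{lv.variant}\t{lv.label}\n")


@dataclass(frozen=True)
class ValidationIssue:
    variant: Variant
    reason: str


def validate_variants(
    variants: list[Variant], query_sequence: str
) -> tuple[list[Variant], list[ValidationIssue]]:
    """Check each variant against the query sequence.

    A variant passes when its position is in range and the sequence letter
    at that position equals its wild-type letter.  Failures are collected
    as issues (with both letters reported) so the run continues.
    """
    if not query_sequence:
        raise ValueError("query sequence is empty")
    valid: list[Variant] = []
    issues: list[ValidationIssue] = []
    for v in variants:
        if v.pos > len(query_sequence):
            issues.append(
                ValidationIssue(v, f"position {v.pos} beyond sequence length "
                                   f"{len(query_sequence)}")
            )
            continue
        actual = query_sequence[v.pos - 1]
        if actual != v.wt:
            issues.append(
                ValidationIssue(
                    v, f"wild-type mismatch at {v.pos}: variant says {v.wt}, "
                       f"sequence has {actual}"
                )
            )
            continue
        valid.append(v)
    return valid, issues
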