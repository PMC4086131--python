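"""Synthetic inputs with controlled statistical structure.

Everything the pipeline consumes — alignments, structures, site
annotations, labelled variant tables — can be generated here with a fixed
seed, so the full stack is testable without external data.  Class signal
is injected at the *input* level (where variants are placed and how
drastic the substitution is), never directly in feature space, so feature
extraction is exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from varmod.conservation import BLOSUM62_BACKGROUND
from varmod.core_io import (
    AA20,
    Alignment,
    Atom,
    LabelledVariant,
    ONE_TO_THREE,
    Residue,
    SiteAnnotation,
    StructureModel,
    Variant,
    write_alignment,
    write_labelled_variants,
    write_sites,
    write_structure,
)

# ideal trans-peptide internal coordinates (lengths in A, angles in degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8
_OMEGA = 180.0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Natural-extension placement: position d from the frame (a, b, c).

    |cd| = bond, angle(b, c, d) = angle_deg, dihedral(a, b, c, d) =
    torsion_deg.
    """
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # idealised tetrahedral beta-carbon from the backbone frame
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def make_backbone(
    n_residues: int,
    phi: float,
    psi: float,
    sequence: str | None = None,
    chain_id: str = "A",
    start_pos: int = 1,
    with_cb: bool = True,
) -> StructureModel:
    """Poly-residue backbone built from ideal geometry at fixed dihedrals."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    if sequence is not None and len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")

    n_atoms = np.zeros((n_residues, 3))
    ca_atoms = np.zeros((n_residues, 3))
    c_atoms = np.zeros((n_residues, 3))

    n_atoms[0] = (0.0, 0.0, 0.0)
    ca_atoms[0] = (_BOND_N_CA, 0.0, 0.0)
    ang = math.radians(_ANGLE_N_CA_C)
    c_atoms[0] = ca_atoms[0] + _BOND_CA_C * np.array(
        [-math.cos(ang), math.sin(ang), 0.0]
    )
    for i in range(1, n_residues):
        n_atoms[i] = place_atom(
            n_atoms[i - 1], ca_atoms[i - 1], c_atoms[i - 1],
            _BOND_C_N, _ANGLE_CA_C_N, psi,
        )
        ca_atoms[i] = place_atom(
            ca_atoms[i - 1], c_atoms[i - 1], n_atoms[i],
            _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA,
        )
        c_atoms[i] = place_atom(
            c_atoms[i - 1], n_atoms[i], ca_atoms[i],
            _BOND_CA_C, _ANGLE_N_CA_C, phi,
        )

    residues = []
    for i in range(n_residues):
        # carbonyl O anti to the next amide N (torsion psi + 180 about CA-C)
        o = place_atom(
            n_atoms[i], ca_atoms[i], c_atoms[i],
            _BOND_C_O, _ANGLE_CA_C_O, psi + 180.0,
        )
        letter = sequence[i] if sequence is not None else "A"
        name = ONE_TO_THREE.get(letter, "ALA")
        atoms = [
            Atom("N", "N", tuple(n_atoms[i])),
            Atom("CA", "C", tuple(ca_atoms[i])),
            Atom("C", "C", tuple(c_atoms[i])),
            Atom("O", "O", tuple(o)),
        ]
        if with_cb and name != "GLY":
            atoms.append(
                Atom("CB", "C", tuple(_cb_position(n_atoms[i], ca_atoms[i], c_atoms[i])))
            )
        residues.append(Residue(start_pos + i, name, atoms))
    return StructureModel(chain_id, residues)


def make_helix(
    n_residues: int,
    phi: float = -57.0,
    psi: float = -47.0,
    sequence: str | None = None,
    start_pos: int = 1,
) -> StructureModel:
    """Ideal alpha-helix fixture."""
    if n_residues < 6:
        raise ValueError("helix fixture needs at least 6 residues")
    return make_backbone(n_residues, phi, psi, sequence, start_pos=start_pos)


def make_strand(
    n_residues: int, phi: float = -139.0, psi: float = 135.0,
    start_pos: int = 1,
) -> StructureModel:
    """Ideal extended beta-strand fixture."""
    return make_backbone(n_residues, phi, psi, start_pos=start_pos)


def _align_to_x(structure: StructureModel) -> StructureModel:
    """Rotate so the first-to-last CA vector lies along +x, first CA at origin."""
    cas = np.array([r.atom("CA").coord for r in structure.residues])
    axis_vec = _unit(cas[-1] - cas[0])
    target = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis_vec, target)
    s = np.linalg.norm(v)
    c = float(np.dot(axis_vec, target))
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return structure.transformed(rot, -rot @ cas[0])


def make_strand_pair(
    n_per_strand: int = 8,
    separation_grid: np.ndarray | None = None,
    shift_grid: np.ndarray | None = None,
) -> StructureModel:
    """Two ideal antiparallel strands registered to maximise E assignment.

    The second strand is the first rotated 180 degrees about the strand
    axis (reversing direction and flipping carbonyls) and translated; the
    translation is chosen from a deterministic grid by running the
    secondary-structure assignment and keeping the placement with the most
    E residues.
    """
    from varmod.struct_features import assign_secondary_structure

    strand_a = _align_to_x(make_strand(n_per_strand, start_pos=1))
    flipped = strand_a.transformed(np.diag([-1.0, 1.0, -1.0]), np.zeros(3))

    if separation_grid is None:
        separation_grid = np.arange(4.0, 5.81, 0.2)
    if shift_grid is None:
        shift_grid = np.arange(-4.0, 30.01, 0.25)

    best: tuple[int, StructureModel] | None = None
    for sep in separation_grid:
        for shift in shift_grid:
            moved = flipped.transformed(
                np.eye(3), np.array([float(shift), float(sep), 0.0])
            )
            residues = list(strand_a.residues) + [
                Residue(n_per_strand + 4 + r.seq_pos, r.name, r.atoms)
                for r in moved.residues
            ]
            candidate = StructureModel("A", residues)
            ss = assign_secondary_structure(candidate)
            n_e = ss.ss8.count("E")
            if best is None or n_e > best[0]:
                best = (n_e, candidate)
    assert best is not None
    return best[1]


def make_msa(
    length: int,
    depth: int,
    conserved_positions: set[int] | list[int],
    seed: int = 17,
    conserved_prob: float = 0.95,
    gap_rate: float = 0.0,
    query_id: str = "query",
    background: np.ndarray = BLOSUM62_BACKGROUND,
) -> Alignment:
    """Random MSA with designated conserved columns and no gaps in the query.

    Conserved columns repeat the query letter with probability
    ``conserved_prob`` in every homologue row; other columns are drawn
    independently from the background distribution.
    """
    conserved = set(conserved_positions)
    if conserved - set(range(1, length + 1)):
        raise ValueError("conserved positions outside 1..length")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA20))
    query = "".join(rng.choice(letters, size=length, p=background))
    rows = [(query_id, query)]
    for h in range(1, depth):
        chars = []
        for pos in range(1, length + 1):
            if gap_rate > 0 and rng.random() < gap_rate:
                chars.append("-")
            elif pos in conserved and rng.random() < conserved_prob:
                chars.append(query[pos - 1])
            else:
                chars.append(str(rng.choice(letters, p=background)))
        rows.append((f"homologue_{h}", "".join(chars)))
    return Alignment(query_id=query_id, rows=rows)


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs controlling the synthetic labelled dataset."""

    n_proteins: int = 20
    variants_per_protein: int = 8
    effect_size: float = 2.0  # 0 makes the two classes exchangeable
    msa_depth: int = 12
    protein_length: int = 60
    conserved_fraction: float = 0.3
    conservation_contrast: float = 0.95
    fraction_with_structure: float = 0.8
    seed: int = 17
    protein_prefix: str = "prot"

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.variants_per_protein, self.msa_depth,
               self.protein_length) < 1:
            raise ValueError("all counts must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")


@dataclass
class LabelledDataset:
    labelled_variants: list[LabelledVariant]
    alignments: dict[str, Alignment]
    structures: dict[str, StructureModel | None]
    sites: dict[str, list[SiteAnnotation]] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        """Write all pieces as plain-text files (FASTA/PDB/TSV)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_labelled_variants(self.labelled_variants, out / "variants.tsv")
        for pid, aln in self.alignments.items():
            write_alignment(aln, out / f"{pid}.aln.fasta")
        for pid, structure in self.structures.items():
            if structure is not None:
                write_structure(structure, out / f"{pid}.pdb")
        for pid, site_list in self.sites.items():
            if site_list:
                write_sites(site_list, out / f"{pid}.sites.tsv")


# substitutions considered drastic (charge flips / large side-chain change)
_DRASTIC_MUTS = "WKDRE"
_CONSERVATIVE_PAIRS = {
    "A": "V", "V": "A", "L": "I", "I": "L", "G": "A", "P": "A",
    "F": "Y", "W": "F", "Y": "F", "S": "T", "T": "S", "C": "M",
    "M": "C", "N": "Q", "Q": "N", "D": "E", "E": "D", "K": "R",
    "R": "K", "H": "K",
}


def make_labelled_dataset(spec: FixtureSpec) -> LabelledDataset:
    """Generate a labelled variant dataset across synthetic proteins.

    With effect size d, pathogenic variants fall on conserved and
    site-proximal positions with probability (1 + (1 - exp(-d))) / 2 and
    prefer drastic substitutions; neutral variants mirror that.  At d = 0
    the two classes are drawn from the same distribution.
    """
    rng = np.random.default_rng(spec.seed)
    bias = 1.0 - math.exp(-spec.effect_size)  # 0 -> exchangeable, inf -> 1
    p_path = 0.5 * (1.0 + bias)
    p_neut = 0.5 * (1.0 - bias)

    labelled: list[LabelledVariant] = []
    alignments: dict[str, Alignment] = {}
    structures: dict[str, StructureModel | None] = {}
    sites: dict[str, list[SiteAnnotation]] = {}

    for p_idx in range(spec.n_proteins):
        pid = f"{spec.protein_prefix}{p_idx:03d}"
        length = spec.protein_length
        n_conserved = max(1, int(round(spec.conserved_fraction * length)))
        conserved = set(
            rng.choice(np.arange(1, length + 1), size=n_conserved, replace=False)
            .tolist()
        )
        aln = make_msa(
            length,
            spec.msa_depth,
            conserved,
            seed=int(rng.integers(0, 2**31)),
            conserved_prob=spec.conservation_contrast,
            query_id=pid,
        )
        alignments[pid] = aln
        query = aln.query_sequence

        has_structure = rng.random() < spec.fraction_with_structure
        if has_structure:
            structures[pid] = make_helix(length, sequence=query)
            site_centre = int(rng.integers(3, length - 3))
            ligand_site = SiteAnnotation(
                "ligand",
                frozenset(range(max(1, site_centre - 2), min(length, site_centre + 2) + 1)),
                confidence_a=float(rng.uniform(1, 20)),
                confidence_b=float(rng.uniform(0, 1)),
            )
            itf_centre = int(rng.integers(3, length - 3))
            interface_site = SiteAnnotation(
                "interface",
                frozenset(range(max(1, itf_centre - 2), min(length, itf_centre + 2) + 1)),
                confidence_a=float(rng.uniform(1, 20)),
                confidence_b=float(rng.uniform(0, 1)),
            )
            sites[pid] = [ligand_site, interface_site]
            site_positions = set(ligand_site.residue_positions) | set(
                interface_site.residue_positions
            )
        else:
            structures[pid] = None
            sites[pid] = []
            site_positions = set()

        functional_pool = sorted(conserved | site_positions)
        background_pool = sorted(set(range(1, length + 1)) - set(functional_pool))
        if not background_pool:
            background_pool = list(range(1, length + 1))

        for v_idx in range(spec.variants_per_protein):
            label = v_idx % 2  # balanced classes
            p_functional_pos = p_path if label == 1 else p_neut
            if rng.random() < p_functional_pos:
                pos = int(rng.choice(functional_pool))
            else:
                pos = int(rng.choice(background_pool))
            wt = query[pos - 1]
            drastic = rng.random() < (p_path if label == 1 else p_neut)
            if drastic:
                options = [m for m in _DRASTIC_MUTS if m != wt]
                mut = str(rng.choice(options))
            else:
                mut = _CONSERVATIVE_PAIRS.get(wt, "A")
                if mut == wt:
                    mut = "S"
            labelled.append(LabelledVariant(Variant(wt, pos, mut), pid, label))

    return LabelledDataset(labelled, alignments, structures, sites)
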