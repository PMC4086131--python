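"""Physicochemical change features of an amino-acid substitution.

Three features depend only on the (wild-type, mutant) pair: the residue
mass ratio, an ordinal charge-group change value, and a side-chain
functional-group change indicator.  All tables are overridable from a
JSON config so the defaults can be swapped for published ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from varmod.core_io import AA20, Variant

# Average (peptide-bonded) residue masses in Da.
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

CHARGE_GROUP = {
    **{aa: "positive" for aa in "KRH"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "neutral" for aa in "ACFGILMNPQSTVWY"},
}

# Side-chain functional groups (explicit stand-in grouping, swappable).
FUNCTIONAL_GROUP = {
    **{aa: "aliphatic" for aa in "AVLIGP"},
    **{aa: "aromatic" for aa in "FWY"},
    **{aa: "hydroxyl" for aa in "ST"},
    **{aa: "sulfur" for aa in "CM"},
    **{aa: "amide" for aa in "NQ"},
    **{aa: "acidic" for aa in "DE"},
    **{aa: "basic" for aa in "KRH"},
}


@dataclass(frozen=True)
class AminoAcidTables:
    mass: dict = field(default_factory=lambda: dict(RESIDUE_MASS))
    charge_group: dict = field(default_factory=lambda: dict(CHARGE_GROUP))
    functional_group: dict = field(default_factory=lambda: dict(FUNCTIONAL_GROUP))

    def __post_init__(self) -> None:
        for table, name in (
            (self.mass, "mass"),
            (self.charge_group, "charge_group"),
            (self.functional_group, "functional_group"),
        ):
            missing = set(AA20) - set(table)
            if missing:
                raise ValueError(f"{name} table missing letters {sorted(missing)}")
        if any(m <= 0 for m in self.mass.values()):
            raise ValueError("all masses must be positive")


def _default_charge_matrix() -> dict:
    """Ordinal severity: 0 same group, 1 neutral<->charged, 2 sign flip."""
    groups = ("positive", "negative", "neutral")
    values = {}
    for a in groups:
        for b in groups:
            if a == b:
                values[(a, b)] = 0.0
            elif {a, b} == {"positive", "negative"}:
                values[(a, b)] = 2.0
            else:
                values[(a, b)] = 1.0
    return values


@dataclass(frozen=True)
class ChangeMatrix:
    """Values for transitions between groups; diagonal is the minimum."""

    values: dict = field(default_factory=_default_charge_matrix)

    def __post_init__(self) -> None:
        diag = [v for (a, b), v in self.values.items() if a == b]
        if diag and min(self.values.values()) < min(diag):
            raise ValueError("diagonal must hold the minimum (no-change) value")

    def __call__(self, group_from: str, group_to: str) -> float:
        return self.values[(group_from, group_to)]


DEFAULT_TABLES = AminoAcidTables()
DEFAULT_CHARGE_MATRIX = ChangeMatrix()


def mass_ratio(
    variant: Variant,
    tables: AminoAcidTables = DEFAULT_TABLES,
    direction: str = "mut_over_wt",
) -> float:
    """Ratio of residue masses; mutant over wild type by default."""
    wt_m, mut_m = tables.mass[variant.wt], tables.mass[variant.mut]
    if direction == "mut_over_wt":
        return mut_m / wt_m
    if direction == "wt_over_mut":
        return wt_m / mut_m
    raise ValueError(f"unknown direction {direction!r}")


def charge_change(
    variant: Variant,
    tables: AminoAcidTables = DEFAULT_TABLES,
    matrix: ChangeMatrix = DEFAULT_CHARGE_MATRIX,
) -> float:
    """Matrix value for the (wt charge group, mut charge group) transition."""
    return matrix(tables.charge_group[variant.wt], tables.charge_group[variant.mut])


def functional_group_change(
    variant: Variant,
    tables: AminoAcidTables = DEFAULT_TABLES,
    matrix: ChangeMatrix | None = None,
) -> float:
    """0 when side-chain groups match; else a positive change value.

    The default table is the 0/1 indicator; a ChangeMatrix over
    functional-group labels can refine it.
    """
    g_wt = tables.functional_group[variant.wt]
    g_mut = tables.functional_group[variant.mut]
    if g_wt == g_mut:
        return 0.0
    if matrix is None:
        return 1.0
    return matrix(g_wt, g_mut)


def sequence_feature_block(
    variant: Variant,
    tables: AminoAcidTables = DEFAULT_TABLES,
    charge_matrix: ChangeMatrix = DEFAULT_CHARGE_MATRIX,
) -> tuple[float, float, float]:
    return (
        mass_ratio(variant, tables),
        charge_change(variant, tables, charge_matrix),
        functional_group_change(variant, tables),
    )


def load_tables(path) -> tuple[AminoAcidTables, ChangeMatrix]:
    """Load amino-acid tables and the charge-change matrix from JSON.

    Keys: "mass", "charge_group", "functional_group" (letter -> value) and
    "charge_matrix" (list of [group_from, group_to, value]); missing keys
    fall back to the shipped defaults.
    """
    with open(path) as fh:
        cfg = json.load(fh)
    tables = AminoAcidTables(
        mass=cfg.get("mass", dict(RESIDUE_MASS)),
        charge_group=cfg.get("charge_group", dict(CHARGE_GROUP)),
        functional_group=cfg.get("functional_group", dict(FUNCTIONAL_GROUP)),
    )
    if "charge_matrix" in cfg:
        matrix = ChangeMatrix(
            {(a, b): float(v) for a, b, v in cfg["charge_matrix"]}
        )
    else:
        matrix = DEFAULT_CHARGE_MATRIX
    return tables, matrix
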