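"""Physicochemical peptide properties and screening filters.

Computes the four quantities the design pipeline screens on:

* molecular weight — sum of average (isotope-averaged) residue masses
  plus one water, assuming free unmodified termini;
* GRAVY — grand average of hydropathy, the mean Kyte-Doolittle
  hydropathy value per residue (negative = hydrophilic);
* net charge — two conventions: an integer formal count at
  physiological pH (+1 per Arg/Lys, -1 per Asp/Glu, His neutral,
  termini cancel) and the continuous Henderson-Hasselbalch charge at
  an arbitrary pH;
* isoelectric point — the pH at which the Henderson-Hasselbalch
  charge is zero, found by bisection with a Bjellqvist-style pKa set.

Default screening thresholds: length >= 10 residues, formal net
charge in [-2, +2], GRAVY in [-1.0, +1.0], all bounds inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.optimize import bisect

from .corpus import AMINO_ACIDS

#: Average (isotope-averaged) residue masses in Da, free-termini
#: convention: peptide MW = sum of residue masses + one water.
AVERAGE_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

#: Mass of one water molecule (Da), added once per free-termini peptide.
WATER_MASS = 18.0153

#: Kyte-Doolittle hydropathy values.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class MassTable:
    """Average residue masses (Da) plus the water mass."""

    residue_masses: dict[str, float] = field(
        default_factory=lambda: dict(AVERAGE_RESIDUE_MASSES)
    )
    water: float = WATER_MASS

    def __post_init__(self) -> None:
        if set(self.residue_masses) != set(AMINO_ACIDS):
            raise ValueError("mass table must cover exactly the 20 residues")
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("residue masses must be positive")


@dataclass(frozen=True)
class PkaSet:
    """Ionisation constants used for the Henderson-Hasselbalch charge.

    Defaults are a Bjellqvist-style set (the family used by common
    proteomics pI calculators).  Cysteine is treated as reduced and
    ionisable here, although it is excluded from the integer formal
    charge count.
    """

    n_term: float = 7.5
    c_term: float = 3.55
    side_chain: dict[str, float] = field(
        default_factory=lambda: {
            "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
            "H": 5.98, "K": 10.0, "R": 12.0,
        }
    )

    #: residues whose side chain is positively charged when protonated
    POSITIVE_SIDE_CHAINS = ("R", "K", "H")
    #: residues whose side chain is negatively charged when deprotonated
    NEGATIVE_SIDE_CHAINS = ("D", "E", "C", "Y")

    def __post_init__(self) -> None:
        for value in (self.n_term, self.c_term, *self.side_chain.values()):
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa {value} outside (0, 14)")


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusive screening thresholds for candidate peptides."""

    min_length: int = 10
    charge_range: tuple[int, int] = (-2, 2)
    gravy_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.charge_range[0] > self.charge_range[1]:
            raise ValueError("charge_range ill-ordered")
        if self.gravy_range[0] > self.gravy_range[1]:
            raise ValueError("gravy_range ill-ordered")


@dataclass(frozen=True)
class PropertyProfile:
    """Computed properties and filter verdicts for one peptide."""

    sequence: str
    length: int
    mw: float
    gravy: float
    net_charge: int
    charge_ph7_4: float
    pi: float
    passes_length: bool
    passes_charge: bool
    passes_gravy: bool
    passes: bool


def _validate(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty peptide sequence")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)} in {sequence!r}")
    return sequence


def molecular_weight(sequence: str, table: MassTable | None = None) -> float:
    """Average molecular weight (Da) with free, unmodified termini."""
    _validate(sequence)
    table = table or MassTable()
    return sum(table.residue_masses[aa] for aa in sequence) + table.water


def gravy(sequence: str) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value)."""
    _validate(sequence)
    return sum(KYTE_DOOLITTLE[aa] for aa in sequence) / len(sequence)


def net_charge_integer(sequence: str) -> int:
    """Formal integer net charge at physiological pH.

    +1 per Arg/Lys, -1 per Asp/Glu; His, Cys and Tyr contribute
    nothing; the terminal amine (+1) and carboxylate (-1) cancel.
    """
    _validate(sequence)
    return sum(sequence.count(aa) for aa in "RK") - sum(
        sequence.count(aa) for aa in "DE"
    )


def charge_at_pH(
    sequence: str, pH: float, pkas: PkaSet | None = None
) -> float:
    """Continuous Henderson-Hasselbalch net charge at a given pH.

    Positive groups (N-terminus, Arg, Lys, His) each contribute
    ``1 / (1 + 10**(pH - pKa))``; negative groups (C-terminus, Asp,
    Glu, Cys, Tyr) each contribute ``-1 / (1 + 10**(pKa - pH))``.
    """
    _validate(sequence)
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    pkas = pkas or PkaSet()
    charge = 1.0 / (1.0 + 10.0 ** (pH - pkas.n_term))
    charge -= 1.0 / (1.0 + 10.0 ** (pkas.c_term - pH))
    for aa in pkas.POSITIVE_SIDE_CHAINS:
        k = pkas.side_chain[aa]
        charge += sequence.count(aa) / (1.0 + 10.0 ** (pH - k))
    for aa in pkas.NEGATIVE_SIDE_CHAINS:
        k = pkas.side_chain[aa]
        charge -= sequence.count(aa) / (1.0 + 10.0 ** (k - pH))
    return charge


def isoelectric_point(
    sequence: str, pkas: PkaSet | None = None, tol: float = 1e-3
) -> float:
    """pH at which the Henderson-Hasselbalch charge is zero.

    The charge is strictly decreasing in pH, so the root on [0, 14]
    is unique; it is bracketed by the termini (positive charge at
    pH 0, negative at pH 14) and located by bisection to ``tol``.
    """
    _validate(sequence)
    pkas = pkas or PkaSet()
    lo, hi = charge_at_pH(sequence, 0.0, pkas), charge_at_pH(sequence, 14.0, pkas)
    if lo <= 0 or hi >= 0:
        raise ValueError("charge function does not change sign on [0, 14]")
    return float(
        bisect(lambda p: charge_at_pH(sequence, p, pkas), 0.0, 14.0, xtol=tol)
    )


def passes_filters(
    sequence: str,
    criteria: FilterCriteria | None = None,
    mass_table: MassTable | None = None,
    pkas: PkaSet | None = None,
) -> PropertyProfile:
    """Full property profile with per-criterion and overall verdicts."""
    _validate(sequence)
    criteria = criteria or FilterCriteria()
    charge = net_charge_integer(sequence)
    g = gravy(sequence)
    ok_len = len(sequence) >= criteria.min_length
    ok_charge = criteria.charge_range[0] <= charge <= criteria.charge_range[1]
    ok_gravy = criteria.gravy_range[0] <= g <= criteria.gravy_range[1]
    return PropertyProfile(
        sequence=sequence,
        length=len(sequence),
        mw=molecular_weight(sequence, mass_table),
        gravy=g,
        net_charge=charge,
        charge_ph7_4=charge_at_pH(sequence, 7.4, pkas),
        pi=isoelectric_point(sequence, pkas),
        passes_length=ok_len,
        passes_charge=ok_charge,
        passes_gravy=ok_gravy,
        passes=ok_len and ok_charge and ok_gravy,
    )


_TSV_HEADER = (
    "id\tsequence\tlength\tmw\tgravy\tnet_charge\tcharge_ph7.4\tpi"
    "\tpass_length\tpass_charge\tpass_gravy\tpass\n"
)


def profiles_to_tsv(
    profiles: list[tuple[str, PropertyProfile]], path
) -> None:
    """Write (id, profile) rows as a TSV screening table."""
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for pid, p in profiles:
            fh.write(
                f"{pid}\t{p.sequence}\t{p.length}\t{p.mw:.2f}\t{p.gravy:.4f}"
                f"\t{p.net_charge:+d}\t{p.charge_ph7_4:.3f}\t{p.pi:.3f}"
                f"\t{int(p.passes_length)}\t{int(p.passes_charge)}"
                f"\t{int(p.passes_gravy)}\t{int(p.passes)}\n"
            )
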