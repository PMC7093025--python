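"""Elemental stoichiometry of the macromolecular pools.

Every macromolecule the allocation model resolves (protein, chlorophyll,
RNA, DNA, thylakoid phospholipid, and the three storage polymers) has a
fixed elemental composition; this module holds those C:N:P conversion
constants and derives the nucleic-acid and cyanophycin ratios from residue
composition.

Nucleic acids are treated as polymers of nucleoside-monophosphate residues:
each residue carries exactly one phosphorus, the base and sugar carry all of
the carbon and nitrogen, and the phosphate group carries neither.  The mean
atoms of C and N per P are then a GC-weighted average over the four residue
formulas, assuming equal G and C fractions (gc/2 each) and equal A and U
(or T) fractions.  Phosphorus storage is polyphosphate (no carbon), nitrogen
storage is cyanophycin, an equimolar aspartate-arginine polymer.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from enum import Enum
from typing import Tuple

from .errors import DomainError

#: Default genomic GC fraction (freshwater Synechococcus-like organism).
DEFAULT_GC = 0.563

# (C, N) atoms per nucleoside-monophosphate residue as incorporated in the
# polymer: base plus pentose; one P per residue in the backbone.
_RNA_RESIDUES = {"A": (10, 5), "G": (10, 5), "C": (9, 3), "U": (9, 2)}
_DNA_RESIDUES = {"A": (10, 5), "G": (10, 5), "C": (9, 3), "T": (10, 2)}

# (C, N) atoms per amino-acid residue in cyanophycin (peptide-bonded,
# i.e. minus water): aspartate C4H4NO3, arginine C6H12N4O.
_CYANOPHYCIN_RESIDUES = {"Asp": (4, 1), "Arg": (6, 4)}


class NucleicAcid(str, Enum):
    RNA = "RNA"
    DNA = "DNA"


@dataclass(frozen=True)
class StoichRatios:
    """Fixed elemental conversion constants between macromolecular pools.

    Attributes
    ----------
    y_pro_nc : float
        mol N per mol C in bulk protein.
    y_chl_nc : float
        mol N per mol C in chlorophyll a.
    y_dna_nc : float
        mol N per mol C in DNA.
    y_rna_np : float
        mol N per mol P in RNA.
    y_rna_cp : float
        mol C per mol P in RNA.
    y_dna_pc : float
        mol P per mol C in DNA.
    y_plip_cp : float
        mol C per mol P in phospholipid.
    y_nsto_cn : float
        mol C per mol N in the nitrogen-storage polymer (cyanophycin).
    """

    y_pro_nc: float
    y_chl_nc: float
    y_dna_nc: float
    y_rna_np: float
    y_rna_cp: float
    y_dna_pc: float
    y_plip_cp: float
    y_nsto_cn: float

    def __post_init__(self):
        for name, value in asdict(self).items():
            if not value > 0:
                raise DomainError(f"stoichiometric ratio {name} must be > 0, got {value}")

    def replace(self, **changes) -> "StoichRatios":
        return replace(self, **changes)


def nucleic_acid_ratios(
    gc_fraction: float, kind: NucleicAcid | str = NucleicAcid.RNA
) -> Tuple[float, float]:
    """Mean (C per P, N per P) of a nucleic acid at a given GC fraction.

    The weighted average over the four monophosphate residues with weights
    gc/2 on G and C and (1-gc)/2 on A and U (or T).  RNA carbon per P is
    exactly 9.5 for any GC fraction because the A+U and G+C residue pairs
    carry the same total carbon.

    Parameters
    ----------
    gc_fraction : float in [0, 1]
        Genomic (or transcriptome-average) GC fraction.
    kind : {'RNA', 'DNA'}

    Returns
    -------
    (c_per_p, n_per_p) : tuple of float
        Mean atoms of carbon and nitrogen per phosphorus.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise DomainError(f"gc_fraction must lie in [0, 1], got {gc_fraction}")
    kind = NucleicAcid(kind)
    residues = _RNA_RESIDUES if kind is NucleicAcid.RNA else _DNA_RESIDUES
    at = "U" if kind is NucleicAcid.RNA else "T"
    weights = {"G": gc_fraction / 2, "C": gc_fraction / 2,
               "A": (1 - gc_fraction) / 2, at: (1 - gc_fraction) / 2}
    c_per_p = sum(weights[b] * residues[b][0] for b in residues)
    n_per_p = sum(weights[b] * residues[b][1] for b in residues)
    return c_per_p, n_per_p


def storage_polymer_ratios() -> Tuple[float, float]:
    """C:N of the N-storage polymer and C:P of the P-storage polymer.

    Cyanophycin is an equimolar polymer of aspartate and arginine residues;
    its C:N follows from the residue atom counts (10 C and 5 N per Asp+Arg
    pair, hence 2).  Polyphosphate carries no carbon, so its C:P is 0.
    """
    c = sum(v[0] for v in _CYANOPHYCIN_RESIDUES.values())
    n = sum(v[1] for v in _CYANOPHYCIN_RESIDUES.values())
    return c / n, 0.0


def cyanophycin_atoms_per_residue_pair() -> Tuple[int, int]:
    """Total (C, N) atoms in one aspartate-arginine residue pair."""
    c = sum(v[0] for v in _CYANOPHYCIN_RESIDUES.values())
    n = sum(v[1] for v in _CYANOPHYCIN_RESIDUES.values())
    return c, n


def default_ratios(gc_fraction: float = DEFAULT_GC) -> StoichRatios:
    """The full default constant set.

    Protein N:C is 1/3.82 (bulk average), chlorophyll a N:C is 4/55,
    phospholipid C:P is 40 (phosphatidylglycerol with C16 fatty acids, taken
    as a given constant), and the nucleic-acid ratios are derived from the
    residue composition at ``gc_fraction`` (full precision, not the printed
    rounding).
    """
    rna_cp, rna_np = nucleic_acid_ratios(gc_fraction, NucleicAcid.RNA)
    dna_cp, dna_np = nucleic_acid_ratios(gc_fraction, NucleicAcid.DNA)
    nsto_cn, _ = storage_polymer_ratios()
    return StoichRatios(
        y_pro_nc=1.0 / 3.82,
        y_chl_nc=4.0 / 55.0,
        y_dna_nc=dna_np / dna_cp,
        y_rna_np=rna_np,
        y_rna_cp=rna_cp,
        y_dna_pc=1.0 / dna_cp,
        y_plip_cp=40.0,
        y_nsto_cn=nsto_cn,
    )


def ratios_from_dict(d: dict) -> StoichRatios:
    """Build :class:`StoichRatios` from a flat mapping, filling defaults.

    Lets a config file override individual constants (e.g. another
    organism's GC-derived nucleic-acid composition) without restating the
    full set.
    """
    base = default_ratios()
    known = set(asdict(base))
    unknown = set(d) - known
    if unknown:
        raise DomainError(f"unknown stoichiometric ratio keys: {sorted(unknown)}")
    return base.replace(**d)


def table_rows(gc_fraction: float = DEFAULT_GC) -> list[dict]:
    """Stoichiometry table (C:N:P per molecule) with derivations, for display."""
    rna_cp, rna_np = nucleic_acid_ratios(gc_fraction, NucleicAcid.RNA)
    dna_cp, dna_np = nucleic_acid_ratios(gc_fraction, NucleicAcid.DNA)
    nsto_cn, psto_cp = storage_polymer_ratios()
    return [
        {"molecule": "Chlorophyll", "c": 55, "n": 4, "p": 0,
         "note": "chlorophyll a"},
        {"molecule": "Protein", "c": 3.82, "n": 1, "p": 0,
         "note": "bulk average"},
        {"molecule": "RNA", "c": round(rna_cp, 2), "n": round(rna_np, 2), "p": 1,
         "note": f"residue-derived at GC={gc_fraction}"},
        {"molecule": "DNA", "c": round(dna_cp, 2), "n": round(dna_np, 2), "p": 1,
         "note": f"residue-derived at GC={gc_fraction}"},
        {"molecule": "P lipid", "c": 40, "n": 0, "p": 1,
         "note": "phosphatidylglycerol, C16 fatty acids"},
        {"molecule": "C store", "c": 1, "n": 0, "p": 0,
         "note": "carbohydrate and non-phospholipid"},
        {"molecule": "N store", "c": nsto_cn, "n": 1, "p": 0,
         "note": "cyanophycin (Asp-Arg polymer)"},
        {"molecule": "P store", "c": psto_cp, "n": 0, "p": 1,
         "note": "polyphosphate"},
    ]
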