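"""Monoisotopic mass arithmetic for peptides, modifications and SILAC labels.

Residue monoisotopic masses come from :mod:`pyteomics.mass` (``std_aa_mass``),
the table search engines assume implicitly.  Modification deltas used
throughout the pipeline:

* phospho (HPO3)            +79.9663 Da on S/T/Y
* carbamidomethyl (C2H3NO)  +57.0215 Da on C (static)
* heavy arginine (13C6 15N4) +10.00827 Da
* heavy lysine   (13C6 15N2)  +8.01420 Da

The heavy-label deltas are also derivable from isotopic mass differences
(see :func:`label_delta_from_isotopes`), which the test suite uses as an
independent check that the printed constants are physically consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from pyteomics import mass as _pmass

# Monoisotopic constants (Da).
WATER = _pmass.calculate_mass(formula="H2O")          # 18.0105646...
PROTON = 1.007276                                     # search-engine convention
PHOSPHO_DELTA = 79.9663                               # HPO3
CARBAMIDOMETHYL_DELTA = 57.0215                       # C2H3NO, iodoacetamide
HEAVY_ARG_DELTA = 10.00827                            # 13C6 15N4 Arg
HEAVY_LYS_DELTA = 8.01420                             # 13C6 15N2 Lys

STD_AA_MASS: Mapping[str, float] = _pmass.std_aa_mass

MOD_KINDS = ("phospho", "carbamidomethyl", "label")
_PHOSPHO_RESIDUES = frozenset("STY")


def _isotope_mass(element: str, a: int) -> float:
    return _pmass.nist_mass[element][a][0]


def label_delta_from_isotopes(n_c13: int, n_n15: int) -> float:
    """Mass shift of substituting ``n_c13`` 12C->13C and ``n_n15`` 14N->15N.

    Heavy Arg is 13C6/15N4 (+10.00827 Da), heavy Lys 13C6/15N2 (+8.01420 Da).
    """
    d_c = _isotope_mass("C", 13) - _isotope_mass("C", 12)
    d_n = _isotope_mass("N", 15) - _isotope_mass("N", 14)
    return n_c13 * d_c + n_n15 * d_n


def phospho_delta_from_formula() -> float:
    """Monoisotopic mass of HPO3, the phosphorylation delta."""
    return _pmass.calculate_mass(formula="HPO3")


def carbamidomethyl_delta_from_formula() -> float:
    """Monoisotopic mass of C2H3NO, the carbamidomethylation delta."""
    return _pmass.calculate_mass(formula="C2H3NO")


@dataclass(frozen=True)
class LabelScheme:
    """Per-residue mass shifts of an isotopic labeling channel.

    The default heavy scheme carries +10.00827 Da on R and +8.01420 Da on K;
    the light scheme carries no shifts.
    """

    residue_deltas: Mapping[str, float] = field(default_factory=dict)
    name: str = "light"

    def __post_init__(self) -> None:
        for res, delta in self.residue_deltas.items():
            if res not in STD_AA_MASS:
                raise ValueError(f"unknown residue in label scheme: {res!r}")
            if delta < 0:
                raise ValueError(f"negative label delta for {res}: {delta}")


LIGHT_SCHEME = LabelScheme({}, name="light")
HEAVY_SCHEME = LabelScheme({"R": HEAVY_ARG_DELTA, "K": HEAVY_LYS_DELTA}, name="heavy")


def residue_label_delta(scheme: LabelScheme, residue: str) -> float:
    """Label mass shift (Da) a scheme assigns to one residue; 0 if unlabeled."""
    if residue not in STD_AA_MASS:
        raise ValueError(f"unknown residue letter: {residue!r}")
    return scheme.residue_deltas.get(residue, 0.0)


@dataclass(frozen=True)
class Mod:
    """A single modification: 0-based position, mass delta (Da), kind."""

    position: int
    delta: float
    kind: str = "phospho"


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with explicit positional modifications and charge.

    Positions are 0-based internally; reports render residue + 1-based number
    (e.g. Y753).  Phospho mods are restricted to S/T/Y and carbamidomethyl to
    C, mirroring the search parameterization.
    """

    sequence: str
    mods: tuple[Mod, ...] = ()
    charge: int = 2

    def __post_init__(self) -> None:
        if not self.sequence.isupper() or any(r not in STD_AA_MASS for r in self.sequence):
            raise ValueError(f"invalid sequence: {self.sequence!r}")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        for m in self.mods:
            if not 0 <= m.position < len(self.sequence):
                raise ValueError(f"mod position {m.position} outside sequence")
            res = self.sequence[m.position]
            if m.kind == "phospho" and res not in _PHOSPHO_RESIDUES:
                raise ValueError(f"phospho on non-S/T/Y residue {res}{m.position + 1}")
            if m.kind == "carbamidomethyl" and res != "C":
                raise ValueError(f"carbamidomethyl on non-C residue {res}{m.position + 1}")
            if m.kind not in MOD_KINDS:
                raise ValueError(f"unknown mod kind {m.kind!r}")

    @property
    def phospho_positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mods if m.kind == "phospho")

    def site_label(self) -> str:
        """Render phosphosites as residue + 1-based position, e.g. 'Y7'."""
        return ",".join(
            f"{self.sequence[p]}{p + 1}" for p in sorted(self.phospho_positions)
        )


def parse_peptide(text: str, charge: int = 2, scheme: LabelScheme = LIGHT_SCHEME) -> ModifiedPeptide:
    """Parse inline phospho notation ('LIEDAEpYTAK': lower-case p = phospho).

    Label mods from ``scheme`` are attached to every matching residue;
    carbamidomethyl is applied statically to every C.
    """
    seq_chars: list[str] = []
    mods: list[Mod] = []
    pending_phospho = False
    for ch in text:
        if ch == "p":
            if pending_phospho:
                raise ValueError(f"dangling 'p' in {text!r}")
            pending_phospho = True
            continue
        if not ch.isupper():
            raise ValueError(f"unexpected character {ch!r} in {text!r}")
        pos = len(seq_chars)
        seq_chars.append(ch)
        if pending_phospho:
            mods.append(Mod(pos, PHOSPHO_DELTA, "phospho"))
            pending_phospho = False
        if ch == "C":
            mods.append(Mod(pos, CARBAMIDOMETHYL_DELTA, "carbamidomethyl"))
        label = scheme.residue_deltas.get(ch, 0.0)
        if label:
            mods.append(Mod(pos, label, "label"))
    if pending_phospho:
        raise ValueError(f"trailing 'p' in {text!r}")
    return ModifiedPeptide("".join(seq_chars), tuple(mods), charge)


def monoisotopic_mass(pep: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass: residue masses + water + all mod deltas."""
    mass = WATER
    for res in pep.sequence:
        mass += STD_AA_MASS[res]
    for m in pep.mods:
        mass += m.delta
    return mass


def precursor_mz(neutral_mass: float, z: int) -> float:
    """m/z of the [M + zH]^z+ ion, proton mass 1.007276 Da."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * PROTON) / z


def mass_error_ppm(theoretical: float, observed: float) -> float:
    """Signed precursor mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be > 0, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical
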