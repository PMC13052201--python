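"""Peptide library enumeration and mass bookkeeping for legumain cyclization assays.

The sunflower trypsin inhibitor (SFTI) precursor scaffold is cyclized
head-to-tail by legumain: the enzyme cleaves after the P1 asparagine and the
released N-terminus attacks the acyl-enzyme intermediate, producing either a
cyclic product (transpeptidation) or a linear hydrolysis product.  This module
enumerates positional-scanning and combinatorial variant libraries on such a
scaffold and computes the neutral masses and [M+H]+ m/z of every reaction
species (precursor, linear, cyclic, and demethylated satellites).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from pyteomics import mass as _pmass

__all__ = [
    "AA20",
    "WATER_MONO",
    "WATER_AVG",
    "DISULFIDE_MONO",
    "DISULFIDE_AVG",
    "DEMETHYL_MONO",
    "DEMETHYL_AVG",
    "PROTON",
    "ScaffoldSpec",
    "PeptideVariant",
    "ModificationSet",
    "Species",
    "SpeciesSet",
    "sfti_scaffold",
    "normalize_site_label",
    "enumerate_positional_library",
    "enumerate_combinatorial_library",
    "peptide_mass",
    "expected_species",
]

#: The 20 proteinogenic amino acids, one-letter code, alphabetical.
AA20: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

# Mass deltas (Da).  Head-to-tail condensation loses one water; a disulfide
# bond loses two hydrogens; the demethylated satellite frequently seen in
# MALDI spectra of these peptides sits one CH2 below the parent.
WATER_MONO = 18.010565
WATER_AVG = 18.0153
DISULFIDE_MONO = -2.015650
DISULFIDE_AVG = -2.0159
DEMETHYL_MONO = -14.015650
DEMETHYL_AVG = -14.0266
#: Mass of the proton for [M+H]+ (Da).
PROTON = 1.007276

_SITE_ALIASES = {
    "p": "'",
    "pp": '"',
    "′": "'",
    "″": '"',
    "’": "'",
    "''": '"',
}


def normalize_site_label(label: str) -> str:
    """Canonicalize a Schechter-Berger site label.

    Accepts ASCII shell-safe spellings (``P2pp``, ``P1p``) and unicode
    prime/double-prime variants; returns the canonical form using ``'`` for
    prime and ``"`` for double prime (e.g. ``P2"``).
    """
    s = label.strip()
    if not s or s[0] not in "Pp":
        raise ValueError(f"not a P-site label: {label!r}")
    core = s[1:]
    digits = ""
    i = 0
    while i < len(core) and core[i].isdigit():
        digits += core[i]
        i += 1
    if not digits:
        raise ValueError(f"not a P-site label: {label!r}")
    suffix = core[i:]
    suffix = _SITE_ALIASES.get(suffix, suffix)
    if suffix not in ("", "'", '"'):
        raise ValueError(f"unrecognized P-site suffix in {label!r}")
    return f"P{digits}{suffix}"


@dataclass(frozen=True)
class ScaffoldSpec:
    """A cyclization scaffold: template sequence plus substrate-site geometry.

    Parameters
    ----------
    template : str
        One-letter sequence of the precursor peptide.
    p_site_map : dict
        Mapping from P-site label (Schechter-Berger, with P1''/P2'' denoting
        the incoming nucleophile's N-terminal residues) to 1-based residue
        index in the template.
    fixed_sites : dict
        1-based index -> required residue; these positions may never be
        varied (for legumain, P1 must be Asn).
    disulfides : tuple of (int, int)
        1-based index pairs of cystines in the scaffold.
    """

    template: str
    p_site_map: dict[str, int]
    fixed_sites: dict[int, str] = field(default_factory=dict)
    disulfides: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.template)
        bad = set(self.template) - set(AA20)
        if bad:
            raise ValueError(f"template contains non-proteinogenic letters: {sorted(bad)}")
        norm = {normalize_site_label(k): v for k, v in self.p_site_map.items()}
        object.__setattr__(self, "p_site_map", norm)
        for label, idx in norm.items():
            if not 1 <= idx <= n:
                raise ValueError(f"site {label} maps to index {idx}, outside template of length {n}")
        if len(set(norm.values())) != len(norm):
            raise ValueError("p_site_map is not injective")
        for idx, res in self.fixed_sites.items():
            if not 1 <= idx <= n:
                raise ValueError(f"fixed site index {idx} outside template")
            if self.template[idx - 1] != res:
                raise ValueError(
                    f"fixed site {idx} requires {res} but template has {self.template[idx - 1]}"
                )
        for i, j in self.disulfides:
            for idx in (i, j):
                if not 1 <= idx <= n or self.template[idx - 1] != "C":
                    raise ValueError(f"disulfide index {idx} does not reference a Cys")

    @property
    def p1_index(self) -> int:
        """1-based index of the P1 (scissile) residue."""
        try:
            return self.p_site_map["P1"]
        except KeyError:
            raise ValueError("scaffold defines no P1 site") from None

    def site_index(self, label: str) -> int:
        label = normalize_site_label(label)
        if label not in self.p_site_map:
            raise KeyError(f"unknown P-site label {label!r}; known: {sorted(self.p_site_map)}")
        return self.p_site_map[label]


@dataclass(frozen=True)
class PeptideVariant:
    """One member of a scanning or combinatorial library."""

    sequence: str
    varied_site: str | None = None
    varied_residue: str | None = None
    library_id: str = ""


@dataclass(frozen=True)
class ModificationSet:
    """Set of mass-affecting modifications applied to one species.

    ``disulfide_pairs`` holds 1-based (i, j) Cys index pairs within the
    species' own sequence; each pair contributes one -2H delta.  ``truncation``
    is handled upstream by slicing the sequence, so it carries no delta here.
    """

    cyclization: bool = False
    disulfide_pairs: tuple[tuple[int, int], ...] = ()
    demethylation: bool = False

    def delta(self, scale: str = "monoisotopic") -> float:
        if scale == "monoisotopic":
            w, ss, ch2 = WATER_MONO, DISULFIDE_MONO, DEMETHYL_MONO
        elif scale == "average":
            w, ss, ch2 = WATER_AVG, DISULFIDE_AVG, DEMETHYL_AVG
        else:
            raise ValueError(f"unknown mass scale {scale!r}")
        d = 0.0
        if self.cyclization:
            d -= w
        d += ss * len(set(map(tuple, map(sorted, self.disulfide_pairs))))
        if self.demethylation:
            d += ch2
        return d


def peptide_mass(
    sequence: str,
    modifications: ModificationSet | None = None,
    scale: str = "monoisotopic",
) -> float:
    """Neutral mass of a peptide in Da, with optional modifications.

    The unmodified value is the sum of residue masses plus one water (free
    termini); cyclization removes that water, each disulfide removes 2 H,
    demethylation removes CH2.
    """
    bad = set(sequence) - set(AA20)
    if bad:
        raise ValueError(f"unknown residue letter(s): {sorted(bad)}")
    if scale not in ("monoisotopic", "average"):
        raise ValueError(f"unknown mass scale {scale!r}")
    if modifications is not None:
        for i, j in modifications.disulfide_pairs:
            for idx in (i, j):
                if not 1 <= idx <= len(sequence) or sequence[idx - 1] != "C":
                    raise ValueError(f"disulfide index {idx} does not reference a Cys in {sequence}")
    m = _pmass.calculate_mass(sequence=sequence, average=(scale == "average"))
    if modifications is not None:
        m += modifications.delta(scale)
    return m


def enumerate_positional_library(
    scaffold: ScaffoldSpec,
    sites: list[str],
    alphabet: tuple[str, ...] = AA20,
) -> list[PeptideVariant]:
    """Enumerate a positional-scanning library on a scaffold.

    Each requested site is substituted, one at a time, with every residue of
    the alphabet, yielding ``len(sites) * len(alphabet)`` variants in
    deterministic order (sites as given, residues alphabetical).  The
    wild-type-coincident sequence is retained once per site, mirroring how
    such libraries are synthesized.
    """
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    bad = set(alphabet) - set(AA20)
    if bad:
        raise ValueError(f"alphabet contains non-proteinogenic letters: {sorted(bad)}")
    variants: list[PeptideVariant] = []
    for raw in sites:
        label = normalize_site_label(raw)
        idx = scaffold.site_index(label)
        if idx in scaffold.fixed_sites:
            raise ValueError(
                f"site {label} (index {idx}) is fixed to "
                f"{scaffold.fixed_sites[idx]!r} and cannot be varied: the P1 "
                "asparagine is essential for legumain processing"
            )
        for res in sorted(alphabet):
            seq = scaffold.template[: idx - 1] + res + scaffold.template[idx:]
            variants.append(
                PeptideVariant(
                    sequence=seq,
                    varied_site=label,
                    varied_residue=res,
                    library_id=f"{label}={res}",
                )
            )
    return variants


def enumerate_combinatorial_library(
    template: str,
    alphabet: tuple[str, ...] = AA20,
    placeholder: str = "X",
) -> list[PeptideVariant]:
    """Expand placeholder positions in a template combinatorially.

    ``template`` uses ``placeholder`` (default ``X``) at positions to vary;
    all ``len(alphabet) ** k`` sequences are returned in lexicographic order
    of the substituted residues.
    """
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    positions = [i for i, c in enumerate(template) if c == placeholder]
    if not positions:
        raise ValueError(f"template {template!r} contains no placeholder {placeholder!r}")
    variants = []
    for combo in itertools.product(sorted(alphabet), repeat=len(positions)):
        chars = list(template)
        for pos, res in zip(positions, combo):
            chars[pos] = res
        seq = "".join(chars)
        variants.append(
            PeptideVariant(sequence=seq, library_id=seq)
        )
    return variants


@dataclass(frozen=True)
class Species:
    """One reaction species with neutral masses and singly protonated m/z."""

    name: str
    sequence: str
    modifications: ModificationSet
    mass_mono: float
    mass_avg: float

    @property
    def mz_mono(self) -> float:
        return self.mass_mono + PROTON

    @property
    def mz_avg(self) -> float:
        return self.mass_avg + PROTON


@dataclass(frozen=True)
class SpeciesSet:
    """Precursor / linear / cyclic species (plus optional Δ14 satellites)."""

    variant_id: str
    species: dict[str, Species]

    def __getitem__(self, name: str) -> Species:
        return self.species[name]

    def __iter__(self):
        return iter(self.species.values())

    @property
    def parents(self) -> list[Species]:
        return [s for s in self if not s.modifications.demethylation]


def _fragment_disulfides(
    scaffold: ScaffoldSpec, length: int, sequence: str
) -> tuple[tuple[int, int], ...]:
    pairs = []
    for i, j in scaffold.disulfides:
        if i <= length and j <= length and sequence[i - 1] == "C" and sequence[j - 1] == "C":
            pairs.append((i, j))
    return tuple(pairs)


def expected_species(
    variant: PeptideVariant,
    scaffold: ScaffoldSpec,
    include_demethylated: bool = False,
) -> SpeciesSet:
    """Compute the species expected in a cyclization reaction of one variant.

    The precursor is the full template; cleavage after P1 removes the
    prime-side tail, leaving the linear product (residues 1..P1); the cyclic
    product is the same fragment head-to-tail condensed (-H2O).  Scaffold
    disulfides are applied wherever both Cys survive.  With
    ``include_demethylated``, each species gains a Δ14 (-CH2) satellite.
    """
    seq = variant.sequence
    if len(seq) != len(scaffold.template):
        raise ValueError("variant length does not match scaffold template")
    p1 = scaffold.p1_index
    core = seq[:p1]

    def build(name: str, s: str, mods: ModificationSet) -> Species:
        return Species(
            name=name,
            sequence=s,
            modifications=mods,
            mass_mono=peptide_mass(s, mods, "monoisotopic"),
            mass_avg=peptide_mass(s, mods, "average"),
        )

    prec_mods = ModificationSet(disulfide_pairs=_fragment_disulfides(scaffold, len(seq), seq))
    lin_mods = ModificationSet(disulfide_pairs=_fragment_disulfides(scaffold, p1, core))
    cyc_mods = replace(lin_mods, cyclization=True)

    out = {
        "precursor": build("precursor", seq, prec_mods),
        "linear": build("linear", core, lin_mods),
        "cyclic": build("cyclic", core, cyc_mods),
    }
    if include_demethylated:
        for key in ("precursor", "linear", "cyclic"):
            parent = out[key]
            mods = replace(parent.modifications, demethylation=True)
            out[key + "_demethyl"] = build(
                key + "_demethyl", parent.sequence, mods
            )
    vid = variant.library_id or seq
    return SpeciesSet(variant_id=vid, species=out)


#: Canonical scan-site order on the SFTI scaffold (nucleophile sites first).
SFTI_SCAN_SITES: tuple[str, ...] = ('P2"', 'P1"', "P3", "P2", "P1'", "P2'", "P3'")


def sfti_scaffold() -> ScaffoldSpec:
    """The 17-mer SFTI precursor scaffold with P1 Asp->Asn, as used for scanning.

    G1-R2-C3-T4-R5-S6-I7-P8-P9-I10-C11-F12-P13-N14-G15-L16-A17 with the
    Cys3-Cys11 disulfide.  Residue 2 is P2'' and residue 1 is P1'' (the
    incoming nucleophile's N-terminus); 12-14 are P3-P2-P1; 15-17 are P1'-P3'.
    """
    return ScaffoldSpec(
        template="GRCTRSIPPICFPNGLA",
        p_site_map={
            'P1"': 1,
            'P2"': 2,
            "P3": 12,
            "P2": 13,
            "P1": 14,
            "P1'": 15,
            "P2'": 16,
            "P3'": 17,
        },
        fixed_sites={14: "N"},
        disulfides=((3, 11),),
    )
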