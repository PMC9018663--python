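"""Elemental-formula arithmetic and the built-in steroid-ester registry.

The screening panel is seventeen anabolic steroid esters (testosterone,
nortestosterone, boldenone, estradiol, trenbolone and drostanolone esters)
commonly found in illicit oily injection preparations.  Each compound is
described by its neutral elemental formula, its protonated molecule
``[M+H]+`` (the only molecular species observed under an open ASAP source),
the m/z actually monitored in SIR mode, and the characteristic in-source
fragment ions produced at elevated cone voltages.

All mass arithmetic is at nominal (unit) resolution, the operating regime of
a single-quadrupole analyzer: integer mass numbers of the most abundant
isotope, no electron-mass correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from pyteomics import mass as _pymass

__all__ = [
    "Formula",
    "FragmentIon",
    "CompoundRecord",
    "nominal_mass",
    "monoisotopic_mass",
    "protonated_nominal_mz",
    "default_registry",
    "registry_table",
]

#: Elements with defined masses (sufficient for steroid esters).
SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "S")

#: element -> (nominal mass number, monoisotopic mass) of the most abundant isotope.
_MASSES: dict[str, tuple[int, float]] = {
    el: (int(round(_pymass.nist_mass[el][0][0])), float(_pymass.nist_mass[el][0][0]))
    for el in SUPPORTED_ELEMENTS
}


@dataclass(frozen=True)
class Formula:
    """An elemental formula, optionally charged (default +1 cation).

    Parameters
    ----------
    element_counts:
        Mapping of element symbol to a non-negative integer count.  At least
        one element must have a positive count.
    charge:
        Integer charge; +1 for the cations handled here.  Charge does not
        contribute mass at nominal resolution.
    """

    element_counts: Mapping[str, int]
    charge: int = 1

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        if not counts or all(n == 0 for n in counts.values()):
            raise ValueError("formula must contain at least one atom")
        for el, n in counts.items():
            if el not in _MASSES:
                raise ValueError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"element count for {el} must be a non-negative integer")
        object.__setattr__(self, "element_counts", counts)

    @classmethod
    def parse(cls, text: str, charge: int = 1) -> "Formula":
        """Parse a Hill-order formula string such as ``"C19H27O"``."""
        comp = _pymass.Composition(formula=text)
        return cls(dict(comp), charge=charge)

    def hill(self) -> str:
        """Formula string in Hill order (C, H, then alphabetical)."""
        counts = dict(self.element_counts)
        parts = []
        for el in ("C", "H"):
            if counts.get(el):
                n = counts.pop(el)
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(counts):
            if counts[el]:
                parts.append(el + (str(counts[el]) if counts[el] > 1 else ""))
        return "".join(parts)

    @property
    def atom_count(self) -> int:
        return sum(self.element_counts.values())


def nominal_mass(formula: Formula) -> int:
    """Nominal mass in Da: sum of integer mass numbers of the most abundant
    isotope (C=12, H=1, N=14, O=16, S=32)."""
    return sum(n * _MASSES[el][0] for el, n in formula.element_counts.items())


def monoisotopic_mass(formula: Formula) -> float:
    """Monoisotopic mass in Da from tabulated IUPAC isotope masses
    (C 12.0000, H 1.007825, N 14.003074, O 15.994915, S 31.972071)."""
    return sum(n * _MASSES[el][1] for el, n in formula.element_counts.items())


@dataclass(frozen=True)
class FragmentIon:
    """A characteristic in-source fragment ion at nominal resolution.

    ``formula`` is present only where an elemental assignment is established;
    when present its nominal mass must equal ``nominal_mz``.
    """

    nominal_mz: int
    formula: Formula | None = None
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.nominal_mz <= 0:
            raise ValueError("fragment m/z must be positive")
        if self.formula is not None and nominal_mass(self.formula) != self.nominal_mz:
            raise ValueError(
                f"fragment formula {self.formula.hill()} has nominal mass "
                f"{nominal_mass(self.formula)}, not {self.nominal_mz}"
            )


@dataclass(frozen=True)
class CompoundRecord:
    """One steroid ester of the screening panel.

    ``sir_mz`` is the m/z actually monitored in SIR mode, which equals the
    protonated molecule for every panel compound except testosterone
    isocaproate (see :attr:`sir_mz_discrepant`).
    """

    name: str
    abbreviation: str
    formula: Formula
    sir_mz: int
    fragments: tuple[FragmentIon, ...] = ()

    @property
    def protonated_mz(self) -> int:
        return protonated_nominal_mz(self)

    @property
    def sir_mz_discrepant(self) -> bool:
        """True when the monitored SIR m/z is not the compound's [M+H]+.

        Holds for testosterone isocaproate: the monitored m/z 289 equals
        protonated testosterone, not the isocaproate ester (387).  Both values
        are kept as-is rather than silently corrected.
        """
        return self.sir_mz != self.protonated_mz


def protonated_nominal_mz(record: CompoundRecord) -> int:
    """Nominal m/z of the protonated molecule [M+H]+ (= neutral mass + 1)."""
    return nominal_mass(record.formula) + 1


def _frag(mz: int, formula: str | None, annotation: str) -> FragmentIon:
    return FragmentIon(
        nominal_mz=mz,
        formula=Formula.parse(formula) if formula else None,
        annotation=annotation,
    )


# Fragment families.  Formulas are attached only where an elemental
# assignment is established; others carry annotation "assignment unclear".
_T_FRAGMENTS = (
    _frag(271, "C19H27O", "ester cleavage of [M+H]+"),
    _frag(109, "C7H9O", "B-ring cleavage"),
    _frag(105, "C7H5O", "B-ring cleavage"),
)
_BOLD_FRAGMENTS = (
    _frag(269, "C19H25O", "ester cleavage of [M+H]+"),
    _frag(135, "C10H15", "B-ring fission"),
    _frag(121, "C8H9O", "B-ring fission"),
)
_E2_CORE = (
    _frag(255, "C18H23O", "loss of R-COOH"),
    _frag(105, "C7H5O", "phenylcarbonyl"),
)
_E2_SHARED = (
    _frag(279, None, "assignment unclear"),
    _frag(159, None, "assignment unclear"),
    _frag(135, "C10H15", "B-ring fission"),
    _frag(109, "C7H9O", "B-ring cleavage"),
)
_TR_ESTER_FRAGMENTS = (
    _frag(271, "C18H23O2", "ester cleavage of [M+H]+"),
    _frag(253, "C18H21O", "water loss from m/z 271"),
    _frag(279, None, "ring cleavage, pathway unclear"),
)
_TR_PARENT_FRAGMENTS = (
    _frag(253, "C18H21O", "water loss from [M+H]+"),
    _frag(279, None, "ring cleavage, pathway unclear"),
)
_NPHPR_FRAGMENTS = (
    _frag(257, None, "ester cleavage of [M+H]+ (nandrolone series)"),
    _frag(155, None, "assignment unclear"),
    _frag(109, "C7H9O", "B-ring cleavage"),
)
_DEN_FRAGMENTS = (
    _frag(287, "C20H31O", "ester cleavage of [M+H]+"),
)

# name, abbreviation, neutral formula, monitored SIR m/z, fragments
_REGISTRY_SPEC: tuple[tuple[str, str, str, int, tuple[FragmentIon, ...]], ...] = (
    ("testosterone acetate", "T Ac", "C21H30O3", 331, _T_FRAGMENTS),
    ("testosterone propionate", "T Pr", "C22H32O3", 345, _T_FRAGMENTS),
    ("testosterone isocaproate", "T Iso", "C25H38O3", 289, _T_FRAGMENTS),
    ("testosterone enanthate", "T En", "C26H40O3", 401, _T_FRAGMENTS),
    ("testosterone decanoate", "T Dc", "C29H46O3", 443, _T_FRAGMENTS),
    ("testosterone benzoate", "T Bz", "C26H32O3", 393, _T_FRAGMENTS),
    ("testosterone phenylpropionate", "T PhPr", "C28H36O3", 421, _T_FRAGMENTS),
    ("testosterone cypionate", "T Cy", "C27H40O3", 413, _T_FRAGMENTS),
    ("nortestosterone phenylpropionate", "N PhPr", "C27H34O3", 407, _NPHPR_FRAGMENTS),
    ("boldenone undecylenate", "B Un", "C30H44O3", 453, _BOLD_FRAGMENTS),
    ("estradiol dipropionate", "E2 DiPr", "C24H32O4", 385, _E2_CORE + _E2_SHARED),
    ("estradiol valerate", "E2 V1", "C23H32O3", 357, _E2_CORE + _E2_SHARED),
    ("estradiol benzoate", "E2 Bz", "C25H28O3", 377, _E2_CORE),
    ("trenbolone", "Tr", "C18H22O2", 271, _TR_PARENT_FRAGMENTS),
    ("trenbolone acetate", "Tr Ac", "C20H24O3", 313, _TR_ESTER_FRAGMENTS),
    ("trenbolone enanthate", "Tr En", "C25H34O3", 383, _TR_ESTER_FRAGMENTS),
    ("drostanolone enanthate", "D En", "C27H44O3", 417, _DEN_FRAGMENTS),
)


def default_registry() -> list[CompoundRecord]:
    """The built-in panel of 17 steroid esters.

    Neutral formulas are fixed from standard chemical identity; every
    protonated m/z is consistent with the monitored SIR value except
    testosterone isocaproate, whose record carries both values and flags the
    discrepancy.
    """
    records = []
    for name, abbr, formula, sir_mz, frags in _REGISTRY_SPEC:
        records.append(
            CompoundRecord(
                name=name,
                abbreviation=abbr,
                formula=Formula.parse(formula, charge=0),
                sir_mz=sir_mz,
                fragments=frags,
            )
        )
    abbrs = [r.abbreviation for r in records]
    if len(set(abbrs)) != len(abbrs):  # pragma: no cover - registry authoring guard
        raise AssertionError("registry abbreviations must be unique")
    return records


def registry_lookup(registry: Sequence[CompoundRecord] | None = None) -> dict[str, CompoundRecord]:
    """Map abbreviation -> record for ``registry`` (default panel if None)."""
    if registry is None:
        registry = default_registry()
    return {r.abbreviation: r for r in registry}


def registry_table(registry: Sequence[CompoundRecord] | None = None) -> str:
    """The registry as a tab-separated table (one row per compound)."""
    if registry is None:
        registry = default_registry()
    lines = ["abbreviation\tname\tformula\tprotonated_mz\tsir_mz\tfragments"]
    for r in registry:
        frags = ",".join(str(f.nominal_mz) for f in r.fragments)
        lines.append(
            f"{r.abbreviation}\t{r.name}\t{r.formula.hill()}\t{r.protonated_mz}\t{r.sir_mz}\t{frags}"
        )
    return "\n".join(lines) + "\n"
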