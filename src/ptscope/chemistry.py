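"""Masses and MRM transitions for PT dinucleotides and deoxyribonucleosides.

Nuclease P1 limit digestion of PT-containing DNA releases the modified
linkage as an intact dinucleotide d(N1*N2) (the phosphorothioate diester
resists the nuclease), so targeted LC-MS/MS monitors 16 possible PT
dinucleotides alongside the four canonical 2'-deoxyribonucleosides.  This
module computes the underlying elemental compositions, neutral monoisotopic
masses and protonated m/z values, and assembles the 20-row transition
reference (precursor and product ions, retention-time windows, collision
energies) used for dynamic multiple-reaction monitoring in positive mode.

Product ions are the protonated free nucleobases (adenine 136.1, guanine
152.1, thymine 127.1, cytosine 112.1), the dominant fragments of both
nucleosides and PT dinucleotides under CID.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

DNA_BASES = ("A", "C", "G", "T")

#: IUPAC monoisotopic atomic masses (Da) of the most abundant isotopes.
ATOMIC_MASS = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
}

#: Mass of a proton (Da); added for [M+H]+ species.
PROTON_MASS = 1.00727646

_ELEMENTS = ("C", "H", "N", "O", "P", "S")


@dataclass(frozen=True)
class ElementalComposition:
    """Integer atom counts over C, H, N, O, P, S.

    Supports element-wise addition and subtraction; subtraction that would
    drive any count negative raises ``ValueError``.
    """

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in _ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count in composition")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) + getattr(other, el) for el in _ELEMENTS}
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = {el: getattr(self, el) - getattr(other, el) for el in _ELEMENTS}
        if any(v < 0 for v in counts.values()):
            raise ValueError("composition subtraction yields a negative count")
        return ElementalComposition(**counts)

    def formula(self) -> str:
        """Hill-style formula string, e.g. ``C20H25N10O7PS``."""
        parts = []
        for el in _ELEMENTS:
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)


WATER = ElementalComposition(H=2, O=1)
PHOSPHORIC_ACID = ElementalComposition(H=3, P=1, O=4)

# Neutral 2'-deoxyribonucleosides (free 5'-OH and 3'-OH).
_NUCLEOSIDE = {
    "A": ElementalComposition(C=10, H=13, N=5, O=3),  # 2'-deoxyadenosine
    "C": ElementalComposition(C=9, H=13, N=3, O=4),   # 2'-deoxycytidine
    "G": ElementalComposition(C=10, H=13, N=5, O=4),  # 2'-deoxyguanosine
    "T": ElementalComposition(C=10, H=14, N=2, O=5),  # thymidine
}

# Free nucleobases (CID product ions are these + proton).
_NUCLEOBASE = {
    "A": ElementalComposition(C=5, H=5, N=5),          # adenine
    "C": ElementalComposition(C=4, H=5, N=3, O=1),     # cytosine
    "G": ElementalComposition(C=5, H=5, N=5, O=1),     # guanine
    "T": ElementalComposition(C=5, H=6, N=2, O=2),     # thymine
}


def _check_base(base: str) -> str:
    if base not in DNA_BASES:
        raise ValueError(f"unknown DNA base {base!r}; expected one of {DNA_BASES}")
    return base


def compose_nucleoside(base: str) -> ElementalComposition:
    """Composition of the neutral 2'-deoxyribonucleoside of ``base``."""
    return _NUCLEOSIDE[_check_base(base)]


def compose_nucleobase(base: str) -> ElementalComposition:
    """Composition of the free nucleobase of ``base``."""
    return _NUCLEOBASE[_check_base(base)]


def compose_pt_dinucleotide(base5: str, base3: str) -> ElementalComposition:
    """Composition of the PT-bridged dinucleotide d(base5*base3).

    Formed by condensing the two nucleosides with phosphoric acid (two
    waters leave) and exchanging one non-bridging phosphate oxygen for
    sulfur — the phosphorothioate diester with free 5'-OH/3'-OH termini.
    The result is symmetric in the two bases.
    """
    dimer = (
        compose_nucleoside(base5)
        + compose_nucleoside(base3)
        + PHOSPHORIC_ACID
        - WATER
        - WATER
    )
    return dimer - ElementalComposition(O=1) + ElementalComposition(S=1)


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Neutral monoisotopic mass (Da) of a composition."""
    return sum(ATOMIC_MASS[el] * getattr(comp, el) for el in _ELEMENTS)


def protonated_mz(comp: ElementalComposition, decimals: int = 5) -> float:
    """m/z of the [M+H]+ species, rounded (round-half-even) to ``decimals``."""
    return round(monoisotopic_mass(comp) + PROTON_MASS, decimals)


def product_ion_mz(base: str) -> float:
    """Protonated free-nucleobase m/z of ``base``, to 1 decimal."""
    return round(monoisotopic_mass(compose_nucleobase(base)) + PROTON_MASS, 1)


@dataclass
class TransitionRecord:
    """One compound's MRM parameters: precursor, products, RT, energies."""

    compound: str
    exact_mz: float                 # protonated species, 5 decimals
    precursor_mz: float             # exact_mz rounded to 1 decimal
    product_mz: list[float]
    rt_window_min: tuple[float, float]
    collision_energy_V: list[float]
    cell_accelerator_V: list[float] = field(default_factory=list)
    stereochemistry: str = "Rp"     # natural PTs are the Rp diastereomer


def pt_label(base5: str, base3: str) -> str:
    return f"d({base5}*{base3})"


def _load_instrument_params() -> pd.DataFrame:
    """Packaged per-transition instrument parameters (measured, not derivable)."""
    with resources.files("ptscope.data").joinpath("ms_params.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def build_reference_table() -> list[TransitionRecord]:
    """Assemble the 20-row MRM reference: 16 PT dinucleotides + dA/dC/dG/dT.

    Exact m/z values are computed from elemental compositions; retention
    times, collision energies and cell-accelerator voltages come from the
    packaged instrument-parameter file.  When the file carries a printed
    precursor that disagrees with the computed one (the d(A*T)/d(T*A) rows,
    whose published exact mass is one hydrogen too high), the computed value
    is emitted and a warning is logged.
    """
    params = _load_instrument_params()
    records: list[TransitionRecord] = []
    for compound, grp in params.groupby("compound", sort=False):
        if compound.startswith("d("):
            b5, b3 = compound[2], compound[4]
            comp = compose_pt_dinucleotide(b5, b3)
            prod_bases = {b5, b3}
        else:
            b = compound[1]
            comp = compose_nucleoside(b)
            prod_bases = {b}
        exact = protonated_mz(comp)
        precursor = round(exact, 1)
        printed_exact = grp["exact_mass_printed"].iloc[0]
        printed_prec = grp["precursor_printed"].iloc[0]
        if abs(printed_exact - exact) > 5e-5:
            logger.warning(
                "%s: published exact mass %.5f disagrees with computed [M+H]+ "
                "%.5f by %+.5f; emitting the computed value",
                compound, printed_exact, exact, printed_exact - exact,
            )
        if abs(printed_prec - precursor) > 0.05:
            logger.warning(
                "%s: published precursor %.1f disagrees with computed %.1f; "
                "emitting the computed value",
                compound, printed_prec, precursor,
            )
        products = [round(p, 1) for p in grp["product_mz"]]
        expected = {product_ion_mz(b) for b in prod_bases}
        if not set(products) <= expected:
            raise ValueError(
                f"{compound}: product ions {products} are not protonated "
                f"nucleobases of its bases ({sorted(expected)})"
            )
        records.append(
            TransitionRecord(
                compound=compound,
                exact_mz=exact,
                precursor_mz=precursor,
                product_mz=products,
                rt_window_min=(grp["rt_min_lo"].min(), grp["rt_min_hi"].max()),
                collision_energy_V=list(grp["collision_energy_V"]),
                cell_accelerator_V=list(grp["cell_accelerator_V"]),
            )
        )
    return records


def reference_table_frame() -> pd.DataFrame:
    """The reference table as a tidy DataFrame (one row per transition)."""
    rows = []
    for rec in build_reference_table():
        for prod, ce, cav in zip(
            rec.product_mz, rec.collision_energy_V, rec.cell_accelerator_V
        ):
            rows.append(
                {
                    "compound": rec.compound,
                    "exact_mz": rec.exact_mz,
                    "precursor_mz": rec.precursor_mz,
                    "product_mz": prod,
                    "rt_min_lo": rec.rt_window_min[0],
                    "rt_min_hi": rec.rt_window_min[1],
                    "collision_energy_V": ce,
                    "cell_accelerator_V": cav,
                }
            )
    return pd.DataFrame(rows)


def rt_windows() -> dict[str, tuple[float, float]]:
    """Retention-time window (min) per compound label."""
    return {rec.compound: rec.rt_window_min for rec in build_reference_table()}
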