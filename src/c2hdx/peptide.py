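"""Peptide sequence model: parsing, elemental composition, isotope envelopes, fragments.

Sequence notation
-----------------
One-letter amino-acid codes, read N- to C-terminus.  Extensions:

* ``H[p]`` — phosphohistidine (adds HPO3 to the His side chain);
* ``bD``  — beta-linked aspartate (compositionally identical to Asp, the
  beta linkage is an isomerism invisible to mass-based observables);
* a trailing ``-NH2`` — C-terminal amide instead of the free acid.

Example: ``"bDRVYIH[p]PF-NH2"``.

Compositions and monoisotopic masses come from the pyteomics residue and
isotope tables (CIAAW/NIST values); isotope envelopes are computed by exact
per-element polynomial convolution, truncated to the requested number of
peaks and renormalized.  No averagine approximation is used: the peptides
this package targets are short enough that the exact distribution is cheap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "PHOS_HIS",
    "BETA_ASP",
    "PROTON_MASS",
    "Peptide",
    "FragmentIon",
    "ParseError",
    "parse_sequence",
    "elemental_composition",
    "monoisotopic_mass",
    "natural_envelope",
    "fragment_ions",
]

PHOS_HIS = "PHOS_HIS"
BETA_ASP = "BETA_ASP"

#: Mass of a proton (charge carrier for singly protonated ions), Da.
PROTON_MASS = _pmass.nist_mass["H+"][0][0]

# Composition delta of N-phosphorylation on the imidazole ring.
_HPO3 = _pmass.Composition(formula="HPO3")
# Caps: free-acid C-terminus contributes H2O to the neutral peptide,
# an amidated C-terminus contributes NH3 instead.
_H2O = _pmass.Composition(formula="H2O")
_NH3 = _pmass.Composition(formula="NH3")

_AA = set("ACDEFGHIKLMNPQRSTVWY")


class ParseError(ValueError):
    """Raised when a sequence string cannot be interpreted."""


@dataclass(frozen=True)
class Peptide:
    """A linear peptide with termini and site modifications.

    ``residues`` are one-letter codes; positions are 1-based from the
    N-terminus.  ``modifications`` maps position -> tag (``PHOS_HIS`` or
    ``BETA_ASP``).
    """

    residues: Tuple[str, ...]
    c_terminus: str = "free-acid"  # or "amide"
    n_terminus: str = "free-amine"
    modifications: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("peptide must contain at least one residue")
        for r in self.residues:
            if r not in _AA:
                raise ValueError(f"unknown residue {r!r}")
        if self.c_terminus not in ("free-acid", "amide"):
            raise ValueError(f"unknown C-terminus {self.c_terminus!r}")
        for pos, tag in self.modifications.items():
            if not 1 <= pos <= len(self.residues):
                raise ValueError(f"modification position {pos} outside 1..{len(self.residues)}")
            if tag == PHOS_HIS and self.residues[pos - 1] != "H":
                raise ValueError(f"PHOS_HIS at position {pos} but residue is {self.residues[pos - 1]!r}")
            if tag == BETA_ASP and self.residues[pos - 1] != "D":
                raise ValueError(f"BETA_ASP at position {pos} but residue is {self.residues[pos - 1]!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def his_positions(self) -> Tuple[int, ...]:
        return tuple(i + 1 for i, r in enumerate(self.residues) if r == "H")

    @property
    def is_phosphorylated(self) -> bool:
        return PHOS_HIS in self.modifications.values()

    def display(self) -> str:
        """Round-trip the notation this peptide was parsed from."""
        out = []
        for i, r in enumerate(self.residues, start=1):
            tag = self.modifications.get(i)
            if tag == BETA_ASP:
                out.append("bD")
            elif tag == PHOS_HIS:
                out.append("H[p]")
            else:
                out.append(r)
        s = "".join(out)
        if self.c_terminus == "amide":
            s += "-NH2"
        return s


_TOKEN = re.compile(r"bD|[A-Z](\[p\])?")


def parse_sequence(text: str) -> Peptide:
    """Parse the package's sequence notation into a :class:`Peptide`.

    Raises :class:`ParseError` naming the offending token and its
    character position on any unrecognized input.
    """
    if not text:
        raise ParseError("empty sequence")
    c_term = "free-acid"
    body = text
    if body.endswith("-NH2"):
        c_term = "amide"
        body = body[: -len("-NH2")]
    residues: List[str] = []
    mods: Dict[int, str] = {}
    i = 0
    while i < len(body):
        m = _TOKEN.match(body, i)
        if m is None:
            raise ParseError(f"unrecognized token {body[i]!r} at character {i + 1} of {text!r}")
        tok = m.group(0)
        pos = len(residues) + 1
        if tok == "bD":
            residues.append("D")
            mods[pos] = BETA_ASP
        elif tok.endswith("[p]"):
            letter = tok[0]
            if letter != "H":
                raise ParseError(f"[p] tag on {letter!r} at character {i + 1}: phosphorylation is modeled on His only")
            residues.append("H")
            mods[pos] = PHOS_HIS
        else:
            if tok not in _AA:
                raise ParseError(f"unknown residue {tok!r} at character {i + 1} of {text!r}")
            residues.append(tok)
        i = m.end()
    return Peptide(tuple(residues), c_terminus=c_term, modifications=mods)


def _residue_comp(residue: str, mod: Optional[str]) -> _pmass.Composition:
    comp = _pmass.std_aa_comp[residue].copy()
    if mod == PHOS_HIS:
        comp += _HPO3
    return comp


def elemental_composition(p: Peptide) -> _pmass.Composition:
    """Elemental composition of the neutral peptide.

    Residue compositions already carry the amide-bond water loss; the free
    termini add one H2O (or NH3 for a C-terminal amide).
    """
    comp = _pmass.Composition()
    for i, r in enumerate(p.residues, start=1):
        comp += _residue_comp(r, p.modifications.get(i))
    comp += _NH3 if p.c_terminus == "amide" else _H2O
    return comp


def monoisotopic_mass(c: _pmass.Composition) -> float:
    """Monoisotopic mass (Da) of an elemental composition."""
    if not c or sum(c.values()) == 0:
        raise ValueError("empty elemental composition has no mass")
    for el in c:
        if el.rstrip("+-") and el.rstrip("+-") not in _pmass.nist_mass:
            raise ValueError(f"unknown element {el!r}")
    return _pmass.calculate_mass(composition=c)


def _element_distribution(element: str) -> np.ndarray:
    """Per-atom isotope distribution indexed by nucleon offset from the lightest isotope."""
    iso = _pmass.nist_mass[element]
    numbers = sorted(a for a in iso if a != 0 and iso[a][1] > 0)
    if not numbers:
        raise ValueError(f"no isotopic abundances for element {element!r}")
    lightest = numbers[0]
    dist = np.zeros(numbers[-1] - lightest + 1)
    for a in numbers:
        dist[a - lightest] = iso[a][1]
    return dist / dist.sum()


def _conv_trunc(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    return np.convolve(a, b)[:n]

def natural_envelope(c: _pmass.Composition, n_peaks: int = 8) -> np.ndarray:
    """Natural isotope envelope at integer offsets 0..n_peaks-1 from the monoisotopic peak.

    Exact polynomial convolution of per-element distributions (truncation to
    ``n_peaks`` terms during the convolution is exact for the retained
    coefficients), renormalized to sum to 1.
    """
    if n_peaks < 2:
        raise ValueError("n_peaks must be >= 2")
    env = np.zeros(n_peaks)
    env[0] = 1.0
    for el, count in c.items():
        if count < 0:
            raise ValueError(f"negative atom count for {el!r}")
        if count == 0 or not el.rstrip("+-"):
            continue
        base = _element_distribution(el.rstrip("+-") or el)
        # exponentiation by squaring with truncation
        power = base
        k = int(count)
        while k:
            if k & 1:
                env = _conv_trunc(env, power, n_peaks)
            k >>= 1
            if k:
                power = _conv_trunc(power, power, n_peaks)
    if env.size < n_peaks:
        env = np.pad(env, (0, n_peaks - env.size))
    return env / env.sum()


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-type backbone fragment with His bookkeeping."""

    ion_type: str  # "b" | "y"
    index: int
    composition: _pmass.Composition
    singly_protonated_mass: float
    contains_his: bool
    contains_exchange_site: bool

    @property
    def label(self) -> str:
        return f"{self.ion_type}{self.index}"


def fragment_ions(p: Peptide, exchange_site: Optional[int] = None) -> List[FragmentIon]:
    """All b_i and y_i (i = 1..len-1) with His-containment flags.

    ``exchange_site`` is the 1-based position of the His whose C2 proton is
    the exchange site.  When omitted it defaults to the peptide's unique
    His; for multi-His peptides it must be given explicitly, since intact-
    mass data cannot identify which ring exchanged.
    """
    n = len(p)
    if n < 2:
        raise ValueError("fragments require at least 2 residues")
    his = p.his_positions
    if exchange_site is None:
        if len(his) == 1:
            exchange_site = his[0]
        elif len(his) > 1:
            raise ValueError("multi-His peptide: designate the exchange site explicitly")
    elif exchange_site not in his:
        raise ValueError(f"exchange_site {exchange_site} is not a His position {his}")

    out: List[FragmentIon] = []
    for i in range(1, n):
        b_comp = _pmass.Composition()
        for j in range(1, i + 1):
            b_comp += _residue_comp(p.residues[j - 1], p.modifications.get(j))
        y_comp = _pmass.Composition()
        for j in range(i + 1, n + 1):
            y_comp += _residue_comp(p.residues[j - 1], p.modifications.get(j))
        # b_i is the protonated N-terminal residue sum; y_i additionally keeps
        # the C-terminal cap, so mass(b_i) + mass(y_{n-i}) = mass([M+H]+) + proton.
        y_comp += _NH3 if p.c_terminus == "amide" else _H2O
        b_mass = monoisotopic_mass(b_comp) + PROTON_MASS
        y_mass = monoisotopic_mass(y_comp) + PROTON_MASS
        b_span = range(1, i + 1)
        y_span = range(i + 1, n + 1)
        out.append(
            FragmentIon(
                "b", i, b_comp, b_mass,
                contains_his=any(p.residues[j - 1] == "H" for j in b_span),
                contains_exchange_site=exchange_site in b_span if exchange_site else False,
            )
        )
        out.append(
            FragmentIon(
                "y", n - i, y_comp, y_mass,
                contains_his=any(p.residues[j - 1] == "H" for j in y_span),
                contains_exchange_site=exchange_site in y_span if exchange_site else False,
            )
        )
    out.sort(key=lambda f: (f.ion_type, f.index))
    return out
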