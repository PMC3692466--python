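"""Per-sequence physicochemical profiles.

Every sequence (an MTS or a mature chain) is summarised by twelve
variables: length, net charge at a working pH (default 7.5), isoelectric
point, and the fractions of nine physicochemical residue groups obtained
by collapsing the 20-letter alphabet:

=====  =======================  ========
code   group                    residues
=====  =======================  ========
a      non-polar aliphatic      G A V I L
f      non-polar aromatic       F W
p      non-polar cyclic         P
c      polar sulphur            C M
s      polar hydroxyl           S T
y      polar aromatic           Y
n      polar acidic-amide       N Q
d      acidic                   D E
b      basic                    R H K
=====  =======================  ========

Charge is a Henderson–Hasselbalch sum over ionizable side chains and,
optionally, the free termini; the pI is the unique root of that sum in pH.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import yaml

__all__ = [
    "GROUP_RESIDUES",
    "GROUP_ORDER",
    "UNKNOWN_RESIDUES",
    "ReducedAlphabetMap",
    "NINE_GROUPS",
    "ChargeModel",
    "SequenceProperties",
    "PROPERTY_NAMES",
    "reduce_sequence",
    "composition",
    "net_charge",
    "isoelectric_point",
    "sequence_properties",
]

GROUP_RESIDUES: dict[str, str] = {
    "a": "GAVIL",
    "f": "FW",
    "p": "P",
    "c": "CM",
    "s": "ST",
    "y": "Y",
    "n": "NQ",
    "d": "DE",
    "b": "RHK",
}

#: canonical ordering of the nine group codes in tables and arrays
GROUP_ORDER: str = "afpcsyndb"

#: residues accepted on input but excluded from chemistry ('?' when reduced)
UNKNOWN_RESIDUES: frozenset[str] = frozenset("XBZUOJ")

STANDARD_RESIDUES: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: the 12 per-sequence variables, in output order
PROPERTY_NAMES: tuple[str, ...] = (
    "length",
    "charge_pH",
    "pI",
) + tuple(f"frac_{g}" for g in GROUP_ORDER)


@dataclass(frozen=True)
class ReducedAlphabetMap:
    """Many-to-one residue -> group-code map partitioning the 20 residues."""

    groups: dict[str, str] = field(default_factory=lambda: dict(GROUP_RESIDUES))

    def __post_init__(self) -> None:
        covered: list[str] = []
        for members in self.groups.values():
            covered.extend(members)
        if sorted(covered) != sorted(STANDARD_RESIDUES):
            raise ValueError("groups must partition the 20 standard residues")

    @property
    def residue_to_group(self) -> dict[str, str]:
        return {r: g for g, members in self.groups.items() for r in members}


NINE_GROUPS = ReducedAlphabetMap()
_R2G = NINE_GROUPS.residue_to_group


@dataclass(frozen=True)
class ChargeModel:
    """A named pKa set for side chains and the two free termini.

    ``acidic`` residues contribute -1 when deprotonated, ``basic`` ones +1
    when protonated; the N-terminal amine behaves as basic and the
    C-terminal carboxyl as acidic.
    """

    name: str
    pka: dict[str, float]

    ACIDIC = ("D", "E", "C", "Y")
    BASIC = ("R", "H", "K")

    def __post_init__(self) -> None:
        required = set(self.ACIDIC) | set(self.BASIC) | {"nterm", "cterm"}
        missing = required - set(self.pka)
        if missing:
            raise ValueError(f"pKa set {self.name!r} missing {sorted(missing)}")
        for key, value in self.pka.items():
            if not 0.0 < float(value) < 14.0:
                raise ValueError(f"pKa out of (0,14): {key}={value}")

    @classmethod
    def available_sets(cls) -> dict[str, dict[str, float]]:
        text = (
            importlib.resources.files("mtsprofile.data")
            .joinpath("pka_sets.yaml")
            .read_text()
        )
        return yaml.safe_load(text)

    @classmethod
    def from_name(cls, name: str = "bjellqvist") -> "ChargeModel":
        sets = cls.available_sets()
        if name not in sets:
            raise KeyError(f"unknown pKa set {name!r}; have {sorted(sets)}")
        return cls(name=name, pka={k: float(v) for k, v in sets[name].items()})


@dataclass(frozen=True)
class SequenceProperties:
    """The 12-variable profile of one sequence."""

    length: int
    charge_pH: float
    pI: float
    frac_a: float
    frac_f: float
    frac_p: float
    frac_c: float
    frac_s: float
    frac_y: float
    frac_n: float
    frac_d: float
    frac_b: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PROPERTY_NAMES}


def reduce_sequence(seq: str, alphabet: ReducedAlphabetMap = NINE_GROUPS) -> str:
    """Rewrite *seq* in group codes; unknown residues become ``?``."""
    r2g = _R2G if alphabet is NINE_GROUPS else alphabet.residue_to_group
    out = []
    for res in seq:
        if res in r2g:
            out.append(r2g[res])
        elif res in UNKNOWN_RESIDUES:
            out.append("?")
        else:
            raise ValueError(f"invalid residue {res!r}")
    return "".join(out)


def composition(
    seq: str, alphabet: ReducedAlphabetMap = NINE_GROUPS
) -> dict[str, float]:
    """Fraction of each group among the classifiable residues of *seq*.

    Unknown residues are excluded from both numerator and denominator.
    Raises ``ValueError`` when no residue can be classified.
    """
    if not seq:
        raise ValueError("empty sequence")
    reduced = reduce_sequence(seq, alphabet)
    counts = {g: 0 for g in alphabet.groups}
    total = 0
    for code in reduced:
        if code != "?":
            counts[code] += 1
            total += 1
    if total == 0:
        raise ValueError("sequence has no classifiable residues")
    return {g: counts[g] / total for g in counts}


def net_charge(
    seq: str,
    pH: float,
    model: ChargeModel | None = None,
    include_termini: bool = True,
) -> float:
    """Henderson–Hasselbalch net charge of *seq* at *pH*, in elementary charges.

    charge = sum_basic 1/(1+10^(pH-pKa)) - sum_acidic 1/(1+10^(pKa-pH)),
    over side chains with a pKa (and the termini when *include_termini*).
    Residues without a pKa contribute zero.
    """
    if not seq:
        raise ValueError("empty sequence")
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH out of (0,14): {pH}")
    if model is None:
        model = ChargeModel.from_name()
    charge = 0.0
    for res in model.BASIC:
        n = seq.count(res)
        if n:
            charge += n / (1.0 + 10.0 ** (pH - model.pka[res]))
    for res in model.ACIDIC:
        n = seq.count(res)
        if n:
            charge -= n / (1.0 + 10.0 ** (model.pka[res] - pH))
    if include_termini:
        charge += 1.0 / (1.0 + 10.0 ** (pH - model.pka["nterm"]))
        charge -= 1.0 / (1.0 + 10.0 ** (model.pka["cterm"] - pH))
    return charge


def isoelectric_point(
    seq: str,
    model: ChargeModel | None = None,
    tol: float = 1e-3,
    max_iter: int = 60,
) -> float:
    """pH at which the net charge (termini included) crosses zero.

    The charge is strictly decreasing in pH and the termini guarantee a
    sign change on (0, 14), so bisection converges to the unique root.
    *max_iter* halvings land far below the guaranteed *tol* of 1e-3 pH
    units, which keeps the net charge at the returned pI near zero even
    for sequences dense in ionizable residues (steep titration curves).
    """
    if model is None:
        model = ChargeModel.from_name()
    iterations = max(max_iter, math.ceil(math.log2(14.0 / tol)))
    lo, hi = 0.0 + 1e-9, 14.0 - 1e-9
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, model, include_termini=True) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sequence_properties(
    seq: str,
    pH: float = 7.5,
    alphabet: ReducedAlphabetMap = NINE_GROUPS,
    model: ChargeModel | None = None,
    include_termini: bool = True,
) -> SequenceProperties:
    """Bundle length, charge at *pH*, pI and the nine group fractions."""
    if model is None:
        model = ChargeModel.from_name()
    fracs = composition(seq, alphabet)
    return SequenceProperties(
        length=len(seq),
        charge_pH=net_charge(seq, pH, model, include_termini),
        pI=isoelectric_point(seq, model),
        **{f"frac_{g}": fracs[g] for g in GROUP_ORDER},
    )
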