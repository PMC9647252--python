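"""Lipid nomenclature: parsing and canonical formatting of species labels.

Labels follow the ``CLASS(c:d_c:d...)`` convention where each ``c:d`` token is
an acyl chain with ``c`` carbons and ``d`` double bonds.  Several dialects seen
in deposited matrices are accepted on input and normalized:

* optional whitespace before the parenthesis: ``"PE (16:0_18:2)"``;
* ``/`` as chain separator and sphingoid prefixes: ``"SM(d18:1/16:0)"``;
* summed triacylglycerol composition without chain resolution: ``"TAG52:3"``
  (read-only; such species carry totals but no chain list).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple

__all__ = [
    "LipidClass",
    "LipidName",
    "LipidParseError",
    "UnknownClassError",
    "ChainArityError",
    "parse_lipid_name",
    "CHAIN_COUNT",
]


class LipidClass(str, Enum):
    TAG = "TAG"
    DAG = "DAG"
    MAG = "MAG"
    PE = "PE"
    PC = "PC"
    PI = "PI"
    LPE = "LPE"
    LPC = "LPC"
    SM = "SM"
    CER = "CER"
    HCER = "HCER"
    LCER = "LCER"
    DCER = "DCER"
    CE = "CE"
    FFA = "FFA"


#: Number of acyl chains carried by each class.
CHAIN_COUNT = {
    LipidClass.TAG: 3,
    LipidClass.DAG: 2,
    LipidClass.PE: 2,
    LipidClass.PC: 2,
    LipidClass.PI: 2,
    LipidClass.SM: 2,
    LipidClass.CER: 2,
    LipidClass.HCER: 2,
    LipidClass.LCER: 2,
    LipidClass.DCER: 2,
    LipidClass.MAG: 1,
    LipidClass.LPE: 1,
    LipidClass.LPC: 1,
    LipidClass.CE: 1,
    LipidClass.FFA: 1,
}


class LipidParseError(ValueError):
    """Raised when a lipid label cannot be parsed."""


class UnknownClassError(LipidParseError):
    """Raised when the class token of a label is not recognized."""


class ChainArityError(LipidParseError):
    """Raised when the number of chains does not match the class."""


Chain = Tuple[int, int]


@dataclass(frozen=True)
class LipidName:
    """Parsed lipid identity: class plus acyl chains.

    ``chains`` is ``None`` for the summed-TAG dialect, in which case
    ``summed`` holds the total (carbons, double_bonds) composition.
    Equality and hashing ignore ``raw_label`` so that dialect variants of the
    same species compare equal after canonicalization.
    """

    lipid_class: LipidClass
    chains: Optional[Tuple[Chain, ...]]
    raw_label: str = field(default="", compare=False)
    summed: Optional[Chain] = None

    def __post_init__(self) -> None:
        if self.chains is None and self.summed is None:
            raise LipidParseError("either chains or summed totals required")
        if self.chains is not None:
            arity = CHAIN_COUNT[self.lipid_class]
            if len(self.chains) != arity:
                raise ChainArityError(
                    f"{self.lipid_class.value} requires {arity} chains, "
                    f"got {len(self.chains)}"
                )
            for c, d in self.chains:
                if c < 2:
                    raise LipidParseError(f"chain carbons must be >= 2, got {c}")
                if d < 0 or d > c:
                    raise LipidParseError(
                        f"double bonds must be in [0, carbons], got {c}:{d}"
                    )
            # canonical chain order: sorted by (carbons, double bonds)
            object.__setattr__(self, "chains", tuple(sorted(self.chains)))

    # -- derived quantities -------------------------------------------------

    @property
    def total_carbons(self) -> int:
        if self.chains is None:
            return self.summed[0]  # type: ignore[index]
        return sum(c for c, _ in self.chains)

    @property
    def total_double_bonds(self) -> int:
        if self.chains is None:
            return self.summed[1]  # type: ignore[index]
        return sum(d for _, d in self.chains)

    @property
    def is_summed(self) -> bool:
        return self.chains is None

    @property
    def key(self):
        """Exact matching key (class + sorted chains, or summed totals)."""
        if self.chains is None:
            return (self.lipid_class.value, "sum", self.summed)
        return (self.lipid_class.value, self.chains)

    @property
    def total_key(self):
        """Composition-level key: class + total carbons:double bonds."""
        return (self.lipid_class.value, self.total_carbons, self.total_double_bonds)

    # -- formatting ---------------------------------------------------------

    def format(self) -> str:
        if self.chains is None:
            c, d = self.summed  # type: ignore[misc]
            return f"{self.lipid_class.value}{c}:{d}"
        body = "_".join(f"{c}:{d}" for c, d in self.chains)
        return f"{self.lipid_class.value}({body})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


_LABEL_RE = re.compile(
    r"^\s*(?P<cls>[A-Za-z]+)\s*"
    r"(?:\(\s*(?P<body>[^)]*?)\s*\)|(?P<bare>[0-9]+:[0-9]+))\s*$"
)
_CHAIN_RE = re.compile(r"^[dtme]?-?(?P<c>[0-9]+):(?P<d>[0-9]+)$")


def parse_lipid_name(label: str) -> LipidName:
    """Parse a lipid species label into a :class:`LipidName`.

    Raises
    ------
    UnknownClassError
        If the leading class token is not one of the known classes.
    ChainArityError
        If the chain count does not match the class arity.
    LipidParseError
        For any other malformed label.
    """
    if not label or not label.strip():
        raise LipidParseError("empty lipid label")
    m = _LABEL_RE.match(label)
    if m is None:
        raise LipidParseError(f"cannot parse lipid label {label!r}")
    cls_token = m.group("cls").upper()
    try:
        cls = LipidClass(cls_token)
    except ValueError:
        raise UnknownClassError(f"unknown lipid class token {cls_token!r}") from None

    body = m.group("body")
    if body is None:
        body = m.group("bare")
    tokens = [t for t in re.split(r"[_/]", body) if t.strip()]
    if not tokens:
        raise LipidParseError(f"no chains found in {label!r}")

    chains = []
    for tok in tokens:
        cm = _CHAIN_RE.match(tok.strip())
        if cm is None:
            raise LipidParseError(f"cannot parse chain token {tok!r} in {label!r}")
        chains.append((int(cm.group("c")), int(cm.group("d"))))

    arity = CHAIN_COUNT[cls]
    if cls is LipidClass.TAG and len(chains) == 1:
        # summed-composition dialect, e.g. "TAG52:3"
        return LipidName(cls, None, raw_label=label, summed=chains[0])
    if len(chains) != arity:
        raise ChainArityError(
            f"{cls.value} requires {arity} chains, got {len(chains)} in {label!r}"
        )
    return LipidName(cls, tuple(chains), raw_label=label)
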