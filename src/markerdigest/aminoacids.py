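"""Canonical amino-acid naming, measurement bases, and physiological groupings.

Digesta and feed tables in digestibility work label the same analyte
inconsistently: acid hydrolysis converts asparagine and glutamine to their
acid forms, so a feed table's "Asparagine" and a digesta table's "Asp" are
one analyte, conventionally written ASX (and GLX for the glutamate pool).
This module pins down a closed set of canonical analyte keys, a total
synonym map over the spellings encountered in practice, and the standard
essential / branched-chain / long-neutral / non-essential groupings used to
aggregate amino-acid masses before digestibility calculation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping


class AminoAcid(str, Enum):
    """Closed set of canonical analyte keys (post-hydrolysis pools)."""

    ILE = "ILE"
    LEU = "LEU"
    VAL = "VAL"
    HIS = "HIS"
    LYS = "LYS"
    MET = "MET"
    PHE = "PHE"
    THR = "THR"
    TRP = "TRP"
    ALA = "ALA"
    ARG = "ARG"
    ASX = "ASX"
    GLX = "GLX"
    CYS = "CYS"
    SER = "SER"
    TYR = "TYR"
    PRO = "PRO"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class UnknownAminoAcidError(ValueError):
    """Raised when a raw label cannot be mapped to a canonical key."""


def _build_synonyms() -> dict[str, AminoAcid]:
    syn: dict[str, AminoAcid] = {}
    for aa in AminoAcid:
        syn[aa.value.lower()] = aa
    full = {
        "isoleucine": AminoAcid.ILE,
        "leucine": AminoAcid.LEU,
        "valine": AminoAcid.VAL,
        "histidine": AminoAcid.HIS,
        "lysine": AminoAcid.LYS,
        "methionine": AminoAcid.MET,
        "phenylalanine": AminoAcid.PHE,
        "threonine": AminoAcid.THR,
        "tryptophan": AminoAcid.TRP,
        "alanine": AminoAcid.ALA,
        "arginine": AminoAcid.ARG,
        "cysteine": AminoAcid.CYS,
        "cystine": AminoAcid.CYS,
        "serine": AminoAcid.SER,
        "tyrosine": AminoAcid.TYR,
        "proline": AminoAcid.PRO,
        # amide + acid forms pool into ASX / GLX after acid hydrolysis
        "asparagine": AminoAcid.ASX,
        "aspartate": AminoAcid.ASX,
        "aspartic acid": AminoAcid.ASX,
        "asp": AminoAcid.ASX,
        "asn": AminoAcid.ASX,
        "glutamine": AminoAcid.GLX,
        "glutamate": AminoAcid.GLX,
        "glutamic acid": AminoAcid.GLX,
        "glu": AminoAcid.GLX,
        "gln": AminoAcid.GLX,
    }
    syn.update(full)
    return syn


SYNONYMS: dict[str, AminoAcid] = _build_synonyms()


def canonicalize_aa_name(raw_name: str) -> AminoAcid:
    """Map a raw amino-acid label (any case, full name or code) to its key.

    Raises
    ------
    UnknownAminoAcidError
        If the label is empty or not in the synonym map; the message lists
        the accepted spellings.
    """
    if not isinstance(raw_name, str) or not raw_name.strip():
        raise UnknownAminoAcidError("empty amino-acid name")
    key = raw_name.strip().lower()
    try:
        return SYNONYMS[key]
    except KeyError:
        accepted = ", ".join(sorted(SYNONYMS))
        raise UnknownAminoAcidError(
            f"unknown amino-acid name {raw_name!r}; accepted: {accepted}"
        ) from None


class Basis(str, Enum):
    """Measurement basis of an amino-acid quantity."""

    MG_PER_G_PROTEIN = "mg_per_g_protein"
    PCT_DM = "pct_DM"
    MG_TOTAL = "mg_total"


class BasisMismatchError(ValueError):
    """Cross-basis arithmetic on profiles is rejected."""


@dataclass(frozen=True)
class AAProfile:
    """Mapping of analyte keys to non-negative quantities on one basis.

    Keys are canonical :class:`AminoAcid` values (as strings) unless
    ``strict_keys=False``, in which case arbitrary names (e.g. group names)
    are allowed. All quantities must be finite and >= 0.
    """

    values: Mapping[str, float]
    basis: Basis
    strict_keys: bool = True

    def __post_init__(self) -> None:
        canon: dict[str, float] = {}
        for name, v in self.values.items():
            key = canonicalize_aa_name(name).value if self.strict_keys else str(name)
            v = float(v)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"quantity for {key} must be finite and >= 0, got {v}")
            canon[key] = v
        object.__setattr__(self, "values", canon)
        object.__setattr__(self, "basis", Basis(self.basis))

    def __getitem__(self, key: "str | AminoAcid") -> float:
        return self.values[str(key)]

    def get(self, key: "str | AminoAcid", default: float | None = None):
        return self.values.get(str(key), default)

    def __contains__(self, key: "str | AminoAcid") -> bool:
        return str(key) in self.values

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def items(self):
        return self.values.items()

    def keys(self):
        return self.values.keys()

    def scale(self, factor: float, basis: "Basis | None" = None) -> "AAProfile":
        """Return the profile scaled by ``factor`` (optionally re-based)."""
        return AAProfile(
            {k: v * factor for k, v in self.values.items()},
            basis or self.basis,
            strict_keys=self.strict_keys,
        )

    def add(self, other: "AAProfile") -> "AAProfile":
        if self.basis is not other.basis:
            raise BasisMismatchError(
                f"cannot add profiles on bases {self.basis.value} and {other.basis.value}"
            )
        keys = set(self.values) | set(other.values)
        return AAProfile(
            {k: self.values.get(k, 0.0) + other.values.get(k, 0.0) for k in keys},
            self.basis,
            strict_keys=self.strict_keys and other.strict_keys,
        )


@dataclass(frozen=True)
class AAGroupDef:
    """Named group of amino acids summed before digestibility calculation."""

    name: str
    members: frozenset[AminoAcid] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        members = frozenset(
            m if isinstance(m, AminoAcid) else canonicalize_aa_name(m)
            for m in self.members
        )
        object.__setattr__(self, "members", members)


BCAA = AAGroupDef("BCAA", frozenset({AminoAcid.ILE, AminoAcid.LEU, AminoAcid.VAL}))
EAA = AAGroupDef(
    "EAA",
    BCAA.members
    | {
        AminoAcid.HIS,
        AminoAcid.LYS,
        AminoAcid.MET,
        AminoAcid.PHE,
        AminoAcid.THR,
        AminoAcid.TRP,
    },
)
LNAA = AAGroupDef(
    "LNAA",
    frozenset(
        {
            AminoAcid.ILE,
            AminoAcid.LEU,
            AminoAcid.VAL,
            AminoAcid.PHE,
            AminoAcid.TRP,
            AminoAcid.TYR,
        }
    ),
)
_NEAA_BASE = frozenset(
    {
        AminoAcid.ALA,
        AminoAcid.ARG,
        AminoAcid.ASX,
        AminoAcid.CYS,
        AminoAcid.GLX,
        AminoAcid.SER,
        AminoAcid.TYR,
    }
)


def default_groups(include_proline_in_neaa: bool = False) -> dict[str, AAGroupDef]:
    """Standard group definitions (BCAA, EAA, NEAA, LNAA).

    Proline is excluded from NEAA by default but can be opted in; NEAA
    membership conventions vary between laboratories.
    """
    neaa = _NEAA_BASE | ({AminoAcid.PRO} if include_proline_in_neaa else frozenset())
    return {
        "BCAA": BCAA,
        "EAA": EAA,
        "NEAA": AAGroupDef("NEAA", neaa),
        "LNAA": LNAA,
    }


class MissingGroupMemberError(KeyError):
    """A strict group aggregation found a member absent from the profile."""


def aggregate_groups(
    profile: AAProfile,
    groups: "Iterable[AAGroupDef] | Mapping[str, AAGroupDef]",
    policy: str = "strict",
) -> AAProfile:
    """Sum profile values over each group; returns a profile keyed by group name.

    With ``policy="strict"`` every member must be present; with
    ``policy="skip-missing"`` absent members contribute zero.
    """
    if isinstance(groups, Mapping):
        groups = list(groups.values())
    if policy not in ("strict", "skip-missing"):
        raise ValueError(f"unknown aggregation policy {policy!r}")
    out: dict[str, float] = {}
    for g in groups:
        total = 0.0
        for m in sorted(g.members, key=lambda a: a.value):
            if m.value in profile:
                total += profile[m]
            elif policy == "strict":
                raise MissingGroupMemberError(
                    f"amino acid {m.value} required by group {g.name} is missing"
                )
        out[g.name] = total
    return AAProfile(out, profile.basis, strict_keys=False)
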