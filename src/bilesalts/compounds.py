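"""Bile-salt structures: nomenclature parsing, classification, and mass arithmetic.

Bile salts are the amphipathic end-metabolites of cholesterol.  Two skeleton
features carry most of the comparative signal: the total carbon count of the
steroid skeleton plus side chain (C27 for the unshortened cholesterol skeleton,
C24 after peroxisomal side-chain shortening, C23 in a few snakes) and the
oxidation state of the side-chain terminus (a primary alcohol, usually
secreted as a sulfate ester, versus a carboxylic acid, usually secreted as a
glycine or taurine amide).  On top of the skeleton sit ring-junction
stereochemistry (5a "allo"/trans vs 5b/cis), a variable set of hydroxyl and
oxo substituents, and occasional side-chain double bonds.

This module represents one compound as a :class:`BileSaltDescriptor`, parses
systematic steroid nomenclature (e.g. ``3a,7a,12a-trihydroxy-5b-cholan-24-oic
acid``) and common trivial names into descriptors, classifies descriptors into
the three broad comparative types (C27 bile alcohols, C27 bile acids, C24 bile
acids), flags the rare structural modifications used in chemotaxonomic tables,
and computes molecular formulas and monoisotopic [M-H]- m/z values for
annotating negative-mode electrospray peak lists.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

from .errors import (
    ConfigurationError,
    ParseError,
    UnsupportedScaffoldError,
    ValidationError,
)

__all__ = [
    "TerminalGroup",
    "Junction",
    "Conjugation",
    "CompoundType",
    "ModificationFlag",
    "BileSaltDescriptor",
    "parse_name",
    "render_name",
    "classify_type",
    "flag_unusual",
    "molecular_formula",
    "formula_string",
    "monoisotopic_mass",
    "mz_mh_minus",
    "CandidateClass",
    "enumerate_search_space",
    "annotate_peaks",
    "REGISTRY",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
]


class TerminalGroup(str, Enum):
    ALCOHOL = "alcohol"
    ACID = "carboxylic_acid"


class Junction(str, Enum):
    FIVE_ALPHA = "5a"
    FIVE_BETA = "5b"
    UNKNOWN = "unknown"


class Conjugation(str, Enum):
    NONE = "none"
    GLYCINE = "glycine"
    TAURINE = "taurine"
    SULFATE = "sulfate"


class CompoundType(str, Enum):
    """The three broad comparative types, plus a catch-all.

    Assignment is a pure function of skeleton size and terminal group;
    C23 acids and other rarities map to OTHER but remain reportable.
    """

    C27_ALCOHOL = "C27_alcohol"
    C27_ACID = "C27_acid"
    C24_ACID = "C24_acid"
    OTHER = "other"


class ModificationFlag(str, Enum):
    """Rare structural modifications tracked for chemotaxonomic reporting."""

    ALLO_5A = "allo_5a"          # 5a (trans, "allo") ring junction
    OH_1A = "oh_1a"              # 1a-hydroxylation
    OH_1B = "oh_1b"              # 1b-hydroxylation
    OH_6A = "oh_6a"              # 6a-hydroxylation (hyocholic pattern)
    OH_6B = "oh_6b"              # 6b-hydroxylation (muricholic pattern)
    OXO_7 = "oxo_7"              # 7-oxo group
    OH_15A = "oh_15a"            # 15a-hydroxylation
    OH_16A = "oh_16a"            # 16a-hydroxylation (pythocholic pattern)
    UDCA_7B = "udca_7b"          # 7b-hydroxyl (ursodeoxycholic pattern)
    DELTA22 = "delta22"          # side-chain double bond at C22
    OH_22_C27 = "oh_22_C27"      # 22-hydroxylated C27 bile salt (turtles)
    OH_23R = "oh_23R"            # 23R-hydroxylation (pinnipeds, some snakes)
    DEOXY_7 = "deoxy_7"          # no oxygen at C7 at all (pythocholic, bitocholic)
    OH_25 = "oh_25"              # 25-hydroxylation (paenungulate bile alcohols)


# orientation codes: 'a'/'b' for nuclear alpha/beta, 'R'/'S' for side-chain
# stereocentres, '' when the source does not specify
_ORIENTATIONS = frozenset({"a", "b", "R", "S", ""})

_ACID_SCAFFOLDS = frozenset({22, 23, 24, 27})
_ALCOHOL_SCAFFOLDS = frozenset({24, 27})


@dataclass(frozen=True)
class BileSaltDescriptor:
    """Structured representation of a single bile salt.

    ``hydroxyls`` holds (position, orientation) pairs; ``oxo_positions`` and
    ``double_bonds`` hold bare carbon positions.  For bile alcohols the
    terminal side-chain hydroxyl is implicit in ``terminal_group`` and is not
    repeated in ``hydroxyls``.  ``trivial_name`` is carried for reporting but
    does not participate in equality.
    """

    carbon_count: int
    terminal_group: TerminalGroup
    junction: Junction = Junction.UNKNOWN
    hydroxyls: frozenset = frozenset()
    oxo_positions: frozenset = frozenset()
    double_bonds: frozenset = frozenset()
    conjugation: Conjugation = Conjugation.NONE
    trivial_name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "terminal_group", TerminalGroup(self.terminal_group))
        object.__setattr__(self, "junction", Junction(self.junction))
        object.__setattr__(self, "conjugation", Conjugation(self.conjugation))
        object.__setattr__(self, "hydroxyls", frozenset(self.hydroxyls))
        object.__setattr__(self, "oxo_positions", frozenset(self.oxo_positions))
        object.__setattr__(self, "double_bonds", frozenset(self.double_bonds))
        if self.carbon_count < 19:
            raise ValidationError(f"carbon_count {self.carbon_count} below steroid minimum")
        for pos, orient in self.hydroxyls:
            if not 1 <= pos <= self.carbon_count:
                raise ValidationError(f"hydroxyl position {pos} outside 1..{self.carbon_count}")
            if orient not in _ORIENTATIONS:
                raise ValidationError(f"unknown orientation {orient!r} at position {pos}")
        for pos in self.oxo_positions:
            if not 1 <= pos <= self.carbon_count:
                raise ValidationError(f"oxo position {pos} outside 1..{self.carbon_count}")
        for pos in self.double_bonds:
            if not 1 <= pos <= self.carbon_count:
                raise ValidationError(f"double-bond position {pos} outside 1..{self.carbon_count}")
        oh_positions = {pos for pos, _ in self.hydroxyls}
        clash = oh_positions & set(self.oxo_positions)
        if clash:
            raise ValidationError(
                f"position(s) {sorted(clash)} carry both a hydroxyl and an oxo group"
            )

    # -- convenience accessors -------------------------------------------------

    def hydroxyl_positions(self) -> frozenset:
        return frozenset(pos for pos, _ in self.hydroxyls)

    def has_hydroxyl(self, position: int, orientation: str | None = None) -> bool:
        if orientation is None:
            return position in self.hydroxyl_positions()
        return (position, orientation) in self.hydroxyls

    def deconjugated(self) -> "BileSaltDescriptor":
        """The aglycone: the same structure with conjugation stripped."""
        if self.conjugation is Conjugation.NONE:
            return self
        return BileSaltDescriptor(
            self.carbon_count,
            self.terminal_group,
            self.junction,
            self.hydroxyls,
            self.oxo_positions,
            self.double_bonds,
            Conjugation.NONE,
            self.trivial_name,
        )

    def __str__(self) -> str:
        return render_name(self)


# ---------------------------------------------------------------------------
# Trivial-name registry
# ---------------------------------------------------------------------------

def _acid(hydroxyls, junction=Junction.FIVE_BETA, carbons=24, oxo=(), name=None):
    return BileSaltDescriptor(
        carbon_count=carbons,
        terminal_group=TerminalGroup.ACID,
        junction=junction,
        hydroxyls=frozenset(hydroxyls),
        oxo_positions=frozenset(oxo),
        trivial_name=name,
    )


#: Trivial names and common abbreviations -> descriptor.  Keys are stored in
#: normalized (lower-case, ASCII a/b) form.
REGISTRY: dict[str, BileSaltDescriptor] = {}


def _register(descriptor: BileSaltDescriptor, *names: str) -> None:
    for n in names:
        REGISTRY[n.lower()] = descriptor


_register(_acid({(3, "a"), (7, "a"), (12, "a")}, name="cholic acid"),
          "cholic acid", "ca")
_register(_acid({(3, "a"), (7, "a"), (12, "a")}, junction=Junction.FIVE_ALPHA,
                name="allocholic acid"),
          "allocholic acid", "allo-cholic acid", "alloca", "allo-ca", "5a-cholic acid")
_register(_acid({(3, "a"), (7, "a")}, name="chenodeoxycholic acid"),
          "chenodeoxycholic acid", "cdca")
_register(_acid({(3, "a"), (12, "a")}, name="deoxycholic acid"),
          "deoxycholic acid", "dca")
_register(_acid({(3, "a")}, name="lithocholic acid"),
          "lithocholic acid", "lca")
_register(_acid({(3, "a"), (7, "b")}, name="ursodeoxycholic acid"),
          "ursodeoxycholic acid", "udca")
_register(_acid({(3, "a"), (6, "a"), (7, "a")}, name="hyocholic acid"),
          "hyocholic acid")
_register(_acid({(3, "a"), (6, "a")}, name="hyodeoxycholic acid"),
          "hyodeoxycholic acid", "hdca")
_register(_acid({(3, "a"), (6, "b"), (7, "a")}, name="a-muricholic acid"),
          "a-muricholic acid")
_register(_acid({(3, "a"), (6, "b"), (7, "b")}, name="b-muricholic acid"),
          "b-muricholic acid")
_register(_acid({(3, "a"), (12, "a"), (16, "a")}, name="pythocholic acid"),
          "pythocholic acid")
_register(_acid({(3, "a"), (12, "a"), (23, "R")}, name="bitocholic acid"),
          "bitocholic acid")
_register(_acid({(3, "a"), (7, "a"), (12, "a"), (24, "R")}, carbons=27,
                name="varanic acid"),
          "varanic acid")
_register(_acid({(3, "a"), (7, "a"), (12, "a")}, carbons=27,
                name="3a,7a,12a-trihydroxy-5b-cholestan-27-oic acid"),
          "thca")  # trihydroxycholestanoic acid, the crocodylian C27 acid
_register(_acid({(3, "a")}, oxo={12}, name="12-oxo-lithocholic acid"),
          "12-oxo-lithocholic acid", "12-oxo-lca", "12-oxolithocholic acid")
_register(_acid({(3, "a"), (12, "a")}, oxo={7}, name="7-oxo-deoxycholic acid"),
          "7-oxo-deoxycholic acid", "7-oxo-dca", "7-oxodeoxycholic acid")


# ---------------------------------------------------------------------------
# Name normalization and parsing
# ---------------------------------------------------------------------------

_GREEK = {"α": "a", "β": "b", "Δ": "delta", "δ": "delta",
          "–": "-", "—": "-", "−": "-"}


def _normalize(name: str) -> str:
    s = name.strip()
    for k, v in _GREEK.items():
        s = s.replace(k, v)
    s = s.lower()
    s = s.replace("alpha", "a").replace("beta", "b")
    s = re.sub(r"\s+", " ", s)
    return s


_CORE_RE = re.compile(
    r"(?:(?P<junc>5[ab])-)?chol(?P<est>est)?"
    r"(?:(?P<an>ane?)|a?-(?P<ene>\d+(?:,\d+)*)-(?:tri|di)?ene?)"
)

_NOR_RE = re.compile(r"(?:(?P<norpos>\d+(?:,\d+)*)-)?(?P<bis>bis)?nor-?$")

_SUB_GROUP_RE = re.compile(
    r"(?P<pos>\d+[abrs]?(?:,\d+[abrs]?)*)-"
    r"(?P<mult>mono|di|tri|tetra|penta|hexa|hepta)?"
    r"(?P<kind>hydroxy|oxo)-?"
)

_ACID_TAIL_RE = re.compile(r"-(?P<pos>\d+)-oic acid$")

_OL_TAIL_RE = re.compile(
    r"-(?P<pos>\d+[abrs]?(?:,\d+[abrs]?)*)-"
    r"(?P<mult>di|tri|tetr|pent|hex|hept)?ol$"
)

_MULTIPLIERS = {None: 1, "mono": 1, "di": 2, "tri": 3, "tetra": 4,
                "penta": 5, "hexa": 6, "hepta": 7,
                "tetr": 4, "pent": 5, "hex": 6, "hept": 7}


def _parse_positions(token: str, original: str) -> list[tuple[int, str]]:
    out = []
    for piece in token.split(","):
        m = re.fullmatch(r"(\d+)([abrs]?)", piece)
        if not m:
            raise ParseError(original, piece, "bad position token")
        orient = m.group(2)
        if orient in ("r", "s"):
            orient = orient.upper()
        out.append((int(m.group(1)), orient))
    return out


def parse_name(name: str) -> BileSaltDescriptor:
    """Parse a systematic or trivial bile-salt name into a descriptor.

    Accepts Greek letters as ``α/β``, ASCII ``a/b``, or spelled-out
    ``alpha/beta``; conjugation prefixes ``glyco-``/``tauro-`` (with or
    without hyphen) and a trailing ``sulfate``; trivial names and common
    abbreviations from the built-in registry (CA, CDCA, DCA, LCA, UDCA,
    varanic, pythocholic, bitocholic, hyocholic, muricholic, allocholic...).

    Raises :class:`ParseError` naming the offending fragment on failure and
    :class:`ValidationError` when substituents conflict (hydroxyl and oxo at
    the same position).
    """
    if not name or not name.strip():
        raise ParseError(name, reason="empty name")
    s = _normalize(name)

    conjugation = Conjugation.NONE
    m = re.search(r"[\s-]*(?:\d+-)?sulfate$", s)
    if m:
        conjugation = Conjugation.SULFATE
        s = s[: m.start()]
    for prefix, conj in (("glyco", Conjugation.GLYCINE), ("tauro", Conjugation.TAURINE)):
        if s.startswith(prefix):
            rest = s[len(prefix):].lstrip("-")
            if conjugation is not Conjugation.NONE:
                raise ParseError(name, prefix, "multiple conjugations")
            conjugation = conj
            s = rest
            break

    hit = REGISTRY.get(s)
    if hit is not None:
        if conjugation is Conjugation.NONE:
            return hit
        return BileSaltDescriptor(
            hit.carbon_count, hit.terminal_group, hit.junction, hit.hydroxyls,
            hit.oxo_positions, hit.double_bonds, conjugation, hit.trivial_name,
        )

    core = _CORE_RE.search(s)
    if core is None:
        raise ParseError(name, s, "no cholane/cholestane skeleton found")

    prefix = s[: core.start()]
    tail = s[core.end():]

    carbon_count = 27 if core.group("est") else 24
    nor = _NOR_RE.search(prefix)
    if nor:
        if nor.group("norpos"):
            carbon_count -= len(nor.group("norpos").split(","))
        else:
            carbon_count -= 2 if nor.group("bis") else 1
        prefix = prefix[: nor.start()]

    junction = Junction(core.group("junc")) if core.group("junc") else Junction.UNKNOWN
    double_bonds = frozenset(
        int(p) for p in core.group("ene").split(",")
    ) if core.group("ene") else frozenset()

    hydroxyls: set[tuple[int, str]] = set()
    oxo: set[int] = set()
    pos = 0
    while pos < len(prefix):
        m = _SUB_GROUP_RE.match(prefix, pos)
        if m is None:
            raise ParseError(name, prefix[pos:], "unrecognized substituent")
        positions = _parse_positions(m.group("pos"), name)
        expected = _MULTIPLIERS[m.group("mult")]
        if len(positions) != expected:
            raise ParseError(
                name, m.group(0),
                f"multiplier {m.group('mult') or 'mono'} does not match "
                f"{len(positions)} position(s)",
            )
        if m.group("kind") == "hydroxy":
            hydroxyls.update(positions)
        else:
            for p, orient in positions:
                if orient:
                    raise ParseError(name, m.group(0), "oxo groups carry no orientation")
                oxo.add(p)
        pos = m.end()

    acid_tail = _ACID_TAIL_RE.fullmatch(tail)
    ol_tail = _OL_TAIL_RE.fullmatch(tail)
    if acid_tail:
        if core.group("an") == "ane":
            raise ParseError(name, "ane" + tail, "acid suffix follows -ane form")
        terminal = TerminalGroup.ACID
        stated = int(acid_tail.group("pos"))
        if stated != carbon_count:
            raise ParseError(
                name, acid_tail.group(0),
                f"-{stated}-oic acid inconsistent with a C{carbon_count} skeleton",
            )
    elif ol_tail:
        terminal = TerminalGroup.ALCOHOL
        positions = _parse_positions(ol_tail.group("pos"), name)
        if len(positions) != _MULTIPLIERS[ol_tail.group("mult")]:
            raise ParseError(name, ol_tail.group(0), "ol multiplier mismatch")
        hydroxyls.update(positions)
        # the highest unoriented side-chain hydroxyl is the terminal group
        side = sorted(
            (p for p, o in hydroxyls if o == "" and p >= 24), reverse=True
        )
        if side:
            hydroxyls.discard((side[0], ""))
    else:
        raise ParseError(name, tail or s, "missing or unrecognized terminal group")

    try:
        return BileSaltDescriptor(
            carbon_count=carbon_count,
            terminal_group=terminal,
            junction=junction,
            hydroxyls=frozenset(hydroxyls),
            oxo_positions=frozenset(oxo),
            double_bonds=double_bonds,
            conjugation=conjugation,
        )
    except ValidationError:
        raise


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_REV_MULT = {1: "", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa", 7: "hepta"}
_OL_MULT = {1: "", 2: "di", 3: "tri", 4: "tetr", 5: "pent", 6: "hex", 7: "hept"}


def _fmt_positions(positions: Iterable[tuple[int, str]]) -> str:
    return ",".join(f"{p}{o}" for p, o in sorted(positions))


def render_name(d: BileSaltDescriptor) -> str:
    """Render a descriptor as a canonical ASCII systematic name.

    The canonical form uses ``a/b`` for nuclear orientations and ``R/S`` for
    side-chain stereocentres; ``render_name(parse_name(x))`` parses back to
    the same descriptor.
    """
    parts: list[str] = []
    oh = sorted(d.hydroxyls)
    oxo = sorted(d.oxo_positions)

    if d.carbon_count == 27:
        base, nor = "cholest", ""
    elif d.carbon_count in (22, 23, 24):
        base = "chol"
        nor = {24: "", 23: "24-nor-", 22: "23,24-bisnor-"}[d.carbon_count]
    else:
        raise UnsupportedScaffoldError(
            f"cannot render a C{d.carbon_count} skeleton systematically"
        )

    if d.terminal_group is TerminalGroup.ACID:
        if oh:
            parts.append(f"{_fmt_positions(oh)}-{_REV_MULT[len(oh)]}hydroxy")
        if oxo:
            parts.append(f"{','.join(map(str, oxo))}-{_REV_MULT[len(oxo)]}oxo")
        suffix = f"-{d.carbon_count}-oic acid"
        ol_list = None
    else:
        if oxo:
            parts.append(f"{','.join(map(str, oxo))}-{_REV_MULT[len(oxo)]}oxo")
        term = 24 if d.carbon_count <= 24 else 26
        if (term, "") in d.hydroxyls:
            term = d.carbon_count
        if (term, "") in d.hydroxyls:
            raise UnsupportedScaffoldError(
                "cannot place the terminal hydroxyl: side-chain termini occupied"
            )
        ol_list = sorted(d.hydroxyls | {(term, "")})
        suffix = f"-{_fmt_positions(ol_list)}-{_OL_MULT[len(ol_list)]}ol"

    junction = "" if d.junction is Junction.UNKNOWN else d.junction.value + "-"

    if d.double_bonds:
        ene = ",".join(map(str, sorted(d.double_bonds)))
        n = len(d.double_bonds)
        link = "a" if n > 1 else ""
        core = f"{base}{link}-{ene}-{_REV_MULT[n] if n > 1 else ''}ene"
        core = core[:-1]  # "-ene" -> "-en" before a suffix
    else:
        core = base + ("ane" if ol_list is not None else "an")

    skeleton = nor + junction + core
    body = skeleton if not parts else "-".join(parts) + "-" + skeleton
    name = body + suffix

    if d.conjugation is Conjugation.GLYCINE:
        name = "glyco-" + name
    elif d.conjugation is Conjugation.TAURINE:
        name = "tauro-" + name
    elif d.conjugation is Conjugation.SULFATE:
        name = name + " sulfate"
    return name


# ---------------------------------------------------------------------------
# Classification and modification flags
# ---------------------------------------------------------------------------

def classify_type(d: BileSaltDescriptor) -> CompoundType:
    """Assign one of the three broad comparative types.

    Side-chain length and terminal oxidation state define the type:
    C27 alcohols, C27 acids, C24 acids; everything else (C23 acids,
    short-chain alcohols) is OTHER.  Conjugation is ignored: the type is a
    property of the aglycone.
    """
    if d.carbon_count == 27:
        return (CompoundType.C27_ALCOHOL if d.terminal_group is TerminalGroup.ALCOHOL
                else CompoundType.C27_ACID)
    if d.carbon_count == 24 and d.terminal_group is TerminalGroup.ACID:
        return CompoundType.C24_ACID
    return CompoundType.OTHER


def flag_unusual(d: BileSaltDescriptor) -> frozenset:
    """Return every chemotaxonomic modification flag whose predicate holds."""
    flags: set[ModificationFlag] = set()
    if d.junction is Junction.FIVE_ALPHA:
        flags.add(ModificationFlag.ALLO_5A)
    if d.has_hydroxyl(1, "a"):
        flags.add(ModificationFlag.OH_1A)
    if d.has_hydroxyl(1, "b"):
        flags.add(ModificationFlag.OH_1B)
    if d.has_hydroxyl(6, "a"):
        flags.add(ModificationFlag.OH_6A)
    if d.has_hydroxyl(6, "b"):
        flags.add(ModificationFlag.OH_6B)
    if 7 in d.oxo_positions:
        flags.add(ModificationFlag.OXO_7)
    if d.has_hydroxyl(15, "a"):
        flags.add(ModificationFlag.OH_15A)
    if d.has_hydroxyl(16, "a"):
        flags.add(ModificationFlag.OH_16A)
    if d.has_hydroxyl(7, "b"):
        flags.add(ModificationFlag.UDCA_7B)
    if 22 in d.double_bonds:
        flags.add(ModificationFlag.DELTA22)
    if d.has_hydroxyl(22) and d.carbon_count == 27:
        flags.add(ModificationFlag.OH_22_C27)
    if (23, "R") in d.hydroxyls:
        flags.add(ModificationFlag.OH_23R)
    if not d.has_hydroxyl(7) and 7 not in d.oxo_positions:
        flags.add(ModificationFlag.DEOXY_7)
    if d.has_hydroxyl(25):
        flags.add(ModificationFlag.OH_25)
    return frozenset(flags)


# ---------------------------------------------------------------------------
# Molecular formulas and monoisotopic masses
# ---------------------------------------------------------------------------

#: Monoisotopic atomic masses (Da), fixed to six decimals for reproducibility.
MONOISOTOPIC_MASS = {
    "C": 12.000000,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
}

#: Mass of a proton (Da); subtracted for the [M-H]- ion.
PROTON_MASS = 1.007276

_CONJUGATION_ATOMS = {
    Conjugation.NONE: {},
    Conjugation.GLYCINE: {"C": 2, "H": 3, "N": 1, "O": 1},
    Conjugation.TAURINE: {"C": 2, "H": 5, "N": 1, "O": 2, "S": 1},
    Conjugation.SULFATE: {"S": 1, "O": 3},
}


def molecular_formula(d: BileSaltDescriptor) -> dict[str, int]:
    """Elemental composition {C, H, N, O, S} built by scaffold arithmetic.

    The unsubstituted saturated scaffolds are CnH(2n-8)O2 for bile acids and
    CnH(2n-6)O for bile alcohols (the terminal hydroxyl is part of the base).
    Each hydroxyl adds O; each oxo adds O and removes 2 H; each double bond
    removes 2 H; glycine amidation adds C2H3NO, taurine C2H5NO2S, and a
    sulfate ester SO3.  Only the final substituent set matters — whether an
    oxo arose from a hydroxyl is irrelevant to the composition.
    """
    n = d.carbon_count
    if d.terminal_group is TerminalGroup.ACID:
        if n not in _ACID_SCAFFOLDS:
            raise UnsupportedScaffoldError(f"C{n} bile acid scaffold not supported")
        atoms = {"C": n, "H": 2 * n - 8, "N": 0, "O": 2, "S": 0}
    else:
        if n not in _ALCOHOL_SCAFFOLDS:
            raise UnsupportedScaffoldError(f"C{n} bile alcohol scaffold not supported")
        atoms = {"C": n, "H": 2 * n - 6, "N": 0, "O": 1, "S": 0}
    atoms["O"] += len(d.hydroxyls)
    atoms["O"] += len(d.oxo_positions)
    atoms["H"] -= 2 * len(d.oxo_positions)
    atoms["H"] -= 2 * len(d.double_bonds)
    for element, count in _CONJUGATION_ATOMS[d.conjugation].items():
        atoms[element] += count
    return atoms


def formula_string(atoms: dict[str, int]) -> str:
    """Hill-style formula string, e.g. C24H40O5."""
    out = []
    for element in ("C", "H", "N", "O", "S"):
        count = atoms.get(element, 0)
        if count == 1:
            out.append(element)
        elif count > 1:
            out.append(f"{element}{count}")
    return "".join(out)


def monoisotopic_mass(atoms: dict[str, int]) -> float:
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in atoms.items())


def mz_mh_minus(d: BileSaltDescriptor) -> float:
    """Monoisotopic m/z of the deprotonated molecular ion [M-H]- (Th)."""
    return monoisotopic_mass(molecular_formula(d)) - PROTON_MASS


# ---------------------------------------------------------------------------
# Peak annotation
# ---------------------------------------------------------------------------

_SCAFFOLD_PARAMS = {
    # scaffold key -> (carbon_count, terminal_group)
    "C23_acid": (23, TerminalGroup.ACID),
    "C24_acid": (24, TerminalGroup.ACID),
    "C27_acid": (27, TerminalGroup.ACID),
    "C27_alcohol": (27, TerminalGroup.ALCOHOL),
}

_COUNT_WORDS = {0: "non", 1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta"}

# arbitrary but clash-free representative positions for equivalence classes
_REP_OH = (3, 7, 12, 16, 1)
_REP_OXO = (6, 11, 15)
_REP_ENE = (22, 4, 14)


@dataclass(frozen=True)
class CandidateClass:
    """A structural equivalence class for m/z annotation.

    m/z cannot localize substituents, so candidates are reported
    position-agnostically: e.g. "glycine-conjugated trihydroxy C24 bile acid".
    """

    scaffold: str
    n_hydroxyl: int
    n_oxo: int
    n_double_bond: int
    conjugation: Conjugation

    @property
    def label(self) -> str:
        carbon, terminal = _SCAFFOLD_PARAMS[self.scaffold]
        kind = "bile acid" if terminal is TerminalGroup.ACID else "bile alcohol"
        bits = []
        if self.conjugation is not Conjugation.NONE:
            bits.append(
                {"glycine": "glycine-conjugated", "taurine": "taurine-conjugated",
                 "sulfate": "sulfated"}[self.conjugation.value]
            )
        bits.append(f"{_COUNT_WORDS[self.n_hydroxyl]}hydroxy")
        if self.n_oxo:
            bits.append(f"{_COUNT_WORDS[self.n_oxo]}oxo")
        if self.n_double_bond:
            bits.append("unsaturated" if self.n_double_bond == 1
                        else f"{_COUNT_WORDS[self.n_double_bond]}unsaturated")
        bits.append(f"C{carbon}")
        bits.append(kind)
        return " ".join(bits)

    def representative(self) -> BileSaltDescriptor:
        carbon, terminal = _SCAFFOLD_PARAMS[self.scaffold]
        return BileSaltDescriptor(
            carbon_count=carbon,
            terminal_group=terminal,
            junction=Junction.FIVE_BETA,
            hydroxyls=frozenset((p, "") for p in _REP_OH[: self.n_hydroxyl]),
            oxo_positions=frozenset(_REP_OXO[: self.n_oxo]),
            double_bonds=frozenset(_REP_ENE[: self.n_double_bond]),
            conjugation=self.conjugation,
        )

    @property
    def theoretical_mz(self) -> float:
        return mz_mh_minus(self.representative())


def enumerate_search_space(
    scaffolds: Sequence[str] = ("C23_acid", "C24_acid", "C27_acid", "C27_alcohol"),
    max_hydroxyl: int = 4,
    max_oxo: int = 2,
    max_double_bond: int = 2,
    conjugations: Sequence[Conjugation] = (
        Conjugation.NONE, Conjugation.GLYCINE, Conjugation.TAURINE, Conjugation.SULFATE,
    ),
) -> list[CandidateClass]:
    """All candidate equivalence classes within the bounded search space."""
    if not scaffolds or not conjugations:
        raise ConfigurationError("empty annotation search space")
    for s in scaffolds:
        if s not in _SCAFFOLD_PARAMS:
            raise ConfigurationError(f"unknown scaffold {s!r}")
    out = []
    for scaffold, noh, noxo, nene, conj in itertools.product(
        scaffolds, range(max_hydroxyl + 1), range(max_oxo + 1),
        range(max_double_bond + 1), conjugations,
    ):
        out.append(CandidateClass(scaffold, noh, noxo, nene, Conjugation(conj)))
    return out


@dataclass(frozen=True)
class PeakAnnotation:
    peak_mz: float
    intensity: float
    candidate: CandidateClass
    theoretical_mz: float
    delta_mz: float


def annotate_peaks(
    peaks: Iterable[tuple[float, float]],
    tolerance: float = 0.5,
    search_space: Sequence[CandidateClass] | None = None,
    **space_kwargs,
) -> list[list[PeakAnnotation]]:
    """Annotate observed [M-H]- peaks with candidate bile-salt classes.

    For each (m/z, intensity) peak, every candidate class whose theoretical
    [M-H]- m/z lies within ``tolerance`` is reported, sorted by |delta m/z|
    (ties broken by label for determinism).  The default 0.5 Da tolerance
    suits unit-resolution quadrupole data; pass a smaller window for
    high-resolution spectra.
    """
    if tolerance <= 0:
        raise ConfigurationError(f"tolerance must be positive, got {tolerance}")
    if search_space is None:
        search_space = enumerate_search_space(**space_kwargs)
    if not search_space:
        raise ConfigurationError("empty annotation search space")
    theoretical = [(c, c.theoretical_mz) for c in search_space]
    results = []
    for mz, intensity in peaks:
        if mz <= 0:
            raise ValidationError(f"non-positive peak m/z {mz}")
        hits = [
            PeakAnnotation(mz, intensity, c, t, mz - t)
            for c, t in theoretical
            if abs(mz - t) <= tolerance
        ]
        hits.sort(key=lambda h: (abs(h.delta_mz), h.candidate.label))
        results.append(hits)
    return results
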