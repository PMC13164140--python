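"""Reaction-mechanism data model for lipid autoxidation kinetics.

A :class:`Mechanism` bundles an ordered species list (with initial mole
fractions), a list of irreversible elementary reactions with modified-Arrhenius
kinetics, and the signed stoichiometry matrix derived from them.  The built-in
mechanism, :func:`tomato_pomace_mechanism`, is the six-step radical-chain model
of linoleic-acid autoxidation moderated by lycopene:

    initiation       LINOLEIC + O2  -> LINRAD + HO2
    oxygen addition  LINRAD + O2    -> ROO
    propagation      ROO + LINOLEIC -> ROOH + LINRAD
    ROOH cracking    ROOH           -> HEXANAL + FRAG12
    ROO scavenging   ROO + LYCOPENE -> ROOH + LYCORAD
    LINRAD rescue    LINRAD + LYCOPENE -> LINOLEIC + LYCORAD

Rate coefficients follow k = A * T**n * exp(-Ea / (R * T)) with Ea in
cal/mol and R = 1.98720425 cal/(mol K).  Pre-exponential factors are in
cm^3/(mol s) for bimolecular steps and 1/s for unimolecular steps, the
standard gas-kinetics (CHEMKIN) unit convention.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np

from .errors import MechanismError, MechanismParseError

#: Gas constant used in the Arrhenius exponent, cal/(mol K).
R_CAL = 1.98720425

_VALID_ROLES = frozenset(
    {"substrate", "oxidant", "radical", "intermediate", "product", "inert", "antioxidant"}
)


@dataclass(frozen=True)
class SpeciesDef:
    """A chemical species: name, mechanistic role, initial mole fraction."""

    name: str
    role: str = "intermediate"
    initial_mole_fraction: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "name", self.name.strip().upper())
        if not self.name:
            raise MechanismError("species name must be nonempty")
        if self.role not in _VALID_ROLES:
            raise MechanismError(f"unknown species role {self.role!r}")
        if self.initial_mole_fraction < 0:
            raise MechanismError(
                f"negative initial mole fraction for {self.name}: "
                f"{self.initial_mole_fraction}"
            )


@dataclass(frozen=True)
class ArrheniusParams:
    """Modified-Arrhenius parameters k = A * T**n * exp(-Ea/(R*T)).

    ``A`` is in cm^3/(mol s) for bimolecular reactions and 1/s for
    unimolecular ones; ``Ea`` is in cal/mol; ``n`` is dimensionless.
    """

    A: float
    n: float = 0.0
    Ea: float = 0.0

    def __post_init__(self):
        if not self.A > 0:
            raise MechanismError(f"pre-exponential factor must be positive, got {self.A}")
        if self.Ea < 0:
            raise MechanismError(f"activation energy must be nonnegative, got {self.Ea}")


@dataclass(frozen=True)
class Reaction:
    """An irreversible elementary reaction with mass-action kinetics.

    ``reactants`` and ``products`` map species names to positive integer
    stoichiometric coefficients.  Total reactant molecularity must be 1 or 2.
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    kinetics: ArrheniusParams
    label: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "reactants", {k.upper(): int(v) for k, v in self.reactants.items()}
        )
        object.__setattr__(
            self, "products", {k.upper(): int(v) for k, v in self.products.items()}
        )
        for side in (self.reactants, self.products):
            if any(v <= 0 for v in side.values()):
                raise MechanismError("stoichiometric coefficients must be positive integers")
        if self.molecularity not in (1, 2):
            raise MechanismError(
                f"reaction {self.equation!r} has molecularity {self.molecularity}; "
                "only unimolecular and bimolecular steps are supported"
            )

    @property
    def molecularity(self) -> int:
        return sum(self.reactants.values())

    @property
    def equation(self) -> str:
        def side(d: Mapping[str, int]) -> str:
            return " + ".join(f"{v if v > 1 else ''}{k}" for k, v in d.items())

        return f"{side(self.reactants)} => {side(self.products)}"


@dataclass
class Mechanism:
    """Ordered species + irreversible reactions + derived stoichiometry matrix."""

    species: list[SpeciesDef]
    reactions: list[Reaction]
    stoich_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise MechanismError("duplicate species names in mechanism")
        index = {n: i for i, n in enumerate(names)}
        S = np.zeros((len(names), len(self.reactions)), dtype=np.int64)
        for j, rx in enumerate(self.reactions):
            for name, nu in rx.reactants.items():
                if name not in index:
                    raise MechanismError(
                        f"reaction {rx.equation!r} uses undeclared species {name}"
                    )
                S[index[name], j] -= nu
            for name, nu in rx.products.items():
                if name not in index:
                    raise MechanismError(
                        f"reaction {rx.equation!r} uses undeclared species {name}"
                    )
                S[index[name], j] += nu
        self.stoich_matrix = S

    # -- lookups ---------------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name.upper())
        except ValueError:
            raise MechanismError(f"unknown species {name!r}") from None

    @property
    def initial_mole_fractions(self) -> np.ndarray:
        return np.array([s.initial_mole_fraction for s in self.species], dtype=float)

    def validate_initial_composition(self, tol: float = 1e-9) -> None:
        total = float(self.initial_mole_fractions.sum())
        if abs(total - 1.0) > tol:
            raise MechanismError(f"initial mole fractions sum to {total}, not 1")

    def rate_constants(self, T: float) -> np.ndarray:
        """Vector of k_j(T) in each reaction's own units."""
        return np.array([rate_constant(rx.kinetics, T) for rx in self.reactions])

    def content_hash(self) -> str:
        """Stable hash of the mechanism data, for run provenance."""
        h = hashlib.sha256()
        for s in self.species:
            h.update(f"{s.name}|{s.role}|{s.initial_mole_fraction!r};".encode())
        for rx in self.reactions:
            k = rx.kinetics
            h.update(f"{rx.equation}|{k.A!r}|{k.n!r}|{k.Ea!r};".encode())
        return h.hexdigest()[:16]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Mechanism):
            return NotImplemented
        return self.species == other.species and self.reactions == other.reactions

    def replace_kinetics(self, reaction_index: int, kinetics: ArrheniusParams) -> "Mechanism":
        """Return a copy with reaction ``reaction_index`` given new kinetics."""
        reactions = list(self.reactions)
        reactions[reaction_index] = replace(reactions[reaction_index], kinetics=kinetics)
        return Mechanism(species=list(self.species), reactions=reactions)


def rate_constant(kinetics: ArrheniusParams, T: float) -> float:
    """Evaluate k = A * T**n * exp(-Ea/(R*T)) at temperature ``T`` in kelvin."""
    if not T > 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return kinetics.A * T**kinetics.n * math.exp(-kinetics.Ea / (R_CAL * T))


def tomato_pomace_mechanism() -> Mechanism:
    """Six-reaction linoleic-acid autoxidation / lycopene scavenging mechanism.

    Eleven species; initial composition N2 0.779, O2 0.210, LINOLEIC 0.010,
    LYCOPENE 0.001 (sums to 1), radicals and products start at zero.
    """
    species = [
        SpeciesDef("LINOLEIC", "substrate", 0.010),
        SpeciesDef("LINRAD", "radical", 0.0),
        SpeciesDef("O2", "oxidant", 0.210),
        SpeciesDef("HO2", "radical", 0.0),
        SpeciesDef("ROO", "radical", 0.0),
        SpeciesDef("ROOH", "intermediate", 0.0),
        SpeciesDef("HEXANAL", "product", 0.0),
        SpeciesDef("FRAG12", "product", 0.0),
        SpeciesDef("N2", "inert", 0.779),
        SpeciesDef("LYCOPENE", "antioxidant", 0.001),
        SpeciesDef("LYCORAD", "radical", 0.0),
    ]
    reactions = [
        Reaction({"LINOLEIC": 1, "O2": 1}, {"LINRAD": 1, "HO2": 1},
                 ArrheniusParams(1.0e13, 0.0, 24_500.0), label="initiation"),
        Reaction({"LINRAD": 1, "O2": 1}, {"ROO": 1},
                 ArrheniusParams(1.0e12, 0.0, 0.0), label="oxygen addition"),
        Reaction({"ROO": 1, "LINOLEIC": 1}, {"ROOH": 1, "LINRAD": 1},
                 ArrheniusParams(1.0e14, 0.0, 14_000.0), label="propagation"),
        Reaction({"ROOH": 1}, {"HEXANAL": 1, "FRAG12": 1},
                 ArrheniusParams(1.0e14, 0.0, 35_000.0), label="hydroperoxide decomposition"),
        Reaction({"ROO": 1, "LYCOPENE": 1}, {"ROOH": 1, "LYCORAD": 1},
                 ArrheniusParams(1.0e11, 0.0, 10_000.0), label="ROO scavenging"),
        Reaction({"LINRAD": 1, "LYCOPENE": 1}, {"LINOLEIC": 1, "LYCORAD": 1},
                 ArrheniusParams(1.0e10, 0.0, 10_000.0), label="LINRAD scavenging"),
    ]
    return Mechanism(species=species, reactions=reactions)


# ---------------------------------------------------------------------------
# Conservation laws


def conservation_laws(mech: Mechanism) -> list[np.ndarray]:
    """Integer basis of the left null space of the stoichiometry matrix.

    Each returned vector ``w`` (length n_species) satisfies
    ``w @ stoich_matrix == 0``, i.e. ``w @ c(t)`` is constant along any
    trajectory.  The basis is computed exactly over the rationals with sympy
    and scaled to coprime integers.
    """
    import sympy

    S = sympy.Matrix(mech.stoich_matrix.tolist())
    basis = S.T.nullspace()
    out: list[np.ndarray] = []
    for v in basis:
        fracs = [Fraction(sympy.nsimplify(x)) for x in v]
        lcm = math.lcm(*(f.denominator for f in fracs)) if fracs else 1
        ints = [int(f * lcm) for f in fracs]
        g = math.gcd(*(abs(i) for i in ints if i != 0)) if any(ints) else 1
        w = np.array([i // g for i in ints], dtype=np.int64)
        # sign convention: first nonzero entry positive
        nz = np.flatnonzero(w)
        if nz.size and w[nz[0]] < 0:
            w = -w
        out.append(w)
    return out


# ---------------------------------------------------------------------------
# Native (YAML) mechanism format

def write_mechanism(mech: Mechanism, dialect: str = "native") -> str:
    """Serialize a mechanism to text in the ``native`` or ``chemkin-subset`` dialect."""
    if dialect == "native":
        return _write_native(mech)
    if dialect == "chemkin-subset":
        return _write_chemkin(mech)
    raise ValueError(f"unknown mechanism dialect {dialect!r}")


def parse_mechanism(text: str, dialect: str = "native") -> Mechanism:
    """Parse mechanism text; inverse of :func:`write_mechanism` for both dialects."""
    if dialect == "native":
        return _parse_native(text)
    if dialect == "chemkin-subset":
        return _parse_chemkin(text)
    raise ValueError(f"unknown mechanism dialect {dialect!r}")


def _write_native(mech: Mechanism) -> str:
    import yaml

    doc = {
        "units": {"A_bimolecular": "cm3/(mol*s)", "A_unimolecular": "1/s", "Ea": "cal/mol"},
        "species": [
            {"name": s.name, "role": s.role, "x0": s.initial_mole_fraction}
            for s in mech.species
        ],
        "reactions": [
            {
                "equation": rx.equation,
                "A": rx.kinetics.A,
                "n": rx.kinetics.n,
                "Ea": rx.kinetics.Ea,
                "label": rx.label,
            }
            for rx in mech.reactions
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def _parse_equation(eq: str, line: int | None = None) -> tuple[dict, dict]:
    if "<=>" in eq or ("=" in eq and "=>" not in eq):
        raise MechanismParseError(
            f"reversible reaction syntax not supported: {eq!r}", line
        )
    if "=>" not in eq:
        raise MechanismParseError(f"missing '=>' arrow in {eq!r}", line)
    lhs, rhs = eq.split("=>", 1)

    def side(s: str) -> dict:
        out: dict[str, int] = {}
        for term in s.split("+"):
            term = term.strip()
            if not term:
                raise MechanismParseError(f"empty species term in {eq!r}", line)
            m = re.fullmatch(r"(\d*)\s*([A-Za-z][A-Za-z0-9_]*)", term)
            if not m:
                raise MechanismParseError(f"malformed species term {term!r}", line)
            nu = int(m.group(1)) if m.group(1) else 1
            name = m.group(2).upper()
            out[name] = out.get(name, 0) + nu
        return out

    return side(lhs), side(rhs)


def _parse_native(text: str) -> Mechanism:
    import yaml

    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise MechanismParseError(f"invalid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "species" not in doc or "reactions" not in doc:
        raise MechanismParseError("native mechanism needs 'species:' and 'reactions:' blocks")
    species = [
        SpeciesDef(d["name"], d.get("role", "intermediate"), float(d.get("x0", 0.0)))
        for d in doc["species"]
    ]
    declared = {s.name for s in species}
    reactions = []
    for d in doc["reactions"]:
        reac, prod = _parse_equation(str(d["equation"]))
        for name in (*reac, *prod):
            if name not in declared:
                raise MechanismParseError(f"unknown species token {name!r}")
        reactions.append(
            Reaction(
                reac,
                prod,
                ArrheniusParams(float(d["A"]), float(d.get("n", 0.0)), float(d.get("Ea", 0.0))),
                label=str(d.get("label", "")),
            )
        )
    _check_duplicate_labels(reactions)
    return Mechanism(species=species, reactions=reactions)


def _check_duplicate_labels(reactions: Iterable[Reaction]) -> None:
    seen: set[str] = set()
    for rx in reactions:
        if rx.label and rx.label in seen:
            raise MechanismParseError(f"duplicate reaction label {rx.label!r}")
        seen.add(rx.label)


# ---------------------------------------------------------------------------
# CHEMKIN-II subset

def _write_chemkin(mech: Mechanism) -> str:
    # Roles, initial fractions and labels have no CHEMKIN syntax; they ride in
    # structured comments the parser understands (plain files still parse).
    lines = ["SPECIES"]
    for s in mech.species:
        lines.append(f"    {s.name}  ! role={s.role} x0={s.initial_mole_fraction!r}")
    lines += ["END", "REACTIONS CAL/MOLE"]
    for rx in mech.reactions:
        eq = rx.equation.replace(" ", "")
        k = rx.kinetics
        tail = f"  ! label={rx.label}" if rx.label else ""
        lines.append(f"{eq}  {k.A:.6E}  {k.n!r}  {k.Ea!r}{tail}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _parse_chemkin(text: str) -> Mechanism:
    """Parse the irreversible-only CHEMKIN subset.

    Accepts SPECIES and REACTIONS blocks terminated by END; an ELEMENTS
    block is skipped.  Reaction lines are ``equation  A  n  Ea`` with Ea in
    cal/mol and arrows restricted to ``=>``.  Species are given zero initial
    fractions (CHEMKIN input carries no composition); callers set them via
    reactor conditions or a native-format file.
    """
    species: list[SpeciesDef] = []
    reactions: list[Reaction] = []
    block = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line, _, comment = raw.partition("!")
        line = line.strip()
        comment = comment.strip()
        if not line:
            continue
        annot = dict(re.findall(r"(role|x0)=(\S+)", comment))
        m_label = re.search(r"label=(.*)$", comment)
        if m_label:
            annot["label"] = m_label.group(1).strip()
        upper = line.upper()
        if upper.startswith("ELEMENTS"):
            block = "elements"
            continue
        if upper.startswith("SPECIES"):
            block = "species"
            continue
        if upper.startswith("REACTIONS"):
            block = "reactions"
            continue
        if upper == "END":
            block = None
            continue
        if block == "elements":
            continue
        if block == "species":
            toks = line.split()
            for tok in toks:
                if not re.fullmatch(r"[A-Za-z][A-Za-z0-9_]*", tok):
                    raise MechanismParseError(f"invalid species token {tok!r}", lineno)
                role = annot.get("role", "intermediate") if len(toks) == 1 else "intermediate"
                x0 = float(annot.get("x0", 0.0)) if len(toks) == 1 else 0.0
                species.append(SpeciesDef(tok, role, x0))
            continue
        if block == "reactions":
            parts = line.split()
            if len(parts) < 4:
                raise MechanismParseError(
                    f"reaction line needs 'equation A n Ea', got {line!r}", lineno
                )
            eq = " ".join(parts[:-3])
            try:
                A, n, Ea = (float(p) for p in parts[-3:])
            except ValueError:
                raise MechanismParseError(
                    f"malformed rate triple {' '.join(parts[-3:])!r}", lineno
                ) from None
            reac, prod = _parse_equation(eq, lineno)
            declared = {s.name for s in species}
            for name in (*reac, *prod):
                if name not in declared:
                    raise MechanismParseError(f"unknown species token {name!r}", lineno)
            try:
                kin = ArrheniusParams(A, n, Ea)
            except MechanismError as exc:
                raise MechanismParseError(str(exc), lineno) from exc
            reactions.append(Reaction(reac, prod, kin, label=annot.get("label", "")))
            continue
        raise MechanismParseError(f"content outside any block: {line!r}", lineno)
    _check_duplicate_labels(reactions)
    return Mechanism(species=species, reactions=reactions)
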