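"""Species, mass-action reactions, and candidate ("ansatz") reaction libraries.

A candidate library is an ordered list of D mass-action reactions over N
species, together with the complete stoichiometric matrix (stored D x N,
reactions as rows; the ODE right-hand side is S.T @ (k * f(X))).  Reactions
are limited to order <= 2 on each side, and a reaction whose reactant and
product multisets coincide (zero net change) is rejected as unidentifiable.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SpeciesSet",
    "Reaction",
    "AnsatzLibrary",
    "LibraryError",
    "parse_reaction",
    "format_reaction",
    "enumerate_ansatz",
    "build_stoichiometric_matrix",
    "load_library",
    "save_library",
    "lotka_volterra_library",
    "lotka_volterra_true_library",
    "autoregulation_true_library",
    "autoregulation_reduced_library",
    "TEMPLATE_GROUPS",
    "library_preset",
]

MAX_ORDER = 2


class LibraryError(ValueError):
    """Raised for malformed reactions or libraries."""


@dataclass(frozen=True)
class SpeciesSet:
    """Ordered, unique species names; the order fixes all matrix columns."""

    names: tuple[str, ...]

    def __init__(self, names: Iterable[str]):
        names = tuple(str(n) for n in names)
        if len(names) == 0:
            raise LibraryError("species set must be nonempty")
        if len(set(names)) != len(names):
            raise LibraryError("species names must be unique")
        object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise LibraryError(f"unknown species {name!r}") from None


def _as_multiset(side: Mapping[str, int] | Iterable[str]) -> Counter:
    ms = Counter(dict(side)) if isinstance(side, Mapping) else Counter(side)
    for name, mult in ms.items():
        if mult < 0:
            raise LibraryError(f"negative multiplicity for {name}")
    return Counter({n: m for n, m in ms.items() if m > 0})


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction: reactant and product multisets (order <= 2 each)."""

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    label: str | None = None

    def __init__(self, reactants, products, label: str | None = None):
        r = _as_multiset(reactants)
        p = _as_multiset(products)
        if sum(r.values()) > MAX_ORDER or sum(p.values()) > MAX_ORDER:
            raise LibraryError(
                f"reaction order exceeds {MAX_ORDER}: "
                f"{dict(r)} -> {dict(p)}"
            )
        if r == p:
            raise LibraryError(f"reaction has no net change: {dict(r)} -> {dict(p)}")
        object.__setattr__(self, "reactants", tuple(sorted(r.items())))
        object.__setattr__(self, "products", tuple(sorted(p.items())))
        object.__setattr__(self, "label", label)

    @property
    def reactant_counts(self) -> Counter:
        return Counter(dict(self.reactants))

    @property
    def product_counts(self) -> Counter:
        return Counter(dict(self.products))

    def key(self) -> tuple:
        # identity ignores the label
        return (self.reactants, self.products)

    def species(self) -> set[str]:
        return {n for n, _ in self.reactants} | {n for n, _ in self.products}

    def __str__(self) -> str:
        return format_reaction(self)


def _format_side(side: tuple[tuple[str, int], ...]) -> str:
    if not side:
        return "0"
    terms = []
    for name, mult in side:
        terms.append(name if mult == 1 else f"{mult} {name}")
    return " + ".join(terms)


def format_reaction(reaction: Reaction) -> str:
    """Serialize a reaction as ``A + B -> 2 C`` (empty side written ``0``)."""
    return f"{_format_side(reaction.reactants)} -> {_format_side(reaction.products)}"


_TERM_RE = re.compile(r"^\s*(?:([12])\s*)?(\S+)\s*$")


def _parse_side(text: str, species: SpeciesSet) -> Counter:
    text = text.strip()
    if text == "0":
        return Counter()
    counts: Counter = Counter()
    for term in text.split("+"):
        term = term.strip()
        # a bare species name wins over a coefficient-prefixed reading,
        # so "P2" is the dimer species, not 2 x "P2"-suffix
        if term in species.names:
            counts[term] += 1
            continue
        m = _TERM_RE.match(term)
        if m is None:
            raise LibraryError(f"cannot parse term {term!r}")
        coeff = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        if name not in species.names:
            raise LibraryError(f"unknown species {name!r} in term {term!r}")
        counts[name] += coeff
    return counts


def parse_reaction(text: str, species: SpeciesSet) -> Reaction:
    """Parse ``side -> side`` where side is ``0`` or ``+``-joined terms.

    A term is a species name with an optional coefficient 1 or 2
    (``2 P`` or ``2P``).  Species names take precedence over coefficient
    prefixes, so a species literally named ``P2`` parses as itself.
    """
    parts = text.split("->")
    if len(parts) != 2:
        raise LibraryError(f"expected exactly one '->' in {text!r}")
    reactants = _parse_side(parts[0], species)
    products = _parse_side(parts[1], species)
    return Reaction(reactants, products)


@dataclass(frozen=True)
class AnsatzLibrary:
    """Ordered candidate reactions plus the complete stoichiometric matrix.

    ``stoich`` is D x N with row d = product counts - reactant counts of
    reaction d; ``reactant_matrix`` is D x N of reactant multiplicities,
    which determines the mass-action rate basis f(X).
    """

    species: SpeciesSet
    reactions: tuple[Reaction, ...]
    stoich: np.ndarray = field(compare=False, repr=False)
    reactant_matrix: np.ndarray = field(compare=False, repr=False)

    def __init__(self, species: SpeciesSet, reactions: Sequence[Reaction]):
        reactions = tuple(reactions)
        if len(reactions) == 0:
            raise LibraryError("library must contain at least one reaction")
        seen = {}
        for i, rxn in enumerate(reactions):
            for name in rxn.species():
                species.index(name)
            k = rxn.key()
            if k in seen:
                raise LibraryError(
                    f"duplicate reaction '{format_reaction(rxn)}' "
                    f"at indices {seen[k]} and {i}"
                )
            seen[k] = i
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "reactions", reactions)
        object.__setattr__(self, "stoich", build_stoichiometric_matrix_raw(species, reactions))
        object.__setattr__(self, "reactant_matrix", _reactant_matrix(species, reactions))

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def __len__(self) -> int:
        return len(self.reactions)

    def index_of(self, reaction: Reaction | str) -> int:
        if isinstance(reaction, str):
            reaction = parse_reaction(reaction, self.species)
        for i, rxn in enumerate(self.reactions):
            if rxn.key() == reaction.key():
                return i
        raise LibraryError(f"reaction '{format_reaction(reaction)}' not in library")

    def subset(self, indices: Sequence[int]) -> "AnsatzLibrary":
        return AnsatzLibrary(self.species, [self.reactions[i] for i in indices])


def _reactant_matrix(species: SpeciesSet, reactions: Sequence[Reaction]) -> np.ndarray:
    R = np.zeros((len(reactions), len(species)), dtype=np.int64)
    for d, rxn in enumerate(reactions):
        for name, mult in rxn.reactants:
            R[d, species.index(name)] = mult
    R.setflags(write=False)
    return R


def build_stoichiometric_matrix_raw(
    species: SpeciesSet, reactions: Sequence[Reaction]
) -> np.ndarray:
    S = np.zeros((len(reactions), len(species)), dtype=np.int64)
    for d, rxn in enumerate(reactions):
        for name, mult in rxn.products:
            S[d, species.index(name)] += mult
        for name, mult in rxn.reactants:
            S[d, species.index(name)] -= mult
    S.setflags(write=False)
    return S


def build_stoichiometric_matrix(library: AnsatzLibrary) -> np.ndarray:
    """Net-change matrix, D reactions x N species, entries in {-2..2}."""
    return library.stoich


# ---------------------------------------------------------------------------
# template-driven enumeration
# ---------------------------------------------------------------------------

# Templates are written over placeholder letters A, B, C, D which bind to
# *distinct* species.  A template with j distinct letters instantiates once
# per injective assignment of species to letters.
_TEMPLATE_LETTERS = ("A", "B", "C", "D")

TEMPLATE_GROUPS: dict[str, tuple[str, ...]] = {
    "birth": ("0 -> A",),
    "decay": ("A -> 0",),
    "autocatalysis": ("A -> 2A",),
    "conversion": ("A -> B",),
    "splitting": ("A -> 2B", "A -> B + C"),
    "catalytic_production": ("A -> A + B",),
    "dimerization": ("2A -> B", "2A -> A", "2A -> 0"),
    "bimolecular": ("A + B -> 2A", "A + B -> A", "A + B -> C", "A + B -> 0"),
    "full_second_order": (
        "A + B -> 2A",
        "A + B -> A",
        "A + B -> C",
        "A + B -> A + C",
        "A + B -> C + D",
        "A + B -> 0",
    ),
}


def _expand_templates(templates: Iterable[str]) -> list[str]:
    out: list[str] = []
    for t in templates:
        if t in TEMPLATE_GROUPS:
            out.extend(TEMPLATE_GROUPS[t])
        else:
            out.append(t)
    return out


def _template_letters(template: str) -> list[str]:
    found = [c for c in _TEMPLATE_LETTERS if re.search(rf"\b2?{c}\b", template)]
    if not found:
        raise LibraryError(f"template {template!r} uses no placeholder letters")
    return found


def enumerate_ansatz(
    species: SpeciesSet, templates: Iterable[str]
) -> AnsatzLibrary:
    """Instantiate each template over every assignment of distinct species.

    Ordering is deterministic: template-major, then lexicographic in the
    assigned species tuple.  Duplicates arising from overlapping templates
    are dropped, keeping the first occurrence.
    """
    templates = _expand_templates(templates)
    if not templates:
        raise LibraryError("empty template set")
    reactions: list[Reaction] = []
    seen: set = set()
    for template in templates:
        letters = _template_letters(template)
        names = sorted(species.names)
        letter_re = re.compile(r"\b(2?)(" + "|".join(letters) + r")\b")
        for combo in itertools.permutations(names, len(letters)):
            binding = dict(zip(letters, combo))
            # one simultaneous pass: species names may themselves look
            # like placeholder letters
            inst = letter_re.sub(
                lambda m: m.group(1) + binding[m.group(2)], template)
            try:
                rxn = parse_reaction(inst, species)
            except LibraryError:
                continue  # e.g. template collapses to zero net change
            if rxn.key() not in seen:
                seen.add(rxn.key())
                reactions.append(rxn)
    if not reactions:
        raise LibraryError("templates produced no reactions over these species")
    return AnsatzLibrary(species, reactions)


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def save_library(library: AnsatzLibrary, path) -> None:
    """Write ``species: ...`` header plus one reaction string per line."""
    lines = [f"species: {', '.join(library.species.names)}"]
    lines += [format_reaction(r) for r in library.reactions]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_library(path) -> AnsatzLibrary:
    species: SpeciesSet | None = None
    reactions: list[Reaction] = []
    seen: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.lower().startswith("species:"):
                names = [n.strip() for n in line.split(":", 1)[1].split(",")]
                species = SpeciesSet([n for n in names if n])
                continue
            if species is None:
                raise LibraryError(f"line {lineno}: reaction before species header")
            try:
                rxn = parse_reaction(line, species)
            except LibraryError as exc:
                raise LibraryError(f"line {lineno}: {exc}") from None
            if rxn.key() in seen:
                raise LibraryError(
                    f"line {lineno}: duplicate reaction '{line}' "
                    f"(first at line {seen[rxn.key()]})"
                )
            seen[rxn.key()] = lineno
            reactions.append(rxn)
    if species is None:
        raise LibraryError("missing species header line")
    return AnsatzLibrary(species, reactions)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: The 16-reaction Lotka-Volterra candidate set over (P predator, Y prey).
#: The true predator-prey system occupies indices 2, 3, 4.
_LV_REACTIONS = (
    "2 Y -> 0",
    "2 P -> 0",
    "Y -> 2 Y",      # prey birth, true rate 1.0
    "P + Y -> 2 P",  # predation, true rate 0.01
    "P -> 0",        # predator death, true rate 0.3
    "P + Y -> 2 Y",
    "Y -> 0",
    "2 P -> P",
    "P -> 2 P",
    "2 Y -> Y",
    "P + Y -> Y",
    "P + Y -> P",
    "2 Y -> P",
    "Y -> P",
    "P -> Y",
    "Y -> 2 P",
)

LV_TRUE_INDICES = (2, 3, 4)
LV_TRUE_RATES = (1.0, 0.01, 0.3)


def lotka_volterra_library() -> AnsatzLibrary:
    """16 candidate reactions for the predator-prey benchmark."""
    species = SpeciesSet(("P", "Y"))
    return AnsatzLibrary(species, [parse_reaction(r, species) for r in _LV_REACTIONS])


def lotka_volterra_true_library() -> AnsatzLibrary:
    return lotka_volterra_library().subset(list(LV_TRUE_INDICES))


#: Prokaryotic auto-regulation of protein P by gene g: repression via the
#: dimer P2 binding g, transcription of mRNA r, translation, dimerization,
#: and degradation.  Species order (g, P2, gP2, r, P).
_AUTOREG_REACTIONS = (
    "g + P2 -> gP2",   # repression, k=0.5
    "gP2 -> g + P2",   # unbinding, k=1
    "g -> g + r",      # transcription, k=0.15
    "r -> r + P",      # translation, k=1
    "2 P -> P2",       # dimerization, k=0.5
    "P2 -> 2 P",       # dissociation, k=0.5
    "r -> 0",          # mRNA degradation, k=1.5
    "P -> 0",          # protein degradation, k=0.3
)

AUTOREG_TRUE_RATES = (0.5, 1.0, 0.15, 1.0, 0.5, 0.5, 1.5, 0.3)
AUTOREG_SPECIES = ("g", "P2", "gP2", "r", "P")

#: Template classes containing the non-obvious half of the true system
#: (dimerization, dissociation, degradation).
AUTOREG_TEMPLATES = (
    "A -> 0",
    "2A -> B",
    "A -> 2B",
)


def autoregulation_true_library() -> AnsatzLibrary:
    species = SpeciesSet(AUTOREG_SPECIES)
    return AnsatzLibrary(
        species, [parse_reaction(r, species) for r in _AUTOREG_REACTIONS]
    )


def autoregulation_reduced_library() -> AnsatzLibrary:
    """Desk-scale candidate set (49 reactions) for the auto-regulation
    system.

    The four binding/expression reactions usually treated as known
    biology (repression, unbinding, transcription, translation) come
    first; candidates for the remaining, mechanistically uncertain
    chemistry are enumerated completely over three template classes —
    degradation A -> 0 (5), dimerization 2A -> B (20), and dissociation
    A -> 2B (20) — so the true dimerization/degradation reactions sit
    inside full decoy classes rather than among hand-picked alternatives.
    """
    species = SpeciesSet(AUTOREG_SPECIES)
    known = [parse_reaction(r, species) for r in _AUTOREG_REACTIONS[:4]]
    enumerated = enumerate_ansatz(species, AUTOREG_TEMPLATES)
    return AnsatzLibrary(species, known + list(enumerated.reactions))


_PRESETS = {
    "lv-table1": lotka_volterra_library,
    "lv-true": lotka_volterra_true_library,
    "autoreg-true": autoregulation_true_library,
    "autoreg-desk": autoregulation_reduced_library,
}


def library_preset(name: str) -> AnsatzLibrary:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise LibraryError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
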