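"""Machine-readable registry of the symbiont-associated (SA) checklist.

The registry holds one :class:`TermDefinition` per checklist term — its stable
7-digit MIXS ID (or the ``TBD`` sentinel for the still-provisional relationship
term), its requirement level per package (M mandatory, C conditional,
O optional), its category, its definition text and its expected value syntax —
plus a :class:`PackageDefinition` for the core checklist, the 17 pre-existing
environmental packages and the new symbiont-associated package.

The bundled default registry is loaded from a TSV document shipped with the
package; :func:`load_registry` also accepts any document in the same dialect so
downstream registries (amended IDs, extra packages) can be swapped in.
"""

from __future__ import annotations

import csv
import difflib
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable

from .errors import (
    IdSyntaxError,
    PackageNotFoundError,
    RegistryDanglingTermError,
    RegistryDuplicateIdError,
    TermNotFoundError,
)

__all__ = [
    "TermDefinition",
    "PackageDefinition",
    "Registry",
    "load_registry",
    "serialize_registry",
    "canonical_key",
    "REQUIREMENT_LEVELS",
    "VALUE_SYNTAXES",
    "CATEGORIES",
    "ENVIRONMENTAL_PACKAGES_PRE_SA",
    "SA_PACKAGE",
    "CORE_PACKAGE",
]

REQUIREMENT_LEVELS = ("M", "C", "O")

VALUE_SYNTAXES = (
    "free_text",
    "ontology_term",
    "taxon_id",
    "integer_count",
    "duration",
    "taxon_name_list",
    "relationship_list",
    "enumeration",
)

CATEGORIES = (
    "symbiont_specific",
    "symbiont_host_relationship",
    "host_of_symbiont",
    "core",
    "shared",
)

#: Environmental packages that predate the symbiont-associated extension.
ENVIRONMENTAL_PACKAGES_PRE_SA: tuple[str, ...] = (
    "air",
    "built environment",
    "host-associated",
    "human-associated",
    "human-gut",
    "human-oral",
    "human-skin",
    "human-vaginal",
    "hydrocarbon resources-cores",
    "hydrocarbon resources-fluids/swabs",
    "microbial mat/biofilm",
    "miscellaneous natural or artificial environment",
    "plant-associated",
    "sediment",
    "soil",
    "wastewater/sludge",
    "water",
)

SA_PACKAGE = "symbiont-associated"
CORE_PACKAGE = "core"

_MIXS_ID_RE = re.compile(r"^[0-9]{7}$")
_PROVISIONAL_RE = re.compile(r"^SA-REL-[0-9]{4}$")
_TBD = "TBD"

#: Aliases the checklist text itself uses for terms, beyond mechanical
#: space/underscore variation (e.g. "mode_transmission" in the definition of
#: "route of transmission").
_EXTRA_ALIASES: dict[str, str] = {
    "mode_transmission": "mode_of_transmission",
}

_REGISTRY_COLUMNS = (
    "canonical_name",
    "display_name",
    "mixs_id",
    "category",
    "packages",
    "requirements",
    "definition",
    "value_syntax",
)


def canonical_key(name: str) -> str:
    """Normalize a term or package reference to its canonical lookup key.

    Lowercases and collapses every run of non-alphanumeric characters to a
    single underscore, so display names ("host dependence"), snake_case tokens
    and mixed variants all resolve identically.
    """
    key = re.sub(r"[^a-z0-9]+", "_", name.strip().lower())
    return key.strip("_")


@dataclass
class TermDefinition:
    """One checklist term as transcribed from the standard."""

    canonical_name: str
    display_name: str
    mixs_id: str  # 7-digit zero-padded decimal string, or "TBD"
    category: str
    packages: tuple[str, ...]
    requirement_by_package: dict[str, str]
    definition: str
    value_syntax: str
    provisional_id: str | None = None

    def __post_init__(self) -> None:
        if self.mixs_id != _TBD and not _MIXS_ID_RE.match(self.mixs_id):
            raise IdSyntaxError(
                f"mixs_id {self.mixs_id!r} for {self.canonical_name!r} is not "
                f"a 7-digit decimal string or {_TBD!r}"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.value_syntax not in VALUE_SYNTAXES:
            raise ValueError(f"unknown value_syntax {self.value_syntax!r}")
        bad = set(self.requirement_by_package) - set(self.packages)
        if bad:
            raise ValueError(
                f"requirement levels for packages not listed on the term: {sorted(bad)}"
            )
        for level in self.requirement_by_package.values():
            if level not in REQUIREMENT_LEVELS:
                raise ValueError(f"unknown requirement level {level!r}")
        if self.is_provisional and self.provisional_id is None:
            raise ValueError("provisional term needs a provisional_id")
        if self.provisional_id is not None and not _PROVISIONAL_RE.match(self.provisional_id):
            raise IdSyntaxError(f"malformed provisional id {self.provisional_id!r}")

    @property
    def is_provisional(self) -> bool:
        """True while the standard has not yet assigned a MIXS ID (``TBD``)."""
        return self.mixs_id == _TBD

    #: Alias kept because the provisional term is excluded from the ID bijection.
    non_canonical = is_provisional

    def requirement(self, package: str) -> str | None:
        return self.requirement_by_package.get(package)


@dataclass
class PackageDefinition:
    """A checklist package (core or environmental) and the terms it carries."""

    name: str
    kind: str  # "environmental" | "core"
    terms: list[str] = field(default_factory=list)


@dataclass
class Registry:
    """Index of terms and packages with name-, ID- and alias-based lookup."""

    terms: dict[str, TermDefinition]
    id_index: dict[str, str]
    packages: dict[str, PackageDefinition]
    aliases: dict[str, str]
    version_label: str = "MIxS-SA 1.0 (MIxS v6 draft)"

    # -------------------------------------------------------------- lookups

    def get_term(self, name: str) -> TermDefinition:
        """Resolve a term by display name, canonical name or any variant.

        Resolution is case-insensitive and treats spaces, hyphens and
        underscores interchangeably.
        """
        key = canonical_key(name)
        key = self.aliases.get(key, key)
        try:
            return self.terms[key]
        except KeyError:
            candidates = list(self.terms) + list(self.aliases)
            suggestions = difflib.get_close_matches(key, candidates, n=3, cutoff=0.5)
            hint = f" (did you mean: {', '.join(suggestions)}?)" if suggestions else ""
            raise TermNotFoundError(
                f"no term named {name!r}{hint}", suggestions=suggestions
            ) from None

    def get_term_by_id(self, mixs_id: str) -> TermDefinition:
        """Resolve a term by its 7-digit MIXS ID or a provisional token."""
        if not (_MIXS_ID_RE.match(mixs_id) or _PROVISIONAL_RE.match(mixs_id)):
            raise IdSyntaxError(
                f"{mixs_id!r} is not a 7-digit MIXS ID or provisional token"
            )
        try:
            return self.terms[self.id_index[mixs_id]]
        except KeyError:
            raise TermNotFoundError(f"no term with id {mixs_id!r}") from None

    def get_package(self, name: str) -> PackageDefinition:
        key = name.strip().lower()
        if key not in self.packages:
            raise PackageNotFoundError(f"no package named {name!r}")
        return self.packages[key]

    def has_term(self, name: str) -> bool:
        key = canonical_key(name)
        return self.aliases.get(key, key) in self.terms

    def terms_for_package(
        self, package: str, level_filter: str | None = None
    ) -> list[TermDefinition]:
        """Terms of a package in registry order, optionally at one level."""
        if level_filter is not None and level_filter not in REQUIREMENT_LEVELS:
            raise ValueError(f"level_filter must be one of {REQUIREMENT_LEVELS}")
        pkg = self.get_package(package)
        out = []
        for name in pkg.terms:
            term = self.terms[name]
            if level_filter is None or term.requirement(pkg.name) == level_filter:
                out.append(term)
        return out

    def list_packages(
        self, kind: str | None = None, exclude_new: bool = False
    ) -> list[PackageDefinition]:
        """List packages, optionally by kind; ``exclude_new`` drops the SA
        package to recover the pre-existing environmental-package census."""
        out = []
        for pkg in self.packages.values():
            if kind is not None and pkg.kind != kind:
                continue
            if exclude_new and pkg.name == SA_PACKAGE:
                continue
            out.append(pkg)
        return out

    def new_terms(self) -> list[TermDefinition]:
        """The terms introduced alongside the SA package for use beyond it:
        the shared term added to several host packages plus the two new core
        terms."""
        return [t for t in self.terms.values() if t.category in ("core", "shared")]

    # ------------------------------------------------------------ integrity

    def check(self) -> None:
        """Re-verify the structural invariants; raises on violation."""
        seen_ids: dict[str, str] = {}
        for term in self.terms.values():
            key = term.provisional_id if term.is_provisional else term.mixs_id
            if key in seen_ids:
                raise RegistryDuplicateIdError(
                    f"id {key} claimed by both {seen_ids[key]!r} and "
                    f"{term.canonical_name!r}"
                )
            seen_ids[key] = term.canonical_name
        for pkg in self.packages.values():
            for name in pkg.terms:
                if name not in self.terms:
                    raise RegistryDanglingTermError(
                        f"package {pkg.name!r} lists undefined term {name!r}"
                    )


# ------------------------------------------------------------------ loading

def _read_registry_rows(source: str | Path | IO[str] | None) -> list[dict[str, str]]:
    if source is None:
        text = (
            resources.files("mixs_sa").joinpath("data/mixs_sa_registry.tsv").read_text("utf-8")
        )
        handle: IO[str] = io.StringIO(text)
    elif isinstance(source, (str, Path)) and "\t" not in str(source):
        handle = open(source, encoding="utf-8", newline="")
    elif isinstance(source, str):
        handle = io.StringIO(source)
    else:
        handle = source  # file-like
    with handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if tuple(reader.fieldnames or ()) != _REGISTRY_COLUMNS:
            raise RegistryDanglingTermError(
                f"registry document must have columns {_REGISTRY_COLUMNS}, "
                f"got {tuple(reader.fieldnames or ())}"
            )
        return list(reader)


def load_registry(source: str | Path | IO[str] | None = None) -> Registry:
    """Build a :class:`Registry` from a TSV document, or the bundled default.

    ``source`` may be a path, an open text stream, an inline TSV string (any
    string containing a tab is treated as document text, not a path), or
    ``None`` for the transcription shipped with the package.
    """
    rows = _read_registry_rows(source)
    terms: dict[str, TermDefinition] = {}
    id_index: dict[str, str] = {}
    aliases: dict[str, str] = dict(_EXTRA_ALIASES)
    provisional_counter = 0

    for row in rows:
        name = row["canonical_name"].strip()
        packages = tuple(p.strip() for p in row["packages"].split(";") if p.strip())
        requirements: dict[str, str] = {}
        for pair in row["requirements"].split(";"):
            pair = pair.strip()
            if not pair:
                continue
            pkg, _, level = pair.partition("=")
            requirements[pkg.strip()] = level.strip()
        mixs_id = row["mixs_id"].strip()
        provisional_id = None
        if mixs_id == _TBD:
            provisional_counter += 1
            provisional_id = f"SA-REL-{provisional_counter:04d}"
        term = TermDefinition(
            canonical_name=name,
            display_name=row["display_name"].strip(),
            mixs_id=mixs_id,
            category=row["category"].strip(),
            packages=packages,
            requirement_by_package=requirements,
            definition=row["definition"].strip(),
            value_syntax=row["value_syntax"].strip(),
            provisional_id=provisional_id,
        )
        if name in terms:
            raise RegistryDuplicateIdError(f"canonical_name {name!r} defined twice")
        id_key = provisional_id if term.is_provisional else term.mixs_id
        if id_key in id_index:
            raise RegistryDuplicateIdError(
                f"mixs_id {id_key} claimed by both {id_index[id_key]!r} and {name!r}"
            )
        terms[name] = term
        id_index[id_key] = name
        display_key = canonical_key(term.display_name)
        if display_key != name:
            aliases[display_key] = name

    packages: dict[str, PackageDefinition] = {}
    packages[CORE_PACKAGE] = PackageDefinition(CORE_PACKAGE, "core")
    for pkg_name in ENVIRONMENTAL_PACKAGES_PRE_SA:
        packages[pkg_name] = PackageDefinition(pkg_name, "environmental")
    packages[SA_PACKAGE] = PackageDefinition(SA_PACKAGE, "environmental")
    for term in terms.values():
        for pkg_name in term.packages:
            if pkg_name not in packages:
                packages[pkg_name] = PackageDefinition(pkg_name, "environmental")
            packages[pkg_name].terms.append(term.canonical_name)

    registry = Registry(terms=terms, id_index=id_index, packages=packages, aliases=aliases)
    registry.check()
    return registry


def serialize_registry(registry: Registry) -> str:
    """Render a registry back to the TSV dialect accepted by
    :func:`load_registry` (round-trip safe)."""
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(_REGISTRY_COLUMNS)
    for term in registry.terms.values():
        writer.writerow(
            [
                term.canonical_name,
                term.display_name,
                term.mixs_id,
                term.category,
                ";".join(term.packages),
                ";".join(f"{p}={lvl}" for p, lvl in term.requirement_by_package.items()),
                term.definition,
                term.value_syntax,
            ]
        )
    return out.getvalue()


# Module-level functional aliases mirroring the operation names.

def get_term(registry: Registry, name: str) -> TermDefinition:
    return registry.get_term(name)


def get_term_by_id(registry: Registry, mixs_id: str) -> TermDefinition:
    return registry.get_term_by_id(mixs_id)


def terms_for_package(
    registry: Registry, package: str, level_filter: str | None = None
) -> list[TermDefinition]:
    return registry.terms_for_package(package, level_filter)


def list_packages(
    registry: Registry, kind: str | None = None, exclude_new: bool = False
) -> list[PackageDefinition]:
    return registry.list_packages(kind=kind, exclude_new=exclude_new)
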