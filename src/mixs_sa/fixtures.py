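"""Built-in study designs and a seeded generator of randomized nested studies.

Two executable demonstration designs ship with the package:

* :func:`fig1a_study` — a trematode (*Coitocaecum parvum*) sampled at four
  life stages across its snail, amphipod and fish hosts, with sediment and
  water samples from the collection site;
* :func:`fig1b_study` — a holoparasitic plant (*Orobanche hederae*) on ivy
  hosts, with soil samples.

:func:`generate_nested_study` emulates the same nested
environment → host → symbiont structure at arbitrary size, and
:func:`inject_error` plants exactly one seeded defect of a chosen kind so the
validator's detection can be exercised systematically. The generator only
produces metadata structure — packages, mandatory attributes, relationship
entries — never sequence data or community composition.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass

from .errors import InjectionImpossibleError, ParamsInvalidError
from .records import MetadataTable, SampleRecord
from .registry import Registry, load_registry

__all__ = [
    "StudyDesignParams",
    "fig1a_study",
    "fig1b_study",
    "generate_nested_study",
    "inject_error",
    "InjectionResult",
    "INJECTION_KINDS",
    "EXPECTED_ISSUE_CODES",
]

MAX_NODES = 10_000

#: Injectable defect kinds and the issue code each must provoke.
EXPECTED_ISSUE_CODES: dict[str, str] = {
    "drop_mandatory": "MISSING_MANDATORY",
    "containment_cycle": "CONTAINMENT_CYCLE",
    "dangling_reference": "DANGLING_REFERENCE",
    "bad_predicate": "BAD_PREDICATE",
    "duplicate_sample": "DUPLICATE_SAMPLE",
    "bad_taxon_id": "VALUE_SYNTAX",
}

INJECTION_KINDS = tuple(EXPECTED_ISSUE_CODES)

_SA = "symbiont-associated"
_HA = "host-associated"

_LIFE_STAGES = ("egg", "larva", "juvenile", "adult")
_ENV_PACKAGES = ("water", "sediment", "soil")


def _sa_attributes(dependence: str, cycle: str, stage: str) -> dict[str, str]:
    return {
        "host_dependence": dependence,
        "symbiotic_host_organism_life_cycle_type": cycle,
        "host_life_stage": stage,
    }


def fig1a_study() -> MetadataTable:
    """Trematode life-stage design: four symbiont samples (sporocyst in a
    snail, free-living cercaria in water, metacercaria in an amphipod, adult
    in a fish), three host samples, one sediment and one water sample."""
    def sa(sample_id: str, stage: str, rels: list[str]) -> SampleRecord:
        return SampleRecord(
            sample_id=sample_id,
            package=_SA,
            attributes={
                **_sa_attributes("obligate", "complex", stage),
                "type_of_symbiosis": "parasitic",
            },
            relationship_entries=rels,
        )

    records = [
        sa("S1", "sporocyst", ["within:H1"]),
        sa("S2", "cercaria", ["within:E2"]),
        sa("S3", "metacercaria", ["within:H2"]),
        sa("S4", "adult", ["within:H3"]),
        SampleRecord(
            "H1", _HA,
            {"observed_host_symbionts": "Coitocaecum parvum"},
            ["next to:E1", "within:E2"],
        ),
        SampleRecord("H2", _HA, {"observed_host_symbionts": "Coitocaecum parvum"}, ["within:E2"]),
        SampleRecord("H3", _HA, {"observed_host_symbionts": "Coitocaecum parvum"}, ["within:E2"]),
        SampleRecord("E1", "sediment", {}, ["next to:E2"]),
        SampleRecord("E2", "water", {}, []),
    ]
    return MetadataTable(records=records, bioproject_id="PRJ-TREMATODE-DEMO")


def fig1b_study() -> MetadataTable:
    """Parasitic-plant design: two symbiont samples on an ivy host stand of
    three plants, with two soil samples."""
    def sa(sample_id: str, rels: list[str]) -> SampleRecord:
        return SampleRecord(
            sample_id=sample_id,
            package=_SA,
            attributes={
                **_sa_attributes("obligate", "simple", "adult"),
                "type_of_symbiosis": "parasitic",
            },
            relationship_entries=rels,
        )

    pa = {"observed_host_symbionts": "Orobanche hederae"}
    records = [
        sa("S5", ["next to:S6"]),
        sa("S6", ["within:P1"]),
        SampleRecord("P1", "plant-associated", dict(pa), ["next to:P2", "next to:P3", "within:E3"]),
        SampleRecord("P2", "plant-associated", dict(pa), ["next to:P3"]),
        SampleRecord("P3", "plant-associated", dict(pa), ["within:E4"]),
        SampleRecord("E3", "soil", {}, ["next to:E4"]),
        SampleRecord("E4", "soil", {}, []),
    ]
    return MetadataTable(records=records, bioproject_id="PRJ-OROBANCHE-DEMO")


# ---------------------------------------------------------------- generator

@dataclass
class StudyDesignParams:
    """Shape of a randomized nested study.

    Defaults give a small but non-trivial design: two environments, three
    hosts each, two symbiont samples per host, sparse co-location, one
    technical-replicate pair.
    """

    n_environments: int = 2
    n_hosts_per_environment: int = 3
    n_symbionts_per_host: int = 2
    p_next_to: float = 0.25
    n_replicate_pairs: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_environments < 1:
            raise ParamsInvalidError("n_environments must be >= 1")
        if self.n_hosts_per_environment < 1:
            raise ParamsInvalidError("n_hosts_per_environment must be >= 1")
        if self.n_symbionts_per_host < 0:
            raise ParamsInvalidError("n_symbionts_per_host must be >= 0")
        if not 0.0 <= self.p_next_to <= 1.0:
            raise ParamsInvalidError("p_next_to must be in [0, 1]")
        if self.n_replicate_pairs < 0:
            raise ParamsInvalidError("n_replicate_pairs must be >= 0")
        if self.total_nodes() > MAX_NODES:
            raise ParamsInvalidError(
                f"design would have {self.total_nodes()} nodes (limit {MAX_NODES})"
            )

    def total_nodes(self) -> int:
        hosts = self.n_environments * self.n_hosts_per_environment
        return (
            self.n_environments
            + hosts
            + hosts * self.n_symbionts_per_host
            + self.n_replicate_pairs
        )


def generate_nested_study(params: StudyDesignParams) -> MetadataTable:
    """Generate a clean nested study (validates with zero ERROR issues).

    Structure: each host is 'within' exactly one environment and each symbiont
    'within' exactly one host; 'next to' edges are drawn independently with
    probability ``p_next_to`` between environments and between siblings (hosts
    sharing an environment, symbionts sharing a host); replicate pairs copy an
    existing sample's attributes under the id ``<id>R<k>`` and link back with
    'technical replicate of'. Output is a pure function of the parameters
    (one seeded random stream, fixed id scheme E1.., H1.., S1..).
    """
    params.validate()
    rng = random.Random(params.seed)
    records: list[SampleRecord] = []

    envs = [f"E{i + 1}" for i in range(params.n_environments)]
    env_records = {
        e: SampleRecord(e, _ENV_PACKAGES[i % len(_ENV_PACKAGES)], {}, [])
        for i, e in enumerate(envs)
    }

    hosts_of_env: dict[str, list[str]] = {e: [] for e in envs}
    host_records: dict[str, SampleRecord] = {}
    h = 0
    for e in envs:
        for _ in range(params.n_hosts_per_environment):
            h += 1
            hid = f"H{h}"
            hosts_of_env[e].append(hid)
            host_records[hid] = SampleRecord(hid, _HA, {}, [f"within:{e}"])

    symbionts_of_host: dict[str, list[str]] = {hid: [] for hid in host_records}
    symbiont_records: dict[str, SampleRecord] = {}
    s = 0
    for hid in host_records:
        for _ in range(params.n_symbionts_per_host):
            s += 1
            sid = f"S{s}"
            symbionts_of_host[hid].append(sid)
            symbiont_records[sid] = SampleRecord(
                sid,
                _SA,
                _sa_attributes(
                    rng.choice(("obligate", "facultative")),
                    rng.choice(("simple", "complex")),
                    rng.choice(_LIFE_STAGES),
                ),
                [f"within:{hid}"],
            )

    def maybe_adjacent(group: list[str], by_id: dict[str, SampleRecord]) -> None:
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if rng.random() < params.p_next_to:
                    by_id[a].relationship_entries.append(f"next to:{b}")

    maybe_adjacent(envs, env_records)
    for e in envs:
        maybe_adjacent(hosts_of_env[e], host_records)
    for hid in host_records:
        maybe_adjacent(symbionts_of_host[hid], symbiont_records)

    records = list(env_records.values()) + list(host_records.values()) + list(
        symbiont_records.values()
    )

    base = list(records)
    rep_count: dict[str, int] = {}
    for _ in range(params.n_replicate_pairs):
        orig = rng.choice(base)
        rep_count[orig.sample_id] = rep_count.get(orig.sample_id, 0) + 1
        records.append(
            SampleRecord(
                f"{orig.sample_id}R{rep_count[orig.sample_id]}",
                orig.package,
                dict(orig.attributes),
                [f"technical replicate of:{orig.sample_id}"],
            )
        )

    return MetadataTable(records=records, bioproject_id=f"PRJ-SIM-{params.seed}")


# ---------------------------------------------------------------- injection

@dataclass
class InjectionResult:
    """A defective copy of a table plus a manifest of what was planted."""

    table: MetadataTable
    manifest: dict[str, str]


def inject_error(
    table: MetadataTable,
    kind: str,
    seed: int = 0,
    registry: Registry | None = None,
) -> InjectionResult:
    """Introduce exactly one defect of ``kind`` at a seed-determined location.

    The input table is never mutated. Raises ``INJECTION_IMPOSSIBLE`` when the
    table cannot host the requested defect (e.g. no mandatory attribute to
    drop).
    """
    if kind not in INJECTION_KINDS:
        raise ParamsInvalidError(
            f"unknown injection kind {kind!r} (choose from {INJECTION_KINDS})"
        )
    registry = registry or load_registry()
    rng = random.Random(seed)
    table = copy.deepcopy(table)
    records = table.records
    if not records:
        raise InjectionImpossibleError("cannot inject into an empty table")
    manifest: dict[str, str] = {"kind": kind}

    if kind == "drop_mandatory":
        candidates = []
        for rec in records:
            try:
                mandatory = registry.terms_for_package(rec.package, "M")
            except Exception:
                continue
            for term in mandatory:
                if term.canonical_name in rec.attributes:
                    candidates.append((rec, term.canonical_name))
        if not candidates:
            raise InjectionImpossibleError("no mandatory attribute present to drop")
        rec, term_name = rng.choice(candidates)
        del rec.attributes[term_name]
        manifest |= {"sample_id": rec.sample_id, "term": term_name}

    elif kind == "containment_cycle":
        from .relgraph import build_graph  # deferred: relgraph imports records

        within = [e for e in build_graph(table).edges if e.predicate == "within"]
        if within:
            edge = rng.choice(sorted(within))
            target = table.get(edge.object)
            assert target is not None
            target.relationship_entries.append(f"within:{edge.subject}")
            manifest |= {"sample_id": target.sample_id, "detail": f"within:{edge.subject}"}
        elif len(records) >= 2:
            a, b = rng.sample(records, 2)
            a.relationship_entries.append(f"within:{b.sample_id}")
            b.relationship_entries.append(f"within:{a.sample_id}")
            manifest |= {"sample_id": a.sample_id, "detail": f"2-cycle with {b.sample_id}"}
        else:
            raise InjectionImpossibleError("need >= 2 samples to form a cycle")

    elif kind == "dangling_reference":
        rec = rng.choice(records)
        missing = "ZZ999"
        while table.get(missing) is not None:  # pragma: no cover - astronomically rare
            missing += "9"
        rec.relationship_entries.append(f"within:{missing}")
        manifest |= {"sample_id": rec.sample_id, "detail": f"within:{missing}"}

    elif kind == "bad_predicate":
        if len(records) < 2:
            raise InjectionImpossibleError("need >= 2 samples for a relationship entry")
        rec, other = rng.sample(records, 2)
        rec.relationship_entries.append(f"inside:{other.sample_id}")
        manifest |= {"sample_id": rec.sample_id, "detail": f"inside:{other.sample_id}"}

    elif kind == "duplicate_sample":
        rec = rng.choice(records)
        records.append(copy.deepcopy(rec))
        manifest |= {"sample_id": rec.sample_id}

    elif kind == "bad_taxon_id":
        rec = rng.choice(records)
        rec.attributes["host_of_the_symbiotic_host_taxon_id"] = "not-a-number"
        manifest |= {
            "sample_id": rec.sample_id,
            "term": "host_of_the_symbiotic_host_taxon_id",
        }

    return InjectionResult(table=table, manifest=manifest)


def manifest_text(result: InjectionResult) -> str:
    """Render an injection manifest as a small key=value document."""
    return "".join(f"{k}={v}\n" for k, v in result.manifest.items())
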