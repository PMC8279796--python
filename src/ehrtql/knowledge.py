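"""Knowledge-graph query expansion.

Diagnosis terminologies (ICD9, ICD10) are parent-child DAGs: if a child code
exists in a patient's record, the transitive closure of its ancestors is
associated to the same time point at load time, so a query for any parent
code returns the patient.  Drugs are expanded from their RxNorm identifier
(RxCUI) to mapped ATC classes plus all ATC ancestors — e.g. acetaminophen
(RxCUI 161) gains N02BE, N02B, N02 and N.  The ORIGINAL command bypasses
expansion at query time by restricting evaluation to source-data events.

Ontologies are supplied as two-column ``child,parent`` edge-list CSVs and a
two-column ``rxcui,atc`` mapping CSV; tiny fixture ontologies covering the
codes used in the worked examples ship with the package, and real
vocabularies drop in through the same format.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

from .errors import OntologyError
from .model import Event, FeatureKey, PatientObject


@dataclass
class CodeOntology:
    """Parent-child DAG over one code namespace."""

    namespace: str
    parents: Dict[str, FrozenSet[str]]  # child -> direct parents
    _closure: Dict[str, FrozenSet[str]] = field(default_factory=dict, repr=False)

    @classmethod
    def from_edges(cls, namespace: str, edges: Iterable[Tuple[str, str]]) -> "CodeOntology":
        """Build from (child, parent) pairs; rejects cyclic graphs."""
        parents: Dict[str, Set[str]] = {}
        for child, parent in edges:
            child, parent = child.strip(), parent.strip()
            if not child or not parent:
                raise OntologyError(f"{namespace}: empty code in edge ({child!r}, {parent!r})")
            parents.setdefault(child, set()).add(parent)
        onto = cls(namespace, {c: frozenset(ps) for c, ps in parents.items()})
        onto._check_acyclic()
        return onto

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color: Dict[str, int] = {}

        for start in self.parents:
            if color.get(start, WHITE) != WHITE:
                continue
            stack: List[Tuple[str, Iterable[str]]] = [(start, iter(self.parents.get(start, ())))]
            color[start] = GREY
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    c = color.get(nxt, WHITE)
                    if c == GREY:
                        raise OntologyError(
                            f"{self.namespace}: cycle through code {nxt!r}")
                    if c == WHITE:
                        color[nxt] = GREY
                        stack.append((nxt, iter(self.parents.get(nxt, ()))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

    def ancestors(self, code: str) -> FrozenSet[str]:
        """Transitive closure of parents, excluding the code itself.

        Unknown codes have no ancestors.
        """
        cached = self._closure.get(code)
        if cached is not None:
            return cached
        out: Set[str] = set()
        frontier = list(self.parents.get(code, ()))
        while frontier:
            c = frontier.pop()
            if c in out:
                continue
            out.add(c)
            frontier.extend(self.parents.get(c, ()))
        result = frozenset(out)
        self._closure[code] = result
        return result


@dataclass
class DrugClassMap:
    """RxCUI → ATC class mapping plus the ATC hierarchy."""

    rx_to_atc: Dict[str, FrozenSet[str]]
    atc_ontology: CodeOntology

    def expand(self, rxcui: str) -> FrozenSet[str]:
        """Mapped ATC codes plus all their ATC ancestors (∅ if unmapped)."""
        atcs = self.rx_to_atc.get(rxcui, frozenset())
        out: Set[str] = set(atcs)
        for code in atcs:
            out |= self.atc_ontology.ancestors(code)
        return frozenset(out)


def ancestors(ontology: CodeOntology, code: str) -> FrozenSet[str]:
    return ontology.ancestors(code)


def expand_drug(drug_map: DrugClassMap, rxcui: str) -> FrozenSet[str]:
    return drug_map.expand(rxcui)


def expand_events(patient: PatientObject,
                  ontologies: Optional[Dict[str, CodeOntology]] = None,
                  drug_map: Optional[DrugClassMap] = None) -> PatientObject:
    """Add derived events for every ancestor/ATC code of each original event.

    Derived events share the source event's interval and carry
    ``original=False``; the operation mutates and returns ``patient`` and is
    idempotent (re-expanding adds nothing).  Intervals, values and the
    patient span are never changed.
    """
    ontologies = ontologies or {}
    existing = {(ev.key, ev.interval) for ev in patient.events if not ev.original}
    derived: List[Event] = []

    def add(key: FeatureKey, interval) -> None:
        if (key, interval) not in existing:
            existing.add((key, interval))
            derived.append(Event(key=key, interval=interval, original=False))

    for ev in patient.events:
        if not ev.original:
            continue
        ns, code = ev.key
        onto = ontologies.get(ns)
        if onto is not None:
            for anc in onto.ancestors(code):
                add(FeatureKey(ns, anc), ev.interval)
        if ns == "RX" and drug_map is not None:
            for atc in drug_map.expand(code):
                add(FeatureKey("ATC", atc), ev.interval)
    if derived:
        patient.events.extend(derived)
        patient.rebuild_key_index()
    return patient


# ---------------------------------------------------------------------------
# CSV loading and packaged fixture ontologies
# ---------------------------------------------------------------------------

def _read_pairs(path) -> List[Tuple[str, str]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        rows = [tuple(r[:2]) for r in reader if len(r) >= 2]
    if header and len(header) >= 2 and header[0].lower() not in ("child", "rxcui"):
        # no header line; first row was data
        rows.insert(0, tuple(header[:2]))
    return rows


def load_ontology_csv(path, namespace: str) -> CodeOntology:
    """Read a ``child,parent`` edge-list CSV into a :class:`CodeOntology`."""
    return CodeOntology.from_edges(namespace, _read_pairs(path))


def load_drug_map_csv(rx_path, atc_ontology: CodeOntology) -> DrugClassMap:
    """Read a ``rxcui,atc`` CSV into a :class:`DrugClassMap`."""
    mapping: Dict[str, Set[str]] = {}
    for rxcui, atc in _read_pairs(rx_path):
        mapping.setdefault(rxcui.strip(), set()).add(atc.strip())
    return DrugClassMap({k: frozenset(v) for k, v in mapping.items()}, atc_ontology)


def _data_path(name: str) -> Path:
    return Path(resources.files("ehrtql").joinpath("data", name))  # type: ignore[arg-type]


def fixture_ontologies() -> Dict[str, CodeOntology]:
    """The packaged toy ICD9/ICD10/ATC hierarchies (~50 codes)."""
    return {
        "ICD9": load_ontology_csv(_data_path("icd9_edges.csv"), "ICD9"),
        "ICD10": load_ontology_csv(_data_path("icd10_edges.csv"), "ICD10"),
        "ATC": load_ontology_csv(_data_path("atc_edges.csv"), "ATC"),
    }


def fixture_drug_map(atc_ontology: Optional[CodeOntology] = None) -> DrugClassMap:
    """The packaged RxCUI→ATC fixture mapping."""
    if atc_ontology is None:
        atc_ontology = load_ontology_csv(_data_path("atc_edges.csv"), "ATC")
    return load_drug_map_csv(_data_path("rx_to_atc.csv"), atc_ontology)
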