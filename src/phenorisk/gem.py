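"""ICD-9 <-> ICD-10 general equivalence mapping (GEM) as a bipartite graph.

The crosswalk between the two diagnosis vocabularies is treated as a
bipartite graph: ICD-9 codes on one side, ICD-10 codes on the other, and
an edge wherever the GEM lists a possible conversion.  Decomposing that
graph into its connected components yields the minimal disjoint bipartite
subgraphs — groups of codes that denote the same clinical concept across
the coding-system transition.  Each group becomes a single era-spanning
"code" usable as a binary feature regardless of whether a patient's
diagnoses were recorded before or after the transition date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "GemGraph",
    "CodeGroup",
    "GroupLookup",
    "normalize_code",
    "read_gem_file",
    "decompose_gem",
    "map_event",
    "write_groups",
]


def normalize_code(code: str) -> str:
    """Normalize an ICD code for matching: strip dots/whitespace, uppercase.

    GEM files conventionally omit the dot ("3310"), while event tables often
    include it ("331.0"); both normalize to the same key.
    """
    norm = code.strip().replace(".", "").upper()
    if not norm:
        raise ValueError(f"empty ICD code after normalization: {code!r}")
    return norm


@dataclass(frozen=True)
class GemGraph:
    """Bipartite crosswalk graph over two disjoint code namespaces."""

    edges: frozenset[tuple[str, str]]
    icd9_vertices: frozenset[str]
    icd10_vertices: frozenset[str]

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_icd9: Iterable[str] = (),
        extra_icd10: Iterable[str] = (),
    ) -> "GemGraph":
        """Build a graph from (icd9, icd10) pairs, normalizing codes.

        ``extra_*`` supply isolated vertices (codes with no crosswalk edge);
        they become singleton groups on decomposition.
        """
        norm_edges = set()
        v9, v10 = set(), set()
        for a, b in edges:
            a, b = normalize_code(a), normalize_code(b)
            norm_edges.add((a, b))
            v9.add(a)
            v10.add(b)
        v9.update(normalize_code(c) for c in extra_icd9)
        v10.update(normalize_code(c) for c in extra_icd10)
        return cls(frozenset(norm_edges), frozenset(v9), frozenset(v10))


@dataclass(frozen=True)
class CodeGroup:
    """One minimal bipartite subgraph: an era-spanning group of ICD codes.

    ``group_id`` is deterministic — the lexicographically smallest namespaced
    member code — so repeated decompositions name groups identically.
    """

    group_id: str
    icd9_codes: frozenset[str]
    icd10_codes: frozenset[str]

    @staticmethod
    def make(icd9_codes: Iterable[str], icd10_codes: Iterable[str]) -> "CodeGroup":
        g9 = frozenset(icd9_codes)
        g10 = frozenset(icd10_codes)
        if not (g9 or g10):
            raise ValueError("a code group must contain at least one code")
        gid = min([f"ICD9:{c}" for c in g9] + [f"ICD10:{c}" for c in g10])
        return CodeGroup(gid, g9, g10)


def read_gem_file(path) -> GemGraph:
    """Read a tab-delimited ``icd9<TAB>icd10`` edge file (CMS GEM layout).

    Blank lines are skipped; duplicate edges (after code normalization) are
    silently de-duplicated with a log entry.
    """
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-delimited fields, got {len(parts)}")
            edge = (normalize_code(parts[0]), normalize_code(parts[1]))
            if edge in seen:
                n_dup += 1
                continue
            seen.add(edge)
            edges.append(edge)
    if n_dup:
        logger.info("read_gem_file: de-duplicated %d repeated edges in %s", n_dup, path)
    return GemGraph.from_edges(edges)


def decompose_gem(graph: GemGraph) -> list[CodeGroup]:
    """Decompose the crosswalk into minimal disjoint bipartite subgraphs.

    The groups are exactly the connected components of the bipartite graph:
    no edge crosses two groups, and no group can be split further without
    breaking an edge.  Isolated vertices become singleton groups.  Groups are
    returned sorted by ``group_id``.
    """
    g = nx.Graph()
    g.add_nodes_from(("9", c) for c in graph.icd9_vertices)
    g.add_nodes_from(("10", c) for c in graph.icd10_vertices)
    g.add_edges_from((("9", a), ("10", b)) for a, b in graph.edges)
    groups = []
    for comp in nx.connected_components(g):
        icd9 = [c for ns, c in comp if ns == "9"]
        icd10 = [c for ns, c in comp if ns == "10"]
        groups.append(CodeGroup.make(icd9, icd10))
    return sorted(groups, key=lambda gr: gr.group_id)


class GroupLookup:
    """Code -> group_id index over a decomposition, one dict per namespace."""

    def __init__(self, groups: Iterable[CodeGroup]):
        self.by_icd9: dict[str, str] = {}
        self.by_icd10: dict[str, str] = {}
        for gr in groups:
            for c in gr.icd9_codes:
                if c in self.by_icd9:
                    raise ValueError(f"code {c} appears in two groups")
                self.by_icd9[c] = gr.group_id
            for c in gr.icd10_codes:
                if c in self.by_icd10:
                    raise ValueError(f"code {c} appears in two groups")
                self.by_icd10[c] = gr.group_id

    def lookup(self, system: str, code: str) -> str:
        """Resolve a diagnosis code to its group id.

        Unmapped codes fall back to a deterministic singleton id
        (``"ICD9:<code>"`` / ``"ICD10:<code>"``) rather than being dropped,
        so rare codes outside the crosswalk still yield features.
        """
        norm = normalize_code(code)
        if system == "ICD9":
            return self.by_icd9.get(norm, f"ICD9:{norm}")
        if system == "ICD10":
            return self.by_icd10.get(norm, f"ICD10:{norm}")
        raise ValueError(f"map_event expects an ICD9 or ICD10 event, got system={system!r}")


def map_event(code_event, groups, transition_date: date | None = None) -> str:
    """Map one dated diagnosis event to its era-spanning group id.

    The event's ``system`` field decides which side of the bipartite graph is
    consulted (the generator guarantees system/era consistency: ICD-9 strictly
    before the transition date, ICD-10 on or after it).  ``groups`` may be a
    list of :class:`CodeGroup` or a prebuilt :class:`GroupLookup`.
    """
    lut = groups if isinstance(groups, GroupLookup) else GroupLookup(groups)
    if transition_date is not None and getattr(code_event, "event_date", None) is not None:
        era_icd10 = code_event.event_date >= transition_date
        if era_icd10 != (code_event.system == "ICD10"):
            logger.warning(
                "map_event: event %s/%s dated %s is inconsistent with transition %s",
                code_event.system, code_event.code, code_event.event_date, transition_date,
            )
    return lut.lookup(code_event.system, code_event.code)


def write_groups(groups: Iterable[CodeGroup], path) -> None:
    """Write a decomposition as CSV with columns group_id, namespace, code."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group_id,namespace,code\n")
        for gr in sorted(groups, key=lambda g: g.group_id):
            for c in sorted(gr.icd9_codes):
                fh.write(f"{gr.group_id},ICD9,{c}\n")
            for c in sorted(gr.icd10_codes):
                fh.write(f"{gr.group_id},ICD10,{c}\n")
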