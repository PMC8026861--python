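"""Signed disease-gene relation tables and literature networks.

A *relation* is one directed, signed assertion mined from the literature:
``subject --(polarity)--> object`` with a count of supporting references.
Tables of such relations (e.g. disease -> gene targets and gene -> disease
regulators) are the raw material for building a signed regulatory network
connecting two diseases.

The quality-control rule keeps only relations with a defined polarity and
at least ``min_refs`` supporting references (default 3).  When several rows
assert the same ordered (subject, object) pair with conflicting signs, the
polarity backed by the larger summed reference count wins; an exact tie
yields an unknown polarity that QC then removes.

Gene symbols are matched case-insensitively and stored upper-case.  No
alias resolution is attempted: the analysis works at the symbol level.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"

#: polarity token -> integer sign used on network edges
POLARITY_SIGN: Mapping[str, int] = {POSITIVE: +1, NEGATIVE: -1}

REQUIRED_COLUMNS = ("subject", "object", "polarity", "ref_count")


@dataclass(frozen=True)
class Relation:
    """One signed, referenced subject -> object assertion."""

    subject: str
    object: str
    polarity: str
    relation_class: str = "regulation"
    ref_count: int = 0
    subject_kind: str = "gene"
    object_kind: str = "gene"
    sentences: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.subject == self.object:
            raise ValueError(
                f"self-relation not allowed: {self.subject!r} -> {self.object!r}"
            )
        if self.ref_count < 0:
            raise ValueError(f"ref_count must be >= 0, got {self.ref_count}")

    @property
    def sign(self) -> int:
        """+1 / -1 for defined polarity; raises for unknown."""
        return POLARITY_SIGN[self.polarity]


def _norm_polarity(token: object) -> str:
    tok = str(token).strip().lower()
    if tok in ("positive", "+", "+1", "1", "activation", "activate"):
        return POSITIVE
    if tok in ("negative", "-", "-1", "inhibition", "inhibit"):
        return NEGATIVE
    return UNKNOWN


def load_relations(path: str | Path) -> list[Relation]:
    """Read a tab-delimited relation table into a list of :class:`Relation`.

    Required columns: ``subject``, ``object``, ``polarity``, ``ref_count``.
    Optional: ``subject_kind``, ``object_kind``, ``relation_class``,
    ``sentences`` (``|``-separated evidence strings).  Unrecognised polarity
    tokens are kept as ``"unknown"`` so that :func:`qc_filter` can remove
    them explicitly; they are never silently dropped at load time.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"relation table {path} is missing required column: {col!r}")
    if df.empty:
        log.warning("relation table %s contains no data rows", path)
        return []
    relations: list[Relation] = []
    for row in df.itertuples(index=False):
        sentences: tuple[str, ...] = ()
        if "sentences" in df.columns:
            raw = getattr(row, "sentences", "")
            if raw:
                sentences = tuple(s for s in str(raw).split("|") if s)
        relations.append(
            Relation(
                subject=str(row.subject).strip().upper(),
                object=str(row.object).strip().upper(),
                polarity=_norm_polarity(row.polarity),
                relation_class=str(getattr(row, "relation_class", "regulation")) or "regulation",
                ref_count=int(row.ref_count),
                subject_kind=str(getattr(row, "subject_kind", "gene")) or "gene",
                object_kind=str(getattr(row, "object_kind", "gene")) or "gene",
                sentences=sentences,
            )
        )
    return relations


def write_relations(relations: Iterable[Relation], path: str | Path) -> None:
    """Serialize relations to the tab-delimited dialect read by :func:`load_relations`."""
    rows = [
        {
            "subject": r.subject,
            "subject_kind": r.subject_kind,
            "object": r.object,
            "object_kind": r.object_kind,
            "polarity": r.polarity,
            "relation_class": r.relation_class,
            "ref_count": r.ref_count,
            "sentences": "|".join(r.sentences),
        }
        for r in relations
    ]
    pd.DataFrame(
        rows,
        columns=[
            "subject",
            "subject_kind",
            "object",
            "object_kind",
            "polarity",
            "relation_class",
            "ref_count",
            "sentences",
        ],
    ).to_csv(path, sep="\t", index=False)


def qc_filter(relations: Sequence[Relation], min_refs: int = 3) -> list[Relation]:
    """Keep relations with defined polarity and >= ``min_refs`` references.

    Order is preserved; the operation is idempotent.
    """
    if min_refs < 1:
        raise ValueError(f"min_refs must be >= 1, got {min_refs}")
    return [
        r
        for r in relations
        if r.polarity in POLARITY_SIGN and r.ref_count >= min_refs
    ]


def aggregate_relations(relations: Sequence[Relation]) -> list[Relation]:
    """Collapse duplicate (subject, object) rows into one relation each.

    Reference counts are summed per polarity; the majority polarity wins
    and carries its summed count.  An exact tie produces polarity
    ``"unknown"`` (removed by a subsequent :func:`qc_filter`).  Output is
    ordered by first appearance of the pair, making the result invariant
    to duplicate rows but stable for equal inputs.
    """
    by_pair: dict[tuple[str, str], dict[str, int]] = {}
    first: dict[tuple[str, str], Relation] = {}
    order: list[tuple[str, str]] = []
    for r in relations:
        key = (r.subject, r.object)
        if key not in by_pair:
            by_pair[key] = defaultdict(int)
            first[key] = r
            order.append(key)
        by_pair[key][r.polarity] += r.ref_count
    out: list[Relation] = []
    for key in order:
        counts = by_pair[key]
        pos, neg = counts.get(POSITIVE, 0), counts.get(NEGATIVE, 0)
        if pos > neg:
            polarity, refs = POSITIVE, pos
        elif neg > pos:
            polarity, refs = NEGATIVE, neg
        else:
            polarity, refs = UNKNOWN, pos + neg
        out.append(replace(first[key], polarity=polarity, ref_count=refs))
    return out


@dataclass
class SignedNetwork:
    """Directed graph with +1/-1 edge polarity and entity-kind node labels."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @classmethod
    def from_relations(cls, relations: Sequence[Relation]) -> "SignedNetwork":
        """Aggregate relations and build the signed graph.

        Unknown-polarity edges (including majority ties) are excluded so
        the invariant "every edge polarity is +1 or -1" holds.
        """
        net = cls()
        for r in aggregate_relations(relations):
            if r.polarity not in POLARITY_SIGN:
                continue
            net.graph.add_node(r.subject, kind=r.subject_kind)
            net.graph.add_node(r.object, kind=r.object_kind)
            net.graph.add_edge(
                r.subject, r.object, polarity=r.sign, ref_count=r.ref_count
            )
        return net

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def genes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "gene"}

    def edge_sign(self, subject: str, obj: str) -> int | None:
        data = self.graph.get_edge_data(subject, obj)
        return None if data is None else data["polarity"]

    def to_edge_table(self) -> pd.DataFrame:
        rows = [
            {"subject": u, "object": v, "polarity": d["polarity"], "ref_count": d["ref_count"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["subject", "object", "polarity", "ref_count"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_edge_table().to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass
class GeneSetsAccounting:
    """Set algebra over one disease's targets and another's regulators.

    ``obesity_targets`` maps gene -> sign of the disease_a -> gene edge;
    ``mi_regulators`` maps gene -> sign of the gene -> disease_b edge.
    """

    obesity_targets: dict[str, int]
    mi_regulators: dict[str, int]

    @property
    def shared(self) -> set[str]:
        return set(self.obesity_targets) & set(self.mi_regulators)

    @property
    def obesity_only(self) -> set[str]:
        return set(self.obesity_targets) - self.shared

    def counts(self) -> dict[str, int]:
        return {
            "obesity_targets": len(self.obesity_targets),
            "mi_regulators": len(self.mi_regulators),
            "shared": len(self.shared),
            "obesity_only": len(self.obesity_only),
        }


def account_gene_sets(
    relations: Sequence[Relation], disease_a: str, disease_b: str
) -> GeneSetsAccounting:
    """Tally targets of ``disease_a`` and regulators of ``disease_b``.

    Expects QC-filtered relations.  Only entities carried with kind
    ``"gene"`` enter the accounting.  Signs come from the aggregated
    network, so duplicate rows cannot double-count a gene.
    """
    disease_a, disease_b = disease_a.upper(), disease_b.upper()
    net = SignedNetwork.from_relations(relations)
    targets: dict[str, int] = {}
    regulators: dict[str, int] = {}
    if disease_a in net:
        for _, g, d in net.graph.out_edges(disease_a, data=True):
            if net.graph.nodes[g].get("kind") == "gene":
                targets[g] = d["polarity"]
    else:
        log.warning("disease %r absent from relation table", disease_a)
    if disease_b in net:
        for g, _, d in net.graph.in_edges(disease_b, data=True):
            if net.graph.nodes[g].get("kind") == "gene":
                regulators[g] = d["polarity"]
    else:
        log.warning("disease %r absent from relation table", disease_b)
    return GeneSetsAccounting(obesity_targets=targets, mi_regulators=regulators)


def protective_networks(
    relations: Sequence[Relation], disease_a: str, disease_b: str
) -> tuple[SignedNetwork, SignedNetwork]:
    """Extract the two cross-disease sign motifs.

    Network 1 ("inhibited promoters"): genes g with disease_a -| g and
    g -> disease_b (disease_a suppresses a promoter of disease_b — the
    sign pattern by which disease_a could slow disease_b progression).
    Network 2 ("activated inhibitors"): genes g with disease_a -> g and
    g -| disease_b.  Each network contains both diseases, the qualifying
    genes, and the two qualifying edges per gene.
    """
    disease_a, disease_b = disease_a.upper(), disease_b.upper()
    acc = account_gene_sets(relations, disease_a, disease_b)
    full = SignedNetwork.from_relations(relations)

    def build(pattern: tuple[int, int]) -> SignedNetwork:
        sub = SignedNetwork()
        for g in sorted(acc.shared):
            if (acc.obesity_targets[g], acc.mi_regulators[g]) != pattern:
                continue
            sub.graph.add_node(disease_a, kind="disease")
            sub.graph.add_node(disease_b, kind="disease")
            sub.graph.add_node(g, kind="gene")
            for u, v in ((disease_a, g), (g, disease_b)):
                d = full.graph.edges[u, v]
                sub.graph.add_edge(u, v, polarity=d["polarity"], ref_count=d["ref_count"])
        return sub

    return build((-1, +1)), build((+1, -1))
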