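"""Per-child lexico-semantic networks from feature norms.

Nodes are the nouns a child produces; an undirected edge links two nouns
that share at least ``threshold`` (default 2) perceptual and/or functional
features in the norms.  Word-level structure is degree; lexicon-level
structure is the global clustering coefficient (transitivity),
3 * triangles / connected triples, which is 1 when every connected triple
closes and 0 when none does.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("perceptual", "functional", "taxonomic", "encyclopedic")
#: Feature classes that count toward semantic links.
DEFAULT_EDGE_CLASSES = frozenset({"perceptual", "functional"})


@dataclass
class FeatureNorms:
    """concept -> {feature_id: feature_class} with class-filtered overlap."""

    features: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for concept, feats in self.features.items():
            bad = {cls for cls in feats.values()} - set(FEATURE_CLASSES)
            if bad:
                raise ValueError(f"{concept}: unknown feature classes {sorted(bad)}")

    @property
    def concepts(self) -> set[str]:
        return set(self.features)

    def feature_set(self, concept: str, classes=DEFAULT_EDGE_CLASSES) -> set[str]:
        if concept not in self.features:
            raise KeyError(f"concept not in norms: {concept!r}")
        return {f for f, c in self.features[concept].items() if c in classes}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureNorms":
        """Build from a long table with columns concept, feature, feature_class."""
        feats: dict[str, dict[str, str]] = {}
        for concept, feature, fclass in zip(
            df["concept"], df["feature"], df["feature_class"]
        ):
            feats.setdefault(concept, {})[feature] = fclass
        return cls(features=feats)

    @classmethod
    def read_csv(cls, path, sep: str = ",") -> "FeatureNorms":
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"concept": c, "feature": f, "feature_class": cls}
            for c, feats in self.features.items()
            for f, cls in feats.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SemanticNetwork:
    """Undirected simple graph over word ids (isolates kept)."""

    nodes: frozenset[str]
    edges: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"edge must join two distinct nodes: {set(e)}")
            if not e <= self.nodes:
                raise ValueError(f"edge endpoints not in node set: {set(e)}")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def edge_frame(self) -> pd.DataFrame:
        pairs = sorted(tuple(sorted(e)) for e in self.edges)
        return pd.DataFrame(pairs, columns=["word_a", "word_b"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


@dataclass(frozen=True)
class StructureMetrics:
    """One child's network summary: GCC plus per-target degree."""

    child_id: str
    gcc: float
    degree: dict[str, int]
    n_triangles: int
    n_triples: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.gcc <= 1.0:
            raise ValueError(f"gcc out of [0,1]: {self.gcc}")
        if self.n_triples == 0 and self.gcc != 0.0:
            raise ValueError("gcc must be 0 with no connected triples")


def shared_feature_count(
    a: str, b: str, norms: FeatureNorms, classes=DEFAULT_EDGE_CLASSES
) -> int:
    """Number of features of the given classes shared by concepts a and b."""
    if a == b:
        raise ValueError("shared_feature_count requires two distinct concepts")
    return len(norms.feature_set(a, classes) & norms.feature_set(b, classes))


def build_network(
    produced_nouns: set[str],
    norms: FeatureNorms,
    threshold: int = 2,
    classes=DEFAULT_EDGE_CLASSES,
    on_missing: str = "warn",
) -> SemanticNetwork:
    """Link every pair of produced nouns sharing >= threshold qualifying features.

    Nouns absent from the norms are dropped with a warning (``on_missing=
    "warn"``) or rejected (``on_missing="raise"``).  All remaining nouns are
    nodes, including isolates.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    missing = set(produced_nouns) - norms.concepts
    if missing:
        if on_missing == "raise":
            raise KeyError(f"concepts not in norms: {sorted(missing)}")
        warnings.warn(
            f"{len(missing)} produced nouns missing from norms, dropped: "
            f"{sorted(missing)[:5]}...",
            stacklevel=2,
        )
    words = sorted(set(produced_nouns) - missing)
    fsets = {w: norms.feature_set(w, classes) for w in words}
    edges = set()
    for i, a in enumerate(words):
        fa = fsets[a]
        for b in words[i + 1 :]:
            if len(fa & fsets[b]) >= threshold:
                edges.add(frozenset((a, b)))
    return SemanticNetwork(nodes=frozenset(words), edges=frozenset(edges))


def word_degree(net: SemanticNetwork, word: str) -> int:
    """Incident edge count; 0 for isolates and for words absent from the net."""
    if word not in net.nodes:
        return 0
    return sum(1 for e in net.edges if word in e)


def count_triangles_triples(net: SemanticNetwork) -> tuple[int, int]:
    """(closed triangles, connected triples).

    A connected triple is a path of length two counted once per center
    vertex, i.e. sum over nodes of C(degree, 2); a triangle is a node triple
    with all three edges (each triangle closes three triples).
    """
    g = net.to_networkx()
    tri = sum(nx.triangles(g).values()) // 3
    deg = np.array([d for _, d in g.degree()], dtype=np.int64)
    triples = int((deg * (deg - 1) // 2).sum())
    return tri, triples


def global_clustering(net: SemanticNetwork) -> float:
    """Transitivity: 3 * triangles / triples, 0 when there are no triples."""
    tri, triples = count_triangles_triples(net)
    if triples == 0:
        return 0.0
    return 3.0 * tri / triples


def compute_structure_metrics(
    child_id: str,
    produced_nouns: set[str],
    norms: FeatureNorms,
    target_words: list[str],
    threshold: int = 2,
    classes=DEFAULT_EDGE_CLASSES,
    augment_targets: bool = True,
    on_missing: str = "warn",
) -> StructureMetrics:
    """GCC over the child's produced nouns plus degree for each target word.

    Degree for a target the child does not produce is computed on the
    produced-noun network augmented with the target node and its qualifying
    edges (``augment_targets=True``, the default); with
    ``augment_targets=False`` unproduced targets get degree 0.  GCC always
    uses the produced nouns only.
    """
    net = build_network(produced_nouns, norms, threshold, classes, on_missing)
    tri, triples = count_triangles_triples(net)
    gcc = 0.0 if triples == 0 else 3.0 * tri / triples
    degree: dict[str, int] = {}
    for target in target_words:
        if target in net.nodes:
            degree[target] = word_degree(net, target)
        elif augment_targets and target in norms.concepts:
            ft = norms.feature_set(target, classes)
            degree[target] = sum(
                1
                for w in net.nodes
                if len(ft & norms.feature_set(w, classes)) >= threshold
            )
        else:
            degree[target] = 0
    return StructureMetrics(
        child_id=child_id, gcc=gcc, degree=degree, n_triangles=tri, n_triples=triples
    )


class NormsAdjacency:
    """Precomputed all-concepts adjacency for fast per-child metrics.

    Computes the shared-feature-count matrix over every concept in the norms
    once (via a boolean concept x feature incidence matrix), so per-child
    networks become submatrix lookups.  Agrees exactly with
    :func:`build_network` / :func:`compute_structure_metrics`; exists because
    cohort-scale simulation touches thousands of child networks.
    """

    def __init__(
        self,
        norms: FeatureNorms,
        threshold: int = 2,
        classes=DEFAULT_EDGE_CLASSES,
    ) -> None:
        if threshold < 1:
            raise ValueError("threshold must be >= 1")
        self.threshold = threshold
        self.concept_index = {c: i for i, c in enumerate(sorted(norms.concepts))}
        feats = sorted({f for c in norms.concepts for f in norms.feature_set(c, classes)})
        fidx = {f: j for j, f in enumerate(feats)}
        inc = np.zeros((len(self.concept_index), len(feats)), dtype=np.float32)
        for c, i in self.concept_index.items():
            for f in norms.feature_set(c, classes):
                inc[i, fidx[f]] = 1.0
        shared = inc @ inc.T
        self.adjacency = (shared >= threshold).astype(np.float32)
        np.fill_diagonal(self.adjacency, 0.0)

    def child_metrics(
        self,
        child_id: str,
        produced_nouns: set[str],
        target_words: list[str],
        augment_targets: bool = True,
    ) -> StructureMetrics:
        """Metrics identical to :func:`compute_structure_metrics`."""
        idx = np.array(
            sorted(self.concept_index[w] for w in produced_nouns if w in self.concept_index),
            dtype=np.intp,
        )
        a = self.adjacency[np.ix_(idx, idx)]
        deg = a.sum(axis=1)
        triples = int(np.round((deg * (deg - 1) / 2).sum()))
        tri = int(np.round(float((a * (a @ a)).sum()) / 6.0))
        gcc = 0.0 if triples == 0 else 3.0 * tri / triples
        pos = {j: k for k, j in enumerate(idx)}
        degree: dict[str, int] = {}
        for t in target_words:
            ti = self.concept_index.get(t)
            if ti is None:
                degree[t] = 0
            elif ti in pos:
                degree[t] = int(deg[pos[ti]])
            elif augment_targets:
                degree[t] = int(self.adjacency[ti, idx].sum())
            else:
                degree[t] = 0
        return StructureMetrics(
            child_id=child_id, gcc=gcc, degree=degree,
            n_triangles=tri, n_triples=triples,
        )


def metrics_table(metrics: list[StructureMetrics]) -> pd.DataFrame:
    """child_id, gcc, n_triangles, n_triples summary table."""
    return pd.DataFrame(
        [
            {
                "child_id": m.child_id,
                "gcc": m.gcc,
                "n_triangles": m.n_triangles,
                "n_triples": m.n_triples,
            }
            for m in metrics
        ]
    )


def degree_table(metrics: list[StructureMetrics]) -> pd.DataFrame:
    """Long table: child_id, target word, degree."""
    return pd.DataFrame(
        [
            {"child_id": m.child_id, "word": w, "degree": d}
            for m in metrics
            for w, d in m.degree.items()
        ]
    )
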