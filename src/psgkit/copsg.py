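"""Proliferation-suppressor co-occurrence network.

Genes acting in the same pathway tend to show the PS phenotype in the same
cell lines.  From a binary genes x screens call matrix, every gene pair is
tested for co-occurrence with Fisher's exact test on the 2x2 table
[both called, a only, b only, neither]; Benjamini-Hochberg-adjusted p-values
below an FDR cutoff define network edges.  Enrichment of the resulting edge
set against an external functional network is assessed by drawing random
pair samples of the same size from the tested-pair universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .mixed_z import PSGCalls


@dataclass
class BinaryCallMatrix:
    """Binary call matrix restricted to recurrently called genes."""

    calls: pd.DataFrame  # genes x screens, 0/1
    min_occurrence: int


@dataclass
class PairTest:
    """Fisher exact test of one gene pair's co-occurrence across screens."""

    gene_a: str
    gene_b: str
    table: tuple  # (both, a_only, b_only, neither)
    p_value: float
    odds_ratio: float
    fdr: float = float("nan")

    @property
    def n_cooccur(self) -> int:
        return self.table[0]


@dataclass
class CoPSNetwork:
    """Co-occurrence network: nodes, FDR-passing edges, connected components."""

    nodes: list
    edges: list  # of PairTest
    components: list  # list of frozensets of gene names
    n_tests: int
    fdr_cutoff: float
    all_tests: pd.DataFrame = field(default=None, repr=False)

    def to_edge_tsv(self, path) -> None:
        rows = [
            {
                "gene_a": e.gene_a,
                "gene_b": e.gene_b,
                "n_cooccur": e.n_cooccur,
                "p": e.p_value,
                "fdr": e.fdr,
                "odds_ratio": e.odds_ratio,
            }
            for e in self.edges
        ]
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "n_cooccur", "p", "fdr", "odds_ratio"]).to_csv(
            path, sep="\t", index=False
        )

    def to_sif(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.edges:
                fh.write(f"{e.gene_a}\tco_ps\t{e.gene_b}\n")


@dataclass
class EnrichmentResult:
    """Empirical enrichment of network edges in a reference pair set."""

    observed_overlap: int
    n_samples: int
    exceed_count: int
    empirical_p: float
    null_mean: float


def build_call_matrix(calls: PSGCalls, min_occurrence: int = 2) -> BinaryCallMatrix:
    """Drop genes called in fewer than ``min_occurrence`` screens."""
    sums = calls.calls.sum(axis=1)
    kept = calls.calls.loc[sums >= min_occurrence]
    return BinaryCallMatrix(calls=kept, min_occurrence=min_occurrence)


def pair_count(m: int) -> int:
    """Number of unordered gene pairs among m genes: m(m-1)/2."""
    if m < 2:
        raise DataError(f"need >= 2 genes to form pairs, got {m}")
    return m * (m - 1) // 2


_ALTERNATIVES = {"greater": "greater", "two_sided": "two-sided", "two-sided": "two-sided"}


def fisher_pair(a, b, alternative: str = "greater") -> PairTest:
    """Fisher exact test of co-occurrence between two binary call vectors."""
    alternative = _ALTERNATIVES[alternative]
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise DataError("call vectors differ in length")
    if a.size < 4:
        raise DataError("need >= 4 screens")
    both = int((a & b).sum())
    a_only = int((a & ~b).sum())
    b_only = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    odds, p = stats.fisher_exact([[both, a_only], [b_only, neither]], alternative=alternative)
    return PairTest(
        gene_a="a", gene_b="b", table=(both, a_only, b_only, neither),
        p_value=float(p), odds_ratio=float(odds),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_network(
    matrix: BinaryCallMatrix,
    fdr_cutoff: float = 0.001,
    alternative: str = "greater",
) -> CoPSNetwork:
    """Test all gene pairs and keep edges at BH FDR <= cutoff.

    The default one-sided "greater" alternative targets co-occurrence
    enrichment; two-sided p-values and odds ratios remain inspectable per
    pair for mutual-exclusivity analyses.
    """
    alternative = _ALTERNATIVES[alternative]
    genes = list(matrix.calls.index)
    if len(genes) < 2:
        raise DataError("need >= 2 retained genes to build a network")
    X = matrix.calls.to_numpy(dtype=bool)
    n = X.shape[1]

    # vectorized 2x2 tables for all pairs
    both = X.astype(np.int64) @ X.T.astype(np.int64)
    row = X.sum(axis=1)
    tests = []
    for i, j in combinations(range(len(genes)), 2):
        bt = int(both[i, j])
        tbl = (bt, int(row[i]) - bt, int(row[j]) - bt, n - int(row[i]) - int(row[j]) + bt)
        odds, p = stats.fisher_exact(
            [[tbl[0], tbl[1]], [tbl[2], tbl[3]]], alternative=alternative
        )
        tests.append(PairTest(genes[i], genes[j], tbl, float(p), float(odds)))

    fdr = bh_adjust([t.p_value for t in tests])
    for t, q in zip(tests, fdr):
        t.fdr = float(q)
    edges = [t for t in tests if t.fdr <= fdr_cutoff]

    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edges_from((e.gene_a, e.gene_b) for e in edges)
    components = [frozenset(c) for c in nx.connected_components(g)]
    all_tests = pd.DataFrame(
        [
            {"gene_a": t.gene_a, "gene_b": t.gene_b, "n_cooccur": t.n_cooccur,
             "p": t.p_value, "fdr": t.fdr, "odds_ratio": t.odds_ratio}
            for t in tests
        ]
    )
    return CoPSNetwork(
        nodes=genes, edges=edges, components=components,
        n_tests=len(tests), fdr_cutoff=fdr_cutoff, all_tests=all_tests,
    )


def _pair_key(a, b):
    return (a, b) if a <= b else (b, a)


def enrichment_test(
    net: CoPSNetwork,
    reference_edges,
    n_samples: int = 10000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Empirical enrichment of network edges in a reference edge set.

    Draws ``n_samples`` random sets of |edges| pairs (without replacement
    within each sample) from the tested-pair universe and counts how often a
    random set overlaps the reference at least as much as the observed edges.
    The add-one empirical p never returns 0: p = (exceed + 1)/(n + 1).
    """
    ref = {_pair_key(a, b) for a, b in reference_edges}
    universe = [
        _pair_key(a, b)
        for a, b in zip(net.all_tests["gene_a"], net.all_tests["gene_b"])
    ]
    n_edges = len(net.edges)
    if n_edges == 0:
        raise DataError("network has no edges to test")
    observed = sum(1 for e in net.edges if _pair_key(e.gene_a, e.gene_b) in ref)

    in_ref = np.fromiter((u in ref for u in universe), dtype=bool, count=len(universe))
    rng = np.random.default_rng(seed)
    exceed = 0
    overlaps = np.empty(n_samples, dtype=np.int64)
    for k in range(n_samples):
        idx = rng.choice(len(universe), size=n_edges, replace=False)
        overlaps[k] = int(in_ref[idx].sum())
    exceed = int((overlaps >= observed).sum())
    return EnrichmentResult(
        observed_overlap=observed,
        n_samples=n_samples,
        exceed_count=exceed,
        empirical_p=(exceed + 1) / (n_samples + 1),
        null_mean=float(overlaps.mean()),
    )


def read_edge_list(path) -> set:
    """Read a reference network edge list TSV (first two columns are genes)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise DataError("edge list needs >= 2 columns")
    return {_pair_key(a, b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}
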