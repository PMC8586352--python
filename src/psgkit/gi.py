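"""Dual-guide genetic-interaction (GI) screen design and scoring.

A dual-guide Cas12a library crosses a small set of query genes against a
larger array panel.  Each construct expresses two crRNAs (positions A and B);
pairing a target crRNA with crRNAs against nonessential control genes yields
accurate single-knockout fitness, and all query-guide x array-guide pairs
measure double-knockout fitness.

Interactions are scored per anchor guide i by regressing combination LFCs
y_ij on the partner guides' single-knockout LFCs x_j:

    y_hat_ij = m_i * x_j + b_i

Residuals y_ij - y_hat_ij are Z-scored within each anchor.  For a gene pair
(I, J), residual Z-scores are summed over the pair's constructs with I as
anchor and divided by sqrt(n_constructs); the same with J as anchor; the two
orientation scores are summed and divided by sqrt(2).  Positive gene-level
scores mean the double knockout is fitter than the additive expectation,
negative scores less fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

#: construct classes
SINGLE_QUERY = "single_query"
SINGLE_ARRAY = "single_array"
DOUBLE = "double"
CONTROL_CONTROL = "control_control"

#: gene label used for nonessential-targeting control crRNAs
CONTROL_GENE = "CTRL"

_DEGENERATE_SD = 1e-12


@dataclass
class GILibrary:
    """Dual-guide library: constructs plus design bookkeeping."""

    constructs: pd.DataFrame  # guide_A, guide_B, gene_A, gene_B, construct_class
    query_genes: list
    array_genes: list
    n_crRNA_per_gene: int
    n_control_crRNA: int

    @property
    def construct_ids(self) -> pd.Index:
        return self.constructs.index

    def to_tsv(self, path) -> None:
        self.constructs.to_csv(path, sep="\t", index_label="construct_id")

    @classmethod
    def from_tsv(cls, path, query_genes, array_genes, n_crRNA, n_controls) -> "GILibrary":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, list(query_genes), list(array_genes), n_crRNA, n_controls)


def _guides(gene: str, n: int) -> list[str]:
    return [f"{gene}.cr{k + 1}" for k in range(n)]


def design_library(
    query_genes, array_genes, n_crRNA: int = 3, n_controls: int = 5
) -> GILibrary:
    """Enumerate constructs for a query x array dual-guide library.

    Per target gene, n_crRNA x n_controls single-knockout constructs (query
    genes in both A and B orientations, to support the position-bias check;
    array genes in the B position).  Per query-array gene pair, n_crRNA^2
    double constructs.  Control-control constructs pair every control crRNA
    with every control crRNA.
    """
    query_genes = list(query_genes)
    array_genes = list(array_genes)
    if not query_genes or not array_genes:
        raise DataError("query and array gene lists must be non-empty")
    if n_crRNA < 1 or n_controls < 1:
        raise DataError("n_crRNA and n_controls must be >= 1")
    ctrl = _guides(CONTROL_GENE, n_controls)
    rows = []

    def add(ga, gb, gene_a, gene_b, cls):
        rows.append(
            {"guide_A": ga, "guide_B": gb, "gene_A": gene_a, "gene_B": gene_b,
             "construct_class": cls}
        )

    for q in query_genes:
        for g in _guides(q, n_crRNA):
            for c in ctrl:
                add(g, c, q, CONTROL_GENE, SINGLE_QUERY)  # query in A
                add(c, g, CONTROL_GENE, q, SINGLE_QUERY)  # query in B
    for a in array_genes:
        if a in query_genes:
            continue  # already covered in both orientations as a query gene
        for g in _guides(a, n_crRNA):
            for c in ctrl:
                add(c, g, CONTROL_GENE, a, SINGLE_ARRAY)
    for q in query_genes:
        for a in array_genes:
            for gq in _guides(q, n_crRNA):
                for ga in _guides(a, n_crRNA):
                    add(gq, ga, q, a, DOUBLE)
    for c1 in ctrl:
        for c2 in ctrl:
            add(c1, c2, CONTROL_GENE, CONTROL_GENE, CONTROL_CONTROL)

    df = pd.DataFrame(rows)
    df.index = [f"c{i:06d}" for i in range(len(df))]
    return GILibrary(df, query_genes, array_genes, n_crRNA, n_controls)


@dataclass
class SingleKOFitness:
    """Mean single-knockout LFC and its Z against control-control constructs."""

    gene: str
    mean_lfc: float
    z: float
    n_constructs: int


def _check_lfc(lfc: pd.Series, lib: GILibrary) -> pd.Series:
    missing = lib.constructs.index.difference(lfc.index)
    if len(missing) > 0:
        raise DataError(f"{len(missing)} constructs missing LFCs, e.g. {missing[0]!r}")
    return lfc.loc[lib.constructs.index]


def single_ko_fitness(lfc: pd.Series, lib: GILibrary) -> list[SingleKOFitness]:
    """Per-gene mean single-KO LFC, standardized against control constructs."""
    lfc = _check_lfc(lfc, lib)
    cons = lib.constructs
    ctrl_lfc = lfc[cons["construct_class"] == CONTROL_CONTROL]
    if ctrl_lfc.empty:
        raise DataError("library has no control_control constructs")
    mu0, sd0 = float(ctrl_lfc.mean()), float(ctrl_lfc.std(ddof=0))
    singles = cons[cons["construct_class"].isin([SINGLE_QUERY, SINGLE_ARRAY])]
    target = singles["gene_A"].where(singles["gene_A"] != CONTROL_GENE, singles["gene_B"])
    out = []
    for gene, grp in lfc[singles.index].groupby(target):
        m = float(grp.mean())
        out.append(
            SingleKOFitness(
                gene=gene, mean_lfc=m,
                z=(m - mu0) / sd0 if sd0 > 0 else 0.0,
                n_constructs=len(grp),
            )
        )
    return out


def position_bias(lfc: pd.Series, lib: GILibrary) -> dict:
    """Compare query-gene single-KO LFC in the A vs B vector position.

    Returns per-gene means in each position, their Pearson correlation, and
    the mean signed difference (A minus B); a position-neutral library gives
    a difference near 0 and a high correlation.
    """
    lfc = _check_lfc(lfc, lib)
    cons = lib.constructs
    sq = cons[cons["construct_class"] == SINGLE_QUERY]
    rows = []
    for gene in lib.query_genes:
        in_a = sq[(sq["gene_A"] == gene)].index
        in_b = sq[(sq["gene_B"] == gene)].index
        if len(in_a) == 0 or len(in_b) == 0:
            raise DataError(f"query gene {gene} lacks constructs in both positions")
        rows.append(
            {"gene": gene, "mean_lfc_A": float(lfc[in_a].mean()),
             "mean_lfc_B": float(lfc[in_b].mean())}
        )
    table = pd.DataFrame(rows).set_index("gene")
    diff = table["mean_lfc_A"] - table["mean_lfc_B"]
    if len(table) > 1 and table["mean_lfc_A"].std() > 0 and table["mean_lfc_B"].std() > 0:
        corr = float(np.corrcoef(table["mean_lfc_A"], table["mean_lfc_B"])[0, 1])
    else:
        corr = float("nan")
    return {"table": table, "pearson_r": corr, "mean_signed_difference": float(diff.mean())}


@dataclass
class AnchorFit:
    """Per-anchor-guide OLS of combination LFC on partner single-guide LFC."""

    anchor_guide: str
    slope: float
    intercept: float
    partner_guides: list
    residuals: np.ndarray
    degenerate: bool = False


def anchor_regression(anchor: str, pairs) -> AnchorFit:
    """OLS (with intercept) of combo LFC on partner single-KO LFC.

    ``pairs`` is a sequence of (partner_guide, x, y).  With fewer than 3
    partners or zero variance in x the fit is degenerate: slope 0, intercept
    at the mean, residuals flagged.
    """
    partners = [p for p, _, _ in pairs]
    x = np.array([v for _, v, _ in pairs], dtype=float)
    y = np.array([v for _, _, v in pairs], dtype=float)
    if x.size < 3:
        raise DataError(f"anchor {anchor}: need >= 3 partners, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError(f"anchor {anchor}: non-finite partner data")
    if np.ptp(x) == 0:
        m, b = 0.0, float(y.mean())
        return AnchorFit(anchor, m, b, partners, y - b, degenerate=True)
    A = np.column_stack([x, np.ones_like(x)])
    (m, b), *_ = np.linalg.lstsq(A, y, rcond=None)
    return AnchorFit(anchor, float(m), float(b), partners, y - (m * x + b))


def zscore_residuals(fit: AnchorFit) -> pd.Series:
    """Z-score residuals within one anchor guide (population s.d.).

    Anchors with (near-)zero residual spread contribute all-zero Z-scores so
    that perfectly additive data yields no interaction signal.
    """
    r = fit.residuals
    sd = float(np.std(r))
    if sd < _DEGENERATE_SD:
        z = np.zeros_like(r)
    else:
        z = (r - r.mean()) / sd
    return pd.Series(z, index=pd.Index(fit.partner_guides, name="partner_guide"),
                     name=fit.anchor_guide)


def guide_single_lfc(lfc: pd.Series, lib: GILibrary) -> pd.Series:
    """Single-knockout LFC of each targeting guide.

    Estimated as the mean LFC of the guide's pairings with nonessential
    control crRNAs (its single-KO constructs), pooling both orientations for
    query guides.
    """
    lfc = _check_lfc(lfc, lib)
    cons = lib.constructs
    singles = cons[cons["construct_class"].isin([SINGLE_QUERY, SINGLE_ARRAY])]
    guide = singles["guide_A"].where(
        singles["gene_A"] != CONTROL_GENE, singles["guide_B"]
    )
    return lfc[singles.index].groupby(guide).mean()


@dataclass
class GIPairScore:
    """Gene-level genetic-interaction score for one gene pair."""

    gene_I: str
    gene_J: str
    score_I_anchor: float
    score_J_anchor: float
    combined_z: float
    n_constructs: int
    flags: list = field(default_factory=list)


def score_gi(lfc: pd.Series, lib: GILibrary) -> list[GIPairScore]:
    """Full GI scoring pipeline for every query-array gene pair.

    Fits an anchor regression for every guide appearing in double constructs,
    Z-scores residuals within anchors, then aggregates per gene pair and
    orientation.
    """
    lfc = _check_lfc(lfc, lib)
    x_guide = guide_single_lfc(lfc, lib)
    doubles = lib.constructs[lib.constructs["construct_class"] == DOUBLE]

    # per anchor guide: (partner guide, x_partner, y) triples over its doubles
    anchor_data: dict[str, list] = {}
    for cid, row in doubles.iterrows():
        y = float(lfc[cid])
        for anchor, partner in (
            (row["guide_A"], row["guide_B"]),
            (row["guide_B"], row["guide_A"]),
        ):
            if partner not in x_guide.index:
                continue
            anchor_data.setdefault(anchor, []).append(
                (cid, partner, float(x_guide[partner]), y)
            )

    # residual Z per (anchor guide, construct)
    zmap: dict[tuple[str, str], float] = {}
    for anchor, rows in anchor_data.items():
        if len(rows) < 3:
            continue
        fit = anchor_regression(anchor, [(cid, x, y) for cid, _, x, y in rows])
        z = zscore_residuals(fit)
        for (cid, _, _, _), zv in zip(rows, z.to_numpy()):
            zmap[(anchor, cid)] = float(zv)

    guides_of = {
        g: _guides(g, lib.n_crRNA_per_gene)
        for g in set(lib.query_genes) | set(lib.array_genes)
    }

    scores = []
    for (gi_gene, gj_gene), grp in doubles.groupby(["gene_A", "gene_B"], sort=False):
        flags = []

        def orientation_score(anchor_gene, partner_gene):
            zs = []
            anchors = set(guides_of[anchor_gene])
            partners = set(guides_of[partner_gene])
            for cid, row in grp.iterrows():
                for a, p in (
                    (row["guide_A"], row["guide_B"]),
                    (row["guide_B"], row["guide_A"]),
                ):
                    if a in anchors and p in partners and (a, cid) in zmap:
                        zs.append(zmap[(a, cid)])
            if not zs:
                return None, 0
            return sum(zs) / np.sqrt(len(zs)), len(zs)

        s_i, n_i = orientation_score(gi_gene, gj_gene)
        s_j, n_j = orientation_score(gj_gene, gi_gene)
        present = [s for s in (s_i, s_j) if s is not None]
        if not present:
            flags.append("no scored constructs")
            combined = float("nan")
        elif len(present) == 1:
            flags.append("single orientation only")
            combined = present[0]
        else:
            combined = (s_i + s_j) / np.sqrt(2.0)
        scores.append(
            GIPairScore(
                gene_I=gi_gene, gene_J=gj_gene,
                score_I_anchor=s_i if s_i is not None else float("nan"),
                score_J_anchor=s_j if s_j is not None else float("nan"),
                combined_z=combined, n_constructs=len(grp), flags=flags,
            )
        )
    return scores


def gene_gi_score(residual_z: pd.DataFrame, lib: GILibrary, pair) -> GIPairScore:
    """Aggregate precomputed residual Z-scores for one gene pair.

    ``residual_z`` has columns anchor_guide, partner_guide, z, one row per
    (anchor, double-construct) observation.  Per orientation, Z-scores whose
    anchor targets one gene of the pair and partner the other are summed and
    divided by sqrt(count); the orientation scores are summed and divided by
    sqrt(2).  A missing orientation is flagged and the available one returned
    unscaled by sqrt(2).
    """
    gene_i, gene_j = pair
    gi = set(_guides(gene_i, lib.n_crRNA_per_gene))
    gj = set(_guides(gene_j, lib.n_crRNA_per_gene))

    def orient(anchors, partners):
        sel = residual_z[
            residual_z["anchor_guide"].isin(anchors)
            & residual_z["partner_guide"].isin(partners)
        ]
        if sel.empty:
            return None, 0
        return float(sel["z"].sum() / np.sqrt(len(sel))), len(sel)

    s_i, n_i = orient(gi, gj)
    s_j, n_j = orient(gj, gi)
    flags = []
    present = [s for s in (s_i, s_j) if s is not None]
    if not present:
        raise DataError(f"pair {pair}: no residual Z-scores in either orientation")
    if len(present) == 1:
        flags.append("single orientation only")
        combined = present[0]
    else:
        combined = (s_i + s_j) / np.sqrt(2.0)
    return GIPairScore(
        gene_I=gene_i, gene_J=gene_j,
        score_I_anchor=s_i if s_i is not None else float("nan"),
        score_J_anchor=s_j if s_j is not None else float("nan"),
        combined_z=combined, n_constructs=n_i + n_j, flags=flags,
    )


def gi_table(scores: list[GIPairScore]) -> pd.DataFrame:
    """Tidy gene-level GI score table."""
    return pd.DataFrame(
        [
            {"gene_I": s.gene_I, "gene_J": s.gene_J, "combined_z": s.combined_z,
             "score_I_anchor": s.score_I_anchor, "score_J_anchor": s.score_J_anchor,
             "n_constructs": s.n_constructs, "flags": ";".join(s.flags)}
            for s in scores
        ]
    )
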