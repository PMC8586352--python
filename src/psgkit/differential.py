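"""Differential coessentiality: group-specific changes in correlation.

Two genes whose knockout-fitness profiles correlate across screens are likely
co-functional.  When a pathway is rewired in a specific cell-line group, the
pair's Pearson correlation inside the group departs from its correlation in
the remaining screens.  The differential Pearson correlation coefficient

    dPCC(a, b) = PCC_in_group(a, b) - PCC_outside(a, b)

is scored against a per-pair permutation null built by repeatedly drawing
random pseudo-groups of the same size, with a sign-dependent tail (right for
positive dPCC, left for negative).  Candidate partners of a seed clique are
genes with a significant dPCC to a clique member and a strong knockout
phenotype somewhere in the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .mixed_z import MixedZMatrix
from .screen_io import LFCTable, ReferenceSets


@dataclass
class QualityReport:
    """Per-screen quality: essential/nonessential separation and recall."""

    screen: str
    cohens_d: float
    essential_recall: float
    passed: bool


def _screen_quality(lfc: pd.Series, refs: ReferenceSets, precision=0.9):
    ess = lfc.loc[lfc.index.isin(refs.essential)]
    non = lfc.loc[lfc.index.isin(refs.nonessential)]
    if len(ess) < 10 or len(non) < 10:
        raise DataError(
            f"fewer than 10 reference genes present (essential {len(ess)}, "
            f"nonessential {len(non)})"
        )
    pooled = np.sqrt((ess.var(ddof=1) + non.var(ddof=1)) / 2.0)
    d = float((non.mean() - ess.mean()) / pooled) if pooled > 0 else 0.0

    # Recall of essentials at the LFC cutoff where precision (vs nonessentials)
    # reaches `precision`, walking cutoffs from the most negative LFC upward.
    vals = np.concatenate([ess.to_numpy(), non.to_numpy()])
    is_ess = np.concatenate([np.ones(len(ess), bool), np.zeros(len(non), bool)])
    order = np.argsort(vals, kind="mergesort")  # ascending: most depleted first
    tp = np.cumsum(is_ess[order])
    fp = np.cumsum(~is_ess[order])
    prec = tp / (tp + fp)
    ok = prec >= precision
    recall = float(tp[ok].max() / len(ess)) if ok.any() else 0.0
    return d, recall


def quality_filter(
    gene_lfc: LFCTable,
    refs: ReferenceSets,
    d_min: float = 2.5,
    recall_min: float = 0.6,
) -> list[QualityReport]:
    """Flag low-quality screens: Cohen's D <= d_min or essential recall <= recall_min.

    Cohen's D is (mean nonessential LFC - mean essential LFC) / pooled s.d.,
    with the pooled s.d. the root of the average of the two variances.  A
    screen passes only with D strictly above ``d_min`` and recall strictly
    above ``recall_min``.
    """
    if not refs.essential or not refs.nonessential:
        raise DataError("essential and nonessential sets must be non-empty")
    reports = []
    for screen in gene_lfc.values.columns:
        d, recall = _screen_quality(gene_lfc.values[screen], refs)
        reports.append(
            QualityReport(
                screen=screen, cohens_d=d, essential_recall=recall,
                passed=(d > d_min and recall > recall_min),
            )
        )
    return reports


@dataclass
class DPCCResult:
    """Per-pair correlations inside/outside the group and their difference."""

    gene_a: str
    gene_b: str
    pcc_in: float
    pcc_out: float
    dpcc: float
    p_value: float = float("nan")
    valid: bool = True


@dataclass
class NullDistribution:
    """Per-pair null dPCC samples from random pseudo-groups."""

    pairs: list  # list of (gene_a, gene_b)
    samples: np.ndarray  # n_pairs x n_reps
    n_reps: int
    seed: int | None


def _split_corr(Z: np.ndarray, in_group: np.ndarray):
    """Correlation matrices within the group columns and their complement.

    Rows with zero variance in a partition produce NaN correlations there.
    """
    def corr(M):
        M = M - M.mean(axis=1, keepdims=True)
        sd = np.sqrt((M**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            C = (M @ M.T) / np.outer(sd, sd)
        C[:, sd == 0] = np.nan
        C[sd == 0, :] = np.nan
        return C

    return corr(Z[:, in_group]), corr(Z[:, ~in_group])


def compute_dpcc(
    zm: MixedZMatrix, group, gene_subset=None
) -> list[DPCCResult]:
    """dPCC for all unordered gene pairs: PCC within ``group`` minus PCC outside.

    ``group`` is an iterable of screen names.  Pairs involving a gene with
    zero variance in either partition are flagged invalid and carry NaN
    correlations; they are excluded from the permutation stage.
    """
    Z = zm.z if gene_subset is None else zm.z.loc[list(gene_subset)]
    in_group = Z.columns.isin(set(group))
    if in_group.sum() < 3 or (~in_group).sum() < 3:
        raise DataError("group and complement must each contain >= 3 screens")
    genes = list(Z.index)
    cin, cout = _split_corr(Z.to_numpy(dtype=float), in_group)
    results = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            pin, pout = cin[i, j], cout[i, j]
            valid = np.isfinite(pin) and np.isfinite(pout)
            results.append(
                DPCCResult(
                    gene_a=genes[i], gene_b=genes[j],
                    pcc_in=float(pin), pcc_out=float(pout),
                    dpcc=float(pin - pout) if valid else float("nan"),
                    valid=bool(valid),
                )
            )
    return results


def permutation_null(
    zm: MixedZMatrix,
    group_size: int,
    n_reps: int = 1000,
    seed: int | None = None,
    gene_subset=None,
) -> NullDistribution:
    """Per-pair null dPCC from random groups of ``group_size`` screens.

    Each repetition draws ``group_size`` screens without replacement, splits
    the panel, and records dPCC for every gene pair.  Deterministic given
    ``seed``.
    """
    Z = zm.z if gene_subset is None else zm.z.loc[list(gene_subset)]
    n_screens = Z.shape[1]
    if not (3 <= group_size <= n_screens - 3):
        raise DataError("group_size must leave >= 3 screens on each side")
    if n_reps < 100:
        warnings.warn("n_reps < 100 gives unstable tail estimates", stacklevel=2)
    genes = list(Z.index)
    iu = np.triu_indices(len(genes), k=1)
    pairs = [(genes[i], genes[j]) for i, j in zip(*iu)]
    M = Z.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    samples = np.empty((len(pairs), n_reps))
    for r in range(n_reps):
        sel = np.zeros(n_screens, dtype=bool)
        sel[rng.choice(n_screens, size=group_size, replace=False)] = True
        cin, cout = _split_corr(M, sel)
        samples[:, r] = (cin - cout)[iu]
    return NullDistribution(pairs=pairs, samples=samples, n_reps=n_reps, seed=seed)


def empirical_p(observed_dpcc: float, null_samples) -> float:
    """Sign-dependent add-one permutation p-value for one pair.

    Right-tailed for positive dPCC, left-tailed for negative; exactly zero
    dPCC returns 1.
    """
    s = np.asarray(null_samples, dtype=float)
    if s.size == 0:
        raise DataError("empty null distribution")
    if observed_dpcc > 0:
        k = int((s >= observed_dpcc).sum())
    elif observed_dpcc < 0:
        k = int((s <= observed_dpcc).sum())
    else:
        return 1.0
    return (1 + k) / (s.size + 1)


def attach_pvalues(results: list[DPCCResult], null: NullDistribution) -> list[DPCCResult]:
    """Fill p_value on each valid DPCCResult from its matching null."""
    idx = {p: i for i, p in enumerate(null.pairs)}
    for r in results:
        if not r.valid:
            continue
        key = (r.gene_a, r.gene_b)
        if key not in idx:
            key = (r.gene_b, r.gene_a)
        row = null.samples[idx[key]]
        r.p_value = empirical_p(r.dpcc, row[np.isfinite(row)])
    return results


def select_candidates(
    dpcc_results: list[DPCCResult],
    zm: MixedZMatrix,
    clique_genes,
    p_max: float = 0.001,
    z_min: float = 5.0,
) -> list[str]:
    """Genes tied to the seed clique by a significant group-specific rewiring.

    A gene qualifies if it pairs with a clique member at p < ``p_max`` and has
    |mixed Z| > ``z_min`` in at least one screen.  Clique genes themselves are
    always included.
    """
    clique = set(clique_genes)
    missing = clique - set(zm.z.index)
    if missing:
        raise DataError(f"clique genes absent from Z matrix: {sorted(missing)}")
    max_abs_z = zm.z.abs().max(axis=1)
    selected = set(clique)
    for r in dpcc_results:
        if not r.valid or not np.isfinite(r.p_value) or r.p_value >= p_max:
            continue
        for gene, partner in ((r.gene_a, r.gene_b), (r.gene_b, r.gene_a)):
            if partner in clique and gene not in clique:
                if gene in max_abs_z.index and max_abs_z[gene] > z_min:
                    selected.add(gene)
    return sorted(selected)


def dpcc_table(results: list[DPCCResult]) -> pd.DataFrame:
    """Tidy table of dPCC results (one row per unordered pair)."""
    return pd.DataFrame(
        [
            {"gene_a": r.gene_a, "gene_b": r.gene_b, "pcc_in": r.pcc_in,
             "pcc_out": r.pcc_out, "dpcc": r.dpcc, "p": r.p_value, "valid": r.valid}
            for r in results
        ]
    )
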