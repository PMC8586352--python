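"""Mixed Z-scores: per-screen Gaussian-mixture outlier scoring of gene LFCs.

A typical knockout screen's LFC distribution has a dominant null-phenotype
peak near zero and a long negative tail of essential genes.  A two-component
Gaussian mixture separates these populations; the higher-mean ("null")
component supplies a screen-specific location and scale, and every gene is
scored as

    Z = (x - mu_high) / sigma_high

where x is the gene's mean LFC.  Negative Z indicates essentiality, large
positive Z a proliferation-suppressor (PS) phenotype.  Standardizing against
the null component normalizes the wide screen-to-screen variance differences
seen across large screen panels, which is what makes outlier calls comparable
between screens.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import DataError, DegenerateInputError
from .screen_io import LFCTable, ReferenceSets

logger = logging.getLogger(__name__)

#: Z cutoff at which tumor-suppressor precision reaches 90% (10% FDR) on the
#: large public screen panel; recomputable on any panel via evaluate_threshold.
PSG_Z_THRESHOLD_10FDR = 3.83

_SIGMA_FLOOR = 1e-6
_MEAN_TIE_TOL = 1e-9
_MIN_VALUES = 50


@dataclass
class MixtureFit:
    """EM fit of a two-component Gaussian mixture, components labeled by mean."""

    mu_low: float
    sigma_low: float
    mu_high: float
    sigma_high: float
    weight_low: float
    weight_high: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(repr=False, default=None)
    reason: str = ""


def _loglik(x, mu, sigma, w):
    # log p(x) under the mixture, via logsumexp over components
    comp = (
        np.log(w)[None, :]
        - 0.5 * np.log(2 * np.pi)
        - np.log(sigma)[None, :]
        - 0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
    )
    return logsumexp(comp, axis=1)


def fit_mixture(
    values,
    max_iter: int = 1000,
    tol: float = 1e-8,
    init: str = "moments",
    random_state: int | None = None,
    n_restarts: int = 0,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture by EM.

    The default initialization is deterministic (moment-based): component
    means at the 10th and 60th percentiles, both variances at the sample
    variance, equal weights.  ``init="random"`` draws seeded random restarts
    instead and keeps the best log-likelihood.

    Raises ``DegenerateInputError`` for zero-variance input; returns a fit
    with ``converged=False`` (never an exception) when EM fails to converge
    within ``max_iter`` or the two component means are indistinguishable.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < _MIN_VALUES:
        raise DataError(f"need >= {_MIN_VALUES} finite values, got {x.size}")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise DegenerateInputError("zero-variance input")

    if init == "moments":
        inits = [(np.percentile(x, [10.0, 60.0]), np.full(2, max(np.var(x), _SIGMA_FLOOR**2)))]
    elif init == "random":
        rng = np.random.default_rng(random_state)
        inits = [
            (rng.choice(x, size=2, replace=False), np.full(2, max(np.var(x), _SIGMA_FLOOR**2)))
            for _ in range(max(1, n_restarts))
        ]
    else:
        raise ValueError(f"unknown init {init!r}")

    best = None
    for mu0, var0 in inits:
        fit = _em(x, np.array(mu0, dtype=float), np.array(var0, dtype=float), max_iter, tol)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def _em(x, mu, var, max_iter, tol):
    w = np.array([0.5, 0.5])
    sigma = np.sqrt(var)
    trace = []
    ll_prev = -np.inf
    converged = False
    n_iter = 0
    reason = ""
    for n_iter in range(1, max_iter + 1):
        # E-step: responsibilities in log space
        log_comp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi)
            - np.log(sigma)[None, :]
            - 0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
        )
        norm = logsumexp(log_comp, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(log_comp - norm[:, None])

        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-300):
            converged = True
            break
        ll_prev = ll

        # M-step
        nk = resp.sum(axis=0)
        if (nk <= 0).any():
            reason = "empty component"
            break
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(np.maximum(var, _SIGMA_FLOOR**2))
        if (sigma <= _SIGMA_FLOOR).any():
            reason = "component variance collapsed"
            break

    if not converged and not reason:
        reason = f"no convergence in {max_iter} iterations"
    order = np.argsort(mu)  # low, high by mean
    lo, hi = order[0], order[1]
    if abs(mu[hi] - mu[lo]) < _MEAN_TIE_TOL:
        converged = False
        reason = "component means indistinguishable"
    return MixtureFit(
        mu_low=float(mu[lo]),
        sigma_low=float(sigma[lo]),
        mu_high=float(mu[hi]),
        sigma_high=float(sigma[hi]),
        weight_low=float(w[lo]),
        weight_high=float(w[hi]),
        loglik=float(trace[-1]),
        n_iter=n_iter,
        converged=converged,
        loglik_trace=np.asarray(trace),
        reason=reason if not converged else "",
    )


def score_mixed_z(gene_lfc, fit: MixtureFit):
    """Mixed Z-score of a gene-level LFC against a converged mixture fit."""
    if not fit.converged:
        raise DataError(f"mixture fit not converged: {fit.reason}")
    return (np.asarray(gene_lfc, dtype=float) - fit.mu_high) / fit.sigma_high


@dataclass
class MixedZMatrix:
    """Genes x screens mixed Z-scores plus per-screen fit metadata."""

    z: pd.DataFrame
    fits: dict  # screen -> MixtureFit (converged only)
    excluded_screens: dict = field(default_factory=dict)  # screen -> reason

    def __post_init__(self) -> None:
        if not np.isfinite(self.z.to_numpy(dtype=float)).all():
            raise DataError("mixed Z matrix contains non-finite values")

    def to_tsv(self, path) -> None:
        self.z.to_csv(path, sep="\t", index_label="gene")

    def fit_metadata(self) -> dict:
        out = {}
        for screen, f in self.fits.items():
            out[screen] = {
                k: getattr(f, k)
                for k in (
                    "mu_low", "sigma_low", "mu_high", "sigma_high",
                    "weight_low", "weight_high", "loglik", "n_iter", "converged",
                )
            }
        return out


def score_panel(
    guide_lfc: LFCTable,
    gene_lfc: LFCTable,
    max_iter: int = 1000,
    tol: float = 1e-8,
    fit_level: str = "guide",
) -> MixedZMatrix:
    """Fit the mixture per screen and score every gene's mean LFC.

    By default the mixture is fitted on guide-level LFCs (the fuller sample of
    the screen's noise structure) and applied to gene-level means; set
    ``fit_level="gene"`` to fit on the gene-level distribution instead.
    Screens whose fit does not converge, or is degenerate, are excluded and
    listed with a reason rather than scored.
    """
    if list(guide_lfc.values.columns) != list(gene_lfc.values.columns):
        raise DataError("guide- and gene-level tables must cover the same screens")
    fit_table = guide_lfc if fit_level == "guide" else gene_lfc
    cols = {}
    fits = {}
    excluded = {}
    for screen in gene_lfc.values.columns:
        try:
            fit = fit_mixture(fit_table.values[screen].to_numpy(), max_iter=max_iter, tol=tol)
        except DataError as exc:
            excluded[screen] = str(exc)
            continue
        if not fit.converged:
            excluded[screen] = fit.reason
            continue
        fits[screen] = fit
        cols[screen] = score_mixed_z(gene_lfc.values[screen].to_numpy(), fit)
    if excluded:
        logger.warning("excluded %d/%d screens: %s", len(excluded),
                       gene_lfc.values.shape[1], excluded)
    z = pd.DataFrame(cols, index=gene_lfc.values.index)
    return MixedZMatrix(z=z, fits=fits, excluded_screens=excluded)


@dataclass
class PSGCalls:
    """Binary proliferation-suppressor calls at a fixed Z threshold."""

    calls: pd.DataFrame  # genes x screens, int 0/1
    z_threshold: float
    fdr_label: str = ""


def call_psg(zm: MixedZMatrix, z_threshold: float = PSG_Z_THRESHOLD_10FDR) -> PSGCalls:
    """Call PS genes at Z >= threshold (inclusive)."""
    if not np.isfinite(z_threshold):
        raise DataError("z_threshold must be finite")
    calls = (zm.z >= z_threshold).astype(int)
    label = "10% FDR" if z_threshold == PSG_Z_THRESHOLD_10FDR else ""
    return PSGCalls(calls=calls, z_threshold=float(z_threshold), fdr_label=label)


@dataclass
class ThresholdReport:
    """Precision/recall curve over pooled gene x screen observations.

    ``recall`` is a count of true-positive (TSG) observations at or above each
    cutoff, not a fraction: there is no expectation that every tumor
    suppressor shows the PS phenotype in any screen, so the size of the
    recoverable set is unknown.
    """

    curve: pd.DataFrame  # columns z_cutoff, precision, recall_count
    chosen_z: float
    precision_target: float


def evaluate_threshold(
    zm: MixedZMatrix, refs: ReferenceSets, precision_target: float = 0.9
) -> ThresholdReport:
    """Choose the smallest Z cutoff reaching the target precision.

    All gene x screen observations are pooled and ranked by Z descending.
    Precision is computed over reference-set observations only: true positives
    are tumor-suppressor genes, false positives oncogenes and nonessentials;
    observations of unannotated genes are ignored.
    """
    if not refs.tsg or not refs.false_positive:
        raise DataError("tsg and oncogene/nonessential sets must be non-empty")
    genes = zm.z.index
    is_tp = genes.isin(refs.tsg)
    is_fp = genes.isin(refs.false_positive)
    keep = is_tp | is_fp
    if not keep.any():
        raise DataError("no reference genes present in the Z matrix")
    zvals = zm.z.values[keep.nonzero()[0], :].ravel()
    labels = np.repeat(is_tp[keep.nonzero()[0]], zm.z.shape[1])

    order = np.argsort(-zvals, kind="mergesort")
    zs = zvals[order]
    tp = np.cumsum(labels[order])
    fp = np.cumsum(~labels[order])
    precision = tp / (tp + fp)
    curve = pd.DataFrame({"z_cutoff": zs, "precision": precision, "recall_count": tp})
    # collapse ties: keep last row of each distinct cutoff
    curve = curve.groupby("z_cutoff", sort=False).last().reset_index()

    ok = curve["precision"] >= precision_target
    if ok.any():
        chosen = float(curve.loc[ok, "z_cutoff"].min())
    else:
        warnings.warn(f"precision target {precision_target} unreachable", stacklevel=2)
        chosen = float("inf")
    return ThresholdReport(curve=curve, chosen_z=chosen, precision_target=precision_target)
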