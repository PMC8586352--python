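"""Seeded synthetic screens with the statistical structure the analyses assume.

The panel generator emulates the features of large knockout-screen compendia
that the scoring machinery relies on: a dominant null-phenotype population,
a negative essential component, per-screen heterogeneity of LFC spread, and
sparse screen-specific positive (proliferation-suppressor) effects organized
into co-occurring gene modules.  The GI generator produces a dual-guide
library whose double-knockout LFCs are additive in the single-guide effects
except for planted interaction terms.  Every generator is a pure function of
its config and seed and ships truth labels alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gi as gi_mod
from .errors import DataError
from .screen_io import GuideMap, LFCTable


@dataclass(frozen=True)
class PSGModule:
    """A set of genes acting as proliferation suppressors in a set of screens."""

    genes: tuple
    screens: tuple  # screen indices
    effect_lfc: float  # positive; in units of the screen's null sigma by default


@dataclass
class PanelConfig:
    """Configuration of a synthetic guide-level LFC panel.

    Defaults describe a modest screen panel: 1200 genes x 4 guides across 40
    screens, 15% essential genes centred at -4 LFC, per-screen null scale
    drawn uniformly from 0.2-1.0 (the variance heterogeneity that motivates
    mixture standardization), and two disjoint 5-gene PS modules, each active
    in 12 screens with an effect of +5 null-sigma.
    """

    n_genes: int = 1200
    n_guides_per_gene: int = 4
    n_screens: int = 40
    essential_fraction: float = 0.15
    essential_mean_lfc: float = -4.0
    null_sigma_range: tuple = (0.2, 1.0)
    psg_modules: list = None  # list of PSGModule; None -> default two modules
    effect_in_sigma_units: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.essential_fraction <= 1:
            raise DataError("essential_fraction must lie in [0, 1]")
        lo, hi = self.null_sigma_range
        if lo <= 0 or hi < lo:
            raise DataError("null_sigma_range must be positive and ordered")


@dataclass
class PanelTruth:
    """Generating truth for a synthetic panel."""

    psg: pd.DataFrame  # genes x screens bool, planted PS effect present
    essential_genes: frozenset
    sigma: pd.Series  # per-screen generating null sigma
    guide_map: GuideMap
    modules: list


def _default_modules(gene_names, essential, n_screens, rng) -> list[PSGModule]:
    pool = [g for g in gene_names if g not in essential]
    genes = rng.choice(pool, size=10, replace=False)
    screens = rng.permutation(n_screens)
    k = min(12, n_screens // 3)
    return [
        PSGModule(tuple(genes[:5]), tuple(int(s) for s in screens[:k]), 5.0),
        PSGModule(tuple(genes[5:]), tuple(int(s) for s in screens[k:2 * k]), 5.0),
    ]


def simulate_panel(config: PanelConfig):
    """Generate (guide LFCTable, gene LFCTable, PanelTruth) from a config.

    Per screen s with null scale sigma_s, null guides draw from N(0, sigma_s),
    essential guides from N(essential_mean_lfc, sigma_s), and PS-module guides
    in member screens from N(effect, sigma_s) where effect is the module's
    effect_lfc times sigma_s (or the raw effect_lfc when
    ``effect_in_sigma_units`` is off).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"gene_{i:04d}" for i in range(config.n_genes)]
    screens = [f"screen_{s:02d}" for s in range(config.n_screens)]
    n_ess = int(round(config.essential_fraction * config.n_genes))
    essential = frozenset(rng.choice(genes, size=n_ess, replace=False))

    modules = config.psg_modules
    if modules is None:
        modules = _default_modules(genes, essential, config.n_screens, rng)
    for m in modules:
        if m.effect_lfc <= 0:
            raise DataError("PS module effect_lfc must be > 0")

    lo, hi = config.null_sigma_range
    sigma = rng.uniform(lo, hi, size=config.n_screens)

    gene_idx = {g: i for i, g in enumerate(genes)}
    mean = np.zeros((config.n_genes, config.n_screens))
    mean[[gene_idx[g] for g in essential], :] = config.essential_mean_lfc
    psg_flag = np.zeros((config.n_genes, config.n_screens), dtype=bool)
    for m in modules:
        rows = [gene_idx[g] for g in m.genes]
        for s in m.screens:
            eff = m.effect_lfc * sigma[s] if config.effect_in_sigma_units else m.effect_lfc
            mean[rows, s] = eff
            psg_flag[rows, s] = True

    ng = config.n_guides_per_gene
    guide_ids = [f"{g}.g{k + 1}" for g in genes for k in range(ng)]
    guide_mean = np.repeat(mean, ng, axis=0)
    noise = rng.standard_normal(guide_mean.shape) * sigma[None, :]
    guide_vals = guide_mean + noise

    guide_lfc = LFCTable(
        level="guide",
        values=pd.DataFrame(guide_vals, index=guide_ids, columns=screens),
        provenance={"generator": "simulate_panel", "seed": config.seed},
    )
    gene_vals = guide_vals.reshape(config.n_genes, ng, config.n_screens).mean(axis=1)
    gene_lfc = LFCTable(
        level="gene",
        values=pd.DataFrame(gene_vals, index=genes, columns=screens),
        provenance={"generator": "simulate_panel", "seed": config.seed},
    )
    gmap = GuideMap(mapping=pd.Series(np.repeat(genes, ng), index=guide_ids))
    truth = PanelTruth(
        psg=pd.DataFrame(psg_flag, index=genes, columns=screens),
        essential_genes=essential,
        sigma=pd.Series(sigma, index=screens),
        guide_map=gmap,
        modules=modules,
    )
    return guide_lfc, gene_lfc, truth


@dataclass
class CooccurrenceTruth:
    """Planted module membership for a simulated binary call matrix."""

    modules: list  # list of (gene names tuple, screen names tuple)
    background_rate: float


def simulate_cooccurrence_calls(
    n_genes: int,
    n_screens: int,
    background_rate: float,
    planted_modules=(),
    seed: int | None = None,
):
    """Binary call matrix: Bernoulli background plus deterministic modules.

    ``planted_modules`` is a sequence of (gene indices, screen indices); every
    listed gene is called in every listed screen.
    """
    if not 0 <= background_rate <= 1:
        raise DataError("background_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    screens = [f"screen_{s:02d}" for s in range(n_screens)]
    calls = (rng.random((n_genes, n_screens)) < background_rate).astype(int)
    modules = []
    for gene_idx, screen_idx in planted_modules:
        for gi in gene_idx:
            for si in screen_idx:
                calls[gi, si] = 1
        modules.append(
            (tuple(genes[i] for i in gene_idx), tuple(screens[s] for s in screen_idx))
        )
    df = pd.DataFrame(calls, index=genes, columns=screens)
    return df, CooccurrenceTruth(modules=modules, background_rate=background_rate)


@dataclass
class GIConfig:
    """Configuration of a synthetic dual-guide GI screen.

    Double-knockout LFCs follow y_ij = x_i + x_j + g_IJ + noise, with x the
    guide single-knockout effects.  Array-gene effects are drawn from a
    three-class mixture (null / essential / PS-like); interactions of
    magnitude ``interaction_magnitude`` with random sign are planted on
    ``interaction_fraction`` of query-array pairs.  Dual targeting of the
    same gene reproduces that gene's single-knockout phenotype.
    """

    n_query: int = 8
    n_array: int = 100
    n_crRNA: int = 3
    n_controls: int = 5
    noise_sigma: float = 0.2
    interaction_fraction: float = 0.05
    interaction_magnitude: float = 1.5
    guide_effect_sd: float = 0.1
    include_query_in_array: bool = False
    seed: int = 0


@dataclass
class GITruth:
    """Generating truth for a synthetic GI screen."""

    gene_effects: pd.Series
    guide_effects: pd.Series
    interactions: dict  # (query gene, array gene) -> g value (nonzero only)
    noise_sigma: float


def simulate_gi(config: GIConfig):
    """Generate (construct LFC Series, GILibrary, GITruth) from a config."""
    rng = np.random.default_rng(config.seed)
    queries = [f"Q{i + 1:02d}" for i in range(config.n_query)]
    arrays = [f"A{i + 1:03d}" for i in range(config.n_array)]
    if config.include_query_in_array:
        arrays = arrays + queries
    lib = gi_mod.design_library(queries, arrays, config.n_crRNA, config.n_controls)

    # gene effects: queries alternate PS-like / essential / null; arrays mixed
    gene_eff = {}
    query_classes = [1.2, -2.0, 0.0, 1.2, -2.0, 0.0, 0.0, 0.0]
    for i, q in enumerate(queries):
        gene_eff[q] = query_classes[i % len(query_classes)]
    cls = rng.choice([0, 1, 2], size=config.n_array, p=[0.7, 0.15, 0.15])
    for a, c in zip([f"A{i + 1:03d}" for i in range(config.n_array)], cls):
        gene_eff[a] = {0: 0.0, 1: -2.0, 2: 1.2}[c] + rng.normal(0, 0.2)
    gene_eff[gi_mod.CONTROL_GENE] = 0.0

    all_guides = sorted(
        set(lib.constructs["guide_A"]) | set(lib.constructs["guide_B"])
    )
    guide_eff = {}
    for g in all_guides:
        gene = g.rsplit(".", 1)[0]
        sd = 0.05 if gene == gi_mod.CONTROL_GENE else config.guide_effect_sd
        guide_eff[g] = gene_eff[gene] + rng.normal(0, sd)

    # planted interactions on query x array pairs (self pairs excluded)
    interactions = {}
    pairs = [(q, a) for q in queries for a in arrays if q != a]
    n_gi = int(round(config.interaction_fraction * len(pairs)))
    if n_gi > 0:
        chosen = rng.choice(len(pairs), size=n_gi, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_gi)
        for k, s in zip(chosen, signs):
            interactions[pairs[k]] = float(s * config.interaction_magnitude)

    vals = np.empty(len(lib.constructs))
    for idx, (cid, row) in enumerate(lib.constructs.iterrows()):
        ga, gb = row["guide_A"], row["guide_B"]
        gene_a, gene_b = row["gene_A"], row["gene_B"]
        if gene_a == gene_b and gene_a != gi_mod.CONTROL_GENE:
            base = 0.5 * (guide_eff[ga] + guide_eff[gb])  # same gene hit twice
        else:
            base = guide_eff[ga] + guide_eff[gb]
            base += interactions.get((gene_a, gene_b), 0.0)
            base += interactions.get((gene_b, gene_a), 0.0)
        eps = rng.normal(0, config.noise_sigma) if config.noise_sigma > 0 else 0.0
        vals[idx] = base + eps
    lfc = pd.Series(vals, index=lib.constructs.index, name="lfc")
    truth = GITruth(
        gene_effects=pd.Series(gene_eff),
        guide_effects=pd.Series(guide_eff),
        interactions=interactions,
        noise_sigma=config.noise_sigma,
    )
    return lfc, lib, truth


def simulate_counts_from_lfc(
    guide_lfc: LFCTable,
    screen: str,
    depth_per_guide: int = 500,
    day: int = 21,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw multinomial read counts consistent with one screen's guide LFCs.

    Reference counts sample a uniform pool; endpoint counts sample abundances
    proportional to 2^LFC.  Columns follow the counts-table header convention,
    so the output round-trips through the screen-reading machinery.
    """
    rng = np.random.default_rng(seed)
    lfc = guide_lfc.values[screen]
    n = len(lfc)
    total = depth_per_guide * n
    ref_p = np.full(n, 1.0 / n)
    end_p = np.exp2(lfc.to_numpy())
    end_p = end_p / end_p.sum()
    ref = rng.multinomial(total, ref_p)
    end = rng.multinomial(total, end_p)
    return pd.DataFrame(
        {"guide": lfc.index, "reference:A:day0": ref, f"endpoint:A:day{day}": end}
    ).set_index("guide")
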