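# psgkit

Toolkit for discovering **proliferation-suppressor genes (PSGs)** — genes
whose knockout makes cells grow *faster* — from pooled CRISPR knockout
fitness screens, and for characterizing them through co-occurrence networks,
differential-correlation analysis, and dual-guide genetic-interaction
scoring. PSGs show positive selection in fitness screens, the mirror image
of essential genes, and are strongly enriched for tumor suppressors; they
are rare, context-specific, and easily drowned out by the large
screen-to-screen differences in log-fold-change (LFC) variance, which is the
problem this toolkit addresses.

Intended users: computational biologists analysing screen compendia
(DepMap/Avana-style guide-level count exports) or dual-guide Cas12a
combinatorial screens, from Python or from the `psgkit` command line.

## The methods

**Mixed Z-score.** For each screen, a two-component Gaussian mixture is
fitted by EM to the guide-level LFC distribution: a broad negative component
(essential knockouts) and a dominant near-zero component (null phenotypes).
Each gene's mean LFC *x* is standardized against the higher-mean ("null")
component:

    Z = (x − μ_high) / σ_high

Negative Z marks essentiality, positive Z the PSG phenotype. Because σ_high
is screen-specific, a fixed threshold (Z ≥ 3.83, the calibration at which
tumor-suppressor precision reaches 90% on a large public panel — i.e. 10%
FDR) is comparable across screens with very different noise levels.
`mixed_z.evaluate_threshold` recomputes this calibration on any panel from
tumor-suppressor (true positive) and oncogene + nonessential (false
positive) reference sets, with recall counted as TSG×screen observations.

**Co-occurrence network.** Binary PSG calls (genes called in ≥ 2 screens)
are tested for all-pairs co-occurrence with Fisher's exact test on the 2×2
table [both, a-only, b-only, neither]; Benjamini–Hochberg FDR ≤ 0.001
defines edges. Edge-set overlap with an external functional network is
scored empirically against 10,000 random samples of equally many pairs from
the tested-pair universe, with an add-one p-value.

**Differential correlation (dPCC).** After excluding low-quality screens
(Cohen's *D* ≤ 2.5 between nonessential and essential LFC distributions, or
core-essential recall ≤ 60%), each gene pair's Pearson correlation of mixed-Z
profiles is computed within a designated screen group and within its
complement; dPCC is their difference. Significance comes from a per-pair
permutation null (1000 random pseudo-groups of the same size), right-tailed
for positive and left-tailed for negative dPCC. Candidate partners of a seed
clique need pair p < 0.001 and |mixed Z| > 5 in at least one screen.

**Genetic interactions.** A dual-guide library pairs each target crRNA with
nonessential-control crRNAs (3 crRNA/gene × 5 controls = 15 constructs for
single-knockout fitness) and crosses query × array genes (9 double
constructs per pair). For each anchor guide *i*, combination LFCs are
regressed on partner single-knockout LFCs, ŷ = m_i·x + b_i; residuals are
Z-scored within the anchor, summed per gene pair and orientation, divided by
√n constructs, and the two orientations are combined with a further /√2.
Positive gene-level Z: the double knockout is fitter than additive.

**Growth kinetics.** With X = X_i·2^(k·t), an LFC over *t* days equals
Δk·t, so Δk = LFC/t doublings/day. An LFC of 2.5 over 21 days is only a
~12% growth-rate gain (doubling time 24 h → 21 h) and would project to just
~1.7 LFC in a 14-day assay — why short screens under-detect PSGs.

A seeded synthetic-data module (`psgkit.synthetic`) generates panels with
per-screen variance heterogeneity and planted PSG modules, binary call
matrices with planted co-occurrence, and additive GI screens with planted
interaction terms — each with truth labels, so every stage is verifiable
without external downloads.

## Worked example

```python
from psgkit import mixed_z, synthetic

guide, gene, truth = synthetic.simulate_panel(synthetic.PanelConfig(seed=1))
zm = mixed_z.score_panel(guide, gene)        # per-screen mixture fit + Z
calls = mixed_z.call_psg(zm)                 # Z >= 3.83
```

Running `python examples/01_simulate_score_call.py` prints:

```
screens scored:        40 (excluded: 0)
PS calls at Z>=3.83:   119
planted PS effects:    120
sensitivity:           0.992
false-discovery rate:  0.000
```

All 40 screens converge; of 120 planted +5σ proliferation-suppressor
effects, 119 are called and no null or essential gene crosses the threshold
— the mixture standardization equalizes detectability across screens whose
raw noise differs five-fold. The other scripts in `examples/` walk through
the co-occurrence network (`02`), differential correlation (`03`), genetic
interactions (`04`), and growth kinetics (`05`) the same way.

The command-line interface mirrors the library:
`psgkit simulate|lfc|mixedz|call-psg|evaluate|copsg|enrich|dpcc|gi|growth`,
each writing TSV/JSON outputs plus a `manifest.json` (version, parameters,
input digests) for byte-for-byte reproducibility.

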