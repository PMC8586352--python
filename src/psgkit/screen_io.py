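"""Read/write pooled-screen data and compute log2 fold changes.

A pooled CRISPR knockout screen produces, for every guide RNA, read counts in
one or more reference samples (typically the plasmid pool or an early
timepoint) and one or more endpoint samples collected after a growth period.
Guide abundances are normalized to reads-per-million (RPM) within each sample,
and each guide's log2 fold change (LFC) is the log2 ratio of endpoint to
reference RPM with a small pseudocount.  Gene-level LFC is the arithmetic mean
of a gene's guide LFCs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

#: Sample conditions recognised in counts-table headers.
REFERENCE = "reference"
ENDPOINT = "endpoint"

# Header convention for count columns: "<condition>:<replicate>:day<d>",
# e.g. "reference:A:day0", "endpoint:A:day21".
_SAMPLE_RE = re.compile(r"^(reference|endpoint):([^:]+):day(\d+)$")


@dataclass(frozen=True)
class SampleLabel:
    """One sequencing sample of a screen."""

    condition: str  # REFERENCE or ENDPOINT
    replicate: str
    day: int

    def __str__(self) -> str:  # column-header form
        return f"{self.condition}:{self.replicate}:day{self.day}"

    @classmethod
    def parse(cls, header: str) -> "SampleLabel":
        m = _SAMPLE_RE.match(header)
        if m is None:
            raise FormatError(
                f"sample column {header!r} does not match "
                "'<reference|endpoint>:<replicate>:day<d>'"
            )
        return cls(m.group(1), m.group(2), int(m.group(3)))


@dataclass
class ScreenCounts:
    """Guide-level read counts for one screen (guides x samples)."""

    counts: pd.DataFrame  # index: guide ids, columns: header strings
    samples: list[SampleLabel]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise FormatError(f"duplicate guide ids: {list(dupes)[:5]}")
        if (self.counts.values < 0).any():
            raise FormatError("negative read counts present")
        conds = {s.condition for s in self.samples}
        if REFERENCE not in conds or ENDPOINT not in conds:
            raise FormatError("need at least one reference and one endpoint sample")
        if len({str(s) for s in self.samples}) != len(self.samples):
            raise FormatError("sample labels are not unique")


@dataclass
class GuideMap:
    """guide id -> single gene symbol (multi-gene guides removed upstream)."""

    mapping: pd.Series  # index guide_id, values gene symbol

    def __post_init__(self) -> None:
        if self.mapping.index.has_duplicates:
            raise FormatError("guide map contains duplicate guide ids")
        if (self.mapping.astype(str).str.strip() == "").any():
            raise FormatError("guide map contains empty gene symbols")

    def gene_of(self, guide_id: str) -> str:
        return self.mapping[guide_id]


@dataclass
class LFCTable:
    """Entities x screens matrix of log2 fold changes.

    ``level`` is "guide" or "gene"; ``provenance`` records normalization and
    pseudocount settings so downstream results are reproducible.
    """

    level: str
    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("guide", "gene"):
            raise ValueError(f"level must be 'guide' or 'gene', got {self.level!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError("LFC table contains non-finite values")
        if self.level == "gene" and self.values.index.has_duplicates:
            raise FormatError("gene-level LFC table has duplicate gene rows")

    def to_tsv(self, path) -> None:
        # %.17g round-trips IEEE doubles exactly through the text format
        self.values.to_csv(path, sep="\t", index_label=self.level, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path, level: str) -> "LFCTable":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return cls(level=level, values=df, provenance={"source": str(path)})


@dataclass
class ReferenceSets:
    """Curated gene sets used for QC and threshold calibration.

    ``tsg`` is the true-positive class for proliferation-suppressor calling;
    ``oncogene`` (with dual-annotated tumor suppressors removed) plus
    ``nonessential`` form the false-positive class.
    """

    essential: frozenset
    nonessential: frozenset
    tsg: frozenset
    oncogene: frozenset

    def __post_init__(self) -> None:
        overlap = self.tsg & (self.oncogene | self.nonessential)
        if overlap:
            raise DataError(
                f"tsg set overlaps false-positive sets after cleaning: {sorted(overlap)[:5]}"
            )

    @property
    def false_positive(self) -> frozenset:
        return self.oncogene | self.nonessential


def read_counts(path, map_path) -> tuple[ScreenCounts, GuideMap]:
    """Read a counts TSV and guide->gene map TSV; drop unmapped guides.

    The counts file has a header row whose first column is the guide id and
    whose remaining columns follow '<condition>:<replicate>:day<d>'.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError("counts file needs a guide column plus >= 2 sample columns")
    guide_col = df.columns[0]
    samples = [SampleLabel.parse(c) for c in df.columns[1:]]
    counts = df.set_index(guide_col)
    try:
        counts = counts.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric counts: {exc}") from exc

    mp = pd.read_csv(map_path, sep="\t")
    if mp.shape[1] < 2:
        raise FormatError("guide map needs guide and gene columns")
    mapping = pd.Series(mp.iloc[:, 1].values, index=mp.iloc[:, 0].values)
    gmap = GuideMap(mapping=mapping)

    unmapped = counts.index.difference(mapping.index)
    if len(unmapped) > 0:
        logger.warning("dropping %d unmapped guides", len(unmapped))
        counts = counts.drop(index=unmapped)
    return ScreenCounts(counts=counts, samples=samples), gmap


def compute_guide_lfc(
    counts: ScreenCounts, pseudocount: float = 1.0, day: int | None = None
) -> LFCTable:
    """Per-guide LFC: log2((RPM_end + pc) / (RPM_ref + pc)), replicate-averaged.

    Each replicate's LFC is computed separately (endpoint replicate against the
    replicate-matched reference where one exists, else the mean reference RPM),
    then averaged.  ``day`` restricts endpoint samples to one collection day.
    """
    if pseudocount <= 0:
        raise DataError("pseudocount must be > 0")
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise DataError(f"sample {zero.index[0]!r} has zero total reads")
    rpm = counts.counts / totals * 1e6

    refs = [s for s in counts.samples if s.condition == REFERENCE]
    ends = [s for s in counts.samples if s.condition == ENDPOINT]
    if day is not None:
        ends = [s for s in ends if s.day == day]
        if not ends:
            raise DataError(f"no endpoint samples at day {day}")

    ref_by_rep = {s.replicate: s for s in refs}
    mean_ref = rpm[[str(s) for s in refs]].mean(axis=1)

    rep_lfcs = []
    for s in ends:
        ref = ref_by_rep.get(s.replicate)
        ref_rpm = rpm[str(ref)] if ref is not None else mean_ref
        # log difference (not log of ratio) so swapping conditions negates
        # every LFC bit-exactly
        rep_lfcs.append(np.log2(rpm[str(s)] + pseudocount) - np.log2(ref_rpm + pseudocount))
    lfc = pd.concat(rep_lfcs, axis=1).mean(axis=1)
    screen_name = f"day{ends[0].day}" if day is not None else "screen"
    return LFCTable(
        level="guide",
        values=lfc.to_frame(name=screen_name),
        provenance={"normalization": "rpm", "pseudocount": pseudocount, "day": day},
    )


def aggregate_gene_lfc(guide_lfc: LFCTable, gmap: GuideMap) -> LFCTable:
    """Gene-level LFC = arithmetic mean of the gene's guide LFCs, per screen."""
    if guide_lfc.level != "guide":
        raise DataError("aggregate_gene_lfc expects a guide-level table")
    missing = guide_lfc.values.index.difference(gmap.mapping.index)
    if len(missing) > 0:
        raise DataError(f"{len(missing)} guides missing from map, e.g. {missing[0]!r}")
    genes = gmap.mapping.loc[guide_lfc.values.index]
    out = guide_lfc.values.groupby(genes.values).mean()
    out.index.name = "gene"
    return LFCTable(level="gene", values=out, provenance=dict(guide_lfc.provenance))


def _read_gene_list(path) -> frozenset:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def read_gene_sets(
    essential_path=None, nonessential_path=None, tsg_path=None, oncogene_path=None
) -> ReferenceSets:
    """Read one-symbol-per-line gene lists and clean them.

    Oncogenes that are also annotated as tumor suppressors are removed from the
    oncogene set (dual-annotated genes are ambiguous as false positives).
    """
    essential = _read_gene_list(essential_path) if essential_path else frozenset()
    noness = _read_gene_list(nonessential_path) if nonessential_path else frozenset()
    tsg = _read_gene_list(tsg_path) if tsg_path else frozenset()
    onco = _read_gene_list(oncogene_path) if oncogene_path else frozenset()
    if tsg_path is not None and not tsg:
        raise DataError(f"empty gene set: {tsg_path}")
    for pth, s in ((essential_path, essential), (nonessential_path, noness), (oncogene_path, onco)):
        if pth is not None and not s:
            raise DataError(f"empty gene set: {pth}")
    dual = onco & tsg
    if dual:
        logger.info("removing %d dual-annotated genes from oncogene set", len(dual))
        onco = onco - dual
    noness = noness - tsg
    return ReferenceSets(
        essential=essential, nonessential=noness, tsg=tsg, oncogene=onco
    )


def reference_sets_from_iterables(essential=(), nonessential=(), tsg=(), oncogene=()) -> ReferenceSets:
    """Build cleaned ReferenceSets directly from in-memory iterables."""
    tsg = frozenset(tsg)
    onco = frozenset(oncogene) - tsg
    noness = frozenset(nonessential) - tsg
    return ReferenceSets(
        essential=frozenset(essential), nonessential=noness, tsg=tsg, oncogene=onco
    )
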