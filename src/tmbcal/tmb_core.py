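"""Labels and predictors for the calibration regression.

The regression target (label) is *exomic TMB*: nonsynonymous mutations per Mb
of a sample's covered coding footprint.  The predictors are per-Mb counts over
a gene panel's footprint (nonsynonymous, all mutations, hotspots) optionally
with one-hot genetic ancestry.  This module turns variant sets into both,
including dinucleotide merging, panel restriction, the per-sample footprint
intersection and the 98th-percentile training cap on panel-derived inputs.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import (
    ANCESTRIES,
    Consequence,
    CoverageMask,
    Interval,
    PanelDefinition,
    VariantRecord,
    intersect_intervals,
    total_length,
)

TRAINING_COLUMNS = [
    "sample_id", "nonsyn_per_mb", "all_per_mb", "hotspot_per_mb",
    "ancestry", "exomic_tmb",
]


@dataclass
class SampleProfile:
    """A sample's variant set, coverage footprint and ancestry.

    ``exomic_tmb`` is derived: nonsynonymous count / exome_footprint_mb.
    """

    sample_id: str
    variants: list[VariantRecord]
    exome_footprint_mb: float
    ancestry: str = "OTHER"

    def __post_init__(self) -> None:
        if self.exome_footprint_mb <= 0:
            raise ValueError("exome_footprint_mb must be positive")

    @property
    def exomic_tmb(self) -> float:
        return exomic_tmb(self)


@dataclass
class InputConfig:
    """Which fields of the input vector are active for a model configuration.

    ``remove_hotspots`` is an input-construction choice: hotspot-flagged
    variants are subtracted from the nonsynonymous and all-mutation counts
    before per-Mb normalization (and the hotspot count itself is zeroed).
    """

    use_nonsyn: bool = True
    use_all: bool = False
    use_hotspot: bool = False
    use_ancestry: bool = False
    remove_hotspots: bool = False

    def active_fields(self) -> list[str]:
        out = []
        if self.use_nonsyn:
            out.append("nonsyn_per_mb")
        if self.use_all:
            out.append("all_per_mb")
        if self.use_hotspot:
            out.append("hotspot_per_mb")
        if self.use_ancestry:
            out.append("ancestry")
        return out

    @property
    def n_features(self) -> int:
        n = int(self.use_nonsyn) + int(self.use_all) + int(self.use_hotspot)
        if self.use_ancestry:
            n += len(ANCESTRIES)
        return n


@dataclass
class InputVector:
    """Per-Mb panel counts plus encoded ancestry — the regression predictor."""

    nonsyn_per_mb: float
    all_per_mb: float
    hotspot_per_mb: float
    ancestry_onehot: np.ndarray
    config: InputConfig = field(default_factory=InputConfig)

    def __post_init__(self) -> None:
        for name in ("nonsyn_per_mb", "all_per_mb", "hotspot_per_mb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.hotspot_per_mb > self.all_per_mb + 1e-9:
            raise ValueError("hotspot_per_mb cannot exceed all_per_mb")

    def to_array(self) -> np.ndarray:
        parts: list[float] = []
        if self.config.use_nonsyn:
            parts.append(self.nonsyn_per_mb)
        if self.config.use_all:
            parts.append(self.all_per_mb)
        if self.config.use_hotspot:
            parts.append(self.hotspot_per_mb)
        arr = np.asarray(parts, dtype=float)
        if self.config.use_ancestry:
            arr = np.concatenate([arr, self.ancestry_onehot.astype(float)])
        return arr


def ancestry_onehot(ancestry: str) -> np.ndarray:
    """One-hot encode ancestry over (EUR, AFR, EAS, AMR, SAS, OTHER);
    unrecognized labels encode as OTHER."""
    vec = np.zeros(len(ANCESTRIES))
    try:
        idx = ANCESTRIES.index(ancestry)
    except ValueError:
        idx = ANCESTRIES.index("OTHER")
    vec[idx] = 1.0
    return vec


# ---------------------------------------------------------------------------
# dinucleotide merging
# ---------------------------------------------------------------------------

def merge_dinucleotides(
    variants: Sequence[VariantRecord], rel_tol: float = 0.2
) -> list[VariantRecord]:
    """Merge adjacent single-base substitutions that are likely in phase.

    Multi-caller somatic call sets report dinucleotide substitutions as two
    separate single-base rows.  Two records on the same chromosome at
    positions differing by exactly 1 whose alt counts agree within ``rel_tol``
    relative difference are treated as one in-phase event: they are replaced
    by a single record at the lower position, labeled nonsynonymous, with
    alt_count and depth the rounded means of the pair.  Pairing is greedy
    left-to-right on position-sorted records.  AF annotations are dropped on
    the merged record (a dinucleotide allele is not the same allele as either
    component SNV); the hotspot flag is the OR of the pair.
    """
    if not (0.0 <= rel_tol <= 1.0):
        raise ValueError(f"rel_tol must be in [0,1], got {rel_tol}")
    ordered = sorted(variants, key=lambda r: (r.chrom, r.pos))
    out: list[VariantRecord] = []
    i = 0
    while i < len(ordered):
        a = ordered[i]
        if i + 1 < len(ordered):
            b = ordered[i + 1]
            if (
                a.chrom == b.chrom
                and b.pos - a.pos == 1
                and max(a.alt_count, b.alt_count) > 0
                and abs(a.alt_count - b.alt_count)
                / max(a.alt_count, b.alt_count)
                <= rel_tol
            ):
                merged = VariantRecord(
                    sample_id=a.sample_id,
                    chrom=a.chrom,
                    pos=a.pos,
                    ref=a.ref + b.ref,
                    alt=a.alt + b.alt,
                    consequence=Consequence.NONSYNONYMOUS,
                    alt_count=round((a.alt_count + b.alt_count) / 2),
                    depth=round((a.depth + b.depth) / 2),
                    origin=a.origin,
                    hotspot=a.hotspot or b.hotspot,
                )
                out.append(merged)
                i += 2
                continue
        out.append(a)
        i += 1
    return out


# ---------------------------------------------------------------------------
# footprints and TMB
# ---------------------------------------------------------------------------

def footprint_mb(
    mask: CoverageMask, cds: Sequence[Interval]
) -> float:
    """Length in Mb of the sample's covered territory intersected with CDS."""
    inter = intersect_intervals(mask.intervals, list(cds))
    length = total_length(inter)
    if length == 0:
        raise ValueError(
            f"sample {mask.sample_id}: coverage mask and CDS are disjoint; "
            "cannot assign an exomic footprint"
        )
    return length / 1e6


def exomic_tmb(profile: SampleProfile) -> float:
    """Nonsynonymous mutations per Mb of the sample's exomic footprint."""
    if profile.exome_footprint_mb <= 0:
        raise ValueError("exome footprint must be positive")
    n = sum(
        1 for v in profile.variants
        if v.consequence is Consequence.NONSYNONYMOUS
    )
    return n / profile.exome_footprint_mb


def restrict_to_panel(
    profile: SampleProfile | Sequence[VariantRecord],
    panel: PanelDefinition,
) -> list[VariantRecord]:
    """Variants whose (0-based) position falls inside a panel interval."""
    variants = (
        profile.variants if isinstance(profile, SampleProfile) else profile
    )
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, start, end in panel.intervals:
        starts, ends = by_chrom.setdefault(chrom, ([], []))
        starts.append(start)
        ends.append(end)
    out = []
    for v in variants:
        entry = by_chrom.get(v.chrom)
        if entry is None:
            continue
        starts, ends = entry
        pos0 = v.pos - 1  # MAF is 1-based, intervals half-open 0-based
        k = bisect_right(starts, pos0) - 1
        if k >= 0 and pos0 < ends[k]:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# input-vector assembly
# ---------------------------------------------------------------------------

def panel_inputs(
    panel_variants: Sequence[VariantRecord],
    panel: PanelDefinition,
    ancestry: str,
    config: InputConfig | None = None,
) -> InputVector:
    """Assemble the per-Mb count vector for one sample over one panel.

    Under ``remove_hotspots`` configurations, hotspot-flagged variants are
    subtracted from the counts before normalization by ``cds_mb``.
    """
    config = config or InputConfig()
    if panel.cds_mb <= 0:
        raise ValueError("panel cds_mb must be positive")
    nonsyn = sum(
        1 for v in panel_variants
        if v.consequence is Consequence.NONSYNONYMOUS
    )
    syn = sum(
        1 for v in panel_variants if v.consequence is Consequence.SYNONYMOUS
    )
    hot = sum(1 for v in panel_variants if v.hotspot)
    hot_nonsyn = sum(
        1 for v in panel_variants
        if v.hotspot and v.consequence is Consequence.NONSYNONYMOUS
    )
    hot_syn = sum(
        1 for v in panel_variants
        if v.hotspot and v.consequence is Consequence.SYNONYMOUS
    )
    if config.remove_hotspots:
        nonsyn -= hot_nonsyn
        syn -= hot_syn
        hot = 0
    return InputVector(
        nonsyn_per_mb=nonsyn / panel.cds_mb,
        all_per_mb=(nonsyn + syn) / panel.cds_mb,
        hotspot_per_mb=hot / panel.cds_mb,
        ancestry_onehot=ancestry_onehot(ancestry),
        config=config,
    )


def cap_training_set(
    table: pd.DataFrame,
    column: str = "nonsyn_per_mb",
    percentile: float = 98.0,
) -> pd.DataFrame:
    """Drop samples above the empirical percentile of panel-derived inputs.

    Rare outlier *input* values are excluded from training; the exomic label
    is never capped (capping on the label would truncate the target
    distribution being modeled).  The percentile uses the linear-interpolation
    estimator; ties at the cutoff are retained.
    """
    if not (0 < percentile <= 100):
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    values = table[column].to_numpy(dtype=float)
    cutoff = np.percentile(values, percentile, method="linear")
    return table[values <= cutoff].reset_index(drop=True)


def build_training_table(
    sample_ids: Sequence[str],
    input_vectors: Sequence[InputVector],
    ancestries: Sequence[str],
    exomic_tmbs: Sequence[float],
) -> pd.DataFrame:
    """Tidy per-sample table: the training set consumed by the regressor."""
    return pd.DataFrame({
        "sample_id": list(sample_ids),
        "nonsyn_per_mb": [iv.nonsyn_per_mb for iv in input_vectors],
        "all_per_mb": [iv.all_per_mb for iv in input_vectors],
        "hotspot_per_mb": [iv.hotspot_per_mb for iv in input_vectors],
        "ancestry": list(ancestries),
        "exomic_tmb": list(exomic_tmbs),
    })[TRAINING_COLUMNS]
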