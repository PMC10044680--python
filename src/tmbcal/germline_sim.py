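"""Tumor-only construction: germline spike-in and population-frequency filtering.

Tumor-only sequencing has no matched normal, so germline variants must be
removed by frequency filtering against population databases; variants too
rare to be cataloged ("private" germline variants) survive and inflate panel
TMB.  This module builds labeled tumor-only datasets by reintroducing
germline calls into somatic profiles, applies permissive/stringent filters
(popmax AF, overall AF, self-cohort frequency with hotspot whitelisting), and
reports somatic/germline classification metrics with somatic as the positive
class.

Removal uses strict inequality (AF > threshold removes, AF == threshold
retains), and absence from a database passes every threshold: a database can
only exclude what it has seen.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from .variant_io import Origin, Site, VariantRecord


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds of one filtering stringency.

    A variant is removed iff any database popmax AF exceeds
    ``popmax_threshold``, or any database overall AF exceeds
    ``overall_af_threshold``, or its self-cohort frequency exceeds
    ``self_cohort_threshold`` and the site is not a whitelisted hotspot.
    """

    name: str
    popmax_threshold: float
    overall_af_threshold: float
    self_cohort_threshold: float
    whitelist_hotspots: bool = True

    def __post_init__(self) -> None:
        for t in (self.popmax_threshold, self.overall_af_threshold,
                  self.self_cohort_threshold):
            if not (0.0 < t < 1.0):
                raise ValueError(f"thresholds must be in (0,1), got {t}")

    @classmethod
    def permissive(cls) -> "FilterPolicy":
        # popmax > 1%, overall AF > 0.1%; self-cohort shares the popmax cut
        return cls("permissive", 0.01, 0.001, 0.01)

    @classmethod
    def stringent(cls) -> "FilterPolicy":
        # popmax > 0.1%, overall AF > 0.01%
        return cls("stringent", 0.001, 0.0001, 0.001)


@dataclass
class FilterReport:
    """Classification metrics of one filtering run (somatic = positive)."""

    n_somatic_in: int
    n_germline_in: int
    n_somatic_retained: int
    n_germline_retained: int
    n_samples: int

    @property
    def sensitivity(self) -> float | None:
        if self.n_somatic_in == 0:
            return None
        return self.n_somatic_retained / self.n_somatic_in

    @property
    def specificity(self) -> float | None:
        if self.n_germline_in == 0:
            return None
        return 1.0 - self.n_germline_retained / self.n_germline_in

    @property
    def mean_private_germline_per_sample(self) -> float:
        if self.n_samples == 0:
            return 0.0
        return self.n_germline_retained / self.n_samples

    def as_dict(self) -> dict:
        return {
            "n_somatic_in": self.n_somatic_in,
            "n_germline_in": self.n_germline_in,
            "n_somatic_retained": self.n_somatic_retained,
            "n_germline_retained": self.n_germline_retained,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mean_private_germline_per_sample":
                self.mean_private_germline_per_sample,
        }


def spike_germline(
    somatic: Sequence[VariantRecord], germline: Sequence[VariantRecord]
) -> list[VariantRecord]:
    """Reintroduce germline calls into a sample's somatic calls.

    Origin labels are preserved; a site present in both lists keeps the
    somatic record.  Records with origin ``unknown`` are rejected — the labels
    are the point of the construction.
    """
    for rec in list(somatic) + list(germline):
        if rec.origin is Origin.UNKNOWN:
            raise ValueError(
                f"variant at {rec.site} has origin 'unknown'; spike-in "
                "requires somatic/germline labels"
            )
    somatic_sites = {(r.sample_id, *r.site) for r in somatic}
    out = list(somatic)
    out.extend(
        g for g in germline if (g.sample_id, *g.site) not in somatic_sites
    )
    return out


def self_cohort_frequencies(
    variants: Sequence[VariantRecord],
) -> dict[Site, float]:
    """Carrier fraction of each site across the samples of a run.

    Emulates using the analyzed cohort itself as a population database (which
    also removes recurrent artifacts).  Carrier fraction — the share of
    samples carrying the site at least once — stands in for allele frequency.
    """
    samples = {r.sample_id for r in variants}
    if not samples:
        return {}
    carriers: dict[Site, set[str]] = defaultdict(set)
    for r in variants:
        carriers[r.site].add(r.sample_id)
    n = len(samples)
    return {site: len(who) / n for site, who in carriers.items()}


def apply_filter(
    variants: Sequence[VariantRecord],
    policy: FilterPolicy,
    self_cohort_af: Mapping[Site, float] | None = None,
    hotspots: set[Site] | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply one stringency of population-frequency filtering.

    Returns the retained variants and a report computed from origin labels.
    The decision rule never looks at origin labels (label-blind): permuting
    labels changes the report, never the retained set.
    """
    hotspots = hotspots or set()
    self_cohort_af = self_cohort_af or {}

    retained: list[VariantRecord] = []
    for rec in variants:
        remove = any(
            af > policy.popmax_threshold for af in rec.popmax_af.values()
        ) or any(
            af > policy.overall_af_threshold
            for af in rec.overall_af.values()
        )
        if not remove:
            cohort_af = self_cohort_af.get(rec.site)
            if cohort_af is not None and cohort_af > policy.self_cohort_threshold:
                whitelisted = (
                    policy.whitelist_hotspots
                    and (rec.hotspot or rec.site in hotspots)
                )
                if not whitelisted:
                    remove = True
        if not remove:
            retained.append(rec)

    def _count(records: Sequence[VariantRecord], origin: Origin) -> int:
        return sum(1 for r in records if r.origin is origin)

    report = FilterReport(
        n_somatic_in=_count(variants, Origin.SOMATIC),
        n_germline_in=_count(variants, Origin.GERMLINE),
        n_somatic_retained=_count(retained, Origin.SOMATIC),
        n_germline_retained=_count(retained, Origin.GERMLINE),
        n_samples=len({r.sample_id for r in variants}),
    )
    return retained, report


def exclude_low_germline_samples(
    sample_ids: Sequence[str],
    prefilter_germline_counts: Mapping[str, int],
    min_pre_filter: int = 400,
) -> list[str]:
    """Drop samples with fewer than ``min_pre_filter`` germline variants over
    the union-of-panels footprint *before* filtering.

    Such samples have incomplete germline calls, so their tumor-only spike-in
    would understate contamination; tumor-normal training sets are unaffected.
    The boundary is inclusive: a sample with exactly ``min_pre_filter``
    variants is retained.
    """
    return [
        s for s in sample_ids
        if prefilter_germline_counts.get(s, 0) >= min_pre_filter
    ]
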