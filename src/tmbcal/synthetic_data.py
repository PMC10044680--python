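"""Synthetic cohorts with the statistical structure of panel-vs-exome TMB data.

Real calibration cohorts pair exome-wide mutation counts with counts over a
small gene panel.  The pairing has four structural features the regression
has to contend with, and this generator reproduces each one:

* right-skewed exomic TMB — per-sample TMB is drawn from a two-component
  log-normal mixture (a low-burden bulk and a hypermutated tail);
* nonlinear panel bias — panels are enriched for recurrently mutated
  (hotspot) genes, so hotspot mutations enter the panel with a multiplied
  capture probability: at low burden the panel over-represents the genome;
* heteroscedastic, asymmetric error — panel counts are small-number binomial
  thinnings of Poisson counts, so conditional spread and skew vary with TMB;
* ancestry-dependent tumor-only contamination — private germline variants
  that survive frequency filtering add Poisson noise to panel counts with an
  ancestry-dependent mean (reference databases under-represent some
  ancestries), at two stringency levels.

The generative model per sample: draw ancestry, then TMB
T = exp(Normal(log-mean, log-sd)) from the mixture, exome size
E ~ Uniform(28, 38) Mb; nonsynonymous exome count ~ Poisson(T·E), each
mutation hotspot with probability ``hotspot_given_mut``; synonymous count
~ Poisson(syn_ratio·T·E).  Each non-hotspot mutation enters the panel
independently with probability panel_mb/E, each hotspot mutation with
probability min(1, enrichment·panel_mb/E).  Residual private germline counts
are Poisson(λ_ancestry · panel_mb/4) at the stringent level (λ doubled-plus
at the permissive level), split 55/45 into nonsynonymous-like and
synonymous-like.  True exomic TMB is the nonsynonymous exome count / E.

A fixed seed makes the cohort byte-for-byte reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import ANCESTRIES, Consequence, Origin, VariantRecord

logger = logging.getLogger("tmbcal")

#: mean private-germline count per 4 Mb surviving *stringent* filtering, by
#: ancestry.  Values are illustrative defaults encoding the qualitative
#: ordering of reference-database representation (European ancestry best
#: represented, African least); the permissive level multiplies them.
DEFAULT_GERMLINE_LAMBDA = {
    "EUR": 15.0, "AFR": 60.0, "EAS": 30.0,
    "AMR": 25.0, "SAS": 35.0, "OTHER": 25.0,
}

#: TCGA-like ancestry mix (European-dominant).
DEFAULT_ANCESTRY_PROPORTIONS = {
    "EUR": 0.77, "AFR": 0.10, "EAS": 0.06,
    "AMR": 0.04, "SAS": 0.015, "OTHER": 0.015,
}


@dataclass
class SimConfig:
    """All knobs of the cohort generator; the seed fixes the output exactly."""

    n_samples: int = 10_000
    seed: int = 0
    exome_mb_range: tuple[float, float] = (28.0, 38.0)
    panel_mb: float = 1.1  # FoundationOne-like footprint; 4.0 = union of panels
    tmb_weights: tuple[float, float] = (0.9, 0.1)
    tmb_log_means: tuple[float, float] = (np.log(2.5), np.log(20.0))
    tmb_log_sds: tuple[float, float] = (0.8, 0.5)
    syn_ratio: float = 0.35
    hotspot_given_mut: float = 0.03
    panel_enrichment: float = 10.0
    germline_lambda: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GERMLINE_LAMBDA))
    permissive_multiplier: float = 2.15
    germline_nonsyn_fraction: float = 0.55
    ancestry_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANCESTRY_PROPORTIONS))

    def __post_init__(self) -> None:
        if abs(sum(self.tmb_weights) - 1.0) > 1e-9:
            raise ValueError("tmb mixture weights must sum to 1")
        if abs(sum(self.ancestry_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("ancestry proportions must sum to 1")
        for name in ("panel_mb", "syn_ratio", "hotspot_given_mut",
                     "panel_enrichment", "permissive_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def mean_germline_per_4mb(self, policy: str = "stringent") -> float:
        """Expected private-germline count per 4 Mb across the ancestry mix."""
        mult = 1.0 if policy == "stringent" else self.permissive_multiplier
        return mult * sum(
            self.ancestry_proportions.get(a, 0.0) * lam
            for a, lam in self.germline_lambda.items()
        )


def scale_germline_lambda(
    config: SimConfig, target_stringent_mean: float
) -> SimConfig:
    """Rescale the ancestry lambdas so the cohort-average stringent
    private-germline mean per 4 Mb equals the target (ancestry ordering and
    the permissive multiplier are preserved)."""
    current = config.mean_germline_per_4mb("stringent")
    if current <= 0:
        raise ValueError("cannot scale an all-zero germline_lambda")
    factor = target_stringent_mean / current
    return replace(config, germline_lambda={
        a: lam * factor for a, lam in config.germline_lambda.items()
    })


@dataclass
class SimSample:
    """One simulated sample: exome truth, panel counts, germline additions."""

    sample_id: str
    ancestry: str
    true_exomic_tmb: float
    exome_mb: float
    exome_nonsyn: int
    exome_syn: int
    exome_hotspot: int
    panel_nonsyn: int
    panel_syn: int
    panel_hotspot: int
    germline_nonsyn: dict[str, int]  # policy -> count
    germline_syn: dict[str, int]

    def tumor_only_counts(self, policy: str) -> tuple[int, int, int]:
        """(nonsyn, syn, hotspot) panel counts with residual germline added."""
        return (
            self.panel_nonsyn + self.germline_nonsyn[policy],
            self.panel_syn + self.germline_syn[policy],
            self.panel_hotspot,
        )


def simulate_cohort(config: SimConfig) -> list[SimSample]:
    """Draw a labeled cohort under the generative model (see module docs)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    anc_names = list(config.ancestry_proportions)
    anc_p = np.array([config.ancestry_proportions[a] for a in anc_names])
    anc_idx = rng.choice(len(anc_names), size=n, p=anc_p)

    comp = rng.choice(2, size=n, p=np.asarray(config.tmb_weights))
    log_means = np.asarray(config.tmb_log_means)[comp]
    log_sds = np.asarray(config.tmb_log_sds)[comp]
    T = np.exp(rng.normal(log_means, log_sds))
    E = rng.uniform(*config.exome_mb_range, size=n)

    exome_nonsyn = rng.poisson(T * E)
    exome_hot = rng.binomial(exome_nonsyn, config.hotspot_given_mut)
    exome_syn = rng.poisson(config.syn_ratio * T * E)

    p_cap = config.panel_mb / E
    p_hot = np.minimum(1.0, config.panel_enrichment * p_cap)
    panel_nonhot = rng.binomial(exome_nonsyn - exome_hot, p_cap)
    panel_hot = rng.binomial(exome_hot, p_hot)
    panel_syn = rng.binomial(exome_syn, p_cap)

    lam = np.array([
        config.germline_lambda.get(a, 0.0) for a in anc_names
    ])[anc_idx] * (config.panel_mb / 4.0)
    germ: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for policy, mult in (("stringent", 1.0),
                         ("permissive", config.permissive_multiplier)):
        total = rng.poisson(lam * mult)
        nonsyn = rng.binomial(total, config.germline_nonsyn_fraction)
        germ[policy] = (nonsyn, total - nonsyn)

    samples = []
    for i in range(n):
        samples.append(SimSample(
            sample_id=f"S{i:06d}",
            ancestry=anc_names[anc_idx[i]],
            true_exomic_tmb=float(exome_nonsyn[i] / E[i]),
            exome_mb=float(E[i]),
            exome_nonsyn=int(exome_nonsyn[i]),
            exome_syn=int(exome_syn[i]),
            exome_hotspot=int(exome_hot[i]),
            panel_nonsyn=int(panel_nonhot[i] + panel_hot[i]),
            panel_syn=int(panel_syn[i]),
            panel_hotspot=int(panel_hot[i]),
            germline_nonsyn={p: int(germ[p][0][i]) for p in germ},
            germline_syn={p: int(germ[p][1][i]) for p in germ},
        ))
    return samples


def cohort_table(
    samples: Sequence[SimSample],
    mode: str = "tumor_normal",
    panel_mb: float | None = None,
) -> pd.DataFrame:
    """Tidy training table for a cohort.

    ``mode`` selects the panel counts: ``tumor_normal`` (germline subtracted
    by design) or a filtering policy name (``stringent``/``permissive``) for
    tumor-only counts with residual private germline included.
    """
    if panel_mb is None:
        raise ValueError("panel_mb is required (pass config.panel_mb)")
    rows = []
    for s in samples:
        if mode == "tumor_normal":
            nonsyn, syn, hot = s.panel_nonsyn, s.panel_syn, s.panel_hotspot
        else:
            nonsyn, syn, hot = s.tumor_only_counts(mode)
        rows.append({
            "sample_id": s.sample_id,
            "nonsyn_per_mb": nonsyn / panel_mb,
            "all_per_mb": (nonsyn + syn) / panel_mb,
            "hotspot_per_mb": hot / panel_mb,
            "ancestry": s.ancestry,
            "exomic_tmb": s.true_exomic_tmb,
        })
    return pd.DataFrame(rows)


def expected_private_germline(
    per_genome_count: float, genome_mb: float, region_mb: float
) -> float:
    """Expected private germline variants in a region, by uniform scaling.

    Population-database studies put the count of coding variants below the
    rare-frequency cut at roughly 200 per genome over a ~32 Mb coding
    region; the expectation over a smaller footprint scales linearly:
    per_genome_count · region_mb / genome_mb.
    """
    if per_genome_count < 0:
        raise ValueError("per_genome_count must be >= 0")
    if genome_mb <= 0 or region_mb <= 0:
        raise ValueError("genome_mb and region_mb must be positive")
    return per_genome_count * region_mb / genome_mb


def oracle_conditional(
    config: SimConfig,
    x_grid: Sequence[float],
    n_mc: int = 100_000,
    mode: str = "tumor_normal",
    min_bin: int = 200,
) -> pd.DataFrame:
    """Monte-Carlo conditional distribution of true TMB given panel input.

    Simulates ``n_mc`` samples under ``config`` and bins the panel
    nonsynonymous-per-Mb input by the edges in ``x_grid``; returns per-bin
    2.5/50/97.5% quantiles of true exomic TMB.  Bins with fewer than
    ``min_bin`` draws are excluded with a warning.  This is the ground-truth
    oracle against which the fitted regressor's conditionals are judged.
    """
    sim = simulate_cohort(replace(config, n_samples=int(n_mc)))
    table = cohort_table(sim, mode=mode, panel_mb=config.panel_mb)
    x = table["nonsyn_per_mb"].to_numpy()
    y = table["exomic_tmb"].to_numpy()
    edges = np.asarray(list(x_grid), float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (x >= lo) & (x < hi)
        n = int(mask.sum())
        if n < min_bin:
            logger.warning(
                "oracle_conditional: bin [%g, %g) has %d < %d draws; excluded",
                lo, hi, n, min_bin,
            )
            continue
        q = np.percentile(y[mask], [2.5, 50, 97.5])
        rows.append({
            "x_lo": lo, "x_hi": hi, "n": n,
            "q025": q[0], "median": q[1], "q975": q[2],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# variant-level toy cohorts (for the filtering pipeline)
# ---------------------------------------------------------------------------

def simulate_variant_cohort(
    n_samples: int,
    seed: int = 0,
    somatic_mean: float = 10.0,
    germline_mean: float = 300.0,
    hotspot_sites: int = 20,
    region: tuple[str, int, int] = ("chr1", 0, 4_000_000),
) -> dict:
    """Per-variant toy cohort over a single 4 Mb-style interval.

    Synthetic stand-in for paired somatic/germline call sets with
    population-frequency annotations.  Somatic variants are mostly absent
    from the databases (a few percent collide with rare catalogued sites).
    A person's germline call set is dominated by common variants, so the
    germline popmax spectrum is a three-part mixture: ~97% common (popmax
    above the permissive 1% cut, removed by both policies), ~1.5%
    intermediate (0.1-1%, removed only by the stringent policy) and ~1.5%
    private (very rare or absent, surviving both) — yielding the realistic
    regime where filtering removes ~97-99% of germline variants and the
    stringent policy trades a little sensitivity for specificity.

    Returns ``{"somatic": [...], "germline": [...], "hotspots": set}`` with
    origin labels set, AF maps attached and hotspot flags applied.
    """
    rng = np.random.default_rng(seed)
    chrom, start, end = region
    hotspot_pos = rng.integers(start + 1, end, size=hotspot_sites)
    hotspots = {(chrom, int(p), "C", "T") for p in hotspot_pos}
    hotspot_list = sorted(hotspots)

    somatic: list[VariantRecord] = []
    germline: list[VariantRecord] = []
    for i in range(n_samples):
        sid = f"S{i:05d}"
        n_som = rng.poisson(somatic_mean)
        for _ in range(n_som):
            depth = int(rng.poisson(80) + 20)
            alt = int(rng.binomial(depth, 0.3))
            if rng.random() < 0.05 and hotspot_list:
                chrom_h, pos, ref, altb = hotspot_list[
                    rng.integers(0, len(hotspot_list))]
                rec = VariantRecord(
                    sample_id=sid, chrom=chrom_h, pos=pos, ref=ref, alt=altb,
                    consequence=Consequence.NONSYNONYMOUS,
                    alt_count=alt, depth=depth, origin=Origin.SOMATIC,
                    hotspot=True,
                )
            else:
                rec = VariantRecord(
                    sample_id=sid, chrom=chrom,
                    pos=int(rng.integers(start + 1, end)),
                    ref="A", alt="G",
                    consequence=(Consequence.NONSYNONYMOUS
                                 if rng.random() < 0.75
                                 else Consequence.SYNONYMOUS),
                    alt_count=alt, depth=depth, origin=Origin.SOMATIC,
                )
                if rng.random() < 0.03:  # rare database collision
                    af = float(10 ** rng.uniform(-6, -2.5))
                    rec.popmax_af = {"exome_db": af}
                    rec.overall_af = {"exome_db": af * 0.5}
            somatic.append(rec)

        n_germ = rng.poisson(germline_mean)
        depths = rng.poisson(80, size=n_germ) + 20
        alts = rng.binomial(depths, 0.5)
        positions = rng.integers(start + 1, end, size=n_germ)
        tier = rng.choice(3, size=n_germ, p=(0.97, 0.015, 0.015))
        for j in range(n_germ):
            rec = VariantRecord(
                sample_id=sid, chrom=chrom, pos=int(positions[j]),
                ref="G", alt="A",
                consequence=(Consequence.NONSYNONYMOUS
                             if rng.random() < 0.55
                             else Consequence.SYNONYMOUS),
                alt_count=int(alts[j]), depth=int(depths[j]),
                origin=Origin.GERMLINE,
            )
            if tier[j] == 0:  # common: above the permissive popmax cut
                af = float(10 ** rng.uniform(-1.9, -0.3))
            elif tier[j] == 1:  # intermediate: only the stringent cut removes
                af = float(10 ** rng.uniform(-2.95, -2.05))
            elif rng.random() < 0.5:  # private: too rare to be excluded
                af = float(10 ** rng.uniform(-6.0, -4.0))
            else:  # private and never catalogued
                af = None
            if af is not None:
                rec.popmax_af = {"exome_db": af, "genome_db": af}
                # overall AF sits well below popmax so the popmax rule drives
                # the tier semantics above
                rec.overall_af = {"exome_db": af * 0.05,
                                  "genome_db": af * 0.05}
            germline.append(rec)

    return {"somatic": somatic, "germline": germline, "hotspots": hotspots}
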