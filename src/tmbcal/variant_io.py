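"""Readers and writers for the tabular inputs of the TMB calibration pipeline.

Somatic and germline variant calls arrive as MAF-style tab-separated tables,
genomic footprints (panels, per-sample coverage, CDS masks) as BED3, population
allele-frequency annotations as a site-keyed TSV (one ``<db>_popmax_af`` /
``<db>_af`` column pair per database), ancestry as a two-column TSV and hotspot
catalogs as VCF-style positional lists.

All interval arithmetic in the package is 0-based half-open; MAF positions
(1-based) are converted on construction of interval queries, never stored
differently.  Strand is ignored throughout: mutation counting is positional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("tmbcal")

Interval = tuple[str, int, int]
Site = tuple[str, int, str, str]

ANCESTRIES: tuple[str, ...] = ("EUR", "AFR", "EAS", "AMR", "SAS", "OTHER")


class Consequence(str, Enum):
    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Origin(str, Enum):
    SOMATIC = "somatic"
    GERMLINE = "germline"
    UNKNOWN = "unknown"


#: Default mapping from MC3-style Variant_Classification terms to the 3-way
#: consequence enum.  The upstream call set does not pin down a nonsynonymous
#: term list, so this dictionary is a documented, overridable choice:
#: protein-altering point/indel/splice classes count as nonsynonymous, silent
#: as synonymous, everything else (UTR, intron, flank, RNA...) as other.
DEFAULT_CONSEQUENCE_MAP: dict[str, Consequence] = {
    "Missense_Mutation": Consequence.NONSYNONYMOUS,
    "Nonsense_Mutation": Consequence.NONSYNONYMOUS,
    "Nonstop_Mutation": Consequence.NONSYNONYMOUS,
    "Frame_Shift_Del": Consequence.NONSYNONYMOUS,
    "Frame_Shift_Ins": Consequence.NONSYNONYMOUS,
    "In_Frame_Del": Consequence.NONSYNONYMOUS,
    "In_Frame_Ins": Consequence.NONSYNONYMOUS,
    "Splice_Site": Consequence.NONSYNONYMOUS,
    "Translation_Start_Site": Consequence.NONSYNONYMOUS,
    "Silent": Consequence.SYNONYMOUS,
    # convenience lower-case aliases
    "missense": Consequence.NONSYNONYMOUS,
    "nonsense": Consequence.NONSYNONYMOUS,
    "frameshift": Consequence.NONSYNONYMOUS,
    "splice": Consequence.NONSYNONYMOUS,
    "nonsynonymous": Consequence.NONSYNONYMOUS,
    "silent": Consequence.SYNONYMOUS,
    "synonymous": Consequence.SYNONYMOUS,
}

#: Logical column -> accepted header names, first match wins.
DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "sample": ("sample", "sample_id", "Tumor_Sample_Barcode"),
    "chrom": ("chrom", "Chromosome"),
    "pos": ("pos", "Start_Position", "Start_position"),
    "ref": ("ref", "Reference_Allele"),
    "alt": ("alt", "Tumor_Seq_Allele2", "Alternate_Allele"),
    "consequence": ("consequence", "Variant_Classification"),
    "alt_count": ("alt_count", "t_alt_count"),
    "depth": ("depth", "t_depth"),
}


@dataclass
class VariantRecord:
    """One variant call: position, consequence class, counts, origin and
    population-frequency annotations.

    ``popmax_af`` / ``overall_af`` map database name to an allele frequency in
    [0, 1].  Absence of a database key means the variant was *not observed*
    there, which is distinct from an explicit 0.0: a database can only exclude
    what it has seen, so frequency filters treat absent as passing.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    consequence: Consequence
    alt_count: int = 0
    depth: int = 0
    origin: Origin = Origin.UNKNOWN
    popmax_af: dict[str, float] = field(default_factory=dict)
    overall_af: dict[str, float] = field(default_factory=dict)
    hotspot: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not (0 <= self.alt_count <= max(self.depth, self.alt_count)):
            raise ValueError("alt_count must be >= 0")
        if self.depth < self.alt_count:
            raise ValueError(
                f"depth ({self.depth}) < alt_count ({self.alt_count})"
            )
        for m in (self.popmax_af, self.overall_af):
            for db, af in m.items():
                if not (0.0 <= af <= 1.0):
                    raise ValueError(f"AF for {db} outside [0,1]: {af}")

    @property
    def site(self) -> Site:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PanelDefinition:
    """A gene panel's genomic footprint and its coding-sequence size in Mb.

    ``cds_mb`` is the denominator of every per-Mb panel count.  When a CDS
    mask is supplied, it is the panel footprint restricted to CDS.
    """

    name: str
    intervals: list[Interval]
    cds_mb: float

    def __post_init__(self) -> None:
        self.intervals = normalize_intervals(self.intervals)
        if self.cds_mb <= 0:
            raise ValueError(f"cds_mb must be positive, got {self.cds_mb}")

    @classmethod
    def from_bed(
        cls,
        name: str,
        path: str,
        cds: Sequence[Interval] | None = None,
    ) -> "PanelDefinition":
        """Build a panel from a BED file; cds_mb is the footprint length
        (restricted to ``cds`` when given) in Mb."""
        intervals = read_bed(path)
        if cds is not None:
            footprint = intersect_intervals(intervals, list(cds))
        else:
            footprint = intervals
        return cls(name=name, intervals=intervals,
                   cds_mb=total_length(footprint) / 1e6)


@dataclass
class CoverageMask:
    """Per-sample covered territory (BED-derived, normalized half-open)."""

    sample_id: str
    intervals: list[Interval]

    def __post_init__(self) -> None:
        self.intervals = normalize_intervals(self.intervals)


# ---------------------------------------------------------------------------
# interval primitives
# ---------------------------------------------------------------------------

def normalize_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping/adjacent-touching half-open intervals.

    Idempotent: normalizing normalized output is the identity.
    """
    ivs = sorted(intervals)
    out: list[Interval] = []
    for chrom, start, end in ivs:
        if start >= end:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out


def intersect_intervals(
    a: Sequence[Interval], b: Sequence[Interval]
) -> list[Interval]:
    """Intersection of two normalized interval sets (sorted sweep)."""
    a = normalize_intervals(a)
    b = normalize_intervals(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        ca, sa, ea = a[i]
        cb, sb, eb = b[j]
        if ca < cb:
            i += 1
            continue
        if cb < ca:
            j += 1
            continue
        lo, hi = max(sa, sb), min(ea, eb)
        if lo < hi:
            out.append((ca, lo, hi))
        if ea <= eb:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Sequence[Interval]) -> int:
    return sum(end - start for _, start, end in intervals)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _resolve_columns(
    header: Sequence[str],
    column_map: Mapping[str, tuple[str, ...]],
    required: Sequence[str],
) -> dict[str, str]:
    resolved: dict[str, str] = {}
    cols = set(header)
    for logical, candidates in column_map.items():
        for cand in candidates:
            if cand in cols:
                resolved[logical] = cand
                break
    for logical in required:
        if logical not in resolved:
            raise ValueError(
                f"MAF-style table is missing the mandatory '{logical}' column "
                f"(accepted headers: {', '.join(column_map[logical])})"
            )
    return resolved


def read_maf(
    path: str,
    origin: Origin = Origin.UNKNOWN,
    column_map: Mapping[str, tuple[str, ...]] | None = None,
    consequence_map: Mapping[str, Consequence] | None = None,
) -> list[VariantRecord]:
    """Read a MAF-style TSV into VariantRecords with the given origin label.

    Consequence strings are mapped through ``consequence_map`` (defaults to
    the MC3-style dictionary); unmappable terms are classified ``other`` and
    counted in a single logged warning.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    conseq = dict(DEFAULT_CONSEQUENCE_MAP)
    if consequence_map:
        conseq.update(consequence_map)

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    resolved = _resolve_columns(
        df.columns, cmap,
        required=("sample", "chrom", "pos", "ref", "alt", "consequence"),
    )

    records: list[VariantRecord] = []
    unmapped = 0
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        term = str(row[resolved["consequence"]])
        cq = conseq.get(term)
        if cq is None:
            unmapped += 1
            cq = Consequence.OTHER
        alt_count = int(float(row[resolved["alt_count"]])) if "alt_count" in resolved and pd.notna(row[resolved["alt_count"]]) else 0
        depth = int(float(row[resolved["depth"]])) if "depth" in resolved and pd.notna(row[resolved["depth"]]) else max(alt_count, 0)
        rec = VariantRecord(
            sample_id=str(row[resolved["sample"]]),
            chrom=str(row[resolved["chrom"]]),
            pos=int(float(row[resolved["pos"]])),
            ref=str(row[resolved["ref"]]),
            alt=str(row[resolved["alt"]]),
            consequence=cq,
            alt_count=alt_count,
            depth=max(depth, alt_count),
            origin=origin,
        )
        if "hotspot" in df.columns:
            rec.hotspot = str(row["hotspot"]).lower() in ("1", "true")
        if "popmax_af" in df.columns and pd.notna(row["popmax_af"]) and str(row["popmax_af"]):
            rec.popmax_af = _parse_af_field(str(row["popmax_af"]))
        if "overall_af" in df.columns and pd.notna(row["overall_af"]) and str(row["overall_af"]):
            rec.overall_af = _parse_af_field(str(row["overall_af"]))
        records.append(rec)
    if unmapped:
        logger.warning(
            "read_maf(%s): %d consequence terms not in the mapping were "
            "classified 'other'", path, unmapped,
        )
    return records


def _parse_af_field(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for part in text.split(";"):
        if part:
            db, val = part.split(":")
            out[db] = float(val)
    return out


def _format_af_field(m: Mapping[str, float]) -> str:
    return ";".join(f"{db}:{v!r}" for db, v in sorted(m.items()))


def write_maf(records: Sequence[VariantRecord], path: str) -> None:
    """Write VariantRecords to a tidy MAF-style TSV that ``read_maf`` round
    trips field-for-field (AF maps serialized as ``db:val;db:val``)."""
    rows = []
    for r in records:
        rows.append({
            "sample": r.sample_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "consequence": r.consequence.value,
            "alt_count": r.alt_count,
            "depth": r.depth,
            "origin": r.origin.value,
            "hotspot": int(r.hotspot),
            "popmax_af": _format_af_field(r.popmax_af),
            "overall_af": _format_af_field(r.overall_af),
        })
    cols = ["sample", "chrom", "pos", "ref", "alt", "consequence",
            "alt_count", "depth", "origin", "hotspot", "popmax_af",
            "overall_af"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_maf_roundtrip(path: str) -> list[VariantRecord]:
    """Read a TSV written by :func:`write_maf`, restoring origin labels."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        records.append(VariantRecord(
            sample_id=d["sample"],
            chrom=d["chrom"],
            pos=int(d["pos"]),
            ref=d["ref"],
            alt=d["alt"],
            consequence=Consequence(d["consequence"]),
            alt_count=int(d["alt_count"]),
            depth=int(d["depth"]),
            origin=Origin(d["origin"]),
            hotspot=bool(int(d["hotspot"])),
            popmax_af=_parse_af_field(d["popmax_af"]),
            overall_af=_parse_af_field(d["overall_af"]),
        ))
    return records


def read_bed(path: str) -> list[Interval]:
    """Read BED3+ lines into normalized (sorted, merged) half-open intervals."""
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start ({start}) must be < end ({end})"
                )
            intervals.append((chrom, start, end))
    return normalize_intervals(intervals)


def annotate_af(
    variants: Sequence[VariantRecord], af_table: str
) -> list[VariantRecord]:
    """Attach population AF annotations keyed by (chrom, pos, ref, alt).

    The table must carry ``chrom, pos, ref, alt`` plus one
    ``<db>_popmax_af`` / ``<db>_af`` column pair per database.  Records absent
    from the table keep empty maps (not observed).  A site listed twice with
    conflicting values is a hard error.  The number of records never changes.
    """
    df = pd.read_csv(af_table, sep="\t")
    popmax_cols = [c for c in df.columns if c.endswith("_popmax_af")]
    af_cols = [c for c in df.columns if c.endswith("_af") and not c.endswith("_popmax_af")]

    table: dict[Site, tuple[dict[str, float], dict[str, float]]] = {}
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        key: Site = (str(d["chrom"]), int(d["pos"]), str(d["ref"]), str(d["alt"]))
        pm = {c[: -len("_popmax_af")]: float(d[c])
              for c in popmax_cols if pd.notna(d[c])}
        ov = {c[: -len("_af")]: float(d[c]) for c in af_cols if pd.notna(d[c])}
        if key in table:
            if table[key] != (pm, ov):
                raise ValueError(
                    f"duplicate AF-table entry for {key} with conflicting values"
                )
        table[key] = (pm, ov)

    out = []
    for rec in variants:
        entry = table.get(rec.site)
        if entry is None:
            out.append(rec)
        else:
            pm, ov = entry
            out.append(replace(rec, popmax_af=dict(pm), overall_af=dict(ov)))
    return out


def read_hotspots(path: str) -> set[Site]:
    """Read a VCF-style positional hotspot list into a site set.

    Lines must carry CHROM POS [ID] REF ALT (tab-separated); header lines
    starting with ``#`` are skipped.
    """
    sites: set[Site] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if len(parts) >= 5:  # CHROM POS ID REF ALT
                    chrom, pos, ref, alt = parts[0], int(parts[1]), parts[3], parts[4]
                elif len(parts) == 4:  # CHROM POS REF ALT
                    chrom, pos, ref, alt = parts[0], int(parts[1]), parts[2], parts[3]
                else:
                    raise ValueError("expected 4 or 5+ columns")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed hotspot line") from exc
            sites.add((chrom, pos, ref, alt))
    return sites


def flag_hotspots(
    variants: Sequence[VariantRecord], hotspots: set[Site]
) -> list[VariantRecord]:
    """Return records with ``hotspot`` set where the site is in the catalog."""
    return [replace(r, hotspot=(r.site in hotspots)) for r in variants]


def read_ancestry(path: str) -> dict[str, str]:
    """Read a two-column sample/ancestry TSV; labels outside the recognized
    set (EUR/AFR/EAS/AMR/SAS) map to OTHER."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    sample_col = df.columns[0]
    anc_col = df.columns[1]
    out: dict[str, str] = {}
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        label = str(d[anc_col]).upper()
        out[str(d[sample_col])] = label if label in ANCESTRIES else "OTHER"
    return out
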