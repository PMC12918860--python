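"""Mutation catalogue, SV table and interval-annotation I/O plus clonality filters.

Coordinate conventions: mutations are 1-based (VCF style, indels anchored on
the base preceding the event); all interval files are 0-based half-open (BED).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SNV, INS, DEL = "SNV", "INS", "DEL"
SV_TYPES = ("DEL", "DUP", "INS", "INV", "TRA")

CATALOGUE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "af",
    "depth", "alt_reads", "sample_id", "donor_id", "var_class",
]


def _classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return SNV
    if len(alt) > len(ref):
        return INS
    return DEL


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV or indel.

    ``pos`` is the 1-based position of the reference base; for indels it is
    the base preceding the event (VCF anchored representation).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    af: float = math.nan
    sample_id: str = ""
    donor_id: str = ""
    var_class: str = ""
    depth: int | None = None
    alt_reads: int | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(
                f"identical alleles at {self.chrom}:{self.pos} ({self.ref})"
            )
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not math.isnan(self.af) and not (0.0 <= self.af <= 1.0):
            raise ValueError(f"allele fraction {self.af} outside [0, 1]")
        inferred = _classify_alleles(self.ref, self.alt)
        if not self.var_class:
            object.__setattr__(self, "var_class", inferred)
        elif self.var_class != inferred:
            raise ValueError(
                f"var_class {self.var_class} inconsistent with alleles "
                f"{self.ref}>{self.alt}"
            )

    @property
    def is_snv(self) -> bool:
        return self.var_class == SNV

    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Clonality/quality gates for SNV and indel catalogues.

    Defaults reproduce the 45%–55% / ≥90% allele-fraction windows and the
    depth gates used for the clone catalogues (both windows closed).
    """

    snv_af_windows: Tuple[Tuple[float, float], ...] = ((0.45, 0.55), (0.90, 1.00))
    min_depth: int = 10
    min_alt_reads: int = 3
    blacklist: Tuple[Tuple[str, int, int], ...] = ()

    def __post_init__(self):
        for lo, hi in self.snv_af_windows:
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"AF window [{lo}, {hi}] outside [0, 1]")


@dataclass
class StructuralVariant:
    """A typed rearrangement with two breakpoints (1-based)."""

    sv_type: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    junction_af: float = math.nan
    sample_id: str = ""
    donor_id: str = ""
    in_hotspot: bool = False
    overlaps_cfs: bool = False

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.sv_type != "TRA":
            if self.chrom1 != self.chrom2:
                raise ValueError("non-TRA SV must have chrom1 == chrom2")
            if self.pos1 > self.pos2:
                raise ValueError("non-TRA SV must have pos1 <= pos2")
        if not math.isnan(self.junction_af) and not (0.0 <= self.junction_af <= 1.0):
            raise ValueError(f"junction_af {self.junction_af} outside [0, 1]")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _record_sort_key(r: MutationRecord):
    return (r.chrom, r.pos, r.alt)


def read_catalogue(path: str | Path, format: str = "maf_tsv") -> List[MutationRecord]:
    """Read a mutation catalogue from a MAF-like TSV or a VCF.

    Records are returned in deterministic (chrom, pos, alt) order; malformed
    rows raise a ValueError naming the offending line.
    """
    if format == "maf_tsv":
        return _read_catalogue_tsv(path)
    if format == "vcf":
        return _read_catalogue_vcf(path)
    raise ValueError(f"unknown catalogue format {format!r}")


def _read_catalogue_tsv(path: str | Path) -> List[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(_row_to_record(row._asdict()))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
    records.sort(key=_record_sort_key)
    return records


def _row_to_record(d: Mapping[str, object]) -> MutationRecord:
    def _opt_int(key):
        v = d.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)) or v in ("", "NA", "."):
            return None
        return int(float(v))

    af = d.get("af")
    af = math.nan if af in (None, "", "NA", ".") else float(af)
    return MutationRecord(
        chrom=str(d["chrom"]),
        pos=int(float(d["pos"])),
        ref=str(d["ref"]).upper(),
        alt=str(d["alt"]).upper(),
        af=af,
        sample_id=str(d.get("sample_id") or ""),
        donor_id=str(d.get("donor_id") or ""),
        depth=_opt_int("depth"),
        alt_reads=_opt_int("alt_reads"),
    )


def _read_catalogue_vcf(path: str | Path) -> List[MutationRecord]:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for n, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            for alt in rec.alts or ():
                af = math.nan
                if rec.samples:
                    sample = rec.samples[next(iter(rec.samples))]
                    if "AF" in sample and sample["AF"] is not None:
                        v = sample["AF"]
                        af = float(v[0] if isinstance(v, tuple) else v)
                if math.isnan(af) and "AF" in rec.info:
                    v = rec.info["AF"]
                    af = float(v[0] if isinstance(v, tuple) else v)
                try:
                    records.append(
                        MutationRecord(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref.upper(),
                            alt=str(alt).upper(),
                            af=af,
                        )
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}: malformed VCF record #{n}: {exc}") from exc
    records.sort(key=_record_sort_key)
    return records


def write_catalogue(records: Iterable[MutationRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "af": "" if math.isnan(r.af) else f"{r.af:.6g}",
            "depth": "" if r.depth is None else r.depth,
            "alt_reads": "" if r.alt_reads is None else r.alt_reads,
            "sample_id": r.sample_id,
            "donor_id": r.donor_id,
            "var_class": r.var_class,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CATALOGUE_COLUMNS).to_csv(path, sep="\t", index=False)


SV_COLUMNS = ["sv_type", "chrom1", "pos1", "chrom2", "pos2",
              "junction_af", "sample_id", "donor_id"]


def read_sv_table(path: str | Path) -> List[StructuralVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(SV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        af = d.get("junction_af")
        try:
            out.append(
                StructuralVariant(
                    sv_type=str(d["sv_type"]),
                    chrom1=str(d["chrom1"]),
                    pos1=int(float(d["pos1"])),
                    chrom2=str(d["chrom2"]),
                    pos2=int(float(d["pos2"])),
                    junction_af=math.nan if af in (None, "", "NA") else float(af),
                    sample_id=str(d.get("sample_id") or ""),
                    donor_id=str(d.get("donor_id") or ""),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
    return out


def write_sv_table(svs: Iterable[StructuralVariant], path: str | Path,
                   flags: bool = True) -> None:
    cols = SV_COLUMNS + (["in_hotspot", "overlaps_cfs"] if flags else [])
    rows = []
    for s in svs:
        row = {
            "sv_type": s.sv_type, "chrom1": s.chrom1, "pos1": s.pos1,
            "chrom2": s.chrom2, "pos2": s.pos2,
            "junction_af": "" if math.isnan(s.junction_af) else f"{s.junction_af:.6g}",
            "sample_id": s.sample_id, "donor_id": s.donor_id,
        }
        if flags:
            row["in_hotspot"] = s.in_hotspot
            row["overlaps_cfs"] = s.overlaps_cfs
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> List[Tuple[str, int, int]]:
    """BED3 intervals (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def read_genes_bed(path: str | Path) -> List[Tuple[str, int, int, str]]:
    """BED6 gene footprints; strand taken from column 6."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: gene BED needs 6 columns, got {len(parts)}")
            out.append((parts[0], int(parts[1]), int(parts[2]), parts[5]))
    return out


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_clonal_snvs(records: Sequence[MutationRecord],
                       cfg: FilterConfig = FilterConfig()) -> List[MutationRecord]:
    """Keep records whose allele fraction falls in any configured closed window.

    Depth gates (min_depth on total reads, min_alt_reads on supporting reads)
    apply only to records that carry those columns.  Records with missing AF
    are dropped with a logged warning.
    """
    kept = []
    n_missing = 0
    for r in records:
        if math.isnan(r.af):
            n_missing += 1
            continue
        if not any(lo <= r.af <= hi for lo, hi in cfg.snv_af_windows):
            continue
        if r.depth is not None and r.depth < cfg.min_depth:
            continue
        if r.alt_reads is not None and r.alt_reads < cfg.min_alt_reads:
            continue
        kept.append(r)
    if n_missing:
        log.warning("dropped %d records with missing allele fraction", n_missing)
    return kept


#: clonality windows on the fraction of junction-supporting reads
SV_AF_WINDOWS = {
    "DEL": ((0.40, 0.60), (0.90, 1.00)),
    "INV": ((0.40, 0.60), (0.90, 1.00)),
    "INS": ((0.40, 0.60), (0.90, 1.00)),
    "TRA": ((0.40, 0.60), (0.90, 1.00)),
    "DUP": ((0.20, 0.60),),
}


def filter_clonal_svs(svs: Sequence[StructuralVariant]) -> List[StructuralVariant]:
    """Keep SVs with clonal junction read fractions.

    DEL/INV/INS/TRA pass at [0.40, 0.60] or >= 0.90; DUP at [0.20, 0.60].
    """
    kept = []
    for s in svs:
        windows = SV_AF_WINDOWS.get(s.sv_type)
        if windows is None:
            raise ValueError(f"unknown sv_type {s.sv_type!r}")
        if math.isnan(s.junction_af):
            continue
        if any(lo <= s.junction_af <= hi for lo, hi in windows):
            kept.append(s)
    return kept


def exclude_blacklist(records: Sequence[MutationRecord],
                      intervals: Sequence[Tuple[str, int, int]]) -> List[MutationRecord]:
    """Drop records whose 1-based position lies inside any 0-based half-open interval."""
    if not intervals:
        return list(records)
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    starts = {c: np.array(sorted(s for s, _ in iv)) for c, iv in by_chrom.items()}
    # intervals may overlap; keep per-chrom arrays of (start, end) sorted by start
    sorted_iv = {c: sorted(iv) for c, iv in by_chrom.items()}

    def _hit(chrom: str, pos1: int) -> bool:
        ivs = sorted_iv.get(chrom)
        if not ivs:
            return False
        # 1-based pos falls in [start, end) iff start < pos1 <= end
        idx = int(np.searchsorted(starts[chrom], pos1, side="left"))
        # overlapping intervals are unordered by end: scan all with start < pos
        for s, e in ivs[:idx][::-1]:
            if pos1 <= e:
                return True
        return False

    return [r for r in records if not _hit(r.chrom, r.pos)]


def find_shared_mutations(catalogues: Mapping[str, Sequence[MutationRecord]]) -> pd.DataFrame:
    """Identical variants occurring in >= 2 sample catalogues.

    Returns a table with one row per shared (chrom, pos, ref, alt); carriers
    are reported but records are never removed from the catalogues.
    """
    if len(catalogues) < 2:
        raise ValueError("need at least two catalogues")
    carriers: Dict[Tuple, Dict[str, str]] = {}
    for sample_id, records in catalogues.items():
        for r in records:
            carriers.setdefault(r.key(), {})[sample_id] = r.donor_id
    rows = []
    for key, samples in sorted(carriers.items()):
        if len(samples) < 2:
            continue
        donors = set(samples.values())
        rows.append({
            "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
            "samples": ",".join(sorted(samples)),
            "n_samples": len(samples),
            "same_donor": len(donors) == 1,
        })
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "samples", "n_samples", "same_donor"])
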