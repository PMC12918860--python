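"""Mutational-motif enrichment, Fisher significance and the minimum estimate
of mutation load (MEML).

The statistic works on "scattered" single-base substitutions (no same-sample
neighbor within 10 bp).  For a motif with pyrimidine reference base B and
alternate base B' it forms four counts:

* ``mut_motif``  — scattered B→B' class mutations matching the motif on either
  strand,
* ``mut_class``  — all scattered B→B' class mutations,
* ``ctx_motif``  — motif-eligible positions (both strands) inside the ±window
  contexts centered on each class mutation,
* ``ctx_base``   — class-base positions (B plus its complement) in the same
  contexts,

from which enrichment = (mut_motif × ctx_base) / (mut_class × ctx_motif) and
MEML = mut_motif × (enrichment − 1)/enrichment when the one-sided Fisher test
is significant after Benjamini-Hochberg correction and enrichment > 1, else 0.
Context windows of different mutations are counted independently (overlaps
double-count) and each window includes its own central position.
"""
from __future__ import annotations

import math
from contextlib import nullcontext as _nullcontext
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalogue_io import MutationRecord
from .genome import IUPAC, IUPAC_COMPLEMENT, Reference, complement, encode, revcomp

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC-degenerate trinucleotide mutation motif.

    ``pattern`` is the 3-letter lower-case IUPAC context in pyrimidine
    representation; the central base (``ref_base``) is concrete and mutates to
    ``alt_base``.  Matching is strand-symmetric: purine-reference records are
    reverse-complemented before comparison.
    """

    name: str
    pattern: str
    ref_base: str
    alt_base: str
    parent: str | None = None

    def __post_init__(self):
        if len(self.pattern) != 3 or any(c not in IUPAC for c in self.pattern):
            raise ValueError(f"illegal IUPAC pattern {self.pattern!r}")
        if self.pattern[1] not in "ct":
            raise ValueError(
                f"central base of {self.pattern!r} must be a concrete pyrimidine"
            )
        if self.ref_base != self.pattern[1].upper():
            raise ValueError("ref_base must equal the pattern's central base")
        if self.alt_base == self.ref_base or self.alt_base not in "ACGT":
            raise ValueError(f"illegal alt_base {self.alt_base!r}")

    @property
    def mut_index(self) -> int:
        return 1

    def matches(self, trinuc: str | None, ref: str, alt: str) -> bool:
        """Does a mutation with plus-strand context ``trinuc`` match this motif?"""
        if trinuc is None or len(trinuc) != 3:
            return False
        trinuc = trinuc.upper()
        if ref in PURINES:
            trinuc, ref, alt = revcomp(trinuc), complement(ref), complement(alt)
        if ref != self.ref_base or alt != self.alt_base:
            return False
        return all(trinuc[i] in IUPAC[self.pattern[i]] for i in range(3))

    def matches_class(self, ref: str, alt: str) -> bool:
        """Is ref→alt this motif's base-change class (either strand)?"""
        if ref in PURINES:
            ref, alt = complement(ref), complement(alt)
        return ref == self.ref_base and alt == self.alt_base


def compile_motif(spec_text: str, name: str | None = None,
                  parent: str | None = None) -> MotifSpec:
    """Parse motif text of the form ``nCg>nTg`` into a MotifSpec."""
    parts = spec_text.split(">")
    if len(parts) != 2:
        raise ValueError(f"malformed motif {spec_text!r}: expected exactly one '>'")
    left, right = parts[0].strip(), parts[1].strip()
    if len(left) != 3 or len(right) != 3:
        raise ValueError(f"malformed motif {spec_text!r}: sides must be 3 bases")
    diffs = [i for i in range(3) if left[i].lower() != right[i].lower()]
    if diffs != [1]:
        raise ValueError(
            f"malformed motif {spec_text!r}: exactly the central base must change"
        )
    if left[1].lower() not in "ct" or right[1].lower() not in "acgt":
        raise ValueError(f"malformed motif {spec_text!r}: central bases must be "
                         "concrete with a pyrimidine reference")
    pattern = left.lower()
    if any(c not in IUPAC for c in pattern):
        raise ValueError(f"illegal IUPAC code in {spec_text!r}")
    return MotifSpec(
        name=name or spec_text,
        pattern=pattern,
        ref_base=left[1].upper(),
        alt_base=right[1].upper(),
        parent=parent,
    )


def default_registry() -> List[MotifSpec]:
    """The 11 shipped knowledge-based motifs and sub-motifs."""
    path = resources.files("somamotif").joinpath("data/motifs.tsv")
    return load_registry(path)


def load_registry(path) -> List[MotifSpec]:
    with resources.as_file(path) if hasattr(path, "joinpath") else _nullcontext(path) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    specs = []
    for d in df.to_dict(orient="records"):
        parent = d.get("parent")
        parent = None if parent in (None, "", "-", "NA") or pd.isna(parent) else parent
        specs.append(MotifSpec(name=d["name"], pattern=d["pattern"].lower(),
                               ref_base=d["ref_base"].upper(),
                               alt_base=d["alt_base"].upper(), parent=parent))
    return specs


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentCounts:
    mut_motif: int
    mut_class: int
    ctx_motif: int
    ctx_base: int

    def __post_init__(self):
        if not (0 <= self.mut_motif <= self.mut_class):
            raise ValueError("require 0 <= mut_motif <= mut_class")
        if not (0 <= self.ctx_motif <= self.ctx_base):
            raise ValueError("require 0 <= ctx_motif <= ctx_base")


@dataclass
class EnrichmentResult:
    counts: EnrichmentCounts
    enrichment: float
    motif_rate: float
    background_rate: float
    p: float = math.nan
    q: float = math.nan
    meml: float = 0.0


def select_scattered(records: Sequence[MutationRecord],
                     min_gap: int = 11) -> List[MutationRecord]:
    """Drop 'complex' mutations: any record with a same-sample neighbor
    within ``min_gap - 1`` bp (<=10 bp by default) on the same chromosome.
    All members of a cluster are removed."""
    by_chrom: Dict[Tuple[str, str], List[MutationRecord]] = {}
    for r in records:
        by_chrom.setdefault((r.sample_id, r.chrom), []).append(r)
    kept: List[MutationRecord] = []
    for group in by_chrom.values():
        group.sort(key=lambda r: r.pos)
        n = len(group)
        for i, r in enumerate(group):
            near_prev = i > 0 and r.pos - group[i - 1].pos < min_gap
            near_next = i < n - 1 and group[i + 1].pos - r.pos < min_gap
            if not (near_prev or near_next):
                kept.append(r)
    kept.sort(key=lambda r: (r.chrom, r.pos, r.alt))
    return kept


class ContextCounter:
    """Cached strand-symmetric motif/base position masks over a reference.

    For each motif the per-contig boolean masks (motif-eligible positions on
    either strand; class-base positions on either strand) are reduced to
    prefix sums so each mutation's ±window context is counted in O(1).
    """

    def __init__(self, reference: Reference):
        self.reference = reference
        self._motif_cum: Dict[Tuple[str, str, str], np.ndarray] = {}
        self._base_cum: Dict[Tuple[str, str], np.ndarray] = {}

    @staticmethod
    def _code_mask(enc: np.ndarray, code: str) -> np.ndarray:
        allowed = np.array([b in IUPAC[code] for b in "ACGT"], dtype=bool)
        mask = np.zeros(enc.shape, dtype=bool)
        valid = enc < 4
        mask[valid] = allowed[enc[valid]]
        return mask

    def motif_mask(self, chrom: str, motif: MotifSpec) -> np.ndarray:
        """Per-position indicator of motif eligibility on either strand."""
        enc = self.reference.encoded(chrom)
        n = enc.size
        mask = np.zeros(n, dtype=bool)
        if n < 3:
            return mask
        p0, p1, p2 = motif.pattern
        # plus strand: base == ref_base, flanks fit the pattern
        plus = self._code_mask(enc, p1).copy()
        plus[1:] &= self._code_mask(enc, p0)[:-1]
        plus[:-1] &= self._code_mask(enc, p2)[1:]
        plus[0] = plus[-1] = False
        # minus strand: position's reverse-complement context fits the pattern
        c0, c1, c2 = (IUPAC_COMPLEMENT[c] for c in (p0, p1, p2))
        minus = self._code_mask(enc, c1).copy()
        minus[:-1] &= self._code_mask(enc, c0)[1:]
        minus[1:] &= self._code_mask(enc, c2)[:-1]
        minus[0] = minus[-1] = False
        return plus | minus

    def _motif_cumsum(self, chrom: str, motif: MotifSpec) -> np.ndarray:
        key = (chrom, motif.pattern, motif.ref_base)
        cum = self._motif_cum.get(key)
        if cum is None:
            mask = self.motif_mask(chrom, motif)
            cum = np.concatenate(([0], np.cumsum(mask, dtype=np.int64)))
            self._motif_cum[key] = cum
        return cum

    def _base_cumsum(self, chrom: str, ref_base: str) -> np.ndarray:
        key = (chrom, ref_base)
        cum = self._base_cum.get(key)
        if cum is None:
            enc = self.reference.encoded(chrom)
            want = {"ACGT".index(ref_base), "ACGT".index(complement(ref_base))}
            mask = (enc == list(want)[0]) | (enc == list(want)[1])
            cum = np.concatenate(([0], np.cumsum(mask, dtype=np.int64)))
            self._base_cum[key] = cum
        return cum

    def window_counts(self, chrom: str, pos1: int, motif: MotifSpec,
                      window: int) -> Tuple[int, int]:
        """(motif, base) position counts in the ±window context of one mutation."""
        n = self.reference.length(chrom)
        lo = max(pos1 - 1 - window, 0)
        hi = min(pos1 + window, n)
        mcum = self._motif_cumsum(chrom, motif)
        bcum = self._base_cumsum(chrom, motif.ref_base)
        return int(mcum[hi] - mcum[lo]), int(bcum[hi] - bcum[lo])


def count_motif_and_context(records: Sequence[MutationRecord],
                            reference: Reference | ContextCounter,
                            motif: MotifSpec,
                            window: int = 20) -> EnrichmentCounts:
    """Counts quadruple for one motif over scattered class mutations.

    ``records`` must already be restricted to the motif's base-change class
    (both strand representations); windows overrunning contig ends are
    truncated.
    """
    counter = (reference if isinstance(reference, ContextCounter)
               else ContextCounter(reference))
    mut_class = len(records)
    mut_motif = 0
    ctx_motif = 0
    ctx_base = 0
    for r in records:
        if not motif.matches_class(r.ref, r.alt):
            raise ValueError(
                f"record {r.chrom}:{r.pos} {r.ref}>{r.alt} is not of class "
                f"{motif.ref_base}>{motif.alt_base}"
            )
        trinuc = counter.reference.trinucleotide(r.chrom, r.pos)
        if motif.matches(trinuc, r.ref, r.alt):
            mut_motif += 1
        m, b = counter.window_counts(r.chrom, r.pos, motif, window)
        ctx_motif += m
        ctx_base += b
    return EnrichmentCounts(mut_motif, mut_class, ctx_motif, ctx_base)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def compute_enrichment(counts: EnrichmentCounts) -> EnrichmentResult:
    """Enrichment and its two component rates; NaN when a denominator is zero."""
    c = counts
    motif_rate = c.mut_motif / c.ctx_motif if c.ctx_motif else math.nan
    background_rate = c.mut_class / c.ctx_base if c.ctx_base else math.nan
    if c.mut_class and c.ctx_motif:
        enrichment = (c.mut_motif * c.ctx_base) / (c.mut_class * c.ctx_motif)
    else:
        enrichment = math.nan
    return EnrichmentResult(counts=c, enrichment=enrichment,
                            motif_rate=motif_rate, background_rate=background_rate)


def fisher_enrichment_test(counts: EnrichmentCounts) -> float:
    """One-sided (greater) Fisher's exact p on
    [[mut_motif, mut_class - mut_motif], [ctx_motif, ctx_base - ctx_motif]]."""
    c = counts
    table = [[c.mut_motif, c.mut_class - c.mut_motif],
             [c.ctx_motif, c.ctx_base - c.ctx_motif]]
    if any(cell < 0 for row in table for cell in row):
        raise ValueError(f"negative cell in Fisher table {table}")
    return float(stats.fisher_exact(table, alternative="greater")[1])


def compute_meml(counts: EnrichmentCounts, enrichment: float, q: float,
                 alpha: float = 0.05) -> float:
    """mut_motif × (E-1)/E when E > 1 and q <= alpha, else 0."""
    if math.isnan(enrichment) or math.isnan(q):
        return 0.0
    if enrichment > 1.0 and q <= alpha:
        return counts.mut_motif * (enrichment - 1.0) / enrichment
    return 0.0


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, math.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def _pool_by_donor(catalogues: Mapping[str, Sequence[MutationRecord]],
                   dedup: bool = True) -> Dict[str, List[MutationRecord]]:
    pooled: Dict[str, List[MutationRecord]] = {}
    seen: Dict[str, set] = {}
    for sample_id in sorted(catalogues):
        for r in catalogues[sample_id]:
            donor = r.donor_id or sample_id
            if dedup:
                if r.key() in seen.setdefault(donor, set()):
                    continue
                seen[donor].add(r.key())
            pooled.setdefault(donor, []).append(r)
    return pooled


def motif_panel(catalogues: Mapping[str, Sequence[MutationRecord]],
                reference: Reference,
                registry: Sequence[MotifSpec] | None = None,
                level: str = "sample",
                window: int = 20,
                alpha: float = 0.05,
                bh_family: str = "units",
                dedup: bool = True) -> pd.DataFrame:
    """Full enrichment/MEML table: one row per (unit, motif).

    Units are the catalogue keys at sample level, or donor_id-pooled
    catalogues (identical variants deduplicated) at donor level.  Scattered
    selection, counting, enrichment and the one-sided Fisher test run per
    unit; BH correction is applied across all units within each motif
    (``bh_family="units"``) or across motifs within each unit
    (``bh_family="motifs"``).
    """
    if registry is None:
        registry = default_registry()
    if not registry:
        raise ValueError("motif registry is empty")
    if level == "donor":
        units = _pool_by_donor(catalogues, dedup=dedup)
    elif level == "sample":
        units = {k: list(v) for k, v in catalogues.items()}
    else:
        raise ValueError(f"unknown level {level!r}")

    counter = ContextCounter(reference)
    scattered = {unit: select_scattered(records) for unit, records in units.items()}
    rows = []
    for unit in sorted(units):
        snvs = [r for r in scattered[unit] if r.is_snv]
        for motif in registry:
            class_records = [r for r in snvs if motif.matches_class(r.ref, r.alt)]
            counts = count_motif_and_context(class_records, counter, motif, window)
            res = compute_enrichment(counts)
            p = (fisher_enrichment_test(counts)
                 if counts.mut_class and counts.ctx_base else math.nan)
            rows.append({
                "unit": unit, "motif": motif.name,
                "mut_motif": counts.mut_motif, "mut_class": counts.mut_class,
                "ctx_motif": counts.ctx_motif, "ctx_base": counts.ctx_base,
                "enrichment": res.enrichment, "motif_rate": res.motif_rate,
                "background_rate": res.background_rate, "p": p,
            })
    df = pd.DataFrame(rows)
    family = "motif" if bh_family == "units" else "unit"
    df["q"] = math.nan
    for _, idx in df.groupby(family).groups.items():
        df.loc[idx, "q"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    df["meml"] = [
        compute_meml(
            EnrichmentCounts(r.mut_motif, r.mut_class, r.ctx_motif, r.ctx_base),
            r.enrichment, r.q, alpha=alpha)
        for r in df.itertuples(index=False)
    ]
    return df


def donor_average_meml(sample_panel: pd.DataFrame,
                       sample_to_donor: Mapping[str, str]) -> pd.DataFrame:
    """Mean per-sample MEML per (donor, motif) from a sample-level panel."""
    df = sample_panel.copy()
    df["donor"] = df["unit"].map(lambda u: sample_to_donor.get(u, u))
    out = (df.groupby(["donor", "motif"], as_index=False)["meml"]
             .mean().rename(columns={"meml": "avg_meml"}))
    return out


def meml_prevalence(panel: pd.DataFrame) -> pd.Series:
    """Fraction of units with non-zero MEML, per motif."""
    return panel.groupby("motif")["meml"].apply(lambda s: float((s > 0).mean()))


def meml_pair_fraction(meml: float, records: Sequence[MutationRecord],
                       pair: str) -> float:
    """MEML as a percentage of all SNVs at the stated base pair.

    ``pair`` is "AT" or "CG"; scattered and complex mutations both count in
    the denominator.  NaN when the denominator is zero.
    """
    if pair not in ("AT", "CG"):
        raise ValueError("pair must be 'AT' or 'CG'")
    bases = frozenset(pair)
    denom = sum(1 for r in records if r.is_snv and r.ref in bases)
    if denom == 0:
        return math.nan
    return 100.0 * meml / denom
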