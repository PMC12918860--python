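"""Six-class substitution spectra and transcription-strand asymmetry.

Substitutions are folded to pyrimidine representation (C>A, C>G, C>T, T>A,
T>C, T>G).  A mutation is labelled *transcribed* when the pyrimidine of its
folded representation lies on the template strand of the covering gene and
*untranscribed* when it lies on the coding strand; intergenic records and
records under genes on both strands are excluded.  The asymmetry test is the
exact conditional binomial test (success probability 1/2 given the total),
with two-sided p = min(1, 2 x min(tails)).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .catalogue_io import MutationRecord
from .genome import Reference, complement, revcomp

log = logging.getLogger(__name__)

CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
STRANDS = ("transcribed", "untranscribed")
TRI_CONTEXTS = tuple(
    f"{a}[{cls}]{b}" for cls in CLASSES for a in "ACGT" for b in "ACGT"
)


def fold_class(ref: str, alt: str) -> str:
    """Pyrimidine-representation base-change class of an SNV."""
    if ref in "AG":
        ref, alt = complement(ref), complement(alt)
    cls = f"{ref}>{alt}"
    if cls not in CLASSES:
        raise ValueError(f"not a substitution class: {ref}>{alt}")
    return cls


def spectrum_6class(records: Sequence[MutationRecord]) -> Dict[str, float]:
    """Fractions over the six folded classes; all-zero (with a warning) on empty input."""
    counts = {cls: 0 for cls in CLASSES}
    n = 0
    for r in records:
        if not r.is_snv:
            raise ValueError("spectrum_6class expects SNVs only")
        counts[fold_class(r.ref, r.alt)] += 1
        n += 1
    if n == 0:
        log.warning("empty catalogue: returning all-zero spectrum")
        return {cls: 0.0 for cls in CLASSES}
    return {cls: counts[cls] / n for cls in CLASSES}


GeneInterval = Tuple[str, int, int, str]  # chrom, start0, end0, strand


def annotate_transcription_strand(records: Sequence[MutationRecord],
                                  genes: Sequence[GeneInterval]) -> List[str]:
    """Strand label per record: 'transcribed' | 'untranscribed' | 'excluded'."""
    by_chrom: Dict[str, List[Tuple[int, int, str]]] = {}
    for chrom, start, end, strand in genes:
        if strand not in "+-":
            raise ValueError(f"gene strand must be + or -, got {strand!r}")
        by_chrom.setdefault(chrom, []).append((start, end, strand))
    labels = []
    for r in records:
        if not r.is_snv:
            labels.append("excluded")
            continue
        covering = {
            strand
            for start, end, strand in by_chrom.get(r.chrom, ())
            if start < r.pos <= end
        }
        if len(covering) != 1:
            labels.append("excluded")
            continue
        gene_strand = covering.pop()
        pyrimidine_on_plus = r.ref in "CT"
        # template (transcribed) strand of a '+' gene is the minus strand
        template_is_plus = gene_strand == "-"
        labels.append(
            "transcribed" if pyrimidine_on_plus == template_is_plus
            else "untranscribed"
        )
    return labels


@dataclass
class StrandedSpectrum:
    """Folded class x strand counts plus the excluded-record count."""

    counts: Dict[Tuple[str, str], int]
    excluded: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.excluded

    def swapped(self) -> "StrandedSpectrum":
        return StrandedSpectrum(
            counts={(cls, STRANDS[1 - STRANDS.index(s)]): v
                    for (cls, s), v in self.counts.items()},
            excluded=self.excluded,
        )


def stranded_spectrum(records: Sequence[MutationRecord],
                      genes: Sequence[GeneInterval]) -> StrandedSpectrum:
    labels = annotate_transcription_strand(records, genes)
    counts = {(cls, s): 0 for cls in CLASSES for s in STRANDS}
    excluded = 0
    for r, label in zip(records, labels):
        if label == "excluded":
            excluded += 1
        else:
            counts[(fold_class(r.ref, r.alt), label)] += 1
    return StrandedSpectrum(counts=counts, excluded=excluded)


def binomial_two_sided(k: int, n: int) -> float:
    """Exact conditional two-sided p for equal rates: min(1, 2*min(tails)) at p=1/2."""
    if n == 0:
        return math.nan
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def strand_asymmetry_test(stranded: StrandedSpectrum) -> pd.DataFrame:
    """Per class: transcribed/untranscribed counts, log2 ratio (NaN if a count
    is 0) and the exact two-sided binomial p."""
    rows = []
    for cls in CLASSES:
        t = stranded.counts.get((cls, "transcribed"), 0)
        u = stranded.counts.get((cls, "untranscribed"), 0)
        ratio = math.log2(t / u) if t > 0 and u > 0 else math.nan
        rows.append({
            "class": cls, "transcribed": t, "untranscribed": u,
            "log2_ratio": ratio, "p": binomial_two_sided(t, t + u),
        })
    return pd.DataFrame(rows)


def stranded_trinucleotide_matrix(records: Sequence[MutationRecord],
                                  reference: Reference,
                                  genes: Sequence[GeneInterval]) -> pd.Series:
    """192-channel stranded trinucleotide counts.

    Index: "<5'>[<class>]<3'>-<strand>" with the context folded to pyrimidine
    representation; excluded records are not counted.
    """
    labels = annotate_transcription_strand(records, genes)
    index = [f"{ctx}-{s}" for ctx in TRI_CONTEXTS for s in STRANDS]
    counts = pd.Series(0, index=index, dtype=int)
    for r, label in zip(records, labels):
        if label == "excluded" or not r.is_snv:
            continue
        tri = reference.trinucleotide(r.chrom, r.pos)
        if tri is None:
            continue
        ref, alt = r.ref, r.alt
        if ref in "AG":
            tri, ref, alt = revcomp(tri), complement(ref), complement(alt)
        channel = f"{tri[0]}[{ref}>{alt}]{tri[2]}-{label}"
        counts[channel] += 1
    return counts
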