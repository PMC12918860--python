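"""Seeded synthetic cohorts with known ground truth.

Generates reference sequences (first-order Markov base composition with
controllable CpG/digram frequencies and planted homopolymer runs), SNV
catalogues mixing motif-targeted processes over a uniform background, slippage
and double-strand-break indels, SV cohorts with cross-donor hotspot loci, and
age-scaled ("clock-like") per-donor process intensities.  Every operation is
bit-reproducible for a given seed.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .catalogue_io import MutationRecord, StructuralVariant
from .genome import BASES, Reference, complement
from .indel_classes import classify_indel
from .motif_enrichment import MotifSpec, default_registry

BACKGROUND = "background"
PROCESS_SUFFIX = "-process"


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort."""

    seed: int
    donors: List[dict] = field(default_factory=list)
    labels: Dict[str, List[str]] = field(default_factory=dict)
    sv_hotspot: List[bool] = field(default_factory=list)
    telomere_kb: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def generate_reference(length: int,
                       gc: float = 0.5,
                       cpg_factor: float = 1.0,
                       homopolymer_runs: Sequence[Tuple[str, int, int]] | None = None,
                       seed: int = 0,
                       dinucleotide_factors: Mapping[str, float] | None = None,
                       name: str = "chr1") -> Reference:
    """A random contig with target GC content and digram control.

    Bases follow a first-order Markov chain whose transition probabilities are
    proportional to the stationary base frequencies scaled per digram:
    ``cpg_factor`` scales the C→G transition (0 guarantees zero CpG);
    ``dinucleotide_factors`` does the same for arbitrary digrams.
    ``homopolymer_runs`` is a list of (base, run_length, count) specs planted
    at non-overlapping positions with non-matching flanks (flank bases are
    chosen so no CpG is created).
    """
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if cpg_factor < 0:
        raise ValueError("cpg_factor must be >= 0")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    factors = {"CG": cpg_factor}
    if dinucleotide_factors:
        factors.update({k.upper(): v for k, v in dinucleotide_factors.items()})
    trans = np.tile(p, (4, 1))
    for digram, f in factors.items():
        i, j = BASES.index(digram[0]), BASES.index(digram[1])
        trans[i, j] *= f
    sums = trans.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("infeasible composition: a base has no allowed successor")
    cum = np.cumsum(trans / sums, axis=1)
    cum_rows = [row.tolist() for row in cum]
    u = rng.random(length).tolist()
    p_cum = np.cumsum(p).tolist()
    out = bytearray(length)
    prev = 0
    while u[0] >= p_cum[prev]:
        prev += 1
    out[0] = prev
    for i in range(1, length):
        row = cum_rows[prev]
        x = u[i]
        b = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
        out[i] = b
        prev = b
    s = list(bytes(out).translate(bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT"))
             .decode("ascii"))

    if homopolymer_runs:
        occupied = np.zeros(length, dtype=bool)
        for base, run_len, count in homopolymer_runs:
            base = base.upper()
            if base not in BASES or run_len < 1:
                raise ValueError(f"bad homopolymer spec ({base}, {run_len})")
            flank = "A" if base != "A" else "T"
            planted = 0
            for _ in range(200 * count):
                if planted >= count:
                    break
                start = int(rng.integers(2, length - run_len - 2))
                lo, hi = start - 1, start + run_len + 1
                if occupied[lo:hi].any():
                    continue
                s[lo] = flank
                s[hi - 1] = flank
                for i in range(start, start + run_len):
                    s[i] = base
                occupied[lo:hi] = True
                planted += 1
            if planted < count:
                raise ValueError(
                    f"could not plant {count} runs of {base}x{run_len}: "
                    "sequence too crowded")
    return Reference({name: "".join(s)})


# ---------------------------------------------------------------------------
# SNV catalogue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleFractionModel:
    """Mixture of clonal (truncated normal around 0.5), homozygous (uniform
    0.95-1.0) and subclonal (scaled beta over 0.05-0.45) allele fractions."""

    weights: Tuple[float, float, float] = (0.85, 0.10, 0.05)
    clonal_sd: float = 0.02
    subclonal_beta: Tuple[float, float] = (2.0, 3.0)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        w = w / w.sum()
        comp = rng.choice(3, size=n, p=w)
        af = np.empty(n)
        n_clonal = int((comp == 0).sum())
        clonal = rng.normal(0.5, self.clonal_sd, size=n_clonal)
        while True:  # sd 0.02: effectively never loops
            bad = (clonal < 0) | (clonal > 1)
            if not bad.any():
                break
            clonal[bad] = rng.normal(0.5, self.clonal_sd, size=int(bad.sum()))
        af[comp == 0] = clonal
        af[comp == 1] = rng.uniform(0.95, 1.0, size=int((comp == 1).sum()))
        a, b = self.subclonal_beta
        af[comp == 2] = 0.05 + 0.40 * rng.beta(a, b, size=int((comp == 2).sum()))
        return af

CLONAL_ONLY = AlleleFractionModel(weights=(0.9, 0.1, 0.0))


def motif_site_positions(reference: Reference, motif: MotifSpec):
    """All (chrom, 1-based pos, strand) where the motif can mutate."""
    from .motif_enrichment import ContextCounter

    counter = ContextCounter(reference)
    sites = []
    for chrom in reference:
        enc = reference.encoded(chrom)
        n = enc.size
        if n < 3:
            continue
        mask = counter.motif_mask(chrom, motif)
        ref_code = BASES.index(motif.ref_base)
        comp_code = BASES.index(complement(motif.ref_base))
        pos0 = np.flatnonzero(mask)
        for i in pos0:
            if enc[i] == ref_code:
                sites.append((chrom, int(i) + 1, "+"))
            elif enc[i] == comp_code:
                sites.append((chrom, int(i) + 1, "-"))
    return sites


def _resolve_motif(key, registry: Sequence[MotifSpec]) -> MotifSpec:
    if isinstance(key, MotifSpec):
        return key
    for m in registry:
        if m.name == key or m.name.split(">")[0] == key:
            return m
    raise ValueError(f"unknown motif {key!r}")


_CLASS_ALTS = {
    "C>A": ("C", "A"), "C>G": ("C", "G"), "C>T": ("C", "T"),
    "T>A": ("T", "A"), "T>C": ("T", "C"), "T>G": ("T", "G"),
}


def simulate_snv_catalogue(reference: Reference,
                           n_background: int,
                           process_counts: Mapping[object, int] | None = None,
                           af_model: AlleleFractionModel | None = None,
                           seed: int = 0,
                           sample_id: str = "S1",
                           donor_id: str = "D1",
                           background_spectrum: Mapping[str, float] | None = None,
                           registry: Sequence[MotifSpec] | None = None,
                           min_spacing: int = 0,
                           ) -> Tuple[List[MutationRecord], List[str]]:
    """SNVs from motif-targeted processes over a uniform background.

    Each process draws sites uniformly (without replacement, both strands)
    from its motif's eligible positions and applies the motif's base change;
    background mutations draw a class from ``background_spectrum`` (uniform
    over the six folded classes by default) and a site uniformly among
    class-eligible bases.  ``min_spacing`` > 0 additionally rejects any site
    closer than that many bp to an already-placed mutation (so the whole
    catalogue survives the scattered-mutation selection when >= 11).
    Returns records sorted by position together with the aligned truth labels.
    """
    import bisect

    rng = np.random.default_rng(seed)
    af_model = af_model or AlleleFractionModel()
    registry = list(registry) if registry is not None else default_registry()
    process_counts = process_counts or {}
    used: set = set()
    placed: Dict[str, List[int]] = {}
    events: List[Tuple[str, int, str, str, str]] = []  # chrom,pos,ref,alt,label

    def blocked(chrom: str, pos: int) -> bool:
        if (chrom, pos) in used:
            return True
        if min_spacing <= 0:
            return False
        lst = placed.setdefault(chrom, [])
        i = bisect.bisect_left(lst, pos)
        for j in (i - 1, i):
            if 0 <= j < len(lst) and abs(lst[j] - pos) < min_spacing:
                return True
        return False

    def occupy(chrom: str, pos: int) -> None:
        used.add((chrom, pos))
        if min_spacing > 0:
            bisect.insort(placed.setdefault(chrom, []), pos)

    for key in process_counts:
        motif = _resolve_motif(key, registry)
        count = process_counts[key]
        sites = motif_site_positions(reference, motif)
        order = rng.permutation(len(sites))
        label = motif.name.split(">")[0] + PROCESS_SUFFIX
        taken = 0
        for i in order:
            if taken >= count:
                break
            chrom, pos, strand = sites[i]
            if blocked(chrom, pos):
                continue
            if strand == "+":
                ref, alt = motif.ref_base, motif.alt_base
            else:
                ref, alt = complement(motif.ref_base), complement(motif.alt_base)
            events.append((chrom, pos, ref, alt, label))
            occupy(chrom, pos)
            taken += 1
        if taken < count:
            raise ValueError(
                f"insufficient sites for motif {motif.name}: "
                f"need {count}, placed {taken} of {len(sites)} candidates")

    if n_background:
        spectrum = background_spectrum or {c: 1 / 6 for c in _CLASS_ALTS}
        classes = sorted(spectrum)
        probs = np.array([spectrum[c] for c in classes], dtype=float)
        probs = probs / probs.sum()
        base_positions: Dict[Tuple[str, str], np.ndarray] = {}
        for chrom in reference:
            enc = reference.encoded(chrom)
            for b in BASES:
                base_positions[(chrom, b)] = np.flatnonzero(enc == BASES.index(b)) + 1
        chroms = sorted(reference)
        drawn = 0
        attempts = 0
        while drawn < n_background:
            attempts += 1
            if attempts > 50 * n_background:
                raise ValueError("could not place background mutations without collision")
            cls = classes[int(rng.choice(len(classes), p=probs))]
            pyr, alt_pyr = _CLASS_ALTS[cls]
            pur = complement(pyr)
            # choose a contig weighted by eligible sites, then a strand-folded site
            counts = np.array([
                base_positions[(c, pyr)].size + base_positions[(c, pur)].size
                for c in chroms], dtype=float)
            chrom = chroms[int(rng.choice(len(chroms), p=counts / counts.sum()))]
            pyr_pos = base_positions[(chrom, pyr)]
            pur_pos = base_positions[(chrom, pur)]
            j = int(rng.integers(pyr_pos.size + pur_pos.size))
            if j < pyr_pos.size:
                pos, ref, alt = int(pyr_pos[j]), pyr, alt_pyr
            else:
                pos = int(pur_pos[j - pyr_pos.size])
                ref, alt = pur, complement(alt_pyr)
            if blocked(chrom, pos):
                continue
            occupy(chrom, pos)
            events.append((chrom, pos, ref, alt, BACKGROUND))
            drawn += 1

    order = sorted(range(len(events)), key=lambda i: (events[i][0], events[i][1]))
    afs = af_model.draw(rng, len(events))
    records, labels = [], []
    for rank, i in enumerate(order):
        chrom, pos, ref, alt, label = events[i]
        records.append(MutationRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                      af=float(afs[rank]), sample_id=sample_id,
                                      donor_id=donor_id))
        labels.append(label)
    return records, labels


# ---------------------------------------------------------------------------
# indels
# ---------------------------------------------------------------------------

def _maximal_runs(reference: Reference, min_len: int = 2):
    """(chrom, start0, length, base) for all maximal single-base runs."""
    runs = []
    for chrom in reference:
        enc = reference.encoded(chrom)
        n = enc.size
        if n == 0:
            continue
        change = np.flatnonzero(enc[1:] != enc[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [n]))
        for s, e in zip(starts, ends):
            if e - s >= min_len and enc[s] < 4 and s > 0:
                runs.append((chrom, int(s), int(e - s), BASES[enc[s]]))
    return runs


def simulate_indels(reference: Reference,
                    slippage_n: int,
                    dsb_n: int,
                    mh_probs: Mapping[int, float] | None = None,
                    seed: int = 0,
                    sample_id: str = "S1",
                    donor_id: str = "D1",
                    min_run: int = 3,
                    af_model: AlleleFractionModel | None = None,
                    ) -> Tuple[List[MutationRecord], List[str]]:
    """Slippage 1 bp indels in homonucleotide runs plus >=5 bp DSB deletions.

    Slippage events pick runs with probability proportional to run length
    (without replacement); DSB deletions are 5-24 bp with microhomology drawn
    from ``mh_probs`` (default {0: 0.5, 1: 0.35, 2: 0.15}) and are placed by
    rejection so the classified microhomology matches the draw.
    """
    rng = np.random.default_rng(seed)
    af_model = af_model or AlleleFractionModel()
    mh_probs = dict(mh_probs) if mh_probs else {0: 0.5, 1: 0.35, 2: 0.15}
    mhs = sorted(mh_probs)
    mh_p = np.array([mh_probs[m] for m in mhs], dtype=float)
    mh_p = mh_p / mh_p.sum()

    events: List[Tuple[MutationRecord, str]] = []
    if slippage_n:
        runs = _maximal_runs(reference, min_len=min_run)
        if not runs:
            raise ValueError(f"no homonucleotide runs of >={min_run} bp in reference")
        if len(runs) < slippage_n:
            raise ValueError(
                f"only {len(runs)} runs available for {slippage_n} slippage events")
        weights = np.array([r[2] for r in runs], dtype=float)
        idx = rng.choice(len(runs), size=slippage_n, replace=False,
                         p=weights / weights.sum())
        is_del = rng.random(slippage_n) < 0.5
        for i, deln in zip(idx, is_del):
            chrom, s0, _, base = runs[i]
            anchor = reference[chrom][s0 - 1]
            if deln:
                rec = MutationRecord(chrom=chrom, pos=s0, ref=anchor + base,
                                     alt=anchor, sample_id=sample_id,
                                     donor_id=donor_id)
            else:
                rec = MutationRecord(chrom=chrom, pos=s0, ref=anchor,
                                     alt=anchor + base, sample_id=sample_id,
                                     donor_id=donor_id)
            events.append((rec, "slippage"))

    used = {(r.chrom, r.pos) for r, _ in events}
    for _ in range(dsb_n):
        target_mh = mhs[int(rng.choice(len(mhs), p=mh_p))]
        placed = False
        for _attempt in range(20000):
            chrom = sorted(reference)[int(rng.integers(len(reference)))]
            n = reference.length(chrom)
            L = int(rng.integers(5, 25))
            pos = int(rng.integers(30, n - L - 30))  # 1-based anchor
            if (chrom, pos) in used:
                continue
            contig = reference[chrom]
            rec = MutationRecord(chrom=chrom, pos=pos,
                                 ref=contig[pos - 1 : pos + L],
                                 alt=contig[pos - 1], sample_id=sample_id,
                                 donor_id=donor_id)
            ch = classify_indel(rec, reference)
            if ch.family == "repeat" and ch.repeat_units == 0:
                got = 0
            elif ch.family == "microhomology":
                got = ch.mh_len
            else:
                continue
            if got == target_mh:
                events.append((rec, "DSB-deletion"))
                used.add((chrom, pos))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place a DSB deletion with microhomology {target_mh}")

    events.sort(key=lambda e: (e[0].chrom, e[0].pos))
    from dataclasses import replace as _replace
    afs = af_model.draw(rng, len(events))
    records = [_replace(rec, af=float(a)) for (rec, _), a in zip(events, afs)]
    labels = [label for _, label in events]
    return records, labels


# ---------------------------------------------------------------------------
# SV cohort
# ---------------------------------------------------------------------------

DEFAULT_SV_TYPE_PROBS = {"DEL": 0.55, "DUP": 0.25, "INS": 0.08,
                         "INV": 0.07, "TRA": 0.05}


def simulate_sv_cohort(n_donors: int,
                       per_donor: int,
                       hotspot_spec: Tuple[int, int] = (2, 400_000),
                       seed: int = 0,
                       chrom: str = "chr1",
                       chrom_length: int = 100_000_000,
                       hotspot_fraction: float = 0.5,
                       type_probs: Mapping[str, float] | None = None,
                       ) -> Tuple[List[StructuralVariant], List[bool]]:
    """SVs for a cohort with k shared hotspot loci.

    A ``hotspot_fraction`` of each donor's SVs place their first breakpoint
    within ``radius`` of one of ``k`` loci shared across donors (truth label
    True); the rest are uniform.  Deletions dominate the type mix, then
    duplications.
    """
    k, radius = hotspot_spec
    if k < 0:
        raise ValueError("hotspot locus count must be >= 0")
    rng = np.random.default_rng(seed)
    probs = dict(type_probs or DEFAULT_SV_TYPE_PROBS)
    types = sorted(probs)
    tp = np.array([probs[t] for t in types], dtype=float)
    tp = tp / tp.sum()
    loci = (rng.integers(2 * radius + 1, chrom_length - 2 * radius, size=k)
            if k else np.array([], dtype=int))
    svs: List[StructuralVariant] = []
    truth: List[bool] = []
    for d in range(n_donors):
        donor = f"D{d + 1:02d}"
        for _ in range(per_donor):
            sv_type = types[int(rng.choice(len(types), p=tp))]
            at_hotspot = k > 0 and rng.random() < hotspot_fraction
            if at_hotspot:
                locus = int(loci[int(rng.integers(k))])
                pos1 = locus + int(rng.integers(-radius, radius + 1))
            else:
                pos1 = int(rng.integers(1, chrom_length - 2_000_000))
            if sv_type == "TRA":
                chrom2 = "chr2"
                pos2 = int(rng.integers(1, chrom_length))
            else:
                chrom2 = chrom
                pos2 = pos1 + int(rng.integers(10_000, 1_000_000))
            if sv_type == "DUP":
                af = float(rng.uniform(0.25, 0.55))
            else:
                af = float(rng.uniform(0.44, 0.56)) if rng.random() < 0.8 \
                    else float(rng.uniform(0.92, 1.0))
            svs.append(StructuralVariant(
                sv_type=sv_type, chrom1=chrom, pos1=pos1,
                chrom2=chrom2, pos2=pos2, junction_af=af,
                sample_id=f"{donor}-a", donor_id=donor))
            truth.append(bool(at_hotspot))
    return svs, truth


# ---------------------------------------------------------------------------
# clock
# ---------------------------------------------------------------------------

def simulate_clock(ages: Mapping[str, float] | Sequence[float],
                   rate_per_year: Mapping[str, float],
                   seed: int = 0,
                   ) -> Tuple[Dict[str, Dict[str, int]], Dict[str, float]]:
    """Poisson process counts with mean rate x age, plus telomere lengths.

    Divisions per donor follow a linear-in-age trend with noise and the
    telomere length is 8.0 kb minus 0.1 kb per division (the inverse of
    ``estimate_divisions`` under default TelomereParams) plus noise.
    Returns ({donor: {process: count}}, {donor: telomere_kb}).
    """
    if not isinstance(ages, Mapping):
        ages = {f"D{i + 1:02d}": a for i, a in enumerate(ages)}
    if any(a <= 0 for a in ages.values()):
        raise ValueError("ages must be positive")
    rng = np.random.default_rng(seed)
    counts: Dict[str, Dict[str, int]] = {}
    telomere: Dict[str, float] = {}
    for donor in sorted(ages):
        age = ages[donor]
        counts[donor] = {
            proc: int(rng.poisson(rate * age))
            for proc, rate in sorted(rate_per_year.items())
        }
        divisions = float(np.clip(0.55 * age + rng.normal(0, 4), 5, 78))
        telomere[donor] = float(max(0.5, 8.0 - divisions / 10 + rng.normal(0, 0.1)))
    return counts, telomere
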