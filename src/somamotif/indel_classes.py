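"""ID83-style indel classification and the headline indel groupings.

Channels follow the COSMIC ID83 conventions:

* 1 bp indels by folded base (C, T) and reference homonucleotide run length —
  for deletions the run includes the deleted base (classes 1..5, 6+), for
  insertions it is the count of the inserted base already present (0..4, 5+);
* longer repeat-mediated indels by size class (2, 3, 4, 5+) and the number of
  additional copies of the event sequence adjacent in the reference;
* non-repeat deletions >=2 bp by the maximum microhomology between either
  edge of the deleted sequence and the flanking reference.

Every classified indel maps to exactly one of the 83 channels.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .catalogue_io import DEL, INS, MutationRecord
from .genome import Reference, complement


@dataclass(frozen=True)
class IndelChannel:
    kind: str                 # INS | DEL
    length: int               # event length in bp
    size_class: str           # "1" | "2" | "3" | "4" | "5+"
    family: str               # "homopolymer" | "repeat" | "microhomology"
    base: str | None = None   # folded base for 1 bp events
    run_len: int | None = None      # reference run length for 1 bp events
    repeat_units: int | None = None # extra adjacent copies for >=2 bp events
    mh_len: int | None = None       # microhomology length for MH deletions
    name: str = ""


def _size_class(length: int) -> str:
    return str(length) if length < 5 else "5+"


def _event_seq(record: MutationRecord) -> str:
    """Inserted or deleted sequence of a VCF-anchored pure indel."""
    if record.var_class == INS:
        if not record.alt.startswith(record.ref) or len(record.ref) != 1:
            raise ValueError("insertion is not VCF-anchored")
        return record.alt[1:]
    if record.var_class == DEL:
        if not record.ref.startswith(record.alt) or len(record.alt) != 1:
            raise ValueError("deletion is not VCF-anchored")
        return record.ref[1:]
    raise ValueError("not an indel")


def left_align(record: MutationRecord, reference: Reference) -> MutationRecord:
    """Shift a VCF-anchored indel to its leftmost equivalent position."""
    seq = _event_seq(record)
    contig = reference[record.chrom]
    if contig[record.pos - 1] != record.ref[0]:
        raise ValueError(
            f"reference mismatch at {record.chrom}:{record.pos}: "
            f"expected {record.ref[0]}, found {contig[record.pos - 1]}"
        )
    if record.var_class == DEL and contig[record.pos : record.pos + len(seq)] != seq:
        raise ValueError(f"reference mismatch for deletion at {record.chrom}:{record.pos}")
    pos = record.pos
    while pos > 1 and contig[pos - 1] == seq[-1]:
        seq = contig[pos - 1] + seq[:-1]
        pos -= 1
    if pos == record.pos:
        return record
    anchor = contig[pos - 1]
    if record.var_class == INS:
        return replace(record, pos=pos, ref=anchor, alt=anchor + seq)
    return replace(record, pos=pos, ref=anchor + seq, alt=anchor)


def _run_length_at(contig: str, start0: int, base: str) -> int:
    n = len(contig)
    i = start0
    while i < n and contig[i] == base:
        i += 1
    return i - start0


def _count_copies(contig: str, start0: int, seq: str) -> int:
    """Full adjacent copies of ``seq`` in the reference starting at start0."""
    n, L, count = len(contig), len(seq), 0
    i = start0
    while i + L <= n and contig[i : i + L] == seq:
        count += 1
        i += L
    return count


def microhomology(deleted: str, upstream: str, downstream: str) -> int:
    """Max identity between the deleted sequence's edges and flanking reference.

    Checked as: longest prefix of the deleted sequence matching the reference
    immediately downstream of the deletion, and longest suffix matching the
    reference immediately upstream; capped at len(deleted) - 1.
    """
    cap = len(deleted) - 1
    fwd = 0
    for i in range(min(cap, len(downstream))):
        if deleted[i] != downstream[i]:
            break
        fwd += 1
    rev = 0
    for i in range(min(cap, len(upstream))):
        if deleted[-1 - i] != upstream[-1 - i]:
            break
        rev += 1
    return max(fwd, rev)


def classify_indel(record: MutationRecord, reference: Reference) -> IndelChannel:
    """Assign one of the 83 channels to a (left-aligned) indel."""
    record = left_align(record, reference)
    seq = _event_seq(record)
    contig = reference[record.chrom]
    L = len(seq)
    kind = record.var_class
    if L == 1:
        base = seq
        if kind == DEL:
            # deleted base sits at 0-based record.pos; run includes it
            run = 1 + _run_length_at(contig, record.pos + 1, base)
            cls = str(run) if run <= 5 else "6+"
        else:
            run = _run_length_at(contig, record.pos, base)
            cls = str(run) if run <= 4 else "5+"
        folded = complement(base) if base in "AG" else base
        return IndelChannel(kind=kind, length=1, size_class="1",
                            family="homopolymer", base=folded, run_len=run,
                            name=f"{kind}_{folded}_1_{cls}")
    size = _size_class(L)
    if kind == DEL:
        copies = _count_copies(contig, record.pos + L, seq)
        if copies >= 1:
            rep_cls = str(copies) if copies <= 4 else "5+"
            return IndelChannel(kind=kind, length=L, size_class=size,
                                family="repeat", repeat_units=copies,
                                name=f"DEL_{size}_R_{rep_cls}")
        upstream = contig[: record.pos]
        downstream = contig[record.pos + L :]
        mh = microhomology(seq, upstream, downstream)
        if mh >= 1:
            mh_cap = {"2": 1, "3": 2, "4": 3, "5+": 5}[size]
            mh_cls = str(min(mh, mh_cap))
            if size == "5+" and mh >= 5:
                mh_cls = "5+"
            return IndelChannel(kind=kind, length=L, size_class=size,
                                family="microhomology", mh_len=mh,
                                name=f"DEL_{size}_MH_{mh_cls}")
        return IndelChannel(kind=kind, length=L, size_class=size,
                            family="repeat", repeat_units=0,
                            name=f"DEL_{size}_R_0")
    copies = _count_copies(contig, record.pos, seq)
    rep_cls = str(copies) if copies <= 4 else "5+"
    return IndelChannel(kind=kind, length=L, size_class=size, family="repeat",
                        repeat_units=copies, name=f"INS_{size}_R_{rep_cls}")


def id83_channels() -> List[str]:
    """Canonical ordering of all 83 channel names."""
    names = []
    for base in ("C", "T"):
        names += [f"DEL_{base}_1_{c}" for c in ["1", "2", "3", "4", "5", "6+"]]
    for base in ("C", "T"):
        names += [f"INS_{base}_1_{c}" for c in ["0", "1", "2", "3", "4", "5+"]]
    for size in ("2", "3", "4", "5+"):
        names += [f"DEL_{size}_R_{c}" for c in ["0", "1", "2", "3", "4", "5+"]]
    for size in ("2", "3", "4", "5+"):
        names += [f"INS_{size}_R_{c}" for c in ["0", "1", "2", "3", "4", "5+"]]
    names += ["DEL_2_MH_1"]
    names += [f"DEL_3_MH_{c}" for c in ["1", "2"]]
    names += [f"DEL_4_MH_{c}" for c in ["1", "2", "3"]]
    names += [f"DEL_5+_MH_{c}" for c in ["1", "2", "3", "4", "5+"]]
    return names


def id83_matrix(records: Sequence[MutationRecord],
                reference: Reference) -> pd.Series:
    """Counts over the 83 channels for one catalogue of indels."""
    counts = pd.Series(0, index=id83_channels(), dtype=int)
    for r in records:
        if r.is_snv:
            continue
        counts[classify_indel(r, reference).name] += 1
    return counts


def summarize_indel_groups(records: Sequence[MutationRecord],
                           reference: Reference) -> pd.DataFrame:
    """Per-sample counts of the headline indel groups.

    Groups: total indels; 1 bp indels in homonucleotide runs of >=5 (run
    includes the deleted base for deletions, existing bases for insertions);
    deletions >=5 bp without and with microhomology (repeat-mediated >=5 bp
    deletions fall in neither microhomology group).
    """
    per_sample: Dict[str, Dict[str, int]] = {}
    for r in records:
        if r.is_snv:
            continue
        ch = classify_indel(r, reference)
        g = per_sample.setdefault(r.sample_id, {
            "total": 0, "homonucleotide_run": 0,
            "del_ge5_no_mh": 0, "del_ge5_mh": 0,
        })
        g["total"] += 1
        if ch.family == "homopolymer" and (ch.run_len or 0) >= 5:
            g["homonucleotide_run"] += 1
        if ch.kind == DEL and ch.length >= 5:
            if ch.family == "microhomology":
                g["del_ge5_mh"] += 1
            elif ch.family == "repeat" and ch.repeat_units == 0:
                g["del_ge5_no_mh"] += 1
    rows = [{"sample_id": s, **g} for s, g in sorted(per_sample.items())]
    return pd.DataFrame(rows, columns=["sample_id", "total", "homonucleotide_run",
                                       "del_ge5_no_mh", "del_ge5_mh"])
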