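"""Hairpin-aware miRNA quantification from collapsed reads.

Collapsed reads are aligned to the precursor catalog allowing at most one
mismatch (all-hits, forward strand).  Precursors whose read distribution is
inconsistent with Drosha/Dicer processing — fewer than three arm reads per
loop read — are discarded; loop reads on surviving precursors are excluded
from quantification.  Remaining reads are assigned to the mature annotation
on the same arm with the largest overlap; well-supported read clusters on
unannotated arms become novel matures named by the -5p/-3p convention.
Reads hitting no precursor are classified by cascade re-alignment against
auxiliary references (genome, other non-coding RNA, cDNA).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hairpin import Catalog, HairpinPrecursor, Interval, MatureAnnotation
from .readprep import CollapsedRead

__all__ = [
    "PrecursorAlignment",
    "QuantResult",
    "align_to_precursors",
    "hairpin_consistency_filter",
    "assign_counts",
    "name_novel",
    "cascade_classify",
    "quantify_samples",
]

MIN_MATURE_OVERLAP = 10
MIN_NOVEL_CLUSTER = 5


@dataclass(frozen=True)
class PrecursorAlignment:
    read_sequence: str
    precursor_id: str
    offset: int
    mismatches: int
    region: str  # arm5 | loop | arm3


@dataclass
class QuantResult:
    counts: pd.DataFrame  # matures x samples, integer
    retained: list[str]
    discarded: dict[str, tuple[int, int]]  # precursor -> (arm, loop) multiplicity
    novel: list[MatureAnnotation]
    unassigned: int = 0
    multi_precursor_reads: list[str] = field(default_factory=list)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().replace("T", "U").encode(), dtype=np.uint8)


def align_to_precursors(
    reads: list[CollapsedRead] | list[str],
    catalog: Catalog,
    max_mismatch: int = 1,
) -> list[PrecursorAlignment]:
    """All forward-strand hits with Hamming distance <= max_mismatch.

    Exact-hit preference: if a read has any 0-mismatch hit anywhere in the
    catalog, its 1-mismatch hits are dropped.  Region labels follow the
    majority-overlap rule of :meth:`HairpinPrecursor.region_of`.
    """
    seqs = [r.sequence if isinstance(r, CollapsedRead) else r for r in reads]
    enc_prec = {p.id: _encode(p.sequence) for p in catalog}
    hits: dict[str, list[PrecursorAlignment]] = defaultdict(list)
    for seq in dict.fromkeys(seqs):  # unique, order kept
        enc = _encode(seq)
        L = len(enc)
        for p in catalog:
            ep = enc_prec[p.id]
            if len(ep) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ep, L)
            mism = (windows != enc).sum(axis=1)
            for off in np.nonzero(mism <= max_mismatch)[0]:
                hits[seq].append(
                    PrecursorAlignment(
                        read_sequence=seq,
                        precursor_id=p.id,
                        offset=int(off),
                        mismatches=int(mism[off]),
                        region=p.region_of((int(off), int(off) + L)),
                    )
                )
    out: list[PrecursorAlignment] = []
    for seq in dict.fromkeys(seqs):
        h = hits.get(seq, [])
        if any(a.mismatches == 0 for a in h):
            h = [a for a in h if a.mismatches == 0]
        out.extend(sorted(h, key=lambda a: (a.precursor_id, a.offset, a.mismatches)))
    return out


def hairpin_consistency_filter(
    alignments: list[PrecursorAlignment],
    read_counts: dict[str, int],
    ratio: float = 3.0,
) -> tuple[list[str], dict[str, tuple[int, int]]]:
    """Retain precursors with arm reads >= ratio x loop reads.

    Multiplicities are collapsed-read counts pooled over samples; a
    precursor exactly at the ratio is retained ("at least 3:1").
    """
    arm: dict[str, int] = defaultdict(int)
    loop: dict[str, int] = defaultdict(int)
    for a in alignments:
        c = read_counts.get(a.read_sequence, 0)
        if a.region == "loop":
            loop[a.precursor_id] += c
        else:
            arm[a.precursor_id] += c
    retained, discarded = [], {}
    for pid in sorted(set(arm) | set(loop)):
        if arm[pid] >= ratio * loop[pid]:
            retained.append(pid)
        else:
            discarded[pid] = (arm[pid], loop[pid])
    return retained, discarded


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def name_novel(
    precursor: HairpinPrecursor,
    arm: str,
    read_stack: list[tuple[Interval, int]],
    known: list[MatureAnnotation],
    min_cluster: int = MIN_NOVEL_CLUSTER,
) -> MatureAnnotation | None:
    """Novel mature from a cluster of reads on an unannotated arm.

    The cluster must carry at least ``min_cluster`` reads in total; its
    interval is the modal (highest-count) read interval.  The name reuses
    the opposite-arm mature's name with the -5p/-3p suffix swapped, or
    falls back to the precursor id plus the arm suffix.
    """
    total = sum(c for _, c in read_stack)
    if total < min_cluster or not read_stack:
        return None
    interval = max(read_stack, key=lambda ic: (ic[1], -ic[0][0]))[0]
    suffix = "-5p" if arm == "arm5" else "-3p"
    other = "arm3" if arm == "arm5" else "arm5"
    opposite = [a for a in known if a.precursor_id == precursor.id and a.arm == other]
    if opposite:
        base = opposite[0].name
        for old in ("-5p", "-3p"):
            if base.endswith(old):
                base = base[: -len(old)]
                break
        name = base + suffix
    else:
        name = precursor.id + suffix
    return MatureAnnotation(
        name=name, precursor_id=precursor.id, interval=interval, arm=arm, novel=True
    )


def assign_counts(
    alignments: list[PrecursorAlignment],
    catalog: Catalog,
    annotations: list[MatureAnnotation],
    sample_counts: dict[str, dict[str, int]],  # read seq -> {sample: count}
    retained: list[str],
    discarded: dict[str, tuple[int, int]] | None = None,
    samples: list[str] | None = None,
    min_overlap: int = MIN_MATURE_OVERLAP,
    min_novel_cluster: int = MIN_NOVEL_CLUSTER,
) -> QuantResult:
    """Accumulate per-sample mature counts from arm reads on retained
    precursors.

    Loop reads contribute nothing.  A read aligning to several redundant
    precursors that carry the same mature name is counted once for that
    name.  Arm reads with no qualifying mature are clustered per
    (precursor, arm) and routed to :func:`name_novel`.
    """
    retained_set = set(retained)
    by_prec: dict[str, list[MatureAnnotation]] = defaultdict(list)
    for a in annotations:
        by_prec[a.precursor_id].append(a)
    if samples is None:
        samples = sorted({s for d in sample_counts.values() for s in d})

    read_hits: dict[str, list[PrecursorAlignment]] = defaultdict(list)
    for a in alignments:
        if a.precursor_id in retained_set and a.region != "loop":
            read_hits[a.read_sequence].append(a)

    assigned: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    novel_stacks: dict[tuple[str, str], dict[Interval, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    novel_members: dict[tuple[str, str], list[str]] = defaultdict(list)
    unassigned = 0
    multi: set[str] = set()

    for seq, hits in read_hits.items():
        per_sample = sample_counts.get(seq, {})
        total = sum(per_sample.values())
        names: set[str] = set()
        orphan_hits: list[PrecursorAlignment] = []
        for a in hits:
            interval = (a.offset, a.offset + len(seq))
            cands = [
                m
                for m in by_prec[a.precursor_id]
                if m.arm == a.region and _overlap(m.interval, interval) >= min_overlap
            ]
            if cands:
                best = max(cands, key=lambda m: (_overlap(m.interval, interval), m.name))
                names.add(best.name)
            else:
                orphan_hits.append(a)
        if len(names) > 1 or (names and len(hits) > 1):
            multi.add(seq)
        if names:
            for name in names:
                for s, c in per_sample.items():
                    assigned[name][s] += c
        elif orphan_hits:
            a = orphan_hits[0]  # cluster on the first qualifying precursor/arm
            key = (a.precursor_id, a.region)
            novel_stacks[key][(a.offset, a.offset + len(seq))] += total
            novel_members[key].append(seq)
        else:
            unassigned += total

    novel: list[MatureAnnotation] = []
    for (pid, arm), stack in sorted(novel_stacks.items()):
        ann = name_novel(
            catalog[pid], arm, sorted(stack.items()), annotations, min_novel_cluster
        )
        if ann is None:
            unassigned += sum(stack.values())
            continue
        novel.append(ann)
        for seq in novel_members[(pid, arm)]:
            for s, c in sample_counts.get(seq, {}).items():
                assigned[ann.name][s] += c

    all_names = sorted(set(assigned) | {a.name for a in annotations if a.precursor_id in retained_set})
    counts = pd.DataFrame(0, index=all_names, columns=samples, dtype=int)
    for name, per_sample in assigned.items():
        for s, c in per_sample.items():
            counts.loc[name, s] += c
    return QuantResult(
        counts=counts,
        retained=sorted(retained_set),
        discarded=dict(discarded or {}),
        novel=novel,
        unassigned=unassigned,
        multi_precursor_reads=sorted(multi),
    )


def cascade_classify(
    reads: list[CollapsedRead],
    references: dict[str, list[str]],
    max_mismatch: int = 1,
) -> dict[str, int]:
    """Assign each unmapped read to the first reference with a <=1-mismatch
    hit; tally collapsed multiplicities.

    ``references`` is an ordered mapping, canonically
    ``{"genome_only": [...], "other_ncRNA": [...], "cDNA": [...]}``.
    """
    tally = {name: 0 for name in references}
    tally["unmapped"] = 0
    enc_refs = {
        name: [_encode(s) for s in seqs] for name, seqs in references.items()
    }
    for r in reads:
        enc = _encode(r.sequence)
        L = len(enc)
        placed = False
        for name, encs in enc_refs.items():
            for ref in encs:
                if len(ref) < L:
                    continue
                win = np.lib.stride_tricks.sliding_window_view(ref, L)
                if ((win != enc).sum(axis=1) <= max_mismatch).any():
                    tally[name] += r.count
                    placed = True
                    break
            if placed:
                break
        if not placed:
            tally["unmapped"] += r.count
    return tally


def quantify_samples(
    per_sample_reads: dict[str, list[CollapsedRead]],
    catalog: Catalog,
    annotations: list[MatureAnnotation],
    ratio: float = 3.0,
    references: dict[str, list[str]] | None = None,
    min_overlap: int = MIN_MATURE_OVERLAP,
    min_novel_cluster: int = MIN_NOVEL_CLUSTER,
) -> tuple[QuantResult, dict[str, int]]:
    """End-to-end quantification over a set of libraries.

    Pools reads across samples for alignment and the 3:1 filter (the
    default policy), then accumulates counts per sample.  Returns the
    QuantResult and the cascade category tally (with the pooled miRNA
    multiplicity under "miRNA").
    """
    sample_counts: dict[str, dict[str, int]] = defaultdict(dict)
    for sample, reads in per_sample_reads.items():
        for r in reads:
            sample_counts[r.sequence][sample] = (
                sample_counts[r.sequence].get(sample, 0) + r.count
            )
    pooled = [
        CollapsedRead(seq, sum(d.values())) for seq, d in sample_counts.items()
    ]
    alignments = align_to_precursors(pooled, catalog)
    pooled_counts = {r.sequence: r.count for r in pooled}
    retained, discarded = hairpin_consistency_filter(alignments, pooled_counts, ratio)
    result = assign_counts(
        alignments,
        catalog,
        annotations,
        dict(sample_counts),
        retained,
        discarded,
        samples=sorted(per_sample_reads),
        min_overlap=min_overlap,
        min_novel_cluster=min_novel_cluster,
    )
    mapped = {a.read_sequence for a in alignments}
    leftover = [r for r in pooled if r.sequence not in mapped]
    tally = cascade_classify(leftover, references or {})
    tally["miRNA"] = sum(pooled_counts[s] for s in mapped)
    return result, tally
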