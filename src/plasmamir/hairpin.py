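"""Hairpin precursor catalog: structure partitioning and mature anchoring.

A pre-miRNA hairpin folds into a stem-loop; Drosha/Dicer excise one mature
miRNA from each arm of the stem ("-5p" from the 5' arm, "-3p" from the 3'
arm).  This module builds a non-redundant precursor catalog from sequences
plus dot-bracket secondary structures, partitions every hairpin into
5' arm / terminal loop / 3' arm, and anchors mature miRNA sequences on the
precursors by exact string match, resolving cross-species redundancy in
favour of the target species.

Coordinates are 0-based half-open throughout; only the GFF3 export uses
1-based inclusive coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "StructureError",
    "NotAHairpinError",
    "HairpinPrecursor",
    "MatureAnnotation",
    "Catalog",
    "partition_hairpin",
    "build_catalog",
    "map_matures",
    "read_precursor_files",
    "read_three_line",
    "read_matures_fasta",
    "catalog_to_gff3",
    "catalog_to_tsv",
]

Interval = tuple[int, int]


class StructureError(ValueError):
    """Malformed dot-bracket input (unbalanced brackets, bad characters)."""


class NotAHairpinError(ValueError):
    """Structure has no base pairs, or branches and no main stem was forced."""


def _normalize_rna(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


def _pair_table(structure: str) -> list[Interval]:
    """All base pairs (i, j), i < j, from a dot-bracket string."""
    stack: list[int] = []
    pairs: list[Interval] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise StructureError(f"invalid character {c!r} at position {i}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def _children(pairs: list[Interval], span: Interval) -> list[Interval]:
    """Maximal pairs directly nested inside ``span`` (exclusive)."""
    lo, hi = span
    inside = [(i, j) for (i, j) in pairs if lo < i and j < hi]
    out: list[Interval] = []
    for i, j in inside:
        if not any(a < i and j < b for (a, b) in inside if (a, b) != (i, j)):
            out.append((i, j))
    return sorted(out)


def partition_hairpin(
    structure: str, force_main_stem: bool = False
) -> tuple[Interval, Interval, Interval]:
    """Partition a dot-bracket structure into (arm5, loop, arm3) intervals.

    The loop is the open interval strictly between the two partners of the
    innermost base pair of the main stem; everything 5' of it (including
    external unpaired bases and bulges) is the 5' arm, everything 3' of it
    the 3' arm.

    Multi-branched structures raise :class:`NotAHairpinError` unless
    ``force_main_stem`` is set, in which case the branch whose subtree holds
    the most base pairs is followed (ties: 5'-most branch).
    """
    n = len(structure)
    pairs = _pair_table(structure)
    if not pairs:
        raise NotAHairpinError("structure contains no base pairs")
    pair_set = set(pairs)

    def subtree_size(p: Interval) -> int:
        i, j = p
        return sum(1 for (a, b) in pair_set if i <= a and b <= j)

    span: Interval = (-1, n)
    current: Interval | None = None
    while True:
        kids = _children(pairs, span)
        if not kids:
            break
        if len(kids) > 1:
            if not force_main_stem:
                raise NotAHairpinError(
                    f"multi-branched structure ({len(kids)} helices inside "
                    f"{span}); pass force_main_stem=True to follow the longest"
                )
            kids.sort(key=lambda p: (-subtree_size(p), p[0]))
        current = kids[0]
        span = current
    assert current is not None
    i, j = current
    loop = (i + 1, j)
    return (0, loop[0]), loop, (loop[1], n)


@dataclass
class HairpinPrecursor:
    """A precursor hairpin with its arm/loop partition."""

    id: str
    sequence: str
    structure: str
    source: str = "experimental"  # or "predicted"
    arm5: Interval = (0, 0)
    loop: Interval = (0, 0)
    arm3: Interval = (0, 0)
    aliases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise StructureError(
                f"{self.id}: structure length {len(self.structure)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def region_of(self, interval: Interval) -> str:
        """Region label for a read/mature interval by majority base overlap.

        Exact ties never go to the loop (the destructive label); between the
        two arms the side holding the interval's 5' end wins.
        """
        s, e = interval
        o5 = max(0, min(e, self.arm5[1]) - max(s, self.arm5[0]))
        ol = max(0, min(e, self.loop[1]) - max(s, self.loop[0]))
        o3 = max(0, min(e, self.arm3[1]) - max(s, self.arm3[0]))
        best = max(o5, ol, o3)
        if o5 == best and (o5 > o3 or s < self.loop[0]):
            return "arm5"
        if o3 == best:
            return "arm3"
        if o5 == best:
            return "arm5"
        return "loop"


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA anchored at an exact-match interval on a precursor."""

    name: str
    precursor_id: str
    interval: Interval
    arm: str  # arm5 | arm3 | loop_spanning
    novel: bool = False


class Catalog:
    """Non-redundant, partitioned precursor collection."""

    def __init__(self, precursors: Sequence[HairpinPrecursor],
                 rejected: Sequence[tuple[str, str]] = ()):
        self.precursors: list[HairpinPrecursor] = list(precursors)
        self.rejected: list[tuple[str, str]] = list(rejected)
        self._by_id = {p.id: p for p in self.precursors}

    def __len__(self) -> int:
        return len(self.precursors)

    def __iter__(self):
        return iter(self.precursors)

    def __getitem__(self, pid: str) -> HairpinPrecursor:
        return self._by_id[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self._by_id


def build_catalog(
    records: Iterable[tuple[str, str, str] | tuple[str, str, str, str]],
    force_main_stem: bool = False,
) -> Catalog:
    """Collapse duplicate precursor sequences and partition every hairpin.

    ``records`` are (id, sequence, structure[, source]) tuples.  Duplicate
    sequences collapse onto the first id seen; later ids become aliases.
    Records whose structure cannot be partitioned (length mismatch,
    unbalanced brackets, no stem) are rejected individually with a reason.
    """
    kept: dict[str, HairpinPrecursor] = {}  # sequence -> record
    rejected: list[tuple[str, str]] = []
    seen_ids: set[str] = set()
    for rec in records:
        pid, seq, struct = rec[0], rec[1], rec[2]
        source = rec[3] if len(rec) > 3 else "experimental"
        if pid in seen_ids:
            raise ValueError(f"duplicate precursor id {pid!r}")
        seen_ids.add(pid)
        seq = _normalize_rna(seq)
        struct = struct.strip()
        if seq in kept:
            kept[seq].aliases.append(pid)
            continue
        try:
            if len(struct) != len(seq):
                raise StructureError(
                    f"structure length {len(struct)} != sequence length {len(seq)}"
                )
            arm5, loop, arm3 = partition_hairpin(struct, force_main_stem)
        except (StructureError, NotAHairpinError) as exc:
            rejected.append((pid, str(exc)))
            warnings.warn(f"precursor {pid} rejected: {exc}", stacklevel=2)
            continue
        kept[seq] = HairpinPrecursor(
            id=pid, sequence=seq, structure=struct, source=source,
            arm5=arm5, loop=loop, arm3=arm3,
        )
    for p in kept.values():
        assert 0 <= p.arm5[0] <= p.arm5[1] <= p.loop[0] < p.loop[1] <= p.arm3[0] <= p.arm3[1] <= len(p)
    return Catalog(list(kept.values()), rejected)


def _mature_arm(precursor: HairpinPrecursor, interval: Interval) -> str:
    region = precursor.region_of(interval)
    return {"arm5": "arm5", "arm3": "arm3", "loop": "loop_spanning"}[region]


def map_matures(
    catalog: Catalog,
    matures: Iterable[tuple[str, str]],
    target_prefix: str = "gga",
) -> tuple[list[MatureAnnotation], list[str]]:
    """Anchor mature sequences on the catalog by exact (0-mismatch) match.

    Every exact occurrence of a mature on a precursor yields a candidate.
    When several species' matures occupy the same (precursor, interval), a
    single annotation survives: names carrying the target-species prefix
    win, then lexicographic name order breaks ties.  Returns the annotation
    list and the names that hit no precursor.
    """
    candidates: dict[tuple[str, Interval], list[str]] = {}
    hit: dict[str, bool] = {}
    mature_list = sorted({(name, _normalize_rna(seq)) for name, seq in matures})
    for name, seq in mature_list:
        hit.setdefault(name, False)
        if not 18 <= len(seq) <= 26:
            warnings.warn(
                f"mature {name}: length {len(seq)} outside 18-26 nt", stacklevel=2
            )
        for prec in catalog:
            start = prec.sequence.find(seq)
            while start != -1:
                key = (prec.id, (start, start + len(seq)))
                candidates.setdefault(key, []).append(name)
                hit[name] = True
                start = prec.sequence.find(seq, start + 1)
    annotations: list[MatureAnnotation] = []
    for (pid, interval), names in sorted(candidates.items()):
        names.sort(key=lambda n: (not n.startswith(target_prefix + "-"), n))
        annotations.append(
            MatureAnnotation(
                name=names[0],
                precursor_id=pid,
                interval=interval,
                arm=_mature_arm(catalog[pid], interval),
            )
        )
    leftovers = sorted(n for n, was_hit in hit.items() if not was_hit)
    return annotations, leftovers


# ---------------------------------------------------------------------------
# IO


def read_precursor_files(fasta_path, structure_path):
    """Precursors from a FASTA plus a parallel dot-bracket file (same ids).

    The structure file holds ``>id`` header lines followed by dot-bracket
    lines, or plain two-column ``id<TAB>structure`` lines.
    """
    from Bio import SeqIO

    structures: dict[str, str] = {}
    with open(structure_path) as fh:
        current = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                structures[current] = ""
            elif "\t" in line:
                pid, struct = line.split("\t", 1)
                structures[pid.strip()] = struct.strip()
            elif current is not None:
                structures[current] += line
            else:
                raise StructureError("structure file line outside any record")
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in structures:
            raise KeyError(f"no structure for precursor {rec.id}")
        records.append((rec.id, str(rec.seq), structures[rec.id]))
    return records


def read_three_line(path):
    """The combined dialect: repeating ``id / sequence / structure`` lines."""
    records = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) % 3:
        raise ValueError("three-line precursor file length not divisible by 3")
    for k in range(0, len(lines), 3):
        pid = lines[k].lstrip(">")
        records.append((pid, lines[k + 1], lines[k + 2]))
    return records


def read_matures_fasta(path):
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def catalog_to_gff3(catalog: Catalog, annotations=(), path=None) -> str:
    """GFF3 export (1-based inclusive) with arm/loop subfeatures."""
    lines = ["##gff-version 3"]
    for p in catalog:
        attrs = f"ID={p.id}"
        if p.aliases:
            attrs += ";Alias=" + ",".join(p.aliases)
        lines.append(
            f"{p.id}\tplasmamir\tmiRNA_primary_transcript\t1\t{len(p)}\t.\t+\t.\t{attrs}"
        )
        for region_name, (s, e) in (("arm5", p.arm5), ("loop", p.loop), ("arm3", p.arm3)):
            if e > s:
                lines.append(
                    f"{p.id}\tplasmamir\t{region_name}\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID={p.id}:{region_name};Parent={p.id}"
                )
    for a in annotations:
        s, e = a.interval
        novel = ";novel=true" if a.novel else ""
        lines.append(
            f"{a.precursor_id}\tplasmamir\tmiRNA\t{s + 1}\t{e}\t.\t+\t.\t"
            f"ID={a.name};Parent={a.precursor_id};arm={a.arm}{novel}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def catalog_to_tsv(catalog: Catalog, path=None) -> str:
    header = "id\tlength\tarm5_start\tarm5_end\tloop_start\tloop_end\tarm3_start\tarm3_end\tsource\taliases\tsequence\tstructure"
    rows = [header]
    for p in catalog:
        rows.append(
            "\t".join(
                map(
                    str,
                    [
                        p.id, len(p), p.arm5[0], p.arm5[1], p.loop[0], p.loop[1],
                        p.arm3[0], p.arm3[1], p.source, ",".join(p.aliases),
                        p.sequence, p.structure,
                    ],
                )
            )
        )
    text = "\n".join(rows) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
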