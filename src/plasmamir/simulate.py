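"""Synthetic-data generators emulating the plasma miRNome study design.

Every input the pipeline consumes can be generated here with full ground
truth: perfect-stem hairpin precursors with analytic dot-bracket
structures, small-RNA FASTQ reads with planted adapter positions and
errors, NB count matrices over the 2 lines x 2 feeding conditions x 3
replicates design with planted effects and cluster structure, and qPCR Ct
tables with animal and batch effects.  All generators are pure functions
of (parameters, seed).

Default scale mirrors the study: 12 sequencing libraries, a few hundred
miRNA features, 3 replicates per line x condition group; qPCR panels of 6
miRNAs on 8 R+ and 7 R- birds sampled in both conditions over two batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hairpin import Catalog, MatureAnnotation, build_catalog
from .readprep import CollapsedRead

__all__ = [
    "HairpinTruth",
    "make_hairpins",
    "simulate_reads",
    "simulate_counts",
    "simulate_qpcr",
    "study_metadata",
]

RNA = np.array(list("ACGU"))
_COMP = str.maketrans("ACGU", "UGCA")

LINES = ("R-", "R+")
CONDITIONS = ("FD", "RF")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class HairpinTruth:
    records: list[tuple[str, str, str]]       # (id, sequence, structure)
    matures: list[tuple[str, str]]            # (name, sequence)
    annotations: list[MatureAnnotation]       # planted intervals
    partitions: dict[str, tuple]              # id -> (arm5, loop, arm3)
    catalog: Catalog = field(default=None, repr=False)


def make_hairpins(
    n: int,
    arm_len: int = 22,
    loop_len: int = 8,
    seed: int | np.random.Generator = 0,
    matures_per_hairpin: int = 2,
    mature_len: int = 21,
    bulges: bool = False,
) -> HairpinTruth:
    """Perfect-stem hairpins with planted mature miRNAs.

    Each hairpin is a random 5' arm, an unpaired loop, and the arm's
    reverse complement, so the dot-bracket is known analytically
    ("("*arm + "."*loop + ")"*arm).  ``bulges`` injects one unpaired base
    into each arm (structure adjusted accordingly) to exercise partition
    edge cases.  Planted matures (1 or 2 per hairpin) sit at the arm ends
    adjacent to the loop-distal side, named gga-miR-s<i>-5p/-3p.
    """
    if arm_len < 19 or loop_len < 3:
        raise ValueError("need arm_len >= 19 and loop_len >= 3")
    if not 1 <= matures_per_hairpin <= 2 or mature_len > arm_len:
        raise ValueError("matures_per_hairpin in {1,2}; mature_len <= arm_len")
    rng = np.random.default_rng(seed)
    records, matures, annotations = [], [], []
    partitions = {}
    for i in range(n):
        arm5 = "".join(rng.choice(RNA, size=arm_len))
        loop = "".join(rng.choice(RNA, size=loop_len))
        arm3 = _revcomp(arm5)
        seq = arm5 + loop + arm3
        struct = "(" * arm_len + "." * loop_len + ")" * arm_len
        if bulges:
            b5 = int(rng.integers(2, arm_len - 2))
            b3 = int(rng.integers(2, arm_len - 2))
            nt5 = str(rng.choice(RNA))
            nt3 = str(rng.choice(RNA))
            seq = arm5[:b5] + nt5 + arm5[b5:] + loop
            struct = "(" * b5 + "." + "(" * (arm_len - b5) + "." * loop_len
            seq += arm3[:b3] + nt3 + arm3[b3:]
            struct += ")" * b3 + "." + ")" * (arm_len - b3)
        pid = f"hp{i:04d}"
        records.append((pid, seq, struct))
        name5 = f"gga-miR-s{i:04d}-5p"
        m5 = arm5[:mature_len] if not bulges else (arm5[:b5] + nt5 + arm5[b5:])[:mature_len]
        matures.append((name5, m5))
        start5 = seq.index(m5)
        annotations.append(
            MatureAnnotation(name5, pid, (start5, start5 + mature_len), "arm5")
        )
        if matures_per_hairpin == 2:
            name3 = f"gga-miR-s{i:04d}-3p"
            m3 = seq[len(seq) - mature_len:]
            matures.append((name3, m3))
            annotations.append(
                MatureAnnotation(
                    name3, pid, (len(seq) - mature_len, len(seq)), "arm3"
                )
            )
    truth = HairpinTruth(
        records=records,
        matures=matures,
        annotations=annotations,
        partitions={},
    )
    truth.catalog = build_catalog(records)
    for p in truth.catalog:
        truth.partitions[p.id] = (p.arm5, p.loop, p.arm3)
    return truth


def study_metadata(n_rep: int = 3) -> pd.DataFrame:
    """The 12-library design: 2 lines x 2 conditions x n_rep animals,
    each animal sequenced in both conditions."""
    rows = []
    for line in LINES:
        tag = "m" if line == "R-" else "p"
        for r in range(n_rep):
            animal = f"{tag}{r + 1}"
            for cond in CONDITIONS:
                rows.append(
                    {
                        "sample": f"{line}_{cond}_{animal}",
                        "line": line,
                        "condition": cond,
                        "animal": animal,
                        "group": f"{line}|{cond}",
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def simulate_reads(
    truth: HairpinTruth,
    abundances: pd.DataFrame,   # mature name x sample, relative weights
    adapter: str = "UGGAAUUCUCGGGUGCCAAGG",
    n_reads: int = 2000,
    sub_rate: float = 0.0,
    loop_rate: float = 0.0,
    read_len: int = 50,
    quality_high: int = 38,
    low_tail: int = 3,
    loop_precursors: list[str] | None = None,
    seed: int | np.random.Generator = 0,
):
    """Per-sample FASTQ-style reads drawn from planted matures.

    Reads are mature sequences length-jittered within 19-24 nt (3' end
    moved within the precursor), substituted at ``sub_rate`` per base; a
    ``loop_rate`` fraction is drawn from hairpin loop regions instead.
    The adapter is appended, the read padded/truncated to ``read_len``,
    and Phred qualities set high with a planted low-quality tail.

    Returns ``{sample: [(id, sequence, quality), ...]}`` and a truth dict
    holding the planted per-sample mature count matrix and per-read
    provenance.
    """
    rng = np.random.default_rng(seed)
    ann_by_name = {a.name: a for a in truth.annotations}
    prec = {p.id: p for p in truth.catalog}
    samples = list(abundances.columns)
    names = list(abundances.index)
    planted = pd.DataFrame(0, index=names, columns=samples, dtype=int)
    fastqs: dict[str, list[tuple[str, str, str]]] = {}
    provenance: dict[str, list[dict]] = {}

    for sample in samples:
        weights = abundances[sample].to_numpy(float)
        weights = weights / weights.sum()
        recs, prov = [], []
        for ridx in range(n_reads):
            if loop_rate > 0 and rng.random() < loop_rate:
                pool = loop_precursors if loop_precursors else sorted(prec)
                p = prec[str(rng.choice(pool))]
                ls, le = p.loop
                L = int(rng.integers(19, 25))
                center = (ls + le) // 2
                start = max(0, min(center - L // 2, len(p) - L))
                insert = p.sequence[start:start + L]
                source = f"loop:{p.id}"
            else:
                name = names[int(rng.choice(len(names), p=weights))]
                a = ann_by_name[name]
                p = prec[a.precursor_id]
                s, e = a.interval
                L = int(rng.integers(19, 25))
                e2 = min(max(s + L, s + 19), len(p))
                insert = p.sequence[s:e2]
                planted.loc[name, sample] += 1
                source = name
            if sub_rate > 0:
                chars = list(insert)
                for k in range(len(chars)):
                    if rng.random() < sub_rate:
                        chars[k] = str(rng.choice([c for c in "ACGU" if c != chars[k]]))
                insert = "".join(chars)
            full = insert + adapter
            while len(full) < read_len:
                full += str(rng.choice(RNA))
            full = full[:read_len]
            qual = [quality_high] * read_len
            for k in range(low_tail):
                qual[read_len - 1 - k] = int(rng.integers(2, 10))
            qstr = "".join(chr(q + 33) for q in qual)
            rid = f"{sample}.{ridx}"
            recs.append((rid, full, qstr))
            prov.append(
                {"id": rid, "source": source, "insert": insert,
                 "adapter_pos": len(insert)}
            )
        fastqs[sample] = recs
        provenance[sample] = prov
    return fastqs, {"planted_counts": planted, "provenance": provenance}


def simulate_counts(
    n_features: int = 300,
    n_rep: int = 3,
    baseline_mean: float = 200.0,
    baseline_sigma: float = 1.5,
    phi: float = 0.2,
    frac_de: float = 0.1,
    lfc: float = 2.0,
    cluster_profiles: np.ndarray | None = None,
    cluster_weights: np.ndarray | None = None,
    lib_sizes: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
):
    """NB count matrix over the 2x2xn_rep design with planted truth.

    Feature means are log-normal around ``baseline_mean``; a ``frac_de``
    fraction receives a +/-``lfc`` log2 line or condition effect (half
    each); optional cluster profiles multiply group means to create
    co-abundance structure.  y ~ NB(mean = depth_factor * mu_gj,
    dispersion phi); phi = 0 gives Poisson counts.

    Returns (counts DataFrame, metadata DataFrame, truth dict).
    """
    rng = np.random.default_rng(seed)
    meta = study_metadata(n_rep)
    n_samples = len(meta)
    if lib_sizes is None:
        lib_sizes = rng.uniform(0.6, 1.6, size=n_samples)
    lib_sizes = np.asarray(lib_sizes, dtype=float)

    base = np.exp(rng.normal(np.log(baseline_mean), baseline_sigma, size=n_features))
    is_line = (meta["line"] == "R+").to_numpy(float)
    is_rf = (meta["condition"] == "RF").to_numpy(float)

    n_de = int(round(frac_de * n_features))
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    de_type = np.array([""] * n_features, dtype=object)
    lfc_g = np.zeros(n_features)
    half = n_de // 2
    for k, g in enumerate(de_idx):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if k < half:
            de_type[g] = "line"
        else:
            de_type[g] = "condition"
        lfc_g[g] = sign * lfc

    groups = meta["group"].to_numpy()
    uniq_groups = sorted(set(groups))
    if cluster_profiles is not None:
        cluster_profiles = np.asarray(cluster_profiles, dtype=float)  # (K, G)
        K = cluster_profiles.shape[0]
        if cluster_profiles.shape[1] != len(uniq_groups):
            raise ValueError("cluster profile width must equal number of groups")
        if cluster_weights is None:
            cluster_weights = np.full(K, 1.0 / K)
        labels = rng.choice(K, size=n_features, p=np.asarray(cluster_weights))
        gmult = cluster_profiles[labels][:, [uniq_groups.index(g) for g in groups]]
    else:
        labels = np.zeros(n_features, dtype=int)
        gmult = np.ones((n_features, n_samples))

    effect = np.where(
        de_type[:, None] == "line", lfc_g[:, None] * is_line[None, :],
        np.where(de_type[:, None] == "condition", lfc_g[:, None] * is_rf[None, :], 0.0),
    )
    mu = lib_sizes[None, :] * base[:, None] * (2.0 ** effect) * gmult
    if phi > 0:
        r = 1.0 / phi
        Y = rng.negative_binomial(r, r / (r + mu))
    else:
        Y = rng.poisson(mu)
    counts = pd.DataFrame(
        Y, index=[f"mir{g:04d}" for g in range(n_features)], columns=meta.index
    )
    truth = {
        "base_mean": base,
        "lib_sizes": lib_sizes,
        "phi": phi,
        "de_type": de_type,
        "lfc": lfc_g,
        "de_features": list(counts.index[de_idx]),
        "cluster_labels": labels,
    }
    return counts, meta, truth


def simulate_qpcr(
    n_mirnas: int = 6,
    n_animals: dict[str, int] | None = None,
    line_effect: float = 1.5,
    condition_effect: float = 1.0,
    batch_effect: float = 0.5,
    sigma_a: float = 0.8,
    sigma_e: float = 0.4,
    baseline: float = 6.0,
    reference_ct: float = 20.0,
    effects_per_mirna: pd.DataFrame | None = None,
    seed: int | np.random.Generator = 0,
):
    """Long-format Ct records over the qPCR validation design.

    Default design: 8 R+ and 7 R- birds, each sampled in FD and RF,
    split over two batches.  The -dCt signal for miRNA m on animal a is
    baseline + line + condition + batch + N(0, sigma_a^2) animal intercept
    + N(0, sigma_e^2) noise; Ct = reference_ct - signal.
    ``effects_per_mirna`` overrides the scalar line/condition effects with
    per-miRNA values (columns "line", "condition").

    Returns (records DataFrame, truth dict).
    """
    rng = np.random.default_rng(seed)
    if n_animals is None:
        n_animals = {"R+": 8, "R-": 7}
    mirnas = [f"qmir{m}" for m in range(n_mirnas)]
    if effects_per_mirna is None:
        effects_per_mirna = pd.DataFrame(
            {"line": [line_effect] * n_mirnas, "condition": [condition_effect] * n_mirnas},
            index=mirnas,
        )
    rows = []
    animal_intercepts = {}
    animal_batches = {}
    idx = 0
    for line, n_a in sorted(n_animals.items()):
        for a in range(n_a):
            animal = f"{'p' if line == 'R+' else 'm'}{a + 1}"
            animal_intercepts[animal] = rng.normal(0.0, sigma_a)
            animal_batches[animal] = f"b{(idx % 2) + 1}"
            idx += 1
            for cond in CONDITIONS:
                for m in mirnas:
                    signal = (
                        baseline
                        + effects_per_mirna.loc[m, "line"] * (line == "R+")
                        + effects_per_mirna.loc[m, "condition"] * (cond == "RF")
                        + batch_effect * (animal_batches[animal] == "b2")
                        + animal_intercepts[animal]
                        + rng.normal(0.0, sigma_e)
                    )
                    rows.append(
                        {
                            "mirna": m,
                            "animal": animal,
                            "line": line,
                            "condition": cond,
                            "batch": animal_batches[animal],
                            "ct": reference_ct - signal,
                            "reference_ct": reference_ct,
                        }
                    )
    records = pd.DataFrame(rows)
    truth = {
        "effects": effects_per_mirna,
        "batch_effect": batch_effect,
        "sigma_a": sigma_a,
        "sigma_e": sigma_e,
        "icc": sigma_a ** 2 / (sigma_a ** 2 + sigma_e ** 2) if sigma_a + sigma_e > 0 else 0.0,
        "animal_intercepts": animal_intercepts,
        "animal_batches": animal_batches,
    }
    return records, truth
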