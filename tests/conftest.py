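import numpy as np
import pandas as pd
import pytest

from plasmamir.hairpin import build_catalog, map_matures
from plasmamir.simulate import make_hairpins, study_metadata


@pytest.fixture(scope="session")
def hairpin_truth():
    """Ten perfect-stem hairpins with planted matures on both arms."""
    return make_hairpins(10, seed=1)


@pytest.fixture(scope="session")
def catalog(hairpin_truth):
    return hairpin_truth.catalog


@pytest.fixture()
def small_catalog():
    """Two hand-built hairpins with known partitions."""
    arm = "AGCUUAGGCAUCGAUCCGGAAU"  # 22 nt, non-periodic
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    rc = "".join(comp[c] for c in reversed(arm))
    seq = arm + "AAAAGGGG" + rc
    struct = "(" * 22 + "." * 8 + ")" * 22
    arm2 = "GGAUCCGGAUCCGGAUCCGGAU"
    rc2 = "".join(comp[c] for c in reversed(arm2))
    seq2 = arm2 + "CCCCAAAA" + rc2
    return build_catalog([("hpA", seq, struct), ("hpB", seq2, struct)])


@pytest.fixture(scope="session")
def meta12():
    return study_metadata()


def brute_force_hamming_hits(read: str, precursors, max_mismatch: int = 1):
    """Independent oracle: scan every (precursor, offset) pair."""
    read = read.upper().replace("T", "U")
    hits = []
    for p in precursors:
        seq = p.sequence
        for off in range(len(seq) - len(read) + 1):
            mm = sum(1 for a, b in zip(read, seq[off:off + len(read)]) if a != b)
            if mm <= max_mismatch:
                hits.append((p.id, off, mm))
    return hits
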