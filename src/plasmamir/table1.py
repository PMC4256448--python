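"""The published plasma differential-abundance summary table and its
cross-tabulations.

The packaged fixture transcribes the study's 41-row summary of
differentially abundant plasma miRNAs: one boolean flag per comparison
(Condition RF vs FD; Line R+ vs R-; Line within each feeding condition;
Condition within each line) plus the co-abundance cluster id (1..5).  A
checksum guards the transcription; known internal inconsistencies between
the printed table and the narrative (the cluster membership of
gga-miR-2188-5p/-3p) are reported as printed, never reconciled.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = ["FLAG_COLUMNS", "load_fixture_table1", "crosstab", "column_totals"]

FLAG_COLUMNS = [
    "RF_vs_FD",
    "Rplus_vs_Rminus",
    "Rplus_vs_Rminus_RF",
    "Rplus_vs_Rminus_FD",
    "RF_vs_FD_Rminus",
    "RF_vs_FD_Rplus",
]
_EXPECTED_ROWS = 41
_SHA256 = "69cb24480157303d01650e6d4c7d1b811b685d3e5c0dffd5c8c38d20ab5b4d4a"


def load_fixture_table1() -> pd.DataFrame:
    """Load and validate the packaged 41-row summary table."""
    ref = resources.files("plasmamir").joinpath("data/table1_plasma_da.tsv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _SHA256:
        raise ValueError(
            f"fixture checksum mismatch ({digest}); the packaged table was edited"
        )
    df = pd.read_csv(ref.open("r"), sep="\t", dtype={"alias": "string"})
    if len(df) != _EXPECTED_ROWS:
        raise ValueError(f"expected {_EXPECTED_ROWS} rows, found {len(df)}")
    for col in FLAG_COLUMNS:
        if not df[col].isin((0, 1)).all():
            raise ValueError(f"non-boolean flag in column {col}")
        df[col] = df[col].astype(bool)
    if not df["cluster"].between(1, 5).all():
        raise ValueError("cluster ids must lie in 1..5")
    return df.set_index("mirna")


def _column(table: pd.DataFrame, spec: str) -> pd.Series:
    if spec in FLAG_COLUMNS:
        return table[spec]
    if spec == "cluster":
        return table["cluster"]
    raise KeyError(f"unknown column {spec!r}; choose a flag column or 'cluster'")


def crosstab(table: pd.DataFrame, row_spec: str, col_spec: str) -> pd.DataFrame:
    """Exact integer contingency table of two flag/cluster columns."""
    return pd.crosstab(_column(table, row_spec), _column(table, col_spec))


def column_totals(table: pd.DataFrame) -> dict:
    """Per-comparison totals, pairwise intersections, and cluster sizes."""
    totals = {col: int(table[col].sum()) for col in FLAG_COLUMNS}
    inter = {}
    for i, a in enumerate(FLAG_COLUMNS):
        for b in FLAG_COLUMNS[i + 1:]:
            inter[f"{a}&{b}"] = int((table[a] & table[b]).sum())
    clusters = table["cluster"].value_counts().sort_index()
    return {
        "n_rows": len(table),
        "totals": totals,
        "intersections": inter,
        "cluster_sizes": {int(k): int(v) for k, v in clusters.items()},
    }
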