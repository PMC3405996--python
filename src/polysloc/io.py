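"""TSV readers and writers for panels, class counts and run tables.

Dialect: tab-separated, UTF-8, header row, ``.`` for missing values.
Marker lists are semicolon-separated within a field.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

MISSING = "."


def write_panel_tsv(panel: pd.DataFrame, path) -> None:
    """Write an accession panel (`accession`, `cluster`, `markers`)."""
    out = panel.copy()
    out["markers"] = out["markers"].map(
        lambda ms: ";".join(ms) if not isinstance(ms, str) else ms)
    out.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "cluster", "markers"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel {path} missing columns: {sorted(missing)}")
    panel["markers"] = panel["markers"].map(
        lambda s: [] if pd.isna(s) or s == MISSING
        else [m for m in str(s).split(";") if m])
    return panel


def write_counts_tsv(counts: Mapping[str, int], path) -> None:
    """Write F2 class counts as a two-column TSV (`class`, `count`)."""
    with open(path, "w") as fh:
        fh.write("class\tcount\n")
        for label, value in counts.items():
            fh.write(f"{label}\t{value}\n")


def read_counts_tsv(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"class": str, "count": int})
    if list(df.columns) != ["class", "count"]:
        raise ValueError(f"{path}: expected columns 'class', 'count'")
    return dict(zip(df["class"], df["count"]))


def read_clusters_tsv(path) -> dict[str, str]:
    """Accession -> cluster mapping from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "accession" not in df.columns or "cluster" not in df.columns:
        raise ValueError(f"{path}: expected columns 'accession', 'cluster'")
    return dict(zip(df["accession"], df["cluster"]))


def read_lnp_tsv(path) -> dict[int, list[float]]:
    """Per-K ln P(X|K) run table: columns `K`, `lnP` (one row per run)."""
    df = pd.read_csv(path, sep="\t")
    if "K" not in df.columns or "lnP" not in df.columns:
        raise ValueError(f"{path}: expected columns 'K', 'lnP'")
    return {int(k): list(map(float, grp["lnP"]))
            for k, grp in df.groupby("K")}
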