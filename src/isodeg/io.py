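"""Readers, writers and domain tables for NR-seq mutation-count data.

The central exchange format is the "cB" (counts binned) table: one row per
(sample, gene, transcript equivalence class, T count, T-to-C count) signature,
with ``n`` giving the number of reads sharing that signature.  Transcript
equivalence classes (TECs) are the sets of annotated isoforms with which a
read is compatible, encoded as '+'-joined, lexicographically sorted transcript
identifiers so that the label is order-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

CB_COLUMNS = ["sample", "XF", "TEC", "nT", "TC", "n"]
ABUNDANCE_COLUMNS = ["sample", "transcript_id", "gene_id", "TPM", "expected_count"]


class FormatError(ValueError):
    """Raised when an input table violates the documented file format."""


def tec_label(transcripts: Iterable[str]) -> str:
    """Canonical TEC label: '+'-joined, lexicographically sorted, unique ids."""
    members = sorted(set(transcripts))
    if not members:
        raise ValueError("a TEC must contain at least one transcript")
    return "+".join(members)


def tec_members(label: str) -> tuple[str, ...]:
    """Inverse of :func:`tec_label`."""
    return tuple(label.split("+"))


@dataclass
class MutationCountTable:
    """Validated cB table.

    ``data`` has columns ``sample, XF, TEC, nT, TC, n``: per (sample, gene,
    TEC) the number ``n`` of reads carrying ``nT`` reference Ts of which
    ``TC`` were read as C.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in CB_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"cB table missing column(s): {', '.join(missing)}")
        df = df[CB_COLUMNS].copy()
        for col in ("nT", "TC", "n"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        if (df["TC"] > df["nT"]).any():
            bad = df.loc[df["TC"] > df["nT"]].index[0]
            raise FormatError(f"row {bad}: TC count exceeds nT count")
        if (df["n"] < 1).any():
            raise FormatError("read count n must be >= 1 in every row")
        if (df["nT"] < 0).any() or (df["TC"] < 0).any():
            raise FormatError("nT and TC counts must be non-negative")
        key = ["sample", "XF", "TEC", "nT", "TC"]
        if df.duplicated(key).any():
            warnings.warn(
                "cB table contains duplicate (sample, XF, TEC, nT, TC) keys; "
                "read counts were aggregated",
                stacklevel=3,
            )
            df = df.groupby(key, as_index=False, sort=False)["n"].sum()
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationCountTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @property
    def total_reads(self) -> int:
        return int(self.data["n"].sum())

    def subset_samples(self, samples: Iterable[str]) -> "MutationCountTable":
        keep = set(samples)
        return MutationCountTable(self.data[self.data["sample"].isin(keep)].copy())


def read_cb(path: str | Path) -> MutationCountTable:
    """Read a cB TSV (columns sample, XF, TEC, nT, TC, n) with validation."""
    return MutationCountTable.from_tsv(path)


def write_cb(table: MutationCountTable, path: str | Path) -> None:
    table.to_tsv(path)


@dataclass
class AbundanceTable:
    """Per-sample isoform quantification (TPM and expected read counts)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ABUNDANCE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(
                f"abundance table missing column(s): {', '.join(missing)}"
            )
        df = df[ABUNDANCE_COLUMNS].copy()
        df["TPM"] = pd.to_numeric(df["TPM"]).astype(float)
        df["expected_count"] = pd.to_numeric(df["expected_count"]).astype(float)
        if (df["TPM"] < 0).any():
            raise FormatError("TPM must be non-negative")
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def read_abundance(path: str | Path) -> AbundanceTable:
    return AbundanceTable.from_tsv(path)


@dataclass
class TECBuildReport:
    """Book-keeping from :func:`build_tecs`: reads kept and reads dropped."""

    n_assigned: int
    n_dropped_empty: int
    n_dropped_multigene: int


def build_tecs(
    compat: Iterable[tuple[str, Iterable[str], int, int]],
    gene_map: Mapping[str, str],
) -> tuple[MutationCountTable, TECBuildReport]:
    """Group per-read compatibility records into cB rows.

    Parameters
    ----------
    compat
        Iterable of ``(sample, compatible_transcripts, nT, nTC)`` records,
        one per sequencing read.
    gene_map
        Transcript id -> gene id.  Reads whose compatible transcripts span
        more than one gene are discarded (and counted); reads with an empty
        compatibility list are likewise dropped and tallied.
    """
    rows: dict[tuple[str, str, str, int, int], int] = {}
    n_empty = 0
    n_multi = 0
    n_ok = 0
    for sample, transcripts, n_t, n_tc in compat:
        txs = sorted(set(transcripts))
        if not txs:
            n_empty += 1
            continue
        genes = {gene_map[t] for t in txs}
        if len(genes) != 1:
            n_multi += 1
            continue
        key = (sample, genes.pop(), "+".join(txs), int(n_t), int(n_tc))
        rows[key] = rows.get(key, 0) + 1
        n_ok += 1
    df = pd.DataFrame(
        [(s, g, t, a, b, n) for (s, g, t, a, b), n in rows.items()],
        columns=CB_COLUMNS,
    )
    report = TECBuildReport(n_ok, n_empty, n_multi)
    return MutationCountTable(df), report
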