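"""Gene-model container and GTF input/output.

Coordinates are stored 0-based half-open internally; the GTF boundary
(1-based, inclusive) is converted at read/write time.  Exons of a transcript
are kept sorted and merged (adjacent or overlapping exon records collapse
into a single interval), so a transcript's splice junctions are exactly the
internal interval boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from collections.abc import Iterable, Sequence

import gffutils

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or book-ended half-open intervals."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]  # 0-based half-open, sorted, non-overlapping

    def __post_init__(self) -> None:
        self.exons = merge_intervals(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def junctions(self) -> list[Interval]:
        """Intron intervals (donor/acceptor pairs) in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def to_genomic(self, t_start: int, t_end: int) -> list[Interval]:
        """Map a transcript-coordinate interval [t_start, t_end) to genomic blocks.

        Transcript coordinates run 5'-to-3' along the *genomic plus strand*
        exon order (orientation does not matter for compatibility logic).
        """
        if not (0 <= t_start < t_end <= self.length):
            raise ValueError("transcript interval out of range")
        blocks: list[Interval] = []
        offset = 0
        for s, e in self.exons:
            exon_len = e - s
            lo = max(t_start - offset, 0)
            hi = min(t_end - offset, exon_len)
            if lo < hi:
                blocks.append((s + lo, s + hi))
            offset += exon_len
        return blocks


@dataclass
class AnnotationBundle:
    """A set of gene models with optional per-transcript support flags."""

    transcripts: dict[str, Transcript]
    attributes: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def tx2gene(self) -> dict[str, str]:
        return {t.transcript_id: t.gene_id for t in self.transcripts.values()}

    @property
    def genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for tx in self.transcripts.values():
            out.setdefault(tx.gene_id, []).append(tx.transcript_id)
        for v in out.values():
            v.sort()
        return out

    def gene_transcripts(self, gene_id: str) -> list[Transcript]:
        return [self.transcripts[t] for t in self.genes[gene_id]]

    def exonic_union(self, gene_id: str) -> list[Interval]:
        ivs: list[Interval] = []
        for tx in self.gene_transcripts(gene_id):
            ivs.extend(tx.exons)
        return merge_intervals(ivs)

    def gene_span(self, gene_id: str) -> Interval:
        union = self.exonic_union(gene_id)
        return union[0][0], union[-1][1]


def parse_gtf(path: str | Path) -> AnnotationBundle:
    """Parse exon features of a GTF file into an :class:`AnnotationBundle`.

    Exon records missing a ``transcript_id`` attribute raise; records with an
    unknown strand character are kept with strand '.' and a warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    raw: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        if "transcript_id" not in feat.attributes:
            raise ValueError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks transcript_id"
            )
        tx_id = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes.get("gene_id", [tx_id])[0]
        strand = feat.strand if feat.strand in ("+", "-") else "."
        if strand == ".":
            warnings.warn(
                f"transcript {tx_id}: unknown strand kept as '.'", stacklevel=2
            )
        rec = raw.setdefault(
            tx_id,
            {"gene": gene_id, "chrom": feat.seqid, "strand": strand, "exons": []},
        )
        # GTF is 1-based inclusive; internal is 0-based half-open
        rec["exons"].append((feat.start - 1, feat.end))
    transcripts = {
        tx_id: Transcript(tx_id, r["gene"], r["chrom"], r["strand"], r["exons"])
        for tx_id, r in raw.items()
    }
    return AnnotationBundle(transcripts)


def write_gtf(bundle: AnnotationBundle, path: str | Path, source: str = "isodeg") -> None:
    """Write transcript and exon features back to GTF (1-based inclusive)."""
    lines = []
    order = sorted(
        bundle.transcripts.values(), key=lambda t: (t.chrom, t.start, t.transcript_id)
    )
    for tx in order:
        extra = bundle.attributes.get(tx.transcript_id, {})
        attr = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
        for k, v in extra.items():
            attr += f' {k} "{v}";'
        lines.append(
            f"{tx.chrom}\t{source}\ttranscript\t{tx.start + 1}\t{tx.end}\t.\t"
            f"{tx.strand}\t.\t{attr}"
        )
        for s, e in tx.exons:
            lines.append(
                f"{tx.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attr}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def fragment_compatible(blocks: Sequence[Interval], exons: Sequence[Interval]) -> bool:
    """Is a spliced fragment (genomic blocks) compatible with a transcript?

    A fragment is compatible when it is a contiguous sub-path of the
    transcript: every block lies within a single exon, and consecutive blocks
    are joined exactly by one of the transcript's splice junctions.
    """
    # locate the exon containing each block
    idx: list[int] = []
    for bs, be in blocks:
        hit = -1
        for j, (es, ee) in enumerate(exons):
            if es <= bs and be <= ee:
                hit = j
                break
        if hit < 0:
            return False
        idx.append(hit)
    for k in range(len(blocks) - 1):
        j = idx[k]
        if idx[k + 1] != j + 1:
            return False
        if blocks[k][1] != exons[j][1] or blocks[k + 1][0] != exons[j + 1][0]:
            return False
    return True


def assign_tec(
    blocks: Sequence[Interval], candidates: Iterable[Transcript]
) -> tuple[str, ...]:
    """Transcript equivalence class of a fragment among candidate isoforms."""
    return tuple(
        sorted(
            t.transcript_id for t in candidates if fragment_compatible(blocks, t.exons)
        )
    )
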