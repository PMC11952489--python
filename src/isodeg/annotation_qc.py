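"""Annotation support filtering: coverage bins, background tests, trimming.

Gene models assembled or taken from references often contain isoforms with
no read support, or with unsupported terminal extensions.  The procedure
here: (1) split every gene into exonic bins (regions exonic in at least one
isoform, default 200 nt) and intronic bins (intronic in all isoforms,
default 600 nt); (2) estimate a per-gene pre-mRNA background rate from
intronic coverage, regularized toward a genome-wide trend of intronic vs
exonic coverage; (3) test each exonic bin's count against that background
with a one-sided negative-binomial test (BH adjusted); (4) trim unsupported
terminal bins from transcript ends, flag transcripts whose unsupported bins
cannot be removed without altering splice junctions as "problematic", and
flag isoforms with a fully unsupported exon as "unsupported"; (5) score each
gene's junction coverage compatibility (JCC) between observed junction reads
and those predicted from isoform abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import nbinom, poisson

from .annotation import AnnotationBundle, Interval, Transcript, merge_intervals
from .differential import bh_adjust
from .io import AbundanceTable

DEFAULT_EXON_BIN = 200
DEFAULT_INTRON_BIN = 600


def _tile(interval: Interval, size: int) -> list[Interval]:
    s, e = interval
    return [(p, min(p + size, e)) for p in range(s, e, size)]


def make_bins(
    annotation: AnnotationBundle,
    exon_bin: int = DEFAULT_EXON_BIN,
    intron_bin: int = DEFAULT_INTRON_BIN,
) -> pd.DataFrame:
    """Tile every gene into exonic and intronic bins.

    Exonic regions are the union of all isoforms' exons, cut left-to-right
    into chunks of at most ``exon_bin`` nt; intronic regions are the gene
    span minus that union, in chunks of at most ``intron_bin`` nt.  Terminal
    partial bins keep their true lengths.  Intronless genes get no intronic
    bins (their background must come from the genome-wide trend alone).
    """
    rows = []
    for gene in sorted(annotation.genes):
        chrom = annotation.gene_transcripts(gene)[0].chrom
        union = annotation.exonic_union(gene)
        span_s, span_e = union[0][0], union[-1][1]
        intronic: list[Interval] = []
        prev = span_s
        for s, e in union:
            if s > prev:
                intronic.append((prev, s))
            prev = e
        k = 0
        for iv in union:
            for b in _tile(iv, exon_bin):
                rows.append((gene, f"{gene}:E{k}", "exonic", chrom, b[0], b[1], b[1] - b[0]))
                k += 1
        k = 0
        for iv in intronic:
            for b in _tile(iv, intron_bin):
                rows.append((gene, f"{gene}:I{k}", "intronic", chrom, b[0], b[1], b[1] - b[0]))
                k += 1
    return pd.DataFrame(
        rows, columns=["gene", "bin", "kind", "chrom", "start", "end", "length"]
    )


def count_fragments_in_bins(bins: pd.DataFrame, fragments: pd.DataFrame) -> pd.DataFrame:
    """Count fragments overlapping each bin, per sample.

    ``fragments`` needs columns sample, gene, start, end (genomic, half-open,
    one row per aligned fragment block or fragment).  A fragment counts once
    in every bin it overlaps.  Returns the bin table in long form with
    ``sample`` and ``count`` columns.
    """
    out = []
    frag_by_gene = dict(tuple(fragments.groupby("gene", sort=False)))
    samples = sorted(fragments["sample"].unique())
    for gene, gbins in bins.groupby("gene", sort=False):
        frs = frag_by_gene.get(gene)
        for sample in samples:
            if frs is None:
                counts = np.zeros(len(gbins), dtype=int)
            else:
                sub = frs[frs["sample"] == sample]
                fs = sub["start"].to_numpy()
                fe = sub["end"].to_numpy()
                counts = [
                    int(((fs < b_end) & (fe > b_start)).sum())
                    for b_start, b_end in zip(gbins["start"], gbins["end"])
                ]
            block = gbins.copy()
            block["sample"] = sample
            block["count"] = counts
            out.append(block)
    return pd.concat(out, ignore_index=True)


def rpkm(counts: np.ndarray, lengths: np.ndarray, library_size: float) -> np.ndarray:
    return counts / (lengths / 1e3) / (library_size / 1e6)


def regularize_intronic(
    gene_stats: pd.DataFrame,
    prior_weight: float = 10.0,
    min_genes: int = 20,
) -> pd.DataFrame:
    """Shrink per-gene intronic (pre-mRNA background) RPKM toward a trend.

    ``gene_stats`` needs columns gene, exonic_rpkm, intronic_rpkm,
    intronic_reads.  A line of log intronic RPKM on log exonic RPKM is fit
    across genes with observed intronic coverage; each gene's background is
    the precision-weighted combination of its observation (weight: intronic
    read count) and the trend prediction (weight: ``prior_weight`` reads).
    Genes with no intronic signal take the trend value.
    """
    df = gene_stats.copy()
    obs = df[(df["intronic_rpkm"] > 0) & (df["exonic_rpkm"] > 0)]
    if len(obs) >= min_genes and np.log(obs["exonic_rpkm"]).nunique() > 1:
        slope, intercept = np.polyfit(
            np.log(obs["exonic_rpkm"]), np.log(obs["intronic_rpkm"]), deg=1
        )
    else:
        warnings.warn(
            "too few genes (or degenerate spread) for the intronic trend; "
            "using the global mean",
            stacklevel=2,
        )
        slope = 0.0
        intercept = (
            float(np.log(obs["intronic_rpkm"]).mean()) if len(obs) else np.log(0.1)
        )
    log_ex = np.log(np.clip(df["exonic_rpkm"].to_numpy(float), 1e-8, None))
    trend = slope * log_ex + intercept
    w_obs = df["intronic_reads"].to_numpy(float)
    log_obs = np.log(np.clip(df["intronic_rpkm"].to_numpy(float), 1e-12, None))
    has_obs = df["intronic_rpkm"].to_numpy(float) > 0
    post = np.where(
        has_obs,
        (w_obs * log_obs + prior_weight * trend) / (w_obs + prior_weight),
        trend,
    )
    out = df[["gene"]].copy()
    out["background_rpkm"] = np.exp(post)
    out["trend_rpkm"] = np.exp(trend)
    return out


def gene_background(
    bin_counts: pd.DataFrame,
    library_sizes: dict[str, float] | None = None,
    prior_weight: float = 10.0,
) -> pd.DataFrame:
    """Per-gene background RPKM from a long-form bin count table (all samples pooled)."""
    df = bin_counts.copy()
    if library_sizes is None:
        library_sizes = df.groupby("sample")["count"].sum().to_dict()
    pooled = (
        df.groupby(["gene", "bin", "kind", "length"], as_index=False)["count"].sum()
    )
    total_lib = float(sum(library_sizes.values()))
    stats = []
    for gene, grp in pooled.groupby("gene", sort=True):
        ex = grp[grp["kind"] == "exonic"]
        intr = grp[grp["kind"] == "intronic"]
        ex_rpkm = (
            float(rpkm(ex["count"].sum(), ex["length"].sum(), total_lib))
            if len(ex)
            else 0.0
        )
        in_rpkm = (
            float(rpkm(intr["count"].sum(), intr["length"].sum(), total_lib))
            if len(intr)
            else 0.0
        )
        stats.append(
            {
                "gene": gene,
                "exonic_rpkm": ex_rpkm,
                "intronic_rpkm": in_rpkm,
                "intronic_reads": float(intr["count"].sum()) if len(intr) else 0.0,
            }
        )
    return regularize_intronic(pd.DataFrame(stats), prior_weight=prior_weight)


def estimate_dispersion(bin_counts: pd.DataFrame) -> float:
    """Method-of-moments NB dispersion pooled across intronic bins.

    phi solves var = mu + phi * mu^2 per gene's intronic bins, averaged with
    count weights; clipped at a small positive floor.
    """
    intr = bin_counts[bin_counts["kind"] == "intronic"]
    phis = []
    weights = []
    for (_, _), grp in intr.groupby(["gene", "sample"], sort=False):
        if len(grp) < 3:
            continue
        # rate varies with bin length; normalize to per-nt then rescale
        x = grp["count"].to_numpy(float) / grp["length"].to_numpy(float)
        mean_len = float(grp["length"].mean())
        c = x * mean_len
        m, v = float(c.mean()), float(c.var(ddof=1))
        if m > 0:
            phis.append(max((v - m) / m**2, 0.0))
            weights.append(c.sum())
    if not phis:
        return 0.01
    return float(np.average(phis, weights=weights)) if sum(weights) else float(np.mean(phis))


def nb_upper_tail(count: np.ndarray, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """P(X >= count) under NB with mean mu and var mu + dispersion*mu^2.

    As dispersion -> 0 this reduces to the Poisson upper tail.
    """
    count = np.asarray(count, float)
    mu = np.asarray(mu, float)
    if dispersion < 1e-10:
        return poisson.sf(count - 1, mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return nbinom.sf(count - 1, r, p)


def score_exonic_bins(
    bin_counts: pd.DataFrame,
    background: pd.DataFrame,
    dispersion: float | None = None,
    alpha: float = 0.05,
    mu_floor: float = 0.1,
    library_sizes: dict[str, float] | None = None,
) -> pd.DataFrame:
    """One-sided NB support test for every exonic bin in every sample.

    The null mean is background RPKM x bin length (kb) x library size (M
    reads), floored at ``mu_floor`` reads.  A bin is ``supported`` when its
    BH-adjusted p-value is below ``alpha`` in at least one sample.
    """
    if dispersion is None:
        dispersion = estimate_dispersion(bin_counts)
    if library_sizes is None:
        library_sizes = bin_counts.groupby("sample")["count"].sum().to_dict()
    ex = bin_counts[bin_counts["kind"] == "exonic"].copy()
    bg = background.set_index("gene")["background_rpkm"]
    lib = ex["sample"].map(library_sizes).to_numpy(float)
    mu = (
        ex["gene"].map(bg).to_numpy(float)
        * (ex["length"].to_numpy(float) / 1e3)
        * (lib / 1e6)
    )
    mu = np.clip(mu, mu_floor, None)
    ex["mu"] = mu
    ex["p"] = nb_upper_tail(ex["count"].to_numpy(float), mu, dispersion)
    ex["padj"] = np.nan
    for sample, idx in ex.groupby("sample").groups.items():
        ex.loc[idx, "padj"] = bh_adjust(ex.loc[idx, "p"])
    sig = ex[ex["padj"] < alpha]["bin"].unique()
    ex["supported"] = ex["bin"].isin(set(sig))
    ex.attrs["dispersion"] = dispersion
    return ex


def _bin_support_map(bin_support: pd.DataFrame) -> pd.DataFrame:
    """Collapse the per-sample support table to one row per bin."""
    return (
        bin_support.groupby(["gene", "bin", "start", "end"], as_index=False)[
            "supported"
        ]
        .any()
        .sort_values(["gene", "start"])
    )


def trim_and_flag(
    annotation: AnnotationBundle, bin_support: pd.DataFrame
) -> tuple[AnnotationBundle, pd.DataFrame]:
    """Trim unsupported terminal bins; flag non-trimmable transcripts.

    Per transcript, the exonic bins overlapping its exons are walked from
    both genomic ends: a contiguous run of unsupported bins at an end is
    removed as long as the removal only shortens (never eliminates) the
    terminal exon.  Any remaining unsupported bin — one over an internal
    exon, or one whose removal would delete an exon and hence change the
    junction chain — makes the transcript ``problematic`` and it is left
    untrimmed.  Returns the (possibly trimmed) bundle plus a per-transcript
    flag table.
    """
    support = _bin_support_map(bin_support)
    by_gene = dict(tuple(support.groupby("gene", sort=False)))
    new_tx: dict[str, Transcript] = {}
    flags = []
    attributes: dict[str, dict[str, str]] = {}
    for tx_id, tx in annotation.transcripts.items():
        sup = by_gene.get(tx.gene_id)
        if sup is None:
            new_tx[tx_id] = tx
            flags.append({"transcript": tx_id, "trimmed": False, "problematic": False})
            continue
        ov = sup[
            (sup["end"].to_numpy() > tx.start) & (sup["start"].to_numpy() < tx.end)
        ]
        # keep only bins overlapping an actual exon of this transcript
        mask = [
            any(bs < e and be > s for s, e in tx.exons)
            for bs, be in zip(ov["start"], ov["end"])
        ]
        ov = ov[np.array(mask, bool)] if len(ov) else ov
        if len(ov) == 0 or bool(ov["supported"].all()):
            new_tx[tx_id] = tx
            flags.append({"transcript": tx_id, "trimmed": False, "problematic": False})
            continue

        starts = ov["start"].to_numpy()
        ends = ov["end"].to_numpy()
        supported = ov["supported"].to_numpy(bool)
        first_exon, last_exon = tx.exons[0], tx.exons[-1]

        def trimmable(bs: int, be: int, left: bool) -> bool:
            exon = first_exon if left else last_exon
            if not (bs < exon[1] and be > exon[0]):
                return False  # not over the terminal exon
            if left:
                return be < exon[1]  # must leave part of the exon
            return bs > exon[0]

        # contiguous unsupported runs at each end
        k_left = 0
        while k_left < len(supported) and not supported[k_left]:
            k_left += 1
        k_right = len(supported)
        while k_right > max(k_left, 0) and not supported[k_right - 1]:
            k_right -= 1
        left_ok = all(
            trimmable(starts[i], ends[i], left=True) or ends[i] <= tx.start
            for i in range(k_left)
        )
        right_ok = all(
            trimmable(starts[i], ends[i], left=False) or starts[i] >= tx.end
            for i in range(k_right, len(supported))
        )
        internal_unsupported = not supported[k_left:k_right].all() if k_right > k_left else False
        if internal_unsupported or not (left_ok and right_ok) or k_left >= k_right:
            new_tx[tx_id] = tx
            flags.append({"transcript": tx_id, "trimmed": False, "problematic": True})
            attributes[tx_id] = {"problematic": "true"}
            continue

        new_start = max(tx.start, int(ends[:k_left].max())) if k_left > 0 else tx.start
        new_end = (
            min(tx.end, int(starts[k_right:].min()))
            if k_right < len(supported)
            else tx.end
        )
        if new_start == tx.start and new_end == tx.end:
            new_tx[tx_id] = tx
            flags.append({"transcript": tx_id, "trimmed": False, "problematic": False})
            continue
        exons = [
            (max(s, new_start), min(e, new_end))
            for s, e in tx.exons
            if min(e, new_end) > max(s, new_start)
        ]
        new_tx[tx_id] = replace(tx, exons=exons)
        flags.append({"transcript": tx_id, "trimmed": True, "problematic": False})
        attributes[tx_id] = {"problematic": "false"}
    bundle = AnnotationBundle(new_tx, attributes=attributes)
    return bundle, pd.DataFrame(flags)


def flag_unsupported_isoforms(
    annotation: AnnotationBundle,
    bin_support: pd.DataFrame,
    abundance: AbundanceTable,
    min_tpm: float = 1.0,
) -> pd.DataFrame:
    """Isoforms with >= 1 exon lacking above-background coverage in all samples.

    An exon is dead when every exonic bin overlapping it is unsupported in
    every sample.  Reporting (``in_report``) is restricted to isoforms with
    TPM > ``min_tpm`` in all samples, the population for which the call is
    meaningful.
    """
    support = _bin_support_map(bin_support)
    by_gene = dict(tuple(support.groupby("gene", sort=False)))
    tpm_ok = (
        abundance.data.groupby("transcript_id")["TPM"].min().gt(min_tpm).to_dict()
    )
    rows = []
    for tx_id, tx in annotation.transcripts.items():
        sup = by_gene.get(tx.gene_id)
        unsupported = False
        if sup is not None:
            for s, e in tx.exons:
                ov = sup[(sup["end"] > s) & (sup["start"] < e)]
                if len(ov) and not ov["supported"].any():
                    unsupported = True
                    break
        rows.append(
            {
                "transcript": tx_id,
                "gene": tx.gene_id,
                "unsupported": unsupported,
                "in_report": bool(tpm_ok.get(tx_id, False)),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Junction:
    chrom: str
    start: int  # donor (end of upstream exon)
    end: int  # acceptor (start of downstream exon)


def jcc_score(
    junction_counts: pd.DataFrame,
    abundance: AbundanceTable,
    annotation: AnnotationBundle,
) -> pd.DataFrame:
    """Junction coverage compatibility score per gene.

    Observed junction read counts (columns gene, start, end, count) are
    compared with counts predicted proportional to the summed TPM of the
    isoforms containing each junction, rescaled so predicted and observed
    totals match per gene.  JCC = sum |obs - pred| / sum obs; 0 means perfect
    agreement, larger is worse.  Junctions observed but absent from the
    annotation get predicted count 0 (inflating the score) and are logged.
    Genes without junction reads score NA.  Scaling choice is recorded in
    ``DataFrame.attrs['scaling']``.
    """
    mean_tpm = abundance.data.groupby("transcript_id")["TPM"].mean().to_dict()
    rows = []
    unknown = 0
    for gene, txs in annotation.genes.items():
        ann_junc: dict[tuple[int, int], float] = {}
        for tx_id in txs:
            for j in annotation.transcripts[tx_id].junctions:
                ann_junc[j] = ann_junc.get(j, 0.0) + float(mean_tpm.get(tx_id, 0.0))
        obs = junction_counts[junction_counts["gene"] == gene]
        total_obs = float(obs["count"].sum()) if len(obs) else 0.0
        if total_obs == 0:
            rows.append({"gene": gene, "jcc": np.nan, "n_junctions": len(ann_junc)})
            continue
        obs_map = {
            (int(r.start), int(r.end)): float(r.count) for r in obs.itertuples()
        }
        unknown += sum(1 for j in obs_map if j not in ann_junc)
        all_j = set(ann_junc) | set(obs_map)
        pred_raw = np.array([ann_junc.get(j, 0.0) for j in sorted(all_j)])
        obs_v = np.array([obs_map.get(j, 0.0) for j in sorted(all_j)])
        pred = (
            pred_raw * total_obs / pred_raw.sum() if pred_raw.sum() > 0 else pred_raw
        )
        rows.append(
            {
                "gene": gene,
                "jcc": float(np.abs(obs_v - pred).sum() / total_obs),
                "n_junctions": len(all_j),
            }
        )
    if unknown:
        warnings.warn(
            f"{unknown} observed junction(s) absent from the annotation "
            "(predicted count 0)",
            stacklevel=2,
        )
    out = pd.DataFrame(rows)
    out.attrs["scaling"] = "per-gene total-count matching"
    return out


__all__ = [
    "make_bins",
    "count_fragments_in_bins",
    "rpkm",
    "regularize_intronic",
    "gene_background",
    "estimate_dispersion",
    "nb_upper_tail",
    "score_exonic_bins",
    "trim_and_flag",
    "flag_unsupported_isoforms",
    "jcc_score",
]
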