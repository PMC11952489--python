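"""Ground-truth NR-seq simulator at the read-record/count level.

The generator emulates a TimeLapse-seq style experiment: synthetic
multi-isoform gene models with shared and distinguishing regions, kinetic
parameters drawn per isoform (minor isoforms have a 50% chance that their
abundance difference is turnover-driven rather than synthesis-driven),
fragments placed uniformly along transcripts and assigned their transcript
equivalence class by exact compatibility, and per-T T-to-C conversions at
rate ``pnew`` in reads from RNA made during the label window versus the
background ``pold`` otherwise.  No-label control samples are generated with
the fraction new forced to zero.  Everything is reproducible from a single
seed.

Sampling distributions that the emulated protocol does not pin down (the
kinetic parameter priors, expression levels, gene architecture) are
explicit keyword arguments recorded in the truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationBundle, Transcript, assign_tec
from .io import AbundanceTable, MutationCountTable, CB_COLUMNS


def simulate_gene_models(
    n_genes: int,
    seed: int,
    isoform_weights: dict[int, float] | None = None,
    chrom: str = "chrS",
) -> AnnotationBundle:
    """Synthetic gene models with guaranteed isoform-distinguishing regions.

    Each gene's major isoform uses all exons.  Every minor isoform skips a
    distinct internal (cassette) exon and carries a distinct 3' extension of
    its final exon, so each isoform pair differs by at least one exonic
    region in both directions and TECs are informative.
    """
    if isoform_weights is None:
        isoform_weights = {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
    ks = sorted(isoform_weights)
    ws = np.array([isoform_weights[k] for k in ks], float)
    ws = ws / ws.sum()
    rng = np.random.default_rng(seed)
    transcripts: dict[str, Transcript] = {}
    cursor = 1000
    for g in range(n_genes):
        gene = f"G{g:04d}"
        n_iso = int(rng.choice(ks, p=ws))
        n_exons = int(rng.integers(5, 9))
        exon_lens = rng.integers(150, 401, n_exons)
        intron_lens = rng.integers(400, 1001, n_exons - 1)
        exons = []
        pos = cursor
        for i in range(n_exons):
            exons.append((pos, pos + int(exon_lens[i])))
            pos = exons[-1][1] + (int(intron_lens[i]) if i < n_exons - 1 else 0)
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts[f"{gene}.1"] = Transcript(f"{gene}.1", gene, chrom, strand, exons)
        internal = list(range(1, n_exons - 1))
        skip_choice = rng.permutation(internal)[: n_iso - 1]
        for m in range(1, n_iso):
            skipped = int(skip_choice[m - 1])
            iso_exons = [e for i, e in enumerate(exons) if i != skipped]
            ext = 150 + 120 * m
            last_s, last_e = iso_exons[-1]
            iso_exons[-1] = (last_s, last_e + ext)
            transcripts[f"{gene}.{m + 1}"] = Transcript(
                f"{gene}.{m + 1}", gene, chrom, strand, iso_exons
            )
        cursor = max(t.end for t in transcripts.values()) + 2000
    return AnnotationBundle(transcripts)


def simulate_kinetics(
    annotation: AnnotationBundle,
    seed: int,
    tlabel: float = 2.0,
    mean_log_kdeg: float = float(np.log(0.3)),
    sd_log_kdeg: float = 0.8,
    p_differential: float = 0.5,
    gene_tpm_meanlog: float = float(np.log(20.0)),
    gene_tpm_sdlog: float = 1.2,
) -> pd.DataFrame:
    """Draw ground-truth abundances and kinetic parameters per isoform.

    Major isoforms draw log kdeg ~ Normal(mean_log_kdeg, sd_log_kdeg).  Each
    minor isoform flips a Bernoulli(``p_differential``) coin: heads, its kdeg
    is drawn independently (differential turnover); tails, it copies the
    major's kdeg (the abundance difference is synthesis-driven).  TPMs are
    log-normal per gene with a dominant major share, renormalized to 1e6.
    ksyn = TPM * kdeg (steady state) and theta = 1 - exp(-kdeg * tlabel).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, txs in sorted(annotation.genes.items()):
        gene_tpm = float(rng.lognormal(gene_tpm_meanlog, gene_tpm_sdlog))
        n_iso = len(txs)
        if n_iso == 1:
            shares = np.array([1.0])
        else:
            major_share = float(rng.uniform(0.5, 0.9))
            minor = rng.dirichlet(np.ones(n_iso - 1)) * (1 - major_share)
            shares = np.concatenate([[major_share], minor])
        kdeg_major = float(np.exp(rng.normal(mean_log_kdeg, sd_log_kdeg)))
        for j, tx in enumerate(txs):
            if j == 0:
                kdeg = kdeg_major
                differential = False
                is_major = True
            else:
                differential = bool(rng.random() < p_differential)
                kdeg = (
                    float(np.exp(rng.normal(mean_log_kdeg, sd_log_kdeg)))
                    if differential
                    else kdeg_major
                )
                is_major = False
            rows.append(
                {
                    "transcript": tx,
                    "gene": gene,
                    "tpm": gene_tpm * shares[j],
                    "kdeg": kdeg,
                    "is_major": is_major,
                    "differential_turnover": differential,
                }
            )
    truth = pd.DataFrame(rows)
    truth["tpm"] *= 1e6 / truth["tpm"].sum()
    truth["ksyn"] = truth["tpm"] * truth["kdeg"]
    truth["theta"] = 1.0 - np.exp(-truth["kdeg"] * tlabel)
    truth["tlabel"] = tlabel
    return truth


@dataclass
class _TxSegments:
    """Start-position segmentation of a transcript at fixed fragment length.

    The TEC of a fragment [s, s+f) is piecewise constant in s, changing only
    where an endpoint crosses an exon boundary of some isoform of the gene.
    ``breaks`` are the segment right edges; ``labels[k]`` is the TEC label of
    starts in segment k.
    """

    frag_len: int
    n_pos: int
    breaks: np.ndarray
    labels: list[str] = field(default_factory=list)


def _genomic_to_tx(tx: Transcript, g: int) -> int | None:
    off = 0
    for s, e in tx.exons:
        if s <= g <= e:
            return off + (g - s)
        off += e - s
    return None


def _segment_transcript(
    tx: Transcript, gene_txs: list[Transcript], read_len: int
) -> _TxSegments:
    length = tx.length
    f = min(read_len, length)
    n_pos = length - f + 1
    cuts = {0, n_pos}
    bounds: set[int] = set()
    for other in gene_txs:
        for s, e in other.exons:
            bounds.add(s)
            bounds.add(e)
    for g in bounds:
        t = _genomic_to_tx(tx, g)
        if t is None:
            continue
        # containment flips when the start reaches t; junction-spanning flips
        # when the exclusive end s+f first exceeds t, i.e. at s = t - f + 1
        for c in (t, t - f + 1):
            if 0 < c < n_pos:
                cuts.add(int(c))
    edges = np.array(sorted(cuts))
    seg = _TxSegments(frag_len=f, n_pos=n_pos, breaks=edges[1:])
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = (lo + hi) // 2
        blocks = tx.to_genomic(mid, mid + f)
        members = assign_tec(blocks, gene_txs)
        seg.labels.append("+".join(members))
    return seg


def segment_tecs(
    annotation: AnnotationBundle, read_len: int
) -> dict[str, _TxSegments]:
    """Precompute the start-position -> TEC map for every transcript."""
    out = {}
    for gene, tx_ids in annotation.genes.items():
        txs = [annotation.transcripts[t] for t in tx_ids]
        for tx in txs:
            out[tx.transcript_id] = _segment_transcript(tx, txs, read_len)
    return out


def simulate_reads(
    truth: pd.DataFrame,
    annotation: AnnotationBundle,
    depth: int,
    seed: int,
    sample: str = "s1",
    read_len: int = 100,
    pnew: float = 0.05,
    pold: float = 0.002,
    t_frac: float = 0.25,
    labeled: bool = True,
    segments: dict[str, _TxSegments] | None = None,
    return_fragments: bool = False,
) -> tuple[MutationCountTable, pd.DataFrame, pd.DataFrame | None]:
    """Simulate one sample's reads and aggregate them into cB rows.

    Reads are allocated across isoforms proportional to TPM x effective
    length, placed uniformly, and their TEC found by exact compatibility
    against the gene's isoforms.  ``nT`` is binomial in the fragment length
    at T fraction ``t_frac``; T-to-C conversions are binomial at ``pnew``
    for reads drawn "new" (probability theta, or 0 when ``labeled`` is
    False) and ``pold`` otherwise.

    Returns the cB table, a per-isoform assignment summary (reads and
    empirical new fraction, for expected counts and simulator QC), and
    optionally a genomic fragment-block table for coverage counting.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    truth = truth.reset_index(drop=True)
    txs = truth["transcript"].to_numpy()
    zero_exp = truth["tpm"].to_numpy() <= 0
    if zero_exp.any():
        truth = truth[~zero_exp].reset_index(drop=True)
        txs = truth["transcript"].to_numpy()
    if segments is None:
        segments = segment_tecs(annotation, read_len)
    lengths = np.array(
        [annotation.transcripts[t].length for t in txs], float
    )
    w = truth["tpm"].to_numpy() * np.minimum(lengths, 1e9)
    counts = rng.multinomial(depth, w / w.sum())

    gene_col, tec_col, nt_col, tc_col = [], [], [], []
    assign_rows = []
    frag_rows: list[tuple] = []
    for i in np.flatnonzero(counts):
        tx_id = txs[i]
        tx = annotation.transcripts[tx_id]
        seg = segments[tx_id]
        c = int(counts[i])
        theta = float(truth.at[i, "theta"]) if labeled else 0.0
        starts = rng.integers(0, seg.n_pos, c)
        seg_idx = np.searchsorted(seg.breaks, starts, side="right")
        labels = np.array(seg.labels, dtype=object)[seg_idx]
        is_new = rng.random(c) < theta
        nt = rng.binomial(seg.frag_len, t_frac, c)
        tc = np.where(
            is_new, rng.binomial(nt, pnew), rng.binomial(nt, pold)
        )
        gene_col.append(np.full(c, truth.at[i, "gene"], dtype=object))
        tec_col.append(labels)
        nt_col.append(nt)
        tc_col.append(tc)
        assign_rows.append(
            {
                "sample": sample,
                "transcript": tx_id,
                "gene": truth.at[i, "gene"],
                "reads": c,
                "new_reads": int(is_new.sum()),
                "theta_truth": float(truth.at[i, "theta"]),
                "new_T": int(nt[is_new].sum()),
                "new_TC": int(tc[is_new].sum()),
            }
        )
        if return_fragments:
            for s in starts:
                for bs, be in tx.to_genomic(int(s), int(s) + seg.frag_len):
                    frag_rows.append((sample, truth.at[i, "gene"], bs, be))

    reads = pd.DataFrame(
        {
            "sample": sample,
            "XF": np.concatenate(gene_col),
            "TEC": np.concatenate(tec_col),
            "nT": np.concatenate(nt_col),
            "TC": np.concatenate(tc_col),
        }
    )
    cb = (
        reads.groupby(["sample", "XF", "TEC", "nT", "TC"], as_index=False, sort=True)
        .size()
        .rename(columns={"size": "n"})
    )[CB_COLUMNS]
    assignments = pd.DataFrame(assign_rows)
    fragments = (
        pd.DataFrame(frag_rows, columns=["sample", "gene", "start", "end"])
        if return_fragments
        else None
    )
    return MutationCountTable(cb), assignments, fragments


@dataclass
class SimulatedExperiment:
    """Bundle of everything a downstream estimator run needs."""

    annotation: AnnotationBundle
    truth: pd.DataFrame  # per (condition, transcript) ground truth
    cb: MutationCountTable
    abundance: AbundanceTable
    assignments: pd.DataFrame
    samples: pd.DataFrame  # sample, condition, replicate, labeled
    pnew: float
    pold: float
    tlabel: float


def simulate_experiment(
    n_genes: int = 300,
    depth: int = 500_000,
    n_reps: int = 3,
    seed: int = 42,
    tlabel: float = 2.0,
    pnew: float = 0.05,
    pold: float = 0.002,
    read_len: int = 100,
    conditions: dict[str, dict[str, float]] | None = None,
    tpm_noise_sd: float = 0.0,
    nolabel_depth: int | None = None,
    **kinetics_kwargs,
) -> SimulatedExperiment:
    """Simulate a complete multi-replicate NR-seq experiment.

    ``conditions`` maps condition name -> per-transcript kdeg multipliers
    (empty dict for no perturbation); the default is a single unperturbed
    condition.  Each condition gets ``n_reps`` labeled replicates plus one
    no-label control at ``nolabel_depth`` (default: depth // 5).
    """
    if conditions is None:
        conditions = {"ctrl": {}}
    if nolabel_depth is None:
        nolabel_depth = max(depth // 5, 1)
    ss = np.random.SeedSequence(seed)
    child = iter(ss.generate_state(2 + 2 * len(conditions) * (n_reps + 1)) % (2**31))

    annotation = simulate_gene_models(n_genes, seed=int(next(child)))
    base = simulate_kinetics(annotation, seed=int(next(child)), tlabel=tlabel, **kinetics_kwargs)
    segments = segment_tecs(annotation, read_len)

    cb_parts, ab_parts, assign_parts, truth_parts, sample_rows = [], [], [], [], []
    for cond, modifiers in conditions.items():
        truth = base.copy()
        if modifiers:
            scale = truth["transcript"].map(modifiers).fillna(1.0)
            truth["kdeg"] = truth["kdeg"] * scale
            truth["ksyn"] = truth["tpm"] * truth["kdeg"]
            truth["theta"] = 1.0 - np.exp(-truth["kdeg"] * tlabel)
        truth["condition"] = cond
        truth_parts.append(truth)
        for rep in range(1, n_reps + 1):
            name = f"{cond}_rep{rep}"
            cb, assigned, _ = simulate_reads(
                truth,
                annotation,
                depth,
                seed=int(next(child)),
                sample=name,
                read_len=read_len,
                pnew=pnew,
                pold=pold,
                segments=segments,
            )
            cb_parts.append(cb.data)
            assign_parts.append(assigned)
            rng_tpm = np.random.default_rng(int(next(child)))
            tpm = truth["tpm"].to_numpy() * (
                rng_tpm.lognormal(0.0, tpm_noise_sd, len(truth))
                if tpm_noise_sd > 0
                else 1.0
            )
            reads_map = assigned.set_index("transcript")["reads"]
            ab_parts.append(
                pd.DataFrame(
                    {
                        "sample": name,
                        "transcript_id": truth["transcript"],
                        "gene_id": truth["gene"],
                        "TPM": tpm,
                        "expected_count": truth["transcript"]
                        .map(reads_map)
                        .fillna(0.0),
                    }
                )
            )
            sample_rows.append(
                {"sample": name, "condition": cond, "replicate": rep, "labeled": True}
            )
        ctrl_name = f"{cond}_nolabel"
        cb, assigned, _ = simulate_reads(
            truth,
            annotation,
            nolabel_depth,
            seed=int(next(child)),
            sample=ctrl_name,
            read_len=read_len,
            pnew=pnew,
            pold=pold,
            labeled=False,
            segments=segments,
        )
        cb_parts.append(cb.data)
        assign_parts.append(assigned)
        sample_rows.append(
            {"sample": ctrl_name, "condition": cond, "replicate": 0, "labeled": False}
        )

    return SimulatedExperiment(
        annotation=annotation,
        truth=pd.concat(truth_parts, ignore_index=True),
        cb=MutationCountTable(pd.concat(cb_parts, ignore_index=True)),
        abundance=AbundanceTable(pd.concat(ab_parts, ignore_index=True)),
        assignments=pd.concat(assign_parts, ignore_index=True),
        samples=pd.DataFrame(sample_rows),
        pnew=pnew,
        pold=pold,
        tlabel=tlabel,
    )


__all__ = [
    "simulate_gene_models",
    "simulate_kinetics",
    "simulate_reads",
    "simulate_experiment",
    "segment_tecs",
    "SimulatedExperiment",
]
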