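"""TSS-aligned genomic tracks, Statistical DNA Profiles and consensus TSS.

A *Statistical DNA Profile* (SDP) extends the usual metagene average: genes
are aligned at a site (typically the transcription start site), a per-base
signal (nucleosome occupancy, nucleotide content, motif density, ...) is
binned along the aligned coordinate, and in each bin the distribution of
the values of one gene cluster is tested against the values of all other
genes.  Each bin thus reports a direction statistic (normalized rank sum r
or Welch t) and a p-value rather than a bare mean, de-emphasizing regions
where the cluster does not deviate from the genomic background.

Coordinate conventions
----------------------
Genomic coordinates are 1-based.  Aligned (TSS-relative) columns use
TSS = +1 with no position 0; the first upstream base is -1.  Minus-strand
genes are flipped so that transcription runs towards increasing positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrich import ranksum_bias, welch_bias

logger = logging.getLogger(__name__)


def aligned_positions(flank: int = 1500) -> np.ndarray:
    """TSS-relative column positions -flank..-1, +1..+flank (no 0)."""
    return np.concatenate([np.arange(-flank, 0), np.arange(1, flank + 1)])


@dataclass
class TSSRecord:
    gene_id: str
    tss: int                 # position relative to the start codon (negative = upstream)
    n_sites: int
    total_weight: float


def align_track(
    signals: dict,
    tss_table: pd.DataFrame,
    flank: int = 1500,
) -> pd.DataFrame:
    """Extract per-gene windows of a genomic signal centered at the TSS.

    Parameters
    ----------
    signals : chromosome -> 1-D array; index 0 is genomic base 1.
    tss_table : DataFrame with columns gene, chrom, strand, tss (genomic,
        1-based).  Genes whose chromosome is missing are dropped with a log
        message; positions beyond the chromosome ends are set missing.
    flank : half-width of the aligned window.

    Returns a genes x positions DataFrame with columns
    ``aligned_positions(flank)``; column +1 holds the value at the TSS and
    positions increase in the direction of transcription.
    """
    pos = aligned_positions(flank)
    rows, idx = [], []
    dropped = 0
    for rec in tss_table.itertuples(index=False):
        sig = signals.get(rec.chrom)
        if sig is None:
            dropped += 1
            continue
        if rec.strand == "+":
            genomic = np.where(pos > 0, rec.tss + pos - 1, rec.tss + pos)
        else:
            genomic = np.where(pos > 0, rec.tss - pos + 1, rec.tss - pos)
        window = np.full(pos.size, np.nan)
        ok = (genomic >= 1) & (genomic <= len(sig))
        window[ok] = np.asarray(sig)[genomic[ok] - 1]
        rows.append(window)
        idx.append(rec.gene)
    if not rows:
        raise ValueError("no gene with a usable TSS")
    if dropped:
        logger.info("align_track: dropped %d genes without chromosome signal", dropped)
    return pd.DataFrame(rows, index=idx, columns=pos)


def _size_class(p: float, p_strong: float = 1e-5, p_weak: float = 0.05) -> float:
    """Symbol-size class in [0, 1]: 1 at p <= p_strong, 0 at p >= p_weak,
    log10-interpolated between (plot-oriented significance scaling)."""
    if p <= p_strong:
        return 1.0
    if p >= p_weak:
        return 0.0
    return (np.log10(p_weak) - np.log10(p)) / (np.log10(p_weak) - np.log10(p_strong))


def sdp(
    track: pd.DataFrame,
    labels: pd.Series,
    binsize: int = 10,
    test: str = "ranksum",
    p_strong: float = 1e-5,
    p_weak: float = 0.05,
) -> pd.DataFrame:
    """Statistical DNA Profile of an aligned track, cluster vs. rest per bin.

    Positions are tiled into half-open bins of ``binsize`` columns; within
    each bin every gene's values are pooled (averaged, missing positions
    dropped) into one value per gene, and the cluster's genes are compared
    with all other genes by the chosen test — one observation per gene, so
    the position autocorrelation within a gene is never pseudo-replicated.
    Output is a tidy table with one row per (cluster, bin):
    ``cluster, bin_start, bin_end, mean, stat, p, size_class``, where
    ``stat`` is the normalized rank sum r (ranksum) or the Welch t.
    Genes without any value in a bin drop out of that bin's test.
    """
    if test not in ("ranksum", "welch"):
        raise ValueError(f"unknown test {test!r}")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("SDP needs at least 2 clusters")
    positions = np.asarray(track.columns, dtype=int)
    if positions.size % binsize != 0:
        raise ValueError(f"binsize {binsize} does not tile {positions.size} positions")
    genes = track.index.intersection(labels.index)
    track = track.loc[genes]
    labs = labels.loc[genes]
    values = track.to_numpy(dtype=float)
    rows = []
    for start in range(0, positions.size, binsize):
        cols = slice(start, start + binsize)
        bin_pos = positions[cols]
        block = values[:, cols]
        counts = np.sum(~np.isnan(block), axis=1)
        per_gene = np.where(counts > 0, np.nansum(block, axis=1) / np.maximum(counts, 1),
                            np.nan)
        for cl in clusters:
            mask = (labs == cl).to_numpy()
            xs = per_gene[mask]
            ys = per_gene[~mask]
            xs, ys = xs[~np.isnan(xs)], ys[~np.isnan(ys)]
            if xs.size == 0 or ys.size == 0:
                continue
            if test == "ranksum":
                res = ranksum_bias(xs, ys)
                stat, p = res.r, res.p
            else:
                stat, _, p = welch_bias(xs, ys)
            rows.append(dict(cluster=cl, bin_start=int(bin_pos[0]),
                             bin_end=int(bin_pos[-1]), mean=float(xs.mean()),
                             stat=float(stat), p=float(p),
                             size_class=_size_class(p, p_strong, p_weak)))
    return pd.DataFrame(rows)


def sliding_content(sequence: str, window: int = 71, symbols=("G", "C")) -> np.ndarray:
    """Centered sliding-window frequency of a symbol set along a sequence.

    GC content uses symbols {G, C}; purine content {A, G}.  The first and
    last ``window//2`` positions are reported missing.  Non-ACGT symbols
    count in the window denominator but never in the numerator.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    seq = sequence.upper()
    if len(seq) < window:
        raise ValueError("sequence shorter than the window")
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n_other = int(np.sum(~np.isin(arr, [b"A", b"C", b"G", b"T"])))
    if n_other:
        logger.info("sliding_content: %d non-ACGT symbols in denominator only", n_other)
    hit = np.isin(arr, [s.encode("ascii") for s in symbols]).astype(float)
    kernel = np.ones(window)
    counts = np.convolve(hit, kernel, mode="valid") / window
    half = window // 2
    out = np.full(len(seq), np.nan)
    out[half:len(seq) - half] = counts
    return out


def sdp_sequence(
    content: pd.DataFrame,
    labels: pd.Series,
    step: int = 10,
    p_strong: float = 1e-5,
    p_weak: float = 0.05,
) -> pd.DataFrame:
    """Per-position Welch SDP of a nucleotide-content track, unbinned.

    Tests are performed at every ``step``-th position (no prior binning of
    values); the sign of t gives the direction of the cluster's bias.
    """
    genes = content.index.intersection(labels.index)
    content = content.loc[genes]
    labs = labels.loc[genes]
    positions = list(content.columns)[::step]
    rows = []
    for pos in positions:
        col = content[pos].to_numpy(dtype=float)
        for cl in sorted(labs.unique()):
            mask = (labs == cl).to_numpy()
            xs, ys = col[mask], col[~mask]
            xs, ys = xs[~np.isnan(xs)], ys[~np.isnan(ys)]
            if xs.size < 2 or ys.size < 2:
                continue
            t, _, p = welch_bias(xs, ys)
            rows.append(dict(cluster=cl, position=pos, mean=float(xs.mean()),
                             stat=float(t), p=float(p),
                             size_class=_size_class(p, p_strong, p_weak)))
    return pd.DataFrame(rows)


def consensus_tss(
    evidence: pd.DataFrame,
    window: int = 73,
    max_upstream: int = 400,
) -> pd.DataFrame:
    """Consensus TSS per gene from multiple evidence sites.

    Sites (start-codon-relative positions, upstream negative, optional
    weights defaulting to 1) are greedily clustered: sorted by position, a
    site joins the current group while it lies within ``window`` nt (about
    half a nucleosome length at the default 73) of the group's running
    weighted center.  Each group's consensus is its weighted mean position,
    rounded to the nearest integer toward the start codon.  Among consensus
    candidates within [-max_upstream, -1], the one closest to the start
    codon is the gene's TSS; genes with no candidate in range get none.
    Zero- or negative-weight sites are skipped.  The result is independent
    of the input row order.
    """
    ev = evidence.copy()
    if "weight" not in ev.columns:
        ev["weight"] = 1.0
    ev = ev[ev["weight"] > 0]
    records = []
    for gene, grp in ev.groupby("gene", sort=False):
        grp = grp.sort_values("position")
        groups = []                     # (center, total_weight, n_sites)
        center = w = cnt = None
        for posn, wt in zip(grp["position"], grp["weight"]):
            if center is not None and abs(posn - center) <= window:
                center = (center * w + posn * wt) / (w + wt)
                w += wt
                cnt += 1
            else:
                if center is not None:
                    groups.append((center, w, cnt))
                center, w, cnt = float(posn), float(wt), 1
        if center is not None:
            groups.append((center, w, cnt))
        # round toward the start codon: for upstream (negative) positions
        # this is the usual half-up rounding
        cands = [(int(np.floor(c + 0.5)), tw, nc) for c, tw, nc in groups]
        in_range = [c for c in cands if -max_upstream <= c[0] <= -1]
        if not in_range:
            continue
        tss, tw, nc = max(in_range, key=lambda c: c[0])
        records.append(dict(gene=gene, tss=tss, n_sites=nc, total_weight=tw))
    return pd.DataFrame(records, columns=["gene", "tss", "n_sites", "total_weight"])


def tss_to_genomic(tss_rel: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Map start-codon-relative consensus TSS to genomic coordinates.

    ``annotation`` needs columns gene, chrom, strand, start (genomic 1-based
    coordinate of the A of the start codon; for minus-strand genes this is
    the higher coordinate).  Relative position -1 is the base immediately
    upstream of the start codon.
    """
    ann = annotation.set_index("gene")
    rows = []
    for rec in tss_rel.itertuples(index=False):
        if rec.gene not in ann.index:
            continue
        a = ann.loc[rec.gene]
        genomic = a.start + rec.tss if a.strand == "+" else a.start - rec.tss
        rows.append(dict(gene=rec.gene, chrom=a.chrom, strand=a.strand,
                         tss=int(genomic), tss_relative=int(rec.tss)))
    return pd.DataFrame(rows, columns=["gene", "chrom", "strand", "tss", "tss_relative"])
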