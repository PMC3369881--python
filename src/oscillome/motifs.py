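"""PWM and IUPAC motif scanning of promoter and 3' regions.

Position weight matrices are used exactly as published: the score of a
window is the plain sum of the per-position weights of its bases and a hit
is called at >= 80% of the matrix's maximum achievable score (the fraction
is configurable).  IUPAC consensus motifs are matched as exact degenerate
patterns.  Search ranges follow the anchor-relative suffix conventions of
the source tables: 500 nt upstream of the START codon or downstream of the
STOP codon by default, "TATA.350" = [-350, -1] of START, "TATA.500" =
[-500, -351], and a ".3p" suffix marking the downstream-of-STOP range.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTNRYWSKMBDHV", "TGCANYRWSMKVHDB")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position weight matrix with rows A, C, G, T."""

    id: str
    weights: np.ndarray          # 4 x L

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != 4 or self.weights.shape[1] < 2:
            raise ValueError(f"PWM {self.id}: need a 4 x L matrix with L >= 2")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError(f"PWM {self.id}: non-finite weights")

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())


@dataclass
class Hit:
    position: int      # 1-based start on the scanned sequence
    strand: str        # '+' or '-'
    score: float | None = None


def _scan_one_strand(seq: str, pwm: PWM, threshold: float) -> list[tuple[int, float]]:
    L = pwm.length
    if len(seq) < L:
        return []
    codes = np.full(len(seq), -1, dtype=int)
    for b, i in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode("ascii"), dtype="S1") == b.encode()] = i
    hits = []
    for off in range(len(seq) - L + 1):
        window = codes[off:off + L]
        if np.any(window < 0):          # window contains N or other ambiguity
            continue
        score = float(pwm.weights[window, np.arange(L)].sum())
        if score >= threshold:
            hits.append((off + 1, score))
    return hits


def pwm_scan(sequence: str, pwm: PWM, frac: float = 0.8,
             strands: str = "both") -> list[Hit]:
    """All PWM hits scoring at least ``frac`` of the maximum possible score.

    Windows containing non-ACGT symbols are skipped.  Reverse-strand hits
    are reported by the 1-based start of the matched window on the forward
    sequence.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    seq = sequence.upper()
    threshold = frac * pwm.max_score
    hits = [Hit(pos, "+", score) for pos, score in _scan_one_strand(seq, pwm, threshold)]
    if strands == "both":
        rc = reverse_complement(seq)
        for pos, score in _scan_one_strand(rc, pwm, threshold):
            hits.append(Hit(len(seq) - pos - pwm.length + 2, "-", score))
    elif strands != "sense":
        raise ValueError(f"unknown strands option {strands!r}")
    return sorted(hits, key=lambda h: (h.position, h.strand))


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for code in motif.upper():
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC code {code!r} in motif {motif!r}")
        opts = IUPAC[code]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so that overlapping matches are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def iupac_scan(sequence: str, motif: str, strands: str = "both") -> list[Hit]:
    """Exact degenerate matching of an IUPAC consensus motif.

    Sequence N (or any non-ACGT symbol) never matches, including against
    the motif code N.
    """
    seq = sequence.upper()
    pat = _iupac_regex(motif)
    hits = [Hit(m.start() + 1, "+") for m in pat.finditer(seq)]
    if strands == "both":
        rc = reverse_complement(seq)
        for m in pat.finditer(rc):
            hits.append(Hit(len(seq) - m.start() - len(motif) + 1, "-"))
    elif strands != "sense":
        raise ValueError(f"unknown strands option {strands!r}")
    return sorted(hits, key=lambda h: (h.position, h.strand))


@dataclass
class RangeSpec:
    """Anchor-relative search range in promoter coordinates (no position 0).

    START anchor: +1 is the A of the start codon, -1 the first upstream
    base.  STOP anchor: +1 is the first base downstream of the stop codon.
    Upstream coordinates are negative.
    """

    anchor: str                 # "START" | "STOP"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.anchor not in ("START", "STOP"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.start == 0 or self.end == 0 or self.start > self.end:
            raise ValueError(f"invalid range [{self.start}, {self.end}] (no 0; start <= end)")

    @classmethod
    def from_name(cls, name: str, span: int = 500) -> "RangeSpec":
        """Range convention from a motif-table name suffix."""
        if name.endswith(".3p"):
            return cls("STOP", 1, span)
        if name.endswith(".350"):
            return cls("START", -350, -1)
        if name.endswith(".500") and "TATA" in name.upper():
            return cls("START", -500, -351)
        return cls("START", -span, -1)


def extract_range(gene, genome: dict, range_spec: RangeSpec) -> str:
    """Anchor-relative sequence slice in transcription orientation.

    ``gene`` provides gene, chrom, strand, start (A of the start codon) and
    stop (last base of the stop codon), all genomic 1-based; minus-strand
    genes are reverse-complemented.  Ranges running off a chromosome end
    are truncated (logged).
    """
    chrom = genome.get(gene.chrom)
    if chrom is None:
        raise KeyError(f"chromosome {gene.chrom!r} not in genome")
    if range_spec.anchor == "START":
        anchor, before = int(gene.start), True
    else:
        anchor, before = int(gene.stop), False

    def rel_to_genomic(r: int) -> int:
        if range_spec.anchor == "START":
            off = r if r < 0 else r - 1            # no position 0; +1 == anchor base
        else:
            off = r if r > 0 else r + 1            # +1 == first base after stop
        return anchor + off if gene.strand == "+" else anchor - off

    g1 = rel_to_genomic(range_spec.start)
    g2 = rel_to_genomic(range_spec.end)
    lo, hi = min(g1, g2), max(g1, g2)
    clo, chi = max(lo, 1), min(hi, len(chrom))
    if (clo, chi) != (lo, hi):
        logger.info("range for %s truncated at chromosome bounds", gene.gene)
    if clo > chi:
        return ""
    seq = chrom[clo - 1:chi]
    return seq.upper() if gene.strand == "+" else reverse_complement(seq)


def motif_presence(
    annotation: pd.DataFrame,
    genome: dict,
    motifs: dict,
    frac: float = 0.8,
    strands: str = "both",
) -> pd.DataFrame:
    """Binary gene x motif presence table over configured search ranges.

    ``motifs`` maps a motif name to a (PWM-or-IUPAC-string, RangeSpec)
    pair.  A gene scores 1 for a motif if at least one hit falls in the
    range (duplicated hits count once).  The table feeds hypergeometric
    enrichment of clusters in motif carriers.
    """
    out = pd.DataFrame(0, index=annotation["gene"], columns=list(motifs), dtype=int)
    for name, (motif, rng) in motifs.items():
        for gene in annotation.itertuples(index=False):
            seq = extract_range(gene, genome, rng)
            if not seq:
                continue
            if isinstance(motif, PWM):
                hits = pwm_scan(seq, motif, frac=frac, strands=strands)
            else:
                hits = iupac_scan(seq, motif, strands=strands)
            if hits:
                out.loc[gene.gene, name] = 1
    return out
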