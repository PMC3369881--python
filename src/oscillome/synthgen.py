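"""Synthetic oscillating transcriptomes and genome fixtures with planted structure.

Two kinds of inputs are generated, mirroring the statistical structure the
analysis assumes so that every downstream stage can be tested against a
known truth:

* two multi-cycle oscillation time-series experiments with different
  periods and sampling (phase-cohort cluster structure, non-oscillating
  background genes, per-array multiplicative scaling artifacts and
  heavy-tailed intensity noise), and
* a toy genome — annotation, chromosome sequences, TSS evidence, aligned
  genomic tracks, GO-style categories, numeric gene data and an expression
  compendium — with cluster-specific motifs, track signatures and
  enrichment blocks planted at stated rates.

The noise model is multiplicative log-normal array scaling times an
additive scaled-t term (heavy tails, dof configurable), emulating raw
summarized microarray intensities that resist conventional normalization.
Gene base intensities are drawn log-uniformly over two decades
(microarray-like dynamic range); planted phases get per-gene wrapped-normal
jitter (default SD 10 degrees).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import aligned_positions

logger = logging.getLogger(__name__)

#: Default phase cohorts: seven consensus-style co-expression cohorts spread
#: over the cycle (label, phase angle in degrees, fraction of genes).
DEFAULT_COHORTS = [
    ("A", 10.0, 0.10),
    ("AB", 61.0, 0.10),
    ("B", 112.0, 0.10),
    ("B.C", 163.0, 0.10),
    ("C", 214.0, 0.10),
    ("B.D", 265.0, 0.10),
    ("D", 316.0, 0.10),
]


@dataclass
class OscillomeSpec:
    """Configuration of the two-experiment synthetic oscillome.

    Cohort fractions must sum to <= 1; the remainder (and any explicit
    ``frac_background``) are non-oscillating background genes.  Periods are
    in hours; each experiment spans ``n_cycles`` phenotypic cycles sampled
    ``samples_per_cycle`` times per cycle (>= 4, the Nyquist requirement
    for reading the phenotypic frequency).
    """

    n_genes: int = 1000
    cluster_phases: list = field(default_factory=lambda: list(DEFAULT_COHORTS))
    periods: tuple = (0.7, 5.0)
    n_cycles: tuple = (4, 3)
    samples_per_cycle: tuple = (10, 12)
    amplitude: float = 0.4
    noise_sd: float = 0.05
    t_dof: float = 5.0
    array_scale_sd: float = 0.1
    frac_background: float | None = None
    phase_jitter_sd: float = 10.0
    base_intensity_range: tuple = (100.0, 10_000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        frac = sum(f for _, _, f in self.cluster_phases)
        if frac > 1 + 1e-9:
            raise ValueError(f"cohort fractions sum to {frac:.3f} > 1")
        if self.frac_background is None:
            self.frac_background = 1.0 - frac
        elif frac + self.frac_background > 1 + 1e-9:
            raise ValueError("cohort fractions plus background exceed 1")
        if any(p <= 0 for p in self.periods):
            raise ValueError("periods must be positive")
        if any(s < 4 for s in self.samples_per_cycle):
            raise ValueError("need >= 4 samples per cycle (Nyquist)")


@dataclass
class SyntheticExperiment:
    """One simulated time-series experiment: genes x timepoints intensities."""

    matrix: pd.DataFrame          # columns are sample times
    period: float
    k_osc: int

    @property
    def sample_times(self) -> np.ndarray:
        return np.asarray(self.matrix.columns, dtype=float)


def _wrapped_normal(rng, sd_deg: float, size) -> np.ndarray:
    return np.deg2rad(rng.normal(0.0, sd_deg, size=size))


def generate_oscillome(spec: OscillomeSpec):
    """Simulate the two oscillation experiments and the planted truth table.

    Oscillating genes follow
    ``base_g * (1 + a*cos(2*pi*k_osc*n/N + phi_cohort + jitter_g)) * scale_n
    + t-noise``; background genes omit the cosine.  Both experiments share
    gene identities, cohort memberships and cohort phase angles (the phase
    is an angle within the phenotypic cycle, so it transfers across
    periods).  Returns ``(experiment_1, experiment_2, truth)`` where truth
    has columns cohort, phase_deg, amplitude, base.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene")

    counts = [int(round(f * n)) for _, _, f in spec.cluster_phases]
    if sum(counts) > n:
        raise ValueError("cohort fractions overflow the gene count")
    labels = np.array(["bg"] * n, dtype=object)
    phases = np.zeros(n)
    order = rng.permutation(n)
    pos = 0
    for (lab, phi, _), cnt in zip(spec.cluster_phases, counts):
        idx = order[pos:pos + cnt]
        labels[idx] = lab
        phases[idx] = np.deg2rad(phi)
        pos += cnt
    oscillating = labels != "bg"
    jitter = _wrapped_normal(rng, spec.phase_jitter_sd, n)
    phases = phases + jitter

    lo, hi = spec.base_intensity_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    amp = np.where(oscillating, spec.amplitude, 0.0)

    experiments = []
    for period, k_osc, spc in zip(spec.periods, spec.n_cycles, spec.samples_per_cycle):
        N = k_osc * spc
        t_idx = np.arange(N)
        cosine = np.cos(2 * np.pi * k_osc * t_idx[None, :] / N + phases[:, None])
        clean = base[:, None] * (1.0 + amp[:, None] * cosine)
        scale = np.exp(rng.normal(0.0, spec.array_scale_sd, size=N)) \
            if spec.array_scale_sd > 0 else np.ones(N)
        noise = (rng.standard_t(spec.t_dof, size=(n, N)) * spec.noise_sd * base[:, None]
                 if spec.noise_sd > 0 else 0.0)
        values = clean * scale[None, :] + noise
        times = np.round(t_idx * period / spc, 6)
        experiments.append(SyntheticExperiment(
            matrix=pd.DataFrame(values, index=genes, columns=times),
            period=period, k_osc=k_osc))

    truth = pd.DataFrame({
        "cohort": labels,
        "phase_deg": np.where(oscillating, np.rad2deg(phases) % 360.0, np.nan),
        "amplitude": amp,
        "base": base,
    }, index=genes)
    return experiments[0], experiments[1], truth


# ---------------------------------------------------------------------------
# genome fixture
# ---------------------------------------------------------------------------

@dataclass
class GenomeFixtureConfig:
    """What to plant, per cluster, in the toy genome.

    ``motif_plants`` maps motif name -> (iupac, cluster, frac_in_cluster,
    frac_elsewhere); ``dip_cluster`` gets an occupancy dip over
    ``dip_interval`` in the "occupancy" track; ``category_plants`` maps a
    term -> (cluster, n_category, frac_from_cluster); compendium experiments
    carry anti-correlated up/down blocks for ``comp_up_cluster`` vs
    ``comp_down_cluster`` in half of the experiments.
    """

    motif_plants: dict = field(default_factory=lambda: {
        "TATA.350": ("TATAWAW", "D", 0.5, 0.05),
    })
    dip_cluster: str = "D"
    dip_interval: tuple = (-150, -50)
    dip_depth: float = 1.0
    track_flank: int = 300
    track_noise_sd: float = 1.0
    category_plants: dict = field(default_factory=lambda: {
        "growth": ("A", 120, 0.5),
    })
    n_random_categories: int = 5
    n_experiments: int = 60
    comp_up_cluster: str = "A"
    comp_down_cluster: str = "D"
    comp_effect: float = 2.0
    promoter_len: int = 500
    gene_len: int = 600
    spacing: int = 2000
    n_chroms: int = 2
    seed: int = 0


@dataclass
class GenomeFixture:
    annotation: pd.DataFrame        # gene, chrom, strand, start, stop
    sequences: dict                 # chrom -> str
    tss_evidence: pd.DataFrame      # gene, position, weight, source
    tracks: dict                    # name -> genes x aligned-positions DataFrame
    categories: dict                # term -> set of genes
    numeric_data: pd.DataFrame      # per-gene numeric columns
    compendium: pd.DataFrame        # genes x experiments
    truth: dict                     # planted structure, for recovery tests


def _realize_iupac(motif: str, rng) -> str:
    from .motifs import IUPAC
    return "".join(rng.choice(list(IUPAC[c])) for c in motif.upper())


def generate_genome_fixture(labels: pd.Series,
                            config: GenomeFixtureConfig | None = None) -> GenomeFixture:
    """Build the toy genome around an existing cluster labeling.

    Genes are laid out on ``n_chroms`` chromosomes with alternating strands
    and generous spacing; promoters of designated clusters carry planted
    motif instances at the configured per-cluster rates, the occupancy-like
    track gets a planted dip for one cluster, categories overlap clusters
    at stated rates, and the compendium carries anti-correlated up/down
    blocks.  The planted truth is retained for recovery tests.
    """
    cfg = config or GenomeFixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = list(labels.index)
    for name, (motif, *_rest) in cfg.motif_plants.items():
        if len(motif) > cfg.promoter_len:
            raise ValueError(f"motif {name!r} longer than the promoter ({cfg.promoter_len} nt)")

    # --- annotation and sequences -------------------------------------
    per_chrom = int(np.ceil(len(genes) / cfg.n_chroms))
    records = []
    chrom_len = {}
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        sub = genes[ci * per_chrom:(ci + 1) * per_chrom]
        coord = cfg.spacing
        for gi, g in enumerate(sub):
            strand = "+" if gi % 2 == 0 else "-"
            if strand == "+":
                start, stop = coord, coord + cfg.gene_len - 1
            else:
                start, stop = coord + cfg.gene_len - 1, coord
            records.append(dict(gene=g, chrom=chrom, strand=strand,
                                start=start, stop=stop))
            coord += cfg.spacing
        chrom_len[chrom] = coord + cfg.spacing
    annotation = pd.DataFrame(records)
    seqs = {c: rng.choice(list("ACGT"), size=L) for c, L in chrom_len.items()}

    # --- planted motifs ------------------------------------------------
    motif_truth = {}
    for name, (motif, cluster, f_in, f_out) in cfg.motif_plants.items():
        carriers = []
        for rec in annotation.itertuples(index=False):
            f = f_in if labels.get(rec.gene) == cluster else f_out
            if rng.random() >= f:
                continue
            inst = _realize_iupac(motif, rng)
            offset = int(rng.integers(20, cfg.promoter_len - len(motif) - 20))
            # place at promoter-relative position -offset on the sense strand
            if rec.strand == "+":
                g0 = rec.start - offset - len(inst)       # 0-based slice start
                seqs[rec.chrom][g0:g0 + len(inst)] = list(inst)
            else:
                g0 = rec.start + offset                    # genomic, 0-based
                rc = inst.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                seqs[rec.chrom][g0:g0 + len(inst)] = list(rc)
            carriers.append(rec.gene)
        motif_truth[name] = set(carriers)
    sequences = {c: "".join(a) for c, a in seqs.items()}

    # --- TSS evidence ---------------------------------------------------
    ev_rows = []
    for g in genes:
        n_sites = int(rng.integers(1, 4))
        center = -int(rng.integers(40, 200))
        for s in range(n_sites):
            ev_rows.append(dict(gene=g,
                                position=center + int(rng.integers(-15, 16)),
                                weight=float(rng.integers(1, 5)),
                                source=f"src{s + 1}"))
    tss_evidence = pd.DataFrame(ev_rows)

    # --- aligned tracks -------------------------------------------------
    pos = aligned_positions(cfg.track_flank)
    occ = rng.normal(0.0, cfg.track_noise_sd, size=(len(genes), pos.size))
    dip_cols = (pos >= cfg.dip_interval[0]) & (pos <= cfg.dip_interval[1])
    dip_rows = np.array([labels.get(g) == cfg.dip_cluster for g in genes])
    occ[np.ix_(dip_rows, dip_cols)] -= cfg.dip_depth
    tracks = {"occupancy": pd.DataFrame(occ, index=pd.Index(genes, name="gene"),
                                        columns=pos)}

    # --- categories -----------------------------------------------------
    categories = {}
    for term, (cluster, n_cat, f_from) in cfg.category_plants.items():
        members = [g for g in genes if labels.get(g) == cluster]
        others = [g for g in genes if labels.get(g) != cluster]
        n_cat = min(n_cat, len(genes))
        k_in = min(int(round(f_from * n_cat)), len(members))
        n_out = min(n_cat - k_in, len(others))
        chosen = list(rng.choice(members, size=k_in, replace=False))
        chosen += list(rng.choice(others, size=n_out, replace=False))
        categories[term] = set(chosen)
    for i in range(cfg.n_random_categories):
        size = int(rng.integers(20, min(100, len(genes))))
        categories[f"random{i + 1}"] = set(rng.choice(genes, size=size, replace=False))

    # --- numeric data ---------------------------------------------------
    numeric = pd.DataFrame({
        "expression_level": rng.lognormal(5.0, 1.0, size=len(genes)),
        "orf_length": rng.integers(300, 3000, size=len(genes)).astype(float),
    }, index=pd.Index(genes, name="gene"))

    # --- compendium -----------------------------------------------------
    comp = rng.normal(0.0, 1.0, size=(len(genes), cfg.n_experiments))
    up = np.array([labels.get(g) == cfg.comp_up_cluster for g in genes])
    down = np.array([labels.get(g) == cfg.comp_down_cluster for g in genes])
    half = cfg.n_experiments // 2
    quarter = cfg.n_experiments // 4
    comp[np.ix_(up, np.arange(half))] += cfg.comp_effect
    comp[np.ix_(down, np.arange(half))] -= cfg.comp_effect
    comp[np.ix_(up, np.arange(half, half + quarter))] -= cfg.comp_effect
    comp[np.ix_(down, np.arange(half, half + quarter))] += cfg.comp_effect
    compendium = pd.DataFrame(comp, index=pd.Index(genes, name="gene"),
                              columns=[f"exp{j + 1:03d}" for j in range(cfg.n_experiments)])

    truth = dict(
        motif_carriers=motif_truth,
        dip_cluster=cfg.dip_cluster,
        dip_interval=cfg.dip_interval,
        category_plants=dict(cfg.category_plants),
        compendium_blocks=dict(up=cfg.comp_up_cluster, down=cfg.comp_down_cluster,
                               n_up_experiments=half, n_flipped=quarter),
    )
    return GenomeFixture(annotation=annotation, sequences=sequences,
                         tss_evidence=tss_evidence, tracks=tracks,
                         categories=categories, numeric_data=numeric,
                         compendium=compendium, truth=truth)
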