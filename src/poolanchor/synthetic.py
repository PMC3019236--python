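"""Synthetic chromosomes, minimal tiling paths, 3-D pools and hybridisation signals.

The generator emulates the statistical structure the analysis assumes:

* a minimal tiling path (MTP) covering a configurable fraction of the
  chromosome (default 82%) with ~30% pairwise BAC overlap, split into
  contigs separated by gaps;
* three-dimensional plate/row/column pools over the BAC wells;
* a centromere-to-telomere gene-density gradient (default twofold) with a
  distance-dependent fraction of genes clustered in islands;
* identity-dependent hybridisation attenuation — no loss at 100%
  probe-target identity, a per-probe decrease drawn from [0.73, 0.99] at
  90% identity, total loss at or below a detectability floor (80%) —
  interpolated piecewise linearly;
* per-BAC abundance heterogeneity (log-normal) and log-normal background;
* repeat-derived probes that light up many unrelated pools;
* synthetic barley genetic-map and rice ortholog references with known
  non-syntenic fractions, for synteny/collinearity recovery tests.

Default sizes are desk-scale (4 x 8 x 12 pool geometry, ~350 BACs on a
100 Mb chromosome, 800 genes), geometry-proportional to the 20 x 16 x 24
plate design of the real screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from poolanchor.core_io import (
    AXES,
    BACRecord,
    DeletionBin,
    GeneticMap,
    OrthologTable,
    PhysicalMap,
    RepeatLibrary,
    ROW_LETTERS,
)
from poolanchor.pooling import PoolLayout, SignalMatrix

_NUC = np.array(list("ACGT"))

# deletion-line style breakpoints, as fractions of each arm measured from
# the centromere (matching the 8-bin layout of wheat 3B)
_ARM_FRACTIONS_S = (1.00, 0.78, 0.57, 0.33, 0.0)
_ARM_FRACTIONS_L = (0.0, 0.22, 0.50, 0.63, 1.00)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic screen.  Lengths in bp, fractions in [0, 1]."""

    chromosome_length_bp: int = 100_000_000
    n_plates: int = 20
    n_rows: int = 16
    n_cols: int = 24
    well_assignment: str = "scattered"  # or "sequential" (plate-by-plate)
    bac_length_mean_bp: int = 335_000
    bac_length_jitter: float = 0.10
    mtp_overlap_fraction: float = 0.30
    mtp_coverage_fraction: float = 0.82
    mean_bacs_per_contig: float = 8.0
    unbinned_contig_fraction: float = 0.10
    centromere_fraction: float = 0.40  # short-arm share of the chromosome
    n_genes: int = 800
    density_gradient_ratio: float = 2.0  # telomere / centromere
    island_fraction_distal: float = 0.5
    island_fraction_proximal: float = 0.2
    island_gap_bp: int = 15_000  # desk-scale chromosome is ~10x smaller than 3B
    island_size_mean: float = 3.0
    duplicate_probability: float = 0.02
    identity_distribution: tuple = ("normal", 0.90, 0.04)
    attenuation_range: tuple[float, float] = (0.73, 0.99)
    detectability_floor: float = 0.80
    base_signal: float = 100.0
    background_lognormal: tuple[float, float] = (0.0, 0.25)  # (mu, sigma) of log
    bac_abundance_cv: float = 0.30
    n_te_probes: int = 5
    te_pool_fraction: float = 0.30
    nonsyntenic_fraction_barley: float = 0.32
    nonsyntenic_fraction_rice: float = 0.41
    mapped_fraction_barley: float = 0.42
    mapped_fraction_rice: float = 0.89
    reference_cM_noise: float = 1.5
    reference_order_noise_bp: float = 2_000_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "mtp_overlap_fraction",
            "mtp_coverage_fraction",
            "island_fraction_distal",
            "island_fraction_proximal",
            "unbinned_contig_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.density_gradient_ratio < 1.0:
            raise ValueError("density_gradient_ratio must be >= 1")
        if self.island_gap_bp >= 150_000 * 10:
            raise ValueError("island_gap_bp is implausibly large")

    @property
    def capacity(self) -> int:
        return self.n_plates * self.n_rows * self.n_cols


@dataclass
class Placement:
    position_bp: int
    bac_ids: tuple[str, ...]


@dataclass
class GeneTruth:
    probe_id: str
    placements: list[Placement]
    identity: float
    island_id: int | None = None  # generation-time cluster, None = isolated


@dataclass
class TruthSet:
    """Ground truth of a simulation, for recovery testing."""

    genes: dict[str, GeneTruth] = field(default_factory=dict)
    te_probes: set[str] = field(default_factory=set)
    abundance: dict[str, float] = field(default_factory=dict)
    probe_sequences: dict[str, str] = field(default_factory=dict)
    attenuation_draw: dict[str, float] = field(default_factory=dict)
    bin_spans_mb: dict[str, tuple[float, float]] = field(default_factory=dict)
    centromere_mb: float = 0.0

    def expected_pools(self, layout: PoolLayout, pm: PhysicalMap) -> dict[str, set[str]]:
        """Pool IDs that should light up per probe, from the true placements."""
        from poolanchor.pooling import column_pool_id, plate_pool_id, row_pool_id

        out: dict[str, set[str]] = {}
        for probe_id, gene in self.genes.items():
            pools: set[str] = set()
            for placement in gene.placements:
                for bac_id in placement.bac_ids:
                    rec = pm.bacs[bac_id]
                    pools.add(plate_pool_id(rec.plate))
                    pools.add(row_pool_id(rec.row))
                    pools.add(column_pool_id(rec.column))
            out[probe_id] = pools
        return out

    def detectable_probes(self, floor: float = 0.80) -> set[str]:
        """Singly-placed genes on at least one BAC with identity above the
        attenuation floor (the genes the screen can in principle find)."""
        return {
            pid
            for pid, g in self.genes.items()
            if len(g.placements) == 1
            and g.placements[0].bac_ids
            and g.identity > floor
        }


@dataclass
class SimBundle:
    """Everything one simulation produces."""

    cfg: SimulationConfig
    pm: PhysicalMap
    layout: PoolLayout
    truth: TruthSet
    signals: SignalMatrix
    library: RepeatLibrary
    gmap: GeneticMap
    orthologs: OrthologTable
    alignments: dict[str, list[tuple[str, float, int]]]
    reference_truth: pd.DataFrame


def _rng(cfg: SimulationConfig, stage: int, rng: np.random.Generator | None):
    return rng if rng is not None else np.random.default_rng([cfg.seed, stage])


# ---------------------------------------------------------------------------
# physical map


def _tile_contig(
    contig_len: int, cfg: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """BAC intervals tiling [0, contig_len) with ~mtp_overlap_fraction overlap."""
    mean = cfg.bac_length_mean_bp
    ov = cfg.mtp_overlap_fraction
    if contig_len <= mean:
        return [(0, contig_len)]
    n = max(1, round((contig_len / mean - ov) / (1.0 - ov)))
    if n == 1:
        return [(0, contig_len)]
    advance = (contig_len - mean) / (n - 1)
    starts = [0]
    for i in range(1, n):
        jitter = rng.normal(0.0, cfg.bac_length_jitter * mean * 0.3)
        starts.append(int(round(i * advance + jitter)))
    starts = sorted(set(np.clip(starts, 0, contig_len - 1).tolist()))
    n = len(starts)
    intervals = []
    for i, s in enumerate(starts):
        if i == n - 1:
            e = contig_len
        elif ov == 0:
            e = starts[i + 1]
        else:
            target = starts[i + 1] + ov * mean * (1.0 + rng.normal(0.0, 0.1))
            hi = starts[i + 2] if i + 2 < n else contig_len
            e = int(round(min(max(target, starts[i + 1] + 1), hi, contig_len)))
        intervals.append((s, max(e, s + 1)))
    return intervals


def _bin_spans(cfg: SimulationConfig) -> dict[str, tuple[int, int]]:
    """Eight deletion-bin intervals, ordered telomere(S) -> centromere -> telomere(L)."""
    L = cfg.chromosome_length_bp
    c = int(round(cfg.centromere_fraction * L))
    spans: dict[str, tuple[int, int]] = {}
    fr = _ARM_FRACTIONS_S
    for i in range(len(fr) - 1):
        hi, lo = fr[i], fr[i + 1]
        start = int(round(c * (1 - hi)))
        end = int(round(c * (1 - lo)))
        name = f"C-S-{hi:.2f}" if lo == 0.0 else f"S-{lo:.2f}-{hi:.2f}"
        spans[name] = (start, end)
    fr = _ARM_FRACTIONS_L
    for i in range(len(fr) - 1):
        lo, hi = fr[i], fr[i + 1]
        start = c + int(round((L - c) * lo))
        end = c + int(round((L - c) * hi))
        name = f"C-L-{hi:.2f}" if lo == 0.0 else f"L-{lo:.2f}-{hi:.2f}"
        spans[name] = (start, end)
    return spans


def simulate_physical_map(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[PhysicalMap, TruthSet]:
    """Generate the MTP physical map and start the truth set.

    Contigs cover ``mtp_coverage_fraction`` of the chromosome, separated by
    gaps; BACs tile each contig with ~``mtp_overlap_fraction`` pairwise
    overlap and are assigned to wells plate by plate.  Contigs are binned by
    midpoint into eight deletion bins (a configurable fraction left
    unbinned); abundance factors are drawn log-normal with the configured
    CV.
    """
    rng = _rng(cfg, 0, rng)
    L = cfg.chromosome_length_bp
    covered = cfg.mtp_coverage_fraction * L
    step = cfg.bac_length_mean_bp * (1.0 - cfg.mtp_overlap_fraction) or cfg.bac_length_mean_bp
    approx_bacs = covered / max(step, 1)
    if approx_bacs > cfg.capacity:
        raise ValueError(
            f"pool geometry capacity {cfg.capacity} cannot hold ~{approx_bacs:.0f} MTP BACs"
        )
    n_contigs = max(1, round(approx_bacs / cfg.mean_bacs_per_contig))
    w = rng.uniform(0.5, 1.5, n_contigs)
    contig_lens = np.round(covered * w / w.sum()).astype(int)
    gap_total = L - int(contig_lens.sum())
    wg = rng.uniform(0.5, 1.5, n_contigs + 1)
    gap_lens = np.floor(gap_total * wg / wg.sum()).astype(int)
    gap_lens[-1] += gap_total - gap_lens.sum()

    spans = _bin_spans(cfg)
    c_bp = cfg.centromere_fraction * L
    records: list[BACRecord] = []
    bin_of: dict[str, str | None] = {}
    pos = int(gap_lens[0])
    idx = 0
    per_plate = cfg.n_rows * cfg.n_cols
    if cfg.well_assignment == "scattered":
        well_order = rng.permutation(cfg.capacity)
    elif cfg.well_assignment == "sequential":
        well_order = np.arange(cfg.capacity)
    else:
        raise ValueError(f"unknown well_assignment {cfg.well_assignment!r}")
    for ci, clen in enumerate(contig_lens):
        contig_id = f"ctg{ci + 1:04d}"
        start = pos
        intervals = _tile_contig(int(clen), cfg, rng)
        for s, e in intervals:
            if idx >= cfg.capacity:
                raise ValueError("pool geometry capacity exceeded while tiling")
            slot = int(well_order[idx])
            plate = slot // per_plate + 1
            rem = slot % per_plate
            row = ROW_LETTERS[rem // cfg.n_cols]
            col = rem % cfg.n_cols + 1
            records.append(
                BACRecord(
                    bac_id=f"B{idx + 1:04d}",
                    plate=plate,
                    row=row,
                    column=col,
                    contig_id=contig_id,
                    start_bp=start + s,
                    end_bp=start + e,
                )
            )
            idx += 1
        mid = start + clen / 2
        if rng.random() < cfg.unbinned_contig_fraction:
            bin_of[contig_id] = None
        else:
            for name, (bs, be) in spans.items():
                if bs <= mid < be:
                    bin_of[contig_id] = name
                    break
        pos = start + int(clen) + int(gap_lens[ci + 1])

    bins = [
        DeletionBin(
            name=name,
            arm="C" if name.startswith("C-") else name[0],
            full_size_mb=(be - bs) / 1e6,
            midpoint_dist_mb=abs(c_bp - (bs + be) / 2) / 1e6,
        )
        for name, (bs, be) in spans.items()
    ]
    pm = PhysicalMap(records, bin_of=bin_of, bins=bins)

    truth = TruthSet(
        bin_spans_mb={n: (bs / 1e6, be / 1e6) for n, (bs, be) in spans.items()},
        centromere_mb=c_bp / 1e6,
    )
    if cfg.bac_abundance_cv > 0:
        sigma = float(np.sqrt(np.log1p(cfg.bac_abundance_cv**2)))
        draws = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=len(records))
    else:
        draws = np.ones(len(records))
    truth.abundance = {rec.bac_id: float(d) for rec, d in zip(records, draws)}
    return pm, truth


# ---------------------------------------------------------------------------
# gene placement


def _gradient_density(x: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Relative gene density at position x: 1 at the centromere rising
    linearly to ``density_gradient_ratio`` at each telomere."""
    L = cfg.chromosome_length_bp
    c = cfg.centromere_fraction * L
    arm_len = np.where(x < c, c, L - c)
    frac = np.abs(x - c) / np.maximum(arm_len, 1)
    return 1.0 + (cfg.density_gradient_ratio - 1.0) * frac


def _sample_positions(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    out: list[np.ndarray] = []
    have = 0
    while have < n:
        x = rng.uniform(0, cfg.chromosome_length_bp, size=max(2 * (n - have), 16))
        keep = rng.random(len(x)) < _gradient_density(x, cfg) / cfg.density_gradient_ratio
        accepted = x[keep]
        out.append(accepted)
        have += len(accepted)
    return np.concatenate(out)[:n]


class _BacIndex:
    """Sorted-interval lookup of BACs containing a position."""

    def __init__(self, pm: PhysicalMap) -> None:
        placed = [
            (rec.start_bp, rec.end_bp, rec.bac_id)
            for rec in pm.bacs.values()
            if rec.start_bp is not None
        ]
        placed.sort()
        self.starts = np.array([p[0] for p in placed])
        self.ends = [p[1] for p in placed]
        self.ids = [p[2] for p in placed]
        self.max_len = max((e - s for s, e, _ in placed), default=0)

    def containing(self, x: int) -> tuple[str, ...]:
        hi = int(np.searchsorted(self.starts, x, side="right"))
        hits = []
        i = hi - 1
        while i >= 0 and self.starts[i] > x - self.max_len:
            if self.starts[i] <= x < self.ends[i]:
                hits.append(self.ids[i])
            i -= 1
        return tuple(sorted(hits))


def _draw_identity(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    kind, *params = cfg.identity_distribution
    if kind == "fixed":
        return float(params[0])
    if kind == "normal":
        return float(np.clip(rng.normal(params[0], params[1]), 0.5, 1.0))
    if kind == "uniform":
        return float(rng.uniform(params[0], params[1]))
    raise ValueError(f"unknown identity distribution {kind!r}")


def place_genes(
    cfg: SimulationConfig,
    pm: PhysicalMap,
    truth: TruthSet,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Place ``n_genes`` genes along the chromosome.

    Positions follow a piecewise-linear density rising from the centromere
    to each telomere by ``density_gradient_ratio``.  A distance-dependent
    fraction of genes (``island_fraction_proximal`` at the centromere to
    ``island_fraction_distal`` at the telomeres) is laid down in clusters
    with intra-cluster gaps below ``island_gap_bp``.  Probe-target identity
    is drawn per gene; a small fraction of genes receives a second,
    independent placement (duplicated loci).
    """
    rng = _rng(cfg, 1, rng)
    L = cfg.chromosome_length_bp
    c = cfg.centromere_fraction * L
    index = _BacIndex(pm)
    positions: list[tuple[int, int | None]] = []
    cluster = 0
    while len(positions) < cfg.n_genes:
        x = float(_sample_positions(1, cfg, rng)[0])
        arm_len = c if x < c else L - c
        dfrac = abs(x - c) / max(arm_len, 1)
        p_isl = (
            cfg.island_fraction_proximal
            + (cfg.island_fraction_distal - cfg.island_fraction_proximal) * dfrac
        )
        # p_isl is the target fraction of *genes* in islands; an island
        # anchor emits a whole cluster (mean size k), so the per-anchor
        # probability must be deflated accordingly
        k_mean = max(2.0, cfg.island_size_mean)
        q = p_isl / (k_mean * (1.0 - p_isl) + p_isl) if p_isl < 1.0 else 1.0
        if rng.random() < q:
            cluster += 1
            k = 2 + int(rng.poisson(max(0.0, cfg.island_size_mean - 2.0)))
            pos = x
            for j in range(k):
                if j > 0:
                    pos = pos + rng.uniform(0.2, 0.9) * cfg.island_gap_bp
                if pos >= L:
                    break
                positions.append((int(pos), cluster))
        else:
            positions.append((int(x), None))
    positions = positions[: cfg.n_genes]
    counts: dict[int, int] = {}
    for _, cl in positions:
        if cl is not None:
            counts[cl] = counts.get(cl, 0) + 1
    for pid_idx, (pos, cl) in enumerate(positions):
        if cl is not None and counts[cl] < 2:
            positions[pid_idx] = (pos, None)

    for i, (pos, cl) in enumerate(positions):
        probe_id = f"G{i + 1:04d}"
        placements = [Placement(position_bp=pos, bac_ids=index.containing(pos))]
        if rng.random() < cfg.duplicate_probability:
            extra = int(_sample_positions(1, cfg, rng)[0])
            placements.append(Placement(position_bp=extra, bac_ids=index.containing(extra)))
        truth.genes[probe_id] = GeneTruth(
            probe_id=probe_id,
            placements=placements,
            identity=_draw_identity(cfg, rng),
            island_id=cl,
        )
    return truth


# ---------------------------------------------------------------------------
# probe sequences and repeat injection


def random_repeat_library(
    n_repeats: int = 3, length: int = 400, rng: np.random.Generator | None = None
) -> RepeatLibrary:
    rng = rng if rng is not None else np.random.default_rng(0)
    seqs = {
        f"REP{i + 1:02d}": "".join(rng.choice(_NUC, size=length))
        for i in range(n_repeats)
    }
    return RepeatLibrary(sequences=seqs)


def _random_probe(rng: np.random.Generator, length: int = 60) -> str:
    return "".join(rng.choice(_NUC, size=length))


def inject_te_probes(
    truth: TruthSet,
    library: RepeatLibrary,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Give every probe a 60-mer sequence; add ``n_te_probes`` repeat-derived
    probes whose sequences are mutated repeat windows (>= 90% identity, so
    the 80%-over-45-nt filter flags them)."""
    rng = _rng(cfg, 2, rng)
    for probe_id in sorted(truth.genes):
        truth.probe_sequences[probe_id] = _random_probe(rng)
    rep_ids = sorted(library.sequences)
    for i in range(cfg.n_te_probes):
        probe_id = f"TE{i + 1:03d}"
        rep = library.sequences[rep_ids[int(rng.integers(len(rep_ids)))]]
        start = int(rng.integers(0, max(1, len(rep) - 60)))
        window = list(rep[start : start + 60])
        n_mut = int(rng.integers(0, 6))
        for p in rng.choice(len(window), size=n_mut, replace=False):
            window[p] = rng.choice([b for b in "ACGT" if b != window[p]])
        truth.probe_sequences[probe_id] = "".join(window)
        truth.te_probes.add(probe_id)
    return truth


# ---------------------------------------------------------------------------
# signals


def attenuation(identity: float, d90: float, floor: float = 0.80) -> float:
    """Fractional decrease in hybridisation signal at a given probe-target
    identity: 0 at 100% identity, ``d90`` at 90%, 1 at or below ``floor``
    (piecewise linear)."""
    if identity >= 1.0:
        return 0.0
    if identity >= 0.90:
        return d90 * (1.0 - identity) / 0.10
    if identity > floor:
        return d90 + (1.0 - d90) * (0.90 - identity) / (0.90 - floor)
    return 1.0


def simulate_signals(
    truth: TruthSet,
    layout: PoolLayout,
    pm: PhysicalMap,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SignalMatrix:
    """Raw probe x pool intensities.

    value(probe, pool) = background + sum over member BACs containing the
    gene of base_signal x (1 - decrease(identity)) x abundance(BAC).
    Repeat-derived probes instead receive moderate signal in a random
    fraction of all pools.
    """
    from poolanchor.pooling import column_pool_id, plate_pool_id, row_pool_id

    rng = _rng(cfg, 3, rng)
    pool_ids = layout.pool_ids()
    probes = sorted(truth.genes) + sorted(truth.te_probes)
    mu, sigma = cfg.background_lognormal
    values = rng.lognormal(mean=mu, sigma=sigma, size=(len(probes), len(pool_ids)))
    col_of = {pid: i for i, pid in enumerate(pool_ids)}
    for ri, probe_id in enumerate(probes):
        if probe_id in truth.te_probes:
            k = max(1, round(cfg.te_pool_fraction * len(pool_ids)))
            cols = rng.choice(len(pool_ids), size=k, replace=False)
            values[ri, cols] += cfg.base_signal * rng.uniform(0.3, 1.0, size=k)
            continue
        gene = truth.genes[probe_id]
        d90 = float(rng.uniform(*cfg.attenuation_range))
        truth.attenuation_draw[probe_id] = d90
        dec = attenuation(gene.identity, d90, cfg.detectability_floor)
        if dec >= 1.0:
            continue
        for placement in gene.placements:
            for bac_id in placement.bac_ids:
                rec = pm.bacs[bac_id]
                strength = (
                    cfg.base_signal * (1.0 - dec) * truth.abundance[bac_id]
                )
                for pid in (
                    plate_pool_id(rec.plate),
                    row_pool_id(rec.row),
                    column_pool_id(rec.column),
                ):
                    values[ri, col_of[pid]] += strength
    df = pd.DataFrame(values, index=probes, columns=pool_ids)
    return SignalMatrix(data=df, state="raw")


# ---------------------------------------------------------------------------
# reference maps (barley genetic map, rice ortholog table)

_OTHER_BARLEY = ("1H", "2H", "4H", "5H", "6H", "7H")
_OTHER_RICE = tuple(f"Os{i:02d}" for i in range(2, 13))


def simulate_reference_maps(
    truth: TruthSet,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GeneticMap, OrthologTable, dict, pd.DataFrame]:
    """Synthetic barley genetic map and rice ortholog table with known
    non-syntenic fractions.

    Syntenic genes receive reference positions that are a noisy monotone
    image of their chromosome position (cM for barley; ordinal index for
    rice), so collinearity is high but not perfect.  Returns the genetic
    map, the ortholog table, probe-marker alignment hits (identity %,
    aligned length) for the 85%/100-nt link rule, and a per-probe truth
    frame with the syntenic flags.
    """
    rng = _rng(cfg, 4, rng)
    L = cfg.chromosome_length_bp
    probes = sorted(truth.genes)
    map_rows = []
    alignments: dict[str, list[tuple[str, float, int]]] = {}
    ref_rows = []
    ortho_rows = []
    rice_members: list[tuple[str, float]] = []
    ordinal_used: dict[str, int] = {}
    for probe_id in probes:
        pos = truth.genes[probe_id].placements[0].position_bp
        row = {"probe_id": probe_id, "barley_chr": None, "rice_chr": None}
        if rng.random() < cfg.mapped_fraction_barley:
            marker = f"M_{probe_id}"
            if rng.random() >= cfg.nonsyntenic_fraction_barley:
                chrom = "3H"
                cm = max(0.0, pos / L * 150.0 + rng.normal(0.0, cfg.reference_cM_noise))
            else:
                chrom = str(rng.choice(_OTHER_BARLEY))
                cm = float(rng.uniform(0.0, 150.0))
            map_rows.append(
                {"marker_id": marker, "chromosome": chrom, "position_cM": cm}
            )
            alignments[probe_id] = [
                (marker, float(rng.uniform(86.0, 99.5)), int(rng.integers(100, 400)))
            ]
            row["barley_chr"] = chrom
        elif rng.random() < 0.3:
            # a hit that fails the 85%/100-nt link rule
            marker = f"M_{probe_id}"
            map_rows.append(
                {"marker_id": marker, "chromosome": "3H",
                 "position_cM": float(rng.uniform(0, 150))}
            )
            alignments[probe_id] = [
                (marker, float(rng.uniform(60.0, 84.0)), int(rng.integers(50, 200)))
            ]
        if rng.random() < cfg.mapped_fraction_rice:
            if rng.random() >= cfg.nonsyntenic_fraction_rice:
                row["rice_chr"] = "Os01"
                rice_members.append(
                    (probe_id, pos + rng.normal(0.0, cfg.reference_order_noise_bp))
                )
            else:
                chrom = str(rng.choice(_OTHER_RICE))
                row["rice_chr"] = chrom
                ordinal_used[chrom] = ordinal_used.get(chrom, 0) + 1
                ortho_rows.append(
                    {"probe_id": probe_id, "chromosome": chrom,
                     "ordinal_index": ordinal_used[chrom]}
                )
        ref_rows.append(row)
    rice_members.sort(key=lambda t: t[1])
    for ordinal, (probe_id, _) in enumerate(rice_members, start=1):
        ortho_rows.append(
            {"probe_id": probe_id, "chromosome": "Os01", "ordinal_index": ordinal}
        )
    gmap = GeneticMap(
        entries=pd.DataFrame(
            map_rows, columns=["marker_id", "chromosome", "position_cM"]
        )
    )
    orthologs = OrthologTable(
        entries=pd.DataFrame(
            ortho_rows, columns=["probe_id", "chromosome", "ordinal_index"]
        )
    )
    return gmap, orthologs, alignments, pd.DataFrame(ref_rows)


# ---------------------------------------------------------------------------
# one-call bundle


def simulate(cfg: SimulationConfig) -> SimBundle:
    """Run the full generator: map, pools, genes, sequences, signals, references."""
    pm, truth = simulate_physical_map(cfg)
    layout = PoolLayout.from_physical_map(pm, cfg.n_plates, cfg.n_rows, cfg.n_cols)
    place_genes(cfg, pm, truth)
    library = random_repeat_library(rng=np.random.default_rng([cfg.seed, 5]))
    inject_te_probes(truth, library, cfg)
    signals = simulate_signals(truth, layout, pm, cfg)
    gmap, orthologs, alignments, ref_truth = simulate_reference_maps(truth, cfg)
    return SimBundle(
        cfg=cfg,
        pm=pm,
        layout=layout,
        truth=truth,
        signals=signals,
        library=library,
        gmap=gmap,
        orthologs=orthologs,
        alignments=alignments,
        reference_truth=ref_truth,
    )
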