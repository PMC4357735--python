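"""Self-contained synthetic datasets with the statistical structure the method assumes.

The generator plants motif instances in a random genome, covers a chosen
fraction of them with ChIP-seq-style peaks, and draws per-cytosine
methylation counts from the generative model the methylation stage fits:
near bound sites the window methylation level follows window-specific beta
distributions whose means dip toward the motif, everywhere else a single
near-fully-methylated background beta.  Counts are binomial given the level,
with Poisson read depth.  Annotation tracks (TSS, TES, exons, introns, CpG
islands, repeats) and a conservation track are random and carry no signal.

CpG placement is uniform at the configured density rather than clustered;
islands are emitted as separate dense intervals placed away from planted
sites.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import AnnotationSet
from .io import (
    ConservationTrack,
    CpGRecord,
    CpGTable,
    GenomicInterval,
    PFM,
    write_bed,
    write_bedgraph,
    write_cpg_table,
    write_fasta,
    write_pfm,
)
from .scan import BOUND, UNBOUND, CandidateSite
from .pipeline import Dataset

_BASES = np.array(list("ACGT"))


def default_dip_profile(n_flank: int = 10, top: float = 0.8, bottom: float = 0.2) -> np.ndarray:
    """Window-mean methylation profile: linear dip from flank ends to the motif window."""
    left = np.linspace(top, bottom, n_flank + 1)
    return np.concatenate([left, left[-2::-1]])


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults realize the standard strong-signal conditions: 500 planted
    sites (30% bound) on two 200-kb chromosomes, CpGs at one per 25 bp with
    mean coverage 20 reads, a hypomethylation dip from 0.8 at the flank ends
    to 0.2 at the motif against a 0.85 background, and beta concentration 20.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 200_000
    motif_consensus: str = "CCACCAGGTGGCAG"
    mutation_rate: float = 0.05
    n_planted_sites: int = 500
    bound_fraction: float = 0.3
    site_spacing: int = 700
    peak_pad: int = 150
    cpg_density: float = 0.04
    coverage_mean: float = 20.0
    window_size: int = 30
    n_flank: int = 10
    bound_profile: np.ndarray | None = None  # defaults to the 0.8 -> 0.2 dip
    background_mean: float = 0.85
    kappa: float = 20.0
    contexts: tuple[str, ...] = ("CG",)
    n_islands: int = 10
    island_length: int = 500
    island_cpg_density: float = 0.2
    n_annotations_per_class: int = 50
    annotation_length: int = 300

    def __post_init__(self) -> None:
        if self.bound_profile is None:
            self.bound_profile = default_dip_profile(self.n_flank)
        self.bound_profile = np.asarray(self.bound_profile, dtype=float)
        if len(self.bound_profile) != 2 * self.n_flank + 1:
            raise ValueError("bound_profile must have 2*n_flank + 1 entries")
        if np.any((self.bound_profile <= 0) | (self.bound_profile >= 1)):
            raise ValueError("profile means must lie strictly inside (0, 1)")
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction must be in [0, 1]")
        if self.n_planted_sites < 1:
            raise ValueError("need at least one planted site")


@dataclass
class Bundle:
    """A generated dataset plus its ground truth."""

    config: SimConfig
    dataset: Dataset
    truth_sites: list[CandidateSite]
    cpg_records: dict[str, list[CpGRecord]] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the bundle in the exact on-disk formats the pipeline reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["genome"] = out / "genome.fa"
        write_fasta(paths["genome"], self.dataset.genome)
        for ctx, records in self.cpg_records.items():
            key = f"cpg_{ctx}"
            paths[key] = out / f"cpg_{ctx}.tsv"
            write_cpg_table(paths[key], records)
        paths["peaks"] = out / "peaks.bed"
        write_bed(paths["peaks"], self.dataset.peaks)
        for name in AnnotationSet.class_names():
            paths[name] = out / f"{name}.bed"
            write_bed(paths[name], getattr(self.dataset.annotations, name))
        paths["conservation"] = out / "conservation.bedgraph"
        write_bedgraph(paths["conservation"], self.dataset.conservation)
        paths["pfm"] = out / "motif.pfm"
        write_pfm(paths["pfm"], self.dataset.pfm)
        paths["truth"] = out / "truth.tsv"
        with open(paths["truth"], "w") as handle:
            handle.write("site_id\tchrom\tstart\tend\tstrand\tlabel\n")
            for site in self.truth_sites:
                iv = site.interval
                handle.write(
                    f"{site.site_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{site.label}\n"
                )
        return paths


def _mutate(rng: np.random.Generator, consensus: str, rate: float) -> str:
    bases = list(consensus)
    for i in range(len(bases)):
        if rng.random() < rate:
            bases[i] = str(rng.choice([b for b in "ACGT" if b != bases[i]]))
    return "".join(bases)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _place_sites(
    rng: np.random.Generator, config: SimConfig
) -> list[tuple[str, int]]:
    """Pick non-overlapping planting loci (chrom, start) with guaranteed spacing."""
    margin = config.n_flank * config.window_size + config.peak_pad + 50
    slots: list[tuple[str, int]] = []
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        pos = margin
        while pos + config.site_spacing < config.chrom_length - margin:
            slots.append((chrom, pos))
            pos += config.site_spacing
    if len(slots) < config.n_planted_sites:
        raise ValueError(
            f"genome holds only {len(slots)} sites at spacing {config.site_spacing}; "
            f"{config.n_planted_sites} requested"
        )
    chosen = rng.choice(len(slots), size=config.n_planted_sites, replace=False)
    jitter = rng.integers(
        0, config.site_spacing - len(config.motif_consensus) - 1, size=len(chosen)
    )
    sites = [
        (slots[i][0], slots[i][1] + int(j)) for i, j in zip(chosen, jitter)
    ]
    sites.sort()
    return sites


def _random_intervals(
    rng: np.random.Generator,
    config: SimConfig,
    count: int,
    length: int,
) -> list[GenomicInterval]:
    out = []
    for _ in range(count):
        chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
        start = int(rng.integers(0, config.chrom_length - length))
        out.append(GenomicInterval(chrom, start, start + length))
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


def simulate_dataset(config: SimConfig) -> Bundle:
    """Generate a full synthetic bundle under the configured conditions.

    Exactly ``round(bound_fraction * n_planted_sites)`` planted sites are
    covered by peaks (motif plus ``peak_pad`` on each side); site spacing
    guarantees a peak never covers a neighboring site, so containment
    labeling recovers the truth exactly.
    """
    rng = np.random.default_rng(config.seed)
    L = len(config.motif_consensus)

    # genome with planted, possibly mutated, motif instances on either strand
    genome: dict[str, str] = {}
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        genome[chrom] = "".join(
            _BASES[rng.integers(0, 4, size=config.chrom_length)]
        )
    loci = _place_sites(rng, config)
    n_bound = int(round(config.bound_fraction * config.n_planted_sites))
    bound_idx = set(rng.choice(len(loci), size=n_bound, replace=False).tolist())

    truth_sites: list[CandidateSite] = []
    instances: list[str] = []
    seqs = {chrom: list(genome[chrom]) for chrom in genome}
    for idx, (chrom, start) in enumerate(loci):
        instance = _mutate(rng, config.motif_consensus, config.mutation_rate)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = instance if strand == "+" else _revcomp(instance)
        seqs[chrom][start : start + L] = list(planted)
        instances.append(instance)
        truth_sites.append(
            CandidateSite(
                interval=GenomicInterval(chrom, start, start + L, strand),
                motif_score=0.0,
                site_id=f"planted_{idx:06d}",
                label=BOUND if idx in bound_idx else UNBOUND,
            )
        )
    genome = {chrom: "".join(seq) for chrom, seq in seqs.items()}

    # PFM from the planted (forward-oriented) instances
    counts = np.zeros((4, L))
    base_index = {b: i for i, b in enumerate("ACGT")}
    for instance in instances:
        for k, b in enumerate(instance):
            counts[base_index[b], k] += 1
    pfm = PFM(counts=counts, name="synthetic_motif")

    # peaks over the bound sites
    peaks = [
        GenomicInterval(
            s.interval.chrom,
            max(0, s.interval.start - config.peak_pad),
            min(config.chrom_length, s.interval.end + config.peak_pad),
        )
        for s in truth_sites
        if s.label == BOUND
    ]
    peaks.sort(key=lambda iv: (iv.chrom, iv.start))

    # CpG islands in site-free gaps, plus random no-signal annotations
    islands = _island_intervals(rng, config, loci)
    annotations = AnnotationSet(
        tss=[
            GenomicInterval(iv.chrom, iv.start, iv.start + 1)
            for iv in _random_intervals(
                rng, config, config.n_annotations_per_class, 1
            )
        ],
        tes=[
            GenomicInterval(iv.chrom, iv.start, iv.start + 1)
            for iv in _random_intervals(
                rng, config, config.n_annotations_per_class, 1
            )
        ],
        exon=_random_intervals(
            rng, config, config.n_annotations_per_class, config.annotation_length
        ),
        intron=_random_intervals(
            rng, config, config.n_annotations_per_class, config.annotation_length
        ),
        cpg_island=islands,
        repeat=_random_intervals(
            rng, config, config.n_annotations_per_class, config.annotation_length
        ),
    )

    # conservation: uniform random score over each planted motif (no signal)
    conservation = ConservationTrack()
    for site in truth_sites:
        value = round(float(rng.random()), 3)
        for pos in range(site.interval.start, site.interval.end):
            conservation.set(site.interval.chrom, pos, value)

    # per-window beta means around bound sites; background elsewhere
    mean_lookup = _window_mean_lookup(truth_sites, config)

    cpg_records: dict[str, list[CpGRecord]] = {}
    cpg_tables: dict[str, CpGTable] = {}
    for ctx in config.contexts:
        records = _draw_methylation(rng, config, genome, islands, mean_lookup, ctx)
        cpg_records[ctx] = records
        cpg_tables[ctx] = CpGTable(records)

    dataset = Dataset(
        genome=genome,
        cpg=cpg_tables,
        peaks=peaks,
        annotations=annotations,
        conservation=conservation,
        pfm=pfm,
    )
    return Bundle(
        config=config,
        dataset=dataset,
        truth_sites=truth_sites,
        cpg_records=cpg_records,
    )


def make_null_dataset(config: SimConfig) -> Bundle:
    """Same construction, but bound sites carry no methylation signal.

    The binding window profile is replaced with the background mean in every
    window, so methylation carries no information about the planted labels.
    """
    flat = np.full(2 * config.n_flank + 1, config.background_mean)
    null_config = dc_replace(config, bound_profile=flat)
    return simulate_dataset(null_config)


def _island_intervals(
    rng: np.random.Generator, config: SimConfig, loci: Sequence[tuple[str, int]]
) -> list[GenomicInterval]:
    """Dense-CpG island intervals placed clear of every planted site's windows."""
    span = config.n_flank * config.window_size + len(config.motif_consensus)
    blocked: dict[str, list[tuple[int, int]]] = {}
    for chrom, start in loci:
        blocked.setdefault(chrom, []).append((start - span, start + span))
    islands: list[GenomicInterval] = []
    attempts = 0
    while len(islands) < config.n_islands and attempts < 1000:
        attempts += 1
        chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
        start = int(rng.integers(0, config.chrom_length - config.island_length))
        end = start + config.island_length
        if any(start < b_end and b_start < end for b_start, b_end in blocked.get(chrom, [])):
            continue
        islands.append(GenomicInterval(chrom, start, end))
    islands.sort(key=lambda iv: (iv.chrom, iv.start))
    return islands


def _window_mean_lookup(
    truth_sites: Sequence[CandidateSite], config: SimConfig
) -> dict[str, list[tuple[int, int, float]]]:
    """Per chromosome, (start, end, beta-mean) for every window of every bound site."""
    from .meth_model import build_windows  # local import to avoid cycle at import time

    lookup: dict[str, list[tuple[int, int, float]]] = {}
    for site in truth_sites:
        if site.label != BOUND:
            continue
        layout = build_windows(
            site, window_size=config.window_size, n_flank=config.n_flank,
            chrom_length=config.chrom_length,
        )
        for j, window in enumerate(layout.windows):
            if window is None:
                continue
            lookup.setdefault(window.chrom, []).append(
                (window.start, window.end, float(config.bound_profile[j]))
            )
    for entries in lookup.values():
        entries.sort()
    return lookup


def _draw_methylation(
    rng: np.random.Generator,
    config: SimConfig,
    genome: dict[str, str],
    islands: Sequence[GenomicInterval],
    mean_lookup: dict[str, list[tuple[int, int, float]]],
    context: str,
) -> list[CpGRecord]:
    records: list[CpGRecord] = []
    for chrom in sorted(genome):
        length = len(genome[chrom])
        n_background = rng.poisson(config.cpg_density * length)
        positions = set(
            rng.integers(0, length, size=n_background).tolist()
        )
        for island in islands:
            if island.chrom != chrom:
                continue
            n_island = rng.poisson(config.island_cpg_density * island.width)
            positions.update(
                rng.integers(island.start, island.end, size=n_island).tolist()
            )
        window_entries = mean_lookup.get(chrom, [])
        starts = np.array([e[0] for e in window_entries], dtype=int)
        ends = np.array([e[1] for e in window_entries], dtype=int)
        means = np.array([e[2] for e in window_entries], dtype=float)
        for pos in sorted(positions):
            mean = config.background_mean
            if len(starts):
                k = np.searchsorted(starts, pos, side="right") - 1
                if k >= 0 and pos < ends[k]:
                    mean = float(means[k])
            p = rng.beta(mean * config.kappa, (1.0 - mean) * config.kappa)
            n = int(rng.poisson(config.coverage_mean))
            x = int(rng.binomial(n, p)) if n > 0 else 0
            records.append(CpGRecord(chrom, int(pos), context, x, n))
    return records
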