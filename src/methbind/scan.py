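"""Genome-wide PWM scanning, candidate-site selection and labeling.

Candidate transcription-factor binding sites are motif matches above a
log-odds threshold.  Both strands are scanned; a reverse-strand match is
reported on the forward coordinates of its window, and when both strands
match at the same locus only the higher-scoring orientation is kept.
Candidates are labeled ``bound`` when their motif interval is covered by a
ChIP-seq peak (full containment by default), otherwise ``unbound``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io import GenomicInterval, PFM

BOUND = "bound"
UNBOUND = "unbound"

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass
class PWM:
    """Log-odds position weight matrix (base 2) with its background model."""

    log_odds: np.ndarray  # 4 x L
    background: np.ndarray  # length-4 base probabilities, order ACGT
    pseudocount: float
    name: str = "motif"

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[0] != 4:
            raise ValueError("log_odds must be 4 x L")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background probabilities must sum to 1")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("log_odds contains non-finite entries")

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @property
    def max_score(self) -> float:
        """Best attainable score: sum of per-column maxima."""
        return float(self.log_odds.max(axis=0).sum())

    def reverse_complement(self) -> np.ndarray:
        # complementing swaps A<->T and C<->G, i.e. reverses the ACGT row
        # order; reading the motif backwards reverses the columns
        return self.log_odds[::-1, ::-1]


@dataclass(frozen=True)
class CandidateSite:
    """A motif hit: candidate binding site with optional gold-standard label."""

    interval: GenomicInterval
    motif_score: float
    site_id: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (BOUND, UNBOUND):
            raise ValueError(f"label must be {BOUND!r} or {UNBOUND!r}, got {self.label!r}")


def genome_background(genome: Mapping[str, str]) -> np.ndarray:
    """Genome-wide mononucleotide frequencies over A, C, G, T (ambiguous bases ignored)."""
    counts = np.zeros(4, dtype=float)
    for seq in genome.values():
        codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("genome contains no unambiguous A/C/G/T bases")
    return counts / counts.sum()


def pfm_to_pwm(
    pfm: PFM,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.8,
) -> PWM:
    """Convert a count matrix to a base-2 log-odds PWM.

    Entry for base *b* at column *k* is
    ``log2(((count + pseudocount * bg_b) / (colsum + pseudocount)) / bg_b)``,
    i.e. the pseudocount mass is split across bases in proportion to the
    background.  Defaults: uniform background, pseudocount 0.8.
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    colsums = pfm.counts.sum(axis=0)
    if pseudocount <= 0:
        if np.any(colsums == 0):
            raise ValueError("zero column sum requires pseudocount > 0")
        if np.any(pfm.counts == 0):
            raise ValueError("zero counts require pseudocount > 0")
    probs = (pfm.counts + pseudocount * background[:, None]) / (colsums + pseudocount)
    return PWM(
        log_odds=np.log2(probs / background[:, None]),
        background=background,
        pseudocount=pseudocount,
        name=pfm.name,
    )


def _window_scores(seq: str, log_odds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every length-L window of ``seq``; windows with non-ACGT bases invalid."""
    L = log_odds.shape[1]
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    m = len(seq) - L + 1
    if m <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores = np.zeros(m)
    valid = np.ones(m, dtype=bool)
    for k in range(L):
        col = codes[k : k + m]
        ok = col < 4
        valid &= ok
        scores += np.where(ok, log_odds[np.minimum(col, 3), k], 0.0)
    return scores, valid


def _strand_best(seq: str, pwm: PWM) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window (best score over strands, strand, valid) arrays."""
    fwd, valid = _window_scores(seq, pwm.log_odds)
    rev, _ = _window_scores(seq, pwm.reverse_complement())
    take_rev = rev > fwd  # ties resolved to '+'
    best = np.where(take_rev, rev, fwd)
    strands = np.where(take_rev, "-", "+")
    return best, strands, valid


def resolve_threshold(pwm: PWM, threshold: float, relative: bool) -> float:
    return threshold * pwm.max_score if relative else threshold


def scan_genome(
    genome: Mapping[str, str],
    pwm: PWM,
    threshold: float,
    relative: bool = False,
    id_prefix: str | None = None,
) -> list[CandidateSite]:
    """Scan both strands of every chromosome for motif matches above threshold.

    ``threshold`` is an absolute log-odds score, or a fraction of the maximum
    attainable score when ``relative`` is set.  Windows containing non-ACGT
    bases are skipped.  Opposite-strand hits at the same locus are collapsed
    to the higher-scoring orientation.  Hits are returned sorted by
    (chrom, start) with stable ``site_id``s.
    """
    cutoff = resolve_threshold(pwm, threshold, relative)
    prefix = id_prefix if id_prefix is not None else pwm.name
    hits: list[CandidateSite] = []
    any_sequence_fit = False
    for chrom in sorted(genome):
        seq = genome[chrom]
        if len(seq) < pwm.length:
            continue
        any_sequence_fit = True
        best, strands, valid = _strand_best(seq, pwm)
        for pos in np.nonzero(valid & (best >= cutoff))[0]:
            hits.append(
                CandidateSite(
                    interval=GenomicInterval(
                        chrom, int(pos), int(pos) + pwm.length, str(strands[pos])
                    ),
                    motif_score=float(best[pos]),
                    site_id="",  # assigned below once ordering is final
                )
            )
    if not any_sequence_fit:
        warnings.warn(
            f"PWM of length {pwm.length} is longer than every sequence; no hits",
            stacklevel=2,
        )
    hits.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    width = max(6, len(str(len(hits))))
    return [
        replace(site, site_id=f"{prefix}_{i:0{width}d}") for i, site in enumerate(hits)
    ]


def choose_threshold(
    genome: Mapping[str, str],
    pwm: PWM,
    target_range: tuple[int, int],
    grid_size: int = 100,
) -> float:
    """Pick a scan threshold whose genome-wide hit count lands in a target range.

    Evaluates hit counts on a grid of ``grid_size`` evenly spaced scores
    between 50% and 100% of the maximum attainable score and returns the
    smallest grid threshold whose count falls inside ``target_range``
    (inclusive).  If no grid point attains the range, the grid point with the
    nearest achievable count is returned with a warning.
    """
    lo, hi = target_range
    if lo <= 0 or hi < lo:
        raise ValueError(f"invalid target range {target_range}")
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    pooled: list[np.ndarray] = []
    for seq in genome.values():
        if len(seq) < pwm.length:
            continue
        best, _, valid = _strand_best(seq, pwm)
        pooled.append(best[valid])
    scores = np.sort(np.concatenate(pooled)) if pooled else np.empty(0)
    grid = np.linspace(0.5, 1.0, grid_size) * pwm.max_score
    # hits at threshold t = number of window scores >= t
    counts = len(scores) - np.searchsorted(scores, grid, side="left")
    in_range = (counts >= lo) & (counts <= hi)
    if in_range.any():
        return float(grid[np.argmax(in_range)])  # smallest qualifying threshold
    nearest = int(np.argmin(np.minimum(np.abs(counts - lo), np.abs(counts - hi))))
    warnings.warn(
        f"no grid threshold yields {lo}-{hi} candidate sites; "
        f"nearest achievable count is {counts[nearest]}",
        stacklevel=2,
    )
    return float(grid[nearest])


def label_candidates(
    sites: Sequence[CandidateSite],
    peaks: Sequence[GenomicInterval],
    min_overlap: float = 1.0,
) -> list[CandidateSite]:
    """Label candidates against gold-standard peaks.

    A site is ``bound`` when some single peak covers at least ``min_overlap``
    of its motif interval (1.0 = full containment, the default), else
    ``unbound``.  Insensitive to peak ordering.
    """
    if not 0.0 < min_overlap <= 1.0:
        raise ValueError("min_overlap must be in (0, 1]")
    trees: dict[str, IntervalTree] = {}
    for peak in peaks:
        trees.setdefault(peak.chrom, IntervalTree()).addi(peak.start, peak.end)
    labeled: list[CandidateSite] = []
    for site in sites:
        iv = site.interval
        needed = min_overlap * iv.width
        is_bound = any(
            min(hit.end, iv.end) - max(hit.begin, iv.start) >= needed
            for hit in trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end)
        )
        labeled.append(replace(site, label=BOUND if is_bound else UNBOUND))
    return labeled


def write_candidate_bed(path, sites: Sequence[CandidateSite]) -> None:
    """Write candidates as BED6: name = site id, score = motif log-odds."""
    with open(path, "w") as handle:
        for site in sites:
            iv = site.interval
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{site.site_id}\t"
                f"{site.motif_score:.6g}\t{iv.strand}\n"
            )


def read_candidate_bed(path) -> list[CandidateSite]:
    """Read candidates written by :func:`write_candidate_bed`."""
    from .io import FormatError

    sites: list[CandidateSite] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: candidate BED needs 6 columns")
            try:
                sites.append(
                    CandidateSite(
                        interval=GenomicInterval(
                            fields[0], int(fields[1]), int(fields[2]), fields[5]
                        ),
                        motif_score=float(fields[4]),
                        site_id=fields[3],
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return sites


def split_train_test(
    sites: Sequence[CandidateSite], seed: int
) -> tuple[list[CandidateSite], list[CandidateSite]]:
    """Random equal split into training and testing halves, reproducible from seed."""
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sites))
    half = (len(sites) + 1) // 2
    train = [sites[i] for i in order[:half]]
    test = [sites[i] for i in order[half:]]
    return train, test
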