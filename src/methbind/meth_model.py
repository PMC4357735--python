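"""Beta-binomial window models of methylation around candidate binding sites.

Model
-----
Each candidate site *i* is surrounded by an ordered layout of ``2*n_flank + 1``
windows (default: ten 30-bp windows on each side of the motif window).  In
window *j* the methylated read count follows

    x_ij | n_ij, p_j ~ Binomial(n_ij, p_j)

with the window methylation level ``p_j`` beta-distributed: at bound sites
each window has its own ``Beta(alpha_j, beta_j)`` (capturing the
hypomethylation dip toward the motif), while at unbound sites all windows
share a single background ``Beta(alpha', beta')`` close to fully methylated.
Marginally the counts are beta-binomial.  Parameters are estimated by the
method of moments on per-window methylation proportions; a candidate's
methylation score is the log-likelihood ratio

    lambda_i = sum_{j : covered} [ log P(x_ij | n_ij, binding_j)
                                   - log P(x_ij | n_ij, background) ]

summed over windows with at least one covered in-context cytosine.  Larger
lambda means stronger evidence of binding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import betaln, gammaln

from .io import CpGRecord, CpGTable, GenomicInterval
from .scan import CandidateSite

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

# method-of-moments clamps for degenerate training slices
KAPPA_MIN = 0.01
KAPPA_MAX = 10_000.0
MEAN_EPS = 1e-6


class InsufficientDataError(ValueError):
    """Too few usable observations to fit a beta distribution."""


@dataclass(frozen=True)
class BetaParams:
    """Parameters of a beta distribution; both must be positive and finite."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (
            np.isfinite(self.alpha)
            and np.isfinite(self.beta)
            and self.alpha > 0
            and self.beta > 0
        ):
            raise ValueError(f"alpha and beta must be finite and > 0, got {self}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass
class WindowLayout:
    """Ordered methylation windows around one candidate site.

    ``windows[n_flank]`` is the motif window itself; entries clipped away
    entirely at a chromosome end are ``None`` so that window indices stay
    aligned with model parameters.
    """

    windows: list[GenomicInterval | None]
    window_size: int
    n_flank: int

    @property
    def n_windows(self) -> int:
        """Number of surviving (non-clipped) windows."""
        return sum(w is not None for w in self.windows)

    @property
    def n_slots(self) -> int:
        return len(self.windows)


@dataclass
class WindowCounts:
    """Aggregated methylation counts per window for one candidate site.

    ``x`` methylated reads, ``n`` total reads, ``cg`` number of in-context
    cytosine positions covered by at least one read.  ``fit_mask`` is set by
    training QC: masked windows are excluded from parameter fitting (they
    still participate in scoring, which is gated on ``cg > 0`` only).
    """

    x: np.ndarray
    n: np.ndarray
    cg: np.ndarray
    context: str = "CG"
    fit_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.cg = np.asarray(self.cg, dtype=np.int64)
        if not (len(self.x) == len(self.n) == len(self.cg)):
            raise ValueError("x, n, cg must have equal length")
        if np.any(self.x < 0) or np.any(self.x > self.n):
            raise ValueError("require 0 <= x <= n in every window")
        if np.any((self.cg == 0) & (self.n > 0)):
            raise ValueError("cg == 0 implies n == 0")

    @property
    def usable(self) -> np.ndarray:
        """Windows usable for fitting: covered, and not masked by QC."""
        base = self.n >= 1
        if self.fit_mask is not None:
            base = base & self.fit_mask
        return base


@dataclass
class MethylationModel:
    """Fitted beta-binomial methylation model for one context.

    ``binding[j]`` are the window-specific parameters at bound sites;
    ``background`` is the single pooled pair for unbound sites.
    """

    binding: list[BetaParams]
    background: BetaParams
    window_size: int
    n_flank: int
    context: str
    n_train_bound: int = 0
    n_train_unbound: int = 0

    def __post_init__(self) -> None:
        if len(self.binding) != 2 * self.n_flank + 1:
            raise ValueError(
                f"expected {2 * self.n_flank + 1} binding parameter pairs, "
                f"got {len(self.binding)}"
            )

    @property
    def binding_means(self) -> np.ndarray:
        return np.array([bp.mean for bp in self.binding])

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "context": self.context,
            "window_size": self.window_size,
            "n_flank": self.n_flank,
            "binding": [[bp.alpha, bp.beta] for bp in self.binding],
            "background": [self.background.alpha, self.background.beta],
            "n_train_bound": self.n_train_bound,
            "n_train_unbound": self.n_train_unbound,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MethylationModel":
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported methylation-model format version {version!r}"
            )
        return cls(
            binding=[BetaParams(a, b) for a, b in payload["binding"]],
            background=BetaParams(*payload["background"]),
            window_size=payload["window_size"],
            n_flank=payload["n_flank"],
            context=payload["context"],
            n_train_bound=payload["n_train_bound"],
            n_train_unbound=payload["n_train_unbound"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MethylationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# window construction and count aggregation
# ---------------------------------------------------------------------------

def build_windows(
    site: CandidateSite | GenomicInterval,
    window_size: int = 30,
    n_flank: int = 10,
    chrom_length: int | None = None,
) -> WindowLayout:
    """Construct the window layout around a candidate site.

    The motif interval is the center window; ``n_flank`` windows of
    ``window_size`` bp are stacked immediately left and right of it (defaults
    give 21 windows).  Windows extending past the chromosome are clipped;
    windows clipped to zero width become ``None`` placeholders so indices are
    preserved.
    """
    motif = site.interval if isinstance(site, CandidateSite) else site
    if window_size < 1 or n_flank < 0:
        raise ValueError("window_size >= 1 and n_flank >= 0 required")
    if motif.start < 0 or (chrom_length is not None and motif.end > chrom_length):
        raise ValueError(
            f"motif {motif.chrom}:{motif.start}-{motif.end} lies outside the chromosome"
        )
    limit = chrom_length if chrom_length is not None else None
    slots: list[GenomicInterval | None] = []
    for j in range(n_flank, 0, -1):
        start = motif.start - j * window_size
        end = motif.start - (j - 1) * window_size
        slots.append(_clip(motif.chrom, start, end, limit))
    slots.append(GenomicInterval(motif.chrom, motif.start, motif.end))
    for j in range(n_flank):
        start = motif.end + j * window_size
        end = motif.end + (j + 1) * window_size
        slots.append(_clip(motif.chrom, start, end, limit))
    return WindowLayout(windows=slots, window_size=window_size, n_flank=n_flank)


def _clip(
    chrom: str, start: int, end: int, limit: int | None
) -> GenomicInterval | None:
    start = max(start, 0)
    if limit is not None:
        end = min(end, limit)
    if start >= end:
        return None
    return GenomicInterval(chrom, start, end)


def aggregate_counts(
    layout: WindowLayout,
    cpg_records: CpGTable | Sequence[CpGRecord],
    context: str = "CG",
) -> WindowCounts:
    """Sum methylation counts into the layout's windows.

    Per window: ``x`` = total methylated reads, ``n`` = total reads over the
    in-window cytosines with at least one read, ``cg`` = how many such
    covered cytosines there are.  Positions with zero coverage contribute
    nothing.  Clipped-away (``None``) windows get (0, 0, 0).
    """
    if isinstance(cpg_records, CpGTable):
        table = cpg_records
    else:
        table = CpGTable(r for r in cpg_records if r.context == context)
    chrom = next(w.chrom for w in layout.windows if w is not None)
    pos, meth, total = table.chrom_arrays(chrom)
    covered = total >= 1
    m = layout.n_slots
    x = np.zeros(m, dtype=np.int64)
    n = np.zeros(m, dtype=np.int64)
    cg = np.zeros(m, dtype=np.int64)
    if pos.size:
        cum_meth = np.concatenate([[0], np.cumsum(np.where(covered, meth, 0))])
        cum_total = np.concatenate([[0], np.cumsum(np.where(covered, total, 0))])
        cum_cov = np.concatenate([[0], np.cumsum(covered.astype(np.int64))])
        for j, window in enumerate(layout.windows):
            if window is None:
                continue
            lo = np.searchsorted(pos, window.start, side="left")
            hi = np.searchsorted(pos, window.end, side="left")
            x[j] = cum_meth[hi] - cum_meth[lo]
            n[j] = cum_total[hi] - cum_total[lo]
            cg[j] = cum_cov[hi] - cum_cov[lo]
    return WindowCounts(x=x, n=n, cg=cg, context=context)


# ---------------------------------------------------------------------------
# training quality control
# ---------------------------------------------------------------------------

def qc_filter_training(
    sites: Sequence[CandidateSite],
    counts: Sequence[WindowCounts] | Sequence[dict[str, WindowCounts]],
    cpg_islands: Sequence[GenomicInterval],
    min_reads: int = 5,
) -> tuple[list[CandidateSite], list]:
    """Training-set quality control.

    Windows with fewer than ``min_reads`` total reads are masked out of
    parameter fitting, and candidates whose motif interval overlaps a CpG
    island are dropped entirely.  Applies to training data only; prediction
    uses unfiltered counts.

    ``counts`` may hold one :class:`WindowCounts` per site, or one
    ``{context: WindowCounts}`` dict per site; the return value mirrors the
    input shape with ``fit_mask`` populated.
    """
    if len(sites) != len(counts):
        raise ValueError("sites and counts must be parallel")
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    island_list = list(cpg_islands)

    def masked(wc: WindowCounts) -> WindowCounts:
        return WindowCounts(
            x=wc.x.copy(),
            n=wc.n.copy(),
            cg=wc.cg.copy(),
            context=wc.context,
            fit_mask=wc.n >= min_reads,
        )

    kept_sites: list[CandidateSite] = []
    kept_counts: list = []
    n_dropped = 0
    for site, wc in zip(sites, counts):
        if any(site.interval.overlaps(island) for island in island_list):
            n_dropped += 1
            continue
        kept_sites.append(site)
        if isinstance(wc, dict):
            kept_counts.append({ctx: masked(w) for ctx, w in wc.items()})
        else:
            kept_counts.append(masked(wc))
    if n_dropped:
        logger.info("QC dropped %d candidate(s) overlapping CpG islands", n_dropped)
    return kept_sites, kept_counts


# ---------------------------------------------------------------------------
# beta fitting (method of moments)
# ---------------------------------------------------------------------------

def fit_beta_mom(x: Sequence[float], n: Sequence[float]) -> BetaParams:
    """Method-of-moments beta fit to methylation proportions.

    With proportions ``p = x / n``: ``m1`` = mean, ``v`` = sample variance
    (n-1 denominator); the concentration is ``kappa = m1 (1 - m1) / v - 1``
    and ``alpha = m1 kappa``, ``beta = (1 - m1) kappa``.  Degenerate slices
    are clamped: zero variance pins ``kappa`` at 10 000 (mean preserved);
    variance at or beyond the ``m1 (1 - m1)`` bound (overdispersion outside
    beta support) pins ``kappa`` at 0.01; the mean itself is clipped away
    from exact 0/1.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    ok = n >= 1
    x, n = x[ok], n[ok]
    if len(x) < 2:
        raise InsufficientDataError(
            f"need >= 2 usable observations to fit a beta distribution, got {len(x)}; "
            "fall back to pooled/background parameters"
        )
    p = x / n
    m1 = float(np.clip(p.mean(), MEAN_EPS, 1.0 - MEAN_EPS))
    v = float(p.var(ddof=1))
    bound = m1 * (1.0 - m1)
    if v == 0.0:
        kappa = KAPPA_MAX
    elif v >= bound:
        kappa = KAPPA_MIN
    else:
        kappa = float(np.clip(bound / v - 1.0, KAPPA_MIN, KAPPA_MAX))
    return BetaParams(alpha=m1 * kappa, beta=(1.0 - m1) * kappa)


def fit_methylation_model(
    bound_counts: Sequence[WindowCounts],
    unbound_counts: Sequence[WindowCounts],
    window_size: int = 30,
    n_flank: int = 10,
    context: str = "CG",
) -> MethylationModel:
    """Fit the per-window binding betas and the pooled background beta.

    Expects QC-filtered training counts.  Window *j*'s binding parameters
    come from the bound sites' usable ``(x_j, n_j)`` pairs; the background
    pair is fit once from all usable windows of all unbound sites pooled,
    since background methylation is assumed identical across windows.  A
    window with fewer than two usable bound observations inherits the
    background parameters (logged).
    """
    m = 2 * n_flank + 1
    bg_x: list[np.ndarray] = []
    bg_n: list[np.ndarray] = []
    for wc in unbound_counts:
        use = wc.usable
        bg_x.append(wc.x[use])
        bg_n.append(wc.n[use])
    background = fit_beta_mom(
        np.concatenate(bg_x) if bg_x else np.empty(0),
        np.concatenate(bg_n) if bg_n else np.empty(0),
    )
    binding: list[BetaParams] = []
    for j in range(m):
        xs = [wc.x[j] for wc in bound_counts if len(wc.x) == m and wc.usable[j]]
        ns = [wc.n[j] for wc in bound_counts if len(wc.n) == m and wc.usable[j]]
        try:
            binding.append(fit_beta_mom(xs, ns))
        except InsufficientDataError:
            logger.warning(
                "window %d has %d usable bound observations; using background "
                "parameters",
                j,
                len(xs),
            )
            binding.append(background)
    return MethylationModel(
        binding=binding,
        background=background,
        window_size=window_size,
        n_flank=n_flank,
        context=context,
        n_train_bound=len(bound_counts),
        n_train_unbound=len(unbound_counts),
    )


# ---------------------------------------------------------------------------
# beta-binomial likelihood and the methylation score
# ---------------------------------------------------------------------------

def betabinom_logpmf(x, n, params: BetaParams):
    """Log-pmf of the beta-binomial marginal, computed via log-gamma.

    ``log[ C(n, x) * B(x + alpha, n - x + beta) / B(alpha, beta) ]``.
    Accepts scalars or arrays; ``n = 0`` gives log-probability 0.
    """
    x = np.asarray(x)
    n = np.asarray(n)
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("require 0 <= x <= n")
    log_choose = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    out = (
        log_choose
        + betaln(x + params.alpha, n - x + params.beta)
        - betaln(params.alpha, params.beta)
    )
    return out if out.ndim else float(out)


def methylation_score(wc: WindowCounts, model: MethylationModel) -> float:
    """Log-likelihood-ratio methylation score (binding vs. background).

    Sums, over windows with at least one covered in-context cytosine, the
    difference between the binding and background beta-binomial log
    likelihoods of the observed counts.  Uncovered windows contribute 0.
    Larger scores mean stronger evidence for binding.
    """
    m = 2 * model.n_flank + 1
    if len(wc.x) != m:
        raise ValueError(
            f"window counts have {len(wc.x)} slots but the model expects {m}"
        )
    score = 0.0
    for j in range(m):
        if wc.cg[j] <= 0:
            continue
        score += betabinom_logpmf(wc.x[j], wc.n[j], model.binding[j])
        score -= betabinom_logpmf(wc.x[j], wc.n[j], model.background)
    return float(score)
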