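"""Ex situ gap analysis and sampling-coverage evaluation.

Two questions are answered here.  First, which alleles observed in the
field (*in situ*) are absent from every genebank accession (*ex situ*),
and where do the trees carrying them grow — the per-cell richness map of
those "missing" alleles points collecting missions at the right valleys.
Second, how well did the sampling cover the species' modeled distribution:
a presence-only distribution surface is thresholded (10-percentile
training presence by default), evaluated against held-out presences plus
random pseudo-absences (AUC, Cohen's kappa), and intersected with the
re-sampled tree counts to classify the modeled range into well-sampled,
under-sampled and unsampled area.

A transparent climate-envelope scorer is included so the pipeline runs
self-contained; any externally modeled surface can be supplied as a
raster instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from .genotype_io import MISSING, GenotypeTable
from .spatial_grid import NODATA, CellAssignment, Raster

__all__ = [
    "GapAlleleSet",
    "SDMEvaluation",
    "CoverageReport",
    "KappaResult",
    "exsitu_missing_alleles",
    "missing_allele_richness_map",
    "ClimateEnvelope",
    "envelope_sdm",
    "training_presence_threshold",
    "generate_pseudo_absences",
    "split_presences",
    "evaluate_auc",
    "evaluate_kappa",
    "sampling_coverage",
]


@dataclass
class GapAlleleSet:
    """(locus, allele) pairs present in situ but in no ex situ sample."""

    missing: tuple[tuple[str, int], ...]
    n_total_alleles: int

    @property
    def n_missing(self) -> int:
        return len(self.missing)

    @property
    def fraction_missing(self) -> float:
        return self.n_missing / self.n_total_alleles if self.n_total_alleles else 0.0


@dataclass
class SDMEvaluation:
    threshold: float
    auc: float
    kappa: float
    kappa_threshold: float
    n_presence_test: int
    n_absence_test: int


@dataclass
class CoverageReport:
    """Percentages of the modeled distribution area by sampling intensity."""

    pct_well_sampled: float
    pct_under_sampled: float
    pct_gap: float
    min_n: int
    n_modeled_cells: int


class KappaResult(NamedTuple):
    kappa: float
    threshold: float


def exsitu_missing_alleles(table: GenotypeTable) -> GapAlleleSet:
    """Alleles carried by in situ trees but absent from all ex situ samples."""
    in_situ = table.status == "in_situ"
    ex_situ = table.status == "ex_situ"
    if not ex_situ.any():
        warnings.warn("no ex situ samples: every observed allele is a gap")
    missing = []
    n_total = 0
    for l, locus in enumerate(table.loci):
        alleles = table.G[:, l, :]
        observed = np.unique(alleles[alleles != MISSING])
        n_total += len(observed)
        ex_alleles = set(np.unique(alleles[ex_situ]).tolist()) - {MISSING}
        in_alleles = set(np.unique(alleles[in_situ]).tolist()) - {MISSING}
        for a in sorted(in_alleles - ex_alleles):
            missing.append((locus, int(a)))
    return GapAlleleSet(missing=tuple(missing), n_total_alleles=n_total)


def missing_allele_richness_map(
    assignment: CellAssignment, table: GenotypeTable, gaps: GapAlleleSet
) -> Raster:
    """Per cell: number of distinct gap alleles carried by its re-sampled trees.

    Occupied cells carrying none score 0; unoccupied cells are nodata.
    """
    order = {sid: i for i, sid in enumerate(table.ids)}
    remap = np.array([order[sid] for sid in assignment.sample_ids], dtype=np.int64)
    samp = remap[assignment.sample_index]
    grid = assignment.grid
    gap_by_locus: dict[int, set[int]] = {}
    for locus, allele in gaps.missing:
        gap_by_locus.setdefault(table.loci.index(locus), set()).add(allele)

    richness = np.zeros(grid.n_cells)
    for l, alleles in gap_by_locus.items():
        for a in alleles:
            carrier = (table.G[:, l, :] == a).any(axis=1)
            hit_cells = np.unique(assignment.cell_id[carrier[samp]])
            richness[hit_cells] += 1.0
    occupied = np.bincount(assignment.cell_id, minlength=grid.n_cells) > 0
    richness[~occupied] = NODATA
    return Raster(
        grid=grid, values=richness.reshape(grid.n_rows, grid.n_cols), nodata=NODATA
    )


# ---------------------------------------------------------------------------
# distribution-surface scoring and evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClimateEnvelope:
    """Percentile-envelope (Bioclim-style) presence-only scorer.

    The score of a point is the fraction of environmental variables whose
    value falls inside the [tail_pct, 100−tail_pct] percentile interval of
    the training presences — continuous in [0, 1].
    """

    lo: np.ndarray
    hi: np.ndarray
    tail_pct: float

    def score(self, env_values: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(env_values, dtype=float))
        inside = (x >= self.lo[None, :]) & (x <= self.hi[None, :])
        return inside.mean(axis=1)

    def score_raster(self, env: Sequence[Raster]) -> Raster:
        env = list(env)
        grid = env[0].grid
        stack = np.stack([r.values for r in env])  # (V, rows, cols)
        bad = np.zeros(stack.shape[1:], dtype=bool)
        for r, layer in zip(env, stack):
            bad |= np.isclose(layer, r.nodata) | ~np.isfinite(layer)
        flat = stack.reshape(len(env), -1).T
        scores = self.score(flat).reshape(grid.n_rows, grid.n_cols)
        scores[bad] = NODATA
        return Raster(grid=grid, values=scores, nodata=NODATA)


def envelope_sdm(presence_env: np.ndarray, tail_pct: float = 0.0) -> ClimateEnvelope:
    """Fit a percentile climate envelope to presence-point environments.

    ``presence_env`` is (n_points, n_variables).  With tail_pct = 0 the
    envelope spans the observed min/max, so every training presence
    scores 1.  A variable constant across presences contributes 1 inside
    its single value and 0 outside.
    """
    x = np.asarray(presence_env, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 presence points")
    lo = np.percentile(x, tail_pct, axis=0)
    hi = np.percentile(x, 100.0 - tail_pct, axis=0)
    return ClimateEnvelope(lo=lo, hi=hi, tail_pct=tail_pct)


def training_presence_threshold(scores: Sequence[float], pct: float = 10.0) -> float:
    """Score cutoff excluding the lowest-scoring ``pct`` % of training presences.

    Returns the largest observed score s such that at most pct% of the
    training presences score strictly below s; the binary surface is then
    score ≥ s.  With pct = 0 this is the minimum training score.
    """
    s = np.sort(np.asarray(scores, dtype=float))
    if s.size == 0:
        raise ValueError("no training scores supplied")
    n = s.size
    # for tied scores, the count strictly below is the first index of the tie
    first_idx = np.searchsorted(s, s, side="left")
    ok = first_idx / n <= pct / 100.0
    return float(s[np.flatnonzero(ok).max()])


def generate_pseudo_absences(
    presences: np.ndarray,
    factor: int = 5,
    expand: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Uniform random background points in the expanded presence bounding box.

    The bounding box is widened by ``expand`` × its width/height on each
    side; ``factor`` × n_presences points are drawn.  Reproducible given
    the seed.
    """
    pts = np.asarray(presences, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 presence points")
    xmin, ymin = pts.min(axis=0)[:2]
    xmax, ymax = pts.max(axis=0)[:2]
    if xmax == xmin or ymax == ymin:
        raise ValueError("degenerate presence bounding box")
    w, h = xmax - xmin, ymax - ymin
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = factor * pts.shape[0]
    x = rng.uniform(xmin - expand * w, xmax + expand * w, size=n)
    y = rng.uniform(ymin - expand * h, ymax + expand * h, size=n)
    return np.column_stack([x, y])


def split_presences(
    points: np.ndarray, test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded train/test split of presence points (default 80/20)."""
    pts = np.asarray(points)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(pts))
    n_test = int(round(test_fraction * len(pts)))
    return pts[idx[n_test:]], pts[idx[:n_test]]


def evaluate_auc(
    presence_scores: Sequence[float], absence_scores: Sequence[float]
) -> float:
    """Rank-based AUC: P(presence outscores absence), ties counting ½."""
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score lists must be non-empty")
    y = np.concatenate([np.ones(p.size), np.zeros(a.size)])
    return float(roc_auc_score(y, np.concatenate([p, a])))


def evaluate_kappa(
    presence_scores: Sequence[float],
    absence_scores: Sequence[float],
    threshold: Optional[float] = None,
) -> KappaResult:
    """Cohen's kappa of the thresholded scores against presence/absence.

    With an explicit threshold the prediction is score ≥ threshold.  When
    no threshold is given, kappa is maximized over all observed scores as
    candidate thresholds and the maximizing threshold is reported.
    """
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score lists must be non-empty")
    y = np.concatenate([np.ones(p.size), np.zeros(a.size)])
    s = np.concatenate([p, a])

    def kappa_at(t: float) -> float:
        pred = (s >= t).astype(int)
        if len(np.unique(pred)) == 1:
            # constant prediction: agreement is all chance
            return 0.0
        return float(cohen_kappa_score(y, pred))

    if threshold is not None:
        return KappaResult(kappa=kappa_at(threshold), threshold=float(threshold))
    candidates = np.unique(s)
    kappas = [kappa_at(t) for t in candidates]
    best = int(np.argmax(kappas))
    return KappaResult(kappa=kappas[best], threshold=float(candidates[best]))


def sampling_coverage(
    binary_distribution: Raster, counts: Raster, min_n: int = 20
) -> CoverageReport:
    """Classify modeled-present cells by re-sampled tree count.

    Over cells where the binary distribution is 1 (present): the share
    with ≥ min_n trees (well sampled), with 1..min_n−1 (under sampled)
    and with none (sampling gaps).  The three percentages sum to 100.
    """
    if binary_distribution.grid != counts.grid:
        raise ValueError("distribution and count rasters are on different grids")
    present = (~binary_distribution.is_nodata()) & (binary_distribution.values > 0)
    n_modeled = int(present.sum())
    if n_modeled == 0:
        raise ValueError("the modeled distribution contains no present cells")
    c = np.where(counts.is_nodata(), 0.0, counts.values)
    well = int(((c >= min_n) & present).sum())
    under = int(((c >= 1) & (c < min_n) & present).sum())
    gap = n_modeled - well - under
    return CoverageReport(
        pct_well_sampled=100.0 * well / n_modeled,
        pct_under_sampled=100.0 * under / n_modeled,
        pct_gap=100.0 * gap / n_modeled,
        min_n=min_n,
        n_modeled_cells=n_modeled,
    )
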