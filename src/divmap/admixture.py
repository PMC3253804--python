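"""Admixture clustering of diploid genotypes and Evanno ΔK model choice.

The model is the classic K-cluster admixture model: individual i carries
membership proportions Q_i (summing to 1 over clusters) and cluster k
carries allele frequencies P_k per locus; each observed allele copy at
locus l is drawn from the mixture Σ_k Q_ik P_k,l.  Parameters are fitted
by maximum-likelihood EM with random restarts — a deterministic,
desk-scale alternative to Bayesian MCMC samplers with the same Q/P
semantics.  The number of clusters is chosen by Evanno's ΔK, the
second-order rate of change of the log-likelihood across K normalized by
the run-to-run standard deviation, computed here from the restart
log-likelihoods.

Per-cell cluster-membership maps average Q over the re-sampled trees in
each grid cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeTable
from .spatial_grid import NODATA, CellAssignment, Raster

__all__ = [
    "AdmixtureResult",
    "DeltaKTable",
    "admixture_loglik",
    "fit_admixture_em",
    "evanno_delta_k",
    "map_cluster_probability",
]

FREQ_FLOOR = 1e-6


@dataclass
class AdmixtureResult:
    """One fitted admixture solution.

    ``P`` maps locus name → (K, n_alleles) frequency array whose columns
    follow ``allele_labels[locus]``; rows of ``Q`` sum to 1.
    """

    K: int
    Q: np.ndarray
    P: dict[str, np.ndarray]
    allele_labels: dict[str, np.ndarray]
    loglik: float
    seed: int
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(repr=False, default=None)


def _encode(table: GenotypeTable):
    """Flatten non-missing allele copies to (individual, global-allele) pairs.

    Returns per-copy individual indices, per-copy global allele slots, the
    per-locus label arrays, per-locus slot offsets and per-individual copy
    counts.
    """
    labels = {}
    offsets = {}
    total = 0
    for l, locus in enumerate(table.loci):
        obs = table.G[:, l, :][table.G[:, l, :] != MISSING]
        labels[locus] = np.unique(obs)
        offsets[locus] = total
        total += len(labels[locus])
    ind_list, slot_list = [], []
    for l, locus in enumerate(table.loci):
        lab = labels[locus]
        for copy in (0, 1):
            a = table.G[:, l, copy]
            ok = a != MISSING
            ind_list.append(np.flatnonzero(ok))
            slot_list.append(offsets[locus] + np.searchsorted(lab, a[ok]))
    ind = np.concatenate(ind_list)
    slot = np.concatenate(slot_list)
    n_copies = np.bincount(ind, minlength=len(table))
    return ind, slot, labels, offsets, total, n_copies


def _pack_P(P_flat: np.ndarray, labels, offsets) -> dict[str, np.ndarray]:
    return {
        locus: P_flat[:, offsets[locus] : offsets[locus] + len(lab)].copy()
        for locus, lab in labels.items()
    }


def admixture_loglik(
    Q: np.ndarray, P: Mapping[str, np.ndarray], table: GenotypeTable
) -> float:
    """Log-likelihood of the genotypes under membership Q and frequencies P.

    logL = Σ_copies log Σ_k Q_ik P_k,l,allele; missing genotypes skipped.
    Raises if some observed allele has zero probability under every
    cluster weighted by its carrier's memberships.
    """
    Q = np.asarray(Q, dtype=float)
    ind, slot, labels, offsets, total, _ = _encode(table)
    K = Q.shape[1]
    P_flat = np.zeros((K, total))
    for locus, lab in labels.items():
        arr = np.asarray(P[locus], dtype=float)
        if arr.shape != (K, len(lab)):
            raise ValueError(
                f"P[{locus!r}] has shape {arr.shape}, expected {(K, len(lab))}"
            )
        P_flat[:, offsets[locus] : offsets[locus] + len(lab)] = arr
    mix = np.einsum("ck,ck->c", Q[ind], P_flat[:, slot].T)
    if np.any(mix <= 0):
        bad = int(np.flatnonzero(mix <= 0)[0])
        raise ValueError(
            f"zero-probability allele copy (individual {table.ids[ind[bad]]!r}); "
            "floor the cluster frequencies"
        )
    return float(np.sum(np.log(mix)))


def fit_admixture_em(
    table: GenotypeTable,
    K: int,
    n_runs: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> list[AdmixtureResult]:
    """Fit the K-cluster admixture model by EM with random restarts.

    Each run starts from Dirichlet(1) memberships and perturbed pooled
    frequencies, alternates Q/P updates to a local maximum (log-likelihood
    non-decreasing every iteration), floors frequencies at 1e-6 and
    renormalizes.  Results are sorted by log-likelihood, best first;
    deterministic given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    if len(table) == 0:
        raise ValueError("empty genotype table")
    ind, slot, labels, offsets, total, n_copies = _encode(table)
    n = len(table)
    locus_slices = [
        slice(offsets[locus], offsets[locus] + len(lab))
        for locus, lab in labels.items()
    ]

    def normalize_P(P_flat: np.ndarray) -> np.ndarray:
        out = np.empty_like(P_flat)
        for sl in locus_slices:
            block = np.maximum(P_flat[:, sl], FREQ_FLOOR)
            out[:, sl] = block / block.sum(axis=1, keepdims=True)
        return out

    pooled = np.bincount(slot, minlength=total).astype(float)
    pooled_P = normalize_P(pooled[None, :].repeat(max(K, 1), axis=0))

    if K == 1:
        Q = np.ones((n, 1))
        P_flat = pooled_P[:1]
        mix = P_flat[0, slot]
        logl = float(np.sum(np.log(mix)))
        res = AdmixtureResult(
            K=1,
            Q=Q,
            P=_pack_P(P_flat, labels, offsets),
            allele_labels=labels,
            loglik=logl,
            seed=seed,
            n_iter=1,
            converged=True,
            loglik_trace=np.array([logl]),
        )
        return [res] * max(n_runs, 1)

    results = []
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    for run, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        Q = rng.dirichlet(np.ones(K), size=n)
        P_flat = normalize_P(
            pooled[None, :] * rng.uniform(0.5, 1.5, size=(K, total))
        )
        trace = []
        prev = -np.inf
        converged = False
        for it in range(max_iter):
            # E-step: responsibilities per allele copy
            w = Q[ind] * P_flat[:, slot].T  # (n_copies_total, K)
            mix = w.sum(axis=1)
            logl = float(np.sum(np.log(mix)))
            trace.append(logl)
            r = w / mix[:, None]
            # M-step
            Q_num = np.zeros((n, K))
            np.add.at(Q_num, ind, r)
            Q = Q_num / n_copies[:, None]
            P_num = np.zeros((K, total))
            np.add.at(P_num.T, slot, r)
            P_flat = normalize_P(P_num)
            if logl - prev < tol and it > 0:
                converged = True
                break
            prev = logl
        if not converged:
            warnings.warn(f"admixture EM run {run} did not converge in {max_iter} iterations")
        final = float(np.sum(np.log((Q[ind] * P_flat[:, slot].T).sum(axis=1))))
        trace.append(final)
        results.append(
            AdmixtureResult(
                K=K,
                Q=Q,
                P=_pack_P(P_flat, labels, offsets),
                allele_labels=labels,
                loglik=final,
                seed=seed,
                n_iter=len(trace) - 1,
                converged=converged,
                loglik_trace=np.array(trace),
            )
        )
    results.sort(key=lambda r: r.loglik, reverse=True)
    return results


@dataclass
class DeltaKTable:
    """Per-K summary of run log-likelihoods with Evanno's ΔK."""

    data: pd.DataFrame  # columns: K, mean_loglik, sd_loglik, delta_k

    @property
    def best_k(self) -> int:
        ok = self.data["delta_k"].notna()
        if not ok.any():
            raise ValueError("ΔK is undefined for every interior K")
        dk = self.data.loc[ok, "delta_k"]
        # idxmax returns the first (smallest-K) maximum, which settles ±inf ties
        return int(self.data.loc[dk.idxmax(), "K"])


def evanno_delta_k(runs: Mapping[int, Sequence[float]]) -> DeltaKTable:
    """Evanno's ΔK from per-K collections of run log-likelihoods.

    L'(K) = mean L(K) − mean L(K−1) and ΔK = |L'(K+1) − L'(K)| / sd L(K),
    defined for interior K only (1 < K < K_max, contiguous range).

    Deterministic optimizers can collapse every restart onto the same
    optimum, making the run-to-run sd exactly 0.  A zero sd with a
    nonzero second difference is maximal support for that K, so ΔK is
    reported as +inf there (ties broken toward the smallest K); a zero
    sd with a zero numerator, or a single run, leaves ΔK undefined and
    excluded from the argmax, with a warning.
    """
    ks = sorted(runs)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    mean = {k: float(np.mean(runs[k])) for k in ks}
    sd = {
        k: float(np.std(runs[k], ddof=1)) if len(runs[k]) > 1 else np.nan
        for k in ks
    }
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            lp = mean[k] - mean[k - 1]
            lp_next = mean[k + 1] - mean[k]
            num = abs(lp_next - lp)
            if not np.isfinite(sd[k]) or (sd[k] == 0 and num == 0):
                warnings.warn(
                    f"ΔK undefined at K={k} (degenerate run log-likelihoods); excluded"
                )
            elif sd[k] == 0:
                warnings.warn(
                    f"zero run-to-run sd at K={k} with nonzero curvature; ΔK = +inf"
                )
                dk = np.inf
            else:
                dk = num / sd[k]
        rows.append(
            {"K": k, "mean_loglik": mean[k], "sd_loglik": sd[k], "delta_k": dk}
        )
    return DeltaKTable(data=pd.DataFrame(rows))


def map_cluster_probability(
    assignment: CellAssignment,
    Q: np.ndarray,
    cluster: int,
    min_n: int = 20,
) -> Raster:
    """Per-cell mean membership probability for one cluster.

    Cells with fewer than ``min_n`` re-sampled trees are nodata.  Summing
    the rasters over clusters gives 1 at every valued cell.
    """
    Q = np.asarray(Q, dtype=float)
    grid = assignment.grid
    counts = np.bincount(assignment.cell_id, minlength=grid.n_cells)
    total = np.bincount(
        assignment.cell_id,
        weights=Q[assignment.sample_index, cluster],
        minlength=grid.n_cells,
    )
    with np.errstate(invalid="ignore"):
        mean = np.where(counts >= max(min_n, 1), total / np.maximum(counts, 1), NODATA)
    return Raster(
        grid=grid, values=mean.reshape(grid.n_rows, grid.n_cols), nodata=NODATA
    )
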