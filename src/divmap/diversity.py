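"""Per-cell α-diversity statistics for codominant (SSR) genotypes.

All statistics are computed per grid cell over the *re-sampled* trees
assigned to the cell by the circular neighborhood, so one tree contributes
to up to |mask| cells by design — no de-duplication is applied.

Statistics
----------
Na            mean number of distinct alleles per locus
Na_rarefied   expected allele count in a standardized subsample of g genes
              (hypergeometric rarefaction; default g = 40 genes = 20
              diploid trees), removing sample-size bias
LCA           mean count per locus of locally common alleles: within-cell
              frequency > 5% while present in ≤ 25% of occupied cells
He            gene diversity 1 − Σ p², averaged over loci
Ho            fraction of heterozygous genotypes, averaged over loci
F             fixation index 1 − Ho/He averaged over polymorphic loci;
              positive = heterozygote deficit (inbreeding), negative =
              heterozygote excess (e.g. clonal heterozygous cultivars)
GD_ref        mean squared codominant genotypic distance to a reference
              genotype (e.g. a commercial cultivar)

Cells with fewer than ``min_n`` re-sampled trees report Na and LCA only;
the remaining statistics are NA there, since they are not interpretable
at small sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeTable, GeoSample
from .spatial_grid import NODATA, CellAssignment, GridSpec, Raster

__all__ = [
    "CellStatsTable",
    "mean_alleles_per_locus",
    "rarefied_richness",
    "locally_common_alleles",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "fixation_index",
    "genotypic_distance",
    "multilocus_distance",
    "mean_distance_to_reference",
    "compute_cell_stats",
]

STAT_COLUMNS = ("na", "na_rarefied", "lca", "he", "ho", "f", "gd_ref")


@dataclass
class CellStatsTable:
    """Per-cell statistics with the grid they were computed on."""

    grid: GridSpec
    data: pd.DataFrame
    min_n: int
    rarefaction_g: int

    def stat_raster(self, column: str) -> Raster:
        """Raster of one statistic; cells without a value are nodata."""
        if column not in self.data.columns:
            raise KeyError(column)
        values = np.full((self.grid.n_rows, self.grid.n_cols), NODATA)
        ok = self.data[column].notna()
        rows = self.data.loc[ok, "row"].to_numpy(dtype=int)
        cols = self.data.loc[ok, "col"].to_numpy(dtype=int)
        values[rows, cols] = self.data.loc[ok, column].to_numpy(dtype=float)
        return Raster(grid=self.grid, values=values, nodata=NODATA)


# ---------------------------------------------------------------------------
# scalar building blocks (operate on plain counts / genotype pairs)
# ---------------------------------------------------------------------------

def mean_alleles_per_locus(counts: Mapping[str, Mapping[int, int]]) -> float:
    """Mean over loci of the number of distinct observed alleles.

    ``counts`` maps locus → {allele label: copy count}; loci with no gene
    copies are excluded from the mean (with a warning).
    """
    per_locus = []
    for locus, c in counts.items():
        n = sum(c.values())
        if n == 0:
            warnings.warn(f"locus {locus!r} has no gene copies; excluded from Na")
            continue
        per_locus.append(sum(1 for v in c.values() if v > 0))
    if not per_locus:
        raise ValueError("no locus has data")
    return float(np.mean(per_locus))


def _ln_choose(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def rarefied_richness(counts: Mapping[int, int], g: int = 40) -> Optional[float]:
    """Expected number of distinct alleles in a subsample of ``g`` genes.

    Hypergeometric rarefaction: E[A_g] = Σ_i [1 − C(N−N_i, g)/C(N, g)]
    where N_i is the copy count of allele i and N = Σ N_i.  Returns None
    when N < g (the locus cannot be rarefied to g genes).
    """
    c = np.array([v for v in counts.values() if v > 0], dtype=float)
    n = c.sum()
    if n < g:
        return None
    rest = n - c
    p_absent = np.where(
        rest < g, 0.0, np.exp(_ln_choose(np.maximum(rest, g), g) - _ln_choose(n, g))
    )
    return float(np.sum(1.0 - p_absent))


def locally_common_alleles(
    cell_freqs: Mapping[object, Mapping[str, Mapping[int, float]]],
    freq_threshold: float = 0.05,
    occupancy_threshold: float = 0.25,
) -> dict[object, dict[str, int]]:
    """Count locally common alleles per cell and locus.

    An allele is counted for a cell iff its within-cell frequency is
    strictly above ``freq_threshold`` and the fraction of occupied cells
    where it is present at all is at most ``occupancy_threshold``.
    ``cell_freqs`` maps cell → locus → {allele: frequency}; the occupancy
    denominator is the number of occupied cells (the keys).
    """
    n_cells = len(cell_freqs)
    presence: dict[tuple[str, int], int] = {}
    for freqs in cell_freqs.values():
        for locus, al in freqs.items():
            for a, f in al.items():
                if f > 0:
                    presence[(locus, a)] = presence.get((locus, a), 0) + 1
    local = {
        key for key, cnt in presence.items() if cnt / n_cells <= occupancy_threshold
    }
    out: dict[object, dict[str, int]] = {}
    for cell, freqs in cell_freqs.items():
        out[cell] = {
            locus: sum(
                1
                for a, f in al.items()
                if f > freq_threshold and (locus, a) in local
            )
            for locus, al in freqs.items()
        }
    return out


def expected_heterozygosity(counts: Mapping[int, int]) -> float:
    """Gene diversity He = 1 − Σ p² from allele copy counts at one locus."""
    c = np.array([v for v in counts.values() if v > 0], dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError("expected_heterozygosity needs at least 2 gene copies")
    p = c / n
    return float(1.0 - np.sum(p * p))


def observed_heterozygosity(
    genotypes: Sequence[Sequence[Optional[tuple[int, int]]]],
) -> float:
    """Mean over loci of the fraction of heterozygous non-missing genotypes.

    ``genotypes`` is a sequence of individuals, each a sequence of per-locus
    allele pairs (or None for missing).
    """
    n_loci = len(genotypes[0])
    per_locus = []
    for l in range(n_loci):
        pairs = [ind[l] for ind in genotypes if ind[l] is not None]
        if not pairs:
            continue
        per_locus.append(sum(1 for a, b in pairs if a != b) / len(pairs))
    if not per_locus:
        raise ValueError("no locus has data")
    return float(np.mean(per_locus))


def fixation_index(he: float, ho: float) -> float:
    """F = 1 − Ho/He; negative values signal heterozygote excess."""
    if he <= 0:
        raise ValueError("fixation index undefined for He = 0")
    return 1.0 - ho / he


def genotypic_distance(
    g1: tuple[int, int], g2: tuple[int, int]
) -> int:
    """Squared codominant genotypic distance between two one-locus genotypes.

    d²(ii,ii) = d²(ij,ij) = 0; d²(ii,ij) = d²(ij,ik) = 1; d²(ij,kl) = 2;
    d²(ii,jk) = 3; d²(ii,jj) = 4.  Symmetric in its arguments.
    """
    a, b = g1
    c, d = g2
    hom1 = a == b
    hom2 = c == d
    shared = len({a, b} & {c, d})
    if hom1 and hom2:
        return 0 if a == c else 4
    if hom1 != hom2:
        # one homozygote ii, one heterozygote
        return 1 if shared else 3
    # both heterozygous
    if {a, b} == {c, d}:
        return 0
    return 1 if shared else 2


def multilocus_distance(
    geno1: Sequence[Optional[tuple[int, int]]],
    geno2: Sequence[Optional[tuple[int, int]]],
) -> int:
    """Sum of single-locus squared distances over loci present in both."""
    total = 0
    for p1, p2 in zip(geno1, geno2):
        if p1 is None or p2 is None:
            continue
        total += genotypic_distance(p1, p2)
    return total


def mean_distance_to_reference(
    genotypes: Sequence[Sequence[Optional[tuple[int, int]]]],
    reference: Sequence[Optional[tuple[int, int]]],
) -> float:
    """Mean multi-locus distance from each individual to a reference genotype."""
    if not genotypes:
        raise ValueError("no genotypes supplied")
    return float(np.mean([multilocus_distance(g, reference) for g in genotypes]))


# ---------------------------------------------------------------------------
# full per-cell computation (vectorized over all re-sampled records)
# ---------------------------------------------------------------------------

def compute_cell_stats(
    assignment: CellAssignment,
    table: GenotypeTable,
    min_n: int = 20,
    rarefaction_g: int = 40,
    reference: Optional[GeoSample] = None,
    freq_threshold: float = 0.05,
    occupancy_threshold: float = 0.25,
) -> CellStatsTable:
    """All per-cell statistics for every occupied cell.

    Na and LCA are reported for every occupied cell; rarefied Na, He, Ho,
    F and GD only for cells with at least ``min_n`` re-sampled trees.  The
    rarefied value is additionally NA unless every data-bearing locus in
    the cell has at least ``rarefaction_g`` gene copies, so that the
    rarefied and raw richness always average over the same locus set
    (making rarefied Na ≤ Na hold cell-wise).
    """
    if set(assignment.sample_ids) - set(table.ids):
        raise ValueError("assignment references samples absent from the table")
    order = {sid: i for i, sid in enumerate(table.ids)}
    remap = np.array([order[sid] for sid in assignment.sample_ids], dtype=np.int64)
    samp = remap[assignment.sample_index]

    L = table.n_loci
    cells, cell_code = np.unique(assignment.cell_id, return_inverse=True)
    n_cells = cells.size
    n_trees = np.bincount(cell_code, minlength=n_cells)

    Ga = table.G[samp]  # (M, L, 2)
    nonmiss = Ga[:, :, 0] != MISSING  # (M, L)
    het = nonmiss & (Ga[:, :, 0] != Ga[:, :, 1])

    # (cell, locus) key for record-level aggregates
    cl = (cell_code[:, None] * L + np.arange(L)[None, :])  # (M, L)
    cl_flat = np.broadcast_to(cl, nonmiss.shape)[nonmiss]
    n_geno = np.bincount(cl_flat, minlength=n_cells * L)  # non-missing genotypes
    n_het = np.bincount(cl_flat, weights=het[nonmiss], minlength=n_cells * L)

    # allele copy counts per (cell, locus, allele)
    copies = pd.DataFrame(
        {
            "cl": np.concatenate([cl_flat, cl_flat]),
            "allele": np.concatenate(
                [Ga[:, :, 0][nonmiss], Ga[:, :, 1][nonmiss]]
            ),
        }
    )
    cnt = copies.groupby(["cl", "allele"], sort=False).size().rename("count")
    cnt = cnt.reset_index()
    cnt["cell_code"] = cnt["cl"] // L
    cnt["locus"] = cnt["cl"] % L
    N = n_geno * 2  # gene count per (cell, locus)
    cnt["N"] = N[cnt["cl"].to_numpy()]
    cnt["freq"] = cnt["count"] / cnt["N"]

    # per (cell, locus): distinct alleles and Σp²
    cnt["p2"] = cnt["freq"] ** 2
    agg = cnt.groupby("cl", sort=False).agg(a=("allele", "size"), p2=("p2", "sum"))
    a_obs = np.zeros(n_cells * L)
    sum_p2 = np.zeros(n_cells * L)
    a_obs[agg.index.to_numpy()] = agg["a"].to_numpy()
    sum_p2[agg.index.to_numpy()] = agg["p2"].to_numpy()

    # hypergeometric rarefaction per (cell, locus)
    g = float(rarefaction_g)
    rest = cnt["N"].to_numpy() - cnt["count"].to_numpy()
    enough = cnt["N"].to_numpy() >= g
    p_absent = np.zeros(len(cnt))
    ok = enough & (rest >= g)
    p_absent[ok] = np.exp(
        _ln_choose(rest[ok].astype(float), g) - _ln_choose(cnt["N"].to_numpy()[ok].astype(float), g)
    )
    contrib = np.where(enough, 1.0 - p_absent, np.nan)
    rare = (
        pd.DataFrame({"cl": cnt["cl"], "c": contrib})
        .groupby("cl", sort=False)["c"]
        .sum(min_count=1)
    )
    a_rare = np.full(n_cells * L, np.nan)
    a_rare[rare.index] = rare.to_numpy()
    a_rare[N < g] = np.nan  # a locus with N < g cannot be rarefied

    # locally common alleles: occupancy over occupied cells
    pres = cnt.groupby(["locus", "allele"], sort=False)["cell_code"].nunique()
    local_pairs = pres[pres / n_cells <= occupancy_threshold]
    key = cnt["locus"].to_numpy() * 10_000_000 + cnt["allele"].to_numpy()
    local_key = set(
        (local_pairs.index.get_level_values(0) * 10_000_000
         + local_pairs.index.get_level_values(1)).tolist()
    )
    is_local = np.fromiter((k in local_key for k in key), dtype=bool, count=len(key))
    lca_hit = is_local & (cnt["freq"].to_numpy() > freq_threshold)
    lca_cl = np.bincount(cnt["cl"].to_numpy()[lca_hit], minlength=n_cells * L)

    # reshape per (cell, locus) aggregates
    def cell_mean(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
        v = values.reshape(n_cells, L)
        m = valid.reshape(n_cells, L)
        with np.errstate(invalid="ignore"):
            out = np.where(
                m.sum(axis=1) > 0,
                np.nansum(np.where(m, v, 0.0), axis=1) / m.sum(axis=1),
                np.nan,
            )
        return out

    has_data = N > 0
    na = cell_mean(a_obs, has_data)
    lca = cell_mean(lca_cl.astype(float), has_data)
    he_cl = np.where(has_data, 1.0 - sum_p2, np.nan)
    ho_cl = np.divide(
        n_het, n_geno, out=np.full(n_cells * L, np.nan), where=n_geno > 0
    )
    he = cell_mean(he_cl, has_data)
    ho = cell_mean(ho_cl, has_data)

    poly = has_data & (he_cl > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_cl = np.where(poly, 1.0 - ho_cl / he_cl, np.nan)
    f = cell_mean(f_cl, poly)

    # rarefied cell value: NA unless every data-bearing locus reached g genes
    rare_ok = (
        has_data.reshape(n_cells, L) & ~np.isnan(a_rare.reshape(n_cells, L))
    ).sum(axis=1) == has_data.reshape(n_cells, L).sum(axis=1)
    na_rare = cell_mean(a_rare, has_data & ~np.isnan(a_rare))
    na_rare[~rare_ok] = np.nan

    # distance to reference, per record then per cell
    gd = None
    if reference is not None:
        ref = list(reference.genotype)
        if len(ref) != L:
            raise ValueError("reference genotype has a different locus count")
        per_sample = np.array(
            [
                multilocus_distance(
                    [
                        None if table.G[i, l, 0] == MISSING
                        else (int(table.G[i, l, 0]), int(table.G[i, l, 1]))
                        for l in range(L)
                    ],
                    ref,
                )
                for i in range(len(table))
            ],
            dtype=float,
        )
        gd = np.bincount(cell_code, weights=per_sample[samp], minlength=n_cells)
        gd = gd / n_trees

    below = n_trees < min_n
    for arr in (na_rare, he, ho, f):
        arr[below] = np.nan
    if gd is not None:
        gd[below] = np.nan

    col, row = assignment.grid.cell_col_row(cells)
    lon, lat = assignment.grid.cell_center(col, row)
    data = pd.DataFrame(
        {
            "cell_id": cells,
            "col": col,
            "row": row,
            "lon": lon,
            "lat": lat,
            "n_trees": n_trees,
            "na": na,
            "na_rarefied": na_rare,
            "lca": lca,
            "he": he,
            "ho": ho,
            "f": f,
        }
    )
    if gd is not None:
        data["gd_ref"] = gd
    return CellStatsTable(
        grid=assignment.grid, data=data, min_n=min_n, rarefaction_g=rarefaction_g
    )
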