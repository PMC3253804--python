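"""Synthetic Andean-like SSR landscapes with known truth.

The generator emulates the statistical structure that the mapping
pipeline assumes in real data, with every feature planted at a known
location so each pipeline stage has a recoverable truth:

* ~1,500 trees scattered in clumps over an Andean-scale lon/lat extent;
* nine codominant loci with ~8 alleles each (≈71 alleles total);
* two ancestral allele-frequency sets joined by a logistic north–south
  admixture cline (clusters "A" and "B");
* a region of elevated inbreeding (genotypes drawn with the standard
  F-mixture law, so E[1 − Ho/He] = F_true there);
* a high-diversity hotspot carrying extra low-frequency alleles;
* a clonal patch where most trees are exact copies of a reference
  cultivar genotype heterozygous at 8 of 9 loci;
* a "genebank gap" region whose private alleles are withheld from all
  ex situ samples;
* optional missing data (default none: the canonical table is complete).

Everything is reproducible from the config seed.  What the generator does
*not* emulate: mutation/drift genealogies, linkage, genotyping error and
null alleles — results on it certify the pipeline arithmetic, not the
biology of any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .genotype_io import GenotypeTable, GeoSample
from .spatial_grid import GridSpec, Raster, make_grid, DEFAULT_CELL_SIZE

__all__ = [
    "LandscapeConfig",
    "simulate_landscape",
    "simulate_env_stack",
    "reference_sample",
    "withheld_alleles",
]

REFERENCE_ID = "CUMBE_REF"


def _label(j: int) -> int:
    """Allele label for within-locus allele slot j (fragment-size-like)."""
    return 101 + 2 * j


@dataclass
class LandscapeConfig:
    """All knobs of the synthetic landscape; defaults mimic the study scale."""

    extent: tuple[float, float, float, float] = (-81.0, -19.0, -62.0, 1.0)
    n_trees: int = 1504
    n_loci: int = 9
    alleles_per_locus: tuple[int, ...] = (8, 8, 8, 8, 8, 8, 8, 8, 7)
    dirichlet_alpha: float = 0.5
    disjoint_ancestral: bool = False
    # admixture cline: P(cluster A) = expit((lat - cline_lat0)/cline_width)
    cline_lat0: float = -9.0
    cline_width: float = 1.5
    # clumped tree scatter
    n_scatter_clusters: int = 24
    scatter_sd: float = 0.25
    # inbreeding
    f_background: float = 0.0
    f_region: float = 0.3
    f_region_center: tuple[float, float] = (-78.75, -1.5)
    f_region_radius: float = 2.0
    # high-diversity hotspot (extra rare alleles)
    hotspot_center: tuple[float, float] = (-78.6, -7.0)
    hotspot_radius: float = 1.5
    hotspot_extra_alleles: int = 2
    hotspot_allele_prob: float = 0.06
    # clonal cultivar patch
    clonal_center: tuple[float, float] = (-76.9, -11.8)
    clonal_radius: float = 0.6
    clonal_fraction: float = 0.8
    # genebank-gap region with withheld private alleles
    gap_center: tuple[float, float] = (-79.0, -3.0)
    gap_radius: float = 0.8
    gap_loci: int = 3
    gap_allele_prob: float = 0.3
    # sampling
    exsitu_fraction: float = 502 / 1504
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.alleles_per_locus) != self.n_loci:
            raise ValueError("alleles_per_locus must have n_loci entries")
        if any(a < 2 for a in self.alleles_per_locus):
            raise ValueError("each locus needs at least 2 core alleles")
        for name in ("f_background", "f_region"):
            f = getattr(self, name)
            if not 0.0 <= f < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in (
            "clonal_fraction",
            "exsitu_fraction",
            "missing_rate",
            "hotspot_allele_prob",
            "gap_allele_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.gap_loci > self.n_loci:
            raise ValueError("gap_loci cannot exceed n_loci")
        if self.gap_loci > 0 and (self.gap_allele_prob <= 0 or self.gap_radius <= 0):
            raise ValueError(
                "withheld alleles would have zero frequency everywhere; "
                "set gap_loci=0 or give gap alleles positive probability"
            )

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(f"SSR{i + 1}" for i in range(self.n_loci))


def withheld_alleles(config: LandscapeConfig) -> tuple[tuple[str, int], ...]:
    """(locus, allele) pairs planted only in the gap region and kept in situ."""
    out = []
    for l in range(config.gap_loci):
        slot = config.alleles_per_locus[l] + config.hotspot_extra_alleles
        out.append((config.locus_names[l], _label(slot)))
    return tuple(out)


def reference_sample(config: LandscapeConfig) -> GeoSample:
    """The clonally propagated reference cultivar: heterozygous at 8/9 loci."""
    geno = []
    for l in range(config.n_loci):
        if l < config.n_loci - 1:
            geno.append((_label(0), _label(1)))
        else:
            geno.append((_label(0), _label(0)))
    return GeoSample(
        sample_id=REFERENCE_ID,
        lon=config.clonal_center[0],
        lat=config.clonal_center[1],
        status="ex_situ",
        genotype=tuple(geno),
    )


def _inside(lon, lat, center, radius) -> np.ndarray:
    return (lon - center[0]) ** 2 + (lat - center[1]) ** 2 <= radius**2


def simulate_landscape(
    config: LandscapeConfig,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Draw the landscape; returns the genotype table and a truth table.

    Genotypes of non-clonal trees follow the inbreeding mixture law at the
    tree's local mixture frequencies p = q·p_A + (1−q)·p_B:
    P(homozygote ii) = p_i² + F p_i(1−p_i) and P(het ij) = 2 p_i p_j (1−F),
    realized by drawing one allele and duplicating it with probability F.
    Clones copy the reference genotype exactly.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    xmin, ymin, xmax, ymax = config.extent
    n = config.n_trees

    # clumped scatter; the planted regions always get their own clump
    forced = [config.hotspot_center, config.clonal_center, config.gap_center,
              config.f_region_center]
    n_free = max(config.n_scatter_clusters - len(forced), 1)
    margin = 1.0
    centers = np.column_stack(
        [
            rng.uniform(xmin + margin, xmax - margin, n_free),
            rng.uniform(ymin + margin, ymax - margin, n_free),
        ]
    )
    centers = np.vstack([np.array(forced), centers])
    which = rng.integers(0, len(centers), size=n)
    lon = np.clip(
        centers[which, 0] + rng.normal(0, config.scatter_sd, n), xmin, xmax - 1e-9
    )
    lat = np.clip(
        centers[which, 1] + rng.normal(0, config.scatter_sd, n), ymin, ymax - 1e-9
    )

    q = expit((lat - config.cline_lat0) / config.cline_width)  # P(cluster A)
    in_f_region = _inside(lon, lat, config.f_region_center, config.f_region_radius)
    f_true = np.where(in_f_region, config.f_region, config.f_background)
    in_hotspot = _inside(lon, lat, config.hotspot_center, config.hotspot_radius)
    in_gap = _inside(lon, lat, config.gap_center, config.gap_radius)
    in_clonal = _inside(lon, lat, config.clonal_center, config.clonal_radius)
    is_clone = in_clonal & (rng.random(n) < config.clonal_fraction)

    ref = reference_sample(config)
    G = np.zeros((n, config.n_loci, 2), dtype=np.int64)
    for l in range(config.n_loci):
        a_core = config.alleles_per_locus[l]
        n_hot = config.hotspot_extra_alleles
        has_gap = l < config.gap_loci
        n_all = a_core + n_hot + (1 if has_gap else 0)
        labels = np.array([_label(j) for j in range(n_all)])

        p_a = np.zeros(n_all)
        p_b = np.zeros(n_all)
        if config.disjoint_ancestral:
            half = a_core // 2
            p_a[:half] = rng.dirichlet(np.full(half, config.dirichlet_alpha))
            p_b[half:a_core] = rng.dirichlet(
                np.full(a_core - half, config.dirichlet_alpha)
            )
        else:
            p_a[:a_core] = rng.dirichlet(np.full(a_core, config.dirichlet_alpha))
            p_b[:a_core] = rng.dirichlet(np.full(a_core, config.dirichlet_alpha))

        p = q[:, None] * p_a[None, :] + (1 - q)[:, None] * p_b[None, :]
        if n_hot > 0 and config.hotspot_allele_prob > 0:
            u_hot = np.zeros(n_all)
            u_hot[a_core : a_core + n_hot] = 1.0 / n_hot
            h = config.hotspot_allele_prob
            p[in_hotspot] = (1 - h) * p[in_hotspot] + h * u_hot[None, :]
        if has_gap:
            delta = np.zeros(n_all)
            delta[-1] = 1.0
            gp = config.gap_allele_prob
            p[in_gap] = (1 - gp) * p[in_gap] + gp * delta[None, :]

        cdf = np.cumsum(p, axis=1)
        cdf[:, -1] = 1.0  # guard against rounding
        draw = lambda: (rng.random(n)[:, None] > cdf).sum(axis=1)
        first = draw()
        second = draw()
        ibd = rng.random(n) < f_true
        second = np.where(ibd, first, second)
        G[:, l, 0] = labels[first]
        G[:, l, 1] = labels[second]

    # clones copy the reference exactly
    ref_geno = np.array(ref.genotype)  # (L, 2)
    G[is_clone] = ref_geno[None, :, :]

    # conservation status; gap-region trees are never in genebanks
    status = np.where(
        (~in_gap) & (rng.random(n) < config.exsitu_fraction), "ex_situ", "in_situ"
    )

    # missing data masks whole genotypes (never half-missing)
    if config.missing_rate > 0:
        miss = rng.random((n, config.n_loci)) < config.missing_rate
        G[miss] = 0

    ids = [f"T{i + 1:05d}" for i in range(n)]
    samples = [
        GeoSample(
            sample_id=ids[i],
            lon=float(lon[i]),
            lat=float(lat[i]),
            status=str(status[i]),
            genotype=tuple(
                None if G[i, l, 0] == 0 else (int(G[i, l, 0]), int(G[i, l, 1]))
                for l in range(config.n_loci)
            ),
        )
        for i in range(n)
    ]
    table = GenotypeTable(samples, config.locus_names)
    truth = pd.DataFrame(
        {
            "sample_id": ids,
            "lon": lon,
            "lat": lat,
            "q_true": q,
            "f_true": f_true,
            "is_clone": is_clone,
            "in_hotspot": in_hotspot,
            "in_gap_region": in_gap,
            "status": status,
        }
    )
    return table, truth


def simulate_env_stack(
    config: LandscapeConfig,
    n_layers: int = 19,
    cell_size: float = DEFAULT_CELL_SIZE,
    grid: Optional[GridSpec] = None,
) -> list[Raster]:
    """Smooth synthetic bioclim-style raster layers on the analysis grid.

    Each layer is a random linear gradient plus a low-frequency sinusoid
    and mild noise, rescaled to a plausible climate-like range; the stack
    is a stand-in for interpolated climate surfaces and is reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7919)))
    grid = grid or make_grid(config.extent, cell_size=cell_size)
    cols, rows = np.meshgrid(np.arange(grid.n_cols), np.arange(grid.n_rows))
    x, y = grid.cell_center(cols, rows)
    xn = (x - x.min()) / max(x.max() - x.min(), 1e-9)
    yn = (y - y.min()) / max(y.max() - y.min(), 1e-9)
    layers = []
    for _ in range(n_layers):
        a, b = rng.uniform(-1, 1, 2)
        fx, fy, phase = rng.uniform(0.5, 2.0, 2).tolist() + [rng.uniform(0, 2 * np.pi)]
        v = (
            a * xn
            + b * yn
            + 0.4 * np.sin(2 * np.pi * (fx * xn + fy * yn) + phase)
            + rng.normal(0, 0.03, xn.shape)
        )
        scale = rng.uniform(5, 300)
        offset = rng.uniform(-10, 25)
        layers.append(Raster(grid=grid, values=offset + scale * v))
    return layers
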