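"""Coordinate-error screening for georeferenced samples.

Two checks are provided, mirroring standard occurrence-data cleaning
practice:

* a climate-outlier screen: a sample whose local values are reverse-
  jackknife outliers on two or more bioclimatic variables most likely has
  erroneous coordinates (it "sits in the wrong climate");
* an optional administrative check: the sample's point must lie within a
  buffer (default 20 arcminutes = 1/3°) of the level-1 administrative
  polygon named in its passport data.

A sample is excluded when the climate screen fires, or when the admin
check fires with polygons supplied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import GenotypeTable
from .spatial_grid import Raster

__all__ = [
    "CleaningReport",
    "reverse_jackknife",
    "flag_climate_outliers",
    "flag_admin_mismatch",
    "merge_reports",
    "clean_dataset",
]

logger = logging.getLogger(__name__)

ADMIN_BUFFER = 1.0 / 3.0  # 20 arcminutes, in degrees


@dataclass
class CleaningReport:
    sample_id: str
    flags: set[str] = field(default_factory=set)
    outlier_vars: tuple[str, ...] = ()
    excluded: bool = False


def reverse_jackknife(values: Sequence[float]) -> set[int]:
    """Indices of tail outliers in a 1-D sample (reverse-jackknife screen).

    A value is an outlier when it sits at either extreme of the sorted
    sample, separated from the body by a gap exceeding the critical
    threshold t = (0.95·√n + 0.2)·(range/50).  The test works outward
    from the most extreme qualifying gap in each tail; if the rule would
    flag half the sample or more there is no meaningful "body" and no
    outliers are reported.  Deterministic; invariant under affine
    rescaling (the threshold scales with the range).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        warnings.warn("reverse_jackknife needs at least 3 values; returning none")
        return set()
    if not np.all(np.isfinite(x)):
        raise ValueError("reverse_jackknife requires finite values")
    rng = x.max() - x.min()
    if rng == 0:
        return set()
    t = (0.95 * np.sqrt(n) + 0.2) * (rng / 50.0)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    gaps = np.diff(xs)
    big = np.flatnonzero(gaps > t)
    flagged: set[int] = set()
    half = n / 2.0
    # lower tail: everything below the outermost qualifying gap whose lower
    # side is a minority tail
    lo = [i for i in big if (i + 1) < half]
    if lo:
        cut = max(lo)
        flagged.update(order[: cut + 1].tolist())
    # upper tail, symmetric
    hi = [i for i in big if (n - 1 - i) < half]
    if hi:
        cut = min(hi)
        flagged.update(order[cut + 1 :].tolist())
    if len(flagged) >= half:
        return set()
    return flagged


def flag_climate_outliers(
    table: GenotypeTable,
    env: Sequence[Raster],
    min_vars: int = 2,
    layer_names: Sequence[str] | None = None,
) -> list[CleaningReport]:
    """Flag samples that are reverse-jackknife outliers on ≥ min_vars layers.

    Samples falling outside the raster extent (or on nodata) contribute no
    climate values; they receive an ``outside_env`` flag but are not
    excluded on that basis.
    """
    env = list(env)
    if not env:
        raise ValueError("no environmental layers supplied")
    if len(env) < 19:
        warnings.warn(
            f"only {len(env)} environmental layers supplied (19 expected); proceeding"
        )
    g0 = env[0].grid
    for r in env[1:]:
        if r.grid != g0:
            raise ValueError("environmental layers are not on a common grid")
    if layer_names is None:
        layer_names = [f"bio{i + 1}" for i in range(len(env))]

    n = len(table)
    hits: list[list[str]] = [[] for _ in range(n)]
    valid_any = np.zeros(n, dtype=bool)
    for name, r in zip(layer_names, env):
        vals = r.value_at(table.lon, table.lat)
        ok = ~(np.isclose(vals, r.nodata) | ~np.isfinite(vals))
        valid_any |= ok
        idx = np.flatnonzero(ok)
        if idx.size < 3:
            continue
        out_local = reverse_jackknife(vals[idx])
        for j in out_local:
            hits[idx[j]].append(name)

    reports = []
    for i in range(n):
        flags: set[str] = set()
        if not valid_any[i]:
            flags.add("outside_env")
        if len(hits[i]) >= min_vars:
            flags.add("climate_outlier")
        reports.append(
            CleaningReport(
                sample_id=table.ids[i],
                flags=flags,
                outlier_vars=tuple(hits[i]),
                excluded="climate_outlier" in flags,
            )
        )
    return reports


def flag_admin_mismatch(
    table: GenotypeTable,
    polygons: Mapping[str, object],
    buffer: float = ADMIN_BUFFER,
) -> list[CleaningReport]:
    """Flag samples farther than ``buffer`` degrees from their declared
    level-1 administrative polygon (shapely geometries keyed by name).

    Samples whose declared unit has no polygon get an ``admin_unresolved``
    flag but are not excluded.
    """
    from shapely.geometry import Point

    reports = []
    for i in range(len(table)):
        flags: set[str] = set()
        excluded = False
        admin = table.admin1[i]
        if admin is None or admin not in polygons:
            flags.add("admin_unresolved")
        else:
            dist = polygons[admin].distance(Point(table.lon[i], table.lat[i]))
            if dist > buffer:
                flags.add("admin_mismatch")
                excluded = True
        reports.append(
            CleaningReport(sample_id=table.ids[i], flags=flags, excluded=excluded)
        )
    return reports


def merge_reports(*report_lists: Sequence[CleaningReport]) -> list[CleaningReport]:
    """Combine per-check reports sample-wise (union of flags)."""
    merged: dict[str, CleaningReport] = {}
    for reports in report_lists:
        for r in reports:
            m = merged.setdefault(r.sample_id, CleaningReport(sample_id=r.sample_id))
            m.flags |= r.flags
            m.outlier_vars = tuple(dict.fromkeys(m.outlier_vars + r.outlier_vars))
            m.excluded = m.excluded or r.excluded
    return list(merged.values())


def clean_dataset(
    table: GenotypeTable, reports: Sequence[CleaningReport]
) -> GenotypeTable:
    """Drop excluded samples; idempotent (a cleaned table cleans to itself)."""
    by_id = {r.sample_id: r for r in reports}
    missing = [sid for sid in table.ids if sid not in by_id]
    if missing:
        raise ValueError(f"reports do not cover samples: {missing[:5]}")
    keep = np.array([not by_id[sid].excluded for sid in table.ids], dtype=bool)
    n_removed = int((~keep).sum())
    logger.info("clean_dataset: removed %d of %d samples", n_removed, len(table))
    if keep.sum() == 0:
        warnings.warn("all samples excluded by cleaning")
    return table.subset(keep)
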