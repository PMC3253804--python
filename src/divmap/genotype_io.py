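"""Read/write georeferenced SSR genotype tables, statistics tables and rasters.

Genotypes are diploid and codominant: each locus carries an ordered pair of
positive-integer allele labels (typically fragment sizes in base pairs), or
is missing entirely.  Half-missing genotypes (one allele recorded, one
absent) are rejected as hard errors rather than silently dropped, since
they would bias gene counts.  The GenAlEx missing convention ``0/0`` and an
empty field are both accepted on input.

Two CSV dialects are supported:

``long_csv``
    one row per (sample, locus):
    ``sample_id,lon,lat,status[,admin1],locus,allele1,allele2``

``genalex_csv``
    one row per sample with a slash-separated pair per locus:
    ``sample_id,lon,lat,status[,admin1],<locus1>,<locus2>,...`` where each
    locus field is ``"101/105"``.

Rasters use the ESRI ASCII grid format (.asc); per-cell statistics tables
export to CSV and to GeoJSON cell polygons.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .spatial_grid import CellAssignment, GridSpec, Raster, neighborhood_mask

__all__ = [
    "MISSING",
    "GeoSample",
    "GenotypeTable",
    "Raster",
    "read_genotype_table",
    "write_genotype_table",
    "read_ascii_raster",
    "write_ascii_raster",
    "write_cell_stats",
    "cell_stats_geojson",
    "write_assignment",
    "read_assignment",
]

MISSING = 0  # allele label reserved for "no data" (GenAlEx convention)

_STATUSES = ("in_situ", "ex_situ")


@dataclass(frozen=True)
class GeoSample:
    """One georeferenced diploid individual.

    ``genotype`` is a tuple with one entry per locus: either an ordered
    pair of positive-integer allele labels or ``None`` for a missing
    genotype.
    """

    sample_id: str
    lon: float
    lat: float
    status: str
    genotype: tuple[Optional[tuple[int, int]], ...]
    admin1: Optional[str] = None

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"{self.sample_id}: lon {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"{self.sample_id}: lat {self.lat} outside [-90, 90]")
        if self.status not in _STATUSES:
            raise ValueError(
                f"{self.sample_id}: status {self.status!r} not in {_STATUSES}"
            )
        for k, pair in enumerate(self.genotype):
            if pair is None:
                continue
            if len(pair) != 2 or any(
                not isinstance(a, (int, np.integer)) or a <= 0 for a in pair
            ):
                raise ValueError(
                    f"{self.sample_id}: locus {k}: allele pair {pair!r} invalid "
                    "(need two positive integers or a missing genotype)"
                )

    def n_heterozygous(self) -> int:
        return sum(1 for p in self.genotype if p is not None and p[0] != p[1])


class GenotypeTable:
    """Ordered collection of :class:`GeoSample` sharing one locus list.

    Internally the genotypes live in an ``(n_samples, n_loci, 2)`` integer
    array with 0 marking missing data, which all downstream statistics
    operate on directly.
    """

    def __init__(self, samples: Sequence[GeoSample], loci: Sequence[str]):
        loci = tuple(str(x) for x in loci)
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dupes}")
        for s in samples:
            if len(s.genotype) != len(loci):
                raise ValueError(
                    f"{s.sample_id}: {len(s.genotype)} loci, expected {len(loci)}"
                )
        self.loci = loci
        self.ids = tuple(ids)
        self.lon = np.array([s.lon for s in samples], dtype=float)
        self.lat = np.array([s.lat for s in samples], dtype=float)
        self.status = np.array([s.status for s in samples], dtype=object)
        self.admin1 = np.array([s.admin1 for s in samples], dtype=object)
        G = np.zeros((len(samples), len(loci), 2), dtype=np.int64)
        for i, s in enumerate(samples):
            for l, pair in enumerate(s.genotype):
                if pair is not None:
                    G[i, l, 0], G[i, l, 1] = pair
        self.G = G

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample(self, i: int) -> GeoSample:
        geno = tuple(
            None if self.G[i, l, 0] == MISSING else (int(self.G[i, l, 0]), int(self.G[i, l, 1]))
            for l in range(self.n_loci)
        )
        return GeoSample(
            sample_id=self.ids[i],
            lon=float(self.lon[i]),
            lat=float(self.lat[i]),
            status=str(self.status[i]),
            genotype=geno,
            admin1=self.admin1[i],
        )

    def __iter__(self) -> Iterator[GeoSample]:
        return (self.sample(i) for i in range(len(self)))

    def __getitem__(self, sample_id: str) -> GeoSample:
        return self.sample(self.ids.index(sample_id))

    def subset(self, keep) -> "GenotypeTable":
        """New table restricted to a boolean mask or index array."""
        idx = np.arange(len(self))[np.asarray(keep)]
        return GenotypeTable([self.sample(int(i)) for i in idx], self.loci)

    # -- bookkeeping ---------------------------------------------------------
    def allele_copy_count(self) -> int:
        """Total number of recorded allele copies (2 per non-missing genotype)."""
        return int((self.G != MISSING).sum())

    def missing_mask(self) -> np.ndarray:
        """(n_samples, n_loci) boolean, True where the genotype is missing."""
        return self.G[:, :, 0] == MISSING

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format frame, one row per (sample, locus)."""
        rows = []
        for i in range(len(self)):
            for l, locus in enumerate(self.loci):
                rows.append(
                    {
                        "sample_id": self.ids[i],
                        "lon": self.lon[i],
                        "lat": self.lat[i],
                        "status": self.status[i],
                        "admin1": self.admin1[i],
                        "locus": locus,
                        "allele1": int(self.G[i, l, 0]),
                        "allele2": int(self.G[i, l, 1]),
                    }
                )
        return pd.DataFrame(rows)


def _parse_pair(
    a1: str, a2: str, sample_id: str, locus: str
) -> Optional[tuple[int, int]]:
    a1 = (a1 or "").strip()
    a2 = (a2 or "").strip()
    if a1 in ("", "0") and a2 in ("", "0"):
        return None
    if a1 in ("", "0") or a2 in ("", "0"):
        raise ValueError(
            f"sample {sample_id!r}, locus {locus!r}: half-missing genotype "
            f"({a1!r}/{a2!r}); record both alleles or mark the locus missing"
        )
    v1, v2 = int(a1), int(a2)
    if v1 <= 0 or v2 <= 0:
        raise ValueError(
            f"sample {sample_id!r}, locus {locus!r}: allele labels must be positive"
        )
    return (v1, v2)


def read_genotype_table(path, dialect: str = "long_csv") -> GenotypeTable:
    """Read a genotype table from CSV in either supported dialect."""
    path = Path(path)
    if dialect == "long_csv":
        return _read_long(path)
    if dialect == "genalex_csv":
        return _read_genalex(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_long(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample_id", "lon", "lat", "status", "locus", "allele1", "allele2"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    loci = list(dict.fromkeys(df["locus"]))
    samples = []
    for sid, grp in df.groupby("sample_id", sort=False):
        geno: dict[str, Optional[tuple[int, int]]] = {}
        for _, r in grp.iterrows():
            geno[r["locus"]] = _parse_pair(r["allele1"], r["allele2"], sid, r["locus"])
        first = grp.iloc[0]
        admin1 = first.get("admin1") or None
        if admin1 == "":
            admin1 = None
        samples.append(
            GeoSample(
                sample_id=str(sid),
                lon=float(first["lon"]),
                lat=float(first["lat"]),
                status=str(first["status"]),
                genotype=tuple(geno.get(l) for l in loci),
                admin1=admin1,
            )
        )
    return GenotypeTable(samples, loci)


def _read_genalex(path: Path) -> GenotypeTable:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        meta_cols = ["sample_id", "lon", "lat", "status"]
        has_admin = len(header) > 4 and header[4] == "admin1"
        n_meta = 5 if has_admin else 4
        loci = header[n_meta:]
        if not loci:
            raise ValueError(f"{path}: header declares no loci")
        samples = []
        seen: set[str] = set()
        for row in reader:
            if not row:
                continue
            sid = row[0].strip()
            if sid in seen:
                raise ValueError(f"duplicate sample_id: {sid!r}")
            seen.add(sid)
            geno = []
            for locus, fld in zip(loci, row[n_meta:]):
                fld = fld.strip()
                if fld == "":
                    geno.append(None)
                    continue
                parts = fld.split("/")
                if len(parts) != 2:
                    raise ValueError(
                        f"sample {sid!r}, locus {locus!r}: malformed pair {fld!r}"
                    )
                geno.append(_parse_pair(parts[0], parts[1], sid, locus))
            if len(geno) < len(loci):
                geno.extend([None] * (len(loci) - len(geno)))
            samples.append(
                GeoSample(
                    sample_id=sid,
                    lon=float(row[1]),
                    lat=float(row[2]),
                    status=row[3].strip(),
                    genotype=tuple(geno),
                    admin1=(row[4].strip() or None) if has_admin else None,
                )
            )
    return GenotypeTable(samples, loci)


def write_genotype_table(table: GenotypeTable, path, dialect: str = "long_csv") -> None:
    path = Path(path)
    if dialect == "long_csv":
        df = table.to_dataframe()
        df["admin1"] = df["admin1"].fillna("")
        df.to_csv(path, index=False)
    elif dialect == "genalex_csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_id", "lon", "lat", "status", "admin1", *table.loci])
            for s in table:
                fields = [
                    "0/0" if p is None else f"{p[0]}/{p[1]}" for p in s.genotype
                ]
                w.writerow(
                    [s.sample_id, repr(s.lon), repr(s.lat), s.status, s.admin1 or "", *fields]
                )
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


# -- ESRI ASCII grid ---------------------------------------------------------

def write_ascii_raster(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid (.asc); rows are written north-to-south."""
    g = raster.grid
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.xll!r}\n")
        fh.write(f"yllcorner {g.yll!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in range(g.n_rows - 1, -1, -1):
            fh.write(" ".join(f"{v:.6g}" for v in raster.values[row]) + "\n")


def read_ascii_raster(path) -> Raster:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        n_cols = int(header["ncols"])
        n_rows = int(header["nrows"])
        if "xllcorner" not in header or "yllcorner" not in header:
            raise ValueError(f"{path}: only corner-registered grids are supported")
        grid = GridSpec(
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            cell_size=header["cellsize"],
            n_cols=n_cols,
            n_rows=n_rows,
        )
        data = np.loadtxt(fh, dtype=float)
        data = np.atleast_2d(data)
        if data.shape != (n_rows, n_cols):
            raise ValueError(f"{path}: data shape {data.shape} != header")
    return Raster(grid=grid, values=data[::-1].copy(), nodata=header["nodata_value"])


# -- cell assignments --------------------------------------------------------

def write_assignment(assignment: CellAssignment, path) -> None:
    """Persist a re-sampling assignment as CSV with grid metadata comments."""
    g = assignment.grid
    m = assignment.mask
    with open(path, "w", newline="") as fh:
        fh.write(
            f"# grid xll={g.xll!r} yll={g.yll!r} cell_size={g.cell_size!r} "
            f"n_cols={g.n_cols} n_rows={g.n_rows}\n"
        )
        fh.write(f"# mask cell_size={m.cell_size!r} diameter={m.diameter!r}\n")
        w = csv.writer(fh)
        w.writerow(["sample_id", "cell_col", "cell_row"])
        for i in range(len(assignment)):
            w.writerow(
                [
                    assignment.sample_ids[assignment.sample_index[i]],
                    int(assignment.cell_col[i]),
                    int(assignment.cell_row[i]),
                ]
            )


def read_assignment(path) -> CellAssignment:
    with open(path) as fh:
        meta: dict[str, float] = {}
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=")
                    meta[k] = float(v)  # mask cell_size duplicates the grid's
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    grid = GridSpec(
        xll=meta["xll"],
        yll=meta["yll"],
        cell_size=meta["cell_size"],
        n_cols=int(meta["n_cols"]),
        n_rows=int(meta["n_rows"]),
    )
    mask = neighborhood_mask(cell_size=meta["cell_size"], diameter=meta["diameter"])
    ids = tuple(dict.fromkeys(df["sample_id"]))
    index = {sid: i for i, sid in enumerate(ids)}
    return CellAssignment(
        grid=grid,
        sample_index=df["sample_id"].map(index).to_numpy(dtype=np.int64),
        cell_col=df["cell_col"].to_numpy(dtype=np.int64),
        cell_row=df["cell_row"].to_numpy(dtype=np.int64),
        sample_ids=ids,
        mask=mask,
    )


# -- per-cell statistics tables ----------------------------------------------

def write_cell_stats(stats, path) -> None:
    """Write a per-cell statistics table as CSV (one row per occupied cell).

    ``stats`` is a :class:`divmap.diversity.CellStatsTable`; statistics that
    were not computable for a cell (below the minimum sample size) are
    emitted as empty fields, with ``n_trees`` always present.
    """
    df = stats.data.copy()
    df.to_csv(path, index=False, na_rep="")


def cell_stats_geojson(stats, path=None) -> dict:
    """GeoJSON FeatureCollection of cell polygons carrying the statistics."""
    grid = stats.grid
    features = []
    for _, row in stats.data.iterrows():
        col, rown = int(row["col"]), int(row["row"])
        props = {
            k: (None if pd.isna(v) else (v if isinstance(v, str) else float(v)))
            for k, v in row.items()
        }
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [grid.cell_polygon(col, rown)],
                },
                "properties": props,
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc
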