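"""Band release/recovery record ingestion and aggregation.

Record-level banding tables are filtered to preseason releases (July to
September, 42-57 degrees N, eastern-Canada banding regions, non-reward band
statuses) and recoveries are restricted to *direct* recoveries: birds shot
and reported in the hunting season (September-February) immediately
following release.  Filtered records are aggregated to a dense count cube
over 1-degree banding blocks x year x age class x band type, holding
releases ``N``, direct recoveries ``y``, and recoveries in Canada ``x``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AGE_CLASSES = ("juvenile", "adult")
BAND_TYPES = ("avise", "zip", "tollfree", "web")
#: era schedule used to impute the band type when the inscription is unknown
BAND_TYPE_ERAS = {"avise": (None, 1992), "zip": (1993, 1995), "tollfree": (1996, 2006), "web": (2007, None)}
ALLOWED_STATUSES = ("normal", "reward", "mail_solicited", "control_reward_program", "night_lighted")

#: banding regions retained: Ontario, Quebec, and the Atlantic Provinces
DEFAULT_REGIONS = frozenset({"ON", "QC", "NB", "NS", "PE", "NL"})


@dataclass(frozen=True)
class BandingRecord:
    """One banded bird: its release and, if any, its reported recovery."""

    band_id: str
    release_date: date
    release_lat: float
    release_lon: float
    age_class: str
    band_status: str = "normal"
    inscription: str | None = None
    recovery_date: date | None = None
    recovery_country: str | None = None
    release_region: str | None = None

    def __post_init__(self):
        if not (-90.0 <= self.release_lat <= 90.0):
            raise ValueError(f"latitude {self.release_lat} outside [-90, 90]")
        if not (-180.0 <= self.release_lon <= 180.0):
            raise ValueError(f"longitude {self.release_lon} outside [-180, 180]")
        if self.recovery_date is not None and self.recovery_date < self.release_date:
            raise ValueError("recovery_date precedes release_date")


def block_index(lat: float, lon: float) -> tuple[int, int]:
    """Map coordinates to the 1-degree banding block (lat_bin, lon_bin).

    Blocks are half-open: [lat_bin, lat_bin + 1) x [lon_bin, lon_bin + 1).
    """
    return int(np.floor(lat)), int(np.floor(lon))


def block_centroid(block: tuple[int, int]) -> tuple[float, float]:
    """Centroid (lat, lon) of a 1-degree block keyed by its floor bins."""
    return block[0] + 0.5, block[1] + 0.5


def classify_band_type(inscription: str | None, release_year: int,
                       span: tuple[int, int] = (1970, 2010)) -> str:
    """Band type from the inscription code, or from the deployment era.

    An explicit inscription always wins (a mismatch with the era schedule is
    logged as an anomaly); an unknown inscription falls back to the era the
    release year belongs to.
    """
    if not (span[0] <= release_year <= span[1]):
        raise ValueError(f"release year {release_year} outside study span {span}")
    era_type = None
    for bt, (lo, hi) in BAND_TYPE_ERAS.items():
        if (lo is None or release_year >= lo) and (hi is None or release_year <= hi):
            era_type = bt
            break
    if inscription is None or inscription == "" or inscription == "unknown":
        return era_type
    if inscription not in BAND_TYPES:
        raise ValueError(f"unknown inscription code {inscription!r}")
    if inscription != era_type:
        logger.warning(
            "band type %s inconsistent with %d deployment era (%s); keeping the inscription",
            inscription, release_year, era_type,
        )
    return inscription


@dataclass
class FilterConfig:
    """Inclusion rules for preseason releases and direct recoveries."""

    release_months: tuple[int, ...] = (7, 8, 9)
    lat_range: tuple[float, float] = (42.0, 57.0)
    regions: frozenset = DEFAULT_REGIONS
    statuses: tuple[str, ...] = ("normal", "control_reward_program", "night_lighted")
    years: tuple[int, int] = (1970, 2010)
    reject_unknown_age: bool = True


@dataclass
class RejectionReport:
    """Counts of records and recoveries dropped, by rule."""

    n_input: int = 0
    n_kept: int = 0
    parse_error: int = 0
    unknown_age: int = 0
    band_status: int = 0
    release_month: int = 0
    latitude: int = 0
    region: int = 0
    year_span: int = 0
    indirect_recovery_dropped: int = 0
    band_type_imputed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def is_direct_recovery(release_date: date, recovery_date: date) -> bool:
    """True iff the recovery falls in Sep(year t) through Feb(year t+1)."""
    t = release_date.year
    y, m = recovery_date.year, recovery_date.month
    return (y == t and m >= 9) or (y == t + 1 and m <= 2)


def apply_filters(records, config: FilterConfig | None = None):
    """Apply the inclusion rules; return (kept records, RejectionReport).

    A release failing any release-side rule is dropped entirely.  A retained
    release whose recovery is not direct keeps the release but sheds the
    recovery fields.  Idempotent.
    """
    cfg = config or FilterConfig()
    report = RejectionReport(n_input=len(records))
    kept: list[BandingRecord] = []
    for r in records:
        yr = r.release_date.year
        if not (cfg.years[0] <= yr <= cfg.years[1]):
            report.year_span += 1
            continue
        if r.band_status not in cfg.statuses:
            report.band_status += 1
            continue
        if r.release_date.month not in cfg.release_months:
            report.release_month += 1
            continue
        if not (cfg.lat_range[0] <= r.release_lat <= cfg.lat_range[1]):
            report.latitude += 1
            continue
        if cfg.regions and r.release_region is not None and r.release_region not in cfg.regions:
            report.region += 1
            continue
        if cfg.reject_unknown_age and r.age_class not in AGE_CLASSES:
            report.unknown_age += 1
            continue
        if r.recovery_date is not None and not is_direct_recovery(r.release_date, r.recovery_date):
            report.indirect_recovery_dropped += 1
            r = BandingRecord(
                band_id=r.band_id, release_date=r.release_date,
                release_lat=r.release_lat, release_lon=r.release_lon,
                age_class=r.age_class, band_status=r.band_status,
                inscription=r.inscription, recovery_date=None,
                recovery_country=None, release_region=r.release_region,
            )
        kept.append(r)
    report.n_kept = len(kept)
    return kept, report


@dataclass
class CountCube:
    """Dense counts over block x year x age x band type.

    ``N`` releases, ``y`` direct recoveries, ``x`` direct recoveries in
    Canada, all keyed by the *release* block; 0 <= x <= y <= N cellwise.
    """

    N: np.ndarray
    y: np.ndarray
    x: np.ndarray
    blocks: list  # list of (lat_bin, lon_bin)
    years: list
    ages: tuple = AGE_CLASSES
    band_types: tuple = BAND_TYPES

    def __post_init__(self):
        shape = (len(self.blocks), len(self.years), len(self.ages), len(self.band_types))
        for name in ("N", "y", "x"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr.astype(np.int64))
        self.validate()

    def validate(self) -> None:
        if np.any(self.N < 0) or np.any(self.y < 0) or np.any(self.x < 0):
            raise ValueError("negative counts")
        if np.any(self.y > self.N):
            raise ValueError("direct recoveries exceed releases in some cell")
        if np.any(self.x > self.y):
            raise ValueError("Canada recoveries exceed total recoveries in some cell")
        years = np.asarray(self.years)
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise ValueError("years must be contiguous")

    @property
    def centroids(self) -> np.ndarray:
        return np.array([block_centroid(b) for b in self.blocks], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table, one row per block-year-age-bandtype."""
        ii, tt, aa, bb = np.meshgrid(
            np.arange(len(self.blocks)), np.arange(len(self.years)),
            np.arange(len(self.ages)), np.arange(len(self.band_types)), indexing="ij",
        )
        blocks = np.asarray(self.blocks)
        return pd.DataFrame({
            "lat_bin": blocks[ii.ravel(), 0],
            "lon_bin": blocks[ii.ravel(), 1],
            "year": np.asarray(self.years)[tt.ravel()],
            "age": np.asarray(self.ages)[aa.ravel()],
            "band_type": np.asarray(self.band_types)[bb.ravel()],
            "n_released": self.N.ravel(),
            "n_recovered": self.y.ravel(),
            "n_recovered_can": self.x.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountCube":
        blocks = sorted({(int(r), int(c)) for r, c in zip(df["lat_bin"], df["lon_bin"])})
        years = sorted(df["year"].unique().tolist())
        ages = tuple(a for a in AGE_CLASSES if a in set(df["age"]))
        bts = tuple(b for b in BAND_TYPES if b in set(df["band_type"]))
        shape = (len(blocks), len(years), len(ages), len(bts))
        N = np.zeros(shape, dtype=np.int64)
        y = np.zeros(shape, dtype=np.int64)
        x = np.zeros(shape, dtype=np.int64)
        bi = {b: k for k, b in enumerate(blocks)}
        ti = {t: k for k, t in enumerate(years)}
        ai = {a: k for k, a in enumerate(ages)}
        gi = {g: k for k, g in enumerate(bts)}
        for row in df.itertuples(index=False):
            key = (bi[(int(row.lat_bin), int(row.lon_bin))], ti[row.year], ai[row.age], gi[row.band_type])
            N[key] += int(row.n_released)
            y[key] += int(row.n_recovered)
            x[key] += int(row.n_recovered_can)
        return cls(N=N, y=y, x=x, blocks=blocks, years=years, ages=ages, band_types=bts)

    @classmethod
    def from_csv(cls, path) -> "CountCube":
        return cls.from_frame(pd.read_csv(path))


def aggregate_counts(records, years: range | list, band_types: tuple = BAND_TYPES,
                     blocks: list | None = None,
                     span: tuple[int, int] | None = None) -> CountCube:
    """Tally filtered records into a dense CountCube (zero-filled).

    Blocks default to those observed among the releases; ``years`` fixes the
    time axis so empty years stay as zero slices.
    """
    years = list(years)
    span = span or (min(years), max(years))
    if blocks is None:
        blocks = sorted({block_index(r.release_lat, r.release_lon) for r in records})
        if not blocks:
            blocks = [(0, 0)]  # empty input: degenerate one-block grid
    shape = (len(blocks), len(years), len(AGE_CLASSES), len(band_types))
    N = np.zeros(shape, dtype=np.int64)
    y = np.zeros(shape, dtype=np.int64)
    x = np.zeros(shape, dtype=np.int64)
    bi = {b: k for k, b in enumerate(blocks)}
    ti = {t: k for k, t in enumerate(years)}
    ai = {a: k for k, a in enumerate(AGE_CLASSES)}
    gi = {g: k for k, g in enumerate(band_types)}
    for r in records:
        yr = r.release_date.year
        bt = classify_band_type(r.inscription, yr, span=span)
        key = (bi[block_index(r.release_lat, r.release_lon)], ti[yr], ai[r.age_class], gi[bt])
        N[key] += 1
        if r.recovery_date is not None:
            y[key] += 1
            if r.recovery_country == "CAN":
                x[key] += 1
    return CountCube(N=N, y=y, x=x, blocks=blocks, years=years, band_types=band_types)


DEFAULT_COLUMN_MAP = {
    "band_id": "band_id", "release_date": "release_date",
    "release_lat": "release_lat", "release_lon": "release_lon",
    "age_class": "age_class", "band_status": "band_status",
    "inscription": "inscription", "recovery_date": "recovery_date",
    "recovery_country": "recovery_country", "release_region": "release_region",
}


def read_records(path, column_map: dict | None = None):
    """Read a comma-delimited banding table into BandingRecords.

    ``column_map`` maps BandingRecord field names to the file's column
    names (a dict, or a path to a YAML/JSON file holding one).  Unparseable
    rows are rejected and counted; returns (records, RejectionReport with
    parse counts only).
    """
    if isinstance(column_map, (str, Path)):
        import yaml

        column_map = yaml.safe_load(Path(column_map).read_text())
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype=str)
    report = RejectionReport(n_input=len(df))
    records = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))

        def get(field_name):
            col = cmap.get(field_name)
            val = row.get(col) if col else None
            return None if (val is None or pd.isna(val) or val == "") else val

        try:
            rec_date = get("recovery_date")
            records.append(BandingRecord(
                band_id=str(get("band_id")),
                release_date=date.fromisoformat(get("release_date")),
                release_lat=float(get("release_lat")),
                release_lon=float(get("release_lon")),
                age_class=(get("age_class") or "unknown"),
                band_status=(get("band_status") or "normal"),
                inscription=get("inscription"),
                recovery_date=date.fromisoformat(rec_date) if rec_date else None,
                recovery_country=get("recovery_country"),
                release_region=get("release_region"),
            ))
        except (ValueError, TypeError):
            report.parse_error += 1
    report.n_kept = len(records)
    return records, report
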