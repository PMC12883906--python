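"""Forecast ensemble construction for a target calendar month.

Two ensemble flavours are supported:

* **climatology** (ESP-style): every prior year's instance of the target
  calendar month in a multi-year hourly archive becomes one equally likely
  member — e.g. a June 2023 forecast replays June 1979..2022;
* **model**: daily ensemble members from a seasonal forecast model are
  disaggregated to hourly resolution and pooled, preserving member count.

Ensembles from several sources (e.g. different forecast models) can be pooled
into a multi-model ensemble.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .disaggregation import DisaggregationConfig, disaggregate_member
from .errors import DataError, DomainError
from .meteo import (
    DailyMeteoSeries,
    HourlyMeteoSeries,
    SiteInfo,
    read_hourly_csv,
    write_hourly_csv,
)


def _days_in_month(year: int, month: int) -> int:
    return pd.Period(f"{year}-{month:02d}").days_in_month


@dataclass
class ForecastEnsemble:
    """A set of member hourly series all spanning one target calendar month."""

    target_year: int
    target_month: int
    source: str
    members: list[HourlyMeteoSeries]
    member_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 1 <= self.target_month <= 12:
            raise DomainError("target_month must be in 1..12")
        if len(self.members) < 1:
            raise DataError("ensemble needs at least one member")
        if not self.member_ids:
            self.member_ids = [str(i) for i in range(len(self.members))]
        if len(self.member_ids) != len(self.members):
            raise DataError("member_ids length mismatch")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise DataError("member_ids must be unique")
        expected = _days_in_month(self.target_year, self.target_month) * 24
        for mid, m in zip(self.member_ids, self.members):
            if len(m) != expected:
                raise DataError(
                    f"member {mid!r} has {len(m)} hours, expected {expected} "
                    f"for {self.target_year}-{self.target_month:02d}"
                )

    def __len__(self) -> int:
        return len(self.members)


def _restamp_month(df: pd.DataFrame, target_year: int, target_month: int) -> pd.DataFrame:
    """Re-index a month of hourly rows onto the target year's calendar month."""
    n_days_target = _days_in_month(target_year, target_month)
    n_days_source = len(df) // 24
    if n_days_source > n_days_target:  # leap-year source feeding a shorter target
        df = df.iloc[: n_days_target * 24]
    elif n_days_source < n_days_target:  # non-leap source, Feb-29 target: reuse the last day
        df = pd.concat([df, df.iloc[-24:]])
    start = pd.Timestamp(year=target_year, month=target_month, day=1)
    out = df.copy()
    out.index = pd.date_range(start, periods=len(out), freq="h")
    return out


def build_climatology_ensemble(
    archive: HourlyMeteoSeries, target_year: int, target_month: int
) -> ForecastEnsemble:
    """ESP-style climatology ensemble: one member per prior archive year.

    Each year strictly earlier than ``target_year`` with a complete instance
    of the target calendar month contributes that month's hours verbatim
    (re-stamped onto the target month's dates); member ids are source years.
    """
    idx = archive.index
    members, ids = [], []
    for year in sorted(set(idx.year)):
        if year >= target_year:
            continue
        mask = (idx.year == year) & (idx.month == target_month)
        sub = archive.data.loc[mask]
        if len(sub) != _days_in_month(year, target_month) * 24:
            continue  # incomplete month at an archive edge
        restamped = _restamp_month(sub, target_year, target_month)
        members.append(HourlyMeteoSeries(restamped, site=archive.site))
        ids.append(str(year))
    if not members:
        raise DataError(
            f"no archive year before {target_year} covers month {target_month}"
        )
    return ForecastEnsemble(target_year, target_month, "climatology", members, ids)


def assemble_model_ensemble(
    member_series: dict[str, DailyMeteoSeries] | list[DailyMeteoSeries],
    target_year: int,
    target_month: int,
    latitude: float | None = None,
    config: DisaggregationConfig | None = None,
    source: str = "model",
) -> ForecastEnsemble:
    """Disaggregate daily forecast members to hourly and pool them.

    Each member must cover at least the full target month (buffer days on
    either side are used for diurnal continuity, then trimmed).  A member
    with missing days is rejected with an error naming it.
    """
    if isinstance(member_series, dict):
        items = list(member_series.items())
    else:
        items = [(str(i), m) for i, m in enumerate(member_series)]
    if not items:
        raise DataError("no members supplied")
    n_days = _days_in_month(target_year, target_month)
    start = pd.Timestamp(year=target_year, month=target_month, day=1)
    wanted = pd.date_range(start, periods=n_days, freq="D")
    members, ids = [], []
    for mid, daily in items:
        if not wanted.isin(daily.index).all():
            missing = wanted[~wanted.isin(daily.index)]
            raise DataError(
                f"member {mid!r} is missing {len(missing)} day(s) of "
                f"{target_year}-{target_month:02d} (first: {missing[0].date()})"
            )
        hourly = disaggregate_member(daily, latitude=latitude, config=config)
        month = hourly.slice_month(target_year, target_month)
        members.append(month)
        ids.append(mid)
    return ForecastEnsemble(target_year, target_month, source, members, ids)


def combine_ensembles(
    ensembles: list[ForecastEnsemble], source: str = "multi-model"
) -> ForecastEnsemble:
    """Pool members of several same-month ensembles (multi-model ensemble)."""
    if not ensembles:
        raise DataError("no ensembles to combine")
    first = ensembles[0]
    members, ids = [], []
    for ens in ensembles:
        if (ens.target_year, ens.target_month) != (first.target_year, first.target_month):
            raise DataError(
                f"cannot combine {ens.target_year}-{ens.target_month:02d} with "
                f"{first.target_year}-{first.target_month:02d}"
            )
        for mid, m in zip(ens.member_ids, ens.members):
            members.append(m)
            ids.append(f"{ens.source}:{mid}")
    return ForecastEnsemble(first.target_year, first.target_month, source, members, ids)


def save_ensemble(ensemble: ForecastEnsemble, directory) -> None:
    """Store an ensemble as one member CSV per file plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for i, (mid, member) in enumerate(zip(ensemble.member_ids, ensemble.members)):
        fname = f"member_{i:03d}.csv"
        write_hourly_csv(member, directory / fname)
        files[mid] = fname
    site = ensemble.members[0].site
    manifest = {
        "target_year": ensemble.target_year,
        "target_month": ensemble.target_month,
        "source": ensemble.source,
        "members": files,
        "site": {"latitude": site.latitude, "longitude": site.longitude,
                 "elevation": site.elevation},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_ensemble(directory) -> ForecastEnsemble:
    """Load an ensemble written by :func:`save_ensemble`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    site = SiteInfo(**manifest["site"])
    members, ids = [], []
    for mid, fname in manifest["members"].items():
        members.append(read_hourly_csv(directory / fname, site=site))
        ids.append(mid)
    return ForecastEnsemble(
        manifest["target_year"], manifest["target_month"], manifest["source"],
        members, ids,
    )
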