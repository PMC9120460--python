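"""Cross-source species integration and temporal summaries.

Combines online detections with LEMIS and CITES species lists into one
profile per species, yielding source-overlap (UpSet-style) counts, species
counts per year, description-to-first-trade lags for recently described
species, and per-website richness statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .taxonomy import NameIndex


@dataclass
class SpeciesTradeProfile:
    """Source membership and detection years for one accepted species."""

    accepted_name: str
    in_online: bool = False
    in_lemis: bool = False
    in_cites: bool = False
    match_basis: str = "any_name"  # exact_only | any_name
    detection_years: set[int] = field(default_factory=set)
    snapshot_only: bool = False
    first_year: int | None = None
    description_year: int | None = None

    def __post_init__(self) -> None:
        if self.detection_years:
            self.first_year = min(self.detection_years)


def _online_species(detections, basis: str) -> dict[str, dict]:
    """Accepted species seen online with their dated years / snapshot flag."""
    out: dict[str, dict] = {}
    for d in detections:
        if d.match_kind == "genus_only" or d.accepted_name is None:
            continue
        if basis == "exact_only" and d.match_kind != "exact_current":
            continue
        entry = out.setdefault(d.accepted_name, {"years": set(), "snapshot": False})
        if d.snapshot_year is None:
            entry["snapshot"] = True
        else:
            entry["years"].add(int(d.snapshot_year))
    return out


def combine_sources(
    online_detections,
    lemis_species,
    cites_species,
    index: NameIndex,
    basis: str = "any_name",
    description_years: dict[str, int] | None = None,
    lemis_years: dict[str, set[int]] | None = None,
):
    """Build per-species trade profiles and source-overlap counts.

    ``lemis_species`` and ``cites_species`` are iterables of accepted names
    (already resolved through the same index).  ``basis`` controls whether
    online membership requires an exact current-name match or any historical
    name.  Returns ``(profiles, overlap)`` where overlap maps each of the 7
    non-empty source combinations (frozenset of source labels) to a species
    count, plus per-source totals under single labels in ``totals``.
    """
    if basis not in ("any_name", "exact_only"):
        raise ValueError(f"unknown basis {basis!r}")
    desc = description_years or {}
    online = _online_species(online_detections, basis)
    lemis = set(lemis_species)
    cites = set(cites_species)
    lemis_years = lemis_years or {}

    profiles: list[SpeciesTradeProfile] = []
    for name in sorted(set(online) | lemis | cites):
        entry = online.get(name, {"years": set(), "snapshot": False})
        years = set(entry["years"])
        for y in lemis_years.get(name, ()):
            if y is not None and not (isinstance(y, float) and math.isnan(y)):
                years.add(int(y))
        profiles.append(SpeciesTradeProfile(
            accepted_name=name,
            in_online=name in online,
            in_lemis=name in lemis,
            in_cites=name in cites,
            match_basis=basis,
            detection_years=years,
            snapshot_only=entry["snapshot"] and not years,
            description_year=desc.get(name),
        ))

    overlap: dict[frozenset, int] = {}
    for p in profiles:
        members = frozenset(
            label for label, flag in (
                ("online", p.in_online), ("lemis", p.in_lemis), ("cites", p.in_cites),
            ) if flag
        )
        overlap[members] = overlap.get(members, 0) + 1
    totals = {
        "online": sum(p.in_online for p in profiles),
        "lemis": sum(p.in_lemis for p in profiles),
        "cites": sum(p.in_cites for p in profiles),
        "all_species": len(profiles),
    }
    return profiles, {"combinations": overlap, "totals": totals}


def species_per_year(profiles):
    """Per-year species counts and unique-to-that-year counts.

    A species counts for every calendar year in its dated detection set
    (all sources jointly); it is unique to a year when that set is exactly
    {year}.  Snapshot-only species are tallied separately under the
    ``snapshot_only`` key.
    """
    per_year: dict[int, int] = {}
    unique: dict[int, int] = {}
    snapshot_only = 0
    for p in profiles:
        if not p.detection_years:
            if p.snapshot_only:
                snapshot_only += 1
            continue
        for y in p.detection_years:
            per_year[y] = per_year.get(y, 0) + 1
        if len(p.detection_years) == 1:
            (y,) = p.detection_years
            unique[y] = unique.get(y, 0) + 1
    return {
        "per_year": dict(sorted(per_year.items())),
        "unique_per_year": dict(sorted(unique.items())),
        "snapshot_only": snapshot_only,
    }


def _mean_sd(values) -> tuple[float | None, float | None]:
    n = len(values)
    if n == 0:
        return None, None
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return mean, sd


def description_lag(profiles, cutoff_year: int = 1999,
                    groups: dict[str, str] | None = None):
    """Description-to-first-dated-detection lag for recently described species.

    Only species described after ``cutoff_year`` with a dated detection year
    contribute; snapshot-only species are excluded from the statistics but
    counted.  Lag = first dated year - description year; negative lags are
    retained and flagged.  ``groups`` optionally maps accepted name ->
    group for per-group means/SDs (sample SD).
    """
    lags: dict[str, int] = {}
    negative: list[str] = []
    snapshot_only = 0
    excluded_unknown = 0
    for p in profiles:
        if p.description_year is None:
            excluded_unknown += 1
            continue
        if p.description_year <= cutoff_year:
            continue
        if not p.detection_years:
            if p.snapshot_only:
                snapshot_only += 1
            continue
        lag = min(p.detection_years) - p.description_year
        lags[p.accepted_name] = lag
        if lag < 0:
            negative.append(p.accepted_name)
    mean, sd = _mean_sd(list(lags.values()))
    result = {
        "per_species": lags,
        "mean": mean,
        "sd": sd,
        "n": len(lags),
        "snapshot_only": snapshot_only,
        "negative_lags": negative,
        "excluded_unknown_description_year": excluded_unknown,
    }
    if groups:
        by_group: dict[str, list[int]] = {}
        for name, lag in lags.items():
            by_group.setdefault(groups.get(name, "unknown"), []).append(lag)
        result["groups"] = {
            g: dict(zip(("mean", "sd", "n"), (*_mean_sd(v), len(v))))
            for g, v in sorted(by_group.items())
        }
    return result


def per_site_richness(detections, snapshot_year=None, all_sites: set[str] | None = None):
    """Distinct-species richness per website for one snapshot.

    ``snapshot_year=None`` selects the contemporary snapshot.  The headline
    mean/SE/range are over sites with at least one species (the
    with-detections denominator); the all-sites alternative, counting
    zero-species sites, is returned alongside.  SE = sample SD / sqrt(n).
    """
    per_site: dict[str, set[str]] = {}
    sites_seen: set[str] = set(all_sites or ())
    for d in detections:
        if d.snapshot_year != snapshot_year:
            continue
        sites_seen.add(d.site_id)
        if d.match_kind == "genus_only" or d.accepted_name is None:
            continue
        per_site.setdefault(d.site_id, set()).add(d.accepted_name)
    counts = {s: len(v) for s, v in per_site.items()}
    values = sorted(counts.values())
    mean, sd = _mean_sd(values)
    n = len(values)
    n_zero = len(sites_seen - set(counts))
    all_values = values + [0] * n_zero
    mean_all, sd_all = _mean_sd(all_values)
    return {
        "per_site": counts,
        "n_sites_with_species": n,
        "n_sites_without_species": n_zero,
        "mean": mean,
        "se": (sd / math.sqrt(n)) if n else None,
        "min": values[0] if values else None,
        "max": values[-1] if values else None,
        "mean_all_sites": mean_all,
        "se_all_sites": (sd_all / math.sqrt(len(all_values))) if all_values else None,
    }
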