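"""LEMIS and CITES trade-record reading, filtering and classification.

LEMIS (the US Fish & Wildlife import ledger) records carry one-letter codes
for what an item is (description), where it came from (source), why it was
shipped (purpose) and what happened at inspection (disposition).  Summaries
are restricted to items that plausibly represent whole individuals and
partition quantities into wild / captive / other origin classes.
"""

from __future__ import annotations

import logging

import pandas as pd

from .taxonomy import NameIndex, resolve_name

logger = logging.getLogger(__name__)

#: Description codes that feasibly represent whole individuals: dead animal,
#: live eggs, dead specimen, live specimen, specimen, whole skin, entire
#: animal trophy.
WHOLE_INDIVIDUAL_CODES = frozenset({"BOD", "EGL", "DEA", "LIV", "SPE", "SKI", "TRO"})

#: Source codes bred in captivity (C, F), commercially bred (D), ranched (R).
CAPTIVE_SOURCES = frozenset({"C", "F", "D", "R"})
WILD_SOURCE = "W"

#: Purpose codes counted as non-commercial: biomedical research (M),
#: scientific (S), reintroduction into the wild (Y).
NONCOMMERCIAL_PURPOSES = frozenset({"M", "S", "Y"})

SEIZED_DISPOSITION = "S"

#: Genus placeholders excluded from per-genus summaries.
GENUS_PLACEHOLDERS = frozenset({"non-cites entry", "na", ""})

LEMIS_COLUMNS = {
    "taxon_class": "class",
    "genus": "genus",
    "species": "species",
    "quantity": "quantity",
    "description_code": "description",
    "disposition": "disposition",
    "purpose": "purpose",
    "source_code": "source",
    "country_origin": "country_origin",
    "shipment_year": "shipment_year",
}


def read_lemis(path, column_map: dict[str, str] | None = None,
               taxon_class: str | None = "Arachnida") -> pd.DataFrame:
    """Read a LEMIS-style CSV into the canonical column layout.

    ``column_map`` overrides the default dialect (that of the public Zenodo
    LEMIS compilation).  Rows are filtered to ``taxon_class`` when the class
    column exists.  Missing quantities become 0 with a logged count;
    negative quantities are rejected with a log entry.
    """
    cmap = dict(LEMIS_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {src: canon for canon, src in cmap.items() if src in df.columns}
    df = df.rename(columns=rename)
    if taxon_class and "taxon_class" in df.columns:
        df = df[df["taxon_class"].str.strip().str.lower() == taxon_class.lower()]
    qty = pd.to_numeric(df.get("quantity", ""), errors="coerce")
    n_missing = int(qty.isna().sum())
    if n_missing:
        logger.info("%d records with missing quantity treated as 0", n_missing)
    df = df.assign(quantity=qty.fillna(0.0))
    neg = df["quantity"] < 0
    if neg.any():
        logger.warning("%d records with negative quantity rejected", int(neg.sum()))
        df = df[~neg]
    for col in ("description_code", "disposition", "purpose", "source_code"):
        if col in df.columns:
            df[col] = df[col].str.strip().str.upper()
    if "shipment_year" in df.columns:
        df["shipment_year"] = pd.to_numeric(df["shipment_year"], errors="coerce")
    return df.reset_index(drop=True)


def filter_whole_individuals(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only records whose description code represents a whole animal."""
    return records[records["description_code"].isin(WHOLE_INDIVIDUAL_CODES)].reset_index(drop=True)


def classify_source(source_code: str) -> str:
    """W -> wild; C, F, D, R -> captive; anything else -> other."""
    code = (source_code or "").strip().upper()
    if code == WILD_SOURCE:
        return "wild"
    if code in CAPTIVE_SOURCES:
        return "captive"
    return "other"


def classify_purpose(purpose: str) -> str:
    """M, S, Y -> non_commercial; everything else -> commercial_or_other."""
    code = (purpose or "").strip().upper()
    return "non_commercial" if code in NONCOMMERCIAL_PURPOSES else "commercial_or_other"


def summarise_lemis(records: pd.DataFrame) -> dict:
    """Quantity-weighted headline summary of whole-individual records.

    ``records`` should already have passed :func:`filter_whole_individuals`.
    Returns total individuals, percentage seized / commercial / wild /
    captive / other, a per-genus table with wild fractions (placeholder
    genera excluded) and a per-origin-country table of wild-sourced totals.
    """
    df = records.copy()
    df["source_class"] = df["source_code"].map(classify_source)
    df["purpose_class"] = df["purpose"].map(classify_purpose)
    total = float(df["quantity"].sum())

    def pct(mask) -> float:
        return 100.0 * float(df.loc[mask, "quantity"].sum()) / total if total else 0.0

    by_source = df.groupby("source_class")["quantity"].sum()
    summary = {
        "total_individuals": total,
        "pct_seized": pct(df["disposition"] == SEIZED_DISPOSITION),
        "pct_commercial": pct(df["purpose_class"] == "commercial_or_other"),
        "pct_wild": 100.0 * float(by_source.get("wild", 0.0)) / total if total else 0.0,
        "pct_captive": 100.0 * float(by_source.get("captive", 0.0)) / total if total else 0.0,
        "pct_other": 100.0 * float(by_source.get("other", 0.0)) / total if total else 0.0,
    }

    g = df.assign(genus_norm=df["genus"].str.strip().str.lower())
    g = g[~g["genus_norm"].isin(GENUS_PLACEHOLDERS)]
    per_genus = (
        g.groupby("genus_norm")
        .apply(
            lambda x: pd.Series({
                "total": float(x["quantity"].sum()),
                "wild": float(x.loc[x["source_class"] == "wild", "quantity"].sum()),
            }),
            include_groups=False,
        )
        .reset_index()
    )
    per_genus["wild_fraction"] = per_genus.apply(
        lambda r: r["wild"] / r["total"] if r["total"] else 0.0, axis=1
    )
    summary["per_genus"] = per_genus

    wild = df[df["source_class"] == "wild"]
    per_country = (
        wild.groupby("country_origin")["quantity"].sum().rename("wild_individuals")
        .reset_index()
    )
    summary["per_origin_country"] = per_country
    return summary


def lemis_species(records: pd.DataFrame, index: NameIndex):
    """Species-level names in LEMIS resolved through the index.

    Genus-only rows (blank species or "sp.") are skipped — they count for
    individuals and genus summaries but not species-level overlap.  Returns
    a DataFrame with raw name, accepted name, match kind and shipment year.
    """
    rows = []
    for _, rec in records.iterrows():
        genus = str(rec.get("genus", "")).strip()
        species = str(rec.get("species", "")).strip()
        if (not species or species.lower() in {"sp.", "sp", "spp.", "spp"}
                or genus.lower() in GENUS_PLACEHOLDERS):
            continue
        raw = f"{genus} {species}"
        res = resolve_name(raw, index)
        rows.append({
            "raw_name": raw,
            "accepted_name": res.accepted_name,
            "match_kind": res.match_kind,
            "shipment_year": rec.get("shipment_year"),
        })
    return pd.DataFrame(rows, columns=["raw_name", "accepted_name", "match_kind", "shipment_year"])


def nonnative_wild_exports(records: pd.DataFrame, ranges: dict[str, set[str]],
                           index: NameIndex):
    """Wild-sourced exports from countries outside the species' native set.

    ``ranges`` maps accepted name -> set of native country ids (as produced
    by the biogeo stage).  Species with no range data fall into an
    "unknown range" bucket and are never counted as non-native.  Returns
    ``(per_country, per_species)`` DataFrames.
    """
    df = records.copy()
    df["source_class"] = df["source_code"].map(classify_source)
    wild = df[df["source_class"] == "wild"]
    country_rows: dict[str, dict[str, float]] = {}
    species_rows: dict[str, float] = {}
    for _, rec in wild.iterrows():
        origin = str(rec.get("country_origin", "")).strip()
        qty = float(rec["quantity"])
        entry = country_rows.setdefault(
            origin, {"wild_individuals": 0.0, "nonnative_individuals": 0.0,
                     "unknown_range_individuals": 0.0})
        entry["wild_individuals"] += qty
        genus = str(rec.get("genus", "")).strip()
        species = str(rec.get("species", "")).strip()
        raw = f"{genus} {species}".strip()
        res = resolve_name(raw, index)
        accepted = res.accepted_name
        native = ranges.get(accepted) if accepted else None
        if not native:
            entry["unknown_range_individuals"] += qty
            continue
        if origin not in native:
            entry["nonnative_individuals"] += qty
            species_rows[accepted] = species_rows.get(accepted, 0.0) + qty
    per_country = pd.DataFrame(
        [{"country": c, **v} for c, v in sorted(country_rows.items())]
    )
    if not per_country.empty:
        per_country["nonnative_share"] = per_country.apply(
            lambda r: (r["nonnative_individuals"] / r["wild_individuals"])
            if r["wild_individuals"] else 0.0, axis=1,
        )
    per_species = pd.DataFrame(
        [{"accepted_name": s, "nonnative_wild_individuals": q}
         for s, q in sorted(species_rows.items())]
    )
    return per_country, per_species


def read_cites(gross_imports_csv, index: NameIndex,
               year_min: int = 1975, year_max: int = 2021):
    """Read a CITES gross-imports export; resolve taxa, keep yearly totals.

    Accepts the standard wide layout (a ``Taxon`` column plus one column per
    year) or a long layout with ``taxon``/``year``/``quantity`` columns.
    Years outside [year_min, year_max] are excluded.  Returns
    ``(species, yearly)``: species is a DataFrame of raw/accepted names
    (unresolvable names kept under the raw name, flagged unknown) and yearly
    a DataFrame of (accepted_or_raw, year, quantity).
    """
    df = pd.read_csv(gross_imports_csv, dtype=str, keep_default_na=False)
    cols_lower = {c.lower(): c for c in df.columns}
    long_rows = []
    if "taxon" in cols_lower and "year" in cols_lower and "quantity" in cols_lower:
        for _, rec in df.iterrows():
            long_rows.append((rec[cols_lower["taxon"]], rec[cols_lower["year"]],
                              rec[cols_lower["quantity"]]))
    else:
        taxon_col = cols_lower.get("taxon")
        if taxon_col is None:
            raise ValueError("CITES export needs a 'Taxon' column")
        year_cols = [c for c in df.columns if c.strip().isdigit()]
        for _, rec in df.iterrows():
            for yc in year_cols:
                if str(rec[yc]).strip():
                    long_rows.append((rec[taxon_col], yc, rec[yc]))
    species_rows = {}
    yearly_rows = []
    for taxon, year, qty in long_rows:
        try:
            year_i = int(str(year).strip())
        except ValueError:
            continue
        if not (year_min <= year_i <= year_max):
            continue
        res = resolve_name(taxon, index)
        key = res.accepted_name or str(taxon).strip()
        species_rows[key] = {
            "raw_name": str(taxon).strip(),
            "accepted_name": res.accepted_name,
            "match_kind": res.match_kind,
            "unresolved": res.accepted_name is None,
        }
        qty_f = pd.to_numeric(pd.Series([qty]), errors="coerce").iloc[0]
        yearly_rows.append({
            "name": key, "year": year_i,
            "quantity": 0.0 if pd.isna(qty_f) else float(qty_f),
        })
    species = pd.DataFrame(
        [{"name": k, **v} for k, v in sorted(species_rows.items())],
        columns=["name", "raw_name", "accepted_name", "match_kind", "unresolved"],
    )
    yearly = pd.DataFrame(yearly_rows, columns=["name", "year", "quantity"])
    if not yearly.empty:
        yearly = yearly.groupby(["name", "year"], as_index=False)["quantity"].sum()
    return species, yearly
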