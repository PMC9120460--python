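"""End-to-end pipeline orchestration with a config file and run manifest.

Stages run in dependency order: checklist -> name index -> corpus cleaning
-> hierarchical matching -> spurious filtering -> colour co-occurrence ->
LEMIS / CITES classification -> cross-source integration -> range
digitisation -> country summaries.  Output is a pure function of (inputs,
config); the manifest records input hashes and the decisions in effect so
reruns are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import biogeo, corpus, integrate, lexical, matcher, taxonomy, trade

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Pipeline configuration invalid (missing field or path)."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Paths are resolved relative to the config file's directory when loaded
    from disk.  ``basis`` picks exact-only or any-name species matching for
    the integration stage; the flags expose the documented alternative
    conventions (strict both-side word boundaries, per-token colour
    multiplicity, all-sites richness denominator).
    """

    checklists: list[dict] = field(default_factory=list)  # {path, group, column_map?}
    corpus_root: str | None = None
    corpus_manifest: str | None = None
    lemis: str | None = None
    cites: str | None = None
    ranges: str | None = None
    country_table: str | None = None
    region_map: str | None = None
    island_map: str | None = None
    blocklist: str | None = None
    colour_list: str | None = None
    colour_exclusions: str | None = None
    basis: str = "any_name"
    strict_boundaries: bool = False
    colour_multiplicity: bool = False
    seed: int = 0
    output_dir: str = "out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        base = path.parent

        def _resolve(p):
            return str((base / p).resolve()) if p and not Path(p).is_absolute() else p

        for f in ("corpus_root", "corpus_manifest", "lemis", "cites", "ranges",
                  "country_table", "region_map", "island_map", "blocklist",
                  "colour_list", "colour_exclusions"):
            setattr(cfg, f, _resolve(getattr(cfg, f)))
        for entry in cfg.checklists:
            entry["path"] = _resolve(entry["path"])
        cfg.output_dir = _resolve(cfg.output_dir) or cfg.output_dir
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.basis not in ("any_name", "exact_only"):
            raise ConfigError(f"basis must be any_name or exact_only, got {self.basis!r}")
        if not self.checklists:
            raise ConfigError("at least one checklist is required")
        for entry in self.checklists:
            if "path" not in entry or "group" not in entry:
                raise ConfigError("each checklist needs 'path' and 'group'")
            if not Path(entry["path"]).exists():
                raise ConfigError(f"checklist path missing: {entry['path']}")
        for fname in ("corpus_manifest", "lemis", "cites", "ranges",
                      "country_table", "region_map", "island_map"):
            p = getattr(self, fname)
            if p and not Path(p).exists():
                raise ConfigError(f"{fname} path missing: {p}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; write CSV summaries plus a manifest.

    Returns a result dict with the in-memory summaries.  A stage failure
    raises with the stage name; partial outputs are marked stale in the
    manifest written on the way out.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    input_hashes: dict[str, str] = {}
    stage = "checklists"
    try:
        records = []
        for entry in config.checklists:
            records.extend(taxonomy.load_checklist(
                entry["path"], entry["group"], entry.get("column_map")))
            input_hashes[entry["path"]] = _sha256(entry["path"])
        index = taxonomy.build_name_index(records)
        index.to_json(out / "name_index.json")
        results["n_species"] = len(index.accepted_names)
        results["n_names"] = len(index) + len(index.conflicts)
        desc_years = {r.accepted_name: r.description_year for r in records
                      if r.description_year is not None}
        groups = {r.accepted_name: r.group for r in records}

        detections = []
        if config.corpus_manifest:
            stage = "corpus"
            input_hashes[config.corpus_manifest] = _sha256(config.corpus_manifest)
            pages = corpus.load_corpus(config.corpus_root or ".", config.corpus_manifest)
            corpus.write_corpus_store(pages, out / "corpus.jsonl")

            stage = "match"
            detections = matcher.search_corpus(pages, index, config.strict_boundaries)
            blocklist = (set(lexical._read_wordlist(config.blocklist))
                         if config.blocklist else matcher.DEFAULT_BLOCKLIST)
            detections, audit = matcher.filter_spurious(detections, blocklist)
            matcher.write_detections_csv(detections, out / "detections.csv")
            results["spurious_audit"] = audit

            stage = "colours"
            lexicon = lexical.build_colour_lexicon(config.colour_list,
                                                   config.colour_exclusions)
            colour_rows, colour_summary = lexical.count_colour_cooccurrence(
                detections, lexicon,
                per_token_multiplicity=config.colour_multiplicity)
            lexical.write_colour_counts_csv(colour_rows, out / "colour_counts.csv")
            lexical.write_colour_summary_csv(colour_summary, out / "colour_summary.csv")
            results["colour_summary"] = colour_summary

        lemis_names: set[str] = set()
        lemis_years: dict[str, set] = {}
        if config.lemis:
            stage = "lemis"
            input_hashes[config.lemis] = _sha256(config.lemis)
            lemis_df = trade.read_lemis(config.lemis)
            whole = trade.filter_whole_individuals(lemis_df)
            summary = trade.summarise_lemis(whole)
            summary["per_genus"].to_csv(out / "lemis_per_genus.csv", index=False)
            summary["per_origin_country"].to_csv(out / "lemis_per_origin.csv", index=False)
            results["lemis_summary"] = {
                k: v for k, v in summary.items()
                if k not in ("per_genus", "per_origin_country")
            }
            sp = trade.lemis_species(lemis_df, index)
            for _, row in sp.iterrows():
                if row["accepted_name"]:
                    lemis_names.add(row["accepted_name"])
                    y = row["shipment_year"]
                    if y == y and y is not None:  # not NaN
                        lemis_years.setdefault(row["accepted_name"], set()).add(int(y))
            results["lemis_df"] = lemis_df

        cites_names: set[str] = set()
        if config.cites:
            stage = "cites"
            input_hashes[config.cites] = _sha256(config.cites)
            cites_species, cites_yearly = trade.read_cites(config.cites, index)
            cites_names = set(cites_species.loc[~cites_species["unresolved"],
                                                "accepted_name"])
            cites_yearly.to_csv(out / "cites_yearly.csv", index=False)
            results["cites_unresolved"] = int(cites_species["unresolved"].sum())

        stage = "integrate"
        profiles, overlap = integrate.combine_sources(
            detections, lemis_names, cites_names, index,
            basis=config.basis, description_years=desc_years,
            lemis_years=lemis_years)
        results["profiles"] = profiles
        results["overlap"] = overlap
        results["per_year"] = integrate.species_per_year(profiles)
        results["lag"] = integrate.description_lag(profiles, groups=groups)
        results["richness"] = integrate.per_site_richness(detections)
        with open(out / "overlap.json", "w", encoding="utf-8") as fh:
            json.dump({"totals": overlap["totals"],
                       "combinations": {"+".join(sorted(k)): v
                                        for k, v in overlap["combinations"].items()}},
                      fh, indent=1, sort_keys=True)

        if config.ranges and config.country_table:
            stage = "ranges"
            for p in (config.ranges, config.country_table):
                input_hashes[p] = _sha256(p)
            table = biogeo.CountryTable.from_csv(config.country_table)
            region_map = (biogeo.load_region_map(config.region_map)
                          if config.region_map else {})
            island_map = {}
            if config.island_map:
                import csv as _csv
                with open(config.island_map, newline="", encoding="utf-8") as fh:
                    for row in _csv.DictReader(fh):
                        island_map[row["island"]] = row["country_id"]
            assertions = biogeo.load_assertions_csv(config.ranges)
            ranges, range_report = biogeo.build_country_ranges(
                assertions, table, region_map, island_map)
            biogeo.write_ranges_csv(ranges, out / "species_countries.csv")
            traded = {p.accepted_name for p in profiles}
            summary_df = biogeo.country_trade_summary(ranges, traded)
            summary_df.to_csv(out / "country_summary.csv", index=False)
            results["ranges"] = ranges
            results["range_report"] = range_report
            results["endemism"] = biogeo.endemism_summary(ranges)
            if "lemis_df" in results:
                per_country, per_species = trade.nonnative_wild_exports(
                    results["lemis_df"],
                    {k: v.countries for k, v in ranges.items()}, index)
                per_country.to_csv(out / "nonnative_per_country.csv", index=False)
                per_species.to_csv(out / "nonnative_per_species.csv", index=False)
                results["nonnative_per_country"] = per_country
                results["nonnative_per_species"] = per_species
    except Exception as exc:
        manifest = {"status": "failed", "stage": stage, "error": str(exc),
                    "config": config.to_dict(), "input_hashes": input_hashes,
                    "stale_outputs": True}
        with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    from . import __version__
    manifest = {
        "status": "ok",
        "version": __version__,
        "config": config.to_dict(),
        "input_hashes": input_hashes,
        "decisions": {
            "basis": config.basis,
            "strict_boundaries": config.strict_boundaries,
            "colour_multiplicity": config.colour_multiplicity,
            "richness_denominator": "sites_with_detections",
        },
    }
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results


def load_config(path) -> RunConfig:
    return RunConfig.from_yaml(path)


__all__ = ["RunConfig", "ConfigError", "run_pipeline", "load_config"]
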