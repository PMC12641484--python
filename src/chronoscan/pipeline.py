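"""End-to-end orchestration: scan, outliers, genes, enrichment, contrast.

``run_scan`` executes one pairwise genome scan (by default the spring
contrast: early- vs late-migrating pool) from a sync file to per-site
statistics, spline windows, outlier calls, candidate genes and term
overrepresentation, writing every table plus a manifest under a run
directory. ``run_contrast`` compares the genome-wide differentiation of
two pool pairs (spring vs autumn) with Z-tests on per-site F_ST and AFD.

A run whose inputs and settings are unchanged (matched by checksum in the
manifest) is skipped and its outputs reloaded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import chronoscan
from chronoscan import genemap, sitestats, windows as windows_mod
from chronoscan.sitestats import ContrastSummary, site_scan, z_contrast
from chronoscan.syncio import (
    FilterSettings,
    filter_sites,
    read_gff_genes,
    read_sync,
    read_term_map,
    write_bed,
)


class ConfigError(ValueError):
    """A configuration problem detected before any compute."""


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of a pipeline run."""

    sync: Path
    gff: Path
    terms: Path
    out_dir: Path
    pool_names: tuple[str, ...] = (
        "early_spring",
        "late_spring",
        "early_autumn",
        "late_autumn",
    )
    pool_individuals: tuple[int, ...] = (9, 9, 9, 9)
    spring_pair: tuple[str, str] = ("early_spring", "late_spring")
    autumn_pair: tuple[str, str] = ("early_autumn", "late_autumn")
    filters: FilterSettings = field(default_factory=FilterSettings)
    smoothness: float | None = None
    alpha: float = 0.01
    min_significant: int = 2
    flank: int = 25_000
    fdr_cut: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pool_individuals) != len(self.pool_names):
            raise ConfigError("pool_individuals must match pool_names in length")
        for pair_name, pair in (("spring", self.spring_pair), ("autumn", self.autumn_pair)):
            for name in pair:
                if name not in self.pool_names:
                    raise ConfigError(
                        f"{pair_name} pair pool {name!r} not in pool_names "
                        f"{list(self.pool_names)}"
                    )
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.fdr_cut < 1.0):
            raise ConfigError("alpha and fdr_cut must be in (0, 1)")
        if self.min_significant < 1 or self.flank < 0:
            raise ConfigError("min_significant >= 1 and flank >= 0 required")

    def pair_indices(self, pair: tuple[str, str]) -> tuple[int, int]:
        return (self.pool_names.index(pair[0]), self.pool_names.index(pair[1]))

    def pair_haploid_sizes(self, pair: tuple[str, str]) -> tuple[int, int]:
        i, j = self.pair_indices(pair)
        return (2 * self.pool_individuals[i], 2 * self.pool_individuals[j])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping of settings")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known - {"filters"}
        if unknown:
            raise ConfigError(f"{path}: unknown settings {sorted(unknown)}")
        kwargs: dict = {}
        for key in ("sync", "gff", "terms", "out_dir"):
            if key not in raw:
                raise ConfigError(f"{path}: missing required setting {key!r}")
            kwargs[key] = Path(raw[key])
        if "filters" in raw:
            kwargs["filters"] = FilterSettings(**raw["filters"])
        for key in (
            "pool_names",
            "pool_individuals",
            "spring_pair",
            "autumn_pair",
        ):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("smoothness", "alpha", "min_significant", "flank", "fdr_cut", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class ScanReport:
    """Everything one scan produced, with the paths it was written to."""

    sites: pd.DataFrame
    windows: pd.DataFrame
    candidates: pd.DataFrame
    enrichment: pd.DataFrame
    summary: dict
    paths: dict[str, Path]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _settings_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    for key in ("sync", "gff", "terms", "out_dir"):
        d[key] = str(d[key])
    return d


def _run_key(config: RunConfig) -> dict:
    for key in ("sync", "gff", "terms"):
        if not Path(getattr(config, key)).exists():
            raise ConfigError(f"input file does not exist: {getattr(config, key)}")
    key = {
        "settings": _settings_dict(config),
        "inputs": {
            name: _sha256(Path(getattr(config, name)))
            for name in ("sync", "gff", "terms")
        },
        "version": chronoscan.__version__,
    }
    # normalize containers (tuple -> list) so the key compares equal to its
    # JSON round-trip in a previously written manifest
    return json.loads(json.dumps(key))


def _scan_paths(out_dir: Path) -> dict[str, Path]:
    return {
        "sites": out_dir / "sites.tsv",
        "windows": out_dir / "windows.tsv",
        "windows_bed": out_dir / "windows.bed",
        "candidates": out_dir / "candidates.tsv",
        "enrichment": out_dir / "enrichment.tsv",
        "summary": out_dir / "scan_summary.json",
        "manifest": out_dir / "manifest.json",
    }


def _cached_report(paths: dict[str, Path], key: dict) -> ScanReport | None:
    manifest_path = paths["manifest"]
    if not manifest_path.exists():
        return None
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError:
        return None
    if manifest.get("key") != key:
        return None
    if not all(p.exists() for p in paths.values()):
        return None
    return ScanReport(
        sites=pd.read_csv(paths["sites"], sep="\t"),
        windows=pd.read_csv(paths["windows"], sep="\t"),
        candidates=pd.read_csv(paths["candidates"], sep="\t"),
        enrichment=pd.read_csv(paths["enrichment"], sep="\t"),
        summary=json.loads(paths["summary"].read_text()),
        paths=paths,
    )


def run_scan(config: RunConfig, pair: tuple[str, str] | None = None) -> ScanReport:
    """Run the pairwise genome scan end to end (default: the spring pair).

    Emits per-site statistics, the window table (TSV and BED6), the
    outlier/candidate/enrichment tables, a JSON summary (site and window
    counts, mean window F_ST genome-wide and over outliers, their ratio,
    combined outlier span, per-site mean F_ST, filter drop reasons) and a
    manifest with settings, input checksums and the package version. The
    run is skipped when an existing manifest matches.
    """
    pair = pair or config.spring_pair
    out_dir = Path(config.out_dir)
    paths = _scan_paths(out_dir)
    key = _run_key(config) | {"pair": list(pair)}
    cached = _cached_report(paths, key)
    if cached is not None:
        return cached
    out_dir.mkdir(parents=True, exist_ok=True)

    records = read_sync(config.sync)
    if records and records[0].n_pools < len(config.pool_names):
        raise ConfigError(
            f"sync file has {records[0].n_pools} pools but config names "
            f"{len(config.pool_names)}"
        )
    pools = config.pair_indices(pair)
    _, mask = filter_sites(records, config.filters, pools)
    drop_reasons = {
        reason: int(sum(m == reason for m in mask))
        for reason in sorted({m for m in mask if m is not None})
    }
    sites = site_scan(
        records,
        config.filters,
        pools,
        haploid_sizes=config.pair_haploid_sizes(pair),
    )
    win, membership = windows_mod.assign_windows(
        sites, smoothness=config.smoothness, alpha=config.alpha
    )
    win, summary = windows_mod.call_outliers(win, config.min_significant)
    sites = sites.assign(window_id=membership)

    genes = read_gff_genes(config.gff)
    term_map = read_term_map(config.terms)
    outlier_windows = win[win["outlier"]]
    candidates = genemap.candidate_genes(outlier_windows, genes, config.flank)
    universe = [g.gene_id for g in genes]
    cand_ids = candidates["gene_id"].tolist() if len(candidates) else []
    enrichment = genemap.overrepresentation(
        cand_ids, universe, term_map, config.fdr_cut
    )

    summary.update(
        {
            "pair": list(pair),
            "n_input_sites": len(records),
            "n_analyzed_sites": int(len(sites)),
            "dropped_by_reason": drop_reasons,
            "mean_site_fst": float(np.nanmean(sites["fst"])) if len(sites) else float("nan"),
            "n_candidate_genes": int(len(candidates)),
            "n_retained_terms": int(enrichment["retained"].sum()) if len(enrichment) else 0,
        }
    )

    sites.to_csv(paths["sites"], sep="\t", index=False, float_format="%.6g")
    win.to_csv(paths["windows"], sep="\t", index=False, float_format="%.6g")
    write_bed(
        (
            (
                row.scaffold,
                int(row.start),
                int(row.end),
                f"window_{i}",
                f"{row.mean_fst:.4g}",
                ".",
            )
            for i, row in enumerate(win.itertuples())
        ),
        paths["windows_bed"],
    )
    candidates.to_csv(paths["candidates"], sep="\t", index=False)
    enrichment.to_csv(paths["enrichment"], sep="\t", index=False, float_format="%.6g")
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    paths["manifest"].write_text(json.dumps({"key": key}, indent=2, sort_keys=True) + "\n")
    return ScanReport(
        sites=sites,
        windows=win,
        candidates=candidates,
        enrichment=enrichment,
        summary=summary,
        paths=paths,
    )


def run_contrast(config: RunConfig) -> dict[str, ContrastSummary]:
    """Z-contrast the spring and autumn comparisons genome-wide.

    Computes per-site F_ST and AFD for both pool pairs on their own
    filtered site sets (one shared FilterSettings), then Z-tests
    spring vs autumn for each metric. Requires >= 30 analyzed sites in
    each comparison. Writes ``contrast.json`` under the run directory and
    returns ``{"fst": ..., "afd": ...}``.
    """
    records = read_sync(config.sync)
    if records and records[0].n_pools < len(config.pool_names):
        raise ConfigError(
            f"sync file has {records[0].n_pools} pools but config names "
            f"{len(config.pool_names)}"
        )
    per_pair = {}
    for label, pair in (("spring", config.spring_pair), ("autumn", config.autumn_pair)):
        per_pair[label] = site_scan(
            records,
            config.filters,
            config.pair_indices(pair),
            haploid_sizes=config.pair_haploid_sizes(pair),
        )
        if len(per_pair[label]) < 30:
            raise ValueError(
                f"{label} comparison has {len(per_pair[label])} analyzed "
                f"sites; the Z-test requires at least 30"
            )
    result = {
        "fst": z_contrast(per_pair["spring"]["fst"], per_pair["autumn"]["fst"]),
        "afd": z_contrast(per_pair["spring"]["afd"], per_pair["autumn"]["afd"]),
    }
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        metric: dataclasses.asdict(summary) for metric, summary in result.items()
    }
    (out_dir / "contrast.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    return result
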