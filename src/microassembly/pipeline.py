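"""End-to-end study-shaped analysis.

Simulate (or ingest) archaeal and bacterial count tables for two sediment
layers on a 7-sites x 3-replicates design, then run rarefaction, alpha/beta
diversity with NMDS, the neutral-model fit with taxon partitioning, a Mantel
panel against physicochemical variables, and core-taxa Venn regions — and
assemble everything into a machine-readable report that is byte-identical
under a fixed master seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging

import numpy as np

from . import __version__
from .community import core_taxa
from .diversity import alpha_diversity, bray_curtis, nmds
from .env_stats import anova_lsd_cld, mantel, significance_band
from .errors import ParameterError
from .io_tables import ENV_VARIABLES, LAYERS, SITES, CountTable, read_count_table, read_metadata, rarefy
from .ncm import fit_ncm
from .synthetic import (
    make_metacommunity,
    make_taxonomy,
    simulate_filtered_samples,
    simulate_metadata,
    simulate_neutral_samples,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: master-seed fan-out: fixed per-stage offsets so stages can be rerun in
#: isolation and still reproduce
SEED_OFFSETS = {
    "metacommunity": 11,
    "community": 101,
    "metadata": 211,
    "rarefaction": 307,
    "nmds": 401,
    "mantel": 503,
}

DEFAULT_CONFIG = {
    "seed": 0,
    "design": {"sites": list(SITES), "layers": list(LAYERS), "replicates": 3},
    "simulate": {
        # archaea: neutral assembly in both layers, weaker dispersal at depth;
        # bacteria: environmentally filtered, more strongly at depth — the
        # study-shaped stochastic-vs-deterministic contrast
        "S": 300,
        "depth": 10_000,
        "meta_sigma": 1.5,
        "env_corr": 0.5,
        "groups": {
            "archaea": {
                "0-20 cm": {"mode": "neutral", "N": 10_000, "m": 0.3},
                "20-40 cm": {"mode": "neutral", "N": 10_000, "m": 0.2},
            },
            "bacteria": {
                "0-20 cm": {"mode": "filtered", "filter_strength": 2.0},
                "20-40 cm": {"mode": "filtered", "filter_strength": 5.0},
            },
        },
    },
    "rarefaction_depth": None,  # None -> minimum sample sum per table
    "detection_count": 1,
    "mantel": {"variables": list(ENV_VARIABLES), "n_perm": 499, "method": "pearson"},
    "core": {"rank": "phylum", "n_phyla": 8, "presence_threshold": 0.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _simulate_tables(config: dict):
    """Simulate per-(group, layer) count tables and per-layer metadata."""
    sim = config["simulate"]
    design = config["design"]
    n_samples = len(design["sites"]) * design["replicates"]
    seed = config["seed"]
    tables, metadata = {}, {}
    gradient = np.linspace(0.0, 1.0, n_samples)
    for li, layer in enumerate(design["layers"]):
        metadata[layer] = simulate_metadata(
            n_samples, env_corr=sim["env_corr"],
            seed=seed + SEED_OFFSETS["metadata"] + li,
            sites=design["sites"], layer=layer, gradient=gradient,
        )
        for gi, (group, layer_cfg) in enumerate(sim["groups"].items()):
            cfg = layer_cfg[layer]
            pool = make_metacommunity(
                sim["S"], sim["meta_sigma"], seed + SEED_OFFSETS["metacommunity"] + gi
            )
            table_seed = seed + SEED_OFFSETS["community"] + 10 * gi + li
            if cfg["mode"] == "neutral":
                table = simulate_neutral_samples(
                    pool, cfg["N"], cfg["m"], n_samples, sim["depth"], table_seed
                )
            elif cfg["mode"] == "filtered":
                table, _ = simulate_filtered_samples(
                    pool, gradient, cfg["filter_strength"], sim["depth"], table_seed
                )
            else:
                raise ParameterError(f"unknown simulation mode {cfg['mode']!r}")
            tables[(group, layer)] = table
    return tables, metadata


def _load_tables(config: dict):
    inputs = config["inputs"]
    tables = {}
    for group, by_layer in inputs["tables"].items():
        for layer, path in by_layer.items():
            tables[(group, layer)] = read_count_table(path)
    metadata = {layer: read_metadata(path) for layer, path in inputs["metadata"].items()}
    return tables, metadata


def run_full_analysis(config: dict | None = None) -> dict:
    """Execute every stage in dependency order and return the report dict.

    Identical config and seed give a byte-identical serialized report.
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    seed = config["seed"]
    if "inputs" in config:
        stage = "ingest"
        try:
            tables, metadata = _load_tables(config)
        except KeyError as exc:
            raise ParameterError(f"stage {stage}: missing input entry {exc}") from exc
    else:
        stage = "simulate"
        tables, metadata = _simulate_tables(config)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "package_version": __version__,
            "config_hash": _config_hash(config),
            "seed": seed,
            "seed_offsets": dict(SEED_OFFSETS),
        },
        "groups": {},
        "mantel_panel": {},
        "core_taxa": {},
    }

    mantel_cfg = config["mantel"]
    design = config["design"]
    for (group, layer), table in sorted(tables.items()):
        stage = f"rarefy[{group}/{layer}]"
        depth = config["rarefaction_depth"] or int(table.sample_sums().min())
        logger.info("stage %s at depth %d", stage, depth)
        rare = rarefy(table, depth, seed + SEED_OFFSETS["rarefaction"])

        stage = f"alpha[{group}/{layer}]"
        alpha = alpha_diversity(rare)
        meta = metadata.get(layer)
        if meta is None:
            raise ParameterError(f"stage mantel[{group}/{layer}]: metadata missing for layer {layer!r}")
        sites = meta.frame.loc[list(rare.sample_ids), "site"].to_numpy()
        anova_res, letters = anova_lsd_cld(alpha["shannon"].to_numpy(), sites)

        stage = f"beta[{group}/{layer}]"
        bc = bray_curtis(rare)
        ordination = nmds(bc, seed=seed + SEED_OFFSETS["nmds"])

        stage = f"ncm[{group}/{layer}]"
        fit = fit_ncm(rare, detection_count=config["detection_count"])

        stage = f"mantel[{group}/{layer}]"
        env = meta.frame.loc[list(rare.sample_ids)]
        panel = {}
        for vi, var in enumerate(mantel_cfg["variables"]):
            from .env_stats import env_distance

            dvar = env_distance(env, [var])
            res = mantel(
                bc, dvar, n_perm=mantel_cfg["n_perm"],
                seed=seed + SEED_OFFSETS["mantel"] + vi,
                method=mantel_cfg["method"],
            )
            panel[var] = {"r": res.r, "p_value": res.p_value,
                          "band": significance_band(res.p_value)}
        report["mantel_panel"][f"{group}/{layer}"] = panel

        stage = f"core[{group}/{layer}]"
        core_cfg = config["core"]
        tax = make_taxonomy(rare.taxon_ids, n_phyla=core_cfg["n_phyla"],
                            seed=seed + SEED_OFFSETS["metacommunity"])
        by_site = {}
        for site in design["sites"]:
            ids = [s for s in rare.sample_ids if meta.frame.at[s, "site"] == site]
            if ids:
                by_site[site] = rare.select_samples(ids)
        core, regions = core_taxa(by_site, tax=tax, rank=core_cfg["rank"],
                                  presence_threshold=core_cfg["presence_threshold"])
        report["core_taxa"][f"{group}/{layer}"] = {
            "core": sorted(core),
            "n_regions": len(regions),
            "region_counts": {"|".join(k): v for k, v in sorted(regions.items())},
        }

        report["groups"].setdefault(group, {})[layer] = {
            "rarefaction_depth": depth,
            "n_samples": rare.n_samples,
            "ncm": fit.summary(),
            "alpha": {
                "richness_mean": float(alpha["richness"].mean()),
                "shannon_mean": float(alpha["shannon"].mean()),
                "anova_F": anova_res.F,
                "anova_p": anova_res.p_value,
                "cld": letters,
            },
            "nmds": {
                "stress": ordination.stress_,
                "converged": bool(ordination.converged_),
                "coordinates": {
                    s: [float(c) for c in row]
                    for s, row in zip(ordination.sample_ids_, ordination.embedding_)
                },
            },
        }

    report["layer_contrast"] = compare_layers(report, layers=design["layers"])
    return _round_floats(report)


def compare_layers(report: dict, layers=LAYERS) -> list:
    """Per-group contrast of NCM statistics between the two depth layers."""
    rows = []
    l1, l2 = layers[0], layers[1]
    for group, by_layer in sorted(report["groups"].items()):
        r2_1 = by_layer.get(l1, {}).get("ncm", {}).get("r_squared")
        r2_2 = by_layer.get(l2, {}).get("ncm", {}).get("r_squared")
        nm_1 = by_layer.get(l1, {}).get("ncm", {}).get("Nm")
        nm_2 = by_layer.get(l2, {}).get("ncm", {}).get("Nm")
        rows.append({
            "group": group,
            f"r_squared {l1}": r2_1, f"r_squared {l2}": r2_2,
            "delta_r_squared": None if None in (r2_1, r2_2) else r2_1 - r2_2,
            f"Nm {l1}": nm_1, f"Nm {l2}": nm_2,
        })
    return rows


def serialize_report(report: dict) -> str:
    """Canonical JSON serialization (sorted keys, fixed float precision)."""
    return json.dumps(_round_floats(report), sort_keys=True, indent=2)
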