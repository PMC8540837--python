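"""Pipeline orchestration: rates -> qpcr -> community -> indval -> tree.

A single flat-ish config (YAML-serializable dict) drives the stage
sequence; every run writes its outputs plus a manifest carrying the
resolved config, its hash, and the master seed, so reruns with the same
config are byte-identical. The demonstration mode generates all inputs
with the synthetic-data module: the grazed-treatment community plants
seven 0.1%-responders and one 1%-responder, the exclosed treatment three
0.1%- and six 1%-responders, echoing the study design the analysis is
built for.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioindicators, community, gas_kinetics, phylogeny, qpcr, simulate

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["gas", "qpcr", "community", "indval", "tree"],
    "henry": {"kh_ref": 1.4e-3, "t_ref": 298.15, "vant_hoff": 1750.0},
    "gas": {
        "n_bottles": 16,
        "k_range": [0.005, 0.1],        # h-1
        "c0_ppm": 10000.0,
        "times_h": [0.0, 10.0, 20.0, 30.0],
        "noise_sd": 0.05,
        "bottle": {"total_volume": 50.0, "liquid_volume": 0.0, "temperature": 8.0},
        "soil": {"fresh_mass": 4.0, "water_fraction": 0.8},
    },
    "qpcr": {
        "slope": -3.45,
        "intercept": 38.0,
        "noise_sd_cq": 0.15,
        "replicates": 3,
        "n_samples": 4,
        "sample_copies": [1e5, 3e4, 1e4, 3e3],
        "elution_and_dilution_factor": 100.0,
        "soil": {"fresh_mass": 4.0, "water_fraction": 0.8},
    },
    "community": {
        "n_references": 5,
        "n_reads": 500,
        "defect_rates": {"stop_codon": 0.05, "frameshift": 0.05,
                         "low_quality_window": 0.1},
        "primer_set": "mb661R",
        "denoise_threshold": 1e-3,
    },
    "indval": {
        "n_per_group": 8,
        "n_otus": 50,
        "base_concentration": 3.0,
        # planted responders start in the rare tail so that boosting them
        # does not compositionally depress the background OTUs into
        # spurious indicators of the opposite CH4 level
        "indicator_base_concentration": 0.5,
        "depth": 10000,
        "fold_effect": 8.0,
        "grazed_indicators": {"0.1%": [0, 1, 2, 3, 4, 5, 6], "1%": [7]},
        "exclosed_indicators": {"0.1%": [0, 1, 2], "1%": [7, 8, 9, 10, 11, 12]},
        "exclosed_absent_otus": [3],     # planted criterion-2 absences
        "grazed_absent_otus": [8],
        "permutations": 10000,
        "alpha": 0.01,
    },
    "tree": {"n_taxa": 8, "alignment_length": 452, "bootstrap": 500,
             "branch_range": [0.05, 0.2]},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge DEFAULT_CONFIG <- YAML file <- overrides (deep merge)."""

    def merge(base: dict, extra: dict) -> dict:
        out = copy.deepcopy(base)
        for key, value in extra.items():
            if isinstance(value, dict) and isinstance(out.get(key), dict):
                out[key] = merge(out[key], value)
            else:
                out[key] = value
        return out

    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            config = merge(config, yaml.safe_load(fh) or {})
    if overrides:
        config = merge(config, overrides)
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _stage_seeds(master_seed: int, stages: list[str]) -> dict[str, int]:
    rng = np.random.default_rng(master_seed)
    return {stage: int(rng.integers(0, 2**31 - 1)) for stage in stages}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _henry(config: dict) -> gas_kinetics.HenryParams:
    h = config["henry"]
    return gas_kinetics.HenryParams(h["kh_ref"], h["t_ref"], h["vant_hoff"])


def _run_gas(config: dict, seed: int, outdir: Path) -> dict:
    cfg = config["gas"]
    henry = _henry(config)
    bottle = gas_kinetics.BottleSpec(**cfg["bottle"])
    soil = gas_kinetics.SoilContext(**cfg["soil"])
    rng = np.random.default_rng(seed)
    ks = rng.uniform(*cfg["k_range"], size=cfg["n_bottles"])
    batch = simulate.gen_gas_batch(
        ks, cfg["c0_ppm"], cfg["times_h"], cfg["noise_sd"], bottle, seed=seed
    )
    rows = []
    for i, (series, truth) in enumerate(batch):
        fit = gas_kinetics.fit_first_order(series)
        mass_rate = fit.k * gas_kinetics.total_ch4_mass(bottle, cfg["c0_ppm"], henry)
        rows.append(
            {
                "bottle_id": f"bottle_{i}",
                "k_true": truth["k"],
                "k_per_h": fit.k,
                "r2": fit.r_squared,
                "n": fit.n_points,
                "rate_ug_per_gdw_d": gas_kinetics.rate_per_dry_weight(mass_rate, soil),
                "rate_dissolved_adjusted_uM_per_h": gas_kinetics.rate_at_concentration(
                    fit,
                    gas_kinetics.dissolved_ch4(cfg["c0_ppm"], bottle.temperature, henry),
                ),
            }
        )
    rates = pd.DataFrame(rows)
    rates.to_csv(outdir / "rates.tsv", sep="\t", index=False)
    return {"rates": rates}


def _run_qpcr(config: dict, seed: int, outdir: Path) -> dict:
    cfg = config["qpcr"]
    rng = np.random.default_rng(seed)
    standard = simulate.gen_dilution_cq(
        cfg["slope"], cfg["intercept"], replicates=cfg["replicates"],
        noise_sd_cq=cfg["noise_sd_cq"], seed=seed,
    )
    curve = qpcr.fit_standard_curve(standard)
    soil = gas_kinetics.SoilContext(**cfg["soil"])
    rows = []
    for i, copies in enumerate(cfg["sample_copies"][: cfg["n_samples"]]):
        cq_true = cfg["intercept"] + cfg["slope"] * np.log10(copies)
        for rep in range(cfg["replicates"]):
            rows.append(
                {
                    "sample_id": f"sample_{i}",
                    "replicate": rep,
                    "cq": cq_true + rng.normal(0, cfg["noise_sd_cq"]),
                    "true_copies": copies,
                }
            )
    samples = pd.DataFrame(rows)
    quantified = qpcr.quantify_samples(
        samples, curve, cfg["elution_and_dilution_factor"],
        soils={s: soil for s in samples["sample_id"].unique()},
    )
    quantified["efficiency"] = curve.efficiency
    quantified.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
    return {"qpcr": quantified, "curve": curve}


def _run_community(config: dict, seed: int, outdir: Path) -> dict:
    cfg = config["community"]
    refs = simulate.gen_reference_orfs(cfg["n_references"], seed=seed)
    reads, truth = simulate.gen_amplicons(
        refs, cfg["n_reads"], cfg["defect_rates"], seed=seed + 1
    )
    quality = community.quality_window_filter(reads)
    kept_rows = []
    for read in quality.kept:
        ok_frame, reason = community.frame_stop_filter(read.nucleotides)
        ok_length = community.length_window_filter(read.nucleotides, cfg["primer_set"])
        kept_rows.append(
            {"read_id": read.id, "frame_ok": ok_frame, "length_ok": ok_length,
             "reason": reason}
        )
    frame_table = pd.DataFrame(kept_rows)
    n_pass = int((frame_table["frame_ok"] & frame_table["length_ok"]).sum())
    report = {
        "n_reads": len(reads),
        "n_quality_rejected": quality.n_rejected,
        "n_frame_rejected": int((~frame_table["frame_ok"]).sum()),
        "n_length_rejected": int((~frame_table["length_ok"]).sum()),
        "n_pass": n_pass,
        "planted_defects": truth["defect"].value_counts().to_dict(),
    }
    (outdir / "filter_report.json").write_text(json.dumps(report, indent=2))
    return {"filter_report": report}


def _plant_indicators(spec: dict, fold: float) -> list[tuple[int, str, float, float]]:
    return [
        (otu, level, fold, 1.0)
        for level, otus in spec.items()
        for otu in otus
    ]


def _run_indval(config: dict, seed: int, outdir: Path) -> dict:
    cfg = config["indval"]
    tables = {}
    for offset, (treatment, key, absent_key) in enumerate(
        [("grazed", "grazed_indicators", "grazed_absent_otus"),
         ("exclosed", "exclosed_indicators", "exclosed_absent_otus")]
    ):
        indicators = _plant_indicators(cfg[key], cfg["fold_effect"])
        base = np.full(cfg["n_otus"], float(cfg["base_concentration"]))
        for otu, _, _, _ in indicators:
            base[otu] = cfg["indicator_base_concentration"]
        table, truth = simulate.gen_community(
            n_per_group=cfg["n_per_group"],
            n_otus=cfg["n_otus"],
            base_concentration=base,
            indicators=indicators,
            depth=cfg["depth"],
            seed=seed + offset,
        )
        counts = table.counts.copy()
        for otu in cfg[absent_key]:
            counts[f"OTU_{otu}"] = 0  # planted treatment-exclusive absence
        tables[treatment] = community.denoise(
            community.OTUTable(counts, table.sample_metadata),
            config["community"]["denoise_threshold"],
        )

    selections, results = {}, {}
    for i, (treatment, den) in enumerate(tables.items()):
        rel = den.relative.counts
        labels = den.relative.sample_metadata["ch4_level"]
        result = bioindicators.permutation_pvalues(
            rel, labels, n_permutations=cfg["permutations"], seed=seed + 100 + i
        )
        results[treatment] = result
        selections[treatment] = bioindicators.responding_bioindicators(
            result, cfg["alpha"]
        )
        out = bioindicators.export_long(result, selections[treatment])
        out.to_csv(outdir / f"indval_{treatment}.tsv", sep="\t", index=False)
    unconditional = bioindicators.unconditional_bioindicators(
        selections["grazed"],
        selections["exclosed"],
        tables["grazed"].table.counts,
        tables["exclosed"].table.counts,
    )
    unconditional.to_csv(outdir / "unconditional_bioindicators.tsv", sep="\t")
    return {"responding": selections, "unconditional": unconditional,
            "results": results}


def _run_tree(config: dict, seed: int, outdir: Path) -> dict:
    cfg = config["tree"]
    true_tree = simulate.random_tree(
        cfg["n_taxa"], seed=seed, branch_range=tuple(cfg["branch_range"])
    )
    alignment, _ = simulate.evolve_sequences(
        true_tree, cfg["alignment_length"], seed=seed + 1
    )
    result = phylogeny.bootstrap_support(
        alignment, n_replicates=cfg["bootstrap"], seed=seed + 2
    )
    (outdir / "tree.nwk").write_text(phylogeny.write_newick(result.tree) + "\n")
    dist = phylogeny.jc_distance(alignment).matrix
    dist.to_csv(outdir / "distances.tsv", sep="\t")
    return {"tree": result, "alignment": alignment}


_STAGES = {
    "gas": _run_gas,
    "qpcr": _run_qpcr,
    "community": _run_community,
    "indval": _run_indval,
    "tree": _run_tree,
}


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the enabled stages in order; outputs land under outdir.

    A stage failure stops the run with a stage-labeled error. The resolved
    config, its hash, and the per-stage seeds are written to manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in config["stages"] if s in _STAGES]
    unknown = set(config["stages"]) - set(_STAGES)
    if unknown:
        raise gas_kinetics.ValidationError(f"unknown stages: {sorted(unknown)}")
    seeds = _stage_seeds(config["seed"], list(_STAGES))
    results = {}
    for stage in stages:
        logger.info("running stage %s (seed %d)", stage, seeds[stage])
        try:
            results[stage] = _STAGES[stage](config, seeds[stage], outdir)
        except Exception as exc:
            raise StageError(stage, exc) from exc
    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": config["seed"],
        "stage_seeds": {s: seeds[s] for s in stages},
        "stages_run": stages,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results
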