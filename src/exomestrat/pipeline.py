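"""End-to-end orchestration: config -> simulate/ingest -> scan -> permute ->
replicate -> catalog -> risk table -> power, with a JSON run manifest.

Every stage is a pure function of (inputs, config, master seed): per-stage
RNG streams are spawned deterministically from the master seed, so a rerun
with an identical config produces byte-identical outputs.  Each stage
writes its TSV/JSON outputs into the run directory; the manifest records
the seed, parameters and row counts per stage, including each cohort's
"unique variations" and gene counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import DEFAULT_PAIRS, pair_label, pairwise_scan
from .catalog import load_catalog, map_to_catalog, parent_term_counts, random_set_enrichment, risk_stratify, trait_enrichment
from .io import read_genotypes, write_sample_sheet, write_vcf
from .permutation import PermutationConfig, permute_scan, retain
from .power import DEFAULT_SIZES, power_curve
from .replication import background_contrasts_all, replicate
from .simulate import PlantedEffect, SimulationConfig, simulate_catalog, simulate_replication_pair

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "exomestrat_run"
    seed: int = 0
    pairs: tuple = DEFAULT_PAIRS
    call_rate_threshold: float = 0.5
    alpha: float = 0.05
    n_perm: int = 2_000
    require_nominal: bool = True
    # either simulation...
    simulate: dict | None = None
    # ...or real inputs: {cohort_label: {"vcf": ..., "sheet": ...}}
    inputs: dict | None = None
    catalog_path: str | None = None
    enrichment_n_iter: int = 1_000
    power_sizes: tuple = DEFAULT_SIZES
    power_n_sim: int = 1_000
    power_freqs: tuple = ((0.8, 0.2),)
    background_genome_wide: bool = False

    def __post_init__(self):
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' block or 'inputs'")
        if not 0.0 < self.alpha < 1.0 or not 0.0 <= self.call_rate_threshold <= 1.0:
            raise ValueError("thresholds must lie in (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pairs" in raw:
            raw["pairs"] = tuple(tuple(p) for p in raw["pairs"])
        for key in ("power_sizes",):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "power_freqs" in raw:
            raw["power_freqs"] = tuple(tuple(f) for f in raw["power_freqs"])
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        block = dict(self.simulate or {})
        effects = block.pop("effects", None)
        if effects is not None:
            block["effects"] = tuple(
                PlantedEffect(pair=tuple(e["pair"]), f_high=e["f_high"], f_low=e["f_low"])
                for e in effects
            )
        block.setdefault("seed", self.seed)
        return SimulationConfig(**block)


def _seeds(master: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(master).spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("exomestrat")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    seeds = _seeds(config.seed, 8)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "n_perm": config.n_perm,
        "call_rate_threshold": config.call_rate_threshold,
        "pairs": [pair_label(p) for p in config.pairs],
        "stages": {},
    }
    try:
        # ---- ingest or simulate -------------------------------------------
        cohorts: dict[str, tuple] = {}
        catalog = None
        if config.simulate is not None:
            sim = config.simulation_config()
            (mA, dA), (mB, dB), truth = simulate_replication_pair(sim)
            label_a = next(iter(dA.assignments.values()))[0]
            label_b = next(iter(dB.assignments.values()))[0]
            cohorts = {label_a: (mA, dA), label_b: (mB, dB)}
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
            for label, (m, d) in cohorts.items():
                write_vcf(m, outdir / f"{label}.vcf")
                write_sample_sheet(d, outdir / f"{label}.samples.tsv")
            catalog = simulate_catalog(mA, seed=seeds[0])
            catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
            manifest["stages"]["simulate"] = {
                "n_variants": sim.n_variants,
                "n_planted": sim.n_planted,
                "cohorts": list(cohorts),
            }
        else:
            for label, paths in config.inputs.items():
                m, d = read_genotypes(paths["vcf"], paths["sheet"])
                cohorts[label] = (m, d)
            if config.catalog_path:
                catalog = load_catalog(config.catalog_path)
            manifest["stages"]["ingest"] = {
                label: {"n_samples": m.n_samples, "n_variants": m.n_variants}
                for label, (m, d) in cohorts.items()
            }
        if config.catalog_path and catalog is None:
            catalog = load_catalog(config.catalog_path)

        # ---- scan + permutation per cohort --------------------------------
        retained_results: dict[str, pd.DataFrame] = {}
        cohort_stats: dict[str, dict] = {}
        for ci, (label, (m, d)) in enumerate(cohorts.items()):
            scan = pairwise_scan(
                m, d, pairs=config.pairs, cohort=label,
                call_rate_threshold=config.call_rate_threshold,
            )
            scan.to_csv(outdir / f"scan_{label}.tsv", sep="\t", index=False)
            perm_frames = []
            for pi, pair in enumerate(config.pairs):
                pcfg = PermutationConfig(
                    n_perm=config.n_perm, alpha=config.alpha,
                    seed=seeds[1] + 97 * ci + pi, require_nominal=config.require_nominal,
                )
                obs = scan[scan["pair"] == pair_label(pair)].set_index("variant_index")
                perm = permute_scan(
                    m, d, pair, pcfg, cohort=label,
                    call_rate_threshold=config.call_rate_threshold, observed=obs,
                )
                perm_frames.append(perm)
            perm_all = pd.concat(perm_frames)
            perm_all.to_csv(outdir / f"permutation_{label}.tsv", sep="\t", index=False)
            keep_ids = retain(perm_all)
            kept_rows = perm_all[perm_all["retained"]][["variant_id", "pair"]]
            ret = scan.merge(kept_rows, on=["variant_id", "pair"])
            ret.to_csv(outdir / f"retained_{label}.tsv", sep="\t", index=False)
            retained_results[label] = ret
            cohort_stats[label] = {
                "n_scanned": int(scan["variant_id"].nunique()),
                "unique_variations": len(keep_ids),
                "genes": int(ret["gene"].nunique()),
            }
        manifest["stages"]["association"] = cohort_stats

        # ---- replication ---------------------------------------------------
        labels = list(cohorts)
        level3_ids: set[str] = set()
        if len(labels) == 2:
            rep = replicate(retained_results[labels[0]], retained_results[labels[1]])
            pd.DataFrame({"gene": sorted(rep.level1_genes)}).to_csv(
                outdir / "replication_level1_genes.tsv", sep="\t", index=False
            )
            pd.DataFrame({"variant_id": sorted(rep.level2_ids)}).to_csv(
                outdir / "replication_level2_snps.tsv", sep="\t", index=False
            )
            rep.level3.to_csv(outdir / "replication_level3_profiles.tsv", sep="\t", index=False)
            level3_ids = rep.level3_ids
            manifest["stages"]["replication"] = {
                "level1_genes": len(rep.level1_genes),
                "level2_snps": len(rep.level2_ids),
                "level3_profile_snps": len(level3_ids),
                "level3_rows": int(len(rep.level3)),
            }
        else:
            manifest["stages"]["replication"] = "single cohort"

        # ---- background contrasts -----------------------------------------
        bg_frames = []
        for label, (m, d) in cohorts.items():
            ids = (
                sorted(set(retained_results[label]["variant_id"]))
                if (config.background_genome_wide or not level3_ids)
                else sorted(level3_ids)
            )
            ids = [i for i in ids if i in set(v.id for v in m.variants)]
            if not ids:
                continue
            bg = background_contrasts_all(m, d, ids, cohort=label, alpha=config.alpha)
            bg.insert(0, "cohort", label)
            bg_frames.append(bg)
        background = (
            pd.concat(bg_frames, ignore_index=True) if bg_frames else pd.DataFrame()
        )
        background.to_csv(outdir / "background_contrasts.tsv", sep="\t", index=False)
        manifest["stages"]["background_contrasts"] = int(len(background))

        # ---- catalog -------------------------------------------------------
        if catalog is not None:
            first = labels[0]
            m0, d0 = cohorts[first]
            diff_ids = sorted(set(retained_results[first]["variant_id"]))
            pool = [v.id for v in m0.variants]
            matches = map_to_catalog(diff_ids, catalog)
            matches.to_csv(outdir / "catalog_matches.tsv", sep="\t", index=False)
            enr = random_set_enrichment(
                pool, diff_ids, catalog, n_iter=config.enrichment_n_iter, seed=seeds[2]
            )
            with open(outdir / "enrichment_summary.json", "w") as fh:
                json.dump(
                    {
                        "observed_count": enr.observed_count,
                        "null_median": enr.null_median,
                        "chi_square": enr.chi_square,
                        "p": enr.p,
                        "n_iter": enr.n_iter,
                        "draw_size": enr.draw_size,
                    },
                    fh,
                    indent=2,
                )
            group_rows = []
            for pair in config.pairs:
                for g in pair:
                    sub = retained_results[first][retained_results[first]["pair"] == pair_label(pair)]
                    gm = map_to_catalog(set(sub["variant_id"]), catalog)
                    gm.insert(0, "group", g)
                    group_rows.append(gm)
            group_matches = pd.concat(group_rows, ignore_index=True).drop_duplicates()
            te = (
                trait_enrichment(group_matches, catalog)
                if not group_matches.empty
                else pd.DataFrame()
            )
            te.to_csv(outdir / "trait_enrichment.tsv", sep="\t", index=False)
            parent_term_counts(matches).to_csv(
                outdir / "parent_term_counts.tsv", sep="\t", index=False
            )
            bg_first = background[background.get("cohort") == first] if len(background) else background
            risk = risk_stratify(
                m0, d0, retained_results[first], bg_first, catalog,
                cohort=first, alpha=config.alpha,
            )
            risk.to_csv(outdir / "risk_table.tsv", sep="\t", index=False)
            manifest["stages"]["catalog"] = {
                "matches": int(len(matches)),
                "enrichment_observed": enr.observed_count,
                "enrichment_null_median": enr.null_median,
                "risk_rows": int(len(risk)),
            }

        # ---- power ---------------------------------------------------------
        curves = []
        for fi, (p1, p2) in enumerate(config.power_freqs):
            pc = power_curve(
                p1, p2, sizes=config.power_sizes, alpha=config.alpha,
                n_sim=config.power_n_sim, seed=seeds[3] + fi,
            )
            curves.append(pc.to_frame())
        power_df = pd.concat(curves, ignore_index=True)
        power_df.to_csv(outdir / "power_curve.tsv", sep="\t", index=False)
        manifest["stages"]["power"] = int(len(power_df))

        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as e:
        logger.error("pipeline aborted: %s", e)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
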