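"""End-to-end analysis on the synthetic virtual-species world.

Chains every stage — world generation, occurrence cleaning, PCA, replicate
model fitting, thresholding, evaluation, future-scenario ensembles, stability
maps, and the niche-overlap tests — under a single master seed, writing all
products plus a JSON manifest under a run directory.  Every random draw is
derived from the master seed through named SeedSequence spawns, so two runs
with the same configuration and seed are bit-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import spearmanr

from . import io as vio
from .grids import RasterGrid
from .maxent import fit_replicates, median_of, predict, sample_background
from .occurrences import (
    OccurrenceSet,
    deduplicate,
    filter_precision,
    split_calibration,
    thin_to_grid,
)
from .overlap import background_similarity_test, overlap_statistics
from .pca import fit_pca, select_components, transform
from .products import (
    apply_threshold,
    area_change,
    ensemble_future,
    stability_map,
    threshold_E,
)
from .evaluation import binomial_test, partial_roc
from .simulate import (
    ScenarioSpec,
    TrueNiche,
    default_grid,
    make_environment,
    make_future,
    make_species,
    sample_occurrences,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class SpeciesConfig:
    name: str = "species_a"
    niche_center: tuple[float, ...] = (0.0, 0.0)
    niche_widths: tuple[float, ...] = (1.0, 1.0)
    n_occurrences: int = 400
    n_independent: int = 200


@dataclass
class PipelineConfig:
    """All tunable parameters of a synthetic-world run."""

    n_rows: int = 100
    n_cols: int = 120
    n_latent: int = 2
    n_layers: int = 15
    smooth_sigma: float = 8.0
    layer_noise_sd: float = 0.05
    species: list[SpeciesConfig] = field(
        default_factory=lambda: [
            SpeciesConfig("species_a", (0.0, 0.0), (1.0, 1.0)),
            SpeciesConfig("species_b", (0.5, 0.5), (1.0, 1.0)),
        ]
    )
    dup_rate: float = 0.1
    lowprec_rate: float = 0.1
    split_fraction: float = 0.5
    n_components: int = 8
    n_replicates: int = 10
    background_n: int = 10_000
    beta: float = 2.0
    feature_classes: tuple[str, ...] = ("linear", "quadratic")
    E: float = 0.05
    proc_iterations: int = 1000
    overlap_replicates: int = 100
    n_gcms: int = 9
    run_futures: bool = True
    run_overlap: bool = True

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        species = [SpeciesConfig(**s) for s in raw.pop("species", [])]
        cfg = cls(**raw)
        if species:
            cfg.species = species
        return cfg


def _prepare_species(
    truth, sp: SpeciesConfig, cfg: "PipelineConfig", grid: RasterGrid, valid_mask, seed_seq
) -> dict:
    """Sample, clean and split one species' occurrences."""
    occ_seed, split_seed, ind_seed = [
        int(s.generate_state(1, np.uint32)[0]) for s in seed_seq.spawn(3)
    ]
    raw = sample_occurrences(
        truth,
        n=sp.n_occurrences,
        dup_rate=cfg.dup_rate,
        lowprec_rate=cfg.lowprec_rate,
        seed=occ_seed,
        species=sp.name,
    )
    precise = filter_precision(raw)
    unique = deduplicate(precise)
    thinned = thin_to_grid(unique, grid, valid_mask)
    calibration, evaluation = split_calibration(thinned, cfg.split_fraction, seed=split_seed)
    independent = sample_occurrences(
        truth, n=sp.n_independent, dup_rate=0.0, lowprec_rate=0.0,
        seed=ind_seed, species=sp.name,
    )
    independent = OccurrenceSet(independent.df, "independent")
    return {
        "raw": raw,
        "thinned": thinned,
        "calibration": calibration,
        "evaluation": evaluation,
        "independent": independent,
        "truth": truth,
        "cascade": {
            "raw": len(raw),
            "precise": len(precise),
            "unique": len(unique),
            "thinned": len(thinned),
            "calibration": len(calibration),
            "evaluation": len(evaluation),
        },
    }


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int = 0,
    outdir: str | os.PathLike | None = None,
) -> dict:
    """Run the full synthetic-world analysis; returns a results dictionary.

    When ``outdir`` is given, suitability/binary/stability GeoTIFFs, cleaned
    occurrence CSVs, a results JSON and a manifest are written there.
    """
    cfg = config or PipelineConfig()
    root = np.random.SeedSequence(seed)
    (world_seed, prep_seed, fit_seed, eval_seed, future_seed, overlap_seed) = root.spawn(6)

    # --- world -------------------------------------------------------------
    grid = default_grid(cfg.n_rows, cfg.n_cols)
    env, latent = make_environment(
        grid,
        n_latent=cfg.n_latent,
        n_layers=cfg.n_layers,
        seed=int(world_seed.generate_state(1, np.uint32)[0]),
        smooth_sigma=cfg.smooth_sigma,
        noise_sd=cfg.layer_noise_sd,
    )
    valid_mask = env.valid_mask

    species: dict[str, dict] = {}
    for sp, sp_seed in zip(cfg.species, prep_seed.spawn(len(cfg.species))):
        niche = TrueNiche(tuple(sp.niche_center), tuple(sp.niche_widths))
        truth = make_species(latent, niche, name=f"truth_{sp.name}")
        species[sp.name] = _prepare_species(truth, sp, cfg, grid, valid_mask, sp_seed)

    # --- PCA ---------------------------------------------------------------
    pca = fit_pca(env)
    n_comp = min(cfg.n_components, env.n_layers)
    pc_present = transform(env, pca, n_comp)

    # --- models ------------------------------------------------------------
    results: dict = {
        "seed": seed,
        "pca": {
            "variance_fraction": pca.variance_fraction.tolist(),
            "n_components": n_comp,
            "components_for_9999": select_components(pca, 0.9999),
        },
        "species": {},
    }
    sp_seed_pairs = fit_seed.spawn(len(species))
    for (name, d), sp_seq in zip(species.items(), sp_seed_pairs):
        sp_fit_seed, sp_eval_seed = [
            int(s.generate_state(1, np.uint32)[0]) for s in sp_seq.spawn(2)
        ]
        models, reps = fit_replicates(
            d["calibration"],
            pc_present,
            n_replicates=cfg.n_replicates,
            seed=sp_fit_seed,
            background_n=cfg.background_n,
            spec_classes=cfg.feature_classes,
            beta=cfg.beta,
        )
        spec_thr, binary = threshold_E(reps.median_map, d["calibration"], cfg.E)
        proc = partial_roc(
            reps.median_map,
            d["evaluation"],
            E=cfg.E,
            n_iterations=cfg.proc_iterations,
            seed=sp_eval_seed,
        )
        binom = binomial_test(binary, d["independent"])
        d.update(models=models, replicates=reps, threshold=spec_thr, binary=binary)
        # ground truth is known on the synthetic world: score niche recovery
        rho = float(
            spearmanr(
                reps.median_map.values[valid_mask], d["truth"].values[valid_mask]
            ).statistic
        )
        results["species"][name] = {
            "cascade": d["cascade"],
            "recovery_spearman": rho,
            "tau": spec_thr.tau,
            "omission": spec_thr.omission,
            "proc": proc.summary(),
            "binomial": {
                "n": binom.n,
                "s": binom.s,
                "p": binom.p,
                "p_value": binom.p_value,
                "pct_predicted": 100.0 * binom.s / binom.n,
            },
        }

    # --- futures -----------------------------------------------------------
    if cfg.run_futures:
        scen = ScenarioSpec(n_gcms=cfg.n_gcms)
        futures = make_future(
            latent, scen, seed=int(future_seed.generate_state(1, np.uint32)[0])
        )
        pc_futures = {tag: transform(stk, pca, n_comp) for tag, stk in futures.items()}
        for name, d in species.items():
            sp_res = results["species"][name]
            sp_res["future"] = {}
            d["ensembles"] = {}
            for rcp_id, _ in scen.rcp_shifts:
                for period_id, _ in scen.periods:
                    gcm_medians = []
                    for gcm_id in scen.gcm_ids:
                        preds = [
                            predict(m, pc_futures[(gcm_id, rcp_id, period_id)])
                            for m in d["models"]
                        ]
                        gcm_medians.append(median_of(preds))
                    ens = ensemble_future(
                        gcm_medians, d["threshold"].tau, rcp=rcp_id, period=period_id
                    )
                    per_gcm_bin = [
                        apply_threshold(m, d["threshold"].tau) for m in gcm_medians
                    ]
                    stab = stability_map(d["binary"], per_gcm_bin, ens.binary)
                    rel, tot = area_change(d["binary"], ens.binary)
                    d["ensembles"][(rcp_id, period_id)] = (ens, stab)
                    sp_res["future"][f"{rcp_id}_{period_id}"] = {
                        "area_change_relative_pct": rel,
                        "area_change_of_total_pct": tot,
                        "stability_counts": stab.counts,
                    }

    # --- overlap -----------------------------------------------------------
    if cfg.run_overlap and len(cfg.species) >= 2:
        a, b = cfg.species[0].name, cfg.species[1].name
        map_a = species[a]["replicates"].median_map
        map_b = species[b]["replicates"].median_map
        D, I = overlap_statistics(map_a, map_b)
        bg_seed_int = int(overlap_seed.generate_state(1, np.uint32)[0])
        background = sample_background(pc_present, None, cfg.background_n, seed=bg_seed_int)
        ov = {}
        for direction, (m1, m2, occ_other) in {
            f"{a}-vs-background({b})": (map_a, map_b, species[b]["calibration"]),
            f"{b}-vs-background({a})": (map_b, map_a, species[a]["calibration"]),
        }.items():
            res = background_similarity_test(
                m1,
                m2,
                None,
                n_points_b=len(occ_other),
                pc_stack=pc_present,
                background=background,
                n_replicates=cfg.overlap_replicates,
                seed=bg_seed_int,
                spec_classes=cfg.feature_classes,
                beta=cfg.beta,
                direction=direction,
            )
            ov[direction] = res.summary()
        results["overlap"] = {"D_observed": D, "I_observed": I, "tests": ov}

    # --- outputs -----------------------------------------------------------
    if outdir is not None:
        _write_outputs(Path(outdir), cfg, seed, species, results)
    return results


def _write_outputs(outdir: Path, cfg, seed, species, results) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, d in species.items():
        vio.write_raster(d["replicates"].median_map.layer, outdir / f"{name}_median.tif")
        vio.write_raster(d["replicates"].range_map, outdir / f"{name}_range.tif")
        vio.write_raster(d["binary"], outdir / f"{name}_binary.tif", dtype="uint8")
        vio.write_raster(d["truth"], outdir / f"{name}_truth.tif")
        for stage in ("thinned", "calibration", "evaluation", "independent"):
            vio.write_occurrences(d[stage], outdir / f"{name}_{stage}.csv")
        for (rcp, period), (ens, stab) in d.get("ensembles", {}).items():
            vio.write_raster(
                ens.ensemble_median.layer, outdir / f"{name}_{rcp}_{period}_median.tif"
            )
            vio.write_raster(
                ens.uncertainty_range, outdir / f"{name}_{rcp}_{period}_range.tif"
            )
            vio.write_raster(
                ens.binary, outdir / f"{name}_{rcp}_{period}_binary.tif", dtype="uint8"
            )
            vio.write_raster(
                stab.layer, outdir / f"{name}_{rcp}_{period}_stability.tif", dtype="uint8"
            )
    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    vio.write_manifest(
        outdir / "manifest.json",
        seed=seed,
        config=asdict(cfg),
        products=sorted(p.name for p in outdir.iterdir()),
    )
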