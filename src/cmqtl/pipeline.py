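"""Configuration and end-to-end orchestration.

`run_pipeline` executes simulate -> fit -> adjust -> rankZ -> kinship ->
scan -> peaks -> haplotype effects on a synthetic screen, writing each
stage's CSV artifact plus a manifest (config hash, seed, stage row counts)
so reruns with the same config are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dose_response, io, mapping, mixed_models, simulate, transforms

logger = logging.getLogger("cmqtl")


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected."""

    out_dir: str = "cmqtl_out"
    seed: int = 0
    # synthetic population
    n_individuals: int = 226
    n_chromosomes: int = 5
    markers_per_chromosome: int = 200
    chromosome_length_bp: int = 150_000_000
    recomb_rate_per_cm: float = 0.1
    # planted QTL
    qtl_marker: str = ""  # default: middle marker of chromosome 1
    qtl_trait: str = "log_EC50"
    qtl_h2: float = 0.25
    polygenic_h2: float = 0.15
    # dose-response fitting
    doses_um: tuple = (0.0, 0.01, 0.1, 0.75, 1.0, 1.25, 2.0, 5.0)
    log_transform: bool = False
    n_restarts: int = 5
    pool_replicates: bool = False
    # variance-component analysis
    run_vca: bool = False
    vca_factors: tuple = mixed_models.DEFAULT_VCA_FACTORS
    # mapping
    lod_threshold: float = 7.5
    peak_drop: float = 1.5
    fdr_q: float = 0.10
    run_fdr: bool = False
    n_perm: int = 100
    map_drp: str = "log_EC50"

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if not 0 <= self.qtl_h2 < 1 or not 0 <= self.polygenic_h2 < 1:
            raise ValueError("heritabilities must be in [0, 1)")
        if self.qtl_h2 + self.polygenic_h2 >= 1:
            raise ValueError("qtl_h2 + polygenic_h2 must be < 1")
        if self.lod_threshold <= 0 or self.peak_drop <= 0:
            raise ValueError("lod_threshold and peak_drop must be positive")
        if not 0 < self.fdr_q <= 1:
            raise ValueError("fdr_q must be in (0, 1]")
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")
        if self.run_fdr and self.n_perm == 0:
            raise ValueError("FDR stage requires n_perm > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("doses_um", "vca_factors"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full synthetic pipeline; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config.as_dict())
    head = {"config_hash": chash, "seed": config.seed}
    manifest = {"config": config.as_dict(), "config_hash": chash, "stages": {}}
    rng_seeds = np.random.SeedSequence(config.seed).spawn(3)

    # --- simulate
    mm = simulate.simulate_marker_map(
        config.n_chromosomes,
        config.markers_per_chromosome,
        config.chromosome_length_bp,
        seed=int(rng_seeds[0].generate_state(1)[0] % (2**31)),
    )
    _, gp = simulate.simulate_do_genoprobs(
        config.n_individuals,
        mm,
        config.recomb_rate_per_cm,
        seed=int(rng_seeds[1].generate_state(1)[0] % (2**31)),
    )
    qtl_marker = config.qtl_marker
    if not qtl_marker:
        idx = mm.chrom_index(mm.chromosomes[0])
        qtl_marker = mm.df["marker_id"].iloc[idx[idx.size // 2]]
    spec = simulate.QtlSpec(
        config.qtl_trait, qtl_marker, simulate.biallelic_effects(), config.qtl_h2
    )
    design = simulate.StudyDesign(doses_um=tuple(config.doses_um))
    screen = simulate.simulate_screen(
        gp,
        [spec],
        design,
        polygenic_h2=config.polygenic_h2,
        seed=int(rng_seeds[2].generate_state(1)[0] % (2**31)),
    )
    io.write_csv(screen.well_table, out / "well_table.csv", head)
    io.write_csv(screen.truth, out / "ground_truth.csv", head)
    io.save_genoprobs_hdf5(gp, out / "genoprobs.h5")
    manifest["stages"]["simulate"] = {
        "wells": len(screen.well_table),
        "qtl_marker": str(qtl_marker),
    }
    logger.info("simulated %d wells", len(screen.well_table))

    # --- optional VCA
    if config.run_vca:
        vca = mixed_models.decompose_feature_variance(
            screen.well_table, config.vca_factors
        )
        io.write_csv(vca, out / "vca.csv", head)
        manifest["stages"]["vca"] = {"rows": len(vca)}

    # --- dose-response fits
    drp = dose_response.fit_drp_table(
        screen.well_table,
        log_transform=config.log_transform,
        pool_replicates=config.pool_replicates,
        n_restarts=config.n_restarts,
        seed=config.seed,
    )
    io.write_csv(drp, out / "drp_table.csv", head)
    n_fail = int((~drp["converged"]).sum())
    manifest["stages"]["fit"] = {"rows": len(drp), "nonconverged": n_fail}
    logger.info("fit DRPs: %d rows, %d non-converged", len(drp), n_fail)

    # --- batch adjust + rankZ
    adjusted = mixed_models.blup_adjust(drp, drps=(config.map_drp,))
    io.write_csv(adjusted, out / "adjusted_phenotypes.csv", head)
    wide = adjusted[adjusted["drp"] == config.map_drp].pivot_table(
        index="individual_id", columns="feature", values="value"
    )
    wide = wide.reindex(gp.individual_ids)
    normalized = transforms.rank_z_table(wide)
    io.write_csv(normalized.reset_index(), out / "normalized_phenotypes.csv", head)
    manifest["stages"]["adjust"] = {"individuals": int(wide.notna().any(axis=1).sum())}

    # --- mapping
    kinship = mapping.calc_kinship(gp, loco=True)
    covariates = pd.DataFrame(
        {
            "sex": [design.sex_of(i) for i in range(gp.n_individuals)],
            "generation": [design.generation_of(i) for i in range(gp.n_individuals)],
        }
    )
    scan = mapping.genome_scan(gp, normalized, covariates, kinship)
    scan_df = scan.lod.reset_index(names="marker_id").merge(
        mm.df[["marker_id", "chromosome", "position_bp"]], on="marker_id"
    )
    io.write_csv(scan_df, out / "scan.csv", head)
    peaks = mapping.find_peaks(scan, config.lod_threshold, config.peak_drop)
    io.write_csv(peaks, out / "peaks.csv", head)
    manifest["stages"]["scan"] = {
        "markers": mm.n_markers,
        "max_lod": scan.max_lod(),
        "peaks": len(peaks),
    }

    # --- haplotype effects at each peak
    eff_rows = []
    for pk in peaks.itertuples(index=False):
        hev = mapping.haplotype_blup_effects(
            gp, pk.marker_id, normalized[pk.trait], covariates, kinship, trait=pk.trait
        )
        eff_rows.append(
            {"trait": pk.trait, "marker_id": pk.marker_id, **hev.as_series().to_dict()}
        )
    effects = pd.DataFrame(eff_rows)
    io.write_csv(effects, out / "effects.csv", head)

    # --- permutations / FDR
    if config.run_fdr:
        trait0 = normalized.columns[0]
        null = mapping.permutation_null(
            gp, normalized[trait0], covariates, kinship, config.n_perm, config.seed
        )
        io.write_csv(
            pd.DataFrame({"max_lod": null.max_lods}), out / "permutation_null.csv", head
        )
        observed = np.array([scan.max_lod(t) for t in scan.traits])
        thr, flags = mapping.fdr_threshold(null, observed, config.fdr_q)
        io.write_csv(
            pd.DataFrame(
                {"trait": scan.traits, "max_lod": observed, "discovery": flags}
            ),
            out / "discoveries.csv",
            head,
        )
        manifest["stages"]["fdr"] = {"threshold": thr, "discoveries": int(flags.sum())}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
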