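"""End-to-end experiment orchestration and power / true-discovery-rate
evaluation.

A run simulates a landscape under one demographic scenario (range expansion
from one refugium, 1R, or two refugia, 2R), masks coordinates, trains the
origin predictor, imputes the environment at predicted coordinates, and
compares three analysis schemes:

* ``regular``          - training-set individuals only, true environments;
* ``geaplus``          - training set (true env) plus the prediction set
                         with environments imputed at predicted coordinates;
* ``perfect_geaplus``  - every sampled individual with its true environment
                         (the no-imputation-error upper bound; no predictor
                         is trained for it).

Power = N_true / N_segQTL and TDR = N_true / N_sigSNPs at the adjusted-p
significance cutoff; TDR is missing (NaN), not 0, when nothing is
significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .env import EnvRaster, make_raster
from .io import RunConfig
from .landscape import Landscape, build_landscape, generate_site_coords, nearest_site
from .origins import accuracy_metrics, make_mask, predict_origins, train_predictor
from .simulate import PROFILES, SimResult, maf_filter, simulate
from .scan import (
    ScanResult,
    cluster_groups,
    group_freqs,
    individual_lrt_scan,
    ld_prune,
    lm_lrt_scan,
    rda_scan,
    structure_covariates,
)

logger = logging.getLogger(__name__)

POPULATION_METHODS = ("LM_naive", "LM_P", "LM_RR", "LM_PRR", "RDA_simple", "RDA_partial")
ALL_METHODS = POPULATION_METHODS + ("IND_LRT",)
SCHEMES = ("regular", "geaplus", "perfect_geaplus")


@dataclass(frozen=True)
class Scheme:
    """Sample-selection and environment-source rule for one analysis arm."""

    name: str

    def __post_init__(self):
        if self.name not in SCHEMES:
            raise ValueError(f"unknown scheme {self.name!r}")

    @property
    def uses_predictor(self) -> bool:
        return self.name == "geaplus"


@dataclass
class EvalRow:
    scheme: str
    method: str
    n_true: int
    n_seg_qtl: int
    n_sig: int
    alpha: float
    power: float
    tdr: float


def compute_power_tdr(scan: ScanResult, qtl_ids, seg_qtl_ids, alpha: float = 0.005) -> EvalRow:
    """Power and TDR of one scan at significance level ``alpha`` on the
    inflation-adjusted p-values."""
    qtl_ids = set(np.asarray(qtl_ids).tolist())
    seg = set(np.asarray(seg_qtl_ids).tolist())
    if not seg <= qtl_ids:
        raise ValueError("segregating QTL set must be a subset of the QTL set")
    ids = scan.locus_ids if scan.locus_ids is not None else np.arange(scan.p_adj.size)
    sig = set(np.asarray(ids)[scan.p_adj <= alpha].tolist())
    n_true = len(sig & seg)
    n_sig = len(sig)
    if len(seg) == 0:
        logger.warning("no segregating QTLs: power undefined")
        power = np.nan
    else:
        power = n_true / len(seg)
    tdr = n_true / n_sig if n_sig > 0 else np.nan
    return EvalRow("", scan.method, n_true, len(seg), n_sig, alpha, power, tdr)


def make_study_landscape(config: RunConfig, raster: EnvRaster, n_sites: int, k_site: int, seed: int) -> Landscape:
    """Random collection sites thinned to the minimum spacing, truncated to
    ``n_sites``, with the stepping-stone migration graph."""
    lp = config.landscape
    lon_min, lon_max, lat_min, lat_max = config.raster.extent
    d = lp.site_inset_deg
    site_extent = (lon_min + d, lon_max - d, lat_min + d, lat_max - d)
    coords = generate_site_coords(lp.n_candidate_sites, site_extent, seed=seed)
    land = build_landscape(
        coords, lp.min_spacing_km, k_site, raster, m0_km=lp.m0_km, m_total=lp.m_total
    )
    if len(land) < n_sites:
        raise ValueError(f"only {len(land)} sites survive thinning; requested {n_sites}")
    if len(land) > n_sites:
        sites = land.sites[:n_sites]
        sub_coords = np.array([[s.lon, s.lat] for s in sites])
        land = build_landscape(
            sub_coords, lp.min_spacing_km, k_site, raster, m0_km=lp.m0_km, m_total=lp.m_total
        )
    return land


def refugia_for_scenario(config: RunConfig, land: Landscape) -> tuple[int, ...]:
    coords = config.landscape.refugium_coords
    n_ref = 1 if config.scenario == "1R" else 2
    if len(coords) < n_ref:
        raise ValueError(f"scenario {config.scenario} needs {n_ref} refugium coordinates")
    ids = []
    for lon, lat in coords[:n_ref]:
        rid = nearest_site(land, lon, lat)
        if rid not in ids:
            ids.append(rid)
    return tuple(ids)


@dataclass
class RunArtifacts:
    """Everything produced by one (sim seed x mask replicate) run."""

    sim: SimResult
    panel_dosages: np.ndarray  # post-sim MAF-filtered
    locus_table: pd.DataFrame
    mask: object
    pred_coords: pd.DataFrame | None  # id, pred_lon, pred_lat, type
    origin_metrics: pd.DataFrame | None
    env_true: pd.Series  # per individual id
    env_imputed: pd.Series | None  # per prediction id (NaN = missing)


@dataclass
class ExperimentResult:
    results: pd.DataFrame
    origin_metrics: pd.DataFrame
    env_accuracy: pd.DataFrame
    manifest: dict
    artifacts: list[RunArtifacts] = field(default_factory=list)


def _scheme_inputs(scheme: Scheme, art: RunArtifacts, sample_table: pd.DataFrame):
    """Assemble (ids, dosages, coords, env) for one scheme."""
    st = sample_table.set_index("id")
    ids_all = list(sample_table["id"])
    pos = {i: k for k, i in enumerate(ids_all)}
    if scheme.name == "regular":
        ids = list(art.mask.train_ids)
        coords = st.loc[ids, ["lon", "lat"]].to_numpy()
        env = art.env_true.loc[ids].to_numpy()
    elif scheme.name == "perfect_geaplus":
        # scheme contract: predictions are never consulted here
        ids = ids_all
        coords = st.loc[ids, ["lon", "lat"]].to_numpy()
        env = art.env_true.loc[ids].to_numpy()
    else:  # geaplus
        if art.pred_coords is None:
            raise ValueError("geaplus scheme requires origin predictions")
        pred = art.pred_coords.set_index("id")
        keep_pred = art.env_imputed.dropna()
        ids = list(art.mask.train_ids) + list(keep_pred.index)
        coords = np.vstack(
            [
                st.loc[art.mask.train_ids, ["lon", "lat"]].to_numpy(),
                pred.loc[keep_pred.index, ["pred_lon", "pred_lat"]].to_numpy(),
            ]
        )
        env = np.concatenate([art.env_true.loc[art.mask.train_ids].to_numpy(), keep_pred.to_numpy()])
    rows = np.array([pos[i] for i in ids])
    return ids, art.panel_dosages[rows], coords, env


def run_scheme_scans(
    dosages: np.ndarray,
    coords: np.ndarray,
    env: np.ndarray,
    locus_ids: np.ndarray,
    is_qtl: np.ndarray,
    config: RunConfig,
) -> tuple[list[EvalRow], dict[str, ScanResult]]:
    sp = config.scan
    G, kept = maf_filter(dosages, sp.maf_pre_scan)
    locus_ids = locus_ids[kept]
    qtl_mask = is_qtl[kept]
    qtl_ids = locus_ids[qtl_mask]
    seg_qtl = qtl_ids  # segregating = QTLs passing the analysis MAF filter
    rows: list[EvalRow] = []
    scans: dict[str, ScanResult] = {}

    pop_methods = [m for m in config.scan.methods if m in POPULATION_METHODS]
    if pop_methods:
        groups = cluster_groups(coords, env, sp.d_thresh_km, sp.sd_frac)
        F = group_freqs(G, groups)
        env_g = groups.mean_env
        needs_struct = any(m != "LM_naive" for m in pop_methods)
        struct = None
        if needs_struct:
            pruned = ld_prune(F * 2.0, sp.r2_prune)
            struct = structure_covariates(F, env_g, k_pc=sp.k_pc, ridge_idx=pruned)
        for m in pop_methods:
            if m.startswith("RDA"):
                res = rda_scan(F, env_g, variant=m.split("_")[1], structure=struct, k_pc=sp.k_pc)
            else:
                cov = {"LM_naive": None, "LM_P": "pc", "LM_RR": "ridge", "LM_PRR": "both"}[m]
                res = lm_lrt_scan(F, env_g, covariates=cov, structure=struct, k_pc=sp.k_pc)
            res.locus_ids = locus_ids
            scans[m] = res
            rows.append(compute_power_tdr(res, qtl_ids, seg_qtl, sp.alpha))
    if "IND_LRT" in config.scan.methods:
        pruned = ld_prune(G, sp.r2_prune)
        struct_i = structure_covariates(G, env, k_pc=sp.k_pc, ridge_idx=pruned)
        res = individual_lrt_scan(G, env, structure=struct_i, k_pc=sp.k_pc)
        res.locus_ids = locus_ids
        scans["IND_LRT"] = res
        rows.append(compute_power_tdr(res, qtl_ids, seg_qtl, sp.alpha))
    return rows, scans


def run_single(config: RunConfig, raster: EnvRaster, land: Landscape, sim_seed: int, mask_seed: int,
               keep_artifacts: bool = False):
    """One sim + mask replicate through every scheme; returns tidy rows,
    origin metrics, env-imputation accuracy and (optionally) artifacts."""
    profile = PROFILES[config.profile]
    overrides = dict(config.sim_overrides)
    overrides.update(refugia=refugia_for_scenario(config, land), seed=sim_seed)
    sim_cfg = profile(**overrides)
    sim = simulate(land, sim_cfg)

    G, kept = maf_filter(sim.genotypes, config.scan.maf_post_sim)
    locus_table = sim.locus_table.iloc[kept].reset_index(drop=True)
    locus_ids = kept
    is_qtl = locus_table["is_qtl"].to_numpy()
    st = sim.sample_table
    env_true = pd.Series(
        raster.extract(st["lon"].to_numpy(), st["lat"].to_numpy()), index=st["id"]
    )

    mask = make_mask(st, config.mask.site_frac, config.mask.n_train_per_site, seed=mask_seed)

    pred_df = None
    origin_metrics = None
    env_imputed = None
    needs_pred = "geaplus" in config.schemes or not config.schemes
    if needs_pred:
        idx = {i: k for k, i in enumerate(st["id"])}
        train_rows = np.array([idx[i] for i in mask.train_ids])
        pred_rows = np.array([idx[i] for i in mask.predict_ids])
        pp = config.predictor
        ens = train_predictor(
            G[train_rows],
            st.loc[st["id"].isin(mask.train_ids)].set_index("id").loc[mask.train_ids, ["lon", "lat"]].to_numpy(),
            qtl_indices=np.flatnonzero(is_qtl),
            n_folds=pp.n_folds,
            n_replicates=pp.n_replicates,
            seed=mask_seed,
            hidden_layer_sizes=tuple(pp.hidden_layer_sizes),
            dropout=pp.dropout,
            learning_rate=pp.learning_rate,
            max_epochs=pp.max_epochs,
            patience=pp.patience,
            batch_size=pp.batch_size,
        )
        pred = predict_origins(ens, G[pred_rows], ids=mask.predict_ids)
        pred_df = pd.DataFrame(
            {
                "id": mask.predict_ids,
                "pred_lon": pred.pred[:, 0],
                "pred_lat": pred.pred[:, 1],
                "type": mask.type_labels.loc[mask.predict_ids].to_numpy(),
            }
        )
        true_xy = st.set_index("id").loc[mask.predict_ids, ["lon", "lat"]].to_numpy()
        origin_metrics = accuracy_metrics(pred.pred, true_xy, mask.type_labels.loc[mask.predict_ids])
        env_imputed = pd.Series(
            raster.extract(pred.pred[:, 0], pred.pred[:, 1]), index=pd.Index(mask.predict_ids, name="id")
        )

    art = RunArtifacts(
        sim=sim,
        panel_dosages=G,
        locus_table=locus_table,
        mask=mask,
        pred_coords=pred_df,
        origin_metrics=origin_metrics,
        env_true=env_true,
        env_imputed=env_imputed,
    )

    rows_out = []
    scans_out = {}
    for name in config.schemes:
        scheme = Scheme(name)
        ids, dosages, coords, env = _scheme_inputs(scheme, art, st)
        rows, scans = run_scheme_scans(dosages, coords, env, locus_ids, is_qtl, config)
        for r in rows:
            r.scheme = name
        rows_out.extend(rows)
        scans_out[name] = scans

    env_rows = []
    if env_imputed is not None:
        for t in ("Type1", "Type2"):
            ids_t = mask.type_labels.index[mask.type_labels == t]
            true_e = env_true.loc[ids_t]
            imp_e = env_imputed.loc[ids_t]
            ok = imp_e.notna()
            if ok.sum() >= 2 and true_e[ok].std() > 0:
                r2 = float(np.corrcoef(true_e[ok], imp_e[ok])[0, 1] ** 2)
            else:
                r2 = np.nan
            env_rows.append({"type": t, "n": int(ok.sum()), "n_missing": int((~ok).sum()), "r2_env": r2})
    env_acc = pd.DataFrame(env_rows)

    return rows_out, origin_metrics, env_acc, (art if keep_artifacts else None), scans_out


def run_experiment(config: RunConfig, keep_artifacts: bool = False) -> ExperimentResult:
    """Full factorial experiment: sim seeds x mask replicates x schemes x
    methods, on a shared landscape/raster (paired-replicate design)."""
    raster_seed = config.seeds[0] + 10_000
    raster = make_raster(
        config.raster.extent,
        config.raster.resolution,
        gradient=tuple(config.raster.gradient),
        n_bumps=config.raster.n_bumps,
        bump_amplitude=config.raster.bump_amplitude,
        bump_scale_deg=config.raster.bump_scale_deg,
        seed=raster_seed,
    )
    profile = PROFILES[config.profile]
    sim_cfg_probe = profile(**{**config.sim_overrides, "seed": 0})
    land_seed = config.seeds[0] + 20_000
    land = make_study_landscape(config, raster, sim_cfg_probe.n_sites, sim_cfg_probe.K_site, land_seed)

    all_rows = []
    om_frames = []
    env_frames = []
    artifacts = []
    for sim_seed in config.seeds:
        for mrep in range(config.n_mask_replicates):
            mask_seed = sim_seed * 100 + mrep + 1
            rows, om, env_acc, art, _ = run_single(
                config, raster, land, sim_seed, mask_seed, keep_artifacts=keep_artifacts
            )
            for r in rows:
                all_rows.append(
                    {
                        "scenario": config.scenario,
                        "sim_seed": sim_seed,
                        "mask_rep": mrep,
                        "scheme": r.scheme,
                        "method": r.method,
                        "n_true": r.n_true,
                        "n_seg_qtl": r.n_seg_qtl,
                        "n_sig": r.n_sig,
                        "alpha": r.alpha,
                        "power": r.power,
                        "tdr": r.tdr,
                    }
                )
            if om is not None:
                om = om.reset_index()
                om["scenario"], om["sim_seed"], om["mask_rep"] = config.scenario, sim_seed, mrep
                om_frames.append(om)
            if not env_acc.empty:
                env_acc = env_acc.copy()
                env_acc["scenario"], env_acc["sim_seed"], env_acc["mask_rep"] = config.scenario, sim_seed, mrep
                env_frames.append(env_acc)
            if art is not None:
                artifacts.append(art)

    manifest = {
        "scenario": config.scenario,
        "profile": config.profile,
        "sim_overrides": dict(config.sim_overrides),
        "seeds": list(config.seeds),
        "n_mask_replicates": config.n_mask_replicates,
        "raster_seed": raster_seed,
        "landscape_seed": land_seed,
        "n_sites": len(land),
        "total_carrying_capacity": land.total_carrying_capacity(),
        "schemes": list(config.schemes),
        "methods": list(config.scan.methods),
        "alpha": config.scan.alpha,
    }
    return ExperimentResult(
        results=pd.DataFrame(all_rows),
        origin_metrics=pd.concat(om_frames, ignore_index=True) if om_frames else pd.DataFrame(),
        env_accuracy=pd.concat(env_frames, ignore_index=True) if env_frames else pd.DataFrame(),
        manifest=manifest,
        artifacts=artifacts,
    )
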