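"""End-to-end pipeline orchestration.

Ties the stages together in dependency order (simulate/read -> morphometry
-> trait models -> P matrices -> PLS), with a single root seed split into
stage-keyed streams so toggling one stage cannot perturb another, and a
manifest recording the configuration, seeds and output hashes so that a
rerun with the same configuration is byte-identical for the deterministic
stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .mixed_models import ChainSettings, RandomTerm, fit_binary, fit_gaussian, Prior
from .morphometry import (
    disparity_test,
    gpa,
    head_shape_terms,
    polygon_area,
    standard_length,
    trajectory_analysis,
)
from .growth_behaviour import (
    fit_growth,
    fit_yolk,
    onset_of_feeding,
    probit_observed_mean,
    repeatability,
)
from .pmatrix import (
    angle_draws,
    fit_pmatrix,
    hpd_interval,
    krzanowski_H,
    posterior_mode,
    project_ellipsoids,
    random_angle_null,
    subspace_null,
    variance_table,
)
from .pls import compare_pls, pls_leave_one_out, pls_permutation, two_block_pls
from .simulate import (
    TRAITS,
    SimDesign,
    SimParams,
    default_params,
    generate_design,
    params_to_yaml,
    simulate_behaviour,
    simulate_landmarks,
    simulate_onset,
    simulate_traits,
    traits_wide,
)
from .tps import read_tps, write_tps

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "morpho", "fit", "pmatrix", "pls")


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Either the simulation block is active (``simulate`` in stages, seed
    mandatory) or input paths to a trait table and landmarks must be
    given."""

    outdir: str = "results"
    seed: int | None = None
    stages: tuple[str, ...] = STAGES
    design: SimDesign = field(default_factory=SimDesign)
    params: SimParams | None = None
    traits_csv: str | None = None
    behaviour_csv: str | None = None
    onset_csv: str | None = None
    landmarks_tps: str | None = None
    iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 20
    n_perm: int = 999
    k_subspace: int = 3
    n_angle_rep: int = 500
    n_null_rep: int = 200

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        simulating = "simulate" in self.stages
        if simulating and self.seed is None:
            raise ValueError("a seed is mandatory when simulating")
        if not simulating and self.traits_csv is None and not self.stages:
            raise ValueError("either input paths or a simulation block is required")

    def chain(self, seed: int) -> ChainSettings:
        return ChainSettings(self.iterations, self.burn_in, self.thin, seed=seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "design" in doc:
            d = doc["design"]
            d["cross_types"] = tuple(d.get("cross_types", ("PL", "SB", "F1")))
            d["stages"] = tuple(d.get("stages", (445.0, 530.0, 840.0, 1100.0)))
            doc["design"] = SimDesign(**d)
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)


def _stage_seed(root: int, stage: str) -> int:
    """Stage-keyed integer seed derived from the root seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=root, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise RuntimeError(
            f"missing upstream output {path.name!r}; run the {produced_by!r} "
            "stage first or point the configuration at existing inputs"
        )
    return path


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages and write results plus a manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    seeds = {s: _stage_seed(config.seed or 0, s) for s in STAGES}

    def save_df(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
        return p

    # ---------------------------------------------------------------- simulate
    if "simulate" in config.stages:
        design = config.design
        params = config.params or default_params(design)
        rng_seeds = np.random.SeedSequence(
            entropy=seeds["simulate"]).generate_state(4)
        roster = generate_design(design, seed=int(rng_seeds[0] % 2**31))
        traits = simulate_traits(roster, params, design, seed=int(rng_seeds[0] % 2**31))
        behaviour, truth = simulate_behaviour(roster, params, design, seed=int(rng_seeds[1] % 2**31))
        onset_records = simulate_onset(roster, seed=int(rng_seeds[2] % 2**31))
        configs, nuisance = simulate_landmarks(
            roster, traits, params, design, seed=int(rng_seeds[3] % 2**31)
        )
        save_df(traits, "traits.csv")
        save_df(behaviour, "behaviour.csv")
        save_df(onset_records, "onset_records.csv")
        save_df(nuisance, "landmark_nuisance.csv")
        tps_path = out / "landmarks.tps"
        write_tps(configs, tps_path, aux_names=("notochord",), scale=0.02)
        written.append(tps_path)
        params_to_yaml(params, design, out / "truth.yaml")
        written.append(out / "truth.yaml")

    def load_traits() -> pd.DataFrame:
        if config.traits_csv:
            return pd.read_csv(config.traits_csv)
        return pd.read_csv(_require(out / "traits.csv", "simulate"))

    def load_landmarks():
        path = config.landmarks_tps or _require(out / "landmarks.tps", "simulate")
        return read_tps(path, curve_names=("head", "yolk"), aux_names=("notochord",))

    # ------------------------------------------------------------------ morpho
    if "morpho" in config.stages:
        traits = load_traits()
        configs = load_landmarks()
        meta_tr = traits[["id", "cross", "family"]].drop_duplicates().set_index("id")
        res = gpa(configs)
        # per-specimen measurements from the synthetic digitization
        mrows = []
        for cfg in configs:
            row = {"id": cfg.specimen_id, "stage": cfg.stage,
                   "centroid_size": None, "sl": None, "yolk_area": None}
            try:
                row["sl"] = standard_length(cfg)
            except KeyError:
                pass
            if "yolk" in cfg.curves:
                row["yolk_area"] = polygon_area(cfg.curves["yolk"])
            mrows.append(row)
        measures = pd.DataFrame(mrows)
        measures["centroid_size"] = res.centroid_sizes
        save_df(measures, "morpho_measures.csv")

        flat = res.flat
        ids = np.asarray(res.specimen_ids)
        stage_arr = np.asarray(res.stages, float)
        meta = pd.DataFrame(
            {
                "id": ids,
                "size": res.centroid_sizes,
                "cross": meta_tr.loc[ids, "cross"].to_numpy(),
                "family": meta_tr.loc[ids, "family"].to_numpy(),
                "age": stage_arr,
            }
        )
        wide_cols = {"id": ids, "stage": stage_arr}
        for j in range(flat.shape[1] // 2):
            wide_cols[f"x{j + 1}"] = flat[:, 2 * j]
            wide_cols[f"y{j + 1}"] = flat[:, 2 * j + 1]
        save_df(pd.DataFrame(wide_cols), "aligned_shapes.csv")

        rrpp = rrpp_table = None
        from .morphometry import rrpp_regression

        rrpp_table = rrpp_regression(
            flat, head_shape_terms(meta), n_perm=config.n_perm, seed=seeds["morpho"]
        )
        save_df(rrpp_table, "rrpp.csv")

        third = np.sort(np.unique(stage_arr))[2]
        m3 = stage_arr == third
        disp = disparity_test(
            flat[m3], meta.loc[m3, "cross"].to_numpy(),
            n_perm=config.n_perm, seed=seeds["morpho"] + 1,
        )
        save_df(disp, "disparity.csv")
        traj = trajectory_analysis(
            flat, meta["cross"].to_numpy(), stage_arr,
            n_perm=config.n_perm, seed=seeds["morpho"] + 2, subjects=ids,
        )
        save_df(traj, "trajectories.csv")

    # --------------------------------------------------------------------- fit
    if "fit" in config.stages:
        traits = load_traits()
        growth_df = traits[traits["trait"] == "log_sl"].rename(
            columns={"stage": "age", "value": "log_length"}
        )
        growth_df["age"] = growth_df["age"].astype(float)
        gfit = fit_growth(growth_df, chain=config.chain(seeds["fit"]))
        save_df(gfit.table, "growth.csv")
        save_df(gfit.variance_components, "growth_variance.csv")

        # yolk model on areas measured from the digitization
        measures = pd.read_csv(_require(out / "morpho_measures.csv", "morpho"))
        stages_sorted = np.sort(measures["stage"].unique())
        d1 = measures[measures["stage"] == stages_sorted[0]].set_index("id")
        d2 = measures[measures["stage"] == stages_sorted[1]].set_index("id")
        meta_tr = traits[["id", "cross", "family"]].drop_duplicates().set_index("id")
        ids = d1.index.intersection(d2.index)
        ydf = pd.DataFrame(
            {
                "id": ids,
                "cross": meta_tr.loc[ids, "cross"].to_numpy(),
                "family": meta_tr.loc[ids, "family"].to_numpy(),
                "yolk_d1": d1.loc[ids, "yolk_area"].to_numpy(float),
                "yolk_d2": d2.loc[ids, "yolk_area"].to_numpy(float),
                "logl_d1": np.log10(d1.loc[ids, "sl"].to_numpy(float)),
                "logl_d2": np.log10(d2.loc[ids, "sl"].to_numpy(float)),
            }
        )
        save_df(fit_yolk(ydf, chain=config.chain(seeds["fit"] + 1)), "yolk.csv")

        # onset of exogeneous feeding
        if config.onset_csv:
            onset_records = pd.read_csv(config.onset_csv)
        else:
            onset_records = pd.read_csv(_require(out / "onset_records.csv", "simulate"))
        onsets, onset_summary = onset_of_feeding(
            onset_records, chain=config.chain(seeds["fit"] + 2)
        )
        save_df(onsets, "onset_individual.csv")
        save_df(onset_summary, "onset_summary.csv")

        # behavioural repeatability per cross
        if config.behaviour_csv:
            behaviour = pd.read_csv(config.behaviour_csv)
        else:
            behaviour = pd.read_csv(_require(out / "behaviour.csv", "simulate"))
        rrows = []
        for ci, cross in enumerate(pd.unique(behaviour["cross"])):
            sub = behaviour[behaviour["cross"] == cross]
            n = len(sub)
            chain = config.chain(seeds["fit"] + 10 + ci)
            bs = fit_binary(
                sub["fed"].to_numpy(), np.ones((n, 1)),
                random=[RandomTerm("individual", sub["id"].to_numpy())],
                chain=chain, fixed_names=["intercept"],
            )
            est = repeatability(bs, "binary", trait="feeding propensity", cross=cross)
            prop = probit_observed_mean(
                bs.fixed_draws("intercept"), bs.G["individual"][:, 0, 0], 1.0
            )
            rrows.append(
                {
                    "trait": "feeding propensity", "cross": cross,
                    "latent_R_mode": est.latent_mode,
                    "latent_R_lo": est.latent_lo, "latent_R_hi": est.latent_hi,
                    "data_R_mode": est.data_mode,
                    "data_R_lo": est.data_lo, "data_R_hi": est.data_hi,
                    "observed_mean_mode": posterior_mode(prop),
                }
            )
            cs = fit_gaussian(
                np.log1p(sub["attacks"].to_numpy(float)), np.ones((n, 1)),
                random=[RandomTerm("individual", sub["id"].to_numpy())],
                prior_R=Prior(1.0, 0.002), chain=chain, fixed_names=["intercept"],
            )
            est_c = repeatability(cs, "gaussian", trait="attacks", cross=cross)
            rrows.append(
                {
                    "trait": "attacks", "cross": cross,
                    "latent_R_mode": est_c.latent_mode,
                    "latent_R_lo": est_c.latent_lo, "latent_R_hi": est_c.latent_hi,
                    "data_R_mode": None, "data_R_lo": None, "data_R_hi": None,
                    "observed_mean_mode": None,
                }
            )
        save_df(pd.DataFrame(rrows), "repeatability.csv")

    # ----------------------------------------------------------------- pmatrix
    if "pmatrix" in config.stages:
        traits = load_traits()
        wide = traits_wide(traits)
        crosses = list(pd.unique(traits["cross"]))
        draws = {}
        resid_data = {}
        for ci, cross in enumerate(crosses):
            sub = wide[wide["cross"] == cross].reset_index(drop=True)
            draws[cross] = fit_pmatrix(
                sub, list(TRAITS), cross=cross,
                chain=config.chain(seeds["pmatrix"] + ci),
            )
            # family-adjusted, mean-standardized residuals for resampling nulls
            x = sub[list(TRAITS)].to_numpy(float)
            x = x / x.mean(axis=0)
            fam_means = pd.DataFrame(x).groupby(sub["family"].to_numpy()).transform("mean")
            resid_data[cross] = x - fam_means.to_numpy() + x.mean(axis=0)

        srows = []
        for cross in crosses:
            s = draws[cross].summary()
            srows.append(
                {
                    "cross": cross, "statistic": "V_tot", "mode": s.vtot_mode,
                    "lo": s.vtot_cri[0], "hi": s.vtot_cri[1],
                }
            )
            srows.append(
                {
                    "cross": cross, "statistic": "Omega", "mode": s.omega_mode,
                    "lo": s.omega_cri[0], "hi": s.omega_cri[1],
                }
            )
        save_df(pd.DataFrame(srows), "pmatrix_summary.csv")
        save_df(variance_table(draws), "variance_table.csv")

        arows = []
        for i, g in enumerate(crosses):
            for h in crosses[i + 1:]:
                th = angle_draws(draws[g], draws[h])
                null = random_angle_null(
                    resid_data[g], resid_data[h],
                    n_rep=config.n_angle_rep, seed=seeds["pmatrix"] + 100 + i,
                )
                lo, hi = hpd_interval(th)
                arows.append(
                    {
                        "cross1": g, "cross2": h,
                        "theta_mode": posterior_mode(th),
                        "theta_lo": lo, "theta_hi": hi,
                        "null_lo": null["cri"][0], "null_hi": null["cri"][1],
                    }
                )
        save_df(pd.DataFrame(arows), "angles.csv")

        sub_res = krzanowski_H(draws, k=config.k_subspace)
        null_eigs = subspace_null(
            resid_data, k=config.k_subspace,
            n_rep=config.n_null_rep, seed=seeds["pmatrix"] + 200,
        )
        cris = sub_res.eigenvalue_cri()
        hrows = []
        for j in range(len(sub_res.eigenvalues)):
            nlo, nhi = np.percentile(null_eigs[:, j], [2.5, 97.5])
            hrows.append(
                {
                    "eigenvalue_rank": j + 1,
                    "observed": sub_res.eigenvalues[j],
                    "obs_lo": cris[j][0], "obs_hi": cris[j][1],
                    "null_lo": nlo, "null_hi": nhi,
                }
            )
        save_df(pd.DataFrame(hrows), "subspace.csv")

        ell = project_ellipsoids(draws, reference=crosses[0])
        with open(out / "ellipsoids.json", "w") as fh:
            json.dump(ell, fh, indent=1, sort_keys=True)
        written.append(out / "ellipsoids.json")

        prows = []
        for cross in crosses:
            d = draws[cross].draws
            for a in range(d.shape[1]):
                for b in range(a, d.shape[2]):
                    for s_i in range(0, d.shape[0], max(1, d.shape[0] // 200)):
                        prows.append(
                            {
                                "cross": cross, "draw": s_i,
                                "row_trait": TRAITS[a], "col_trait": TRAITS[b],
                                "value": d[s_i, a, b],
                            }
                        )
        save_df(pd.DataFrame(prows), "p_draws.csv")

    # --------------------------------------------------------------------- pls
    if "pls" in config.stages:
        traits = load_traits()
        wide = traits_wide(traits).set_index("id")
        shapes = pd.read_csv(_require(out / "aligned_shapes.csv", "morpho"))
        third = np.sort(shapes["stage"].unique())[2]
        s3 = shapes[shapes["stage"] == third].set_index("id")
        crosses = list(pd.unique(traits["cross"]))
        results = {}
        lrows = {t: {} for t in TRAITS}
        sum_rows = []
        for ci, cross in enumerate(crosses):
            ids = wide.index[wide["cross"] == cross].intersection(s3.index)
            x = wide.loc[ids, list(TRAITS)].to_numpy(float)
            x = x / x.mean(axis=0)
            y = s3.loc[ids].drop(columns=["stage"]).to_numpy(float)
            res = two_block_pls(x, y, label=cross)
            res = pls_permutation(res, x, y, n_perm=config.n_perm,
                                  seed=seeds["pls"] + ci)
            results[cross] = (res, x, y)
            for t, v in zip(TRAITS, res.loadings1):
                lrows[t][cross] = v
            sum_rows.append({"cross": cross, "r": res.r, "p": res.p, "Z": res.z})
        loadings = pd.DataFrame(
            [{"trait": t, **vals} for t, vals in lrows.items()]
        )
        save_df(loadings, "pls_loadings.csv")
        save_df(pd.DataFrame(sum_rows), "pls_summary.csv")
        crows = []
        for i, g in enumerate(crosses):
            for h in crosses[i + 1:]:
                z12, p12 = compare_pls(results[g][0], results[h][0])
                crows.append({"cross1": g, "cross2": h, "Z": z12, "p": p12})
        save_df(pd.DataFrame(crows), "pls_comparison.csv")
        loo = []
        for cross, (res, x, y) in results.items():
            d = pls_leave_one_out(x, y)
            d.insert(0, "cross", cross)
            loo.append(d)
        save_df(pd.concat(loo, ignore_index=True), "pls_loo.csv")

    # ---------------------------------------------------------------- manifest
    cfg_dict = asdict(config)
    cfg_dict["design"] = asdict(config.design)
    cfg_dict["params"] = None if config.params is None else "explicit"
    manifest = {
        "version": __version__,
        "config": _jsonable(cfg_dict),
        "stage_seeds": seeds,
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return float(obj)
    return obj
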