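"""End-to-end pipeline: simulate -> prep -> fit -> predict -> biodiversity ->
co-occurrence -> climate -> report, with a manifest of every written artifact."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from arcbio import __version__, biodiversity, climate, cooccurrence
from arcbio import occurrence_prep as prep
from arcbio import sdm_ensemble as sdm
from arcbio.cli_io.config import PipelineConfig
from arcbio.synthetic_data import build_scenario
from arcbio.synthetic_data.io import write_env_netcdf, write_occurrences_csv, write_raster_netcdf

log = logging.getLogger("arcbio.pipeline")

STAGES = ["simulate", "prep", "fit", "predict", "richness", "beta", "cooccur", "climate", "report"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Stateful pipeline over one configuration; stages populate ``self`` and
    register every output file in the manifest."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "config_hash": config.config_hash(),
            "config": config.model_dump(mode="json"),
            "seed": config.seed,
            "outputs": {},
            "counts": {},
        }

    # -- helpers ----------------------------------------------------------
    def _write_csv(self, df: pd.DataFrame, name: str) -> Path:
        path = self.out / name
        df.to_csv(path, index=False)
        self.manifest["outputs"][name] = _sha256(path)
        return path

    def _write_nc(self, arrays: dict, name: str, year_coord=None) -> Path:
        path = self.out / name
        write_raster_netcdf(
            {k: np.asarray(v, dtype=float) for k, v in arrays.items()},
            self.grid, path, year_coord=year_coord,
        )
        self.manifest["outputs"][name] = _sha256(path)
        return path

    # -- stages -----------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config
        self.scenario = build_scenario(
            seed=cfg.seed,
            extent=cfg.grid.extent,
            cell_size_deg=cfg.grid.cell_size_deg,
            years=cfg.scenario.years,
            n_regions=cfg.grid.n_regions,
            n_apex=cfg.scenario.n_apex,
            n_meso=cfg.scenario.n_meso,
            n_samples_per_year=cfg.scenario.n_samples_per_year,
        )
        self.grid = self.scenario.grid
        self.env = self.scenario.env
        env_path = self.out / "environment.nc"
        write_env_netcdf(self.env, env_path)
        self.manifest["outputs"]["environment.nc"] = _sha256(env_path)
        occ_path = self.out / "occurrences.csv"
        write_occurrences_csv(self.scenario.occurrences, occ_path)
        self.manifest["outputs"]["occurrences.csv"] = _sha256(occ_path)
        self.manifest["counts"]["occurrences_raw"] = int(len(self.scenario.occurrences))
        self.manifest["counts"]["species"] = len(self.scenario.species)

    def stage_prep(self) -> None:
        cfg = self.config
        cleaned = prep.clean_occurrences(self.scenario.occurrences, self.grid)
        thinned = prep.thin_occurrences(
            cleaned, cfg.prep.thin_km, n_reps=cfg.prep.thin_reps, seed=cfg.seed
        )
        self.presences = thinned
        self._write_csv(thinned, "occurrences_thinned.csv")
        report = prep.thinning_report(cleaned, thinned, cfg.prep.thin_km, cfg.prep.thin_reps, cfg.seed)
        (self.out / "thinning_report.json").write_text(json.dumps(report, indent=2))
        self.manifest["outputs"]["thinning_report.json"] = _sha256(self.out / "thinning_report.json")
        self.manifest["counts"]["occurrences_cleaned"] = int(len(cleaned))
        self.manifest["counts"]["occurrences_thinned"] = int(len(thinned))

    def stage_fit(self) -> None:
        cfg = self.config
        candidates = cfg.sdm.candidate_variables
        self.sdms: dict[str, sdm.SpeciesSDM] = {}
        self.selected_vars: dict[str, list[str]] = {}
        eval_rows = []
        importance_rows = []
        training_frames = []
        for sp in self.scenario.species:
            sid = sp.species_id
            pres = self.presences[self.presences["species_id"] == sid]
            if pres.empty:
                log.warning("no presences for %s after prep; skipped", sid)
                continue
            # round 1: buffered-random pseudo-absences on all candidates -> importance
            train1 = prep.build_training_set(
                sid, self.presences, self.grid, self.env, candidates,
                cfg.prep.pseudoabsence_per_year, buffer_km=cfg.prep.buffer_km,
                mode="random", seed=cfg.seed,
            )
            models1 = sdm.fit_single_models(train1, candidates, cfg.sdm.algorithms, seed=cfg.seed)
            imp = sdm.averaged_importance(
                models1, train1, candidates, n_perm=cfg.sdm.importance_permutations, seed=cfg.seed
            )
            imp.insert(0, "species_id", sid)
            importance_rows.append(imp)
            variables = sdm.select_variables(imp)
            if len(variables) < 2:  # models need >= 2 covariates
                order = imp.groupby("variable", sort=False)["importance"].mean().sort_values(ascending=False)
                variables = list(order.index[:2])
            self.selected_vars[sid] = variables
            # round 2: environmental profiling on the selected variables
            pres_cov = prep.extract_covariates(pres, self.env, variables)
            profile = prep.build_env_profile(pres_cov, variables)
            train2 = prep.build_training_set(
                sid, self.presences, self.grid, self.env, variables,
                cfg.prep.pseudoabsence_per_year, buffer_km=cfg.prep.buffer_km,
                mode="profiled", profile=profile, seed=cfg.seed,
            )
            training_frames.append(train2)
            fitted = sdm.fit_species_sdm(
                sid, train2, variables, cfg.sdm.algorithms, tss_gate=cfg.sdm.tss_gate,
                n_splits=cfg.sdm.n_splits, seed=cfg.seed,
            )
            self.sdms[sid] = fitted
            for name, ev in fitted.evaluations.items():
                eval_rows.append(
                    {
                        "species_id": sid,
                        "algorithm": name,
                        "TSS": ev.TSS,
                        "kappa": ev.kappa,
                        "AUC": ev.AUC,
                        "threshold": ev.binarization_threshold,
                    }
                )
        self._write_csv(pd.concat(importance_rows, ignore_index=True), "variable_importance.csv")
        self._write_csv(pd.DataFrame(eval_rows), "evaluations.csv")
        self._write_csv(pd.concat(training_frames, ignore_index=True), "training_sets.csv")
        self.manifest["counts"]["species_fitted"] = len(self.sdms)

    def stage_predict(self) -> None:
        years = self.env.years
        shape = (len(years),) + self.grid.shape
        self.binaries: dict[str, np.ndarray] = {}
        scores = {}
        allowed = {sp.species_id: sp.allowed_regions for sp in self.scenario.species}
        for sid, fitted in self.sdms.items():
            bin_stack = np.zeros(shape, dtype=bool)
            score_stack = np.full(shape, np.nan)
            for k, year in enumerate(years):
                predn = sdm.predict_species_year(fitted, self.env, year, allowed_regions=allowed[sid])
                bin_stack[k] = predn.binary_map
                score_stack[k] = predn.committee_score
            self.binaries[sid] = bin_stack
            scores[sid] = score_stack
        self._write_nc({f"binary_{sid}": b for sid, b in self.binaries.items()}, "predictions_binary.nc", years)
        self._write_nc({f"score_{sid}": s for sid, s in scores.items()}, "predictions_score.nc", years)

    def stage_richness(self) -> None:
        cfg = self.config
        years = self.env.years
        guilds = self.scenario.guilds
        self.sr_by_year: dict[int, dict[str, np.ndarray]] = {}
        for k, year in enumerate(years):
            per_guild = {}
            for guild in ("apex", "meso"):
                members = {s: b[k] for s, b in self.binaries.items() if guilds[s] == guild}
                per_guild[guild] = (
                    biodiversity.richness_stack(members) if members else np.zeros(self.grid.shape, int)
                )
            per_guild["all"] = per_guild["apex"] + per_guild["meso"]
            self.sr_by_year[year] = per_guild
        series = biodiversity.richness_series_table(self.sr_by_year, self.grid)
        self._write_csv(series, "richness_series.csv")
        self._write_csv(biodiversity.regional_trend_table(series), "richness_trends.csv")
        self.richness_series = series

        all_sr = {y: g["all"] for y, g in self.sr_by_year.items()}
        self.trend = biodiversity.richness_trend(all_sr)
        self.accrual = biodiversity.accrual_mask(self.trend, cfg.analysis.accrual_min_per_decade)
        self._write_nc(
            {"slope": self.trend.slope, "p_value": self.trend.p_value, "accrual": self.accrual},
            "richness_trend_map.nc",
        )
        self._write_csv(biodiversity.accrual_frequencies(self.accrual, self.grid), "accrual_frequencies.csv")

    def stage_beta(self) -> None:
        cfg = self.config
        # regimes come from the SSIC anomaly sign per region
        ssic_anom = climate.summer_anomaly(self.env, "SSIC", self.grid, cfg.analysis.climatology_years)
        self.regimes = climate.classify_ice_regimes(ssic_anom)
        self.ssic_anomaly = ssic_anom
        years = self.env.years
        low = sorted(self.regimes.pooled_low) or years
        high = sorted(self.regimes.pooled_high) or years
        species = sorted(self.binaries)
        self.regime_maps = {}
        for label, subset in (("low", low), ("high", high)):
            self.regime_maps[label] = {
                s: biodiversity.regime_average_binary(self.binaries[s], years, subset) for s in species
            }
        stack_high = np.stack([self.regime_maps["high"][s] for s in species])
        stack_low = np.stack([self.regime_maps["low"][s] for s in species])
        beta = biodiversity.beta_decompose(stack_high, stack_low, species)
        self._write_nc(beta, "beta_decomposition.nc")

        change_rows = []
        for s in species:
            change_rows.append(
                biodiversity.range_change_by_region(
                    self.regime_maps["high"][s], self.regime_maps["low"][s], self.grid, s
                )
            )
        self._write_csv(pd.concat(change_rows, ignore_index=True), "range_size_change.csv")

    def stage_cooccur(self) -> None:
        cfg = self.config
        years = self.env.years
        pair_frames = []
        count_rows = []
        for r in self.grid.region_ids:
            for k, year in enumerate(years):
                binaries = {s: self.binaries[s][k] for s in sorted(self.binaries)}
                matrix = cooccurrence.build_matrix(binaries, self.grid, int(r), str(year))
                results, counts, _ = cooccurrence.region_cooccurrence(
                    matrix, alpha=cfg.analysis.alpha, min_expected=cfg.analysis.min_expected
                )
                pair_frames.append(cooccurrence.pair_results_table(results, int(r), str(year)))
                count_rows.append({"region": int(r), "year": int(year), **counts})
        self._write_csv(pd.concat(pair_frames, ignore_index=True), "cooccurrence_pairs.csv")
        counts_df = pd.DataFrame(count_rows)
        self._write_csv(counts_df, "cooccurrence_counts.csv")
        sr_all = self.richness_series[self.richness_series["guild"] == "all"][["region", "year", "SR"]]
        self._write_csv(cooccurrence.cooccurrence_trend(counts_df, sr_all), "cooccurrence_trends.csv")

    def stage_climate(self) -> None:
        cfg = self.config
        anom_frames = [self.ssic_anomaly]
        for var in ("SSST", "SCHL", "SZOOC"):
            anom_frames.append(climate.summer_anomaly(self.env, var, self.grid, cfg.analysis.climatology_years))
        anomalies = pd.concat(anom_frames, ignore_index=True)
        regime_flag = anomalies["variable"].eq("SSIC") & (anomalies["anomaly"] < 0)
        anomalies["regime"] = np.where(
            anomalies["variable"].eq("SSIC"), np.where(regime_flag, "low", "high"), ""
        )
        self._write_csv(anomalies.fillna(""), "anomalies.csv")

        trend_maps = {}
        mk_arrays = {}
        for var in climate.HOTSPOT_SIGNS:
            tm = climate.mann_kendall_map(self.env.data[var], var)
            trend_maps[var] = tm
            mk_arrays[f"{var}_sen"] = tm.sen_slope
            mk_arrays[f"{var}_p"] = tm.p
        self._write_nc(mk_arrays, "mk_trends.nc")
        hotspots = climate.hotspot_map(
            trend_maps, self.accrual, self.grid,
            bounds=cfg.analysis.hotspot_bounds or None,
            p_threshold=cfg.analysis.hotspot_p_threshold,
        )
        self.hotspots = hotspots
        self._write_nc(
            {"hotspot": hotspots.hotspot, "n_large": hotspots.n_large,
             **{f"large_{v}": m for v, m in hotspots.indicators.items()}},
            "hotspot_map.nc",
        )
        self._write_csv(hotspots.overlap, "hotspot_overlap.csv")

        sst_anom = anomalies[anomalies["variable"] == "SSST"]
        low_years = self.regimes.low_years
        all_sr = {y: g["all"] for y, g in self.sr_by_year.items()}
        hov = biodiversity.accrual_series(self.accrual, all_sr, self.grid, sst_anom, low_years)
        self._write_csv(hov, "accrual_series.csv")
        self._write_csv(biodiversity.accrual_sst_correlation(hov), "accrual_sst_correlation.csv")

    def stage_report(self) -> None:
        path = self.out / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))

    def run(self, upto: str = "report") -> Path:
        if upto not in STAGES:
            raise ValueError(f"unknown stage {upto!r}")
        for stage in STAGES[: STAGES.index(upto) + 1]:
            log.info("stage %s", stage)
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:  # persist partial state, then halt loudly
                self.manifest["failed_stage"] = stage
                (self.out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
                raise PipelineError(stage, exc) from exc
        return self.out


def run_pipeline(config: PipelineConfig, upto: str = "report") -> Path:
    """Execute the configured pipeline; returns the run directory."""
    handler = logging.StreamHandler(sys.stderr)
    logging.getLogger("arcbio").setLevel(logging.INFO)
    run = PipelineRun(config)
    file_handler = logging.FileHandler(run.out / "pipeline.log")
    root = logging.getLogger("arcbio")
    root.addHandler(handler)
    root.addHandler(file_handler)
    try:
        return run.run(upto=upto)
    finally:
        root.removeHandler(handler)
        root.removeHandler(file_handler)
        file_handler.close()
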