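"""Orchestration: simulate -> preprocess -> spectra -> PAF -> EEG-age -> stats.

A run is driven by a :class:`RunConfig` whose defaults reproduce the
reference analysis settings (500 Hz sampling, 1025-sample 3rd-order SG
baseline, +/-120 uV artifact criterion, AR order 256 on the 0.1-45 Hz /
0.1 Hz grid, 4096 ms Hamming Welch windows with 50% overlap, 5th-order
11-bin smoothing, 7-13 Hz alpha band, 1000 permutations, 25 PARAFAC
replications, JZS r scale 0.354).  All randomness flows from the single
top-level seed, so a rerun with the same config reproduces identical
artefacts; a JSON manifest records parameters, versions and file hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import age_models, paf as paf_mod, preprocess, simulate, spectra as spectra_mod, stats
from .io import RawEEG, read_eeg, write_eeg_text, write_json

log = logging.getLogger("eegage")

STAGES = ("simulate", "preprocess", "spectra", "paf", "eeg_age", "stats")
PAF_METHODS = ("N", "D", "M", "C", "K")
AGE_MODELS = ("pls", "rpls", "mpls")


@dataclass
class RunConfig:
    # input source
    mode: str = "synthetic"  # or "eeg_dir"
    eeg_dir: str | None = None
    cohort_csv: str | None = None
    out_dir: str = "eegage_run"
    seed: int = 0
    stages: tuple = STAGES
    log_level: str = "info"
    write_raw_eeg: bool = False
    # synthetic cohort
    n_participants: int = 60
    recording_seconds: float = 120.0
    paf_residual_sd: float = 0.9
    artifact_rate: float = 2.0
    drift_amplitude: float = 20.0
    cohort_overrides: dict = field(default_factory=dict)
    # preprocessing
    fs: float = 500.0
    sg_window: int = 1025
    sg_order: int = 3
    artifact_threshold_uv: float = 120.0
    target_seconds: float = 100.0
    max_drop: int = 16
    # spectra
    ar_order: int = 256
    grid_start: float = 0.1
    grid_stop: float = 45.0
    grid_step: float = 0.1
    welch_window_ms: float = 4096.0
    welch_overlap: float = 0.5
    smooth_window_bins: int = 11
    smooth_order: int = 5
    # PAF
    alpha_band: tuple = (7.0, 13.0)
    fit_starts: int = 10
    corcoran_min_channels: int = 3
    # EEG-age
    max_pls_factors: int = 5
    n_permutations: int = 1000
    perm_level: float = 0.05
    rpls_factors: int = 2
    rpls_max_iter: int = 50
    tripls_factors: int = 3
    run_parafac_diagnostics: bool = False
    parafac_max_factors: int = 10
    parafac_replications: int = 25
    parafac_max_iter: int = 2500
    parafac_compress_rank: int = 60
    # stats
    r_scale: float = 0.354

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        self.alpha_band = tuple(self.alpha_band)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.mode not in ("synthetic", "eeg_dir"):
            raise ValueError(f"unknown mode {self.mode!r}")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> Path:
        import yaml

        path = Path(path)
        d = self.to_dict()
        d["stages"] = list(d["stages"])
        d["alpha_band"] = list(d["alpha_band"])
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def grid(self) -> spectra_mod.FrequencyGrid:
        return spectra_mod.FrequencyGrid(self.grid_start, self.grid_stop, self.grid_step)

    def cohort_spec(self) -> simulate.CohortSpec:
        kwargs = dict(
            n_participants=self.n_participants,
            seed=self.seed,
            recording_seconds=self.recording_seconds,
            paf_residual_sd=self.paf_residual_sd,
            artifact_rate=self.artifact_rate,
            drift_amplitude=self.drift_amplitude,
        )
        kwargs.update(self.cohort_overrides)
        return simulate.CohortSpec(**kwargs)


@dataclass
class ParticipantResult:
    participant_id: str
    age: float
    clean: preprocess.CleanResult | None = None
    ar_log2: np.ndarray | None = None  # channels x grid
    ar_labels: list[str] = field(default_factory=list)
    svd: spectra_mod.SvdSummary | None = None
    welch_freqs: np.ndarray | None = None
    welch_smoothed: np.ndarray | None = None  # channels x welch bins
    paf: dict = field(default_factory=dict)  # method -> PafEstimate
    model_params: object = None


@dataclass
class RunReport:
    config: RunConfig
    cohort: pd.DataFrame
    participants: list[ParticipantResult]
    paf_table: pd.DataFrame | None = None
    eeg_age: pd.DataFrame | None = None
    models: dict = field(default_factory=dict)
    stats_tables: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _needed_through(stages) -> int:
    return max(STAGES.index(s) for s in stages)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _process_recording(raw: RawEEG, config: RunConfig, through: int, result: ParticipantResult):
    """Preprocess one recording and compute its spectral summaries."""
    clean = preprocess.clean_raw(
        raw,
        threshold=config.artifact_threshold_uv,
        window=config.sg_window,
        order=config.sg_order,
        target_seconds=config.target_seconds,
        max_drop=config.max_drop,
    )
    result.clean = clean
    if through < STAGES.index("spectra"):
        return
    grid = config.grid
    ar_rows = []
    welch_rows = []
    welch_freqs = None
    for c in range(clean.segment.shape[0]):
        ar = spectra_mod.ar_psd_covariance(clean.segment[c], order=config.ar_order,
                                           fs=clean.fs, grid=grid)
        ar_rows.append(spectra_mod.power_to_log2amplitude(ar.values))
        w = spectra_mod.welch_psd(clean.segment[c], fs=clean.fs,
                                  window_ms=config.welch_window_ms,
                                  overlap=config.welch_overlap)
        welch_freqs = w.freqs
        welch_rows.append(
            spectra_mod.normalize_and_smooth(w.values, w.freqs,
                                             band=(config.grid_start, config.grid_stop),
                                             window_bins=config.smooth_window_bins,
                                             order=config.smooth_order)
        )
    result.ar_log2 = np.vstack(ar_rows)
    result.ar_labels = list(clean.labels)
    result.svd = spectra_mod.svd_first_component(result.ar_log2)
    result.welch_freqs = welch_freqs
    result.welch_smoothed = np.vstack(welch_rows)


def _estimate_paf(result: ParticipantResult, config: RunConfig, seed: int):
    grid = config.grid
    band = config.alpha_band
    result.paf["N"] = paf_mod.naive_paf(result.ar_log2, grid.values, result.ar_labels, band)
    result.paf["D"] = paf_mod.direct_paf(result.svd, grid.values, band)
    params = paf_mod.fit_spectral_model(result.svd.component_spectrum, grid.values,
                                        n_starts=config.fit_starts, seed=seed)
    result.model_params = params
    result.paf["M"] = paf_mod.modeled_paf(params)
    result.paf["C"] = paf_mod.corcoran_paf(result.welch_smoothed, result.welch_freqs,
                                           result.ar_labels,
                                           min_channels=config.corcoran_min_channels,
                                           alpha_band=band)
    result.paf["K"] = paf_mod.klimesch_paf(result.welch_smoothed, result.welch_freqs,
                                           result.ar_labels, alpha_band=band)


def _paf_tables(results: list[ParticipantResult]):
    rows, chan_rows = [], []
    for res in results:
        for method in PAF_METHODS:
            est = res.paf[method]
            rows.append({
                "participant_id": res.participant_id, "method": method,
                "value": np.nan if est.value is None else est.value,
                "n_channels_used": est.n_channels_used,
                "missing": est.value is None,
            })
        for lab, v in res.paf["N"].per_channel.items():
            chan_rows.append({
                "participant_id": res.participant_id, "channel": lab,
                "paf": np.nan if v is None else v,
                "amplitude": res.paf["N"].per_channel_amplitude.get(lab, np.nan),
            })
    return pd.DataFrame(rows), pd.DataFrame(chan_rows)


def _fit_age_models(report: RunReport, config: RunConfig, rng: np.random.Generator):
    results = report.participants
    ages = np.array([r.age for r in results])
    x = np.vstack([r.svd.component_spectrum for r in results])
    n_sel, perm_p = age_models.select_factors_by_permutation(
        x, ages, max_factors=config.max_pls_factors, n_perm=config.n_permutations,
        level=config.perm_level, seed=int(rng.integers(2**31)),
    )
    n_factors = max(n_sel, 1)
    pls = age_models.fit_pls(x, ages, n_factors)
    pls.perm_pvalues = perm_p
    vip = age_models.vip_scores(pls)
    eeg_age_pls = pls.predict(x)
    loo = np.empty_like(ages)
    for i in range(ages.size):
        keep = np.arange(ages.size) != i
        loo[i] = age_models.fit_pls(x[keep], ages[keep], n_factors).predict(x[i : i + 1])[0]
    rpls = age_models.rpls_select(x, ages, freqs=config.grid.values,
                                  n_factors=config.rpls_factors,
                                  max_iter=config.rpls_max_iter)
    eeg_age_rpls = rpls.final_model.predict(x[:, rpls.selected])

    common = set(results[0].ar_labels)
    for res in results[1:]:
        common &= set(res.ar_labels)
    common = [lab for lab in results[0].ar_labels if lab in common]
    tensor = np.stack([
        res.ar_log2[[res.ar_labels.index(lab) for lab in common]] for res in results
    ])
    tri = age_models.fit_tripls(tensor, ages, min(config.tripls_factors, len(common)))
    eeg_age_mpls = tri.fitted
    report.eeg_age = pd.DataFrame({
        "participant_id": [r.participant_id for r in results],
        "age": ages,
        "eeg_age_pls": eeg_age_pls,
        "eeg_age_pls_loo": loo,
        "eeg_age_rpls": eeg_age_rpls,
        "eeg_age_mpls": eeg_age_mpls,
    })
    report.models = {
        "pls": {
            "n_factors_selected": int(n_sel), "n_factors_used": int(n_factors),
            "perm_pvalues": perm_p, "beta": pls.beta, "intercept": pls.intercept,
            "vip": vip, "explained_y_variance": pls.explained_y_variance,
        },
        "rpls": {
            "iterations": rpls.iterations,
            "selected_frequencies": rpls.selected_frequencies,
            "beta": rpls.final_model.beta, "intercept": rpls.final_model.intercept,
        },
        "mpls": {
            "n_factors": tri.n_factors, "channels": common,
            "score_age_corr": tri.score_age_corr, "coef": tri.coef,
            "channel_weights": tri.channel_weights,
            "frequency_weights": tri.frequency_weights,
        },
        "_pls_model": pls, "_rpls": rpls, "_tri": tri, "_x": x, "_tensor": tensor,
    }
    if config.run_parafac_diagnostics:
        diag, _ = age_models.diagnose_parafac(
            tensor, max_factors=config.parafac_max_factors,
            n_replications=config.parafac_replications,
            seed=int(rng.integers(2**31)), max_iter=config.parafac_max_iter,
            compress_rank=config.parafac_compress_rank,
        )
        report.models["parafac_diagnostics"] = diag


def _run_stats(report: RunReport, config: RunConfig):
    results = report.participants
    cohort = report.cohort.set_index("participant_id")
    table = report.eeg_age.set_index("participant_id").copy()
    for method in ("D", "M", "C", "K"):
        table[f"paf_{method.lower()}"] = [
            np.nan if r.paf[method].value is None else r.paf[method].value for r in results
        ]
    table["nart_iq"] = cohort["nart_iq"]
    table["qmci"] = cohort["qmci"]
    age = table["age"].to_numpy()

    method_cols = {
        "D-PAF": "paf_d", "M-PAF": "paf_m", "C-PAF": "paf_c", "K-PAF": "paf_k",
        "PLS": "eeg_age_pls", "R-PLS": "eeg_age_rpls", "M-PLS": "eeg_age_mpls",
    }
    # a method with fewer than 3 available estimates cannot enter any test
    method_cols = {k: v for k, v in method_cols.items() if table[v].notna().sum() >= 3}
    # distributions (with normality check)
    dist_rows = []
    for name, col in method_cols.items():
        v = table[col].dropna().to_numpy()
        w, p = stats.shapiro_wilk(v)
        dist_rows.append({"measure": name, "mean": v.mean(), "sd": v.std(ddof=1),
                          "min": v.min(), "max": v.max(), "n": v.size,
                          "shapiro_w": w, "shapiro_p": p})
    distributions = pd.DataFrame(dist_rows)

    # correlation matrix among methods (pairwise complete) and with age
    names = list(method_cols)
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    age_corr = {}
    for i, a in enumerate(names):
        va = table[method_cols[a]]
        ok = va.notna()
        r_age, p_age = stats.pearson(va[ok], table["age"][ok])
        age_corr[a] = {"r": r_age, "p": p_age}
        for b in names[i + 1:]:
            vb = table[method_cols[b]]
            both = va.notna() & vb.notna()
            r, _ = stats.pearson(va[both], vb[both])
            corr.loc[a, b] = corr.loc[b, a] = r

    # Hotelling-Williams comparisons of each method's correlation with age
    comp_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = table[method_cols[a]], table[method_cols[b]]
            both = va.notna() & vb.notna()
            n = int(both.sum())
            r13, _ = stats.pearson(va[both], table["age"][both])
            r23, _ = stats.pearson(vb[both], table["age"][both])
            r12, _ = stats.pearson(va[both], vb[both])
            try:
                cmp_res = stats.compare_dependent_correlations(abs(r13), abs(r23), abs(r12), n)
                comp_rows.append({"method_a": a, "method_b": b,
                                  "r_diff": abs(r13) - abs(r23),
                                  "t": cmp_res.t_stat, "df": cmp_res.df, "p": cmp_res.p})
            except ValueError:
                comp_rows.append({"method_a": a, "method_b": b,
                                  "r_diff": abs(r13) - abs(r23),
                                  "t": np.nan, "df": n - 3, "p": np.nan})
    comparisons = pd.DataFrame(comp_rows)

    # Bland-Altman + paired t over PAF estimator pairs
    paf_names = [n for n in ("D-PAF", "M-PAF", "C-PAF", "K-PAF") if n in method_cols]
    ba_rows = []
    for i, a in enumerate(paf_names):
        for b in paf_names[i + 1:]:
            va, vb = table[method_cols[a]], table[method_cols[b]]
            both = va.notna() & vb.notna()
            ba = stats.bland_altman(va[both], vb[both])
            t, df, p = stats.paired_t(va[both], vb[both])
            ba_rows.append({"method_a": a, "method_b": b, "bias": ba.bias,
                            "sd_diff": ba.sd_diff, "loa_low": ba.loa_low,
                            "loa_high": ba.loa_high,
                            "proportional_slope": ba.proportional_slope,
                            "n": ba.n, "paired_t": t, "paired_df": df, "paired_p": p})
    bland = pd.DataFrame(ba_rows)

    # regressions: age on each estimate (r, RMSE) and the PAF-on-age line
    reg_rows = []
    for name, col in method_cols.items():
        v = table[col]
        ok = v.notna()
        fit = stats.linreg_rmse(v[ok].to_numpy(), table["age"][ok].to_numpy())
        reg_rows.append({"measure": name, "response": "age", "slope": fit.coefficients[0],
                         "intercept": fit.intercept, "r": fit.r, "rmse": fit.rmse, "n": fit.n})
    ok = table["paf_m"].notna()
    line = stats.linreg_rmse(table["age"][ok].to_numpy(), table["paf_m"][ok].to_numpy())
    reg_rows.append({"measure": "age", "response": "M-PAF", "slope": line.coefficients[0],
                     "intercept": line.intercept, "r": line.r, "rmse": line.rmse,
                     "n": line.n})
    regressions = pd.DataFrame(reg_rows)

    # MINQUE variance components on the per-channel N-PAF grid
    chan_labels = sorted({lab for r in results for lab in r.paf["N"].per_channel})
    grid = np.full((len(results), len(chan_labels)), np.nan)
    for i, r in enumerate(results):
        for j, lab in enumerate(chan_labels):
            v = r.paf["N"].per_channel.get(lab)
            if v is not None:
                grid[i, j] = v
    vc = stats.minque_components(grid)

    # partial correlation of PLS EEG-age with age, controlling the PAFs
    control_cols = [c for c in ("paf_m", "paf_d", "paf_c", "paf_k") if c in table]
    paf_cols = table[control_cols]
    ok = paf_cols.notna().all(axis=1) & table["eeg_age_pls"].notna()
    if int(ok.sum()) > len(control_cols) + 3:
        r_part, p_part = stats.partial_correlation(
            table["eeg_age_pls"][ok], table["age"][ok], paf_cols[ok].to_numpy()
        )
        partials = pd.DataFrame([
            {"x": "PLS EEG-age", "y": "age", "controls": ",".join(control_cols),
             "r": r_part, "p": p_part}
        ])
    else:
        partials = pd.DataFrame(columns=["x", "y", "controls", "r", "p"])

    # Bayes factors for the nested regressions of interest
    ok = table["paf_m"].notna()
    paf_age_m = stats.linreg_rmse(table["paf_m"][ok].to_numpy(),
                                  table["age"][ok].to_numpy()).fitted
    yy = table["age"][ok].to_numpy()
    pls_age = table["eeg_age_pls"][ok].to_numpy()
    qmci = table["qmci"][ok].to_numpy()
    bayes = {"r_scale": config.r_scale}
    try:
        bayes["age~pls_vs_pls+mpaf"] = stats.jzs_regression_bf01(
            yy, pls_age, np.column_stack([pls_age, paf_age_m]), r_scale=config.r_scale
        ).bf01
        bayes["qmci~mpaf_vs_mpaf+pls"] = stats.jzs_regression_bf01(
            qmci, paf_age_m, np.column_stack([paf_age_m, pls_age]),
            r_scale=config.r_scale
        ).bf01
    except ValueError as exc:  # cohort too small for the nested comparison
        log.warning("Bayes-factor comparison skipped: %s", exc)
        bayes["skipped"] = str(exc)

    report.stats_tables = {
        "distributions": distributions,
        "correlations": corr,
        "age_correlations": pd.DataFrame(age_corr).T,
        "correlation_comparisons": comparisons,
        "bland_altman": bland,
        "regressions": regressions,
        "variance_components": vc,
        "partial_correlations": partials,
        "bayes_factors": bayes,
    }


def write_report(report: RunReport, out_dir) -> dict:
    """Write every cohort-level table as CSV/JSON; returns path -> sha256."""
    if report.cohort is None or len(report.cohort) == 0:
        raise ValueError("empty cohort: nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def emit_csv(frame: pd.DataFrame, name: str, **kw):
        path = out / name
        frame.to_csv(path, float_format="%.10g", **kw)
        written[name] = _sha256(path)

    emit_csv(report.cohort, "cohort.csv", index=False)
    if report.paf_table is not None:
        emit_csv(report.paf_table, "paf.csv", index=False)
    if report.eeg_age is not None:
        emit_csv(report.eeg_age, "eeg_age.csv", index=False)
    if report.models:
        serialisable = {
            k: v for k, v in report.models.items()
            if not k.startswith("_") and not isinstance(v, pd.DataFrame)
        }
        path = write_json(serialisable, out / "models.json")
        written["models.json"] = _sha256(path)
        if "parafac_diagnostics" in report.models:
            emit_csv(report.models["parafac_diagnostics"], "parafac_diagnostics.csv",
                     index=False)
    for name, tbl in report.stats_tables.items():
        if isinstance(tbl, pd.DataFrame):
            emit_csv(tbl, f"stats_{name}.csv")
        else:
            path = write_json(tbl, out / f"stats_{name}.json")
            written[f"stats_{name}.json"] = _sha256(path)
    return written


def run_analysis(config: RunConfig) -> RunReport:
    """Execute the enabled stages in fixed order and write their artefacts."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    through = _needed_through(config.stages)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xEE6]))

    if config.mode == "synthetic":
        spec = config.cohort_spec()
        cohort = simulate.generate_cohort(spec)
        frame = simulate.cohort_to_frame(cohort)
    else:
        if not config.cohort_csv:
            raise ValueError("eeg_dir mode requires cohort_csv with participant ages")
        frame = pd.read_csv(config.cohort_csv)
        cohort = None
    if len(frame) == 0:
        raise ValueError("empty cohort")
    report = RunReport(config=config, cohort=frame, participants=[])
    log.info("cohort of %d participants", len(frame))

    ts_seeds = rng.integers(2**31, size=len(frame))
    fit_seeds = rng.integers(2**31, size=len(frame))
    for i, row in frame.iterrows():
        pid = row["participant_id"]
        result = ParticipantResult(participant_id=pid, age=float(row["age"]))
        report.participants.append(result)
        if through < STAGES.index("preprocess") and config.mode == "synthetic":
            continue
        if config.mode == "synthetic":
            synth = simulate.synthesize_timeseries(
                cohort[i], duration_s=config.recording_seconds, fs=config.fs,
                drift_amplitude=spec.drift_amplitude, artifact_rate=spec.artifact_rate,
                seed=int(ts_seeds[i]),
            )
            raw = synth.raw
            if config.write_raw_eeg:
                (out / "eeg").mkdir(exist_ok=True)
                write_eeg_text(raw, out / "eeg" / f"{pid}.tsv")
        else:
            raw = read_eeg(Path(config.eeg_dir) / f"{pid}.tsv")
        _process_recording(raw, config, through, result)
        if through >= STAGES.index("paf"):
            _estimate_paf(result, config, seed=int(fit_seeds[i]))
        log.info("participant %s done (%.1f s elapsed)", pid, time.time() - t0)

    if through >= STAGES.index("preprocess") and report.participants and \
            report.participants[0].clean is not None:
        clean_rows = [{
            "participant_id": r.participant_id,
            "duration_s": r.clean.duration,
            "start_sample": r.clean.interval[0],
            "end_sample": r.clean.interval[1],
            "n_dropped": len(r.clean.dropped_channels),
            "dropped_channels": ";".join(r.clean.dropped_channels),
            "reached_target": r.clean.reached_target,
        } for r in report.participants]
        pd.DataFrame(clean_rows).to_csv(out / "clean_summary.csv", index=False,
                                        float_format="%.10g")
    if through >= STAGES.index("spectra") and report.participants and \
            report.participants[0].svd is not None:
        svd_frame = pd.DataFrame(
            np.vstack([r.svd.component_spectrum for r in report.participants]),
            index=[r.participant_id for r in report.participants],
            columns=[f"{f:.1f}" for f in config.grid.values],
        )
        svd_frame.to_csv(out / "svd_spectra.tsv", sep="\t", float_format="%.10g")
    if through >= STAGES.index("paf"):
        report.paf_table, chan_table = _paf_tables(report.participants)
        chan_table.to_csv(out / "paf_channels.csv", index=False, float_format="%.10g")
    if through >= STAGES.index("eeg_age"):
        _fit_age_models(report, config, rng)
    if "stats" in config.stages:
        _run_stats(report, config)

    written = write_report(report, out)
    if config.mode == "synthetic" and "simulate" in config.stages:
        truth = {
            p.participant_id: {
                "spectral_params": p.true_params.as_dict(),
                "channel_gains": p.channel_gains,
            }
            for p in cohort
        }
        path = write_json(truth, out / "cohort_truth.json")
        written["cohort_truth.json"] = _sha256(path)
    report.manifest = {
        "stages": list(config.stages),
        "parameters": config.to_dict(),
        "seed": config.seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "artifacts": written,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    write_json(report.manifest, out / "manifest.json")
    log.info("run complete in %.1f s", time.time() - t0)
    return report
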