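"""End-to-end orchestration: prep -> candidate fits -> AIC selection ->
decoding -> budgets -> caching report -> residency, with seeds and a run
manifest.  A pure function of (inputs, config, seed).

The four candidate covariate sets are fitted in the fixed nested order
(none; time of day; + temperature; + hunger), each warm-started from the
previous (nested) optimum, mirroring stepwise covariate entry.
"""

from __future__ import annotations

import hashlib
import json
import sys
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import caching, decoding, hmm_core, residency, track_prep

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "fit_candidates"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    fixes_csv: str
    outdir: str
    kill_sites_csv: str | None = None
    collaring_dates: dict = field(default_factory=dict)  # animal_id -> date
    life_stages: dict = field(default_factory=dict)  # animal_id -> stage or "auto"
    n_states: int = 3
    n_starts: int = 10
    seed: int = 1
    interval_tolerance_min: float = 5.0
    radius_m: float = 200.0
    candidate_sets: tuple = hmm_core.CANDIDATE_COVARIATE_SETS
    mode: str = "general"
    column_aliases: dict = field(default_factory=dict)

    def validate(self):
        if not Path(self.fixes_csv).exists():
            raise FileNotFoundError(self.fixes_csv)
        if self.n_states < 1 or self.n_starts < 1:
            raise ValueError("n_states and n_starts must be positive")


def fit_candidates(
    series: pd.DataFrame,
    n_states: int,
    zero_mass: bool,
    candidate_sets,
    n_starts: int,
    seed: int,
) -> list[hmm_core.FittedHMM]:
    """Fit the nested candidate models stepwise, warm-starting each model
    from the previous optimum padded with zero slopes."""
    fits: list[hmm_core.FittedHMM] = []
    prev = None
    for covs in candidate_sets:
        spec = hmm_core.HMMSpec(n_states=n_states, zero_mass=zero_mass, covariates=covs)
        x0 = _pad_warm_start(prev, spec) if prev is not None else None
        starts = n_starts if prev is None else max(2, n_starts // 3)
        fit = hmm_core.fit_hmm(
            series, spec, n_starts=starts, seed=seed, x0=x0, compute_cov=False
        )
        fits.append(fit)
        prev = fit
    # covariance only for the AIC-best model (the one used downstream)
    best = min(fits, key=lambda f: f.aic)
    refit = hmm_core.fit_hmm(
        series, best.spec, n_starts=1, seed=seed, x0=best.x, compute_cov=True
    )
    fits[fits.index(best)] = refit
    return fits


def _pad_warm_start(prev: hmm_core.FittedHMM, spec: hmm_core.HMMSpec) -> np.ndarray:
    """Embed a nested fit's working vector into a larger spec (new slopes 0)."""
    idx_new = hmm_core._ParamIndex(spec)
    x = np.zeros(idx_new.n)
    s_old = prev.index.slices
    s_new = idx_new.slices
    for k in ("log_mu", "log_sigma", "logit_pi0", "angle_mean", "log_kappa", "delta_logit"):
        x[s_new[k]] = prev.x[s_old[k]]
    N = spec.n_states
    p_old = len(prev.spec.regressors)
    p_new = len(spec.regressors)
    b_old = prev.x[s_old["beta"]].reshape(N * (N - 1), 1 + p_old)
    b_new = np.zeros((N * (N - 1), 1 + p_new))
    b_new[:, : 1 + p_old] = b_old
    x[s_new["beta"]] = b_new.ravel()
    return x


def aic_table(fits) -> pd.DataFrame:
    """Candidate-model comparison table: model, K, AIC, dAIC, weight."""
    w = hmm_core.akaike_weights(fits)
    df = pd.DataFrame(
        {
            "model": [f.spec.label() for f in fits],
            "K": [f.K for f in fits],
            "AIC": [round(f.aic, 1) for f in fits],
            "dAIC": [round(f.aic - min(g.aic for g in fits), 1) for f in fits],
            "weight": np.round(w, 4),
        }
    )
    return df.sort_values("AIC").reset_index(drop=True)


def params_table(fit: hmm_core.FittedHMM) -> pd.DataFrame:
    """Natural-scale emission estimates with 95% CIs, one column per state."""
    cis = hmm_core.parameter_cis(fit)
    rows = []
    for label, key in [
        ("Step mean (km)", "step_mean"),
        ("Step SD (km)", "step_sd"),
        ("Angle mean (radians)", "angle_mean"),
        ("Angle concentration", "angle_conc"),
    ]:
        est, lo, hi = cis[key]["estimate"], cis[key]["lo"], cis[key]["hi"]
        rows.append(
            [label]
            + [f"{e:.3f} ({l:.3f},{h:.3f})" for e, l, h in zip(est, lo, hi)]
        )
    if fit.spec.zero_mass:
        est, lo, hi = (cis["zero_mass"][k] for k in ("estimate", "lo", "hi"))
        rows.append(
            ["Zero-step mass"]
            + [f"{e:.3f} ({l:.3f},{h:.3f})" for e, l, h in zip(est, lo, hi)]
        )
    cols = ["parameter"] + [f"state_{k + 1}" for k in range(fit.spec.n_states)]
    return pd.DataFrame(rows, columns=cols)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Per life stage x sampling interval: AIC table, best-model parameter
    table with CIs, stationary-curve data, decoded step table, activity
    budgets, cluster report and variogram/classification.  Partial outputs
    are retained if a later stage fails.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = lambda msg: print(f"[pipeline] {msg}", file=sys.stderr)

    fixes = _stage("read")(track_prep.read_fixes)(
        config.fixes_csv, config.column_aliases
    )
    kill_sites = None
    if config.kill_sites_csv:
        kill_sites = pd.read_csv(config.kill_sites_csv, parse_dates=["t_first", "t_last"])

    datasets: dict[tuple[str, int], list] = {}
    variogram_rows = []
    residency_calls = {}
    for animal, grp in fixes.groupby("animal_id"):
        grp = grp.sort_values("t").reset_index(drop=True)
        cd = config.collaring_dates.get(animal, grp["t"].iloc[0])
        filtered = _stage("filters")(track_prep.apply_study_filters)(grp, cd, config.mode)
        # residency diagnosis
        stage_lbl = config.life_stages.get(animal, "auto")
        span_h = (filtered["t"].iloc[-1] - filtered["t"].iloc[0]) / pd.Timedelta(hours=1)
        bins = np.linspace(0, max(span_h / 2, 1.0), 25)
        try:
            vg = residency.empirical_svf(filtered, bins)
            call = residency.classify_residency(vg)
            vdf = vg.to_frame()
            vdf.insert(0, "animal_id", animal)
            variogram_rows.append(vdf)
        except ValueError as exc:
            call = {"classification": "indeterminate", "reason": str(exc)}
        residency_calls[animal] = call
        if stage_lbl == "auto":
            stage_lbl = call["classification"]
            if stage_lbl == "indeterminate":
                log(f"{animal}: residency indeterminate, treated as non_resident")
                stage_lbl = "non_resident"
        by_interval = _stage("split")(track_prep.split_by_interval)(
            filtered, config.interval_tolerance_min, animal, stage_lbl
        )
        for interval, tracks in by_interval.items():
            if not tracks:
                continue
            tbl = track_prep.steps_table(tracks)
            if kill_sites is not None and len(kill_sites):
                hunger, _ = caching.hunger_covariate(tbl["t"], kill_sites)
                tbl["hunger_days"] = hunger
            tbl["animal_id"] = animal
            tbl["life_stage"] = stage_lbl
            datasets.setdefault((stage_lbl, interval), []).append(tbl)

    if variogram_rows:
        pd.concat(variogram_rows, ignore_index=True).to_csv(
            out / "variograms.csv", index=False
        )
    with open(out / "residency.json", "w") as fh:
        json.dump(residency_calls, fh, indent=1, default=str)

    budget_frames = []
    for (stage_lbl, interval), frames in sorted(datasets.items()):
        tag = f"{stage_lbl}_{interval}h"
        series = pd.concat(frames, ignore_index=True)
        # unique burst ids across animals
        series["burst_id"] = (
            series["animal_id"].astype(str) + "/" + series["burst_id"].astype(str)
        )
        zero_mass = bool((series["step_km"] == 0).any())
        usable_sets = [
            c
            for c in config.candidate_sets
            if all(
                (cov == "tod")
                or (cov == "temperature" and series["temp_c"].notna().all())
                or (cov == "hunger" and "hunger_days" in series)
                for cov in c
            )
        ]
        log(f"{tag}: fitting {len(usable_sets)} candidate models on {len(series)} steps")
        fits = _stage("fit")(fit_candidates)(
            series, config.n_states, zero_mass, usable_sets, config.n_starts, config.seed
        )
        atab = aic_table(fits)
        atab.to_csv(out / f"aic_{tag}.csv", index=False)
        best = min(fits, key=lambda f: f.aic)
        params_table(best).to_csv(out / f"params_{tag}.csv", index=False)
        with open(out / f"fit_{tag}.json", "w") as fh:
            json.dump(best.to_dict(), fh, indent=1)
        states = _stage("decode")(decoding.viterbi)(best, series)
        series = series.assign(state=states)
        series.to_csv(out / f"steps_{tag}.csv", index=False)
        for cov in best.spec.covariates:
            grid = (
                np.linspace(0, 23.5, 48)
                if cov == "tod"
                else np.linspace(
                    series["temp_c" if cov == "temperature" else "hunger_days"].min(),
                    series["temp_c" if cov == "temperature" else "hunger_days"].max(),
                    25,
                )
            )
            curves = decoding.stationary_curves(
                best, cov, grid, n_draws=200, seed=config.seed
            )
            cdf = pd.DataFrame(
                curves["pi"], columns=[f"pi_state_{k + 1}" for k in range(best.spec.n_states)]
            )
            cdf.insert(0, "grid", curves["grid"])
            if curves["lo"] is not None:
                for k in range(best.spec.n_states):
                    cdf[f"lo_state_{k + 1}"] = curves["lo"][:, k]
                    cdf[f"hi_state_{k + 1}"] = curves["hi"][:, k]
            cdf.to_csv(out / f"stationary_{cov}_{tag}.csv", index=False)
        resid = decoding.step_pseudo_residuals(best, series, seed=config.seed)
        pd.DataFrame({"pseudo_residual": resid}).to_csv(
            out / f"residuals_{tag}.csv", index=False
        )
        # phases and budgets
        if kill_sites is not None and len(kill_sites):
            phase = _phase_for_steps(series, fixes, kill_sites, config.radius_m)
        else:
            phase = np.array(["general"] * len(series), dtype=object)
        bt = decoding.activity_budget(
            states, phase, life_stages=series["life_stage"].to_numpy()
        )
        budget_frames.append(bt.reset_index())
    if budget_frames:
        pd.concat(budget_frames, ignore_index=True).to_csv(
            out / "budgets.csv", index=False
        )

    # cluster report per animal on the general-phase fixes
    cluster_frames = []
    for animal, grp in fixes.groupby("animal_id"):
        grp = grp.sort_values("t").reset_index(drop=True)
        clusters = _stage("clusters")(caching.detect_clusters)(grp, config.radius_m)
        caching.classify_clusters(clusters, kill_sites, config.radius_m)
        rep = caching.cluster_report(clusters, grp, config.radius_m)
        rep.insert(0, "animal_id", animal)
        cluster_frames.append(rep)
    if cluster_frames:
        pd.concat(cluster_frames, ignore_index=True).to_csv(
            out / "clusters.csv", index=False
        )

    manifest = {
        "config": {k: str(v) for k, v in asdict(config).items()},
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps({k: str(v) for k, v in asdict(config).items()}, sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_fixes": int(len(fixes)),
        "datasets": [f"{s}_{i}h" for s, i in sorted(datasets)],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log(f"done -> {out}")
    return out


def main(argv=None):
    """`python -m movestates.pipeline config.yaml` — thin YAML front end."""
    import yaml

    argv = argv if argv is not None else sys.argv[1:]
    if len(argv) != 1:
        print("usage: python -m movestates.pipeline CONFIG.yaml", file=sys.stderr)
        return 2
    with open(argv[0]) as fh:
        cfg = PipelineConfig(**yaml.safe_load(fh))
    run_pipeline(cfg)
    return 0


def _phase_for_steps(series, fixes, kill_sites, radius_m):
    """Phase label per step row, matched by timestamp to the fix table."""
    fx = fixes.sort_values("t").reset_index(drop=True)
    labels = caching.label_caching_phase(fx, kill_sites, radius_m)
    lookup = dict(zip(pd.to_datetime(fx["t"]), labels))
    return np.array(
        [lookup.get(pd.Timestamp(t), "general") for t in series["t"]], dtype=object
    )


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main())
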