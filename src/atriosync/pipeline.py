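"""End-to-end study orchestration.

``run_study`` drives synthesis -> preprocessing -> feature extraction ->
association analysis for a whole cohort across the three procedure phases
(pre-ablation, after left-pulmonary-vein isolation, post-ablation) and
emits:

* a per-feature, per-phase cohort Pearson table (raw and HR-adjusted
  features side by side),
* the cross-validated regression analogue (adjusted R2 per cell),
* the ablation-transition table: cross-patient correlation of each
  feature's percent change (including the rate-variability indices),
* the cross-quadratic sample entropy summary,
* a run log with seeds, options, and exclusion accounting.

Everything is deterministic under a fixed cohort seed: per-patient child
seeds are spawned from the master seed, regression fold seeds are derived
per (patient, phase, feature), and two identical runs write byte-identical
CSVs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlate import (CorrelationResult, ca_variation, cohort_correlation,
                        pearson, regression_cv, transition_correlation)
from .cqse import cohort_cqse
from .features import ARV_FEATURES, HRA_FEATURES, MORPH_FEATURES, extract_features
from .preprocess import (delineate, detect_ectopics, remove_baseline_wander,
                         remove_powerline)
from .records import CHANNELS, CS, PHASES, SURFACE, TRANSITIONS
from .synth import CohortConfig, generate_patient, patient_seeds

__all__ = ["StudyOptions", "StudyResult", "run_study", "render_report",
           "pair_activations", "duration_coupling_summary"]

ALL_ANALYSES = ("pearson", "regression", "transitions", "cqse")


@dataclass
class StudyOptions:
    """Knobs of the analysis stage (the generator has its own config)."""

    m: int = 1                 # CQSE template length
    r: float = 0.35            # CQSE tolerance (in sd units)
    k_folds: int = 10
    alpha: float = 0.05
    pooled: bool = False       # pool activations across patients instead of
                               # aggregating per-recording statistics
    waveforms: bool = True     # render samples; False = fiducial-level only
    preprocess: bool = True    # notch + high-pass before feature extraction
    use_truth_annotations: bool = True  # False: re-delineate from samples
    detect_ectopic_beats: bool = False  # True: re-detect even when the
                                        # annotations carry ectopic flags
    pair_tolerance_ms: float = 200.0
    analyses: tuple[str, ...] = ALL_ANALYSES


@dataclass
class StudyResult:
    tables: dict[str, pd.DataFrame]
    log: dict
    config: CohortConfig
    options: StudyOptions


def pair_activations(surface_ms: np.ndarray, cs_ms: np.ndarray,
                     tolerance_ms: float = 200.0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one nearest-peak matching of the two channels' activations.

    The median inter-channel delay is removed first; each invasive
    activation is then matched to the nearest unused surface activation
    within ``tolerance_ms``.  Returns (surface indices, invasive indices).
    """
    surface_ms = np.asarray(surface_ms, dtype=float)
    cs_ms = np.asarray(cs_ms, dtype=float)
    if len(surface_ms) == 0 or len(cs_ms) == 0:
        return np.array([], int), np.array([], int)
    nearest = np.clip(np.searchsorted(surface_ms, cs_ms), 0, len(surface_ms) - 1)
    alt = np.clip(nearest - 1, 0, len(surface_ms) - 1)
    pick = np.where(np.abs(surface_ms[alt] - cs_ms)
                    < np.abs(surface_ms[nearest] - cs_ms), alt, nearest)
    delay = float(np.median(cs_ms - surface_ms[pick]))
    target = cs_ms - delay
    used = np.zeros(len(surface_ms), dtype=bool)
    si, ci = [], []
    for j, t in enumerate(target):
        k = np.searchsorted(surface_ms, t)
        best, best_d = -1, tolerance_ms
        for cand in (k - 1, k):
            if 0 <= cand < len(surface_ms) and not used[cand]:
                d = abs(surface_ms[cand] - t)
                if d <= best_d:
                    best, best_d = cand, d
        if best >= 0:
            used[best] = True
            si.append(best)
            ci.append(j)
    return np.array(si, int), np.array(ci, int)


def duration_coupling_summary(config: CohortConfig, phase: str = "pre"
                              ) -> dict:
    """Raw vs HR-adjusted duration coupling across one phase of a cohort.

    The fast fiducial-level path: per patient, paired activation durations
    (raw ms and HR-adjusted) are correlated across channels, and the
    per-recording correlations are aggregated with the cohort rule
    (Shapiro-gated mean/median).  This is the summary behind the central
    claim that heart-rate fluctuation masks duration coupling that the
    adjustment recovers.
    """
    seeds = patient_seeds(config)
    out = {"raw": [], "hra": [], "latent_rho": []}
    for p_idx in range(config.n_patients):
        surf, cs, truth = generate_patient(config, phase, int(seeds[p_idx]),
                                           render=False)
        fs_surf = extract_features(surf)
        fs_cs = extract_features(cs)
        si, ci = pair_activations(surf.peak_times_ms(), cs.peak_times_ms())
        out["latent_rho"].append(truth.latent_rho)
        for feat, key in (("duration", "raw"), ("hra_duration", "hra")):
            x = fs_surf.table[feat].to_numpy(dtype=float)[si]
            y = fs_cs.table[feat].to_numpy(dtype=float)[ci]
            ok = np.isfinite(x) & np.isfinite(y)
            out[key].append(pearson(x[ok], y[ok]))
    out["raw_rho"] = cohort_correlation(out["raw"])[0]
    out["hra_rho"] = cohort_correlation(out["hra"])[0]
    return out


def _regression_seed(master: int, p: int, phase: str, f: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master) & 0x7FFFFFFF,
                                spawn_key=(p, PHASES.index(phase), f))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _prepare_recording(rec, options: StudyOptions, config: CohortConfig):
    """Filter, (re-)delineate and flag one channel; returns a FeatureSeries."""
    if rec.samples is not None and options.preprocess:
        x = remove_powerline(rec.samples, rec.fs, config.powerline_freq)
        x = remove_baseline_wander(x, rec.fs)
        rec.samples = x
    if not options.use_truth_annotations and rec.samples is not None:
        ann = delineate(rec.samples, rec.fs, rec.annotations[:, 1],
                        rec.channel_kind)
        rec.annotations = ann
        rec.ectopic_flags = None
    if (options.detect_ectopic_beats or rec.ectopic_flags is None) \
            and rec.n_activations >= 12:
        rec.ectopic_flags = detect_ectopics(rec.annotations, rec.fs)
    return rec


def run_study(config: CohortConfig, options: StudyOptions | None = None
              ) -> StudyResult:
    """Run the full cohort analysis; see the module docstring."""
    options = options or StudyOptions()
    feat_list = list(MORPH_FEATURES) + list(HRA_FEATURES) if options.waveforms \
        else ["duration", "hra_duration"]
    seeds = patient_seeds(config)

    per_rec_pearson: dict[tuple, list[CorrelationResult]] = {}
    per_rec_regr: dict[tuple, list] = {}
    per_rec_rows = []
    pooled_pairs: dict[tuple, list[tuple[np.ndarray, np.ndarray]]] = {}
    cqse_rows = []
    median_rows = []
    exclusions = {"unmatched_activations": 0, "first_beat_no_ibi": 0,
                  "ectopic_flagged": 0, "total_activations": 0,
                  "degenerate_feature_pairs": 0}

    for p_idx in range(config.n_patients):
        pid = f"P{p_idx:03d}"
        for phase in PHASES:
            surf, cs, truth = generate_patient(config, phase,
                                               int(seeds[p_idx]),
                                               render=options.waveforms)
            surf = _prepare_recording(surf, options, config)
            cs = _prepare_recording(cs, options, config)
            fs_surf = extract_features(surf, phase=phase, patient_id=pid)
            fs_cs = extract_features(cs, phase=phase, patient_id=pid)
            exclusions["total_activations"] += (surf.n_activations
                                                + cs.n_activations)
            for fseries in (fs_surf, fs_cs):
                flags = None
                if fseries.channel_kind == SURFACE:
                    flags = surf.ectopic_flags
                else:
                    flags = cs.ectopic_flags
                if flags is not None:
                    exclusions["ectopic_flagged"] += int(np.sum(flags))

            si, ci = pair_activations(surf.peak_times_ms(), cs.peak_times_ms(),
                                      options.pair_tolerance_ms)
            exclusions["unmatched_activations"] += (
                (surf.n_activations - len(si)) + (cs.n_activations - len(ci)))

            # per-recording medians (for transitions) incl. ARV scalars
            med = {"patient": pid, "phase": phase}
            for ch_name, fser in ((SURFACE, fs_surf), (CS, fs_cs)):
                for f in feat_list:
                    med[f"{ch_name}:{f}"] = float(fser.table[f].median())
                med[f"{ch_name}:sdnn"] = fser.arv.sdnn
                med[f"{ch_name}:varnn"] = fser.arv.varnn
                med[f"{ch_name}:rmssd"] = fser.arv.rmssd
            median_rows.append(med)

            for f_idx, f in enumerate(feat_list):
                xs = fs_surf.table[f].to_numpy(dtype=float)[si]
                ys = fs_cs.table[f].to_numpy(dtype=float)[ci]
                ok = np.isfinite(xs) & np.isfinite(ys)
                if f.startswith("hra_"):
                    exclusions["first_beat_no_ibi"] += int((~ok).sum())
                xs, ys = xs[ok], ys[ok]
                key = (phase, f)
                if len(xs) < max(3, 2 * options.k_folds) or np.ptp(xs) == 0 \
                        or np.ptp(ys) == 0:
                    exclusions["degenerate_feature_pairs"] += 1
                    continue
                rec_row = {"patient": pid, "phase": phase, "feature": f,
                           "n_pairs": len(xs)}
                if "pearson" in options.analyses:
                    res = pearson(xs, ys)
                    per_rec_pearson.setdefault(key, []).append(res)
                    rec_row["rho"] = res.rho
                    rec_row["p"] = res.p_value
                if "regression" in options.analyses:
                    rseed = _regression_seed(config.seed, p_idx, phase, f_idx)
                    reg = regression_cv(xs, ys, k=options.k_folds, seed=rseed)
                    per_rec_regr.setdefault(key, []).append(reg)
                    rec_row["r2_adjusted"] = reg.r2_adjusted
                per_rec_rows.append(rec_row)
                pooled_pairs.setdefault(key, []).append((xs, ys))
                if "cqse" in options.analyses:
                    cqse_rows.append({"patient": pid, "phase": phase,
                                      "feature": f, "surface": xs,
                                      "invasive": ys})

    tables: dict[str, pd.DataFrame] = {}
    medians = pd.DataFrame(median_rows)
    tables["recording_medians"] = medians
    tables["per_recording"] = pd.DataFrame(per_rec_rows)

    if "pearson" in options.analyses:
        tables["pearson"] = _cohort_table(per_rec_pearson, pooled_pairs,
                                          options, kind="pearson")
    if "regression" in options.analyses:
        tables["regression"] = _cohort_table(per_rec_regr, pooled_pairs,
                                             options, kind="regression")
    if "transitions" in options.analyses:
        tables["transition_cv"], tables["transitions"] = _transition_tables(
            medians, feat_list, options)
    if "cqse" in options.analyses and cqse_rows:
        cq_table, cq_summary = cohort_cqse(pd.DataFrame(cqse_rows),
                                           m=options.m, r=options.r)
        tables["cqse"] = cq_table
        tables["cqse_summary"] = cq_summary

    log = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "n_beats": config.n_beats,
        "version": __version__,
        "options": {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(options).items()},
        "exclusions": exclusions,
        "aggregation": "pooled" if options.pooled else "per_recording_median",
        "p_combination": "median of per-recording p-values",
        "features": feat_list,
    }
    return StudyResult(tables=tables, log=log, config=config, options=options)


def _cohort_table(per_rec: dict, pooled_pairs: dict, options: StudyOptions,
                  kind: str) -> pd.DataFrame:
    rows = []
    for (phase, f), results in sorted(per_rec.items(),
                                      key=lambda kv: (PHASES.index(kv[0][0]),
                                                      kv[0][1])):
        if options.pooled:
            xs = np.concatenate([x for x, _ in pooled_pairs[(phase, f)]])
            ys = np.concatenate([y for _, y in pooled_pairs[(phase, f)]])
            if kind == "pearson":
                res = pearson(xs, ys)
                stat, p, n = res.rho, res.p_value, res.n
            else:
                res = regression_cv(xs, ys, k=options.k_folds, seed=0)
                stat, p, n = res.r2_adjusted, res.p_value, len(xs)
        elif kind == "pearson":
            stat, p, n = cohort_correlation(results)
        else:
            stat = float(np.median([r.r2_adjusted for r in results]))
            p = float(np.median([r.p_value for r in results]))
            n = len(results)
        rows.append({"feature": f, "phase": phase,
                     "statistic": stat, "p": p, "n": n,
                     "significant": bool(p < options.alpha)})
    return pd.DataFrame(rows)


def _transition_tables(medians: pd.DataFrame, feat_list: list[str],
                       options: StudyOptions
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    cv_rows = []
    trans_features = feat_list + list(ARV_FEATURES)
    for pid, group in medians.groupby("patient", sort=True):
        by_phase = {row["phase"]: row for _, row in group.iterrows()}
        for before, after in TRANSITIONS:
            if before not in by_phase or after not in by_phase:
                continue
            tname = f"{before}->{after}"
            for f in trans_features:
                row = {"patient": pid, "feature": f, "transition": tname}
                for ch, col in ((SURFACE, "cv_surface"), (CS, "cv_invasive")):
                    b = by_phase[before][f"{ch}:{f}"]
                    a = by_phase[after][f"{ch}:{f}"]
                    row[col] = ca_variation(b, a)
                cv_rows.append(row)
    cv_table = pd.DataFrame(cv_rows)
    rows = []
    if len(cv_table):
        for (f, t), _ in cv_table.groupby(["feature", "transition"],
                                          sort=True):
            try:
                res = transition_correlation(cv_table, f, t)
            except ValueError:
                continue
            rows.append({"feature": f, "transition": t, "statistic": res.rho,
                         "p": res.p_value, "n": res.n,
                         "significant": bool(res.p_value < options.alpha)})
    return cv_table, pd.DataFrame(rows)


def render_report(result: StudyResult, outdir: str | Path,
                  plots: bool = True) -> list[Path]:
    """Write the result bundle as CSVs (+ optional PNG plots); returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    name_map = {"pearson": "pearson_by_phase.csv",
                "regression": "regression_by_phase.csv",
                "transitions": "transition_correlations.csv",
                "transition_cv": "transition_cv.csv",
                "cqse": "cqse.csv", "cqse_summary": "cqse_summary.csv",
                "recording_medians": "recording_medians.csv",
                "per_recording": "per_recording.csv"}
    for key, df in result.tables.items():
        path = outdir / name_map.get(key, f"{key}.csv")
        df.to_csv(path, index=False, float_format="%.6f")
        written.append(path)
    log_path = outdir / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(result.log, fh, indent=2, sort_keys=True)
    written.append(log_path)
    if plots:
        written += _render_plots(result, outdir)
    return written


def _render_plots(result: StudyResult, outdir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    if "pearson" in result.tables and len(result.tables["pearson"]):
        df = result.tables["pearson"]
        fig, ax = plt.subplots(figsize=(10, 4))
        piv = df.pivot(index="feature", columns="phase", values="statistic")
        piv = piv.reindex(columns=[p for p in PHASES if p in piv.columns])
        piv.plot.bar(ax=ax)
        ax.set_ylabel("median Pearson correlation (%)")
        ax.axhline(0, color="k", lw=0.5)
        fig.tight_layout()
        p = outdir / "fig_pearson_by_phase.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    if "transitions" in result.tables and len(result.tables["transitions"]):
        df = result.tables["transitions"]
        fig, ax = plt.subplots(figsize=(10, 4))
        piv = df.pivot(index="feature", columns="transition", values="statistic")
        piv.plot.bar(ax=ax)
        ax.set_ylabel("CV correlation (%)")
        ax.axhline(0, color="k", lw=0.5)
        fig.tight_layout()
        p = outdir / "fig_transition_cv.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    if "cqse" in result.tables and len(result.tables["cqse"]):
        df = result.tables["cqse"].dropna(subset=["cqse"])
        fig, ax = plt.subplots(figsize=(7, 4))
        groups = [g["cqse"].to_numpy() for _, g in df.groupby("phase",
                                                              sort=False)]
        labels = list(df.groupby("phase", sort=False).groups)
        if groups:
            ax.boxplot(groups, tick_labels=labels)
            for i, g in enumerate(groups, start=1):
                jitter = (np.arange(len(g)) % 7 - 3) * 0.02
                ax.plot(np.full(len(g), i) + jitter, g, ".", alpha=0.4, ms=3)
        ax.set_ylabel("CQSE (nats)")
        fig.tight_layout()
        p = outdir / "fig_cqse.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    return written
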