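"""End-to-end orchestration: simulate -> preprocess -> derive -> register
-> stack -> fit -> report.

A run is fully described by a :class:`RunConfig` (round-trippable to
YAML); every stochastic stage draws from the single run seed, so a
rerun with the same config reproduces every artifact bit for bit.
Outputs are plain CSV/JSON plus optional figures.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bands as bands_mod
from . import preprocess as pre
from . import registration as reg
from . import stats as st
from .containers import AverageResponse
from .dispersion import GroupDelayParams
from .simulate import BROADBAND, CohortData, SimCohortSpec, simulate_cohort

__all__ = ["RunConfig", "run_full", "make_fixtures", "extract_latencies"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a full analysis run."""

    cohort: dict = field(default_factory=dict)  # SimCohortSpec overrides
    block_size: int = 250
    zero_phase: bool = True
    reg_penalty: float = 0.05
    reg_knots: int = 10
    reg_max_iter: int = 10
    latency_source: str = "masked"  # masked | derived
    pick_halfwidth_ms: float = 1.5
    n_perm: int = 5000
    n_boot: int = 5000
    alpha: float = 0.05
    seed: int = 0
    outdir: str | None = None
    make_figures: bool = False

    def cohort_spec(self) -> SimCohortSpec:
        kw = dict(self.cohort)
        for key in ("dispersion", "chirp_params"):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = GroupDelayParams(**kw[key])
        kw.setdefault("seed", self.seed)
        return SimCohortSpec(**kw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _cross_sectional_mean(responses) -> AverageResponse:
    ref = responses[0]
    return ref.copy(values=np.mean([r.values for r in responses], axis=0))


def preprocess_cohort(cohort: CohortData, config: RunConfig) -> dict:
    """Average every (subject, stimulus, profile, cutoff) epoch set."""
    averages = {}
    for key, epochs in cohort.epochs.items():
        averages[key] = pre.preprocess_condition(
            epochs, block_size=config.block_size, zero_phase=config.zero_phase
        )
    return averages


def build_masked_sets(cohort: CohortData, averages: dict) -> dict:
    """Group averages into HighpassMaskedSets keyed by subject x condition."""
    sets = {}
    for subj in cohort.subjects:
        for kind, profile in cohort.spec.stimuli:
            masked = {
                c: averages[(subj.id, kind, profile, c)]
                for c in cohort.spec.cutoffs
            }
            bb = averages[(subj.id, kind, profile, BROADBAND)]
            sets[(subj.id, kind, profile)] = bands_mod.HighpassMaskedSet(
                masked=masked, broadband=bb,
                meta={"subject": subj.id, "stimulus": kind, "profile": profile},
            )
    return sets


def _expected_latency(spec: SimCohortSpec, wave: str, f_khz: float,
                      kind: str) -> float:
    tmpl = spec.wave_templates[wave]
    lat = tmpl.base_latency + spec.chirp_params.K * f_khz ** (-spec.chirp_params.D)
    if kind == "chirp":
        lat -= spec.chirp_params.K * f_khz ** (-spec.chirp_params.D)
    return lat


def extract_latencies(cohort: CohortData, masked_sets: dict,
                      config: RunConfig) -> pd.DataFrame:
    """Registration-based automatic latencies for every condition.

    For each stimulus condition and masking cutoff (or derived band,
    per ``config.latency_source``), the individual responses are
    registered to a structural average, waves I and V are picked once on
    it within windows centred on the design-prior latencies, and picks
    are mapped back through the inverse warps.
    """
    spec = cohort.spec
    subj_ids = [s.id for s in cohort.subjects]
    sex_of = {s.id: s.sex for s in cohort.subjects}
    labels = spec.band_labels
    freqs = spec.band_freqs
    rows = []
    for kind, profile in spec.stimuli:
        if config.latency_source == "derived":
            band_resps = {
                sid: bands_mod.derive_bands(masked_sets[(sid, kind, profile)])
                for sid in subj_ids
            }
            items = [
                (labels[b], freqs[b],
                 [band_resps[sid][b].response for sid in subj_ids])
                for b in range(spec.n_bands)
            ]
        else:  # highpass-masked latencies as derived-band proxies
            items = []
            for b, cutoff in enumerate(spec.cutoffs):
                resps = [masked_sets[(sid, kind, profile)].masked[cutoff]
                         for sid in subj_ids]
                items.append((labels[b], freqs[b], resps))
            resps = [masked_sets[(sid, kind, profile)].broadband
                     for sid in subj_ids]
            items.append((labels[-1], freqs[-1], resps))
        for label, f_khz, resps in items:
            hw = config.pick_halfwidth_ms
            windows = {
                w: (
                    _expected_latency(spec, w, f_khz, kind) - hw,
                    _expected_latency(spec, w, f_khz, kind) + hw,
                )
                for w in spec.wave_templates
            }
            win_hi = max(hi for _, hi in windows.values()) + 2.0
            # picks must stay inside the registered window for the
            # inverse warp to be defined
            windows = {
                w: (max(lo, 0.05), min(hi, win_hi - 0.05))
                for w, (lo, hi) in windows.items()
            }
            result = reg.register(
                resps, penalty=config.reg_penalty, n_knots=config.reg_knots,
                max_iter=config.reg_max_iter, window_ms=(0.0, win_hi),
            )
            picks = reg.pick_peaks(result.structural_average, windows)
            lat = reg.individual_latencies(
                result.warps, picks, ids=subj_ids,
                meta={"stimulus": kind, "profile": profile,
                      "band": float(label), "f": float(f_khz)},
            )
            rows.append(lat)
    table = pd.concat(rows, ignore_index=True)
    table["sex"] = table["subject"].map(sex_of)
    return table


def stack_analyses(cohort: CohortData, masked_sets: dict, latencies: pd.DataFrame,
                   config: RunConfig) -> dict:
    """Average- vs individual-stacked ABRs and their effective means."""
    spec = cohort.spec
    out = {}
    for kind, profile in spec.stimuli:
        sub = latencies[(latencies.stimulus == kind)
                        & (latencies.profile == profile)]
        avg_lat = {
            w: sub[sub.wave == w].groupby("band")["latency_ms"].mean()
            for w in spec.wave_templates
        }
        # one alignment latency shared by every subject and both stacking
        # modes, so across-subject comparisons see a common time base
        reference = float(avg_lat["V"].mean())
        per_subject = {"average": [], "individual": []}
        for sid in sorted({s.id for s in cohort.subjects}):
            dbs = bands_mod.derive_bands(masked_sets[(sid, kind, profile)])
            me = sub[sub.subject == sid]
            ind_lat = {
                w: me[me.wave == w].set_index("band")["latency_ms"]
                for w in spec.wave_templates
            }
            for mode, lats in (("average", avg_lat), ("individual", ind_lat)):
                lat_I = lats["I"].reindex(dbs.labels)
                lat_V = lats["V"].reindex(dbs.labels)
                if lat_I.isna().any() or lat_V.isna().any():
                    continue
                stacked = bands_mod.stack_spliced(
                    dbs, lat_I.to_dict(), lat_V.to_dict(),
                    reference=reference, mode=mode,
                )
                per_subject[mode].append(stacked)
        cond = {}
        for mode, stacks in per_subject.items():
            if len(stacks) >= 2:
                cond[mode] = {
                    "mean": _cross_sectional_mean([s.response for s in stacks]),
                    "effective_mean": bands_mod.effective_mean(stacks),
                    "n": len(stacks),
                    "stacks": stacks,
                }
        out[(kind, profile)] = cond
    return out


def run_full(config: RunConfig) -> dict:
    """Execute the complete analysis on a simulated cohort.

    Returns a report dict with the latency tables, dispersion fits,
    model comparisons, stacking summaries and amplitude statistics;
    writes CSV/JSON artifacts (and figures on request) to
    ``config.outdir`` when set.
    """
    spec = config.cohort_spec()
    cohort = simulate_cohort(spec)
    averages = preprocess_cohort(cohort, config)
    masked_sets = build_masked_sets(cohort, averages)
    latencies = extract_latencies(cohort, masked_sets, config)

    report: dict = {"config": asdict(config), "n_subjects": len(cohort.subjects)}
    report["latencies"] = latencies
    report["truth"] = cohort.truth

    # dispersion model: null (A by wave) vs K,D varying by wave and sex
    fit_table = latencies.copy()
    if {"click", "chirp"} <= set(fit_table.stimulus.unique()):
        fit_table = st.adjust_chirp_latencies(fit_table)
        report["chirp_adjustment_ms"] = fit_table.attrs["chirp_adjustment_ms"]
    strata_null = {"A": ["wave", "sex", "wave:sex"]}
    strata_alt = {"A": ["wave", "sex", "wave:sex"],
                  "K": ["wave", "sex"], "D": ["wave", "sex"]}
    fit_null = st.fit_dispersion(fit_table, strata=strata_null)
    fit_alt = st.fit_dispersion(fit_table, strata=strata_alt)
    comparison = st.compare_models(fit_null, fit_alt)
    report["fit_null"] = fit_null
    report["fit_alt"] = fit_alt
    report["dispersion_test"] = comparison

    # stacked ABRs and effective means
    stacks = stack_analyses(cohort, masked_sets, latencies, config)
    report["stacks"] = stacks
    tmax_results = {}
    for cond, modes in stacks.items():
        if {"average", "individual"} <= set(modes):
            pairs = zip(modes["individual"]["stacks"], modes["average"]["stacks"])
            diffs = [
                i.response.copy(values=i.response.values - a.response.values)
                for i, a in pairs
            ]
            tmax_results[cond] = st.tmax_permutation(
                diffs, n_perm=config.n_perm, alpha=config.alpha,
                seed=np.random.default_rng([config.seed, 1]),
            )
    report["tmax_individual_vs_average"] = tmax_results

    # derived-band aggregate amplitudes and chirp benefit per band
    benefit = _chirp_benefit_table(cohort, masked_sets, config)
    report["chirp_benefit"] = benefit

    if config.outdir:
        _write_outputs(report, config)
    return report


def _chirp_benefit_table(cohort: CohortData, masked_sets: dict,
                         config: RunConfig) -> pd.DataFrame | None:
    """Per-band chirp benefit on the aggregate absolute amplitude.

    Click- and chirp-evoked band responses live in different time ranges
    (the chirp undoes the cochlear delay), so all responses of a band
    are first aligned by curve registration to a joint target; the
    aggregate |amplitude| is then integrated over the standard 2-9 ms
    window on the aligned waveforms and expressed per subject as a
    percentage of the click aggregate.
    """
    spec = cohort.spec
    profiles = {p for k, p in spec.stimuli}
    sids = sorted({s.id for s in cohort.subjects})
    rows = []
    for profile in sorted(profiles):
        kinds = {k for k, p in spec.stimuli if p == profile}
        if not {"click", "chirp"} <= kinds:
            continue
        dbs = {
            (sid, k): bands_mod.derive_bands(masked_sets[(sid, k, profile)])
            for sid in sids for k in ("click", "chirp")
        }
        for b, label in enumerate(dbs[(sids[0], "click")].labels):
            # undo the known stimulus group-delay advance of the chirp
            # responses (a pure time shift; aggregates are shift-invariant)
            # so registration only has to absorb jitter-scale offsets
            advance = spec.chirp_params.K * spec.band_freqs[b] ** (
                -spec.chirp_params.D)
            resps = [dbs[(sid, "click")][b].response for sid in sids] + [
                bands_mod.time_shift(dbs[(sid, "chirp")][b].response, advance)
                for sid in sids
            ]
            result = reg.register(
                resps, penalty=config.reg_penalty, n_knots=config.reg_knots,
                max_iter=config.reg_max_iter, window_ms=(0.0, 14.0),
            )
            grid = resps[0].times_ms
            sel = (grid >= 0.0) & (grid <= 14.0)
            aligned = []
            for resp, warp in zip(resps, result.warps):
                vals = resp.values.copy()
                vals[sel] = np.interp(warp.to_individual(grid[sel]),
                                      grid[sel], resp.values[sel])
                aligned.append(resp.copy(values=vals))
            n = len(sids)
            benefits = []
            for i, sid in enumerate(sids):
                agg_click = st.aggregate_amplitude(aligned[i], (2.0, 9.0))
                agg_chirp = st.aggregate_amplitude(aligned[n + i], (2.0, 9.0))
                if agg_click > 0:
                    benefits.append(st.chirp_benefit(agg_click, agg_chirp))
            if len(benefits) >= 2:
                mean, se = st.bootstrap_se(
                    np.asarray(benefits), n_boot=config.n_boot,
                    seed=np.random.default_rng([config.seed, 2]))
                rows.append({"profile": profile, "band": float(label),
                             "benefit_pct": mean, "se_pct": se,
                             "n": len(benefits)})
    return pd.DataFrame(rows) if rows else None


def _write_outputs(report: dict, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report["latencies"].to_csv(outdir / "latencies.csv", index=False)
    report["truth"].to_csv(outdir / "truth.csv", index=False)
    if report.get("chirp_benefit") is not None:
        report["chirp_benefit"].to_csv(outdir / "chirp_benefit.csv", index=False)
    summary = {
        "n_subjects": report["n_subjects"],
        "seed": config.seed,
        "zero_phase": config.zero_phase,
        "latency_source": config.latency_source,
        "fit_null": {"bic": report["fit_null"].bic,
                     "llf": report["fit_null"].llf},
        "fit_alt": {"bic": report["fit_alt"].bic,
                    "llf": report["fit_alt"].llf,
                    "params": report["fit_alt"].params.to_dict()},
        "dispersion_test": {
            "chi2": report["dispersion_test"].statistic,
            "df": report["dispersion_test"].df,
            "p": report["dispersion_test"].pvalue,
            "bf": report["dispersion_test"].bf_label(),
        },
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=1))
    (outdir / "fit_alt_summary.txt").write_text(report["fit_alt"].summary())
    if config.make_figures:
        _figures(report, outdir)


def _figures(report: dict, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lat = report["latencies"]
    fig, ax = plt.subplots(figsize=(6, 4))
    for (kind, wave), sub in lat.groupby(["stimulus", "wave"]):
        mean = sub.groupby("band")["latency_ms"].mean()
        ax.plot(mean.index, mean.values, marker="o", label=f"{kind} wave {wave}")
    ax.set_xscale("log")
    ax.set_xlabel("band centre frequency (kHz)")
    ax.set_ylabel("latency (ms)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "latencies.png", dpi=120)
    plt.close(fig)

    for cond, modes in report["stacks"].items():
        if {"average", "individual"} <= set(modes):
            fig, ax = plt.subplots(figsize=(6, 4))
            for mode in ("average", "individual"):
                em = modes[mode]["effective_mean"]
                ax.plot(em.times_ms, em.values, label=f"{mode}-stacked")
            ax.set_xlim(0, 12)
            ax.set_xlabel("time (ms)")
            ax.set_ylabel("effective mean (mean / SD)")
            ax.legend()
            fig.tight_layout()
            fig.savefig(outdir / f"effective_mean_{cond[0]}_{cond[1]}.png",
                        dpi=120)
            plt.close(fig)


def make_fixtures(scale: str = "tiny", seed: int = 0,
                  outdir: str | Path | None = None) -> CohortData:
    """Generate a small packaged synthetic dataset for tests and demos.

    ``tiny`` (4 subjects, 20 sweeps, white stimuli only) generates in a
    few seconds; ``default`` is a mid-sized cohort for smoke-testing the
    statistics.  Deterministic given ``seed``.
    """
    if scale == "tiny":
        spec = SimCohortSpec(
            n_F=2, n_M=2, n_epochs=20, epoch_noise_sd=0.5,
            stimuli=(("click", "white"), ("chirp", "white")), seed=seed,
        )
    elif scale == "default":
        spec = SimCohortSpec(n_F=6, n_M=6, n_epochs=200, epoch_noise_sd=2.0,
                             seed=seed)
    else:
        raise ValueError(f"unknown fixture scale {scale!r}")
    cohort = simulate_cohort(spec)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort.truth.to_csv(outdir / "truth.csv", index=False)
        manifest = {"scale": scale, "seed": seed,
                    "n_subjects": len(cohort.subjects),
                    "conditions": [list(map(str, k)) for k in cohort.epochs]}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for (sid, kind, profile, cutoff), es in cohort.epochs.items():
            cname = "inf" if math.isinf(cutoff) else f"{cutoff:g}"
            df = pd.DataFrame(es.data.T)
            df.insert(0, "time_ms", es.times_ms)
            df.to_csv(outdir / f"{sid}_{kind}_{profile}_hp{cname}.csv",
                      index=False)
    return cohort
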