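"""End-to-end workflow: simulate → preprocess → reject → ERD/HR → stats → report.

The fixed stage order is: load/generate → Laplacian (foot/Cz derivation) →
EMG rejection → EEG epoching → subject-band selection (on the
motor-execution block) → ERD curves/maps → QRS detection → instantaneous
HR → HR epoching → iterative IQR rejection → HR responses → hypothetical
(go−nogo) HR → feature table → group statistics → figures.  Every stage logs
input/output counts; the configuration, seeds and a config hash are embedded
in all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cardiac, erd, rejection, stats, synthetic
from .errors import MicardiaError, ParameterError
from .montage import FOOT_DERIVATION
from .session import GO, NOGO, Session, epoch, laplacian

logger = logging.getLogger(__name__)

#: reference-mode name -> window in seconds relative to cue onset.
#: 'pre10' ("1–0 s prior") and 'pre01' ("0–1 s prior") are the same interval
#: written in opposite order; both names are accepted.
REFERENCE_MODES = {"pre24": (-4.0, -2.0), "pre10": (-1.0, 0.0), "pre01": (-1.0, 0.0)}

CONDITIONS = (GO, NOGO)


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run depends on."""

    n_subjects: int = 16
    seed: int = 0
    paradigm: synthetic.ParadigmSpec = field(default_factory=synthetic.ParadigmSpec)
    effects: synthetic.EffectSpec = field(default_factory=synthetic.EffectSpec)
    reference_mode: str = "pre24"
    epoch_window: tuple[float, float] = (-5.0, 6.0)
    rebound_window: tuple[float, float] = (0.5, 2.5)
    search_window: tuple[float, float] = (0.0, 1.0)
    alpha: float = 0.05
    n_resamples: int = 500
    band_selection: bool = True      # select from an ME block; else planted band
    artifact_fraction: float = 0.1
    make_tf_maps: bool = True        # time-frequency maps for the first subject
    session_paths: list[str] | None = None  # analyse real files instead of simulating

    def __post_init__(self) -> None:
        if self.reference_mode not in REFERENCE_MODES:
            raise ParameterError(
                f"reference_mode must be one of {sorted(REFERENCE_MODES)}"
            )
        ref = REFERENCE_MODES[self.reference_mode]
        if ref[0] < self.epoch_window[0] or ref[1] > self.epoch_window[1]:
            raise ParameterError("reference window must lie inside the epoch window")

    @property
    def reference_window(self) -> tuple[float, float]:
        return REFERENCE_MODES[self.reference_mode]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "paradigm" in d and isinstance(d["paradigm"], dict):
            d["paradigm"] = synthetic.ParadigmSpec(**d["paradigm"])
        if "effects" in d and isinstance(d["effects"], dict):
            eff = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["effects"].items()
            }
            d["effects"] = synthetic.EffectSpec(**eff)
        for key in ("epoch_window", "rebound_window", "search_window"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        import yaml

        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


@dataclass
class SubjectResult:
    """One subject's per-condition curves and bookkeeping."""

    erd_curves: dict[str, erd.ErdCurve]
    hr_responses: dict[str, cardiac.HrResponse]
    hypothetical: cardiac.HrResponse | None
    band: tuple[float, float]
    rejection: rejection.RejectionReport
    truth: synthetic.GroundTruth | None = None


@dataclass
class Bundle:
    """Everything the pipeline computed for one cohort run."""

    config: RunConfig
    subjects: list[SubjectResult]
    times: np.ndarray
    grand_erd: dict[str, stats.BootstrapBand]
    grand_hr: dict[str, stats.BootstrapBand]
    grand_hypothetical: stats.BootstrapBand | None
    erd_comparison: tuple[stats.BootstrapBand, float | None] | None
    hr_comparison: tuple[stats.BootstrapBand, float | None] | None
    feature_table: pd.DataFrame
    feature_summary: pd.DataFrame
    paired_tests: dict[str, tuple[float, float, int]]
    correlations: dict[str, tuple[float, float]]
    tf_maps: dict[str, erd.ErdMap] | None

    def to_dir(self, out_dir: str | Path) -> Path:
        """Serialise curves, tables and provenance as TSV/JSON text files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg_hash = self.config.hash()
        prov = {"config": self.config.to_dict(), "config_hash": cfg_hash}
        (out / "provenance.json").write_text(
            json.dumps(prov, indent=1, sort_keys=True, default=str)
        )

        def band_frame(band: stats.BootstrapBand) -> pd.DataFrame:
            return pd.DataFrame(
                {
                    "time_s": self.times,
                    "mean": band.mean,
                    "lower": band.lower,
                    "upper": band.upper,
                    "significant": band.significant.astype(int),
                }
            )

        for cond, band in self.grand_erd.items():
            band_frame(band).to_csv(
                out / f"grand_erd_{cond}.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
        for cond, band in self.grand_hr.items():
            band_frame(band).to_csv(
                out / f"grand_hr_{cond}.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
        if self.grand_hypothetical is not None:
            band_frame(self.grand_hypothetical).to_csv(
                out / "grand_hr_hypothetical.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
        self.feature_table.to_csv(
            out / "feature_table.tsv", sep="\t", index=False, float_format="%.10g"
        )
        self.feature_summary.to_csv(
            out / "feature_summary.tsv", sep="\t", float_format="%.10g"
        )
        rej = pd.concat(
            [s.rejection.table.assign(subject=i) for i, s in enumerate(self.subjects)],
            ignore_index=True,
        )
        rej.to_csv(out / "rejection_report.tsv", sep="\t", index=False)
        tests = {
            "paired_t": {k: list(v) for k, v in self.paired_tests.items()},
            "pearson": {k: list(v) for k, v in self.correlations.items()},
            "erd_difference_earliest_s": (
                None if self.erd_comparison is None else self.erd_comparison[1]
            ),
            "hr_difference_earliest_s": (
                None if self.hr_comparison is None else self.hr_comparison[1]
            ),
            "config_hash": cfg_hash,
        }
        (out / "group_tests.json").write_text(
            json.dumps(tests, indent=1, sort_keys=True)
        )
        return out


def analyse_subject(
    session: Session,
    config: RunConfig,
    band: tuple[float, float],
    truth: synthetic.GroundTruth | None = None,
) -> SubjectResult:
    """Run the full single-subject analysis chain on one MI session."""
    fs = session.sample_rate_hz
    ref = config.reference_window
    lap = laplacian(session, FOOT_DERIVATION)

    erd_curves: dict[str, erd.ErdCurve] = {}
    hr_resps: dict[str, cardiac.HrResponse] = {}
    reports: list[rejection.RejectionReport] = []

    beats = cardiac.detect_qrs(session.ecg, fs)
    hr = cardiac.hr_signal(beats, session.n_samples, fs)
    logger.info("detected %d beats", len(beats))

    present = [c for c in CONDITIONS if (session.events["label"] == c).any()]
    for cond in present:
        emg_l = epoch(session.emg[0], session.events, fs, config.epoch_window, cond)
        emg_r = epoch(session.emg[1], session.events, fs, config.epoch_window, cond)
        keep_emg, rep_emg = rejection.emg_reject(emg_l, emg_r, cond)

        eeg_ep = epoch(
            lap, session.events, fs, config.epoch_window, cond, FOOT_DERIVATION
        )
        erd_curves[cond] = erd.erd_timecourse(
            eeg_ep.subset(keep_emg), band, ref, alpha=config.alpha
        )

        hr_ep = cardiac.hr_epochs(hr, session.events, cond, config.epoch_window)
        hr_surv = hr_ep.subset(keep_emg)
        keep_iqr, rep_iqr = rejection.hr_iqr_reject(hr_surv, cond)
        hr_resps[cond] = cardiac.hr_response(
            hr_surv.subset(keep_iqr), reference_window=ref
        )
        # stitch IQR provenance back into the per-trial EMG report
        table = rep_emg.table.copy()
        surv_idx = np.flatnonzero(keep_emg)
        table.loc[surv_idx[~keep_iqr], "rule"] = rejection.RULE_HR_IQR
        table.loc[surv_idx[~keep_iqr], "keep"] = False
        table.loc[surv_idx, "iteration"] = rep_iqr.table["iteration"].to_numpy()
        reports.append(rejection.RejectionReport(table))

    hypo = None
    if GO in hr_resps and NOGO in hr_resps:
        hypo = cardiac.hypothetical_hr(hr_resps[GO], hr_resps[NOGO])
    else:
        logger.warning("only one condition present: hypothetical HR stage skipped")

    report = reports[0]
    for r in reports[1:]:
        report = report.merge(r)
    return SubjectResult(
        erd_curves=erd_curves,
        hr_responses=hr_resps,
        hypothetical=hypo,
        band=band,
        rejection=report,
        truth=truth,
    )


def run_pipeline(config: RunConfig | None = None) -> Bundle:
    """Run the whole workflow on a (generated or loaded) cohort."""
    config = config or RunConfig()
    rng_seed = np.random.SeedSequence(config.seed)

    if config.session_paths:
        from .session import read_session

        sessions = [(read_session(p), None) for p in config.session_paths]
    else:
        sessions = synthetic.generate_cohort(
            config.n_subjects,
            config.paradigm,
            config.effects,
            seed=config.seed,
            artifact_fraction=config.artifact_fraction,
        )
    logger.info("pipeline: %d sessions", len(sessions))

    subjects: list[SubjectResult] = []
    for i, (session, truth) in enumerate(sessions):
        if config.band_selection and truth is not None:
            # band selection runs on the subject's motor-execution block
            me_session, _ = synthetic.generate_session(
                config.paradigm,
                truth.effects,
                seed=np.random.SeedSequence(entropy=(config.seed, 1000 + i)),
                mode="me",
                artifact_fraction=0.0,
                modalities=("eeg",),
            )
            me_lap = laplacian(me_session, FOOT_DERIVATION)
            me_go = epoch(
                me_lap, me_session.events, me_session.sample_rate_hz,
                config.epoch_window, GO, FOOT_DERIVATION,
            )
            sel = erd.select_band(
                me_go, config.rebound_window, config.reference_window
            )
            band = sel.band
        elif truth is not None:
            band = truth.beta_band_hz
        else:
            band = config.effects.beta_band_hz
        logger.info("subject %d: band %s", i, band)
        subjects.append(analyse_subject(session, config, band, truth))

    times = subjects[0].erd_curves[next(iter(subjects[0].erd_curves))].times
    boot_seeds = rng_seed.spawn(8)

    def stack(getter) -> dict[str, np.ndarray]:
        out = {}
        for cond in CONDITIONS:
            rows = [getter(s, cond) for s in subjects if getter(s, cond) is not None]
            if rows:
                out[cond] = np.vstack(rows)
        return out

    erd_stack = stack(lambda s, c: s.erd_curves[c].values if c in s.erd_curves else None)
    hr_stack = stack(lambda s, c: s.hr_responses[c].values if c in s.hr_responses else None)

    grand_erd = {
        c: stats.tpercentile_bootstrap(v, config.alpha, config.n_resamples, np.random.default_rng(boot_seeds[0]))
        for c, v in erd_stack.items()
    }
    grand_hr = {
        c: stats.tpercentile_bootstrap(v, config.alpha, config.n_resamples, np.random.default_rng(boot_seeds[1]))
        for c, v in hr_stack.items()
    }
    grand_hypo = None
    erd_cmp = hr_cmp = None
    if GO in erd_stack and NOGO in erd_stack and len(subjects) >= 2:
        hyp_rows = np.vstack([s.hypothetical.values for s in subjects if s.hypothetical])
        grand_hypo = stats.tpercentile_bootstrap(
            hyp_rows, config.alpha, config.n_resamples, np.random.default_rng(boot_seeds[2])
        )
        erd_cmp = stats.compare_conditions(
            erd_stack[GO], erd_stack[NOGO], config.alpha, config.n_resamples,
            np.random.default_rng(boot_seeds[3]), times,
        )
        hr_cmp = stats.compare_conditions(
            hr_stack[GO], hr_stack[NOGO], config.alpha, config.n_resamples,
            np.random.default_rng(boot_seeds[4]), times,
        )

    feature_table = stats.build_feature_table(
        {i: s.erd_curves for i, s in enumerate(subjects)},
        {i: s.hr_responses for i, s in enumerate(subjects)},
        conditions=tuple(c for c in CONDITIONS if c in erd_stack),
        search_window=config.search_window,
    )
    feature_summary = stats.summarize_features(feature_table)

    paired = {}
    corr = {}
    if GO in erd_stack and NOGO in erd_stack and len(subjects) >= 2:
        piv = feature_table.pivot(index="subject", columns="condition")
        paired["erd_amplitude"] = stats.paired_t(
            piv[("erd_amplitude_pct", GO)], piv[("erd_amplitude_pct", NOGO)]
        )
        paired["hr_amplitude"] = stats.paired_t(
            piv[("hr_amplitude_pct", GO)], piv[("hr_amplitude_pct", NOGO)]
        )
        if len(subjects) >= 3:
            for cond in CONDITIONS:
                try:
                    corr[cond] = stats.pearson_r(
                        piv[("erd_amplitude_pct", cond)], piv[("hr_amplitude_pct", cond)]
                    )
                except MicardiaError:
                    pass

    tf_maps = None
    if config.make_tf_maps:
        session0, _ = sessions[0]
        lap0 = laplacian(session0, FOOT_DERIVATION)
        tf_maps = {}
        for cond in [c for c in CONDITIONS if (session0.events["label"] == c).any()]:
            ep0 = epoch(
                lap0, session0.events, session0.sample_rate_hz,
                config.epoch_window, cond, FOOT_DERIVATION,
            )
            tf_maps[cond] = erd.tf_map(
                ep0, config.reference_window, alpha=config.alpha
            )

    return Bundle(
        config=config,
        subjects=subjects,
        times=times,
        grand_erd=grand_erd,
        grand_hr=grand_hr,
        grand_hypothetical=grand_hypo,
        erd_comparison=erd_cmp,
        hr_comparison=hr_cmp,
        feature_table=feature_table,
        feature_summary=feature_summary,
        paired_tests=paired,
        correlations=corr,
        tf_maps=tf_maps,
    )


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


def render_report(bundle: Bundle, out_dir: str | Path) -> Path:
    """Figures and a markdown summary for one bundle.

    Panels follow the conventions of the field's standard displays: ERD in
    red / ERS in blue on the time–frequency maps (significant cells only),
    grand-average HR over ERD with significance asterisks (one row p<0.05,
    two rows p<0.01), the first-second go/nogo ERD comparison, the HR
    go/nogo/difference panel, and the ERD-vs-HR scatter.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    times = bundle.times
    figures = []

    if bundle.tf_maps:
        fig, axes = plt.subplots(
            1, len(bundle.tf_maps), figsize=(6 * len(bundle.tf_maps), 4), squeeze=False
        )
        for ax, (cond, tfm) in zip(axes[0], bundle.tf_maps.items()):
            centers = [0.5 * (a + b) for a, b in tfm.bands]
            vmax = np.nanmax(np.abs(tfm.values)) or 1.0
            ax.pcolormesh(
                tfm.times, centers, tfm.masked(),
                cmap="RdBu", vmin=-vmax, vmax=vmax, shading="nearest",
            )
            ax.axvline(0.0, color="k", lw=0.8)
            ax.set(title=f"{cond} (significant cells)", xlabel="time vs cue (s)",
                   ylabel="frequency (Hz)")
        fig.tight_layout()
        p = out / "fig_tf_maps.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        figures.append(p.name)

    def _asterisks(ax, band: stats.BootstrapBand, y: float) -> None:
        sig = band.significant
        if sig.any():
            ax.plot(times[sig], np.full(sig.sum(), y), "k*", ms=3)

    if bundle.grand_erd and bundle.grand_hr:
        conds = list(bundle.grand_erd)
        fig, axes = plt.subplots(2, len(conds), figsize=(6 * len(conds), 6), squeeze=False)
        for j, cond in enumerate(conds):
            hrb = bundle.grand_hr.get(cond)
            erdb = bundle.grand_erd[cond]
            if hrb is not None:
                axes[0, j].plot(times, hrb.mean, "k")
                axes[0, j].plot(times, hrb.lower, "k:", lw=0.8)
                axes[0, j].plot(times, hrb.upper, "k:", lw=0.8)
                _asterisks(axes[0, j], hrb, float(np.nanmax(hrb.upper)) * 1.05)
                axes[0, j].set(title=f"HR {cond}", ylabel="HR change (%)")
            axes[1, j].plot(times, erdb.mean, "k")
            axes[1, j].plot(times, erdb.lower, "k:", lw=0.8)
            axes[1, j].plot(times, erdb.upper, "k:", lw=0.8)
            _asterisks(axes[1, j], erdb, float(np.nanmax(erdb.upper)) * 1.05)
            axes[1, j].set(title=f"beta power {cond}", xlabel="time vs cue (s)",
                           ylabel="power change (%)")
            for ax in axes[:, j]:
                ax.axvline(0.0, color="0.6", lw=0.8)
        fig.tight_layout()
        p = out / "fig_grand_hr_erd.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        figures.append(p.name)

    if bundle.erd_comparison is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        mask = (times >= -0.1) & (times <= 1.0)
        for cond, ls in ((GO, "--"), (NOGO, "-")):
            ax.plot(times[mask], bundle.grand_erd[cond].mean[mask], "k" + ls, label=cond)
        band, earliest = bundle.erd_comparison
        sig = band.significant & mask
        if sig.any():
            ax.plot(times[sig], np.full(sig.sum(), 2.0), "k*", ms=4)
        title = "beta power, first second"
        if earliest is not None:
            title += f" (difference significant from {earliest * 1000:.0f} ms)"
        ax.set(title=title, xlabel="time vs cue (s)", ylabel="power change (%)")
        ax.legend()
        fig.tight_layout()
        p = out / "fig_first_second_erd.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        figures.append(p.name)

    if bundle.grand_hypothetical is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(times, bundle.grand_hr[GO].mean, label="go")
        ax.plot(times, bundle.grand_hr[NOGO].mean, label="nogo")
        ax.plot(times, bundle.grand_hypothetical.mean, "k", label="difference")
        if bundle.hr_comparison is not None:
            _asterisks(ax, bundle.hr_comparison[0],
                       float(np.nanmax(bundle.grand_hypothetical.mean)) * 1.1)
        ax.axvline(0.0, color="0.6", lw=0.8)
        ax.set(title="HR responses and hypothetical difference",
               xlabel="time vs cue (s)", ylabel="HR change (%)")
        ax.legend()
        fig.tight_layout()
        p = out / "fig_hr_difference.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        figures.append(p.name)

    if len(bundle.feature_table):
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), squeeze=False)
        for ax, cond in zip(axes[0], CONDITIONS):
            sub = bundle.feature_table[bundle.feature_table["condition"] == cond]
            if len(sub):
                ax.scatter(sub["erd_amplitude_pct"], sub["hr_amplitude_pct"], c="k", s=18)
                r = bundle.correlations.get(cond)
                suffix = f" (r={r[0]:.2f}, p={r[1]:.2f})" if r else ""
                ax.set(title=f"{cond}{suffix}", xlabel="early beta ERD (%)",
                       ylabel="brisk HR change (%)")
        fig.tight_layout()
        p = out / "fig_erd_hr_scatter.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        figures.append(p.name)

    lines = [
        "# Cohort analysis report",
        "",
        f"Config hash: `{bundle.config.hash()}` — seed {bundle.config.seed}, "
        f"{len(bundle.subjects)} subjects, reference mode "
        f"`{bundle.config.reference_mode}` {bundle.config.reference_window} s.",
        "",
        "## Feature summary (mean ± SD across subjects)",
        "",
        bundle.feature_summary.round(2).to_markdown(),
        "",
        "## Group tests",
        "",
    ]
    for name, (t, p, df) in bundle.paired_tests.items():
        lines.append(f"- paired t ({name}, go vs nogo): t({df}) = {t:.2f}, p = {p:.3g}")
    for cond, (r, p) in bundle.correlations.items():
        lines.append(f"- Pearson ERD vs HR ({cond}): r = {r:.2f}, p = {p:.2f}")
    if bundle.erd_comparison is not None and bundle.erd_comparison[1] is not None:
        lines.append(
            f"- earliest significant go/nogo ERD difference: "
            f"{bundle.erd_comparison[1] * 1000:.0f} ms after cue onset"
        )
    lines += ["", "## Figures", ""]
    lines += [f"![{name}]({name})" for name in figures]
    lines += [
        "",
        "## Rejection",
        "",
        pd.concat([s.rejection.summary() for s in bundle.subjects])
        .groupby("condition").sum().to_markdown(),
        "",
    ]
    report_path = out / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
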