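"""End-to-end orchestration: release fitting -> PK -> NCA -> PK/PD -> dosing.

``analyze`` runs whatever stages the configuration enables and collects the
results in an :class:`AnalysisReport`.  Every concentration-derived number
is labelled with its provenance — fitted from profile data, or
reconstructed from printed summary parameters — because the two routes
answer different questions and must never be mixed silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .bateman import OneCompartmentFit, calibrate_from_summary, fit_bateman
from .dosing import DosingRegimen, DosingSimulation, superpose
from .io import RunConfig, read_conc_csv, read_release_csv, write_table
from .nca import NCAResult, relative_bioavailability, run_nca
from .pkpd import PkPdReport, build_report
from .release import DEFAULT_MODELS, ReleaseFitResult, select_best_model

__all__ = ["ArmResult", "AnalysisReport", "analyze"]


@dataclass
class ArmResult:
    arm: str
    fit: OneCompartmentFit
    fit_source: str  # "profile" or "summary"
    nca: Optional[NCAResult]
    pkpd: PkPdReport
    dosing: Optional[DosingSimulation]
    auc_0_24: float
    dose: float = 1.0


@dataclass
class AnalysisReport:
    config: RunConfig
    release_ranking: list = field(default_factory=list)
    arms: dict = field(default_factory=dict)
    relative_bioavailability: Optional[float] = None
    notes: list = field(default_factory=list)

    def ranking_table(self) -> pd.DataFrame:
        rows = []
        for r in self.release_ranking:
            row = {
                "model": r.model_name,
                "r_squared": r.r_squared,
                "n_value": r.n_value,
                "mechanism": r.mechanism.label if r.mechanism else None,
                "converged": r.converged,
                "message": r.message,
            }
            row.update({f"param_{k}": v for k, v in r.params.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def pk_table(self) -> pd.DataFrame:
        rows = []
        for arm, res in self.arms.items():
            f = res.fit
            rows.append(
                {
                    "arm": arm,
                    "source": res.fit_source,
                    "ka_per_h": f.ka,
                    "ke_per_h": f.ke,
                    "amplitude_ug_ml": f.amplitude,
                    "tmax_h": f.tmax,
                    "cmax_ug_ml": f.cmax,
                    "t_half_h": f.t_half,
                    "auc_0_24_h_ug_ml": res.auc_0_24,
                    "auc_0_inf_h_ug_ml": res.nca.auc_0_inf if res.nca else np.nan,
                    "flip_flop": f.flip_flop,
                }
            )
        return pd.DataFrame(rows)

    def pkpd_table(self) -> pd.DataFrame:
        rows = []
        for arm, res in self.arms.items():
            p = res.pkpd
            rows.append(
                {
                    "arm": arm,
                    "mic90_ug_ml": p.mic90,
                    "cmax_over_mic": p.cmax_over_mic,
                    "auc24_over_mic_h": p.auc24_over_mic,
                    "auc_above_mic_h_ug_ml": p.auc_above_mic,
                    "t_above_mic_h": p.t_above_mic,
                    "t_above_k_mic_h": p.t_above_k_mic,
                    "dosing_interval_tau_h": p.dosing_interval_tau,
                    "n_instillations": (
                        res.dosing.n_instillations if res.dosing else None
                    ),
                }
            )
        return pd.DataFrame(rows)


def _arm_from_summary(arm: str, summary: dict, cfg: RunConfig) -> ArmResult:
    ka, ke, cmax = summary["ka"], summary["ke"], summary["cmax"]
    fit = calibrate_from_summary(ka, ke, cmax)
    auc24 = summary.get("auc_0_24", None)
    nca = None
    if auc24 is not None:
        # extrapolate with the model-predicted 24-h concentration, since the
        # observed tail level is not part of the summary
        from .nca import extrapolate_auc_inf
        from .bateman import bateman_conc

        c24 = float(bateman_conc(fit, cfg.window_h))
        nca = NCAResult(
            auc_0_tlast=auc24,
            auc_0_inf=extrapolate_auc_inf(auc24, c24, ke),
            clast=c24,
            tlast=cfg.window_h,
            cmax_obs=cmax,
            tmax_obs=fit.tmax,
            extrapolated_fraction=(c24 / ke) / (auc24 + c24 / ke),
        )
    report = build_report(
        arm,
        fit,
        cfg.mic90_ug_ml,
        k=cfg.threshold_multiplier,
        window=(0.0, cfg.window_h),
        cmax=cmax,
        auc_0_24=auc24,
    )
    dosing = _simulate(fit, report, cfg)
    return ArmResult(
        arm=arm,
        fit=fit,
        fit_source="summary",
        nca=nca,
        pkpd=report,
        dosing=dosing,
        auc_0_24=auc24 if auc24 is not None else np.nan,
        dose=summary.get("dose", 1.0),
    )


def _arm_from_profile(arm: str, profile, cfg: RunConfig) -> ArmResult:
    fit = fit_bateman(profile, n_terminal=cfg.n_terminal)
    nca = run_nca(profile, fit.ke)
    from .nca import trapezoidal_auc

    t_end = min(cfg.window_h, profile.times[-1])
    auc24 = trapezoidal_auc(profile, 0.0, t_end)
    report = build_report(
        arm,
        fit,
        cfg.mic90_ug_ml,
        k=cfg.threshold_multiplier,
        window=(0.0, cfg.window_h),
        cmax=nca.cmax_obs,
        auc_0_24=auc24,
    )
    dosing = _simulate(fit, report, cfg)
    return ArmResult(
        arm=arm,
        fit=fit,
        fit_source="profile",
        nca=nca,
        pkpd=report,
        dosing=dosing,
        auc_0_24=auc24,
    )


def _simulate(fit, report: PkPdReport, cfg: RunConfig) -> Optional[DosingSimulation]:
    if report.dosing_interval_tau is None:
        return None
    regimen = DosingRegimen(tau=report.dosing_interval_tau, horizon=cfg.horizon_h)
    return superpose(fit, regimen, mic_threshold=cfg.mic90_ug_ml)


def analyze(config: RunConfig) -> AnalysisReport:
    """Run every configured stage; deterministic given inputs and seed."""
    report = AnalysisReport(config=config)

    if config.release_csv is not None:
        profiles = read_release_csv(config.release_csv)
        for label, prof in profiles.items():
            ranking = select_best_model(
                prof, DEFAULT_MODELS, fit_window=config.release_fit_window
            )
            report.release_ranking.extend(ranking)

    if config.summary is not None:
        for arm, summ in config.summary.items():
            try:
                report.arms[arm] = _arm_from_summary(arm, summ, config)
            except Exception as exc:
                raise RuntimeError(f"stage pk/pkpd failed for arm {arm!r}: {exc}") from exc
    elif config.conc_csv is not None:
        profiles = read_conc_csv(config.conc_csv)
        for arm, prof in profiles.items():
            try:
                report.arms[arm] = _arm_from_profile(arm, prof, config)
            except Exception as exc:
                raise RuntimeError(f"stage pk/pkpd failed for arm {arm!r}: {exc}") from exc

    test, ref = config.test_arm, config.reference_arm
    if test in report.arms and ref in report.arms:
        a, b = report.arms[test], report.arms[ref]
        if np.isfinite(a.auc_0_24) and np.isfinite(b.auc_0_24):
            report.relative_bioavailability = relative_bioavailability(
                a.auc_0_24, a.dose, b.auc_0_24, b.dose
            )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if report.release_ranking:
            write_table(report.ranking_table(), out / "release_ranking.csv")
        if report.arms:
            write_table(report.pk_table(), out / "pk_parameters.csv")
            write_table(report.pkpd_table(), out / "pkpd_indices.csv")
            for arm, res in report.arms.items():
                if res.dosing is not None:
                    pd.DataFrame(
                        {
                            "time_h": res.dosing.grid_times,
                            "total_conc": res.dosing.total_conc,
                        }
                    ).to_csv(out / f"dosing_{arm}.csv", index=False)
    return report
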