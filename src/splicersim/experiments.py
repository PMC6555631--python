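"""Canned experiments: scan-time sweeps, the gated-vs-ungated image demo and
optimum-TR tables.

These drive the library modules end to end and write plain-file artefacts
(CSV, NIfTI, YAML, PNG); the command-line interface is a thin wrapper around
the functions here.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import kspace as ks
from . import stability as st
from .config import RunConfig, dump_config
from .respiration import ZERO_GATE, RespModel, availability_fraction, generate_trace
from .scheduler import ScanConfig, run_splicer, run_ungated, scan_time_stats, subseed
from .signal_model import (
    RelaxationParams,
    optimum_tr_spgr,
    optimum_tr_spin_echo,
    se_snr_efficiency,
)

__all__ = ["run_sweep", "run_demo", "optimum_tr_table", "sweep_heatmaps"]

log = logging.getLogger("splicersim")

SWEEP_COLUMNS = [
    "tr",
    "sigma_frac",
    "mu_resp",
    "mean_scantime",
    "sd_scantime",
    "n_incomplete",
    "mean_multiple",
    "infeasible",
]


def run_sweep(cfg: RunConfig, outdir: str | Path | None = None) -> pd.DataFrame:
    """Monte-Carlo scan-time statistics over a (TR, sigma) grid per mu.

    Follows the sweep conventions: a single projection stream, gate margins
    zeroed so the whole breath-motion window is the unavailable window, the
    scan clock started at the centre of a breath, and scan times normalised
    to the extended scan time (ungated time / availability).  Cells where
    the per-slice slot exceeds the quiet inter-breath window at sigma = 0
    are flagged infeasible: synchronous breathing can then starve the
    schedule indefinitely.
    """
    sw = cfg.sweep
    trs = np.linspace(sw.tr_min, sw.tr_max, sw.n_tr)
    sig_fracs = np.linspace(sw.sigma_frac_min, sw.sigma_frac_max, sw.n_sigma)
    rows = []
    cell = 0
    for mu in sw.mu_values:
        quiet = mu - sw.breath_duration
        for sf in sig_fracs:
            model = RespModel(
                mu=mu, sigma=sf * mu, breath_duration=sw.breath_duration
            )
            for tr in trs:
                scan = ScanConfig(tr=float(tr), n_slices=1, n_pe=sw.n_pe, etl=1)
                stats = scan_time_stats(
                    scan,
                    model,
                    ZERO_GATE,
                    n_repeats=sw.n_repeats,
                    seed=int(
                        np.random.SeedSequence(
                            cfg.seed, spawn_key=(cell,)
                        ).generate_state(1)[0]
                        % 2**31
                    ),
                )
                ungated = scan.ungated_time()
                rows.append(
                    {
                        "tr": float(tr),
                        "sigma_frac": float(sf),
                        "mu_resp": float(mu),
                        "mean_scantime": stats.mean,
                        "sd_scantime": stats.sd,
                        "n_incomplete": stats.n_incomplete,
                        "mean_multiple": stats.mean / ungated,
                        "infeasible": bool(scan.slot_width > quiet),
                    }
                )
                cell += 1
        log.info("sweep: finished mu=%.2f s", mu)
    df = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "sweep.csv", index=False, float_format="%.6g")
        dump_config(cfg, outdir / "resolved_config.yaml")
        sweep_heatmaps(df, outdir)
    return df


def sweep_heatmaps(df: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Mean/SD scan-time heat maps over (TR, sigma), one figure per mu."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    paths = []
    for mu, sub in df.groupby("mu_resp"):
        piv_mean = sub.pivot(index="sigma_frac", columns="tr", values="mean_multiple")
        piv_sd = sub.pivot(index="sigma_frac", columns="tr", values="sd_scantime")
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), constrained_layout=True)
        for ax, piv, title in (
            (axes[0], piv_mean, "mean scan time / ungated"),
            (axes[1], piv_sd, "SD of scan time (s)"),
        ):
            im = ax.pcolormesh(piv.columns, piv.index, piv.values, shading="nearest")
            ax.set_xlabel("TR (s)")
            ax.set_ylabel("sigma / mu")
            ax.set_title(f"{title}, mu = {mu} s")
            fig.colorbar(im, ax=ax)
        p = outdir / f"sweep_mu{mu:g}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def _noisy_image(kdata: ks.KSpaceData, sigma_img: float, rng) -> np.ndarray:
    """Reconstruct with additive complex Gaussian k-space noise equivalent to
    an image-domain noise SD of ``sigma_img``."""
    n = kdata.data.shape[-1]
    noisy = ks.KSpaceData(
        data=kdata.data
        + sigma_img
        * n
        * (
            rng.standard_normal(kdata.data.shape)
            + 1j * rng.standard_normal(kdata.data.shape)
        ),
        line_time=kdata.line_time,
        line_shot=kdata.line_shot,
        filled=kdata.filled,
        fov=kdata.fov,
        config=kdata.config,
    )
    return ks.reconstruct(noisy)


def run_demo(cfg: RunConfig, outdir: str | Path) -> dict:
    """Simulate matched ungated and SPLICER repeat stacks on one phantom and
    compute their temporal-SNR statistics.

    The study layout is 20 ungated versus 10 gated repeats acquired in
    virtually identical total scan time; the default breathing model
    (mu = 1.0 s, breath 0.5 s) has availability 1/2, so 10 gated repeats
    naturally occupy the time of 20 ungated ones.  Outputs: one 4D NIfTI
    stack per mode, mean/SD/SNR maps per mode, the SNR enhancement map and a
    per-slice ROI summary CSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = cfg.demo
    scan = cfg.scan.build()
    if scan.n_pe != d.matrix:
        raise ValueError("demo requires scan.n_pe == demo.matrix")
    model = cfg.respiration.build()
    gate = cfg.gate.build()
    motion = cfg.motion.build()
    relax = RelaxationParams(t1=d.t1, flip=d.flip)
    phantom = ks.default_phantom(matrix=d.matrix, fov=d.fov)
    rng = np.random.default_rng(subseed(cfg.seed, 0))

    # one long trace covers both protocols back to back
    t_ungated = scan.ungated_time()
    est_avail = max(availability_estimate(model, gate), 0.1)
    duration = (d.n_ungated + 2 * d.n_splicer / est_avail + 2) * t_ungated
    trace = generate_trace(model, duration, subseed(cfg.seed, 1))

    log_u = run_ungated(scan, n_repeats=d.n_ungated)
    frames_u = []
    for r in range(d.n_ungated):
        kd = ks.acquire(phantom, log_u, motion, trace, relax, repeat=r)
        frames_u.append(_noisy_image(kd, d.noise_sigma, rng))
    stack_u = st.ImageStack(
        np.stack(frames_u, axis=-1).transpose(1, 2, 0, 3), fov=d.fov
    )

    frames_s = []
    t0 = 0.0
    splicer_total = 0.0
    for _ in range(d.n_splicer):
        log_s = run_splicer(scan, trace, gate, start_time=t0)
        if not log_s.completed:
            raise RuntimeError("gated repeat did not complete; enlarge the trace")
        kd = ks.acquire(phantom, log_s, motion, trace, relax)
        frames_s.append(_noisy_image(kd, d.noise_sigma, rng))
        t0 += log_s.scan_time
        splicer_total += log_s.scan_time
    stack_s = st.ImageStack(
        np.stack(frames_s, axis=-1).transpose(1, 2, 0, 3), fov=d.fov
    )

    stack_u.to_nifti(outdir / "ungated_stack.nii.gz")
    stack_s.to_nifti(outdir / "splicer_stack.nii.gz")

    maps = {}
    for name, stack in (("ungated", stack_u), ("splicer", stack_s)):
        mean, sd, snr = st.pixel_stats(stack)
        for stat, arr in (("mean", mean), ("sd", sd), ("snr", snr)):
            st.save_map(arr, stack, outdir / f"{name}_{stat}.nii.gz")
        maps[name] = snr
    enh = st.enhancement_map(maps["splicer"], maps["ungated"])
    st.save_map(enh, stack_u, outdir / "snr_enhancement.nii.gz")

    roi = st.RoiSpec(centre=(d.matrix / 2, d.matrix / 2), area=d.roi_area)
    rows = []
    for s in range(enh.shape[2]):
        mean_ex, n_bad = st.roi_mean(enh[:, :, s], roi, d.fov, nonfinite="exclude")
        mean_un, _ = st.roi_mean(enh[:, :, s], roi, d.fov, nonfinite="unity")
        rows.append(
            {
                "slice": s,
                "n_pixels": st.roi_pixel_count(roi, d.fov, d.matrix),
                "enhancement_mean": mean_ex,
                "enhancement_mean_voids_unity": mean_un,
                "n_nonfinite": n_bad,
            }
        )
    roi_df = pd.DataFrame(rows)
    roi_df.to_csv(outdir / "roi_summary.csv", index=False, float_format="%.6g")
    dump_config(cfg, outdir / "resolved_config.yaml")

    summary = {
        "ungated_time": d.n_ungated * t_ungated,
        "splicer_time": splicer_total,
        "roi_enhancement_mean": float(roi_df["enhancement_mean"].mean()),
        "roi_enhancement_mean_voids_unity": float(
            roi_df["enhancement_mean_voids_unity"].mean()
        ),
        "outdir": str(outdir),
    }
    log.info(
        "demo: ungated %.0f s vs gated %.0f s; ROI-mean SNR enhancement %.2f",
        summary["ungated_time"],
        summary["splicer_time"],
        summary["roi_enhancement_mean"],
    )
    return summary


def availability_estimate(model: RespModel, gate) -> float:
    """Long-run availability implied by the model parameters alone."""
    width = max(
        model.breath_duration
        + gate.post_breath_extension
        + gate.reacq_lookback
        - gate.detection_latency,
        0.0,
    )
    return max(1.0 - width / model.mu, 0.0)


def optimum_tr_table(t1: float, flip: float | None = None) -> pd.DataFrame:
    """Optimum TRs (seconds) and the familiar efficiency ratio for a tissue T1."""
    if t1 <= 0:
        raise ValueError("t1 must be > 0")
    x_se = optimum_tr_spin_echo()
    rows = [
        {
            "sequence": "spin echo (90 deg)",
            "optimum_tr_over_t1": x_se,
            "optimum_tr_s": x_se * t1,
            "efficiency_vs_tr5t1": se_snr_efficiency(x_se) / se_snr_efficiency(5.0),
        }
    ]
    if flip is not None:
        x_gre = optimum_tr_spgr(flip)
        rows.append(
            {
                "sequence": f"spoiled gradient echo ({flip:g} deg)",
                "optimum_tr_over_t1": x_gre,
                "optimum_tr_s": x_gre * t1,
                "efficiency_vs_tr5t1": np.nan,
            }
        )
    return pd.DataFrame(rows)
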