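"""Synthetic multirun DIA experiments with known ground truth.

The generator emulates the phenomena that make multirun quantification
hard: per-run monotone retention-time warps (linear drift plus a smooth
nonlinear component), analyte-specific local shifts on top of the global
warp, decoy peaks that offer the peak scorer plausible wrong answers,
interfering peaks that score as well as the true one (the classic cause
of inconsistent cross-run peak picking), occasional mis-scored true
peaks, and missing signals. Everything is emitted in the package's own
containers, so every other module is testable without external data.

Score calibration: decoy q values are Uniform(0, 1); true-peak q values
concentrate near zero (log-uniform), with a configurable fraction of
weakly scored true peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .model import AnnotationTable, Feature, ValidationError, Xic, XicGroup

__all__ = ["SimConfig", "GroundTruth", "SimResult", "simulate_experiment", "make_multisite"]


@dataclass
class SimConfig:
    """Conditions of one simulated multirun experiment.

    Times are seconds. ``grid_step`` of 3.4 s resembles a typical SWATH
    cycle time; ``window_halfwidth`` is the extraction window around the
    library retention time; ``peak_sigma`` a typical chromatographic peak
    width (sigma). ``snr`` is the apex amplitude over the white-noise sd
    of a fragment trace.
    """

    n_runs: int = 6
    n_sites: int = 1
    n_precursors: int = 200
    fragments_per_precursor: int = 6
    grid_step: float = 3.4
    gradient_span: float = 2400.0
    window_halfwidth: float = 60.0
    peak_sigma: float = 5.0
    snr: float = 10.0
    # global warp family (per run)
    warp_slope_sd: float = 0.015
    warp_intercept_sd: float = 8.0
    spline_amplitude: float = 10.0
    n_warp_knots: int = 5
    # multisite structure: sites differ by large warps, runs within a site
    # share the site warp up to a small jitter
    site_slope_sd: float = 0.02
    site_intercept_sd: float = 20.0
    site_spline_amplitude: float = 15.0
    within_site_slope_sd: float = 0.003
    within_site_intercept_sd: float = 2.0
    within_site_spline_amplitude: float = 2.0
    # analyte-specific local shifts applied after the global warp
    local_shift_prob: float = 0.5
    local_shift_min: float = 5.0
    local_shift_max: float = 12.0
    # column-specific analyte behaviour: a systematic per-(site, analyte)
    # shift shared by all runs of a site, the main driver of cross-site
    # residual error that a smooth global fit cannot absorb
    site_analyte_shift_prob: float = 0.4
    site_analyte_shift_min: float = 5.0
    site_analyte_shift_max: float = 15.0
    # decoy and interference peaks
    decoys_per_precursor: int = 2
    decoy_offset_min: float = 18.0
    decoy_offset_max: float = 45.0
    decoy_intensity_ratio: float = 0.8
    confusable_prob: float = 0.1
    confusable_intensity_ratio: float = 0.9
    # score model and missingness
    weak_score_prob: float = 0.1
    signal_dropout: float = 0.02
    feature_dropout: float = 0.05
    apex_jitter: float = 0.5
    charge3_fraction: float = 0.0
    # optional exactly-known linear warps, one (slope, intercept) per run;
    # overrides the random warp family when set
    fixed_linear_warps: Optional[List[Tuple[float, float]]] = None
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "local_shift_prob",
            "confusable_prob",
            "weak_score_prob",
            "signal_dropout",
            "feature_dropout",
            "charge3_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {v}")
        if self.grid_step <= 0:
            raise ValidationError("grid_step must be > 0")
        if self.peak_sigma * 6 >= 2 * self.window_halfwidth:
            raise ValidationError(
                "peaks wider than the extraction window: decrease peak_sigma "
                "or widen window_halfwidth"
            )
        if self.peak_sigma * 6 >= self.gradient_span:
            raise ValidationError("peaks wider than the gradient")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    # per (precursor, run): warped true apex in that run's time scale
    apex: Dict[Tuple[str, str], float]
    boundaries: Dict[Tuple[str, str], Tuple[float, float]]
    present: Dict[Tuple[str, str], bool]
    warps: Dict[str, Callable[[np.ndarray], np.ndarray]]
    local_shifts: Dict[Tuple[str, str], float]
    reference_apex: Dict[str, float]  # precursor -> apex on the reference scale


@dataclass
class SimResult:
    xics: Dict[Tuple[str, str], XicGroup]
    features: List[Feature]
    annotations: AnnotationTable
    truth: GroundTruth
    site_labels: Dict[str, str]
    run_ids: List[str]
    precursors: List[str]
    config: SimConfig


def _monotone_warp(
    rng: np.random.Generator,
    span: float,
    slope_sd: float,
    intercept_sd: float,
    spline_amplitude: float,
    n_knots: int,
    base: Optional[Callable] = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """A monotone warp: linear drift plus a smooth bounded spline term.

    Built as a PCHIP interpolant through strictly increasing knot values,
    which guarantees a monotone (hence invertible) mapping.
    """
    slope = 1.0 + rng.normal(0.0, slope_sd)
    intercept = rng.normal(0.0, intercept_sd)
    knots = np.linspace(-0.1 * span, 1.1 * span, max(n_knots, 3))
    values = slope * knots + intercept + rng.normal(0.0, spline_amplitude, len(knots))
    if base is not None:
        values = np.asarray(base(knots)) + (values - knots)  # compose with site warp
    # enforce strictly increasing knot values with a minimum slope of 0.2
    min_step = 0.2 * (knots[1] - knots[0])
    for k in range(1, len(values)):
        if values[k] < values[k - 1] + min_step:
            values[k] = values[k - 1] + min_step
    return PchipInterpolator(knots, values, extrapolate=True)


def _precursor_ids(n: int, charge3_fraction: float, rng: np.random.Generator) -> List[str]:
    ids = []
    for k in range(n):
        seq = f"PEP{k:05d}"
        ids.append(f"{seq}/2")
    n3 = int(round(n * charge3_fraction))
    for k in range(n3):
        ids.append(f"PEP{k:05d}/3")
    return ids


def simulate_experiment(config: SimConfig) -> SimResult:
    """Generate one experiment; reproducible under a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_total_runs = config.n_runs * max(config.n_sites, 1)
    run_ids = [f"run{r:02d}" for r in range(n_total_runs)]
    site_labels = {
        run_ids[r]: f"site{r // config.n_runs:02d}" for r in range(n_total_runs)
    }

    warps: Dict[str, Callable] = {}
    if config.fixed_linear_warps is not None:
        if len(config.fixed_linear_warps) != n_total_runs:
            raise ValidationError("need one (slope, intercept) per run")
        for run, (slope, icept) in zip(run_ids, config.fixed_linear_warps):
            if slope <= 0:
                raise ValidationError("warp slopes must be positive")
            warps[run] = (lambda s, b: (lambda t: s * np.asarray(t) + b))(
                slope, icept
            )
    elif config.n_sites > 1:
        for s in range(config.n_sites):
            site_warp = _monotone_warp(
                rng,
                config.gradient_span,
                config.site_slope_sd,
                config.site_intercept_sd,
                config.site_spline_amplitude,
                config.n_warp_knots,
            )
            for r in range(config.n_runs):
                run = run_ids[s * config.n_runs + r]
                warps[run] = _monotone_warp(
                    rng,
                    config.gradient_span,
                    config.within_site_slope_sd,
                    config.within_site_intercept_sd,
                    config.within_site_spline_amplitude,
                    config.n_warp_knots,
                    base=site_warp,
                )
    else:
        for run in run_ids:
            warps[run] = _monotone_warp(
                rng,
                config.gradient_span,
                config.warp_slope_sd,
                config.warp_intercept_sd,
                config.spline_amplitude,
                config.n_warp_knots,
            )

    precursors = _precursor_ids(config.n_precursors, config.charge3_fraction, rng)
    sigma = config.peak_sigma
    half_width = 2.5 * sigma  # reported peak boundaries

    xics: Dict[Tuple[str, str], XicGroup] = {}
    features: List[Feature] = []
    annotations = AnnotationTable()
    truth = GroundTruth(
        apex={}, boundaries={}, present={}, warps=warps, local_shifts={},
        reference_apex={},
    )

    n_pts = int(round(2 * config.window_halfwidth / config.grid_step)) + 1

    for prec in precursors:
        mu = float(rng.uniform(0.1, 0.9) * config.gradient_span)
        truth.reference_apex[prec] = mu
        # fragment intensity pattern, fixed across runs for this precursor
        amp_total = 10.0 ** rng.uniform(2.5, 4.0)
        pattern = rng.dirichlet(np.ones(config.fragments_per_precursor) * 2.0)
        frag_ids = [f"y{k+3}" for k in range(config.fragments_per_precursor)]
        decoy_patterns = [
            rng.dirichlet(np.ones(config.fragments_per_precursor) * 2.0)
            for _ in range(config.decoys_per_precursor + 1)
        ]
        # decoy and interfering peaks are co-eluting analytes in their own
        # right: they hold a characteristic position on the reference time
        # scale and move with the run warp like any other analyte
        decoy_mus = [
            mu
            + float(
                rng.choice([-1.0, 1.0])
                * rng.uniform(config.decoy_offset_min, config.decoy_offset_max)
            )
            for _ in range(config.decoys_per_precursor)
        ]
        has_confusable = rng.uniform() < config.confusable_prob
        confusable_mu = mu + float(
            rng.choice([-1.0, 1.0])
            * rng.uniform(config.decoy_offset_min, config.decoy_offset_max)
        )
        # per-(site, analyte) systematic shifts; analyte index 0 is the true
        # analyte, 1..K the decoys, K+1 the interfering analyte
        site_shift: Dict[Tuple[str, int], float] = {}
        if config.n_sites > 1:
            for site in sorted(set(site_labels.values())):
                for a in range(config.decoys_per_precursor + 2):
                    sh = 0.0
                    if rng.uniform() < config.site_analyte_shift_prob:
                        sh = float(
                            rng.choice([-1.0, 1.0])
                            * rng.uniform(
                                config.site_analyte_shift_min,
                                config.site_analyte_shift_max,
                            )
                        )
                    site_shift[(site, a)] = sh
        for run in run_ids:
            key = (prec, run)
            warped_mu = float(warps[run](mu))
            shift = 0.0
            if rng.uniform() < config.local_shift_prob:
                shift = float(
                    rng.choice([-1.0, 1.0])
                    * rng.uniform(config.local_shift_min, config.local_shift_max)
                )
            tau = warped_mu + shift + site_shift.get((site_labels[run], 0), 0.0)
            present = rng.uniform() >= config.signal_dropout
            truth.apex[key] = tau
            truth.present[key] = present
            truth.local_shifts[key] = shift
            truth.boundaries[key] = (tau - half_width, tau + half_width)
            if present:
                annotations.set(prec, run, (tau - half_width, tau + half_width))
            else:
                annotations.set(prec, run, None)

            start = warped_mu - config.window_halfwidth + rng.uniform(
                0, config.grid_step
            )
            grid = start + config.grid_step * np.arange(n_pts)

            # peaks inside the window: the analyte, decoys, maybe interference
            peaks: List[Tuple[float, float, np.ndarray, str]] = []
            if present:
                peaks.append((tau, amp_total, pattern, "true"))
            for k in range(config.decoys_per_precursor):
                d_shift = 0.0
                if rng.uniform() < config.local_shift_prob:
                    d_shift = float(
                        rng.choice([-1.0, 1.0])
                        * rng.uniform(config.local_shift_min, config.local_shift_max)
                    )
                d_apex = float(
                    np.clip(
                        warps[run](decoy_mus[k])
                        + d_shift
                        + site_shift.get((site_labels[run], k + 1), 0.0),
                        grid[0] + 2 * sigma,
                        grid[-1] - 2 * sigma,
                    )
                )
                peaks.append(
                    (
                        d_apex,
                        amp_total * config.decoy_intensity_ratio,
                        decoy_patterns[k],
                        "decoy",
                    )
                )
            if has_confusable:
                c_shift = 0.0
                if rng.uniform() < config.local_shift_prob:
                    c_shift = float(
                        rng.choice([-1.0, 1.0])
                        * rng.uniform(config.local_shift_min, config.local_shift_max)
                    )
                c_apex = float(
                    np.clip(
                        warps[run](confusable_mu)
                        + c_shift
                        + site_shift.get(
                            (site_labels[run], config.decoys_per_precursor + 1), 0.0
                        ),
                        grid[0] + 2 * sigma,
                        grid[-1] - 2 * sigma,
                    )
                )
                peaks.append(
                    (
                        c_apex,
                        amp_total * config.confusable_intensity_ratio,
                        decoy_patterns[-1],
                        "confusable",
                    )
                )

            traces = np.zeros((config.fragments_per_precursor, n_pts))
            for apex_t, amp, pat, _kind in peaks:
                for f in range(config.fragments_per_precursor):
                    traces[f] += (
                        amp
                        * pat[f]
                        * np.exp(-((grid - apex_t) ** 2) / (2 * sigma**2))
                    )
            noise_sd = amp_total * pattern.max() / config.snr
            traces += rng.normal(0.0, noise_sd, traces.shape)
            traces = np.clip(traces, 0.0, None)
            xics[key] = XicGroup(
                precursor_id=prec,
                run_id=run,
                fragment_ids=list(frag_ids),
                traces=[Xic(grid, traces[f]) for f in range(traces.shape[0])],
            )

            # emitted (picked + scored) features
            area = amp_total * sigma * math.sqrt(2 * math.pi)
            for apex_t, amp, _pat, kind in peaks:
                if kind == "true":
                    if rng.uniform() < config.feature_dropout:
                        continue
                    if rng.uniform() < config.weak_score_prob:
                        q = float(rng.uniform(0.01, 0.5))
                    else:
                        q = float(10.0 ** rng.uniform(-4.0, -1.6))
                elif kind == "confusable":
                    # confident (passes common cut-offs) but on average a
                    # decade weaker than the true analyte's score
                    q = float(10.0 ** rng.uniform(-2.5, -1.0))
                else:
                    q = float(rng.uniform())
                q = min(max(q, 1e-12), 1.0)
                p = q * float(rng.uniform(0.1, 1.0))
                d = -math.log10(q) + float(rng.normal(0.0, 0.2))
                f_apex = apex_t + float(rng.normal(0.0, config.apex_jitter))
                features.append(
                    Feature(
                        precursor_id=prec,
                        run_id=run,
                        rt_apex=f_apex,
                        left_boundary=f_apex - half_width,
                        right_boundary=f_apex + half_width,
                        intensity=area * (amp / amp_total),
                        d_score=d,
                        p_value=max(p, 1e-12),
                        q_value=q,
                    )
                )

    return SimResult(
        xics=xics,
        features=features,
        annotations=annotations,
        truth=truth,
        site_labels=site_labels,
        run_ids=run_ids,
        precursors=precursors,
        config=config,
    )


def make_multisite(config: SimConfig) -> SimResult:
    """Experiment with per-site shared warp families.

    ``n_runs`` is the number of runs per site. With a single site this is
    exactly :func:`simulate_experiment`.
    """
    if config.n_sites < 2:
        return simulate_experiment(config)
    return simulate_experiment(config)
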