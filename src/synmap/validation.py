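"""End-to-end validation studies on synthetic ground truth.

These studies exercise the whole pipeline — simulate, detect, quantify,
colocalize — against the generator's ground truth, at the density and
intensity regimes of the bundled marker survey.  They are what the test
suite and the reproduction script run; keeping them in the package makes
the benchmark itself part of the public surface.

Problem sizes: the density study renders one native-size tile
(942 × 920 px, ≈ 4 000 µm²) per marker × region cell, giving a few
hundred puncta per cell; the colocalization studies use a 200 × 200 µm
field so binomial error on the recovered fraction is ≈ 1 percentage
point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import refdata
from ._matching import match_points
from .colocalize import (
    expected_chance_percent,
    match_puncta,
    percent_with_reference,
)
from .detect import DetectionParams, PunctaSet, detect_puncta
from .micrograph import DEFAULT_TILE_SHAPE
from .synthgen import (
    ChannelConfig,
    PairConfig,
    SynthConfig,
    evaluate_detection,
    generate_field,
    sample_ground_truth,
)

__all__ = [
    "DensityRecoveryResult",
    "density_recovery_study",
    "ColocRecoveryResult",
    "colocalization_recovery_study",
    "null_calibration_study",
]

#: Native tile field size (µm) at 68 nm pixels: 920 × 942 px.
_TILE_FIELD_UM = (
    DEFAULT_TILE_SHAPE[1] * 0.068,  # width
    DEFAULT_TILE_SHAPE[0] * 0.068,  # height
)

#: Detection knobs used for all synthetic studies.  The quality threshold
#: scales with the marker's amplitude (the per-antibody tuning step);
#: 0.12·A sits far above the noise floor yet below the dimmest puncta.
_RADIUS_UM = 0.12
_MATCH_DIST_UM = 0.3


def _marker_params(amplitude_mean: float) -> DetectionParams:
    return DetectionParams(
        punctum_radius_um=_RADIUS_UM,
        quality_threshold=0.12 * amplitude_mean,
        intensity_threshold=0.0,
        subpixel=True,
        # ground truth covers the whole field, so detection must too
        exclude_border=False,
    )


def _single_channel_config(
    name: str, density: float, amplitude: float, seed: int
) -> SynthConfig:
    return SynthConfig(
        field_size_um=_TILE_FIELD_UM,
        channels=[
            ChannelConfig(
                name=name,
                density_per_100um2=density,
                amplitude_mean=amplitude,
                amplitude_sd=0.15 * amplitude,
            )
        ],
        seed=seed,
    )


@dataclass
class DensityRecoveryResult:
    """Per-cell density recovery plus pooled detection scores."""

    table: pd.DataFrame  # marker, region, true_density, realized, detected, rel_error
    recall: float
    precision: float
    rmse_um: float
    max_abs_rel_error: float


def density_recovery_study(
    seed: int,
    density_table: pd.DataFrame | None = None,
    intensity_table: pd.DataFrame | None = None,
) -> DensityRecoveryResult:
    """Recover a marker × region density table from rendered fields.

    For every cell of the design (default: the bundled mouse survey,
    7 markers × 9 regions), one tile-sized field is simulated at the
    cell's published density with the marker's published mean amplitude,
    puncta are detected, and detected density is compared with the
    realized ground-truth density (the Poisson draw actually rendered).
    Recall/precision/RMSE are pooled over all cells.
    """
    if density_table is None:
        density_table = refdata.mouse_density_mean()
    if intensity_table is None:
        intensity_table = refdata.mouse_intensity_mean()
    regions = [c for c in density_table.columns if c != "Mean"]
    seeds = np.random.SeedSequence(seed).generate_state(
        len(density_table.index) * len(regions)
    )
    rows = []
    matched = truth_n = det_n = 0
    sq_err_sum = 0.0
    k = 0
    for marker in density_table.index:
        amplitude = float(intensity_table.loc[marker].drop("Mean", errors="ignore").mean())
        for region in regions:
            rho = float(density_table.loc[marker, region])
            cfg = _single_channel_config(
                marker, rho, amplitude, seed=int(seeds[k] % (2**31))
            )
            k += 1
            images, truth = generate_field(cfg)
            ps = detect_puncta(
                images[0], _marker_params(amplitude), marker=marker, region=region
            )
            score = evaluate_detection(
                ps.positions, truth.positions(marker), _MATCH_DIST_UM
            )
            realized = 100.0 * truth.count(marker) / cfg.area_um2
            detected = 100.0 * len(ps) / ps.roi_area_um2
            rows.append(
                (
                    marker,
                    region,
                    rho,
                    realized,
                    detected,
                    (detected - realized) / realized if realized else 0.0,
                )
            )
            matched += score.n_matched
            truth_n += score.n_truth
            det_n += score.n_detected
            sq_err_sum += score.rmse_um**2 * score.n_matched
    table = pd.DataFrame(
        rows,
        columns=[
            "marker", "region", "true_density", "realized_density",
            "detected_density", "rel_error",
        ],
    )
    return DensityRecoveryResult(
        table=table,
        recall=matched / truth_n,
        precision=matched / det_n,
        rmse_um=math.sqrt(sq_err_sum / matched) if matched else 0.0,
        max_abs_rel_error=float(table["rel_error"].abs().max()),
    )


@dataclass
class ColocRecoveryResult:
    configured_fraction: float
    observed_percent: float
    corrected_percent: float
    ci_halfwidth_percent: float
    n_b: int
    mode: str


def colocalization_recovery_study(
    seed: int,
    fraction: float = 0.67,
    mode: str = "colocalized",
    rho_a: float = 19.0,
    rho_b: float = 16.0,
    field_um: float = 200.0,
    max_dist_um: float | None = None,
) -> ColocRecoveryResult:
    """Recover a configured colocalized/juxtaposed fraction end-to-end.

    Two channels are simulated with a known paired fraction, both are
    detected, matched one-to-one, and the recovered fraction is compared
    with the configured value.  Chance correction uses a parametric
    bootstrap: synthetic B point sets with candidate paired fractions are
    matched against the *observed* A detections, and the estimate is the
    fraction whose expected matched count reproduces the observed count.
    This captures everything the analytic Poisson formula misses (border
    effects, reference occupancy, the cascade behaviour of one-to-one
    maximum-cardinality matching).  The returned CI half-width is the
    binomial 95 % interval on the configured fraction at the observed
    n_B, widened by the chance-correction factor.
    """
    amp_a, amp_b = 386.0, 236.0
    cfg = SynthConfig(
        field_size_um=(field_um, field_um),
        channels=[
            ChannelConfig("A", rho_a, amplitude_mean=amp_a, amplitude_sd=0.15 * amp_a),
            ChannelConfig("B", rho_b, amplitude_mean=amp_b, amplitude_sd=0.15 * amp_b),
        ],
        pairs=[PairConfig("A", "B", fraction=fraction, mode=mode)],
        seed=seed % (2**31),
    )
    images, truth = generate_field(cfg)
    ps_a = detect_puncta(images[0], _marker_params(amp_a), marker="A")
    ps_b = detect_puncta(images[1], _marker_params(amp_b), marker="B")
    pairing = match_puncta(ps_a, ps_b, max_dist_um=max_dist_um, mode=mode)
    res = percent_with_reference(pairing, ps_b)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed % (2**31), 17]).generate_state(1)[0]
    )
    f_hat, p_null = _bootstrap_fraction_estimate(
        ps_a, pairing, cfg, mode, rng
    )
    ci = 1.96 * math.sqrt(fraction * (1 - fraction) / max(res.n_b, 1))
    ci_pct = 100.0 * ci / max(1.0 - p_null, 1e-9)
    return ColocRecoveryResult(
        configured_fraction=fraction,
        observed_percent=res.percent_b_with_a,
        corrected_percent=100.0 * f_hat,
        ci_halfwidth_percent=ci_pct,
        n_b=res.n_b,
        mode=mode,
    )


def _bootstrap_fraction_estimate(
    ps_a: PunctaSet,
    pairing,
    cfg: SynthConfig,
    mode: str,
    rng: np.random.Generator,
    n_reps: int = 6,
) -> tuple[float, float]:
    """Solve for the paired fraction reproducing the observed match count.

    The expected matched count at fraction f is estimated by placing
    round(f * n_B) synthetic B points on randomly chosen observed A
    detections (with the pair geometry of ``mode``) and the rest
    uniformly, then running the matcher; the near-linear count-vs-f curve
    is solved by two secant refinements.  Returns (f_hat, null matched
    fraction).
    """
    xy_a = ps_a.positions
    n_b = pairing.n_b
    w, h = cfg.field_size_um
    offset_um = 0.2 if mode == "juxtaposed" else 0.0
    s_um = cfg.pixel_size_nm / 1000.0

    def simulated_count(f: float) -> float:
        counts = []
        for _ in range(n_reps):
            n_pair = min(int(round(f * n_b)), len(xy_a))
            idx = rng.choice(len(xy_a), size=n_pair, replace=False)
            theta = rng.uniform(0, 2 * np.pi, size=n_pair)
            if mode == "juxtaposed":
                r = np.full(n_pair, offset_um)
            else:
                r = s_um * np.sqrt(rng.uniform(0, 1, size=n_pair))
            paired = xy_a[idx] + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            free = np.column_stack(
                [rng.uniform(0, w, size=n_b - n_pair), rng.uniform(0, h, size=n_b - n_pair)]
            )
            xy_b = np.vstack([np.clip(paired, 0, [w, h]), free])
            counts.append(len(match_points(xy_a, xy_b, pairing.max_dist_um)))
        return float(np.mean(counts))

    n_obs = pairing.n_matched
    m0 = simulated_count(0.0)
    p_null = m0 / n_b
    f = min(max((n_obs - m0) / max(n_b - m0, 1.0), 0.0), 1.0)
    for _ in range(2):
        mf = simulated_count(f)
        f = min(max(f + (n_obs - mf) / max(n_b - m0, 1.0), 0.0), 1.0)
    return f, p_null


def null_calibration_study(
    seed: int,
    distances_um: tuple[float, ...] = (0.2, 0.3, 0.5),
    rho_a: float = 19.0,
    rho_b: float = 2.0,
    field_um: float = 300.0,
    n_fields: int = 3,
) -> pd.DataFrame:
    """Null calibration: independent channels vs the Poisson chance formula.

    With no configured pairing (f = 0), the observed percentage of B
    puncta matched to A should equal the analytic chance level
    ``100·(1 − exp(−(ρ_A/100)·π·d²))``.  Matching runs on ground-truth
    centroids pooled over ``n_fields`` independent fields; the returned
    table reports, per distance, the observed percent, expected percent,
    Monte-Carlo standard error and the deviation in SE units.
    """
    cfg = SynthConfig(
        field_size_um=(field_um, field_um),
        channels=[ChannelConfig("A", rho_a), ChannelConfig("B", rho_b)],
        seed=seed % (2**31),
    )
    seeds = np.random.SeedSequence(seed).generate_state(n_fields)
    truths = [
        sample_ground_truth(cfg, np.random.default_rng(int(s) % (2**31)))
        for s in seeds
    ]
    rows = []
    for d in distances_um:
        n_b = n_matched = 0
        for truth in truths:
            a = PunctaSet(marker="A", puncta=_as_puncta(truth.positions("A")),
                          roi_area_um2=cfg.area_um2)
            b = PunctaSet(marker="B", puncta=_as_puncta(truth.positions("B")),
                          roi_area_um2=cfg.area_um2)
            pairing = match_puncta(a, b, max_dist_um=d)
            n_b += len(b)
            n_matched += pairing.n_matched
        observed = 100.0 * n_matched / n_b
        expected = expected_chance_percent(rho_a, d)
        p = expected / 100.0
        se = 100.0 * math.sqrt(p * (1 - p) / n_b)
        rows.append((d, observed, expected, se, abs(observed - expected) / se))
    return pd.DataFrame(
        rows,
        columns=["max_dist_um", "observed_percent", "expected_percent",
                 "mc_se_percent", "deviation_se"],
    )


def _as_puncta(xy: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_um": xy[:, 0] if len(xy) else [],
            "y_um": xy[:, 1] if len(xy) else [],
            "quality": 1.0,
            "mean_intensity": 1.0,
            "radius_um": _RADIUS_UM,
        }
    )
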