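"""Synthetic MNV masks and synthetic eye-level cohorts.

Two generators make the whole pipeline testable without clinical data:

* :func:`simulate_mnv_pair` grows a stochastic branching vessel tree,
  rasterizes it into a flow mask of known total centerline length (the
  ground truth for sumL), and derives a lesion mask by morphological
  closing — a stand-in for a manually outlined MNV complex on en-face OCTA.

* :func:`simulate_cohort` draws eye-level records whose marginal
  distributions (age, visual acuity, injection counts, MNV-type mix,
  fluid/PED states and their transitions after the three-injection loading
  phase, central retinal thickness, and the four OCTA descriptors) default
  to the published cohort moments of a 96-eye nAMD series; in *effect* mode
  one designated outcome is generated from a configurable linear model so
  slope recovery can be tested against known truth.

Distribution families: truncated normal at 0 for non-negative skewed
quantities (heights, areas, lengths), plain normal for logMAR acuity and
fractal dimension, categorical for states. Only the first two moments are
published, so truncated columns are parameterized by the parent (pre-
truncation) moments; where truncation bites, the realized mean exceeds the
configured one (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import line as _draw_line
from skimage.morphology import closing as _closing, dilation as _dilation, disk

from .morphometry import DEFAULT_PIXEL_SIZE_MM, MnvMaskPair

__all__ = [
    "VesselTreeParams",
    "CohortConfig",
    "EffectSpec",
    "COHORT_COLUMNS",
    "simulate_mnv_pair",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]


# ---------------------------------------------------------------------------
# Vessel-tree mask generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselTreeParams:
    """Parameters of the stochastic branching-growth rasterizer."""

    seed: int = 0
    n_trunks: int = 3
    branch_prob: float = 0.25
    angle_jitter_deg: float = 18.0
    segment_len_px: float = 22.0
    len_decay: float = 0.92
    thickness_px: float = 3.0
    frame_px: tuple[int, int] = (256, 256)
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM
    max_generation: int = 6
    max_segments: int = 4000

    def __post_init__(self) -> None:
        if not (0 <= self.branch_prob <= 1):
            raise ValueError("branch_prob must be in [0, 1]")
        if not (0 < self.len_decay <= 1):
            raise ValueError("len_decay must be in (0, 1]")
        for name in ("n_trunks", "segment_len_px", "thickness_px"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.segment_len_px >= min(self.frame_px):
            raise ValueError("frame too small for segment_len_px")


def simulate_mnv_pair(params: VesselTreeParams) -> tuple[MnvMaskPair, float]:
    """Grow and rasterize one synthetic MNV; returns (mask pair, ground-truth sumL in mm).

    Branches are chains of straight segments; segment length decays by
    ``len_decay`` per generation, direction jitters by a Gaussian of SD
    ``angle_jitter_deg`` per segment, and each segment spawns a side branch
    with probability ``branch_prob``. Growth stops at the frame border, so
    the summed Euclidean centerline length of the drawn segments is an
    exact ground truth for the rasterized tree. Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.frame_px
    flow = np.zeros((h, w), dtype=bool)
    total_len_px = 0.0
    segs_drawn = 0

    # roots in the central third, headings uniform
    stack = []
    for _ in range(params.n_trunks):
        r0 = rng.uniform(h / 3, 2 * h / 3)
        c0 = rng.uniform(w / 3, 2 * w / 3)
        theta = rng.uniform(0, 2 * np.pi)
        stack.append((r0, c0, theta, float(params.segment_len_px), 0))

    min_len = 2.0
    while stack and segs_drawn < params.max_segments:
        r, c, theta, length, gen = stack.pop()
        n_chain = rng.integers(3, 8)  # segments per branch before natural stop
        for _ in range(n_chain):
            if length < min_len:
                break
            theta += np.deg2rad(rng.normal(0.0, params.angle_jitter_deg))
            r2 = r + length * np.sin(theta)
            c2 = c + length * np.cos(theta)
            ri, ci = int(round(r)), int(round(c))
            ri2, ci2 = int(round(r2)), int(round(c2))
            if not (0 <= ri2 < h and 0 <= ci2 < w and 0 <= ri < h and 0 <= ci < w):
                break
            rr, cc = _draw_line(ri, ci, ri2, ci2)
            flow[rr, cc] = True
            total_len_px += float(np.hypot(r2 - r, c2 - c))
            segs_drawn += 1
            r, c = r2, c2
            if gen < params.max_generation and rng.random() < params.branch_prob:
                side = np.deg2rad(rng.uniform(25, 50)) * rng.choice([-1.0, 1.0])
                stack.append((r, c, theta + side, length * params.len_decay, gen + 1))
            length *= params.len_decay

    radius = max(int(round((params.thickness_px - 1) / 2)), 0)
    if radius > 0:
        flow = _dilation(flow, disk(radius)).astype(bool)
    lesion = _closing(flow, disk(3)).astype(bool) | flow
    pair = MnvMaskPair(lesion, flow, params.pixel_size_mm)
    return pair, total_len_px * params.pixel_size_mm


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "eye_id",
    "age_years",
    "mnv_type",
    "bcva_baseline_logmar",
    "bcva_1y_logmar",
    "n_ivi_1y",
    "crt_baseline_um",
    "crt_upload_um",
    "ped_present_baseline",
    "ped_present_upload",
    "ped_height_baseline_um",
    "ped_height_upload_um",
    "irf_state_baseline",
    "srf_state_baseline",
    "irf_after_upload",
    "srf_after_upload",
    "both_after_upload",
    "area_mm2",
    "flow_density_pct",
    "fd",
    "suml_mm",
]

_STRING_COLUMNS = {"eye_id", "irf_state_baseline", "srf_state_baseline"}


@dataclass(frozen=True)
class EffectSpec:
    """Linear generative model for one (IV, DV) pair in effect mode.

    ``dv = intercept + slope * (iv / unit) + Normal(0, residual_sd)``;
    injection counts are additionally rounded and floored at 3 (every
    treated eye receives the three loading injections). ``iv_dist``
    optionally overrides the marginal predictor distribution with
    ``("normal", mean, sd)`` or ``("bernoulli", p)``.
    """

    iv_name: str
    dv_name: str
    slope: float
    intercept: float
    residual_sd: float
    unit: float = 1.0
    iv_dist: tuple | None = None


@dataclass(frozen=True)
class CohortConfig:
    """Marginal moments, state-transition probabilities and missingness.

    Defaults are the published cohort's printed values: n = 96 eyes, age
    77.9 ± 7.1 y, MNV types 1/2/3 at 49.0/30.2/20.8%, BCVA 0.58 ± 0.33
    (baseline) and 0.54 ± 0.40 logMAR (1 year), 8.26 ± 2.92 injections;
    baseline fluid IRF-only/SRF-only/both at 8.3/41.7/50.0%; PED prevalence
    65.5% with height 177 ± 202 µm; CRT 469 ± 177 µm dropping by
    83.3 ± 26.5 µm over the loading phase, PED height by 47.0 ± 48.0 µm;
    OCTA panel (area 1.56 ± 1.84 mm², flow density 41.2 ± 5.2%, FD
    1.292 ± 0.142, sumL 18.2 ± 21.7 mm) missing as a block for 16/96 eyes.
    Transitions: IRF disappears/persists/new/stable-absent at
    40.6/17.7/2.1/39.6% of the cohort; SRF disappears/persists at
    64.6/27.1%; PED disappears/persists/new at 22.3/42.6/6.4%.
    """

    n_eyes: int = 96
    seed: int = 0
    age_mean: float = 77.9
    age_sd: float = 7.1
    mnv_type_probs: tuple[float, float, float] = (0.490, 0.302, 0.208)
    bcva_baseline_mean: float = 0.58
    bcva_baseline_sd: float = 0.33
    bcva_1y_mean: float = 0.54
    bcva_1y_sd: float = 0.40
    ivi_mean: float = 8.26
    ivi_sd: float = 2.92
    fluid_baseline_probs: tuple[float, float, float] = (0.083, 0.417, 0.500)
    ped_prob_baseline: float = 0.655
    ped_height_mean_um: float = 177.0
    ped_height_sd_um: float = 202.0
    ped_decrease_mean_um: float = 47.0
    ped_decrease_sd_um: float = 48.0
    crt_baseline_mean_um: float = 469.0
    crt_baseline_sd_um: float = 177.0
    crt_decrease_mean_um: float = 83.3
    crt_decrease_sd_um: float = 26.5
    # conditional transition probabilities derived from the cohort-level
    # proportions above (e.g. P(IRF persists | IRF at baseline) = 17.7/58.3)
    irf_persist_given_present: float = 0.177 / 0.583
    irf_new_given_absent: float = 0.021 / 0.417
    srf_persist_given_present: float = 0.271 / 0.917
    srf_new_given_absent: float = 0.0
    ped_persist_given_present: float = 0.426 / 0.655
    ped_new_given_absent: float = 0.064 / 0.345
    octa_missing_frac: float = 16 / 96
    area_mean_mm2: float = 1.56
    area_sd_mm2: float = 1.84
    flow_density_mean_pct: float = 41.2
    flow_density_sd_pct: float = 5.2
    fd_mean: float = 1.292
    fd_sd: float = 0.142
    suml_mean_mm: float = 18.2
    suml_sd_mm: float = 21.7
    missingness: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be positive")
        for name in ("mnv_type_probs", "fluid_baseline_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
                raise ValueError(f"{name} must be non-negative and sum to 1")
        probs = [
            self.ped_prob_baseline,
            self.irf_persist_given_present,
            self.irf_new_given_absent,
            self.srf_persist_given_present,
            self.srf_new_given_absent,
            self.ped_persist_given_present,
            self.ped_new_given_absent,
            self.octa_missing_frac,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("transition probabilities must lie in [0, 1]")
        for name in ("age_sd", "bcva_baseline_sd", "bcva_1y_sd", "ivi_sd",
                     "ped_height_sd_um", "crt_baseline_sd_um", "fd_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _truncnorm0(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated below at 0, drawn with ``rng``."""
    if sd == 0:
        return np.full(size, max(mean, 0.0))
    a = (0.0 - mean) / sd
    dist = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    return dist.rvs(size=size, random_state=rng)


def simulate_cohort(
    config: CohortConfig,
    mode: str = "marginal",
    effect: EffectSpec | None = None,
) -> pd.DataFrame:
    """Draw a synthetic eye-level cohort table.

    ``mode="marginal"`` draws every column independently from its configured
    distribution. ``mode="effect"`` additionally rewrites the designated
    dependent variable from the linear model in ``effect`` (and, if
    requested, redraws the predictor from ``effect.iv_dist``), with no
    missingness on the designated pair.
    """
    if mode not in ("marginal", "effect"):
        raise ValueError("mode must be 'marginal' or 'effect'")
    if mode == "effect" and effect is None:
        raise ValueError("effect mode requires an EffectSpec")
    rng = np.random.default_rng(config.seed)
    n = config.n_eyes

    df = pd.DataFrame({"eye_id": [f"eye{i:04d}" for i in range(n)]})
    df["age_years"] = rng.normal(config.age_mean, config.age_sd, n)
    df["mnv_type"] = rng.choice([1, 2, 3], size=n, p=config.mnv_type_probs)
    df["bcva_baseline_logmar"] = rng.normal(
        config.bcva_baseline_mean, config.bcva_baseline_sd, n
    )
    df["bcva_1y_logmar"] = rng.normal(config.bcva_1y_mean, config.bcva_1y_sd, n)
    ivi_raw = rng.normal(config.ivi_mean, config.ivi_sd, n)
    df["n_ivi_1y"] = np.maximum(np.rint(ivi_raw), 3).astype(float)

    df["crt_baseline_um"] = _truncnorm0(
        rng, config.crt_baseline_mean_um, config.crt_baseline_sd_um, n
    )
    crt_drop = rng.normal(config.crt_decrease_mean_um, config.crt_decrease_sd_um, n)
    df["crt_upload_um"] = np.maximum(df["crt_baseline_um"] - crt_drop, 50.0)

    # baseline fluid category: IRF-only / SRF-only / both
    cat = rng.choice(3, size=n, p=config.fluid_baseline_probs)
    irf_b = (cat == 0) | (cat == 2)
    srf_b = (cat == 1) | (cat == 2)
    df["irf_state_baseline"] = np.where(irf_b, "present", "absent")
    df["srf_state_baseline"] = np.where(srf_b, "present", "absent")
    u = rng.random(n)
    irf_u = np.where(irf_b, u < config.irf_persist_given_present,
                     u < config.irf_new_given_absent)
    u = rng.random(n)
    srf_u = np.where(srf_b, u < config.srf_persist_given_present,
                     u < config.srf_new_given_absent)
    df["irf_after_upload"] = irf_u.astype(float)
    df["srf_after_upload"] = srf_u.astype(float)
    df["both_after_upload"] = (irf_u & srf_u).astype(float)

    ped_b = rng.random(n) < config.ped_prob_baseline
    df["ped_present_baseline"] = ped_b.astype(float)
    height_b = np.where(
        ped_b,
        _truncnorm0(rng, config.ped_height_mean_um, config.ped_height_sd_um, n),
        np.nan,
    )
    df["ped_height_baseline_um"] = height_b
    u = rng.random(n)
    ped_u = np.where(ped_b, u < config.ped_persist_given_present,
                     u < config.ped_new_given_absent)
    df["ped_present_upload"] = ped_u.astype(float)
    ped_drop = rng.normal(config.ped_decrease_mean_um, config.ped_decrease_sd_um, n)
    new_height = _truncnorm0(rng, config.ped_height_mean_um, config.ped_height_sd_um, n)
    height_u = np.where(
        ped_u,
        np.where(ped_b, np.maximum(height_b - ped_drop, 5.0), new_height),
        np.nan,
    )
    df["ped_height_upload_um"] = height_u

    df["area_mm2"] = _truncnorm0(rng, config.area_mean_mm2, config.area_sd_mm2, n)
    df["flow_density_pct"] = np.clip(
        rng.normal(config.flow_density_mean_pct, config.flow_density_sd_pct, n), 0, 100
    )
    df["fd"] = rng.normal(config.fd_mean, config.fd_sd, n)
    df["suml_mm"] = _truncnorm0(rng, config.suml_mean_mm, config.suml_sd_mm, n)
    octa_missing = rng.random(n) < config.octa_missing_frac
    for col in ("area_mm2", "flow_density_pct", "fd", "suml_mm"):
        df.loc[octa_missing, col] = np.nan

    for col, rate in config.missingness.items():
        if col not in df.columns:
            raise KeyError(f"missingness refers to unknown column {col!r}")
        df.loc[rng.random(n) < rate, col] = np.nan

    if mode == "effect":
        assert effect is not None
        if effect.iv_name not in df.columns or effect.dv_name not in df.columns:
            raise KeyError("effect spec names unknown columns")
        if effect.iv_dist is not None:
            kind = effect.iv_dist[0]
            if kind == "normal":
                iv = rng.normal(effect.iv_dist[1], effect.iv_dist[2], n)
            elif kind == "bernoulli":
                iv = (rng.random(n) < effect.iv_dist[1]).astype(float)
            else:
                raise ValueError(f"unknown iv_dist kind {kind!r}")
            df[effect.iv_name] = iv
        else:
            iv = df[effect.iv_name].to_numpy(float)
            if np.isnan(iv).any():  # designated pair is complete by contract
                fill = rng.normal(np.nanmean(iv), np.nanstd(iv), n)
                iv = np.where(np.isnan(iv), np.maximum(fill, 0), iv)
                df[effect.iv_name] = iv
        dv = (
            effect.intercept
            + effect.slope * (np.asarray(iv, dtype=float) / effect.unit)
            + rng.normal(0.0, effect.residual_sd, n)
        )
        if effect.dv_name == "n_ivi_1y":
            dv = np.maximum(np.rint(dv), 3)
        df[effect.dv_name] = dv

    return df[COHORT_COLUMNS]


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV; missing values become empty cells."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks mandatory columns: {missing}")
    table[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and schema-validate a cohort CSV (lossless round trip)."""
    df = pd.read_csv(path, dtype={c: str for c in _STRING_COLUMNS})
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise ValueError(f"unknown columns in cohort file: {unknown}")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks mandatory columns: {missing}")
    for col in COHORT_COLUMNS:
        if col in _STRING_COLUMNS:
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
            raise ValueError(f"malformed numeric in column {col!r} at file row(s) {rows}") from exc
    return df[COHORT_COLUMNS]
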