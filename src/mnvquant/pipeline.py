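"""End-to-end orchestration: cohort -> morphometry -> regression battery -> report.

The default regression battery mirrors the published outcome analysis: 15
independent variables (OCT: central retinal thickness at baseline/after the
loading phase and its relative decrease; pigment epithelium detachment
presence/height at both timepoints and relative height decrease;
intraretinal/subretinal-fluid presence indicators after loading; OCTA: MNV
area, total vessel length, flow density, fractal dimension) against two
dependent variables, 1-year best corrected visual acuity (logMAR) and the
1-year intravitreal-injection count. Relative decreases are
``100 * (baseline - follow-up) / baseline``, defined only where the
baseline is positive, and are fitted per 10% of decrease.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regression import RegressionSpec, run_regression_battery
from .synthetic import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "default_iv_specs",
    "default_battery",
    "derive_change_columns",
    "summarize_cohort",
    "run_pipeline",
    "render_report",
]

# (iv column, unit divisor, unit label); units follow the published tables
_IV_TABLE = [
    ("crt_baseline_um", 200.0, "200 µm"),
    ("crt_upload_um", 200.0, "200 µm"),
    ("crt_decrease_pct", 10.0, "10%"),
    ("ped_present_baseline", 1.0, "present"),
    ("ped_height_baseline_um", 200.0, "200 µm"),
    ("ped_present_upload", 1.0, "present"),
    ("ped_height_upload_um", 200.0, "200 µm"),
    ("ped_height_decrease_pct", 10.0, "10%"),
    ("irf_after_upload", 1.0, "present"),
    ("srf_after_upload", 1.0, "present"),
    ("both_after_upload", 1.0, "present"),
    ("area_mm2", 1.0, "1 mm"),
    ("suml_mm", 20.0, "20 mm"),
    ("flow_density_pct", 10.0, "10%"),
    ("fd", 1.0, ""),
]

DEFAULT_DVS = ("bcva_1y_logmar", "n_ivi_1y")


def default_iv_specs(dv_name: str) -> list[RegressionSpec]:
    """The 15 default IV rows for one dependent variable."""
    return [
        RegressionSpec(iv_name=iv, dv_name=dv_name, unit=unit, unit_label=label)
        for iv, unit, label in _IV_TABLE
    ]


def default_battery() -> list[RegressionSpec]:
    """All default specs: 15 IVs for each of the two outcomes (30 rows)."""
    return [spec for dv in DEFAULT_DVS for spec in default_iv_specs(dv)]


def derive_change_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add relative-decrease columns for CRT and PED height.

    ``*_decrease_pct = 100 * (baseline - follow_up) / baseline`` where the
    baseline is positive, NaN otherwise. A PED that resolved completely
    counts as a 100% height decrease; eyes without baseline PED have no
    defined decrease (this reproduces the published per-row n).
    """
    df = cohort.copy()
    b = df["crt_baseline_um"]
    u = df["crt_upload_um"]
    df["crt_decrease_pct"] = np.where(b > 0, 100.0 * (b - u) / b, np.nan)

    hb = df["ped_height_baseline_um"].to_numpy(float)
    hu = df["ped_height_upload_um"].to_numpy(float)
    present_u = df["ped_present_upload"].to_numpy(float)
    hu_eff = np.where(present_u == 0, 0.0, hu)  # resolved PED has height 0
    dec = np.where(hb > 0, 100.0 * (hb - hu_eff) / hb, np.nan)
    df["ped_height_decrease_pct"] = dec
    return df


def summarize_cohort(cohort: pd.DataFrame) -> dict:
    """Cohort descriptives shaped like a 'general clinical data' table."""
    def ms(col):
        s = cohort[col].dropna()
        return {"mean": float(s.mean()), "sd": float(s.std(ddof=1)), "n": int(s.size)}

    types = cohort["mnv_type"].value_counts(normalize=True)
    return {
        "n_eyes": int(len(cohort)),
        "age_years": ms("age_years"),
        "mnv_type_pct": {int(k): round(100 * float(v), 1) for k, v in types.items()},
        "bcva_baseline_logmar": ms("bcva_baseline_logmar"),
        "bcva_1y_logmar": ms("bcva_1y_logmar"),
        "n_ivi_1y": ms("n_ivi_1y"),
        "n_octa": int(cohort["fd"].notna().sum()),
    }


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one cohort source: a CSV path (``cohort_path``) or a simulation
    config (``cohort_sim``). Mask quantification is optional and driven by a
    manifest CSV with columns eye_id, lesion_path, flow_path.
    """

    out_dir: str | Path = "out"
    seed: int = 0
    cohort_path: str | Path | None = None
    cohort_sim: CohortConfig | None = None
    manifest_path: str | Path | None = None
    pixel_size_mm: float = 6.0 / 500
    fd_substrate: str = "skeleton"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.cohort_sim is None):
            raise ValueError("exactly one of cohort_path / cohort_sim is required")
        if self.fd_substrate not in ("skeleton", "binarized"):
            raise ValueError("fd_substrate must be 'skeleton' or 'binarized'")


def _config_hash(config: RunConfig) -> str:
    payload = {
        "seed": config.seed,
        "cohort_path": str(config.cohort_path),
        "cohort_sim": asdict(config.cohort_sim) if config.cohort_sim else None,
        "manifest_path": str(config.manifest_path),
        "pixel_size_mm": config.pixel_size_mm,
        "fd_substrate": config.fd_substrate,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=False)


def _quantify_manifest(manifest_path, pixel_size_mm, fd_substrate) -> pd.DataFrame:
    from .morphometry import load_mask_pair, quantify

    manifest = pd.read_csv(manifest_path)
    for col in ("eye_id", "lesion_path", "flow_path"):
        if col not in manifest.columns:
            raise ValueError(f"manifest lacks column {col!r}")
    rows = []
    for rec in manifest.itertuples(index=False):
        pair = load_mask_pair(rec.lesion_path, rec.flow_path, pixel_size_mm)
        ms = quantify(pair, fd_substrate=fd_substrate)
        rows.append(
            {
                "eye_id": rec.eye_id,
                "area_mm2": ms.area_mm2,
                "flow_density_pct": ms.flow_density_pct,
                "fd": ms.fractal_dimension,
                "suml_mm": ms.suml_mm,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; writes the report bundle and returns its paths.

    Outputs under ``config.out_dir``: ``morph.csv`` (per-eye descriptors,
    if a mask manifest was given), ``results_bcva.csv`` / ``results_ivi.csv``
    (the regression batteries), ``summary.json`` (cohort descriptives),
    ``report.md`` and ``run.log``. Deterministic for a fixed seed; every
    output carries the config hash.
    """
    from .synthetic import read_cohort
    from dataclasses import replace

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mnvquant")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        import mnvquant

        logger.info("mnvquant %s  seed=%d  config_hash=%s",
                    mnvquant.__version__, config.seed, cfg_hash)

        if config.cohort_sim is not None:
            sim = replace(config.cohort_sim, seed=config.seed)
            cohort = simulate_cohort(sim, mode="marginal")
            logger.info("simulated cohort of %d eyes", len(cohort))
        else:
            cohort = read_cohort(config.cohort_path)
            logger.info("loaded cohort of %d eyes from %s", len(cohort), config.cohort_path)

        paths = {"run_log": log_path}

        if config.manifest_path is not None:
            try:
                morph = _quantify_manifest(
                    config.manifest_path, config.pixel_size_mm, config.fd_substrate
                )
            except Exception as exc:
                raise RuntimeError(f"stage morphometry failed: {exc}") from exc
            _write_csv(morph, out / "morph.csv", cfg_hash)
            paths["morph"] = out / "morph.csv"
            # manifest-derived descriptors replace the cohort's OCTA block
            cohort = cohort.drop(
                columns=["area_mm2", "flow_density_pct", "fd", "suml_mm"]
            ).merge(morph, on="eye_id", how="left")

        cohort = derive_change_columns(cohort)

        for dv, fname in zip(DEFAULT_DVS, ("results_bcva.csv", "results_ivi.csv")):
            specs, skipped = [], []
            for spec in default_iv_specs(dv):
                if spec.iv_name not in cohort.columns:
                    skipped.append(spec.iv_name)
                    continue
                sub = cohort[[spec.iv_name, dv]].dropna()
                if len(sub) < 3 or sub[spec.iv_name].nunique() < 2:
                    skipped.append(spec.iv_name)
                    continue
                specs.append(spec)
            for name in skipped:
                logger.warning("regression[%s]: IV %s skipped (missing or degenerate)", dv, name)
            try:
                results = run_regression_battery(cohort, specs)
            except Exception as exc:
                raise RuntimeError(f"stage regression[{dv}] failed: {exc}") from exc
            _write_csv(results, out / fname, cfg_hash)
            paths[fname.removesuffix(".csv")] = out / fname
            logger.info("battery for %s: %d rows, n range %d-%d",
                        dv, len(results), results["n"].min(), results["n"].max())

        summary = {"config_hash": cfg_hash, "seed": config.seed}
        summary.update(summarize_cohort(cohort))
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        paths["summary"] = out / "summary.json"

        report = [f"<!-- config_hash: {cfg_hash} -->"]
        for dv, key in zip(
            ("BCVA at 1 year (logMAR)", "Number of IVIs at 1 year"),
            ("results_bcva", "results_ivi"),
        ):
            df = pd.read_csv(paths[key], comment="#")
            report.append(render_report(df, title=dv))
        (out / "report.md").write_text("\n\n".join(report) + "\n")
        paths["report"] = out / "report.md"
        return paths
    finally:
        root.removeHandler(handler)
        handler.close()


def _p_band(p: float) -> str:
    if p < 0.01:
        return "<0.01"
    if p < 0.05:
        return "<0.05"
    return f"{p:.3f}"


def render_report(results: pd.DataFrame, title: str = "") -> str:
    """Render a results table as markdown with 3-decimal formatting.

    Confidence intervals print as ``[low; high]``; p-values print both the
    significance band (``<0.01`` / ``<0.05``) and the exact value.
    """
    lines = []
    if title:
        lines.append(f"## {title}")
        lines.append("")
    lines.append("| IV | Unit | n | Beta | 95% CI | p | p (exact) |")
    lines.append("|---|---|---|---|---|---|---|")
    for row in results.itertuples(index=False):
        unit = row.unit_label if isinstance(row.unit_label, str) else ""
        lines.append(
            f"| {row.iv} | {unit} | {int(row.n)} | {row.beta:.3f} "
            f"| [{row.ci_low:.3f}; {row.ci_high:.3f}] "
            f"| {_p_band(row.p_value)} | {row.p_value:.3g} |"
        )
    return "\n".join(lines)
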