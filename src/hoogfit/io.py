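"""File formats, configuration and plotting.

All tabular data are delimited text (CSV/TSV): the unit of exchange is the
peak-intensity table (one row per spin x spinlock power x offset x delay) or
the derived R1rho dispersion table, never a vendor NMR format.  Fit reports
are JSON (full provenance: inputs, seed, bounds, package version, config
hash) plus a flat CSV summary with one row per spin x temperature.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import DecayCurve, ExchangeModel, FieldContext, RDProfile, SpinlockCondition, r1rho_profile
from .fitting import ExchangeFit, FitBounds
from .thermo import ThermoFit

__all__ = [
    "StudyConfig",
    "read_decay_table",
    "write_decay_table",
    "read_profile_table",
    "write_profile_table",
    "write_fit_report",
    "read_fit_report",
    "plot_dispersion",
    "write_trajectory_csv",
    "write_landscape_csv",
]

DECAY_COLUMNS = [
    "spin_label", "nucleus", "omega_sl_hz", "offset_hz",
    "delay_s", "intensity", "intensity_error",
]
PROFILE_COLUMNS = [
    "spin_label", "nucleus", "omega_sl_hz", "offset_hz", "r1rho", "r1rho_error",
]
REPORT_CSV_COLUMNS = [
    "spin_label", "temperature", "model", "alignment",
    "p_b", "p_b_sd", "k_ex", "k_ex_sd", "delta_omega", "delta_omega_sd",
    "r1", "r1_sd", "r2", "r2_sd",
    "chi2", "reduced_chi2", "aic", "bic", "n_points", "seed",
]


@dataclass
class StudyConfig:
    """Declarative description of one analysis run."""

    scenario: str = ""
    input_paths: tuple[str, ...] = ()
    field_mhz: float = 700.0
    nucleus_map: dict = field(default_factory=dict)  # spin_label -> nucleus
    temperature: float | None = None
    alignment: str = "ground"
    bounds: FitBounds = field(default_factory=FitBounds)
    n_mc: int = 1000
    seed: int = 0

    def config_hash(self) -> str:
        payload = asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "bounds" in raw and isinstance(raw["bounds"], dict):
            raw["bounds"] = FitBounds(**{k: tuple(v) for k, v in raw["bounds"].items()})
        if "input_paths" in raw:
            raw["input_paths"] = tuple(raw["input_paths"])
        cfg = cls(**raw)
        for p in cfg.input_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input path does not exist: {p}")
        return cfg


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    numeric = [c for c in required if c not in ("spin_label", "nucleus")]
    for c in numeric:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[col.isna() & df[c].notna()].tolist()
        if bad:
            rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric value(s) in column {c!r} at line(s) {rows}")
        df[c] = col
    return df


def read_decay_table(path: str | Path, field_mhz: float = 700.0, alignment: str = "ground") -> list[DecayCurve]:
    """Read a peak-intensity decay table into per-(spin, condition) curves.

    Expected header: spin_label, nucleus, omega_sl_hz, offset_hz, delay_s,
    intensity, intensity_error.  Rows are validated (missing columns,
    non-numeric cells and duplicate (spin, condition, delay) rows are rejected
    with line numbers); curve order follows first appearance in the file.
    """
    df = _read_table(path, DECAY_COLUMNS)
    key = ["spin_label", "nucleus", "omega_sl_hz", "offset_hz", "delay_s"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.index[dup].tolist()
        rows = ", ".join(str(i + 2) for i in first[:6])
        raise ValueError(f"{path}: duplicate (spin, condition, delay) row(s) at line(s) {rows}")
    curves: list[DecayCurve] = []
    group_key = ["spin_label", "nucleus", "omega_sl_hz", "offset_hz"]
    for (label, nuc, osl, off), grp in df.groupby(group_key, sort=False):
        grp = grp.sort_values("delay_s")
        fld = FieldContext(field_mhz, nuc)
        cond = SpinlockCondition(osl, off, fld, alignment, tuple(grp["delay_s"]))
        errs = None
        if grp["intensity_error"].notna().all() and (grp["intensity_error"] > 0).all():
            errs = tuple(grp["intensity_error"])
        curves.append(DecayCurve(cond, tuple(grp["intensity"]), errs, label))
    return curves


def write_decay_table(curves: list[DecayCurve], path: str | Path, nucleus_of=None) -> None:
    rows = []
    for c in curves:
        errs = c.intensity_errors or [np.nan] * len(c.intensities)
        for t, i, e in zip(c.condition.delays, c.intensities, errs):
            rows.append(
                {
                    "spin_label": c.spin_label,
                    "nucleus": c.condition.field.nucleus,
                    "omega_sl_hz": c.condition.omega_sl,
                    "offset_hz": c.condition.offset,
                    "delay_s": t,
                    "intensity": i,
                    "intensity_error": e,
                }
            )
    pd.DataFrame(rows, columns=DECAY_COLUMNS).to_csv(path, index=False, float_format="%.12g")


def read_profile_table(
    path: str | Path,
    field_mhz: float = 700.0,
    alignment: str = "ground",
    temperature: float | None = None,
    ph: float | None = None,
) -> list[RDProfile]:
    """Read an R1rho dispersion table into per-spin profiles."""
    df = _read_table(path, PROFILE_COLUMNS)
    profiles = []
    for (label, nuc), grp in df.groupby(["spin_label", "nucleus"], sort=False):
        fld = FieldContext(field_mhz, nuc)
        conds = tuple(
            SpinlockCondition(o, f, fld, alignment)
            for o, f in zip(grp["omega_sl_hz"], grp["offset_hz"])
        )
        errs = None
        if grp["r1rho_error"].notna().all() and (grp["r1rho_error"] > 0).all():
            errs = tuple(grp["r1rho_error"])
        profiles.append(RDProfile(label, conds, tuple(grp["r1rho"]), errs, temperature, ph))
    return profiles


def write_profile_table(profiles: list[RDProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        errs = p.r1rho_error or [np.nan] * len(p.r1rho)
        for c, r, e in zip(p.conditions, p.r1rho, errs):
            rows.append(
                {
                    "spin_label": p.spin_label,
                    "nucleus": c.field.nucleus,
                    "omega_sl_hz": c.omega_sl,
                    "offset_hz": c.offset,
                    "r1rho": r,
                    "r1rho_error": e,
                }
            )
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False, float_format="%.12g")


def _fit_row(fit: ExchangeFit) -> dict:
    unc = fit.uncertainties or {}
    m = fit.model
    return {
        "spin_label": fit.spin_label,
        "temperature": fit.temperature,
        "model": "two_state" if fit.n_params > 2 else "no_exchange",
        "alignment": fit.alignment_used,
        "p_b": m.p_b, "p_b_sd": unc.get("p_b"),
        "k_ex": m.k_ex, "k_ex_sd": unc.get("k_ex"),
        "delta_omega": m.delta_omega, "delta_omega_sd": unc.get("delta_omega"),
        "r1": m.r1, "r1_sd": unc.get("r1"),
        "r2": m.r2, "r2_sd": unc.get("r2"),
        "chi2": fit.chi2, "reduced_chi2": fit.reduced_chi2,
        "aic": fit.aic, "bic": fit.bic,
        "n_points": fit.n_points, "seed": fit.seed,
    }


def write_fit_report(
    fits: list[ExchangeFit],
    path_prefix: str | Path,
    thermo: list[ThermoFit] | None = None,
    config: StudyConfig | None = None,
) -> tuple[Path, Path]:
    """Write a JSON report (full provenance) and a flat CSV summary.

    Returns the (json_path, csv_path) pair; an empty thermo section is
    permitted for single-temperature studies.
    """
    if not fits:
        raise ValueError("need at least one fit to report")
    prefix = Path(path_prefix)
    json_path = prefix.with_suffix(".json")
    csv_path = prefix.with_suffix(".csv")
    payload = {
        "version": __version__,
        "config": asdict(config) if config is not None else None,
        "config_hash": config.config_hash() if config is not None else None,
        "seed": fits[0].seed,
        "fits": [_fit_row(f) for f in fits],
        "thermo": [asdict(t) for t in (thermo or [])],
    }
    json_path.write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")
    pd.DataFrame([_fit_row(f) for f in fits], columns=REPORT_CSV_COLUMNS).to_csv(
        csv_path, index=False, float_format="%.12g"
    )
    return json_path, csv_path


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, FitBounds):
        return asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_fit_report(path_prefix: str | Path) -> dict:
    return json.loads(Path(path_prefix).with_suffix(".json").read_text())


def plot_dispersion(
    profile: RDProfile,
    fit: ExchangeFit | None = None,
    path: str | Path | None = None,
    n_curve: int = 120,
):
    """Off-resonance dispersion plot: R2 + Rex versus offset per spinlock power.

    Data points carry one-s.d. error bars; when a fit is given, the model
    curve from its exchange parameters is overlaid per power.  R2 + Rex is
    obtained from R1rho as (R1rho - R1 cos^2 theta) / sin^2 theta with R1 from
    the fit (or the smallest observed R1rho without one).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r1 = fit.model.r1 if fit is not None else min(profile.r1rho)
    fig, ax = plt.subplots(figsize=(5.0, 3.4))
    powers = sorted({c.omega_sl for c in profile.conditions})
    cmap = plt.get_cmap("viridis")
    for i, p in enumerate(powers):
        idx = [j for j, c in enumerate(profile.conditions) if c.omega_sl == p]
        off = np.array([profile.conditions[j].offset for j in idx])
        r = np.array([profile.r1rho[j] for j in idx])
        th = np.arctan2(p, off)
        y = (r - r1 * np.cos(th) ** 2) / np.sin(th) ** 2
        yerr = None
        if profile.r1rho_error is not None:
            yerr = np.array([profile.r1rho_error[j] for j in idx]) / np.sin(th) ** 2
        color = cmap(i / max(len(powers) - 1, 1))
        ax.errorbar(off, y, yerr=yerr, fmt="o", ms=3.5, color=color,
                    label=f"{p:g} Hz", capsize=2, lw=1)
        if fit is not None and len(idx) > 1:
            dense = np.linspace(off.min(), off.max(), n_curve)
            conds = [
                SpinlockCondition(p, float(o), profile.conditions[idx[0]].field,
                                  fit.alignment_used, profile.conditions[idx[0]].delays)
                for o in dense
            ]
            rm = r1rho_profile(fit.model, conds, fit.method)
            thd = np.arctan2(p, dense)
            ym = (rm - fit.model.r1 * np.cos(thd) ** 2) / np.sin(thd) ** 2
            ax.plot(dense, ym, "-", color=color, lw=1.2)
    ax.set_xlabel(r"$\Omega/2\pi$ (Hz)")
    ax.set_ylabel(r"$R_2 + R_\mathrm{ex}$ (s$^{-1}$)")
    title = profile.spin_label
    if profile.temperature is not None:
        title += f", {profile.temperature:g} C"
    ax.set_title(title, fontsize=10)
    ax.legend(fontsize=7, title=r"$\omega_\mathrm{SL}/2\pi$", title_fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150, metadata=_figure_metadata(Path(path).suffix))
        plt.close(fig)
        return Path(path)
    return fig


def _figure_metadata(suffix: str) -> dict | None:
    # pin volatile metadata so identical inputs give identical bytes
    if suffix == ".png":
        return {"Software": "hoogfit"}
    if suffix == ".svg":
        return {"Date": None}
    return None


def write_trajectory_csv(traj, path: str | Path) -> None:
    """Biased-dynamics trajectory time series as CSV."""
    pd.DataFrame(
        {
            "chi_deg": traj.chi,
            "theta_deg": traj.theta,
            "rho_A2": traj.rho,
            "rho_a_A2": traj.rho_a,
            "bias_kcal": traj.bias_energy,
            "energy_kcal": traj.energy,
        }
    ).to_csv(path, index=False, float_format="%.8g")


def write_landscape_csv(grid: dict, path: str | Path) -> None:
    """Binned (chi, theta) mean-energy grid as long-format CSV."""
    xc = 0.5 * (grid["chi_edges"][:-1] + grid["chi_edges"][1:])
    yc = 0.5 * (grid["theta_edges"][:-1] + grid["theta_edges"][1:])
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    pd.DataFrame(
        {
            "chi_deg": X.ravel(),
            "theta_deg": Y.ravel(),
            "mean_energy_kcal": grid["mean_energy"].ravel(),
            "count": grid["counts"].ravel().astype(int),
        }
    ).to_csv(path, index=False, float_format="%.8g")
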