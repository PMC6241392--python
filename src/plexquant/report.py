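"""End-to-end pipeline and diagnostic plots.

``run_pipeline`` wires the stages together: read FCS files -> two-stage
bead/analyte identification (pooled across samples by default, so the
clustering decision is identical for every sample) -> per-analyte MFI ->
split standards from experimental samples by file-name pattern ->
standard-curve fit per analyte -> inverse concentration estimation ->
CSV export. Every stage logs its event counts, and identical inputs
plus the same seed give byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .analyte_ident import (
    ANALYTE_ID_COL,
    BEAD_GROUP_COL,
    IdentStageArgs,
    identify_legendplex_analyte,
)
from .clustering import ClusterParams
from .errors import ConfigError, DataError, FitError
from .fcs_io import (
    EXPERIMENTAL_PATTERN,
    STANDARD_PATTERN,
    parse_sample_name,
    read_fcs,
)
from .panel import PanelInfo, load_panel
from .quantify import (
    StandardCurve,
    calc_analyte_mfi,
    calc_std_conc,
    calculate_concentration,
    fit_standard_curve,
    logistic5,
)

logger = logging.getLogger("plexquant")

DEFAULT_CONFIG = {
    "fsc_ssc": ["FSC-A", "SSC-A"],
    "discrimination_channel": "FL6-H",
    "reporter_channel": "FL2-H",
    "filters": None,
    "cofactor": 1.0,
    "method": "clara",
    "scatter_trim": 0.01,
    "reporter_trim": 0.03,
    "mean_fun": "geometric",
    "model": "5PL",
    "seed": 0,
    "standard_pattern": STANDARD_PATTERN,
    "experimental_pattern": EXPERIMENTAL_PATTERN,
    "per_sample": False,
    "plots": False,
}


def _merge_config(config: Mapping | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        config = yaml.safe_load(path.read_text()) or {}
    cfg = dict(DEFAULT_CONFIG)
    unknown = set(config) - set(DEFAULT_CONFIG) - {"fcs_dir", "panel", "out_dir"}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(config)
    for key in ("fcs_dir", "panel"):
        if key not in cfg or cfg[key] in (None, ""):
            raise ConfigError(f"config must set {key!r}")
    return cfg


def _stage_args(cfg: dict, n_groups: int) -> tuple[IdentStageArgs, IdentStageArgs]:
    scatter = IdentStageArgs(
        parameters=tuple(cfg["fsc_ssc"]),
        column_name=BEAD_GROUP_COL,
        params=ClusterParams(
            method=cfg["method"],
            k=n_groups,
            trim=float(cfg["scatter_trim"]),
            seed=int(cfg["seed"]),
        ),
    )
    reporter = IdentStageArgs(
        parameters=(cfg["discrimination_channel"],),
        column_name=ANALYTE_ID_COL,
        params=ClusterParams(
            method=cfg["method"],
            trim=float(cfg["reporter_trim"]),
            seed=int(cfg["seed"]) + 1,
        ),
    )
    return scatter, reporter


def quantify_experiment(
    samples: Mapping[str, pd.DataFrame],
    panel: PanelInfo,
    config: Mapping | None = None,
) -> tuple[pd.DataFrame, dict[str, StandardCurve], pd.DataFrame]:
    """Identify, summarize and quantify a set of already-loaded samples.

    ``samples`` maps sample name to an ingested event table (scatter on
    the native scale, bead channels arcsinh-transformed). Returns the
    experimental quantification table, the fitted curves per analyte,
    and the per-analyte standard tables (with back-calculated
    concentrations, for QC).
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    frames = []
    for name in sorted(samples):
        df = samples[name].copy()
        if "sample_id" not in df.columns:
            df.insert(0, "sample_id", name)
        frames.append(df)
    events = pd.concat(frames, ignore_index=True)
    logger.info("pooled %d events from %d samples", len(events), len(frames))

    scatter_args, reporter_args = _stage_args(cfg, len(panel.group_ids))
    if cfg["per_sample"]:
        parts = []
        for name, grp in events.groupby("sample_id", sort=True):
            parts.append(
                identify_legendplex_analyte(grp, panel, scatter_args, reporter_args)
            )
        events = pd.concat(parts, ignore_index=True)
    else:
        events = identify_legendplex_analyte(events, panel, scatter_args, reporter_args)
    n_assigned = int(events[ANALYTE_ID_COL].notna().sum())
    logger.info(
        "identification: %d events assigned, %d missing (total %d)",
        n_assigned,
        len(events) - n_assigned,
        len(events),
    )
    assert n_assigned + int(events[ANALYTE_ID_COL].isna().sum()) == len(events)

    mfi = calc_analyte_mfi(
        events,
        parameter=cfg["reporter_channel"],
        column_name=ANALYTE_ID_COL,
        mean_fun=cfg["mean_fun"],
    )
    roles = {
        s: parse_sample_name(
            s, cfg["standard_pattern"], cfg["experimental_pattern"]
        )
        for s in mfi["sample_id"].unique()
    }
    mfi["role"] = mfi["sample_id"].map(lambda s: roles[s].role)
    mfi["sample_number"] = mfi["sample_id"].map(lambda s: roles[s].number)
    standards = mfi[mfi["role"] == "standard"]
    experimental = mfi[mfi["role"] == "experimental"]
    if standards.empty:
        raise DataError("no standard samples matched the standard pattern")

    analyte_names = {
        aid: panel.entry(aid).name for aid in panel.analyte_ids
    }
    curves: dict[str, StandardCurve] = {}
    std_tables: list[pd.DataFrame] = []
    quant_rows: list[pd.DataFrame] = []
    for aid in panel.analyte_ids:
        std = standards[standards[ANALYTE_ID_COL] == aid].copy()
        if std.empty:
            raise DataError(f"no standard MFIs for analyte {aid!r}")
        numbers = np.sort(std["sample_number"].unique())[::-1]
        conc_of = dict(
            zip(
                numbers,
                calc_std_conc(
                    numbers,
                    panel.entry(aid).start_concentration,
                    panel.std_dilution,
                ),
            )
        )
        std["concentration"] = std["sample_number"].map(conc_of)
        std["log10_mfi"] = np.log10(std["mfi"])
        curve = fit_standard_curve(std, model=cfg["model"])
        curves[aid] = curve
        std_tables.append(calculate_concentration(std, curve))

        exp = experimental[experimental[ANALYTE_ID_COL] == aid].copy()
        if not exp.empty:
            quant_rows.append(calculate_concentration(exp, curve))

    std_all = pd.concat(std_tables, ignore_index=True)
    quant = (
        pd.concat(quant_rows, ignore_index=True)
        if quant_rows
        else pd.DataFrame(columns=list(experimental.columns) + ["calc_conc"])
    )
    quant["analyte_name"] = quant[ANALYTE_ID_COL].map(analyte_names)
    std_all["analyte_name"] = std_all[ANALYTE_ID_COL].map(analyte_names)
    quant = quant.sort_values(["sample_id", ANALYTE_ID_COL], kind="stable").reset_index(
        drop=True
    )
    return quant, curves, std_all


def _export_table(quant: pd.DataFrame, units: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Sample": quant["sample_id"],
            "Analyte ID": quant[ANALYTE_ID_COL],
            "Analyte name": quant["analyte_name"],
            "MFI": quant["mfi"],
            f"Concentration ({units})": quant["calc_conc"],
            "Concentration error": quant["calc_conc_error"],
            "flag": quant["flag"],
        }
    )


def run_pipeline(
    config: Mapping | str | Path, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, dict[str, Path]]:
    """Run the full pipeline described by a config mapping or YAML file.

    Required keys: ``fcs_dir`` and ``panel``; every other key of
    :data:`DEFAULT_CONFIG` may be overridden. Writes ``conc.csv`` (the
    experimental quantification), ``standards.csv`` (QC back-calculation
    of the standards) and, with ``plots: true``, one standard-curve plot
    per analyte. Partial outputs are removed if a stage fails.
    """
    cfg = _merge_config(config)
    panel = load_panel(cfg["panel"])  # fails before any FCS is read
    fcs_dir = Path(cfg["fcs_dir"])
    files = sorted(fcs_dir.glob("*.fcs"))
    if not files:
        raise DataError(f"no .fcs files found in {fcs_dir}")
    out_dir = Path(out_dir if out_dir is not None else cfg.get("out_dir", fcs_dir))
    out_dir.mkdir(parents=True, exist_ok=True)

    samples = {}
    for path in files:
        df = read_fcs(
            path,
            fsc_ssc=tuple(cfg["fsc_ssc"]),
            bead_channels=(cfg["discrimination_channel"], cfg["reporter_channel"]),
            filters=cfg["filters"],
            cofactor=float(cfg["cofactor"]),
        )
        logger.info("read %s: %d events retained", path.name, len(df))
        samples[path.stem] = df

    artifacts: dict[str, Path] = {}
    try:
        quant, curves, std_all = quantify_experiment(samples, panel, cfg)
        conc_path = out_dir / "conc.csv"
        _export_table(quant, panel.units).to_csv(conc_path, index=False)
        artifacts["conc"] = conc_path
        std_path = out_dir / "standards.csv"
        std_all.to_csv(std_path, index=False)
        artifacts["standards"] = std_path
        if cfg["plots"]:
            for aid, curve in curves.items():
                std = std_all[std_all[ANALYTE_ID_COL] == aid]
                est = quant[quant[ANALYTE_ID_COL] == aid]
                p = out_dir / f"std_curve_{aid}.png"
                plot_standard_curve(std, curve, estimates=est, path=p)
                artifacts[f"plot_{aid}"] = p
    except Exception:
        for p in artifacts.values():
            p.unlink(missing_ok=True)
        raise
    logger.info("wrote %s", artifacts["conc"])
    return quant, artifacts


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def plot_scatter(
    events: pd.DataFrame,
    x: str,
    y: str,
    color_by: str | None = None,
    hexbin: bool = False,
    bins: int = 75,
    path: str | Path = "scatter.png",
) -> Path:
    """Monochrome or hexbin-density scatter plot of two channels.

    The hexbin variant colors by per-bin event count, which keeps
    high-density regions visible where a monochrome point cloud
    saturates.
    """
    for col in (x, y):
        if col not in events.columns:
            raise DataError(
                f"channel {col!r} not present; available: {list(events.columns)}"
            )
    fig, ax = plt.subplots(figsize=(5, 4))
    if events.empty:
        import warnings

        warnings.warn("plotting an empty event table", stacklevel=2)
    elif hexbin:
        hb = ax.hexbin(events[x], events[y], gridsize=bins, cmap="jet", mincnt=1)
        fig.colorbar(hb, ax=ax, label="events")
    elif color_by is not None and color_by in events.columns:
        for val, grp in events.groupby(color_by, sort=True, dropna=False):
            label = "NA" if pd.isna(val) else str(val)
            ax.scatter(grp[x], grp[y], s=2, label=label)
        ax.legend(markerscale=4, fontsize=8)
    else:
        ax.scatter(events[x], events[y], s=2, color="black")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_standard_curve(
    standards: pd.DataFrame,
    curve: StandardCurve,
    estimates: pd.DataFrame | None = None,
    path: str | Path = "std_curve.png",
    title: str | None = None,
) -> Path:
    """Log-log standard-curve plot: points, fitted line, delta-method
    confidence band, and optional overlay of experimental estimates."""
    if not curve.converged:
        raise FitError("cannot plot an unconverged standard curve")
    std = standards[standards["concentration"] > 0]
    x = np.log10(std["concentration"].to_numpy(dtype=float))
    y = std["log10_mfi"].to_numpy(dtype=float)
    grid = np.linspace(x.min() - 0.3, x.max() + 0.3, 200)
    fit = logistic5(grid, curve)

    band = None
    if curve.covariance is not None and np.all(np.isfinite(curve.covariance)):
        theta = curve.theta
        grad = np.empty((len(theta), len(grid)))
        for i in range(len(theta)):
            h = 1e-6 * max(1.0, abs(theta[i]))
            up, dn = theta.copy(), theta.copy()
            up[i] += h
            dn[i] -= h
            names = curve.param_names
            kw_up = dict(zip(names, up))
            kw_dn = dict(zip(names, dn))
            kw_up.setdefault("f", curve.f)
            kw_dn.setdefault("f", curve.f)
            cu = StandardCurve(**{**kw_up, "model": curve.model})
            cd = StandardCurve(**{**kw_dn, "model": curve.model})
            grad[i] = (logistic5(grid, cu) - logistic5(grid, cd)) / (2 * h)
        var = np.einsum("in,ij,jn->n", grad, curve.covariance, grad)
        band = 1.96 * np.sqrt(np.maximum(var, 0.0))

    fig, ax = plt.subplots(figsize=(5, 4))
    if band is not None:
        ax.fill_between(grid, fit - band, fit + band, color="0.8", label="95% CI")
    ax.plot(grid, fit, color="black", label="fit")
    ax.scatter(x, y, color="tab:blue", zorder=3, label="standards")
    if estimates is not None and not estimates.empty:
        est = estimates[np.isfinite(estimates["calc_conc"])]
        ax.scatter(
            np.log10(est["calc_conc"]),
            est["log10_mfi"],
            color="tab:red",
            marker="x",
            zorder=4,
            label="samples",
        )
    ax.set_xlabel("log10 concentration")
    ax.set_ylabel("log10 MFI")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
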