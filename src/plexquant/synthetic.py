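"""Seeded synthetic bead-assay experiments with ground truth.

Emulates a LEGENDplex-style experiment acquired on a digital cytometer:
two bead groups as well-separated bivariate-Gaussian scatter (FSC/SSC)
populations, analyte sub-populations as narrow Gaussians along the
discrimination (APC, ``FL6-H``) channel, and a reporter (PE, ``FL2-H``)
channel whose log10 arcsinh-intensity follows a known 5PL curve of the
log10 analyte concentration plus lognormal noise. Samples comprise an
eight-level standard dilution series (C7 high ... C1 low, C0 blank) and
one experimental sample, each in duplicate -- 18 event files in total.

Raw channel values are written on the detector scale (``sinh`` of the
transformed value for fluorescence channels), so the generated files
are read back through exactly the same ingestion path as real data. A
small fraction of events is saturated at the scatter detector limit to
exercise boundary-event removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .fcs_io import write_fcs_file
from .panel import PanelInfo, load_panel
from .quantify import StandardCurve, calc_std_conc, logistic5

CHANNELS = ("FSC-A", "SSC-A", "FL6-H", "FL2-H")

#: detector ranges ($PnR) used when writing synthetic FCS files
DETECTOR_RANGES = {
    "FSC-A": 2**20,
    "SSC-A": 2**20,
    "FL6-H": 2**28,
    "FL2-H": 2**28,
}


@dataclass
class SyntheticTruth:
    """Complete generating configuration plus ground truth."""

    panel: PanelInfo
    #: per-analyte true 5PL curve (log10 conc -> log10 arcsinh-PE)
    curves: dict[str, StandardCurve]
    #: per-analyte true concentration of the experimental sample (pg/ml)
    experimental_conc: dict[str, float]
    #: bead-group scatter geometry: group -> (mean(2,), sd(2,))
    scatter_mean: dict[str, np.ndarray]
    scatter_sd: dict[str, np.ndarray]
    #: analyte -> (APC mean, APC sd) on the arcsinh scale
    apc_mean: dict[str, float]
    apc_sd: dict[str, float]
    noise_sd: float = 0.02       # per (sample, analyte) shift on log10 MFI
    event_sd: float = 0.05       # per-event spread on log10 reporter
    n_events: int = 2000         # events per sample
    boundary_rate: float = 0.005  # fraction saturated at the FSC limit
    n_standards: int = 8         # C0 (blank) .. C7
    n_replicates: int = 2
    prefix: str = "K1"
    seed: int = 0

    def __post_init__(self):
        for gid in self.panel.group_ids:
            means = [self.apc_mean[a] for a in self.panel.analytes_in(gid)]
            if not all(m2 > m1 for m1, m2 in zip(means, means[1:])):
                raise DataError(
                    f"APC means must be strictly increasing within group {gid!r} "
                    "(the lowest analyte ID must have the lowest intensity)"
                )
        if any(sd <= 0 for sd in self.apc_sd.values()):
            raise DataError("APC sds must be positive")
        if self.noise_sd < 0 or self.event_sd < 0:
            raise DataError("noise sds must be non-negative")


def default_truth(
    seed: int = 0,
    n_events: int = 2000,
    noise_sd: float = 0.02,
    hard: bool = False,
    panel: PanelInfo | None = None,
    boundary_rate: float = 0.005,
) -> SyntheticTruth:
    """Default 13-plex configuration.

    Scatter group means sit >= 8 sd apart (the clean case); ``hard``
    widens the scatter spread to a 3 sd separation to exercise
    clustering robustness. Per-analyte curve parameters and the true
    experimental concentrations are drawn once from the given seed.
    """
    if panel is None:
        panel = load_panel("Growth Factor")
    rng = np.random.default_rng(seed)

    curves: dict[str, StandardCurve] = {}
    experimental: dict[str, float] = {}
    apc_mean: dict[str, float] = {}
    apc_sd: dict[str, float] = {}
    apc_levels = {
        gid: 6.5 + 0.8 * np.arange(len(panel.analytes_in(gid)))
        for gid in panel.group_ids
    }
    for gid in panel.group_ids:
        for j, aid in enumerate(panel.analytes_in(gid)):
            e = rng.uniform(2.7, 3.0)
            curves[aid] = StandardCurve(
                b=rng.uniform(-3.6, -3.0),
                c=rng.uniform(0.30, 0.40),
                d=rng.uniform(1.10, 1.18),
                e=e,
                f=rng.uniform(0.8, 1.3),
                model="5PL",
            )
            # experimental concentration in the steep part of the curve
            experimental[aid] = float(10 ** rng.uniform(e - 0.45, e + 0.45))
            apc_mean[aid] = float(apc_levels[gid][j])
            apc_sd[aid] = 0.08

    scatter_sd_scale = 8.0 / 3.0 if hard else 1.0
    scatter_mean = {
        "A": np.array([4.2e5, 5.0e5]),
        "B": np.array([5.0e5, 7.5e5]),
    }
    scatter_sd = {
        "A": np.array([1.0e4, 2.0e4]) * scatter_sd_scale,
        "B": np.array([1.0e4, 2.0e4]) * scatter_sd_scale,
    }
    # map panel group ids onto the two scatter slots in panel order
    gids = panel.group_ids
    if len(gids) != 2:
        raise DataError("default geometry expects a two-group panel")
    return SyntheticTruth(
        panel=panel,
        curves=curves,
        experimental_conc=experimental,
        scatter_mean={gids[0]: scatter_mean["A"], gids[1]: scatter_mean["B"]},
        scatter_sd={gids[0]: scatter_sd["A"], gids[1]: scatter_sd["B"]},
        apc_mean=apc_mean,
        apc_sd=apc_sd,
        noise_sd=noise_sd,
        n_events=n_events,
        boundary_rate=boundary_rate,
        seed=seed,
    )


def sample_plan(truth: SyntheticTruth) -> list[tuple[str, str, int]]:
    """(sample name, role, sample number) for every generated file, in
    the C7..C0 then S1.. naming convention with replicate suffixes."""
    plan = []
    for num in range(truth.n_standards - 1, -1, -1):
        for rep in range(1, truth.n_replicates + 1):
            plan.append((f"{truth.prefix}-C{num}-{rep}", "standard", num))
    for rep in range(1, truth.n_replicates + 1):
        plan.append((f"{truth.prefix}-S1-{rep}", "experimental", 1))
    return plan


def true_standard_concentrations(truth: SyntheticTruth) -> pd.DataFrame:
    """Long table of the true concentration per (standard number, analyte)."""
    numbers = list(range(truth.n_standards - 1, -1, -1))
    rows = []
    for aid in truth.panel.analyte_ids:
        c0 = truth.panel.entry(aid).start_concentration
        conc = calc_std_conc(numbers, c0, truth.panel.std_dilution)
        for num, cc in zip(numbers, conc):
            rows.append({"sample_number": num, "analyte_id": aid, "concentration": cc})
    return pd.DataFrame(rows)


def _one_sample(
    truth: SyntheticTruth, rng: np.random.Generator, conc: dict[str, float]
) -> pd.DataFrame:
    panel = truth.panel
    weights = np.array(
        [len(panel.analytes_in(g)) for g in panel.group_ids], dtype=float
    )
    group_counts = rng.multinomial(truth.n_events, weights / weights.sum())
    frames = []
    for gid, n_g in zip(panel.group_ids, group_counts):
        aids = list(panel.analytes_in(gid))
        counts = rng.multinomial(n_g, np.full(len(aids), 1.0 / len(aids)))
        for aid, m in zip(aids, counts):
            if m == 0:
                continue
            fsc = rng.normal(truth.scatter_mean[gid][0], truth.scatter_sd[gid][0], m)
            ssc = rng.normal(truth.scatter_mean[gid][1], truth.scatter_sd[gid][1], m)
            apc_t = rng.normal(truth.apc_mean[aid], truth.apc_sd[aid], m)
            x = np.log10(conc[aid]) if conc[aid] > 0 else -np.inf
            level = float(logistic5(x, truth.curves[aid]))
            shift = rng.normal(0.0, truth.noise_sd)
            y = level + shift + rng.normal(0.0, truth.event_sd, m)
            pe_t = 10.0**y
            frames.append(
                pd.DataFrame(
                    {
                        "FSC-A": fsc,
                        "SSC-A": ssc,
                        "FL6-H": np.sinh(apc_t),
                        "FL2-H": np.sinh(pe_t),
                        "true_bead_group": gid,
                        "true_analyte_id": aid,
                    }
                )
            )
    events = pd.concat(frames, ignore_index=True)
    events = events.iloc[rng.permutation(len(events))].reset_index(drop=True)
    if truth.boundary_rate > 0:
        n_sat = int(round(truth.boundary_rate * len(events)))
        if n_sat:
            idx = rng.choice(len(events), size=n_sat, replace=False)
            events.loc[events.index[idx], "FSC-A"] = DETECTOR_RANGES["FSC-A"]
    return events


def generate_experiment(
    truth: SyntheticTruth, out_dir: str | Path | None = None
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Generate all samples of the experiment.

    Returns ``{sample name: raw event table}`` (channels on the detector
    scale plus ``true_bead_group`` / ``true_analyte_id`` columns) and
    the truth. When ``out_dir`` is given, each sample is additionally
    written as ``<name>.fcs`` alongside ``truth_concentrations.csv`` and
    ``truth_curves.csv``.
    """
    rng = np.random.default_rng(truth.seed)
    std_conc = {
        aid: dict(
            zip(
                range(truth.n_standards - 1, -1, -1),
                calc_std_conc(
                    list(range(truth.n_standards - 1, -1, -1)),
                    truth.panel.entry(aid).start_concentration,
                    truth.panel.std_dilution,
                ),
            )
        )
        for aid in truth.panel.analyte_ids
    }
    samples: dict[str, pd.DataFrame] = {}
    for name, role, number in sample_plan(truth):
        if role == "standard":
            conc = {aid: std_conc[aid][number] for aid in truth.panel.analyte_ids}
        else:
            conc = dict(truth.experimental_conc)
        samples[name] = _one_sample(truth, rng, conc)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, events in samples.items():
            write_fcs(events, out_dir / f"{name}.fcs")
        pd.DataFrame(
            [
                {"sample": "S1", "analyte_id": aid, "concentration": cc}
                for aid, cc in truth.experimental_conc.items()
            ]
        ).to_csv(out_dir / "truth_concentrations.csv", index=False)
        pd.DataFrame(
            [
                {"analyte_id": aid, **{p: getattr(cv, p) for p in ("b", "c", "d", "e", "f")}}
                for aid, cv in truth.curves.items()
            ]
        ).to_csv(out_dir / "truth_curves.csv", index=False)
        with open(out_dir / "truth_config.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "panel_name": truth.panel.panel_name,
                    "seed": truth.seed,
                    "n_events": truth.n_events,
                    "noise_sd": truth.noise_sd,
                    "event_sd": truth.event_sd,
                    "boundary_rate": truth.boundary_rate,
                },
                fh,
            )
    return samples, truth


def write_fcs(events: pd.DataFrame, path: str | Path) -> Path:
    """Write an event table as a minimal FCS 3.1 file.

    Only the instrument channels are written; annotation columns
    (``sample_id``, truth labels, assigned IDs) are dropped.
    """
    chans = [c for c in events.columns if c in CHANNELS] or [
        c
        for c in events.columns
        if c not in ("sample_id", "true_bead_group", "true_analyte_id",
                     "bead_group", "analyte_id")
    ]
    ranges = {c: DETECTOR_RANGES.get(c, 2**20) for c in chans}
    return write_fcs_file(path, events[chans], ranges=ranges)
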