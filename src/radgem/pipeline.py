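"""End-to-end orchestration: simulate or load, analyse, report.

A run is driven by a :class:`RunConfig` (usually loaded from YAML, or from
a shipped preset). It produces tidy CSVs for every analysis stage, an
optional set of plots, a human-readable ``summary.md`` and a
machine-readable ``manifest.json`` carrying the package version, a hash of
the canonical configuration and per-file content hashes — identical
config + seed gives identical manifest hashes.

All randomness flows from the single run seed through named substreams,
one per module, so adding one stage never perturbs another.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources as _resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dosimetry import (
    DoseParameters,
    TimeActivitySeries,
    absorbed_dose_from_series,
)
from .groupstats import FAMILY_ALL_DAYS, FAMILY_PER_DAY, per_day_comparisons
from .growth import (
    Cohort,
    animal_table,
    cohort_to_frame,
    group_table,
    read_measurements_csv,
)
from .histology import analyse_section_pair, results_table
from .interaction import evaluate_interaction
from .survival import curve_table, detect_progression, km_estimator, median_ttp, records_table
from .synthetic import (
    ArmConfig,
    GrowthModelConfig,
    SectionLayoutConfig,
    render_section_pair,
    simulate_growth_cohort,
    simulate_time_activity,
)

logger = logging.getLogger(__name__)

PRESETS = ("study-like", "null", "strong-synergy")


def substream_seed(seed: int, name: str) -> int:
    """Stable named child seed (< 2**31) derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int
    control_arm: str
    growth: Optional[GrowthModelConfig] = None
    measurements_csv: Optional[str] = None
    combinations: dict = field(default_factory=dict)  # combo -> [rad, gem]
    interaction_tolerance: float = 0.05
    equal_var: bool = True
    family: str = FAMILY_PER_DAY
    alpha: float = 0.05
    dosimetry: Optional[dict] = None
    histology: Optional[dict] = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.growth is None) == (self.measurements_csv is None):
            raise ValueError("exactly one of growth / measurements_csv required")
        if self.family not in (FAMILY_PER_DAY, FAMILY_ALL_DAYS):
            raise ValueError(f"unknown correction family {self.family!r}")
        if self.growth is not None:
            arm_names = {a.name for a in self.growth.arms}
            if self.control_arm not in arm_names:
                raise ValueError(f"control arm {self.control_arm!r} not configured")
            for combo, pair in self.combinations.items():
                if combo not in arm_names:
                    raise ValueError(f"combination arm {combo!r} not configured")
                if len(pair) != 2 or any(p not in arm_names for p in pair):
                    raise ValueError(
                        f"combination {combo!r} must reference exactly two "
                        f"configured monotherapy arms, got {pair}"
                    )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.growth is not None:
            d["growth"] = asdict(self.growth)
            d["growth"]["arms"] = [asdict(a) for a in self.growth.arms]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        g = d.get("growth")
        if g is not None:
            g = dict(g)
            g["arms"] = tuple(ArmConfig(**a) for a in g["arms"])
            for key in ("gem_window", "schedule"):
                if key in g:
                    g[key] = tuple(g[key])
            d["growth"] = GrowthModelConfig(**g)
        combos = d.get("combinations") or {}
        d["combinations"] = {k: list(v) for k, v in combos.items()}
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the canonical configuration, excluding the run seed."""
        d = _plain(self.to_dict())
        d.pop("seed", None)
        canonical = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _plain(obj):
    """Recursively coerce numpy scalars/tuples for canonical YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_preset(name: str, seed: int) -> RunConfig:
    """Load a shipped preset ('study-like', 'null', 'strong-synergy')."""
    fname = name.replace("-", "_") + ".yaml"
    ref = _resources.files("radgem").joinpath("presets", fname)
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ValueError(f"unknown preset {name!r} (have {PRESETS})") from None
    d = yaml.safe_load(text)
    d["seed"] = seed
    return RunConfig.from_dict(d)


def load_config(path, seed: Optional[int] = None) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if seed is not None:
        d["seed"] = seed
    return RunConfig.from_dict(d)


# ---------------------------------------------------------------------------
# the run itself
# ---------------------------------------------------------------------------

def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Writes per-animal, per-group, survival, interaction, statistics and
    (when configured) dosimetry / histology outputs plus summary.md and
    manifest.json into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: list[str] = [f"# radgem run summary\n", f"seed: {config.seed}\n"]

    # -- growth -------------------------------------------------------------
    if config.growth is not None:
        cohort = simulate_growth_cohort(
            config.growth, substream_seed(config.seed, "growth"),
            control_arm=config.control_arm,
        )
        _write_csv(cohort_to_frame(cohort), out / "measurements.csv")
    else:
        cohort = read_measurements_csv(config.measurements_csv, config.control_arm)
    per_animal = animal_table(cohort)
    per_group = group_table(cohort)
    _write_csv(per_animal, out / "per_animal.csv")
    _write_csv(per_group, out / "per_group.csv")
    summary.append("## Growth\n")
    last = per_group.sort_values("day").groupby("group").tail(1)
    for _, r in last.iterrows():
        summary.append(
            f"- {r['group']}: final mean RTV {r['mean_rtv']:.2f} "
            f"(day {r['day']:g}, n={int(r['n'])}, "
            f"ratio to control {r['ratio_to_control']:.2f})\n"
        )

    # -- survival -----------------------------------------------------------
    records = [detect_progression(s) for s in cohort.series]
    by_group: dict[str, list] = {}
    for s, rec in zip(cohort.series, records):
        by_group.setdefault(s.group, []).append(rec)
    _write_csv(records_table(records), out / "survival_records.csv")
    curve_frames, medians = [], {}
    for grp, recs in by_group.items():
        curve = km_estimator(recs)
        curve_frames.append(curve_table(curve, group=grp))
        medians[grp] = median_ttp(curve)
    _write_csv(pd.concat(curve_frames, ignore_index=True), out / "survival_curves.csv")
    summary.append("\n## Progression-free survival\n")
    for grp, med in medians.items():
        shown = f"{med:g} d" if med is not None else "not reached"
        summary.append(f"- {grp}: median TTP {shown}\n")

    # -- interaction --------------------------------------------------------
    interactions = {}
    for combo, (rad, gem) in config.combinations.items():
        tbl = evaluate_interaction(
            per_group, rad_arm=rad, gem_arm=gem, combo_arm=combo,
            control_arm=config.control_arm, tolerance=config.interaction_tolerance,
        )
        interactions[combo] = tbl
        safe = combo.replace(" ", "_").replace("+", "plus")
        _write_csv(tbl, out / f"interaction_{safe}.csv")
    if interactions:
        summary.append("\n## Bliss interaction\n")
        for combo, tbl in interactions.items():
            counts = tbl["classification"].value_counts().to_dict()
            summary.append(f"- {combo}: {counts}\n")

    # -- statistics ---------------------------------------------------------
    stats = per_day_comparisons(
        per_animal, equal_var=config.equal_var, family=config.family,
        alpha=config.alpha,
    )
    _write_csv(stats, out / "stats.csv")
    if not stats.empty:
        sig = stats[stats["significant"]]
        summary.append(
            f"\n## Statistics\n- {len(sig)} of {len(stats)} comparisons "
            f"significant at adjusted alpha = {config.alpha}\n"
        )

    # -- dosimetry ----------------------------------------------------------
    if config.dosimetry:
        dcfg = config.dosimetry
        params = DoseParameters(
            energy_per_decay_kev=dcfg.get("energy_per_decay_kev", 147.9),
            absorbed_fraction=dcfg.get("absorbed_fraction", 1.0),
        )
        if "simulate" in dcfg:
            s = dcfg["simulate"]
            series = simulate_time_activity(
                c0=s["c0"], lambda_eff=s["lambda_per_h"],
                times_h=s["times_h"], noise_cv=s.get("noise_cv", 0.0),
                seed=substream_seed(config.seed, "dosimetry"),
            )
        else:
            df = pd.read_csv(dcfg["csv"])
            series = TimeActivitySeries(
                times_h=df["time_h"].to_numpy(),
                concentrations=df["concentration"].to_numpy(),
                unit=df["unit"].iloc[0],
                injected_mbq=dcfg.get("injected_mbq"),
            )
        result = absorbed_dose_from_series(series, params,
                                           method=dcfg.get("method", "loglinear"))
        (out / "dosimetry.json").write_text(
            json.dumps(_plain(asdict(result)), indent=2) + "\n"
        )
        summary.append(
            f"\n## Dosimetry\n- C0 = {result.c0:.4g} MBq/g, effective half-life "
            f"{result.half_life_h:.3g} h, A-tilde {result.a_tilde_mbq_h_per_g:.4g} "
            f"MBq*h/g, mean absorbed dose {result.dose_gy:.3g} Gy\n"
        )

    # -- histology ----------------------------------------------------------
    if config.histology:
        hrows = []
        size = tuple(config.histology.get("size", (256, 256)))
        for i, pair_cfg in enumerate(config.histology.get("pairs", [])):
            layout = SectionLayoutConfig(
                seed=substream_seed(config.seed, f"histology-{i}"),
                size=size,
                necrotic_fraction=pair_cfg.get("necrotic_fraction", 0.2),
                ki67_positive_fraction=pair_cfg.get("ki67_positive_fraction", 0.64),
                mt_collagen_fraction=pair_cfg.get("mt_collagen_fraction", 0.03),
            )
            mt, ki, pts, _truth = render_section_pair(layout)
            quant, rms = analyse_section_pair(mt, ki, pts)
            hrows.append(
                {
                    "section_id": f"pair-{i + 1:02d}",
                    "group": pair_cfg.get("group", ""),
                    "ki67_percent_viable": quant.ki67_percent_viable,
                    "mt_percent_whole": quant.mt_percent_whole,
                    "viable_area_mm2": quant.viable_area_mm2,
                    "tumour_area_mm2": quant.tumour_area_mm2,
                    "registration_rms_px": rms,
                }
            )
        if hrows:
            _write_csv(results_table(hrows), out / "histology.csv")
            summary.append("\n## Histology\n")
            for r in hrows:
                summary.append(
                    f"- {r['section_id']} ({r['group']}): Ki67 in viable "
                    f"{r['ki67_percent_viable']:.1f}%, MT whole-tumour "
                    f"{r['mt_percent_whole']:.1f}%\n"
                )

    # -- plots --------------------------------------------------------------
    if config.make_plots:
        _make_plots(per_group, by_group, out)

    (out / "summary.md").write_text("".join(summary))

    manifest = {
        "package": "radgem",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "outputs": {
            p.name: _sha256_file(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _make_plots(per_group: pd.DataFrame, survival_by_group: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(14, 4))
    for grp, sub in per_group.groupby("group"):
        sub = sub.sort_values("day")
        axes[0].errorbar(sub["day"], sub["mean_rtv"], yerr=sub["sem_rtv"],
                         marker="o", ms=3, capsize=2, label=grp)
        axes[1].plot(sub["day"], sub["ratio_to_control"], marker="o", ms=3,
                     label=grp)
        curve = km_estimator(survival_by_group[grp])
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        axes[2].step(t, 100 * s, where="post", label=grp)
    axes[0].set(xlabel="day", ylabel="mean RTV")
    axes[1].set(xlabel="day", ylabel="RTV / RTV$_{control}$")
    axes[2].set(xlabel="day", ylabel="% without progression", ylim=(0, 105))
    for ax in axes:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "growth_survival.png", dpi=120)
    plt.close(fig)
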