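"""End-to-end orchestration: simulate -> NCC / constriction / hydration ->
state-space comparison -> group tests -> plots, with a reproducibility
manifest.

Every stage writes plain-text outputs (CSV/JSON) plus figure files; any
stage failure aborts with a stage-tagged error while retaining partial
outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from vacmorph import constriction as vc
from vacmorph import hydration as vh
from vacmorph import morphodynamics as vm
from vacmorph import ssm as vs
from vacmorph import synthetic as vg

__all__ = ["RunConfig", "run_pipeline", "compare_groups", "significance_stars"]

log = logging.getLogger("vacmorph")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run on synthetic scenarios."""

    scenarios: list[str]
    control: str
    out_dir: str
    seed: int = 0
    n_cells: int = 5
    n_pollen: int = 8
    percentile: float = 97.0
    per_sequence_normalization: bool = False
    detector: vc.DetectorParams = field(default_factory=vc.DetectorParams)
    ssm_chains: int = 4
    ssm_warmup: int = 500
    ssm_draws: int = 500
    run_ssm: bool = True
    make_plots: bool = True
    pollen_noise_sd: float = 0.4
    frame_count: int | None = None  # override preset movie length (testing/speed)

    def validate(self) -> None:
        if len(self.scenarios) < 1:
            raise ValueError("at least one scenario is required")
        if self.control not in self.scenarios:
            raise ValueError(
                f"control condition {self.control!r} is not among the scenarios"
            )
        if len(set(self.scenarios)) != len(self.scenarios):
            raise ValueError("duplicate scenario names")
        if self.n_cells < 1 or self.n_pollen < 1:
            raise ValueError("n_cells and n_pollen must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        det = raw.pop("detector", None)
        cfg = cls(**raw)
        if det:
            cfg.detector = vc.DetectorParams(**det)
        return cfg


def significance_stars(p: float) -> str:
    """Figure-legend style significance marks (** p<0.01, *** p<0.001)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return "N.S."


def compare_groups(
    values_by_group: dict[str, np.ndarray],
    method: str = "dunnett",
    control: str | None = None,
) -> pd.DataFrame:
    """Two-sided multiple-comparison table (statistic, p, stars).

    ``dunnett`` compares every group against the named control; ``tukey``
    performs all pairwise comparisons; ``welch`` performs pairwise t tests
    without assuming equal variances.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    rows = []
    if method == "dunnett":
        if control is None or control not in groups:
            raise ValueError("dunnett requires a control group label")
        others = [k for k in groups if k != control]
        res = stats.dunnett(*[groups[k] for k in others], control=groups[control])
        for name, stat, p in zip(others, np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)):
            rows.append((f"{name} vs {control}", float(stat), float(p)))
    elif method == "tukey":
        names = list(groups)
        res = stats.tukey_hsd(*[groups[k] for k in names])
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    (
                        f"{names[i]} vs {names[j]}",
                        float(res.statistic[i, j]),
                        float(res.pvalue[i, j]),
                    )
                )
    elif method == "welch":
        names = list(groups)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = stats.ttest_ind(groups[names[i]], groups[names[j]], equal_var=False)
                rows.append((f"{names[i]} vs {names[j]}", float(r.statistic), float(r.pvalue)))
    else:
        raise ValueError(f"unknown method {method!r}")
    df = pd.DataFrame(rows, columns=["comparison", "statistic", "p"])
    df["significance"] = df["p"].map(significance_stars)
    return df


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # re-tag for traceability
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


@_stage("simulate+ncc+constrict")
def _movies_stage(config: RunConfig, out: Path, child_seeds):
    series: list[vm.NCCSeries] = []
    counts: dict[str, list[int]] = {}
    truth_counts: dict[str, list[int]] = {}
    geometry = vg.CellGeometry()
    mask = geometry.cell_mask()
    movie_dir = out / "movies"
    movie_dir.mkdir(exist_ok=True)
    for s_i, name in enumerate(config.scenarios):
        counts[name] = []
        truth_counts[name] = []
        for c_i in range(config.n_cells):
            seed = int(child_seeds[s_i * config.n_cells + c_i])
            scenario = vg.scenario_presets(name, seed=seed)
            if config.frame_count is not None:
                scenario = scenario.replace(frame_count=config.frame_count)
            stack, truth = vg.simulate_vacuole_sequence(scenario, geometry)
            vg.write_tiff(stack, movie_dir / f"{name}_cell{c_i}.tif")
            pre = vm.preprocess_stack(
                stack,
                percentile=config.percentile,
                per_sequence=config.per_sequence_normalization,
            )
            series.append(
                vm.ncc_series(pre, cell_id=f"{name}_cell{c_i}", condition=name)
            )
            det = vc.detect_constrictions(
                pre, mask, config.detector, cell_id=f"{name}_cell{c_i}", condition=name
            )
            counts[name].append(det.count)
            truth_counts[name].append(truth.count("constriction", window_s=600.0))
    vm.series_to_csv(series, out / "ncc_series.csv")
    rows = [
        {"condition": cond, "cell": i, "count": c, "truth_count": truth_counts[cond][i]}
        for cond, cs in counts.items()
        for i, c in enumerate(cs)
    ]
    pd.DataFrame(rows).to_csv(out / "constriction_counts.csv", index=False)
    vc.compare_counts(counts).to_csv(out / "constriction_summary.csv", index=False)
    return series, counts


@_stage("count-tests")
def _count_tests_stage(config: RunConfig, out: Path, counts):
    if len(counts) < 2:
        return None
    method = "dunnett" if len(counts) > 2 else "welch"
    table = compare_groups(counts, method=method, control=config.control)
    table.to_csv(out / "constriction_tests.csv", index=False)
    return table


@_stage("hydration")
def _hydration_stage(config: RunConfig, out: Path, child_seeds):
    tracks: list[vh.PollenTrack] = []
    for s_i, name in enumerate(config.scenarios):
        kw = vg.hydration_preset(name)
        for p_i in range(config.n_pollen):
            seed = int(child_seeds[s_i * config.n_pollen + p_i])
            tracks.append(
                vg.simulate_pollen_assay(
                    noise_sd=config.pollen_noise_sd,
                    seed=seed,
                    pollen_id=f"{name}_pollen{p_i}",
                    condition=name,
                    **kw,
                )
            )
    vh.tracks_to_csv(tracks, out / "pollen_widths.csv")
    results = [vh.hydration_timecourse(t) for t in tracks]
    rates = pd.concat([r.to_frame() for r in results], ignore_index=True)
    rates.to_csv(out / "hydration_rates.csv", index=False)
    return rates


@_stage("ssm")
def _ssm_stage(config: RunConfig, out: Path, series):
    summaries = {}
    for name in config.scenarios:
        if name == config.control:
            continue
        data = vs.SSMData.from_series(series, config.control, name)
        settings = vs.SamplerSettings(
            chains=config.ssm_chains,
            warmup=config.ssm_warmup,
            draws=config.ssm_draws,
            seed=config.seed,
        )
        post = vs.sample_posterior(data, settings)
        summary = vs.summarize(post)
        tag = f"{config.control}_vs_{name}"
        summary.to_csv(out / f"ssm_summary_{tag}.csv", index=False)
        post.draws_table().to_csv(out / f"ssm_draws_{tag}.csv", index=False)
        summaries[name] = summary
    return summaries


@_stage("plots")
def _plots_stage(config: RunConfig, out: Path, series, counts, summaries):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)

    # NCC points + posterior mean band per comparison
    for name, summary in (summaries or {}).items():
        fig, ax = plt.subplots(figsize=(6, 4))
        for s in series:
            if s.condition in (config.control, name):
                color = "C0" if s.condition == config.control else "C1"
                ax.plot(s.times_s, s.values, ".", color=color, alpha=0.4, ms=3)
        t = summary["time_s"]
        ax.plot(t, summary["mu_med"], "C0", label=config.control)
        ax.fill_between(t, summary["mu_lo"], summary["mu_hi"], color="C0", alpha=0.3)
        exp_med = summary["mu_med"] + summary["delta_med"]
        ax.plot(t, exp_med, "C1", label=name)
        ax.set(xlabel="time (s)", ylabel="NCC", ylim=(0, 1.05))
        ax.legend()
        fig.savefig(fig_dir / f"ncc_band_{config.control}_vs_{name}.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(6, 3))
        ax.axhline(0.0, color="k", lw=0.8)
        ax.plot(t, summary["delta_med"], "C3")
        ax.fill_between(t, summary["delta_lo"], summary["delta_hi"], color="C3", alpha=0.3)
        ax.set(xlabel="time (s)", ylabel=f"difference vs {config.control}")
        fig.savefig(fig_dir / f"ncc_difference_{config.control}_vs_{name}.png", dpi=120)
        plt.close(fig)

    # constriction count bar plot, mean +/- SEM
    summary = vc.compare_counts(counts)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(summary["condition"], summary["mean"], yerr=summary["sem"], capsize=4)
    ax.set_ylabel("constrictions / 10 min")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(fig_dir / "constriction_counts.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return a manifest of the produced outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(config.seed)
    movie_seeds = root.spawn(1)[0].generate_state(
        len(config.scenarios) * config.n_cells
    )
    pollen_seeds = root.spawn(2)[1].generate_state(
        len(config.scenarios) * config.n_pollen
    )

    series, counts = _movies_stage(config, out, movie_seeds)
    _count_tests_stage(config, out, counts)
    _hydration_stage(config, out, pollen_seeds)
    summaries = _ssm_stage(config, out, series) if config.run_ssm else {}
    if config.make_plots:
        _plots_stage(config, out, series, counts, summaries)

    from vacmorph import __version__

    cfg_dict = asdict(config)
    cfg_dict["detector"] = asdict(config.detector)
    manifest = {
        "vacmorph_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": cfg_dict,
        "outputs": sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
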