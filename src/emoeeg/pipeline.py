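"""End-to-end orchestration: simulate → preprocess → features → stats → classify.

A single :class:`RunConfig` drives every stage; given a seed the whole run
is deterministic, and each stage can be re-run from the on-disk
intermediates of the previous one (long-format CSVs plus a JSON manifest
recording the configuration hash and package versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import (SET_IDS, TASKS, SldaParams, experiment_table,
                       run_feature_set_experiment)
from .features import assemble_feature_set, composite_frontal, hit_rate, power_feature
from .layout import FRONTAL_PAIRS, MIDLINE_SITES
from .signal import BandPowerTable, process_cohort
from .stats import (RegressionModel, StatResult, bh_fdr, chi_square_gof,
                    paired_t, stepwise_regression, partial_correlation,
                    within_interaction_multivariate,
                    within_interaction_univariate)
from .synth import CONDITIONS, SAM_DIMENSIONS, SynthConfig, generate_subject

log = logging.getLogger("emoeeg")

POSITIVE_PAIR = ("amusement", "tenderness")
NEGATIVE_PAIR = ("anger", "fear")


@dataclass(frozen=True)
class RunConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    filter_band: tuple[float, float] = (1.0, 35.0)
    epoch_len_s: float = 2.0
    overlap_frac: float = 0.5
    amp_threshold_uv: float = 100.0
    apply_filter: bool = True
    feature_sets: tuple[str, ...] = SET_IDS
    tasks: tuple[str, ...] = tuple(TASKS)
    feature_value: str = "normalized"
    svm_c: float = 1.0
    slda_l1: float = 0.01
    slda_l2: float = 0.01
    top_k: int | None = None
    p_enter: float = 0.05
    p_remove: float = 0.10

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, synth=replace(self.synth, seed=seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        synth = d["synth"]
        synth["effect_multipliers"] = {
            "|".join(k): v for k, v in self.synth.effect_multipliers.items()}
        synth["layout"] = {
            "names": list(self.synth.layout.names),
            "scalp": sorted(self.synth.layout.scalp),
            "midline": sorted(self.synth.layout.midline),
            "pairs": [list(p) for p in self.synth.layout.pairs],
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        synth_d = dict(d.pop("synth", {}))
        if "effect_multipliers" in synth_d:
            synth_d["effect_multipliers"] = {
                tuple(k.split("|")): v
                for k, v in synth_d["effect_multipliers"].items()}
        if "bands" in synth_d:
            synth_d["bands"] = {k: tuple(v) for k, v in synth_d["bands"].items()}
        synth_d.pop("layout", None)      # custom layouts are API-only
        for key in ("conditions",):
            if key in synth_d:
                synth_d[key] = tuple(synth_d[key])
        known = {f for f in SynthConfig.__dataclass_fields__}
        synth = SynthConfig(**{k: v for k, v in synth_d.items() if k in known})
        for key in ("filter_band", "feature_sets", "tasks"):
            if key in d:
                d[key] = tuple(d[key])
        known_run = {f for f in cls.__dataclass_fields__} - {"synth"}
        return cls(synth=synth, **{k: v for k, v in d.items() if k in known_run})

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    """Read a YAML run configuration; defaults when path is None."""
    if path is None:
        cfg = RunConfig()
    else:
        import yaml
        cfg = RunConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})
    if seed is not None:
        cfg = cfg.with_seed(seed)
    return cfg


def simulate_powers(config: RunConfig) -> tuple[BandPowerTable, pd.DataFrame]:
    """Generate the cohort and reduce it to band powers subject by subject.

    Streaming keeps only one subject's raw signals in memory at a time;
    the full default cohort would otherwise occupy gigabytes.
    """
    seqs = np.random.SeedSequence(config.synth.seed).spawn(config.synth.n_subjects)
    tables, rating_rows = [], []
    for i, seq in enumerate(seqs):
        recordings, rows = generate_subject(config.synth, i, seq)
        tables.append(process_cohort(
            recordings, bands=config.synth.bands, filter_band=config.filter_band,
            epoch_len_s=config.epoch_len_s, overlap_frac=config.overlap_frac,
            amp_threshold_uv=config.amp_threshold_uv,
            apply_filter=config.apply_filter))
        rating_rows.extend(rows)
    powers = BandPowerTable(
        data=pd.concat([t.data for t in tables], ignore_index=True),
        baseline=pd.concat([t.baseline for t in tables], ignore_index=True),
        n_norm=tables[0].n_norm)
    return powers, pd.DataFrame(rating_rows)


def new19_candidates(powers: BandPowerTable, value: str = "normalized"
                     ) -> pd.DataFrame:
    """The 19 new features as a regression/correlation candidate matrix:
    theta+alpha at the two frontal asymmetries, theta+alpha+beta at the
    five midline sites."""
    return assemble_feature_set(powers, "new19", value).data


def _pair_cells(powers: BandPowerTable, pair: tuple[str, str],
                contrast: tuple[str, str], bands: Sequence[str],
                value: str) -> np.ndarray:
    """subjects × emotion × hemisphere (× band) cell array for one site pair."""
    left, right = pair
    per_band = []
    for band in bands:
        if pair == ("Fleft", "Fright"):
            comp = composite_frontal(powers, bands=(band,), value=value)
            l = comp[f"Fleft_{band}"]
            r = comp[f"Fright_{band}"]
        else:
            l = power_feature(powers, left, band, value)
            r = power_feature(powers, right, band, value)
        cells = np.stack([
            np.stack([l.xs(c, level="condition").to_numpy(),
                      r.xs(c, level="condition").to_numpy()], axis=1)
            for c in contrast], axis=1)          # n × 2(emotion) × 2(hemi)
        per_band.append(cells)
    out = np.stack(per_band, axis=3)             # n × 2 × 2 × n_bands
    return out


def run_stats_battery(powers: BandPowerTable, ratings: pd.DataFrame,
                      config: RunConfig | None = None
                      ) -> tuple[pd.DataFrame, dict[str, RegressionModel]]:
    """The full statistical report as one long table.

    Sections: film hit rates; rating similarity t tests and the valence
    frequency χ²; 2×2 emotion × hemisphere interaction contrasts
    (multivariate theta+alpha and univariate per band) at FP1/FP2, F3/F4
    and the composite frontal pair; midline paired t tests per band and
    site; partial correlations (liking/dominance vs the 19 new features,
    controlling arousal, valence and familiarity) with BH-FDR; and
    stepwise regressions of each film's target-emotion rating on the 19
    new features.
    """
    config = config or RunConfig()
    value = config.feature_value
    available = set(powers.data["condition"].unique()) & \
        set(ratings["condition"].unique())
    results: list[StatResult] = []

    def ratings_of(cond: str, col: str) -> pd.Series:
        return ratings[ratings["condition"] == cond].set_index("subject")[col]

    for film in CONDITIONS:
        if film in available:
            rate = hit_rate(ratings, film)
            results.append(StatResult(statistic=rate, df=(0,), p=np.nan,
                                      effect_size=np.nan, kind="hit_rate",
                                      label=f"hit_rate[{film}]"))

    contrasts = [(POSITIVE_PAIR, "pos"), (NEGATIVE_PAIR, "neg")]
    for (a, b), tag in contrasts:
        if not {a, b} <= available:
            log.warning("skipping %s/%s comparisons: condition missing", a, b)
            continue
        for dim in SAM_DIMENSIONS:
            x, y = ratings_of(a, dim).align(ratings_of(b, dim), join="inner")
            results.append(paired_t(x, y, label=f"rating_{dim}[{a}-{b}]"))

    if {"anger", "fear"} <= available:
        va = ratings_of("anger", "valence")
        vf = ratings_of("fear", "valence")
        va, vf = va.align(vf, join="inner")
        n = len(va)
        higher = int((vf >= va + 1).sum())
        results.append(chi_square_gof([higher, n - higher], [n / 2, n / 2],
                                      label="chi2_valence_frequency[anger/fear]"))

    pairs = list(FRONTAL_PAIRS) + [("Fleft", "Fright")]
    for (a, b), tag in contrasts:
        if not {a, b} <= available:
            continue
        for pair in pairs:
            site = "".join(pair)
            cells = _pair_cells(powers, pair, (a, b), ("theta", "alpha"), value)
            results.append(within_interaction_multivariate(
                cells, label=f"interaction_mv_theta_alpha[{site}][{a}-{b}]"))
            for k, band in enumerate(("theta", "alpha")):
                results.append(within_interaction_univariate(
                    cells[:, :, :, k],
                    label=f"interaction_{band}[{site}][{a}-{b}]"))

    for (a, b), tag in contrasts:
        if not {a, b} <= available:
            continue
        for band in ("theta", "alpha", "beta"):
            for site in MIDLINE_SITES:
                pa = power_feature(powers, site, band, value).xs(a, level="condition")
                pb = power_feature(powers, site, band, value).xs(b, level="condition")
                results.append(paired_t(pa, pb,
                                        label=f"midline_{band}[{site}][{a}-{b}]"))

    # Partial correlations within each emotion pair, BH-FDR per DV family.
    candidates = new19_candidates(powers, value)
    merged = candidates.join(
        ratings.set_index(["subject", "condition"]), how="inner")
    for (a, b), tag in contrasts:
        if not {a, b} <= available:
            continue
        sub = merged[merged.index.get_level_values("condition").isin((a, b))]
        Z = sub[["arousal", "valence", "familiarity"]].to_numpy()
        for dv in ("liking", "dominance"):
            family = [
                partial_correlation(sub[feat], sub[dv], Z,
                                    label=f"partial_r_{dv}[{feat}][{a}-{b}]")
                for feat in candidates.columns]
            adj = bh_fdr([r.p for r in family])
            for r, q in zip(family, adj):
                r.extra["p_fdr"] = float(q)
            results.extend(family)

    models: dict[str, RegressionModel] = {}
    for film in CONDITIONS:
        if film not in available:
            continue
        y = merged[f"des_{film}"]
        model = stepwise_regression(candidates.loc[y.index], y,
                                    p_enter=config.p_enter,
                                    p_remove=config.p_remove)
        models[film] = model
        results.append(StatResult(
            statistic=model.f_stat, df=(len(model.predictors),
                                        model.n - len(model.predictors) - 1),
            p=model.f_p, effect_size=model.adj_r2, kind="F",
            label=f"stepwise[{film}]: {'+'.join(model.predictors) or 'intercept'}"))

    report = pd.DataFrame([r.as_row() for r in results])
    return report, models


def run_classification(powers: BandPowerTable, config: RunConfig
                       ) -> dict[tuple[str, str], "ClassificationReport"]:
    """Feature-set × task LOSO experiment, skipping unsatisfiable tasks."""
    available = set(powers.data["condition"].unique())
    tasks = []
    for task in config.tasks:
        if set(TASKS[task]) <= available:
            tasks.append(task)
        else:
            log.warning("skipping task %s: conditions %s not all present",
                        task, TASKS[task])
    return run_feature_set_experiment(
        powers, set_ids=config.feature_sets, tasks=tuple(tasks),
        classifier_params={"C": config.svm_c, "kernel": "linear"},
        top_k=config.top_k,
        slda_params=SldaParams(l1=config.slda_l1, l2=config.slda_l2),
        value=config.feature_value)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("simulate+preprocess: %d subjects", config.synth.n_subjects)
    powers, ratings = simulate_powers(config)
    powers.to_csv(out / "band_powers.csv")
    powers.baseline.to_csv(out / "baseline_powers.csv", index=False)
    ratings.to_csv(out / "ratings.csv", index=False)

    for sid in config.feature_sets:
        assemble_feature_set(powers, sid, config.feature_value).to_csv(
            out / f"features_{sid}.csv")

    report, models = run_stats_battery(powers, ratings, config)
    report.to_csv(out / "stats_report.csv", index=False)

    reports = run_classification(powers, config)
    experiment_table(reports).to_csv(out / "classification_report.csv")
    pd.concat([r.predictions.assign(task=t, feature_set=s)
               for (t, s), r in reports.items()],
              ignore_index=True).to_csv(out / "predictions.csv", index=False)

    manifest = {
        "package": "emoeeg",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.synth.seed,
        "n_norm": powers.n_norm,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": ["simulate", "preprocess", "features", "stats", "classify"],
        "stepwise_models": {
            film: {"predictors": m.predictors, "adj_r2": m.adj_r2}
            for film, m in models.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True, default=str))
    return out
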