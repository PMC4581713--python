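"""End-to-end orchestration: simulate -> genotype -> fit -> evaluate.

A run is fully described by a :class:`RunConfig` (YAML-serializable) plus a
master seed; every random draw derives from named substreams of that seed,
recorded in the run manifest, so any artifact is reproducible bit-for-bit
from the config alone (figures excepted).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    calibrate_baseline_rate,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .coxrisk import MODEL_SPECS, CoxRiskModel
from .evaluation import (
    DEFAULT_THRESHOLDS,
    concordance_probability,
    cv_averaged_auc,
    predictive_values,
    risk_distribution_summary,
)
from .genotypes import SnpPanel, default_panel, grs_quintiles, simulate_genotype_dataset
from .schema import (
    DEFAULT_N_SUBJECTS,
    DEFAULT_TARGET_EVENTS,
    default_hazard_spec,
    default_schema,
)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "ValidationReport"]

logger = logging.getLogger(__name__)

#: substream labels hung off the master seed, in spawn order
_SUBSTREAMS = ("cohort", "genotypes", "cv_folds", "bootstrap")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    n_subjects: int = DEFAULT_N_SUBJECTS
    target_events: int = DEFAULT_TARGET_EVENTS
    panel: str = "default"
    cohort_file: str | None = None
    n_replicates: int = 1000
    k_folds: int = 10
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_bootstrap: int = 200
    seed: int = 0
    out_dir: str = "mammorisk_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("config must be a YAML mapping")
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be at least 10")
        if not 0 <= self.target_events < self.n_subjects:
            raise ValueError("target_events must lie in [0, n_subjects)")
        if self.n_replicates < 1 or self.k_folds < 2:
            raise ValueError("n_replicates >= 1 and k_folds >= 2 required")
        for tau in self.thresholds:
            if not 0.0 < tau < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    def load_panel(self) -> SnpPanel:
        if self.panel == "default":
            return default_panel()
        return SnpPanel.from_tsv(self.panel)


@dataclass
class ValidationReport:
    ok: bool
    messages: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        status = "OK" if self.ok else "INVALID"
        return "\n".join([f"validation: {status}", *self.messages])


def validate_inputs(panel_path=None, cohort_path=None) -> ValidationReport:
    """Schema, range and uniqueness checks with line-level diagnostics."""
    messages: list[str] = []
    ok = True
    if panel_path is not None:
        try:
            df = pd.read_csv(panel_path, sep="\t")
        except Exception as exc:
            return ValidationReport(False, [f"panel: cannot parse TSV ({exc})"])
        missing = {"snp_id", "risk_allele_freq", "odds_ratio"} - set(df.columns)
        if missing:
            ok = False
            messages.append(f"panel: missing columns {sorted(missing)}")
        else:
            freq = pd.to_numeric(df["risk_allele_freq"], errors="coerce")
            bad = df.index[~((freq > 0) & (freq < 1))]
            for i in bad:
                ok = False
                messages.append(
                    f"panel line {i + 2}: frequency out of range "
                    f"({df.loc[i, 'risk_allele_freq']!r})"
                )
            orr = pd.to_numeric(df["odds_ratio"], errors="coerce")
            for i in df.index[~(orr > 0)]:
                ok = False
                messages.append(
                    f"panel line {i + 2}: odds ratio must be positive "
                    f"({df.loc[i, 'odds_ratio']!r})"
                )
            dup = df["snp_id"][df["snp_id"].duplicated()]
            for i, s in dup.items():
                ok = False
                messages.append(f"panel line {i + 2}: duplicate snp_id {s!r}")
            if ok:
                messages.append(f"panel: {len(df)} SNPs accepted")
    if cohort_path is not None:
        try:
            df = read_cohort(cohort_path)
            messages.append(
                f"cohort: {len(df)} subjects, {int(df['event'].sum())} events accepted"
            )
        except Exception as exc:
            ok = False
            messages.append(f"cohort: {exc}")
    return ValidationReport(ok, messages)


def _table1(cohort: pd.DataFrame, grs: np.ndarray, schema) -> pd.DataFrame:
    """Covariate distributions split by case status, plus GRS quintiles."""
    case = cohort["event"] == 1
    rows = []
    frames = [(v.name, cohort[v.name]) for v in schema.variables]
    q = grs_quintiles(grs)
    frames.append(("grs_quintile", pd.Series([f"Q{i}" for i in q], index=cohort.index)))
    for name, col in frames:
        for lvl in sorted(col.unique(), key=list(col.unique()).index):
            n_case = int(((col == lvl) & case).sum())
            n_ctrl = int(((col == lvl) & ~case).sum())
            rows.append(
                {
                    "variable": name,
                    "level": lvl,
                    "cases": n_case,
                    "non_cases": n_ctrl,
                    "cases_pct": round(100 * n_case / max(case.sum(), 1), 1),
                    "non_cases_pct": round(100 * n_ctrl / max((~case).sum(), 1), 1),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the artifact set.

    Artifacts (CSV unless noted): cohort table, covariate distributions by
    case status, per-model hazard-ratio tables, concordance probabilities,
    PPV/NPV by threshold, averaged ROC curves (+PNG), predicted-risk
    distributions (+PNG), and a JSON run manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "mammorisk",
        "version": __version__,
        "config": config.to_dict(),
        "substreams": {name: i for i, name in enumerate(_SUBSTREAMS)},
        "stages": {},
    }
    timings: dict[str, float] = {}
    stage = "init"
    try:
        # -- cohort ------------------------------------------------------
        stage = "cohort"
        t0 = time.perf_counter()
        schema = default_schema()
        ss = np.random.SeedSequence(config.seed)
        streams = dict(zip(_SUBSTREAMS, ss.spawn(len(_SUBSTREAMS))))
        if config.cohort_file:
            cohort = read_cohort(config.cohort_file, schema)
        else:
            lam = calibrate_baseline_rate(
                schema,
                default_hazard_spec(),
                n=config.n_subjects,
                target_events=config.target_events,
            )
            manifest["baseline_rate_per_year"] = lam
            cohort_seed = int(streams["cohort"].generate_state(1)[0] % 2**31)
            cohort = generate_cohort(
                n=config.n_subjects,
                target_events=config.target_events,
                seed=cohort_seed,
            )
        write_cohort(cohort, out / "cohort.csv")
        timings[stage] = time.perf_counter() - t0

        # -- genotypes ---------------------------------------------------
        stage = "genotypes"
        t0 = time.perf_counter()
        panel = config.load_panel()
        status = cohort["event"].to_numpy(dtype=int)
        geno_seed = int(streams["genotypes"].generate_state(1)[0] % 2**31)
        grs0 = simulate_genotype_dataset(panel, status, 0, seed=geno_seed).grs
        _table1(cohort, grs0, schema).to_csv(out / "cohort_distributions.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        # -- fits --------------------------------------------------------
        stage = "fit"
        t0 = time.perf_counter()
        fits = {}
        hr_tables = []
        for name in MODEL_SPECS:
            grs = grs0 if MODEL_SPECS[name].include_grs else None
            res = CoxRiskModel(cohort, name, grs=grs, schema=schema).fit()
            fits[name] = res
            tab = res.summary_frame().reset_index()
            tab.insert(0, "model", name)
            hr_tables.append(tab)
        pd.concat(hr_tables, ignore_index=True).to_csv(
            out / "hazard_ratios.csv", index=False
        )
        timings[stage] = time.perf_counter() - t0

        # -- evaluation --------------------------------------------------
        stage = "evaluate"
        t0 = time.perf_counter()
        cv_seed = int(streams["cv_folds"].generate_state(1)[0] % 2**31)
        boot_seed = int(streams["bootstrap"].generate_state(1)[0] % 2**31)
        labels = cohort["label_10y"].to_numpy(dtype=int)
        eval_rows, roc_frames, pv_frames = [], [], []
        risks_by_model = {}
        for name in MODEL_SPECS:
            ev = cv_averaged_auc(
                cohort,
                name,
                panel=panel,
                n_replicates=config.n_replicates,
                k_folds=config.k_folds,
                seed=cv_seed,
                schema=schema,
                keep_mean_risks=True,
            )
            if config.n_bootstrap > 0:
                conc, c_lo, c_hi = concordance_probability(
                    fits[name].linear_predictor,
                    n_bootstrap=config.n_bootstrap,
                    seed=boot_seed,
                )
            else:
                conc = concordance_probability(fits[name].linear_predictor)
                c_lo = c_hi = float("nan")
            eval_rows.append(
                {
                    "model": name,
                    "auc_mean": ev.auc_mean,
                    "auc_lower": ev.auc_lower,
                    "auc_upper": ev.auc_upper,
                    "concordance": conc,
                    "concordance_lower": c_lo,
                    "concordance_upper": c_hi,
                    "n_replicates": ev.n_replicates,
                    "k_folds": ev.k_folds,
                }
            )
            roc = ev.roc_grid.copy()
            roc.insert(0, "model", name)
            roc_frames.append(roc)
            risks_by_model[name] = ev.mean_cv_risks
            pv = predictive_values(ev.mean_cv_risks, labels, config.thresholds)
            pv.insert(0, "model", name)
            pv_frames.append(pv)
        pd.DataFrame(eval_rows).to_csv(out / "discrimination.csv", index=False)
        pd.concat(roc_frames, ignore_index=True).to_csv(
            out / "roc_curves.csv", index=False
        )
        pd.concat(pv_frames, ignore_index=True).to_csv(
            out / "predictive_values.csv", index=False
        )
        risk_distribution_summary(risks_by_model, labels).to_csv(
            out / "risk_distributions.csv", index=False
        )
        _plot_roc(roc_frames, out / "roc_curves.png")
        _plot_risk_distributions(risks_by_model, labels, out / "risk_distributions.png")
        timings[stage] = time.perf_counter() - t0

        manifest["stages"] = {k: round(v, 3) for k, v in timings.items()}
        manifest["n_events"] = int(cohort["event"].sum())
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out)
    return manifest


def _plot_roc(roc_frames: list[pd.DataFrame], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for roc in roc_frames:
        ax.plot(roc["fpr"], roc["tpr_mean"], label=roc["model"].iloc[0])
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_risk_distributions(
    risks_by_model: dict[str, np.ndarray], labels: np.ndarray, path: Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, len(risks_by_model), figsize=(4 * len(risks_by_model), 3.2), sharey=True
    )
    axes = np.atleast_1d(axes)
    for ax, (name, risks) in zip(axes, risks_by_model.items()):
        ax.hist(
            risks[labels == 0], bins=50, density=True, histtype="step", color="black",
            label="non-cases",
        )
        ax.hist(
            risks[labels == 1], bins=50, density=True, histtype="step", color="red",
            label="cases",
        )
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("predicted 10-year risk")
    axes[0].set_ylabel("density")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
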