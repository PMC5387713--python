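"""End-to-end orchestration of the four-step analysis.

normalize (TICV) -> residualize (confounds) -> age^2 screen -> Step 1
(omnibus per metric, FDR across metrics) -> for each surviving metric:
Step 2 (predictor LOO, regression frame), Step 3 (predictor LOO, CCA frame)
and Step 4 (per-parcel response LOO). Steps 2-4 exist only for metrics whose
omnibus null was rejected, unless ``force_all_steps`` is set (recorded in
provenance). Given identical config and seed, outputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import read_atlas
from .cca import predictor_loo_step3, response_loo_step4
from .cohort import (
    METRICS,
    CohortTable,
    MetricPanel,
    read_cohort,
    read_metric_panel,
    validate_dataset,
)
from .demographics import summarize_cohort
from .exceptions import ConnManovaError
from .manova import omnibus_step1, predictor_loo_step2
from .preprocess import (
    ConfoundResidualizer,
    ConfoundSpec,
    TICVNormalizer,
    quadratic_age_screen,
)
from .simulate import SyntheticSpec, generate_dataset

logger = logging.getLogger("connmanova")


def _py(v):
    """numpy scalar -> native Python (exact json round trip)."""
    if isinstance(v, np.bool_):
        return bool(v)
    if isinstance(v, np.integer):
        return int(v)
    if isinstance(v, np.floating):
        return float(v)
    return v

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    """Inputs and knobs of one pipeline run.

    Exactly one of ``data_dir`` (files written by ``connmanova simulate`` or
    arranged the same way) or ``spec`` (generate in memory) must be set.
    """

    data_dir: str | None = None
    spec: SyntheticSpec | None = None
    seed: int = 0
    alpha: float = 0.05
    das_scales: tuple[str, ...] = ("gca",)
    interaction_order: int = 3
    adjust_df: bool = True
    normalize_ticv: bool = True
    ticv_exempt_metrics: tuple[str, ...] = ()
    force_all_steps: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if (self.data_dir is None) == (self.spec is None):
            raise ValueError("set exactly one of data_dir or spec")

    def confound_spec(self) -> ConfoundSpec:
        return ConfoundSpec(tuple(self.das_scales), self.interaction_order, self.adjust_df)

    def to_dict(self) -> dict:
        return {
            "data_dir": self.data_dir,
            "spec": self.spec.to_dict() if self.spec is not None else None,
            "seed": self.seed,
            "alpha": self.alpha,
            "das_scales": list(self.das_scales),
            "interaction_order": self.interaction_order,
            "adjust_df": self.adjust_df,
            "normalize_ticv": self.normalize_ticv,
            "ticv_exempt_metrics": list(self.ticv_exempt_metrics),
            "force_all_steps": self.force_all_steps,
        }

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineReport:
    demographics: pd.DataFrame
    age2_screen: pd.DataFrame
    step1: pd.DataFrame
    step2: dict[str, pd.DataFrame] = field(default_factory=dict)
    step3: dict[str, pd.DataFrame] = field(default_factory=dict)
    step4: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    @property
    def advanced_metrics(self) -> tuple[str, ...]:
        return tuple(self.step2)

    def to_json(self) -> str:
        def df(d: pd.DataFrame) -> dict:
            # exact float round trip: json of Python floats preserves every bit
            out = {
                "columns": list(d.columns),
                "index": list(d.index),
                "data": [[_py(v) for v in row] for row in d.itertuples(index=False)],
            }
            if d.attrs:
                out["attrs"] = {k: _py(v) for k, v in d.attrs.items()}
            return out

        payload = {
            "demographics": df(self.demographics),
            "age2_screen": df(self.age2_screen),
            "step1": df(self.step1),
            "step2": {k: df(v) for k, v in self.step2.items()},
            "step3": {k: df(v) for k, v in self.step3.items()},
            "step4": {k: df(v) for k, v in self.step4.items()},
            "provenance": self.provenance,
            "log": self.log,
        }
        return json.dumps(payload, sort_keys=True, indent=1, default=float)

    @classmethod
    def from_json(cls, text: str) -> "PipelineReport":
        def df(d: dict) -> pd.DataFrame:
            attrs = d.pop("attrs", {})
            out = pd.DataFrame(d["data"], index=d["index"], columns=d["columns"])
            out.attrs.update(attrs)
            return out

        payload = json.loads(text)
        return cls(
            demographics=df(payload["demographics"]),
            age2_screen=df(payload["age2_screen"]),
            step1=df(payload["step1"]),
            step2={k: df(v) for k, v in payload["step2"].items()},
            step3={k: df(v) for k, v in payload["step3"].items()},
            step4={k: df(v) for k, v in payload["step4"].items()},
            provenance=payload["provenance"],
            log=payload["log"],
        )


def _load_dataset(config: PipelineConfig):
    if config.spec is not None:
        return generate_dataset(config.spec, config.seed)
    d = Path(config.data_dir)
    atlas = read_atlas(d / "atlas.txt")
    cohort = read_cohort(d / "cohort.tsv")
    panels = {
        m: read_metric_panel(d / f"panel_{m}.tsv", atlas, cohort, metric_name=m)
        for m in METRICS
    }
    return cohort, panels


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis; see the module docstring for the stages."""
    log: list[str] = []

    def note(msg: str) -> None:
        logger.info(msg)
        log.append(msg)

    cohort, panels = _load_dataset(config)
    report_check = validate_dataset(cohort, list(panels.values()))
    if not report_check.ok:
        raise ConnManovaError(
            f"stage validate: dataset inconsistent ({report_check.violations[:3]}); "
            "fix the input files before analysis"
        )
    note(f"validate: {report_check.summary()}")

    demographics = summarize_cohort(cohort)
    note("demographics: summary computed")

    if config.normalize_ticv:
        norm = TICVNormalizer().fit(cohort)
        panels = {
            m: (p if m in config.ticv_exempt_metrics else norm.transform(p))
            for m, p in panels.items()
        }
        note("normalize: metrics divided by TICV"
             + (f" (exempt: {config.ticv_exempt_metrics})" if config.ticv_exempt_metrics else ""))

    cspec = config.confound_spec()
    age2 = quadratic_age_screen(panels, cohort, spec=cspec, alpha=config.alpha)
    n_age2 = int(age2["reject"].sum())
    note(
        "age2 screen: "
        + (f"{n_age2} metric(s) show a quadratic age effect" if n_age2
           else "no quadratic age effect; age enters linearly")
    )

    resid = ConfoundResidualizer(cspec.das_scales, cspec.interaction_order).fit(cohort)
    panels = {m: resid.transform(p) for m, p in panels.items()}
    from .manova import build_design

    design = build_design(cohort)
    if config.adjust_df:
        # honest accounting: project the predictors too (partial regression)
        # and charge the confound columns against the error df
        design = resid.transform_design(design)
        df_adjust = resid.n_confounds_
    else:
        df_adjust = 0
    note(f"residualize: {resid.n_confounds_} confound columns projected out "
         f"(df_adjust={df_adjust})")

    step1 = omnibus_step1(panels, cohort, alpha=config.alpha, df_adjust=df_adjust,
                          design=design)
    advancing = [m for m in panels if bool(step1.loc[m, "reject"])]
    note(f"step1: omnibus rejected for {advancing or 'no metric'}")
    if config.force_all_steps:
        advancing = list(panels)
        note("step1: force_all_steps set; all metrics advance (exploratory)")

    step2: dict[str, pd.DataFrame] = {}
    step3: dict[str, pd.DataFrame] = {}
    step4: dict[str, pd.DataFrame] = {}
    for m in advancing:
        fit_kwargs = dict(alpha=config.alpha, df_adjust=df_adjust, design=design)
        step2[m] = predictor_loo_step2(panels[m], cohort, **fit_kwargs)
        step3[m] = predictor_loo_step3(panels[m], cohort, **fit_kwargs)
        step4[m] = response_loo_step4(panels[m], cohort, **fit_kwargs)
        note(
            f"steps 2-4 [{m}]: predictors rejected = "
            f"{list(step2[m].index[step2[m]['reject']])}; "
            f"{int(step4[m]['reject'].sum())} parcel(s) significant in step 4"
        )

    provenance = {
        "package": "connmanova",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": config.to_dict(),
        "forced_all_steps": config.force_all_steps,
    }
    return PipelineReport(
        demographics=demographics,
        age2_screen=age2,
        step1=step1,
        step2=step2,
        step3=step3,
        step4=step4,
        provenance=provenance,
        log=log,
    )


def write_report(report: PipelineReport, out) -> list[str]:
    """Write TSVs per step plus report.json and a manifest of file hashes.

    Step-4 tables are written sorted descending by partial F. Returns the
    manifest (file names in written order). Rewriting into the same
    directory yields identical hashes.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(name: str, df: pd.DataFrame, index_label: str | None = None) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)
        written.append(name)

    emit("demographics.tsv", report.demographics, index_label="descriptor")
    emit("age2_screen.tsv", report.age2_screen, index_label="metric")
    emit("step1_omnibus.tsv", report.step1, index_label="metric")
    for m, df in report.step2.items():
        emit(f"step2_predictor_loo_{m}.tsv", df, index_label="predictor")
    for m, df in report.step3.items():
        emit(f"step3_cca_loo_{m}.tsv", df, index_label="predictor")
    for m, df in report.step4.items():
        ordered = df.sort_values("partial_f", ascending=False, kind="mergesort")
        emit(f"step4_region_loo_{m}.tsv", ordered)
    (out / "report.json").write_text(report.to_json(), encoding="utf-8")
    written.append("report.json")

    lines = []
    for name in written:
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
        lines.append(f"{digest}  {name}")
    (out / "manifest.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    written.append("manifest.txt")
    return written
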