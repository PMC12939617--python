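"""End-to-end orchestration: bundles in, signal tables and TTO results out.

``run_pipeline`` wires the stages together — read quarter directories,
deduplicate, age-standardise and filter to the pediatric background, define
cases, screen every Primary-Suspect drug with the four disproportionality
algorithms (broad and narrow PT query), and run the time-to-onset analysis
— writing TSV/JSON outputs plus a flowchart-style count summary.  Every
output is fully determined by the configuration (and the seed recorded in
it for provenance).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import faers_io, preprocess
from .case_definition import DrugNameMap
from .disproportionality import DisproportionalityScreen
from .tto import WeibullTTO, WeibullFitError, bin_tto, compare_onset_groups, tto_inclusion


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """A pipeline stage failed on the data (CLI exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    input_dir: Optional[str] = None
    output_dir: str = "faersig_out"
    age_lower: float = 0.0
    age_upper: float = 18.0
    query_mode: str = "both"  # broad | narrow | both
    min_reports: int = 3
    bcpnn_strict: bool = False
    tto_edges: tuple[int, ...] = (30, 60, 90, 180, 360)
    implausible_days: int = 6574
    age_bands: tuple[tuple[str, float, float], ...] = (
        ("0-5", 0.0, 6.0), ("6-13", 6.0, 14.0), ("14-17", 14.0, 18.0),
    )
    seed: int = 0
    make_plots: bool = False
    drug_map_path: Optional[str] = None

    def validate(self) -> None:
        if self.query_mode not in ("broad", "narrow", "both"):
            raise ConfigError(f"query_mode must be broad|narrow|both, got {self.query_mode!r}")
        if not self.age_lower < self.age_upper:
            raise ConfigError("age_lower must be below age_upper")
        if self.min_reports < 1:
            raise ConfigError("min_reports must be >= 1")
        if any(e2 <= e1 for e1, e2 in zip(self.tto_edges, self.tto_edges[1:])):
            raise ConfigError("tto_edges must be strictly increasing")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path


@dataclass
class PipelineResult:
    dataset: pd.DataFrame
    qc: dict
    flowchart: dict
    screens: dict[str, pd.DataFrame]
    descriptives: dict
    tto_summary: dict
    output_dir: Optional[Path] = None


def _age_band_counts(ages: pd.Series, bands) -> dict[str, int]:
    out = {}
    for label, lo, hi in bands:
        out[label] = int(((ages >= lo) & (ages < hi)).sum())
    return out


def descriptive_summary(cases: pd.DataFrame, bands) -> dict:
    """Fig-2-style descriptive tables for the case reports."""
    out: dict = {"n_cases": len(cases)}
    out["age_bands"] = _age_band_counts(cases["age_years"], bands)
    out["sex"] = cases["sex"].fillna("UNK").value_counts().to_dict() if "sex" in cases else {}
    if "occp_cod" in cases:
        out["reporter_occupation"] = cases["occp_cod"].fillna("").value_counts().to_dict()
    if "reporter_country" in cases:
        out["country"] = cases["reporter_country"].fillna("").value_counts().to_dict()
    if "outcomes" in cases:
        flat = cases["outcomes"].fillna("").str.split(",").explode()
        flat = flat[flat != ""]
        out["outcomes"] = flat.value_counts().to_dict()
    if "fda_dt" in cases:
        years = cases["fda_dt"].astype(str).str[:4]
        out["report_year"] = years.value_counts().sort_index().to_dict()
    return out


def load_bundles(input_dir: str | Path) -> faers_io.QuarterBundle:
    """Read one quarter directory, or a directory of quarter directories."""
    input_dir = Path(input_dir)
    if not input_dir.exists():
        raise ConfigError(f"input directory {input_dir} does not exist")
    if (input_dir / "demo.txt").exists():
        return faers_io.read_quarter_dir(input_dir)
    subdirs = sorted(p for p in input_dir.iterdir() if (p / "demo.txt").exists())
    if not subdirs:
        raise ConfigError(f"no quarter files found under {input_dir}")
    bundles = [faers_io.read_quarter_dir(p, quarter_label=p.name) for p in subdirs]
    return faers_io.concat_bundles(bundles)


def run_pipeline(
    config: PipelineConfig, bundle: Optional[faers_io.QuarterBundle] = None
) -> PipelineResult:
    """Run every stage; any stage failure aborts naming the stage and cause."""
    config.validate()
    if bundle is None:
        if config.input_dir is None:
            raise ConfigError("either input_dir or an in-memory bundle is required")
        try:
            bundle = load_bundles(config.input_dir)
        except ConfigError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise DataError("read", exc) from exc

    name_map = (
        DrugNameMap.from_tsv(config.drug_map_path)
        if config.drug_map_path
        else DrugNameMap.packaged()
    )

    try:
        dataset, qc = preprocess.prepare_dataset(
            bundle,
            name_map,
            age_lower=config.age_lower,
            age_upper=config.age_upper,
            implausible_days=config.implausible_days,
        )
    except Exception as exc:  # noqa: BLE001
        raise DataError("preprocess", exc) from exc

    flowchart = {
        "raw_reports": qc["raw_reports"],
        "missing_caseid": qc["missing_caseid"],
        "duplicates_removed": qc["duplicates_removed"],
        "deduplicated": qc["kept"],
        "pediatric_retained": qc["pediatric_retained"],
        "cases_broad": qc["cases_broad"],
        "cases_narrow": qc["cases_narrow"],
        "ps_assigned": qc["ps_assigned"],
    }

    modes = ("broad", "narrow") if config.query_mode == "both" else (config.query_mode,)
    screens: dict[str, pd.DataFrame] = {}
    for mode in modes:
        try:
            res = DisproportionalityScreen(
                dataset,
                query=mode,
                min_reports=config.min_reports,
                bcpnn_strict=config.bcpnn_strict,
            ).fit()
        except Exception as exc:  # noqa: BLE001
            raise DataError(f"screen[{mode}]", exc) from exc
        screens[mode] = res.table

    cases = dataset[dataset["is_case_broad"]]
    descriptives = descriptive_summary(cases, config.age_bands)

    tto_summary: dict = {}
    try:
        included, counts = tto_inclusion(cases)
        tto_summary["inclusion"] = counts
        days = included["tto_days"].dropna().astype(int)
        if len(days):
            bins = bin_tto(days, edges=config.tto_edges)
            tto_summary["bins"] = bins.to_dict(orient="records")
        try:
            fit = WeibullTTO(days).fit()
            tto_summary["weibull"] = fit.to_dict()
        except WeibullFitError as exc:
            tto_summary["weibull"] = {"skipped": str(exc)}
        if "ps_class" in included.columns and len(days):
            grp = included["ps_class"].fillna("other").map(
                lambda c: "glucocorticoid" if c == "glucocorticoid" else "other"
            )
            if grp.nunique() == 2:
                cmp = compare_onset_groups(days, grp[included["tto_days"].notna()])
                tto_summary["logrank"] = {
                    "statistic": cmp.statistic,
                    "p_value": cmp.p_value,
                    "group_sizes": dict(cmp.group_sizes),
                }
    except DataError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise DataError("tto", exc) from exc

    result = PipelineResult(
        dataset=dataset, qc=qc, flowchart=flowchart, screens=screens,
        descriptives=descriptives, tto_summary=tto_summary,
    )

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_json(outdir / "pipeline_config.json")
        dataset.to_csv(outdir / "dataset.tsv", sep="\t", index=False)
        (outdir / "qc.json").write_text(json.dumps(qc, indent=1, default=str))
        (outdir / "flowchart.json").write_text(json.dumps(flowchart, indent=1))
        (outdir / "descriptives.json").write_text(json.dumps(descriptives, indent=1))
        for mode, tbl in screens.items():
            tbl.to_csv(outdir / f"signals_{mode}.tsv", sep="\t", index=False)
            tbl.to_json(outdir / f"signals_{mode}.json", orient="records", indent=1)
        (outdir / "tto_summary.json").write_text(
            json.dumps(tto_summary, indent=1, default=str)
        )
        cases_tto = cases[["primaryid", "ps_entity", "ps_class", "tto_days", "tto_reason"]]
        cases_tto.to_csv(outdir / "tto_records.tsv", sep="\t", index=False)
        if config.make_plots:
            from . import plots

            plots.render_all(result, outdir)
        result.output_dir = outdir

    return result
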