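"""End-to-end orchestration: signals -> features -> epochs -> selection -> models.

Everything the command-line interface does is a thin wrapper around the
functions here, so scripted analyses and tests use the same code paths.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FEATURE_NAMES, POSITIVE_LABEL, AnalysisConfig
from .epoching import BISTrace, NoAwakeningError, detect_t0, extract_measurements, timepoint_counts
from .features import sliding_features
from .modeling import ArousalLogit, ArousalTree
from .preprocess import RRSeries, clean
from .selection import SelectionRules, pca_varimax, pearson_matrix, select_uncorrelated

#: the study's preference ordering and always-keep set for variable selection
DOMAIN_PREFS = ["SDNN", "LF", "HR", "ANI", "RMSSD", "LTV", "STV", "HF"]
ALWAYS_KEEP = {"RMSSD"}


def process_case(
    rr: RRSeries,
    bis: BISTrace,
    drug_stop: float,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Clean one case's RR series and extract its labeled measurement rows."""
    config = config or AnalysisConfig()
    cleaned, _ = clean(rr, config.artifact_threshold, config.artifact_window)
    tracks = sliding_features(
        cleaned,
        config.windows,
        alpha=config.ani_alpha,
        beta=config.ani_beta,
        divisor=config.ani_divisor,
    )
    t0 = detect_t0(bis, drug_stop, config.bis_threshold)
    return extract_measurements(tracks, bis, t0, case_id=rr.case_id, config=config)


def build_measurement_table(
    cases: list[tuple[RRSeries, BISTrace, float]],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Measurement table over a cohort; cases without a captured awakening are skipped."""
    config = config or AnalysisConfig()
    frames = []
    for rr, bis, drug_stop in cases:
        try:
            frames.append(process_case(rr, bis, drug_stop, config))
        except NoAwakeningError:
            continue
    if not frames:
        raise ValueError("no case produced measurements")
    return pd.concat(frames, ignore_index=True)


@dataclass
class AnalysisResult:
    """Bundle of every analysis stage run on one measurement table."""

    table: pd.DataFrame
    correlations: pd.DataFrame
    factor_model: object
    selection_rules: SelectionRules
    selected: list[str]
    logit: object          # ArousalLogitResults
    tree: object           # ArousalTreeResults
    config: AnalysisConfig
    seed: int

    def summary(self) -> str:
        parts = [
            "Selected variables: " + ", ".join(self.selected),
            "",
            self.logit.summary(),
            "",
            self.tree.summary(),
        ]
        return "\n".join(parts)


def analyze_table(
    table: pd.DataFrame,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> AnalysisResult:
    """Run variable selection and both classifiers on a measurement table."""
    config = config or AnalysisConfig()
    variables = [v for v in FEATURE_NAMES if v in table.columns]
    corr = pearson_matrix(table, variables)
    fm = pca_varimax(table, variables, config.n_factors)
    rules = SelectionRules(config.loading_cutoff, config.corr_cutoff)
    selected, rules = select_uncorrelated(
        fm, corr, rules, domain_prefs=DOMAIN_PREFS, always_keep=ALWAYS_KEEP
    )
    logit = ArousalLogit(table, selected, config).fit(seed=seed)
    tree = ArousalTree(table, selected, config).fit()
    return AnalysisResult(table, corr, fm, rules, selected, logit, tree, config, seed)


def validate_table(table: pd.DataFrame, config: AnalysisConfig | None = None) -> dict:
    """Schema/range diagnostics and the per-time-point design layout."""
    config = config or AnalysisConfig()
    problems: list[str] = []
    required = ["case_id", "timepoint_min", *FEATURE_NAMES, "BIS", "class"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        problems.append(f"missing columns: {missing}")
    if len(table) == 0:
        problems.append("no rows")
        return {"n_rows": 0, "problems": problems, "counts": None,
                "n_positive": 0, "n_negative": 0}
    if not missing:
        for col, lo, hi in (("BIS", 0, 100), ("ANI", 0, 100)):
            bad = table[(table[col] < lo) | (table[col] > hi)]
            if len(bad):
                problems.append(f"{col} outside [{lo},{hi}] in {len(bad)} row(s)")
        for col in ("STV", "SDNN", "LTV", "RMSSD", "LF", "HF"):
            bad = table[table[col] < 0]
            if len(bad):
                problems.append(f"negative {col} in {len(bad)} row(s)")
        mismatch = table[
            (table["class"] == POSITIVE_LABEL) != (table["BIS"] >= config.bis_threshold)
        ]
        if len(mismatch):
            problems.append(f"class/BIS mismatch in {len(mismatch)} row(s)")
    counts = timepoint_counts(table, config) if "timepoint_min" in table.columns else None
    n_pos = int((table.get("class") == POSITIVE_LABEL).sum()) if "class" in table.columns else 0
    return {
        "n_rows": len(table),
        "n_positive": n_pos,
        "n_negative": len(table) - n_pos,
        "counts": counts,
        "problems": problems,
    }


# ---------------------------------------------------------------------------
# file-based runs
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def read_measurement_table(path) -> pd.DataFrame:
    """Read a measurement table from CSV or an S1-shaped XLSX sheet."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    rename = {c: c.strip() for c in df.columns}
    df = df.rename(columns=rename)
    if "class" not in df.columns and "BIS" in df.columns:
        df["class"] = np.where(df["BIS"] >= 60, POSITIVE_LABEL, "BIS<60")
    return df


def run_pipeline(
    cases: list[tuple[RRSeries, BISTrace, float]],
    out_dir,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> RunManifest:
    """Full run writing the measurement table, reports and a run manifest."""
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.hash(), seed=seed)

    t = time.perf_counter()
    table = build_measurement_table(cases, config)
    manifest.timings["signals"] = time.perf_counter() - t
    table_path = out / "measurements.csv"
    table.to_csv(table_path, index=False)
    manifest.outputs["measurements"] = str(table_path)

    t = time.perf_counter()
    result = analyze_table(table, config, seed)
    manifest.timings["analysis"] = time.perf_counter() - t
    write_reports(result, out, manifest)
    return manifest


def write_reports(result: AnalysisResult, out_dir, manifest: RunManifest | None = None) -> dict:
    """Write the selection/model report CSVs and the plain-text run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["correlations"] = out / "correlations.csv"
    result.correlations.to_csv(paths["correlations"])
    paths["loadings"] = out / "factor_loadings.csv"
    result.factor_model.loadings.round(6).to_csv(paths["loadings"])

    freq = result.logit.selection_trace.frequencies
    paths["retention"] = out / "bootstrap_retention.csv"
    freq.to_frame().to_csv(paths["retention"])

    if result.logit.final is not None:
        paths["odds_ratios"] = out / "odds_ratios.csv"
        result.logit.final.odds_ratios.round(6).to_csv(paths["odds_ratios"])
        rep = result.logit.classify()
        if rep.by_timepoint is not None:
            paths["logit_misclassification"] = out / "logit_misclassification.csv"
            rep.by_timepoint.to_csv(paths["logit_misclassification"], index=False)

    tree_rep = result.tree.classify()
    if tree_rep.by_timepoint is not None:
        paths["tree_misclassification"] = out / "tree_misclassification.csv"
        tree_rep.by_timepoint.to_csv(paths["tree_misclassification"], index=False)

    paths["summary"] = out / "run_log.txt"
    header = (
        f"config_hash: {result.config.hash()}\nseed: {result.seed}\n\n"
    )
    paths["summary"].write_text(header + result.summary() + "\n")

    if manifest is not None:
        manifest.outputs.update({k: str(v) for k, v in paths.items()})
    return paths


def write_cohort(cases, out_dir) -> Path:
    """Write per-case RR/BIS CSVs and the cohort manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rr, bis, drug_stop in cases:
        rr_path = out / f"{rr.case_id}_rr.csv"
        bis_path = out / f"{rr.case_id}_bis.csv"
        rr.to_csv(rr_path)
        bis.to_csv(bis_path)
        rows.append(
            {
                "case_id": rr.case_id,
                "rr_path": rr_path.name,
                "bis_path": bis_path.name,
                "drug_stop_s": drug_stop,
            }
        )
    manifest_path = out / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


def read_cohort(manifest_path) -> list[tuple[RRSeries, BISTrace, float]]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    cases = []
    for _, row in df.iterrows():
        rr = RRSeries.from_csv(base / row["rr_path"], case_id=str(row["case_id"]))
        bis = BISTrace.from_csv(base / row["bis_path"])
        cases.append((rr, bis, float(row["drug_stop_s"])))
    return cases
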