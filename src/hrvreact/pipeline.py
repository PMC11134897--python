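"""End-to-end orchestration: simulate/load -> preprocess -> indexes -> deltas
-> ROC -> cohort statistics, with a digest-covered run manifest.

Subjects with a missing or unusable recording are excluded pairwise (per
analysis), never listwise: a missing maneuver flags that maneuver's deltas
as NaN and drops the subject from that maneuver's ROC only.  Any hard stage
failure aborts with the stage (and subject/condition where known) in the
message and leaves partial outputs under a ``failed`` marker file.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import re
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .clinical import ECHO_FIELDS, EchoPanel, SubjectRecord
from .config import (BASELINE, CONDITIONS, CriteriaConfig, FOLLOWUP,
                     FilterConfig, MANEUVERS, SUPINE, TIMEPOINTS, SimConfig,
                     WelchSettings, sim_config_to_yaml)
from .errors import (ConfigurationError, HRVReactError, InsufficientDataError,
                     MissingDataError, NonPositiveDataError, UndefinedROCError)
from .indexes import INDEX_FIELDS, compute_all
from .preprocess import clean_to_nn, select_segment
from .reactivity import MANEUVER_MINUS_SUPINE, compute_deltas
from .roc import analyze
from .series import RRSeries, read_tachogram, write_tachogram
from .simulate import generate_cohort
from .stats import (classify_cardiotoxicity, compare_groups, normality_gate,
                    pearson_matrix)

_FILE_RE = re.compile(r"^(?P<sid>[A-Za-z0-9]+)_(?P<tp>baseline|followup)_"
                      r"(?P<cond>supine|standing|breathing)\.rr$")


class PipelineError(HRVReactError):
    """A stage failed; the message names the stage (and subject/condition)."""


@dataclass
class RunManifest:
    seed: int
    config: dict
    version: str
    digests: Dict[str, str]
    warnings: List[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class ValidationReport:
    defects: List[str]
    n_files: int

    @property
    def ok(self) -> bool:
        return not self.defects


# --------------------------------------------------------------------------
# data layer
# --------------------------------------------------------------------------

def tachogram_name(subject_id: str, timepoint: str, condition: str) -> str:
    return f"{subject_id}_{timepoint}_{condition}.rr"


def simulate_to_dir(config: SimConfig, data_dir) -> List[Path]:
    """Generate a cohort and write one tachogram per recording plus cohort.csv."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    written = []
    rows = []
    for subj in cohort:
        for (tp, cond), series in sorted(subj.recordings.items()):
            path = data_dir / tachogram_name(subj.subject_id, tp, cond)
            write_tachogram(series, path)
            written.append(path)
        row = {"subject_id": subj.subject_id, "group": subj.group,
               "troponin_baseline": subj.troponin_positive[BASELINE],
               "troponin_followup": subj.troponin_positive[FOLLOWUP]}
        for tp in TIMEPOINTS:
            for name, value in subj.echo[tp].as_dict().items():
                row[f"{name}_{tp}"] = value
        rows.append(row)
    cohort_path = data_dir / "cohort.csv"
    pd.DataFrame(rows).to_csv(cohort_path, index=False)
    written.append(cohort_path)
    return written


def load_cohort_dir(data_dir) -> Tuple[Dict[str, SubjectRecord],
                                       Dict[Tuple[str, str, str], RRSeries]]:
    """Read cohort.csv and every recognised tachogram from a directory."""
    data_dir = Path(data_dir)
    cohort_path = data_dir / "cohort.csv"
    if not cohort_path.exists():
        raise MissingDataError(f"{cohort_path} not found")
    table = pd.read_csv(cohort_path)
    records: Dict[str, SubjectRecord] = {}
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        rec = SubjectRecord(subject_id=sid, group=row.get("group"))
        for tp in TIMEPOINTS:
            echo_vals = {name: row.get(f"{name}_{tp}", math.nan) for name in ECHO_FIELDS}
            if all(np.isfinite(list(echo_vals.values()))):
                rec.echo[tp] = EchoPanel(**echo_vals)
            key = f"troponin_{tp}"
            if key in row and not pd.isna(row[key]):
                rec.troponin_positive[tp] = bool(row[key])
        records[sid] = rec
    recordings: Dict[Tuple[str, str, str], RRSeries] = {}
    for path in sorted(data_dir.glob("*.rr")):
        m = _FILE_RE.match(path.name)
        if not m:
            continue
        recordings[(m["sid"], m["tp"], m["cond"])] = read_tachogram(
            path, subject_id=m["sid"], timepoint=m["tp"], condition=m["cond"])
    return records, recordings


def validate_inputs(data_dir) -> ValidationReport:
    """Check tachogram dialect, positivity and per-subject completeness."""
    data_dir = Path(data_dir)
    defects: List[str] = []
    if not data_dir.is_dir():
        return ValidationReport([f"{data_dir}: not a directory"], 0)
    seen = set()
    files = sorted(data_dir.glob("*.rr"))
    for path in files:
        m = _FILE_RE.match(path.name)
        if not m:
            defects.append(f"{path.name}: filename does not match "
                           "<subject>_<timepoint>_<condition>.rr")
            continue
        seen.add((m["sid"], m["tp"], m["cond"]))
        try:
            text = path.read_text(encoding="utf-8")
        except OSError as exc:
            defects.append(f"{path.name}: unreadable ({exc})")
            continue
        n_vals = 0
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            token = line.split()[0]
            try:
                v = float(token)
            except ValueError:
                defects.append(f"{path.name}:{lineno}: not a number: {token!r}")
                continue
            if v <= 0:
                defects.append(f"{path.name}:{lineno}: non-positive interval {v}")
            n_vals += 1
        if n_vals == 0:
            defects.append(f"{path.name}: no intervals")
    subjects = sorted({sid for sid, _, _ in seen})
    if (data_dir / "cohort.csv").exists():
        try:
            listed = pd.read_csv(data_dir / "cohort.csv")["subject_id"].astype(str)
            subjects = sorted(set(subjects) | set(listed))
        except Exception as exc:  # defective table is a report entry, not a crash
            defects.append(f"cohort.csv: unreadable ({exc})")
    else:
        defects.append("cohort.csv: missing")
    for sid in subjects:
        for tp in TIMEPOINTS:
            for cond in CONDITIONS:
                if (sid, tp, cond) not in seen:
                    defects.append(f"missing recording: ({sid}, {tp}, {cond})")
    return ValidationReport(defects, len(files))


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, header_lines: List[str],
               index: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=index)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(out_dir, config: Optional[SimConfig] = None,
                 input_dir=None, seed: Optional[int] = None,
                 filter_config: FilterConfig = FilterConfig(),
                 welch: WelchSettings = WelchSettings(),
                 criteria: CriteriaConfig = CriteriaConfig(),
                 L: int = 300, skip_s: float = 180.0) -> RunManifest:
    """Run every stage and return the digest-covered manifest.

    With ``input_dir`` unset, a cohort is simulated from ``config`` (seed
    optionally overridden) and its data files are written under
    ``out_dir/data``; otherwise tachograms and cohort.csv are read from
    ``input_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or SimConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    warn_list: List[str] = []
    stage = "setup"
    try:
        # ---- data -------------------------------------------------------
        stage = "data"
        if input_dir is None:
            simulate_to_dir(config, out_dir / "data")
            records, recordings = load_cohort_dir(out_dir / "data")
        else:
            records, recordings = load_cohort_dir(input_dir)
        subject_ids = sorted(records)

        # ---- preprocessing + indexes ------------------------------------
        stage = "indexes"
        index_rows = []
        index_sets: Dict[Tuple[str, str, str], object] = {}
        for sid in subject_ids:
            for tp in TIMEPOINTS:
                for cond in CONDITIONS:
                    series = recordings.get((sid, tp, cond))
                    if series is None:
                        warn_list.append(f"missing recording ({sid}, {tp}, {cond})")
                        continue
                    try:
                        cleaned = clean_to_nn(series, filter_config)
                        segment = select_segment(
                            cleaned.series, L=L, skip_s=skip_s,
                            min_rr_ms=filter_config.min_rr_ms,
                            max_rr_ms=filter_config.max_rr_ms)
                        idx = compute_all(segment, welch)
                    except (InsufficientDataError, ConfigurationError) as exc:
                        warn_list.append(f"excluded ({sid}, {tp}, {cond}): {exc}")
                        continue
                    index_sets[(sid, tp, cond)] = idx
                    index_rows.append({"subject_id": sid, "timepoint": tp,
                                       "condition": cond,
                                       "n_excluded": cleaned.n_excluded,
                                       **idx.as_dict()})
        indexes_df = pd.DataFrame(index_rows)

        # ---- deltas -----------------------------------------------------
        stage = "deltas"
        delta_rows = []
        delta_sets: Dict[Tuple[str, str], object] = {}
        for sid in subject_ids:
            for tp in TIMEPOINTS:
                per_cond = {cond: index_sets[(sid, tp, cond)]
                            for cond in CONDITIONS if (sid, tp, cond) in index_sets}
                try:
                    ds = compute_deltas(per_cond, subject_id=sid, timepoint=tp,
                                        convention=criteria.delta_convention)
                except MissingDataError as exc:
                    warn_list.append(f"deltas unavailable: {exc}")
                    continue
                delta_sets[(sid, tp)] = ds
                for maneuver in MANEUVERS:
                    if maneuver not in per_cond:
                        warn_list.append(
                            f"delta flagged missing ({sid}, {tp}, {maneuver})")
                    delta_rows.append({"subject_id": sid, "timepoint": tp,
                                       "maneuver": maneuver,
                                       **ds.deltas[maneuver]})
        deltas_df = pd.DataFrame(delta_rows)

        # ---- cardiotoxicity labels --------------------------------------
        stage = "classification"
        labels: Dict[str, str] = {}
        for sid in subject_ids:
            try:
                labels[sid] = classify_cardiotoxicity(records[sid], criteria)
            except MissingDataError as exc:
                warn_list.append(f"unclassifiable: {exc}")
        label_df = pd.DataFrame(
            [{"subject_id": sid, "group": records[sid].group,
              "cardiotox_label": labels.get(sid, ""),
              "cardiotox": labels.get(sid, "none") != "none" if sid in labels else math.nan}
             for sid in subject_ids])

        # ---- ROC table --------------------------------------------------
        stage = "roc"
        roc_rows = []
        for maneuver in MANEUVERS:
            for index in INDEX_FIELDS:
                scores, y = [], []
                for sid in subject_ids:
                    if sid not in labels or (sid, BASELINE) not in delta_sets:
                        continue
                    v = delta_sets[(sid, BASELINE)].get(index, maneuver)
                    if math.isfinite(v):
                        scores.append(v)
                        y.append(labels[sid] != "none")
                row = {"index": index, "maneuver": maneuver, "n": len(scores),
                       "n_case": int(sum(y)), "n_control": int(len(y) - sum(y))}
                try:
                    res = analyze(np.array(scores), np.array(y),
                                  name=index, maneuver=maneuver)
                    row.update(auc=res.auc, auc_ci_low=res.auc_ci95[0],
                               auc_ci_high=res.auc_ci95[1],
                               p_value=res.p_value_vs_half,
                               direction=res.direction,
                               cutoff=res.best_cutoff,
                               cutoff_label=res.cutoff_label,
                               sensitivity_pct=res.sensitivity_pct,
                               specificity_pct=res.specificity_pct)
                except (UndefinedROCError, ValueError) as exc:
                    warn_list.append(f"ROC undefined for ({index}, {maneuver}): {exc}")
                    row.update(auc=math.nan, auc_ci_low=math.nan,
                               auc_ci_high=math.nan, p_value=math.nan,
                               direction="", cutoff=math.nan, cutoff_label="",
                               sensitivity_pct=math.nan, specificity_pct=math.nan)
                roc_rows.append(row)
        roc_df = pd.DataFrame(roc_rows)

        # ---- summary tables ---------------------------------------------
        stage = "stats"
        summary_rows = []
        if not indexes_df.empty:
            for (tp, cond), grp in indexes_df.groupby(["timepoint", "condition"]):
                for index in INDEX_FIELDS:
                    vals = grp[index].to_numpy(dtype=float)
                    vals = vals[np.isfinite(vals)]
                    summary_rows.append({
                        "timepoint": tp, "condition": cond, "index": index,
                        "n": vals.size,
                        "mean": float(np.mean(vals)) if vals.size else math.nan,
                        "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else math.nan})
        summary_df = pd.DataFrame(summary_rows)

        comparison_rows = []
        case_ids = [s for s in subject_ids if labels.get(s) not in (None, "none")]
        ctrl_ids = [s for s in subject_ids if labels.get(s) == "none"]
        for maneuver in MANEUVERS:
            for index in INDEX_FIELDS:
                def _vals(ids):
                    out = []
                    for sid in ids:
                        if (sid, BASELINE) in delta_sets:
                            v = delta_sets[(sid, BASELINE)].get(index, maneuver)
                            if math.isfinite(v):
                                out.append(v)
                    return np.array(out)

                a, b = _vals(case_ids), _vals(ctrl_ids)
                row = {"index": index, "maneuver": maneuver,
                       "n_case": a.size, "n_control": b.size,
                       "transformed": False}
                if a.size >= 2 and b.size >= 2:
                    xa, xb = a, b
                    try:
                        pooled, flag = normality_gate(np.concatenate([a, b]))
                        if flag:
                            xa, xb = np.log10(a), np.log10(b)
                            row["transformed"] = True
                    except (NonPositiveDataError, HRVReactError):
                        warn_list_entry = (f"log10 gate skipped for "
                                           f"({index}, {maneuver}): non-positive values")
                        if warn_list_entry not in warn_list:
                            warn_list.append(warn_list_entry)
                    res = compare_groups(xa, xb, paired=False)
                    row.update(mean_case=res.mean_a, sd_case=res.sd_a,
                               mean_control=res.mean_b, sd_control=res.sd_b,
                               t=res.statistic, p_value=res.p_value)
                else:
                    row.update(mean_case=math.nan, sd_case=math.nan,
                               mean_control=math.nan, sd_control=math.nan,
                               t=math.nan, p_value=math.nan)
                comparison_rows.append(row)
        comparison_df = pd.DataFrame(comparison_rows)

        echo_rows = []
        for name in ECHO_FIELDS:
            pairs = [(records[s].echo[BASELINE].as_dict()[name],
                      records[s].echo[FOLLOWUP].as_dict()[name])
                     for s in subject_ids
                     if BASELINE in records[s].echo and FOLLOWUP in records[s].echo]
            if len(pairs) < 2:
                continue
            a = np.array([p[0] for p in pairs])
            b = np.array([p[1] for p in pairs])
            res = compare_groups(a, b, paired=True)
            echo_rows.append({"variable": name, "n": a.size,
                              "mean_baseline": res.mean_a, "sd_baseline": res.sd_a,
                              "mean_followup": res.mean_b, "sd_followup": res.sd_b,
                              "t": res.statistic, "p_value": res.p_value})
        echo_df = pd.DataFrame(echo_rows)

        echo_base = pd.DataFrame(
            {name: [records[s].echo[BASELINE].as_dict()[name]
                    if BASELINE in records[s].echo else math.nan
                    for s in subject_ids] for name in ECHO_FIELDS},
            index=subject_ids)
        hrv_base = pd.DataFrame(
            {index: [getattr(index_sets[(s, BASELINE, SUPINE)], index)
                     if (s, BASELINE, SUPINE) in index_sets else math.nan
                     for s in subject_ids] for index in INDEX_FIELDS},
            index=subject_ids)
        corr_r, corr_p = pearson_matrix(echo_base, hrv_base)

        # ---- outputs ----------------------------------------------------
        stage = "write"
        header = [f"hrvreact {__version__}", f"seed: {config.seed}",
                  f"delta_convention: {criteria.delta_convention}",
                  f"L: {L}", f"skip_s: {skip_s}",
                  f"welch: {welch.resample_hz} Hz, nperseg {welch.nperseg}, "
                  f"{welch.window}, overlap {welch.overlap}"]
        tables = {
            "indexes.csv": indexes_df,
            "deltas.csv": deltas_df,
            "labels.csv": label_df,
            "roc_table.csv": roc_df,
            "hrv_summary.csv": summary_df,
            "delta_group_comparison.csv": comparison_df,
            "echo_paired.csv": echo_df,
        }
        for fname, df in tables.items():
            _write_csv(df, out_dir / fname, header)
        _write_csv(corr_r, out_dir / "correlations_r.csv", header, index=True)
        _write_csv(corr_p, out_dir / "correlations_p.csv", header, index=True)

        stage = "manifest"
        digests = {}
        for path in sorted(out_dir.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                digests[str(path.relative_to(out_dir))] = _sha256(path)
        manifest = RunManifest(seed=config.seed,
                               config=json.loads(json.dumps(dataclasses.asdict(config))),
                               version=__version__, digests=digests,
                               warnings=warn_list)
        (out_dir / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
        return manifest
    except HRVReactError as exc:
        (out_dir / "failed").write_text(f"stage: {stage}\n{exc}\n", encoding="utf-8")
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc
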